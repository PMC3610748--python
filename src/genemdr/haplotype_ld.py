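"""Pairwise LD, Gabriel block calling, and haplotype likelihood-ratio tests.

Pairwise LD between two SNPs is summarised by Lewontin's D' (two-locus
haplotype frequencies estimated by EM from unphased genotypes), the log10
likelihood ratio against linkage equilibrium (LOD), and a two-sided 90%
confidence interval on |D'| from the normalised likelihood over a grid of D'
values. Gabriel blocks are contiguous SNP runs in which at least 95% of the
informative pairs show "strong LD" (CI low >= 0.70 and CI high >= 0.98;
"strong recombination" is CI high < 0.90).

Within each block, group-specific versus pooled EM haplotype frequencies give
the overall likelihood-ratio test, and a target-versus-rest collapse gives the
individual haplotype test; both take their p-values from case/control label
permutation, p = (b+1)/(B+1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import em
from .datamodel import MISSING, Dataset
from .qc import bh_fdr

_TIE_EPS = 1e-12

# Gabriel block-calling defaults (published thresholds of the cited method)
STRONG_LD_CI_LOW = 0.70
STRONG_LD_CI_HIGH = 0.98
RECOMB_CI_HIGH = 0.90
STRONG_FRACTION = 0.95


@dataclass(frozen=True)
class LdPair:
    i: int
    j: int
    dprime: float
    lod: float
    ci_low: float
    ci_high: float

    @property
    def strong_ld(self) -> bool:
        return self.ci_low >= STRONG_LD_CI_LOW and self.ci_high >= STRONG_LD_CI_HIGH

    @property
    def strong_recombination(self) -> bool:
        return self.ci_high < RECOMB_CI_HIGH


@dataclass
class HaplotypeBlock:
    gene: str
    snp_indices: list[int]  # dataset column indices, contiguous in map order
    haplotypes: list[tuple[str, float, float, float]]  # (alleles, case, control, combined)


def _two_locus_freqs_grid(p_a: float, p_b: float, d_values: np.ndarray) -> np.ndarray:
    """Haplotype frequency vectors [f00,f01,f10,f11] for a grid of D values."""
    f11 = p_a * p_b + d_values
    f10 = p_a * (1 - p_b) - d_values
    f01 = (1 - p_a) * p_b - d_values
    f00 = (1 - p_a) * (1 - p_b) + d_values
    return np.clip(np.stack([f00, f01, f10, f11], axis=1), 0.0, 1.0)


def pairwise_ld(g1: np.ndarray, g2: np.ndarray, seed: int = 0) -> LdPair:
    """Lewontin D', LOD and a 90% CI on |D'| for one SNP pair.

    Samples missing at either SNP are dropped. The CI comes from the
    likelihood of the genotype data over a 0.01-step grid of D' in [0,1]
    (sign fixed at the MLE's sign, allele frequencies fixed at their sample
    values), normalised to a unit mass; the interval cuts 5% from each tail.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    keep = (g1 != MISSING) & (g2 != MISSING)
    geno = np.stack([g1[keep], g2[keep]], axis=1)
    p_a = geno[:, 0].mean() / 2.0
    p_b = geno[:, 1].mean() / 2.0
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise ValueError("pairwise LD needs both SNPs polymorphic")

    patterns, counts = em.pattern_counts(geno)
    expansion = em.PatternExpansion(patterns)
    res = em.em_from_expansion(expansion, counts, seed=seed)
    f = res.freqs  # [f00, f01, f10, f11] with bit0 = SNP2 allele
    p11 = f[3]
    d = p11 - p_a * p_b
    if d >= 0:
        dmax = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        dmax = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    dprime = 0.0 if dmax <= 0 else min(abs(d) / dmax, 1.0)

    le = _two_locus_freqs_grid(p_a, p_b, np.array([0.0]))[0]
    ll_le = expansion.loglik(le, counts)
    lod = max((res.loglik - ll_le) / np.log(10.0), 0.0)

    grid = np.linspace(0.0, 1.0, 101)
    sign = 1.0 if d >= 0 else -1.0
    freq_grid = _two_locus_freqs_grid(p_a, p_b, sign * grid * dmax)
    ll = np.array([expansion.loglik(fg, counts) for fg in freq_grid])
    lik = np.exp(ll - ll.max())
    total = lik.sum()
    csum = np.cumsum(lik)
    ci_low = float(grid[np.searchsorted(csum, 0.05 * total)])
    rsum = np.cumsum(lik[::-1])
    ci_high = float(grid[::-1][np.searchsorted(rsum, 0.05 * total)])
    return LdPair(i=0, j=1, dprime=float(dprime), lod=float(lod), ci_low=ci_low, ci_high=ci_high)


def gabriel_blocks(
    pairs: dict[tuple[int, int], LdPair],
    n_snps: int,
    max_block_snps: int = 8,
) -> list[tuple[int, int]]:
    """Call maximal non-overlapping Gabriel blocks from within-gene LD pairs.

    ``pairs`` maps local index pairs (i < j) to their LdPair. A contiguous run
    is a candidate when >= 95% of its informative pairs (strong LD or strong
    recombination) are strong LD; candidates are chosen greedily by size.
    Returns (start, end) inclusive local index ranges.
    """
    candidates = []
    for a in range(n_snps - 1):
        for b in range(a + 1, min(n_snps, a + max_block_snps)):
            strong = informative = 0
            for i in range(a, b):
                for j in range(i + 1, b + 1):
                    p = pairs.get((i, j))
                    if p is None:  # e.g. a monomorphic SNP: uninformative
                        continue
                    if p.strong_ld:
                        strong += 1
                        informative += 1
                    elif p.strong_recombination:
                        informative += 1
            if informative >= 1 and strong >= 1 and strong / informative >= STRONG_FRACTION:
                candidates.append((b - a + 1, a, b))
    blocks: list[tuple[int, int]] = []
    used = np.zeros(n_snps, dtype=bool)
    for size, a, b in sorted(candidates, key=lambda t: (-t[0], t[1])):
        if not used[a : b + 1].any():
            blocks.append((a, b))
            used[a : b + 1] = True
    return sorted(blocks)


def em_haplotype_frequencies(
    genotypes: np.ndarray, seed: int = 0, restarts: int = 5
) -> np.ndarray:
    """ML haplotype frequencies for a SNP set (columns) via EM."""
    res = em.em_frequencies(genotypes, seed=seed, restarts=restarts)
    return res.freqs


def _collapsed_g(
    p_case: float, p_ctrl: float, p_pool: float, n_case: int, n_ctrl: int
) -> float:
    """1-df G statistic for target-vs-other collapsed haplotype frequencies.

    Evaluated on EM-expected allele counts (2n per group)."""

    def term(p_g: float, n_g: int) -> float:
        c = 2 * n_g * p_g
        rest = 2 * n_g - c
        out = 0.0
        if c > 0 and p_pool > 0:
            out += c * np.log(p_g / p_pool)
        if rest > 0 and p_pool < 1:
            out += rest * np.log((1 - p_g) / (1 - p_pool))
        return out

    if p_pool <= 0 or p_pool >= 1:
        return 0.0
    return max(2.0 * (term(p_case, n_case) + term(p_ctrl, n_ctrl)), 0.0)


def block_lr_tests(
    genotypes: np.ndarray,
    case_mask: np.ndarray,
    n_permutations: int,
    seed: int = 0,
    copy_floor: int = 2,
) -> dict:
    """Overall + individual haplotype LR tests for one block.

    Returns a dict with combined/group frequencies, the overall LR and raw p,
    and per-target (haplotype index) LR and raw p. Targets are haplotypes
    whose estimated combined copy count is at least ``copy_floor``. The same
    permutation stream serves the overall and all individual tests; per-
    permutation EM runs are warm-started at the pooled frequencies.
    """
    genotypes = np.asarray(genotypes, dtype=np.int8)
    case_mask = np.asarray(case_mask, dtype=bool)
    n, m = genotypes.shape
    n_case = int(case_mask.sum())
    n_ctrl = n - n_case

    patterns, pat_of = np.unique(genotypes, axis=0, return_inverse=True)
    expansion = em.PatternExpansion(patterns)
    n_pat = len(patterns)
    counts_comb = np.bincount(pat_of, minlength=n_pat).astype(float)
    ss = np.random.SeedSequence(seed)
    s_comb, s_case, s_ctrl, s_perm = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(4))

    res_comb = em.em_from_expansion(expansion, counts_comb, seed=s_comb)
    counts_case = np.bincount(pat_of[case_mask], minlength=n_pat).astype(float)
    counts_ctrl = counts_comb - counts_case
    res_case = em.em_from_expansion(expansion, counts_case, seed=s_case)
    res_ctrl = em.em_from_expansion(expansion, counts_ctrl, seed=s_ctrl)

    f_comb, f_case, f_ctrl = res_comb.freqs, res_case.freqs, res_ctrl.freqs
    lr_overall = max(2.0 * (res_case.loglik + res_ctrl.loglik - res_comb.loglik), 0.0)

    targets = [
        h for h in range(expansion.n_hap) if f_comb[h] * 2 * n >= copy_floor
    ]
    lr_ind = {
        h: _collapsed_g(f_case[h], f_ctrl[h], f_comb[h], n_case, n_ctrl)
        for h in targets
    }

    rng = np.random.default_rng(s_perm)
    b_overall = 0
    b_ind = {h: 0 for h in targets}
    for _ in range(n_permutations):
        perm = rng.permutation(case_mask)
        c_case = np.bincount(pat_of[perm], minlength=n_pat).astype(float)
        c_ctrl = counts_comb - c_case
        r_case = em.em_from_expansion(expansion, c_case, init=f_comb)
        r_ctrl = em.em_from_expansion(expansion, c_ctrl, init=f_comb)
        lr_p = 2.0 * (r_case.loglik + r_ctrl.loglik - res_comb.loglik)
        if lr_p >= lr_overall - _TIE_EPS:
            b_overall += 1
        for h in targets:
            g = _collapsed_g(r_case.freqs[h], r_ctrl.freqs[h], f_comb[h], n_case, n_ctrl)
            if g >= lr_ind[h] - _TIE_EPS:
                b_ind[h] += 1

    return {
        "freqs_combined": f_comb,
        "freqs_case": f_case,
        "freqs_control": f_ctrl,
        "overall_lr": lr_overall,
        "overall_p": (b_overall + 1) / (n_permutations + 1),
        "targets": targets,
        "individual_lr": lr_ind,
        "individual_p": {h: (b_ind[h] + 1) / (n_permutations + 1) for h in targets},
        "n_haplotypes_df": max(int((f_comb * 2 * n >= copy_floor).sum()) - 1, 1),
    }


def overall_haplotype_lr_test(
    genotypes: np.ndarray, case_mask: np.ndarray, n_permutations: int, seed: int = 0
) -> tuple[float, float]:
    """Overall haplotype LR test; returns (LR, permutation raw p)."""
    r = block_lr_tests(genotypes, case_mask, n_permutations, seed=seed)
    return r["overall_lr"], r["overall_p"]


def individual_haplotype_lr_test(
    genotypes: np.ndarray,
    case_mask: np.ndarray,
    target: int,
    n_permutations: int,
    seed: int = 0,
    copy_floor: int = 2,
) -> tuple[float, float]:
    """Individual (target-vs-other) haplotype LR test; returns (LR, raw p).

    Raises ValueError when the target's estimated combined copies are below
    the copy floor (test skipped).
    """
    r = block_lr_tests(genotypes, case_mask, n_permutations, seed=seed, copy_floor=copy_floor)
    if target not in r["targets"]:
        raise ValueError(
            f"haplotype {target} below the {copy_floor}-copy floor; test skipped"
        )
    return r["individual_lr"][target], r["individual_p"][target]


def _hap_string(h: int, snps, m: int) -> str:
    alleles = em.hap_alleles(h, m)
    return "".join(snps[k].alleles[alleles[k]] for k in range(m))


def run_haplotype_scan(
    dataset: Dataset,
    n_permutations: int = 10_000,
    seed: int = 0,
    max_block_snps: int = 8,
    copy_floor: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list[HaplotypeBlock]]:
    """Per-gene LD -> Gabriel blocks -> overall + individual LR tests.

    Returns (ld table, block table, test results, blocks). pFDR_H is BH-FDR
    over all overall-and-individual raw p-values in the scan (one family per
    analysis set).
    """
    ss = np.random.SeedSequence(seed)
    ld_rows = []
    block_rows = []
    result_rows = []
    blocks_out: list[HaplotypeBlock] = []
    genes = sorted(dataset.gene_map)
    gene_seeds = {g: s for g, s in zip(genes, ss.spawn(len(genes)))}

    for gene in genes:
        cols = dataset.gene_map[gene]
        if len(cols) < 2:
            continue
        gseed = gene_seeds[gene]
        pair_seeds = gseed.spawn(len(cols) * (len(cols) - 1) // 2 + len(cols))
        pairs: dict[tuple[int, int], LdPair] = {}
        k = 0
        for a in range(len(cols) - 1):
            for b in range(a + 1, len(cols)):
                try:
                    lp = pairwise_ld(
                        dataset.genotypes[:, cols[a]],
                        dataset.genotypes[:, cols[b]],
                        seed=int(pair_seeds[k].generate_state(1)[0] % 2**31),
                    )
                except ValueError:  # monomorphic in this analysis set
                    k += 1
                    continue
                k += 1
                pairs[(a, b)] = LdPair(a, b, lp.dprime, lp.lod, lp.ci_low, lp.ci_high)
                ld_rows.append(
                    {
                        "gene": gene,
                        "snp_i": dataset.snps[cols[a]].snp_id,
                        "snp_j": dataset.snps[cols[b]].snp_id,
                        "dprime": lp.dprime,
                        "lod": lp.lod,
                        "ci_low": lp.ci_low,
                        "ci_high": lp.ci_high,
                    }
                )
        spans = gabriel_blocks(pairs, len(cols), max_block_snps=max_block_snps)
        for bi, (a, b) in enumerate(spans):
            block_cols = cols[a : b + 1]
            m = len(block_cols)
            tests = block_lr_tests(
                dataset.genotypes[:, block_cols],
                dataset.case_mask,
                n_permutations,
                seed=int(pair_seeds[min(k + bi, len(pair_seeds) - 1)].generate_state(1)[0] % 2**31),
                copy_floor=copy_floor,
            )
            block_snps = [dataset.snps[c] for c in block_cols]
            block_label = f"{gene}_block{bi + 1}"
            haplotypes = [
                (
                    _hap_string(h, block_snps, m),
                    float(tests["freqs_case"][h]),
                    float(tests["freqs_control"][h]),
                    float(tests["freqs_combined"][h]),
                )
                for h in tests["targets"]
            ]
            blocks_out.append(
                HaplotypeBlock(gene=gene, snp_indices=list(block_cols), haplotypes=haplotypes)
            )
            block_rows.append(
                {
                    "gene": gene,
                    "block": block_label,
                    "snps": ",".join(s.snp_id for s in block_snps),
                    "n_snps": m,
                }
            )
            df_overall = tests["n_haplotypes_df"]
            result_rows.append(
                {
                    "gene": gene,
                    "block": block_label,
                    "test": "overall",
                    "haplotype": "-",
                    "freq_case": np.nan,
                    "freq_control": np.nan,
                    "freq_combined": np.nan,
                    "lr": tests["overall_lr"],
                    "asym_p": float(stats.chi2.sf(tests["overall_lr"], df_overall)),
                    "raw_p": tests["overall_p"],
                }
            )
            for h in tests["targets"]:
                result_rows.append(
                    {
                        "gene": gene,
                        "block": block_label,
                        "test": "individual",
                        "haplotype": _hap_string(h, block_snps, m),
                        "freq_case": float(tests["freqs_case"][h]),
                        "freq_control": float(tests["freqs_control"][h]),
                        "freq_combined": float(tests["freqs_combined"][h]),
                        "lr": tests["individual_lr"][h],
                        "asym_p": float(stats.chi2.sf(tests["individual_lr"][h], 1)),
                        "raw_p": tests["individual_p"][h],
                    }
                )

    ld_df = pd.DataFrame(ld_rows)
    block_df = pd.DataFrame(block_rows)
    result_df = pd.DataFrame(result_rows)
    if len(result_df):
        result_df["pfdr_h"] = bh_fdr(result_df["raw_p"].to_numpy())
    else:
        result_df["pfdr_h"] = pd.Series(dtype=float)
    return ld_df, block_df, result_df, blocks_out
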