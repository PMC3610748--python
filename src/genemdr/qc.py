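"""Sequential sample/SNP quality control and missing-genotype imputation.

The exclusion procedure is sequential: (1) samples with genotyping call rate
(GCR) < 0.9, (2) SNPs with GCR < 0.9 in the case *or* control group, (3) SNPs
with minor allele frequency < 0.01, (4) SNPs whose exact Hardy-Weinberg test
in the control group has an FDR-adjusted p-value < 0.05. Each rule is
evaluated on the data remaining after the earlier rules, thresholds are strict
inequalities, and a removed entity is tagged with the first rule that fired.

Missing genotypes in the cleaned data are then imputed by within-gene
EM-haplotype posterior sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from . import em
from .datamodel import MISSING, DataError, Dataset


@dataclass(frozen=True)
class QcThresholds:
    """Thresholds of the sequential QC procedure (all strict inequalities)."""

    gcr_min: float = 0.9
    maf_min: float = 0.01
    hwe_alpha: float = 0.05  # on the FDR-adjusted scale
    hwe_permutations: int = 10_000

    def __post_init__(self) -> None:
        for name in ("gcr_min", "maf_min", "hwe_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if self.hwe_permutations < 1:
            raise ValueError("hwe_permutations must be >= 1")


@dataclass
class QcReport:
    """What QC removed, why, in what order, plus the per-SNP evidence table."""

    removed_samples: list[tuple[str, float]] = field(default_factory=list)
    removed_snps: list[tuple[str, str, float]] = field(default_factory=list)
    snp_table: Optional[pd.DataFrame] = None
    imputed_fraction: float = 0.0
    thresholds: Optional[QcThresholds] = None


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def sample_call_rates(dataset: Dataset) -> np.ndarray:
    """Per-sample fraction of non-missing genotype calls."""
    if dataset.n_snps < 1:
        raise DataError("need at least one SNP")
    return (dataset.genotypes != MISSING).mean(axis=1)


def snp_group_call_rates(dataset: Dataset) -> pd.DataFrame:
    """Per-SNP call rate in the case and control groups."""
    case = dataset.case_mask
    called = dataset.genotypes != MISSING
    return pd.DataFrame(
        {
            "snp_id": dataset.snp_ids,
            "gcr_case": called[case].mean(axis=0),
            "gcr_control": called[~case].mean(axis=0),
        }
    )


def minor_allele_frequency(codes: np.ndarray) -> float:
    """MAF over the non-missing genotypes of one SNP (codes 0/1/2)."""
    codes = np.asarray(codes)
    obs = codes[codes != MISSING]
    if obs.size == 0:
        raise DataError("all genotypes missing; MAF undefined")
    p = obs.sum() / (2.0 * obs.size)
    return float(min(p, 1.0 - p))


def _levene_pmf(n_het_values: np.ndarray, n: int, n_minor: int) -> np.ndarray:
    """Exact conditional distribution of the heterozygote count given allele counts."""
    n_major = 2 * n - n_minor
    h = n_het_values.astype(float)
    n_mm = (n_minor - n_het_values) / 2.0
    n_MM = (n_major - n_het_values) / 2.0
    logp = (
        gammaln(n + 1)
        - gammaln(n_mm + 1)
        - gammaln(h + 1)
        - gammaln(n_MM + 1)
        + h * np.log(2.0)
        + gammaln(n_minor + 1)
        + gammaln(n_major + 1)
        - gammaln(2 * n + 1)
    )
    return np.exp(logp)


def hwe_exact_test(
    n_hom_major: int,
    n_het: int,
    n_hom_minor: int,
    permutations: int = 10_000,
    seed: int = 0,
    method: str = "auto",
) -> float:
    """Exact Hardy-Weinberg test p-value for one SNP's genotype counts.

    The null distribution is Levene's conditional distribution of the
    heterozygote count given the allele counts; the p-value is the total
    probability of tables at most as probable as the observed one
    (probability-mass convention).

    ``method='enumerate'`` sums the full conditional distribution;
    ``method='permute'`` draws ``permutations`` tables from it — the exact
    distribution induced by randomly permuting the alleles into genotypes —
    and reports (b+1)/(B+1). ``'auto'`` enumerates when 2n <= 200.
    """
    if min(n_hom_major, n_het, n_hom_minor) < 0:
        raise DataError("negative genotype counts")
    n = n_hom_major + n_het + n_hom_minor
    if n < 1:
        raise DataError("empty genotype table")
    n_minor = 2 * n_hom_minor + n_het
    n_minor = min(n_minor, 2 * n - n_minor)  # symmetric in allele labels
    if n_minor == 0:
        return 1.0
    het_values = np.arange(n_minor % 2, n_minor + 1, 2)
    pmf = _levene_pmf(het_values, n, n_minor)
    pmf = pmf / pmf.sum()
    p_obs = pmf[np.searchsorted(het_values, n_het)]
    if method == "auto":
        method = "enumerate" if 2 * n <= 200 else "permute"
    if method == "enumerate":
        return float(min(pmf[pmf <= p_obs * (1 + 1e-12)].sum(), 1.0))
    if method == "permute":
        rng = np.random.default_rng(seed)
        draws = rng.choice(len(het_values), size=permutations, p=pmf)
        b = int((pmf[draws] <= p_obs * (1 + 1e-12)).sum())
        return (b + 1) / (permutations + 1)
    raise ValueError(f"unknown method {method!r}")


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise DataError("p-values must be in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# the sequential procedure
# ---------------------------------------------------------------------------

def apply_qc(dataset: Dataset, thresholds: QcThresholds = QcThresholds()) -> tuple[Dataset, QcReport]:
    """Run the four sequential exclusion rules; returns (clean data, report)."""
    report = QcReport(thresholds=thresholds)

    # rule 1: sample call rate
    rates = sample_call_rates(dataset)
    keep_samples = rates >= thresholds.gcr_min
    for i in np.flatnonzero(~keep_samples):
        report.removed_samples.append((dataset.samples[i].sample_id, float(rates[i])))
    if not keep_samples.any():
        raise DataError("QC removed every sample")
    d = dataset.subset(sample_idx=np.flatnonzero(keep_samples))
    if not (d.case_mask.any() and (~d.case_mask).any()):
        raise DataError("QC left no cases or no controls")

    removed_rule: dict[str, tuple[str, float]] = {}

    # rule 2: SNP call rate per group (flag if below threshold in either group)
    gcr = snp_group_call_rates(d)
    low = (gcr["gcr_case"] < thresholds.gcr_min) | (gcr["gcr_control"] < thresholds.gcr_min)
    for j in np.flatnonzero(low.to_numpy()):
        value = float(min(gcr["gcr_case"][j], gcr["gcr_control"][j]))
        removed_rule[d.snps[j].snp_id] = ("group_gcr", value)
    d = _drop_snps(d, low.to_numpy())

    # rule 3: minor allele frequency (combined sample, after earlier removals)
    mafs = np.array([minor_allele_frequency(d.genotypes[:, j]) for j in range(d.n_snps)])
    low = mafs < thresholds.maf_min
    for j in np.flatnonzero(low):
        removed_rule[d.snps[j].snp_id] = ("maf", float(mafs[j]))
    d = _drop_snps(d, low)
    mafs = mafs[~low]

    # rule 4: exact HWE in controls, FDR across the surviving SNPs
    ctrl = d.genotypes[~d.case_mask]
    hwe_raw = np.empty(d.n_snps)
    for j in range(d.n_snps):
        col = ctrl[:, j]
        obs = col[col != MISSING]
        counts = np.bincount(obs, minlength=3)
        hwe_raw[j] = hwe_exact_test(
            int(counts[0]), int(counts[1]), int(counts[2]),
            permutations=thresholds.hwe_permutations,
            seed=_hwe_seed(d.snps[j].snp_id),
        )
    hwe_adj = bh_fdr(hwe_raw)
    low = hwe_adj < thresholds.hwe_alpha
    for j in np.flatnonzero(low):
        removed_rule[d.snps[j].snp_id] = ("hwe", float(hwe_adj[j]))
    snp_evidence = pd.DataFrame(
        {
            "snp_id": d.snp_ids,
            "maf": mafs,
            "hwe_raw_p": hwe_raw,
            "hwe_pfdr": hwe_adj,
        }
    )
    d = _drop_snps(d, low)

    if d.n_snps == 0:
        raise DataError("QC removed every SNP")

    for snp_id, (rule, value) in removed_rule.items():
        report.removed_snps.append((snp_id, rule, value))

    gcr_full = snp_group_call_rates(dataset.subset(sample_idx=np.flatnonzero(keep_samples)))
    report.snp_table = gcr_full.merge(snp_evidence, on="snp_id", how="left")
    report.imputed_fraction = float((d.genotypes == MISSING).mean())
    return d, report


def _drop_snps(d: Dataset, mask: np.ndarray) -> Dataset:
    if mask.any():
        return d.subset(snp_idx=np.flatnonzero(~mask))
    return d


def _hwe_seed(snp_id: str) -> int:
    # stable per-SNP stream for the Monte-Carlo HWE path
    return (hash_str(snp_id) ^ 0x5DEECE66) % (2**31)


def hash_str(s: str) -> int:
    h = 2166136261
    for ch in s.encode():
        h = (h ^ ch) * 16777619 % (2**32)
    return h


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def impute_missing(
    dataset: Dataset,
    seed: int = 0,
    method: str = "haplotype",
    window: int = 5,
) -> Dataset:
    """Replace every missing genotype; returns a new Dataset.

    ``method='haplotype'`` (default): for each gene, EM haplotype frequencies
    are fitted on a window of up to ``window`` SNPs around each missing call
    (the whole gene when it is at most that size) and the missing code is
    drawn from the haplotype-pair posterior given the sample's observed
    genotypes in the window. Single-SNP genes, and ``method='marginal'``,
    fall back to sampling from the SNP's combined-sample genotype
    distribution. All non-missing codes are preserved.
    """
    rng = np.random.default_rng(seed)
    geno = dataset.genotypes.copy()
    missing_cols = np.flatnonzero((geno == MISSING).any(axis=0))
    if missing_cols.size == 0:
        return dataset

    col_to_gene = {}
    for gene, idx in dataset.gene_map.items():
        for pos_in_gene, j in enumerate(idx):
            col_to_gene[j] = (gene, pos_in_gene)

    em_cache: dict[tuple[int, ...], np.ndarray] = {}

    for j in sorted(missing_cols):
        gene, pos_in_gene = col_to_gene[j]
        gene_cols = dataset.gene_map[gene]
        use_marginal = method == "marginal" or len(gene_cols) == 1
        if not use_marginal:
            win_cols = _window_columns(gene_cols, pos_in_gene, window)
            key = tuple(win_cols)
            if key not in em_cache:
                try:
                    res = em.em_frequencies(geno[:, win_cols], seed=int(rng.integers(2**31)))
                    em_cache[key] = res.freqs
                except em.EmConvergenceError as err:
                    em_cache[key] = err.best.freqs
            freqs = em_cache[key]
            k = win_cols.index(j)
            m = len(win_cols)
            for i in np.flatnonzero(geno[:, j] == MISSING):
                pattern = geno[i, win_cols]
                h1, h2 = em.sample_pair(freqs, pattern, rng)
                geno[i, j] = ((h1 >> (m - 1 - k)) & 1) + ((h2 >> (m - 1 - k)) & 1)
        else:
            col = geno[:, j]
            obs = col[col != MISSING]
            if obs.size == 0:
                raise DataError(f"SNP {dataset.snps[j].snp_id}: no observed genotypes")
            probs = np.bincount(obs, minlength=3) / obs.size
            fill = rng.choice(3, size=int((col == MISSING).sum()), p=probs)
            geno[col == MISSING, j] = fill

    out = Dataset(
        genotypes=geno,
        samples=dataset.samples,
        snps=dataset.snps,
        gene_map=dataset.gene_map,
    )
    return out


def _window_columns(gene_cols: list[int], pos_in_gene: int, window: int) -> list[int]:
    if len(gene_cols) <= window:
        return list(gene_cols)
    half = window // 2
    start = min(max(0, pos_in_gene - half), len(gene_cols) - window)
    return list(gene_cols[start : start + window])
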