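"""Seeded synthetic case-control cohorts for every pipeline stage.

The generator emulates the structure the analysis assumes: ~10 genes of 3-21
SNPs each, within-gene LD organised as segments of shared haplotypes joined by
free recombination, a retrospective case-control design (893 cases / 554
controls by default), an optional rare case-enriched risk haplotype (~1.24%
carrier probability in cases, 0 in controls), optional marginal-null epistatic
penetrance effects, CPT endophenotype strata proportions, and ~0.57% random
missingness.

Genes are simulated independently (no between-gene LD), as for genes on
different chromosomes. All randomness flows from a single master seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .datamodel import (
    MISSING,
    DataError,
    Dataset,
    SampleRecord,
    SnpAnnotation,
    recode_to_minor,
)
from . import io as gio

DEFAULT_GENE_SIZES = (15, 7, 10, 4, 21, 9, 5, 4, 3, 6)
#: CPT stratum proportions for cases: (at_or_above -2.5, below -2.5, missing)
DEFAULT_ZD_PROPORTIONS = (0.50, 0.33, 0.17)
DEFAULT_ZMD_PROPORTIONS = (0.39, 0.41, 0.20)


@dataclass
class HaplotypePool:
    """Per-gene haplotype distribution, stored per LD segment.

    ``segments`` is a list of (haplotype allele matrix, frequency vector);
    haplotypes of a gene are the product across segments (independent
    segments = free recombination between them, full LD structure within).
    """

    gene: str
    segments: list[tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        for haps, freqs in self.segments:
            if abs(freqs.sum() - 1.0) > 1e-9:
                raise DataError(f"gene {self.gene}: segment frequencies must sum to 1")
            if haps.shape[0] != len(freqs):
                raise DataError(f"gene {self.gene}: haplotype/frequency length mismatch")

    @property
    def n_snps(self) -> int:
        return sum(h.shape[1] for h, _ in self.segments)

    def flat(self) -> list[tuple[str, float]]:
        """Explicit gene-level pool: full-length haplotype strings + frequencies."""
        strings = [""]
        freqs = [1.0]
        for haps, f in self.segments:
            strings = [
                s + "".join(map(str, haps[k]))
                for s in strings
                for k in range(len(f))
            ]
            freqs = [w * fk for w in freqs for fk in f]
        return list(zip(strings, freqs))

    def allele_frequencies(self) -> np.ndarray:
        """Expected frequency of allele 1 at each SNP."""
        out = []
        for haps, f in self.segments:
            out.append(f @ haps)
        return np.concatenate(out)

    def sample_haplotypes(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n haplotypes (rows of 0/1 alleles over the whole gene)."""
        parts = []
        for haps, f in self.segments:
            idx = rng.choice(len(f), size=n, p=f)
            parts.append(haps[idx])
        return np.concatenate(parts, axis=1)


@dataclass
class PenetranceModel:
    """Disease probability per multilocus genotype of a small SNP combination.

    ``snps`` are (gene index, snp-within-gene index) pairs; ``table`` maps the
    base-3 encoded genotype combination to P(disease).
    """

    snps: list[tuple[int, int]]
    table: np.ndarray  # (3^order,)

    def __post_init__(self) -> None:
        order = len(self.snps)
        self.table = np.asarray(self.table, dtype=float)
        if self.table.shape != (3**order,):
            raise DataError(f"penetrance table must cover all {3**order} combinations")
        if np.any((self.table < 0) | (self.table > 1)):
            raise DataError("penetrance values must be probabilities")


@dataclass
class RareHaplotypePlan:
    """Planted rare risk haplotype: carriers get one copy at fixed positions."""

    gene_index: int
    positions: tuple[int, ...]  # SNP indices within the gene
    alleles: tuple[int, ...]  # risk alleles (0/1) at those positions
    carrier_prob_case: float = 0.0124
    carrier_prob_control: float = 0.0


@dataclass
class SimulationConfig:
    gene_sizes: tuple[int, ...] = DEFAULT_GENE_SIZES
    n_case: int = 893
    n_control: int = 554
    baseline_prevalence: float = 0.05
    penetrance_models: list[PenetranceModel] = field(default_factory=list)
    rare_haplotype: Optional[RareHaplotypePlan] = None
    zd_proportions: tuple[float, float, float] = DEFAULT_ZD_PROPORTIONS
    zmd_proportions: tuple[float, float, float] = DEFAULT_ZMD_PROPORTIONS
    missing_rate: float = 0.0057
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.gene_sizes):
            raise DataError("gene sizes must be positive")
        if not 0 <= self.missing_rate < 1:
            raise DataError("missing rate must be in [0,1)")
        for name in ("zd_proportions", "zmd_proportions"):
            p = getattr(self, name)
            if abs(sum(p) - 1.0) > 1e-9:
                raise DataError(f"{name} must sum to 1")


# ---------------------------------------------------------------------------
# pools
# ---------------------------------------------------------------------------

def build_gene_pools(
    config: SimulationConfig,
    seed: Optional[int] = None,
    max_segment: int = 5,
) -> list[HaplotypePool]:
    """Random per-gene segment pools with high within-segment LD.

    Each gene is split into LD segments of at most ``max_segment`` SNPs; each
    segment gets 2-4 distinct haplotypes with Dirichlet frequencies,
    resampled until every SNP has expected MAF >= 0.05. Two-locus D' within a
    segment is high by construction (few haplotypes); between segments it is
    0 in expectation.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pools = []
    for g, size in enumerate(config.gene_sizes):
        segments = []
        remaining = size
        while remaining > 0:
            seg = int(min(remaining, rng.integers(2, max_segment + 1)))
            if remaining - seg == 1:
                seg = remaining  # avoid stranding a single-SNP segment
            seg = min(seg, remaining)
            segments.append(_random_segment(seg, rng))
            remaining -= seg
        pools.append(HaplotypePool(gene=f"G{g + 1:02d}", segments=segments))
    return pools


def _random_segment(
    n_snps: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    for _ in range(200):
        k = int(rng.integers(2, 5)) if n_snps > 1 else 2
        k = min(k, 2**n_snps)
        haps = rng.integers(0, 2, size=(k, n_snps))
        if len(np.unique(haps, axis=0)) < k:
            continue
        freqs = rng.dirichlet(np.full(k, 2.0))
        af = freqs @ haps
        if np.all((af >= 0.05) & (af <= 0.95)):
            return haps.astype(np.int8), freqs
    raise DataError("could not draw a feasible segment recipe")


def segment_pool(haplotypes: Sequence[str], freqs: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Build one explicit segment from haplotype strings + frequencies."""
    freqs = np.asarray(freqs, dtype=float)
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise DataError("segment frequencies must sum to 1")
    haps = np.array([[int(c) for c in h] for h in haplotypes], dtype=np.int8)
    return haps, freqs


# ---------------------------------------------------------------------------
# planted effects
# ---------------------------------------------------------------------------

def plant_rare_risk_haplotype(
    pools: list[HaplotypePool],
    gene_index: int,
    positions: Sequence[int],
    alleles: Sequence[int],
    carrier_prob_case: float = 0.0124,
    carrier_prob_control: float = 0.0,
) -> RareHaplotypePlan:
    """Define the rare risk-haplotype carrier rule; validates positions."""
    pool = pools[gene_index]
    if any(p < 0 or p >= pool.n_snps for p in positions):
        raise DataError(f"positions outside gene {pool.gene}")
    if not (0 <= carrier_prob_case <= 1 and 0 <= carrier_prob_control <= 1):
        raise DataError("carrier probabilities must be in [0,1]")
    return RareHaplotypePlan(
        gene_index=gene_index,
        positions=tuple(int(p) for p in positions),
        alleles=tuple(int(a) for a in alleles),
        carrier_prob_case=carrier_prob_case,
        carrier_prob_control=carrier_prob_control,
    )


def hwe_cell_probs(allele_freqs: Sequence[float]) -> np.ndarray:
    """HWE genotype-cell probabilities for independent SNPs (base-3 encoding)."""
    probs = np.ones(1)
    for p in allele_freqs:
        g = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
        probs = np.outer(probs, g).ravel()
    return probs


def plant_epistasis(
    pools: list[HaplotypePool],
    snps: Sequence[tuple[int, int]],
    target_balanced_accuracy: float,
    baseline_prevalence: float = 0.05,
) -> PenetranceModel:
    """Two-SNP marginal-null epistatic penetrance with a target Bayes accuracy.

    Starts from an XOR-style pattern on the genotype parity, double-centres it
    with HWE weights so each SNP's marginal disease probability (hence its
    case/control allele-frequency contrast) is exactly null, and scales the
    pattern so the optimal MDR rule achieves the requested balanced accuracy
    in expectation. Raises when the target is unreachable at these allele
    frequencies.
    """
    if not 0.5 <= target_balanced_accuracy <= 1.0:
        raise DataError("target balanced accuracy must be in [0.5, 1]")
    if len(snps) != 2:
        raise DataError("epistasis planting supports SNP pairs")
    afs = [pools[g].allele_frequencies()[k] for g, k in snps]
    w1 = np.array([(1 - afs[0]) ** 2, 2 * afs[0] * (1 - afs[0]), afs[0] ** 2])
    w2 = np.array([(1 - afs[1]) ** 2, 2 * afs[1] * (1 - afs[1]), afs[1] ** 2])
    g1, g2 = np.meshgrid(np.arange(3), np.arange(3), indexing="ij")
    pattern = np.where((g1 + g2) % 2 == 1, 1.0, -1.0)
    # weighted double-centring: zero marginal mean in each row and column
    row = (pattern * w2[None, :]).sum(axis=1)
    col = (pattern * w1[:, None]).sum(axis=0)
    grand = float(w1 @ pattern @ w2)
    pattern = pattern - row[:, None] - col[None, :] + grand
    cell_probs = np.outer(w1, w2)

    def bayes_ba(scale: float) -> float:
        f = baseline_prevalence * (1.0 + scale * pattern)
        prev = float((cell_probs * f).sum())
        p_case = cell_probs * f / prev
        p_ctrl = cell_probs * (1 - f) / (1 - prev)
        return 0.5 + 0.25 * float(np.abs(p_case - p_ctrl).sum())

    # keep every cell's penetrance inside [0, 1]
    lim = np.max(np.abs(pattern))
    scale_max = min(
        1.0 / lim, (1 - baseline_prevalence) / (baseline_prevalence * lim)
    ) * 0.999
    if target_balanced_accuracy <= bayes_ba(0.0) + 1e-12:
        scale = 0.0
    elif target_balanced_accuracy > bayes_ba(scale_max):
        raise DataError(
            f"target accuracy {target_balanced_accuracy} unreachable "
            f"(max {bayes_ba(scale_max):.4f} at these allele frequencies)"
        )
    else:
        scale = brentq(
            lambda s: bayes_ba(s) - target_balanced_accuracy, 0.0, scale_max
        )
    table = baseline_prevalence * (1.0 + scale * pattern)
    return PenetranceModel(snps=list(snps), table=table.ravel())


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------

def _disease_prob(
    hap_pairs: list[np.ndarray], models: list[PenetranceModel], baseline: float
) -> np.ndarray:
    """P(disease) per individual under multiplicative relative risks."""
    n = hap_pairs[0].shape[0]
    p = np.full(n, baseline)
    for model in models:
        codes = np.zeros(n, dtype=np.int64)
        for g, k in model.snps:
            geno = hap_pairs[g][:, 0, k] + hap_pairs[g][:, 1, k]
            codes = codes * 3 + geno
        p = p * model.table[codes] / baseline
    return np.clip(p, 0.0, 1.0)


def simulate_cohort(
    pools: list[HaplotypePool],
    n_case: int,
    n_control: int,
    penetrance_models: Optional[list[PenetranceModel]] = None,
    seed: int = 0,
    baseline_prevalence: float = 0.05,
    rare_haplotype: Optional[RareHaplotypePlan] = None,
) -> Dataset:
    """Retrospective sampling of a case-control cohort.

    Individuals are drawn as two haplotypes per gene (independent across
    genes); disease status is Bernoulli in the penetrance; draws are accepted
    into the case/control quotas until both are filled. The rare risk
    haplotype, if planted, is injected post-acceptance: a carrier gets the
    risk alleles written onto one chromosome at the designated positions.
    Genotype codes are recoded so they count the combined-sample minor allele.
    """
    models = penetrance_models or []
    rng = np.random.default_rng(seed)
    need_case, need_ctrl = n_case, n_control
    case_haps: list[list[np.ndarray]] = []
    ctrl_haps: list[list[np.ndarray]] = []
    max_rounds = 4000
    for _ in range(max_rounds):
        if need_case <= 0 and need_ctrl <= 0:
            break
        batch = int(min(20000, max(2000, 4 * (need_case / max(baseline_prevalence, 1e-3) + need_ctrl))))
        hap_pairs = [
            np.stack(
                [pool.sample_haplotypes(batch, rng), pool.sample_haplotypes(batch, rng)],
                axis=1,
            )
            for pool in pools
        ]  # per gene: (batch, 2, n_snps)
        p = _disease_prob(hap_pairs, models, baseline_prevalence)
        is_case = rng.random(batch) < p
        take_case = np.flatnonzero(is_case)[:need_case]
        take_ctrl = np.flatnonzero(~is_case)[:need_ctrl]
        for sel, bucket in ((take_case, case_haps), (take_ctrl, ctrl_haps)):
            if len(sel):
                bucket.append([hp[sel] for hp in hap_pairs])
        need_case -= len(take_case)
        need_ctrl -= len(take_ctrl)
    if need_case > 0 or need_ctrl > 0:
        raise DataError(
            "could not fill case/control quotas; penetrance model incompatible"
        )

    def concat(buckets: list[list[np.ndarray]]) -> list[np.ndarray]:
        return [np.concatenate([b[g] for b in buckets], axis=0) for g in range(len(pools))]

    case_h = concat(case_haps)
    ctrl_h = concat(ctrl_haps)

    if rare_haplotype is not None:
        _inject_carriers(case_h, rare_haplotype, rare_haplotype.carrier_prob_case, rng)
        _inject_carriers(ctrl_h, rare_haplotype, rare_haplotype.carrier_prob_control, rng)

    blocks = []
    for g in range(len(pools)):
        both = np.concatenate([case_h[g], ctrl_h[g]], axis=0)
        blocks.append(both[:, 0, :] + both[:, 1, :])
    codes = np.concatenate(blocks, axis=1).astype(np.int8)

    snps: list[SnpAnnotation] = []
    allele_pairs: list[tuple[str, str]] = []
    for g, pool in enumerate(pools):
        for k in range(pool.n_snps):
            snps.append(
                SnpAnnotation(
                    snp_id=f"{pool.gene}_s{k + 1}",
                    gene=pool.gene,
                    chromosome=f"chr{g + 1}",
                    position=10_000 + 1_000 * k,
                    alleles=("A", "G"),
                )
            )
            allele_pairs.append(("A", "G"))

    codes, allele_pairs = recode_to_minor(codes, allele_pairs)
    snps = [
        SnpAnnotation(s.snp_id, s.gene, s.chromosome, s.position, allele_pairs[j])
        for j, s in enumerate(snps)
    ]
    samples = [SampleRecord(f"case{i + 1:04d}", "case") for i in range(n_case)] + [
        SampleRecord(f"ctrl{i + 1:04d}", "control") for i in range(n_control)
    ]
    gene_map: dict[str, list[int]] = {}
    j = 0
    for pool in pools:
        gene_map[pool.gene] = list(range(j, j + pool.n_snps))
        j += pool.n_snps
    return Dataset(genotypes=codes, samples=samples, snps=snps, gene_map=gene_map)


def _inject_carriers(
    haps: list[np.ndarray],
    plan: RareHaplotypePlan,
    prob: float,
    rng: np.random.Generator,
) -> None:
    if prob <= 0:
        return
    gene_h = haps[plan.gene_index]
    carriers = rng.random(gene_h.shape[0]) < prob
    for i in np.flatnonzero(carriers):
        chrom = int(rng.integers(2))
        for pos, allele in zip(plan.positions, plan.alleles):
            gene_h[i, chrom, pos] = allele


# ---------------------------------------------------------------------------
# CPT scores and missingness
# ---------------------------------------------------------------------------

def simulate_cpt_scores(
    dataset: Dataset,
    zd_proportions: tuple[float, float, float] = DEFAULT_ZD_PROPORTIONS,
    zmd_proportions: tuple[float, float, float] = DEFAULT_ZMD_PROPORTIONS,
    seed: int = 0,
    threshold: float = -2.5,
) -> Dataset:
    """Assign zd/zmd z-scores to cases (controls stay unmeasured).

    Per measure each case lands in (at_or_above, below, missing) with the
    given proportions; the numeric score is uniform within its side of the
    threshold (only the side matters downstream).
    """
    for name, p in (("zd", zd_proportions), ("zmd", zmd_proportions)):
        if abs(sum(p) - 1.0) > 1e-9:
            raise DataError(f"{name} proportions must sum to 1")
    rng = np.random.default_rng(seed)
    samples = []
    for s in dataset.samples:
        if not s.is_case:
            samples.append(s)
            continue
        values = {}
        for name, props in (("zd", zd_proportions), ("zmd", zmd_proportions)):
            u = rng.random()
            if u < props[0]:
                values[name] = float(rng.uniform(threshold, threshold + 4.0))
            elif u < props[0] + props[1]:
                values[name] = float(rng.uniform(threshold - 2.5, threshold))
            else:
                values[name] = None
        samples.append(SampleRecord(s.sample_id, s.status, zd=values["zd"], zmd=values["zmd"]))
    return Dataset(dataset.genotypes.copy(), samples, dataset.snps, dataset.gene_map)


def inject_missingness(dataset: Dataset, rate: float, seed: int = 0) -> Dataset:
    """Set each genotype to MISSING independently with the given probability."""
    if not 0 <= rate < 1:
        raise DataError("missing rate must be in [0,1)")
    if rate == 0:
        return dataset
    rng = np.random.default_rng(seed)
    mask = rng.random(dataset.genotypes.shape) < rate
    geno = dataset.genotypes.copy()
    geno[mask] = MISSING
    return Dataset(geno, dataset.samples, dataset.snps, dataset.gene_map)


def simulate_dataset(config: SimulationConfig, pools: Optional[list[HaplotypePool]] = None) -> Dataset:
    """Full recipe: pools -> cohort -> CPT scores -> missingness."""
    ss = np.random.SeedSequence(config.seed)
    s_pool, s_cohort, s_cpt, s_miss = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(4))
    if pools is None:
        pools = build_gene_pools(config, seed=s_pool)
    d = simulate_cohort(
        pools,
        config.n_case,
        config.n_control,
        config.penetrance_models,
        seed=s_cohort,
        baseline_prevalence=config.baseline_prevalence,
        rare_haplotype=config.rare_haplotype,
    )
    d = simulate_cpt_scores(
        d, config.zd_proportions, config.zmd_proportions, seed=s_cpt
    )
    return inject_missingness(d, config.missing_rate, seed=s_miss)


# ---------------------------------------------------------------------------
# benchmark scenarios
# ---------------------------------------------------------------------------

def scenario_config(name: str, seed: int) -> tuple[SimulationConfig, list[HaplotypePool]]:
    """The four benchmark scenarios: null / marginal / haplotype / epistasis."""
    if name == "null":
        cfg = SimulationConfig(gene_sizes=(3, 3), n_case=300, n_control=300, seed=seed)
        pools = build_gene_pools(cfg)
        return cfg, pools
    if name == "marginal":
        # one SNP with an additive risk allele (case/control allele-frequency
        # contrast around 0.36 vs 0.28, mirroring a strong single-locus hit)
        cfg = SimulationConfig(gene_sizes=(3, 3), seed=seed)
        pools = build_gene_pools(cfg)
        afs = pools[0].allele_frequencies()
        b = 0.05
        model = PenetranceModel(
            snps=[(0, 1)], table=np.array([b, 1.45 * b, 2.1 * b])
        )
        cfg.penetrance_models = [model]
        return cfg, pools
    if name == "haplotype":
        cfg = SimulationConfig(gene_sizes=(5, 4), seed=seed)
        pools = [
            HaplotypePool(
                gene="G01",
                # every allele frequency stays clear of 0.5 so the minor-
                # allele orientation is stable across sampled cohorts
                segments=[
                    segment_pool(["000", "011", "110"], [0.55, 0.27, 0.18]),
                    segment_pool(["00", "01", "11"], [0.55, 0.25, 0.2]),
                ],
            ),
            build_gene_pools(SimulationConfig(gene_sizes=(4,), seed=seed + 1))[0],
        ]
        pools[1].gene = "G02"
        # risk triplet 010 is absent from the segment pool yet pairwise-
        # compatible with its gametes, so the planted copies leave D' = 1
        # within the block (as a real in-block rare haplotype would)
        cfg.rare_haplotype = plant_rare_risk_haplotype(
            pools, 0, positions=(0, 1, 2), alleles=(0, 1, 0)
        )
        return cfg, pools
    if name == "epistasis":
        # one 4-haplotype segment per gene: within-gene LD without any two
        # SNP columns being copies, so the planted SNPs stay identifiable
        cfg = SimulationConfig(gene_sizes=(3, 3), seed=seed)
        pools = [
            HaplotypePool(
                gene="G01",
                segments=[segment_pool(["000", "011", "101", "110"], [0.35, 0.25, 0.2, 0.2])],
            ),
            HaplotypePool(
                gene="G02",
                segments=[segment_pool(["000", "110", "011", "101"], [0.4, 0.25, 0.2, 0.15])],
            ),
        ]
        cfg.penetrance_models = [
            plant_epistasis(pools, [(0, 1), (1, 0)], target_balanced_accuracy=0.60)
        ]
        return cfg, pools
    raise DataError(f"unknown scenario {name!r}")


def generate_benchmark_suite(out_dir: str, master_seed: int = 0) -> dict[str, str]:
    """Write the four scenarios as VCF + phenotype TSV + gene map TSV.

    Returns scenario name -> directory. Each directory round-trips through
    :func:`genemdr.io.load_dataset`.
    """
    ss = np.random.SeedSequence(master_seed)
    seeds = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(4)]
    out = {}
    for name, seed in zip(("null", "marginal", "haplotype", "epistasis"), seeds):
        cfg, pools = scenario_config(name, seed)
        d = simulate_dataset(cfg, pools=pools)
        sdir = os.path.join(out_dir, name)
        os.makedirs(sdir, exist_ok=True)
        # express codes as alt-allele counts: alt = the counted (minor) allele
        gio.write_vcf(
            {
                "sample_ids": d.sample_ids,
                "snp_ids": d.snp_ids,
                "chromosomes": [s.chromosome for s in d.snps],
                "positions": [s.position for s in d.snps],
                "ref": [s.alleles[0] for s in d.snps],
                "alt": [s.alleles[1] for s in d.snps],
                "codes": d.genotypes,
            },
            os.path.join(sdir, "genotypes.vcf"),
        )
        gio.write_phenotypes(d.samples, os.path.join(sdir, "phenotypes.tsv"))
        gio.write_gene_map(d.snps, os.path.join(sdir, "genemap.tsv"))
        out[name] = sdir
    return out
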