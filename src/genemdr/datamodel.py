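"""Core data model for the case-control SNP analysis pipeline.

The single object flowing through every stage is a :class:`Dataset`: a
samples x SNPs genotype matrix coded as minor-allele counts (0/1/2, with
``MISSING = -1``), plus per-sample phenotype records, per-SNP annotations and
a gene map assigning each SNP to exactly one candidate gene.

Genotype coding convention: the minor allele is defined on the *combined*
case+control sample, so a code of 2 always means "homozygous for the allele
that is rarer overall". Loaders are responsible for recoding to this
convention (see :func:`recode_to_minor`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

#: Sentinel for a missing genotype call.
MISSING: int = -1

CASE = "case"
CONTROL = "control"


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass(frozen=True)
class SnpAnnotation:
    """Annotation for one biallelic SNP.

    ``alleles`` is the ordered pair (major, minor) with minor defined by
    combined-sample frequency; ``position`` is 1-based (VCF convention).
    """

    snp_id: str
    gene: str
    chromosome: str
    position: int
    alleles: tuple[str, str]
    function_tag: Optional[str] = None

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise DataError(f"SNP {self.snp_id}: position must be positive")
        if self.alleles[0] == self.alleles[1]:
            raise DataError(f"SNP {self.snp_id}: alleles must be distinct")


@dataclass(frozen=True)
class SampleRecord:
    """One study subject: disease status plus optional CPT z-scores.

    ``zd``/``zmd`` are the unmasked / 25%-masked sustained-attention
    sensitivity z-scores; controls are expected to have neither.
    """

    sample_id: str
    status: str
    zd: Optional[float] = None
    zmd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.status not in (CASE, CONTROL):
            raise DataError(
                f"sample {self.sample_id}: status must be 'case' or 'control', "
                f"got {self.status!r}"
            )

    @property
    def is_case(self) -> bool:
        return self.status == CASE


@dataclass(frozen=True)
class StratumSpec:
    """One CPT endophenotype stratum: cases split on a z-score threshold.

    The canonical analysis uses four strata: {zd, zmd} x {below, at_or_above}
    at threshold -2.5 (z < -2.5 defines the attention-deficit subgroup).
    """

    name: str
    measure: str  # "zd" | "zmd"
    relation: str  # "below" | "at_or_above"
    threshold: float = -2.5

    def __post_init__(self) -> None:
        if self.measure not in ("zd", "zmd"):
            raise DataError(f"stratum {self.name}: measure must be zd or zmd")
        if self.relation not in ("below", "at_or_above"):
            raise DataError(
                f"stratum {self.name}: relation must be below or at_or_above"
            )
        if not np.isfinite(self.threshold):
            raise DataError(f"stratum {self.name}: threshold must be finite")

    def accepts(self, value: Optional[float]) -> bool:
        """Does a case with this measure value belong to the stratum?"""
        if value is None or not np.isfinite(value):
            return False
        if self.relation == "below":
            return value < self.threshold
        return value >= self.threshold


#: The four canonical CPT strata at the standard deficit threshold.
CANONICAL_STRATA: tuple[StratumSpec, ...] = (
    StratumSpec("zd_below", "zd", "below"),
    StratumSpec("zd_at_or_above", "zd", "at_or_above"),
    StratumSpec("zmd_below", "zmd", "below"),
    StratumSpec("zmd_at_or_above", "zmd", "at_or_above"),
)


@dataclass
class Dataset:
    """Genotypes + samples + SNP annotations + gene map.

    ``genotypes`` is an ``(n_samples, n_snps)`` int8 array of minor-allele
    counts with ``MISSING`` (-1) for no-calls. ``gene_map`` maps gene symbol
    to the column indices of its SNPs, ordered by physical position.
    """

    genotypes: np.ndarray
    samples: list[SampleRecord]
    snps: list[SnpAnnotation]
    gene_map: dict[str, list[int]]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n, m = self.genotypes.shape
        if n != len(self.samples):
            raise DataError(
                f"genotype rows ({n}) != number of samples ({len(self.samples)})"
            )
        if m != len(self.snps):
            raise DataError(
                f"genotype columns ({m}) != number of SNPs ({len(self.snps)})"
            )
        vals = self.genotypes
        ok = (vals == MISSING) | ((vals >= 0) & (vals <= 2))
        if not ok.all():
            raise DataError("genotype codes must be in {0,1,2} or MISSING")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise DataError("snp_id values must be unique")
        sids = [s.sample_id for s in self.samples]
        if len(set(sids)) != len(sids):
            raise DataError("sample_id values must be unique")
        if not any(s.is_case for s in self.samples) or not any(
            not s.is_case for s in self.samples
        ):
            raise DataError("dataset needs at least one case and one control")
        seen: set[int] = set()
        for gene, idx in self.gene_map.items():
            for j in idx:
                if j in seen:
                    raise DataError(f"SNP index {j} assigned to more than one gene")
                seen.add(j)
                if self.snps[j].gene != gene:
                    raise DataError(
                        f"gene map / annotation mismatch for {self.snps[j].snp_id}"
                    )
            pos = [self.snps[j].position for j in idx]
            if any(b <= a for a, b in zip(pos, pos[1:])):
                raise DataError(f"gene {gene}: SNPs not strictly increasing in position")
        if seen != set(range(m)):
            missing = sorted(set(range(m)) - seen)
            raise DataError(
                f"every SNP must belong to exactly one gene; unassigned columns {missing}"
            )

    # -- convenience --------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def case_mask(self) -> np.ndarray:
        return np.array([s.is_case for s in self.samples], dtype=bool)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def subset(
        self,
        sample_idx: Optional[Sequence[int]] = None,
        snp_idx: Optional[Sequence[int]] = None,
    ) -> "Dataset":
        """New Dataset restricted to the given sample/SNP indices (order kept)."""
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        snps = [self.snps[j] for j in vi]
        remap = {int(old): new for new, old in enumerate(vi)}
        gene_map: dict[str, list[int]] = {}
        for gene, idx in self.gene_map.items():
            kept = [remap[j] for j in idx if j in remap]
            if kept:
                gene_map[gene] = kept
        return Dataset(
            genotypes=self.genotypes[np.ix_(si, vi)].copy(),
            samples=[self.samples[i] for i in si],
            snps=snps,
            gene_map=gene_map,
        )


def recode_to_minor(
    codes: np.ndarray, alleles: list[tuple[str, str]]
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Flip genotype codes so that the counted allele is the combined-sample minor.

    ``codes`` counts ``alleles[j][1]``; wherever that allele's frequency
    exceeds 0.5 the codes are flipped (0 <-> 2) and the allele pair swapped.
    Ties (frequency exactly 0.5) keep the incoming orientation.
    """
    codes = np.asarray(codes, dtype=np.int8)
    out = codes.copy()
    new_alleles = list(alleles)
    for j in range(codes.shape[1]):
        col = codes[:, j]
        obs = col[col != MISSING]
        if obs.size == 0:
            continue
        freq = obs.sum() / (2.0 * obs.size)
        if freq > 0.5:
            flip = col != MISSING
            out[flip, j] = 2 - col[flip]
            a, b = new_alleles[j]
            new_alleles[j] = (b, a)
    return out, new_alleles


def stratify_samples(dataset: Dataset, spec: StratumSpec) -> Dataset:
    """Restrict a dataset to one CPT stratum.

    Cases are retained iff their stratum measure is present and satisfies the
    relation; cases without the measure drop out of both strata of that
    measure. All controls are retained in every stratum (controls have no CPT
    scores; each stratum compares its cases against the full control group).
    """
    keep = []
    for i, s in enumerate(dataset.samples):
        if not s.is_case:
            keep.append(i)
            continue
        value = s.zd if spec.measure == "zd" else s.zmd
        if spec.accepts(value):
            keep.append(i)
    sub = [dataset.samples[i] for i in keep]
    if not any(s.is_case for s in sub):
        raise DataError(f"stratum {spec.name} leaves zero cases")
    return dataset.subset(sample_idx=keep)
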