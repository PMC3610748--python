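"""Pipeline orchestration: QC -> imputation -> per-analysis-set scans.

The full run executes quality control once on the overall sample, imputes the
cleaned data, and then runs the single-locus, haplotype and interaction scans
on the overall sample and on each of the four CPT strata (stratum cases vs
all controls), reusing the same cleaned, imputed genotypes. A
``qc_per_stratum`` switch re-runs QC inside each stratum instead.

Outputs are TSV reports with fixed column order plus one JSON run summary;
re-running with the same inputs and seed yields byte-identical files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import io as gio
from .datamodel import CANONICAL_STRATA, DataError, Dataset, StratumSpec, stratify_samples
from .haplotype_ld import run_haplotype_scan
from .mdr import run_interaction_scan
from .qc import QcReport, QcThresholds, apply_qc, impute_missing
from .single_locus import run_single_locus_scan


@dataclass
class AnalysisConfig:
    """Every tunable of a full pipeline run."""

    qc: QcThresholds = field(default_factory=QcThresholds)
    b_assoc: int = 10_000  # permutations for single-locus and haplotype tests
    b_mdr: int = 1_000  # permutations for MDR candidate validation
    folds: int = 10
    max_order: int = 4
    cvc_min: float = 0.8
    fdr_alpha: float = 0.05
    max_block_snps: int = 8
    hap_copy_floor: int = 2
    balanced_accuracy: bool = True
    qc_per_stratum: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.b_assoc < 1 or self.b_mdr < 1:
            raise ValueError("permutation counts must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not 1 <= self.max_order <= 4:
            raise ValueError("max interaction order must be in 1..4")
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must be in (0,1)")

    @classmethod
    def from_toml(cls, path: str) -> "AnalysisConfig":
        """Load a config from a TOML file mirroring the field names."""
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        qc_raw = raw.pop("qc", {})
        return cls(qc=QcThresholds(**qc_raw), **raw)


@dataclass
class AnalysisSetResult:
    name: str
    n_case: int
    n_control: int
    single_locus: pd.DataFrame
    ld: pd.DataFrame
    blocks: pd.DataFrame
    haplotype: pd.DataFrame
    interactions: pd.DataFrame


@dataclass
class PipelineResult:
    qc_report: QcReport
    analysis_sets: dict[str, AnalysisSetResult]
    config: AnalysisConfig


def _analysis_sets(dataset: Dataset, use_strata: bool) -> list[tuple[str, Dataset]]:
    sets: list[tuple[str, Dataset]] = [("overall", dataset)]
    if use_strata:
        for spec in CANONICAL_STRATA:
            sets.append((spec.name, stratify_samples(dataset, spec)))
    return sets


def run_pipeline(
    dataset: Dataset,
    config: AnalysisConfig = AnalysisConfig(),
    use_strata: bool = True,
) -> PipelineResult:
    """QC -> imputation -> (overall + strata) x (single-locus, haplotype, MDR)."""
    ss = np.random.SeedSequence(config.seed)
    s_impute = int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)

    try:
        clean, report = apply_qc(dataset, config.qc)
    except DataError as err:
        raise DataError(f"qc: {err}") from err
    if not config.qc_per_stratum:
        clean = impute_missing(clean, seed=s_impute)

    sets = _analysis_sets(clean, use_strata)
    results: dict[str, AnalysisSetResult] = {}
    for (name, d), child in zip(sets, ss.spawn(len(sets))):
        s_sl, s_hap, s_mdr, s_imp = (
            int(c.generate_state(1)[0] % 2**31) for c in child.spawn(4)
        )
        if config.qc_per_stratum:
            try:
                d, _ = apply_qc(d, config.qc)
                d = impute_missing(d, seed=s_imp)
            except DataError as err:
                raise DataError(f"qc[{name}]: {err}") from err
        try:
            sl = run_single_locus_scan(d, n_permutations=config.b_assoc, seed=s_sl)
        except Exception as err:
            raise DataError(f"single_locus[{name}]: {err}") from err
        try:
            ld, blocks, hap, _ = run_haplotype_scan(
                d,
                n_permutations=config.b_assoc,
                seed=s_hap,
                max_block_snps=config.max_block_snps,
                copy_floor=config.hap_copy_floor,
            )
        except Exception as err:
            raise DataError(f"haplotype[{name}]: {err}") from err
        try:
            inter = run_interaction_scan(
                d,
                max_order=config.max_order,
                folds=config.folds,
                n_permutations=config.b_mdr,
                cvc_min=config.cvc_min,
                fdr_alpha=config.fdr_alpha,
                seed=s_mdr,
                balanced=config.balanced_accuracy,
            )
        except Exception as err:
            raise DataError(f"interaction[{name}]: {err}") from err
        results[name] = AnalysisSetResult(
            name=name,
            n_case=int(d.case_mask.sum()),
            n_control=int((~d.case_mask).sum()),
            single_locus=sl,
            ld=ld,
            blocks=blocks,
            haplotype=hap,
            interactions=inter,
        )
    return PipelineResult(qc_report=report, analysis_sets=results, config=config)


def write_outputs(result: PipelineResult, out_dir: str) -> list[str]:
    """Write every stage report as TSV plus one JSON run summary.

    Deterministic byte-for-byte given identical inputs, config and seed.
    """
    os.makedirs(out_dir, exist_ok=True)
    written: list[str] = []

    rep = result.qc_report
    path = os.path.join(out_dir, "qc_removed_samples.tsv")
    gio.write_table(
        pd.DataFrame(rep.removed_samples, columns=["sample_id", "gcr"]), path
    )
    written.append(path)
    path = os.path.join(out_dir, "qc_removed_snps.tsv")
    gio.write_table(
        pd.DataFrame(rep.removed_snps, columns=["snp_id", "rule", "value"]), path
    )
    written.append(path)
    if rep.snp_table is not None:
        path = os.path.join(out_dir, "qc_snp_table.tsv")
        gio.write_table(rep.snp_table, path)
        written.append(path)

    for name, aset in result.analysis_sets.items():
        for label, df in (
            ("single_locus", aset.single_locus),
            ("ld", aset.ld),
            ("blocks", aset.blocks),
            ("haplotype", aset.haplotype),
            ("interactions", aset.interactions),
        ):
            path = os.path.join(out_dir, f"{name}__{label}.tsv")
            gio.write_table(df, path)
            written.append(path)

    summary = {
        "genotype_coding": "count of combined-sample minor allele",
        "seed": result.config.seed,
        "b_assoc": result.config.b_assoc,
        "b_mdr": result.config.b_mdr,
        "folds": result.config.folds,
        "max_order": result.config.max_order,
        "cvc_min": result.config.cvc_min,
        "fdr_alpha": result.config.fdr_alpha,
        "qc_thresholds": {
            "gcr_min": result.config.qc.gcr_min,
            "maf_min": result.config.qc.maf_min,
            "hwe_alpha": result.config.qc.hwe_alpha,
            "hwe_permutations": result.config.qc.hwe_permutations,
        },
        "imputed_fraction": rep.imputed_fraction,
        "removed_samples": len(rep.removed_samples),
        "removed_snps": len(rep.removed_snps),
        "analysis_sets": {
            name: {"n_case": a.n_case, "n_control": a.n_control}
            for name, a in result.analysis_sets.items()
        },
    }
    path = os.path.join(out_dir, "run_summary.json")
    gio.write_json(summary, path)
    written.append(path)
    return written
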