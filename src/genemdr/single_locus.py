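"""Permutation genotype-, allele-, and trend-based single-locus tests.

Each SNP gets three statistics — Pearson chi-square on the 2x3 genotype table,
Pearson chi-square on the 2x2 allele table, and the Cochran-Armitage trend
statistic with additive scores (0,1,2) — with p-values from case/control label
permutation, p = (b+1)/(B+1). Benjamini-Hochberg FDR is applied separately per
test type within each analysis set (overall sample or CPT stratum), giving the
adjusted columns pFDR_SG, pFDR_SA and pFDR_ST.

One permutation stream is shared across SNPs per scan so a run is reproducible
from the master seed alone.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import Dataset
from .qc import bh_fdr

_TIE_EPS = 1e-12


# ---------------------------------------------------------------------------
# statistics on contingency tables
# ---------------------------------------------------------------------------

def _pearson_chi2(table: np.ndarray) -> float:
    """Pearson chi-square with zero-margin rows/columns dropped."""
    t = np.asarray(table, dtype=float)
    t = t[:, t.sum(axis=0) > 0]
    t = t[t.sum(axis=1) > 0, :]
    if t.shape[0] < 2 or t.shape[1] < 2:
        return 0.0
    exp = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    return float(((t - exp) ** 2 / exp).sum())


def genotype_association_test(table: np.ndarray) -> float:
    """Chi-square on the 2x3 case/control genotype table (zero columns dropped)."""
    return _pearson_chi2(table)


def allele_association_test(table: np.ndarray) -> float:
    """Chi-square on the 2x2 case/control allele-count table."""
    return _pearson_chi2(table)


def genotype_to_allele_table(table: np.ndarray) -> np.ndarray:
    """Collapse a 2x3 genotype table to the 2x2 allele table."""
    t = np.asarray(table, dtype=float)
    minor = t[:, 1] + 2 * t[:, 2]
    major = 2 * t[:, 0] + t[:, 1]
    return np.column_stack([major, minor])


def trend_test(table: np.ndarray, scores: tuple[float, ...] = (0.0, 1.0, 2.0)) -> float:
    """Cochran-Armitage trend statistic (additive genotype scores)."""
    t = np.asarray(table, dtype=float)
    s = np.asarray(scores, dtype=float)
    n = t.sum()
    cols = t.sum(axis=0)
    r = t[0].sum()  # cases
    if n == 0 or r == 0 or r == n:
        return 0.0
    num = float(np.dot(s, t[0]) - r * np.dot(s, cols) / n)
    var = r * (n - r) / n * (np.dot(s**2, cols) - np.dot(s, cols) ** 2 / n) / n
    if var <= 0:
        return 0.0
    return num**2 / var


# ---------------------------------------------------------------------------
# permutation machinery
# ---------------------------------------------------------------------------

def permutation_pvalue(
    observed: float,
    statistic: Callable[[np.ndarray], float],
    values: np.ndarray,
    labels: np.ndarray,
    n_permutations: int,
    seed: int = 0,
) -> float:
    """Generic label-permutation p-value, p = (b+1)/(B+1).

    ``statistic`` receives the 2x3 genotype count table built from ``values``
    (codes 0/1/2) and a permuted case indicator.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels, dtype=bool)
    b = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        tab = _count_table(values, perm)
        if statistic(tab) >= observed - _TIE_EPS:
            b += 1
    return (b + 1) / (n_permutations + 1)


def _count_table(values: np.ndarray, case_mask: np.ndarray) -> np.ndarray:
    case = np.bincount(values[case_mask], minlength=3)[:3]
    ctrl = np.bincount(values[~case_mask], minlength=3)[:3]
    return np.vstack([case, ctrl])


def _vector_stats(case_counts: np.ndarray, totals: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Genotype/allele/trend statistics for many 2x3 tables at once.

    ``case_counts`` is (B, 3); ``totals`` the fixed column totals (3,).
    Returns three length-B arrays.
    """
    ctrl_counts = totals[None, :] - case_counts
    n = totals.sum()
    r = case_counts.sum(axis=1)

    # genotype chi-square with zero-total columns dropped (totals fixed)
    live = totals > 0
    t_case = case_counts[:, live].astype(float)
    t_ctrl = ctrl_counts[:, live].astype(float)
    tot = totals[live].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        e_case = r[:, None] * tot[None, :] / n
        e_ctrl = (n - r)[:, None] * tot[None, :] / n
        chi_g = np.nansum((t_case - e_case) ** 2 / e_case, axis=1) + np.nansum(
            (t_ctrl - e_ctrl) ** 2 / e_ctrl, axis=1
        )
    if live.sum() < 2:
        chi_g = np.zeros(case_counts.shape[0])

    # allele chi-square
    minor_case = case_counts[:, 1] + 2 * case_counts[:, 2]
    minor_tot = totals[1] + 2 * totals[2]
    n_all = 2 * n
    r_all = 2 * r
    with np.errstate(invalid="ignore", divide="ignore"):
        e11 = r_all * minor_tot / n_all
        e10 = r_all * (n_all - minor_tot) / n_all
        e01 = (n_all - r_all) * minor_tot / n_all
        e00 = (n_all - r_all) * (n_all - minor_tot) / n_all
        major_case = r_all - minor_case
        minor_ctrl = minor_tot - minor_case
        major_ctrl = (n_all - minor_tot) - major_case
        chi_a = (
            (minor_case - e11) ** 2 / e11
            + (major_case - e10) ** 2 / e10
            + (minor_ctrl - e01) ** 2 / e01
            + (major_ctrl - e00) ** 2 / e00
        )
    if minor_tot == 0 or minor_tot == n_all:
        chi_a = np.zeros(case_counts.shape[0])
    chi_a = np.nan_to_num(chi_a, nan=0.0, posinf=0.0)

    # Cochran-Armitage trend, scores (0,1,2)
    s = np.array([0.0, 1.0, 2.0])
    sc = float(np.dot(s, totals))
    s2c = float(np.dot(s**2, totals))
    num = case_counts @ s - r * sc / n
    var = r * (n - r) / n * (s2c - sc**2 / n) / n
    with np.errstate(invalid="ignore", divide="ignore"):
        chi_t = np.where(var > 0, num**2 / var, 0.0)
    return chi_g, chi_a, chi_t


def run_single_locus_scan(
    dataset: Dataset,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """All three tests for every SNP, permutation p-values, per-test FDR.

    Returns one row per SNP with the observed statistics, asymptotic
    chi-square p-values (diagnostic), permutation raw p-values and the
    BH-adjusted columns pfdr_sg / pfdr_sa / pfdr_st.
    """
    case_mask = dataset.case_mask
    n = dataset.n_samples
    n_case = int(case_mask.sum())
    rng = np.random.default_rng(seed)
    # one shared permutation stream: row b = a permuted choice of case indices
    perm_cases = np.empty((n_permutations, n_case), dtype=np.int32)
    for b in range(n_permutations):
        perm_cases[b] = rng.choice(n, size=n_case, replace=False)

    rows = []
    for j in range(dataset.n_snps):
        codes = dataset.genotypes[:, j].astype(np.int64)
        totals = np.bincount(codes, minlength=3)[:3]
        obs_case = np.bincount(codes[case_mask], minlength=3)[:3]
        obs_g, obs_a, obs_t = (
            float(x[0]) for x in _vector_stats(obs_case[None, :], totals)
        )

        perm_codes = codes[perm_cases]  # (B, n_case)
        case_counts = np.stack([(perm_codes == k).sum(axis=1) for k in range(3)], axis=1)
        chi_g, chi_a, chi_t = _vector_stats(case_counts, totals)
        p_g = (np.sum(chi_g >= obs_g - _TIE_EPS) + 1) / (n_permutations + 1)
        p_a = (np.sum(chi_a >= obs_a - _TIE_EPS) + 1) / (n_permutations + 1)
        p_t = (np.sum(chi_t >= obs_t - _TIE_EPS) + 1) / (n_permutations + 1)

        live_cols = int((totals > 0).sum())
        df_g = max(live_cols - 1, 1)
        rows.append(
            {
                "snp_id": dataset.snps[j].snp_id,
                "gene": dataset.snps[j].gene,
                "stat_genotype": obs_g,
                "stat_allele": obs_a,
                "stat_trend": obs_t,
                "asym_p_genotype": float(stats.chi2.sf(obs_g, df_g)) if obs_g > 0 else 1.0,
                "asym_p_allele": float(stats.chi2.sf(obs_a, 1)) if obs_a > 0 else 1.0,
                "asym_p_trend": float(stats.chi2.sf(obs_t, 1)) if obs_t > 0 else 1.0,
                "raw_p_genotype": p_g,
                "raw_p_allele": p_a,
                "raw_p_trend": p_t,
            }
        )
    out = pd.DataFrame(rows)
    out["pfdr_sg"] = bh_fdr(out["raw_p_genotype"].to_numpy())
    out["pfdr_sa"] = bh_fdr(out["raw_p_allele"].to_numpy())
    out["pfdr_st"] = bh_fdr(out["raw_p_trend"].to_numpy())
    return out
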