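"""Gene-based multifactor dimensionality reduction (MDR) interaction scan.

MDR pools multilocus genotype cells into high/low risk by the training-fold
case:control ratio and scores the pooled rule as a binary classifier on the
held-out fold. For every gene (within-gene scan) and every unordered gene
pair (between-gene scan) all SNP combinations of order 1-4 are evaluated by
10-fold stratified cross-validation; the combination with the highest average
testing accuracy is the best model. A within-gene interaction requires a best
model of order >= 2; a between-gene interaction requires the best model to
span both genes; both additionally require cross-validation consistency
(folds in which the combination is fold-best) >= 0.8. Candidates are
validated by label permutation of the full CV score and the empirical
p-values are BH-FDR adjusted separately for the within-gene and between-gene
families (pFDR_WG / pFDR_BG).

Testing accuracy is balanced accuracy, (sensitivity + specificity)/2, because
the study design is unbalanced (case:control about 893:554); raw accuracy is
available via ``balanced=False``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import Dataset
from .qc import bh_fdr

_TIE_EPS = 1e-12


# ---------------------------------------------------------------------------
# combination enumeration and cell machinery
# ---------------------------------------------------------------------------

def enumerate_snp_combinations(
    snp_indices: Sequence[int], max_order: int = 4
) -> list[tuple[int, ...]]:
    """All subsets of size 1..min(4, n), in (order, lexicographic) order."""
    snp_indices = sorted(snp_indices)
    combos: list[tuple[int, ...]] = []
    for order in range(1, min(max_order, len(snp_indices)) + 1):
        combos.extend(itertools.combinations(snp_indices, order))
    return combos


def encode_cells(genotypes: np.ndarray, combo: Sequence[int]) -> np.ndarray:
    """Map each sample to its multilocus genotype cell index (base-3)."""
    powers = 3 ** np.arange(len(combo) - 1, -1, -1)
    return genotypes[:, list(combo)].astype(np.int64) @ powers


def mdr_train_cells(
    cells: np.ndarray, case_mask: np.ndarray, n_cells: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Label cells high/low risk from training counts.

    Threshold T = training cases / training controls; a non-empty cell is
    high iff caseCount >= T * controlCount (ties high; a cell with cases and
    zero controls is high). Empty cells carry no label and are predicted
    control at evaluation. Returns (case counts, control counts, high mask).
    """
    case_counts = np.bincount(cells[case_mask], minlength=n_cells).astype(float)
    ctrl_counts = np.bincount(cells[~case_mask], minlength=n_cells).astype(float)
    t_num = case_counts.sum()
    t_den = ctrl_counts.sum()
    high = (case_counts * t_den >= t_num * ctrl_counts) & (case_counts + ctrl_counts > 0)
    return case_counts, ctrl_counts, high


def mdr_evaluate(
    high: np.ndarray,
    cells_eval: np.ndarray,
    case_mask_eval: np.ndarray,
    balanced: bool = True,
) -> float:
    """Score the high/low rule on evaluation samples.

    High cells predict case, everything else (low, empty, unseen) predicts
    control. Balanced accuracy = (sensitivity + specificity)/2.
    """
    pred_case = high[cells_eval]
    n_case = case_mask_eval.sum()
    n_ctrl = (~case_mask_eval).sum()
    tp = float(np.sum(pred_case & case_mask_eval))
    tn = float(np.sum(~pred_case & ~case_mask_eval))
    if balanced:
        sens = tp / n_case if n_case else 0.0
        spec = tn / n_ctrl if n_ctrl else 0.0
        return 0.5 * (sens + spec)
    return (tp + tn) / (n_case + n_ctrl)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class MdrCvResult:
    combo: tuple[int, ...]
    fold_accuracy: np.ndarray  # (folds,)
    avg_testing_accuracy: float
    cvc: int


def stratified_folds(
    case_mask: np.ndarray, folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Class-stratified fold assignment (0..folds-1 per sample)."""
    n = len(case_mask)
    out = np.empty(n, dtype=np.int64)
    for mask in (case_mask, ~case_mask):
        idx = np.flatnonzero(mask)
        if len(idx) < folds:
            raise ValueError(f"class with {len(idx)} members < {folds} folds")
        perm = rng.permutation(idx)
        out[perm] = np.arange(len(perm)) % folds
    return out


def _combo_fold_accuracies(
    cells: np.ndarray,
    case_mask: np.ndarray,
    fold_id: np.ndarray,
    folds: int,
    n_cells: int,
    balanced: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """(held-out, training) accuracy per fold for one encoded combination."""
    # per-(cell, fold) counts in two bincounts, then train = total - fold
    key = cells * folds + fold_id
    case_cf = np.bincount(key[case_mask], minlength=n_cells * folds).reshape(n_cells, folds)
    ctrl_cf = np.bincount(key[~case_mask], minlength=n_cells * folds).reshape(n_cells, folds)
    case_tot = case_cf.sum(axis=1, keepdims=True)
    ctrl_tot = ctrl_cf.sum(axis=1, keepdims=True)
    train_case = case_tot - case_cf  # (n_cells, folds)
    train_ctrl = ctrl_tot - ctrl_cf
    t_num = train_case.sum(axis=0)  # (folds,)
    t_den = train_ctrl.sum(axis=0)
    high = (train_case * t_den[None, :] >= t_num[None, :] * train_ctrl) & (
        train_case + train_ctrl > 0
    )

    def score(case_cf_: np.ndarray, ctrl_cf_: np.ndarray) -> np.ndarray:
        tp = (case_cf_ * high).sum(axis=0)
        tn = (ctrl_cf_ * ~high).sum(axis=0)
        n_case = case_cf_.sum(axis=0)
        n_ctrl = ctrl_cf_.sum(axis=0)
        if balanced:
            with np.errstate(invalid="ignore", divide="ignore"):
                sens = np.where(n_case > 0, tp / n_case, 0.0)
                spec = np.where(n_ctrl > 0, tn / n_ctrl, 0.0)
            return 0.5 * (sens + spec)
        return (tp + tn) / np.maximum(n_case + n_ctrl, 1)

    return score(case_cf, ctrl_cf), score(train_case, train_ctrl)


def mdr_cross_validate(
    genotypes: np.ndarray,
    case_mask: np.ndarray,
    combos: Sequence[tuple[int, ...]],
    folds: int = 10,
    seed: int = 0,
    balanced: bool = True,
    fold_id: Optional[np.ndarray] = None,
) -> list[MdrCvResult]:
    """CV testing accuracy and CV consistency for every combination.

    A combination's cvc is the number of folds in which it is the fold-best
    model *of its order* by training accuracy (the selection the original MDR
    software repeats on each 9/10 training portion; ties broken
    lexicographically). Held-out fold accuracies give avg_testing_accuracy.
    """
    case_mask = np.asarray(case_mask, dtype=bool)
    if fold_id is None:
        rng = np.random.default_rng(seed)
        fold_id = stratified_folds(case_mask, folds, rng)
    acc = np.empty((len(combos), folds))
    train_acc = np.empty((len(combos), folds))
    for c, combo in enumerate(combos):
        cells = encode_cells(genotypes, combo)
        acc[c], train_acc[c] = _combo_fold_accuracies(
            cells, case_mask, fold_id, folds, 3 ** len(combo), balanced
        )
    # per order: fold winner by training accuracy (ties to enumeration order)
    cvc = np.zeros(len(combos), dtype=int)
    orders = np.array([len(c) for c in combos])
    for order in np.unique(orders):
        members = np.flatnonzero(orders == order)
        for f in range(folds):
            col = train_acc[members, f]
            winner = members[np.argmax(col > col.max() - _TIE_EPS)]
            cvc[winner] += 1
    return [
        MdrCvResult(
            combo=tuple(combos[c]),
            fold_accuracy=acc[c].copy(),
            avg_testing_accuracy=float(acc[c].mean()),
            cvc=int(cvc[c]),
        )
        for c in range(len(combos))
    ]


def select_best_model(results: Sequence[MdrCvResult]) -> MdrCvResult:
    """Highest average testing accuracy; ties by higher cvc, lower order, lex."""
    if not results:
        raise ValueError("no CV results")
    return min(
        results,
        key=lambda r: (-r.avg_testing_accuracy, -r.cvc, len(r.combo), r.combo),
    )


def order_champions(results: Sequence[MdrCvResult]) -> list[MdrCvResult]:
    """The most consistently chosen model of each order.

    Mirrors the MDR software's summary: per order, the model selected on the
    most training folds (highest cvc; ties by higher testing accuracy, then
    lexicographic). The final cross-order comparison by testing accuracy then
    runs on these champions, which keeps overfit higher-order models from
    displacing a consistently chosen lower-order one.
    """
    champs: list[MdrCvResult] = []
    for order in sorted({len(r.combo) for r in results}):
        members = [r for r in results if len(r.combo) == order]
        champs.append(
            min(members, key=lambda r: (-r.cvc, -r.avg_testing_accuracy, r.combo))
        )
    return champs


def classify_interaction(
    best: MdrCvResult,
    scope: str,
    gene_of: dict[int, str],
    genes: tuple[str, ...],
    folds: int,
    cvc_min: float = 0.8,
) -> tuple[bool, str]:
    """Is the best model an interaction candidate? Returns (candidate, reason).

    Within-gene: the best model must be order >= 2. Between-gene: it must
    contain at least one SNP from each gene of the pair. Both require
    cvc/folds >= cvc_min.
    """
    if scope == "within":
        if len(best.combo) < 2:
            return False, "best model is order-1: no within-gene interaction"
    elif scope == "between":
        present = {gene_of[j] for j in best.combo}
        if not all(g in present for g in genes):
            return False, "best model does not span both genes"
    else:
        raise ValueError(f"unknown scope {scope!r}")
    if best.cvc / folds < cvc_min:
        return False, f"cross-validation consistency {best.cvc}/{folds} below {cvc_min}"
    return True, "candidate"


def mdr_permutation_test(
    genotypes: np.ndarray,
    case_mask: np.ndarray,
    combo: tuple[int, ...],
    observed_accuracy: float,
    n_permutations: int,
    folds: int = 10,
    seed: int = 0,
    balanced: bool = True,
) -> float:
    """Empirical p of a candidate's CV testing accuracy under label permutation.

    The identified combination is held fixed (not re-searched); each
    permutation shuffles case/control status preserving class counts and
    re-runs the same 10-fold CV scoring. p = (b+1)/(B+1).
    """
    case_mask = np.asarray(case_mask, dtype=bool)
    cells = encode_cells(genotypes, combo)
    n_cells = 3 ** len(combo)
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_permutations):
        perm = rng.permutation(case_mask)
        fold_id = stratified_folds(perm, folds, rng)
        acc, _ = _combo_fold_accuracies(cells, perm, fold_id, folds, n_cells, balanced)
        if acc.mean() >= observed_accuracy - _TIE_EPS:
            b += 1
    return (b + 1) / (n_permutations + 1)


# ---------------------------------------------------------------------------
# the scan
# ---------------------------------------------------------------------------

def run_interaction_scan(
    dataset: Dataset,
    max_order: int = 4,
    folds: int = 10,
    n_permutations: int = 1000,
    cvc_min: float = 0.8,
    fdr_alpha: float = 0.05,
    seed: int = 0,
    balanced: bool = True,
) -> pd.DataFrame:
    """Within-gene scan per gene + between-gene scan per gene pair.

    Every scan reports its best model; candidates get a permutation empirical
    p and BH-FDR within their family (within-gene vs between-gene), and are
    confirmed iff pFDR < fdr_alpha.
    """
    genes = sorted(dataset.gene_map)
    gene_of = {j: g for g in genes for j in dataset.gene_map[g]}
    ss = np.random.SeedSequence(seed)
    scopes: list[tuple[str, tuple[str, ...]]] = [("within", (g,)) for g in genes]
    scopes += [("between", pair) for pair in itertools.combinations(genes, 2)]
    seeds = ss.spawn(len(scopes))

    rows = []
    for (scope, scope_genes), scope_seed in zip(scopes, seeds):
        snp_idx: list[int] = []
        for g in scope_genes:
            snp_idx.extend(dataset.gene_map[g])
        combos = enumerate_snp_combinations(snp_idx, max_order)
        s_cv, s_perm = (int(c.generate_state(1)[0] % 2**31) for c in scope_seed.spawn(2))
        results = mdr_cross_validate(
            dataset.genotypes, dataset.case_mask, combos, folds=folds,
            seed=s_cv, balanced=balanced,
        )
        best = select_best_model(order_champions(results))
        is_candidate, reason = classify_interaction(
            best, scope, gene_of, scope_genes, folds, cvc_min
        )
        emp_p = np.nan
        if is_candidate:
            emp_p = mdr_permutation_test(
                dataset.genotypes, dataset.case_mask, best.combo,
                best.avg_testing_accuracy, n_permutations, folds=folds,
                seed=s_perm, balanced=balanced,
            )
        rows.append(
            {
                "scope": scope,
                "genes": "*".join(scope_genes),
                "snps": ",".join(dataset.snps[j].snp_id for j in best.combo),
                "order": len(best.combo),
                "avg_testing_accuracy": best.avg_testing_accuracy,
                "cvc": best.cvc,
                "candidate": is_candidate,
                "reason": reason,
                "empirical_p": emp_p,
            }
        )
    out = pd.DataFrame(rows)
    out["pfdr"] = np.nan
    for scope in ("within", "between"):
        mask = (out["scope"] == scope) & out["candidate"]
        if mask.any():
            out.loc[mask, "pfdr"] = bh_fdr(out.loc[mask, "empirical_p"].to_numpy())
    out["confirmed"] = out["pfdr"] < fdr_alpha
    return out
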