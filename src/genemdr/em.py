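"""EM estimation of haplotype frequencies from unphased genotypes.

Shared engine used by pairwise LD, block haplotype frequencies, the
likelihood-ratio association tests, and genotype imputation.

Haplotypes over ``m`` biallelic SNPs are indexed 0..2^m-1, bit ``m-1-j``
holding the allele at SNP ``j`` (0 = major, 1 = minor), so index 0 is the
all-major haplotype and string rendering follows SNP order.

A genotype pattern is a length-``m`` vector of codes {0,1,2} with -1 for a
missing call; each pattern expands to its compatible unordered haplotype
pairs. The EM runs on collapsed (pattern, count) data, which keeps the cost
per iteration proportional to the number of *distinct* multilocus genotypes
rather than the sample size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .datamodel import MISSING

MAX_EM_SNPS = 8  # guard: 2^8 haplotypes is the largest block the EM will phase


class EmConvergenceError(RuntimeError):
    """EM failed to converge in any restart; carries the best estimate."""

    def __init__(self, message: str, best: "EmResult"):
        super().__init__(message)
        self.best = best


@dataclass
class EmResult:
    freqs: np.ndarray  # (2^m,) haplotype frequencies
    loglik: float
    n_iter: int
    converged: bool
    loglik_trace: Optional[list[float]] = None


_SITE_OPTIONS = {
    0: ((0, 0),),
    2: ((1, 1),),
    1: ((0, 1), (1, 0)),
    MISSING: ((0, 0), (0, 1), (1, 0), (1, 1)),
}


def pattern_counts(genotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse an (n, m) genotype matrix to unique patterns and counts."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    patterns, counts = np.unique(genotypes, axis=0, return_counts=True)
    return patterns, counts.astype(float)


def compatible_pairs(pattern: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unordered haplotype pairs compatible with one genotype pattern.

    Returns (h1, h2, mult) with h1 <= h2 and mult = 2 for heterozygous pairs
    (the two phase orderings) and 1 for h1 == h2.
    """
    m = len(pattern)
    h1 = np.zeros(1, dtype=np.int64)
    h2 = np.zeros(1, dtype=np.int64)
    for j, code in enumerate(pattern):
        opts = _SITE_OPTIONS[int(code)]
        shift = m - 1 - j
        new1 = []
        new2 = []
        for a, b in opts:
            new1.append(h1 * 2 + a if shift >= 0 else h1)
            new2.append(h2 * 2 + b)
        h1 = np.concatenate(new1)
        h2 = np.concatenate(new2)
    lo = np.minimum(h1, h2)
    hi = np.maximum(h1, h2)
    key = lo * (2**m) + hi
    uniq, idx = np.unique(key, return_index=True)
    lo, hi = lo[idx], hi[idx]
    mult = np.where(lo == hi, 1.0, 2.0)
    return lo, hi, mult


class PatternExpansion:
    """Precomputed pair expansion for a fixed set of genotype patterns."""

    def __init__(self, patterns: np.ndarray):
        self.m = patterns.shape[1]
        self.n_hap = 2**self.m
        h1_all, h2_all, mult_all, pat_idx = [], [], [], []
        for p, pattern in enumerate(patterns):
            h1, h2, mult = compatible_pairs(pattern)
            h1_all.append(h1)
            h2_all.append(h2)
            mult_all.append(mult)
            pat_idx.append(np.full(len(h1), p, dtype=np.int64))
        self.h1 = np.concatenate(h1_all)
        self.h2 = np.concatenate(h2_all)
        self.mult = np.concatenate(mult_all)
        self.pat_idx = np.concatenate(pat_idx)
        self.n_patterns = len(patterns)

    def loglik(self, freqs: np.ndarray, counts: np.ndarray) -> float:
        w = freqs[self.h1] * freqs[self.h2] * self.mult
        s = np.bincount(self.pat_idx, weights=w, minlength=self.n_patterns)
        s = np.maximum(s, 1e-300)
        return float(np.dot(counts, np.log(s)))

    def em(
        self,
        counts: np.ndarray,
        init: np.ndarray,
        tol: float = 1e-8,
        max_iter: int = 1000,
        track: bool = False,
    ) -> EmResult:
        f = np.asarray(init, dtype=float)
        f = f / f.sum()
        total = counts.sum()
        trace: Optional[list[float]] = [] if track else None
        loglik = -np.inf
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            w = f[self.h1] * f[self.h2] * self.mult
            s = np.bincount(self.pat_idx, weights=w, minlength=self.n_patterns)
            s = np.maximum(s, 1e-300)
            loglik = float(np.dot(counts, np.log(s)))
            if track:
                trace.append(loglik)
            post = w * counts[self.pat_idx] / s[self.pat_idx]
            exp_counts = np.bincount(
                self.h1, weights=post, minlength=self.n_hap
            ) + np.bincount(self.h2, weights=post, minlength=self.n_hap)
            f_new = exp_counts / (2.0 * total)
            delta = np.max(np.abs(f_new - f))
            f = f_new
            if delta < tol:
                converged = True
                break
        return EmResult(freqs=f, loglik=loglik, n_iter=it, converged=converged, loglik_trace=trace)


def em_frequencies(
    genotypes: Optional[np.ndarray] = None,
    *,
    patterns: Optional[np.ndarray] = None,
    counts: Optional[np.ndarray] = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
    restarts: int = 5,
    seed: int = 0,
    init: Optional[np.ndarray] = None,
    track: bool = False,
) -> EmResult:
    """Maximum-likelihood haplotype frequencies by EM with seeded restarts.

    Either ``genotypes`` (n x m codes) or pre-collapsed ``patterns, counts``
    must be given. Runs one uniform-start chain plus ``restarts - 1`` chains
    from seeded Dirichlet(1) draws and keeps the best converged log-likelihood
    (or, with ``init``, a single warm-started chain). Raises
    :class:`EmConvergenceError` carrying the best estimate if no chain
    converges.
    """
    if patterns is None:
        if genotypes is None:
            raise ValueError("need genotypes or (patterns, counts)")
        patterns, counts = pattern_counts(genotypes)
    m = patterns.shape[1]
    if m > MAX_EM_SNPS:
        raise ValueError(f"EM limited to {MAX_EM_SNPS} SNPs, got {m}")
    expansion = PatternExpansion(patterns)
    return em_from_expansion(
        expansion, counts, tol=tol, max_iter=max_iter, restarts=restarts,
        seed=seed, init=init, track=track,
    )


def em_from_expansion(
    expansion: PatternExpansion,
    counts: np.ndarray,
    *,
    tol: float = 1e-8,
    max_iter: int = 1000,
    restarts: int = 5,
    seed: int = 0,
    init: Optional[np.ndarray] = None,
    track: bool = False,
) -> EmResult:
    counts = np.asarray(counts, dtype=float)
    n_hap = expansion.n_hap
    if init is not None:
        return expansion.em(counts, init, tol=tol, max_iter=max_iter, track=track)
    rng = np.random.default_rng(seed)
    inits = [np.full(n_hap, 1.0 / n_hap)]
    for _ in range(max(0, restarts - 1)):
        inits.append(rng.dirichlet(np.ones(n_hap)))
    best: Optional[EmResult] = None
    for start in inits:
        res = expansion.em(counts, start, tol=tol, max_iter=max_iter, track=track)
        if best is None or res.loglik > best.loglik + 1e-12:
            best = res
    assert best is not None
    if not best.converged:
        raise EmConvergenceError("EM did not converge in any restart", best)
    return best


def sample_pair(
    freqs: np.ndarray, pattern: np.ndarray, rng: np.random.Generator
) -> tuple[int, int]:
    """Draw one haplotype pair from the posterior given an observed pattern."""
    h1, h2, mult = compatible_pairs(np.asarray(pattern))
    w = freqs[h1] * freqs[h2] * mult
    total = w.sum()
    if total <= 0:  # degenerate EM solution: fall back to uniform over pairs
        w = np.ones_like(w)
        total = w.sum()
    k = rng.choice(len(w), p=w / total)
    return int(h1[k]), int(h2[k])


def hap_alleles(h: int, m: int) -> np.ndarray:
    """Bit-decode haplotype index to an allele vector (0 major / 1 minor)."""
    return np.array([(h >> (m - 1 - j)) & 1 for j in range(m)], dtype=np.int8)
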