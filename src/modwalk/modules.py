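"""Muscle-module extraction by non-negative matrix factorization.

The averaged, normalized envelope matrix X (muscles x 101) is factorized as
X ~ W @ C with W (muscles x k) the module weights and C (k x 101) the module
activations, both nonnegative, by multiplicative updates minimizing squared
Frobenius error.  The number of modules is chosen by the variability-
accounted-for (VAF) rule used throughout the gait-synergy literature: add
modules until VAF >= 90% for every muscle and every gait-cycle bin, or until
adding one raises no individual muscle/bin VAF by more than 5 percentage
points.  Subjects are dichotomized as walking with two modules
(mass flexion-extension co-excitation) versus more than two.

VAF is uncentered: 100 * (1 - sum(residual^2) / sum(data^2)), computed
overall, per muscle (row) and per bin (column range), with per-bin VAF pooled
across muscles.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .emg import PCT_GRID
from .errors import UndefinedVAFError

_EPS = 1e-12


@dataclass
class ModuleDecomposition:
    """One NNMF solution in canonical form (unit-maximum weight columns)."""

    W: np.ndarray  # muscles x k
    C: np.ndarray  # k x 101
    k: int
    final_sse: float
    seed_used: int
    restarts: int

    @property
    def reconstruction(self) -> np.ndarray:
        return self.W @ self.C


@dataclass
class VAFReport:
    vaf_overall: float
    vaf_per_muscle: np.ndarray  # (n_muscles,)
    vaf_per_bin: np.ndarray | None  # (6,) or None when no bin edges given
    k: int

    def min_vaf(self) -> float:
        parts = [self.vaf_per_muscle]
        if self.vaf_per_bin is not None:
            parts.append(self.vaf_per_bin)
        return float(np.min(np.concatenate(parts)))


@dataclass
class ModuleCountDecision:
    k_selected: int
    stop_reason: str  # all_thresholds_met | gain_below_5pct | k_max_reached
    trail: list  # [(k, VAFReport, ModuleDecomposition), ...] for each k fitted

    @property
    def pattern_class(self) -> str:
        return "two_modules" if self.k_selected <= 2 else "more_than_two"

    @property
    def decomposition(self) -> ModuleDecomposition:
        for k, _, dec in self.trail:
            if k == self.k_selected:
                return dec
        raise KeyError(self.k_selected)


def _canonicalize(W: np.ndarray, C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scale = W.max(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    return W / scale, C * scale[:, None]


def _sse(X: np.ndarray, W: np.ndarray, C: np.ndarray) -> float:
    R = X - W @ C
    return float(np.sum(R * R))


def _mu_run(
    X: np.ndarray,
    W: np.ndarray,
    C: np.ndarray,
    max_iter: int,
    tol: float,
    check_every: int = 10,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Multiplicative updates (Lee-Seung, Frobenius loss); SSE is monotonically
    nonincreasing, so convergence is judged on its relative change."""
    prev = _sse(X, W, C)
    for it in range(1, max_iter + 1):
        C *= (W.T @ X) / (W.T @ W @ C + _EPS)
        W *= (X @ C.T) / (W @ (C @ C.T) + _EPS)
        if it % check_every == 0:
            cur = _sse(X, W, C)
            if prev - cur <= tol * max(prev, _EPS):
                prev = cur
                break
            prev = cur
    return W, C, _sse(X, W, C)


def nnmf_fit(
    X: np.ndarray,
    k: int,
    seed: int = 0,
    restarts: int = 50,
    max_iter: int = 10_000,
    tol: float = 1e-6,
    warm_start: tuple[np.ndarray, np.ndarray] | None = None,
) -> ModuleDecomposition:
    """Best-of-restarts multiplicative-update NNMF, deterministic given
    (X, k, seed, restarts).

    warm_start: (W, C) of a previous smaller-k solution; it is padded with a
    tiny random extra module and used as one additional candidate, which makes
    overall VAF monotone in k across a selection sweep.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if np.any(X < 0):
        raise ValueError("X must be nonnegative")
    if np.any(~X.any(axis=1)):
        raise ValueError("X must have no all-zero rows")
    m, n = X.shape
    if not 1 <= k <= m:
        raise ValueError(f"k must be in [1, {m}]")

    scale = np.sqrt(X.mean() / k)
    candidates = []
    if warm_start is not None:
        Wp, Cp = warm_start
        if Wp.shape[1] >= k:
            raise ValueError("warm start must come from a smaller k")
        rng = np.random.default_rng([seed, k, 9999])
        pad = k - Wp.shape[1]
        Wc = np.hstack([Wp, 1e-3 * scale * rng.random((m, pad))])
        Cc = np.vstack([Cp, 1e-3 * scale * rng.random((pad, n))])
        candidates.append((Wc, Cc))
    for r in range(restarts):
        rng = np.random.default_rng([seed, k, r])
        candidates.append(
            (scale * rng.random((m, k)) + _EPS, scale * rng.random((k, n)) + _EPS)
        )

    best = None
    for W0, C0 in candidates:
        W, C, sse = _mu_run(X, W0.copy(), C0.copy(), max_iter, tol)
        if best is None or sse < best[2]:
            best = (W, C, sse)
    W, C, sse = best
    W, C = _canonicalize(W, C)
    return ModuleDecomposition(W, C, k, _sse(X, W, C), seed, restarts)


def _bin_column_slices(bin_edges_pct: np.ndarray) -> list[np.ndarray]:
    """Column indices of the 101-point grid belonging to each bin
    (half-open on the right; the last bin includes 100%)."""
    cols = []
    for j in range(len(bin_edges_pct) - 1):
        lo, hi = bin_edges_pct[j], bin_edges_pct[j + 1]
        if j == len(bin_edges_pct) - 2:
            sel = (PCT_GRID >= lo) & (PCT_GRID <= hi)
        else:
            sel = (PCT_GRID >= lo) & (PCT_GRID < hi)
        cols.append(np.flatnonzero(sel))
    return cols


def _vaf(sse: float, ssq: float, what: str) -> float:
    if ssq <= 0:
        raise UndefinedVAFError(f"zero sum of squares in partition: {what}")
    return 100.0 * (1.0 - sse / ssq)


def compute_vaf(
    X: np.ndarray,
    decomp: ModuleDecomposition,
    bin_edges_pct: np.ndarray | None = None,
) -> VAFReport:
    """Uncentered VAF overall, per muscle row, and per gait-cycle bin."""
    X = np.asarray(X, dtype=float)
    E = X - decomp.reconstruction
    if E.shape != X.shape:
        raise ValueError("decomposition shape does not match X")
    overall = _vaf(float(np.sum(E * E)), float(np.sum(X * X)), "overall")
    per_muscle = np.array(
        [
            _vaf(float(np.sum(E[i] ** 2)), float(np.sum(X[i] ** 2)), f"muscle {i}")
            for i in range(X.shape[0])
        ]
    )
    per_bin = None
    if bin_edges_pct is not None:
        per_bin = np.array(
            [
                _vaf(
                    float(np.sum(E[:, c] ** 2)),
                    float(np.sum(X[:, c] ** 2)),
                    f"bin {j}",
                )
                for j, c in enumerate(_bin_column_slices(np.asarray(bin_edges_pct)))
            ]
        )
    return VAFReport(overall, per_muscle, per_bin, decomp.k)


def select_module_number(
    X: np.ndarray,
    bin_edges_pct: np.ndarray,
    seed: int = 0,
    restarts: int = 50,
    k_max: int = 8,
    vaf_threshold: float = 90.0,
    gain_threshold: float = 5.0,
    **fit_kwargs,
) -> ModuleCountDecision:
    """Add modules until every muscle and bin VAF reaches the threshold, or
    until one more module raises no individual VAF by more than the gain
    threshold (that lookahead fit is kept in the trail but not selected)."""
    k = 1
    dec = nnmf_fit(X, k, seed=seed, restarts=restarts, **fit_kwargs)
    rep = compute_vaf(X, dec, bin_edges_pct)
    trail = [(k, rep, dec)]
    while True:
        if rep.min_vaf() >= vaf_threshold:
            return ModuleCountDecision(k, "all_thresholds_met", trail)
        if k >= k_max:
            return ModuleCountDecision(k, "k_max_reached", trail)
        dec_next = nnmf_fit(
            X, k + 1, seed=seed, restarts=restarts,
            warm_start=(dec.W, dec.C), **fit_kwargs,
        )
        rep_next = compute_vaf(X, dec_next, bin_edges_pct)
        trail.append((k + 1, rep_next, dec_next))
        gains = np.concatenate(
            [
                rep_next.vaf_per_muscle - rep.vaf_per_muscle,
                rep_next.vaf_per_bin - rep.vaf_per_bin,
            ]
        )
        if gains.max() <= gain_threshold:
            return ModuleCountDecision(k, "gain_below_5pct", trail)
        k, dec, rep = k + 1, dec_next, rep_next


def _cosine_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    An = A / np.maximum(np.linalg.norm(A, axis=0, keepdims=True), _EPS)
    Bn = B / np.maximum(np.linalg.norm(B, axis=0, keepdims=True), _EPS)
    return An.T @ Bn


def match_modules(
    W: np.ndarray, W_ref: np.ndarray
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Optimal one-to-one assignment of extracted to reference weight columns
    maximizing summed cosine similarity (Hungarian algorithm; identical to the
    exhaustive permutation search for small k).

    Returns (pairs, similarities) where pairs[i] = (extracted_col, ref_col).
    """
    W = np.asarray(W, dtype=float)
    W_ref = np.asarray(W_ref, dtype=float)
    sim = _cosine_matrix(W, W_ref)
    rows, cols = linear_sum_assignment(-sim)
    pairs = list(zip(rows.tolist(), cols.tolist()))
    return pairs, sim[rows, cols]


def exhaustive_match_score(W: np.ndarray, W_ref: np.ndarray) -> float:
    """Brute-force best-permutation mean cosine similarity (test oracle)."""
    sim = _cosine_matrix(np.asarray(W, float), np.asarray(W_ref, float))
    k = min(sim.shape)
    best = -np.inf
    for perm in itertools.permutations(range(sim.shape[1]), k):
        best = max(best, float(np.mean([sim[i, p] for i, p in enumerate(perm)])))
    return best
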