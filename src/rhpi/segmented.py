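"""Continuous piecewise-linear (segmented) regression.

Breakpoints between linear segments are estimated by iterative
linearisation: given working breakpoints, the model

    y ~ 1 + x + sum_j beta_j (x - psi_j)_+  + sum_j gamma_j (-1{x > psi_j})

is fit by ordinary least squares and each breakpoint updated by
psi_j <- psi_j + gamma_j / beta_j until the gamma terms vanish.  The number
of breakpoints is chosen by BIC among 0..max_breakpoints (ties resolved
toward fewer breaks).  Multi-start initialisation from quantile grids with
seeded jitter makes the fit deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = ["SegmentedFit", "fit_segmented", "fit_segmented_fixed"]


class SegmentedFitError(RuntimeError):
    """Raised when no admissible segmented fit converges."""


@dataclass(frozen=True)
class SegmentedFit:
    """A continuous piecewise-linear fit.

    ``slopes``/``intercepts`` are per segment (``len(breakpoints) + 1``
    entries, left to right); segments join continuously at the breakpoints.
    """

    breakpoints: tuple[float, ...]
    slopes: tuple[float, ...]
    intercepts: tuple[float, ...]
    rss: float
    bic: float
    n: int
    n_per_segment: tuple[int, ...]

    @property
    def n_breakpoints(self) -> int:
        return len(self.breakpoints)

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        edges = (-np.inf, *self.breakpoints, np.inf)
        out = np.empty_like(x)
        for s, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
            m = (x >= lo) & (x < hi) if np.isfinite(hi) else (x >= lo)
            out[m] = self.intercepts[s] + self.slopes[s] * x[m]
        return out


def _design(x: np.ndarray, psi: np.ndarray) -> np.ndarray:
    cols = [np.ones_like(x), x]
    for p in psi:
        cols.append(np.maximum(x - p, 0.0))
    return np.column_stack(cols)


def _ols(X: np.ndarray, y: np.ndarray):
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, float(resid @ resid)


def _segment_params(coef: np.ndarray, psi: np.ndarray):
    """Convert hinge coefficients to per-segment slope/intercept."""
    b0, b1 = coef[0], coef[1]
    slopes = [b1]
    intercepts = [b0]
    for j, p in enumerate(psi):
        slopes.append(slopes[-1] + coef[2 + j])
        intercepts.append(intercepts[-1] - coef[2 + j] * p)
    return tuple(float(s) for s in slopes), tuple(float(i) for i in intercepts)


def _muggeo(
    x: np.ndarray,
    y: np.ndarray,
    psi0: np.ndarray,
    *,
    min_per_segment: int,
    max_iter: int = 100,
    tol: float = 1e-9,
):
    """One Muggeo run from starting breakpoints; returns (psi, rss) or None."""
    lo, hi = x.min(), x.max()
    psi = np.sort(psi0.astype(float))
    for _ in range(max_iter):
        U = [np.maximum(x - p, 0.0) for p in psi]
        V = [-(x > p).astype(float) for p in psi]
        X = np.column_stack([np.ones_like(x), x, *U, *V])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        k = len(psi)
        beta = coef[2 : 2 + k]
        gamma = coef[2 + k : 2 + 2 * k]
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(np.abs(beta) > 1e-12, gamma / beta, 0.0)
        new = np.sort(psi + step)
        # keep breakpoints interior and separated
        span = hi - lo
        new = np.clip(new, lo + 1e-6 * span, hi - 1e-6 * span)
        if np.any(np.diff(new) < 1e-6 * span):
            return None
        moved = np.max(np.abs(new - psi))
        psi = new
        if moved < tol * max(span, 1.0):
            break
    psi = _polish(x, y, psi)
    # admissibility: enough observations per segment
    edges = (-np.inf, *psi, np.inf)
    counts = [
        int(np.sum((x >= a) & (x < b)) if np.isfinite(b) else np.sum(x >= a))
        for a, b in zip(edges[:-1], edges[1:])
    ]
    if min(counts) < min_per_segment:
        return None
    coef, rss = _ols(_design(x, psi), y)
    return psi, coef, rss, tuple(counts)


def _polish(x: np.ndarray, y: np.ndarray, psi: np.ndarray, sweeps: int = 2) -> np.ndarray:
    """Coordinate-wise bounded refinement of the profiled RSS.

    The iterative linearisation lands very near the optimum; this polish
    removes the residual bias from its stopping rule.
    """
    if psi.size == 0:
        return psi
    lo, hi = x.min(), x.max()
    psi = psi.copy()

    def rss_at(j, b):
        trial = psi.copy()
        trial[j] = b
        if np.any(np.diff(np.sort(trial)) <= 0):
            return np.inf
        _, rss = _ols(_design(x, np.sort(trial)), y)
        return rss

    for _ in range(sweeps):
        for j in range(psi.size):
            left = psi[j - 1] if j > 0 else lo
            right = psi[j + 1] if j + 1 < psi.size else hi
            span = right - left
            res = optimize.minimize_scalar(
                lambda b: rss_at(j, b),
                bounds=(left + 1e-9 * span, right - 1e-9 * span),
                method="bounded",
                options={"xatol": 1e-8},
            )
            if np.isfinite(res.fun) and res.fun <= rss_at(j, psi[j]):
                psi[j] = res.x
    return np.sort(psi)


def fit_segmented_fixed(
    x,
    y,
    n_breakpoints: int,
    *,
    seed: int | None = 0,
    n_starts: int = 8,
    min_per_segment: int = 10,
) -> SegmentedFit:
    """Best segmented fit with exactly ``n_breakpoints`` breaks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < min_per_segment * (n_breakpoints + 1):
        raise SegmentedFitError(
            f"need at least {min_per_segment} observations per candidate segment"
        )
    if n_breakpoints == 0:
        coef, rss = _ols(_design(x, np.array([])), y)
        slopes, intercepts = _segment_params(coef, np.array([]))
        bic = _bic(n, rss, 0)
        return SegmentedFit((), slopes, intercepts, rss, bic, n, (n,))
    rng = np.random.default_rng(seed)
    qs = np.linspace(0, 100, n_breakpoints + 2)[1:-1]
    base = np.percentile(x, qs)
    span = x.max() - x.min()
    best = None
    for s in range(n_starts):
        psi0 = base if s == 0 else np.sort(
            base + rng.normal(scale=0.1 * span, size=n_breakpoints)
        )
        res = _muggeo(x, y, psi0, min_per_segment=min_per_segment)
        if res is None:
            continue
        if best is None or res[2] < best[2]:
            best = res
    if best is None:
        raise SegmentedFitError(
            f"no admissible fit with {n_breakpoints} breakpoint(s) converged"
        )
    psi, coef, rss, counts = best
    slopes, intercepts = _segment_params(coef, psi)
    bic = _bic(n, rss, n_breakpoints)
    return SegmentedFit(
        tuple(float(p) for p in psi), slopes, intercepts, rss, bic, n, counts
    )


def _bic(n: int, rss: float, k: int) -> float:
    # parameters: intercept, slope, one slope change + one breakpoint per break
    p = 2 + 2 * k
    return float(n * np.log(max(rss, 1e-300) / n) + p * np.log(n))


def fit_segmented(
    x,
    y,
    max_breakpoints: int = 2,
    *,
    seed: int | None = 0,
    n_starts: int = 8,
    min_per_segment: int = 10,
) -> SegmentedFit:
    """Segmented fit with the breakpoint count chosen by BIC.

    Fits 0..max_breakpoints breaks and keeps the lowest BIC; ties (within
    1e-9) go to the model with fewer breaks.
    """
    best: SegmentedFit | None = None
    for k in range(max_breakpoints + 1):
        try:
            fit = fit_segmented_fixed(
                x, y, k, seed=seed, n_starts=n_starts,
                min_per_segment=min_per_segment,
            )
        except SegmentedFitError:
            continue
        if best is None or fit.bic < best.bic - 1e-9:
            best = fit
    if best is None:
        raise SegmentedFitError("no segmented model of any order converged")
    return best
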