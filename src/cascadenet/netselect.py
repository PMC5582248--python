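"""Scale-free cutoff selection for the inferred network.

Thresholding the connection-strength matrix trades completeness for
interpretability.  The cutoff is chosen by watching the network evolve
over a grid of cutoffs and keeping the one whose degree distribution is
most adequately described by a discrete power law, measured by a
Clauset-Shalizi-Newman goodness-of-fit: maximum-likelihood exponent,
Kolmogorov-Smirnov choice of the lower bound xmin, and a
semi-parametric bootstrap p-value (large p = the power law is a
plausible generator of the tail, i.e. the thresholded network remains
scale-free).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special

from .cascade import CascadeModel

__all__ = [
    "PowerlawFit",
    "ThresholdedNetwork",
    "DegenerateEvolutionError",
    "powerlaw_gof",
    "evolve_cutoff",
]

DEFAULT_CUTOFF = 0.10  # documented operating point when evolution is bypassed
_MIN_DEGREES = 10


@dataclass(frozen=True)
class PowerlawFit:
    alpha: float
    xmin: int
    p_value: float
    ks: float
    n_tail: int


@dataclass
class ThresholdedNetwork:
    """A cutoff, the surviving edges, and the scale-freeness evidence."""

    cutoff: float
    edges: tuple[tuple[str, str, float], ...]
    powerlaw_fit: PowerlawFit | None
    degree_sequence: tuple[int, ...]
    evolution: pd.DataFrame


class DegenerateEvolutionError(ValueError):
    """Raised when no cutoff on the grid leaves a testable network."""

    def __init__(self, message: str, evolution: pd.DataFrame) -> None:
        super().__init__(message)
        self.evolution = evolution


def _zeta(alpha: float, xmin: int) -> float:
    return float(special.zeta(alpha, xmin))


def _fit_alpha(tail: np.ndarray, xmin: int) -> float:
    """Discrete maximum-likelihood exponent for the tail >= xmin."""
    logsum = float(np.log(tail).sum())
    n = tail.size

    def nll(alpha: float) -> float:
        return n * np.log(_zeta(alpha, xmin)) + alpha * logsum

    res = optimize.minimize_scalar(nll, bounds=(1.0001, 25.0), method="bounded")
    return float(res.x)


def _ks_distance(tail: np.ndarray, alpha: float, xmin: int) -> float:
    xs = np.unique(tail)
    n = tail.size
    z0 = _zeta(alpha, xmin)
    # fitted P(X <= x) on the tail support
    fit_cdf = 1.0 - special.zeta(alpha, xs + 1) / z0
    emp_cdf = np.searchsorted(np.sort(tail), xs, side="right") / n
    return float(np.max(np.abs(emp_cdf - fit_cdf)))


def _fit_tail(degrees: np.ndarray, min_tail: int) -> tuple[float, int, float]:
    """Scan xmin candidates, return (alpha, xmin, ks) minimizing KS."""
    xs = np.unique(degrees)
    candidates = [int(x) for x in xs if (degrees >= x).sum() >= min_tail]
    if not candidates:
        candidates = [int(xs.min())]
    best = None
    for xmin in candidates:
        tail = degrees[degrees >= xmin]
        alpha = _fit_alpha(tail, xmin)
        ks = _ks_distance(tail, alpha, xmin)
        if best is None or ks < best[2]:
            best = (alpha, xmin, ks)
    return best


def _sample_powerlaw(
    alpha: float, xmin: int, size: int, rng: np.random.Generator, cap: int
) -> np.ndarray:
    support = np.arange(xmin, cap + 1)
    pmf = support.astype(float) ** (-alpha)
    cdf = np.cumsum(pmf / pmf.sum())
    u = rng.random(size)
    return support[np.searchsorted(cdf, u)]


def powerlaw_gof(
    degrees, n_boot: int = 100, seed: int = 0, *, min_tail: int | None = None
) -> PowerlawFit:
    """Clauset-style goodness of fit of a discrete power law to degrees.

    The exponent is fitted by maximum likelihood, the lower bound xmin
    by minimizing the KS distance over candidates leaving at least
    ``min_tail`` observations — by default half the sample (never fewer
    than 10), so that the adequacy statement concerns the bulk of the
    degree distribution and not an arbitrarily small upper tail — and
    the p-value by a semi-parametric bootstrap: each replicate resamples
    the body empirically and the tail from the fitted law, is refitted
    from scratch, and contributes its KS distance; p is the fraction of
    replicates fitting no better than the data.  Deterministic given
    ``seed``.
    """
    degrees = np.asarray(list(degrees), dtype=int)
    degrees = degrees[degrees > 0]
    if degrees.size < _MIN_DEGREES:
        raise ValueError(
            f"insufficient data: need >= {_MIN_DEGREES} nonzero degrees, "
            f"got {degrees.size}"
        )
    if np.unique(degrees).size == 1:
        raise ValueError("degenerate degree sequence: all degrees equal")
    if min_tail is None:
        min_tail = max(_MIN_DEGREES, degrees.size // 2)

    alpha, xmin, ks_obs = _fit_tail(degrees, min_tail)
    n = degrees.size
    tail = degrees[degrees >= xmin]
    body = degrees[degrees < xmin]
    p_tail = tail.size / n
    cap = int(max(10_000, 10 * degrees.max()))

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_boot):
        take_tail = rng.random(n) < p_tail
        k = int(take_tail.sum())
        boot = np.empty(n, dtype=int)
        boot[:k] = _sample_powerlaw(alpha, xmin, k, rng, cap)
        if n - k:
            if body.size:
                boot[k:] = rng.choice(body, size=n - k, replace=True)
            else:
                boot[k:] = _sample_powerlaw(alpha, xmin, n - k, rng, cap)
        if np.unique(boot).size == 1:
            exceed += 1  # a constant replicate fits no better than the data
            continue
        _, _, ks_b = _fit_tail(boot, min_tail)
        if ks_b >= ks_obs:
            exceed += 1
    return PowerlawFit(alpha, xmin, exceed / n_boot, ks_obs, int(tail.size))


def _degree_sequence(edges) -> np.ndarray:
    deg: dict[str, int] = {}
    for reg, tgt, _ in edges:
        deg[reg] = deg.get(reg, 0) + 1
        deg[tgt] = deg.get(tgt, 0) + 1
    return np.array(sorted(deg.values()), dtype=int)


def evolve_cutoff(
    model: CascadeModel,
    grid=None,
    n_boot: int = 100,
    seed: int = 0,
    *,
    grid_step: float = 0.01,
    min_tail: int | None = None,
) -> ThresholdedNetwork:
    """Watch the thresholded network evolve and keep the best cutoff.

    For every cutoff in ``grid`` (default: 0 to max|w| in ``grid_step``
    steps) the surviving network's total-degree sequence (undirected
    skeleton, isolated nodes dropped) is tested for power-law adequacy;
    the cutoff with maximal bootstrap p-value wins, ties going to the
    smallest cutoff.  Cutoffs leaving too few or all-equal degrees are
    recorded in the evolution table but cannot win.
    """
    if grid is None:
        wmax = float(np.abs(model.w).max())
        grid = np.arange(0.0, wmax + grid_step, grid_step)
    grid = np.asarray(sorted(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("cutoff grid is empty")

    rows = []
    fits: dict[float, PowerlawFit | None] = {}
    seeds = np.random.SeedSequence(seed).spawn(grid.size)
    prev_edges = None
    for cutoff, ss in zip(grid, seeds):
        edges = model.edges(cutoff=float(cutoff))
        degrees = _degree_sequence(edges)
        fit = None
        if edges == prev_edges:
            fit = fits.get(rows[-1]["cutoff"])
        elif degrees.size >= _MIN_DEGREES and np.unique(degrees).size > 1:
            fit = powerlaw_gof(
                degrees,
                n_boot=n_boot,
                seed=int(ss.generate_state(1)[0] % (2**31)),
                min_tail=min_tail,
            )
        fits[float(cutoff)] = fit
        rows.append(
            {
                "cutoff": float(cutoff),
                "n_nodes": int(degrees.size),
                "n_edges": len(edges),
                "alpha": fit.alpha if fit else np.nan,
                "xmin": fit.xmin if fit else np.nan,
                "p_value": fit.p_value if fit else np.nan,
            }
        )
        prev_edges = edges
    table = pd.DataFrame(rows)

    if table["p_value"].isna().all():
        raise DegenerateEvolutionError(
            "every cutoff yields a degenerate or too-small network", table
        )
    # argmax p; pandas idxmax returns the first (= smallest cutoff) on ties
    best_idx = int(table["p_value"].idxmax())
    best_cut = float(table.loc[best_idx, "cutoff"])
    edges = tuple(model.edges(cutoff=best_cut))
    return ThresholdedNetwork(
        cutoff=best_cut,
        edges=edges,
        powerlaw_fit=fits[best_cut],
        degree_sequence=tuple(_degree_sequence(edges)),
        evolution=table,
    )
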