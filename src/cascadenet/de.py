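"""Differential-expression ranking and filtering for time-course contrasts.

Two designs are supported: a two-condition design contrasted per
timepoint (normal vs carcinoma cells at each hour of stimulation), with
top-k retention per timepoint plus a top-k global list; and a baseline
design where every later timepoint of a single course is contrasted
against hour 0 and genes pass on joint p-value and fold-change cuts.

The test statistic is the empirical-Bayes moderated t: per-gene sample
variances are shrunk toward a pooled prior variance s0^2 with prior
degrees of freedom d0, both estimated by moment matching of log sample
variances across genes (digamma/trigamma inversion).  The moderated
t uses the posterior variance s~^2 = (d0*s0^2 + d*s^2)/(d0 + d) on
d0 + d degrees of freedom, which stabilizes inference at the handful of
replicates time-course microarrays afford.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .synthetic import ExpressionCube

__all__ = [
    "SelectionSpec",
    "DEResult",
    "moderated_t",
    "moderated_f",
    "rank_and_select",
    "call_regulation",
    "baseline_contrast",
]

_MAX_DF = 1e6  # stands in for an infinite prior df (complete shrinkage)


@dataclass(frozen=True)
class SelectionSpec:
    """Thresholds of the selection procedures.

    Defaults are the published operating points: top 20 genes per
    timepoint and top 20 globally; up-call above 0.37 log2 units and
    down-call below -1.5 (strict inequalities); baseline mode keeps
    p < 0.001 together with fold change > 2.
    """

    top_k_per_timepoint: int = 20
    top_k_global: int = 20
    up_threshold: float = 0.37
    down_threshold: float = -1.5
    baseline_p: float = 0.001
    baseline_fold: float = 2.0

    def __post_init__(self) -> None:
        if self.top_k_per_timepoint < 0 or self.top_k_global < 0:
            raise ValueError("top-k counts must be >= 0")
        for t in (self.up_threshold, self.down_threshold, self.baseline_p, self.baseline_fold):
            if not np.isfinite(t):
                raise ValueError("thresholds must be finite")


@dataclass
class DEResult:
    """Per-contrast moderated-t tables plus the selection outcome.

    ``tables`` maps contrast label (an hour) to a per-gene frame with
    columns log2_ratio, t_stat, p_value, rank; ``global_table`` is the
    across-timepoint moderated-F ranking; ``selected`` the retained gene
    list with provenance.
    """

    tables: dict[float, pd.DataFrame]
    global_table: pd.DataFrame | None = None
    selected: pd.DataFrame | None = None
    calls: pd.Series | None = None
    warnings: list[str] = field(default_factory=list)


def _trigamma_inverse(y: np.ndarray) -> np.ndarray:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    y = np.asarray(y, dtype=float)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif) < 1e-10 * x):
            break
    return x


def _fit_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Moment-match the scaled-F model of sample variances.

    Returns (d0, s0_sq): prior degrees of freedom and prior variance such
    that log s^2 has the mean/variance implied by s^2 ~ s0^2 * F(d, d0).
    d0 = inf (returned as a large cap) when the observed spread of
    log variances is no larger than the sampling spread alone.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return 0.0, float(np.mean(s2)) if s2.size else 0.0
    z = np.log(s2[ok])
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = e.mean()
    n = e.size
    evar = np.sum((e - emean) ** 2) / (n - 1) - special.polygamma(1, d / 2.0)
    if evar <= 0:
        return _MAX_DF, float(np.exp(emean))
    d0 = 2.0 * float(_trigamma_inverse(np.array(evar)))
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def _moderated_t_arrays(
    a: np.ndarray, b: np.ndarray
) -> pd.DataFrame:
    """Moderated t between two (genes x replicates) matrices (a minus b)."""
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 replicates per group")
    d = na + nb - 2
    diff = a.mean(axis=1) - b.mean(axis=1)
    ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (b - b.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / d
    d0, s0_sq = _fit_prior(s2, d)
    degenerate = (s2 == 0) & (d0 == 0 or s0_sq == 0)
    if d0 >= _MAX_DF:
        s2_post = np.full_like(s2, s0_sq)
        df_total = _MAX_DF
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d0 + d
    # the pooled information cannot exceed the summed residual df
    df_total = min(df_total, a.shape[0] * d)
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df=min(df_total, _MAX_DF))
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} gene(s) with zero variance and no "
            "estimable prior; p set to 1",
            stacklevel=3,
        )
        t = np.where(degenerate, 0.0, t)
        p = np.where(degenerate, 1.0, p)
    return pd.DataFrame(
        {
            "log2_ratio": diff,
            "t_stat": t,
            "p_value": p,
            "s2": s2,
            "s2_post": s2_post,
            "df_total": df_total,
            "d0": d0,
            "s0_sq": s0_sq,
            "zero_variance": degenerate,
        }
    )


def moderated_t(
    cube_a: ExpressionCube, cube_b: ExpressionCube, timepoint: float
) -> pd.DataFrame:
    """Per-gene moderated t of condition a vs b at one timepoint.

    Returns a frame indexed by gene with log2_ratio (mean a minus mean b,
    data already on log2 scale), t_stat, p_value and shrinkage
    diagnostics.
    """
    if cube_a.genes != cube_b.genes:
        raise ValueError("cubes must share an identical gene set")
    ta, tb = cube_a.time_index(timepoint), cube_b.time_index(timepoint)
    out = _moderated_t_arrays(cube_a.values[:, :, ta], cube_b.values[:, :, tb])
    out.index = pd.Index(cube_a.genes, name="gene")
    out["rank"] = out["p_value"].rank(method="first").astype(int)
    return out


def moderated_f(tables: dict[float, pd.DataFrame]) -> pd.DataFrame:
    """Across-timepoint global ranking by a moderated F statistic.

    F per gene is the mean squared moderated t over the timepoint
    contrasts, referred to an F distribution with (n_contrasts, mean
    total df) degrees of freedom.  Ranks break ties by gene identifier.
    """
    if not tables:
        raise ValueError("need at least one contrast")
    genes = next(iter(tables.values())).index
    t2 = np.vstack([tables[k]["t_stat"].to_numpy() ** 2 for k in sorted(tables)])
    fstat = t2.mean(axis=0)
    df2 = float(np.mean([tables[k]["df_total"].iloc[0] for k in tables]))
    p = stats.f.sf(fstat, dfn=len(tables), dfd=min(df2, _MAX_DF))
    out = pd.DataFrame({"f_stat": fstat, "p_value": p}, index=genes)
    out["rank"] = out["p_value"].rank(method="first").astype(int)
    return out


def _top_k(table: pd.DataFrame, k: int) -> list[str]:
    if k >= len(table):
        if k > len(table):
            warnings.warn(
                f"requested top {k} of only {len(table)} genes", stacklevel=3
            )
        k = len(table)
    order = table.assign(_g=table.index).sort_values(["p_value", "_g"])
    return list(order.index[:k])


def rank_and_select(
    tables: dict[float, pd.DataFrame],
    spec: SelectionSpec,
    global_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Union of per-timepoint top-k lists and the global top-k list.

    Returns a frame indexed by selected gene with a ``sources`` column
    naming the list(s) each gene came from ("t<h>" or "global"); with
    L per-timepoint lists the union holds at most (L + 1) * k genes,
    with equality exactly when all lists are disjoint.
    """
    if not tables:
        raise ValueError("need at least one timepoint contrast")
    if global_table is None:
        global_table = moderated_f(tables)
    provenance: dict[str, list[str]] = {}
    for hour in sorted(tables):
        for g in _top_k(tables[hour], spec.top_k_per_timepoint):
            provenance.setdefault(g, []).append(f"t{hour:g}")
    for g in _top_k(global_table, spec.top_k_global):
        provenance.setdefault(g, []).append("global")
    genes = sorted(provenance)
    return pd.DataFrame(
        {"sources": [",".join(provenance[g]) for g in genes]},
        index=pd.Index(genes, name="gene"),
    )


def call_regulation(
    log2_ratios: pd.DataFrame, spec: SelectionSpec
) -> pd.Series:
    """Up/down calls from per-timepoint log2 ratios (genes x timepoints).

    A gene is called up if any timepoint ratio strictly exceeds the up
    threshold, down if any falls strictly below the down threshold;
    meeting both yields "both" with a warning; otherwise "unchanged".
    """
    vals = log2_ratios.to_numpy()
    if not np.isfinite(vals).all():
        raise ValueError("log2 ratios must be finite")
    up = (vals > spec.up_threshold).any(axis=1)
    down = (vals < spec.down_threshold).any(axis=1)
    call = np.where(
        up & down, "both", np.where(up, "up", np.where(down, "down", "unchanged"))
    )
    if (up & down).any():
        both = list(log2_ratios.index[up & down])
        warnings.warn(f"genes meet both thresholds: {both}", stacklevel=2)
    return pd.Series(call, index=log2_ratios.index, name="call")


def baseline_contrast(
    cube: ExpressionCube, spec: SelectionSpec
) -> tuple[dict[float, set[str]], set[str], dict[float, pd.DataFrame]]:
    """Timepoint-vs-hour-0 DE selection within a single course.

    For every timepoint t > 0, genes pass when the moderated-t p-value
    against hour 0 is strictly below ``baseline_p`` and the absolute
    log2 ratio strictly exceeds log2(``baseline_fold``).  Returns the
    per-timepoint sets, their union, and the full statistic tables.
    """
    if 0.0 not in cube.timepoints:
        raise ValueError("baseline missing: cube has no timepoint 0")
    i0 = cube.time_index(0.0)
    lfc_min = np.log2(spec.baseline_fold)
    per_tp: dict[float, set[str]] = {}
    tabs: dict[float, pd.DataFrame] = {}
    for t in cube.timepoints:
        if t == 0.0:
            continue
        it = cube.time_index(t)
        tab = _moderated_t_arrays(cube.values[:, :, it], cube.values[:, :, i0])
        tab.index = pd.Index(cube.genes, name="gene")
        tabs[t] = tab
        keep = (tab["p_value"] < spec.baseline_p) & (
            tab["log2_ratio"].abs() > lfc_min
        )
        per_tp[t] = set(tab.index[keep])
    union = set().union(*per_tp.values()) if per_tp else set()
    return per_tp, union, tabs
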