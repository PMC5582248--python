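"""In-silico knock-out prediction on a fitted cascade network.

A knock-out clamps one gene's (centered) expression to a basal value
from a chosen timepoint onward and re-propagates the fitted linear
model through the time-cluster DAG, so indirect effects reach genes two
or more steps downstream.  The readout is qualitative: per-gene trend
signs of the perturbed-minus-baseline difference, and same/opposite
trend relations between gene pairs — the form in which such predictions
are stated and checked against perturbation experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cascade import CascadeModel
from .synthetic import ExpressionCube

__all__ = ["KnockoutScenario", "KnockoutPrediction", "knockout", "trend_report"]

_TREND_TOL = 1e-9


@dataclass(frozen=True)
class KnockoutScenario:
    """Which gene to silence and from which hour onward."""

    gene: str
    from_timepoint: float
    #: expression level the silenced gene is clamped to, on the data's
    #: absolute log2 scale (0 = basal, i.e. no change vs reference).
    clamp_value: float = 0.0


@dataclass
class KnockoutPrediction:
    """Baseline vs perturbed propagated trajectories and trend calls.

    Trajectories cover the predicted window (timepoints 2..T) averaged
    over subjects; ``trend`` maps gene -> sign in {-1, 0, +1} of the
    perturbed-minus-baseline difference summed over affected timepoints;
    ``relation`` maps unordered gene pairs to same/opposite/null by the
    product of trend signs.
    """

    scenario: KnockoutScenario
    genes: tuple[str, ...]
    timepoints: tuple[float, ...]
    baseline: pd.DataFrame
    perturbed: pd.DataFrame
    trend: dict[str, int]
    relation: dict[tuple[str, str], str] = field(default_factory=dict)


def _propagate(
    model: CascadeModel,
    observed_centered: np.ndarray,
    clamp: tuple[int, np.ndarray, float] | None,
) -> np.ndarray:
    """Propagate the model through the cluster DAG.

    Returns simulated centered values, shape (G, P, T).  Genes without
    candidate regulators keep their observed trajectories; regulated
    genes keep the observed first timepoint and take model predictions
    afterwards, computed from the *simulated* (not observed) regulator
    values so higher-order effects flow through.  ``clamp`` is
    (gene index, timepoint mask, value) for the silenced gene.
    """
    G, P, T = observed_centered.shape
    m = model.clusters.m
    sim = observed_centered.copy()

    def apply_clamp() -> None:
        # the clamp level is absolute; sim holds deviations from the
        # per-(gene, timepoint) mean, so subtract the stored center
        if clamp is not None:
            j, mask, value = clamp
            sim[j, :, mask] = (value - model.center[j, mask])[:, None]

    apply_clamp()
    for cluster in sorted(set(m.values())):
        for j, g in enumerate(model.genes):
            if m[g] != cluster:
                continue
            cands = [i for i, h in enumerate(model.genes) if m[h] < m[g]]
            if not cands:
                continue
            pred = np.zeros((P, T - 1))
            for i in cands:
                if model.w[i, j] != 0.0:
                    a, b = m[model.genes[i]], m[g]
                    xh = sim[i, :, :-1] / model.scale[i]
                    pred += model.w[i, j] * (xh @ model.F[(a, b)].T)
            sim[j, :, 1:] = pred
        apply_clamp()  # keep the silenced gene clamped between cluster sweeps
    return sim


def knockout(
    model: CascadeModel, cube: ExpressionCube, scenario: KnockoutScenario
) -> KnockoutPrediction:
    """Predict expression modulations after silencing one gene.

    Baseline and perturbed trajectories are both obtained by propagating
    the fitted model through the cluster DAG from the observed inputs;
    the perturbed run additionally clamps the silenced gene from
    ``from_timepoint`` onward.  Trends are signs of the summed
    difference over affected timepoints (|sum| < 1e-9 counts as 0);
    genes with no directed path from the silenced gene are exactly
    unchanged.
    """
    if scenario.gene not in model.genes:
        raise ValueError(f"gene {scenario.gene!r} absent from the model")
    if cube.genes != model.genes:
        raise ValueError("gene set mismatch between model and cube")
    times = np.asarray(model.timepoints)
    if scenario.from_timepoint not in model.timepoints:
        raise ValueError(
            f"from_timepoint {scenario.from_timepoint} is not a model timepoint"
        )
    affected = times >= scenario.from_timepoint
    if not affected[1:].any():
        raise ValueError("no affected timepoints in the predicted window")

    centered = cube.values - model.center[:, None, :]
    j = model.genes.index(scenario.gene)
    base = _propagate(model, centered, clamp=None)
    pert = _propagate(model, centered, clamp=(j, affected, scenario.clamp_value))

    # predicted window only (timepoints 2..T), averaged over subjects,
    # reported back on the absolute log2 scale
    pred_times = tuple(model.timepoints[1:])
    base_df = pd.DataFrame(
        base[:, :, 1:].mean(axis=1) + model.center[:, 1:],
        index=list(model.genes),
        columns=pred_times,
    )
    pert_df = pd.DataFrame(
        pert[:, :, 1:].mean(axis=1) + model.center[:, 1:],
        index=list(model.genes),
        columns=pred_times,
    )

    win = affected[1:]
    diff = (pert_df.to_numpy() - base_df.to_numpy())[:, win].sum(axis=1)
    trend = {
        g: (0 if abs(d) < _TREND_TOL else (1 if d > 0 else -1))
        for g, d in zip(model.genes, diff)
    }

    pred = KnockoutPrediction(
        scenario=scenario,
        genes=model.genes,
        timepoints=pred_times,
        baseline=base_df,
        perturbed=pert_df,
        trend=trend,
    )
    pred.relation = {
        (a, b): _relation(trend[a], trend[b])
        for ia, a in enumerate(model.genes)
        for b in model.genes[ia + 1 :]
    }
    return pred


def _relation(ta: int, tb: int) -> str:
    if ta == 0 or tb == 0:
        return "null"
    return "same" if ta * tb > 0 else "opposite"


def trend_report(
    pred: KnockoutPrediction, genes_of_interest: list[str]
) -> pd.DataFrame:
    """Pairwise same/opposite/null relations among the given genes."""
    missing = [g for g in genes_of_interest if g not in pred.genes]
    if missing:
        raise ValueError(f"genes absent from prediction: {missing}")
    rows = []
    for i, a in enumerate(genes_of_interest):
        for b in genes_of_interest[i + 1 :]:
            key = (a, b) if (a, b) in pred.relation else (b, a)
            rows.append(
                {
                    "gene_a": a,
                    "gene_b": b,
                    "trend_a": pred.trend[a],
                    "trend_b": pred.trend[b],
                    "relation": pred.relation[key],
                }
            )
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "trend_a", "trend_b", "relation"])
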