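"""Synthetic time-course expression data from a planted cascade network.

The generator realizes the statistical structure the cascade regression
model assumes: genes are partitioned into time-clusters, regulation flows
strictly from earlier clusters to later ones, and a target's trajectory
over timepoints 2..T is a weighted sum of time-actions applied to its
regulators' trajectories over timepoints 1..T-1, plus Gaussian noise.
Two conditions with a mean shift on a planted subset of genes emulate the
case/control contrast; a toy protein-interaction graph with planted
overlapping and nested link communities exercises the edge-clustering
stage.  Everything is deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "GeneratorConfig",
    "PlantedTruth",
    "ExpressionCube",
    "generate_network",
    "simulate_cube",
    "simulate_expression",
    "generate_toy_ppi",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the planted network and its simulated readout.

    Defaults are the desk-scale study conditions used throughout the test
    suite: 20 genes, 10 subjects, a 4-point time course (hours), 3
    time-clusters, 20% of feasible cascade edges realized with effect
    sizes in ±[0.5, 1.5], measurement noise sd 0.1 on the log2 scale, and
    a quarter of genes carrying a 1 log2-unit condition effect.
    """

    n_genes: int = 20
    n_subjects: int = 10
    timepoints: tuple[float, ...] = (0.0, 1.0, 4.0, 12.0)
    n_clusters: int = 3
    edge_density: float = 0.2
    weight_range: tuple[float, float] = (0.5, 1.5)
    #: magnitude range of the baseline bump profiles (log2 units):
    #: the strength of the intrinsic temporal dynamics.
    amplitude_range: tuple[float, float] = (0.5, 1.5)
    noise_sd: float = 0.1
    #: sd of per-subject perturbations of the baseline-profile cubic
    #: coefficients: biological replicate-to-replicate variability, the
    #: signal the per-timepoint-centered regressions run on.
    subject_sd: float = 0.5
    de_fraction: float = 0.25
    de_effect: float = 1.0
    #: hour from which the condition effect applies; None = all timepoints
    #: (two-condition design).  Set to a positive hour for a single-course
    #: design where differential expression appears after the baseline.
    de_onset_time: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        tp = tuple(float(t) for t in self.timepoints)
        object.__setattr__(self, "timepoints", tp)
        if len(tp) < 3:
            raise ValueError("need at least 3 timepoints")
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.n_clusters > len(tp) - 1:
            raise ValueError("n_clusters must be <= T - 1")
        if not 0.0 <= self.edge_density <= 1.0:
            raise ValueError("edge_density must be in [0, 1]")
        lo, hi = self.weight_range
        if not 0 < lo <= hi:
            raise ValueError("weight_range must satisfy 0 < lo <= hi")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be >= 0")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoints)


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of a generated cascade network.

    ``edges`` holds (regulator, target, weight) with every edge pointing
    from a strictly earlier time-cluster to a later one, ``cluster_of``
    is the planted time-cluster map m(n) in 1..K, and ``de_genes`` the
    genes carrying the condition effect.
    """

    edges: tuple[tuple[str, str, float], ...]
    cluster_of: Mapping[str, int]
    de_genes: frozenset[str]

    def __post_init__(self) -> None:
        for reg, tgt, w in self.edges:
            if self.cluster_of[reg] >= self.cluster_of[tgt]:
                raise ValueError(
                    f"edge {reg}->{tgt} is not strictly time-forward"
                )
            if w == 0:
                raise ValueError("planted weights must be nonzero")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.cluster_of)

    def regulators_of(self, gene: str) -> list[tuple[str, float]]:
        return [(r, w) for r, t, w in self.edges if t == gene]


@dataclass
class ExpressionCube:
    """Log2-scale expression indexed by (gene, subject, timepoint).

    ``values`` has shape (n_genes, n_subjects, n_timepoints); indices are
    positional against ``genes``, ``subjects`` and ``timepoints``.
    """

    values: np.ndarray
    genes: tuple[str, ...]
    subjects: tuple[str, ...]
    timepoints: tuple[float, ...]
    condition_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.genes = tuple(self.genes)
        self.subjects = tuple(self.subjects)
        self.timepoints = tuple(float(t) for t in self.timepoints)
        if self.values.shape != (
            len(self.genes),
            len(self.subjects),
            len(self.timepoints),
        ):
            raise ValueError(
                f"values shape {self.values.shape} does not match axes"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene identifiers must be unique")
        if len(self.timepoints) < 2:
            raise ValueError("need at least 2 timepoints")
        if np.isnan(self.values).any():
            raise ValueError("missing values are not allowed")
        if not self.condition_of:
            self.condition_of = {s: "control" for s in self.subjects}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoints)

    def gene_index(self, gene: str) -> int:
        return self.genes.index(gene)

    def time_index(self, hour: float) -> int:
        return self.timepoints.index(float(hour))


def _gene_names(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def generate_network(config: GeneratorConfig) -> PlantedTruth:
    """Draw a planted sparse time-forward regulatory network.

    Each gene is assigned uniformly at random to one of K time-clusters;
    every ordered pair with a strictly earlier regulator cluster is a
    candidate edge, kept independently with probability ``edge_density``;
    weights are uniform on ±``weight_range``.  DE genes are a simple
    random sample of size round(de_fraction * n_genes).
    """
    if config.n_clusters < 2 and config.edge_density > 0:
        raise ValueError(
            "no feasible edges: n_clusters < 2 leaves no earlier cluster"
        )
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes)
    clusters = rng.integers(1, config.n_clusters + 1, size=config.n_genes)
    cluster_of = {g: int(c) for g, c in zip(genes, clusters)}

    edges: list[tuple[str, str, float]] = []
    lo, hi = config.weight_range
    for i, reg in enumerate(genes):
        for j, tgt in enumerate(genes):
            if cluster_of[reg] >= cluster_of[tgt]:
                continue
            if rng.random() < config.edge_density:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                w = sign * rng.uniform(lo, hi)
                edges.append((reg, tgt, float(w)))

    n_de = int(round(config.de_fraction * config.n_genes))
    de = frozenset(rng.choice(genes, size=n_de, replace=False)) if n_de else frozenset()
    return PlantedTruth(tuple(edges), cluster_of, de)


def _resolve_time_action(
    time_action, T: int
) -> "np.ndarray | dict[tuple[int, int], np.ndarray] | None":
    """Validate the (T-1)x(T-1) time-action; None means identity lag."""
    if time_action is None:
        return None
    if isinstance(time_action, dict):
        return {k: _check_lower(np.asarray(v, float), T) for k, v in time_action.items()}
    return _check_lower(np.asarray(time_action, float), T)


def _check_lower(F: np.ndarray, T: int) -> np.ndarray:
    if F.shape != (T - 1, T - 1):
        raise ValueError(f"time-action must be {(T - 1, T - 1)}, got {F.shape}")
    if not np.allclose(F, np.tril(F)):
        raise ValueError("time-action must be lower-triangular")
    return F


def _time_powers(config: GeneratorConfig) -> np.ndarray:
    t = np.asarray(config.timepoints)
    u = (t - t[0]) / (t[-1] - t[0])  # rescale hours to [0, 1]
    return np.vstack([np.ones_like(u), u, u**2, u**3])


def cluster_time_bins(T: int, K: int) -> list[np.ndarray]:
    """Contiguous partition of timepoint indices 2..T into K bins."""
    return np.array_split(np.arange(1, T), K)


def _baseline_profiles(
    config: GeneratorConfig,
    rng: np.random.Generator,
    cluster_index: np.ndarray,
) -> np.ndarray:
    """Random smooth bump curves, one per gene (shape G x T).

    Each gene's curve is a Gaussian bump in rescaled time, peaked at a
    timepoint drawn from the gene's time-cluster bin and narrow enough
    (width half the gap to the nearest other timepoint) that the peak
    still dominates after per-gene centering, so peak-based cluster
    assignment of an unregulated gene is recoverable on noiseless data.
    """
    T = config.n_timepoints
    t = np.asarray(config.timepoints)
    u = (t - t[0]) / (t[-1] - t[0])
    bins = cluster_time_bins(T, config.n_clusters)
    profiles = np.empty((config.n_genes, T))
    for i in range(config.n_genes):
        peak_t = int(rng.choice(bins[cluster_index[i] - 1]))
        up = u[peak_t]
        width = 0.5 * np.min(np.abs(np.delete(u, peak_t) - up))
        amp = rng.uniform(*config.amplitude_range) * rng.choice([-1.0, 1.0])
        profiles[i] = amp * np.exp(-0.5 * ((u - up) / width) ** 2) + rng.normal(0.0, 0.5)
    return profiles


def simulate_cube(
    truth: PlantedTruth,
    config: GeneratorConfig,
    *,
    condition: str = "control",
    apply_de: bool = False,
    seed: int | None = None,
    time_action=None,
) -> ExpressionCube:
    """Simulate one condition's expression cube from the planted network.

    Genes without regulators follow their own smooth baseline profile;
    regulated genes take their baseline value at the first timepoint and
    are then driven forward by the cascade model (weighted time-actions of
    their regulators' realized, i.e. noisy, trajectories) plus independent
    Gaussian noise per subject.  With ``apply_de`` the condition effect
    ``de_effect`` is added to the planted DE genes, at all timepoints or
    from ``de_onset_time`` onward.

    Baseline profiles depend only on ``config.seed`` so the two conditions
    share biology; noise depends on ``seed`` (default ``config.seed``), so
    two calls with equal seeds agree bit-for-bit.
    """
    T = config.n_timepoints
    G, S = config.n_genes, config.n_subjects
    genes = list(truth.genes)
    if len(genes) != G:
        raise ValueError("truth and config disagree on gene count")
    fa = _resolve_time_action(time_action, T)

    profile_rng = np.random.default_rng(config.seed)
    cluster_index = np.array([truth.cluster_of[g] for g in genes])
    pop_profiles = _baseline_profiles(config, profile_rng, cluster_index)
    noise_rng = np.random.default_rng(config.seed if seed is None else seed)
    # per-subject biological variation of the smooth profiles, then
    # per-measurement noise; both from the condition's noise stream
    subj_coef = noise_rng.normal(0.0, 1.0, size=(G, S, 4)) * config.subject_sd
    profiles = pop_profiles[:, None, :] + subj_coef @ _time_powers(config)
    noise = noise_rng.normal(0.0, 1.0, size=(G, S, T)) * config.noise_sd

    regulators = {g: truth.regulators_of(g) for g in genes}
    order = sorted(range(G), key=lambda i: truth.cluster_of[genes[i]])

    x = np.empty((G, S, T))
    for i in order:
        g = genes[i]
        regs = regulators[g]
        if not regs:
            # exogenous input: smooth profile plus noise at every timepoint
            x[i] = profiles[i] + noise[i]
            continue
        x[i, :, 0] = profiles[i, :, 0] + noise[i, :, 0]
        drive = np.zeros((S, T - 1))
        for reg, w in regs:
            j = genes.index(reg)
            xhat = x[j, :, : T - 1]  # regulator at timepoints 1..T-1
            if fa is None:
                acted = xhat
            else:
                F = fa if not isinstance(fa, dict) else fa[
                    (truth.cluster_of[reg], truth.cluster_of[g])
                ]
                acted = xhat @ F.T
            drive += w * acted
        x[i, :, 1:] = drive + noise[i, :, 1:]

    if apply_de and truth.de_genes:
        shift = np.full(T, config.de_effect)
        if config.de_onset_time is not None:
            shift = np.where(
                np.asarray(config.timepoints) >= config.de_onset_time,
                config.de_effect,
                0.0,
            )
        for i, g in enumerate(genes):
            if g in truth.de_genes:
                x[i] += shift[None, :]

    subjects = [f"{condition}{s + 1:02d}" for s in range(S)]
    return ExpressionCube(
        x,
        tuple(genes),
        tuple(subjects),
        config.timepoints,
        {s: condition for s in subjects},
    )


def simulate_expression(
    truth: PlantedTruth,
    config: GeneratorConfig,
    *,
    time_action=None,
) -> tuple[ExpressionCube, ExpressionCube]:
    """Simulate the two-condition experiment: (control, stimulated) cubes.

    The two cubes share the planted network and baseline profiles; noise
    is independent between conditions (streams spawned from the config
    seed); the stimulated cube carries the condition effect on the
    planted DE genes.
    """
    seed_a, seed_b = np.random.SeedSequence(config.seed).spawn(2)
    a = simulate_cube(
        truth,
        config,
        condition="control",
        apply_de=False,
        seed=int(seed_a.generate_state(1)[0] % (2**31)),
        time_action=time_action,
    )
    b = simulate_cube(
        truth,
        config,
        condition="stimulated",
        apply_de=True,
        seed=int(seed_b.generate_state(1)[0] % (2**31)),
        time_action=time_action,
    )
    return a, b


def _clique_edges(nodes: Sequence[str]) -> list[tuple[str, str]]:
    return [
        (nodes[i], nodes[j])
        for i in range(len(nodes))
        for j in range(i + 1, len(nodes))
    ]


def generate_toy_ppi(
    n_nodes: int,
    n_communities: int,
    overlap: int = 1,
    seed: int = 0,
    *,
    nested_motif: bool = False,
    disease_fraction: float = 1.0,
) -> tuple[list[tuple[str, str]], list[str]]:
    """Build a toy interaction graph with planted link communities.

    ``n_communities`` cliques are chained so that consecutive cliques
    share ``overlap`` hub nodes; node identities split ``n_nodes`` as
    evenly as possible.  Hubs therefore belong to two link communities
    downstream, non-hub members to one.  With ``nested_motif`` a
    7-node, 11-edge component is appended whose link communities are
    nested at the partition-density-optimal cut: two triangles joined by
    four bridge edges plus one pendant — the bridges form a community
    whose node set strictly contains one triangle's.

    Returns an undirected edge list and a disease-gene list covering a
    random ``disease_fraction`` of the nodes (always all of them when 1).
    """
    if n_communities < 1:
        raise ValueError("n_communities must be >= 1")
    if n_nodes < n_communities:
        raise ValueError("n_nodes too small for the requested communities")
    # split the n_nodes distinct identities among the cliques; overlap
    # hubs are borrowed from the previous clique, not new nodes
    sizes = [n_nodes // n_communities] * n_communities
    for k in range(n_nodes % n_communities):
        sizes[k] += 1

    names = iter(_gene_names(n_nodes + (10 if nested_motif else 0)))
    edges: list[tuple[str, str]] = []
    nodes: list[str] = []
    prev_hubs: list[str] = []
    for size in sizes:
        members = prev_hubs + [next(names) for _ in range(size)]
        if overlap >= len(members):
            raise ValueError("overlap must be smaller than the clique size")
        edges.extend(_clique_edges(members))
        nodes.extend(m for m in members if m not in nodes)
        prev_hubs = members[-overlap:] if overlap > 0 and n_communities > 1 else []

    if nested_motif:
        a, b, c, d, e, f, p = (next(names) for _ in range(7))
        motif = [
            (b, c), (c, d), (b, d),          # inner triangle 1
            (a, e), (a, f), (e, f),          # inner triangle 2 (the nested one)
            (a, b), (a, d), (b, e), (d, f),  # bridges spanning both triangles
            (a, p),                          # pendant separating a's neighborhood
        ]
        edges.extend(motif)
        nodes.extend(sorted({n for pair in motif for n in pair} - set(nodes)))

    seen = set()
    dedup = []
    for u, v in edges:
        key = (u, v) if u < v else (v, u)
        if key not in seen and u != v:
            seen.add(key)
            dedup.append(key)

    rng = np.random.default_rng(seed)
    k = int(round(disease_fraction * len(nodes)))
    disease = sorted(rng.choice(nodes, size=k, replace=False)) if k else []
    return dedup, list(disease)
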