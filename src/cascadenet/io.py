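"""Plain-text readers and writers for every pipeline artifact.

Expression cubes travel as a tab-separated matrix (one row per gene,
columns ``<condition>_<subject>_<time>h``) with a companion sample
sheet; networks as edge lists; everything else as small TSV/JSON files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cascade import CascadeModel, TimeClusterAssignment
from .linkcomm import LinkCommunityResult, PPIGraph
from .synthetic import ExpressionCube, PlantedTruth

__all__ = [
    "write_cube",
    "read_cube",
    "write_truth",
    "read_ppi",
    "write_ppi",
    "read_gene_list",
    "write_gene_list",
    "write_model",
    "read_model",
    "write_link_communities",
]


def _sample_name(condition: str, subject: str, hour: float) -> str:
    return f"{condition}_{subject}_{hour:g}h"


def write_cube(cube: ExpressionCube, matrix_path, samples_path) -> None:
    """Write a cube as gene x sample TSV plus a sample sheet."""
    cols, meta = [], []
    data = {}
    for si, s in enumerate(cube.subjects):
        cond = cube.condition_of[s]
        for ti, t in enumerate(cube.timepoints):
            name = _sample_name(cond, s, t)
            cols.append(name)
            meta.append({"sample": name, "condition": cond, "subject": s, "time_h": t})
            data[name] = cube.values[:, si, ti]
    frame = pd.DataFrame(data, index=pd.Index(cube.genes, name="gene"))[cols]
    frame.to_csv(matrix_path, sep="\t")
    pd.DataFrame(meta).to_csv(samples_path, sep="\t", index=False)


def read_cube(matrix_path, samples_path) -> ExpressionCube:
    """Read a cube written by :func:`write_cube` (or equivalent TSVs)."""
    frame = pd.read_csv(matrix_path, sep="\t", index_col=0)
    sheet = pd.read_csv(samples_path, sep="\t")
    subjects = list(dict.fromkeys(sheet["subject"].astype(str)))
    timepoints = sorted(set(sheet["time_h"].astype(float)))
    genes = tuple(frame.index.astype(str))
    values = np.empty((len(genes), len(subjects), len(timepoints)))
    cond_of: dict[str, str] = {}
    for row in sheet.itertuples(index=False):
        si = subjects.index(str(row.subject))
        ti = timepoints.index(float(row.time_h))
        values[:, si, ti] = frame[row.sample].to_numpy()
        cond_of[str(row.subject)] = str(row.condition)
    return ExpressionCube(values, genes, tuple(subjects), tuple(timepoints), cond_of)


def write_truth(truth: PlantedTruth, edges_path, genes_path) -> None:
    pd.DataFrame(truth.edges, columns=["regulator", "target", "weight"]).to_csv(
        edges_path, sep="\t", index=False
    )
    pd.DataFrame(
        {
            "gene": list(truth.genes),
            "cluster": [truth.cluster_of[g] for g in truth.genes],
            "is_de": [g in truth.de_genes for g in truth.genes],
        }
    ).to_csv(genes_path, sep="\t", index=False)


def read_ppi(path) -> PPIGraph:
    """Read an edge TSV with columns gene_a, gene_b and optional score."""
    frame = pd.read_csv(path, sep="\t")
    edges = tuple(zip(frame["gene_a"].astype(str), frame["gene_b"].astype(str)))
    scores = {}
    if "score" in frame.columns:
        scores = {e: s for e, s in zip(edges, frame["score"].astype(float))}
    return PPIGraph(edges, scores)


def write_ppi(graph: PPIGraph, path) -> None:
    rows = [
        {"gene_a": a, "gene_b": b, **({"score": graph.scores[(a, b)]} if (a, b) in graph.scores else {})}
        for a, b in graph.edges
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gene_list(path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments skipped."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_gene_list(genes, path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def write_model(model: CascadeModel, edges_path, meta_path) -> None:
    """Edge TSV plus a JSON sidecar with operators and diagnostics."""
    rows = [
        {
            "regulator": r,
            "target": t,
            "weight": w,
            "regulator_cluster": model.clusters.m[r],
            "target_cluster": model.clusters.m[t],
        }
        for r, t, w in model.edges()
    ]
    pd.DataFrame(
        rows, columns=["regulator", "target", "weight", "regulator_cluster", "target_cluster"]
    ).to_csv(edges_path, sep="\t", index=False)
    meta = {
        "genes": list(model.genes),
        "timepoints": list(model.timepoints),
        "clusters": {g: model.clusters.m[g] for g in model.genes},
        "K": model.clusters.K,
        "flagged": sorted(model.clusters.flagged),
        "lambda_n": model.lambda_n,
        "sigma2": model.sigma2,
        "n_iter": model.n_iter,
        "converged": model.converged,
        "objective_trace": model.objective_trace,
        "F": {f"{a},{b}": f.tolist() for (a, b), f in model.F.items()},
        "center": model.center.tolist(),
        "scale": model.scale.tolist(),
        "w": model.w.tolist(),
    }
    Path(meta_path).write_text(json.dumps(meta, indent=1))


def read_model(meta_path) -> CascadeModel:
    meta = json.loads(Path(meta_path).read_text())
    clusters = TimeClusterAssignment(
        {g: int(c) for g, c in meta["clusters"].items()},
        int(meta["K"]),
        frozenset(meta["flagged"]),
    )
    F = {
        tuple(int(x) for x in key.split(",")): np.asarray(val)
        for key, val in meta["F"].items()
    }
    return CascadeModel(
        genes=tuple(meta["genes"]),
        w=np.asarray(meta["w"]),
        F=F,
        lambda_n=meta["lambda_n"],
        sigma2=float(meta["sigma2"]),
        clusters=clusters,
        timepoints=tuple(float(t) for t in meta["timepoints"]),
        center=np.asarray(meta["center"]),
        scale=np.asarray(meta["scale"]),
        objective_trace=list(meta["objective_trace"]),
        n_iter=int(meta["n_iter"]),
        converged=bool(meta["converged"]),
    )


def write_link_communities(result: LinkCommunityResult, out_dir) -> None:
    """Cluster, membership, nested-pair and density-curve TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [
        {"cluster_id": cid, "gene_a": a, "gene_b": b}
        for cid, cl in enumerate(result.clusters)
        for a, b in sorted(cl)
    ]
    pd.DataFrame(rows).to_csv(out / "clusters.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(
            ({"gene": g, "n_clusters": len(c)} for g, c in result.node_membership.items()),
            key=lambda r: (-r["n_clusters"], r["gene"]),
        )
    ).to_csv(out / "membership.tsv", sep="\t", index=False)
    pd.DataFrame(result.nested_pairs, columns=["inner", "outer"]).to_csv(
        out / "nested_pairs.tsv", sep="\t", index=False
    )
    pd.DataFrame(result.density_curve, columns=["height", "partition_density"]).to_csv(
        out / "density_curve.tsv", sep="\t", index=False
    )
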