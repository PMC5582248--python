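# cascadenet

Time-course gene-regulatory-network analysis for stimulation studies:
differential-expression filtering, Lasso-cascade network inference,
in-silico knock-outs, scale-free cutoff selection, and overlapping gene
clusters via link communities.

The package is aimed at systems biologists analyzing short time-course
expression experiments — the typical design being cells stimulated with
a cytokine (e.g. TGF-β) and profiled at a handful of hours, with a few
replicates and, often, a paired normal/tumor or control/treated
contrast. Every stage runs on plain tab-separated files, and a
synthetic-data generator with planted ground truth makes the whole
pipeline testable without any external download.

## The model

Genes are partitioned into *K* time-clusters by the map *m(n)*;
regulation flows only from earlier clusters to later ones, so the
network is a DAG. Writing *x̃ₙ* for gene *n*'s trajectory over
timepoints 2…T (stacked across the *P* subjects) and *x̂ₙ* for the
trajectory over 1…T−1, the cascade regression model is

    x̃ₙ = Σₙ′ F_{m(n′)m(n)} · w_{n′n} · x̂ₙ′ + ε,   E ε = 0, Var ε = σ²,

where *w_{n′n}* is the signed connection strength of regulator *n′* on
target *n* and *F_{ab}* is a causal (lower-triangular Toeplitz)
(T−1)×(T−1) time-action operator shared by all gene pairs of cluster
pair (a, b). Estimation minimizes the residual sum of squares with an
L1 constraint ‖w·ₙ‖₁ ≤ λₙ per target (the Lasso), alternating a
penalized regression for *w* with least squares for the *F* operators;
the penalty level is cross-validated over subjects with a
one-standard-error rule. Downstream stages consume the fitted model:

- **DE selection** — empirical-Bayes moderated t per timepoint
  (variance shrinkage with moment-matched prior df), top-*k* retention
  per timepoint plus a top-*k* global moderated-F list, up/down calls at
  log2 ratios > 0.37 / < −1.5, and a baseline mode keeping p < 0.001
  with fold change > 2 against hour 0.
- **Cutoff selection** — threshold |w| over a grid and keep the cutoff
  whose degree distribution is most adequately power-law
  (Clauset-style discrete MLE + KS bootstrap).
- **Knock-out prediction** — clamp one gene to basal level from a chosen
  hour and re-propagate the model through the cluster DAG; report trend
  signs and same/opposite relations between genes.
- **Link communities** — cluster the *links* of a disease-filtered
  protein-interaction subnetwork by the Jaccard coefficient of endpoint
  neighborhoods, cut the dendrogram at maximal partition density, and
  report genes with multiple memberships and nested clusters.

## Worked example

`examples/02_infer_network.py` simulates the default study conditions
(20 genes in 3 time-clusters, 10 subjects, hours 0/1/4/12, noise sd
0.1), fits the cascade model and scores the recovered edges against the
planted truth:

```
planted edges: 24; fitted nonzero edges: 97
residual variance sigma^2 = 0.0523
objective trace (50 iterations, non-increasing):
  5.155 -> 3.827 -> 3.373 -> 3.135 -> 2.970 -> 2.850
edge-support AUPR vs planted truth: 0.816
```

The fitted support is deliberately larger than the truth (the
cross-validated penalty errs toward inclusion); what matters is the
ranking: an AUPR of 0.82 means ranking candidate edges by |w| places
the planted regulations almost entirely ahead of the spurious ones.
Thresholding then prunes the network — `examples/03_choose_cutoff.py`
selects the cutoff (0.40 here) whose surviving degree sequence best
supports a power law (bootstrap p = 0.85). The other examples walk
through DE selection, knock-out prediction and link communities the
same way; each prints a short interpretation of its numbers.

A thin CLI mirrors the stages for shell use
(`cascadenet simulate | de-select | infer | threshold | knockout |
communities`); see `cascadenet --help`.

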