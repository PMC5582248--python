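"""Differential-expression statistics against long-form recomputation."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from cascadenet.de import (
    SelectionSpec,
    _moderated_t_arrays,
    baseline_contrast,
    call_regulation,
    moderated_f,
    moderated_t,
    rank_and_select,
)
from cascadenet.synthetic import GeneratorConfig, generate_network, simulate_cube


def brute_force_moderated_t(a: np.ndarray, b: np.ndarray):
    """Straight-line recomputation of the moderated t, kept deliberately
    naive (per-gene loops, explicit formulas) as an independent oracle."""
    G = a.shape[0]
    na, nb = a.shape[1], b.shape[1]
    d = na + nb - 2
    s2 = np.empty(G)
    diff = np.empty(G)
    for g in range(G):
        ma, mb = a[g].mean(), b[g].mean()
        diff[g] = ma - mb
        s2[g] = (((a[g] - ma) ** 2).sum() + ((b[g] - mb) ** 2).sum()) / d
    # moment matching of log s^2 against the scaled-F model
    z = np.log(s2)
    e = z - special.digamma(d / 2) + np.log(d / 2)
    evar = np.var(e, ddof=1) - special.polygamma(1, d / 2)
    assert evar > 0, "fixture must have spread in gene variances"
    # invert trigamma by bisection (independent of the package's Newton)
    lo, hi = 1e-6, 1e8
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if special.polygamma(1, mid) > evar:
            lo = mid
        else:
            hi = mid
    d0 = 2 * lo
    s0_sq = np.exp(e.mean() + special.digamma(d0 / 2) - np.log(d0 / 2))
    s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
    t = diff / np.sqrt(s2_post * (1 / na + 1 / nb))
    df_total = min(d0 + d, G * d)
    p = 2 * stats.t.sf(np.abs(t), df=df_total)
    return t, p, diff


class TestModeratedT:
    def test_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, (20, 5))
        a[:5] += 1.5
        b = rng.normal(0, 1, (20, 5))
        tab = _moderated_t_arrays(a, b)
        t_ref, p_ref, diff_ref = brute_force_moderated_t(a, b)
        np.testing.assert_allclose(tab["t_stat"], t_ref, rtol=1e-6)
        np.testing.assert_allclose(tab["p_value"], p_ref, rtol=1e-5)
        np.testing.assert_allclose(tab["log2_ratio"], diff_ref)

    def test_identical_group_means_give_zero_t_unit_p(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, (10, 4))
        a = np.concatenate([base, base], axis=1)  # mean(a) == mean(b) per gene
        tab = _moderated_t_arrays(a[:, :4], a[:, 4:])
        np.testing.assert_allclose(tab["t_stat"], 0.0, atol=1e-12)
        np.testing.assert_allclose(tab["p_value"], 1.0)

    def test_invariant_to_common_constant_shift(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, (15, 5))
        b = rng.normal(0, 1, (15, 6))
        t1 = _moderated_t_arrays(a, b)
        t2 = _moderated_t_arrays(a + 7.5, b + 7.5)
        np.testing.assert_allclose(t1["t_stat"], t2["t_stat"], rtol=1e-9)
        np.testing.assert_allclose(t1["p_value"], t2["p_value"], rtol=1e-9)

    def test_zero_variance_genes_flagged_with_p_one(self):
        a = np.ones((12, 4))
        b = np.ones((12, 4))
        with pytest.warns(UserWarning, match="zero variance"):
            tab = _moderated_t_arrays(a, b)
        assert tab["zero_variance"].all()
        np.testing.assert_allclose(tab["p_value"], 1.0)

    def test_requires_two_replicates_per_group(self):
        with pytest.raises(ValueError, match="replicates"):
            _moderated_t_arrays(np.ones((5, 1)), np.ones((5, 3)))

    def test_cube_interface_checks_gene_sets(self, two_condition_cubes):
        a, b = two_condition_cubes
        tab = moderated_t(a, b, a.timepoints[0])
        assert list(tab.index) == list(a.genes)
        assert set(tab["rank"]) == set(range(1, len(a.genes) + 1))


def _tables_from_pvalues(pmat: np.ndarray, genes):
    """Build minimal per-timepoint tables from a (genes x timepoints) p grid."""
    tables = {}
    for k in range(pmat.shape[1]):
        tables[float(k)] = pd.DataFrame(
            {
                "p_value": pmat[:, k],
                "t_stat": stats.norm.ppf(1 - pmat[:, k] / 2),
                "df_total": np.full(pmat.shape[0], 50.0),
            },
            index=pd.Index(genes, name="gene"),
        )
    return tables


class TestRankAndSelect:
    def test_disjoint_lists_select_eighty(self):
        # 3 timepoints x 20 + 20 global, engineered fully disjoint
        genes = [f"g{i:03d}" for i in range(100)]
        pmat = np.ones((100, 3))
        for k in range(3):
            pmat[20 * k : 20 * (k + 1), k] = 1e-6
        tables = _tables_from_pvalues(pmat, genes)
        glob = pd.DataFrame(
            {"p_value": np.ones(100)}, index=pd.Index(genes, name="gene")
        )
        glob.iloc[60:80, 0] = 1e-6
        sel = rank_and_select(tables, SelectionSpec(), global_table=glob)
        assert len(sel) == 80

    def test_identical_lists_collapse_to_twenty(self):
        genes = [f"g{i:03d}" for i in range(50)]
        pmat = np.ones((50, 3))
        pmat[:20, :] = np.linspace(1e-8, 1e-4, 20)[:, None]
        tables = _tables_from_pvalues(pmat, genes)
        glob = pd.DataFrame(
            {"p_value": pmat[:, 0]}, index=pd.Index(genes, name="gene")
        )
        sel = rank_and_select(tables, SelectionSpec(), global_table=glob)
        assert len(sel) == 20
        assert all("global" in s for s in sel["sources"])

    def test_zero_k_selects_nothing(self):
        genes = [f"g{i}" for i in range(30)]
        tables = _tables_from_pvalues(
            np.random.default_rng(0).random((30, 2)), genes
        )
        spec = SelectionSpec(top_k_per_timepoint=0, top_k_global=0)
        assert len(rank_and_select(tables, spec)) == 0

    def test_selection_monotone_in_k(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(40)]
        tables = _tables_from_pvalues(rng.random((40, 3)), genes)
        glob = pd.DataFrame(
            {"p_value": rng.random(40)}, index=pd.Index(genes, name="gene")
        )
        prev: set = set()
        for k in range(0, 25, 4):
            spec = SelectionSpec(top_k_per_timepoint=k, top_k_global=k)
            cur = set(rank_and_select(tables, spec, global_table=glob).index)
            assert prev <= cur
            prev = cur

    def test_moderated_f_ranks_consistent_signal(self, two_condition_cubes):
        a, b = two_condition_cubes
        tables = {t: moderated_t(a, b, t) for t in a.timepoints}
        glob = moderated_f(tables)
        assert set(glob.columns) >= {"f_stat", "p_value", "rank"}
        assert (glob["f_stat"] >= 0).all()


class TestCallRegulation:
    @pytest.mark.parametrize(
        "ratios, expected",
        [
            ((0.4, 0.0, 0.1), "up"),
            ((0.37, 0.37, 0.37), "unchanged"),  # strict boundary
            ((-1.5, -1.4), "unchanged"),
            ((-1.6, 0.0), "down"),
        ],
    )
    def test_threshold_calls(self, ratios, expected):
        frame = pd.DataFrame([ratios], index=["g1"])
        calls = call_regulation(frame, SelectionSpec())
        assert calls["g1"] == expected

    def test_both_directions_warns(self):
        frame = pd.DataFrame([[0.5, -1.6]], index=["g1"])
        with pytest.warns(UserWarning, match="both"):
            calls = call_regulation(frame, SelectionSpec())
        assert calls["g1"] == "both"

    def test_nonfinite_ratio_rejected(self):
        frame = pd.DataFrame([[np.inf, 0.0]], index=["g1"])
        with pytest.raises(ValueError, match="finite"):
            call_regulation(frame, SelectionSpec())


class TestBaselineContrast:
    def test_missing_baseline_errors(self, default_cube):
        from cascadenet.synthetic import ExpressionCube

        no_zero = ExpressionCube(
            default_cube.values[:, :, 1:],
            default_cube.genes,
            default_cube.subjects,
            default_cube.timepoints[1:],
            default_cube.condition_of,
        )
        with pytest.raises(ValueError, match="baseline missing"):
            baseline_contrast(no_zero, SelectionSpec())

    def test_exact_twofold_change_excluded(self):
        # gene 0 changes by exactly one log2 unit (a 2-fold change):
        # the strict inequality must leave it out however small its p
        rng = np.random.default_rng(2)
        G, S = 12, 6
        vals = rng.normal(0, 0.05, (G, S, 3))
        vals[0, :, 1] = vals[0, :, 0] + 1.0
        vals[0, :, 2] = vals[0, :, 0] + 1.0
        genes = tuple(f"g{i}" for i in range(G))
        from cascadenet.synthetic import ExpressionCube

        cube = ExpressionCube(
            vals, genes, tuple(f"s{i}" for i in range(S)), (0.0, 4.0, 8.0)
        )
        per_tp, union, tabs = baseline_contrast(cube, SelectionSpec())
        assert tabs[4.0].loc["g0", "log2_ratio"] == pytest.approx(1.0, abs=1e-12)
        assert "g0" not in union

    def test_recovers_planted_onset_genes(self):
        hits = []
        for seed in range(1, 11):
            # single-course onset design: weak intrinsic dynamics so the
            # temporal change of the DE genes is the planted onset shift
            cfg = GeneratorConfig(
                edge_density=0.0,
                amplitude_range=(0.05, 0.1),
                de_effect=2.0,
                de_onset_time=1.0,
                noise_sd=0.1,
                seed=seed,
            )
            truth = generate_network(cfg)
            cube = simulate_cube(truth, cfg, apply_de=True)
            _, union, _ = baseline_contrast(cube, SelectionSpec())
            de = truth.de_genes
            others = set(cube.genes) - de
            sens = len(union & de) / len(de)
            spec_ = len(others - union) / len(others)
            hits.append((sens, spec_))
        sens = np.mean([h[0] for h in hits])
        spec_ = np.mean([h[1] for h in hits])
        assert sens >= 0.9
        assert spec_ >= 0.9

    def test_permissive_thresholds_keep_changed_genes(self, default_cube):
        spec = SelectionSpec(baseline_p=1.0001, baseline_fold=1.0)
        per_tp, union, tabs = baseline_contrast(default_cube, spec)
        changed = {
            g
            for t, tab in tabs.items()
            for g in tab.index[tab["log2_ratio"].abs() > 0]
        }
        assert union == changed
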