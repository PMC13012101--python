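"""Digital twin: per-cell normalization, GGM recovery, perturbation contracts."""

import numpy as np
import pandas as pd
import pytest

from synpas import twin as tw
from synpas.io import ExpressionMatrix, PNNode, ProteostasisNetwork
from synpas.simulate import gen_single_cell, make_planted_precision
from synpas.stats import cohens_d


def cells_from(values: np.ndarray, genes=None) -> ExpressionMatrix:
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=genes,
                      columns=[f"c{i}" for i in range(values.shape[1])])
    return ExpressionMatrix(df, scale="linear")


class TestPerCellZscore:
    def test_direct_formula(self):
        mat = cells_from(np.array([[2.0], [4.0], [6.0]]))
        z, stats = tw.zscore_per_cell(mat)
        assert np.allclose(z.values["c0"], [-1.224744871391589, 0.0, 1.224744871391589])
        assert stats.loc["c0", "mean"] == 4.0

    def test_frozen_stats_are_idempotent_and_invertible(self):
        rng = np.random.default_rng(0)
        mat = cells_from(rng.uniform(1, 20, size=(8, 5)))
        z, stats = tw.zscore_per_cell(mat)
        z2 = tw.apply_norm_stats(mat.values, stats)
        pd.testing.assert_frame_equal(z.values, z2)
        back = z.values.mul(stats["sd"], axis=1).add(stats["mean"], axis=1)
        assert np.allclose(back, mat.values, atol=1e-10)

    def test_constant_cell_rejected(self):
        with pytest.raises(ValueError):
            tw.zscore_per_cell(cells_from(np.ones((3, 2))))


class TestGGM:
    def test_identity_precision_yields_no_structure(self):
        prec, _ = make_planted_precision(10, 0.0, structure="pairs")
        rng = np.random.default_rng(1)
        z = pd.DataFrame(rng.standard_normal((10, 2000)), index=prec.index)
        fit = tw.fit_ggm(z)
        off = fit.pcor.to_numpy()[np.triu_indices(10, 1)]
        q = fit.q.to_numpy()[np.triu_indices(10, 1)]
        assert np.abs(off).max() < 0.1
        assert (q >= 0.05).mean() >= 0.95

    def test_chain_conditional_independence(self):
        # A-B-C chain: pcor(A,C | B) should be near zero
        prec, _ = make_planted_precision(3, 0.45, structure="chain",
                                         genes=["A", "B", "C"])
        cells, _ = gen_single_cell(prec, 2000, seed=2, n_background=0)
        vals = cells.values - 10.0  # back to the raw Gaussian scale
        fit = tw.fit_ggm(vals)
        assert abs(fit.pcor.loc["A", "C"]) < 0.1
        # oracle: invert the sample covariance directly
        cov = np.cov(vals.to_numpy())
        om = np.linalg.inv(cov)
        oracle_ac = -om[0, 2] / np.sqrt(om[0, 0] * om[2, 2])
        assert fit.pcor.loc["A", "C"] == pytest.approx(oracle_ac, abs=0.05)

    def test_symmetry_unit_diagonal_and_lambda_range(self):
        rng = np.random.default_rng(3)
        z = pd.DataFrame(rng.standard_normal((6, 200)),
                         index=[f"G{i}" for i in range(6)])
        fit = tw.fit_ggm(z)
        p = fit.pcor.to_numpy()
        assert np.allclose(p, p.T)
        assert np.allclose(np.diag(p), 1.0)
        assert np.abs(p).max() <= 1.0 + 1e-12
        assert 0.0 <= fit.shrinkage_lambda <= 1.0
        assert ((fit.q.to_numpy() >= 0) & (fit.q.to_numpy() <= 1)).all()

    def test_planted_edge_recovery(self):
        prec, edges = make_planted_precision(20, 0.3)
        cells, _ = gen_single_cell(prec, 2000, seed=4, n_background=100)
        z, stats = tw.zscore_per_cell(cells)
        fit = tw.fit_ggm(z.values.loc[list(prec.index)], norm_stats=stats)
        called = {frozenset(e) for e in fit.significant_edges(0.05)}
        planted = {frozenset(e) for e in edges}
        assert len(called & planted) / len(planted) >= 0.9

    def test_input_guards(self):
        z = pd.DataFrame(np.random.default_rng(0).standard_normal((2, 100)))
        with pytest.raises(ValueError):
            tw.fit_ggm(z)


class TestLinearTwin:
    def test_ols_slopes_on_significant_edges_only(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(500)
        y = 0.7 * x + 0.1 * rng.standard_normal(500)
        w = rng.standard_normal(500)
        z = pd.DataFrame({"X": x, "Y": y, "W": w}).T
        fit = tw.fit_ggm(z)
        twin = tw.build_linear_twin(fit, z, q_cut=0.05)
        slope_xy = np.cov(y, x)[0, 1] / np.var(x, ddof=1)
        assert twin.slope("Y", "X") == pytest.approx(slope_xy, abs=1e-12)
        assert twin.slope("W", "X") == 0.0  # non-significant pair stays zero

    def test_json_round_trip(self, tmp_path):
        twin = tw.LinearTwin(genes=["A", "B"], slopes={("A", "B"): 0.5}, q_cut=0.01)
        twin.to_json(tmp_path / "twin.json")
        back = tw.LinearTwin.from_json(tmp_path / "twin.json")
        assert back.slopes == twin.slopes and back.q_cut == 0.01


@pytest.fixture
def planted_setup():
    """Query couples positively to two promoters; network has mixed signs."""
    genes = ["Q", "P1", "P2", "A1", "F1", "F2"]
    nodes = [PNNode("Q", "promoter", 1, "first_degree"),
             PNNode("P1", "promoter", 1, "first_degree"),
             PNNode("P2", "promoter", 1, "first_degree"),
             PNNode("A1", "attenuator", -1, "first_degree"),
             PNNode("F1", "promoter", 1, "first_degree"),
             PNNode("F2", "attenuator", -1, "first_degree")]
    pn = ProteostasisNetwork("SNCA", nodes, [])
    rng = np.random.default_rng(6)
    cells = cells_from(rng.normal(10, 1, (6, 400)), genes)
    _, stats = tw.zscore_per_cell(cells)
    twin = tw.LinearTwin(genes=genes, slopes={("P1", "Q"): 0.8, ("P2", "Q"): 0.6})
    return twin, cells, stats, pn


class TestPerturbation:
    def test_factor_one_is_bitwise_identity(self, planted_setup):
        twin, cells, stats, pn = planted_setup
        out = tw.simulate_perturbation(twin, cells, stats, pn, "Q", 1.0)
        assert (out.pas_perturbed == out.pas_baseline).all()
        assert out.cohen_d == 0.0

    def test_propagated_delta_z_equals_slope_times_query_delta(self, planted_setup):
        twin, cells, stats, pn = planted_setup
        factor = 3.0
        z0 = tw.apply_norm_stats(cells.values, stats)
        dzq = cells.values.loc["Q"] * (factor - 1.0) / stats["sd"]
        out = tw.simulate_perturbation(twin, cells, stats, pn, "Q", factor)
        # reconstruct the perturbed PAS from the linear contract
        signs = pn.signs
        k = pn.K
        expected = out.pas_baseline + (
            signs["Q"] * dzq + signs["P1"] * 0.8 * dzq + signs["P2"] * 0.6 * dzq
        ).to_numpy() / k
        assert np.allclose(out.pas_perturbed, expected, atol=1e-12)

    def test_zero_slope_promoter_query_raises_pas(self, planted_setup):
        _, cells, stats, pn = planted_setup
        inert = tw.LinearTwin(genes=list(cells.values.index), slopes={})
        out = tw.simulate_perturbation(inert, cells, stats, pn, "Q", 8.0)
        assert out.pas_perturbed.mean() > out.pas_baseline.mean()

    def test_direction_and_monotonicity_of_effect_size(self, planted_setup):
        twin, cells, stats, pn = planted_setup
        d = {f: tw.simulate_perturbation(twin, cells, stats, pn, "Q", f).cohen_d
             for f in list(tw.KNOCKDOWN_FACTORS) + list(tw.OVEREXPRESSION_FACTORS)}
        assert d[0.12] < 0 and d[8.0] > 0
        ordered = sorted(d, key=lambda f: abs(np.log2(f)))
        mags = [abs(d[f]) for f in ordered if f != 1.0]
        # |d| grows with |log2 factor| within each arm and overall ordering
        kd = [abs(d[f]) for f in (0.75, 0.5, 0.25, 0.12, 0.06)]
        ov = [abs(d[f]) for f in (1.25, 1.5, 1.75, 2.0, 4.0, 8.0)]
        assert kd == sorted(kd) and ov == sorted(ov)

    def test_cohens_d_matches_independent_formula(self, planted_setup):
        twin, cells, stats, pn = planted_setup
        out = tw.simulate_perturbation(twin, cells, stats, pn, "Q", 2.0)
        assert out.cohen_d == pytest.approx(
            cohens_d(out.pas_perturbed, out.pas_baseline), abs=1e-14)

    def test_invalid_inputs(self, planted_setup):
        twin, cells, stats, pn = planted_setup
        with pytest.raises(ValueError):
            tw.simulate_perturbation(twin, cells, stats, pn, "Q", 0.0)
        with pytest.raises(ValueError):
            tw.simulate_perturbation(twin, cells, stats, pn, "NOPE", 2.0)


class TestScreen:
    def test_cardinality_and_ranking(self, planted_setup):
        twin, cells, stats, pn = planted_setup
        outcomes, ranking = tw.perturbation_screen(
            twin, cells, stats, pn, ["Q", "F1"])
        assert len(outcomes) == 22  # 2 queries x 11 factors
        # the coupled query moves PAS more than the inert one
        assert ranking.iloc[0]["query"] == "Q"
        assert list(ranking["rank"]) == [1, 2]

    def test_deterministic_across_calls(self, planted_setup):
        twin, cells, stats, pn = planted_setup
        _, r1 = tw.perturbation_screen(twin, cells, stats, pn, ["Q", "F1"])
        _, r2 = tw.perturbation_screen(twin, cells, stats, pn, ["Q", "F1"])
        pd.testing.assert_frame_equal(r1, r2)
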