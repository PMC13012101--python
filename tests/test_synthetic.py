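"""Synthetic generators: determinism, planted structure, recoverability."""

import numpy as np
import pandas as pd
import pytest

from synpas import network as net
from synpas import simulate as sim
from synpas.io import PNNode, ProteostasisNetwork


def small_net():
    nodes = [PNNode("A", "promoter", 1, "first_degree"),
             PNNode("B", "attenuator", -1, "first_degree"),
             PNNode("C", "promoter", 1, "first_degree"),
             PNNode("D", "attenuator", -1, "first_degree")]
    return ProteostasisNetwork("SNCA", nodes, [])


class TestEdgelist:
    def test_same_seed_identical_different_seed_not(self):
        e1, r1, t1 = sim.gen_edgelist(8, 30, 4, seed=11)
        e2, r2, t2 = sim.gen_edgelist(8, 30, 4, seed=11)
        e3, _, _ = sim.gen_edgelist(8, 30, 4, seed=12)
        assert e1 == e2 and r1 == r2 and t1 == t2
        assert e1 != e3

    def test_planted_structure_counts(self):
        edges, roles, truth = sim.gen_edgelist(10, 50, 5, seed=0,
                                               promoter_fraction=0.6)
        assert len(truth["first_degree"]) == 10
        assert len(truth["upstream"]) == 5
        assert sum(r == "promoter" for r in roles.values()) == 6
        # every first-degree gene has a directed edge into the focal gene
        inward = {e.source for e in edges if e.target == "SNCA" and e.directed}
        assert set(truth["first_degree"]) <= inward
        # non-member inward genes point at the focal but are not members
        assert set(truth["non_member_inward"]) <= inward
        assert not set(truth["non_member_inward"]) & set(truth["pn_members"])
        # upstream genes never touch the focal directly
        for e in edges:
            assert not ("UP" in e.source and e.target == "SNCA")

    def test_first_degree_recovered_exactly(self):
        edges, _, truth = sim.gen_edgelist(12, 40, 6, seed=3)
        fd = net.first_degree_interactors(edges, set(truth["pn_members"]), "SNCA")
        assert fd == set(truth["first_degree"])


class TestCaseControl:
    GENES = ["SNCA"] + [f"P{i}" for i in range(4)] + [f"B{i}" for i in range(20)]

    def test_determinism(self):
        planted = [("P0", "up", 1.0)]
        d1, t1 = sim.gen_case_control_sets(3, 6, 6, self.GENES, planted, 0.2, 2, seed=5)
        d2, t2 = sim.gen_case_control_sets(3, 6, 6, self.GENES, planted, 0.2, 2, seed=5)
        for a, b in zip(d1, d2):
            pd.testing.assert_frame_equal(a.values, b.values)
        assert t1["planted"] == t2["planted"]

    def test_noiseless_effect_exact(self):
        planted = [("P0", "up", 0.8), ("P1", "down", 0.5)]
        datasets, truth = sim.gen_case_control_sets(
            2, 6, 6, self.GENES, planted, 0.0, 2, seed=1)
        for mat in datasets:
            rel = net.relative_expression(mat, "SNCA")
            res = {r.gene: r for r in net.differential_relative_expression(
                rel, "case", "control")}
            assert res["P0"].fc == pytest.approx(0.8, abs=1e-10)
            assert res["P1"].fc == pytest.approx(-0.5, abs=1e-10)
            assert res["B0"].fc == pytest.approx(0.0, abs=1e-10)

    def test_reference_gene_cannot_be_planted(self):
        with pytest.raises(ValueError):
            sim.gen_case_control_sets(2, 6, 6, self.GENES,
                                      [("SNCA", "up", 1.0)], 0.1, 2, seed=0)

    def test_carrier_datasets_respected(self):
        planted = [("P0", "up", 2.0)]
        datasets, truth = sim.gen_case_control_sets(
            5, 6, 6, self.GENES, planted, 0.0, 3, seed=7)
        carriers = set(truth["planted"][0]["datasets"])
        assert len(carriers) == 3
        for d, mat in enumerate(datasets):
            rel = net.relative_expression(mat, "SNCA")
            fc = {r.gene: r.fc for r in net.differential_relative_expression(
                rel, "case", "control")}["P0"]
            assert fc == pytest.approx(2.0 if d in carriers else 0.0, abs=1e-10)

    def test_monte_carlo_effect_recovery(self):
        """Mean observed fc across many datasets approaches the planted shift."""
        planted = [("P0", "up", 1.0)]
        datasets, _ = sim.gen_case_control_sets(
            30, 10, 10, self.GENES, planted, 0.4, 30, seed=9)
        fcs = []
        for mat in datasets:
            rel = net.relative_expression(mat, "SNCA")
            fcs.append({r.gene: r.fc for r in net.differential_relative_expression(
                rel, "case", "control")}["P0"])
        # sd of each fc estimate ~ 0.4*sqrt(2)*sqrt(2/10); mean of 30 ~ 0.065
        assert np.mean(fcs) == pytest.approx(1.0, abs=0.25)


class TestSingleCell:
    def test_precision_validation(self):
        bad = pd.DataFrame(np.array([[1.0, 2.0], [2.0, 1.0]]),
                           index=["A", "B"], columns=["A", "B"])
        with pytest.raises(ValueError):
            sim.gen_single_cell(bad, 100, seed=0)

    def test_determinism_and_offset(self):
        prec, _ = sim.make_planted_precision(6, 0.3)
        c1, t1 = sim.gen_single_cell(prec, 50, seed=4)
        c2, t2 = sim.gen_single_cell(prec, 50, seed=4)
        pd.testing.assert_frame_equal(c1.values, c2.values)
        assert (c1.values >= 1.0 - 1e-9).all().all()
        assert t1["offset"] == t2["offset"] >= 10.0

    def test_background_genes_appended(self):
        prec, _ = sim.make_planted_precision(5, 0.2)
        cells, truth = sim.gen_single_cell(prec, 30, seed=1, n_background=17)
        assert cells.values.shape[0] == 22
        assert sum(g.startswith("BGC") for g in truth["genes"]) == 17

    def test_planted_pairwise_correlation_sign(self):
        """Adjacent chain genes correlate positively when -pcor off-diagonals
        are planted (covariance of a tridiagonal precision chain)."""
        prec, edges = sim.make_planted_precision(4, 0.4, structure="pairs")
        cells, truth = sim.gen_single_cell(prec, 4000, seed=2, n_background=0)
        vals = cells.values.to_numpy() - truth["offset"]
        corr = np.corrcoef(vals)
        genes = list(prec.index)
        for a, b in edges:
            assert corr[genes.index(a), genes.index(b)] > 0.25

    def test_chain_marginal_variances_match_inverse_precision(self):
        prec, _ = sim.make_planted_precision(5, 0.3)
        cells, truth = sim.gen_single_cell(prec, 20000, seed=6, n_background=0)
        vals = cells.values.to_numpy() - truth["offset"]
        expected = np.diag(np.linalg.inv(prec.to_numpy()))
        assert np.allclose(vals.var(axis=1, ddof=1), expected, atol=0.05)


class TestDoseSignatures:
    def test_determinism(self):
        pn = small_net()
        r1, t1 = sim.gen_dose_signatures(5, [0.1, 1, 10], ["L1"], pn, seed=3)
        r2, t2 = sim.gen_dose_signatures(5, [0.1, 1, 10], ["L1"], pn, seed=3)
        assert t1["slopes"] == t2["slopes"]
        for a, b in zip(r1, r2):
            pd.testing.assert_series_equal(a.e, b.e)

    def test_delta_pas_identity_exact_even_with_jitter(self):
        from synpas.screen import signature_delta_pas
        pn = small_net()
        recs, truth = sim.gen_dose_signatures(
            ["d"], [0.1, 1.0, 10.0], ["L1"], pn,
            slope_map={"d": 0.7}, noise_sd=0.0, gene_jitter_sd=1.0, seed=8)
        df = signature_delta_pas(recs, pn).sort_values("concentration")
        b = truth["intercepts"][("d", "L1")]
        expected = [0.7 * np.log10(c) + b for c in (0.1, 1.0, 10.0)]
        assert np.allclose(df["delta_pas"], expected, atol=1e-12)

    def test_cardinality_and_naming(self):
        pn = small_net()
        recs, truth = sim.gen_dose_signatures(4, [0.1, 1, 10], ["L1", "L2"], pn, seed=0)
        assert len(recs) == 4 * 3 * 2
        assert set(truth["slopes"]) == {f"DRUG{i:03d}" for i in range(1, 5)}

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError):
            sim.gen_dose_signatures(2, [0.1, 1.0], ["L1"], small_net(), seed=0)


class TestCellLineTable:
    def test_determinism(self):
        pn = small_net()
        t1, tr1 = sim.gen_cell_line_table(15, 0.6, pn, seed=2)
        t2, tr2 = sim.gen_cell_line_table(15, 0.6, pn, seed=2)
        pd.testing.assert_frame_equal(t1, t2)
        assert tr1["expected_rank"] == tr2["expected_rank"]

    def test_detectable_count_exact(self):
        pn = small_net()
        for frac, n, expect in ((0.6, 10, 6), (0.5, 11, 6), (1.0, 7, 7)):
            table, truth = sim.gen_cell_line_table(n, frac, pn, seed=1)
            assert len(truth["detectable"]) == expect
            snca = table["SNCA"]
            assert (snca.loc[truth["detectable"]] > 2.0).all()
            rest = snca.drop(index=truth["detectable"])
            assert (rest <= 2.0).all()

    def test_expected_rank_is_permutation(self):
        pn = small_net()
        _, truth = sim.gen_cell_line_table(12, 0.75, pn, seed=5)
        ranks = sorted(truth["expected_rank"].values())
        assert ranks == list(range(1, 10))

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            sim.gen_cell_line_table(10, 0.0, small_net(), seed=0)
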