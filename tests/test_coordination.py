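import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest

from protectomics.coordination import (
    build_network,
    classify_coordination,
    condition_edges,
    cross_set_percentages,
    detect_switches,
    pair_count,
    pairwise_correlation,
    r_critical,
    switch_census,
)
from protectomics.normalize import normalize_experiment
from protectomics.pathway import GeneSet
from protectomics.synthetic import (
    SimulationConfig,
    correlated_block,
    generate_experiment,
)


class TestPairCount:
    @pytest.mark.parametrize("g, want", [(0, 0), (1, 0), (2, 1), (5, 10)])
    def test_small_cases(self, g, want):
        assert pair_count(g) == want

    def test_transcriptome_scale(self):
        assert pair_count(12_710) == 80_765_695


class TestCriticalValue:
    def test_four_replicates_exact(self):
        # t_{0.975,2} = 4.3027 -> r_crit = t/sqrt(t^2+2) = 0.9500
        assert r_critical(0.05, 4) == pytest.approx(0.9500, abs=1e-4)

    def test_decreases_with_n(self):
        assert r_critical(0.05, 10) < r_critical(0.05, 4)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            r_critical(0.05, 2)


class TestClassify:
    @pytest.mark.parametrize("r, want", [
        (0.96, "S"), (-0.96, "A"), (0.0, "I"), (0.25, "I"),
        (0.5, "U"), (-0.94, "U"),
    ])
    def test_classes_at_n4(self, r, want):
        assert classify_coordination(r, 4)[()] == want

    def test_uncomputable_stays_unclassified(self):
        out = classify_coordination(np.array([np.nan, 0.99]), 4)
        assert out[0] is None and out[1] == "S"


class TestPairwiseCorrelation:
    def test_exact_linearity(self):
        vals = pd.DataFrame(
            [[1, 2, 3, 4], [2, 4, 6, 8], [8, 6, 4, 2]],
            index=["x", "y1", "y2"], dtype=float)
        out = pairwise_correlation(vals).set_index(["gene_a", "gene_b"])["r"]
        assert out[("x", "y1")] == pytest.approx(1.0)
        assert out[("x", "y2")] == pytest.approx(-1.0)

    def test_pair_enumeration_count(self):
        rng = np.random.default_rng(0)
        vals = pd.DataFrame(rng.normal(size=(30, 4)),
                            index=[f"g{i}" for i in range(30)])
        out = pairwise_correlation(vals)
        assert len(out) == pair_count(30)
        # each unordered pair exactly once
        keys = {frozenset(p) for p in zip(out["gene_a"], out["gene_b"])}
        assert len(keys) == len(out)

    def test_matches_numpy_oracle(self):
        rng = np.random.default_rng(3)
        vals = pd.DataFrame(rng.normal(size=(12, 6)),
                            index=[f"g{i}" for i in range(12)])
        out = pairwise_correlation(vals, block_size=5)
        ref = np.corrcoef(vals.to_numpy())
        idx = {g: i for i, g in enumerate(vals.index)}
        for _, row in out.iterrows():
            assert row["r"] == pytest.approx(
                ref[idx[row["gene_a"]], idx[row["gene_b"]]], abs=1e-12)

    def test_affine_invariance_and_sign_flip(self):
        vals = pd.DataFrame([[1.0, 2, 3, 5], [4, 1, 7, 2]], index=["a", "b"])
        r0 = pairwise_correlation(vals)["r"][0]
        vals2 = vals.copy()
        vals2.loc["a"] = 3.0 * vals.loc["a"] + 10
        assert pairwise_correlation(vals2)["r"][0] == pytest.approx(r0)
        vals2.loc["a"] = -2.0 * vals.loc["a"] + 1
        assert pairwise_correlation(vals2)["r"][0] == pytest.approx(-r0)

    def test_zero_variance_uncomputable(self):
        vals = pd.DataFrame([[1.0, 1, 1, 1], [1, 2, 3, 4]], index=["a", "b"])
        out = pairwise_correlation(vals)
        assert np.isnan(out["r"][0])

    def test_cross_pairs(self):
        rng = np.random.default_rng(1)
        vals = pd.DataFrame(rng.normal(size=(6, 4)),
                            index=[f"g{i}" for i in range(6)])
        out = pairwise_correlation(vals, ["g0", "g1"], ["g2", "g3", "g4"])
        assert len(out) == 6


class TestCrossSetPercentages:
    def edges(self, classes):
        rows = [(f"a{i}", f"b{j}", c)
                for (i, j), c in zip(itertools.product(range(2), range(2)),
                                     classes)]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "class"])

    def test_all_synergistic(self):
        e = self.edges(["S", "S", "S", "S"])
        assert cross_set_percentages(["a0", "a1"], ["b0", "b1"], e) == \
            (100.0, 0.0, 0.0)

    def test_mixed_counts(self):
        e = self.edges(["S", "S", "A", "I"])
        assert cross_set_percentages(["a0", "a1"], ["b0", "b1"], e) == \
            (50.0, 25.0, 25.0)

    def test_undetermined_leaves_remainder(self):
        e = self.edges(["S", "U", "U", "U"])
        s, a, i = cross_set_percentages(["a0", "a1"], ["b0", "b1"], e)
        assert (s, a, i) == (25.0, 0.0, 0.0)

    def test_common_genes_dropped_from_both_sides(self):
        e = pd.DataFrame([("x", "b0", "S"), ("a0", "b0", "A")],
                         columns=["gene_a", "gene_b", "class"])
        # x is in both sets -> only the a0-b0 pair counts
        s, a, i = cross_set_percentages(["a0", "x"], ["b0", "x"], e)
        assert (s, a, i) == (0.0, 100.0, 0.0)

    def test_empty_cross_pairs_rejected(self):
        e = self.edges(["S"])[:0]
        with pytest.raises(ValueError, match="cross-set"):
            cross_set_percentages(["a0"], ["b0"], e)


def _edges(rows):
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "class"])


class TestSwitches:
    def test_s_to_a_detected(self):
        e1 = _edges([("x", "y", "S"), ("x", "z", "S")])
        e2 = _edges([("x", "y", "A"), ("x", "z", "S")])
        sw = detect_switches(e1, e2)
        assert len(sw) == 1
        assert sw.iloc[0]["switch_type"] == "S->A"

    def test_stable_pairs_silent(self):
        e = _edges([("x", "y", "S")])
        assert detect_switches(e, e).empty

    def test_uncomputable_pairs_excluded(self):
        e1 = _edges([("x", "y", "S"), ("x", "z", None)])
        e2 = _edges([("x", "y", "A"), ("x", "z", "S")])
        assert len(detect_switches(e1, e2)) == 1

    def test_mismatched_universe_rejected(self):
        e1 = _edges([("x", "y", "S")])
        e2 = _edges([("x", "z", "S")])
        with pytest.raises(ValueError, match="universes"):
            detect_switches(e1, e2)

    def test_census_counts_per_gene(self):
        e1 = _edges([("j", "a", "S"), ("j", "b", "S"), ("j", "c", "A")])
        e2 = _edges([("j", "a", "A"), ("j", "b", "A"), ("j", "c", "S")])
        census = switch_census(detect_switches(e1, e2))
        assert census.loc["j", "S->A"] == 2
        assert census.loc["j", "A->S"] == 1


@pytest.fixture(scope="module")
def flipped_block_experiment():
    """Two coordinated groups whose cross-correlation sign flips in CES."""
    flip = {"CES": frozenset({"Gene0004", "Gene0005", "Gene0006"})}
    block = correlated_block(
        [f"Gene{i:04d}" for i in range(1, 7)], rho=0.98,
        condition_flips=flip)
    cfg = dataclasses.replace(
        SimulationConfig(n_genes=40, seed=21, invalid_spot_fraction=0.0,
                         technical_cv=0.05),
        planted_correlation_blocks=(block,),
    )
    spots, design, truth = generate_experiment(cfg)
    em, _, _ = normalize_experiment(spots, design)
    return em, truth


class TestOnSimulatedData:
    def test_switch_detection_equals_brute_force(self, flipped_block_experiment):
        """detect_switches must agree with re-classifying every pair in
        both conditions and differencing the class maps."""
        em, _ = flipped_block_experiment
        genes = [g for g in em.genes
                 if em.mask["CEN"].loc[g].all() and em.mask["CES"].loc[g].all()]
        e1 = condition_edges(em, "CEN", genes_a=genes)
        e2 = condition_edges(em, "CES", genes_a=genes)
        sw = detect_switches(e1, e2)
        got = {(r["gene_a"], r["gene_b"]): (r["from_class"], r["to_class"])
               for _, r in sw.iterrows()}

        # brute force oracle over explicit pairs
        c1 = e1.set_index(["gene_a", "gene_b"])["class"]
        c2 = e2.set_index(["gene_a", "gene_b"])["class"]
        want = {}
        for pair in c1.index:
            a, b = c1[pair], c2[pair]
            if a is not None and b is not None and not pd.isna(a) \
                    and not pd.isna(b) and a != b:
                want[pair] = (a, b)
        assert got == want

    def test_planted_flip_produces_cross_switches(self, flipped_block_experiment):
        em, truth = flipped_block_experiment
        keep = [f"Gene{i:04d}" for i in range(1, 7)]
        e1 = condition_edges(em, "CEN", genes_a=keep)
        e2 = condition_edges(em, "CES", genes_a=keep)
        sw = detect_switches(e1, e2)
        flipped = truth.coordination.query(
            "condition == 'CES' and r_planted < 0")[["gene_a", "gene_b"]]
        flipped_pairs = set(map(frozenset, flipped.to_numpy()))
        sa = sw[sw["switch_type"] == "S->A"]
        found = set(frozenset(p) for p in zip(sa["gene_a"], sa["gene_b"]))
        # every detected S->A switch is a genuinely flipped pair
        assert found <= flipped_pairs
        assert len(found) > 0


class TestBuildNetwork:
    def test_empty_common_genes_empty_network(self):
        esg = GeneSet("ESG", ("e1", "e2"))
        nt = GeneSet("GLU", ("n1", "n2"))
        edges = _edges([("e1", "n1", "S")])
        g = build_network(esg, nt, [], edges)
        assert g.number_of_edges() == 0

    def test_two_layer_edges_through_common_gene(self):
        esg = GeneSet("ESG", ("e1", "cg"))
        nt = GeneSet("GLU", ("n1", "cg"))
        edges = _edges([("cg", "e1", "S"), ("cg", "n1", "A"),
                        ("e1", "n1", "S")])  # direct ESG-NT edge excluded
        g = build_network(esg, nt, ["cg"], edges)
        assert g.number_of_edges() == 2
        assert g.edges[("cg", "e1")]["coordination"] == "S"
        assert g.nodes["cg"]["layer"] == "CG"

    def test_undetermined_draws_no_line(self):
        esg = GeneSet("ESG", ("e1", "cg"))
        nt = GeneSet("GLU", ("n1", "cg"))
        edges = _edges([("cg", "e1", "U"), ("cg", "n1", "I")])
        g = build_network(esg, nt, ["cg"], edges)
        assert g.number_of_edges() == 1

    def test_stray_common_genes_warned(self, caplog):
        esg = GeneSet("ESG", ("e1",))
        nt = GeneSet("GLU", ("n1",))
        with caplog.at_level("WARNING"):
            build_network(esg, nt, ["zz"], _edges([]))
        assert "zz" in caplog.text

    def test_regulation_annotation(self):
        esg = GeneSet("ESG", ("e1", "cg"))
        nt = GeneSet("GLU", ("n1", "cg"))
        reg = pd.DataFrame({"x": [2.0], "call": ["up"]},
                           index=pd.Index(["cg"], name="gene"))
        g = build_network(esg, nt, ["cg"], _edges([]), regulation=reg)
        assert g.nodes["cg"]["regulation"] == "up"
        assert g.nodes["e1"]["regulation"] == "unquantified"
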