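"""Similarity networks and sequence-feature statistics of associated TCRs."""

from itertools import combinations, permutations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from tcrhla.association import AssociationRecord
from tcrhla.network import (
    annotate_epitopes,
    build_network,
    cdr3_length_profile,
    compare_repertoire_v_usage,
    hamming1,
    v_usage_enrichment,
    write_network,
)

from conftest import A0201, B0702, alpha, beta


def record(clonotype, allele=A0201):
    return AssociationRecord(
        clonotype=clonotype, allele=allele, n_pp=5, n_pn=1, n_np=1, n_nn=5,
        p_raw=0.001, p_adj=0.005,
    )


class TestHamming:
    def test_distance_one_and_equal_length_rule(self):
        assert hamming1("CASSLGETQYF", "CASSLGDTQYF")
        assert hamming1("CASSF", "CASSF")
        assert not hamming1("CASSLGETQYF", "CASSLGDTQYA" "A")  # length differs
        assert not hamming1("CASSAA", "CASSTT")  # two mismatches


class TestBuildNetwork:
    def test_edge_and_component_structure(self):
        records = [
            record(beta("CASSLGETQYF")),
            record(beta("CASSLGDTQYF")),
            record(beta("CASSIRSSYEQYF"), allele=B0702),
        ]
        g = build_network(records)
        assert g.number_of_nodes() == 3
        assert g.number_of_edges() == 1
        components = {g.nodes[n]["component"] for n in g.nodes}
        assert len(components) == 2

    def test_same_cdr3_different_v_family_no_edge(self):
        records = [record(beta("CASSLGETQYF")), record(beta("CASSLGETQYF", v="TRBV7"))]
        g = build_network(records)
        assert g.number_of_edges() == 0

    def test_all_distant_nodes_are_singletons(self):
        records = [record(beta("CASS" + aa * 3 + "F")) for aa in "AGLPW"]
        g = build_network(records)
        assert g.number_of_edges() == 0
        assert len({g.nodes[n]["component"] for n in g.nodes}) == 5

    def test_order_invariance(self):
        records = [
            record(beta("CASSLGETQYF")),
            record(beta("CASSLGDTQYF")),
            record(beta("CASSLGDAQYF"), allele=B0702),
        ]
        g1 = build_network(records)
        g2 = build_network(records[::-1])
        assert set(g1.edges) == set(g2.edges)
        assert {n: g1.nodes[n]["component"] for n in g1} == {
            n: g2.nodes[n]["component"] for n in g2
        }

    def test_single_allele_components_have_purity_one(self):
        records = [record(beta("CASSLG" + s + "QYF")) for s in ("ET", "DT", "EA")]
        g = build_network(records)
        assert all(g.nodes[n]["purity"] == 1.0 for n in g)

    def test_export_round_trip_columns(self, tmp_path):
        records = [record(beta("CASSLGETQYF")), record(beta("CASSLGDTQYF"))]
        g = build_network(records)
        write_network(g, tmp_path / "e.tsv", tmp_path / "n.tsv")
        nodes = pd.read_csv(tmp_path / "n.tsv", sep="\t")
        edges = pd.read_csv(tmp_path / "e.tsv", sep="\t")
        assert len(nodes) == 2 and len(edges) == 1
        assert set(nodes["alleles"]) == {"A*02:01"}


class TestAnnotateEpitopes:
    def _graph(self):
        return build_network([record(beta("CASSLGETQYF")), record(beta("CASSIRSSYEQYF"))])

    def test_exact_match_attaches_epitope(self):
        g = self._graph()
        ref = pd.DataFrame(
            [{"cdr3_aa": "CASSLGETQYF", "v_family": "TRBV19", "epitope": "GILGFVFTL"}]
        )
        annotate_epitopes(g, ref)
        annotated = {c.cdr3_aa: g.nodes[c].get("epitopes") for c in g.nodes}
        assert annotated["CASSLGETQYF"] == ("GILGFVFTL",)
        assert annotated["CASSIRSSYEQYF"] is None

    def test_v_family_mismatch_blocks_annotation(self):
        g = self._graph()
        ref = pd.DataFrame(
            [{"cdr3_aa": "CASSLGETQYF", "v_family": "TRBV7", "epitope": "GILGFVFTL"}]
        )
        annotate_epitopes(g, ref)
        assert all(g.nodes[c].get("epitopes") is None for c in g.nodes)

    def test_empty_reference_leaves_network_unchanged(self):
        g = self._graph()
        ref = pd.DataFrame(columns=["cdr3_aa", "v_family", "epitope"])
        annotate_epitopes(g, ref)
        assert all("epitopes" not in g.nodes[c] for c in g.nodes)

    def test_malformed_rows_are_skipped(self):
        g = self._graph()
        ref = pd.DataFrame(
            [
                {"cdr3_aa": None, "v_family": "TRBV19", "epitope": "X"},
                {"cdr3_aa": "CASSLGETQYF", "v_family": "TRBV19", "epitope": "GILGFVFTL"},
            ]
        )
        annotate_epitopes(g, ref)
        assert g.nodes[beta("CASSLGETQYF")]["epitopes"] == ("GILGFVFTL",)


class TestCdr3LengthProfile:
    def test_identical_lists_give_identical_histograms(self):
        clonos = [beta("C" + "A" * k + "F") for k in range(6, 16) for _ in range(20)]
        out = cdr3_length_profile(clonos, clonos)
        beta_out = out["beta"]
        assert np.allclose(beta_out["subset_hist"], beta_out["background_hist"])
        assert beta_out["mwu_p"] >= 0.5

    def test_planted_shift_detected_by_sign(self):
        short = [beta("C" + "A" * 6 + "F") for _ in range(50)]
        long = [beta("C" + "A" * 10 + "F") for _ in range(50)]
        out = cdr3_length_profile(short, long)
        assert out["beta"]["subset_mean"] < out["beta"]["background_mean"]

    def test_single_length_subset_has_unit_mass(self):
        subset = [beta("CASSLGETQYF")]
        background = [beta("CASSF"), beta("CASSLGETQYF")]
        hist = cdr3_length_profile(subset, background)["beta"]["subset_hist"]
        assert hist.loc[11] == 1.0 and hist.sum() == 1.0


class TestVUsage:
    def test_planted_composition_ratio(self):
        subset = [beta(f"CAS{'A' * i}SF", v="TRBV19") for i in range(5)] + [
            beta(f"CAS{'G' * i}SF", v="TRBV7") for i in range(5)
        ]
        background = [beta(f"CAS{'L' * i}SF", v="TRBV19") for i in range(1)] + [
            beta(f"CAS{'P' * i}SF", v="TRBV7") for i in range(9)
        ]
        df = v_usage_enrichment(subset, background)
        row = df[(df.chain == "beta") & (df.v_family == "TRBV19")].iloc[0]
        assert row.ratio == pytest.approx(0.5 / 0.1)

    def test_identical_lists_give_unit_ratios(self):
        clonos = [beta("CASSF"), beta("CAWWF", v="TRBV7")]
        df = v_usage_enrichment(clonos, clonos)
        assert (df.ratio == 1.0).all()

    def test_family_absent_from_subset_reported_as_zero(self):
        subset = [beta("CASSF")]
        background = [beta("CAWWF", v="TRBV7"), beta("CASSF")]
        df = v_usage_enrichment(subset, background)
        row = df[df.v_family == "TRBV7"].iloc[0]
        assert row.freq_subset == 0.0


def mwu_exact_oracle(a, b):
    """Two-sided p by exhaustive enumeration of group assignments."""
    pooled = list(a) + list(b)
    n_a = len(a)

    def u_stat(xs, ys):
        return sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in xs for y in ys)

    observed = u_stat(a, b)
    mean_u = len(a) * len(b) / 2.0
    count = 0
    total = 0
    for idx in combinations(range(len(pooled)), n_a):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_stat(xs, ys) - mean_u) >= abs(observed - mean_u) - 1e-12:
            count += 1
    return count / total


class TestCompareRepertoireVUsage:
    def test_small_groups_match_exact_permutation_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = list(rng.uniform(size=4))
            b = list(rng.uniform(size=4))
            df = compare_repertoire_v_usage(
                [{"TRBV19": x} for x in a], [{"TRBV19": x} for x in b]
            )
            assert df.p_raw.iloc[0] == pytest.approx(mwu_exact_oracle(a, b), abs=1e-9)

    def test_planted_shift_flags_only_the_shifted_family(self):
        rng = np.random.default_rng(1)
        group_a = [
            {"TRBV19": 0.2 + rng.normal(0, 0.01), "TRBV7": 0.1 + rng.normal(0, 0.01)}
            for _ in range(30)
        ]
        group_b = [
            {"TRBV19": 0.1 + rng.normal(0, 0.01), "TRBV7": 0.1 + rng.normal(0, 0.01)}
            for _ in range(30)
        ]
        df = compare_repertoire_v_usage(group_a, group_b).set_index("v_family")
        assert df.loc["TRBV19", "p_BH"] < 0.01
        assert df.loc["TRBV7", "p_BH"] > 0.05

    def test_null_gives_roughly_uniform_p(self):
        rng = np.random.default_rng(2)
        n_below = 0
        n_rep = 100
        for _ in range(n_rep):
            a = [{"TRBV19": x} for x in rng.uniform(size=10)]
            b = [{"TRBV19": x} for x in rng.uniform(size=10)]
            df = compare_repertoire_v_usage(a, b)
            n_below += df.p_raw.iloc[0] < 0.05
        # binomial(100, ~0.05): allow generous 3-sigma band
        assert n_below <= 12

    def test_constant_identical_values_flagged_tied(self):
        a = [{"TRBV19": 0.5}] * 3
        b = [{"TRBV19": 0.5}] * 3
        df = compare_repertoire_v_usage(a, b)
        assert df.p_raw.iloc[0] == 1.0 and bool(df.all_tied.iloc[0])

    def test_fewer_than_two_donors_is_an_error(self):
        with pytest.raises(ValueError):
            compare_repertoire_v_usage([{"TRBV19": 0.1}], [{"TRBV19": 0.1}] * 3)
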