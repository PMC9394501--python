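"""Phylogeny loading, SNP QC, haplogroup calling and indicator matrices."""

import numpy as np
import pandas as pd
import pytest

from ykin import simdata, ytree
from ykin.ytree import UNASSIGNED, GenotypePanel

from conftest import TOY_NEWICK, TOY_SNPS, toy_panel


# ---------------------------------------------------------------------------
# loading


def test_toy_tree_structure(toy_tree):
    assert toy_tree.root == "ROOT"
    assert set(toy_tree.nodes) == {"ROOT", "A", "A1", "A2", "B"}
    assert toy_tree.parent["A1"] == "A"
    assert sum(len(v) for v in toy_tree.branch_snps.values()) == 4
    assert [s.snp_id for s in toy_tree.path_snps("A1")] == ["sA", "sA1"]


def test_load_rejects_unknown_node(tmp_path):
    (tmp_path / "t.nwk").write_text(TOY_NEWICK)
    (tmp_path / "s.tsv").write_text(TOY_SNPS + "C\tsC\tA\tG\n")
    with pytest.raises(ValueError, match="'C'"):
        ytree.load_phylogeny(tmp_path / "t.nwk", tmp_path / "s.tsv")


def test_load_rejects_duplicate_labels(tmp_path):
    (tmp_path / "t.nwk").write_text("((A1,A2)A,A1)ROOT;\n")
    (tmp_path / "s.tsv").write_text(TOY_SNPS)
    with pytest.raises(ValueError):
        ytree.load_phylogeny(tmp_path / "t.nwk", tmp_path / "s.tsv")


def test_multiple_snps_attach_to_one_branch(tmp_path):
    (tmp_path / "t.nwk").write_text(TOY_NEWICK)
    extra = "A\tsA_b\tC\tA\nA\tsA_c\tG\tT\n"
    (tmp_path / "s.tsv").write_text(TOY_SNPS + extra)
    tree = ytree.load_phylogeny(tmp_path / "t.nwk", tmp_path / "s.tsv")
    assert len(tree.branch_snps["A"]) == 3


def test_fixture_tree_invariants(fixture_tree):
    assert fixture_tree.root == "ROOT"
    assert len(fixture_tree.nodes) == 21
    for n in fixture_tree.nodes:
        if n != "ROOT":
            assert fixture_tree.branch_snps[n]


# ---------------------------------------------------------------------------
# QC


def _panel_from_matrix(arr, snps=None):
    arr = np.asarray(arr, dtype=object)
    cols = snps or [f"s{j}" for j in range(arr.shape[1])]
    return GenotypePanel(pd.DataFrame(arr, columns=cols,
                                      index=[f"i{i}" for i in range(arr.shape[0])]))


def test_qc_drops_low_call_and_monomorphic():
    rng = np.random.default_rng(0)
    n = 20
    cols = {}
    for j in range(8):  # clean, polymorphic
        c = rng.choice(["A", "C"], size=n).astype(object)
        c[0], c[1] = "A", "C"
        cols[f"ok{j}"] = c
    low = rng.choice(["A", "C"], size=n).astype(object)
    low[:3] = np.nan  # call rate 0.85
    cols["lowcall"] = low
    cols["mono"] = np.array(["A"] * n, dtype=object)
    panel = GenotypePanel(pd.DataFrame(cols, index=[f"i{i}" for i in range(n)]))
    out = ytree.qc_snps(panel, min_call_rate=0.95)
    assert out.calls.shape[1] == 8
    assert "lowcall" not in out.snps and "mono" not in out.snps


def test_qc_monomorphism_judged_on_observed_calls():
    # variable calls exist but are all missing -> observed calls monomorphic
    col = np.array(["A", "A", "A", "A", "A", "A", "A", "A", "A", "A",
                    "A", "A", "A", "A", "A", "A", "A", "A", "A", np.nan], dtype=object)
    ok = np.array(["A", "C"] * 10, dtype=object)
    panel = _panel_from_matrix(np.column_stack([col, ok]), ["hidden_poly", "ok"])
    out = ytree.qc_snps(panel, min_call_rate=0.9)
    assert out.snps == ["ok"]


def test_qc_all_removed_is_error():
    panel = _panel_from_matrix(np.array([["A"] * 3] * 10, dtype=object))
    with pytest.raises(ValueError):
        ytree.qc_snps(panel)


def test_qc_idempotent():
    panel = simdata.qc_demo_panel(3)
    once = ytree.qc_snps(panel)
    twice = ytree.qc_snps(once)
    pd.testing.assert_frame_equal(once.calls, twice.calls)


# ---------------------------------------------------------------------------
# assignment, with a brute-force oracle


def brute_force_assign(tree, calls: dict[str, int | None]) -> str:
    """Independent enumeration of all root-to-node path scores."""
    observed = {s: v for s, v in calls.items() if v is not None}
    total_derived = sum(1 for v in observed.values() if v == 1)
    if not observed:
        return UNASSIGNED
    if total_derived == 0:
        return tree.root
    ranked = []
    for node in tree.nodes:
        path = {s.snp_id for s in tree.path_snps(node)}
        der = sum(1 for s in path if observed.get(s) == 1)
        anc = sum(1 for s in path if observed.get(s) == 0)
        miss = sum(1 for s in path if s not in observed)
        off = total_derived - der
        ranked.append((-(der - anc), off, miss, -tree.depth(node), node))
    return min(ranked)[4]


def test_all_ancestral_maps_to_root(toy_tree):
    panel = toy_panel(toy_tree, {"x": {s: 0 for s in toy_tree.snp_alleles}})
    assert ytree.assign_haplogroup(toy_tree, panel, "x") == "ROOT"


def test_assignment_examples_match_oracle(toy_tree):
    cases = {
        "path_A1": {"sA": 1, "sA1": 1},          # clean A1 carrier
        "conflict": {"sA1": 1, "sB": 1},         # derived on two branches
        "internal": {"sA": 1, "sA1": 0, "sA2": 0, "sB": 0},  # internal node A
        "noisyA2": {"sA": 1, "sA2": 1, "sB": 1},
    }
    panel = toy_panel(toy_tree, cases)
    got = ytree.assign_haplogroups(toy_tree, panel)
    for ind, calls in cases.items():
        assert got[ind] == brute_force_assign(toy_tree, calls), ind
    assert got["path_A1"] == "A1"
    assert got["internal"] == "A"


def test_assignment_random_calls_match_oracle(fixture_tree):
    rng = np.random.default_rng(7)
    snps = list(fixture_tree.snp_alleles)
    cases = {}
    for i in range(60):
        calls = {}
        for s in snps:
            r = rng.uniform()
            calls[s] = None if r < 0.2 else (1 if r < 0.45 else 0)
        cases[f"r{i}"] = calls
    panel = toy_panel(fixture_tree, cases)
    got = ytree.assign_haplogroups(fixture_tree, panel)
    for ind, calls in cases.items():
        assert got[ind] == brute_force_assign(fixture_tree, calls), ind


def test_all_missing_is_unassigned(toy_tree):
    panel = toy_panel(toy_tree, {"x": {s: None for s in toy_tree.snp_alleles}})
    assert ytree.assign_haplogroup(toy_tree, panel, "x") == UNASSIGNED


def test_absent_individual_is_error(toy_tree):
    panel = toy_panel(toy_tree, {"x": {}})
    with pytest.raises(KeyError):
        ytree.assign_haplogroup(toy_tree, panel, "nobody")


def test_roundtrip_recovery_any_node(fixture_tree):
    """Noise-free carriers of every node (internal included) are recovered."""
    cases = {}
    for node in fixture_tree.nodes:
        calls = {s: 0 for s in fixture_tree.snp_alleles}
        for s in fixture_tree.path_snps(node):
            calls[s.snp_id] = 1
        cases[node] = calls
    panel = toy_panel(fixture_tree, cases)
    got = ytree.assign_haplogroups(fixture_tree, panel)
    for node in fixture_tree.nodes:
        assert got[node] == node


def test_roundtrip_with_offpath_missingness(fixture_tree):
    """Half the off-path SNPs missing still gives exact recovery."""
    rng = np.random.default_rng(5)
    cases = {}
    truth = {}
    for i in range(80):
        node = rng.choice(fixture_tree.nodes)
        path = {s.snp_id for s in fixture_tree.path_snps(node)}
        calls = {}
        for s in fixture_tree.snp_alleles:
            if s in path:
                calls[s] = 1
            else:
                calls[s] = None if rng.uniform() < 0.5 else 0
        cases[f"i{i}"] = calls
        truth[f"i{i}"] = node
    got = ytree.assign_haplogroups(fixture_tree, toy_panel(fixture_tree, cases))
    assert all(got[k] == v for k, v in truth.items())


# ---------------------------------------------------------------------------
# indicator matrix


def _assignments(labels):
    return pd.Series(labels, index=[f"i{k}" for k in range(len(labels))])


def test_composite_union(toy_tree):
    asg = _assignments(["A1", "A2", "B"])
    mat = ytree.build_indicator_matrix(asg, toy_tree, {"Agrp": {"A1", "A2"}})
    assert mat.indicators["Agrp"].tolist() == [1, 1, 0]
    assert (mat.indicators["Agrp"] ==
            (mat.indicators["A1"] | mat.indicators["A2"])).all()


def test_composite_over_all_atoms_is_ones_for_assigned(toy_tree):
    asg = _assignments(["A1", "B", UNASSIGNED])
    mat = ytree.build_indicator_matrix(asg, toy_tree,
                                       {"all": set(toy_tree.nodes)})
    assert mat.indicators["all"].tolist() == [1, 1, 0]


def test_unassigned_rows_are_all_zero(toy_tree):
    asg = _assignments([UNASSIGNED, "A1"])
    mat = ytree.build_indicator_matrix(asg, toy_tree)
    assert mat.indicators.loc["i0"].sum() == 0


def test_paragroup_excludes_descendant_subtrees(fixture_tree):
    asg = _assignments(["R1b-M343", "R1b1-L21", "R1b2-U106", "P-M45"])
    mat = ytree.build_indicator_matrix(
        asg, fixture_tree,
        paragroup_defs={"R1b-M343*": {"ancestor": "R1b-M343",
                                      "exclude": ["R1b1-L21", "R1b2-U106"]}},
    )
    assert mat.indicators["R1b-M343*"].tolist() == [1, 0, 0, 0]
    assert mat.kinds["R1b-M343*"] == "paragroup"


def test_atomic_columns_mutually_exclusive(fixture_tree):
    rng = np.random.default_rng(0)
    asg = _assignments(rng.choice(fixture_tree.nodes, size=50))
    mat = ytree.build_indicator_matrix(asg, fixture_tree)
    atomic = [g for g, k in mat.kinds.items() if k == "atomic"]
    assert (mat.indicators[atomic].sum(axis=1) == 1).all()


def test_composite_unknown_node_is_error(toy_tree):
    with pytest.raises(ValueError):
        ytree.build_indicator_matrix(_assignments(["A1"]), toy_tree, {"bad": {"Z"}})


def test_column_sums_invariant_to_individual_order(fixture_tree):
    rng = np.random.default_rng(1)
    labels = rng.choice(fixture_tree.nodes, size=40)
    m1 = ytree.build_indicator_matrix(_assignments(labels), fixture_tree)
    m2 = ytree.build_indicator_matrix(_assignments(labels[::-1]), fixture_tree)
    pd.testing.assert_series_equal(m1.counts, m2.counts)


# ---------------------------------------------------------------------------
# group filtering and area prevalence


def test_filter_carrier_boundary(toy_tree):
    asg = _assignments(["A1"] * 99 + ["B"] * 101)
    mat = ytree.build_indicator_matrix(asg, toy_tree)
    kept = ytree.filter_groups(mat, min_carriers=100)
    assert "B" in kept.groups and "A1" not in kept.groups


def test_filter_case_boundary_closed(toy_tree):
    asg = _assignments(["A1"] * 80 + ["B"] * 20)
    mat = ytree.build_indicator_matrix(asg, toy_tree)
    cases = pd.Series([1.0] * 40 + [0.0] * 60, index=mat.indicators.index)
    kept = ytree.filter_groups(mat, case_indicator=cases, min_cases=40)
    assert "A1" in kept.groups  # exactly 40 carrier-cases is kept
    assert "B" not in kept.groups


def test_filter_zero_threshold_is_identity(toy_tree):
    asg = _assignments(["A1", "B"])
    mat = ytree.build_indicator_matrix(asg, toy_tree)
    kept = ytree.filter_groups(mat, min_carriers=0)
    assert kept.groups == mat.groups


def test_prevalence_single_area(toy_tree):
    asg = _assignments(["A1"] * 12 + ["B"] * 88)
    mat = ytree.build_indicator_matrix(asg, toy_tree)
    areas = pd.DataFrame({"ward": ["w1"] * 100}, index=mat.indicators.index)
    prev = ytree.prevalence_by_area(mat, areas, min_area_n=100)
    assert prev.loc[prev["area"] == "w1", "A1"].iloc[0] == pytest.approx(0.12)


def test_prevalence_rollup_and_conservation(toy_tree):
    asg = _assignments(["A1"] * 60 + ["B"] * 140)
    mat = ytree.build_indicator_matrix(asg, toy_tree)
    # fine area w_small holds 50 (< 100) -> those roll up to region r1 (150)
    ward = ["w_small"] * 50 + ["w_big"] * 150
    region = ["r1"] * 150 + ["r2"] * 50
    areas = pd.DataFrame({"ward": ward, "region": region},
                         index=mat.indicators.index)
    prev = ytree.prevalence_by_area(mat, areas, min_area_n=100)
    assert set(prev["area"]) == {"w_big", "r1"} or "w_big" in set(prev["area"])
    total_carriers = (prev["A1"] * prev["n"]).sum()
    assert total_carriers == pytest.approx(mat.counts["A1"])
    assert ((prev["A1"] >= 0) & (prev["A1"] <= 1)).all()


def test_vcf_input_haploid_and_het_handling(tmp_path, toy_tree):
    """VCF genotypes load haploid calls; diploid heterozygous Y calls are
    artifacts and become missing."""
    cyvcf2 = pytest.importorskip("cyvcf2")  # noqa: F841
    vcf = tmp_path / "y.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=Y>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tm1\tm2\tm3\n"
        "Y\t100\tsA\tC\tT\t.\t.\t.\tGT\t1\t0\t0/1\n"
        "Y\t200\tsA1\tG\tA\t.\t.\t.\tGT\t1\t.\t0\n"
    )
    panel = ytree.GenotypePanel.from_vcf(vcf)
    assert panel.calls.loc["m1", "sA"] == "T"
    assert panel.calls.loc["m2", "sA"] == "C"
    assert pd.isna(panel.calls.loc["m3", "sA"])  # het on the Y -> missing
    assert pd.isna(panel.calls.loc["m2", "sA1"])
    got = ytree.assign_haplogroups(toy_tree, panel)
    assert got["m1"] == "A1"
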