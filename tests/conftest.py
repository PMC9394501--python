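import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ykin import simdata, ytree
from ykin.pipeline import build_analysis_table

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

TOY_NEWICK = "((A1,A2)A,B)ROOT;\n"
TOY_SNPS = (
    "node\tsnp_id\tancestral\tderived\n"
    "A\tsA\tC\tT\n"
    "A1\tsA1\tG\tA\n"
    "A2\tsA2\tG\tC\n"
    "B\tsB\tT\tG\n"
)


@pytest.fixture(scope="session")
def toy_tree(tmp_path_factory):
    """The 4-leaf toy phylogeny: ((A1,A2)A,B)ROOT with one SNP per branch."""
    d = tmp_path_factory.mktemp("toy")
    (d / "tree.nwk").write_text(TOY_NEWICK)
    (d / "snps.tsv").write_text(TOY_SNPS)
    return ytree.load_phylogeny(d / "tree.nwk", d / "snps.tsv")


@pytest.fixture(scope="session")
def fixture_tree():
    return ytree.load_fixture_phylogeny()


@pytest.fixture(scope="session")
def small_sim():
    """One modest synthetic cohort shared by read-only tests."""
    cfg = simdata.SimConfig(n_subjects=2500, seed=42, n_pcs=10)
    sim = simdata.simulate_cohort(cfg)
    return cfg, sim


@pytest.fixture(scope="session")
def small_cohort(small_sim):
    """Analysis-ready table + filtered indicator matrix for the shared sim."""
    cfg, sim = small_sim
    tree = cfg.resolved_tree()
    cohort = build_analysis_table(sim.cohort, sim.records, sim.meds)
    asg = ytree.assign_haplogroups(tree, ytree.qc_snps(sim.panel))
    gdefs = cfg.resolved_groups()
    mat = ytree.build_indicator_matrix(
        asg.reindex(cohort.index), tree,
        {k: v["members"] for k, v in gdefs["composites"].items()},
        gdefs["paragroups"],
    )
    return cohort, mat


def toy_panel(tree, rows: dict[str, dict[str, int | None]]) -> ytree.GenotypePanel:
    """Build a panel from {individual: {snp_id: 1 derived / 0 ancestral / None}}."""
    alleles = tree.snp_alleles
    data = {}
    for ind, calls in rows.items():
        row = {}
        for snp, (anc, der) in alleles.items():
            st = calls.get(snp)
            row[snp] = np.nan if st is None else (der if st else anc)
        data[ind] = row
    return ytree.GenotypePanel(pd.DataFrame.from_dict(data, orient="index"))
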