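"""Y phylogeny handling, SNP panel QC and haplogroup assignment.

The male-specific region of the Y chromosome (MSY) does not recombine, so
each man carries the derived alleles of every SNP on the path from the root
of the Y genealogy down to his own lineage, and ancestral alleles elsewhere
(bar genotyping error and recurrent mutation, which we treat as noise).
Haplogroup calling therefore reduces to finding the tree node whose
root-to-node path best explains the observed derived calls.

Beyond atomic (per-node) assignments, analyses use *composite* groups —
unions of atomic lineages that recover power for deep nodes of the genealogy
— and *paragroups* (asterisk suffix), which are an ancestor's subtree minus
its enumerated derived subgroups.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"

__all__ = [
    "BranchSNP",
    "YPhylogeny",
    "GenotypePanel",
    "HaplogroupMatrix",
    "UNASSIGNED",
    "load_phylogeny",
    "load_fixture_phylogeny",
    "load_group_definitions",
    "qc_snps",
    "assign_haplogroup",
    "assign_haplogroups",
    "build_indicator_matrix",
    "filter_groups",
    "prevalence_by_area",
]


@dataclass(frozen=True)
class BranchSNP:
    """A SNP defining the branch leading into a node."""

    snp_id: str
    ancestral: str
    derived: str


@dataclass
class YPhylogeny:
    """Rooted Y genealogy whose branches carry defining SNPs.

    ``branch_snps`` is keyed by the child node of each branch; the root has
    no incoming branch and hence no defining SNPs.
    """

    root: str
    parent: dict[str, str | None]
    branch_snps: dict[str, list[BranchSNP]]

    def __post_init__(self) -> None:
        self._children: dict[str, list[str]] = {n: [] for n in self.parent}
        for node, par in self.parent.items():
            if par is not None:
                self._children[par].append(node)
        self._validate()

    def _validate(self) -> None:
        roots = [n for n, p in self.parent.items() if p is None]
        if roots != [self.root]:
            raise ValueError(f"tree must have the single root {self.root!r}, found {roots}")
        # acyclicity + reachability: walking to the root must terminate
        for node in self.parent:
            seen = set()
            cur: str | None = node
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"cycle detected at node {cur!r}")
                seen.add(cur)
                cur = self.parent[cur]
        for node in self.nodes:
            if node != self.root and not self.branch_snps.get(node):
                raise ValueError(f"non-root node {node!r} has no defining SNP")
            if node.endswith("*"):
                raise ValueError(f"paragroup label {node!r} cannot be a tree node")

    @property
    def nodes(self) -> list[str]:
        return list(self.parent)

    def children(self, node: str) -> list[str]:
        return list(self._children[node])

    def path(self, node: str) -> list[str]:
        """Nodes from the root down to ``node``, inclusive."""
        out = []
        cur: str | None = node
        while cur is not None:
            out.append(cur)
            cur = self.parent[cur]
        return out[::-1]

    def depth(self, node: str) -> int:
        return len(self.path(node)) - 1

    def subtree(self, node: str) -> set[str]:
        """All nodes of the clade rooted at ``node`` (inclusive)."""
        out, stack = set(), [node]
        while stack:
            cur = stack.pop()
            out.add(cur)
            stack.extend(self._children[cur])
        return out

    def path_snps(self, node: str) -> list[BranchSNP]:
        """Defining SNPs of every branch on the root-to-node path."""
        out: list[BranchSNP] = []
        for n in self.path(node):
            out.extend(self.branch_snps.get(n, []))
        return out

    @property
    def snp_to_node(self) -> dict[str, str]:
        return {s.snp_id: n for n, snps in self.branch_snps.items() for s in snps}

    @property
    def snp_alleles(self) -> dict[str, tuple[str, str]]:
        """snp_id -> (ancestral, derived)."""
        return {
            s.snp_id: (s.ancestral, s.derived)
            for snps in self.branch_snps.values()
            for s in snps
        }


def load_phylogeny(tree_file: str | Path, snp_map: str | Path) -> YPhylogeny:
    """Read a Newick tree and a branch-SNP map into a :class:`YPhylogeny`.

    The SNP map is a TSV with columns ``node, snp_id, ancestral, derived``;
    every node it names must be a (leaf or internal) label in the tree.
    Duplicate node labels in the tree are a hard error; SNP rows naming an
    unknown node are a hard error identifying that node.
    """
    try:
        tree = dendropy.Tree.get(path=str(tree_file), schema="newick",
                                 suppress_internal_node_taxa=False)
    except dendropy.utility.error.DataParseError as exc:
        raise ValueError(f"invalid tree file: {exc}") from exc
    parent: dict[str, str | None] = {}
    for nd in tree.preorder_node_iter():
        label = nd.taxon.label if nd.taxon is not None else nd.label
        if label is None:
            raise ValueError("tree contains an unlabeled node")
        label = label.replace(" ", "_")
        if label in parent:
            raise ValueError(f"duplicate node label {label!r} in tree")
        if nd.parent_node is None:
            parent[label] = None
        else:
            pn = nd.parent_node
            plabel = pn.taxon.label if pn.taxon is not None else pn.label
            parent[label] = plabel.replace(" ", "_")
    root = next(n for n, p in parent.items() if p is None)

    snp_df = pd.read_csv(snp_map, sep="\t", dtype=str)
    required = {"node", "snp_id", "ancestral", "derived"}
    if not required.issubset(snp_df.columns):
        raise ValueError(f"snp_map must have columns {sorted(required)}")
    branch_snps: dict[str, list[BranchSNP]] = {n: [] for n in parent}
    for row in snp_df.itertuples(index=False):
        if row.node not in parent:
            raise ValueError(f"snp_map references node {row.node!r} absent from the tree")
        branch_snps[row.node].append(BranchSNP(row.snp_id, row.ancestral, row.derived))
    return YPhylogeny(root=root, parent=parent, branch_snps=branch_snps)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("ykin").joinpath("data", name)))


def load_fixture_phylogeny() -> YPhylogeny:
    """The ~20-node fixture tree shipped with the package."""
    return load_phylogeny(_data_path("fixture_tree.nwk"), _data_path("fixture_snps.tsv"))


def load_group_definitions(path: str | Path | None = None) -> dict:
    """Composite/paragroup definitions from YAML (fixture file by default)."""
    with open(path or _data_path("fixture_groups.yaml")) as fh:
        return yaml.safe_load(fh)


# ---------------------------------------------------------------------------
# Genotype panel


@dataclass
class GenotypePanel:
    """Haploid Y genotype calls, individuals x SNPs.

    ``calls`` holds raw alleles as strings with NaN for missing. Mapping to
    ancestral/derived status happens against a phylogeny at assignment time.
    """

    calls: pd.DataFrame

    @property
    def individuals(self) -> list[str]:
        return list(self.calls.index)

    @property
    def snps(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def call_rate(self) -> pd.Series:
        return self.calls.notna().mean(axis=0)

    @classmethod
    def from_long_tsv(cls, path: str | Path) -> "GenotypePanel":
        """Long-format TSV with columns individual, snp_id, allele."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        wide = df.pivot(index="individual", columns="snp_id", values="allele")
        wide.index.name = None
        wide.columns.name = None
        return cls(wide)

    @classmethod
    def from_vcf(cls, path: str | Path) -> "GenotypePanel":
        """Y calls from a VCF. Haploid GTs give the called allele; diploid
        heterozygous GTs are artifacts on the haploid Y and become missing."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        data: dict[str, list] = {}
        for var in vcf:
            snp_id = var.ID or f"{var.CHROM}:{var.POS}"
            alleles = [var.REF] + list(var.ALT)
            col = []
            for gt in var.genotypes:  # [a, b, phased] or [a, phased]
                calls = [a for a in gt[:-1] if a is not None and a >= 0]
                if not calls or len(set(calls)) > 1:
                    col.append(np.nan)
                else:
                    col.append(alleles[calls[0]])
            data[snp_id] = col
        return cls(pd.DataFrame(data, index=samples))

    def status(self, tree: YPhylogeny) -> pd.DataFrame:
        """Map raw alleles to 1=derived / 0=ancestral / NaN=missing.

        Alleles matching neither the ancestral nor the derived state (and
        SNPs absent from the tree) are treated as missing, with a log line.
        """
        alleles = tree.snp_alleles
        out = pd.DataFrame(np.nan, index=self.calls.index, columns=self.calls.columns)
        unmapped = [s for s in self.calls.columns if s not in alleles]
        if unmapped:
            logger.info("dropping %d SNPs not on the tree: %s", len(unmapped), unmapped[:10])
        for snp in self.calls.columns:
            if snp not in alleles:
                continue
            anc, der = alleles[snp]
            col = self.calls[snp]
            out.loc[col == anc, snp] = 0.0
            out.loc[col == der, snp] = 1.0
            bad = col.notna() & (col != anc) & (col != der)
            if bad.any():
                logger.info("SNP %s: %d calls match neither allele; set missing", snp, int(bad.sum()))
        return out[[s for s in self.calls.columns if s in alleles]]


def qc_snps(panel: GenotypePanel, min_call_rate: float = 0.95) -> GenotypePanel:
    """Drop low-call-rate SNPs, then monomorphic SNPs among the survivors.

    The order is fixed: call-rate first, then monomorphism judged on the
    observed (non-missing) calls of the SNPs that passed the call-rate
    filter. Removal tallies are logged per reason. Removing every SNP is a
    hard error.
    """
    if panel.calls.empty:
        raise ValueError("empty genotype panel")
    cr = panel.call_rate
    low_call = cr.index[cr < min_call_rate]
    surviving = panel.calls.drop(columns=low_call)
    n_obs_alleles = surviving.nunique(axis=0, dropna=True)
    mono = n_obs_alleles.index[n_obs_alleles < 2]
    kept = surviving.drop(columns=mono)
    logger.info(
        "SNP QC: %d in, %d removed for call rate < %s, %d monomorphic, %d retained",
        panel.calls.shape[1], len(low_call), min_call_rate, len(mono), kept.shape[1],
    )
    if kept.shape[1] == 0:
        raise ValueError("SNP QC removed every SNP")
    return GenotypePanel(kept)


# ---------------------------------------------------------------------------
# Haplogroup assignment


def _score_nodes(
    tree: YPhylogeny, status: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Per (individual, node): derived and observed-ancestral counts on the
    root-to-node path, plus each individual's total derived count."""
    nodes = tree.nodes
    snps = list(status.columns)
    snp_idx = {s: j for j, s in enumerate(snps)}
    # node x snp path-membership
    P = np.zeros((len(nodes), len(snps)), dtype=np.int64)
    for i, node in enumerate(nodes):
        for s in tree.path_snps(node):
            j = snp_idx.get(s.snp_id)
            if j is not None:
                P[i, j] = 1
    arr = status.to_numpy(dtype=float)
    D = np.nan_to_num(arr, nan=0.0)
    A = np.nan_to_num(1.0 - arr, nan=0.0)  # observed ancestral
    M = np.isnan(arr).astype(float)
    derived_on = D @ P.T  # individuals x nodes
    anc_on = A @ P.T
    miss_on = M @ P.T
    total = D.sum(axis=1)
    return derived_on, anc_on, miss_on, total, nodes


def assign_haplogroups(tree: YPhylogeny, panel: GenotypePanel) -> pd.Series:
    """Vectorised most-derived assignment for every individual in the panel.

    Each individual is assigned the node maximising the path score: derived
    calls on the root-to-node path minus observed ancestral calls on that
    path (the penalty is what lets internal nodes win over their
    descendants, so a noise-free carrier of any node is recovered exactly).
    Ties break by (i) fewer derived calls off the path, then (ii) fewer
    missing calls on the path (prefer nodes whose defining evidence was
    observed, so missingness on a descendant branch cannot pull the call
    deeper), then (iii) greater path depth, then (iv) lexicographically
    smallest label. Zero derived calls map to the root; all-missing
    individuals get the sentinel ``"unassigned"``.
    """
    status = panel.status(tree)
    derived_on, anc_on, miss_on, total, nodes = _score_nodes(tree, status)
    score = derived_on - anc_on
    off_path = total[:, None] - derived_on
    depth = np.array([tree.depth(n) for n in nodes])
    # lexicographic preference encoded as a rank (smaller label preferred)
    lex_rank = np.argsort(np.argsort(nodes))
    n_nodes = len(nodes)
    n_snps = status.shape[1]
    tie4 = (n_nodes - lex_rank).astype(np.int64)  # larger is better
    B4 = n_nodes + 1
    B3 = (depth.max() + 1) * B4
    B2 = (n_snps + 1) * B3
    B1 = (n_snps + 1) * B2
    key = (score.astype(np.int64) * B1
           - off_path.astype(np.int64) * B2
           - miss_on.astype(np.int64) * B3
           + depth[None, :] * B4
           + tie4[None, :])
    best = np.asarray(key).argmax(axis=1)
    labels = np.array(nodes, dtype=object)[best]
    all_missing = status.isna().all(axis=1).to_numpy()
    labels[total == 0] = tree.root
    labels[all_missing] = UNASSIGNED
    return pd.Series(labels, index=status.index, name="haplogroup")


def assign_haplogroup(tree: YPhylogeny, panel: GenotypePanel, individual: str) -> str:
    """Most-derived haplogroup for one individual (see :func:`assign_haplogroups`)."""
    if individual not in panel.calls.index:
        raise KeyError(f"individual {individual!r} not in panel")
    sub = GenotypePanel(panel.calls.loc[[individual]])
    return assign_haplogroups(tree, sub).iloc[0]


# ---------------------------------------------------------------------------
# Indicator matrix


@dataclass
class HaplogroupMatrix:
    """Binary carrier indicators for atomic, composite and paragroup lineages."""

    indicators: pd.DataFrame  # individuals x groups, int8
    definitions: dict[str, set[str]] = field(default_factory=dict)
    kinds: dict[str, str] = field(default_factory=dict)  # group -> atomic|composite|paragroup

    @property
    def groups(self) -> list[str]:
        return list(self.indicators.columns)

    @property
    def counts(self) -> pd.Series:
        return self.indicators.sum(axis=0)

    def select(self, groups: Sequence[str]) -> "HaplogroupMatrix":
        return HaplogroupMatrix(
            self.indicators[list(groups)],
            {g: self.definitions[g] for g in groups if g in self.definitions},
            {g: self.kinds[g] for g in groups if g in self.kinds},
        )

    def to_tsv(self, path: str | Path) -> None:
        self.indicators.to_csv(path, sep="\t", index_label="individual")


def build_indicator_matrix(
    assignments: pd.Series,
    tree: YPhylogeny,
    composite_defs: Mapping[str, Iterable[str]] | None = None,
    paragroup_defs: Mapping[str, Mapping] | None = None,
) -> HaplogroupMatrix:
    """Atomic, composite and paragroup indicator columns from assignments.

    Atomic columns (one per tree node) are mutually exclusive. A composite
    column is the logical OR of its member atomic columns. A paragroup
    column covers carriers assigned anywhere in its ancestor's subtree minus
    carriers of the excluded descendant groups' subtrees. ``"unassigned"``
    individuals are all-zero: they sit in the non-carrier reference of every
    model, matching the contrast of each haplogroup against all others.
    """
    composite_defs = dict(composite_defs or {})
    paragroup_defs = dict(paragroup_defs or {})
    nodes = tree.nodes
    valid = set(nodes) | {UNASSIGNED}
    bad = set(assignments.unique()) - valid
    if bad:
        raise ValueError(f"assignments contain labels not on the tree: {sorted(bad)}")

    atomic = pd.DataFrame(
        {n: (assignments == n).astype(np.int8) for n in nodes}, index=assignments.index
    )
    cols: dict[str, pd.Series] = {n: atomic[n] for n in nodes}
    definitions: dict[str, set[str]] = {n: {n} for n in nodes}
    kinds = {n: "atomic" for n in nodes}

    for label, members in composite_defs.items():
        members = set(members)
        unknown = members - set(nodes)
        if unknown:
            raise ValueError(f"composite {label!r} references unknown nodes {sorted(unknown)}")
        cols[label] = (atomic[sorted(members)].sum(axis=1) > 0).astype(np.int8)
        definitions[label] = members
        kinds[label] = "composite"

    for label, spec in paragroup_defs.items():
        anc, excl = spec["ancestor"], set(spec.get("exclude", []))
        unknown = ({anc} | excl) - set(nodes)
        if unknown:
            raise ValueError(f"paragroup {label!r} references unknown nodes {sorted(unknown)}")
        member_nodes = tree.subtree(anc)
        for e in excl:
            member_nodes -= tree.subtree(e)
        cols[label] = (atomic[sorted(member_nodes)].sum(axis=1) > 0).astype(np.int8)
        definitions[label] = member_nodes
        kinds[label] = "paragroup"

    return HaplogroupMatrix(pd.DataFrame(cols, index=assignments.index), definitions, kinds)


def filter_groups(
    matrix: HaplogroupMatrix,
    min_carriers: int = 100,
    case_indicator: pd.Series | np.ndarray | None = None,
    min_cases: int = 40,
) -> HaplogroupMatrix:
    """Keep groups with enough carriers (continuous traits) or enough
    carrier-cases (binary outcomes). Thresholds are closed (>=)."""
    if case_indicator is not None:
        cases = pd.Series(np.asarray(case_indicator), index=matrix.indicators.index)
        if len(cases) != len(matrix.indicators):
            raise ValueError("case_indicator not aligned with individuals")
        carrier_cases = matrix.indicators.mul(cases.fillna(0).astype(float), axis=0).sum()
        keep = carrier_cases[carrier_cases >= min_cases].index
    else:
        counts = matrix.counts
        keep = counts[counts >= min_carriers].index
    logger.info("group filter retained %d/%d groups", len(keep), matrix.indicators.shape[1])
    return matrix.select(list(keep))


def prevalence_by_area(
    matrix: HaplogroupMatrix,
    area_levels: pd.DataFrame,
    min_area_n: int = 100,
) -> pd.DataFrame:
    """Per-group carrier prevalence by area, rolled up a level hierarchy.

    ``area_levels`` has one column per level ordered finest-to-coarsest. Each
    individual is counted at the finest level whose containing area holds at
    least ``min_area_n`` individuals. Individuals with no qualifying area at
    any level are excluded (logged). Per-group carrier totals are conserved.
    """
    levels = list(area_levels.columns)
    idx = matrix.indicators.index
    area_levels = area_levels.reindex(idx)
    chosen_level = pd.Series(pd.NA, index=idx, dtype=object)
    chosen_area = pd.Series(pd.NA, index=idx, dtype=object)
    unplaced = pd.Series(True, index=idx)
    for lvl in levels:
        sizes = area_levels[lvl].value_counts()
        ok_areas = set(sizes.index[sizes >= min_area_n])
        hit = unplaced & area_levels[lvl].isin(ok_areas)
        chosen_level[hit] = lvl
        chosen_area[hit] = area_levels.loc[hit, lvl]
        unplaced &= ~hit
    if unplaced.any():
        logger.info("prevalence_by_area: %d individuals in no area of size >= %d",
                    int(unplaced.sum()), min_area_n)
    placed = ~unplaced
    df = matrix.indicators[placed].copy()
    df["_level"] = chosen_level[placed]
    df["_area"] = chosen_area[placed]
    grouped = df.groupby(["_level", "_area"], observed=True)
    n = grouped.size().rename("n")
    carriers = grouped.sum()
    prev = carriers.div(n, axis=0)
    out = prev.reset_index().rename(columns={"_level": "level", "_area": "area"})
    out.insert(2, "n", n.to_numpy())
    return out
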