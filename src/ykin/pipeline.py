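"""End-to-end pipeline: QC -> assignment -> indicators -> phenotypes ->
association battery -> kin-cohort validation -> reports.

Every stage is a plain function over the library types; :func:`run_pipeline`
chains them from a :class:`RunConfig`, writes tidy TSV results plus a JSON
run manifest, and is fully reproducible from the manifest's seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, kincohort, phenotypes, simdata, ytree

logger = logging.getLogger(__name__)

STAGES = ("qc", "assign", "indicators", "phenotypes", "association", "kin", "reports")

PHENOTYPE_FAMILIES = {
    "bp": ["sbp", "dbp", "map"],
    "lipids": ["total_chol", "ldl", "hdl", "log_trig"],
}


class StageError(RuntimeError):
    """Raised with the failing stage's name so shell callers can tell."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Resolved run configuration; defaults follow the analysis protocol."""

    simulate: bool = True
    n_subjects: int = 5000
    seed: int = 0
    outdir: str = "results"
    covariate_set: str = "robust"
    outcomes: tuple = (
        ("sbp", "linear"), ("dbp", "linear"), ("map", "linear"),
        ("total_chol", "linear"), ("ldl", "linear"), ("hdl", "linear"),
        ("log_trig", "linear"),
        ("hypertension", "logistic"), ("cad", "logistic"),
        ("mortality", "cox"),
    )
    kin_outcomes: tuple = (("cad", "logistic"), ("hypertension", "logistic"),
                           ("mortality", "cox"))
    min_call_rate: float = 0.95
    min_carriers: int = 100
    min_cases: int = 40
    suggestive_p: float = 0.10
    variance_fraction: float = 0.95
    kinship_threshold: float = 0.2
    n_boot: int = 100_000
    censor_date: str = "2021-11-01"
    n_pcs: int = 40
    # file-based inputs (ignored when simulate=True)
    tree_file: str | None = None
    snp_map: str | None = None
    genotypes: str | None = None
    phenotype_table: str | None = None
    records_table: str | None = None
    meds_table: str | None = None
    kinship_table: str | None = None
    codelists: str | None = None
    group_defs: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "outcomes" in raw:
            raw["outcomes"] = tuple(tuple(o) for o in raw["outcomes"])
        if "kin_outcomes" in raw:
            raw["kin_outcomes"] = tuple(tuple(o) for o in raw["kin_outcomes"])
        return cls(**raw)


def build_analysis_table(
    cohort: pd.DataFrame,
    records: pd.DataFrame | None,
    meds: pd.DataFrame | None,
    codelists: dict | None = None,
    censor_date: str = "2021-11-01",
) -> pd.DataFrame:
    """Derive every analysis phenotype from raw measurements and records.

    Applies, in order: iterative Tukey filtering of measured SBP/DBP,
    medication adjustment (+15/+10), mean arterial pressure, hypertension
    classification on measured values, lipid medication adjustment with
    log-triglycerides and per-trait Tukey filtering, CAD classification
    from coded records and exclusion medications, parental proxy phenotypes
    and parent survival fields.
    """
    out = cohort.copy()
    sbp = out["sbp_measured"].astype(float).copy()
    dbp = out["dbp_measured"].astype(float).copy()
    for v in (sbp, dbp):
        keep = phenotypes.tukey_filter(v)
        v[(keep == False).to_numpy()] = np.nan  # noqa: E712
    sbp_adj, dbp_adj = phenotypes.adjust_blood_pressure(
        sbp, dbp, out["on_antihypertensive"].astype(bool))
    out["sbp"], out["dbp"] = sbp_adj, dbp_adj
    out["map"] = phenotypes.mean_arterial_pressure(sbp_adj, dbp_adj)
    out["hypertension"] = phenotypes.classify_hypertension(
        out["sbp_measured"], out["dbp_measured"], out["on_antihypertensive"])
    lipids = phenotypes.adjust_lipids(
        out["total_chol_measured"], out["ldl_measured"], out["hdl_measured"],
        out["trig_measured"], out["on_lipid_lowering"])
    for col in lipids.columns:
        out[col] = lipids[col].to_numpy()
    out["cad"] = phenotypes.classify_cad_cohort(
        records, meds, list(out.index), codelists)
    if "father_conditions" in out.columns:
        parents = phenotypes.build_parent_phenotypes(
            out[["father_conditions", "mother_conditions", "father_age",
                 "mother_age", "father_dead", "mother_dead"]])
        for col in parents.columns:
            out[col] = parents[col]
    return out


def make_area_levels(cohort: pd.DataFrame, n_fine: int = 4, n_coarse: int = 2) -> pd.DataFrame:
    """Hierarchical area codes (fine grid -> coarse grid -> national) from
    birth coordinates, for prevalence roll-ups."""
    def grid(n):
        qn = np.clip(np.floor((cohort["north_birth"].rank(pct=True) - 1e-9) * n), 0, n - 1)
        qe = np.clip(np.floor((cohort["east_birth"].rank(pct=True) - 1e-9) * n), 0, n - 1)
        return qn.astype(int).astype(str) + "_" + qe.astype(int).astype(str)

    return pd.DataFrame({
        "ward": "w" + grid(n_fine),
        "region": "r" + grid(n_coarse),
        "nation": "GB",
    }, index=cohort.index)


def run_pipeline(
    config: RunConfig | str | Path,
    only: str | None = None,
    skip: tuple[str, ...] = (),
) -> Path:
    """Execute the pipeline and return the results directory."""
    cfg = config if isinstance(config, RunConfig) else RunConfig.from_yaml(config)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(filename=outdir / "run.log", level=logging.INFO, force=False)

    def active(stage: str) -> bool:
        if only is not None:
            return stage == only or STAGES.index(stage) <= STAGES.index(only)
        return stage not in skip

    manifest: dict = {"seed": cfg.seed, "config": dataclasses.asdict(cfg),
                      "censor_date": cfg.censor_date, "n_eff": {}}
    codelists = phenotypes.load_codelists(cfg.codelists)

    # ---- inputs ----------------------------------------------------------
    try:
        if cfg.simulate:
            sim_cfg = simdata.SimConfig(n_subjects=cfg.n_subjects, seed=cfg.seed,
                                        n_pcs=cfg.n_pcs)
            tree = sim_cfg.resolved_tree()
            gdefs = sim_cfg.resolved_groups()
            sim = simdata.simulate_cohort(sim_cfg)
            panel, raw_cohort = sim.panel, sim.cohort
            records, meds, kinship = sim.records, sim.meds, sim.kinship
        else:
            if not (cfg.tree_file and cfg.snp_map and cfg.genotypes and cfg.phenotype_table):
                raise ValueError("file-based run needs tree_file, snp_map, genotypes "
                                 "and phenotype_table (or pass --simulate)")
            tree = ytree.load_phylogeny(cfg.tree_file, cfg.snp_map)
            gdefs = ytree.load_group_definitions(cfg.group_defs)
            if str(cfg.genotypes).endswith((".vcf", ".vcf.gz")):
                panel = ytree.GenotypePanel.from_vcf(cfg.genotypes)
            else:
                panel = ytree.GenotypePanel.from_long_tsv(cfg.genotypes)
            raw_cohort = _load_phenotype_table(cfg.phenotype_table)
            records = (pd.read_csv(cfg.records_table, sep="\t", dtype=str)
                       if cfg.records_table else None)
            meds = (pd.read_csv(cfg.meds_table, sep="\t", dtype=str)
                    if cfg.meds_table else None)
            kinship = (pd.read_csv(cfg.kinship_table, sep="\t")
                       if cfg.kinship_table else None)
    except Exception as exc:
        raise StageError("inputs", exc) from exc

    # ---- qc --------------------------------------------------------------
    try:
        panel_qc = ytree.qc_snps(panel, cfg.min_call_rate) if active("qc") else panel
        manifest["n_snps_post_qc"] = panel_qc.calls.shape[1]
    except StageError:
        raise
    except Exception as exc:
        raise StageError("qc", exc) from exc
    if only == "qc":
        _write_manifest(outdir, manifest)
        return outdir

    # ---- assignment ------------------------------------------------------
    try:
        assignments = ytree.assign_haplogroups(tree, panel_qc)
        assignments.to_frame().to_csv(outdir / "assignments.tsv", sep="\t",
                                      index_label="individual")
    except Exception as exc:
        raise StageError("assign", exc) from exc
    if only == "assign":
        _write_manifest(outdir, manifest)
        return outdir

    # ---- indicators ------------------------------------------------------
    try:
        matrix = ytree.build_indicator_matrix(
            assignments.reindex(raw_cohort.index), tree,
            {k: v["members"] for k, v in (gdefs.get("composites") or {}).items()},
            gdefs.get("paragroups") or {},
        )
        matrix.to_tsv(outdir / "indicator_matrix.tsv")
        prev = ytree.prevalence_by_area(matrix, make_area_levels(raw_cohort))
        prev.to_csv(outdir / "prevalence.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError("indicators", exc) from exc
    if only == "indicators":
        _write_manifest(outdir, manifest)
        return outdir

    # ---- phenotypes ------------------------------------------------------
    try:
        cohort = build_analysis_table(raw_cohort, records, meds, codelists,
                                      cfg.censor_date)
        drop = [c for c in ("father_conditions", "mother_conditions") if c in cohort]
        cohort.drop(columns=drop).to_csv(outdir / "phenotypes.tsv", sep="\t",
                                         index_label="individual")
    except Exception as exc:
        raise StageError("phenotypes", exc) from exc
    if only == "phenotypes":
        _write_manifest(outdir, manifest)
        return outdir

    # ---- association battery --------------------------------------------
    try:
        n_eff_phen = {}
        for fam, cols in PHENOTYPE_FAMILIES.items():
            present = [c for c in cols if c in cohort]
            sub = cohort[present].dropna()
            if len(present) >= 2 and len(sub) > 2:
                n_eff_phen[fam] = association.effective_tests(
                    sub.to_numpy(), cfg.variance_fraction)
        manifest["n_eff"]["phenotypes"] = n_eff_phen

        rows = []
        for outcome, family in cfg.outcomes:
            fam_key = next((k for k, v in PHENOTYPE_FAMILIES.items() if outcome in v), None)
            nep = n_eff_phen.get(fam_key, 1)
            if family == "linear":
                mat = ytree.filter_groups(matrix, min_carriers=cfg.min_carriers)
            elif family == "logistic":
                case = association._outcome_series(
                    cohort, association.ModelSpec(outcome, "logistic"))
                mat = ytree.filter_groups(matrix, case_indicator=case,
                                          min_cases=cfg.min_cases)
            else:
                mat = ytree.filter_groups(matrix, min_carriers=cfg.min_carriers)
            if not mat.groups:
                logger.warning("no groups pass the filter for %s", outcome)
                continue
            spec = association.ModelSpec(outcome, family, cfg.covariate_set)
            results = association.fit_battery(spec, cohort, mat, nep,
                                              cfg.variance_fraction)
            ok = [r for r in results if r.converged]
            if len(ok) >= 2:
                manifest["n_eff"][outcome] = association.effective_tests(
                    mat.indicators[[r.haplogroup for r in ok]], cfg.variance_fraction)
            rows += [dict(r.to_dict(), covariate_set=cfg.covariate_set) for r in results]
        assoc_df = pd.DataFrame(rows)
        assoc_df.to_csv(outdir / "associations.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError("association", exc) from exc
    if only == "association":
        _write_manifest(outdir, manifest)
        return outdir

    # ---- kin-cohort validation -------------------------------------------
    try:
        kin_rows = []
        for outcome, family in cfg.kin_outcomes:
            if family == "logistic":
                case = association._outcome_series(
                    cohort, association.ModelSpec(outcome, "logistic"))
                mat = ytree.filter_groups(matrix, case_indicator=case,
                                          min_cases=cfg.min_cases)
            else:
                mat = ytree.filter_groups(matrix, min_carriers=cfg.min_carriers)
            if not mat.groups:
                continue
            spec = association.ModelSpec(outcome, family, cfg.covariate_set)
            vals = kincohort.run_kin_battery(mat, cohort, outcome, spec,
                                             cfg.suggestive_p)
            kin_rows += [v.to_dict() for v in vals]
        kin_df = pd.DataFrame(kin_rows)
        kin_df.to_csv(outdir / "kin_validation.tsv", sep="\t", index=False)
        with open(outdir / "forest.json", "w") as fh:
            json.dump(kin_rows, fh, indent=1, default=_jsonable)

        if cfg.simulate:
            fs = simdata.simulate_father_son_records(raw_cohort, sim_cfg)
            pairs = kincohort.infer_father_son_pairs(
                fs.kinship, fs.pair_cohort, cfg.kinship_threshold)
            father_ids = [p.father_id for p in pairs]
            cad_flags = phenotypes.classify_cad_cohort(
                fs.father_records, None, father_ids, codelists) == "case"
            hd_flags = fs.reported_hd.reindex(father_ids).to_numpy()
            point, ci = kincohort.proxy_accuracy(
                pairs, cad_flags.to_numpy(), hd_flags,
                n_boot=cfg.n_boot, seed=cfg.seed)
            manifest["proxy_accuracy"] = {"n_pairs": len(pairs), "point": point,
                                          "ci95": list(ci)}
        elif kinship is not None:
            manifest["proxy_accuracy"] = "kinship table supplied; run "\
                "kincohort.infer_father_son_pairs with a phenotype table of fathers"
    except StageError:
        raise
    except Exception as exc:
        raise StageError("kin", exc) from exc

    # ---- reports ----------------------------------------------------------
    _write_manifest(outdir, manifest)
    return outdir


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (np.bool_,)):
        return bool(x)
    if x is pd.NA:
        return None
    return str(x)


def _write_manifest(outdir: Path, manifest: dict) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=_jsonable)


def _load_phenotype_table(path: str | Path) -> pd.DataFrame:
    """Phenotype TSV with semicolon-joined parental condition tokens
    ('' = answered, nothing selected; 'NA' = preferred not to answer)."""
    df = pd.read_csv(path, sep="\t", index_col="individual")
    for col in ("father_conditions", "mother_conditions"):
        if col in df.columns:
            df[col] = [
                None if (pd.isna(v) or v == "NA")
                else tuple(t for t in str(v).split(";") if t)
                for v in df[col]
            ]
    return df
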