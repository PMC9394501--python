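"""Synthetic cohort generator.

Emulates the statistical structure the analysis modules assume, so the
whole pipeline runs without access-controlled data: geographically
structured haplogroup frequencies (lineage frequencies tilt along north/
east birth coordinates), geography-correlated deprivation and outcome
confounding, genetic PCs that only partially tag geography, Y genotypes
emitted along tree paths with call error and missingness, cardiovascular
phenotypes (blood pressure and lipids under medication, CAD emitted as
ICD/OPCS-coded health records so the phenotyping algorithm itself is
exercised), Gompertz survival for subjects and parents, father phenotypes
sharing the son's lineage effect, mother phenotypes independent of the Y by
construction, and an optional collider scenario where the lineage affects a
heritable risk factor but not CAD itself.

Every draw flows from the single seed in :class:`SimConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping

import numpy as np
import pandas as pd

from .ytree import (
    GenotypePanel,
    HaplogroupMatrix,
    YPhylogeny,
    build_indicator_matrix,
    load_fixture_phylogeny,
    load_group_definitions,
)

CENSOR_YEAR = 2021.835  # 2021-11-01 as a decimal year

#: Atomic assignment frequencies on the fixture tree, loosely mirroring a
#: British male cohort (R1b lineages dominant, I1 second).
DEFAULT_BASE_FREQS: dict[str, float] = {
    "ROOT": 0.02, "E-M96": 0.01, "E1b-V13": 0.02, "E2-M75": 0.01,
    "F-M89": 0.02, "G-M201": 0.01, "G1-M342": 0.01, "G2a-P15": 0.01,
    "IJ-M429": 0.01, "I-M170": 0.02, "I1-M253": 0.12, "I2-M438": 0.04,
    "J-M304": 0.01, "J1-M267": 0.02, "J2-M172": 0.03, "K-M9": 0.02,
    "P-M45": 0.02, "R1a-M420": 0.05, "R1b-M343": 0.05, "R1b1-L21": 0.40,
    "R1b2-U106": 0.10,
}

#: Log-frequency slopes on standardised (north, east) birth coordinates.
#: Signs echo the familiar British clines: I1 more common to the south/east,
#: older P/R1a-like lineages toward the north and west.
DEFAULT_GEO_GRADIENT: dict[str, tuple[float, float]] = {
    "I1-M253": (-0.6, 0.2),
    "P-M45": (0.6, -0.2),
    "R1b1-L21": (0.2, -0.4),
    "E1b-V13": (-0.3, -0.6),
}

#: Geography -> outcome confounding: (slope on north coordinate, slope on
#: deprivation at assessment), per outcome. Units are the outcome's natural
#: scale per SD of the confounder.
DEFAULT_CONFOUNDING: dict[str, tuple[float, float]] = {
    "bp": (3.0, 1.0),          # mm Hg
    "lipid": (0.08, 0.04),     # mmol/L
    "cad": (0.30, 0.15),       # log-odds
    "mortality": (0.20, 0.10), # log-hazard
}


@dataclass
class SimConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions."""

    n_subjects: int = 5000
    tree: YPhylogeny | None = None
    base_freqs: Mapping[str, float] = dc_field(default_factory=lambda: dict(DEFAULT_BASE_FREQS))
    geo_gradient: Mapping[str, tuple[float, float]] = dc_field(
        default_factory=lambda: dict(DEFAULT_GEO_GRADIENT))
    confounding: Mapping[str, tuple[float, float]] = dc_field(
        default_factory=lambda: dict(DEFAULT_CONFOUNDING))
    snp_error_rate: float = 0.001
    snp_missing_rate: float = 0.01
    #: haplogroup label -> (outcome in {sbp, dbp, map, ldl, total_chol,
    #: log_trig, cad, hypertension, mortality}, effect on natural scale)
    effect_map: Mapping[str, tuple[str, float]] = dc_field(
        default_factory=lambda: {"IJK-S137": ("map", 0.93)})
    group_defs: Mapping | None = None  # composite/paragroup YAML structure
    n_pcs: int = 40
    pc_geo_corr: float = 0.3
    shared_env_corr: float = 0.2
    collider_scenario: bool = False
    collider_rf_slope: float = 3.0   # latent U -> BMI (the risk factor), kg/m2 per SD
    collider_cad_slope: float = 0.8  # latent U -> CAD log-odds per SD
    gompertz_rate: float = 2e-5
    gompertz_shape: float = 0.09
    seed: int = 0

    def resolved_tree(self) -> YPhylogeny:
        return self.tree or load_fixture_phylogeny()

    def resolved_groups(self) -> Mapping:
        return self.group_defs if self.group_defs is not None else load_group_definitions()

    def validate(self) -> None:
        tree = self.resolved_tree()
        freqs = dict(self.base_freqs)
        unknown = set(freqs) - set(tree.nodes)
        if unknown:
            raise ValueError(f"base_freqs name nodes absent from the tree: {sorted(unknown)}")
        total = sum(freqs.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"base_freqs must sum to 1 (got {total})")
        if any(f < 0 for f in freqs.values()):
            raise ValueError("base_freqs must be non-negative")


@dataclass
class SimulatedCohort:
    """Everything simulate_cohort emits."""

    panel: GenotypePanel
    cohort: pd.DataFrame
    records: pd.DataFrame       # individual, source, code
    meds: pd.DataFrame          # individual, med_code
    kinship: pd.DataFrame       # id1, id2, kinship (background pairs)
    true_indicators: HaplogroupMatrix
    ledger: dict


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _gompertz_unconditional(rng, a, b, size):
    """Age at death from a Gompertz hazard a*exp(b*t); a may be a vector."""
    u = rng.uniform(size=size)
    return np.log1p(-(b / a) * np.log(u)) / b


def _gompertz_residual(rng, a, b, x0):
    """Residual time to death given survival to age x0."""
    u = rng.uniform(size=len(np.atleast_1d(x0)))
    ebx0 = np.exp(b * np.asarray(x0))
    return (np.log(ebx0 - (b / a) * np.log(u)) / b) - np.asarray(x0)


def simulate_cohort(cfg: SimConfig) -> SimulatedCohort:
    """Draw a full synthetic cohort; the seed determines every byte."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    tree = cfg.resolved_tree()
    n = cfg.n_subjects
    ids = np.array([f"S{i:06d}" for i in range(n)])

    # --- geography, deprivation, ancestry PCs -----------------------------
    zN = rng.standard_normal(n)
    zE = rng.standard_normal(n)
    north_assess = 0.8 * zN + 0.6 * rng.standard_normal(n)
    east_assess = 0.8 * zE + 0.6 * rng.standard_normal(n)
    dep_birth = 0.5 * zN - 0.2 * zE + rng.standard_normal(n) * 0.85
    dep_assess = 0.7 * dep_birth + 0.71 * rng.standard_normal(n)
    c = cfg.pc_geo_corr
    pcs = rng.standard_normal((n, cfg.n_pcs))
    if cfg.n_pcs >= 1:
        pcs[:, 0] = c * zN + np.sqrt(1 - c**2) * pcs[:, 0]
    if cfg.n_pcs >= 2:
        pcs[:, 1] = c * zE + np.sqrt(1 - c**2) * pcs[:, 1]

    # --- haplogroup assignment with geographic tilt -----------------------
    nodes = tree.nodes
    base = np.array([cfg.base_freqs.get(nd, 0.0) for nd in nodes])
    logit = np.log(np.maximum(base, 1e-12))[None, :].repeat(n, axis=0)
    for nd, (sN, sE) in cfg.geo_gradient.items():
        j = nodes.index(nd)
        logit[:, j] += sN * zN + sE * zE
    probs = np.exp(logit)
    probs /= probs.sum(axis=1, keepdims=True)
    cum = probs.cumsum(axis=1)
    draw = rng.uniform(size=(n, 1))
    hap_idx = (draw > cum).sum(axis=1)
    assignments = pd.Series(np.array(nodes, dtype=object)[hap_idx], index=ids,
                            name="haplogroup")

    # --- Y genotypes along the tree path ----------------------------------
    alleles = tree.snp_alleles
    snp_ids = list(alleles)
    snp_idx = {s: j for j, s in enumerate(snp_ids)}
    P = np.zeros((len(nodes), len(snp_ids)), dtype=bool)
    for i, nd in enumerate(nodes):
        for s in tree.path_snps(nd):
            P[i, snp_idx[s.snp_id]] = True
    derived = P[hap_idx]
    flips = rng.uniform(size=derived.shape) < cfg.snp_error_rate
    derived = derived ^ flips
    anc = np.array([alleles[s][0] for s in snp_ids], dtype=object)
    der = np.array([alleles[s][1] for s in snp_ids], dtype=object)
    calls = np.where(derived, der[None, :], anc[None, :]).astype(object)
    missing = rng.uniform(size=derived.shape) < cfg.snp_missing_rate
    calls[missing] = np.nan
    panel = GenotypePanel(pd.DataFrame(calls, index=ids, columns=snp_ids))

    # --- true lineage effects ---------------------------------------------
    gdefs = cfg.resolved_groups()
    true_ind = build_indicator_matrix(
        assignments, tree,
        {k: v["members"] for k, v in (gdefs.get("composites") or {}).items()},
        gdefs.get("paragroups") or {},
    )
    eff = {k: np.zeros(n) for k in
           ("sbp", "dbp", "ldl", "total_chol", "log_trig", "cad", "hypertension",
            "mortality", "bmi")}
    for group, (outcome, size) in cfg.effect_map.items():
        if group not in true_ind.indicators.columns:
            raise ValueError(f"effect_map group {group!r} not among indicator columns")
        z = true_ind.indicators[group].to_numpy(dtype=float)
        if outcome == "map":  # equal shift of SBP and DBP shifts MAP by the same amount
            eff["sbp"] += size * z
            eff["dbp"] += size * z
        else:
            eff[outcome] += size * z

    # --- demographics ------------------------------------------------------
    age = rng.uniform(40, 70, size=n)
    assess_year = rng.uniform(2006.0, 2010.5, size=n)
    dob_year = assess_year - age
    batch = rng.choice(["axiom", "bileve"], size=n, p=[0.78, 0.22])

    confN_bp, confD_bp = cfg.confounding.get("bp", (0.0, 0.0))
    confN_lip, confD_lip = cfg.confounding.get("lipid", (0.0, 0.0))
    confN_cad, confD_cad = cfg.confounding.get("cad", (0.0, 0.0))
    confN_mort, confD_mort = cfg.confounding.get("mortality", (0.0, 0.0))

    # --- blood pressure -----------------------------------------------------
    u = rng.standard_normal(n)  # latent heritable/environmental risk factor
    bp_noise = rng.standard_normal(n)
    # a hypertension-target effect is a latent blood-pressure shift (6 mm Hg
    # per log-odds unit, matching the parent reporting scale below)
    htn_shift = 6.0 * eff["hypertension"]
    sbp_true = (138.0 + 0.45 * (age - 55) + confN_bp * zN + confD_bp * dep_assess
                + eff["sbp"] + htn_shift + 14.0 * bp_noise)
    dbp_true = (82.0 + 0.12 * (age - 55) + 0.5 * (confN_bp * zN + confD_bp * dep_assess)
                + eff["dbp"] + htn_shift + 6.0 * bp_noise + 5.0 * rng.standard_normal(n))
    map_true = dbp_true + (sbp_true - dbp_true) / 3.0
    on_bp_med = rng.uniform(size=n) < (0.05 + 0.55 * _sigmoid((sbp_true - 155) / 8))
    sbp_measured = sbp_true - 15.0 * on_bp_med
    dbp_measured = dbp_true - 10.0 * on_bp_med

    # --- lipids -------------------------------------------------------------
    chol_conf = confN_lip * zN + confD_lip * dep_assess
    total_true = 5.7 + 0.01 * (age - 55) + chol_conf + eff["total_chol"] + rng.standard_normal(n) * 1.0
    ldl_true = 0.62 * total_true + eff["ldl"] + rng.standard_normal(n) * 0.45
    hdl = 1.45 + rng.standard_normal(n) * 0.33
    log_trig_true = np.log(1.5) + 0.3 * chol_conf + eff["log_trig"] + rng.standard_normal(n) * 0.45
    trig_true = np.exp(log_trig_true)
    on_lipid_med = rng.uniform(size=n) < (0.05 + 0.45 * _sigmoid((ldl_true - 4.6) / 0.7))
    ldl_measured = ldl_true * np.where(on_lipid_med, 0.7, 1.0)
    total_measured = total_true * np.where(on_lipid_med, 0.8, 1.0)

    # --- CAD (emitted as coded health records) ------------------------------
    cad_lp = -2.35 + 0.06 * (age - 55) + confN_cad * zN + confD_cad * dep_assess + eff["cad"]
    if cfg.collider_scenario:
        # lineage -> BMI <- U -> CAD; no direct lineage -> CAD path
        cad_lp = cad_lp + cfg.collider_cad_slope * u
    cad_true = rng.uniform(size=n) < _sigmoid(cad_lp)
    records, meds = _emit_cad_records(rng, ids, cad_true)

    # --- subject survival ----------------------------------------------------
    mort_lp = confN_mort * zN + confD_mort * dep_assess + eff["mortality"]
    a_subj = cfg.gompertz_rate * np.exp(mort_lp)
    resid = _gompertz_residual(rng, a_subj, cfg.gompertz_shape, age)
    followup = CENSOR_YEAR - assess_year
    dead = resid <= followup
    event_age = age + np.minimum(resid, followup)

    # --- parents -------------------------------------------------------------
    father_gap = np.clip(rng.normal(28, 5, size=n), 16, 55)
    mother_gap = np.clip(rng.normal(26, 5, size=n), 16, 50)
    father_age_now = age + father_gap
    mother_age_now = age + mother_gap
    f_death = _gompertz_unconditional(  # father shares the son's lineage effect
        rng, cfg.gompertz_rate * np.exp(mort_lp), cfg.gompertz_shape, n)
    m_death = _gompertz_unconditional(
        rng, cfg.gompertz_rate * np.exp(confN_mort * zN + confD_mort * dep_assess),
        cfg.gompertz_shape, n)
    father_dead = f_death <= father_age_now
    mother_dead = m_death <= mother_age_now
    father_age_rep = np.where(father_dead, f_death, father_age_now)
    mother_age_rep = np.where(mother_dead, m_death, mother_age_now)

    rho = cfg.shared_env_corr
    f_env = rho * bp_noise + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    m_env = rho * bp_noise + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    f_map = (96.0 + 0.15 * (np.minimum(father_age_rep, 80) - 70)
             + confN_bp * zN + confD_bp * dep_assess + eff["sbp"] * 2 / 3 + eff["dbp"] * 1 / 3
             + eff["hypertension"] * 6.0 + 8.0 * f_env)
    m_map = (96.0 + 0.15 * (np.minimum(mother_age_rep, 80) - 70)
             + confN_bp * zN + confD_bp * dep_assess + 8.0 * m_env)
    f_htn = rng.uniform(size=n) < _sigmoid((f_map - 100.0) / 6.0)
    m_htn = rng.uniform(size=n) < _sigmoid((m_map - 100.0) / 6.0)
    f_cad_lp = (-1.3 + 0.04 * (np.minimum(father_age_rep, 90) - 75)
                + confN_cad * zN + confD_cad * dep_assess + eff["cad"])
    m_cad_lp = (-1.5 + 0.04 * (np.minimum(mother_age_rep, 90) - 75)
                + confN_cad * zN + confD_cad * dep_assess)
    f_hd = rng.uniform(size=n) < _sigmoid(f_cad_lp)
    m_hd = rng.uniform(size=n) < _sigmoid(m_cad_lp)
    no_answer = rng.uniform(size=n) < 0.02

    def conditions(hd, htn, skip):
        out = []
        for h, t, s in zip(hd, htn, skip):
            if s:
                out.append(None)
            else:
                sel = []
                if h:
                    sel.append("heart_disease")
                if t:
                    sel.append("high_blood_pressure")
                out.append(tuple(sel))
        return out

    father_conditions = conditions(f_hd, f_htn, no_answer)
    mother_conditions = conditions(m_hd, m_htn, no_answer)

    # --- brothers (sons with exactly one male sibling share the Y) ----------
    has_brother = rng.uniform(size=n) < 0.15
    b_env = rho * bp_noise + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    b_map = (96.0 + confN_bp * zN + confD_bp * dep_assess
             + eff["sbp"] * 2 / 3 + eff["dbp"] * 1 / 3 + eff["hypertension"] * 6.0
             + 8.0 * b_env)
    b_htn = rng.uniform(size=n) < _sigmoid((b_map - 100.0) / 6.0)
    brother_htn = pd.array(np.where(has_brother, b_htn, None), dtype="boolean")

    # --- lifestyle covariates (for the risk-factor-adjusted model) -----------
    bmi = 27.0 + 0.6 * dep_assess + eff["bmi"] + rng.standard_normal(n) * 4.0
    if cfg.collider_scenario:
        bmi = bmi + cfg.collider_rf_slope * u
    lifestyle = {
        "exercise": rng.integers(0, 8, size=n),
        "income": np.clip(np.round(3 - 0.7 * dep_assess + rng.standard_normal(n)), 1, 5).astype(int),
        "smoking": (rng.uniform(size=n) < _sigmoid(-1.2 + 0.3 * dep_assess)).astype(int),
        "education": (rng.uniform(size=n) < _sigmoid(0.4 - 0.3 * dep_assess)).astype(int),
        "employment": rng.integers(1, 7, size=n),
        "alcohol": rng.integers(1, 7, size=n),
    }

    cohort = pd.DataFrame({
        "age": age, "assess_year": assess_year, "dob_year": dob_year, "batch": batch,
        "north_assess": north_assess, "east_assess": east_assess,
        "north_birth": zN, "east_birth": zE,
        "deprivation_assess": dep_assess, "deprivation_birth": dep_birth,
        **{f"pc_{j + 1}": pcs[:, j] for j in range(cfg.n_pcs)},
        "sbp_measured": sbp_measured, "dbp_measured": dbp_measured,
        "on_antihypertensive": on_bp_med,
        "total_chol_measured": total_measured, "ldl_measured": ldl_measured,
        "hdl_measured": hdl, "trig_measured": trig_true,
        "on_lipid_lowering": on_lipid_med,
        "bmi": bmi, **lifestyle,
        "entry_age": age, "event_age": event_age, "dead": dead,
        "father_conditions": father_conditions, "mother_conditions": mother_conditions,
        "father_age": father_age_rep, "mother_age": mother_age_rep,
        "father_dead": father_dead, "mother_dead": mother_dead,
        "brother_hypertension": brother_htn,
        "true_haplogroup": assignments.to_numpy(),
        "cad_true": cad_true,
    }, index=pd.Index(ids, name="individual"))

    # background kinship pairs (unrelated noise for pair-inference contracts)
    n_bg = min(200, n * (n - 1) // 2)
    i1 = rng.integers(0, n, size=n_bg)
    i2 = (i1 + 1 + rng.integers(0, n - 1, size=n_bg)) % n
    kinship = pd.DataFrame({
        "id1": ids[i1], "id2": ids[i2],
        "kinship": rng.uniform(0.0, 0.05, size=n_bg),
    })

    ledger = {
        "seed": cfg.seed, "n_subjects": n,
        "effect_map": {k: list(v) for k, v in cfg.effect_map.items()},
        "base_freqs": dict(cfg.base_freqs),
        "geo_gradient": {k: list(v) for k, v in cfg.geo_gradient.items()},
        "confounding": {k: list(v) for k, v in cfg.confounding.items()},
        "snp_error_rate": cfg.snp_error_rate,
        "snp_missing_rate": cfg.snp_missing_rate,
        "collider_scenario": cfg.collider_scenario,
        "censor_year": CENSOR_YEAR,
        "n_cad_true": int(cad_true.sum()),
    }
    return SimulatedCohort(panel, cohort, records, meds, kinship, true_ind, ledger)


def _emit_cad_records(rng, ids, cad_true):
    """Coded health records and medications realising the CAD status.

    Cases receive one MI/PCI/CABG/death code at random; a slice of non-cases
    receives angina codes or exclusion medications and will be excluded by
    the classifier; everyone else stays record-free (controls).
    """
    case_codes = [
        ("hospital_icd10", "I21.0"), ("hospital_icd10", "I22.9"),
        ("hospital_icd10", "I23.1"), ("hospital_icd10", "I25.2"),
        ("hospital_icd9", "4109"), ("self_report", "heart_attack"),
        ("operation_opcs", "K49.1"), ("operation_opcs", "K40.2"),
        ("operation_opcs", "K75.0"),
        ("death_icd10_primary_or_secondary", "I21.9"),
    ]
    probs = np.array([0.25, 0.12, 0.08, 0.10, 0.05, 0.18, 0.08, 0.05, 0.04, 0.05])
    rows = []
    case_ids = ids[cad_true]
    choice = rng.choice(len(case_codes), size=len(case_ids), p=probs / probs.sum())
    for ind, ci in zip(case_ids, choice):
        src, code = case_codes[ci]
        rows.append((ind, src, code))
    noncase_ids = ids[~cad_true]
    angina = rng.uniform(size=len(noncase_ids)) < 0.03
    angina_codes = ["I20.0", "I20.1", "I20.8", "I20.9"]
    for ind, ci in zip(noncase_ids[angina],
                       rng.integers(0, len(angina_codes), size=int(angina.sum()))):
        rows.append((ind, "hospital_icd10", angina_codes[ci]))
    records = pd.DataFrame(rows, columns=["individual", "source", "code"])
    on_excl_med = rng.uniform(size=len(noncase_ids)) < 0.04
    med_codes = ["SYN-ASP-075", "SYN-GTN-400", "SYN-ISMN-060", "SYN-NIC-020"]
    med_rows = [
        (ind, med_codes[ci]) for ind, ci in zip(
            noncase_ids[on_excl_med],
            rng.integers(0, len(med_codes), size=int(on_excl_med.sum())))
    ]
    meds = pd.DataFrame(med_rows, columns=["individual", "med_code"])
    return records, meds


# ---------------------------------------------------------------------------
# Father-son pair fixtures


@dataclass
class FatherSonSim:
    """Paired records for pedigree inference and proxy-accuracy tests."""

    kinship: pd.DataFrame       # id1, id2, kinship (true pairs + distractors)
    pair_cohort: pd.DataFrame   # per-id dob_year, assess_year, father_age
    father_records: pd.DataFrame
    reported_hd: pd.Series      # by father id
    father_cad_true: pd.Series  # by father id
    true_pairs: list[tuple[str, str]]  # (son, father)


def simulate_father_son_records(
    cohort: pd.DataFrame,
    cfg: SimConfig,
    n_pairs: int = 301,
    n_reported_hd: int = 37,
    cad_given_hd: float = 26 / 37,
    cad_rate_no_hd: float = 0.08,
    kinship_mean: float = 0.25,
    kinship_noise_sd: float = 0.01,
    age_jitter: float = 0.4,
    n_distractors: int = 150,
) -> FatherSonSim:
    """Emit genetically inferable father-son pairs.

    True pairs get kinship around ``kinship_mean`` (the parent-offspring
    expectation for kinship-coefficient estimators); distractor pairs sit
    well below the 0.2 threshold. Reported father ages carry up to
    ``age_jitter`` years of error (within the +/- 6-month matching window
    when <= 0.5). Exactly ``n_reported_hd`` fathers are reported to have
    heart disease, of whom a ``cad_given_hd`` fraction carry CAD-qualifying
    records (MI codes); remaining fathers carry CAD records at
    ``cad_rate_no_hd``.
    """
    if n_pairs > len(cohort):
        raise ValueError("n_pairs exceeds cohort size")
    rng = np.random.default_rng(cfg.seed + 1)
    sons = cohort.index[:n_pairs]
    father_ids = np.array([f"F{i:05d}" for i in range(n_pairs)])
    true_father_age = np.clip(rng.normal(66, 7, size=n_pairs), 45, 95)
    assess = cohort.loc[sons, "assess_year"].to_numpy()
    father_dob = assess - true_father_age
    reported_father_age = true_father_age + rng.uniform(-age_jitter, age_jitter, size=n_pairs)

    pair_cohort = pd.DataFrame({
        "dob_year": np.concatenate([cohort.loc[sons, "dob_year"].to_numpy(), father_dob]),
        "assess_year": np.concatenate([assess, assess]),
        "father_age": np.concatenate([reported_father_age, np.full(n_pairs, np.nan)]),
    }, index=pd.Index(np.concatenate([sons.to_numpy(), father_ids]), name="individual"))

    kin_rows = [
        (s, f, float(np.clip(rng.normal(kinship_mean, kinship_noise_sd), 0.01, 0.49)))
        for s, f in zip(sons, father_ids)
    ]
    for _ in range(n_distractors):
        i, j = rng.integers(0, n_pairs, size=2)
        kin_rows.append((sons[i], father_ids[j] if i != j else father_ids[(j + 1) % n_pairs],
                         float(rng.uniform(0.0, 0.1))))
    kinship = pd.DataFrame(kin_rows, columns=["id1", "id2", "kinship"])

    hd = np.zeros(n_pairs, dtype=bool)
    hd[rng.choice(n_pairs, size=n_reported_hd, replace=False)] = True
    n_cad_hd = int(round(cad_given_hd * n_reported_hd))
    cad = np.zeros(n_pairs, dtype=bool)
    hd_idx = np.flatnonzero(hd)
    cad[rng.choice(hd_idx, size=n_cad_hd, replace=False)] = True
    no_hd_idx = np.flatnonzero(~hd)
    n_cad_no = int(round(cad_rate_no_hd * len(no_hd_idx)))
    cad[rng.choice(no_hd_idx, size=n_cad_no, replace=False)] = True

    father_records = pd.DataFrame(
        [(f, "hospital_icd10", "I21.9") for f, c in zip(father_ids, cad) if c],
        columns=["individual", "source", "code"],
    )
    return FatherSonSim(
        kinship=kinship,
        pair_cohort=pair_cohort,
        father_records=father_records,
        reported_hd=pd.Series(hd, index=father_ids, name="reported_hd"),
        father_cad_true=pd.Series(cad, index=father_ids, name="father_cad"),
        true_pairs=[(s, f) for s, f in zip(sons, father_ids)],
    )


def qc_demo_panel(seed: int = 0, n_individuals: int = 100) -> GenotypePanel:
    """A 232-SNP synthetic panel mirroring the array QC arithmetic:
    39 SNPs below the 95% call-rate bar, 27 monomorphic among the
    survivors, 166 clean — so QC retains exactly 166."""
    rng = np.random.default_rng(seed)
    cols = {}
    for j in range(232):
        alleles = rng.choice(["A", "C"], size=n_individuals)
        if j < 39:  # low call rate (10% missing)
            miss = rng.choice(n_individuals, size=max(1, n_individuals // 10), replace=False)
            col = alleles.astype(object)
            col[miss] = np.nan
        elif j < 39 + 27:  # monomorphic, fully called
            col = np.array(["A"] * n_individuals, dtype=object)
        else:
            col = alleles.astype(object)
            col[0] = "A"  # guarantee both alleles observed
            col[1] = "C"
        cols[f"snp{j:03d}"] = col
    return GenotypePanel(pd.DataFrame(cols, index=[f"I{i:03d}" for i in range(n_individuals)]))
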