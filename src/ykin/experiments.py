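"""Replicated simulation studies exercising the full analysis path.

Each routine generates seeded synthetic cohorts, runs them through the
actual pipeline components (genotype QC, haplogroup calling, phenotype
construction, model fitting) and summarises the operating characteristics:
effect recovery, negative-control calibration, collider bias, caller
round-trip accuracy and the proxy-accuracy bootstrap. They back both the
test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from . import association, kincohort, phenotypes, simdata, ytree
from .pipeline import build_analysis_table

__all__ = [
    "prepare_cohort",
    "haplogroup_roundtrip",
    "map_effect_recovery",
    "mother_null_calibration",
    "collider_bias_experiment",
    "proxy_accuracy_experiment",
]


def prepare_cohort(cfg: simdata.SimConfig):
    """Simulate and push one cohort through QC, calling and phenotyping."""
    sim = simdata.simulate_cohort(cfg)
    tree = cfg.resolved_tree()
    cohort = build_analysis_table(sim.cohort, sim.records, sim.meds)
    asg = ytree.assign_haplogroups(tree, ytree.qc_snps(sim.panel))
    gdefs = cfg.resolved_groups()
    mat = ytree.build_indicator_matrix(
        asg.reindex(cohort.index), tree,
        {k: v["members"] for k, v in (gdefs.get("composites") or {}).items()},
        gdefs.get("paragroups") or {},
    )
    return sim, cohort, mat


def haplogroup_roundtrip(n: int = 1000, seed: int = 0) -> float:
    """Fraction of noise-free individuals whose lineage is recovered exactly."""
    cfg = simdata.SimConfig(n_subjects=n, seed=seed, snp_error_rate=0.0,
                            snp_missing_rate=0.0, n_pcs=2)
    sim = simdata.simulate_cohort(cfg)
    asg = ytree.assign_haplogroups(cfg.resolved_tree(), sim.panel)
    return float((asg == sim.cohort["true_haplogroup"]).mean())


def map_effect_recovery(
    n_reps: int = 200,
    n_subjects: int = 20_000,
    effect: float = 0.93,
    seed: int = 0,
    group: str = "IJK-S137",
) -> dict:
    """Recover a lineage effect on mean arterial pressure with the
    geography/deprivation-adjusted linear model, end to end."""
    gammas = np.empty(n_reps)
    for i in range(n_reps):
        cfg = simdata.SimConfig(
            n_subjects=n_subjects, seed=seed * 100_003 + i, n_pcs=10,
            effect_map={group: ("map", effect)})
        _, cohort, mat = prepare_cohort(cfg)
        r = association.fit_haplogroup_model(
            association.ModelSpec("map", "linear", "robust", haplogroup=group),
            cohort, mat)
        gammas[i] = r.gamma
    mean = float(np.mean(gammas))
    return {
        "mean_gamma": mean,
        "bias": mean - effect,
        "mc_se": float(np.std(gammas) / np.sqrt(n_reps)),
        "n_reps": n_reps,
        "n_subjects": n_subjects,
        "true_effect": effect,
    }


def mother_null_calibration(
    n_reps: int = 500,
    n_subjects: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Type-I error of the mother negative control: with mother phenotype
    independent of the son's Y lineage, the fraction of haplogroup tests
    with mother P < alpha should be near alpha."""
    pvals = []
    for i in range(n_reps):
        cfg = simdata.SimConfig(n_subjects=n_subjects, seed=seed * 100_003 + i,
                                n_pcs=10, effect_map={})
        _, cohort, mat = prepare_cohort(cfg)
        case = association._outcome_series(
            cohort, association.ModelSpec("hypertension", "logistic",
                                          parent="mother"))
        matf = ytree.filter_groups(mat, case_indicator=case, min_cases=40)
        for g in matf.groups:
            r = association.fit_haplogroup_model(
                association.ModelSpec("hypertension", "logistic", "robust",
                                      haplogroup=g, parent="mother"),
                cohort, matf)
            if r.converged and np.isfinite(r.p_raw):
                pvals.append(r.p_raw)
    p = np.asarray(pvals)
    frac = float((p < alpha).mean())
    return {
        "fraction_significant": frac,
        "n_tests": len(p),
        "mc_sd": float(np.sqrt(alpha * (1 - alpha) / len(p))),
        "alpha": alpha,
        "n_reps": n_reps,
        "n_subjects": n_subjects,
    }


def collider_bias_experiment(
    n_reps: int = 500,
    n_subjects: int = 2000,
    seed: int = 0,
    group: str = "IJK-S137",
) -> dict:
    """Lineage -> risk factor <- U -> CAD with zero direct lineage effect:
    the risk-factor-adjusted model is biased, the robust model is null."""
    g_adj = np.empty(n_reps)
    g_rob = np.empty(n_reps)
    for i in range(n_reps):
        cfg = simdata.SimConfig(
            n_subjects=n_subjects, seed=seed * 100_003 + i, n_pcs=10,
            collider_scenario=True, effect_map={group: ("bmi", 2.0)})
        _, cohort, mat = prepare_cohort(cfg)
        for cs, store in (("eales", g_adj), ("robust", g_rob)):
            r = association.fit_haplogroup_model(
                association.ModelSpec("cad", "logistic", cs, haplogroup=group),
                cohort, mat)
            store[i] = r.gamma
    return {
        "mean_gamma_adjusted": float(np.nanmean(g_adj)),
        "se_adjusted": float(np.nanstd(g_adj) / np.sqrt(n_reps)),
        "mean_gamma_robust": float(np.nanmean(g_rob)),
        "se_robust": float(np.nanstd(g_rob) / np.sqrt(n_reps)),
        "n_reps": n_reps,
        "n_subjects": n_subjects,
    }


def proxy_accuracy_experiment(seed: int = 0, n_boot: int = 10_000) -> dict:
    """Bootstrap of the heart-disease -> CAD proxy accuracy on the study
    configuration: 301 inferred father-son pairs, 37 reported heart-disease
    fathers of whom 26 meet CAD record criteria."""
    cfg = simdata.SimConfig(n_subjects=400, seed=seed, n_pcs=2)
    sim = simdata.simulate_cohort(cfg)
    fs = simdata.simulate_father_son_records(sim.cohort, cfg)
    pairs = kincohort.infer_father_son_pairs(fs.kinship, fs.pair_cohort)
    father_ids = [p.father_id for p in pairs]
    cad = (phenotypes.classify_cad_cohort(fs.father_records, None, father_ids)
           == "case").to_numpy()
    hd = fs.reported_hd.reindex(father_ids).to_numpy()
    point, ci = kincohort.proxy_accuracy(pairs, cad, hd, n_boot=n_boot,
                                         seed=seed + 17)
    return {"point": point, "ci_low": ci[0], "ci_high": ci[1],
            "n_pairs": len(pairs), "n_boot": n_boot}
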