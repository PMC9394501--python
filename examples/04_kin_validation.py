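"""Kin-cohort validation: father as replication, mother as negative control.

Simulates a lineage effect on hypertension shared between sons and their
fathers (who carry the same Y), runs the subject/father/mother model battery
and prints the verdict per haplogroup: a real Y effect replicates in
fathers and stays null in mothers.
"""

from ykin import association, experiments, kincohort, simdata, ytree

cfg = simdata.SimConfig(
    n_subjects=15_000, seed=11, n_pcs=6,
    effect_map={"I1-M253": ("hypertension", 0.35)})
sim, cohort, matrix = experiments.prepare_cohort(cfg)

case = cohort["hypertension"].astype("Float64").astype(float)
groups = ytree.filter_groups(matrix, case_indicator=case, min_cases=40)
validations = kincohort.run_kin_battery(
    groups, cohort, "hypertension",
    association.ModelSpec("hypertension", "logistic", "robust"))

print(f"{'group':<12}{'subject':>9}{'father':>9}{'mother':>9}  verdict")
for v in validations:
    print(f"{v.haplogroup:<12}{v.subject.gamma:>9.3f}{v.father.gamma:>9.3f}"
          f"{v.mother.gamma:>9.3f}  {v.verdict}")
# 'validated' requires: subject P < 0.10, father effect sign-concordant,
# mother 95% CI spanning zero. The causal group (I1-M253) shows the clearest
# subject+father signal; note the suggestive screen is deliberately lenient,
# so the occasional null group slips through it by chance (~10% suggestive x
# ~50% sign-concordant) -- the verdict flags candidates, the effect sizes and
# adjusted P values do the confirming.
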