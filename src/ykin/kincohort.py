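"""Kin-cohort validation of Y-haplogroup associations.

Fathers share their son's Y lineage, so a real Y-haplogroup effect on
disease must reappear in father phenotypes (replication); mothers do not
carry the Y, so any association with mother phenotypes signals confounding
(negative control). For each haplogroup reaching suggestive significance in
subjects (raw P < 0.10), the verdict is

    validated      — father effect sign-concordant AND mother 95% CI spans 0
    not_supported  — suggestive but father discordant or mother non-null
    inconclusive   — not suggestive in subjects

Also provided: genetic inference of father-son pairs from a kinship table
plus reported father ages, and the bootstrap estimate of how often reported
"heart disease" in a father corresponds to algorithmic CAD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import AssocResult, ModelSpec, fit_battery
from .ytree import HaplogroupMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "KinValidation",
    "FatherSonPair",
    "validate_triple",
    "run_kin_battery",
    "infer_father_son_pairs",
    "proxy_accuracy",
]


@dataclass
class KinValidation:
    """Subject/father/mother (and optional brother) effects for one group."""

    haplogroup: str
    outcome: str
    subject: AssocResult
    father: AssocResult
    mother: AssocResult
    brother: AssocResult | None = None
    suggestive: bool = False
    father_concordant: bool | None = None
    mother_null: bool | None = None
    verdict: str = "inconclusive"

    def to_dict(self) -> dict:
        d = {
            "haplogroup": self.haplogroup, "outcome": self.outcome,
            "suggestive": self.suggestive,
            "father_concordant": self.father_concordant,
            "mother_null": self.mother_null, "verdict": self.verdict,
        }
        for name, res in (("subject", self.subject), ("father", self.father),
                          ("mother", self.mother), ("brother", self.brother)):
            if res is None:
                continue
            lo, hi = res.ci95
            d.update({f"{name}_gamma": res.gamma, f"{name}_ci_low": lo,
                      f"{name}_ci_high": hi, f"{name}_p": res.p_raw})
        return d


def validate_triple(
    subject: AssocResult,
    father: AssocResult,
    mother: AssocResult,
    suggestive_p: float = 0.10,
) -> tuple[bool, bool | None, bool | None, str]:
    """Pure verdict logic over a subject/father/mother result triple.

    Returns (suggestive, father_concordant, mother_null, verdict). When the
    subject model is not suggestive — or any of the three fits did not
    converge — the verdict is inconclusive and the flags are undetermined.
    """
    usable = subject.converged and np.isfinite(subject.p_raw)
    suggestive = bool(usable and subject.p_raw < suggestive_p)
    if not suggestive:
        return suggestive, None, None, "inconclusive"
    if not (father.converged and mother.converged
            and np.isfinite(father.gamma) and np.isfinite(mother.gamma)):
        return suggestive, None, None, "inconclusive"
    concordant = bool(np.sign(subject.gamma) == np.sign(father.gamma))
    lo, hi = mother.ci95
    mother_null = bool(lo <= 0.0 <= hi)
    verdict = "validated" if (concordant and mother_null) else "not_supported"
    return suggestive, concordant, mother_null, verdict


def run_kin_battery(
    haplogroups: HaplogroupMatrix,
    cohort: pd.DataFrame,
    outcome: str,
    spec: ModelSpec | None = None,
    suggestive_p: float = 0.10,
    include_brother: bool | None = None,
) -> list[KinValidation]:
    """Fit subject, father and mother models per haplogroup and judge each.

    The same covariate set is reused across the three (four with brothers)
    fits, with parent age replacing subject age in parent models. Brother
    models are added when a ``brother_<outcome>`` column is present (sons
    with exactly one male sibling).
    """
    spec = spec or ModelSpec(outcome=outcome, family="logistic", covariate_set="robust")
    for parent in ("father", "mother"):
        needed = ([f"{parent}_event_age", f"{parent}_dead"] if spec.family == "cox"
                  else [f"{parent}_{outcome}"])
        for col in needed:
            if col not in cohort.columns:
                raise KeyError(f"cohort lacks required column {col}")
    if include_brother is None:
        include_brother = spec.family != "cox" and f"brother_{outcome}" in cohort.columns

    def battery(parent: str | None) -> dict[str, AssocResult]:
        s = ModelSpec(outcome, spec.family, spec.covariate_set, parent=parent)
        return {r.haplogroup: r for r in fit_battery(s, cohort, haplogroups)}

    subj = battery(None)
    fath = battery("father")
    moth = battery("mother")
    # brothers share the subject's age structure; reuse the subject covariates
    brot = (
        {r.haplogroup: r
         for r in fit_battery(ModelSpec(f"brother_{outcome}", spec.family,
                                        spec.covariate_set), cohort, haplogroups)}
        if include_brother else {}
    )

    out = []
    for g in haplogroups.groups:
        suggestive, conc, mnull, verdict = validate_triple(
            subj[g], fath[g], moth[g], suggestive_p
        )
        out.append(KinValidation(g, outcome, subj[g], fath[g], moth[g],
                                 brot.get(g), suggestive, conc, mnull, verdict))
    return out


# ---------------------------------------------------------------------------
# Father-son pair inference


@dataclass(frozen=True)
class FatherSonPair:
    son_id: str
    father_id: str
    kinship: float
    dob_match: bool = True


def infer_father_son_pairs(
    kinship_table: pd.DataFrame,
    cohort: pd.DataFrame,
    kinship_threshold: float = 0.2,
    window_years: float = 0.5,
) -> list[FatherSonPair]:
    """Orient close relative pairs into father-son pairs.

    ``kinship_table`` has columns id1, id2, kinship; ``cohort`` is indexed
    by individual id with columns dob_year, assess_year and father_age (the
    son's reported age of his living father at assessment; NaN otherwise).

    A pair qualifies when kinship is strictly above the threshold and
    exactly one member's date of birth lies inside the other member's
    implied father-date-of-birth interval (assessment date minus reported
    father age, +/- 6 months, closed at both ends). Pairs matching in both
    directions are ambiguous and dropped with a log line.
    """
    pairs: list[FatherSonPair] = []
    for row in kinship_table.itertuples(index=False):
        if row.kinship <= kinship_threshold:
            continue
        a, b = str(row.id1), str(row.id2)
        if a not in cohort.index or b not in cohort.index:
            continue

        def is_father_of(son: str, cand: str) -> bool:
            fa = cohort.at[son, "father_age"]
            if pd.isna(fa):
                return False
            center = cohort.at[son, "assess_year"] - float(fa)
            dob = cohort.at[cand, "dob_year"]
            return bool(center - window_years <= dob <= center + window_years)

        b_is_father = is_father_of(a, b)
        a_is_father = is_father_of(b, a)
        if a_is_father and b_is_father:
            logger.info("pair (%s, %s): both orientations match; dropped as ambiguous", a, b)
            continue
        if b_is_father:
            pairs.append(FatherSonPair(a, b, float(row.kinship)))
        elif a_is_father:
            pairs.append(FatherSonPair(b, a, float(row.kinship)))
    return pairs


def proxy_accuracy(
    pairs: list[FatherSonPair] | int,
    father_cad,
    reported_hd,
    n_boot: int = 100_000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, tuple[float, float]]:
    """Proportion of reported heart-disease fathers meeting CAD criteria.

    ``father_cad`` and ``reported_hd`` are boolean flags aligned to the
    pair list (``pairs`` may be the bare pair count). The point estimate is
    |CAD and HD| / |HD|; the 95% CI is the 2.5/97.5 percentile of the
    proportion over ``n_boot`` resamples of the full pair list.
    """
    cad = np.asarray(father_cad, dtype=bool)
    hd = np.asarray(reported_hd, dtype=bool)
    n = pairs if isinstance(pairs, int) else len(list(pairs))
    if len(cad) != n or len(hd) != n:
        raise ValueError("flags not aligned to pairs")
    n_hd = int(hd.sum())
    if n_hd == 0:
        raise ValueError("no reported heart-disease fathers; proportion undefined")
    point = float((cad & hd).sum() / n_hd)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    both = (cad & hd).astype(np.int8)
    hd8 = hd.astype(np.int8)
    props = np.empty(n_boot)
    chunk = 2000
    for start in range(0, n_boot, chunk):
        m = min(chunk, n_boot - start)
        idx = rng.integers(0, n, size=(m, n))
        num = both[idx].sum(axis=1)
        den = hd8[idx].sum(axis=1)
        with np.errstate(invalid="ignore"):
            props[start:start + m] = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    props = props[np.isfinite(props)]
    lo, hi = np.percentile(props, [2.5, 97.5])
    return point, (float(lo), float(hi))
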