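"""Synthetic knowledge bases and VA cohorts with known ground truth.

The published knowledge base and the reference datasets are external
downloads, so every stage of the pipeline is exercised against
generated material instead: a KB in which each cause owns a disjoint
"signature" set of indicators with a high conditional grade (all other
cells low), and a cohort drawn from a planted cause distribution under
the same conditional-independence-given-cause assumption the
propagation model itself makes. That assumption match is deliberate:
it makes CSMF recovery a well-posed oracle test of the engine, not a
realism claim about field VA data.

Defaults describe a cohort a desk test can afford: 30 symptom
indicators over 5 causes, strong signal (informativeness 0.9, i.e.
signature items fire with probability ~0.8 for their own cause against
0.05 off-cause, the mid-low rung of the grade ladder) and 5% missing
responses — roughly the answered-item density of a clean VA archive.
All randomness flows from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .kb import (AGE_BANDS, DEFAULT_GRADE_MAP, CauseDef, GradeMap, IndicatorDef,
                 KnowledgeBase)
from .records_io import MISSING, NO, YES, VARecord

__all__ = ["SimulationConfig", "SyntheticError", "generate_kb", "generate_cohort",
           "PREGNANCY_CATEGORIES", "COMCAT_CATEGORIES"]


class SyntheticError(ValueError):
    pass


#: Pregnancy-status categories; the last is the not-applicable residual.
PREGNANCY_CATEGORIES = ("pregnant at death", "recently delivered",
                        "not pregnant or not applicable")

#: A generic circumstance-of-mortality category list (configuration,
#: not a claim about the published COMCAT semantics).
COMCAT_CATEGORIES = ("sought care", "barriers to access", "no care sought")

#: Off-signature conditional grade: "B" on the default ladder (0.05).
_OFF_GRADE = "B"
#: Probability ceiling a fully informative signature item reaches.
_MAX_ON = 0.8

ROLE_INDICATORS = (("i_adult", "adult"), ("i_female", "female"), ("i_male", "male"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic KB + cohort."""

    n_indicators: int = 30
    n_causes: int = 5
    n_cases: int = 500
    planted_csmf: Mapping[str, float] | None = None
    informativeness: float = 0.9
    missingness: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_indicators < self.n_causes:
            raise SyntheticError(
                f"{self.n_indicators} indicators cannot give {self.n_causes} "
                "causes disjoint signatures")
        if not 0.0 <= self.informativeness <= 1.0:
            raise SyntheticError("informativeness must lie in [0, 1]")
        if not 0.0 <= self.missingness <= 1.0:
            raise SyntheticError("missingness must lie in [0, 1]")
        if self.planted_csmf is not None:
            total = sum(self.planted_csmf.values())
            if abs(total - 1.0) > 1e-9:
                raise SyntheticError(f"planted CSMF sums to {total}, not 1")
            if any(not 0.0 <= v <= 1.0 for v in self.planted_csmf.values()):
                raise SyntheticError("planted fractions must lie in [0, 1]")

    def cause_codes(self) -> list[str]:
        if self.planted_csmf is not None:
            return list(self.planted_csmf)
        return [f"{c + 1:02d}.01" for c in range(self.n_causes)]

    def csmf(self) -> dict[str, float]:
        if self.planted_csmf is not None:
            return dict(self.planted_csmf)
        codes = self.cause_codes()
        return {c: 1.0 / len(codes) for c in codes}


def generate_kb(config: SimulationConfig,
                grade_map: GradeMap = DEFAULT_GRADE_MAP) -> KnowledgeBase:
    """Deterministic signature-structured KB for the given conditions.

    Symptom indicator j is a signature of cause j mod n_causes: its
    conditional grade for that cause snaps to the ladder rung nearest
    p_off + informativeness * (0.8 - p_off); all other cells hold the
    off grade. Informativeness 0 therefore degenerates to identical
    cause columns. Priors are planted numerically so the cohort's true
    CSMF is exact, not grade-quantised. Three role indicators (adult /
    female / male) carry a uniform mid grade and thus never move the
    posterior.
    """
    codes = config.cause_codes()
    n_causes = len(codes)
    p_off = grade_map[_OFF_GRADE]
    p_on = p_off + config.informativeness * (_MAX_ON - p_off)
    on_grade = grade_map.nearest_grade(p_on)

    indicators: list[IndicatorDef] = []
    rows: list[list[str]] = []
    for j in range(config.n_indicators):
        # every 7th item exercises the "substantive response is no" polarity
        substantive = "no" if j % 7 == 3 else "yes"
        indicators.append(IndicatorDef(code=f"s{j:03d}", text=f"symptom {j}",
                                       substantive_value=substantive))
        owner = j % n_causes
        rows.append([on_grade if k == owner else _OFF_GRADE
                     for k in range(n_causes)])
    for code, role in ROLE_INDICATORS:
        indicators.append(IndicatorDef(code=code, text=f"deceased is {role}",
                                       role=role))
        rows.append(["A"] * n_causes)

    conditional = pd.DataFrame(rows, index=[i.code for i in indicators],
                               columns=codes, dtype=object)
    causes = [CauseDef(code=c, label=f"cause {c}",
                       broad_group="Synthetic causes",
                       prior_grade=repr(float(f)))
              for c, f in config.csmf().items()]

    n_ind = len(indicators)
    preg_prior = pd.Series(["0.05", "0.05", "0.9"], index=list(PREGNANCY_CATEGORIES),
                           dtype=object)
    preg_cond = pd.DataFrame([["A"] * 3] * n_ind,
                             index=[i.code for i in indicators],
                             columns=list(PREGNANCY_CATEGORIES), dtype=object)
    com_prior = pd.Series(["0.4", "0.3", "0.3"], index=list(COMCAT_CATEGORIES),
                          dtype=object)
    com_cond = pd.DataFrame([["A"] * 3] * n_ind,
                            index=[i.code for i in indicators],
                            columns=list(COMCAT_CATEGORIES), dtype=object)

    return KnowledgeBase(indicators=indicators, causes=causes,
                         conditional=conditional,
                         pregnancy_prior=preg_prior, pregnancy_conditional=preg_cond,
                         comcat_prior=com_prior, comcat_conditional=com_cond,
                         grade_map=grade_map)


def generate_cohort(kb: KnowledgeBase, config: SimulationConfig,
                    ) -> tuple[list[VARecord], pd.DataFrame]:
    """Draw a cohort from the planted CSMF under the KB's conditionals.

    Per case: a true cause is drawn from the planted distribution; each
    symptom indicator records its substantive response with probability
    P(i | cause) and the opposite response otherwise; missingness then
    blanks responses independently. Role indicators assert an adult of
    random sex. Returns the records and a truth table (id, true_cause).
    """
    rng = np.random.default_rng(config.seed)
    csmf = config.csmf()
    codes = list(csmf)
    probs = np.array([csmf[c] for c in codes], dtype=float)
    cond = kb.conditional_probabilities()
    symptom_inds = [i for i in kb.indicators if i.role is None]

    records: list[VARecord] = []
    truth_rows = []
    for case in range(config.n_cases):
        cause = codes[rng.choice(len(codes), p=probs)]
        responses: dict[str, str] = {}
        for ind in symptom_inds:
            p = cond.at[ind.code, cause]
            substantive = rng.random() < p
            resp = ind.substantive_value if substantive else (
                NO if ind.substantive_value == YES else YES)
            if rng.random() < config.missingness:
                resp = MISSING
            responses[ind.code] = resp
        female = bool(rng.random() < 0.5)
        responses["i_adult"] = YES
        responses["i_female"] = YES if female else NO
        responses["i_male"] = NO if female else YES
        rid = f"case{case:05d}"
        records.append(VARecord(id=rid, responses=responses))
        truth_rows.append({"id": rid, "true_cause": cause})

    return records, pd.DataFrame(truth_rows, columns=["id", "true_cause"])
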