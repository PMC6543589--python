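"""Per-case probabilistic propagation.

Each case is classified three times with the same machinery, in order:
pregnancy status, cause of death, and circumstance-of-mortality
category (COMCAT). The core update is naive-Bayes over the knowledge
base: starting from the prior over categories, every indicator whose
recorded response equals its substantive (evidential) polarity
multiplies in its conditional-probability row; missing and
non-substantive responses contribute nothing. The product is
accumulated in log space and normalised.

Cause reporting then applies the InterVA-lineage truncation: up to
three causes, the top one only if its likelihood reaches ``top_min``
(default 0.4), the second and third only if they reach ``ratio_min``
(default 0.5) of the top likelihood. Whatever likelihood is not
reported is carried as the case's indeterminate residual, so reported
plus indeterminate always sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .kb import KnowledgeBase
from .records_io import MISSING, VARecord, resolve_age, resolve_sex

__all__ = [
    "EngineError", "ClassifierSettings", "CaseClassification",
    "propagate", "select_reported_causes",
    "classify_pregnancy", "classify_cause", "classify_comcat",
    "classify_case", "classify_cohort", "classifications_to_frame",
    "OUTPUT_COLUMNS",
]


class EngineError(ValueError):
    pass


#: Bit-stable per-case output column order.
OUTPUT_COLUMNS = ["ID", "PREG_STATUS", "PREG_LIK", "CAUSE1", "LIK1", "CAUSE2",
                  "LIK2", "CAUSE3", "LIK3", "INDET", "COMCAT", "COMCAT_LIK",
                  "WARNINGS"]

#: Maternal cause chapter, gated off when pregnancy status is not applicable.
MATERNAL_PREFIX = "09."


def _safe_log(p: np.ndarray) -> np.ndarray:
    out = np.full(p.shape, -np.inf)
    positive = p > 0
    out[positive] = np.log(p[positive])
    return out


@dataclass(frozen=True)
class ClassifierSettings:
    """Reporting thresholds for cause truncation."""

    top_min: float = 0.4       # minimum likelihood for any cause to be reported
    ratio_min: float = 0.5     # 2nd/3rd reported iff >= ratio_min * top likelihood
    max_causes: int = 3


DEFAULT_SETTINGS = ClassifierSettings()


@dataclass
class CaseClassification:
    """The full per-case output row."""

    id: str
    pregnancy_status: tuple[str, float] | None
    reported_causes: list[tuple[str, float]]
    indeterminate: float
    comcat: tuple[str, float] | None
    flags: list[str] = field(default_factory=list)
    age_band: str | None = None
    sex: str | None = None


def propagate(responses: Mapping[str, str], prior: pd.Series,
              conditional: pd.DataFrame,
              substantive: Mapping[str, str]) -> tuple[pd.Series, bool]:
    """Bayes update of ``prior`` by the substantive responses.

    ``conditional`` is indicators x categories; its columns must match
    the prior's index. Returns the normalised posterior and a flag that
    is True when every category annihilated (a zero conditional on an
    observed response for each) and the uniform-over-applicable
    fallback was used. Categories with zero prior stay zero.

    Accumulation is in log space, so long products cannot underflow;
    the result matches the direct product to well below 1e-9.
    """
    if list(prior.index) != list(conditional.columns):
        raise EngineError("prior categories and conditional columns differ: "
                          f"{list(prior.index)} vs {list(conditional.columns)}")
    prior_v = prior.to_numpy(dtype=float)
    if prior_v.sum() <= 0:
        raise EngineError("prior has no positive mass")

    log_post = _safe_log(prior_v)
    applicable = prior_v > 0

    for code, resp in responses.items():
        if resp == MISSING or substantive.get(code) != resp:
            continue
        if code not in conditional.index:
            continue
        p = conditional.loc[code].to_numpy(dtype=float)
        log_post = log_post + _safe_log(p)

    fallback = not np.isfinite(log_post).any()
    if fallback:
        post = applicable / applicable.sum()
    else:
        m = log_post[np.isfinite(log_post)].max()
        post = np.exp(np.clip(log_post - m, -745.0, 0.0))
        post[~np.isfinite(log_post)] = 0.0
        post = post / post.sum()
    return pd.Series(post, index=prior.index), fallback


def select_reported_causes(posterior: pd.Series,
                           settings: ClassifierSettings = DEFAULT_SETTINGS,
                           ) -> tuple[list[tuple[str, float]], float]:
    """Truncate a normalised posterior to at most three reported causes.

    Ranking ties are broken by knowledge-base category order (stable
    sort). The unreported remainder is returned as the indeterminate
    residual, so reported + indeterminate == 1.
    """
    vals = posterior.to_numpy(dtype=float)
    order = np.argsort(-vals, kind="stable")
    reported: list[tuple[str, float]] = []
    if len(order) and vals[order[0]] >= settings.top_min:
        top = vals[order[0]]
        reported.append((str(posterior.index[order[0]]), float(top)))
        for idx in order[1:settings.max_causes]:
            if vals[idx] >= settings.ratio_min * top and vals[idx] > 0:
                reported.append((str(posterior.index[idx]), float(vals[idx])))
            else:
                break
    indeterminate = 1.0 - sum(lik for _, lik in reported)
    return reported, float(indeterminate)


def _not_applicable_category(kb: KnowledgeBase) -> str:
    # convention: the last pregnancy category in the KB is the
    # "not pregnant / not applicable" residual category
    return str(kb.pregnancy_prior.index[-1])


def classify_pregnancy(record: VARecord, kb: KnowledgeBase,
                       ) -> tuple[tuple[str, float], bool]:
    """Argmax pregnancy-status category with its normalised likelihood.

    Male deceased, and age bands where pregnancy cannot apply
    (neonates), short-circuit to the not-applicable category with
    likelihood 1.
    """
    if len(kb.pregnancy_prior) == 0:
        raise EngineError("knowledge base has no pregnancy block")
    sex = resolve_sex(record, kb)
    age = resolve_age(record, kb)
    if sex == "male" or age == "neonate":
        return (_not_applicable_category(kb), 1.0), False
    post, fallback = propagate(record.responses, kb.pregnancy_prior_probabilities(),
                               kb.pregnancy_conditional_probabilities(),
                               kb.substantive_values)
    i = int(np.argmax(post.to_numpy()))
    return (str(post.index[i]), float(post.iloc[i])), fallback


def classify_cause(record: VARecord, kb: KnowledgeBase,
                   settings: ClassifierSettings = DEFAULT_SETTINGS,
                   pregnancy_status: str | None = None,
                   ) -> tuple[list[tuple[str, float]], float, list[str]]:
    """Cause posterior restricted to the case's applicable causes, truncated.

    A cause is applicable when the case's resolved sex and age band
    fall inside the cause's applicability, and the maternal chapter
    (09.*) is gated off whenever pregnancy status resolved to the
    not-applicable category.
    """
    flags: list[str] = []
    sex = resolve_sex(record, kb)
    age = resolve_age(record, kb)

    prior = kb.prior_probabilities().copy()
    for cause in kb.causes:
        if sex in ("male", "female") and cause.sex_applicability not in ("any", sex):
            prior[cause.code] = 0.0
        elif (age is not None and age != "conflict"
              and age not in cause.age_applicability):
            prior[cause.code] = 0.0
    if pregnancy_status is not None and len(kb.pregnancy_prior) \
            and pregnancy_status == _not_applicable_category(kb):
        for code in prior.index:
            if code.startswith(MATERNAL_PREFIX):
                prior[code] = 0.0

    if prior.sum() <= 0:
        flags.append("no-applicable-cause")
        return [], 1.0, flags

    post, fallback = propagate(record.responses, prior,
                               kb.conditional_probabilities(),
                               kb.substantive_values)
    if fallback:
        flags.append("all-causes-annihilated")
    reported, indet = select_reported_causes(post, settings)
    return reported, indet, flags


def classify_comcat(record: VARecord, kb: KnowledgeBase,
                    ) -> tuple[tuple[str, float] | None, bool]:
    """Argmax COMCAT category; None when the KB carries no COMCAT block."""
    if not kb.has_comcat:
        return None, False
    post, fallback = propagate(record.responses, kb.comcat_prior_probabilities(),
                               kb.comcat_conditional_probabilities(),
                               kb.substantive_values)
    i = int(np.argmax(post.to_numpy()))
    return (str(post.index[i]), float(post.iloc[i])), fallback


def classify_case(record: VARecord, kb: KnowledgeBase,
                  settings: ClassifierSettings = DEFAULT_SETTINGS,
                  ) -> CaseClassification:
    """Run the three classifiers in order and assemble the output row."""
    flags: list[str] = []
    pregnancy: tuple[str, float] | None = None
    preg_status = None
    if len(kb.pregnancy_prior):
        pregnancy, fb = classify_pregnancy(record, kb)
        preg_status = pregnancy[0]
        if fb:
            flags.append("pregnancy-fallback")
    reported, indet, cause_flags = classify_cause(record, kb, settings, preg_status)
    flags.extend(cause_flags)
    comcat, fb = classify_comcat(record, kb)
    if fb:
        flags.append("comcat-fallback")
    return CaseClassification(
        id=record.id, pregnancy_status=pregnancy, reported_causes=reported,
        indeterminate=indet, comcat=comcat, flags=flags,
        age_band=resolve_age(record, kb), sex=resolve_sex(record, kb))


def classify_cohort(records: Sequence[VARecord], kb: KnowledgeBase,
                    settings: ClassifierSettings = DEFAULT_SETTINGS,
                    ) -> list[CaseClassification]:
    return [classify_case(rec, kb, settings) for rec in records]


def classifications_to_frame(classifications: Sequence[CaseClassification],
                             ) -> pd.DataFrame:
    """Tabulate classifications in the fixed per-case output column order."""
    def r4(x: float) -> float:
        return float(np.round(x, 4))

    rows = []
    for clf in classifications:
        causes = [(c, r4(lik)) for c, lik in clf.reported_causes] \
            + [("", np.nan)] * 3
        rows.append({
            "ID": clf.id,
            "PREG_STATUS": clf.pregnancy_status[0] if clf.pregnancy_status else "",
            "PREG_LIK": r4(clf.pregnancy_status[1]) if clf.pregnancy_status else np.nan,
            "CAUSE1": causes[0][0], "LIK1": causes[0][1],
            "CAUSE2": causes[1][0], "LIK2": causes[1][1],
            "CAUSE3": causes[2][0], "LIK3": causes[2][1],
            "INDET": r4(clf.indeterminate),
            "COMCAT": clf.comcat[0] if clf.comcat else "",
            "COMCAT_LIK": r4(clf.comcat[1]) if clf.comcat else np.nan,
            "WARNINGS": ";".join(clf.flags),
        })
    return pd.DataFrame(rows, columns=OUTPUT_COLUMNS)
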