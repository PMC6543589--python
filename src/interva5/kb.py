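"""Knowledge-base definition, loading and parameterisation.

The knowledge base (KB) is the single data structure that drives all
probabilistic processing: a matrix of conditional probabilities
P(substantive response on indicator i | cause c), encoded as letter
grades, together with unconditional cause priors and two auxiliary
blocks of the same shape over pregnancy-status categories and
circumstance-of-mortality (COMCAT) categories.

Grades are resolved to probabilities through a :class:`GradeMap` — a
strictly decreasing ladder from ``A+`` down to ``E``, with ``N``
meaning "no association" (probability zero). The published KB
spreadsheets use this encoding; the numeric values of the ladder are
configuration, not physiology, and can be overridden.

File dialect
------------
A KB is a plain UTF-8 CSV. The first column holds indicator codes;
optional metadata columns (``text``, ``substantive``, ``sex``,
``ages``, ``group``, ``role``, ``formats``) may follow; every other
column is a category column: cause codes (e.g. ``01.04``), pregnancy
categories prefixed ``PREG:`` and COMCAT categories prefixed
``COMCAT:``. Reserved rows: ``PRIOR`` (required — unconditional
priors, as grades or numeric literals), ``SEX`` and ``AGE``
(optional — per-cause applicability).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "KBError",
    "GradeMap",
    "DEFAULT_GRADE_MAP",
    "IndicatorDef",
    "CauseDef",
    "KnowledgeBase",
    "grade_to_probability",
    "load_knowledge_base",
    "write_knowledge_base",
    "apply_prevalence",
    "broad_group_for_code",
    "AGE_BANDS",
    "FORMATS",
    "PREGNANCY_PREFIX",
    "COMCAT_PREFIX",
    "PREVALENCE_MULTIPLIERS",
    "HIV_CAUSE",
    "MALARIA_CAUSE",
]


class KBError(ValueError):
    """Raised when a knowledge base fails to load or validate."""


AGE_BANDS = ("neonate", "child", "adult")
FORMATS = ("who2016", "who2012", "tariff2")
SEXES = ("any", "female", "male")

PREGNANCY_PREFIX = "PREG:"
COMCAT_PREFIX = "COMCAT:"

#: Reserved first-column tokens that are not indicator rows.
RESERVED_ROWS = ("PRIOR", "SEX", "AGE")

#: Metadata columns recognised between the indicator code and the
#: category columns. All are optional.
METADATA_COLUMNS = ("text", "substantive", "sex", "ages", "group", "role", "formats")

HIV_CAUSE = "01.03"
MALARIA_CAUSE = "01.05"

#: Prior multiplier per prevalence level. "high" is the reference
#: population, so it leaves the KB untouched.
PREVALENCE_MULTIPLIERS: dict[str, float] = {"high": 1.0, "low": 0.1, "very low": 0.01}

_LEVEL_ALIASES = {"h": "high", "l": "low", "v": "very low", "very_low": "very low",
                  "verylow": "very low"}

#: Seven-group rollup of the WHO-2016 cause codes, keyed by the code's
#: leading chapter. ``99`` (indeterminate) is reported separately.
_BROAD_GROUPS = {
    "01": "Infections",
    "02": "Neoplasms",
    "03": "Other non-communicable diseases",
    "04": "Cardiovascular diseases",
    "05": "Other non-communicable diseases",
    "06": "Other non-communicable diseases",
    "07": "Other non-communicable diseases",
    "08": "Other non-communicable diseases",
    "09": "Maternal and neonatal causes",
    "10": "Maternal and neonatal causes",
    "11": "Stillbirths",
    "12": "External causes",
    "98": "Other non-communicable diseases",
    "99": "Indeterminate",
}


def broad_group_for_code(code: str) -> str:
    """Broad group implied by a WHO-2016 cause code's chapter prefix."""
    prefix = code.split(".")[0].split("&")[0].strip()[:2]
    try:
        return _BROAD_GROUPS[prefix]
    except KeyError:
        raise KBError(f"no broad group defined for cause code {code!r}") from None


@dataclass(frozen=True)
class GradeMap:
    """Ordered ladder of letter grades and their probabilities.

    ``grades`` maps tokens to probabilities in [0, 1]; ``order`` lists
    the tokens from strongest (``A+``) to absent (``N``). The ladder
    must be strictly decreasing and end at ``N = 0``.
    """

    grades: Mapping[str, float]
    order: tuple[str, ...]

    def __post_init__(self) -> None:
        vals = [self.grades[g] for g in self.order]
        if set(self.order) != set(self.grades):
            raise KBError("grade order and grade mapping name different tokens")
        if any(not 0.0 <= v <= 1.0 for v in vals):
            raise KBError("grade probabilities must lie in [0, 1]")
        if any(a <= b for a, b in zip(vals, vals[1:])):
            raise KBError("grade ladder must be strictly decreasing")
        if self.grades.get("N", 0.0) != 0.0:
            raise KBError("grade 'N' must map to probability 0")

    def __contains__(self, grade: str) -> bool:
        return grade in self.grades

    def __getitem__(self, grade: str) -> float:
        return self.grades[grade]

    def nearest_grade(self, p: float) -> str:
        """Token whose probability is closest to ``p`` (ties: stronger grade)."""
        return min(self.order, key=lambda g: (abs(self.grades[g] - p),
                                              self.order.index(g)))


_DEFAULT_LADDER = (
    ("A+", 0.8), ("A", 0.5), ("A-", 0.2),
    ("B+", 0.1), ("B", 0.05), ("B-", 0.02),
    ("C+", 0.01), ("C", 0.005), ("C-", 0.002),
    ("D+", 0.001), ("D", 0.0005), ("D-", 0.0001),
    ("E", 0.00001), ("N", 0.0),
)

DEFAULT_GRADE_MAP = GradeMap(dict(_DEFAULT_LADDER), tuple(g for g, _ in _DEFAULT_LADDER))


def grade_to_probability(grade: str, grade_map: GradeMap = DEFAULT_GRADE_MAP) -> float:
    """Resolve a letter grade to its probability under ``grade_map``."""
    try:
        return grade_map[grade]
    except KeyError:
        raise KBError(f"unknown grade token {grade!r}") from None


@dataclass(frozen=True)
class IndicatorDef:
    """One binary input item of the VA instrument.

    ``substantive_value`` is the evidential polarity: the response
    ("yes" or "no") that triggers a likelihood update. ``role`` marks
    the handful of demographic items (sex and age-band assertions) the
    consistency checks use to resolve who the deceased was.
    """

    code: str
    text: str = ""
    substantive_value: str = "yes"
    sex_applicability: str = "any"
    age_applicability: frozenset[str] = frozenset(AGE_BANDS)
    formats: frozenset[str] = frozenset(FORMATS)
    exclusivity_group: str | None = None
    role: str | None = None

    def __post_init__(self) -> None:
        if self.substantive_value not in ("yes", "no"):
            raise KBError(f"indicator {self.code!r}: substantive value must be "
                          f"'yes' or 'no', got {self.substantive_value!r}")
        if self.sex_applicability not in SEXES:
            raise KBError(f"indicator {self.code!r}: bad sex applicability "
                          f"{self.sex_applicability!r}")
        if not self.age_applicability <= set(AGE_BANDS):
            raise KBError(f"indicator {self.code!r}: bad age bands "
                          f"{sorted(self.age_applicability)}")
        if "who2016" not in self.formats:
            raise KBError(f"indicator {self.code!r}: every indicator belongs "
                          "to the WHO-2016 format")
        if self.role is not None and self.role not in ("male", "female") + AGE_BANDS:
            raise KBError(f"indicator {self.code!r}: bad role {self.role!r}")


@dataclass(frozen=True)
class CauseDef:
    """One WHO-2016 cause-of-death category."""

    code: str
    label: str = ""
    broad_group: str = ""
    age_applicability: frozenset[str] = frozenset(AGE_BANDS)
    sex_applicability: str = "any"
    prior_grade: str = "N"

    def __post_init__(self) -> None:
        if not self.broad_group:
            object.__setattr__(self, "broad_group", broad_group_for_code(self.code))
        if self.sex_applicability not in SEXES:
            raise KBError(f"cause {self.code!r}: bad sex applicability "
                          f"{self.sex_applicability!r}")


def _resolve_token(token: str, grade_map: GradeMap, where: str) -> float:
    """A cell is either a grade token or a numeric probability literal."""
    if token in grade_map:
        return grade_map[token]
    try:
        value = float(token)
    except ValueError:
        raise KBError(f"unknown grade token {token!r} at {where}") from None
    if not 0.0 <= value <= 1.0:
        raise KBError(f"numeric probability {token!r} at {where} outside [0, 1]")
    return value


@dataclass
class KnowledgeBase:
    """Indicators, causes and the grade matrices connecting them."""

    indicators: list[IndicatorDef]
    causes: list[CauseDef]
    conditional: pd.DataFrame          # grade tokens, indicators x causes
    pregnancy_prior: pd.Series         # tokens over pregnancy categories
    pregnancy_conditional: pd.DataFrame
    comcat_prior: pd.Series            # may be empty
    comcat_conditional: pd.DataFrame
    grade_map: GradeMap = DEFAULT_GRADE_MAP
    prior_multipliers: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        codes = [i.code for i in self.indicators]
        if len(set(codes)) != len(codes):
            dupes = sorted({c for c in codes if codes.count(c) > 1})
            raise KBError(f"duplicate indicator codes: {dupes}")
        if self.conditional.shape != (len(self.indicators), len(self.causes)):
            raise KBError(
                f"conditional matrix shape {self.conditional.shape} does not "
                f"match {len(self.indicators)} indicators x {len(self.causes)} causes")

    # -- lookups ---------------------------------------------------------

    @property
    def indicator_codes(self) -> list[str]:
        return [i.code for i in self.indicators]

    @property
    def cause_codes(self) -> list[str]:
        return [c.code for c in self.causes]

    def indicator(self, code: str) -> IndicatorDef:
        for ind in self.indicators:
            if ind.code == code:
                return ind
        raise KeyError(code)

    def cause(self, code: str) -> CauseDef:
        for cause in self.causes:
            if cause.code == code:
                return cause
        raise KeyError(code)

    @property
    def substantive_values(self) -> dict[str, str]:
        return {i.code: i.substantive_value for i in self.indicators}

    def role_indicators(self, roles: Iterable[str]) -> list[IndicatorDef]:
        wanted = set(roles)
        return [i for i in self.indicators if i.role in wanted]

    # -- numeric views ---------------------------------------------------
    #
    # The KB is treated as immutable once built (parameterisation goes
    # through apply_prevalence, which returns a new object), so resolved
    # matrices are memoised per instance.

    def _memo(self, key: str, build):
        cache = self.__dict__.setdefault("_cache", {})
        if key not in cache:
            cache[key] = build()
        return cache[key]

    def _resolve_frame(self, frame: pd.DataFrame, what: str) -> pd.DataFrame:
        tokens = frame.astype(str).to_numpy()
        lut = {}
        for t in np.unique(tokens):
            where = f"{what} (token {t!r})"
            lut[t] = _resolve_token(t, self.grade_map, where)
        out = np.vectorize(lut.__getitem__, otypes=[float])(tokens) \
            if tokens.size else np.empty(frame.shape, dtype=float)
        return pd.DataFrame(out, index=frame.index, columns=frame.columns)

    def prior_probabilities(self) -> pd.Series:
        """Cause priors with any prevalence multipliers applied, clipped to [0, 1]."""
        vals = self._memo("prior", lambda: pd.Series(
            [_resolve_token(c.prior_grade, self.grade_map, f"prior of {c.code}")
             for c in self.causes],
            index=self.cause_codes, dtype=float)).copy()
        for code, mult in self.prior_multipliers.items():
            if code in vals.index:
                vals[code] *= mult
        return vals.clip(0.0, 1.0)

    def conditional_probabilities(self) -> pd.DataFrame:
        return self._memo("conditional",
                          lambda: self._resolve_frame(self.conditional, "conditional"))

    def pregnancy_prior_probabilities(self) -> pd.Series:
        return pd.Series(
            [_resolve_token(str(t), self.grade_map, f"pregnancy prior {c}")
             for c, t in self.pregnancy_prior.items()],
            index=self.pregnancy_prior.index, dtype=float)

    def pregnancy_conditional_probabilities(self) -> pd.DataFrame:
        return self._memo("pregnancy", lambda: self._resolve_frame(
            self.pregnancy_conditional, "pregnancy block"))

    def comcat_prior_probabilities(self) -> pd.Series:
        return pd.Series(
            [_resolve_token(str(t), self.grade_map, f"comcat prior {c}")
             for c, t in self.comcat_prior.items()],
            index=self.comcat_prior.index, dtype=float)

    def comcat_conditional_probabilities(self) -> pd.DataFrame:
        return self._memo("comcat", lambda: self._resolve_frame(
            self.comcat_conditional, "comcat block"))

    @property
    def has_comcat(self) -> bool:
        return len(self.comcat_prior) > 0


# ---------------------------------------------------------------------------
# loading / writing


def _parse_set(token: str, default: frozenset[str]) -> frozenset[str]:
    token = token.strip()
    if not token or token == "*":
        return default
    return frozenset(t.strip() for t in token.split("|") if t.strip())


def load_knowledge_base(path: str | Path,
                        grade_map: GradeMap = DEFAULT_GRADE_MAP) -> KnowledgeBase:
    """Load and validate a knowledge base from the CSV dialect above.

    Raises :class:`KBError` with the offending row or token named when
    the file has duplicate indicator codes, unresolvable grade tokens,
    or no ``PRIOR`` row.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    raw = raw.rename(columns={raw.columns[0]: "indicator"})

    meta_cols = [c for c in raw.columns[1:] if c in METADATA_COLUMNS]
    category_cols = [c for c in raw.columns[1:] if c not in METADATA_COLUMNS]
    cause_cols = [c for c in category_cols
                  if not c.startswith((PREGNANCY_PREFIX, COMCAT_PREFIX))]
    preg_cols = [c for c in category_cols if c.startswith(PREGNANCY_PREFIX)]
    com_cols = [c for c in category_cols if c.startswith(COMCAT_PREFIX)]
    if not cause_cols:
        raise KBError(f"{path}: no cause columns found")

    first = raw["indicator"].astype(str)
    seen: dict[str, int] = {}
    for rownum, code in enumerate(first, start=2):  # header is line 1
        if code in RESERVED_ROWS:
            continue
        if code in seen:
            raise KBError(f"{path}: duplicate indicator code {code!r} at row "
                          f"{rownum} (first at row {seen[code]})")
        seen[code] = rownum

    special = {code: raw.iloc[i] for i, code in enumerate(first) if code in RESERVED_ROWS}
    if "PRIOR" not in special:
        raise KBError(f"{path}: reserved row 'PRIOR' is missing")
    body = raw[~first.isin(RESERVED_ROWS)].reset_index(drop=True)

    indicators = []
    for _, row in body.iterrows():
        indicators.append(IndicatorDef(
            code=row["indicator"],
            text=row.get("text", ""),
            substantive_value=(row.get("substantive", "") or "yes"),
            sex_applicability=(row.get("sex", "") or "any"),
            age_applicability=_parse_set(row.get("ages", ""), frozenset(AGE_BANDS)),
            formats=_parse_set(row.get("formats", ""), frozenset(FORMATS)),
            exclusivity_group=(row.get("group", "") or None),
            role=(row.get("role", "") or None),
        ))

    sex_row = special.get("SEX")
    age_row = special.get("AGE")
    causes = []
    for code in cause_cols:
        causes.append(CauseDef(
            code=code,
            prior_grade=str(special["PRIOR"][code]),
            sex_applicability=(str(sex_row[code]).strip() or "any") if sex_row is not None else "any",
            age_applicability=(_parse_set(str(age_row[code]), frozenset(AGE_BANDS))
                               if age_row is not None else frozenset(AGE_BANDS)),
        ))

    conditional = body[cause_cols].copy()
    conditional.index = [i.code for i in indicators]

    def _block(cols: list[str], prefix: str) -> tuple[pd.Series, pd.DataFrame]:
        cats = [c[len(prefix):] for c in cols]
        prior = pd.Series([str(special["PRIOR"][c]) for c in cols], index=cats, dtype=object)
        cond = body[cols].copy()
        cond.columns = cats
        cond.index = [i.code for i in indicators]
        return prior, cond

    preg_prior, preg_cond = _block(preg_cols, PREGNANCY_PREFIX) if preg_cols else (
        pd.Series(dtype=object), pd.DataFrame(index=[i.code for i in indicators]))
    com_prior, com_cond = _block(com_cols, COMCAT_PREFIX) if com_cols else (
        pd.Series(dtype=object), pd.DataFrame(index=[i.code for i in indicators]))

    kb = KnowledgeBase(indicators=indicators, causes=causes, conditional=conditional,
                       pregnancy_prior=preg_prior, pregnancy_conditional=preg_cond,
                       comcat_prior=com_prior, comcat_conditional=com_cond,
                       grade_map=grade_map)
    # fail fast on unresolvable tokens anywhere in the matrices
    kb.conditional_probabilities()
    kb.prior_probabilities()
    if len(preg_cols):
        kb.pregnancy_conditional_probabilities()
        kb.pregnancy_prior_probabilities()
    if len(com_cols):
        kb.comcat_conditional_probabilities()
        kb.comcat_prior_probabilities()
    return kb


def write_knowledge_base(kb: KnowledgeBase, path: str | Path) -> None:
    """Write a KB back to the CSV dialect; grade cells round-trip exactly."""
    rows = []
    cause_cols = kb.cause_codes
    preg_cols = [PREGNANCY_PREFIX + c for c in kb.pregnancy_prior.index]
    com_cols = [COMCAT_PREFIX + c for c in kb.comcat_prior.index]

    prior_row: dict[str, str] = {"indicator": "PRIOR"}
    for cause in kb.causes:
        prior_row[cause.code] = cause.prior_grade
    for col, cat in zip(preg_cols, kb.pregnancy_prior.index):
        prior_row[col] = str(kb.pregnancy_prior[cat])
    for col, cat in zip(com_cols, kb.comcat_prior.index):
        prior_row[col] = str(kb.comcat_prior[cat])
    rows.append(prior_row)
    rows.append({"indicator": "SEX", **{c.code: c.sex_applicability for c in kb.causes}})
    rows.append({"indicator": "AGE",
                 **{c.code: "|".join(sorted(c.age_applicability)) for c in kb.causes}})

    for ind in kb.indicators:
        row = {
            "indicator": ind.code,
            "text": ind.text,
            "substantive": ind.substantive_value,
            "sex": ind.sex_applicability,
            "ages": "|".join(sorted(ind.age_applicability)),
            "group": ind.exclusivity_group or "",
            "role": ind.role or "",
            "formats": "|".join(f for f in FORMATS if f in ind.formats),
        }
        for cause in cause_cols:
            row[cause] = str(kb.conditional.at[ind.code, cause])
        for col, cat in zip(preg_cols, kb.pregnancy_prior.index):
            row[col] = str(kb.pregnancy_conditional.at[ind.code, cat])
        for col, cat in zip(com_cols, kb.comcat_prior.index):
            row[col] = str(kb.comcat_conditional.at[ind.code, cat])
        rows.append(row)

    columns = (["indicator"] + list(METADATA_COLUMNS) + cause_cols + preg_cols + com_cols)
    pd.DataFrame(rows).reindex(columns=columns).fillna("").to_csv(path, index=False)


# ---------------------------------------------------------------------------
# user parameters


def normalise_level(level: str) -> str:
    token = level.strip().lower()
    token = _LEVEL_ALIASES.get(token, token)
    if token not in PREVALENCE_MULTIPLIERS:
        raise KBError(f"unknown prevalence level {level!r}; expected one of "
                      f"{sorted(PREVALENCE_MULTIPLIERS)}")
    return token


def apply_prevalence(kb: KnowledgeBase, hiv: str | None = "high",
                     malaria: str | None = "high",
                     multipliers: Mapping[str, float] = PREVALENCE_MULTIPLIERS,
                     hiv_cause: str = HIV_CAUSE,
                     malaria_cause: str = MALARIA_CAUSE) -> KnowledgeBase:
    """Scale the HIV and malaria cause priors by the population prevalence level.

    Returns a new KB; multipliers are *set* (not compounded), so the
    operation is idempotent and the two diseases commute. Level "high"
    is the multiplier-1 reference; None leaves a disease untouched.
    """
    mult = dict(kb.prior_multipliers)
    if hiv is not None:
        mult[hiv_cause] = multipliers[normalise_level(hiv)]
    if malaria is not None:
        mult[malaria_cause] = multipliers[normalise_level(malaria)]
    return replace(kb, prior_multipliers=mult,
                   conditional=kb.conditional.copy(),
                   indicators=list(kb.indicators), causes=list(kb.causes))
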