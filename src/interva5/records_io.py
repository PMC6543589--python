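"""Reading, harmonising and consistency-checking VA record files.

Input records are CSV rows of one free-text identifier followed by one
column per binary indicator, with a ternary response per cell:
yes / no / missing. The WHO-2012 and Tariff-2 item sets are both
subsets of WHO-2016, so "converting" a record to an earlier format
means masking the responses that fall outside that format's subset.

Consistency checking classifies rule violations into two severities:
ERROR-class violations (the deceased's age band or sex cannot be
resolved, or is asserted contradictorily) exclude the record, while
WARNING-class violations (a substantive response on an item that does
not apply to this age/sex, or more than one "yes" inside a mutually
exclusive category group) blank the offending responses and keep the
record.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .kb import FORMATS, AGE_BANDS, KnowledgeBase

__all__ = [
    "YES", "NO", "MISSING",
    "ResponseDialect", "DEFAULT_DIALECT",
    "VARecord", "FormatRegistry", "ConsistencyReport", "ConsistencyRules",
    "RecordsError",
    "read_va_csv", "write_va_csv", "convert_format", "check_consistency",
    "binarize_category", "resolve_sex", "resolve_age", "normalise_format",
]

YES = "yes"
NO = "no"
MISSING = "missing"


class RecordsError(ValueError):
    """Raised on unrecoverable input-file problems (header mismatch etc.)."""


_FORMAT_ALIASES = {
    "who2016": "who2016", "who-2016": "who2016", "interva5": "who2016",
    "who2012": "who2012", "who-2012": "who2012", "interva4": "who2012",
    "tariff2": "tariff2", "tariff-2": "tariff2", "smartva": "tariff2",
}


def normalise_format(tag: str) -> str:
    token = tag.strip().lower().replace("_", "").replace(" ", "")
    try:
        return _FORMAT_ALIASES[token]
    except KeyError:
        raise RecordsError(f"unknown input format tag {tag!r}; expected one of "
                           f"{list(FORMATS)}") from None


@dataclass(frozen=True)
class ResponseDialect:
    """Token sets mapped to yes/no; anything else reads as missing."""

    yes_tokens: frozenset[str] = frozenset({"y", "yes", "1"})
    no_tokens: frozenset[str] = frozenset({"n", "no", "0"})

    def decode(self, token: str) -> str:
        t = token.strip().lower()
        if t in self.yes_tokens:
            return YES
        if t in self.no_tokens:
            return NO
        return MISSING

    def encode(self, response: str) -> str:
        return {YES: "y", NO: "n", MISSING: "."}[response]


DEFAULT_DIALECT = ResponseDialect()


@dataclass
class VARecord:
    """One verbal-autopsy interview: an identifier plus ternary responses."""

    id: str
    responses: dict[str, str]

    def copy(self) -> "VARecord":
        return VARecord(self.id, dict(self.responses))

    def substantive_set(self, kb: KnowledgeBase) -> set[str]:
        """Indicator codes whose recorded response equals their evidential polarity."""
        subs = kb.substantive_values
        return {code for code, resp in self.responses.items()
                if resp != MISSING and subs.get(code) == resp}


# ---------------------------------------------------------------------------
# format registry


@dataclass(frozen=True)
class FormatRegistry:
    """Per-indicator membership in the three input formats."""

    membership: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for code, fmts in self.membership.items():
            if "who2016" not in fmts:
                raise RecordsError(
                    f"indicator {code!r}: every indicator belongs to WHO-2016")

    @classmethod
    def from_knowledge_base(cls, kb: KnowledgeBase) -> "FormatRegistry":
        return cls({i.code: i.formats for i in kb.indicators})

    @classmethod
    def from_csv(cls, path: str | Path) -> "FormatRegistry":
        """Registry CSV: columns indicator, who2016, who2012, tariff2 (1/0 flags)."""
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        frame = frame.rename(columns={frame.columns[0]: "indicator"})
        membership = {}
        for _, row in frame.iterrows():
            fmts = frozenset(f for f in FORMATS if str(row.get(f, "0")).strip()
                             in ("1", "y", "yes", "true"))
            membership[row["indicator"]] = fmts
        return cls(membership)

    def members(self, fmt: str) -> set[str]:
        fmt = normalise_format(fmt)
        return {code for code, fmts in self.membership.items() if fmt in fmts}


def convert_format(record: VARecord, target: str,
                   registry: FormatRegistry) -> VARecord:
    """Mask responses outside the target format's indicator subset to missing."""
    keep = registry.members(target)
    out = record.copy()
    for code in out.responses:
        if code not in keep:
            out.responses[code] = MISSING
    return out


# ---------------------------------------------------------------------------
# reading / writing


def read_va_csv(path: str | Path, kb: KnowledgeBase,
                dialect: ResponseDialect = DEFAULT_DIALECT) -> list[VARecord]:
    """Read a VA input CSV against a KB.

    The header must be the identifier column followed by exactly the
    KB's indicator codes (any order). Unknown or absent columns are a
    hard failure naming them; a short data row raises with the row
    number.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise RecordsError(f"{path}: empty file") from None
        id_col, *ind_cols = header
        expected = set(kb.indicator_codes)
        unknown = [c for c in ind_cols if c not in expected]
        missing_cols = sorted(expected - set(ind_cols))
        if unknown or missing_cols:
            parts = []
            if unknown:
                parts.append(f"unknown columns {unknown}")
            if missing_cols:
                parts.append(f"missing indicator columns {missing_cols}")
            raise RecordsError(f"{path}: header does not match knowledge base: "
                               + "; ".join(parts))
        records = []
        for rownum, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) != len(header):
                raise RecordsError(f"{path}: row {rownum} has {len(row)} fields, "
                                   f"expected {len(header)}")
            responses = {code: dialect.decode(tok)
                         for code, tok in zip(ind_cols, row[1:])}
            records.append(VARecord(id=row[0], responses=responses))
    return records


def write_va_csv(records: Sequence[VARecord], path: str | Path, kb: KnowledgeBase,
                 dialect: ResponseDialect = DEFAULT_DIALECT,
                 id_column: str = "ID") -> None:
    codes = kb.indicator_codes
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow([id_column] + codes)
        for rec in records:
            writer.writerow([rec.id] + [dialect.encode(rec.responses.get(c, MISSING))
                                        for c in codes])


# ---------------------------------------------------------------------------
# demographic resolution


def resolve_sex(record: VARecord, kb: KnowledgeBase) -> str | None:
    """'male', 'female', None (unresolvable) or 'conflict'."""
    asserted = {ind.role for ind in kb.role_indicators(("male", "female"))
                if record.responses.get(ind.code) == YES}
    if len(asserted) > 1:
        return "conflict"
    return next(iter(asserted), None)


def resolve_age(record: VARecord, kb: KnowledgeBase) -> str | None:
    """Age band asserted by the record's role indicators, or 'conflict'/None."""
    asserted = {ind.role for ind in kb.role_indicators(AGE_BANDS)
                if record.responses.get(ind.code) == YES}
    if len(asserted) > 1:
        return "conflict"
    return next(iter(asserted), None)


# ---------------------------------------------------------------------------
# consistency checking


@dataclass
class ConsistencyRules:
    """Which rule families are enforced; the rule set is configuration."""

    require_age: bool = True
    require_sex: bool = True
    mask_inapplicable: bool = True
    enforce_exclusivity: bool = True


@dataclass
class ConsistencyReport:
    errors: list[tuple[str, str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str, str]] = field(default_factory=list)
    excluded_ids: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = ([{"severity": "error", "id": i, "rule": r, "message": m}
                 for i, r, m in self.errors]
                + [{"severity": "warning", "id": i, "rule": r, "message": m}
                   for i, r, m in self.warnings])
        return pd.DataFrame(rows, columns=["severity", "id", "rule", "message"])


def check_consistency(records: Iterable[VARecord], kb: KnowledgeBase,
                      rules: ConsistencyRules | None = None,
                      ) -> tuple[list[VARecord], ConsistencyReport]:
    """Apply the consistency rule set; returns (cleaned records, report).

    ERROR-class firings exclude the record from the cleaned list;
    WARNING-class firings blank the offending responses and keep it.
    Rules that need demographic role indicators are skipped when the KB
    defines none (small fixture KBs).
    """
    rules = rules or ConsistencyRules()
    report = ConsistencyReport()
    cleaned: list[VARecord] = []

    has_sex_roles = bool(kb.role_indicators(("male", "female")))
    has_age_roles = bool(kb.role_indicators(AGE_BANDS))
    groups: dict[str, list[str]] = {}
    for ind in kb.indicators:
        if ind.exclusivity_group:
            groups.setdefault(ind.exclusivity_group, []).append(ind.code)

    for record in records:
        rec = record.copy()
        errored = False

        sex = resolve_sex(rec, kb) if has_sex_roles else None
        age = resolve_age(rec, kb) if has_age_roles else None
        if rules.require_sex and has_sex_roles:
            if sex == "conflict":
                report.errors.append((rec.id, "sex-conflict",
                                      "both male and female asserted"))
                errored = True
            elif sex is None:
                report.errors.append((rec.id, "sex-unresolved",
                                      "no resolvable sex"))
                errored = True
        if rules.require_age and has_age_roles:
            if age == "conflict":
                report.errors.append((rec.id, "age-conflict",
                                      "more than one age band asserted"))
                errored = True
            elif age is None:
                report.errors.append((rec.id, "age-unresolved",
                                      "no resolvable age band"))
                errored = True
        if errored:
            report.excluded_ids.append(rec.id)
            continue

        if rules.mask_inapplicable:
            for ind in kb.indicators:
                if ind.role is not None:
                    continue
                resp = rec.responses.get(ind.code)
                if resp is None or resp == MISSING or resp != ind.substantive_value:
                    continue
                if sex is not None and ind.sex_applicability not in ("any", sex):
                    report.warnings.append(
                        (rec.id, "sex-inapplicable",
                         f"substantive response on {ind.code} "
                         f"({ind.sex_applicability}-only) for {sex} deceased; "
                         "set to missing"))
                    rec.responses[ind.code] = MISSING
                elif age is not None and age not in ind.age_applicability:
                    report.warnings.append(
                        (rec.id, "age-inapplicable",
                         f"substantive response on {ind.code} (applies to "
                         f"{sorted(ind.age_applicability)}) for {age}; "
                         "set to missing"))
                    rec.responses[ind.code] = MISSING

        if rules.enforce_exclusivity:
            for group, members in groups.items():
                yes_members = [c for c in members if rec.responses.get(c) == YES]
                if len(yes_members) > 1:
                    # members are listed in ascending duration/severity;
                    # keep the last (longest/most severe) and blank the rest
                    for code in yes_members[:-1]:
                        rec.responses[code] = MISSING
                    report.warnings.append(
                        (rec.id, "exclusivity",
                         f"{len(yes_members)} 'yes' responses in group {group}; "
                         f"kept {yes_members[-1]}"))

        cleaned.append(rec)

    return cleaned, report


# ---------------------------------------------------------------------------
# categorical expansion of continuous items


def binarize_category(value: float | None, cut_points: Sequence[float],
                      band_codes: Sequence[str]) -> dict[str, str]:
    """Expand a continuous measurement into one-of-k binary indicators.

    Bands are left-closed/right-open: (-inf, c1), [c1, c2), ..., [ck, inf).
    Exactly one band reads yes and the rest no; a missing input yields
    all-missing.
    """
    cuts = list(cut_points)
    if any(a >= b for a, b in zip(cuts, cuts[1:])):
        raise RecordsError(f"cut points must be strictly increasing: {cuts}")
    if len(band_codes) != len(cuts) + 1:
        raise RecordsError(f"need {len(cuts) + 1} band codes for {len(cuts)} "
                           f"cut points, got {len(band_codes)}")
    if value is None or (isinstance(value, float) and value != value):
        return {code: MISSING for code in band_codes}
    band = sum(value >= c for c in cuts)
    return {code: (YES if i == band else NO) for i, code in enumerate(band_codes)}
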