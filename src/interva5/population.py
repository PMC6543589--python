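"""Population-level aggregation of case classifications into CSMF tables.

A cause-specific mortality fraction (CSMF) table holds, per stratum
(by default the under-5 / 5-plus reporting split), the fraction of
deaths attributed to each cause. Fractions are derived by summing the
individually assigned cause likelihoods over cases and dividing by the
stratum death count; the per-case indeterminate residuals aggregate
identically into an indeterminate fraction, so each stratum row sums
to one.

Downstream operations: proportional redistribution of the
indeterminate fraction over the reported causes, amalgamation of
causes a comparator does not distinguish (e.g. fresh + macerated
stillbirths), and rollup into the seven broad cause groups.
Fractions are carried as proportions; rendering as percentages is a
formatting concern only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import CaseClassification
from .kb import CauseDef, broad_group_for_code

__all__ = [
    "INDETERMINATE", "PopulationError", "CSMFTable",
    "aggregate_csmf", "redistribute_indeterminate", "merge_causes",
    "broad_groups", "default_stratum", "write_csmf_csv", "read_csmf_csv",
    "csmf_table_from_columns",
]

#: Column code for the indeterminate fraction (WHO category 99).
INDETERMINATE = "99"


class PopulationError(ValueError):
    pass


@dataclass
class CSMFTable:
    """stratum x cause fractions plus per-stratum death counts.

    ``fractions`` rows are strata, columns cause codes (possibly
    including :data:`INDETERMINATE`). NaN marks a cause with no value
    for that stratum (e.g. not printed / not applicable); present
    values in a stratum sum to 1 within tolerance unless the table was
    built from an external source.
    """

    fractions: pd.DataFrame
    n_deaths: pd.Series

    @property
    def strata(self) -> list[str]:
        return list(self.fractions.index)

    @property
    def has_indeterminate(self) -> bool:
        return INDETERMINATE in self.fractions.columns

    def stratum_row(self, stratum: str) -> pd.Series:
        return self.fractions.loc[stratum]

    def copy(self) -> "CSMFTable":
        return CSMFTable(self.fractions.copy(), self.n_deaths.copy())


def default_stratum(clf: CaseClassification) -> str:
    """The under-5 / 5-plus reporting split; neonates count as under-5."""
    if clf.age_band in ("neonate", "child"):
        return "under5"
    if clf.age_band == "adult":
        return "5plus"
    return "all"


def aggregate_csmf(classifications: Sequence[CaseClassification],
                   stratum_of: Callable[[CaseClassification], str] = default_stratum,
                   causes: Sequence[str] | None = None) -> CSMFTable:
    """Mean assigned likelihood per cause and stratum.

    CSMF(c) = sum over the stratum's cases of the likelihood reported
    for c, divided by the stratum death count; the indeterminate
    residual aggregates the same way, so each row sums to 1.
    """
    if not classifications:
        raise PopulationError("no classifications to aggregate")
    if causes is None:
        seen: dict[str, None] = {}
        for clf in classifications:
            for code, _ in clf.reported_causes:
                seen.setdefault(code)
        causes = list(seen)
    columns = list(causes) + [INDETERMINATE]

    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    col_index = {c: i for i, c in enumerate(columns)}
    for clf in classifications:
        stratum = stratum_of(clf)
        acc = sums.setdefault(stratum, np.zeros(len(columns)))
        counts[stratum] = counts.get(stratum, 0) + 1
        for code, lik in clf.reported_causes:
            acc[col_index[code]] += lik
        acc[col_index[INDETERMINATE]] += clf.indeterminate

    strata = sorted(sums)
    frame = pd.DataFrame([sums[s] / counts[s] for s in strata],
                         index=strata, columns=columns)
    return CSMFTable(frame, pd.Series({s: counts[s] for s in strata}, dtype=int))


def redistribute_indeterminate(table: CSMFTable) -> CSMFTable:
    """Remove the indeterminate fraction by proportional rescaling.

    Each cause fraction is scaled by 1/(1 - indeterminate) per stratum;
    idempotent (a table without indeterminate is returned unchanged).
    """
    if not table.has_indeterminate:
        return table.copy()
    frac = table.fractions.copy()
    indet = frac[INDETERMINATE].fillna(0.0)
    if (indet >= 1.0 - 1e-12).any():
        bad = list(indet.index[indet >= 1.0 - 1e-12])
        raise PopulationError(f"indeterminate fraction is 1 in strata {bad}; "
                              "nothing to redistribute over")
    frac = frac.drop(columns=[INDETERMINATE])
    out = frac.div(1.0 - indet, axis=0)
    return CSMFTable(out, table.n_deaths.copy())


def merge_causes(table: CSMFTable, merge_map: Mapping[str, str]) -> CSMFTable:
    """Sum the fractions of merged source causes into their targets.

    Chains are followed (a -> b, b -> c puts a's mass in c); a cycle is
    an error. An empty map is the identity.
    """
    resolved: dict[str, str] = {}
    for src in merge_map:
        target, seen = src, {src}
        while target in merge_map:
            target = merge_map[target]
            if target in seen:
                raise PopulationError(f"cyclic merge map at {src!r}")
            seen.add(target)
        resolved[src] = target

    frac = table.fractions.copy()
    for src, target in resolved.items():
        if src not in frac.columns or src == target:
            continue
        if target not in frac.columns:
            frac[target] = np.nan
        src_vals = frac[src]
        merged = frac[target].fillna(0.0).where(
            ~(frac[target].isna() & src_vals.isna()), np.nan)
        frac[target] = merged + src_vals.fillna(0.0)
        frac = frac.drop(columns=[src])
    return CSMFTable(frac, table.n_deaths.copy())


def broad_groups(table: CSMFTable,
                 cause_defs: Iterable[CauseDef] | None = None) -> CSMFTable:
    """Roll causes up into the seven broad groups (indeterminate kept apart).

    Group membership comes from the cause definitions when given,
    otherwise from the cause code's chapter prefix. A cause that maps
    to no group is an error naming it.
    """
    lookup = {c.code: c.broad_group for c in cause_defs} if cause_defs else {}
    frac = table.fractions
    group_of: dict[str, str] = {}
    for code in frac.columns:
        if code == INDETERMINATE:
            group_of[code] = "Indeterminate"
            continue
        group = lookup.get(code) or broad_group_for_code(code)
        if not group:
            raise PopulationError(f"cause {code!r} has no broad group")
        group_of[code] = group

    groups = list(dict.fromkeys(group_of.values()))
    out = pd.DataFrame(index=frac.index, columns=groups, dtype=float)
    for group in groups:
        members = [c for c, g in group_of.items() if g == group]
        block = frac[members]
        summed = block.sum(axis=1, min_count=1)
        out[group] = summed
    return CSMFTable(out, table.n_deaths.copy())


# ---------------------------------------------------------------------------
# CSV interface


def write_csmf_csv(table: CSMFTable, path, cause_defs: Iterable[CauseDef] | None = None,
                   percent: bool = True) -> None:
    """Long-format CSMF CSV: stratum, cause, label, broad_group, fraction."""
    labels = {c.code: c.label for c in cause_defs} if cause_defs else {}
    rows = []
    for stratum in table.strata:
        for code, value in table.fractions.loc[stratum].items():
            if pd.isna(value):
                continue
            group = ("Indeterminate" if code == INDETERMINATE
                     else _safe_group(str(code)))
            rows.append({
                "stratum": stratum, "cause": code,
                "label": labels.get(code, "Indeterminate" if code == INDETERMINATE else ""),
                "broad_group": group,
                "fraction": value * 100 if percent else value,
            })
    pd.DataFrame(rows, columns=["stratum", "cause", "label", "broad_group",
                                "fraction"]).to_csv(path, index=False)


def _safe_group(code: str) -> str:
    try:
        return broad_group_for_code(code)
    except Exception:
        return ""


def read_csmf_csv(path, percent: bool = True) -> CSMFTable:
    """Read a long-format CSMF CSV back into a table (counts unknown)."""
    frame = pd.read_csv(path, dtype={"cause": str, "stratum": str})
    wide = frame.pivot(index="stratum", columns="cause", values="fraction")
    if percent:
        wide = wide / 100.0
    wide.columns = [str(c) for c in wide.columns]
    n = pd.Series(0, index=wide.index, dtype=int)
    return CSMFTable(wide, n)


def csmf_table_from_columns(frame: pd.DataFrame, value_column: str,
                            stratum_column: str = "age_group",
                            cause_column: str = "cause",
                            percent: bool = True) -> CSMFTable:
    """Build a CSMFTable from one value column of a long-format frame.

    Used by the packaged published-table fixtures, whose cells are
    percentages; blanks (causes not printed for a stratum) become NaN.
    """
    wide = frame.pivot(index=stratum_column, columns=cause_column,
                       values=value_column)
    wide.columns = [str(c) for c in wide.columns]
    if percent:
        wide = wide / 100.0
    return CSMFTable(wide, pd.Series(0, index=wide.index, dtype=int))
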