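"""Packaged published CSMF comparison tables.

Two evaluation tables ship with the package as plain CSV, holding
cause-specific mortality fractions (printed as percentages, two
decimals) by age group:

* PHMRC hospital comparison — 6130 deaths from the Population Health
  Metrics Research Consortium reference dataset, with the
  hospital-assigned and the model-assigned CSMF per WHO-2016 cause
  category (indeterminate already redistributed proportionally).
* Afghanistan format comparison — 4009 deaths from the Afghanistan
  2010 national mortality survey, processed three times from the
  WHO-2016, WHO-2012 and Tariff-2 indicator subsets (indeterminate
  retained as category 99).

A blank cell in the source table (a cause not printed for an age
group) is carried as NaN. Matching broad-group rollup tables are
packaged alongside.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .population import CSMFTable, csmf_table_from_columns

__all__ = [
    "load_phmrc_comparison", "load_afghanistan_comparison",
    "load_phmrc_broad_groups", "load_afghanistan_broad_groups",
    "comparison_tables",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("interva5.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, dtype={"cause": str})


def load_phmrc_comparison() -> pd.DataFrame:
    """Long frame: cause, label, age_group, phmrc, interva5 (CSMF %)."""
    return _read("phmrc_hospital_vs_interva5_csmf.csv")


def load_afghanistan_comparison() -> pd.DataFrame:
    """Long frame: cause, label, age_group, who2016, who2012, tariff2 (CSMF %)."""
    return _read("afghanistan_format_comparison_csmf.csv")


def load_phmrc_broad_groups() -> pd.DataFrame:
    return _read("phmrc_broad_groups.csv")


def load_afghanistan_broad_groups() -> pd.DataFrame:
    return _read("afghanistan_broad_groups.csv")


def comparison_tables(frame: pd.DataFrame,
                      value_columns: list[str]) -> dict[str, CSMFTable]:
    """One CSMFTable per value column of a packaged comparison frame."""
    return {col: csmf_table_from_columns(frame, col) for col in value_columns}
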