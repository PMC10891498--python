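"""Published summary tables of the validation study, as fixed inputs.

The study's raw survey data are not deposited; what is public are the
summary tables (per-variable medians, signed-rank p-values and Spearman
correlations for 16 food groups and 29 nutrients).  These printed rows are
shipped as TSV assets and serve as worked-example inputs to downstream
rules such as the relevance flag — they are never recomputed here.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .validity_stats import relevance_flag

__all__ = [
    "parse_p_value",
    "load_food_group_summary",
    "load_nutrient_summary",
    "flag_summary_table",
]


def parse_p_value(printed: str) -> float:
    """Numeric p from a printed table cell.

    Cells like ``"<.001"`` state an upper bound; the bound itself is returned,
    which is conservative and decision-identical for any significance level
    at or above the bound.
    """
    s = str(printed).strip()
    if s.startswith("<"):
        s = s[1:]
    if s.startswith("."):
        s = "0" + s
    return float(s)


def _load(asset: str) -> pd.DataFrame:
    path = resources.files("dietvalid.data") / asset
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", dtype={"p_value": str})
    df["p_numeric"] = df["p_value"].map(parse_p_value)
    return df


def load_food_group_summary() -> pd.DataFrame:
    """The 16 food-group rows of the main published comparison table."""
    return _load("reference_food_group_summary.tsv")


def load_nutrient_summary() -> pd.DataFrame:
    """The 29 nutrient rows of the published nutrient comparison table."""
    return _load("reference_nutrient_summary.tsv")


def flag_summary_table(df: pd.DataFrame) -> pd.DataFrame:
    """Apply the relevance rule to printed medians and p-values.

    Adds ``relevant`` (nullable boolean; None when the reference median is 0)
    and ``direction`` columns.
    """
    out = df.copy()
    flags = [
        relevance_flag(row.median_record, row.median_recall, row.p_numeric)
        for row in df.itertuples(index=False)
    ]
    out["relevant"] = [f.relevant for f in flags]
    out["direction"] = [f.direction.value for f in flags]
    return out
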