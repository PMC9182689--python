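"""Summary of the SEER 2000-2016 incidence extract (six cancer types).

The screening analyses were designed around registry extracts for
esophageal, kidney, liver, mesothelioma, ovarian and pancreatic cancer.
This module embeds the published summary counts of that extract —
cases stratified by sex, 5-year age band and ancestry, plus survival
summary statistics per cancer type — as a small in-package fixture.
Only the per-stratum counts and per-cancer survival moments are stored;
totals, shares and pooled statistics are recomputed, which doubles as
an arithmetic consistency check on ingestion.
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

__all__ = [
    "CANCERS",
    "summary_counts",
    "survival_summary",
    "totals_by_cancer",
    "overall_total",
    "share_of_overall",
    "pooled_mean_survival",
]

CANCERS = ["esophagus", "kidney", "liver", "mesothelioma", "ovary", "pancreas"]

# section,level,esophagus,kidney,liver,mesothelioma,ovary,pancreas
_COUNTS_CSV = """\
section,level,esophagus,kidney,liver,mesothelioma,ovary,pancreas
sex,female,11303,70726,22093,2017,85530,70213
sex,male,45142,125959,69343,8075,0,77467
age,25-29,0,592,0,0,782,0
age,30-34,0,1990,0,0,1436,201
age,35-39,212,4100,316,0,2165,713
age,40-44,752,8098,1409,0,4429,2406
age,45-49,2314,13549,4900,104,7350,5490
age,50-54,4575,20016,10873,383,9967,10214
age,55-59,7097,25790,16476,639,11187,15604
age,60-64,8812,28823,16431,1142,11320,20251
age,65-69,9593,29798,13412,1533,10645,23201
age,70-74,8893,26132,11126,1936,9778,24112
age,75-79,8089,22219,9551,2298,8913,24190
age,80-84,6108,15578,6942,2057,7558,21298
ancestry,African American,6668,22642,12026,0,6885,18091
ancestry,Asian/Pacific Islander,1934,9021,14454,0,6183,9716
ancestry,Caucasian,44149,139920,47688,9414,62426,105221
ancestry,Hispanic,3694,25102,17268,678,10036,14652
"""

# cancer,mean_survival_months,sd_survival_months,median_survival_months
_SURVIVAL_CSV = """\
cancer,mean_months,sd_months,median_months
esophagus,25.3,36.6,10.0
kidney,77.3,53.1,75.1
liver,22.5,32.7,8.13
mesothelioma,16.1,22.1,9.00
ovary,56.6,51.3,43.8
pancreas,13.5,23.6,5.00
"""


def summary_counts() -> pd.DataFrame:
    """Long-format stratum counts: section, level, one column per cancer."""
    return pd.read_csv(StringIO(_COUNTS_CSV))


def survival_summary() -> pd.DataFrame:
    """Per-cancer survival summary (months), indexed by cancer type."""
    return pd.read_csv(StringIO(_SURVIVAL_CSV), index_col="cancer")


def totals_by_cancer(section: str = "sex") -> pd.Series:
    """Total cases per cancer recomputed by summing one stratification.

    Every section (sex, age, ancestry) partitions the same cases, so
    the totals must agree across sections — a built-in ingestion check.
    """
    df = summary_counts()
    sub = df[df["section"] == section]
    if sub.empty:
        raise KeyError(f"unknown section {section!r}")
    return sub[CANCERS].sum()


def overall_total() -> int:
    """Total cases across all six cancers (from the sex stratification)."""
    return int(totals_by_cancer("sex").sum())


def share_of_overall(section: str, level: str) -> float:
    """Percent of all cases in one stratum, recomputed from counts."""
    df = summary_counts()
    row = df[(df["section"] == section) & (df["level"] == level)]
    if row.empty:
        raise KeyError(f"no stratum ({section}, {level})")
    return 100.0 * float(row[CANCERS].sum(axis=1).iloc[0]) / overall_total()


def pooled_mean_survival() -> float:
    """Case-weighted mean survival (months) pooled across cancers."""
    totals = totals_by_cancer("sex")
    means = survival_summary()["mean_months"]
    return float((totals * means).sum() / totals.sum())
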