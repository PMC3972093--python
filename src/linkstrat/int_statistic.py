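"""The INT statistic and its conditional summary tables.

INT is the difference between the stratified and unstratified maximum
multipoint lod score in the linkage interval containing the test locus B,
computed per dataset:

    INT = max lod (stratified) - max lod (unstratified)

A strictly positive INT indicates evidence of gene-gene interaction: the
linkage signal at B grows when family members who cannot express the
disease through the known locus A are removed.  INT <= 0 suggests no
interaction (the apparent penetrance at B did not rise).

Summaries are reported conditionally on the unstratified lod score
because in practice one would only probe a region with some initial
linkage signal: the strata are lod >= 0, lod >= 1.5, 1.5 <= lod < 3, and
lod < 0 (thresholds inclusive on the left), plus dataset percentages at
<0 / >=0 / >=1.5 / >=3 for both analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import isfinite

import numpy as np
import pandas as pd

__all__ = [
    "DatasetResult",
    "INTSummary",
    "int_value",
    "summarize",
    "percent_positive",
    "lod_threshold_table",
]

#: conditioning strata, keyed by label: (inclusive lower bound, exclusive
#: upper bound) on the unstratified lod
STRATA = {
    "lod>=0": (0.0, np.inf),
    "lod>=1.5": (1.5, np.inf),
    "1.5<=lod<3": (1.5, 3.0),
    "lod<0": (-np.inf, 0.0),
}

LOD_THRESHOLDS = {
    "lod<0": lambda x: x < 0.0,
    "lod>=0": lambda x: x >= 0.0,
    "lod>=1.5": lambda x: x >= 1.5,
    "lod>=3": lambda x: x >= 3.0,
}


def int_value(lod_stratified: float, lod_unstratified: float) -> float:
    """INT = stratified - unstratified maximum lod at the test locus."""
    if not (isfinite(lod_stratified) and isfinite(lod_unstratified)):
        raise ValueError("lod scores must be finite")
    return float(lod_stratified) - float(lod_unstratified)


@dataclass
class DatasetResult:
    """Per-dataset record of the stratification analysis."""

    dataset: int
    lod_unstratified: float
    lod_stratified: float
    families_before: int
    families_after: int
    subjects_before: int
    subjects_after: int
    seed: int | None = None

    @property
    def int_statistic(self) -> float:
        return int_value(self.lod_stratified, self.lod_unstratified)

    def as_dict(self) -> dict:
        d = {
            "dataset": self.dataset,
            "lod_unstratified": self.lod_unstratified,
            "lod_stratified": self.lod_stratified,
            "int": self.int_statistic,
            "families_before": self.families_before,
            "families_after": self.families_after,
            "subjects_before": self.subjects_before,
            "subjects_after": self.subjects_after,
        }
        if self.seed is not None:
            d["seed"] = self.seed
        return d


@dataclass
class INTSummary:
    """Stratified summary of INT and lod scores over datasets.

    ``table`` has one row per conditioning stratum with: n datasets,
    percent with INT > 0 (strictly; INT = 0 counts as non-positive),
    mean +- sd of INT, and mean +- sd of the unstratified and stratified
    lods.  Standard deviations are sample (n-1) standard deviations.
    Empty strata keep n = 0 with NaN statistics.
    """

    table: pd.DataFrame
    thresholds: pd.DataFrame
    n_datasets: int


def _frame(results) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        df = results.copy()
    else:
        df = pd.DataFrame(
            [r.as_dict() if isinstance(r, DatasetResult) else dict(r)
             for r in results]
        )
    if "int" not in df.columns:
        df["int"] = df["lod_stratified"] - df["lod_unstratified"]
    return df


def percent_positive(results, lod_min: float = 0.0, strict: bool = False) -> float:
    """Percent of datasets with INT > 0 among those whose unstratified lod
    meets the conditioning bound (``>= lod_min``, or ``> lod_min`` with
    ``strict=True``).  NaN if the conditioning set is empty."""
    df = _frame(results)
    cond = (
        df["lod_unstratified"] > lod_min
        if strict
        else df["lod_unstratified"] >= lod_min
    )
    sel = df.loc[cond, "int"]
    if len(sel) == 0:
        return float("nan")
    return float(100.0 * (sel > 0).mean())


def lod_threshold_table(results) -> pd.DataFrame:
    """Percent of datasets meeting each lod threshold, per analysis."""
    df = _frame(results)
    rows = {}
    for label, pred in LOD_THRESHOLDS.items():
        rows[label] = {
            "unstratified_pct": 100.0 * pred(df["lod_unstratified"]).mean(),
            "stratified_pct": 100.0 * pred(df["lod_stratified"]).mean(),
        }
    return pd.DataFrame(rows).T


def summarize(results, strata: dict | None = None) -> INTSummary:
    """Conditional INT summary over per-dataset results.

    ``results`` is an iterable of DatasetResult (or mappings with
    lod_unstratified / lod_stratified fields).
    """
    df = _frame(results)
    if len(df) == 0:
        raise ValueError("need at least one dataset result")
    strata = STRATA if strata is None else strata
    rows = []
    for label, (lo, hi) in strata.items():
        sel = df[(df["lod_unstratified"] >= lo) & (df["lod_unstratified"] < hi)]
        n = len(sel)
        row = {"stratum": label, "n": n}
        if n:
            row["pct_pos_int"] = 100.0 * (sel["int"] > 0).mean()
            for col, name in [
                ("int", "int"),
                ("lod_unstratified", "lod_unstr"),
                ("lod_stratified", "lod_str"),
            ]:
                row[f"mean_{name}"] = sel[col].mean()
                row[f"sd_{name}"] = sel[col].std(ddof=1) if n > 1 else np.nan
        else:
            for k in (
                "pct_pos_int",
                "mean_int",
                "sd_int",
                "mean_lod_unstr",
                "sd_lod_unstr",
                "mean_lod_str",
                "sd_lod_str",
            ):
                row[k] = np.nan
        rows.append(row)
    table = pd.DataFrame(rows).set_index("stratum")
    # consistency: strata are nested
    n_ge0 = int(table.loc["lod>=0", "n"])
    n_ge15 = int(table.loc["lod>=1.5", "n"]) if "lod>=1.5" in table.index else 0
    assert n_ge15 <= n_ge0 <= len(df)
    return INTSummary(
        table=table, thresholds=lod_threshold_table(df), n_datasets=len(df)
    )
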