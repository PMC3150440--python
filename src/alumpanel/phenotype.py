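"""Relative root growth (RRG) tolerance indices and their summaries.

Al tolerance of a line is quantified as relative root growth: the mean root
growth of its Al-treated replicates divided by the mean growth of its control
replicates, computed separately for total (TRG), primary (PRG) and longest
(LRG) root growth.  Values above 1 are legitimate (lines whose root growth
is enhanced under Al).  Group summaries, Tukey-fence outlier flags and the
one-way ANOVA fraction of variance explained by a grouping all operate on
these indices.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

ROOT_CLASSES = ("total", "primary", "longest")
INDEX_NAMES = {"total": "TRG_RRG", "primary": "PRG_RRG", "longest": "LRG_RRG"}

#: subpopulations comprising each varietal group
VARIETAL_GROUPS = {
    "indica": "Indica",
    "aus": "Indica",
    "tropical_japonica": "Japonica",
    "temperate_japonica": "Japonica",
    "aromatic": "Japonica",
}


def varietal_group(subpop: str) -> str:
    """Map a subpopulation label to its varietal group (admixed passes through)."""
    return VARIETAL_GROUPS.get(subpop, "admixed")


def compute_rrg(records: pd.DataFrame) -> pd.DataFrame:
    """Per-line tolerance indices: mean growth (Al) / mean growth (control).

    ``records`` has columns ``line``, ``treatment`` in {control, Al},
    ``replicate`` and one column per root class (``total``, ``primary``,
    ``longest``; absent classes are skipped).  A line whose control mean is
    zero for a class gets NaN for that index and a row in
    ``result.attrs['undefined']`` instead of a number.
    """
    present = [c for c in ROOT_CLASSES if c in records.columns]
    if not present:
        raise ValueError("no root-growth columns found")
    if not set(records["treatment"]) <= {"control", "Al"}:
        bad = set(records["treatment"]) - {"control", "Al"}
        raise ValueError(f"unknown treatment labels: {sorted(bad)}")

    means = records.groupby(["line", "treatment"])[present].mean()
    out = {}
    undefined = []
    for line in records["line"].unique():
        if ("control" not in means.loc[line].index) or ("Al" not in means.loc[line].index):
            raise ValueError(f"line {line} lacks one of the treatments")
        row = {}
        for cls in present:
            ctrl = means.loc[(line, "control"), cls]
            al = means.loc[(line, "Al"), cls]
            if ctrl == 0:
                row[INDEX_NAMES[cls]] = np.nan
                undefined.append((line, INDEX_NAMES[cls]))
            else:
                row[INDEX_NAMES[cls]] = al / ctrl
        out[line] = row
    result = pd.DataFrame.from_dict(out, orient="index")
    result.index.name = "line"
    result = result.reset_index()
    result.attrs["undefined"] = undefined
    return result


def group_summary(values: pd.Series, labels: pd.Series) -> pd.DataFrame:
    """Per-group mean, SD, quartiles, selected percentiles and range.

    Percentiles use linear interpolation (the numpy default).  Groups with a
    single member report NaN SD; empty groups are omitted with a warning.
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float), "group": np.asarray(labels)})
    df = df.dropna(subset=["value"])
    rows = []
    for g, grp in df.groupby("group", sort=False):
        v = grp["value"].to_numpy()
        if v.size == 0:
            warnings.warn(f"group {g} has no observations; omitted")
            continue
        q1, q2, q3 = np.percentile(v, [25, 50, 75])
        rows.append(
            {
                "group": g,
                "n": v.size,
                "mean": v.mean(),
                "sd": v.std(ddof=1) if v.size > 1 else np.nan,
                "min": v.min(),
                "p10": np.percentile(v, 10),
                "q1": q1,
                "median": q2,
                "q3": q3,
                "p90": np.percentile(v, 90),
                "max": v.max(),
                "iqr": q3 - q1,
            }
        )
    return pd.DataFrame(rows)


def anova_r2(values, labels) -> float:
    """One-way ANOVA fraction of variance explained: SS_between / SS_total.

    Returns NaN (flagged undefined) for constant input; requires >= 2 groups.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(labels)
    keep = ~np.isnan(v)
    v, g = v[keep], g[keep]
    groups = np.unique(g)
    if groups.size < 2:
        raise ValueError("anova_r2 needs >= 2 groups with observations")
    grand = v.mean()
    ss_tot = ((v - grand) ** 2).sum()
    if ss_tot == 0:
        return float("nan")
    ss_between = sum(
        (v[g == grp].size) * (v[g == grp].mean() - grand) ** 2 for grp in groups
    )
    return float(ss_between / ss_tot)


def flag_outliers(values: pd.Series, labels: pd.Series, k: float = 1.5) -> pd.DataFrame:
    """Tukey-fence outliers within each group.

    A line is an outlier if its value lies outside
    [Q1 - k*IQR, Q3 + k*IQR] of its group (default k = 1.5); ``direction``
    records whether it is a tolerant (high) or susceptible (low) outlier.
    """
    v = pd.Series(np.asarray(values, dtype=float))
    g = pd.Series(np.asarray(labels))
    idx = getattr(values, "index", v.index)
    rows = []
    for grp in g.unique():
        mask = (g == grp).to_numpy()
        vals = v[mask]
        if vals.size < 2:
            continue
        q1, q3 = np.percentile(vals.dropna(), [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - k * iqr, q3 + k * iqr
        for pos, val in vals.items():
            if np.isnan(val):
                continue
            if val > hi:
                rows.append({"line": idx[pos], "group": grp, "value": val,
                             "direction": "tolerant"})
            elif val < lo:
                rows.append({"line": idx[pos], "group": grp, "value": val,
                             "direction": "susceptible"})
    return pd.DataFrame(rows, columns=["line", "group", "value", "direction"])


def broad_sense_h2(records: pd.DataFrame, root_class: str = "total",
                   treatment: str = "Al") -> float:
    """Fraction of phenotypic variance attributable to line identity.

    Computed as Var(line) / Var(total) from a one-way line-replicate random
    effects ANOVA (method of moments) on the growth values of one treatment.
    """
    sub = records[records["treatment"] == treatment]
    groups = [g[root_class].to_numpy(dtype=float) for _, g in sub.groupby("line")]
    k = len(groups)
    if k < 2:
        raise ValueError("need >= 2 lines")
    n_i = np.array([len(g) for g in groups], dtype=float)
    N = n_i.sum()
    grand = np.concatenate(groups).mean()
    ss_b = float(sum(n * (g.mean() - grand) ** 2 for n, g in zip(n_i, groups)))
    ss_w = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    ms_b = ss_b / (k - 1)
    ms_w = ss_w / max(N - k, 1)
    n0 = (N - (n_i**2).sum() / N) / (k - 1)
    var_g = max((ms_b - ms_w) / n0, 0.0)
    total = var_g + ms_w
    return float(var_g / total) if total > 0 else float("nan")
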