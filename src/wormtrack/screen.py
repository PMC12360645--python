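"""Phenotypic-screen comparison statistics.

Feature tables are pandas DataFrames indexed by well with metadata columns
(``drug``, ``dose``, ``is_control``) plus one column per behavioural feature.
Provided statistics: per-feature Pearson correlation between two trackers
(with a histogram modal value), one-way F-statistics across groups, and
small-sample-corrected standardized effect sizes (Hedge's d) aggregated
across doses.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "METADATA_COLUMNS",
    "feature_columns",
    "basic_features",
    "feature_correlations",
    "modal_correlation",
    "feature_f_statistic",
    "hedges_d",
    "mean_abs_effect",
]

METADATA_COLUMNS = ["drug", "dose", "is_control"]


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in METADATA_COLUMNS]


def _signed_curvature(skeleton: np.ndarray) -> np.ndarray:
    """Signed curvature (1/px): turning angle between consecutive segments
    divided by the local arclength step (exact on circular arcs); endpoint
    values copy their interior neighbours."""
    seg = np.diff(skeleton, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    seglen[seglen == 0] = np.inf
    ang = np.arctan2(seg[:, 1], seg[:, 0])
    turn = np.diff(ang)
    turn = (turn + np.pi) % (2 * np.pi) - np.pi
    ds = 0.5 * (seglen[:-1] + seglen[1:])
    kappa = np.empty(len(skeleton))
    kappa[1:-1] = turn / ds
    kappa[0] = kappa[1]
    kappa[-1] = kappa[-2]
    return kappa


def basic_features(
    trajectories_by_well: Mapping[str, Sequence],
    fps: float = 25.0,
) -> pd.DataFrame:
    """Exemplar behavioural features per well.

    * ``midbody_speed``: median centroid speed of the middle third of
      skeleton points, px/s.
    * ``tail_curvature``: median absolute signed curvature over the tail
      third of points, 1/px.
    """
    if not trajectories_by_well:
        raise ValueError("no trajectories given")
    rows = {}
    for well, trajectories in trajectories_by_well.items():
        speeds, curvs = [], []
        for tr in trajectories:
            entries = tr.entries
            if len(entries) < 2:
                continue
            n = entries[0].skeleton.shape[0]
            third = max(n // 3, 1)
            mid = slice(third, 2 * third)
            tail = slice(n - third, n)
            cents = np.array([e.skeleton[mid].mean(axis=0) for e in entries])
            frames = np.array([e.frame for e in entries], dtype=float)
            step = np.linalg.norm(np.diff(cents, axis=0), axis=1)
            dt = np.diff(frames) / fps
            speeds.extend(step / dt)
            for e in entries:
                curvs.extend(np.abs(_signed_curvature(e.skeleton)[tail]))
        if not speeds:
            raise ValueError(f"well {well!r} has no trajectory with >= 2 frames")
        rows[well] = {
            "midbody_speed": float(np.median(speeds)),
            "tail_curvature": float(np.median(curvs)),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def feature_correlations(
    table_a: pd.DataFrame, table_b: pd.DataFrame, min_wells: int = 3
) -> pd.Series:
    """Pearson r per shared feature over matched wells (pairwise-complete).

    Features with fewer than ``min_wells`` complete pairs come back as NaN.
    """
    features = [f for f in feature_columns(table_a) if f in feature_columns(table_b)]
    wells = table_a.index.intersection(table_b.index)
    out = {}
    for f in features:
        a = table_a.loc[wells, f].astype(float)
        b = table_b.loc[wells, f].astype(float)
        ok = a.notna() & b.notna()
        if ok.sum() < min_wells:
            out[f] = np.nan
            continue
        av = a[ok].to_numpy()
        bv = b[ok].to_numpy()
        sa, sb = av.std(), bv.std()
        if sa == 0 or sb == 0:
            out[f] = np.nan
            continue
        out[f] = float(np.corrcoef(av, bv)[0, 1])
    return pd.Series(out, name="pearson_r")


def modal_correlation(r_values, bin_width: float = 0.05) -> float:
    """Histogram mode of the correlation coefficients (bin centre of the
    fullest fixed-width bin over [-1, 1])."""
    r = np.asarray(r_values, dtype=float)
    r = r[np.isfinite(r)]
    if r.size == 0:
        raise ValueError("no finite correlation values")
    edges = np.arange(-1.0, 1.0 + bin_width, bin_width)
    counts, _ = np.histogram(r, bins=edges)
    k = int(np.argmax(counts))
    return float(0.5 * (edges[k] + edges[k + 1]))


def feature_f_statistic(table: pd.DataFrame, group_labels) -> pd.Series:
    """One-way ANOVA F (between/within mean-square ratio) per feature.

    Zero between-group variability gives F = 0; zero within-group variance
    with distinct means is reported as +inf.
    """
    labels = np.asarray(group_labels)
    if labels.shape[0] != len(table):
        raise ValueError("group labels must align with table rows")
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    out = {}
    for f in feature_columns(table):
        y = table[f].astype(float).to_numpy()
        ok = np.isfinite(y)
        yv, lv = y[ok], labels[ok]
        grand = yv.mean()
        ss_between = 0.0
        ss_within = 0.0
        k = 0
        for gname in groups:
            yg = yv[lv == gname]
            if len(yg) < 2:
                raise ValueError(f"group {gname!r} needs >= 2 wells")
            k += 1
            ss_between += len(yg) * (yg.mean() - grand) ** 2
            ss_within += float(np.sum((yg - yg.mean()) ** 2))
        ms_between = ss_between / (k - 1)
        ms_within = ss_within / (len(yv) - k)
        if ms_between == 0:
            out[f] = 0.0
        elif ms_within == 0:
            out[f] = np.inf
        else:
            out[f] = ms_between / ms_within
    return pd.Series(out, name="f_statistic")


def hedges_d(treated, control) -> float:
    """Standardized mean difference with the small-sample correction
    ``J = 1 - 3 / (4 (n_t + n_c) - 9)`` applied to Cohen's d."""
    t = np.asarray(treated, dtype=float)
    c = np.asarray(control, dtype=float)
    nt, nc = len(t), len(c)
    if nt < 2 or nc < 2:
        raise ValueError("both samples need at least 2 values")
    s_pooled = np.sqrt(
        ((nt - 1) * t.var(ddof=1) + (nc - 1) * c.var(ddof=1)) / (nt + nc - 2)
    )
    if s_pooled == 0:
        raise ValueError("zero pooled variance: effect size undefined")
    j = 1.0 - 3.0 / (4.0 * (nt + nc) - 9.0)
    return float((t.mean() - c.mean()) / s_pooled * j)


def mean_abs_effect(
    table: pd.DataFrame,
    drug: str,
    features: Optional[Sequence[str]] = None,
) -> pd.Series:
    """Mean absolute Hedge's d per feature for one drug.

    For each dose of the drug, |d| is computed against the pooled control
    wells, then averaged across doses.
    """
    if "is_control" not in table.columns:
        raise ValueError("table needs an is_control metadata column")
    controls = table[table["is_control"].astype(bool)]
    if len(controls) < 2:
        raise ValueError("need at least 2 control wells")
    treated = table[(table["drug"] == drug) & (~table["is_control"].astype(bool))]
    if treated.empty:
        raise ValueError(f"no treated wells for drug {drug!r}")
    if features is None:
        features = feature_columns(table)
    doses = sorted(pd.unique(treated["dose"]))
    out = {}
    for f in features:
        vals = []
        for dose in doses:
            tv = treated.loc[treated["dose"] == dose, f].dropna().to_numpy()
            cv = controls[f].dropna().to_numpy()
            if len(tv) < 2 or len(cv) < 2:
                continue
            try:
                vals.append(abs(hedges_d(tv, cv)))
            except ValueError:
                continue
        out[f] = float(np.mean(vals)) if vals else np.nan
    return pd.Series(out, name=f"mean_abs_hedges_d[{drug}]")
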