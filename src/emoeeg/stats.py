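"""Severity statistics: PANSS correlation/regression and group t tests.

The clinical question is whether entropy features of emotion-evoked EEG
track symptom severity.  Severity is measured by the PANSS (Positive and
Negative Syndrome Scale; positive, negative and general-psychopathology
subscales summing to the total score — totals near 75 mark moderate,
near 95 marked illness).  Two analyses are provided:

* Pearson correlation (with simple linear regression) of each feature
  cell against patients' PANSS totals, over the 5 bands × 3 emotions ×
  3 sections grid of one electrode/method;
* pooled-variance independent-samples t tests between the moderate and
  marked groups per cell, computable either from raw feature vectors or
  from published summary statistics (mean, SD, n) alone — the two routes
  agree algebraically.

No multiple-testing correction is applied by default; the grids can
optionally append Benjamini–Hochberg adjusted p values, clearly labelled
as an extra.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import FeatureTable
from .preprocess import EMOTIONS

__all__ = [
    "GROUPS",
    "SubjectMetadata",
    "StatResult",
    "significance_stars",
    "pearson_with_p",
    "simple_regression",
    "t_independent",
    "t_from_summary",
    "correlation_grid",
    "ttest_grid",
]

GROUPS = ("normal", "moderately_ill", "markedly_ill")
PATIENT_GROUPS = ("moderately_ill", "markedly_ill")


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class SubjectMetadata:
    """Group membership and PANSS scores of one subject."""

    subject_id: str
    group: Literal["normal", "moderately_ill", "markedly_ill"]
    panss_positive: float = 0.0
    panss_negative: float = 0.0
    panss_global: float = 0.0
    panss_total: float = 0.0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise StatsError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        for name in ("panss_positive", "panss_negative", "panss_global", "panss_total"):
            if getattr(self, name) < 0:
                raise StatsError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class StatResult:
    """One statistic with its two-sided p value and degrees of freedom."""

    statistic: str           # "pearson_r" | "t" | "slope"
    value: float
    p: float
    df: int
    cell: tuple = ()
    extras: dict = field(default_factory=dict, repr=False)

    @property
    def stars(self) -> str:
        return significance_stars(self.p)


def significance_stars(p: float) -> str:
    """The three conventional significance markers: * .05, ** .01, *** .001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError(f"inputs must be equal-length 1-D sequences, got {x.shape}, {y.shape}")
    if x.size < 3:
        raise StatsError(f"need at least 3 paired observations, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise StatsError("paired inputs contain non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatsError("correlation undefined for a constant input")
    return x, y


def pearson_with_p(x: Sequence[float], y: Sequence[float], cell: tuple = ()) -> StatResult:
    """Pearson product-moment r with the two-sided p from the t transform
    (df = n − 2)."""
    x, y = _paired(x, y)
    res = sps.pearsonr(x, y)
    return StatResult("pearson_r", float(res.statistic), float(res.pvalue), x.size - 2, cell)


def simple_regression(x: Sequence[float], y: Sequence[float], cell: tuple = ()) -> StatResult:
    """Least-squares regression y = a + b·x; the slope's two-sided p value
    equals the Pearson p for the same pair."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if np.ptp(y) == 0:
        # degenerate but well-defined: a flat response has slope 0
        if x.shape != y.shape or x.size < 3 or np.ptp(x) == 0:
            raise StatsError("regression needs >= 3 points with nonconstant x")
        return StatResult(
            "slope", 0.0, 1.0, x.size - 2, cell, extras={"intercept": float(y[0]), "r": 0.0}
        )
    x, y = _paired(x, y)
    res = sps.linregress(x, y)
    return StatResult(
        "slope",
        float(res.slope),
        float(res.pvalue),
        x.size - 2,
        cell,
        extras={"intercept": float(res.intercept), "r": float(res.rvalue)},
    )


def t_independent(
    group_a: Sequence[float],
    group_b: Sequence[float],
    pooled: bool = True,
    cell: tuple = (),
) -> StatResult:
    """Two-sample t test, pooled-variance (equal variances assumed) by
    default; ``pooled=False`` gives the Welch variant.

    Degenerate inputs with zero pooled variance return t = 0, p = 1 when
    the means agree and signal a divergent statistic (t = ±inf, p = 0)
    when they do not.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise StatsError("each group needs at least 2 observations")
    df = a.size + b.size - 2 if pooled else None
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        dfi = a.size + b.size - 2
        if a.mean() == b.mean():
            return StatResult("t", 0.0, 1.0, dfi, cell)
        return StatResult(
            "t", math.copysign(math.inf, a.mean() - b.mean()), 0.0, dfi, cell
        )
    res = sps.ttest_ind(a, b, equal_var=pooled)
    dfi = int(round(res.df)) if df is None else df
    return StatResult(
        "t",
        float(res.statistic),
        float(res.pvalue),
        dfi,
        cell,
        extras={
            "mean_a": float(a.mean()),
            "mean_b": float(b.mean()),
            "sd_a": float(a.std(ddof=1)),
            "sd_b": float(b.std(ddof=1)),
            "n_a": int(a.size),
            "n_b": int(b.size),
        },
    )


def t_from_summary(
    mean_a: float,
    sd_a: float,
    n_a: int,
    mean_b: float,
    sd_b: float,
    n_b: int,
    cell: tuple = (),
) -> StatResult:
    """Pooled-variance two-sample t from summary statistics only.

    Algebraically identical to :func:`t_independent` applied to any raw
    data with exactly these means, SDs and sizes — which is what makes
    published group summaries re-analysable without the raw recordings.
    """
    if n_a < 2 or n_b < 2:
        raise StatsError("each group needs n >= 2")
    if sd_a < 0 or sd_b < 0:
        raise StatsError("standard deviations must be nonnegative")
    df = n_a + n_b - 2
    sp2 = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df
    if sp2 == 0:
        if mean_a == mean_b:
            return StatResult("t", 0.0, 1.0, df, cell)
        return StatResult("t", math.copysign(math.inf, mean_a - mean_b), 0.0, df, cell)
    t = (mean_a - mean_b) / math.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    p = 2.0 * sps.t.sf(abs(t), df)
    return StatResult(
        "t",
        t,
        p,
        df,
        cell,
        extras={
            "mean_a": mean_a, "sd_a": sd_a, "n_a": n_a,
            "mean_b": mean_b, "sd_b": sd_b, "n_b": n_b,
        },
    )


def _patient_metadata(
    metadata: Iterable[SubjectMetadata], subjects: Sequence[str]
) -> pd.DataFrame:
    meta = {m.subject_id: m for m in metadata}
    missing = [s for s in subjects if s not in meta]
    if missing:
        raise StatsError(f"metadata missing for subjects: {missing}")
    rows = []
    for s in subjects:
        m = meta[s]
        if m.group in PATIENT_GROUPS:
            rows.append((s, m.group, m.panss_total))
    if not rows:
        raise StatsError("no patient-group subjects in the table")
    return pd.DataFrame(rows, columns=["subject_id", "group", "panss_total"]).set_index(
        "subject_id"
    )


def correlation_grid(
    table: FeatureTable,
    metadata: Iterable[SubjectMetadata],
    electrode: str = "Fz",
    method: str = "ApEn",
    emotions: Sequence[str] = EMOTIONS,
    bands: Sequence[str] | None = None,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Feature-vs-PANSS-total Pearson correlations over the cell grid.

    Patients only (the control group has no PANSS scores).  Returns one
    row per band × emotion × section with columns ``r``, ``p`` and the
    conventional significance stars; ``bh_adjust`` appends a
    Benjamini–Hochberg adjusted p column (an extra beyond the modelled
    protocol, which reports unadjusted p values).
    """
    patients = _patient_metadata(metadata, table.subjects)
    rows = []
    for emotion in emotions:
        cell = table.select_cell(electrode, method, emotion)
        cell = cell.loc[patients.index]
        for band, section in cell.columns:
            if bands is not None and band not in bands:
                continue
            res = pearson_with_p(
                cell[(band, section)].to_numpy(),
                patients["panss_total"].to_numpy(),
                cell=(band, emotion, section),
            )
            rows.append(
                {
                    "band": band, "emotion": emotion, "section": section,
                    "r": res.value, "p": res.p, "stars": res.stars,
                }
            )
    frame = pd.DataFrame(rows).set_index(["band", "emotion", "section"]).sort_index()
    if bh_adjust:
        frame["p_bh"] = sps.false_discovery_control(frame["p"].to_numpy(), method="bh")
    return frame


def ttest_grid(
    table: FeatureTable,
    metadata: Iterable[SubjectMetadata],
    electrode: str = "Fz",
    method: str = "ApEn",
    emotions: Sequence[str] = EMOTIONS,
    bands: Sequence[str] = ("beta1", "beta2", "beta3"),
    pooled: bool = True,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Moderate-vs-marked group t tests per band × emotion × section cell.

    Returns group means/SDs, the pooled-variance t (moderate minus
    marked), its two-sided p and significance stars — the β-band grid by
    default (27 cells).
    """
    patients = _patient_metadata(metadata, table.subjects)
    mod_ids = patients.index[patients["group"] == "moderately_ill"]
    mark_ids = patients.index[patients["group"] == "markedly_ill"]
    if len(mod_ids) < 2 or len(mark_ids) < 2:
        raise StatsError("both patient groups need at least 2 subjects")
    rows = []
    for emotion in emotions:
        cell = table.select_cell(electrode, method, emotion)
        for band, section in cell.columns:
            if band not in bands:
                continue
            a = cell.loc[mod_ids, (band, section)].to_numpy()
            b = cell.loc[mark_ids, (band, section)].to_numpy()
            res = t_independent(a, b, pooled=pooled, cell=(band, emotion, section))
            rows.append(
                {
                    "band": band, "emotion": emotion, "section": section,
                    "mean_moderate": a.mean(), "sd_moderate": a.std(ddof=1),
                    "mean_marked": b.mean(), "sd_marked": b.std(ddof=1),
                    "t": res.value, "p": res.p, "stars": res.stars,
                }
            )
    frame = pd.DataFrame(rows).set_index(["band", "emotion", "section"]).sort_index()
    if bh_adjust:
        frame["p_bh"] = sps.false_discovery_control(frame["p"].to_numpy(), method="bh")
    return frame
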