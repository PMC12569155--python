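"""FDA/PI fluorescence viability quantification and time-course statistics.

Viability of alginate-encapsulated liver spheroids is quantified from
paired fluorescence images: fluorescein diacetate (FDA) stains
metabolically active (live) cells, propidium iodide (PI) stains
membrane-compromised (dead) cells.  The viability of an image pair is the
intensity ratio

    viability = sum(FDA) / (sum(FDA) + sum(PI))

computed on raw channel sums by default (an optional constant-offset
background subtraction, clipped at zero, is available).  Recovery
time-courses — conditions x timepoints {0, 2, 24, 48, 72, 96} h x
replicates — are compared with a two-way ANOVA (condition, timepoint,
interaction) after a Shapiro–Wilk residual-normality check, followed by
Tukey-adjusted pairwise condition comparisons.

Note the ratio is invariant under a common rescaling of both channels but
not under a change to one exposure only; the study's FDA and PI exposures
differ (100 vs 800 ms) and are deliberately not cross-normalised here — an
optional ``pi_scale`` correction factor is exposed for users who need one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "FluorescencePair",
    "ViabilityRecord",
    "TimecourseDataset",
    "TimecourseStats",
    "sum_intensity",
    "viability_ratio",
    "quantify_pair",
    "viability_timecourse_stats",
    "recovery_trajectory",
]


@dataclass(frozen=True)
class FluorescencePair:
    """Paired FDA/PI images of the same field of view."""

    fda_image: np.ndarray
    pi_image: np.ndarray
    condition: str = ""
    timepoint_h: float = 0.0
    replicate: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        fda = np.asarray(self.fda_image)
        pi = np.asarray(self.pi_image)
        object.__setattr__(self, "fda_image", fda)
        object.__setattr__(self, "pi_image", pi)
        if fda.shape != pi.shape:
            raise ValueError("FDA and PI images must share a shape")
        if fda.ndim != 2:
            raise ValueError("images must be 2-D")
        if np.any(fda < 0) or np.any(pi < 0):
            raise ValueError("image intensities must be non-negative")


def sum_intensity(
    image: np.ndarray, background_mode: str = "none", background: float = 0.0
) -> float:
    """Total pixel intensity with optional constant background handling.

    ``background_mode="none"`` sums the raw pixels; ``"constant"``
    subtracts a constant offset per pixel, clips at zero, then sums.
    """
    img = np.asarray(image, dtype=float)
    if np.any(img < 0):
        raise ValueError("image intensities must be non-negative")
    if background_mode == "none":
        return float(img.sum())
    if background_mode == "constant":
        return float(np.clip(img - background, 0.0, None).sum())
    raise ValueError(f"unknown background_mode {background_mode!r}")


def viability_ratio(fda_sum: float, pi_sum: float) -> float:
    """Viability fraction ``fda / (fda + pi)`` of channel sum intensities."""
    if fda_sum < 0 or pi_sum < 0:
        raise ValueError("channel sums must be non-negative")
    total = fda_sum + pi_sum
    if total == 0:
        raise ValueError("viability undefined: both channel sums are zero")
    return fda_sum / total


@dataclass(frozen=True)
class ViabilityRecord:
    fda_sum: float
    pi_sum: float
    viability: float
    condition: str = ""
    timepoint_h: float = 0.0
    replicate: int = 0


def quantify_pair(
    pair: FluorescencePair, background_mode: str = "none", background: float = 0.0
) -> ViabilityRecord:
    """Channel sums and viability ratio for one image pair."""
    fda = sum_intensity(pair.fda_image, background_mode, background)
    pi = sum_intensity(pair.pi_image, background_mode, background)
    return ViabilityRecord(
        fda_sum=fda,
        pi_sum=pi,
        viability=viability_ratio(fda, pi),
        condition=pair.condition,
        timepoint_h=pair.timepoint_h,
        replicate=pair.replicate,
    )


class TimecourseDataset:
    """Condition x timepoint x replicate measurements (viability or counts).

    Wraps a DataFrame with columns ``condition``, ``timepoint_h``,
    ``replicate`` and ``value``.  The same container serves viability
    fractions and viable-cell-number counts.
    """

    REQUIRED = ("condition", "timepoint_h", "replicate", "value")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise ValueError(f"dataset missing columns: {missing}")
        if len(frame) == 0:
            raise ValueError("dataset is empty")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: list[ViabilityRecord]) -> "TimecourseDataset":
        return cls(
            pd.DataFrame(
                {
                    "condition": [r.condition for r in records],
                    "timepoint_h": [r.timepoint_h for r in records],
                    "replicate": [r.replicate for r in records],
                    "value": [r.viability for r in records],
                }
            )
        )

    @property
    def conditions(self) -> list[str]:
        return sorted(self.frame["condition"].unique())

    @property
    def timepoints(self) -> list[float]:
        return sorted(self.frame["timepoint_h"].unique())

    def is_balanced(self) -> bool:
        counts = self.frame.groupby(["condition", "timepoint_h"]).size()
        full = len(self.conditions) * len(self.timepoints)
        return counts.size == full and counts.nunique() == 1


@dataclass(frozen=True)
class TimecourseStats:
    """Two-way ANOVA report for a recovery time-course."""

    shapiro_w: float
    shapiro_p: float
    anova_table: pd.DataFrame
    condition_p: float
    timepoint_p: float
    interaction_p: float | None
    pairwise_conditions: pd.DataFrame


def viability_timecourse_stats(
    dataset: TimecourseDataset,
    include_interaction: bool = True,
    allow_unbalanced: bool = False,
    alpha: float = 0.05,
) -> TimecourseStats:
    """Two-way ANOVA over condition and timepoint with Tukey follow-up.

    Residual normality is reported with a Shapiro–Wilk test on the fitted
    model's residuals.  Pairwise condition comparisons pool across
    timepoints with family-wise (Tukey HSD) adjustment, mirroring a
    multiple-comparison-of-means follow-up on the condition factor.
    """
    df = dataset.frame
    if len(dataset.conditions) < 2 or len(dataset.timepoints) < 2:
        raise ValueError("need at least 2 conditions and 2 timepoints")
    cell_counts = df.groupby(["condition", "timepoint_h"]).size()
    if (cell_counts < 2).any():
        raise ValueError("each condition x timepoint cell needs >= 2 replicates")
    if not dataset.is_balanced() and not allow_unbalanced:
        raise ValueError(
            "unbalanced layout; pass allow_unbalanced=True to proceed"
        )
    formula = (
        "value ~ C(condition) * C(timepoint_h)"
        if include_interaction
        else "value ~ C(condition) + C(timepoint_h)"
    )
    model = ols(formula, data=df).fit()
    resid = model.resid.to_numpy()
    if np.allclose(resid, 0.0):
        # all-identical replicates: normality test undefined
        shapiro_w, shapiro_p = float("nan"), float("nan")
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            shapiro_w, shapiro_p = sps.shapiro(resid)
    table = sm.stats.anova_lm(model, typ=2)

    def _p(row: str) -> float:
        p = float(table.loc[row, "PR(>F)"])
        return 1.0 if np.isnan(p) else p

    cond_p = _p("C(condition)")
    time_p = _p("C(timepoint_h)")
    inter_p = _p("C(condition):C(timepoint_h)") if include_interaction else None
    tukey = pairwise_tukeyhsd(
        df["value"].to_numpy(), df["condition"].to_numpy(), alpha=alpha
    )
    pairwise = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    return TimecourseStats(
        shapiro_w=float(shapiro_w),
        shapiro_p=float(shapiro_p),
        anova_table=table,
        condition_p=cond_p,
        timepoint_p=time_p,
        interaction_p=inter_p,
        pairwise_conditions=pairwise,
    )


def recovery_trajectory(dataset: TimecourseDataset) -> pd.DataFrame:
    """Per-condition mean ± SD value at each timepoint.

    Conditions with no observations at a given timepoint are simply absent
    from the output; conditions empty everywhere trigger a warning when the
    dataset frame lists them categorically.
    """
    df = dataset.frame
    if df["value"].isna().all():
        raise ValueError("dataset has no values")
    present = df.dropna(subset=["value"])
    dropped = set(df["condition"].unique()) - set(present["condition"].unique())
    for cond in sorted(dropped):
        warnings.warn(f"condition {cond!r} has no values and is excluded")
    out = (
        present.groupby(["condition", "timepoint_h"])["value"]
        .agg(mean="mean", sd=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0, n="size")
        .reset_index()
    )
    return out
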