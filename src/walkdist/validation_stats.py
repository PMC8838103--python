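"""Agreement statistics between algorithmic and manual walk distances.

Implements the error metrics used to validate sensor-derived walk
distances against a manual (tape-measure) ground truth:

* percentage error against a fixed protocol distance (400 m walk),
* average absolute error rate
  ``100 · mean(|manual − digital|) / mean(manual)`` (fixed-time walks),
* Bland–Altman bias and 95% limits of agreement with confidence
  intervals,
* ICC(2,1) — two-way random-effects, absolute-agreement, single-measure
  intraclass correlation — with its exact F-based 95% CI.

Differences are taken as ``digital − manual`` throughout, so a negative
bias means the algorithm underestimates the manual distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError


@dataclass
class PairedDistances:
    """Per-subject manual (ground-truth) and digital (algorithm) distances."""

    manual: np.ndarray
    digital: np.ndarray

    def __post_init__(self) -> None:
        self.manual = np.asarray(self.manual, dtype=float)
        self.digital = np.asarray(self.digital, dtype=float)
        if self.manual.shape != self.digital.shape or self.manual.ndim != 1:
            raise ValidationError("manual and digital must be 1-D arrays of equal length")
        if self.n < 1:
            raise ValidationError("at least one subject required")
        if np.any(self.manual <= 0) or np.any(self.digital <= 0):
            raise ValidationError("distances must be positive")

    @property
    def n(self) -> int:
        return self.manual.shape[0]


@dataclass
class BlandAltmanResult:
    bias: float
    loa_lower: float
    loa_upper: float
    sd: float
    bias_ci: tuple[float, float] | None
    loa_lower_ci: tuple[float, float] | None
    loa_upper_ci: tuple[float, float] | None
    n: int


@dataclass
class IccResult:
    icc: float
    ci: tuple[float, float] | None
    n: int
    k: int


@dataclass
class AgreementReport:
    """Full agreement summary for one cohort."""

    n: int
    mean_abs_error: float
    error_rate_pct: float
    bland_altman: BlandAltmanResult
    icc: IccResult

    def to_dict(self) -> dict:
        ba, icc = self.bland_altman, self.icc
        return {
            "n": self.n,
            "mean_abs_error_m": self.mean_abs_error,
            "error_rate_pct": self.error_rate_pct,
            "bias_m": ba.bias,
            "bias_ci_m": list(ba.bias_ci) if ba.bias_ci else None,
            "loa_lower_m": ba.loa_lower,
            "loa_lower_ci_m": list(ba.loa_lower_ci) if ba.loa_lower_ci else None,
            "loa_upper_m": ba.loa_upper,
            "loa_upper_ci_m": list(ba.loa_upper_ci) if ba.loa_upper_ci else None,
            "icc_2_1": None if np.isnan(icc.icc) else icc.icc,
            "icc_ci": list(icc.ci) if icc.ci else None,
        }


def fixed_distance_error_pct(digital, fixed: float) -> tuple[float, float]:
    """Percentage error of per-subject estimates against a fixed distance.

    Returns ``(absolute_rate, signed_rate)``:
    mean of 100·|fixed − d_j|/fixed and mean of 100·(d_j − fixed)/fixed.
    """
    digital = np.asarray(digital, dtype=float)
    if digital.size == 0:
        raise ValidationError("empty input")
    if not fixed > 0:
        raise ValidationError("fixed distance must be positive")
    abs_rate = float(np.mean(np.abs(fixed - digital)) / fixed * 100.0)
    signed_rate = float(np.mean(digital - fixed) / fixed * 100.0)
    return abs_rate, signed_rate


def average_absolute_error_rate(pd_: PairedDistances) -> float:
    """``100 · mean(|manual_j − digital_j|) / mean(manual_j)``."""
    denom = float(np.mean(pd_.manual))
    if denom == 0:
        raise ValidationError("mean manual distance is zero")
    return float(100.0 * np.mean(np.abs(pd_.manual - pd_.digital)) / denom)


def bland_altman(pd_: PairedDistances, agreement_multiplier: float = 1.96) -> BlandAltmanResult:
    """Bland–Altman bias and limits of agreement, differences digital − manual.

    ``LOA = bias ± multiplier·SD`` with the sample SD (n−1). 95% CIs use
    the t distribution: SE(bias) = SD/√n, SE(LOA) = √3·SD/√n. CIs are
    omitted (None) for n < 3.
    """
    if pd_.n < 2:
        raise ValidationError("Bland–Altman needs at least 2 subjects")
    d = pd_.digital - pd_.manual
    n = pd_.n
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    half = agreement_multiplier * sd
    lower, upper = bias - half, bias + half
    if sd == 0:
        warnings.warn("zero variance of differences: LOAs collapse to the bias", stacklevel=2)
    if n >= 3 and sd > 0:
        tcrit = float(stats.t.ppf(0.975, n - 1))
        se_bias = sd / np.sqrt(n)
        se_loa = np.sqrt(3.0) * sd / np.sqrt(n)
        bias_ci = (bias - tcrit * se_bias, bias + tcrit * se_bias)
        lo_ci = (lower - tcrit * se_loa, lower + tcrit * se_loa)
        hi_ci = (upper - tcrit * se_loa, upper + tcrit * se_loa)
    else:
        bias_ci = lo_ci = hi_ci = None
    return BlandAltmanResult(bias, lower, upper, sd, bias_ci, lo_ci, hi_ci, n)


def icc_2_1(ratings: np.ndarray) -> IccResult:
    """ICC(2,1) of a subjects × raters matrix, with exact F-based 95% CI.

    Two-way random effects, absolute agreement, single measure. Raises on
    a constant matrix (zero between-subject variance leaves the
    coefficient undefined).
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2 or ratings.shape[1] < 2:
        raise ValidationError("ratings must be a subjects × raters matrix, k >= 2")
    if np.ptp(ratings) == 0:
        raise ValidationError("constant ratings matrix: ICC undefined")
    n, k = ratings.shape
    df = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "score": ratings.ravel(),
        }
    )
    import pingouin as pg

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = pg.intraclass_corr(
            data=df, targets="subject", raters="rater", ratings="score"
        )
    table = table.set_index("Type")
    # McGraw–Wong "ICC(A,1)" (absolute agreement, single measure) is the
    # classical ICC(2,1); older pingouin releases label it "ICC2"
    label = "ICC(A,1)" if "ICC(A,1)" in table.index else "ICC2"
    row = table.loc[label]
    ci_col = "CI95" if "CI95" in table.columns else "CI95%"
    ci = tuple(float(b) for b in row[ci_col])
    return IccResult(float(row["ICC"]), ci, n, k)


def agreement_report(pd_: PairedDistances) -> AgreementReport:
    """Error rate + Bland–Altman + ICC(2,1) for one manual/digital cohort."""
    rate = average_absolute_error_rate(pd_)
    mae = float(np.mean(np.abs(pd_.manual - pd_.digital)))
    ba = bland_altman(pd_)
    if pd_.n >= 5:
        icc = icc_2_1(np.column_stack([pd_.manual, pd_.digital]))
    else:  # too few subjects for a meaningful ANOVA decomposition
        icc = IccResult(float("nan"), None, pd_.n, 2)
    return AgreementReport(pd_.n, mae, rate, ba, icc)


def bland_altman_plot(pd_: PairedDistances, ax=None):
    """Mean-vs-difference scatter with bias and LOA lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ba = bland_altman(pd_)
    mean = 0.5 * (pd_.manual + pd_.digital)
    diff = pd_.digital - pd_.manual
    ax.scatter(mean, diff, s=18, color="tab:blue", alpha=0.8)
    ax.axhline(ba.bias, color="k", lw=1.2, label=f"bias {ba.bias:.2f} m")
    for y, label in ((ba.loa_upper, "upper LOA"), (ba.loa_lower, "lower LOA")):
        ax.axhline(y, color="k", lw=1, ls="--", label=f"{label} {y:.2f} m")
    ax.set_xlabel("mean of manual and digital distance (m)")
    ax.set_ylabel("digital − manual (m)")
    ax.legend(fontsize=8)
    return ax
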