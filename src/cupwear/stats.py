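"""Method-agreement and error statistics for paired wear measurements.

Implements the statistical toolbox used to validate an imaging-based
wear method against a reference method: Bland–Altman difference
analysis with 95% limits of agreement, a Student-t interval estimate of
the bias, ISO-style repeatability from duplicate measurements, 95%-level
accuracy (systematic plus random error), summary tables over per-cup
results, and creep estimation from unloaded soak-control cups.

Paired measurement tables are plain :class:`pandas.DataFrame` objects
with columns ``unit_id``, ``method``, ``value`` and (for repeated
measurements) ``replicate``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AgreementSummary",
    "InsufficientDataError",
    "bland_altman",
    "bias_interval",
    "repeatability_iso",
    "accuracy_95",
    "summarize_wear_table",
    "estimate_creep",
    "bland_altman_plot",
]


class InsufficientDataError(ValueError):
    """Raised when fewer observations are supplied than the statistic needs."""


@dataclass(frozen=True)
class AgreementSummary:
    """Agreement of two methods over paired measurements (one unit system).

    ``loa_low``/``loa_high`` are the 95% limits of agreement
    (mean difference +/- 1.96 SD); the bias confidence interval uses the
    Student t distribution. ``repeatability`` and ``accuracy`` are
    filled only by the dedicated estimators.
    """

    mean_difference: float
    sd_difference: float
    loa_low: float
    loa_high: float
    bias_ci_low: float
    bias_ci_high: float
    n: int
    repeatability: float | None = None
    accuracy: float | None = None

    def __post_init__(self) -> None:
        if not (self.loa_low - 1e-12 <= self.mean_difference <= self.loa_high + 1e-12):
            raise ValueError("limits of agreement must bracket the mean difference")
        if not (
            self.bias_ci_low - 1e-12 <= self.mean_difference <= self.bias_ci_high + 1e-12
        ):
            raise ValueError("bias CI must contain the mean difference")


def _differences(method_a, method_b=None) -> np.ndarray:
    a = np.asarray(method_a, dtype=float)
    if method_b is None:
        d = a
    else:
        b = np.asarray(method_b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("paired measurement arrays must have equal length")
        d = a - b
    if not np.all(np.isfinite(d)):
        raise ValueError("measurements must be finite")
    return d


def bias_interval(
    differences, confidence: float = 0.95
) -> tuple[float, float]:
    """Student-t confidence interval for the mean difference (the bias).

    Returns ``mean +/- t_{(1+confidence)/2, n-1} * SD / sqrt(n)`` with
    the sample (n-1) standard deviation.
    """
    d = _differences(differences)
    n = d.size
    if n < 2:
        raise InsufficientDataError("bias interval needs at least 2 differences")
    if not 0 < confidence < 1:
        raise ValueError("confidence must lie in (0, 1)")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    half = sps.t.ppf((1 + confidence) / 2, n - 1) * sd / np.sqrt(n)
    return mean - half, mean + half


def bland_altman(
    method_a, method_b=None, confidence: float = 0.95
) -> AgreementSummary:
    """Bland–Altman analysis of paired measurements.

    Pass two equal-length arrays of paired values, or a single array of
    precomputed differences. Limits of agreement are
    ``mean difference +/- 1.96 SD`` (sample SD, n-1 denominator); the
    bias interval is the t-based CI of the mean difference.
    """
    d = _differences(method_a, method_b)
    n = d.size
    if n < 2:
        raise InsufficientDataError("Bland-Altman analysis needs at least 2 pairs")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = bias_interval(d, confidence)
    return AgreementSummary(
        mean_difference=mean,
        sd_difference=sd,
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
        bias_ci_low=lo,
        bias_ci_high=hi,
        n=n,
    )


def repeatability_iso(
    replicate_pairs, convention: str = "duplicate"
) -> float:
    """Repeatability at the 95% level from duplicate measurements.

    ``replicate_pairs`` is an ``(n, 2)`` array-like: each unit measured
    twice under stipulated conditions (for the phantom study, two scans
    in different positions). The within-unit standard deviation is
    estimated from the duplicate differences ``d_i`` as
    ``s_w = sqrt(sum d_i^2 / (2 n))`` and the repeatability is
    ``1.96 * sqrt(2) * s_w`` (~ ``2.77 s_w``), the largest absolute
    difference expected between two repeated measurements in 95% of
    cases. ``convention="sd_of_differences"`` instead returns
    ``1.96 * SD(d)`` with the sample SD of the signed differences.
    """
    pairs = np.asarray(replicate_pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("expected an (n, 2) array of duplicate measurements")
    if not np.all(np.isfinite(pairs)):
        raise ValueError("replicate measurements must be finite")
    n = pairs.shape[0]
    if n < 2:
        raise InsufficientDataError("repeatability needs at least 2 units")
    d = pairs[:, 0] - pairs[:, 1]
    if convention == "duplicate":
        s_w = np.sqrt(np.sum(d**2) / (2.0 * n))
        return float(1.96 * np.sqrt(2.0) * s_w)
    if convention == "sd_of_differences":
        return float(1.96 * d.std(ddof=1))
    raise ValueError(f"unknown repeatability convention {convention!r}")


def accuracy_95(differences_vs_reference) -> float:
    """Accuracy at the 95% level against a reference method.

    Combines systematic and random error as
    ``|mean(d)| + 1.96 * SD(d)`` over the differences ``d`` between the
    method under test and the reference. With a zero random component
    this reduces to the absolute bias.
    """
    d = _differences(differences_vs_reference)
    if d.size < 2:
        raise InsufficientDataError("accuracy needs at least 2 differences")
    return float(abs(d.mean()) + 1.96 * d.std(ddof=1))


def summarize_wear_table(
    per_cup_results: pd.DataFrame,
    method_a: str = "CT",
    method_b: str = "CMM",
) -> pd.DataFrame:
    """Per-cup mean (SD) wear by method, difference column and column means.

    ``per_cup_results`` columns: ``unit_id``, ``method``, ``value`` —
    one row per replicate measurement (a single row per cup and method
    is treated as one replicate). Returns a frame indexed by ``unit_id``
    with columns ``<a>_mean, <a>_sd, <b>_mean, <b>_sd, difference`` and
    a final ``"all"`` row holding the column means (the difference cell
    of that row is the mean difference between the methods).
    """
    df = per_cup_results
    required = {"unit_id", "method", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"per-cup table needs columns {sorted(required)}")
    methods = set(df["method"].unique())
    if not {method_a, method_b}.issubset(methods):
        raise ValueError(
            f"table must contain both methods {method_a!r} and {method_b!r}"
        )
    g = df.groupby(["unit_id", "method"])["value"]
    means = g.mean().unstack("method")
    sds = g.std(ddof=1).unstack("method")
    out = pd.DataFrame(
        {
            f"{method_a}_mean": means[method_a],
            f"{method_a}_sd": sds[method_a],
            f"{method_b}_mean": means[method_b],
            f"{method_b}_sd": sds[method_b],
        }
    )
    out["difference"] = out[f"{method_a}_mean"] - out[f"{method_b}_mean"]
    all_row = out.mean(axis=0)
    out.loc["all"] = all_row
    return out


def estimate_creep(control_penetrations) -> float:
    """Mean penetration of the soak-control cups (mm).

    Soak controls are immersed but never loaded, so any apparent
    penetration reflects creep (plus fluid absorption), not wear; their
    average estimates the creep contribution in the wear readings.
    """
    d = np.asarray(control_penetrations, dtype=float)
    if d.size < 1:
        raise InsufficientDataError("creep estimate needs at least 1 control cup")
    if not np.all(np.isfinite(d)):
        raise ValueError("control penetrations must be finite")
    return float(d.mean())


def bland_altman_plot(method_a, method_b, ax=None, units: str = "mm"):
    """Difference-against-mean plot with bias and 95% limit lines.

    Returns the matplotlib Axes. Import of matplotlib is deferred so the
    numerical API stays usable in headless batch runs.
    """
    import matplotlib.pyplot as plt

    a = np.asarray(method_a, float)
    b = np.asarray(method_b, float)
    summary = bland_altman(a, b)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((a + b) / 2.0, a - b, s=18, color="tab:blue", zorder=3)
    ax.axhline(summary.mean_difference, color="k", lw=1, label="mean difference")
    for y in (summary.loa_low, summary.loa_high):
        ax.axhline(y, color="k", lw=1, ls="--")
    ax.set_xlabel(f"mean of methods ({units})")
    ax.set_ylabel(f"difference ({units})")
    ax.legend(loc="best", frameon=False)
    return ax
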