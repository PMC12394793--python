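"""MS1 stability quantification: XIC extraction, peak-area integration,
normalization to control, and group significance testing.

The assay this reproduces spikes lipidated peptides into a digest before or
after a chemical treatment, extracts the precursor's MS1 ion chromatogram,
integrates the elution peak, normalizes each replicate area to the mean of
the control (spike-after) replicates, and tests conditions against control
with an unpaired equal-variance t-test (two groups) or one-way ANOVA with
Tukey's HSD (several groups).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .spectra import Spectrum

__all__ = [
    "XicTrace",
    "StabilityResult",
    "extract_xic",
    "integrate_peak",
    "normalize_and_test",
    "significance_label",
]


@dataclass
class XicTrace:
    """Extracted ion chromatogram for one target m/z window."""

    target_mz: float
    tol_ppm: float
    times: np.ndarray       # seconds, strictly increasing
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("time and intensity arrays differ in length")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("retention times must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("negative XIC intensity")


@dataclass
class StabilityResult:
    conditions: list[str]
    control: str
    areas: dict[str, np.ndarray]
    normalized: dict[str, np.ndarray]
    test: str                           # "t_test" | "anova_tukey"
    statistic: float                    # t or F statistic
    p_value: float                      # global test p (t-test or ANOVA F-test)
    adjusted_p: dict[tuple[str, str], float]
    labels: dict[tuple[str, str], str]  # ns / * / ** / ***


def extract_xic(
    ms1_spectra: Sequence[Spectrum],
    target_mz: float,
    tol_ppm: float = 10.0,
    rt_window: tuple[float, float] | None = None,
) -> XicTrace:
    """Per-MS1-scan summed intensity within ±tol_ppm of ``target_mz``.

    Scans without a matching peak contribute zero.  ``rt_window`` restricts
    to a retention-time interval (seconds).
    """
    tol = target_mz * tol_ppm * 1e-6
    times: list[float] = []
    intensities: list[float] = []
    for s in ms1_spectra:
        if s.ms_level != 1 or s.retention_time is None:
            continue
        if rt_window and not (rt_window[0] <= s.retention_time <= rt_window[1]):
            continue
        lo = int(np.searchsorted(s.mz, target_mz - tol, side="left"))
        hi = int(np.searchsorted(s.mz, target_mz + tol, side="right"))
        times.append(s.retention_time)
        intensities.append(float(s.intensity[lo:hi].sum()))
    if not times:
        raise ValueError(
            f"no MS1 scans in retention-time window {rt_window!r} for m/z {target_mz}"
        )
    order = np.argsort(times)
    trace = XicTrace(target_mz, tol_ppm,
                     np.asarray(times)[order], np.asarray(intensities)[order])
    if not trace.intensities.any():
        warnings.warn(f"all-zero XIC for m/z {target_mz} (±{tol_ppm} ppm)")
    return trace


def integrate_peak(trace: XicTrace, boundary_fraction: float = 0.05) -> float:
    """Trapezoidal area of the apex-containing elution peak.

    Peak boundaries are the widest contiguous region around the apex whose
    intensity exceeds ``boundary_fraction`` x apex.  Units: intensity x
    seconds.  An all-zero trace integrates to 0.
    """
    if trace.times.size < 3:
        raise ValueError("peak integration requires at least 3 points")
    y = trace.intensities
    apex = int(np.argmax(y))
    if y[apex] <= 0:
        return 0.0
    threshold = boundary_fraction * y[apex]
    lo = apex
    while lo > 0 and y[lo - 1] > threshold:
        lo -= 1
    hi = apex
    while hi < y.size - 1 and y[hi + 1] > threshold:
        hi += 1
    # include the sub-threshold crossing points so the peak tails are kept
    lo = max(lo - 1, 0)
    hi = min(hi + 1, y.size - 1)
    return float(np.trapezoid(y[lo:hi + 1], trace.times[lo:hi + 1]))


def significance_label(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def normalize_and_test(
    areas: Mapping[str, Sequence[float]],
    control_label: str,
    design: str | None = None,
    equal_var: bool = True,
    alpha: float = 0.05,
) -> StabilityResult:
    """Normalize replicate areas to the control mean and test group effects.

    design="two_group": unpaired two-sided t-test (equal-variance by
    default; ``equal_var=False`` switches to Welch).  design="multi_group":
    one-way ANOVA followed by Tukey's HSD adjusted pairwise p-values
    (studentized-range distribution on the pooled residual variance, all
    pairs).  When ``design`` is None it is inferred from the number of
    conditions.
    """
    if control_label not in areas:
        raise ValueError(f"control condition {control_label!r} not present")
    groups = {label: np.asarray(vals, dtype=float) for label, vals in areas.items()}
    for label, vals in groups.items():
        if vals.size < 2:
            raise ValueError(f"condition {label!r} has fewer than 2 replicates")
    conditions = list(groups)
    if design is None:
        design = "two_group" if len(conditions) == 2 else "multi_group"

    control_mean = float(groups[control_label].mean())
    if control_mean <= 0:
        raise ValueError("control mean area must be positive")
    normalized = {label: vals / control_mean for label, vals in groups.items()}

    adjusted_p: dict[tuple[str, str], float] = {}
    if design == "two_group":
        if len(conditions) != 2:
            raise ValueError("two_group design requires exactly 2 conditions")
        other = next(c for c in conditions if c != control_label)
        stat, p = stats.ttest_ind(
            normalized[other], normalized[control_label], equal_var=equal_var
        )
        adjusted_p[(control_label, other)] = float(p)
        test_name, statistic, p_global = "t_test", float(stat), float(p)
    elif design == "multi_group":
        stat, anova_p = stats.f_oneway(*(normalized[c] for c in conditions))
        ordered = sorted(conditions)
        tukey = stats.tukey_hsd(*(normalized[c] for c in ordered))
        for i, j in itertools.combinations(range(len(ordered)), 2):
            adjusted_p[(ordered[i], ordered[j])] = float(tukey.pvalue[i, j])
        test_name, statistic, p_global = "anova_tukey", float(stat), float(anova_p)
    else:
        raise ValueError(f"unknown design {design!r}")

    labels = {pair: significance_label(p) for pair, p in adjusted_p.items()}
    return StabilityResult(
        conditions=conditions,
        control=control_label,
        areas=groups,
        normalized=normalized,
        test=test_name,
        statistic=statistic,
        p_value=p_global,
        adjusted_p=adjusted_p,
        labels=labels,
    )
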