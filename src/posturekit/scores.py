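"""Cognitive / symptom score construction and the motor outlier screen.

The d2 test of attention yields per-line counts; two summary scores enter
the analysis: the processing-speed count of completed targets and the
concentration capacity (targets identified minus missed and falsely marked
targets). Symptom questionnaires yield per-scale item scores averaged into
one attention-deficit and one hyperactivity mean score per child (lower =
better). Motor target errors are screened for artifacts with a 1.5 x IQR
rule applied per dependent variable and fit dataset; cognitive and symptom
scores are never screened.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import OutlierCapWarning, ParameterError

__all__ = ["D2Counts", "d2_scores", "symptom_scores", "iqr_outlier_filter"]


@dataclass
class D2Counts:
    """Per-line counts from one d2 sheet."""

    targets_identified: np.ndarray
    targets_missed: np.ndarray
    falsely_marked: np.ndarray
    letters_processed: np.ndarray

    def __post_init__(self):
        for name in (
            "targets_identified",
            "targets_missed",
            "falsely_marked",
            "letters_processed",
        ):
            arr = np.asarray(getattr(self, name), dtype=float).reshape(-1)
            if (arr < 0).any():
                raise ParameterError(f"{name} contains negative counts")
            setattr(self, name, arr)
        n = len(self.targets_identified)
        for name in ("targets_missed", "falsely_marked", "letters_processed"):
            if len(getattr(self, name)) != n:
                raise ParameterError("all per-line counts must have equal length")
        if (self.targets_identified > self.letters_processed).any():
            raise ParameterError(
                "targets_identified cannot exceed letters_processed on a line"
            )


def d2_scores(counts: D2Counts) -> tuple:
    """(completed_targets, concentration_capacity); higher = better.

    Completed targets counts every target the child worked through
    (identified + missed), the processing-speed measure; concentration
    capacity subtracts both error types from the identified targets.
    """
    completed = float(counts.targets_identified.sum() + counts.targets_missed.sum())
    concentration = float(
        counts.targets_identified.sum()
        - counts.targets_missed.sum()
        - counts.falsely_marked.sum()
    )
    return completed, concentration


def symptom_scores(item_scores: dict) -> tuple:
    """Mean attention-deficit and hyperactivity scores; lower = better.

    ``item_scores`` maps scale names ('attention_deficit', 'hyperactivity')
    to item-score arrays. Missing items (NaN) are dropped from the mean and
    flagged with a warning; an absent or empty scale is an error.
    """
    means = []
    for scale in ("attention_deficit", "hyperactivity"):
        if scale not in item_scores:
            raise ParameterError(f"missing scale {scale!r}")
        items = np.asarray(item_scores[scale], dtype=float).reshape(-1)
        if len(items) == 0:
            raise ParameterError(f"scale {scale!r} has no items")
        observed = items[np.isfinite(items)]
        if len(observed) == 0:
            raise ParameterError(f"scale {scale!r} has no observed items")
        if len(observed) < len(items):
            warnings.warn(
                f"{scale}: {len(items) - len(observed)} of {len(items)} items "
                "missing; mean taken over observed items",
                UserWarning,
                stacklevel=2,
            )
        means.append(float(observed.mean()))
    return tuple(means)


def iqr_outlier_filter(values, k: float = 1.5, cap: float = 0.05):
    """Mask values outside [Q1 - k*IQR, Q3 + k*IQR]; report removed fraction.

    Returns ``(is_outlier, removed_fraction)``. Quartiles use linear
    interpolation. If more than ``cap`` of the values are masked an
    :class:`OutlierCapWarning` is emitted (the screen is meant to catch
    occasional artifacts, not to trim the distribution). A degenerate IQR of
    zero removes only values different from the common value.
    """
    values = np.asarray(values, dtype=float).reshape(-1)
    if len(values) < 4:
        raise ParameterError("outlier screen needs at least 4 values per group")
    if k < 0:
        raise ParameterError("k must be non-negative")
    q1, q3 = np.quantile(values, [0.25, 0.75])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    is_outlier = (values < lo) | (values > hi)
    removed_fraction = float(is_outlier.mean())
    if removed_fraction > cap:
        warnings.warn(
            f"outlier screen removed {removed_fraction:.1%} of values, above "
            f"the {cap:.0%} cap; inspect the data for systematic artifacts",
            OutlierCapWarning,
            stacklevel=2,
        )
    return is_outlier, removed_fraction
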