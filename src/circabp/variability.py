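"""Fit diagnostics and variability summaries.

Weighted residuals (residuals as a percentage of the observed value)
diagnose model fit; per-subject medians/ranges and coefficients of
variation of ``base`` and ``incr`` across days quantify intra-individual
variability, and the same statistics pooled over all subjects' day-level
estimates quantify inter-individual variability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitting import DayFit, FitCollection, PARAM_NAMES

__all__ = [
    "SubjectSummary",
    "PopulationSummary",
    "weighted_residuals",
    "coefficient_of_variation",
    "summarize_subject",
    "summarize_population",
    "summarize_collection",
]


@dataclass(frozen=True)
class SubjectSummary:
    """Median, range and CVs of one subject's day-level estimates."""

    subject_id: str
    channel: str
    variant: str
    n_days: int
    median: dict[str, float]
    range: dict[str, tuple[float, float]]
    cv_base: float | None
    cv_incr: float | None


@dataclass(frozen=True)
class PopulationSummary:
    """The same statistics pooled over all subjects' day fits."""

    channel: str
    variant: str
    n_days: int
    n_subjects: int
    median: dict[str, float]
    range: dict[str, tuple[float, float]]
    cv_base: float
    cv_incr: float


def weighted_residuals(observed: np.ndarray, predicted: np.ndarray) -> np.ndarray:
    """Element-wise ``100 * (observed - predicted) / observed`` (%)."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have equal length")
    if (observed <= 0).any():
        raise ValueError("observed pressures must be positive")
    return 100.0 * (observed - predicted) / observed


def coefficient_of_variation(values) -> float:
    """Sample standard deviation (n-1 denominator) over the mean, in %."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("CV needs at least 2 values")
    mean = values.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * values.std(ddof=1) / mean)


def _param_matrix(fits: list[DayFit]) -> np.ndarray:
    return np.array([f.params.as_array() for f in fits])


def summarize_subject(fits: list[DayFit]) -> SubjectSummary:
    """Summarise one subject/channel/variant's fitted days; skipped days
    are excluded.  CVs need at least two fitted days and are ``None``
    otherwise."""
    fitted = [f for f in fits if f.fitted]
    if not fitted:
        raise ValueError("no fitted days to summarise")
    keys = {(f.subject_id, f.channel, f.variant) for f in fitted}
    if len(keys) != 1:
        raise ValueError("fits must come from a single subject/channel/variant")
    (subject_id, channel, variant), = keys

    mat = _param_matrix(fitted)
    median = dict(zip(PARAM_NAMES, np.median(mat, axis=0)))
    rng = {n: (float(mat[:, i].min()), float(mat[:, i].max())) for i, n in enumerate(PARAM_NAMES)}
    cv_base = coefficient_of_variation(mat[:, 0]) if len(fitted) >= 2 else None
    cv_incr = None
    if len(fitted) >= 2 and mat[:, 1].mean() != 0:
        cv_incr = coefficient_of_variation(mat[:, 1])
    return SubjectSummary(
        subject_id=subject_id, channel=channel, variant=variant, n_days=len(fitted),
        median=median, range=rng, cv_base=cv_base, cv_incr=cv_incr,
    )


def summarize_population(fits: list[DayFit]) -> PopulationSummary:
    """Pool all subjects' day-level estimates for one channel/variant:
    overall medians, ranges, and inter-individual CVs of base and incr
    computed across every fitted day of every subject."""
    fitted = [f for f in fits if f.fitted]
    subjects = {f.subject_id for f in fitted}
    if len(subjects) < 2:
        raise ValueError("population summary needs at least 2 subjects")
    keys = {(f.channel, f.variant) for f in fitted}
    if len(keys) != 1:
        raise ValueError("fits must share one channel/variant")
    (channel, variant), = keys

    mat = _param_matrix(fitted)
    median = dict(zip(PARAM_NAMES, np.median(mat, axis=0)))
    rng = {n: (float(mat[:, i].min()), float(mat[:, i].max())) for i, n in enumerate(PARAM_NAMES)}
    return PopulationSummary(
        channel=channel, variant=variant, n_days=len(fitted), n_subjects=len(subjects),
        median=median, range=rng,
        cv_base=coefficient_of_variation(mat[:, 0]),
        cv_incr=coefficient_of_variation(mat[:, 1]),
    )


def summarize_collection(
    collection: FitCollection, channel: str
) -> tuple[list[SubjectSummary], PopulationSummary]:
    """Per-subject summaries plus the pooled overall row for one channel."""
    fits = collection.select(channel=channel)
    per_subject = [
        summarize_subject(collection.select(subject_id=s, channel=channel))
        for s in collection.subjects
        if any(f.fitted for f in collection.select(subject_id=s, channel=channel))
    ]
    return per_subject, summarize_population(fits)
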