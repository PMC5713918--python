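"""Targeting-error metrics: per-point 3-D errors, RMSE, cohort summaries, CDFs.

Tracking accuracy is only measurable where internal truth exists — at
imaging instants — so all metrics operate on paired predicted/actual
3-D positions.  The 3-D targeting error is the Euclidean residual;
per-patient performance is its RMSE over imaging points; cohorts are
summarized by the median and interquartile range of per-patient RMSEs
(linear-interpolation quantiles); pooled errors are compared via
empirical CDFs, with the fraction of residuals beyond 6 mm as the tail
criterion of clinical interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Tail threshold of clinical interest for pooled targeting residuals (mm).
TAIL_THRESHOLD_MM = 6.0


def targeting_errors(predicted: np.ndarray, actual: np.ndarray) -> np.ndarray:
    """Per-point 3-D targeting error ||pred_t - actual_t||_2 in mm."""
    predicted = np.atleast_2d(np.asarray(predicted, dtype=float))
    actual = np.atleast_2d(np.asarray(actual, dtype=float))
    if predicted.shape != actual.shape:
        raise ValueError(
            f"shape mismatch: predicted {predicted.shape} vs actual {actual.shape}"
        )
    return np.linalg.norm(predicted - actual, axis=1)


def rmse(errors: np.ndarray) -> float:
    """Root-mean-square of a non-empty error vector."""
    errors = np.asarray(errors, dtype=float).ravel()
    if errors.size == 0:
        raise ValueError("cannot compute RMSE of an empty error vector")
    return float(np.sqrt(np.mean(errors**2)))


def cohort_summary(per_patient_rmse: np.ndarray) -> tuple[float, float]:
    """Median and interquartile range (Q3 - Q1, linear-interpolation quantiles)."""
    v = np.asarray(per_patient_rmse, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("need at least one patient")
    q1, med, q3 = np.percentile(v, [25.0, 50.0, 75.0], method="linear")
    return float(med), float(q3 - q1)


def empirical_cdf(errors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Right-continuous empirical CDF: unique sorted support and P(E <= support)."""
    errors = np.asarray(errors, dtype=float).ravel()
    if errors.size == 0:
        raise ValueError("cannot build a CDF from no errors")
    support, counts = np.unique(errors, return_counts=True)
    return support, np.cumsum(counts) / errors.size


def cdf_at(errors: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Evaluate the empirical CDF of ``errors`` at arbitrary points."""
    errors = np.sort(np.asarray(errors, dtype=float).ravel())
    points = np.asarray(points, dtype=float)
    return np.searchsorted(errors, points, side="right") / errors.size


def tail_fraction(errors: np.ndarray, threshold: float = TAIL_THRESHOLD_MM) -> float:
    """Fraction of targeting residuals strictly beyond ``threshold`` mm."""
    errors = np.asarray(errors, dtype=float).ravel()
    if errors.size == 0:
        raise ValueError("empty error vector")
    return float(np.mean(errors > threshold))


@dataclass
class TrackingReport:
    """Per-point errors plus per-patient and cohort-level summaries."""

    per_point_errors: list  # one error vector (mm) per patient
    per_patient_rmse: np.ndarray
    median_rmse: float
    iqr_rmse: float
    cdf_support: np.ndarray
    cdf_values: np.ndarray
    fraction_beyond_6mm: float

    @classmethod
    def from_errors(cls, per_patient_errors) -> "TrackingReport":
        per_patient_errors = [np.asarray(e, dtype=float).ravel() for e in per_patient_errors]
        rmses = np.asarray([rmse(e) for e in per_patient_errors])
        med, iqr = cohort_summary(rmses)
        pooled = np.concatenate(per_patient_errors)
        support, values = empirical_cdf(pooled)
        return cls(
            per_point_errors=per_patient_errors,
            per_patient_rmse=rmses,
            median_rmse=med,
            iqr_rmse=iqr,
            cdf_support=support,
            cdf_values=values,
            fraction_beyond_6mm=tail_fraction(pooled),
        )

    @classmethod
    def from_predictions(cls, predicted, actual) -> "TrackingReport":
        return cls.from_errors([targeting_errors(predicted, actual)])
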