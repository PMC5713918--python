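"""Containers and I/O for synchronized external/internal respiratory motion data.

External motion is the optically tracked position of three chest-surface
markers — nine channels (x, y, z per marker), in mm, sampled at roughly
25 Hz.  Internal motion is the tumor (implanted fiducial) position in mm,
available only at sparse stereoscopic-imaging instants.  A correlation
model maps the continuous external signal to an internal position estimate.

This module holds the plumbing every such model shares:

* :class:`MarkerTrace` — a timestamped multichannel position series,
* :class:`TrainingSet` — synchronized (external 9-vector, internal
  3-vector) pairs at imaging instants,
* :func:`synchronize` — interpolation-based pairing of the two streams,
* :class:`NormalizationSpec` — per-dimension [0, 1] range scaling, stored
  inside every fitted model so that cluster radii are expressed as a
  fraction of the training data width uniformly across dimensions,
* plain-text CSV trace formats and a versioned JSON model format.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

EXTERNAL_COLUMNS = ("t", "m1x", "m1y", "m1z", "m2x", "m2y", "m2z", "m3x", "m3y", "m3z")
INTERNAL_COLUMNS = ("t", "tx", "ty", "tz")
TRAINING_COLUMNS = EXTERNAL_COLUMNS + INTERNAL_COLUMNS[1:]
MODEL_SCHEMA_VERSION = 1

#: Default synchronization tolerance: the bracketing external samples must be
#: at most this many seconds apart (~5 samples at 25 Hz).
DEFAULT_SYNC_TOLERANCE_S = 0.2


class TraceFormatError(ValueError):
    """Malformed trace/training CSV (bad header, non-numeric cell, bad times)."""


class SynchronizationError(ValueError):
    """No internal point could be paired with the external trace."""


class ModelFormatError(ValueError):
    """Model file is truncated, malformed, or of an unsupported schema version."""


class ModelKind(str, Enum):
    """The three fuzzy correlation model families."""

    SUB_FIS = "sub-fis"
    FCM_FIS = "fcm-fis"
    ANFIS = "anfis"


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class MarkerTrace:
    """A timestamped multichannel position series in mm.

    ``values`` is ``n_samples x n_channels`` with 9 channels for external
    surface-marker traces and 3 for internal tumor traces.  Timestamps are
    seconds, strictly increasing.
    """

    timestamps: np.ndarray
    values: np.ndarray
    sample_rate_hint: float | None = None

    def __post_init__(self) -> None:
        t = _as_float_array(self.timestamps, "timestamps")
        v = _as_float_array(self.values, "values")
        if v.ndim == 1:
            v = v[:, None]
        if t.ndim != 1 or v.ndim != 2 or t.shape[0] != v.shape[0]:
            raise ValueError("timestamps and values have inconsistent shapes")
        if t.size == 0:
            raise ValueError("empty trace")
        if v.shape[1] not in (3, 9):
            raise ValueError(f"channel count must be 3 or 9, got {v.shape[1]}")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise TraceFormatError("timestamps must be strictly increasing")
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "values", v)

    @property
    def n_samples(self) -> int:
        return self.timestamps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])


@dataclass(frozen=True)
class TrainingSet:
    """Synchronized (external input, internal output) pairs at imaging instants."""

    X: np.ndarray  # n_points x 9, mm
    Y: np.ndarray  # n_points x 3, mm
    timestamps: np.ndarray  # seconds per row

    def __post_init__(self) -> None:
        X = _as_float_array(self.X, "X")
        Y = _as_float_array(self.Y, "Y")
        t = _as_float_array(self.timestamps, "timestamps")
        X = np.atleast_2d(X)
        Y = np.atleast_2d(Y)
        if X.shape[0] != Y.shape[0] or X.shape[0] != t.shape[0]:
            raise ValueError("X, Y and timestamps must have equal row counts")
        if X.shape[0] < 1:
            raise ValueError("training set must contain at least one point")
        if X.shape[1] != 9 or Y.shape[1] != 3:
            raise ValueError("X must have 9 columns and Y 3 columns")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("training rows must be strictly time-ordered")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Y", Y)
        object.__setattr__(self, "timestamps", t)

    @property
    def n_points(self) -> int:
        return self.X.shape[0]

    def subset(self, idx) -> "TrainingSet":
        idx = np.asarray(idx)
        return TrainingSet(self.X[idx], self.Y[idx], self.timestamps[idx])


def concat_training_sets(a: TrainingSet, b: TrainingSet) -> TrainingSet:
    """Concatenate two time-ordered sets; ``b`` must come strictly after ``a``."""
    if b.timestamps[0] <= a.timestamps[-1]:
        raise ValueError("second set must start strictly after the first ends")
    return TrainingSet(
        np.vstack([a.X, b.X]),
        np.vstack([a.Y, b.Y]),
        np.concatenate([a.timestamps, b.timestamps]),
    )


def synchronize(
    external: MarkerTrace,
    internal: MarkerTrace,
    tolerance: float = DEFAULT_SYNC_TOLERANCE_S,
) -> TrainingSet:
    """Pair each internal sample with the external trace at the same instant.

    The external 9-channel row is linearly interpolated at each internal
    timestamp, provided the bracketing external samples are at most
    ``tolerance`` seconds apart; internal points that fall outside the
    external time range, or inside a gap wider than the tolerance, are
    dropped.  An internal timestamp that coincides exactly with an external
    sample copies that row unchanged.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if external.n_channels != 9:
        raise ValueError("external trace must have 9 channels")
    if internal.n_channels != 3:
        raise ValueError("internal trace must have 3 channels")
    te = external.timestamps
    ve = external.values
    rows = []
    keep = []
    for k, t in enumerate(internal.timestamps):
        i = int(np.searchsorted(te, t, side="left"))
        if i < te.size and te[i] == t:
            rows.append(ve[i])
            keep.append(k)
            continue
        if i == 0 or i == te.size:
            continue  # outside external range
        lo, hi = i - 1, i
        gap = te[hi] - te[lo]
        if gap > tolerance:
            continue
        frac = (t - te[lo]) / gap
        rows.append(ve[lo] + frac * (ve[hi] - ve[lo]))
        keep.append(k)
    if not rows:
        raise SynchronizationError("no synchronized points within tolerance")
    keep = np.asarray(keep)
    return TrainingSet(np.asarray(rows), internal.values[keep], internal.timestamps[keep])


@dataclass(frozen=True)
class NormalizationSpec:
    """Per-dimension affine map of inputs/outputs to the [0, 1] training range.

    Degenerate (constant) dimensions keep a unit scale and are flagged so
    downstream width computations can floor them.
    """

    in_offset: np.ndarray
    in_scale: np.ndarray
    in_degenerate: np.ndarray
    out_offset: np.ndarray
    out_scale: np.ndarray
    out_degenerate: np.ndarray

    def normalize_inputs(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) - self.in_offset) / self.in_scale

    def denormalize_inputs(self, Xn: np.ndarray) -> np.ndarray:
        return np.atleast_2d(Xn) * self.in_scale + self.in_offset

    def normalize_outputs(self, Y: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(Y) - self.out_offset) / self.out_scale

    def denormalize_outputs(self, Yn: np.ndarray) -> np.ndarray:
        return np.atleast_2d(Yn) * self.out_scale + self.out_offset


def _fit_dims(values: np.ndarray):
    offset = values.min(axis=0)
    span = values.max(axis=0) - offset
    degenerate = span <= 0
    scale = np.where(degenerate, 1.0, span)
    return offset, scale, degenerate


def fit_normalization(train: TrainingSet) -> NormalizationSpec:
    """Fit the [0, 1] range normalization from a training set (>= 2 points)."""
    if train.n_points < 2:
        raise ValueError("at least 2 points are required to fit normalization")
    in_off, in_sc, in_deg = _fit_dims(train.X)
    out_off, out_sc, out_deg = _fit_dims(train.Y)
    return NormalizationSpec(in_off, in_sc, in_deg, out_off, out_sc, out_deg)


@dataclass
class CorrelationModel:
    """A fitted fuzzy external/internal correlation model.

    Holds one single-output rule base per internal coordinate (x, y, z),
    the [0, 1] normalization fitted on the training data, and training
    provenance (point count, clustering radius, per-output rule counts,
    fit diagnostics).  Rule bases operate entirely in normalized space;
    :meth:`predict` converts to and from mm.
    """

    model_kind: ModelKind
    rule_bases: list
    normalization: NormalizationSpec
    training_provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.model_kind = ModelKind(self.model_kind)
        if len(self.rule_bases) != 3:
            raise ValueError("a correlation model needs exactly 3 rule bases")
        for rb in self.rule_bases:
            if len(rb.rules) < 1:
                raise ValueError("every rule base needs at least one rule")

    def predict(self, X_mm: np.ndarray) -> np.ndarray:
        """Predict internal positions (n x 3, mm) from external rows (n x 9, mm)."""
        Xn = self.normalization.normalize_inputs(X_mm)
        Yn = np.column_stack([rb.infer_batch(Xn) for rb in self.rule_bases])
        return self.normalization.denormalize_outputs(Yn)

    def predict_one(self, x_mm: np.ndarray) -> np.ndarray:
        return self.predict(np.asarray(x_mm, dtype=float)[None, :])[0]


# ---------------------------------------------------------------------------
# CSV trace I/O
# ---------------------------------------------------------------------------

_LAYOUT_COLUMNS = {"external": EXTERNAL_COLUMNS, "internal": INTERNAL_COLUMNS}


def _parse_numeric(df: pd.DataFrame, path) -> np.ndarray:
    arr = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = ~np.isfinite(arr)
    if bad.any():
        row = int(np.argwhere(bad.any(axis=1))[0, 0])
        raise TraceFormatError(f"{path}: non-numeric cell in data row {row + 1}")
    return arr


def _check_monotone(t: np.ndarray, path) -> None:
    if t.size > 1:
        d = np.diff(t)
        if not np.all(d > 0):
            row = int(np.argwhere(d <= 0)[0, 0]) + 2
            raise TraceFormatError(f"{path}: timestamps not strictly increasing at data row {row}")


def read_trace(path, layout: str) -> MarkerTrace:
    """Read an external (10-column) or internal (4-column) CSV trace."""
    if layout not in _LAYOUT_COLUMNS:
        raise ValueError(f"layout must be 'external' or 'internal', got {layout!r}")
    expected = _LAYOUT_COLUMNS[layout]
    df = pd.read_csv(path)
    if tuple(df.columns) != expected:
        raise TraceFormatError(
            f"{path}: expected header {','.join(expected)}, got {','.join(map(str, df.columns))}"
        )
    arr = _parse_numeric(df, path)
    t = arr[:, 0]
    _check_monotone(t, path)
    hint = float(1.0 / np.median(np.diff(t))) if t.size > 1 else None
    return MarkerTrace(t, arr[:, 1:], sample_rate_hint=hint)


def write_trace(trace: MarkerTrace, path) -> None:
    """Write a trace as CSV (12 significant digits, round-trips below 1e-9 mm)."""
    cols = EXTERNAL_COLUMNS if trace.n_channels == 9 else INTERNAL_COLUMNS
    df = pd.DataFrame(
        np.column_stack([trace.timestamps, trace.values]), columns=list(cols)
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_training_set(path) -> TrainingSet:
    """Read a synchronized training set (13-column CSV)."""
    df = pd.read_csv(path)
    if tuple(df.columns) != TRAINING_COLUMNS:
        raise TraceFormatError(
            f"{path}: expected header {','.join(TRAINING_COLUMNS)}, got {','.join(map(str, df.columns))}"
        )
    arr = _parse_numeric(df, path)
    _check_monotone(arr[:, 0], path)
    return TrainingSet(arr[:, 1:10], arr[:, 10:13], arr[:, 0])


def write_training_set(train: TrainingSet, path) -> None:
    df = pd.DataFrame(
        np.column_stack([train.timestamps, train.X, train.Y]),
        columns=list(TRAINING_COLUMNS),
    )
    df.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Model serialization (versioned JSON)
# ---------------------------------------------------------------------------


def save_model(model: CorrelationModel, path) -> None:
    """Serialize a fitted model losslessly to a versioned JSON file."""
    norm = model.normalization
    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "model_kind": model.model_kind.value,
        "normalization": {
            "in_offset": norm.in_offset.tolist(),
            "in_scale": norm.in_scale.tolist(),
            "in_degenerate": norm.in_degenerate.astype(bool).tolist(),
            "out_offset": norm.out_offset.tolist(),
            "out_scale": norm.out_scale.tolist(),
            "out_degenerate": norm.out_degenerate.astype(bool).tolist(),
        },
        "rule_bases": [
            {
                "output_label": rb.output_label,
                "input_dim": rb.input_dim,
                "rules": [
                    {
                        "centers": [mf.center for mf in rule.premise],
                        "sigmas": [mf.sigma for mf in rule.premise],
                        "coeffs": rule.coeffs.tolist(),
                        "intercept": rule.intercept,
                    }
                    for rule in rb.rules
                ],
            }
            for rb in model.rule_bases
        ],
        "training_provenance": model.training_provenance,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path) -> CorrelationModel:
    """Load a model saved by :func:`save_model`; checks the schema version."""
    from .fis import GaussianMF, Rule, RuleBase  # deferred to avoid an import cycle

    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path}: not a valid model file ({exc})") from exc
    if not isinstance(payload, dict) or "schema_version" not in payload:
        raise ModelFormatError(f"{path}: missing schema_version")
    if payload["schema_version"] != MODEL_SCHEMA_VERSION:
        raise ModelFormatError(
            f"{path}: schema version {payload['schema_version']} is not supported "
            f"(expected {MODEL_SCHEMA_VERSION})"
        )
    try:
        n = payload["normalization"]
        norm = NormalizationSpec(
            np.asarray(n["in_offset"], float),
            np.asarray(n["in_scale"], float),
            np.asarray(n["in_degenerate"], bool),
            np.asarray(n["out_offset"], float),
            np.asarray(n["out_scale"], float),
            np.asarray(n["out_degenerate"], bool),
        )
        rule_bases = []
        for rb in payload["rule_bases"]:
            rules = [
                Rule(
                    premise=tuple(
                        GaussianMF(c, s) for c, s in zip(r["centers"], r["sigmas"])
                    ),
                    coeffs=np.asarray(r["coeffs"], float),
                    intercept=float(r["intercept"]),
                )
                for r in rb["rules"]
            ]
            rule_bases.append(RuleBase(rules, rb["input_dim"], rb["output_label"]))
        return CorrelationModel(
            ModelKind(payload["model_kind"]),
            rule_bases,
            norm,
            payload.get("training_provenance", {}),
        )
    except (KeyError, TypeError, IndexError) as exc:
        raise ModelFormatError(f"{path}: malformed model payload ({exc})") from exc
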