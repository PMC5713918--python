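"""Synthetic respiratory motion: correlated surface-marker and tumor traces.

The clinical data regime this package targets — three optically tracked
chest markers at ~25 Hz, tumor position at a handful of imaging instants —
comes from proprietary treatment logs, so experiments run on a synthetic
generator instead.  Breathing is modelled with a cosine-power (Lujan-type)
kernel on a latent respiratory phase that advances cycle by cycle with a
jittered period; each external channel is

    baseline + drift * t + amplitude * a_k * sin^(2n)((phi(t) + offset) / 2) + noise,

with a_k a per-cycle amplitude factor.  The internal (tumor) truth is a
coupling map — affine, two-regime piecewise linear, or sigmoidal
saturation — applied to the lag-shifted noiseless external signal, plus an
optional hysteresis term (a phase-velocity-dependent offset opening the
inhale/exhale loop) and an internal-only baseline drift.  External drift
passes through the coupling and therefore does not degrade a static
external-to-internal map; internal-only drift is what makes intra-treatment
model updating necessary.

Imaging observations are the internal truth sampled sparsely (uniform,
random, or burst-then-sparse schedules), with observation noise, paired to
interpolated external rows — the same pairing the clinical workflow uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .motion_data import MarkerTrace, TrainingSet, synchronize

_SEED_CAP = 2**31 - 1


# ---------------------------------------------------------------------------
# Coupling maps (external 9-vector -> internal 3-vector, mm)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AffineCoupling:
    """y = matrix @ x + offset."""

    matrix: np.ndarray  # 3 x 9
    offset: np.ndarray  # 3

    def apply(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(X) @ np.asarray(self.matrix, float).T + np.asarray(
            self.offset, float
        )


@dataclass(frozen=True)
class PiecewiseLinearCoupling:
    """Two-regime response to the scalar drive s = weights . x.

    Each internal axis follows slope_low below the threshold and slope_high
    above it, continuously joined at the knee.
    """

    weights: np.ndarray  # 9
    threshold: float
    slopes_low: np.ndarray  # 3
    slopes_high: np.ndarray  # 3
    offset: np.ndarray  # 3

    def apply(self, X: np.ndarray) -> np.ndarray:
        s = np.atleast_2d(X) @ np.asarray(self.weights, float)
        lo = np.asarray(self.slopes_low, float)
        hi = np.asarray(self.slopes_high, float)
        below = np.minimum(s, self.threshold)[:, None] * lo
        above = np.maximum(s - self.threshold, 0.0)[:, None] * hi
        return np.asarray(self.offset, float) + below + above


@dataclass(frozen=True)
class SigmoidCoupling:
    """Saturating response scale / (1 + exp(-(s - center) / width)) per axis."""

    weights: np.ndarray  # 9
    center: float
    width: float
    scale: np.ndarray  # 3
    offset: np.ndarray  # 3

    def apply(self, X: np.ndarray) -> np.ndarray:
        s = np.atleast_2d(X) @ np.asarray(self.weights, float)
        g = 1.0 / (1.0 + np.exp(-(s - self.center) / self.width))
        return np.asarray(self.offset, float) + g[:, None] * np.asarray(self.scale, float)


#: A plausible surface-to-tumor affine map: tumor motion dominated by the
#: superior-inferior (z) marker channels, with smaller AP/LR components.
DEFAULT_AFFINE = AffineCoupling(
    matrix=np.array(
        [
            [0.10, 0.00, 0.30, 0.10, 0.00, 0.20, 0.00, 0.00, 0.10],
            [0.00, 0.15, 0.50, 0.00, 0.10, 0.40, 0.00, 0.00, 0.20],
            [0.00, 0.00, 1.00, 0.00, 0.00, 0.80, 0.00, 0.00, 0.60],
        ]
    ),
    offset=np.zeros(3),
)


def _nine(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 0:
        arr = np.full(9, float(arr))
    if arr.shape != (9,):
        raise ValueError("expected a scalar or length-9 vector")
    return arr


@dataclass(frozen=True)
class BreathingParams:
    """Generator settings; defaults emulate a calm, regular breather.

    Units: seconds, mm, Hz, mm/min.  Amplitudes are per external channel
    (x, y, z per marker); the z channels carry most of the respiratory
    excursion.  ``shape_exponent`` is the cosine-power flattening exponent
    (larger -> longer end-exhale dwell).
    """

    period_s: float = 4.0
    period_jitter_s: float = 0.15
    amplitudes_mm: np.ndarray = field(
        default_factory=lambda: np.array([1.5, 2.5, 8.0, 1.2, 2.0, 7.0, 1.0, 1.5, 5.0])
    )
    amplitude_jitter_frac: float = 0.05
    #: probability that a cycle is a "sigh" (intermittent deep breath) whose
    #: amplitude is multiplied by ``sigh_factor``
    sigh_prob: float = 0.0
    sigh_factor: float = 1.8
    #: relative spread of the sigh depth from breath to breath
    sigh_jitter: float = 0.0
    #: slow multiplicative deepening (or shallowing) of the breathing
    #: amplitude, per minute — e.g. 0.2 means breaths are 20% deeper after
    #: one minute (progressive relaxation)
    amplitude_drift_per_min: float = 0.0
    shape_exponent: int = 2
    baselines_mm: np.ndarray = field(default_factory=lambda: np.zeros(9))
    drift_mm_per_min: np.ndarray = field(default_factory=lambda: np.zeros(9))
    internal_drift_mm_per_min: np.ndarray = field(default_factory=lambda: np.zeros(3))
    external_noise_mm: float = 0.2
    internal_noise_mm: float = 0.5
    lag_s: float = 0.15
    hysteresis: float = 0.0
    coupling: object = DEFAULT_AFFINE
    duration_s: float = 300.0
    rate_hz: float = 25.0
    channel_phase_offsets: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 0.25, 9)
    )
    n_imaging: int = 27
    imaging_schedule: str = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period_s <= 0 or self.duration_s <= 0 or self.rate_hz <= 0:
            raise ValueError("period, duration and rate must be positive")
        for name in (
            "amplitudes_mm",
            "baselines_mm",
            "drift_mm_per_min",
            "channel_phase_offsets",
        ):
            object.__setattr__(self, name, _nine(getattr(self, name)))
        if np.any(self.amplitudes_mm < 0):
            raise ValueError("amplitudes must be non-negative")
        object.__setattr__(
            self,
            "internal_drift_mm_per_min",
            np.broadcast_to(
                np.asarray(self.internal_drift_mm_per_min, float), (3,)
            ).copy(),
        )


@dataclass
class SimulatedPatient:
    """Dense external/internal traces plus the sparse noisy imaging set."""

    external: MarkerTrace  # 9-channel, noisy, ~25 Hz
    internal_truth: MarkerTrace  # 3-channel, dense, noiseless
    imaging: TrainingSet
    params: BreathingParams


class _PhaseModel:
    """Piecewise-linear latent phase with per-cycle period/amplitude jitter."""

    def __init__(self, params: BreathingParams, rng: np.random.Generator) -> None:
        t_start = -(abs(params.lag_s) + 2.0 * params.period_s)
        horizon = params.duration_s + params.period_s - t_start
        durations: list[float] = []
        total = 0.0
        while total < horizon:
            d = params.period_s + params.period_jitter_s * rng.standard_normal()
            d = max(d, 0.3 * params.period_s)
            durations.append(d)
            total += d
        durations = np.asarray(durations)
        self.boundaries = t_start + np.concatenate([[0.0], np.cumsum(durations)])
        self._amp_drift = params.amplitude_drift_per_min
        self.amp_factors = np.clip(
            1.0 + params.amplitude_jitter_frac * rng.standard_normal(durations.size),
            0.2,
            None,
        )
        if params.sigh_prob > 0:
            sighs = rng.uniform(size=durations.size) < params.sigh_prob
            depth = params.sigh_factor * np.clip(
                1.0 + params.sigh_jitter * rng.standard_normal(durations.size), 0.5, None
            )
            self.amp_factors = np.where(
                sighs, self.amp_factors * depth, self.amp_factors
            )

    def phase(self, t: np.ndarray) -> np.ndarray:
        cycles = 2.0 * np.pi * np.arange(self.boundaries.size)
        return np.interp(t, self.boundaries, cycles)

    def amplitude_factor(self, t: np.ndarray) -> np.ndarray:
        k = np.clip(
            np.searchsorted(self.boundaries, t, side="right") - 1,
            0,
            self.amp_factors.size - 1,
        )
        ramp = np.clip(1.0 + self._amp_drift * np.asarray(t) / 60.0, 0.2, None)
        return self.amp_factors[k] * ramp


def _external_clean(t: np.ndarray, params: BreathingParams, phase: _PhaseModel) -> np.ndarray:
    phi = phase.phase(t)
    a = phase.amplitude_factor(t)
    osc = (
        np.sin((phi[:, None] + params.channel_phase_offsets[None, :]) / 2.0)
        ** (2 * params.shape_exponent)
    )
    return (
        params.baselines_mm
        + params.drift_mm_per_min * (t / 60.0)[:, None]
        + params.amplitudes_mm * a[:, None] * osc
    )


def _internal_clean(t: np.ndarray, params: BreathingParams, phase: _PhaseModel) -> np.ndarray:
    lagged = t - params.lag_s
    Y = params.coupling.apply(_external_clean(lagged, params, phase))
    if params.hysteresis:
        # loop-opening term: different inhale/exhale paths, scaled to the
        # mean oscillation amplitude, applied isotropically
        amp_scale = float(np.mean(params.amplitudes_mm))
        Y = Y + (
            params.hysteresis * amp_scale * np.sin(phase.phase(lagged))
        )[:, None] / np.sqrt(3.0)
    return Y + params.internal_drift_mm_per_min * (t / 60.0)[:, None]


def simulate_patient(params: BreathingParams) -> SimulatedPatient:
    """Generate dense external/internal traces and the sparse imaging set.

    Fully reproducible from ``params.seed``: the same parameters always
    produce bit-identical traces.
    """
    rng = np.random.default_rng(params.seed)
    phase = _PhaseModel(params, rng)
    n = int(round(params.duration_s * params.rate_hz))
    t = np.arange(n) / params.rate_hz
    ext_clean = _external_clean(t, params, phase)
    ext_noise = params.external_noise_mm * rng.standard_normal(ext_clean.shape)
    external = MarkerTrace(t, ext_clean + ext_noise, params.rate_hz)
    internal_truth = MarkerTrace(t, _internal_clean(t, params, phase), params.rate_hz)
    imaging = sample_imaging(
        external,
        internal_truth,
        params.n_imaging,
        schedule=params.imaging_schedule,
        seed=int(rng.integers(_SEED_CAP)),
        noise_mm=params.internal_noise_mm,
    )
    return SimulatedPatient(external, internal_truth, imaging, params)


def sample_imaging(
    external: MarkerTrace,
    internal_truth: MarkerTrace,
    n_points: int,
    schedule: str = "uniform",
    seed: int = 0,
    noise_mm: float = 0.5,
    window: tuple[float, float] | None = None,
) -> TrainingSet:
    """Sparse noisy imaging observations paired with interpolated external rows.

    Schedules: ``uniform`` (evenly spaced over the window), ``random``
    (sorted uniform draws), ``burst-then-sparse`` (half the points in the
    first fifth of the window, the rest spread over the remainder).
    """
    if n_points < 4:
        raise ValueError("need at least 4 imaging points")
    if n_points > internal_truth.n_samples:
        raise ValueError("more imaging points than dense samples")
    t0, t1 = window if window is not None else (
        float(internal_truth.timestamps[0]),
        float(internal_truth.timestamps[-1]),
    )
    rng = np.random.default_rng(seed)
    if schedule == "uniform":
        times = np.linspace(t0, t1, n_points)
    elif schedule == "random":
        times = np.sort(rng.uniform(t0, t1, n_points))
        # enforce strict ordering under (unlikely) duplicate draws
        times = times + np.arange(n_points) * 1e-9
    elif schedule == "burst-then-sparse":
        n_burst = n_points // 2
        burst = np.linspace(t0, t0 + 0.2 * (t1 - t0), n_burst, endpoint=False)
        sparse = np.linspace(t0 + 0.2 * (t1 - t0), t1, n_points - n_burst)
        times = np.concatenate([burst, sparse])
    else:
        raise ValueError(f"unknown imaging schedule {schedule!r}")
    times = np.clip(times, t0, t1)

    obs = np.column_stack(
        [
            np.interp(times, internal_truth.timestamps, internal_truth.values[:, c])
            for c in range(3)
        ]
    )
    obs = obs + noise_mm * rng.standard_normal(obs.shape)
    internal = MarkerTrace(times, obs)
    # pairing runs through the same synchronization used on real logs
    return synchronize(external, internal, tolerance=2.0 / (external.sample_rate_hint or 25.0) + 1e-9)


# ---------------------------------------------------------------------------
# Cohort presets
# ---------------------------------------------------------------------------

PRESET_NAMES = ("control", "worst")


def preset_params(name: str, seed: int, **overrides) -> BreathingParams:
    """Named synthetic patient presets with seeded inter-patient variability.

    ``control``: mild cycle-to-cycle jitter, affine coupling, no hysteresis —
    a patient current clinical correlation handles easily.  ``worst``: heavy
    period/amplitude jitter, internal baseline drift, large-amplitude
    two-regime piecewise-linear coupling and hysteresis — an operational
    stand-in for the difficult end of the clinical spectrum.  Both are
    synthetic constructions, not fits to any clinical case.
    """
    rng = np.random.default_rng(seed)
    base_amp = np.array([1.5, 2.5, 8.0, 1.2, 2.0, 7.0, 1.0, 1.5, 5.0])
    period = float(3.2 + rng.uniform(0.0, 1.6))
    sim_seed = int(rng.integers(_SEED_CAP))
    if name == "control":
        gains = 1.0 + 0.15 * rng.uniform(-1.0, 1.0, size=(3, 1))
        coupling = AffineCoupling(
            matrix=DEFAULT_AFFINE.matrix * gains, offset=rng.uniform(-2.0, 2.0, 3)
        )
        params = BreathingParams(
            period_s=period,
            period_jitter_s=0.12,
            amplitudes_mm=base_amp * rng.uniform(0.8, 1.2),
            amplitude_jitter_frac=0.05,
            drift_mm_per_min=np.zeros(9),
            internal_drift_mm_per_min=np.full(3, 0.05),
            external_noise_mm=0.2,
            internal_noise_mm=0.4,
            lag_s=0.12,
            hysteresis=0.0,
            coupling=coupling,
            seed=sim_seed,
        )
    elif name == "worst":
        amps = base_amp * rng.uniform(1.8, 2.4)
        weights = np.zeros(9)
        weights[[2, 5, 8]] = 1.0 / 3.0
        s_peak = float(weights @ amps)
        slopes_low = np.array([0.25, 0.6, 1.1]) * rng.uniform(0.9, 1.1)
        gap = rng.uniform(2.5, 3.5)
        coupling = PiecewiseLinearCoupling(
            weights=weights,
            # the knee sits above the quiet-breathing peak: only deep sighs
            # drive the tumor into the stiff regime
            threshold=rng.uniform(1.1, 1.25) * s_peak,
            slopes_low=slopes_low,
            slopes_high=slopes_low * gap,
            offset=rng.uniform(-2.0, 2.0, 3),
        )
        params = BreathingParams(
            period_s=period,
            period_jitter_s=0.3,
            amplitudes_mm=amps,
            amplitude_jitter_frac=0.10,
            shape_exponent=5,
            sigh_prob=0.35,
            sigh_factor=1.9,
            sigh_jitter=0.2,
            drift_mm_per_min=np.concatenate([np.full(3, 0.3), np.zeros(6)]),
            internal_drift_mm_per_min=np.array([0.2, 0.4, 0.8]),
            external_noise_mm=0.3,
            internal_noise_mm=0.8,
            lag_s=0.15,
            hysteresis=0.2,
            coupling=coupling,
            seed=sim_seed,
        )
    else:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    return replace(params, **overrides) if overrides else params


@dataclass
class CohortPatient:
    name: str
    seed: int
    patient: SimulatedPatient


def make_cohort(
    preset_names, master_seed: int = 0, **overrides
) -> list[CohortPatient]:
    """Simulate one patient per preset name with derived per-patient seeds.

    The whole cohort regenerates identically from the same master seed.
    """
    rng = np.random.default_rng(master_seed)
    cohort = []
    for name in preset_names:
        seed = int(rng.integers(_SEED_CAP))
        params = preset_params(name, seed, **overrides)
        cohort.append(CohortPatient(name=name, seed=seed, patient=simulate_patient(params)))
    return cohort
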