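"""Adaptive neuro-fuzzy training of the Sugeno correlation model.

ANFIS realizes the first-order Sugeno system of :mod:`fuzzytrack.fis` as a
five-layer network (membership grades, rule firing products, firing
normalization, per-rule weighted consequents, output sum) and trains it by
hybrid learning: per epoch, consequent parameters are solved exactly by the
same joint least squares the other builders use (forward pass), then the
Gaussian premise parameters (c, sigma) are moved one normalized-gradient
step against the squared training error (backward pass).  The premise
structure is initialized by subtractive clustering, exactly as the SUB-FIS
builder does, so an untrained (0-epoch) ANFIS is the SUB-FIS model.

The step size follows the classical heuristic: multiplied by
``step_increase`` after four consecutive error decreases, by
``step_decrease`` after a sustained up-down oscillation.  The returned
model is the epoch snapshot with minimum training error per output, which
guarantees it is never worse on the training set than its initialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fis import SIGMA_FLOOR, RuleBase, build_sub_fis, fit_consequents, _premise_rule_base
from .motion_data import CorrelationModel, ModelKind, TrainingSet


@dataclass(frozen=True)
class AnfisConfig:
    """Hybrid-learning settings (all in normalized units)."""

    epochs: int = 20
    initial_step: float = 0.01
    step_increase: float = 1.1
    step_decrease: float = 0.9
    radius: float = 1.0 / 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.initial_step < 0:
            raise ValueError("initial_step must be >= 0 (0 freezes the premises)")
        if self.step_increase <= 0 or self.step_decrease <= 0:
            raise ValueError("step factors must be positive")


@dataclass
class TrainingHistory:
    """Per-epoch overall 3-D training RMSE (mm) and mean premise step size."""

    rmse_mm: np.ndarray = field(default_factory=lambda: np.empty(0))
    step_size: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_epochs(self) -> int:
        return int(self.rmse_mm.size)


def _gradients_arrays(centers, sigmas, P, r0, X, y):
    """Batch gradient of sum-squared error w.r.t. premise centers and widths.

    Uses d/d(log w_i): with wbar the softmax of log firing strengths,
    dE/d(log w_ti) = 2 e_t wbar_ti (f_ti - yhat_t), then the chain rule
    through log w_i = -sum_d (x_d - c_id)^2 / (2 sigma_id^2).
    """
    X = np.atleast_2d(X)
    z = (X[:, None, :] - centers[None, :, :]) / sigmas[None, :, :]  # (n, K, d)
    lw = -0.5 * np.einsum("nkd,nkd->nk", z, z)
    lw -= lw.max(axis=1, keepdims=True)
    w = np.exp(lw)
    wbar = w / w.sum(axis=1, keepdims=True)
    F = X @ P.T + r0  # (n, K)
    yhat = (wbar * F).sum(axis=1)
    e = yhat - y
    dlw = (2.0 * e)[:, None] * wbar * (F - yhat[:, None])  # (n, K)
    diff = X[:, None, :] - centers[None, :, :]
    g_centers = np.einsum("nk,nkd->kd", dlw, diff / sigmas[None] ** 2)
    g_sigmas = np.einsum("nk,nkd->kd", dlw, diff**2 / sigmas[None] ** 3)
    return g_centers, g_sigmas, float(np.sqrt(np.mean(e**2)))


def premise_gradients(rb: RuleBase, X: np.ndarray, y: np.ndarray):
    """Gradient of the summed squared error w.r.t. every (center, sigma).

    Returns two (n_rules, input_dim) arrays.  Consequents are taken as
    fixed at the rule base's current values.
    """
    centers, sigmas = rb._premise_arrays()
    P, r0 = rb._consequent_arrays()
    gc, gs, _ = _gradients_arrays(centers, sigmas, P, r0, np.atleast_2d(X), np.asarray(y, float).ravel())
    return gc, gs


def _adapt_step(step: float, errors: list[float], cfg: AnfisConfig) -> float:
    """Classical step-size heuristic on the recent error history."""
    if len(errors) >= 5:
        last = np.diff(errors[-5:])
        if np.all(last < 0):
            return step * cfg.step_increase
        signs = np.sign(last)
        if np.all(signs != 0) and np.all(signs[1:] != signs[:-1]):
            return step * cfg.step_decrease
    return step


def anfis_train(
    train: TrainingSet, config: AnfisConfig | None = None
) -> tuple[CorrelationModel, TrainingHistory]:
    """Hybrid least-squares / gradient-descent training of the three rule bases.

    Each internal coordinate's rule base is trained independently (its own
    error history, step size, and best snapshot); the history reports the
    combined 3-D training RMSE per epoch.  ``epochs=0`` returns the
    subtractive-initialized model unchanged.
    """
    config = config or AnfisConfig()
    init = build_sub_fis(train, radius=config.radius)
    norm = init.normalization
    provenance = {
        "builder": ModelKind.ANFIS.value,
        "n_points": train.n_points,
        "radius": config.radius,
        "epochs": config.epochs,
        "initial_step": config.initial_step,
        "sigma_refloor_events": 0,
    }
    if config.epochs == 0:
        model = CorrelationModel(ModelKind.ANFIS, init.rule_bases, norm, provenance)
        return model, TrainingHistory()

    Xn = norm.normalize_inputs(train.X)
    Yn = norm.normalize_outputs(train.Y)
    out_scale = norm.out_scale

    states = []
    for j, rb in enumerate(init.rule_bases):
        centers, sigmas = rb._premise_arrays()
        states.append(
            {
                "centers": centers.copy(),
                "sigmas": sigmas.copy(),
                "rb": rb,
                "label": rb.output_label,
                "step": config.initial_step,
                "errors": [],
                "best_rmse": np.inf,
                "best_rb": rb,
            }
        )
        # the initialization is epoch-0 state; record its error as the baseline
        resid = rb.infer_batch(Xn) - Yn[:, j]
        states[j]["best_rmse"] = float(np.sqrt(np.mean(resid**2)))

    refloors = 0
    hist_rmse = []
    hist_step = []
    for _ in range(config.epochs):
        epoch_mse_mm = 0.0
        for j, st in enumerate(states):
            y = Yn[:, j]
            # forward: exact consequent solve for the current premises
            rb = _premise_rule_base(st["centers"], st["sigmas"], 9, st["label"])
            rb, _ = fit_consequents(rb, Xn, y)
            P, r0 = rb._consequent_arrays()
            gc, gs, rmse = _gradients_arrays(st["centers"], st["sigmas"], P, r0, Xn, y)
            if rmse <= st["best_rmse"]:
                st["best_rmse"] = rmse
                st["best_rb"] = rb
            st["errors"].append(rmse)
            epoch_mse_mm += (rmse * out_scale[j]) ** 2
            # backward: one normalized-gradient step on the premises
            gnorm = float(np.sqrt((gc**2).sum() + (gs**2).sum()))
            if np.isfinite(gnorm) and gnorm > 0:
                st["centers"] = st["centers"] - st["step"] * gc / gnorm
                new_sigmas = st["sigmas"] - st["step"] * gs / gnorm
                if np.any(new_sigmas < SIGMA_FLOOR) or not np.all(np.isfinite(new_sigmas)):
                    refloors += int(np.sum(~(new_sigmas >= SIGMA_FLOOR)))
                    new_sigmas = np.where(
                        np.isfinite(new_sigmas), new_sigmas, SIGMA_FLOOR
                    )
                st["sigmas"] = np.maximum(new_sigmas, SIGMA_FLOOR)
            st["step"] = _adapt_step(st["step"], st["errors"], config)
        hist_rmse.append(float(np.sqrt(epoch_mse_mm)))
        hist_step.append(float(np.mean([st["step"] for st in states])))

    provenance["sigma_refloor_events"] = refloors
    provenance["per_output"] = [
        {"n_rules": st["best_rb"].n_rules, "best_train_rmse_norm": st["best_rmse"]}
        for st in states
    ]
    model = CorrelationModel(
        ModelKind.ANFIS, [st["best_rb"] for st in states], norm, provenance
    )
    return model, TrainingHistory(np.asarray(hist_rmse), np.asarray(hist_step))


def anfis_predict(model: CorrelationModel, x: np.ndarray) -> np.ndarray:
    """Predict the internal 3-vector (mm) for one external 9-vector (mm).

    ANFIS layers 1-5 are algebraically the same forward pass as Sugeno
    inference, so this simply delegates to the model's rule bases.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return model.predict_one(x)
    return model.predict(x)
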