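"""First-order Takagi-Sugeno fuzzy inference and the SUB-FIS / FCM-FIS builders.

A rule base is a set of rules "IF x_1 is G_i1 AND ... AND x_9 is G_i9 THEN
f_i = p_i . x + r_i", with Gaussian membership functions G_id on each input
dimension.  The firing strength of rule i at input x is the product of its
per-dimension membership grades, w_i = prod_d exp(-(x_d - c_id)^2 / (2 s_id^2));
the system output is the normalized-firing-strength weighted average of the
per-rule linear consequents,

    f(x) = sum_i wbar_i(x) (p_i . x + r_i),    wbar_i = w_i / sum_j w_j.

Rules come one-per-cluster from clustering the joint (input + output)
normalized training space: subtractive clustering for SUB-FIS, subtractive-
seeded fuzzy C-means for FCM-FIS.  Consequent parameters are estimated by a
joint linear least-squares fit of the inference-time prediction objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clustering import FcmParams, SubtractiveParams, fcm, subtractive_cluster
from .motion_data import (
    CorrelationModel,
    ModelKind,
    TrainingSet,
    fit_normalization,
)

#: Minimum premise width in normalized units; floors widths arising from
#: singleton or degenerate clusters so no premise becomes singular.
SIGMA_FLOOR = 1e-4

#: Conversion from a subtractive influence range to a Gaussian premise width:
#: sigma = radius * data_width / sqrt(8).
SIGMA_FROM_RADIUS = 1.0 / np.sqrt(8.0)

OUTPUT_LABELS = ("x", "y", "z")


@dataclass(frozen=True)
class GaussianMF:
    """A Gaussian membership function exp(-(x - center)^2 / (2 sigma^2))."""

    center: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma >= SIGMA_FLOOR:
            raise ValueError(f"sigma must be >= {SIGMA_FLOOR}, got {self.sigma}")


def mf_eval(mf: GaussianMF, x) -> np.ndarray | float:
    """Membership grade in (0, 1], symmetric about the center."""
    x = np.asarray(x, dtype=float)
    out = np.exp(-((x - mf.center) ** 2) / (2.0 * mf.sigma**2))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class Rule:
    """One fuzzy rule: Gaussian premise per input dimension, linear consequent."""

    premise: tuple[GaussianMF, ...]
    coeffs: np.ndarray  # length = input dimension
    intercept: float

    def __post_init__(self) -> None:
        coeffs = np.asarray(self.coeffs, dtype=float)
        if coeffs.shape != (len(self.premise),):
            raise ValueError("consequent coefficient length must match premise dimension")
        object.__setattr__(self, "coeffs", coeffs)

    def linear_output(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(X) @ self.coeffs + self.intercept


class RuleBase:
    """A single-output first-order Sugeno rule base in normalized space."""

    def __init__(self, rules, input_dim: int, output_label: str = "y") -> None:
        rules = list(rules)
        if not rules:
            raise ValueError("a rule base needs at least one rule")
        for rule in rules:
            if len(rule.premise) != input_dim:
                raise ValueError("all rules must share the rule base input dimension")
        self.rules = rules
        self.input_dim = int(input_dim)
        self.output_label = output_label

    @property
    def n_rules(self) -> int:
        return len(self.rules)

    def _premise_arrays(self):
        centers = np.array([[mf.center for mf in r.premise] for r in self.rules])
        sigmas = np.array([[mf.sigma for mf in r.premise] for r in self.rules])
        return centers, sigmas

    def _consequent_arrays(self):
        P = np.array([r.coeffs for r in self.rules])
        r0 = np.array([r.intercept for r in self.rules])
        return P, r0

    def log_firing(self, X: np.ndarray) -> np.ndarray:
        """Log firing strengths, (n_samples, n_rules)."""
        X = np.atleast_2d(X)
        centers, sigmas = self._premise_arrays()
        z = (X[:, None, :] - centers[None, :, :]) / sigmas[None, :, :]
        return -0.5 * np.einsum("nkd,nkd->nk", z, z)

    def firing(self, X: np.ndarray) -> np.ndarray:
        return np.exp(self.log_firing(X))

    def normalized_firing(self, X: np.ndarray) -> np.ndarray:
        """Row-stochastic firing strengths, computed stably in log space."""
        lw = self.log_firing(X)
        lw -= lw.max(axis=1, keepdims=True)
        w = np.exp(lw)
        return w / w.sum(axis=1, keepdims=True)

    def infer_batch(self, X: np.ndarray) -> np.ndarray:
        """Sugeno output for each row of X (normalized units)."""
        X = np.atleast_2d(X)
        wbar = self.normalized_firing(X)
        P, r0 = self._consequent_arrays()
        F = X @ P.T + r0
        return (wbar * F).sum(axis=1)


def firing_strengths(rb: RuleBase, x: np.ndarray) -> np.ndarray:
    """Per-rule firing strength (product of membership grades) at one input."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input must be finite")
    return rb.firing(x[None, :])[0]


def normalize_firing(w: np.ndarray) -> np.ndarray:
    """Normalize firing strengths to sum to one."""
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError("firing strengths must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("all firing strengths vanished; cannot normalize")
    return w / total


def infer(rb: RuleBase, x: np.ndarray) -> float:
    """Scalar Sugeno inference at one input vector."""
    return float(rb.infer_batch(np.asarray(x, dtype=float)[None, :])[0])


def fit_consequents(
    rb: RuleBase,
    X: np.ndarray,
    y: np.ndarray,
    ridge_lambda: float = 1e-8,
):
    """Estimate all consequent parameters by joint linear least squares.

    Minimizes ``sum_t (y_t - sum_i wbar_i(x_t)(p_i . x_t + r_i))^2`` over
    every rule's (p_i, r_i) at once.  On the tiny training sets this
    package targets (4-27 points against ``n_rules * (d + 1)`` parameters)
    the plain minimizer is not unique and interpolates observation noise,
    so the solve is parameterized as a global affine fit plus per-rule
    deviations, and the deviation system is solved by ridge regression
    with the ridge strength chosen by generalized cross-validation (GCV),
    floored at ``ridge_lambda``.  Affine data leaves a zero residual for
    the deviation system, so the affine predictor is always recovered
    exactly; under noise the GCV ridge keeps the rule deviations from
    chasing it.

    Returns a new rule base plus a diagnostics dict (training residual
    RMSE, chosen ridge, rank-deficiency and underdetermination flags).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, d = X.shape
    K = rb.n_rules
    n_params = K * (d + 1)

    # global affine stage: centered GCV ridge — the nine surrogate channels
    # are driven by one latent breathing phase and are therefore nearly
    # collinear, so an unregularized solve amplifies noise along the weak
    # directions of the design
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    slope, lam0, _ = _gcv_ridge(X - x_mean, y - y_mean, ridge_lambda)
    theta0 = np.concatenate([slope, [y_mean - x_mean @ slope]])
    B = np.column_stack([X, np.ones(n)])
    resid = y - B @ theta0

    wbar = rb.normalized_firing(X)
    A = (wbar[:, :, None] * B[:, None, :]).reshape(n, n_params)
    delta, lam, rank = _gcv_ridge(A, resid, ridge_lambda)
    rank_deficient = rank < n_params
    delta = delta.reshape(K, d + 1)

    rules = [
        Rule(
            premise=rule.premise,
            coeffs=theta0[:d] + delta[i, :d],
            intercept=float(theta0[d] + delta[i, d]),
        )
        for i, rule in enumerate(rb.rules)
    ]
    fitted = RuleBase(rules, rb.input_dim, rb.output_label)
    pred = fitted.infer_batch(X)
    diagnostics = {
        "residual_rmse": float(np.sqrt(np.mean((pred - y) ** 2))),
        "ridge": float(lam),
        "rank_deficient": bool(rank_deficient),
        "underdetermined": bool(n < n_params),
    }
    return fitted, diagnostics


def _gcv_ridge(A: np.ndarray, r: np.ndarray, lambda_floor: float):
    """Ridge solve of ``A x ~ r`` with GCV-selected strength.

    Searches a log grid of ridge values (floored at ``lambda_floor``) and
    minimizes the generalized cross-validation score
    ``n ||r - A x||^2 / (n - tr(H))^2``; computed via one SVD of A.
    Returns (solution, chosen lambda, rank of A).
    """
    n = A.shape[0]
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(A.shape) * np.finfo(float).eps)) if s.size else 0
    c = U.T @ r
    out_of_span = float(max(r @ r - c @ c, 0.0))

    # exact candidate: truncated-SVD least squares, taken only when the
    # target is representable to machine precision (noiseless data) —
    # under noise it would amount to interpolation
    rss0 = float(np.sum(c[rank:] ** 2)) + out_of_span
    if rank < n and rss0 <= 1e-12 * float(r @ r):
        return Vt.T[:, :rank] @ (c[:rank] / s[:rank]), 0.0, rank

    best = None
    for lam in np.concatenate([[lambda_floor], np.geomspace(1e-6, 1e2, 25)]):
        shrink = s**2 / (s**2 + lam)
        rss = float(np.sum(((1.0 - shrink) * c) ** 2)) + out_of_span
        df = float(np.sum(shrink))
        score = n * rss / max(n - df, 1e-9) ** 2
        if best is None or score < best[0]:
            best = (score, lam)
    lam = best[1]
    x = Vt.T @ (c * s / (s**2 + lam))
    return x, lam, rank


def _premise_rule_base(
    centers: np.ndarray, sigmas: np.ndarray, input_dim: int, label: str
) -> RuleBase:
    """Rule base with given premises and zeroed consequents."""
    rules = [
        Rule(
            premise=tuple(GaussianMF(float(c), float(s)) for c, s in zip(ci, si)),
            coeffs=np.zeros(input_dim),
            intercept=0.0,
        )
        for ci, si in zip(np.atleast_2d(centers), np.atleast_2d(sigmas))
    ]
    return RuleBase(rules, input_dim, label)


def _floored(sigmas: np.ndarray) -> np.ndarray:
    return np.maximum(np.asarray(sigmas, dtype=float), SIGMA_FLOOR)


def build_sub_fis(
    train: TrainingSet,
    radius: float = 1.0 / 3.0,
    sub_params: SubtractiveParams | None = None,
) -> CorrelationModel:
    """Build a SUB-FIS correlation model (one rule base per internal coordinate).

    Per output coordinate the joint normalized (9 input + 1 output) space is
    clustered subtractively; each cluster becomes one rule whose premise
    centers are the input block of the cluster center and whose premise
    widths are ``radius * data_width / sqrt(8)`` per dimension.
    """
    if train.n_points < 2:
        raise ValueError("need at least 2 training points")
    params = sub_params or SubtractiveParams(radius=radius)
    norm = fit_normalization(train)
    Xn = norm.normalize_inputs(train.X)
    Yn = norm.normalize_outputs(train.Y)
    widths = _floored(params.radius * np.ptp(Xn, axis=0) * SIGMA_FROM_RADIUS)

    rule_bases = []
    diagnostics = []
    for j, label in enumerate(OUTPUT_LABELS):
        joint = np.column_stack([Xn, Yn[:, j]])
        result = subtractive_cluster(joint, params)
        centers_in = result.centers[:, :9]
        sigmas = np.tile(widths, (result.n_clusters, 1))
        rb = _premise_rule_base(centers_in, sigmas, 9, label)
        rb, diag = fit_consequents(rb, Xn, Yn[:, j])
        rule_bases.append(rb)
        diagnostics.append({"n_rules": rb.n_rules, **diag})
    return CorrelationModel(
        ModelKind.SUB_FIS,
        rule_bases,
        norm,
        {
            "builder": ModelKind.SUB_FIS.value,
            "n_points": train.n_points,
            "radius": params.radius,
            "per_output": diagnostics,
        },
    )


def build_fcm_fis(
    train: TrainingSet,
    radius: float = 1.0 / 3.0,
    fcm_params: FcmParams | None = None,
    sub_params: SubtractiveParams | None = None,
) -> CorrelationModel:
    """Build an FCM-FIS correlation model.

    The cluster count C comes from subtractive clustering of the joint
    space (which also provides the initial centers); fuzzy C-means then
    refines the centers.  Premise widths are the membership-weighted
    spread of the data about each center per input dimension,
    ``sigma_dj = sqrt(sum_i u_ij^m (x_id - c_jd)^2 / sum_i u_ij^m)``,
    floored at half the subtractive width ``radius * data_width / sqrt(8)``
    — on few-point clusters the raw spread can collapse to near zero, and
    a near-singular premise makes its rule dominate arbitrarily far inputs
    (the normalized firing strength is scale-free), extrapolating its
    local consequent wildly.
    """
    if train.n_points < 2:
        raise ValueError("need at least 2 training points")
    s_params = sub_params or SubtractiveParams(radius=radius)
    norm = fit_normalization(train)
    Xn = norm.normalize_inputs(train.X)
    Yn = norm.normalize_outputs(train.Y)
    width_floor = np.maximum(
        0.5 * s_params.radius * np.ptp(Xn, axis=0) * SIGMA_FROM_RADIUS, SIGMA_FLOOR
    )

    rule_bases = []
    diagnostics = []
    for j, label in enumerate(OUTPUT_LABELS):
        joint = np.column_stack([Xn, Yn[:, j]])
        seed_result = subtractive_cluster(joint, s_params)
        C = seed_result.n_clusters
        f_params = fcm_params or FcmParams(n_clusters=C)
        if f_params.n_clusters != C:
            f_params = FcmParams(
                n_clusters=C,
                fuzzifier=f_params.fuzzifier,
                eps=f_params.eps,
                max_iterations=f_params.max_iterations,
                seed=f_params.seed,
            )
        result = fcm(joint, f_params, initial_centers=seed_result.centers)
        um = result.memberships**f_params.fuzzifier
        weights = um / um.sum(axis=0, keepdims=True)  # (N, C)
        centers_in = result.centers[:, :9]
        spread = np.sqrt(
            np.einsum("nc,ncd->cd", weights, (Xn[:, None, :] - centers_in[None]) ** 2)
        )
        rb = _premise_rule_base(centers_in, np.maximum(spread, width_floor), 9, label)
        rb, diag = fit_consequents(rb, Xn, Yn[:, j])
        rule_bases.append(rb)
        diagnostics.append(
            {
                "n_rules": rb.n_rules,
                "fcm_iterations": int(result.objective_history.size),
                **diag,
            }
        )
    return CorrelationModel(
        ModelKind.FCM_FIS,
        rule_bases,
        norm,
        {
            "builder": ModelKind.FCM_FIS.value,
            "n_points": train.n_points,
            "radius": s_params.radius,
            "per_output": diagnostics,
        },
    )
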