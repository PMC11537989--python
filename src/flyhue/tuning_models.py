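"""Encoding models of chromatic responses.

Three nested stimulus->response models map a stimulus's chromatic vector
(saturation ``s``, hue angle ``theta`` relative to the neuron's preferred
direction ``p_hat``) and luminance ``l`` to a response:

* linear:       y = a_L * s * cos(theta) + b * l
* LNL:          the linear drive passed through an asymmetric saturating
                tanh (output gain ``a_NL``, asymmetry ``gamma``)
* selectivity:  y = (a_NL * s**alpha / kappa) * (exp(kappa*cos(theta)) - 1)
                + b * l  — a von Mises dependence on hue with sharpness
                ``kappa`` and a saturation exponent ``alpha``; kappa -> 0,
                alpha = 1 recovers the linear model.

Fits are weighted least squares with per-stimulus observation counts as
weights.  The selectivity model is fitted over a fixed log-spaced grid of
(kappa, alpha) with the preferred direction and the two linear coefficients
optimized at each grid point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, minimize

__all__ = [
    "KAPPA_GRID",
    "ALPHA_GRID",
    "SaturatingNonlinearity",
    "TuningFit",
    "linear_response",
    "saturating_output",
    "selectivity_response",
    "predict",
    "fit_linear",
    "fit_lnl",
    "fit_selectivity",
    "chromatic_gradient",
]

#: kappa: 20 uniform log steps in [1e-2, 1e1]; alpha: 13 in [1e-1, 1e1].
KAPPA_GRID = np.logspace(-2, 1, 20)
ALPHA_GRID = np.logspace(-1, 1, 13)


@dataclass
class SaturatingNonlinearity:
    """Asymmetric saturating tanh: output gain ``a_nl``, asymmetry ``gamma``.

    The positive branch saturates at a_nl*(1-gamma), the negative branch at
    -a_nl*(1+gamma); the small-signal slope is a_nl for every gamma.
    """

    a_nl: float = 1.0
    gamma: float = 0.0

    def __post_init__(self) -> None:
        if not -1.0 < self.gamma < 1.0:
            raise ValueError("|gamma| must be < 1")


@dataclass
class TuningFit:
    """Fitted encoding-model parameters for one neuron."""

    kind: str  # linear | lnl | selectivity
    p_hat: np.ndarray
    gain: float  # a_L (linear) or a_NL (lnl / selectivity)
    b: float
    nonlinearity: SaturatingNonlinearity | None = None
    kappa: float | None = None
    alpha: float | None = None
    r2: float | None = None
    sse: float | None = None
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Forward models
# ---------------------------------------------------------------------------

def _s_cos(chroma: np.ndarray, p_hat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    chroma = np.atleast_2d(np.asarray(chroma, dtype=float))
    s = np.linalg.norm(chroma, axis=1)
    dot = chroma @ np.asarray(p_hat, dtype=float)
    cos = np.divide(dot, s, out=np.zeros_like(dot), where=s > 0)
    return s, cos


def linear_response(chroma: np.ndarray, lum: np.ndarray, fit: TuningFit) -> np.ndarray:
    """y = a_L * (p_hat . x) + b * l."""
    s, cos = _s_cos(chroma, fit.p_hat)
    return fit.gain * s * cos + fit.b * np.asarray(lum, dtype=float)


def saturating_output(y_tilde: np.ndarray, nl: SaturatingNonlinearity) -> np.ndarray:
    """Asymmetric tanh output stage, continuous with slope a_nl at 0."""
    y_tilde = np.asarray(y_tilde, dtype=float)
    neg = nl.a_nl * (1.0 + nl.gamma) * np.tanh(y_tilde / (1.0 + nl.gamma))
    pos = nl.a_nl * (1.0 - nl.gamma) * np.tanh(y_tilde / (1.0 - nl.gamma))
    return np.where(y_tilde <= 0, neg, pos)


def selectivity_response(chroma: np.ndarray, lum: np.ndarray, fit: TuningFit) -> np.ndarray:
    """y = (a * s**alpha / kappa) * (exp(kappa cos) - 1) + b * l.

    kappa == 0 is evaluated as the analytic limit a * s**alpha * cos + b*l.
    The chromatic term vanishes at the white point (s = 0) for any alpha.
    """
    if fit.alpha is None or fit.alpha <= 0:
        raise ValueError("alpha must be positive")
    kappa = fit.kappa or 0.0
    s, cos = _s_cos(chroma, fit.p_hat)
    s_alpha = np.where(s > 0, s, 1.0) ** fit.alpha
    s_alpha = np.where(s > 0, s_alpha, 0.0)
    if kappa == 0.0:
        chromatic = fit.gain * s_alpha * cos
    else:
        chromatic = fit.gain * s_alpha / kappa * (np.exp(kappa * cos) - 1.0)
    return chromatic + fit.b * np.asarray(lum, dtype=float)


def predict(fit: TuningFit, chroma: np.ndarray, lum: np.ndarray) -> np.ndarray:
    """Evaluate any fitted model on a batch of stimuli."""
    if fit.kind == "linear":
        return linear_response(chroma, lum, fit)
    if fit.kind == "lnl":
        s, cos = _s_cos(chroma, fit.p_hat)
        drive = fit.gain * s * cos + fit.b * np.asarray(lum, dtype=float)
        return saturating_output(drive, fit.nonlinearity)
    if fit.kind == "selectivity":
        return selectivity_response(chroma, lum, fit)
    raise ValueError(f"unknown model kind {fit.kind!r}")


def chromatic_gradient(fit: TuningFit, chroma: np.ndarray, lum: float = 0.0, eps: float = 1e-5) -> np.ndarray:
    """Numerical gradient of the response w.r.t. the chromatic vector.

    The gradient is normal to the iso-response contour through ``chroma``;
    comparing its direction at different points on the same level set
    distinguishes parallel (linear) from U-shaped (selective) contours.
    """
    chroma = np.asarray(chroma, dtype=float)
    g = np.zeros_like(chroma)
    for k in range(chroma.size):
        dp = np.zeros_like(chroma)
        dp[k] = eps
        hi = predict(fit, (chroma + dp)[None, :], np.array([lum]))[0]
        lo = predict(fit, (chroma - dp)[None, :], np.array([lum]))[0]
        g[k] = (hi - lo) / (2 * eps)
    return g


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _weights(v: np.ndarray, m: np.ndarray | None) -> np.ndarray:
    return np.ones_like(v) if m is None else np.asarray(m, dtype=float)


def fit_linear(
    chroma: np.ndarray,
    lum: np.ndarray,
    v: np.ndarray,
    m: np.ndarray | None = None,
    sigma2: float = 0.0,
) -> TuningFit:
    """Weighted least squares for the linear model.

    The preferred direction is parameterized as an unconstrained 3-vector
    whose norm becomes the gain a_L; the luminance coefficient b is the
    fourth free coefficient.
    """
    chroma = np.atleast_2d(np.asarray(chroma, dtype=float))
    lum = np.asarray(lum, dtype=float)
    v = np.asarray(v, dtype=float)
    if chroma.shape[0] < 4:
        raise ValueError("need at least 4 stimuli")
    w = np.sqrt(_weights(v, m))
    design = np.column_stack([chroma, lum])
    if np.linalg.matrix_rank(design * w[:, None]) < 4:
        raise ValueError("rank-deficient design: stimuli do not span chroma and luminance")
    coef, *_ = np.linalg.lstsq(design * w[:, None], v * w, rcond=None)
    c, b = coef[:3], float(coef[3])
    a_l = float(np.linalg.norm(c))
    p_hat = c / a_l if a_l > 0 else np.array([1.0, 0.0, 0.0])
    y = design @ coef
    sse = float(np.sum(_weights(v, m) * (v - y) ** 2))
    fit = TuningFit(kind="linear", p_hat=p_hat, gain=a_l, b=b, sse=sse)
    fit.r2 = _safe_r2(y, v, m, sigma2)
    return fit


def _safe_r2(y, v, m, sigma2):
    from .metrics import noise_corrected_r2

    try:
        return noise_corrected_r2(y, v, m=m, sigma2=sigma2)
    except ValueError:
        return None


def fit_lnl(
    chroma: np.ndarray,
    lum: np.ndarray,
    v: np.ndarray,
    m: np.ndarray | None = None,
    sigma2: float = 0.0,
    max_restarts: int = 50,
    seed: int = 0,
) -> TuningFit:
    """Nonlinear weighted least squares for the LNL model.

    Jointly optimizes the linear stage (3-vector direction folded with its
    gain, plus b) and the output nonlinearity (a_NL, gamma).  Initialized at
    the linear solution with gamma = 0; seeded random restarts (up to
    ``max_restarts``) guard against poor local minima.
    """
    chroma = np.atleast_2d(np.asarray(chroma, dtype=float))
    lum = np.asarray(lum, dtype=float)
    v = np.asarray(v, dtype=float)
    weights = _weights(v, m)
    sw = np.sqrt(weights)
    lin = fit_linear(chroma, lum, v, m=m)

    def unpack(theta):
        c = theta[:3]
        b = theta[3]
        a_nl = np.exp(theta[4])
        gamma = 0.999 * np.tanh(theta[5])  # keep strictly inside (-1, 1)
        return c, b, a_nl, gamma

    def resid(theta):
        c, b, a_nl, gamma = unpack(theta)
        drive = chroma @ c + b * lum
        y = saturating_output(drive, SaturatingNonlinearity(a_nl, gamma))
        return sw * (y - v)

    scale = max(np.max(np.abs(v)), 1e-3)
    theta0 = np.concatenate([lin.gain * lin.p_hat / scale, [lin.b / scale], [np.log(scale)], [0.0]])
    best = least_squares(resid, theta0, method="lm", max_nfev=2000)
    rng = np.random.default_rng(seed)
    restarts = 0
    while best.cost > 1e-10 and restarts < max_restarts:
        # A couple of cheap perturbed restarts; stop early once stable.
        if restarts >= 3:
            break
        theta_r = theta0 * (1 + 0.3 * rng.standard_normal(theta0.shape))
        trial = least_squares(resid, theta_r, method="lm", max_nfev=2000)
        if trial.cost < best.cost * (1 - 1e-9):
            best = trial
        restarts += 1
    c, b, a_nl, gamma = unpack(best.x)
    a_lin = float(np.linalg.norm(c))
    p_hat = c / a_lin if a_lin > 0 else np.array([1.0, 0.0, 0.0])
    nl = SaturatingNonlinearity(a_nl, float(gamma))
    fit = TuningFit(
        kind="lnl",
        p_hat=p_hat,
        gain=a_lin,
        b=float(b),
        nonlinearity=nl,
        sse=float(2 * best.cost),
        converged=bool(best.success),
        diagnostics={"nfev": best.nfev, "status": best.status},
    )
    drive = chroma @ c + b * lum
    fit.r2 = _safe_r2(saturating_output(drive, nl), v, m, sigma2)
    return fit


def _grid_features(s, cos, kappa_grid, alpha_grid):
    """T[k, a, i] = s_i**alpha_a * (exp(kappa_k * cos_i) - 1) / kappa_k."""
    s_alpha = np.where(s > 0, s, 1.0)[None, :] ** alpha_grid[:, None]
    s_alpha = np.where(s[None, :] > 0, s_alpha, 0.0)
    von_mises = (np.exp(kappa_grid[:, None] * cos[None, :]) - 1.0) / kappa_grid[:, None]
    return von_mises[:, None, :] * s_alpha[None, :, :]


def _profiled_sse_grid(T, lum, v, weights):
    """Closed-form weighted LSQ of v ~ a*T + b*l for every grid point.

    T is (nk, na, n); returns (sse, a, b) arrays of shape (nk, na).
    """
    w = weights
    ll = float(np.sum(w * lum * lum))
    lv = float(np.sum(w * lum * v))
    vv = float(np.sum(w * v * v))
    tt = np.einsum("kai,i->ka", T**2, w)
    tl = np.einsum("kai,i->ka", T, w * lum)
    tv = np.einsum("kai,i->ka", T, w * v)
    det = tt * ll - tl**2
    safe = np.abs(det) > 1e-300
    a = np.where(safe, (tv * ll - tl * lv) / np.where(safe, det, 1.0), 0.0)
    b = np.where(safe, (tt * lv - tl * tv) / np.where(safe, det, 1.0), 0.0)
    if ll == 0.0:  # no luminance variation at all
        a = np.where(tt > 0, tv / np.where(tt > 0, tt, 1.0), 0.0)
        b = np.zeros_like(a)
    sse = vv - 2 * a * tv - 2 * b * lv + a**2 * tt + b**2 * ll + 2 * a * b * tl
    return sse, a, b


def _profiled_sse_at(p, chroma, lum, v, weights, kappa, alpha):
    """Profiled weighted SSE at one (kappa, alpha) for direction p (any norm)."""
    norm = np.linalg.norm(p)
    if norm == 0:
        return np.inf, np.zeros(3), 0.0, 0.0
    p_hat = p / norm
    s = np.linalg.norm(chroma, axis=1)
    cos = np.divide(chroma @ p_hat, s, out=np.zeros_like(s), where=s > 0)
    T = _grid_features(s, cos, np.array([kappa]), np.array([alpha]))[0, 0]
    sse, a, b = _profiled_sse_grid(T[None, None, :], lum, v, weights)
    return float(sse[0, 0]), p_hat, float(a[0, 0]), float(b[0, 0])


def fit_selectivity(
    chroma: np.ndarray,
    lum: np.ndarray,
    v: np.ndarray,
    m: np.ndarray | None = None,
    sigma2: float = 0.0,
    kappa_grid: np.ndarray = KAPPA_GRID,
    alpha_grid: np.ndarray = ALPHA_GRID,
    n_refine: int = 6,
) -> TuningFit:
    """Grid search over (kappa, alpha) for the nonlinear selectivity model.

    For a candidate preferred direction, the gain and luminance coefficient
    are profiled out in closed form at every grid point simultaneously; the
    direction itself is refined by quasi-Newton optimization at the
    ``n_refine`` most promising grid points, and the final grid point is the
    one with minimal weighted SSE (ties broken toward smaller kappa).
    """
    chroma = np.atleast_2d(np.asarray(chroma, dtype=float))
    lum = np.asarray(lum, dtype=float)
    v = np.asarray(v, dtype=float)
    weights = _weights(v, m)
    lin = fit_linear(chroma, lum, v, m=m)
    p0 = lin.p_hat if lin.gain > 0 else np.array([1.0, 0.0, 0.0])

    s = np.linalg.norm(chroma, axis=1)

    def grid_sweep(p_hat):
        cos = np.divide(chroma @ p_hat, s, out=np.zeros_like(s), where=s > 0)
        T = _grid_features(s, cos, kappa_grid, alpha_grid)
        return _profiled_sse_grid(T, lum, v, weights)

    sse0, _, _ = grid_sweep(p0)
    order = np.argsort(sse0, axis=None, kind="stable")
    best = None  # (sse, ik, ia, p_hat, a, b)
    tried = set()
    for flat in order[:n_refine]:
        ik, ia = np.unravel_index(flat, sse0.shape)
        kappa, alpha = float(kappa_grid[ik]), float(alpha_grid[ia])

        def objective(p, kappa=kappa, alpha=alpha):
            return _profiled_sse_at(p, chroma, lum, v, weights, kappa, alpha)[0]

        res = minimize(objective, p0, method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 400})
        p_ref = res.x / np.linalg.norm(res.x)
        key = tuple(np.round(p_ref, 6))
        if key in tried:
            continue
        tried.add(key)
        sse_ref, a_ref, b_ref = grid_sweep(p_ref)
        flat_ref = int(np.argmin(np.round(sse_ref, 12), axis=None))
        jk, ja = np.unravel_index(flat_ref, sse_ref.shape)
        cand = (float(sse_ref[jk, ja]), int(jk), int(ja), p_ref,
                float(a_ref[jk, ja]), float(b_ref[jk, ja]))
        if best is None or cand[0] < best[0] * (1 - 1e-12) or (
            np.isclose(cand[0], best[0], rtol=1e-9) and cand[1] < best[1]
        ):
            best = cand
    sse, ik, ia, p_hat, a, b = best
    if a < 0:  # flip direction so the gain is positive
        sse2, p2, a2, b2 = _profiled_sse_at(-p_hat, chroma, lum, v, weights,
                                            float(kappa_grid[ik]), float(alpha_grid[ia]))
        if sse2 <= sse * (1 + 1e-9):
            p_hat, a, b, sse = p2, a2, b2, sse2
    fit = TuningFit(
        kind="selectivity",
        p_hat=p_hat,
        gain=float(a),
        b=float(b),
        kappa=float(kappa_grid[ik]),
        alpha=float(alpha_grid[ia]),
        sse=float(sse),
    )
    y = selectivity_response(chroma, lum, fit)
    fit.r2 = _safe_r2(y, v, m, sigma2)
    return fit
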