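"""Connectome-constrained recurrent circuit model of the medulla color circuit.

Twelve rate units — pR7, yR7, pR8, yR8, the horizontal cell Dm9, the
amacrine-like pDm8/yDm8, and the transmedullary outputs Tm5a, Tm5b, Tm5c and
the two Tm20 subtypes — interact through signed weights taken from synaptic
counts.  Each unit obeys

    tau_a dy_a/dt = -y_a + f( g_a ( sum_b w_ab y_b
                                    + sum_mu j_amu X_mu + p_a x_0 ) )

with f the asymmetric saturating tanh (unit output gain, per-neuron
asymmetry gamma; Dm9's gamma fixed at 0), X the log relative opsin captures,
and x_0 the log relative Rh1 capture (the achromatic R1-6 drive).  All
weights onto a neuron are normalized so |w| and the opsin input j sum to 1.

Responses are the fixed points of the dynamics, found by Anderson
acceleration; parameters are fitted by Adam on a negative-correlation loss,
with gradients obtained by implicit differentiation through the fixed point
(never by unrolling solver iterations).  Fitting proceeds in three stages —
photoreceptors+Dm9, then the Dm8 circuit, then the Tm circuit — and the
module provides the perturbation experiments: output blocking of single Tm
neurons (TeNT), removal of Tm-Tm recurrence, random-weight null
distributions, free-sign search for the recurrent Tm edges, and the
pale/yellow mixing of the two Tm20 subtypes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "NEURONS",
    "PHOTORECEPTORS",
    "DM8S",
    "TMS",
    "OPSIN_OF_PHOTORECEPTOR",
    "CircuitSpec",
    "CircuitTemplate",
    "FitResult",
    "FitConfig",
    "ConnectivityTable",
    "normalize_weights",
    "modified_tanh",
    "steady_state",
    "steady_state_batch",
    "correlation_loss",
    "staged_fit",
    "refit_tent",
    "sign_search",
    "ablate_recurrence",
    "simulate_tent",
    "random_weight_null",
    "mix_tm20",
    "summarize_connectivity",
    "free_parameter_audit",
    "example_connectivity",
    "example_template",
    "example_spec",
]

NEURONS = (
    "pR7", "yR7", "pR8", "yR8", "Dm9",
    "pDm8", "yDm8", "Tm5a", "Tm5b", "Tm5c", "pTm20", "yTm20",
)
PHOTORECEPTORS = (0, 1, 2, 3)
DM9 = 4
DM8S = (5, 6)
TMS = (7, 8, 9, 10, 11)
IDX = {name: k for k, name in enumerate(NEURONS)}

#: Which opsin (index into Rh3, Rh4, Rh5, Rh6) drives each photoreceptor.
OPSIN_OF_PHOTORECEPTOR = {0: 0, 1: 1, 2: 2, 3: 3}  # pR7-Rh3, yR7-Rh4, pR8-Rh5, yR8-Rh6


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class CircuitSpec:
    """A fully specified 12-neuron circuit (weights, gains, nonlinearities)."""

    w: np.ndarray  # (12, 12) signed normalized weights, w[a, b]: b -> a
    j: np.ndarray  # (12, 4) opsin input weights (photoreceptor rows only)
    p: np.ndarray  # (12,) achromatic R1-6 input weights
    g: np.ndarray  # (12,) gains
    gamma: np.ndarray  # (12,) tanh asymmetries (Dm9 fixed at 0)
    tau: np.ndarray = field(default_factory=lambda: np.full(12, 0.05))  # s

    def copy(self) -> "CircuitSpec":
        return CircuitSpec(
            w=self.w.copy(), j=self.j.copy(), p=self.p.copy(),
            g=self.g.copy(), gamma=self.gamma.copy(), tau=self.tau.copy(),
        )

    def row_norms(self) -> np.ndarray:
        """sum_b |w_ab| + sum_mu j_amu per neuron (1 for a valid spec)."""
        return np.abs(self.w).sum(axis=1) + self.j.sum(axis=1)


@dataclass
class ConnectivityTable:
    """Edge list of synapse counts (pre -> post, direct or disynaptic)."""

    data: pd.DataFrame  # columns: pre, post, count, path, sign

    def __post_init__(self) -> None:
        required = {"pre", "post", "count"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"connectivity table needs columns {sorted(required)}")
        if (self.data["count"] < 0).any():
            raise ValueError("synapse counts must be nonnegative")

    def count_matrix(self, neurons: tuple[str, ...] = NEURONS) -> np.ndarray:
        """(n, n) matrix of counts onto each row neuron, direct + disynaptic."""
        n = len(neurons)
        pos = {name: k for k, name in enumerate(neurons)}
        mat = np.zeros((n, n))
        for _, row in self.data.iterrows():
            if row["pre"] in pos and row["post"] in pos:
                mat[pos[row["post"]], pos[row["pre"]]] += row["count"]
        return mat

    def sign_matrix(self, neurons: tuple[str, ...] = NEURONS, default: float = 1.0) -> np.ndarray:
        n = len(neurons)
        pos = {name: k for k, name in enumerate(neurons)}
        signs = np.full((n, n), default)
        if "sign" not in self.data.columns:
            return signs
        for _, row in self.data.iterrows():
            if row["pre"] in pos and row["post"] in pos and row["sign"] in (-1, 1, -1.0, 1.0):
                signs[pos[row["post"]], pos[row["pre"]]] = float(row["sign"])
        return signs


def normalize_weights(
    counts: np.ndarray,
    signs: np.ndarray | None = None,
    j_counts: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Row-normalize synaptic counts so |w| (+ j) sums to 1 per neuron.

    ``counts[a, b]`` is the synapse count from b onto a; ``signs`` the signed
    pattern applied after scaling.  When ``j_counts`` (opsin input
    magnitudes) is given it participates in the row normalization.
    """
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1)
    if j_counts is not None:
        j_counts = np.asarray(j_counts, dtype=float)
        totals = totals + j_counts.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("every modeled neuron needs at least one nonzero input")
    w = counts / totals[:, None]
    if signs is not None:
        w = w * np.asarray(signs, dtype=float)
    j = None if j_counts is None else j_counts / totals[:, None]
    return w, j


# ---------------------------------------------------------------------------
# Nonlinearity and fixed-point solver
# ---------------------------------------------------------------------------

def modified_tanh(z: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """Asymmetric tanh with unit small-signal slope, f(0) = 0."""
    gm = 1.0 + gamma
    gp = 1.0 - gamma
    return np.where(z <= 0, gm * np.tanh(z / gm), gp * np.tanh(z / gp))


def _tanh_prime(z: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    u = np.where(z <= 0, z / (1.0 + gamma), z / (1.0 - gamma))
    return 1.0 - np.tanh(u) ** 2


def _tanh_dgamma(z: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    # d/dgamma of modified_tanh at fixed z.
    u_neg = z / (1.0 + gamma)
    u_pos = z / (1.0 - gamma)
    neg = np.tanh(u_neg) - u_neg * (1.0 - np.tanh(u_neg) ** 2)
    pos = -np.tanh(u_pos) + u_pos * (1.0 - np.tanh(u_pos) ** 2)
    return np.where(z <= 0, neg, pos)


def _drive(spec: CircuitSpec, y: np.ndarray, X: np.ndarray, x0: np.ndarray) -> np.ndarray:
    """Preactivation zeta = W y + j X + p x0 for a batch: y (n,12), X (n,4)."""
    return y @ spec.w.T + X @ spec.j.T + np.multiply.outer(x0, spec.p)


def _apply(spec: CircuitSpec, y: np.ndarray, X: np.ndarray, x0: np.ndarray) -> np.ndarray:
    return modified_tanh(spec.g * _drive(spec, y, X, x0), spec.gamma)


def steady_state_batch(
    spec: CircuitSpec,
    X: np.ndarray,
    x0: np.ndarray | float = 0.0,
    tol: float = 1e-4,
    max_iter: int = 500,
    memory: int = 5,
    damping: float = 1.0,
) -> np.ndarray:
    """Fixed points y = f(g(Wy + jX + p x0)) for a batch of stimuli.

    Uses Anderson acceleration (type II, memory ``memory``, damping 1.0)
    from a zero initial iterate, vectorized across stimuli; iteration stops
    when the sup-norm residual of every stimulus is below ``tol``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    x0 = np.broadcast_to(np.asarray(x0, dtype=float), (n,)).astype(float)
    y = np.zeros((n, 12))
    r = _apply(spec, y, X, x0) - y
    ys = [y]
    rs = [r]
    res_norm = np.max(np.abs(r))
    best_y, best_norm = y, res_norm
    stall = 0
    for it in range(max_iter):
        if res_norm < tol:
            return y
        mk = min(memory, len(rs) - 1)
        if mk == 0:
            y_new = y + damping * r
        else:
            dR = np.stack([rs[-1] - rs[-2 - i] for i in range(mk)], axis=2)  # (n,12,mk)
            dY = np.stack([ys[-1] - ys[-2 - i] for i in range(mk)], axis=2)
            G = np.einsum("nik,nil->nkl", dR, dR)
            G += 1e-12 * np.eye(mk)[None]
            rhs = np.einsum("nik,ni->nk", dR, rs[-1])
            try:
                coef = np.linalg.solve(G, rhs[..., None])[..., 0]
            except np.linalg.LinAlgError:
                coef = np.zeros((n, mk))
            correction = np.einsum("nik,nk->ni", dY + damping * dR, coef)
            y_new = y + damping * r - correction
        y = y_new
        r = _apply(spec, y, X, x0) - y
        res_norm = np.max(np.abs(r))
        if res_norm < best_norm * (1 - 1e-3):
            best_y, best_norm, stall = y, res_norm, 0
        else:
            stall += 1
            if stall >= 25:
                break  # the accelerated map is cycling; switch to Newton
        ys.append(y)
        rs.append(r)
        if len(rs) > memory + 1:
            ys.pop(0)
            rs.pop(0)
    if res_norm < tol:
        return y
    # Root-finding phase for the stimuli the accelerated map cannot settle.
    # A fixed point always exists (f maps into a bounded box) but can repel
    # the Picard map when recurrent inhibition is strong; the residual root
    # is then found directly, per stimulus, with the exact 12x12 Jacobian.
    from scipy.optimize import root

    y = best_y.copy()
    r = _apply(spec, y, X, x0) - y
    unresolved = np.where(np.max(np.abs(r), axis=1) >= tol)[0]
    if unresolved.size:
        # Heavily damped Picard sweep: a damping factor beta maps a Jacobian
        # eigenvalue lam to 1 - beta + beta*lam, which stabilizes the
        # oscillatory (lam < -1) fixed points that defeat the plain map.
        yd = y[unresolved]
        Xd, x0d = X[unresolved], x0[unresolved]
        for _ in range(2000):
            rd = _apply(spec, yd, Xd, x0d) - yd
            if np.max(np.abs(rd)) < tol:
                break
            yd = yd + 0.25 * rd
        y[unresolved] = yd
        r = _apply(spec, y, X, x0) - y
        unresolved = np.where(np.max(np.abs(r), axis=1) >= tol)[0]
    for i in unresolved:
        Xi, x0i = X[i : i + 1], x0[i : i + 1]

        def residual_and_jac(yi):
            yi = yi[None, :]
            ri = _apply(spec, yi, Xi, x0i) - yi
            z = spec.g * _drive(spec, yi, Xi, x0i)
            fp = _tanh_prime(z, spec.gamma)
            J = fp[0, :, None] * (spec.g[:, None] * spec.w)
            return ri[0], J - np.eye(12)

        rng = np.random.default_rng(12345)  # fixed: the solve stays deterministic
        starts = [y[i], np.zeros(12)] + [rng.uniform(-1.5, 1.5, 12) for _ in range(30)]
        sol = None
        for start in starts:
            trial = root(residual_and_jac, start, jac=True, method="hybr",
                         options={"xtol": min(tol, 1e-10)})
            if np.max(np.abs(trial.fun)) < tol:
                sol = trial.x
                break
        if sol is None:
            raise RuntimeError(
                f"fixed-point solve did not converge for stimulus {i}: "
                f"residual {np.max(np.abs(trial.fun)):.3g}"
            )
        y[i] = sol
    return y


def steady_state(
    spec: CircuitSpec,
    X: np.ndarray,
    x0: float = 0.0,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> np.ndarray:
    """Steady-state 12-vector for a single stimulus."""
    return steady_state_batch(spec, np.asarray(X)[None, :], np.array([x0]), tol=tol, max_iter=max_iter)[0]


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def correlation_loss(
    y: np.ndarray,
    v: np.ndarray,
    m: np.ndarray | None = None,
    neuron_mask: np.ndarray | None = None,
) -> float:
    """L = -sum_a corr_a with the m-weighted uncentered correlation per neuron.

    ``y`` and ``v`` are (n_stimuli, n_neurons).  Neurons with zero response
    norm (in y or v) are excluded with a warning.
    """
    loss, _ = _correlation_loss_grad(y, v, m, neuron_mask, want_grad=False)
    return loss


def _correlation_loss_grad(y, v, m=None, neuron_mask=None, want_grad=True):
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    n, k = y.shape
    m = np.ones(n) if m is None else np.asarray(m, dtype=float)
    mask = np.ones(k, dtype=bool) if neuron_mask is None else np.asarray(neuron_mask, dtype=bool)
    sy = np.sqrt(np.einsum("i,ia->a", m, y**2))
    sv = np.sqrt(np.einsum("i,ia->a", m, v**2))
    dead = (sy == 0) | (sv == 0)
    if np.any(dead & mask):
        import warnings

        warnings.warn("excluding zero-norm neurons from correlation loss", stacklevel=3)
    use = mask & ~dead
    cross = np.einsum("i,ia,ia->a", m, y, v)
    corr = np.zeros(k)
    corr[use] = cross[use] / (sy[use] * sv[use])
    loss = -float(corr[use].sum())
    if not want_grad:
        return loss, None
    grad = np.zeros_like(y)
    grad[:, use] = -(
        m[:, None] * v[:, use] / (sy[use] * sv[use])
        - corr[use] * m[:, None] * y[:, use] / sy[use] ** 2
    )
    return loss, grad


# ---------------------------------------------------------------------------
# Template: fixed structure + parameter vector -> CircuitSpec
# ---------------------------------------------------------------------------

#: Parameter slot layout (stage, name, size).  The unconstrained vector theta
#: maps through exp / tanh / sigmoid transforms to the natural parameters.
_PARAM_SLOTS = [
    (1, "log_g_pr", 1),       # shared photoreceptor gain
    (1, "log_g_dm9", 1),      # Dm9 gain
    (1, "logit_j", 1),        # shared opsin-input magnitude, in (0, 1)
    (1, "atanh_gamma_pr", 4),
    (2, "p_dm8", 2),          # R1-6 weight onto pDm8/yDm8 (positive, exp)
    (2, "logit_d_dm8", 2),    # Dm8<->Dm8 weight proportion, in (0, 1)
    (2, "log_g_dm8", 1),      # shared Dm8 gain
    (2, "atanh_gamma_dm8", 2),
    (3, "p_tm", 5),           # R1-6 weight onto each Tm (free sign)
    (3, "log_g_tm", 5),
    (3, "atanh_gamma_tm", 5),
]


def _slot_index() -> dict[str, slice]:
    out, start = {}, 0
    for _, name, size in _PARAM_SLOTS:
        out[name] = slice(start, start + size)
        start += size
    return out


_SLOTS = _slot_index()
N_PARAMS = sum(size for _, _, size in _PARAM_SLOTS)


def free_parameter_audit() -> dict[str, int]:
    """Count the free parameters of the staged circuit fit by category."""
    audit = {"gains": 0, "gamma": 0, "opsin_input": 0, "achromatic": 0, "dm8_weights": 0}
    for _, name, size in _PARAM_SLOTS:
        if name.startswith("log_g"):
            audit["gains"] += size
        elif "gamma" in name:
            audit["gamma"] += size
        elif name == "logit_j":
            audit["opsin_input"] += size
        elif name.startswith("p_"):
            audit["achromatic"] += size
        elif name == "logit_d_dm8":
            audit["dm8_weights"] += size
    audit["total"] = sum(audit.values())
    return audit


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class CircuitTemplate:
    """Fixed circuit structure plus the staged free-parameter mapping.

    ``w_base`` holds signed, row-normalized count weights.  Photoreceptor
    rows are scaled by (1 - j); Dm8 rows mix their fixed R7 input with the
    free recurrent Dm8 weight (proportion d); Dm9 and Tm rows are used
    as-is.  This keeps sum|w| + sum j = 1 exactly for every parameter value.
    """

    w_base: np.ndarray  # (12, 12) signed, each constrained row sums to |.| = 1
    dm8_partner: dict[int, int] = field(
        default_factory=lambda: {DM8S[0]: DM8S[1], DM8S[1]: DM8S[0]}
    )
    theta0: np.ndarray = field(default_factory=lambda: np.zeros(N_PARAMS))
    tau: np.ndarray = field(default_factory=lambda: np.full(12, 0.05))

    def build_spec(self, theta: np.ndarray) -> CircuitSpec:
        theta = np.asarray(theta, dtype=float)
        j_mag = _sigmoid(theta[_SLOTS["logit_j"]])[0]
        d = _sigmoid(theta[_SLOTS["logit_d_dm8"]])
        w = self.w_base.copy()
        jmat = np.zeros((12, 4))
        for a in PHOTORECEPTORS:
            w[a] = (1.0 - j_mag) * self.w_base[a]
            jmat[a, OPSIN_OF_PHOTORECEPTOR[a]] = j_mag
        for k, a in enumerate(DM8S):
            partner = self.dm8_partner[a]
            row = (1.0 - d[k]) * self.w_base[a]
            row[partner] = -d[k]  # indirect Dm8<->Dm8 coupling is inhibitory
            w[a] = row
        g = np.empty(12)
        g[list(PHOTORECEPTORS)] = np.exp(theta[_SLOTS["log_g_pr"]])[0]
        g[DM9] = np.exp(theta[_SLOTS["log_g_dm9"]])[0]
        g[list(DM8S)] = np.exp(theta[_SLOTS["log_g_dm8"]])[0]
        g[list(TMS)] = np.exp(theta[_SLOTS["log_g_tm"]])
        gamma = np.zeros(12)
        gamma[list(PHOTORECEPTORS)] = np.tanh(theta[_SLOTS["atanh_gamma_pr"]])
        gamma[list(DM8S)] = np.tanh(theta[_SLOTS["atanh_gamma_dm8"]])
        gamma[list(TMS)] = np.tanh(theta[_SLOTS["atanh_gamma_tm"]])
        p = np.zeros(12)
        p[list(DM8S)] = np.exp(theta[_SLOTS["p_dm8"]])  # R1-6 onto Dm8 positive
        p[list(TMS)] = theta[_SLOTS["p_tm"]]  # free sign
        return CircuitSpec(w=w, j=jmat, p=p, g=g, gamma=gamma, tau=self.tau.copy())

    def stage_mask(self, stage: int) -> np.ndarray:
        mask = np.zeros(N_PARAMS, dtype=bool)
        for st, name, _ in _PARAM_SLOTS:
            if st == stage:
                mask[_SLOTS[name]] = True
        return mask

    def with_tm_weights(self, rows: dict[int, np.ndarray]) -> "CircuitTemplate":
        """Copy of the template with replaced (signed, normalized) Tm rows."""
        w = self.w_base.copy()
        for a, row in rows.items():
            w[a] = row
        return replace(self, w_base=w)


# ---------------------------------------------------------------------------
# Implicit gradients
# ---------------------------------------------------------------------------

def _theta_gradient(template, theta, spec, X, x0, y, adj):
    """dL/dtheta given per-stimulus adjoints ``adj`` (n, 12).

    ``adj`` solves (I - J^T) lambda = dL/dy at the fixed point; here we
    accumulate lambda^T dF/dtheta analytically for every parameter slot,
    including the transform Jacobians.
    """
    n = X.shape[0]
    zeta = _drive(spec, y, X, x0)
    z = spec.g * zeta
    fp = _tanh_prime(z, spec.gamma)
    grad = np.zeros(N_PARAMS)

    lam_f = adj * fp  # (n, 12): lambda_a * f'(z_a)

    # Gains (log-parameterized: dg/dtheta = g).
    dg = np.einsum("na,na->a", lam_f, zeta) * spec.g
    grad[_SLOTS["log_g_pr"]] = dg[list(PHOTORECEPTORS)].sum()
    grad[_SLOTS["log_g_dm9"]] = dg[DM9]
    grad[_SLOTS["log_g_dm8"]] = dg[list(DM8S)].sum()
    grad[_SLOTS["log_g_tm"]] = dg[list(TMS)]

    # Gammas (tanh-parameterized: dgamma/dtheta = 1 - gamma^2).
    dgam = np.einsum("na->a", adj * _tanh_dgamma(z, spec.gamma)) * (1.0 - spec.gamma**2)
    grad[_SLOTS["atanh_gamma_pr"]] = dgam[list(PHOTORECEPTORS)]
    grad[_SLOTS["atanh_gamma_dm8"]] = dgam[list(DM8S)]
    grad[_SLOTS["atanh_gamma_tm"]] = dgam[list(TMS)]

    # Achromatic inputs p.
    dp = np.einsum("na,na,n->a", lam_f, spec.g[None, :].repeat(n, 0), x0)
    grad[_SLOTS["p_dm8"]] = dp[list(DM8S)] * spec.p[list(DM8S)]  # exp transform
    grad[_SLOTS["p_tm"]] = dp[list(TMS)]

    # Shared opsin input j (sigmoid transform).
    j_mag = _sigmoid(theta[_SLOTS["logit_j"]])[0]
    dj = 0.0
    for a in PHOTORECEPTORS:
        dzeta_dj = -(template.w_base[a] @ y.T) + X[:, OPSIN_OF_PHOTORECEPTOR[a]]
        dj += float(np.sum(lam_f[:, a] * spec.g[a] * dzeta_dj))
    grad[_SLOTS["logit_j"]] = dj * j_mag * (1.0 - j_mag)

    # Dm8 recurrent proportions d (sigmoid transform).
    d = _sigmoid(theta[_SLOTS["logit_d_dm8"]])
    dd = np.zeros(2)
    for k, a in enumerate(DM8S):
        partner = template.dm8_partner[a]
        dzeta_dd = -(template.w_base[a] @ y.T) - y[:, partner]
        dd[k] = float(np.sum(lam_f[:, a] * spec.g[a] * dzeta_dd))
    grad[_SLOTS["logit_d_dm8"]] = dd * d * (1.0 - d)
    return grad


def loss_and_grad(
    template: CircuitTemplate,
    theta: np.ndarray,
    X: np.ndarray,
    x0: np.ndarray,
    v: np.ndarray,
    m: np.ndarray | None = None,
    neuron_mask: np.ndarray | None = None,
    tol: float = 1e-6,
) -> tuple[float, np.ndarray]:
    """Correlation loss and its implicit gradient w.r.t. theta.

    The fixed point is treated as an implicit function of the parameters:
    the adjoint solves (I - J)^T lambda = dL/dy with J the Jacobian of the
    update map at the fixed point, and gradients never differentiate the
    solver's iteration path.
    """
    spec = template.build_spec(theta)
    X = np.atleast_2d(X)
    n = X.shape[0]
    x0 = np.broadcast_to(np.asarray(x0, dtype=float), (n,)).astype(float)
    y = steady_state_batch(spec, X, x0, tol=tol)
    loss, dLdy = _correlation_loss_grad(y, v, m, neuron_mask)
    z = spec.g * _drive(spec, y, X, x0)
    fp = _tanh_prime(z, spec.gamma)
    # J[n, a, b] = f'(z_a) g_a w_ab ; solve (I - J)^T lambda = dL/dy per stimulus.
    J = fp[:, :, None] * (spec.g[:, None] * spec.w)[None, :, :]
    A = np.eye(12)[None] - np.transpose(J, (0, 2, 1))
    adj = np.linalg.solve(A, dLdy[:, :, None])[:, :, 0]
    grad = _theta_gradient(template, theta, spec, X, x0, y, adj)
    return loss, grad


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class FitConfig:
    """Optimization schedule for the staged circuit fit."""

    batch_size: int = 64
    epochs: int = 100
    learning_rate: float = 0.001
    early_stop_tol: float = 1e-7
    patience: int = 10
    fixed_point_tol: float = 1e-6
    seed: int = 0
    restarts: int = 2  # extra jittered Adam runs per stage; best loss wins


@dataclass
class FitResult:
    spec: CircuitSpec
    theta: np.ndarray
    loss_trajectory: list
    r2: dict
    stages: list


_STAGE_NEURONS = {
    1: list(PHOTORECEPTORS) + [DM9],
    2: list(DM8S),
    3: list(TMS),
}


def _adam_stage(template, theta, free_mask, X, x0, v, m, neuron_mask, cfg, rng):
    n = X.shape[0]
    mt = np.zeros(N_PARAMS)
    vt = np.zeros(N_PARAMS)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    history = []
    best_loss = np.inf
    stall = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            _, grad = loss_and_grad(
                template, theta, X[idx], x0[idx], v[idx],
                None if m is None else m[idx], neuron_mask, tol=cfg.fixed_point_tol,
            )
            grad = grad * free_mask
            t += 1
            mt = beta1 * mt + (1 - beta1) * grad
            vt = beta2 * vt + (1 - beta2) * grad**2
            mhat = mt / (1 - beta1**t)
            vhat = vt / (1 - beta2**t)
            theta = theta - cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
        full_loss, _ = loss_and_grad(
            template, theta, X, x0, v, m, neuron_mask, tol=cfg.fixed_point_tol
        )
        history.append(full_loss)
        if full_loss > best_loss - cfg.early_stop_tol:
            stall += 1
            if stall >= cfg.patience:
                break
        else:
            stall = 0
        best_loss = min(best_loss, full_loss)
    return theta, history


def staged_fit(
    template: CircuitTemplate,
    X: np.ndarray,
    x0: np.ndarray,
    v: np.ndarray,
    m: np.ndarray | None = None,
    sigma2: float = 0.0,
    config: FitConfig | None = None,
    stages: tuple[int, ...] = (1, 2, 3),
    theta0: np.ndarray | None = None,
    free_mask_override: np.ndarray | None = None,
) -> FitResult:
    """Three-stage fit of the circuit model to response data.

    Stage 1 fits the photoreceptor-Dm9 subcircuit (shared photoreceptor
    gain, Dm9 gain, shared opsin-input magnitude, photoreceptor
    asymmetries); stage 2 the Dm8 circuit (R1-6 weights, Dm8<->Dm8
    proportions, shared gain, asymmetries); stage 3 the Tm circuit (per-Tm
    R1-6 weight, gain and asymmetry), with all count-derived weights fixed.
    Each stage minimizes the summed negative correlation over that stage's
    neurons by mini-batch Adam with implicit fixed-point gradients.
    """
    cfg = config or FitConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    x0 = np.broadcast_to(np.asarray(x0, dtype=float), (n,)).astype(float)
    v = np.asarray(v, dtype=float)
    rng = np.random.default_rng(cfg.seed)
    theta = template.theta0.copy() if theta0 is None else np.asarray(theta0, dtype=float).copy()
    trajectory = []
    stage_labels = []
    for stage in stages:
        neuron_mask = np.zeros(12, dtype=bool)
        neuron_mask[_STAGE_NEURONS[stage]] = True
        has_data = ~np.all(v == 0, axis=0)
        neuron_mask &= has_data
        if not neuron_mask.any():
            raise ValueError(f"no response data for stage {stage} neurons")
        free = template.stage_mask(stage) if free_mask_override is None else free_mask_override
        best = None
        for attempt in range(1 + max(cfg.restarts, 0)):
            start = theta.copy()
            if attempt > 0:  # jitter only the stage's free parameters
                start[free] += 0.15 * rng.standard_normal(int(free.sum()))
            try:
                cand_theta, history = _adam_stage(
                    template, start, free, X, x0, v, m, neuron_mask, cfg, rng
                )
            except RuntimeError:
                continue  # unstable start: the fixed point solve failed
            if best is None or history[-1] < best[1][-1]:
                best = (cand_theta, history)
        if best is None:
            raise RuntimeError(f"all optimization attempts failed in stage {stage}")
        theta, history = best
        trajectory.append(history)
        stage_labels.append(f"stage{stage}")
    spec = template.build_spec(theta)
    y = steady_state_batch(spec, X, x0, tol=cfg.fixed_point_tol)
    from .metrics import noise_corrected_r2

    r2 = {}
    for a, name in enumerate(NEURONS):
        if np.any(v[:, a] != 0) and np.any(y[:, a] != 0):
            r2[name] = noise_corrected_r2(y[:, a], v[:, a], m=m, sigma2=sigma2)
    return FitResult(spec=spec, theta=theta, loss_trajectory=trajectory, r2=r2, stages=stage_labels)


def refit_tent(
    template: CircuitTemplate,
    theta: np.ndarray,
    target: str,
    X: np.ndarray,
    x0: np.ndarray,
    v: np.ndarray,
    m: np.ndarray | None = None,
    config: FitConfig | None = None,
) -> FitResult:
    """Companion refit after TeNT: only the target's gain and asymmetry move.

    The template must already carry the silenced outgoing weights (see
    :func:`simulate_tent`); the fit mirrors the two-free-parameter refit
    used for the TeNT experiments.
    """
    a = IDX[target]
    if a not in TMS:
        raise ValueError("TeNT refit targets must be Tm neurons")
    k = list(TMS).index(a)
    free = np.zeros(N_PARAMS, dtype=bool)
    gslice = _SLOTS["log_g_tm"]
    gamslice = _SLOTS["atanh_gamma_tm"]
    free[gslice.start + k] = True
    free[gamslice.start + k] = True
    return staged_fit(
        template, X, x0, v, m=m, config=config, stages=(3,), theta0=theta,
        free_mask_override=free,
    )


def sign_search(
    template: CircuitTemplate,
    free_edges: list[tuple[str, str]],
    X: np.ndarray,
    x0: np.ndarray,
    v: np.ndarray,
    m: np.ndarray | None = None,
    budget: int = 64,
    seed: int = 0,
    config: FitConfig | None = None,
    theta0: np.ndarray | None = None,
) -> tuple[dict, float, list]:
    """Search sign assignments for free-sign recurrent Tm edges.

    Exhaustive when 2**k fits the evaluation budget, otherwise a seeded
    random sample of assignments; each candidate re-runs the Tm fitting
    stage and the best post-fit loss wins.  Returns
    (assignment, best_loss, all_results).
    """
    k = len(free_edges)
    rng = np.random.default_rng(seed)
    if 2**k <= budget:
        candidates = list(itertools.product((1.0, -1.0), repeat=k))
    else:
        seen = set()
        while len(seen) < budget:
            seen.add(tuple(rng.choice([1.0, -1.0], size=k)))
        candidates = sorted(seen)
    results = []
    best = None
    X = np.atleast_2d(X)
    n = X.shape[0]
    x0b = np.broadcast_to(np.asarray(x0, dtype=float), (n,)).astype(float)
    for signs in candidates:
        w = template.w_base.copy()
        for (pre, post), s in zip(free_edges, signs):
            a, b = IDX[post], IDX[pre]
            w[a, b] = s * abs(w[a, b])
        trial = replace(template, w_base=w)
        fit = staged_fit(trial, X, x0b, v, m=m, config=config, stages=(3,), theta0=theta0)
        mask = np.zeros(12, dtype=bool)
        mask[list(TMS)] = True
        y = steady_state_batch(fit.spec, X, x0b, tol=(config or FitConfig()).fixed_point_tol)
        loss = correlation_loss(y, v, m=m, neuron_mask=mask & ~np.all(v == 0, axis=0))
        results.append((dict(zip(free_edges, signs)), loss))
        if best is None or loss < best[1]:
            best = (dict(zip(free_edges, signs)), loss)
    return best[0], best[1], results


# ---------------------------------------------------------------------------
# Perturbations and controls
# ---------------------------------------------------------------------------

def ablate_recurrence(spec: CircuitSpec) -> CircuitSpec:
    """Zero all Tm->Tm weights (direct + disynaptic); no renormalization."""
    out = spec.copy()
    tm = np.asarray(TMS)
    out.w[np.ix_(tm, tm)] = 0.0
    return out


def simulate_tent(spec: CircuitSpec, target: str) -> CircuitSpec:
    """Block the synaptic output of one Tm neuron (TeNT).

    Outgoing weights from ``target`` are zeroed; the neuron keeps its inputs
    and continues to respond.
    """
    a = IDX.get(target)
    if a is None or a not in TMS:
        raise ValueError("TeNT targets must be Tm neurons")
    out = spec.copy()
    out.w[:, a] = 0.0
    return out


def random_weight_null(
    template: CircuitTemplate,
    X: np.ndarray,
    x0: np.ndarray,
    v: np.ndarray,
    m: np.ndarray | None = None,
    sigma2: float = 0.0,
    n_draws: int = 200,
    seed: int = 0,
    config: FitConfig | None = None,
    theta0: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Null distribution of mean Tm R^2 under random (non-connectomic) weights.

    Per draw, the magnitudes of all inputs onto the Tm neurons are replaced
    by standard-uniform samples (sign pattern kept), rows renormalized, and
    the Tm fitting stage re-run; the mean noise-corrected R^2 over Tm
    neurons with data is recorded.  Returns (distribution, 95th percentile).
    """
    rng = np.random.default_rng(seed)
    dist = np.empty(n_draws)
    X = np.atleast_2d(X)
    n = X.shape[0]
    x0b = np.broadcast_to(np.asarray(x0, dtype=float), (n,)).astype(float)
    for draw in range(n_draws):
        rows = {}
        for a in TMS:
            base = template.w_base[a]
            mask = base != 0
            mags = rng.uniform(size=mask.sum())
            row = np.zeros(12)
            row[mask] = np.sign(base[mask]) * mags / mags.sum()
            rows[a] = row
        trial = template.with_tm_weights(rows)
        fit = staged_fit(trial, X, x0b, v, m=m, sigma2=sigma2, config=config,
                         stages=(3,), theta0=theta0)
        tm_r2 = [fit.r2[NEURONS[a]] for a in TMS if NEURONS[a] in fit.r2]
        dist[draw] = float(np.mean(tm_r2))
    return dist, float(np.percentile(dist, 95))


def mix_tm20(y_ptm20: np.ndarray, y_ytm20: np.ndarray) -> np.ndarray:
    """Column-weighted Tm20 response: 1/3 pale + 2/3 yellow."""
    y_ptm20 = np.asarray(y_ptm20, dtype=float)
    y_ytm20 = np.asarray(y_ytm20, dtype=float)
    if y_ptm20.shape != y_ytm20.shape:
        raise ValueError("pTm20 and yTm20 responses must share stimulus index")
    return y_ptm20 / 3.0 + 2.0 * y_ytm20 / 3.0


def summarize_connectivity(
    table: ConnectivityTable | pd.DataFrame,
    seed_neurons: set | None = None,
    input_threshold: int = 2,
    output_threshold: int = 4,
    total_postsynaptic_sites: int | None = None,
    total_presynaptic_sites: int | None = None,
) -> dict:
    """Input/output site accounting for a set of reconstructed seed neurons.

    Inputs are edges onto a seed neuron with more than ``input_threshold``
    synapses; outputs are edges from a seed neuron with more than
    ``output_threshold`` synapses.  Percentages are relative to the supplied
    totals of post-/presynaptic sites (identified + unidentified) when
    given, else to the table's own totals.
    """
    df = table.data if isinstance(table, ConnectivityTable) else table
    if df.empty:
        return {
            "input_sites": 0, "output_sites": 0,
            "input_partners": 0, "output_partners": 0,
            "input_percentage": 0.0, "output_percentage": 0.0,
        }
    if seed_neurons is None:
        seed_neurons = set(df["post"]).union(df["pre"])
    inputs = df[df["post"].isin(seed_neurons) & (df["count"] > input_threshold)]
    outputs = df[df["pre"].isin(seed_neurons) & (df["count"] > output_threshold)]
    in_sites = int(inputs["count"].sum())
    out_sites = int(outputs["count"].sum())
    in_total = total_postsynaptic_sites or int(df[df["post"].isin(seed_neurons)]["count"].sum())
    out_total = total_presynaptic_sites or int(df[df["pre"].isin(seed_neurons)]["count"].sum())
    return {
        "input_sites": in_sites,
        "output_sites": out_sites,
        "input_partners": int(inputs["pre"].nunique()),
        "output_partners": int(outputs["post"].nunique()),
        "input_percentage": 100.0 * in_sites / in_total if in_total else 0.0,
        "output_percentage": 100.0 * out_sites / out_total if out_total else 0.0,
    }


# ---------------------------------------------------------------------------
# Packaged example circuit (synthetic)
# ---------------------------------------------------------------------------

def example_connectivity() -> ConnectivityTable:
    """Synthetic illustrative synapse-count table (NOT measured data).

    Counts are invented to exercise the model with the qualitative sign
    constraints of the medulla circuit: photoreceptors are histaminergic
    (negative) onto each other, Dm9 and most Tm targets; R8 is positive
    onto Tm5c; pDm8 is positive onto Tm5b and yDm8 negative onto Tm5a;
    Tm-Tm recurrence (direct + disynaptic) is dominated by mutual
    inhibition.  Real counts live in the study's supplementary material and
    can be supplied as a CSV with the same columns.
    """
    edges = [
        # pre, post, count, path, sign
        ("Dm9", "pR7", 30, "direct", -1), ("pR8", "pR7", 20, "direct", -1),
        ("Dm9", "yR7", 30, "direct", -1), ("yR8", "yR7", 20, "direct", -1),
        ("Dm9", "pR8", 30, "direct", -1), ("pR7", "pR8", 20, "direct", -1),
        ("Dm9", "yR8", 30, "direct", -1), ("yR7", "yR8", 20, "direct", -1),
        ("pR7", "Dm9", 25, "direct", -1), ("yR7", "Dm9", 25, "direct", -1),
        ("pR8", "Dm9", 25, "direct", -1), ("yR8", "Dm9", 25, "direct", -1),
        ("pR7", "pDm8", 70, "direct", -1),
        ("yR7", "yDm8", 70, "direct", -1),
        ("yR7", "Tm5a", 35, "direct", -1), ("yDm8", "Tm5a", 12, "direct", -1),
        ("Tm5b", "Tm5a", 5, "disynaptic", -1), ("Tm5c", "Tm5a", 5, "disynaptic", -1),
        ("Tm5a", "Tm5a", 28, "direct", 1),
        ("pR7", "Tm5b", 25, "direct", -1), ("pDm8", "Tm5b", 20, "direct", 1),
        ("Tm5a", "Tm5b", 5, "disynaptic", -1), ("Tm5c", "Tm5b", 5, "disynaptic", -1),
        ("Tm5b", "Tm5b", 30, "direct", 1),
        ("yR8", "Tm5c", 45, "direct", 1), ("pR8", "Tm5c", 15, "direct", 1),
        ("Tm5a", "Tm5c", 3, "disynaptic", -1), ("Tm5b", "Tm5c", 3, "disynaptic", -1),
        ("Tm5c", "Tm5c", 4, "direct", 1),
        ("pR8", "pTm20", 30, "direct", -1), ("Tm5b", "pTm20", 5, "disynaptic", -1),
        ("Tm5c", "pTm20", 5, "disynaptic", -1), ("pTm20", "pTm20", 22, "direct", 1),
        ("yR8", "yTm20", 30, "direct", -1), ("Tm5a", "yTm20", 5, "disynaptic", -1),
        ("Tm5c", "yTm20", 5, "disynaptic", -1), ("yTm20", "yTm20", 22, "direct", 1),
    ]
    return ConnectivityTable(pd.DataFrame(edges, columns=["pre", "post", "count", "path", "sign"]))


def example_template(table: ConnectivityTable | None = None) -> CircuitTemplate:
    """Circuit template built from the packaged synthetic connectivity."""
    table = table or example_connectivity()
    counts = table.count_matrix()
    signs = table.sign_matrix()
    w_rows = np.zeros((12, 12))
    for a in range(12):
        row = counts[a] * signs[a]
        total = np.abs(row).sum()
        if total == 0:
            raise ValueError(f"neuron {NEURONS[a]} has no inputs in the table")
        w_rows[a] = row / total
    # Dm8 rows keep only their R7 part here; the recurrent Dm8 weight is a
    # fitted proportion mixed in by the template.
    for a in DM8S:
        row = counts[a] * signs[a]
        partner = DM8S[1] if a == DM8S[0] else DM8S[0]
        row[partner] = 0.0
        total = np.abs(row).sum()
        w_rows[a] = row / total
    theta0 = _default_theta0()
    return CircuitTemplate(w_base=w_rows, theta0=theta0)


def _default_theta0() -> np.ndarray:
    """Default parameters of the packaged example circuit.

    Chosen so the example exhibits the qualitative behavior of the medulla
    circuit: broadly tuned opponent photoreceptors, and Tm analogs whose hue
    selectivity is created by recurrent amplification (self/disynaptic
    loops) of rectified, achromatically thresholded drives.
    """
    theta = np.zeros(N_PARAMS)
    theta[_SLOTS["log_g_pr"]] = np.log(2.0)
    theta[_SLOTS["log_g_dm9"]] = np.log(2.0)
    theta[_SLOTS["logit_j"]] = 0.0  # j = 0.5
    theta[_SLOTS["atanh_gamma_pr"]] = np.arctanh(0.2)
    theta[_SLOTS["p_dm8"]] = np.log(0.3)
    theta[_SLOTS["logit_d_dm8"]] = np.log(0.25 / 0.75)  # d = 0.25
    theta[_SLOTS["log_g_dm8"]] = np.log(2.0)
    theta[_SLOTS["atanh_gamma_dm8"]] = 0.0
    # Tm order: Tm5a, Tm5b, Tm5c, pTm20, yTm20.
    theta[_SLOTS["p_tm"]] = np.array([-0.3, -0.15, 0.0, -0.2, -0.2])
    theta[_SLOTS["log_g_tm"]] = np.log(np.array([3.2, 3.0, 2.5, 3.0, 3.0]))
    theta[_SLOTS["atanh_gamma_tm"]] = np.arctanh(np.array([-0.8, -0.7, 0.0, -0.7, -0.7]))
    return theta


def example_spec() -> CircuitSpec:
    """The packaged example circuit at its default parameters (synthetic)."""
    return example_template().build_spec(_default_theta0())
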