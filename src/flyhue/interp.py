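"""Smooth tuning maps over color space and spectral/nonspectral tuning curves.

Responses sampled at scattered points of photoreceptor-excitation space
(log relative captures, combining the gamut and contrast stimulus sets) are
interpolated with a thin-plate-spline radial basis function whose constant
term is removed — amplitudes are baseline subtracted, so the interpolant has
no offset.  Query points outside the convex hull of the training set are
projected onto the hull to stay in an interpolative regime.

Two families of one-dimensional paths probe the map: the single-wavelength
line (narrow-band Gaussian lights of increasing peak wavelength, normalized
to the isoluminant plane) and the nonspectral lines connecting the
single-wavelength points of maximal excitation of each nonadjacent opsin
pair (Rh3-Rh5, Rh3-Rh6, Rh4-Rh6).  A neuron is classified nonspectral when
its peak interpolated response along a nonspectral line exceeds its peak
along the single-wavelength line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import ConvexHull

from . import colorspace as cs
from .colorspace import OPSINS, OpsinTemplate

__all__ = [
    "NONADJACENT_PAIRS",
    "TuningInterpolator",
    "TuningCurve",
    "fit_interpolator",
    "project_to_hull",
    "single_wavelength_line",
    "nonspectral_lines",
    "classify_spectral",
]

#: Opsin pairs not adjacent along the spectral locus.
NONADJACENT_PAIRS = (("Rh3", "Rh5"), ("Rh3", "Rh6"), ("Rh4", "Rh6"))


def _tps_kernel(r: np.ndarray) -> np.ndarray:
    # r^2 log r, zero at r = 0.
    with np.errstate(divide="ignore", invalid="ignore"):
        out = r**2 * np.log(r)
    return np.where(r > 0, out, 0.0)


@dataclass
class TuningInterpolator:
    """Thin-plate-spline interpolant without a constant (bias) term.

    Exactly interpolates the training values at the nodes.  The polynomial
    tail keeps the linear monomials but drops the constant, so a zero
    response field maps to the zero interpolant with no offset.
    """

    points: np.ndarray  # (n, d) training coordinates
    values: np.ndarray  # (n,)
    _coef_rbf: np.ndarray = None
    _coef_lin: np.ndarray = None
    hull: ConvexHull = None

    def __post_init__(self) -> None:
        P = np.asarray(self.points, dtype=float)
        v = np.asarray(self.values, dtype=float)
        n, d = P.shape
        if n < d + 2:
            raise ValueError("need at least d+2 training points")
        # Duplicate points with conflicting values make the system inconsistent.
        _, inverse = np.unique(np.round(P, 12), axis=0, return_inverse=True)
        for grp in np.unique(inverse):
            vals = v[inverse == grp]
            if np.ptp(vals) > 1e-10:
                raise ValueError("duplicate training points with conflicting values")
        r = np.linalg.norm(P[:, None, :] - P[None, :, :], axis=2)
        K = _tps_kernel(r)
        A = np.block([[K, P], [P.T, np.zeros((d, d))]])
        rhs = np.concatenate([v, np.zeros(d)])
        sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
        self._coef_rbf = sol[:n]
        self._coef_lin = sol[n:]
        self.points = P
        self.values = v
        self.hull = ConvexHull(P, qhull_options="QJ" if n <= d + 2 else None)

    def __call__(self, query: np.ndarray, project: bool = True) -> np.ndarray:
        q = np.atleast_2d(np.asarray(query, dtype=float))
        if project:
            q = project_to_hull(q, self.hull)
        r = np.linalg.norm(q[:, None, :] - self.points[None, :, :], axis=2)
        return _tps_kernel(r) @ self._coef_rbf + q @ self._coef_lin


def fit_interpolator(points: np.ndarray, values: np.ndarray) -> TuningInterpolator:
    """Fit the bias-free thin-plate-spline interpolant to scattered responses."""
    return TuningInterpolator(points=np.asarray(points, dtype=float),
                              values=np.asarray(values, dtype=float))


def project_to_hull(query: np.ndarray, hull: ConvexHull, tol: float = 1e-9) -> np.ndarray:
    """Map points outside a convex hull to their nearest hull point.

    Interior points are returned unchanged; exterior points solve the
    quadratic program min |y - x|^2 subject to the hull's facet
    inequalities A y <= b.  The map is idempotent.
    """
    q = np.atleast_2d(np.asarray(query, dtype=float)).copy()
    A = hull.equations[:, :-1]
    b = -hull.equations[:, -1]
    outside = (q @ A.T - b).max(axis=1) > tol
    for i in np.where(outside)[0]:
        x = q[i]

        def objective(y, x=x):
            return float(np.sum((y - x) ** 2))

        def gradient(y, x=x):
            return 2.0 * (y - x)

        constraints = {"type": "ineq", "fun": lambda y: b - A @ y, "jac": lambda y: -A}
        start = hull.points[hull.vertices].mean(axis=0)
        res = minimize(objective, start, jac=gradient, method="SLSQP",
                       constraints=[constraints], options={"maxiter": 200, "ftol": 1e-14})
        q[i] = res.x
    return q


@dataclass
class TuningCurve:
    """Interpolated response along a one-dimensional path in color space."""

    grid: np.ndarray  # wavelength (nm) or mixture fraction in [0, 1]
    response: np.ndarray
    kind: str  # "single_wavelength" or "nonspectral:<Rh_a>-<Rh_b>"
    points: np.ndarray = None  # X-space path

    def __post_init__(self) -> None:
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("curve grid must be sorted ascending")

    @property
    def peak_location(self) -> float:
        return float(self.grid[int(np.argmax(self.response))])

    @property
    def peak_value(self) -> float:
        return float(np.max(self.response))


def single_wavelength_line(
    templates: dict[str, OpsinTemplate],
    wavelengths: np.ndarray | None = None,
    width: float = 10.0,
    c_iso: float = 5.0,
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """X-space path traced by narrow-band lights across the spectrum.

    For each peak wavelength a Gaussian spectrum of the given width is
    converted to opsin captures, normalized to the isoluminant total
    ``c_iso``, and mapped to log-capture space.  Returns
    (peak_wavelengths, q (n, 4), X (n, 4)).
    """
    if wavelengths is None:
        wavelengths = np.arange(320.0, 581.0, 5.0)
    if grid is None:
        grid = np.arange(280.0, 701.0, 1.0)
    qs = np.empty((wavelengths.size, 4))
    sens = {name: templates[name].sensitivity(grid) for name in OPSINS}
    for i, peak in enumerate(wavelengths):
        spectrum = np.exp(-0.5 * ((grid - peak) / width) ** 2)
        raw = np.array([np.trapezoid(sens[name] * spectrum, grid) for name in OPSINS])
        qs[i] = raw / raw.sum() * c_iso
    return np.asarray(wavelengths, dtype=float), qs, cs.log_capture(qs)


def nonspectral_lines(
    wavelengths: np.ndarray,
    q_line: np.ndarray,
    templates: dict[str, OpsinTemplate],
    pairs: tuple = NONADJACENT_PAIRS,
    n_steps: int = 21,
    c_iso: float = 5.0,
) -> dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Straight capture-space segments between nonadjacent-opsin endpoints.

    The endpoint for an opsin is the single-wavelength point at which that
    opsin's capture is maximal.  Segments are renormalized to the
    isoluminant total and parameterized by the mixture fraction of the
    second opsin's endpoint.  Returns pair -> (fraction, q, X).
    """
    out = {}
    fractions = np.linspace(0.0, 1.0, n_steps)
    for a, b in pairs:
        ia = int(np.argmax(q_line[:, OPSINS.index(a)]))
        ib = int(np.argmax(q_line[:, OPSINS.index(b)]))
        qa, qb = q_line[ia], q_line[ib]
        q = (1.0 - fractions)[:, None] * qa + fractions[:, None] * qb
        q = q / q.sum(axis=1, keepdims=True) * c_iso
        out[(a, b)] = (fractions, q, cs.log_capture(q))
    return out


def classify_spectral(
    interpolator: TuningInterpolator,
    templates: dict[str, OpsinTemplate],
    c_iso: float = 5.0,
    wavelengths: np.ndarray | None = None,
) -> dict:
    """Spectral vs nonspectral classification of a tuning map.

    Evaluates the interpolated response along the single-wavelength line and
    the three nonspectral lines (all projected into the training hull); the
    neuron is nonspectral when its peak along a nonspectral line exceeds its
    single-wavelength peak.  Returns the decision, the winning curve and all
    curves.
    """
    wl, q_line, X_line = single_wavelength_line(templates, wavelengths=wavelengths, c_iso=c_iso)
    spectral_curve = TuningCurve(
        grid=wl, response=interpolator(X_line), kind="single_wavelength", points=X_line
    )
    curves = {"single_wavelength": spectral_curve}
    best_ns = None
    for pair, (frac, _, X_seg) in nonspectral_lines(wl, q_line, templates, c_iso=c_iso).items():
        curve = TuningCurve(
            grid=frac, response=interpolator(X_seg),
            kind=f"nonspectral:{pair[0]}-{pair[1]}", points=X_seg,
        )
        curves[curve.kind] = curve
        if best_ns is None or curve.peak_value > best_ns.peak_value:
            best_ns = curve
    nonspectral = best_ns.peak_value > spectral_curve.peak_value
    winner = best_ns if nonspectral else spectral_curve
    return {
        "classification": "nonspectral" if nonspectral else "spectral",
        "winning_line": winner.kind,
        "peak_location": winner.peak_location,
        "peak_value": winner.peak_value,
        "curves": curves,
    }
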