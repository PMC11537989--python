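"""Tetrachromatic fly color space.

The fly eye expresses four chromatic opsins (Rh3, Rh4, Rh5, Rh6 in the R7/R8
photoreceptors) plus the broadband Rh1 (R1-6, achromatic pathway).  A stimulus
is summarized by its vector of photon captures relative to the adapting
background, ``q`` (background = 1 for every opsin).  Log relative captures
``X = ln((q + 0.001) / 1.001)`` are decomposed into a 3-vector living in the
chromatic tetrahedron plus a scalar luminance along the "white" axis of equal
captures.  Saturation is the length of the chromatic vector and hue its
direction; a fixed 2D opponent projection gives the plotting plane
``(Rh5+Rh6)-(Rh3+Rh4)`` vs ``(Rh4+Rh5)-(Rh3+Rh6)``.

The module also covers the radiometric front end: converting spectrometer
counts to absolute irradiance, irradiance to photon flux, and evaluating
visual-pigment sensitivity templates so that captures can be computed from
arbitrary spectra by quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OPSINS",
    "DEFAULT_LAMBDA_MAX",
    "PLANCK_H",
    "SPEED_OF_LIGHT",
    "AVOGADRO",
    "TETRA_BASIS",
    "WHITE_AXIS",
    "SpectrometerReading",
    "OpsinTemplate",
    "ColorPoint",
    "irradiance_from_counts",
    "photon_flux",
    "opsin_sensitivity",
    "relative_capture",
    "log_capture",
    "decompose",
    "embed",
    "opponent_projection",
    "hue_saturation",
    "make_templates",
]

#: Chromatic opsin order used for every 4-vector in the package.
OPSINS = ("Rh3", "Rh4", "Rh5", "Rh6")

#: Approximate peak sensitivities (nm) for the Drosophila opsins.  These are
#: configuration defaults (literature ballpark values), used by the synthetic
#: data generator and tests as fixtures; real analyses should supply their own.
DEFAULT_LAMBDA_MAX = {"Rh1": 478.0, "Rh3": 331.0, "Rh4": 355.0, "Rh5": 442.0, "Rh6": 515.0}

PLANCK_H = 6.63e-34  # J s
SPEED_OF_LIGHT = 2.998e8  # m / s
AVOGADRO = 6.022e23  # 1 / mol

#: Unit vector along the "white" axis of equal log captures.
WHITE_AXIS = np.full(4, 0.5)

#: Fixed orthonormal basis of the chromatic subspace (rows orthonormal and
#: orthogonal to WHITE_AXIS).  The four opsin axes map to the vertices of a
#: regular tetrahedron: column mu of TETRA_BASIS is the vertex for opsin mu.
TETRA_BASIS = 0.5 * np.array(
    [
        [1.0, 1.0, -1.0, -1.0],
        [1.0, -1.0, 1.0, -1.0],
        [1.0, -1.0, -1.0, 1.0],
    ]
)


# ---------------------------------------------------------------------------
# Radiometry
# ---------------------------------------------------------------------------

@dataclass
class SpectrometerReading:
    """Raw spectrometer measurement on a common wavelength grid.

    Attributes
    ----------
    wavelength : array, nm
    sample_counts : array, counts (S_p)
    dark_counts : array, counts (D_p)
    calibration : array, uJ/count (C_p)
    integration_time : float, s
    collection_area : float, cm^2
    """

    wavelength: np.ndarray
    sample_counts: np.ndarray
    dark_counts: np.ndarray
    calibration: np.ndarray
    integration_time: float
    collection_area: float

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.sample_counts = np.asarray(self.sample_counts, dtype=float)
        self.dark_counts = np.asarray(self.dark_counts, dtype=float)
        self.calibration = np.asarray(self.calibration, dtype=float)
        n = self.wavelength.shape[0]
        for name in ("sample_counts", "dark_counts", "calibration"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"{name} length does not match wavelength grid")
        if self.integration_time <= 0:
            raise ValueError("integration_time must be positive")
        if self.collection_area <= 0:
            raise ValueError("collection_area must be positive")


def irradiance_from_counts(reading: SpectrometerReading) -> np.ndarray:
    """Absolute irradiance I_p(lambda) in W/m^2/nm from spectrometer counts.

    I_p = C_p * (S_p - D_p) / (dt * A * 100).
    """
    return (
        reading.calibration
        * (reading.sample_counts - reading.dark_counts)
        / (reading.integration_time * reading.collection_area * 100.0)
    )


def photon_flux(irradiance: np.ndarray, wavelength: np.ndarray) -> np.ndarray:
    """Convert absolute irradiance (W/m^2/nm) to photon flux E_p in uE/nm.

    E_p = I_p * lambda / (c * h * N_A * 1e6), lambda in nm.
    """
    irradiance = np.asarray(irradiance, dtype=float)
    wavelength = np.asarray(wavelength, dtype=float)
    if np.any(wavelength <= 0):
        raise ValueError("wavelengths must be positive")
    if np.any(irradiance < 0):
        raise ValueError("irradiance must be nonnegative")
    return irradiance * wavelength / (SPEED_OF_LIGHT * PLANCK_H * AVOGADRO * 1e6)


# ---------------------------------------------------------------------------
# Opsin sensitivity templates
# ---------------------------------------------------------------------------

@dataclass
class OpsinTemplate:
    """Peak-normalized visual-pigment sensitivity template.

    Uses the standard A1-pigment nomogram of Govardovskii et al. (2000): an
    alpha band parameterized solely by ``lambda_max`` plus a small beta band.
    ``sensitivity(lambda_max) == 1`` by construction (renormalized).
    """

    name: str
    lambda_max: float
    beta_band: bool = True

    def sensitivity(self, wavelength: np.ndarray) -> np.ndarray:
        lam = np.asarray(wavelength, dtype=float)
        s = _govardovskii(lam, self.lambda_max, beta=self.beta_band)
        peak = _govardovskii(np.array([self.lambda_max]), self.lambda_max, beta=self.beta_band)[0]
        return s / peak


def _govardovskii(lam: np.ndarray, lmax: float, beta: bool = True) -> np.ndarray:
    # Alpha band (A1 template).
    x = lmax / lam
    a = 0.8795 + 0.0459 * np.exp(-((lmax - 300.0) ** 2) / 11940.0)
    A, B, C, D = 69.7, 28.0, -14.9, 0.674
    b = 0.922
    c = 1.104
    alpha = 1.0 / (
        np.exp(A * (a - x))
        + np.exp(B * (b - x))
        + np.exp(C * (c - x))
        + D
    )
    if not beta:
        return alpha
    # Beta band.
    lmb = 189.0 + 0.315 * lmax
    bbeta = -40.5 + 0.195 * lmax
    Abeta = 0.26
    beta_band = Abeta * np.exp(-(((lam - lmb) / bbeta) ** 2))
    return alpha + beta_band


def opsin_sensitivity(template: OpsinTemplate, wavelength: np.ndarray) -> np.ndarray:
    """Relative sensitivity curve of ``template`` on ``wavelength`` (nm)."""
    return template.sensitivity(wavelength)


def make_templates(lambda_max: dict[str, float] | None = None) -> dict[str, OpsinTemplate]:
    """Build the standard template set (Rh1, Rh3-Rh6) from peak wavelengths."""
    lm = dict(DEFAULT_LAMBDA_MAX)
    if lambda_max:
        lm.update(lambda_max)
    return {name: OpsinTemplate(name, peak) for name, peak in lm.items()}


def relative_capture(
    wavelength: np.ndarray,
    stimulus_flux: np.ndarray,
    background_flux: np.ndarray,
    templates: dict[str, OpsinTemplate],
    opsins: tuple[str, ...] = OPSINS,
) -> np.ndarray:
    """Photon captures of ``stimulus_flux`` relative to ``background_flux``.

    q_mu = int S_mu(lam) E_stim(lam) dlam / int S_mu(lam) E_bg(lam) dlam,
    by trapezoid quadrature on the provided grid.  stimulus == background
    gives q = 1 for every opsin.
    """
    wavelength = np.asarray(wavelength, dtype=float)
    stimulus_flux = np.asarray(stimulus_flux, dtype=float)
    background_flux = np.asarray(background_flux, dtype=float)
    if wavelength.min() > 300.0 or wavelength.max() < 700.0:
        import warnings

        warnings.warn(
            "wavelength grid does not cover 300-700 nm; captures may truncate "
            "opsin sensitivity",
            stacklevel=2,
        )
    q = np.empty(len(opsins))
    for k, name in enumerate(opsins):
        sens = templates[name].sensitivity(wavelength)
        denom = np.trapezoid(sens * background_flux, wavelength)
        if denom <= 0:
            raise ValueError(f"zero background capture for opsin {name}")
        q[k] = np.trapezoid(sens * stimulus_flux, wavelength) / denom
    return q


# ---------------------------------------------------------------------------
# Log captures and tetrahedron decomposition
# ---------------------------------------------------------------------------

def log_capture(q: np.ndarray) -> np.ndarray:
    """Elementwise X_mu = ln((q_mu + 0.001) / 1.001); background q=1 -> X=0."""
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("relative captures must be nonnegative")
    return np.log((q + 0.001) / 1.001)


def decompose(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split log captures into (chromatic 3-vector, luminance scalar).

    ``l = X . u`` with ``u = (1,1,1,1)/2`` and ``x = B (X - l u)`` for the
    fixed orthonormal tetrahedron basis ``B``.  Accepts a single 4-vector or
    an (n, 4) batch.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    lum = X @ WHITE_AXIS
    chroma = (X - np.multiply.outer(lum, WHITE_AXIS)) @ TETRA_BASIS.T
    return chroma, lum


def embed(chroma: np.ndarray, lum: np.ndarray | float) -> np.ndarray:
    """Inverse of :func:`decompose`: X = B^T x + l u."""
    chroma = np.asarray(chroma, dtype=float)
    return chroma @ TETRA_BASIS + np.multiply.outer(np.asarray(lum, dtype=float), WHITE_AXIS)


def opponent_projection(X: np.ndarray, use_q: bool = False) -> np.ndarray:
    """2D opponent coordinates of log captures (or raw captures).

    component 1 = (Rh5 + Rh6) - (Rh3 + Rh4)
    component 2 = (Rh4 + Rh5) - (Rh3 + Rh6)

    ``X`` is indexed in OPSINS order.  ``use_q`` only documents intent (the
    formula is identical for captures); pass captures directly when wanted.
    """
    X = np.asarray(X, dtype=float)
    proj = np.array(
        [
            [-1.0, -1.0, 1.0, 1.0],
            [-1.0, 1.0, 1.0, -1.0],
        ]
    )
    return X @ proj.T


def hue_saturation(chroma: np.ndarray, preferred: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Saturation s = |x| and hue cosine cos(theta) = p . x / s.

    ``preferred`` must be a unit 3-vector.  cos(theta) is defined as 0 where
    s == 0 (the white point has no hue).
    """
    preferred = np.asarray(preferred, dtype=float)
    if abs(np.linalg.norm(preferred) - 1.0) > 1e-8:
        raise ValueError("preferred direction must be a unit vector")
    chroma = np.asarray(chroma, dtype=float)
    s = np.linalg.norm(chroma, axis=-1)
    dot = chroma @ preferred
    cos = np.divide(dot, s, out=np.zeros_like(dot), where=s > 0)
    return s, cos


# ---------------------------------------------------------------------------
# ColorPoint container
# ---------------------------------------------------------------------------

@dataclass
class ColorPoint:
    """A stimulus located in the fly color space.

    Built from relative captures; all derived coordinates are computed once.
    ``achromatic`` is the log relative Rh1 capture (R1-6 channel) when given.
    """

    q: np.ndarray
    achromatic_q: float | None = None
    X: np.ndarray = field(init=False)
    chroma: np.ndarray = field(init=False)
    luminance: float = field(init=False)
    saturation: float = field(init=False)
    opponent: np.ndarray = field(init=False)
    achromatic: float = field(init=False)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.X = log_capture(self.q)
        chroma, lum = decompose(self.X)
        self.chroma = chroma
        self.luminance = float(lum)
        self.saturation = float(np.linalg.norm(chroma))
        self.opponent = opponent_projection(self.X)
        if self.achromatic_q is None:
            self.achromatic = 0.0
        else:
            self.achromatic = float(log_capture(np.array([self.achromatic_q]))[0])
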