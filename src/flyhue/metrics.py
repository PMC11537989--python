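"""Tuning indices, noise-corrected goodness of fit, and bootstrap machinery.

Three scalar indices summarize a neuron's response profile over a stimulus
set:

* sparsity index — 1 minus the mean max-normalized absolute response; 0 for
  equal responses, 1 - 1/N for a single responder, 0.5 for uniformly
  distributed amplitudes;
* luminance invariance index — R^2 of a chromatic-only linear regression
  divided by R^2 of a luminance-only regression (both without intercepts);
* hue sensitivity index (HSI) — the norm of the observation-weighted vector
  sum of unit hue directions in the 2D opponent plane, restricted to
  low-saturation stimuli; 1 = single-direction responder, 0 = uniform.

Model fits are scored with a noise-corrected R^2 that removes the bias that
trial noise of power sigma^2 introduces into the plain weighted uncentered
correlation.  Confidence intervals come from bootstrapping ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "IndexResult",
    "HueVector",
    "sparsity_index",
    "luminance_invariance_index",
    "hue_sensitivity_index",
    "noise_corrected_r2",
    "bootstrap",
]


@dataclass
class IndexResult:
    """Point estimate with a bootstrap distribution and percentile CI."""

    estimate: float
    distribution: np.ndarray
    ci_low: float
    ci_high: float


@dataclass
class HueVector:
    """Hue sensitivity vector in opponent space and its norm (the HSI)."""

    h_vec: np.ndarray
    hsi: float


def sparsity_index(v: np.ndarray) -> float:
    """1 - mean(|v_i| / max_j |v_j|); in [0, 1 - 1/N]."""
    v = np.abs(np.asarray(v, dtype=float))
    peak = v.max()
    if peak == 0:
        raise ValueError("sparsity index undefined for all-zero responses")
    return 1.0 - float(np.mean(v / peak))


def _r2_no_intercept(design: np.ndarray, v: np.ndarray, m: np.ndarray) -> float:
    """Uncentered R^2 of an intercept-free weighted least-squares fit."""
    w = np.sqrt(m)
    A = design * w[:, None]
    b = v * w
    coef, *_ = np.linalg.lstsq(A, b, rcond=None)
    ss_res = float(np.sum((b - A @ coef) ** 2))
    ss_tot = float(np.sum(b**2))
    if ss_tot == 0:
        return 0.0
    return 1.0 - ss_res / ss_tot


def luminance_invariance_index(
    v: np.ndarray,
    chroma: np.ndarray,
    luminance: np.ndarray,
    m: np.ndarray | None = None,
    floor: float = 1e-6,
    cap: float = 1e6,
) -> tuple[float, bool]:
    """R^2(chromatic-only fit) / R^2(luminance-only fit).

    Both regressions are intercept-free least squares: v ~ b*l and
    v ~ a*(p.x) with p the fitted chromatic direction.  Returns
    ``(index, capped)``; when the luminance R^2 falls below ``floor`` the
    ratio is capped and flagged.
    """
    v = np.asarray(v, dtype=float)
    chroma = np.asarray(chroma, dtype=float)
    luminance = np.asarray(luminance, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 stimuli")
    m = np.ones_like(v) if m is None else np.asarray(m, dtype=float)
    r2_chrom = max(_r2_no_intercept(chroma, v, m), 0.0)
    r2_lum = max(_r2_no_intercept(luminance[:, None], v, m), 0.0)
    if r2_lum < floor:
        return min(r2_chrom / floor, cap), True
    return r2_chrom / r2_lum, False


def hue_sensitivity_index(
    v: np.ndarray,
    opponent: np.ndarray,
    m: np.ndarray | None = None,
    saturation_cutoff: float = 0.5,
) -> HueVector:
    """Hue sensitivity vector and index from opponent-plane responses.

    Saturations (opponent-vector norms) are scaled to [0, 1] by the set
    maximum; stimuli at or above ``saturation_cutoff`` and exactly at the
    white point are dropped.  For the retained stimuli,

        h_vec = sum_i m_i p_hat_i y_i / sum_i m_i |y_i|,   HSI = |h_vec|,

    with p_hat_i the unit hue direction of stimulus i.
    """
    v = np.asarray(v, dtype=float)
    opponent = np.atleast_2d(np.asarray(opponent, dtype=float))
    m = np.ones_like(v) if m is None else np.asarray(m, dtype=float)
    sat = np.linalg.norm(opponent, axis=1)
    peak = sat.max()
    if peak == 0:
        raise ValueError("all stimuli at the white point")
    scaled = sat / peak
    keep = (scaled < saturation_cutoff) & (sat > 0)
    if not keep.any():
        raise ValueError("no stimuli retained below the saturation cutoff")
    units = opponent[keep] / sat[keep, None]
    y = v[keep]
    w = m[keep]
    denom = float(np.sum(w * np.abs(y)))
    if denom == 0:
        raise ValueError("retained responses are all zero")
    h_vec = (units * (w * y)[:, None]).sum(axis=0) / denom
    return HueVector(h_vec=h_vec, hsi=float(np.linalg.norm(h_vec)))


def noise_corrected_r2(
    y: np.ndarray,
    v: np.ndarray,
    m: np.ndarray | None = None,
    sigma2: float = 0.0,
    reading: str = "correlation",
) -> float:
    """Noise-corrected R^2 between model predictions y and data v.

    With m_i the observations per stimulus, m_bar their mean and m_hat their
    total,

        R^2 = [ (sum m y v)^2 - (sigma2/m_bar) sum m y^2 ]
              / [ sum m y^2 sum m v^2 - sigma2 (m_hat - 1)/m_bar sum m y^2 ].

    At sigma2 = 0 this is the squared weighted uncentered correlation.  The
    alternative ``reading="literal"`` uses sum m (y v)^2 in the numerator's
    first term instead of the squared sum.  A nonpositive denominator yields
    NaN.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    m = np.ones_like(y) if m is None else np.asarray(m, dtype=float)
    syy = float(np.sum(m * y**2))
    svv = float(np.sum(m * v**2))
    if syy <= 0 or svv <= 0:
        raise ValueError("y and v must have nonzero weighted norms")
    m_bar = float(np.mean(m))
    m_hat = float(np.sum(m))
    if reading == "correlation":
        cross = float(np.sum(m * y * v)) ** 2
    elif reading == "literal":
        cross = float(np.sum(m * (y * v) ** 2))
    else:
        raise ValueError("reading must be 'correlation' or 'literal'")
    num = cross - (sigma2 / m_bar) * syy
    den = syy * svv - (sigma2 * (m_hat - 1.0) / m_bar) * syy
    if den <= 0:
        return float("nan")
    return num / den


def bootstrap(
    responses_by_roi: np.ndarray,
    statistic,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    ci: tuple[float, float] = (2.5, 97.5),
) -> IndexResult:
    """Percentile-bootstrap CI of a statistic of the ROI-mean responses.

    ``responses_by_roi`` is (n_rois, n_stimuli); each draw resamples ROIs
    with replacement, averages across the resampled ROIs, and applies
    ``statistic`` to the mean response vector.
    """
    responses_by_roi = np.atleast_2d(np.asarray(responses_by_roi, dtype=float))
    n_rois = responses_by_roi.shape[0]
    if n_rois < 2:
        raise ValueError("need at least 2 ROIs to bootstrap")
    rng = np.random.default_rng(seed)
    estimate = float(statistic(responses_by_roi.mean(axis=0)))
    dist = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n_rois, size=n_rois)
        dist[b] = statistic(responses_by_roi[idx].mean(axis=0))
    lo, hi = np.percentile(dist, ci)
    return IndexResult(estimate=estimate, distribution=dist, ci_low=float(lo), ci_high=float(hi))
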