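"""Signal extraction: dF/F traces to per-stimulus response amplitudes.

The pipeline entry point for imaging data (real or synthetic).  Fluorescence
traces are baseline-corrected with a rolling 25th-percentile window, smoothed
with a Savitzky-Golay filter, converted to per-stimulus amplitudes by window
means around each stimulus onset, filtered by a signal-to-noise criterion,
and finally normalized so that the squared response vector of each ROI sums
to N - 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import percentile_filter
from scipy.signal import savgol_filter

__all__ = [
    "Trace",
    "ResponseTable",
    "dff_baseline",
    "extract_amplitude",
    "baseline_amplitudes",
    "snr_filter",
    "normalize_responses",
    "extract_response_table",
]


@dataclass
class Trace:
    """A fluorescence (or dF/F) time series with stimulus onsets."""

    time: np.ndarray  # s, strictly increasing
    values: np.ndarray
    onsets: np.ndarray  # s
    stimulus_ids: np.ndarray
    fs: float  # Hz

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.onsets = np.asarray(self.onsets, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.onsets < self.time[0]) or np.any(self.onsets > self.time[-1]):
            raise ValueError("stimulus onsets must lie within the record")


@dataclass
class ResponseTable:
    """Per-ROI x per-stimulus response amplitudes.

    Wraps a long-format DataFrame with columns roi_id, stimulus_id,
    amplitude (v), m (observations), sigma2 (baseline noise power) and,
    after :func:`normalize_responses`, amplitude_norm (v').
    """

    data: pd.DataFrame

    def rois(self) -> list:
        return list(self.data["roi_id"].unique())

    def vector(self, roi_id, stimulus_order: np.ndarray | None = None, column: str = "amplitude"):
        """(v, m) for one ROI, aligned to ``stimulus_order`` if given."""
        sub = self.data[self.data["roi_id"] == roi_id].set_index("stimulus_id")
        if stimulus_order is None:
            stimulus_order = sub.index.to_numpy()
        sub = sub.loc[stimulus_order]
        return sub[column].to_numpy(), sub["m"].to_numpy()


def dff_baseline(
    trace: Trace,
    window: float = 40.0,
    percentile: float = 25.0,
    smooth: float = 0.5,
    polyorder: int = 3,
) -> Trace:
    """Baseline-corrected, smoothed dF/F from a raw fluorescence trace.

    The baseline F0 is the rolling ``percentile`` of a ``window``-second
    window; dF/F = (F - F0) / F0 is then smoothed with a Savitzky-Golay
    filter of ``smooth`` seconds and order ``polyorder``.
    """
    duration = trace.time[-1] - trace.time[0]
    if duration <= window:
        raise ValueError("record must be longer than the baseline window")
    win = int(round(window * trace.fs))
    f0 = percentile_filter(trace.values, percentile, size=win, mode="nearest")
    f0 = np.where(np.abs(f0) < 1e-12, 1e-12, f0)
    dff = (trace.values - f0) / f0
    smooth_win = max(polyorder + 2, int(round(smooth * trace.fs)))
    if smooth_win % 2 == 0:
        smooth_win += 1
    dff = savgol_filter(dff, smooth_win, polyorder)
    return Trace(
        time=trace.time,
        values=dff,
        onsets=trace.onsets,
        stimulus_ids=trace.stimulus_ids,
        fs=trace.fs,
    )


def _window_mean(trace: Trace, start: float, stop: float) -> float:
    # Samples whose timestamps fall in the closed interval [start, stop].
    mask = (trace.time >= start) & (trace.time <= stop)
    if not mask.any():
        raise ValueError("amplitude window contains no samples")
    return float(trace.values[mask].mean())


def extract_amplitude(trace: Trace, onset: float) -> float:
    """Response amplitude around one stimulus onset.

    v = mean dF/F over [onset+0.35, onset+0.5] minus the mean over
    [onset-0.35, onset-0.1].
    """
    if onset - 0.35 < trace.time[0] or onset + 0.5 > trace.time[-1]:
        raise ValueError("amplitude windows lie outside the record")
    during = _window_mean(trace, onset + 0.35, onset + 0.5)
    before = _window_mean(trace, onset - 0.35, onset - 0.1)
    return during - before


def baseline_amplitudes(
    trace: Trace,
    n_windows: int = 100,
    window: float = 0.15,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Amplitude-like means from randomly placed windows outside stimulation.

    Windows of ``window`` seconds are drawn uniformly from the pre- and
    post-stimulation segments of the record; their dF/F means estimate the
    baseline noise that enters the SNR filter and the sigma^2 of the
    noise-corrected R^2.
    """
    rng = np.random.default_rng(seed)
    pre_end = trace.onsets.min() - 0.5
    post_start = trace.onsets.max() + 1.0
    segments = []
    if pre_end - window > trace.time[0]:
        segments.append((trace.time[0], pre_end - window))
    if trace.time[-1] - window > post_start:
        segments.append((post_start, trace.time[-1] - window))
    if not segments:
        raise ValueError("no baseline segments outside stimulation")
    out = np.empty(n_windows)
    for k in range(n_windows):
        lo, hi = segments[int(rng.integers(len(segments)))]
        start = rng.uniform(lo, hi)
        out[k] = _window_mean(trace, start, start + window)
    return out


def snr_filter(v_stim: np.ndarray, v_baseline: np.ndarray, threshold: float = 2.0):
    """Keep an ROI iff SNR = ||v_stim||^2 / ||v_baseline||^2 >= threshold.

    Returns (keep, snr).  A zero baseline norm leaves the SNR undefined; the
    ROI is kept with snr = inf and a warning.
    """
    v_stim = np.asarray(v_stim, dtype=float)
    v_baseline = np.asarray(v_baseline, dtype=float)
    if v_stim.size == 0 or v_baseline.size == 0:
        raise ValueError("both amplitude vectors must be nonempty")
    denom = float(np.sum(v_baseline**2))
    if denom == 0.0:
        import warnings

        warnings.warn("zero baseline norm: SNR undefined, keeping ROI", stacklevel=2)
        return True, np.inf
    snr = float(np.sum(v_stim**2)) / denom
    return snr >= threshold, snr


def normalize_responses(v: np.ndarray) -> np.ndarray:
    """v' = v / sqrt(sum(v^2) / (N-1)), so that sum(v'^2) = N - 1."""
    v = np.asarray(v, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 stimuli to normalize")
    ss = float(np.sum(v**2))
    if ss == 0.0:
        raise ValueError("cannot normalize an all-zero response vector")
    return v / np.sqrt(ss / (v.size - 1))


def extract_response_table(
    traces: dict,
    n_baseline_windows: int = 100,
    snr_threshold: float = 2.0,
    seed: int | np.random.Generator = 0,
    m: np.ndarray | None = None,
) -> ResponseTable:
    """Full extraction stage: raw traces -> filtered, normalized amplitudes.

    ``traces`` maps roi_id -> raw fluorescence :class:`Trace`.  Per ROI:
    dF/F conversion, per-onset amplitudes averaged across repeats of the
    same stimulus, SNR filtering against randomly placed baseline windows,
    and Eq.-style normalization.  sigma^2 is recorded as the mean squared
    baseline amplitude (per-observation noise power).
    """
    rng = np.random.default_rng(seed)
    frames = []
    for roi_id, raw in traces.items():
        dff = dff_baseline(raw)
        amps = {}
        for onset, sid in zip(dff.onsets, dff.stimulus_ids):
            amps.setdefault(sid, []).append(extract_amplitude(dff, onset))
        sids = np.array(sorted(amps))
        v = np.array([np.mean(amps[s]) for s in sids])
        counts = np.array([len(amps[s]) for s in sids]) if m is None else m
        vb = baseline_amplitudes(dff, n_windows=n_baseline_windows, seed=rng)
        keep, snr = snr_filter(v, vb[: v.size], threshold=snr_threshold)
        if not keep:
            continue
        sigma2 = float(np.mean(vb**2))
        frames.append(
            pd.DataFrame(
                {
                    "roi_id": roi_id,
                    "stimulus_id": sids,
                    "amplitude": v,
                    "amplitude_norm": normalize_responses(v),
                    "m": counts,
                    "sigma2": sigma2,
                    "snr": snr,
                }
            )
        )
    if not frames:
        return ResponseTable(
            pd.DataFrame(
                columns=["roi_id", "stimulus_id", "amplitude", "amplitude_norm", "m", "sigma2", "snr"]
            )
        )
    return ResponseTable(pd.concat(frames, ignore_index=True))
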