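"""Stimulus design and synthetic-data generation.

Builds the two stimulus sets used to characterize chromatic tuning:

* a *gamut* set — random capture 4-vectors on the isoluminant hyperplane
  (summed relative capture ``C_iso``, default 5x background), realized by a
  six-LED stimulation system via nonnegative least squares on LED drives;
* a *contrast* set — single LEDs and fixed mixtures flashed at increasing
  added intensities (0.1 to 3 uE per LED).

It also provides the synthetic ground-truth stage: noisy response amplitudes
drawn around the means of an encoding model or of the recurrent circuit
model, and stimulus-locked dF/F traces for the signal-extraction stage.  All
randomness flows through explicit ``numpy.random.Generator`` seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import colorspace as cs
from .colorspace import OPSINS, OpsinTemplate, make_templates

__all__ = [
    "LED_NAMES",
    "LED_PEAKS",
    "LED_MAX_INTENSITY",
    "LED_BACKGROUND",
    "CONTRAST_STEPS",
    "CONTRAST_MIXTURES",
    "LEDSystem",
    "StimulusSet",
    "SyntheticDataset",
    "sample_gamut",
    "max_distance_subsample",
    "solve_led_drive",
    "build_contrast_set",
    "simulate_responses",
    "simulate_traces",
    "session_observation_counts",
]

LED_NAMES = ("D", "U", "V", "B", "L", "O")  # deep-UV, UV, violet, blue, lime, orange
LED_PEAKS = {"D": 340.0, "U": 360.0, "V": 415.0, "B": 455.0, "L": 565.0, "O": 615.0}
LED_MAX_INTENSITY = {"D": 6.0, "U": 7.0, "V": 11.0, "B": 18.0, "L": 25.0, "O": 160.0}  # uE
LED_BACKGROUND = {"D": 0.01, "U": 0.06, "V": 0.1, "B": 0.25, "L": 0.33, "O": 0.25}  # uE

#: Added intensity steps for the contrast set, in uE per LED.
CONTRAST_STEPS = (0.1, 0.3, 0.5, 0.75, 1.0, 3.0)

#: LED mixtures of the contrast set (single-letter LED names).
CONTRAST_MIXTURES = (
    "DU", "UL", "DULO", "VBLO", "UVB", "BLO",
    "DLO", "DUVBLO", "VB", "DUO", "DUV",
)


# ---------------------------------------------------------------------------
# LED system
# ---------------------------------------------------------------------------

@dataclass
class LEDSystem:
    """Six-LED full-field stimulation system with synthetic Gaussian spectra.

    Spectra are Gaussians at the nominal LED peaks, normalized so one unit of
    drive delivers one uE of total photon flux; drives are therefore in uE.
    Only the resulting opsin captures matter downstream, so the Gaussian
    width is a free parameter (default sd 12 nm).
    """

    wavelength: np.ndarray = field(default_factory=lambda: np.arange(280.0, 701.0, 1.0))
    peak_sd: float = 12.0
    max_intensity: dict[str, float] = field(default_factory=lambda: dict(LED_MAX_INTENSITY))
    background: dict[str, float] = field(default_factory=lambda: dict(LED_BACKGROUND))
    templates: dict[str, OpsinTemplate] = field(default_factory=make_templates)

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        spectra = {}
        for name in LED_NAMES:
            s = np.exp(-0.5 * ((self.wavelength - LED_PEAKS[name]) / self.peak_sd) ** 2)
            total = np.trapezoid(s, self.wavelength)
            spectra[name] = s / total  # unit total flux per unit drive
        self.spectra = spectra
        # Capture of each opsin per unit drive of each LED.
        names = OPSINS + ("Rh1",)
        cap = np.zeros((len(names), len(LED_NAMES)))
        for i, opsin in enumerate(names):
            sens = self.templates[opsin].sensitivity(self.wavelength)
            for j, led in enumerate(LED_NAMES):
                cap[i, j] = np.trapezoid(sens * spectra[led], self.wavelength)
        self._capture_per_drive = cap
        self.background_drive = np.array([self.background[n] for n in LED_NAMES])
        bg = cap @ self.background_drive
        if np.any(bg <= 0):
            raise ValueError("background produces zero capture for some opsin")
        self._background_capture = bg

    def captures(self, drive: np.ndarray, include_rh1: bool = False) -> np.ndarray:
        """Relative opsin captures produced by absolute LED ``drive`` (uE)."""
        drive = np.asarray(drive, dtype=float)
        q = (self._capture_per_drive @ drive.T).T / self._background_capture
        return q if include_rh1 else q[..., :4]

    @property
    def capture_matrix(self) -> np.ndarray:
        """(4, 6) matrix M with q = M @ drive for the chromatic opsins."""
        return self._capture_per_drive[:4] / self._background_capture[:4, None]


# ---------------------------------------------------------------------------
# Stimulus containers
# ---------------------------------------------------------------------------

@dataclass
class StimulusSet:
    """Table of stimuli with capture vectors and derived color coordinates."""

    q: np.ndarray  # (n, 4) relative captures
    m: np.ndarray | None = None  # observation counts
    label: str = "gamut"
    stimulus_id: np.ndarray | None = None
    led_drive: np.ndarray | None = None  # (n, 6) absolute drives, optional
    q_rh1: np.ndarray | None = None  # relative Rh1 captures, optional

    def __post_init__(self) -> None:
        self.q = np.atleast_2d(np.asarray(self.q, dtype=float))
        n = self.q.shape[0]
        if self.m is None:
            self.m = np.ones(n, dtype=int)
        self.m = np.asarray(self.m)
        if np.any(self.m < 1):
            raise ValueError("observation counts must be >= 1")
        if self.stimulus_id is None:
            self.stimulus_id = np.arange(n)
        self.X = cs.log_capture(self.q)
        chroma, lum = cs.decompose(self.X)
        self.chroma = chroma
        self.luminance = lum
        self.saturation = np.linalg.norm(chroma, axis=1)
        self.opponent = cs.opponent_projection(self.X)
        if self.q_rh1 is not None:
            self.q_rh1 = np.asarray(self.q_rh1, dtype=float)
            self.achromatic = cs.log_capture(self.q_rh1)
        else:
            self.achromatic = np.zeros(n)

    def __len__(self) -> int:
        return self.q.shape[0]

    def subset(self, idx: np.ndarray) -> "StimulusSet":
        return StimulusSet(
            q=self.q[idx],
            m=self.m[idx],
            label=self.label,
            stimulus_id=self.stimulus_id[idx],
            led_drive=None if self.led_drive is None else self.led_drive[idx],
            q_rh1=None if self.q_rh1 is None else self.q_rh1[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"stimulus_id": self.stimulus_id, "m": self.m, "label": self.label})
        for k, name in enumerate(OPSINS):
            df[f"q_{name}"] = self.q[:, k]
        if self.q_rh1 is not None:
            df["q_Rh1"] = self.q_rh1
        df["luminance"] = self.luminance
        df["saturation"] = self.saturation
        df[["opp1", "opp2"]] = self.opponent
        df[["x1", "x2", "x3"]] = self.chroma
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "StimulusSet":
        q = df[[f"q_{n}" for n in OPSINS]].to_numpy()
        q_rh1 = df["q_Rh1"].to_numpy() if "q_Rh1" in df else None
        label = str(df["label"].iloc[0]) if "label" in df else "gamut"
        m = df["m"].to_numpy() if "m" in df else None
        sid = df["stimulus_id"].to_numpy() if "stimulus_id" in df else None
        return cls(q=q, m=m, label=label, stimulus_id=sid, q_rh1=q_rh1)

    @staticmethod
    def concat(sets: list["StimulusSet"]) -> "StimulusSet":
        q = np.vstack([s.q for s in sets])
        m = np.concatenate([s.m for s in sets])
        qr = None
        if all(s.q_rh1 is not None for s in sets):
            qr = np.concatenate([s.q_rh1 for s in sets])
        return StimulusSet(q=q, m=m, label="combined", q_rh1=qr)


@dataclass
class SyntheticDataset:
    """Bundle of stimuli, simulated responses and the generating ground truth."""

    stimuli: StimulusSet
    responses: "pd.DataFrame"
    ground_truth: object
    seed: int


# ---------------------------------------------------------------------------
# Gamut sampling
# ---------------------------------------------------------------------------

def sample_gamut(
    n: int,
    c_iso: float = 5.0,
    constraints: list[tuple[np.ndarray, float]] | None = None,
    seed: int | np.random.Generator = 0,
    max_tries: int = 2000,
    led_system: LEDSystem | None = None,
    gamut_tol: float = 0.02,
) -> StimulusSet:
    """Sample ``n`` capture vectors uniformly on the isoluminant simplex.

    Captures are Dirichlet(1,1,1,1) draws scaled to sum to ``c_iso``;
    optional half-space ``constraints`` [(a, b) meaning a.q <= b] are applied
    by rejection.  When an ``led_system`` is given, sampling is further
    restricted to targets the LEDs can realize (relative residual below
    ``gamut_tol``) and the returned set carries LED drives and the broadband
    Rh1 capture of the realized mixture.  Deterministic under a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if c_iso <= 0:
        raise ValueError("c_iso must be positive")
    rng = np.random.default_rng(seed)
    out: list[np.ndarray] = []
    drives: list[np.ndarray] = []
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > max_tries and not out:
            raise ValueError("gamut constraints appear infeasible")
        batch = rng.dirichlet(np.ones(4), size=max(n, 64)) * c_iso
        if constraints:
            keep = np.ones(batch.shape[0], dtype=bool)
            for a, b in constraints:
                keep &= batch @ np.asarray(a, dtype=float) <= b
            batch = batch[keep]
        for q in batch:
            if led_system is not None:
                d, residual, _ = solve_led_drive(q, led_system)
                if residual > gamut_tol * np.linalg.norm(q):
                    continue
                drives.append(d)
            out.append(q)
            if len(out) == n:
                break
    q = np.asarray(out[:n])
    if led_system is not None:
        drive_arr = np.asarray(drives[:n])
        q_full = led_system.captures(drive_arr, include_rh1=True)
        return StimulusSet(q=q_full[:, :4], label="gamut", led_drive=drive_arr,
                           q_rh1=q_full[:, 4])
    return StimulusSet(q=q, label="gamut")


def realize_gamut(stimuli: StimulusSet, led_system: LEDSystem | None = None) -> StimulusSet:
    """Realize target captures with the LED system, attaching drives and Rh1.

    Solves the LED drives for every stimulus and recomputes the achieved
    captures, including the broadband Rh1 channel, so that the achromatic
    input x0 of the circuit model is defined.
    """
    led_system = led_system or LEDSystem()
    drives = np.empty((len(stimuli), 6))
    for i in range(len(stimuli)):
        drives[i], _, _ = solve_led_drive(stimuli.q[i], led_system)
    q_full = led_system.captures(drives, include_rh1=True)
    return StimulusSet(
        q=q_full[:, :4], m=stimuli.m, label=stimuli.label,
        stimulus_id=stimuli.stimulus_id, led_drive=drives, q_rh1=q_full[:, 4],
    )


def max_distance_subsample(
    stimuli: StimulusSet,
    fraction: float,
    candidate_pool_size: int = 10,
    seed: int | np.random.Generator = 0,
) -> StimulusSet:
    """Greedy spread (farthest-point) subsampling of a stimulus set.

    The first stimulus is picked at random; each subsequent pick is drawn
    uniformly from the ``candidate_pool_size`` not-yet-chosen stimuli that
    are farthest, in chromatic space, from the already-chosen set (maximin
    criterion), so every session spans color space.
    """
    n = len(stimuli)
    if n == 0:
        raise ValueError("empty stimulus set")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    k = max(1, int(round(fraction * n)))
    rng = np.random.default_rng(seed)
    points = stimuli.chroma
    chosen = [int(rng.integers(n))]
    remaining = set(range(n)) - set(chosen)
    dist_min = np.linalg.norm(points - points[chosen[0]], axis=1)
    while len(chosen) < k:
        rem = np.fromiter(remaining, dtype=int)
        pool = rem[np.argsort(dist_min[rem])[::-1][:candidate_pool_size]]
        pick = int(rng.choice(pool))
        chosen.append(pick)
        remaining.discard(pick)
        dist_min = np.minimum(dist_min, np.linalg.norm(points - points[pick], axis=1))
    idx = np.asarray(chosen)
    return stimuli.subset(idx)


# ---------------------------------------------------------------------------
# LED solving and the contrast set
# ---------------------------------------------------------------------------

def solve_led_drive(
    target_q: np.ndarray,
    led_system: LEDSystem,
    residual_tol: float = 1e-6,
) -> tuple[np.ndarray, float, bool]:
    """LED drives whose captures best match ``target_q`` (relative captures).

    Captures are linear in the absolute drives, so this is a bounded linear
    least-squares problem (drives in [0, max intensity]).  Six LEDs against
    four opsins leave the capture-matching solution underdetermined; ties
    are broken toward the background mixture scaled to the target's overall
    capture, which keeps the solve deterministic and physically sensible.
    Returns ``(drive, residual, in_gamut)``; out-of-gamut targets are
    flagged and the achieved point lies on the boundary of the LED gamut.
    """
    from scipy.optimize import lsq_linear

    target_q = np.asarray(target_q, dtype=float)
    if np.any(target_q < 0):
        raise ValueError("target captures must be nonnegative")
    M = led_system.capture_matrix
    ub = np.array([led_system.max_intensity[n] for n in LED_NAMES])
    anchor = led_system.background_drive * float(np.mean(target_q))
    eps = 1e-4
    A = np.vstack([M, eps * np.eye(6)])
    b = np.concatenate([target_q, eps * anchor])
    res = lsq_linear(A, b, bounds=(np.zeros(6), ub), tol=1e-12)
    residual = float(np.linalg.norm(M @ res.x - target_q))
    return res.x, residual, residual <= max(residual_tol, 1e-6 * np.linalg.norm(target_q))


def build_contrast_set(
    led_system: LEDSystem,
    steps: tuple[float, ...] = CONTRAST_STEPS,
    mixtures: tuple[str, ...] = CONTRAST_MIXTURES,
) -> StimulusSet:
    """Contrast stimulus set: single LEDs and mixtures at added intensities.

    Each LED named in a mixture is set to the step intensity *added on top of*
    the background drive, so a two-LED mixture at 1 uE adds 2 uE total.
    """
    combos = [(name,) for name in LED_NAMES] + [tuple(mix) for mix in mixtures]
    for combo in combos:
        for name in combo:
            if name not in LED_NAMES:
                raise ValueError(f"unknown LED name {name!r}")
    drives = []
    for combo in combos:
        for step in steps:
            d = led_system.background_drive.copy()
            for name in combo:
                d[LED_NAMES.index(name)] += step
            drives.append(d)
    drives = np.asarray(drives)
    q = led_system.captures(drives, include_rh1=True)
    return StimulusSet(q=q[:, :4], label="contrast", led_drive=drives, q_rh1=q[:, 4])


# ---------------------------------------------------------------------------
# Observation-count schemes
# ---------------------------------------------------------------------------

def session_observation_counts(
    stimuli: StimulusSet,
    n_sessions: int = 15,
    session_fraction: float = 0.2,
    repeats: int = 3,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Accumulate per-stimulus observation counts over simulated sessions.

    Each session covers ~``session_fraction`` of the stimuli (chosen by the
    greedy spread subsampler) with ``repeats`` presentations each, so counts
    vary across stimuli as in the real design.  Stimuli never chosen get a
    floor of one observation.
    """
    rng = np.random.default_rng(seed)
    m = np.zeros(len(stimuli), dtype=int)
    for _ in range(n_sessions):
        sub = max_distance_subsample(stimuli, session_fraction, seed=rng)
        pos = {int(s): i for i, s in enumerate(stimuli.stimulus_id)}
        for sid in sub.stimulus_id:
            m[pos[int(sid)]] += repeats
    m[m == 0] = 1
    return m


# ---------------------------------------------------------------------------
# Response and trace simulation
# ---------------------------------------------------------------------------

def _ground_truth_means(stimuli: StimulusSet, ground_truth) -> np.ndarray:
    """(n_stimuli, n_units) mean responses from a TuningFit or CircuitSpec."""
    from .circuit import CircuitSpec, steady_state_batch
    from .tuning_models import TuningFit, predict

    if isinstance(ground_truth, TuningFit):
        return predict(ground_truth, stimuli.chroma, stimuli.luminance)[:, None]
    if isinstance(ground_truth, CircuitSpec):
        return steady_state_batch(ground_truth, stimuli.X, stimuli.achromatic)
    raise TypeError("ground_truth must be a TuningFit or CircuitSpec")


def simulate_responses(
    stimuli: StimulusSet,
    ground_truth,
    noise_sd: float = 0.0,
    m: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
    unit_names: list[str] | None = None,
) -> pd.DataFrame:
    """Noisy per-stimulus response amplitudes from a ground-truth model.

    The observed amplitude of unit ``a`` to stimulus ``i`` is the model mean
    plus Gaussian noise of sd ``noise_sd / sqrt(m_i)`` (the ROI aggregate of
    ``m_i`` observations).  ``noise_sd**2`` is recorded as the single-trial
    noise power used by the noise-corrected R^2.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    means = _ground_truth_means(stimuli, ground_truth)
    n, n_units = means.shape
    m = stimuli.m if m is None else np.asarray(m)
    sd = noise_sd / np.sqrt(m)
    obs = means + rng.standard_normal(means.shape) * sd[:, None]
    if unit_names is None:
        unit_names = [f"unit{k}" for k in range(n_units)]
    rows = []
    for k, name in enumerate(unit_names):
        rows.append(
            pd.DataFrame(
                {
                    "roi_id": name,
                    "stimulus_id": stimuli.stimulus_id,
                    "amplitude": obs[:, k],
                    "m": m,
                    "sigma2": noise_sd**2,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def simulate_traces(
    amplitudes: np.ndarray,
    fs: float = 30.0,
    stim_dur: float = 0.5,
    isi: float = 2.0,
    pre_post: float = 20.0,
    noise_sd: float = 0.0,
    drift_amplitude: float = 0.0,
    baseline_f: float = 1.0,
    decay_tau: float = 0.2,
    plateau_ext: float = 0.3,
    seed: int | np.random.Generator = 0,
):
    """Stimulus-locked fluorescence traces with indicator-like step responses.

    Each stimulus evokes a plateau at its amplitude lasting the stimulus
    duration plus ``plateau_ext`` seconds, then an exponential decay of
    ``decay_tau`` seconds — a caricature of calcium-indicator offset
    kinetics, which also keeps the falling edge clear of the amplitude
    window so the extraction's smoothing stage cannot clip it.  The dF/F
    extraction recovers ``amplitudes`` (one per stimulus, presented in
    order) in the noiseless case.  ``drift_amplitude`` adds a slow
    sinusoidal baseline drift; noise is white Gaussian on the fluorescence.
    """
    from .signals import Trace

    if fs < 15.0:
        raise ValueError("sampling rate must be >= 15 Hz")
    amplitudes = np.asarray(amplitudes, dtype=float)
    rng = np.random.default_rng(seed)
    n = amplitudes.shape[0]
    onsets = pre_post + np.arange(n) * (stim_dur + isi)
    total = onsets[-1] + stim_dur + pre_post
    t = np.arange(0.0, total, 1.0 / fs)
    signal = np.zeros_like(t)
    for onset, amp in zip(onsets, amplitudes):
        u = t - onset
        hold = stim_dur + plateau_ext
        kernel = np.where(
            (u >= 0) & (u <= hold), 1.0,
            np.where(u > hold, np.exp(-(u - hold) / decay_tau), 0.0),
        )
        signal += amp * kernel
    drift = drift_amplitude * np.sin(2 * np.pi * t / (total * 2.0))
    f = baseline_f * (1.0 + signal + drift) + noise_sd * rng.standard_normal(t.shape)
    return Trace(time=t, values=f, onsets=onsets, stimulus_ids=np.arange(n), fs=fs)
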