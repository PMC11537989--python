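"""Shared independent oracles for the circuit tests."""

import numpy as np

from flyhue import circuit as c


def euler_steady_state(spec, X, x0, dt=0.001, t_end=10.0):
    """Forward-Euler integration of the rate equations to equilibrium."""
    y = np.zeros(12)
    for _ in range(int(t_end / dt)):
        drive = spec.w @ y + spec.j @ X + spec.p * x0
        target = c.modified_tanh(spec.g * drive, spec.gamma)
        y = y + dt / spec.tau * (-y + target)
    return y


def random_stable_spec(rng):
    """Random spec whose Picard map is a contraction (spectral norm < 1)."""
    w = rng.standard_normal((12, 12)) * rng.binomial(1, 0.4, (12, 12))
    g = rng.uniform(0.5, 1.5, 12)
    row = np.abs(w).sum(axis=1)
    w = w / np.maximum(row, 1e-9)[:, None] * rng.uniform(0.3, 0.8, 12)[:, None] / g[:, None]
    j = np.zeros((12, 4))
    for a in c.PHOTORECEPTORS:
        j[a, c.OPSIN_OF_PHOTORECEPTOR[a]] = 1.0 - np.abs(w[a]).sum()
    for a in range(4, 12):
        w[a] /= max(np.abs(w[a]).sum(), 1e-9)
    p = rng.standard_normal(12) * 0.3
    gamma = rng.uniform(-0.6, 0.6, 12)
    gamma[c.DM9] = 0.0
    return c.CircuitSpec(w=w, j=j, p=p, g=g, gamma=gamma)
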