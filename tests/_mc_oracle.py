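"""Independent Monte-Carlo random-walk oracles for restricted-diffusion signals.

Simulates spins inside a reflecting sphere (3-D) or an infinite reflecting
cylinder's cross-section (2-D disk) under a PGSE gradient pair and returns the
magnitude attenuation E = <cos phi>.  Used only as a cross-check of the GPD
series kernels; deliberately shares no code with the package implementation.
"""

from __future__ import annotations

import numpy as np

GAMMA = 2.6751525e8  # rad s^-1 T^-1 (proton)


def _uniform_in_ball(rng, n, radius, dim):
    pts = rng.standard_normal((n, dim))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1.0 / dim)
    return pts * r[:, None]


def _reflect(pos, radius):
    r = np.linalg.norm(pos, axis=1)
    out = r > radius
    if out.any():
        scale = (2.0 * radius - r[out]) / r[out]
        # a large overshoot could re-exit; clamp to the boundary in that case
        scale = np.maximum(scale, 0.0)
        pos[out] *= scale[:, None]
    return pos


def mc_restricted_attenuation(
    D: float,
    radius_m: float,
    G: float,
    delta_s: float,
    Delta_s: float,
    geometry: str = "sphere",
    n_walkers: int = 50_000,
    seed: int = 0,
    dt_max: float = 2.0e-4,
) -> float:
    """Random-walk PGSE attenuation in a reflecting sphere or disk.

    The gradient is applied along the first coordinate axis; for the disk
    geometry this is a perpendicular-plane simulation (no parallel component).
    """
    dim = 3 if geometry == "sphere" else 2
    rng = np.random.default_rng(seed)
    # step small enough to resolve both the pulse and the geometry
    dt = min(dt_max, delta_s / 25.0, radius_m**2 / (2.0 * dim * D) / 25.0)
    n_steps = int(np.ceil((Delta_s + delta_s) / dt))
    dt = (Delta_s + delta_s) / n_steps
    sigma = np.sqrt(2.0 * D * dt)
    pos = _uniform_in_ball(rng, n_walkers, radius_m, dim)
    phase = np.zeros(n_walkers)
    for k in range(n_steps):
        t_mid = (k + 0.5) * dt
        pos += sigma * rng.standard_normal((n_walkers, dim))
        pos = _reflect(pos, radius_m)
        if t_mid < delta_s:
            g = G
        elif Delta_s <= t_mid < Delta_s + delta_s:
            g = -G
        else:
            g = 0.0
        if g != 0.0:
            phase += GAMMA * g * pos[:, 0] * dt
    return float(np.mean(np.cos(phase)))


def g_from_b(b_smm2: float, delta_s: float, Delta_s: float) -> float:
    """Gradient amplitude (T/m) giving nominal b (s/mm²) for a PGSE pair."""
    b_si = b_smm2 * 1e6
    return float(np.sqrt(b_si / (GAMMA**2 * delta_s**2 * (Delta_s - delta_s / 3.0))))
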