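"""Monte-Carlo random-walk simulation of restricted diffusion in a cylinder.

Walkers diffuse in the 2-D cross-section of an impermeable (reflecting)
cylinder; spin phase is accumulated under the PGSE effective gradient
waveform (+g during the first pulse, -g during the second).  The parallel
component is free and factors out analytically, so only the transverse plane
is simulated.  This simulator is deliberately independent of the
Gaussian-phase-approximation series in :mod:`reffmap.forward_model` and
serves as its validation oracle.

Steps are dichotomous (+/- sigma per axis, sigma = sqrt(2 D0 dt)), the
standard fixed-step scheme for restricted-geometry walkers: over thousands
of steps the walk converges to Brownian motion while the per-step cost stays
small.  Reflection uses the radial-mirror rule, accurate for step sizes much
smaller than the cylinder radius.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .units import GAMMA

__all__ = ["random_walk_cylinder_perp"]


@njit(cache=True, fastmath=True)
def _walk_phases(R, sigma, n1, n2, n3, n_walkers, seed):
    """Per-walker integral sum_t f_t x_t (in step units) for the PGSE waveform.

    The waveform is +1 for n1 steps, 0 for n2 steps, -1 for n3 steps.
    Returns an array of sum(x, pulse1) - sum(x, pulse2) per walker.
    """
    out = np.empty(n_walkers)
    R2 = R * R
    state = np.uint64(seed * np.uint64(6364136223846793005) + np.uint64(1442695040888963407))
    n_steps = n1 + n2 + n3
    for i in range(n_walkers):
        # uniform start in the disc via rejection on xorshift64* uniforms
        while True:
            state ^= state >> np.uint64(12)
            state ^= state << np.uint64(25)
            state ^= state >> np.uint64(27)
            u1 = np.float64(state * np.uint64(2685821657736338717) >> np.uint64(11)) * 1.1102230246251565e-16
            state ^= state >> np.uint64(12)
            state ^= state << np.uint64(25)
            state ^= state >> np.uint64(27)
            u2 = np.float64(state * np.uint64(2685821657736338717) >> np.uint64(11)) * 1.1102230246251565e-16
            x = (2.0 * u1 - 1.0) * R
            y = (2.0 * u2 - 1.0) * R
            if x * x + y * y <= R2:
                break
        m = 0.0
        bits = np.uint64(0)
        nbits = 0
        for t in range(n_steps):
            if nbits == 0:
                state ^= state >> np.uint64(12)
                state ^= state << np.uint64(25)
                state ^= state >> np.uint64(27)
                bits = state * np.uint64(2685821657736338717)
                nbits = 32
            x += sigma if (bits & np.uint64(1)) else -sigma
            y += sigma if (bits & np.uint64(2)) else -sigma
            bits >>= np.uint64(2)
            nbits -= 1
            r2 = x * x + y * y
            if r2 > R2:
                scale = (2.0 * R - math.sqrt(r2)) / math.sqrt(r2)
                x *= scale
                y *= scale
            if t < n1:
                m += x
            elif t >= n1 + n2:
                m -= x
        out[i] = m
    return out


def random_walk_cylinder_perp(
    r: float,
    g_perp: float,
    delta: float,
    Delta: float,
    D0: float,
    n_walkers: int = 200_000,
    n_steps: int = 20_000,
    seed: int = 0,
    gamma: float = GAMMA,
) -> float:
    """Perpendicular PGSE cylinder signal by random walk.

    Parameters mirror :func:`reffmap.forward_model.gpa_cylinder_perp`:
    radius ``r`` (um), perpendicular gradient ``g_perp`` (mT/m), pulse width
    ``delta`` and mixing time ``Delta`` (ms), diffusivity ``D0`` (um^2/ms).

    Returns the signal fraction ``E[cos(phi)]`` (the sine component vanishes
    by symmetry).
    """
    if r <= 0:
        raise ValueError("radius must be > 0")
    if not 0 < delta < Delta:
        raise ValueError("require 0 < delta < Delta")
    total_t = Delta + delta
    dt = total_t / n_steps
    sigma = math.sqrt(2.0 * D0 * dt)
    # waveform segments by midpoint rule: +1 on [0, delta), 0, -1 on [Delta, .)
    t_mid = (np.arange(n_steps) + 0.5) * dt
    n1 = int(np.sum(t_mid < delta))
    n3 = int(np.sum(t_mid >= Delta))
    n2 = n_steps - n1 - n3
    m = _walk_phases(r, sigma, n1, n2, n3, n_walkers, np.uint64(seed + 1))
    phases = gamma * g_perp * m * dt
    return float(np.mean(np.cos(phases)))
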