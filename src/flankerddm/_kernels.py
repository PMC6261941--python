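"""Numba kernels for the discrete-time multistage diffusion.

The decision variable evolves in three stages measured from flanker onset:
a zero-drift noisy segment during the non-decision time, a flanker-driven
drift segment lasting one stimulus-onset asynchrony (SOA), and a
target-driven segment thereafter.  Boundary crossings are only registered
once drift accumulation has begun (at the realised non-decision time); the
zero-drift segment therefore collapses to a single Gaussian displacement
with standard deviation s*sqrt(ter_t), which is distributionally exact.

Each trial consumes an independent noise stream derived from the master
seed and the trial index, so a trial is reproducible in isolation and the
same stream is reused across optimiser proposals (common random numbers).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Knuth multiplicative-hash constant; keeps per-trial seeds decorrelated.
_SEED_MIX = 2654435761
_SEED_MOD = 2147483647


@njit(cache=True)
def _trial_seed(seed, index):
    return (seed + _SEED_MIX * (index + 1)) % _SEED_MOD


@njit(cache=True)
def simulate_batch(v_t, f_t, z_t, ter_t, flanker_dir, target_dir,
                   a, s, dt, soa, max_time, seed):
    """Simulate n trials; returns (choice, rt, crossed_during_flanker).

    choice: +1 positive boundary (left hand), -1 negative, 0 miss.
    rt is referenced to target onset (crossing time minus SOA), NaN on miss.
    """
    n = v_t.shape[0]
    choice = np.zeros(n, np.int8)
    rt = np.full(n, np.nan)
    flanker_cross = np.zeros(n, np.bool_)
    sqdt = np.sqrt(dt)
    for i in range(n):
        np.random.seed(_trial_seed(seed, i))
        # Zero-drift noisy diffusion during the non-decision time,
        # collapsed to its exact Gaussian displacement.
        x = z_t[i] + s * np.sqrt(ter_t[i]) * np.random.standard_normal()
        mu1 = flanker_dir[i] * v_t[i] * f_t[i]
        mu2 = target_dir[i] * v_t[i]
        n_steps = int((max_time - ter_t[i]) / dt)
        for k in range(n_steps):
            elapsed = k * dt  # time since accumulation onset
            mu = mu1 if elapsed < soa else mu2
            x += mu * dt + s * sqdt * np.random.standard_normal()
            if x >= a or x <= -a:
                tc = ter_t[i] + (k + 1) * dt  # from flanker onset
                choice[i] = 1 if x > 0.0 else -1
                rt[i] = tc - soa
                flanker_cross[i] = (k + 1) * dt <= soa
                break
    return choice, rt, flanker_cross


@njit(cache=True)
def simulate_batch_cached_noise(v_t, f_t, z_t, ter_t, flanker_dir, target_dir,
                                a, s, dt, soa, noise):
    """Like :func:`simulate_batch` but reading a pre-generated standard
    normal matrix ``noise`` of shape (n, 1 + n_steps): column 0 feeds the
    collapsed non-decision displacement, columns 1.. the decision-stage
    steps.  Reusing one matrix across optimiser proposals gives exact
    common random numbers at a fraction of the RNG cost.  A trial that
    has not crossed within the matrix width counts as a miss.
    """
    n = v_t.shape[0]
    n_steps = noise.shape[1] - 1
    choice = np.zeros(n, np.int8)
    rt = np.full(n, np.nan)
    flanker_cross = np.zeros(n, np.bool_)
    sqdt = np.sqrt(dt)
    for i in range(n):
        x = z_t[i] + s * np.sqrt(ter_t[i]) * noise[i, 0]
        mu1 = flanker_dir[i] * v_t[i] * f_t[i]
        mu2 = target_dir[i] * v_t[i]
        for k in range(n_steps):
            elapsed = k * dt
            mu = mu1 if elapsed < soa else mu2
            x += mu * dt + s * sqdt * noise[i, k + 1]
            if x >= a or x <= -a:
                tc = ter_t[i] + (k + 1) * dt
                choice[i] = 1 if x > 0.0 else -1
                rt[i] = tc - soa
                flanker_cross[i] = (k + 1) * dt <= soa
                break
    return choice, rt, flanker_cross


@njit(cache=True)
def simulate_trace_batch(v_t, f_t, z_t, ter_t, flanker_dir, target_dir,
                         a, s, dt, soa, t_start, max_time, decay_rate, seed):
    """Full decision-variable paths on a fixed grid from t_start (<= 0,
    pre-flanker) to max_time, both relative to flanker onset.

    Pre-flanker samples sit noiselessly at the start point; from flanker
    onset the zero-drift noisy non-decision segment is stepped explicitly
    so the path is visible.  After a boundary crossing the variable
    relaxes back to baseline with rate ``decay_rate`` (mean-reverting,
    Ornstein-Uhlenbeck-like).  Returns (paths, choice, rt, crossing
    sample index or -1).
    """
    n = v_t.shape[0]
    n_samp = int(np.round((max_time - t_start) / dt)) + 1
    paths = np.zeros((n, n_samp))
    choice = np.zeros(n, np.int8)
    rt = np.full(n, np.nan)
    cross_idx = np.full(n, -1, np.int64)
    sqdt = np.sqrt(dt)
    for i in range(n):
        np.random.seed(_trial_seed(seed, i))
        xi = z_t[i]
        mu1 = flanker_dir[i] * v_t[i] * f_t[i]
        mu2 = target_dir[i] * v_t[i]
        t1 = ter_t[i]
        t2 = ter_t[i] + soa
        crossed = False
        for k in range(n_samp):
            t = t_start + k * dt  # time of this sample, from flanker onset
            if t <= 0.0:
                paths[i, k] = xi  # noiseless baseline at the start point
                continue
            if not crossed:
                if t <= t1:
                    mu = 0.0
                elif t <= t2:
                    mu = mu1
                else:
                    mu = mu2
                xi += mu * dt + s * sqdt * np.random.standard_normal()
                if t > t1 and (xi >= a or xi <= -a):
                    crossed = True
                    cross_idx[i] = k
                    choice[i] = 1 if xi > 0.0 else -1
                    rt[i] = t - soa
            else:
                xi += -decay_rate * xi * dt + s * sqdt * np.random.standard_normal()
            paths[i, k] = xi
    return paths, choice, rt, cross_idx
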