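"""Synthetic flanker-task data with the statistical structure the
analyses assume.

Three generators cover the full pipeline without any recorded data:

* ``generate_task_design`` — the counterbalanced 1088-trial design
  (50% congruent, close/far flanker distance, short/long
  response-stimulus interval, breaks every 200 trials) with transition
  counts between successive congruence/distance levels balanced via a
  randomised Eulerian circuit.
* ``generate_behavior`` — sequential diffusion simulation in which each
  trial's parameters depend on its condition and on the accuracy of the
  previous simulated trial (post-error boundary increase, drift decrease,
  flanker-weight decrease by default), recording the ground-truth
  single-trial parameter realisations for later regression tests.
* ``generate_beta_epochs`` — two-channel "sensorimotor" band-power
  epochs in which the lateralised component is proportional to the
  simulated decision variable (signed toward the chosen hand) plus white
  channel noise, emulating what the lateralisation analyses assume about
  motor beta power.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels
from .ddm_core import (DEFAULT_DT, DEFAULT_MAX_TIME, SOA, DDMParams,
                       DecisionTrace, sample_trial_params_batch)

#: trials between task breaks
BLOCK_LENGTH = 200
RSI_SHORT = 0.25
RSI_LONG = 0.70

#: group-level diffusion parameters used as generator defaults.  Non-decision
#: time and its width follow the fitted group means (ter = 290 ms,
#: st = 120 ms) and the flanker weighting its group mean (f = 0.44); the
#: remaining values were chosen once to give realistic flanker behaviour
#: (rare congruent errors, ~80% incongruent accuracy, ~65 ms interference,
#: fast incongruent errors) at the conventional noise scale s = 0.1.
GROUP_PARAMS = DDMParams(v=2.5, a=0.16, ter=0.29, f=0.44,
                         sv=0.5, sz=0.08, st=0.12, sf=0.15)


@dataclass(frozen=True)
class BetaSpec:
    """Mapping from decision variable to synthetic two-channel beta power.

    The contralateral channel receives baseline - lambda/2 * D(t) and the
    ipsilateral channel baseline + lambda/2 * D(t), where D is the
    decision variable signed toward the chosen hand, so the expected
    lateralisation (contra minus ipsi) is -lambda * D(t).  Defaults give a
    single-trial signal-to-noise ratio of roughly 0.3 so that group-level
    statistics are required, as with real scalp data.
    """

    lambda_gain: float = 5.0
    baseline: float = 10.0
    noise_sd: float = 1.9
    sfreq: float = 250.0


@dataclass(frozen=True)
class GeneratorSpec:
    """Ground-truth effect structure for the behavioural generator."""

    base: DDMParams = GROUP_PARAMS
    #: multiplicative change of the effective flanker weight by distance;
    #: close flankers interfere more
    distance_f: dict = field(default_factory=lambda: {"close": 1.2, "far": 0.85})
    #: post-error parameter changes: boundary up, drift down, flanker
    #: weight down, non-decision time unchanged
    posterror_a: float = 1.3
    posterror_v: float = 0.8
    posterror_f: float = 0.6
    posterror_ter_shift: float = 0.0
    #: boundary multiplier after a long response-stimulus interval
    rsi_a: float = 1.0
    beta: BetaSpec = BetaSpec()
    decay_rate: float = 20.0
    seed: int = 0

    def params_for(self, distance: str, prev_error: bool,
                   rsi_long: bool) -> DDMParams:
        """Trial parameter set given condition and one-back history."""
        p = self.base
        f = p.f * self.distance_f[distance]
        a, v, ter = p.a, p.v, p.ter
        if prev_error:
            a *= self.posterror_a
            v *= self.posterror_v
            f *= self.posterror_f
            ter += self.posterror_ter_shift
        if rsi_long:
            a *= self.rsi_a
        return replace(p, v=v, a=a, ter=ter, f=f)


def _eulerian_state_sequence(n_trials: int, rng: np.random.Generator) -> np.ndarray:
    """Random sequence over the 4 congruence-by-distance states whose
    16 transition counts are as equal as possible (Eulerian circuit)."""
    base, rem = divmod(n_trials, 16)
    mult = np.full((4, 4), base, int)
    if rem:  # rem == 8 for sizes divisible by 8 but not 16
        for i in range(4):
            mult[i, i] += 1                 # self loops keep degrees equal
        for i in range(4):
            mult[i, (i + 1) % 4] += 1       # a 4-cycle keeps degrees equal
    # multiset of outgoing edges per node, shuffled
    out_edges = [list(np.repeat(np.arange(4), mult[i])) for i in range(4)]
    for e in out_edges:
        rng.shuffle(e)
    # Hierholzer's algorithm
    stack = [int(rng.integers(4))]
    circuit: list[int] = []
    while stack:
        v = stack[-1]
        if out_edges[v]:
            stack.append(out_edges[v].pop())
        else:
            circuit.append(stack.pop())
    circuit.reverse()
    return np.array(circuit[:n_trials])


def generate_task_design(n_trials: int = 1088, seed: int = 0) -> pd.DataFrame:
    """Counterbalanced pseudorandom flanker task design.

    Exactly half the trials are congruent; within each congruence level
    and within each distance level, half the trials are preceded by a
    short and half by a long response-stimulus interval.  Transition
    counts between successive congruence/distance states are balanced to
    within one trial.  Sizes not divisible by 8 are rounded to the
    nearest feasible size with a warning.
    """
    if n_trials % 8:
        import warnings
        feasible = max(8, 8 * round(n_trials / 8))
        warnings.warn(f"n_trials must be divisible by 8; using {feasible}")
        n_trials = feasible
    rng = np.random.default_rng(seed)
    states = _eulerian_state_sequence(n_trials, rng)
    congruent = states < 2
    distance = np.where(states % 2 == 0, "close", "far")
    # preceding-interval balance within each congruence x distance cell
    rsi = np.empty(n_trials)
    for st in range(4):
        idx = np.flatnonzero(states == st)
        half = len(idx) // 2
        vals = np.r_[np.full(half, RSI_SHORT),
                     np.full(len(idx) - half, RSI_LONG)]
        rng.shuffle(vals)
        rsi[idx] = vals
    # balanced target directions within each cell
    target_dir = np.empty(n_trials, int)
    for st in range(4):
        idx = np.flatnonzero(states == st)
        half = len(idx) // 2
        vals = np.r_[np.ones(half, int), -np.ones(len(idx) - half, int)]
        rng.shuffle(vals)
        target_dir[idx] = vals
    trial = np.arange(1, n_trials + 1)
    return pd.DataFrame({
        "trial": trial,
        "congruent": congruent,
        "distance": distance,
        "rsi": rsi,
        "target_dir": target_dir,
        "block": (trial - 1) // BLOCK_LENGTH,
        "trials_since_break": (trial - 1) % BLOCK_LENGTH,
    })


def generate_behavior(design: pd.DataFrame, spec: GeneratorSpec | None = None,
                      dt: float = DEFAULT_DT,
                      max_time: float = DEFAULT_MAX_TIME) -> pd.DataFrame:
    """Sequentially simulate the design with history-dependent parameters.

    Each trial's diffusion parameters are the base set adjusted by the
    trial's distance and preceding interval and by the accuracy of the
    previous simulated trial.  The returned table carries the realised
    single-trial parameter values (v_t, f_t, z_t, ter_t), the per-trial
    noise-stream seed (so any trial replays bit-identically through
    ``simulate_trial``), and all factors used by the regression analyses.
    """
    spec = spec or GeneratorSpec()
    rng = np.random.default_rng(spec.seed)
    n = len(design)
    congruent = design["congruent"].to_numpy(bool)
    distance = design["distance"].to_numpy()
    rsi = design["rsi"].to_numpy(float)
    target_dir = design["target_dir"].to_numpy(float)
    first_of_block = design["trials_since_break"].to_numpy() == 0

    rows = []
    prev_error = False
    base_seed = int(rng.integers(2**31 - 1))
    for i in range(n):
        p = spec.params_for(distance[i], prev_error and not first_of_block[i],
                            rsi[i] == RSI_LONG)
        tp = sample_trial_params_batch(p, 1, rng)
        fdir = target_dir[i] if congruent[i] else -target_dir[i]
        trial_seed = (base_seed + 7919 * i) % (2**31 - 1)
        choice, rt, fcross = _kernels.simulate_batch(
            tp["v_t"], tp["f_t"], tp["z_t"], tp["ter_t"],
            np.array([fdir]), np.array([target_dir[i]]),
            p.a, p.s, dt, SOA, max_time, trial_seed)
        c = int(choice[0])
        correct = c == target_dir[i]
        rows.append({
            "prev_accuracy": 1 if prev_error else -1,
            "choice": c, "rt": float(rt[0]), "correct": bool(correct),
            "miss": c == 0,
            "crossed_during_flanker_stage": bool(fcross[0]),
            "v_t": float(tp["v_t"][0]), "f_t": float(tp["f_t"][0]),
            "z_t": float(tp["z_t"][0]), "ter_t": float(tp["ter_t"][0]),
            "a_true": p.a, "trial_seed": trial_seed,
        })
        prev_error = not correct
    out = design.reset_index(drop=True).join(pd.DataFrame(rows))
    out["rt_ms"] = out["rt"] * 1000.0
    out["hand"] = -out["choice"]  # positive boundary = left hand = -1 coding
    out["first_of_block"] = first_of_block
    out["following_rsi"] = np.r_[rsi[1:], np.nan]
    return out


@dataclass
class BetaEpochs:
    """Epoched two-channel band power with per-trial metadata.

    ``power`` has shape (n_trials, 2, n_samples); channel 0 is the left
    hemisphere, channel 1 the right.  ``times`` is in seconds relative to
    the alignment event (flanker onset, or the response after
    re-epoching).  The metadata table resolves each trial's contralateral
    and ipsilateral channel through the response hand (-1 left, +1 right)
    and carries the response sample index for response locking.
    """

    power: np.ndarray
    times: np.ndarray
    sfreq: float
    metadata: pd.DataFrame
    alignment: str = "flanker"
    ch_names: tuple[str, str] = ("left_hemi", "right_hemi")


def generate_beta_epochs(traces: DecisionTrace, spec: GeneratorSpec | None = None,
                         metadata: pd.DataFrame | None = None,
                         seed: int | None = None) -> BetaEpochs:
    """Synthetic beta-band power epochs derived from decision traces.

    Trials without a response are dropped.  The decision variable is
    signed toward the chosen hand and injected antisymmetrically into the
    two channels (see :class:`BetaSpec`); independent white noise is added
    per channel and sample, and the trace is resampled to the beta
    pipeline's working rate.
    """
    spec = spec or GeneratorSpec()
    b = spec.beta
    if b.lambda_gain < 0:
        raise ValueError("lambda_gain must be non-negative "
                         "(zero gives pure-noise channels)")
    rng = np.random.default_rng(spec.seed + 101 if seed is None else seed)
    keep = traces.choice != 0
    choice = traces.choice[keep].astype(float)
    x = traces.x[keep]
    rt = traces.rt[keep]
    # decimate the 1 kHz trace to the band-power rate
    step = max(1, int(round(1.0 / (b.sfreq * (traces.times[1] - traces.times[0])))))
    x = x[:, ::step]
    times = traces.times[::step]
    n, t = x.shape
    d = x * choice[:, None]   # positive = evidence for the chosen hand
    hand = -choice            # -1 = left hand (positive boundary)
    contra = b.baseline - 0.5 * b.lambda_gain * d + b.noise_sd * rng.standard_normal((n, t))
    ipsi = b.baseline + 0.5 * b.lambda_gain * d + b.noise_sd * rng.standard_normal((n, t))
    power = np.empty((n, 2, t))
    left_hand = hand < 0      # contra = right hemisphere (channel 1)
    power[left_hand, 1] = contra[left_hand]
    power[left_hand, 0] = ipsi[left_hand]
    power[~left_hand, 0] = contra[~left_hand]
    power[~left_hand, 1] = ipsi[~left_hand]
    # response sample index on the decimated grid (times are flanker-locked,
    # rt is target-locked)
    resp_t = rt + SOA
    resp_idx = np.round((resp_t - times[0]) * b.sfreq).astype(int)
    if metadata is not None:
        meta = metadata.loc[keep].reset_index(drop=True).copy()
    else:
        meta = traces.stimuli.loc[keep].reset_index(drop=True).copy()
    if "target_dir" in meta:
        meta["correct"] = (choice == meta["target_dir"].to_numpy()).astype(bool)
    meta["hand"] = hand.astype(int)
    meta["choice"] = choice.astype(int)
    meta["rt"] = rt
    meta["response_idx"] = resp_idx
    return BetaEpochs(power=power, times=times, sfreq=b.sfreq, metadata=meta,
                      alignment="flanker")
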