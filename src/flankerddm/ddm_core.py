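"""Multistage drift-diffusion model of the arrow flanker task.

The model describes a two-choice decision as a noisy accumulation of
evidence toward one of two symmetric boundaries at +/- ``a``.  Because the
flanking arrows appear 83 ms before the target, evidence first follows the
flanker direction, weighted by a dimensionless gain ``f`` (f < 1 means
distractor suppression), and switches to the target direction thereafter.
Accumulation begins only after a non-decision time ``ter`` measured from
flanker onset; reported response times are referenced to target onset.

Trial-to-trial variability follows the standard diffusion-model
conventions: drift ``v`` and flanker weight ``f`` vary as Gaussians with
standard deviations ``sv`` and ``sf``; the start point and non-decision
time vary uniformly over widths ``sz`` and ``st``.  The diffusion noise
scale ``s`` is fixed at 0.1 (evidence units per square-root second), so
increments over a step dt are Normal(drift * dt, s^2 * dt) and parameter
values do not depend on the step size.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from . import _kernels

#: stimulus-onset asynchrony between flankers and target, seconds
SOA = 0.083
#: simulation step, seconds
DEFAULT_DT = 0.001
#: trials that have not crossed a boundary by this time count as misses
DEFAULT_MAX_TIME = 3.0
#: default relaxation rate of the decision variable after a response (1/s)
DEFAULT_DECAY_RATE = 20.0


@dataclass(frozen=True)
class DDMParams:
    """The eight diffusion parameters plus the fixed noise scale.

    v : drift rate (evidence / s)
    sv : SD of trial-to-trial drift variability
    a : boundary separation half-height; boundaries at +/- a
    sz : width of the uniform start-point distribution
    ter : non-decision time from flanker onset (s)
    st : width of the uniform non-decision-time distribution (s)
    f : flanker weighting, drift multiplier during the flanker stage
    sf : SD of trial-to-trial flanker-weight variability
    s : diffusion noise scale, fixed at 0.1
    """

    v: float
    a: float
    ter: float
    f: float = 1.0
    sv: float = 0.0
    sz: float = 0.0
    st: float = 0.0
    sf: float = 0.0
    s: float = 0.1

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("boundary a must be positive")
        if min(self.sv, self.sz, self.st, self.sf) < 0:
            raise ValueError("variability parameters must be non-negative")
        if self.ter <= 0:
            raise ValueError("non-decision time must be positive")
        if self.ter - self.st / 2 < 0:
            raise ValueError("ter - st/2 must be non-negative")
        if self.sz / 2 >= self.a:
            raise ValueError("start points must lie strictly inside the boundaries")

    def replace(self, **kwargs) -> "DDMParams":
        return dataclasses.replace(self, **kwargs)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class TrialParams:
    """Realised single-trial parameter values."""

    v_t: float
    f_t: float
    z_t: float
    ter_t: float


@dataclass(frozen=True)
class StimulusSpec:
    """One flanker-task stimulus.

    target_dir: +1 if the left-hand (positive-boundary) response is
    correct, -1 otherwise.  Flankers point with the target on congruent
    trials and against it on incongruent trials.
    """

    target_dir: int
    congruent: bool
    soa: float = SOA

    @property
    def flanker_dir(self) -> int:
        return self.target_dir if self.congruent else -self.target_dir


@dataclass(frozen=True)
class TrialOutcome:
    """Simulated response of one trial.

    choice is +1 (left hand, positive boundary), -1 (right hand) or None
    when no boundary was crossed before ``max_time``.  rt is in seconds
    relative to target onset.
    """

    choice: int | None
    rt: float | None
    correct: bool
    crossed_during_flanker_stage: bool = False


def sample_trial_params(params: DDMParams, rng: np.random.Generator) -> TrialParams:
    """Draw realised single-trial parameters.

    Drift and flanker weight are Gaussian (untruncated: a draw of f above
    one models a trial on which the distractors were not suppressed);
    start point and non-decision time are uniform over their widths.
    """
    return TrialParams(
        v_t=params.v + params.sv * rng.standard_normal(),
        f_t=params.f + params.sf * rng.standard_normal(),
        z_t=rng.uniform(-params.sz / 2, params.sz / 2),
        ter_t=rng.uniform(params.ter - params.st / 2, params.ter + params.st / 2),
    )


def sample_trial_params_batch(params: DDMParams, n: int,
                              rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Vectorised version of :func:`sample_trial_params`."""
    return {
        "v_t": params.v + params.sv * rng.standard_normal(n),
        "f_t": params.f + params.sf * rng.standard_normal(n),
        "z_t": rng.uniform(-params.sz / 2, params.sz / 2, n),
        "ter_t": rng.uniform(params.ter - params.st / 2,
                             params.ter + params.st / 2, n),
    }


def _check_config(dt: float, max_time: float) -> None:
    if dt <= 0 or max_time <= 0:
        raise ValueError("dt and max_time must be positive")


def simulate_trial(tp: TrialParams, stim: StimulusSpec, params: DDMParams,
                   dt: float = DEFAULT_DT, max_time: float = DEFAULT_MAX_TIME,
                   seed: int = 0) -> TrialOutcome:
    """Simulate a single trial with realised parameters ``tp``.

    The noise stream is fully determined by ``seed``, so a trial recorded
    during a batch run can be replayed bit-identically.
    """
    _check_config(dt, max_time)
    choice, rt, fcross = _kernels.simulate_batch(
        np.array([tp.v_t]), np.array([tp.f_t]), np.array([tp.z_t]),
        np.array([tp.ter_t]),
        np.array([float(stim.flanker_dir)]), np.array([float(stim.target_dir)]),
        params.a, params.s, dt, stim.soa, max_time, seed)
    c = int(choice[0])
    if c == 0:
        return TrialOutcome(choice=None, rt=None, correct=False)
    return TrialOutcome(choice=c, rt=float(rt[0]), correct=(c == stim.target_dir),
                        crossed_during_flanker_stage=bool(fcross[0]))


def deterministic_rt(params: DDMParams, stim: StimulusSpec) -> tuple[int | None, float | None]:
    """Closed-form response of the noise-free, zero-variance limit.

    Evidence moves piecewise linearly: at rate flanker_dir*v*f for one SOA
    after accumulation onset (ter), then at rate target_dir*v.  Returns
    (choice, rt) with rt referenced to target onset, or (None, None) if no
    boundary is ever reached.
    """
    if max(params.sv, params.st, params.sz, params.sf) > 0:
        raise ValueError("deterministic_rt requires zero variability parameters")
    mu1 = stim.flanker_dir * params.v * params.f
    mu2 = stim.target_dir * params.v
    a = params.a
    # flanker stage: x(t) = mu1 * t for t in [0, soa]
    if mu1 != 0:
        t_cross = a / abs(mu1)
        if t_cross <= stim.soa:
            choice = 1 if mu1 > 0 else -1
            return choice, params.ter + t_cross - stim.soa
    x1 = mu1 * stim.soa
    if mu2 == 0:
        return None, None
    target = a if mu2 > 0 else -a
    t2 = (target - x1) / mu2
    choice = 1 if mu2 > 0 else -1
    return choice, params.ter + stim.soa + t2 - stim.soa


@dataclass(frozen=True)
class DecisionTrace:
    """Sampled decision-variable paths for a set of trials."""

    times: np.ndarray          # seconds from flanker onset
    x: np.ndarray              # (n_trials, n_samples)
    choice: np.ndarray         # +1 / -1 / 0 (miss)
    rt: np.ndarray             # seconds from target onset, NaN on miss
    cross_idx: np.ndarray      # sample index of the crossing, -1 on miss
    trial_params: pd.DataFrame # realised v_t, f_t, z_t, ter_t per trial
    stimuli: pd.DataFrame      # target_dir, flanker_dir, congruent


def simulate_trials(params_map: Mapping[str, DDMParams] | DDMParams,
                    design: pd.DataFrame, n_reps: int = 1, seed: int = 0,
                    dt: float = DEFAULT_DT,
                    max_time: float = DEFAULT_MAX_TIME) -> pd.DataFrame:
    """Simulate one outcome per design row (times ``n_reps``).

    ``design`` needs a boolean ``congruent`` column; a ``condition``
    column selects the entry of ``params_map`` per trial (a single
    DDMParams applies to all trials).  A ``target_dir`` column is used if
    present, otherwise directions are assigned +1/-1 in alternation.

    Returns a trial table with the realised single-trial parameters, the
    choice (+1 left / -1 right / 0 miss), target-onset-referenced RT and
    accuracy.  Misses carry NaN RT and are flagged.
    """
    _check_config(dt, max_time)
    if isinstance(params_map, DDMParams):
        params_map = {"all": params_map}
        cond = pd.Series("all", index=design.index)
    else:
        if "condition" not in design.columns:
            raise KeyError("design must carry a 'condition' column")
        cond = design["condition"]
        missing = set(cond.unique()) - set(params_map)
        if missing:
            raise KeyError(f"no parameters for conditions {sorted(missing)}")

    design = pd.concat([design] * n_reps, ignore_index=True)
    cond = pd.concat([cond] * n_reps, ignore_index=True)
    n = len(design)
    rng = np.random.default_rng(seed)
    if "target_dir" in design.columns:
        target_dir = design["target_dir"].to_numpy(float)
    else:
        # balanced directions in random order (avoids confounding the
        # start point with any systematic pattern in the design)
        target_dir = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
        rng.shuffle(target_dir)
    congruent = design["congruent"].to_numpy(bool)
    flanker_dir = np.where(congruent, target_dir, -target_dir)

    v_t = np.empty(n); f_t = np.empty(n); z_t = np.empty(n); ter_t = np.empty(n)
    a_arr = np.empty(n)
    s = None
    for name, p in params_map.items():
        m = (cond == name).to_numpy()
        draws = sample_trial_params_batch(p, int(m.sum()), rng)
        v_t[m] = draws["v_t"]; f_t[m] = draws["f_t"]
        z_t[m] = draws["z_t"]; ter_t[m] = draws["ter_t"]
        a_arr[m] = p.a
        s = p.s if s is None else s
    # the kernel takes a scalar boundary; simulate per condition group
    choice = np.zeros(n, np.int8)
    rt = np.full(n, np.nan)
    fcross = np.zeros(n, bool)
    base_seed = int(rng.integers(0, 2**31 - 1))
    for name, p in params_map.items():
        m = (cond == name).to_numpy()
        idx = np.flatnonzero(m)
        c, r, fc = _kernels.simulate_batch(
            v_t[idx], f_t[idx], z_t[idx], ter_t[idx],
            flanker_dir[idx], target_dir[idx],
            p.a, p.s, dt, SOA, max_time, base_seed)
        choice[idx] = c; rt[idx] = r; fcross[idx] = fc

    out = design.copy()
    out["target_dir"] = target_dir.astype(int)
    out["choice"] = choice.astype(int)
    out["rt"] = rt
    out["rt_ms"] = rt * 1000.0
    out["correct"] = choice == target_dir
    out["miss"] = choice == 0
    out["crossed_during_flanker_stage"] = fcross
    out["v_t"] = v_t; out["f_t"] = f_t; out["z_t"] = z_t; out["ter_t"] = ter_t
    return out


def simulate_traces(params: DDMParams, design: pd.DataFrame | None = None,
                    n: int = 5000, decay_rate: float = DEFAULT_DECAY_RATE,
                    seed: int = 0, dt: float = DEFAULT_DT,
                    t_start: float = -0.3,
                    max_time: float = 1.2) -> DecisionTrace:
    """Simulate full decision-variable paths for display-style analyses.

    Paths include the noiseless pre-flanker baseline at the trial's start
    point, the staged accumulation, and a mean-reverting return to
    baseline after the crossing (``decay_rate`` per second).  When
    ``design`` is None, a 50% congruent design with balanced target
    directions is used.
    """
    _check_config(dt, max_time)
    if decay_rate < 0 or decay_rate * dt >= 1:
        raise ValueError("require 0 <= decay_rate * dt < 1 for stability")
    if design is None:
        design = pd.DataFrame({
            "congruent": np.arange(n) % 2 == 0,
            "target_dir": np.where(np.arange(n) % 4 < 2, 1, -1),
        })
    else:
        design = design.reset_index(drop=True)
        n = len(design)
    rng = np.random.default_rng(seed)
    draws = sample_trial_params_batch(params, n, rng)
    congruent = design["congruent"].to_numpy(bool)
    if "target_dir" in design.columns:
        target_dir = design["target_dir"].to_numpy(float)
    else:
        target_dir = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    flanker_dir = np.where(congruent, target_dir, -target_dir)
    base_seed = int(rng.integers(0, 2**31 - 1))
    paths, choice, rt, cross_idx = _kernels.simulate_trace_batch(
        draws["v_t"], draws["f_t"], draws["z_t"], draws["ter_t"],
        flanker_dir, target_dir, params.a, params.s, dt, SOA,
        t_start, max_time, decay_rate, base_seed)
    times = t_start + dt * np.arange(paths.shape[1])
    return DecisionTrace(
        times=times, x=paths, choice=choice.astype(int), rt=rt,
        cross_idx=cross_idx,
        trial_params=pd.DataFrame(draws),
        stimuli=pd.DataFrame({"target_dir": target_dir.astype(int),
                              "flanker_dir": flanker_dir.astype(int),
                              "congruent": congruent}),
    )
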