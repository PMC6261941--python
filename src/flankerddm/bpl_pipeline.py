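"""Beta-power lateralisation (BPL): computation and analyses.

BPL is the difference in normalised 13-25 Hz power between the
sensorimotor channel contralateral to the responding hand and the
ipsilateral one.  More negative values mean stronger beta suppression in
favour of the executed response, so BPL tracks the state of evidence
accumulation with the sign convention of a decision variable pointing at
the chosen response.  Derived measures:

* threshold — mean BPL in a +/-12 ms window around the button press, a
  proxy for the decision boundary;
* slope — local rate of change from a short-window (80 ms) line fit on a
  hop grid, a proxy for the net speed of evidence accumulation;
* onset — earliest time at which group-level slopes deviate from zero
  (Bonferroni over time points);
* peak latency — time of the most negative response-locked average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .behavior_stats import (GroupTest, RegressionResult, build_design,
                             group_level_test, robust_regress)
from .synthetic_data import BetaEpochs

BETA_BAND = (13.0, 25.0)
THRESHOLD_WINDOW = 0.012   # seconds around the response
SLOPE_WINDOW = 0.080       # seconds
SLOPE_HOP = 10             # samples between slope evaluations


def bandpower_timecourse(epochs, sfreq: float | None = None,
                         metadata: pd.DataFrame | None = None,
                         band: tuple[float, float] = BETA_BAND,
                         freq_range: tuple[float, float] = (4.0, 25.0),
                         n_freqs: int = 20, n_cycles: float = 6.0,
                         out_sfreq: float = 250.0,
                         times: np.ndarray | None = None) -> BetaEpochs:
    """Morlet band-power time course of epoched two-channel signals.

    ``epochs`` may be a raw (n_trials, n_channels, n_samples) array — it
    is convolved with complex Morlet wavelets on ``n_freqs`` linear
    frequency steps, log-transformed, averaged over the frequencies
    inside ``band`` and downsampled to ``out_sfreq`` — or an existing
    :class:`BetaEpochs` (already band power, e.g. the synthetic path),
    which is returned unchanged.
    """
    if isinstance(epochs, BetaEpochs):
        return epochs
    from mne.time_frequency import tfr_array_morlet

    data = np.asarray(epochs, float)
    if sfreq is None:
        raise ValueError("sfreq required for raw-signal input")
    freqs = np.linspace(freq_range[0], freq_range[1], n_freqs)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not in_band.any():
        raise ValueError(f"band {band} outside computed frequencies {freq_range}")
    power = tfr_array_morlet(data, sfreq=sfreq, freqs=freqs,
                             n_cycles=n_cycles, output="power", verbose=False)
    power = np.log(power[:, :, in_band, :]).mean(axis=2)
    step = max(1, int(round(sfreq / out_sfreq)))
    power = power[:, :, ::step]
    if times is None:
        times = np.arange(data.shape[-1]) / sfreq
    times = np.asarray(times)[::step]
    meta = metadata if metadata is not None else pd.DataFrame(
        index=range(data.shape[0]))
    return BetaEpochs(power=power, times=times, sfreq=sfreq / step,
                      metadata=meta, alignment="flanker")


def normalize_power(beta: BetaEpochs) -> BetaEpochs:
    """Within-participant channel normalisation: divide by the pooled SD
    over trials and samples, then subtract the pooled mean of the rescaled
    values, leaving each channel with zero mean and unit SD."""
    power = beta.power.astype(float).copy()
    for ch in range(power.shape[1]):
        sd = power[:, ch].std()
        if sd == 0:
            raise ValueError(f"zero variance in channel {beta.ch_names[ch]}")
        power[:, ch] /= sd
        power[:, ch] -= power[:, ch].mean()
    return replace(beta, power=power)


@dataclass
class BPLSeries:
    """Lateralised (contralateral minus ipsilateral) power per trial."""

    values: np.ndarray          # (n_trials, n_samples)
    times: np.ndarray
    sfreq: float
    metadata: pd.DataFrame
    alignment: str = "flanker"


def compute_bpl(beta: BetaEpochs) -> BPLSeries:
    """Contralateral minus ipsilateral channel series under the hand
    mapping (channel 0 = left hemisphere, channel 1 = right; a left-hand
    response makes the right hemisphere contralateral).  Trials with an
    unresolved hand are dropped with a warning."""
    hand = beta.metadata["hand"].to_numpy(float)
    ok = np.isfinite(hand) & (hand != 0)
    if not ok.all():
        warnings.warn(f"dropping {int((~ok).sum())} trials with unresolved hand")
    power = beta.power[ok]
    hand = hand[ok]
    contra = np.where(hand[:, None] < 0, power[:, 1], power[:, 0])
    ipsi = np.where(hand[:, None] < 0, power[:, 0], power[:, 1])
    return BPLSeries(values=contra - ipsi, times=beta.times, sfreq=beta.sfreq,
                     metadata=beta.metadata.loc[ok].reset_index(drop=True),
                     alignment=beta.alignment)


def channel_role_series(beta: BetaEpochs, role: str) -> BPLSeries:
    """Single-channel series for ``role`` in {'contralateral',
    'ipsilateral'}, for hemisphere-wise regressions."""
    hand = beta.metadata["hand"].to_numpy(float)
    ok = np.isfinite(hand) & (hand != 0)
    power = beta.power[ok]
    hand = hand[ok]
    contra_is_right = hand < 0
    if role == "contralateral":
        vals = np.where(contra_is_right[:, None], power[:, 1], power[:, 0])
    elif role == "ipsilateral":
        vals = np.where(contra_is_right[:, None], power[:, 0], power[:, 1])
    else:
        raise ValueError("role must be 'contralateral' or 'ipsilateral'")
    return BPLSeries(values=vals, times=beta.times, sfreq=beta.sfreq,
                     metadata=beta.metadata.loc[ok].reset_index(drop=True),
                     alignment=beta.alignment)


def response_locked(series: BPLSeries, t_min: float = -0.5,
                    t_max: float = 0.5) -> BPLSeries:
    """Re-epoch a flanker-locked series around the per-trial response.

    Trials whose window would exceed the epoch are dropped with a flag in
    the returned metadata removed.  Requires a ``response_idx`` column.
    """
    if series.alignment == "response":
        return series
    idx = series.metadata["response_idx"].to_numpy(int)
    before = int(round(-t_min * series.sfreq))
    after = int(round(t_max * series.sfreq))
    n_samp = series.values.shape[1]
    ok = (idx - before >= 0) & (idx + after < n_samp)
    if not ok.all():
        warnings.warn(f"dropping {int((~ok).sum())} trials with truncated "
                      "response window")
    rows = [series.values[i, idx[i] - before: idx[i] + after + 1]
            for i in np.flatnonzero(ok)]
    times = np.arange(-before, after + 1) / series.sfreq
    meta = series.metadata.loc[ok].reset_index(drop=True)
    return BPLSeries(values=np.array(rows), times=times, sfreq=series.sfreq,
                     metadata=meta, alignment="response")


def bpl_threshold(series: BPLSeries,
                  window: float = THRESHOLD_WINDOW) -> np.ndarray:
    """Per-trial mean lateralisation within +/-``window`` of the button
    press (7 samples at 250 Hz), the boundary proxy.  Accepts a
    response-locked series; trials with a truncated window get NaN."""
    if series.alignment != "response":
        raise ValueError("bpl_threshold needs a response-locked series")
    sel = np.abs(series.times) <= window + 1e-9
    if not sel.any():
        raise ValueError("threshold window contains no samples")
    return series.values[:, sel].mean(axis=1)


@dataclass
class SlopeSeries:
    """Local BPL slopes on a hop grid (normalised units per second)."""

    times: np.ndarray          # window-centre times
    slopes: np.ndarray         # (n_series, n_grid)
    window: float
    hop: int
    sfreq: float
    group: GroupTest | None = None


def bpl_slope(values: np.ndarray, times: np.ndarray, sfreq: float,
              window: float = SLOPE_WINDOW, hop: int = SLOPE_HOP) -> SlopeSeries:
    """Least-squares line slope of BPL in a centred ``window`` around
    every ``hop``-th sample.  ``values`` is (n_series, n_samples) —
    per-participant averages or single trials.  Grid points whose window
    would exceed the epoch are omitted.  Exact for linear signals
    everywhere and for quadratics at the window centre."""
    values = np.atleast_2d(np.asarray(values, float))
    half = int(round(window * sfreq / 2))
    n_samp = values.shape[1]
    centers = np.arange(half, n_samp - half, hop)
    if len(centers) == 0:
        raise ValueError("window exceeds the epoch")
    rel = (np.arange(-half, half + 1)) / sfreq
    w = rel / np.sum(rel**2)          # closed-form OLS slope weights
    segs = np.stack([values[:, c - half: c + half + 1] for c in centers],
                    axis=1)           # (n_series, n_grid, win)
    slopes = segs @ w
    return SlopeSeries(times=times[centers], slopes=slopes, window=window,
                       hop=hop, sfreq=sfreq)


def detect_onset(slope: SlopeSeries, alpha: float = 0.05,
                 correction: str = "bonferroni") -> float | None:
    """Earliest grid time at which per-participant slopes deviate from
    zero by a group t-test, Bonferroni-corrected over time points.
    Returns None when no point is significant."""
    s = slope.slopes
    if s.shape[0] < 2:
        raise ValueError("need at least two participants")
    t, p = stats.ttest_1samp(s, 0.0, axis=0)
    n_tests = s.shape[1] if correction == "bonferroni" else 1
    sig = p < alpha / n_tests
    if not sig.any():
        return None
    return float(slope.times[np.argmax(sig)])


def slope_group_test(slope: SlopeSeries, alpha: float = 0.05) -> pd.DataFrame:
    """Per-time-point group t-test of slopes against zero (or of
    condition differences if differences are supplied)."""
    t, p = stats.ttest_1samp(slope.slopes, 0.0, axis=0)
    n_tests = slope.slopes.shape[1]
    return pd.DataFrame({"time": slope.times, "t": t, "p": p,
                         "significant": p < alpha / n_tests})


def peak_latency(avg_bpl: np.ndarray, times: np.ndarray,
                 search_window: float = 0.3) -> float | None:
    """Latency of the most negative response-locked average within
    +/-``search_window`` of the response; None for a flat signal."""
    avg = np.asarray(avg_bpl, float)
    sel = np.abs(times) <= search_window + 1e-9
    seg = avg[sel]
    if np.ptp(seg) == 0:
        return None
    return float(times[sel][np.argmin(seg)])


def bpl_regression(scalar: np.ndarray, trials: pd.DataFrame,
                   participant: np.ndarray | pd.Series,
                   equation_id: str = "eq7",
                   family_size: int | None = None
                   ) -> tuple[list[RegressionResult], GroupTest]:
    """Per-participant robust regression of a BPL scalar (threshold or
    pre-stimulus mean) on the task factor set, followed by a group-level
    test of the within-participant t-values."""
    trials = trials.copy()
    trials["_y"] = np.asarray(scalar, float)
    pid = np.asarray(participant)
    results: list[RegressionResult] = []
    tvals = []
    for p in pd.unique(pid):
        sub = trials.loc[pid == p]
        X, _ = build_design(sub, equation_id)
        y = sub.loc[X.index, "_y"]
        res = robust_regress(X, y)
        results.append(res)
        tvals.append(res.t_named())
    tmat = pd.DataFrame(tvals).reset_index(drop=True)
    group = group_level_test(tmat.drop(columns="intercept", errors="ignore"),
                             family_size=family_size)
    return results, group
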