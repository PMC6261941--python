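"""End-to-end orchestration: simulate -> QC -> regressions -> summaries ->
model fits -> lateralisation analyses, from a single config and seed.

Every stage draws its randomness from a named substream of the master
seed, so toggling one stage never shifts another stage's random numbers,
and the produced bundle is a pure function of (config, seed, code
version).
"""

from __future__ import annotations

import hashlib
import time
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import __version__
from .behavior_stats import (detect_noncompliant, build_design,
                             group_level_test, logistic_regress,
                             posterror_summaries, robust_regress)
from .bpl_pipeline import (bpl_regression, bpl_slope, bpl_threshold,
                           compute_bpl, detect_onset, normalize_power,
                           peak_latency, response_locked)
from .ddm_core import simulate_traces
from .ddm_fit import DEConfig, fit_ddm, fit_posterror_split
from .synthetic_data import (GROUP_PARAMS, GeneratorSpec, generate_behavior,
                             generate_beta_epochs, generate_task_design)

ALL_STAGES = ("simulate", "qc", "glm", "summaries", "fit", "compare",
              "split", "bpl")


@dataclass
class RunConfig:
    """Configuration of one experiment run."""

    seed: int = 0
    n_participants: int = 8
    n_trials: int = 1088
    stages: tuple[str, ...] = ("simulate", "qc", "glm", "summaries", "bpl")
    #: between-participant SD of v, a, ter, f (fractions of the group mean)
    participant_sd: float = 0.08
    #: trials per participant entering the lateralisation stage
    n_bpl_trials: int = 300
    fit_variant: str = "DDM3"
    de: DEConfig = field(default_factory=lambda: DEConfig(
        popsize=6, maxiter=25, tol=0.01, n_sim=3000, final_n_sim=20000))
    fit_bounds: dict = field(default_factory=lambda: {
        "v": (0.5, 5.0), "a": (0.05, 0.4), "ter": (0.15, 0.45),
        "f": (0.0, 1.2)})

    def config_hash(self) -> str:
        payload = repr(sorted(asdict(self).items())).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class ReportBundle:
    tables: dict[str, pd.DataFrame]
    meta: dict
    timings: dict[str, float] = field(default_factory=dict)


def stage_seed(master: int, stage: str) -> int:
    """Named substream of the master seed (stable across stage toggling)."""
    ss = np.random.SeedSequence([int(master), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _participant_specs(config: RunConfig) -> list[GeneratorSpec]:
    rng = np.random.default_rng(stage_seed(config.seed, "participants"))
    specs = []
    for i in range(config.n_participants):
        g = GROUP_PARAMS
        jitter = 1.0 + config.participant_sd * rng.standard_normal(4)
        base = g.replace(v=g.v * jitter[0], a=g.a * max(jitter[1], 0.3),
                         ter=min(max(g.ter * jitter[2], g.st / 2 + 0.01), 0.45),
                         f=g.f * jitter[3])
        specs.append(GeneratorSpec(base=base,
                                   seed=stage_seed(config.seed, f"sim{i}")))
    return specs


def run_experiment(config: RunConfig) -> ReportBundle:
    """Execute the enabled stages in dependency order.

    A stage failure halts its dependents but the partial bundle is
    returned with an ``error`` entry in the metadata.
    """
    meta = {"seed": config.seed, "config_hash": config.config_hash(),
            "version": __version__}
    tables: dict[str, pd.DataFrame] = {}
    timings: dict[str, float] = {}
    stages = list(config.stages)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    specs = _participant_specs(config)

    def record(name: str, df: pd.DataFrame) -> None:
        df = df.copy()
        df.attrs.update(meta)
        tables[name] = df

    data = None
    try:
        if "simulate" in stages:
            t0 = time.perf_counter()
            parts = []
            for i, spec in enumerate(specs):
                design = generate_task_design(
                    config.n_trials, seed=stage_seed(config.seed, f"design{i}"))
                beh = generate_behavior(design, spec)
                beh.insert(0, "participant", i)
                parts.append(beh)
            data = pd.concat(parts, ignore_index=True)
            record("behavior", data)
            timings["simulate"] = time.perf_counter() - t0

        if "qc" in stages and data is not None:
            t0 = time.perf_counter()
            miss_rates = data.groupby("participant")["miss"].mean()
            res = detect_noncompliant(
                miss_rates.to_numpy(), alpha=0.01, side="upper")
            record("qc", pd.DataFrame({
                "participant": miss_rates.index,
                "miss_rate": miss_rates.to_numpy(),
                "flagged": res.flagged}))
            meta["qc_cutoff"] = res.cutoff
            timings["qc"] = time.perf_counter() - t0

        if "glm" in stages and data is not None:
            t0 = time.perf_counter()
            rows_rt, rows_acc = [], []
            for i, sub in data.groupby("participant"):
                X, y = build_design(sub, "eq1")
                rows_rt.append(robust_regress(X, y).t_named())
                X, y = build_design(sub, "eq2")
                rows_acc.append(logistic_regress(X, y).t_named())
            t_rt = pd.DataFrame(rows_rt).reset_index(drop=True)
            t_acc = pd.DataFrame(rows_acc).reset_index(drop=True)
            g_rt = group_level_test(t_rt.drop(columns="intercept"))
            g_acc = group_level_test(t_acc.drop(columns="intercept"))
            record("glm_rt_group", g_rt.table.reset_index())
            record("glm_accuracy_group", g_acc.table.reset_index())
            timings["glm"] = time.perf_counter() - t0

        if "summaries" in stages and data is not None:
            t0 = time.perf_counter()
            rows = []
            for i, sub in data.groupby("participant"):
                s = posterror_summaries(sub)
                rows.append({"participant": i, "pes_ms": s.pes_ms,
                             "peri_ms": s.peri_ms, "pia": s.pia,
                             "n_posterror": s.n_posterror})
            record("posterror_summaries", pd.DataFrame(rows))
            timings["summaries"] = time.perf_counter() - t0

        if "fit" in stages and data is not None:
            t0 = time.perf_counter()
            rows = []
            for i, sub in data.groupby("participant"):
                fixed = {"sv": GROUP_PARAMS.sv, "sz": GROUP_PARAMS.sz,
                         "st": GROUP_PARAMS.st, "sf": GROUP_PARAMS.sf}
                fit = fit_ddm(sub, config.fit_variant, config=config.de,
                              seed=stage_seed(config.seed, f"fit{i}"),
                              bounds=config.fit_bounds, fixed_params=fixed)
                row = fit.to_series()
                row["participant"] = i
                rows.append(row)
            record("fits", pd.DataFrame(rows))
            timings["fit"] = time.perf_counter() - t0

        if "compare" in stages and data is not None:
            t0 = time.perf_counter()
            rows = []
            fixed = {"sv": GROUP_PARAMS.sv, "sz": GROUP_PARAMS.sz,
                     "st": GROUP_PARAMS.st}
            sub = data[data["participant"] == 0]
            for variant in ("DDM1", "DDM3"):
                fit = fit_ddm(sub, variant, config=config.de,
                              seed=stage_seed(config.seed, f"cmp-{variant}"),
                              bounds=config.fit_bounds, fixed_params=fixed)
                rows.append(fit.to_series())
            record("model_comparison", pd.DataFrame(rows))
            timings["compare"] = time.perf_counter() - t0

        if "split" in stages and data is not None:
            t0 = time.perf_counter()
            rows = []
            gv = {"sv": GROUP_PARAMS.sv, "sz": GROUP_PARAMS.sz,
                  "st": GROUP_PARAMS.st, "sf": GROUP_PARAMS.sf}
            for i, sub in data.groupby("participant"):
                split = fit_posterror_split(
                    sub, gv, config=config.de,
                    seed=stage_seed(config.seed, f"split{i}"),
                    bounds=config.fit_bounds)
                if split.excluded:
                    rows.append({"participant": i, "excluded": True,
                                 "n_posterror": split.n_posterror})
                    continue
                for tag, fit in (("post_correct", split.post_correct),
                                 ("post_error", split.post_error)):
                    row = fit.to_series()
                    row["participant"] = i
                    row["trial_type"] = tag
                    row["excluded"] = False
                    rows.append(row)
            record("split_fits", pd.DataFrame(rows))
            timings["split"] = time.perf_counter() - t0

        if "bpl" in stages:
            t0 = time.perf_counter()
            thresholds, trial_tables, pids = [], [], []
            slope_rows, peaks = [], []
            for i, spec in enumerate(specs):
                design = generate_task_design(
                    max(8, 8 * (config.n_bpl_trials // 8)),
                    seed=stage_seed(config.seed, f"bpl-design{i}"))
                traces = simulate_traces(
                    spec.base, design=design, decay_rate=spec.decay_rate,
                    seed=stage_seed(config.seed, f"bpl{i}"))
                epochs = generate_beta_epochs(traces, spec, metadata=design)
                bpl = compute_bpl(normalize_power(epochs))
                resp = response_locked(bpl, -0.3, 0.3)
                thr = bpl_threshold(resp)
                thresholds.append(thr)
                meta_i = resp.metadata.copy()
                meta_i["participant"] = i
                meta_i["prev_accuracy"] = np.where(
                    meta_i["correct"].shift(1, fill_value=True), -1, 1)
                trial_tables.append(meta_i)
                pids.append(np.full(len(thr), i))
                cong = bpl.metadata["congruent"].to_numpy(bool)
                avg = bpl.values[cong].mean(axis=0)
                ss = bpl_slope(avg, bpl.times, bpl.sfreq)
                slope_rows.append(ss.slopes[0])
                peaks.append(peak_latency(resp.values.mean(axis=0), resp.times))
            slope_mat = np.vstack(slope_rows)
            ss = bpl_slope(np.zeros((1, len(bpl.times))), bpl.times, bpl.sfreq)
            from .bpl_pipeline import SlopeSeries
            slope_series = SlopeSeries(times=ss.times, slopes=slope_mat,
                                       window=ss.window, hop=ss.hop,
                                       sfreq=ss.sfreq)
            onset = detect_onset(slope_series)
            trials = pd.concat(trial_tables, ignore_index=True)
            thr_all = np.concatenate(thresholds)
            _, group = bpl_regression(thr_all, trials,
                                      trials["participant"], "eq7")
            record("bpl_threshold_group", group.table.reset_index())
            record("bpl_slopes", pd.DataFrame(
                slope_mat, columns=np.round(slope_series.times, 4)))
            meta["bpl_onset_s"] = onset
            meta["bpl_peak_latency_s"] = float(np.nanmean(
                [p for p in peaks if p is not None]))
            timings["bpl"] = time.perf_counter() - t0
    except Exception as exc:
        meta["error"] = f"{type(exc).__name__}: {exc}"
        raise
    return ReportBundle(tables=tables, meta=meta, timings=timings)
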