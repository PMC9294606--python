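"""End-to-end synthetic study: generate recordings for two groups of
cells, run every analysis stage, and write per-cell tables, group
statistics and summary plots.

The pipeline is a pure function of (config, seed): per-cell seeds are
derived arithmetically from the root seed, so identical configs yield
byte-identical outputs.  Every analysis default that the underlying
operations leave configurable (detection criterion, fit windows, slope
thresholds, AHP reference) is recorded in ``params_log.yaml`` so a run
is auditable.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from . import aps as ap_mod
from . import minis as mini_mod
from . import recovery as rec_mod
from . import trains as train_mod
from .depletion import DepletionParams, simulate_recovery
from .errors import ConfigurationError
from .signal_core import StimulusProtocol, Trace, average_sweeps
from .stats import group_compare
from .synth import (
    APTemplateSpec,
    KernelParams,
    gen_ap_sweeps,
    gen_evoked_sweeps,
    gen_mini_trace,
)

__all__ = ["run_pipeline", "DEFAULT_CONFIG"]

# Two-group default study: a control synapse/cell and one with reduced
# vesicle replenishment (the depression phenotype the model predicts).
DEFAULT_CONFIG: dict = {
    "seed": 0,
    "groups": {
        "control": {},
        "low_replenishment": {"depletion": {"repl_rate": 96.0}},
    },
    "base": {
        "depletion": {
            "n0": 300.0,
            "p_r": 0.2,
            "q": 57.4,          # pA per vesicle, one vesicle = one quantum
            "repl_rate": 240.0,  # vesicles/s = 0.8% of the pool per 10 ms ISI
            "mode": "stochastic",
        },
        "kernel": {"tau_rise": 1.3, "tau_fast": 6.25, "tau_slow": 13.4,
                   "fast_fraction": 0.6},
        "minis": {"rate": 78.1, "amp_mean": 57.4, "amp_cv": 0.3},
        "ap_template": {"threshold": -45.0, "amplitude": 80.0, "half_width": 0.40,
                        "max_rise": 300.0, "max_fall": 200.0, "ahp": 15.0},
    },
    "stages": {
        "minis": {"n_cells": 4, "duration": 10.0},
        "trains": {"n_cells": 6, "n_sweeps": 10, "n_stimuli": 40,
                   "frequency": 100.0, "noise_sd": 5.0},
        "recovery": {"n_cells": 4,
                     "intervals": [0.05, 0.1, 0.25, 0.5, 1.0, 2.0, 4.0]},
        "aps": {"n_cells": 4, "step_pA": 50.0, "spont_rate": 35.6,
                "spont_duration": 2.0},
    },
}

ANALYSIS_DEFAULTS = {
    "mini_detection_criterion": 3.5,
    "amplitude_window_ms": [0.5, 8.0],
    "baseline_window_ms": 1.0,
    "baseline_mode": "extrapolate",
    "train_fit_stimuli": [33, 40],
    "eq_fit_points": 5,
    "steady_state_n_last": 5,
    "spike_dvdt_threshold_mV_per_ms": 20.0,
    "ahp_reference": "threshold",
    "ahp_window_ms": 10.0,
    "ttest_variant": "student",
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _cell_seed(root: int, stage: int, group: int, cell: int) -> int:
    return (root * 1_000_003 + stage * 10_007 + group * 101 + cell) % (2**31 - 1)


def _group_params(cfg: dict, group: str) -> dict:
    return _merge(cfg["base"], cfg["groups"][group])


def _stage_minis(cfg: dict, out: Path) -> pd.DataFrame:
    stage = cfg["stages"]["minis"]
    rows = []
    for gi, group in enumerate(cfg["groups"]):
        gp = _group_params(cfg, group)
        kp = KernelParams(**gp["kernel"])
        for cell in range(stage["n_cells"]):
            seed = _cell_seed(cfg["seed"], 0, gi, cell)
            trace, truth = gen_mini_trace(
                duration=stage["duration"], kp=kp, seed=seed, **gp["minis"]
            )
            events = mini_mod.detect_events(
                trace, kp, criterion_threshold=ANALYSIS_DEFAULTS["mini_detection_criterion"]
            )
            summary = mini_mod.mini_summary(events, trace.duration)
            row = {"group": group, "cell": cell, "seed": seed, **summary}
            avg = _average_event(trace, events)
            if avg is not None:
                kin = mini_mod.event_kinetics(avg)
                row.update(
                    time_to_peak_ms=kin.time_to_peak,
                    rise_10_90_ms=kin.rise_10_90,
                    tau_fast_ms=kin.tau_fast,
                    tau_slow_ms=kin.tau_slow,
                )
            rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(out / "minis_per_cell.csv", index=False)
    return df


def _average_event(trace: Trace, events: pd.DataFrame, pre_ms=2.0, post_ms=40.0):
    """Average detected-event snippets (skipping ones near the trace edge)."""
    rate = trace.sampling_rate
    npre = int(round(pre_ms * 1e-3 * rate))
    npost = int(round(post_ms * 1e-3 * rate))
    snips = []
    for t in events["time"]:
        i = trace.index_of(t)
        if i - npre >= 0 and i + npost < trace.n_samples:
            snips.append(trace.samples[i - npre : i + npost])
    if not snips:
        return None
    return Trace(np.mean(snips, axis=0), rate, kind="current")


def _stage_trains(cfg: dict, out: Path) -> tuple[pd.DataFrame, dict]:
    stage = cfg["stages"]["trains"]
    rows = []
    curves: dict[str, list[np.ndarray]] = {g: [] for g in cfg["groups"]}
    for gi, group in enumerate(cfg["groups"]):
        gp = _group_params(cfg, group)
        dp = DepletionParams(**gp["depletion"])
        kp = KernelParams(**gp["kernel"])
        protocol = StimulusProtocol.train(stage["n_stimuli"], stage["frequency"],
                                          start=0.05)
        pp_protocol = StimulusProtocol.paired_pulse(start=0.05)
        for cell in range(stage["n_cells"]):
            seed = _cell_seed(cfg["seed"], 1, gi, cell)
            sweeps, _ = gen_evoked_sweeps(
                dp, protocol, kp, noise_sd=stage["noise_sd"],
                n_sweeps=stage["n_sweeps"], seed=seed,
            )
            avg = average_sweeps(sweeps)
            amps = train_mod.measure_train_amplitudes(avg, protocol)
            norm = train_mod.normalize_amplitudes(amps)
            curves[group].append(norm)
            tm = train_mod.train_method(norm, tuple(ANALYSIS_DEFAULTS["train_fit_stimuli"]))
            eq = train_mod.eq_method(norm, ANALYSIS_DEFAULTS["eq_fit_points"])
            pp_sweeps, _ = gen_evoked_sweeps(
                dp, pp_protocol, kp, noise_sd=stage["noise_sd"],
                n_sweeps=stage["n_sweeps"], seed=seed + 1,
            )
            pp_amps = train_mod.measure_train_amplitudes(
                average_sweeps(pp_sweeps), pp_protocol
            )
            rows.append(
                {
                    "group": group,
                    "cell": cell,
                    "seed": seed,
                    "first_ipsc_pa": amps[0],
                    "ppr": train_mod.paired_pulse_ratio(pp_amps),
                    "steady_state": train_mod.steady_state_depression(
                        norm, ANALYSIS_DEFAULTS["steady_state_n_last"]
                    ),
                    "train_rrp_rel": tm.rrp_rel,
                    "train_p_r": tm.p_r_est,
                    "train_repl_slope": tm.repl_slope_rel,
                    "train_fit_r2": tm.fit_r2,
                    "eq_rrp_rel": eq.rrp_rel,
                    "eq_p_r": eq.p_r_est,
                    "eq_fit_r2": eq.fit_r2,
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(out / "trains_per_cell.csv", index=False)
    return df, curves


def _stage_recovery(cfg: dict, out: Path) -> pd.DataFrame:
    stage = cfg["stages"]["recovery"]
    rows = []
    for gi, group in enumerate(cfg["groups"]):
        gp = _group_params(cfg, group)
        dp = DepletionParams(**gp["depletion"])
        protocol = StimulusProtocol.train(
            cfg["stages"]["trains"]["n_stimuli"], cfg["stages"]["trains"]["frequency"]
        )
        for cell in range(stage["n_cells"]):
            seed = _cell_seed(cfg["seed"], 2, gi, cell)
            table = simulate_recovery(dp, protocol, stage["intervals"], seed=seed)
            for _, r in table.iterrows():
                rows.append(
                    {
                        "group": group,
                        "cell": cell,
                        "interval_s": r["interval_s"],
                        "recovery_ratio": r["recovery_ratio"],
                    }
                )
    df = pd.DataFrame(rows)
    df.to_csv(out / "recovery_per_cell.csv", index=False)
    return df


def _stage_aps(cfg: dict, out: Path) -> pd.DataFrame:
    stage = cfg["stages"]["aps"]
    rows = []
    for gi, group in enumerate(cfg["groups"]):
        gp = _group_params(cfg, group)
        spec = APTemplateSpec(**gp["ap_template"])
        step = StimulusProtocol.current_step(amplitude=stage["step_pA"])
        for cell in range(stage["n_cells"]):
            seed = _cell_seed(cfg["seed"], 3, gi, cell)
            sweeps, truth = gen_ap_sweeps(spec, step_protocol=step, seed=seed)
            sweep = sweeps.sweeps[0]
            rate, latency, count = ap_mod.evoked_firing_metrics(sweep, step)
            row = {
                "group": group, "cell": cell, "seed": seed,
                "evoked_rate_hz": rate, "latency_ms": latency, "spike_count": count,
            }
            spikes = ap_mod.detect_spikes(sweep)
            if spikes.size:
                feats = ap_mod.ap_features(sweep, spikes[0])
                row.update(
                    threshold_mv=feats.threshold,
                    amplitude_mv=feats.amplitude,
                    half_width_ms=feats.half_width,
                    max_rise_mv_ms=feats.max_rise,
                    max_fall_mv_ms=feats.max_fall,
                    ahp_mv=feats.ahp,
                )
            spont, _ = gen_ap_sweeps(
                spec, spont_rate=stage["spont_rate"],
                duration=stage["spont_duration"], seed=seed + 1,
            )
            row["spont_rate_hz"] = ap_mod.spontaneous_rate(spont.sweeps[0])
            rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(out / "aps_per_cell.csv", index=False)
    return df


def _group_stats(tables: dict[str, pd.DataFrame], groups: list[str], out: Path) -> pd.DataFrame:
    rows = []
    if len(groups) >= 2:
        a, b = groups[0], groups[1]
        for stage, df in tables.items():
            if df.empty or "group" not in df:
                continue
            for col in df.columns:
                if col in ("group", "cell", "seed") or not np.issubdtype(
                    df[col].dtype, np.number
                ):
                    continue
                va = df.loc[df["group"] == a, col].dropna().to_numpy()
                vb = df.loc[df["group"] == b, col].dropna().to_numpy()
                if va.size < 2 or vb.size < 2:
                    continue
                cmpres = group_compare(va, vb, ANALYSIS_DEFAULTS["ttest_variant"],
                                       label_a=a, label_b=b)
                rows.append({"stage": stage, "metric": col, **asdict(cmpres)})
    df = pd.DataFrame(rows)
    df.to_csv(out / "group_summary.csv", index=False)
    return df


def _plots(curves: dict[str, list[np.ndarray]], recovery: pd.DataFrame, out: Path):
    if curves and all(len(v) for v in curves.values()):
        fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
        for group, norms in curves.items():
            mean = np.mean(norms, axis=0)
            k = np.arange(1, mean.size + 1)
            axes[0].plot(k, mean, marker="o", ms=3, label=group)
            axes[1].plot(k, np.cumsum(mean), marker="o", ms=3, label=group)
            cum_prev = np.concatenate([[0.0], np.cumsum(mean)[:-1]])
            axes[2].plot(cum_prev, mean, marker="o", ms=3, label=group)
        axes[0].set(xlabel="stimulus", ylabel="IPSC (norm.)", title="depression")
        axes[1].set(xlabel="stimulus", ylabel="cumulative IPSC", title="train method")
        axes[2].set(xlabel="cumulative IPSC (preceding)", ylabel="IPSC (norm.)",
                    title="EQ method")
        for ax in axes:
            ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / "train_analysis.png", dpi=120)
        plt.close(fig)
    if recovery is not None and not recovery.empty:
        fig, ax = plt.subplots(figsize=(4.5, 3.5))
        for group, sub in recovery.groupby("group"):
            m = sub.groupby("interval_s")["recovery_ratio"].mean()
            ax.plot(m.index, m.values, marker="o", label=group)
        ax.set(xlabel="recovery interval (s)", ylabel="IPSC recovery ratio")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / "recovery.png", dpi=120)
        plt.close(fig)


def run_pipeline(config: dict | str | Path | None, out_dir: str | Path) -> dict:
    """Run all configured stages and write the report bundle to ``out_dir``.

    ``config`` may be a dict, a YAML file path, or None for the default
    two-group study.  Returns the per-stage tables plus the group summary.
    """
    if config is None:
        cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    elif isinstance(config, (str, Path)):
        cfg = _merge(DEFAULT_CONFIG, yaml.safe_load(Path(config).read_text()) or {})
    elif isinstance(config, dict):
        cfg = _merge(DEFAULT_CONFIG, config)
    else:
        raise ConfigurationError("config must be a dict, path or None")
    for key in ("groups", "stages", "base"):
        if key not in cfg or not cfg[key]:
            raise ConfigurationError(f"pipeline config lacks section {key!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    tables: dict[str, pd.DataFrame] = {}
    curves: dict[str, list[np.ndarray]] = {}
    if "minis" in cfg["stages"]:
        tables["minis"] = _stage_minis(cfg, out)
    if "trains" in cfg["stages"]:
        tables["trains"], curves = _stage_trains(cfg, out)
    if "recovery" in cfg["stages"]:
        tables["recovery"] = _stage_recovery(cfg, out)
    if "aps" in cfg["stages"]:
        tables["aps"] = _stage_aps(cfg, out)

    groups = list(cfg["groups"])
    summary = _group_stats(tables, groups, out)
    _plots(curves, tables.get("recovery"), out)
    (out / "params_log.yaml").write_text(
        yaml.safe_dump({"config": cfg, "analysis_defaults": ANALYSIS_DEFAULTS},
                       sort_keys=True)
    )
    tables["summary"] = summary
    return tables
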