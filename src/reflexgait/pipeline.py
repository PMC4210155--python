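"""End-to-end pipeline: generate -> preprocess -> identify -> build -> fit -> simulate.

Orchestrates the full path from (synthetic) treadmill recordings to a
walking surrogate robot, mirroring the study workflow: per-subject
recordings are conditioned and segmented, heel-contact -> envelope
transfer functions are identified per muscle/trigger pairing, joint-action
segments are extracted and fitted with the twitch model, fitted parameter
sets are aggregated across subjects under several policies (mean of all
subjects, per-cohort means, per-subject, minimum-MSE selection), and each
aggregated set is finalized into motor transfer functions and evaluated
closed-loop on the surrogate plant.

Every stage is seeded from the single pipeline seed and all outputs carry
provenance (seed, config hash, package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .controller import ControllerConfig, ReflexController
from .preprocessing import condition_emg, detect_heel_strikes, GaitEvents, mean_heel_template, segment_strides
from .synthetic import SynthConfig, default_kernels, generate_recording, generate_speed_sequence
from .system_id import apply_half_hanning, decimate_pair, lms_identify
from .transfer import build_action_segments, fsr_convolve
from .twitch import CurveParams, characterize, finalize_motor_tf, fit_curve, stability_heuristic
from .walker import PlantConfig, gait_metrics, simulate

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("reflexgait")

#: muscle/trigger pairings identified for the controller (TA is excluded:
#: it acts only on the ankle, which the walker does not have)
PAIRINGS = (("RF", "CH"), ("BF", "IH"), ("BF", "CH"), ("LG", "CH"))


@dataclass(frozen=True)
class PipelineConfig:
    """Scales and per-stage parameters of a pipeline run."""

    n_subjects: int = 3
    cohorts: tuple[str, ...] = ("m", "f", "f")  # arbitrary cohort tags
    n_settings: int = 10
    speed_range: tuple[float, float] = (0.9, 1.4)
    strides_per_setting: int = 8
    envelope_snr: float = 50.0
    speed_gain: float = 0.5
    ident_rate_hz: float = 50.0
    lms_mu: float = 0.01
    lms_iterations: int = 100
    sim_duration_s: float = 20.0
    seed: int = 0

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _identify_subject(cfg: PipelineConfig, subject: int) -> dict:
    """Generate, preprocess and identify one synthetic subject."""
    seed = (cfg.seed * 1000 + subject) % (2**31)
    scfg = SynthConfig(seed=seed, envelope_snr=cfg.envelope_snr, speed_gain=cfg.speed_gain)
    profile = generate_speed_sequence(
        cfg.n_settings, cfg.speed_range, repeats=1, seed=seed,
        strides_per_setting=cfg.strides_per_setting, config=scfg,
    )
    rec, events_true, kernels = generate_recording(profile, scfg)

    heel = {"L": rec.channel("FSR_L_heel"), "R": rec.channel("FSR_R_heel")}
    events = GaitEvents(
        left_times=detect_heel_strikes(heel["L"], rec.rate_hz),
        right_times=detect_heel_strikes(heel["R"], rec.rate_hz),
    )
    seg = segment_strides(events, "left")
    template = mean_heel_template(heel["L"], rec.rate_hz, seg)

    results = {}
    for mus, trig in PAIRINGS:
        env = condition_emg(rec.channel(f"EMG_L_{mus}"), rec.rate_hz, mus)
        # left-leg muscle: CH = right heel, IH = left heel
        x = heel["R"] if trig == "CH" else heel["L"]
        xd, dd, r = decimate_pair(x, env.values, rec.rate_hz, cfg.ident_rate_hz)
        resp = lms_identify(xd, dd, r, seg.mean_duration_s,
                            mu=cfg.lms_mu, iterations=cfg.lms_iterations)
        h1 = apply_half_hanning(resp)
        q = int(round(rec.rate_hz / r))
        u = template[::q]  # heel template at the identification rate
        curve = fsr_convolve(h1, u, r, trigger=trig)
        results[(mus, trig)] = {"response": resp, "curve": curve, "final_mse": resp.final_mse}
    return {
        "subject": subject, "cohort": cfg.cohorts[subject % len(cfg.cohorts)],
        "results": results, "stride_s": seg.mean_duration_s, "rate": rec.rate_hz,
    }


def _fit_subject_segments(sub: dict) -> dict[str, dict]:
    """Extract the four joint-action segments and fit twitch curves."""
    curves = {key: val["curve"] for key, val in sub["results"].items()}
    segments = build_action_segments(curves)
    fits = {}
    for name, seg in segments.items():
        t_ms = seg.t_s * 1000.0  # hip keeps the trigger delay, knee starts at 0
        res = fit_curve(t_ms, seg.values)
        fits[name] = {"params": res.params, "residual_rms": res.residual_rms,
                      "converged": res.converged, "trigger": seg.trigger}
    return fits


def _aggregate(param_rows: list[dict], policy_rows: list[tuple[str, list[int]]]) -> dict[str, dict[str, CurveParams]]:
    """Aggregate per-subject fitted params into named sets."""
    sets = {}
    for name, subjects in policy_rows:
        agg = {}
        for ch in ("hip_flexion", "hip_extension", "knee_flexion", "knee_extension"):
            ps = [param_rows[s][ch]["params"] for s in subjects]
            agg[ch] = CurveParams(
                A=float(np.mean([p.A for p in ps])),
                tau1_ms=float(np.mean([p.tau1_ms for p in ps])),
                tau2_ms=float(np.mean([p.tau2_ms for p in ps])),
                T0_ms=float(np.mean([p.T0_ms for p in ps])),
            )
        sets[name] = agg
    return sets


def run_pipeline(config: PipelineConfig | None = None, outdir: str | Path | None = None) -> dict:
    """Run the full pipeline; optionally write the report to ``outdir``."""
    cfg = config or PipelineConfig()
    log.info("pipeline: %d subjects, seed %d", cfg.n_subjects, cfg.seed)

    subjects = [_identify_subject(cfg, s) for s in range(cfg.n_subjects)]
    fits = [_fit_subject_segments(sub) for sub in subjects]

    mse_rows = [
        {"subject": sub["subject"], "cohort": sub["cohort"], "muscle": mus,
         "trigger": trig, "final_mse": sub["results"][(mus, trig)]["final_mse"]}
        for sub in subjects for mus, trig in PAIRINGS
    ]
    mse_table = pd.DataFrame(mse_rows)

    # aggregation policies over subjects (per-cohort means, min-MSE pick)
    all_idx = list(range(cfg.n_subjects))
    policies: list[tuple[str, list[int]]] = [("mean_all", all_idx)]
    for tag in sorted(set(cfg.cohorts[: cfg.n_subjects])):
        idx = [s for s in all_idx if subjects[s]["cohort"] == tag]
        if idx:
            policies.append((f"mean_{tag}", idx))
    best = int(mse_table.groupby("subject")["final_mse"].mean().idxmin())
    policies.append(("min_mse", [best]))
    policies += [(f"subject_{s}", [s]) for s in all_idx]

    sets = _aggregate(fits, policies)

    param_rows, char_rows, sim_rows = [], [], []
    plant = PlantConfig()
    for name, params in sets.items():
        tfs = {}
        for ch, p in params.items():
            joint = "hip" if ch.startswith("hip") else "knee"
            trigger = {"hip_flexion": "CH", "hip_extension": "IH",
                       "knee_flexion": "CH", "knee_extension": "AEA"}[ch]
            tfs[ch] = finalize_motor_tf(p, joint, trigger=trigger, action=ch.split("_")[1])
            param_rows.append({"set": name, "channel": ch, "tau1_ms": p.tau1_ms,
                               "tau2_ms": p.tau2_ms, "T0_ms": p.T0_ms})
        flex = characterize(tfs["hip_flexion"])
        ext = characterize(tfs["hip_extension"])
        verdict, margin = stability_heuristic(flex, ext)
        char_rows.append({"set": name, "hip_flex_dT50_ms": flex.dT50_ms,
                          "hip_flex_Tpeak_ms": flex.Tpeak_ms,
                          "hip_ext_dT50_ms": ext.dT50_ms, "hip_ext_Tpeak_ms": ext.Tpeak_ms,
                          "rule_verdict": verdict, "margin_ms": margin})
        controller = ReflexController(tfs, ControllerConfig())
        res = simulate(controller, plant, duration_s=cfg.sim_duration_s, seed=cfg.seed)
        row = {"set": name, "n_strides": res.n_strides, "fell": res.fell,
               "halt_reason": res.halt_reason}
        if res.n_strides >= 2:
            row.update(gait_metrics(res, plant))
        sim_rows.append(row)

    report = {
        "provenance": {"seed": cfg.seed, "config_hash": cfg.hash(), "version": __version__},
        "mse_table": mse_table,
        "parameter_table": pd.DataFrame(param_rows),
        "characteristics_table": pd.DataFrame(char_rows),
        "simulation_table": pd.DataFrame(sim_rows),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for key in ("mse_table", "parameter_table", "characteristics_table", "simulation_table"):
            report[key].to_csv(outdir / f"{key}.csv", index=False)
        (outdir / "provenance.json").write_text(json.dumps(report["provenance"], indent=1))
        log.info("report written to %s", outdir)
    return report
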