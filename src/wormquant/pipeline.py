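"""End-to-end pipeline: simulate -> quantify/score -> summarize.

``run_pipeline`` executes the stages into a run directory and writes a
provenance manifest (configuration hash, package version, per-stage row
counts) plus a plain-text log with per-stage timing.  Given the same
configuration and seed, two runs produce byte-identical result tables.
"""

from __future__ import annotations

import logging
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._rng import stream
from .behavior import call_paralysis, thrash_frequency
from .calcium import Roi, call_response, compute_ratio_trace, track_roi
from .config import RunConfig
from .errors import ParameterError
from .io import read_event_table, write_event_table, write_json
from .popstats import (
    compare_habituated_level,
    habituation_curve,
    proportion_endpoint,
    qc_day,
)
from .synthetic import (
    StackParams,
    SwimParams,
    gen_image_stack,
    gen_swim_traces,
    gen_tap_experiment,
    linear_drift_path,
)

__all__ = ["run_pipeline", "simulate_swim_endpoints", "simulate_calcium_endpoints"]

_FLOAT_FMT = "%.10g"


def _write(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return len(df)


def simulate_swim_endpoints(config: RunConfig, seed: int) -> pd.DataFrame:
    """Simulate swim traces per strain and score SWIP endpoints on them.

    Returns one row per worm: strain, worm index, swimming-at-10-min outcome,
    thrash frequency over the 11-min window, and the simulated truth.
    """
    rows = []
    b = config.behavior
    for strain in sorted(config.swim):
        opts = config.swim[strain]
        rng = stream(seed, f"swim-assign/{strain}")
        paralyzed = rng.random(config.n_worms) < opts["paralysis_prob"]
        # paralysis onset early enough that the quiet window is truly quiet
        onsets = rng.uniform(120.0, 500.0, config.n_worms)
        params = [
            SwimParams(
                sample_rate=10.0,
                duration=660.0,
                thrash_freq=opts["thrash_freq"],
                amplitude=60.0,
                paralysis_time=float(onsets[i]) if paralyzed[i] else None,
                noise_sd=5.0,
            )
            for i in range(config.n_worms)
        ]
        traces = gen_swim_traces(params, seed=(seed + zlib.crc32(strain.encode()) % 1000) % 2**31)
        for i, (trace, truth) in enumerate(traces):
            par = call_paralysis(
                trace,
                assay_time=b.swip_assay_time,
                quiet_window=b.swip_quiet_window,
                theta_c=b.theta_c,
                hysteresis=b.hysteresis,
            )
            thrash = thrash_frequency(trace, theta_c=b.theta_c, hysteresis=b.hysteresis)
            rows.append(
                dict(strain=strain, worm=i, swimming=not par,
                     thrash_hz=thrash.frequency_hz,
                     true_paralysis_time=truth.paralysis_time
                     if truth.paralysis_time is not None else np.nan)
            )
    return pd.DataFrame(rows)


def simulate_calcium_endpoints(config: RunConfig, seed: int) -> pd.DataFrame:
    """Simulate stimulus trials per strain and quantify responses.

    Each trial renders a small two-channel stack (responding trials carry a
    transient at the configured peak, non-responding trials none), tracks the
    ROI, computes the ratio trace and calls the response.
    """
    rows = []
    c = config.calcium
    for strain in sorted(config.calcium_sim):
        opts = config.calcium_sim[strain]
        rng = stream(seed, f"ca-assign/{strain}")
        for trial in range(int(opts["n_trials"])):
            responds = bool(rng.random() < opts["response_prob"])
            n_frames = 240
            params = StackParams(
                frame_rate=10.0,
                duration=n_frames / 10.0,
                image_shape=(48, 48),
                cell_path=linear_drift_path(n_frames, (20.0, 20.0), (0.02, 0.03)),
                transient_onset=8.0,
                transient_peak_dRR0=float(opts["peak_dRR0"]) if responds else 0.0,
                alpha_true=c.alpha,
            )
            stack, truth = gen_image_stack(
                params, seed=(seed * 1000 + trial + zlib.crc32(strain.encode()) % 997) % 2**31
            )
            roi = Roi(center=tuple(truth.centroid_path[0]), half_height=6, half_width=6)
            path = track_roi(stack, roi)
            trace = compute_ratio_trace(
                stack, path, alpha=c.alpha,
                baseline_window=c.baseline_window, background_mode=c.background_mode,
            )
            call = call_response(
                trace, stimulus_onset=params.transient_onset, stimulus_kind="buzz",
                threshold_k=c.threshold_k, floor_pct=c.floor_pct,
            )
            rows.append(
                dict(strain=strain, trial=trial, responder=call.responder,
                     peak_dRR0=call.peak_dRR0, true_peak=params.transient_peak_dRR0,
                     true_responder=responds)
            )
    return pd.DataFrame(rows)


def _stats_outputs(events: pd.DataFrame, config: RunConfig, outdir: Path,
                   counts: dict, log: logging.Logger) -> None:
    s = config.stats
    curves = []
    for strain in sorted(events["strain"].unique()):
        cur = habituation_curve(events, strain, level=s.level, method=s.ci_method)
        cur.insert(0, "strain", strain)
        curves.append(cur)
    counts["habituation_curves"] = _write(
        pd.concat(curves, ignore_index=True), outdir / "habituation_curves.csv"
    )
    try:
        qc = qc_day(events, s.qc_reference_strain, s.qc_min_initial_response)
        write_json(
            dict(passed=qc.passed, proportion=qc.proportion, numerator=qc.numerator,
                 denominator=qc.denominator, reference_strain=qc.reference_strain,
                 min_initial_response=qc.min_initial_response),
            outdir / "qc_day.json",
        )
    except ParameterError:
        log.warning("QC gate not evaluable: reference strain missing")
    comparison = compare_habituated_level(events, endpoint_tap=s.endpoint_tap)
    counts["habituated_level_contrasts"] = _write(
        comparison.contrasts, outdir / "habituated_level_contrasts.csv"
    )
    _write(comparison.coefficients, outdir / "habituated_level_coefficients.csv")


def run_pipeline(config: RunConfig, mode: str = "simulate") -> Path:
    """Run the pipeline into ``config.outdir``; returns the run directory."""
    if mode not in ("simulate", "analyze"):
        raise ParameterError("mode must be 'simulate' or 'analyze'")
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log = logging.getLogger("wormquant.pipeline")
    log.setLevel(logging.INFO)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    counts: dict[str, int] = {}
    t_start = time.perf_counter()
    try:
        if mode == "simulate":
            t0 = time.perf_counter()
            events, truth = gen_tap_experiment(
                config.strains, config.n_worms, config.protocol, seed=config.seed
            )
            counts["events"] = _write(events, outdir / "events.csv")
            write_json({s: p for s, p in truth.items()}, outdir / "tap_truth.json")
            log.info("stage taps: %d rows in %.2f s", counts["events"], time.perf_counter() - t0)

            t0 = time.perf_counter()
            swim = simulate_swim_endpoints(config, config.seed)
            counts["swim_endpoints"] = _write(swim, outdir / "swim_endpoints.csv")
            log.info("stage swim: %d rows in %.2f s",
                     counts["swim_endpoints"], time.perf_counter() - t0)

            t0 = time.perf_counter()
            calcium = simulate_calcium_endpoints(config, config.seed)
            counts["calcium_trials"] = _write(calcium, outdir / "calcium_trials.csv")
            log.info("stage calcium: %d rows in %.2f s",
                     counts["calcium_trials"], time.perf_counter() - t0)
        else:
            if "events" not in config.inputs:
                raise ParameterError("analyze mode requires inputs['events']")
            path = Path(config.inputs["events"])
            if not path.exists():
                raise ParameterError(f"missing input file: {path}")
            events = read_event_table(path)
            counts["events"] = len(events)
            swim = calcium = None
            swim_path = config.inputs.get("swim_endpoints")
            if swim_path:
                swim = pd.read_csv(swim_path)
            ca_path = config.inputs.get("calcium_trials")
            if ca_path:
                calcium = pd.read_csv(ca_path)

        t0 = time.perf_counter()
        _stats_outputs(events, config, outdir, counts, log)
        if swim is not None and len(swim):
            outcomes = swim.rename(columns={"swimming": "outcome"})[["strain", "outcome"]]
            if outcomes["strain"].nunique() >= 2:
                cis, comp = proportion_endpoint(
                    outcomes, endpoint="swimming-at-10-min",
                    level=config.stats.level, method=config.stats.ci_method,
                )
                counts["swip_contrasts"] = _write(comp.contrasts, outdir / "swip_contrasts.csv")
                _write(_ci_table(cis), outdir / "swip_proportions.csv")
        if calcium is not None and len(calcium):
            outcomes = calcium.rename(columns={"responder": "outcome"})[["strain", "outcome"]]
            if outcomes["strain"].nunique() >= 2:
                cis, comp = proportion_endpoint(
                    outcomes, endpoint="responding-to-buzz",
                    level=config.stats.level, method=config.stats.ci_method,
                )
                counts["responder_contrasts"] = _write(
                    comp.contrasts, outdir / "responder_contrasts.csv"
                )
                _write(_ci_table(cis), outdir / "responder_proportions.csv")
        log.info("stage stats in %.2f s", time.perf_counter() - t0)

        manifest = dict(
            config_sha256=config.digest(),
            version=__version__,
            mode=mode,
            seed=config.seed,
            row_counts=counts,
        )
        write_json(manifest, outdir / "manifest.json")
        config.to_yaml(outdir / "config.yaml")
        log.info("pipeline complete in %.2f s", time.perf_counter() - t_start)
    finally:
        log.removeHandler(handler)
        handler.close()
    return outdir


def _ci_table(cis: dict) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(strain=s, numerator=ci.numerator, denominator=ci.denominator,
                 proportion=ci.proportion, ci_low=ci.ci_low, ci_high=ci.ci_high,
                 method=ci.method, level=ci.level)
            for s, ci in sorted(cis.items())
        ]
    )
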