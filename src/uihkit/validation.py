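"""End-to-end parameter-recovery studies on synthetic data.

Each study generates inputs with :mod:`uihkit.synth` at known ground
truth, runs the corresponding analysis pipeline, and reports how well the
programmed quantity is recovered.  These are the package's built-in
verification experiments; the problem sizes are chosen so the full battery
runs in minutes on one CPU.
"""

from __future__ import annotations

import numpy as np

from . import controller as ctl
from . import endpoints as ep
from . import histoquant as hq
from . import nucseq as ns
from . import photometry as ph
from . import synth
from . import thermography as tg

__all__ = [
    "dip_recovery_study",
    "photometry_recovery_study",
    "histology_recovery_study",
    "controller_study",
    "nucseq_recovery_study",
    "plant_endpoint_demo",
]


def dip_recovery_study(
    depths_degc: tuple[float, ...] = (1.0, 2.0, 3.0),
    n_runs: int = 99,
    seed: int = 0,
    noise_sd: float = 0.1,
    frame_rate_hz: float = 0.25,
    lowpass_cutoff_hz: float = 0.05,
) -> dict:
    """Thermography-to-endpoint pipeline recovery of programmed BAT dips.

    For each run a Gaussian-shaped T_BAT dip of programmed depth is
    rendered into a drifting-body thermal video with pixel noise, the BAT
    ROI is re-tracked frame by frame, the trace low-pass filtered, and the
    windowed dip endpoint compared with the programmed depth.  Runs are
    spread evenly over ``depths_degc``.
    """
    rng = np.random.default_rng(seed)
    errors = []
    per_depth: dict[float, list[float]] = {d: [] for d in depths_degc}
    for i in range(n_runs):
        depth = depths_degc[i % len(depths_degc)]
        run_seed = int(rng.integers(0, 2**31 - 1))
        trace, truth = synth.dip_trace(depth, sample_interval_s=1.0 / frame_rate_hz)
        geo = synth.BodyGeometry(drift_mm_per_s=(0.002, 0.003))
        stack, video_truth = synth.render_thermal_video(
            {"T_BAT": trace},
            geometry=geo,
            frame_rate_hz=None,  # one frame per trace sample
            noise_sd=noise_sd,
            seed=run_seed,
        )
        head_px = tuple(video_truth["head_mm"][0] / stack.pixel_size_mm)
        measured = tg.bat_trace(stack, head_hint=head_px)
        filtered = tg.lowpass(measured, lowpass_cutoff_hz)
        delta = ep.max_delta(filtered, ep.BAT_CONFIG, us_onset=0.0)
        err = delta - (-depth)
        errors.append(err)
        per_depth[depth].append(abs(err))
    errors = np.asarray(errors)
    return {
        "n_runs": n_runs,
        "max_abs_error_degc": float(np.abs(errors).max()),
        "mean_abs_error_degc": float(np.abs(errors).mean()),
        "mean_error_degc": float(errors.mean()),
        "per_depth_max_abs_error": {d: float(max(v)) for d, v in per_depth.items()},
    }


def photometry_recovery_study(
    n_seeds: int = 100,
    seed: int = 0,
    noise_sd: float = 0.1,
    amp_over_noise: float = 5.0,
    fs_hz: float = 20.0,
    min_prominence: float = 2.0,
    smooth_cutoff_hz: float = 0.5,
) -> dict:
    """Transient count and timing recovery from bleaching photometry traces.

    Six stimulus-locked transients (amplitude ``amp_over_noise`` times the
    noise s.d.) ride on an exponential bleach; the pipeline is
    :func:`uihkit.photometry.transient_peaks` (de-bleach, matched
    smoothing, z-score, prominence detection, leading-edge refinement).  A
    seed counts as a count success when exactly six peaks are found; as a
    peak-timing success when additionally every refined peak lies within 2
    samples of its programmed time; and as an onset success when the
    3-s.d. evoked-activity onset statistic relative to each stimulus is
    within 2 samples of the programmed (zero) latency.
    """
    rng = np.random.default_rng(seed)
    onsets = 5.0 + 30.0 * np.arange(6)  # train of 6, period 30 s
    count_ok = 0
    timing_ok = 0
    onset_ok = 0
    for _ in range(n_seeds):
        run_seed = int(rng.integers(0, 2**31 - 1))
        trace, truth = synth.simulate_photometry(
            transient_times_s=onsets,
            transient_amp=amp_over_noise * noise_sd,
            noise_sd=noise_sd,
            fs_hz=fs_hz,
            duration_s=190.0,
            seed=run_seed,
        )
        peaks, z_raw = ph.transient_peaks(
            trace, smooth_cutoff_hz=smooth_cutoff_hz, min_prominence=min_prominence
        )
        tol = 2.0 / fs_hz + 1e-9
        if peaks.n == onsets.size:
            count_ok += 1
            if np.all(np.abs(peaks.times - truth["transient_times_s"]) <= tol):
                timing_ok += 1
        lat = [ph.onset_time(z_raw, t) for t in onsets]
        if all(l is not None and l <= tol for l in lat):
            onset_ok += 1
    return {
        "n_seeds": n_seeds,
        "count_exact_pct": 100.0 * count_ok / n_seeds,
        "count_and_timing_pct": 100.0 * timing_ok / n_seeds,
        "onset_within_2_samples_pct": 100.0 * onset_ok / n_seeds,
    }


def histology_recovery_study(
    fractions: tuple[float, ...] = (0.02, 0.10, 0.30),
    n_cells_per_region: int = 500,
    seed: int = 0,
) -> dict:
    """Recovery of programmed positive fractions by the positivity rule.

    One region per programmed fraction, ``n_cells_per_region`` cells each;
    the recovered region fraction is compared against the programmed value
    in units of the binomial standard error sqrt(f(1-f)/n).
    """
    regions = [f"R{i}" for i in range(len(fractions))]
    prog = dict(zip(regions, fractions))
    cells, truth = synth.simulate_cell_table(
        regions, n_cells_per_region, prog, seed=seed
    )
    bg = truth["background"]
    out = {}
    worst = 0.0
    for r in regions:
        f = prog[r]
        rec = hq.region_fraction(cells, "fos", bg, r)
        se = np.sqrt(f * (1 - f) / n_cells_per_region)
        dev = abs(rec - f) / se
        worst = max(worst, dev)
        out[r] = {"programmed": f, "recovered": rec, "abs_error_over_se": float(dev)}
    return {"by_region": out, "max_error_over_se": float(worst)}


def controller_study(
    n_sessions: int = 100,
    duration_h: float = 24.0,
    seed: int = 0,
    dt_min: float = 0.1,
) -> dict:
    """Safety and efficacy of the bang-bang loop over seeded 24-h sessions.

    Safety: no train may start at a sample with measured T_core <= T_set.
    Efficacy: fraction of post-convergence samples (after the first sample
    at or below T_set) inside [T_set - 2, T_set + 0.5] degC.
    """
    cfg = ctl.ControllerConfig()
    plant = synth.PlantParams()
    rng = np.random.default_rng(seed)
    violations = 0
    in_band = 0
    total = 0
    per_session = []
    mean_t = []
    hours_below = []
    for _ in range(n_sessions):
        run_seed = int(rng.integers(0, 2**31 - 1))
        log = ctl.run_closed_loop(plant, cfg, duration_h, seed=run_seed, dt_min=dt_min)
        sample_lookup = dict(zip(log.samples.times, log.samples.values))
        for t0 in log.schedule.train_onsets():
            if sample_lookup.get(t0, np.inf) <= cfg.T_set:
                violations += 1
        vals = log.samples.values
        converged = vals <= cfg.T_set
        if converged.any():
            start = int(np.argmax(converged))
            post = vals[start:]
            ok = (post >= cfg.T_set - 2.0) & (post <= cfg.T_set + 0.5)
            in_band += int(ok.sum())
            total += post.size
            per_session.append(100.0 * ok.mean())
        summary = ctl.summarize_session(log)
        mean_t.append(summary["mean_T_core"])
        hours_below.append(summary["hours_below_threshold"])
    return {
        "n_sessions": n_sessions,
        "safety_violations": violations,
        "in_band_pct": 100.0 * in_band / total if total else float("nan"),
        "worst_session_in_band_pct": float(min(per_session)) if per_session else float("nan"),
        "mean_T_core": float(np.mean(mean_t)),
        "mean_hours_below_34": float(np.mean(hours_below)),
    }


def _nucseq_spec(fold_change: float, base: float = 0.2) -> list[synth.ClusterSpec]:
    """Eight planted clusters: three torpor-marker-high, one IEG-activated."""
    hi = base * fold_change
    specs = []
    for i in range(8):
        torpor = i < 3
        activated = i == 1
        markers = {g: (hi if torpor else base) for g in synth.TORPOR_MARKERS}
        markers.update({g: (hi if activated else base) for g in synth.IEG_MARKERS})
        markers["Slc17a6"] = 2.0 if torpor else 0.2
        markers["Gad1"] = 0.2 if torpor else 2.0
        specs.append(
            synth.ClusterSpec(name=f"c{i}", marker_means=markers, activated=activated)
        )
    return specs


def nucseq_recovery_study(
    n_seeds: int = 100,
    seed: int = 0,
    fold_change: float = 8.0,
    n_genes: int = 2000,
    n_cells: int = 3000,
) -> dict:
    """Recovery of the planted activated torpor cluster.

    Each seed generates a count matrix with eight clusters, three of them
    torpor-marker-high (fold change ``fold_change``) and one of those with
    elevated IEGs; the pipeline (QC, log-normalise, marker k-means, IEG
    ranking) must return the planted activated cluster.
    """
    rng = np.random.default_rng(seed)
    spec = _nucseq_spec(fold_change)
    torpor_truth = {c.name for c in spec if c.marker_means["Adcyap1"] > 0.5}
    torpor_ok = 0
    activated_ok = 0
    for _ in range(n_seeds):
        run_seed = int(rng.integers(0, 2**31 - 1))
        m, truth = synth.simulate_counts(n_cells, spec, seed=run_seed, n_genes=n_genes)
        filtered, _ = ns.qc_filter(m)
        norm = ns.lognormalize(filtered)
        prof = ns.cluster_profiles(
            norm, filtered.genes, filtered.cluster_labels, synth.TORPOR_MARKERS
        )
        torpor = ns.torpor_kmeans(prof, k=2, seed=run_seed)
        if torpor == torpor_truth:
            torpor_ok += 1
        ieg_prof = ns.cluster_profiles(
            norm, filtered.genes, filtered.cluster_labels, synth.IEG_MARKERS
        )
        rank = ns.ieg_activation_rank(ieg_prof, torpor)
        if rank.index[0] == truth["activated_cluster"]:
            activated_ok += 1
    return {
        "n_seeds": n_seeds,
        "torpor_set_exact_pct": 100.0 * torpor_ok / n_seeds,
        "activated_recovery_pct": 100.0 * activated_ok / n_seeds,
    }


def plant_endpoint_demo(seed: int = 0) -> dict:
    """Endpoint readout of one default open-loop bout (single 6-stimulus train).

    Simulates the default plant with ultrasound at t=0 after a 30-min
    baseline, then computes the windowed endpoint statistics exactly as for
    a recorded session: max dT_core, max dVO2 (as % of baseline), minimum
    RQ, bout onset/end/duration.
    """
    train = ctl.build_train(ctl.TrainParams(), t0_s=0.0)
    params = synth.PlantParams()
    traces = synth.simulate_plant(params, _shift(train, 1800.0), 120.0, seed=seed)
    shift = -1800.0
    t_core = traces.t_core.shifted(shift)
    # gas-exchange telemetry is slow; filter sensor noise before the ratio
    vo2 = tg.lowpass(traces.vo2.shifted(shift), 0.002)
    vco2 = tg.lowpass(traces.vco2.shifted(shift), 0.002)
    d_core = ep.max_delta(t_core, ep.CORE_CONFIG, 0.0)
    base_vo2 = ep.baseline_mean(vo2, (-360.0, -60.0))
    d_vo2 = ep.max_delta(vo2, ep.VO2_CONFIG, 0.0)
    rq = ep.rq_trace(vco2, vo2)
    rq_min = float(np.nanmin(rq.window(0.0, 3600.0).values))
    onset = ep.uih_onset(t_core, 0.0)
    end = None
    if onset is not None:
        search = t_core.window(0.0, 3600.0)
        nadir_t = float(search.times[np.argmin(search.values)])
        end = ep.uih_end(t_core, after=nadir_t)
    return {
        "max_delta_t_core_degc": d_core,
        "max_delta_vo2_pct": 100.0 * d_vo2 / base_vo2,
        "min_rq": rq_min,
        "uih_duration_min": ep.uih_duration(onset, end),
    }


def _shift(schedule, dt_s: float):
    from .core import StimulusSchedule

    return StimulusSchedule(
        schedule.onsets + dt_s, schedule.offsets + dt_s, schedule.pressures, schedule.train_ids
    )
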