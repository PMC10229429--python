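"""Synthetic-data generators with known ground truth.

Every generator in this module is a pure function of its parameters and a
seed, and returns its ground truth alongside the data so that downstream
stages can be verified without any external recording.

The centrepiece is a first-order thermoregulatory *plant*: Newtonian
cooling toward ambient temperature plus a suppressible thermogenic drive,

    dT/dt = -k_loss * (T - T_amb) + k_therm * H(t)

where the drive ``H`` is decremented by ``suppression_per_train`` at each
ultrasound train onset and relaxes back to ``H0`` with time constant
``tau_recovery``.  The drive is floored at ``h_floor``, the basal
(obligatory) component of thermogenesis that ultrasound stimulation of the
preoptic area does not remove; only the facultative component above the
floor is suppressible.  This is the simplest model that produces the
dip-and-spontaneous-recovery shape of an ultrasound-induced hypothermia
bout and a stable bang-bang closed loop, and it stands in for the animal
in closed-loop simulations.  It is an emulation target, not a biophysical
claim.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from .core import StimulusSchedule, ThermalStack, TimeSeries

__all__ = [
    "PlantParams",
    "PlantTraces",
    "simulate_plant",
    "plant_equilibrium",
    "suppression_for_dip",
    "dose_scale",
    "BodyGeometry",
    "render_thermal_video",
    "dip_trace",
    "simulate_photometry",
    "simulate_cell_table",
    "simulate_counts",
    "ClusterSpec",
    "TORPOR_MARKERS",
    "IEG_MARKERS",
]

#: torpor-associated neuron markers
TORPOR_MARKERS = ("Adcyap1", "Qrfp", "Esr1")
#: immediate-early genes marking recently activated neurons
IEG_MARKERS = ("Fos", "Fosb", "Nr4a1", "Egr1", "Dusp1")


# ---------------------------------------------------------------------------
# thermoregulatory plant
# ---------------------------------------------------------------------------

@dataclass
class PlantParams:
    """Parameters of the simulated thermoregulatory plant.

    Defaults were chosen once, in closed form, so that the plant at 22 degC
    ambient sits at a 36.5 degC equilibrium, a single default 6-stimulus
    train produces a ~3.3 degC core-temperature dip, and the bout (onset to
    return above 34 degC) lasts roughly one hour.

    Attributes
    ----------
    T_amb:
        Ambient temperature, degC.
    k_loss:
        Heat-loss rate constant, 1/min.
    k_therm:
        Thermogenic gain at full drive, degC/min.
    H0:
        Baseline thermogenic drive, in [0, 1].
    h_floor:
        Basal (non-suppressible) drive floor, in [0, H0].
    suppression_per_train:
        Drive decrement applied at each stimulus-train onset, in [0, 1].
    tau_recovery:
        Drive recovery time constant, min.
    noise_sd:
        Temperature measurement noise, degC.
    vo2_gain:
        Oxygen consumption per unit drive, ml/min.
    vo2_noise_sd:
        VO2/VCO2 measurement noise, ml/min.
    rq_normal, rq_torpid:
        Respiratory quotient at full vs fully suppressed drive.
    bat_gain:
        Extra BAT surface-temperature excursion per unit drive deficit,
        degC (T_BAT = T_core + bat_gain * (H - H0)).
    """

    T_amb: float = 22.0
    k_loss: float = 0.05
    k_therm: float = 0.725
    H0: float = 1.0
    h_floor: float = 0.55
    suppression_per_train: float = 0.39
    tau_recovery: float = 60.0
    noise_sd: float = 0.05
    vo2_gain: float = 1.8
    vo2_noise_sd: float = 0.02
    rq_normal: float = 0.85
    rq_torpid: float = 0.72
    bat_gain: float = 4.0

    def __post_init__(self) -> None:
        for name in ("T_amb", "k_loss", "k_therm", "H0", "h_floor",
                     "suppression_per_train", "tau_recovery", "noise_sd",
                     "vo2_gain", "vo2_noise_sd", "rq_normal", "rq_torpid",
                     "bat_gain"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"plant parameter {name!r} must be finite, got {v!r}")
        for name in ("k_loss", "k_therm", "tau_recovery"):
            if not getattr(self, name) > 0:
                raise ValueError(f"plant parameter {name!r} must be > 0")
        for name in ("H0", "suppression_per_train"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"plant parameter {name!r} must be in [0, 1], got {v}")
        if not 0.0 <= self.h_floor <= self.H0:
            raise ValueError("plant parameter 'h_floor' must be in [0, H0]")
        for name in ("rq_normal", "rq_torpid"):
            v = getattr(self, name)
            if not 0.6 <= v <= 1.1:
                raise ValueError(f"plant parameter {name!r} must be in [0.6, 1.1], got {v}")
        for name in ("noise_sd", "vo2_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"plant parameter {name!r} must be >= 0")


def plant_equilibrium(params: PlantParams, drive: float | None = None) -> float:
    """Fixed-point core temperature at constant drive (default: ``H0``)."""
    h = params.H0 if drive is None else drive
    return params.T_amb + params.k_therm * h / params.k_loss


def dose_scale(pressure_mpa: float, threshold_mpa: float = 0.8,
               reference_mpa: float = 1.6) -> float:
    """Acoustic-pressure dose factor applied to per-train drive suppression.

    Linear between the response threshold (no effect at or below 0.8 MPa)
    and the reference pressure, saturating at 1 above it.  NaN pressure
    (schedule without acoustic metadata) maps to 1.
    """
    if not np.isfinite(pressure_mpa):
        return 1.0
    x = (pressure_mpa - threshold_mpa) / (reference_mpa - threshold_mpa)
    return float(np.clip(x, 0.0, 1.0))


def _rq(params: PlantParams, h: float) -> float:
    span = params.H0 - params.h_floor
    frac = 1.0 if span <= 0 else np.clip((h - params.h_floor) / span, 0.0, 1.0)
    return params.rq_torpid + (params.rq_normal - params.rq_torpid) * frac


@dataclass
class PlantTraces:
    """Observable traces plus noiseless truth from a plant simulation."""

    t_core: TimeSeries
    t_bat: TimeSeries
    vo2: TimeSeries
    vco2: TimeSeries
    #: noiseless core temperature (ground truth)
    t_core_true: TimeSeries
    #: thermogenic drive H(t) (ground truth)
    drive: TimeSeries
    seed: int


def simulate_plant(
    params: PlantParams,
    schedule: StimulusSchedule,
    duration_min: float,
    dt_min: float = 0.05,
    seed: int = 0,
    T0: float | None = None,
) -> PlantTraces:
    """Integrate the plant ODE under a stimulus schedule (explicit Euler).

    Times in the returned traces are seconds, starting at 0.  The schedule
    is in seconds; drive suppression is applied at each *train* onset,
    scaled by the train's acoustic pressure through :func:`dose_scale`.
    """
    if not dt_min > 0:
        raise ValueError("dt_min must be > 0")
    if duration_min < dt_min:
        raise ValueError("duration_min must be >= dt_min")
    rng = np.random.default_rng(seed)

    n = int(round(duration_min / dt_min)) + 1
    t_min = np.arange(n) * dt_min
    onsets_min = schedule.train_onsets() / 60.0
    pressures = schedule.train_pressures()

    T = plant_equilibrium(params) if T0 is None else float(T0)
    H = params.H0
    T_arr = np.empty(n)
    H_arr = np.empty(n)
    next_train = 0
    for i in range(n):
        t = t_min[i]
        while next_train < onsets_min.size and onsets_min[next_train] <= t:
            drop = params.suppression_per_train * dose_scale(pressures[next_train])
            H = max(params.h_floor, H - drop)
            next_train += 1
        T_arr[i] = T
        H_arr[i] = H
        # Euler step
        T = T + dt_min * (-params.k_loss * (T - params.T_amb) + params.k_therm * H)
        H = H + dt_min * (params.H0 - H) / params.tau_recovery

    t_s = t_min * 60.0
    noise_T = rng.normal(0.0, params.noise_sd, n) if params.noise_sd else np.zeros(n)
    noise_B = rng.normal(0.0, params.noise_sd, n) if params.noise_sd else np.zeros(n)
    noise_v = rng.normal(0.0, params.vo2_noise_sd, n) if params.vo2_noise_sd else np.zeros(n)
    noise_c = rng.normal(0.0, params.vo2_noise_sd, n) if params.vo2_noise_sd else np.zeros(n)

    bat = T_arr + params.bat_gain * (H_arr - params.H0)
    vo2 = params.vo2_gain * H_arr
    rq = np.array([_rq(params, h) for h in H_arr])
    vco2 = rq * vo2

    return PlantTraces(
        t_core=TimeSeries(t_s, T_arr + noise_T, "degC"),
        t_bat=TimeSeries(t_s, bat + noise_B, "degC"),
        vo2=TimeSeries(t_s, vo2 + noise_v, "ml/min"),
        vco2=TimeSeries(t_s, vco2 + noise_c, "ml/min"),
        t_core_true=TimeSeries(t_s, T_arr, "degC"),
        drive=TimeSeries(t_s, H_arr, "drive"),
        seed=seed,
    )


def suppression_for_dip(depth_degc: float, params: PlantParams | None = None) -> PlantParams:
    """Plant parameters programmed to dip ``depth_degc`` after one train.

    For the linear plant the single-train core-temperature response from
    equilibrium is ``x(t) = -k_therm * s * (exp(-t/tau) - exp(-k t)) / (k - 1/tau)``,
    whose extremum depth is proportional to the suppression ``s``.  This
    closed form is inverted to program an exact dip depth, the ground truth
    used in parameter-recovery checks.
    """
    p = PlantParams() if params is None else params
    k = p.k_loss
    lam = 1.0 / p.tau_recovery
    if abs(k - lam) < 1e-12:
        t_star = 1.0 / k
        factor = t_star * math.exp(-k * t_star)
    else:
        t_star = math.log(k / lam) / (k - lam)
        factor = (math.exp(-lam * t_star) - math.exp(-k * t_star)) / (k - lam)
    s = depth_degc / (p.k_therm * factor)
    if s > p.H0 - p.h_floor + 1e-9:
        raise ValueError(
            f"programmed dip {depth_degc} degC needs suppression {s:.3f} "
            f"exceeding the facultative drive span {p.H0 - p.h_floor:.3f}"
        )
    return dataclasses.replace(p, suppression_per_train=float(s))


# ---------------------------------------------------------------------------
# thermal video rendering
# ---------------------------------------------------------------------------

@dataclass
class BodyGeometry:
    """Geometry of the rendered mouse body in a thermal scene.

    The body is an ellipse with semi-axes ``(semi_major_mm, semi_minor_mm)``;
    the BAT hotspot disk sits 25% of the body length anterior to the body
    centre along the major axis; a thin tail extends from the posterior end.
    """

    center_mm: tuple[float, float] = (32.0, 40.0)
    semi_major_mm: float = 25.0
    semi_minor_mm: float = 12.0
    orientation_deg: float = 0.0
    drift_mm_per_s: tuple[float, float] = (0.0, 0.0)
    #: radius of the painted BAT patch; the interscapular depot is ~10 mm
    #: across, comfortably wider than the 3-mm measurement ROI
    bat_radius_mm: float = 5.0
    bat_fraction: float = 0.25
    tail_length_mm: float = 25.0
    tail_width_mm: float = 2.0


def render_thermal_video(
    traces: dict[str, TimeSeries | float],
    geometry: BodyGeometry | None = None,
    pixel_size_mm: float = 1.0,
    frame_rate_hz: float | None = 0.5,
    seed: int = 0,
    frame_shape: tuple[int, int] = (64, 80),
    T_amb: float = 22.0,
    noise_sd: float = 0.0,
) -> tuple[ThermalStack, dict]:
    """Render a thermography scene following a programmed T_BAT trace.

    ``traces`` must contain ``"T_BAT"`` (a :class:`TimeSeries`); optional
    entries ``"T_body"`` and ``"T_tail"`` may be traces or constants
    (defaults 34 and 28 degC).  Frames are sampled at ``frame_rate_hz``
    over the span of the T_BAT trace (or exactly at its timestamps when
    ``frame_rate_hz`` is None), with traces linearly interpolated.

    Returns the stack and a truth dict with per-frame BAT centre, body
    centroid and head position (all in mm, row/col) plus the painted
    T_BAT values.
    """
    geo = BodyGeometry() if geometry is None else geometry
    if not pixel_size_mm > 0:
        raise ValueError("pixel_size_mm must be > 0")
    t_bat = traces["T_BAT"]
    if not isinstance(t_bat, TimeSeries):
        raise TypeError("traces['T_BAT'] must be a TimeSeries")
    h, w = frame_shape
    if 2 * geo.semi_major_mm >= min(h, w) * pixel_size_mm:
        raise ValueError("body larger than frame")

    if frame_rate_hz is None:
        times = t_bat.times.copy()
    else:
        times = np.arange(t_bat.times[0], t_bat.times[-1] + 1e-9, 1.0 / frame_rate_hz)

    def sample(key: str, default: float) -> np.ndarray:
        v = traces.get(key, default)
        if isinstance(v, TimeSeries):
            return np.interp(times, v.times, v.values)
        return np.full(times.size, float(v))

    bat_vals = np.interp(times, t_bat.times, t_bat.values)
    body_vals = sample("T_body", 34.0)
    tail_vals = sample("T_tail", 28.0)

    rng = np.random.default_rng(seed)
    rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    pos_r = rows * pixel_size_mm  # pixel centre positions, mm
    pos_c = cols * pixel_size_mm

    theta = math.radians(geo.orientation_deg)
    u = np.array([math.cos(theta), math.sin(theta)])  # anterior unit (row, col)
    n_vec = np.array([-math.sin(theta), math.cos(theta)])

    frames = np.empty((times.size, h, w), dtype=np.float32)
    bat_centers = np.empty((times.size, 2))
    centroids = np.empty((times.size, 2))
    heads = np.empty((times.size, 2))
    t0 = times[0]
    for i, t in enumerate(times):
        ctr = np.array(geo.center_mm) + np.array(geo.drift_mm_per_s) * (t - t0)
        dr = pos_r - ctr[0]
        dc = pos_c - ctr[1]
        ax = dr * u[0] + dc * u[1]
        perp = dr * n_vec[0] + dc * n_vec[1]
        frame = np.full((h, w), T_amb, dtype=float)
        # tail strip from posterior end
        tail_mask = (
            (ax <= -geo.semi_major_mm * 0.8)
            & (ax >= -(geo.semi_major_mm + geo.tail_length_mm))
            & (np.abs(perp) <= geo.tail_width_mm / 2.0)
        )
        frame[tail_mask] = tail_vals[i]
        # body ellipse
        body_mask = (ax / geo.semi_major_mm) ** 2 + (perp / geo.semi_minor_mm) ** 2 <= 1.0
        frame[body_mask] = body_vals[i]
        # BAT disk, painted last so disk pixels carry exactly the trace value
        bat_ctr = ctr + geo.bat_fraction * (2 * geo.semi_major_mm) * u
        dist = np.hypot(pos_r - bat_ctr[0], pos_c - bat_ctr[1])
        frame[dist <= geo.bat_radius_mm] = bat_vals[i]
        if noise_sd:
            frame = frame + rng.normal(0.0, noise_sd, frame.shape)
        frames[i] = frame
        bat_centers[i] = bat_ctr
        centroids[i] = ctr
        heads[i] = ctr + geo.semi_major_mm * u

    stack = ThermalStack(frames, times, pixel_size_mm)
    truth = {
        "bat_center_mm": bat_centers,
        "centroid_mm": centroids,
        "head_mm": heads,
        "anterior_unit": u,
        "t_bat": bat_vals,
        "seed": seed,
    }
    return stack, truth


def dip_trace(
    depth_degc: float,
    baseline_degc: float = 37.0,
    t_start_s: float = -900.0,
    t_end_s: float = 780.0,
    nadir_s: float = 570.0,
    sigma_s: float = 120.0,
    sample_interval_s: float = 1.0,
) -> tuple[TimeSeries, dict]:
    """Gaussian-shaped temperature dip with an exactly programmed depth.

    The nadir defaults to 9.5 min after stimulation onset (time 0), inside
    the 7-12 min search window used for the BAT endpoint, and the trace
    spans the 15-min pre-stimulus baseline.  Returns the trace and a truth
    dict with the programmed depth and nadir time.
    """
    times = np.arange(t_start_s, t_end_s, sample_interval_s)
    vals = baseline_degc - depth_degc * np.exp(-0.5 * ((times - nadir_s) / sigma_s) ** 2)
    truth = {"depth": depth_degc, "nadir_s": nadir_s, "baseline": baseline_degc}
    return TimeSeries(times, vals, "degC"), truth


# ---------------------------------------------------------------------------
# photometry
# ---------------------------------------------------------------------------

def simulate_photometry(
    bleach_tau_s: float = 120.0,
    transient_times_s: np.ndarray | list[float] = (),
    transient_amp: float = 1.0,
    transient_tau_s: float = 1.0,
    noise_sd: float = 0.1,
    fs_hz: float = 20.0,
    duration_s: float = 60.0,
    seed: int = 0,
    bleach_amp: float = 2.0,
) -> tuple[TimeSeries, dict]:
    """Exponentially bleaching fluorescence with stimulus-locked transients.

    signal = bleach_amp * exp(-t / bleach_tau_s)
             + sum_i transient_amp * exp(-(t - t_i)/transient_tau_s) [t >= t_i]
             + N(0, noise_sd)

    Each transient rises instantaneously at its programmed time, so the
    de-trended signal peaks there; truth records the programmed times.
    """
    if not fs_hz > 0:
        raise ValueError("fs_hz must be > 0")
    transient_times_s = np.asarray(transient_times_s, dtype=float)
    if transient_times_s.size and (
        transient_times_s.min() < 0 or transient_times_s.max() > duration_s
    ):
        raise ValueError("transient_times must lie within [0, duration]")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s, 1.0 / fs_hz)
    sig = bleach_amp * np.exp(-t / bleach_tau_s)
    for ti in transient_times_s:
        dt = t - ti
        sig = sig + np.where(dt >= 0, transient_amp * np.exp(-np.maximum(dt, 0) / transient_tau_s), 0.0)
    if noise_sd:
        sig = sig + rng.normal(0.0, noise_sd, t.size)
    truth = {"transient_times_s": transient_times_s, "seed": seed}
    return TimeSeries(t, sig, "a.u."), truth


# ---------------------------------------------------------------------------
# histology cell tables
# ---------------------------------------------------------------------------

def simulate_cell_table(
    regions: list[str],
    n_cells_per_region: int | dict[str, int],
    positive_fraction_per_region: float | dict[str, float],
    pos_intensity_dist: tuple[float, float] = (30.0, 3.0),
    neg_intensity_dist: tuple[float, float] = (10.0, 2.0),
    background_mean: float = 10.0,
    background_sd: float = 2.0,
    seed: int = 0,
    channel: str = "fos",
):
    """Per-cell mean-intensity table with a programmed positive fraction.

    Intensities are normal draws (clipped at 0) from the positive or
    negative distribution, assigned per cell by a Bernoulli draw of the
    region's programmed fraction.  Returns ``(DataFrame, truth)`` where the
    frame has columns ``cell_id``, ``region`` and ``<channel>``, and truth
    records per-cell labels, realised fractions and the background stats.
    """
    import pandas as pd

    from .core import BackgroundStats

    if isinstance(n_cells_per_region, int):
        n_cells_per_region = {r: n_cells_per_region for r in regions}
    if isinstance(positive_fraction_per_region, (int, float)):
        positive_fraction_per_region = {r: float(positive_fraction_per_region) for r in regions}
    for r in regions:
        f = positive_fraction_per_region[r]
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"positive fraction for region {r!r} must be in [0, 1]")

    rng = np.random.default_rng(seed)
    rows = []
    labels = []
    cid = 0
    for r in regions:
        n = n_cells_per_region[r]
        pos = rng.random(n) < positive_fraction_per_region[r]
        mu_p, sd_p = pos_intensity_dist
        mu_n, sd_n = neg_intensity_dist
        inten = np.where(pos, rng.normal(mu_p, sd_p, n), rng.normal(mu_n, sd_n, n))
        inten = np.clip(inten, 0.0, None)
        for j in range(n):
            rows.append((cid, r, inten[j]))
            labels.append(bool(pos[j]))
            cid += 1
    df = pd.DataFrame(rows, columns=["cell_id", "region", channel])
    realised = {
        r: float(np.mean([lab for (c, reg, _), lab in zip(rows, labels) if reg == r]))
        for r in regions
    }
    truth = {
        "labels": np.asarray(labels),
        "fraction_by_region": realised,
        "programmed_fraction_by_region": dict(positive_fraction_per_region),
        "background": BackgroundStats(background_mean, background_sd, 10_000),
        "seed": seed,
    }
    return df, truth


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

@dataclass
class ClusterSpec:
    """Mean marker expression (counts/cell) for one planted cluster."""

    name: str
    weight: float = 1.0
    marker_means: dict[str, float] = field(default_factory=dict)
    activated: bool = False


N_MITO_GENES = 13


def simulate_counts(
    n_cells: int,
    cluster_spec: list[ClusterSpec],
    mito_fraction_dist: tuple[float, float] = (0.02, 0.01),
    depth_dist: tuple[float, float] = (2000.0, 400.0),
    seed: int = 0,
    n_genes: int = 2000,
):
    """Poisson count matrix with planted cluster structure over marker genes.

    The gene universe holds the torpor markers, the five IEGs, Slc17a6 and
    Gad1, ``N_MITO_GENES`` mitochondrial ('mt-') genes and filler genes up
    to ``n_genes``.  Filler rates are drawn once (seeded) from a lognormal
    and scaled per cell by a depth factor; marker genes use the per-cluster
    means from ``cluster_spec`` exactly (zero mean => identically zero row
    within that cluster).  Mitochondrial counts target a per-cell fraction
    drawn from ``mito_fraction_dist`` (clipped at 0).

    Returns ``(CountMatrix, truth)`` with truth carrying cluster labels and
    the name of the activated (elevated-IEG) cluster, if any.
    """
    import scipy.sparse as sp

    from .core import CountMatrix

    if not cluster_spec:
        raise ValueError("cluster_spec must contain at least one cluster")
    rng = np.random.default_rng(seed)

    special = list(TORPOR_MARKERS + IEG_MARKERS) + ["Slc17a6", "Gad1"]
    mito = [f"mt-Gene{i}" for i in range(1, N_MITO_GENES + 1)]
    n_filler = n_genes - len(special) - len(mito)
    if n_filler < 0:
        raise ValueError("n_genes too small for the marker + mito gene set")
    filler = [f"Gene{i:05d}" for i in range(n_filler)]
    genes = special + mito + filler

    weights = np.array([c.weight for c in cluster_spec], dtype=float)
    weights = weights / weights.sum()
    labels_idx = rng.choice(len(cluster_spec), size=n_cells, p=weights)
    labels = np.array([cluster_spec[i].name for i in labels_idx])

    depth = np.clip(rng.normal(depth_dist[0], depth_dist[1], n_cells), 1.0, None)
    depth_factor = depth / depth_dist[0]

    # heavy-tailed gene expression: most genes rare, a few dominate totals
    filler_rates = rng.lognormal(mean=-1.0, sigma=1.8, size=n_filler)
    filler_rates = filler_rates / filler_rates.sum() * depth_dist[0]

    lam = np.zeros((n_genes, n_cells))
    for gi, g in enumerate(special):
        means = np.array([c.marker_means.get(g, 0.0) for c in cluster_spec])
        lam[gi, :] = means[labels_idx]
    mito_target = np.clip(rng.normal(*mito_fraction_dist, n_cells), 0.0, 0.5)
    # expected non-mito counts per cell ~ depth; mt rate chosen to hit target fraction
    non_mito = lam[: len(special)].sum(axis=0) + filler_rates.sum() * depth_factor
    mito_total = mito_target / np.clip(1.0 - mito_target, 1e-9, None) * non_mito
    for mi in range(N_MITO_GENES):
        lam[len(special) + mi, :] = mito_total / N_MITO_GENES
    lam[len(special) + N_MITO_GENES:, :] = filler_rates[:, None] * depth_factor[None, :]

    counts = rng.poisson(lam)
    mat = sp.csr_matrix(counts)
    barcodes = [f"cell{i:06d}" for i in range(n_cells)]
    cm = CountMatrix(mat, genes, barcodes, cluster_labels=labels)
    activated = [c.name for c in cluster_spec if c.activated]
    truth = {
        "labels": labels,
        "activated_cluster": activated[0] if activated else None,
        "marker_means": {c.name: dict(c.marker_means) for c in cluster_spec},
        "seed": seed,
    }
    return cm, truth
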