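"""Format readers/writers: trace CSV, thermal TIFF stacks, MTX matrices,
stimulus schedules and run manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp
import tifffile

from .core import CountMatrix, StimulusSchedule, ThermalStack, TimeSeries

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_tiff_stack",
    "read_tiff_stack",
    "write_mtx",
    "read_mtx",
    "write_schedule_csv",
    "read_schedule_csv",
    "save_roi_overlay",
    "sha256_file",
    "write_manifest",
]


def write_trace_csv(trace: TimeSeries, path: str | Path) -> Path:
    """Write a trace as CSV with columns ``time_s,value,unit``."""
    path = Path(path)
    df = pd.DataFrame({"time_s": trace.times, "value": trace.values, "unit": trace.unit})
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_trace_csv(path: str | Path) -> TimeSeries:
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"empty or missing trace file: {path}")
    df = pd.read_csv(path)
    for col in ("time_s", "value"):
        if col not in df.columns:
            raise ValueError(f"trace CSV {path} lacks required column {col!r}")
    unit = str(df["unit"].iloc[0]) if "unit" in df.columns and len(df) else "a.u."
    return TimeSeries(df["time_s"].to_numpy(), df["value"].to_numpy(), unit)


def write_tiff_stack(stack: ThermalStack, path: str | Path) -> Path:
    """Multi-page 32-bit float TIFF plus sidecar times CSV and meta JSON."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32))
    times = pd.DataFrame({"frame_index": np.arange(stack.n_frames), "time_s": stack.times})
    times.to_csv(path.with_suffix(".times.csv"), index=False, float_format="%.17g")
    meta = {"pixel_size_mm": stack.pixel_size_mm, "unit": "degC"}
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2) + "\n")
    return path


def read_tiff_stack(path: str | Path) -> ThermalStack:
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"empty or missing TIFF stack: {path}")
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    times_path = path.with_suffix(".times.csv")
    meta_path = path.with_suffix(".meta.json")
    if not times_path.exists():
        raise ValueError(f"missing sidecar times CSV for {path}")
    times = pd.read_csv(times_path)["time_s"].to_numpy()
    pixel_size = 1.0
    if meta_path.exists():
        pixel_size = float(json.loads(meta_path.read_text())["pixel_size_mm"])
    return ThermalStack(frames, times, pixel_size)


def write_mtx(matrix: CountMatrix, out_dir: str | Path) -> Path:
    """MatrixMarket MTX with features.tsv / barcodes.tsv sidecars."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(out_dir / "matrix.mtx", sp.coo_matrix(matrix.matrix))
    (out_dir / "features.tsv").write_text("\n".join(matrix.genes) + "\n")
    (out_dir / "barcodes.tsv").write_text("\n".join(matrix.barcodes) + "\n")
    if matrix.cluster_labels is not None:
        (out_dir / "clusters.tsv").write_text(
            "\n".join(str(c) for c in matrix.cluster_labels) + "\n"
        )
    return out_dir


def read_mtx(in_dir: str | Path) -> CountMatrix:
    in_dir = Path(in_dir)
    mtx = in_dir / "matrix.mtx"
    if not mtx.exists():
        raise ValueError(f"missing matrix.mtx in {in_dir}")
    matrix = sp.csr_matrix(sio.mmread(mtx))
    genes = (in_dir / "features.tsv").read_text().splitlines()
    barcodes = (in_dir / "barcodes.tsv").read_text().splitlines()
    clusters_path = in_dir / "clusters.tsv"
    clusters = None
    if clusters_path.exists():
        clusters = np.array(clusters_path.read_text().splitlines())
    return CountMatrix(matrix, genes, barcodes, cluster_labels=clusters)


def write_schedule_csv(schedule: StimulusSchedule, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "onset_s": schedule.onsets,
            "offset_s": schedule.offsets,
            "pressure_mpa": schedule.pressures,
            "train_id": schedule.train_ids,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_schedule_csv(path: str | Path) -> StimulusSchedule:
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"empty or missing schedule CSV: {path}")
    df = pd.read_csv(path)
    if df.empty:
        return StimulusSchedule.empty()
    return StimulusSchedule(
        df["onset_s"].to_numpy(),
        df["offset_s"].to_numpy(),
        df["pressure_mpa"].to_numpy(),
        df["train_id"].to_numpy(),
    )


def save_roi_overlay(
    frame: np.ndarray,
    rois: list,
    path: str | Path,
    pixel_size_mm: float = 1.0,
    title: str | None = None,
) -> Path:
    """QC figure: a thermal frame with disk ROIs drawn on top (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(frame, cmap="inferno")
    fig.colorbar(im, ax=ax, label="temperature (degC)")
    for roi in rois:
        if roi is None:
            continue
        circ = plt.Circle(
            (roi.center[1], roi.center[0]),
            roi.radius_mm / pixel_size_mm,
            fill=False, color="cyan", lw=1.5,
        )
        ax.add_patch(circ)
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    stage: str,
    params: dict,
    inputs: list[str | Path],
    outputs: list[str | Path],
    seed: int | None,
) -> Path:
    """Run manifest: stage, parameters, seed, checksummed inputs/outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    manifest = {
        "stage": stage,
        "package_version": __version__,
        "seed": seed,
        "params": params,
        "inputs": {str(p): sha256_file(p) for p in inputs},
        "outputs": {str(p): sha256_file(p) for p in outputs},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
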