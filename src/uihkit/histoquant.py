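"""Threshold-based positivity quantification for FISH/IHC cell tables.

A cell is positive for a marker when its mean intensity strictly exceeds
the whole-brain background mean + 3 s.d.  Cell segmentation is out of
scope: the functions consume per-cell intensity tables (pandas DataFrames
with ``cell_id``, ``region`` and one column per channel).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import BackgroundStats

__all__ = [
    "background_stats",
    "call_positive",
    "region_fraction",
    "coexpression_fraction",
]


def background_stats(
    image: np.ndarray, brain_mask: np.ndarray, cell_mask: np.ndarray
) -> BackgroundStats:
    """Mean and sample s.d. over brain pixels excluding cell areas."""
    image = np.asarray(image, dtype=float)
    bg = np.asarray(brain_mask, dtype=bool) & ~np.asarray(cell_mask, dtype=bool)
    n = int(bg.sum())
    if n == 0:
        raise ValueError("empty background: brain mask minus cell mask has no pixels")
    vals = image[bg]
    sd = float(vals.std(ddof=1)) if n > 1 else 0.0
    return BackgroundStats(mean=float(vals.mean()), sd=sd, n_pixels=n)


def call_positive(cell_intensity, bg: BackgroundStats):
    """Positive iff intensity > mean + 3 s.d. (strict). Vectorised over arrays."""
    intensity = np.asarray(cell_intensity, dtype=float)
    if not np.all(np.isfinite(intensity)):
        raise ValueError("cell intensity must be finite")
    result = intensity > bg.threshold
    if np.isscalar(cell_intensity) or intensity.ndim == 0:
        return bool(result)
    return result


def region_fraction(
    cells: pd.DataFrame, channel: str, bg: BackgroundStats, region: str
) -> float | None:
    """Fraction of positive cells within one region; None for an empty region."""
    sub = cells.loc[cells["region"] == region, channel]
    if sub.empty:
        return None
    return float(call_positive(sub.to_numpy(), bg).mean())


def coexpression_fraction(
    cells: pd.DataFrame,
    channel_a: str,
    channel_b: str,
    bg_a: BackgroundStats,
    bg_b: BackgroundStats,
    denominator: str = "a",
) -> float | None:
    """Fraction of marker-A-positive cells that are also B-positive.

    ``denominator="a"`` (default) counts B-positives among A-positives;
    ``denominator="b"`` swaps the roles.  None when no cell is positive for
    the denominator marker.
    """
    pos_a = call_positive(cells[channel_a].to_numpy(), bg_a)
    pos_b = call_positive(cells[channel_b].to_numpy(), bg_b)
    if denominator == "b":
        pos_a, pos_b = pos_b, pos_a
    elif denominator != "a":
        raise ValueError("denominator must be 'a' or 'b'")
    n_denom = int(pos_a.sum())
    if n_denom == 0:
        return None
    return float((pos_a & pos_b).sum() / n_denom)
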