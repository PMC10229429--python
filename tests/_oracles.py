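"""Independent brute-force reference implementations.

Every function here recomputes a pipeline operation by plain loops over
the raw data, sharing no code path with the package implementation, so
that agreement on random instances is meaningful evidence of correctness.
"""

from __future__ import annotations

import math

import numpy as np


def roi_mean_bruteforce(frame, center, radius_mm, pixel_size_mm):
    """Mean over pixels whose centre is within radius, by full double loop."""
    total = 0.0
    n = 0
    h, w = frame.shape
    for r in range(h):
        for c in range(w):
            d = math.hypot(r - center[0], c - center[1]) * pixel_size_mm
            if d <= radius_mm:
                total += float(frame[r, c])
                n += 1
    if n == 0:
        return None
    return total / n


def max_delta_bruteforce(times, values, baseline, search, aggregation="min"):
    """Windowed extremum minus baseline mean with explicit sample loops."""
    base = [v for t, v in zip(times, values) if baseline[0] <= t < baseline[1]]
    win = [v for t, v in zip(times, values) if search[0] <= t < search[1]]
    if not base or not win:
        return None
    agg = min(win) if aggregation == "min" else max(win)
    return agg - math.fsum(base) / len(base)


def uih_onset_bruteforce(times, values, us_onset, b0, b1):
    """First post-onset crossing of baseline mean - 2 sample s.d., by scan."""
    base = [v for t, v in zip(times, values) if b0 <= t < b1]
    if len(base) < 2:
        return None
    mean = math.fsum(base) / len(base)
    var = math.fsum((v - mean) ** 2 for v in base) / (len(base) - 1)
    thr = mean - 2.0 * math.sqrt(var)
    for t, v in zip(times, values):
        if t >= us_onset and v < thr:
            return t
    return None


def peaks_bruteforce(values, min_prominence):
    """Strict local maxima with topographic prominence, exhaustively.

    Prominence of a peak: height minus the higher of the two bases, where
    each base is the minimum between the peak and the nearest strictly
    higher sample (or the trace end) on that side.
    """
    x = list(map(float, values))
    n = len(x)
    out = []
    for i in range(1, n - 1):
        if not (x[i - 1] < x[i] and x[i] > x[i + 1]):
            continue
        left_min = x[i]
        j = i - 1
        while j >= 0 and x[j] <= x[i]:
            left_min = min(left_min, x[j])
            j -= 1
        right_min = x[i]
        j = i + 1
        while j < n and x[j] <= x[i]:
            right_min = min(right_min, x[j])
            j += 1
        if x[i] - max(left_min, right_min) >= min_prominence:
            out.append(i)
    return out


def qc_keep_bruteforce(counts, genes, mito_max, features_min, features_max):
    """Per-cell QC decision on a dense genes x cells integer array."""
    n_genes, n_cells = counts.shape
    mito_rows = [i for i, g in enumerate(genes) if g.startswith("mt-")]
    keep = []
    for j in range(n_cells):
        col = counts[:, j]
        total = int(col.sum())
        mito = sum(int(col[i]) for i in mito_rows)
        frac = mito / total if total else 0.0
        nfeat = int((col > 0).sum())
        ok = frac <= mito_max and features_min <= nfeat <= features_max
        keep.append(ok)
    return keep


def top_features_bruteforce(norm_dense, genes, n, exclude):
    """Top-n genes by dispersion (var/mean, ddof=1) with exclusions, by loops."""
    n_genes, n_cells = norm_dense.shape
    excluded = set(exclude)
    scored = []
    for i in range(n_genes):
        if genes[i] in excluded:
            continue
        vals = [float(v) for v in norm_dense[i]]
        mean = math.fsum(vals) / n_cells
        if mean <= 0:
            disp = 0.0
        else:
            var = math.fsum((v - mean) ** 2 for v in vals) / (n_cells - 1)
            disp = var / mean
        scored.append((i, disp))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return [genes[i] for i, _ in scored[: min(n, len(scored))]]


def top_features_agree(got, norm_dense, genes, n, exclude):
    """True when ``got`` is a valid brute-force top-n selection.

    Exact agreement is required except among genes whose brute-force
    dispersions are *exactly* tied (math.fsum arithmetic), where any order
    is acceptable — mathematically tied dispersions have no defined order.
    """
    exp = top_features_bruteforce(norm_dense, genes, n, exclude)
    if got == exp:
        return True
    if len(got) != len(exp):
        return False
    # recompute exact dispersions for the tie check
    n_genes, n_cells = norm_dense.shape
    disp = {}
    for i in range(n_genes):
        vals = [float(v) for v in norm_dense[i]]
        mean = math.fsum(vals) / n_cells
        if mean <= 0:
            disp[genes[i]] = 0.0
        else:
            var = math.fsum((v - mean) ** 2 for v in vals) / (n_cells - 1)
            disp[genes[i]] = var / mean
    if sorted(disp[g] for g in got) != sorted(disp[g] for g in exp):
        return False
    d = [disp[g] for g in got]
    return all(a >= b for a, b in zip(d, d[1:])) and not set(got) & set(exclude)


def call_positive_bruteforce(intensities, bg_mean, bg_sd):
    return [float(v) > bg_mean + 3.0 * bg_sd for v in intensities]
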