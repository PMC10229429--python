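"""Rule-based single-nucleus RNA-seq processing on count matrices.

Implements the deterministic rule set applied to a preoptic-area neuronal
count matrix: QC filtering (mitochondrial fraction > 5%, unique feature
counts > 7,500 or < 200 removed), log-normalisation at scale 10,000,
top-variable-feature selection with immediate-early genes excluded,
k-means labelling of torpor-associated clusters on the Adcyap1/Qrfp/Esr1
marker profile, and ranking of torpor clusters by IEG expression to single
out the ultrasound-activated population.

Graph-based community detection is deliberately not reimplemented: cluster
labels are an input (here, the synthetic ground truth).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.cluster import KMeans

from .core import CountMatrix
from .synth import IEG_MARKERS, TORPOR_MARKERS

__all__ = [
    "QCThresholds",
    "qc_filter",
    "lognormalize",
    "load_ieg_list",
    "select_variable_features",
    "cluster_profiles",
    "torpor_kmeans",
    "ieg_activation_rank",
    "classify_excitatory_inhibitory",
]


@dataclass(frozen=True)
class QCThresholds:
    """Cell-level QC cutoffs.  Removal is strict (> / <): boundary cells kept."""

    mito_max: float = 0.05
    features_max: int = 7500
    features_min: int = 200

    def __post_init__(self) -> None:
        if not self.features_min < self.features_max:
            raise ValueError("features_min must be < features_max")


def qc_filter(m: CountMatrix, thr: QCThresholds = QCThresholds()) -> tuple[CountMatrix, dict]:
    """Drop cells failing mitochondrial or feature-count QC.

    A cell is removed when its mitochondrial count fraction exceeds
    ``mito_max`` (strictly), or its number of detected genes exceeds
    ``features_max`` or falls below ``features_min`` (strictly); cells
    exactly at a boundary are kept.  Returns the filtered matrix and a
    per-rule removal report.
    """
    mito = m.mito_fraction()
    nfeat = m.features_per_cell()
    bad_mito = mito > thr.mito_max
    bad_high = nfeat > thr.features_max
    bad_low = nfeat < thr.features_min
    keep = ~(bad_mito | bad_high | bad_low)
    report = {
        "n_input": m.n_cells,
        "removed_mito": int(bad_mito.sum()),
        "removed_features_high": int(bad_high.sum()),
        "removed_features_low": int(bad_low.sum()),
        "n_kept": int(keep.sum()),
    }
    if not keep.any():
        warnings.warn("all cells removed by QC", stacklevel=2)
    return m.subset_cells(keep), report


def lognormalize(m: CountMatrix, scale: float = 10_000.0) -> sp.csr_matrix:
    """LogNormalize: ln(1 + count / cell_total * scale), zeros preserved.

    Returns a sparse genes x cells float matrix.
    """
    totals = m.counts_per_cell().astype(float)
    if np.any(totals <= 0):
        raise ValueError("every cell must have a positive total count")
    out = m.matrix.tocsc(copy=True).astype(float)
    for j in range(out.shape[1]):
        sl = slice(out.indptr[j], out.indptr[j + 1])
        out.data[sl] = np.log1p(out.data[sl] / totals[j] * scale)
    return out.tocsr()


def load_ieg_list() -> list[str]:
    """The packaged 139-gene IEG exclusion list (synthetic stand-in; replaceable)."""
    text = resources.files("uihkit.data").joinpath("ieg_list_synthetic.tsv").read_text()
    genes = [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    return genes


def select_variable_features(
    normalized: sp.spmatrix,
    genes: list[str],
    n: int = 4000,
    exclude: list[str] | None = None,
) -> list[str]:
    """Top-``n`` genes by dispersion of normalised expression, after exclusions.

    Dispersion is variance / mean of the normalised values per gene (sample
    variance, n-1 denominator; genes with zero mean get dispersion 0).
    ``exclude`` (defaults to the packaged IEG list) never appears in the
    output.  Fewer than ``n`` candidates returns them all with a warning.
    """
    if exclude is None:
        exclude = load_ieg_list()
    excluded = set(exclude)
    X = sp.csr_matrix(normalized)
    n_cells = X.shape[1]
    if n_cells < 2:
        raise ValueError("need at least 2 cells")
    mean = np.asarray(X.mean(axis=1)).ravel()
    # two-pass centred variance (numerically stable; exact zeros contribute m^2)
    nnz_per_row = np.diff(X.indptr)
    centred = X.copy()
    centred.data = centred.data - np.repeat(mean, nnz_per_row)
    ss = np.asarray(centred.multiply(centred).sum(axis=1)).ravel()
    ss += (n_cells - nnz_per_row) * mean**2
    var = ss / (n_cells - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(mean > 0, var / mean, 0.0)
    candidates = [i for i, g in enumerate(genes) if g not in excluded]
    if len(candidates) < n:
        warnings.warn(
            f"only {len(candidates)} candidate genes for top-{n} selection; returning all",
            stacklevel=2,
        )
        n = len(candidates)
    # stable sort: descending dispersion, ties by gene order
    order = sorted(candidates, key=lambda i: (-dispersion[i], i))
    return [genes[i] for i in order[:n]]


def cluster_profiles(
    normalized: sp.spmatrix,
    genes: list[str],
    cluster_labels: np.ndarray,
    marker_genes: tuple[str, ...],
) -> pd.DataFrame:
    """Mean normalised expression of ``marker_genes`` per cluster.

    Returns a clusters x markers DataFrame indexed by cluster label
    (sorted), the common input to the labelling rules below.
    """
    cluster_labels = np.asarray(cluster_labels)
    X = sp.csr_matrix(normalized)
    gene_idx = {g: i for i, g in enumerate(genes)}
    missing = [g for g in marker_genes if g not in gene_idx]
    if missing:
        raise ValueError(f"marker genes missing from matrix: {missing}")
    clusters = sorted(set(cluster_labels.tolist()))
    rows = []
    for c in clusters:
        mask = cluster_labels == c
        sub = X[:, np.flatnonzero(mask)]
        rows.append([float(np.asarray(sub[gene_idx[g]].mean())) for g in marker_genes])
    return pd.DataFrame(rows, index=clusters, columns=list(marker_genes))


def torpor_kmeans(
    profiles: pd.DataFrame,
    k: int = 2,
    seed: int = 0,
    n_restarts: int = 10,
) -> set:
    """Torpor-associated cluster set from k-means on marker profiles.

    k-means (seeded, ``n_restarts`` initialisations) partitions the
    clusters' 3-D torpor-marker profiles; the component whose centroid has
    the highest mean marker expression is the torpor-associated set.
    ``profiles`` is typically ``cluster_profiles(..., TORPOR_MARKERS)``.
    """
    if k > len(profiles):
        raise ValueError(f"k={k} exceeds the number of clusters ({len(profiles)})")
    X = profiles.to_numpy(dtype=float)
    if np.allclose(X, X[0]):
        warnings.warn("all cluster profiles identical: degenerate single cluster", stacklevel=2)
        return set(profiles.index)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    assign = km.fit_predict(X)
    top = int(np.argmax(km.cluster_centers_.mean(axis=1)))
    return {profiles.index[i] for i in np.flatnonzero(assign == top)}


def ieg_activation_rank(profiles: pd.DataFrame, torpor_set: set) -> pd.DataFrame:
    """Rank torpor-associated clusters by IEG expression; top = activated.

    Each IEG column is z-scored across the torpor-set clusters (sample
    s.d.; a zero-variance gene contributes 0) and clusters are ordered by
    descending mean z.  Exact ties are broken by cluster id and flagged.
    Returns a DataFrame with ``ieg_score``, ``rank`` (1 = activated) and
    ``tied``.
    """
    if not torpor_set:
        raise ValueError("torpor_set must be non-empty")
    sub = profiles.loc[sorted(torpor_set)]
    X = sub.to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    z = np.where(sd > 0, (X - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    scores = z.mean(axis=1)
    out = pd.DataFrame({"ieg_score": scores}, index=sub.index)
    out = out.sort_values("ieg_score", ascending=False, kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    out["tied"] = out["ieg_score"].duplicated(keep=False)
    return out


def classify_excitatory_inhibitory(
    profiles: pd.DataFrame,
    threshold: float = 0.5,
    excitatory_marker: str = "Slc17a6",
    inhibitory_marker: str = "Gad1",
) -> dict:
    """Label clusters by vesicular transporter / GABA-synthesis markers.

    Mean normalised expression above ``threshold`` for one marker gives the
    corresponding label; both above gives ``hybrid``; neither gives
    ``unassigned``.
    """
    for g in (excitatory_marker, inhibitory_marker):
        if g not in profiles.columns:
            raise ValueError(f"marker {g!r} missing from profiles")
    labels = {}
    for c in profiles.index:
        exc = profiles.loc[c, excitatory_marker] > threshold
        inh = profiles.loc[c, inhibitory_marker] > threshold
        if exc and inh:
            labels[c] = "hybrid"
        elif exc:
            labels[c] = "excitatory"
        elif inh:
            labels[c] = "inhibitory"
        else:
            labels[c] = "unassigned"
    return labels
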