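"""Microarray-style preprocessing: low-signal filtering, log2 + quantile
normalization, duplicate-probe averaging and outlier-sample removal.

The low-signal rule keeps a feature only if its raw intensity exceeds the
per-array background mean plus two background standard deviations in at
least ``min_samples`` arrays (default 3).  Quantile normalization is the
classical rank-mean procedure: every array's sorted intensity vector is
replaced by the across-array mean at each rank, so all arrays end up with
identical empirical distributions; ties are broken by stable sort order,
which makes the procedure exactly idempotent.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .core import ExpressionMatrix
from .simulate import RawProbeTable

__all__ = [
    "flag_low_signal",
    "log_quantile_normalize",
    "quantile_normalize",
    "average_probe_replicates",
    "drop_samples",
    "preprocess_raw",
    "correlation_to_median",
]


def flag_low_signal(raw: RawProbeTable, min_samples: int = 3) -> list[str]:
    """Features to exclude: above background in fewer than ``min_samples`` arrays.

    A feature is kept iff intensity > bg_mean + 2*bg_sd in at least
    ``min_samples`` samples; the returned list holds the excluded probes.
    """
    if raw.background is None or raw.background.empty:
        raise ValueError("background statistics are required for low-signal filtering")
    missing = set(raw.intensities.columns) - set(raw.background.index)
    if missing:
        raise ValueError(f"background statistics missing for samples: {sorted(missing)}")
    bg = raw.background.loc[raw.intensities.columns]
    threshold = (bg["bg_mean"] + 2.0 * bg["bg_sd"]).to_numpy()
    above = (raw.intensities.to_numpy() > threshold[None, :]).sum(axis=1)
    return list(raw.intensities.index[above < min_samples])


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Classical quantile normalization on a features x samples frame."""
    arr = values.to_numpy(dtype=float)
    order = np.argsort(arr, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(arr, order, axis=0)
    if arr.shape[1] and np.all(sorted_vals == sorted_vals[:, [0]]):
        # all arrays already share one distribution: QN is the identity
        # (a recomputed rank mean could drift by one ulp)
        return values.copy()
    rank_means = sorted_vals.mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        out[order[:, j], j] = rank_means
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def log_quantile_normalize(
    raw: RawProbeTable,
    offset: float = 1.0,
    exclude: list[str] | None = None,
) -> pd.DataFrame:
    """log2(x + offset) followed by quantile normalization.

    ``offset`` guards against zero intensities; with offset 0, non-positive
    intensities raise.  ``exclude`` drops flagged features before
    normalization.  Returns a probe-level log2 frame.
    """
    values = raw.intensities
    if exclude:
        values = values.drop(index=exclude)
    arr = values.to_numpy(dtype=float) + offset
    if np.any(arr <= 0):
        raise ValueError(
            "non-positive intensities after offset; configure a positive offset"
        )
    logged = pd.DataFrame(np.log2(arr), index=values.index, columns=values.columns)
    return quantile_normalize(logged)


def average_probe_replicates(values: pd.DataFrame, probe_map: pd.Series) -> pd.DataFrame:
    """Collapse probe-level values to genes by arithmetic mean.

    Single-probe genes pass through unchanged.
    """
    missing = set(values.index) - set(probe_map.index)
    if missing:
        raise KeyError(f"probes without gene mapping: {sorted(missing)[:5]} ...")
    genes = probe_map.loc[values.index]
    out = values.groupby(genes.to_numpy()).mean()
    out.index.name = "gene"
    return out.sort_index()


def drop_samples(matrix: ExpressionMatrix, sample_ids: list[str]) -> ExpressionMatrix:
    """Remove listed samples (e.g. flagged outlier arrays)."""
    unknown = set(sample_ids) - set(matrix.sample_ids)
    if unknown:
        raise KeyError(f"cannot drop unknown samples: {sorted(unknown)}")
    keep = [s for s in matrix.sample_ids if s not in set(sample_ids)]
    return matrix.subset_samples(keep)


def correlation_to_median(matrix: ExpressionMatrix) -> pd.Series:
    """Per-sample Pearson correlation to the gene-wise median profile.

    Optional QC helper for spotting outlier arrays; removal itself is by
    explicit id list for reproducibility.
    """
    med = matrix.values.median(axis=1)
    return matrix.values.corrwith(med)


def preprocess_raw(
    raw: RawProbeTable,
    min_samples: int = 3,
    offset: float = 1.0,
    drop: list[str] | None = None,
) -> ExpressionMatrix:
    """Full preprocessing chain: filter, log2+QN, probe-average, drop outliers."""
    excluded_probes = flag_low_signal(raw, min_samples=min_samples)
    norm = log_quantile_normalize(raw, offset=offset, exclude=excluded_probes)
    gene_level = average_probe_replicates(norm, raw.probe_map)
    excluded = pd.DataFrame({"feature": excluded_probes, "reason": "low_signal"})
    matrix = ExpressionMatrix(values=gene_level, samples=raw.samples.copy(), excluded=excluded)
    if drop:
        matrix = drop_samples(matrix, drop)
    return matrix
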