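"""Spectral-count differential protein abundance and transcript-protein
integration.

Spectral counts are normalized by per-sample totals, summed over the
replicates of each strain at a time point, and compared as
log2((HP + c) / (WT + c)) with a symmetric pseudocount c.  A protein is
*eligible* for a fold change when at least one of its raw counts at the
time point exceeds 10; it is called differentially abundant when eligible
and |logFC| > 1.5.  Fold changes are restricted to the first two time
points by default (the late samples of a high-producer bioprocess suffer
proteolytic degradation); later time points require ``force=True``.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "spectral_logfc",
    "call_da",
    "spot_ratio_call",
    "transcript_protein_correlation",
    "group_average_logfc",
]

#: time points with trustworthy protein quantification
DEFAULT_QUANT_TIMES = ("t1", "t2")


def _samples_at(samples: pd.DataFrame, strain: str, time: str) -> list[str]:
    mask = (samples["strain"] == strain) & (samples["time"] == time)
    return list(samples.index[mask])


def spectral_logfc(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    time: str,
    pseudocount: float = 0.5,
    count_floor: int = 10,
    normalize: bool = True,
) -> pd.DataFrame:
    """Per-protein HP/WT log2 ratio and eligibility at one time point.

    ``counts`` is proteins x samples (raw spectral counts).  Totals
    normalization rescales each sample to the mean library size before the
    ratio; eligibility (strictly > ``count_floor`` in at least one sample
    of either strain) is evaluated on raw counts.  Proteins with zero raw
    counts in both strains are dropped.
    """
    hp_ids = _samples_at(samples, "HP", time)
    wt_ids = _samples_at(samples, "WT", time)
    if not hp_ids or not wt_ids:
        raise ValueError(f"no samples for one of the strains at {time}")

    raw = counts[hp_ids + wt_ids]
    present = raw.sum(axis=1) > 0
    raw = raw[present]

    if normalize:
        totals = counts.sum(axis=0)
        scale = totals.mean() / totals.replace(0, np.nan)
        norm = raw * scale[raw.columns]
    else:
        norm = raw.astype(float)

    c_hp = norm[hp_ids].sum(axis=1)
    c_wt = norm[wt_ids].sum(axis=1)
    logfc = np.log2((c_hp + pseudocount) / (c_wt + pseudocount))
    eligible = raw.max(axis=1) > count_floor
    return pd.DataFrame(
        {"time": time, "logfc": logfc, "eligible": eligible,
         "count_HP": raw[hp_ids].sum(axis=1), "count_WT": raw[wt_ids].sum(axis=1)}
    ).rename_axis("protein")


def call_da(
    results: pd.DataFrame,
    cut: float = 1.5,
    allowed_times: tuple[str, ...] = DEFAULT_QUANT_TIMES,
    force: bool = False,
) -> pd.DataFrame:
    """Differential-abundance flags: eligible and |logFC| > cut.

    Time points outside ``allowed_times`` are refused unless ``force``
    (protein quantification is unreliable there).
    """
    bad = set(results["time"]) - set(allowed_times)
    if bad and not force:
        raise ValueError(
            f"differential abundance not computed at {sorted(bad)}; pass force=True to override"
        )
    out = results.copy()
    out["da"] = out["eligible"] & (out["logfc"].abs() > cut)
    out["direction"] = np.where(out["logfc"] > 0, "up", "down")
    return out


def spot_ratio_call(
    volumes_hp: pd.DataFrame,
    volumes_wt: pd.DataFrame,
    fold: float = 1.5,
    p_cut: float = 0.05,
) -> pd.DataFrame:
    """Two-dimensional gel spot calls on normalized volumes.

    Inputs are spots x replicate gels of raw spot volumes per strain.
    Volumes are normalized by each gel's total volume; a spot is called
    when the mean normalized HP/WT ratio differs from unity by more than
    ``fold`` (either direction) and a two-sample t-test across gels has
    p < ``p_cut``.
    """
    nh = volumes_hp / volumes_hp.sum(axis=0)
    nw = volumes_wt / volumes_wt.sum(axis=0)
    common = nh.index.intersection(nw.index)
    nh, nw = nh.loc[common], nw.loc[common]
    ratio = nh.mean(axis=1) / nw.mean(axis=1)
    t_p = np.full(len(common), np.nan)
    for i, spot in enumerate(common):
        a, b = nh.loc[spot].to_numpy(), nw.loc[spot].to_numpy()
        if np.allclose(a.std(), 0) and np.allclose(b.std(), 0) and np.allclose(a.mean(), b.mean()):
            t_p[i] = 1.0
        else:
            t_p[i] = stats.ttest_ind(a, b).pvalue
    called = ((ratio > fold) | (ratio < 1.0 / fold)) & (t_p < p_cut)
    return pd.DataFrame(
        {"ratio": ratio, "p": t_p, "called": called}, index=common
    ).rename_axis("spot")


def transcript_protein_correlation(
    de_table: pd.DataFrame,
    protein_results: pd.DataFrame,
    time: str,
) -> tuple[float, int]:
    """Pearson r between gene and protein log fold changes at one time point.

    Pairing is by gene id (proteins carry their gene's id); only proteins
    eligible at the time point enter.  Returns (r, number of matched pairs).
    """
    de_t = de_table[de_table["time"] == time].set_index("gene")["logfc"]
    prot = protein_results[(protein_results["time"] == time) & protein_results["eligible"]]
    common = prot.index.intersection(de_t.index)
    if len(common) < 3:
        raise ValueError(f"fewer than 3 matched transcript-protein pairs at {time}")
    r = float(np.corrcoef(de_t.loc[common], prot.loc[common, "logfc"])[0, 1])
    return r, len(common)


def group_average_logfc(
    results: pd.DataFrame,
    groups: pd.Series,
    min_size: int = 3,
) -> pd.DataFrame:
    """Functional-group mean logFC per time point.

    ``groups`` maps protein/gene id -> functional group label.  Returns a
    group x time matrix plus a ``small_group`` flag column for groups
    below ``min_size``.
    """
    df = results.copy()
    df["group"] = groups.reindex(df.index)
    df = df.dropna(subset=["group"])
    mat = df.pivot_table(index="group", columns="time", values="logfc", aggfunc="mean")
    id_col = df.index.name or "id"
    sizes = df.reset_index().groupby("group")[id_col].nunique()
    mat["small_group"] = sizes.reindex(mat.index) < min_size
    return mat
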