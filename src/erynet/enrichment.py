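"""Gene-set enrichment: Signal2Noise ranking, weighted Kolmogorov-Smirnov
enrichment score, gene-set permutation null and signed significance calls.

The ranking metric for HP vs WT at a time point is

    S2N_g = (mu_HP - mu_WT) / (sd_HP + sd_WT)

with the customary standard-deviation floors (sd is raised to 0.2*|mu| of
its group, and to 0.2 when the group mean is zero) so that near-constant
genes cannot dominate the ranking.  The enrichment score is the signed
maximum deviation of a running sum that increments by |metric|^p / N_R at
member genes and decrements by 1/(N - N_hit) elsewhere.  Significance is
assessed against random same-size gene sets ("gene_set" permutation), with
add-one smoothing and sign-conditional counting.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .core import ExpressionMatrix

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "SIZE_BOUNDS",
    "SIGNIFICANCE_CUTOFFS",
    "signal2noise_ranking",
    "enrichment_score",
    "gene_set_permutation_p",
    "filter_sets_by_size",
    "run_enrichment",
    "summarize_directions",
]

#: inclusive size bounds per ontology after filtering
SIZE_BOUNDS = {"KEGG": (8, 400), "GO": (15, 500)}

#: nominal-p significance cut-offs per ontology
SIGNIFICANCE_CUTOFFS = {"KEGG": 0.01, "GO": 0.05}


@dataclass(frozen=True)
class GeneSet:
    name: str
    ontology: str
    genes: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.genes)


class GeneSetCollection:
    """An ordered collection of named gene sets."""

    def __init__(self, sets: Sequence[GeneSet]):
        names = [s.name for s in sets]
        if len(names) != len(set(names)):
            raise ValueError("duplicate gene-set names")
        self.sets = list(sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)


def filter_sets_by_size(
    collection: GeneSetCollection,
    bounds: dict[str, tuple[int, int]] | None = None,
) -> GeneSetCollection:
    """Drop sets outside their ontology's size bounds (bounds inclusive)."""
    bounds = bounds or SIZE_BOUNDS
    kept = []
    for s in collection:
        lo, hi = bounds.get(s.ontology, (1, np.inf))
        if lo <= s.size <= hi:
            kept.append(s)
    return GeneSetCollection(kept)


def signal2noise_ranking(
    matrix: ExpressionMatrix,
    time: str,
    sd_floor_frac: float = 0.2,
    sd_floor_abs: float = 0.2,
) -> pd.Series:
    """Genes ranked (descending) by the Signal2Noise metric at one time point.

    Ties in the metric are broken by gene id for determinism.
    """
    hp = matrix.group_values("HP", time)
    wt = matrix.group_values("WT", time)
    if hp.shape[1] < 2 or wt.shape[1] < 2:
        raise ValueError("Signal2Noise needs >=2 samples per group")

    def floored_sd(frame: pd.DataFrame) -> np.ndarray:
        mu = frame.mean(axis=1).to_numpy()
        sd = frame.std(axis=1, ddof=1).to_numpy()
        floor = np.where(mu == 0.0, sd_floor_abs, sd_floor_frac * np.abs(mu))
        return np.maximum(sd, floor), mu

    sd_hp, mu_hp = floored_sd(hp)
    sd_wt, mu_wt = floored_sd(wt)
    metric = (mu_hp - mu_wt) / (sd_hp + sd_wt)
    s = pd.Series(metric, index=matrix.genes, name="s2n")
    order = sorted(s.index, key=lambda g: (-s[g], g))
    return s.loc[order]


def enrichment_score(ranked: pd.Series, gene_set: Iterable[str], weight: float = 1.0) -> float:
    """Weighted-KS enrichment score on a ranked metric series.

    ``ranked`` must be sorted descending by metric.  weight=0 reduces to
    the classical unweighted KS statistic.
    """
    members = set(gene_set)
    hit = np.fromiter((g in members for g in ranked.index), dtype=bool, count=len(ranked))
    n = len(ranked)
    n_hit = int(hit.sum())
    if n_hit == 0 or n_hit == n:
        # degenerate: empty misses give a running sum that climbs to exactly 1
        return 1.0 if n_hit == n else 0.0
    w = np.abs(ranked.to_numpy()) ** weight
    n_r = w[hit].sum()
    steps = np.where(hit, (w / n_r) if n_r > 0 else 0.0, -1.0 / (n - n_hit))
    if n_r == 0:
        # all member metrics are zero: fall back to equal hit increments
        steps = np.where(hit, 1.0 / n_hit, -1.0 / (n - n_hit))
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def gene_set_permutation_p(
    ranked: pd.Series,
    gene_set: Iterable[str],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> tuple[float, float]:
    """Nominal p for a set's ES against random same-size sets.

    p = (1 + #{null of same sign with |ES_null| >= |ES_obs|})
        / (1 + #{null of same sign}),  deterministic under ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    members = [g for g in gene_set if g in set(ranked.index)]
    es_obs = enrichment_score(ranked, members, weight=weight)
    rng = np.random.default_rng(seed)
    size = len(members)
    genes = np.asarray(ranked.index)
    null = np.empty(n_perm)
    for k in range(n_perm):
        draw = rng.choice(genes, size=size, replace=False)
        null[k] = enrichment_score(ranked, draw, weight=weight)
    same_sign = null * es_obs >= 0 if es_obs != 0 else np.ones_like(null, dtype=bool)
    extreme = same_sign & (np.abs(null) >= abs(es_obs))
    p = (1.0 + extreme.sum()) / (1.0 + same_sign.sum())
    return es_obs, float(p)


def run_enrichment(
    matrix: ExpressionMatrix,
    collection: GeneSetCollection,
    times: list[str] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    apply_size_filter: bool = True,
) -> pd.DataFrame:
    """ES and nominal p for every set at every time point."""
    if apply_size_filter:
        collection = filter_sets_by_size(collection)
    times = times if times is not None else matrix.times()
    rows = []
    for ti, t in enumerate(times):
        ranked = signal2noise_ranking(matrix, t)
        for i, gene_set in enumerate(collection):
            # distinct deterministic stream per (time, set)
            sub_seed = np.random.SeedSequence([seed, ti, i]).generate_state(1)[0] % 2**31
            es, p = gene_set_permutation_p(
                ranked, gene_set.genes, n_perm=n_perm, seed=int(sub_seed), weight=weight,
            )
            rows.append(
                {
                    "set": gene_set.name,
                    "ontology": gene_set.ontology,
                    "size": gene_set.size,
                    "time": t,
                    "es": es,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)


def summarize_directions(
    results: pd.DataFrame,
    cutoffs: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Signed significance table: '+' / '-' per set per time point.

    '+' where the set is significantly enriched with positive ES at its
    ontology's cut-off, '-' for negative ES, blank otherwise.
    """
    cutoffs = cutoffs or SIGNIFICANCE_CUTOFFS
    times = list(dict.fromkeys(results["time"]))
    table = pd.DataFrame("", index=list(dict.fromkeys(results["set"])), columns=times)
    for _, row in results.iterrows():
        cut = cutoffs.get(row["ontology"], 0.05)
        if row["p"] < cut and row["es"] != 0:
            table.loc[row["set"], row["time"]] = "+" if row["es"] > 0 else "-"
    table.index.name = "set"
    return table
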