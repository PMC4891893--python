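"""Context-specific differential co-expression analysis.

This is the analytical core of the package.  Three gene-gene Pearson
correlation matrices are computed — one on all samples pooled (ALL), one
on wild-type samples only (WT) and one on high-producer samples only
(HP).  Significance of an observed correlation is assessed against a
*reshuffling* permutation null: in each permutation round every gene's
sample vector is independently reshuffled and the correlation matrix is
recomputed, which destroys all gene-gene association while preserving each
gene's marginal expression distribution.  Off-diagonal values of the
permuted matrices are pooled into one empirical null (all pairs are
exchangeable under full reshuffling), giving a two-sided empirical p-value
per pair with add-one smoothing; Benjamini-Hochberg q-values are computed
on top.

Per-gene anchor scores drive the network views:

* ``ery_score``  — sum of squared correlations to all members of the
  anchor (erythromycin-cluster-like) gene set;
* ``mut_score``  — maximum squared correlation to any mutated gene;

both computed per context and combined with top-fraction filters and a
maintained / perturbed / global edge classification to build the four
network views (maintained edges anchored on mutated genes; global edges
among anchor-correlated, strongly-changed genes; perturbed edges; and
anchor-vs-regulator edges).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx


from .core import CONTEXTS, ExpressionMatrix

__all__ = [
    "CorrelationContext",
    "correlation_matrices",
    "permutation_null",
    "attach_permutation_null",
    "corr_pvalues",
    "bh_qvalues",
    "anchor_scores",
    "top_fraction_filter",
    "classify_edge",
    "classify_edges",
    "build_network",
    "NetworkConfig",
]


# ---------------------------------------------------------------------------
# correlation contexts
# ---------------------------------------------------------------------------

@dataclass
class CorrelationContext:
    """One context's Pearson matrix with its permutation-null machinery."""

    label: str
    genes: pd.Index
    r: np.ndarray                      # (G, G), NaN rows/cols for invalid genes
    sample_ids: list[str]
    valid: np.ndarray                  # bool per gene (non-zero variance)
    null_abs_sorted: np.ndarray | None = None  # sorted |r| permutation null

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def r_of(self, gene1: str, gene2: str) -> float:
        i, j = self.genes.get_loc(gene1), self.genes.get_loc(gene2)
        return float(self.r[i, j])

    def pvalues(self, r_values: np.ndarray | float) -> np.ndarray | float:
        """Two-sided empirical p for given correlation values."""
        if self.null_abs_sorted is None:
            raise ValueError(f"context {self.label}: permutation null not attached")
        return corr_pvalues(r_values, self.null_abs_sorted)


def _pearson_matrix(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Correlation matrix with zero-variance genes masked to NaN."""
    sd = values.std(axis=1)
    valid = sd > 0
    r = np.full((values.shape[0],) * 2, np.nan)
    if valid.sum() >= 2:
        sub = np.corrcoef(values[valid])
        r[np.ix_(valid, valid)] = sub
    r[np.diag_indices_from(r)] = np.where(valid, 1.0, np.nan)
    return r, valid


def correlation_matrices(
    matrix: ExpressionMatrix,
    contexts: tuple[str, ...] = CONTEXTS,
) -> dict[str, CorrelationContext]:
    """Pearson matrices for the requested contexts (ALL / WT / HP)."""
    out = {}
    for label in contexts:
        ids = matrix.context_samples(label)
        if len(ids) < 3:
            raise ValueError(f"context {label}: fewer than 3 samples")
        values = matrix.values[ids].to_numpy()
        r, valid = _pearson_matrix(values)
        out[label] = CorrelationContext(
            label=label, genes=matrix.genes, r=r, sample_ids=ids, valid=valid
        )
    return out


def permutation_null(
    values: np.ndarray,
    n_perm: int,
    seed: int,
    max_values_per_round: int | None = 100_000,
) -> np.ndarray:
    """Empirical null of Pearson r under independent per-gene reshuffling.

    Each round independently permutes every gene's sample vector and
    recomputes the full correlation matrix; off-diagonal values are pooled
    across rounds.  For large gene counts a uniform subsample of
    ``max_values_per_round`` off-diagonal values per round is retained
    (the pooled null is identically distributed either way).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    values = np.asarray(values, dtype=float)
    sd = values.std(axis=1)
    values = values[sd > 0]  # constant genes are excluded before permutation
    g = values.shape[0]
    if g < 2:
        raise ValueError("need at least two non-constant genes")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(g, k=1)
    n_pairs = iu[0].size
    chunks = []
    for _ in range(n_perm):
        shuffled = rng.permuted(values, axis=1)
        r = np.corrcoef(shuffled)[iu]
        if max_values_per_round is not None and n_pairs > max_values_per_round:
            r = rng.choice(r, size=max_values_per_round, replace=False)
        chunks.append(r)
    return np.concatenate(chunks)


def attach_permutation_null(
    contexts: dict[str, CorrelationContext],
    matrix: ExpressionMatrix,
    n_perm: int = 200,
    seed: int = 0,
    max_values_per_round: int | None = 100_000,
) -> dict[str, CorrelationContext]:
    """Compute and attach the reshuffling null to each context (in place)."""
    for k, (label, ctx) in enumerate(contexts.items()):
        values = matrix.values[ctx.sample_ids].to_numpy()
        sub_seed = int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % 2**31)
        null = permutation_null(values, n_perm, sub_seed, max_values_per_round)
        ctx.null_abs_sorted = np.sort(np.abs(null))
    return contexts


def corr_pvalues(r_values: np.ndarray | float, null_abs_sorted: np.ndarray) -> np.ndarray | float:
    """Two-sided empirical p with add-one smoothing.

    p = (1 + #{|r_null| >= |r_obs|}) / (1 + N_null); NaN observations give
    NaN p.
    """
    scalar = np.isscalar(r_values)
    r = np.atleast_1d(np.asarray(r_values, dtype=float))
    n = null_abs_sorted.size
    ge = n - np.searchsorted(null_abs_sorted, np.abs(r), side="left")
    p = (1.0 + ge) / (1.0 + n)
    p = np.where(np.isnan(r), np.nan, p)
    return float(p[0]) if scalar else p


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, NaN passthrough).

    q_(i) = min_{j >= i} min(1, p_(j) * n / j) on the sorted p-values,
    computed with the textbook operation order so the result is bit-exact
    against a scalar step-up implementation.
    """
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    n = int(ok.sum())
    if n:
        vals = p[ok]
        order = np.argsort(vals, kind="stable")
        ranks = np.arange(1, n + 1, dtype=float)
        stepped = vals[order] * n / ranks
        monotone = np.minimum(np.minimum.accumulate(stepped[::-1])[::-1], 1.0)
        out = np.empty(n)
        out[order] = monotone
        q[ok] = out
    return q


# ---------------------------------------------------------------------------
# anchor scores and filters
# ---------------------------------------------------------------------------

def anchor_scores(
    ctx: CorrelationContext,
    ery_members: list[str],
    mutated_genes: list[str],
) -> pd.DataFrame:
    """Per-gene anchor scores in one context.

    ery_score = sum of r^2 to the anchor-set members; mut_score = max r^2
    to any mutated gene.  Self-pairs are excluded; undefined correlations
    contribute 0.
    """
    genes = ctx.genes
    ery_idx = [genes.get_loc(g) for g in ery_members if g in genes]
    mut_idx = [genes.get_loc(g) for g in mutated_genes if g in genes]
    r2 = ctx.r**2
    n_undef = int(np.isnan(ctx.r[np.triu_indices_from(ctx.r, k=1)]).sum())
    if n_undef:
        import warnings

        warnings.warn(
            f"context {ctx.label}: {n_undef} undefined correlations contribute 0 to scores"
        )
    r2 = np.nan_to_num(r2, nan=0.0)

    def score_block(cols: list[int], reducer) -> np.ndarray:
        if not cols:
            return np.zeros(len(genes))
        block = r2[:, cols].copy()
        for j, c in enumerate(cols):  # exclude self-correlation
            block[c, j] = 0.0
        return reducer(block)

    ery_score = score_block(ery_idx, lambda b: b.sum(axis=1))
    mut_score = score_block(mut_idx, lambda b: b.max(axis=1) if b.shape[1] else np.zeros(len(genes)))
    # p-value of the best mutated-gene correlation (for the network node filters)
    mut_p = np.full(len(genes), np.nan)
    if mut_idx and ctx.null_abs_sorted is not None:
        best_r = np.sqrt(score_block(mut_idx, lambda b: b.max(axis=1)))
        mut_p = corr_pvalues(best_r, ctx.null_abs_sorted)
    return pd.DataFrame(
        {"ery_score": ery_score, "mut_score": mut_score, "mut_p": mut_p},
        index=genes,
    )


def top_fraction_filter(scores: pd.Series, fraction: float) -> pd.Index:
    """Genes in the top ``fraction`` of the score, boundary ties included."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    s = scores.dropna()
    k = max(1, int(np.ceil(fraction * len(s))))
    threshold = s.sort_values(ascending=False).iloc[k - 1]
    return s.index[s >= threshold]


# ---------------------------------------------------------------------------
# edge classification
# ---------------------------------------------------------------------------

def classify_edge(
    r_wt: float,
    p_wt: float,
    r_hp: float,
    p_hp: float,
    p_all: float | None = None,
    tau_strong: float = 0.005,
    tau_weak: float = 0.05,
) -> str:
    """Classify one gene pair as maintained / perturbed / global / none.

    maintained: strong (p <= tau_strong) in both strain contexts with the
    same correlation sign; perturbed: strong in WT but weak (p > tau_weak)
    or sign-flipped in HP; global: strong in the pooled context.  Missing
    correlations yield "none".  Symmetric in the pair by construction.
    """
    def ok(x):
        return x is not None and np.isfinite(x)

    if ok(p_wt) and ok(p_hp) and p_wt <= tau_strong and p_hp <= tau_strong and (
        np.sign(r_wt) == np.sign(r_hp)
    ):
        return "maintained"
    if ok(p_wt) and p_wt <= tau_strong and (
        (not ok(p_hp)) or p_hp > tau_weak or np.sign(r_wt) != np.sign(r_hp)
    ):
        return "perturbed"
    if ok(p_all) and p_all <= tau_strong:
        return "global"
    return "none"


def classify_edges(
    contexts: dict[str, CorrelationContext],
    genes: list[str],
    tau_strong: float = 0.005,
    tau_weak: float = 0.05,
) -> pd.DataFrame:
    """Edge records with per-context r, p and class for all pairs of ``genes``."""
    for label in ("WT", "HP"):
        if label not in contexts:
            raise ValueError(f"context {label} required for edge classification")
    idx = [contexts["WT"].genes.get_loc(g) for g in genes]
    rows = []
    for a in range(len(genes)):
        for b in range(a + 1, len(genes)):
            i, j = idx[a], idx[b]
            rec = {"gene1": genes[a], "gene2": genes[b]}
            for label, ctx in contexts.items():
                r = ctx.r[i, j]
                rec[f"r_{label}"] = r
                rec[f"p_{label}"] = ctx.pvalues(r) if ctx.null_abs_sorted is not None else np.nan
            rec["class"] = classify_edge(
                rec.get("r_WT"), rec.get("p_WT"),
                rec.get("r_HP"), rec.get("p_HP"),
                rec.get("p_ALL"),
                tau_strong=tau_strong, tau_weak=tau_weak,
            )
            rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

@dataclass
class NetworkConfig:
    """Thresholds for the four network views.

    The node p cut-offs and top fractions default to the stringent values
    used for the published network figures; ``tau_strong`` is the
    individual-edge significance cut.
    """

    tau_strong: float = 0.005
    tau_weak: float = 0.05
    mut_p_maintained: float = 0.00017   # node filter, maintained view
    mut_p_perturbed: float = 0.00016    # node filter, perturbed view
    ery_top_fraction: float = 0.06      # global view, anchor-correlation filter
    change_top_fraction: float = 0.037  # global/perturbed views, expression change


def build_network(
    mode: str,
    contexts: dict[str, CorrelationContext],
    ery_members: list[str],
    mutated_genes: list[str],
    change_score: pd.Series | None = None,
    regulator_genes: list[str] | None = None,
    config: NetworkConfig | None = None,
) -> nx.Graph:
    """Build one of the four network views.

    * ``maintained_mutation`` — maintained edges among genes whose best WT
      correlation to a mutated gene beats the node cut-off;
    * ``global_anchor`` — pooled-context edges among genes in the top
      fraction by anchor score and by expression change;
    * ``perturbed_mutation`` — perturbed edges among strongly-changed genes
      anchored on mutated genes in WT;
    * ``anchor_regulators`` — maintained edges between the anchor set and a
      regulator gene list (positive edges: candidate activators, negative:
      candidate repressors).

    Aliases fig3a/fig3b/fig3c/fig3d are accepted.
    """
    cfg = config or NetworkConfig()
    aliases = {
        "fig3a": "maintained_mutation",
        "fig3b": "global_anchor",
        "fig3c": "perturbed_mutation",
        "fig3d": "anchor_regulators",
    }
    mode = aliases.get(mode, mode)

    if mode in ("maintained_mutation", "perturbed_mutation"):
        scores_wt = anchor_scores(contexts["WT"], ery_members, mutated_genes)
        cut = cfg.mut_p_maintained if mode == "maintained_mutation" else cfg.mut_p_perturbed
        nodes = set(scores_wt.index[scores_wt["mut_p"] < cut])
        if mode == "perturbed_mutation":
            if change_score is None:
                raise ValueError("perturbed view needs a change score")
            nodes &= set(top_fraction_filter(change_score, cfg.change_top_fraction))
        wanted = "maintained" if mode == "maintained_mutation" else "perturbed"
    elif mode == "global_anchor":
        if change_score is None:
            raise ValueError("global view needs a change score")
        scores_all = anchor_scores(contexts["ALL"], ery_members, mutated_genes)
        nodes = set(top_fraction_filter(scores_all["ery_score"], cfg.ery_top_fraction))
        nodes &= set(top_fraction_filter(change_score, cfg.change_top_fraction))
        wanted = "global"
    elif mode == "anchor_regulators":
        if regulator_genes is None:
            raise ValueError("regulator view needs a regulator gene list")
        nodes = set(ery_members) | set(regulator_genes)
        wanted = "maintained"
    else:
        raise ValueError(f"unknown network mode {mode!r}")

    graph = nx.Graph(mode=mode)
    node_list = sorted(nodes)
    graph.add_nodes_from(node_list)
    if len(node_list) < 2:
        return graph

    edges = classify_edges(contexts, node_list, cfg.tau_strong, cfg.tau_weak)
    if mode == "anchor_regulators":
        # only cross edges between the anchor set and the regulators
        ery = set(ery_members)
        cross = edges["gene1"].isin(ery) != edges["gene2"].isin(ery)
        edges = edges[cross]
    for _, e in edges[edges["class"] == wanted].iterrows():
        graph.add_edge(
            e["gene1"], e["gene2"],
            r_WT=float(e.get("r_WT", np.nan)),
            r_HP=float(e.get("r_HP", np.nan)),
            r_ALL=float(e.get("r_ALL", np.nan)),
            edge_class=e["class"],
        )
    return graph
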