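"""Synthetic multi-omics generator emulating a two-strain bioprocess study.

The generator produces a gene-level expression matrix for a wild-type (WT)
and a high-producer (HP) strain sampled at four bioprocess time points with
three biological replicates each, together with a ground-truth ledger.  The
statistical backbone is a one-factor latent model per co-expression module:

    x[g, s] = mu_g + a_g * (profile_m(strain(s), time(s)) + z_m(s))
              + delta[g, s] + eps[g, s]

with a shared latent factor score ``z_m(s) ~ N(0, latent_sd^2)`` per module
and sample, gene loading ``a_g`` (strain-specific), a deterministic
strain/time latent profile, planted differential-expression shifts
``delta`` and gene-wise Gaussian noise ``eps``.  Because the model is
linear-Gaussian the expected pairwise Pearson correlation of two module
genes has the closed form  a1*a2*V / sqrt((a1^2 V + s1^2)(a2^2 V + s2^2))
where V is the latent variance (factor plus profile) within the sample
context — which makes every downstream recovery test checkable.

Module classes mirror the co-expression behaviours seen in high-producer
strain comparisons: an *anchor* module (erythromycin-biosynthesis-like
cluster, overexpressed and prolonged in HP), a *maintained* feeder module
riding the same factor in both strains (precursor-supply-like), a
*perturbed* module strongly co-expressed in WT but decorrelated and
downregulated in HP (pks2/pks8-like), and an *hp_gained* module weakly
coupled to the anchor in WT but strongly co-overexpressed with it in HP
(pks6-like).

A spectral-count proteome is linked stochastically to the transcriptome
(negative-binomial counts whose log-mean tracks log2 expression, with
gene-by-strain noise calibrated so the transcript-protein log-fold-change
correlation hits a target value), and per-strain variant tables with known
shared/unique/reference-error structure complete the fixture set.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import STRAINS, TIME_POINTS, ExpressionMatrix, make_sample_table

__all__ = [
    "ModuleSpec",
    "DEEffect",
    "SimConfig",
    "PlantedTruth",
    "RawProbeTable",
    "default_modules",
    "default_config",
    "simulate_expression",
    "simulate_raw_probes",
    "simulate_proteome",
    "simulate_variants",
    "make_gene_sets",
    "make_annotation",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModuleSpec:
    """A planted co-expression module.

    ``wt_profile`` / ``hp_profile`` give the deterministic latent-factor
    level at each time point (log2 units, before the gene loading is
    applied).  ``factor`` names the shared latent factor; modules that name
    the same factor are correlated with each other (e.g. a feeder module
    tracking the anchor cluster).  ``hp_shift`` is an additive expression
    offset applied to all HP samples of the module's genes (planted
    up-/down-regulation independent of the correlation structure).
    """

    name: str
    size: int
    kind: str  # anchor | maintained | perturbed | hp_gained
    wt_loading: float = 1.0
    hp_loading: float = 1.0
    wt_profile: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0)
    hp_profile: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0)
    factor: str | None = None  # defaults to own name
    hp_shift: float = 0.0

    @property
    def factor_name(self) -> str:
        return self.factor or self.name

    def loading(self, strain: str) -> float:
        return self.wt_loading if strain == "WT" else self.hp_loading

    def profile(self, strain: str) -> tuple[float, ...]:
        return self.wt_profile if strain == "WT" else self.hp_profile


@dataclass(frozen=True)
class DEEffect:
    """A planted differential shift for one gene at one (strain, time)."""

    gene: str
    time: str
    strain: str
    delta: float


def default_modules() -> tuple[ModuleSpec, ...]:
    """The four study-design module classes with their default geometry.

    Profile amplitudes are chosen so that within-module correlations are
    strong (r ~ 0.93 in the 10-12 samples of a single-strain context),
    matching the "strong correlation" regime the network filters target.
    """
    return (
        # erythromycin-cluster-like anchor: expression ramps up over the
        # bioprocess, earlier/stronger and prolonged in HP
        ModuleSpec(
            name="ery",
            size=20,
            kind="anchor",
            wt_profile=(0.0, 2.0, 4.0, 4.0),
            hp_profile=(0.0, 3.0, 5.0, 5.0),
        ),
        # precursor-feeder module: same latent factor as the anchor in both
        # strains (maintained correlation)
        ModuleSpec(
            name="feeder",
            size=30,
            kind="maintained",
            factor="ery",
            wt_profile=(0.0, 2.0, 4.0, 4.0),
            hp_profile=(0.0, 3.0, 5.0, 5.0),
        ),
        # pks2/pks8-like module: own factor, strongly co-expressed in WT,
        # silent (loading 0) and downregulated in HP
        ModuleSpec(
            name="pks_wt",
            size=30,
            kind="perturbed",
            hp_loading=0.0,
            wt_profile=(0.0, 3.0, 5.0, 3.0),
            hp_profile=(0.0, 0.0, 0.0, 0.0),
            hp_shift=-2.0,
        ),
        # pks6-like module: weakly coupled to the anchor factor in WT,
        # strongly co-overexpressed with it in HP
        ModuleSpec(
            name="pks_hp",
            size=20,
            kind="hp_gained",
            factor="ery",
            wt_loading=0.3,
            hp_loading=1.2,
            wt_profile=(0.0, 2.0, 4.0, 4.0),
            hp_profile=(0.0, 3.0, 5.0, 5.0),
            hp_shift=2.0,
        ),
    )


def _default_de_effects(n_up: int = 120, n_down: int = 80) -> tuple[DEEffect, ...]:
    # planted per-time-point shifts on background genes (outside modules);
    # |delta| = 2 at t2 so the DE caller is evaluated on clean 3v3 groups
    effects = []
    for i in range(n_up):
        effects.append(DEEffect(gene=f"G{100 + i:04d}", time="t2", strain="HP", delta=2.0))
    for i in range(n_down):
        effects.append(DEEffect(gene=f"G{100 + n_up + i:04d}", time="t2", strain="HP", delta=-2.0))
    return tuple(effects)


def _default_mutated_genes() -> tuple[str, ...]:
    # overlap the planted modules: one feeder gene (mutB-like member of a
    # precursor operon), two perturbed-module genes, one hp_gained gene
    # (pks6-like cluster member), plus background mutations
    module_hits = ("G0030", "G0055", "G0060", "G0085")
    background = tuple(f"G{g:04d}" for g in range(300, 310))
    return module_hits + background


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults encode the study design: 2 strains x 4 time points x 3
    biological replicates (24 arrays) with two WT outlier samples (one at
    t1, one at t3) carrying an additive batch shift and listed for removal,
    leaving 22 usable samples.  ``noise_sd`` is the median gene-wise noise
    standard deviation (log2 units); individual genes draw their sd from a
    lognormal around it (``noise_log_sd``), the mild gene-to-gene variance
    dispersion that variance-moderated testing presumes.
    """

    n_genes: int = 2000
    n_replicates: int = 3
    time_points: tuple[str, ...] = TIME_POINTS
    strains: tuple[str, ...] = STRAINS
    modules: tuple[ModuleSpec, ...] = field(default_factory=default_modules)
    noise_sd: float = 0.5
    noise_log_sd: float = 0.10
    latent_sd: float = 1.0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    de_effects: tuple[DEEffect, ...] = field(default_factory=_default_de_effects)
    mutated_genes: tuple[str, ...] = field(default_factory=_default_mutated_genes)
    outlier_samples: tuple[str, ...] = ("WT_t1_r3", "WT_t3_r3")
    outlier_shift: float = 1.0
    # proteome
    proteome_rho: float = 0.6
    proteome_size: int = 300
    proteome_mean_count: float = 60.0
    proteome_dispersion: float = 0.3
    # variants
    variant_strains: tuple[str, ...] = ("HP", "Px", "E3")
    n_shared_variants: int = 10
    n_unique_variants: int = 5
    n_reference_errors: int = 4
    seed: int = 0

    # -- derived ---------------------------------------------------------
    def gene_ids(self) -> pd.Index:
        return pd.Index([f"G{i:04d}" for i in range(self.n_genes)], name="gene")

    def module_members(self) -> dict[str, list[str]]:
        """Module name -> gene ids; modules occupy the leading gene slots."""
        members: dict[str, list[str]] = {}
        start = 0
        for mod in self.modules:
            members[mod.name] = [f"G{i:04d}" for i in range(start, start + mod.size)]
            start += mod.size
        return members

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_replicates < 1:
            raise ValueError("n_genes and n_replicates must be positive")
        if sum(m.size for m in self.modules) > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not -1.0 <= self.proteome_rho <= 1.0:
            raise ValueError("proteome_rho must lie in [-1, 1]")
        genes = set(self.gene_ids())
        for eff in self.de_effects:
            if eff.gene not in genes:
                raise ValueError(f"DE effect references unknown gene {eff.gene}")
            if eff.time not in self.time_points or eff.strain not in self.strains:
                raise ValueError(f"DE effect references unknown group {eff.strain}/{eff.time}")
        for g in self.mutated_genes:
            if g not in genes:
                raise ValueError(f"mutated gene {g} not in genome")
        for mod in self.modules:
            if len(mod.wt_profile) != len(self.time_points) or len(mod.hp_profile) != len(
                self.time_points
            ):
                raise ValueError(f"module {mod.name}: profile length != number of time points")


def default_config(**overrides) -> SimConfig:
    """The study-design configuration (see :class:`SimConfig` defaults).

    When ``n_genes`` is overridden below the default genome size, planted
    differential-expression effects and mutated genes whose positional ids
    fall outside the smaller genome are dropped (the default plants are
    positional conventions of the full design).
    """
    cfg = replace(SimConfig(), **overrides) if overrides else SimConfig()
    if "n_genes" in overrides:
        genes = set(cfg.gene_ids())
        if "de_effects" not in overrides:
            cfg = replace(
                cfg, de_effects=tuple(e for e in cfg.de_effects if e.gene in genes)
            )
        if "mutated_genes" not in overrides:
            cfg = replace(
                cfg, mutated_genes=tuple(g for g in cfg.mutated_genes if g in genes)
            )
    return cfg


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class PlantedTruth:
    """Ground-truth ledger emitted alongside every simulated dataset."""

    membership: pd.DataFrame        # gene, module, kind
    expected_logfc: pd.DataFrame    # genes x time points (HP minus WT, log2)
    de_genes: pd.DataFrame          # gene, time, strain, delta (explicit plants)
    mutated_genes: list[str]
    noise_sd: pd.Series             # per-gene noise sd actually used
    config: SimConfig
    protein_truth: pd.DataFrame | None = None  # protein, time, expected_logfc
    variant_truth: dict | None = None

    def module_genes(self, *names: str) -> list[str]:
        mask = self.membership["module"].isin(names)
        return list(self.membership.loc[mask, "gene"])

    def expected_correlation(self, gene1: str, gene2: str, context: str) -> float:
        """Closed-form expected Pearson r for two module genes in a context.

        Returns 0.0 for genes that do not share a latent factor.  The latent
        variance V is the factor variance plus the empirical variance of the
        (loading-free) profile over the context's samples.
        """
        cfg = self.config
        by_gene = self.membership.set_index("gene")["module"]
        if gene1 not in by_gene.index or gene2 not in by_gene.index:
            return 0.0
        mods = {m.name: m for m in cfg.modules}
        m1, m2 = mods[by_gene[gene1]], mods[by_gene[gene2]]
        if m1.factor_name != m2.factor_name:
            return 0.0
        strains = list(cfg.strains) if context == "ALL" else [context]
        # profile values across the context's sample grid (equal replicates)
        prof1 = [p for s in strains for p in m1.profile(s) for _ in range(cfg.n_replicates)]
        prof2 = [p for s in strains for p in m2.profile(s) for _ in range(cfg.n_replicates)]
        a1 = np.repeat([m1.loading(s) for s in strains], len(cfg.time_points) * cfg.n_replicates)
        a2 = np.repeat([m2.loading(s) for s in strains], len(cfg.time_points) * cfg.n_replicates)
        sig1 = a1 * np.asarray(prof1)
        sig2 = a2 * np.asarray(prof2)
        vz = cfg.latent_sd**2
        cov = np.mean((sig1 - sig1.mean()) * (sig2 - sig2.mean())) + np.mean(a1 * a2) * vz
        v1 = np.var(sig1) + np.mean(a1**2) * vz + self.noise_sd[gene1] ** 2
        v2 = np.var(sig2) + np.mean(a2**2) * vz + self.noise_sd[gene2] ** 2
        return float(cov / np.sqrt(v1 * v2))


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(config: SimConfig) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Draw a gene x sample log2 expression matrix plus its truth ledger.

    Deterministic: the same config (including seed) yields a bit-identical
    matrix.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    genes = config.gene_ids()
    samples = make_sample_table(config.strains, config.time_points, config.n_replicates)
    n_genes, n_samples = len(genes), len(samples)

    # gene-wise noise sd: lognormal around noise_sd (median)
    noise_sd = config.noise_sd * np.exp(rng.normal(0.0, config.noise_log_sd, size=n_genes))
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n_genes)

    x = baseline[:, None] + rng.normal(0.0, 1.0, size=(n_genes, n_samples)) * noise_sd[:, None]

    # latent factor scores: one N(0, latent_sd^2) draw per factor per sample
    factor_names = sorted({m.factor_name for m in config.modules})
    factor_scores = {
        name: rng.normal(0.0, config.latent_sd, size=n_samples) for name in factor_names
    }

    strain_arr = samples["strain"].to_numpy()
    time_idx = np.array([config.time_points.index(t) for t in samples["time"]])
    gene_pos = {g: i for i, g in enumerate(genes)}
    members = config.module_members()

    membership_rows = []
    for mod in config.modules:
        z = factor_scores[mod.factor_name]
        loading = np.where(strain_arr == "WT", mod.wt_loading, mod.hp_loading)
        profile = np.where(
            strain_arr == "WT",
            np.asarray(mod.wt_profile)[time_idx],
            np.asarray(mod.hp_profile)[time_idx],
        )
        shift = np.where(strain_arr == "HP", mod.hp_shift, 0.0)
        signal = loading * (profile + z) + shift
        for g in members[mod.name]:
            x[gene_pos[g]] += signal
            membership_rows.append({"gene": g, "module": mod.name, "kind": mod.kind})
    module_gene_set = {r["gene"] for r in membership_rows}
    for g in genes:
        if g not in module_gene_set:
            membership_rows.append({"gene": g, "module": "", "kind": "background"})
    membership = pd.DataFrame(membership_rows).sort_values("gene").reset_index(drop=True)

    # planted per-time-point DE shifts
    for eff in config.de_effects:
        cols = (samples["strain"] == eff.strain) & (samples["time"] == eff.time)
        x[gene_pos[eff.gene], cols.to_numpy()] += eff.delta

    # outlier arrays: additive batch shift (to be removed downstream)
    for sid in config.outlier_samples:
        if sid not in samples.index:
            raise ValueError(f"outlier sample {sid} not in design")
        x[:, samples.index.get_loc(sid)] += config.outlier_shift

    values = pd.DataFrame(x, index=genes, columns=samples.index)

    # expected HP-vs-WT logFC per gene per time point
    expected = pd.DataFrame(0.0, index=genes, columns=list(config.time_points))
    for mod in config.modules:
        for ti, t in enumerate(config.time_points):
            lfc = mod.hp_loading * mod.hp_profile[ti] - mod.wt_loading * mod.wt_profile[ti]
            lfc += mod.hp_shift
            expected.loc[members[mod.name], t] += lfc
    for eff in config.de_effects:
        sign = 1.0 if eff.strain == "HP" else -1.0
        expected.loc[eff.gene, eff.time] += sign * eff.delta

    de_genes = pd.DataFrame(
        [
            {"gene": e.gene, "time": e.time, "strain": e.strain, "delta": e.delta}
            for e in config.de_effects
        ]
    )
    truth = PlantedTruth(
        membership=membership,
        expected_logfc=expected,
        de_genes=de_genes,
        mutated_genes=list(config.mutated_genes),
        noise_sd=pd.Series(noise_sd, index=genes),
        config=config,
    )
    return ExpressionMatrix(values=values, samples=samples), truth


# ---------------------------------------------------------------------------
# raw probe-level intensities (to exercise preprocessing)
# ---------------------------------------------------------------------------

@dataclass
class RawProbeTable:
    """Probe-level raw intensities with per-array background statistics."""

    intensities: pd.DataFrame   # probes x samples, linear scale
    probe_map: pd.Series        # probe id -> gene id
    background: pd.DataFrame    # per sample: bg_mean, bg_sd
    samples: pd.DataFrame


def simulate_raw_probes(
    expr: ExpressionMatrix,
    config: SimConfig,
    n_low_signal: int = 8,
    probe_noise_sd: float = 0.1,
) -> RawProbeTable:
    """Expand a log2 matrix into duplicated raw probes plus background.

    Each gene gets two probes (the duplicated-spot design); the last
    ``n_low_signal`` genes are replaced by background-level noise so the
    low-signal filter has something to remove.
    """
    rng = np.random.default_rng([config.seed, 1])
    genes = expr.genes
    probes, gene_of = [], []
    for g in genes:
        for k in (1, 2):
            probes.append(f"{g}_p{k}")
            gene_of.append(g)
    log2 = np.repeat(expr.values.to_numpy(), 2, axis=0)
    log2 = log2 + rng.normal(0.0, probe_noise_sd, size=log2.shape)
    inten = np.power(2.0, log2)

    bg_mean = rng.uniform(18.0, 24.0, size=len(expr.sample_ids))
    bg_sd = rng.uniform(3.0, 6.0, size=len(expr.sample_ids))
    if n_low_signal:
        low = np.abs(rng.normal(bg_mean, bg_sd, size=(2 * n_low_signal, len(bg_mean))))
        inten[-2 * n_low_signal:, :] = low

    return RawProbeTable(
        intensities=pd.DataFrame(inten, index=pd.Index(probes, name="probe"),
                                 columns=expr.sample_ids),
        probe_map=pd.Series(gene_of, index=pd.Index(probes, name="probe"), name="gene"),
        background=pd.DataFrame({"bg_mean": bg_mean, "bg_sd": bg_sd},
                                index=pd.Index(expr.sample_ids, name="sample")),
        samples=expr.samples.copy(),
    )


# ---------------------------------------------------------------------------
# proteome
# ---------------------------------------------------------------------------

def simulate_proteome(
    expr: ExpressionMatrix,
    truth: PlantedTruth,
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spectral-count table linked to expression with target correlation.

    Counts are negative-binomial with log2-mean equal to the gene's
    (centred) expression plus a gene-by-strain noise term whose variance is
    calibrated, via the delta-method count-noise estimate, so that the
    expected Pearson correlation between transcript and protein
    log-fold-changes equals ``config.proteome_rho``.

    Returns ``(counts, sample_meta)`` where counts is proteins x samples.
    """
    rho = config.proteome_rho
    if not -1.0 <= rho <= 1.0:
        raise ValueError("proteome_rho must lie in [-1, 1]")
    rng = np.random.default_rng([config.seed, 2])

    # protein panel: module + planted-DE genes first, background fill
    module_genes = [g for g in truth.membership.loc[truth.membership["kind"] != "background", "gene"]]
    de_genes = list(dict.fromkeys(truth.de_genes["gene"])) if len(truth.de_genes) else []
    panel = list(dict.fromkeys(module_genes + de_genes))
    background = [g for g in expr.genes if g not in set(panel)]
    n_fill = max(0, config.proteome_size - len(panel))
    panel = (panel + background[:n_fill])[: config.proteome_size]

    x = expr.values.loc[panel].copy()
    # the outlier batch shift is an array artifact; the protein assay links
    # to the underlying biological signal, so it is removed here
    for s in config.outlier_samples:
        if s in x.columns:
            x[s] = x[s] - config.outlier_shift
    centred = x.sub(x.mean(axis=1), axis=0).to_numpy()

    # calibrate gene-by-strain-by-time noise so that, at each time point,
    # corr(transcript logFC, protein logFC) = rho.  The transcript logFC
    # variance across the panel differs strongly between time points, so
    # the calibration is per time point.
    slope = 0.0 if rho == 0.0 else np.sign(rho)
    times = list(dict.fromkeys(expr.samples["time"]))
    # delta-method count-noise contribution to a logFC of summed replicates
    mu = config.proteome_mean_count
    phi = config.proteome_dispersion
    n_rep = config.n_replicates
    v_count = 2.0 * (1.0 + phi * mu) / (n_rep * mu) / np.log(2.0) ** 2
    tau = {}
    for t in times:
        if rho == 0.0:
            tau[t] = 0.0
            continue
        hp = expr.values.loc[panel, expr.select_samples("HP", t)].mean(axis=1)
        wt = expr.values.loc[panel, expr.select_samples("WT", t)].mean(axis=1)
        var_d = float(np.var((hp - wt).to_numpy()))
        v_needed = var_d * (1.0 / rho**2 - 1.0)
        tau[t] = float(np.sqrt(max(0.0, v_needed - v_count) / 2.0))

    eta = {
        (s, t): rng.normal(0.0, tau[t], size=len(panel)) if tau[t] > 0 else np.zeros(len(panel))
        for s in config.strains
        for t in times
    }
    eta_mat = np.column_stack(
        [eta[(s, t)] for s, t in zip(expr.samples["strain"], expr.samples["time"])]
    )

    size_factor = rng.lognormal(0.0, 0.5, size=len(panel))
    log2_mean = slope * centred + eta_mat
    mean = config.proteome_mean_count * size_factor[:, None] * np.power(2.0, log2_mean)

    phi = config.proteome_dispersion
    if phi > 0:
        n_param = 1.0 / phi
        p_param = n_param / (n_param + mean)
        counts = rng.negative_binomial(n_param, p_param)
    else:
        counts = rng.poisson(mean)

    counts_df = pd.DataFrame(counts, index=pd.Index(panel, name="protein"),
                             columns=expr.sample_ids)

    # expected abundance ratios ledger
    rows = []
    for t in ("t1", "t2"):
        hp_cols = expr.select_samples("HP", t)
        wt_cols = expr.select_samples("WT", t)
        hp_i = [expr.sample_ids.index(c) for c in hp_cols]
        wt_i = [expr.sample_ids.index(c) for c in wt_cols]
        exp_lfc = (
            slope * (centred[:, hp_i].mean(axis=1) - centred[:, wt_i].mean(axis=1))
            + (eta[("HP", t)] - eta[("WT", t)])
        )
        for g, v in zip(panel, exp_lfc):
            rows.append({"protein": g, "time": t, "expected_logfc": float(v)})
    truth.protein_truth = pd.DataFrame(rows)
    return counts_df, expr.samples.copy()


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

_GENE_SPAN = 1000  # toy genome: gene i occupies [i*1000+201, i*1000+800]


def make_annotation(config: SimConfig) -> pd.DataFrame:
    """Toy genome annotation: one gene per 1 kb tile, alternating strand."""
    genes = config.gene_ids()
    rows = []
    for i, g in enumerate(genes):
        rows.append(
            {
                "gene": g,
                "start": i * _GENE_SPAN + 201,
                "end": i * _GENE_SPAN + 800,
                "strand": "+" if i % 2 == 0 else "-",
            }
        )
    return pd.DataFrame(rows)


def simulate_variants(config: SimConfig) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, dict]:
    """Per-strain variant tables with planted shared/unique/error structure.

    Returns (tables, reference_errors, truth_counts).  Every strain's table
    contains the shared variants, its unique variants, and the planted
    reference errors (which genuine-variant filtering must remove).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 3])
    bases = np.array(list("ACGT"))

    def draw_snv(pos):
        ref, alt = rng.choice(bases, size=2, replace=False)
        return {"pos": int(pos), "ref": str(ref), "alt": str(alt)}

    def draw_mnv(pos):
        ref = "".join(rng.choice(bases, size=2))
        while True:
            alt = "".join(rng.choice(bases, size=2))
            if alt != ref and alt[0] != ref[0] and alt[1] != ref[1]:
                return {"pos": int(pos), "ref": ref, "alt": alt}

    # distinct positions inside ORFs of mutated genes first, then background
    anchor_genes = [int(g[1:]) for g in config.mutated_genes]
    positions = [i * _GENE_SPAN + 450 for i in anchor_genes]
    extra = [int(p) for p in rng.choice(config.n_genes, size=200, replace=False)]
    positions += [i * _GENE_SPAN + 500 for i in extra if i not in anchor_genes]
    positions = list(dict.fromkeys(positions))

    it = iter(positions)
    shared, unique, errors = [], {s: [] for s in config.variant_strains}, []
    n_shared = config.n_shared_variants
    for k in range(n_shared):
        pos = next(it)
        if k == 0 and n_shared >= 2:
            v = {"pos": pos, "ref": "AC", "alt": "A"}  # deletion
        elif k == 1 and n_shared >= 2:
            v = {"pos": pos, "ref": "A", "alt": "AG"}  # insertion
        elif k < 4:
            v = draw_mnv(pos)
        else:
            v = draw_snv(pos)
        shared.append(v)
    for strain in config.variant_strains:
        n_u = config.n_unique_variants if strain == "HP" else max(1, config.n_unique_variants // 2)
        for k in range(n_u):
            pos = next(it)
            unique[strain].append(draw_mnv(pos) if (strain == "HP" and k == 0) else draw_snv(pos))
    for _ in range(config.n_reference_errors):
        errors.append(draw_snv(next(it)))

    tables = {}
    for strain in config.variant_strains:
        recs = shared + unique[strain] + errors
        df = pd.DataFrame(recs).sort_values("pos").reset_index(drop=True)
        df["strain"] = strain
        tables[strain] = df
    errors_df = pd.DataFrame(errors).sort_values("pos").reset_index(drop=True)
    truth_counts = {
        "shared": len(shared),
        "unique": {s: len(unique[s]) for s in config.variant_strains},
        "reference_errors": len(errors),
    }
    return tables, errors_df, truth_counts


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def make_gene_sets(
    truth: PlantedTruth,
    config: SimConfig,
    n_random: int = 30,
    random_size_range: tuple[int, int] = (10, 50),
    ontology: str = "KEGG",
    size_bounds: tuple[int, int] | None = None,
):
    """Planted-module gene sets plus random decoy sets, GMT-serializable.

    Set sizes are checked against the ontology's bounds (KEGG 8-400,
    GO 15-500 by default); a requested set that violates them raises.
    """
    from .enrichment import GeneSet, GeneSetCollection, SIZE_BOUNDS

    lo, hi = size_bounds if size_bounds is not None else SIZE_BOUNDS[ontology]
    rng = np.random.default_rng([config.seed, 4])
    genes = list(config.gene_ids())
    sets = []
    for mod in config.modules:
        members = config.module_members()[mod.name]
        if not lo <= len(members) <= hi:
            raise ValueError(
                f"module set {mod.name} (size {len(members)}) violates {ontology} bounds"
            )
        sets.append(GeneSet(name=f"module_{mod.name}", ontology=ontology,
                            genes=frozenset(members)))
    for k in range(n_random):
        size = int(rng.integers(random_size_range[0], random_size_range[1] + 1))
        if not lo <= size <= hi:
            raise ValueError(f"random set size {size} violates {ontology} bounds")
        members = rng.choice(genes, size=size, replace=False)
        sets.append(GeneSet(name=f"random_{k:03d}", ontology=ontology,
                            genes=frozenset(members.tolist())))
    return GeneSetCollection(sets)
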