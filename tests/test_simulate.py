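"""Generator tests: determinism, planted structure, closed-form oracles."""
import numpy as np
import pandas as pd
import pytest

from erynet import simulate
from erynet.simulate import DEEffect, ModuleSpec, SimConfig


def test_simulation_is_deterministic(small_config):
    a, _ = simulate.simulate_expression(small_config)
    b, _ = simulate.simulate_expression(small_config)
    assert (a.values.to_numpy() == b.values.to_numpy()).all()
    assert list(a.sample_ids) == list(b.sample_ids)


def test_seed_changes_matrix(small_config):
    a, _ = simulate.simulate_expression(small_config)
    b, _ = simulate.simulate_expression(simulate.default_config(n_genes=300, seed=8))
    assert not (a.values.to_numpy() == b.values.to_numpy()).all()


def test_design_shape(default_sim, default_config):
    expr, truth = default_sim
    assert expr.values.shape == (default_config.n_genes, 24)
    assert set(expr.samples["strain"]) == {"WT", "HP"}
    assert expr.times() == ["t1", "t2", "t3", "t4"]
    assert len(truth.membership) == default_config.n_genes
    counts = truth.membership["module"].value_counts()
    assert counts["ery"] == 20 and counts["feeder"] == 30
    assert counts["pks_wt"] == 30 and counts["pks_hp"] == 20


def test_closed_form_correlation_flat_module():
    """a=1, V_f=1, sigma^2=1, flat profiles -> expected pairwise r = 0.5.

    Uses many two-gene modules with independent latent factors, since the
    average over pairs converges to the closed form only across independent
    factor draws (pairs sharing one factor co-fluctuate with its realized
    sample variance).
    """
    mods = tuple(
        ModuleSpec(name=f"m{k}", size=2, kind="maintained") for k in range(250)
    )
    cfg = SimConfig(
        n_genes=500, modules=mods, de_effects=(), mutated_genes=(),
        noise_sd=1.0, noise_log_sd=0.0, latent_sd=1.0,
        outlier_samples=(), seed=12,
    )
    expr, truth = simulate.simulate_expression(cfg)
    g0 = truth.module_genes("m0")
    assert truth.expected_correlation(g0[0], g0[1], "ALL") == pytest.approx(0.5)
    rs = []
    for k in range(250):
        a, b = truth.module_genes(f"m{k}")
        rs.append(np.corrcoef(expr.values.loc[a], expr.values.loc[b])[0, 1])
    assert len(rs) >= 200
    # 250 independent pairs at 24 samples: SE ~ 0.012
    assert np.mean(rs) == pytest.approx(0.5, abs=0.05)


def test_expected_correlation_matches_empirical_mean_defaults(default_sim):
    expr, truth = default_sim
    ery = truth.module_genes("ery")
    wt_ids = expr.select_samples(strain="WT")
    wt_ids = [s for s in wt_ids if s not in truth.config.outlier_samples]
    r = np.corrcoef(expr.values.loc[ery, wt_ids])
    iu = np.triu_indices(len(ery), 1)
    expected = truth.expected_correlation(ery[0], ery[1], "WT")
    assert expected > 0.85
    assert np.mean(r[iu]) == pytest.approx(expected, abs=0.08)


def test_planted_logfc_recovered_small_noise():
    """delta=+2 at (HP, t2), sigma=0.1 -> sample logFC within 2*sigma*sqrt(2/3)."""
    cfg = SimConfig(
        n_genes=5, modules=(), mutated_genes=(), outlier_samples=(),
        noise_sd=0.1, noise_log_sd=0.0,
        de_effects=(DEEffect(gene="G0002", time="t2", strain="HP", delta=2.0),),
        seed=3,
    )
    expr, truth = simulate.simulate_expression(cfg)
    hp = expr.group_values("HP", "t2").loc["G0002"].mean()
    wt = expr.group_values("WT", "t2").loc["G0002"].mean()
    assert abs((hp - wt) - 2.0) <= 2 * 0.1 * np.sqrt(2.0 / 3.0)
    assert truth.expected_logfc.loc["G0002", "t2"] == 2.0
    assert truth.expected_logfc.loc["G0002", "t1"] == 0.0


def test_outlier_samples_carry_shift(default_config):
    expr, _ = simulate.simulate_expression(default_config)
    no_out = simulate.default_config(outlier_samples=())
    expr2, _ = simulate.simulate_expression(no_out)
    sid = default_config.outlier_samples[0]
    diff = expr.values[sid] - expr2.values[sid]
    assert np.allclose(diff, default_config.outlier_shift)


def test_config_validation_errors():
    with pytest.raises(ValueError, match="mutated gene"):
        SimConfig(n_genes=150, de_effects=(), mutated_genes=("G0300",)).validate()
    with pytest.raises(ValueError, match="unknown gene"):
        SimConfig(
            n_genes=50, modules=(), mutated_genes=(),
            de_effects=(DEEffect("G9999", "t2", "HP", 2.0),),
        ).validate()
    with pytest.raises(ValueError, match="module sizes"):
        SimConfig(n_genes=50).validate()
    with pytest.raises(ValueError, match="proteome_rho"):
        simulate.default_config(proteome_rho=1.5).validate()


def test_default_config_scales_plants_to_genome():
    cfg = simulate.default_config(n_genes=150)
    cfg.validate()
    assert all(e.gene in set(cfg.gene_ids()) for e in cfg.de_effects)
    assert all(g in set(cfg.gene_ids()) for g in cfg.mutated_genes)


def test_raw_probes_structure(small_sim, small_config):
    expr, _ = small_sim
    raw = simulate.simulate_raw_probes(expr, small_config, n_low_signal=4)
    assert raw.intensities.shape == (2 * small_config.n_genes, 24)
    assert (raw.intensities.to_numpy() > 0).all()
    assert raw.probe_map.loc["G0000_p1"] == "G0000"
    # the low-signal probes sit at background level
    bg_hi = (raw.background["bg_mean"] + 2 * raw.background["bg_sd"]).to_numpy()
    low = raw.intensities.iloc[-8:].to_numpy()
    assert (low.mean(axis=0) < bg_hi * 3).all()


def test_proteome_counts_and_truth(default_sim, default_config):
    expr, truth = default_sim
    counts, meta = simulate.simulate_proteome(expr, truth, default_config)
    assert counts.shape == (default_config.proteome_size, 24)
    arr = counts.to_numpy()
    assert (arr >= 0).all() and np.issubdtype(arr.dtype, np.integer)
    assert truth.protein_truth is not None
    assert set(truth.protein_truth["time"]) == {"t1", "t2"}
    # module genes are on the panel
    assert set(truth.module_genes("ery")) <= set(counts.index)


def test_proteome_rho_bounds(default_sim, default_config):
    expr, truth = default_sim
    with pytest.raises(ValueError, match="proteome_rho"):
        bad = simulate.default_config(proteome_rho=2.0)
        simulate.simulate_proteome(expr, truth, bad)


def test_variant_fixture_structure(default_config):
    tables, errors, truth_counts = simulate.simulate_variants(default_config)
    assert set(tables) == set(default_config.variant_strains)
    assert truth_counts["shared"] == default_config.n_shared_variants
    assert truth_counts["reference_errors"] == default_config.n_reference_errors
    assert len(errors) == default_config.n_reference_errors
    key = ["pos", "ref", "alt"]
    err_keys = set(map(tuple, errors[key].itertuples(index=False)))
    for strain, df in tables.items():
        # planted errors are present in every raw strain table
        strain_keys = set(map(tuple, df[key].itertuples(index=False)))
        assert err_keys <= strain_keys
        assert df["pos"].is_monotonic_increasing


def test_gene_sets_bounds_and_content(default_sim, default_config):
    _, truth = default_sim
    sets = simulate.make_gene_sets(truth, default_config, n_random=5)
    names = [s.name for s in sets]
    assert "module_ery" in names and "random_000" in names
    for s in sets:
        assert 8 <= s.size <= 400
    assert set(sets["module_ery"].genes) == set(truth.module_genes("ery"))
    with pytest.raises(ValueError, match="bounds"):
        simulate.make_gene_sets(truth, default_config, n_random=1,
                                random_size_range=(2, 2))
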