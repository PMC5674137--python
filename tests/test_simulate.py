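"""Cross simulator: parents, meiosis, pooling, sequencing, power experiment."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from bulkseg import (
    ConfigurationError,
    DataError,
    EmptyInputError,
    apply_filters,
    delta_index,
    sliding_window_analysis,
)
from bulkseg.simulate import (
    CrossSimConfig,
    power_experiment,
    simulate_cross,
    simulate_offspring,
    simulate_parents,
)


def _cfg(**kwargs):
    base = dict(
        n_scaffolds=1,
        scaffold_length=200_000,
        snp_density=0.002,
        qtl_scaffold=0,
        qtl_position=100_000,
        n_offspring=40,
        n_offspring_per_pool=(10, 10),
        mean_depth=30.0,
        seed=7,
    )
    base.update(kwargs)
    return CrossSimConfig(**base)


# ---------------------------------------------------------------------------
# Parents
# ---------------------------------------------------------------------------


def test_zero_heterozygosity_parents_have_identical_haplotypes():
    parents = simulate_parents(
        _cfg(parent_heterozygosity=0.0), np.random.default_rng(1)
    )
    haps = parents.haplotypes[0]
    s, k = parents.qtl_site
    mask = np.ones(haps.shape[1], dtype=bool)
    mask[k] = False  # the trait site is heterozygous by construction (Rr x rr)
    assert np.array_equal(haps[0, mask], haps[1, mask])
    assert np.array_equal(haps[2, mask], haps[3, mask])


def test_full_heterozygosity_every_site_heterozygous_in_both_parents():
    parents = simulate_parents(
        _cfg(parent_heterozygosity=1.0), np.random.default_rng(1)
    )
    haps = parents.haplotypes[0]
    assert np.all(haps[0] != haps[1])
    s, k = parents.qtl_site
    mask = np.ones(haps.shape[1], dtype=bool)
    mask[k] = False
    assert np.all(haps[2, mask] != haps[3, mask])


def test_qtl_site_alleles_follow_cross_type():
    parents = simulate_parents(_cfg(), np.random.default_rng(1))
    s, k = parents.qtl_site
    assert parents.positions[s][k] == 100_000
    assert list(parents.haplotypes[s][:, k]) == [1, 0, 0, 0]  # Rr x rr, R on P1 hap 1
    parents2 = simulate_parents(_cfg(cross_type="RrXRr"), np.random.default_rng(1))
    s2, k2 = parents2.qtl_site
    assert list(parents2.haplotypes[s2][:, k2]) == [1, 0, 1, 0]


def test_zero_density_raises_empty_input():
    with pytest.raises(EmptyInputError):
        simulate_parents(_cfg(snp_density=0.0), np.random.default_rng(1))


# ---------------------------------------------------------------------------
# Offspring
# ---------------------------------------------------------------------------


def test_no_recombination_gametes_are_intact_parental_haplotypes():
    config = _cfg(recombination_rate=0.0, n_offspring=20)
    rng = np.random.default_rng(3)
    parents = simulate_parents(config, rng)
    offspring = simulate_offspring(parents, config, rng)
    haps = parents.haplotypes[0]
    for i in range(config.n_offspring):
        for parent in range(2):
            gamete = offspring.genotypes[0][i, parent]
            assert np.array_equal(gamete, haps[2 * parent]) or np.array_equal(
                gamete, haps[2 * parent + 1]
            )


def test_dominant_trait_segregates_one_to_one():
    """Rr x rr with full penetrance: red fraction ~ Binomial(n, 1/2)."""
    config = _cfg(n_offspring=500, n_offspring_per_pool=(10, 10))
    rng = np.random.default_rng(5)
    parents = simulate_parents(config, rng)
    offspring = simulate_offspring(parents, config, rng)
    n_red = int(offspring.phenotype_red.sum())
    lo, hi = stats.binom.interval(0.99, 500, 0.5)
    assert lo <= n_red <= hi


def test_crossover_counts_are_poisson_distributed():
    """Mean crossovers per gamete matches the scaffold's genetic length (reduced alpha)."""
    config = _cfg(
        scaffold_length=1_000_000,
        recombination_rate=100.0,  # 1 Morgan per scaffold
        snp_density=0.005,
        qtl_position=500_000,
        n_offspring=200,
    )
    rng = np.random.default_rng(11)
    parents = simulate_parents(config, rng)
    offspring = simulate_offspring(parents, config, rng)
    # infer switch counts from haplotype-block changes at parent-1-informative sites
    haps = parents.haplotypes[0]
    informative = haps[0] != haps[1]
    switches = []
    for i in range(config.n_offspring):
        gamete = offspring.genotypes[0][i, 0][informative]
        source = (gamete == haps[1][informative]).astype(int)
        switches.append(int((np.diff(source) != 0).sum()))
    mean = np.mean(switches)
    # observed switches undercount crossovers (double crossovers between
    # informative sites collapse), so test against a generous Poisson band
    se = np.std(switches, ddof=1) / np.sqrt(len(switches))
    assert 1.0 - 4 * se - 0.15 <= mean <= 1.0 + 4 * se


def test_penetrance_zero_flips_every_phenotype():
    config = _cfg(penetrance=1.0, n_offspring=100)
    rng = np.random.default_rng(9)
    parents = simulate_parents(config, rng)
    strict = simulate_offspring(parents, config, rng)
    config0 = _cfg(penetrance=0.0, n_offspring=100)
    rng = np.random.default_rng(9)
    parents = simulate_parents(config0, rng)
    flipped = simulate_offspring(parents, config0, rng)
    assert np.array_equal(strict.phenotype_red, ~flipped.phenotype_red)


# ---------------------------------------------------------------------------
# Pools and sequencing
# ---------------------------------------------------------------------------


def test_same_seed_gives_identical_datasets(small_config, small_sim):
    again = simulate_cross(small_config)
    assert again.variants == small_sim.variants
    assert again.truth.qtl_position == small_sim.truth.qtl_position
    for name, cuts in again.truth.reference_breakpoints.items():
        assert np.array_equal(cuts, small_sim.truth.reference_breakpoints[name])


def test_observed_index_tracks_true_pool_frequency_at_high_depth():
    config = _cfg(mean_depth=5_000.0, sequencing_error=0.0, reference_mode="parental")
    sim = simulate_cross(config)
    truth = sim.truth
    for v, fa, fb in zip(
        sim.variants, truth.true_freq_a["scaffold01"], truth.true_freq_b["scaffold01"]
    ):
        assert v.index_a == pytest.approx(fa, abs=0.05)
        assert v.index_b == pytest.approx(fb, abs=0.05)


def test_qtl_site_pool_contrast_is_half_in_parental_mode():
    """Rr x rr with perfect penetrance: |index_red - index_green| -> 0.5 at the trait site."""
    config = _cfg(mean_depth=5_000.0, sequencing_error=0.0, reference_mode="parental",
                  n_offspring=200, n_offspring_per_pool=(50, 50))
    sim = simulate_cross(config)
    at_qtl = [v for v in sim.variants if v.position == 100_000]
    assert len(at_qtl) == 1
    assert abs(delta_index(at_qtl[0])) == pytest.approx(0.5, abs=0.03)


def test_pool_exceeding_available_phenotypes_raises():
    # 80 offspring of a 1:1 cross cannot supply 55 red individuals
    config = _cfg(n_offspring=80, n_offspring_per_pool=(55, 20))
    with pytest.raises(DataError):
        simulate_cross(config)


def test_mosaic_reference_attenuates_signed_window_delta_but_not_absolute():
    """Reference haplotype switching cancels windowed signed delta near the trait
    locus while |delta| windows keep their height (the pseudoexchange effect)."""
    base = dict(
        n_scaffolds=1,
        scaffold_length=1_000_000,
        snp_density=0.003,
        qtl_scaffold=0,
        qtl_position=500_000,
        recombination_rate=45.0,
        n_offspring=60,
        n_offspring_per_pool=(15, 15),
        mean_depth=30.0,
        mosaic_switch_rate=20.0,
    )
    signed = {"parental": [], "mosaic": []}
    absolute = {"parental": [], "mosaic": []}
    for rep in range(20):
        for mode in ("parental", "mosaic"):
            config = CrossSimConfig(reference_mode=mode, seed=100 + rep, **base)
            sim = simulate_cross(config)
            kept = apply_filters(sim.variants).kept
            windows = sliding_window_analysis(kept, sim.scaffold_lengths)
            at_qtl = [w for w in windows if w.start <= 500_000 <= w.end]
            signed[mode].append(np.nanmean([abs(w.mean_delta) for w in at_qtl]))
            absolute[mode].append(np.nanmean([w.mean_abs_delta for w in at_qtl]))
    assert np.mean(signed["mosaic"]) < 0.5 * np.mean(signed["parental"])
    assert np.mean(absolute["mosaic"]) > 0.8 * np.mean(absolute["parental"])


# ---------------------------------------------------------------------------
# Power experiment
# ---------------------------------------------------------------------------


def test_power_experiment_structure_and_determinism():
    config = CrossSimConfig(
        n_scaffolds=2,
        scaffold_length=500_000,
        snp_density=0.002,
        qtl_position=250_000,
        n_offspring=60,
        n_offspring_per_pool=(15, 15),
        seed=3,
    )
    result = power_experiment(config, 3)
    assert set(result.frame["method"]) == {"delta", "abs_delta"}
    assert len(result.frame) == 6
    summary = result.summary()
    assert ((summary["ci_low"] <= summary["detection_rate"])
            & (summary["detection_rate"] <= summary["ci_high"])).all()
    again = power_experiment(config, 3)
    assert again.frame.equals(result.frame)
    assert 0.0 <= result.paired_pvalue() <= 1.0


def test_power_experiment_rejects_zero_density():
    with pytest.raises(EmptyInputError):
        power_experiment(_cfg(snp_density=0.0), 2)


def test_config_validation():
    with pytest.raises(ConfigurationError):
        _cfg(qtl_position=10_000_000)
    with pytest.raises(ConfigurationError):
        _cfg(parent_heterozygosity=1.5)
    with pytest.raises(ConfigurationError):
        _cfg(reference_mode="other")
    with pytest.raises(ConfigurationError):
        _cfg(n_offspring=10, n_offspring_per_pool=(10, 10))
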