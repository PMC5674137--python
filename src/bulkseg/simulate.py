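"""Pooled-sequencing simulator for an F1 cross of two heterozygous parents.

The generator produces exactly the data a two-bulk QTL-seq experiment yields --
per-site ref/alt read depths for a "red" and a "green" pool -- from a fully
specified genetic model, so every window statistic and the signed-vs-absolute
delta comparison can be tested without any external download.

Model
-----
* A SNP map is drawn per scaffold at a fixed density. Each parent is heterozygous
  at a site with probability ``parent_heterozygosity``, with random phase;
  homozygous sites carry a random allele. Sites monomorphic across all four
  parental haplotypes are discarded (they could never be called as variants).
* A single dominant trait allele R sits at ``qtl_position``; the cross is
  Rr x rr (default) or Rr x Rr, with parent 1 carrying R on haplotype 1.
* Each offspring receives one recombinant gamete per parent; crossovers per
  gamete are Poisson with mean = scaffold genetic length in Morgans
  (``recombination_rate`` cM/Mb), uniformly placed. Phenotype is red iff the
  offspring carries at least one R, flipped with probability 1 - penetrance.
* Pools take the first ``n_offspring_per_pool`` red and green offspring. At each
  site the pool's true alternate-allele frequency is the mean dosage of the
  non-reference allele, measured against the chosen reference.
* Reference modes: ``parental`` uses parent 1, haplotype 1 everywhere. ``mosaic``
  switches the reference between parent 1's two haplotypes at Poisson breakpoints
  (``mosaic_switch_rate`` per Mb). A switch flips which allele is "alt" at every
  site where parent 1 is heterozygous, flipping the sign of delta segment-wise:
  the pseudoexchange effect that cancels windowed signed delta in heterozygous
  material while leaving |delta| intact.
* Sequencing: per-site per-pool depth ~ Poisson(``mean_depth``); alt reads ~
  Binomial(depth, f(1-e) + (1-f)e) with per-base error rate e. No overdispersion
  term (future hook).

All randomness flows through one ``numpy.random.Generator``; the same seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from statsmodels.stats.proportion import proportion_confint

from .errors import ConfigurationError, DataError, EmptyInputError
from .intervals import SparsityPolicy, call_intervals, filter_sparse, total_length
from .variants import FilterPolicy, PooledVariant, apply_filters
from .windows import (
    DEFAULT_STEP,
    DEFAULT_WINDOW_SIZE,
    flag_windows,
    quantile_thresholds,
    sliding_window_analysis,
)

_BASES = np.array(["A", "C", "G", "T"])

REFERENCE_MODES = ("parental", "mosaic")
CROSS_TYPES = ("RrXrr", "RrXRr")


@dataclass(frozen=True)
class CrossSimConfig:
    """Full parameterization of the synthetic cross, pools and sequencing.

    Defaults describe a desk-scale version of a heterozygous fruit-tree BSA
    experiment: a 5 x 2-Mb toy genome at ~4.5 SNPs/kb, highly heterozygous
    parents, 28 + 27 offspring pooled, ~20x coverage per pool, and a mosaic
    reference switching haplotype state 5 times per Mb.
    """

    n_scaffolds: int = 5
    scaffold_length: int = 2_000_000
    snp_density: float = 0.0045  # expected SNPs per bp
    qtl_scaffold: int = 0
    qtl_position: int = 1_000_000
    parent_heterozygosity: float = 0.5
    recombination_rate: float = 45.0  # cM per Mb
    cross_type: str = "RrXrr"
    n_offspring: int = 120
    n_offspring_per_pool: tuple[int, int] = (28, 27)  # (red, green)
    mean_depth: float = 20.0
    sequencing_error: float = 0.005
    reference_mode: str = "mosaic"
    mosaic_switch_rate: float = 5.0  # expected reference switches per Mb
    penetrance: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_scaffolds < 1 or self.scaffold_length < 1:
            raise ConfigurationError("need at least one scaffold of positive length")
        if self.snp_density < 0:
            raise ConfigurationError("snp_density must be >= 0")
        if not 0 <= self.qtl_scaffold < self.n_scaffolds:
            raise ConfigurationError("qtl_scaffold out of range")
        if not 1 <= self.qtl_position <= self.scaffold_length:
            raise ConfigurationError("qtl_position must lie on the QTL scaffold")
        for name in ("parent_heterozygosity", "sequencing_error", "penetrance"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {val}")
        if self.recombination_rate < 0 or self.mosaic_switch_rate < 0:
            raise ConfigurationError("rates must be non-negative")
        if self.cross_type not in CROSS_TYPES:
            raise ConfigurationError(f"cross_type must be one of {CROSS_TYPES}")
        if self.reference_mode not in REFERENCE_MODES:
            raise ConfigurationError(f"reference_mode must be one of {REFERENCE_MODES}")
        if self.mean_depth <= 0:
            raise ConfigurationError("mean_depth must be positive")
        if min(self.n_offspring_per_pool) < 1:
            raise ConfigurationError("pool sizes must be positive")
        if sum(self.n_offspring_per_pool) > self.n_offspring:
            raise ConfigurationError(
                "n_offspring must be at least the summed pool sizes"
            )

    @property
    def scaffold_names(self) -> list[str]:
        return [f"scaffold{i + 1:02d}" for i in range(self.n_scaffolds)]

    @property
    def scaffold_lengths(self) -> dict[str, int]:
        return {name: self.scaffold_length for name in self.scaffold_names}


@dataclass
class ParentalGenomes:
    """Phased parental haplotypes over a shared SNP map.

    ``haplotypes[s]`` has shape (4, n_sites): rows are parent-1 hap 1/2 and
    parent-2 hap 1/2 with allele codes 0/1; ``bases[s]`` (2, n_sites) maps the
    codes to nucleotides. ``qtl_site`` locates the trait site (scaffold index,
    site index); allele code 1 at that site is the dominant red allele R,
    carried on parent-1 haplotype 1.
    """

    scaffolds: list[str]
    positions: list[np.ndarray]
    haplotypes: list[np.ndarray]
    bases: list[np.ndarray]
    qtl_site: tuple[int, int]


@dataclass
class OffspringPopulation:
    """F1 genotypes (per scaffold: (n_offspring, 2, n_sites) allele codes) and phenotypes."""

    genotypes: list[np.ndarray]
    phenotype_red: np.ndarray
    qtl_dosage: np.ndarray


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset, for parameter-recovery tests."""

    qtl_scaffold: str
    qtl_position: int
    phenotype_red: np.ndarray
    pool_a_members: np.ndarray
    pool_b_members: np.ndarray
    positions: dict[str, np.ndarray]
    true_freq_a: dict[str, np.ndarray]
    true_freq_b: dict[str, np.ndarray]
    reference_breakpoints: dict[str, np.ndarray]


@dataclass
class SimResult:
    """A simulated dataset: variant records, ground truth, scaffold lengths."""

    variants: list[PooledVariant]
    truth: SimTruth
    scaffold_lengths: dict[str, int]
    config: CrossSimConfig


def simulate_parents(
    config: CrossSimConfig, rng: np.random.Generator
) -> ParentalGenomes:
    """Draw the SNP map and two phased heterozygous parental genomes."""
    positions: list[np.ndarray] = []
    haplotypes: list[np.ndarray] = []
    bases: list[np.ndarray] = []
    L = config.scaffold_length
    for s in range(config.n_scaffolds):
        n_raw = rng.poisson(L * config.snp_density)
        pos = np.unique(rng.integers(1, L + 1, size=n_raw))
        n = pos.size
        haps = np.empty((4, n), dtype=np.int8)
        for parent in range(2):
            het = rng.random(n) < config.parent_heterozygosity
            hom_allele = rng.integers(0, 2, size=n).astype(np.int8)
            phase = rng.integers(0, 2, size=n).astype(np.int8)
            hap1 = np.where(het, phase, hom_allele)
            hap2 = np.where(het, 1 - phase, hom_allele)
            haps[2 * parent] = hap1
            haps[2 * parent + 1] = hap2
        # Sites monomorphic across all four parental haplotypes can never be
        # called as variants in the cross.
        poly = ~((haps[0] == haps[1]) & (haps[1] == haps[2]) & (haps[2] == haps[3]))
        pos, haps = pos[poly], haps[:, poly]
        n = pos.size
        b0_idx = rng.integers(0, 4, size=n)
        b1_idx = (b0_idx + rng.integers(1, 4, size=n)) % 4
        site_bases = np.stack([_BASES[b0_idx], _BASES[b1_idx]])
        positions.append(pos)
        haplotypes.append(haps)
        bases.append(site_bases)

    if sum(p.size for p in positions) == 0:
        raise EmptyInputError("simulated SNP map is empty; raise snp_density")

    # Insert the trait site. Allele 1 = R (dominant red), on parent-1 hap 1.
    s = config.qtl_scaffold
    existing = positions[s] != config.qtl_position
    positions[s] = positions[s][existing]
    haplotypes[s] = haplotypes[s][:, existing]
    bases[s] = bases[s][:, existing]
    k = int(np.searchsorted(positions[s], config.qtl_position))
    qtl_haps = np.array([1, 0, 0, 0] if config.cross_type == "RrXrr" else [1, 0, 1, 0], dtype=np.int8)
    qtl_b0 = rng.integers(0, 4)
    qtl_bases = np.array([_BASES[qtl_b0], _BASES[(qtl_b0 + rng.integers(1, 4)) % 4]])
    positions[s] = np.insert(positions[s], k, config.qtl_position)
    haplotypes[s] = np.insert(haplotypes[s], k, qtl_haps, axis=1)
    bases[s] = np.insert(bases[s], k, qtl_bases, axis=1)

    return ParentalGenomes(
        scaffolds=config.scaffold_names,
        positions=positions,
        haplotypes=haplotypes,
        bases=bases,
        qtl_site=(s, k),
    )


def _recombinant_gamete(
    hap_top: np.ndarray,
    hap_bot: np.ndarray,
    positions: np.ndarray,
    scaffold_length: int,
    morgans: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One meiotic product: alternate between the two haplotypes at Poisson crossovers."""
    start = int(rng.integers(0, 2))
    n_co = int(rng.poisson(morgans))
    if n_co == 0:
        return (hap_top if start == 0 else hap_bot).copy()
    cuts = np.sort(rng.integers(1, scaffold_length + 1, size=n_co))
    segment = np.searchsorted(cuts, positions)
    sel = (start + segment) % 2
    return np.where(sel == 0, hap_top, hap_bot).astype(np.int8)


def simulate_offspring(
    parents: ParentalGenomes, config: CrossSimConfig, rng: np.random.Generator
) -> OffspringPopulation:
    """Generate F1 offspring genotypes and red/green phenotypes."""
    n = config.n_offspring
    L = config.scaffold_length
    morgans = L / 1e6 * config.recombination_rate / 100.0
    genotypes = [
        np.empty((n, 2, parents.positions[s].size), dtype=np.int8)
        for s in range(config.n_scaffolds)
    ]
    for i in range(n):
        for parent in range(2):
            for s in range(config.n_scaffolds):
                haps = parents.haplotypes[s]
                genotypes[s][i, parent] = _recombinant_gamete(
                    haps[2 * parent],
                    haps[2 * parent + 1],
                    parents.positions[s],
                    L,
                    morgans,
                    rng,
                )
    s, k = parents.qtl_site
    qtl_dosage = genotypes[s][:, :, k].astype(np.int64).sum(axis=1)
    red_true = qtl_dosage >= 1
    flips = rng.random(n) >= config.penetrance
    phenotype_red = red_true ^ flips
    return OffspringPopulation(
        genotypes=genotypes, phenotype_red=phenotype_red, qtl_dosage=qtl_dosage
    )


def build_pools_and_sequence(
    parents: ParentalGenomes,
    offspring: OffspringPopulation,
    config: CrossSimConfig,
    rng: np.random.Generator,
) -> tuple[list[PooledVariant], SimTruth]:
    """Pool extreme-phenotype offspring and draw pooled reads against the reference."""
    n_a, n_b = config.n_offspring_per_pool
    red_idx = np.flatnonzero(offspring.phenotype_red)
    green_idx = np.flatnonzero(~offspring.phenotype_red)
    if red_idx.size < n_a or green_idx.size < n_b:
        raise DataError(
            f"not enough offspring to fill the pools: "
            f"{red_idx.size} red / {green_idx.size} green available, "
            f"{n_a} + {n_b} requested"
        )
    pool_a = red_idx[:n_a]
    pool_b = green_idx[:n_b]

    e = config.sequencing_error
    variants: list[PooledVariant] = []
    true_freq_a: dict[str, np.ndarray] = {}
    true_freq_b: dict[str, np.ndarray] = {}
    breakpoints: dict[str, np.ndarray] = {}
    positions_out: dict[str, np.ndarray] = {}
    for s, name in enumerate(config.scaffold_names):
        pos = parents.positions[s]
        haps = parents.haplotypes[s]
        n_sites = pos.size
        if config.reference_mode == "parental":
            ref_sel = np.zeros(n_sites, dtype=np.int8)
            cuts = np.empty(0, dtype=np.int64)
        else:
            n_switch = int(rng.poisson(config.mosaic_switch_rate * config.scaffold_length / 1e6))
            cuts = np.sort(rng.integers(1, config.scaffold_length + 1, size=n_switch))
            start = int(rng.integers(0, 2))
            ref_sel = ((start + np.searchsorted(cuts, pos)) % 2).astype(np.int8)
        ref_code = np.where(ref_sel == 0, haps[0], haps[1]).astype(np.int8)
        alt_code = (1 - ref_code).astype(np.int8)

        pool_freqs = []
        pool_reads = []
        for members in (pool_a, pool_b):
            g = offspring.genotypes[s][members]  # (n_pool, 2, n_sites)
            alt_dosage = (g == alt_code).sum(axis=(0, 1))
            f = alt_dosage / (2.0 * members.size)
            depth = rng.poisson(config.mean_depth, size=n_sites)
            p_alt = f * (1.0 - e) + (1.0 - f) * e
            alt_reads = rng.binomial(depth, p_alt)
            pool_freqs.append(f)
            pool_reads.append((depth - alt_reads, alt_reads))

        ref_base = np.where(ref_code == 0, parents.bases[s][0], parents.bases[s][1])
        alt_base = np.where(ref_code == 0, parents.bases[s][1], parents.bases[s][0])
        (a_ref, a_alt), (b_ref, b_alt) = pool_reads
        for j in range(n_sites):
            variants.append(
                PooledVariant(
                    scaffold=name,
                    position=int(pos[j]),
                    ref_allele=str(ref_base[j]),
                    alt_allele=str(alt_base[j]),
                    depth_a_ref=int(a_ref[j]),
                    depth_a_alt=int(a_alt[j]),
                    depth_b_ref=int(b_ref[j]),
                    depth_b_alt=int(b_alt[j]),
                )
            )
        true_freq_a[name] = pool_freqs[0]
        true_freq_b[name] = pool_freqs[1]
        breakpoints[name] = cuts
        positions_out[name] = pos

    truth = SimTruth(
        qtl_scaffold=config.scaffold_names[config.qtl_scaffold],
        qtl_position=config.qtl_position,
        phenotype_red=offspring.phenotype_red,
        pool_a_members=pool_a,
        pool_b_members=pool_b,
        positions=positions_out,
        true_freq_a=true_freq_a,
        true_freq_b=true_freq_b,
        reference_breakpoints=breakpoints,
    )
    return variants, truth


def simulate_cross(
    config: CrossSimConfig, rng: np.random.Generator | None = None
) -> SimResult:
    """End-to-end simulation: parents -> offspring -> pools -> pooled reads."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    parents = simulate_parents(config, rng)
    offspring = simulate_offspring(parents, config, rng)
    variants, truth = build_pools_and_sequence(parents, offspring, config, rng)
    return SimResult(
        variants=variants,
        truth=truth,
        scaffold_lengths=config.scaffold_lengths,
        config=config,
    )


def write_truth(truth: SimTruth, path: str | Path) -> Path:
    """Ground-truth TSV: QTL location, pool composition, reference breakpoints."""
    path = Path(path)
    rows = [
        ("qtl_scaffold", truth.qtl_scaffold),
        ("qtl_position", str(truth.qtl_position)),
        ("n_red_offspring", str(int(truth.phenotype_red.sum()))),
        ("n_green_offspring", str(int((~truth.phenotype_red).sum()))),
        ("pool_a_members", ",".join(map(str, truth.pool_a_members))),
        ("pool_b_members", ",".join(map(str, truth.pool_b_members))),
    ]
    for name, cuts in truth.reference_breakpoints.items():
        rows.append((f"reference_breakpoints:{name}", ",".join(map(str, cuts))))
    with open(path, "w") as fh:
        fh.write("key\tvalue\n")
        for key, value in rows:
            fh.write(f"{key}\t{value}\n")
    return path


# ---------------------------------------------------------------------------
# Detection-power experiment
# ---------------------------------------------------------------------------


@dataclass
class PowerResult:
    """Replicate-level detection outcomes of the signed vs. absolute delta pipelines."""

    frame: pd.DataFrame  # columns: replicate, method, detected, total_candidate_bp

    def summary(self, alpha: float = 0.05) -> pd.DataFrame:
        """Detection rate per method with a Clopper-Pearson confidence interval."""
        rows = []
        for method, grp in self.frame.groupby("method"):
            n = len(grp)
            k = int(grp["detected"].sum())
            lo, hi = proportion_confint(k, n, alpha=alpha, method="beta")
            rows.append(
                {
                    "method": method,
                    "n_replicates": n,
                    "n_detected": k,
                    "detection_rate": k / n,
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                }
            )
        return pd.DataFrame(rows)

    def paired_pvalue(
        self,
        better: str = "abs_delta",
        worse: str = "delta",
        alternative: str = "greater",
    ) -> float:
        """Exact sign (McNemar) test on paired per-replicate detections.

        ``alternative='greater'`` tests whether ``better`` detects the locus in
        strictly more replicates than ``worse``; ``'two-sided'`` tests any
        difference. With no discordant replicates the p-value is 1.
        """
        wide = self.frame.pivot(index="replicate", columns="method", values="detected")
        b = int((wide[better] & ~wide[worse]).sum())
        c = int((~wide[better] & wide[worse]).sum())
        if b + c == 0:
            return 1.0
        return float(binomtest(b, b + c, 0.5, alternative=alternative).pvalue)


def _run_method(
    windows,
    kept_variants,
    truth: SimTruth,
    method: str,
    abs_upper_q: float,
    delta_upper_q: float,
    delta_lower_q: float,
    sparsity: SparsityPolicy,
) -> tuple[bool, float]:
    if method == "abs_delta":
        thresholds = quantile_thresholds(windows, "abs_delta", upper_q=abs_upper_q)
    elif method == "delta":
        thresholds = quantile_thresholds(
            windows, "delta", upper_q=delta_upper_q, lower_q=delta_lower_q
        )
    else:
        raise ConfigurationError(f"unknown method {method!r}")
    flags = flag_windows(windows, thresholds)
    raw = call_intervals(windows, flags)
    kept = filter_sparse(raw, kept_variants, sparsity).kept
    detected = any(
        iv.scaffold == truth.qtl_scaffold and iv.start <= truth.qtl_position <= iv.end
        for iv in kept
    )
    return detected, total_length(kept, unit="bp", mode="inclusive")


def power_experiment(
    config: CrossSimConfig,
    n_replicates: int,
    methods: Sequence[str] = ("delta", "abs_delta"),
    *,
    window_size: int = DEFAULT_WINDOW_SIZE,
    step: int = DEFAULT_STEP,
    filter_policy: FilterPolicy | None = None,
    min_snps_per_window: int = 1,
    abs_upper_q: float = 0.005,
    delta_upper_q: float = 0.0025,
    delta_lower_q: float = 0.0025,
    sparsity: SparsityPolicy | None = None,
) -> PowerResult:
    """Replicate the full pipeline and record per-method QTL detection.

    Each replicate simulates one dataset from ``config`` (with a per-replicate
    seed derived from ``config.seed``), filters it, computes the window grid
    once, then calls candidate intervals with each method's thresholds: the top
    ``abs_upper_q`` |delta| windows, or the two-tailed
    ``delta_upper_q``/``delta_lower_q`` signed-delta windows. Detection means a
    called interval covers the true trait position.
    """
    if config.snp_density <= 0:
        raise EmptyInputError("snp_density must be positive to run a power experiment")
    if n_replicates < 1:
        raise ConfigurationError("n_replicates must be >= 1")
    filter_policy = filter_policy or FilterPolicy()
    sparsity = sparsity or SparsityPolicy()
    rows = []
    for rep in range(n_replicates):
        rng = np.random.default_rng([rep, config.seed])
        sim = simulate_cross(config, rng=rng)
        kept = apply_filters(sim.variants, filter_policy).kept
        windows = sliding_window_analysis(
            kept,
            sim.scaffold_lengths,
            window_size=window_size,
            step=step,
            min_snps=min_snps_per_window,
        )
        for method in methods:
            detected, total_bp = _run_method(
                windows,
                kept,
                sim.truth,
                method,
                abs_upper_q,
                delta_upper_q,
                delta_lower_q,
                sparsity,
            )
            rows.append(
                {
                    "replicate": rep,
                    "method": method,
                    "detected": detected,
                    "total_candidate_bp": total_bp,
                }
            )
    return PowerResult(frame=pd.DataFrame(rows))
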