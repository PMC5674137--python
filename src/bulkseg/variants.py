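"""Pooled-variant I/O and quality filtering for two-bulk sequencing designs.

A bulked-segregant (QTL-seq) experiment sequences two DNA pools of offspring with
opposite phenotypes. Each biallelic site carries per-pool reference/alternate read
depths, from which the per-pool SNP-index (fraction of reads showing the
non-reference allele) is derived: 0 means every read matches the reference, 1 means
every read differs. Missing values -- a pool with zero coverage at a site -- are
represented as ``float('nan')`` throughout the package.

Inputs are standard multi-sample VCF 4.x with per-sample ``AD`` fields (read via
cyvcf2) or a plain tab-separated table with one row per site. Quality filtering
follows common QTL-seq practice: drop sites that are low-depth, low-index in both
pools, or covered in only one pool.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, EmptyInputError

log = logging.getLogger(__name__)

#: Column order of the tab-separated variant-table format.
TABLE_COLUMNS = ("scaffold", "pos", "ref", "alt", "a_ref", "a_alt", "b_ref", "b_alt")

INDEX_RULES = ("both_pools_below", "either_pool_below")
DEPTH_RULES = ("either_pool_below", "both_pools_below", "combined_below")


def compute_snp_index(alt_depth: int, ref_depth: int) -> float:
    """Fraction of reads carrying the non-reference allele at one site in one pool.

    Parameters
    ----------
    alt_depth, ref_depth
        Non-negative read counts supporting the alternate and reference allele.

    Returns
    -------
    float
        ``alt_depth / (alt_depth + ref_depth)``; equal to 1.0 when all reads
        differ from the reference and 0.0 when all reads match it. ``nan`` when
        the site has no coverage.
    """
    if alt_depth < 0 or ref_depth < 0:
        raise ValueError(
            f"read depths must be non-negative, got alt={alt_depth}, ref={ref_depth}"
        )
    total = alt_depth + ref_depth
    if total == 0:
        return math.nan
    return alt_depth / total


@dataclass(frozen=True, slots=True)
class PooledVariant:
    """One biallelic site with per-pool allele depths.

    Coordinates are 1-based inclusive. The per-pool SNP-indices are derived
    properties, so they can never disagree with the stored depths.
    """

    scaffold: str
    position: int
    ref_allele: str
    alt_allele: str
    depth_a_ref: int
    depth_a_alt: int
    depth_b_ref: int
    depth_b_alt: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if (
            self.depth_a_ref < 0
            or self.depth_a_alt < 0
            or self.depth_b_ref < 0
            or self.depth_b_alt < 0
        ):
            raise ValueError("read depths must be non-negative")

    @property
    def depth_a(self) -> int:
        """Total pool-A read depth."""
        return self.depth_a_ref + self.depth_a_alt

    @property
    def depth_b(self) -> int:
        """Total pool-B read depth."""
        return self.depth_b_ref + self.depth_b_alt

    @property
    def index_a(self) -> float:
        """Pool-A SNP-index (nan when pool A has no coverage)."""
        return compute_snp_index(self.depth_a_alt, self.depth_a_ref)

    @property
    def index_b(self) -> float:
        """Pool-B SNP-index (nan when pool B has no coverage)."""
        return compute_snp_index(self.depth_b_alt, self.depth_b_ref)


@dataclass(frozen=True)
class FilterPolicy:
    """Low-quality site filters.

    Defaults mirror standard QTL-seq cleanup: drop sites with SNP-index < 0.3
    (uninformative in both bulks under the default rule), total depth < 7 in a
    pool, or no SNP-index in one of the pools.
    """

    min_index: float = 0.3
    min_depth: int = 7
    drop_if_missing_in_one_pool: bool = True
    index_rule: str = "both_pools_below"
    depth_rule: str = "either_pool_below"

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_index <= 1.0:
            raise ConfigurationError(f"min_index must be in [0, 1], got {self.min_index}")
        if self.min_depth < 0:
            raise ConfigurationError(f"min_depth must be >= 0, got {self.min_depth}")
        if self.index_rule not in INDEX_RULES:
            raise ConfigurationError(f"index_rule must be one of {INDEX_RULES}")
        if self.depth_rule not in DEPTH_RULES:
            raise ConfigurationError(f"depth_rule must be one of {DEPTH_RULES}")


@dataclass
class FilterResult:
    """Partition of the input produced by :func:`apply_filters`.

    ``reasons[i]`` is the single drop reason for ``dropped[i]``; input order is
    preserved within both partitions.
    """

    kept: list[PooledVariant]
    dropped: list[PooledVariant]
    reasons: list[str]

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for reason in self.reasons:
            out[reason] = out.get(reason, 0) + 1
        return out


def _drop_reason(v: PooledVariant, policy: FilterPolicy) -> str | None:
    ia, ib = v.index_a, v.index_b
    missing_a, missing_b = math.isnan(ia), math.isnan(ib)
    if policy.drop_if_missing_in_one_pool and (missing_a or missing_b):
        return "missing_index"

    if policy.depth_rule == "either_pool_below":
        low_depth = v.depth_a < policy.min_depth or v.depth_b < policy.min_depth
    elif policy.depth_rule == "both_pools_below":
        low_depth = v.depth_a < policy.min_depth and v.depth_b < policy.min_depth
    else:  # combined_below
        low_depth = v.depth_a + v.depth_b < policy.min_depth
    if low_depth:
        return "low_depth"

    # nan comparisons are False, so a missing index never counts as "below".
    below_a = ia < policy.min_index
    below_b = ib < policy.min_index
    if policy.index_rule == "both_pools_below":
        low_index = below_a and below_b
    else:
        low_index = below_a or below_b
    if low_index:
        return "low_index"
    return None


def apply_filters(
    variants: Iterable[PooledVariant], policy: FilterPolicy | None = None
) -> FilterResult:
    """Partition variants into kept and dropped sets under ``policy``.

    Idempotent: re-filtering the kept set drops nothing.
    """
    policy = policy or FilterPolicy()
    kept: list[PooledVariant] = []
    dropped: list[PooledVariant] = []
    reasons: list[str] = []
    for v in variants:
        reason = _drop_reason(v, policy)
        if reason is None:
            kept.append(v)
        else:
            dropped.append(v)
            reasons.append(reason)
    return FilterResult(kept=kept, dropped=dropped, reasons=reasons)


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------


def _infer_format(path: Path) -> str:
    name = path.name
    if name.endswith(".vcf") or name.endswith(".vcf.gz") or name.endswith(".bcf"):
        return "vcf"
    return "table"


def read_variants(
    path: str | Path,
    pool_a: str | None = None,
    pool_b: str | None = None,
    format: str | None = None,
) -> list[PooledVariant]:
    """Read pooled variant records from a VCF or a tab-separated table.

    Parameters
    ----------
    path
        Input file. Format inferred from the suffix unless ``format`` is given.
    pool_a, pool_b
        VCF sample names of the two pools (required for VCF input). Pool A is
        the pool whose index enters delta computations with a positive sign.
    format
        ``"vcf"`` or ``"table"``.

    Returns
    -------
    list of :class:`PooledVariant`, sorted by (scaffold, position).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file does not exist: {path}")
    fmt = format or _infer_format(path)
    if fmt == "vcf":
        if pool_a is None or pool_b is None:
            raise ConfigurationError("VCF input requires pool_a and pool_b sample names")
        variants = _read_vcf(path, pool_a, pool_b)
    elif fmt == "table":
        variants = _read_table(path)
    else:
        raise ConfigurationError(f"unknown variant format: {fmt!r}")
    variants.sort(key=lambda v: (v.scaffold, v.position))
    if not variants:
        raise EmptyInputError(f"no parsable variant records in {path}")
    return variants


def _read_vcf(path: Path, pool_a: str, pool_b: str) -> list[PooledVariant]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for name in (pool_a, pool_b):
        if name not in samples:
            raise ConfigurationError(
                f"sample {name!r} not found in {path} (samples: {samples})"
            )
    ia, ib = samples.index(pool_a), samples.index(pool_b)

    out: list[PooledVariant] = []
    n_multi = 0
    for rec in vcf:
        alts = rec.ALT
        if not alts:
            continue
        ad = rec.format("AD")
        if ad is None:
            depths = np.zeros((len(samples), len(alts) + 1), dtype=int)
        else:
            depths = np.asarray(ad, dtype=np.int64)
            depths = np.where(depths < 0, 0, depths)  # negative = missing sentinel
        if len(alts) > 1:
            # Keep only the alt allele with the most supporting reads over both
            # pools; the window statistics are defined on biallelic indices.
            support = depths[ia, 1:] + depths[ib, 1:]
            k = int(np.argmax(support))
            n_multi += 1
        else:
            k = 0
        out.append(
            PooledVariant(
                scaffold=rec.CHROM,
                position=rec.POS,
                ref_allele=rec.REF,
                alt_allele=alts[k],
                depth_a_ref=int(depths[ia, 0]),
                depth_a_alt=int(depths[ia, k + 1]),
                depth_b_ref=int(depths[ib, 0]),
                depth_b_alt=int(depths[ib, k + 1]),
            )
        )
    if n_multi:
        log.info("reduced %d multi-allelic sites to their best-supported alt allele", n_multi)
    return out


def _read_table(path: Path) -> list[PooledVariant]:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pandas raises several parser error types
        raise DataError(f"could not parse variant table {path}: {exc}") from exc
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"variant table {path} lacks required columns: {missing}")
    out: list[PooledVariant] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            out.append(
                PooledVariant(
                    scaffold=str(row.scaffold),
                    position=int(row.pos),
                    ref_allele=str(row.ref),
                    alt_allele=str(row.alt),
                    depth_a_ref=int(row.a_ref),
                    depth_a_alt=int(row.a_alt),
                    depth_b_ref=int(row.b_ref),
                    depth_b_alt=int(row.b_alt),
                )
            )
        except (ValueError, TypeError) as exc:
            # +2: one for the header line, one for 1-based numbering
            raise DataError(f"malformed record at {path} line {i + 2}: {exc}") from exc
    return out


def read_scaffold_lengths(path: str | Path) -> dict[str, int]:
    """Read a scaffold-length table (FASTA ``.fai`` style: name, length, ...).

    Only the first two columns are used; an optional header row is tolerated.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"scaffold-length file does not exist: {path}")
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise DataError(f"{path}: expected at least two tab-separated columns")
    rows = df.itertuples(index=False)
    lengths: dict[str, int] = {}
    for i, row in enumerate(rows):
        try:
            length = int(row[1])
        except (ValueError, TypeError):
            if i == 0:
                continue  # header row
            raise DataError(f"{path} line {i + 1}: non-integer scaffold length {row[1]!r}")
        if length < 1:
            raise DataError(f"{path} line {i + 1}: scaffold length must be >= 1")
        lengths[str(row[0])] = length
    if not lengths:
        raise EmptyInputError(f"no scaffold lengths in {path}")
    return lengths


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def write_variants(
    variants: Sequence[PooledVariant],
    path: str | Path,
    format: str | None = None,
    sample_names: tuple[str, str] = ("pool_a", "pool_b"),
    scaffold_lengths: dict[str, int] | None = None,
) -> Path:
    """Write variants as VCF 4.2 (two samples with AD fields) or as a TSV table.

    The output round-trips through :func:`read_variants`.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "vcf":
        _write_vcf(variants, path, sample_names, scaffold_lengths)
    elif fmt == "table":
        _write_table(variants, path)
    else:
        raise ConfigurationError(f"unknown variant format: {fmt!r}")
    return path


def _write_vcf(
    variants: Sequence[PooledVariant],
    path: Path,
    sample_names: tuple[str, str],
    scaffold_lengths: dict[str, int] | None,
) -> None:
    if scaffold_lengths is None:
        scaffold_lengths = {}
        for v in variants:
            scaffold_lengths[v.scaffold] = max(
                scaffold_lengths.get(v.scaffold, 0), v.position
            )
    lines = [
        "##fileformat=VCFv4.2",
        "##source=bulkseg",
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description='
        '"Allelic depths for the ref and alt alleles in the order listed">',
    ]
    for name, length in scaffold_lengths.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_names)
    )
    for v in variants:
        lines.append(
            f"{v.scaffold}\t{v.position}\t.\t{v.ref_allele}\t{v.alt_allele}\t.\t.\t.\t"
            f"AD\t{v.depth_a_ref},{v.depth_a_alt}\t{v.depth_b_ref},{v.depth_b_alt}"
        )
    path.write_text("\n".join(lines) + "\n")


def _write_table(variants: Sequence[PooledVariant], path: Path) -> None:
    df = pd.DataFrame(
        {
            "scaffold": [v.scaffold for v in variants],
            "pos": [v.position for v in variants],
            "ref": [v.ref_allele for v in variants],
            "alt": [v.alt_allele for v in variants],
            "a_ref": [v.depth_a_ref for v in variants],
            "a_alt": [v.depth_a_alt for v in variants],
            "b_ref": [v.depth_b_ref for v in variants],
            "b_alt": [v.depth_b_alt for v in variants],
        }
    )
    df.to_csv(path, sep="\t", index=False)
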