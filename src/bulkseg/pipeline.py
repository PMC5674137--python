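"""End-to-end runs: variants -> filters -> windows -> thresholds -> intervals.

`run_qtlseq` ties the analysis modules into one deterministic pass over a pooled
variant file and writes a report bundle (window TSV, candidate intervals in BED
and a human-readable table, machine-readable JSON summary, run log, optional
per-scaffold plots). `run_simulate` wraps the cross simulator and writes a
dataset bundle (VCF + truth + scaffold lengths) consumable by `run_qtlseq`.

All outputs except the timestamped log are byte-identical across reruns with the
same inputs; partial outputs are removed if a run fails.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .intervals import (
    SparsityPolicy,
    call_intervals,
    filter_sparse,
    format_length,
    total_length,
    write_intervals_bed,
    write_intervals_tsv,
)
from .simulate import CrossSimConfig, SimResult, simulate_cross, write_truth
from .variants import (
    FilterPolicy,
    apply_filters,
    read_scaffold_lengths,
    read_variants,
    write_variants,
)
from .windows import (
    DEFAULT_STEP,
    DEFAULT_WINDOW_SIZE,
    flag_windows,
    quantile_thresholds,
    sliding_window_analysis,
    write_windows_tsv,
)

log = logging.getLogger(__name__)

SUMMARY_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Parameters of one QTL-seq analysis run.

    ``pool_a`` is the pool whose SNP-index enters delta with a positive sign
    (the pool orientation); it is echoed into every report because the sign of
    delta is uninterpretable without it.
    """

    variants: str | Path
    scaffold_lengths: str | Path
    out_dir: str | Path
    pool_a: str = "pool_red"
    pool_b: str = "pool_green"
    format: str | None = None  # None = infer from suffix
    filter_policy: FilterPolicy = field(default_factory=FilterPolicy)
    window_size: int = DEFAULT_WINDOW_SIZE
    step: int = DEFAULT_STEP
    min_snps_per_window: int = 1
    statistic: str = "abs_delta"
    upper_quantile: float = 0.005
    lower_quantile: float | None = None
    sparsity: SparsityPolicy = field(default_factory=SparsityPolicy)
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from a YAML mapping; nested filter/sparsity blocks allowed."""
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: expected a YAML mapping")
        if "filter_policy" in data:
            data["filter_policy"] = FilterPolicy(**data["filter_policy"])
        if "sparsity" in data:
            data["sparsity"] = SparsityPolicy(**data["sparsity"])
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigurationError(f"{path}: {exc}") from exc

    def parameters(self) -> dict:
        """JSON-serializable echo of every parameter."""
        out = dataclasses.asdict(self)
        out["variants"] = str(self.variants)
        out["scaffold_lengths"] = str(self.scaffold_lengths)
        out["out_dir"] = str(self.out_dir)
        return out


@dataclass
class QtlseqResult:
    """In-memory results of :func:`run_qtlseq` plus the paths written."""

    windows: list
    thresholds: object
    flags: object
    intervals_raw: list
    intervals: list
    summary: dict
    paths: dict[str, Path]


def run_qtlseq(config: PipelineConfig) -> QtlseqResult:
    """Run the full windowed-BSA analysis and write the report bundle.

    Raises :class:`bulkseg.errors.DataError` subclasses on malformed or empty
    input; no partial outputs remain after a failure.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger = logging.getLogger("bulkseg.pipeline.run")
    logger.setLevel(logging.INFO)
    logger.addHandler(handler)

    written: list[Path] = [log_path]
    try:
        logger.info("parameters: %s", json.dumps(config.parameters(), sort_keys=True))

        scaffold_lengths = read_scaffold_lengths(config.scaffold_lengths)
        variants = read_variants(
            config.variants, pool_a=config.pool_a, pool_b=config.pool_b, format=config.format
        )
        logger.info("read %d variant records on %d scaffolds", len(variants), len(scaffold_lengths))

        filtered = apply_filters(variants, config.filter_policy)
        logger.info(
            "filters kept %d / %d records (dropped: %s)",
            len(filtered.kept),
            len(variants),
            filtered.counts(),
        )

        windows = sliding_window_analysis(
            filtered.kept,
            scaffold_lengths,
            window_size=config.window_size,
            step=config.step,
            min_snps=config.min_snps_per_window,
        )
        thresholds = quantile_thresholds(
            windows,
            statistic=config.statistic,
            upper_q=config.upper_quantile,
            lower_q=config.lower_quantile,
        )
        flags = flag_windows(windows, thresholds)
        logger.info(
            "thresholds on %s: upper=%.6g lower=%s; %d / %d windows flagged",
            config.statistic,
            thresholds.upper_value,
            "none" if math.isnan(thresholds.lower_value) else f"{thresholds.lower_value:.6g}",
            int(flags.sum()),
            len(windows),
        )

        intervals_raw = call_intervals(windows, flags)
        sparse = filter_sparse(intervals_raw, filtered.kept, config.sparsity)
        intervals = sparse.kept
        total_bp = total_length(intervals, unit="bp", mode="inclusive")
        logger.info(
            "%d raw intervals -> %d after sparsity filter (total %s)",
            len(intervals_raw),
            len(intervals),
            format_length(total_bp, "Mb"),
        )

        summary = {
            "schema_version": SUMMARY_SCHEMA_VERSION,
            "parameters": config.parameters(),
            "pool_orientation": {"pool_a": config.pool_a, "pool_b": config.pool_b},
            "n_variants_input": len(variants),
            "n_variants_kept": len(filtered.kept),
            "drop_counts": filtered.counts(),
            "n_windows": len(windows),
            "n_windows_flagged": int(flags.sum()),
            "thresholds": {
                "statistic": thresholds.statistic,
                "upper_quantile": thresholds.upper_quantile,
                "lower_quantile": thresholds.lower_quantile,
                "upper_value": thresholds.upper_value,
                "lower_value": None
                if math.isnan(thresholds.lower_value)
                else thresholds.lower_value,
            },
            "n_intervals_raw": len(intervals_raw),
            "n_intervals_dropped_sparse": len(sparse.dropped),
            "intervals": [
                {
                    "scaffold": iv.scaffold,
                    "start": iv.start,
                    "end": iv.end,
                    "length_bp_inclusive": iv.length_bp,
                    "length_bp_difference": iv.end - iv.start,
                    "n_snps": iv.n_snps,
                }
                for iv in intervals
            ],
            "total_candidate_bp_inclusive": int(total_bp),
            "total_candidate_display": format_length(total_bp, "Mb"),
        }

        paths = {
            "windows": out_dir / "windows.tsv",
            "intervals_bed": out_dir / "intervals.bed",
            "intervals_tsv": out_dir / "intervals.tsv",
            "summary": out_dir / "summary.json",
            "log": log_path,
        }
        write_windows_tsv(windows, paths["windows"])
        written.append(paths["windows"])
        write_intervals_bed(intervals, paths["intervals_bed"])
        written.append(paths["intervals_bed"])
        write_intervals_tsv(intervals, paths["intervals_tsv"])
        written.append(paths["intervals_tsv"])
        paths["summary"].write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        written.append(paths["summary"])

        if config.make_plots:
            from .plotting import plot_scaffold_tracks

            plot_dir = out_dir / "plots"
            plot_dir.mkdir(exist_ok=True)
            for scaffold in scaffold_lengths:
                p = plot_dir / f"{scaffold}.png"
                plot_scaffold_tracks(windows, scaffold, thresholds=thresholds, path=p)
                written.append(p)
                paths[f"plot:{scaffold}"] = p

        logger.info("run complete: %s", paths["summary"])
        return QtlseqResult(
            windows=windows,
            thresholds=thresholds,
            flags=flags,
            intervals_raw=intervals_raw,
            intervals=intervals,
            summary=summary,
            paths=paths,
        )
    except Exception:
        for p in written:
            try:
                p.unlink(missing_ok=True)
            except OSError:
                pass
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


@dataclass
class SimulateResult:
    """Paths of a written simulated dataset plus the in-memory simulation."""

    sim: SimResult
    paths: dict[str, Path]


def run_simulate(
    config: CrossSimConfig,
    out_dir: str | Path,
    sample_names: tuple[str, str] = ("pool_red", "pool_green"),
) -> SimulateResult:
    """Simulate a cross and write VCF + truth + scaffold-length table.

    Deterministic given ``config.seed``; the seed and all parameters are echoed
    into ``sim_config.json`` so any dataset can be regenerated from its bundle.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim = simulate_cross(config)
    paths = {
        "vcf": out_dir / "pools.vcf",
        "truth": out_dir / "truth.tsv",
        "scaffold_lengths": out_dir / "scaffold_lengths.tsv",
        "config": out_dir / "sim_config.json",
    }
    write_variants(
        sim.variants,
        paths["vcf"],
        format="vcf",
        sample_names=sample_names,
        scaffold_lengths=sim.scaffold_lengths,
    )
    write_truth(sim.truth, paths["truth"])
    with open(paths["scaffold_lengths"], "w") as fh:
        for name, length in sim.scaffold_lengths.items():
            fh.write(f"{name}\t{length}\n")
    cfg = dataclasses.asdict(config)
    cfg["samples"] = {"pool_a": sample_names[0], "pool_b": sample_names[1]}
    paths["config"].write_text(json.dumps(cfg, indent=2, sort_keys=True) + "\n")
    log.info("simulated dataset written to %s (%d variants)", out_dir, len(sim.variants))
    return SimulateResult(sim=sim, paths=paths)
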