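"""End-to-end pipeline: files in, artifact bundle + manifest out.

Thin orchestration over :class:`mbresil.model.MicrobiomeResilience` for
shell/CLI use: reads the abundance and metadata tables, fits the analysis,
and writes every intermediate (selected taxa, trajectories, FPCA model,
scores with outlier flags, correlations, summary) into an output directory
together with a manifest recording the package version, the configuration
and its hash.  Outputs are deterministic: identical inputs and configuration
produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from . import io as _io
from .compositions import ZeroReplacementParams
from .model import MicrobiomeResilience, ResilienceResults

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("mbresil")


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end run; mirrors the CLI flags and YAML keys."""

    zero_method: str = "multiplicative"
    zero_delta: float | str = "auto"
    lra_threshold: float = 0.9
    baseline_mode: str = "per_condition"
    fixed_baseline: str | None = None
    baseline_condition: str | None = None
    include_t0: bool = True
    missing: str = "drop"
    K: int = 2
    fpca_weights: str = "trapezoid"
    bagplot_min_n: int = 10
    fence_factor: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.lra_threshold <= 1):
            raise ValueError("lra_threshold must be in (0, 1]")
        if self.K < 1:
            raise ValueError("K must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls().__dict__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def run_pipeline(
    table_path: str | Path,
    meta_path: str | Path,
    outdir: str | Path,
    config: PipelineConfig | None = None,
) -> ResilienceResults:
    """Execute the full analysis on files and write all artifacts.

    Writes into ``outdir``: ``selected_taxa.tsv``, ``positive_table.tsv``,
    ``trajectories.csv``, ``fpca_model.json``, ``scores.csv``,
    ``correlations.csv``, ``group_summary.csv``, ``summary.txt`` and
    ``manifest.json``.  Stage timings and record counts are logged.
    """
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def _stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        logger.info("stage %-12s %.3fs", name, time.perf_counter() - t0)
        return result

    table = _stage("read_table", lambda: _io.read_abundance_table(table_path))
    meta = _stage("read_meta", lambda: _io.read_metadata(meta_path))
    logger.info("loaded %d samples × %d taxa", table.n_samples, table.n_taxa)

    model = MicrobiomeResilience(
        table,
        meta,
        zero_replacement=ZeroReplacementParams(
            method=config.zero_method, delta=config.zero_delta
        ),
        lra_threshold=config.lra_threshold,
        baseline_mode=config.baseline_mode,  # type: ignore[arg-type]
        fixed_baseline=config.fixed_baseline,
        baseline_condition=config.baseline_condition,
        include_t0=config.include_t0,
        missing=config.missing,  # type: ignore[arg-type]
        K=config.K,
        fpca_weights=config.fpca_weights,  # type: ignore[arg-type]
        bagplot_min_n=config.bagplot_min_n,
        fence_factor=config.fence_factor,
    )
    results = _stage("fit", model.fit)
    logger.info(
        "selected %d/%d taxa, %d trajectories, FPCA explains %s",
        len(results.selected_taxa),
        table.n_taxa,
        len(results.trajectories),
        "/".join(f"{f:.1%}" for f in results.explained_fractions),
    )

    def _write():
        results.ranked_taxa().to_csv(
            outdir / "selected_taxa.tsv", sep="\t", index=False,
            float_format=_io.FLOAT_FORMAT,
        )
        _io.write_abundance_table(results.positive_table, outdir / "positive_table.tsv")
        _io.write_trajectories(results.trajectories, outdir / "trajectories.csv")
        _io.write_fpca_model(results.fpca, outdir / "fpca_model.json")
        _io.write_scores(results.scores, outdir / "scores.csv")
        if results.correlations is not None:
            results.correlations.to_csv(
                outdir / "correlations.csv", float_format=_io.FLOAT_FORMAT
            )
        results.group_summary.to_csv(
            outdir / "group_summary.csv", index=False, float_format=_io.FLOAT_FORMAT
        )
        (outdir / "summary.txt").write_text(results.summary() + "\n", encoding="utf-8")
        manifest = {
            "package": "mbresil",
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "n_samples": table.n_samples,
            "n_taxa": table.n_taxa,
            "n_trajectories": len(results.trajectories),
        }
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")

    _stage("write", _write)
    return results
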