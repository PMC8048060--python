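"""End-to-end orchestration: distances -> summary -> classification -> fragments.

A single :func:`run_pipeline` call reads the alignment, label table and
reference designations, runs every analysis stage, and writes one report
bundle plus a manifest (config echo, seed, input checksums, package version)
sufficient to re-run the analysis exactly.  Any stage failure aborts with
the stage name and cause; outputs already written are kept alongside a
``FAILED`` marker file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from . import classify as _classify
from . import diagnostics as _diagnostics
from . import distances as _distances
from . import io as _io
from . import summary as _summary
from .errors import BarcodegapError, ConfigError

logger = logging.getLogger(__name__)


class StageError(BarcodegapError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    alignment_path: Path
    labels_path: Path
    references_path: Path
    out_dir: Path
    exclude_species: tuple[str, ...] = ()
    genus_cutoff: float = _classify.DEFAULT_GENUS_CUTOFF
    tie_epsilon: float = 0.0
    merge_gap: int = 5
    min_diag: int = 2
    fragment_species: tuple[str, ...] = ()
    bootstrap_replicates: int = 0
    seed: int = 0
    strict: bool = True
    percent: bool = True

    def __post_init__(self) -> None:
        for p in (self.alignment_path, self.labels_path, self.references_path):
            if not Path(p).exists():
                raise ConfigError(f"input path does not exist: {p}")
        if not 0.0 <= self.genus_cutoff <= 1.0:
            raise ConfigError("genus_cutoff must be in [0, 1]")
        if self.tie_epsilon < 0:
            raise ConfigError("tie_epsilon must be >= 0")
        if self.min_diag < 2:
            raise ConfigError("min_diag must be >= 2")
        if self.merge_gap < 0:
            raise ConfigError("merge_gap must be >= 0")
        if self.bootstrap_replicates < 0:
            raise ConfigError("bootstrap_replicates must be >= 0")


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run all stages and write the report bundle into ``config.out_dir``.

    Returns a mapping from output name to written path.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stage = "io"
    t_start = time.perf_counter()
    try:
        alignment = _io.read_alignment(config.alignment_path)
        labels = _io.read_labels(config.labels_path, alignment, strict=config.strict)
        designations = _io.read_references(config.references_path, labels)
        logger.info(
            "io: %d sequences x %d columns, %d species",
            alignment.n_rows, alignment.n_columns, len(labels.species()),
        )

        stage = "distances"
        t0 = time.perf_counter()
        dm = _distances.distance_matrix(alignment)
        if config.bootstrap_replicates > 0:
            se = _distances.bootstrap_se_matrix(
                alignment, config.bootstrap_replicates, seed=config.seed
            )
            dm = dataclasses.replace(dm, se=se)
        outputs["distances"] = out / "distances.tsv"
        dm.write_long_tsv(outputs["distances"], percent=config.percent)
        outputs["distances_square"] = out / "distances_square.tsv"
        dm.write_square_tsv(outputs["distances_square"], percent=config.percent)
        logger.info("distances: %.2fs", time.perf_counter() - t0)

        stage = "summary"
        t0 = time.perf_counter()
        summ = _summary.summarize(dm, labels, exclude_species=config.exclude_species)
        outputs["summary"] = out / "summary.tsv"
        summ.write_tsv(outputs["summary"], percent=config.percent)
        outputs["summary_json"] = out / "summary.json"
        summ.write_json(outputs["summary_json"])
        logger.info(
            "summary: cutoff %.2f%%, gap_ok=%s (%.2fs)",
            summ.cutoff * 100, summ.gap_ok, time.perf_counter() - t0,
        )

        stage = "classify"
        t0 = time.perf_counter()
        panel = _classify.build_reference_set(alignment, labels, designations)
        results = _classify.classify_all(
            alignment, labels, panel,
            genus_cutoff=config.genus_cutoff, tie_epsilon=config.tie_epsilon,
        )
        report = _classify.mislabel_report(results, labels)
        outputs["classification"] = out / "classification.tsv"
        _classify.write_classification_tsv(
            results, outputs["classification"], percent=config.percent
        )
        outputs["mislabel_report"] = out / "mislabel_report.json"
        _classify.write_report_json(report, outputs["mislabel_report"])
        logger.info(
            "classify: %d mislabeled of %d (%.2fs)",
            report["totals"]["mislabeled"], report["n_queries"],
            time.perf_counter() - t0,
        )

        stage = "fragments"
        t0 = time.perf_counter()
        fragments = _diagnostics.find_diagnostic_fragments(
            alignment, labels,
            species_set=config.fragment_species or None,
            min_diag=config.min_diag, merge_gap=config.merge_gap,
        )
        outputs["fragments"] = out / "fragments.tsv"
        _io.write_fragments_table(fragments, outputs["fragments"])
        logger.info("fragments: %d found (%.2fs)", len(fragments), time.perf_counter() - t0)

        stage = "manifest"
        manifest = {
            "package": "barcodegap",
            "version": __version__,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
            "seed": config.seed,
            "config": {
                k: (str(v) if isinstance(v, Path) else list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(config).items()
            },
            "input_checksums": {
                "alignment": _sha256(config.alignment_path),
                "labels": _sha256(config.labels_path),
                "references": _sha256(config.references_path),
            },
            "outputs": {k: str(v) for k, v in outputs.items()},
        }
        outputs["manifest"] = out / "manifest.json"
        outputs["manifest"].write_text(json.dumps(manifest, indent=2) + "\n")
    except Exception as exc:
        marker = out / "FAILED"
        marker.write_text(f"stage: {stage}\ncause: {exc}\n")
        raise StageError(stage, exc) from exc

    logger.info("pipeline done in %.2fs", time.perf_counter() - t_start)
    return outputs
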