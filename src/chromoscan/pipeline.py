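"""End-to-end pipeline: clean -> quantify -> coverage profiles ->
tandem/screen on contigs, driven by a single declarative YAML config so
every threshold lives in one auditable place.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .align import ScoringScheme
from .classify import quantify
from .coverage import (
    detect_enriched_segments,
    profile,
    write_bedgraph,
    write_segments_bed,
)
from .library import RepeatLibrary, load_library
from .qc import QCParams, clean_readset, parse_fastq, write_fastq
from .screen import ScreenCriteria, screen_batch, write_screen_tsv
from .simulate import generate_library
from .tandem import TRCriteria, find_tandem_arrays, write_arrays_gff3


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    reads: str
    outdir: str
    library_fasta: str | None = None  # None -> synthetic default library
    library_meta: str | None = None
    contigs: str | None = None
    seed: int = 0
    qc: QCParams = field(default_factory=QCParams)
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    tr_criteria: TRCriteria = field(default_factory=TRCriteria)
    screen_criteria: list[ScreenCriteria] = field(default_factory=list)
    profile_consensuses: list[str] = field(default_factory=list)
    smooth_window: int = 101
    fold_threshold: float = 3.0
    min_segment_len: int = 200

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw = dict(raw)
        if "qc" in kw:
            q = dict(kw["qc"])
            if "adapters" in q:
                q["adapters"] = frozenset(q["adapters"])
            kw["qc"] = QCParams(**q)
        if "scheme" in kw:
            kw["scheme"] = ScoringScheme(**kw["scheme"])
        if "tr_criteria" in kw:
            kw["tr_criteria"] = TRCriteria(**kw["tr_criteria"])
        if "screen_criteria" in kw:
            kw["screen_criteria"] = [
                ScreenCriteria(**c) for c in kw["screen_criteria"]
            ]
        return cls(**kw)


def _stage(log, name):
    log.write(f"[{time.strftime('%H:%M:%S')}] stage {name}\n")
    log.flush()


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Execute all configured stages; returns paths of the report bundle.

    Stages on missing optional inputs (no contigs) are skipped and
    logged as skipped.  Any stage error raises PipelineError naming the
    stage.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    cfg_repr = repr(cfg).encode()
    cfg_hash = hashlib.sha256(cfg_repr).hexdigest()[:16]
    log_path = outdir / "run.log"
    with open(log_path, "w") as log:
        log.write(
            f"chromoscan {__version__}\nconfig sha256/16: {cfg_hash}\n"
            f"seed: {cfg.seed}\nqc: {cfg.qc}\nscheme: {cfg.scheme}\n"
            f"tr_criteria: {cfg.tr_criteria}\n"
            f"screen_criteria: {cfg.screen_criteria}\n"
            f"profiler: smooth_window={cfg.smooth_window} "
            f"fold_threshold={cfg.fold_threshold} "
            f"min_segment_len={cfg.min_segment_len}\n"
        )
        try:
            _stage(log, "library")
            if cfg.library_fasta:
                lib = load_library(cfg.library_fasta, cfg.library_meta)
            else:
                lib = generate_library(cfg.seed)
                log.write("library: synthetic default (seeded)\n")
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"stage library: {e}") from e

        try:
            _stage(log, "qc")
            reads, stats = clean_readset(parse_fastq(cfg.reads), cfg.qc)
            log.write(
                f"qc: {stats.n_input} in, {stats.n_kept} kept, "
                f"{stats.fraction_removed:.2f}% removed\n"
            )
            paths["cleaned_fastq"] = outdir / "cleaned.fastq"
            write_fastq(reads, paths["cleaned_fastq"])
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"stage qc: {e}") from e

        try:
            _stage(log, "quantify")
            table = quantify(reads, lib, cfg.scheme)
            paths["composition"] = outdir / "composition.tsv"
            paths["rollups"] = outdir / "rollups.tsv"
            table.to_tsv(paths["composition"])
            table.rollups_to_tsv(paths["rollups"])
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"stage quantify: {e}") from e

        try:
            _stage(log, "profiles")
            profdir = outdir / "profiles"
            profdir.mkdir(exist_ok=True)
            paths["profiles"] = profdir
            for name in cfg.profile_consensuses:
                p = profile(reads, lib[name], cfg.scheme)
                write_bedgraph(p, profdir / f"{name}.bedgraph")
                segs = detect_enriched_segments(
                    p,
                    cfg.smooth_window,
                    cfg.fold_threshold,
                    cfg.min_segment_len,
                )
                write_segments_bed(segs, name, profdir / f"{name}.segments.bed")
                log.write(f"profile {name}: {len(segs)} enriched segment(s)\n")
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"stage profiles: {e}") from e

        if cfg.contigs:
            try:
                _stage(log, "tandem+screen")
                from Bio import SeqIO

                contigs = [
                    (rec.id, str(rec.seq).upper())
                    for rec in SeqIO.parse(cfg.contigs, "fasta")
                ]
                arrays = []
                for cid, seq in contigs:
                    arrays.extend(
                        find_tandem_arrays(
                            cid, seq, lib, cfg.scheme, cfg.tr_criteria
                        )
                    )
                paths["arrays"] = outdir / "arrays.gff3"
                write_arrays_gff3(arrays, paths["arrays"])
                if cfg.screen_criteria:
                    counts, results = screen_batch(
                        contigs,
                        cfg.screen_criteria,
                        lib,
                        cfg.scheme,
                        cfg.tr_criteria,
                    )
                    paths["screen"] = outdir / "screen.tsv"
                    write_screen_tsv(results, paths["screen"])
                    log.write(f"screen positives: {counts}\n")
            except Exception as e:  # noqa: BLE001
                raise PipelineError(f"stage tandem+screen: {e}") from e
        else:
            log.write("stage tandem+screen: skipped (no contigs)\n")
        _stage(log, "done")
    paths["log"] = log_path
    return paths
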