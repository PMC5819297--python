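"""Per-nucleotide read coverage along a consensus and enrichment calling.

A coverage profile counts, at every consensus position, how many aligned
read bases cover it.  Profiles from datasets of different depth are made
comparable by reads-per-million scaling.  Enriched sub-element segments
(the signature of an over-represented fragment of a transposable
element) are called by comparing a moving-average-smoothed profile with
the profile median: contiguous runs at or above ``fold_threshold`` times
the median, merged across short gaps and at least ``min_segment_len``
long, are reported with their mean fold enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy.ndimage import uniform_filter1d

from .align import ScoringScheme, SeedIndex
from .library import RepeatRecord
from .qc import Read


@dataclass
class CoverageProfile:
    consensus_name: str
    values: np.ndarray  # length == consensus length
    n_reads_total: int  # dataset size used for normalization
    normalized: bool = False
    aligned_bases: int = 0  # bookkeeping for the conservation check

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)


@dataclass(frozen=True)
class EnrichmentSegment:
    start: int  # 0-based half-open consensus coordinates
    end: int
    mean_fold: float

    @property
    def width(self) -> int:
        return self.end - self.start


def profile(
    reads: Iterable[Read],
    consensus: RepeatRecord,
    scheme: ScoringScheme = ScoringScheme(),
    seed_only: bool = True,
) -> CoverageProfile:
    """Raw coverage of ``consensus`` by the best local alignment of each
    read that passes the scoring thresholds.

    Tandem consensuses are searched in duplicated form and coverage is
    wrapped modulo the stored consensus length.  ``n_reads_total`` counts
    every read seen (aligned or not), i.e. the dataset size.  By default
    only seed-supported alignments contribute (uniform thinning of a few
    percent at realistic error rates, irrelevant to fold-based calls);
    ``seed_only=False`` rescans seedless reads exhaustively.
    """
    L = len(consensus.seq)
    search_seq = (
        consensus.seq + consensus.seq if consensus.is_tandem else consensus.seq
    )
    index = SeedIndex([(consensus.name, search_seq)], scheme=scheme)
    values = np.zeros(L, dtype=np.float64)
    n = 0
    aligned_bases = 0
    for read in reads:
        n += 1
        best = index.best_per_ref(read.seq, fallback=not seed_only)
        if not best:
            continue
        aln = best[0]
        span = np.arange(aln.r_start, aln.r_end)
        if consensus.is_tandem:
            span %= L
            np.add.at(values, span, 1.0)
        else:
            values[aln.r_start : aln.r_end] += 1.0
        aligned_bases += aln.r_end - aln.r_start
    p = CoverageProfile(consensus.name, values, n, aligned_bases=aligned_bases)
    assert int(p.values.sum()) == aligned_bases  # conservation
    return p


def normalize(p: CoverageProfile, per: float = 1e6) -> CoverageProfile:
    """Scale a raw profile to reads-per-``per`` of dataset size.

    Normalizing an already-normalized profile, or a profile with zero
    dataset size, is an error.
    """
    if p.normalized:
        raise ValueError("profile is already normalized")
    if p.n_reads_total == 0:
        raise ValueError("cannot normalize a profile with n_reads_total == 0")
    return replace(
        p, values=p.values * (per / p.n_reads_total), normalized=True
    )


def detect_enriched_segments(
    p: CoverageProfile,
    smooth_window: int = 101,
    fold_threshold: float = 3.0,
    min_segment_len: int = 200,
) -> list[EnrichmentSegment]:
    """Call sub-element segments enriched over the profile median.

    Centered moving-average smoothing; positions with smoothed coverage
    >= fold_threshold * median(profile) are marked; marked runs closer
    than ``smooth_window`` are merged; runs >= ``min_segment_len`` are
    reported.  A profile whose median is zero yields no calls.
    """
    if len(p.values) <= smooth_window:
        raise ValueError(
            f"profile length {len(p.values)} must exceed smooth_window "
            f"{smooth_window}"
        )
    med = float(np.median(p.values))
    if med == 0.0:
        return []
    smoothed = uniform_filter1d(p.values, smooth_window, mode="nearest")
    mask = smoothed >= fold_threshold * med
    # runs of marked positions
    edges = np.flatnonzero(np.diff(np.r_[0, mask.view(np.int8), 0]))
    runs = list(zip(edges[::2], edges[1::2]))
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] < smooth_window:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    out = []
    for s, e in merged:
        if e - s >= min_segment_len:
            fold = float(smoothed[s:e].mean() / med)
            out.append(EnrichmentSegment(int(s), int(e), fold))
    return out


def write_bedgraph(p: CoverageProfile, path: str | Path) -> None:
    """bedGraph with the consensus as the 'chromosome'; adjacent equal
    values are collapsed into one interval."""
    v = p.values
    with open(path, "w") as fh:
        fh.write(
            f'track type=bedGraph name="{p.consensus_name}"'
            f' description="read coverage"\n'
        )
        if len(v) == 0:
            return
        change = np.flatnonzero(np.diff(v)) + 1
        starts = np.r_[0, change]
        ends = np.r_[change, len(v)]
        for s, e in zip(starts, ends):
            fh.write(f"{p.consensus_name}\t{s}\t{e}\t{v[s]:g}\n")


def write_segments_bed(
    segments: Iterable[EnrichmentSegment], consensus_name: str, path: str | Path
) -> None:
    """BED3+1: chrom, start, end, mean_fold."""
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(
                f"{consensus_name}\t{seg.start}\t{seg.end}\t{seg.mean_fold:.3f}\n"
            )
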