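"""Read cleaning: adapter dropping, sliding-window quality trimming,
minimum-length filtering.

The trimming rule follows SLIDINGWINDOW semantics of common read
trimmers: scan 5'->3' over all windows of ``window`` bases; at the first
window whose mean quality drops below ``min_mean_q``, cut the read — but
first extend past the window start over any leading bases whose
individual quality still meets the threshold, so a single low-quality
tail base inside an otherwise good window does not cost good bases.
Reads shorter than ``min_len`` after trimming are dropped, as are reads
containing any adapter sequence as an exact substring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator


@dataclass
class Read:
    id: str
    seq: str
    qual: np.ndarray  # phred scores, same length as seq

    def __post_init__(self):
        self.qual = np.asarray(self.qual, dtype=np.int16)
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"read {self.id!r}: seq length {len(self.seq)} != "
                f"qual length {len(self.qual)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class QCParams:
    window: int = 4
    min_mean_q: float = 25.0
    min_len: int = 30
    adapters: frozenset[str] = frozenset()


@dataclass
class QCStats:
    n_input: int = 0
    n_kept: int = 0
    n_dropped_short: int = 0
    n_dropped_adapter: int = 0

    @property
    def fraction_removed(self) -> float:
        """Percent of input reads removed; 0 for empty input."""
        if self.n_input == 0:
            return 0.0
        return 100.0 * (self.n_input - self.n_kept) / self.n_input


DROP = None  # sentinel: sliding_window_trim returns None for dropped reads


def sliding_window_trim(read: Read, params: QCParams) -> Read | None:
    """Trim one read; returns the (possibly shortened) read or None (DROP)."""
    for a in params.adapters:
        if a and a in read.seq:
            return DROP
    q = read.qual
    n = len(q)
    w = params.window
    cut = n
    if n >= w:
        means = np.convolve(q, np.ones(w), mode="valid") / w
        bad = np.nonzero(means < params.min_mean_q)[0]
        if bad.size:
            s = int(bad[0])
            # keep bases past the window start while they individually pass
            e = s
            while e < n and q[e] >= params.min_mean_q:
                e += 1
            cut = e
    if cut < params.min_len:
        return DROP
    if cut == n:
        return read
    return Read(read.id, read.seq[:cut], q[:cut])


def clean_readset(
    reads: Iterable[Read], params: QCParams = QCParams()
) -> tuple[list[Read], QCStats]:
    """Apply sliding_window_trim to a read stream; exact bookkeeping.

    n_input == n_kept + n_dropped_short + n_dropped_adapter.
    """
    stats = QCStats()
    kept: list[Read] = []
    for read in reads:
        stats.n_input += 1
        dropped_adapter = any(a and a in read.seq for a in params.adapters)
        out = sliding_window_trim(read, params)
        if out is DROP:
            if dropped_adapter:
                stats.n_dropped_adapter += 1
            else:
                stats.n_dropped_short += 1
        else:
            stats.n_kept += 1
            kept.append(out)
    return kept, stats


def parse_fastq(path: str | Path | TextIO) -> Iterator[Read]:
    """Stream reads from a phred+33 FASTQ file."""
    close = False
    if isinstance(path, (str, Path)):
        fh = open(path)
        close = True
    else:
        fh = path
    try:
        for i, (title, seq, qual) in enumerate(FastqGeneralIterator(fh)):
            if len(seq) != len(qual):
                raise ValueError(f"malformed FASTQ record {i}: {title}")
            q = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(
                np.int16
            ) - 33
            yield Read(title.split()[0], seq.upper(), q)
    finally:
        if close:
            fh.close()


def write_fastq(reads: Iterable[Read], path: str | Path | TextIO) -> int:
    """Write reads as phred+33 FASTQ; returns the number written."""
    close = False
    if isinstance(path, (str, Path)):
        fh = open(path, "w")
        close = True
    else:
        fh = path
    n = 0
    try:
        for r in reads:
            qual = (r.qual.astype(np.uint8) + 33).tobytes().decode("ascii")
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")
            n += 1
    finally:
        if close:
            fh.close()
    return n
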