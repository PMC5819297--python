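"""Detection of head-to-tail tandem monomer arrays in contigs.

A large tandem-repeat array is operationally defined as a run of
monomers arranged head to tail without inserts, with monomer length
under ``max_monomer_len`` (2 kb) and array span over ``min_array_len``
(3 kb).  "Without inserts" is operationalized as an inter-monomer gap of
at most ``max_insert_gap`` bases (small indel slack without admitting
interrupted arrays).  Monomers come from the library; there is no
de-novo monomer discovery here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .align import LocalAlignment, ScoringScheme, find_local_hits
from .library import RepeatLibrary, RepeatRecord

#: fraction of the monomer a hit must cover to count as a complete copy
COMPLETE_FRACTION = 0.9


@dataclass(frozen=True)
class TRCriteria:
    max_monomer_len: int = 2000
    min_array_len: int = 3000
    max_insert_gap: int = 50
    identity_threshold: float = 75.0


@dataclass(frozen=True)
class MonomerHit:
    """One aligned monomer copy on a contig (forward contig coords)."""

    start: int
    end: int
    strand: str
    identity: float
    score: int
    monomer_cov: float  # fraction of the monomer covered by the alignment

    @property
    def complete(self) -> bool:
        return self.monomer_cov >= COMPLETE_FRACTION


@dataclass(frozen=True)
class TandemArray:
    contig_id: str
    family: str
    start: int  # 0-based half-open contig coordinates
    end: int
    n_monomers: int  # complete monomer copies only
    strand: str
    mean_identity: float
    meets_large_TR: bool
    score: int  # summed hit scores (used for structure-map precedence)


def find_monomer_hits(
    contig: str,
    monomer: RepeatRecord,
    scheme: ScoringScheme = ScoringScheme(),
    identity_threshold: float = TRCriteria.identity_threshold,
) -> list[MonomerHit]:
    """All non-overlapping local alignments of the monomer on the contig
    with identity >= threshold, both strands, sorted by start."""
    if not monomer.is_tandem:
        raise ValueError(f"record {monomer.name!r} is not tandem")
    mlen = monomer.monomer_len
    # the stored sequence is the monomer, except for pre-expanded records
    # (e.g. telomere) where copy count is judged by contig span instead
    query = monomer.seq
    hits = find_local_hits(
        query, contig, scheme=scheme, min_identity=identity_threshold
    )
    out = []
    qlen = len(query)
    for h in hits:
        if monomer.is_expanded:
            cov = (h.r_end - h.r_start) / mlen
        else:
            cov = (h.q_end - h.q_start) / qlen
        out.append(
            MonomerHit(
                h.r_start, h.r_end, h.strand, h.identity, h.score, cov
            )
        )
    return out


def chain_arrays(
    hits: Sequence[MonomerHit],
    criteria: TRCriteria,
    monomer_len: int,
    contig_id: str = "",
    family: str = "",
) -> list[TandemArray]:
    """Chain consecutive same-strand hits with gap <= max_insert_gap into
    arrays.

    ``n_monomers`` counts complete copies (monomer coverage >= 90%);
    partial trailing copies extend the span but not the count.  Chains
    with no complete copy are dropped.  ``meets_large_TR`` applies the
    large-TR definition: monomer < max_monomer_len and span >
    min_array_len.
    """
    hits = sorted(hits, key=lambda h: h.start)
    chains: list[list[MonomerHit]] = []
    for h in hits:
        if (
            chains
            and chains[-1][-1].strand == h.strand
            and h.start - chains[-1][-1].end <= criteria.max_insert_gap
        ):
            chains[-1].append(h)
        else:
            chains.append([h])
    arrays = []
    for chain in chains:
        n_complete = sum(1 for h in chain if h.complete)
        if n_complete < 1:
            continue
        start = chain[0].start
        end = chain[-1].end
        arrays.append(
            TandemArray(
                contig_id=contig_id,
                family=family,
                start=start,
                end=end,
                n_monomers=n_complete,
                strand=chain[0].strand,
                mean_identity=sum(h.identity for h in chain) / len(chain),
                meets_large_TR=(
                    monomer_len < criteria.max_monomer_len
                    and end - start > criteria.min_array_len
                ),
                score=sum(h.score for h in chain),
            )
        )
    return arrays


def find_tandem_arrays(
    contig_id: str,
    contig: str,
    lib: RepeatLibrary,
    scheme: ScoringScheme = ScoringScheme(),
    criteria: TRCriteria = TRCriteria(),
    families: Sequence[str] | None = None,
) -> list[TandemArray]:
    """Arrays of every tandem family (or the named subset) on one contig."""
    records = (
        lib.tandem_records()
        if families is None
        else [lib[f] for f in families]
    )
    arrays: list[TandemArray] = []
    for rec in records:
        hits = find_monomer_hits(
            contig, rec, scheme, criteria.identity_threshold
        )
        arrays.extend(
            chain_arrays(hits, criteria, rec.monomer_len, contig_id, rec.name)
        )
    arrays.sort(key=lambda a: (a.start, a.family))
    return arrays


def write_arrays_gff3(arrays: Iterable[TandemArray], path: str | Path) -> None:
    """GFF3 (1-based inclusive coordinates) of detected arrays."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in arrays:
            attrs = (
                f"Name={a.family};n_monomers={a.n_monomers};"
                f"mean_identity={a.mean_identity:.1f};"
                f"large_TR={'true' if a.meets_large_TR else 'false'}"
            )
            fh.write(
                f"{a.contig_id}\tchromoscan\ttandem_array\t{a.start + 1}\t"
                f"{a.end}\t{a.score}\t{a.strand}\t.\t{attrs}\n"
            )
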