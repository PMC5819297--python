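"""Read classification against a repeat library and composition tables.

Every cleaned read is assigned to at most one repeat family: the family
with the single best local-alignment score across the whole library
(tandem consensuses searched in duplicated form).  Ties across families
are broken by repclass priority and then name, and surfaced through the
``ambiguous`` flag rather than hidden.  Percentages always use the full
cleaned-read count (assigned + unassigned) as denominator, so "all
repeats" directly measures the annotated fraction of the dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .align import ScoringScheme, SeedIndex, library_index
from .library import RepeatLibrary
from .qc import Read

UNASSIGNED = "UNASSIGNED"


@dataclass(frozen=True)
class Assignment:
    read_id: str
    family: str  # record name or UNASSIGNED
    score: int = 0
    ref_start: int = -1
    ref_end: int = -1
    strand: str = "+"
    ambiguous: bool = False

    @property
    def assigned(self) -> bool:
        return self.family != UNASSIGNED


def classify_read(
    read: Read,
    lib: RepeatLibrary,
    scheme: ScoringScheme = ScoringScheme(),
    index: SeedIndex | None = None,
    exhaustive: bool = False,
) -> Assignment:
    """Assign one read to its best-scoring family (or UNASSIGNED).

    For tandem references the reported start is reduced modulo the
    monomer length; the end is start + aligned length and may exceed the
    monomer length for junction-spanning reads.
    """
    if len(lib) == 0:
        raise ValueError("empty library")
    if index is None:
        index = library_index(lib, scheme)
    best = index.best_per_ref(read.seq, exhaustive=exhaustive)
    if not best:
        return Assignment(read.id, UNASSIGNED)
    top = max(a.score for a in best.values())
    tied = [i for i, a in best.items() if a.score == top]
    tied.sort(
        key=lambda i: (
            lib.priority_rank(lib.records[i].repclass),
            lib.records[i].name,
        )
    )
    win = tied[0]
    aln = best[win]
    rec = lib.records[win]
    rs, re = aln.r_start, aln.r_end
    if rec.is_tandem:
        mlen = rec.monomer_len
        rs_m = rs % mlen
        re = rs_m + (re - rs)
        rs = rs_m
    return Assignment(
        read.id, rec.name, aln.score, rs, re, aln.strand, len(tied) > 1
    )


def classify_reads(
    reads: Iterable[Read],
    lib: RepeatLibrary,
    scheme: ScoringScheme = ScoringScheme(),
    exhaustive: bool = False,
) -> Iterator[Assignment]:
    """Classify a read stream with a shared index."""
    index = library_index(lib, scheme)
    for read in reads:
        yield classify_read(read, lib, scheme, index=index, exhaustive=exhaustive)


@dataclass
class CompositionTable:
    """Per-family read counts/percentages with hierarchical roll-ups.

    ``families`` has one row per library record (family, subclass,
    repclass, te_part, count, percent); ``rollups()`` reproduces the
    class-level summary rows (per-repclass, ERV three ways, satellite
    families split out, an all-repeats total).
    """

    families: pd.DataFrame
    total_reads: int
    n_unassigned: int
    n_ambiguous: int = 0

    @property
    def zero_denominator(self) -> bool:
        return self.total_reads == 0

    def percent(self, family: str) -> float:
        row = self.families.loc[self.families["family"] == family]
        if row.empty:
            raise KeyError(f"no family {family!r}")
        return float(row["percent"].iloc[0])

    def _pct(self, count: int) -> float:
        return 0.0 if self.total_reads == 0 else 100.0 * count / self.total_reads

    def rollups(self) -> pd.DataFrame:
        """Class-level summary in the style of a repeat-composition table:
        ERV total / per class / IAP separately, the dispersed classes, the
        named satellites, telomere, and an all-repeats total."""
        f = self.families
        rows: list[tuple[str, int]] = []

        def tot(mask) -> int:
            return int(f.loc[mask, "count"].sum())

        erv = f["repclass"].isin(["ERV1", "ERV2", "ERV3"])
        rows.append(("ERVAll", tot(erv)))
        rows.append(("ERV3", tot(f["repclass"] == "ERV3")))
        rows.append(("ERV2All", tot(f["repclass"] == "ERV2")))
        rows.append(("IAP", tot((f["repclass"] == "ERV2") & (f["subclass"] == "IAP"))))
        rows.append(("ERV1", tot(f["repclass"] == "ERV1")))
        rows.append(("LINE", tot(f["repclass"] == "LINE")))
        rows.append(("SINE", tot(f["repclass"] == "SINE")))
        rows.append(("DNA", tot(f["repclass"] == "DNA")))
        tr = f["repclass"] == "TR"
        tel = tr & (f["subclass"] == "telomere")
        masat = tr & (f["subclass"] == "MaSat")
        misat = tr & (f["subclass"] == "MiSat")
        rows.append(("TR-MaSat", tot(masat)))
        rows.append(("TR-MiSat", tot(misat)))
        rows.append(("TR-Other", tot(tr & ~tel & ~masat & ~misat)))
        rows.append(("Tel", tot(tel)))
        rows.append(("All", tot(f["repclass"].notna())))
        return pd.DataFrame(
            {
                "row": [r for r, _ in rows],
                "count": [c for _, c in rows],
                "percent": [self._pct(c) for _, c in rows],
            }
        )

    def rollup(self, row: str) -> float:
        r = self.rollups()
        m = r.loc[r["row"] == row]
        if m.empty:
            raise KeyError(f"no rollup row {row!r}")
        return float(m["percent"].iloc[0])

    def erv_table(self) -> pd.DataFrame:
        """Per-ERV-consensus percentages split internal vs LTR, sorted
        descending within each part."""
        f = self.families
        erv = f.loc[
            f["repclass"].isin(["ERV1", "ERV2", "ERV3"])
            & (f["te_part"] != "none")
        ].copy()
        erv = erv.sort_values(
            ["te_part", "percent"], ascending=[True, False]
        ).reset_index(drop=True)
        return erv[["family", "te_part", "repclass", "count", "percent"]]

    def to_tsv(self, path: str | Path) -> None:
        self.families.to_csv(path, sep="\t", index=False, float_format="%.6f")

    def rollups_to_tsv(self, path: str | Path) -> None:
        self.rollups().to_csv(path, sep="\t", index=False, float_format="%.6f")

    def validate(self) -> None:
        """Internal consistency: percentages in range, family counts plus
        unassigned conserve the denominator, repclass roll-ups match."""
        f = self.families
        assert (f["percent"] >= 0).all() and (f["percent"] <= 100).all()
        assert int(f["count"].sum()) + self.n_unassigned == self.total_reads
        r = self.rollups()
        assert float(r.loc[r["row"] == "All", "percent"].iloc[0]) <= 100.0 + 1e-9
        for cls in f["repclass"].unique():
            sub = f.loc[f["repclass"] == cls, "percent"].sum()
            if cls in ("ERV1", "ERV2", "ERV3"):
                lab = {"ERV1": "ERV1", "ERV2": "ERV2All", "ERV3": "ERV3"}[cls]
                roll = float(r.loc[r["row"] == lab, "percent"].iloc[0])
                assert abs(sub - roll) < 1e-9


def quantify(
    reads: Iterable[Read],
    lib: RepeatLibrary,
    scheme: ScoringScheme = ScoringScheme(),
    exhaustive: bool = False,
) -> CompositionTable:
    """Classify every read and aggregate into a CompositionTable.

    The percentage denominator is the total number of (cleaned) reads
    including those left UNASSIGNED.
    """
    counts = {rec.name: 0 for rec in lib.records}
    total = 0
    unassigned = 0
    ambiguous = 0
    for a in classify_reads(reads, lib, scheme, exhaustive=exhaustive):
        total += 1
        if a.assigned:
            counts[a.family] += 1
            if a.ambiguous:
                ambiguous += 1
        else:
            unassigned += 1
    fam = pd.DataFrame(
        {
            "family": [r.name for r in lib.records],
            "subclass": [r.subclass for r in lib.records],
            "repclass": [r.repclass for r in lib.records],
            "te_part": [r.te_part for r in lib.records],
            "count": [counts[r.name] for r in lib.records],
        }
    )
    fam["percent"] = (
        0.0 if total == 0 else 100.0 * fam["count"] / total
    )
    table = CompositionTable(fam, total, unassigned, ambiguous)
    table.validate()
    return table
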