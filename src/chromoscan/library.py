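"""Repeat consensus library: records, validation, tandem-junction handling.

A library couples a FASTA file of consensus sequences with a 6-column TSV
sidecar (name, repclass, subclass, is_tandem, monomer_len, te_part) so the
class scheme needed for composition roll-ups is machine-readable.

Tandem (satellite) consensuses are single monomers; reads that span the
head-to-tail junction of a real array are recovered by aligning against
the duplicated consensus (monomer concatenated with itself), which
contains every junction-spanning k-mer as long as reads are shorter than
the monomer.  The telomeric reference is the one deliberate exception:
its 6-bp unit is far shorter than a read, so the stored sequence is the
unit expanded to ``n_units`` copies and flagged ``is_expanded``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

REPCLASSES = ("TR", "LINE", "SINE", "ERV1", "ERV2", "ERV3", "DNA", "OTHER")
TE_PARTS = ("internal", "LTR", "none")

#: default repclass precedence for breaking classification ties
DEFAULT_PRIORITY = ("TR", "LINE", "SINE", "ERV1", "ERV2", "ERV3", "DNA", "OTHER")

TELOMERE_UNIT = "TTAGGG"


class LibraryError(ValueError):
    """Raised on malformed library input."""


@dataclass(frozen=True)
class RepeatRecord:
    """One consensus sequence with its classification metadata."""

    name: str
    seq: str
    repclass: str
    subclass: str = ""
    is_tandem: bool = False
    monomer_len: int | None = None
    te_part: str = "none"
    is_expanded: bool = False

    def __post_init__(self):
        object.__setattr__(self, "seq", self.seq.upper().replace("U", "T"))
        if not self.seq:
            raise LibraryError(f"record {self.name!r}: empty sequence")
        if set(self.seq) - set("ACGTN"):
            bad = sorted(set(self.seq) - set("ACGTN"))
            raise LibraryError(f"record {self.name!r}: invalid characters {bad}")
        if self.repclass not in REPCLASSES:
            raise LibraryError(
                f"record {self.name!r}: invalid repclass {self.repclass!r} "
                f"(expected one of {REPCLASSES})"
            )
        if self.te_part not in TE_PARTS:
            raise LibraryError(
                f"record {self.name!r}: invalid te_part {self.te_part!r}"
            )
        if self.is_tandem:
            if self.monomer_len is None or self.monomer_len <= 0:
                raise LibraryError(
                    f"record {self.name!r}: tandem record needs positive monomer_len"
                )
            if self.is_expanded:
                if len(self.seq) % self.monomer_len != 0:
                    raise LibraryError(
                        f"record {self.name!r}: expanded sequence length "
                        f"{len(self.seq)} is not a multiple of monomer_len "
                        f"{self.monomer_len}"
                    )
            elif self.monomer_len != len(self.seq):
                raise LibraryError(
                    f"record {self.name!r}: monomer_len {self.monomer_len} != "
                    f"sequence length {len(self.seq)}"
                )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class RepeatLibrary:
    """Ordered collection of RepeatRecord plus a repclass tie-break order."""

    records: list[RepeatRecord]
    priority: tuple[str, ...] = DEFAULT_PRIORITY

    def __post_init__(self):
        names = [r.name for r in self.records]
        dup = {n for n in names if names.count(n) > 1}
        if dup:
            raise LibraryError(f"duplicate record names: {sorted(dup)}")
        classes = {r.repclass for r in self.records}
        missing = classes - set(self.priority)
        if missing:
            raise LibraryError(f"repclass {sorted(missing)} absent from priority")
        if len(set(self.priority)) != len(self.priority):
            raise LibraryError("priority list contains duplicates")
        self._by_name = {r.name: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, name: str) -> RepeatRecord:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"no record named {name!r} in library") from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def priority_rank(self, repclass: str) -> int:
        return self.priority.index(repclass)

    def tandem_records(self) -> list[RepeatRecord]:
        return [r for r in self.records if r.is_tandem]

    def te_records(self) -> list[RepeatRecord]:
        return [r for r in self.records if r.te_part != "none"]


_META_COLS = ("name", "repclass", "subclass", "is_tandem", "monomer_len", "te_part")


def _parse_bool(s: str, ctx: str) -> bool:
    v = s.strip().lower()
    if v in ("1", "true", "yes"):
        return True
    if v in ("0", "false", "no"):
        return False
    raise LibraryError(f"{ctx}: cannot parse boolean {s!r}")


def load_library(
    fasta_path: str | Path,
    metadata_path: str | Path,
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
) -> RepeatLibrary:
    """Load and validate a consensus library from FASTA + TSV sidecar.

    Every FASTA record must have a metadata row; sequences are uppercased
    and U is converted to T.  Unknown or missing names raise LibraryError.
    """
    fasta_path = Path(fasta_path)
    metadata_path = Path(metadata_path)
    meta: dict[str, dict] = {}
    with open(metadata_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _META_COLS:
            raise LibraryError(
                f"metadata header {header} != expected {list(_META_COLS)}"
            )
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(_META_COLS):
                raise LibraryError(f"{metadata_path}:{ln}: expected 6 columns")
            name, repclass, subclass, is_tandem, monomer_len, te_part = parts
            if name in meta:
                raise LibraryError(f"{metadata_path}:{ln}: duplicate name {name!r}")
            meta[name] = dict(
                repclass=repclass,
                subclass=subclass,
                is_tandem=_parse_bool(is_tandem, f"{metadata_path}:{ln}"),
                monomer_len=int(monomer_len) if monomer_len not in ("", ".") else None,
                te_part=te_part if te_part else "none",
            )
    records = []
    seen = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in meta:
            raise LibraryError(
                f"FASTA record {rec.id!r} has no row in {metadata_path}"
            )
        seen.add(rec.id)
        m = meta[rec.id]
        seq = str(rec.seq)
        mlen = m["monomer_len"]
        # a tandem row whose sequence is an exact multiple of monomer_len
        # is treated as a pre-expanded array (e.g. the telomeric reference)
        is_expanded = bool(
            m["is_tandem"]
            and mlen
            and mlen != len(seq)
            and len(seq) % mlen == 0
        )
        records.append(
            RepeatRecord(
                name=rec.id,
                seq=seq,
                repclass=m["repclass"],
                subclass=m["subclass"],
                is_tandem=m["is_tandem"],
                monomer_len=mlen,
                te_part=m["te_part"],
                is_expanded=is_expanded,
            )
        )
    unused = set(meta) - seen
    if unused:
        raise LibraryError(
            f"metadata rows without FASTA record: {sorted(unused)}"
        )
    return RepeatLibrary(records, priority=priority)


def write_library(
    lib: RepeatLibrary, fasta_path: str | Path, metadata_path: str | Path
) -> None:
    """Write FASTA + metadata TSV; inverse of load_library."""
    recs = [
        SeqRecord(Seq(r.seq), id=r.name, description="") for r in lib.records
    ]
    with open(fasta_path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")
    with open(metadata_path, "w") as fh:
        fh.write("\t".join(_META_COLS) + "\n")
        for r in lib.records:
            fh.write(
                "\t".join(
                    [
                        r.name,
                        r.repclass,
                        r.subclass,
                        "true" if r.is_tandem else "false",
                        str(r.monomer_len) if r.monomer_len else "",
                        r.te_part,
                    ]
                )
                + "\n"
            )


def build_telomere_reference(n_units: int, name: str = "TEL") -> RepeatRecord:
    """Vertebrate telomeric reference (TTAGGG)^n_units.

    The stored sequence is the expanded array with monomer_len = 6 and the
    ``is_expanded`` marker set, because the 6-bp unit alone is shorter than
    any read.
    """
    if n_units < 1:
        raise ValueError(f"n_units must be >= 1, got {n_units}")
    return RepeatRecord(
        name=name,
        seq=TELOMERE_UNIT * n_units,
        repclass="TR",
        subclass="telomere",
        is_tandem=True,
        monomer_len=len(TELOMERE_UNIT),
        is_expanded=True,
    )


def duplicate_tandem_consensus(rec: RepeatRecord) -> RepeatRecord:
    """Monomer concatenated with itself so junction-spanning reads align.

    Downstream coordinates obtained on the duplicated reference are
    reported modulo ``monomer_len``.
    """
    if not rec.is_tandem:
        raise ValueError(f"record {rec.name!r} is not tandem")
    return replace(rec, seq=rec.seq + rec.seq, is_expanded=True)
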