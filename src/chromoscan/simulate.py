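"""Seeded generator of chromocenter-like repeat libraries, read sets and
contigs with per-read / per-feature ground truth.

The generator emulates the statistical structure the pipeline assumes
about pericentromeric heterochromatin sequencing data:

* a consensus library of synthetic (seeded random) stand-ins at
  realistic lengths — 234-bp major-satellite and 120-bp minor-satellite
  monomers, a short previously-classified satellite, the telomeric
  (TTAGGG)n unit, a full-length ~6.4-kb LINE, a SINE, three ERV classes
  as LTR-internal-LTR elements (~5-6 kb), and a DNA transposon;
* 37-bp paired-end reads at ~100-bp median insert drawn family-by-family
  from a multinomial over the chromocenter composition (major satellite
  0.662, minor satellite 0.044, other satellite 0.009, telomere 0.001,
  LINE 0.109, SINE 0.021, ERV 0.088 split by class, DNA 0.006; the
  remainder is unannotated background);
* satellite reads come from long head-to-tail arrays of independently
  mutated copies, so junction-spanning reads occur naturally;
* LINE reads come from a copy pool in which a fraction
  (``line_3prime_bias``) of copies expose only the 3'-terminal
  ``line_fragment_len`` window of the consensus — the two-component
  truncation model behind the sub-element enrichment signal;
* contigs are built from explicit blueprints (satellite arrays, TE
  fragments, spacers) whose intended screen verdict is computed directly
  from the positivity rule, giving truth tables for the screen.

Identical seed and configuration give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import _sw
from .library import (
    RepeatLibrary,
    RepeatRecord,
    build_telomere_reference,
)
from .qc import Read

#: chromocenter read-set composition used as simulation truth; subclass
#: rows are authoritative and sum to 0.940, the rest is unannotated
DEFAULT_COMPOSITION: dict[str, float] = {
    "MaSat": 0.662,
    "MiSat": 0.044,
    "TRPC-21A": 0.009,
    "TEL": 0.001,
    "L1": 0.109,
    "B1": 0.021,
    "RLTR6": 0.005,  # ERV1
    "IAP": 0.022,  # ERV2, IAP proper
    "MMERVK10C": 0.029,  # ERV2, non-IAP
    "MERVL": 0.032,  # ERV3
    "DNAtrans": 0.006,
}

#: element family -> (repclass, parts) where parts are the record names
#: a full element is assembled from, in order
ELEMENT_PARTS: dict[str, tuple[str, tuple[str, ...]]] = {
    "RLTR6": ("ERV1", ("RLTR6-LTR", "RLTR6-int", "RLTR6-LTR")),
    "IAP": ("ERV2", ("IAP-LTR", "IAPEZ-int", "IAP-LTR")),
    "MMERVK10C": ("ERV2", ("MMERVK10C-LTR", "MMERVK10C-int", "MMERVK10C-LTR")),
    "MERVL": ("ERV3", ("MERVL-LTR", "MERVL-int", "MERVL-LTR")),
}

BACKGROUND_GC = 0.41  # mouse-like base composition for unannotated DNA

# Each generator gets its own RNG domain so that, e.g., contig spacers
# seeded with the same integer as the library do not replay the very
# uniform stream that produced the consensuses (which would plant
# near-copies of library sequence inside "random" background).
_DOMAIN_LIBRARY, _DOMAIN_READS, _DOMAIN_CONTIGS = 11, 12, 13


def _rng(seed: int, domain: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([domain, seed]))


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    composition: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION)
    )
    read_len: int = 37
    insert_median: int = 100
    per_base_error: float = 0.002
    monomer_divergence: float = 5.0  # percent, per array/pool copy
    line_3prime_bias: float = 0.8  # fraction of LINE copies truncated
    line_fragment_len: int = 2000  # 3'-terminal window length

    def __post_init__(self):
        total = sum(self.composition.values())
        if any(v < 0 for v in self.composition.values()):
            raise ValueError("composition fractions must be >= 0")
        if total > 1.0 + 1e-9:
            raise ValueError(f"composition sums to {total:.4f} > 1")
        if self.read_len < 30:
            raise ValueError("read_len below the minimum QC length")


@dataclass
class TruthTable:
    """Per-read source family and realized composition fractions."""

    reads: pd.DataFrame  # read_id, family, repclass
    realized: dict[str, float]
    n_reads: int


def _rand_seq_codes(rng: np.random.Generator, n: int, gc: float = 0.5) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _mutate(rng: np.random.Generator, codes: np.ndarray, rate: float) -> np.ndarray:
    """Substitute each base with probability ``rate`` (to a different base)."""
    out = codes.copy()
    if rate <= 0:
        return out
    hit = np.nonzero(rng.random(len(codes)) < rate)[0]
    if hit.size:
        out[hit] = (out[hit] + rng.integers(1, 4, size=hit.size)) % 4
    return out


def generate_library(seed: int = 0) -> RepeatLibrary:
    """Synthetic consensus library at realistic lengths, deterministic for
    a given seed.  Sequences are random (hence mutually dissimilar); only
    their lengths and class structure mimic the real families."""
    rng = _rng(seed, _DOMAIN_LIBRARY)

    def mk(name, n, repclass, subclass, is_tandem=False, te_part="none", gc=0.45):
        seq = _sw.decode(_rand_seq_codes(rng, n, gc))
        return RepeatRecord(
            name=name,
            seq=seq,
            repclass=repclass,
            subclass=subclass,
            is_tandem=is_tandem,
            monomer_len=n if is_tandem else None,
            te_part=te_part,
        )

    records = [
        mk("MaSat", 234, "TR", "MaSat", is_tandem=True, gc=0.36),
        mk("MiSat", 120, "TR", "MiSat", is_tandem=True, gc=0.36),
        mk("TRPC-21A", 210, "TR", "TRPC-21A", is_tandem=True),
        build_telomere_reference(20, name="TEL"),
        mk("L1", 6400, "LINE", "L1", gc=0.40),
        mk("B1", 150, "SINE", "B1", gc=0.55),
        mk("RLTR6-int", 4600, "ERV1", "RLTR6", te_part="internal"),
        mk("RLTR6-LTR", 480, "ERV1", "RLTR6", te_part="LTR"),
        mk("IAPEZ-int", 5000, "ERV2", "IAP", te_part="internal"),
        mk("IAP-LTR", 450, "ERV2", "IAP", te_part="LTR"),
        mk("MMERVK10C-int", 4800, "ERV2", "MMERVK10C", te_part="internal"),
        mk("MMERVK10C-LTR", 520, "ERV2", "MMERVK10C", te_part="LTR"),
        mk("MERVL-int", 4500, "ERV3", "MERVL", te_part="internal"),
        mk("MERVL-LTR", 500, "ERV3", "MERVL", te_part="LTR"),
        mk("DNAtrans", 1000, "DNA", "hAT"),
    ]
    return RepeatLibrary(records)


# ---------------------------------------------------------------------------
# read simulation

#: copies per source pool (arrays for tandem families, copy pools else)
_POOL_COPIES = {
    "MaSat": 100,
    "MiSat": 100,
    "TRPC-21A": 60,
    "TEL": 500,  # telomeric units, not monomeric copies
    "L1": 25,
    "B1": 40,
    "RLTR6": 4,
    "IAP": 4,
    "MMERVK10C": 4,
    "MERVL": 4,
    "DNAtrans": 8,
}

_BACKGROUND_LEN = 50_000


def _element_seq(lib: RepeatLibrary, family: str) -> np.ndarray:
    _cls, parts = ELEMENT_PARTS[family]
    return np.concatenate([_sw.encode(lib[p].seq) for p in parts])


def _build_pools(
    cfg: SimConfig, lib: RepeatLibrary, rng: np.random.Generator
) -> dict[str, list[np.ndarray]]:
    """Source pools per family.  Tandem families give one long array of
    independently mutated copies (junction reads arise naturally);
    dispersed families give a pool of mutated copies; LINE copies are
    truncated to the 3'-terminal window with probability
    ``line_3prime_bias``."""
    div = cfg.monomer_divergence / 100.0
    pools: dict[str, list[np.ndarray]] = {}
    for family in cfg.composition:
        if family == "background":
            continue
        n_copies = _POOL_COPIES.get(family, 10)
        if family in ELEMENT_PARTS:
            base = _element_seq(lib, family)
            pools[family] = [
                _mutate(rng, base, div) for _ in range(n_copies)
            ]
        elif family in lib and lib[family].is_tandem:
            rec = lib[family]
            if rec.is_expanded:  # telomere: tile the 6-bp unit
                unit = _sw.encode(rec.seq[: rec.monomer_len])
                arr = np.tile(unit, n_copies)
                pools[family] = [_mutate(rng, arr, div)]
            else:
                mono = _sw.encode(rec.seq)
                arr = np.concatenate(
                    [_mutate(rng, mono, div) for _ in range(n_copies)]
                )
                pools[family] = [arr]
        elif family == "L1":
            base = _sw.encode(lib[family].seq)
            window = base[-cfg.line_fragment_len :]
            n_trunc = int(round(cfg.line_3prime_bias * n_copies))
            pool = []
            for i in range(n_copies):
                src = window if i < n_trunc else base
                pool.append(_mutate(rng, src, div))
            pools[family] = pool
        else:
            base = _sw.encode(lib[family].seq)
            pools[family] = [_mutate(rng, base, div) for _ in range(n_copies)]
    pools["background"] = [
        _rand_seq_codes(rng, _BACKGROUND_LEN, gc=BACKGROUND_GC)
    ]
    return pools


def generate_reads(
    cfg: SimConfig,
    lib: RepeatLibrary,
    n_reads: int,
    out_fastq: str | Path | None = None,
) -> tuple[list[Read], TruthTable]:
    """Simulate ``n_reads`` 37-bp paired-end reads (pairs pooled and
    counted as single reads) at the configured composition.

    ``n_reads`` is rounded down to an even number (two mates per
    fragment).  Returns the reads plus a per-read truth table; when
    ``out_fastq`` is given the reads are also written as FASTQ.
    """
    rng = _rng(cfg.seed, _DOMAIN_READS)
    pools = _build_pools(cfg, lib, rng)
    families = list(cfg.composition.keys())
    probs = [cfg.composition[f] for f in families]
    bg = 1.0 - sum(probs)
    families.append("background")
    probs.append(bg)
    n_frags = n_reads // 2
    counts = rng.multinomial(n_frags, probs)

    def fam_class(family: str) -> str:
        if family == "background":
            return "background"
        if family in ELEMENT_PARTS:
            return ELEMENT_PARTS[family][0]
        return lib[family].repclass

    rl = cfg.read_len
    qual = np.full(rl, 38, dtype=np.int16)
    reads: list[Read] = []
    truth_ids: list[str] = []
    truth_fam: list[str] = []
    idx = 0
    for family, n_f in zip(families, counts):
        if n_f == 0:
            continue
        pool = pools[family]
        lens = np.array([len(s) for s in pool], dtype=float)
        w = lens / lens.sum()
        cls = fam_class(family)
        for _ in range(n_f):
            src = pool[rng.choice(len(pool), p=w)] if len(pool) > 1 else pool[0]
            L = int(round(cfg.insert_median * np.exp(rng.normal(0.0, 0.35))))
            L = max(rl, min(L, len(src)))
            pos = int(rng.integers(0, len(src) - L + 1))
            frag = src[pos : pos + L]
            r1 = _mutate(rng, frag[:rl], cfg.per_base_error)
            r2 = _mutate(
                rng, _sw.revcomp_codes(frag[L - rl :]), cfg.per_base_error
            )
            for mate, codes in ((1, r1), (2, r2)):
                rid = f"read{idx:08d}/{mate}"
                reads.append(Read(rid, _sw.decode(codes), qual.copy()))
                truth_ids.append(rid)
                truth_fam.append(family)
            idx += 1
    realized = {
        f: 2 * int(c) / (2 * n_frags) if n_frags else 0.0
        for f, c in zip(families, counts)
    }
    truth = TruthTable(
        reads=pd.DataFrame(
            {
                "read_id": truth_ids,
                "family": truth_fam,
                "repclass": [fam_class(f) for f in truth_fam],
            }
        ),
        realized=realized,
        n_reads=2 * n_frags,
    )
    if out_fastq is not None:
        from .qc import write_fastq

        write_fastq(reads, out_fastq)
    return reads, truth


# ---------------------------------------------------------------------------
# contig simulation

@dataclass(frozen=True)
class ContigBlueprint:
    """Declarative contig recipe.

    Features, in order:
      ("tr", family, n_copies)        - tandem array of mutated monomers
      ("te", record_name, length, strand) - TE fragment (exact sequence,
                                        taken from the record 5' end;
                                        length None = full record)
      ("spacer", length)              - random background DNA
    """

    contig_id: str
    features: tuple[tuple, ...]


@dataclass
class ContigTruth:
    """Planted features with coordinates plus rule-derived verdicts."""

    features: pd.DataFrame  # contig_id, kind, name, start, end, strand, n_copies

    def n_monomers(self, contig_id: str, family: str) -> int:
        f = self.features
        m = f[
            (f["contig_id"] == contig_id)
            & (f["kind"] == "tr")
            & (f["name"] == family)
        ]
        return int(m["n_copies"].sum())

    def best_te_len(self, contig_id: str, ltr_only: bool = False) -> int:
        f = self.features
        m = f[(f["contig_id"] == contig_id) & (f["kind"] == "te")]
        if ltr_only:
            m = m[m["te_part"] == "LTR"]
        if m.empty:
            return 0
        return int((m["end"] - m["start"]).max())

    def verdict(
        self,
        contig_id: str,
        tr_family: str,
        min_monomers: int = 1,
        min_te_fragment_len: int = 400,
        ltr_only: bool = False,
    ) -> bool:
        """Direct application of the positivity rule to planted truth."""
        return (
            self.n_monomers(contig_id, tr_family) >= min_monomers
            and self.best_te_len(contig_id, ltr_only) > min_te_fragment_len
        )


def generate_contigs(
    blueprints: Sequence[ContigBlueprint],
    lib: RepeatLibrary,
    seed: int = 0,
    tr_divergence: float = 5.0,
) -> tuple[list[tuple[str, str]], ContigTruth]:
    """Assemble contigs by concatenating blueprint features.

    Satellite copies are independently mutated at ``tr_divergence``
    percent; TE fragments are planted exactly so truth fragment lengths
    are exact (the boundary cases of the screen depend on them).
    """
    rng = _rng(seed, _DOMAIN_CONTIGS)
    contigs: list[tuple[str, str]] = []
    rows = []
    for bp in blueprints:
        parts: list[np.ndarray] = []
        pos = 0
        for feat in bp.features:
            kind = feat[0]
            if kind == "tr":
                _, family, n_copies = feat
                rec = lib[family]
                if not rec.is_tandem:
                    raise ValueError(f"{family!r} is not a tandem record")
                mono = _sw.encode(rec.seq)
                arr = np.concatenate(
                    [
                        _mutate(rng, mono, tr_divergence / 100.0)
                        for _ in range(n_copies)
                    ]
                )
                rows.append(
                    dict(
                        contig_id=bp.contig_id,
                        kind="tr",
                        name=family,
                        start=pos,
                        end=pos + len(arr),
                        strand="+",
                        n_copies=n_copies,
                        te_part="none",
                    )
                )
                parts.append(arr)
                pos += len(arr)
            elif kind == "te":
                _, name, length, strand = feat
                if name not in lib:
                    raise ValueError(f"blueprint references unknown record {name!r}")
                rec = lib[name]
                codes = _sw.encode(rec.seq)
                if length is not None:
                    if length > len(codes):
                        raise ValueError(
                            f"{name!r}: requested length {length} exceeds "
                            f"record length {len(codes)}"
                        )
                    codes = codes[:length]
                if strand == "-":
                    codes = _sw.revcomp_codes(codes)
                rows.append(
                    dict(
                        contig_id=bp.contig_id,
                        kind="te",
                        name=name,
                        start=pos,
                        end=pos + len(codes),
                        strand=strand,
                        n_copies=0,
                        te_part=rec.te_part,
                    )
                )
                parts.append(codes.copy())
                pos += len(codes)
            elif kind == "spacer":
                _, length = feat
                parts.append(_rand_seq_codes(rng, length, gc=BACKGROUND_GC))
                pos += length
            else:
                raise ValueError(f"unknown blueprint feature kind {kind!r}")
        seq = _sw.decode(np.concatenate(parts)) if parts else ""
        contigs.append((bp.contig_id, seq))
    cols = [
        "contig_id", "kind", "name", "start", "end", "strand", "n_copies",
        "te_part",
    ]
    truth = ContigTruth(pd.DataFrame(rows, columns=cols))
    return contigs, truth


def default_screen_blueprints(seed: int = 0, n: int = 50) -> list[ContigBlueprint]:
    """A deterministic blueprint set for exercising the screen: the
    boundary cases first (exactly-400-bp fragment, two vs three short
    monomers, evidence of only one kind, empty contig), then randomized
    positive/negative layouts up to ``n`` contigs."""
    rng = np.random.default_rng(seed)
    bps = [
        # major satellite + long LTR -> positive at >=1 monomer
        ContigBlueprint("c00", (("tr", "MaSat", 2), ("spacer", 100), ("te", "IAP-LTR", 410, "+"))),
        # two short-monomer copies -> negative under the three-copy rule
        ContigBlueprint("c01", (("tr", "TRPC-21A", 2), ("spacer", 150), ("te", "RLTR6-LTR", 410, "+"))),
        ContigBlueprint("c02", (("tr", "TRPC-21A", 3), ("spacer", 150), ("te", "RLTR6-LTR", 410, "+"))),
        # fragment of exactly 400 bases -> negative (strict > 400)
        ContigBlueprint("c03", (("tr", "MaSat", 5), ("spacer", 200), ("te", "MERVL-LTR", 400, "+"))),
        # internal ERV fragment qualifies under the broad reading
        ContigBlueprint("c04", (("tr", "MaSat", 1), ("spacer", 120), ("te", "IAPEZ-int", 800, "+"))),
        ContigBlueprint("c05", (("tr", "MiSat", 1), ("spacer", 100), ("te", "MMERVK10C-LTR", 450, "-"))),
        # no features / only one kind of evidence -> negative
        ContigBlueprint("c06", (("spacer", 5000),)),
        ContigBlueprint("c07", (("tr", "MaSat", 4),)),
        ContigBlueprint("c08", (("te", "IAP-LTR", 450, "+"), ("te", "IAPEZ-int", 1200, "+"), ("te", "IAP-LTR", 450, "-"))),
        # the characteristic layout: internal part surrounded by LTRs
        ContigBlueprint("c09", (("tr", "MaSat", 2), ("spacer", 600), ("te", "IAP-LTR", 450, "+"), ("te", "IAPEZ-int", 1500, "+"), ("te", "IAP-LTR", 450, "+"))),
    ]
    tr_fams = ["MaSat", "MiSat", "TRPC-21A"]
    te_recs = [
        ("IAP-LTR", 450),
        ("RLTR6-LTR", 480),
        ("MMERVK10C-LTR", 520),
        ("MERVL-LTR", 500),
        ("IAPEZ-int", 5000),
        ("MERVL-int", 4500),
    ]
    for i in range(len(bps), n):
        feats: list[tuple] = []
        fam = tr_fams[int(rng.integers(0, len(tr_fams)))]
        n_copies = int(rng.integers(0, 6))
        if n_copies:
            feats.append(("tr", fam, n_copies))
            feats.append(("spacer", int(rng.integers(100, 400))))
        if rng.random() < 0.7:
            te_name, te_max = te_recs[int(rng.integers(0, len(te_recs)))]
            length = int(rng.integers(60, min(te_max, 1200) + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            feats.append(("te", te_name, length, strand))
            feats.append(("spacer", int(rng.integers(100, 400))))
        if not feats:
            feats.append(("spacer", int(rng.integers(500, 2000))))
        bps.append(ContigBlueprint(f"c{i:02d}", tuple(feats)))
    return bps


def write_contigs_fasta(contigs: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for cid, seq in contigs:
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
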