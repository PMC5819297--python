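"""Read classification and composition tables."""

import numpy as np
import pytest

from chromoscan import (
    RepeatLibrary,
    RepeatRecord,
    Read,
    ScoringScheme,
    SimConfig,
    UNASSIGNED,
    classify_read,
    classify_reads,
    duplicate_tandem_consensus,
    generate_reads,
    quantify,
)
from chromoscan.simulate import ELEMENT_PARTS


def mkread(seq, rid="r"):
    return Read(rid, seq, np.full(len(seq), 38))


def element_of(lib, family):
    """Map an assigned record name to its element-level family."""
    rec = lib[family]
    if rec.te_part != "none":
        return rec.subclass  # ERV parts carry the element name as subclass
    return family


class TestClassifyRead:
    def test_masat_read_assigned_unambiguously(self, lib):
        read = mkread(lib["MaSat"].seq[50:87])
        a = classify_read(read, lib)
        assert a.family == "MaSat" and not a.ambiguous
        assert (a.ref_start, a.ref_end) == (50, 87)

    def test_junction_read_coordinates_mod_monomer(self, lib):
        """A read spanning the monomer junction (last 18 + first 19 bases)
        maps inside the duplicated consensus; start is reported modulo
        234 near the monomer end."""
        mono = lib["MaSat"].seq
        read = mkread(mono[-18:] + mono[:19])
        dup = duplicate_tandem_consensus(lib["MaSat"]).seq
        assert read.seq in dup  # junction 37-mer is contiguous there
        a = classify_read(read, lib)
        assert a.family == "MaSat"
        assert a.ref_start == 234 - 18
        assert a.ref_end == a.ref_start + 37  # wraps past the monomer end
        assert a.score == 74

    def test_tie_broken_by_priority_and_flagged(self):
        """Identical block planted in a TR and a LINE record: TR wins by
        class priority and the tie is surfaced."""
        rng = np.random.default_rng(8)
        block = "".join("ACGT"[i] for i in rng.integers(0, 4, 37))
        pad = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        pad2 = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        lib = RepeatLibrary(
            [
                RepeatRecord(name="lineA", seq=pad + block, repclass="LINE"),
                RepeatRecord(
                    name="trB",
                    seq=block + pad2[: 234 - 37],
                    repclass="TR",
                    subclass="x",
                    is_tandem=True,
                    monomer_len=234,
                ),
            ]
        )
        a = classify_read(mkread(block), lib)
        assert a.family == "trB" and a.ambiguous

    def test_tie_within_class_broken_by_name(self):
        rng = np.random.default_rng(9)
        block = "".join("ACGT"[i] for i in rng.integers(0, 4, 37))
        mk = lambda name, pad: RepeatRecord(
            name=name,
            seq=pad + block,
            repclass="ERV2",
            subclass="IAP",
            te_part="LTR" if "LTR" in name else "internal",
        )
        pads = ["".join("ACGT"[i] for i in rng.integers(0, 4, 150)) for _ in range(2)]
        lib = RepeatLibrary([mk("z-int", pads[0]), mk("a-LTR", pads[1])])
        a = classify_read(mkread(block), lib)
        assert a.family == "a-LTR" and a.ambiguous

    def test_unrelated_read_unassigned(self, lib):
        rng = np.random.default_rng(12)
        read = mkread("".join("ACGT"[i] for i in rng.integers(0, 4, 37)))
        assert classify_read(read, lib).family == UNASSIGNED

    def test_empty_library_errors(self, lib):
        with pytest.raises(ValueError):
            classify_read(mkread("ACGT" * 10), RepeatLibrary([]))


class TestNoiseFreeRecovery:
    @staticmethod
    def _max_single_part_overlap(lib, family, seq):
        """Longest overlap of the read with any single part record of an
        LTR-internal-LTR element, over both strands."""
        from .oracle import revcomp

        _cls, parts = ELEMENT_PARTS[family]
        element = "".join(lib[p].seq for p in parts)
        bounds = []
        pos = 0
        for p in parts:
            bounds.append((pos, pos + len(lib[p].seq)))
            pos += len(lib[p].seq)
        best = 0
        for s in (seq, revcomp(seq)):
            at = element.find(s)
            while at != -1:
                for lo, hi in bounds:
                    best = max(best, min(at + len(s), hi) - max(at, lo))
                at = element.find(s, at + 1)
        return best

    def test_all_reads_recovered_at_element_level(self, lib):
        """With zero divergence and zero sequencing error every read maps
        back to its true family; background reads stay unassigned.  The
        one legitimate exception: ERV reads straddling an LTR-internal
        junction with under 20 bases in each part cannot reach the score
        floor against any single record."""
        cfg = SimConfig(seed=4, per_base_error=0.0, monomer_divergence=0.0)
        reads, truth = generate_reads(cfg, lib, 2000)
        fam = dict(zip(truth.reads["read_id"], truth.reads["family"]))
        seqs = {r.id: r.seq for r in reads}
        for a in classify_reads(reads, lib):
            true = fam[a.read_id]
            if true == "background":
                assert a.family == UNASSIGNED
            elif a.assigned:
                assert element_of(lib, a.family) == true
            else:
                assert true in ELEMENT_PARTS, f"{a.read_id} from {true}"
                assert (
                    self._max_single_part_overlap(lib, true, seqs[a.read_id])
                    < 20
                )


class TestQuantify:
    def test_percentages_are_simple_fractions(self, lib):
        reads = [
            mkread(lib["MaSat"].seq[i % 190 : i % 190 + 37], f"m{i}")
            for i in range(66)
        ]
        rng = np.random.default_rng(3)
        reads += [
            mkread("".join("ACGT"[i] for i in rng.integers(0, 4, 37)), f"b{j}")
            for j in range(34)
        ]
        table = quantify(reads, lib)
        assert table.percent("MaSat") == pytest.approx(66.0)
        assert table.total_reads == 100
        assert table.n_unassigned == 34
        assert table.rollup("All") == pytest.approx(66.0)

    def test_zero_reads_flagged(self, lib):
        table = quantify([], lib)
        assert table.zero_denominator
        assert table.rollup("All") == 0.0

    def test_no_repeat_reads_all_zero(self, lib):
        rng = np.random.default_rng(6)
        reads = [
            mkread("".join("ACGT"[i] for i in rng.integers(0, 4, 37)), f"b{j}")
            for j in range(50)
        ]
        table = quantify(reads, lib)
        assert table.rollup("All") == 0.0
        assert table.n_unassigned == 50

    def test_min_score_monotonicity(self, lib):
        """Raising min_score never increases any family's count."""
        cfg = SimConfig(seed=7)
        reads, _ = generate_reads(cfg, lib, 600)
        lo = quantify(reads, lib, ScoringScheme(min_score=40))
        hi = quantify(reads, lib, ScoringScheme(min_score=60))
        merged = lo.families.merge(hi.families, on="family", suffixes=("_lo", "_hi"))
        assert (merged["count_hi"] <= merged["count_lo"]).all()

    def test_denominator_conservation_and_rollups(self, lib):
        cfg = SimConfig(seed=10)
        reads, _ = generate_reads(cfg, lib, 1000)
        table = quantify(reads, lib)
        assert int(table.families["count"].sum()) + table.n_unassigned == 1000
        r = table.rollups().set_index("row")["percent"]
        assert r["ERVAll"] == pytest.approx(
            r["ERV1"] + r["ERV2All"] + r["ERV3"], abs=1e-9
        )
        assert r["IAP"] <= r["ERV2All"]
        erv = table.erv_table()
        assert set(erv["te_part"]) <= {"internal", "LTR"}
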