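"""Synthetic-data generator: determinism, truth consistency, composition
convergence, consensus dissimilarity."""

import numpy as np
import pytest

from chromoscan import (
    SimConfig,
    generate_contigs,
    generate_library,
    generate_reads,
)
from chromoscan.qc import write_fastq
from chromoscan.simulate import (
    DEFAULT_COMPOSITION,
    ELEMENT_PARTS,
    ContigBlueprint,
    default_screen_blueprints,
)

from .oracle import revcomp


class TestLibraryGeneration:
    def test_same_seed_identical(self):
        a = generate_library(3)
        b = generate_library(3)
        assert [(r.name, r.seq) for r in a] == [(r.name, r.seq) for r in b]

    def test_different_seed_differs(self):
        a = generate_library(3)
        b = generate_library(4)
        assert a["MaSat"].seq != b["MaSat"].seq

    def test_stated_monomer_lengths(self, lib):
        assert len(lib["MaSat"].seq) == 234
        assert len(lib["MiSat"].seq) == 120
        assert lib["TEL"].seq == "TTAGGG" * 20

    def test_consensuses_mutually_dissimilar(self, lib):
        """Pairwise global identity < 55% for all record pairs, checked
        with edlib as the independent aligner."""
        import edlib

        recs = [r for r in lib if r.name != "TEL"]
        for i, a in enumerate(recs):
            for b in recs[i + 1 :]:
                d = edlib.align(a.seq, b.seq, task="distance")["editDistance"]
                ident = 1.0 - d / max(len(a.seq), len(b.seq))
                assert ident < 0.55, f"{a.name} vs {b.name}: {ident:.2f}"


class TestReadGeneration:
    def test_same_seed_byte_identical_fastq(self, lib, tmp_path):
        f1, f2 = tmp_path / "a.fastq", tmp_path / "b.fastq"
        r1, _ = generate_reads(SimConfig(seed=9), lib, 500, out_fastq=f1)
        r2, _ = generate_reads(SimConfig(seed=9), lib, 500, out_fastq=f2)
        assert f1.read_bytes() == f2.read_bytes()
        assert [r.seq for r in r1] == [r.seq for r in r2]

    def test_noise_free_reads_are_exact_source_substrings(self, lib):
        """With zero error and divergence, every read is a substring of
        its family's (tiled/assembled) consensus on either strand."""
        cfg = SimConfig(seed=10, per_base_error=0.0, monomer_divergence=0.0)
        reads, truth = generate_reads(cfg, lib, 1000)
        fam = dict(zip(truth.reads["read_id"], truth.reads["family"]))
        sources = {}
        for name, frac in DEFAULT_COMPOSITION.items():
            if name in ELEMENT_PARTS:
                _cls, parts = ELEMENT_PARTS[name]
                sources[name] = "".join(lib[p].seq for p in parts)
            elif lib[name].is_tandem:
                unit = (
                    lib[name].seq[: lib[name].monomer_len]
                    if lib[name].is_expanded
                    else lib[name].seq
                )
                sources[name] = unit * (3 + 240 // len(unit))
            else:
                sources[name] = lib[name].seq
        for r in reads:
            f = fam[r.id]
            if f == "background":
                continue
            src = sources[f]
            assert r.seq in src or revcomp(r.seq) in src, (f, r.id)

    def test_realized_composition_recorded(self, lib):
        _reads, truth = generate_reads(SimConfig(seed=11), lib, 2000)
        assert truth.n_reads == 2000
        assert truth.reads.shape[0] == 2000
        assert sum(truth.realized.values()) == pytest.approx(1.0)

    def test_composition_converges_with_n(self, lib):
        """Multinomial sampling: absolute deviation from the target
        composition shrinks from n=2e3 to n=2e4."""
        def total_dev(n, seed):
            _r, truth = generate_reads(SimConfig(seed=seed), lib, n)
            return sum(
                abs(truth.realized[f] - v)
                for f, v in DEFAULT_COMPOSITION.items()
            )

        assert total_dev(20_000, 12) < total_dev(2_000, 12)

    def test_composition_above_one_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(composition={"MaSat": 0.7, "MiSat": 0.4})

    def test_reads_have_fixed_length_and_pairing(self, lib):
        reads, _ = generate_reads(SimConfig(seed=13), lib, 100)
        assert all(len(r) == 37 for r in reads)
        assert sum(r.id.endswith("/1") for r in reads) == 50
        assert sum(r.id.endswith("/2") for r in reads) == 50


class TestContigGeneration:
    def test_blueprint_truth_verdicts(self, lib):
        bps = [
            ContigBlueprint("v0", (("tr", "MaSat", 2), ("spacer", 100), ("te", "IAP-LTR", 450, "+"))),
            ContigBlueprint("v1", (("tr", "TRPC-21A", 2), ("te", "IAP-LTR", 450, "+"))),
            ContigBlueprint("v2", (("spacer", 5000),)),
        ]
        _contigs, truth = generate_contigs(bps, lib, seed=20)
        assert truth.verdict("v0", "MaSat", 1) is True
        assert truth.verdict("v1", "TRPC-21A", 3) is False
        assert truth.verdict("v2", "MaSat", 1) is False

    def test_planted_coordinates_match_sequence(self, lib):
        bps = [
            ContigBlueprint(
                "w0", (("spacer", 250), ("te", "MERVL-LTR", 420, "+"), ("spacer", 100))
            )
        ]
        contigs, truth = generate_contigs(bps, lib, seed=21)
        seq = contigs[0][1]
        row = truth.features.iloc[0]
        assert seq[row.start : row.end] == lib["MERVL-LTR"].seq[:420]

    def test_unknown_feature_errors(self, lib):
        with pytest.raises(ValueError):
            generate_contigs(
                [ContigBlueprint("x", (("te", "NoSuchTE", 100, "+"),))], lib
            )

    def test_te_length_beyond_record_errors(self, lib):
        with pytest.raises(ValueError):
            generate_contigs(
                [ContigBlueprint("x", (("te", "IAP-LTR", 9999, "+"),))], lib
            )

    def test_default_blueprints_deterministic_and_sized(self):
        a = default_screen_blueprints(7, 50)
        b = default_screen_blueprints(7, 50)
        assert len(a) == 50
        assert a == b
        assert len({bp.contig_id for bp in a}) == 50
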