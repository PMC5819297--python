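"""TR + ERV co-occurrence screen: TE annotation, discard rule, verdicts,
structure maps."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from chromoscan import (
    ScoringScheme,
    ScreenCriteria,
    annotate_te,
    generate_contigs,
    screen_batch,
    screen_contig,
)
from chromoscan.screen import evalue, karlin_lambda
from chromoscan.simulate import ContigBlueprint

from .oracle import revcomp


def rand_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestEvalue:
    def test_lambda_solves_the_karlin_equation(self):
        lam = karlin_lambda(2, -3)
        # independent check of sum p_i p_j exp(lambda s_ij) = 1
        val = 0.25 * math.exp(lam * 2) + 0.75 * math.exp(lam * -3)
        assert val == pytest.approx(1.0, abs=1e-9)

    def test_evalue_against_independent_formula(self, scheme):
        lam = brentq(
            lambda l: 0.25 * math.exp(2 * l) + 0.75 * math.exp(-3 * l) - 1,
            1e-9,
            5,
        )
        expected = 0.1 * 450 * 3000 * math.exp(-lam * 120)
        assert evalue(120, 450, 3000, scheme) == pytest.approx(expected, rel=1e-9)

    def test_evalue_decreases_with_score(self, scheme):
        assert evalue(100, 450, 3000, scheme) < evalue(60, 450, 3000, scheme)


class TestAnnotateTE:
    def test_exact_ltr_copy_retained(self, lib):
        rng = np.random.default_rng(41)
        ltr = lib["IAP-LTR"].seq
        contig = rand_seq(rng, 600) + ltr + rand_seq(rng, 400)
        frags = annotate_te("c", contig, lib)
        assert len(frags) == 1
        f = frags[0]
        assert f.te_name == "IAP-LTR" and f.te_part == "LTR"
        assert f.length == 450
        assert not (f.evalue > 1e-10 and f.score < 100)

    def test_weak_decoy_fails_both_thresholds_and_is_discarded(self, lib):
        """A 22-base planted fragment scores 44 (< 100) with e-value
        >> 1e-10, so the discard rule removes it — confirmed against the
        independently computed e-value."""
        rng = np.random.default_rng(42)
        decoy = lib["IAP-LTR"].seq[100:122]
        contig = rand_seq(rng, 1000) + decoy + rand_seq(rng, 978)
        lam = brentq(
            lambda l: 0.25 * math.exp(2 * l) + 0.75 * math.exp(-3 * l) - 1,
            1e-9,
            5,
        )
        ev = 0.1 * 450 * 2000 * math.exp(-lam * 44)
        assert ev > 1e-10 and 44 < 100  # decoy fails both thresholds
        frags = annotate_te("c", contig, lib)
        assert frags == []

    def test_score_only_mode_keeps_by_score_alone(self, lib):
        rng = np.random.default_rng(43)
        piece = lib["IAP-LTR"].seq[:60]  # score 120 >= 100
        contig = rand_seq(rng, 500) + piece + rand_seq(rng, 500)
        frags = annotate_te("c", contig, lib, score_only=True)
        # chance extension into the flanking random sequence may add a
        # few positive-scoring columns beyond the planted 60
        assert len(frags) == 1
        assert 60 <= frags[0].length <= 80 and frags[0].score >= 120

    def test_ltr_internal_ltr_layout_in_order(self, lib):
        ltr = lib["IAP-LTR"].seq
        internal = lib["IAPEZ-int"].seq[:1200]
        contig = ltr + internal + revcomp(ltr)
        frags = annotate_te("c", contig, lib)
        assert [f.te_part for f in frags] == ["LTR", "internal", "LTR"]
        assert [f.start for f in frags] == sorted(f.start for f in frags)
        assert frags[2].strand == "-"


class TestScreenContig:
    def bp_contig(self, lib, features, seed=50):
        contigs, _ = generate_contigs(
            [ContigBlueprint("c", tuple(features))], lib, seed=seed
        )
        return contigs[0][1]

    def test_masat_plus_long_ltr_positive(self, lib):
        seq = self.bp_contig(
            lib, [("tr", "MaSat", 2), ("spacer", 100), ("te", "IAP-LTR", 450, "+")]
        )
        res = screen_contig("c", seq, ScreenCriteria("MaSat", 1), lib)
        assert res.positive

    def test_two_trpc_monomers_negative_three_positive(self, lib):
        crit = ScreenCriteria("TRPC-21A", 3)
        seq2 = self.bp_contig(
            lib, [("tr", "TRPC-21A", 2), ("spacer", 100), ("te", "IAP-LTR", 450, "+")]
        )
        seq3 = self.bp_contig(
            lib, [("tr", "TRPC-21A", 3), ("spacer", 100), ("te", "IAP-LTR", 450, "+")]
        )
        assert not screen_contig("c", seq2, crit, lib).positive
        assert screen_contig("c", seq3, crit, lib).positive

    def test_exactly_400_base_fragment_negative(self, lib):
        """The rule is strictly 'longer than 400'."""
        seq = self.bp_contig(
            lib, [("tr", "MaSat", 5), ("spacer", 200), ("te", "MERVL-LTR", 400, "+")]
        )
        res = screen_contig("c", seq, ScreenCriteria("MaSat", 1), lib)
        assert not res.positive
        assert max(f.length for f in res.te_evidence) == 400

    def test_internal_fragment_counts_unless_ltr_only(self, lib):
        seq = self.bp_contig(
            lib, [("tr", "MaSat", 1), ("spacer", 120), ("te", "IAPEZ-int", 800, "+")]
        )
        crit = ScreenCriteria("MaSat", 1)
        assert screen_contig("c", seq, crit, lib).positive
        assert not screen_contig("c", seq, crit, lib, ltr_only=True).positive

    def test_unknown_tr_family_errors(self, lib):
        with pytest.raises(KeyError):
            screen_contig("c", "ACGT" * 100, ScreenCriteria("NoSuchSat"), lib)

    def test_te_monotonicity(self, lib):
        """Appending a qualifying fragment flips negative -> positive;
        removing all long fragments forces negative."""
        crit = ScreenCriteria("MaSat", 1)
        base = self.bp_contig(lib, [("tr", "MaSat", 3)])
        assert not screen_contig("c", base, crit, lib).positive
        plus = base + lib["IAP-LTR"].seq
        assert screen_contig("c", plus, crit, lib).positive
        short = base + lib["IAP-LTR"].seq[:300]
        assert not screen_contig("c", short, crit, lib).positive

    def test_structure_map_partitions_contig(self, lib):
        seq = self.bp_contig(
            lib,
            [
                ("tr", "MaSat", 2),
                ("spacer", 600),
                ("te", "IAP-LTR", 450, "+"),
                ("te", "IAPEZ-int", 1500, "+"),
                ("te", "IAP-LTR", 450, "+"),
            ],
        )
        res = screen_contig("c", seq, ScreenCriteria("MaSat", 1), lib)
        ivs = res.structure_map
        assert ivs[0].start == 0 and ivs[-1].end == len(seq)
        for a, b in zip(ivs, ivs[1:]):
            assert a.end == b.start  # no gaps, no overlaps
        labels = [iv.label for iv in ivs]
        assert "TR" in labels and "TE-LTR" in labels and "TE-internal" in labels


class TestScreenBatch:
    def test_duplicate_contig_ids_rejected(self, lib):
        contigs = [("c1", "ACGT" * 300), ("c1", "ACGT" * 300)]
        with pytest.raises(ValueError, match="duplicate"):
            screen_batch(contigs, [ScreenCriteria("MaSat", 1)], lib)

    def test_empty_set_zero_counts(self, lib):
        counts, results = screen_batch([], [ScreenCriteria("MaSat", 1)], lib)
        assert counts == {"MaSat": 0} and results == {"MaSat": []}

    def test_counts_match_manual_rule_application(self, lib):
        """Verdict counts equal direct application of the positivity rule
        to the blueprint truth (10 contigs, 4 constructed MaSat-positive)."""
        bps = [
            ContigBlueprint("k0", (("tr", "MaSat", 1), ("te", "IAP-LTR", 450, "+"))),
            ContigBlueprint("k1", (("tr", "MaSat", 2), ("te", "MERVL-LTR", 500, "-"))),
            ContigBlueprint("k2", (("tr", "MaSat", 3), ("te", "IAPEZ-int", 600, "+"))),
            ContigBlueprint("k3", (("tr", "MaSat", 1), ("spacer", 300), ("te", "RLTR6-LTR", 480, "+"))),
            ContigBlueprint("k4", (("tr", "MaSat", 4),)),
            ContigBlueprint("k5", (("te", "IAP-LTR", 450, "+"),)),
            ContigBlueprint("k6", (("tr", "MiSat", 2), ("te", "IAP-LTR", 450, "+"))),
            ContigBlueprint("k7", (("tr", "MaSat", 2), ("te", "MERVL-LTR", 400, "+"))),
            ContigBlueprint("k8", (("spacer", 2000),)),
            ContigBlueprint("k9", (("tr", "TRPC-21A", 4), ("te", "IAP-LTR", 450, "+"))),
        ]
        contigs, truth = generate_contigs(bps, lib, seed=55)
        crit = ScreenCriteria("MaSat", 1)
        counts, results = screen_batch(contigs, [crit], lib)
        manual = sum(
            truth.verdict(cid, "MaSat", 1) for cid, _ in contigs
        )
        assert manual == 4
        assert counts["MaSat"] == 4
        for res in results["MaSat"]:
            assert res.positive == truth.verdict(res.contig_id, "MaSat", 1)

    def test_determinism(self, lib):
        bps = [
            ContigBlueprint("d0", (("tr", "MaSat", 2), ("te", "IAP-LTR", 450, "+"))),
            ContigBlueprint("d1", (("spacer", 1500),)),
        ]
        contigs, _ = generate_contigs(bps, lib, seed=60)
        c1, _ = screen_batch(contigs, [ScreenCriteria("MaSat", 1)], lib)
        c2, _ = screen_batch(contigs, [ScreenCriteria("MaSat", 1)], lib)
        assert c1 == c2
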