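"""Motif discovery, stem-loop detection and shuffled-background enrichment."""

from collections import Counter

import numpy as np
import pytest

from clipribo import motifs

LBE_RNA = "UUUUAACAUUAUUUU"


def _random_seqs(n, length, seed, alphabet="ACGT"):
    rng = np.random.default_rng(seed)
    return ["".join(rng.choice(list(alphabet), size=length)) for _ in range(n)]


class TestSplit:
    def test_equal_halves_974(self):
        train, test = motifs.split_train_test(["ACGT"] * 974, seed=0)
        assert (len(train), len(test)) == (487, 487)

    def test_ceil_rule_odd(self):
        train, test = motifs.split_train_test(list("ABCDE"), seed=0)
        assert (len(train), len(test)) == (3, 2)
        assert sorted(train + test) == list("ABCDE")

    def test_deterministic(self):
        seqs = _random_seqs(10, 20, 3)
        assert motifs.split_train_test(seqs, seed=4) == motifs.split_train_test(seqs, seed=4)

    def test_too_few_sequences(self):
        with pytest.raises(ValueError):
            motifs.split_train_test(["A"], seed=0)


class TestDiscoverPwm:
    def test_recovers_planted_motif_exactly(self):
        rng = np.random.default_rng(7)
        seqs = []
        for _ in range(80):
            s = "".join(rng.choice(list("ACGU"), size=45))
            off = int(rng.integers(0, 45 - 15))
            seqs.append(s[:off] + LBE_RNA + s[off + 15 :])
        pwm = motifs.discover_pwm(seqs, width=15, n_restarts=6, seed=1)
        assert pwm.consensus == LBE_RNA
        assert pwm.rna  # consensus reported in the input alphabet

    def test_noise_gives_weak_columns(self):
        # EM self-selection sharpens noise columns to ~0.8 bits; signal
        # columns of an exactly planted motif reach ~2 bits
        pwm = motifs.discover_pwm(_random_seqs(200, 50, 0), width=15, seed=1)
        assert pwm.information_content().max() < 1.2

    def test_repeated_sequence_gives_point_masses(self):
        pwm = motifs.discover_pwm(["ACGTACGTACGTACGTAC"] * 20, width=15, seed=0)
        assert pwm.matrix.max(axis=1).min() > 0.9
        assert pwm.consensus in "ACGTACGTACGTACGTAC"

    def test_degenerate_input_flagged(self):
        pwm = motifs.discover_pwm(["A" * 20] * 5, width=15, seed=0)
        assert pwm.low_complexity

    def test_columns_sum_to_one(self):
        pwm = motifs.discover_pwm(_random_seqs(30, 30, 2), width=15, seed=3)
        assert np.allclose(pwm.matrix.sum(axis=1), 1.0)
        assert ((pwm.information_content() >= 0) & (pwm.information_content() <= 2)).all()

    def test_sequence_shorter_than_width_rejected(self):
        with pytest.raises(ValueError):
            motifs.discover_pwm(["ACGTACGT"], width=15)


@pytest.fixture(scope="module")
def pwm():
    rng = np.random.default_rng(7)
    seqs = []
    for _ in range(60):
        s = "".join(rng.choice(list("ACGU"), size=40))
        off = int(rng.integers(0, 40 - 15))
        seqs.append(s[:off] + LBE_RNA + s[off + 15 :])
    return motifs.discover_pwm(seqs, width=15, n_restarts=6, seed=1)


class TestScanPwm:

    def test_consensus_scores_maximally_at_offset_zero(self, pwm):
        hits = motifs.scan_pwm(pwm, [pwm.consensus], score_cutoff=0.0)
        assert hits and hits[0].start == 0
        assert hits[0].score == pytest.approx(pwm.max_score(), abs=1e-9)

    def test_reverse_complement_not_hit(self, pwm):
        rc = pwm.consensus.translate(str.maketrans("ACGU", "UGCA"))[::-1]
        cutoff = 0.8 * pwm.max_score()
        assert motifs.scan_pwm(pwm, [rc], cutoff) == []
        assert motifs.scan_pwm(pwm, [pwm.consensus], cutoff) != []

    def test_infinite_cutoff_yields_no_hits(self, pwm):
        assert motifs.scan_pwm(pwm, [pwm.consensus * 3], np.inf) == []

    def test_short_sequence_yields_no_hits(self, pwm):
        assert motifs.scan_pwm(pwm, ["ACGU"], -np.inf) == []


def brute_force_stem_loops(seq, stem_range=(4, 5), loop_range=(3, 12), min_u=0.5):
    """Independent oracle: try every (start, stem, loop) decomposition using
    string reversal + complement lookup."""
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    seq = seq.upper().replace("U", "T")
    found = set()
    for start in range(len(seq)):
        for stem in range(stem_range[0], stem_range[1] + 1):
            for loop in range(loop_range[0], loop_range[1] + 1):
                end = start + 2 * stem + loop
                if end > len(seq):
                    continue
                arm1 = seq[start : start + stem]
                arm2 = seq[end - stem : end]
                expected = "".join(comp[b] for b in reversed(arm1))
                if arm2 != expected:
                    continue
                loop_seq = seq[start + stem : end - stem]
                if loop_seq.count("T") / loop < min_u:
                    continue
                found.add((start, end))
    return found


class TestStemLoops:
    def test_handchecked_example(self):
        # GGUG / UUUAU / CACC: 4-bp stem with a 5-nt U-rich loop
        hits = motifs.detect_stem_loops(["GGUGUUUAUCACC"])
        assert {(h.start, h.end) for h in hits} == {(0, 13)}

    def test_polya_has_no_hits(self):
        assert motifs.detect_stem_loops(["A" * 30]) == []

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_bruteforce_enumeration(self, seed):
        for seq in _random_seqs(80, 55, seed, alphabet="ACGTTT"):
            ours = {
                (h.start, h.end) for h in motifs.detect_stem_loops([seq])
            }
            assert ours == brute_force_stem_loops(seq)

    def test_wobble_extends_hit_set(self):
        # G:U closing pair only valid with wobble enabled
        seq = "GGTGTTTTGCACT"  # arm GGTG vs TACC would fail; craft G-T pair
        strict = {(h.start, h.end) for h in motifs.detect_stem_loops([seq])}
        wobble = {
            (h.start, h.end)
            for h in motifs.detect_stem_loops([seq], motifs.StemLoopRule(allow_wobble=True))
        }
        assert strict <= wobble

    def test_cde_rule_requires_py_pu_py_triloop(self):
        # stem GGGG + loop TAT (Py-Pu-Py) + CCCC
        assert motifs.detect_stem_loops(["GGGGTATCCCC"], motifs.CDE_RULE)
        # loop ATA (Pu-Py-Pu) rejected
        assert not motifs.detect_stem_loops(["GGGGATACCCC"], motifs.CDE_RULE)


class TestShuffleAndEnrichment:
    def test_composition_conserved(self, rng):
        seqs = _random_seqs(20, 30, 5)
        (shuffled,) = motifs.shuffle_background(seqs, n_sets=1, seed=1)
        for orig, shuf in zip(seqs, shuffled):
            assert Counter(orig) == Counter(shuf)

    def test_homopolymer_unchanged(self):
        (shuffled,) = motifs.shuffle_background(["UUUUUUUU"], n_sets=1, seed=0)
        assert shuffled == ["UUUUUUUU"]

    def test_dinucleotide_shuffle_preserves_dinucleotides(self, rng):
        seq = "ACGTACGGTTACGATCGA"
        shuf = motifs.dinucleotide_shuffle(seq, rng)
        pairs = lambda s: Counter(zip(s[:-1], s[1:]))
        assert pairs(shuf) == pairs(seq) and len(shuf) == len(seq)

    def test_identical_background_gives_fold_one(self):
        seqs = {f"s{i}": s for i, s in enumerate(_random_seqs(40, 40, 8, "ACGTT"))}
        scanner = lambda d: motifs.detect_stem_loops(d)
        comp = motifs.motif_enrichment("SL_motif", seqs, [list(seqs.values())], scanner)
        assert comp.fold == pytest.approx(1.0)
        assert comp.empirical_p == 1.0

    def test_empirical_p_granularity(self):
        seqs = {f"s{i}": s for i, s in enumerate(_random_seqs(30, 40, 9))}
        shuffled = motifs.shuffle_background(list(seqs.values()), n_sets=3, seed=2)
        comp = motifs.motif_enrichment(
            "SL_motif", seqs, shuffled, lambda d: motifs.detect_stem_loops(d)
        )
        assert comp.empirical_p in (0.0, 1 / 3, 2 / 3, 1.0)

    def test_shuffling_destroys_planted_hits(self):
        rng = np.random.default_rng(3)
        seqs = []
        for _ in range(60):
            s = "".join(rng.choice(list("ACGU"), size=45))
            seqs.append(s[:10] + LBE_RNA + s[25:])
        pwm = motifs.discover_pwm(seqs, width=15, n_restarts=4, seed=0)
        shuffled = motifs.shuffle_background(seqs, n_sets=3, seed=4)
        cutoff = motifs.score_cutoff_from_shuffles(pwm, shuffled[0])
        named = {f"s{i}": s for i, s in enumerate(seqs)}
        comp = motifs.motif_enrichment(
            "LBE", named, shuffled, lambda d: motifs.scan_pwm(pwm, d, cutoff)
        )
        assert comp.observed_fraction > 0.9
        assert comp.background_fraction < 0.3
        assert comp.fold > 2

    def test_fold_invariant_under_duplication(self):
        seqs = _random_seqs(30, 40, 11, "ACGTT")
        named = {f"s{i}": s for i, s in enumerate(seqs)}
        doubled = {f"s{i}": s for i, s in enumerate(seqs + seqs)}
        scanner = lambda d: motifs.detect_stem_loops(d)
        shuffled = [list(named.values())]
        c1 = motifs.motif_enrichment("SL_motif", named, shuffled, scanner)
        c2 = motifs.motif_enrichment("SL_motif", doubled, [seqs + seqs], scanner)
        assert c1.fold == pytest.approx(c2.fold)


class TestSiteCounting:
    def test_overlapping_kinds_count_once(self):
        hits = [
            motifs.MotifHit("tx1", 100, 115, "LBE", 5.0),
            motifs.MotifHit("tx1", 105, 118, "SL_motif", 4.0),
            motifs.MotifHit("tx1", 200, 215, "LBE", 5.0),
        ]
        counts = motifs.count_sites_per_transcript(hits)
        assert counts.set_index("transcript_id").loc["tx1", "n_sites"] == 2
        assert counts.iloc[0]["element_kinds"] == "LBE,SL_motif"

    def test_no_hits_empty_frame(self):
        assert motifs.count_sites_per_transcript([]).empty

    def test_strata_histogram(self):
        hits = []
        for tid, n in [("a", 1), ("b", 2), ("c", 5)]:
            hits += [motifs.MotifHit(tid, 50 * i, 50 * i + 15, "LBE", 1.0) for i in range(n)]
        hist = motifs.site_count_histogram(motifs.count_sites_per_transcript(hits))
        assert hist.to_dict() == {"1": 1, "2": 1, "3": 0, "4+": 1}

    def test_lift_hits_back_to_transcript_coordinates(self):
        h = motifs.MotifHit("tx7:120-160", 5, 20, "LBE", 3.0)
        (lifted,) = motifs.lift_hits_to_transcripts([h])
        assert (lifted.transcript_id, lifted.start, lifted.end) == ("tx7", 125, 140)


class TestPositionalDistribution:
    def _tx(self, tid="tx", utr3=500):
        from clipribo.types import TranscriptModel

        seq = "A" * 10 + "ATG" + "C" * 24 + "TAA" + "G" * utr3
        return TranscriptModel(tid, seq, 10, 40)

    def test_single_site_at_stop_codon(self):
        t = self._tx()
        hits = [motifs.MotifHit("tx", 40, 55, "LBE", 1.0)]
        dist = motifs.site_positional_distribution(hits, [t])
        assert dist.loc[dist["bin"] == 1, "density"].iloc[0] == 1.0

    def test_bimodal_for_first_and_last_decile(self):
        t = self._tx()
        hits = [
            motifs.MotifHit("tx", 45, 60, "LBE", 1.0),       # first decile
            motifs.MotifHit("tx", 520, 535, "LBE", 1.0),     # last decile
        ]
        dist = motifs.site_positional_distribution(hits, [t]).set_index("bin")
        assert dist.loc[1, "density"] == 0.5 and dist.loc[10, "density"] == 0.5
        assert dist["density"].sum() == pytest.approx(1.0)
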