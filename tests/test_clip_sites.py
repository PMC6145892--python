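"""Site-calling operations against brute-force oracles and boundary rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clipribo import clip_sites
from clipribo.simulate import (
    SimulationConfig,
    draw_abundances,
    generate_transcriptome,
    plant_sites,
    simulate_clip_reads,
)
from clipribo.types import AlignedRead, BindingCluster, ReadSet, TranscriptModel


def _readset(rows, qualities=None, **kw):
    """rows: (transcript_id, start, length)."""
    reads = [AlignedRead(f"r{i}", tid, s, ln) for i, (tid, s, ln) in enumerate(rows)]
    rs = ReadSet.from_reads(reads, **kw)
    rs.qualities = qualities
    return rs


def _transcript(length=550, utr5=50, cds=300, tid="tx"):
    seq = "A" * utr5 + "ATG" + "C" * (cds - 6) + "TAA" + "G" * (length - utr5 - cds)
    return TranscriptModel(tid, seq, utr5, utr5 + cds)


class TestQcFilter:
    def test_length_and_quality_rules(self):
        rows = [("tx", 0, 19), ("tx", 0, 20), ("tx", 0, 20)]
        quals = [None, [30] * 20, [30] * 17 + [10] * 3]  # 3/20 = 15% below Q20
        rs = _readset(rows, qualities=quals)
        kept = clip_sites.qc_filter_reads(rs)
        assert len(kept) == 1 and kept.lengths[0] == 20

    def test_missing_qualities_skips_quality_clause(self):
        rs = _readset([("tx", 0, 25), ("tx", 5, 19)])
        kept = clip_sites.qc_filter_reads(rs)
        assert list(kept.lengths) == [25]

    def test_order_preserved(self):
        rs = _readset([("tx", i, 20 + i) for i in range(5)])
        kept = clip_sites.qc_filter_reads(rs)
        assert list(kept.starts) == list(range(5))


class TestWindowCounts:
    def test_single_read_overlap_span(self):
        t = _transcript(550)
        rs = _readset([("tx", 100, 30)])
        counts = clip_sites.window_counts(rs, [t], width=40)["tx"]
        hit = np.flatnonzero(counts == 1)
        assert hit.min() == 61 and hit.max() == 129
        assert counts.sum() == 129 - 61 + 1

    def test_no_reads_all_zero(self):
        t = _transcript(100, utr5=10, cds=60)
        counts = clip_sites.window_counts(_readset([]), [t], width=40)["tx"]
        assert counts.shape == (61,) and not counts.any()

    def test_duplicate_reads_additive(self):
        t = _transcript(200)
        one = clip_sites.window_counts(_readset([("tx", 50, 25)]), [t])["tx"]
        two = clip_sites.window_counts(
            _readset([("tx", 50, 25), ("tx", 50, 25)]), [t]
        )["tx"]
        assert np.array_equal(two, 2 * one)

    def test_short_transcript_yields_no_windows(self):
        t = TranscriptModel("tiny", "ATG" + "A" * 6 + "TAA", 0, 9)
        assert clip_sites.window_counts(_readset([]), [t], width=40)["tiny"].size == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_overlap_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        L, width = 120, 15
        t = _transcript(L, utr5=10, cds=60)
        rows = []
        for _ in range(40):
            s = int(rng.integers(0, L - 5))
            ln = int(rng.integers(5, min(30, L - s) + 1))
            rows.append(("tx", s, ln))
        counts = clip_sites.window_counts(_readset(rows), [t], width=width)["tx"]
        brute = np.zeros(L - width + 1, dtype=int)
        for w in range(L - width + 1):
            for _, s, ln in rows:
                if s < w + width and s + ln > w:
                    brute[w] += 1
        assert np.array_equal(counts, brute)


class TestEnrichmentStatistic:
    @pytest.mark.parametrize(
        "r_i,r,p_i,expected",
        [(0, 1000, 0.05, 0.0), (50, 1000, 0.05, 1.0), (100, 1000, 0.05, 2.0)],
    )
    def test_examples(self, r_i, r, p_i, expected):
        assert clip_sites.enrichment_statistic(r_i, r, p_i) == pytest.approx(expected)

    def test_undefined_flagged_not_raised(self):
        assert np.isnan(clip_sites.enrichment_statistic(5, 1000, 0.0))
        assert np.isnan(clip_sites.enrichment_statistic(5, 0, 0.1))

    def test_monotonicity_and_scale_invariance(self, rng):
        r_i = rng.integers(1, 100, size=50)
        p = rng.uniform(0.01, 0.5, size=50)
        e = clip_sites.enrichment_statistic(r_i, 1000, p)
        assert (clip_sites.enrichment_statistic(r_i + 1, 1000, p) > e).all()
        assert (clip_sites.enrichment_statistic(r_i, 1000, p * 1.5) < e).all()
        scaled = clip_sites.enrichment_statistic(r_i * 7, 7000, p)
        assert np.allclose(scaled, e)


class TestBinomialTail:
    def test_basic_values(self):
        assert clip_sites.binomial_tail_probability(0, 10, 0.3) == 1.0
        assert clip_sites.binomial_tail_probability(3, 3, 0.5) == pytest.approx(0.125)

    def test_against_direct_pmf_summation(self):
        # brute force: sum_{j=k..n} C(n,j) p^j (1-p)^(n-j)
        from math import comb

        k, n, p = 7, 20, 0.1
        brute = sum(comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1))
        assert clip_sites.binomial_tail_probability(k, n, p) == pytest.approx(
            brute, abs=1e-12
        )

    def test_domain_error(self):
        with pytest.raises(ValueError):
            clip_sites.binomial_tail_probability(5, 3, 0.1)

    def test_small_grid_oracle(self):
        for n in (1, 5, 17, 60):
            for p in (0.001, 0.05, 0.5):
                k = np.arange(n + 1)
                pmf = stats.binom.pmf(np.arange(n + 1), n, p)
                brute = pmf[::-1].cumsum()[::-1]
                ours = clip_sites.binomial_tail_probability(k, n, p)
                assert np.abs(ours - brute).max() < 1e-9


class TestCallWindows:
    def test_zero_count_windows_never_significant(self):
        counts = {"tx": np.zeros(50, dtype=int)}
        ab = pd.Series({"tx": 0.5})
        out = clip_sites.call_enriched_windows(counts, ab, total_clip_reads=100)
        assert out.empty

    def test_cutoff_degeneracy(self):
        counts = {"tx": np.array([0, 1, 3, 0, 2])}
        ab = pd.Series({"tx": 0.01})
        out = clip_sites.call_enriched_windows(
            counts, ab, total_clip_reads=100, prob_cutoff=0.0
        )
        # alpha = 1: every window with r_i >= 1 (tail < 1) is significant
        assert sorted(out["window_start"]) == [1, 2, 4]

    def test_unknown_transcript_skipped(self):
        counts = {"ghost": np.array([5, 5])}
        ab = pd.Series({"tx": 1.0})
        out = clip_sites.call_enriched_windows(counts, ab, total_clip_reads=10)
        assert out.empty


def _window_frame(tid, starts, rep_tail=1e-6):
    return pd.DataFrame(
        {
            "transcript_id": tid,
            "window_start": starts,
            "r_i": 10,
            "p_i": 0.01,
            "enrichment": 5.0,
            "tail_probability": rep_tail,
        }
    )


class TestMergeAndFilter:
    def test_overlapping_windows_across_replicates_merge(self):
        sig = {1: _window_frame("tx", [0]), 2: _window_frame("tx", [20])}
        reads = {1: _readset([("tx", 10, 20)]), 2: _readset([("tx", 30, 20)])}
        (c,) = clip_sites.merge_clusters(sig, reads, width=40)
        assert (c.start, c.end) == (0, 60)
        assert c.replicate_support == frozenset({1, 2})
        assert c.total_clip_reads == 2

    def test_disjoint_windows_stay_separate(self):
        sig = {1: _window_frame("tx", [0, 100])}
        clusters = clip_sites.merge_clusters(sig, {1: _readset([])}, width=40)
        assert [(c.start, c.end) for c in clusters] == [(0, 40), (100, 140)]

    def test_merge_idempotent_and_disjoint(self, rng):
        starts = sorted(rng.integers(0, 400, size=30))
        sig = {1: _window_frame("tx", starts)}
        clusters = clip_sites.merge_clusters(sig, {1: _readset([])}, width=40)
        spans = [(c.start, c.end) for c in clusters]
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2  # strictly disjoint after maximal merging
        again = clip_sites._merge_intervals(np.array(spans))
        assert again == spans

    @pytest.mark.parametrize(
        "reads,support,kept",
        [
            (50, {1, 2, 3}, False),   # strict > 50
            (51, {1, 2, 3}, True),
            (200, {1, 2}, False),     # must cover all replicates
        ],
    )
    def test_retention_rules(self, reads, support, kept):
        c = BindingCluster("tx", 0, 60, frozenset(support), reads, 1e-9)
        out = clip_sites.filter_clusters([c], min_reads=50, required_replicates=(1, 2, 3))
        assert bool(out) is kept


class TestRegionDensityAndProfile:
    def test_only_utr3_clusters(self):
        t = _transcript(550, utr5=50, cds=300)
        clusters = [
            BindingCluster("tx", 360, 420, frozenset({1}), 100, 1e-9, "3UTR"),
            BindingCluster("tx", 500, 540, frozenset({1}), 100, 1e-9, "3UTR"),
        ]
        dens = clip_sites.region_density(clusters, [t])
        by_region = dens.groupby("region")["clusters_per_nt"].sum()
        assert by_region["5UTR"] == 0 and by_region["CDS"] == 0
        assert by_region["3UTR"] > 0
        assert (dens.groupby("region").size() == 10).all()

    def test_tc_profile_zero_rate_is_flat_zero(self):
        cfg = SimulationConfig(
            n_transcripts=5, clip_depth=20_000, tc_conversion_rate=0.0,
            target_fraction=0.0, seed=3,
        )
        tx = generate_transcriptome(cfg)
        tx, sites = plant_sites(tx, {tx[0].transcript_id: ["LBE"]}, cfg)
        ab = draw_abundances(tx, cfg)
        rs = simulate_clip_reads(tx, sites, ab, cfg, replicate=1)
        anchors = [(s.transcript_id, (s.start + s.end) // 2) for s in sites]
        prof = clip_sites.tc_profile([rs], anchors, tx)
        observed = prof["mean_density"].dropna()
        assert (observed == 0).all()

    def test_tc_profile_recovers_conversion_rate_at_crosslinks(self):
        cfg = SimulationConfig(
            n_transcripts=20, clip_depth=400_000, target_fraction=0.0, seed=6,
        )
        tx = generate_transcriptome(cfg)
        plan = {t.transcript_id: ["LBE"] for t in tx[:15]}
        tx, sites = plant_sites(tx, plan, cfg)
        ab = draw_abundances(tx, cfg)
        rs = simulate_clip_reads(tx, sites, ab, cfg, replicate=1)
        # anchor at the CAC core; crosslinks are the flanking Us
        anchors = []
        for s in sites:
            seq = next(t for t in tx if t.transcript_id == s.transcript_id).sequence
            core = seq[s.start : s.end].find("CAC")
            anchors.append((s.transcript_id, s.start + core + 1))
        prof = clip_sites.tc_profile([rs], anchors, tx, flank=8).set_index("offset")
        # flanking-U densities approach the conversion rate; the core has no T
        flank_density = prof.loc[[-3, -4, 3, 4], "mean_density"].mean()
        assert flank_density == pytest.approx(0.55, abs=0.05)
        assert np.isnan(prof.loc[0, "mean_density"])  # core A: no T positions


def test_cluster_sequences_extracts_spans():
    t = _transcript(200, utr5=30, cds=90)
    c = BindingCluster("tx", 130, 150, frozenset({1}), 60, 1e-9)
    ((name, seq),) = clip_sites.cluster_sequences([c], [t])
    assert name == "tx:130-150" and seq == t.sequence[130:150]
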