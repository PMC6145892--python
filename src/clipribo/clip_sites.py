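"""CLIP binding-site calling against an mRNA-seq abundance background.

The unit of testing is a 40-nt sliding window: with ``r_i`` CLIP reads
overlapping window *i*, ``r`` total CLIP reads in the library and ``p_i`` the
relative mRNA abundance of the host transcript, the enrichment is
``r_i / (p_i * r)`` and the window is significant when the binomial tail
``P(X >= r_i | X ~ Binomial(r, p_i))`` — a regularized incomplete beta
function — drops below ``1 - prob_cutoff``. Significant windows from all
replicates are merged into clusters, which are retained when they carry more
than ``min_reads`` pooled CLIP reads and have support from every replicate.

``p_i`` convention: the default is the transcript-level relative abundance
(the literal definition); ``window_scaled=True`` rescales it by
``width / transcript_length`` so the null refers to the window rather than
the whole mRNA. The literal null only fires when CLIP coverage is far more
concentrated at sites than anywhere else on the transcript; the pipeline
front-ends default to the window-scaled variant for that reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .types import BindingCluster, ReadSet, TranscriptModel, transcripts_by_id

logger = logging.getLogger(__name__)

WINDOW_COLUMNS = [
    "transcript_id", "window_start", "r_i", "p_i", "enrichment", "tail_probability",
]


@dataclass(frozen=True)
class WindowEnrichment:
    """Enrichment statistics for a single 40-nt window."""

    transcript_id: str
    window_start: int
    clip_reads: int          # r_i
    total_clip_reads: int    # r
    mrna_relative_abundance: float  # p_i
    enrichment: float
    tail_probability: float


def qc_filter_reads(
    reads: ReadSet,
    min_len: int = 20,
    max_lowq_frac: float = 0.10,
    q_threshold: int = 20,
) -> ReadSet:
    """Discard reads shorter than ``min_len`` or with more than
    ``max_lowq_frac`` of bases below PHRED ``q_threshold``; order preserved.
    Without quality profiles the quality clause is skipped (logged)."""
    mask = reads.lengths >= min_len
    if reads.qualities is not None:
        for i, q in enumerate(reads.qualities):
            if q is None:
                continue
            q = np.asarray(q)
            if len(q) and (q < q_threshold).mean() > max_lowq_frac:
                mask[i] = False
    else:
        logger.debug("no quality profiles present; PHRED clause skipped")
    return reads.subset(mask)


def window_counts(
    reads: ReadSet,
    transcripts: Sequence[TranscriptModel],
    width: int = 40,
    step: int = 1,
) -> dict[str, np.ndarray]:
    """Per-transcript CLIP read counts for sliding windows.

    A read contributes to a window iff they overlap by >= 1 nt. Window *j*
    spans ``[j*step, j*step + width)``; transcripts shorter than ``width``
    yield zero windows (logged).
    """
    out: dict[str, np.ndarray] = {}
    spans: dict[str, np.ndarray] = {}
    if len(reads):
        order = np.argsort(reads.transcript_ids, kind="stable")
        tid_sorted = reads.transcript_ids[order]
        boundaries = np.flatnonzero(np.r_[True, tid_sorted[1:] != tid_sorted[:-1], True])
        spans = {
            str(tid_sorted[boundaries[i]]): order[boundaries[i] : boundaries[i + 1]]
            for i in range(len(boundaries) - 1)
        }
    for t in transcripts:
        if t.length < width:
            logger.info("transcript %s shorter than window width; no windows", t.transcript_id)
            out[t.transcript_id] = np.zeros(0, dtype=np.int64)
            continue
        n_pos = t.length - width + 1
        diff = np.zeros(n_pos + 1, dtype=np.int64)
        idx = spans.get(t.transcript_id)
        if idx is not None and len(idx):
            starts = reads.starts[idx]
            ends = starts + reads.lengths[idx]
            first = np.clip(starts - width + 1, 0, n_pos - 1)
            last = np.clip(ends, 0, n_pos)  # exclusive window-start bound
            np.add.at(diff, first, 1)
            np.add.at(diff, last, -1)
        counts = np.cumsum(diff[:-1])
        out[t.transcript_id] = counts[::step].astype(np.int64)
    return out


def enrichment_statistic(r_i, r, p_i):
    """CLIP enrichment ``r_i / (p_i * r)``; NaN (flagged, not raised) when
    ``p_i`` or ``r`` is zero. Accepts scalars or arrays."""
    r_i = np.asarray(r_i, dtype=float)
    p_i = np.asarray(p_i, dtype=float)
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = np.where((p_i > 0) & (r > 0), r_i / (p_i * r), np.nan)
    return res if res.ndim else float(res)


def binomial_tail_probability(k, n, p):
    """Upper binomial tail ``P(X >= k)`` for ``X ~ Binomial(n, p)`` via the
    regularized incomplete beta function ``I_p(k, n - k + 1)``; ``P(X >= 0)``
    is 1. Vectorized; ``k > n`` raises."""
    k = np.asarray(k)
    n = np.asarray(n)
    p = np.asarray(p, dtype=float)
    if np.any(k > n) or np.any(k < 0):
        raise ValueError("k must satisfy 0 <= k <= n")
    k_b, n_b, p_b = np.broadcast_arrays(k, n, p)
    out = np.ones(k_b.shape, dtype=float)
    pos = k_b >= 1
    out[pos] = special.betainc(k_b[pos], n_b[pos] - k_b[pos] + 1, p_b[pos])
    return out if out.ndim else float(out)


def mrna_relative_abundance(
    mrna_reads: Iterable[ReadSet], transcripts: Sequence[TranscriptModel]
) -> pd.Series:
    """Relative mRNA abundance per transcript, pooled over replicates."""
    index = [t.transcript_id for t in transcripts]
    counts = pd.Series(0.0, index=index)
    for rs in mrna_reads:
        vc = pd.Series(rs.transcript_ids).value_counts()
        counts = counts.add(vc, fill_value=0.0)
    counts = counts.reindex(index).fillna(0.0)
    total = counts.sum()
    if total == 0:
        raise ValueError("no mRNA reads to estimate abundances from")
    return counts / total


def call_enriched_windows(
    counts: Mapping[str, np.ndarray],
    mrna_abundances: pd.Series,
    total_clip_reads: int,
    prob_cutoff: float = 0.999,
    width: int = 40,
    step: int = 1,
    window_scaled: bool = False,
    transcripts: Sequence[TranscriptModel] | None = None,
    effective_read_length: float | None = None,
) -> pd.DataFrame:
    """Significant windows: ``tail_probability < 1 - prob_cutoff``.

    ``counts`` is the output of :func:`window_counts`; ``total_clip_reads``
    is ``r``, the library read total (window counts cannot recover it because
    one read overlaps many windows). Transcripts missing from the abundance
    table are skipped with a log message.

    With ``window_scaled`` the null probability becomes
    ``p_i * (width + effective_read_length - 1) / length`` (requires
    ``transcripts``): a read overlaps the window iff its start lies in a span
    of ``width + readlen - 1`` positions, so scaling by ``width`` alone makes
    every expressed window look enriched. Pass ``effective_read_length=1`` to
    recover plain ``width / length`` scaling.
    """
    if not 0.0 <= prob_cutoff < 1.0:
        raise ValueError("prob_cutoff must be in [0, 1)")
    if window_scaled and transcripts is None:
        raise ValueError("window_scaled requires transcript models")
    lengths = {t.transcript_id: t.length for t in transcripts} if transcripts else {}
    alpha = 1.0 - prob_cutoff
    frames = []
    r = int(total_clip_reads)
    span = width + (effective_read_length or 1.0) - 1.0
    for tid, c in counts.items():
        if tid not in mrna_abundances.index:
            logger.info("transcript %s absent from abundance table; windows skipped", tid)
            continue
        if len(c) == 0:
            continue
        p_i = float(mrna_abundances[tid])
        if window_scaled:
            p_i = min(p_i * span / lengths[tid], 1.0)
        nz = np.flatnonzero(c)  # r_i = 0 is never significant (tail = 1)
        if len(nz) == 0 or p_i <= 0:
            continue
        k = np.minimum(c[nz], r)
        tail = binomial_tail_probability(k, r, p_i)
        sig = tail < alpha
        if not np.any(sig):
            continue
        frames.append(
            pd.DataFrame(
                {
                    "transcript_id": tid,
                    "window_start": nz[sig] * step,
                    "r_i": c[nz][sig],
                    "p_i": p_i,
                    "enrichment": enrichment_statistic(c[nz][sig], r, p_i),
                    "tail_probability": tail[sig],
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=WINDOW_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def _merge_intervals(intervals: np.ndarray) -> list[tuple[int, int]]:
    """Union of half-open intervals (n x 2 array) into maximal disjoint runs."""
    if len(intervals) == 0:
        return []
    order = np.lexsort((intervals[:, 1], intervals[:, 0]))
    merged: list[list[int]] = []
    for s, e in intervals[order]:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], int(e))
        else:
            merged.append([int(s), int(e)])
    return [(s, e) for s, e in merged]


def merge_clusters(
    significant_windows: Mapping[int, pd.DataFrame],
    clip_reads: Mapping[int, ReadSet],
    width: int = 40,
    transcripts: Sequence[TranscriptModel] | None = None,
) -> list[BindingCluster]:
    """Merge overlapping significant windows from all replicates into
    clusters.

    ``significant_windows`` maps replicate id -> frame from
    :func:`call_enriched_windows`. Overlapping windows (union over
    replicates) become maximal intervals; ``replicate_support`` records which
    replicates contributed at least one significant window to the interval and
    ``total_clip_reads`` sums, over replicates, the reads overlapping it.
    """
    by_tid: dict[str, list[tuple[int, int, int, float]]] = {}
    for rep, frame in significant_windows.items():
        for tid, ws, tail in zip(
            frame["transcript_id"], frame["window_start"], frame["tail_probability"]
        ):
            by_tid.setdefault(str(tid), []).append((int(ws), int(ws) + width, rep, float(tail)))
    tmap = transcripts_by_id(transcripts) if transcripts else {}
    clusters: list[BindingCluster] = []
    for tid, rows in by_tid.items():
        arr = np.array([(s, e) for s, e, _, _ in rows], dtype=np.int64)
        for cs, ce in _merge_intervals(arr):
            support = frozenset(rep for s, e, rep, _ in rows if s < ce and e > cs)
            min_tail = min(t for s, e, _, t in rows if s < ce and e > cs)
            total = 0
            for rep, rs in clip_reads.items():
                on_t = rs.transcript_ids == tid
                total += int(np.sum(on_t & (rs.starts < ce) & (rs.ends > cs)))
            region = "3UTR"
            if tid in tmap:
                t = tmap[tid]
                region = t.region_of((cs + ce) // 2)  # midpoint rule
                if t.region_of(cs) != t.region_of(min(ce, t.length) - 1):
                    region += "(spanning)"
            clusters.append(
                BindingCluster(
                    transcript_id=tid, start=cs, end=ce,
                    replicate_support=support, total_clip_reads=total,
                    min_tail_probability=min_tail, region=region,
                )
            )
    clusters.sort(key=lambda c: (c.transcript_id, c.start))
    return clusters


def filter_clusters(
    clusters: Sequence[BindingCluster],
    min_reads: int = 50,
    required_replicates: Iterable[int] = (1, 2, 3),
) -> list[BindingCluster]:
    """Retain clusters with strictly more than ``min_reads`` pooled CLIP
    reads and support from every required replicate."""
    required = set(required_replicates)
    return [
        c for c in clusters
        if c.total_clip_reads > min_reads and required <= set(c.replicate_support)
    ]


def region_density(
    clusters: Sequence[BindingCluster],
    transcripts: Sequence[TranscriptModel],
    n_bins: int = 10,
) -> pd.DataFrame:
    """Clusters per nucleotide in each region decile (5'UTR/CDS/3'UTR).

    A cluster is assigned to the region decile containing its midpoint; the
    density divides decile counts by the summed decile length over all
    transcripts, as in a clusters-per-nucleotide metagene.
    """
    tmap = transcripts_by_id(transcripts)
    region_bounds = {
        "5UTR": lambda t: (0, t.utr5_end),
        "CDS": lambda t: (t.utr5_end, t.cds_end),
        "3UTR": lambda t: (t.cds_end, t.length),
    }
    rows = []
    for region, bounds in region_bounds.items():
        lengths = np.array([max(bounds(t)[1] - bounds(t)[0], 0) for t in transcripts], float)
        bin_len_total = lengths.sum() / n_bins
        counts = np.zeros(n_bins)
        for c in clusters:
            t = tmap.get(c.transcript_id)
            if t is None:
                continue
            lo, hi = bounds(t)
            mid = c.midpoint
            if lo <= mid < hi and hi > lo:
                rel = (mid - lo) / (hi - lo)
                counts[min(int(rel * n_bins), n_bins - 1)] += 1
        for b in range(n_bins):
            dens = counts[b] / bin_len_total if bin_len_total > 0 else 0.0
            if bin_len_total == 0:
                logger.info("region %s has zero total length; density reported as 0", region)
            rows.append({"region": region, "decile": b + 1, "clusters_per_nt": dens})
    return pd.DataFrame(rows)


def tc_profile(
    reads: Iterable[ReadSet],
    anchors: Sequence[tuple[str, int]],
    transcripts: Sequence[TranscriptModel],
    flank: int = 20,
) -> pd.DataFrame:
    """T>C conversion density around motif anchors.

    For each offset in ``[-flank, flank]`` the per-anchor density is
    (T>C mismatches at the position) / (read coverage of the position),
    evaluated only where the transcript base is T/U; densities are averaged
    over anchors (mean +/- SEM). Offsets with no covered T at any anchor are
    reported as NaN.
    """
    tmap = transcripts_by_id(transcripts)
    reads = list(reads)
    coverage: dict[str, np.ndarray] = {}
    conversions: dict[str, np.ndarray] = {}
    for t in transcripts:
        coverage[t.transcript_id] = np.zeros(t.length, dtype=np.int64)
        conversions[t.transcript_id] = np.zeros(t.length, dtype=np.int64)
    for rs in reads:
        for t in transcripts:
            on_t = rs.transcript_ids == t.transcript_id
            if not np.any(on_t):
                continue
            diff = np.zeros(t.length + 1, dtype=np.int64)
            np.add.at(diff, rs.starts[on_t], 1)
            np.add.at(diff, np.minimum(rs.ends[on_t], t.length), -1)
            coverage[t.transcript_id] += np.cumsum(diff[:-1])
        if len(rs.mismatches):
            mm = rs.mismatches
            tc = mm[(mm["ref"].isin(["T", "U"])) & (mm["alt"] == "C")]
            for tid, sub in tc.groupby(rs.transcript_ids[tc["read_index"].to_numpy()]):
                if tid in conversions:
                    np.add.at(conversions[tid], sub["pos"].to_numpy(), 1)
    offsets = np.arange(-flank, flank + 1)
    per_anchor = np.full((len(anchors), len(offsets)), np.nan)
    for a, (tid, pos) in enumerate(anchors):
        t = tmap.get(tid)
        if t is None:
            continue
        for j, d in enumerate(offsets):
            p = pos + d
            if 0 <= p < t.length and t.sequence[p] in "TU":
                cov = coverage[tid][p]
                if cov > 0:
                    per_anchor[a, j] = conversions[tid][p] / cov
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN offsets
        mean = np.nanmean(per_anchor, axis=0)
        n = np.sum(~np.isnan(per_anchor), axis=0)
        sd = np.nanstd(per_anchor, axis=0, ddof=1)
        sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    return pd.DataFrame({"offset": offsets, "mean_density": mean, "sem": sem, "n_anchors": n})


def call_binding_sites(
    clip_reads: Mapping[int, ReadSet],
    mrna_abundances: pd.Series,
    transcripts: Sequence[TranscriptModel],
    width: int = 40,
    step: int = 1,
    prob_cutoff: float = 0.999,
    min_reads: int = 50,
    window_scaled: bool = True,
    qc: bool = True,
) -> list[BindingCluster]:
    """End-to-end site calling: QC -> window counts -> binomial calling per
    replicate -> cross-replicate merging -> the >min_reads / all-replicates
    retention filter."""
    filtered = {
        rep: (qc_filter_reads(rs) if qc else rs) for rep, rs in clip_reads.items()
    }
    sig = {}
    for rep, rs in filtered.items():
        counts = window_counts(rs, transcripts, width=width, step=step)
        sig[rep] = call_enriched_windows(
            counts, mrna_abundances, total_clip_reads=len(rs),
            prob_cutoff=prob_cutoff, width=width, step=step,
            window_scaled=window_scaled, transcripts=transcripts,
            effective_read_length=float(rs.lengths.mean()) if len(rs) else None,
        )
    clusters = merge_clusters(sig, filtered, width=width, transcripts=transcripts)
    return filter_clusters(clusters, min_reads=min_reads, required_replicates=filtered.keys())


def cluster_sequences(
    clusters: Sequence[BindingCluster], transcripts: Sequence[TranscriptModel]
) -> list[tuple[str, str]]:
    """(name, sequence) pairs for retained clusters, for motif discovery."""
    tmap = transcripts_by_id(transcripts)
    out = []
    for c in clusters:
        t = tmap[c.transcript_id]
        out.append((f"{c.transcript_id}:{c.start}-{c.end}", t.sequence[c.start : c.end]))
    return out
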