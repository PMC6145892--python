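"""Binding-element discovery in CLIP cluster sequences.

Three element classes are handled:

* the linear binding element (LBE) — a ~15-nt U-rich sequence with a central
  CAC/CAU trinucleotide — modeled as a PWM learned by expectation-
  maximization under a zero-or-one-occurrence-per-sequence (ZOOPS) model and
  scanned by log-odds score;
* generic stem-loops (4-5 bp stem, U-rich 3-12 nt loop), detected by an
  explicit complementarity rule;
* CDE-like hairpins — the same stem rule with a pyrimidine-purine-pyrimidine
  tri-loop.

Enrichment of each class is quantified against per-sequence mononucleotide
shuffles of the same cluster sequences (three shuffle sets by default).
Sequences may be RNA (U) or DNA (T); results come back in the input alphabet.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .types import DNA_TO_RNA, RNA_TO_DNA, TranscriptModel

_ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_ALPHABET)}
_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_WOBBLE = {("G", "T"), ("T", "G")}


@dataclass(frozen=True)
class MotifHit:
    transcript_id: str
    start: int
    end: int
    kind: str  # LBE | SL_motif | CDE_like
    score: float


@dataclass(frozen=True)
class StemLoopRule:
    """Rule defining an acceptable stem-loop element."""

    stem_range: tuple[int, int] = (4, 5)
    loop_range: tuple[int, int] = (3, 12)
    min_loop_u_fraction: float = 0.5
    allow_wobble: bool = False
    loop_pattern: str | None = None  # e.g. "YRY" for the CDE tri-loop

    def __post_init__(self) -> None:
        if self.stem_range[0] > self.stem_range[1] or self.loop_range[0] > self.loop_range[1]:
            raise ValueError("empty stem or loop range")
        if not 0.0 <= self.min_loop_u_fraction <= 1.0:
            raise ValueError("min_loop_u_fraction must be in [0, 1]")


#: rule for the CDE-like hairpin: tri-loop with Py-Pu-Py sequence
CDE_RULE = StemLoopRule(loop_range=(3, 3), min_loop_u_fraction=0.0, loop_pattern="YRY")


class PWM:
    """Position weight matrix over A/C/G/U-or-T with a 0-order background."""

    def __init__(
        self,
        matrix: np.ndarray,
        background: np.ndarray,
        pseudocount: float = 0.1,
        rna: bool = False,
        low_complexity: bool = False,
    ) -> None:
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[1] != 4:
            raise ValueError("matrix must be (width, 4)")
        self.matrix = matrix / matrix.sum(axis=1, keepdims=True)
        self.background = np.asarray(background, dtype=float)
        self.background = self.background / self.background.sum()
        self.pseudocount = pseudocount
        self.rna = rna
        self.low_complexity = low_complexity

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        cons = "".join(_ALPHABET[i] for i in self.matrix.argmax(axis=1))
        return cons.translate(DNA_TO_RNA) if self.rna else cons

    def information_content(self) -> np.ndarray:
        """Per-column IC in bits (0..2), relative to the uniform background."""
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = self.matrix * np.log2(np.where(self.matrix > 0, self.matrix, 1.0) / 0.25)
        return terms.sum(axis=1)

    def log_odds(self) -> np.ndarray:
        return np.log2(self.matrix / self.background)

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=1).sum())

    def to_meme_text(self, name: str = "motif1") -> str:
        lines = [
            "MEME version 4", "",
            f"ALPHABET= {'ACGU' if self.rna else 'ACGT'}", "",
            f"MOTIF {name}",
            f"letter-probability matrix: alength= 4 w= {self.width}",
        ]
        for row in self.matrix:
            lines.append(" " + " ".join(f"{v:.6f}" for v in row))
        return "\n".join(lines) + "\n"


def _encode(seq: str) -> np.ndarray:
    seq = seq.upper().translate(RNA_TO_DNA)
    return np.fromiter((_BASE_INDEX.get(b, 0) for b in seq), dtype=np.int64, count=len(seq))


def _is_rna(sequences: Sequence[str]) -> bool:
    return any("U" in s.upper() for s in sequences)


def split_train_test(
    sequences: Sequence[str], seed: int = 0
) -> tuple[list[str], list[str]]:
    """Deterministic random split into equal halves (train gets ceil(n/2))."""
    n = len(sequences)
    if n < 2:
        raise ValueError("need at least 2 sequences to split")
    order = np.random.default_rng(seed).permutation(n)
    cut = math.ceil(n / 2)
    return [sequences[i] for i in order[:cut]], [sequences[i] for i in order[cut:]]


def _window_matrix(enc: np.ndarray, width: int) -> np.ndarray:
    """(n_windows, width) int matrix of all windows of one sequence."""
    n = len(enc) - width + 1
    if n <= 0:
        return np.empty((0, width), dtype=np.int64)
    return np.lib.stride_tricks.sliding_window_view(enc, width)


def _em_zoops(
    windows: list[np.ndarray],
    init: np.ndarray,
    background: np.ndarray,
    pseudocount: float,
    max_iter: int = 60,
    tol: float = 1e-7,
) -> tuple[np.ndarray, float]:
    """ZOOPS EM from one initial matrix; returns (matrix, log-likelihood)."""
    width = init.shape[0]
    mat = init / init.sum(axis=1, keepdims=True)
    gamma = 0.5
    ll_old = -np.inf
    for _ in range(max_iter):
        log_odds = np.log(mat) - np.log(background)
        new_counts = np.full((width, 4), pseudocount)
        gamma_sum = 0.0
        ll = 0.0
        for w in windows:
            if len(w) == 0:
                continue
            lr = np.exp(log_odds[np.arange(width), w].sum(axis=1))
            site_term = gamma * lr.mean()
            denom = (1.0 - gamma) + site_term
            ll += np.log(denom)
            z = (gamma / len(lr)) * lr / denom
            gamma_sum += z.sum()
            for c in range(width):
                np.add.at(new_counts[c], w[:, c], z)
        mat = new_counts / new_counts.sum(axis=1, keepdims=True)
        gamma = min(max(gamma_sum / max(len(windows), 1), 0.02), 0.98)
        if abs(ll - ll_old) < tol * max(abs(ll), 1.0):
            ll_old = ll
            break
        ll_old = ll
    return mat, ll_old


def _seed_matrices(
    encoded: list[np.ndarray], width: int, n_restarts: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """MEME-style starting points: the most frequent exact width-mers plus
    random windows, softened to 0.7/0.1 probability matrices."""
    counts: dict[bytes, int] = {}
    for enc in encoded:
        for w in _window_matrix(enc, width):
            key = w.tobytes()
            counts[key] = counts.get(key, 0) + 1
    top = sorted(counts.items(), key=lambda kv: -kv[1])[:3]
    seeds = [np.frombuffer(k, dtype=np.int64).copy() for k, _ in top]
    long_enough = [e for e in encoded if len(e) >= width]
    for _ in range(n_restarts):
        enc = long_enough[rng.integers(len(long_enough))]
        off = int(rng.integers(len(enc) - width + 1))
        seeds.append(enc[off : off + width].copy())
    mats = []
    for s in seeds:
        m = np.full((width, 4), 0.1)
        m[np.arange(width), s] = 0.7
        mats.append(m)
    return mats


def discover_pwm(
    train_sequences: Sequence[str],
    width: int = 15,
    n_restarts: int = 8,
    seed: int = 0,
    pseudocount: float = 0.1,
) -> PWM:
    """Learn the most enriched width-mer motif by ZOOPS EM over restarts.

    Starting points are the most frequent exact width-mers in the training
    set plus ``n_restarts`` random windows; the matrix with the highest EM
    log-likelihood wins, after a +/-3-column shift refinement. The background
    is the 0-order composition of the training set.
    """
    if any(len(s) < width for s in train_sequences):
        raise ValueError("all sequences must be at least `width` long")
    rna = _is_rna(train_sequences)
    encoded = [_encode(s) for s in train_sequences]
    comp = np.bincount(np.concatenate(encoded), minlength=4).astype(float)
    low_complexity = bool((comp > 0).sum() <= 1)
    background = (comp + 1.0) / (comp + 1.0).sum()
    rng = np.random.default_rng(seed)
    windows = [_window_matrix(e, width) for e in encoded]

    best: tuple[float, np.ndarray] | None = None
    for init in _seed_matrices(encoded, width, n_restarts, rng):
        mat, ll = _em_zoops(windows, init, background, pseudocount)
        if best is None or ll > best[0]:
            best = (ll, mat)
    assert best is not None
    # shift refinement: the EM can lock onto a phase-shifted version
    ll_best, mat_best = best
    for shift in (-3, -2, -1, 1, 2, 3):
        shifted = np.tile(background, (width, 1))
        if shift > 0:
            shifted[: width - shift] = mat_best[shift:]
        else:
            shifted[-shift:] = mat_best[: width + shift]
        mat, ll = _em_zoops(windows, shifted + 1e-3, background, pseudocount, max_iter=25)
        if ll > ll_best:
            ll_best, mat_best = ll, mat
    return PWM(mat_best, background, pseudocount=pseudocount, rna=rna,
               low_complexity=low_complexity)


def greedy_deoverlap(hits: Sequence[MotifHit]) -> list[MotifHit]:
    """Resolve overlaps within each sequence greedily by descending score."""
    chosen: list[MotifHit] = []
    by_seq: dict[str, list[MotifHit]] = {}
    for h in hits:
        by_seq.setdefault(h.transcript_id, []).append(h)
    for name, hs in by_seq.items():
        taken: list[MotifHit] = []
        for h in sorted(hs, key=lambda h: (-h.score, h.start)):
            if all(h.end <= t.start or h.start >= t.end for t in taken):
                taken.append(h)
        chosen.extend(sorted(taken, key=lambda h: h.start))
    chosen.sort(key=lambda h: (h.transcript_id, h.start))
    return chosen


def scan_pwm(
    pwm: PWM,
    sequences: Sequence[str] | dict[str, str],
    score_cutoff: float,
    kind: str = "LBE",
    deoverlap: bool = True,
) -> list[MotifHit]:
    """Log-odds scan of the sense strand; windows scoring >= cutoff are hits,
    overlaps resolved greedily by score."""
    if not isinstance(sequences, dict):
        sequences = {f"seq{i}": s for i, s in enumerate(sequences)}
    lo = pwm.log_odds()
    width = pwm.width
    hits: list[MotifHit] = []
    for name, seq in sequences.items():
        enc = _encode(seq)
        wins = _window_matrix(enc, width)
        if len(wins) == 0:
            continue
        scores = lo[np.arange(width), wins].sum(axis=1)
        for j in np.flatnonzero(scores >= score_cutoff):
            hits.append(MotifHit(name, int(j), int(j) + width, kind, float(scores[j])))
    return greedy_deoverlap(hits) if deoverlap else hits


def score_cutoff_from_shuffles(
    pwm: PWM, shuffled_sequences: Sequence[str], hit_rate: float = 0.05
) -> float:
    """Cutoff giving approximately ``hit_rate`` of shuffled sequences a hit:
    the (1 - hit_rate) quantile of per-sequence maximal window scores."""
    lo = pwm.log_odds()
    width = pwm.width
    maxima = []
    for s in shuffled_sequences:
        wins = _window_matrix(_encode(s), width)
        if len(wins):
            maxima.append(lo[np.arange(width), wins].sum(axis=1).max())
    if not maxima:
        return np.inf
    return float(np.quantile(maxima, 1.0 - hit_rate))


def _pairs_ok(a: str, b: str, allow_wobble: bool) -> bool:
    return (a, b) in _PAIRS or (allow_wobble and (a, b) in _WOBBLE)


def _matches_pattern(loop: str, pattern: str) -> bool:
    classes = {"Y": "CT", "R": "AG", "N": "ACGT"}
    if len(loop) != len(pattern):
        return False
    return all(b in classes.get(p, p) for b, p in zip(loop, pattern))


def detect_stem_loops(
    sequences: Sequence[str] | dict[str, str],
    rule: StemLoopRule = StemLoopRule(),
    kind: str = "SL_motif",
    deoverlap: bool = False,
) -> list[MotifHit]:
    """Every locus where a 4-5 nt arm, an enclosed U-rich loop, and the arm's
    reverse complement occur; score = stem pairs + loop U-fraction.

    This is itself an exhaustive enumeration of (arm, loop) decompositions,
    so it doubles as its own specification; tests compare it against an
    independently written brute force.
    """
    if not isinstance(sequences, dict):
        sequences = {f"seq{i}": s for i, s in enumerate(sequences)}
    hits: list[MotifHit] = []
    for name, raw in sequences.items():
        seq = raw.upper().translate(RNA_TO_DNA)
        L = len(seq)
        for stem in range(rule.stem_range[0], rule.stem_range[1] + 1):
            for loop_len in range(rule.loop_range[0], rule.loop_range[1] + 1):
                span = 2 * stem + loop_len
                for i in range(L - span + 1):
                    arm1 = seq[i : i + stem]
                    arm2 = seq[i + stem + loop_len : i + span]
                    if not all(
                        _pairs_ok(arm1[k], arm2[stem - 1 - k], rule.allow_wobble)
                        for k in range(stem)
                    ):
                        continue
                    loop = seq[i + stem : i + stem + loop_len]
                    u_frac = loop.count("T") / loop_len
                    if u_frac < rule.min_loop_u_fraction:
                        continue
                    if rule.loop_pattern and not _matches_pattern(loop, rule.loop_pattern):
                        continue
                    hits.append(MotifHit(name, i, i + span, kind, stem + u_frac))
    return greedy_deoverlap(hits) if deoverlap else hits


def shuffle_background(
    sequences: Sequence[str], n_sets: int = 3, seed: int = 0
) -> list[list[str]]:
    """``n_sets`` independent per-sequence mononucleotide shuffles; each
    shuffled sequence keeps its length and exact base composition."""
    rng = np.random.default_rng(seed)
    sets = []
    for _ in range(n_sets):
        shuffled = []
        for s in sequences:
            chars = np.array(list(s))
            rng.shuffle(chars)
            shuffled.append("".join(chars))
        sets.append(shuffled)
    return sets


def dinucleotide_shuffle(sequence: str, rng: np.random.Generator) -> str:
    """Dinucleotide-preserving shuffle (Altschul-Erikson style via a random
    Eulerian walk on the dinucleotide graph); offered as an option since the
    composition model of the background is not pinned down."""
    s = list(sequence)
    if len(s) < 3:
        return sequence
    edges: dict[str, list[str]] = {}
    for a, b in zip(s[:-1], s[1:]):
        edges.setdefault(a, []).append(b)
    for a in edges:
        rng.shuffle(edges[a])
    # walk greedily; retry until all edges are used (small alphabets converge fast)
    for _ in range(100):
        pools = {a: list(bs) for a, bs in edges.items()}
        walk = [s[0]]
        cur = s[0]
        while pools.get(cur):
            nxt = pools[cur].pop()
            walk.append(nxt)
            cur = nxt
        if len(walk) == len(s):
            return "".join(walk)
        for a in edges:
            rng.shuffle(edges[a])
    return sequence


@dataclass(frozen=True)
class EnrichmentComparison:
    """Observed vs shuffled-background hit fractions for one element kind."""

    kind: str
    observed_fraction: float
    background_fraction: float
    n_shuffles: int
    fold: float
    empirical_p: float


def _hit_fraction(hits: Sequence[MotifHit], names: Sequence[str]) -> float:
    with_hit = {h.transcript_id for h in hits}
    return sum(n in with_hit for n in names) / len(names) if names else 0.0


def motif_enrichment(
    kind: str,
    real_sequences: dict[str, str],
    shuffled_sets: Sequence[Sequence[str]],
    scanner: Callable[[dict[str, str]], Sequence[MotifHit]],
) -> EnrichmentComparison:
    """Fraction of real cluster sequences with >= 1 hit vs the mean fraction
    over shuffle sets, using the same ``scanner`` for both; the empirical p
    is the fraction of shuffle sets reaching the observed fraction."""
    names = list(real_sequences)
    observed = _hit_fraction(list(scanner(real_sequences)), names)
    bg_fractions = []
    for ss in shuffled_sets:
        named = {f"shuf{i}": s for i, s in enumerate(ss)}
        bg_fractions.append(_hit_fraction(list(scanner(named)), list(named)))
    background = float(np.mean(bg_fractions)) if bg_fractions else 0.0
    fold = observed / background if background > 0 else math.inf
    p = (
        sum(b >= observed for b in bg_fractions) / len(bg_fractions)
        if bg_fractions
        else math.nan
    )
    return EnrichmentComparison(kind, observed, background, len(bg_fractions), fold, p)


def lift_hits_to_transcripts(hits: Sequence[MotifHit]) -> list[MotifHit]:
    """Map hits on cluster sequences named ``tid:start-end`` back to
    transcript coordinates."""
    out = []
    for h in hits:
        if ":" in h.transcript_id and "-" in h.transcript_id.rsplit(":", 1)[1]:
            tid, span = h.transcript_id.rsplit(":", 1)
            cstart = int(span.split("-")[0])
            out.append(MotifHit(tid, h.start + cstart, h.end + cstart, h.kind, h.score))
        else:
            out.append(h)
    return out


def count_sites_per_transcript(hits: Sequence[MotifHit]) -> pd.DataFrame:
    """Per-transcript count of non-overlapping binding sites (union over
    kinds): overlapping hits of any kind collapse into one site.

    Returns a frame with ``transcript_id``, ``n_sites`` and the histogram
    stratum label (``1``, ``2``, ``3`` or ``4+``); transcripts without hits
    simply do not appear.
    """
    by_tid: dict[str, list[tuple[int, int]]] = {}
    kinds_by_tid: dict[str, set[str]] = {}
    for h in hits:
        by_tid.setdefault(h.transcript_id, []).append((h.start, h.end))
        kinds_by_tid.setdefault(h.transcript_id, set()).add(h.kind)
    rows = []
    for tid, iv in by_tid.items():
        arr = np.array(iv, dtype=np.int64)
        order = np.lexsort((arr[:, 1], arr[:, 0]))
        n = 0
        cur_end = -1
        for s, e in arr[order]:
            if s >= cur_end:
                n += 1
                cur_end = e
            else:
                cur_end = max(cur_end, e)
        rows.append(
            {
                "transcript_id": tid,
                "n_sites": n,
                "stratum": f"{n}" if n < 4 else "4+",
                "element_kinds": ",".join(sorted(kinds_by_tid[tid])),
            }
        )
    return pd.DataFrame(rows, columns=["transcript_id", "n_sites", "stratum", "element_kinds"])


def site_count_histogram(site_counts: pd.DataFrame) -> pd.Series:
    """Frequency of transcripts with 1 / 2 / 3 / 4+ binding sites."""
    order = ["1", "2", "3", "4+"]
    return site_counts["stratum"].value_counts().reindex(order).fillna(0).astype(int)


def site_positional_distribution(
    hits: Sequence[MotifHit],
    transcripts: Sequence[TranscriptModel],
    groups: dict[str, str] | None = None,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Density of binding sites along the normalized 3'UTR coordinate.

    Each hit contributes its midpoint mapped to [0, 1] along its
    transcript's 3'UTR (0 = stop codon); densities are per-bin fractions of
    hits, computed per transcript then averaged (mean +/- SEM) within each
    group (a single "all" group when ``groups`` is None). Zero-length 3'UTRs
    are skipped.
    """
    tmap = {t.transcript_id: t for t in transcripts}
    per_tx: dict[str, list[float]] = {}
    for h in hits:
        t = tmap.get(h.transcript_id)
        if t is None or t.utr3_length == 0:
            continue
        mid = (h.start + h.end) / 2 - t.cds_end
        if not 0 <= mid <= t.utr3_length:
            continue
        per_tx.setdefault(h.transcript_id, []).append(min(mid / t.utr3_length, 1.0 - 1e-9))
    rows = []
    group_members: dict[str, list[np.ndarray]] = {}
    for tid, pos in per_tx.items():
        hist, _ = np.histogram(pos, bins=n_bins, range=(0, 1))
        g = groups.get(tid, "all") if groups else "all"
        group_members.setdefault(g, []).append(hist / hist.sum())
    for g, profiles in group_members.items():
        arr = np.array(profiles)
        mean = arr.mean(axis=0)
        sem = arr.std(axis=0, ddof=1) / np.sqrt(len(arr)) if len(arr) > 1 else np.full(n_bins, np.nan)
        for b in range(n_bins):
            rows.append(
                {"group": g, "bin": b + 1, "rel_position": (b + 0.5) / n_bins,
                 "density": mean[b], "sem": sem[b], "n_transcripts": len(arr)}
            )
    return pd.DataFrame(rows)
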