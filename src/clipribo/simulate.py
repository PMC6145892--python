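"""Ground-truth simulator for CLIP / mRNA-seq / Ribo-seq experiments.

Everything is generated directly in transcript space (no genome, no mapper):
random transcript models with realistic length mixes, log-normal abundances,
binding elements written into 3'UTR sequences, CLIP reads concentrated at the
planted sites with T>C conversions at crosslinked uridines, background
mRNA-seq reads proportional to abundance, and ribosome-protected fragments
(RPFs) of 28-30 nt with per-length A-site offsets and 3-nt periodicity.

Sequences are stored in the DNA alphabet (A/C/G/T); crosslink conversions are
recorded as T>C mismatches, matching how the reads would be sequenced.

All randomness flows from a single top-level seed; each assay/condition/
replicate gets its own deterministic child stream, so a fixed config yields
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import PlantedSite, ReadSet, TranscriptModel

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# stream codes for deterministic child RNGs
_STREAM_TRANSCRIPTOME = 0
_STREAM_PLANT = 1
_STREAM_CLIP = 2
_STREAM_MRNA = 3
_STREAM_RPF = 4

#: the linear binding element written into sequences by default: a CAC
#: trinucleotide embedded in a uridine run (DNA alphabet)
DEFAULT_LBE = "TTTTTTCACTTTTTT"


class ConfigurationError(ValueError):
    pass


class PlantingError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Stated world for one synthetic experiment.

    Effects are log2 fold-changes applied in the perturbed condition, keyed by
    the number of planted binding sites (the ``4`` key covers 4+). Defaults:
    mRNA-level repression deepens with site count; TE-level repression is
    confined to the 4+ stratum.
    """

    n_transcripts: int = 200
    utr5_range: tuple[int, int] = (50, 200)
    cds_range: tuple[int, int] = (300, 1500)
    utr3_range: tuple[int, int] = (200, 1000)
    abundance_log_mean: float = 0.0
    abundance_log_sd: float = 1.0
    # per-replicate sequencing depths
    clip_depth: int = 500_000
    mrna_depth: int = 300_000
    rpf_depth: int = 300_000
    clip_replicates: int = 3
    expression_replicates: int = 3
    tc_conversion_rate: float = 0.55
    sequencing_error_rate: float = 0.0
    clip_length_range: tuple[int, int] = (20, 40)
    mrna_length_range: tuple[int, int] = (20, 40)
    rpf_length_probs: Mapping[int, float] = field(
        default_factory=lambda: {28: 1 / 3, 29: 1 / 3, 30: 1 / 3}
    )
    asite_offsets: Mapping[int, int] = field(
        default_factory=lambda: {28: 11, 29: 12, 30: 13, 31: 13}
    )
    periodicity: float = 0.8
    frame_uniform_lengths: frozenset[int] = field(default_factory=frozenset)
    enrichment_factor: float = 20.0
    target_fraction: float = 0.25
    # site-count mix among targets, echoing the observed 1/2/3/4+ strata
    site_count_probs: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.661, 2: 0.153, 3: 0.149, 4: 0.037}
    )
    element_kind_probs: Mapping[str, float] = field(
        default_factory=lambda: {"LBE": 0.5, "stem_loop_SL": 0.3, "CDE_like": 0.2}
    )
    mrna_effect: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.0, 1: -0.25, 2: -0.5, 3: -0.75, 4: -1.0}
    )
    te_effect: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.0, 1: 0.0, 2: 0.0, 3: 0.0, 4: -1.0}
    )
    rpf_stall_bias: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("utr5_range", "cds_range", "utr3_range", "clip_length_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ConfigurationError(f"{name}: invalid range ({lo}, {hi})")
        if self.n_transcripts < 1:
            raise ConfigurationError("n_transcripts must be >= 1")
        for p in (self.tc_conversion_rate, self.periodicity, self.target_fraction):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("probabilities must be in [0, 1]")
        for depth in (self.clip_depth, self.mrna_depth, self.rpf_depth):
            if depth <= 0:
                raise ConfigurationError("depths must be > 0")
        for length, off in self.asite_offsets.items():
            if not 10 <= off <= 14:
                raise ConfigurationError(f"A-site offset for length {length} outside [10, 14]")

    def rng(self, stream: int, replicate: int = 0, condition: str = "ctrl") -> np.random.Generator:
        cond_code = 0 if condition == "ctrl" else 1
        return np.random.default_rng([self.seed, stream, replicate, cond_code])


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def generate_transcriptome(config: SimulationConfig) -> list[TranscriptModel]:
    """Random transcript models: uniform base composition, ATG-initiated CDS
    divisible by 3 ending in a TAA stop."""
    rng = config.rng(_STREAM_TRANSCRIPTOME)
    transcripts = []
    for i in range(config.n_transcripts):
        utr5 = int(rng.integers(config.utr5_range[0], config.utr5_range[1] + 1))
        cds = int(rng.integers(config.cds_range[0], config.cds_range[1] + 1))
        cds -= cds % 3
        cds = max(cds, 6)
        utr3 = int(rng.integers(config.utr3_range[0], config.utr3_range[1] + 1))
        seq = rng.choice(_BASES, size=utr5 + cds + utr3)
        seq[utr5 : utr5 + 3] = list("ATG")
        seq[utr5 + cds - 3 : utr5 + cds] = list("TAA")
        transcripts.append(
            TranscriptModel(
                transcript_id=f"tx{i:04d}",
                sequence="".join(seq),
                utr5_end=utr5,
                cds_end=utr5 + cds,
            )
        )
    return transcripts


def draw_site_plan(
    transcripts: Sequence[TranscriptModel], config: SimulationConfig
) -> dict[str, list[str]]:
    """Draw which transcripts are targets and which element kinds they carry."""
    rng = config.rng(_STREAM_PLANT)
    counts = sorted(config.site_count_probs)
    count_p = np.array([config.site_count_probs[c] for c in counts], dtype=float)
    count_p /= count_p.sum()
    kinds = sorted(config.element_kind_probs)
    kind_p = np.array([config.element_kind_probs[k] for k in kinds], dtype=float)
    kind_p /= kind_p.sum()
    plan: dict[str, list[str]] = {}
    for t in transcripts:
        if rng.random() < config.target_fraction:
            n = int(rng.choice(counts, p=count_p))
            # cap by what fits in the 3'UTR (widest element 22 nt, 60-nt gaps)
            n = min(n, max((t.utr3_length + 60) // 82, 0))
            if n > 0:
                plan[t.transcript_id] = [str(rng.choice(kinds, p=kind_p)) for _ in range(n)]
    return plan


def _build_element(kind: str, rng: np.random.Generator) -> tuple[str, list[int]]:
    """Return (element sequence, crosslink offsets within the element)."""
    if kind == "LBE":
        seq = DEFAULT_LBE
        core = seq.find("CAC")
        xl = [i for i, b in enumerate(seq) if b == "T" and not core <= i < core + 3]
        return seq, xl
    if kind == "stem_loop_SL":
        stem = int(rng.integers(4, 6))
        loop_lo = max(3, 15 - 2 * stem)
        loop_len = int(rng.integers(loop_lo, 13))
        arm = "".join(rng.choice(_BASES, size=stem))
        loop = ["T" if rng.random() < 0.75 else str(rng.choice(["A", "C", "G"])) for _ in range(loop_len)]
        # enforce the U-rich loop the rule-based detector expects
        while sum(b == "T" for b in loop) / loop_len < 0.5:
            loop[int(rng.integers(loop_len))] = "T"
        loop = "".join(loop)
        seq = arm + loop + _revcomp(arm)
        xl = [stem + i for i, b in enumerate(loop) if b == "T"]
        return seq, xl
    if kind == "CDE_like":
        # pyrimidine-purine-pyrimidine tri-loop hairpin, padded with U to 15 nt
        stem = int(rng.integers(4, 6))
        arm = "".join(rng.choice(_BASES, size=stem))
        hairpin = arm + "TGT" + _revcomp(arm)
        pad = 15 - len(hairpin)
        left = pad // 2
        seq = "T" * left + hairpin + "T" * (pad - left)
        xl = [i for i, b in enumerate(seq) if b == "T" and (i < left or i >= left + len(hairpin))]
        xl += [left + stem, left + stem + 2]  # loop uridines
        return seq, sorted(xl)
    raise ConfigurationError(f"unknown element kind: {kind}")


def plant_sites(
    transcripts: Sequence[TranscriptModel],
    site_plan: Mapping[str, Sequence[str]],
    config: SimulationConfig,
    min_gap: int = 60,
    region: str = "3UTR",
) -> tuple[list[TranscriptModel], list[PlantedSite]]:
    """Write binding elements into transcript sequences (default: 3'UTR).

    Sites on one transcript are non-overlapping and separated by ``min_gap``
    nt so that merged CLIP clusters resolve them individually. Returns the
    rewritten transcripts and the ground-truth site table.
    """
    out_transcripts: list[TranscriptModel] = []
    sites: list[PlantedSite] = []
    rng = config.rng(_STREAM_PLANT, replicate=1)
    for t in transcripts:
        kinds = site_plan.get(t.transcript_id, [])
        if not kinds:
            out_transcripts.append(t)
            continue
        if region == "3UTR":
            lo, hi = t.cds_end, t.length
        elif region == "CDS":
            lo, hi = t.utr5_end, t.cds_end
        else:
            lo, hi = 0, t.length
        seq = list(t.sequence)
        elements = [_build_element(kind, rng) for kind in kinds]
        widths = [len(e) for e, _ in elements]
        needed = sum(widths) + min_gap * (len(kinds) - 1)
        slack = (hi - lo) - needed
        if slack < 0:
            raise PlantingError(
                f"{t.transcript_id}: cannot place {len(kinds)} sites "
                f"({needed} nt incl. {min_gap}-nt gaps) in {region} of length {hi - lo}"
            )
        # random placement by distributing the slack over the k+1 spacers
        cuts = np.sort(rng.integers(0, slack + 1, size=len(kinds)))
        pos = lo
        prev_cut = 0
        for (kind, (elem, xl_off)), width, cut in zip(
            zip(kinds, elements), widths, cuts
        ):
            pos += int(cut - prev_cut)
            prev_cut = int(cut)
            start = pos
            seq[start : start + width] = list(elem)
            pos += width + min_gap
            sites.append(
                PlantedSite(
                    transcript_id=t.transcript_id,
                    start=start,
                    end=start + width,
                    element_kind=kind,
                    crosslink_positions=tuple(start + o for o in xl_off),
                    enrichment_factor=config.enrichment_factor,
                )
            )
        out_transcripts.append(
            TranscriptModel(t.transcript_id, "".join(seq), t.utr5_end, t.cds_end)
        )
    return out_transcripts, sites


def draw_abundances(transcripts: Sequence[TranscriptModel], config: SimulationConfig) -> pd.Series:
    """Log-normal relative abundances, normalized to sum to 1."""
    rng = config.rng(_STREAM_TRANSCRIPTOME, replicate=1)
    raw = rng.lognormal(config.abundance_log_mean, config.abundance_log_sd, len(transcripts))
    raw /= raw.sum()
    return pd.Series(raw, index=[t.transcript_id for t in transcripts], name="abundance")


def _site_counts(transcripts: Sequence[TranscriptModel], sites: Sequence[PlantedSite]) -> pd.Series:
    counts = pd.Series(0, index=[t.transcript_id for t in transcripts], dtype=int)
    for s in sites:
        counts[s.transcript_id] += 1
    return counts


def simulate_clip_reads(
    transcripts: Sequence[TranscriptModel],
    sites: Sequence[PlantedSite],
    abundances: pd.Series,
    config: SimulationConfig,
    replicate: int = 1,
) -> ReadSet:
    """One CLIP replicate: read-start rates proportional to abundance per
    position, boosted by the enrichment factor inside planted sites; reads
    covering a crosslink position acquire a T>C mismatch with probability
    ``tc_conversion_rate``."""
    if not np.isclose(abundances.sum(), 1.0, atol=1e-6):
        raise ConfigurationError("abundances must be normalized to sum to 1")
    rng = config.rng(_STREAM_CLIP, replicate=replicate)
    tids = [t.transcript_id for t in transcripts]
    lengths = np.array([t.length for t in transcripts])
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    weights = np.empty(offsets[-1], dtype=float)
    for i, t in enumerate(transcripts):
        weights[offsets[i] : offsets[i + 1]] = abundances[t.transcript_id] / t.length
    tid_index = {tid: i for i, tid in enumerate(tids)}
    for s in sites:
        i = tid_index[s.transcript_id]
        weights[offsets[i] + s.start : offsets[i] + s.end] *= s.enrichment_factor
    weights /= weights.sum()

    counts = rng.multinomial(config.clip_depth, weights)
    flat_pos = np.repeat(np.arange(len(weights)), counts)
    rng.shuffle(flat_pos)  # decorrelate read order from position
    t_idx = np.searchsorted(offsets, flat_pos, side="right") - 1
    starts = flat_pos - offsets[t_idx]
    lo, hi = config.clip_length_range
    read_lens = rng.integers(lo, hi + 1, size=len(starts))
    read_lens = np.minimum(read_lens, lengths[t_idx] - starts)

    mm_rows: list[tuple[int, int, str, str]] = []
    ends = starts + read_lens
    for s in sites:
        i = tid_index[s.transcript_id]
        on_t = np.flatnonzero(t_idx == i)
        if len(on_t) == 0:
            continue
        for pos in s.crosslink_positions:
            over = on_t[(starts[on_t] <= pos) & (ends[on_t] > pos)]
            if len(over) == 0:
                continue
            hit = over[rng.random(len(over)) < config.tc_conversion_rate]
            mm_rows.extend((int(r), int(pos), "T", "C") for r in hit)
    if config.sequencing_error_rate > 0:
        n_err = rng.binomial(int(read_lens.sum()), config.sequencing_error_rate)
        seqs = {t.transcript_id: t.sequence for t in transcripts}
        for _ in range(n_err):
            r = int(rng.integers(len(starts)))
            pos = int(starts[r] + rng.integers(read_lens[r]))
            ref = seqs[tids[t_idx[r]]][pos]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            mm_rows.append((r, pos, ref, alt))
    mm = (
        pd.DataFrame(mm_rows, columns=["read_index", "pos", "ref", "alt"])
        .sort_values(["read_index", "pos"], kind="stable")
        .reset_index(drop=True)
        if mm_rows
        else None
    )
    return ReadSet(
        "CLIP", "ctrl", replicate,
        np.array(tids, dtype=object)[t_idx], starts, read_lens, mm,
    )


def _condition_weights(
    transcripts: Sequence[TranscriptModel],
    site_counts: pd.Series,
    abundances: pd.Series,
    config: SimulationConfig,
    condition: str,
    assay: str,
) -> np.ndarray:
    w = abundances.loc[[t.transcript_id for t in transcripts]].to_numpy(float).copy()
    if condition == "perturbed":
        strata = np.minimum(site_counts.loc[[t.transcript_id for t in transcripts]].to_numpy(), 4)
        log2fc = np.array([config.mrna_effect[int(s)] for s in strata])
        if assay == "RPF":
            log2fc = log2fc + np.array([config.te_effect[int(s)] for s in strata])
        w = w * np.exp2(log2fc)
    return w / w.sum()


def simulate_expression_reads(
    assay: str,
    transcripts: Sequence[TranscriptModel],
    sites: Sequence[PlantedSite],
    abundances: pd.Series,
    config: SimulationConfig,
    condition: str = "ctrl",
    replicate: int = 1,
) -> ReadSet:
    """One mRNA-seq or Ribo-seq replicate.

    mRNA reads start uniformly along the transcript. RPF reads are placed so
    that their A-site (5' start + per-length offset) falls on a CDS codon,
    landing on frame 0 with probability ``periodicity`` (or uniformly across
    frames for lengths listed in ``frame_uniform_lengths``); in the perturbed
    condition a positive ``rpf_stall_bias`` piles RPFs towards the 5' end of
    the CDS, emulating an elongation stall.
    """
    if assay not in ("mRNA", "RPF"):
        raise ConfigurationError(f"unknown assay: {assay}")
    stream = _STREAM_MRNA if assay == "mRNA" else _STREAM_RPF
    rng = config.rng(stream, replicate=replicate, condition=condition)
    site_counts = _site_counts(transcripts, sites)
    w = _condition_weights(transcripts, site_counts, abundances, config, condition, assay)
    depth = config.mrna_depth if assay == "mRNA" else config.rpf_depth
    per_t = rng.multinomial(depth, w)
    tids = np.array([t.transcript_id for t in transcripts], dtype=object)

    all_tid: list[np.ndarray] = []
    all_start: list[np.ndarray] = []
    all_len: list[np.ndarray] = []
    rpf_lengths = sorted(config.rpf_length_probs)
    rpf_p = np.array([config.rpf_length_probs[L] for L in rpf_lengths], dtype=float)
    rpf_p /= rpf_p.sum()
    for i, t in enumerate(transcripts):
        n = int(per_t[i])
        if n == 0:
            continue
        if assay == "mRNA":
            lo, hi = config.mrna_length_range
            rl = rng.integers(lo, hi + 1, size=n)
            st = rng.integers(0, t.length, size=n)
            rl = np.minimum(rl, t.length - st)
        else:
            rl = np.asarray(rng.choice(rpf_lengths, size=n, p=rpf_p))
            n_codons = t.cds_length // 3
            if config.rpf_stall_bias > 0 and condition == "perturbed":
                rel = np.arange(n_codons) / max(n_codons - 1, 1)
                cw = np.exp(-config.rpf_stall_bias * rel)
                codons = rng.choice(n_codons, size=n, p=cw / cw.sum())
            else:
                codons = rng.integers(0, n_codons, size=n)
            frames = np.zeros(n, dtype=np.int64)
            uniform = np.isin(rl, list(config.frame_uniform_lengths))
            off_frame = rng.random(n) >= config.periodicity
            off_frame |= uniform  # frame drawn uniformly below
            frames[off_frame] = rng.integers(1, 3, size=int(off_frame.sum()))
            frames[uniform] = rng.integers(0, 3, size=int(uniform.sum()))
            asite = t.utr5_end + 3 * codons + frames
            offs = np.array([config.asite_offsets[int(L)] for L in rl])
            st = np.clip(asite - offs, 0, None)
            rl = np.minimum(rl, t.length - st)
        all_tid.append(np.repeat(tids[i], n))
        all_start.append(st.astype(np.int64))
        all_len.append(rl.astype(np.int64))
    if all_tid:
        tid_arr = np.concatenate(all_tid)
        st_arr = np.concatenate(all_start)
        rl_arr = np.concatenate(all_len)
    else:
        tid_arr = np.array([], dtype=object)
        st_arr = np.array([], dtype=np.int64)
        rl_arr = np.array([], dtype=np.int64)
    return ReadSet(assay, condition, replicate, tid_arr, st_arr, rl_arr)


@dataclass
class SimulatedExperiment:
    """Full simulated dataset plus the ground truth the tests consume."""

    config: SimulationConfig
    transcripts: list[TranscriptModel]
    sites: list[PlantedSite]
    abundances: pd.Series
    clip: list[ReadSet]
    expression: dict[tuple[str, str, int], ReadSet]  # (assay, condition, replicate)

    @property
    def site_counts(self) -> pd.Series:
        return _site_counts(self.transcripts, self.sites)

    def ground_truth_sites(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "transcript_id": s.transcript_id,
                    "start": s.start,
                    "end": s.end,
                    "element_kind": s.element_kind,
                    "crosslink_positions": ";".join(map(str, s.crosslink_positions)),
                    "enrichment_factor": s.enrichment_factor,
                }
                for s in self.sites
            ]
        )

    def ground_truth_effects(self) -> pd.DataFrame:
        counts = self.site_counts
        strata = np.minimum(counts.to_numpy(), 4)
        return pd.DataFrame(
            {
                "transcript_id": counts.index,
                "n_sites": counts.to_numpy(),
                "mrna_log2fc": [self.config.mrna_effect[int(s)] for s in strata],
                "te_log2fc": [self.config.te_effect[int(s)] for s in strata],
            }
        )


def simulate_experiment(
    config: SimulationConfig,
    site_plan: Mapping[str, Sequence[str]] | None = None,
    with_expression: bool = True,
) -> SimulatedExperiment:
    """Run the whole generator: transcriptome, sites, abundances, read sets."""
    transcripts = generate_transcriptome(config)
    if site_plan is None:
        site_plan = draw_site_plan(transcripts, config)
    transcripts, sites = plant_sites(transcripts, site_plan, config)
    abundances = draw_abundances(transcripts, config)
    clip = [
        simulate_clip_reads(transcripts, sites, abundances, config, replicate=r)
        for r in range(1, config.clip_replicates + 1)
    ]
    expression: dict[tuple[str, str, int], ReadSet] = {}
    if with_expression:
        for assay in ("mRNA", "RPF"):
            for condition in ("ctrl", "perturbed"):
                for r in range(1, config.expression_replicates + 1):
                    expression[(assay, condition, r)] = simulate_expression_reads(
                        assay, transcripts, sites, abundances, config, condition, r
                    )
    return SimulatedExperiment(config, transcripts, sites, abundances, clip, expression)
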