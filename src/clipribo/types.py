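"""Core domain containers shared across the pipeline.

Coordinates are 0-based, half-open, in transcript space (plus strand only).
Large read collections are held column-wise in :class:`ReadSet` (numpy arrays)
for speed; :class:`AlignedRead` is the record-level view used by the TSV codec
and by tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

RNA_TO_DNA = str.maketrans("Uu", "Tt")
DNA_TO_RNA = str.maketrans("Tt", "Uu")


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript sequence with its 5'UTR/CDS/3'UTR boundaries.

    ``utr5_end`` is the half-open end of the 5'UTR (= CDS start) and
    ``cds_end`` the half-open end of the CDS (= 3'UTR start).
    """

    transcript_id: str
    sequence: str
    utr5_end: int
    cds_end: int

    def __post_init__(self) -> None:
        if not (0 <= self.utr5_end < self.cds_end <= len(self.sequence)):
            raise ValueError(
                f"{self.transcript_id}: invalid region boundaries "
                f"0 <= {self.utr5_end} < {self.cds_end} <= {len(self.sequence)}"
            )
        if (self.cds_end - self.utr5_end) % 3 != 0:
            raise ValueError(f"{self.transcript_id}: CDS length not divisible by 3")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.utr5_end

    @property
    def utr3_length(self) -> int:
        return len(self.sequence) - self.cds_end

    @property
    def utr3_sequence(self) -> str:
        return self.sequence[self.cds_end :]

    def region_of(self, position: int) -> str:
        """Region label ('5UTR', 'CDS' or '3UTR') of a transcript position."""
        if position < self.utr5_end:
            return "5UTR"
        if position < self.cds_end:
            return "CDS"
        return "3UTR"


@dataclass(frozen=True)
class PlantedSite:
    """Ground-truth binding site written into a simulated transcript."""

    transcript_id: str
    start: int
    end: int
    element_kind: str  # LBE | stem_loop_SL | CDE_like
    crosslink_positions: tuple[int, ...]
    enrichment_factor: float

    def __post_init__(self) -> None:
        if not 15 <= self.end - self.start <= 40:
            raise ValueError("site width must be in [15, 40] nt")


@dataclass
class AlignedRead:
    """A read aligned to a transcript, with its T>C-relevant mismatches."""

    read_id: str
    transcript_id: str
    start: int
    length: int
    mismatches: list[tuple[int, str, str]] = field(default_factory=list)
    quality_profile: list[int] | None = None

    @property
    def end(self) -> int:
        return self.start + self.length


class ReadSet:
    """Column-wise collection of aligned reads for one assay/condition/replicate.

    Parameters
    ----------
    transcript_ids, starts, lengths
        Parallel arrays, one entry per read.
    mismatches
        Long-format frame with columns ``read_index`` (row into the parallel
        arrays), ``pos`` (transcript coordinate), ``ref``, ``alt``.
    qualities
        Optional per-read PHRED arrays (list parallel to reads) for QC.
    """

    def __init__(
        self,
        assay: str,
        condition: str,
        replicate: int,
        transcript_ids: np.ndarray,
        starts: np.ndarray,
        lengths: np.ndarray,
        mismatches: pd.DataFrame | None = None,
        qualities: list | None = None,
    ) -> None:
        self.assay = assay
        self.condition = condition
        self.replicate = int(replicate)
        self.transcript_ids = np.asarray(transcript_ids)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.lengths = np.asarray(lengths, dtype=np.int64)
        if mismatches is None:
            mismatches = pd.DataFrame(
                {"read_index": pd.Series(dtype=np.int64), "pos": pd.Series(dtype=np.int64),
                 "ref": pd.Series(dtype=str), "alt": pd.Series(dtype=str)}
            )
        self.mismatches = mismatches
        self.qualities = qualities

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.lengths

    def subset(self, mask: np.ndarray) -> "ReadSet":
        """New ReadSet with the reads selected by a boolean mask, order kept."""
        mask = np.asarray(mask, dtype=bool)
        keep_idx = np.flatnonzero(mask)
        remap = -np.ones(len(self), dtype=np.int64)
        remap[keep_idx] = np.arange(len(keep_idx))
        mm = self.mismatches
        if len(mm):
            sel = mask[mm["read_index"].to_numpy()]
            mm = mm.loc[sel].copy()
            mm["read_index"] = remap[mm["read_index"].to_numpy()]
            mm = mm.reset_index(drop=True)
        quals = None
        if self.qualities is not None:
            quals = [self.qualities[i] for i in keep_idx]
        return ReadSet(
            self.assay, self.condition, self.replicate,
            self.transcript_ids[mask], self.starts[mask], self.lengths[mask],
            mm, quals,
        )

    def to_frame(self) -> pd.DataFrame:
        """Per-read table with mismatches encoded as ``pos:ref>alt;...``."""
        enc = np.full(len(self), "", dtype=object)
        if len(self.mismatches):
            mm = self.mismatches
            token = (
                mm["pos"].astype(str) + ":" + mm["ref"].astype(str) + ">" + mm["alt"].astype(str)
            )
            grouped = token.groupby(mm["read_index"]).agg(";".join)
            enc[grouped.index.to_numpy()] = grouped.to_numpy()
        return pd.DataFrame(
            {
                "read_id": [f"{self.assay}_{self.condition}_r{self.replicate}_{i}" for i in range(len(self))],
                "transcript_id": self.transcript_ids,
                "start": self.starts,
                "length": self.lengths,
                "assay": self.assay,
                "condition": self.condition,
                "replicate": self.replicate,
                "mismatches": enc,
            }
        )

    def iter_reads(self) -> Iterator[AlignedRead]:
        by_read: dict[int, list[tuple[int, str, str]]] = {}
        for ri, pos, ref, alt in self.mismatches.itertuples(index=False):
            by_read.setdefault(int(ri), []).append((int(pos), ref, alt))
        for i in range(len(self)):
            yield AlignedRead(
                read_id=f"{self.assay}_{self.condition}_r{self.replicate}_{i}",
                transcript_id=str(self.transcript_ids[i]),
                start=int(self.starts[i]),
                length=int(self.lengths[i]),
                mismatches=by_read.get(i, []),
                quality_profile=None if self.qualities is None else list(self.qualities[i]),
            )

    @classmethod
    def from_reads(
        cls, reads: Sequence[AlignedRead], assay: str = "CLIP",
        condition: str = "ctrl", replicate: int = 1,
    ) -> "ReadSet":
        rows = []
        for i, r in enumerate(reads):
            for pos, ref, alt in r.mismatches:
                rows.append((i, pos, ref, alt))
        mm = pd.DataFrame(rows, columns=["read_index", "pos", "ref", "alt"]) if rows else None
        quals = None
        if any(r.quality_profile is not None for r in reads):
            quals = [r.quality_profile for r in reads]
        return cls(
            assay, condition, replicate,
            np.array([r.transcript_id for r in reads], dtype=object),
            np.array([r.start for r in reads], dtype=np.int64),
            np.array([r.length for r in reads], dtype=np.int64),
            mm, quals,
        )


@dataclass
class BindingCluster:
    """Merged, replicate-supported enriched interval on a transcript."""

    transcript_id: str
    start: int
    end: int
    replicate_support: frozenset[int]
    total_clip_reads: int
    min_tail_probability: float
    region: str = "3UTR"

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class OffsetEntry:
    """Per-read-length A-site offset with its frame-periodicity evidence."""

    read_length: int
    asite_offset: int
    frame_counts: tuple[int, int, int]
    periodicity_pass: bool


class OffsetTable(dict):
    """Mapping read length -> :class:`OffsetEntry`."""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "read_length": e.read_length,
                    "asite_offset": e.asite_offset,
                    "frame0": e.frame_counts[0],
                    "frame1": e.frame_counts[1],
                    "frame2": e.frame_counts[2],
                    "periodicity_pass": e.periodicity_pass,
                }
                for e in self.values()
            ]
        )


def transcripts_by_id(transcripts: Sequence[TranscriptModel]) -> dict[str, TranscriptModel]:
    return {t.transcript_id: t for t in transcripts}
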