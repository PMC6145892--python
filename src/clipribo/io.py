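"""Plain-text readers/writers for the pipeline's on-disk formats.

Transcripts travel as FASTA (Biopython) plus a tab-separated annotation of
region boundaries; reads as TSV alignment records with mismatches encoded as
``pos:ref>alt;...``; sites and clusters additionally as BED6 with the
transcript as the chromosome.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import BindingCluster, PlantedSite, ReadSet, TranscriptModel

READ_COLUMNS = [
    "read_id", "transcript_id", "start", "length", "assay", "condition",
    "replicate", "mismatches",
]


def write_transcripts_fasta(transcripts: Sequence[TranscriptModel], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(t.sequence), id=t.transcript_id,
                  description=f"utr5_end={t.utr5_end} cds_end={t.cds_end}")
        for t in transcripts
    ]
    SeqIO.write(records, str(path), "fasta")


def write_annotation(transcripts: Sequence[TranscriptModel], path: str | Path) -> None:
    pd.DataFrame(
        {
            "transcript_id": [t.transcript_id for t in transcripts],
            "utr5_end": [t.utr5_end for t in transcripts],
            "cds_end": [t.cds_end for t in transcripts],
            "length": [t.length for t in transcripts],
        }
    ).to_csv(path, sep="\t", index=False)


def read_transcripts(fasta_path: str | Path, annotation_path: str | Path) -> list[TranscriptModel]:
    annot = pd.read_csv(annotation_path, sep="\t").set_index("transcript_id")
    transcripts = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        row = annot.loc[rec.id]
        transcripts.append(
            TranscriptModel(rec.id, str(rec.seq).upper(), int(row["utr5_end"]), int(row["cds_end"]))
        )
    return transcripts


def write_reads_tsv(readset: ReadSet, path: str | Path) -> None:
    readset.to_frame().to_csv(path, sep="\t", index=False)


def read_reads_tsv(path: str | Path) -> ReadSet:
    frame = pd.read_csv(path, sep="\t", dtype={"mismatches": str}, keep_default_na=False)
    assay = frame["assay"].iloc[0] if len(frame) else "CLIP"
    condition = frame["condition"].iloc[0] if len(frame) else "ctrl"
    replicate = int(frame["replicate"].iloc[0]) if len(frame) else 1
    mm_rows = []
    for i, enc in enumerate(frame["mismatches"]):
        if not enc:
            continue
        for token in enc.split(";"):
            pos, rest = token.split(":")
            ref, alt = rest.split(">")
            mm_rows.append((i, int(pos), ref, alt))
    mm = pd.DataFrame(mm_rows, columns=["read_index", "pos", "ref", "alt"]) if mm_rows else None
    return ReadSet(
        assay, condition, replicate,
        frame["transcript_id"].to_numpy(dtype=object),
        frame["start"].to_numpy(np.int64),
        frame["length"].to_numpy(np.int64),
        mm,
    )


def sites_to_bed(sites: Sequence[PlantedSite]) -> pd.DataFrame:
    """BED6 with the transcript as chromosome; score is the enrichment
    factor, strand is '+' (transcript space)."""
    return pd.DataFrame(
        {
            "chrom": [s.transcript_id for s in sites],
            "start": [s.start for s in sites],
            "end": [s.end for s in sites],
            "name": [s.element_kind for s in sites],
            "score": [s.enrichment_factor for s in sites],
            "strand": "+",
        }
    )


def write_bed(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False, header=False)


def clusters_to_frame(clusters: Sequence[BindingCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": [c.transcript_id for c in clusters],
            "start": [c.start for c in clusters],
            "end": [c.end for c in clusters],
            "region": [c.region for c in clusters],
            "total_clip_reads": [c.total_clip_reads for c in clusters],
            "replicate_support": [
                ",".join(map(str, sorted(c.replicate_support))) for c in clusters
            ],
            "min_tail_probability": [c.min_tail_probability for c in clusters],
        }
    )


def clusters_to_bed(clusters: Sequence[BindingCluster]) -> pd.DataFrame:
    """BED6 plus total_reads, replicate_support and min tail probability."""
    return pd.DataFrame(
        {
            "chrom": [c.transcript_id for c in clusters],
            "start": [c.start for c in clusters],
            "end": [c.end for c in clusters],
            "name": [f"cluster_{i}" for i in range(len(clusters))],
            "score": [c.total_clip_reads for c in clusters],
            "strand": "+",
            "total_reads": [c.total_clip_reads for c in clusters],
            "replicate_support": [
                ",".join(map(str, sorted(c.replicate_support))) for c in clusters
            ],
            "min_tail_probability": [c.min_tail_probability for c in clusters],
        }
    )


def write_cluster_fasta(
    named_sequences: Iterable[tuple[str, str]], path: str | Path
) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in named_sequences]
    SeqIO.write(records, str(path), "fasta")


def read_cluster_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_ground_truth(
    sites_frame: pd.DataFrame, effects_frame: pd.DataFrame, outdir: str | Path
) -> None:
    outdir = Path(outdir)
    sites_frame.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
    effects_frame.to_csv(outdir / "truth_effects.tsv", sep="\t", index=False)


def read_design(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t")
    required = {"sample", "assay", "condition", "replicate"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    return design
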