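"""Ribo-seq / mRNA-seq processing: A-site offsets, counts, fold-changes.

Ribosome-protected fragments are assigned to codons through a per-read-length
A-site offset, inferred from start-codon-anchored 3-nt periodicity; read
lengths that fail the periodicity check are dropped. Gene counts (CDS A-site
counts for RPFs, whole-transcript counts for mRNA) are normalized with
median-of-ratios size factors, turned into pseudocounted log2 fold-changes,
and combined into translational-efficiency (TE) changes:

    te_log2fc = rpf_log2fc - mrna_log2fc    (exact identity, per gene)

TE significance comes from a joint label-permutation test (condition labels
permuted over replicate units, identically in both assays), a transparent
stand-in for negative-binomial machinery.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import OffsetEntry, OffsetTable, ReadSet, TranscriptModel

logger = logging.getLogger(__name__)

RIBO_ADAPTER = "AGATCGGAAGAGCACACGTCT"
MRNA_ADAPTER = "AGATCGGAAGAGCGGTT"


def trim_adapter(sequences: Iterable[str], adapter: str, min_overlap: int = 3) -> list[str]:
    """Remove the 3' adapter: the longest read suffix equal to an adapter
    prefix of length >= ``min_overlap`` (or containing the whole adapter)."""
    out = []
    for seq in sequences:
        trimmed = seq
        full = seq.find(adapter)
        if full >= 0:
            trimmed = seq[:full]
        else:
            for k in range(min(len(adapter), len(seq)) - 1, min_overlap - 1, -1):
                if seq.endswith(adapter[:k]):
                    trimmed = seq[: len(seq) - k]
                    break
        out.append(trimmed)
    return out


def _region_arrays(
    reads: ReadSet, transcripts: Sequence[TranscriptModel]
) -> tuple[np.ndarray, np.ndarray]:
    utr5 = {t.transcript_id: t.utr5_end for t in transcripts}
    cdse = {t.transcript_id: t.cds_end for t in transcripts}
    u = np.array([utr5.get(t, -1) for t in reads.transcript_ids], dtype=np.int64)
    c = np.array([cdse.get(t, -1) for t in reads.transcript_ids], dtype=np.int64)
    return u, c


def infer_asite_offsets(
    rpf_reads: Sequence[ReadSet] | ReadSet,
    transcripts: Sequence[TranscriptModel],
    candidate_offsets: Sequence[int] = (10, 11, 12, 13, 14),
    min_reads: int = 100,
    preferred_offset: int = 12,
    min_frame0_fraction: float = 0.4,
) -> OffsetTable:
    """Per-read-length A-site offset from start-codon-anchored periodicity.

    For each read length the offset is the candidate maximizing the number of
    reads whose A-site (5' start + offset) lands on frame 0 of the CDS; ties
    break toward ``preferred_offset``. ``frame_counts`` and the periodicity
    verdict are recorded at the chosen offset. Because the offset is chosen
    to maximize frame 0, frame 0 is nominally maximal even for frame-uniform
    reads; the periodicity verdict therefore additionally requires the
    frame-0 fraction to clear ``min_frame0_fraction``, a margin above the
    uniform 1/3. Lengths with fewer than ``min_reads`` reads are excluded.
    """
    readsets = [rpf_reads] if isinstance(rpf_reads, ReadSet) else list(rpf_reads)
    starts = np.concatenate([rs.starts for rs in readsets])
    lengths = np.concatenate([rs.lengths for rs in readsets])
    u_list, c_list = zip(*[_region_arrays(rs, transcripts) for rs in readsets])
    utr5 = np.concatenate(u_list)
    cds_end = np.concatenate(c_list)
    table = OffsetTable()
    for L in sorted(np.unique(lengths)):
        sel = lengths == L
        if int(sel.sum()) < min_reads:
            logger.info("read length %d has <%d reads; offset undefined", L, min_reads)
            continue
        st, u5, ce = starts[sel], utr5[sel], cds_end[sel]
        best_offset, best_f0 = None, -1
        for o in candidate_offsets:
            asite = st + o
            in_cds = (asite >= u5) & (asite < ce) & (u5 >= 0)
            f0 = int(np.sum(((asite - u5) % 3 == 0) & in_cds))
            better = f0 > best_f0 or (
                f0 == best_f0
                and best_offset is not None
                and abs(o - preferred_offset) < abs(best_offset - preferred_offset)
            )
            if better:
                best_offset, best_f0 = o, f0
        asite = st + best_offset
        in_cds = (asite >= u5) & (asite < ce) & (u5 >= 0)
        frames = (asite[in_cds] - u5[in_cds]) % 3
        fc = tuple(int(np.sum(frames == f)) for f in range(3))
        total = max(sum(fc), 1)
        table[int(L)] = OffsetEntry(
            read_length=int(L),
            asite_offset=int(best_offset),
            frame_counts=fc,
            periodicity_pass=(
                fc[0] > fc[1] and fc[0] > fc[2] and fc[0] / total >= min_frame0_fraction
            ),
        )
    return table


def periodicity_filter(offset_table: OffsetTable) -> list[int]:
    """Read lengths showing the expected 3-nt periodicity; error when none."""
    retained = [L for L, e in offset_table.items() if e.periodicity_pass]
    if not retained:
        raise ValueError(
            "no read length shows 3-nt periodicity; inspect the offset table "
            "before proceeding"
        )
    return sorted(retained)


def count_reads(
    reads: ReadSet,
    transcripts: Sequence[TranscriptModel],
    assay: str,
    offsets: OffsetTable | None = None,
    retained_lengths: Sequence[int] | None = None,
) -> pd.Series:
    """Per-gene counts: an RPF is counted iff its A-site lies in the CDS
    (after length filtering); an mRNA read iff it overlaps the transcript."""
    index = [t.transcript_id for t in transcripts]
    if assay == "mRNA":
        vc = pd.Series(reads.transcript_ids).value_counts()
        return vc.reindex(index).fillna(0).astype(int)
    if assay != "RPF":
        raise ValueError(f"unknown assay: {assay}")
    if offsets is None:
        raise ValueError("RPF counting requires an offset table")
    if retained_lengths is None:
        retained_lengths = periodicity_filter(offsets)
    utr5, cds_end = _region_arrays(reads, transcripts)
    keep = np.isin(reads.lengths, list(retained_lengths))
    off = np.array([offsets[int(L)].asite_offset if int(L) in offsets else -999
                    for L in reads.lengths])
    asite = reads.starts + off
    in_cds = keep & (off > -999) & (asite >= utr5) & (asite < cds_end) & (utr5 >= 0)
    vc = pd.Series(reads.transcript_ids[in_cds]).value_counts()
    return vc.reindex(index).fillna(0).astype(int)


def build_count_table(
    readsets: Mapping[tuple[str, str, int], ReadSet],
    transcripts: Sequence[TranscriptModel],
    offsets: OffsetTable | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x sample count matrix plus its design table.

    ``readsets`` maps (assay, condition, replicate) -> ReadSet; sample names
    are ``{assay}_{condition}_{replicate}``.
    """
    cols, design_rows = {}, []
    for (assay, condition, rep), rs in sorted(readsets.items()):
        name = f"{assay}_{condition}_{rep}"
        cols[name] = count_reads(rs, transcripts, assay, offsets=offsets)
        design_rows.append(
            {"sample": name, "assay": assay, "condition": condition, "replicate": rep}
        )
    return pd.DataFrame(cols), pd.DataFrame(design_rows)


def normalize(count_table: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors and the normalized count matrix.

    Genes with a zero in any sample are excluded from factor estimation (the
    geometric-mean reference is undefined there), as in the standard
    median-of-ratios recipe.
    """
    if count_table.shape[1] < 2:
        raise ValueError("need >= 2 samples to normalize")
    counts = count_table.to_numpy(dtype=float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in all samples")
    log_gm = np.log(counts[positive]).mean(axis=1)
    ratios = np.log(counts[positive]) - log_gm[:, None]
    factors = pd.Series(np.exp(np.median(ratios, axis=0)), index=count_table.columns,
                        name="size_factor")
    return factors, count_table / factors


def _log2fc(
    norm: pd.DataFrame, samples_ctrl: Sequence[str], samples_pert: Sequence[str],
    pseudocount: float,
) -> pd.Series:
    mc = norm[list(samples_ctrl)].mean(axis=1)
    mp = norm[list(samples_pert)].mean(axis=1)
    return np.log2(mp + pseudocount) - np.log2(mc + pseudocount)


def fold_changes(
    count_table: pd.DataFrame,
    design: pd.DataFrame,
    pseudocount: float = 0.5,
    n_perm: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene mRNA / RPF / TE log2 fold-changes (perturbed vs ctrl).

    Size factors are estimated within each assay. With ``n_perm > 0`` a
    two-sided permutation p-value for the TE change is computed by permuting
    condition labels over (condition, replicate) units, applying the same
    relabeling to the mRNA and RPF samples of a unit; the estimator is
    ``(1 + #extreme) / (1 + n_perm)``. Genes with zero counts in every sample
    of one assay have undefined TE (NaN, flagged in ``te_defined``).
    """
    norm_parts, sample_map = {}, {}
    for assay in ("mRNA", "RPF"):
        cols = design.loc[design["assay"] == assay, "sample"].tolist()
        if not cols:
            raise ValueError(f"design has no {assay} samples")
        _, norm_parts[assay] = normalize(count_table[cols])
        for _, row in design[design["assay"] == assay].iterrows():
            sample_map[(assay, row["condition"], int(row["replicate"]))] = row["sample"]
    units = sorted(
        {(c, int(r)) for c, r in zip(design["condition"], design["replicate"])}
    )
    n_ctrl = sum(c == "ctrl" for c, _ in units)

    # per-unit normalized counts, genes x units, one matrix per assay
    unit_mats = {
        assay: np.column_stack(
            [norm_parts[assay][sample_map[(assay, c, r)]].to_numpy(float) for c, r in units]
        )
        for assay in ("mRNA", "RPF")
    }

    def stat_for(ctrl_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(mrna, rpf, te) log2FC for one ctrl/perturbed assignment."""
        fcs = {}
        for assay in ("mRNA", "RPF"):
            mc = unit_mats[assay][:, ctrl_mask].mean(axis=1)
            mp = unit_mats[assay][:, ~ctrl_mask].mean(axis=1)
            fcs[assay] = np.log2(mp + pseudocount) - np.log2(mc + pseudocount)
        return fcs["mRNA"], fcs["RPF"], fcs["RPF"] - fcs["mRNA"]

    identity = np.array([c == "ctrl" for c, _ in units])
    mrna_fc, rpf_fc, te_fc = stat_for(identity)
    defined = ~(
        (count_table[[s for (a, c, r), s in sample_map.items() if a == "mRNA"]].sum(axis=1) == 0)
        | (count_table[[s for (a, c, r), s in sample_map.items() if a == "RPF"]].sum(axis=1) == 0)
    ).to_numpy()
    result = pd.DataFrame(
        {
            "gene_id": count_table.index,
            "mrna_log2fc": mrna_fc,
            "rpf_log2fc": rpf_fc,
            "te_log2fc": te_fc,
            "te_defined": defined,
            "base_mean_mrna": norm_parts["mRNA"].mean(axis=1).to_numpy(),
            "base_mean_rpf": norm_parts["RPF"].mean(axis=1).to_numpy(),
        }
    ).set_index("gene_id")
    if n_perm > 0:
        # enumerate the distinct joint relabelings (same assignment applied to
        # the mRNA and RPF samples of a unit); sample n_perm of them per gene
        # independently so p-values are uncorrelated across genes
        from itertools import combinations as _combinations

        combos = []
        for j, comb in enumerate(_combinations(range(len(units)), n_ctrl)):
            combos.append(comb)
            if j >= 4999:  # cap the enumeration for very large designs
                break
        if len(combos) <= max(2, n_perm // 10):
            logger.warning(
                "only %d distinct label permutations exist for this design; "
                "permutation p-values are coarse", len(combos),
            )
        stat_table = np.empty((len(count_table), len(combos)))
        for j, comb in enumerate(combos):
            mask = np.zeros(len(units), dtype=bool)
            mask[list(comb)] = True
            stat_table[:, j] = np.abs(stat_for(mask)[2])
        rng = np.random.default_rng(seed)
        draws = rng.integers(0, len(combos), size=(len(count_table), n_perm))
        obs = np.abs(te_fc)[:, None]
        extreme = np.take_along_axis(stat_table, draws, axis=1) >= obs - 1e-12
        result["te_p"] = (1.0 + extreme.sum(axis=1)) / (1.0 + n_perm)
        result.loc[~defined, "te_p"] = np.nan
    result.loc[~defined, ["te_log2fc"]] = np.nan
    return result


def _bin_positions(
    reads: ReadSet,
    transcripts: Sequence[TranscriptModel],
    assay: str,
    offsets: OffsetTable | None,
    retained_lengths: Sequence[int] | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(transcript ids, positions, validity mask) for metagene binning:
    A-site positions for RPFs, read midpoints for mRNA."""
    if assay == "RPF":
        if offsets is None:
            raise ValueError("RPF binning requires offsets")
        if retained_lengths is None:
            retained_lengths = periodicity_filter(offsets)
        off = np.array([offsets[int(L)].asite_offset if int(L) in offsets else -999
                        for L in reads.lengths])
        pos = reads.starts + off
        ok = np.isin(reads.lengths, list(retained_lengths)) & (off > -999)
    else:
        pos = reads.starts + reads.lengths // 2
        ok = np.ones(len(reads), dtype=bool)
    return reads.transcript_ids, pos, ok


def metagene_profile(
    readsets: Mapping[tuple[str, str, int], ReadSet],
    transcripts: Sequence[TranscriptModel],
    offsets: OffsetTable | None = None,
    bin_size: int = 100,
    n_bins: int = 10,
    pseudocount: float = 0.5,
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Mean +/- SEM log2 fold-change in ``n_bins`` x ``bin_size``-nt ORF bins.

    Bins span the first and last ``n_bins * bin_size`` nt of the CDS: on the
    ``first`` end bin 1 starts at the start codon; on the ``last`` end bin
    ``n_bins`` ends at the stop codon. Only genes with an ORF of at least
    ``n_bins * bin_size`` nt contribute. RPFs are binned by A-site, mRNA
    reads by midpoint. Samples are scaled by ``size_factors`` when given
    (otherwise by total gene-level counts per sample within assay).
    """
    span = n_bins * bin_size
    genes = [t for t in transcripts if t.cds_length >= span]
    if len(genes) < 10:
        logger.warning("only %d genes have an ORF >= %d nt; profile is noisy", len(genes), span)
    gmap = {t.transcript_id: i for i, t in enumerate(genes)}
    utr5 = np.array([t.utr5_end for t in genes], dtype=np.int64)
    cds_end = np.array([t.cds_end for t in genes], dtype=np.int64)

    # per sample: (n_genes, 2, n_bins) counts for first/last ends
    sample_bins: dict[str, np.ndarray] = {}
    sample_meta = []
    for (assay, condition, rep), rs in sorted(readsets.items()):
        name = f"{assay}_{condition}_{rep}"
        sample_meta.append((name, assay, condition))
        arr = np.zeros((len(genes), 2, n_bins))
        tids, pos, ok = _bin_positions(rs, transcripts, assay, offsets, None)
        gidx = np.array([gmap.get(t, -1) for t in tids], dtype=np.int64)
        ok = ok & (gidx >= 0)
        g, p = gidx[ok], pos[ok]
        rel_first = p - utr5[g]
        in_first = (rel_first >= 0) & (rel_first < span)
        np.add.at(arr, (g[in_first], 0, rel_first[in_first] // bin_size), 1)
        rel_last = cds_end[g] - 1 - p
        in_last = (rel_last >= 0) & (rel_last < span)
        # bin n_bins is adjacent to the stop codon
        np.add.at(arr, (g[in_last], 1, n_bins - 1 - rel_last[in_last] // bin_size), 1)
        sample_bins[name] = arr

    if size_factors is None:
        totals = {n: sample_bins[n].sum() for n, _, _ in sample_meta}
        by_assay: dict[str, list[str]] = {}
        for n, a, _ in sample_meta:
            by_assay.setdefault(a, []).append(n)
        assay_means = {a: np.mean([totals[m] for m in ns]) for a, ns in by_assay.items()}
        size_factors = pd.Series(
            {
                n: totals[n] / assay_means[a] if assay_means[a] > 0 else 1.0
                for n, a, _ in sample_meta
            }
        )
    rows = []
    for assay in ("mRNA", "RPF"):
        ctrl = [n for n, a, c in sample_meta if a == assay and c == "ctrl"]
        pert = [n for n, a, c in sample_meta if a == assay and c == "perturbed"]
        if not ctrl or not pert:
            continue
        mean_ctrl = np.mean([sample_bins[n] / size_factors[n] for n in ctrl], axis=0)
        mean_pert = np.mean([sample_bins[n] / size_factors[n] for n in pert], axis=0)
        log2fc = np.log2(mean_pert + pseudocount) - np.log2(mean_ctrl + pseudocount)
        for e, end in enumerate(("first", "last")):
            for b in range(n_bins):
                vals = log2fc[:, e, b]
                rows.append(
                    {
                        "assay": assay, "end": end, "bin": b + 1,
                        "mean_log2fc": float(vals.mean()) if len(vals) else np.nan,
                        "sem": float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan,
                        "n_genes": len(vals),
                    }
                )
    return pd.DataFrame(rows)
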