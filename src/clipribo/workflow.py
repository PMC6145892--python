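"""End-to-end orchestration: simulate -> callsites -> motifs -> riboseq ->
stratify, driven by a YAML config, with a machine-readable JSON report.

The config carries either a ``simulation`` block (the synthetic generator's
parameters) or an ``inputs`` block with paths to real transcript-space data;
every stage writes its outputs under ``outdir`` and the report records
parameter echoes, per-output SHA-256 digests and headline numbers, so a fixed
config + seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import clip_sites, io, motifs, riboseq, stratify
from .simulate import SimulationConfig, simulate_experiment

logger = logging.getLogger(__name__)

#: small simulation that exercises every stage in well under a minute
DEFAULT_DEMO_CONFIG: dict[str, Any] = {
    "seed": 7,
    "outdir": "clipribo_demo",
    "simulation": {
        "n_transcripts": 60,
        "clip_depth": 150_000,
        "mrna_depth": 120_000,
        "rpf_depth": 120_000,
        "target_fraction": 0.4,
    },
    "callsites": {"width": 40, "step": 1, "prob_cutoff": 0.999, "min_reads": 50,
                  "window_scaled": True},
    "motifs": {"width": 15, "n_shuffles": 3, "hit_rate": 0.05, "n_restarts": 6},
    "riboseq": {"min_reads_per_length": 100, "n_perm": 100, "pseudocount": 0.5},
    "stratify": {"match_n": 8, "top_frac": 0.10, "multiple_by": "kinds"},
}


class ConfigError(ValueError):
    pass


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a YAML mapping")
    return cfg


def validate_config(config: Mapping[str, Any]) -> list[tuple[str, str]]:
    """Return (level, message) issues; empty list iff the config is runnable.

    Levels are ``error`` (blocks the run) and ``warning`` (deviation from
    the reference analysis settings)."""
    issues: list[tuple[str, str]] = []
    has_sim = bool(config.get("simulation"))
    inputs = config.get("inputs") or {}
    has_inputs = bool(inputs.get("transcripts_fasta") and inputs.get("annotation"))
    if not has_sim and not has_inputs:
        issues.append(("error", "either a simulation block or input paths (transcripts_fasta + annotation) are required"))
    cs = config.get("callsites", {})
    prob = cs.get("prob_cutoff", 0.999)
    if not 0.0 < prob < 1.0:
        issues.append(("error", f"callsites.prob_cutoff must be in (0, 1), got {prob}"))
    if cs.get("min_reads", 50) < 0:
        issues.append(("error", "callsites.min_reads must be >= 0"))
    mo = config.get("motifs", {})
    if mo.get("n_shuffles", 3) < 3:
        issues.append(("warning", "motifs.n_shuffles < 3; the reference analysis used three shuffle sets"))
    st = config.get("stratify", {})
    if not 0.0 < st.get("top_frac", 0.10) <= 1.0:
        issues.append(("error", "stratify.top_frac must be in (0, 1]"))
    if has_sim:
        try:
            SimulationConfig(**{**config["simulation"], "seed": int(config.get("seed", 0))})
        except Exception as exc:  # surfaced as a config issue, not a crash
            issues.append(("error", f"simulation block invalid: {exc}"))
    return issues


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: Mapping[str, Any] | str | Path) -> dict[str, Any]:
    """Run all stages; returns the report (also written to
    ``outdir/report.json``). Aborts naming the failing stage."""
    if not isinstance(config, Mapping):
        config = load_config(config)
    issues = validate_config(config)
    errors = [m for lvl, m in issues if lvl == "error"]
    if errors:
        raise ConfigError("; ".join(errors))
    for lvl, msg in issues:
        logger.warning("config: %s", msg)

    outdir = Path(config.get("outdir", "clipribo_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    report: dict[str, Any] = {
        "config": json.loads(json.dumps(config, default=str)),
        "seed": seed,
        "stages": {},
        "headline": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    outputs: dict[str, Path] = {}
    stage = "setup"
    try:
        # ---- simulate / load -------------------------------------------------
        stage = "simulate"
        if config.get("simulation"):
            sim_cfg = SimulationConfig(**{**config["simulation"], "seed": seed})
            experiment = simulate_experiment(sim_cfg)
            transcripts = experiment.transcripts
            clip_by_rep = {rs.replicate: rs for rs in experiment.clip}
            expression = experiment.expression
            io.write_transcripts_fasta(transcripts, outdir / "transcripts.fa")
            io.write_annotation(transcripts, outdir / "annotation.tsv")
            io.write_ground_truth(
                experiment.ground_truth_sites(), experiment.ground_truth_effects(), outdir
            )
            io.write_bed(io.sites_to_bed(experiment.sites), outdir / "truth_sites.bed")
            outputs.update(
                {
                    "transcripts.fa": outdir / "transcripts.fa",
                    "annotation.tsv": outdir / "annotation.tsv",
                    "truth_sites.tsv": outdir / "truth_sites.tsv",
                    "truth_effects.tsv": outdir / "truth_effects.tsv",
                    "truth_sites.bed": outdir / "truth_sites.bed",
                }
            )
            report["stages"]["simulate"] = {
                "n_transcripts": len(transcripts),
                "n_planted_sites": len(experiment.sites),
                "clip_reads_per_replicate": sim_cfg.clip_depth,
            }
        else:
            inputs = config["inputs"]
            transcripts = io.read_transcripts(inputs["transcripts_fasta"], inputs["annotation"])
            clip_by_rep = {
                i + 1: io.read_reads_tsv(p) for i, p in enumerate(inputs.get("clip_reads", []))
            }
            expression = {}
            for key in ("mrna_reads", "rpf_reads"):
                for reads_path in inputs.get(key, []):
                    rs = io.read_reads_tsv(reads_path)
                    expression[(rs.assay, rs.condition, rs.replicate)] = rs
            report["stages"]["simulate"] = {"loaded_inputs": True}

        # ---- callsites -------------------------------------------------------
        stage = "callsites"
        cs = dict(config.get("callsites", {}))
        mrna_ctrl = [rs for (assay, cond, _), rs in expression.items()
                     if assay == "mRNA" and cond == "ctrl"]
        if mrna_ctrl:
            abundances = clip_sites.mrna_relative_abundance(mrna_ctrl, transcripts)
        else:
            abundances = pd.Series(
                1.0 / len(transcripts), index=[t.transcript_id for t in transcripts]
            )
        clusters = clip_sites.call_binding_sites(
            clip_by_rep, abundances, transcripts,
            width=cs.get("width", 40), step=cs.get("step", 1),
            prob_cutoff=cs.get("prob_cutoff", 0.999),
            min_reads=cs.get("min_reads", 50),
            window_scaled=cs.get("window_scaled", True),
        )
        cluster_frame = io.clusters_to_frame(clusters)
        cluster_frame.to_csv(outdir / "clusters.tsv", sep="\t", index=False)
        io.write_bed(io.clusters_to_bed(clusters), outdir / "clusters.bed")
        density = clip_sites.region_density(clusters, transcripts)
        density.to_csv(outdir / "region_density.tsv", sep="\t", index=False)
        outputs.update(
            {
                "clusters.tsv": outdir / "clusters.tsv",
                "clusters.bed": outdir / "clusters.bed",
                "region_density.tsv": outdir / "region_density.tsv",
            }
        )
        report["stages"]["callsites"] = {"n_clusters": len(clusters)}
        report["headline"]["n_retained_clusters"] = len(clusters)
        report["headline"]["n_target_transcripts"] = int(cluster_frame["transcript_id"].nunique())

        # ---- motifs ----------------------------------------------------------
        stage = "motifs"
        mo = dict(config.get("motifs", {}))
        named = dict(clip_sites.cluster_sequences(clusters, transcripts))
        io.write_cluster_fasta(named.items(), outdir / "clusters.fa")
        outputs["clusters.fa"] = outdir / "clusters.fa"
        annotations = pd.DataFrame(columns=["transcript_id", "n_sites", "stratum", "element_kinds"])
        if len(named) >= 2:
            seqs = list(named.values())
            train, _test = motifs.split_train_test(seqs, seed=seed)
            width = mo.get("width", 15)
            train_ok = [s for s in train if len(s) >= width]
            hits: list[motifs.MotifHit] = []
            if len(train_ok) >= 2:
                pwm = motifs.discover_pwm(
                    train_ok, width=width, n_restarts=mo.get("n_restarts", 8), seed=seed
                )
                (outdir / "motif.meme.txt").write_text(pwm.to_meme_text("LBE"))
                outputs["motif.meme.txt"] = outdir / "motif.meme.txt"
                shuffled = motifs.shuffle_background(
                    seqs, n_sets=mo.get("n_shuffles", 3), seed=seed + 1
                )
                cutoff = motifs.score_cutoff_from_shuffles(
                    pwm, shuffled[0], hit_rate=mo.get("hit_rate", 0.05)
                )
                lbe_hits = motifs.scan_pwm(pwm, named, cutoff, kind="LBE")
                sl_hits = motifs.detect_stem_loops(named, deoverlap=True)
                cde_hits = motifs.detect_stem_loops(
                    named, motifs.CDE_RULE, kind="CDE_like", deoverlap=True
                )
                enrich_rows = []
                for kind, scanner in (
                    ("LBE", lambda s: motifs.scan_pwm(pwm, s, cutoff, kind="LBE")),
                    ("SL_motif", lambda s: motifs.detect_stem_loops(s, deoverlap=True)),
                    ("CDE_like", lambda s: motifs.detect_stem_loops(s, motifs.CDE_RULE, kind="CDE_like", deoverlap=True)),
                ):
                    comp = motifs.motif_enrichment(kind, named, shuffled, scanner)
                    enrich_rows.append(
                        {
                            "kind": comp.kind, "observed_fraction": comp.observed_fraction,
                            "background_fraction": comp.background_fraction,
                            "n_shuffles": comp.n_shuffles, "fold": comp.fold,
                            "empirical_p": comp.empirical_p,
                        }
                    )
                pd.DataFrame(enrich_rows).to_csv(outdir / "motif_enrichment.tsv", sep="\t", index=False)
                outputs["motif_enrichment.tsv"] = outdir / "motif_enrichment.tsv"
                hits = motifs.lift_hits_to_transcripts(lbe_hits + sl_hits + cde_hits)
            annotations = motifs.count_sites_per_transcript(hits)
        annotations.to_csv(outdir / "targets.tsv", sep="\t", index=False)
        outputs["targets.tsv"] = outdir / "targets.tsv"
        report["stages"]["motifs"] = {
            "n_targets_with_sites": len(annotations),
            "site_count_histogram": (
                motifs.site_count_histogram(annotations).to_dict() if len(annotations) else {}
            ),
        }

        # ---- riboseq ---------------------------------------------------------
        stage = "riboseq"
        rb = dict(config.get("riboseq", {}))
        fc = pd.DataFrame()
        if expression:
            rpf_sets = [rs for (assay, _, _), rs in expression.items() if assay == "RPF"]
            offsets = riboseq.infer_asite_offsets(
                rpf_sets, transcripts, min_reads=rb.get("min_reads_per_length", 100)
            )
            offsets.to_frame().to_csv(outdir / "offsets.tsv", sep="\t", index=False)
            outputs["offsets.tsv"] = outdir / "offsets.tsv"
            counts, design = riboseq.build_count_table(expression, transcripts, offsets)
            counts.to_csv(outdir / "counts.tsv", sep="\t")
            outputs["counts.tsv"] = outdir / "counts.tsv"
            fc = riboseq.fold_changes(
                counts, design, pseudocount=rb.get("pseudocount", 0.5),
                n_perm=rb.get("n_perm", 100), seed=seed,
            )
            fc.to_csv(outdir / "fold_changes.tsv", sep="\t")
            outputs["fold_changes.tsv"] = outdir / "fold_changes.tsv"
            sf = {}
            for assay_name in ("mRNA", "RPF"):
                cols = design.loc[design["assay"] == assay_name, "sample"].tolist()
                f, _ = riboseq.normalize(counts[cols])
                sf.update(f.to_dict())
            meta = riboseq.metagene_profile(
                expression, transcripts, offsets, size_factors=pd.Series(sf)
            )
            meta.to_csv(outdir / "metagene.tsv", sep="\t", index=False)
            outputs["metagene.tsv"] = outdir / "metagene.tsv"
            report["stages"]["riboseq"] = {
                "offsets": {int(L): e.asite_offset for L, e in offsets.items()},
                "retained_lengths": riboseq.periodicity_filter(offsets),
                "n_genes": int(len(fc)),
            }

        # ---- stratify --------------------------------------------------------
        stage = "stratify"
        st = dict(config.get("stratify", {}))
        if len(fc) and len(annotations):
            result = stratify.stratify_by_site_count(annotations, fc)
            result["comparisons"].to_csv(outdir / "stratum_tests.tsv", sep="\t", index=False)
            result["medians"].to_csv(outdir / "stratum_medians.tsv", sep="\t", index=False)
            outputs["stratum_tests.tsv"] = outdir / "stratum_tests.tsv"
            outputs["stratum_medians.tsv"] = outdir / "stratum_medians.tsv"
            target_ids = annotations["transcript_id"].astype(str).tolist()
            repressed = stratify.call_translational_repression(
                fc, target_ids, fraction=st.get("top_frac", 0.10)
            )
            summary: dict[str, Any] = {
                "n_targets": len(target_ids),
                "n_translationally_repressed": len(repressed),
            }
            tmap = {t.transcript_id: t for t in transcripts}
            t_len = pd.Series({g: tmap[g].utr3_length for g in target_ids if g in tmap})
            nt_ids = [g for g in fc.index if g not in set(target_ids) and g in tmap]
            nt_len = pd.Series({g: tmap[g].utr3_length for g in nt_ids})
            match_n = st.get("match_n", 500)
            if len(t_len) >= match_n and len(nt_len) >= match_n:
                matched = stratify.match_by_utr_length(t_len, nt_len, n=match_n, seed=seed)
                summary["matched_ks_distance"] = matched.ks_distance
                for metric in ("mrna_log2fc", "rpf_log2fc", "te_log2fc"):
                    comp = stratify.ecdf_compare(
                        fc.loc[matched.target_ids, metric].dropna(),
                        fc.loc[matched.nontarget_ids, metric].dropna(),
                        "targets", "nontargets",
                    )
                    summary[f"matched_{metric}_p"] = comp.p_value
            else:
                logger.warning("pools too small for match_n=%d; matching skipped", match_n)
            if repressed and len(annotations):
                try:
                    chi = stratify.multi_element_association(
                        repressed, annotations, multiple_by=st.get("multiple_by", "kinds")
                    )
                    summary["multi_element_chi2"] = chi.statistic
                    summary["multi_element_p"] = chi.p_value
                except ValueError as exc:
                    logger.warning("chi-square skipped: %s", exc)
            kinds_tests = stratify.element_kind_vs_regulation(annotations, fc)
            kinds_tests.to_csv(outdir / "element_kind_tests.tsv", sep="\t", index=False)
            outputs["element_kind_tests.tsv"] = outdir / "element_kind_tests.tsv"
            with open(outdir / "stratify_summary.json", "w") as fh:
                json.dump(summary, fh, indent=2, default=float)
            outputs["stratify_summary.json"] = outdir / "stratify_summary.json"
            report["stages"]["stratify"] = summary
            report["headline"].update(summary)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    report["digests"] = {name: _sha256(path) for name, path in sorted(outputs.items())}
    report["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
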