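"""End-to-end orchestration: refdb -> align -> community -> quantify.

Each stage is a plain function over files plus in-memory objects, so the
command-line interface and tests can run stages individually; `run_pipeline`
chains them over a run directory and records a manifest (seed, parameters,
sha256 digest of every output) for reproducibility.  Inputs are either
generated by :mod:`butyragene.synthfix` or supplied as files with the same
layout.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import community, quantify, refdb, synthfix
from .framealign import (
    AmpliconRead,
    FilterThresholds,
    FrameAlignment,
    QCParams,
    ScoringParams,
    apply_filters,
    closest_match,
    exclude_outside_cluster,
    frameshift_stats,
    quality_filter,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_reads_fastq"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and a re-runnable command."""


@dataclass(frozen=True)
class PipelineConfig:
    outdir: Path
    seed: int = 0
    inputs_dir: Path | None = None  # default: generate synthetic inputs
    n_samples: int = 8
    n_reads_per_sample: int = 250
    coverage_cutoff: float = 0.93
    merge_cutoff: float = 0.02
    conservation_threshold: float = 0.95
    nmds_k: int = 2
    nmds_restarts: int = 20
    qc: QCParams = field(default_factory=QCParams)
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    scoring: ScoringParams = field(default_factory=ScoringParams)
    families: tuple[str, ...] = ("but", "buk")

    def synth_config(self) -> synthfix.SynthConfig:
        fams = {k: v for k, v in synthfix.default_families().items()
                if k in self.families}
        return synthfix.SynthConfig(
            seed=self.seed, n_samples=self.n_samples,
            n_reads_per_sample=self.n_reads_per_sample, families=fams,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_reads_fastq(path: Path) -> list[AmpliconRead]:
    """Read amplicons from FASTQ; the sample id is taken from `sample=` tags."""
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        sample = ""
        for token in rec.description.split():
            if token.startswith("sample="):
                sample = token.split("=", 1)[1]
        reads.append(AmpliconRead(
            rec.id, str(rec.seq), sample,
            tuple(rec.letter_annotations["phred_quality"]),
        ))
    return reads


def _require(path: Path, stage: str, cmd: str) -> Path:
    if not path.exists():
        raise PipelineError(f"stage {stage}: missing input file {path}; re-run with `{cmd}`")
    return path


# --- stages ----------------------------------------------------------------

def stage_refdb(inputs_dir: Path, outdir: Path, families: Sequence[str],
                coverage_cutoff: float, merge_cutoff: float
                ) -> dict[str, refdb.CurationResult]:
    outdir.mkdir(parents=True, exist_ok=True)
    results = {}
    for fam in families:
        fasta = _require(inputs_dir / f"{fam}_refs.faa", "refdb", "butyragene synth")
        meta = _require(inputs_dir / f"{fam}_refs_meta.tsv", "refdb", "butyragene synth")
        refs = refdb.read_reference_set(fasta, meta)
        res = refdb.curate(refs, coverage_cutoff, merge_cutoff)
        results[fam] = res
        seqs = {r.id: r.sequence for r in refs}
        with (outdir / f"{fam}_curated.faa").open("w") as fh:
            for rid in res.curated.kept:
                fh.write(f">{rid}\n{seqs[rid]}\n")
        res.tree.write(str(outdir / f"{fam}_nj.nwk"))
        pd.DataFrame(
            [{"representative": rep, "members": ",".join(members)}
             for rep, members in res.curated.merge_groups.items()]
        ).to_csv(outdir / f"{fam}_merge_groups.tsv", sep="\t", index=False)
        res.report.to_csv(outdir / f"{fam}_curation_report.tsv", sep="\t", index=False)
    return results


def stage_align(inputs_dir: Path, outdir: Path,
                curations: Mapping[str, refdb.CurationResult],
                qc: QCParams, thresholds: FilterThresholds,
                scoring: ScoringParams) -> dict[str, dict]:
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict[str, dict] = {}
    for fam, cur in curations.items():
        fastq = _require(inputs_dir / f"{fam}_reads.fastq", "align", "butyragene synth")
        raw = load_reads_fastq(fastq)
        passed, reasons = quality_filter(raw, qc)
        # align against every coverage-passing reference (kept and excluded);
        # out-of-cluster matches are dropped afterwards
        ref_seqs = {rid: cur.aligned[rid].replace("-", "")
                    for rid in (*cur.curated.kept, *cur.curated.excluded)}
        alignments = [closest_match(read, ref_seqs, scoring) for read in passed]
        assigned = [a for a in alignments if a.is_aligned]
        outcome = apply_filters(assigned, fam, thresholds)
        stats = frameshift_stats(outcome.initial_pass) if outcome.initial_pass else None
        kept, dropped_fraction = exclude_outside_cluster(outcome.downstream_pass,
                                                         cur.curated)
        sample_of = {r.id: r.sample_id for r in passed}
        rows = [{
            "read_id": a.read_id, "sample": sample_of.get(a.read_id, ""),
            "ref_id": a.ref_id, "identity": round(a.identity_pct, 3),
            "aligned_len": a.aligned_len_aa, "frameshifts": a.frameshift_count,
            "strand": a.strand, "score": a.score,
            "gate": ("downstream" if a in set(outcome.downstream_pass)
                     else "initial" if a in set(outcome.initial_pass) else "fail"),
        } for a in assigned]
        pd.DataFrame(rows, columns=["read_id", "sample", "ref_id", "identity",
                                    "aligned_len", "frameshifts", "strand",
                                    "score", "gate"]).to_csv(
            outdir / f"{fam}_alignments.tsv", sep="\t", index=False)
        with (outdir / f"{fam}_corrected.faa").open("w") as fh:
            for a in kept:
                fh.write(f">{a.read_id} ref={a.ref_id}\n{a.corrected_protein}\n")
        summary = {
            "n_raw": len(raw),
            "n_qc_pass": len(passed),
            "qc_pass_fraction": len(passed) / len(raw) if raw else 0.0,
            "n_initial_pass": len(outcome.initial_pass),
            "initial_pass_fraction": outcome.initial_fraction,
            "n_downstream_pass": len(outcome.downstream_pass),
            "downstream_fraction": outcome.downstream_fraction,
            "outside_cluster_dropped_fraction": dropped_fraction,
            "mean_frameshifts_per_read": stats.mean_frameshifts_per_read if stats else None,
            "fraction_with_frameshift": stats.fraction_with_frameshift if stats else None,
        }
        (outdir / f"{fam}_stats.json").write_text(json.dumps(summary, indent=2,
                                                             sort_keys=True))
        results[fam] = {
            "qc_reasons": reasons, "sample_of": sample_of, "outcome": outcome,
            "kept": kept, "summary": summary, "frame_stats": stats,
        }
    return results


def stage_community(outdir: Path, curations: Mapping[str, refdb.CurationResult],
                    align_results: Mapping[str, dict], seed: int,
                    nmds_k: int, nmds_restarts: int,
                    conservation_threshold: float = 0.95) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    tables = []
    conservation = {}
    for fam, res in align_results.items():
        sample_of = res["sample_of"]
        by_sample: dict[str, list[FrameAlignment]] = {
            s: [] for s in sorted(set(sample_of.values()))
        }
        for a in res["kept"]:
            by_sample.setdefault(sample_of.get(a.read_id, ""), []).append(a)
        table = community.bin_counts(by_sample, curations[fam].curated.merge_groups,
                                     gene_family=fam)
        tables.append(table)
        # conservation over model coordinates: reference rows vs amplicon
        # proteins whose corrected sequence spans their reference gap-free
        aligned = curations[fam].aligned
        ref_rows = [aligned[rid] for rid in curations[fam].curated.kept]
        width = len(ref_rows[0])
        amp_rows = []
        for a in res["kept"]:
            if len(a.corrected_protein) == a.ref_end - a.ref_start:
                row = "-" * a.ref_start + a.corrected_protein
                amp_rows.append(row + "-" * (width - len(row)))
            if len(amp_rows) >= 500:
                break
        if amp_rows:
            conservation[fam] = community.conservation_profile(
                ref_rows, amp_rows, conservation_threshold)
    combined = pd.concat(tables, axis=1).fillna(0).astype(int)
    combined.index.name = "sample"
    combined.to_csv(outdir / "bin_table.tsv", sep="\t")

    shannon = pd.Series({s: community.shannon(combined.loc[s])
                         for s in combined.index}, name="shannon")
    shannon.rename_axis("sample").to_csv(outdir / "shannon.tsv", sep="\t")

    nonzero = combined[combined.sum(axis=1) > 0]
    dm = community.chao_jaccard_matrix(nonzero)
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        outdir / "chao_jaccard.tsv", sep="\t")
    ordination = community.nmds(dm, k=nmds_k, seed=seed, restarts=nmds_restarts)
    ordination.coordinates.to_csv(outdir / "nmds_coordinates.tsv", sep="\t")
    pd.DataFrame(ordination.shepard_pairs,
                 columns=["observed", "ordination"]).to_csv(
        outdir / "shepard_pairs.tsv", sep="\t", index=False)
    for fam, (ref_prof, amp_prof, jointly) in conservation.items():
        pd.DataFrame({
            "consensus": list(ref_prof.consensus),
            "ref_max_freq": ref_prof.frequencies.max(axis=1),
            "amp_max_freq": amp_prof.frequencies.max(axis=1),
            "jointly_conserved": [i in set(jointly)
                                  for i in range(len(ref_prof.consensus))],
        }).rename_axis("column").to_csv(outdir / f"{fam}_conservation.tsv", sep="\t")
    return {"bin_table": combined, "shannon": shannon, "distances": dm,
            "ordination": ordination, "conservation": conservation}


def stage_quantify(inputs_dir: Path, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    curves_tsv = _require(inputs_dir / "qpcr_curves.tsv", "quantify", "butyragene synth")
    cq_tsv = _require(inputs_dir / "qpcr_cq.tsv", "quantify", "butyragene synth")
    curve_df = pd.read_csv(curves_tsv, sep="\t")
    curves = {
        assay: quantify.fit_standard_curve(
            list(zip(grp["log10_copies"], grp["cq"])), assay)
        for assay, grp in curve_df.groupby("assay")
    }
    cq_df = pd.read_csv(cq_tsv, sep="\t")
    measurements = [
        quantify.QpcrMeasurement(r["sample"], r["assay"], (r["cq1"], r["cq2"]))
        for r in cq_df.to_dict("records")
    ]
    quants = {}
    import warnings as _warnings

    for m in measurements:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            quants[(m.sample, m.assay)] = quantify.quantify(m, curves[m.assay])
    totals = {s: q.copies for (s, a), q in quants.items() if a == "total_16S"}
    rows = []
    for (sample, assay), q in sorted(quants.items()):
        if assay == "total_16S":
            continue
        pct = (quantify.percent_of_community(q.copies, totals[sample])
               if totals.get(sample, 0) > 0 else float("nan"))
        q = dataclasses.replace(q, percent_of_community=pct)
        quants[(sample, assay)] = q
        rows.append({
            "sample": sample, "assay": assay, "copies": q.copies,
            "half_range": q.copies_half_range, "percent_of_community": pct,
            "below_detection": q.below_detection,
        })
    pd.DataFrame(rows).to_csv(outdir / "quant_results.tsv", sep="\t", index=False)

    taxa_path = inputs_dir / "taxon_counts.tsv"
    screen = None
    if taxa_path.exists():
        counts = pd.read_csv(taxa_path, sep="\t", index_col="sample")
        copies = pd.read_csv(inputs_dir / "copy_numbers.tsv", sep="\t")
        cands = pd.read_csv(inputs_dir / "candidates.tsv", sep="\t")
        table = quantify.CopyNumberTable(dict(zip(copies["taxon"], copies["copies"])))
        ge, pct = quantify.screen_taxa(
            counts, dict(zip(cands["taxon"], cands["pathway"])), table)
        pct.to_csv(outdir / "taxon_pathway_percent.tsv", sep="\t")
        screen = {"genome_equivalents": ge, "pathway_percent": pct}
    return {"curves": curves, "quants": quants, "screen": screen}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest (also written to manifest.json)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.inputs_dir is None:
        inputs_dir = outdir / "inputs"
        synthfix.write_fixtures(config.synth_config(), inputs_dir)
    else:
        inputs_dir = Path(config.inputs_dir)

    stage_dirs = {name: outdir / name
                  for name in ("refdb", "align", "community", "quantify")}
    manifest: dict = {
        "seed": config.seed,
        "parameters": {
            "coverage_cutoff": config.coverage_cutoff,
            "merge_cutoff": config.merge_cutoff,
            "min_identity_initial": config.thresholds.min_identity_initial,
            "min_identity_downstream": config.thresholds.min_identity_downstream,
            "min_len_aa": config.thresholds.min_len_aa,
            "conservation_threshold": config.conservation_threshold,
            "nmds_k": config.nmds_k,
            "nmds_restarts": config.nmds_restarts,
            "n_samples": config.n_samples,
            "n_reads_per_sample": config.n_reads_per_sample,
        },
        "inputs": {p.name: _sha256(p) for p in sorted(inputs_dir.glob("*"))},
        "stages": [],
    }

    def _record(name: str) -> None:
        manifest["stages"].append({
            "name": name,
            "outputs": {p.name: _sha256(p)
                        for p in sorted(stage_dirs[name].glob("*")) if p.is_file()},
        })

    try:
        curations = stage_refdb(inputs_dir, stage_dirs["refdb"], config.families,
                                config.coverage_cutoff, config.merge_cutoff)
        _record("refdb")
        align_results = stage_align(inputs_dir, stage_dirs["align"], curations,
                                    config.qc, config.thresholds, config.scoring)
        _record("align")
        stage_community(stage_dirs["community"], curations, align_results,
                        config.seed, config.nmds_k, config.nmds_restarts,
                        config.conservation_threshold)
        _record("community")
        stage_quantify(inputs_dir, stage_dirs["quantify"])
        _record("quantify")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        done = {s["name"] for s in manifest["stages"]}
        order = ["refdb", "align", "community", "quantify"]
        current = next(s for s in order if s not in done)
        raise PipelineError(
            f"stage {current} failed ({exc}); re-run with "
            f"`butyragene run --seed {config.seed} --out {outdir}`"
        ) from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
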