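"""End-to-end orchestration: simulate → preprocess → assign → miRNA → QC.

Alignment itself is pluggable: any stage that consumes alignments accepts
either a real SAM/BAM (from an external aligner) or the simulator's truth
BED, so the default path needs no aligner.  A JSON manifest records the
parameters, output hashes and per-stage summaries of each run; identical
configs produce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Union

from . import __version__
from .assign import (
    count_categories,
    count_genes,
    load_alignments,
    summarize_biotypes,
)
from .mirna import quantify_mature, write_mature_counts
from .preprocess import process_fastq, write_stats
from .qc import (
    composition_report,
    gene_body_coverage,
    rpm_tracks,
    write_bedgraph,
    write_profile,
)
from .simulate import SimConfig, build_toy_reference, simulate_library


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def sim_config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    if "class_mix" in d:
        d["class_mix"] = dict(d["class_mix"])
    if "size_window" in d:
        d["size_window"] = tuple(d["size_window"])
    if "tail_length_dist" in d:
        name, params = d["tail_length_dist"]
        d["tail_length_dist"] = (name, dict(params))
    return SimConfig(**d)


def run_pipeline(config: dict, out_dir: Union[str, Path]) -> dict:
    """Run all stages on the toy reference and return the manifest.

    ``config`` keys (all optional): ``seed``, ``simulate`` (SimConfig
    fields), ``preprocess`` (min_tail/min_insert/max_interruptions),
    ``assign`` (strand_mode/min_overlap), ``alignments`` (path to an
    external BAM or BED overriding the truth alignments), ``library_id``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    library_id = config.get("library_id", "toy")
    manifest: dict = {
        "stakit_version": __version__,
        "config": config,
        "stages": {},
        "files": {},
    }

    def record(name: str, path: Path) -> None:
        manifest["files"][name] = {
            "path": path.name,
            "sha256": _sha256(path),
        }

    # -- simulate ----------------------------------------------------------
    try:
        sim_params = dict(config.get("simulate", {}))
        sim_params.setdefault("seed", seed)
        sim_config = sim_config_from_dict(sim_params)
        reference = build_toy_reference(seed)
        ref_paths = reference.write(out_dir / "reference")
        library = simulate_library(reference, sim_config)
        fastq = out_dir / "reads.fastq"
        truth_bed = out_dir / "truth.bed"
        truth_tsv = out_dir / "truth.tsv"
        library.write_fastq(fastq)
        library.write_truth_bed(truth_bed)
        library.write_truth_tsv(truth_tsv)
        library.write_config(out_dir / "sim_config.json")
        for name, p in ref_paths.items():
            record(f"reference.{name}", p)
        for name, p in (("reads", fastq), ("truth_bed", truth_bed), ("truth_tsv", truth_tsv)):
            record(name, p)
        manifest["stages"]["simulate"] = {"n_reads": len(library.reads)}
    except Exception as exc:
        raise PipelineError(f"simulate: {exc}") from exc

    # -- preprocess --------------------------------------------------------
    try:
        pp = config.get("preprocess", {})
        clipped = out_dir / "clipped.fastq"
        stats = process_fastq(
            fastq,
            clipped,
            min_tail=pp.get("min_tail", 9),
            min_insert=pp.get("min_insert", 18),
            max_interruptions=pp.get("max_interruptions", 0),
            library_id=library_id,
        )
        write_stats(stats, out_dir / "preprocess_stats.json")
        record("clipped", clipped)
        manifest["stages"]["preprocess"] = stats.as_dict()
    except Exception as exc:
        raise PipelineError(f"preprocess: {exc}") from exc

    # -- alignments (external BAM/BED or simulated truth) ------------------
    aln_path = config.get("alignments")
    try:
        if aln_path is not None:
            if not Path(aln_path).exists():
                raise FileNotFoundError(aln_path)
            alignments = load_alignments(aln_path)
        else:
            alignments = library.truth_alignments()
        bundle = reference.bundle()
    except Exception as exc:
        raise PipelineError(f"alignments: {exc}") from exc

    # -- assign ------------------------------------------------------------
    try:
        ap = config.get("assign", {})
        strand_mode = ap.get("strand_mode", "forward")
        min_overlap = ap.get("min_overlap", 1)
        category = count_categories(
            alignments, bundle, min_overlap=min_overlap, library_id=library_id
        )
        genes = count_genes(
            alignments, bundle, strand_mode=strand_mode,
            min_overlap=min_overlap, library_id=library_id,
        )
        biotypes = summarize_biotypes(
            alignments, bundle, min_overlap=min_overlap, library_id=library_id
        )
        counts_tsv = out_dir / "gene_counts.tsv"
        genes.as_series().to_csv(counts_tsv, sep="\t", header=["count"],
                                 index_label="gene_id")
        record("gene_counts", counts_tsv)
        manifest["stages"]["assign"] = {
            "categories": category.as_dict(),
            "aligned_total": category.aligned_total,
        }
    except Exception as exc:
        raise PipelineError(f"assign: {exc}") from exc

    # -- mature miRNA ------------------------------------------------------
    try:
        mature = quantify_mature(
            alignments, bundle.mirna_primary, bundle.mirna_mature,
            library_id=library_id,
        )
        mature_tsv = out_dir / "mature_mirna_counts.tsv"
        write_mature_counts(mature, bundle.mirna_mature, mature_tsv)
        record("mature_mirna_counts", mature_tsv)
        manifest["stages"]["mirna"] = {
            "input_reads": mature.input_reads,
            "removed_reads": mature.removed_reads,
            "mature_total": mature.total,
        }
    except Exception as exc:
        raise PipelineError(f"mirna: {exc}") from exc

    # -- qc ----------------------------------------------------------------
    try:
        profile = gene_body_coverage(alignments, reference.transcripts)
        write_profile(profile, out_dir / "gene_body_profile.json")
        track = rpm_tracks(alignments)
        track_paths = write_bedgraph(track, out_dir / library_id)
        report = composition_report(
            library_id=library_id,
            preprocess=stats,
            category=category,
            biotype=biotypes,
            mature=mature,
        )
        (out_dir / "composition_report.json").write_text(
            json.dumps(report, indent=2) + "\n"
        )
        record("gene_body_profile", out_dir / "gene_body_profile.json")
        for p in track_paths:
            record(p.name, p)
        record("composition_report", out_dir / "composition_report.json")
        manifest["stages"]["qc"] = {
            "three_prime_mass": profile.three_prime_mass,
            "n_profile_transcripts": profile.n_transcripts,
        }
    except Exception as exc:
        raise PipelineError(f"qc: {exc}") from exc

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
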