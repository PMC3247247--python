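"""End-to-end pipeline orchestration.

Runs preprocess -> collapse -> annotate -> quantify -> (novel, when a
genome is configured) over one library and writes per-stage TSV
reports plus a summary table of reads per class and conserved/novel
miRNA counts. Two branches exist: a species with a sequenced genome
runs novel discovery; a species without one is annotated against a
close relative's references and skips the novel stage. Re-running
with identical config and inputs produces a bit-identical run
directory.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import annotate as annotate_mod
from . import io_formats, mirna, novel, preprocess, tagging

__all__ = ["PipelineConfig", "ConfigurationError", "InputError", "run_pipeline", "load_config"]


class ConfigurationError(ValueError):
    """Invalid or inconsistent pipeline configuration (exit code 2)."""


class InputError(ValueError):
    """Missing or unreadable input file (exit code 3)."""


class PipelineConfig(BaseModel):
    """All stage parameters; unknown keys are rejected at load time."""

    model_config = ConfigDict(extra="forbid")

    sample_id: str = "sample"
    fastq: str
    out_dir: str = "run"
    quality_offset: int = 33
    quality_cutoff: int = 20
    adapter3: str
    adapter5: Optional[str] = None
    adapter_min_score: float = 5.0
    adapter_min_matches: int = 6
    min_len: int = 17
    max_len: int = 26
    collapse_max_length_diff: int = 2
    collapse_anchor: str = "five_prime"
    conserved_min_reads: int = 2
    novel_min_reads: int = 5
    flank: int = 70
    genome_max_evalue: Optional[float] = 1e-3
    # reference FASTA paths, in classification precedence order
    trna: Optional[str] = None
    rrna: Optional[str] = None
    snrna_snorna: Optional[str] = None
    mirna_mature: Optional[str] = None
    mirna_hairpin: Optional[str] = None
    mrna: Optional[str] = None
    genome: Optional[str] = None
    other_species_tags: Optional[str] = None

    @field_validator("quality_offset")
    @classmethod
    def _offset(cls, v: int) -> int:
        if v not in (33, 64):
            raise ValueError("quality_offset must be 33 or 64")
        return v

    @field_validator("collapse_anchor")
    @classmethod
    def _anchor(cls, v: str) -> str:
        if v not in ("five_prime", "both_ends"):
            raise ValueError("collapse_anchor must be five_prime or both_ends")
        return v


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML key/value configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    try:
        return PipelineConfig(**data)
    except Exception as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc


_REF_FIELDS = (
    ("trna", "tRNA"),
    ("rrna", "rRNA"),
    ("snrna_snorna", "snRNA_snoRNA"),
    ("mirna_mature", "miRNA_mature"),
    ("mirna_hairpin", "miRNA_hairpin"),
    ("mrna", "mRNA"),
    ("genome", "genome"),
)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the pipeline and return the run directory."""
    # validate inputs before any compute
    for field_name in ("fastq",) + tuple(f for f, _ in _REF_FIELDS) + (
        "other_species_tags",
    ):
        value = getattr(config, field_name)
        if value is not None and not Path(value).exists():
            raise InputError(f"input file for {field_name!r} not found: {value}")
    if config.mirna_mature is None:
        raise ConfigurationError(
            "a mature miRNA reference is required (mirna_mature)"
        )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"sample: {config.sample_id}"]

    refsets = []
    for field_name, label in _REF_FIELDS:
        path = getattr(config, field_name)
        if path is not None:
            refsets.append(io_formats.read_fasta(path, label))
    genome_set = next((r for r in refsets if r.class_label == "genome"), None)

    # --- preprocess -------------------------------------------------------
    reads = io_formats.read_fastq(config.fastq, config.quality_offset)
    kept, stats = preprocess.preprocess_library_stats(
        reads,
        adapter3=config.adapter3,
        adapter5=config.adapter5,
        quality_cutoff=config.quality_cutoff,
        min_len=config.min_len,
        max_len=config.max_len,
        min_score=config.adapter_min_score,
        min_matches=config.adapter_min_matches,
    )
    io_formats.write_fastq(kept, out / "trimmed.fastq", config.quality_offset)
    hist = pd.DataFrame(
        sorted(stats.length_histogram.items()), columns=["length", "reads"]
    )
    hist.to_csv(out / "length_histogram.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            ("input_reads", stats.n_input),
            ("discarded_low_quality", stats.n_discarded_quality),
            ("discarded_adapter_dimer", stats.n_discarded_adapter_dimer),
            ("discarded_length", stats.n_discarded_length),
            ("kept_reads", stats.n_kept),
        ],
        columns=["stage", "reads"],
    ).to_csv(out / "preprocess_stats.tsv", sep="\t", index=False)
    log_lines.append(
        f"preprocess: {stats.n_input} reads in, {stats.n_kept} kept "
        f"({stats.n_discarded_quality} low-quality, "
        f"{stats.n_discarded_adapter_dimer} adapter-dimer, "
        f"{stats.n_discarded_length} length-filtered)"
    )

    # --- collapse ---------------------------------------------------------
    tags = tagging.collapse_reads(
        kept,
        max_length_diff=config.collapse_max_length_diff,
        anchor=config.collapse_anchor,
    )
    io_formats.write_tag_fasta(tags, out / "tags.fa")
    pd.DataFrame(
        [(t.tag_id, t.seq, t.count, len(t.members)) for t in tags],
        columns=["tag_id", "representative", "count", "n_members"],
    ).to_csv(out / "tags.tsv", sep="\t", index=False)
    assert sum(t.count for t in tags) == stats.n_kept
    log_lines.append(f"collapse: {len(tags)} tags from {stats.n_kept} reads")

    # --- annotate ---------------------------------------------------------
    params = dict(annotate_mod.DEFAULT_CLASS_PARAMS)
    params["genome"] = annotate_mod.ClassParams(12, 0.80, config.genome_max_evalue)
    annotations, summary = annotate_mod.classify_tags(tags, refsets, params)
    pd.DataFrame(
        [
            (
                a.tag_id,
                a.assigned_class,
                a.best_hit.subject_id if a.best_hit else "",
                a.best_hit.strand if a.best_hit else "",
                f"{a.best_hit.identity:.4f}" if a.best_hit else "",
                f"{a.best_hit.evalue:.3g}" if a.best_hit else "",
            )
            for a in annotations
        ],
        columns=["tag_id", "class", "subject", "strand", "identity", "evalue"],
    ).to_csv(out / "annotations.tsv", sep="\t", index=False)
    summary.to_csv(out / "class_summary.tsv", sep="\t", index=False)
    log_lines.append(
        "annotate: "
        + ", ".join(f"{cls}={reads}" for cls, _, reads in summary.itertuples(index=False))
    )

    # --- quantify conserved miRNAs ---------------------------------------
    mature_db = next(r for r in refsets if r.class_label == "miRNA_mature")
    hairpin_db = next(
        (r for r in refsets if r.class_label == "miRNA_hairpin"), None
    )
    profile = mirna.assign_conserved(
        tags,
        mature_db,
        hairpin_db,
        min_reads=config.conserved_min_reads,
        sample_id=config.sample_id,
    )
    pd.DataFrame(
        [
            (g, c.mature_count, c.star_count, int(c.star_exceeds_mature))
            for g, c in sorted(profile.genes.items())
        ],
        columns=["gene", "mature_reads", "star_reads", "star_exceeds_mature"],
    ).to_csv(out / "profile.tsv", sep="\t", index=False)
    n_conserved = len(profile.expressed_genes())
    log_lines.append(
        f"quantify: {n_conserved} conserved miRNA genes, "
        f"{profile.totals} miRNA-mapped reads"
    )

    # --- novel discovery (genome branch only) -----------------------------
    novel_candidates = []
    if genome_set is not None:
        class_by_tag = {a.tag_id: a.assigned_class for a in annotations}
        unannotated = [
            t
            for t in tags
            if class_by_tag[t.tag_id] in ("genome_unannotated", "unknown")
        ]
        other_tags = (
            io_formats.read_tag_fasta(config.other_species_tags)
            if config.other_species_tags
            else []
        )
        novel_candidates = novel.discover_novel(
            unannotated,
            genome_set,
            known_matures=mature_db,
            other_species_tags=other_tags,
            min_reads=config.novel_min_reads,
            flank=config.flank,
        )
        pd.DataFrame(
            [
                (
                    c.locus.contig,
                    c.locus.start,
                    c.locus.end,
                    c.locus.strand,
                    c.mature_seq,
                    c.structure,
                    c.signature[0],
                    c.signature[1],
                    c.signature[2],
                    f"{c.score:.3f}",
                    ";".join(getattr(c, "seed_matches", [])),
                    int(getattr(c, "present_in_other", False)),
                )
                for c in novel_candidates
            ],
            columns=[
                "contig",
                "start",
                "end",
                "strand",
                "mature",
                "structure",
                "mature_reads",
                "star_reads",
                "loop_reads",
                "score",
                "seed_matches",
                "present_in_other_species",
            ],
        ).to_csv(out / "novel.tsv", sep="\t", index=False)
        log_lines.append(f"novel: {len(novel_candidates)} passing candidates")
    else:
        log_lines.append("novel: skipped (no genome configured)")

    # --- summary ----------------------------------------------------------
    rows = [("total_reads", stats.n_input), ("tags", len(tags))]
    for record in summary.itertuples(index=False):
        rows.append((f"reads_{record[0]}", record.reads))
    rows.append(("conserved_mirnas", n_conserved))
    rows.append(("novel_mirnas", len(novel_candidates)))
    pd.DataFrame(rows, columns=["quantity", "value"]).to_csv(
        out / "summary.tsv", sep="\t", index=False
    )
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
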