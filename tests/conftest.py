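"""Shared fixtures: toy genomes and simulated libraries.

The large library (1e5 reads) is session-scoped so the recovery and
invariant checks share a single pipeline run.
"""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from echinomir import annotate, mirna, novel, preprocess, synthetic, tagging

SIM_GENOME_SEED = 42
SIM_READS_SEED = 43


@pytest.fixture(scope="session")
def toy():
    """A planted toy genome (20 miRNA hairpins, one held out)."""
    genome, truth = synthetic.make_toy_genome(seed=SIM_GENOME_SEED)
    return genome, truth


@dataclass
class PipelineRun:
    genome: object
    truth: object
    n_reads: int
    stats: object
    tags: list
    annotations: list
    summary: object
    profile: object
    novel_candidates: list


def _run(genome, truth, n_reads: int) -> PipelineRun:
    reads = synthetic.simulate_reads(truth, n_reads, seed=SIM_READS_SEED)
    kept, stats = preprocess.preprocess_library_stats(
        reads, truth.adapter3, truth.adapter5
    )
    tags = tagging.collapse_reads(kept)
    refsets = [
        truth.references["tRNA"],
        truth.references["rRNA"],
        truth.references["snRNA_snoRNA"],
        truth.references["miRNA_mature"],
        truth.references["miRNA_hairpin"],
        truth.references["mRNA"],
        genome,
    ]
    annotations, summary = annotate.classify_tags(tags, refsets)
    profile = mirna.assign_conserved(
        tags, truth.references["miRNA_mature"], truth.references["miRNA_hairpin"]
    )
    class_by_tag = {a.tag_id: a.assigned_class for a in annotations}
    unannotated = [
        t for t in tags if class_by_tag[t.tag_id] in ("genome_unannotated", "unknown")
    ]
    candidates = novel.discover_novel(
        unannotated, genome, known_matures=truth.references["miRNA_mature"]
    )
    return PipelineRun(
        genome, truth, n_reads, stats, tags, annotations, summary, profile, candidates
    )


@pytest.fixture(scope="session")
def run100k(toy):
    """Full pipeline over a 1e5-read simulated library."""
    genome, truth = toy
    return _run(genome, truth, 100_000)
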