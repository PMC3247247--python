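"""Ground-truthed toy genomes and small-RNA libraries.

The generator emulates an Illumina GA era 36-cycle small-RNA run on an
embryonic library: each read is a short insert (miRNA inserts peak at
22 nt; degradation fragments of tRNA/rRNA/mRNA and genomic background
are 17-26 nt) followed by the 3' sequencing adapter, with per-cycle
mean quality decaying toward the 3' end and substitution errors
weighted toward the low-quality cycles. The planted class mixture
follows the composition reported for urchin embryos in the 17-26 nt
window: 14% miRNA, 10% other non-coding RNA (split 9.6 rRNA / 0.2
tRNA / 0.2 snRNA-snoRNA), 25% mRNA degradation, 13% unannotated
genomic, 38% unmappable. One planted miRNA hairpin is held out of the
mature/hairpin references so that the novel-discovery stage has a
known target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .io_formats import Read, ReferenceSet, reverse_complement, write_fasta, write_fastq

__all__ = [
    "SimTruth",
    "make_toy_genome",
    "simulate_reads",
    "DEFAULT_MIXTURE",
    "ADAPTER_3P",
    "ADAPTER_5P",
]

# Illumina v1.5-style small-RNA adapters
ADAPTER_3P = "TCGTATGCCGTCTTCTGCTTG"
ADAPTER_5P = "GTTCAGAGTTCTACAGTCCGACGATC"

DEFAULT_MIXTURE = {
    "miRNA": 0.14,
    "rRNA": 0.096,
    "tRNA": 0.002,
    "snRNA_snoRNA": 0.002,
    "mRNA": 0.25,
    "genome_unannotated": 0.13,
    "unknown": 0.38,
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class PlantedMirna:
    gene: str
    mature: str
    star: str
    hairpin: str
    arm: str  # arm carrying the mature species: '5p' or '3p'
    strand: str
    start: int  # hairpin start on the forward strand
    end: int
    mature_ext: str  # next transcript-orientation base after the mature 3' end
    held_out: bool = False


@dataclass
class SimTruth:
    """Everything the generator planted, for downstream verification."""

    seed: int
    contig_id: str
    genome: ReferenceSet
    mirnas: list[PlantedMirna]
    references: dict[str, ReferenceSet]
    expression: dict[str, float]  # gene -> fraction of miRNA-class reads
    mixture: dict[str, float]
    adapter3: str = ADAPTER_3P
    adapter5: str = ADAPTER_5P
    planted_intervals: list[tuple[int, int]] = field(default_factory=list)

    @property
    def held_out_gene(self) -> PlantedMirna:
        return next(m for m in self.mirnas if m.held_out)

    def expressed_conserved_genes(self) -> list[str]:
        return [
            m.gene
            for m in self.mirnas
            if not m.held_out and self.expression[m.gene] > 0
        ]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def make_toy_genome(
    n_mirna: int = 20,
    n_trna: int = 5,
    n_rrna: int = 3,
    contig_len: int = 100_000,
    seed: int = 0,
    n_snrna: int = 2,
    n_mrna: int = 4,
    spacing: int = 50,
) -> tuple[ReferenceSet, SimTruth]:
    """Build a single-contig toy genome with planted small-RNA genes.

    Plants ``n_mirna`` miRNA hairpins (22-nt mature, 8-12 nt loop,
    perfectly base-paired stem, random arm and strand), plus tRNA-,
    rRNA-, snRNA- and mRNA-like genes, each separated by at least
    ``spacing`` nt of random background. The last miRNA is held out of
    the mature/hairpin reference sets to exercise novel discovery.
    Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    lengths = (
        [("miRNA", None)] * n_mirna
        + [("tRNA", 72)] * n_trna
        + [("rRNA", 120)] * n_rrna
        + [("snRNA_snoRNA", 100)] * n_snrna
        + [("mRNA", 500)] * n_mrna
    )

    elements: list[tuple[str, str]] = []  # (class, planted forward-strand seq)
    mirnas: list[PlantedMirna] = []
    per_class: dict[str, list[tuple[str, str]]] = {
        "tRNA": [],
        "rRNA": [],
        "snRNA_snoRNA": [],
        "mRNA": [],
    }
    counters = {k: 0 for k in ("miRNA", "tRNA", "rRNA", "snRNA_snoRNA", "mRNA")}
    for cls, length in lengths:
        counters[cls] += 1
        if cls == "miRNA":
            gene = f"mir-{counters[cls]:03d}"
            mature = _random_seq(rng, 22)
            loop = _random_seq(rng, int(rng.integers(8, 13)))
            arm = "5p" if rng.random() < 0.5 else "3p"
            if arm == "5p":
                hairpin = mature + loop + reverse_complement(mature)
            else:
                hairpin = reverse_complement(mature) + loop + mature
            strand = "+" if rng.random() < 0.5 else "-"
            planted = hairpin if strand == "+" else reverse_complement(hairpin)
            elements.append((cls, planted))
            mirnas.append(
                PlantedMirna(
                    gene=gene,
                    mature=mature,
                    star=reverse_complement(mature),
                    hairpin=hairpin,
                    arm=arm,
                    strand=strand,
                    start=-1,
                    end=-1,
                    mature_ext="",
                    held_out=(counters[cls] == n_mirna),
                )
            )
        else:
            name = f"{cls.lower()}-{counters[cls]}"
            seq = _random_seq(rng, length)
            elements.append((cls, seq))
            per_class[cls].append((name, seq))

    total_planted = sum(len(seq) for _, seq in elements)
    min_needed = total_planted + spacing * (len(elements) + 1)
    if min_needed > contig_len:
        raise ValueError(
            f"contig of {contig_len} nt cannot hold {len(elements)} elements "
            f"({min_needed} nt needed with {spacing} nt spacing)"
        )

    # spread elements across the contig with random gaps >= spacing
    slack = contig_len - total_planted - spacing * (len(elements) + 1)
    cuts = np.sort(rng.integers(0, slack + 1, size=len(elements)))
    extra = np.diff(np.concatenate(([0], cuts)))
    parts: list[str] = []
    pos = 0
    intervals: list[tuple[int, int]] = []
    mirna_idx = 0
    for k, (cls, seq) in enumerate(elements):
        gap = spacing + int(extra[k])
        parts.append(_random_seq(rng, gap))
        pos += gap
        parts.append(seq)
        intervals.append((pos, pos + len(seq)))
        if cls == "miRNA":
            m = mirnas[mirna_idx]
            m.start, m.end = pos, pos + len(seq)
            mirna_idx += 1
        pos += len(seq)
    parts.append(_random_seq(rng, contig_len - pos))
    contig = "".join(parts)
    assert len(contig) == contig_len

    for m in mirnas:
        # transcript-orientation base just 3' of the mature end, used for
        # +1 nt isoforms; always defined because the mature sits inside
        # the hairpin (5p arm) or the hairpin is followed by background
        if m.arm == "5p":
            m.mature_ext = m.hairpin[22]
        else:
            if m.strand == "+":
                m.mature_ext = contig[m.end] if m.end < contig_len else "A"
            else:
                m.mature_ext = (
                    reverse_complement(contig[m.start - 1]) if m.start > 0 else "A"
                )

    genome = ReferenceSet("genome", [("contig1", contig)])
    references = {
        "tRNA": ReferenceSet("tRNA", per_class["tRNA"]),
        "rRNA": ReferenceSet("rRNA", per_class["rRNA"]),
        "snRNA_snoRNA": ReferenceSet("snRNA_snoRNA", per_class["snRNA_snoRNA"]),
        "mRNA": ReferenceSet("mRNA", per_class["mRNA"]),
        "miRNA_mature": ReferenceSet(
            "miRNA_mature",
            [(m.gene, m.mature) for m in mirnas if not m.held_out],
        ),
        "miRNA_hairpin": ReferenceSet(
            "miRNA_hairpin",
            [(m.gene, m.hairpin) for m in mirnas if not m.held_out],
        ),
    }

    # per-gene expression: log-uniform over two decades, normalised; the
    # held-out (novel) gene is pinned at 1.5% of the miRNA class, the
    # conserved:novel read ratio typical of an embryonic library
    HELD_OUT_FRACTION = 0.015
    weights = 10.0 ** rng.uniform(0.0, 2.0, size=n_mirna)
    conserved = [i for i, m in enumerate(mirnas) if not m.held_out]
    weights[[m.held_out for m in mirnas]] = 0.0
    weights[conserved] *= (1.0 - HELD_OUT_FRACTION) / weights[conserved].sum()
    for i, m in enumerate(mirnas):
        if m.held_out:
            weights[i] = HELD_OUT_FRACTION
    expression = {m.gene: float(w) for m, w in zip(mirnas, weights)}

    truth = SimTruth(
        seed=seed,
        contig_id="contig1",
        genome=genome,
        mirnas=mirnas,
        references=references,
        expression=expression,
        mixture=dict(DEFAULT_MIXTURE),
        planted_intervals=intervals,
    )
    return genome, truth


def default_quality_profile(read_len: int = 36) -> np.ndarray:
    """Mean Phred per cycle: 38 at cycle 1 decaying linearly to 18."""
    return np.linspace(38.0, 18.0, read_len)


def simulate_reads(
    truth: SimTruth,
    n_reads: int,
    read_len: int = 36,
    adapter3: Optional[str] = None,
    quality_profile: Optional[np.ndarray] = None,
    seed: int = 0,
    error_rate: float = 0.002,
    five_prime_adapter_rate: float = 0.01,
    star_fraction: float = 0.08,
    quality_sd: float = 3.0,
) -> list[Read]:
    """Simulate a 36-cycle library from a planted truth.

    Inserts are drawn per the class mixture; miRNA inserts are the
    planted matures with 3' length variation (21/22/23 nt at
    0.15/0.70/0.15) and an optional star species at ``star_fraction``;
    degradation fragments are uniform 17-26 nt substrings of the
    planted tRNA/rRNA/mRNA genes; genomic fragments come from
    background regions only; unknown inserts are random sequence.
    Substitution errors occur at ``error_rate`` per base on average,
    weighted toward low-quality cycles. Deterministic given the seed.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    rng = np.random.default_rng(seed)
    adapter3 = adapter3 or truth.adapter3
    profile = (
        np.asarray(quality_profile, dtype=float)
        if quality_profile is not None
        else default_quality_profile(read_len)
    )
    if len(profile) != read_len:
        raise ValueError("quality profile length must equal read length")

    classes = list(truth.mixture)
    probs = np.array([truth.mixture[c] for c in classes])
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("mixture proportions must sum to 1")
    class_draw = rng.choice(len(classes), size=n_reads, p=probs)

    genes = [m.gene for m in truth.mirnas]
    gene_w = np.array([truth.expression[g] for g in genes])
    gene_w = gene_w / gene_w.sum()
    by_gene = {m.gene: m for m in truth.mirnas}
    contig = truth.genome.records[0][1]
    contig_len = len(contig)
    planted = sorted(truth.planted_intervals)

    def background_fragment(length: int) -> str:
        while True:
            start = int(rng.integers(0, contig_len - length + 1))
            end = start + length
            if all(end <= s or start >= e for s, e in planted):
                frag = contig[start:end]
                return frag if rng.random() < 0.5 else reverse_complement(frag)

    frag_sources = {
        cls: truth.references[cls].records
        for cls in ("tRNA", "rRNA", "snRNA_snoRNA", "mRNA")
    }

    # batched qualities and per-cycle error weighting
    quals = rng.normal(profile, quality_sd, size=(n_reads, read_len))
    quals = np.clip(np.rint(quals), 2, 40).astype(int)
    miscall = 10.0 ** (-profile / 10.0)
    per_cycle = error_rate * miscall / miscall.mean()
    error_mask = rng.random((n_reads, read_len)) < per_cycle
    error_shift = rng.integers(1, 4, size=(n_reads, read_len))
    with_5p = rng.random(n_reads) < five_prime_adapter_rate

    reads: list[Read] = []
    for i in range(n_reads):
        cls = classes[class_draw[i]]
        if cls == "miRNA":
            gene = genes[int(rng.choice(len(genes), p=gene_w))]
            m = by_gene[gene]
            if rng.random() < star_fraction:
                insert = m.star
            else:
                u = rng.random()
                if u < 0.15:
                    insert = m.mature[:-1]
                elif u < 0.85:
                    insert = m.mature
                else:
                    insert = m.mature + m.mature_ext
        elif cls in frag_sources:
            records = frag_sources[cls]
            _, src = records[int(rng.integers(0, len(records)))]
            length = int(rng.integers(17, 27))
            start = int(rng.integers(0, len(src) - length + 1))
            insert = src[start : start + length]
        elif cls == "genome_unannotated":
            insert = background_fragment(int(rng.integers(17, 27)))
        else:  # unknown
            insert = _random_seq(rng, int(rng.integers(17, 27)))

        if with_5p[i]:
            plen = int(rng.integers(10, len(truth.adapter5) + 1))
            raw = truth.adapter5[-plen:] + insert + adapter3
        else:
            raw = insert + adapter3
        raw = (raw + _random_seq(rng, max(0, read_len - len(raw))))[:read_len]

        seq = np.frombuffer(raw.encode(), dtype=np.uint8).copy()
        errs = np.nonzero(error_mask[i])[0]
        for pos in errs:
            base_idx = int(np.where(_BASES == seq[pos])[0][0]) if seq[pos] in _BASES else 0
            seq[pos] = _BASES[(base_idx + error_shift[i, pos]) % 4]
        reads.append(Read(f"read{i + 1}", seq.tobytes().decode(), tuple(quals[i])))
    return reads


def export_truth(truth: SimTruth, out_dir: str | Path) -> dict[str, Path]:
    """Write genome + per-class reference FASTAs and a truth TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    gpath = out / "genome.fa"
    write_fasta(truth.genome.records, gpath)
    paths["genome"] = gpath
    for cls, refset in truth.references.items():
        p = out / f"{cls.lower()}.fa"
        write_fasta(refset.records, p)
        paths[cls] = p
    tpath = out / "truth.tsv"
    with open(tpath, "w") as fh:
        fh.write("gene\tmature\tarm\tstrand\tstart\tend\texpression\theld_out\n")
        for m in truth.mirnas:
            fh.write(
                f"{m.gene}\t{m.mature}\t{m.arm}\t{m.strand}\t{m.start}\t{m.end}\t"
                f"{truth.expression[m.gene]:.6g}\t{int(m.held_out)}\n"
            )
    paths["truth"] = tpath
    return paths
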