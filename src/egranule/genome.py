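"""Toy annotated genomes with ground-truth siRNA dependence classes.

Everything downstream of the simulator — read mapping, per-gene 22G counts,
class calls, metagene profiles — needs a coordinate frame.  This module
builds small random genomes in which every gene is a single-exon,
non-overlapping interval carrying three hidden attributes used as ground
truth:

* a **biotype** (``germline_coding``, ``soma_coding``, one of the structural
  RNA categories, ``miRNA`` or ``piRNA_21U``), which drives the filtering
  and normalization rules of the quantification stage;
* a **truth class** for germline coding genes — ``E`` (antisense 22G RNAs
  depend on the E granule factors EGC-1/ELLI-1), ``M`` (depend on the
  Mutator focus, i.e. MUT-16), ``UP`` (siRNAs amplified when E granules are
  lost) or ``NEUTRAL``;
* a **base rate**, the relative wild-type 22G synthesis rate of the gene.

Genomes serialize to plain FASTA + GFF3 and round-trip losslessly, so every
pipeline stage can also be exercised from files on disk.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GERMLINE = "germline_coding"
SOMA = "soma_coding"
STRUCTURAL_BIOTYPES = frozenset({"rRNA", "tRNA", "snRNA", "snoRNA", "ncRNA"})
FILTERED_BIOTYPES = frozenset({"miRNA", "piRNA_21U"})
CODING_BIOTYPES = frozenset({GERMLINE, SOMA})
ALL_BIOTYPES = CODING_BIOTYPES | STRUCTURAL_BIOTYPES | FILTERED_BIOTYPES
TRUTH_CLASSES = ("E", "M", "UP", "NEUTRAL")

_ID_PREFIX = {
    GERMLINE: "glg",
    SOMA: "som",
    "rRNA": "rrn",
    "tRNA": "trn",
    "snRNA": "snr",
    "snoRNA": "sno",
    "ncRNA": "ncr",
    "miRNA": "mir",
    "piRNA_21U": "p21",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T}."""
    return seq.translate(_COMPLEMENT)[::-1]


def largest_remainder(fractions: Mapping[str, float], n: int) -> dict[str, int]:
    """Partition ``n`` items into integer counts proportional to ``fractions``.

    Deterministic: ties in the fractional remainders are broken by key order.
    """
    keys = list(fractions)
    total = float(sum(fractions.values()))
    if total <= 0:
        raise ValueError("fractions must sum to a positive value")
    raw = {k: n * fractions[k] / total for k in keys}
    counts = {k: int(np.floor(raw[k])) for k in keys}
    short = n - sum(counts.values())
    order = sorted(keys, key=lambda k: (-(raw[k] - counts[k]), keys.index(k)))
    for k in order[:short]:
        counts[k] += 1
    return counts


@dataclass(frozen=True)
class GeneRecord:
    """One single-exon gene model (0-based, half-open coordinates)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str  # '+' or '-'
    biotype: str
    truth_class: str = "NA"  # E/M/UP/NEUTRAL for germline coding genes, else NA
    base_rate: float = 0.0   # relative WT 22G synthesis rate (coding genes)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenomeConfig:
    """Study conditions for :func:`make_genome`.

    Defaults describe the demo panel used throughout: 120 germline genes
    split 30:30:15:45 into E/M/UP/NEUTRAL truth classes, a small soma set,
    structural RNA loci exercising the normalization rules, and miRNA/21U
    loci exercising the biotype exclusions.
    """

    n_germline_genes: int = 120
    n_soma_genes: int = 10
    n_structural: Mapping[str, int] = field(
        default_factory=lambda: {"rRNA": 4, "tRNA": 4, "snRNA": 3, "snoRNA": 3, "ncRNA": 4}
    )
    n_mirna: int = 6
    n_21u: int = 6
    gene_length_range: tuple[int, int] = (200, 400)
    chrom_length: int = 120_000
    chrom_name: str = "chrI"
    min_spacing: int = 50
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"E": 0.25, "M": 0.25, "UP": 0.125, "NEUTRAL": 0.375}
    )
    # WT base rates of UP-class genes are scaled down by this factor: the
    # up-regulated set has near-zero wild-type signal (sid-1/rde-11-like).
    up_rate_scale: float = 0.1
    seed: int = 0

    def validate(self) -> list[str]:
        """Return a list of human-readable invariant violations (empty if valid)."""
        problems: list[str] = []
        counts = {
            "n_germline_genes": self.n_germline_genes,
            "n_soma_genes": self.n_soma_genes,
            "n_mirna": self.n_mirna,
            "n_21u": self.n_21u,
        }
        for name, v in counts.items():
            if v < 0:
                problems.append(f"{name} must be >= 0, got {v}")
        for cat, v in self.n_structural.items():
            if cat not in STRUCTURAL_BIOTYPES:
                problems.append(f"unknown structural category {cat!r}")
            if v < 0:
                problems.append(f"n_structural[{cat!r}] must be >= 0, got {v}")
        lo, hi = self.gene_length_range
        if lo < 100:
            problems.append(f"gene_length_range min must be >= 100 nt, got {lo}")
        if hi < lo:
            problems.append("gene_length_range max must be >= min")
        if set(self.class_fractions) - set(TRUTH_CLASSES):
            problems.append("class_fractions keys must be a subset of E/M/UP/NEUTRAL")
        if self.min_spacing < 0:
            problems.append("min_spacing must be >= 0")
        if self.up_rate_scale <= 0:
            problems.append("up_rate_scale must be > 0")
        # worst-case packing check: every gene at max length plus max gap
        n_genes = self.total_genes
        worst = n_genes * (hi + self.min_spacing + 100)
        if worst > self.chrom_length:
            problems.append(
                f"total gene span may exceed chrom_length ({worst} > {self.chrom_length})"
            )
        return problems

    @property
    def total_genes(self) -> int:
        return (
            self.n_germline_genes
            + self.n_soma_genes
            + sum(self.n_structural.values())
            + self.n_mirna
            + self.n_21u
        )


class AnnotatedGenome:
    """Chromosome sequences plus annotated gene records.

    The object is the in-memory hub shared by simulation and
    quantification; :meth:`transcript` yields the sense mRNA/ncRNA sequence
    of a gene in its 5'->3' orientation regardless of genomic strand.
    """

    def __init__(self, chromosomes: Mapping[str, str], genes: Sequence[GeneRecord]):
        self.chromosomes = dict(chromosomes)
        self.genes = list(genes)
        self._by_id = {g.gene_id: g for g in self.genes}
        if len(self._by_id) != len(self.genes):
            raise ValueError("gene_ids are not unique")
        self._check_invariants()

    def _check_invariants(self) -> None:
        by_chrom: dict[str, list[GeneRecord]] = {}
        for g in self.genes:
            if g.chrom not in self.chromosomes:
                raise ValueError(f"{g.gene_id}: unknown chromosome {g.chrom!r}")
            if not (0 <= g.start < g.end <= len(self.chromosomes[g.chrom])):
                raise ValueError(f"{g.gene_id}: coordinates out of bounds")
            if g.strand not in "+-":
                raise ValueError(f"{g.gene_id}: bad strand {g.strand!r}")
            if g.biotype not in ALL_BIOTYPES:
                raise ValueError(f"{g.gene_id}: unknown biotype {g.biotype!r}")
            if g.truth_class != "NA" and g.biotype != GERMLINE:
                raise ValueError(f"{g.gene_id}: truth_class set on non-germline gene")
            by_chrom.setdefault(g.chrom, []).append(g)
        for recs in by_chrom.values():
            recs = sorted(recs, key=lambda g: g.start)
            for a, b in zip(recs, recs[1:]):
                if b.start < a.end:
                    raise ValueError(f"genes {a.gene_id} and {b.gene_id} overlap")

    # -- access -----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.genes)

    def gene(self, gene_id: str) -> GeneRecord:
        return self._by_id[gene_id]

    def transcript(self, gene_id: str) -> str:
        g = self._by_id[gene_id]
        seq = self.chromosomes[g.chrom][g.start:g.end]
        return seq if g.strand == "+" else revcomp(seq)

    def genes_with_biotype(self, *biotypes: str) -> list[GeneRecord]:
        want = set(biotypes)
        return [g for g in self.genes if g.biotype in want]

    def truth_genes(self, truth_class: str) -> list[str]:
        return [g.gene_id for g in self.genes if g.truth_class == truth_class]

    # -- serialization ----------------------------------------------------
    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in sorted(self.chromosomes.items())
        ]
        SeqIO.write(records, str(path), "fasta")

    def to_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in sorted(self.genes, key=lambda g: (g.chrom, g.start)):
                attrs = (
                    f"ID={g.gene_id};biotype={g.biotype};"
                    f"truth_class={g.truth_class};base_rate={g.base_rate!r}"
                )
                fh.write(
                    f"{g.chrom}\tegranule_sim\tgene\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )

    @classmethod
    def from_files(cls, fasta: str | Path, gff3: str | Path) -> "AnnotatedGenome":
        chromosomes = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}
        genes: list[GeneRecord] = []
        with open(gff3) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                cols = line.rstrip("\n").split("\t")
                if len(cols) != 9 or cols[2] != "gene":
                    continue
                attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
                genes.append(
                    GeneRecord(
                        gene_id=attrs["ID"],
                        chrom=cols[0],
                        start=int(cols[3]) - 1,
                        end=int(cols[4]),
                        strand=cols[6],
                        biotype=attrs.get("biotype", GERMLINE),
                        truth_class=attrs.get("truth_class", "NA"),
                        base_rate=float(attrs.get("base_rate", 0.0)),
                    )
                )
        return cls(chromosomes, genes)


def make_genome(config: GenomeConfig) -> AnnotatedGenome:
    """Build a random annotated genome under ``config``.

    Deterministic for a fixed ``config.seed``.  Genes are placed
    sequentially along the chromosome in a seeded random order with gaps of
    at least ``min_spacing`` nt (so antisense read assignment is never
    ambiguous); a :class:`ValueError` is raised if the requested genes do
    not fit.
    """
    problems = config.validate()
    if problems:
        raise ValueError("invalid GenomeConfig: " + "; ".join(problems))
    rng = np.random.default_rng(config.seed)

    biotypes: list[str] = (
        [GERMLINE] * config.n_germline_genes
        + [SOMA] * config.n_soma_genes
        + [b for b, n in sorted(config.n_structural.items()) for _ in range(n)]
        + ["miRNA"] * config.n_mirna
        + ["piRNA_21U"] * config.n_21u
    )
    n_genes = len(biotypes)

    # truth classes for germline genes: exact largest-remainder counts,
    # assigned in a seeded random order
    class_counts = largest_remainder(config.class_fractions, config.n_germline_genes)
    class_labels = [c for c in TRUTH_CLASSES for _ in range(class_counts.get(c, 0))]
    class_labels = [class_labels[i] for i in rng.permutation(len(class_labels))]

    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=n_genes)
    order = rng.permutation(n_genes)
    gaps = rng.integers(config.min_spacing, config.min_spacing + 101, size=n_genes)
    strands = rng.choice(np.array(["+", "-"]), size=n_genes)
    rates = rng.gamma(2.0, 1.0, size=n_genes) + 0.2

    chrom_seq = "".join(rng.choice(np.array(list("ACGT")), size=config.chrom_length))

    genes: list[GeneRecord] = []
    counters: dict[str, int] = {}
    germline_seen = 0
    cursor = 0
    for slot, idx in enumerate(order):
        biotype = biotypes[idx]
        start = cursor + int(gaps[slot])
        end = start + int(lengths[idx])
        if end > config.chrom_length:
            raise ValueError(
                f"cannot place {n_genes} genes without overlap in {config.chrom_length} nt"
            )
        counters[biotype] = counters.get(biotype, 0) + 1
        gene_id = f"{_ID_PREFIX[biotype]}-{counters[biotype]:04d}"
        truth = "NA"
        rate = 0.0
        if biotype == GERMLINE:
            truth = class_labels[germline_seen]
            germline_seen += 1
            rate = float(rates[idx])
            if truth == "UP":
                rate *= config.up_rate_scale
        elif biotype == SOMA:
            rate = float(rates[idx])
        genes.append(
            GeneRecord(
                gene_id=gene_id,
                chrom=config.chrom_name,
                start=start,
                end=end,
                strand=str(strands[idx]),
                biotype=biotype,
                truth_class=truth,
                base_rate=rate,
            )
        )
        cursor = end
    return AnnotatedGenome({config.chrom_name: chrom_seq}, genes)
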