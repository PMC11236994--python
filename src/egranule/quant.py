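"""Small-RNA quantification: cleaning, exact-match mapping, 22G counting.

This stage turns a raw library into normalized, strand-aware per-gene and
per-position antisense 22G counts.  Two normalization denominators are
tracked throughout:

* **quantification RPM** — reads per million *total genome mappers minus
  sense rRNA reads* (5S/5.8S/18S/26S-style degradation fragments are
  subtracted from the denominator);
* **metagene RPM** — reads per million "nonstructural" mappers: 18-26 nt
  reads none of whose hits land on structural biotypes
  (rRNA/tRNA/snRNA/snoRNA/ncRNA).

Mapping is full-length exact matching against both strands of every
annotated transcript (a deliberate, reproducible stand-in for a short-read
aligner at toy scale): a read hitting n loci receives weight 1/n at each.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import (
    FILTERED_BIOTYPES,
    SOMA,
    STRUCTURAL_BIOTYPES,
    AnnotatedGenome,
    revcomp,
)
from .simulate import DEFAULT_ADAPTER3, PRIMER_G, Read, ReadSet

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class CleaningParams:
    """Adapter trimming and length-filter settings.

    The quantification stage keeps 17-30 nt clean reads; the metagene
    stage keeps 18-26 nt (use :meth:`metagene`).
    """

    adapter3: str = DEFAULT_ADAPTER3
    adapter5: str = PRIMER_G
    min_len: int = 17
    max_len: int = 30
    discard_untrimmed: bool = True
    min_adapter_overlap: int = 8

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if not self.adapter3:
            raise ValueError("adapter3 must be non-empty")
        if self.min_adapter_overlap < 1:
            raise ValueError("min_adapter_overlap must be >= 1")

    @classmethod
    def metagene(cls, **overrides) -> "CleaningParams":
        return cls(**{"min_len": 18, "max_len": 26, **overrides})


def _trim3(seq: str, adapter: str, min_overlap: int) -> str | None:
    """Cut at the longest prefix of ``adapter`` (>= ``min_overlap`` nt) found
    in ``seq``; None when no adapter hit."""
    for k in range(min(len(adapter), len(seq)), min_overlap - 1, -1):
        idx = seq.find(adapter[:k])
        if idx >= 0:
            return seq[:idx]
    return None


def _trim5(seq: str, adapter: str, min_overlap: int) -> str:
    """Remove a leading 5' adapter remnant: the longest suffix of ``adapter``
    (>= ``min_overlap`` nt) found in ``seq`` and everything before it."""
    for k in range(min(len(adapter), len(seq)), min_overlap - 1, -1):
        idx = seq.find(adapter[-k:])
        if idx >= 0:
            return seq[idx + k :]
    return seq


def clean_reads(raw: ReadSet, params: CleaningParams = CleaningParams()) -> ReadSet:
    """Trim adapters and length-filter a raw library.

    Reads without a 3' adapter hit are dropped when
    ``params.discard_untrimmed``; survivors are filtered to
    ``[min_len, max_len]``.  Empty input yields empty output.
    """
    kept: list[Read] = []
    for r in raw.reads:
        seq = _trim3(r.sequence, params.adapter3, params.min_adapter_overlap)
        if seq is None:
            if params.discard_untrimmed:
                continue
            seq = r.sequence
        if params.adapter5:
            seq = _trim5(seq, params.adapter5, params.min_adapter_overlap)
        if params.min_len <= len(seq) <= params.max_len:
            kept.append(replace(r, sequence=seq))
    return ReadSet(kept, raw.genotype, raw.seed, raw.adapter3)


def is_22g(read: str | Read, strict: bool = False) -> bool:
    """Is this read a 22G RNA?

    Strict: exactly 22 nt with a 5' G.  Relaxed (the counting default):
    21-23 nt with a 5' G.
    """
    seq = read.sequence if isinstance(read, Read) else read
    if not seq:
        raise ValueError("empty read")
    if seq[0] != "G":
        return False
    return len(seq) == 22 if strict else 21 <= len(seq) <= 23


@dataclass(frozen=True)
class MappedHit:
    """One exact full-length alignment of a read to a transcript.

    ``offset`` follows the 5'-most-base convention: the distance from the
    transcript 5' end to the transcript position under the read's 5'-most
    base (for antisense hits that is the *rightmost* base of the aligned
    span).  ``span_start``/``span_end`` give the aligned interval in
    transcript coordinates (0-based, half-open) for coverage.
    """

    read_id: str
    gene_id: str
    offset: int
    span_start: int
    span_end: int
    orientation: str  # 'sense' | 'antisense'
    weight: float
    length: int
    first_base: str


@dataclass
class NormalizationStats:
    """Library-level tallies feeding the two RPM denominators."""

    total_genome_mappers: int = 0
    sense_rRNA_reads: float = 0.0
    nonstructural_mappers: int = 0

    @property
    def denom_quant(self) -> float:
        return self.total_genome_mappers - self.sense_rRNA_reads

    @property
    def denom_meta(self) -> float:
        return float(self.nonstructural_mappers)

    def validate(self) -> None:
        if self.sense_rRNA_reads > self.total_genome_mappers + 1e-9:
            raise ValueError("sense rRNA reads exceed total mappers")
        if self.nonstructural_mappers > self.total_genome_mappers:
            raise ValueError("nonstructural mappers exceed total mappers")
        if self.denom_quant <= 0:
            raise ValueError("quantification denominator must be > 0")


class TranscriptIndex:
    """Seed-and-verify exact-match index over both strands of each transcript."""

    def __init__(self, genome: AnnotatedGenome, k: int = 12):
        self.genome = genome
        self.k = k
        self.strands: dict[tuple[str, str], str] = {}
        self.index: dict[str, list[tuple[str, str, int]]] = {}
        for g in genome.genes:
            t = genome.transcript(g.gene_id)
            for orientation, seq in (("sense", t), ("antisense", revcomp(t))):
                self.strands[(g.gene_id, orientation)] = seq
                for pos in range(len(seq) - k + 1):
                    self.index.setdefault(seq[pos : pos + k], []).append(
                        (g.gene_id, orientation, pos)
                    )

    def hits(self, seq: str) -> list[tuple[str, str, int]]:
        """All (gene_id, orientation, position-on-indexed-strand) exact matches."""
        L = len(seq)
        if L < self.k:
            return []
        out = []
        for gene_id, orientation, pos in self.index.get(seq[: self.k], ()):
            if self.strands[(gene_id, orientation)][pos : pos + L] == seq:
                out.append((gene_id, orientation, pos))
        return out


def map_reads(
    reads: ReadSet,
    genome: AnnotatedGenome,
    index: TranscriptIndex | None = None,
) -> tuple[list[MappedHit], NormalizationStats]:
    """Map cleaned reads by full-length exact match; tally normalization stats.

    Multi-mapping reads get fractional weight 1/n at each locus.  Raises on
    reads containing characters outside {A,C,G,T}.
    """
    if index is None:
        index = TranscriptIndex(genome)
    biotype = {g.gene_id: g.biotype for g in genome.genes}
    tlen = {g.gene_id: g.length for g in genome.genes}
    hits: list[MappedHit] = []
    stats = NormalizationStats()
    for r in reads.reads:
        if set(r.sequence) - _VALID_BASES:
            raise ValueError(f"read {r.read_id} contains non-ACGT characters")
        raw_hits = index.hits(r.sequence)
        if not raw_hits:
            continue
        stats.total_genome_mappers += 1
        w = 1.0 / len(raw_hits)
        L = len(r.sequence)
        all_nonstructural = True
        for gene_id, orientation, pos in raw_hits:
            if orientation == "sense":
                span_start, offset = pos, pos
            else:
                T = tlen[gene_id]
                span_start = T - pos - L
                offset = T - pos - 1
            bt = biotype[gene_id]
            if bt in STRUCTURAL_BIOTYPES:
                all_nonstructural = False
            if bt == "rRNA" and orientation == "sense":
                stats.sense_rRNA_reads += w
            hits.append(
                MappedHit(
                    read_id=r.read_id,
                    gene_id=gene_id,
                    offset=offset,
                    span_start=span_start,
                    span_end=span_start + L,
                    orientation=orientation,
                    weight=w,
                    length=L,
                    first_base=r.sequence[0],
                )
            )
        if 18 <= L <= 26 and all_nonstructural:
            stats.nonstructural_mappers += 1
    return hits, stats


def brute_force_hits(read: str, genome: AnnotatedGenome) -> set[tuple[str, str, int]]:
    """Independent oracle: naive scan of every transcript substring.

    Returns {(gene_id, orientation, transcript span_start)}.
    """
    out: set[tuple[str, str, int]] = set()
    L = len(read)
    for g in genome.genes:
        t = genome.transcript(g.gene_id)
        for s in range(len(t) - L + 1):
            sub = t[s : s + L]
            if sub == read:
                out.add((g.gene_id, "sense", s))
            if revcomp(sub) == read:
                out.add((g.gene_id, "antisense", s))
    return out


@dataclass
class GeneCountTable:
    """Per-gene weighted antisense 22G counts with both RPM normalizations.

    ``table`` columns: biotype, truth_class, raw, rpm, rpm_meta,
    excluded_biotype, soma_specific.  ``coverage`` holds raw per-base
    antisense coverage (18-26 nt reads, full aligned span, weighted) in
    transcript coordinates per gene.
    """

    table: pd.DataFrame
    coverage: dict[str, np.ndarray]
    stats: NormalizationStats

    def rpm(self) -> pd.Series:
        return self.table["rpm"]

    def coverage_rpm_meta(self, gene_id: str) -> np.ndarray:
        if self.stats.denom_meta <= 0:
            raise ValueError("metagene denominator is zero")
        return self.coverage[gene_id] * 1e6 / self.stats.denom_meta

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")

    def coverage_to_bedgraph(self, path: str | Path, sample: str = "sample") -> None:
        """Antisense coverage (metagene RPM scale) as a bedGraph text track."""
        scale = 1e6 / self.stats.denom_meta if self.stats.denom_meta > 0 else 0.0
        genes = {g.gene_id: g for g in self._genes} if hasattr(self, "_genes") else {}
        with open(path, "w") as fh:
            fh.write(f'track type=bedGraph name="{sample}_antisense_rpm_meta"\n')
            for gene_id, cov in sorted(self.coverage.items()):
                g = genes.get(gene_id)
                if g is None or not cov.any():
                    continue
                vals = cov * scale
                genomic = vals if g.strand == "+" else vals[::-1]
                run_start = 0
                for i in range(1, len(genomic) + 1):
                    if i == len(genomic) or genomic[i] != genomic[run_start]:
                        v = genomic[run_start]
                        if v != 0:
                            fh.write(
                                f"{g.chrom}\t{g.start + run_start}\t{g.start + i}\t{v:.6g}\n"
                            )
                        run_start = i


def count_genes(
    hits: Sequence[MappedHit],
    genome: AnnotatedGenome,
    stats: NormalizationStats,
    only_22g: bool = True,
) -> GeneCountTable:
    """Aggregate mapped hits into the per-gene count table.

    Only antisense hits count toward gene totals; with ``only_22g`` (the
    default) counting is restricted to relaxed 22G reads (21-23 nt, 5' G).
    miRNA/21U loci are flagged ``excluded_biotype`` and soma genes
    ``soma_specific`` so the class-calling stage can drop them.  Raises when
    the hit weights are inconsistent with ``stats``.
    """
    stats.validate()
    total_weight = sum(h.weight for h in hits)
    if abs(total_weight - stats.total_genome_mappers) > 1e-6 * max(1, stats.total_genome_mappers):
        raise ValueError(
            f"hit weights ({total_weight:.3f}) do not tally with mapped reads "
            f"({stats.total_genome_mappers})"
        )
    raw = {g.gene_id: 0.0 for g in genome.genes}
    coverage = {g.gene_id: np.zeros(g.length) for g in genome.genes}
    for h in hits:
        if h.orientation != "antisense":
            continue
        if 18 <= h.length <= 26:
            coverage[h.gene_id][h.span_start : h.span_end] += h.weight
        if only_22g and not (21 <= h.length <= 23 and h.first_base == "G"):
            continue
        raw[h.gene_id] += h.weight
    denom_meta = stats.denom_meta
    rows = []
    for g in genome.genes:
        r = raw[g.gene_id]
        rows.append(
            (
                g.gene_id,
                g.biotype,
                g.truth_class,
                r,
                r * 1e6 / stats.denom_quant,
                r * 1e6 / denom_meta if denom_meta > 0 else np.nan,
                g.biotype in FILTERED_BIOTYPES,
                g.biotype == SOMA,
            )
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "biotype",
            "truth_class",
            "raw",
            "rpm",
            "rpm_meta",
            "excluded_biotype",
            "soma_specific",
        ],
    ).set_index("gene_id")
    out = GeneCountTable(table=table, coverage=coverage, stats=stats)
    out._genes = list(genome.genes)  # for bedGraph export
    return out
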