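"""Genotype-aware simulators: 22G small-RNA libraries, mRNA counts, Ct tables.

The small-RNA simulator is the heart of the synthetic-data stage.  It draws
reads *antisense* to coding transcripts under a per-gene, per-region rate
model that encodes what loss of each germ-granule compartment does to 22G
RNA synthesis:

* in ``egc1``/``elli1`` (E-granule) mutants, rates over the 5' region of
  E-class genes are multiplied by ``delta5`` while the 3'-terminal region
  keeps ``delta3`` (the E granule makes only the 5' siRNAs);
* in ``ego1`` both regions of E-class genes are scaled down (the RdRP
  itself is gone);
* in ``mut16`` M-class genes are scaled by ``deltaM`` and the UP class by
  ``deltaUp``;
* double mutants compose the two parent models multiplicatively.

Reads are 18-26 nt with the length distribution peaked at 22 nt, start with
a 5' G with probability ``p_g`` (implemented by conditioning the template
start on a C at the pairing position, so every simulated read remains an
exact antisense substring of its template), and a configurable fraction of
sense rRNA fragments is added to exercise the rRNA-subtraction
normalization downstream.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GERMLINE, SOMA, AnnotatedGenome, revcomp

# DNA sequence of the ligated 3' adaptor; appended to every insert on FASTQ
# export and trimmed again by the cleaning stage.
DEFAULT_ADAPTER3 = "TCGTATGCCGTCTTCTGCTTG"
# PCR primer sequences (the cleaning stage also accepts these as adapters).
PRIMER_A = "AATGATACGGCGACCACCGA"
PRIMER_G = "CAAGCAGAAGACGGCATACGA"

#: default read-length distribution: support 18-26 nt, peaked at 22
LENGTH_PMF: dict[int, float] = {
    18: 0.01, 19: 0.02, 20: 0.05, 21: 0.10, 22: 0.60,
    23: 0.10, 24: 0.06, 25: 0.04, 26: 0.02,
}

GENOTYPES = ("WT", "egc1", "elli1", "ego1", "mut16", "egc1_mut16", "elli1_mut16")

_SINGLE_DEFAULTS: dict[str, dict[str, float]] = {
    "WT": {},
    "egc1": {"delta5": 0.1, "deltaUp": 8.0},
    "elli1": {"delta5": 0.1, "deltaUp": 8.0},
    "ego1": {"delta5": 0.1, "delta3": 0.1},
    "mut16": {"deltaM": 0.05, "deltaUp": 0.05},
}


@dataclass(frozen=True)
class GenotypeModel:
    """Per-genotype rate multipliers for the 22G emission model."""

    genotype: str
    delta5: float = 1.0
    delta3: float = 1.0
    deltaM: float = 1.0
    deltaUp: float = 1.0
    five_prime_fraction: float = 0.8
    three_prime_fraction: float = 0.2

    def __post_init__(self) -> None:
        for name in ("delta5", "delta3", "deltaM", "deltaUp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if abs(self.five_prime_fraction + self.three_prime_fraction - 1.0) > 1e-9:
            raise ValueError("five_prime_fraction + three_prime_fraction must equal 1")

    @classmethod
    def for_genotype(cls, genotype: str, **overrides: float) -> "GenotypeModel":
        """Default model for one of the study genotypes (doubles compose)."""
        if genotype in _SINGLE_DEFAULTS:
            return cls(genotype=genotype, **{**_SINGLE_DEFAULTS[genotype], **overrides})
        if genotype.count("_") == 1:
            a, b = genotype.split("_")
            model = cls.compose(cls.for_genotype(a), cls.for_genotype(b))
            return replace(model, **overrides) if overrides else model
        raise ValueError(f"unknown genotype {genotype!r}")

    @staticmethod
    def compose(a: "GenotypeModel", b: "GenotypeModel") -> "GenotypeModel":
        """Multiplicative composition of two mutant models (double mutant)."""
        if (a.five_prime_fraction, a.three_prime_fraction) != (
            b.five_prime_fraction,
            b.three_prime_fraction,
        ):
            raise ValueError("cannot compose models with different region splits")
        return GenotypeModel(
            genotype=f"{a.genotype}_{b.genotype}",
            delta5=a.delta5 * b.delta5,
            delta3=a.delta3 * b.delta3,
            deltaM=a.deltaM * b.deltaM,
            deltaUp=a.deltaUp * b.deltaUp,
            five_prime_fraction=a.five_prime_fraction,
            three_prime_fraction=a.three_prime_fraction,
        )

    def region_multiplier(self, truth_class: str, region: str) -> float:
        if truth_class == "E":
            return self.delta5 if region == "five" else self.delta3
        if truth_class == "M":
            return self.deltaM
        if truth_class == "UP":
            return self.deltaUp
        return 1.0


@dataclass(frozen=True)
class Read:
    """A simulated (or loaded) small-RNA insert with optional ground truth."""

    read_id: str
    sequence: str
    truth_gene_id: str | None = None
    truth_template_start: int | None = None
    truth_orientation: str | None = None  # 'antisense' (signal) or 'sense' (contaminant)


@dataclass
class ReadSet:
    """A small-RNA library: reads plus library metadata."""

    reads: list[Read]
    genotype: str = "NA"
    seed: int | None = None
    adapter3: str = DEFAULT_ADAPTER3

    def __len__(self) -> int:
        return len(self.reads)

    def with_adapter(self) -> "ReadSet":
        """Raw-library view: the 3' adapter appended to every insert."""
        reads = [replace(r, sequence=r.sequence + self.adapter3) for r in self.reads]
        return ReadSet(reads, self.genotype, self.seed, self.adapter3)

    def to_fastq(self, path: str | Path, with_adapter: bool = True) -> None:
        """Write as FASTQ with constant Phred-33 quality."""
        with open(path, "w") as fh:
            for r in self.reads:
                seq = r.sequence + self.adapter3 if with_adapter else r.sequence
                fh.write(f"@{r.read_id}\n{seq}\n+\n{'I' * len(seq)}\n")

    @classmethod
    def from_fastq(cls, path: str | Path, genotype: str = "NA") -> "ReadSet":
        from Bio import SeqIO

        reads = [
            Read(read_id=rec.id, sequence=str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fastq")
        ]
        return cls(reads, genotype=genotype)


def expected_rates(genome: AnnotatedGenome, model: GenotypeModel) -> pd.DataFrame:
    """Unnormalized expected emission rates per coding gene and region.

    The multinomial read sampler draws from these rates normalized to 1;
    double-mutant rate vectors are elementwise products of the parents'
    vectors divided by wild type (multiplicative composition contract).
    """
    rows = []
    for g in genome.genes_with_biotype(GERMLINE, SOMA):
        r5 = g.base_rate * model.five_prime_fraction * model.region_multiplier(g.truth_class, "five")
        r3 = g.base_rate * model.three_prime_fraction * model.region_multiplier(g.truth_class, "three")
        rows.append((g.gene_id, g.truth_class, r5, r3, r5 + r3))
    df = pd.DataFrame(rows, columns=["gene_id", "truth_class", "rate5", "rate3", "total"])
    return df.set_index("gene_id")


def expected_fold_change(
    genome: AnnotatedGenome,
    model: GenotypeModel,
    reference: GenotypeModel | None = None,
) -> pd.Series:
    """Expected per-gene RPM fold change of ``model`` versus ``reference``.

    Libraries are compositional (reads per million), so the expected fold
    change of a gene is the ratio of its *share* of the emission rates
    under the two models, not of its raw rate multipliers.  This is the
    generative ground truth the class-recovery metrics compare against.
    """
    reference = reference or GenotypeModel.for_genotype("WT")
    mut = expected_rates(genome, model)["total"]
    wt = expected_rates(genome, reference)["total"]
    return (mut / mut.sum()) / (wt / wt.sum())


def simulate_sirna_library(
    genome: AnnotatedGenome,
    model: GenotypeModel,
    depth: int,
    seed: int,
    *,
    contamination: float = 0.05,
    p_g: float = 0.9,
    length_pmf: Mapping[int, float] | None = None,
    adapter3: str = DEFAULT_ADAPTER3,
) -> ReadSet:
    """Draw a 22G small-RNA library of expected size ``depth``.

    Signal reads are exact antisense substrings of coding transcripts;
    ``contamination`` of the library is sense rRNA fragments.  Deterministic
    for fixed inputs and ``seed``.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if not genome.genes_with_biotype(GERMLINE):
        raise ValueError("genome contains no germline_coding genes")
    pmf = dict(LENGTH_PMF if length_pmf is None else length_pmf)
    lens = np.array(sorted(pmf))
    lprobs = np.array([pmf[int(L)] for L in lens], dtype=float)
    lprobs = lprobs / lprobs.sum()
    rng = np.random.default_rng(seed)

    rrna = [g.gene_id for g in genome.genes_with_biotype("rRNA")]
    if contamination > 0 and not rrna:
        raise ValueError("contamination > 0 requires rRNA genes in the genome")

    # per-gene emission rates; the 5'/3' split is applied to the read *start*
    # space so that wild-type per-base coverage is uniform along the gene
    f5, f3 = model.five_prime_fraction, model.three_prime_fraction
    coding = [g for g in genome.genes_with_biotype(GERMLINE, SOMA) if g.base_rate > 0]
    entries: list[tuple[str, float, float]] = []  # gene_id, rate, p5
    for g in coding:
        m5 = model.region_multiplier(g.truth_class, "five")
        m3 = model.region_multiplier(g.truth_class, "three")
        mass5, mass3 = g.base_rate * f5 * m5, g.base_rate * f3 * m3
        rate = mass5 + mass3
        if rate > 0:
            entries.append((g.gene_id, rate, mass5 / rate))
    if not entries:
        raise ValueError("all emission rates are zero under this model")

    n_contam = int(rng.binomial(depth, contamination)) if contamination > 0 else 0
    n_signal = depth - n_contam
    probs = np.array([e[1] for e in entries])
    counts = rng.multinomial(n_signal, probs / probs.sum())

    transcripts = {e[0]: genome.transcript(e[0]) for e in entries}
    is_c = {
        gid: np.frombuffer(seq.encode(), dtype=np.uint8) == ord("C")
        for gid, seq in transcripts.items()
    }

    raw: list[tuple[str, str, int, str]] = []  # sequence, gene, start, orientation
    for (gene_id, _rate, p5), count in zip(entries, counts):
        if count == 0:
            continue
        seq = transcripts[gene_id]
        T = len(seq)
        read_lens = rng.choice(lens, p=lprobs, size=count)
        for L in np.unique(read_lens):
            L = int(L)
            c = int((read_lens == L).sum())
            n_starts = T - L + 1
            n5s = int(round(f5 * n_starts))  # 5' region boundary in start space
            c5 = int(rng.binomial(c, p5))
            for region_count, lo, hi in ((c5, 0, n5s), (c - c5, n5s, n_starts)):
                if region_count == 0:
                    continue
                if hi <= lo:  # degenerate region; negligible at >=100 nt genes
                    continue
                n_g = int(rng.binomial(region_count, p_g))
                g_starts = np.flatnonzero(is_c[gene_id][lo + L - 1 : hi + L - 1]) + lo
                starts = []
                if n_g and len(g_starts):
                    starts.append(rng.choice(g_starts, size=n_g, replace=True))
                else:
                    n_g = 0
                if region_count - n_g:
                    starts.append(rng.integers(lo, hi, size=region_count - n_g))
                for s in np.concatenate(starts):
                    s = int(s)
                    raw.append((revcomp(seq[s : s + L]), gene_id, s, "antisense"))

    if n_contam:
        idxs = rng.integers(0, len(rrna), size=n_contam)
        contam_lens = rng.choice(lens, p=lprobs, size=n_contam)
        for i, L in zip(idxs, contam_lens):
            gid = rrna[int(i)]
            seq = genome.transcript(gid)
            L = int(L)
            s = int(rng.integers(0, len(seq) - L + 1))
            raw.append((seq[s : s + L], gid, s, "sense"))

    order = rng.permutation(len(raw))
    reads = [
        Read(
            read_id=f"sim_{n:07d}",
            sequence=raw[i][0],
            truth_gene_id=raw[i][1],
            truth_template_start=raw[i][2],
            truth_orientation=raw[i][3],
        )
        for n, i in enumerate(order)
    ]
    return ReadSet(reads, genotype=model.genotype, seed=seed, adapter3=adapter3)


def simulate_mrna_counts(
    genome: AnnotatedGenome,
    genotype: str,
    mean_depth: float = 200_000.0,
    dispersion: float = 0.05,
    seed: int = 0,
    *,
    silenced_genes: Sequence[str] = (),
    silencing_factor: float = 4.0,
    n_reps: int = 2,
) -> pd.DataFrame:
    """Negative-binomial-style mRNA count table (``n_reps`` replicates).

    ``silenced_genes`` emulates sid-1/rde-11-like behaviour: those genes'
    expected counts are divided by ``silencing_factor`` in this genotype.
    Counts are gamma-Poisson with variance ``mu + dispersion * mu**2``.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    if silencing_factor <= 0:
        raise ValueError("silencing_factor must be > 0")
    rng = np.random.default_rng(seed)
    coding = genome.genes_with_biotype(GERMLINE, SOMA)
    w = np.array([g.base_rate for g in coding], dtype=float)
    mu = mean_depth * w / w.sum()
    silenced = set(silenced_genes)
    for i, g in enumerate(coding):
        if g.gene_id in silenced:
            mu[i] /= silencing_factor
    data = {}
    for rep in range(1, n_reps + 1):
        lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
        data[f"{genotype}_rep{rep}"] = rng.poisson(lam)
    return pd.DataFrame(data, index=[g.gene_id for g in coding])


def simulate_ct_table(
    true_relative_levels: Mapping[str, Mapping[str, float]],
    noise_sd: float = 0.1,
    seed: int = 0,
    *,
    reference_gene: str = "eft-3",
    n_bio: int = 3,
    n_tech: int = 3,
    target_baseline: float = 24.0,
    reference_baseline: float = 16.0,
) -> pd.DataFrame:
    """Simulate a qPCR Ct table recoverable by the 2^-ddCt operation.

    ``true_relative_levels`` maps target gene -> {sample -> relative level}
    (levels are relative to whatever sample the caller will designate as
    control).  Ct for a target is ``target_baseline - log2(level) + noise``;
    the reference gene is flat at ``reference_baseline`` plus noise.
    Returns a tidy frame with columns gene/sample/bio_rep/tech_rep/ct.
    """
    rng = np.random.default_rng(seed)
    samples: list[str] = []
    for gene, lv in true_relative_levels.items():
        for sample, level in lv.items():
            if level <= 0:
                raise ValueError(f"level for {gene}/{sample} must be > 0")
            if sample not in samples:
                samples.append(sample)
    rows = []
    for gene, lv in true_relative_levels.items():
        for sample in samples:
            if sample not in lv:
                continue
            base = target_baseline - np.log2(lv[sample])
            for b in range(1, n_bio + 1):
                for t in range(1, n_tech + 1):
                    ct = base + rng.normal(0.0, noise_sd) if noise_sd > 0 else base
                    rows.append((gene, sample, b, t, float(ct)))
    for sample in samples:
        for b in range(1, n_bio + 1):
            for t in range(1, n_tech + 1):
                ct = (
                    reference_baseline + rng.normal(0.0, noise_sd)
                    if noise_sd > 0
                    else reference_baseline
                )
                rows.append((reference_gene, sample, b, t, float(ct)))
    return pd.DataFrame(rows, columns=["gene", "sample", "bio_rep", "tech_rep", "ct"])
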