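"""Gene-class machinery: fold changes, target sets, E/M/UP classes, ddCt.

The class definitions mirror the study's comparative analysis: a gene is a
mutant's *target* when its antisense 22G RPM drops at least twofold versus
wild type (with a 10 RPM wild-type floor and biotype/soma exclusions);
E-granule factor targets are the per-factor consensus over two independent
alleles; the E class is the union of EGC-1 and ELLI-1 targets, the M class
the mut-16 targets, and the UP class the genes whose siRNAs *rise* at least
twofold when E granules are lost.
"""

from __future__ import annotations

from collections.abc import Set
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quant import GeneCountTable


@dataclass(frozen=True)
class ContrastParams:
    fc_cutoff: float = 2.0
    wt_min_rpm: float = 10.0
    pseudocount: float = 0.1
    direction: str = "down"  # 'down' or 'up'

    def __post_init__(self) -> None:
        if self.fc_cutoff <= 1:
            raise ValueError("fc_cutoff must be > 1")
        if self.wt_min_rpm < 0:
            raise ValueError("wt_min_rpm must be >= 0")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if self.direction not in ("down", "up"):
            raise ValueError("direction must be 'down' or 'up'")


def fold_change(rpm_mut: float, rpm_wt: float, pseudocount: float = 0.1) -> float:
    """(mutant + eps) / (wild type + eps)."""
    if rpm_mut < 0 or rpm_wt < 0:
        raise ValueError("RPM values must be >= 0")
    if rpm_wt + pseudocount == 0:
        raise ValueError("undefined fold change: wild-type RPM and pseudocount both zero")
    return (rpm_mut + pseudocount) / (rpm_wt + pseudocount)


def _as_frame(table: GeneCountTable | pd.DataFrame) -> pd.DataFrame:
    return table.table if isinstance(table, GeneCountTable) else table


def depleted_genes(
    table_mut: GeneCountTable | pd.DataFrame,
    table_wt: GeneCountTable | pd.DataFrame,
    params: ContrastParams = ContrastParams(),
) -> frozenset[str]:
    """Genes whose siRNAs change at least ``fc_cutoff``-fold in the mutant.

    direction='down': wild-type RPM floor applies, fold change <= 1/cutoff.
    direction='up': the abundance floor applies to the *mutant* RPM instead
    (the up-set contains genes with near-zero wild-type signal).
    Biotype-excluded (miRNA/21U) and soma-specific genes never qualify.
    """
    mut, wt = _as_frame(table_mut), _as_frame(table_wt)
    if set(mut.index) != set(wt.index):
        raise ValueError("mutant and wild-type tables cover different gene universes")
    wt = wt.loc[mut.index]
    eps = params.pseudocount
    fc = (mut["rpm"] + eps) / (wt["rpm"] + eps)
    eligible = ~(wt["excluded_biotype"] | wt["soma_specific"])
    if params.direction == "down":
        sel = eligible & (wt["rpm"] >= params.wt_min_rpm) & (fc <= 1.0 / params.fc_cutoff)
    else:
        sel = eligible & (mut["rpm"] >= params.wt_min_rpm) & (fc >= params.fc_cutoff)
    return frozenset(mut.index[sel])


def consensus_targets(set_allele_1: Set[str], set_allele_2: Set[str]) -> frozenset[str]:
    """Allele-consensus target set: genes depleted in both independent alleles."""
    return frozenset(set_allele_1) & frozenset(set_allele_2)


@dataclass(frozen=True)
class OverlapStats:
    """Exact set-overlap arithmetic behind proportional Venn diagrams."""

    size_a: int
    size_b: int
    size_intersection: int
    size_union: int
    pct_of_a_shared: float
    pct_of_b_shared: float

    @classmethod
    def from_sets(cls, a: Set[str], b: Set[str]) -> "OverlapStats":
        inter = len(set(a) & set(b))
        return cls.from_counts(len(set(a)), len(set(b)), inter)

    @classmethod
    def from_counts(cls, size_a: int, size_b: int, size_intersection: int) -> "OverlapStats":
        if size_intersection > min(size_a, size_b):
            raise ValueError("intersection cannot exceed either set")
        union = size_a + size_b - size_intersection
        return cls(
            size_a=size_a,
            size_b=size_b,
            size_intersection=size_intersection,
            size_union=union,
            pct_of_a_shared=100.0 * size_intersection / size_a if size_a else 0.0,
            pct_of_b_shared=100.0 * size_intersection / size_b if size_b else 0.0,
        )


def overlap_stats(a: Set[str], b: Set[str]) -> OverlapStats:
    return OverlapStats.from_sets(a, b)


@dataclass(frozen=True)
class ClassAssignment:
    """Per-gene membership in the target sets and derived classes."""

    egc1_targets: frozenset[str]
    elli1_targets: frozenset[str]
    e_class: frozenset[str]
    m_class: frozenset[str]
    up_class: frozenset[str]

    def memberships(self) -> pd.DataFrame:
        genes = sorted(
            self.e_class | self.m_class | self.up_class | self.egc1_targets | self.elli1_targets
        )
        return pd.DataFrame(
            {
                "EGC1_target": [g in self.egc1_targets for g in genes],
                "ELLI1_target": [g in self.elli1_targets for g in genes],
                "E_class": [g in self.e_class for g in genes],
                "M_class": [g in self.m_class for g in genes],
                "UP_class": [g in self.up_class for g in genes],
            },
            index=pd.Index(genes, name="gene_id"),
        )


def define_classes(
    egc1_targets: Set[str],
    elli1_targets: Set[str],
    mut16_targets: Set[str],
    up_egc1: Set[str] = frozenset(),
    up_elli1: Set[str] = frozenset(),
) -> ClassAssignment:
    """E class = EGC-1 union ELLI-1 targets; M class = mut-16 targets;
    UP class = union of the egc-1/elli-1 up-contrasts."""
    return ClassAssignment(
        egc1_targets=frozenset(egc1_targets),
        elli1_targets=frozenset(elli1_targets),
        e_class=frozenset(egc1_targets) | frozenset(elli1_targets),
        m_class=frozenset(mut16_targets),
        up_class=frozenset(up_egc1) | frozenset(up_elli1),
    )


def mrna_de_genes(
    counts_mut: pd.DataFrame,
    counts_wt: pd.DataFrame,
    fc_cutoff: float = 2.0,
    min_mean: float = 5.0,
    pseudocount: float = 0.5,
) -> tuple[frozenset[str], frozenset[str]]:
    """Two-fold mRNA differential-expression filter (up_set, down_set).

    Columns are replicates; counts are library-size normalized (each column
    scaled to the mean library size), condition means ratioed with a
    pseudocount, and genes below ``min_mean`` normalized counts in both
    conditions are ignored.
    """
    if fc_cutoff <= 1:
        raise ValueError("fc_cutoff must be > 1")
    if set(counts_mut.index) != set(counts_wt.index):
        raise ValueError("count tables cover different gene universes")
    counts_wt = counts_wt.loc[counts_mut.index]
    sizes = pd.concat([counts_mut.sum(), counts_wt.sum()])
    if (sizes == 0).any():
        raise ValueError("a condition/replicate has zero total counts")
    target = sizes.mean()
    norm_mut = counts_mut * target / counts_mut.sum()
    norm_wt = counts_wt * target / counts_wt.sum()
    mean_mut, mean_wt = norm_mut.mean(axis=1), norm_wt.mean(axis=1)
    eligible = np.maximum(mean_mut, mean_wt) >= min_mean
    ratio = (mean_mut + pseudocount) / (mean_wt + pseudocount)
    up = frozenset(counts_mut.index[eligible & (ratio >= fc_cutoff)])
    down = frozenset(counts_mut.index[eligible & (ratio <= 1.0 / fc_cutoff)])
    return up, down


@dataclass(frozen=True)
class DdctResult:
    """2^-ddCt levels per biological replicate plus mean +/- SD."""

    per_replicate: pd.DataFrame  # columns gene, sample, bio_rep, relative_level
    summary: pd.DataFrame        # index (gene, sample), columns mean_level, sd_level


def ddct(
    ct_table: pd.DataFrame,
    control_sample: str,
    reference_gene: str = "eft-3",
) -> DdctResult:
    """Relative RNA levels by the 2^-ddCt method.

    Technical replicates are averaged per biological replicate; dCt is
    Ct(target) - Ct(reference) per sample and replicate; ddCt subtracts the
    control sample's mean dCt; levels are 2^-ddCt.  Raises when reference
    rows are missing for any sample.
    """
    required = {"gene", "sample", "bio_rep", "ct"}
    if not required <= set(ct_table.columns):
        raise ValueError(f"ct_table must have columns {sorted(required)}")
    mean_ct = ct_table.groupby(["gene", "sample", "bio_rep"])["ct"].mean()
    if reference_gene not in mean_ct.index.get_level_values("gene"):
        raise ValueError(f"no reference-gene ({reference_gene!r}) rows in table")
    ref = mean_ct.xs(reference_gene, level="gene")
    targets = [g for g in mean_ct.index.get_level_values("gene").unique() if g != reference_gene]
    rows = []
    for gene in targets:
        tgt = mean_ct.xs(gene, level="gene")
        for sample in tgt.index.get_level_values("sample").unique():
            for bio_rep in tgt.xs(sample, level="sample").index:
                if (sample, bio_rep) not in ref.index:
                    raise ValueError(
                        f"missing reference rows for sample {sample!r} replicate {bio_rep}"
                    )
        dct = tgt - ref.loc[tgt.index]
        if control_sample not in dct.index.get_level_values("sample"):
            raise ValueError(f"control sample {control_sample!r} missing for gene {gene!r}")
        ddct_vals = dct - dct.xs(control_sample, level="sample").mean()
        for (sample, bio_rep), v in ddct_vals.items():
            rows.append((gene, sample, bio_rep, float(2.0 ** (-v))))
    per_rep = pd.DataFrame(rows, columns=["gene", "sample", "bio_rep", "relative_level"])
    summary = (
        per_rep.groupby(["gene", "sample"])["relative_level"]
        .agg(mean_level="mean", sd_level="std")
        .fillna({"sd_level": 0.0})
    )
    return DdctResult(per_replicate=per_rep, summary=summary)
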