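"""End-to-end seeded pipeline: simulate -> quantify -> classify -> metagene.

One :class:`RunConfig` describes the whole computational experiment: the
toy genome, a panel of genotypes (each with a rate model, a sequencing
depth and a number of independent alleles/libraries), the contrast
thresholds and the metagene windows.  :func:`run_pipeline` executes every
stage deterministically from a single seed (fanned out to per-stage child
streams), audits internal consistency, and returns a report whose summary
serializes to JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from collections.abc import Mapping
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .classes import (
    ClassAssignment,
    ContrastParams,
    OverlapStats,
    consensus_targets,
    define_classes,
    depleted_genes,
    overlap_stats,
)
from .genome import AnnotatedGenome, GenomeConfig, make_genome
from .metagene import bias_table, gene_profile, metaprofile
from .quant import CleaningParams, GeneCountTable, TranscriptIndex, clean_reads, count_genes, map_reads
from .simulate import GENOTYPES, GenotypeModel, expected_fold_change, simulate_sirna_library
from .util import derive_seed

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LibrarySpec:
    """One genotype in the panel: rate model, depth, number of alleles."""

    genotype: str
    model: GenotypeModel
    depth: int = 200_000
    alleles: int = 1


@dataclass
class RunConfig:
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    libraries: dict[str, LibrarySpec] = field(default_factory=dict)
    contrast: ContrastParams = field(default_factory=ContrastParams)
    # genotypes whose targets are the consensus of two alleles
    consensus_genotypes: tuple[str, ...] = ("egc1", "elli1")
    up_genotypes: tuple[str, ...] = ("egc1", "elli1")
    n_bins: int = 100
    five_fraction: float = 0.8
    min_window_reads: float = 25.0
    contamination: float = 0.05
    p_g: float = 0.9
    seed: int | None = None

    @classmethod
    def default_panel(cls, seed: int, depth: int = 200_000) -> "RunConfig":
        """The demo study: 7 genotypes over the default 120-gene genome."""
        libraries = {}
        for genotype in GENOTYPES:
            libraries[genotype] = LibrarySpec(
                genotype=genotype,
                model=GenotypeModel.for_genotype(genotype),
                depth=depth,
                alleles=2 if genotype in ("egc1", "elli1") else 1,
            )
        return cls(genome=GenomeConfig(seed=derive_seed(seed, "genome")), libraries=libraries, seed=seed)

    # -- (de)serialization for the CLI ------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "genome": dict(asdict(self.genome)),
            "libraries": {
                name: {
                    "genotype": ls.genotype,
                    "model": asdict(ls.model),
                    "depth": ls.depth,
                    "alleles": ls.alleles,
                }
                for name, ls in self.libraries.items()
            },
            "contrast": asdict(self.contrast),
            "consensus_genotypes": list(self.consensus_genotypes),
            "up_genotypes": list(self.up_genotypes),
            "n_bins": self.n_bins,
            "five_fraction": self.five_fraction,
            "min_window_reads": self.min_window_reads,
            "contamination": self.contamination,
            "p_g": self.p_g,
            "seed": self.seed,
        }
        d["genome"]["n_structural"] = dict(self.genome.n_structural)
        d["genome"]["class_fractions"] = dict(self.genome.class_fractions)
        d["genome"]["gene_length_range"] = list(self.genome.gene_length_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        g = dict(d.get("genome", {}))
        if "gene_length_range" in g:
            g["gene_length_range"] = tuple(g["gene_length_range"])
        libraries = {
            name: LibrarySpec(
                genotype=ls["genotype"],
                model=GenotypeModel(**ls["model"]),
                depth=int(ls.get("depth", 200_000)),
                alleles=int(ls.get("alleles", 1)),
            )
            for name, ls in d.get("libraries", {}).items()
        }
        return cls(
            genome=GenomeConfig(**g),
            libraries=libraries,
            contrast=ContrastParams(**d.get("contrast", {})),
            consensus_genotypes=tuple(d.get("consensus_genotypes", ("egc1", "elli1"))),
            up_genotypes=tuple(d.get("up_genotypes", ("egc1", "elli1"))),
            n_bins=int(d.get("n_bins", 100)),
            five_fraction=float(d.get("five_fraction", 0.8)),
            min_window_reads=float(d.get("min_window_reads", 25.0)),
            contamination=float(d.get("contamination", 0.05)),
            p_g=float(d.get("p_g", 0.9)),
            seed=d.get("seed"),
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def validate_config(config: RunConfig) -> list[str]:
    """All invariant violations in ``config`` (empty list iff valid)."""
    problems: list[str] = []
    if config.seed is None:
        problems.append("seed: a seed is mandatory")
    problems += [f"genome: {p}" for p in config.genome.validate()]
    if "WT" not in config.libraries:
        problems.append("libraries: a WT library is required as the contrast baseline")
    for name, ls in config.libraries.items():
        if ls.depth <= 0:
            problems.append(f"libraries[{name}].depth must be > 0")
        if ls.alleles < 1:
            problems.append(f"libraries[{name}].alleles must be >= 1")
    for genotype in config.consensus_genotypes + config.up_genotypes:
        if genotype not in config.libraries:
            problems.append(f"contrast references undefined genotype {genotype!r}")
    try:
        ContrastParams(**asdict(config.contrast))
    except ValueError as exc:  # re-validate in case of direct field mutation
        problems.append(f"contrast: {exc} (fc_cutoff={config.contrast.fc_cutoff})")
    if not 0 < config.five_fraction < 1:
        problems.append("five_fraction must be in (0, 1)")
    if not 0 <= config.contamination < 1:
        problems.append("contamination must be in [0, 1)")
    return problems


@dataclass
class RunReport:
    """Pipeline result: a JSON-able summary plus in-memory artifacts."""

    summary: dict[str, Any]
    genome: AnnotatedGenome | None = None
    tables: dict[tuple[str, int], GeneCountTable] | None = None
    assignment: ClassAssignment | None = None
    bias: dict[str, pd.DataFrame] | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.summary, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _overlap_dict(o: OverlapStats) -> dict[str, float]:
    return {
        "size_a": o.size_a,
        "size_b": o.size_b,
        "size_intersection": o.size_intersection,
        "size_union": o.size_union,
        "pct_of_a_shared": o.pct_of_a_shared,
        "pct_of_b_shared": o.pct_of_b_shared,
    }


def _precision_recall(called: set[str], truth: set[str]) -> dict[str, float]:
    tp = len(called & truth)
    return {
        "precision": tp / len(called) if called else float("nan"),
        "recall": tp / len(truth) if truth else float("nan"),
        "n_called": len(called),
        "n_truth": len(truth),
    }


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path | None = None,
    keep_artifacts: bool = True,
    write_fastq: bool = False,
) -> RunReport:
    """Execute the full study: simulate every library, quantify, call
    classes, profile gene bodies, and audit consistency.

    Deterministic for fixed config + seed.  With ``out_dir`` all tabular
    intermediates (FASTA/GFF3/TSV/bedGraph) and the JSON report are
    written; FASTQ only with ``write_fastq`` (it is the bulkiest
    intermediate).
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid RunConfig: " + "; ".join(violations))
    seed = int(config.seed)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    t0 = time.monotonic()
    genome = make_genome(config.genome)
    logger.info("genome: %d genes in %.1fs", len(genome), time.monotonic() - t0)
    if out is not None:
        genome.to_fasta(out / "genome.fa")
        genome.to_gff3(out / "genes.gff3")

    index = TranscriptIndex(genome)
    cleaning = CleaningParams()
    tables: dict[tuple[str, int], GeneCountTable] = {}
    for name, ls in config.libraries.items():
        for allele in range(ls.alleles):
            t1 = time.monotonic()
            child = derive_seed(seed, f"sirna/{name}/{allele}")
            lib = simulate_sirna_library(
                genome,
                ls.model,
                ls.depth,
                child,
                contamination=config.contamination,
                p_g=config.p_g,
            )
            cleaned = clean_reads(lib.with_adapter(), cleaning)
            hits, stats = map_reads(cleaned, genome, index)
            gct = count_genes(hits, genome, stats)
            tables[(name, allele)] = gct
            logger.info(
                "library %s/%d: %d reads, %d mapped in %.1fs",
                name, allele, len(lib), stats.total_genome_mappers, time.monotonic() - t1,
            )
            if out is not None:
                gct.to_tsv(out / f"counts_{name}_{allele}.tsv")
                gct.coverage_to_bedgraph(out / f"coverage_{name}_{allele}.bedgraph", f"{name}_{allele}")
                if write_fastq:
                    lib.to_fastq(out / f"reads_{name}_{allele}.fastq")

    wt = tables[("WT", 0)]
    down = ContrastParams(**{**asdict(config.contrast), "direction": "down"})
    up = ContrastParams(**{**asdict(config.contrast), "direction": "up"})

    def contrast_set(genotype: str, params: ContrastParams) -> frozenset[str]:
        alleles = config.libraries[genotype].alleles
        sets = [depleted_genes(tables[(genotype, a)], wt, params) for a in range(alleles)]
        if genotype in config.consensus_genotypes and alleles >= 2:
            return consensus_targets(sets[0], sets[1])
        return sets[0]

    egc1_targets = contrast_set("egc1", down) if "egc1" in config.libraries else frozenset()
    elli1_targets = contrast_set("elli1", down) if "elli1" in config.libraries else frozenset()
    mut16_targets = contrast_set("mut16", down) if "mut16" in config.libraries else frozenset()
    ego1_targets = contrast_set("ego1", down) if "ego1" in config.libraries else frozenset()
    up_sets = {
        genotype: contrast_set(genotype, up)
        for genotype in config.up_genotypes
        if genotype in config.libraries
    }
    assignment = define_classes(
        egc1_targets,
        elli1_targets,
        mut16_targets,
        up_sets.get("egc1", frozenset()),
        up_sets.get("elli1", frozenset()),
    )

    truth = {c: set(genome.truth_genes(c)) for c in ("E", "M", "UP", "NEUTRAL")}
    for cls_name, members in (("E", assignment.e_class), ("M", assignment.m_class)):
        if len(truth[cls_name]) < 5:
            logger.warning("truth class %s has < 5 genes; recovery metrics unstable", cls_name)

    # model-derived truth: which eligible genes are *expected* to cross the
    # fold-change cutoff under each genotype's rate model (libraries are
    # compositional, so e.g. the up-class, being Mutator-derived, also
    # belongs to the expected mut-16-depleted set)
    wt_frame = wt.table
    eligible = set(
        wt_frame.index[
            ~(wt_frame["excluded_biotype"] | wt_frame["soma_specific"])
            & (wt_frame["biotype"] == "germline_coding")
        ]
    )

    def model_truth(genotype: str, direction: str) -> set[str]:
        if genotype not in config.libraries:
            return set()
        exp_fc = expected_fold_change(genome, config.libraries[genotype].model)
        cut = config.contrast.fc_cutoff
        sel = exp_fc <= 1.0 / cut if direction == "down" else exp_fc >= cut
        return set(exp_fc.index[sel]) & eligible

    truth_model = {
        "E": model_truth("egc1", "down") | model_truth("elli1", "down"),
        "M": model_truth("mut16", "down"),
        "UP": model_truth("egc1", "up") | model_truth("elli1", "up"),
    }

    overlaps = {
        "egc1_vs_elli1_targets": _overlap_dict(overlap_stats(egc1_targets, elli1_targets)),
        "e_class_vs_m_class": _overlap_dict(overlap_stats(assignment.e_class, assignment.m_class)),
        "e_class_vs_ego1_targets": _overlap_dict(overlap_stats(assignment.e_class, ego1_targets)),
    }
    recovery = {
        "E_class": _precision_recall(set(assignment.e_class), truth_model["E"]),
        "M_class": _precision_recall(set(assignment.m_class), truth_model["M"]),
        "UP_class": _precision_recall(set(assignment.up_class), truth_model["UP"]),
    }
    # up-regulated calls must disappear when Mutator foci are also lost
    up_in_double = {}
    for genotype, double in (("egc1", "egc1_mut16"), ("elli1", "elli1_mut16")):
        if genotype in up_sets and double in config.libraries:
            double_up = depleted_genes(tables[(double, 0)], wt, up)
            up_in_double[double] = {
                "n_up_single": len(up_sets[genotype]),
                "n_up_single_still_up_in_double": len(up_sets[genotype] & double_up),
            }

    # -- metagene ---------------------------------------------------------
    profiles: dict[str, dict[str, list[float]]] = {}
    bias: dict[str, pd.DataFrame] = {}
    meta_genotypes = [g for g in config.libraries]
    class_genes = {"E": sorted(truth["E"]), "M": sorted(truth["M"]), "UP": sorted(truth["UP"])}
    for genotype in meta_genotypes:
        gct = tables[(genotype, 0)]
        profiles[genotype] = {}
        for cls_name, genes in class_genes.items():
            if not genes:
                continue
            profs = [
                gene_profile(gct.coverage_rpm_meta(g), config.n_bins) for g in genes
            ]
            profiles[genotype][cls_name] = metaprofile(
                profs, label=f"{genotype}:{cls_name}"
            ).values.tolist()
    contrasts = [g for g in meta_genotypes if g != "WT"]
    positional: dict[str, dict[str, Any]] = {}
    for genotype in contrasts:
        gct = tables[(genotype, 0)]
        for cls_name in ("E", "M"):
            genes = class_genes[cls_name]
            if not genes:
                continue
            bt = bias_table(
                gct.coverage,
                wt.coverage,
                genes,
                n_bins=config.n_bins,
                five_fraction=config.five_fraction,
                min_window_reads=config.min_window_reads,
            )
            bias[f"{genotype}:{cls_name}"] = bt
            called = bt[bt["callable"]]
            positional[f"{genotype}:{cls_name}"] = {
                "n_genes": len(bt),
                "n_callable": int(bt["callable"].sum()),
                "frac_five_prime_depleted": (
                    float((called["label"] == "five_prime_depleted").mean()) if len(called) else float("nan")
                ),
                "frac_uniform_depleted": (
                    float((called["label"] == "uniform_depleted").mean()) if len(called) else float("nan")
                ),
                "frac_unchanged": (
                    float((called["label"] == "unchanged").mean()) if len(called) else float("nan")
                ),
                "mean_fc5": float(called["fc5"].mean()) if len(called) else float("nan"),
                "mean_fc3": float(called["fc3"].mean()) if len(called) else float("nan"),
            }
            if out is not None:
                bt.to_csv(out / f"positional_bias_{genotype}_{cls_name}.tsv", sep="\t")

    # -- internal-consistency audit ---------------------------------------
    recomputed_union = frozenset(egc1_targets) | frozenset(elli1_targets)
    if recomputed_union != assignment.e_class:
        raise RuntimeError("report audit failed: E class is not the target-set union")
    ov = overlaps["egc1_vs_elli1_targets"]
    if ov["size_a"] + ov["size_b"] - ov["size_intersection"] != ov["size_union"]:
        raise RuntimeError("report audit failed: inclusion-exclusion violated")

    norm_stats = {
        f"{name}_{allele}": {
            "total_genome_mappers": gct.stats.total_genome_mappers,
            "sense_rRNA_reads": gct.stats.sense_rRNA_reads,
            "nonstructural_mappers": gct.stats.nonstructural_mappers,
            "denom_quant": gct.stats.denom_quant,
        }
        for (name, allele), gct in tables.items()
    }

    config_dict = config.to_dict()
    config_hash = hashlib.sha256(
        json.dumps(config_dict, sort_keys=True).encode()
    ).hexdigest()[:16]
    summary: dict[str, Any] = {
        "provenance": {"seed": seed, "config_hash": config_hash, "n_genes": len(genome)},
        "set_sizes": {
            "egc1_targets": len(egc1_targets),
            "elli1_targets": len(elli1_targets),
            "e_class": len(assignment.e_class),
            "m_class": len(assignment.m_class),
            "up_class": len(assignment.up_class),
            "ego1_targets": len(ego1_targets),
        },
        "overlaps": overlaps,
        "recovery": recovery,
        "up_in_double": up_in_double,
        "positional": positional,
        "metaprofiles": profiles,
        "normalization": norm_stats,
        "runtime_s": round(time.monotonic() - t0, 2),
    }
    report = RunReport(summary=summary)
    if keep_artifacts:
        report.genome = genome
        report.tables = tables
        report.assignment = assignment
        report.bias = bias
    if out is not None:
        # runtime varies between reruns; keep the persisted report byte-stable
        stable = dict(summary)
        stable.pop("runtime_s", None)
        RunReport(summary=stable).to_json(out / "report.json")
        assignment.memberships().to_csv(out / "class_assignment.tsv", sep="\t")
    return report


def plot_metaprofiles(report: RunReport, path: str | Path, cls_name: str = "E") -> None:
    """Line plot of the per-genotype metaprofiles for one truth class."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for genotype, per_class in report.summary["metaprofiles"].items():
        if cls_name in per_class:
            ax.plot(per_class[cls_name], label=genotype, lw=1.2)
    ax.set_xlabel("gene body bin (5' -> 3')")
    ax.set_ylabel("mean antisense coverage (RPM, nonstructural)")
    ax.set_title(f"{cls_name}-class metaprofile")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
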