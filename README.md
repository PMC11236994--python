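# egranule

Simulation and analysis of germ-granule-dependent 22G siRNAs in *C. elegans*.

The *C. elegans* germ granule is partitioned into subcompartments (P granule,
Z granule, Mutator focus, SIMR focus, and the E granule housing the RdRP
EGO-1 with EGC-1/ELLI-1/DRH-3/EKL-1). Different compartments synthesize
different populations of 22G RNAs — 22-nt, 5′-G endogenous siRNAs made
antisense to mRNA templates. Loss of the E granule (*egc-1* or *elli-1*
mutants) removes siRNAs mapping to the **5′ portions** of a specific set of
germline genes (the E class) while 3′-terminal siRNAs persist; loss of
Mutator foci (*mut-16*) ablates a distinct gene set (the M class); a third
set gains siRNAs when E granules are lost (the UP class), an amplification
that disappears when Mutator foci are also removed.

`egranule` is a library for studying exactly this kind of comparative
small-RNA experiment end to end, with ground truth:

- **synthetic data** — annotated toy genomes (FASTA + GFF3) whose germline
  genes carry hidden truth classes; genotype-aware 22G library simulation
  (antisense reads, length peaked at 22 nt, 5′ G, sense rRNA contamination,
  adapters); mRNA count tables; qPCR Ct tables; multi-channel foci images
  with known contact topology;
- **quantification** — adapter trimming and length filtering, a
  deterministic exact-match transcriptome mapper with fractional
  multi-mapper weights, and per-gene antisense 22G counts under two RPM
  normalizations:

  `RPM = raw × 10⁶ / (total genome mappers − sense rRNA reads)` and
  `RPM_meta = raw × 10⁶ / (nonstructural 18–26 nt mappers)`;
- **class machinery** — twofold-change contrasts with a 10 RPM wild-type
  floor, allele-consensus target sets, E/M/UP class definitions, exact
  set-overlap (Venn) arithmetic, a 2-fold mRNA DE filter and the 2^−ΔΔCt
  method;
- **metagene** — 100-bin gene-body profiles and per-gene 5′/3′
  positional-bias labels (`five_prime_depleted` when
  fc₅ ≤ 0.5 and fc₃ ≥ 0.75);
- **imaging** — ROI-restricted Pearson colocalization, threshold/
  connected-component focus detection, a pixel-distance contact test and
  the E/P/Z tri-condensate arrangement taxonomy;
- **pipeline** — one seeded run of simulate → quantify → classify →
  metagene over a 7-genotype panel, with a JSON report and full
  determinism audit.

## Worked example

```python
import egranule as eg

config = eg.RunConfig.default_panel(seed=7, depth=60_000)
report = eg.run_pipeline(config)
print(report.summary["set_sizes"])
```

prints

```
{'egc1_targets': 30, 'elli1_targets': 30, 'e_class': 30,
 'm_class': 45, 'up_class': 15, 'ego1_targets': 30}
```

The 30-gene E class is exactly the set of genes the generator made
E-granule-dependent; the 45-gene M class is the union of the 30 M-truth
genes and the 15 UP-class genes, whose siRNAs are Mutator-derived (their
amplification in *egc-1* vanishes in the *egc-1;mut-16* double). The
positional signature comes out of `examples/03_metagene_positional_bias.py`:

```
29/30 E-class genes callable (>= 25 wild-type reads in each window)
labeled five_prime_depleted: 97%
mean 5' window fold change (mutant/WT): 0.19
mean 3' window fold change (mutant/WT): 1.18
```

i.e. in the *egc-1* library the first 80% of each E-class gene body loses
~5× of its antisense coverage while the 3′-terminal window is untouched —
the hallmark of E-granule-restricted 5′ siRNA synthesis. Each script in
`examples/` demonstrates one capability (simulation + quantification,
class assignment, metagene bias, granule arrangements, ΔΔCt) and prints a
short interpretation of its numbers.

A thin CLI wraps the pipeline for shell use:

```sh
egranule demo-config run.yaml
egranule run --config run.yaml --out outdir
```

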