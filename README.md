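# bahdscape

Phylogenomic characterization and functional prediction for large plant
enzyme families, built around the BAHD acyltransferases — a family that
ranges from a handful of genes in algae to hundreds per angiosperm
genome, spanning anthocyanin, wax, phenylpropanoid and amide metabolism.

`bahdscape` is a Python library for the analyses this kind of family
demands once its members have been identified in a set of genomes:

* **Gene-structure profiling** — intron counts and lengths, locus length
  and CDS length per family member from GFF3, summarized per species with
  a cross-species grand mean (`genome_features`).
* **Clade assignment** — each member is placed into a previously defined
  clade (0–7 plus subclades) by its best hit against a panel of
  biochemically characterized references.  Two call sets are emitted: a
  *Relaxed* set (best hit's clade, unconditionally) and a *Conservative*
  set that keeps a call only if the hit shows ≥ 40% identity over ≥ 200
  aligned residues (or e-value ≤ 1e−50 for profile hits); conservative
  "unassigned" members flag candidate novel clades (`clade_assignment`).
* **Clade-discriminative motifs** — fixed-width consensus motifs (with
  'X' wildcards, e.g. `TFFDXXW`) over-represented in one clade versus all
  other family sequences, scored by one-sided Fisher exact tests with BH
  correction (`motif_enrichment`).
* **Paralog expression divergence** — all-pairs Pearson correlation r of
  expression profiles, co-expression calls at the 95th/5th percentiles of
  the pairwise distribution, Nei–Gojobori (1986) Ka/Ks with Jukes–Cantor
  correction d = −(3/4)·ln(1 − (4/3)·p), Ks bins of width 0.2, and
  Kruskal–Wallis plus pairwise two-sample Kolmogorov–Smirnov tests with
  BH-FDR across bins (`expression_divergence`).
* **Pathway prediction** — for each focal gene, partners with
  co-expression z ≥ 3 vs z ≤ 1 define a 2×2 Fisher test per annotated
  pathway; q-values (BH or Storey) flag enriched pathways, which are
  merged with orthology-based substrate-class calls into a combined
  agreement verdict (`pathway_prediction`).
* **Synthetic data** — generators for every input format with recorded
  ground truth (intron distributions, labeled clade ancestors, paralog
  pairs at target Ks, expression with corr = exp(−λ·Ks), co-expression
  tables with planted pathway enrichments), so the whole pipeline is
  testable without downloads (`synthetic_data`).

## Worked example

`examples/paralog_divergence.py` simulates 100 paralog pairs across Ks
0–1 whose expression correlation decays as exp(−2.5·Ks), re-estimates Ks
from the simulated CDS with NG86, and runs the bin statistics:

```
NG86 vs true Ks, mean abs error: 0.0395
PCC ~ Ks: slope -0.755, R^2 0.715
Kruskal-Wallis across bins: H=70.10, p=2.16e-14
     bin_b        D   p_adjusted
[0.2, 0.4) 0.720824 1.632055e-05
[0.4, 0.6) 1.000000 1.642065e-09
[0.6, 0.8) 1.000000 2.829233e-10
[0.8, 1.0) 1.000000 2.829233e-10
```

The NG86 estimates track the generator's true synonymous divergence to
within ~0.04; the negative slope and the small adjusted p-values of the
`[0.0, 0.2)` rows show that only the youngest paralogs remain
co-expressed — correlation is lost by Ks ≈ 0.4, the expected signature of
rapid regulatory divergence after duplication.

The other scripts in `examples/` each demonstrate one capability
(gene-structure profiling, clade calls at low vs high divergence, motif
discovery, pathway prediction) on inputs they generate themselves.  A
thin CLI mirrors the library:

```sh
bahdscape simulate genome --seed 1 --out sim/
bahdscape features --gff sim/genes.gff3 --ids ids.txt --out features.tsv
bahdscape clades --queries family.faa --panel refs.faa \
    --panel-labels refs.tsv --out calls.tsv
```

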