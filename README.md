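# dualgene

Some cancer genes are "double agents": depending on cellular context they
act as proto-oncogenes *and* as tumor suppressors (POTSF genes — e.g.
NOTCH1, TP53, RUNX1). `dualgene` is a pipeline for comparing this gene
class against plain oncogenes (ONC), tumor-suppressor genes (TSG) and
non-cancer-related genes (NCRG) along three axes:

1. **Somatic mutation burden and rate** — MAF-style tables are filtered to
   the eight protein-altering variant classes (missense, nonsense,
   frameshift/in-frame indels, splice-site, nonstop; silent and non-coding
   RNA records are removed), counted per gene and cohort, and summarized by
   the per-gene mutation rate
   `rate = (n_mutations / n_cases) / gene_length_bp`,
   where the numerator includes silent mutations.
2. **Expression level** — tumor RSEM matrices are median-normalized per
   sample and averaged per gene within a cohort; organ RNA-seq exon
   coverage is converted to RPKM, log2-transformed and Z-scored within each
   organ so genes are comparable across organs.
3. **Interactome position** — per-gene degree *k* and clustering
   coefficient *C*(*v*) = 2·T(*v*)/(k(k−1)) on an undirected simple PPI
   graph, extraction of the POTSF neighborhood network, MCODE-style dense
   module detection (vertex weight = core density of the closed
   neighborhood × core number; seed-and-grow with vertex weight percentage
   0.2, haircut on), and pairwise Nei–Gojobori (1986) dN/dS with
   Jukes–Cantor correction as a proxy for evolutionary constraint.

Set-level contrasts use two-sided Kolmogorov–Smirnov and Wilcoxon rank-sum
tests (exact permutation p-values for small samples) and chi-square tests,
flagged at α = 0.05 with the "higher" set marked.

Because the original data layers (pan-cancer MAF, expression matrices,
mentha interactome, orthologous CDS pairs) are large external downloads,
the package ships a first-class synthetic-data module that generates all
of them with controlled effect sizes (Poisson mutation counts with
set-specific rate multipliers, log-normal expression with location shifts,
a hub-biased growth interactome, codon pairs diverged at a target ω), so
every stage of the pipeline is testable offline and effect-size recovery
is verifiable.

## Worked example

```python
import numpy as np
from dualgene import simulate as sim
from dualgene import mutations, network, stats

cfg = sim.SimulationConfig(
    n_genes={"POTSF": 60, "ONC": 120, "TSG": 100, "NCRG": 200},
    cohorts={"BRCA": 120, "LAML": 80},
    seed=42,
)
part = sim.generate_universe(cfg)
maf = sim.generate_mutations(part, cfg)
profiles = mutations.build_profiles(maf, part, cohort_sizes=cfg.cohorts)
print(profiles.groupby("set_label")["n_nonsilent"].mean().round(2))
vectors = {lab: profiles.loc[profiles.set_label == lab, "n_nonsilent"].values
           for lab in ("POTSF", "ONC", "TSG", "NCRG")}
for r in stats.compare_matrix(vectors, test="KS"):
    print(r.set_a, "vs", r.set_b, f"D={r.statistic:.3f} p={r.p_value:.3g}",
          "higher:", r.higher)
```

Output (1,620 simulated mutation records, 1,263 non-silent):

```
NCRG     0.82
ONC      2.02
POTSF    2.15
TSG      0.96
KS POTSF vs ONC: D=0.079 p=0.668 higher=-
KS POTSF vs TSG: D=0.303 p=1.28e-06 higher=POTSF *
KS POTSF vs NCRG: D=0.328 p=2.46e-09 higher=POTSF *
KS ONC vs TSG: D=0.278 p=5.86e-08 higher=ONC *
KS ONC vs NCRG: D=0.303 p=9.63e-13 higher=ONC *
KS TSG vs NCRG: D=0.052 p=0.838 higher=-
```

POTSFs and oncogenes carry a significantly higher non-silent burden than
tumor suppressors and non-cancer genes, are statistically indistinguishable
from each other, and (on the hub-biased synthetic interactome generated by
the same config) a POTSF has a mean degree of 11.4 partners versus ~3 for
the other sets — the qualitative pattern the pipeline is designed to
measure.

The same steps are available from a shell:

```bash
dualgene simulate --config sim.yaml --out data/
dualgene partition --onc data/onc_list.tsv --tsg data/tsg_list.tsv \
    --curated data/curated_potsf.tsv --universe data/universe.tsv \
    --out partition.tsv
dualgene mutations --maf data/mutations.maf.tsv --partition partition.tsv \
    --out profiles.tsv
dualgene network --edges data/edges.tsv --partition partition.tsv --mcode \
    --out netmetrics.tsv
dualgene compare --profiles profiles.tsv --test KS --out comparisons.tsv
```

The curated POTSF table (83 genes: 41 transcription factors, 13 kinases,
29 others) ships as a packaged fixture:

```python
from dualgene import geneset
table1 = geneset.load_table1()   # gene_id, potsf_class
```

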