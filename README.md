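# clonalpop

Analyses for clonal bacterial isolate collections sampled over time:

- **conservation** — per-column Shannon entropy of aligned protein products,
  summed and standardized by protein length into a per-gene conservation
  score, with Welch/Student t and exact/Monte-Carlo permutation comparisons
  of a target gene group (e.g. a biosynthetic cluster) against a reference
  group (housekeeping genes).
- **clades** — exact pairwise nucleotide identity matrices (or ingestion of
  externally computed whole-genome identity matrices), average-linkage
  hierarchical clade assignment at an explicit identity cut, species-threshold
  checks, Newick dendrogram export, and clade relative-abundance timelines.
- **abundance** — statistics for Log10 CFU series that are left-censored at a
  limit of detection: detected/substituted summaries, Kruskal–Wallis with
  Dunn's post-hoc (Bonferroni-adjusted), occupancy/bimodality classification,
  and host-versus-seawater peak-lag detection.
- **synthetic_data** — a forward-time simulator of a clonal, seasonally
  bottlenecked population with founder clades and per-gene purifying
  constraint (modeled as immutable sites), plus a censored abundance
  observation layer, so every downstream analysis is testable offline.
- **io_cli** — FASTA/CSV/TSV/YAML plumbing, a packaged sampling-table
  fixture, and the command-line interface.

## Command line

```sh
clonalpop --help
clonalpop simulate --config demo.yaml --out outdir --seed 1
clonalpop entropy --genes outdir --base 2 --test welch
clonalpop clades --fasta-dir outdir --cut-identity 0.993 --metadata outdir/metadata.csv
clonalpop abundance --series outdir/abundance.csv --lod 1.0
clonalpop report --config demo.yaml --out outdir --seed 1
```

`report` chains the full pipeline — simulate, score gene entropy, cluster
clades, summarize censored abundance — and writes `report.json` plus TSV/CSV
artifacts; identical config and seed give byte-identical reports.

A minimal `demo.yaml`:

```yaml
seed: 1
simulation:
  n_years: 2
  mu: 1.0e-4
  founder_divergence_nt: 80
entropy:
  base: 2.0
  test: welch
```

Unknown configuration keys are rejected. The gene roster, seasonal schedule
and sample sizes default to a packaged two-season, multi-year population
(`clonalpop.synthetic_data.default_config`).

## Library use

```python
from clonalpop.synthetic_data import default_config, simulate_population
from clonalpop.conservation import ProteinAlignment, translate_cds, gene_entropy_score

config = default_config(seed=1, n_years=4)
isolates, truth = simulate_population(config)
rows = tuple(translate_cds(i.sequences["tdaC"]) for i in isolates)
aln = ProteinAlignment("tdaC", tuple(i.isolate_id for i in isolates), rows)
print(gene_entropy_score(aln).score)
```
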