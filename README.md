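# phewas-view

Visualization of Phenome-Wide Association Study (PheWAS) results.

A PheWAS tests one or more SNPs against a broad spectrum of phenotypes —
the transpose of a GWAS, which tests many SNPs against one phenotype.  The
result is a long table of association tests (SNP, phenotype, p-value, and
optionally gene symbol, signed effect size, population/ancestry group,
sample size and phenotype class).  Interpreting such tables — spotting
pleiotropy, separating it from phenotype correlation, comparing ancestry
strata — needs purpose-built plots, and that is what this package draws:

- **Standard plot** — a Manhattan-style scatter of −log₁₀(p) with one axis
  position per phenotype, in input-file order (sort your file, sort the
  plot).  Optional: blue/grey highlighting below a p-value threshold
  (`-p`), a red reference line (`-R`), a retention cutoff (`-m`),
  expected-vs-novel coloring in blue/purple from a known-pair file (`-x`),
  and filtering by phenotype class (`-c`), phenotype list (`-L`), SNP
  (`-s`) or ancestry groups (`-r`).
- **Vertical plot** (`-a`) — phenotypes down the y-axis with readable
  labels; `-B` annotates each phenotype with its most significant hit
  ("rs673548 GENE1 −": SNP, gene, effect-direction sign).
- **Tracks** — per-association effect size (`-b`) and sample size (`-A`)
  panels sharing the phenotype axis.
- **Group comparison** — per-group colored triangles, pointing up for a
  positive direction of effect and down for negative, with built-in
  ancestry colors (EA red, AA blue, H green, API purple, AI orange) or a
  user map file (`-l`).
- **Correlation heatmap** (`-C`) — pairwise phenotype |r| on a linear
  yellow (|r| = 1) → blue (|r| = 0) ramp, aligned to the phenotype axis,
  to help distinguish pleiotropy from correlated phenotypes.
- **Sun plot** (`-S`) — all qualifying results for one SNP, gene or
  phenotype as rays around a center label: ray length is linear in
  −log₁₀(p) normalized to the most significant result, which sits at
  12 o'clock with the remaining rays sweeping clockwise at uniform
  spacing; rays are red when p is strictly below the `-p` threshold.

Input is a single UTF-8 tab-delimited file with header columns `SNP`,
`Phenotype` and `p-value` (aliases `pvalue`/`p_value`); optional columns
`phenotype_class`, `Gene`, `ES`, `Groups`, `N` (alias `Sample_Size`) and
`Phenotype_long` unlock the corresponding features.  Output is a raster
image (PNG by default, 300 dpi, 72 dpi with `-w`) plus, with
`--debug-layout`, a machine-readable JSON description of the plot
geometry.

## Worked example

Real PheWAS result files are study-specific, so the package ships a
synthetic-data generator that emits a complete demo input set:

```python
from phewas_view import paper_like_spec, write_demo_directory
paths = write_demo_directory("demo", paper_like_spec(seed=11))
```

writes five files into `demo/`: `phewas_results.txt` (400 association
tests: 8 SNPs × 25 phenotypes × 2 ancestry groups, with ~8% injected
signal), `group_map.txt`, `correlations.txt`, `expected_pairs.txt` and
`phenotype_list.txt`.  Then:

```
$ phewas-view -e phewas_results.txt -c Allergy -p 0.01 -R 0.01 -t "Allergy phenotypes"
phewas_results.png
$ phewas-view -e phewas_results.txt -S -s rs673548 -m 0.05 -p 0.001 -b -G --debug-layout
phewas_results_sun.png
```

The first command restricts the plot to the "Allergy" phenotype class,
colors results with p < 0.01 blue (the rest grey) and draws a red line at
−log₁₀(0.01) = 2.  The second draws a sun plot of every rs673548 result
with p ≤ 0.05, red rays for p < 10⁻³, gene symbol in the center and a
+/− effect sign on each label.  Its serialized layout
(`phewas_results_sun.png.layout.json`) reads, for this seed:

```
center: rs673548 (GENE1)
scale:  p = 0.0169
rays:   3
{'angle': 0.0,   'color': 'grey', 'label': 'Phen24 -', 'length': 1.0,   'p': 0.0169}
{'angle': 120.0, 'color': 'grey', 'label': 'Phen2 -',  'length': 0.870, 'p': 0.0287}
{'angle': 240.0, 'color': 'grey', 'label': 'Phen21 -', 'length': 0.835, 'p': 0.0331}
```

Three results pass the 0.05 cutoff; none beats 10⁻³, so all rays are
grey; the most significant (p = 0.0169) sits at 12 o'clock with length 1,
and ray lengths decrease clockwise as −log₁₀(p)/−log₁₀(p_min).

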