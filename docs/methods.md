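# Methods

## The display model

The package visualizes tables of PheWAS association tests.  Every plot is
built in two stages: a **layout engine** converts a parsed, filtered and
classified dataset into a renderer-independent geometry object (axis
positions, point coordinates, color roles, glyphs, labels, tracks), and a
**renderer** rasterizes that object verbatim with matplotlib.  The split
makes the geometry a deterministic, serializable test surface: two runs of
the same command produce byte-identical layout JSON, while the raster may
differ only in backend metadata.

Significance is displayed as −log₁₀(p).  p-values are required to lie in
(0, 1]: an input of exactly 0 (or one that underflows double precision) is
clamped to 10⁻³⁰⁰ with a logged warning so the magnitude stays finite,
while negative values or p > 1 are rejected as malformed rows — they
indicate a broken file rather than an extreme result.

Phenotypes occupy consecutive integer axis positions in first-appearance
order of the input file.  The tool never sorts: ordering is delegated to
the user's file, so pre-sorting by p-value (or anything else) directly
controls the plot.  All records of one phenotype share one axis coordinate
with no jitter.

## Threshold semantics

Two different comparisons coexist and are deliberately distinct:

- *Highlight* thresholds ("more significant than") are **strict**:
  a record is blue (or a sun ray red) iff p < t.  A boundary value
  p = t is background grey.
- The *retention* cutoff `-m` ("values less significant are not plotted")
  is **non-strict**: p ≤ t survives, since equality is not "less
  significant".

Expected-vs-novel coloring gates on the same strict highlight threshold
when one is given; without a threshold the expected/novel split applies to
every plotted record.  The red reference line `-R` is purely an annotation
at height −log₁₀(p*) and never filters or recolors anything.

## Filters

Filters (phenotype class, phenotype list, SNP, groups, max-p) are pure,
order-preserving and idempotent, and they commute; the CLI applies them in
the fixed order class/list → SNP → groups → max-p, which therefore only
affects which empty-result warning fires first.  Class and phenotype names
match exactly and case-sensitively — they are identifiers, not prose.  The
best-hit-per-phenotype operation takes the minimal p-value with ties
broken by the first occurrence in file order, keeping annotations
deterministic.

## Color and glyph conventions

- Default series color is blue; grey is reserved for below-threshold
  background; novel associations are purple.
- Group comparison draws one triangle per record: up for effect ≥ 0, down
  for negative.  Zero effect is assigned to "up" because "+" is the
  non-negative convention used in the best-hit annotations.  Colors come
  from the group style map; the built-in map covers EA (red), AA (blue),
  H (green), API (purple) and AI (orange), and a user map file
  (`label TAB color [TAB description]`) replaces it.  Color names are
  validated against matplotlib's named-color table at parse time.
- The correlation heatmap encodes |r| by linear RGB interpolation from
  blue (0, 0, 255) at |r| = 0 to yellow (255, 255, 0) at |r| = 1; the
  ramp endpoints are the specified convention and linear interpolation is
  the simplest monotone map between them.  Using |r| makes the display
  invariant under r → −r.

## Vertical plots

Vertical mode is a true re-layout — the point set is the exact transpose
of the horizontal layout and phenotype labels render horizontally — not a
90° rotation of the raster, which would leave labels sideways.  Best-hit
annotations (`-B`) imply vertical mode, where there is room for per-row
text; the annotation format is `<snp> <gene> <sign>` with missing fields
omitted.

## Sun plots

A sun plot shows all qualifying results for one SNP, gene or phenotype.
Records are selected by key, retained at p ≤ max-p, and sorted by
ascending p (ties by file order).  Rays are placed at uniform angular
spacing 360°/n, the most significant at 12 o'clock, sweeping clockwise in
significance order — uniform spacing and significance ordering are the
only layout consistent with an even, monotone sweep.  Ray length is
−log₁₀(p) / −log₁₀(p_min), linear in the displayed magnitude and
normalized so the top ray has length 1; the minimal p-value is annotated
to give the radial scale.  With no red threshold supplied, every ray is
grey.  A phenotype-centred plot swaps label roles and tags rays with SNP
identifiers.  Tip labels are horizontal, right-aligned on the left half of
the circle — purely presentational.

## Input dialects

All five inputs are UTF-8 tab-delimited text (LF or CRLF).  Header
matching is case-insensitive with whitespace stripped.  The required
columns answer to `SNP`, `Phenotype` and `p-value` (also `pvalue`,
`p_value`); sample size answers to `N` or `Sample_Size`; the long
phenotype description to `Phenotype_long`.  These alias sets are a
compatibility choice: the optional annotation columns (`phenotype_class`,
`Gene`, `ES`, `Groups`) have fixed canonical names, while the remaining
headers vary across exports.  Identifier-like strings such as `NULL` or
`NA` are treated as data, never as missing values; only an empty cell is
absent.  The correlation matrix must be square and symmetric within 10⁻⁶
with a unit diagonal — asymmetry beyond rounding means the file was not
produced by an exhaustive pairwise computation and is rejected.

## Synthetic data generator

The generator emulates the shape of real PheWAS result exports without
simulating genotypes: a full SNP × phenotype × group grid of tests whose
null p-values are uniform(0, 1) and whose signal fraction (default 5–8%)
is drawn log-uniform over 10⁻⁸–10⁻³, so −log₁₀ axes and sun plots span
several orders of magnitude.  Effects are Normal(0, 0.3), sample sizes
uniform integers in [500, 3000] — magnitudes typical of survey-based
association cohorts.  Correlation matrices are built analytically from a
block structure (constant within-block r, zero between blocks, unit
diagonal), which is positive semidefinite by construction as the
correlation of a one-factor model, and verified by an eigenvalue check.
The `paper_like_spec` preset (8 SNPs including rs673548, 25 phenotypes in
three classes including "Allergy", AA/EA groups) exercises every optional
column and the default styling.

What the generator does **not** emulate: linkage disequilibrium between
SNPs, case/control imbalance, correlation between the phenotype values and
the injected p-values, or realistic phenotype vocabularies.  Passing tests
therefore demonstrate the correctness of parsing, filtering, geometry and
rendering contracts on realistic table shapes — not statistical properties
of any real cohort.

## Numerical and interface choices

- Clamp floor 10⁻³⁰⁰ keeps −log₁₀ ≤ 300, within double range.
- Heatmap channels round half-to-even, so |r| = 0.5 maps to `#808080`.
- `-c` takes a single class; `-c` and `-L` are mutually exclusive
  alternatives.
- Default output name is the input file stem (plus `_sun` for sun plots)
  with the format extension; `-o` overrides it.
- Exit codes: 0 success, 2 usage error, 3 input-format/configuration
  error, 4 empty result after filtering.
- Problem sizes in the test suite and acceptance script (1,000-record
  round trips, 2,000-record null calibration, a 13-command CLI matrix at
  72 dpi) were chosen to exercise every code path at comfortably
  interactive runtimes.

## Known limitations

PNG is the only guaranteed raster format; others depend on the matplotlib
backend.  The heatmap is never reordered or clustered.  Very long
phenotype labels can collide at small figure sizes; the layout does not
attempt collision avoidance beyond upright label placement.  Sample-size
tracks use a linear axis.
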