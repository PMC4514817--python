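# Methods

## Model

Each repeat element *r* is scored against a background frequency *p(r)*
with an exact binomial model.  Three counting modes define *p* and the
observed pair (*k*, *n*):

| mode | p(r) | n | k(r) |
|---|---|---|---|
| gene counts | fraction of all genes with ≥1 instance of *r* in the chosen neighborhood | number of query genes | query genes with ≥1 instance of *r* in their neighborhood |
| repeat counts | *r*'s share of all repeat occurrences in all genes' neighborhoods | total occurrences of all repeats in the query neighborhoods | occurrences of *r* there |
| whole-genome repeat counts | *r*'s share of all occurrences in the genome | total occurrences in the queried locus | occurrences of *r* in the locus |

The "at least once" rule applies to both the background and the observed
side of the gene-counts statistic; this symmetry is what makes the identity
hold exactly: when the query set is all genes, every ratio is 1.0 by
construction (same integers divided in the same order, hence bit-identical
doubles).

The ratio (*k*/*n*)/*p* measures over- (>1) or under- (<1) representation.
The default p-value is the one-sided tail in the direction of the observed
deviation — P(X ≥ k) or P(X ≤ k) under X ~ Binomial(n, p).  The point mass
P(X = k) is selectable (`pvalue_mode="point"`) but is not a calibrated
significance measure and is off by default.  Note the directional selection
makes the default test behave like an undoubled two-sided test: its exact
null size oscillates with the discreteness of the binomial grid, typically
0.05–0.09 at α = 0.05 for n ≈ 100.  Stricter α or `--adjust bh`
(Benjamini–Hochberg over the tested set) are available; no adjustment is
applied by default.

Repeats whose background frequency is exactly 0 or 1 are degenerate under
the binomial model; they are excluded from testing and listed separately
with a reason rather than reported with a fake p-value.

## Neighborhoods and counting rules

Coordinates are 0-based half-open everywhere internally; RepeatMasker
`.out` and the gene TSV are converted at the file boundary (1-based
inclusive; strand `C` ≡ `-`).  The TSS of a minus-strand gene is its
half-open end coordinate, which makes the window algebra mirror-symmetric:
mapping x → L − x and flipping strands maps every window kind onto itself
(tested exhaustively).

- upstream/downstream of TSS and downstream of gene end: one window of the
  nominal size;
- around TSS: one window of twice the size (size per side);
- around gene: two flanks of the nominal size each, gene body excluded.

Windows are clipped to the chromosome; fully clipped windows vanish.  A
repeat instance counts toward a window when it overlaps by ≥1 bp (half-open
abutment does not count); a stricter full-containment rule is available
(`--overlap-rule contained`) for sensitivity checks.  Overlapping windows
of different genes are evaluated independently: one instance can count for
two genes, and in repeat-counts mode it contributes once per window it
overlaps.  Fragmented RepeatMasker elements are counted per row; the `.out`
ID column is preserved for future merging.

Locus analysis uses repeat-counts statistics against whole-genome
frequencies.  When a repeat-class filter is given, both the observed
tallies and the background are restricted to the filtered classes and the
background is renormalised over that universe, so frequencies remain
shares within the filter and a locus spanning the whole genome still gives
unit ratios.

Ortholog analysis runs the gene-set screen independently per species, each
against that species' own background.  The common set is the repeats
significant in the query species and in ≥1 other species with the same
deviation direction (direction agreement can be relaxed; mixed-direction
hits are hard to interpret).  If a query gene's homology group has several
members in a target species, all are included by default
(`--ortholog-policy first` keeps one).

## Numerics

Binomial probabilities are computed in log space from `gammaln` and
summed with `logsumexp`.  The incomplete-beta route used by generic
statistics libraries loses relative accuracy in extreme tails (errors
reaching order 1 below ~1e-283); the log-space summation keeps the
relative error near 1e-12 all the way down to the double-precision floor,
verified against exact rational arithmetic over all k for n up to 1000.
Values below the smallest normal double cannot carry 9 significant digits
by construction; there the implementation agrees with the exact value to
within 1e-300 absolute.

Interval lookup uses per-chromosome start-sorted arrays: binary search on
the start coordinate bounds the candidates, a vectorised end-coordinate
mask finishes the query.  Coverage merges sorted intervals per chromosome
before summing, so duplicate and overlapping annotations are counted once.

Summary tables are sorted by ascending p-value, ties broken by repeat
name; floats are written with 6 significant digits.  Reports never contain
NaN/inf — untestable repeats go to the separate untested listing.

## Synthetic data generator

The generator emulates a desk-scale mammalian annotation: 2,000 genes of
2–10 kb on 4 × 50 Mb chromosomes (≈1 gene / 100 kb), an 8-element repeat
catalog (LINE/SINE/LTR/DNA/simple classes) scattered as a homogeneous
per-bp process at 1e-5 instances/bp (~16,000 instances), and one planted
element placed uniformly inside the around-gene 10 kb window of each query
gene with probability 0.8 and of each non-query gene with probability 0.1
(100 query genes of 2,000).  Gene placement draws lengths first and then
sorted uniform offsets in the remaining free space, which guarantees
non-overlap in one pass.  A single seeded generator drives all randomness;
the same seed reproduces every output file byte for byte.

What the generator does **not** emulate: sequence content, repeat
fragmentation and divergence structure, clustered (non-homogeneous) repeat
placement, transcript isoform diversity, and the strong length/GC biases
of real genomes.  Passing the planted-recovery and calibration tests
therefore shows the statistics and plumbing are correct under the stated
model, not that the binomial background is an adequate null for any real
genome — on real data, correlated repeat placement can make raw p-values
anticonservative, which is one reason stricter cutoffs and BH adjustment
are exposed.

Because planted instances land inside their own gene's windows, windows of
near neighbors can pick them up too; at the default density this raises
the effective per-gene presence rate only mildly (≈0.11 for a nominal
0.10 planting rate, measured over 600 seeds).

The ortholog-pair generator produces a second species as an independent
re-generation with a 1:1 homology map; under shared planting the signal is
planted on the ortholog image of the query set, otherwise only in the
first species.

## Test scale

The test suite and the acceptance script size their simulations to run in
a few minutes on one CPU: 100 seeds for planted recovery, 200 for null
calibration, 50 random fixtures (≤3,000 repeats × ≤200 genes) for the
brute-force counting cross-checks, and an n-ladder up to 1000 with a
7-point p grid for the exact-rational binomial comparison.

## Known limitations

- No multiple-testing correction by default; the raw α = 0.05 short-list
  deliberately errs toward sensitivity.
- Gene-level backgrounds ignore GC content, gene length, and repeat
  clustering; matched backgrounds are out of scope.
- GFF3 input is not supported (gene TSV and BED only); no network access
  or sequence retrieval of any kind.
- One-sided tails only; the direction-selected default is slightly
  anticonservative relative to a doubled two-sided test (see Model).
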