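# Methods

This note documents the models, rules and numerical choices behind
`glycosecretome`, and what the synthetic benchmarks do and do not show.

## Glycan typing

Intact glycopeptide searches report glycans as monosaccharide composition
strings in the `Residue(count)` dialect (`HexNAc(2)Hex(9)`). Compositions are
assigned to exactly one of five types ordered by maturation through the
ER-Golgi processing pathway: high mannose (1, least mature), paucimannose (2),
complex/hybrid (3), fucosylated (4), sialylated (5, most mature). The decision
rule is a strict precedence cascade over residue counts:

1. **sialic_acid** — any NeuAc or NeuGc;
2. **fucose** — any Fuc;
3. **complex_hybrid** — more than 2 HexNAc (antennary GlcNAc beyond the
   chitobiose core);
4. **high_mannose** — at most 2 HexNAc and ≥ 5 Hex;
5. **paucimannose** — at most 2 HexNAc and < 5 Hex.

Two boundary choices are deliberate. Man5 (`HexNAc(2)Hex(5)`) is counted as
high mannose, its canonical class in glycobiology, by implementing the hexose
rule as ≥ 5. Truncated structures with fewer than 2 HexNAc follow the same
hexose split, which makes the cascade total: every composition over the
plausible residue ranges receives exactly one label. Residues outside the
canonical five parse into an `other` map and never influence typing, so larger
glycan databases (phospho-, sulfo-, pentose-bearing entries) pass through
unchanged.

## Acetylation stoichiometry

After exhaustive chemical acetylation with D6-acetic anhydride, every lysine
carries either the endogenous (light) acetyl or a chemical d3-acetyl that is
3 × (m(²H) − m(¹H)) = 3.0188304 Da heavier per acetyl group; heavy partner
m/z values are generated in silico as `light + n·Δ/z`. Site occupancy is

    s = Σ light / (Σ light + Σ heavy)

with the sums pooled over all fragment ions and chromatographic fractions of
the site. Pooling areas before the ratio (rather than averaging per-fragment
ratios) weights each fragment by its signal and is robust to low-area
fragments; a per-fragment-median estimator is available via `method="median"`
for sensitivity analysis, without any claim that one or the other matches any
particular external workflow. Pairs with both areas zero are discarded as
undefined (0/0); a site with no usable pair is skipped with a warning rather
than reported as 0.

## Differential statistics

Intensities are log2-transformed before testing (MS intensity ratios are
multiplicative) and fold changes are means of log2 values. Two testing paths
are kept deliberately distinct:

* **Glycoform path** — plain two-sided pooled-variance Student's t-test per
  glycoform, significance at raw p < α (default 0.05), no FDR correction.
* **Proteome path** — an F-test on the variance ratio (two-sided, default
  gate α = 0.05, configurable) selects pooled Student or Welch; per-batch
  p-values are combined with Fisher's method (X² = −2Σln pᵢ on 2k df) and
  fold changes averaged across batches on the log2 scale.

Degenerate features are resolved deterministically: zero variance in both
groups gives p = 1 when means are equal and p = 0 (with a logged warning) when
they differ. Missing values are dropped per feature, never imputed; a group
left with fewer than two values skips the feature with a warning. Enrichment
uses the upper-tail hypergeometric test with annotation sets intersected
against the user-supplied background, BH-adjusted across sets. BH adjustment
and the t/F/χ²/hypergeometric distributions come from statsmodels and scipy;
the test suite checks them against independent brute-force references
(step-up recursion, closed forms, exhaustive enumeration).

## Subcellular binning and secretome topology

Proteins are binned inclusively into 12 compartments by case-insensitive
keyword matching on GO Cellular Component term names (not GO ids, since the
rules are phrased over words): plasma membrane; other membrane ('membrane'
without 'plasma membrane'); neural ('axon'/'neuro'/'myelin'); ER
('endoplasmic'); Golgi ('golgi' in a term without 'endoplasmic', so ERGIC
terms count as ER only); cell surface; synapse; extracellular; vesicle;
lysosome; secreted; none listed (only when nothing else matched). The Golgi
exclusion applies per term, so a protein annotated with both "Golgi apparatus"
and "endoplasmic reticulum" belongs to both compartments. Because GO CC
rarely contains the literal word "secreted", the secreted keyword list
defaults to ("secreted", "secretory") and is configurable.

Each (dataset × category) group becomes a vector over the sorted union of
glycoforms — identity is the (protein, site, composition) triple, since one
sequon can carry several regulated glycans — significant in at least one
included dataset: +1 up-regulated, −1 down-regulated, 0 otherwise (not
significant, or protein outside the category). The union spans whichever
datasets enter a given comparison; its dimension is a property of the data,
not a constant. Pairwise Euclidean distances between these vectors separate
compartments whose regulation diverges between genotypes (opposite signs
contribute 4 per dimension) from compartments that respond convergently
(contribution 0). Dataset concordance is summarised by exact-membership
(upset) pattern counts and by overlap percentages whose denominator
(union by default; min, a, b available) is always named alongside the number,
since a bare percentage is ambiguous.

## Imaging metrics

A cargo is released when it traffics strictly more than 2 µm within 3 min of
its first frame. "Trafficked" is implemented as maximum net displacement from
the track origin — an out-and-back excursion of large path length but small
displacement is retained — with a cumulative path-length mode behind a flag
for comparison. Speeds are inter-frame displacement over actual timestamps
(robust to dropped frames); the per-cell summary is the mean over cargo of
each cargo's maximum speed. Golgi accumulation series are divided by their own
maximum, mapping each cell to [0, 1] regardless of expression level.

## Synthetic data

The generators are pure functions of a single integer seed, fanned out into
per-layer substreams so adding one generator never perturbs another.

* **Glycoproteome** — 150 proteins, site and glycan counts 1 + Poisson(0.5)
  and 1 + Poisson(0.6) (a few hundred glycoforms), over WT / sTg / S113R ×
  two sexes × two brain regions with n = 3 replicates per group. Log2
  intensities are Normal(20, 2) baselines plus Normal(0, 0.25) noise.
  Each protein gets one true compartment (weighted draw) and a GO term
  engineered to map to exactly that compartment, so category membership is
  known. Effects of log2 = 4 are planted in 80% of glycoforms of five
  compartments: divergent directions between the two mutant genotypes in
  vesicle, extracellular and plasma-membrane proteins, convergent directions
  in lysosome and Golgi — the pattern expected when Golgi-to-plasma-membrane
  transport is differentially disrupted.
* **Fragment pairs** — sites on an 11-point stoichiometry grid (0 to 1),
  10 fragments over 2 fractions, total areas log-normal around 10⁵ split
  light : heavy = s : (1 − s), with optional multiplicative log-normal noise
  (default σ = 0.05).
* **Tracks** — 20 cargo per cell at 3 s cadence over 3 min; released tracks
  move ballistically to twice the threshold, retained tracks perform an
  out-and-back excursion peaking at 40% of it, so the released fraction is
  exact by construction.

What the benchmarks show — and do not. Passing the recovery benchmarks shows
the statistics, encodings and metrics are implemented correctly and calibrated
under the generative model (independent log-normal noise, exact group design,
clean annotation, planted effect sizes). Real glycoproteomics data add
correlated measurement error, missingness that is intensity-dependent,
annotation noise and much smaller effects; the benchmarks say nothing about
power or error control under those violations, only that the machinery itself
is sound.

## Problem sizes and numerical conventions

The bundled benchmarks use ~400 glycoforms × 36 samples, 1,001 stoichiometry
sites, 10,000-feature null tables, 2,000-dimension distance checks and 10
replicate seeds — sizes chosen so the whole battery runs in seconds while
keeping every estimate stable to well within its acceptance margin. All
tables are tab-separated UTF-8 with `.` decimals; missing intensities are
empty fields (never 0); glycosites are 1-based residue positions; every
randomised step takes an explicit seed and the pipeline run log records seed,
versions and parameters sufficient to reproduce any output byte-for-byte.
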