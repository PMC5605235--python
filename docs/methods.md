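# Methods

This note records the models, conventions and numerical choices behind
`imotifkit`, and what its synthetic-data tests do and do not demonstrate.

## The folding rule and the scanner

An i-motif is a four-stranded DNA structure held together by intercalated,
hemi-protonated C:C+ base pairs; it forms in cytosine-rich sequences and is
favoured at acidic pH, with a subset of sequences folding at neutral pH.
The screening pattern is the folding rule **C5(N1-19C5)3**: four tracts of
at least five consecutive cytosines separated by three loops of 1–19
arbitrary bases.  Loops may themselves contain cytosine, so a candidate
region often admits many tract placements; the scanner therefore fixes a
canonical form:

* **Non-overlap, leftmost-first.** Hits on a strand are non-overlapping;
  scanning resumes after the end of each reported hit.  This matches the
  behaviour of the common quadruplex pattern scanners.
* **Shortest loops first.** Within a hit, each successive tract is placed
  at the earliest admissible position, i.e. the loop tuple is
  lexicographically minimal.  The regex engine's lazy quantifiers find the
  match span; an explicit backtracking placement recovers the tract
  coordinates and asserts agreement with the regex span.
* **Minus strand by mirror.** The reverse complement of the stored
  sequence is scanned with the same rule and coordinates are mirrored back.
  This makes plus/minus results exact mirror images (scanning G-runs
  left-to-right on the stored sequence instead would give the same loci but
  a different canonical register inside homopolymer runs).  Hits on the
  two strands are counted independently; genomic candidates split roughly
  evenly between strands, and no cross-strand merging is defined.
* **N handling.** `N` never matches a tract base but may sit in a loop —
  conservative for tract identity.

### Decomposition of single oligonucleotides

For feature analysis each oligonucleotide is reduced to four tracts and
three loops.  If the strict rule matches, the canonical (leftmost,
shortest-loop) match is used.  Several printed genomic candidates (the
three RUNX1 sequences) do not match the strict rule as printed; for these
a fallback takes the four longest maximal C-runs (length >= 2, ties broken
leftmost) in genomic order, with inter-run gaps as loops, and flags the
result `fallback_used`.

### Counting loop bases

The "total loop length" of a candidate — the sum of all loop bases — is
computed under one of two conventions:

* `non_tract_bases` (default): every non-cytosine base counts as a loop
  base.  In a C-rich candidate each cytosine can in principle join the
  intercalated C:C+ core, so this is the literal reading of "sum of all
  loop bases"; it is parameter-free and reproduces the published panel
  correlations (r = −0.62 vs pH_T, −0.26 vs Tm, against published values
  of −0.65548 and −0.3304).
* `decomposition`: the three loop lengths of the canonical decomposition
  are summed.  Because rule loops may contain cytosine, extended C runs
  make this count smaller; it yields the same signs with magnitudes of
  −0.44 and −0.23.

The choice between them was genuinely open (the published analysis does not
spell out its convention); the default follows the convention that
reproduces the published figures.

### Expected hit counts in random sequence

For an i.i.d. background the expected number of (start position,
loop-assignment) matches is exact and closed-form: a specific loop
combination matches at a given start with probability
p_C^(n_tracts·tract_len) (loop bases are unconstrained), so the
expectation is that probability times the number of admissible
(start, combination) pairs.  No first-occurrence or clump correction is
applied — this is the "simple probability" benchmark, not a first-passage
statistic.  For four tracts the number of loop combinations is
(loop_max − loop_min + 1)^3, hence the cubic law; observed genome counts
grow roughly linearly in loop_max instead, which is the interesting
discrepancy the scaling command exposes.

## Promoter and GO enrichment

* Promoters are the 1 kb immediately upstream of a gene-level TSS,
  strand-aware: `[tss − 1000, tss)` for `+` genes, `[tss + 1, tss + 1001)`
  for `−` genes, clipped to chromosome bounds.  One TSS per gene;
  transcript-level multiplicity is out of scope.
* A hit overlaps a promoter with >= 1 shared bp, regardless of strand
  pairing.  Each hit counts once at the hit level but increments every
  gene window it touches.
* The chance expectation is the union-coverage fraction of the promoter
  windows — the simplest null for "predicted by chance".
* Significance is a 1-df chi-squared goodness of fit over the two cells
  (overlapping, non-overlapping), without continuity correction.  An
  expected cell below 1 attaches a warning to the result.
* GO terms applicable to fewer than `min_genes` (default 100) universe
  genes are excluded before testing; each remaining term gets a two-sided
  Fisher's exact test on the 2×2 hit-membership table, with
  Benjamini–Hochberg step-up q-values over the tested terms only.
  Fisher's exact was chosen because it is exact at any count; BH because
  the screen tests hundreds of partially overlapping terms.

## UV melting analysis

Transition temperatures use the first-derivative method: the
absorbance-vs-temperature curve (295 nm) is smoothed with a 7-point,
order-2 Savitzky–Golay filter, differentiated on its grid
(`numpy.gradient`), and peaks of |dA/dT| are picked with
`scipy.signal.find_peaks`.  Peaks need prominence >= 25% of the largest
extremum; at most two are kept (largest first) and reported ascending.
Peak positions are refined by a three-point quadratic fit (sub-grid
accuracy on the 1 degC grid).  A curve whose derivative never exceeds its
median by five robust standard deviations is declared transition-free and
returns a warning rather than a temperature.  Curves spanning less than
20 degC or with fewer than 10 points are rejected.

Hysteresis is Tm − Ta.  For two-step melts the largest-amplitude melt
transition is paired with the largest-amplitude anneal transition, since a
single annealing temperature is conventionally reported even when two Tm
values are.  Replicates are averaged on a shared grid before analysis
(each experimental point is itself the average of three scans).

## Thermal difference spectra

TDS = spectrum(95 degC) − spectrum(4 degC) over 220–320 nm, normalized so
the maximum change is exactly +1 (an all-non-positive difference is an
error, not a spectrum).  Classification: **i_motif** if the global
positive extremum lies within 240 ± 10 nm and the 295 ± 10 nm window dips
to −0.2 or below; **random_coil** if nothing in 280–320 nm reaches −0.2;
**other** otherwise.  The ±10 nm windows and −0.2 depth are tolerances
added here — the published signature gives peak positions only.

## CD pH titrations

Ellipticity at 288 nm vs pH is fitted with a symmetric four-parameter
logistic in base-10 (Henderson–Hasselbalch-like):

    E(pH) = e_u + (e_f − e_u) / (1 + 10^(slope·(pH − pH_T)))

pH_T — the transitional pH at which the sequence is 50% folded — is the
analytic inflection of this model, so it is invariant under affine
transforms of the ellipticity scale (fitting raw or normalized data gives
the same pH_T).  Initialization takes the plateaus from the two most
acidic / most basic points, pH_T from the point nearest the midpoint, and
multistarts the slope over {1, 2, 4}; best RMSE wins, ties to the smallest
slope.  pH_T is bounded to the data range ± 1 unit.  A fit whose plateau
separation is under 3× its RMSE raises "no transition".  Summary tables
round pH_T to 0.1 (matching how it is conventionally reported); full
precision is kept internally.

CD scans are classified by band positions: folded i-motif +288/−260 nm,
unfolded +273/−250 nm, each with ±6 nm windows (the two positive peaks are
15 nm apart, so ±6 keeps the windows disjoint).

## The bundled oligonucleotide panel

`datasets` carries two published plain-text tables: the model library
C_n(T_x C_n)_3 (tract lengths 1–10, loop lengths 1–4, plus the human
telomeric C-strand control) with Tm/Ta at pH 5.5 and 7.4 and pH_T, and the
33 genomic candidate oligonucleotides (23–116 nt) with Tm/Ta at pH 7.0 and
pH_T.  One model entry's printed notation is internally inconsistent with
its printed length and is stored under the consistent reading
(C5(T3C5)3, 29 nt).  Where two melting transitions are printed both are
kept; stability analyses use the larger (final unfolding) Tm.

## Synthetic data: what it emulates and what it does not

All generators are pure functions of their arguments including the seed.

* **Genomes.** i.i.d. backgrounds with planted motifs.  Loop bases of
  plants are drawn from {A, T} and plants get one-base non-tract flanks so
  the planted coordinates are exactly what the scanner must report; the
  background is re-drawn (plants kept) in the rare event a spurious rule
  match appears.  Real genomes are not i.i.d. — CpG islands, repeats and
  compositional heterogeneity are absent — so scanner tests prove
  correctness of the pattern matching, not realism of genome-wide counts.
* **Annotations.** Uniform TSS placement and random GO assignment; no
  gene clustering, no GO graph structure.
* **Melting curves.** Two-state van't Hoff folding with linear folded /
  unfolded baselines, an additive Gaussian noise of 0.002 AU, and an
  annealing hysteresis modelled phenomenologically as a downshift of the
  apparent midpoint (real hysteresis is kinetic, i.e. scan-rate
  dependent; this generator is an equilibrium stand-in).  The default
  apparent enthalpy is −700 kJ/mol, giving 10–90% transition widths of
  roughly 4–6 degC: the sharp cooperative regime in which transitions
  8 degC apart remain separable by the first-derivative method under the
  25%-prominence criterion at the stated noise level.  Measured i-motif
  van't Hoff enthalpies are often shallower, and correspondingly broad
  experimental transitions this close together would *not* be reliably
  resolved — the closed-loop resolution figures characterize the detector
  under sharp-transition conditions, not all chemistries.  theta(Tm) = 0.5
  exactly; temperatures are converted to kelvin internally with
  R = 8.314 J/(mol K).
* **Spectra.** Gaussian-band templates (1 nm grid, 220–320 nm for
  absorbance pairs; 0.5 nm, 200–320 nm for CD) carrying the i-motif or
  random-coil signatures; real band shapes are not Gaussian and real
  baselines drift.
* **Titrations.** The logistic model itself plus Gaussian noise on the
  default experimental grid (pH 4.0–8.0 in 0.5 steps), so titration tests
  measure estimator behaviour under the model, not model misspecification.

## Problem sizes used in the test suite

Scanner correctness is checked against exhaustive brute-force enumeration
on 1,000 random sequences (length <= 200, cytosine-skewed so matches
occur) and on a 200 kb i.i.d. genome at loop_max 7/13/19; the exhaustive
expectation oracle enumerates all 4^8 length-8 sequences for a miniature
two-tract rule.  Recovery statistics use 200 melting curves, 100
titrations, 100 two-transition pairs, 50 seeds per spectral class, and
200 null replicates for FDR control.

## Known limitations

* The scanner assigns no score; hits are pattern matches, not ranked
  predictions.
* The canonical register (shortest loops, leftmost) is one of several
  defensible conventions; tract/loop statistics for sequences with long C
  runs depend on it.
* The chi-squared null treats hits as independent single-base events;
  clumping of motifs inflates significance slightly.
* Genome-scale published counts (thousands of hits, promoter overlap
  fractions) require the reference human genome and are not recomputed by
  the test suite; the pipeline is validated desk-scale on synthetic
  genomes and the printed oligonucleotide panel.
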