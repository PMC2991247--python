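# Methods

This note records the statistical model, the defaults and why they were
chosen, the numerical decisions, and what the synthetic benchmarks do and do
not demonstrate.

## Coordinates and data model

All coordinates are 0-based, half-open (BED convention) internally; reports
convert to 1-based closed form only at print time.  Integration sites and
controls are points — a BED interval given as a site collapses to its
midpoint, since the analysis is built on distances between a site and marker
positions.  ChIP-seq peaks are scored intervals with a summit; when a peak
file carries no summit column the interval midpoint stands in, because many
published peak sets ship without summits.  Strand is parsed but ignored:
the within-window criterion is symmetric on the chromosome.  Distances can be
measured to peak summits (default) or to peak boundaries (0 inside the
interval); both modes are exposed because published analyses are split on
this point.

## Matched controls

Integration sites are recovered by restriction digestion and ligation-mediated
PCR, so the observable sites are constrained by the distance to the nearest
recognition site of the cloning enzyme.  The control model reproduces exactly
that constraint and nothing else: for each experimental site, its distance
d to the nearest recognition site on its own chromosome is measured, and each
of its ρ controls (default ρ = 10) is placed at distance exactly d from a
recognition site drawn uniformly over the whole genome, with a random sign.
Genome-wide drawing is the default (a per-chromosome flag exists) because the
digest bias is a property of the enzyme, not of chromosome identity; the sign
is symmetric because nothing in the protocol distinguishes upstream from
downstream.  Controls falling outside a chromosome are resampled (new
recognition site, new sign) rather than clipped, so the matched distance is
preserved exactly; after 1000 failed retries — only possible on pathological
toy genomes — generation aborts with an error.  All randomness flows from one
integer seed through `numpy.random.default_rng`, and each control records its
source site, chosen recognition site and signed offset, so cross-validation
can partition controls together with their source sites.

## The association score

At window w (default 2000 bp, inclusive: "within 2 kb" reads as d ≤ w):

    tp = experimental sites with d ≤ w     fn = V − tp
    fp = control sites with d ≤ w          tn = C − fp

Sites on chromosomes with no marker peak count as beyond-window — the
conservative choice, never inflating tp.  The false-positive count is
normalized to the control ratio, fp′ = fp·V/C, making Precision — and hence
the F score — independent of how many controls were generated.  The score is
the van Rijsbergen F with β = 0.5:

    P = tp/(tp + fp′),  R = tp/V,  F = (1 + β²)PR / (β²P + R)

Under this normalization a marker covering every base of the genome (the
null predictor) has fp′ = V and therefore P = 1/2, R = 1 exactly; plugging
those into the β = 0.5 formula gives F = 5/9 ≈ 0.56.  We keep the standard
formula and document the baseline as ≈ 0.56; the conventional significance
band for calling a marker associated remains F ∈ (0.5, 1].

Significance is the two-sided Fisher exact test under the point-probability
criterion (sum over all tables with the observed margins whose probability
does not exceed the observed table's, with the customary 1 + 10⁻⁷ relative
tolerance) — the dominant convention for "exact two-sided".  The sum is
carried in log space (`logsumexp` over `hypergeom.logpmf`), so p-values far
below the double floor (10⁻³⁰⁸) remain meaningful; reports print both the
float and a "<1E-350"-style string, flooring the printed exponent at −350.
For tables with more than 10,000 observations and all expected counts ≥ 5
the χ² approximation is used instead (df = 1 survival computed through
`log_ndtr`, again finite arbitrarily far into the tail).  Degenerate margins
(an empty row or column) return p = 1, flagged.  Multiple testing uses
Bonferroni (multiplication in log10 space, capped at 1), with n tests equal
to the number of markers in the batch.

## Metric bench

AUC is computed in the rank (Mann–Whitney) form — the probability that a
random site distance beats a random control distance, ties ½ — which equals
the threshold-sweep ROC area.  AUPR integrates precision over recall by
trapezoid across all distance thresholds, with precision on the same
normalized-fp′ scale as the F score so the two live on one axis.  The odds
ratio applies the Haldane–Anscombe +0.5 correction when any cell is zero
(flagged); mutual information is the empirical 2×2 plug-in estimate in bits
with 0·log 0 = 0; difference of proportions is tp/V − fp/C.

Rankings are strict-inequality N×N indicator matrices (ties score 0 both
ways); the significance reference uses raw −log10 p capped at 350, matching
the printed reporting floor (capping can only affect rankings among markers
that all sit at the floor).  Agreement with significance is

    D = 1 − Σ_{i≠j} |M_X[i,j] − S[i,j]| / (N(N−1))

which is 1 exactly when the strict rankings coincide and 0 for a fully
reversed strict ranking.  The published definition of D is not machine-
readable in our sources; this reconstruction satisfies every stated
constraint and is what the discordance grids visualize.

## Supermarker

Each marker M_j with peak set Γ_j becomes a density

    p(M_j = x) = (1/|Γ_j|) Σ_{peaks} Normal(x; summit, σ_j²)

with kernel scale σ_j set by policy: `width` (default, σ = mean peak width in
bp), `sqrt-width`, or `fixed:N`.  "Variance tied to the average peak size"
is dimensionally ambiguous; σ = mean width puts the kernel support on the
10²–10³ bp scale of real ChIP-seq peaks, which is compatible with the 2 kb
window optimum, so it is the default.  Markers combine as a mixture

    p(V = x) = K Σ_j λ_j p(M_j = x)

with λ_j = F_j/(1 − F_j) by default (pluggable: linear F, log-odds) and K
normalizing Σλ = 1.  The odds form is monotone in F, vanishes as F → 0 and
diverges as F → 1, consistent with a first-order weighting by marker
quality; it requires F_j strictly inside (0, 1), and candidates outside that
range are excluded with a warning.

Composite peaks are local maxima of the mixture on a grid (default 10 bp,
clamped to min σ/4 so no kernel is under-resolved), restricted to the union
of component-peak ±4σ neighborhoods — outside that support the density is
numerically negligible.  Maxima closer than min σ merge keeping the larger
(the merge radius is a reconstruction; unmerged near-duplicates would only
pad the ranking).  Reported positions are integers and amplitudes are
re-evaluated at the reported position, so a reported peak is exactly the
density value there.  Peaks are ranked by amplitude; the threshold k* is the
arg-max of the training F of the top-k set over all k (all k when ≤ 500
peaks, else ~50 log-spaced values refined around the best), with ties going
to the smallest k — favoring precision.  The subset of candidate markers is
chosen by exhaustive search over all non-empty subsets (capped at 8
candidates = 255 fits; pre-filter by single-marker F beyond that), ties
preferring fewer markers, then fewer peaks.

The fitted model is a Gaussian mixture over Γ* with per-peak weight
proportional to composite amplitude, truncated to chromosome bounds and
renormalized so the genome-wide integral is exactly 1.  Locus probabilities
are closed-form CDF sums (no quadrature error); density/site-count
correlation aggregates both over non-overlapping windows (default 10 kb)
tiling each chromosome, dropping the ragged tail window, and reports Pearson
r.  Models serialize to JSON with the layout, Γ*, σ, the marker subset and
all fitting metadata; a round trip reproduces locus probabilities to
10⁻¹² or better.

Cross-validation shuffles sites into k folds (sizes differing by ≤ 1) with a
seeded permutation; every control travels with its source site, keeping
folds independent; per fold the marker F scores, composite weights and
threshold are re-fit on the training part and scored on the held-out part.
A separate entry point (`evaluate_model`) scores a frozen model against any
external site/control pair for cross-dataset transfer.

## Mandala plots

Angle is genomic position on the circularized scope (one chromosome, or all
chromosomes concatenated gap-free in layout order, arc length proportional
to length); radius is r = R_max·(1 − log10(max(d, 1))/6), clipped to
[0, R_max] — the contour at 1 bp, the center at ≥ 1 Mb.  Distances below
1 bp clamp to 1 before the log.  Sites within the window draw blue, beyond
it red; the window radius is drawn as a dashed circle; optional supermarker
shading fills the annulus between the window circle and the contour with
gray linear in angular density mass (the published shading transfer function
is not described; linear is the simplest monotone choice).

## Synthetic data

The generator emulates the structure of integration-site studies on a toy
genome: default 2 chromosomes × 5 Mb — large enough for 10³ peaks and
5×10³ controls, small enough for seconds-scale tests.  Restriction sites are
a Poisson process at 1/256 bp (the density of a 4-cutter).  Peak widths are
log-normal with arithmetic mean 400 bp (log-sd 0.4), the ChIP-seq scale;
summits are uniform, or clustered for testing correlation nulls.  Integration
sites plant a fraction q at (random target summit + Normal(0, s²)) with the
rest uniform; offsets are Normal because that makes the achievable
within-window fraction analytic, wi(w) = q·P(|N(0,s)| ≤ w) + (1−q)·(genome
fraction within w of a summit), and the generator keeps per-site
planted/background labels so tests can verify recovery exactly.  The default
study condition used by the stability tests is V = 500, q = 0.7, s = 500 bp,
ρ = 10.  The gene scenario places sites uniformly inside non-overlapping
20 kb gene bodies against a one-summit-per-TSS virtual marker.

What the generator does **not** model: chromatin-state co-occurrence between
markers, sequence composition beyond restriction motifs, peak-width/summit
correlation with signal strength, mappability gaps, or partial digestion and
fragment-size selection in cloning.  Passing tests therefore demonstrate the
correctness and statistical behavior of the estimators under a clean planted
model, not biological performance on real ChIP-seq data.

## Problem sizes and runtime choices

The test suite runs at desk scale by design: genomes of 10 Mb, 10²–10³
peaks per marker, V of 120–500, ρ of 3–10.  The Fisher oracle comparison
covers 600 randomized plus edge-case tables with V + C ≤ 200 against exact
integer-arithmetic enumeration at 10⁻¹² relative error (the support
enumeration is exhaustive per table; the table sample is randomized because
enumerating every possible table of that size is ~10⁸ oracle sums).
Recovery checks pool 5 seeds and test at the two-sided 3σ level, using the
exact binomial test where the expected beyond-window count is below one
event and the normal SE would be invalid.

## Known limitations

* The mixture-weight form λ = F/(1−F) and the D agreement formula are
  principled reconstructions (documented above), not transcriptions.
* The χ² route is an approximation used only for large, well-populated
  tables; in extreme tails it can differ from the exact test by orders of
  magnitude in log p, which is why the exact route is the default.
* Composite-peak extraction is grid-based; positions are accurate to the
  grid step (≤ min σ/4, default 10 bp).
* `window_sweep` recomputes nothing per window (distances are computed
  once), but `fit_supermarker` refits the full pipeline per subset and can
  be slow beyond ~8 candidates × 10³ peaks.
* Boundary-mode distances treat the interval end as the last covered base;
  adjacent intervals merge before distance computation.
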