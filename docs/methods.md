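# Methods

`gametoco` models sex-specific meiotic crossover (CO) formation in maize
and re-implements, as tested library code, the analysis chain that goes
from single-gametophyte genotype matrices to a recombination landscape and
from CO position sets to mechanistic interference parameters.

## Beam-Film simulation (`bf_sim`)

The Beam-Film (BF) model treats CO designation as stress and stress
relief along a bivalent. The simulator works on the unit interval of
normalized genetic length and is controlled by nine parameters:

| parameter | meaning | default | units |
|---|---|---|---|
| N | mean precursor count per bivalent | 16 | count |
| E | spacing evenness (1 = even grid, 0 = i.i.d. uniform) | 1 | — |
| B | count dispersion (1 = fixed, 0 = Poisson) | 1 | — |
| Y | probability a precursor is active | 1 | probability |
| A | sensitivity skew exponent (u^A law) | 1 | — |
| Smax | starting stress level (firing threshold is 1) | 3.5 | — |
| L | interference spread distance | 0.3 | fraction of genetic length |
| M | class I maturation probability | 1 | probability |
| T2prob | per-precursor class II probability | 0 | probability |

Precursor counts follow `round(B*N + (1-B)*Poisson(N))`, which
interpolates between Poisson dispersion and a fixed count with mean N for
every B. Positions at evenness E jitter a regular grid by a centred
uniform offset of half-width (1 − E/2)/2 per grid cell — a quarter of a
cell at E = 1 (a jittered even grid, never an exact lattice) widening to
stratified-uniform as E → 0; E = 0 switches to exactly i.i.d. uniform
positions (the stratified law approaches, but does not equal, the i.i.d.
law, a documented convention). Keeping jitter at E = 1 matters: lattice
positions make inter-CO distances lattice multiples, a visible artifact
in renewal-model fits.
Sensitivities are `u^A` for `u ~ Uniform(0,1)`: A = 1 is uniform and
larger A skews precursors toward insensitivity.

Designation is greedy: the active precursor with the highest potential
`Smax * s` fires if its potential exceeds 1, after which every remaining
potential on that bivalent is multiplied by the relief factor

    R(d) = 1 − exp(−(d/L)^4)

at distance `d` from the new CO, and the process repeats until no
potential exceeds 1. Exact ties designate the lowest index (a
measure-zero event under continuous sensitivities).

**Why the relief exponent is 4.** With a first-order exponential profile
`1 − exp(−d/L)` the distance at which a suppressed precursor re-crosses
the firing threshold is `−L·log(1 − 1/(Smax·s))`: the suppression radius
rescales with the stress level. Because fitting calibrates Smax to match
the observed CO count, that rescaling makes CoC curves at a matched count
almost independent of L — the interference distance would be
unidentifiable from data. A steep shoulder (`(d/L)^4` inside the
exponential) pins the suppression radius at ≈ L regardless of Smax, so
the CoC curve's crossing distance tracks L (measured: Distance_CoC=1 =
0.32/0.39/0.45/0.47 for L = 0.25/0.35/0.45/0.55 at a matched mean of
2.27 COs per bivalent), and the long-distance CoC fluctuations above 1
(apparent negative interference) emerge as a packing effect. The exponent
is a fixed shape constant of the package, not a fitted quantity.

Designated COs mature into class I COs independently with probability M;
immature designations are retained with labels so maturation-inefficiency
accounting (designated = mature + immature) stays exact. Active
non-designated precursors become non-interfering class II COs with
probability T2prob. The chromatid transform assigns each transmissible
bivalent CO (mature class I or class II) to one of the four
chromatid-pair combinations with probability 1/4; a sampled single
chromatid therefore carries each CO independently with probability 1/2,
halving the expected count and preserving both CoC diagnostics.

Randomness: every operation derives per-purpose Philox streams from the
root seed, each consumed in bivalent order with fixed-size blocks, so
enlarging `n_bivalents` appends new bivalents without reshuffling earlier
ones.

## CoC diagnostics (`interference_stats`)

CO positions are histogrammed into equal-width intervals (default 15;
the interval count is a package convention balancing curve resolution
against pair-count starvation at ~2–4 COs per bivalent). CoC(i,j) is the
fraction of samples with a CO in both intervals divided by the product of
the single-interval fractions, using presence (≥ 1 CO), with undefined
entries (an interval no sample hits) excluded rather than imputed. The
curve averages CoC over interval pairs at each center-to-center distance.

Two scalars summarise a curve: `coc_at_min_distance` (the value at the
smallest distance bin; rises with the class II load T2prob) and
`distance_coc1` (the first upward crossing of 1, linearly interpolated;
tracks L; flagged undefined if the curve never reaches 1). Distances are
measured between interval centers, and no smoothing is applied before
reading the crossing.

The bootstrap procedure subsamples a large CO set without replacement
(defaults: 320 samples × 100 replicates), computes both features per
replicate, forms all C(100,2) = 4950 pairwise absolute differences, and
reports the percentage of those D-values strictly below an observed
between-group D-value — the confidence that the observed difference
exceeds subsampling noise.

The gamma two-pathway model places a fraction p of COs by a homogeneous
Poisson process and the rest by a stationary gamma renewal process with
shape nu and matched mean rate; stationarity is approximated by starting
the renewal chain ten mean gaps before the observed interval. Fitting is
maximum likelihood over a (nu, p) grid against simulated inter-CO
distance distributions histogrammed at bin width 0.02 with a 0.5
pseudo-count per bin.

## Beam-Film fitting and CMI (`param_fit`)

An observed CO set is summarised by its CoC curve, mean CO count and
count histogram. The fit objective is a weighted sum (default weights
1,1,1) of the pair-count-weighted mean squared CoC-curve deviation over
shared distance bins, the squared mean-count difference, and the
total-variation distance between count histograms. Pair-count weighting
keeps the curve term focused on the short/mid-distance region where CoC
is well estimated; distant bins average very few interval pairs.

The search grids L (0.05–0.60, step 0.05) and T2prob (0–0.10, step 0.01;
M on 0.5–1.0, step 0.05 when free) and never searches Smax: the
designated class I mean depends on (L, Smax) but not on T2prob or M, and
the transmissible mean obeys `mean = M*des + T2prob*(Y*N − des)`, so one
designation-versus-Smax profile per L (9 probe points, monotone
interpolation) calibrates Smax for every (T2prob, M) cell. A half-step
local refinement follows the coarse grid, and an optional two-stage
re-ranking re-scores the top candidates at a larger simulation size with
a fresh seed, which suppresses argmin noise in nearly flat directions of
the objective. Chromatid-level data are matched against
chromatid-transformed simulations.

CMI detection contrasts a constrained fit (M = 1) with a free-M fit and
refits the three alternative count-reducing explanations (A: 1→6,
Y: 1→0.5, N: 16→9, all at M = 1). CMI is flagged when the free-M fit
improves the joint objective by more than a noise margin (15%), lands at
M < 1, and no alternative refit reaches the free fit's joint objective —
the alternatives can reduce the count but cannot rescue the fit. Curve
components of all candidates are re-measured at 2× the evaluation size
with a common seed and reported for inspection. The reported
overprediction re-simulates the free fit with maturation forced
complete: on CMI data the designated load exceeds the observed count.
The margin and the strict alternative comparison make the detector
conservative: maturation-complete data is essentially never flagged (the
free fit collapses onto M = 1), at the cost of missing genuine CMI in
roughly one run in five at the validation sizes, when the
sensitivity-skew alternative happens to mimic thinning's count
overdispersion.

Identifiability note: at high CO density the interference distance is
bounded below sharply but bounded above only weakly once L approaches the
typical inter-CO spacing (suppression beyond the spacing is rarely
observable). The two-stage re-ranking plus the ~2-fold separation between
the female and male fitted L values keeps recovery within one grid step
under the package's validation conditions.

## CO calling and landscape (`co_landscape`)

Bins are maximal runs of consecutive same-parent SNP calls; missing calls
are skipped, never run-breaking, because sparse single-cell coverage
makes gaps uninformative. Runs below `min_snps` (default 20) are absorbed
into their flanks and logged. Two filters follow:

* shared bins — identical boundaries within ±2 union-SNP indices in ≥ 3
  samples mark residual parental heterozygosity and are removed in every
  carrier; bins anchored at a chromosome end are exempt (their boundaries
  coincide across samples trivially);
* short bins — bins spanning fewer than `short_bp` base pairs (default
  1.2 Mb; 1.5 Mb is the alternative documented threshold) are flagged and
  by default excluded from CO calling.

One CO is called per junction between adjacent opposite-parent retained
bins, localised to the interval between the flanking supporting SNPs,
with the midpoint as the point position.

The windowed map uses the convention `window cM = 50 × (CO count /
n_samples)` so that the summed map length satisfies the counting identity
`total cM = 50 × mean COs per gamete`; cM/Mb divides by the actual window
width (trailing windows are partial). Windows tile from the chromosome
start. Hot regions are windows above 1 cM/Mb; a hot window is
sex-preferred at a ≥ 2-fold rate ratio (a zero in the other population
counts as preferred), and swapping the two tracks swaps the labels
exactly. Arm-normalized positions divide the distance from the telomere
(configurable to the centromere) by the arm length, excluding COs inside
the centromere interval. The CO-to-gene profile uses a metagene
coordinate (0 at gene start, 1 at gene end, flanks rescaled by the same
gene's length), restricted to COs resolved below 10 kb, against n_null
uniformly simulated position sets pooled for a two-sided
Kolmogorov–Smirnov test.

## Synthetic data (`synthetic_data`)

The generator emulates the downstream structure of single-gametophyte
sequencing with no external data. Defaults: 10 chromosomes with
maize-proportional lengths totalling 100 Mb (a 1/21-scale genome), SNPs
at 73 bp median spacing via exponential gaps (~1.4M SNPs — the study-like
informative-SNP count per sample at desk scale), random non-overlapping
genes (30 per Mb, mean 3 kb), centromeres at 0.45 of each chromosome, a
telomere-inflated genetic map (density `1 + 3(2x−1)^2`, piecewise-linear
and exactly invertible), 100 gametes, and i.i.d. call dropout at rate 0.6
(≈ 40% coverage, the female-like value; male-like runs use 0.71).
Gametes take one sampled chromatid per bivalent (each real gametophyte is
one meiotic product). Artifact injection provides the two failure modes
the filters must handle: a fixed residual-heterozygosity segment flipped
at identical coordinates in a configured number of samples, and isolated
opposite-parent false bins of a configured SNP length.

What the generator does not model: correlated (MDA amplification-bias)
dropout, genotyping errors at single-SNP scale, structural variation, and
chromosome-specific genetic map shapes. Passing round-trip tests
therefore demonstrate the pipeline's logic (run/filter/junction rules,
map identities), not robustness to every real-data failure mode.

## Problem sizes

Tests and the acceptance script use scaled problem sizes chosen as the
package's validation conditions: 5000 bivalents for simulator identities
(the recommended simulation size), 12,000-bivalent observed sets with
6000-bivalent evaluations (re-ranked at 36,000) for headline parameter
recovery, 2000-bivalent observed sets with 1000-bivalent evaluations for
the 100 paired sex refits, 4000-bivalent sets for CMI detection, a
4-chromosome 40 Mb genome with 100 gametes for the pipeline round-trip,
1000-sample sets for gamma-model parameter recovery, and 8000-chromatid
sets for the reported sex-contrast gamma fits (the non-interfering
proportion p is only weakly identified below that size).

## Known limitations

* The relief-profile exponent (4) and the firing threshold (1) are fixed
  conventions; only their combination with Smax and L is identified.
* Equivalence with the original MATLAB Beam-Film program is not asserted;
  parameters share semantics (N, E, B, Y, A, Smax, L, M, T2prob) but not
  necessarily numerical values.
* The fit explores L and T2prob (optionally M) with the precursor-array
  parameters fixed; N trades off against T2prob (refitting with larger N
  lowers T2prob while the class II load stays constant), so class II
  conclusions should be stated as loads, not probabilities.
* Physical (SC-length) coordinates are out of scope; all interference
  statistics are computed on normalized genetic length.
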