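# Methods

This note documents the models and procedures implemented in `fjordtrace`,
the assumptions behind them, the defaults of the synthetic-study generator,
and the numerical choices that matter when reproducing or extending the
analysis.

## The study design being modelled

The package targets an integrated field design for comparing two sympatric
Atlantic cod ecotypes — a resident "Fjord" (FJ) form and an oceanic "North
Sea" (NS) form — inside a narrow ~9 km fjord:

1. fish are caught, genotyped at a 27-SNP diagnostic panel, assigned to
   ecotype, and tagged with acoustic transmitters;
2. moored receivers log tag transmissions: paired gate transects near the
   outlet (an outer line defining departure from the system and a secondary
   line ~500 m further in) plus a dense array covering the basin during a
   summer–autumn window;
3. muscle biopsies are analysed for δ13C and δ15N;
4. movement metrics (residence distance, home range, emigration) and
   isotopic niche metrics are compared between ecotypes.

## Telemetry processing

**Position averages.** Within each UTC-aligned 30-minute period, a fish's
position is estimated as the detection-count-weighted mean of the
coordinates of the receivers that logged it (a short-term center of
activity). This estimator is deliberately coarse: it shrinks positions
toward receivers and therefore *underestimates* true space use; home ranges
derived from it are comparable between groups processed the same way, not
absolute. Distances are measured as along-axis arclength from the position's
orthogonal projection onto the fjord axis to the outlet, because the basin
is elongated; lateral offsets carry no distance information.

**Fate classification.** A fish has departed when its last detection sits
on the outer transect and nothing follows. Absence gaps after an
outer-transect detection are classified by duration: re-detection within
48 h is a *short excursion*; 48 h or longer a *prolonged departure with
return* (the return stamped by the first outer-transect detection back);
no re-detection before the study end is *permanent*. Two thresholds are not
fixed by the design and are package choices, both configurable:

* `min_absence` (default 6 h): the minimum silence after an outer-transect
  hit that counts as an exit at all. Without it, a fish loitering at the
  gate would log dozens of spurious "excursions" between consecutive pings.
* `resident_gap_max` (default 7 d): a fish whose record dries up away from
  the outer transect for longer than this before study end is *lost*
  (death, tag shedding, undetected exit, or removal — no cause attribution
  is attempted).

**Gate order QC.** Outward passages should hit the secondary transect
before the outer one, and returns the reverse; violations are reported per
tag and timestamp as an array-efficiency diagnostic.

## Home ranges

95% minimum convex polygons, adehabitat-style: the floor(0.95·n) positions
nearest the arithmetic centroid are kept (ties broken by input order), the
convex hull is taken by Andrew's monotone chain, and the shoelace area is
converted to hectares. Sedentary fish pinned to a single receiver yield
degenerate zero-area polygons; these are reported as 0 ha with a flag, not
errors, because they genuinely occur. Fish with fewer than 5 positions
(configurable) are excluded.

## Genetic assignment

The assignment likelihood is the Rannala–Mountain posterior-predictive
form. Per locus, with reference gene-copy counts `n_a` (total `n`) and a
symmetric Dirichlet(1/k) prior whose k counts the alleles observed at that
locus *across all samples*:

    P(aa) = (n_a + 1/k)(n_a + 1 + 1/k) / ((n + 1)(n + 2))
    P(ab) = 2 (n_a + 1/k)(n_b + 1/k) / ((n + 1)(n + 2))

Missing loci contribute nothing. Multilocus log-likelihoods against the two
reference populations are converted to percentage scores by log-sum-exp
(no underflow at 27 loci); an individual is labelled only if its top score
strictly exceeds 80% and it was typed at ≥ 20 loci, with the loci filter
taking precedence in the recorded reason. Study individuals are not members
of the reference panels, so no leave-one-out correction applies. Exact
ties can never clear a >50% threshold and fall to "unassigned".

## Isotope processing

Run sheets interleave Gel-A gelatine standards (known δ15N = 5.4‰,
δ13C = −21.8‰) with duplicate muscle samples. Per element, ordinary least
squares of the standards' measured values on run position gives an offset
and a drift slope; every measurement at run i is corrected by subtracting
the fitted value minus the known value. The correction is exact for any
truly linear drift and idempotent; corrected standards regress to the known
values, and their residual spread is reported as a run-sheet QC statistic.
Duplicates are averaged after correction. Run position counts standards and
samples alike (ordinal position in the sheet).

## Isotopic niche metrics

Because the δ15N baseline varies along the fjord, niche metrics are
computed on residuals from one pooled OLS per element of isotope value on
mean residence distance (per-ecotype fitting is available but not the
default — the biplot compares ecotype clouds around a common baseline).
On the bivariate (residual δ13C, residual δ15N) cloud:

* **SEA** = π√det(S), with S the n−1 sample covariance — the area of the
  1-SD Mahalanobis contour (~40% coverage standard ellipse);
* **SEAc** = SEA·(n−1)/(n−2), the small-sample correction;
* **TA** = convex hull area;
* **overlap** = area of intersection of the two SEAc-scaled ellipses
  (boundary radius inflated by √((n−1)/(n−2))), computed by discretizing
  each boundary with 1024 vertices and clipping the convex polygons.
  Discretization error is second order (≈ 2π²/3n² relative, ~10⁻⁵ at 1024
  vertices) and quarters with each doubling of the vertex count.

Pooled-versus-group hull ratios are reported to 2 decimals. Pearson
correlations of the corrected values per ecotype are reported as a QC
statistic (computed on corrected values).

## Inferential models

* Home-range size: Gaussian GLM of log area on ecotype, length, and their
  interaction; two-sided t tests on n−p df.
* Isotope values: Gaussian GLM on ecotype, distance, and ecotype×distance.
  Interactions with p ≥ 0.05 are removed by backward elimination, one at a
  time, mirroring the design's covariate-dropping rule. Collinearity is
  screened with VIF = 1/(1−R²_j).
* Residence distance over time: gamma GLMM with log link —
  y_ij | b_i ~ Gamma(α, mean exp(x_ijᵀβ + b_i)), b_i ~ N(0, σ_b²) — with a
  random intercept per fish (fish identity is the only plausible grouping
  for repeated daily positions). The marginal likelihood integrates the
  scalar random effect by a Laplace approximation at the per-group
  conditional mode, found by a vectorized Newton iteration (the mode
  equation is scalar and concave, so convergence is fast and safe).
  (β, log α, log σ_b) are maximized by L-BFGS-B; Wald z tests come from the
  central-difference observed information. Laplace is accurate for a single
  scalar random effect; adaptive quadrature would change third-decimal
  digits at these shapes. With σ_b fixed at 0 the model reduces exactly to
  a gamma GLM and matches IRLS estimates to ~10⁻⁸, which is used as an
  internal cross-check.
* Ecotype coding: Fjord is the reference level in the residence model
  (is_ns = 1 for North Sea); the isotope models use is_fj = 1 so the
  ecotype coefficient is the Fjord offset. Coding is explicit in every
  output table. P-values are reported unadjusted.

## The synthetic-study generator

The generator produces every pipeline input with the statistical structure
the analysis assumes. Defaults are the study conditions:

| parameter | default | meaning |
|---|---|---|
| n_fish / p_northsea | 72 / 0.43 | tagged cohort and NS share |
| emigration_prob | NS 0.42, FJ 0.07 | per-individual departure probability |
| excursion_prob | 0.08 | one short (<2 d) out-and-back trip |
| transmit_interval_s | (30, 90) | i.i.d. uniform gaps, mean 60 s |
| max range / half range | 130 m / 65 m | logistic detection decay, scale 14 m |
| n_loci / differential | 27 / 0.3 | SNP panel and per-locus |p_FJ−p_NS| |
| ref_sample_size | 200 | gene copies per reference population |
| δ15N slope | −0.135 ‰/km | baseline change per km of distance to outlet |
| δ13C slope | −0.038 ‰/km | same, carbon |
| ecotype offsets | +0.389 ‰ N, +0.626 ‰ C | Fjord shift |
| isotope_sd | 0.55 ‰ | between-fish residual spread |
| drift_per_run | 0.01 ‰ | linear instrument drift per run position |

Movement is a discrete-time mean-reverting (AR(1)/discrete OU) walk around
a per-fish home center (lognormal movement scale, median 110 m), clipped to
the basin; the stationary process is simulated exactly via a linear filter.
Home centers sit near moored receivers, which mirrors the observational
reality that sedentary fish are only seen near receivers and yields
hectare-scale, right-skewed home ranges. Departing fish swim down the
channel past both gate lines (hugging the channel side where the gate
receivers are moored, so passage detection is near-certain at default
transmit rates) and fall silent beyond the outlet; a small fraction return
months later. The detection model is logistic in distance with probability
< 0.01 at the stated 130 m maximum and zero beyond it; receivers only log
while active (the array only during its deployment window). All randomness
derives from per-purpose child streams of one seed; identical
configurations are bit-identical.

What the generator does **not** emulate: tides and salinity structure,
depth use and 3-D positioning, fishing or natural mortality, tag shedding,
seasonally varying behavior, and spatially correlated detection noise.
Passing tests therefore demonstrate the *analysis chain* is correct under
the stated statistical assumptions, not that those assumptions exhaust
real fjord data.

## Problem sizes and verification scales

The calibration experiments use scales chosen to make their Monte-Carlo
error informative:

* OLS coverage: 500 replicates of n = 50 fish; coverage of the generator
  truths is required to land in [92%, 98%] around the nominal 95%.
* Gamma GLMM: 100 replicates of 50 fish × 180 days; the medians of the
  intercept, time slope, and interaction must fall within 10% of truth.
  The ecotype main effect is checked at a wider band: it is identified by
  only ~21 NS fish per replicate, so its between-fish sampling noise is an
  order larger than the other terms'.
* Emigration classification: 10,000 fish run through the full track →
  detection → classification path on a compressed 10-day horizon with
  4–12-minute transmit gaps (classification depends on gate passages and
  continued residence, not on horizon length); classified departure
  fractions must fall within 3 binomial SE of the configured
  probabilities.
* Assignment: a 10,000-individual cohort at differential 0.3 (27 loci,
  200 reference copies) gives ~98.8% assigned and ~99.6% accuracy among
  assigned; this frozen Monte-Carlo value anchors the genetics tests.

## Degenerate inputs and tie-breaking

Collinear point clouds give zero-area hulls and degenerate (zero-SEA)
ellipses with flags rather than exceptions. MCP peeling breaks distance
ties by stable input order. Rank-deficient model designs raise with the
aliased columns named. Assignment with every locus missing returns
log-likelihood 0 for both populations (scores 50/50, unassigned). The
drift fit requires ≥ 2 standards at distinct run positions.

## Known limitations

* Position averages bias home ranges downward; 0-area MCPs are common for
  fish pinned to one receiver.
* The fate classifier implements the gate rule literally; a fish that dies
  at the gate after an outer-transect ping is indistinguishable from an
  emigrant.
* The GLMM's Laplace approximation assumes a scalar random intercept; no
  random slopes or temporal autocorrelation structures are offered.
* Lipid normalization, trophic discrimination factors, and Bayesian
  standard-ellipse posteriors are out of scope.
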