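# Methods

This package implements a comparative analysis of three eggshell surface
traits — areal surface roughness (S_a, nm), wettability (sessile-droplet
contact angle, degrees) and calcium carbonate content (% of dry shell
mass) — across bird species that are obligate brood parasites, their
hosts, and non-parasitic relatives. It answers two questions within a
phylogenetically controlled framework: do parasitic species differ
overall from non-parasitic species in these traits, and are parasitic
eggs more similar to their hosts' eggs than to random non-parasitic eggs
(convergence on the shared nest environment)?

## Trait derivation

**Surface roughness.** A profilometric height map (a rectangular grid of
surface heights in nm; the instrument resolution this targets is
768 × 576 pixels) is detrended by fitting the full bivariate quadratic
`z = a·x² + b·xy + c·y² + d·x + e·y + f` by ordinary least squares over
all pixels, correcting for the curvature of the eggshell fragment. S_a is
the arithmetic mean absolute deviation of heights from the fitted
surface (the ISO 25178 areal roughness parameter). Consequences that the
tests exploit: any exactly quadratic surface has S_a = 0; adding a
quadratic trend never changes S_a; and for an i.i.d. Gaussian residual
field of standard deviation σ the expected S_a is σ·√(2/π) (the mean of
a folded normal). Pixel indices serve as coordinates (centred and scaled
internally for conditioning; the fitted span is unchanged). A per-egg
S_a is the arithmetic mean over replicate scan locations (typically
3–4). A rank-deficient design (e.g. a single pixel row) is an error, not
a silent pseudo-inverse fit.

**Wettability.** The contact angle of a deposited water droplet is read
once it has settled — the 5 s mark of per-second left/right series — as
the mean of the left- and right-hand angles. Categories: hydrophilic
(CA < 90°), hydrophobic (90° ≤ CA < 150°), superhydrophobic (CA ≥ 150°);
boundary values classify upward, exactly as the inequalities are
written. (Published descriptions of such datasets sometimes describe
sub-90° eggs as "hydrophobic"; this package follows the definitional
inequalities above and does not attempt to resolve that usage.)

**Calcium carbonate.** From crucible / crucible+dry / crucible+ash
masses (grams, 4-decimal balance), CaCO₃% = 100 × ash/dry, both net of
the crucible. The ash ≤ dry ≤ total-ordering invariants are enforced on
construction, so the percentage is always in [0, 100].

## Phylogenetic covariance

A rooted Newick tree with branch lengths induces the Brownian-motion
covariance `C[i,j]` = shared root-to-MRCA path length of species i and
j. Before model fitting, C is standardized to `A = C / max(diag(C))`, so
that the species variance component keeps squared trait units and the
heritability is scale-free; on an ultrametric tree A has unit diagonal
(the BM correlation matrix). Polytomies are retained — the covariance is
well defined on them and random resolution would introduce a hidden RNG
dependency. Trees without branch lengths are rejected unless the caller
explicitly requests Grafen's assignment (node height = (descendant
leaves − 1)/(n − 1)), because a silent default would change H².

## The phylogenetic mixed model

For egg-level observations grouped by species,

    y = Xβ + Zu + ε,   u ~ N(0, σ²_p A),   ε ~ N(0, σ²_e I),

with Z the observation→species incidence matrix. A is either the
standardized phylogenetic covariance or the identity (an ordinary
species random intercept, used for the CA~S_a model). Phylogenetic
heritability is H² = σ²_p/(σ²_p + σ²_e): 0 = no phylogenetic signal,
1 = trait covariance fully consistent with Brownian motion; its
interpretation parallels Pagel's λ in phylogenetic GLS, and with one
observation per species the ML fit coincides with λ-GLS exactly (this
was verified against ape/nlme during development and the identity-A
route is cross-checked against lme4 in the test suite).

Estimation profiles the ratio θ = σ²_p/σ²_e. In the eigenbasis of ZAZᵀ
the GLS coefficients and the profiled σ̂²_e are closed-form for fixed θ,
so the REML (or ML) criterion is a smooth scalar function of θ,
maximized by a 201-point log-spaced grid over θ ∈ [10⁻⁶, 10⁶] followed
by bounded scalar refinement (absolute tolerance 10⁻⁸ on log₁₀ θ).
θ = 0 is evaluated exactly and returned (with a boundary flag and
H² = 0 exactly) when it is at least as good as the interior optimum.
The wide search interval is deliberate: empirical signal in these traits
spans H² ≈ 0.03 to ≈ 0.95, so both extremes must be reachable. There is
no random initialization; fits are reproducible bit-for-bit. One species
effect plus one residual component is the entire random structure — a
further non-phylogenetic species intercept would not be identifiable at
~45 species and is deliberately not offered; H² is defined at the egg
level from the two fitted components.

Fixed effects are reported with standard errors and t ratios from the
GLS information matrix without denominator-degrees-of-freedom
correction; the p-value for a predictor comes from a likelihood-ratio
χ² test between nested models fitted by **ML** (REML likelihoods are not
comparable across fixed-effect structures), with the statistic clamped
at zero and df = number of dropped terms. Pearson correlations carry
Fisher-z 95% intervals.

## Host matching

For every parasitic egg with trait data the builder emits at most one
**host pair** and one **random pair** of per-egg values. The host-side
reference is an egg of the recorded laying host when that is known, or —
for generalist parasites whose individual eggs carry no host record —
the mean of the candidate host species' mean values (the multi-host
averaging rule; e.g. a cuckoo with three possible hosts). Random
partners are drawn uniformly (seeded) from measured non-parasitic eggs,
excluding the focal parasite's own host species by default (a switch
restores inclusion for sensitivity analysis); explicit target counts can
subsample the two groups to mimic unequal group sizes arising from data
availability. The group contrast mean(|Δ| random) − mean(|Δ| host) is
tested with a pooled-variance two-sample t (df = n_pairs − 2, reported
because published analyses of this design print a t statistic) and with
a two-sided label-shuffling permutation test (default B = 10 000,
p = (1 + #{|perm| ≥ |obs|})/(B + 1)).

## Synthetic data

The generator reproduces the statistical structure the analysis assumes,
with all parameters explicit and every draw a pure function of
(config, seed):

* **Trees**: direct Yule sampler — from two lineages, inter-speciation
  waits while k lineages exist are Exp(k·b); after the nth speciation
  tips are extended by a final Exp(n·b) hold time (so no zero-length
  terminal cherries), then rescaled to unit height.
* **Traits**: species effects MVN(0, σ²_p A) via a symmetric eigen
  square root (tolerant of near-singular A); parasitic species get a
  fixed shift β; convergence pulls each parasite's species value a
  fraction w ∈ [0, 1] toward its host's value (w = 1 copies it exactly);
  eggs add i.i.d. N(0, σ²_e).
* **Hosts**: each parasite is assigned one non-parasitic host, either at
  random or as its phylogenetically nearest non-parasite; per-egg host
  identity is recorded, as in field-collected specimens.
* **Height maps**: quadratic curvature surface plus an i.i.d. Gaussian
  roughness field of chosen sd.

Defaults mirror the scale of the empirical study this pipeline targets:
45 species, 14 parasites, 2–10 eggs per species, roughness-like units
(mean 1500 nm, species-level sd ≈ 450 nm, H² ≈ 0.95 — the strong
signal observed for S_a), β = 0 and w = 0. Where the study gives no
value (the variance scale, the convergence strength), values were chosen
once for realism: the trait spread matches the published S_a range
(roughly 400–4000 nm), and w is swept by the tests rather than
calibrated, since no effect size in trait units is available for
convergence.

What the generator does **not** emulate: non-Gaussian egg noise,
measurement-instrument error structure, missing-data patterns driven by
specimen availability, multi-host gentes beyond the averaging rule, and
any relationship between the three traits. Passing recovery tests
therefore show the estimator is correct under its own model, not that
real eggshell data satisfy that model.

## Calibration properties and known limitations

* **Recovery**: across study-scale replicates the REML H² estimate is
  approximately unbiased at weak, intermediate and strong signal and is
  monotone in the truth (the test suite checks ±0.1 over 200 replicates
  at H² ∈ {0.05, 0.5, 0.95}).
* **LRT**: the χ² reference is asymptotic. At the default strong-signal
  conditions the status LRT is essentially nominal; at intermediate
  signal (H² ≈ 0.5) it is mildly anticonservative on ~45 species (a
  known small-sample property of ML likelihood-ratio tests for
  between-species predictors, not an implementation defect).
* **Permutation test**: label shuffling across pairs assumes the
  absolute differences are exchangeable under the null. Because several
  eggs of the same parasite species are compared against the same host
  species, host-pair differences are clustered; when trait variation is
  almost entirely species-level (strong signal, the default regime) the
  exchangeability assumption fails and the test is anticonservative,
  while at moderate signal the shared parasite egg between a host pair
  and its random counterpart makes it slightly conservative. This is a
  property of the published pairing design itself, which this package
  reproduces deliberately; the test suite documents the strong-signal
  inflation rather than hiding it. A paired scheme (swapping host/random
  labels within each parasitic egg) would restore exactness and is a
  natural extension, but is not the published construction and is
  therefore not the default.
* **Degenerate inputs** are refused loudly: identity covariance with one
  egg per species (variance components not separable), rank-deficient
  fixed-effect designs, non-PSD covariances, zero-depth trees,
  rank-deficient height maps.
* Problem sizes in the test suite (200–500 replicates, B = 499–10 000
  permutations, 45–50 species) were chosen to keep Monte-Carlo error
  well inside each asserted tolerance while the whole suite stays
  desk-scale.

## Reproducibility

All randomness flows from explicit integer seeds; the pipeline derives
per-stage seeds from one top-level seed via `numpy.random.SeedSequence`
spawning, echoes them in the report, and a rerun from the echoed config
reproduces the JSON report byte-for-byte.
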