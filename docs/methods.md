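# Methods

`lulcesv` implements a post-classification land-use/land-cover (LULC) change
analysis coupled to benefit-value-transfer (BVT) ecosystem-service valuation,
the workflow used throughout the change-detection literature on multi-epoch
Landsat-style imagery. This note records the models, the defaults and why they
are what they are, and what the synthetic test conditions do and do not show.

## Supervised classification

Each class k is modelled spectrally as a multivariate Gaussian N(μ_k, Σ_k)
over the B reflectance bands, fitted from training pixels with the unbiased
(n−1) covariance. A pixel x is assigned

    argmax_k  −½ [ ln det Σ_k + (x − μ_k)ᵀ Σ_k⁻¹ (x − μ_k) ],

i.e. plain maximum likelihood with equal priors (no prior weighting — the
method is ML, not MAP). Ties break toward the lowest class code so the result
is deterministic. When the empirical covariance is numerically singular
(smallest eigenvalue < 1e-10 × largest, e.g. duplicate training pixels), a
ridge ε·I with ε = 1e-6 × mean diagonal is added; ε defaults to 1e-6 when the
diagonal is all zero. The tie-break, the ridge form and its thresholds are
package choices; they only matter on degenerate inputs. With a covariance
shared across classes the rule reduces to nearest class mean in Mahalanobis
distance, which the tests use as a closed-form cross-check, alongside an
exhaustive per-pixel argmax oracle.

## NDVI and vegetation-density classes

NDVI = (NIR − R)/(NIR + R), defined where NIR + R > 0 and reported as
undefined (not 0) elsewhere — 0 would silently mean "sparse vegetation".
Values are clamped to [−1, 1] only against float round-off (excursions
< 1e-12). The five density classes use the Hartoyo-style thresholds −0.03,
0.15, 0.25 and 0.35. Published bin lists share endpoints, so the bins here
are half-open and lower-inclusive with the top bin closed at 1: a value on a
boundary goes to the upper class. Class 4 is named by its density
("moderate vegetation"); it is the bin conventionally used as a grassland
proxy.

## Accuracy assessment

Confusion matrices put reference classes in rows and mapped classes in
columns (the orientation is a convention; producer's accuracy X_ii/n_i uses
row sums, user's accuracy X_jj/n_j column sums). Overall accuracy is
Σ X_ii / M; kappa is

    K = (M·ΣX_ii − Σ n_i·n_j) / (M² − Σ n_i·n_j),

with the agreement bands >0.80 strong, 0.40–0.80 moderate, <0.40 poor.
Classes absent from both margins are dropped rather than zero-padded, which
keeps the kappa denominator meaningful; a single-nonempty-class matrix yields
an explicit "undefined" rather than a number. No kappa variance or
area-weighted correction is computed.

## Change detection

Areas are pixel counts × pixel_size²/10 000 ha. The annualised rate between
epochs is ((A_end − A_start)/A_start)/t × 100 %/yr with t in years, positive
for expansion. Cross-tabulating two epochs over the pixels valid in both
gives the transition matrix in hectares; per class, loss = row total −
diagonal, gain = column total − diagonal, net change Nc = gain − loss, and
the net-change-to-persistence ratio Np = Nc / diagonal (undefined when
nothing persisted). Row/column totals equal the per-epoch area tables by
construction and Σ_k Nc_k = 0 on every instance.

## Valuation and elasticity

BVT prices class k with coefficients VC_kf (US$ ha⁻¹ yr⁻¹) per service
function f, transferred from biome-equivalent estimates; the packaged table
is the modified conservative set for a tropical-Afromontane setting (after
Kindu et al. 2016, in the Costanza et al. 1997 framework): 17 functions in
four categories, class totals forest 986.69, cultivated 225.56, grassland
293.25, water 8103.5, and built-up/barren priced 0 (no suitable equivalent
biome). ESV_k = A_k Σ_f VC_kf, ESV_f = Σ_k A_k VC_kf, and the total equals
both marginal sums — an identity the tests enforce on random tables.

Percent changes between epochs come in two modes: `raw` uses the values as
computed; `paper` first rounds both to the nearest 0.1 million US$ (half away
from zero). Published one-decimal tables are internally consistent only under
the pre-rounded convention, so `paper` is the default when comparing against
printed tables. All printed-style output rounds half away from zero.

The coefficient of sensitivity for class k scales its whole coefficient row
by (1 + p) (default p = ±0.5), recomputes the total, and divides relative ESV
response by relative coefficient change. Because the total is linear in the
row, CS_k = ESV_k / ESV_total exactly — independent of p's size and sign —
and Σ_k CS_k = 1 over all classes; the tests verify this identity to 1e-12
against the perturb-and-recompute route. CS of a zero-coefficient class is
defined as 0 (the 0/0 limit of the elasticity). CS < 1 means the valuation is
inelastic to that class's coefficients. When a class's ESV is published but
its area is not, the implied area ESV_k / Σ_f VC_kf is substituted; by
linearity every downstream number is unchanged.

## Synthetic scenes

The generator produces what the pipeline consumes, with known statistical
structure: epoch 1 is drawn i.i.d. from initial class proportions; each later
epoch resamples every pixel's class from its row of a row-stochastic
transition matrix, independently across pixels (first-order Markov, no
spatial autocorrelation — exactly the per-pixel bookkeeping a transition
matrix assumes, and deliberately simpler than real landscapes). Reflectances
are drawn per pixel from the class band model N(μ_k, Σ_k) and clipped at 0;
a nodata mask is sampled once at epoch 1 and held fixed so cross-tabulation
has constant support. One master seed drives everything through
deterministically spawned sub-streams per epoch and operation, so runs are
bit-reproducible and adding epochs does not perturb earlier ones.

Default conditions mirror the north-eastern Ethiopian-highlands case study
the package's worked example reproduces: 30 m pixels, epochs labelled
1984/1991/2001/2021, six classes with 1984 proportions forest 10.8 %,
grassland 26.5 %, water 6.9 % (published); the unpublished remainder is split
cultivated 33.0 %, built-up 10.0 %, barren 12.8 % as a package choice
(cropland dominant, as in the study region). The default transition matrix
encodes the study's qualitative dynamics — forest, grassland and water lose
area to cultivation and settlement, which only gain — applied once per epoch
step regardless of the unequal year gaps. The default band model has four
bands (blue, green, red, NIR) with diagonal covariance σ = 0.008; class means
are placed so each class-mean NDVI falls inside the density bin its name
implies (water −0.33; built-up 0.05; barren 0.06; cultivated 0.18; grassland
0.30; forest 0.84) and classes sit ≥ 7 Mahalanobis units apart, giving
essentially error-free Bayes classification. Per-class spectral separability
is not a published quantity; the defaults represent a clean, well-separated
scene, and `noise_scale` inflates every covariance to degrade it on purpose.

What passing synthetic tests show: the estimators are correct (classifier
equals its oracle, transition frequencies recover the generating matrix to
±0.02 on a 200×200 grid, recovered areas and ESV trajectories match truth to
<1 %). What they do not show: robustness to mixed pixels, spatial
autocorrelation, atmospheric effects, class imbalance in training data, or
sensor artefacts — none of which the generator emulates.

## Problem sizes and numerics

Statistical checks run on 200×200 grids (40 000 pixels), where binomial
standard errors are ≲0.0025 and the ±0.02 recovery tolerances are comfortable
law-of-large-numbers bounds; oracle-equivalence checks use 100×100 since they
are exact. Ground truth defaults to 50 points per class, matching the case
study's campaign. Monetary values are kept in raw US$ at double precision and
rounded only for presentation (millions at one decimal). Degenerate inputs
fail loudly: empty truth sets, classes with <2 training points, zero start
areas, zero-total baselines and undefined Np/kappa all raise or return
explicit undefined markers rather than numbers.

## Known limitations

- The valuation assumes spatially uniform coefficients (the standard BVT
  caveat); no per-pixel value surfaces are produced.
- Rasters are written as plain TIFF with a JSON metadata sidecar; projection
  metadata is carried, not interpreted.
- Only the Gaussian ML classifier is provided — no random forest/SVM, no
  object-based segmentation, no sub-pixel unmixing.
- The published case-study table prints the 1984 water-bodies ESV as 55.1
  million US$ while its own printed area × coefficient give 55.16 (→ 55.2 at
  one decimal); the package reports the computed value. Likewise the
  published overall-loss figure of "32.7 %" matches the *remaining* share
  (26.4/80.8); the package reports the 67.3 % loss.
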