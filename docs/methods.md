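# Methods

`movescape` implements a dispersal-informed landscape-connectivity
analysis for GPS-collared ungulates: seasonal habitat-selection models
estimated from telemetry, friction surfaces derived from the movement
model, normalized least-cost corridors between residency core areas, and
a roads-versus-no-roads permeability comparison.  A seeded synthetic-data
module generates landscapes and telemetry with known selection
coefficients so that every stage can be validated without field data.

## 1. The models

### Resource selection (residency)

Habitat selection during winter (Jan–Mar) and summer (Jul–Aug) residency
is modelled with a used–available design: each used GPS location is
contrasted with 10 random locations drawn uniformly inside the 100%
minimum convex polygon of all relocations.  Coefficients are estimated by
a binomial GLMM with a per-animal random intercept, maximised under the
Laplace approximation (1-D Newton inner loop per animal for the
conditional modes).  When the intercept-variance estimate collapses to
zero — which is the correct answer for the synthetic generator, whose
animals share one selection rule — the fit falls back to plain logistic
regression with cluster-robust (per-animal) standard errors and is
flagged in `meta['fallback']`.  The selection score is the exponential
form

    w(x) = exp(b1 x1 + b2 x2 + ... + bp xp)

without the intercept, rescaled by its maximum over the scored set so
0 ≤ w ≤ 1.  `w` is proportional to, not equal to, a selection
probability.

Model building follows the standard screen-then-prune protocol:
covariates with pairwise |Pearson r| > 0.7 are reduced to one member per
pair, variance inflation factors above 3 drop the worst offender
iteratively, every continuous predictor enters standardized with a
quadratic companion, and backward elimination removes the least
significant term with Wald p > 0.05 (a quadratic before its linear term,
a categorical land-cover block as a unit; ties broken by the larger
standard error).  Standardization constants are learned on training data
only, including inside every cross-validation fold.

### Step selection (movement)

Spring (Apr–Aug) and autumn (Sep–Nov) movements are modelled at the step
level.  Speeds are first separated into foraging and directional-travel
regimes by the broken-stick model: speeds are binned (50 equal-width bins
over the 0.1–99.9 percentile range by default), the natural log of
non-zero bin counts is regressed on bin midpoints with a continuous
two-segment line, and the residual-sum-of-squares-minimising breakpoint
(grid-searched over every interior bin boundary) is the threshold.  A fit
is flagged degenerate when the two slopes differ by less than 1% or the
second segment buys essentially no RSS — the signature of single-regime
data; note that a *sample* from a single exponential still produces
distinguishable slopes through small-count noise in the tail bins, so the
degeneracy flag certifies exact linearity, not distributional purity.
Before fitting, an equal number of steps per animal (800 in spring, 600
in autumn) is drawn so that well-sampled animals do not dominate.

Steps faster than the threshold (strictly greater) are each matched with
10 random steps sharing the start point, with lengths and turning angles
drawn from the pooled empirical distributions of the observed long steps
(50 m and 10° bins, uniform within bin), the endpoint placed at the
previous absolute bearing plus the drawn turn.  The conditional-logit
likelihood

    L(b) = prod_s  exp(b.x_used,s) / sum_{j in s} exp(b.x_j,s)

is maximised by Newton–Raphson (analytic gradient and Hessian, vectorised
when all strata share the 1+10 size).  A per-animal random intercept is
stratum-constant and therefore unidentifiable in a conditional logit; the
default is the fixed-effects conditional logit.  Standard errors come
from the observed information; three further inference options are
available for hard cases — `robust_cluster='animal_id'` (cluster-robust
sandwich), `firth=True` (bias-reducing penalized score), and
`ssf_profile_ci` (profile-likelihood intervals).  In synthetic recovery
experiments the three agree closely with the Wald baseline: the
conditional likelihood factorizes exactly over strata even though
consecutive steps of one animal share terrain, so the information-based
errors are valid.  The genuinely hard case is a covariate informative in
few strata — the 1-km-capped gravel-road distance is non-constant in
only ~5% of cells at 250 m resolution — whose interval coverage at the
default study size falls below nominal across landscape draws in a way
none of these corrections repairs; tripling the number of animals
restores it.  See the package's validation suite for the measured rates.

Road-distance covariates are capped before standardization — 2,000 m for
highways, 1,000 m for gravel roads — so the models never extrapolate road
effects into areas where traffic cannot plausibly matter.

### Validation

RSFs are validated by 5-fold cross-validation on the used points: the
withheld used points and the availability sample are scored by the
training model, scores are cut into 10 quantile bins of the availability
scores, and the Spearman correlation between bin rank and area-adjusted
frequency (withheld-used frequency over available frequency per bin) is
reported per fold.  Scoring uses the linear predictor; quantile bins and
rank correlation are invariant to the monotone exponential.

SSFs are validated by the case-control procedure: fit on 80% of randomly
selected strata, rank each withheld used step's score among its 10 random
steps (rank 1 = highest score, ties averaged — the rank convention is
recorded in the output because the sign of the statistic depends on it),
tally rank frequencies and report the Spearman correlation between rank
and frequency over 100 repetitions (mean and percentile 95% CI).  Under
this convention a well-performing model yields a strongly *negative*
correlation.  The null ranks one withheld random step against the
remaining random steps; its interval should cover zero.

## 2. Friction and corridors

The movement model is mapped over the landscape (step-geometry terms
excluded), normalized by its maximum, and inverted:

    friction = max(1 − w, ε),      ε = 1e−6

so friction is 1 where predicted selection is nil and ε where it is
maximal.  The no-roads counterfactual re-scores every cell with both
road distances held at their caps — removing the road terms instead would
misspecify the model — and renormalizes by its own maximum.

Corridors connect residency cores: cells at or above the upper quartile
of the seasonal RSF surface, dissolved into 8-connected components
(components below a minimum size are discarded), plus 50% kernel-density
isopleths of winter locations as winter source polygons.  For every core
pair within 80 km (edge to edge, inclusive), cost-weighted distances
(CWD) from each core are computed by Dijkstra over the 8-connected move
graph, with the Linkage-Mapper edge convention: mean of the two cell
frictions times centre-to-centre distance (cell size, √2·cell size
diagonally).  The normalized least-cost corridor is

    NLCC_AB = CWD_A + CWD_B − LCD_AB,

zero exactly on the least-cost path; the corridor map is the cellwise
minimum over pairs.

**Cropping.** Corridor maps are cropped at a maximum cost-weighted
distance.  Two mosaics are carried: the NLCC mosaic (cellwise minimum of
normalized corridors) and the CWD mosaic (cellwise minimum of raw
CWD_A + CWD_B, i.e. the total cost of the cheapest core-to-core route
through the cell).  The analysis crops on the CWD mosaic
(`CorridorSet.cropped()`): the cutoff then acts as a movement-cost
budget, and a core pair whose least-cost route exceeds the budget drops
out entirely.  This is deliberate: cropping the *normalized* mosaic can
only narrow a crossing, never close it (every surviving pair keeps
NLCC = 0 cells along its path, wherever it crosses a road), so a road
barrier could never remove a highway segment from the corridor network —
contradicting the behaviour the analysis is meant to expose.  The
generic raster threshold (`crop_corridors`) is available for either
mosaic.  The cutoff is friction-scale dependent; the default (5,000 cost
units ≈ a 20-km crossing of mid-range friction on the synthetic scale)
suits the synthetic world, and published analyses at other friction
scales have used values such as 200,000.

## 3. Road impact

The highway network is cut into 20 contiguous near-equal-length segments
(segment ids deterministic along the network).  Per segment and scenario
the polyline length lying inside valid cropped-corridor cells is
measured by exact polygon intersection, and the per-segment lengths are
compared between scenarios by a classical paired t-test (df = 19 for 20
segments; degenerate inputs resolved explicitly: all-zero differences
give t = 0, p = 1; identical nonzero differences give t = ±∞, p = 0).

## 4. The synthetic world

The generator's defaults state one coherent study design:

| parameter | default | rationale |
|---|---|---|
| animals | 54 | emulated study size (young males surviving ≥ to September) |
| fix interval | 120 min | collar schedule |
| extent | 320 × 320 cells at 250 m (80 × 80 km) | spans the longest recorded dispersal (~98 km straight line), so the 80-km pairing rule binds |
| field correlation length | 4 km | coherent mountain-scale terrain and vegetation |
| encamped / travel mean speed | 3 / 40 m·min⁻¹ | two-regime mixture bracketing published breakpoints (~6–7 m·min⁻¹); exponential within regime so log bin frequencies are piecewise linear, the broken-stick model's own assumption |
| P(travel per fix) | 0.25 | travel steps a minority of movement-window fixes |
| turn concentration (travel) | von Mises κ = 5 | forward-directed travel |
| candidates per travel step | K = 30 | the choice set behind the exponential selection form |
| autumn mortality | 0.15 | hunting-season attrition, motivating 600 autumn steps |
| seasonal windows | winter Jan 1–Mar 31, spring Apr 1–Aug 31, summer Jul 1–Aug 31, autumn Sep 1–Nov 30 | the emulated calendar; the spring/summer overlap is preserved, not resolved — a July fix carries both labels |

Selection coefficients are defined on z-standardized layer values
(capped road distances first, standardized over valid cells), the scale
the fitting stage estimates.  Residency fixes are drawn cell-weighted by
exp(b·x) and jittered within cell; during residency months the encamped
walk chooses its *direction* among K candidates weighted by the seasonal
residency model (speeds keep the exact encamped marginal), so track fixes
carry RSF structure.  Travel steps choose among K candidate endpoints
with probability ∝ exp(b_ssf·x).  Endpoints that would leave the
landscape are redrawn or zero-weighted, never clipped — clipping would
bias observed speeds low.

The generator can record each travel step's candidate set
(`record_candidates=True`).  Parameter-recovery experiments fit the
conditional logit on the chosen endpoint plus 10 uniformly sampled
alternatives from the same choice set, which is consistent (uniform
sampling of alternatives).  Rebuilding availability from the *observed*
long steps — the pipeline's field-realistic path — attenuates
coefficients by roughly 10–20% in the synthetic world, because observed
steps are already selected and their empirical length/turn kernel is not
the candidate kernel.  This attenuation is a known property of matched
step designs, not an estimation bug; green recovery tests therefore
establish correctness of the estimator under matched availability, while
the pipeline's absolute coefficients should be read as conservative.

The road-counterfactual experiment states its own world: movement
selection dominated by road avoidance (`dist_highway +3.0`,
`dist_gravel +1.0` on distance, i.e. strong proximity avoidance, with
weak habitat terms at 0.05), cores of at least 1,000 cells, a CWD budget
of 5,000.  Avoidance saturates near coefficient 3 because friction is
capped at 1.  The landscape carries a two-route highway network (one
north–south, one west–east); with a single route, permeability losses
concentrate in too few of the 20 segments for a paired t-test to detect
reliably.

What the generator does **not** emulate: GPS error and fix failure,
mother–calf association and sociality, memory or home-range fidelity,
temporally varying NDVI within a season, and real road-network topology.
A green test certifies the statistical machinery under the stated
generative model, not ecological realism beyond it.

## 5. Numerical choices

- Raster convention: upper-left origin, row-major, cell centres at
  `origin + (i + 0.5)·cell_size`; extent boundaries inclusive.
- Terrain ruggedness uses only existing neighbours at edges; a single
  cell has TRI 0.
- Isopleths: Gaussian KDE with Silverman's bandwidth, cells accumulated
  in decreasing density order until the target mass — nested across
  levels by construction.
- GLMM: inner Newton tolerance 1e−10; L-BFGS-B over (β, log σ);
  fallback to logistic + cluster-robust errors when σ̂² < 1e−6; standard
  errors from a central-difference Hessian of the Laplace log-likelihood.
- Conditional logit: Newton tolerance 1e−11; a covariate constant within
  every stratum raises an inestimable-term error.
- Steps across gaps longer than twice the nominal fix interval are
  discarded; a step inherits the phase of its start fix, movement phases
  taking priority over residency labels where windows overlap.
- Wald elimination on ill-conditioned fits: a singular covariance block
  falls back to the largest per-column p in the block.
- Seeds: every stochastic operation takes an explicit seed; the pipeline
  derives per-stage seeds from the master seed by hashing the stage name
  (SHA-256, reduced below 2³¹).

## 6. Known limitations

- The random-intercept conditional logit of some published analyses is
  not identifiable as stated; this package fits the fixed-effects
  conditional logit and offers cluster-robust errors instead.
- Friction = 1 − w saturates: once selection is strong, most of the map
  sits near friction 1 and relative structure is compressed; coefficient
  magnitudes beyond ~3 on any single term change friction little.
- Corridor geometry on small extents is blanket-prone: with many cores,
  nearly every cell lies within a small detour of some pair's least-cost
  path.  Discrete corridors require cores that are few and large relative
  to the extent — which the default world provides.
- I/O uses ESRI ASCII grids and GeoJSON (plain text); no CRS
  transformation is performed — all inputs must share one projected
  metric coordinate system.
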