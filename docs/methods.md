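# Methods

This note documents the model, the numerical choices, the synthetic-data
generator and the known limitations of `herdhmm`.

## The behaviour model

Herd mobility is discretised into N latent activity states on a 30-min
grid; the state sequence is a first-order Markov chain (transition matrix
Γ, initial distribution Π) and each state emits a pair of trajectory
metrics, step length and turning angle, assumed conditionally independent
given the state.

**Step law.** Field reports in this domain print step-length parameters as
the mean and SD of a normal law, but a normal has mass on negative
lengths. The default family is therefore the normal truncated to (0, ∞)
and renormalised, *parameterised by the untruncated (μ, σ)* so printed
values keep their meaning; a gamma family with the same moment
parameterisation is selectable (`step_family="gamma"`). The discrepancy
between the two readings is deliberate and visible, not hidden: the
serialized model records which family produced it. A step is "exactly
zero" when the computed distance falls below 10⁻⁶ m; an extra point mass ζ
at zero absorbs these collar-motionless observations (zero inflation).

**Angle law.** Von Mises with mean μ′ ∈ (−π, π] and concentration κ ≥ 0
(κ = 0 is the circular uniform). Angles are undefined at segment starts
and next to zero steps; missing angles contribute a factor 1 to the
likelihood rather than being imputed.

**Transitions.** Row-wise multinomial logit with the diagonal as reference
category, so Γ rows are valid probability vectors for any finite covariate
value. Covariates are centred internally (the centring constants are
stored with the model) purely for optimizer conditioning; slopes are
unaffected, and intercepts are reported on the centred scale.

**Initial distribution.** One shared Π across segments, estimated on a
softmax scale; every segment restarts the forward recursion from Π.

## Likelihood, gradients, optimisation

The joint log likelihood sums independent segments, each computed by the
scaled forward algorithm (per-step normalisation with accumulated log
scale; no underflow at 10⁵ observations). Fitting minimises −ln L by
L-BFGS-B over unconstrained working parameters: log(μ), log(σ), log(κ),
logit(ζ), raw μ′ (the density depends on it only through cos(θ−μ′), so the
parameter is periodic and needs no transform), transition β, and Π
logits. The gradient is analytic: a forward–backward pass yields posterior
state probabilities γₜ(s) and pairwise posteriors ξₜ(i,j); emission-score
terms are γ-weighted sums of closed-form derivatives, the transition
gradient is Σₜ[ξₜ(i,j) − (Σⱼ′ξₜ(i,j′))Γₜ(i,j)] (times the covariate for
slope entries), and the Π gradient is γ₀ − Π per segment. The gradient is
unit-tested against finite differences for both step families, with and
without covariates. Box bounds on the working parameters (e.g. log μ ∈
[ln 10⁻², ln 10⁶]) only prevent numerical overflow, they are not
scientific constraints. Defaults: maxiter 1000, gradient tolerance 10⁻⁶,
relative function tolerance 10⁻⁸. The fit keeps the best point ever
evaluated, so the returned ln L never falls below the initial one.

**Multistart.** The likelihood surface is multimodal (a secondary optimum
that swaps or merges states is routinely found). Initial emission
parameters are drawn uniformly within per-state sampling limits —
`table1_bounds` ships the published 3-state limits (μ: 5–100 / 50–250 /
100–1000 m, σ: 5–100 / 50–500 / 100–1000 m, μ′: ±3 / ±3 / ±0.5 rad, κ:
0.1–1 / 1.5–5 / 1–15), with ζ started at the dataset zero fraction p₀ for
the slowest state and p₀/100 elsewhere; `quantile_bounds` builds analogous
limits from step quantiles for other state counts. Bounds constrain
initialisation only, never the optimizer — fitted values may leave them.
Transition inits are diagonal-dominant (self-stay 0.8) with zero slopes; Π
starts uniform. Results are canonicalized (states relabelled by ascending
μ, ties by σ then index; Π, Γ/β and emissions permuted together, ln L
invariant) and two restarts count as the same optimum when their ln L
agree within Δ = 0.5 log-units — Δ is a reporting convention for the
consensus fraction, nothing else depends on it.

**Decoding and selection.** Viterbi runs in log space with ties broken
toward the lower state index. BIC = k·ln(n) − 2·ln(L) is reported under
two k conventions — free-parameter count (5N + N(N−1)(1+C) + (N−1); the
default for ranking) and state count, which some reports use; both appear
side by side so the difference stays visible. The state range is capped at
6: beyond that the model stops being interpretable as herd behaviour and
multistart cost grows combinatorially.

## Geometry and time

Distances default to great-circle (haversine, R = 6371 km); a planar mode
through a local azimuthal equidistant projection is available, and at herd
scales (steps ≪ 1 km) the two agree to well under 0.5%. Turning angles are
signed bearing differences wrapped to the half-open interval (−π, π] with
ties at the cut mapped to +π — the resting-state angle mean sits near ±π,
so the wrap convention matters and is fixed once. Day/night labels use
NOAA solar sunrise/sunset (zenith 90.833°) at the survey's geographic
centre, computed in UTC; the algorithm is a couple of minutes accurate,
ample for 30-min fixes, and refuses |latitude| > 60° where the polar
cases it does not handle begin. Seasons follow the local calendar: Nov–Feb
cold dry, Mar–May warm dry, Jun–Oct rainy.

## Cleaning contract

Every removed fix is counted under a named rule (malformed row, duplicate,
outside any collar-assignment period, member of a too-short run), and
n_collected = n_usable + Σ removals always holds. Assignment periods are
half-open [start, end); collar swaps simply produce distinct periods and
no cross-animal stitching is attempted. Segmentation cuts where the
inter-fix gap deviates from the nominal 30 min by more than ±5 min and
drops runs shorter than 10 fixes — defaults chosen so that segments carry
enough turning angles to inform the HMM; both are parameters. Fixes with
missing DOP or temperature are retained (neither is required), fixes with
missing position or time are not.

## Land-use attribution

Vector layers only, WGS84 throughout (the polygons involved are small
enough that geodesic effects are far below GPS noise). Each layer carries
a legend mapping raw labels to the unified units (homefields, bushfields,
rangelands, lowlands, fallows, other, unclassified) — unmapped labels are
an error naming the offenders, not a silent "other". A fix takes the unit
of the highest-priority layer with a polygon covering it (closed-boundary
rule; among same-priority overlaps the lowest polygon ID wins, so boundary
fixes resolve identically across runs), and "unclassified" otherwise.
STR-tree indexing keeps the join near-linear.

## Summaries

Activity budgets are per-state fix proportions within arbitrary key
combinations (hour, season, herd type, diel, land unit); counts are kept
alongside proportions so conservation (cell totals sum to the fix count)
is checkable, and empty cells simply do not appear. Daily metrics: time
per state = 0.5 h × fix count, distance per state = sum of step lengths
whose origin fix is in the state; days with gaps are flagged partial, not
dropped. Transhumance segmentation works on daily centroids (planar mean
of the day's fixes): departure is the first day of a ≥2-day run outside
the home area, stops are maximal runs of ≥3 days within 2 km of the
running stop centroid, the return is the first day back inside home after
the furthest stop, and stop durations are clustered by seeded 1-D k-means
(3 clusters, best of 50 inits). The stop algorithm is a stated convention
— field reports give cluster means but no procedure — and all four
parameters are exposed.

## The synthetic generator

`simulate_survey` emulates the structure of a Sahelian collar survey: per
herd a latent state sequence from the model, a correlated random walk in a
local planar frame (step from the state's zero-inflated law, heading
accumulating von Mises turning angles from a uniform initial heading),
expressed in WGS84. Defaults are the study conditions: 30-min fixes,
isotropic GPS noise with sd 4.09 m — calibrated so the 95% radial quantile
equals the collars' advertised 10 m accuracy — and 2% random fix drop-out,
matching the ~2.3% loss a real cleaning pass reports. Resident herds are
forced into the resting state between sunset+1h and sunrise−1h (night
tethering); transhumant herds follow a phase schedule, marching toward
each phase anchor by day (travelling state, heading toward the target)
and held within ~1.5 km of the anchor while stationary. Overrides act on
the *state sequence*, never post-hoc on positions, so decoded-state
recovery against stored truth is meaningful. The land-use map is
concentric — homefields within 1 km of the village, bushfields 1–3 km,
rangelands beyond, with a fallow block and a lowland patch — in a fine
local layer plus a coarse country-scale layer, mirroring how mixed-
resolution products are used in practice. The published numeric Γ of the
field model exists only graphically, so recovery studies use a stated
diagonal-dominant convention (`DEFAULT_REFERENCE_GAMMA`: resting self-stay
0.90; leaving travel reaches foraging five times more often than rest;
foraging splits evenly) built from the qualitative published structure.

What the generator does **not** emulate: vegetation/biomass dynamics and
their feedback on movement, herder decision heterogeneity, DOP-correlated
noise, multi-species droves, or collar failure modes beyond uniform
drop-out. Passing recovery tests therefore show the estimator is correct
under the model's own assumptions at survey scale — not that real herds
satisfy those assumptions.

## Problem sizes and determinism

The test suite runs recovery at 30,000 steps (10 restarts), covariate
recovery at 30,000 steps, and BIC selection at 10,000 steps × 10
replicates — sizes at which the asymptotics that matter (relative errors
of a few percent) are already visible while a full study-scale refit
(~5.6×10⁵ fixes × 110 restarts) is not needed to exercise any code path.
All randomness flows from explicit integer seeds through
`numpy.random.Generator`; identical seeds give byte-identical surveys,
fits and pipeline outputs. The pipeline stamps every output with a config
hash and input hashes (manifest.json) and caches the fitting stage on
those hashes, since multistart fitting dominates run time.

## Known limitations

- Emission independence of step and angle given the state is assumed, as
  is conditional independence over time; real tracks show residual
  autocorrelation within states.
- The truncated-normal reading of printed (μ, σ) is one of two defensible
  interpretations; the gamma alternative typically fits positive skew
  better.
- Covariate effects enter transitions only (not emissions), and one slope
  per covariate per off-diagonal entry.
- No hidden semi-Markov dwell times, no random effects across herds, no
  Bayesian uncertainty; confidence statements come from simulation.
- Transhumance phase labels (agropastoral-1, …, pastoral) are assigned by
  chronology and remoteness, which matches the canonical journey shape but
  not every itinerary.
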