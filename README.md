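# herdhmm

Hidden Markov behaviour models for GPS-collared cattle herds in Sahelian
agropastoral systems.

Mobile pastoralism in the West-African Sahel mixes free daytime grazing,
night-time tethering on cultivated parcels, and seasonal long-distance
transhumance between the agropastoral south and the pastoral savannah.
GPS collars recording a fix every 30 minutes capture all of this, but raw
positions say nothing about *what the herd is doing*. `herdhmm` turns such
surveys into behavioural time series and thematic summaries, for movement
ecologists, livestock scientists and anyone modelling herd mobility:

- **track preparation** — validated ingestion of GPS and collar-assignment
  tables, removal of malformed fixes, segmentation into regular 30-min
  sequences, season (cold dry / warm dry / rainy) and day/night labelling
  from NOAA solar geometry;
- **trajectory metrics** — step lengths and turning angles per segment,
  with per-step covariates such as collar temperature;
- **the behaviour model** — an N-state hidden Markov model whose states
  (canonically *resting*, *foraging*, *travelling* for N = 3) emit a
  zero-inflated step length and a von Mises turning angle each 30-min step,
  fitted by multistart quasi-Newton likelihood maximisation with analytic
  gradients, with optional covariate-dependent transition probabilities,
  BIC state-count selection and Viterbi decoding;
- **spatial attribution** — point-in-polygon land-use annotation against
  prioritised vector layers with harmonised legends;
- **summaries** — hourly/seasonal activity budgets, daily distance and time
  per state, and transhumance chronologies (departure, stops, phases);
- **a synthetic survey generator** — multi-herd surveys with known ground
  truth (tethered residents, phase-structured transhumants, GPS noise,
  gaps, collar swaps, a concentric land-use map), so the whole pipeline is
  testable without field data.

## The model

At each 30-min step the herd occupies one latent state
$i \in \{1,\dots,N\}$. The state sequence is Markov with transition matrix
$\Gamma$ and initial distribution $\Pi$; optionally the off-diagonal
entries of $\Gamma$ depend on covariates $z_t$ through a row-wise
multinomial logit,

$$\Gamma_{ij}(z_t) = \frac{e^{\eta_{ij}}}{1+\sum_{j'\neq i} e^{\eta_{ij'}}},
\qquad \eta_{ij} = \beta^{(0)}_{ij} + \beta_{ij}\cdot z_t .$$

State $i$ emits a step length from a zero-inflated positive law — mass
$\zeta_i$ at exactly zero, otherwise a normal law with mean $\mu_i$ and SD
$\sigma_i$ truncated to $(0,\infty)$ (a gamma family is selectable) — and
a turning angle from a von Mises law with mean $\mu'_i$ and concentration
$\kappa_i$. The likelihood is computed by the scaled forward algorithm,
maximised by L-BFGS-B over unconstrained working parameters from many
random initial points drawn within per-state sampling limits, model order
is compared by $\mathrm{BIC} = k\ln n - 2\ln L$, and states are assigned
by the Viterbi algorithm. A packaged reference model carries the published
3-state emission parameters for Sahel cattle
($\mu$ = 13.53 / 180.1 / 685.4 m per 30 min).

## Worked example

```sh
python examples/02_fit_behaviour_model.py
```

simulates 10,000 steps from the reference model and refits it from scratch
(5 random starts within the published sampling limits):

```
log likelihood : -72305.6
consensus      : 0.80 of restarts at the optimum
resting     mu =   13.37 m/30min (truth   13.53), kappa = 0.32 (truth 0.29)
foraging    mu =  184.77 m/30min (truth  180.10), kappa = 0.21 (truth 0.19)
travelling  mu =  723.72 m/30min (truth  685.40), kappa = 1.97 (truth 1.95)
decoded-state agreement with truth: 95.5%
```

Emission means land within a few percent of the generating values (one of
the five restarts settles on a locally optimal model — exactly why the
multistart and its consensus fraction exist); the mean step
lengths convert to speeds of ≈0.36 km/h (foraging) and ≈1.37 km/h
(travelling), and the Viterbi path recovers ~95% of the hidden states.
The other scripts in `examples/` walk through survey simulation, BIC
state-count selection, land-use budgets and transhumance phase detection.
A thin CLI wraps the same functions: `herdhmm simulate | prepare | fit |
decode | select | annotate | summarise | run`.

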