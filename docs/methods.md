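# Methods

`groupcot` implements a trajectory-energetics analysis for high-resolution
GPS tracking of a terrestrial, group-living bird (the motivating system is
vulturine guineafowl, *Acryllium vulturinum*, in a semi-arid savannah): how
much energy does an individual spend to move a metre, and how does that
cost differ between moving with a group on normal ranging days, moving with
a group during large range-shifting displacements, and moving alone during
natal dispersal?  Because the kind of field dataset this targets is not
freely available, the package pairs the analysis pipeline with a synthetic
cohort generator that imposes known context effects, so that every stage can
be validated by parameter recovery.

## Sampling design emulated by the generator

Tags record during a 13 h tracking day (06.00–19.00 local time, 46 800 s)
in one of two regimes per day: continuous 1 Hz fixes, or a 10-fix / 10 s
burst every 5 min.  From either regime a *5 min series* is built from the
fix at the 10th second of every 5 min slot (156 slots per full day); maximal
runs of 1 Hz data longer than one burst (≥ 11 consecutive fixes) form the
*high-resolution blocks*.  The fraction of days recorded at 1 Hz defaults
to 0.4 (tags charge every second to third day).

## Movement model

Each simulated day is a correlated random walk driven by a four-state
latent behavioural chain:

* **States.** 1 = stationary, 2 = slow tortuous foraging, 3 = medium walk,
  4 = fast directed travel.  Mean per-second step lengths default to
  (0, 0.2, 0.6, 1.2) m s⁻¹ with gamma-distributed steps (CV 0.3); heading
  deviations are wrapped-normal with state sds (0, 0.8, 0.3, 0.1) rad s⁻¹.
  No emission family is prescribed by the motivating study (it fits state
  distributions empirically); gamma step lengths and wrapped-normal turns
  are the conventional movement-ecology choice.
* **Bout-scale transitions.** The per-context 4×4 transition matrices are
  defined at the 10 s behavioural-bin scale — the scale at which states are
  later decoded, and the scale on which the published persistence of the
  fastest state is reported (65.2 % for the reference context, 75.2 % for
  lone dispersers; both are embedded in the defaults).  The 1 Hz chain uses
  the matrix 10th root, so the chain subsampled every 10 s follows the
  configured matrix exactly while bouts persist over tens of seconds, as
  real behavioural bouts do.  A per-second interpretation of the same
  matrices would give 2–7 s dwell times and make every 10 s bin a state
  mixture, which no bin-scale decoder could recover.  The remaining matrix
  entries are not published; they were fixed once at realistic values with
  the qualitative ordering normal < large-displacement < disperser in
  persistence of the moving states.
* **Contexts.** `group-normal`, `group-large` (the reference) and
  `lone-disperser` differ in three imposed ways: the transition matrix
  (continuity), a speed multiplier, and path straightness (a turn
  concentration dividing the heading sds, plus a goal-bias gain pulling the
  heading toward a per-day target bearing; zero gain on normal ranging
  days, which is what keeps their net daily displacement small).  The speed
  multipliers are defined as the *total* imposed effect on mean speed while
  moving (0.912, 1.0, 1.272): because contexts distribute moving time
  differently across states 2–4, the generator rescales per-step draws by
  the inverse of the composition ratio so the realised ground-truth
  contrast equals the configured number.  The disperser goal-bias gain
  (0.015 vs 0.02 for the reference) was calibrated once, by matching
  expected daily straightness between the two large-movement contexts,
  because their daily-scale straightness contrast is approximately zero in
  the motivating system.
* **Individuals.** Each individual carries a log-normal speed factor
  (sd 0.06 on the log scale).  Without between-individual variance the
  random-intercept models downstream would be vacuous and their confidence
  intervals meaningless.
* **GPS error.** Position noise is AR(1) per axis: absolute error sd 3 m,
  but with the error difference between consecutive fixes held to 0.1 m sd —
  clustered GPS sampling yields strongly time-correlated errors, and the
  apparent per-second movement induced by noise must stay on the decimetre
  scale for 1 Hz speeds to be usable at all.  White noise of realistic
  absolute magnitude would swamp per-second speeds; noise small enough to
  be white would be unrealistically accurate in absolute terms.

What the generator does **not** emulate: multi-agent cohesion (contexts
differ only through movement parameters), roost-site fidelity (roosts are
the day's endpoints), habitat selection, heterogeneous fix accuracy across
habitats, and diurnal activity rhythms.  Passing recovery tests therefore
show that the pipeline measures imposed movement differences correctly, not
that real birds behave like the generator.

## Analysis pipeline

1. **Resolution split and smoothing.**  Per-second speed is the mean
   per-second displacement over a centred 5 s window within a block
   (truncated at block edges), suppressing residual GPS jitter.
2. **Day classification.**  A day is a *large displacement* when the
   roost-to-roost distance (net displacement between the day's first and
   last fix) exceeds 1500 m, or exceeds 1200 m with a ratio of net to total
   5 min track length above 0.3.  Strict inequalities; boundary values are
   normal days.  A matched-day sampler draws, per individual, as many
   random normal days as that individual has large days.
3. **Behavioural states.**  1 Hz blocks are summarised into 10 s bins
   (summed step lengths; summed absolute turning angles at the bin's nine
   interior fixes).  A single four-state HMM is fitted across the whole
   high-resolution dataset: shared diagonal-Gaussian emissions on
   log(distance + 0.1 m) and log(turn sum + 0.01 rad), and one transition
   matrix per context (a saturated categorical covariate, reference =
   group-large).  Fitting is EM with one deterministic quantile start plus
   nine random restarts, each run 25 iterations, the best continued until
   the log-likelihood gain drops below 1e-6 per observation; states are
   relabelled by ascending mean distance, making results invariant to
   initialisation.  Bins are posterior-decoded (forward–backward marginal),
   and every second inherits its bin's state; seconds 2–4 count as moving.
4. **Energetics.**  Terrain slope and aspect come from Horn's 8-neighbour
   method (reflected edges; aspect = direction of steepest ascent, compass
   convention).  The incline experienced on a step is
   θ′ = atan(tan θ · cos Δψ) with Δψ the angle between aspect and bearing.
   Percent grade 100·tan θ′ maps to three cost bands: level (< 5 %,
   including all downhill movement), 10 % (5–15 %) and 20 % (≥ 15 %).
   Per-second cost is VO₂/60 × 20.1 J ml⁻¹ with VO₂ = a_g·v + b_g
   (ml O₂ kg⁻¹ min⁻¹; level 24.0 v + 27.2, 10 % 30.7 v + 27.6, 20 %
   47.7 v + 21.3) for moving seconds and 19.1 for stationary seconds.
5. **Cost of transport.**  Blocks are partitioned into consecutive 50 m
   *net* (straight-line from segment start) or *cumulative* (summed step
   lengths) displacement segments.  The crossing fix closes one segment and
   opens the next; its cost belongs to the closing segment only, so the
   block's opening segment carries one extra second of cost — a boundary
   effect the closed-form checks account for.  Trailing incomplete segments
   are discarded (and logged).  CoT = summed energy / achieved distance.
   Daily energy standardises the day's mean per-second cost to 46 800 s;
   days under 2 h of high-resolution data are excluded.
6. **Metrics.**  Daily track length (summed 5 min displacements), daily
   straightness (net / track length), windowed speed-while-moving (tiling
   windows, > 50 % 1 Hz coverage, strictly) and windowed straightness
   (> 95 % coverage), with a sensitivity grid over window lengths from 30 s
   to 1 h.
7. **Contrasts.**  Linear mixed models (maximum likelihood, statsmodels
   MixedLM) for log track length, log windowed speed, segment CoT (raw
   scale) and daily energy (raw scale); mixed beta regression (logit link)
   for straightness.  Random intercepts: individual everywhere; hour of day
   additionally for windowed speed, windowed straightness and CoT.  Crossed
   intercepts use MixedLM's variance-components formulation.  The beta
   mixed model is fitted by Laplace approximation (inner Newton on the
   joint mode, outer L-BFGS-B over fixed effects, log-precision and
   log-sds; Wald intervals from a finite-difference Hessian) because no
   Python library provides one; it collapses to statsmodels' BetaModel when
   the random-effect variances vanish.  Boundary responses are squeezed by
   (y·(n−1)+0.5)/n.  Percent differences are 100(exp β − 1) for log- and
   logit-scale models; raw-scale coefficients are expressed relative to the
   model intercept, with raw group-mean ratios available alongside
   (`stats.raw_mean_ratio`), since either convention can stand behind a
   published percentage.

## Numerical and design choices

* The 5 s speed smoother is centred (2 s before, 2 s behind), truncated at
  block edges; blocks of one fix get speed 0.
* Turning angles at zero-length steps are undefined and contribute 0.
* The transverse-Mercator projection (Krüger series, 3rd order in the
  third flattening) is centred on the data extent; over a study-area-sized
  extent the distance distortion is far below GPS error.
* DEM cell lookup is half-open with row 0 at the north edge; positions off
  the grid clamp to the nearest edge cell.
* Grade ≥ 25 % still uses the 20 % cost relationship (steeper experienced
  grades are vanishingly rare for a terrestrial walker on 30 m terrain).
* EM convergence: log-likelihood gain < 1e-6 per observation; variance
  floors 1e-6; a fit that leaves a state empty is returned with a flag
  rather than an error.
* Singular random-intercept fits are refitted without the offending
  intercept and flagged in the results.

## Problem sizes

The recovery analyses use a cohort of 3 contexts × 20 individuals ×
10 days (≈ 28 M simulated seconds, ≈ 1 M 10 s bins on high-resolution
days), a direct bin-level harness of 5 × 10⁴ bins per context for HMM
parameter recovery, and 200 reduced null cohorts (3 × 8 individuals ×
3 days over a 1 h window, burst regime only) for type-I calibration of the
contrast intervals.  These sizes give Monte-Carlo error comfortably below
the tolerances being checked while keeping a full validation run on one
CPU in the tens of minutes.

## Known limitations

* The HMM assumes bin-scale Markov dynamics; the generator's bout
  structure satisfies this at lag 10 s by construction, but real data need
  not.
* Emission families (log-Gaussian) are a modelling choice; the manifest
  flags the simulated families so recovery tests are interpreted against
  the matching generator.
* Wald intervals from the Laplace beta model are first-order accurate;
  with very few individuals they can undercover slightly.
* No multiple-comparison adjustment is applied (none is used in the
  motivating analysis).
* Cost coefficients are for a morphologically similar congener walking on
  a treadmill; all costs are per kg of body mass with no allometric
  rescaling.
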