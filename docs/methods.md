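# Methods

This note records the models, conventions and numerical choices behind
`checkfish`, in the order data flow through the package.

## Arena geometry and the visit rule

The open field is a 95 × 95 cm square with two fixed objects; the six
checking zones are discs of radius 10 cm at the object centres and quarter
discs of radius 15 cm anchored at the corner vertices (these radii were
calibrated against blinded human scoring in the original behavioural
protocol and are taken as given). Coordinates put the origin at the SW
corner, x east, y north, in cm; timestamps in seconds; the tracked point
is the head. Zone membership is a Euclidean distance test; the
constructor rejects any geometry in which two zones overlap, so no sample
can ever belong to two zones.

The behavioural literature counts a visit only when the animal *interacts*
with the object or corner, not when it passes through. That distinction is
operationalized deterministically:

* a candidate visit opens at an outside→inside transition of the head;
* it is **confirmed** when the span from the first to the last sample
  inside the zone radius reaches `min_dwell` (default 0.5 s);
* it **closes** at the first sample beyond radius + `hysteresis`
  (default 2 cm), so jitter across the boundary cannot split one
  interaction into several events.

Both parameters are exposed everywhere. The implementation is a
vectorised state machine; the test suite holds it to *exact* equality
with a naive pure-python per-frame oracle over hundreds of seeded
trajectories, including full-length simulated sessions.

## A–F ranking, pooling, standardization

Visits are summed over days 1–10 per animal and the six zones relabelled
A (most visited) through F (least); ties break by the fixed enumeration
order (corner_NW, corner_NE, corner_SW, corner_SE, object_1, object_2) —
the source protocol is silent on ties, so the rule is simply documented.
Ranking aligns idiosyncratic spatial patterns, letting cohorts be pooled
by rank label. Day-11 comparability: day-10 counts (50-min session) are
divided by 10 and the two 5-min probe counts pass through, giving a
common unit of visits per 5 minutes; any other "standardization" reading
would change only the common scale, not contrasts between zones.

Per-day *zone-A dominance* is assessed with one-sided paired t-tests of
rank-A counts against each of B–F across animals (dominant = all five
reject at α = 0.05). A caveat is intrinsic to the design: rank A is
chosen by sorting the same animals' summed counts, so the per-day test is
anti-conservative for unstructured cohorts — simulated control cohorts
show occasional single dominant days. Cohort-level dominance is therefore
defined as dominance on **every** day 4–10, which simulated checking
cohorts always reach and unstructured cohorts essentially never do,
mirroring the qualitative group contrast.

## Trajectory simulator

Movement is bout-based: a goal-directed straight segment to a target
point followed by an exponential dwell (mean `dwell_mean`, default 4 s on
day 1). The arms differ only in target choice and day scaling:

* **QNP arm** — each animal gets one preferred corner and one preferred
  object, a deterministic function of (seed, animal index), so its
  pattern is stable across days by construction. With probability
  `home_zone_attraction` (default 0.75) a bout targets the preferred
  pair, alternating corner ↔ object — the characteristic checking loop.
  Speed multiplies and dwells divide by `sensitization_factor`
  (default 1.15) each day, which makes the *expected daily path length*
  scale exactly as base × factor^(day−1); the day-10/day-1 ratio is then
  1.15⁹ ≈ 3.5, recovered within ~7 % by simulation (boundary truncation
  and tracking jitter account for the shortfall).
* **control arm** — uniform interior targets with a mild wall-following
  bias (`wall_bias` = 0.3 of bouts target a wall-adjacent point) and a
  slight per-day drift (`control_drift_factor` = 1.03, i.e. a
  non-significant 1.03⁹ ≈ 1.3 ten-day ratio, matching the reported
  control locomotion ratio; set 1.0 for perfectly flat kinematics).

Defaults mirror the study design: 15 QNP / 14 control animals, ten 50-min
daily sessions sampled at 25 Hz, two 300-s probes (A1, A2) on day 11,
day-1 speed 8 cm/s capped at 60 cm/s, and 0.03 cm per-frame tracking
jitter. No quantitative kinematics were published for this protocol, so
the bout parameters are stated choices, not inferences; the simulator's
purpose is recoverable ground truth (planted preferences, planted growth),
not behavioural realism. Randomness flows from one seed through spawned
per-animal streams, so output is bit-identical across runs and platforms
and each animal's idiosyncrasy is independent of cohort composition.

## Nucleus-population simulator

Each nucleus draws a latent activity pair from a 2 × 2 joint law
parameterised by the two marginal activity probabilities and a target
similarity s:

    p_double = p1·p2 + s·(min(p1, p2) − p1·p2),

inverted to the four cells and rejected loudly if any cell would be
negative. Exploring-arm defaults use the reported CA1 group proportions
(control 29.4 %/30.6 %, QNP 11.2 %/20.7 % for epochs 1/2), moderate
cortical levels with no treatment effect (ACC/mPFC 15 %, OFC 18 %),
s = 0.3 in both arms, and a 3 % home-cage baseline at independence.
Channel focus intensities come from a positive N(25, 3²) or negative
N(5, 2²) distribution (arbitrary units, ≈4 SD separation, clipped at 0)
according to the latent state. A `glia_fraction` (default 0.15) of
records mimics glia: smaller (N(90,15²) vs N(180,30²)), elongated
(N(2.2,0.3²) vs N(1.3,0.15²)), brighter counterstain (N(160,20²) vs
N(100,15²)), and no IEG signal. Animals are interleaved into slide blocks
(6 animals, 3 slides) so every slide carries exploring animals; the k = 3
weakest true-active nuclei per slide × region × channel among exploring
animals are flagged as threshold exemplars (home-cage animals never are —
their expression is too low to provide weak-positive exemplars). How many
exemplars were picked per slide in the original protocol is unstated;
k = 3 is a stated default.

`n_nuclei_per_region` defaults to 1,500 so that after the mid-Z cut
(20 %) and glia exclusion a few hundred neurons per animal × region
remain analysable — the scale at which the quantified confocal data were
reported. This matters for the similarity score, whose small-sample bias
at a few dozen nuclei differs between arms with different marginals; at
~250 analysed nuclei the bias difference (~0.01) is negligible against
the per-animal score SD (~0.07–0.11).

## Classification chain

1. **mid-Z selection** — keep nuclei with z-centroid fraction in the
   half-open band [0.5 − b/2, 0.5 + b/2), b = 0.20, avoiding truncated
   nuclei at section faces that would read falsely negative. Excluded
   nuclei are marked, never dropped, so counts are conserved. For a
   21-slice stack the band covers centre fractions 8.5/21 through
   12.5/21, i.e. 0-based slices 8–12.
2. **thresholds** — per slide × region × channel, the minimum intensity
   over that group's exemplar nuclei (the exemplars are by construction
   the weakest unambiguous positives, making the minimum the natural
   cut); a low quantile is available for robustness. Thresholds are never
   imputed across slides or regions; a nucleus in a group without a
   threshold is an error, not a guess.
3. **glia exclusion** — `putative_glia` requires *all three*: size below
   the slide's 25 % size quantile, elongation > 1.8 **or** counterstain
   brightness > 140, and both channels below threshold. The
   signal-vetoes-glia clause means an IEG-bright nucleus is never
   excluded however small or elongated. All cuts are parameters with
   logged defaults; the source protocol lists the features only
   qualitatively.
4. **classification** — intensity ≥ threshold is positive (boundary
   counts positive, documented); the two booleans give
   negative/homer_pos/arc_pos/double_pos. Channel→epoch semantics are
   fixed: green/*Homer1a* reports session A1, orange-red/*Arc* session
   A2 (the probe-kinetics convention of the methods protocol).
5. **proportions** — per animal × region counts and fractions of the four
   classes, plus marginals pE1 = p_homer + p_double, pE2 = p_arc +
   p_double. Zero-included groups yield an explicit missing-value row
   with a warning.

On well-separated synthetic populations the chain recovers latent labels
at ≥ 99 % and configured marginals within 3 binomial SE of the analysed
count. Feature extraction from 3-channel TIFF stacks uses provided label
masks (segmentation is out of scope): size = voxel count, elongation =
√(λ_max/λ_min) of the mask inertia tensor, and per-channel focus
intensity = mean of the top 1 % brightest in-mask voxels, which tracks
bright intranuclear transcription foci rather than diffuse background.

## Similarity score

score = (pD − pE1·pE2)/(min(pE1, pE2) − pE1·pE2): 0 at independence, 1 at
the Fréchet upper bound, negative under avoidance; the normalisation
makes animals with different overall activity levels comparable. The
original report does not print the formula (it defers to the established
catFISH methodology); this standard form is adopted and documented as
such. A vanishing denominator (an epoch with zero or saturated activity)
makes the score *undefined* — flagged and excluded listwise from score
ANOVAs with the exclusion count reported, never silently zero. Scores are
computed from per-animal pooled counts (pooling across slides within an
animal); per-slide averaging is not implemented because slide-level
counts are far below the bias-safe regime.

## Statistics

The IEG design is 2 (treatment) × 2 (environment) between × 2 (session)
within, per region. `run_mixed_anova` implements the classical split-plot
decomposition: between effects tested on subject means against
subjects-within-groups; session and its interactions tested against the
session × subject residual, with sequential sums of squares obtained from
nested OLS fits (statsmodels), which keeps interaction degrees of freedom
correct when the subject factor absorbs the between main effects. It
matches `pingouin.mixed_anova` exactly (F and p) on one-between designs,
agrees with a permutation oracle within Monte-Carlo error, and holds the
nominal type-I error (0.05 ± 0.02 over 1,000 null replicates, both
wrappers). The original analyses used SPSS "general mixed models";
replicating a specific covariance structure is out of scope, and the
split-plot ANOVA is the documented stand-in with the same factor
structure. Zero error variance (degenerate data) reports F = ∞, p = 0
with a warning rather than a numerically noisy ratio. Similarity scores
(one value per animal) use a plain two-way between-subjects ANOVA
(pingouin) per region; follow-ups are Bonferroni-corrected Welch simple
effects.

## What passing tests do and do not show

The generators emulate the *design* (cohort sizes, session structure,
activity levels, two-epoch overlap) with clean parametric noise. They do
not emulate video-tracking artefacts, arena inhomogeneity, session
non-stationarity, optical crosstalk, segmentation errors, or
between-animal variability in activity levels beyond binomial sampling.
Parameter-recovery results therefore validate the *pipeline arithmetic
and conventions*, not robustness to real-data pathology; real micrograph
use additionally requires upstream nucleus segmentation.

Problem sizes used by the test and acceptance runs: 200 seeded
1,500-frame trajectories (plus full-length 75,000-frame sessions) for the
visit oracle; cohorts of 15 + 14 animals × ten 50-min sessions for the
behavioural structure checks (ten seeds for the control contrast); 1,000
nuclei per animal × region for marginal recovery and 2 × 10,000 for
overlap recovery; 1,000 null replicates per ANOVA calibration.

## Known limitations

* The visit rule is one deterministic operationalization of
  "interaction"; the human-scoring criterion it stands in for was never
  printed, only the calibrated radii.
* Rank-A per-day dominance tests are anti-conservative under the null
  because ranking and testing share data (see above); conclusions should
  rest on the sustained-dominance contrast.
* The similarity score is bias-prone below ~100 analysed nuclei; the
  package pools within animal before scoring and sizes synthetic
  populations accordingly, but offers no small-sample bias correction.
* Balanced or mildly unbalanced designs are assumed by the split-plot
  decomposition; strongly unbalanced data would warrant a true mixed
  model.
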