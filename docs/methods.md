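# Methods

`forestsignal` detects afforestation, deforestation and fire-regime signals
in stratigraphic palaeoecological records — pollen count tables, charcoal
concentration series — around a documented contact/depopulation year, and
classifies each record semi-quantitatively. This note describes the model
and procedure, the parameters that matter, what the synthetic generator does
and does not emulate, and the numerical and design choices made where the
procedure was genuinely open.

## Record screening

Records are screened before analysis. Three criteria are metadata
assertions that cannot be recomputed from a count table (located in former
colonial territory; directly dated; spanning at least 600–1900 CE); three
are computed: a tropical/subtropical biome flag, the presence of at least
one sample dated 1500–1600 CE, and a temporal resolution finer than 200
years per sample over the most recent two millennia. Resolution is the
clipped window span divided by the number of in-window samples, with the
window fixed at [−50 CE, record top]. A per-site override list retains
sites that narrowly fail (e.g. a culturally critical site at 212 yr/sample).
East-Indies-style records are screened liberally: coverage of the 200 years
before contact plus at least one post-contact sample.

All internal ages are calendar years CE (increasing toward the present);
`ce_to_bp`/`bp_to_ce` convert to the cal-yr-BP convention (present = 1950).

## Composition: functional groups and openness

Pollen taxa are collapsed into nine plant functional groups: five arboreal
(tropical trees, montane trees, conifers, shrubs, palms), two non-arboreal
dryland (grasses, dry herbs) and two excluded from the openness proxy
(aquatic/wetland taxa and ferns, whose fluctuations typically record local
hydrology, not regional forest cover). The packaged default taxon→group
assignment is a small seed list; real analyses supply a YAML map per record,
and unmapped taxa fall into an excluded `OTHER` bin by default so unknown
taxa cannot move the proxy.

Landscape openness is the bounded proportion NAP/(NAP+AP) over dryland taxa
(higher = more open), rather than the unbounded quotient NAP/AP, because the
downstream transform is a logit, which needs (0, 1) support. A grass-only
numerator variant (`GRASS_AP`) covers records where only grass curves exist.
Charcoal concentrations (fragments cm⁻³) are converted to influx (fragments
cm⁻² yr⁻¹) by dividing by the deposition time |d age/d depth| from the
age–depth model, evaluated by central finite difference with step h = 0.1 cm
(below typical sampling resolution).

## Age–depth models

Bayesian age modelling is out of scope: the chronology module consumes
already-calibrated control points (depth, age, age sd) and interpolates them
linearly or with a shape-preserving monotone cubic (PCHIP), which cannot
overshoot and therefore preserves the strict age decrease. Extrapolation
beyond the control range uses the terminal segment's slope and is flagged.
Gaussian perturbation of control ages (rejection-sampled to stay monotone)
supports Monte-Carlo sensitivity runs.

## Trend fitting

Each proxy series is standardized — logit for proportions (clamped to
[ε, 1−ε], ε = 1/(2·max counting sum), or 1e−3 when counts are unknown),
log(x+1) for counts/frequencies — and z-scored (sample sd, n−1). Trends are
fitted with a one-dimensional low-rank thin-plate regression spline: radial
basis |t−t′|³ (order-2 penalty, null space {1, t}), eigen-truncated to rank

    k = max(ceil(n/10), 5),   capped at n − 1,

with the smoothing parameter chosen by REML (GCV available as a sensitivity
option). The implementation reproduces R mgcv's `s(t, bs="tp")` REML fit to
~1e−6 in fitted mean, standard error and effective degrees of freedom (one
test runs that comparison through Rscript). Pointwise 95% bands are
μ ± 1.96·s from the penalized fit's Bayesian posterior covariance. The time
axis is internally rescaled to [0, 1] for conditioning (|t−t′|³ over
millennia is otherwise badly scaled); the reported λ lives on that scale.

First derivatives come from finite differences of B = 200 posterior draws of
the curve on a 10-year grid (fixed seed, so interval endpoints are
reproducible); a grid point "detects" a trend where the 2.5–97.5 percentile
interval of the draws excludes zero.

## Zonation

CONISS: agglomerative clustering of per-sample functional-group proportion
vectors in which only stratigraphically adjacent clusters may merge; each
step merges the pair that least increases the total within-cluster sum of
squares (squared Euclidean dispersion about the cluster mean). Ties break
toward the youngest pair, making the tree deterministic. An optional
square-root transform of proportions is off by default. The implementation
agrees with scikit-learn's contiguity-constrained Ward clustering at every
cut level on randomized checks.

The number of significant zones compares each successive dispersion
reduction with its broken-stick expectation — the expected j-th largest of
n−1 random stick pieces, (TSS/(n−1))·Σ_{i≥j} 1/i — and takes the largest
cluster count whose reductions all exceed expectation (the conventional
crossing rule; minimum one zone). Note that greedy agglomeration does not
always attain the per-level optimal contiguous partition: the per-level
optima need not nest into a single tree. On random compositions with n ≤ 6
the greedy tree attains the exhaustive optimum at every level in roughly
88–90% of instances (the acceptance script recomputes this rate), is always
optimal at its first merge, and is never below the optimum. This is a
property of the classic algorithm, not of this implementation.

## Classification

Windows are anchored on the site's contact year c: the post window
[c, c+100] is compared against the baseline [c−100, c]; the pre-contact
period is [1000, 1400] CE (Neotropics) or [1000, c] (East Indies), with its
proxy comparison taken between the period's final and first centuries and
its trend/zonation evidence counted anywhere inside the period. (A
baseline outside the pre period — e.g. 900–1000 CE — was rejected: with
typical ~50-year sampling it holds ~2 samples and makes the comparison
noise-dominated.)

Three lines of evidence per window:

* **Proxy direction** — window-mean openness vs baseline mean, at threshold
  θ = 0.02 on the proportion scale (closing / opening / flat).
* **Trend direction** — derivative sign detections inside the window. Each
  contiguous detected run is attributed to its |slope|-weighted centre and
  must reach 50% of the record's peak same-sign slope; this keeps the
  smeared tail of a transition centred centuries away, or a featureless
  millennial drift fitted as a straight line, from registering inside a
  later window.
* **Clear compositional change** — a zonation boundary inside the window
  (dendrogram cut at ≥2 clusters) whose arboreal-share change reaches
  δ = 5 percentage points, signed.

Because smoothing at rank k over ~2,000 years plus ~50-year sampling blurs
apparent event timing (and blurs it asymmetrically late — a transition is
expressed only once enough younger samples record the new state), the trend
and boundary windows are padded by 75 years before and 250 years after.
These pads were calibrated on the synthetic generator by measuring where
fitted transition centres and zone boundaries actually land for events of
known timing; they, θ, δ and the localization fraction are all `Thresholds`
config keys, and `sensitivity_sweep` reports class stability across a grid.

Classes follow a strict precedence. Full post-contact afforestation needs
proxy closing ∧ trend closing (∧, in the Neotropics only, a clear signed
compositional change); minor/unclear afforestation is proxy ∧ trend without
the compositional change, or proxy ∧ compositional change without the trend.
Deforestation mirrors with opening. Only if no post-contact class fires is
the pre-contact window tested for a (full or minor) afforestation pattern;
otherwise the record is a limited forest response. Fire classes are the
charcoal analogue: a ≥20% relative change in window-mean influx plus a
matching trend detection is a full increase/decrease; one line of evidence
without the other is minor; records without usable charcoal data are
not-applicable. Post-1850 change is reported descriptively but never enters
the headline classes.

## Synthetic records

`ScenarioSpec` draws records with the statistical structure the analysis
assumes: sample ages even, jittered (default) or clustered over [0, 1950]
CE; per-sample expected composition derived from a piecewise-linear arboreal
fraction (of the dryland sum) with an optional step/ramp event, split across
the nine groups with fixed within-role weights plus a 15% excluded
(aquatic/fern) share; counts Dirichlet-multinomial with precision φ = 50
around a Poisson(300) counting sum, n = 40 samples by default. Charcoal
twins draw gamma-noise concentrations whose mean steps by a multiplier at
the event year, on a linear age–depth model. Everything is deterministic
given the scenario seed. The library ships five documented scenarios
(post-contact afforestation with fire decrease, pre-contact afforestation,
post-contact deforestation with fire increase, industrial-era deforestation,
stationary null).

The generator emulates compositional noise, irregular sampling and coupled
sedimentation; it does **not** emulate taxonomic richness gradients,
pollen-productivity bias, taphonomic loss, age-model structure beyond
linearity, or autocorrelated environmental variability. Passing tests
therefore demonstrate that the pipeline recovers signals of stated size
under realistic counting noise — not that it would resolve the messier
chronological uncertainty of real archives.

## Operating characteristics and limitations

At the default study conditions (ΔAP = 0.15 events, n = 40, counting sum
~300, φ = 50), per-sample openness noise has sd ≈ 0.07, so a comparison of
two 100-year window means (~2 samples each) carries noise sd ≈ 0.075. This
sets hard limits: the post-contact proxy comparison detects a true event in
roughly 9 of 10 records, and false-fires on a stationary pair of windows
roughly a third of the time, while the rank-5 spline (identical to mgcv's)
cannot localize a step much better than ±200 years. Sensitivity to true
post-contact events and selectivity against mis-dating pre-contact events
therefore trade off directly; the default thresholds sit at a balanced
operating point where `scripts/acceptance.py` measures recovery of
post-contact events, pre-contact events and stationary nulls each in the
mid-80s-to-mid-90s percent range. Tightening θ or the pads raises one rate
at the other's expense — `sensitivity_sweep` quantifies this per record.

Other limitations: records with two genuine transitions of the same sign
attribute only the stronger to a window; the broken-stick rule is
conservative for gradual change; the default functional-group map is a
stand-in that real analyses must override; and classification quality
degrades quickly when the contact century holds fewer than two samples
(such windows are flagged insufficient rather than guessed).
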