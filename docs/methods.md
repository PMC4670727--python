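# Methods

## Model structure

The state vector holds inactive receptor R, active receptor R\*, internalized
receptor R_i\* (internalization variant only), the active fractions of the
three cascade tiers (Raf\*, MEK\*, ERK\*), the two feedback species (NFB\*,
PFB\*), and DUSP mRNA and protein. Concentrations are dimensionless with all
totals defaulting to 1; time is minutes. Every kinase and feedback cycle is
conserved (X = X_tot − X\*), so inactive forms are never integrated
explicitly and conservation holds to machine precision by construction.

Receptor activation is first-order in the saturating dose drive
u = dose/(dose + K_gf); K_EGF = 0.1 ng/ml and K_NGF = 0.2 ng/ml place the
low reference doses (1 ng/ml EGF, 2 ng/ml NGF) at ≥ 90% of the high-dose
drive, consistent with the saturated, switch-like first peaks above those
thresholds. Receptor kinetics are deliberately slow (k_on·u ≈ 0.12/min,
k_off = 0.35/min): the ~3-min receptor tail after a pulse is what lets the
feedback gates — which require receptor activity — see the ERK transient
that peaks only after a 3′ pulse has ended.

The cascade uses Michaelis–Menten activation/deactivation pairs. The Raf
tier is driven far above its deactivation capacity (≈ 6-fold at saturating
dose), which makes the first ERK peak dose-insensitive; the MEK and ERK
tiers are graded so that feedback-level changes in Raf drive are visible in
the ERK output.

### Negative feedback

NFB activation is

```
dNFB*/dt = k3_F · s · e(ERK*) · K(R*)/(K(R*) + NFB*) · (NFB_tot − NFB*) − d · NFB*
```

with e(ERK\*) = ERK\*/(K_E + ERK\*) saturating (K_E = 0.1) and a
product-inhibition ceiling K(R\*) = K_s · [basal + (1−basal)·f_N(R\*)] gated
by a saturating (Hill) function of receptor activity. Inhibition of Raf
activation is 1/(1 + (g·NFB\*)²). Three design features matter:

* activation is *fast* but *stalls* at a ceiling, so each pulse refills NFB
  to the same level within minutes — giving the 10-min refractory window
  without requiring slow decay;
* the *ceiling*, not the rate, carries the receptor feed-forward input, so
  the standing feedback strength in a pulse train is dose-ordered even
  though the suppressed ERK level would otherwise erase the contrast (an
  AND-gate on the rate is self-defeating: stronger feedback lowers ERK,
  which lowers feedback activation);
* decay (d = 0.2/min) is fast enough that a single pulse's NFB has relaxed
  20 min later, reproducing full second-peak recovery.

k3_F = 0.0286/min is the published negative-feedback strength; it scales
the loop as a whole and is the parameter rescanned (0.0286 → 0.0045 →
0.001/min) in the crosstalk-removal analysis. The fixed internal scale s
converts it to the minute-scale onset the data require. Removing a
feed-forward crosstalk pins the corresponding gate at its ceiling of 1 —
i.e. the loop runs at full strength, no longer modulated by receptor
activity.

### Positive feedback

PFB activation is cooperatively gated by ERK (fourth-order Hill,
half-point 0.2) and by the receptor feed-forward gate, and decays slowly
(0.008/min). Its drive onto Raf,

```
pos = g_P · f_E(ERK*) · PFB*² / (K_p + PFB*),
```

bypasses the NFB inhibition (a parallel activation route) and is convex in
PFB\* so that trace amounts leak no drive. The latch is a race: when the
pulse ends, ERK collapses under NFB unless the PFB level accumulated during
the pulse is high enough to re-ignite the cascade once NFB relaxes. A 10′
high-dose pulse crosses that threshold, a 10′ low-dose pulse (weaker
receptor gate) and 3′ pulses (insufficient accumulation time) do not. In
pulse trains the standing PFB built over repeated pulses boosts late peaks,
which is why NGF trains desensitize least. The whole pathway is gated off
for EGF (zero flux), making EGF simulations exactly invariant to PFB
parameters.

The feed-forward modality for PFB is Hill-shaped by default; the LINEAR
modality is a clipped line matched to the Hill curve's half-effect point
*and* its local slope there. A line through the origin cannot retain any
dose contrast after the receptor drive has saturated, so slope matching is
the calibration that makes the two modalities comparable; with it, both
yield identical transient/sustained classifications for all four
single-pulse NGF conditions.

### DUSP module

ERK\*-proportional mRNA synthesis, first-order translation, and mRNA and
protein degradation fixed at ln 2/90 per min (90-min half-lives). DUSP
protein adds a Michaelis–Menten ERK dephosphorylation flux. This is the
hour-scale eroder: it contributes the slow component of multi-pulse decay
and guarantees that bistable cells eventually shut off; removing DUSP
synthesis makes a latched cell sustained indefinitely.

### Receptor internalization variant

Replaces the NFB crosstalk with explicit receptor traffic: synthesis and
degradation with an 8-h half-life, internalization of active receptor at
0.22/min, recycling at 20% of that, and degradation of internalized
receptor with a scannable half-life (default 30 min). Because receptor
occupancy is nearly dose-saturated, no internalization half-life produces a
dose-dependent difference in train desensitization — the signature that
rules this mechanism out.

## Simulation

LSODA with rtol 1e-8 / atol 1e-10, integrated segment-by-segment between
stimulus switch times (the drive is constant within a segment, so pulse
edges are never smeared). Initial conditions come from a resting-state
solve (long zero-drive integration polished by a Newton solve to residual
< 1e-8); ensembles recompute the resting state per cell because each cell's
totals differ and every cell must start on a flat baseline. Ensemble totals
(all kinase, feedback-protein and phosphatase totals) are lognormal with
median equal to the reference value and log-sd 0.25; sampling is
reproducible bit-for-bit from the seed. Multi-pulse horizons are rounded to
whole pulse periods (~5 h) so that the final pulse is never truncated. The
right-hand side is jit-compiled with numba when available; a 1000-cell,
70-min ensemble takes ~10 s on one CPU.

## Trajectory metrics

Normalization divides by the mean of the five samples immediately before
stimulus onset (fold-change semantics for ratiometric data). First-peak
amplitude is the change from the value at onset to the first-response
maximum; duration uses the sample-point half-maximum rule (last sample
below half-max before the rise, first below after the fall; an
interpolating mode exists but is off by default); traces that never descend
below half-maximum are reported right-censored. A trajectory is classified
*sustained* when its activity excess 40 min after onset is at least half
the first-peak amplitude (the 0.5 fraction and the 40-min horizon are
configuration, not biology; no published numeric rule exists). Pulse-train
decay is the excess of the last pulse maximum over baseline divided by the
first. ERK^INT is the trapezoidal integral of baseline-subtracted activity,
floored at zero per sample. Oscillatory responses are not auto-detected;
they fall into the transient/sustained dichotomy by the 40-min rule.

Dose-saturation comparisons measure the ERK excess at a fixed early time
(8 min post-stimulus, the model's first-peak time): the sustained high-NGF
trace climbs monotonically from its first-peak shoulder into the
positive-feedback plateau, so a window-maximum rule would compare plateaus
rather than first peaks.

## Clustering

Trajectories are pooled on the common grid and clustered with k-means
(squared Euclidean distance, k-means++ seeding, best of 50 restarts,
deterministic per seed), k = 5 by default. No standardization is applied:
amplitude differences carry the biology. Unequal-length inputs are
truncated to shared support.

## Synthetic data

The measured-data generator maps simulated ERK activity to an emission
ratio ER = 1 + 0.4·ERK\*/ERK_tot (peak fold-changes ~1.2–1.5, typical for
ratiometric biosensors) and applies per-sample multiplicative lognormal
noise (σ = 0.02 by default). It emulates: flat pre-stimulus baselines,
switch-like first peaks, heterogeneous transient/sustained shapes, and
lognormal cell-to-cell parameter variability. It does not emulate
photobleaching, segmentation artifacts, cell movement, flow-onset
transients, or biosensor saturation — so pipeline tests passing on this
generator demonstrate correctness of the analysis operators, not robustness
to every imaging artifact. The planted-cluster generator uses closed-form
templates (difference of exponentials, saturating rise, damped oscillation,
slow decay, low amplitude) with lognormal amplitude jitter, retaining
ground-truth labels. Every dataset carries a manifest (seed, spec, content
hash) sufficient for exact regeneration.

## Calibration and problem sizes

Parameter values not fixed by published numbers (k3_F = 0.0286/min; DUSP
half-lives 90 min; internalization 0.22/min with 20% recycling and 8-h
receptor turnover) were calibrated once against the qualitative behavioral
signatures — sustained-stimulation phenotypes, refractory timing, train
desensitization ordering, latch selectivity, ablation signatures — and
committed to `defaults/full_model.json`. The shipped analysis sizes
(1000-cell ensembles for classification fractions, 200-cell ensembles for
ablation comparisons, ~5-h train horizons, 150-cell synthetic recovery
sets) were chosen so the complete acceptance computation runs in a few
minutes on a single CPU.

## Known limitations

* The model is single-compartment; nuclear/cytosolic ERK shuttling, AKT and
  other parallel pathways are out of scope.
* Only total-abundance parameters vary across the ensemble; kinetic
  constants are shared by all cells, and there is no intrinsic (molecular
  noise) or temporal parameter fluctuation.
* Several kinetic forms (the NFB stall ceiling, the ERK-gated convex PFB
  transfer) are phenomenological devices chosen as the simplest forms that
  reconcile the fast-feedback timing constraints; they are not
  mechanistically identified.
* The bistable latch margins are calibrated for the reference doses and
  σ = 0.25 population spread; far outside that regime the classification
  fractions shift.
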