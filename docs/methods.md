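# Methods

This note documents the models, numerical choices and limitations of
`crocinopt`. The package optimizes a UHPLC gradient separation of
saffron crocins over three factors — column temperature T (°C),
gradient duration t_g (min) and eluent flow rate φ (mL/min) — by
modelling adjacent-peak resolutions with a neural-network surrogate
and maximizing a global resolution objective over the factor domain.

## Experimental design

The calibration design is a three-level full factorial on coded levels
{−1, 0, 1} in (T, t_g, φ), 27 points, mapped linearly to the natural
domain T ∈ [25, 35] °C, t_g ∈ [8, 12] min, φ ∈ [0.6, 1.0] mL/min.
The default campaign adds two replicate runs of the center point
(0, 0, 0), bringing the calibration block to 29 chromatograms; center
replication is standard practice for estimating pure error in a
factorial campaign and keeps all downstream sample counts
(29 × 21 = 609) consistent. Eight further runs at the centers of the
eight cubic subspaces of the domain — coded (±0.5, ±0.5, ±0.5) — are
held out for external validation and never touch training, validation
or scaling statistics. Point ordering is lexicographic in coded levels
(T slowest, φ fastest), which is a fixed convention so that run ids,
and therefore the Kennard–Stone split and every artifact hash, are
stable; no randomization of run order is modelled.

## Synthetic chromatograms

Real peak tables for such a campaign are not publicly available, so
the generator produces them. Each of the 22 tracked analytes i has
ground-truth parameters (base retention time, four selectivity slopes,
base half-height width) drawn once per master seed. At a condition
with coded levels (c_T, c_tg, c_φ) and natural flow φ:

    rt_i = base_rt_i · (0.8/φ)^0.85
           + s_tg,i · c_tg + s_T,i · c_T + s_TxTg,i · c_T · c_tg + s_φ,i · c_φ + ε
    w_i  = width_base_i · (rt_i / base_rt_i) · (φ/0.8)^0.3 · (1 + η)

with ε ~ N(0, 0.005 min) and η ~ N(0, 0.02) (relative). The
multiplicative power law in φ captures the first-order effect of flow
on gradient elution: lower flow stretches the whole chromatogram
(exponent 0.85, slightly sub-linear because the gradient program is
fixed in time, not in volume) while widths grow more slowly (exponent
0.3), so resolution improves toward φ = 0.6. The linear coded terms
are analyte-specific selectivity shifts, and the T × t_g interaction
makes temperature and gradient effects non-additive — without an
interaction a quadratic polynomial would suffice and the network
surrogate would be pointless. The realized (noisy) retention time
enters the width scaling, so retention and width noise are weakly
coupled, as they are in integrated peak tables.

Base retention times span ≈ 5.3–12.3 min at the center point. Ten
adjacent pairs — positions (4,5), (5,6), (7,8), (9,10), (11,12),
(12,13), (13,14), (14,15), (15,16), (21,22) — receive small center
gaps (0.05–0.09 min against widths of 0.035–0.055 min) and slope
increments biased so that longer gradients and lower temperatures open
them up; the remaining pairs get wide gaps (0.42–0.68 min) and larger,
sign-free increments. This places the true separation optimum at the
(T = 25 °C, t_g = 12 min, φ = 0.6 mL/min) corner of the domain — a
boundary optimum, the generic case for resolution maximization — and
makes the ten close pairs the ones whose resolution actually depends
on the conditions. The per-analyte percentage-area vector is a fixed
fixture with one dominant analyte (45 %, the t-4GG analogue at
position 4) and a realistic tail of minors; it sums to 100 exactly.

Default noise levels (0.005 min retention SD, 2 % width CV) are small
relative to peak widths, consistent with the run-to-run repeatability
of a modern UHPLC within a day. Everything emitted is a deterministic
function of (master seed, design point id, replicate seed).

The noise-free model doubles as the ground-truth oracle:
`true_global_resolution` evaluates it through the same resolution code
path the pipeline uses, and `oracle_argmax` scans it on a dense grid.
Parameter-recovery tests therefore compare two routes that share only
the resolution arithmetic, not the surrogate.

What the generator does *not* emulate: signal-level detector traces,
peak tailing and asymmetry, co-elution-induced area bias, drift
between days, or peak-matching errors (analyte identity is carried
explicitly). Passing recovery tests shows the pipeline recovers the
structure it assumes; it does not certify performance on real
chromatograms where those effects are present.

## Resolution and response

R_ij = 2·(RT(j) − RT(i)) / (W½(i) + W½(j)) for the 21 consecutive
pairs of the 22 ordered peaks, with W½ the full width at half height
and the leading factor 2 kept as-is (this statistic, not the
USP/1.18-based definition, is the modelled quantity). A negative gap —
an elution-order swap under noise — is floored to R = 0: for
optimization purposes a swapped pair is maximally unresolved, and an
absolute value would reward swaps. The regression response is
y = log₁₀(R + 1), base 10; on that scale the working R_G values
(≈ 0.3–0.5) correspond to mean pair resolutions around 1–2, the
chromatographically interesting regime, and the transform compresses
the well-separated pairs so their error does not dominate the loss.

## Dataset encoding and splitting

Each (condition, pair) record becomes a 25-vector: (φ, t_g, T)
followed by 22 indicator bits with exactly bits i and i+1 set. The
variable order is a frozen convention. One network sees all pairs at
once; the bit pattern acts as a learned per-pair offset into the
hidden layer, which is what lets 29 chromatograms support a
609-sample regression.

The 609 calibration samples are split 486/123 by classic
Kennard–Stone: seed with the two mutually most distant samples, then
repeatedly add the candidate maximizing its minimum Euclidean distance
to the selected set. Distances are computed on auto-scaled (z-scored)
25-vectors including the bits — excluding them would make samples of
the same condition coincide — and excluding the response. Ties break
toward the lowest sample index, making the split fully deterministic.
External samples are scaled with the calibration statistics, never
their own.

## Network and training

Architecture 25-H-1: one hidden layer (logistic or tanh), linear
output neuron. Inputs and output are range-scaled to [0, 1] on the
calibration set; external samples may fall slightly outside and are
not clipped. Weights initialize uniformly in (−0.1, 0.1).

Training minimizes full-batch MSE by BFGS (scipy's implementation,
strong-Wolfe line search) with analytic backpropagation gradients;
full-batch quasi-Newton is appropriate at ~600 samples and ~220
weights. One epoch is one BFGS iteration. After each epoch the
validation MSE is recorded; training stops when it has not improved
for `patience` epochs (default 30) or at `max_epochs` (default 1000),
and the returned weights are those of the validation-minimum epoch.
The patience is deliberately generous: quasi-Newton validation traces
make tiny non-monotone moves between line searches, and stopping on
the first uptick (or after only a few) leaves the surrogate visibly
under-converged. On noise-free data training typically runs 50–300
epochs before the gradient norm or patience ends it.

Because a single initialization can land in a poor local minimum, the
chosen architecture is re-trained `restarts` times (default 100,
matching the full protocol; the tests and the acceptance script use 10
as a scaled-down count) from seeds master+0, master+1, …, and the
ensemble prediction is the arithmetic mean of member outputs on the
natural response scale. All restarts share one Kennard–Stone split.
An exhaustive grid scan over H ∈ {2, 4, 6, 8, 10, 12, 16} × {logistic,
tanh} is available (`select_architecture`); the pipeline default is
the fixed 25-8-1 tanh topology, which on the seed-0 noise-free fixture
reproduces the simulator's R_G surface to a maximum absolute deviation
of about 0.016 — inside the 0.02 band the recovery tests require.

Fit metrics are R² = 1 − SS_res/SS_tot and SE = root mean squared
residual, both on the natural y scale.

## Surface and optimum

R_G(T, t_g, φ) is the arithmetic mean of the ensemble-predicted y over
the retained pairs ("mean" rather than median: the objective should
feel every retained pair, including the worst ones). Predictions are
floored at 0 before averaging since y is nonnegative by construction;
without the floor, mild extrapolation artifacts could push R_G
negative. The default retained set is the ten close pairs above; an
automatic variant retains every pair whose y range across the campaign
exceeds 0.05, for campaigns where the fixed list is not appropriate.

Surfaces are evaluated on a 0.25 °C × 0.01 mL/min grid at fixed t_g
(the three design levels 8/10/12 min for reporting); the optimum
search additionally scans t_g in 0.1 min steps, 41 × 41 × 41 ≈ 69 k
nodes in total. The argmax is reported with ties broken toward lower
φ, then lower T, then lower t_g (solvent and thermal economy), plus a
boundary flag and any near-optimal alternatives at shorter t_g within
ΔR_G ≤ 0.005 — a separation 0.005 worse but two minutes faster is
usually the better method, and the report surfaces that trade-off
instead of deciding it.

## Diagnostics

*Sensitivity*: the analytic partial derivative of the ensemble output
with respect to each [0, 1]-scaled factor input, averaged in absolute
value over the calibration samples and normalized to sum 1 across the
three factors. Derivatives with respect to the bit inputs exist but
are excluded from the report — an indicator variable has no marginal
perturbation worth interpreting.

*SRD/CRRN*: absolute residuals |y_pred − y_obs| per pair (21 objects)
are compared across calibration design points. Within each column the
objects are ranked (midranks for ties); a point's SRD is the sum of
absolute rank differences against the center point's column, center
replicates having been averaged into a single reference column first.
Absolute rather than signed residuals are ranked because a ranking of
signed residuals would conflate error direction with magnitude.
Normalization uses the maximum attainable SRD, n²/2 for even n and
(n² − 1)/2 for odd n. The null distribution (CRRN) is simulated by
scoring uniformly random rankings against the same reference, a
Gaussian is fitted by moments, and the report gives both the fitted
mean ± 1.96 σ band and the empirical 2.5/97.5 percentiles, plus a
per-point inside-the-band flag. The report deliberately encodes no
interpretation of "inside": by the conventional CRRN reading a point
inside the band ranks residuals indistinguishably from chance, which
for *residuals* means no design point is modelled systematically
differently — the reader decides which framing applies.

## Quantification

c_i (mg/g) = Mw_i · E1%1cm(440 nm) · A_i / ε, with A_i the percentage
of the total integrated 440 nm area (all integrated peaks, not crocin
peaks only), E the ISO-3632 coloring strength supplied by the user,
and ε = 89,000 (trans) or 63,350 (cis) M⁻¹cm⁻¹. The relation is an
empirically validated convention from the spectroscopic literature and
is implemented exactly as stated; its units do not reduce
transparently (a molar extinction coefficient against a mass-based
E1%), so no hidden conversion factor is inserted, and users comparing
against first-principles calibrations should treat the outputs as
method-consistent rather than absolute. Molecular weights follow
Mw = 328.40 + 162.14 · n_glucose (crocetin core plus anhydroglucose
units); a built-in table covers the named crocins (t-5tG … t-1g,
c-4GG … c-2G) and per-analyte overrides are accepted. Because A_i is
a percentage, any common scale factor on raw areas cancels.

## Problem sizes and determinism

Default test and acceptance runs use 10-restart ensembles, the
0.25 °C × 0.01 mL/min surface grid and a 0.1 min t_g scan; a full
campaign (training, surfaces, optimum, diagnostics, quantification)
completes in seconds on one CPU, and the 100-restart protocol scales
linearly. Every random draw — analyte parameters, measurement noise,
weight initializations, CRRN rankings — descends from the single
master seed, so reruns reproduce artifact hashes exactly; the run
manifest records seeds, versions and SHA-256 hashes for audit.

## Known limitations

- The surrogate is only as good as the peak table: peak tracking
  across conditions is assumed solved, and co-elution bias on areas is
  not modelled.
- The retention model is a deliberately simple closed form; it spans
  the qualitative behaviour (flow power law, selectivity shifts, one
  interaction) but not gradient-theory subtleties such as pre-elution
  isocratic holds or dwell-volume effects.
- R² / SE values obtained on synthetic campaigns reflect the
  generator's small noise levels and are not comparable to values
  obtained on instrument data.
- The grid argmax is exact only to the grid step; no continuous
  refinement is performed (at 0.25 °C / 0.1 min / 0.01 mL/min the step
  is below any practically settable increment).
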