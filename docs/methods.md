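# Methods

## Measurement model

During rebreathing through an external dead space (volume DV) the CO₂
expired into the dead space at partial pressure avPet is re-inspired and
redistributes in the effective lung volume ELV — the gas compartment
(FRC) plus the lung tissue and pulmonary capillary blood in which CO₂
equilibrates. Mass balance for one breath gives the end-tidal rise
ΔPet = avPet·DV/ELV, hence ELV = avPet·DV/ΔPet. avPet is taken as the
end-tidal value of breath 0 (the expiration that fills the dead space);
with DV/TV below ~0.25 the CO₂ level decays roughly linearly along the
dead space, so the mid-dead-space sampling point reads a representative
average, which we treat as equal to the airway-opening end-tidal value.

The wash-in of the dead-space CO₂ is summarised by a single exponential
with rate constant k (default 0.06 s⁻¹; 90% of the plateau rise at
ln(10)/k ≈ 38 s). Metabolic CO₂ production and recirculation are not
modelled separately; their net effect is absorbed into k. Breath-wise,
with period T and a = e^(−kT):

    Pet(n) = Pet0 + ΔP∞·(1 − aⁿ),     ΔP∞ = Pet0·DV/(ELV·(1 − a)).

This parameterisation makes the first-breath rise exactly the ideal
increment Pet0·DV/ELV, so the estimator below is exact on noiseless
simulator output — the package's primary oracle.

## Two-breath estimator and the second-breath weight

With cumulative rises ΔPet1 = Pet(1)−Pet(0) and ΔPet2 = Pet(2)−Pet(0),

    ΔPet = 0.5·(ΔPet1 + w·ΔPet2),    ELV = 2·avPet·DV/(ΔPet1 + w·ΔPet2),
    FRC  = K·ELV.

Under the exponential model ΔPet2 = ΔPet1·(1+a), so w = 1/(1+a) =
1/(1+e^(−kT)) makes the estimator exact; at k = 0.06 s⁻¹ and T = 5 s this
is 0.574, which motivates the shipped fixed default w = 0.57. The fixed
weight is exact near 12.8 breaths/min and biases ELV by < +9% at
4.6/min and about −2% at 16.8/min (tabulated in the test suite; the sign
follows from the denominator: w too small ⇒ ELV too high).

`weight="auto"` refines w per record by fitting the wash-in to *all*
detected breaths. The fit is done in breath-index domain,
Pet(n) = p0 + A(1 − ρⁿ) with ρ = e^(−kT) and w = 1/(1+ρ): index-domain
fitting is immune to the sample-grid quantisation of detected breath
times, which a clock-time fit propagates into ~10⁻⁴ relative ELV error.
A clock-time exponential fit (`fit_rebreathing_kinetics`, ≥ 4 breaths
spanning ≥ 15 s) is kept for reporting k itself. If the geometric fit
fails (non-rising sequence, ρ outside (0,1)) the estimator falls back to
w = 0.57.

K defaults to 0.82 (healthy adults); values reported in ventilated
patients (≈0.88 non-ARDS, ≈0.77 severe ARDS) can be supplied instead.
The geometry module's sphere-layer check — tissue+blood spread as a layer
of thickness h = (V_t+V_b)/A over the alveolar surface, FRC/ELV =
r³/(r+h)³ for an average 125 µm alveolus — gives 0.86–0.81 for
h = 6.7–8.9 µm, bracketing 0.82. (Direct evaluation of the cube ratio is
reported; no attempt is made to reproduce any differently rounded
interval.)

## Breath segmentation

Samples are classified expiratory/inspiratory by a Schmitt trigger on an
adaptive mid-range threshold: mean of the running minimum and maximum
over a sliding window of one nominal breath period, hysteresis 10% of the
running range. A fixed threshold fails during rebreathing because the
inspiratory trough climbs towards ~0.8× the previous end-tidal value; the
one-period window keeps the threshold between the *current* trough and
plateau. Phases shorter than 0.3 s are merged into their neighbours to
suppress threshold chatter under noise. The nominal period comes from the
autocorrelation of a band-passed copy of the signal (0.3 s smoothing
minus a 10 s running mean), skipping the first quarter of the trace so
the manoeuvre-onset step does not dominate, with a subharmonic guard
(earliest peak within 60% of the strongest). Degenerate inputs: a trace
whose running range never exceeds 0.2 kPa raises "no respiratory signal";
fewer than three detected expirations raises "insufficient breaths".

End-tidal extraction: median-of-3 smoothing (edges passed through), then
the maximum over the final 25% of the expiratory phase; a width-1 spike
cannot survive the median, and ties resolve to the later sample. Both the
tail fraction and the hysteresis are configurable.

## Simulator

Each breath is rendered as a sigmoid expiratory upstroke (0.4 s), a
linearly rising alveolar plateau ending at that breath's Pet, a 0.15 s
end-expiratory pause held exactly at Pet, and a sigmoid inspiratory
downstroke to the trough (dead-space gas at 0.8× the previous Pet during
rebreathing; ~0 beforehand). Expiration occupies 60% of the period. The
pause guarantees that at zero distortion several consecutive samples
equal Pet(n) exactly, so median-of-3 extraction returns Pet(n) to machine
precision — without it the plateau→downstroke corner loses one sample of
slope and the exactness oracle degrades to ~10⁻³ kPa. The clean waveform
then passes a first-order analyzer lag (default τ = 0.15 s), a transport
delay (0.5 s) and additive Gaussian noise (SD 0.05 kPa) from a single
seeded generator per call; the seed is recorded in the trace metadata.

Default study conditions: tidal volume 1.1 L and respiratory rate
11/min (the cohort means), DV = 0.148 L, baseline Pet₀ = 5 kPa (typical
resting end-tidal), k = 0.06 s⁻¹, sampling 25 Hz (typical sidestream
module), six breaths per record (≈33 s at the mean rate), 1 s lead-in
before the first expiration. The simulator refuses DV/TV outside (0, 0.5).

Artifacts: `leak` scales all pressures after the onset of rebreathing
(end of breath 0's expiration) by 1 − severity, emulating dead-space gas
escaping — the apparent rise shrinks and ELV biases high until the
non-rising-Pet guard trips. `irregular_breathing` draws per-breath
log-normal factors with log-SD ln(1 + severity) (a ±severity·100%
one-sigma multiplicative band) and applies them as a time-warp of each
breath and a scaling of the expiratory excursion above the local
baseline. Severity → 0 returns the input unchanged.

What the simulator does *not* emulate: ventilation/perfusion
heterogeneity, CO₂ dissociation-curve chemistry, baseline drift,
cardiogenic oscillations, and recording sessions with long pre-manoeuvre
baselines (the segmentation assumes the manoeuvre starts within a few
breaths of the record start; for other recordings pass `nominal_period_s`
or trim the trace). Passing tests therefore demonstrate correctness of
the algorithms under the stated model, not clinical performance.

## Quality control

Flags, never exceptions: `dv_tv_low`/`dv_tv_high` when DV/TV leaves the
0.10–0.25 operating window (only if TV is supplied); `leak_suspected`
when ΔPet1 ≤ 0 or Pet(2) < Pet(1); `insufficient_breaths`; `irregular`
when either (a) the coefficient of variation of the three breath periods
around the analysed breaths exceeds 0.25, or (b) the end-tidal sequence
drops by more than 0.1 kPa anywhere in the record. Criterion (b) exists
because irregular breathing perturbs depth as well as timing: a Pet fall
beyond the extraction noise floor is incompatible with monotone wash-in,
and a three-sample CV test alone has limited power against realistic
timing jitter. The 0.1 kPa tolerance is twice the default analyzer noise
SD; on clean default simulations it produces no false positives (0/100
seeds) while severity-0.5 artifacts of either kind are flagged in
100/100 seeded runs.

## Agreement statistics

Bland–Altman from the definitions: bias = mean(method − reference),
sd with the n−1 denominator, limits of agreement bias ± 1.96·sd (1.96,
not 2.0, matching the 95% CI language). Percentage error =
1.96·sd/mean(reference); the reference-mean denominator follows the
exchangeability criterion's convention and is configurable to the mean
of all measurements, since published values do not always state their
denominator. Replicates are either treated as independent observations
or collapsed via `average_replicates` (method values averaged per
subject, the single reference untouched) — two separate pathways, as in
replicated method-comparison studies. For independent errors, averaging
two replicates shrinks PE by √2; the test suite confirms this on
simulated cohorts (the larger ~2× gain sometimes observed clinically
would imply negatively correlated repeat errors and is not asserted).
t-tests compute the statistic from the definitions (Welch by default for
the unpaired case, pooled optional) with p-values from the t
distribution; degenerate zero-variance inputs return (0, 1) for
identical samples and (±∞, 0) otherwise.

## Numerical choices and problem sizes

Pressures are kPa internally; mmHg is converted on input (×0.133322).
ELV is unit-invariant, so the choice affects only I/O and noise defaults.
Trace CSVs are written with nine decimals, round-tripping to 1e-9. The
geometric fit uses an exact three-point solution when only three breaths
exist and tightly toleranced least squares otherwise; the clock-time
kinetics fit uses bounded Levenberg–Marquardt with an increment-ratio
initial guess. Monte-Carlo suites in the tests use 100–200 seeded
replicates and 5000 null simulations for t-test calibration; the
simulated records are six breaths at 25 Hz, keeping the full suite in a
few seconds on one core.

## Known limitations

The estimator trusts the first three end-tidal values; it does not
attempt outlier-robust re-estimation from later breaths. TV is never
estimated from the capnogram (user-supplied for the DV/TV check). The
FRC conversion is only as good as K for the population at hand. The
clinical headline agreement figures of the underlying validation study
cannot be recomputed here because the subject-level data are not
published; the statistics module reproduces the *procedures*, and the
test suite validates them on synthetic cohorts with known truth.
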