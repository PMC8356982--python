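# Methods

This note documents the models, numerical choices, and known limitations of
`spesnet`. It is organized by pipeline stage; defaults given here are the
package defaults and are all overridable through `PipelineConfig` /
`SimConfig`.

## Data model

The analysis node is an electrode contact (or, after bipolar derivation, a
contact pair labelled by its first contact). A contact carries hemisphere,
anatomical structure (`amygdala`, `hippocampus`, `entorhinal`,
`parahippocampal`, `other`), seizure-onset-zone (SOZ) membership, and a
stimulated flag. MTR membership is derived: a contact is mesial temporal
iff its structure is one of the four named structures. Patients are
grouped by SOZ topography: `focal_mtr` (SOZ isolated to one hemisphere's
MTR), `multifocal_mtr` (MTR involved but SOZ extends beyond it),
`non_epileptogenic_mtr` (no MTR contact in the SOZ). An optional override
flag covers the clinical situation where SOZ extent is known to exceed
electrode coverage.

Recordings are exchanged as float32 little-endian flat binary plus a JSON
sidecar (sampling rate, channel ids, montage). The sidecar's `montage`
field distinguishes raw contact recordings (`referential`) from recordings
whose channels are already analysis nodes (`bipolar`); the orchestrator
skips the re-referencing step for the latter.

## Preprocessing

Order is fixed: channel rejection → bipolar re-referencing → artifact
replacement → 50 Hz low-pass → epoching. Artifact replacement must precede
filtering: the zero-phase filter would otherwise smear the broadband
stimulus artifact well beyond its −5..+10 ms window.

* **Channel rejection.** "Excessive noise" is operationalized as a robust
  SD (1.4826·MAD) above `sd_multiplier` (default 5) times the median robust
  SD across channels; flat channels (SD = 0) are rejected with reason
  `flat`. The rule is deliberately simple; any sharper criterion would be
  unverifiable against the source pipeline.
* **Bipolar montage.** Adjacent contacts on the same shank/grid row
  (ordered by channel index) form derived channels `c[i] − c[i+1]`. The
  derived channel inherits the first (deeper) contact's labels; pairs
  straddling the MTR boundary are flagged `boundary=True` so sensitivity
  analyses can drop them. Cross-shank pairs are never formed; singleton
  shanks are dropped with a warning.
* **Artifact replacement.** Samples in `[onset−5 ms, onset+10 ms]`
  (inclusive; window length L) are replaced by
  `rev_pre·w + rev_post·(1−w)`, where `rev_pre`/`rev_post` are the
  time-reversed L-sample flanks on either side and `w` ramps linearly from
  1 to 0 across the window. The first replaced sample equals the last
  pre-window sample and the last equals the first post-window sample, so
  the splice is continuous at both boundaries; because the replacement is
  built from the local signal, the surrounding time-frequency content is
  preserved (verified to <0.5% band-amplitude deviation against a
  clean-signal oracle). `taper_ms` optionally confines the cross-fade to
  the window's tail. The construction is idempotent: re-running it on
  cleaned data reproduces the same output bit for bit.
* **Filter.** Order-4 Butterworth low-pass at 50 Hz applied
  forward-backward (`sosfiltfilt`): zero phase, effective order 8,
  ≈48 dB attenuation at 100 Hz.
* **Epoching.** 2 s ISI: window −500..+1500 ms, baseline −500..−10 ms;
  1 s ISI: −250..+750 ms, baseline −250..−10 ms (2001/1001 samples at
  1 kHz). Trials that overrun the recording edges are dropped and counted.
  The baseline ends at −10 ms, not −5 ms: where the two source statements
  of the window disagreed, the methods-text value was taken. No
  trial-level rejection is applied — all epochs are retained.

## Evoked quantification

Each trial is baseline-mean-centered, trials are averaged, and the average
is divided by the sample SD of its own baseline segment. The Z-score is
the absolute extremum of the normalized average within 10–50 ms (N1);
70–300 ms gives N2. Window endpoints are inclusive; exact ties resolve to
the earlier latency. Peak polarity is recorded rather than assumed
negative because bipolar derivation makes the deflection sign
montage-dependent, while `|N1|` is what the edge weight needs. A response
is significant iff `Z > 6` (strict; 6.0 itself is not significant). The
channels of the stimulated pair are excluded from their own block.

Normalizing by the *average's* baseline SD (rather than the pooled
single-trial SD) makes Z the amplitude in units of the averaged response's
noise, which is the scale on which a Z = 6 cutoff is meaningful for the
average. Whether the original pipeline pooled single-trial SDs is not
determinable; both are implemented (`baseline_sd_mode="average"|"pooled"`)
with `average` as default.

## Network construction

Each stimulation block's significant Z-scores populate the adjacency rows
of *both* member electrodes of the stimulated pair (config
`pair_mapping="duplicate"`; `"split"` attributes the row to the anode
alone). An electrode stimulated in several pairs keeps the maximum Z per
target, avoiding double counting. `possible_mask[s, t]` is true iff `s`
belonged to a stimulated pair and `t` was a recorded, usable channel
outside that pair — this mask is the denominator of every density and
degree normalization. Electrodes of a stimulated pair act as ordinary
response targets in other blocks.

Connection classes relative to a chosen hemisphere's MTR: `within`
(source and target in that MTR), `out`, `in`, `outside`. Any ordered pair
touching SOZ tissue outside the MTR is excluded entirely, so
epileptogenicity varies only within the MTR. For bilateral patients the
same classification is repeated with the contralateral MTR as origin.
Weighted density of a class = ΣZ over significant class connections ÷
possible class connections (equivalently the class's average Z with
insignificant responses counted as 0); a class with zero possible
connections is reported missing, not zero. The class densities satisfy a
conservation identity — Σ(density × possible count) over the four classes
equals the total classified network weight — asserted in the tests on
every simulated network.

## Centralities

Six measures per node: indegree/outdegree (sum of incoming/outgoing edge
weights ÷ the node's possible incoming/outgoing connection count; nodes
with no possible connections are missing, not 0), HITS authority/hub
(alternating power iteration `a ← Wᵀh`, `h ← Wa` with Euclidean
renormalization, uniform nonnegative start, stopping at max-change
< 1e−12 or 5000 iterations), and Katz receive/broadcast
(`x = (I − αM)⁻¹β·1` with `M = Wᵀ` or `W`, solved directly). The Katz
attenuation is spectral-radius-relative, `α = alpha_frac/λ` with
`alpha_frac = 0.9`, `β = 1` by default — the source method names Katz
centrality without parameters, so the attenuation is exposed in config and
results should be read as conditional on it. For cycle-free (nilpotent)
graphs λ = 0; the attenuation then scales by the largest singular value,
and the (terminating) series is still summed exactly. HITS and Katz
vectors are unit-normalized over the patient's node set; rescaling all
weights leaves both invariant (HITS exactly; Katz because α adapts via λ).
HITS/Katz run on the full weight matrix including non-stimulated nodes;
outgoing measures (outdegree, hub, Katz broadcast) are masked to
stimulated nodes at reporting time, since non-stimulated nodes have no
observable outgoing edges. Location groups for comparisons: `ipsi_mtr`,
`contra_mtr`, `outside_nonepi`; SOZ-outside nodes are dropped.

## Statistics

Pooled analyses (one row per significant connection or per stimulated
node) use grouped Kruskal–Wallis tests (tie-corrected H, χ²_{k−1}
reference) followed by Dunn's pairwise rank tests,
`z = (R̄_i − R̄_j)/√((N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/n_i + 1/n_j))`,
two-sided normal p-values. Per-patient summary metrics (densities,
location-mean centralities) are fit with linear mixed models — fixed
effects patient group × connection type (or × location), random intercept
per patient. Interaction and simple effects are tested by likelihood-ratio
tests of full vs reduced maximum-likelihood fits against χ² with the
fixed-parameter difference as df; simple effects are tested regardless of
the interaction outcome. Residual normality is checked by Shapiro–Wilk.
Post hoc pairwise contrasts of marginal means use the REML fit's pooled
fixed-effect covariance and containment degrees of freedom: a
between-patient factor gets `n_patients − n_groups` df (15 for 18
patients/3 groups; 7 for the 10-patient bilateral subset), a
within-patient factor gets the observation-level residual df
`N − n_patients − n_groups·(k − 1)`. ML fits drive the LRTs and REML the
contrast estimates; fitting uses L-BFGS with a Powell fallback (a
five-optimizer comparison showed no measurable LRT difference). Count
comparisons use Fisher's exact test (2×2, two-sided hypergeometric) or
chi-squared without continuity correction. All p-values are
Benjamini–Hochberg adjusted; FDR families follow analysis blocks (one
family per metric × comparison table), recorded in the `family_id`
column of every output row, since the original family partition is not
recoverable from the source.

## Synthetic cohort generator

The generator is the package's test bed and defines the study conditions
under which all validation claims hold.

* **Protocol.** 50-trial blocks, biphasic pulse bookkeeping (0.3 ms,
  ≤10 mA), ISI 1 s by default (2 s supported), sequential blocks with 1 s
  gaps; all patients bilaterally stimulated, seizure-onset side
  alternating across patients. Default layout per patient: 6 ipsilateral
  MTR, 4 contralateral MTR, and 12 lateral contacts (two of which carry
  the extra-mesial SOZ for multifocal and non-epileptogenic patients);
  9 stimulated pairs.
* **Noise.** Stationary Gaussian noise with power spectrum
  `(1−f_w)/(f² + f₀²) + f_w·white`, knee f₀ = 12 Hz, white fraction
  f_w = 0.1, scaled to exactly `noise_sd_uV` (15 µV) per channel. The knee
  keeps the correlation time (~13 ms) short against the 240 ms baseline
  window so the baseline-SD estimator has adequate effective degrees of
  freedom; real iEEG has more long-range 1/f power than this, which is a
  deliberate trade — see Limitations.
* **Evoked responses.** Difference-of-gamma template: unit-peak gamma
  bumps `(t/t_p)^k e^{k(1−t/t_p)}` with N1 (t_p = 25 ms, k = 8, latency
  jitter SD 3 ms, clipped to 11–49 ms) and N2 at half amplitude
  (t_p = 150 ms, k = 6, jitter 15 ms). Only the latency windows and
  polarity of the two deflections are constrained by the source method;
  the shape is a generator choice.
* **Amplitude calibration.** Ground-truth weights are target Z-scores. Per
  trial the injected amplitude is `w·σ·r/(g·√n_trials)` µV where `g` is
  the numerically computed peak retention of the jitter-smeared, 50
  Hz-filtered N1 template and `r` calibrates the *measured* baseline SD:
  from the filtered-noise autocovariance the expected sample variance of
  the mean-removed baseline segment is `tr(AC)` (A the centering quadratic
  form), matched to a scaled χ² with effective dof
  `ν = tr(AC)²/tr((AC)²)`, and `r` is set so that `E[1/ŝ]·σ·r = 1` — i.e.
  the calibration targets the reciprocal moment the Z statistic actually
  uses. This makes the end-to-end mapping from injected `w` to estimated Z
  unbiased by construction; the measured Monte-Carlo slope is 1.00–1.05
  with a sub-SD intercept from extremum picking.
* **Ground-truth profiles.** Connection presence is Bernoulli and weight
  `8 + Gamma(2, scale)` per stimulated pair → target (both pair members
  share the row). Defaults: within-MTR (either side, all groups)
  p = 0.65, mean 16; epileptogenic-MTR out/in — focal p = 0.40/mean 14,
  multifocal p = 0.22/mean 11, non-epileptogenic p = 0.20/mean 10.5;
  contralateral-MTR out/in and cross-MTR shared across groups
  (p = 0.20/mean 10.5); outside–outside p = 0.12, mean 10. These encode
  the qualitative pattern the analysis should recover — within-MTR densest
  everywhere, focal in/out elevated, contralateral MTR group-invariant —
  at effect sizes strong enough to be directionally stable at 6 patients
  per group.
* **Artifact.** A hann-windowed 250 Hz burst confined exactly to
  −5..+10 ms, amplitude 500 µV with ±50% per-channel gain spread.
* **Determinism.** All randomness flows from one seed through
  `SeedSequence` spawns (per-patient substreams); recordings are rounded
  through float32 so reruns are byte-identical.
* **Montage.** Sessions are generated directly at the analysis-node
  (bipolar-equivalent) montage — ground truth is defined on the nodes the
  network is built on. Bipolar re-referencing is exercised by dedicated
  contact-level unit fixtures instead of the simulator.

## Validation experiments and problem sizes

`spesnet.evaluation` backs both the acceptance tests and
`scripts/acceptance.py`: Z-recovery regression over 200 sessions × 8
injected amplitudes (6–20) at 50 trials; null false-positive rate over
1000 no-connection channels; centrality oracle equivalence over 50 random
digraphs (n ≤ 20) against dense eigensolver / 200-term Neumann summation /
explicit summation; mixed-model calibration with a 600-replicate null arm
(18 patients × 4 conditions; the tripled count keeps the Monte-Carlo error
of the rate estimate small against the tolerance) and a 200-replicate
recovery arm (6 patients, known shift δ = 2); and the directional pattern
on a 6-per-group cohort. These sizes keep the full battery at a few
minutes on one CPU.

## What passing tests do and do not show

The generator produces stationary Gaussian noise, isolated stereotyped
deflections, disjoint stimulated pairs, and no physiological rhythms,
epileptiform transients, after-discharges, delayed responses, or
inter-trial nonstationarity. Tests passing on it validate the *pipeline
arithmetic* — artifact locality, amplitude calibration, graph and
statistical machinery — not the clinical sensitivity of the Z > 6 rule on
real iEEG, where heavier low-frequency noise and artifacts will widen the
null distribution. The null false-positive bound in particular is a
statement about Gaussian baselines.

## Known limitations

* EDF input is not supported; recordings use the flat-binary + JSON
  contract. Conversion from EDF is a one-liner with any EDF reader.
* Katz results depend on `alpha_frac`; there is no principled default
  beyond convergence, and cross-study comparability requires fixing it.
* Containment df for within-patient factors follows the rule stated
  above; other software draws these df differently, which changes post hoc
  p-values slightly (the between-patient df, which the headline contrasts
  use, are the standard `n_patients − n_groups`).
* The ML likelihood-ratio test is mildly anti-conservative at 18 patients
  (measured type-I ≈ 0.063–0.067 at nominal 0.05); this is inherent to
  χ²-referenced LRTs at this sample size and matches the tolerance used in
  validation.
* The reference cohort table is stored as printed, including one patient
  whose listed right-side MTR structures carry zero implanted electrodes,
  and one whose stimulated-electrode count (18) lies below the printed
  cohort range minimum (20); aggregates are computed from the table, not
  reconciled to the prose.
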