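# Methods

## The behavioural model

Larval zebrafish respond to a sudden acoustic/vibratory stimulus with a
fast escape manoeuvre. Under rapid repetition the escape distance declines
approximately exponentially — short-term habituation — toward a
non-habituating steady state. After a concussive insult two distinct
processes shape this curve in opposite directions: impaired habituation
*slows* the decline, while fatigue (a gradually accumulating incapacity to
respond) *steepens* the apparent decline and depresses both the initial
response and the steady state. `zebrahab` implements these two processes
as first-order stages in series.

**Habituation stage.** For a unit stimulus train indexed by stimulus
number *n* (1-based):

    r_n = h3 + (h1 − h3) · exp(−h2 · (n − 1))

`h1` is the input gain (the first response equals `h1`), `h3` the
non-habituating offset, and `1/h2` the habituation decay constant in
stimuli. Impairment means a smaller `h2`.

**Fatigue stage.** A low-pass-growing fatigue signal

    F_n = max(0, (1 − f3) − f1 · exp(−f2 · (n − 1)))

saturates at `1 − f3` with growth constant `1/f2`, starting a distance
`f1` below the asymptote; it is subtracted from the habituated signal:

    s_n = r_n − F_n.

With `F` unclipped this is a two-phase exponential with rates `h2` and
`f2` and offset `h3 + f3 − 1`. The configuration `(f1, f2, f3) = (0, 0, 1)`
is the exact no-fatigue identity: `s_n ≡ r_n` bit for bit.

Canonical regimes (used throughout the tests and the synthetic cohorts):

| regime | h1 | h2 | h3 | f1 | f2 | f3 |
|---|---|---|---|---|---|---|
| normal habituation | 1 | 1/1.3 | 0.2 | 0 | 0 | 1 |
| impaired habituation | 1 | 1/4 | 0.2 | 0 | 0 | 1 |
| impaired + fatigue | 1 | 1/4 | 0.2 | 0.5 | 0.8 | 0.4 |

### Design choices in the model

* **Stimulus-indexed time base.** Rate gains are expressed per stimulus;
  with the assay's 1 s ISI, per-stimulus and per-second rates coincide.
  The closed forms in *n* are normative; the continuous-time simulator is
  a cross-check.
* **Where `f1` acts.** The stage constraints (identity at `(0,0,1)`,
  steady-state offset `1 − f3`, growth constant `1/f2`) leave the role of
  `f1` open; it is housed as the initial distance of the fatigue state
  from its asymptote, giving the transmission `g_n = f3 + f1·e^(−f2(n−1))`
  — the only assignment that uses all three gains and satisfies every
  constraint.
* **Subtractive composition.** Fatigue is subtracted from (not multiplied
  into) the habituated signal; only subtraction yields the two-phase
  exponential form.
* **Autonomous fatigue drive.** The fatigue state relaxes on its own once
  stimulation begins (unit drive), rather than being driven by the
  attenuated habituation output, preserving the exact two-phase form.
* **Rectification.** With the canonical impaired+fatigue gains the
  combined output goes negative (asymptote −0.4). A `rectify` flag clips
  at 0; it is off for model analysis (fits to model traces use the
  unrectified curve with a negative offset allowed) and on inside the
  synthetic generator, where outputs are distances.
* **Clipping `F_n` at 0** when `f1 > 1 − f3`: fatigue is a deficit and
  cannot be negative.

### The iterative simulator

`simulate_block_diagram` integrates the equivalent continuous-time system
(habituation state relaxing to `h3` at rate `h2`/ISI from `h1`; fatigue
state relaxing to `1 − f3` at rate `f2`/ISI from `(1 − f3) − f1`) with a
fixed-step classical RK4 scheme and reads the states at stimulus onsets.
Sub-steps tile each inter-onset interval exactly (`round(isi/dt)` steps),
so samples sit on the onset grid with no accumulated drift. At the default
`dt = 1e−3` s the discrepancy against the closed forms is ~1e−15; steps
coarser than `isi/100` are refused. The RK4 loop runs in plain floats —
the 100-gain-set equivalence suite completes in a few seconds.

## Decay fitting and model selection

Each larva's habituation-phase distances are fitted with
`f(x) = a·e^(−bx) + c`, `x = n − 1` (0-based), by bounded nonlinear least
squares (`scipy.optimize.curve_fit`, trust-region reflective). Derived
parameters: **amplitude** `a + c` (the value at the first habituating
stimulus — the 0-based convention makes `f(0) = a + c`), **decay
constant** `1/b`, **offset** `c`.

Numerical choices:

* Multi-start initialisation: `a0 = y[0] − mean(last 5)`,
  `c0 = mean(last 5)`, rate grid `b0 ∈ {0.05, 0.2, 0.5, 1.0}`; lowest-RSS
  converged start wins. Bounds `b ∈ [1e−6, 10]`, `a ≥ 0`; `c ≥ 0` for
  empirical data, unbounded with `allow_negative_offset` (model traces).
* Degenerate inputs (constant series, total optimizer failure) return a
  result with `converged=False` and the offset at the series mean rather
  than raising; a rate pinned at its bound is also flagged unconverged.
* The double exponential `a1·e^(−b1x) + a2·e^(−b2x) + c` is additionally
  seeded from the single-exponential solution (so the nested inequality
  `rss(double) ≤ rss(single)` holds by construction) and rates are
  reported sorted `b1 < b2`.

`fit_candidates` ranks six curves — linear, full single exponential,
single exponential without offset, with unit amplitude, the rate-pinned
constant (pure offset), and the double exponential — by log-likelihood,
AIC, AICc, CAIC, BIC and adjusted R², using the profile Gaussian
likelihood `logL = −n/2·(ln(2π·rss/n) + 1)`. The parameter count `k` adds
+1 for the estimated error variance uniformly across candidates, so the
rankings are internally consistent; adjusted R² uses the curve-coefficient
count only. The exact membership of the restricted-variant family is a
package choice (recorded in the comparison output); each omitted
coefficient is pinned to its natural neutral value.

## Assay metrics

The standard protocol is 50 pulses (0.5 s, 300 Hz) in three phases —
10 sub-threshold (20 dB) at 60 s ISI, 10 supra-threshold (108 dB) at 60 s
ISI ("pre-habituation"), 30 supra-threshold at 1 s ISI ("habituation") —
with 300 s breaks between phases. Tracking is binned at 1 s into three
speed categories (<2, 2–20, >20 mm/s); an escape is movement in the
>20 mm/s category during a stimulus bin (stimuli last 0.5 s, so the 1 s
bin is the finest observable unit). Fast movement outside stimulus bins is
a swim bout and never counts as an escape. A missing bin is reported as
missing, never as zero.

* Responsiveness AUC over a 10-stimulus phase uses the trapezoid rule on
  integer stimulus index (the quadrature is a package choice; a constant
  5 mm series gives 45 mm·stimulus over the 9 unit intervals).
* The non-responder rule is strict: pre-habituation response rate < 0.40
  excludes; exactly 0.40 retains.
* Spontaneous activity sums all three categories over the two 300 s break
  windows (10 min total); partial coverage yields NaN with a warning.

## Synthetic cohorts

No behavioural data ship with the package; `zebrahab.cohort` generates
virtual cohorts with the structure the analysis assumes. Defaults (the
bundled `default_profiles.yaml`):

* **Groups and sizes.** control n=136, low-impact n=70, high-impact n=69
  at baseline; six timepoints (pre, 5 min, 1 h, 2 h, 24 h, 48 h) with
  per-timepoint attrition hazards chosen so expected surviving counts
  follow the canonical longitudinal pattern (e.g. high-impact
  69→61→60→60→46→39).
* **Phenotypes.** Controls habituate normally at every timepoint;
  low-impact larvae are impaired (h2 = 1/4) at 5 min–2 h and recover by
  24 h; high-impact larvae combine impairment with fatigue
  (0.5, 0.8, 0.4) from 5 min through 24 h, easing at 48 h to normal h2
  with milder residual fatigue (0.3, 0.8, 0.6) — decay constant recovered,
  amplitude/offset still depressed.
* **Between-larva heterogeneity.** True gains are drawn per larva and
  timepoint from normals truncated at the validity bounds with a 10%
  coefficient of variation (no between-larva variance is reported for the
  real assay; 10% is a plausible choice fixed once). The no-fatigue
  configuration is never jittered, so controls cannot acquire spurious
  fatigue.
* **Observation model.** Habituation distances are the rectified model
  output scaled by a nominal 30 mm first-response distance plus Gaussian
  noise truncated at 0 (σ default 3 mm = 10% of the control amplitude).
  Pre-habituation and sub-threshold responses are Bernoulli at 85% and
  20%; 5% of larvae are injected as non-responders (pre-habituation
  response probability 20%). Spontaneous activity is group-independent
  (mean 110 mm per 10 min).
* **What it does not emulate.** Within-bout kinematics, sensitisation,
  startle latency, inter-stimulus correlations, day/clutch effects, and
  any dependence of spontaneous activity on injury. Passing recovery tests
  therefore demonstrates that the pipeline estimates what the generator
  encodes — not that real larvae satisfy the generator's assumptions.

Tracking-format emission writes one ZebraLab-style long CSV per timepoint
(contiguous 1 s bins spanning the whole ~30 min assay); escape distances
sit in the >20 mm/s category of the stimulus bin and spontaneous activity
is spread uniformly over the break bins, so the assay readers recover the
generated responses and break totals exactly.

## Group statistics

Each parameter × timepoint cell is tested with the normality-gated path:
Shapiro–Wilk per group ("normally distributed" is interpreted as *all*
groups passing at α = 0.05), Levene's test recorded; all-normal routes to
one-way ANOVA with Dunnett's many-to-one comparisons against control
(scipy, with a pinned quadrature state so p-values are reproducible),
otherwise Kruskal–Wallis with Dunn's mean-rank z tests (tie-corrected)
restricted to control comparisons, Holm-adjusted (no particular correction
is canonical for Dunn; Holm is the default and configurable). A constant
group routes to the nonparametric path with a warning. Mortality uses
Pearson's χ² without continuity correction (a flag enables Yates for 2×2).
The hand-rolled Dunn test is validated against the identity
z² = tie-corrected Kruskal–Wallis H in the two-group case.

## Kinematics

Trajectory severity features: length = |net displacement|; duration = the
span between the at-rest samples bracketing all non-negligible motion
(relative speed threshold 1e−6 of the peak), so a profile starting and
ending at rest reports its full programmed duration; peaks of
|velocity| / |acceleration| / |jerk| from successive `np.gradient` calls
with second-order boundary stencils (first-order edges compound to >10%
error on the third derivative of a smooth profile). No smoothing by
default; an optional moving-average window is available. Peak
acceleration and jerk of a synthesized profile are shape-dependent, so
only length and duration are treated as round-trip invariants of the
synthesiser (raised-cosine and trapezoidal-velocity shapes, endpoint
pinned to the requested displacement).

## Problem sizes

The test suite and the acceptance script run everything at the scale the
analysis is defined at: full-size cohorts (136/70/69) for the group-level
ordering checks (a 10-seed sweep of the 5 min timepoint), 500 noisy series
for fit-bias calibration, 200 null replicates for type-I error, 100 random
gain sets for the simulator-equivalence suite. Pipeline determinism tests
use reduced cohorts (6/4/4) since they exercise plumbing, not statistics.

## Known limitations

* The closed forms assume the ISI-locked regime; continuous within-pulse
  dynamics beyond onset samples are out of scope.
* Single-exponential fits to two-phase data are intentionally
  misspecified (that is the point of the opposing-effects analysis); the
  fitted decay constant is then an *apparent* constant whose value depends
  on the rectification and offset-bound settings.
* Dunnett p-values rely on scipy's randomized multivariate-t quadrature;
  they are reproducible (pinned state) but carry ~1e−3 integration noise.
* The generator's dispersions and the 30 mm distance scale are plausible
  fixed choices, not estimates.
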