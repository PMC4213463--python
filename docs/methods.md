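# Methods

## Model

The network couples four layers: (1) an IPTG/LacI induction module that
tunes *kinA* expression; (2) signal-driven activation of KinA (dimerization
and SS-dependent autophosphorylation); (3) the Spo0F → Spo0B → Spo0A
phosphotransfer relay with first-order dephosphorylation drains standing in
for the Rap/Spo0E phosphatases; (4) Spo0A~P–activated transcription of the
*spoIIA/E/G* operons and translation of their six effector proteins.
Spo0A~P feeds back positively on *kinA*, *spo0F* and *spo0A* transcription,
summarizing AbrB/sigma-H derepression.  Regulators not represented
explicitly (AbrB, SinI/SinR, the kinases KinB–KinE, downstream sigma
factors) are deliberately abstracted into these effective laws.

Counting transcripts, dimers and phospho-forms, 13 species yield 27 forms.
Reactions: 29 published mass-action/Hill laws + 1 first-order Spo0B~P
dephosphorylation + 25 first-order degradations (one per form except the
two clamped inputs) = 55 unidirectional reactions.  All rate laws are
nonnegative for nonnegative states, including the all-zero state (every
Hill denominator carries a positive constant).

Interpretation choices where the published table is ambiguous:

- Translation laws are driven by the transcript (`tl3`: k·[spo0F_t], etc.);
  the protein symbols printed in three of the translation rows are treated
  as typos, consistent with the stated modelling rule that translation is
  proportional to the mRNA.
- `k1` sequesters the **protein** (k·[LacI]·[IPTG] → LacI_d); the printed
  [lacI_t] substrate contradicts the reversible protein-sequestration
  mechanism the model text describes.
- IPTG and SS are clamped boundary inputs; `k1` does not deplete IPTG.
- The feedback coefficient `tr2.k3` is dimensionless (fold-activation)
  despite its printed rate units: it sits inside a multiplicative factor.
- Only the unphosphorylated KinA dimer dissociates; `k3` consumes two KinA
  monomers per dimer and `k4` releases two.
- The Spo0A transcription constant printed without an index (0.1388) is the
  activation-term amplitude `tr5.k2`.

## Units and the stimulus scale

The internal concentration unit is the nM of the published kinetic
constants; time is in seconds.  The published outputs are quoted on
inconsistent scales, and the package preserves each printed number on its
own scale: total KinA (200–2800) is reported in internal units, while the
Spo0A benchmarks (4.5 and 37.5 µM) are µM = 1000 internal units.

The stimulus axes (IPTG 0–20, SS 0–2) are in µM while the binding constants
are per-nM, so clamp values are converted by `stimulus_scale = 1000`
(nM per stimulus unit) when they enter the state vector.  This conversion
is forced by the algebra: with the inducer read in internal units the LacI
sequestration factor `1 + k1·I/(k2 + d)` could never exceed 1.22 over the
whole axis and the induction response would be essentially flat,
contradicting the sigmoidal dose-response the model is built to produce.

## Calibration of the unpublished constants

The degradation rates, the Spo0B turnover, and the nominal SS clamp do not
appear in the published table; they were fixed once against the published
steady-state anchors of the inducible system and then frozen:

| constant | value | role |
|---|---|---|
| `d_mRNA` | 2.2778e-3 /s | shared transcript turnover (t½ ≈ 5 min); solved so basal total KinA = 200 exactly |
| `d_prot` | 4.0e-3 /s | shared protein turnover (effective dilution); places the LacI operating point so the response roughly doubles between induction levels 4 and 10 |
| `deg.spo0B_t.k` | 5.0e-3 /s | Spo0B arm mRNA turnover |
| `deg.Spo0B.k`, `deg.Spo0BP.k` | 2.5e-5 /s | slow Spo0B protein turnover → large constitutive pool |
| `kBdeph.k` | 1.0e-4 /s | small free Spo0B~P dephosphorylation, toggleable |
| `SS_in` | 0.07 µM | nominal sporulation signal: visible but small basal activation (basal Spo0A~P ≈ 4% of the fully induced level) |

Anchors at the frozen point: total KinA 200.0 at IPTG = 0, 2633 at
IPTG = 20 (published endpoint 2800; −6%), +114% between induction levels 4
and 10 ("about 100%").

The Spo0B arm deviates from the shared protein turnover on purpose.  Spo0B
is synthesized constitutively and unregulated in this model; giving it a
slow turnover (hence a pool large enough that `k8·[Spo0B] ≫ k7`) makes the
Spo0F~P → Spo0B~P transfer branch ratio insensitive to the pool size.
That regime is what produces the model's signature robustness results:
scanning the Spo0B translation rate 50–150% moves only Spo0F~P (>5%) while
KinA2~P, Spo0B~P and Spo0A~P stay within a few percent, and the local
sensitivity matrix has |S| = 1 rows confined to the Spo0B forms.  The same
regime necessarily flattens the local leverage of the phosphorylation rate
`k8` itself (S(Spo0B~P; k8) = 1 − k8B/(k7 + k8B + d) → 0 as k8B grows):
a proportional Spo0B~P response to `k8` and insensitivity of the relay to
the Spo0B pool are mutually exclusive in this rate structure, whatever the
turnover values.  We keep the regime that reproduces the scan behaviour and
report the `k8` coefficient as computed.

## Numerics

- **Steady states.** Damped Newton (`scipy.optimize.root`, hybr) on the 25
  free forms with the analytic Jacobian, warm-started from the basal state
  (or the previous grid point in scans); residual tolerance 1e-9 max-norm
  in model units/s.  On failure: integrate toward equilibrium over growing
  horizons (1e5 s × 10ᵏ) and re-polish.  Uniqueness is not assumed — the
  state reached from the guess is reported; an up-scan and a down-scan of
  the IPTG axis agree to ~1e-13, so the operating regime is monostable.
- **Transients.** LSODA with rtol 1e-8 / atol 1e-10 and the analytic
  Jacobian; reported trajectories are clipped at zero and excursions below
  −1e-9 raise.
- **Sensitivities.** Central differences with relative step 1e-3; the two
  one-sided estimates are compared and the step halved (≤3 times) if they
  disagree by >10%.  Nominal concentrations below 1e-9 (numerically zero,
  e.g. LacI_d without inducer) get S ≡ 0 rather than noise amplification.
  Near-ties within 1% of the maximum coefficient are reported together.
- **Compensation refit.** Nelder-Mead on the mean relative distance of the
  KinA2~P curves over (tr2.k2 ∈ [0, 10×nominal], KL ∈ [1, 20×nominal]),
  two starts; zero-valued reference points are excluded from the metric.
- **Degenerate inputs.** The all-zero state is legal; rate laws are finite
  there.  A goodness-of-agreement input with any observed value ≤ 0 is an
  error (the metric divides by it); a linear fit of a zero-variance series
  returns a flagged result with undefined R².

## Synthetic data

The generators emulate the statistical structure of the two experimental
comparisons, not their biology:

- **Dose-response observations**: the deterministic steady-state curve times
  `(1 + cv·z)`, z standard normal truncated at −90% (multiplicative noise,
  because the concentrations span orders of magnitude and the comparison
  metric is relative).  The truth column is exactly the pipeline output.
- **Wild-type time courses**: per-species linear truth (slope in µM/min)
  plus additive Gaussian noise (constant scatter).  Defaults in the
  analysis driver put total Spo0A at 37.5 µM after 150 min and size σ from
  the closed form R² = s²Var(t)/(s²Var(t)+σ²) for fit qualities ≈ 0.95.

Both are pure functions of (parameters, seed).  Passing tests on these
generators shows the machinery (solvers, metric, fitting loop) behaves
correctly under the assumed noise model; it says nothing about measurement
noise in real single-cell data, which is neither multiplicative-normal nor
time-independent.

- **Parameter recovery** refits one "Fitted" constant at a time (log-scale
  bounded scalar minimization of the distance on a total-KinA curve, 11
  grid points).  Problem sizes throughout (21-point scans, 21×21 stimulus
  envelopes, 20 recovery replicates) were chosen as the smallest grids on
  which the reported quantities are stable to well under the comparison
  tolerances.

## Known limitations

- No stochastic simulation; the deterministic ODE interpretation only.
- The molecular identity of SS is abstract, and its clamp value is an
  effective calibrated constant, not a measurement.
- The wild-type comparison is a discrepancy report by design: the model's
  total-Spo0A ceiling (~3.3 µM across the whole stimulus envelope, a hard
  bound set by the saturating *spo0A* transcription law and its turnover)
  sits an order of magnitude below the measured 37.5 µM accumulation.
- Published agreement percentages against digitized experimental curves
  (4.03%, 8.84%) and the experimental R² values are not recomputable here:
  the underlying measured data points are not published.  The goodness
  metric and the linear-fit machinery they used are implemented and
  validated on synthetic data instead.
- The `k8` sensitivity row is structurally at odds with the published
  proportionality claim, as derived above; this is a property of the rate
  structure, not a numerical artifact.
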