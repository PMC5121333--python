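# Methods

## Model structure

The network is a deterministic mass-action ODE system over eleven protein
pools (IR, IRS, PI3K_PDK1, PI3K_variant, Akt, TSC1–TSC2, mTORC1, mTORC2,
AMPK, PRAS40, p70-S6K). Every reaction is a state interconversion inside one
pool,

    v = k · gate(t) · (Σ catalyst amounts, or 1) · [substrate],

so mass is conserved per pool by construction (verified along every
trajectory to 1e-8). Stimuli are unitless step functions switching from 0 to
1 at t = 0: cells are modelled as fully starved beforehand, all
phosphorylated/activated states start at 0 and basal activity is neglected.
Inhibitors and knockdowns are represented purely as t = 0 scalings of a
pool's total amount (residual fraction in (0, 1]); drug binding kinetics and
pre-incubation timing are outside model time. The "PI3K" perturbation scales
both PI3K pools together, because both variants are sensitive to the same
class-I PI3K inhibitor.

Combinatorial phospho-proteins (Akt, PRAS40, p70-S6K carry two sites each)
are expanded into all state combinations, with the first- and second-site
copies of each site-specific (de)phosphorylation sharing one rate constant.
This keeps the fitted parameter count at 36 for the final model (3 insulin
receptor + 33 network constants) while representing every internal state. A
useful consequence: the total phosphorylation level of one site on a
two-site protein evolves independently of the other site's occupancy, so
observables (sums over phospho-states) behave like single-site readouts.

Design choices where the wiring was genuinely open:

* **mTORC2 upstream input.** The PI3K_variant pool (the Akt-independent
  relay to mTORC2) is activated by phosphorylated IRS rather than directly
  by the insulin receptor. With an IR-only catalyst, mTORC2 — and hence the
  Akt-S473 readout — would be completely decoupled from the network under
  aa-only stimulation (insulin gate = 0 means the IR never fires), and no
  parameterization could reproduce two benchmark phenotypes: suppression of
  Akt-pS473 by PI3K knockdown, and the rise of Akt-pS473 under mTORC1
  knockdown through the negative-feedback loop. Routing through IRS-p keeps
  the relay insulin-responsive and Akt-independent while giving both
  phenotypes a mechanism.
* **AMPK ⊣ mTORC1.** AMPK phosphorylates TSC2-S1387; both plain TSC and the
  S1387 state form the GAP-active pool that deactivates mTORC1, whereas the
  Akt-phosphorylated T1462 state is GAP-inactive. AMPK therefore inhibits
  mTORC1 by sequestering TSC away from the Akt-inactivatable state, without
  a separate Raptor species or extra reactions.
* **Negative feedback.** One reaction (active p70-S6K catalysing
  IRS-p → IRS-pS636) absorbs both feedback mechanisms (direct S636
  phosphorylation and transcriptional IRS suppression). The IRS-p pool also
  relays an insulin-responsive activation arm to AMPK.
* **Candidate sites for extra aa inputs.** All activatable states except the
  IR pool (the insulin sensor; aa-only protocols have insulin = 0), the
  inhibitory IRS-pS636 state, and mTORC1 itself (which carries the canonical
  input) — exactly 12 sites. Each added input contributes aa-gated
  activation reactions from every precursor state, all sharing one new rate
  constant `k_aa_<site>`.

## Simulation

LSODA (stiff-capable) with analytic Jacobian, relative tolerance 1e-6,
absolute tolerance 1e-12; default protocol 120 min at 0.1 min output steps.
Because stimuli are steps at t = 0, the gates are constants during
integration. Nonnegativity is enforced by the solver tolerances, not by
clipping: any state below -1e-6 raises an integration error carrying a hash
of the rate-constant vector. Halving the output step changes no observable
by more than 1e-6 (the solver's internal steps are independent of the output
grid).

## Estimation

Weighted least squares with a 10% proportional error model,
σ = max(0.10·y_obs, floor); the floor is 1% of each observable's maximum over
the dataset, preventing zero-variance points at t = 0 where all readouts are
exactly 0. Optimization runs in log10-parameter space inside [1e-6, 1e4]
with scipy's trust-region-reflective least squares (ftol = xtol = gtol =
1e-5, at most 250 iterations' worth of function evaluations per start).
Start points are the current best-known values disturbed multiplicatively by
10^N(0, 0.4) per parameter; the first start is undisturbed by default so
that a fit launched at an optimum is a fixed point (recovery experiments set
`perturb_first_start=True`). Integration failures return a large constant
residual so single bad starts never abort a multi-start ensemble. Model
scores use AIC = χ² + 2k (Gaussian likelihood with known variances,
constants dropped); with this form the 1% selection rule reproduces the
published acceptance boundaries exactly. Ensemble spread (log10 SD and
linear CV over the best half of starts) serves as the uncertainty report in
`FitResults.summary()`.

The three insulin-receptor constants can be calibrated separately against
insulin-containing conditions (`calibrate_ir`) and frozen for variant fits;
the IR module is upstream of everything and is not excited by aa-only data.

## Structure selection

Stage 1 is the canonical single-input model. Stage 2 attaches one extra aa
input at each of the 12 candidate sites; stage 3 tests all unordered pairs
of the components whose single addition was accepted; stage 4 tests all
three-component unions of pairs of accepted stage-3 sets (deduplicated;
unions with four components would be quintuple-input models and are
discarded). A model is accepted when its AIC is at least 1% below the best
AIC of the previous stage — a guard against improvements on the order of the
numerical noise of the estimation. Ties for the final best model break
toward fewer inputs, then lexicographically. Under the reported survivor
pattern (9 of 12 doubles accepted, 7 of 36 triples, all sharing the IRS
component) the procedure enumerates 1 + 12 + 36 + 21 = 70 models; the
stage-3 count is C(survivors, 2) whenever stage-2 survivors are singleton
additions, and both identities are tested against brute-force enumeration.

## Identifiability

`mota_flags` regresses each parameter (log10, over the best 50% of ensemble
fits) on greedily chosen tuples of at most four other parameters and flags
tuples with r² > 0.9 whose target also varies with CV > 15% across the
ensemble — strongly co-varying groups that the data constrain only jointly.
The two thresholds (r² > 0.9, CV > 15%) follow the method's definition: a
tuple is only meaningfully non-identifiable when the relation is tight *and*
the target actually wanders. `profile_likelihood` steps one parameter over
±2 decades (21 steps), re-optimizes all others per step, and classifies by
the Δχ² = 3.84 threshold (95%, 1 df): both arms crossing ⇒ identifiable, one
flat arm ⇒ practically non-identifiable, both flat ⇒ structurally
non-identifiable. Failed re-optimizations are recorded as missing grid
points.

## Synthetic data

**Time courses.** The ground-truth fixture is the quadruple-input extended
model with hand-calibrated rate constants (all pool totals 1.0 arbitrary
units, rates in 1/min). Calibration criteria, checked automatically by
`behaviour_checklist`: acute AMPK-T172 activation (≥50% of max by 5 min) but
delayed p70-S6K-T389 (15 min > 5 min); no readout exceeding 0.95 of its pool
(no saturation); PI3K knockdown to 10% suppresses Akt-pT308 ≥50% while AMPK
stays within 20%; mTORC1 knockdown to 25% suppresses p70-S6K-pT389 ≥50% and
*raises* Akt-pS473 (the feedback phenotype); AMPK knockdown to 50% leaves
p70-S6K-pT389 within 20%; mTORC2 knockdown to 40% suppresses Akt-pS473 ≥30%
with p70-S6K-pT389 and AMPK unchanged. The planted aa inputs are strong
enough that each contributes a detectable χ² signature at the 10% noise
level — a fixture property the structure-recovery benchmark depends on.
Noise is multiplicative Gaussian, y = ŷ(1 + ε), ε ~ N(0, CV) truncated at
-0.99 (densitometry-like, never negative), independent per replicate;
defaults are CV = 0.10 (matching the fitting error model), 3 replicates, and
a 12-point grid spanning 0–120 min. What the generator does **not** emulate:
blot-to-blot normalization artefacts, saturation of chemiluminescent
detection, correlated replicate errors, and unmodelled biology (basal
activity, ULK1, c-Jun). Passing benchmarks therefore demonstrate correctness
of the pipeline under its own assumptions, not performance on real blots.

**Phosphosite tables.** MaxQuant-dialect tables with per-experiment
`Intensity L/M/H` columns following the five-experiment triple-SILAC design
(0/5/30 min in experiments 1–3, 10/15/30 min in 4–5, labels rotated per
experiment); log-normal baseline intensities (median ~1e7), multiplicative
lognormal channel noise (CV 0.15), planted effects as 2^log2FC factors in
stimulated channels, a sub-0.75 localization-probability contaminant
fraction (10%), and missing values injected as zero intensities (2%).
Spectra, retention times and identification scores are not simulated.

## Phosphoproteomics pipeline

For t ∈ {5, 10, 15} min, all cross-experiment bridged ratios
(I_t/I_30)_i / (I_0/I_30)_j are formed (9 combinations at 5 min, 6 at
10/15 min under the default design); the bridge rule is applied uniformly
even when t and 0 share an experiment (the bridge then cancels
algebraically). Zero intensity counts as missing; any missing term drops
that single combination. Log2 ratios are median-centered per ratio column
across sites (the alternative — one global median — differs only when
columns have systematically different label biases, which the per-column
form absorbs). Sites with ≥2 finite ratios at a time point are tested with a
two-sided one-sample t-test against 0 (n−1 df, no multiple-testing
correction); a zero-variance ratio vector leaves t undefined and passes the
p-gate iff its mean is nonzero. A site is regulated at a fold-change cutoff
(1.5 or 2.0) if |mean log2 ratio| ≥ log2(cutoff) and p < 0.05 at one or more
time points. Because ratio combinations share channels, they are positively
correlated and the nominal t-test is mildly anti-conservative at the loose
cutoff; the null false-call rate stays ≈α (Monte-Carlo checked) and is ~0 at
the twofold cutoff.

## Benchmark problem sizes

The shipped benchmarks are desk scale by design: structure recovery scans a
six-site candidate list (the three planted inputs plus three decoys) and
fits only the aa-gate rate constants per candidate (2 starts each), holding
the calibrated network kinetics fixed — the same staged strategy used for
the original calibration, where previously calibrated modules were frozen
while new connections were estimated. Twenty seeded datasets (CV 10%, 3
replicates) take ~3 min in total; the recovery criterion is the planted set
being returned in ≥80% of seeds. Parameter recovery refits all 36 constants
of the quadruple model from 0.4-decade-disturbed starts on noise-free data
(~40 s) and requires every constant back within ×/÷1.5. Full-scale analyses
(thousands of multi-starts, 12-site scans, all parameters free) use the same
code paths through `FitConfig(n_starts=...)` and `SelectionConfig`.

## Known limitations

* The reaction list is a reconstruction constrained by the published
  connection diagram and printed counts (31 species / 48 reactions / 12
  observables / 12 candidate sites), not a transcription of the original ODE
  system, so individual rate-law assignments (notably the PI3K_variant
  catalyst, see above) are this package's own choices.
* Observable scale factors are fixed at 1 (synthetic data are generated on
  the model scale); fitting real blot intensities would require per-readout
  scale parameters.
* Stimulus gates are binary steps; graded or transient aa/insulin inputs are
  not modelled.
* The SBML writer targets L2V4 with a package annotation for pool/gate
  metadata; models written by other tools can be read only if they follow
  the same annotation convention.
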