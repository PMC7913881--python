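# Methods

## The model

HcdE is a zinc-dependent, alcohol-dehydrogenase-family ene-reductase
that reduces the C3–C4 double bond of 7-hydroxycoumarin (7HK) at the
expense of NADPH.  The package models its kinetics as a ping-pong
bi-substrate cycle with a dead-end substrate-inhibition branch:

    E0 + NADPH  <=>[k1/k-1]  E1  -->[k_NADPH]  E2          (reductive half)
    E2 + 7HK    <=>[k2/k-2]  E3  -->[k_7HK]    E0 + NADP+ + 7HKH2
    E1 + 7HK    <=>[ka/kd]   Ei                            (dead end)

E0 is oxidized free enzyme, E1 the E0·NADPH charge-transfer complex,
E2 the reduced enzyme carrying NADP⁺, E3 its complex with 7HK, and Ei
the inactive E1·7HK complex.  7HKH2 is the reduction product
7-hydroxy-3,4-dihydrocoumarin.  NADP⁺ release is lumped into the k_7HK
step, exactly as the scheme is written; whether release actually
precedes 7HK binding is not resolvable from steady-state data and does
not affect the steady-state rate law.

### Steady-state rate law

With clamped substrates A = [NADPH], B = [7HK], setting the time
derivatives of the enzyme forms to zero gives, exactly,

    v = k_NADPH · E_tot / ( Km_NADPH/A + 1 + B/K_i
                            + k_NADPH/(k_bim·B) + k_NADPH/k_7HK )

where Km_NADPH = (k-1 + k_NADPH)/k1, Km_7HK = (k-2 + k_7HK)/k2,
k_bim = k_7HK/Km_7HK and K_i = kd/ka.  (Derivation: the Ei balance
gives Ei = (B/K_i)·E1 and cancels the ka/kd terms from the E1 balance;
the E1 balance then gives E0 = (Km_NADPH/A)·E1; the E3 balance gives
E2 = (Km_7HK/B)·E3; the cycle flux condition k_NADPH·E1 = k_7HK·E3
closes the system, and the enzyme conservation sum yields the bracket.)

Dropping the last term — valid when the oxidative hydride transfer is
much faster than NADPH oxidation, k_7HK ≫ k_NADPH — and multiplying
through by k_bim·k_NADPH·A·B gives the working four-parameter form

    v = E_tot · k_bim · k_NADPH · A · B
        / ( k_NADPH·A + k_bim·B·(Km_NADPH + A + A·B/K_i) )       (*)

implemented in `hcdkin.kinetics.velocity_mM`.  The neglected term is a
single additive denominator contribution (k_NADPH/k_7HK)·k_bim·A·B;
equivalently 1/v_exact − 1/v_(*) = 1/(E_tot·k_7HK) exactly, which the
test suite asserts against the linear-algebra steady-state oracle.

**Reading of the inhibition term.**  The inhibition contribution is
implemented as A·B/K_i, i.e. K_i enters as a *dissociation* constant
in concentration units.  Three reasons: (i) K_i = kd/ka has units of
concentration (22 mM for 7HK), so the denominator bracket — a sum of
concentrations — stays dimensionally consistent only when A·B is
divided by K_i; (ii) inhibition must strengthen with B and vanish as
K_i → ∞, which this form does; (iii) the independent steady-state
derivation above produces exactly this term.  A multiplicative
K_i·A·B reading would make the term dimensionally inconsistent and
invert the direction of the effect.

### Parameters

| symbol | meaning | unit | reported value |
|---|---|---|---|
| E_tot | total enzyme | nM | 99 (assay load, fixed) |
| k_bim | bimolecular constant of 7HK reduction, k_7HK/Km_7HK | mM⁻¹s⁻¹ | 1490 |
| k_NADPH | NADPH-oxidation rate constant (reported k_cat) | s⁻¹ | 27 |
| Km_NADPH | Michaelis constant for NADPH at saturating 7HK | µM | 20 |
| K_i | dissociation constant of the dead-end E1·7HK complex | mM | 22 |

K_i = ∞ (no inhibition) is an explicit sentinel (`NO_INHIBITION`,
stored as `math.inf`), never a large float standing in for infinity.

### Units

Internally everything is mM and seconds; quantities cross the API in
bench units (enzyme nM, substrates µM, K_i mM) and every field and
argument carries its unit in its name.  A property test asserts that
µM- and mM-route evaluations agree to 1e-12 relative.

## Mechanism oracle

`hcdkin.mechanism` expands the scheme into 9 mass-action ODEs
(5 enzyme forms + 4 metabolites, 7 elementary processes).  Two
independent routes serve as oracles for (*):

* **Clamped-substrate steady state** — solved exactly as a 5×5 linear
  system in the enzyme forms (four balance rows + the conservation
  row); velocity is k_7HK·[E3].  With ka = 0 the Ei balance row is
  degenerate and is replaced by Ei = 0.
* **Time-course integration** — stiff BDF with analytic Jacobian,
  rtol 1e-10 / atol 1e-15 mM; conserved totals (enzyme; NADPH + NADP⁺
  + enzyme-bound cofactor; 7HK + 7HKH2 + enzyme-bound coumarin) drift
  below 1e-9 relative on all tested trajectories.  Note the bound
  forms must be included: free NADPH + NADP⁺ alone is conserved only
  to O(E_tot).

The macro → micro expansion is degenerate; `micro_from_macro` resolves
it with two documented ratios, commitment = k-1/k_NADPH (default 4)
and excess = k_7HK/k_NADPH (default 100), plus an arbitrary ka scale
and the choice k-2 = k_7HK (only the combination k_bim is identified).
The default excess keeps the neglected term below 1% across the design
grid; excess ≤ 1 triggers a warning because the closed form then
visibly disagrees with the mechanism.

Time-course initial rates carry one further, physically real, offset:
the enzyme-form distribution relaxes to steady state on a timescale
~1/k_NADPH ≈ 37 ms, so a windowed early slope sits slightly below the
clamped steady state (≈0.5% at the standard condition) in addition to
the ≈0.7% QSSA offset.  Tests therefore hold the slope to 1% of the
exact steady state and 2% of the closed form.

## Assay math

Beer–Lambert conversion c = A/(ε·l) with the assay's coefficients:
ε340 = 5580 (7-hydroxycoumarin), 4780 (6-hydroxycoumarin), 4440
(6-methylcoumarin), 8500 (6,7-dihydroxycoumarin), 3690 (coumarin) and
ε365 = 3500 M⁻¹cm⁻¹ (NADPH).  The 340 nm values are composite
coefficients of the coupled NADPH+coumarin signal and are used as
single-ε conversions, as the assay does.  Pathlength is not part of
the assay description; the default is 1 cm (0.8 mL reaction volume
suggests a standard cuvette) and it is configurable.

Initial rates are least-squares slopes over the initial contiguous
window in which analyte conversion stays ≤ 5% (≥ 5 points required),
reported as positive magnitudes for both depletion and formation.
Replicate panels aggregate by the mean of per-replicate slopes, not
the slope of pooled points.  Relative activity across substrates is
v_ref/v_substrate on replicate means, with zero-mean substrates
flagged "no activity" rather than given an infinite fold.

## Fitting

`PingPongRateLaw` is a scikit-learn style regressor
(`fit(X, y)` / `predict` / `get_params`), X = (NADPH µM, 7HK µM),
y = v µM/s:

* **Weighting** — relative (residuals divided by observed velocity,
  floored at 0.1% of the max) by default, because velocities span more
  than an order of magnitude over the design; absolute weighting
  available.
* **Parameterization** — log-space over (k_bim, k_NADPH, Km_NADPH,
  K_i), enforcing positivity and conditioning the problem.
* **Multi-start** — a Michaelis-style heuristic start (Vmax/E_tot for
  k_cat, the median NADPH level for Km, a low-B/high-A secant for
  k_bim, 5× the largest 7HK level for K_i) plus log-uniform
  perturbations within ±2 decades, 8 starts, seeded and deterministic.
* **E_tot fixed** — the enzyme load is a known assay constant;
  estimating it would be exactly collinear with k_NADPH.
* **Uncertainty** — Gauss–Newton covariance on the log scale,
  delta-method standard errors; case-resampling bootstrap
  (observations resampled with replacement, warm-started refits,
  percentile intervals, deterministic per seed, warning above 20%
  refit failures); profile likelihood by re-optimizing the remaining
  parameters on a grid.

**K_i identifiability.**  On the 5–150 µM 7HK design the inhibition
term perturbs v by at most 150 µM / 22 mM ≈ 0.7%, below the default
noise — K_i is practically non-identifiable there, its profile flat
over 1–1000 mM (a test asserts this).  The canonical recovery
experiment therefore extends the 7HK series to 60 mM (five log-spaced
levels from 0.5 mM).  This extended series is a reconstruction: the
inhibition experiment at multi-mM 7HK is described qualitatively but
not tabulated.  The fit flags K_i as non-identifiable when its
log-scale standard error exceeds ~1.15 (a 1σ band wider than a
decade).

## qPCR quantification

Relative amount = efficiency^(Ct_ref − Ct_gene) against the 16S rRNA
reference; fold change is the ratio of replicate-mean amounts against
the glucose-grown baseline, equal to efficiency^(−ΔΔCt) on mean Ct.
Efficiency defaults to 2.0 (perfect doubling) since no standard-curve
efficiencies are available; it is configurable per call.  Replicates
are averaged on the Ct scale (geometric mean of amounts) — the
averaging scale of the original three-run averages is unstated, and
the geometric choice is the one consistent with Ct-space noise.
Undetermined amplification is a missing Ct propagating to amount 0
with a `detected = False` flag, never an imputed cycle cap.

## Ion masses and stoichiometry

Formulas are parsed from Hill notation; nominal mass sums the mass
numbers of the most abundant isotopes (the "Da" values quoted for ESI
ions are nominal), monoisotopic mass sums CODATA/IUPAC exact isotope
masses, and adducts are [M±H]∓ (nominal ±1; monoisotopic ± the proton
mass 1.007276 Da, electron mass neglected at the 0.5 mDa level).
The registry ships the seven proposed pathway intermediates
(7-hydroxycoumarin C9H6O3 → succinate C4H6O4) plus the pyridine
side-product C9H9NO5 seen in engineered strains; their computed ions
reproduce the observed 161/163/181 [M-H]⁻ and 212 [M+H]⁺ exactly.

Conversion yield uses average molecular weights, as bench
stoichiometry does: 59 mg C9H6O3 → theoretical 66.3 mg C9H10O4, so a
50 mg recovery is 75.4% of theory.  The originally stated figure of
75.7% is not reproducible from standard atomic weights; the package
reports its own computed value and documents the ~0.3-point
discrepancy rather than forcing agreement.

## Synthetic data

Generators are deterministic functions of (config, seed) and emulate
the study conditions: an 8×8 log-spaced velocity grid over 5–200 µM
NADPH × 5–150 µM 7HK in triplicate at 99 nM enzyme (log placement of
levels within the stated ranges is an assumption; the true placement
is unpublished), optionally extended with the multi-mM inhibition
series; A365 depletion traces integrated from the full mechanism; and
Ct tables with programmed inductions (1000-fold for hcd genes under
7HK or the propionate product, 100-fold under 7-methylcoumarin, 2–3×
for xenA38, one never-detected gene).

Noise defaults — 3% proportional CV + 0.005 µM/s additive floor on
velocities, 0.002 AU absorbance read noise, 0.3-cycle Ct SD — are
typical bench magnitudes chosen once; the original error model is
unreported.  Negative velocity draws are truncated at zero and
counted.

What the generators do **not** emulate: whole-cell transport effects
(the in vivo / in vitro activity discrepancy for 7-methylcoumarin and
relatives), enzyme inactivation or cell lysis over long incubations,
instrument drift, pipetting covariance between replicates, or
non-Gaussian Ct error.  Passing recovery tests therefore demonstrate
the estimator is correct and well-conditioned under the stated error
model at the stated design — not that real data of unknown error
structure would yield the same constants.

## Numerical choices

* ODE: BDF, analytic Jacobian, rtol 1e-10, atol 1e-15 mM; trajectories
  clipped at 0 after integration (round-off only).
* Optimizer: Levenberg–Marquardt (trust-region fallback when the
  problem is under-determined), xtol = ftol = gtol = 1e-14, wild
  multi-start points protected by clipping log-parameters to ±200
  before exponentiation; a runaway log-K_i (> 500) is reported as ∞.
* Rate law returns exactly 0 when either substrate or the enzyme is 0
  (0/0 guarded).
* Degenerate designs (< 2 distinct levels per substrate) are rejected
  before optimization.

## Problem sizes

Default analyses are desk-scale: the canonical dataset is 312
observations (8 × 13 × 3); the bias/RMSE study uses 50 seeds; the
bootstrap defaults to 200 draws (tests use 100–150); the qPCR
Monte-Carlo uses 50 seeds.  The full test suite runs in well under a
minute.

## Known limitations

* Initial-rate paradigm only: no progress-curve (global) fitting, no
  pre-steady-state modelling beyond the lag discussion above.
* The scheme is irreversible as written; product inhibition by NADP⁺
  or the dihydrocoumarin is not modelled.
* pH/temperature dependence, cofactor specificity and whole-cell
  bioconversion spectra are out of scope.
* The qPCR module quantifies from threshold cycles only; amplification
  curve processing and primer design belong to instrument software.
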