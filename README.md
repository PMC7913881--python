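# hcdkin

Kinetics and analysis toolkit for **HcdE**, the NADPH-dependent
ene-reductase that carries out the first step of 7-hydroxycoumarin
(umbelliferone) degradation in *Pseudomonas mandelii* 7HK4.  The
package is aimed at enzymologists and systems biologists who want to
fit, simulate and sanity-check bi-substrate kinetics with substrate
inhibition, together with the surrounding assay arithmetic: Beer–Lambert
conversion of spectrophotometric traces, qPCR relative expression
against a 16S reference, and ESI-MS ion-mass bookkeeping for the
catabolic pathway intermediates.

## The model

HcdE follows a ping-pong bi-substrate cycle — NADPH first reduces the
enzyme, then the coumarin's C3–C4 double bond is reduced — with a
dead-end complex formed when 7-hydroxycoumarin (7HK) binds the
enzyme·NADPH charge-transfer complex.  The steady-state velocity is

    v = E₀ · k_bim · k_NADPH · [NADPH][7HK]
        ─────────────────────────────────────────────────────────────
        k_NADPH[NADPH] + k_bim[7HK]·(Km,NADPH + [NADPH] + [NADPH][7HK]/K_i)

with k_bim the bimolecular constant of coumarin reduction
(= k_7HK/Km,7HK), k_NADPH the NADPH-oxidation rate constant (k_cat),
Km,NADPH the Michaelis constant for NADPH at saturating coumarin, and
K_i = kd/ka the dissociation constant of the dead-end complex
(pseudo-competitive substrate inhibition).  A full mass-action
simulation of the underlying five-enzyme-species mechanism serves as
an exact oracle for this closed form; see `docs/methods.md` for the
derivation and the one denominator term the closed form neglects.

## Worked example

Closed-loop parameter recovery: generate a synthetic initial-velocity
experiment at the reported constants, then fit the rate law back.

```python
from hcdkin import (REPORTED_PARAMETERS, VelocityDesign,
                    generate_velocity_dataset, velocity_uM)
from hcdkin.fitting import fit_rate_law

# velocity at the standard assay load: 160 µM NADPH, 60 µM 7HK, 99 nM enzyme
print(round(velocity_uM(REPORTED_PARAMETERS, 160.0, 60.0), 3))   # 1.87 µM/s

# 8 NADPH levels (5–200 µM) x 13 7HK levels (5 µM – 60 mM), triplicate, 3% CV
data = generate_velocity_dataset(VelocityDesign(extended=True), seed=42)
print(len(data))                                                 # 312

res = fit_rate_law(data, e_total_nM=99.0, random_state=42)
p = res.params
print(f"k_bim     = {p.k_bim_per_mM_s:7.1f} mM^-1 s^-1   (truth 1490)")
print(f"k_cat     = {p.k_nadph_per_s:7.2f} s^-1          (truth 27)")
print(f"Km_NADPH  = {p.km_nadph_uM:7.2f} uM            (truth 20)")
print(f"K_i       = {p.k_i_mM:7.2f} mM            (truth 22)")
```

prints

```
1.87
312
k_bim     =  1483.5 mM^-1 s^-1   (truth 1490)
k_cat     =   26.92 s^-1          (truth 27)
Km_NADPH  =   19.92 uM            (truth 20)
K_i       =   21.67 mM            (truth 22)
```

i.e. all four constants come back within ~2% of the generating values
under 3% measurement noise.  The 1.87 µM/s is the rate-law velocity at
the standard assay condition; the fitted K_i is identifiable only
because the design extends the 7HK series into the multi-mM range
where inhibition bites (`res.ki_identifiable` is `True` here and
`False` on the 5–150 µM design alone).

The estimator is also available as a scikit-learn regressor
(`hcdkin.PingPongRateLaw`) composing with sklearn model selection, and
everything is scriptable from the shell:

```sh
hcdkin synth --kind velocity --extended --seed 42 --out data.csv
hcdkin fit --inp data.csv --seed 42 --out fit.json
hcdkin reproduce --seed 42 --outdir run/     # full pipeline + JSON report
```

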