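"""Seeded generators for every input the pipeline consumes.

These emulate the study conditions of the HcdE kinetic and expression
experiments so every stage is testable without measured data:

* velocity grids — 8 log-spaced NADPH levels over 5–200 µM crossed with
  8 log-spaced 7HK levels over 5–150 µM, triplicate, 99 nM enzyme;
  the extended-inhibition variant appends 7HK levels up to 60 mM so
  the substrate-inhibition constant (~22 mM) becomes identifiable.
* NADPH-depletion absorbance traces at 365 nm (ε = 3500 M⁻¹cm⁻¹),
  integrated from the full mass-action mechanism.
* qPCR Ct tables against a 16S reference with programmed inductions
  (1000-fold for the hcd cluster under 7-hydroxycoumarin or the
  propionic-acid product, 100-fold under 7-methylcoumarin, 2–3-fold
  for xenA38, and an undetected gene).

Noise defaults — 3% proportional CV plus a 0.005 µM/s additive floor on
velocities, 0.002 AU absorbance read noise, 0.3-cycle Ct SD — are
typical bench magnitudes; the measurement error model of the original
experiments is unreported.  Every generator is a deterministic function
of (config, seed); sub-streams are derived from the one seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assay import DEFAULT_EXTINCTIONS, AbsorbanceTrace, ExtinctionTable
from .kinetics import REPORTED_PARAMETERS, KineticParameters, velocity_uM
from .mechanism import MechanismState, micro_from_macro, simulate_mechanism

__all__ = [
    "VelocityDesign",
    "ScenarioConfig",
    "generate_velocity_dataset",
    "generate_absorbance_traces",
    "generate_activity_panel",
    "generate_ct_table",
]


def _levels(lo: float, hi: float, n: int) -> tuple:
    return tuple(float(x) for x in np.geomspace(lo, hi, n))


@dataclass(frozen=True)
class VelocityDesign:
    """Design of an initial-velocity experiment.

    Defaults mirror the bench design: NADPH 5–200 µM and 7HK 5–150 µM,
    8 log-spaced levels each, triplicate, 99 nM enzyme.  ``extended``
    appends five 7HK levels from 0.5 to 60 mM; this high-concentration
    series is a reconstruction (the inhibition experiment is described
    but not tabulated) and is required to pin down K_i.
    """

    nadph_levels_uM: tuple = _levels(5.0, 200.0, 8)
    s7hk_levels_uM: tuple = _levels(5.0, 150.0, 8)
    replicates: int = 3
    e_total_nM: float = 99.0
    cv: float = 0.03
    floor_uM_s: float = 0.005
    extended: bool = False

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if self.cv < 0 or self.floor_uM_s < 0:
            raise ValueError("noise magnitudes must be non-negative")

    @property
    def all_s7hk_levels_uM(self) -> tuple:
        if not self.extended:
            return self.s7hk_levels_uM
        return self.s7hk_levels_uM + _levels(500.0, 60000.0, 5)


@dataclass(frozen=True)
class ScenarioConfig:
    """End-to-end scenario: generating truths for all synthetic inputs.

    ``panel_folds`` are activity reductions relative to
    7-hydroxycoumarin across the coumarin substrate panel;
    ``inductions`` maps (gene, condition) to programmed fold change over
    glucose-grown baseline (None = gene undetected everywhere).
    """

    params: KineticParameters = REPORTED_PARAMETERS
    panel_folds: dict = field(
        default_factory=lambda: {
            "7-hydroxycoumarin": 1.0,
            "6,7-dihydroxycoumarin": 1.6,
            "6-hydroxycoumarin": 2.0,
            "6-methylcoumarin": 3.4,
            "coumarin": 17.0,
        }
    )
    genes: tuple = ("hcdE", "hcdA", "xenA38", "xenA45")
    conditions: tuple = ("glucose", "7-hydroxycoumarin", "DHPP", "7-methylcoumarin",
                         "6-hydroxycoumarin")
    inductions: dict = field(
        default_factory=lambda: {
            ("hcdE", "7-hydroxycoumarin"): 1000.0,
            ("hcdE", "DHPP"): 1000.0,
            ("hcdE", "7-methylcoumarin"): 100.0,
            ("hcdA", "7-hydroxycoumarin"): 1000.0,
            ("hcdA", "DHPP"): 1000.0,
            ("hcdA", "7-methylcoumarin"): 100.0,
            ("xenA38", "7-hydroxycoumarin"): 3.0,
            ("xenA38", "6-hydroxycoumarin"): 2.0,
        }
    )
    undetected_genes: tuple = ("xenA45",)
    ct_sd: float = 0.3
    reference_gene: str = "16S"
    baseline_condition: str = "glucose"


def generate_velocity_dataset(
    design: VelocityDesign = VelocityDesign(),
    params: KineticParameters = REPORTED_PARAMETERS,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicated (NADPH, 7HK, v) observations with multiplicative +
    additive noise.

    v_obs = v_true * (1 + cv*xi) + floor*zeta with independent standard
    normal xi, zeta; negative draws are truncated to 0 and counted in
    ``df.attrs["n_truncated"]``.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for a in design.nadph_levels_uM:
        for b in design.all_s7hk_levels_uM:
            v_true = velocity_uM(
                params_with_e(params, design.e_total_nM), a, b
            )
            for rep in range(1, design.replicates + 1):
                v = v_true * (1.0 + design.cv * rng.standard_normal())
                v += design.floor_uM_s * rng.standard_normal()
                rows.append((a, b, v, rep, v_true))
    df = pd.DataFrame(rows, columns=["nadph_uM", "s7hk_uM", "v_uM_per_s",
                                     "replicate", "v_true_uM_per_s"])
    n_trunc = int((df["v_uM_per_s"] < 0).sum())
    df["v_uM_per_s"] = df["v_uM_per_s"].clip(lower=0.0)
    df.attrs.update(
        {"provenance": f"synthetic(seed={seed})", "n_truncated": n_trunc,
         "extended": design.extended}
    )
    return df


def params_with_e(params: KineticParameters, e_total_nM: float) -> KineticParameters:
    """The same rate constants at a different enzyme load."""
    if math.isclose(params.e_total_nM, e_total_nM):
        return params
    return KineticParameters.from_assay_units(
        e_total_nM=e_total_nM,
        k_bim_per_mM_s=params.k_bim_per_mM_s,
        k_nadph_per_s=params.k_nadph_per_s,
        km_nadph_uM=params.km_nadph_uM,
        k_i_mM=params.k_i_mM,
    )


def generate_absorbance_traces(
    conditions=((160.0, 60.0),),
    params: KineticParameters = REPORTED_PARAMETERS,
    epsilon_table: ExtinctionTable = DEFAULT_EXTINCTIONS,
    duration_s: float = 1.5,
    n_points: int = 60,
    noise_sd_AU: float = 0.002,
    replicates: int = 1,
    seed: int = 0,
    use_mechanism: bool = True,
) -> list:
    """A365 NADPH-depletion traces for a list of (NADPH µM, 7HK µM) loads.

    Concentration courses come from the full mass-action mechanism
    (or, with ``use_mechanism=False``, the linearized early-time model
    c(t) = c0 − v·t); Beer–Lambert maps them to absorbance at 365 nm
    with Gaussian read noise.
    """
    rng = np.random.default_rng(seed)
    eps = epsilon_table.epsilon("NADPH", 365.0)
    path = epsilon_table.pathlength_cm
    t = np.linspace(0.0, duration_s, n_points)
    traces = []
    for nadph_uM, s7hk_uM in conditions:
        if use_mechanism:
            micro = micro_from_macro(params)
            init = MechanismState.assay_load(
                e_total_mM=params.e_total_mM,
                nadph_mM=nadph_uM / 1e3,
                s7hk_mM=s7hk_uM / 1e3,
            )
            traj = simulate_mechanism(micro, init, t)
            conc_uM = traj.species("nadph") * 1e3
        else:
            v = velocity_uM(params, nadph_uM, s7hk_uM)
            conc_uM = np.maximum(nadph_uM - v * t, 0.0)
        a_clean = conc_uM * 1e-6 * eps * path
        for rep in range(1, replicates + 1):
            a = a_clean + noise_sd_AU * rng.standard_normal(t.shape)
            traces.append(
                AbsorbanceTrace(
                    time_s=t,
                    absorbance=a,
                    wavelength_nm=365.0,
                    analyte="NADPH",
                    replicate=rep,
                    meta={"nadph_uM": nadph_uM, "s7hk_uM": s7hk_uM,
                          "seed": seed},
                )
            )
    return traces


def generate_activity_panel(
    config: ScenarioConfig = ScenarioConfig(),
    v_ref_uM_s: float | None = None,
    replicates: int = 3,
    cv: float = 0.03,
    seed: int = 0,
) -> dict:
    """Replicate velocities per substrate with programmed fold reductions.

    The reference velocity defaults to the rate-law value at the
    standard assay load (160 µM NADPH, 60 µM substrate); each other
    substrate's mean is v_ref / fold.
    """
    rng = np.random.default_rng(seed)
    if v_ref_uM_s is None:
        v_ref_uM_s = velocity_uM(config.params, 160.0, 60.0)
    panel = {}
    for name, fold in config.panel_folds.items():
        mean = v_ref_uM_s / fold
        panel[name] = list(mean * (1.0 + cv * rng.standard_normal(replicates)))
    return panel


def generate_ct_table(
    config: ScenarioConfig = ScenarioConfig(),
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format Ct table with programmed inductions.

    Per gene a baseline Ct is drawn once (uniform 24–30 cycles, glucose
    condition); an induced condition shifts it by −log2(fold).  The 16S
    reference amplifies at a constant Ct (~12 cycles) in every
    condition.  Replicate noise is N(0, ct_sd).  Undetected genes carry
    missing Ct everywhere.
    """
    rng = np.random.default_rng(seed)
    rows = []
    base_ct = {g: rng.uniform(24.0, 30.0) for g in config.genes}
    ref_ct = 12.0
    all_genes = (config.reference_gene,) + tuple(config.genes)
    for cond in config.conditions:
        for gene in all_genes:
            for rep in range(1, replicates + 1):
                if gene == config.reference_gene:
                    ct = ref_ct + config.ct_sd * rng.standard_normal()
                elif gene in config.undetected_genes:
                    ct = np.nan
                else:
                    fold = config.inductions.get((gene, cond), 1.0)
                    ct = (
                        base_ct[gene]
                        - math.log2(fold)
                        + config.ct_sd * rng.standard_normal()
                    )
                rows.append((gene, cond, rep, ct))
    df = pd.DataFrame(rows, columns=["gene", "condition", "replicate", "ct"])
    df.attrs["provenance"] = f"synthetic(seed={seed})"
    return df
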