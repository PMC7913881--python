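"""Closed-form rate law of the HcdE ping-pong mechanism with substrate
inhibition, and the mapping between macroscopic kinetic parameters and
elementary (microscopic) rate constants.

The enzyme cycles through an oxidized form E0, a charge-transfer complex
E1 (E0·NADPH), a reduced form E2 carrying NADP+, and a second
charge-transfer complex E3 (E2·7HK); 7-hydroxycoumarin (7HK) can also
bind E1 to form a catalytically dead complex Ei, which produces
pseudo-competitive substrate inhibition with dissociation constant
K_i = kd/ka.

Under the quasi-steady-state approximation, with hydride transfer to the
coumarin fast relative to NADPH oxidation (k_7hk >> k_nadph), the
steady-state velocity is

    v = E0_tot * k_bim * k_nadph * A * B
        / ( k_nadph*A + k_bim*B*(Km_NADPH + A + A*B/K_i) )

with A = [NADPH], B = [7HK], k_bim = k_7hk/Km_7HK the bimolecular
constant of coumarin reduction, k_nadph the NADPH-oxidation rate
constant (the reported k_cat), and Km_NADPH the Michaelis constant for
NADPH at saturating coumarin.  The inhibition term is A*B/K_i: K_i is a
dissociation constant in concentration units, so the bracket stays
dimensionally a concentration and inhibition strengthens with B and
weakens as K_i grows.  See docs/methods.md for the full steady-state
derivation and the single denominator term this form neglects.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .units import nm_to_mm, um_to_mm, mm_to_um, mm_to_nm

__all__ = [
    "NO_INHIBITION",
    "KineticParameters",
    "MicroscopicRates",
    "velocity_mM",
    "velocity_uM",
    "macro_from_micro",
    "micro_from_macro",
    "REPORTED_PARAMETERS",
]

#: Sentinel for "no substrate inhibition" (K_i -> infinity).  Stored as
#: math.inf so the rate law degenerates to the plain ping-pong form.
NO_INHIBITION = math.inf


def _require_positive(name: str, value: float, allow_inf: bool = False) -> None:
    if allow_inf and math.isinf(value) and value > 0:
        return
    if not (math.isfinite(value) and value > 0):
        raise ValueError(f"{name} must be strictly positive and finite, got {value!r}")


@dataclass(frozen=True)
class KineticParameters:
    """Macroscopic parameter set of the steady-state rate law.

    Internal storage is mM / s.  Use :meth:`from_assay_units` to build
    from the units kinetic parameters are reported in (enzyme nM,
    Km µM, K_i mM).
    """

    e_total_mM: float
    k_bim_per_mM_s: float
    k_nadph_per_s: float
    km_nadph_mM: float
    k_i_mM: float = NO_INHIBITION

    def __post_init__(self) -> None:
        _require_positive("e_total_mM", self.e_total_mM)
        _require_positive("k_bim_per_mM_s", self.k_bim_per_mM_s)
        _require_positive("k_nadph_per_s", self.k_nadph_per_s)
        _require_positive("km_nadph_mM", self.km_nadph_mM)
        _require_positive("k_i_mM", self.k_i_mM, allow_inf=True)

    @classmethod
    def from_assay_units(
        cls,
        e_total_nM: float,
        k_bim_per_mM_s: float,
        k_nadph_per_s: float,
        km_nadph_uM: float,
        k_i_mM: float = NO_INHIBITION,
    ) -> "KineticParameters":
        return cls(
            e_total_mM=nm_to_mm(e_total_nM),
            k_bim_per_mM_s=k_bim_per_mM_s,
            k_nadph_per_s=k_nadph_per_s,
            km_nadph_mM=um_to_mm(km_nadph_uM),
            k_i_mM=k_i_mM,
        )

    # convenience views in assay units
    @property
    def e_total_nM(self) -> float:
        return mm_to_nm(self.e_total_mM)

    @property
    def km_nadph_uM(self) -> float:
        return mm_to_um(self.km_nadph_mM)

    @property
    def has_inhibition(self) -> bool:
        return math.isfinite(self.k_i_mM)

    def without_inhibition(self) -> "KineticParameters":
        return replace(self, k_i_mM=NO_INHIBITION)

    def to_dict(self) -> dict:
        return {
            "e_total_nM": self.e_total_nM,
            "k_bim_per_mM_s": self.k_bim_per_mM_s,
            "k_nadph_per_s": self.k_nadph_per_s,
            "km_nadph_uM": self.km_nadph_uM,
            "k_i_mM": self.k_i_mM,
        }


#: Point estimates reported for HcdE: k_bim = 1490 mM^-1 s^-1,
#: k_cat(NADPH) = 27 s^-1, Km_NADPH = 20 µM, K_i = 22 mM, at the assay
#: enzyme load of 99 nM.
REPORTED_PARAMETERS = KineticParameters.from_assay_units(
    e_total_nM=99.0,
    k_bim_per_mM_s=1490.0,
    k_nadph_per_s=27.0,
    km_nadph_uM=20.0,
    k_i_mM=22.0,
)


@dataclass(frozen=True)
class MicroscopicRates:
    """Elementary rate constants of the five-species mechanism.

        E0 + NADPH <=>[k1/k_m1] E1 -->[k_nadph] E2
        E2 + 7HK   <=>[k2/k_m2] E3 -->[k_7hk]   E0 + NADP+ + 7HKH2
        E1 + 7HK   <=>[ka/kd]   Ei

    Units: mM^-1 s^-1 for the bimolecular constants (k1, k2, ka) and
    s^-1 for the rest.  ``ka = 0`` encodes the no-inhibition limit
    (the dead-end channel is absent and K_i is infinite).
    """

    k1_per_mM_s: float
    k_m1_per_s: float
    k_nadph_per_s: float
    k2_per_mM_s: float
    k_m2_per_s: float
    k_7hk_per_s: float
    ka_per_mM_s: float
    kd_per_s: float

    def __post_init__(self) -> None:
        for name in ("k1_per_mM_s", "k_m1_per_s", "k_nadph_per_s",
                     "k2_per_mM_s", "k_m2_per_s", "k_7hk_per_s"):
            _require_positive(name, getattr(self, name))
        if self.ka_per_mM_s < 0 or self.kd_per_s < 0:
            raise ValueError("ka and kd must be non-negative")
        if self.ka_per_mM_s > 0 and self.kd_per_s == 0:
            raise ValueError("kd must be positive when ka > 0 (K_i would be 0)")

    @property
    def km_nadph_mM(self) -> float:
        return (self.k_m1_per_s + self.k_nadph_per_s) / self.k1_per_mM_s

    @property
    def km_7hk_mM(self) -> float:
        return (self.k_m2_per_s + self.k_7hk_per_s) / self.k2_per_mM_s

    @property
    def k_bim_per_mM_s(self) -> float:
        return self.k_7hk_per_s / self.km_7hk_mM

    @property
    def k_i_mM(self) -> float:
        if self.ka_per_mM_s == 0:
            return NO_INHIBITION
        return self.kd_per_s / self.ka_per_mM_s


def velocity_mM(params: KineticParameters, nadph_mM, s7hk_mM):
    """Steady-state velocity (mM/s) at NADPH and 7HK concentrations in mM.

    Vectorized: accepts scalars or broadcastable arrays; concentrations
    must be non-negative.  Returns 0 wherever either substrate is absent.
    """
    a = np.asarray(nadph_mM, dtype=float)
    b = np.asarray(s7hk_mM, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("substrate concentrations must be non-negative")

    kb = params.k_bim_per_mM_s
    kn = params.k_nadph_per_s
    km = params.km_nadph_mM
    inhib = 0.0 if not params.has_inhibition else 1.0 / params.k_i_mM

    num = params.e_total_mM * kb * kn * a * b
    den = kn * a + kb * b * (km + a + a * b * inhib)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(num == 0.0, 0.0, num / den)
    if v.ndim == 0:
        return float(v)
    return v


def velocity_uM(params: KineticParameters, nadph_uM, s7hk_uM):
    """Steady-state velocity in µM/s at substrate concentrations in µM."""
    v = velocity_mM(params, um_to_mm(np.asarray(nadph_uM, dtype=float)),
                    um_to_mm(np.asarray(s7hk_uM, dtype=float)))
    return mm_to_um(v)


def macro_from_micro(micro: MicroscopicRates, e_total_nM: float) -> KineticParameters:
    """Collapse elementary rate constants to the macroscopic parameter set.

    Applies the defining relations exactly:
    Km_NADPH = (k_m1 + k_nadph)/k1, k_bim = k_7hk / Km_7HK with
    Km_7HK = (k_m2 + k_7hk)/k2, and K_i = kd/ka (infinite when ka = 0).
    """
    return KineticParameters(
        e_total_mM=nm_to_mm(e_total_nM),
        k_bim_per_mM_s=micro.k_bim_per_mM_s,
        k_nadph_per_s=micro.k_nadph_per_s,
        km_nadph_mM=micro.km_nadph_mM,
        k_i_mM=micro.k_i_mM,
    )


def micro_from_macro(
    params: KineticParameters,
    commitment: float = 4.0,
    excess: float = 100.0,
    ka_per_mM_s: float = 1.0,
) -> MicroscopicRates:
    """Expand macroscopic parameters to one consistent microscopic rate set.

    The macro -> micro map is degenerate; two documented ratios resolve it:

    commitment
        k_m1 / k_nadph, the reverse-to-forward ratio at E1 (default 4,
        i.e. NADPH binding is near rapid-equilibrium).
    excess
        k_7hk / k_nadph (default 100).  The closed-form rate law drops a
        denominator term of relative size k_nadph/k_7hk; the default
        keeps that neglect below 1%.  ``excess <= 1`` is accepted but
        warned about, since the closed form then degrades visibly.

    The oxidative half is completed with k_m2 = k_7hk (an arbitrary,
    documented choice: only the combination k_7hk*k2/(k_m2+k_7hk) = k_bim
    is identified) and kd = ka * K_i.  ``ka_per_mM_s`` is a free scale;
    for inhibition-free parameters (K_i infinite) ka is forced to 0.
    """
    if not (commitment > 0):
        raise ValueError("commitment ratio must be positive")
    if not (excess > 0):
        raise ValueError("excess ratio must be positive")
    if excess <= 1:
        warnings.warn(
            "excess = k_7hk/k_nadph <= 1: the closed-form rate law neglects a "
            "term of relative size k_nadph/k_7hk and will disagree with the "
            "full mechanism",
            stacklevel=2,
        )
    kn = params.k_nadph_per_s
    k_m1 = commitment * kn
    k1 = (k_m1 + kn) / params.km_nadph_mM
    k_7hk = excess * kn
    k_m2 = k_7hk
    # k_bim = k_7hk * k2 / (k_m2 + k_7hk)  =>  k2 = k_bim*(k_m2+k_7hk)/k_7hk
    k2 = params.k_bim_per_mM_s * (k_m2 + k_7hk) / k_7hk
    if params.has_inhibition:
        if not (ka_per_mM_s > 0):
            raise ValueError("ka must be positive when K_i is finite")
        ka, kd = ka_per_mM_s, ka_per_mM_s * params.k_i_mM
    else:
        ka, kd = 0.0, 0.0
    return MicroscopicRates(
        k1_per_mM_s=k1,
        k_m1_per_s=k_m1,
        k_nadph_per_s=kn,
        k2_per_mM_s=k2,
        k_m2_per_s=k_m2,
        k_7hk_per_s=k_7hk,
        ka_per_mM_s=ka,
        kd_per_s=kd,
    )
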