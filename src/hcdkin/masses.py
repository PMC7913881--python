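"""Pathway compound registry, formula parsing and adduct m/z arithmetic.

Covers the proposed 7-hydroxycoumarin catabolic pathway: the coumarin
is reduced to 7-hydroxy-3,4-dihydrocoumarin, which hydrolyzes to
3-(2,4-dihydroxyphenyl)propionic acid and is degraded further via
ring-hydroxylation and meta-cleavage down to succinate.  ESI-MS
detects these intermediates as [M-H]- or [M+H]+ ions; this module
computes nominal and monoisotopic adduct masses from elemental
formulas, matches observed ions to the registry, and does conversion
stoichiometry on average molecular weights.

Atomic masses are an embedded CODATA/IUPAC table (no external
database): nominal = mass number of the most abundant isotope,
monoisotopic = its exact mass, average = standard atomic weight.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "Compound",
    "IonObservation",
    "PATHWAY_REGISTRY",
    "parse_formula",
    "formula_string",
    "molecular_mass",
    "adduct_mz",
    "match_ions",
    "theoretical_yield",
]

PROTON_MASS = 1.007276466

#: (nominal mass number, monoisotopic mass, average atomic weight)
_ELEMENTS = {
    "H": (1, 1.00782503207, 1.008),
    "C": (12, 12.0, 12.011),
    "N": (14, 14.0030740048, 14.007),
    "O": (16, 15.9949146196, 15.999),
    "Na": (23, 22.9897692809, 22.98976928),
    "P": (31, 30.97376163, 30.973761998),
    "S": (32, 31.97207100, 32.06),
    "Cl": (35, 34.96885268, 35.45),
    "K": (39, 38.96370668, 39.0983),
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

_ADDUCTS = {
    "[M-H]-": ("-", -1),
    "[M+H]+": ("+", +1),
}


def parse_formula(s: str) -> dict:
    """Parse a Hill-notation molecular formula into an element->count map.

    >>> parse_formula("C9H9NO5")
    {'C': 9, 'H': 9, 'N': 1, 'O': 5}
    """
    comp: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(s):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {s!r} at position {pos}")
        pos = m.end()
        symbol, count = m.group(1), int(m.group(2) or 1)
        if symbol not in _ELEMENTS:
            raise ValueError(f"unknown element {symbol!r} in formula {s!r}")
        if count <= 0:
            raise ValueError(f"element count must be positive in {s!r}")
        comp[symbol] = comp.get(symbol, 0) + count
    if pos != len(s) or not comp:
        raise ValueError(f"cannot parse formula {s!r}")
    return comp


def formula_string(comp: dict) -> str:
    """Canonical Hill-order string (C, H, then alphabetical)."""
    def fmt(el):
        n = comp[el]
        return el if n == 1 else f"{el}{n}"

    out = []
    for el in ("C", "H"):
        if el in comp:
            out.append(fmt(el))
    for el in sorted(k for k in comp if k not in ("C", "H")):
        out.append(fmt(el))
    return "".join(out)


def molecular_mass(comp: dict, kind: str = "monoisotopic") -> float:
    """Neutral molecular mass: 'nominal', 'monoisotopic' or 'average'."""
    idx = {"nominal": 0, "monoisotopic": 1, "average": 2}
    if kind not in idx:
        raise ValueError(f"mass kind must be one of {sorted(idx)}")
    i = idx[kind]
    total = 0.0
    for el, n in comp.items():
        if el not in _ELEMENTS:
            raise ValueError(f"unknown element {el!r}")
        total += n * _ELEMENTS[el][i]
    return float(total)


def adduct_mz(comp: dict, adduct: str, mass_kind: str = "nominal") -> float:
    """m/z of a protonation/deprotonation adduct.

    Nominal: integer molecular mass ± 1.  Monoisotopic: exact molecular
    mass minus/plus the proton mass (electron mass neglected at the
    0.5 mDa level).
    """
    if adduct not in _ADDUCTS:
        raise ValueError(f"unsupported adduct {adduct!r}; supported: {sorted(_ADDUCTS)}")
    _, sign = _ADDUCTS[adduct]
    if mass_kind == "nominal":
        return float(molecular_mass(comp, "nominal") + sign * 1)
    if mass_kind == "monoisotopic":
        return molecular_mass(comp, "monoisotopic") + sign * PROTON_MASS
    raise ValueError("mass_kind must be 'nominal' or 'monoisotopic'")


@dataclass(frozen=True)
class Compound:
    """A named pathway compound with its elemental composition."""

    name: str
    formula: str
    pathway_index: int | None = None  # position in the proposed pathway, 1-7

    @property
    def composition(self) -> dict:
        return parse_formula(self.formula)

    def mz(self, adduct: str, mass_kind: str = "nominal") -> float:
        return adduct_mz(self.composition, adduct, mass_kind)

    @property
    def average_mw(self) -> float:
        return molecular_mass(self.composition, "average")


#: The proposed catabolic pathway (indices 1-7), plus the pyridine
#: side-product formed from the propionic acid in engineered strains.
PATHWAY_REGISTRY = (
    Compound("7-hydroxycoumarin", "C9H6O3", 1),
    Compound("7-hydroxy-3,4-dihydrocoumarin", "C9H8O3", 2),
    Compound("3-(2,4-dihydroxyphenyl)propionic acid", "C9H10O4", 3),
    Compound("3-(2,3,5-trihydroxyphenyl)propionic acid", "C9H10O5", 4),
    Compound("(2E,4E)-2,4-dihydroxy-6-oxonona-2,4-dienedioic acid", "C9H10O7", 5),
    Compound("(E)-2-hydroxy-4-oxopent-2-enoic acid", "C5H6O4", 6),
    Compound("succinic acid", "C4H6O4", 7),
    Compound(
        "6-(2-carboxyethyl)-4-oxo-1,4-dihydropyridine-2-carboxylic acid",
        "C9H9NO5",
    ),
)


@dataclass(frozen=True)
class IonObservation:
    """An observed ESI ion."""

    mz: float
    polarity: str  # "+" or "-"
    adduct: str | None = None  # defaults to [M+H]+ / [M-H]- by polarity
    source: str = ""

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("m/z must be positive")
        if self.polarity not in ("+", "-"):
            raise ValueError("polarity must be '+' or '-'")

    @property
    def effective_adduct(self) -> str:
        if self.adduct is not None:
            return self.adduct
        return "[M+H]+" if self.polarity == "+" else "[M-H]-"


def match_ions(
    observed,
    registry=PATHWAY_REGISTRY,
    tol: float = 0.5,
    mass_kind: str = "nominal",
) -> list:
    """Assign observed ions to registry compounds within a mass tolerance.

    Returns one record per observation with all compounds whose adduct
    m/z (at the matching polarity) falls within ``tol`` Da; observations
    with no match carry an empty assignment list.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    results = []
    for obs in observed:
        adduct = obs.effective_adduct
        if _ADDUCTS[adduct][0] != obs.polarity:
            raise ValueError(f"adduct {adduct} inconsistent with polarity {obs.polarity}")
        hits = [
            {"compound": c.name, "formula": c.formula,
             "mz_calc": c.mz(adduct, mass_kind),
             "delta": obs.mz - c.mz(adduct, mass_kind)}
            for c in registry
            if abs(c.mz(adduct, mass_kind) - obs.mz) <= tol
        ]
        results.append({"observation": obs, "assignments": hits})
    return results


def theoretical_yield(
    mass_in_mg: float,
    comp_in: dict,
    comp_out: dict,
    actual_mg: float | None = None,
) -> tuple:
    """Mole-conserving conversion yield on average molecular weights.

    theoretical (mg) = mass_in * MW_out / MW_in; if ``actual_mg`` is
    given the second element is actual/theoretical * 100 (percent of
    theoretical), else None.
    """
    if mass_in_mg <= 0:
        raise ValueError("input mass must be positive")
    if actual_mg is not None and actual_mg <= 0:
        raise ValueError("actual mass must be positive")
    mw_in = molecular_mass(comp_in, "average")
    mw_out = molecular_mass(comp_out, "average")
    theo = mass_in_mg * mw_out / mw_in
    percent = None if actual_mg is None else 100.0 * actual_mg / theo
    return theo, percent
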