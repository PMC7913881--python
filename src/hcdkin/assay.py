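"""Spectrophotometric assay math.

Absorbance-vs-time traces are converted to concentration by
Beer–Lambert (c = A / (ε·l)) using the extinction coefficients of the
coupled NADPH/coumarin reaction, initial rates are extracted from the
early linear window, and substrate panels are summarized as fold
activity relative to 7-hydroxycoumarin.

The shipped extinction table holds the per-substrate coefficients of
the coupled assay at 340 nm and the NADPH-only coefficient at 365 nm.
These 340 nm values are composite reaction coefficients — the signal
mixes NADPH and coumarin absorbance — and are applied as single-ε
conversions, exactly as the assay uses them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ExtinctionTable",
    "AbsorbanceTrace",
    "DEFAULT_EXTINCTIONS",
    "absorbance_to_concentration",
    "initial_rate",
    "relative_activity",
    "NO_ACTIVITY",
]

#: flag value used for substrates with zero mean velocity
NO_ACTIVITY = "no activity"


@dataclass(frozen=True)
class ExtinctionTable:
    """Extinction coefficients ε (M^-1 cm^-1) keyed by (analyte, wavelength nm).

    ``pathlength_cm`` defaults to 1 cm (standard cuvette); configurable for
    other geometries.
    """

    coefficients: dict = field(default_factory=dict)
    pathlength_cm: float = 1.0

    def __post_init__(self) -> None:
        for key, eps in self.coefficients.items():
            if eps <= 0:
                raise ValueError(f"extinction coefficient for {key} must be positive")
        if self.pathlength_cm <= 0:
            raise ValueError("pathlength must be positive")

    def epsilon(self, analyte: str, wavelength_nm: float) -> float:
        key = (analyte, float(wavelength_nm))
        if key not in self.coefficients:
            raise KeyError(
                f"no extinction coefficient for {analyte!r} at {wavelength_nm:g} nm; "
                f"known: {sorted(self.coefficients)}"
            )
        return self.coefficients[key]

    def to_yaml(self, path) -> None:
        data = {
            "pathlength_cm": self.pathlength_cm,
            "coefficients": [
                {"analyte": a, "wavelength_nm": w, "epsilon_per_M_cm": e}
                for (a, w), e in sorted(self.coefficients.items())
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExtinctionTable":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        coeffs = {
            (row["analyte"], float(row["wavelength_nm"])): float(row["epsilon_per_M_cm"])
            for row in data["coefficients"]
        }
        return cls(coefficients=coeffs, pathlength_cm=float(data.get("pathlength_cm", 1.0)))


#: assay coefficients: coupled reaction at 340 nm per coumarin substrate,
#: NADPH alone at 365 nm
DEFAULT_EXTINCTIONS = ExtinctionTable(
    coefficients={
        ("7-hydroxycoumarin", 340.0): 5580.0,
        ("6-hydroxycoumarin", 340.0): 4780.0,
        ("6-methylcoumarin", 340.0): 4440.0,
        ("6,7-dihydroxycoumarin", 340.0): 8500.0,
        ("coumarin", 340.0): 3690.0,
        ("NADPH", 365.0): 3500.0,
    }
)


@dataclass
class AbsorbanceTrace:
    """A single absorbance time course at one wavelength."""

    time_s: np.ndarray
    absorbance: np.ndarray
    wavelength_nm: float
    analyte: str = "NADPH"
    replicate: int | str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.time_s.shape != self.absorbance.shape:
            raise ValueError("time and absorbance must have equal length")
        if self.time_s.size and np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance must be finite")

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.time_s, "absorbance": self.absorbance}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, wavelength_nm: float, analyte: str = "NADPH") -> "AbsorbanceTrace":
        df = pd.read_csv(path)
        return cls(
            time_s=df["time_s"].to_numpy(),
            absorbance=df["absorbance"].to_numpy(),
            wavelength_nm=wavelength_nm,
            analyte=analyte,
        )


def absorbance_to_concentration(
    trace: AbsorbanceTrace,
    table: ExtinctionTable = DEFAULT_EXTINCTIONS,
    analyte: str | None = None,
) -> np.ndarray:
    """Beer–Lambert conversion of a trace to concentration in µM.

    c = A / (ε·l), with ε in M^-1 cm^-1 and l in cm, scaled to µM.
    """
    name = analyte if analyte is not None else trace.analyte
    eps = table.epsilon(name, trace.wavelength_nm)
    conc_M = trace.absorbance / (eps * table.pathlength_cm)
    return conc_M * 1e6


def initial_rate(
    time_s,
    conc_uM,
    max_conversion: float = 0.05,
    min_points: int = 5,
) -> float:
    """Initial rate (µM/s) from a concentration trace.

    For a depleting analyte the window keeps points where the drop from
    the initial concentration is at most ``max_conversion`` of it; the
    rate is the least-squares slope there, reported as a positive
    magnitude (sign convention: substrate depletion and product
    formation are both positive velocities).  Constant traces give 0.
    A constant baseline offset shifts concentrations but not the slope,
    so the rate is baseline-invariant.
    """
    if max_conversion <= 0:
        raise ValueError("max_conversion must be positive")
    t = np.asarray(time_s, dtype=float)
    c = np.asarray(conc_uM, dtype=float)
    if t.shape != c.shape or t.size < min_points:
        raise ValueError(
            f"trace must have at least {min_points} points with matching time axis"
        )
    c0 = c[0]
    span = abs(c0) if c0 != 0 else np.max(np.abs(c)) or 1.0
    mask = np.abs(c - c0) <= max_conversion * span
    # the window is the initial contiguous run inside the conversion cap
    below = np.flatnonzero(~mask)
    end = below[0] if below.size else t.size
    if end < min_points:
        raise ValueError(
            f"only {end} points inside the {max_conversion:.0%} conversion window; "
            "trace too short or too coarse"
        )
    slope = np.polyfit(t[:end], c[:end], 1)[0]
    return float(abs(slope))


def relative_activity(panel: dict, reference: str = "7-hydroxycoumarin") -> dict:
    """Fold reduction in activity of each substrate relative to the reference.

    ``panel`` maps substrate name to an iterable of replicate velocities;
    folds are computed on replicate means as v_ref / v_substrate.
    Substrates with zero mean velocity are reported as ``NO_ACTIVITY``.
    """
    if not panel:
        raise ValueError("empty activity panel")
    if reference not in panel:
        raise ValueError(f"reference substrate {reference!r} missing from panel")
    means = {name: float(np.mean(np.asarray(v, dtype=float))) for name, v in panel.items()}
    v_ref = means[reference]
    if v_ref <= 0:
        raise ValueError("reference substrate shows no activity")
    out = {}
    for name, v in means.items():
        out[name] = NO_ACTIVITY if v <= 0 else v_ref / v
    return out
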