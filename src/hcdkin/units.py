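"""Unit conventions and conversions.

All internal computation uses millimolar (mM) for concentrations and
seconds for time, so second-order rate constants are mM^-1 s^-1 and
velocities are mM/s.  Quantities cross the package boundary in the units
the bench uses (enzyme in nM, substrates in µM, K_i in mM); every public
field and argument carries its unit in its name, and these helpers are
the only place scale factors appear.
"""

from __future__ import annotations

#: scale factors relative to mM
UM_PER_MM = 1e3
NM_PER_MM = 1e6
MM_PER_M = 1e3


def um_to_mm(x):
    """µM -> mM."""
    return x / UM_PER_MM


def mm_to_um(x):
    """mM -> µM."""
    return x * UM_PER_MM


def nm_to_mm(x):
    """nM -> mM."""
    return x / NM_PER_MM


def mm_to_nm(x):
    """mM -> nM."""
    return x * NM_PER_MM


def m_to_mm(x):
    """M -> mM."""
    return x * MM_PER_M


def mm_to_m(x):
    """mM -> M."""
    return x / MM_PER_M
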