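"""Amyloid-beta peptide panel: sequences, average masses and observed m/z.

The analysis targets N- and C-terminally truncated A-beta species named
``Abeta<start>[pE]-<end>`` where ``start``/``end`` index the canonical
A-beta 1-42 sequence and ``pE`` marks an N-terminal pyroglutamate.  Masses
use the *average* (not monoisotopic) convention because linear-mode TOF at
m/dm = 1000 does not resolve isotopes; observed m/z is the singly protonated
species [M+H]+.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "ABETA42_SEQUENCE",
    "AVERAGE_RESIDUE_MASS",
    "WATER_AVG",
    "PROTON",
    "DEFAULT_PANEL",
    "AbetaPeptide",
    "build_abeta_panel",
    "parse_peptide_name",
]

#: Canonical human A-beta 1-42 sequence (APP 672-713).
ABETA42_SEQUENCE = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA"

#: Average residue (i.e. water-free) masses in Da.
AVERAGE_RESIDUE_MASS = {
    "G": 57.0513, "A": 71.0779, "S": 87.0773, "P": 97.1152, "V": 99.1311,
    "T": 101.1039, "C": 103.1429, "L": 113.1576, "I": 113.1576,
    "N": 114.1026, "D": 115.0874, "Q": 128.1292, "K": 128.1723,
    "E": 129.1140, "M": 131.1961, "H": 137.1393, "F": 147.1739,
    "R": 156.1857, "Y": 163.1733, "W": 186.2099,
}

WATER_AVG = 18.0153
PROTON = 1.008

#: Acquisition window of the linear-mode TOF run (Da).
MZ_RANGE = (1500.0, 6000.0)

#: Peptides quantified across every group comparison in the study.
DEFAULT_PANEL = (
    "Abeta1-40", "Abeta1-42", "Abeta2-42", "Abeta3pE-40", "Abeta3pE-42",
    "Abeta4-40", "Abeta4-42", "Abeta5-42", "Abeta11pE-42",
)

_NAME_RE = re.compile(r"^Abeta(\d+)(pE)?-(\d+)$")


@dataclass(frozen=True)
class AbetaPeptide:
    """One A-beta species with its sequence and mass bookkeeping."""

    name: str
    sequence: str
    n_term_mod: str  # "none" | "pyroglutamate"
    neutral_avg_mass: float
    mz_obs: float

    def __post_init__(self):
        if not (MZ_RANGE[0] <= self.mz_obs <= MZ_RANGE[1]):
            raise ValueError(
                f"{self.name}: m/z {self.mz_obs:.1f} outside the "
                f"{MZ_RANGE[0]:.0f}-{MZ_RANGE[1]:.0f} Da acquisition window"
            )


def parse_peptide_name(name: str) -> tuple[int, int, bool]:
    """Parse ``Abeta<start>[pE]-<end>`` -> (start, end, pyroglutamate)."""
    m = _NAME_RE.match(name)
    if m is None:
        raise ValueError(
            f"cannot parse peptide name {name!r}; expected Abeta<start>[pE]-<end>"
        )
    start, pe, end = int(m.group(1)), m.group(2) is not None, int(m.group(3))
    if not (1 <= start < end <= len(ABETA42_SEQUENCE)):
        raise ValueError(f"{name}: invalid residue range {start}-{end}")
    if end not in (40, 42):
        raise ValueError(f"{name}: C-terminus must be 40 or 42, got {end}")
    return start, end, pe


def _peptide_from_name(name: str) -> AbetaPeptide:
    start, end, pe = parse_peptide_name(name)
    seq = ABETA42_SEQUENCE[start - 1 : end]
    if pe and seq[0] not in ("E", "Q"):
        raise ValueError(
            f"{name}: pyroglutamate requires an E or Q start residue, "
            f"found {seq[0]!r} at position {start}"
        )
    try:
        mass = sum(AVERAGE_RESIDUE_MASS[r] for r in seq) + WATER_AVG
    except KeyError as exc:  # pragma: no cover - canonical sequence is clean
        raise ValueError(f"{name}: unknown residue {exc.args[0]!r}") from exc
    if pe:
        # cyclisation of N-terminal Glu loses water; Gln loses ammonia
        mass -= WATER_AVG if seq[0] == "E" else 17.0305
    return AbetaPeptide(
        name=name,
        sequence=seq,
        n_term_mod="pyroglutamate" if pe else "none",
        neutral_avg_mass=mass,
        mz_obs=mass + PROTON,
    )


def build_abeta_panel(panel_names=DEFAULT_PANEL) -> list[AbetaPeptide]:
    """Build the peptide panel with average masses and [M+H]+ m/z values.

    Raises ``ValueError`` on unparseable names, out-of-range termini,
    pyroglutamate on a non-E/Q start, or an m/z outside 1500-6000 Da.
    """
    return [_peptide_from_name(n) for n in panel_names]
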