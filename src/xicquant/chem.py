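"""Peptide chemistry: elemental compositions, monoisotopic masses and
theoretical isotope envelopes.

Quantification from survey (MS1) scans needs three things per peptide ion:
its monoisotopic m/z, the m/z of the A+1 and A+2 isotopes, and the expected
relative abundances of those three isotopes.  The relative abundances act as
a fingerprint: an extracted chromatographic peak is only accepted when the
observed per-isotope intensities correlate with the theoretical envelope.

The isotope distribution is computed on the aggregated (unit-mass-binned)
level by convolving per-element isotope-abundance vectors; isotopic fine
structure is far below the tolerance at which the envelope is used.
Element masses and abundances are frozen in ``data/elements.tsv`` so
envelopes are bit-reproducible.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np

PROTON_MASS = 1.00727646688  # Da, mass of H+
ISOTOPE_SPACING = 1.0033548350  # Da, 13C - 12C; standard averagine spacing

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(-?\d*)")


def _load_elements() -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """element -> (masses indexed by neutron offset, abundances)."""
    table: dict[str, dict[int, tuple[float, float]]] = {}
    text = resources.files("xicquant.data").joinpath("elements.tsv").read_text()
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("element"):
            continue
        el, off, mass, ab = line.split("\t")
        table.setdefault(el, {})[int(off)] = (float(mass), float(ab))
    out = {}
    for el, rows in table.items():
        n = max(rows) + 1
        masses = np.zeros(n)
        abund = np.zeros(n)
        for off, (m, a) in rows.items():
            masses[off] = m
            abund[off] = a
        out[el] = (masses, abund)
    return out


ELEMENTS: dict[str, tuple[np.ndarray, np.ndarray]] = _load_elements()

# Residue compositions (peptide-bond monomer, i.e. amino acid minus water).
RESIDUE_FORMULAS: dict[str, str] = {
    "G": "C2H3N1O1", "A": "C3H5N1O1", "S": "C3H5N1O2", "P": "C5H7N1O1",
    "V": "C5H9N1O1", "T": "C4H7N1O2", "C": "C3H5N1O1S1", "L": "C6H11N1O1",
    "I": "C6H11N1O1", "N": "C4H6N2O2", "D": "C4H5N1O3", "Q": "C5H8N2O2",
    "K": "C6H12N2O1", "E": "C5H7N1O3", "M": "C5H9N1O1S1", "H": "C6H7N3O1",
    "F": "C9H9N1O1", "R": "C6H12N4O1", "Y": "C9H9N1O2", "W": "C11H10N2O1",
}

WATER_FORMULA = "H2O1"


class ChemError(ValueError):
    pass


@dataclass(frozen=True)
class ElementalComposition:
    """Counts per element.  Negative counts are permitted transiently (a
    modification delta may be a loss), but a realised peptide composition
    must be non-negative with C > 0 and N > 0."""

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        clean = {el: int(n) for el, n in self.counts.items() if n != 0}
        for el in clean:
            if el not in ELEMENTS:
                raise ChemError(f"unknown element {el!r}")
        object.__setattr__(self, "counts", clean)

    @classmethod
    def from_formula(cls, formula: str) -> "ElementalComposition":
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(formula):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ChemError(f"cannot parse formula {formula!r}")
            pos = m.end()
            el = m.group(1)
            n = int(m.group(2)) if m.group(2) else 1
            counts[el] = counts.get(el, 0) + n
        if pos != len(formula):
            raise ChemError(f"cannot parse formula {formula!r}")
        return cls(counts)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        counts = dict(self.counts)
        for el, n in other.counts.items():
            counts[el] = counts.get(el, 0) + n
        return ElementalComposition(counts)

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        return self + ElementalComposition({el: -n for el, n in other.counts.items()})

    def __getitem__(self, el: str) -> int:
        return self.counts.get(el, 0)

    @property
    def n_atoms(self) -> int:
        return sum(abs(n) for n in self.counts.values())

    def is_valid_molecule(self) -> bool:
        return all(n >= 0 for n in self.counts.values())

    def formula(self) -> str:
        return "".join(f"{el}{self.counts[el]}" for el in sorted(self.counts))


@dataclass(frozen=True)
class Modification:
    """A named compositional delta restricted to a residue set or terminus.

    ``target`` is a string of residue letters, or ``nt``/``ct`` optionally
    qualified with a residue (``nt:Q``).
    """

    name: str
    target: str
    delta: ElementalComposition

    def applies_to(self, sequence: str, position: int | str) -> bool:
        if self.target.startswith(("nt", "ct")):
            parts = self.target.split(":")
            term = parts[0]
            residue = parts[1] if len(parts) > 1 else None
            if position not in ("nt", "ct") or position != term:
                return False
            res = sequence[0] if term == "nt" else sequence[-1]
            return residue is None or res == residue
        if not isinstance(position, int):
            return False
        return sequence[position - 1] in self.target


def _load_modifications() -> dict[str, Modification]:
    mods = {}
    text = resources.files("xicquant.data").joinpath("modifications.tsv").read_text()
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("name"):
            continue
        name, target, formula = line.split("\t")
        mods[name] = Modification(name, target, ElementalComposition.from_formula(formula))
    return mods


MODIFICATIONS: dict[str, Modification] = _load_modifications()

#: positions are 1-based residue indices, or "nt"/"ct" for the termini
ModList = Iterable[tuple[int | str, Modification]]


def composition_of(sequence: str, modifications: ModList = ()) -> ElementalComposition:
    """Elemental composition of a modified peptide.

    Sum of residue compositions plus one water (the condensed backbone) plus
    every modification delta.  Raises :class:`ChemError` for residues outside
    the 20-letter alphabet or a modification placed on a residue it does not
    target.
    """
    if not sequence:
        raise ChemError("empty sequence")
    comp = ElementalComposition.from_formula(WATER_FORMULA)
    for i, res in enumerate(sequence):
        if res not in RESIDUE_FORMULAS:
            raise ChemError(f"unknown residue {res!r} at position {i + 1}")
        comp = comp + ElementalComposition.from_formula(RESIDUE_FORMULAS[res])
    for pos, mod in modifications:
        if isinstance(pos, int) and not (1 <= pos <= len(sequence)):
            raise ChemError(f"modification position {pos} outside sequence")
        if not mod.applies_to(sequence, pos):
            raise ChemError(
                f"modification {mod.name!r} does not apply at position {pos} "
                f"of {sequence!r}"
            )
        comp = comp + mod.delta
    if not comp.is_valid_molecule():
        raise ChemError(f"negative element count after modifications: {comp.counts}")
    return comp


def monoisotopic_mass(composition: ElementalComposition) -> float:
    """Mass using the lightest isotope of each element, in Da."""
    return float(
        sum(n * ELEMENTS[el][0][0] for el, n in composition.counts.items())
    )


def ion_mz(mass: float, z: int) -> float:
    """m/z of the [M + zH]^z+ ion."""
    if z < 1:
        raise ChemError(f"charge must be >= 1, got {z}")
    return (mass + z * PROTON_MASS) / z


@dataclass(frozen=True)
class IsotopeEnvelope:
    """The first ``n`` isotopes of a peptide ion: m/z values spaced by
    1.00335/z from the monoisotopic peak, and relative abundances rescaled
    so the most abundant isotope equals 1."""

    mz_values: np.ndarray
    relative_abundances: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "mz_values", np.asarray(self.mz_values, float))
        object.__setattr__(
            self, "relative_abundances", np.asarray(self.relative_abundances, float)
        )


def aggregated_isotope_distribution(
    composition: ElementalComposition, n_isotopes: int = 3
) -> np.ndarray:
    """Absolute probabilities of the first ``n_isotopes`` nominal-mass
    isotopologue bins, by iterated convolution of per-element abundance
    vectors (exponentiation by squaring, truncated — truncation is exact
    because lower bins never depend on higher ones)."""
    dist = np.zeros(n_isotopes)
    dist[0] = 1.0
    for el, count in composition.counts.items():
        if count < 0:
            raise ChemError(f"negative count for {el}")
        base = ELEMENTS[el][1][:]
        power = np.zeros(n_isotopes)
        power[0] = 1.0
        b = np.convolve(base, [1.0])[:n_isotopes]
        n = count
        while n:
            if n & 1:
                power = np.convolve(power, b)[:n_isotopes]
            n >>= 1
            if n:
                b = np.convolve(b, b)[:n_isotopes]
        dist = np.convolve(dist, power)[:n_isotopes]
    return dist


def theoretical_envelope(
    composition: ElementalComposition, z: int, n_isotopes: int = 3
) -> IsotopeEnvelope:
    """Theoretical isotope envelope of the [M + zH]^z+ ion.

    Abundances are the aggregated distribution rescaled to max = 1 (the
    downstream Pearson correlation is scale-invariant; the convention only
    matters for serialization).
    """
    if z < 1:
        raise ChemError(f"charge must be >= 1, got {z}")
    dist = aggregated_isotope_distribution(composition, n_isotopes)
    peak = dist.max()
    if peak > 0:
        dist = dist / peak
    mono = ion_mz(monoisotopic_mass(composition), z)
    mzs = mono + np.arange(n_isotopes) * ISOTOPE_SPACING / z
    return IsotopeEnvelope(mzs, dist)


@dataclass(frozen=True)
class PeptideIon:
    """An identified, modified peptide at one charge state with a reference
    retention time — the unit of targeted quantification."""

    sequence: str
    modifications: tuple[tuple[int | str, Modification], ...]
    charge: int
    reference_tR: float  # minutes

    def __post_init__(self):
        composition_of(self.sequence, self.modifications)  # validates
        if self.charge < 1:
            raise ChemError(f"charge must be >= 1, got {self.charge}")

    @property
    def composition(self) -> ElementalComposition:
        return composition_of(self.sequence, self.modifications)

    @property
    def monoisotopic_mass(self) -> float:
        return monoisotopic_mass(self.composition)

    @property
    def mz(self) -> float:
        return ion_mz(self.monoisotopic_mass, self.charge)

    def envelope(self, n_isotopes: int = 3) -> IsotopeEnvelope:
        return theoretical_envelope(self.composition, self.charge, n_isotopes)
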