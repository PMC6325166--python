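"""Exact monoisotopic mass arithmetic for glycerophospholipids.

Everything downstream — precursor m/z prediction, Paternò–Büchi product
masses, diagnostic-ion pairs — reduces to integer element counts and a
five-element monoisotopic mass table (C, H, N, O, P).  Lipid neutral
formulas come from closed-form subclass templates parameterised by the
total acyl-chain carbon count ``c`` and total double-bond count ``D``;
the templates are algebraically equivalent to assembling glycerol, a
phosphate, the subclass headgroup alcohol and the fatty acids with loss
of one water per condensation.

Ion m/z uses the proton mass 1.007276 Da as the charge carrier, which
makes singly protonated/deprotonated ions correct to <1e-4 Da (the
electron mass is thereby accounted for).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "ChemicalFormula",
    "AcylChain",
    "LipidSpecies",
    "Adduct",
    "ADDUCTS",
    "ScanDescriptor",
    "formula_of_species",
    "monoisotopic_mass",
    "precursor_mz",
    "acyl_anion_mz",
    "headgroup_scan",
    "parse_species",
    "nominal_mz",
    "FormulaError",
    "SpeciesError",
    "AdductError",
]

#: IUPAC 2021 monoisotopic masses (Da) of the elements occurring in
#: glycerophospholipids.  Overridable per-call in :func:`monoisotopic_mass`.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
}

#: Mass of the proton charge carrier (Da).
PROTON_MASS = 1.007276


class FormulaError(ValueError):
    """Ill-formed chemical formula or negative element count."""


class SpeciesError(ValueError):
    """Unsupported or inconsistent lipid species definition."""


class AdductError(ValueError):
    """Adduct incompatible with the species' ionization behaviour."""


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ChemicalFormula:
    """Immutable element → count mapping with element-wise arithmetic."""

    counts: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        for element, n in self.counts:
            if n < 0:
                raise FormulaError(f"negative count for {element}: {n}")
        # canonical order (Hill: C, H, then alphabetical), zero counts dropped
        cleaned = {e: n for e, n in self.counts if n > 0}
        ordered = tuple(sorted(cleaned.items(), key=_hill_key))
        object.__setattr__(self, "counts", ordered)

    @classmethod
    def from_dict(cls, counts: Mapping[str, int]) -> "ChemicalFormula":
        return cls(tuple(counts.items()))

    @classmethod
    def from_string(cls, text: str) -> "ChemicalFormula":
        """Parse a plain formula string such as ``"C3H6O"``."""
        pos = 0
        counts: dict[str, int] = {}
        for match in _FORMULA_TOKEN.finditer(text):
            if match.start() != pos:
                raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
            if not match.group(0):
                break
            element, digits = match.group(1), match.group(2)
            counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
            pos = match.end()
        if pos != len(text):
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        return cls.from_dict(counts)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __getitem__(self, element: str) -> int:
        return dict(self.counts).get(element, 0)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.counts)

    def __add__(self, other: "ChemicalFormula") -> "ChemicalFormula":
        merged = self.as_dict()
        for e, n in other.counts:
            merged[e] = merged.get(e, 0) + n
        return ChemicalFormula.from_dict(merged)

    def __sub__(self, other: "ChemicalFormula") -> "ChemicalFormula":
        merged = self.as_dict()
        for e, n in other.counts:
            merged[e] = merged.get(e, 0) - n
            if merged[e] < 0:
                raise FormulaError(
                    f"subtraction yields negative {e} count ({self} - {other})"
                )
        return ChemicalFormula.from_dict(merged)

    def __mul__(self, k: int) -> "ChemicalFormula":
        return ChemicalFormula.from_dict({e: n * k for e, n in self.counts})

    __rmul__ = __mul__

    def __str__(self) -> str:
        return "".join(f"{e}{n if n != 1 else ''}" for e, n in self.counts) or "(empty)"

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)


def _hill_key(item: tuple[str, int]) -> tuple[int, str]:
    order = {"C": 0, "H": 1}
    return (order.get(item[0], 2), item[0])


def monoisotopic_mass(
    formula: ChemicalFormula, table: Mapping[str, float] | None = None
) -> float:
    """Sum of element monoisotopic masses, deterministic to 1e-6 Da."""
    table = MONOISOTOPIC_MASS if table is None else table
    total = 0.0
    for element, n in formula:
        try:
            total += n * table[element]
        except KeyError:
            raise FormulaError(f"element {element!r} not in mass table") from None
    return total


def nominal_mz(mz: float) -> int:
    """Unit-resolution view of an m/z value (round half up)."""
    return int(math.floor(mz + 0.5))


# ---------------------------------------------------------------------------
# named formulas / constants used throughout the diagnostic-ion algebra

F = ChemicalFormula.from_string

ACETONE = F("C3H6O")  # Paternò–Büchi reagent; the signature +58 Da shift
ETHYNE = F("C2H2")  # F_O − F_A spacing
OXYGEN_ATOM = F("O")
PHOSPHOETHANOLAMINE = F("C2H8NO4P")  # PE headgroup neutral loss (141 Da)
ACETATE = F("C2H3O2")
WATER = F("H2O")

PB_MASS_SHIFT = monoisotopic_mass(ACETONE)  # 58.041865
C2H2_MASS = monoisotopic_mass(ETHYNE)  # 26.015650
OXYGEN_MASS = monoisotopic_mass(OXYGEN_ATOM)
PE_HEADGROUP_LOSS_MASS = monoisotopic_mass(PHOSPHOETHANOLAMINE)  # 141.0191


# ---------------------------------------------------------------------------
# acyl chains and species

LINKAGES = ("acyl", "O-alkyl", "O-alkenyl")


@dataclass(frozen=True)
class AcylChain:
    """A fatty acyl (or ether-linked alkyl) chain.

    ``double_bond_positions`` are Δ positions counted from the carboxyl
    carbon; when present the list must be strictly increasing, with each
    position in ``[2, carbons - 1]`` and length equal to ``double_bonds``.
    """

    carbons: int
    double_bonds: int
    positions: tuple[int, ...] | None = None
    linkage: str = "acyl"

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise SpeciesError(f"chain needs >=2 carbons, got {self.carbons}")
        if self.double_bonds < 0:
            raise SpeciesError("negative double-bond count")
        if self.double_bonds > (self.carbons - 2) // 2 + 1:
            raise SpeciesError(
                f"{self.carbons}:{self.double_bonds} exceeds the geometric "
                "double-bond capacity of the chain"
            )
        if self.linkage not in LINKAGES:
            raise SpeciesError(f"unknown linkage {self.linkage!r}")
        if self.positions is not None:
            pos = tuple(self.positions)
            object.__setattr__(self, "positions", pos)
            if len(pos) != self.double_bonds:
                raise SpeciesError(
                    f"{len(pos)} positions declared for {self.double_bonds} bonds"
                )
            if list(pos) != sorted(set(pos)):
                raise SpeciesError(f"positions must be strictly increasing: {pos}")
            for n in pos:
                if not 2 <= n <= self.carbons - 1:
                    raise SpeciesError(
                        f"Δ{n} outside [2, {self.carbons - 1}] for C{self.carbons}"
                    )

    @property
    def is_ether(self) -> bool:
        return self.linkage != "acyl"

    def with_positions(self, positions: tuple[int, ...] | None) -> "AcylChain":
        return AcylChain(self.carbons, self.double_bonds, positions, self.linkage)

    def label(self, with_positions: bool = True) -> str:
        prefix = {"acyl": "", "O-alkyl": "O-", "O-alkenyl": "P-"}[self.linkage]
        base = f"{prefix}{self.carbons}:{self.double_bonds}"
        if with_positions and self.positions:
            base += "(Δ" + ",".join(str(n) for n in self.positions) + ")"
        return base

    def __str__(self) -> str:  # pragma: no cover - display helper
        return self.label()


GP_SUBCLASSES = ("PC", "PE", "PG", "PI", "PA", "PS")
SUBCLASSES = GP_SUBCLASSES + ("FA",)


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid at any of the three identification levels.

    Subclass level carries only total carbons:double-bonds; fatty-acyl
    level has the per-chain split; C=C level adds per-chain Δ positions.
    sn positions are never resolved (the ``_`` separator in names).
    """

    subclass: str
    chains: tuple[AcylChain, ...]
    sn_resolved: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.subclass not in SUBCLASSES:
            raise SpeciesError(f"unsupported subclass {self.subclass!r}")
        chains = tuple(self.chains)
        object.__setattr__(self, "chains", chains)
        expected = 1 if self.subclass == "FA" else 2
        if len(chains) != expected:
            raise SpeciesError(
                f"{self.subclass} requires {expected} chain(s), got {len(chains)}"
            )
        if self.subclass == "FA" and chains[0].is_ether:
            raise SpeciesError("free fatty acids cannot be ether-linked")
        if self.sn_resolved:
            raise SpeciesError("sn positions cannot be resolved by this workflow")

    @property
    def total_carbons(self) -> int:
        return sum(ch.carbons for ch in self.chains)

    @property
    def total_double_bonds(self) -> int:
        return sum(ch.double_bonds for ch in self.chains)

    def name(self, level: str = "cc") -> str:
        """Display name at ``"species"``, ``"chain"`` or ``"cc"`` level."""
        if level == "species":
            return f"{self.subclass} {self.total_carbons}:{self.total_double_bonds}"
        with_pos = level == "cc"
        return f"{self.subclass} " + "_".join(
            ch.label(with_positions=with_pos) for ch in self.chains
        )

    def __str__(self) -> str:
        return self.name()


_CHAIN_RE = re.compile(
    r"^(?P<prefix>O-|P-)?(?P<c>\d+):(?P<d>\d+)(?:\((?P<pos>[^)]*)\))?$"
)


def _parse_chain(text: str) -> AcylChain:
    m = _CHAIN_RE.match(text.strip())
    if not m:
        raise SpeciesError(f"cannot parse chain {text!r}")
    linkage = {"O-": "O-alkyl", "P-": "O-alkenyl", None: "acyl"}[m.group("prefix")]
    positions: tuple[int, ...] | None = None
    if m.group("pos") is not None:
        tokens = [t.strip().lstrip("Δ").lstrip("d") for t in m.group("pos").split(",")]
        positions = tuple(int(t) for t in tokens if t)
    return AcylChain(int(m.group("c")), int(m.group("d")), positions, linkage)


def parse_species(text: str) -> LipidSpecies:
    """Parse shorthand such as ``"PE 16:0_18:1(Δ9,11)"`` or ``"PC O-16:1/16:0"``."""
    parts = text.strip().split(None, 1)
    if len(parts) != 2 or parts[0] not in SUBCLASSES:
        raise SpeciesError(f"cannot parse species {text!r}")
    subclass, rest = parts
    chain_texts = re.split(r"[_/]", rest)
    chains = tuple(_parse_chain(t) for t in chain_texts)
    return LipidSpecies(subclass, chains)


# ---------------------------------------------------------------------------
# formula templates

# closed-form diacyl templates in (c, D) = (total chain carbons, total bonds);
# each O-alkyl / O-alkenyl ether chain modifies the result by -O +2H.
_TEMPLATES = {
    "PC": lambda c, D: {"C": c + 8, "H": 2 * c + 16 - 2 * D, "N": 1, "O": 8, "P": 1},
    "PE": lambda c, D: {"C": c + 5, "H": 2 * c + 10 - 2 * D, "N": 1, "O": 8, "P": 1},
    "PG": lambda c, D: {"C": c + 6, "H": 2 * c + 11 - 2 * D, "O": 10, "P": 1},
    "PI": lambda c, D: {"C": c + 9, "H": 2 * c + 15 - 2 * D, "O": 13, "P": 1},
    "PA": lambda c, D: {"C": c + 3, "H": 2 * c + 5 - 2 * D, "O": 8, "P": 1},
    "PS": lambda c, D: {"C": c + 6, "H": 2 * c + 10 - 2 * D, "N": 1, "O": 10, "P": 1},
    "FA": lambda c, D: {"C": c, "H": 2 * c - 2 * D, "O": 2},
}


def formula_of_species(species: LipidSpecies) -> ChemicalFormula:
    """Neutral molecular formula from the subclass template."""
    c = species.total_carbons
    D = species.total_double_bonds
    counts = dict(_TEMPLATES[species.subclass](c, D))
    n_ether = sum(1 for ch in species.chains if ch.is_ether)
    if n_ether:
        counts["O"] = counts.get("O", 0) - n_ether
        counts["H"] = counts.get("H", 0) + 2 * n_ether
    if min(counts.values()) < 0:
        raise SpeciesError(f"template yields negative counts for {species}")
    return ChemicalFormula.from_dict(counts)


# ---------------------------------------------------------------------------
# adducts and precursor m/z

@dataclass(frozen=True)
class Adduct:
    """Singly charged adduct: ion m/z = neutral mass + ``mass_delta``."""

    name: str
    polarity: str  # "+" or "-"
    mass_delta: float
    charge: int = 1

    def __post_init__(self) -> None:
        if self.polarity not in ("+", "-"):
            raise AdductError(f"polarity must be '+' or '-', got {self.polarity!r}")
        if self.charge != 1:
            raise AdductError("only singly charged adducts are modeled")


ADDUCTS: dict[str, Adduct] = {
    a.name: a
    for a in (
        Adduct("[M+H]+", "+", PROTON_MASS),
        Adduct("[M-H]-", "-", -PROTON_MASS),
        Adduct("[M+CH3COO]-", "-", 59.013304),
        Adduct("[M+NH4]+", "+", 18.033823),
        Adduct("[M+Na]+", "+", 22.989218),
    )
}

# subclass → named adducts it is observed with in this workflow
_ALLOWED_ADDUCTS = {
    "PE": {"[M+H]+", "[M-H]-", "[M+Na]+"},
    "PC": {"[M+H]+", "[M+CH3COO]-", "[M+Na]+"},
    "PG": {"[M-H]-"},
    "PI": {"[M-H]-"},
    "PA": {"[M-H]-"},
    "PS": {"[M-H]-", "[M+H]+"},
    "FA": {"[M-H]-"},
}


def precursor_mz(
    species: LipidSpecies, adduct: Adduct | str, strict: bool = True
) -> float:
    """m/z of the intact-lipid ion under the given adduct."""
    if isinstance(adduct, str):
        adduct = ADDUCTS[adduct]
    if strict and adduct.name in ADDUCTS:
        if adduct.name not in _ALLOWED_ADDUCTS[species.subclass]:
            raise AdductError(
                f"{adduct.name} is not a supported ionization for {species.subclass}"
            )
    return monoisotopic_mass(formula_of_species(species)) + adduct.mass_delta


def acyl_anion_mz(chain: AcylChain) -> float | None:
    """m/z of the fatty-acyl carboxylate anion; ``None`` for ether chains."""
    if chain.is_ether:
        return None
    fa = LipidSpecies("FA", (AcylChain(chain.carbons, chain.double_bonds),))
    return monoisotopic_mass(formula_of_species(fa)) - PROTON_MASS


# ---------------------------------------------------------------------------
# headgroup profiling scan constants

@dataclass(frozen=True)
class ScanDescriptor:
    """A triple-quadrupole profiling scan: NLS neutral mass or PIS fragment m/z."""

    mode: str  # "NLS" or "PIS"
    subclass: str
    polarity: str
    value: float  # neutral-loss mass (NLS) or fragment m/z (PIS)

    @property
    def nominal(self) -> int:
        return nominal_mz(self.value)


def headgroup_scan(subclass: str, polarity: str) -> ScanDescriptor:
    """The subclass-selective profiling scan used in stage 1.

    PE: 141 Da neutral-loss scan (phosphoethanolamine, positive mode);
    PC: precursor-ion scan of phosphocholine m/z 184 (positive); PG and
    PI: negative-mode precursor-ion scans of m/z 153 and 241.
    """
    key = (subclass, polarity)
    if key == ("PE", "+"):
        return ScanDescriptor("NLS", "PE", "+", PE_HEADGROUP_LOSS_MASS)
    if key == ("PC", "+"):
        # protonated phosphocholine C5H15NO4P+
        return ScanDescriptor(
            "PIS", "PC", "+", monoisotopic_mass(F("C5H14NO4P")) + PROTON_MASS
        )
    if key == ("PG", "-"):
        # deprotonated glycerophosphate C3H6O5P-
        return ScanDescriptor(
            "PIS", "PG", "-", monoisotopic_mass(F("C3H7O5P")) - PROTON_MASS
        )
    if key == ("PI", "-"):
        # deprotonated dehydrated inositol phosphate C6H10O8P-
        return ScanDescriptor(
            "PIS", "PI", "-", monoisotopic_mass(F("C6H11O8P")) - PROTON_MASS
        )
    raise SpeciesError(f"no profiling scan defined for {subclass} ({polarity})")
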