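"""In-silico Paternò–Büchi chemistry.

The PB reaction adds acetone (+58.0419 Da) across a C=C.  Collisional
activation of the oxetane product cleaves at the former double-bond
position, producing a pair of diagnostic fragments: an aldehyde-bearing
ion ``F_A`` and an olefin-bearing ion ``F_O`` spaced by exactly one
ethyne unit (26.0157 Da).  For a bond at Δn on a chain of ``C`` carbons
the cleavage discards the methyl-side ``m = C − n`` carbons (with the
``k`` double bonds methyl-side of the cut) and leaves one acetone-derived
oxygen on the charged fragment:

    F_A = basis_mz − mass(C_m H_{2m−2k}) + mass(O) − NL

where the basis is the intact-lipid precursor for PE/PC (NL is the
141.0191 Da phosphoethanolamine loss for PE in positive mode, nothing
for PC) and the fatty-acyl carboxylate anion for PG/PI (the MS3 route)
and free fatty acids.  ``F_O = F_A + 26.0157``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .chem import (
    ADDUCTS,
    C2H2_MASS,
    OXYGEN_MASS,
    PB_MASS_SHIFT,
    PE_HEADGROUP_LOSS_MASS,
    AcylChain,
    Adduct,
    ChemicalFormula,
    LipidSpecies,
    SpeciesError,
    acyl_anion_mz,
    monoisotopic_mass,
    precursor_mz,
)

__all__ = [
    "DiagnosticPair",
    "PBTarget",
    "pb_precursor_mz",
    "diagnostic_pair",
    "diagnostic_pairs_for_set",
    "enumerate_candidate_positions",
    "omega_of",
    "pair_collision_report",
    "default_pb_adduct",
    "SaturatedSpeciesError",
]


class SaturatedSpeciesError(SpeciesError):
    """PB targets/diagnostics requested for a species without C=C."""


#: per-(subclass, polarity) neutral loss applied before diagnostic ions form
NEUTRAL_LOSS: dict[tuple[str, str], float] = {
    ("PE", "+"): PE_HEADGROUP_LOSS_MASS,
    ("PC", "+"): 0.0,
    ("FA", "-"): 0.0,
}

#: subclasses whose diagnostic ions are computed on the fatty-acyl-anion
#: basis (MS3-style second precursor) rather than the intact lipid
ACYL_ANION_BASIS = ("PG", "PI")


def default_pb_adduct(subclass: str) -> Adduct:
    """Adduct used for the PB-MS/MS stage of each subclass."""
    if subclass in ("PE", "PC"):
        return ADDUCTS["[M+H]+"]
    return ADDUCTS["[M-H]-"]


@dataclass(frozen=True)
class DiagnosticPair:
    """Theoretical F_A/F_O pair for one C=C position."""

    chain: AcylChain
    position: int
    positions: tuple[int, ...]  # the full candidate set this position belongs to
    fa_mz: float
    fo_mz: float
    basis: str  # "intact-lipid" | "fatty-acyl-anion"
    neutral_loss: float
    basis_mz: float

    def __post_init__(self) -> None:
        if not (abs(self.fo_mz - self.fa_mz - C2H2_MASS) < 1e-4):
            raise ValueError("F_O - F_A must equal the ethyne mass")
        if self.fa_mz >= self.fo_mz:
            raise ValueError("F_A must lie below F_O")


@dataclass(frozen=True)
class PBTarget:
    """Precursor-list entry for the data-dependent PB-MS/MS run."""

    species: LipidSpecies
    adduct: Adduct
    mz: float
    rt_window: tuple[float, float]
    polarity: str
    basis: str = "intact-lipid"

    def __post_init__(self) -> None:
        base = precursor_mz(self.species, self.adduct, strict=False)
        if abs(self.mz - base - PB_MASS_SHIFT) > 1e-4:
            raise ValueError("PB precursor must sit +58.0419 Da above the precursor")


def pb_precursor_mz(species: LipidSpecies, adduct: Adduct | str | None = None) -> float:
    """m/z of the single-acetone PB product ion (+58.0419 over the precursor)."""
    if species.total_double_bonds < 1:
        raise SaturatedSpeciesError(f"{species.name('chain')} carries no C=C")
    if adduct is None:
        adduct = default_pb_adduct(species.subclass)
    return precursor_mz(species, adduct) + PB_MASS_SHIFT


def _basis(species: LipidSpecies, chain: AcylChain, adduct: Adduct | str | None):
    """(basis name, basis m/z, neutral loss, polarity) for diagnostics."""
    if species.subclass in ACYL_ANION_BASIS:
        base = acyl_anion_mz(chain)
        if base is None:
            raise SpeciesError("ether chains have no fatty-acyl anion basis")
        return "fatty-acyl-anion", base, 0.0, "-"
    if adduct is None:
        adduct = default_pb_adduct(species.subclass)
    elif isinstance(adduct, str):
        adduct = ADDUCTS[adduct]
    nl = NEUTRAL_LOSS.get((species.subclass, adduct.polarity))
    if nl is None:
        raise SpeciesError(
            f"no diagnostic-ion rule for {species.subclass} in {adduct.polarity} mode"
        )
    return "intact-lipid", precursor_mz(species, adduct), nl, adduct.polarity


def diagnostic_pair(
    species: LipidSpecies,
    chain: AcylChain,
    position: int,
    adduct: Adduct | str | None = None,
    positions: Sequence[int] | None = None,
) -> DiagnosticPair:
    """Theoretical F_A/F_O pair for one C=C of ``chain`` within ``species``.

    ``positions`` is the full double-bond set of the candidate structure
    (defaults to the chain's declared positions; a lone ``position`` for
    monounsaturated chains).  It determines ``k``, the number of bonds
    methyl-side of the cleavage.
    """
    if chain not in species.chains:
        raise SpeciesError("chain does not belong to the species")
    if positions is None:
        positions = chain.positions if chain.positions else (position,)
    pos_set = tuple(sorted(set(positions)))
    if position not in pos_set:
        raise SpeciesError(f"Δ{position} not in candidate set {pos_set}")
    if len(pos_set) != chain.double_bonds:
        raise SpeciesError(
            f"candidate set {pos_set} inconsistent with chain "
            f"{chain.carbons}:{chain.double_bonds}"
        )
    if not 2 <= position <= chain.carbons - 2:
        raise SpeciesError(
            f"Δ{position} outside the localizable range [2, {chain.carbons - 2}]"
        )
    m = chain.carbons - position
    k = sum(1 for p in pos_set if p > position)
    basis, base_mz, nl, _pol = _basis(species, chain, adduct)
    lost = ChemicalFormula.from_dict({"C": m, "H": 2 * m - 2 * k})
    fa = base_mz - monoisotopic_mass(lost) + OXYGEN_MASS - nl
    return DiagnosticPair(chain, position, pos_set, fa, fa + C2H2_MASS, basis, nl, base_mz)


def diagnostic_pairs_for_set(
    species: LipidSpecies,
    chain: AcylChain,
    positions: Sequence[int],
    adduct: Adduct | str | None = None,
) -> list[DiagnosticPair]:
    """One pair per position of a candidate double-bond set."""
    return [
        diagnostic_pair(species, chain, n, adduct, positions) for n in positions
    ]


def enumerate_candidate_positions(
    chain: AcylChain, constraint: str = "methylene-interrupted"
) -> list[tuple[int, ...]]:
    """Candidate Δ-position sets for de novo localization.

    Monounsaturated chains get every position in ``[2, C − 2]``.  For
    polyunsaturated chains the default enumerates methylene-interrupted
    sets ``(n, n+3, …)`` — the pattern of essentially all biological
    PUFA — while ``constraint="unconstrained"`` enumerates every d-subset.
    """
    c, d = chain.carbons, chain.double_bonds
    if d == 0:
        return []
    if d == 1:
        return [(n,) for n in range(2, c - 1)]
    if constraint == "methylene-interrupted":
        out = []
        n = 2
        while n + 3 * (d - 1) <= c - 2:
            out.append(tuple(n + 3 * i for i in range(d)))
            n += 1
        return out
    if constraint == "unconstrained":
        return [tuple(s) for s in itertools.combinations(range(2, c - 1), d)]
    raise ValueError(f"unknown constraint {constraint!r}")


def omega_of(
    position: int, chain: AcylChain, positions: Sequence[int] | None = None
) -> int:
    """ω number: chain length minus the last bond of the set containing n."""
    if positions is None:
        positions = chain.positions if chain.positions else (position,)
    if position not in positions:
        raise SpeciesError(f"Δ{position} not in {tuple(positions)}")
    return chain.carbons - max(positions)


def pair_collision_report(
    species: LipidSpecies,
    adduct: Adduct | str | None = None,
    tolerance: float = 0.3,
    constraint: str = "methylene-interrupted",
) -> list[dict]:
    """Theoretical ion collisions among candidate diagnostic pairs.

    Enumerates every candidate position set of every unsaturated chain,
    computes all F_A/F_O ions, and reports each pair of distinct ions
    whose m/z differ by less than ``tolerance`` — the basis for flagging
    or suppressing ambiguous C=C calls.
    """
    ions: list[tuple[AcylChain, tuple[int, ...], int, str, float]] = []
    for chain in species.chains:
        if chain.double_bonds == 0:
            continue
        for pos_set in enumerate_candidate_positions(chain, constraint):
            for pair in diagnostic_pairs_for_set(species, chain, pos_set, adduct):
                ions.append((chain, pos_set, pair.position, "F_A", pair.fa_mz))
                ions.append((chain, pos_set, pair.position, "F_O", pair.fo_mz))
    report = []
    for (a, b) in itertools.combinations(ions, 2):
        if (a[0], a[2], a[3]) == (b[0], b[2], b[3]) and abs(a[4] - b[4]) < 1e-9:
            continue  # the same theoretical ion shared by two candidate sets
        if abs(a[4] - b[4]) < tolerance:
            report.append(
                {
                    "chain_a": a[0].label(False), "set_a": a[1], "position_a": a[2],
                    "ion_a": a[3], "mz_a": a[4],
                    "chain_b": b[0].label(False), "set_b": b[1], "position_b": b[2],
                    "ion_b": b[3], "mz_b": b[4],
                    "delta_mz": abs(a[4] - b[4]),
                }
            )
    return report
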