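"""Subclass profiling, fatty-acyl chain assignment, PB target generation.

Stage 1 reads NLS/PIS pseudo-profiles and annotates peaks on a (total
carbons × total double bonds) species grid.  Stage 2 resolves the chain
split of each annotated species from negative-mode MS/MS via fatty-acyl
carboxylate anions.  The unsaturated survivors become the precursor list
for the data-dependent PB-MS/MS run (+58.0419 Da).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from . import pb
from .chem import (
    ADDUCTS,
    AcylChain,
    Adduct,
    LipidSpecies,
    formula_of_species,
    monoisotopic_mass,
    precursor_mz,
    headgroup_scan,
)
from .spectra import PeakMatch, Spectrum, match_peak

__all__ = [
    "ProfilingConfig",
    "SubclassHit",
    "Composition",
    "ChainAssignment",
    "ChainTarget",
    "profile_subclass",
    "build_chain_targets",
    "assign_chains",
    "build_pb_targets",
]

#: negative-mode adduct used for the chain-analysis run, per subclass
CHAIN_ADDUCT = {
    "PE": "[M-H]-",
    "PC": "[M+CH3COO]-",
    "PG": "[M-H]-",
    "PI": "[M-H]-",
    "FA": "[M-H]-",
}

#: positive-mode profiling adduct (neutral mass is recovered by undoing it)
PROFILE_ADDUCT = {"PE": "[M+H]+", "PC": "[M+H]+", "PG": "[M-H]-", "PI": "[M-H]-"}


@dataclass
class ProfilingConfig:
    """Tunable knobs of stages 1-2.

    RT windows default to the HILIC subclass elution windows; the species
    grid spans total carbons 24-48 (odd values included — odd chains are
    real) and 0-8 double bonds.
    """

    rt_windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "PE": (5.1, 6.5),
            "PC": (13.8, 15.1),
            "PG": (0.0, 5.0),
            "PI": (0.0, 5.0),
            "FA": (0.0, 5.0),
        }
    )
    tolerance_da: float = 0.3
    carbon_range: tuple[int, int] = (24, 48)
    double_bond_range: tuple[int, int] = (0, 8)
    rel_intensity_floor: float = 0.001  # fraction of the profile base peak
    chain_carbon_range: tuple[int, int] = (2, 26)
    dominance_ratio: float = 3.0
    pb_mz_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"PE": (350.0, 1000.0), "PC": (500.0, 1000.0)}
    )
    enabled_subclasses: tuple[str, ...] = ("PE", "PC", "PG", "PI", "FA")


def _bin_of(rel_pct: float) -> str:
    if rel_pct < 1.0:
        return "<1%"
    if rel_pct <= 10.0:
        return "1-10%"
    return ">10%"


@dataclass
class SubclassHit:
    """One annotated (or flagged unannotated) profile peak."""

    mz: float
    rt: float
    subclass: str
    carbons: int | None
    double_bonds: int | None
    intensity: float
    rel_intensity_pct: float = 0.0
    bin: str = "<1%"
    unannotated: bool = False
    sample_id: str | None = None

    @property
    def species(self) -> LipidSpecies | None:
        """Subclass-level species (chain split still unknown)."""
        if self.unannotated:
            return None
        c, d = self.carbons, self.double_bonds
        if self.subclass == "FA":
            return LipidSpecies("FA", (AcylChain(c, d),))
        # placeholder even split carries the totals; chains are resolved later
        c1 = c // 2 if c % 2 == 0 else c // 2 + 1
        d1 = min(d, (c1 - 2) // 2 + 1)
        return LipidSpecies(self.subclass, (AcylChain(c1, d1), AcylChain(c - c1, d - d1)))

    def label(self) -> str:
        if self.unannotated:
            return f"{self.subclass}? m/z {self.mz:.4f}"
        return f"{self.subclass} {self.carbons}:{self.double_bonds}"


@dataclass(frozen=True)
class Composition:
    """A candidate chain pair with its acyl-anion evidence."""

    chains: tuple[AcylChain, AcylChain]
    score: float  # summed matched acyl-anion intensity
    rank: int
    matches: tuple[PeakMatch, PeakMatch]

    def label(self) -> str:
        return "_".join(ch.label(False) for ch in self.chains)


@dataclass
class ChainAssignment:
    """Ranked chain compositions for one subclass hit."""

    hit: SubclassHit
    compositions: list[Composition]
    spectrum_id: str = ""

    @property
    def resolved(self) -> bool:
        return bool(self.compositions)

    def dominant(self, ratio: float = 3.0) -> Composition | None:
        """Top composition if it dominates the runner-up by ``ratio``."""
        if not self.compositions:
            return None
        if len(self.compositions) == 1:
            return self.compositions[0]
        top, second = self.compositions[0], self.compositions[1]
        if second.score <= 0 or top.score / second.score >= ratio:
            return top
        return None

    def species(self, composition: Composition | None = None) -> LipidSpecies:
        comp = composition or self.compositions[0]
        if self.hit.subclass == "FA":
            return LipidSpecies("FA", comp.chains[:1])
        return LipidSpecies(self.hit.subclass, comp.chains)


@dataclass(frozen=True)
class ChainTarget:
    """Negative-mode precursor target for the chain-analysis run."""

    hit: SubclassHit
    adduct: Adduct
    mz: float
    rt_window: tuple[float, float]
    polarity: str = "-"


# ---------------------------------------------------------------------------
# stage 1: subclass profiling

def _species_grid(subclass: str, config: ProfilingConfig) -> list[tuple[int, int, float]]:
    """(carbons, double bonds, neutral mass) for the annotation grid."""
    c_lo, c_hi = config.carbon_range
    d_lo, d_hi = config.double_bond_range
    grid = []
    for c in range(c_lo, c_hi + 1):
        for d in range(d_lo, d_hi + 1):
            c1 = c // 2 + c % 2
            c2 = c - c1
            if c2 < 2:
                continue
            d1 = min(d, (c1 - 2) // 2 + 1)
            if d - d1 > (c2 - 2) // 2 + 1:
                continue
            sp = LipidSpecies(subclass, (AcylChain(c1, d1), AcylChain(c2, d - d1)))
            grid.append((c, d, monoisotopic_mass(formula_of_species(sp))))
    return grid


def profile_subclass(
    spectra: Iterable[Spectrum], subclass: str, config: ProfilingConfig | None = None
) -> list[SubclassHit]:
    """Annotate NLS/PIS profile peaks of one subclass on the species grid.

    Only spectra whose scan mode and polarity match the subclass'
    headgroup scan, and whose RT falls in the configured window, are
    considered.  Peaks with no grid species within tolerance are kept
    with an ``unannotated`` flag.
    """
    config = config or ProfilingConfig()
    descriptor = headgroup_scan(subclass, "+" if subclass in ("PE", "PC") else "-")
    window = config.rt_windows.get(subclass)
    adduct = ADDUCTS[PROFILE_ADDUCT[subclass]]
    grid = _species_grid(subclass, config)
    hits: list[SubclassHit] = []
    for sp in spectra:
        if sp.scan_type != descriptor.mode or sp.polarity != descriptor.polarity:
            continue
        # a profile scan that declares its monitored NLS mass / PIS m/z must
        # declare this subclass' (PIS 153 PG profiles are not PI profiles)
        if sp.scan_value is not None and abs(sp.scan_value - descriptor.value) > 0.5:
            continue
        if window and sp.rt_min is not None and not (
            window[0] <= sp.rt_min <= window[1]
        ):
            continue
        if not len(sp):
            continue
        floor = config.rel_intensity_floor * sp.base_peak_intensity
        for mz, inten in zip(sp.mz, sp.intensity):
            if inten < floor:
                continue
            neutral = float(mz) - adduct.mass_delta
            best = min(grid, key=lambda g: abs(g[2] - neutral))
            if abs(best[2] - neutral) <= config.tolerance_da:
                hits.append(
                    SubclassHit(
                        float(mz), sp.rt_min or 0.0, subclass, best[0], best[1],
                        float(inten), sample_id=sp.sample_id,
                    )
                )
            else:
                hits.append(
                    SubclassHit(
                        float(mz), sp.rt_min or 0.0, subclass, None, None,
                        float(inten), unannotated=True, sample_id=sp.sample_id,
                    )
                )
    annotated = [h for h in hits if not h.unannotated]
    if annotated:
        base = max(h.intensity for h in annotated)
        for h in annotated:
            h.rel_intensity_pct = 100.0 * h.intensity / base
            h.bin = _bin_of(h.rel_intensity_pct)
    return hits


# ---------------------------------------------------------------------------
# stage 2: chain analysis

def build_chain_targets(
    hits: Iterable[SubclassHit], config: ProfilingConfig | None = None
) -> list[ChainTarget]:
    """Negative-mode precursor list for the chain-analysis MS/MS run."""
    config = config or ProfilingConfig()
    targets = []
    for hit in hits:
        if hit.unannotated:
            continue
        adduct = ADDUCTS[CHAIN_ADDUCT[hit.subclass]]
        neutral = monoisotopic_mass(formula_of_species(hit.species))
        targets.append(
            ChainTarget(
                hit, adduct, neutral + adduct.mass_delta,
                config.rt_windows.get(hit.subclass, (0.0, 20.0)),
            )
        )
    return targets


def _chain_pairs(c: int, d: int, config: ProfilingConfig):
    lo, hi = config.chain_carbon_range
    for c1 in range(lo, c // 2 + 1):
        c2 = c - c1
        if c2 > hi:
            continue
        for d1 in range(0, d + 1):
            d2 = d - d1
            if d1 > (c1 - 2) // 2 + 1 or d2 > (c2 - 2) // 2 + 1:
                continue
            if c1 == c2 and d1 > d2:
                continue  # symmetric duplicate
            yield AcylChain(c1, d1), AcylChain(c2, d2)


def assign_chains(
    spectrum: Spectrum, hit: SubclassHit, config: ProfilingConfig | None = None
) -> ChainAssignment:
    """Resolve the chain split of a hit from its negative-mode MS/MS.

    Every chain pair summing to the hit's totals is scored by the summed
    intensity of its two matched fatty-acyl anions; both anions must be
    present.  Compositions are ranked by score; an empty list marks the
    hit "chains unresolved" and excludes it from the C=C stage.
    """
    config = config or ProfilingConfig()
    adduct = ADDUCTS[CHAIN_ADDUCT[hit.subclass]]
    neutral = monoisotopic_mass(formula_of_species(hit.species))
    target = neutral + adduct.mass_delta
    if spectrum.precursor_mz is None or abs(spectrum.precursor_mz - target) > config.tolerance_da:
        raise ValueError(
            f"spectrum precursor {spectrum.precursor_mz} does not match "
            f"{hit.label()} target {target:.4f}"
        )
    scored = []
    if hit.subclass == "FA":
        chain = AcylChain(hit.carbons, hit.double_bonds)
        fa = LipidSpecies("FA", (chain,))
        m = match_peak(spectrum, precursor_mz(fa, adduct), config.tolerance_da)
        if m:
            scored.append(((chain, chain), m.intensity, (m, m)))
    else:
        from .chem import acyl_anion_mz

        for ch1, ch2 in _chain_pairs(hit.carbons, hit.double_bonds, config):
            m1 = match_peak(spectrum, acyl_anion_mz(ch1), config.tolerance_da)
            m2 = match_peak(spectrum, acyl_anion_mz(ch2), config.tolerance_da)
            if m1 is None or m2 is None:
                continue
            scored.append(((ch1, ch2), m1.intensity + m2.intensity, (m1, m2)))
    scored.sort(key=lambda t: -t[1])
    compositions = [
        Composition(chains, score, rank + 1, matches)
        for rank, (chains, score, matches) in enumerate(scored)
    ]
    return ChainAssignment(hit, compositions, spectrum.scan_id)


# ---------------------------------------------------------------------------
# PB target list

def build_pb_targets(
    assignments: Iterable[ChainAssignment], config: ProfilingConfig | None = None
) -> list[pb.PBTarget]:
    """PB-MS/MS precursor list: one +58.0419 Da target per unsaturated hit.

    Saturated species never enter the list; configured m/z range filters
    (PE 350-1000, PC 500-1000 by default) are applied.
    """
    config = config or ProfilingConfig()
    targets: list[pb.PBTarget] = []
    for assignment in assignments:
        if not assignment.resolved:
            continue
        comp = assignment.dominant(config.dominance_ratio) or assignment.compositions[0]
        species = assignment.species(comp)
        if species.total_double_bonds < 1:
            continue
        adduct = pb.default_pb_adduct(species.subclass)
        mz = pb.pb_precursor_mz(species, adduct)
        mz_range = config.pb_mz_ranges.get(species.subclass)
        if mz_range and not (mz_range[0] <= mz <= mz_range[1]):
            continue
        basis = (
            "fatty-acyl-anion"
            if species.subclass in pb.ACYL_ANION_BASIS
            else "intact-lipid"
        )
        targets.append(
            pb.PBTarget(
                species, adduct, mz,
                config.rt_windows.get(species.subclass, (0.0, 20.0)),
                adduct.polarity, basis,
            )
        )
    return targets
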