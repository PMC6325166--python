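"""De novo C=C localization from PB-MS/MS spectra and isomer quantitation.

A candidate double-bond position (or methylene-interrupted position set,
for polyunsaturated chains) is accepted only when *both* of its
diagnostic ions F_A and F_O are found, each with adequate signal-to-
noise, at similar intensities.  Surviving single-bond candidates are
coexisting C=C location isomers; their relative amount is read directly
off the summed diagnostic-ion intensities, e.g. for the Δ9/Δ11 pair of
an 18:1 chain::

    R = (I_FA(Δ9) + I_FO(Δ9)) / (I_FA(Δ11) + I_FO(Δ11))
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from . import pb
from .chem import AcylChain, LipidSpecies
from .profiling import ChainAssignment, Composition
from .spectra import PeakMatch, Spectrum, match_peak

__all__ = [
    "LocalizationConfig",
    "PairEvidence",
    "CCAssignment",
    "IsomerRatio",
    "assign_cc",
    "isomer_ratio",
    "annotate_omega",
]


@dataclass
class LocalizationConfig:
    """Acceptance thresholds of the C=C caller.

    ``snr_min``: both diagnostic ions must exceed this S/N.
    ``intensity_ratio_limit`` r: F_A and F_O must agree within [1/r, r]
    (the pair is expected "at similar ion intensities").
    ``low_confidence_fraction``: surviving isomers whose summed evidence
    falls below this fraction of the strongest isomer are reported but
    flagged low-confidence (unusual structures remain possible).
    """

    tolerance_da: float = 0.3
    snr_min: float = 3.0
    intensity_ratio_limit: float = 5.0
    constraint: str = "methylene-interrupted"
    low_confidence_fraction: float = 0.05
    dominance_ratio: float = 3.0


@dataclass(frozen=True)
class PairEvidence:
    """Matched F_A/F_O evidence for one position of a candidate set."""

    position: int
    pair: pb.DiagnosticPair
    fa_match: PeakMatch
    fo_match: PeakMatch

    @property
    def intensity(self) -> float:
        return self.fa_match.intensity + self.fo_match.intensity


@dataclass
class CCAssignment:
    """One C=C call (a full position set) for one chain of a species.

    ``positions is None`` marks the chain unassigned (no candidate
    survived the pair-completeness / S/N / similarity rules).
    """

    species: LipidSpecies
    chain: AcylChain
    positions: tuple[int, ...] | None
    evidence: tuple[PairEvidence, ...] = ()
    flags: frozenset[str] = frozenset()
    spectrum_id: str = ""

    @property
    def assigned(self) -> bool:
        return self.positions is not None

    @property
    def intensity(self) -> float:
        return sum(ev.intensity for ev in self.evidence)

    @property
    def omega(self) -> int | None:
        if not self.positions:
            return None
        return self.chain.carbons - max(self.positions)

    def label(self) -> str:
        if not self.assigned:
            return f"{self.species.name('chain')} [{self.chain.label(False)} unassigned]"
        chain_cc = self.chain.with_positions(self.positions)
        chains = tuple(
            chain_cc if ch == self.chain else ch for ch in self.species.chains
        )
        return LipidSpecies(self.species.subclass, chains).name("cc")


def _pair_ok(ev: PairEvidence, config: LocalizationConfig) -> bool:
    if ev.fa_match.snr < config.snr_min or ev.fo_match.snr < config.snr_min:
        return False
    r = config.intensity_ratio_limit
    fa, fo = ev.fa_match.intensity, ev.fo_match.intensity
    if fa <= 0 or fo <= 0:
        return False
    return 1.0 / r <= fa / fo <= r


def _match_set(
    spectrum: Spectrum,
    species: LipidSpecies,
    chain: AcylChain,
    pos_set: tuple[int, ...],
    config: LocalizationConfig,
) -> tuple[PairEvidence, ...] | None:
    """Evidence for a candidate set, or None unless every pair survives."""
    evidence = []
    for pair in pb.diagnostic_pairs_for_set(species, chain, pos_set):
        fa = match_peak(spectrum, pair.fa_mz, config.tolerance_da)
        fo = match_peak(spectrum, pair.fo_mz, config.tolerance_da)
        if fa is None or fo is None:
            return None
        ev = PairEvidence(pair.position, pair, fa, fo)
        if not _pair_ok(ev, config):
            return None
        evidence.append(ev)
    return tuple(evidence)


def _theoretical_ions(
    species: LipidSpecies, chain: AcylChain, pos_set: tuple[int, ...]
) -> list[float]:
    out = []
    for pair in pb.diagnostic_pairs_for_set(species, chain, pos_set):
        out.extend((pair.fa_mz, pair.fo_mz))
    return out


def assign_cc(
    spectrum: Spectrum,
    assignment: ChainAssignment,
    config: LocalizationConfig | None = None,
) -> list[CCAssignment]:
    """Call C=C positions for every unsaturated chain of a hit.

    The dominant composition's chains are localized directly.  Chains of
    minor compositions are attempted only when their diagnostic ions are
    collision-free against the dominant composition's ions; otherwise
    the chain is not reported (flag ``minor-collision``).
    """
    config = config or LocalizationConfig()
    comp = assignment.dominant(config.dominance_ratio) or (
        assignment.compositions[0] if assignment.resolved else None
    )
    if comp is None:
        return []
    target = pb.pb_precursor_mz(assignment.species(comp))
    if spectrum.precursor_mz is None or abs(spectrum.precursor_mz - target) > max(
        config.tolerance_da, 0.35
    ):
        raise ValueError(
            f"spectrum precursor {spectrum.precursor_mz} does not match the "
            f"PB target {target:.4f} of {assignment.hit.label()}"
        )
    results: list[CCAssignment] = []
    dominant_ions: list[float] = []
    ranked = sorted(assignment.compositions, key=lambda cmp_: cmp_.rank)
    for composition in ranked:
        is_dominant = composition is comp
        if not is_dominant and composition.rank > 2:
            continue  # only the dominant and first minor composition are attempted
        species = assignment.species(composition)
        for chain in _unique_chains(species):
            if chain.double_bonds == 0:
                continue
            if chain.is_ether:
                results.append(
                    CCAssignment(species, chain, None,
                                 flags=frozenset({"ether-not-localized"}),
                                 spectrum_id=spectrum.scan_id)
                )
                continue
            calls = _localize_chain(
                spectrum, species, chain, config, is_dominant, dominant_ions
            )
            results.extend(calls)
            if is_dominant:
                for call in calls:
                    if call.positions:
                        dominant_ions.extend(
                            _theoretical_ions(species, chain, call.positions)
                        )
    return results


def _unique_chains(species: LipidSpecies) -> list[AcylChain]:
    seen: list[AcylChain] = []
    for ch in species.chains:
        if ch not in seen:
            seen.append(ch)
    return seen


def _localize_chain(
    spectrum: Spectrum,
    species: LipidSpecies,
    chain: AcylChain,
    config: LocalizationConfig,
    is_dominant: bool,
    dominant_ions: list[float],
) -> list[CCAssignment]:
    candidates = pb.enumerate_candidate_positions(chain, config.constraint)
    surviving: list[tuple[tuple[int, ...], tuple[PairEvidence, ...]]] = []
    for pos_set in candidates:
        evidence = _match_set(spectrum, species, chain, pos_set, config)
        if evidence is None:
            continue
        if not is_dominant and dominant_ions:
            ions = _theoretical_ions(species, chain, pos_set)
            if any(
                abs(mz - dmz) < config.tolerance_da
                for mz in ions
                for dmz in dominant_ions
            ):
                return [
                    CCAssignment(
                        species, chain, None,
                        flags=frozenset({"minor-collision", "not-reported"}),
                        spectrum_id=spectrum.scan_id,
                    )
                ]
        surviving.append((pos_set, evidence))
    if not surviving:
        return [CCAssignment(species, chain, None, spectrum_id=spectrum.scan_id)]
    # all surviving candidates are reported, strongest first: for d = 1 they
    # are coexisting location isomers (the Δ9 + Δ11 logic); for d > 1 the
    # best set is the primary call and the rest coexisting PUFA isomers
    # (e.g. ω-3/ω-6) or low-confidence alternatives
    surviving.sort(key=lambda t: -sum(ev.intensity for ev in t[1]))
    top = sum(ev.intensity for ev in surviving[0][1])
    out = []
    for pos_set, evidence in surviving:
        total = sum(ev.intensity for ev in evidence)
        flags = {"pair-complete", "snr-ok"}
        if total < config.low_confidence_fraction * top:
            flags.add("low-confidence")
        out.append(
            CCAssignment(
                species, chain, pos_set, evidence, frozenset(flags),
                spectrum.scan_id,
            )
        )
    return out


# ---------------------------------------------------------------------------
# isomer relative quantitation

@dataclass
class IsomerRatio:
    """Relative amount of isomer A over isomer B (A = lower Δ set)."""

    lipid: str
    chain: str
    positions_a: tuple[int, ...]
    positions_b: tuple[int, ...]
    replicate_ratios: tuple[float, ...]
    ratio: float | None
    sd: float | None
    rsd_pct: float | None
    undefined: bool = False

    def inverted(self) -> "IsomerRatio":
        ratios = tuple(1.0 / r for r in self.replicate_ratios)
        mean = statistics.fmean(ratios) if ratios else None
        sd = statistics.stdev(ratios) if len(ratios) > 1 else (0.0 if ratios else None)
        return IsomerRatio(
            self.lipid, self.chain, self.positions_b, self.positions_a,
            ratios, mean,
            sd, (100.0 * sd / mean) if ratios and mean else None, self.undefined,
        )


def isomer_ratio(
    replicates: Sequence[Sequence[CCAssignment]] | Sequence[CCAssignment],
    positions_a: tuple[int, ...] | None = None,
    positions_b: tuple[int, ...] | None = None,
) -> IsomerRatio | None:
    """Diagnostic-ion intensity ratio between two coexisting isomers.

    ``replicates`` is a list of per-replicate assignment lists (a flat
    list of assignments is treated as a single replicate).  By default
    the two most abundant isomer position sets are compared, with isomer
    A the lower-Δ set.  Collision-flagged assignments never contribute.
    """
    if replicates and isinstance(replicates[0], CCAssignment):
        replicates = [replicates]  # type: ignore[list-item]
    usable = [
        [
            a
            for a in rep
            if a.assigned and not ({"minor-collision", "not-reported"} & a.flags)
        ]
        for rep in replicates
    ]
    flat = [a for rep in usable for a in rep]
    if not flat:
        return None
    if positions_a is None or positions_b is None:
        totals: dict[tuple[int, ...], float] = {}
        for a in flat:
            totals[a.positions] = totals.get(a.positions, 0.0) + a.intensity
        sets = sorted(totals, key=lambda s: -totals[s])
        if len(sets) < 2:
            return None
        positions_a, positions_b = sorted(sets[:2])
    ratios = []
    undefined = False
    for rep in usable:
        num = sum(a.intensity for a in rep if a.positions == positions_a)
        den = sum(a.intensity for a in rep if a.positions == positions_b)
        if den <= 0 or num <= 0:
            undefined = True
            continue
        ratios.append(num / den)
    a0 = flat[0]
    mean = statistics.fmean(ratios) if ratios else None
    sd = statistics.stdev(ratios) if len(ratios) > 1 else (0.0 if ratios else None)
    rsd = 100.0 * sd / mean if ratios and mean else None
    return IsomerRatio(
        a0.species.name("chain"), a0.chain.label(False),
        positions_a, positions_b, tuple(ratios), mean, sd, rsd, undefined,
    )


def annotate_omega(assignment: CCAssignment) -> str:
    """ω-nomenclature label for a call, e.g. ``"18:2 ω-6"``."""
    if not assignment.assigned:
        raise ValueError("cannot annotate an unassigned chain")
    return f"{assignment.chain.carbons}:{assignment.chain.double_bonds} ω-{assignment.omega}"
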