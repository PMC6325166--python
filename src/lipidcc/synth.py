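"""Seeded ground-truth lipidomes and simulated scan layers.

The generator emulates the three data layers the pipeline consumes:

* NLS/PIS subclass pseudo-profiles (peaks ∝ species abundance),
* negative-mode chain-analysis MS/MS (fatty-acyl anions ∝ composition),
* positive/negative PB-MS/MS spectra whose F_A/F_O pair intensities are
  proportional to abundance × PB conversion yield × isomer mixing ratio.

Defaults mirror the study conditions: PB yield 20–30% (0.25), single-
acetone addition fraction ≥ 0.9 (0.92, the remainder appearing as a
double-addition ion +116.08 Da above the precursor), m/z jitter and
multiplicative intensity noise at unit-resolution QTRAP scale, and a
"bovine-liver-like" template that includes the C18:1 Δ9/Δ11 duplex, the
odd-chain PUFA species PE 17:0_22:4 and the PE 39:4 / PC 36:4 isobaric
pair that only retention time and scan type can separate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import pb
from .chem import (
    ADDUCTS,
    PB_MASS_SHIFT,
    AcylChain,
    LipidSpecies,
    acyl_anion_mz,
    formula_of_species,
    headgroup_scan,
    monoisotopic_mass,
    parse_species,
    precursor_mz,
)
from .profiling import CHAIN_ADDUCT, PROFILE_ADDUCT, ProfilingConfig
from .spectra import Spectrum
from .stats import SampleRatioTable

__all__ = [
    "IsomerComponent",
    "TruthSpecies",
    "SimulationParams",
    "GroundTruth",
    "generate_lipidome",
    "simulate_run",
    "simulate_cohort",
]

DOUBLE_PB_SHIFT = 2 * PB_MASS_SHIFT  # +116.0837 over the unmodified precursor


@dataclass(frozen=True)
class IsomerComponent:
    """One C=C location isomer of a chain with its mixing weight."""

    positions: tuple[int, ...]
    weight: float

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("isomer mixing weight must be positive")


@dataclass
class TruthSpecies:
    """A ground-truth lipid: chains, per-chain isomer mixtures, abundance, RT."""

    species: LipidSpecies  # chains without positions (fatty-acyl level)
    chain_isomers: dict[int, tuple[IsomerComponent, ...]]  # chain index → mixture
    abundance: float
    rt: float

    def __post_init__(self) -> None:
        for idx, components in self.chain_isomers.items():
            chain = self.species.chains[idx]
            if chain.double_bonds == 0:
                raise ValueError(
                    f"isomer mixture declared for saturated chain {chain.label(False)}"
                )
            for comp in components:
                chain.with_positions(comp.positions)  # validates bounds/length


@dataclass
class SimulationParams:
    """Knobs of the scan simulator; defaults are the study conditions."""

    pb_yield: float = 0.25  # PB conversion, within the 20-30% envelope
    single_addition_fraction: float = 0.92  # >= 0.9 single-acetone products
    mz_jitter_sd: float = 0.02  # Da, unit-resolution QTRAP mass accuracy
    intensity_cv: float = 0.05  # multiplicative (lognormal) noise
    background_density: float = 0.01  # background peaks per Da of scan range
    background_rel_intensity: float = 0.002  # vs the layer base peak
    rt_jitter_sd: float = 0.1  # min
    base_intensity: float = 1.0e6

    def __post_init__(self) -> None:
        if not 0.2 <= self.pb_yield <= 0.3:
            raise ValueError("PB yield outside the modeled 20-30% range")
        if self.single_addition_fraction < 0.9:
            raise ValueError("single-addition fraction must be >= 0.9")

    @classmethod
    def noiseless(cls) -> "SimulationParams":
        """Noise-free limit: every theoretical ion at its exact m/z."""
        return cls(
            mz_jitter_sd=0.0, intensity_cv=0.0, background_density=0.0,
            rt_jitter_sd=0.0,
        )


@dataclass
class GroundTruth:
    species: list[TruthSpecies]
    params: SimulationParams
    seed: int

    def table(self) -> pd.DataFrame:
        rows = []
        for ts in self.species:
            for idx, comps in ts.chain_isomers.items():
                for comp in comps:
                    rows.append(
                        {
                            "lipid": ts.species.name("chain"),
                            "chain_index": idx,
                            "chain": ts.species.chains[idx].label(False),
                            "positions": ",".join(map(str, comp.positions)),
                            "weight": comp.weight,
                            "abundance": ts.abundance,
                            "rt": ts.rt,
                        }
                    )
            if not ts.chain_isomers:
                rows.append(
                    {
                        "lipid": ts.species.name("chain"), "chain_index": -1,
                        "chain": "", "positions": "", "weight": 1.0,
                        "abundance": ts.abundance, "rt": ts.rt,
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# lipidome generation

# canonical isomer mixtures by chain (major first), as observed in mammalian
# tissue: C18:1 Δ9 > Δ11; C16:1 Δ9 > Δ7; C18:2/C20:2 ω-6 > ω-9;
# C18:3/C20:3/C22:5 ω-3 with ω-6; C20:4 and C22:4 essentially single.
_CANONICAL_MIXTURES: dict[tuple[int, int], tuple[tuple[tuple[int, ...], float], ...]] = {
    (18, 1): (((9,), 3.0), ((11,), 1.0)),
    (16, 1): (((9,), 4.0), ((7,), 1.0)),
    (18, 2): (((9, 12), 5.0), ((6, 9), 1.0)),
    (20, 2): (((11, 14), 5.0), ((8, 11), 1.0)),
    (18, 3): (((9, 12, 15), 2.0), ((6, 9, 12), 1.0)),
    (20, 3): (((11, 14, 17), 2.0), ((8, 11, 14), 1.0)),
    (22, 5): (((7, 10, 13, 16, 19), 2.0), ((4, 7, 10, 13, 16), 1.0)),
    (20, 4): (((5, 8, 11, 14), 1.0),),
    (22, 4): (((7, 10, 13, 16), 1.0),),
    (22, 6): (((4, 7, 10, 13, 16, 19), 1.0),),
    (17, 1): (((9,), 1.0),),
    (19, 1): (((9,), 1.0),),
}

_SATURATED_POOL = ((14, 0), (15, 0), (16, 0), (17, 0), (18, 0))
_UNSATURATED_POOL = tuple(_CANONICAL_MIXTURES)


def _mixture_for(chain: AcylChain) -> tuple[IsomerComponent, ...]:
    entry = _CANONICAL_MIXTURES.get((chain.carbons, chain.double_bonds))
    if entry is None:
        # fall back to a single methylene-interrupted set ending ω-6-ish
        last = chain.carbons - 6
        first = last - 3 * (chain.double_bonds - 1)
        if first < 2:
            first = 2
            last = first + 3 * (chain.double_bonds - 1)
        entry = ((tuple(first + 3 * i for i in range(chain.double_bonds)), 1.0),)
    return tuple(IsomerComponent(p, w) for p, w in entry)


def _truth_species(
    rng: np.random.Generator,
    subclass: str,
    chains: tuple[AcylChain, ...],
    rt_windows: dict[str, tuple[float, float]],
    abundance: float | None = None,
) -> TruthSpecies:
    species = LipidSpecies(subclass, chains)
    isomers = {
        i: _mixture_for(ch)
        for i, ch in enumerate(species.chains)
        if ch.double_bonds > 0
    }
    lo, hi = rt_windows.get(subclass, (0.0, 5.0))
    pad = 0.1 * (hi - lo)
    rt = float(rng.uniform(lo + pad, hi - pad))
    if abundance is None:
        abundance = float(np.exp(rng.normal(0.0, 1.0)))
    return TruthSpecies(species, isomers, abundance, rt)


def generate_lipidome(
    n_species: int = 20,
    seed: int = 0,
    params: SimulationParams | None = None,
    template: str = "bovine-liver-like",
    rt_windows: dict[str, tuple[float, float]] | None = None,
) -> GroundTruth:
    """Deterministic ground-truth lipidome of ``n_species`` lipids.

    The ``bovine-liver-like`` template seeds the lipidome with the
    workflow's reference structures (PE 16:0_18:1 with its Δ9/Δ11
    duplex, PE 17:0_22:4, PC 16:0_20:4, FA 18:1) before sampling the
    remainder from the chain pool; with ``n_species >= 20`` it therefore
    always contains an odd-carbon species and the PE 39:4 / PC 36:4
    isobaric pair.
    """
    params = params or SimulationParams()
    rt_windows = rt_windows or ProfilingConfig().rt_windows
    rng = np.random.default_rng(seed)
    out: list[TruthSpecies] = []
    if n_species <= 0:
        return GroundTruth([], params, seed)
    if template == "bovine-liver-like":
        anchors = [
            ("PE", (AcylChain(16, 0), AcylChain(18, 1))),
            ("PE", (AcylChain(17, 0), AcylChain(22, 4))),  # the PE 39:4 isobar
            ("PC", (AcylChain(16, 0), AcylChain(20, 4))),  # the PC 36:4 isobar
            ("PC", (AcylChain(16, 0), AcylChain(18, 1))),
            ("FA", (AcylChain(18, 1),)),
            ("PE", (AcylChain(18, 0), AcylChain(18, 1))),
        ]
        for subclass, chains in anchors[:n_species]:
            out.append(_truth_species(rng, subclass, chains, rt_windows))
    elif template != "random":
        raise ValueError(f"unknown template {template!r}")
    seen = {ts.species.name("chain") for ts in out}
    subclass_pool = ("PE", "PC", "PE", "PC", "PG", "PI")
    guard = 0
    while len(out) < n_species and guard < 50 * n_species:
        guard += 1
        subclass = subclass_pool[int(rng.integers(len(subclass_pool)))]
        sat = _SATURATED_POOL[int(rng.integers(len(_SATURATED_POOL)))]
        uns = _UNSATURATED_POOL[int(rng.integers(len(_UNSATURATED_POOL)))]
        chains = (AcylChain(*sat), AcylChain(*uns))
        candidate = LipidSpecies(subclass, chains)
        if candidate.name("chain") in seen:
            continue
        seen.add(candidate.name("chain"))
        out.append(_truth_species(rng, subclass, chains, rt_windows))
    return GroundTruth(out, params, seed)


# ---------------------------------------------------------------------------
# scan simulation

def _noisy(rng: np.random.Generator, value: float, cv: float) -> float:
    if cv <= 0:
        return value
    sigma = math.sqrt(math.log(1 + cv * cv))
    return value * float(rng.lognormal(-0.5 * sigma * sigma, sigma))


def _jitter(rng: np.random.Generator, mz: float, sd: float) -> float:
    return mz + float(rng.normal(0.0, sd)) if sd > 0 else mz


def _background(
    rng: np.random.Generator,
    params: SimulationParams,
    mz_range: tuple[float, float],
    base: float,
) -> tuple[list[float], list[float]]:
    span = mz_range[1] - mz_range[0]
    n = rng.poisson(params.background_density * span) if params.background_density else 0
    mzs = [float(rng.uniform(*mz_range)) for _ in range(int(n))]
    intens = [
        base * params.background_rel_intensity * float(rng.uniform(0.2, 1.0))
        for _ in range(int(n))
    ]
    return mzs, intens


def _dedupe(mzs: list[float], intens: list[float]) -> tuple[list[float], list[float]]:
    """Sum intensities of coincident centroids (identical m/z)."""
    acc: dict[float, float] = {}
    for m, i in zip(mzs, intens):
        acc[m] = acc.get(m, 0.0) + i
    pairs = sorted(acc.items())
    return [p[0] for p in pairs], [p[1] for p in pairs]


def simulate_run(
    truth: GroundTruth,
    seed: int | None = None,
    sample_id: str = "sim",
) -> dict[str, list[Spectrum]]:
    """Simulate the three scan layers for a ground-truth lipidome.

    Returns ``{"profile": [...], "chains": [...], "pb": [...]}``; write
    each layer with :func:`lipidcc.spectra.write_mgf` to obtain MGF files.
    """
    params = truth.params
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    layers: dict[str, list[Spectrum]] = {"profile": [], "chains": [], "pb": []}

    # --- layer 1: NLS/PIS pseudo-profiles, one per subclass present
    by_subclass: dict[str, list[TruthSpecies]] = {}
    for ts in truth.species:
        by_subclass.setdefault(ts.species.subclass, []).append(ts)
    for subclass, members in sorted(by_subclass.items()):
        if subclass not in PROFILE_ADDUCT:
            continue  # FA has no headgroup profiling scan
        adduct = ADDUCTS[PROFILE_ADDUCT[subclass]]
        descriptor = headgroup_scan(subclass, adduct.polarity)
        scan_type = descriptor.mode
        polarity = adduct.polarity
        mzs, intens = [], []
        for ts in members:
            mz = precursor_mz(ts.species, adduct, strict=False)
            mzs.append(_jitter(rng, mz, params.mz_jitter_sd))
            intens.append(
                _noisy(rng, ts.abundance * params.base_intensity, params.intensity_cv)
            )
        rt = float(np.mean([ts.rt for ts in members]))
        base = max(intens)
        bg_mz, bg_int = _background(rng, params, (min(mzs) - 50, max(mzs) + 50), base)
        mzs, intens = _dedupe(mzs + bg_mz, intens + bg_int)
        layers["profile"].append(
            Spectrum(
                np.array(mzs), np.array(intens),
                scan_id=f"profile_{subclass}", scan_type=scan_type,
                polarity=polarity, rt_min=rt, sample_id=sample_id,
                scan_value=descriptor.value,
            )
        )

    # --- layer 2: negative-mode chain-analysis EPI spectra
    for i, ts in enumerate(truth.species):
        adduct = ADDUCTS[CHAIN_ADDUCT[ts.species.subclass]]
        prec = precursor_mz(ts.species, adduct, strict=False)
        mzs, intens = [], []
        total = ts.abundance * params.base_intensity
        if ts.species.subclass == "FA":
            mzs.append(_jitter(rng, prec, params.mz_jitter_sd))
            intens.append(_noisy(rng, total, params.intensity_cv))
        else:
            split = rng.uniform(0.45, 0.55) if params.intensity_cv > 0 else 0.5
            for frac, chain in zip((split, 1 - split), ts.species.chains):
                anion = acyl_anion_mz(chain)
                if anion is None:
                    continue
                mzs.append(_jitter(rng, anion, params.mz_jitter_sd))
                intens.append(_noisy(rng, total * frac, params.intensity_cv))
        bg_mz, bg_int = _background(rng, params, (100.0, prec + 20.0), max(intens))
        mzs, intens = _dedupe(mzs + bg_mz, intens + bg_int)
        layers["chains"].append(
            Spectrum(
                np.array(mzs), np.array(intens),
                scan_id=f"chain_{i:04d}", scan_type="EPI-MS2", polarity="-",
                precursor_mz=prec,
                rt_min=max(ts.rt + float(rng.normal(0, params.rt_jitter_sd)), 0.0)
                if params.rt_jitter_sd else ts.rt,
                sample_id=sample_id,
            )
        )

    # --- layer 3: PB-MS/MS spectra of unsaturated species
    for i, ts in enumerate(truth.species):
        if ts.species.total_double_bonds < 1:
            continue
        adduct = pb.default_pb_adduct(ts.species.subclass)
        pb_prec = pb.pb_precursor_mz(ts.species, adduct)
        unmodified = precursor_mz(ts.species, adduct, strict=False)
        mzs, intens = [], []
        converted = ts.abundance * params.base_intensity * params.pb_yield
        for idx, components in ts.chain_isomers.items():
            chain = ts.species.chains[idx]
            wsum = sum(c.weight for c in components)
            for comp in components:
                share = converted * comp.weight / wsum
                per_pair = share / (2 * len(comp.positions))
                for pair in pb.diagnostic_pairs_for_set(
                    ts.species, chain, comp.positions, adduct
                ):
                    for ion_mz in (pair.fa_mz, pair.fo_mz):
                        mzs.append(_jitter(rng, ion_mz, params.mz_jitter_sd))
                        intens.append(_noisy(rng, per_pair, params.intensity_cv))
        # residual (unreacted + double-addition) precursor-region ions
        mzs.append(_jitter(rng, pb_prec, params.mz_jitter_sd))
        intens.append(converted * params.single_addition_fraction)
        double_frac = 1.0 - params.single_addition_fraction
        if double_frac > 0:
            mzs.append(_jitter(rng, unmodified + DOUBLE_PB_SHIFT, params.mz_jitter_sd))
            intens.append(converted * double_frac)
        bg_mz, bg_int = _background(rng, params, (100.0, pb_prec + 20.0), max(intens))
        mzs, intens = _dedupe(mzs + bg_mz, intens + bg_int)
        layers["pb"].append(
            Spectrum(
                np.array(mzs), np.array(intens),
                scan_id=f"pb_{i:04d}", scan_type="EPI-PB", polarity=adduct.polarity,
                precursor_mz=pb_prec,
                rt_min=max(ts.rt + float(rng.normal(0, params.rt_jitter_sd)), 0.0)
                if params.rt_jitter_sd else ts.rt,
                sample_id=sample_id,
            )
        )
    return layers


# ---------------------------------------------------------------------------
# cohort simulation for the statistics layer

def simulate_cohort(
    n_per_group: int = 6,
    n_ratio_lipids: int = 19,
    n_subclass_lipids: int = 19,
    seed: int = 0,
    ratio_means: tuple[float, float] = (5.0, 3.7),
    ratio_cv: float = 0.10,
    subclass_means: tuple[float, float] = (0.17, 0.21),
    subclass_cv: float = 0.40,
    technical_cv: float = 0.08,
    n_technical: int = 3,
    group_names: tuple[str, str] = ("control", "case"),
    lipid_spread_cv: float = 0.2,
) -> SampleRatioTable:
    """Simulate a two-group cohort with nested technical repeats.

    Isomer-ratio measurements shift between groups with small biological
    CV (the paper-scale 5.0 → 3.7 contrast at ~10% RSD); subclass-level
    I/I_IS measurements carry ~40% biological CV, reproducing the
    precision contrast between the two measurement kinds.
    """
    if n_per_group < 1:
        raise ValueError("need at least one sample per group")
    rng = np.random.default_rng(seed)

    def lognormal_around(mean: float, cv: float) -> float:
        if cv <= 0:
            return mean
        sigma = math.sqrt(math.log(1 + cv * cv))
        return float(mean * rng.lognormal(-0.5 * sigma * sigma, sigma))

    ratio_cols = [f"ratio_{i:02d}" for i in range(n_ratio_lipids)]
    sub_cols = [f"subclass_{i:02d}" for i in range(n_subclass_lipids)]
    # per-lipid baseline variation across the panel
    ratio_scale = [lognormal_around(1.0, lipid_spread_cv) for _ in ratio_cols]
    sub_scale = [lognormal_around(1.0, lipid_spread_cv) for _ in sub_cols]

    rows, groups, individuals, index = [], [], [], []
    for g, gname in enumerate(group_names):
        for s in range(n_per_group):
            ind = f"{gname}_{s + 1}"
            ind_ratio = [
                lognormal_around(ratio_means[g] * sc, ratio_cv) for sc in ratio_scale
            ]
            ind_sub = [
                lognormal_around(subclass_means[g] * sc, subclass_cv)
                for sc in sub_scale
            ]
            for t in range(n_technical):
                row = [lognormal_around(v, technical_cv) for v in ind_ratio]
                row += [lognormal_around(v, technical_cv) for v in ind_sub]
                rows.append(row)
                groups.append(gname)
                individuals.append(ind)
                index.append(f"{ind}_t{t + 1}")
    data = pd.DataFrame(rows, index=index, columns=ratio_cols + sub_cols)
    kinds = {c: "isomer_ratio" for c in ratio_cols}
    kinds.update({c: "subclass" for c in sub_cols})
    return SampleRatioTable(
        data,
        pd.Series(groups, index=index),
        pd.Series(individuals, index=index),
        kinds,
    )
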