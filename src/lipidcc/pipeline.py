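"""End-to-end orchestration of the three-stage workflow.

profile (NLS/PIS) → chain assignment (negative MS/MS) → PB target list →
C=C localization (PB-MS/MS) → isomer ratios → group statistics.  Each
lipid's failures are isolated: the pipeline continues past unmatched or
unresolvable species and reports per-stage counts at the end.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from . import localize, pb, profiling, spectra
from .localize import CCAssignment, IsomerRatio, LocalizationConfig
from .profiling import ChainAssignment, ChainTarget, ProfilingConfig, SubclassHit

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "make_target_lists"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    """Everything a run needs; echoed verbatim into the outputs."""

    profile_mgf: list[str] = field(default_factory=list)
    chain_mgf: list[str] = field(default_factory=list)
    pb_mgf: list[str] = field(default_factory=list)
    subclasses: list[str] = field(default_factory=lambda: ["PE", "PC", "PG", "PI"])
    profiling: ProfilingConfig = field(default_factory=ProfilingConfig)
    localization: LocalizationConfig = field(default_factory=LocalizationConfig)
    output_dir: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if not (self.profile_mgf or self.chain_mgf or self.pb_mgf):
            raise ConfigError("no input MGF files configured")
        for path in (*self.profile_mgf, *self.chain_mgf, *self.pb_mgf):
            if not Path(path).exists():
                raise ConfigError(f"input file does not exist: {path}")
        if self.localization.snr_min <= 0 or self.localization.intensity_ratio_limit <= 0:
            raise ConfigError("acceptance thresholds must be positive")
        if self.profiling.dominance_ratio <= 0:
            raise ConfigError("dominance ratio must be positive")

    # -- (de)serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        prof = raw.pop("profiling", {})
        loc = raw.pop("localization", {})
        cfg = cls(**raw)
        if prof:
            # YAML round-trips tuples as lists; restore tuple-valued fields
            for key in ("rt_windows", "pb_mz_ranges"):
                if key in prof:
                    prof[key] = {k: tuple(v) for k, v in prof[key].items()}
            for key in ("carbon_range", "double_bond_range", "chain_carbon_range",
                        "enabled_subclasses"):
                if key in prof:
                    prof[key] = tuple(prof[key])
            cfg.profiling = ProfilingConfig(**prof)
        if loc:
            cfg.localization = LocalizationConfig(**loc)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not raw:
            raise ConfigError(f"empty config file: {path}")
        return cls.from_dict(raw)


@dataclass
class PipelineResult:
    hits: list[SubclassHit]
    chain_assignments: list[ChainAssignment]
    pb_targets: list[pb.PBTarget]
    cc_assignments: list[CCAssignment]
    ratios: list[IsomerRatio]
    counts: dict[str, float]
    config: RunConfig

    def identification_table(self) -> pd.DataFrame:
        rows = []
        for a in self.cc_assignments:
            rows.append(
                {
                    "sample": a.spectrum_id,
                    "lipid": a.species.name("chain"),
                    "chain": a.chain.label(False),
                    "positions": ",".join(map(str, a.positions)) if a.positions else "",
                    "omega": a.omega if a.assigned else "",
                    "name": a.label(),
                    "intensity": a.intensity,
                    "flags": ";".join(sorted(a.flags)),
                }
            )
        return pd.DataFrame(rows)

    def ratio_table(self) -> pd.DataFrame:
        rows = []
        for r in self.ratios:
            rows.append(
                {
                    "lipid": r.lipid,
                    "chain": r.chain,
                    "isomer_a": ",".join(map(str, r.positions_a)),
                    "isomer_b": ",".join(map(str, r.positions_b)),
                    "ratio": r.ratio,
                    "sd": r.sd,
                    "rsd_pct": r.rsd_pct,
                    "undefined": r.undefined,
                }
            )
        return pd.DataFrame(rows)


def _match_spectrum(
    spectra_list: Sequence[spectra.Spectrum],
    target_mz: float,
    rt_window: tuple[float, float] | None,
    tolerance: float,
) -> spectra.Spectrum | None:
    """Best precursor match (closest m/z within tolerance and RT window)."""
    best, best_err = None, None
    for sp in spectra_list:
        if sp.precursor_mz is None:
            continue
        err = abs(sp.precursor_mz - target_mz)
        if err > tolerance:
            continue
        if rt_window and sp.rt_min is not None and not (
            rt_window[0] - 0.5 <= sp.rt_min <= rt_window[1] + 0.5
        ):
            continue
        if best_err is None or err < best_err:
            best, best_err = sp, err
    return best


def run_pipeline(
    config: RunConfig,
    profile_spectra: Sequence[spectra.Spectrum] | None = None,
    chain_spectra: Sequence[spectra.Spectrum] | None = None,
    pb_spectra: Sequence[spectra.Spectrum] | None = None,
) -> PipelineResult:
    """Execute the full workflow; spectra may be passed in memory or via files."""
    if profile_spectra is None and chain_spectra is None and pb_spectra is None:
        config.validate()
    profile_spectra = list(profile_spectra or []) or _read_all(config.profile_mgf)
    chain_spectra = list(chain_spectra or []) or _read_all(config.chain_mgf)
    pb_spectra = list(pb_spectra or []) or _read_all(config.pb_mgf)

    pconf, lconf = config.profiling, config.localization

    # stage 1: subclass profiling
    hits: list[SubclassHit] = []
    for subclass in config.subclasses:
        try:
            hits.extend(profiling.profile_subclass(profile_spectra, subclass, pconf))
        except Exception as exc:  # pragma: no cover - per-subclass isolation
            logger.warning("profiling failed for %s: %s", subclass, exc)
    annotated = [h for h in hits if not h.unannotated]

    # stage 2: chain assignment
    assignments: list[ChainAssignment] = []
    if chain_spectra:
        for target in profiling.build_chain_targets(annotated, pconf):
            sp = _match_spectrum(
                chain_spectra, target.mz, target.rt_window, pconf.tolerance_da
            )
            if sp is None:
                logger.info("no chain spectrum for %s", target.hit.label())
                continue
            try:
                assignments.append(profiling.assign_chains(sp, target.hit, pconf))
            except Exception as exc:
                logger.warning("chain assignment failed for %s: %s",
                               target.hit.label(), exc)
    resolved = [a for a in assignments if a.resolved]

    # PB target list
    pb_targets = profiling.build_pb_targets(resolved, pconf)

    # stage 3: C=C localization
    cc: list[CCAssignment] = []
    localizable = 0
    if pb_spectra:
        target_by_assignment = {
            id(a): t
            for t in pb_targets
            for a in resolved
            if a.species(a.dominant(pconf.dominance_ratio) or a.compositions[0])
            .name("chain") == t.species.name("chain")
        }
        for a in resolved:
            t = target_by_assignment.get(id(a))
            if t is None:
                continue
            localizable += 1
            sp = _match_spectrum(pb_spectra, t.mz, t.rt_window, pconf.tolerance_da)
            if sp is None:
                logger.info("no PB spectrum for %s", t.species.name("chain"))
                continue
            try:
                cc.extend(localize.assign_cc(sp, a, lconf))
            except Exception as exc:
                logger.warning("C=C assignment failed for %s: %s",
                               t.species.name("chain"), exc)

    # isomer ratios per (lipid, chain)
    grouped: dict[tuple[str, str], list[CCAssignment]] = {}
    for a in cc:
        grouped.setdefault((a.species.name("chain"), a.chain.label(False)), []).append(a)
    ratios = []
    for (_lipid, _chain), group in sorted(grouped.items()):
        r = localize.isomer_ratio([group])
        if r is not None:
            ratios.append(r)

    assigned_chains = {
        (a.species.name("chain"), a.chain.label(False)) for a in cc if a.assigned
    }
    attempted_chains = {
        (a.species.name("chain"), a.chain.label(False)) for a in cc
    }
    counts = {
        "profile_peaks": len(hits),
        "species_subclass_level": len(annotated),
        "species_chain_level": len(resolved),
        "pb_targets": len(pb_targets),
        "chains_attempted": len(attempted_chains),
        "chains_localized": len(assigned_chains),
        "cc_calls": sum(1 for a in cc if a.assigned),
        "isomer_ratios": len(ratios),
        "pct_localized": (
            100.0 * len(assigned_chains) / len(attempted_chains)
            if attempted_chains
            else 0.0
        ),
    }
    result = PipelineResult(hits, assignments, pb_targets, cc, ratios, counts, config)
    if config.output_dir:
        _write_reports(result, Path(config.output_dir))
    return result


def _read_all(paths: Iterable[str]) -> list[spectra.Spectrum]:
    out: list[spectra.Spectrum] = []
    for path in paths:
        out.extend(spectra.read_mgf(path))
    return out


def _write_reports(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.identification_table().to_csv(outdir / "identifications.csv", index=False)
    result.ratio_table().to_csv(outdir / "isomer_ratios.csv", index=False)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(
            {"counts": result.counts, "config": result.config.to_dict()},
            fh, indent=2, default=str,
        )


def make_target_lists(
    result: PipelineResult, outdir: str | Path, stage: str = "both"
) -> list[Path]:
    """Export tab-delimited instrument precursor lists.

    ``stage``: ``"chains"``, ``"pb"`` or ``"both"``.  Columns are m/z,
    RT window, polarity and a collision-energy placeholder, one row per
    precursor, importable as an instrument inclusion list.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    if stage in ("chains", "both"):
        rows = [
            {
                "mz": f"{t.mz:.4f}",
                "rt_start_min": t.rt_window[0],
                "rt_end_min": t.rt_window[1],
                "polarity": t.polarity,
                "collision_energy": "",
                "name": t.hit.label(),
            }
            for t in profiling.build_chain_targets(
                [h for h in result.hits if not h.unannotated], result.config.profiling
            )
        ]
        path = outdir / "chain_targets.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        written.append(path)
    if stage in ("pb", "both"):
        if not result.pb_targets:
            logger.warning("PB target list is empty (no unsaturated species)")
        rows = [
            {
                "mz": f"{t.mz:.4f}",
                "rt_start_min": t.rt_window[0],
                "rt_end_min": t.rt_window[1],
                "polarity": t.polarity,
                "collision_energy": "",
                "name": t.species.name("chain"),
                "basis": t.basis,
            }
            for t in result.pb_targets
        ]
        path = outdir / "pb_targets.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        written.append(path)
    return written
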