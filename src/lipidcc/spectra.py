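"""Centroided spectrum container, MGF input/output, tolerance peak matching.

MGF blocks are read and written through :mod:`pyteomics.mgf`.  Scan
metadata beyond the MGF standard (scan type, polarity, sample id) rides
in the TITLE line as ``key=value`` tokens, e.g.::

    TITLE=id=pb_0003 scan_type=EPI-PB polarity=+ sample=liver1

Profiling scans (NLS/PIS) are pseudo-spectra whose "peaks" are
(precursor m/z, summed intensity) pairs accumulated over the subclass
retention-time window; they carry no PEPMASS of their own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from pyteomics import mgf as _mgf

__all__ = [
    "Spectrum",
    "PeakMatch",
    "read_mgf",
    "write_mgf",
    "match_peak",
    "MGFError",
]

logger = logging.getLogger(__name__)

SCAN_TYPES = ("NLS", "PIS", "EPI-MS2", "EPI-PB")
PROFILE_SCAN_TYPES = ("NLS", "PIS")


class MGFError(ValueError):
    """Malformed MGF content."""


@dataclass
class Spectrum:
    """One centroided scan (or NLS/PIS pseudo-profile)."""

    mz: np.ndarray
    intensity: np.ndarray
    scan_id: str = ""
    scan_type: str = "EPI-PB"
    polarity: str = "+"
    precursor_mz: float | None = None
    rt_min: float | None = None
    sample_id: str | None = None
    #: NLS neutral mass or PIS fragment m/z for profile scans (tells a
    #: PIS-153 PG profile apart from a PIS-241 PI profile)
    scan_value: float | None = None

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape:
            raise ValueError("m/z and intensity arrays must be parallel")
        order = np.argsort(mz, kind="stable")
        self.mz = mz[order]
        self.intensity = inten[order]
        if np.any(self.intensity < 0):
            raise ValueError("negative peak intensity")
        if self.rt_min is not None and self.rt_min < 0:
            raise ValueError("negative retention time")
        if self.scan_type not in SCAN_TYPES:
            raise ValueError(f"unknown scan type {self.scan_type!r}")

    def __len__(self) -> int:
        return len(self.mz)

    @property
    def is_profile(self) -> bool:
        return self.scan_type in PROFILE_SCAN_TYPES

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if len(self) else 0.0


@dataclass(frozen=True)
class PeakMatch:
    """An observed peak matched to a theoretical target m/z."""

    target_mz: float
    mz: float
    intensity: float
    error_da: float
    error_ppm: float
    snr: float


def match_peak(
    spectrum: Spectrum,
    target_mz: float,
    tolerance: float = 0.3,
    unit: str = "Da",
) -> PeakMatch | None:
    """Most intense peak within ``tolerance`` of ``target_mz``, or ``None``.

    S/N is estimated as the peak intensity over the median intensity of
    the other peaks in a ±50 Da local window, floored at 1.  The median
    is a noise estimate only when the window actually contains a noise
    population, so it is used only when the window holds at least 10
    other peaks; in sparser spectra the floor of 1 applies.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    window = tolerance if unit == "Da" else target_mz * tolerance * 1e-6
    lo = np.searchsorted(spectrum.mz, target_mz - window, side="left")
    hi = np.searchsorted(spectrum.mz, target_mz + window, side="right")
    if hi <= lo:
        return None
    i = lo + int(np.argmax(spectrum.intensity[lo:hi]))
    mz, inten = float(spectrum.mz[i]), float(spectrum.intensity[i])
    nlo = np.searchsorted(spectrum.mz, mz - 50.0, side="left")
    nhi = np.searchsorted(spectrum.mz, mz + 50.0, side="right")
    others = np.delete(spectrum.intensity[nlo:nhi], i - nlo)
    noise = float(np.median(others)) if others.size >= 10 else 1.0
    noise = max(noise, 1.0)
    err = mz - target_mz
    return PeakMatch(target_mz, mz, inten, err, err / target_mz * 1e6, inten / noise)


# ---------------------------------------------------------------------------
# MGF

def _parse_title(title: str) -> dict[str, str]:
    out = {}
    for token in title.split():
        if "=" in token:
            key, _, value = token.partition("=")
            out[key] = value
    return out


def _locate_bad_peak_line(path: str | Path) -> int | None:
    """First non-numeric peak line, for actionable parse errors."""
    in_block = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if line == "BEGIN IONS":
                in_block = True
            elif line == "END IONS":
                in_block = False
            elif in_block and line and "=" not in line:
                try:
                    [float(tok) for tok in line.split()[:2]]
                except ValueError:
                    return lineno
    return None


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read all spectra from an MGF file.

    Optional headers that are missing default to polarity ``"+"`` and
    scan type ``"EPI-PB"`` with a logged warning; a missing PEPMASS on a
    product-ion (EPI) block is an error.
    """
    spectra: list[Spectrum] = []
    try:
        with _mgf.MGF(str(path), convert_arrays=1) as reader:
            for block in reader:
                spectra.append(_spectrum_from_block(block, path))
    except MGFError:
        raise
    except Exception as exc:
        lineno = _locate_bad_peak_line(path)
        if lineno is not None:
            raise MGFError(f"{path}: malformed peak line at line {lineno}") from exc
        raise MGFError(f"{path}: {exc}") from exc
    return spectra


def _spectrum_from_block(block: dict, path: str | Path) -> Spectrum:
    params = block.get("params", {})
    title = str(params.get("title", ""))
    meta = _parse_title(title)
    scan_type = meta.get("scan_type")
    if scan_type not in SCAN_TYPES:
        logger.warning("%s: block %r lacks a scan_type; assuming EPI-PB", path, title)
        scan_type = "EPI-PB"
    polarity = meta.get("polarity")
    if polarity not in ("+", "-"):
        charge = params.get("charge")
        if charge:
            polarity = "-" if int(charge[0]) < 0 else "+"
        else:
            logger.warning("%s: block %r lacks a polarity; assuming '+'", path, title)
            polarity = "+"
    precursor = None
    if scan_type not in PROFILE_SCAN_TYPES:
        pepmass = params.get("pepmass")
        if not pepmass or not pepmass[0]:
            raise MGFError(f"{path}: EPI block {title!r} is missing PEPMASS")
        precursor = float(pepmass[0])
    rt = params.get("rtinseconds")
    scan_value = meta.get("scan_value")
    return Spectrum(
        mz=block["m/z array"],
        intensity=block["intensity array"],
        scan_id=meta.get("id", title),
        scan_type=scan_type,
        polarity=polarity,
        precursor_mz=precursor,
        rt_min=float(rt) / 60.0 if rt is not None else None,
        sample_id=meta.get("sample"),
        scan_value=float(scan_value) if scan_value is not None else None,
    )


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF (m/z to 4 decimals, intensity to 1 decimal)."""
    blocks = []
    for sp in spectra:
        title = (
            f"id={sp.scan_id or 'scan'} scan_type={sp.scan_type} "
            f"polarity={sp.polarity}"
        )
        if sp.sample_id:
            title += f" sample={sp.sample_id}"
        if sp.scan_value is not None:
            title += f" scan_value={sp.scan_value:.4f}"
        params: dict = {"title": title, "pepmass": sp.precursor_mz or 0.0}
        if sp.rt_min is not None:
            params["rtinseconds"] = round(sp.rt_min * 60.0, 3)
        blocks.append(
            {
                "m/z array": np.round(sp.mz, 4),
                "intensity array": np.round(sp.intensity, 1),
                "params": params,
            }
        )
    _mgf.write(
        blocks,
        str(path),
        fragment_format="%.4f %.1f",
        write_charges=False,
        file_mode="w",
    )
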