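"""Accurate-mass annotation of MALDI intact-protein peaks.

A proteoform library built from the LC-MS/MS pipeline (neutral monoisotopic
masses with annotations) is matched against peaks of an averaged MALDI
spectrum.  MALDI protein ions carry low charge (z <= 3 typically), so each
peak is tested at charges 1..z_max.  Because isotopically unresolved MALDI
peaks sit at the isotope-envelope apex rather than the monoisotopic
position, an "apex" mode shifts each library mass up by an estimated integer
number of isotope spacings before computing the expected m/z; monoisotopic
mode compares at the monoisotopic position directly.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

from .grouping import ppm_error
from .records import (
    ISOTOPE_SPACING,
    PROTON_MASS,
    AnnotationHit,
    LibraryEntry,
    MaldiPeakList,
)

logger = logging.getLogger(__name__)

#: Isotope-apex offset per Da of protein mass (averagine-like composition):
#: the envelope apex sits roughly APEX_ISOTOPES_PER_DA * M isotopes above
#: the monoisotopic peak.
APEX_ISOTOPES_PER_DA = 5.5e-4

DEFAULT_TOL_PPM = {"monoisotopic": 15.0, "apex": 50.0}


def mz_from_mass(mass: float, z: int) -> float:
    """m/z of the [M + zH]^z+ ion of a neutral mass M."""
    if z < 1:
        raise ValueError("charge must be >= 1")
    return (mass + z * PROTON_MASS) / z


def mass_from_mz(mz: float, z: int) -> float:
    """Neutral mass from an [M + zH]^z+ m/z."""
    if z < 1:
        raise ValueError("charge must be >= 1")
    return mz * z - z * PROTON_MASS


def apex_offset_isotopes(mass: float, isotopes_per_da: float = APEX_ISOTOPES_PER_DA) -> int:
    """Estimated integer isotope offset of the envelope apex above the
    monoisotopic peak for a protein of the given mass (linear heuristic)."""
    return int(round(isotopes_per_da * mass))


def predicted_mz(
    entry: LibraryEntry,
    z: int,
    mode: str = "monoisotopic",
    isotope_spacing_da: float = ISOTOPE_SPACING,
    isotopes_per_da: float = APEX_ISOTOPES_PER_DA,
) -> float:
    """Expected peak m/z for a library proteoform at charge z in either mode."""
    k = 0 if mode == "monoisotopic" else apex_offset_isotopes(entry.mono_mass, isotopes_per_da)
    return mz_from_mass(entry.mono_mass + k * isotope_spacing_da, z)


def annotate_peaks(
    peaks: MaldiPeakList,
    library: Sequence[LibraryEntry],
    z_max: int = 3,
    tol_ppm: Optional[float] = None,
    mode: str = "monoisotopic",
    isotope_spacing_da: float = ISOTOPE_SPACING,
    isotopes_per_da: float = APEX_ISOTOPES_PER_DA,
) -> list[AnnotationHit]:
    """Annotate each peak with its best library match by accurate mass.

    Every (peak, entry, charge <= z_max) combination within ``tol_ppm`` is a
    candidate; the best candidate per peak (smallest |ppm error|) wins.
    Defaults: 15 ppm in monoisotopic mode, 50 ppm in apex mode (the apex
    offset is an estimate).  Deterministic and independent of peak or
    library order.
    """
    if mode not in ("monoisotopic", "apex"):
        raise ValueError(f"unknown mode {mode!r}")
    if tol_ppm is None:
        tol_ppm = DEFAULT_TOL_PPM[mode]
    hits: list[AnnotationHit] = []
    lib = sorted(library, key=lambda e: (e.mono_mass, e.annotation))
    for mz, inten in zip(peaks.mz, peaks.intensity):
        best: Optional[AnnotationHit] = None
        for entry in lib:
            for z in range(1, z_max + 1):
                pred = predicted_mz(entry, z, mode, isotope_spacing_da, isotopes_per_da)
                err = ppm_error(mz, pred)
                if abs(err) <= tol_ppm and (best is None or abs(err) < abs(best.mass_error_ppm)):
                    best = AnnotationHit(
                        peak_mz=mz,
                        peak_intensity=inten,
                        entry=entry,
                        charge=z,
                        mode=mode,
                        mass_error_ppm=err,
                    )
        if best is not None:
            hits.append(best)
    return hits


def library_from_groups(groups) -> list[LibraryEntry]:
    """Build the annotation library from identified feature groups."""
    entries = []
    for g in groups:
        if g.id_annotation is None or g.id_annotation.is_noise:
            continue
        entries.append(
            LibraryEntry(annotation=g.id_annotation.annotation, mono_mass=g.consensus_mass)
        )
    return entries


def write_annotation_report(hits: Sequence[AnnotationHit], path) -> None:
    """TSV report: peak m/z, intensity, annotation, charge, ppm error, mode."""
    with open(path, "w") as fh:
        fh.write("peak_mz\tintensity\tannotation\tmono_mass\tcharge\tppm_error\tmode\n")
        for h in hits:
            fh.write(
                f"{h.peak_mz!r}\t{h.peak_intensity!r}\t{h.entry.annotation}\t"
                f"{h.entry.mono_mass!r}\t{h.charge}\t{h.mass_error_ppm:.3f}\t{h.mode}\n"
            )
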