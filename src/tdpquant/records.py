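"""Core data model for the proteoform quantitation pipeline.

The pipeline reconciles proteoform identifications from two search-engine
dialects (an open-modification engine and a PTM-database engine), aligns and
recalibrates FAIMS-split LC-MS runs, groups deconvoluted intact-mass features
across runs, and attaches identifications to quantifiable feature groups.
These dataclasses are the in-memory currency shared by every stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

#: Mass of a proton in Da, used for m/z <-> neutral-mass conversion.
PROTON_MASS = 1.007276466622

#: Average spacing between isotopologue peaks of an intact protein, Da.
#: Deconvolution off-by-one ("deisotoping") errors displace the reported
#: monoisotopic mass by integer multiples of this spacing.
ISOTOPE_SPACING = 1.00235


@dataclass(frozen=True)
class Modification:
    """One modification on a proteoform.

    Either a named PTM (``name`` set) or a bare mass shift in Da from an
    open-modification search (``mass_shift`` set).  ``position`` is the
    1-based residue index when the engine localized the modification;
    ``localized`` is False for unlocalized or range-only annotations.
    """

    name: Optional[str] = None
    mass_shift: Optional[float] = None
    position: Optional[int] = None
    localized: bool = False

    @property
    def is_unknown_shift(self) -> bool:
        """True when this is a bare mass shift with no named PTM."""
        return self.name is None and self.mass_shift is not None


@dataclass
class PrSMRecord:
    """One proteoform-spectrum match from either search engine.

    Masses are neutral monoisotopic Da; retention time in minutes; ``cv`` is
    the FAIMS compensation voltage in volts (negative, e.g. -40).  The
    ``adjusted_mass`` is the engine's shift-corrected precursor mass when
    exported; ``intensity`` the precursor (feature) intensity when exported.
    """

    run_id: str
    cv: Optional[int]
    scan: int
    rt_min: float
    precursor_mass: float
    charge: int
    evalue: float
    accession: str
    proteoform: str
    first_residue: int
    last_residue: int
    engine: str  # "toppic" | "tdportal"
    adjusted_mass: Optional[float] = None
    gene: Optional[str] = None
    qvalue: Optional[float] = None
    intensity: Optional[float] = None
    modifications: list[Modification] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.precursor_mass <= 0:
            raise ValueError(f"precursor_mass must be > 0, got {self.precursor_mass}")
        if self.rt_min < 0:
            raise ValueError(f"rt_min must be >= 0, got {self.rt_min}")
        if self.first_residue > self.last_residue:
            raise ValueError(
                f"first_residue {self.first_residue} > last_residue {self.last_residue}"
            )
        if self.engine not in ("toppic", "tdportal"):
            raise ValueError(f"unknown engine {self.engine!r}")

    @property
    def has_unknown_shift(self) -> bool:
        """True iff any modification is a bare mass shift without a named PTM."""
        return any(m.is_unknown_shift for m in self.modifications)

    def with_rt(self, rt_min: float) -> "PrSMRecord":
        return replace(self, rt_min=rt_min)

    def with_mass(self, precursor_mass: float) -> "PrSMRecord":
        return replace(self, precursor_mass=precursor_mass)


@dataclass
class MS1Feature:
    """One deconvoluted intact-mass feature from one run/CV.

    ``abundance`` is the integrated feature abundance; ``None`` marks a
    missing value (the on-disk token is "NA", never 0).
    """

    run_id: str
    cv: Optional[int]
    mono_mass: float
    rt_apex: float
    rt_start: float
    rt_end: float
    abundance: Optional[float]
    charge_min: int = 1
    charge_max: int = 1

    def __post_init__(self) -> None:
        if self.mono_mass <= 0:
            raise ValueError(f"mono_mass must be > 0, got {self.mono_mass}")
        if not (self.rt_start <= self.rt_apex <= self.rt_end):
            raise ValueError(
                f"need rt_start <= rt_apex <= rt_end, got "
                f"{self.rt_start}, {self.rt_apex}, {self.rt_end}"
            )
        if self.abundance is not None and self.abundance < 0:
            raise ValueError(f"abundance must be >= 0, got {self.abundance}")

    def with_rt(self, rt_apex: float) -> "MS1Feature":
        shift = rt_apex - self.rt_apex
        return replace(
            self,
            rt_apex=rt_apex,
            rt_start=self.rt_start + shift,
            rt_end=self.rt_end + shift,
        )

    def with_mass(self, mono_mass: float) -> "MS1Feature":
        return replace(self, mono_mass=mono_mass)


@dataclass
class MaldiPeakList:
    """A centroided MALDI peak list: (m/z, intensity) pairs, m/z ascending."""

    mz: list[float]
    intensity: list[float]
    mz_range: tuple[float, float] = (3500.0, 20000.0)

    def __post_init__(self) -> None:
        if len(self.mz) != len(self.intensity):
            raise ValueError("mz and intensity lengths differ")
        for a, b in zip(self.mz, self.mz[1:]):
            if not a < b:
                raise ValueError("m/z values must be strictly increasing")
        if any(i < 0 for i in self.intensity):
            raise ValueError("intensities must be nonnegative")

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class ProteoformCluster:
    """A proteoform cluster (PfC): PrSMs judged to be one proteoform.

    Cluster ids ending in "_0" are reserved for the per-accession noise
    cluster that pools sub-minimum clusters.
    """

    pfc_id: str
    accession: str
    members: list[PrSMRecord]
    representative: PrSMRecord
    is_noise: bool = False

    def __post_init__(self) -> None:
        if self.representative not in self.members:
            raise ValueError("representative must be a cluster member")
        if self.is_noise != self.pfc_id.endswith("_0"):
            raise ValueError('noise clusters and only noise clusters end in "_0"')


@dataclass(frozen=True)
class AmbiguityAssessment:
    """Five-level ambiguity classification of a proteoform identification.

    Level "1" = unambiguous.  A single ambiguous attribute maps to a
    two-character code (A=PTM localization, B=PTM identity, C=sequence,
    D=gene); k>=2 ambiguous attributes map to level str(1+k), up to "5".
    Sequence ambiguity is never asserted here (engines report a single
    sequence), so level "5" is unreachable in practice but representable.
    """

    ptm_localization_ambiguous: bool
    ptm_identity_ambiguous: bool
    sequence_ambiguous: bool
    gene_ambiguous: bool

    @property
    def level(self) -> str:
        flags = [
            (self.ptm_localization_ambiguous, "A"),
            (self.ptm_identity_ambiguous, "B"),
            (self.sequence_ambiguous, "C"),
            (self.gene_ambiguous, "D"),
        ]
        set_codes = [code for on, code in flags if on]
        if not set_codes:
            return "1"
        if len(set_codes) == 1:
            return "2" + set_codes[0]
        return str(1 + len(set_codes))


@dataclass(frozen=True)
class CalibrationAnchor:
    """A proteoform shared between a target run and the reference run.

    The anchor pairs the apex (most intense, else best-scoring) PrSM of the
    proteoform in each run; the RT pair drives the LOESS warp and the mass
    pair the ppm-offset estimate.
    """

    key: tuple[str, str]  # (accession, proteoform string)
    rt_ref: float
    rt_target: float
    mass_ref: float
    mass_target: float


@dataclass(frozen=True)
class CollapsedID:
    """One deduplicated identification competing to annotate feature groups.

    Open-search results are collapsed per PfC; PTM-database results per
    (accession, rounded monoisotopic mass).  The lowest-E-value proteoform
    represents each key.
    """

    source: str  # "toppic" | "tdportal"
    key: str
    mass: float
    rt: float
    evalue: float
    has_unknown_shift: bool
    annotation: str
    accession: str = ""
    is_noise: bool = False
    level: Optional[str] = None


@dataclass(frozen=True)
class LibraryEntry:
    """One proteoform in the accurate-mass annotation library."""

    annotation: str
    mono_mass: float

    def __post_init__(self) -> None:
        if self.mono_mass <= 0:
            raise ValueError("mono_mass must be > 0")


@dataclass(frozen=True)
class AnnotationHit:
    """An accurate-mass match of a MALDI peak to a library proteoform."""

    peak_mz: float
    peak_intensity: float
    entry: LibraryEntry
    charge: int
    mode: str  # "monoisotopic" | "apex"
    mass_error_ppm: float
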