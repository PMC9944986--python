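"""Readers and writers for every external table the pipeline touches.

Two search-engine dialects (TopPIC-style PrSM tables and TDPortal/TDViewer-style
proteoform exports), ProMex-style MS1 feature tables, two-column MALDI peak
lists, and the output quantitation table.  Column-name dialects are declared
as config mappings (internal field -> column header) with shipped defaults,
because engine versions rename columns; RT units are normalized to minutes at
read time.  The on-disk missing-value token is "NA"; in memory it is ``None``
(never 0).  Readers never silently drop rows: every rejected row is logged
with its index and the returned container records the rejects, so
``len(result) + len(result.rejected) == n_rows``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .records import MaldiPeakList, Modification, MS1Feature, PrSMRecord

logger = logging.getLogger(__name__)


class TableFormatError(ValueError):
    """A table is missing a mandatory column or is otherwise unreadable."""


class ReadResult(list):
    """A list of parsed records that also carries per-row rejects.

    ``rejected`` holds ``(row_index, reason)`` pairs, so
    ``len(result) + len(result.rejected)`` equals the number of data rows.
    """

    def __init__(self, records=(), rejected=None):
        super().__init__(records)
        self.rejected: list[tuple[int, str]] = list(rejected or [])


# ---------------------------------------------------------------------------
# dialects

@dataclass
class PrsmDialect:
    """Column mapping for a PrSM/proteoform table dialect.

    ``columns`` maps internal field names to on-disk headers.  Fields absent
    from the mapping (or mapped to a header missing from the file) are read
    as absent.  ``rt_unit`` is "min" or "s".
    """

    engine: str
    columns: dict[str, str]
    rt_unit: str = "min"
    mandatory: tuple[str, ...] = ("precursor_mass", "rt_min", "accession")


#: Default TopPIC export headers (RT exported in seconds).
TOPPIC_DIALECT = PrsmDialect(
    engine="toppic",
    columns={
        "run_id": "Data file name",
        "scan": "Scan(s)",
        "rt_min": "Retention time",
        "precursor_mass": "Precursor mass",
        "adjusted_mass": "Adjusted precursor mass",
        "charge": "Charge",
        "evalue": "E-value",
        "qvalue": "Proteoform FDR",
        "accession": "Protein accession",
        "proteoform": "Proteoform",
        "first_residue": "First residue",
        "last_residue": "Last residue",
        "intensity": "Feature intensity",
    },
    rt_unit="s",
)

#: Best-effort TDViewer export headers; engine versions vary, override via
#: config when they do.
TDPORTAL_DIALECT = PrsmDialect(
    engine="tdportal",
    columns={
        "run_id": "File Name",
        "scan": "Scan",
        "rt_min": "Retention Time",
        "precursor_mass": "Monoisotopic Mass",
        "charge": "Charge",
        "evalue": "E-Value",
        "qvalue": "Q-Value",
        "accession": "Accession",
        "gene": "Gene",
        "proteoform": "Proteoform",
        "modifications": "Modifications",
        "first_residue": "First Residue",
        "last_residue": "Last Residue",
    },
    rt_unit="min",
)


@dataclass
class FeatureDialect:
    """Column mapping for a ProMex-style MS1 feature table."""

    columns: dict[str, str] = field(
        default_factory=lambda: {
            "mono_mass": "MonoMass",
            "rt_apex": "ApexElutionTime",
            "rt_start": "MinElutionTime",
            "rt_end": "MaxElutionTime",
            "abundance": "Abundance",
            "charge_min": "MinCharge",
            "charge_max": "MaxCharge",
        }
    )
    rt_unit: str = "min"
    mandatory: tuple[str, ...] = ("mono_mass", "rt_apex", "abundance")


PROMEX_DIALECT = FeatureDialect()


# ---------------------------------------------------------------------------
# filename parsing

#: Default pattern for the FAIMS CV token in run file names, e.g.
#: "Hubmap_Intact_Brain_C1_CV40.raw" -> run "Hubmap_Intact_Brain_C1", CV -40.
CV_PATTERN = re.compile(r"[._-]CV(\d+)", re.IGNORECASE)


def parse_run_cv(
    filename: str, pattern: re.Pattern = CV_PATTERN, strict: bool = True
) -> tuple[str, Optional[int]]:
    """Split a per-CV raw-file name into (run_id, compensation voltage).

    The CV token encodes the magnitude of the (negative) FAIMS compensation
    voltage; "..._CV40" yields -40 V.  ``run_id`` is the filename stem with
    the CV token removed.  Without a CV token, strict mode raises and lenient
    mode returns ``cv=None``.
    """
    stem = Path(filename).name
    for suffix in (".raw", ".tsv", ".txt", ".csv", ".ms1ft"):
        if stem.lower().endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    m = pattern.search(stem)
    if m is None:
        if strict:
            raise ValueError(f"no CV token in filename {filename!r}")
        return stem, None
    run_id = (stem[: m.start()] + stem[m.end():]).strip("_-.")
    return run_id, -int(m.group(1))


# ---------------------------------------------------------------------------
# proteoform-string / modification parsing

_BRACKET = re.compile(r"\[([^\]]*)\]")
_NUMERIC = re.compile(r"^[+-]?\d+(\.\d+)?$")


def parse_proteoform_string(proteoform: str) -> list[Modification]:
    """Extract modifications from a TopPIC-style proteoform string.

    Bracketed annotations are modifications: numeric content (e.g.
    "[+446.956]") is an unknown mass shift from the open search; anything
    else is a named PTM.  "&"-joined contents list several modifications at
    one site region.  A bracket following a parenthesized residue range,
    e.g. "A(BC)[Acetyl]", is unlocalized; a bracket following a single
    residue is localized at that residue (1-based within the matched core
    sequence).
    """
    core = proteoform
    # strip flanking "X." prefix / ".X" suffix if present
    if len(core) > 4 and core[1] == "." and core[-2] == ".":
        core = core[2:-2]
    mods: list[Modification] = []
    pos = 0  # residues seen so far
    i = 0
    depth_closed_at = -1
    while i < len(core):
        ch = core[i]
        if ch == "[":
            m = _BRACKET.match(core, i)
            if m is None:
                i += 1
                continue
            localized = depth_closed_at != pos  # preceded by ')' -> range
            for part in m.group(1).split("&"):
                part = part.strip()
                if not part:
                    continue
                if _NUMERIC.match(part):
                    mods.append(
                        Modification(
                            mass_shift=float(part),
                            position=pos if localized else None,
                            localized=False,
                        )
                    )
                else:
                    mods.append(
                        Modification(
                            name=part,
                            position=pos if localized else None,
                            localized=localized,
                        )
                    )
            i = m.end()
        elif ch == ")":
            depth_closed_at = pos
            i += 1
        elif ch.isalpha():
            pos += 1
            i += 1
        else:
            i += 1
    return mods


def parse_modifications_field(text: str) -> list[Modification]:
    """Parse a semicolon-separated Modifications column, "name@pos" entries.

    A bare numeric entry is an unknown mass shift; "@pos" localizes, a
    missing or "?" position leaves the modification unlocalized.
    """
    mods: list[Modification] = []
    if not text or str(text).strip() in ("", "NA", "nan"):
        return mods
    for entry in str(text).split(";"):
        entry = entry.strip()
        if not entry:
            continue
        name_part, _, pos_part = entry.partition("@")
        name_part = name_part.strip()
        pos_part = pos_part.strip()
        position = int(pos_part) if pos_part.isdigit() else None
        if _NUMERIC.match(name_part):
            mods.append(Modification(mass_shift=float(name_part), position=position))
        else:
            mods.append(
                Modification(name=name_part, position=position, localized=position is not None)
            )
    return mods


def format_modifications_field(mods: list[Modification]) -> str:
    parts = []
    for m in mods:
        name = m.name if m.name is not None else f"{m.mass_shift:+.5f}".rstrip("0").rstrip(".")
        if m.position is not None and (m.localized or m.name is None):
            parts.append(f"{name}@{m.position}")
        else:
            parts.append(name)
    return ";".join(parts)


# ---------------------------------------------------------------------------
# PrSM readers / writer

def _require_columns(df: pd.DataFrame, dialect, fields) -> None:
    for f in fields:
        col = dialect.columns.get(f)
        if col is None or col not in df.columns:
            raise TableFormatError(
                f"mandatory column for field {f!r} "
                f"({col or 'unmapped'}) missing from table"
            )


def _get(row, dialect, fld, default=None):
    col = dialect.columns.get(fld)
    if col is None or col not in row.index:
        return default
    v = row[col]
    if pd.isna(v) or (isinstance(v, str) and v.strip() in ("", "NA")):
        return default
    return v


def read_prsm_table(
    path, dialect: PrsmDialect, run_id: Optional[str] = None, cv: Optional[int] = None
) -> ReadResult:
    """Read one PrSM/proteoform table in the given dialect.

    ``run_id``/``cv`` override values parsed from the table's file-name
    column (or, failing that, from ``path``).  Rows with unparseable masses
    are rejected individually and logged with their row index.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, dialect, dialect.mandatory)
    records: list[PrSMRecord] = []
    rejected: list[tuple[int, str]] = []
    rt_scale = 1.0 / 60.0 if dialect.rt_unit == "s" else 1.0
    for idx, row in df.iterrows():
        try:
            fname = _get(row, dialect, "run_id")
            if fname is not None:
                rrun, rcv = parse_run_cv(str(fname), strict=False)
            else:
                rrun, rcv = parse_run_cv(str(path), strict=False)
            mass = float(_get(row, dialect, "precursor_mass"))
            adj = _get(row, dialect, "adjusted_mass")
            proteoform = str(_get(row, dialect, "proteoform", ""))
            mods_field = _get(row, dialect, "modifications")
            if mods_field is not None:
                mods = parse_modifications_field(mods_field)
            else:
                mods = parse_proteoform_string(proteoform)
            rec = PrSMRecord(
                run_id=run_id if run_id is not None else rrun,
                cv=cv if cv is not None else rcv,
                scan=int(float(_get(row, dialect, "scan", 0))),
                rt_min=float(_get(row, dialect, "rt_min")) * rt_scale,
                precursor_mass=mass,
                adjusted_mass=float(adj) if adj is not None else None,
                charge=int(float(_get(row, dialect, "charge", 1))),
                evalue=float(_get(row, dialect, "evalue", 1.0)),
                accession=str(_get(row, dialect, "accession")),
                gene=_get(row, dialect, "gene"),
                qvalue=(lambda q: float(q) if q is not None else None)(
                    _get(row, dialect, "qvalue")
                ),
                intensity=(lambda x: float(x) if x is not None else None)(
                    _get(row, dialect, "intensity")
                ),
                proteoform=proteoform,
                first_residue=int(float(_get(row, dialect, "first_residue", 1))),
                last_residue=int(float(_get(row, dialect, "last_residue", 1))),
                engine=dialect.engine,
                modifications=mods,
            )
            records.append(rec)
        except (TypeError, ValueError) as exc:
            logger.warning("rejected row %d of %s: %s", idx, path, exc)
            rejected.append((idx, str(exc)))
    return ReadResult(records, rejected)


def read_toppic_prsms(path, dialect: PrsmDialect = TOPPIC_DIALECT, **kw) -> ReadResult:
    """Read a TopPIC-style PrSM table (one row per proteoform-spectrum match)."""
    return read_prsm_table(path, dialect, **kw)


def read_tdportal_table(path, dialect: PrsmDialect = TDPORTAL_DIALECT, **kw) -> ReadResult:
    """Read a TDPortal/TDViewer-style proteoform export."""
    return read_prsm_table(path, dialect, **kw)


def write_prsm_table(records: list[PrSMRecord], path, dialect: PrsmDialect) -> None:
    """Write PrSM records in the given dialect (inverse of the reader)."""
    cols = dialect.columns
    rt_scale = 60.0 if dialect.rt_unit == "s" else 1.0
    rows = []
    for r in records:
        row = {}
        def put(fld, value):
            if fld in cols:
                row[cols[fld]] = "NA" if value is None else value
        cv_mag = abs(r.cv) if r.cv is not None else 0
        put("run_id", f"{r.run_id}_CV{cv_mag}.raw" if r.cv is not None else r.run_id)
        put("scan", r.scan)
        put("rt_min", r.rt_min * rt_scale)
        put("precursor_mass", repr(r.precursor_mass))
        put("adjusted_mass", repr(r.adjusted_mass) if r.adjusted_mass is not None else None)
        put("charge", r.charge)
        put("evalue", repr(r.evalue))
        put("qvalue", repr(r.qvalue) if r.qvalue is not None else None)
        put("accession", r.accession)
        put("gene", r.gene)
        put("proteoform", r.proteoform)
        put("modifications", format_modifications_field(r.modifications))
        put("first_residue", r.first_residue)
        put("last_residue", r.last_residue)
        put("intensity", repr(r.intensity) if r.intensity is not None else None)
        rows.append(row)
    header = list(dialect.columns.values())
    pd.DataFrame(rows, columns=header).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# feature tables

def read_promex_features(
    path,
    dialect: FeatureDialect = PROMEX_DIALECT,
    run_id: Optional[str] = None,
    cv: Optional[int] = None,
) -> ReadResult:
    """Read a ProMex-style MS1 feature table.

    "NA" abundances become the in-memory missing marker (``None``); negative
    abundances reject the row.  ``run_id``/``cv`` default to values parsed
    from the file name.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, dialect, dialect.mandatory)
    if run_id is None or cv is None:
        prun, pcv = parse_run_cv(str(path), strict=False)
        run_id = run_id if run_id is not None else prun
        cv = cv if cv is not None else pcv
    rt_scale = 1.0 / 60.0 if dialect.rt_unit == "s" else 1.0
    feats: list[MS1Feature] = []
    rejected: list[tuple[int, str]] = []
    for idx, row in df.iterrows():
        try:
            ab = _get(row, dialect, "abundance")
            apex = float(_get(row, dialect, "rt_apex")) * rt_scale
            start = _get(row, dialect, "rt_start")
            end = _get(row, dialect, "rt_end")
            feats.append(
                MS1Feature(
                    run_id=run_id,
                    cv=cv,
                    mono_mass=float(_get(row, dialect, "mono_mass")),
                    rt_apex=apex,
                    rt_start=float(start) * rt_scale if start is not None else apex,
                    rt_end=float(end) * rt_scale if end is not None else apex,
                    abundance=float(ab) if ab is not None else None,
                    charge_min=int(float(_get(row, dialect, "charge_min", 1))),
                    charge_max=int(float(_get(row, dialect, "charge_max", 1))),
                )
            )
        except (TypeError, ValueError) as exc:
            logger.warning("rejected row %d of %s: %s", idx, path, exc)
            rejected.append((idx, str(exc)))
    return ReadResult(feats, rejected)


def write_promex_features(
    features: list[MS1Feature], path, dialect: FeatureDialect = PROMEX_DIALECT
) -> None:
    cols = dialect.columns
    rt_scale = 60.0 if dialect.rt_unit == "s" else 1.0
    rows = []
    for f in features:
        rows.append(
            {
                cols["mono_mass"]: repr(f.mono_mass),
                cols["rt_apex"]: repr(f.rt_apex * rt_scale),
                cols["rt_start"]: repr(f.rt_start * rt_scale),
                cols["rt_end"]: repr(f.rt_end * rt_scale),
                cols["abundance"]: "NA" if f.abundance is None else repr(f.abundance),
                cols["charge_min"]: f.charge_min,
                cols["charge_max"]: f.charge_max,
            }
        )
    pd.DataFrame(rows, columns=list(cols.values())).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# MALDI peak lists

def read_maldi_peaks(path, mz_range=(3500.0, 20000.0)) -> MaldiPeakList:
    """Read a two-column (m/z, intensity) text peak list."""
    mz: list[float] = []
    inten: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split()
            mz.append(float(parts[0]))
            inten.append(float(parts[1]) if len(parts) > 1 else 0.0)
    return MaldiPeakList(mz=mz, intensity=inten, mz_range=mz_range)


def write_maldi_peaks(peaks: MaldiPeakList, path) -> None:
    with open(path, "w") as fh:
        fh.write("# m/z\tintensity\n")
        for mz, inten in zip(peaks.mz, peaks.intensity):
            fh.write(f"{mz!r}\t{inten!r}\n")


# ---------------------------------------------------------------------------
# quant table

def write_quant_table(qm, path) -> None:
    """Write a quantitation matrix (annotations + per-sample abundances +
    statistics) as a lossless tab-separated table."""
    qm.to_tsv(path)
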