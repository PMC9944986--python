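"""Cross-run feature alignment, feature-group construction, and attachment
of collapsed identifications to quantifiable feature groups.

MS1 intact-mass features from every run are first aligned per FAIMS CV
(match-between-runs on mass and RT, missing cells marked NA), then all CVs
are concatenated and grouped: masses sorted ascending are chained into a
mass group while each subsequent mass stays within 1 Da and 15 ppm of its
predecessor; within a mass group, RTs sorted ascending chain into an RT
group while each gap stays within 4 min.  A (mass group x RT group) cell is
a "feature group" — the unit of label-free quantitation, summarized by
member count, max monoisotopic mass, mean RT, and per-sample median
intensity.

Identifications are collapsed to one candidate per proteoform (per PfC for
the open-search engine, per accession+mass for the PTM-database engine) and
matched to feature groups within 15 ppm and +/-4 min, also trying +/-1 and
+/-2 isotope-spacing shifts of the ID mass to absorb deisotoping errors.
When several IDs hit one group, priority is: no unknown modification first,
then non-noise PfC, then smaller E-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .records import ISOTOPE_SPACING, CollapsedID, MS1Feature, ProteoformCluster, PrSMRecord

logger = logging.getLogger(__name__)

DEFAULT_MASS_TOL_PPM = 15.0
DEFAULT_RT_TOL_MIN = 4.0
DEFAULT_MASS_GROUP_DA = 1.0
DEFAULT_SHIFTS = (0, 1, -1, 2, -2)


def ppm_error(observed: float, reference: float) -> float:
    """(observed - reference) / reference * 1e6."""
    return (observed - reference) / reference * 1e6


# ---------------------------------------------------------------------------
# cross-run alignment (match-between-runs)

def align_features_across_runs(
    features_by_run: dict[str, Sequence[MS1Feature]],
    mass_tol_ppm: float = DEFAULT_MASS_TOL_PPM,
    rt_tol_min: float = DEFAULT_RT_TOL_MIN,
) -> pd.DataFrame:
    """Align one CV's feature lists across runs into a master table.

    A master list is seeded from the run with the most features; every other
    run's features are matched greedily (best |ppm| first, each feature used
    once) to master rows within the mass and RT tolerances, and unmatched
    features are appended as new rows.  The result has one row per aligned
    feature with columns ``mono_mass`` (max of matched member masses),
    ``rt`` (mean member RT), ``n_members``, and one abundance column per run
    (NaN where the run lacks the feature).

    This aligner is a deliberately minimal match-between-runs step standing
    behind the same table contract as dedicated alignment tools.
    """
    runs = sorted(features_by_run, key=lambda r: (-len(features_by_run[r]), r))
    if not runs:
        return pd.DataFrame(columns=["mono_mass", "rt", "n_members"])
    master_run = runs[0]
    rows: list[dict] = []
    for f in sorted(features_by_run[master_run], key=lambda f: f.mono_mass):
        rows.append(
            {
                "masses": [f.mono_mass],
                "rts": [f.rt_apex],
                "abund": {master_run: f.abundance},
            }
        )
    for run in runs[1:]:
        feats = list(features_by_run[run])
        # candidate (row, feature) pairs within tolerance, best ppm first
        cands = []
        for j, f in enumerate(feats):
            for i, row in enumerate(rows):
                if run in row["abund"]:
                    continue
                ref_mass = max(row["masses"])
                p = ppm_error(f.mono_mass, ref_mass)
                if abs(p) <= mass_tol_ppm and abs(f.rt_apex - np.mean(row["rts"])) <= rt_tol_min:
                    cands.append((abs(p), i, j))
        cands.sort()
        used_rows: set[int] = set()
        used_feats: set[int] = set()
        for _, i, j in cands:
            if i in used_rows or j in used_feats:
                continue
            used_rows.add(i)
            used_feats.add(j)
            f = feats[j]
            rows[i]["masses"].append(f.mono_mass)
            rows[i]["rts"].append(f.rt_apex)
            rows[i]["abund"][run] = f.abundance
        for j, f in enumerate(feats):
            if j not in used_feats:
                rows.append(
                    {"masses": [f.mono_mass], "rts": [f.rt_apex], "abund": {run: f.abundance}}
                )
    out = pd.DataFrame(
        {
            "mono_mass": [max(r["masses"]) for r in rows],
            "rt": [float(np.mean(r["rts"])) for r in rows],
            "n_members": [len(r["masses"]) for r in rows],
        }
    )
    for run in sorted(features_by_run):
        out[run] = [
            (np.nan if r["abund"].get(run) is None else r["abund"].get(run, np.nan))
            for r in rows
        ]
    return out.sort_values("mono_mass", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# chained mass / RT grouping

def assign_mass_groups(
    masses: Sequence[float],
    tol_da: float = DEFAULT_MASS_GROUP_DA,
    tol_ppm: float = DEFAULT_MASS_TOL_PPM,
) -> list[int]:
    """Chain sorted masses into mass groups.

    Each mass joins the current group iff its gap to the immediately
    preceding mass is <= ``tol_da`` AND <= ``tol_ppm`` (evaluated against the
    preceding mass); otherwise it starts a new group.  Input must be sorted
    ascending.  Comparisons are inclusive.
    """
    masses = list(masses)
    if any(b < a for a, b in zip(masses, masses[1:])):
        raise ValueError("masses must be sorted ascending")
    groups: list[int] = []
    g = -1
    prev = None
    for m in masses:
        if prev is None or not (m - prev <= tol_da and ppm_error(m, prev) <= tol_ppm):
            g += 1
        groups.append(g)
        prev = m
    return groups


def assign_rt_groups(rts: Sequence[float], tol_min: float = DEFAULT_RT_TOL_MIN) -> list[int]:
    """Chain sorted RTs into RT groups: gap to predecessor <= ``tol_min``."""
    rts = list(rts)
    if any(b < a for a, b in zip(rts, rts[1:])):
        raise ValueError("RTs must be sorted ascending")
    groups: list[int] = []
    g = -1
    prev = None
    for t in rts:
        if prev is None or not (t - prev <= tol_min):
            g += 1
        groups.append(g)
        prev = t
    return groups


@dataclass
class FeatureGroup:
    """A cross-run, cross-CV feature cluster: the unit of quantitation."""

    group_id: str
    mass_group: int
    rt_group: int
    consensus_mass: float  # max member mass
    mean_rt: float
    count: int  # number of member features (all runs, all CVs)
    per_sample_abundance: dict[str, float] = field(default_factory=dict)
    id_annotation: Optional[CollapsedID] = None
    id_shift: Optional[int] = None
    rows: Optional[pd.DataFrame] = None


def build_feature_groups(
    aligned_by_cv: dict[Optional[int], pd.DataFrame],
    mass_tol_da: float = DEFAULT_MASS_GROUP_DA,
    mass_tol_ppm: float = DEFAULT_MASS_TOL_PPM,
    rt_tol_min: float = DEFAULT_RT_TOL_MIN,
) -> list[FeatureGroup]:
    """Concatenate all CVs and build (mass group x RT group) feature groups.

    Summary fields per group: member feature count, max monoisotopic mass,
    mean RT, and per-sample median intensity over the group's aligned rows.
    """
    frames = []
    for cv, df in aligned_by_cv.items():
        d = df.copy()
        d["cv"] = cv
        frames.append(d)
    if not frames:
        return []
    allrows = pd.concat(frames, ignore_index=True, sort=False)
    allrows = allrows.sort_values("mono_mass", kind="stable").reset_index(drop=True)
    allrows["mass_group"] = assign_mass_groups(
        allrows["mono_mass"].tolist(), mass_tol_da, mass_tol_ppm
    )
    sample_cols = [
        c for c in allrows.columns
        if c not in ("mono_mass", "rt", "n_members", "cv", "mass_group")
    ]
    groups: list[FeatureGroup] = []
    for mg, sub in allrows.groupby("mass_group", sort=True):
        sub = sub.sort_values("rt", kind="stable")
        rtg = assign_rt_groups(sub["rt"].tolist(), rt_tol_min)
        sub = sub.assign(rt_group=rtg)
        for rg, cell in sub.groupby("rt_group", sort=True):
            per_sample = {}
            for s in sample_cols:
                vals = cell[s].dropna()
                if len(vals):
                    per_sample[s] = float(vals.median())
            groups.append(
                FeatureGroup(
                    group_id=f"FG{mg}_{rg}",
                    mass_group=int(mg),
                    rt_group=int(rg),
                    consensus_mass=float(cell["mono_mass"].max()),
                    mean_rt=float(cell["rt"].mean()),
                    count=int(cell["n_members"].sum()),
                    per_sample_abundance=per_sample,
                    rows=cell,
                )
            )
    return groups


# ---------------------------------------------------------------------------
# collapsing identifications

def collapse_ids(
    pfcs: Sequence[ProteoformCluster],
    tdportal_prsms: Sequence[PrSMRecord] = (),
) -> list[CollapsedID]:
    """One identification candidate per proteoform.

    Open-search results collapse per PfC (noise clusters included, keyed by
    their "_0" id); PTM-database results collapse per (accession, rounded
    monoisotopic mass).  The lowest-E-value proteoform represents each key.
    """
    out: list[CollapsedID] = []
    for pfc in pfcs:
        rep = pfc.representative
        out.append(
            CollapsedID(
                source="toppic",
                key=pfc.pfc_id,
                mass=rep.precursor_mass,
                rt=rep.rt_min,
                evalue=rep.evalue,
                has_unknown_shift=rep.has_unknown_shift,
                annotation=rep.proteoform or pfc.accession,
                accession=pfc.accession,
                is_noise=pfc.is_noise,
            )
        )
    best: dict[tuple[str, float], PrSMRecord] = {}
    for p in tdportal_prsms:
        key = (p.accession, round(p.precursor_mass, 2))
        cur = best.get(key)
        if cur is None or p.evalue < cur.evalue:
            best[key] = p
    for (acc, mass), p in sorted(best.items()):
        out.append(
            CollapsedID(
                source="tdportal",
                key=f"{acc}@{mass:.2f}",
                mass=p.precursor_mass,
                rt=p.rt_min,
                evalue=p.evalue,
                has_unknown_shift=p.has_unknown_shift,
                annotation=p.proteoform or acc,
                accession=acc,
                is_noise=False,
            )
        )
    return out


@dataclass(frozen=True)
class MatchCandidate:
    """One (identification, feature group) match, with the isotope shift used."""

    cid: CollapsedID
    group_index: int
    shift: int
    residual_ppm: float
    input_order: int = 0


def match_id_to_group(
    cid: CollapsedID,
    groups: Sequence[FeatureGroup],
    mass_tol_ppm: float = DEFAULT_MASS_TOL_PPM,
    rt_tol_min: float = DEFAULT_RT_TOL_MIN,
    isotope_spacing_da: float = ISOTOPE_SPACING,
    shifts: Sequence[int] = DEFAULT_SHIFTS,
    input_order: int = 0,
) -> list[MatchCandidate]:
    """All feature groups this identification can annotate.

    A group matches iff for some shift k the shifted ID mass
    (mass + k * isotope spacing) agrees with the group's consensus mass
    within ``mass_tol_ppm`` and the RT difference is within ``rt_tol_min``.
    For each group the preferred shift is 0, then ascending |k|.
    """
    cands: list[MatchCandidate] = []
    for gi, g in enumerate(groups):
        if abs(cid.rt - g.mean_rt) > rt_tol_min:
            continue
        for k in sorted(set(shifts), key=lambda k: (abs(k), k < 0)):
            shifted = cid.mass + k * isotope_spacing_da
            resid = ppm_error(shifted, g.consensus_mass)
            if abs(resid) <= mass_tol_ppm:
                cands.append(MatchCandidate(cid, gi, k, resid, input_order))
                break  # best (smallest |k|) shift for this group
    return cands


_SOURCE_ORDER = {"toppic": 0, "tdportal": 1}


def resolve_conflicts(candidates: Sequence[MatchCandidate]) -> Optional[MatchCandidate]:
    """Pick the winning identification for one feature group.

    Lexicographic priority: (1) no unknown modification beats unknown;
    (2) non-noise PfC beats the noise cluster; (3) smaller E-value; then
    smaller |shift|, open-search engine before the PTM-database engine, and
    finally stable input order.
    """
    if not candidates:
        return None
    return min(
        candidates,
        key=lambda c: (
            c.cid.has_unknown_shift,
            c.cid.is_noise,
            c.cid.evalue,
            abs(c.shift),
            _SOURCE_ORDER.get(c.cid.source, 9),
            c.input_order,
        ),
    )


def annotate_feature_groups(
    groups: list[FeatureGroup],
    collapsed: Sequence[CollapsedID],
    mass_tol_ppm: float = DEFAULT_MASS_TOL_PPM,
    rt_tol_min: float = DEFAULT_RT_TOL_MIN,
    isotope_spacing_da: float = ISOTOPE_SPACING,
    shifts: Sequence[int] = DEFAULT_SHIFTS,
) -> list[FeatureGroup]:
    """Attach at most one winning identification to every feature group."""
    per_group: dict[int, list[MatchCandidate]] = {}
    for order, cid in enumerate(collapsed):
        for cand in match_id_to_group(
            cid, groups, mass_tol_ppm, rt_tol_min, isotope_spacing_da, shifts, order
        ):
            per_group.setdefault(cand.group_index, []).append(cand)
    n_annotated = 0
    for gi, cands in per_group.items():
        win = resolve_conflicts(cands)
        if win is not None:
            groups[gi].id_annotation = win.cid
            groups[gi].id_shift = win.shift
            n_annotated += 1
    logger.info("annotated %d / %d feature groups", n_annotated, len(groups))
    return groups
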