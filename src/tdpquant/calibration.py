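"""Retention-time alignment and mass-error recalibration.

Runs drift against each other in retention time (gradient and column aging)
and carry small systematic mass-calibration offsets.  Both are corrected
against a reference run — the run with the most PrSMs — using proteoforms
identified in both runs as anchors.  The RT correction is a LOESS regression
of reference RT on target RT through the anchor pairs; the mass correction
is a single per-run ppm offset, the median anchor ppm error (robust to
outlier PrSMs).  Each FAIMS compensation voltage is aligned independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .records import CalibrationAnchor, MS1Feature, PrSMRecord

logger = logging.getLogger(__name__)

#: Minimum number of shared proteoforms for a trustworthy fit; below this the
#: warp falls back to the identity.
MIN_ANCHORS = 5


def ppm_error(observed: float, reference: float) -> float:
    """Relative mass error in parts per million: (obs - ref)/ref * 1e6."""
    return (observed - reference) / reference * 1e6


@dataclass
class RtWarp:
    """A monotone-in-practice RT mapping target-run minutes -> reference minutes.

    Inside the anchor span the warp interpolates the LOESS fit; beyond it the
    boundary trend continues linearly.
    """

    x: np.ndarray  # target RTs (sorted)
    y: np.ndarray  # fitted reference RTs
    median_abs_residual: float = 0.0
    n_anchors: int = 0

    @classmethod
    def identity(cls) -> "RtWarp":
        return cls(x=np.array([0.0, 1.0]), y=np.array([0.0, 1.0]))

    @property
    def is_identity(self) -> bool:
        return len(self.x) == 2 and np.array_equal(self.x, self.y)

    def _edge_slope(self, left: bool) -> tuple[float, float, float]:
        k = max(2, len(self.x) // 5)
        sl = slice(0, k) if left else slice(len(self.x) - k, len(self.x))
        xs, ys = self.x[sl], self.y[sl]
        if np.ptp(xs) == 0:
            return 1.0, xs[0], ys[0]
        slope, intercept = np.polyfit(xs, ys, 1)
        x0 = xs[0] if left else xs[-1]
        return slope, x0, slope * x0 + intercept

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if self.is_identity:
            return float(t) if t.ndim == 0 else t.copy()
        out = np.interp(t, self.x, self.y)
        lo, hi = self.x[0], self.x[-1]
        below, above = t < lo, t > hi
        if np.any(below):
            s, x0, y0 = self._edge_slope(left=True)
            out = np.where(below, y0 + s * (t - x0), out)
        if np.any(above):
            s, x0, y0 = self._edge_slope(left=False)
            out = np.where(above, y0 + s * (t - x0), out)
        return float(out) if out.ndim == 0 else out


@dataclass
class RunAlignmentModel:
    """Per-run (per-CV) alignment: an RT warp plus a constant ppm offset."""

    run_id: str
    warp: RtWarp
    ppm_offset: float
    n_anchors: int


# ---------------------------------------------------------------------------

def select_reference_run(prsms_by_run: dict[str, Sequence[PrSMRecord]]) -> str:
    """The run with the most PrSMs; ties go to the lexicographically smallest id."""
    if not prsms_by_run:
        raise ValueError("no runs")
    return min(prsms_by_run, key=lambda r: (-len(prsms_by_run[r]), r))


def _anchor_key(rec: PrSMRecord) -> tuple[str, str]:
    # proteoform identity: per-run ppm offsets shift intact-protein masses by
    # more than any fixed decimal rounding can absorb, so the reported
    # proteoform string (not a rounded mass) keys shared proteoforms
    return rec.accession, rec.proteoform


def _apex(records: list[PrSMRecord]) -> PrSMRecord:
    """Apex PrSM: most intense if intensities are reported, else best E-value."""
    if any(r.intensity is not None for r in records):
        return max(records, key=lambda r: (r.intensity or 0.0, -r.evalue))
    return min(records, key=lambda r: r.evalue)


def build_anchors(
    ref: Sequence[PrSMRecord], target: Sequence[PrSMRecord]
) -> list[CalibrationAnchor]:
    """Pair the apex PrSM of every proteoform observed in both runs."""
    by_key_ref: dict[tuple, list[PrSMRecord]] = {}
    by_key_tgt: dict[tuple, list[PrSMRecord]] = {}
    for r in ref:
        by_key_ref.setdefault(_anchor_key(r), []).append(r)
    for r in target:
        by_key_tgt.setdefault(_anchor_key(r), []).append(r)
    anchors = []
    for key in sorted(set(by_key_ref) & set(by_key_tgt)):
        a, b = _apex(by_key_ref[key]), _apex(by_key_tgt[key])
        anchors.append(
            CalibrationAnchor(
                key=key,
                rt_ref=a.rt_min,
                rt_target=b.rt_min,
                mass_ref=a.precursor_mass,
                mass_target=b.precursor_mass,
            )
        )
    if len(anchors) < MIN_ANCHORS:
        logger.warning(
            "only %d shared proteoforms between runs; alignment will fall back "
            "to the identity warp",
            len(anchors),
        )
    return anchors


def fit_rt_warp(
    anchors: Sequence[CalibrationAnchor], frac: float = 0.5, it: int = 2
) -> RtWarp:
    """LOESS regression of reference RT on target RT through the anchors.

    ``frac`` is the LOESS span (fraction of anchors per local fit) and ``it``
    the number of robustness iterations; defaults suit a few hundred anchors
    with occasional outlier PrSMs.  Fewer than MIN_ANCHORS anchors, or
    degenerate anchors with no RT spread, give the identity warp.
    """
    if len(anchors) < MIN_ANCHORS:
        return RtWarp.identity()
    x = np.array([a.rt_target for a in anchors])
    y = np.array([a.rt_ref for a in anchors])
    if np.ptp(x) == 0:
        logger.warning("degenerate anchors (all same RT); identity warp")
        return RtWarp.identity()
    fitted = lowess(y, x, frac=frac, it=it, return_sorted=True)
    xs, ys = fitted[:, 0], fitted[:, 1]
    # collapse duplicate x for interpolation
    xs_u, idx = np.unique(xs, return_index=True)
    ys_u = ys[idx]
    warp = RtWarp(x=xs_u, y=ys_u, n_anchors=len(anchors))
    warp.median_abs_residual = float(np.median(np.abs(warp(x) - y)))
    return warp


def apply_rt_warp(records, warp: RtWarp):
    """Map every record's RT through the warp; all other fields unchanged."""
    out = []
    for r in records:
        if isinstance(r, MS1Feature):
            out.append(r.with_rt(float(warp(r.rt_apex))))
        else:
            out.append(r.with_rt(float(warp(r.rt_min))))
    return out


def estimate_ppm_offset(anchors: Sequence[CalibrationAnchor]) -> float:
    """Median ppm error of target anchor masses against the reference."""
    if not anchors:
        return 0.0
    errs = [ppm_error(a.mass_target, a.mass_ref) for a in anchors]
    return float(np.median(errs))


def recalibrate_masses(records, offset_ppm: float):
    """Remove a constant ppm offset: mass' = mass * (1 - offset*1e-6)."""
    factor = 1.0 - offset_ppm * 1e-6
    out = []
    for r in records:
        if isinstance(r, MS1Feature):
            out.append(r.with_mass(r.mono_mass * factor))
        else:
            out.append(r.with_mass(r.precursor_mass * factor))
    return out


def align_run(
    ref_prsms: Sequence[PrSMRecord],
    target_prsms: Sequence[PrSMRecord],
    run_id: str,
    frac: float = 0.5,
    it: int = 2,
) -> RunAlignmentModel:
    """Fit the full per-run alignment model against the reference run."""
    anchors = build_anchors(ref_prsms, target_prsms)
    warp = fit_rt_warp(anchors, frac=frac, it=it)
    offset = estimate_ppm_offset(anchors)
    return RunAlignmentModel(
        run_id=run_id, warp=warp, ppm_offset=offset, n_anchors=len(anchors)
    )


def calibrate_all_runs(
    prsms_by_run_cv: dict[tuple[str, Optional[int]], list[PrSMRecord]],
    features_by_run_cv: Optional[dict[tuple[str, Optional[int]], list[MS1Feature]]] = None,
    frac: float = 0.5,
    it: int = 2,
):
    """Align every (run, CV) dataset to the per-CV reference run.

    Each FAIMS CV is aligned independently: within a CV, the run with the
    most PrSMs is the reference and every other run gets an RT warp and a
    ppm offset, applied to its PrSMs (and its features when given).

    Returns ``(prsms_by_run_cv, features_by_run_cv, models)`` with aligned
    and recalibrated copies.
    """
    cvs = sorted({cv for (_, cv) in prsms_by_run_cv}, key=lambda v: (v is None, v))
    out_prsms: dict[tuple, list[PrSMRecord]] = {}
    out_feats: dict[tuple, list[MS1Feature]] = {}
    models: dict[tuple, RunAlignmentModel] = {}
    for cv in cvs:
        runs = {r: v for (r, c), v in prsms_by_run_cv.items() if c == cv}
        ref_run = select_reference_run(runs)
        for run_id, prsms in runs.items():
            if run_id == ref_run:
                model = RunAlignmentModel(run_id, RtWarp.identity(), 0.0, len(prsms))
            else:
                model = align_run(runs[ref_run], prsms, run_id, frac=frac, it=it)
            models[(run_id, cv)] = model
            aligned = apply_rt_warp(prsms, model.warp)
            out_prsms[(run_id, cv)] = recalibrate_masses(aligned, model.ppm_offset)
            if features_by_run_cv is not None and (run_id, cv) in features_by_run_cv:
                feats = apply_rt_warp(features_by_run_cv[(run_id, cv)], model.warp)
                out_feats[(run_id, cv)] = recalibrate_masses(feats, model.ppm_offset)
        if features_by_run_cv is not None:
            # features for runs lacking PrSMs pass through unaligned
            for (run_id, c), feats in features_by_run_cv.items():
                if c == cv and (run_id, cv) not in out_feats:
                    out_feats[(run_id, cv)] = list(feats)
    return out_prsms, out_feats, models
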