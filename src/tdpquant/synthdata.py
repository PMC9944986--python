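"""Ground-truthed synthetic inputs for every pipeline stage.

The generator emulates the structure of a FAIMS-split spatial top-down
proteomics study: two tissue-region groups (five cortex and four
hypothalamus samples), each sample acquired as one LC-MS run split into
FAIMS compensation voltages (-30/-40/-50 V); proteoforms with log-uniform
masses (3.5-30 kDa), log-normal abundances and region fold-changes; smooth
monotone RT drift between runs; per-run ppm mass offsets; off-by-one/two
deisotoping errors at a stated rate; missing features; and two
partially-overlapping search engines observing the proteoform population.
Everything derives deterministically from one seed: regenerating with the
same seed reproduces byte-identical tables.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import io_tables
from .records import ISOTOPE_SPACING, MaldiPeakList, MS1Feature, PrSMRecord
from .maldi import mz_from_mass, predicted_mz
from .records import LibraryEntry

CVS = (-30, -40, -50)

_AA = "ACDEFGHIKLMNPQRSTVWY"
_PTMS = ("Acetyl", "Methyl", "Dimethyl", "Phospho", "Trimethyl")


@dataclass
class SynthParams:
    """Tunable condition parameters of the synthetic study.

    Defaults describe a realistic nanoPOTS-scale acquisition; ``clean()``
    zeroes every noise source for exact-recovery checks.
    """

    n_proteoforms: int = 200
    n_cortex: int = 5
    n_hypothalamus: int = 4
    mass_range_da: tuple[float, float] = (3500.0, 30000.0)
    rt_range_min: tuple[float, float] = (10.0, 120.0)
    log_abundance_mean: float = math.log(1e7)
    log_abundance_sigma: float = 1.0
    frac_regulated: float = 0.2
    effect_log2fc: float = 1.0  # two-fold between regions
    frac_unknown_shift: float = 0.3
    p_both_engines: float = 0.5
    p_toppic_only: float = 0.25
    p_tdportal_only: float = 0.15
    prsm_rate: float = 3.0  # extra PrSMs per (proteoform, sample, CV) ~ Poisson
    rt_warp_slope_sd: float = 0.02
    rt_warp_intercept_sd: float = 1.0
    rt_warp_sine_amp_max: float = 0.5  # min, period 60 min
    ppm_offset_max: float = 6.0
    dropout: float = 0.10
    deisotoping_rate: float = 0.05
    abundance_cv: float = 0.2  # lognormal coefficient of variation
    rt_jitter_sd_min: float = 0.15
    mass_jitter_ppm_sd: float = 1.0

    @classmethod
    def clean(cls, **overrides) -> "SynthParams":
        """Zero-noise conditions: identity warps, no offsets, no dropout,
        no deisotoping errors, noise-free abundances, both engines see all."""
        base = dict(
            rt_warp_slope_sd=0.0,
            rt_warp_intercept_sd=0.0,
            rt_warp_sine_amp_max=0.0,
            ppm_offset_max=0.0,
            dropout=0.0,
            deisotoping_rate=0.0,
            abundance_cv=0.0,
            rt_jitter_sd_min=0.0,
            mass_jitter_ppm_sd=0.0,
            p_both_engines=1.0,
            p_toppic_only=0.0,
            p_tdportal_only=0.0,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class TrueProteoform:
    index: int
    accession: str
    gene: str
    annotation: str  # proteoform string in the open-search dialect
    mono_mass: float
    true_rt: float
    base_abundance: float
    log2fc: float  # cortex minus hypothalamus
    cvs: tuple[int, ...]  # FAIMS CVs where the proteoform ionizes
    cv_weights: tuple[float, ...]
    has_unknown_shift: bool
    in_toppic: bool
    in_tdportal: bool


@dataclass
class SampleDesign:
    sample_id: str
    region: str  # "cortex" | "hypothalamus"
    warp_slope: float
    warp_intercept: float
    warp_sine_amp: float
    ppm_offset: float

    def warp(self, t):
        """Observed RT in this run for a true RT (smooth monotone drift)."""
        t = np.asarray(t, dtype=float)
        out = (
            self.warp_slope * t
            + self.warp_intercept
            + self.warp_sine_amp * np.sin(2 * np.pi * t / 60.0)
        )
        return float(out) if out.ndim == 0 else out


@dataclass
class GroundTruth:
    seed: int
    params: SynthParams
    proteoforms: list[TrueProteoform]
    samples: list[SampleDesign]

    @property
    def sample_groups(self) -> dict[str, str]:
        return {s.sample_id: s.region for s in self.samples}

    def to_json(self, path) -> None:
        obj = {
            "seed": self.seed,
            "params": asdict(self.params),
            "proteoforms": [asdict(p) for p in self.proteoforms],
            "samples": [asdict(s) for s in self.samples],
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        obj = json.loads(Path(path).read_text())
        params = SynthParams(**obj["params"])
        for key in ("mass_range_da", "rt_range_min"):
            setattr(params, key, tuple(getattr(params, key)))
        pfs = []
        for d in obj["proteoforms"]:
            d["cvs"] = tuple(d["cvs"])
            d["cv_weights"] = tuple(d["cv_weights"])
            pfs.append(TrueProteoform(**d))
        samples = [SampleDesign(**d) for d in obj["samples"]]
        return cls(obj["seed"], params, pfs, samples)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


def generate_truth(
    n_proteoforms: Optional[int] = None,
    n_samples_per_group: Optional[tuple[int, int]] = None,
    seed: int = 0,
    params: Optional[SynthParams] = None,
) -> GroundTruth:
    """Draw the ground-truth proteoform population and sample designs."""
    params = params or SynthParams()
    if n_proteoforms is not None:
        params.n_proteoforms = n_proteoforms
    if n_samples_per_group is not None:
        params.n_cortex, params.n_hypothalamus = n_samples_per_group
    rng = _rng(seed, 0)
    lo, hi = params.mass_range_da
    pfs: list[TrueProteoform] = []
    for i in range(params.n_proteoforms):
        mass = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        rt = float(rng.uniform(*params.rt_range_min))
        abundance = float(
            np.exp(rng.normal(params.log_abundance_mean, params.log_abundance_sigma))
        )
        regulated = rng.random() < params.frac_regulated
        log2fc = float(rng.choice([-1.0, 1.0]) * params.effect_log2fc) if regulated else 0.0
        n_cv = int(rng.integers(1, len(CVS) + 1))
        cvs = tuple(sorted(rng.choice(CVS, size=n_cv, replace=False).tolist(), reverse=True))
        w = rng.dirichlet(np.ones(n_cv))
        unknown = rng.random() < params.frac_unknown_shift
        seq = "".join(rng.choice(list(_AA), size=int(rng.integers(12, 25))))
        if unknown:
            shift = float(np.round(rng.uniform(14.0, 500.0), 3))
            k = int(rng.integers(1, len(seq)))
            annotation = f"{seq[:k]}[{shift:+.3f}]{seq[k:]}"
        elif rng.random() < 0.4:
            ptm = str(rng.choice(_PTMS))
            k = int(rng.integers(1, len(seq)))
            annotation = f"{seq[:k]}[{ptm}]{seq[k:]}"
        else:
            annotation = seq
        u = rng.random()
        in_tp = u < params.p_both_engines + params.p_toppic_only
        in_td = (u < params.p_both_engines) or (
            params.p_both_engines + params.p_toppic_only
            <= u
            < params.p_both_engines + params.p_toppic_only + params.p_tdportal_only
        )
        pfs.append(
            TrueProteoform(
                index=i,
                accession=f"P{i:05d}",
                gene=f"Gene{i}",
                annotation=annotation,
                mono_mass=mass,
                true_rt=rt,
                base_abundance=abundance,
                log2fc=log2fc,
                cvs=cvs,
                cv_weights=tuple(float(x) for x in w),
                has_unknown_shift=unknown,
                in_toppic=bool(in_tp),
                in_tdportal=bool(in_td),
            )
        )
    samples: list[SampleDesign] = []
    n_total = params.n_cortex + params.n_hypothalamus
    for j in range(n_total):
        region = "cortex" if j < params.n_cortex else "hypothalamus"
        samples.append(
            SampleDesign(
                sample_id=f"S{j+1:02d}",
                region=region,
                warp_slope=float(1.0 + rng.normal(0, params.rt_warp_slope_sd)),
                warp_intercept=float(rng.normal(0, params.rt_warp_intercept_sd)),
                warp_sine_amp=float(rng.uniform(0, params.rt_warp_sine_amp_max)),
                ppm_offset=float(rng.uniform(-params.ppm_offset_max, params.ppm_offset_max)),
            )
        )
    # the first sample anchors the common timescale (it has the most PrSMs
    # by construction below), so give it the identity drift
    if samples:
        samples[0].warp_slope, samples[0].warp_intercept = 1.0, 0.0
        samples[0].warp_sine_amp, samples[0].ppm_offset = 0.0, 0.0
    return GroundTruth(seed=seed, params=params, proteoforms=pfs, samples=samples)


@dataclass
class SimulatedTables:
    """In-memory simulated inputs, keyed like the pipeline expects."""

    toppic_prsms: dict[tuple[str, int], list[PrSMRecord]]
    tdportal_prsms: dict[tuple[str, int], list[PrSMRecord]]
    features: dict[tuple[str, int], list[MS1Feature]]
    truth: GroundTruth


def _sample_abundance(pf: TrueProteoform, s: SampleDesign) -> float:
    fc = 2.0 ** (pf.log2fc if s.region == "cortex" else 0.0)
    return pf.base_abundance * fc


def simulate_tables(truth: GroundTruth) -> SimulatedTables:
    """Simulate PrSM tables for both engines and per-run/CV feature tables.

    Features carry the run's RT drift, ppm mass offset, deisotoping shifts at
    the stated rate, lognormal abundance noise, and dropout; PrSMs are
    sampled per (proteoform, sample, CV) with log-uniform E-values.  The
    first sample gets one extra PrSM per proteoform so the reference-run
    choice is deterministic.
    """
    p = truth.params
    rng = _rng(truth.seed, 1)
    sigma_ln = math.sqrt(math.log(1.0 + p.abundance_cv**2))
    toppic: dict[tuple[str, int], list[PrSMRecord]] = {}
    tdportal: dict[tuple[str, int], list[PrSMRecord]] = {}
    features: dict[tuple[str, int], list[MS1Feature]] = {}
    for si, s in enumerate(truth.samples):
        for cv in CVS:
            toppic[(s.sample_id, cv)] = []
            tdportal[(s.sample_id, cv)] = []
            features[(s.sample_id, cv)] = []
    scan = 1000
    for pf in truth.proteoforms:
        mods = io_tables.parse_proteoform_string(pf.annotation)
        for si, s in enumerate(truth.samples):
            base = _sample_abundance(pf, s)
            for cv, w in zip(pf.cvs, pf.cv_weights):
                key = (s.sample_id, cv)
                obs_rt = s.warp(pf.true_rt)
                # --- feature ---
                if rng.random() >= p.dropout:
                    mass = pf.mono_mass * (
                        1.0
                        + (s.ppm_offset + rng.normal(0, p.mass_jitter_ppm_sd) if p.mass_jitter_ppm_sd > 0 else s.ppm_offset)
                        * 1e-6
                    )
                    if rng.random() < p.deisotoping_rate:
                        k = int(rng.choice([-2, -1, 1, 2], p=[0.1, 0.4, 0.4, 0.1]))
                        mass += k * ISOTOPE_SPACING
                    noise = np.exp(rng.normal(0, sigma_ln)) if sigma_ln > 0 else 1.0
                    frt = obs_rt + (rng.normal(0, p.rt_jitter_sd_min) if p.rt_jitter_sd_min > 0 else 0.0)
                    frt = max(frt, 0.0)
                    features[key].append(
                        MS1Feature(
                            run_id=s.sample_id,
                            cv=cv,
                            mono_mass=mass,
                            rt_apex=frt,
                            rt_start=max(frt - 0.5, 0.0),
                            rt_end=frt + 0.5,
                            abundance=float(base * w * noise),
                            charge_min=5,
                            charge_max=15,
                        )
                    )
                # --- PrSMs ---
                n_prsm = 3 + int(rng.poisson(p.prsm_rate)) + (1 if si == 0 else 0)
                for engine, table, seen in (
                    ("toppic", toppic, pf.in_toppic),
                    ("tdportal", tdportal, pf.in_tdportal),
                ):
                    if not seen:
                        continue
                    n = n_prsm if engine == "toppic" else max(1, n_prsm // 2)
                    for _ in range(n):
                        scan += 1
                        if engine == "tdportal":
                            # PTM-database engines report the database
                            # (theoretical) monoisotopic mass: constant
                            # across runs, no calibration error
                            mass = pf.mono_mass
                        else:
                            mass = pf.mono_mass * (
                                1.0
                                + (s.ppm_offset + (rng.normal(0, p.mass_jitter_ppm_sd) if p.mass_jitter_ppm_sd > 0 else 0.0))
                                * 1e-6
                            )
                        rt = obs_rt + (rng.normal(0, p.rt_jitter_sd_min) if p.rt_jitter_sd_min > 0 else 0.0)
                        evalue = float(10 ** rng.uniform(-15, -2))
                        table[key].append(
                            PrSMRecord(
                                run_id=s.sample_id,
                                cv=cv,
                                scan=scan,
                                rt_min=max(rt, 0.0),
                                precursor_mass=mass,
                                adjusted_mass=mass,
                                charge=int(rng.integers(5, 16)),
                                evalue=evalue,
                                accession=pf.accession,
                                # TopPIC-style exports carry no gene column
                                gene=pf.gene if engine == "tdportal" else None,
                                qvalue=float(10 ** rng.uniform(-6, -2.1)),
                                intensity=float(base * w),
                                proteoform=pf.annotation,
                                first_residue=1,
                                last_residue=max(
                                    1, sum(c.isalpha() for c in pf.annotation.split("[")[0])
                                ),
                                engine=engine,
                                modifications=list(mods),
                            )
                        )
    return SimulatedTables(toppic, tdportal, features, truth)


def simulate_maldi(
    truth: GroundTruth,
    top_k: int = 20,
    mode: str = "monoisotopic",
    n_noise_peaks: int = 10,
    mz_range: tuple[float, float] = (3500.0, 20000.0),
) -> tuple[MaldiPeakList, list[LibraryEntry]]:
    """A MALDI peak list: low-charge peaks of the top_k most abundant
    proteoforms (charges 1-2, within the m/z window) plus random noise
    peaks, and the matching true library entries."""
    rng = _rng(truth.seed, 2)
    ranked = sorted(truth.proteoforms, key=lambda pf: -pf.base_abundance)[:top_k]
    entries = [LibraryEntry(annotation=pf.annotation, mono_mass=pf.mono_mass) for pf in ranked]
    peaks: dict[float, float] = {}
    for pf, entry in zip(ranked, entries):
        for z in (1, 2):
            mz = predicted_mz(entry, z, mode=mode)
            if mz_range[0] <= mz <= mz_range[1]:
                peaks[mz] = peaks.get(mz, 0.0) + pf.base_abundance / z
    true_mzs = np.array(sorted(peaks)) if peaks else np.array([])
    n_added = 0
    while n_added < n_noise_peaks:
        mz = float(rng.uniform(*mz_range))
        # keep noise well away from true peaks so it stays unannotatable
        if len(true_mzs) and np.min(np.abs(true_mzs - mz) / true_mzs) * 1e6 < 500:
            continue
        peaks[mz] = float(np.exp(rng.normal(math.log(1e5), 0.5)))
        n_added += 1
    mzs = sorted(peaks)
    return (
        MaldiPeakList(
            mz=mzs, intensity=[peaks[m] for m in mzs], mz_range=mz_range
        ),
        entries,
    )


def write_tables(
    tables: SimulatedTables, out_dir, maldi: Optional[MaldiPeakList] = None
) -> dict[str, list[str]]:
    """Write every simulated table in its on-disk dialect under ``out_dir``.

    File names follow the per-CV raw-file convention ("<sample>_CV40_...").
    Returns the written paths grouped by kind.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, list[str]] = {"toppic": [], "tdportal": [], "features": [], "maldi": []}
    for (sample, cv), recs in sorted(tables.toppic_prsms.items()):
        p = out / f"{sample}_CV{abs(cv)}_toppic_prsm.tsv"
        io_tables.write_prsm_table(recs, p, io_tables.TOPPIC_DIALECT)
        paths["toppic"].append(str(p))
    for (sample, cv), recs in sorted(tables.tdportal_prsms.items()):
        p = out / f"{sample}_CV{abs(cv)}_tdportal.tsv"
        io_tables.write_prsm_table(recs, p, io_tables.TDPORTAL_DIALECT)
        paths["tdportal"].append(str(p))
    for (sample, cv), feats in sorted(tables.features.items()):
        p = out / f"{sample}_CV{abs(cv)}.ms1ft"
        io_tables.write_promex_features(feats, p)
        paths["features"].append(str(p))
    if maldi is not None:
        p = out / "maldi_peaks.txt"
        io_tables.write_maldi_peaks(maldi, p)
        paths["maldi"].append(str(p))
    tables.truth.to_json(out / "truth.json")
    return paths
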