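"""Config-driven end-to-end orchestration.

Stage order: read -> protein FDR filter -> per-CV RT alignment and mass
recalibration -> PfC clustering -> ambiguity classification -> cross-run
feature alignment -> feature grouping -> ID collapsing -> ID/group matching
with conflict resolution -> quantitation (filter, normalize, log2, impute)
-> differential test -> PCA.  Every stage logs its input/output record
counts; identical config + seed reproduces identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field, replace as dc_replace
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import calibration, grouping, io_tables, pfc as pfc_mod, quant
from .records import ISOTOPE_SPACING

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All inputs, tolerances and switches of one pipeline run."""

    toppic_paths: list[str] = dc_field(default_factory=list)
    tdportal_paths: list[str] = dc_field(default_factory=list)
    feature_paths: list[str] = dc_field(default_factory=list)
    sample_groups: dict[str, str] = dc_field(default_factory=dict)
    group_a: str = "cortex"
    group_b: str = "hypothalamus"
    mass_tol_ppm: float = 15.0
    rt_tol_min: float = 4.0
    mass_group_da: float = 1.0
    isotope_spacing: float = ISOTOPE_SPACING
    min_prsm: int = 3
    min_samples: int = 2
    fdr: float = 0.01
    impute_width: float = 0.3
    impute_downshift: float = 1.8
    loess_frac: float = 0.5
    use_adjusted_mass: bool = False
    equal_var_ttest: bool = True
    seed: int = 0
    output_dir: Optional[str] = None

    def validate(self) -> None:
        for name in (
            "mass_tol_ppm", "rt_tol_min", "mass_group_da", "isotope_spacing",
            "impute_width", "impute_downshift", "fdr",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for group in ("toppic_paths", "tdportal_paths", "feature_paths"):
            for p in getattr(self, group):
                if not Path(p).exists():
                    raise ConfigError(f"input file not found: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        try:
            obj = yaml.safe_load(Path(path).read_text())
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(str(exc)) from exc
        if not isinstance(obj, dict):
            raise ConfigError("config must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(obj) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**obj)

    def to_yaml(self, path) -> None:
        obj = {k: getattr(self, k) for k in self.__dataclass_fields__}
        Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


@dataclass
class PipelineResult:
    """Everything one run produces, in memory."""

    config: PipelineConfig
    pfcs: list
    feature_groups: list
    collapsed_ids: list
    qm_raw: quant.QuantMatrix
    qm_imputed: quant.QuantMatrix
    differential: pd.DataFrame
    pca_scores: pd.DataFrame
    alignment_models: dict
    counts: dict[str, int] = dc_field(default_factory=dict)


def _read_stage(config: PipelineConfig):
    toppic: dict[tuple, list] = {}
    tdportal: dict[tuple, list] = {}
    features: dict[tuple, list] = {}
    for paths, reader, store in (
        (config.toppic_paths, io_tables.read_toppic_prsms, toppic),
        (config.tdportal_paths, io_tables.read_tdportal_table, tdportal),
        (config.feature_paths, io_tables.read_promex_features, features),
    ):
        for p in paths:
            run_id, cv = io_tables.parse_run_cv(p, strict=False)
            recs = reader(p)
            store.setdefault((run_id, cv), []).extend(recs)
    return toppic, tdportal, features


def run_pipeline(
    config: PipelineConfig,
    toppic_prsms: Optional[dict] = None,
    tdportal_prsms: Optional[dict] = None,
    features: Optional[dict] = None,
) -> PipelineResult:
    """Run the full pipeline from a config (and/or in-memory tables).

    In-memory tables, keyed ``(run_id, cv)``, take precedence over file
    paths in the config; this is how the simulator feeds the pipeline
    without touching disk.
    """
    config.validate()
    counts: dict[str, int] = {}

    def stage(name):
        logger.info("stage %s", name)
        return name

    name = stage("read")
    try:
        if toppic_prsms is None and tdportal_prsms is None and features is None:
            toppic_prsms, tdportal_prsms, features = _read_stage(config)
        toppic_prsms = {k: list(v) for k, v in (toppic_prsms or {}).items()}
        tdportal_prsms = {k: list(v) for k, v in (tdportal_prsms or {}).items()}
        features = {k: list(v) for k, v in (features or {}).items()}
    except (OSError, io_tables.TableFormatError, ValueError) as exc:
        raise StageError(name, str(exc)) from exc
    counts["prsms_toppic_in"] = sum(len(v) for v in toppic_prsms.values())
    counts["prsms_tdportal_in"] = sum(len(v) for v in tdportal_prsms.values())
    counts["features_in"] = sum(len(v) for v in features.values())
    logger.info(
        "read %d TopPIC PrSMs, %d TDPortal records, %d features",
        counts["prsms_toppic_in"], counts["prsms_tdportal_in"], counts["features_in"],
    )

    name = stage("fdr_filter")
    try:
        for store, label in ((toppic_prsms, "toppic"), (tdportal_prsms, "tdportal")):
            pooled = [p for v in store.values() for p in v]
            if not pooled:
                continue
            kept = pfc_mod.filter_protein_fdr(pooled, config.fdr, strict=False)
            kept_ids = {id(p) for p in kept}
            for key in store:
                store[key] = [p for p in store[key] if id(p) in kept_ids]
            counts[f"prsms_{label}_fdr"] = len(kept)
    except ValueError as exc:
        raise StageError(name, str(exc)) from exc

    name = stage("calibrate")
    try:
        toppic_prsms, features_cal, models = calibration.calibrate_all_runs(
            toppic_prsms, features, frac=config.loess_frac
        )
        # the same per-(run, CV) warps align the second engine's RTs; its
        # masses are the engine's database (theoretical) monoisotopic masses
        # and carry no per-run calibration error, so they are not recalibrated
        for key, recs in tdportal_prsms.items():
            if key in models:
                tdportal_prsms[key] = calibration.apply_rt_warp(recs, models[key].warp)
    except ValueError as exc:
        raise StageError(name, str(exc)) from exc
    counts["features_calibrated"] = sum(len(v) for v in features_cal.values())

    name = stage("cluster_pfcs")
    all_toppic = [p for v in toppic_prsms.values() for p in v]
    pfcs = pfc_mod.cluster_prsms(
        all_toppic,
        mass_tol_ppm=config.mass_tol_ppm,
        rt_tol_min=config.rt_tol_min,
        min_size=config.min_prsm,
        use_adjusted=config.use_adjusted_mass,
    )
    counts["pfcs"] = sum(1 for c in pfcs if not c.is_noise)
    counts["pfcs_noise"] = sum(1 for c in pfcs if c.is_noise)
    assert sum(len(c.members) for c in pfcs) == len(all_toppic)
    logger.info("%d PfCs (+%d noise clusters)", counts["pfcs"], counts["pfcs_noise"])

    name = stage("classify")
    levels = {c.pfc_id: pfc_mod.classify_level(c.representative).level for c in pfcs}

    name = stage("align_features")
    try:
        cvs = sorted({cv for (_, cv) in features_cal}, key=lambda v: (v is None, v))
        aligned_by_cv = {}
        for cv in cvs:
            per_run = {}
            for (run, c), feats in features_cal.items():
                if c == cv:
                    per_run[run] = feats
            aligned_by_cv[cv] = grouping.align_features_across_runs(
                per_run, config.mass_tol_ppm, config.rt_tol_min
            )
    except ValueError as exc:
        raise StageError(name, str(exc)) from exc

    name = stage("group_features")
    groups = grouping.build_feature_groups(
        aligned_by_cv, config.mass_group_da, config.mass_tol_ppm, config.rt_tol_min
    )
    counts["feature_groups"] = len(groups)
    counts["features_grouped"] = sum(g.count for g in groups)
    if counts["features_grouped"] != counts["features_calibrated"]:
        raise StageError(name, "feature count not conserved through grouping")

    name = stage("collapse_ids")
    all_td = [p for v in tdportal_prsms.values() for p in v]
    collapsed = grouping.collapse_ids(pfcs, all_td)
    collapsed = [
        cid if cid.source != "toppic" else dc_replace(cid, level=levels.get(cid.key))
        for cid in collapsed
    ]
    counts["collapsed_ids"] = len(collapsed)

    name = stage("match_ids")
    groups = grouping.annotate_feature_groups(
        groups,
        collapsed,
        mass_tol_ppm=config.mass_tol_ppm,
        rt_tol_min=config.rt_tol_min,
        isotope_spacing_da=config.isotope_spacing,
    )
    counts["groups_annotated"] = sum(1 for g in groups if g.id_annotation is not None)

    name = stage("quant")
    try:
        qm_raw = quant.QuantMatrix.from_feature_groups(groups, config.sample_groups)
        qm = quant.filter_min_samples(qm_raw, config.min_samples)
        counts["quant_rows"] = len(qm.data)
        qm = quant.normalize_median(qm)
        qm = quant.log2_transform(qm)
        qm_imp = quant.impute_downshifted(
            qm, config.impute_width, config.impute_downshift, seed=config.seed
        )
    except ValueError as exc:
        raise StageError(name, str(exc)) from exc

    name = stage("test")
    try:
        diff = quant.ttest_unpaired(
            qm_imp, config.group_a, config.group_b, equal_var=config.equal_var_ttest
        )
    except ValueError as exc:
        raise StageError(name, str(exc)) from exc

    name = stage("pca")
    pca_scores = quant.run_pca(qm_imp)

    result = PipelineResult(
        config=config,
        pfcs=pfcs,
        feature_groups=groups,
        collapsed_ids=collapsed,
        qm_raw=qm_raw,
        qm_imputed=qm_imp,
        differential=diff,
        pca_scores=pca_scores,
        alignment_models=models,
        counts=counts,
    )
    if config.output_dir:
        write_outputs(result, config.output_dir)
    return result


def write_outputs(result: PipelineResult, out_dir) -> dict[str, str]:
    """Write the artifact set: quant table, differential table, PCA scores,
    audit dumps, and the stage-count log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    qm = result.qm_imputed.copy()
    merged = pd.concat([qm.annotations, qm.data, result.differential], axis=1)
    merged.index.name = "group_id"
    paths["quant_table"] = str(out / "quant_table.tsv")
    merged.to_csv(paths["quant_table"], sep="\t", na_rep="NA")

    paths["differential"] = str(out / "differential.tsv")
    d = result.differential.copy()
    d.index.name = "group_id"
    d.to_csv(paths["differential"], sep="\t", na_rep="NA")

    paths["pca_scores"] = str(out / "pca_scores.tsv")
    p = result.pca_scores.copy()
    p.index.name = "sample"
    p.to_csv(paths["pca_scores"], sep="\t")

    paths["pfc_audit"] = str(out / "pfc_members.tsv")
    with open(paths["pfc_audit"], "w") as fh:
        fh.write("pfc_id\taccession\tis_noise\tn_members\trun_id\tcv\tscan\tevalue\n")
        for c in result.pfcs:
            for m in c.members:
                fh.write(
                    f"{c.pfc_id}\t{c.accession}\t{int(c.is_noise)}\t{len(c.members)}\t"
                    f"{m.run_id}\t{m.cv}\t{m.scan}\t{m.evalue!r}\n"
                )

    paths["group_audit"] = str(out / "feature_groups.tsv")
    with open(paths["group_audit"], "w") as fh:
        fh.write(
            "group_id\tmass_group\trt_group\tconsensus_mass\tmean_rt\tcount\t"
            "annotation\tsource\tid_key\tshift\n"
        )
        for g in result.feature_groups:
            cid = g.id_annotation
            fh.write(
                f"{g.group_id}\t{g.mass_group}\t{g.rt_group}\t{g.consensus_mass!r}\t"
                f"{g.mean_rt!r}\t{g.count}\t"
                f"{cid.annotation if cid else 'NA'}\t{cid.source if cid else 'NA'}\t"
                f"{cid.key if cid else 'NA'}\t"
                f"{g.id_shift if g.id_shift is not None else 'NA'}\n"
            )

    paths["counts"] = str(out / "stage_counts.tsv")
    with open(paths["counts"], "w") as fh:
        fh.write("stage\tcount\n")
        for k, v in result.counts.items():
            fh.write(f"{k}\t{v}\n")
    return paths
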