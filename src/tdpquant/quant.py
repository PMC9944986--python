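"""Proteoform quantitation: filtering, normalization, imputation,
differential testing, and PCA.

The annotated feature groups become a proteoform x sample abundance matrix
that moves one-way through the stages raw -> normalized -> log2 -> imputed:

1. keep proteoforms observed in at least two samples;
2. normalize each sample's abundances to its median (all FAIMS CVs already
   combined upstream), rescaled so the common median is the grand median;
3. log2 transform;
4. impute missing cells from a downshifted normal — per sample, missing
   values are drawn from N(mu - 1.8 sigma, (0.3 sigma)^2) where mu and sigma
   describe that sample's observed log2 intensity distribution;
5. unpaired two-sample t-test between the two tissue-region groups, and PCA
   of the samples (also available on non-imputed data via pairwise-complete
   covariance).
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

STAGES = ("raw", "normalized", "log2", "imputed")

DEFAULT_IMPUTE_WIDTH = 0.3
DEFAULT_IMPUTE_DOWNSHIFT = 1.8


class QuantMatrix:
    """A proteoform x sample abundance matrix with annotations.

    ``data`` holds abundances (rows: feature groups, columns: samples) with
    NaN for missing; ``annotations`` carries per-row metadata (proteoform
    annotation, consensus mass, mean RT, member count, ...);
    ``sample_groups`` maps each sample to its region label.  ``stage``
    records how far along the raw -> normalized -> log2 -> imputed pipeline
    the values are; transitions are one-way.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        annotations: Optional[pd.DataFrame] = None,
        sample_groups: Optional[dict[str, str]] = None,
        stage: str = "raw",
    ):
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        self.data = data.astype(float)
        self.annotations = (
            annotations if annotations is not None else pd.DataFrame(index=data.index)
        )
        self.sample_groups = dict(sample_groups or {})
        self.stage = stage

    # -- construction -------------------------------------------------------

    @classmethod
    def from_feature_groups(
        cls,
        groups: Sequence,
        sample_groups: Optional[dict[str, str]] = None,
        annotated_only: bool = True,
        include_noise: bool = False,
    ) -> "QuantMatrix":
        """Build the raw matrix from annotated feature groups.

        By default only groups carrying a (non-noise) identification enter
        quantitation; the noise cluster is excluded from quantitative
        analysis.
        """
        rows = []
        ann_rows = []
        index = []
        for g in groups:
            cid = g.id_annotation
            if annotated_only and cid is None:
                continue
            if cid is not None and cid.is_noise and not include_noise:
                continue
            index.append(g.group_id)
            rows.append(dict(g.per_sample_abundance))
            ann_rows.append(
                {
                    "annotation": cid.annotation if cid else "",
                    "accession": cid.accession if cid else "",
                    "source": cid.source if cid else "",
                    "id_key": cid.key if cid else "",
                    "evalue": cid.evalue if cid else np.nan,
                    "has_unknown_shift": cid.has_unknown_shift if cid else False,
                    "isotope_shift": g.id_shift if cid else np.nan,
                    "level": cid.level if cid else "",
                    "consensus_mass": g.consensus_mass,
                    "mean_rt": g.mean_rt,
                    "count": g.count,
                }
            )
        samples = sorted(sample_groups) if sample_groups else sorted(
            {s for r in rows for s in r}
        )
        data = pd.DataFrame(rows, index=index, columns=samples, dtype=float)
        ann = pd.DataFrame(ann_rows, index=index)
        return cls(data, ann, sample_groups, stage="raw")

    # -- helpers ------------------------------------------------------------

    def _advance(self, new_stage: str) -> None:
        if STAGES.index(new_stage) < STAGES.index(self.stage):
            raise ValueError(f"stage transition {self.stage} -> {new_stage} is one-way")
        self.stage = new_stage

    def copy(self) -> "QuantMatrix":
        qm = QuantMatrix(
            self.data.copy(), self.annotations.copy(), dict(self.sample_groups), self.stage
        )
        return qm

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def samples_in_group(self, label: str) -> list[str]:
        return [s for s in self.data.columns if self.sample_groups.get(s) == label]

    # -- serialization ------------------------------------------------------

    def to_tsv(self, path) -> None:
        """Annotations + per-sample abundances (+ any attached statistics),
        one row per feature group, "NA" for missing, losslessly re-readable."""
        out = pd.concat([self.annotations, self.data], axis=1)
        out.index.name = "group_id"
        out.to_csv(path, sep="\t", na_rep="NA")

    @classmethod
    def from_tsv(cls, path, sample_groups: Optional[dict[str, str]] = None,
                 stage: str = "raw") -> "QuantMatrix":
        df = pd.read_csv(path, sep="\t", index_col="group_id", na_values=["NA"])
        if sample_groups:
            samples = [s for s in df.columns if s in sample_groups]
        else:
            samples = [c for c in df.columns if c.startswith("sample")]
        ann = df[[c for c in df.columns if c not in samples]]
        return cls(df[samples], ann, sample_groups, stage=stage)


# ---------------------------------------------------------------------------
# pipeline steps (each returns a new QuantMatrix)

def filter_min_samples(qm: QuantMatrix, k: int = 2) -> QuantMatrix:
    """Keep rows observed (pre-imputation) in at least ``k`` samples."""
    observed = qm.data.notna().sum(axis=1)
    keep = observed >= k
    dropped = int((~keep).sum())
    logger.info("min-samples filter (k=%d): kept %d rows, dropped %d",
                k, int(keep.sum()), dropped)
    out = qm.copy()
    out.data = qm.data.loc[keep]
    out.annotations = qm.annotations.loc[keep]
    return out


def normalize_median(qm: QuantMatrix) -> QuantMatrix:
    """Normalize each sample's abundances to that sample's median.

    Each observed value is divided by its sample median, then rescaled by
    the grand median of the sample medians so values stay on the intensity
    scale; afterwards every sample's median is the grand median.
    """
    if qm.stage != "raw":
        raise ValueError("normalize_median operates on the raw stage")
    medians = qm.data.median(axis=0, skipna=True)
    if (medians <= 0).any():
        raise ValueError("non-positive sample median; cannot normalize")
    grand = float(np.median(medians.values))
    out = qm.copy()
    out.data = qm.data.div(medians, axis=1) * grand
    out._advance("normalized")
    return out


def log2_transform(qm: QuantMatrix) -> QuantMatrix:
    """log2 of the (normalized) abundances; missing stays missing."""
    if (qm.data <= 0).any().any():
        raise ValueError("non-positive abundance; cannot log2 transform")
    out = qm.copy()
    out.data = np.log2(qm.data)
    out._advance("log2")
    return out


def impute_downshifted(
    qm: QuantMatrix,
    width: float = DEFAULT_IMPUTE_WIDTH,
    downshift: float = DEFAULT_IMPUTE_DOWNSHIFT,
    seed: int = 0,
) -> QuantMatrix:
    """Impute missing log2 cells from a downshifted normal, per sample.

    For each sample with observed mean mu and sd sigma, missing cells are
    drawn i.i.d. from Normal(mu - downshift * sigma, (width * sigma)^2).
    This places imputed values in the low tail of the sample's intensity
    distribution, emulating censoring at the detection limit.  Deterministic
    given ``seed``.
    """
    if qm.stage != "log2":
        raise ValueError("impute_downshifted operates on log2 values")
    rng = np.random.default_rng(seed)
    out = qm.copy()
    data = out.data
    for s in data.columns:
        col = data[s]
        miss = col.isna()
        if not miss.any():
            continue
        obs = col.dropna()
        mu, sigma = float(obs.mean()), float(obs.std(ddof=1))
        if not np.isfinite(sigma) or sigma == 0:
            sigma = 0.0
        draws = rng.normal(mu - downshift * sigma, width * sigma, size=int(miss.sum()))
        data.loc[miss, s] = draws
    out._advance("imputed")
    return out


# ---------------------------------------------------------------------------
# statistics

def ttest_unpaired(
    qm: QuantMatrix,
    group_a: str,
    group_b: str,
    equal_var: bool = True,
    bh_qvalues: bool = True,
) -> pd.DataFrame:
    """Row-wise unpaired two-sided t-test between two region groups.

    Operates on (imputed) log2 values.  Returns a DataFrame with
    ``log2fc`` (mean A - mean B), ``t``, ``p`` and, optionally,
    Benjamini-Hochberg ``q``.  The Student (equal-variance) form is the
    default; ``equal_var=False`` gives Welch.
    """
    cols_a = qm.samples_in_group(group_a)
    cols_b = qm.samples_in_group(group_b)
    if not cols_a or not cols_b:
        raise ValueError(f"empty group among {group_a!r}, {group_b!r}")
    a = qm.data[cols_a].values
    b = qm.data[cols_b].values
    import warnings

    with warnings.catch_warnings():
        # near-identical rows trigger a precision warning; such rows are
        # reported as t=0, p=1 below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    log2fc = np.nanmean(a, axis=1) - np.nanmean(b, axis=1)
    # zero-variance identical rows: difference 0 with no spread -> t=0, p=1
    degenerate = ~np.isfinite(t) & np.isclose(log2fc, 0.0)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    res = pd.DataFrame({"log2fc": log2fc, "t": t, "p": p}, index=qm.data.index)
    if bh_qvalues:
        finite = np.isfinite(res["p"].values)
        q = np.full(len(res), np.nan)
        if finite.any():
            q[finite] = multipletests(res["p"].values[finite], method="fdr_bh")[1]
        res["q"] = q
    return res


def run_pca(qm: QuantMatrix, n_components: int = 2) -> pd.DataFrame:
    """PCA of the samples on row-centered abundances.

    With complete (imputed) data this is the standard SVD of the
    sample x proteoform matrix after centering each proteoform.  With
    missing values (non-imputed data) the sample-sample covariance is
    computed pairwise-complete and eigendecomposed; scores are the scaled
    eigenvectors.  Returns one row per sample with columns PC1, PC2, ... and
    an ``explained_variance_ratio`` attribute in ``DataFrame.attrs``.
    """
    X = qm.data.values  # rows: proteoforms, cols: samples
    n_samples = X.shape[1]
    n_components = min(n_components, n_samples)
    centered = X - np.nanmean(X, axis=1, keepdims=True)
    if not np.isnan(X).any():
        # samples as observations
        U, s, Vt = np.linalg.svd(centered.T, full_matrices=False)
        scores = U[:, :n_components] * s[:n_components]
        var = s**2
    else:
        C = np.empty((n_samples, n_samples))
        for i in range(n_samples):
            for j in range(i, n_samples):
                both = ~np.isnan(centered[:, i]) & ~np.isnan(centered[:, j])
                if both.sum() < 2:
                    C[i, j] = C[j, i] = 0.0
                else:
                    C[i, j] = C[j, i] = float(
                        np.mean(centered[both, i] * centered[both, j])
                    )
        var, vec = np.linalg.eigh(C)
        order = np.argsort(var)[::-1]
        var = np.clip(var[order], 0, None)
        vec = vec[:, order]
        scores = vec[:, :n_components] * np.sqrt(var[:n_components])
    out = pd.DataFrame(
        scores,
        index=qm.data.columns,
        columns=[f"PC{i+1}" for i in range(n_components)],
    )
    total = var.sum()
    out.attrs["explained_variance_ratio"] = (
        (var[:n_components] / total).tolist() if total > 0 else [0.0] * n_components
    )
    out["group"] = [qm.sample_groups.get(s, "") for s in out.index]
    return out
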