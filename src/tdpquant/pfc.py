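"""Proteoform clustering (PfCs), representatives, noise rule, FDR filter,
and the five-level ambiguity classification.

After alignment and recalibration, PrSMs of the same accession that agree in
precursor mass (within 15 ppm of the smaller mass) and retention time
(within 4 min) are single-linkage clustered into proteoform clusters (PfCs),
each treated as one proteoform.  Clusters with fewer than three PrSMs are
pooled into a per-accession noise cluster whose id ends in "_0"; noise is
excluded from quantitation but still competes (at low priority) to annotate
feature groups.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from typing import Optional, Sequence

from .calibration import ppm_error
from .records import AmbiguityAssessment, ProteoformCluster, PrSMRecord

logger = logging.getLogger(__name__)

DEFAULT_MASS_TOL_PPM = 15.0
DEFAULT_RT_TOL_MIN = 4.0
DEFAULT_MIN_SIZE = 3


def prsms_link(
    a: PrSMRecord,
    b: PrSMRecord,
    mass_tol_ppm: float = DEFAULT_MASS_TOL_PPM,
    rt_tol_min: float = DEFAULT_RT_TOL_MIN,
    use_adjusted: bool = False,
) -> bool:
    """Two PrSMs link iff mass agrees within tolerance (ppm evaluated against
    the smaller mass — symmetric and conservative) and RT within tolerance."""
    ma = _cluster_mass(a, use_adjusted)
    mb = _cluster_mass(b, use_adjusted)
    small, big = min(ma, mb), max(ma, mb)
    return (
        abs(ppm_error(big, small)) <= mass_tol_ppm
        and abs(a.rt_min - b.rt_min) <= rt_tol_min
    )


def _cluster_mass(p: PrSMRecord, use_adjusted: bool) -> float:
    if use_adjusted and p.adjusted_mass is not None:
        return p.adjusted_mass
    return p.precursor_mass


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_prsms(
    prsms: Sequence[PrSMRecord],
    mass_tol_ppm: float = DEFAULT_MASS_TOL_PPM,
    rt_tol_min: float = DEFAULT_RT_TOL_MIN,
    min_size: int = DEFAULT_MIN_SIZE,
    use_adjusted: bool = False,
) -> list[ProteoformCluster]:
    """Partition PrSMs into proteoform clusters.

    PrSMs are first partitioned by accession, then single-linkage clustered
    under the pairwise link rule.  Clusters smaller than ``min_size`` are
    merged into that accession's noise cluster ("<accession>_0").  The result
    is a partition: every PrSM belongs to exactly one PfC.

    ``use_adjusted`` clusters on the engine's shift-adjusted mass instead of
    the precursor mass (the adjusted mass folds unknown shifts back in, which
    merges modified forms and is kept as an option for comparison).
    """
    by_acc: dict[str, list[PrSMRecord]] = defaultdict(list)
    for p in prsms:
        by_acc[p.accession].append(p)

    clusters: list[ProteoformCluster] = []
    for acc in sorted(by_acc):
        group = sorted(
            by_acc[acc],
            key=lambda p: (_cluster_mass(p, use_adjusted), p.rt_min, p.run_id, p.scan),
        )
        n = len(group)
        uf = _UnionFind(n)
        # sorted by mass: once the mass gap alone exceeds tolerance, stop
        for i in range(n):
            mi = _cluster_mass(group[i], use_adjusted)
            for j in range(i + 1, n):
                if ppm_error(_cluster_mass(group[j], use_adjusted), mi) > mass_tol_ppm:
                    break
                if prsms_link(group[i], group[j], mass_tol_ppm, rt_tol_min, use_adjusted):
                    uf.union(i, j)
        comps: dict[int, list[PrSMRecord]] = defaultdict(list)
        for i, p in enumerate(group):
            comps[uf.find(i)].append(p)
        noise: list[PrSMRecord] = []
        kept = []
        for root in sorted(comps):
            members = comps[root]
            if len(members) >= min_size:
                kept.append(members)
            else:
                noise.extend(members)
        for k, members in enumerate(kept, start=1):
            rep = select_representative_of(members)
            clusters.append(
                ProteoformCluster(
                    pfc_id=f"{acc}_{k}",
                    accession=acc,
                    members=members,
                    representative=rep,
                    is_noise=False,
                )
            )
        if noise:
            rep = select_representative_of(noise)
            clusters.append(
                ProteoformCluster(
                    pfc_id=f"{acc}_0",
                    accession=acc,
                    members=noise,
                    representative=rep,
                    is_noise=True,
                )
            )
    return clusters


def select_representative_of(members: Sequence[PrSMRecord]) -> PrSMRecord:
    """The cluster representative.

    Among the distinct proteoform strings in the cluster, the one backed by
    the most PrSMs wins; ties go to the proteoform with the lowest E-value.
    The representative PrSM is that proteoform's lowest-E-value PrSM.
    """
    counts = Counter(p.proteoform for p in members)
    best_by_form: dict[str, PrSMRecord] = {}
    for p in members:
        cur = best_by_form.get(p.proteoform)
        if cur is None or p.evalue < cur.evalue:
            best_by_form[p.proteoform] = p
    winner = min(
        counts,
        key=lambda form: (-counts[form], best_by_form[form].evalue, form),
    )
    return best_by_form[winner]


def select_representative(pfc: ProteoformCluster) -> PrSMRecord:
    return select_representative_of(pfc.members)


def filter_protein_fdr(
    prsms: Sequence[PrSMRecord], threshold: float = 0.01, strict: bool = True
) -> list[PrSMRecord]:
    """Protein-level FDR filter.

    Keeps records of proteins whose protein-level q-value is <= threshold.
    Engines here report per-record q-values, so the protein q-value is
    approximated as the minimum q-value over the protein's PrSMs (the
    protein's best-supported identification).  With no q-values at all,
    strict mode raises; lenient mode keeps everything with a logged caveat.
    """
    if not any(p.qvalue is not None for p in prsms):
        if strict:
            raise ValueError("no q-value column present; cannot FDR-filter")
        logger.warning("no q-values present; protein FDR filter skipped")
        return list(prsms)
    protein_q: dict[str, float] = {}
    for p in prsms:
        if p.qvalue is None:
            continue
        q = protein_q.get(p.accession)
        protein_q[p.accession] = p.qvalue if q is None else min(q, p.qvalue)
    kept = [p for p in prsms if protein_q.get(p.accession, 1.0) <= threshold]
    logger.info("protein FDR <= %g: kept %d / %d PrSMs", threshold, len(kept), len(prsms))
    return kept


def classify_level(
    representative: PrSMRecord,
    gene_map: Optional[dict[str, Sequence[str]]] = None,
) -> AmbiguityAssessment:
    """Five-level ambiguity classification of a cluster representative.

    - An unknown mass shift makes both the PTM identity and its localization
      ambiguous (the open search reports a shift, not a PTM or a site).
    - A named PTM without a confident site makes localization alone ambiguous.
    - Gene ambiguity: the accession maps to more than one gene in
      ``gene_map``.  Without a map the flag stays False (logged caveat).
    - Sequence ambiguity is never asserted: each engine reports one sequence.
    """
    unknown = representative.has_unknown_shift
    unlocalized_named = any(
        m.name is not None and not m.localized for m in representative.modifications
    )
    if gene_map is None:
        gene_amb = False
        logger.debug("no accession->gene map; gene ambiguity assumed absent")
    else:
        genes = gene_map.get(representative.accession, [])
        gene_amb = len(set(genes)) > 1
    return AmbiguityAssessment(
        ptm_localization_ambiguous=unknown or unlocalized_named,
        ptm_identity_ambiguous=unknown,
        sequence_ambiguous=False,
        gene_ambiguous=gene_amb,
    )
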