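"""Feature alignment, chain grouping, ID collapsing, matching, conflicts."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tdpquant.grouping import (
    CollapsedID,
    MatchCandidate,
    align_features_across_runs,
    annotate_feature_groups,
    assign_mass_groups,
    assign_rt_groups,
    build_feature_groups,
    collapse_ids,
    match_id_to_group,
    ppm_error,
    resolve_conflicts,
    FeatureGroup,
)
from tdpquant.pfc import cluster_prsms
from tdpquant.records import ISOTOPE_SPACING

from conftest import make_feature, make_prsm


@pytest.mark.parametrize(
    "obs,ref,expected",
    [(1000.0, 1000.0, 0.0), (10000.15, 10000.0, 15.0), (4999.925, 5000.0, -15.0)],
)
def test_ppm_error(obs, ref, expected):
    assert ppm_error(obs, ref) == pytest.approx(expected)


def oracle_chain(values, gaps_ok):
    """Explicit chain scan: new group whenever the predecessor gap violates."""
    groups, g = [], -1
    prev = None
    for v in values:
        if prev is None or not gaps_ok(prev, v):
            g += 1
        groups.append(g)
        prev = v
    return groups


class TestMassGroups:
    def test_chaining_within_ppm(self):
        masses = [5000.000, 5000.030, 5000.060]  # successive gaps 6 ppm
        assert assign_mass_groups(masses) == [0, 0, 0]

    def test_gap_beyond_ppm_splits(self):
        assert assign_mass_groups([5000.000, 5000.090]) == [0, 1]  # 18 ppm

    def test_gap_beyond_da_splits(self):
        assert assign_mass_groups([50000.0, 50001.2]) == [0, 1]  # 1.2 Da > 1 Da

    def test_unsorted_raises(self):
        with pytest.raises(ValueError):
            assign_mass_groups([2.0, 1.0])

    def test_random_instances_match_chain_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(0, 101))
            masses = np.sort(rng.uniform(5000, 5010, size=n)).tolist()
            expected = oracle_chain(
                masses, lambda a, b: (b - a) <= 1.0 and ppm_error(b, a) <= 15.0
            )
            assert assign_mass_groups(masses) == expected


class TestRtGroups:
    def test_examples(self):
        assert assign_rt_groups([10.0, 13.9, 18.0]) == [0, 0, 1]
        assert assign_rt_groups([0.0, 4.0, 8.0, 12.0]) == [0, 0, 0, 0]  # inclusive
        assert assign_rt_groups([]) == []

    def test_random_instances_match_chain_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(0, 101))
            rts = np.sort(rng.uniform(0, 120, size=n)).tolist()
            assert assign_rt_groups(rts) == oracle_chain(rts, lambda a, b: b - a <= 4.0)


class TestAlignAcrossRuns:
    def test_identical_runs_no_na(self):
        feats = [make_feature(mono_mass=5000.0 + 10 * i, rt_apex=10.0 + i) for i in range(5)]
        out = align_features_across_runs({"A": feats, "B": feats})
        assert len(out) == 5
        assert not out[["A", "B"]].isna().any().any()

    def test_missing_feature_one_na(self):
        feats = [make_feature(mono_mass=5000.0 + 10 * i, rt_apex=10.0 + i) for i in range(5)]
        out = align_features_across_runs({"A": feats, "B": feats[:-1]})
        assert int(out["B"].isna().sum()) == 1 and int(out["A"].isna().sum()) == 0

    def test_unmatched_appended_as_new_rows(self):
        a = [make_feature(mono_mass=5000.0)]
        b = [make_feature(mono_mass=9000.0, run_id="B")]
        out = align_features_across_runs({"A": a, "B": b})
        assert len(out) == 2

    def test_simulated_correspondence_recovered(self, rng):
        """3 runs, 100 true features, 10% dropout: >=98% correct matches."""
        true_mass = rng.uniform(4000, 25000, size=100)
        true_rt = rng.uniform(10, 110, size=100)
        per_run = {}
        truth_cells = {}
        for run in ("R1", "R2", "R3"):
            feats = []
            for i in range(100):
                if rng.random() < 0.10:
                    continue
                feats.append(
                    make_feature(
                        run_id=run,
                        mono_mass=float(true_mass[i] * (1 + rng.normal(0, 1e-6))),
                        rt_apex=float(true_rt[i] + rng.normal(0, 0.1)),
                        abundance=float(1000 + i),  # encodes the true index
                    )
                )
                truth_cells[(run, 1000.0 + i)] = i
            per_run[run] = feats
        out = align_features_across_runs(per_run)
        correct = total = 0
        for _, row in out.iterrows():
            idx = {
                truth_cells[(run, row[run])]
                for run in ("R1", "R2", "R3")
                if pd.notna(row[run])
            }
            total += sum(pd.notna(row[run]) for run in ("R1", "R2", "R3"))
            # all members of the row should share one true index
            correct += (
                sum(pd.notna(row[run]) for run in ("R1", "R2", "R3"))
                if len(idx) == 1
                else 0
            )
        assert correct / total >= 0.98


class TestBuildFeatureGroups:
    def test_single_feature(self):
        aligned = align_features_across_runs({"A": [make_feature()]})
        groups = build_feature_groups({-40: aligned})
        assert len(groups) == 1
        g = groups[0]
        assert g.count == 1 and g.consensus_mass == 10000.0

    def test_summary_fields(self):
        feats = {
            "A": [make_feature(mono_mass=10000.00, rt_apex=30.0, abundance=10.0)],
            "B": [make_feature(run_id="B", mono_mass=10000.05, rt_apex=31.0, abundance=20.0)],
        }
        groups = build_feature_groups({-40: align_features_across_runs(feats)})
        assert len(groups) == 1
        g = groups[0]
        assert g.consensus_mass == 10000.05  # max member mass
        assert g.mean_rt == pytest.approx(30.5)
        assert g.per_sample_abundance == {"A": 10.0, "B": 20.0}

    def test_feature_count_and_abundance_conserved(self, small_tables):
        from tdpquant.calibration import calibrate_all_runs

        _, feats_cal, _ = calibrate_all_runs(
            small_tables.toppic_prsms, small_tables.features
        )
        total_in = sum(len(v) for v in feats_cal.values())
        cvs = {cv for (_, cv) in feats_cal}
        aligned = {}
        sum_in = 0.0
        for cv in cvs:
            per_run = {r: f for (r, c), f in feats_cal.items() if c == cv}
            sum_in += sum(x.abundance or 0.0 for f in per_run.values() for x in f)
            aligned[cv] = align_features_across_runs(per_run)
        groups = build_feature_groups(aligned)
        assert sum(g.count for g in groups) == total_in
        sample_cols = sorted({r for (r, _) in feats_cal})
        sum_out = sum(
            float(g.rows[s].sum(skipna=True)) for g in groups for s in sample_cols
        )
        assert sum_out == pytest.approx(sum_in, rel=1e-9)

    def test_recovered_group_count_close_to_truth(self):
        """200 true proteoforms, 9 samples x 3 CVs, dropout but no
        deisotoping errors: group count within +/-2% of truth."""
        from tdpquant import synthdata
        from tdpquant.calibration import calibrate_all_runs

        params = synthdata.SynthParams(deisotoping_rate=0.0)
        truth = synthdata.generate_truth(200, seed=21, params=params)
        tables = synthdata.simulate_tables(truth)
        _, feats_cal, _ = calibrate_all_runs(tables.toppic_prsms, tables.features)
        aligned = {}
        for cv in {-30, -40, -50}:
            per_run = {r: f for (r, c), f in feats_cal.items() if c == cv}
            aligned[cv] = align_features_across_runs(per_run)
        groups = build_feature_groups(aligned)
        assert abs(len(groups) - 200) <= 0.02 * 200


class TestCollapseIds:
    def test_empty(self):
        assert collapse_ids([], []) == []

    def test_one_pfc_one_id(self):
        clusters = cluster_prsms([make_prsm(scan=i) for i in range(3)])
        ids = collapse_ids(clusters, [])
        assert len(ids) == 1 and ids[0].source == "toppic"
        assert ids[0].key == clusters[0].pfc_id

    def test_noise_pfc_keyed_with_zero_suffix(self):
        clusters = cluster_prsms([make_prsm()])
        ids = collapse_ids(clusters, [])
        assert ids[0].is_noise and ids[0].key.endswith("_0")

    def test_tdportal_lowest_evalue_wins(self):
        rows = [
            make_prsm(engine="tdportal", scan=1, evalue=1e-8, proteoform="GOOD"),
            make_prsm(engine="tdportal", scan=2, evalue=1e-3, proteoform="BAD"),
        ]
        ids = collapse_ids([], rows)
        assert len(ids) == 1
        assert ids[0].evalue == 1e-8 and ids[0].annotation == "GOOD"


def _group(mass, rt, gi=0):
    return FeatureGroup(
        group_id=f"FG{gi}", mass_group=gi, rt_group=0,
        consensus_mass=mass, mean_rt=rt, count=1,
    )


def _cid(mass=11000.0, rt=30.0, evalue=1e-8, unknown=False, noise=False, source="toppic"):
    return CollapsedID(
        source=source, key="K_1" if not noise else "K_0", mass=mass, rt=rt,
        evalue=evalue, has_unknown_shift=unknown, annotation="X", is_noise=noise,
    )


class TestMatchIdToGroup:
    def test_plus_one_isotope_shift(self):
        groups = [_group(11001.002, 30.0)]
        cands = match_id_to_group(_cid(mass=11000.0, rt=29.0), groups)
        assert len(cands) == 1
        assert cands[0].shift == 1
        assert abs(cands[0].residual_ppm) < 1.0

    def test_equal_masses_zero_shift(self):
        cands = match_id_to_group(_cid(), [_group(11000.0, 30.0)])
        assert cands[0].shift == 0 and cands[0].residual_ppm == 0.0

    def test_three_da_away_no_match(self):
        assert match_id_to_group(_cid(), [_group(11003.0, 30.0)]) == []

    def test_rt_window_excludes(self):
        assert match_id_to_group(_cid(rt=40.0), [_group(11000.0, 30.0)]) == []
        assert match_id_to_group(_cid(rt=34.0), [_group(11000.0, 30.0)])  # inclusive 4

    def test_zero_shift_preferred(self):
        # group mass matches both k=0 (exactly) and nothing else
        cands = match_id_to_group(_cid(mass=11000.0), [_group(11000.0, 30.0)])
        assert cands[0].shift == 0


class TestResolveConflicts:
    def test_empty(self):
        assert resolve_conflicts([]) is None

    def test_clean_beats_unknown_despite_evalue(self):
        clean = MatchCandidate(_cid(evalue=1e-4), 0, 0, 0.0, 0)
        dirty = MatchCandidate(_cid(evalue=1e-9, unknown=True), 0, 0, 0.0, 1)
        assert resolve_conflicts([dirty, clean]) is clean

    def test_non_noise_beats_noise(self):
        noise = MatchCandidate(_cid(evalue=1e-12, noise=True), 0, 0, 0.0, 0)
        real = MatchCandidate(_cid(evalue=1e-5), 0, 0, 0.0, 1)
        assert resolve_conflicts([noise, real]) is real

    def test_smaller_evalue_wins(self):
        a = MatchCandidate(_cid(evalue=1e-10), 0, 0, 0.0, 0)
        b = MatchCandidate(_cid(evalue=1e-5), 0, 0, 0.0, 1)
        assert resolve_conflicts([b, a]) is a

    def test_full_priority_order_exhaustive(self):
        """All 8 (unknown, noise, E-value) flag combinations: the winner is
        always the lexicographic minimum of the priority tuple."""
        combos = list(itertools.product([False, True], [False, True], [1e-10, 1e-4]))
        cands = [
            MatchCandidate(_cid(evalue=e, unknown=u, noise=n), 0, 0, 0.0, i)
            for i, (u, n, e) in enumerate(combos)
        ]
        for subset_size in (2, 3, len(cands)):
            for subset in itertools.combinations(cands, subset_size):
                win = resolve_conflicts(list(subset))
                expected = min(
                    subset,
                    key=lambda c: (c.cid.has_unknown_shift, c.cid.is_noise, c.cid.evalue,
                                   c.input_order),
                )
                assert win is expected


def test_deisotoping_robustness(rng):
    """20% of features reported one isotope off: >=95% of the affected
    proteoforms' IDs still match their true feature group."""
    n = 200
    mass = rng.uniform(4000, 25000, size=n)
    rt = rng.uniform(10, 110, size=n)
    shifted = rng.random(n) < 0.20
    feats = {
        "A": [
            make_feature(
                mono_mass=float(m + (ISOTOPE_SPACING * (1 if rng.random() < 0.5 else -1) if s else 0.0)),
                rt_apex=float(t),
                abundance=float(i),
            )
            for i, (m, t, s) in enumerate(zip(mass, rt, shifted))
        ]
    }
    aligned = align_features_across_runs(feats)
    groups = build_feature_groups({-40: aligned})
    ids = [_cid(mass=float(m), rt=float(t)) for m, t in zip(mass, rt)]
    n_affected = n_matched = 0
    for i, cid in enumerate(ids):
        if not shifted[i]:
            continue
        n_affected += 1
        cands = match_id_to_group(cid, groups)
        # the true group is the one holding this feature's abundance index
        for c in cands:
            g = groups[c.group_index]
            if g.rows is not None and (g.rows["A"] == float(i)).any():
                n_matched += 1
                break
    assert n_affected > 20
    assert n_matched / n_affected >= 0.95


def test_annotate_feature_groups_one_winner_each(small_tables):
    from tdpquant.calibration import calibrate_all_runs

    prsms, feats_cal, _ = calibrate_all_runs(
        small_tables.toppic_prsms, small_tables.features
    )
    pfcs = cluster_prsms([p for v in prsms.values() for p in v])
    all_td = [p for v in small_tables.tdportal_prsms.values() for p in v]
    aligned = {}
    for cv in {-30, -40, -50}:
        per_run = {r: f for (r, c), f in feats_cal.items() if c == cv}
        aligned[cv] = align_features_across_runs(per_run)
    groups = build_feature_groups(aligned)
    ids = collapse_ids(pfcs, all_td)
    groups = annotate_feature_groups(groups, ids)
    assert all(g.id_annotation is None or isinstance(g.id_annotation, CollapsedID) for g in groups)
    # most groups should be identified in this fully-covered simulation
    frac = sum(g.id_annotation is not None for g in groups) / len(groups)
    assert frac > 0.8
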