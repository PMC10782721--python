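"""Landscape statistics: brute-force agreement, identities, edge cases."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mthet import landscape as L


def make_events(rows):
    return pd.DataFrame(rows, columns=L.EVENT_COLUMNS)


def random_events(rng, n_donors=8, n_positions=30, n_events=60):
    donors = [f"D{i}" for i in range(n_donors)]
    positions = rng.choice(np.arange(1, 16570), size=n_positions, replace=False)
    rows, seen = [], set()
    for _ in range(n_events):
        d = rng.choice(donors)
        t = rng.choice(["buccal", "blood"])
        p = int(rng.choice(positions))
        if (d, t, p) in seen:
            continue
        seen.add((d, t, p))
        rows.append({"donor_id": d, "tissue": t, "position": p,
                     "major_allele": "C", "minor_allele": "T",
                     "maf": float(np.exp(rng.uniform(np.log(0.001), np.log(0.5))))})
    return make_events(rows)


class TestAggregateEvents:
    def test_empty_input_is_all_zero(self):
        _, counts = L.aggregate_events(make_events([]))
        assert all(v == 0 for v in counts.values())

    def test_single_php_in_both_tissues(self):
        ev = make_events([
            {"donor_id": "D1", "tissue": "buccal", "position": 152,
             "major_allele": "T", "minor_allele": "C", "maf": 0.004},
            {"donor_id": "D1", "tissue": "blood", "position": 152,
             "major_allele": "T", "minor_allele": "C", "maf": 0.002},
        ])
        _, counts = L.aggregate_events(ev)
        assert counts["events_total"] == 2
        assert counts["positions_total"] == 1
        assert counts["positions_both"] == 1

    def test_sum_identities_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            ev = random_events(rng)
            _, c = L.aggregate_events(ev)
            assert c["positions_total"] == (c["positions_both"]
                                            + c["positions_buccal_only"]
                                            + c["positions_blood_only"])
            assert c["events_total"] == c["events_buccal"] + c["events_blood"]

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(7)
        ev = random_events(rng)
        _, c = L.aggregate_events(ev)
        # naive recomputation straight off the event table
        assert c["events_total"] == len(ev)
        pos_tissues = ev.groupby("position").tissue.apply(lambda s: frozenset(s))
        assert c["positions_both"] == sum(
            t == {"buccal", "blood"} for t in pos_tissues)


class TestRegionDistribution:
    def test_hotspot_positions_are_all_cr(self):
        from mthet.io import read_hotspot_fixture

        tab = read_hotspot_fixture()
        ev = make_events([
            {"donor_id": f"D{i}", "tissue": "blood", "position": int(p),
             "major_allele": "C", "minor_allele": "T", "maf": 0.01}
            for i, p in enumerate(tab.position)])
        dist = L.region_distribution(ev)
        assert dist.loc["control_region", "fraction_positions"] == 1.0
        assert dist.loc["control_region", "fraction_events"] == 1.0

    def test_distributions_sum_to_one(self):
        ev = random_events(np.random.default_rng(3))
        dist = L.region_distribution(ev)
        assert dist.fraction_positions.sum() == pytest.approx(1.0)
        assert dist.fraction_events.sum() == pytest.approx(1.0)

    def test_uniform_positions_match_length_ratio(self):
        # every 7th position, one event each: CR fraction ~ 1103/16569
        ev = make_events([
            {"donor_id": "D", "tissue": "blood", "position": p,
             "major_allele": "C", "minor_allele": "T", "maf": 0.01}
            for p in range(1, 16570, 7)])
        dist = L.region_distribution(ev)
        assert dist.loc["control_region", "fraction_positions"] == pytest.approx(
            1103 / 16569, abs=0.01)

    def test_single_event_is_degenerate(self):
        ev = make_events([{"donor_id": "D", "tissue": "blood", "position": 16093,
                           "major_allele": "T", "minor_allele": "C", "maf": 0.03}])
        dist = L.region_distribution(ev)
        assert list(dist.index) == ["control_region"]


class TestMafCutoffProfile:
    def test_boundary_uses_greater_or_equal(self):
        ev = make_events([{"donor_id": "D", "tissue": "blood", "position": 100,
                           "major_allele": "C", "minor_allele": "T", "maf": 0.004}])
        prof = L.maf_cutoff_profile(ev)
        at_005 = prof[prof.cutoff == 0.005]
        assert (at_005.n_php == 0).all()
        at_floor = prof[prof.cutoff == 0.001]
        assert (at_floor.n_php == 1).all()

    def test_count_two_at_ten_percent(self):
        ev = make_events([
            {"donor_id": "D", "tissue": "blood", "position": p,
             "major_allele": "C", "minor_allele": "T", "maf": m}
            for p, m in [(100, 0.12), (200, 0.30)]])
        prof = L.maf_cutoff_profile(ev, cutoffs=[0.10])
        assert prof.n_php.iloc[0] == 2

    def test_profile_matches_brute_force_and_is_monotone(self):
        rng = np.random.default_rng(11)
        ev = random_events(rng)
        prof = L.maf_cutoff_profile(ev)
        for row in prof.itertuples(index=False):
            naive = len(ev[(ev.donor_id == row.donor_id) & (ev.tissue == row.tissue)
                           & (ev.maf >= row.cutoff)])
            assert row.n_php == naive
        wide = prof.pivot_table(index=["donor_id", "tissue"], columns="cutoff",
                                values="n_php")
        diffs = wide.to_numpy()[:, 1:] - wide.to_numpy()[:, :-1]
        assert (diffs <= 0).all()

    def test_invalid_cutoffs(self):
        ev = random_events(np.random.default_rng(0))
        with pytest.raises(L.ParameterError):
            L.maf_cutoff_profile(ev, cutoffs=[0.0, 0.1])
        with pytest.raises(L.ParameterError):
            L.maf_cutoff_profile(ev, cutoffs=[0.6])


class TestHotspotTable:
    def test_pooled_median_pattern(self):
        # six events at one position across tissues of three donors,
        # median 3.0% over the pooled MAFs, range 1.6-12%
        mafs = [0.016, 0.024, 0.028, 0.032, 0.05, 0.12]
        rows = []
        for i, m in enumerate(mafs):
            rows.append({"donor_id": f"D{i // 2}", "tissue": ["buccal", "blood"][i % 2],
                         "position": 16093, "major_allele": "C",
                         "minor_allele": "T", "maf": m})
        tab = L.hotspot_table(make_events(rows))
        row = tab.iloc[0]
        assert row.position == 16093
        assert row.n_persons == 3
        assert row.total_php_count == 6
        assert row.median_maf == pytest.approx(0.03)  # midpoint of central pair
        assert row.min_maf == pytest.approx(0.016)
        assert row.max_maf == pytest.approx(0.12)
        assert row.locus == "MT-HV1"

    def test_single_person_positions_excluded(self):
        ev = make_events([
            {"donor_id": "D1", "tissue": "blood", "position": 100,
             "major_allele": "C", "minor_allele": "T", "maf": 0.01},
            {"donor_id": "D1", "tissue": "buccal", "position": 100,
             "major_allele": "C", "minor_allele": "T", "maf": 0.01},
        ])
        assert L.hotspot_table(ev).empty

    def test_requires_events(self):
        with pytest.raises(L.ParameterError):
            L.hotspot_table(make_events([]))

    def test_planted_hotspot_recovered(self):
        rng = np.random.default_rng(5)
        ev = random_events(rng, n_events=40)
        planted = make_events([
            {"donor_id": f"P{i}", "tissue": "blood", "position": 146,
             "major_allele": "T", "minor_allele": "C", "maf": 0.003}
            for i in range(4)])
        tab = L.hotspot_table(pd.concat([ev, planted], ignore_index=True))
        row = tab[tab.position == 146].iloc[0]
        assert row.n_persons >= 4 and row.total_php_count >= 4


class TestTissueSpecificity:
    def test_classifications(self):
        ev = make_events([
            {"donor_id": "D1", "tissue": "blood", "position": 146,
             "major_allele": "T", "minor_allele": "C", "maf": 0.004},
            {"donor_id": "D1", "tissue": "buccal", "position": 152,
             "major_allele": "T", "minor_allele": "C", "maf": 0.02},
            {"donor_id": "D2", "tissue": "blood", "position": 152,
             "major_allele": "T", "minor_allele": "C", "maf": 0.002},
            {"donor_id": "D2", "tissue": "buccal", "position": 152,
             "major_allele": "T", "minor_allele": "C", "maf": 0.002},
        ])
        per_donor, pref = L.tissue_specificity(ev)
        cls = {(r.donor_id, r.position): r.classification
               for r in per_donor.itertuples(index=False)}
        assert cls[("D1", 146)] == "blood_only"
        assert cls[("D1", 152)] == "buccal_only"
        assert cls[("D2", 152)] == "both"
        low = {(r.donor_id, r.position): r.low_level
               for r in per_donor.itertuples(index=False)}
        assert low[("D1", 146)] and not low[("D1", 152)]
        row152 = pref[pref.position == 152].iloc[0]
        assert row152.n_both == 1 and row152.n_buccal_only == 1

    def test_empty(self):
        per_donor, pref = L.tissue_specificity(make_events([]))
        assert per_donor.empty and pref.empty

    def test_matches_brute_force(self):
        ev = random_events(np.random.default_rng(9))
        per_donor, _ = L.tissue_specificity(ev)
        for r in per_donor.itertuples(index=False):
            tissues = set(ev[(ev.donor_id == r.donor_id)
                             & (ev.position == r.position)].tissue)
            expected = {frozenset({"buccal", "blood"}): "both",
                        frozenset({"buccal"}): "buccal_only",
                        frozenset({"blood"}): "blood_only"}[frozenset(tissues)]
            assert r.classification == expected


class TestLinkage:
    def test_identical_donor_sets_give_small_p(self):
        donors = [f"D{i}" for i in range(11)]
        rows = []
        for d in donors[:4]:
            for pos in (146, 16129):
                rows.append({"donor_id": d, "tissue": "blood", "position": pos,
                             "major_allele": "T", "minor_allele": "C", "maf": 0.004})
        ev = make_events(rows)
        res = L.linkage_test(ev, n_permutations=2000, rng_seed=1, donors=donors)
        (row,) = res.itertuples(index=False)
        assert row.observed == 4
        # exact null: overlap of two random 4-subsets of 11 donors
        exact = stats.hypergeom.sf(3, 11, 4, 4)
        assert row.p_value == pytest.approx(exact, abs=0.005)

    def test_forced_overlap_is_not_significant(self):
        donors = [f"D{i}" for i in range(6)]
        rows = []
        for d in donors:  # position in all donors: any partner overlaps fully
            rows.append({"donor_id": d, "tissue": "blood", "position": 100,
                         "major_allele": "C", "minor_allele": "T", "maf": 0.01})
        for d in donors[:3]:
            rows.append({"donor_id": d, "tissue": "blood", "position": 200,
                         "major_allele": "C", "minor_allele": "T", "maf": 0.01})
        res = L.linkage_test(make_events(rows), n_permutations=500, rng_seed=2,
                             donors=donors)
        assert res.p_value.iloc[0] == 1.0

    def test_too_few_donors_unavailable(self):
        ev = make_events([{"donor_id": "D1", "tissue": "blood", "position": 100,
                           "major_allele": "C", "minor_allele": "T", "maf": 0.01}])
        assert L.linkage_test(ev, n_permutations=100, rng_seed=0).empty

    def test_minimum_permutations_enforced(self):
        with pytest.raises(L.ParameterError):
            L.linkage_test(random_events(np.random.default_rng(0)),
                           n_permutations=10, rng_seed=0)


class TestLongitudinal:
    def obs(self, rows):
        return pd.DataFrame(rows, columns=["donor_id", "tissue", "position",
                                           "timepoint", "maf", "minor_count",
                                           "depth"])

    def test_planted_loss_at_sufficient_depth(self):
        # MAF 3.6% at t1, zero minor reads later at 1400x: expected 50 >> 2
        o = self.obs([("D", "buccal", 3586, 1, 0.036, 280, 7746),
                      ("D", "buccal", 3586, 2, 0.0, 0, 1400),
                      ("D", "buccal", 3586, 3, 0.0, 0, 1400)])
        res = L.longitudinal_stability(o)
        assert res.status.iloc[0] == "lost"

    def test_dropout_is_unevaluable_not_lost(self):
        # zero minor reads at depth 10 after MAF 0.2%: expected 0.02 reads
        o = self.obs([("D", "blood", 5000, 1, 0.002, 15, 7746),
                      ("D", "blood", 5000, 2, 0.0, 0, 10)])
        res = L.longitudinal_stability(o)
        assert res.status.iloc[0] == "unevaluable"

    def test_gained_and_stable(self):
        o = self.obs([("D", "blood", 100, 1, 0.0, 0, 7746),
                      ("D", "blood", 100, 2, 0.01, 77, 7746),
                      ("D", "blood", 200, 1, 0.01, 77, 7746),
                      ("D", "blood", 200, 2, 0.012, 90, 7746)])
        res = L.longitudinal_stability(o).set_index("position")
        assert res.loc[100, "status"] == "gained"
        assert res.loc[200, "status"] == "stable"

    def test_single_timepoint_unevaluable(self):
        o = self.obs([("D", "blood", 100, 1, 0.01, 77, 7746)])
        assert L.longitudinal_stability(o).status.iloc[0] == "unevaluable"


class TestBloodBuccalRatio:
    def ev(self, buccal, blood):
        return make_events([
            {"donor_id": "D", "tissue": "buccal", "position": 152,
             "major_allele": "T", "minor_allele": "C", "maf": buccal},
            {"donor_id": "D", "tissue": "blood", "position": 152,
             "major_allele": "T", "minor_allele": "C", "maf": blood},
        ])

    def test_seventeen_fold_is_flagged(self):
        res = L.blood_buccal_ratio(self.ev(0.001, 0.017))
        assert res.ratio.iloc[0] == pytest.approx(17.0)
        assert bool(res.flagged.iloc[0])

    def test_equal_mafs_unflagged(self):
        res = L.blood_buccal_ratio(self.ev(0.01, 0.01))
        assert res.ratio.iloc[0] == pytest.approx(1.0)
        assert not bool(res.flagged.iloc[0])

    def test_zero_buccal_gives_infinite_sentinel(self):
        res = L.blood_buccal_ratio(self.ev(0.0, 0.01))
        assert np.isinf(res.ratio.iloc[0])

    def test_structural_pattern_six_of_33_pairs(self):
        # 33 both-tissue pairs, six with the higher MAF in blood
        rows = []
        for i in range(33):
            blood_higher = i < 6
            rows.append({"donor_id": f"D{i}", "tissue": "buccal", "position": 152,
                         "major_allele": "T", "minor_allele": "C",
                         "maf": 0.002 if blood_higher else 0.01})
            rows.append({"donor_id": f"D{i}", "tissue": "blood", "position": 152,
                         "major_allele": "T", "minor_allele": "C",
                         "maf": 0.01 if blood_higher else 0.002})
        res = L.blood_buccal_ratio(make_events(rows))
        assert (res.ratio > 1).sum() == 6
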