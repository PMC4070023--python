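"""Agreement statistics: CCC oracles, calibration, quintiles, tracking kappa."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss

from schoolva.stability import (AgreementError, between_year_table, lin_ccc,
                                pearson, proportion_constant_quintile,
                                quintile_track, quintiles, tracking_kappa,
                                within_year_table)


class TestLinCcc:
    def test_self_concordance_is_exactly_one(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0])
        assert lin_ccc(x, x).value == 1.0

    def test_perfect_reversal(self):
        assert lin_ccc([1, 2, 3], [3, 2, 1]).value == pytest.approx(-1.0)

    def test_hand_formula_scale_shift(self):
        # s_xy=2.5, s_x2=1.25, s_y2=5, (dx)^2=6.25 -> 2*2.5/12.5 = 0.4
        res = lin_ccc([1, 2, 3, 4], [2, 4, 6, 8])
        assert res.value == pytest.approx(0.4, abs=1e-12)

    def test_abs_ccc_never_exceeds_abs_r(self):
        rng = np.random.default_rng(13)
        for _ in range(500):
            n = rng.integers(4, 40)
            x = rng.normal(rng.normal(), rng.uniform(0.5, 2), n)
            y = rng.normal(rng.normal(), rng.uniform(0.5, 2), n)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            ccc = lin_ccc(x, y).value
            r = np.corrcoef(x, y)[0, 1]
            assert abs(ccc) <= abs(r) + 1e-12

    @settings(max_examples=100, deadline=None)
    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5), seed=st.integers(0, 10_000))
    def test_invariance_to_shared_positive_affine_map(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 20)
        y = rng.normal(0.3, 1.2, 20)
        base = lin_ccc(x, y).value
        mapped = lin_ccc(a * x + b, a * y + b).value
        assert mapped == pytest.approx(base, abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=30), rng.normal(size=30)
        assert lin_ccc(x, y).value == pytest.approx(lin_ccc(y, x).value)

    def test_ci_coverage_near_nominal(self):
        rng = np.random.default_rng(99)
        rho, n, reps = 0.6, 60, 500
        pop = 2 * rho / 2  # equal sd, no shift
        cover = 0
        for _ in range(reps):
            x = rng.normal(0, 1, n)
            y = rho * x + np.sqrt(1 - rho ** 2) * rng.normal(0, 1, n)
            res = lin_ccc(x, y)
            cover += res.ci_lower <= pop <= res.ci_upper
        assert 0.90 <= cover / reps <= 0.985

    def test_degenerate_input_rejected(self):
        with pytest.raises(AgreementError):
            lin_ccc([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        with pytest.raises(AgreementError):
            lin_ccc([1.0, 2.0], [1.0, 2.0])  # n < 3


class TestPearson:
    def test_location_scale_shift_keeps_r_at_one(self):
        r = pearson([1, 2, 3, 4], [2, 4, 6, 8])
        assert r.value == pytest.approx(1.0)
        assert lin_ccc([1, 2, 3, 4], [2, 4, 6, 8]).value == pytest.approx(0.4)

    def test_permutation_null_centred_on_zero(self):
        rng = np.random.default_rng(5)
        n, reps = 300, 300
        base = np.arange(n, dtype=float)
        rs = [pearson(base, rng.permutation(base)).value for _ in range(reps)]
        assert abs(np.mean(rs)) < 3 / np.sqrt(n - 1) / np.sqrt(reps) * 3 + 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(AgreementError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestQuintiles:
    def test_even_split(self):
        labels = quintiles(pd.Series(np.arange(1.0, 11.0)))
        assert labels.value_counts().tolist() == [2, 2, 2, 2, 2]

    def test_remainder_rule_303(self):
        labels = quintiles(pd.Series(np.arange(1.0, 304.0)))
        sizes = labels.value_counts().sort_index().tolist()
        assert sizes == [61, 61, 61, 60, 60]

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(1)
        ranks = pd.Series(rng.permutation(np.arange(1.0, 48.0)))
        labels = quintiles(ranks)
        ordered = labels[ranks.sort_values().index]
        assert np.all(np.diff(ordered.to_numpy()) >= 0)

    def test_too_few_rejected(self):
        with pytest.raises(AgreementError):
            quintiles(pd.Series([1.0, 2.0, 3.0]))


class TestTrackingKappa:
    def test_identical_labels_give_one(self):
        lab = pd.DataFrame(np.tile(np.repeat(np.arange(1, 6), 6), (4, 1)).T)
        assert tracking_kappa(lab).value == pytest.approx(1.0)

    def test_matches_statsmodels_fleiss(self):
        rng = np.random.default_rng(8)
        lab = pd.DataFrame(rng.integers(1, 6, size=(120, 5)))
        counts = np.stack([(lab.to_numpy() == c).sum(axis=1)
                           for c in range(1, 6)], axis=1)
        assert tracking_kappa(lab).value == pytest.approx(
            sm_fleiss(counts), abs=1e-12)

    def test_two_years_reduce_to_scott_pi(self):
        # hand-computed chance-corrected two-rater coefficient
        y1 = [1, 1, 2, 2, 3, 3, 4, 4, 5, 5, 1, 2]
        y2 = [1, 2, 2, 2, 3, 1, 4, 5, 5, 5, 1, 3]
        lab = pd.DataFrame({"a": y1, "b": y2})
        agree = np.mean([a == b for a, b in zip(y1, y2)])
        pooled = pd.Series(y1 + y2).value_counts(normalize=True)
        pe = float((pooled ** 2).sum())
        scott_pi = (agree - pe) / (1 - pe)
        assert tracking_kappa(lab).value == pytest.approx(scott_pi, abs=1e-12)

    def test_single_year_rejected(self):
        with pytest.raises(AgreementError):
            tracking_kappa(pd.DataFrame({"a": [1, 2, 3, 4, 5]}))

    def test_incomplete_schools_dropped(self):
        lab = pd.DataFrame({"a": [1, 2, 3, 4, 5, np.nan],
                            "b": [1, 2, 3, 4, 5, 1]})
        res = tracking_kappa(lab)
        assert res.n == 5
        assert res.value == pytest.approx(1.0)


class TestProportionConstant:
    def test_identical(self):
        lab = pd.DataFrame(np.tile([1, 2, 3, 4, 5], (3, 1)).T)
        assert proportion_constant_quintile(lab) == 1.0

    def test_one_mover_out_of_300(self):
        lab = pd.DataFrame(np.tile(np.repeat(np.arange(1, 6), 60), (5, 1)).T)
        lab.iloc[0, 2] = lab.iloc[0, 2] % 5 + 1
        assert proportion_constant_quintile(lab) == pytest.approx(299 / 300)


@pytest.fixture(scope="module")
def rankings(small_panel):
    from schoolva.league_tables import (expected_ranking, observed_ranking,
                                        value_added_ranking)
    out = {}
    for year in ("2006/07", "2007/08"):
        out[year] = {
            "observed": observed_ranking(small_panel, year),
            "expected": expected_ranking(small_panel, year),
            "value_added": value_added_ranking(small_panel, year),
        }
    return out


class TestAgreementTables:
    def test_within_year_matches_direct_ccc(self, rankings):
        yr = rankings["2006/07"]
        table = within_year_table(yr)
        row = table[(table["pair"] == "observed/expected")
                    & (table["statistic"] == "lin_ccc")].iloc[0]
        common = yr["observed"].table.index.intersection(yr["expected"].table.index)
        direct = lin_ccc(yr["observed"].table.loc[common, "rank"],
                         yr["expected"].table.loc[common, "rank"])
        assert row["value"] == pytest.approx(direct.value, abs=1e-12)

    def test_within_year_symmetric_in_pair_order(self, rankings):
        yr = rankings["2006/07"]
        a = yr["observed"].table["rank"]
        b = yr["expected"].table["rank"]
        assert lin_ccc(a, b).value == pytest.approx(lin_ccc(b, a).value)

    def test_missing_type_rejected(self, rankings):
        partial = {k: v for k, v in rankings["2006/07"].items()
                   if k != "value_added"}
        with pytest.raises(AgreementError):
            within_year_table(partial)

    def test_between_year_diagonal_is_exactly_one(self, rankings):
        obs = {y: rankings[y]["observed"] for y in rankings}
        table = between_year_table(obs)
        diag = table[table["pair"].isin(["2006/07/2006/07",
                                         "2007/08/2007/08"])]
        assert (diag["value"] == 1.0).all()

    def test_between_year_matches_direct_ccc(self, rankings):
        obs = {y: rankings[y]["observed"] for y in rankings}
        table = between_year_table(obs)
        row = table[table["pair"] == "2006/07/2007/08"].iloc[0]
        a, b = obs["2006/07"].table, obs["2007/08"].table
        common = a.index.intersection(b.index)
        direct = lin_ccc(a.loc[common, "rank"], b.loc[common, "rank"])
        assert row["value"] == pytest.approx(direct.value, abs=1e-12)

    def test_quintile_track_consistency(self, rankings):
        obs = {y: rankings[y]["observed"] for y in rankings}
        track = quintile_track(obs)
        assert set(track.labels.columns) == set(obs)
        assert 0.0 <= track.proportion_constant <= 1.0
        assert -1.0 <= track.kappa.value <= 1.0
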