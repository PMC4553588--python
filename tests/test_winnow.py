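import numpy as np
import pandas as pd
import pytest

from tagwinnow.errors import ConsistencyError, ParameterError
from tagwinnow.winnow import pearson_r, winnow_all, winnow_group

from oracle import pearson_brute, pearson_scipy, winnow_rescan


def _profiles(**rows):
    return pd.DataFrame.from_dict(rows, orient="index")


class TestPearson:
    def test_self_correlation_is_one(self):
        assert pearson_r((302, 1969, 6633), (302, 1969, 6633)) == 1.0

    def test_perfect_anticorrelation(self):
        assert pearson_r((1, 2, 3), (3, 2, 1)) == pytest.approx(-1.0)

    @pytest.mark.parametrize(
        "a,b",
        [
            ((302, 1969, 6633), (4, 156, 587)),  # published PGRP vs Attacin counts
            ((66, 58, 844), (395, 19, 72)),
            ((0, 19, 65), (10, 60, 0)),
        ],
    )
    def test_matches_independent_formula(self, a, b):
        assert pearson_r(a, b) == pytest.approx(pearson_brute(a, b), abs=1e-12)
        assert pearson_r(a, b) == pytest.approx(pearson_scipy(list(a), list(b)), abs=1e-12)

    def test_zero_variance_identical_is_one(self):
        assert pearson_r((5, 5, 5), (5, 5, 5)) == 1.0

    def test_zero_variance_nonidentical_is_undefined(self):
        assert pearson_r((5, 5, 5), (1, 2, 3)) is None
        assert pearson_r((5, 5, 5), (7, 7, 7)) is None

    def test_length_mismatch_rejected(self):
        with pytest.raises(ConsistencyError):
            pearson_r((1, 2), (1, 2, 3))

    def test_single_treatment_rejected(self):
        with pytest.raises(ConsistencyError):
            pearson_r((1,), (2,))


class TestWinnowGroup:
    def test_singleton_survives_with_zero_rounds(self):
        gw = winnow_group(_profiles(c1=(3, 4, 5)))
        assert gw.survivors == ["c1"] and gw.rounds == 0

    def test_higher_hit_member_of_identical_pair_retained(self):
        gw = winnow_group(_profiles(big=(50, 30, 20), small=(25, 15, 10)))
        assert gw.survivors == ["big"]
        assert gw.ledger == [("small", "big", 1.0)]

    def test_chained_correlation_resolved_by_greedy_rule(self):
        # r(A,B) ~ 0.9935 and r(B,C) ~ 0.9937 above threshold, r(A,C) ~ 0.974
        # below it; hit totals A > B > C
        profiles = {
            "A": (0, 100, 200),
            "B": (0, 60, 100),
            "C": (0, 14, 20),
        }
        gw = winnow_group(pd.DataFrame.from_dict(profiles, orient="index"), 0.99)
        survivors, ledger = winnow_rescan(profiles, 0.99)
        assert gw.survivors == ["A"]  # B and C fold into A's group representative
        assert sorted(gw.survivors) == survivors
        assert [(d, k) for d, k, _ in gw.ledger] == [(d, k) for d, k, _ in ledger]
        for (_, _, r1), (_, _, r2) in zip(gw.ledger, ledger):
            assert r1 == pytest.approx(r2, abs=1e-12)

    def test_zero_variance_members_never_collapse_unless_identical(self):
        gw = winnow_group(_profiles(flat5=(5, 5, 5), flat7=(7, 7, 7), other=(1, 9, 2)))
        assert sorted(gw.survivors) == ["flat5", "flat7", "other"]
        gw2 = winnow_group(_profiles(flat5=(5, 5, 5), flat5b=(5, 5, 5)))
        assert gw2.survivors == ["flat5"]  # hit tie -> lexicographically larger dropped

    def test_threshold_above_one_rejected(self):
        with pytest.raises(ParameterError, match="r_threshold"):
            winnow_group(_profiles(c1=(1, 2, 3)), r_threshold=1.5)

    def test_threshold_one_collapses_proportional_profiles(self):
        gw = winnow_group(_profiles(a=(1, 2, 3), b=(2, 4, 6), c=(1, 9, 2)), r_threshold=1.0)
        assert sorted(gw.survivors) == ["b", "c"]


class TestWinnowAll:
    def test_singleton_groups_are_identity(self):
        counts = _profiles(c1=(1, 2, 3), c2=(9, 1, 4))
        counts.columns = ["control", "bacterial", "fungal"]
        res = winnow_all({"A": {"c1"}, "B": {"c2"}}, counts)
        pd.testing.assert_frame_equal(res.counts, counts)
        assert res.ledger == {}

    def test_zero_fragment_noise_collapses_each_group_to_one(self, small_params):
        # at zero fragment noise, fragments of one transcript have exactly
        # proportional expected profiles (distinct depths, same shape), so
        # within-group r = 1 forces a single survivor; every transcript is
        # regulated so no profile is flat
        import dataclasses

        from tagwinnow.simulate import simulate_catalogue
        from tagwinnow.grouping import group_by_accession

        params = dataclasses.replace(
            small_params, fragment_corr_noise=0.0, frac_up=0.6, frac_down=0.4
        )
        contigs, truth = simulate_catalogue(params)
        lam = params.depth_per_treatment / truth.contig_expression["control"].sum()
        counts = (truth.contig_expression * lam).round().astype("int64")
        groups, _ = group_by_accession(contigs)
        res = winnow_all(groups, counts)
        assert res.n_survivors == len(groups)
        # every dropped contig resolves to its group's single survivor
        for acc, members in groups.items():
            (survivor,) = res.survivors[acc]
            assert all(res.resolve(m) == survivor for m in members)

    def test_missing_group_member_raises(self):
        counts = _profiles(c1=(1, 2, 3))
        with pytest.raises(ConsistencyError, match="c2"):
            winnow_all({"A": {"c1", "c2"}}, counts)

    def test_survivor_keeps_own_counts_not_sum(self):
        counts = _profiles(big=(50, 30, 20), small=(25, 15, 10))
        res = winnow_all({"A": {"big", "small"}}, counts)
        assert list(res.counts.index) == ["big"]
        assert res.counts.loc["big"].tolist() == [50, 30, 20]


class TestWinnowProperties:
    """Idempotence, fixed point, permutation determinism, oracle agreement."""

    @staticmethod
    def _random_group(rng, n_members):
        """Random integer profiles with deliberate redundant structure."""
        ids = [f"g{i}" for i in range(n_members)]
        profiles = {}
        base = rng.integers(0, 30, size=3)
        for i, cid in enumerate(ids):
            kind = rng.random()
            if kind < 0.3 and i > 0:  # exact duplicate of an earlier member
                profiles[cid] = profiles[ids[rng.integers(0, i)]]
            elif kind < 0.5:  # noisy copy of the shared base profile
                profiles[cid] = tuple(
                    int(max(0, v)) for v in base + rng.integers(-3, 4, size=3)
                )
            else:
                profiles[cid] = tuple(int(v) for v in rng.integers(0, 30, size=3))
        return profiles

    def test_agrees_with_rescan_oracle_on_random_groups(self, rng):
        for _ in range(200):
            profiles = self._random_group(rng, int(rng.integers(1, 7)))
            frame = pd.DataFrame.from_dict(profiles, orient="index")
            gw = winnow_group(frame, 0.8)
            survivors, _ = winnow_rescan(profiles, 0.8)
            assert sorted(gw.survivors) == survivors

    def test_idempotent_and_fixed_point(self, rng):
        for _ in range(50):
            profiles = self._random_group(rng, 6)
            frame = pd.DataFrame.from_dict(profiles, orient="index")
            gw = winnow_group(frame, 0.8)
            again = winnow_group(frame.loc[sorted(gw.survivors)], 0.8)
            assert sorted(again.survivors) == sorted(gw.survivors)
            for a in gw.survivors:
                for b in gw.survivors:
                    if a < b:
                        r = pearson_r(frame.loc[a], frame.loc[b])
                        assert r is None or r < 0.8

    def test_row_order_does_not_change_outcome(self, rng):
        for _ in range(50):
            profiles = self._random_group(rng, 6)
            frame = pd.DataFrame.from_dict(profiles, orient="index")
            shuffled = frame.sample(frac=1, random_state=int(rng.integers(2**31)))
            a = winnow_group(frame, 0.8)
            b = winnow_group(shuffled, 0.8)
            assert a.survivors == b.survivors and a.ledger == b.ledger
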