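import numpy as np
import pandas as pd
import pytest

from methylage.errors import MatchingFailureError
from methylage.matching import (
    age_balance_p,
    balance_tests,
    draw_many,
    draw_matched,
    draws_to_tsv,
    sex_balance_p,
)

from _oracles import welch_oracle


def make_group(ages, sexes=None, prefix="g"):
    n = len(ages)
    return pd.DataFrame(
        {
            "sample_id": [f"{prefix}{i:04d}" for i in range(n)],
            "sex": sexes if sexes is not None else ["female"] * n,
            "age_years": np.asarray(ages, dtype=float),
        }
    )


def uniform_group(n, lo=10, hi=65, seed=0, female_frac=0.6, prefix="g"):
    rng = np.random.default_rng(seed)
    sexes = np.where(rng.random(n) < female_frac, "female", "male")
    return make_group(rng.uniform(lo, hi, n), sexes, prefix=prefix)


class TestBalanceTests:
    def test_identical_groups_are_perfectly_balanced(self):
        g = uniform_group(40, seed=1)
        p_age, p_sex = balance_tests(g, g.copy())
        assert p_age == pytest.approx(1.0)
        assert p_sex == 1.0

    def test_gross_age_shift_detected(self):
        ref = uniform_group(83, seed=2)
        shifted = ref.copy()
        shifted["age_years"] += 30.0
        p_age, _ = balance_tests(shifted, ref)
        assert p_age < 0.001

    def test_welch_p_matches_hand_computed_oracle(self):
        a = [12.0, 25.0, 31.0, 44.0, 52.0, 19.0, 28.0, 35.0, 47.0, 61.0]
        b = [15.0, 22.0, 39.0, 41.0, 58.0, 24.0, 33.0, 38.0, 50.0, 44.0]
        _, _, p_oracle = welch_oracle(a, b)
        assert age_balance_p(a, b) == pytest.approx(p_oracle, rel=1e-8)

    def test_identical_constant_groups(self):
        assert age_balance_p([40.0] * 5, [40.0] * 5) == 1.0

    def test_ks_option(self):
        rng = np.random.default_rng(3)
        a, b = rng.uniform(10, 65, 80), rng.uniform(10, 65, 80)
        assert 0 < age_balance_p(a, b, method="ks") <= 1

    def test_single_sex_identical_composition(self):
        assert sex_balance_p(["female"] * 10, ["female"] * 10) == 1.0

    def test_single_sex_vs_mixed_detected(self):
        p = sex_balance_p(["female"] * 40, ["female"] * 20 + ["male"] * 20)
        assert p < 0.001

    def test_small_counts_use_exact_test(self):
        # expected counts < 5 -> Fisher; just confirm a sane p-value
        p = sex_balance_p(["female", "female", "male"], ["female", "male", "male"])
        assert 0 < p <= 1


class TestDrawMatched:
    def test_pool_equal_to_reference_accepts_whole_pool(self):
        ref = uniform_group(40, seed=4)
        draw = draw_matched(ref, ref.copy(), seed=0)
        assert draw.n_attempts == 1
        assert draw.p_age == pytest.approx(1.0)
        assert draw.p_sex == 1.0
        assert sorted(draw.indices.tolist()) == list(range(40))

    def test_sex_counts_match_reference_exactly(self):
        pool = uniform_group(287, seed=5, female_frac=0.55)
        ref = uniform_group(83, seed=6, female_frac=0.66, prefix="r")
        draw = draw_matched(pool, ref, seed=1)
        got = pool.iloc[draw.indices]["sex"].value_counts().to_dict()
        want = ref["sex"].value_counts().to_dict()
        assert got == want

    def test_determinism_and_seed_sensitivity(self):
        pool = uniform_group(287, seed=7)
        ref = uniform_group(83, seed=8, prefix="r")
        d1 = draw_matched(pool, ref, seed=9)
        d2 = draw_matched(pool, ref, seed=9)
        d3 = draw_matched(pool, ref, seed=10)
        np.testing.assert_array_equal(d1.indices, d2.indices)
        assert not np.array_equal(d1.indices, d3.indices)

    def test_acceptance_is_fast_for_same_distribution(self):
        """Matched source distributions: accepted within 10 attempts in >=99% of seeds."""
        pool = uniform_group(287, seed=11)
        ref = uniform_group(83, seed=12, prefix="r")
        quick = sum(
            draw_matched(pool, ref, seed=s).n_attempts <= 10 for s in range(1000)
        )
        assert quick >= 990

    def test_feasible_concentrated_reference(self):
        rng = np.random.default_rng(13)
        ref = make_group(rng.uniform(60, 65, 40), ["female"] * 20 + ["male"] * 20, prefix="r")
        # each sex stratum holds enough in-range donors; whole-subset rejection
        # sampling tolerates only light out-of-range contamination
        pool_ages = np.concatenate(
            [rng.uniform(60, 65, 25), rng.uniform(10, 60, 2)] * 2
        )
        pool = make_group(pool_ages, ["female"] * 27 + ["male"] * 27)
        draw = draw_matched(pool, ref, seed=2, max_attempts=5000)
        assert min(draw.p_age, draw.p_sex) > 0.3

    def test_infeasible_pool_raises_matching_failure(self):
        rng = np.random.default_rng(14)
        ref = make_group(rng.uniform(60, 65, 40), prefix="r")
        # all-young pool: no subsample can balance age at any attempt budget
        pool = make_group(rng.uniform(10, 20, 80))
        with pytest.raises(MatchingFailureError) as err:
            draw_matched(pool, ref, seed=3, max_attempts=50)
        assert err.value.best_p_age is not None

    def test_insufficient_sex_stratum_raises(self):
        ref = make_group([30.0] * 10, ["female"] * 5 + ["male"] * 5, prefix="r")
        pool = make_group([30.0] * 20, ["female"] * 18 + ["male"] * 2)
        with pytest.raises(MatchingFailureError, match="male"):
            draw_matched(pool, ref, seed=0)

    def test_rejection_strategy_also_balances(self):
        pool = uniform_group(287, seed=15)
        ref = uniform_group(83, seed=16, prefix="r")
        draw = draw_matched(pool, ref, seed=4, strategy="rejection")
        assert min(draw.p_age, draw.p_sex) > 0.3

    def test_acceptance_monotone_in_threshold(self):
        pool = uniform_group(287, seed=17)
        ref = uniform_group(83, seed=18, prefix="r")
        mean_attempts = []
        for threshold in (0.1, 0.3, 0.5, 0.7):
            attempts = [
                draw_matched(pool, ref, threshold=threshold, seed=s).n_attempts
                for s in range(200)
            ]
            mean_attempts.append(np.mean(attempts))
        assert all(a <= b + 1e-9 for a, b in zip(mean_attempts, mean_attempts[1:]))


class TestDrawMany:
    def test_all_draws_satisfy_threshold(self):
        pool = uniform_group(287, seed=19)
        ref = uniform_group(83, seed=20, prefix="r")
        draws = draw_many(pool, ref, runs=50, threshold=0.3, seed=5)
        assert len(draws) == 50
        assert all(min(d.p_age, d.p_sex) > 0.3 for d in draws)

    def test_determinism(self):
        pool = uniform_group(287, seed=21)
        ref = uniform_group(83, seed=22, prefix="r")
        a = draw_many(pool, ref, runs=3, seed=6)
        b = draw_many(pool, ref, runs=3, seed=6)
        for d1, d2 in zip(a, b):
            np.testing.assert_array_equal(d1.indices, d2.indices)

    def test_union_covers_most_of_a_feasible_pool(self):
        pool = uniform_group(287, seed=23)
        ref = uniform_group(83, seed=24, prefix="r")
        draws = draw_many(pool, ref, runs=500, seed=7)
        union = set()
        for d in draws:
            union.update(d.indices.tolist())
        assert len(union) > 0.9 * len(pool)

    def test_failure_reports_run_index(self):
        rng = np.random.default_rng(25)
        ref = make_group(rng.uniform(60, 65, 40), prefix="r")
        pool = make_group(rng.uniform(10, 20, 80))
        with pytest.raises(MatchingFailureError, match="run 0"):
            draw_many(pool, ref, runs=3, seed=8, max_attempts=20)

    def test_audit_tsv(self, tmp_path):
        pool = uniform_group(100, seed=26)
        ref = uniform_group(40, seed=27, prefix="r")
        draws = draw_many(pool, ref, runs=4, seed=9)
        path = tmp_path / "draws.tsv"
        draws_to_tsv(draws, pool, path)
        lines = path.read_text().splitlines()
        assert lines[0].split("\t") == ["run", "n_attempts", "p_age", "p_sex", "sample_ids"]
        assert len(lines) == 5
        assert len(lines[1].split("\t")[4].split(",")) == 40
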