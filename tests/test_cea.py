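"""CEA engine: dominance ladder vs brute-force oracle, NMB, OWSA, PSA,
PERT sampling."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crcsim.cea import (
    DOMINATED,
    EXTENDED_DOMINATED,
    UNDOMINATED,
    WTPSpec,
    build_icer_ladder,
    nmb,
    one_way_sa,
    run_psa,
    sample_distribution,
    sample_pert,
)


def frontier_oracle(df: pd.DataFrame):
    """Exhaustive pairwise-dominance + convex-frontier reference.

    Returns the set of undominated strategy names: points on the upper-left
    convex hull of (qalyg, cost) reachable with increasing ICERs.
    """
    rows = list(df.itertuples(index=False))
    # simple dominance (with the tie rule: equal rows keep the first)
    simple = []
    for i, r in enumerate(rows):
        beaten = any(
            (o.cost < r.cost and o.qalyg >= r.qalyg)
            or (o.cost <= r.cost and o.qalyg > r.qalyg)
            or (o.cost == r.cost and o.qalyg == r.qalyg and j < i)
            for j, o in enumerate(rows) if j != i
        )
        if not beaten:
            simple.append(r)
    # extended dominance: keep subsets forming a strictly increasing ICER chain
    # and pick the maximal frontier (every point on the upper convex hull)
    simple.sort(key=lambda r: (r.cost, -r.qalyg))
    frontier = set()
    for r in simple:
        others = [o for o in simple if o is not r]
        # r is extended-dominated iff a convex combination of two others
        # yields at least as many QALYG at no more cost
        dominated = False
        for a, b in itertools.combinations(others, 2):
            lo, hi = (a, b) if a.cost <= b.cost else (b, a)
            if not (lo.cost <= r.cost <= hi.cost) or hi.cost == lo.cost:
                continue
            t = (r.cost - lo.cost) / (hi.cost - lo.cost)
            mix_q = lo.qalyg + t * (hi.qalyg - lo.qalyg)
            if mix_q > r.qalyg + 1e-12:
                dominated = True
                break
        if not dominated:
            frontier.add(r.strategy)
    return frontier


def random_outcomes(rng, n=6):
    return pd.DataFrame({
        "strategy": [f"s{i}" for i in range(n)],
        "cost": np.round(rng.uniform(0, 10e6, n), 2),
        "qalyg": np.round(rng.uniform(0, 80, n), 3),
    })


class TestIcerLadder:
    def test_published_two_row_example(self):
        """CTC with more QALYG at lower cost than no screening is dominant."""
        df = pd.DataFrame({
            "strategy": ["no_screening", "ctc_only"],
            "cost": [8.10e6, 5.13e6],
            "qalyg": [0.0, 64.0],
        })
        ladder = build_icer_ladder(df)
        assert ladder.dominant == "ctc_only"
        statuses = dict(zip(ladder.table["strategy"], ladder.table["status"]))
        assert statuses["no_screening"] == DOMINATED
        assert ladder.cost_effective(100_000) == "ctc_only"

    def test_identical_rows_tie_rule(self):
        df = pd.DataFrame({
            "strategy": ["a", "b"],
            "cost": [1.0, 1.0],
            "qalyg": [1.0, 1.0],
        })
        table = build_icer_ladder(df).table
        statuses = dict(zip(table["strategy"], table["status"]))
        assert statuses["a"] == UNDOMINATED
        assert statuses["b"] == DOMINATED

    def test_matches_brute_force_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            df = random_outcomes(rng)
            ladder = build_icer_ladder(df)
            got = set(ladder.undominated()["strategy"])
            assert got == frontier_oracle(df)

    def test_undominated_rows_increase_in_both_axes_with_icers(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            und = build_icer_ladder(random_outcomes(rng)).undominated()
            assert und["cost"].is_monotonic_increasing
            assert und["qalyg"].is_monotonic_increasing
            icers = und["icer"].dropna().to_numpy()
            assert np.all(np.diff(icers) > 0)

    def test_invariant_to_row_order(self):
        rng = np.random.default_rng(2)
        df = random_outcomes(rng)
        a = build_icer_ladder(df).table
        b = build_icer_ladder(df.sample(frac=1, random_state=3)).table
        pd.testing.assert_frame_equal(a.reset_index(drop=True), b.reset_index(drop=True))

    def test_rejects_duplicates_and_singletons(self):
        df = pd.DataFrame({"strategy": ["a", "a"], "cost": [1, 2], "qalyg": [1, 2]})
        with pytest.raises(ValueError, match="unique"):
            build_icer_ladder(df)
        with pytest.raises(ValueError, match="two strategies"):
            build_icer_ladder(df.iloc[:1])

    def test_nmb_argmax_agrees_with_ladder_rule(self):
        """For deterministic outcomes the max-NMB strategy equals the
        ladder's cost-effective pick at the same WTP."""
        rng = np.random.default_rng(4)
        for _ in range(50):
            df = random_outcomes(rng)
            ladder = build_icer_ladder(df)
            for wtp in (20_000, 100_000, 400_000):
                by_nmb = df.loc[(wtp * df["qalyg"] - df["cost"]).idxmax(), "strategy"]
                assert ladder.cost_effective(wtp) == by_nmb


class TestNMB:
    def test_zero_wtp_is_negative_cost(self):
        assert nmb(5.0, 123.0, 0.0) == -123.0

    def test_zero_qalyg(self):
        assert nmb(0.0, 50.0, 100_000) == -50.0

    def test_published_scale_arithmetic(self):
        # 64 QALYG and $5.13M per 1000 at $100,000/QALYG
        assert nmb(64.0, 5.13e6, 100_000) == pytest.approx(64 * 100_000 - 5.13e6)

    def test_rejects_negative_wtp(self):
        with pytest.raises(ValueError):
            nmb(1.0, 1.0, -1.0)


class TestPert:
    def test_mean_matches_formula(self):
        """PERT(min, mode, max) mean is (min + 4 mode + max) / 6."""
        rng = np.random.default_rng(5)
        n = 100_000
        draws = np.array([sample_pert(3.45, 2.94, 4.0, rng) for _ in range(n)])
        expected = (2.94 + 4 * 3.45 + 4.0) / 6
        assert abs(draws.mean() - expected) < 3 * draws.std() / math.sqrt(n)
        assert draws.min() >= 2.94 and draws.max() <= 4.0

    def test_degenerate_returns_constant(self):
        rng = np.random.default_rng(6)
        assert sample_pert(2.0, 2.0, 2.0, rng) == 2.0

    def test_symmetric_case_centered(self):
        rng = np.random.default_rng(7)
        n = 100_000
        draws = np.array([sample_pert(0.5, 0.0, 1.0, rng) for _ in range(n)])
        assert abs(draws.mean() - 0.5) < 3 * draws.std() / math.sqrt(n)

    def test_rejects_bad_ordering(self):
        with pytest.raises(ValueError):
            sample_pert(5.0, 2.0, 3.0, np.random.default_rng(0))

    def test_distribution_spec_dispatch(self):
        rng = np.random.default_rng(8)
        assert 0 <= sample_distribution(("beta", 2, 5), rng) <= 1
        assert 2.94 <= sample_distribution(("pert", 2.94, 3.45, 4.0), rng) <= 4.0
        assert sample_distribution(("fixed", 0.5), rng) == 0.5
        with pytest.raises(ValueError):
            sample_distribution(("gamma", 1, 1), rng)


class TestOneWaySA:
    @staticmethod
    def _toy_evaluate(param, value):
        # closed-form toy: focal qalyg rises linearly with the parameter
        return {"ctc_only": (value, 100.0), "status_quo": (1.0, 50.0)}

    def test_degenerate_range_zero_swing(self):
        rows = one_way_sa(self._toy_evaluate, {"p": (2.0, 2.0)}, wtp=10.0)
        assert rows[0].swing == 0.0

    def test_swing_matches_closed_form(self):
        rows = one_way_sa(self._toy_evaluate, {"p": (1.0, 3.0)}, wtp=10.0)
        # incremental NMB = 10 v - 100 - (10 - 50) -> swing = 10 (3 - 1)
        assert rows[0].swing == pytest.approx(20.0)
        assert rows[0].nmb_low == pytest.approx(10 * 1 - 100 + 40)

    def test_rows_sorted_by_swing_top_k(self):
        ranges = {f"p{i}": (0.0, float(i)) for i in range(12)}

        def evaluate(param, value):
            return {"ctc_only": (value, 0.0), "status_quo": (0.0, 0.0)}

        rows = one_way_sa(evaluate, ranges, wtp=1.0, top=10)
        assert len(rows) == 10
        swings = [r.swing for r in rows]
        assert swings == sorted(swings, reverse=True)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            one_way_sa(self._toy_evaluate, {"p": (3.0, 1.0)}, wtp=10.0)


class TestPSA:
    def test_dominant_strategy_has_unit_ceac(self):
        def simulate_draw(d, rng):
            return {"a": (10.0, 1.0), "b": (1.0, 5.0)}

        res = run_psa(simulate_draw, n_draws=20, wtp_grid=[1e4, 1e5], seed=0)
        wide = res.ceac_wide()
        assert (wide["a"] == 1.0).all()
        assert (wide["b"] == 0.0).all()

    def test_reproducible_with_seed(self):
        def simulate_draw(d, rng):
            x = rng.normal()
            return {"a": (x, 0.0), "b": (0.0, 0.0)}

        a = run_psa(simulate_draw, 2, [1.0], seed=42)
        b = run_psa(simulate_draw, 2, [1.0], seed=42)
        pd.testing.assert_frame_equal(a.ceac, b.ceac)

    def test_columns_sum_to_one(self):
        def simulate_draw(d, rng):
            return {s: (rng.normal(), rng.normal()) for s in ("a", "b", "c")}

        res = run_psa(simulate_draw, n_draws=64, wtp_grid=[1e4, 5e4, 1e5], seed=1)
        sums = res.ceac.groupby("wtp")["probability"].sum()
        assert np.allclose(sums, 1.0)

    def test_two_strategy_normal_matches_analytic_probability(self):
        """With NMB difference ~ Normal(mu, sigma), the CEAC for the focal
        strategy approaches Phi(mu/sigma)."""
        mu, sigma = 0.3, 1.0

        def simulate_draw(d, rng):
            return {"focal": (rng.normal(mu, sigma), 0.0), "ref": (0.0, 0.0)}

        n = 4000
        res = run_psa(simulate_draw, n_draws=n, wtp_grid=[1.0], seed=9)
        p_hat = res.ceac_wide()["focal"].iloc[0]
        p = stats.norm.cdf(mu / sigma)
        assert abs(p_hat - p) < 3 * math.sqrt(p * (1 - p) / n)


def test_wtp_spec_validation():
    with pytest.raises(ValueError):
        WTPSpec(threshold=0.0)
    spec = WTPSpec()
    assert spec.threshold == 100_000
    assert spec.psa_grid[0] == 10_000 and spec.psa_grid[-1] == 500_000
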