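"""Data containers, summaries, CSV I/O and the delta-lognormal sampler."""

import math

import numpy as np
import pytest

from dlnq import (
    GroupData,
    load_groups,
    rainfall_fixture,
    sample_delta_lognormal,
    summarize,
    write_fixture_csv,
)

# Published per-region statistics of the bundled rainfall dataset.
PUBLISHED_STATS = {
    "Northern": (29, 6, 23, 0.56, 2.28),
    "Northeastern": (28, 10, 18, 1.10, 3.26),
    "Central": (22, 1, 21, 1.63, 1.38),
    "Eastern": (15, 1, 14, 1.54, 3.21),
    "Southern": (29, 13, 16, 2.07, 3.66),
}


class TestSummarize:
    @pytest.mark.parametrize("region", list(PUBLISHED_STATS))
    def test_rainfall_summaries_match_published_statistics(self, rain_summaries, region):
        s = next(s for s in rain_summaries if s.label == region)
        n, n0, n1, ybar, s2 = PUBLISHED_STATS[region]
        assert (s.n, s.n0, s.n1) == (n, n0, n1)
        assert round(s.ybar1, 2) == ybar
        assert round(s.s2_1, 2) == s2

    def test_all_positive_sample_unit_log_moments(self):
        s = summarize(GroupData("g", (1.0, math.e, math.e**2)))
        assert s.n0 == 0 and s.delta_hat == 0.0
        assert s.ybar1 == pytest.approx(1.0)
        assert s.s2_1 == pytest.approx(1.0)

    def test_southern_log_moments_against_direct_arithmetic(self, rain_groups):
        southern = next(g for g in rain_groups if g.label == "Southern")
        logs = [math.log(v) for v in southern.values if v > 0]
        mean = sum(logs) / len(logs)
        var = sum((x - mean) ** 2 for x in logs) / (len(logs) - 1)
        s = summarize(southern)
        assert s.ybar1 == pytest.approx(mean, abs=1e-12)
        assert s.s2_1 == pytest.approx(var, abs=1e-12)

    def test_permutation_invariance(self, rng):
        vals = tuple(rng.exponential(size=20)) + (0.0, 0.0)
        s1 = summarize(GroupData("a", vals))
        perm = tuple(np.array(vals)[rng.permutation(len(vals))])
        s2 = summarize(GroupData("a", perm))
        assert s1.ybar1 == pytest.approx(s2.ybar1)
        assert s1.s2_1 == pytest.approx(s2.s2_1)
        assert (s1.n, s1.n0, s1.n1) == (s2.n, s2.n0, s2.n1)

    def test_fewer_than_two_positives_rejected(self):
        with pytest.raises(ValueError, match="insufficient positive"):
            summarize(GroupData("g", (0.0, 0.0, 1.0)))

    def test_negative_values_rejected_at_construction(self):
        with pytest.raises(ValueError, match="negative"):
            GroupData("g", (1.0, -1.0))


class TestLoadGroups:
    def test_two_row_file(self, tmp_path):
        f = tmp_path / "d.csv"
        f.write_text("group,value\ng,0\ng,1.5\n")
        groups = load_groups(f)
        assert len(groups) == 1
        assert groups[0].values == (0.0, 1.5)

    def test_fixture_csv_roundtrip(self, tmp_path):
        f = tmp_path / "rain.csv"
        write_fixture_csv(f)
        groups = load_groups(f)
        assert [g.label for g in groups] == [
            "Northern", "Northeastern", "Central", "Eastern", "Southern",
        ]
        assert [g.n for g in groups] == [29, 28, 22, 15, 29]

    def test_negative_value_rejected_with_line_number(self, tmp_path):
        f = tmp_path / "bad.csv"
        f.write_text("group,value\ng,1.0\ng,-1\n")
        with pytest.raises(ValueError, match=":3:"):
            load_groups(f)

    def test_malformed_row_names_line(self, tmp_path):
        f = tmp_path / "bad.csv"
        f.write_text("group,value\ng,abc\n")
        with pytest.raises(ValueError, match=":2:"):
            load_groups(f)

    def test_bad_header_rejected(self, tmp_path):
        f = tmp_path / "bad.csv"
        f.write_text("a,b\ng,1\n")
        with pytest.raises(ValueError, match="header"):
            load_groups(f)


class TestRainfallFixture:
    def test_value_spot_checks(self, rain_groups):
        eastern = next(g for g in rain_groups if g.label == "Eastern")
        southern = next(g for g in rain_groups if g.label == "Southern")
        assert 118.3 in eastern.values
        assert 145.2 in southern.values

    def test_immutable_across_calls(self):
        a, b = rainfall_fixture(), rainfall_fixture()
        for ga, gb in zip(a, b):
            assert ga.values == gb.values
        with pytest.raises(Exception):
            a[0].values = ()  # frozen dataclass

    def test_printed_variant_differs_only_in_southern(self):
        rec = rainfall_fixture(reconciled=True)
        raw = rainfall_fixture(reconciled=False)
        for gr, gp in zip(rec[:4], raw[:4]):
            assert gr.values == gp.values
        assert rec[4].values != raw[4].values
        # the printed Southern series has 6 zeros, the reconciled one 13
        assert sum(v == 0 for v in raw[4].values) == 6
        assert sum(v == 0 for v in rec[4].values) == 13


class TestSampler:
    def test_no_zeros_when_delta_zero(self, rng):
        g = sample_delta_lognormal(200, 0.0, 1.0, 0.0, rng)
        assert all(v > 0 for v in g.values)

    def test_parameter_recovery_at_large_n(self, rng):
        n, mu, s2, dp = 100_000, 1.0, 0.5, 0.3
        s = summarize(sample_delta_lognormal(n, mu, s2, dp, rng))
        se_delta = math.sqrt(dp * (1 - dp) / n)
        assert abs(s.delta_hat - dp) < 3 * se_delta
        n1 = s.n1
        assert abs(s.ybar1 - mu) < 3 * math.sqrt(s2 / n1)
        assert abs(s.s2_1 - s2) < 3 * s2 * math.sqrt(2 / (n1 - 1))

    def test_seed_reproducibility(self):
        a = sample_delta_lognormal(50, 1.0, 0.5, 0.2, np.random.default_rng(5))
        b = sample_delta_lognormal(50, 1.0, 0.5, 0.2, np.random.default_rng(5))
        assert a.values == b.values

    @pytest.mark.parametrize(
        "kwargs",
        [dict(n=0), dict(sigma2=0.0), dict(sigma2=-1.0), dict(delta_prime=1.0),
         dict(delta_prime=-0.1)],
    )
    def test_invalid_parameters(self, rng, kwargs):
        base = dict(n=10, mu=0.0, sigma2=1.0, delta_prime=0.1, rng=rng)
        base.update(kwargs)
        with pytest.raises(ValueError):
            sample_delta_lognormal(**base)
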