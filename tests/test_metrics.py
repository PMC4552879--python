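import pytest

from conftest import mk_table, mk_variant

from ctdna.filters import FilterConfig, apply_filters
from ctdna.metrics import (
    UndefinedInputError,
    ValidationOutcome,
    as_percent,
    concordance,
    estimate_tumor_fraction,
    longitudinal_compare,
    mean_vaf,
    plasma_yield,
    vaf_correlation,
    validation_rate,
)


class TestMeanVaf:
    def test_arithmetic_mean(self):
        table = mk_table(
            [
                mk_variant(100, {"normal": (50, 0, 0, 0), "plasma": (100, 2, 1, 1)}),
                mk_variant(200, {"normal": (50, 0, 0, 0), "plasma": (100, 4, 2, 2)}),
            ]
        )
        calls = {("1", 100, "A", "T"), ("1", 200, "A", "T")}
        assert mean_vaf(calls, "plasma", table) == pytest.approx(0.03)

    def test_single_site_identity(self):
        table = mk_table(
            [mk_variant(100, {"normal": (50, 0, 0, 0), "plasma": (100, 15, 8, 7)})]
        )
        assert mean_vaf({("1", 100, "A", "T")}, "plasma", table) == pytest.approx(0.15)

    def test_empty_calls_undefined(self):
        table = mk_table(
            [mk_variant(100, {"normal": (50, 0, 0, 0), "plasma": (100, 15, 8, 7)})]
        )
        with pytest.raises(UndefinedInputError):
            mean_vaf(set(), "plasma", table)


class TestTumorFraction:
    @pytest.mark.parametrize(
        "mv,expected",
        [(0.037, 0.074), (0.14, 0.28), (0.0, 0.0), (0.6, 1.0)],
    )
    def test_doubling_with_clip(self, mv, expected):
        assert estimate_tumor_fraction(mv) == pytest.approx(expected)

    def test_domain_error_outside_unit_interval(self):
        with pytest.raises(ValueError):
            estimate_tumor_fraction(1.5)

    def test_monotone_and_two_lipschitz_below_clip(self):
        grid = [i / 200 for i in range(101)]
        vals = [estimate_tumor_fraction(x) for x in grid]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        for a, b in zip(grid, grid[1:]):
            assert abs(
                estimate_tumor_fraction(b) - estimate_tumor_fraction(a)
            ) <= 2 * (b - a) + 1e-12

    def test_percent_rendering_rounds_half_away_from_zero(self):
        assert as_percent(0.037 * 2) == 7.4
        assert as_percent(0.28) == 28.0
        assert as_percent(6 / 14, decimals=0) == 43.0
        assert as_percent(0.0625, decimals=0) == 6.0
        assert as_percent(0.065, decimals=0) == 7.0  # .5 rounds away from zero


def _concordance_table():
    mk = lambda pos, primary, plasma: mk_variant(
        pos,
        {
            "normal": (50, 0, 0, 0),
            "primary": primary,
            "plasma": plasma,
        },
    )
    return mk_table(
        [
            mk(1, (100, 30, 15, 15), (500, 20, 10, 10)),  # shared
            mk(2, (100, 25, 12, 13), (500, 15, 8, 7)),  # shared
            mk(3, (100, 30, 15, 15), (500, 2, 2, 0)),  # primary only
            mk(4, (100, 5, 3, 2), (500, 30, 15, 15)),  # plasma only, subthreshold
            mk(5, (100, 0, 0, 0), (500, 30, 15, 15)),  # plasma only, absent in primary
        ]
    )


class TestConcordance:
    def test_partition_and_subthreshold_rescue(self):
        table = _concordance_table()
        cfg = FilterConfig()
        calls, _ = apply_filters(table, cfg)
        ref_calls = calls["primary"]
        summary = concordance(ref_calls, "primary", "plasma", table, cfg)
        key = lambda pos: ("1", pos, "A", "T")
        assert summary.shared == {key(1), key(2)}
        assert summary.reference_only == {key(3)}
        assert summary.query_only == {key(4), key(5)}
        # site 4 has reads in the primary at VAF 0.05 < 0.10: rescued category
        assert summary.query_only_subthreshold_in_reference == {key(4)}
        assert len(summary.shared) + len(summary.reference_only) == len(ref_calls)

    def test_identical_call_sets_leave_unique_sets_empty(self):
        table = _concordance_table()
        cfg = FilterConfig()
        calls, _ = apply_filters(table, cfg)
        summary = concordance(calls["plasma"], "plasma", "plasma", table, cfg)
        assert summary.shared == calls["plasma"]
        assert not summary.reference_only and not summary.query_only

    def test_unknown_sample_rejected(self):
        from ctdna.model import ValidationError

        table = _concordance_table()
        with pytest.raises(ValidationError):
            concordance(set(), "primary", "ghost", table, FilterConfig())


class TestVafCorrelation:
    def test_identical_vectors_give_one(self):
        table = mk_table(
            [
                mk_variant(
                    p, {"normal": (50, 0, 0, 0), "primary": o, "plasma": o}
                )
                for p, o in [(1, (100, 10, 5, 5)), (2, (100, 20, 10, 10)), (3, (100, 30, 15, 15))]
            ]
        )
        keys = {("1", p, "A", "T") for p in (1, 2, 3)}
        assert vaf_correlation("primary", "plasma", keys, table) == pytest.approx(1.0)

    def test_proportional_vectors_give_one(self):
        pairs = [((100, 10, 5, 5), (100, 20, 10, 10)),
                 ((100, 20, 10, 10), (100, 40, 20, 20)),
                 ((100, 30, 15, 15), (100, 60, 30, 30))]
        table = mk_table(
            [
                mk_variant(p, {"normal": (50, 0, 0, 0), "primary": a, "plasma": b})
                for p, (a, b) in enumerate(pairs, start=1)
            ]
        )
        keys = {("1", p, "A", "T") for p in (1, 2, 3)}
        assert vaf_correlation("primary", "plasma", keys, table) == pytest.approx(1.0)

    def test_anti_ordered_vectors_give_minus_one(self):
        pairs = [((100, 10, 5, 5), (100, 30, 15, 15)),
                 ((100, 20, 10, 10), (100, 20, 10, 10)),
                 ((100, 30, 15, 15), (100, 10, 5, 5))]
        table = mk_table(
            [
                mk_variant(p, {"normal": (50, 0, 0, 0), "primary": a, "plasma": b})
                for p, (a, b) in enumerate(pairs, start=1)
            ]
        )
        keys = {("1", p, "A", "T") for p in (1, 2, 3)}
        assert vaf_correlation("primary", "plasma", keys, table) == pytest.approx(-1.0)

    def test_too_few_points_or_zero_variance_undefined(self):
        table = _concordance_table()
        keys = {("1", 1, "A", "T"), ("1", 2, "A", "T")}
        with pytest.raises(UndefinedInputError):
            vaf_correlation("primary", "plasma", keys, table)


class TestValidationRate:
    def test_not_sequenced_excluded_from_denominator(self):
        rate = validation_rate(ValidationOutcome(6, 8, 1))
        assert rate == pytest.approx(6 / 14)
        assert as_percent(rate, decimals=0) == 43.0

    def test_all_confirmed(self):
        assert validation_rate(ValidationOutcome(3, 0, 0)) == 1.0

    def test_no_sequenced_sites_undefined(self):
        with pytest.raises(UndefinedInputError):
            validation_rate(ValidationOutcome(0, 0, 5))


class TestPlasmaYield:
    @pytest.mark.parametrize(
        "volume,conc,total", [(25, 63, 1575), (10, 98, 980), (0, 98, 0)]
    )
    def test_product(self, volume, conc, total):
        assert plasma_yield(volume, conc) == total

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            plasma_yield(-1, 10)


class TestLongitudinal:
    def _table(self, during_counts):
        variants = []
        for i, (pre, dur) in enumerate(during_counts, start=1):
            variants.append(
                mk_variant(
                    i,
                    {
                        "normal": (50, 0, 0, 0),
                        "pre": pre,
                        "during": dur,
                    },
                    roles={"normal": "normal", "pre": "plasma", "during": "plasma"},
                )
            )
        # two plasma timepoints plus the normal
        from ctdna.model import VariantTable

        return VariantTable(
            variants=variants,
            sample_ids=["normal", "pre", "during"],
            sample_roles={"normal": "normal", "pre": "plasma", "during": "plasma"},
        )

    def test_all_sites_undetected_during_treatment(self):
        table = self._table(
            [((500, 50, 25, 25), (500, 0, 0, 0)), ((500, 40, 20, 20), (500, 0, 0, 0))]
        )
        keys = {("1", 1, "A", "T"), ("1", 2, "A", "T")}
        result = longitudinal_compare("pre", "during", keys, table)
        assert result.mean_vaf_during is None
        assert result.n_zero_during == 2
        assert result.mean_vaf_pre == pytest.approx(0.09)

    def test_identical_observations_give_equal_pairs(self):
        obs = (500, 50, 25, 25)
        table = self._table([(obs, obs), (obs, obs)])
        keys = {("1", 1, "A", "T"), ("1", 2, "A", "T")}
        result = longitudinal_compare("pre", "during", keys, table)
        assert (result.per_variant.vaf_pre == result.per_variant.vaf_during).all()
        assert result.n_zero_during == 0

    def test_missing_observation_lists_coordinates(self):
        table = self._table([((500, 50, 25, 25), (500, 0, 0, 0))])
        from ctdna.model import ValidationError

        with pytest.raises(ValidationError, match="99"):
            longitudinal_compare(
                "pre", "during", {("1", 99, "A", "T")}, table
            )
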