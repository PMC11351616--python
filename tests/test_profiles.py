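"""Loading, replicate averaging and B-spline smoothing."""

import numpy as np
import pytest
from scipy.integrate import simpson

from sigbnet.errors import (
    ConfigurationError,
    ExtrapolationError,
    GridAlignmentError,
    InsufficientDataError,
    IntensityParseError,
    ProteinLookupError,
    TableFormatError,
)
from sigbnet.profiles import (
    ExpressionSeries,
    average_replicates,
    build_driving_profiles,
    load_expression_table,
    smooth_and_resample,
)

TIMES = np.arange(0.0, 140.0, 10.0)


def write_table(path, rows, header="protein_id,time_min,replicate,intensity",
                sep=","):
    lines = [header] + [sep.join(str(v) for v in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


def sigb_rows(n_replicates=3):
    return [
        ("SigB", t, r, 1000.0 + 10.0 * t + r)
        for r in range(1, n_replicates + 1)
        for t in TIMES
    ]


class TestLoadExpressionTable:
    def test_loads_replicate_series(self, tmp_path):
        path = write_table(tmp_path / "t.csv", sigb_rows())
        (series,) = load_expression_table(path, ["SigB"])
        assert series.protein_id == "SigB"
        assert series.times.size == 14
        assert series.n_replicates == 3
        assert np.all(np.diff(series.times) == 10)

    def test_tsv_autodetected(self, tmp_path):
        path = write_table(
            tmp_path / "t.tsv", sigb_rows(1),
            header="protein_id\ttime_min\treplicate\tintensity", sep="\t",
        )
        (series,) = load_expression_table(path, ["SigB"])
        assert series.n_replicates == 1

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("protein_id,time_min,intensity\nSigB,0,1\n")
        with pytest.raises(TableFormatError, match="replicate"):
            load_expression_table(path)

    def test_absent_protein_named_in_error(self, tmp_path):
        path = write_table(tmp_path / "t.csv", sigb_rows(1))
        with pytest.raises(ProteinLookupError, match="RsbW"):
            load_expression_table(path, ["SigB", "RsbW"])

    def test_non_numeric_intensity_reports_row(self, tmp_path):
        rows = sigb_rows(1)
        rows[4] = ("SigB", rows[4][1], 1, "n/a")
        path = write_table(tmp_path / "t.csv", rows)
        with pytest.raises(IntensityParseError, match="row 6") as exc:
            load_expression_table(path)
        assert exc.value.row == 6

    def test_incomplete_replicate_grid_rejected(self, tmp_path):
        rows = sigb_rows(2)[:-1]  # drop last measurement of replicate 2
        path = write_table(tmp_path / "t.csv", rows)
        with pytest.raises(TableFormatError, match="missing"):
            load_expression_table(path)


class TestExpressionSeries:
    def test_rejects_unsorted_times(self):
        with pytest.raises(TableFormatError, match="increasing"):
            ExpressionSeries("x", [0, 20, 10], np.ones((1, 3)))

    def test_rejects_negative_intensity(self):
        with pytest.raises(TableFormatError, match="negative"):
            ExpressionSeries("x", [0, 10], np.array([[1.0, -1.0]]))


class TestAverageReplicates:
    @pytest.mark.parametrize(
        "replicates, expected",
        [([2.0, 4.0, 6.0], 4.0), ([0.0, 0.0, 3.0], 1.0)],
    )
    def test_arithmetic_mean(self, replicates, expected):
        series = ExpressionSeries(
            "x", [0, 10, 20, 30],
            np.tile(np.asarray(replicates)[:, None], (1, 4)),
        )
        averaged = average_replicates(series)
        assert averaged.n_replicates == 1
        assert np.allclose(averaged.replicate_values, expected)

    def test_single_replicate_is_identity(self):
        series = ExpressionSeries("x", TIMES, np.arange(14.0)[None, :] + 1)
        averaged = average_replicates(series)
        assert np.array_equal(averaged.replicate_values, series.replicate_values)


class TestSmoothAndResample:
    def test_constant_series_scaled_flat(self):
        series = ExpressionSeries("c", TIMES, np.full((2, 14), 370.0))
        profile = smooth_and_resample(series, scale_divisor=37.0)
        assert profile.grid.size == 131
        assert np.allclose(profile.values, 10.0, atol=1e-9)
        assert np.allclose(profile.derivatives, 0.0, atol=1e-9)

    def test_linear_series_has_constant_derivative(self):
        series = ExpressionSeries("lin", TIMES, (5.0 + 2.0 * TIMES)[None, :])
        profile = smooth_and_resample(series, scale_divisor=1.0)
        assert np.allclose(profile.derivatives, 2.0, atol=1e-8)

    def test_noisy_logistic_recovered_within_rms(self, synth_dataset, driving,
                                                 synth_spec):
        # generator truth on the y scale vs the fitted spline; smoothing
        # must not be worse than the replicate-mean noise floor at peak
        # signal (cv / sqrt(n_replicates) of the curve maximum)
        _, truth = synth_dataset
        curve = truth["SigB"](driving.grid) / driving.S.scale_divisor
        rms = np.sqrt(np.mean((driving.S.values - curve) ** 2))
        noise_floor = synth_spec.noise_cv / np.sqrt(synth_spec.n_replicates)
        assert rms < noise_floor * curve.max()

    def test_scaling_divides_values_elementwise(self):
        rng = np.random.default_rng(0)
        series = ExpressionSeries(
            "n", TIMES, rng.uniform(10, 20, (3, 14))
        )
        unscaled = smooth_and_resample(series, scale_divisor=1.0)
        scaled = smooth_and_resample(series, scale_divisor=8.0)
        assert np.allclose(scaled.values, unscaled.values / 8.0, rtol=1e-12)

    def test_negative_excursions_clipped_in_values_only(self):
        values = np.zeros(14)
        values[0] = 1000.0
        series = ExpressionSeries("dip", TIMES, values[None, :])
        profile = smooth_and_resample(series, scale_divisor=1.0)
        assert profile.spline(profile.grid).min() < 0  # the fit undershoots
        assert profile.values.min() == 0.0
        # derivatives left as fitted: integral identity must survive clipping
        assert not np.allclose(profile.derivatives, 0.0)

    def test_too_few_points_rejected(self):
        series = ExpressionSeries("s", [0, 10, 20], np.ones((1, 3)))
        with pytest.raises(InsufficientDataError):
            smooth_and_resample(series)

    def test_incompatible_knot_count_rejected(self):
        series = ExpressionSeries("s", TIMES, np.ones((1, 14)))
        with pytest.raises(ConfigurationError):
            smooth_and_resample(series, knot_count=11)  # needs 15 points

    def test_extrapolation_forbidden(self, driving):
        with pytest.raises(ExtrapolationError):
            driving.S.value(140.0)
        with pytest.raises(ExtrapolationError):
            driving.S.derivative(-1.0)

    def test_fundamental_theorem_on_derivative(self, driving):
        # independent quadrature of the analytic derivative recovers the
        # endpoint difference of the fitted values
        for profile in (driving.S, driving.AS, driving.AAS):
            fine = np.linspace(profile.t_min, profile.t_max, 1301)
            integral = simpson(profile.derivative(fine), x=fine)
            diff = profile.values[-1] - profile.values[0]
            assert abs(integral - diff) <= 1e-6 * abs(diff)


class TestBuildDrivingProfiles:
    def smoothed(self, value=100.0, times=TIMES):
        out = {}
        for protein in ("SigB", "RsbW", "RsbV", "RsbU", "RsbP"):
            series = ExpressionSeries(
                protein, times, np.full((1, times.size), value)
            )
            out[protein] = smooth_and_resample(series, scale_divisor=1.0)
        return out

    def test_happy_path_maps_symbols(self):
        driving = build_driving_profiles(self.smoothed())
        assert driving.S.protein_id == "SigB"
        assert driving.AS.protein_id == "RsbW"
        assert driving.AAS.protein_id == "RsbV"

    def test_grid_mismatch_rejected(self):
        profiles = self.smoothed()
        short = ExpressionSeries(
            "RsbP", TIMES[:10], np.full((1, 10), 1.0)
        )
        profiles["RsbP"] = smooth_and_resample(short, scale_divisor=1.0)
        with pytest.raises(GridAlignmentError):
            build_driving_profiles(profiles)

    def test_missing_protein_named(self):
        profiles = self.smoothed()
        del profiles["RsbU"]
        with pytest.raises(ProteinLookupError, match="RsbU"):
            build_driving_profiles(profiles)

    def test_near_zero_rsbp_accepted(self, driving):
        # the physiological regime: the energy-stress phosphatase barely
        # expressed, the environmental-stress branch carries the signal
        assert float(np.max(driving.RsbP.values)) < 0.01 * np.max(driving.S.values)
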