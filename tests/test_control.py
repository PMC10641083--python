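"""Acquisition planning, the simulated microscope, and closed-loop bookkeeping."""

import numpy as np
import pytest

from mlao.control import (
    OracleEstimator,
    SimulatedMicroscope,
    ZeroEstimator,
    correct_iterate,
    evaluate_statistics,
    make_scheme,
    plan_acquisitions,
)
from mlao.imaging import ModalityConfig
from mlao.metrics import metric_yI
from mlao.zernike import ZernikeCoefficients


class TestPlanning:
    @pytest.mark.parametrize(
        "name,n,expected_m",
        [
            ("2N", 5, 10),
            ("conv2N1", 5, 11),
            ("ast2", 5, 2),
            ("ast4", 7, 4),
            ("4N", 7, 28),
            ("conv3N", 8, 24),
        ],
    )
    def test_planned_image_counts(self, name, n, expected_m):
        scheme = make_scheme(name, n)
        assert len(plan_acquisitions(scheme)) == expected_m
        assert scheme.m_images == expected_m

    def test_ast2_biases_astigmatism_only(self):
        scheme = make_scheme("ast2", 5)
        for bias in scheme.biases:
            assert set(bias.coeffs) == {5}
        assert scheme.biases[0][5] == -scheme.biases[1][5]

    def test_mlao_pairs_are_equal_and_opposite(self):
        scheme = make_scheme("2N", 3)
        for plus, minus in scheme.pairs:
            assert plus.coeffs == (-minus).coeffs
        assert scheme.n_channels == 6

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            make_scheme("5N", 3)

    def test_mode_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            make_scheme("2N", 3, modes=(5, 6))
        scheme = make_scheme("2N", 3)
        with pytest.raises(ValueError):
            plan_acquisitions(scheme, n_modes=5)


class TestMicroscope:
    def test_noise_seeds_advance_between_acquisitions(self, grid, bead_field):
        cfg = ModalityConfig("2P", photon_scale=1e4)
        system = SimulatedMicroscope(bead_field, ZernikeCoefficients(), cfg, grid, seed=3)
        a = system.acquire()
        b = system.acquire()
        assert not np.array_equal(a.pixels, b.pixels)
        assert system.images_acquired == 2

    def test_corrector_accumulates(self, grid, bead_field, noiseless_2p):
        system = SimulatedMicroscope(
            bead_field, ZernikeCoefficients({5: 1.0}), noiseless_2p, grid
        )
        system.apply_correction(ZernikeCoefficients({5: -0.4}))
        system.apply_correction(ZernikeCoefficients({5: -0.6}))
        assert system.residual_rms() == pytest.approx(0.0, abs=1e-12)


class TestClosedLoop:
    def test_oracle_reaches_zero_residual_in_one_cycle(self, grid, bead_field, noiseless_2p):
        for name in ("ast2", "2N"):
            scheme = make_scheme(name, 3)
            system = SimulatedMicroscope(
                bead_field, ZernikeCoefficients({5: 1.1, 7: -0.6}), noiseless_2p, grid
            )
            trace = correct_iterate(system, OracleEstimator(scheme), iterations=1)
            assert trace.residual_rms[-1] == pytest.approx(0.0, abs=1e-12)

    def test_zero_estimator_leaves_residual_unchanged(self, grid, bead_field, noiseless_2p):
        scheme = make_scheme("ast2", 3)
        aberration = ZernikeCoefficients({6: 0.9})
        system = SimulatedMicroscope(bead_field, aberration, noiseless_2p, grid)
        trace = correct_iterate(system, ZeroEstimator(scheme), iterations=2)
        assert trace.residual_rms == pytest.approx([0.9, 0.9, 0.9])

    def test_image_accounting_matches_plan(self, grid, bead_field, noiseless_2p):
        scheme = make_scheme("2N", 4)
        system = SimulatedMicroscope(bead_field, ZernikeCoefficients({5: 0.5}), noiseless_2p, grid)
        trace = correct_iterate(system, OracleEstimator(scheme), iterations=3)
        assert trace.images == [0, 8, 16, 24]

    def test_metric_logging_uses_a_dedicated_extra_frame(self, grid, bead_field, noiseless_2p):
        scheme = make_scheme("ast2", 3)
        system = SimulatedMicroscope(bead_field, ZernikeCoefficients({5: 0.5}), noiseless_2p, grid)
        trace = correct_iterate(
            system, OracleEstimator(scheme), iterations=2,
            metric_fn=lambda px: metric_yI(px, l=256),
        )
        assert trace.images == [0, 3, 6]  # 2 scheme frames + 1 metric frame per cycle
        assert trace.rows[1]["metric"] > 0

    def test_correction_additivity(self, grid, bead_field, noiseless_2p):
        scheme = make_scheme("2N", 3)
        system = SimulatedMicroscope(bead_field, ZernikeCoefficients({5: 2.0}), noiseless_2p, grid)

        class HalfOracle:
            def one_cycle(self, sys):
                c = -0.5 * sys.residual()
                sys.apply_correction(c)
                return c

        corrections = []
        est = HalfOracle()
        for _ in range(3):
            corrections.append(est.one_cycle(system))
        total = corrections[0] + corrections[1] + corrections[2]
        assert system.corrector.coeffs == pytest.approx(total.coeffs)

    def test_invalid_iterations_rejected(self, grid, bead_field, noiseless_2p):
        system = SimulatedMicroscope(bead_field, ZernikeCoefficients(), noiseless_2p, grid)
        with pytest.raises(ValueError):
            correct_iterate(system, OracleEstimator(make_scheme("ast2", 3)), iterations=0)


class TestStatistics:
    def _runs(self, estimator_kind):
        rng = np.random.default_rng(0)
        runs = []
        for _ in range(40):
            rms = rng.uniform(0.63, 2.23)
            residual = 0.0 if estimator_kind == "oracle" else rms
            runs.append({"method": estimator_kind, "input_rms": rms, "residual_rms": residual})
        return runs

    def test_oracle_residuals_are_zero_in_every_bin(self):
        stats = evaluate_statistics(self._runs("oracle"))
        filled = stats.dropna(subset=["mean"])
        assert (filled["mean"] == 0).all()

    def test_zero_estimator_residual_equals_input(self):
        runs = self._runs("zero")
        stats = evaluate_statistics(runs)
        filled = stats.dropna(subset=["mean"])
        # per-bin mean residual must sit inside the bin's input range
        for _, row in filled.iterrows():
            assert row["rms_bin"].left <= row["mean"] <= row["rms_bin"].right

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            evaluate_statistics([])
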