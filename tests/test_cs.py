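"""Compressed sensing: sensing matrix, lift, PRD, CS-ResNet and the
augmentation-benchmark bookkeeping."""

import numpy as np
import pytest

from eeggan import (CSResNetReconstructor, build_cs_resnet,
                    build_measurement_matrix, compress, mean_prd, prd,
                    pseudoinverse_lift, run_augmentation_benchmark)
from eeggan import autodiff as ad
from eeggan import nn
from eeggan.autodiff import Tensor
from eeggan.cs import CSResNetSpec, PRDTable, truncate2
from eeggan.models import SpecError
from eeggan.preprocess import DataError
from eeggan.reference import (STATED_DELTA_RANGES, computed_delta_ranges,
                              reference_table)
from eeggan.presets import smoke_cs_spec


class TestMeasurementMatrix:
    def test_column_sums_and_binary_entries(self):
        mm = build_measurement_matrix(40, 100, ones_per_column=4, seed=1)
        assert set(np.unique(mm.phi)) <= {0.0, 1.0}
        np.testing.assert_array_equal(mm.phi.sum(axis=0), np.full(100, 4))

    def test_compression_ratio_grid_value(self):
        mm = build_measurement_matrix(450, 500, seed=0)
        assert mm.cr == pytest.approx(0.90)

    def test_permutation_case_inverts_exactly(self, rng):
        mm = build_measurement_matrix(64, 64, ones_per_column=1, seed=3)
        x = rng.normal(size=64)
        x0 = pseudoinverse_lift(compress(x, mm), mm)
        assert prd(x, x0) == pytest.approx(0.0, abs=1e-9)

    def test_determinism_and_serialization(self, tmp_path):
        a = build_measurement_matrix(20, 50, seed=9)
        b = build_measurement_matrix(20, 50, seed=9)
        np.testing.assert_array_equal(a.phi, b.phi)
        p = tmp_path / "mm.npz"
        a.save(p)
        c = type(a).load(p)
        np.testing.assert_array_equal(a.phi, c.phi)
        assert (c.M, c.N, c.ones_per_column, c.seed) == (20, 50, 4, 9)

    def test_infeasible_density_rejected(self):
        with pytest.raises(DataError, match="infeasible"):
            build_measurement_matrix(3, 10, ones_per_column=5)


class TestCompressLift:
    def test_linearity(self, rng):
        mm = build_measurement_matrix(30, 80, seed=2)
        x1, x2 = rng.normal(size=80), rng.normal(size=80)
        np.testing.assert_allclose(compress(x1 + x2, mm),
                                   compress(x1, mm) + compress(x2, mm), atol=1e-12)
        np.testing.assert_allclose(compress(np.zeros(80), mm), np.zeros(30))

    def test_lift_of_zero_is_zero(self):
        mm = build_measurement_matrix(30, 80, seed=2)
        np.testing.assert_allclose(pseudoinverse_lift(np.zeros(30), mm), np.zeros(80))

    def test_measurement_space_roundtrip_full_row_rank(self, rng):
        # rows independent (generically true for M << N): phi @ pinv = I
        mm = build_measurement_matrix(10, 100, ones_per_column=2, seed=4)
        y = rng.normal(size=10)
        np.testing.assert_allclose(compress(pseudoinverse_lift(y, mm), mm), y,
                                   atol=1e-8)


class TestPRD:
    def test_identity_zero(self, rng):
        x = rng.normal(size=20)
        assert prd(x, x) == 0.0

    def test_hand_value(self):
        assert prd([3, 4], [3, 4.5]) == pytest.approx(10.0)

    def test_full_distortion_and_zero_norm(self):
        assert prd([3, 4], [0, 0]) == pytest.approx(100.0)
        with pytest.raises(DataError, match="zero reference norm"):
            prd([0, 0], [1, 1])

    def test_error_scale_equivariance(self, rng):
        x = rng.normal(size=30)
        e = rng.normal(size=30)
        base = prd(x, x + e)
        for alpha in (0.5, 2.0, -3.0):
            assert prd(x, x + alpha * e) == pytest.approx(abs(alpha) * base)


class TestCSResNet:
    def test_shape_contract(self, rng):
        spec = smoke_cs_spec()
        net = build_cs_resnet(spec, seed=0)
        x = Tensor(rng.normal(size=(3, spec.signal_len)))
        with ad.no_grad():
            assert net(x).shape == (3, spec.signal_len)

    def test_residual_blocks_preserve_channel_geometry(self, rng):
        spec = smoke_cs_spec()
        net = build_cs_resnet(spec, seed=0)
        h = net.stem(Tensor(rng.normal(size=(2, spec.signal_len))))
        assert h.shape == (2, spec.stem_filters, spec.signal_len)
        with ad.no_grad():
            out = net.block0(h)
        assert out.shape == h.shape

    def test_zeroed_block_weights_make_blocks_identity(self, rng):
        spec = smoke_cs_spec()
        net = build_cs_resnet(spec, seed=0)
        for b in range(spec.blocks):
            block = getattr(net, f"block{b}")
            last_conv = [m for m in block.modules() if isinstance(m, nn.Conv1d)][-1]
            last_conv.W.data[:] = 0.0
            last_conv.b.data[:] = 0.0
        h = net.stem(Tensor(rng.normal(size=(2, spec.signal_len))))
        with ad.no_grad():
            out = net.block1(net.block0(h))
        np.testing.assert_allclose(out.data, h.data, atol=1e-12)

    def test_identity_lift_baseline_at_init(self, rng):
        """With the output layer zero-initialized and the global skip active,
        the untrained refiner reproduces its lifted input exactly."""
        spec = smoke_cs_spec()
        net = build_cs_resnet(spec, seed=0)
        x = rng.normal(size=(3, spec.signal_len))
        with ad.no_grad():
            out = net(Tensor(x)).data
        np.testing.assert_allclose(out, x, atol=1e-12)

    def test_mismatched_skip_channels_rejected(self):
        with pytest.raises(SpecError, match="stem_filters"):
            CSResNetSpec(stem_filters=16, block_filters=(32, 16, 8),
                         block_kernels=(3, 3, 3)).validate()

    def test_training_reduces_reconstruction_error(self, rng):
        spec = smoke_cs_spec()
        X = rng.normal(size=(48, spec.signal_len))
        mm = build_measurement_matrix(60, spec.signal_len, seed=0)
        rec = CSResNetReconstructor(matrix=mm, spec=spec, epochs=8,
                                    batch_size=16, seed=0)
        rec.fit(X)
        assert rec.loss_history_[-1] < rec.loss_history_[0]
        assert rec.predict(X[:4]).shape == (4, spec.signal_len)


class TestPRDTableBookkeeping:
    def test_truncation_not_rounding(self):
        assert truncate2(3.7965) == 3.79
        assert truncate2(0.8016) == 0.80
        assert truncate2(-1.239) == -1.23

    def test_deltas_from_known_rows(self):
        t = PRDTable(rows={50: {0: 10.0, 50: 9.123456, 100: 8.2}}).compute_deltas()
        assert t.deltas[50][50] == pytest.approx(0.87)  # 0.876543 truncated
        assert t.deltas[50][100] == pytest.approx(1.80)

    @pytest.mark.parametrize("model", ["cnn", "cs_resnet"])
    def test_reference_grids_reproduce_stated_ranges(self, model):
        assert computed_delta_ranges(model) == STATED_DELTA_RANGES[model]

    def test_reference_table_monotone_in_fraction(self):
        t = reference_table("cs_resnet")
        for cr, row in t.rows.items():
            vals = [row[f] for f in sorted(row)]
            assert vals == sorted(vals, reverse=True)  # more augmentation, less PRD


class TestBenchmark:
    def test_fraction_zero_equals_baseline_and_reproducible(self, rng):
        spec = smoke_cs_spec()
        R = rng.normal(size=(24, spec.signal_len))
        G = rng.normal(size=(24, spec.signal_len))
        T = rng.normal(size=(8, spec.signal_len))
        kw = dict(fractions=(0, 100), cr_grid=(30,), spec=spec, epochs=2,
                  batch_size=8, seed=5)
        t1 = run_augmentation_benchmark(R, G, T, **kw)
        t2 = run_augmentation_benchmark(R, G, T, **kw)
        assert t1.rows == t2.rows
        base = CSResNetReconstructor(
            matrix=build_measurement_matrix(30, spec.signal_len, 4, seed=5),
            spec=spec, epochs=2, batch_size=8, seed=5).fit(R)
        assert t1.rows[30][0] == pytest.approx(base.prd_score(T))

    def test_prd_improves_with_more_measurements(self, rng):
        """More measurements make the inverse problem easier: mean test PRD
        at high CR should not exceed that at low CR (majority over seeds)."""
        from eeggan import SyntheticConfig, generate_frames, normalize
        spec = smoke_cs_spec()
        wins = 0
        for seed in range(3):
            nf = normalize(generate_frames(SyntheticConfig(
                n_frames=70, frame_len=spec.signal_len, seed=300 + seed)))
            X, T = nf.frames[:60], nf.frames[60:]
            scores = []
            for cr in (10, 90):
                mm = build_measurement_matrix(cr, spec.signal_len, seed=seed)
                rec = CSResNetReconstructor(matrix=mm, spec=spec, epochs=8,
                                            batch_size=30, seed=seed).fit(X)
                scores.append(rec.prd_score(T))
            wins += scores[1] <= scores[0]
        assert wins >= 2
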