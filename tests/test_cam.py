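"""Class activation maps: identities, oracle equivalence, exemplars, rendering."""

import numpy as np
import pytest

from acticam.cam import (
    cam_for_window,
    class_score,
    compute_cam,
    panel_ylim,
    rank_by_logit,
    render_cam_plot,
    select_exemplars,
    upsample_cam,
)
from acticam.models import FeatureMap, ModelConfig, build_dixonnet
from acticam.nn.optim import Adam
from acticam.prep import LabelledWindow
from acticam.training import bce_grad, bce_loss


def bruteforce_cam(S, w):
    out = np.zeros(S.shape[1])
    for x in range(S.shape[1]):
        for k in range(S.shape[0]):
            out[x] += w[k] * S[k, x]
    return out


def make_window(values, drive_id="d0", start=0, label=1, participant="P001"):
    return LabelledWindow(values=values, label=label, participant_id=participant, drive_id=drive_id, start_index=start)


class TestClassScore:
    def test_mean_pooled_example(self):
        fmap = FeatureMap(S=np.array([[2.0, 4.0]]))
        assert class_score(fmap, np.array([3.0])) == pytest.approx(9.0)

    def test_zero_weights(self):
        fmap = FeatureMap(S=np.random.default_rng(0).normal(0, 1, (4, 6)))
        assert class_score(fmap, np.zeros(4)) == 0.0

    def test_weight_length_mismatch(self):
        with pytest.raises(ValueError, match="channels"):
            class_score(FeatureMap(S=np.ones((3, 5))), np.ones(4))

    def test_consistency_with_model_logit(self):
        model = build_dixonnet(ModelConfig(architecture="dixonnet", width=8, seed=1))
        rng = np.random.default_rng(1)
        for _ in range(5):
            x = rng.normal(0, 1, (3, 128)).astype(np.float32)
            logit, fmap, w, bias = model.forward_with_features(x)
            assert class_score(fmap, w) + bias == pytest.approx(logit, abs=1e-5)


class TestComputeCam:
    def test_selector_weight(self):
        S = np.random.default_rng(2).normal(0, 1, (2, 7))
        assert np.allclose(compute_cam(FeatureMap(S=S), np.array([1.0, 0.0])), S[0])

    def test_zero_weights_zero_map(self):
        assert np.array_equal(compute_cam(FeatureMap(S=np.ones((3, 4))), np.zeros(3)), np.zeros(4))

    def test_hand_arithmetic(self):
        S = np.array([[2.0, 0.0], [1.0, 3.0]])
        assert compute_cam(FeatureMap(S=S), np.array([0.5, -1.0])) == pytest.approx([0.0, -3.0])

    def test_linearity(self):
        rng = np.random.default_rng(3)
        S = rng.normal(0, 1, (5, 9))
        w1, w2 = rng.normal(0, 1, 5), rng.normal(0, 1, 5)
        fmap = FeatureMap(S=S)
        assert np.allclose(compute_cam(FeatureMap(S=2.5 * S), w1), 2.5 * compute_cam(fmap, w1), atol=1e-6)
        assert np.allclose(
            compute_cam(fmap, w1 + w2), compute_cam(fmap, w1) + compute_cam(fmap, w2), atol=1e-6
        )

    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            k, t = rng.integers(1, 8), rng.integers(1, 12)
            S, w = rng.normal(0, 1, (k, t)), rng.normal(0, 1, k)
            assert np.allclose(compute_cam(FeatureMap(S=S), w), bruteforce_cam(S, w), atol=1e-6)

    def test_mean_of_map_equals_class_score(self):
        rng = np.random.default_rng(5)
        S, w = rng.normal(0, 1, (6, 10)), rng.normal(0, 1, 6)
        fmap = FeatureMap(S=S)
        assert compute_cam(fmap, w).mean() == pytest.approx(class_score(fmap, w), abs=1e-10)


class TestUpsample:
    def test_constant_map(self):
        assert np.allclose(upsample_cam(np.array([1.0, 1.0, 1.0]), 12), np.ones(12))

    def test_midpoint(self):
        assert upsample_cam(np.array([0.0, 1.0]), 3) == pytest.approx([0.0, 0.5, 1.0])

    def test_linear_ramp_preserves_mean(self):
        m = np.linspace(-1.0, 3.0, 16)
        up = upsample_cam(m, 256)
        assert up.mean() == pytest.approx(m.mean(), abs=1e-3)

    def test_endpoints_preserved(self):
        m = np.array([2.0, -1.0, 5.0])
        up = upsample_cam(m, 100)
        assert up[0] == 2.0 and up[-1] == 5.0

    def test_nearest_mode(self):
        assert np.array_equal(upsample_cam(np.array([0.0, 1.0]), 4, mode="nearest"), [0, 0, 1, 1])

    def test_bad_target_length(self):
        with pytest.raises(ValueError, match="length"):
            upsample_cam(np.array([1.0]), 0)


class TestRanking:
    def test_descending_magnitude(self):
        windows = [make_window(np.zeros((3, 4)), drive_id=f"d{i}") for i in range(4)]
        order = rank_by_logit(windows, np.array([2.3, -3.1, 0.2, -0.1]))
        assert order == [1, 0, 2, 3]

    def test_single_sample(self):
        assert rank_by_logit([make_window(np.zeros((3, 4)))], np.array([0.5])) == [0]

    def test_tie_broken_by_drive_then_offset(self):
        windows = [
            make_window(np.zeros((3, 4)), drive_id="b", start=0),
            make_window(np.zeros((3, 4)), drive_id="a", start=5),
            make_window(np.zeros((3, 4)), drive_id="a", start=2),
        ]
        assert rank_by_logit(windows, np.array([1.0, -1.0, 1.0])) == [2, 1, 0]

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            rank_by_logit([make_window(np.zeros((3, 4)))], np.array([np.nan]))


class TestExemplars:
    @staticmethod
    def _model_and_windows(n, seed=6):
        model = build_dixonnet(ModelConfig(architecture="dixonnet", width=4, seed=seed))
        rng = np.random.default_rng(seed)
        windows = []
        logits = []
        for i in range(n):
            x = rng.normal(0, 1, (3, 64)).astype(np.float32)
            w = make_window(x, drive_id=f"d{i}", label=0)
            logit, *_ = model.forward_with_features(x)
            w.label = int(logit >= 0)  # force correctness so selection is exercised
            windows.append(w)
            logits.append(logit)
        return model, windows, np.array(logits)

    def test_top_and_bottom_disjoint(self):
        model, windows, logits = self._model_and_windows(40)
        ex = select_exemplars(model, windows, logits, n=5)
        for cls in (0, 1):
            top_ids = {(c.window.drive_id, c.window.start_index) for c in ex.highest[cls]}
            bottom_ids = {(c.window.drive_id, c.window.start_index) for c in ex.lowest[cls]}
            if len(top_ids) == 5 and len(bottom_ids) == 5:
                assert top_ids.isdisjoint(bottom_ids)

    def test_few_samples_warns_and_returns_all(self):
        model, windows, logits = self._model_and_windows(3)
        with pytest.warns(UserWarning, match="overlap"):
            ex = select_exemplars(model, windows, logits, n=5)
        counted = sum(len(v) for v in ex.highest.values())
        assert counted == 3

    def test_sign_convention_for_negative_class(self):
        model = build_dixonnet(ModelConfig(architecture="dixonnet", width=4, seed=8))
        rng = np.random.default_rng(8)
        for _ in range(10):
            x = rng.normal(0, 1, (3, 64)).astype(np.float32)
            window = make_window(x)
            result = cam_for_window(model, window)
            _, fmap, w, _ = model.forward_with_features(x)
            expected_w = w if result.predicted_class == 1 else -w
            assert np.allclose(result.M, compute_cam(fmap, expected_w), atol=1e-6)
            if result.predicted_class == 0:
                break
        else:
            pytest.skip("random model never predicted the negative class")


class TestRendering:
    def test_panel_range_rule(self):
        values = np.full(100, 0.98)
        assert panel_ylim(values) == pytest.approx((0.48, 1.48))

    def test_plot_file_written(self, tmp_path):
        rng = np.random.default_rng(9)
        window = make_window(rng.normal(0, 0.1, (3, 128)).astype(np.float32))
        model = build_dixonnet(ModelConfig(architecture="dixonnet", width=4, seed=9))
        result = cam_for_window(model, window)
        out = tmp_path / "cam.png"
        render_cam_plot(window, result, out)
        assert out.exists() and out.stat().st_size > 0

    def test_constant_cam_renders(self, tmp_path):
        window = make_window(np.zeros((3, 64), dtype=np.float32))
        model = build_dixonnet(ModelConfig(architecture="dixonnet", width=4, seed=10))
        result = cam_for_window(model, window)
        render_cam_plot(window, result, tmp_path / "flat.png")
        assert (tmp_path / "flat.png").exists()


class TestLocalization:
    def test_cam_peak_lies_within_injected_burst(self):
        """Train a small net where class evidence is one burst; the CAM
        maximum for the positive class must localize that burst."""
        rng = np.random.default_rng(12)
        L, burst_len = 512, 40

        def sample(n):
            x = rng.normal(0, 0.05, (n, 3, L))
            labels = rng.integers(0, 2, n)
            positions = np.full(n, -1)
            for i in range(n):
                if labels[i]:
                    p = int(rng.integers(0, L - burst_len))
                    envelope = np.sin(np.pi * np.arange(burst_len) / burst_len) ** 2
                    x[i, 0, p : p + burst_len] += 1.5 * envelope
                    positions[i] = p
            return x.astype(np.float32), labels.astype(np.float64), positions

        model = build_dixonnet(ModelConfig(architecture="dixonnet", width=16, dropout_p=0.0, seed=12))
        opt = Adam(model.params(), lr=1e-3)
        for _ in range(60):
            xb, yb, _ = sample(32)
            logits = model.forward(xb, train=True)
            opt.zero_grad()
            model.backward(bce_grad(logits, yb).astype(np.float32))
            opt.step()

        x_test, y_test, pos = sample(60)
        receptive_field = 160  # 4 convs of kernel 16 around one max-pool of 4
        hits = trials = 0
        for i in range(len(y_test)):
            if y_test[i] != 1:
                continue
            window = make_window(x_test[i])
            result = cam_for_window(model, window)
            if result.predicted_class != 1:
                continue
            trials += 1
            peak = int(np.argmax(result.upsampled))
            lo = pos[i] - receptive_field
            hi = pos[i] + burst_len + receptive_field
            hits += int(lo <= peak <= hi)
        assert trials >= 10
        assert hits / trials >= 0.9
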