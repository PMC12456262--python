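from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nadd_ct import (
    CNN10,
    NetworkSpec,
    adjust_width_for_parity,
    augment_input_channels,
    build_cnn10,
    count_parameters,
)
from nadd_ct.networks import BackboneDescriptor, CANONICAL_CNN10, NetworkSpecError


class TestParameterAccounting:
    def test_canonical_augmented_count(self):
        assert count_parameters(replace(CANONICAL_CNN10, N=10)) == 76_353

    def test_width_adjusted_baseline_count(self):
        adjusted = adjust_width_for_parity(CANONICAL_CNN10, reference_N=10)
        assert adjusted.n1 == 205
        assert count_parameters(adjusted) == 76_683
        assert count_parameters(adjusted) > 76_353

    def test_unaugmented_count_term_by_term(self):
        # hand evaluation: 64*81*1 + 64 + 32*9*64 + 32 + 25*32 + 1
        assert count_parameters(CANONICAL_CNN10) == 5184 + 64 + 18432 + 32 + 800 + 1

    def test_formula_matches_built_network_for_canonical_specs(self):
        for N in (0, 3, 10):
            spec = replace(CANONICAL_CNN10, N=N)
            assert build_cnn10(spec).n_parameters() == count_parameters(spec)

    @settings(max_examples=50, deadline=None)
    @given(
        s1=st.sampled_from([1, 3, 5, 9]),
        s2=st.sampled_from([1, 3, 5]),
        s3=st.sampled_from([1, 3, 5]),
        n1=st.integers(1, 32),
        n2=st.integers(1, 16),
        N=st.integers(0, 10),
    )
    def test_formula_equals_enumeration_property(self, s1, s2, s3, n1, n2, N):
        spec = NetworkSpec(s1=s1, s2=s2, s3=s3, n1=n1, n2=n2, N=N)
        assert build_cnn10(spec).n_parameters() == count_parameters(spec)

    def test_count_strictly_increasing_in_each_hyperparameter(self):
        base = replace(CANONICAL_CNN10, N=2)
        for field, step in (("n1", 1), ("n2", 1), ("N", 1)):
            bumped = replace(base, **{field: getattr(base, field) + step})
            assert count_parameters(bumped) > count_parameters(base)


class TestParityAdjustment:
    def test_adjusted_n1_is_minimal(self):
        adjusted = adjust_width_for_parity(CANONICAL_CNN10, reference_N=10)
        target = count_parameters(replace(CANONICAL_CNN10, N=10))
        assert count_parameters(replace(adjusted, n1=adjusted.n1 - 1)) < target

    def test_parity_with_itself_is_identity(self):
        assert adjust_width_for_parity(CANONICAL_CNN10, reference_N=0) == CANONICAL_CNN10

    def test_requires_unaugmented_base(self):
        with pytest.raises(NetworkSpecError):
            adjust_width_for_parity(replace(CANONICAL_CNN10, N=2), reference_N=10)


class TestAugmentationContract:
    def test_spec_augmentation_reaches_canonical(self):
        assert augment_input_channels(CANONICAL_CNN10, 10) == replace(CANONICAL_CNN10, N=10)

    def test_zero_is_identity(self):
        assert augment_input_channels(CANONICAL_CNN10, 0) == CANONICAL_CNN10

    def test_parameter_delta_is_first_layer_kernel_volume(self):
        delta = count_parameters(replace(CANONICAL_CNN10, N=10)) - count_parameters(
            CANONICAL_CNN10
        )
        assert delta == 64 * 81 * 10

    def test_generic_backbone(self):
        bb = BackboneDescriptor(
            name="resnet", input_channels=1, first_layer_kernel=3, first_layer_features=128
        )
        out = augment_input_channels(bb, 6)
        assert out.input_channels == 7
        assert bb.augmentation_parameter_delta(6) == 9 * 128 * 6

    def test_unsupported_backbone_rejected(self):
        with pytest.raises(NetworkSpecError):
            augment_input_channels(object(), 3)


class TestLabels:
    def test_subscript_notation_round_trips(self):
        for N in (0, 1, 6, 10):
            spec = replace(CANONICAL_CNN10, N=N)
            assert NetworkSpec.from_label(spec.label) == spec
        assert replace(CANONICAL_CNN10, N=6).label == "CNN10+6"
        assert CANONICAL_CNN10.label == "CNN10"

    def test_spec_serialization_round_trip(self):
        spec = replace(CANONICAL_CNN10, N=4)
        assert NetworkSpec.from_dict(spec.to_dict()) == spec


class TestNetworkForward:
    def test_same_padding_preserves_spatial_size(self):
        model = build_cnn10(replace(CANONICAL_CNN10, N=10))
        out = model.predict(np.zeros((2, 11, 64, 64), np.float32))
        assert out.shape == (2, 1, 64, 64)

    def test_zero_weights_emit_constant_bias(self):
        model = build_cnn10(CANONICAL_CNN10)
        model.set_parameters([np.zeros_like(p) for p in model.parameters()])
        model.b3[:] = 2.5
        out = model.predict(np.random.default_rng(0).normal(size=(1, 1, 16, 16)).astype(np.float32))
        assert np.allclose(out, 2.5)

    def test_channel_mismatch_raises(self):
        model = build_cnn10(replace(CANONICAL_CNN10, N=3))
        with pytest.raises(NetworkSpecError, match="4"):
            model.predict(np.zeros((1, 2, 16, 16), np.float32))

    def test_gradients_match_finite_differences(self):
        spec = NetworkSpec(s1=3, s2=3, s3=3, n1=4, n2=3, N=1)
        model = build_cnn10(spec, seed=2)
        x = np.random.default_rng(1).normal(size=(1, 2, 8, 8)).astype(np.float32)
        t = np.random.default_rng(2).normal(size=(1, 1, 8, 8)).astype(np.float32)

        def loss():
            out = model.forward(x)
            return 0.5 * float(np.sum((out - t) ** 2)), out

        _, out = loss()
        grads = model.backward(out - t)
        rng = np.random.default_rng(3)
        for p, g in zip(model.parameters(), grads):
            flat = rng.integers(0, p.size, size=2)
            for k in flat:
                idx = np.unravel_index(k, p.shape)
                eps = 2e-3
                orig = p[idx]
                p[idx] = orig + eps
                l_plus, _ = loss()
                p[idx] = orig - eps
                l_minus, _ = loss()
                p[idx] = orig
                numeric = (l_plus - l_minus) / (2 * eps)
                # float32 forward passes limit finite-difference accuracy
                assert g[idx] == pytest.approx(numeric, rel=0.08, abs=5e-3)

    def test_invalid_spec_rejected(self):
        with pytest.raises(NetworkSpecError):
            NetworkSpec(s1=4)
        with pytest.raises(NetworkSpecError):
            NetworkSpec(n1=0)
        with pytest.raises(NetworkSpecError):
            NetworkSpec(N=-1)
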