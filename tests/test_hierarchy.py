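"""Network assembly and training: tiling, architecture identities, batch
training, generic lower-layer training, ICA attachment, forward pass."""

import numpy as np
import pytest

import placesim as ps
from placesim import hierarchy
from placesim.hierarchy import _sfa_outputs
from placesim.sfa import apply_sfa

from conftest import tiny_network


class TestTiling:
    @pytest.mark.parametrize(
        "args,expected",
        [
            ((320, 40, (10, 8), (5, 4)), (63, 9)),
            ((63, 9, (14, 5), (7, 4)), (8, 2)),
            ((10, 10, (4, 4), (3, 3)), (3, 3)),
        ],
    )
    def test_exact_tilings(self, args, expected):
        assert ps.tile(*args) == expected

    def test_inexact_tiling_reports_residue(self):
        with pytest.raises(ps.ConfigurationError, match="residue"):
            ps.tile(320, 40, (10, 8), (6, 4))

    def test_default_architecture_grids(self):
        net = hierarchy.default_architecture()
        assert net.grid_shapes() == [(63, 9), (8, 2), (1, 1)]
        l1, l2 = net.layers[0].spec, net.layers[1].spec
        # tiling identities of the decided receptive fields
        assert (l1.cols - 1) * l1.stride[0] + l1.rf[0] == 320
        assert (l1.rows - 1) * l1.stride[1] + l1.rf[1] == 40
        assert l2.cols * l2.rows == 16

    def test_reduced_architecture_grids(self):
        net = hierarchy.reduced_architecture()
        assert net.grid_shapes() == [(12, 3), (3, 1), (1, 1)]
        assert (net.input_w, net.input_h) == (64, 16)


class TestTraining:
    def test_batch_count_formula(self, smooth_frames):
        """1,000 frames at batch size 100 accumulate in 10 batches per layer
        (the same code path as 100,000 frames at batch size 10,000)."""
        net = tiny_network()
        hierarchy.train(net, smooth_frames[:1000], batch_size=100,
                        with_ica=False, noise_sigma=1e-4, seed=0)
        assert net.meta["n_batches"] == 10

    def test_frame_size_mismatch_rejected(self, smooth_frames):
        net = hierarchy.reduced_architecture()
        with pytest.raises(ps.ConfigurationError, match="does not match"):
            hierarchy.train(net, smooth_frames, batch_size=500)

    def test_top_outputs_satisfy_constraints(self, open_field_net, box_plan,
                                             reduced_view):
        """The trained top node's SFA outputs honor the zero-mean /
        unit-variance / decorrelation constraints on (re-rendered) training
        frames to good approximation."""
        from conftest import OPEN_FIELD

        params = ps.MotionParams()
        states = ps.generate_trajectory(
            box_plan, params, 4_000, seed=OPEN_FIELD["seed"]
        )
        frames = ps.render_sequence(box_plan, states, reduced_view) / 255.0
        y = _sfa_outputs(open_field_net, frames)
        assert np.abs(y.mean(axis=0)).max() < 0.2
        assert np.abs(y.var(axis=0) - 1).max() < 0.3

    def test_determinism_same_seed_same_network(self, smooth_frames):
        nets = []
        for _ in range(2):
            net = tiny_network()
            hierarchy.train(net, smooth_frames, batch_size=500,
                            with_ica=True, noise_sigma=1e-4, seed=42)
            nets.append(net)
        assert nets[0].parameter_hash() == nets[1].parameter_hash()

    def test_batch_equivalence(self, smooth_frames):
        """One batch vs ten batches: forward outputs agree to 1e-6 (moment
        accumulation is exact across batch boundaries)."""
        t = smooth_frames.shape[0]
        outs = []
        for bs in (t, t // 10):
            net = tiny_network()
            hierarchy.train(net, smooth_frames, batch_size=bs,
                            with_ica=False, noise_sigma=1e-4, seed=7)
            outs.append(hierarchy.forward_batch(net, smooth_frames[:100]))
        assert np.abs(outs[0] - outs[1]).max() <= 1e-6


class TestGenericTraining:
    @pytest.fixture()
    def generic_net(self, smooth_frames):
        net = tiny_network()
        hierarchy.train_generic(net, smooth_frames, batch_size=500,
                                noise_sigma=1e-4, seed=1)
        return net

    def test_lower_layers_frozen_top_untrained(self, generic_net, smooth_frames):
        assert generic_net.layers[0].trained
        assert generic_net.layers[0].frozen
        assert not generic_net.layers[-1].trained
        with pytest.raises(ps.StateError):
            hierarchy.forward_batch(generic_net, smooth_frames[:5])

    def test_train_top_leaves_lower_layers_untouched(self, generic_net,
                                                     smooth_frames):
        before = {
            k: v.copy()
            for k, v in generic_net.state_arrays().items()
            if k.startswith("layer0")
        }
        hierarchy.train_top(generic_net, smooth_frames, batch_size=500,
                            with_ica=True, seed=2)
        after = generic_net.state_arrays()
        for k, v in before.items():
            assert np.array_equal(v, after[k])
        assert hierarchy.forward_batch(
            generic_net, smooth_frames[:3]
        ).shape == (3, generic_net.out_dim)

    def test_retraining_top_loses_first_environment(self, box_plan,
                                                    reduced_view):
        """Retraining the top layer in a second enclosure destroys the first
        enclosure's place code (the model keeps no memory state)."""
        from placesim import sampling

        params = ps.MotionParams()
        plan_b = ps.make_circle(5.0, 24)
        net = hierarchy.reduced_architecture()
        frames_a = ps.render_sequence(
            box_plan,
            ps.generate_trajectory(box_plan, params, 4_000, seed=31),
            reduced_view,
        )
        hierarchy.train(net, frames_a, batch_size=2_000, with_ica=False,
                        noise_sigma=1e-4, seed=32)
        for layer in net.layers[:-1]:
            layer.frozen = True
        maps_a1 = sampling.sample_place(net, box_plan, reduced_view,
                                        spacing=1.0, signals=(1, 8))
        frames_b = ps.render_sequence(
            plan_b,
            ps.generate_trajectory(plan_b, params, 4_000, seed=33),
            reduced_view,
        )
        hierarchy.train_top(net, frames_b, batch_size=2_000, with_ica=False,
                            seed=34)
        maps_a2 = sampling.sample_place(net, box_plan, reduced_view,
                                        spacing=1.0, signals=(1, 8))
        rs = []
        for sig in range(1, 9):
            a1 = [m for m in maps_a1
                  if m.signal_index == sig and m.direction == "average"][0]
            a2 = [m for m in maps_a2
                  if m.signal_index == sig and m.direction == "average"][0]
            rs.append(abs(np.corrcoef(a1.grid[a1.mask], a2.grid[a2.mask])[0, 1]))
        assert np.median(rs) < 0.5


class TestAddICA:
    def test_add_ica_preserves_sfa_layers(self, smooth_frames):
        net = tiny_network()
        hierarchy.train(net, smooth_frames, batch_size=500, with_ica=False,
                        noise_sigma=1e-4, seed=3)
        before = net.parameter_hash()
        hierarchy.add_ica(net, smooth_frames, seed=4)
        after_arrays = net.state_arrays()
        assert "ica/rotation" in after_arrays
        net.ica = None
        assert net.parameter_hash() == before

    def test_add_ica_twice_rejected(self, smooth_frames):
        net = tiny_network()
        hierarchy.train(net, smooth_frames, batch_size=500, with_ica=True,
                        noise_sigma=1e-4, seed=3)
        with pytest.raises(ps.StateError):
            hierarchy.add_ica(net, smooth_frames)

    def test_output_dimension_unchanged(self, smooth_frames):
        net = tiny_network()
        hierarchy.train(net, smooth_frames, batch_size=500, with_ica=False,
                        noise_sigma=1e-4, seed=3)
        d0 = hierarchy.forward_batch(net, smooth_frames[:2]).shape[1]
        hierarchy.add_ica(net, smooth_frames, seed=4)
        assert hierarchy.forward_batch(net, smooth_frames[:2]).shape[1] == d0


class TestForward:
    def test_output_is_32_signals(self, open_field_net, box_plan, reduced_view):
        frame = ps.render_view(box_plan, ps.AgentState((5.0, 5.0), 0.0),
                               reduced_view)
        out = hierarchy.forward(open_field_net, frame)
        assert out.shape == (32,)

    def test_identical_frames_identical_outputs(self, open_field_net,
                                                box_plan, reduced_view):
        frame = ps.render_view(box_plan, ps.AgentState((3.0, 7.0), 1.0),
                               reduced_view)
        a = hierarchy.forward(open_field_net, frame)
        b = hierarchy.forward(open_field_net, frame)
        assert np.array_equal(a, b)

    def test_untrained_network_raises(self, smooth_frames):
        net = tiny_network()
        with pytest.raises(ps.StateError):
            hierarchy.forward_batch(net, smooth_frames[:2])

    def test_matches_hand_rolled_composition(self, smooth_frames):
        """forward equals explicitly gathering receptive fields and chaining
        apply_sfa node by node."""
        net = tiny_network()
        hierarchy.train(net, smooth_frames, batch_size=500, with_ica=False,
                        noise_sigma=1e-4, seed=5)
        probe = smooth_frames[:7]
        expected = []
        l1, l2 = net.layers
        cols = l1.spec.cols
        outs1 = []
        for col in range(cols):
            c0 = col * l1.spec.stride[0]
            window = probe[:, :, c0: c0 + l1.spec.rf[0]].reshape(7, -1)
            node = l1.node(0, col)
            outs1.append(apply_sfa(node.stage2, apply_sfa(node.stage1, window)))
        layer1_out = np.concatenate(outs1, axis=1)
        node2 = l2.node(0, 0)
        expected = apply_sfa(node2.stage2, apply_sfa(node2.stage1, layer1_out))
        actual = hierarchy.forward_batch(net, probe)
        assert np.allclose(actual, expected, atol=1e-12)
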