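"""Agent-based homogenizer: rules, sweeps, fixed points and dynamics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from abmff.abm import (ABMConfig, abm_step, apply_rule, neighbor_consensus,
                       run_abm)
from abmff.pipeline import pooled_within_region_std
from abmff.synthetic import generate, two_region_spec


class TestNeighborConsensus:
    def test_uniform_neighborhood_gives_zero(self):
        g = np.full((3, 3), 77)
        assert neighbor_consensus(g, 1, 1) == 0

    def test_darker_center_gives_plus_one(self):
        g = np.full((3, 3), 200)
        g[1, 1] = 10
        assert neighbor_consensus(g, 1, 1) == 1

    def test_balanced_edge_gives_zero(self):
        g = np.array([[255, 255, 255],
                      [255, 128, 0],
                      [0, 0, 0]])
        assert neighbor_consensus(g, 1, 1) == 0

    def test_boundary_uses_existing_neighbors_only(self):
        g = np.array([[5, 9], [9, 9]])
        assert neighbor_consensus(g, 0, 0) == 1  # 3 neighbours, all higher
        assert neighbor_consensus(g, 1, 1) == -1

    def test_von_neumann_ignores_diagonals(self):
        g = np.array([[9, 0, 9], [0, 5, 0], [9, 0, 9]])
        assert neighbor_consensus(g, 1, 1, "von_neumann") == -1
        assert neighbor_consensus(g, 1, 1, "moore") == 0

    def test_out_of_bounds_rejected(self):
        with pytest.raises(IndexError):
            neighbor_consensus(np.zeros((3, 3)), 3, 0)


@pytest.mark.parametrize("state,s,delta,expected", [
    (100, 1, 1, 101),
    (100, 0, 5, 100),
    (0, -1, 1, 0),       # clamp at the bottom
    (254, 1, 5, 255),    # clamp at the top
    (100, -1, 7, 93),
])
def test_apply_rule(state, s, delta, expected):
    assert apply_rule(state, s, delta) == expected


class TestSweep:
    @pytest.mark.parametrize("delta", [1, 5, 255])
    @pytest.mark.parametrize("sync", [False, True])
    def test_constant_image_is_a_fixed_point(self, delta, sync):
        g = np.full((8, 8), 77, np.uint8)
        cfg = ABMConfig(iter1=1, delta=delta, synchronous=sync)
        assert np.array_equal(abm_step(g, cfg), g)

    def test_hand_trace_pepper_pixel_in_small_field(self):
        # one sweep: the impulse takes one step up, everything moves <= delta
        g = np.full((5, 5), 200, np.uint8)
        g[2, 2] = 0
        out = abm_step(g, ABMConfig(iter1=1, delta=1))
        assert out[2, 2] == 1
        assert int(np.max(np.abs(out.astype(int) - g.astype(int)))) <= 1

    @given(seed=st.integers(0, 2 ** 20), delta=st.integers(1, 9),
           sync=st.booleans())
    def test_bounded_states_and_lipschitz_step(self, seed, delta, sync):
        g = np.random.default_rng(seed).integers(0, 256, (7, 7)).astype(np.uint8)
        out = abm_step(g, ABMConfig(iter1=1, delta=delta, synchronous=sync))
        assert out.min() >= 0 and out.max() <= 255
        assert int(np.max(np.abs(out.astype(int) - g.astype(int)))) <= delta

    @pytest.mark.parametrize("neighborhood", ["moore", "von_neumann"])
    @pytest.mark.parametrize("scan", ["right_to_left", "left_to_right"])
    def test_sweep_equals_literal_transcription(self, neighborhood, scan,
                                                literal_sweep_oracle):
        rng = np.random.default_rng(11)
        for delta in (1, 2, 5):
            g = rng.integers(0, 256, (6, 6)).astype(np.uint8)
            out = abm_step(g, ABMConfig(iter1=1, delta=delta,
                                        neighborhood=neighborhood, scan=scan))
            ref = literal_sweep_oracle(g, delta, neighborhood,
                                       scan == "right_to_left")
            assert np.array_equal(out, ref)


class TestRunABM:
    def test_zero_iterations_is_identity(self):
        g = np.random.default_rng(0).integers(0, 256, (10, 10)).astype(np.uint8)
        assert np.array_equal(run_abm(g, ABMConfig(iter1=0)), g)

    def test_impulse_and_field_meet_in_the_middle(self):
        # In an exactly uniform field the sign rule is tie-dominated: the
        # field drains delta per sweep while the impulse climbs, so the
        # grid converges to a uniform value midway between the two - the
        # impulse is removed collectively, not by climbing to the field.
        g = np.full((11, 11), 200, np.uint8)
        g[5, 5] = 0
        out = run_abm(g, ABMConfig(iter1=150, delta=1))
        assert out.min() == out.max() == 100

    def test_homogenization_shrinks_within_region_dispersion(self):
        spec = two_region_spec(40, 40, sp_count=160, seed=5)
        _, noisy, labels = generate(spec)
        before = pooled_within_region_std(noisy, labels)
        after = pooled_within_region_std(
            run_abm(noisy, ABMConfig(iter1=30, delta=1)), labels)
        assert after < before

    def test_callback_sees_every_iteration(self):
        seen = []
        run_abm(np.full((4, 4), 9, np.uint8), ABMConfig(iter1=3),
                callback=lambda t, g: seen.append((t, g.dtype)))
        assert [t for t, _ in seen] == [0, 1, 2, 3]
        assert all(d == np.uint8 for _, d in seen)


def test_config_validation():
    with pytest.raises(ValueError):
        ABMConfig(iter1=-1)
    with pytest.raises(ValueError):
        ABMConfig(delta=0)
    with pytest.raises(ValueError):
        ABMConfig(neighborhood="hex")
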