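import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import vesiflow as vf
from vesiflow.direction import (
    Label,
    angle_difference,
    center_angle_map,
    center_error_sensitivity,
    classify,
    direction_map,
    sensitivity_by_offset,
    summaries_to_dataframe,
    summarize_series,
    to_center_angle,
)
from vesiflow.errors import ValidationError
from vesiflow.optical_flow import FlowField, FlowParams


def make_flow(vx, vy, valid=None):
    vx = np.asarray(vx, dtype=float)
    vy = np.asarray(vy, dtype=float)
    if valid is None:
        valid = np.ones(vx.shape, dtype=bool)
    return FlowField(vx=vx, vy=vy, valid=valid, params=FlowParams())


def radial_flow(shape, center, outward=False, speed=1.0):
    """Synthetic flow pointing exactly at (or away from) the center."""
    alpha = center_angle_map(shape, center)
    vx = speed * np.cos(alpha)
    vy = speed * np.sin(alpha)
    if outward:
        vx, vy = -vx, -vy
    valid = np.isfinite(alpha)
    return make_flow(np.nan_to_num(vx), np.nan_to_num(vy), valid)


angles = st.floats(min_value=-np.pi + 1e-9, max_value=np.pi, allow_nan=False)


class TestAngles:
    def test_axis_cases(self):
        # one column left of center: to-center vector points +x
        assert to_center_angle((5, 4), (5, 5)) == pytest.approx(0.0)
        # one row above center (smaller row index): +y in the y-down frame
        assert to_center_angle((4, 5), (5, 5)) == pytest.approx(np.pi / 2)
        # one column right: -x direction, angle pi
        assert abs(to_center_angle((5, 6), (5, 5))) == pytest.approx(np.pi)
        # one row below: -y
        assert to_center_angle((6, 5), (5, 5)) == pytest.approx(-np.pi / 2)

    def test_pixel_at_center_undefined(self):
        assert np.isnan(to_center_angle((5.0, 5.0), (5.0, 5.0)))

    @given(
        st.tuples(st.floats(0, 20), st.floats(0, 20)),
        st.tuples(st.floats(0, 20), st.floats(0, 20)),
    )
    def test_matches_componentwise_atan2(self, pixel, center):
        alpha = to_center_angle(pixel, center)
        dy = center[0] - pixel[0]
        dx = center[1] - pixel[1]
        if np.hypot(dx, dy) < 1e-9:
            assert np.isnan(alpha)
        else:
            assert alpha == pytest.approx(np.arctan2(dy, dx))

    def test_map_matches_scalar(self):
        amap = center_angle_map((7, 7), (3.2, 3.8))
        for pix in [(0, 0), (6, 2), (3, 3)]:
            assert amap[pix] == pytest.approx(to_center_angle(pix, (3.2, 3.8)))


class TestAngleDifference:
    def test_equal_angles(self):
        assert angle_difference(1.2, 1.2) == 0.0

    def test_wrap_across_branch_cut(self):
        """3pi/4 vs -3pi/4: the short way round is pi/2, not 3pi/2."""
        assert angle_difference(3 * np.pi / 4, -3 * np.pi / 4) == pytest.approx(np.pi / 2)

    @given(angles, angles)
    def test_matches_enumeration_oracle(self, a, b):
        expected = min(abs(a - b + 2 * np.pi * k) for k in (-1, 0, 1))
        delta = float(angle_difference(a, b))
        assert delta == pytest.approx(expected, abs=1e-12)
        assert 0.0 <= delta <= np.pi


class TestClassify:
    def test_boundary_semantics(self):
        """delta=0 inward, pi outward, pi/2 inward (closed interval)."""
        assert classify(0.0, 1.0) == Label.INWARD
        assert classify(np.pi, 1.0) == Label.OUTWARD
        assert classify(np.pi / 2, 1.0) == Label.INWARD
        assert classify(np.pi / 2 + 1e-9, 1.0) == Label.OUTWARD

    def test_magnitude_threshold_excludes(self):
        assert classify(0.0, 0.05, magnitude_min=0.1) == Label.EXCLUDED

    def test_tangential_band_option(self):
        assert classify(np.pi / 2, 1.0, tangential_band=0.1) == Label.EXCLUDED
        assert classify(np.pi / 2 - 0.2, 1.0, tangential_band=0.1) == Label.INWARD

    def test_exhaustive_grid(self):
        deltas = np.linspace(0, np.pi, 721)
        labels = classify(deltas, np.ones_like(deltas))
        expected = np.where(deltas <= np.pi / 2, Label.INWARD, Label.OUTWARD)
        np.testing.assert_array_equal(labels, expected)


class TestDirectionMap:
    center = (10.0, 10.0)
    shape = (21, 21)

    def test_purely_inward_flow_all_inward(self):
        flow = radial_flow(self.shape, self.center)
        dmap = direction_map(flow, self.center)
        assert np.all(dmap.label[dmap.included] == Label.INWARD)
        assert dmap.included.sum() > 400 - 5

    def test_purely_outward_flow_all_outward(self):
        flow = radial_flow(self.shape, self.center, outward=True)
        dmap = direction_map(flow, self.center)
        assert np.all(dmap.label[dmap.included] == Label.OUTWARD)
        np.testing.assert_allclose(dmap.delta[dmap.included], np.pi, atol=1e-9)

    def test_tangential_flow_is_inward_at_half_pi(self):
        """Rotating flow sits exactly on the pi/2 boundary -> Inward."""
        inw = radial_flow(self.shape, self.center)
        tang = make_flow(-inw.vy, inw.vx, inw.valid)  # rotate each vector +90 deg
        dmap = direction_map(tang, self.center)
        np.testing.assert_allclose(dmap.delta[dmap.included], np.pi / 2, atol=1e-9)
        assert np.all(dmap.label[dmap.included] == Label.INWARD)

    def test_center_pixel_excluded(self):
        flow = radial_flow(self.shape, self.center)
        dmap = direction_map(flow, self.center)
        assert dmap.label[10, 10] == Label.EXCLUDED

    def test_negating_flow_swaps_labels_except_boundary(self, rng):
        vx, vy = rng.normal(size=(2, 15, 15))
        flow = make_flow(vx, vy)
        neg = make_flow(-vx, -vy)
        d0 = direction_map(flow, (7.0, 7.0), magnitude_min=0.0)
        d1 = direction_map(neg, (7.0, 7.0), magnitude_min=0.0)
        both = d0.included & d1.included
        at_boundary = np.isclose(d0.delta, np.pi / 2)
        swapped = both & ~at_boundary
        assert np.all(d0.label[swapped] != d1.label[swapped])
        assert np.all(d1.label[both & at_boundary] == Label.INWARD)

    def test_quarter_turn_rotation_preserves_delta(self, rng):
        """Rigidly rotating flow and grid about the center leaves delta unchanged."""
        vx, vy = rng.normal(size=(2, 21, 21))
        d0 = direction_map(make_flow(vx, vy), self.center, magnitude_min=0.0)
        # rotate the grid by +90 deg in (x, y): out[i, j] = in[j, n-1-i],
        # and each vector (vx, vy) -> (-vy, vx)
        vx_r = np.rot90(-vy, k=-1)
        vy_r = np.rot90(vx, k=-1)
        d1 = direction_map(make_flow(vx_r, vy_r), self.center, magnitude_min=0.0)
        np.testing.assert_allclose(
            np.rot90(d0.delta, k=-1), d1.delta, atol=1e-9, equal_nan=True
        )

    def test_geometry_mismatch_rejected(self):
        est = vf.CenterEstimate(
            std_map=np.zeros((8, 8)), sigma_mean=1.0, sigma_s=0.5,
            mask=np.ones((8, 8), dtype=bool), center=(4.0, 4.0), mask_size=64,
            mode="literal", foreground=np.ones((8, 8), dtype=bool),
        )
        bad = make_flow(np.zeros((4, 4)), np.zeros((4, 4)))
        with pytest.raises(ValidationError):
            direction_map(bad, est)


class TestSummaries:
    def test_counts_and_proportions(self):
        label = np.array([[1, 1, 1, 2, 0]], dtype=np.uint8)
        mag = np.array([[1.0, 1.0, 1.0, 2.0, 0.0]])
        dmap = vf.DirectionMap(
            alpha=np.zeros((1, 5)), beta=np.zeros((1, 5)), delta=np.zeros((1, 5)),
            magnitude=mag, label=label, center=(0.0, 0.0), magnitude_min=0.1,
        )
        s = summarize_series([dmap])[0]
        assert (s.n_vectors, s.n_inward, s.n_outward) == (4, 3, 1)
        assert s.prop_inward == pytest.approx(0.75)
        assert s.total_magnitude == pytest.approx(5.0)

    def test_empty_frame_proportions_undefined(self):
        label = np.zeros((3, 3), dtype=np.uint8)
        dmap = vf.DirectionMap(
            alpha=np.zeros((3, 3)), beta=np.full((3, 3), np.nan),
            delta=np.full((3, 3), np.nan), magnitude=np.zeros((3, 3)),
            label=label, center=(1.0, 1.0), magnitude_min=0.1,
        )
        s = summarize_series([dmap])[0]
        assert s.n_vectors == 0
        assert np.isnan(s.prop_inward) and np.isnan(s.prop_outward)

    def test_matches_brute_force_recount(self, rng):
        maps = []
        for _ in range(3):
            vx, vy = rng.normal(size=(2, 12, 12))
            maps.append(direction_map(make_flow(vx, vy), (5.5, 5.5)))
        df = summaries_to_dataframe(summarize_series(maps))
        for k, dmap in enumerate(maps):
            inc = dmap.label != Label.EXCLUDED
            assert df.loc[k, "n_inward"] == int((dmap.label == Label.INWARD).sum())
            assert df.loc[k, "n_vectors"] == int(inc.sum())
            assert df.loc[k, "total_magnitude"] == pytest.approx(
                dmap.magnitude[inc].sum()
            )


class TestSensitivity:
    def test_zero_offset_zero_discrepancy(self):
        flow = radial_flow((21, 21), (10.0, 10.0))
        df = center_error_sensitivity([flow], (10.0, 10.0), offsets=[0], n_angles=4)
        assert (df["flip_percent"] == 0.0).all()
        assert (df["mean_delta_error"] == 0.0).all()

    def test_row_bookkeeping(self):
        flow = radial_flow((21, 21), (10.0, 10.0))
        df = center_error_sensitivity([flow], (10.0, 10.0), offsets=[1, 2], n_angles=6)
        assert len(df) == 12
        assert set(df["offset"]) == {1, 2}

    def test_flip_decision_matches_hand_geometry(self):
        """One vector, one displaced center, flip checked by hand.

        A vector at pixel (10, 4) pointing +x (toward a center at column
        10) is Inward for the true center but Outward once the center is
        displaced to (4, 10): the to-center direction turns by more than
        pi/2 (hand computation: alpha_true = 0, alpha_disp = atan2(-6, 6)
        = -pi/4 ... delta_disp = pi/4 -> no flip; displacing to (10, 2)
        puts the center behind the pixel: alpha_disp = pi, delta = pi ->
        flip).
        """
        vx = np.zeros((21, 21))
        vy = np.zeros((21, 21))
        valid = np.zeros((21, 21), dtype=bool)
        vx[10, 4] = 1.0
        valid[10, 4] = True
        flow = make_flow(vx, vy, valid)
        ref = direction_map(flow, (10.0, 10.0))
        assert ref.label[10, 4] == Label.INWARD
        behind = direction_map(flow, (10.0, 2.0))
        assert behind.label[10, 4] == Label.OUTWARD

    def test_flip_percentage_nondecreasing_on_radial_scene(self):
        cfg = vf.SceneConfig(seed=0, n_frames=5)
        stack, truth = vf.generate_movie(cfg)
        flows = vf.compute_flow_series(stack)
        df = center_error_sensitivity(flows, truth.cell_center, offsets=(1, 2, 5, 10))
        agg = sensitivity_by_offset(df)
        flips = agg.sort_values("offset")["flip_percent"].to_numpy()
        assert np.all(np.diff(flips) >= 0)

    def test_out_of_image_displacement_skipped(self):
        flow = radial_flow((15, 15), (7.0, 7.0))
        df = center_error_sensitivity([flow], (7.0, 7.0), offsets=[20], n_angles=4)
        assert len(df) == 0

    def test_invalid_arguments(self):
        flow = radial_flow((15, 15), (7.0, 7.0))
        with pytest.raises(ValidationError):
            center_error_sensitivity([flow], (7.0, 7.0), offsets=[-1])
        with pytest.raises(ValidationError):
            center_error_sensitivity([flow], (7.0, 7.0), n_angles=2)
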