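"""Segmentation and volume quantification: nuclei, foci, and the
IQR valid-range rule."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from irif3d import (
    DEFAULT_ROLES,
    FocusGeometry,
    SimulationConfig,
    VoxelGrid,
    classify_phase,
    count_foci,
    detect_foci,
    max_valid_value,
    parse_condition_label,
    render_focus,
    segment_nuclei,
    volume_summary,
)
from irif3d.grids import ROLE_53BP1, ROLE_CYCLE, ChannelError
from irif3d.quantify import DetectionParams, NucleusRecord
from irif3d.simulate import _ellipsoid_mask, iter_condition_nuclei


def nuclear_stack(centres, semi=(1.5, 2.5, 2.5), extent=(6.0, 14.0, 14.0), amp=80.0):
    """Stack with pan-nuclear marker ellipsoids at the given µm centres."""
    vs = (0.2, 0.1, 0.1)
    shape = tuple(int(e / v) for e, v in zip(extent, vs))
    grid = VoxelGrid.empty(shape, vs, DEFAULT_ROLES)
    for c in centres:
        grid.channel(ROLE_CYCLE)[_ellipsoid_mask(shape, vs, c, semi)] += amp
    return grid


def full_mask_nucleus(grid):
    return NucleusRecord(nucleus_id=0, mask=np.ones(grid.shape, bool), mean_cycle_marker=0.0)


class TestSegmentNuclei:
    def test_three_disjoint_nuclei(self):
        stack = nuclear_stack([(3.0, 3.0, 3.0), (3.0, 3.0, 10.0), (3.0, 10.0, 6.0)])
        assert len(segment_nuclei(stack)) == 3

    def test_empty_stack_gives_no_nuclei(self):
        stack = nuclear_stack([])
        assert segment_nuclei(stack) == []

    def test_touching_nuclei_excluded_by_size_ceiling(self):
        # two barely-overlapping ellipsoids form one oversized component
        # (single ellipsoid volume ~147 µm³; merged pair well above 176)
        stack = nuclear_stack([(3.0, 4.5, 3.5), (3.0, 4.5, 10.5)], semi=(2.2, 4.0, 4.0))
        params = DetectionParams(max_nucleus_volume_um3=176.0)
        assert segment_nuclei(stack, params) == []

    def test_missing_nuclear_channel_raises(self):
        grid = VoxelGrid.empty((4, 4, 4), (0.2, 0.1, 0.1), ("A",))
        with pytest.raises(ChannelError):
            segment_nuclei(grid)


class TestClassifyPhase:
    def test_generator_phases_recovered(self):
        cfg = SimulationConfig(n_nuclei=2, seed=3)
        for label, expected in (("control_G2_8h", "G2"), ("control_G1_8h", "G1")):
            for stack, _ in iter_condition_nuclei(parse_condition_label(label), cfg):
                (nucleus,) = segment_nuclei(stack)
                assert classify_phase(nucleus, stack) == expected

    def test_zero_marker_is_g1(self):
        stack = nuclear_stack([(3.0, 3.0, 3.0)], amp=80.0)
        (nucleus,) = segment_nuclei(stack)
        stack.channel(ROLE_CYCLE)[:] = 0.0
        assert classify_phase(nucleus, stack) == "G1"

    def test_infinite_threshold_makes_everything_g1(self):
        stack = nuclear_stack([(3.0, 3.0, 3.0)])
        (nucleus,) = segment_nuclei(stack)
        assert classify_phase(nucleus, stack, threshold=math.inf) == "G1"


class TestDetectFoci:
    VS = (0.1, 0.1, 0.1)

    def render(self, geom_kwargs, extent=3.0):
        shape = (int(extent / 0.1),) * 3
        grid = VoxelGrid.empty(shape, self.VS, ("53BP1",) + DEFAULT_ROLES[1:])
        centre = (extent / 2,) * 3
        render_focus(grid, FocusGeometry(centre=centre, amplitude=100.0, **geom_kwargs),
                     ROLE_53BP1)
        return grid

    def test_solid_sphere_volume_within_15_percent(self):
        grid = self.render(dict(kind="solid_sphere", outer_radius=0.5))
        (focus,) = detect_foci(grid, full_mask_nucleus(grid), ROLE_53BP1)
        assert focus.volume == pytest.approx(4 / 3 * math.pi * 0.5**3, rel=0.15)

    def test_hollow_shell_is_one_filled_focus(self):
        grid = self.render(dict(kind="hollow_shell", outer_radius=0.6, inner_radius=0.3))
        regions = detect_foci(grid, full_mask_nucleus(grid), ROLE_53BP1)
        assert len(regions) == 1
        assert regions[0].volume == pytest.approx(4 / 3 * math.pi * 0.6**3, rel=0.15)

    def test_zero_signal_gives_no_foci(self):
        grid = VoxelGrid.empty((20, 20, 20), self.VS, DEFAULT_ROLES)
        assert detect_foci(grid, full_mask_nucleus(grid), ROLE_53BP1) == []

    def test_foci_confined_to_nucleus_mask(self):
        grid = self.render(dict(kind="solid_sphere", outer_radius=0.5))
        nucleus = full_mask_nucleus(grid)
        nucleus.mask[:, :, : grid.shape[2] // 2] = False  # cut through the focus
        (focus,) = detect_foci(grid, nucleus, ROLE_53BP1)
        assert nucleus.mask[tuple(focus.coords.T)].all()

    def test_volume_estimation_unbiased_over_random_spheres(self):
        rng = np.random.default_rng(17)
        errors = []
        for _ in range(30):
            r = rng.uniform(0.3, 1.0)
            grid = self.render(dict(kind="solid_sphere", outer_radius=r))
            (focus,) = detect_foci(grid, full_mask_nucleus(grid), ROLE_53BP1)
            truth = 4 / 3 * math.pi * r**3
            errors.append(abs(focus.volume - truth) / truth)
        assert np.median(errors) < 0.15

    def test_clumped_foci_merge_and_exceed_the_fence(self):
        # several isolated foci plus one deliberately clumped pair
        extent, r = 6.0, 0.45
        shape = (int(extent / 0.1),) * 3
        grid = VoxelGrid.empty(shape, self.VS, DEFAULT_ROLES)
        singles = [(1.2, 1.2, 1.2), (1.2, 1.2, 4.5), (1.2, 4.5, 1.2),
                   (4.5, 1.2, 1.2), (4.5, 4.5, 4.5), (1.2, 4.5, 4.5)]
        for c in singles:
            render_focus(grid, FocusGeometry(kind="solid_sphere", outer_radius=r,
                                             amplitude=100.0, centre=c), ROLE_53BP1)
        for c in [(4.5, 4.5, 1.1), (4.5, 4.5, 1.75)]:  # overlapping pair
            render_focus(grid, FocusGeometry(kind="solid_sphere", outer_radius=r,
                                             amplitude=100.0, centre=c), ROLE_53BP1)
        regions = detect_foci(grid, full_mask_nucleus(grid), ROLE_53BP1)
        assert len(regions) == len(singles) + 1  # pair merged into one object
        summary = volume_summary(regions)
        assert summary.n_excluded >= 1
        assert summary.max_valid < max(x.volume for x in regions)


class TestCountFoci:
    def test_mean_count_recovers_poisson_mean(self):
        cfg = SimulationConfig(n_nuclei=50, seed=21)
        counts = []
        for stack, _ in iter_condition_nuclei(parse_condition_label("control_G2_0.5h"), cfg):
            (nucleus,) = segment_nuclei(stack)
            counts.append(count_foci(stack, nucleus, ROLE_53BP1))
        se = math.sqrt(cfg.foci_per_nucleus_mean / cfg.n_nuclei)
        assert abs(np.mean(counts) - cfg.foci_per_nucleus_mean) <= 2 * se

    def test_empty_nucleus_counts_zero(self):
        grid = VoxelGrid.empty((20, 20, 20), (0.1, 0.1, 0.1), DEFAULT_ROLES)
        assert count_foci(grid, full_mask_nucleus(grid), ROLE_53BP1) == 0


class TestMaxValidValue:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([1, 2, 3, 4, 100], 4.0),  # Q1=2, Q3=4, fence=7
            ([5, 5, 5], 5.0),  # zero IQR
            ([1, 2, 3, 4, 5], 5.0),  # fence=7 above the maximum
        ],
    )
    def test_hand_computed_fences(self, values, expected):
        assert max_valid_value(values) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            max_valid_value([])

    @given(st.lists(st.floats(0.01, 1e4), min_size=1, max_size=60),
           st.randoms(use_true_random=False))
    @settings(max_examples=100, deadline=None)
    def test_permutation_invariant_and_bounded(self, values, rnd):
        mv = max_valid_value(values)
        shuffled = list(values)
        rnd.shuffle(shuffled)
        assert max_valid_value(shuffled) == mv
        assert mv <= max(values)
        q1, q3 = np.quantile(values, [0.25, 0.75])
        assert mv <= q3 + 1.5 * (q3 - q1) + 1e-9

    @given(st.lists(st.floats(0.01, 1e4), min_size=2, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_monotone_under_adding_below_fence_values(self, values):
        mv = max_valid_value(values)
        assert max_valid_value(values + [min(values)]) >= min(values)
        # adding a value at the current max_valid never lowers it
        assert max_valid_value(values + [mv]) >= mv


class TestVolumeSummary:
    def test_example_summary(self):
        s = volume_summary([1, 2, 3, 4, 100])
        assert (s.median, s.minimum, s.max_valid, s.n_excluded) == (3.0, 1.0, 4.0, 1)

    def test_single_focus(self):
        s = volume_summary([2.5])
        assert s.median == s.minimum == s.max_valid == 2.5
        assert s.n_excluded == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            volume_summary([])
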