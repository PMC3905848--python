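"""Line-profile metrics: peaks, polarity, clearance, outer width, and the
3D core/shell cross-check."""

import math

import numpy as np
import pytest

from irif3d import (
    DEFAULT_ROLES,
    FocusGeometry,
    IntensityProfile,
    SimulationConfig,
    VoxelGrid,
    apply_psf_and_noise,
    average_profiles,
    classify_polarity,
    core_shell_score_3d,
    detect_foci,
    extract_profile,
    find_profile_peaks,
    outer_width,
    render_focus,
)
from irif3d.grids import ROLE_53BP1, ROLE_FK2, ROLE_RPA
from irif3d.profiles import ProfileBorderError, ProfileError, ProfileParams
from irif3d.quantify import NucleusRecord

from conftest import gaussian_profile

FWHM_FACTOR = 2 * math.sqrt(2 * math.log(2))  # 2.3548


def rendered_focus(kind="solid_sphere", outer=0.6, inner=0.0, blur=True, extent=5.0,
                   amplitude=200.0, noise=False, seed=4, psf=(0.12, 0.05)):
    vs = (0.2, 0.1, 0.1)
    shape = tuple(int(extent / v) for v in vs)
    grid = VoxelGrid.empty(shape, vs, DEFAULT_ROLES)
    centre = (extent / 2,) * 3
    render_focus(grid, FocusGeometry(kind=kind, outer_radius=outer, inner_radius=inner,
                                     amplitude=amplitude, centre=centre), ROLE_53BP1)
    cfg = SimulationConfig(
        psf_sigma=psf if blur else (0, 0),
        noise_gaussian_sd=6.0 if noise else 0.0,
        noise_poisson_scale=2.0 if noise else 0.0,
        seed=seed,
    )
    if noise:
        grid.data += 15.0  # nucleoplasm background, as in generated stacks
    grid = apply_psf_and_noise(grid, cfg)
    nucleus = NucleusRecord(0, np.ones(grid.shape, bool), 0.0)
    regions = detect_foci(grid, nucleus, ROLE_53BP1)
    # under noise, small spurious blobs can appear; the focus is the largest
    return grid, max(regions, key=lambda r: r.volume)


class TestExtractProfile:
    def test_solid_sphere_peaks_at_centre(self):
        grid, focus = rendered_focus()
        p = extract_profile(grid, focus)
        y = p.channel(ROLE_53BP1)
        assert abs(p.positions[int(np.argmax(y))]) <= p.step + 1e-9
        assert y.max() == pytest.approx(1.0)

    def test_hollow_shell_gives_two_symmetric_maxima(self):
        grid, focus = rendered_focus(kind="hollow_shell", outer=0.76, inner=0.3)
        p = extract_profile(grid, focus)
        pos, _ = find_profile_peaks(p, ROLE_53BP1)
        assert len(pos) == 2
        assert pos[0] == pytest.approx(-pos[1], abs=2 * p.step)

    def test_orientation_count_irrelevant_for_spherical_focus(self):
        # blur comparable to the sampling step so the voxelized edge does
        # not alias between on-axis and diagonal line orientations
        grid, focus = rendered_focus(psf=(0.2, 0.12))
        p1 = extract_profile(grid, focus, n_orientations=1)
        p8 = extract_profile(grid, focus, n_orientations=8)
        # small deviations allowed: trilinear interpolation is slightly
        # anisotropic between on-axis and diagonal sampling
        np.testing.assert_allclose(p1.channel(ROLE_53BP1), p8.channel(ROLE_53BP1),
                                   atol=0.06)

    def test_focus_near_border_raises(self):
        grid, focus = rendered_focus()
        with pytest.raises(ProfileBorderError):
            extract_profile(grid, focus, length_um=20.0)


class TestAverageProfiles:
    def test_average_of_identical_profiles_is_identity_with_zero_sd(self):
        p = gaussian_profile([0.0])
        avg = average_profiles([p, p, p])
        np.testing.assert_allclose(avg.intensities, p.intensities)
        np.testing.assert_allclose(avg.sd, 0.0, atol=1e-12)
        assert avg.n_cells_averaged == 3

    def test_mirror_pair_averages_to_symmetric_profile(self):
        a = gaussian_profile([-1.0, 0.7])
        b = IntensityProfile(a.positions.copy(), a.intensities[:, ::-1].copy(),
                             a.channel_roles)
        avg = average_profiles([a, b])
        np.testing.assert_allclose(avg.intensities, avg.intensities[:, ::-1], atol=1e-12)

    def test_sd_recovers_injected_noise_scale(self):
        rng = np.random.default_rng(0)
        base = gaussian_profile([0.0])
        noisy = []
        for _ in range(40):
            y = base.intensities + rng.normal(0, 0.05, size=base.intensities.shape)
            noisy.append(IntensityProfile(base.positions.copy(), y, base.channel_roles))
        avg = average_profiles(noisy)
        assert np.median(avg.sd) == pytest.approx(0.05, rel=0.25)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ProfileError):
            average_profiles([gaussian_profile([0.0], step=0.05),
                              gaussian_profile([0.0], step=0.1)])


class TestFindPeaks:
    def test_two_gaussians_found_at_their_centres(self):
        p = gaussian_profile([-1.0, 1.0])
        pos, heights = find_profile_peaks(p, "A")
        assert len(pos) == 2
        assert pos[0] == pytest.approx(-1.0, abs=p.step)
        assert pos[1] == pytest.approx(1.0, abs=p.step)

    def test_monotone_ramp_has_no_interior_peak(self):
        x = np.linspace(-1, 1, 41)
        p = IntensityProfile(x, (x - x.min())[None, :] / 2, ("A",))
        pos, _ = find_profile_peaks(p, "A")
        assert pos.size == 0  # edges are excluded by policy

    def test_flat_zero_profile_has_no_peaks(self):
        x = np.linspace(-1, 1, 41)
        p = IntensityProfile(x, np.zeros((1, 41)), ("A",))
        pos, _ = find_profile_peaks(p, "A")
        assert pos.size == 0


class TestClassifyPolarity:
    def test_two_gaussians_with_deep_trough_are_bipolar(self):
        p = gaussian_profile([-1.0, 1.0])
        m = classify_polarity(p, "A")
        assert m.polarity == "bipolar"
        assert m.clearance == pytest.approx(2.0, abs=2 * p.step)
        assert m.trough_ratio < 0.1

    def test_single_gaussian_is_monopolar(self):
        m = classify_polarity(gaussian_profile([0.0]), "A")
        assert m.polarity == "monopolar"
        assert m.clearance is None

    def test_shallow_trough_fails_bipolarity(self):
        p = gaussian_profile([-0.25, 0.25], sigma=0.3)
        m = classify_polarity(p, "A")
        assert m.polarity == "monopolar"

    def test_zero_profile_is_undetected(self):
        x = np.linspace(-1, 1, 41)
        p = IntensityProfile(x, np.zeros((1, 41)), ("A",))
        m = classify_polarity(p, "A")
        assert m.polarity == "undetected"
        assert m.outer_width is None

    def test_mirror_invariance(self):
        p = gaussian_profile([-0.9, 1.1], sigma=0.25)
        mirrored = IntensityProfile(p.positions.copy(), p.intensities[:, ::-1].copy(),
                                    p.channel_roles)
        a, b = classify_polarity(p, "A"), classify_polarity(mirrored, "A")
        assert a.polarity == b.polarity == "bipolar"
        assert a.clearance == pytest.approx(b.clearance, abs=1e-9)
        assert a.outer_width == pytest.approx(b.outer_width, abs=1e-9)

    def test_intensity_rescaling_invariance_via_normalization(self):
        grid, focus = rendered_focus(kind="hollow_shell", outer=0.76, inner=0.3)
        p1 = extract_profile(grid, focus)
        grid.data *= 7.5
        p2 = extract_profile(grid, focus)
        m1, m2 = classify_polarity(p1, ROLE_53BP1), classify_polarity(p2, ROLE_53BP1)
        assert m1.polarity == m2.polarity
        assert m1.outer_width == pytest.approx(m2.outer_width, rel=1e-6)

    def test_rendered_shell_bipolar_and_sphere_monopolar_with_margin(self):
        params = ProfileParams()
        grid, focus = rendered_focus(kind="hollow_shell", outer=0.76, inner=0.3)
        shell = classify_polarity(extract_profile(grid, focus), ROLE_53BP1, params)
        grid, focus = rendered_focus(kind="solid_sphere", outer=0.6)
        sphere = classify_polarity(extract_profile(grid, focus), ROLE_53BP1, params)
        assert shell.polarity == "bipolar"
        assert sphere.polarity == "monopolar"
        # ~5x margin on the trough criterion for noiseless constructions
        assert shell.trough_ratio < params.trough_ratio_max / 2


class TestOuterWidth:
    def test_gaussian_fwhm(self):
        p = gaussian_profile([0.0], sigma=0.3, step=0.05)
        assert outer_width(p, "A") == pytest.approx(FWHM_FACTOR * 0.3, abs=p.step)

    def test_two_gaussian_outer_edges(self):
        # outer 50% crossings of unit Gaussians at ±1 (σ=0.3) sit at ±1.353
        p = gaussian_profile([-1.0, 1.0], sigma=0.3, step=0.05)
        assert outer_width(p, "A") == pytest.approx(2 * 1.3533, abs=2 * p.step)

    def test_no_peak_raises(self):
        x = np.linspace(-1, 1, 41)
        p = IntensityProfile(x, np.zeros((1, 41)), ("A",))
        with pytest.raises(ProfileError):
            outer_width(p, "A")


class TestCoreShellScore:
    def test_uniform_sphere_scores_near_zero(self):
        grid, focus = rendered_focus(blur=False)
        assert core_shell_score_3d(grid, focus, ROLE_53BP1) < 0.1

    def test_ideal_shell_scores_near_one(self):
        grid, focus = rendered_focus(kind="hollow_shell", outer=0.76, inner=0.3,
                                     blur=False)
        assert core_shell_score_3d(grid, focus, ROLE_53BP1, core_fraction=0.3) > 0.9

    def test_score_separates_devoid_from_solid_foci(self):
        scores, labels = [], []
        for kind, inner, devoid in (("hollow_shell", 0.3, 1), ("solid_sphere", 0.0, 0)):
            for rep in range(5):
                grid, focus = rendered_focus(kind=kind, outer=0.72, inner=inner,
                                             noise=True, seed=50 + rep)
                scores.append(core_shell_score_3d(grid, focus, ROLE_53BP1, 0.3))
                labels.append(devoid)
        scores, labels = np.asarray(scores), np.asarray(labels)
        r = np.corrcoef(scores, labels)[0, 1]  # point-biserial correlation
        assert r > 0.8


class TestPipelineProfiles:
    def test_rpa_peak_sits_in_the_53bp1_trough(self, measured_conditions):
        m = measured_conditions["control_G2_8h"]
        rpa = m.metrics[ROLE_RPA]
        bp = m.metrics[ROLE_53BP1]
        assert bp.polarity == "bipolar"
        assert rpa.polarity == "monopolar"
        trough_position = 0.0  # symmetric averaged profile troughs at the centre
        step = m.mean_profile.step
        assert abs(rpa.peak_positions[0] - trough_position) <= 2 * step
        # and the trough sits between the 53BP1 peaks
        assert bp.peak_positions[0] < rpa.peak_positions[0] < bp.peak_positions[1]

    def test_fk2_tracks_53bp1_polarity(self, measured_conditions):
        for m in measured_conditions.values():
            assert m.metrics[ROLE_FK2].polarity == m.metrics[ROLE_53BP1].polarity
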