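import math

import numpy as np
import pytest

from focipipe.synthetic_scenes import (
    FrapCurve,
    PackingError,
    SceneParams,
    generate_illumination_field,
    generate_plate,
    render_timelapse,
    sample_ground_truth,
    simulate_frap_curve,
)
from focipipe.workbench import PlateLayout


class TestIlluminationField:
    def test_zero_strength_is_flat(self):
        field = generate_illumination_field((64, 64), 0.0)
        assert np.allclose(field, 1.0)

    def test_max_is_one(self):
        field = generate_illumination_field((64, 80), 0.35, asymmetry=(0.1, -0.2))
        assert field.max() == pytest.approx(1.0)
        assert field.min() >= 1.0 - 0.35

    def test_centered_corner_value(self):
        # analytic radial profile: corner = 1 - strength
        field = generate_illumination_field((101, 101), 0.4, asymmetry=(0.0, 0.0))
        center = field[50, 50]
        corner = field[0, 0]
        assert corner < center
        assert corner >= 0.6 - 1e-9
        assert corner == pytest.approx(0.6, abs=1e-6)

    def test_asymmetry_shifts_peak(self):
        field = generate_illumination_field((101, 101), 0.4, asymmetry=(0.3, 0.0))
        peak = np.unravel_index(np.argmax(field), field.shape)
        assert peak[0] > 55  # peak moved toward larger rows

    def test_strength_one_rejected(self):
        with pytest.raises(ValueError):
            generate_illumination_field((32, 32), 1.0)


class TestRenderTimelapse:
    def test_no_late_s_means_no_foci(self):
        params = SceneParams(n_cells=10, n_frames=5, late_s_fraction=0.0, seed=1)
        _, truth = render_timelapse(params)
        assert truth.total_foci() == 0
        assert truth.count_matrix().sum() == 0

    def test_constant_background_without_bleach(self):
        params = SceneParams(
            n_cells=0,
            n_frames=6,
            background_level=0.1,
            bleach_halflife=math.inf,
            noise_sd=0.0,
            vignette_strength=0.0,
            seed=0,
        )
        tl, _ = render_timelapse(params)
        assert np.allclose(tl.frames, tl.frames[0])
        assert tl.frames[0, 0, 0] == pytest.approx(0.1, abs=1e-6)

    def test_bleaching_halves_background(self):
        params = SceneParams(
            n_cells=0, n_frames=5, background_level=0.2, bleach_halflife=2.0,
            noise_sd=0.0, vignette_strength=0.0, seed=0,
        )
        tl, _ = render_timelapse(params)
        assert tl.frames[2, 10, 10] == pytest.approx(0.1, rel=1e-5)
        assert tl.frames[4, 10, 10] == pytest.approx(0.05, rel=1e-5)

    def test_poisson_rate_recovered(self):
        # empirical mean foci per body-positive cell within 3 SE of lambda
        lam = 3.0
        counts = []
        for seed in range(5):
            params = SceneParams(
                image_shape=(680, 680), n_cells=100, n_frames=3,
                late_s_fraction=1.0, foci_rate_lambda=lam, seed=seed,
            )
            truth = sample_ground_truth(params)
            counts.extend(
                c.n_foci for c in truth.cells if c.viability in ("normal", "micronucleated")
            )
        counts = np.asarray(counts, float)
        assert len(counts) == 500
        se = math.sqrt(lam / len(counts))
        assert abs(counts.mean() - lam) < 3 * se

    def test_determinism(self):
        params = SceneParams(n_cells=5, n_frames=4, noise_sd=0.01, late_s_fraction=0.5, seed=9)
        tl1, gt1 = render_timelapse(params)
        tl2, gt2 = render_timelapse(params)
        assert np.array_equal(tl1.frames, tl2.frames)
        assert np.array_equal(gt1.count_matrix(), gt2.count_matrix())

    def test_cell_count_conserved(self):
        params = SceneParams(n_cells=12, n_frames=3, seed=2)
        _, truth = render_timelapse(params)
        assert len(truth.cells) == 12
        df = truth.to_frame()
        assert df[df.frame == 0].cell_id.nunique() == 12

    def test_packing_error(self):
        params = SceneParams(image_shape=(64, 64), n_cells=100, nucleus_radius_mean=12, seed=0)
        with pytest.raises(PackingError):
            render_timelapse(params)

    def test_focus_amplitude_scaling(self):
        # doubling focus_amplitude doubles the focus peak above local background
        def peak_excess(amp, seed=5):
            params = SceneParams(
                image_shape=(128, 128), n_cells=1, n_frames=1,
                nucleus_radius_mean=20, late_s_fraction=1.0, foci_count_fixed=1,
                focus_amplitude=amp, noise_sd=0.0, vignette_strength=0.0, seed=seed,
            )
            tl, gt = render_timelapse(params)
            cell = gt.cells[0]
            fy, fx = cell.foci_positions(0)[0]
            params0 = params.__class__(**{**params.__dict__, "focus_amplitude": 0.0})
            tl0, _ = render_timelapse(params0)
            return tl.frames[0, round(fy), round(fx)] - tl0.frames[0, round(fy), round(fx)]

        e1 = peak_excess(0.04)
        e2 = peak_excess(0.08)
        assert e2 == pytest.approx(2 * e1, rel=1e-3)

    def test_foci_inside_nucleus(self):
        params = SceneParams(n_cells=8, n_frames=6, late_s_fraction=1.0, seed=4)
        _, truth = render_timelapse(params)
        for cell in truth.cells:
            if cell.window is None:
                continue
            r = np.hypot(cell.foci_offsets[:, 0], cell.foci_offsets[:, 1])
            assert (r <= cell.radius).all()
            lo, hi = cell.window
            counts = cell.counts(truth.n_frames)
            assert (counts[lo : hi + 1] == cell.n_foci).all()
            assert counts[:lo].sum() == 0 and counts[hi + 1 :].sum() == 0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SceneParams(late_s_fraction=1.5).validate()
        with pytest.raises(ValueError):
            SceneParams(vignette_strength=1.0).validate()
        with pytest.raises(ValueError):
            SceneParams(foci_rate_lambda=-1).validate()


class TestGeneratePlate:
    def _base(self):
        return SceneParams(
            image_shape=(300, 300), n_cells=40, n_frames=10,
            late_s_fraction=0.6, seed=0,
        )

    def test_effect_multiplier_on_truth(self, small_layout):
        ds = generate_plate(
            small_layout, self._base(), effects={"LIB1": 3.0},
            n_positions=4, seed=5, n_replicates=2, render=False,
        )
        lib, neg = [], []
        for pos in ds:
            mean_foci = np.mean(
                [c.n_foci for c in pos.truth.cells if c.viability == "normal"]
            )
            (lib if pos.role == "library" else neg).append(mean_foci)
        ratio = np.mean(lib) / np.mean(neg)
        assert ratio == pytest.approx(3.0, rel=0.25)

    def test_determinism(self, small_layout):
        a = generate_plate(small_layout, self._base(), n_positions=2, seed=1, render=False)
        b = generate_plate(small_layout, self._base(), n_positions=2, seed=1, render=False)
        for pa, pb in zip(a, b):
            assert (pa.replicate, pa.well, pa.position) == (pb.replicate, pb.well, pb.position)
            assert np.array_equal(pa.truth.count_matrix(), pb.truth.count_matrix())

    def test_unknown_effect_rejected(self, small_layout):
        with pytest.raises(ValueError, match="absent from layout"):
            generate_plate(small_layout, self._base(), effects={"NOPE": 2.0}, render=False)

    def test_null_plate_wells_comparable(self, small_layout):
        ds = generate_plate(small_layout, self._base(), n_positions=3, seed=2, render=False)
        means = {}
        for pos in ds:
            means.setdefault(pos.well, []).append(
                np.mean([c.n_foci for c in pos.truth.cells if c.viability == "normal"])
            )
        grand = np.mean([np.mean(v) for v in means.values()])
        for v in means.values():
            assert abs(np.mean(v) - grand) < 1.0  # sampling noise only


class TestSimulateFrap:
    def test_asymptote_and_closed_form(self):
        t = np.linspace(0, 200, 400)
        c = simulate_frap_curve(10.0, 0.8, t, noise_sd=0.0)
        assert c.intensities[-1] == pytest.approx(0.8, abs=1e-6)
        idx = np.searchsorted(t, 10.0)
        assert c.intensities[idx] == pytest.approx(0.8 * (1 - math.exp(-1)), abs=1e-3)

    def test_prebleach_is_one(self):
        t = np.array([-3.0, -1.0, 0.0, 5.0, 10.0])
        c = simulate_frap_curve(5.0, 0.7, t)
        assert np.allclose(c.intensities[:2], 1.0)
        assert c.bleach_index == 2
        assert c.intensities[2] == pytest.approx(0.0)

    def test_bad_tau_rejected(self):
        with pytest.raises(ValueError):
            simulate_frap_curve(0.0, 0.5, np.linspace(0, 10, 20))
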