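"""Focus detection, background estimation, intensity measurement, stoichiometry."""

import numpy as np
import pytest

from cringdyn import focimetry
from cringdyn.focimetry import ImageStack
from cringdyn.synthgen import (StackSimConfig, render_focus,
                               simulate_focus_stacks)
from conftest import make_focus_stack


def brute_force_detect(stack, threshold_sd=5.0, min_separation_px=3):
    """Voxel-by-voxel oracle: explicit neighbor scan + greedy suppression."""
    mean, sd = sigma_clip_oracle(stack.voxels)
    thr = mean + threshold_sd * sd
    vox = stack.voxels
    nz, ny, nx = vox.shape
    cands = []
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                v = vox[z, y, x]
                if v <= thr:
                    continue
                is_max = True
                for dz in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            if dz == dy == dx == 0:
                                continue
                            if vox[(z + dz) % nz, (y + dy) % ny,
                                   (x + dx) % nx] > v:
                                is_max = False
                if is_max:
                    cands.append((v, z, y, x))
    cands.sort(key=lambda c: (-c[0], c[1], c[2], c[3]))
    kept = []
    for v, z, y, x in cands:
        if all((y - ky) ** 2 + (x - kx) ** 2 >= min_separation_px ** 2
               for _, ky, kx in kept):
            kept.append((z, y, x))
    return sorted(kept)


def sigma_clip_oracle(vox, sigma=3.0, max_iter=10):
    vals = vox.ravel().copy()
    for _ in range(max_iter):
        m, s = vals.mean(), vals.std()
        if s == 0:
            return m, 0.0
        keep = np.abs(vals - m) <= sigma * s
        if keep.all():
            break
        vals = vals[keep]
    return vals.mean(), vals.std()


class TestEstimateBackground:
    def test_constant_stack(self):
        stack = ImageStack(voxels=np.full((3, 8, 8), 7.0))
        assert focimetry.estimate_background(stack) == (7.0, 0.0)

    def test_robust_to_bright_outliers(self, rng):
        vox = rng.normal(100.0, 5.0, size=(6, 40, 40))
        clean_mean, clean_sd = vox.mean(), vox.std()
        flat = vox.ravel()
        idx = rng.choice(flat.size, size=flat.size // 100, replace=False)
        flat[idx] = 5000.0  # 1% bright focus-like voxels
        stack = ImageStack(voxels=flat.reshape(vox.shape))
        mean, sd = focimetry.estimate_background(stack)
        assert mean == pytest.approx(clean_mean, abs=0.5)
        assert sd == pytest.approx(clean_sd, abs=0.5)

    def test_pure_background_tail_rate(self, rng):
        vox = rng.normal(100.0, 5.0, size=(8, 64, 64))
        stack = ImageStack(voxels=vox)
        mean, sd = focimetry.estimate_background(stack)
        n_above = int((vox > mean + 5 * sd).sum())
        # Gaussian tail at 5 sigma: expect << 1 voxel; allow a tiny margin
        assert n_above <= 2


class TestDetectFoci:
    def test_uniform_stack_empty(self):
        stack = ImageStack(voxels=np.full((4, 16, 16), 3.0))
        assert focimetry.detect_foci(stack) == []

    def test_single_focus_found_at_center(self, rng):
        stack = make_focus_stack(centers=((4.0, 16.0, 16.0),),
                                 total_photons=20000.0, noise_rng=rng)
        foci = focimetry.detect_foci(stack)
        assert len(foci) == 1
        z, y, x = foci[0].position
        assert abs(y - 16) <= 1 and abs(x - 16) <= 1

    def test_two_close_sources_suppressed_to_one(self):
        stack = make_focus_stack(
            centers=((4.0, 16.0, 15.0), (4.0, 16.0, 17.0)),  # 2 px apart
            total_photons=20000.0)
        assert len(focimetry.detect_foci(stack)) == 1

    def test_two_separated_sources_both_found(self):
        stack = make_focus_stack(centers=((4.0, 10.0, 10.0), (4.0, 22.0, 22.0)),
                                 total_photons=20000.0)
        assert len(focimetry.detect_foci(stack)) == 2

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        centers = [(rng.uniform(1, 6), rng.uniform(6, 26), rng.uniform(6, 26))
                   for _ in range(4)]
        stack = make_focus_stack(shape=(8, 32, 32), centers=centers,
                                 total_photons=15000.0, noise_rng=rng)
        ours = sorted(f.position for f in focimetry.detect_foci(stack))
        assert ours == brute_force_detect(stack)

    def test_gain_invariance_of_positions(self, rng):
        stack = make_focus_stack(centers=((4.0, 10.0, 20.0),),
                                 total_photons=20000.0, noise_rng=rng)
        scaled = ImageStack(voxels=stack.voxels * 3.7, stack_id=stack.stack_id)
        pos1 = [f.position for f in focimetry.detect_foci(stack)]
        pos2 = [f.position for f in focimetry.detect_foci(scaled)]
        assert pos1 == pos2

    def test_translation_equivariance(self, rng):
        stack = make_focus_stack(centers=((4.0, 12.0, 12.0),),
                                 total_photons=20000.0, noise_rng=rng)
        shift = (2, 5, 3)
        shifted = ImageStack(voxels=np.roll(stack.voxels, shift, axis=(0, 1, 2)))
        pos = focimetry.detect_foci(stack)[0].position
        pos_shifted = focimetry.detect_foci(shifted)[0].position
        expected = tuple((p + s) % n for p, s, n
                         in zip(pos, shift, stack.voxels.shape))
        assert pos_shifted == expected


class TestMeasureFocusIntensity:
    def test_noiseless_focus_recovers_integrated_signal(self):
        emitted = 8000.0
        stack = make_focus_stack(centers=((4.0, 16.0, 16.0),),
                                 total_photons=emitted, background=50.0)
        # in-stack signal: emitted photons minus what axial truncation loses
        signal = stack.voxels.sum() - 50.0 * stack.voxels.size
        focus = focimetry.detect_foci(stack)[0]
        corrected = focimetry.measure_focus_intensity(stack, focus, 50.0, 0.0)
        assert corrected == pytest.approx(signal, rel=0.02)  # ROI truncation
        assert not focus.edge

    def test_corner_focus_flagged_edge(self):
        stack = make_focus_stack(centers=((4.0, 1.0, 1.0),),
                                 total_photons=20000.0)
        focus = focimetry.detect_foci(stack)[0]
        focimetry.measure_focus_intensity(stack, focus, 100.0, 0.0)
        assert focus.edge

    def test_background_only_roi_is_near_zero(self):
        stack = ImageStack(voxels=np.full((6, 32, 32), 80.0))
        focus = focimetry.Focus(position=(3, 16, 16), peak_value=80.0)
        corrected = focimetry.measure_focus_intensity(stack, focus, 70.0, 10.0)
        assert corrected == pytest.approx(0.0, abs=1e-9)

    def test_gain_scales_corrected_intensity(self):
        signal = 8000.0
        stack = make_focus_stack(centers=((4.0, 16.0, 16.0),),
                                 total_photons=signal, background=50.0)
        focus = focimetry.detect_foci(stack)[0]
        v1 = focimetry.measure_focus_intensity(stack, focus, 50.0)
        g = 2.5
        scaled = ImageStack(voxels=stack.voxels * g)
        focus2 = focimetry.Focus(position=focus.position, peak_value=0.0)
        v2 = focimetry.measure_focus_intensity(scaled, focus2, 50.0 * g)
        assert v2 == pytest.approx(g * v1, rel=1e-9)


class TestRelativeStoichiometry:
    def test_identity_gives_reference_copies(self):
        group = {f"s{i}": np.full(120, 100.0) for i in range(3)}
        est = focimetry.relative_stoichiometry(group, group)
        assert est.mean_copies == pytest.approx(24.0)

    def test_arithmetic(self):
        target = {f"t{i}": np.full(120, 110.0) for i in range(3)}
        ref = {f"r{i}": np.full(120, 120.0) for i in range(3)}
        est = focimetry.relative_stoichiometry(target, ref)
        assert est.mean_copies == pytest.approx(24.0 * 110.0 / 120.0)
        assert est.mean_copies == pytest.approx(22.0)

    def test_gain_invariance_applied_to_both_groups(self):
        rng = np.random.default_rng(0)
        target = {f"t{i}": rng.normal(90, 10, 150) for i in range(3)}
        ref = {f"r{i}": rng.normal(100, 10, 150) for i in range(3)}
        est1 = focimetry.relative_stoichiometry(target, ref)
        g = 5.5
        est2 = focimetry.relative_stoichiometry(
            {k: g * v for k, v in target.items()},
            {k: g * v for k, v in ref.items()})
        assert est2.mean_copies == pytest.approx(est1.mean_copies, rel=1e-12)
        assert est2.sd_copies == pytest.approx(est1.sd_copies, rel=1e-12)

    def test_nonpositive_reference_rejected(self):
        target = {"t0": np.full(120, 1.0), "t1": np.full(120, 1.0)}
        ref = {"r0": np.full(120, -1.0), "r1": np.full(120, 1.0)}
        with pytest.raises(ValueError):
            focimetry.relative_stoichiometry(target, ref)

    def test_warns_on_small_groups(self):
        small = {"s0": np.full(10, 1.0)}
        with pytest.warns(UserWarning):
            focimetry.relative_stoichiometry(small, small)

    @pytest.mark.parametrize("copies", [6, 48])
    def test_copy_number_recovery_across_range(self, copies):
        """Full pipeline recovers copy numbers far from the reference within 5%."""
        def run(c, seed):
            cfg = StackSimConfig(n_stacks=4, cells_per_stack=8, foci_per_cell=9,
                                 copies_per_focus=c, unit_intensity=600.0,
                                 seed=seed)
            stacks, _ = simulate_focus_stacks(cfg)
            foci = []
            for s in stacks:
                foci.extend(focimetry.quantify_stack(s))
            return focimetry.group_intensities(foci)

        est = focimetry.relative_stoichiometry(run(copies, 10 + copies),
                                               run(24, 99))
        assert abs(est.mean_copies - copies) / copies < 0.05


class TestIntensityDistribution:
    def test_single_focus_single_bin(self):
        df = focimetry.intensity_distribution(np.array([5.0]), n_bins=10)
        assert (df["density"] > 0).sum() == 1

    def test_scale_equivariance_of_shape(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(100, 10, 500)
        d1 = focimetry.intensity_distribution(vals, n_bins=20)
        d2 = focimetry.intensity_distribution(2.0 * vals, n_bins=20)
        # doubling intensities doubles bin widths, halves densities
        assert np.allclose(d2["bin_left"], 2.0 * d1["bin_left"])
        assert np.allclose(d2["density"], d1["density"] / 2.0)

    def test_matched_generative_variance_gives_matched_relative_spread(self):
        """22-mer and 24-mer groups with identical z-placement noise (shared
        seed, differing only in brightness) have matching relative SDs."""
        def spreads(copies):
            cfg = StackSimConfig(n_stacks=5, cells_per_stack=11,
                                 foci_per_cell=10,
                                 copies_per_focus=copies, seed=5)
            stacks, _ = simulate_focus_stacks(cfg)
            vals = []
            for s in stacks:
                vals.extend(f.corrected_intensity
                            for f in focimetry.quantify_stack(s) if not f.edge)
            vals = np.array(vals)
            return vals.std(ddof=1) / vals.mean()

        assert spreads(22) == pytest.approx(spreads(24), rel=0.10)
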