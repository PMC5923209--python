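"""Synthetic LV phantom: geometry, fiber field, DWI and optical synthesis."""

import numpy as np
import pytest

import cardiohelix as ch
from cardiohelix.dti import fit_tensor_loglinear, eigendecompose, _B_SCALE
from cardiohelix.phantom import (LABEL_INFARCT, LABEL_PERI, LABEL_REMOTE,
                                 LesionSpec)


class TestGeometry:
    def test_annulus_voxel_count(self):
        spec = ch.PhantomSpec(shape=(64, 64, 4), spacing=(1.0, 1.0, 1.0),
                              center=(32.0, 32.0),
                              endo_radius_um=10.0, epi_radius_um=20.0)
        geom = ch.make_lv_geometry(spec)
        per_slice = geom.myocardium[:, :, 0].sum()
        expected = np.pi * (20.0 ** 2 - 10.0 ** 2)
        assert abs(per_slice - expected) / expected < 0.02
        # brute-force rasterization oracle
        x = np.arange(64)[:, None] - 32.0
        y = np.arange(64)[None, :] - 32.0
        r = np.hypot(x, y)
        assert per_slice == ((r >= 10) & (r < 20)).sum()

    def test_mask_centroid_symmetric(self):
        spec = ch.PhantomSpec(shape=(64, 64, 2), spacing=(1.0, 1.0, 1.0),
                              center=(32.0, 32.0),
                              endo_radius_um=10.0, epi_radius_um=20.0)
        geom = ch.make_lv_geometry(spec)
        xs, ys = np.nonzero(geom.myocardium[:, :, 0])
        assert abs(xs.mean() - 32.0) < 0.1
        assert abs(ys.mean() - 32.0) < 0.1

    def test_degenerate_radii_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            ch.PhantomSpec(endo_radius_um=1000.0, epi_radius_um=1000.0)

    def test_eigenvalue_order_enforced(self):
        with pytest.raises(ValueError, match="eigenvalues"):
            ch.PhantomSpec(eigenvalues=(0.5, 0.7, 1.2))


class TestFiberField:
    def test_zero_ramp_is_circumferential(self):
        spec = ch.PhantomSpec(shape=(32, 32, 4), spacing=(125.0,) * 3,
                              endo_radius_um=500.0, epi_radius_um=1500.0,
                              ha_endo_deg=0.0, ha_epi_deg=0.0)
        geom = ch.make_lv_geometry(spec)
        fibers, gt = ch.make_fiber_field(geom, spec)
        assert gt.global_hat == 0.0
        _, c_hat, _ = geom.frame.basis(spec.shape)
        dot = np.einsum("...i,...i->...", fibers.vectors, c_hat)
        assert np.allclose(np.abs(dot[geom.myocardium]), 1.0, atol=1e-9)

    def test_true_hat_is_ramp_slope(self, medium_phantom):
        spec, geom, fibers, gt = medium_phantom
        assert gt.global_hat == (spec.ha_epi_deg - spec.ha_endo_deg) / 100.0
        assert gt.global_hat == -1.2

    def test_ha_ramp_linear_in_td(self, medium_phantom):
        spec, geom, fibers, gt = medium_phantom
        m = geom.myocardium
        expected = 60.0 - 1.2 * gt.td_percent[m]
        assert np.allclose(gt.ha_deg[m], expected, atol=1e-9)

    def test_lesion_flattening_zero(self):
        lesion = LesionSpec(azimuth_center_deg=0.0, azimuth_width_deg=60.0,
                            taper_deg=1e-9, ha_flattening=0.0)
        spec = ch.PhantomSpec(shape=(48, 48, 4), spacing=(125.0,) * 3,
                              endo_radius_um=750.0, epi_radius_um=2250.0,
                              lesion=lesion)
        geom = ch.make_lv_geometry(spec)
        fibers, gt = ch.make_fiber_field(geom, spec)
        core = geom.myocardium & (np.abs(
            (geom.azimuth_deg + 180) % 360 - 180) < 29.0)
        outside = geom.myocardium & (np.abs(
            (geom.azimuth_deg + 180) % 360 - 180) > 31.0)
        assert np.allclose(gt.ha_deg[core], 0.0, atol=1e-9)
        ramp = 60.0 - 1.2 * gt.td_percent[outside]
        assert np.allclose(gt.ha_deg[outside], ramp, atol=1e-9)

    def test_region_labels_partition_myocardium(self):
        spec = ch.PhantomSpec(shape=(48, 48, 4), spacing=(125.0,) * 3,
                              endo_radius_um=750.0, epi_radius_um=2250.0,
                              lesion=LesionSpec())
        geom = ch.make_lv_geometry(spec)
        _, gt = ch.make_fiber_field(geom, spec)
        m = geom.myocardium
        assert (gt.labels[m] > 0).all()
        assert (gt.labels[~m] == 0).all()
        for lab in (LABEL_REMOTE, LABEL_PERI, LABEL_INFARCT):
            assert (gt.labels == lab).any()


class TestSynthesizeDWI:
    def test_b0_equals_s0_noise_free(self, medium_phantom, medium_dwi):
        spec, geom, *_ = medium_phantom
        stack, protocol = medium_dwi
        b0 = stack.data[..., protocol.bvals == 0][..., 0]
        assert np.allclose(b0[geom.myocardium], spec.s0)

    def test_isotropic_tensor_direction_independent(self):
        d = 0.9
        spec = ch.PhantomSpec(shape=(24, 24, 4), spacing=(125.0,) * 3,
                              endo_radius_um=500.0, epi_radius_um=1250.0,
                              eigenvalues=(d, d, d))
        geom = ch.make_lv_geometry(spec)
        fibers, gt = ch.make_fiber_field(geom, spec)
        stack, protocol = ch.synthesize_dwi(fibers, geom, spec,
                                            ground_truth=gt)
        myo = geom.myocardium
        for j in np.nonzero(protocol.bvals > 0)[0]:
            expected = spec.s0 * np.exp(-protocol.bvals[j] * _B_SCALE * d)
            assert np.allclose(stack.data[..., j][myo], expected, atol=1e-9)

    def test_round_trip_tensor_recovery(self, medium_phantom, medium_dwi):
        """Noise-free synthesis refit by the tensor module is exact."""
        spec, geom, fibers, gt = medium_phantom
        stack, protocol = medium_dwi
        field = fit_tensor_loglinear(stack, protocol, geom.myocardium)
        eigs = eigendecompose(field)
        lam = eigs.eigenvalues[geom.myocardium]
        assert np.abs(lam - np.array(spec.eigenvalues)).max() < 1e-8 * 1.2

    def test_round_trip_ha_map(self, medium_phantom, medium_dwi):
        """Fitted e1 reproduces the prescribed HA ramp off the boundary."""
        spec, geom, fibers, gt = medium_phantom
        stack, protocol = medium_dwi
        field = fit_tensor_loglinear(stack, protocol, geom.myocardium)
        _, c_hat, _ = geom.frame.basis(spec.shape)
        eigs = eigendecompose(field, reference=c_hat)
        ha, valid = ch.helix_angle(eigs.e1, geom.frame)
        interior = (geom.myocardium & (gt.td_percent > 8)
                    & (gt.td_percent < 92))
        err = np.abs(ha[interior] - gt.ha_deg[interior])
        assert np.nanmax(err) < 0.5

    def test_too_few_directions_rejected(self, medium_phantom):
        from cardiohelix.dti import DWIProtocol
        spec, geom, fibers, gt = medium_phantom
        vecs = np.eye(3)
        protocol = DWIProtocol(
            bvals=[0.0, 1000, 1000, 1000],
            bvecs=np.vstack([np.zeros(3), vecs]))
        with pytest.raises(ValueError, match="underdetermined"):
            ch.synthesize_dwi(fibers, geom, spec, protocol, ground_truth=gt)

    def test_rician_background_mean(self):
        """Magnitude noise on a zero-signal background averages σ√(π/2)."""
        spec = ch.PhantomSpec(shape=(48, 48, 8), spacing=(125.0,) * 3,
                              endo_radius_um=750.0, epi_radius_um=1500.0,
                              noise="rician", sigma=20.0, seed=7)
        geom = ch.make_lv_geometry(spec)
        fibers, gt = ch.make_fiber_field(geom, spec)
        stack, protocol = ch.synthesize_dwi(fibers, geom, spec,
                                            ground_truth=gt)
        bg = ~geom.myocardium & ~geom.blood_pool
        vals = stack.data[..., 0][bg]
        assert vals.size >= 10_000
        expected = 20.0 * np.sqrt(np.pi / 2)
        assert abs(vals.mean() - expected) / expected < 0.05

    def test_seeded_outputs_bit_reproducible(self):
        spec = ch.PhantomSpec(shape=(24, 24, 4), spacing=(125.0,) * 3,
                              endo_radius_um=500.0, epi_radius_um=1250.0,
                              noise="rician", sigma=10.0, seed=3)
        out = []
        for _ in range(2):
            geom = ch.make_lv_geometry(spec)
            fibers, gt = ch.make_fiber_field(geom, spec)
            stack, _ = ch.synthesize_dwi(fibers, geom, spec, ground_truth=gt)
            out.append(stack.data)
        assert (out[0] == out[1]).all()

    def test_lesion_md_elevated(self):
        spec = ch.PhantomSpec(shape=(48, 48, 4), spacing=(125.0,) * 3,
                              endo_radius_um=750.0, epi_radius_um=2250.0,
                              lesion=LesionSpec(md_multiplier=1.5))
        geom = ch.make_lv_geometry(spec)
        fibers, gt = ch.make_fiber_field(geom, spec)
        stack, protocol = ch.synthesize_dwi(fibers, geom, spec,
                                            ground_truth=gt)
        field = fit_tensor_loglinear(stack, protocol, geom.myocardium)
        from cardiohelix.dti import mean_diffusivity
        md = mean_diffusivity(eigendecompose(field))
        core = gt.labels == LABEL_INFARCT
        assert np.nanmin(md[core]) > 1.12
        remote = gt.labels == LABEL_REMOTE
        assert abs(np.nanmedian(md[remote]) - 0.8) < 0.01


class TestSynthesizeOptical:
    def test_wavelength_below_3_voxels_rejected(self, medium_phantom):
        spec, geom, fibers, gt = medium_phantom
        tex = ch.TextureParams(wavelength_um=200.0)  # spacing 125 µm
        with pytest.raises(ValueError, match="aliasing"):
            ch.synthesize_optical(fibers, geom, spec, tex, ground_truth=gt)

    def test_contrast_zero_constant_inside(self, medium_phantom):
        spec, geom, fibers, gt = medium_phantom
        tex = ch.TextureParams(contrast=0.0, layer_contrast=0.0,
                               wavelength_um=500.0)
        vol = ch.synthesize_optical(fibers, geom, spec, tex, ground_truth=gt)
        assert np.allclose(vol[geom.myocardium], tex.base)
        # downstream orientation is undefined on a constant region
        from cardiohelix.structure_tensor import (sobel_gradients,
                                                  structure_tensor_orientation)
        g = sobel_gradients(vol[8:24, 8:24, :], spacing=spec.spacing)
        o = structure_tensor_orientation(g, 2.0)
        assert not o.valid[5:-5, 5:-5].any() or np.isnan(
            o.vectors[5:-5, 5:-5]).any()

    def test_artifact_free_texture_unchanged_by_destripe(self):
        """The stripe notch is near-identity on texture outside its band."""
        from cardiohelix.structure_tensor import remove_stripes
        x, y, z = np.meshgrid(*(np.arange(n, dtype=float)
                                for n in (64, 64, 16)), indexing="ij")
        # periodic-exact frequencies so no spectral leakage into the notch
        vol = 300 * np.cos(2 * np.pi * (13 * x / 64 + 6 * y / 64 + 2 * z / 16))
        out = remove_stripes(vol, artifact_axis=0, strength=1.0)
        rms_change = np.sqrt(((out - vol) ** 2).mean())
        assert rms_change < 0.01 * np.sqrt((vol ** 2).mean())

    def test_shadow_stripes_injected_and_removed(self, medium_phantom):
        """Shadow artifacts raise stripe-band power; the notch restores it."""
        from cardiohelix.structure_tensor import remove_stripes
        spec, geom, fibers, gt = medium_phantom
        opt_spec = spec.refined((2, 2, 2))
        og = ch.make_lv_geometry(opt_spec)
        of, ogt = ch.make_fiber_field(og, opt_spec)
        clean = ch.synthesize_optical(of, og, opt_spec,
                                      ch.TextureParams(), ground_truth=ogt)
        striped = ch.synthesize_optical(
            of, og, opt_spec,
            ch.TextureParams(shadow_axis=0, shadow_amplitude=80.0),
            ground_truth=ogt)
        artifact_bin = np.unravel_index(
            np.argmax(np.abs(np.fft.rfftn(striped - clean))),
            np.fft.rfftn(clean).shape)
        out = remove_stripes(striped, artifact_axis=0, strength=1.0)
        power_before = np.abs(np.fft.rfftn(striped)[artifact_bin]) ** 2
        power_after = np.abs(np.fft.rfftn(out)[artifact_bin]) ** 2
        assert power_after < power_before / 10

    def test_circumferential_round_trip(self):
        """Uniform circumferential field: optical reanalysis gives HA ~ 0."""
        spec = ch.PhantomSpec(shape=(48, 48, 12), spacing=(125.0,) * 3,
                              endo_radius_um=750.0, epi_radius_um=2250.0,
                              ha_endo_deg=0.0, ha_epi_deg=0.0)
        opt_spec = spec.refined((3, 3, 3))
        og = ch.make_lv_geometry(opt_spec)
        of, ogt = ch.make_fiber_field(og, opt_spec)
        vol = ch.synthesize_optical(of, og, opt_spec, ch.TextureParams(),
                                    ground_truth=ogt)
        from cardiohelix.io_cli import analyze_optical
        res = analyze_optical(vol, opt_spec.spacing)
        err = np.abs(res.ha[np.isfinite(res.ha)])
        assert (err < 2.0).mean() >= 0.95

    def test_optical_bit_reproducible(self, small_phantom):
        spec, geom, fibers, gt = small_phantom
        tex = ch.TextureParams(noise_sigma=15.0, wavelength_um=500.0)
        v1 = ch.synthesize_optical(fibers, geom, spec, tex, ground_truth=gt)
        v2 = ch.synthesize_optical(fibers, geom, spec, tex, ground_truth=gt)
        assert (v1 == v2).all()
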