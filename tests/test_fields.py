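"""Gridded-field gradient estimation, modality fields, averages, structures."""

import numpy as np
import pytest

import lvflow as lv
from lvflow.fields import _sss_batch
from lvflow.synth import FieldSpec, make_field


def sinusoid_field(n: int, extent: float = 0.1, amp: float = 1.0):
    """Smooth analytic fixture u = amp*(sin(ky), sin(kz), sin(kx)) with its
    closed-form gradient (k = 2*pi/extent)."""
    half = extent / 2
    ax = np.linspace(-half, half, n)
    sp = np.full(3, ax[1] - ax[0])
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    k = 2 * np.pi / extent
    u = np.stack([amp * np.sin(k * y), amp * np.sin(k * z), amp * np.sin(k * x)], axis=-1)
    g = np.zeros(x.shape + (3, 3))
    g[..., 0, 1] = amp * k * np.cos(k * y)
    g[..., 1, 2] = amp * k * np.cos(k * z)
    g[..., 2, 0] = amp * k * np.cos(k * x)
    field = lv.GridVelocityField(velocity=u, spacing=sp, origin=np.full(3, -half))
    return field, g


class TestComputeGradient:
    def test_exact_for_linear_diagonal_field(self):
        f, g_exact = make_field(FieldSpec("extensional", n=8))
        gf = lv.compute_gradient(f)
        assert np.allclose(gf.tensors, g_exact, atol=1e-10)
        assert gf.defined.all()

    def test_exact_for_couette(self):
        f, g_exact = make_field(FieldSpec("couette", n=8, params=(("k", 37.0),)))
        gf = lv.compute_gradient(f)
        assert np.allclose(gf.tensors[..., 0, 1], 37.0, atol=1e-10)
        assert np.allclose(gf.tensors, g_exact, atol=1e-10)

    def test_second_order_convergence(self):
        errs = []
        for n in (17, 33):
            f, g_exact = sinusoid_field(n)
            gf = lv.compute_gradient(f)
            errs.append(np.max(np.abs(gf.tensors - g_exact)))
        # halving the spacing should cut the error ~4x for an O(h^2) stencil
        assert errs[0] / errs[1] > 3.4

    def test_rejects_thin_grid(self):
        u = np.zeros((2, 5, 5, 3))
        f = lv.GridVelocityField(velocity=u, spacing=[1, 1, 1])
        with pytest.raises(ValueError, match="at least 3 nodes"):
            lv.compute_gradient(f)

    def test_mask_drops_stencil_crossing_nodes(self):
        f, _ = make_field(FieldSpec("couette", n=8))
        mask = np.ones(f.dims, dtype=bool)
        mask[:, :2, :] = False
        fm = lv.GridVelocityField(
            velocity=f.velocity, spacing=f.spacing, origin=f.origin, mask=mask
        )
        gf = lv.compute_gradient(fm)
        # nodes adjacent to the masked slab and all grid-boundary nodes drop
        assert not gf.defined[:, 2, :].any()
        assert gf.defined[3, 3, 3]
        assert not gf.defined[0, :, :].any()
        assert np.all(np.isnan(gf.tensors[~gf.defined]))
        assert np.allclose(gf.tensors[gf.defined][..., 0, 1], 100.0)

    def test_mask_monotonicity(self):
        f, _ = make_field(FieldSpec("solid_rotation", n=9))
        big = np.ones(f.dims, dtype=bool)
        small = big.copy()
        small[-3:, :, :] = False
        fb = lv.GridVelocityField(f.velocity, f.spacing, f.origin, mask=big)
        fs = lv.GridVelocityField(f.velocity, f.spacing, f.origin, mask=small)
        gb, gs = lv.compute_gradient(fb), lv.compute_gradient(fs)
        both = gs.defined
        assert np.array_equal(gb.tensors[both], gs.tensors[both])


class TestDecomposeField:
    def test_couette_is_pure_shear(self):
        f, _ = make_field(FieldSpec("couette", n=8))
        m = lv.decompose_field(f)
        assert np.allclose(m.shear[m.defined], 100.0)
        assert np.allclose(m.rotation[m.defined], 0.0, atol=1e-9)
        assert np.allclose(m.strain[m.defined], 0.0, atol=1e-9)
        assert np.allclose(m.sss[m.defined], 100.0)

    def test_solid_rotation_is_pure_rotation(self):
        f, _ = make_field(FieldSpec("solid_rotation", n=8))
        m = lv.decompose_field(f)
        assert np.allclose(m.rotation[m.defined], 50.0 * np.sqrt(2.0), atol=1e-8)
        assert np.allclose(m.shear[m.defined], 0.0, atol=1e-8)
        assert np.allclose(m.strain[m.defined], 0.0, atol=1e-8)
        assert np.allclose(m.sss[m.defined], 0.0, atol=1e-8)

    def test_round_jet_shear_layer(self):
        f, _ = make_field(
            FieldSpec("round_jet", n=33, extent=0.08, params=(("r", 0.02), ("delta", 0.004)))
        )
        m = lv.decompose_field(f)
        c = 16  # axis node
        assert m.rotation[c, c, :].max() < 1e-6
        assert m.shear[c, c, c] < 1.0
        # shear peaks on the shear-layer radius r ~ R (10 nodes off axis)
        axis_r = np.abs(np.arange(33) - c) * f.spacing[0]
        line = m.shear[:, c, c]
        peak = np.nanargmax(line)
        assert abs(axis_r[peak] - 0.02) <= 2 * f.spacing[0]

    def test_batch_matches_pointwise_schur_route(self):
        rng = np.random.default_rng(12)
        u = rng.normal(scale=0.5, size=(6, 6, 6, 3))
        f = lv.GridVelocityField(velocity=u, spacing=[0.01, 0.01, 0.01])
        mb = lv.decompose_field(f)
        mp = lv.decompose_field(f, pointwise=True)
        for name in ("rotation", "shear", "strain", "sss"):
            a, b = mb.get(name), mp.get(name)
            assert np.allclose(a[mb.defined], b[mb.defined], rtol=1e-8, atol=1e-8)

    def test_homogeneity_in_velocity_amplitude(self):
        f1, _ = make_field(FieldSpec("lamb_oseen", n=9))
        u3 = 3.0 * f1.velocity
        f3 = lv.GridVelocityField(u3, f1.spacing, f1.origin)
        m1, m3 = lv.decompose_field(f1), lv.decompose_field(f3)
        for name in ("rotation", "shear", "strain", "sss"):
            assert np.allclose(
                m3.get(name)[m3.defined], 3.0 * m1.get(name)[m1.defined], rtol=1e-9, atol=1e-12
            )


class TestSpatialAverage:
    @staticmethod
    def _modalities_from(values, spacing=(1.0, 1.0, 1.0)):
        values = np.asarray(values, dtype=float)
        defined = ~np.isnan(values)
        return lv.ModalityFields(
            rotation=values,
            shear=values,
            strain=values,
            sss=values,
            defined=defined,
            spacing=np.asarray(spacing),
            origin=np.zeros(3),
        )

    def test_constant_field(self):
        m = self._modalities_from(np.full((4, 4, 4), 7.5))
        assert lv.spatial_average(m)["shear"] == pytest.approx(7.5)

    def test_half_and_half_with_equal_weights(self):
        vals = np.full((4, 4, 4), np.nan)
        # use an interior 2x2x2 block so every node carries equal weight
        vals[1:3, 1:3, 1:3] = 6.0
        vals[1:3, 1:3, 1] = 0.0
        m = self._modalities_from(vals)
        assert lv.spatial_average(m)["shear"] == pytest.approx(3.0)

    def test_matches_bruteforce_weighted_sum(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(size=(5, 6, 7))
        m = self._modalities_from(vals, spacing=(0.1, 0.2, 0.3))
        # independent oracle: explicit trapezoid weights
        num = den = 0.0
        for i in range(5):
            for j in range(6):
                for k in range(7):
                    w = 1.0
                    for idx, n in ((i, 5), (j, 6), (k, 7)):
                        w *= 0.5 if idx in (0, n - 1) else 1.0
                    num += w * vals[i, j, k]
                    den += w
        assert lv.spatial_average(m)["rotation"] == pytest.approx(num / den, rel=1e-12)

    def test_empty_mask_raises(self):
        m = self._modalities_from(np.full((3, 3, 3), np.nan))
        with pytest.raises(ValueError, match="defined"):
            lv.spatial_average(m)


class TestExtractStructures:
    @staticmethod
    def _modalities(values):
        return TestSpatialAverage._modalities_from(values)

    def test_threshold_above_max_is_empty(self):
        f, _ = make_field(FieldSpec("solid_rotation", n=8))
        m = lv.decompose_field(f)
        assert lv.extract_structures(m, "rotation", 1e6) == []

    def test_two_disjoint_blobs(self):
        vals = np.zeros((10, 10, 10))
        vals[1:3, 1:3, 1:3] = 5.0  # 8 voxels
        vals[6:10, 6:10, 6:10] = 5.0  # 64 voxels
        m = self._modalities(vals)
        comps = lv.extract_structures(m, "shear", 1.0)
        assert [c.voxels for c in comps] == [64, 8]
        assert comps[0].centroid == pytest.approx((7.5, 7.5, 7.5))
        assert comps[1].centroid == pytest.approx((1.5, 1.5, 1.5))

    def test_matches_floodfill_oracle(self):
        rng = np.random.default_rng(9)
        vals = (rng.uniform(size=(8, 8, 8)) > 0.7).astype(float)
        m = self._modalities(vals)
        comps = lv.extract_structures(m, "rotation", 0.5)
        # oracle: BFS flood fill over 26-neighbourhoods
        binary = vals > 0.5
        seen = np.zeros_like(binary, dtype=bool)
        sizes = []
        offsets = [
            (i, j, k)
            for i in (-1, 0, 1)
            for j in (-1, 0, 1)
            for k in (-1, 0, 1)
            if (i, j, k) != (0, 0, 0)
        ]
        for start in zip(*np.nonzero(binary)):
            if seen[start]:
                continue
            stack, size = [start], 0
            seen[start] = True
            while stack:
                p = stack.pop()
                size += 1
                for o in offsets:
                    q = tuple(p[d] + o[d] for d in range(3))
                    if all(0 <= q[d] < 8 for d in range(3)) and binary[q] and not seen[q]:
                        seen[q] = True
                        stack.append(q)
            sizes.append(size)
        assert sorted(c.voxels for c in comps) == sorted(sizes)

    def test_strict_inequality_and_unknown_modality(self):
        vals = np.full((3, 3, 3), 2.0)
        m = self._modalities(vals)
        assert lv.extract_structures(m, "strain", 2.0) == []
        with pytest.raises(ValueError, match="unknown modality"):
            lv.extract_structures(m, "vorticity", 1.0)


class TestTimeSeries:
    def test_single_and_constant_frames(self):
        f0, _ = make_field(FieldSpec("couette", n=6, time=0.0))
        s = lv.time_series([f0])
        assert len(s.times) == 1
        assert s.mean_shear[0] == pytest.approx(100.0)
        f1, _ = make_field(FieldSpec("couette", n=6, time=0.1))
        s2 = lv.time_series([f0, f1])
        assert np.allclose(s2.mean_shear, 100.0)

    def test_amplitude_ramp_scales_linearly(self):
        frames = []
        for i, k in enumerate((10.0, 20.0, 40.0)):
            f, _ = make_field(FieldSpec("couette", n=6, time=0.1 * i, params=(("k", k),)))
            frames.append(f)
        s = lv.time_series(frames)
        assert s.mean_shear == pytest.approx([10.0, 20.0, 40.0])
        assert np.all(np.diff(s.mean_shear) > 0)

    def test_rejects_inconsistent_geometry(self):
        f0, _ = make_field(FieldSpec("couette", n=6, time=0.0))
        f1, _ = make_field(FieldSpec("couette", n=8, time=0.1))
        with pytest.raises(ValueError, match="geometry"):
            lv.time_series([f0, f1])

    def test_rejects_non_increasing_times(self):
        f0, _ = make_field(FieldSpec("couette", n=6, time=0.2))
        f1, _ = make_field(FieldSpec("couette", n=6, time=0.1))
        with pytest.raises(ValueError, match="increasing"):
            lv.time_series([f0, f1])


class TestBatchHelpers:
    def test_sss_batch_matches_scalar(self):
        from lvflow.synth import random_gradients

        g = random_gradients(50, seed=4)
        batch = _sss_batch(g)
        scalar = np.array([lv.sss(t) for t in g])
        assert np.allclose(batch, scalar, rtol=1e-12)

    def test_triple_magnitudes_homogeneous(self):
        from lvflow.synth import random_gradients

        g = random_gradients(100, seed=6)
        m1 = np.stack(lv.triple_magnitudes(g))
        m2 = np.stack(lv.triple_magnitudes(2.5 * g))
        assert np.allclose(m2, 2.5 * m1, rtol=1e-9)
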