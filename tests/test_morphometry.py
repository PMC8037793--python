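import math

import pytest

from porocoil.morphometry import (
    AneurysmMorphometry,
    AneurysmShape,
    CoilSpec,
    MM_PER_INCH,
    aneurysm_volume,
    coil_volume,
    first_coil_length_for_vpd,
    morphometric_indices,
    packing_metrics,
)


def morph(shape=AneurysmShape.SPHERICAL, **over):
    base = dict(
        height_H=6.0, width_S=4.0, depth_D=4.0, neck_N=3.0, parent_P=3.0, hmax=6.0
    )
    base.update(over)
    return AneurysmMorphometry(shape=shape, **base)


class TestAneurysmVolume:
    @pytest.mark.parametrize(
        "m, expected",
        [
            (morph(height_H=6, width_S=6, depth_D=6), 113.097),  # sphere d=6
            (morph(AneurysmShape.ELLIPSOID, height_H=6, width_S=4, depth_D=4), 50.265),
            (
                morph(
                    AneurysmShape.BILOBED,
                    bilobed_components=((4.0, 6.0), (4.0, 6.0)),
                ),
                100.531,
            ),
        ],
    )
    def test_shape_formulas(self, m, expected):
        assert aneurysm_volume(m) == pytest.approx(expected, abs=1e-3)

    def test_sphere_uses_largest_diameter(self):
        assert aneurysm_volume(morph(height_H=2, width_S=6, depth_D=3)) == pytest.approx(
            math.pi * 6**3 / 6
        )

    @pytest.mark.parametrize("k", [0.5, 2.0])
    def test_cubic_scaling(self, k):
        m1 = morph(AneurysmShape.ELLIPSOID)
        m2 = morph(
            AneurysmShape.ELLIPSOID,
            height_H=m1.height_H * k,
            width_S=m1.width_S * k,
            depth_D=m1.depth_D * k,
            neck_N=m1.neck_N * k,
            parent_P=m1.parent_P * k,
            hmax=m1.hmax * k,
        )
        assert aneurysm_volume(m2) == pytest.approx(k**3 * aneurysm_volume(m1))

    def test_nonpositive_dimension_names_field(self):
        with pytest.raises(ValueError, match="width_S"):
            morph(width_S=-1.0)

    def test_bilobed_requires_components(self):
        with pytest.raises(ValueError, match="bilobed"):
            morph(AneurysmShape.BILOBED)


class TestCoilVolume:
    @pytest.mark.parametrize(
        "inch, length, expected",
        [(0.010, 100.0, 5.0671), (0.018, 100.0, 16.417), (0.010, 0.0, 0.0)],
    )
    def test_cylinder_formula(self, inch, length, expected):
        spec = CoilSpec(wire_diameter_inch=inch, length_mm=length)
        assert coil_volume(spec) == pytest.approx(expected, abs=1e-3)

    def test_inch_mm_round_trip(self):
        spec = CoilSpec(wire_diameter_inch=0.010, length_mm=1.0)
        assert spec.wire_diameter_mm / MM_PER_INCH == pytest.approx(0.010, rel=1e-12)

    def test_rejects_nonpositive_diameter(self):
        with pytest.raises(ValueError):
            CoilSpec(wire_diameter_inch=0.0, length_mm=10.0)


class TestPackingMetrics:
    def test_single_coil_pd_equals_first_vpd(self):
        res = packing_metrics(
            113.097, [CoilSpec(0.010, 100.0, is_first_coil=True)]
        )
        assert res.packing_density_pct == pytest.approx(4.480, abs=1e-3)
        assert res.first_vpd_pct == res.packing_density_pct

    def test_full_packing_is_100_pct(self):
        coil = CoilSpec(0.010, 100.0, is_first_coil=True)
        res = packing_metrics(coil_volume(coil), [coil])
        assert res.packing_density_pct == pytest.approx(100.0)

    def test_additive_in_coils(self):
        first = CoilSpec(0.010, 150.0, is_first_coil=True)
        second = CoilSpec(0.018, 80.0)
        vol = 200.0
        combined = packing_metrics(vol, [first, second])
        alone = packing_metrics(vol, [first])
        other = packing_metrics(vol, [CoilSpec(0.018, 80.0, is_first_coil=True)])
        assert combined.packing_density_pct == pytest.approx(
            alone.packing_density_pct + other.packing_density_pct
        )
        assert combined.first_vpd_pct <= combined.packing_density_pct

    def test_cutoff_inversion(self):
        # coil length delivering the 10.56 % predictor cut-off in a 6-mm sphere
        length = first_coil_length_for_vpd(10.56, 113.097, 0.010)
        assert length == pytest.approx(235.7, abs=0.1)
        res = packing_metrics(113.097, [CoilSpec(0.010, length, is_first_coil=True)])
        assert res.first_vpd_pct == pytest.approx(10.56, rel=1e-9)

    def test_requires_exactly_one_first_coil(self):
        with pytest.raises(ValueError, match="is_first_coil"):
            packing_metrics(100.0, [CoilSpec(0.010, 50.0), CoilSpec(0.010, 50.0)])
        with pytest.raises(ValueError):
            packing_metrics(0.0, [])


class TestIndices:
    def test_aspect_ratio_from_group_means(self):
        m = morph(hmax=12.03, neck_N=4.14)
        assert morphometric_indices(m).aspect_ratio_AR == pytest.approx(2.906, abs=1e-3)

    def test_identity_ratios(self):
        m = morph(height_H=3.0, parent_P=3.0, neck_N=3.0)
        idx = morphometric_indices(m)
        assert idx.size_ratio_SR == pytest.approx(1.0)
        assert idx.neck_parent_ratio == pytest.approx(1.0)
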