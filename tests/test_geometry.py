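import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svtether import (GeometryConfig, HeightDistributionSpec,
                      assembly_rate_profile, build_height_pdf, location_pdf)
from svtether.errors import DegenerateProfileError, InvalidSpecError
from svtether.geometry import _unnormalized_profile

CFG = GeometryConfig()


class TestHeightPDF:
    def test_uniform_density_and_support(self):
        pdf = build_height_pdf(HeightDistributionSpec.uniform(2, 8), CFG)
        assert np.allclose(pdf.density, 1.0 / 6.0)
        assert pdf.h_min == 2.0 and pdf.h_max == 8.0
        assert abs(pdf.area - 1.0) < 1e-6

    def test_narrow_angle_concentrates_at_sine_height(self):
        # l·sin(80°) = 19.696 nm; a vanishing angle spread pins h there
        spec = HeightDistributionSpec.angle_normal(20.0, 80.0, 1e-3)
        pdf = build_height_pdf(spec, CFG)
        mean_h = np.trapezoid(pdf.h_grid * pdf.density, pdf.h_grid)
        assert mean_h == pytest.approx(20.0 * np.sin(np.radians(80.0)), abs=0.02)

    def test_angle_fold_keeps_heights_below_length(self):
        # angles beyond 90° fold back: h never exceeds the protein length
        spec = HeightDistributionSpec.angle_normal(20.0, 90.0, 15.0)
        pdf = build_height_pdf(spec, CFG)
        assert pdf.h_max <= 20.0 + 1e-9
        assert abs(pdf.area - 1.0) < 1e-6

    @given(h_min=st.floats(0.5, 15.0), width=st.floats(0.5, 20.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_uniform_pdfs_normalize(self, h_min, width):
        pdf = build_height_pdf(
            HeightDistributionSpec.uniform(h_min, h_min + width), CFG)
        assert abs(pdf.area - 1.0) < 1e-6

    @given(mean=st.floats(30.0, 150.0), sd=st.floats(0.5, 20.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_angle_normal_pdfs_normalize(self, mean, sd):
        pdf = build_height_pdf(
            HeightDistributionSpec.angle_normal(20.0, mean, sd), CFG)
        assert abs(pdf.area - 1.0) < 1e-6

    @pytest.mark.parametrize("bad", [
        dict(kind="uniform", h_min=-1.0, h_max=5.0),
        dict(kind="uniform", h_min=5.0, h_max=2.0),
        dict(kind="angle-normal", protein_length=-3.0, angle_mean=80.0, angle_sd=5.0),
        dict(kind="angle-normal", protein_length=20.0, angle_mean=80.0, angle_sd=0.0),
        dict(kind="nonsense"),
    ])
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(InvalidSpecError):
            HeightDistributionSpec(**bad)


class TestLocationPDF:
    def test_values_and_domain(self):
        assert location_pdf(20.0, 20.0) == pytest.approx(0.1)
        assert location_pdf(0.0, 20.0) == 0.0
        assert location_pdf(25.0, 20.0) == 0.0
        with pytest.raises(InvalidSpecError):
            location_pdf(-1.0, 20.0)

    def test_integrates_to_one_over_vesicle_radius(self):
        x = np.linspace(0.0, 20.0, 20001)
        assert np.trapezoid(location_pdf(x, 20.0), x) == pytest.approx(1.0, abs=1e-8)


class TestAssemblyProfile:
    def test_profile_shapes_of_reference_species(self, model):
        d = model.fine.d_grid
        snare, munc13, syt = (p.values for p in model.fine.profiles)
        # SNARE cannot bridge gaps beyond its tallest height; the rate keeps
        # growing as the vesicle approaches (more attachment circumference)
        assert np.all(snare[d >= 8.0] == 0.0)
        inside = (d > 0.05) & (d < 7.95)
        assert np.all(np.diff(snare[inside]) < 0)
        # Syt is longer than the vesicle radius: its peak sits at 5-10 nm
        peak_d = d[np.argmax(syt)]
        assert 5.0 <= peak_d <= 10.0
        assert np.all(munc13[d >= 20.0] == 0.0)
        for values in (snare, munc13, syt):
            assert values.max() == 1.0
            assert values.min() >= 0.0

    def test_support_matches_height_reachability(self, model):
        # g_on(d) = 0 exactly where [max(h_min, d), min(h_max, d+r)] holds no
        # height mass; checked independently from the height PDFs
        r = model.geometry.r
        d = model.sim.d_grid
        for hpdf, prof in zip(model.height_pdfs, model.sim.profiles):
            for dk, g in zip(d, prof.values):
                lo, hi = max(hpdf.h_min, dk), min(hpdf.h_max, dk + r)
                sel = (hpdf.h_grid >= lo) & (hpdf.h_grid <= hi)
                mass = (np.trapezoid(hpdf.density[sel], hpdf.h_grid[sel])
                        if sel.sum() > 1 else 0.0)
                assert (g == 0.0) == (hi <= lo or mass <= 1e-12 or hi <= 1e-12)

    def test_quadrature_convergence_under_step_halving(self, model):
        d = model.sim.d_grid
        for spec in model.specs:
            coarse = assembly_rate_profile(
                build_height_pdf(spec.height_spec, CFG), CFG, d).values
            fine_cfg = GeometryConfig(h_quadrature_step=CFG.h_quadrature_step / 2,
                                      angle_step_deg=CFG.angle_step_deg / 2)
            fine = assembly_rate_profile(
                build_height_pdf(spec.height_spec, fine_cfg), fine_cfg, d).values
            assert np.max(np.abs(coarse - fine)) < 1e-4

    def test_profile_matches_monte_carlo_oracle(self, model):
        # sample h from f2, average the attachment-offset density: the mean
        # estimates the assembly integral without any quadrature
        rng = np.random.default_rng(1234)
        r = model.geometry.r
        probes = np.array([1.0, 3.0, 6.0, 10.0, 20.0])
        n_samples = 100_000
        for spec, hpdf in zip(model.specs, model.height_pdfs):
            raw = _unnormalized_profile(hpdf, model.geometry, probes)
            hs = spec.height_spec
            if hs.kind == "uniform":
                h = rng.uniform(hs.h_min, hs.h_max, n_samples)
            else:
                a = np.radians(rng.normal(hs.angle_mean, hs.angle_sd, n_samples))
                h = hs.protein_length * np.sin(a)
            for d, expected in zip(probes, raw):
                arg = r**2 - (r - h + d) ** 2
                ok = (h >= d) & (h <= d + r) & (arg > 0)
                vals = np.where(ok, 2.0 * np.sqrt(np.where(ok, arg, 0.0)) / r**2, 0.0)
                se = vals.std(ddof=1) / np.sqrt(n_samples)
                assert abs(vals.mean() - expected) <= 3.0 * se + 1e-6

    def test_degenerate_profile_raises(self):
        hpdf = build_height_pdf(HeightDistributionSpec.uniform(2, 8), CFG)
        far = np.array([50.0, 80.0])  # beyond any SNARE reach
        with pytest.raises(DegenerateProfileError):
            assembly_rate_profile(hpdf, CFG, far)
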