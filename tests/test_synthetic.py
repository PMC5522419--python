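"""Synthetic campaign generator: line shapes, adsorption model, noise
structure, determinism, and end-to-end consistency."""

import numpy as np
import pytest

import sersmix as sx
from sersmix.exceptions import DesignError
from sersmix.synthetic import _pure_profiles, total_coverage
from tests.conftest import make_study


class TestComponentLibrary:
    def test_four_probe_molecules(self):
        lib = sx.default_component_library()
        assert [c.name for c in lib] == ["1,4-BDT", "2-NaT", "4-MBA", "4-MPY"]

    def test_mpy_ring_breathing_band_present(self):
        mpy = next(c for c in sx.default_component_library() if c.name == "4-MPY")
        assert 1007.0 in mpy.peak_centers

    def test_all_centers_inside_default_grid(self):
        lo, hi = sx.DEFAULT_GRID[0], sx.DEFAULT_GRID[-1]
        for c in sx.default_component_library():
            assert np.all((c.peak_centers >= lo) & (c.peak_centers <= hi))

    def test_positive_k_required(self):
        with pytest.raises(DesignError):
            sx.ComponentSpec("bad", [1000.0], 1.0, 10.0, k_true=0.0)


class TestLineShape:
    def test_lorentzian_center_value_is_amplitude(self):
        spec = sx.ComponentSpec("one", [1000.0], 3.0, 20.0)
        grid = np.arange(600.0, 1801.0, 1.0)
        s = sx.render_pure_spectrum(spec, grid)
        assert s.intensity[np.argmin(np.abs(grid - 1000.0))] == pytest.approx(3.0, abs=1e-9)

    def test_half_amplitude_at_half_width(self):
        spec = sx.ComponentSpec("one", [1000.0], 2.0, 14.0)
        grid = np.arange(600.0, 1801.0, 1.0)
        s = sx.render_pure_spectrum(spec, grid)
        for shift in (993.0, 1007.0):
            assert s.intensity[np.argmin(np.abs(grid - shift))] == pytest.approx(1.0, abs=1e-9)

    def test_integral_matches_lorentzian_area(self):
        """Numeric quadrature over a wide grid vs the closed-form band area
        sum(A * pi * w / 2)."""
        spec = sx.ComponentSpec("multi", [900.0, 1200.0], [2.0, 1.0], [12.0, 20.0])
        grid = np.arange(200.0, 2500.0, 0.5)
        s = sx.render_pure_spectrum(spec, grid)
        numeric = np.trapezoid(s.intensity, grid)
        exact = 2.0 * np.pi * 12.0 / 2 + 1.0 * np.pi * 20.0 / 2
        assert numeric == pytest.approx(exact, rel=0.02)

    def test_gaussian_lineshape_available(self):
        spec = sx.ComponentSpec("one", [1000.0], 1.0, 14.0)
        grid = np.arange(900.0, 1101.0, 1.0)
        s = sx.render_pure_spectrum(spec, grid, lineshape="gaussian")
        assert s.intensity[np.argmin(np.abs(grid - 1007.0))] == pytest.approx(0.5, abs=1e-9)


class TestAdsorptionModel:
    def setup_method(self):
        lib = {c.name: c for c in sx.default_component_library()}
        self.names = ["4-MBA", "4-MPY"]
        self.comps = [lib[n] for n in self.names]

    def design(self, **kw):
        return sx.SimulationDesign(self.comps, [], **kw)

    def test_equal_k_means_surface_equals_solution(self):
        comps = [sx.ComponentSpec(n, [1000.0 + 100 * i], 1.0, 14.0, k_true=0.7)
                 for i, n in enumerate("abc")]
        design = sx.SimulationDesign(comps, [])
        sol = sx.Composition(list("abc"), [0.2, 0.3, 0.5])
        np.testing.assert_allclose(
            sx.surface_fractions(sol, design), [0.2, 0.3, 0.5], atol=1e-12
        )

    def test_binary_closed_form(self):
        comps = [sx.ComponentSpec("a", [1000.0], 1.0, 14.0, 2.0),
                 sx.ComponentSpec("b", [1100.0], 1.0, 14.0, 1.0)]
        design = sx.SimulationDesign(comps, [])
        sol = sx.Composition(["a", "b"], [0.5, 0.5])
        np.testing.assert_allclose(
            sx.surface_fractions(sol, design), [2 / 3, 1 / 3], atol=1e-12
        )

    def test_langmuir_fractions_match_linear_but_coverage_saturates(self):
        comps = [sx.ComponentSpec("a", [1000.0], 1.0, 14.0, 2.0),
                 sx.ComponentSpec("b", [1100.0], 1.0, 14.0, 1.0)]
        lin = sx.SimulationDesign(comps, [], adsorption_model="linear")
        lang = sx.SimulationDesign(comps, [], adsorption_model="langmuir")
        sol = sx.Composition(["a", "b"], [0.5, 0.5])
        np.testing.assert_allclose(
            sx.surface_fractions(sol, lin), sx.surface_fractions(sol, lang), atol=1e-12
        )
        assert total_coverage(sol, lang) == pytest.approx(1.5 / 2.5)
        assert total_coverage(sol, lin) == 1.0

    def test_unknown_component_in_sample_rejected(self):
        with pytest.raises(DesignError):
            sx.SimulationDesign(
                self.comps,
                [("S", sx.Composition(["nope", "4-MPY"], [0.5, 0.5]))],
            )


class TestSimulateSample:
    def test_zero_noise_is_exact_convex_combination(self):
        study = make_study(compositions={"M": [0.3, 0.7]})
        design = study.design
        profiles = _pure_profiles(design)
        s = sx.surface_fractions(
            sx.Composition(design.component_names, [0.3, 0.7]), design
        )
        expected = s @ profiles
        for spot in study.mixtures.select("M"):
            np.testing.assert_allclose(spot.intensity, expected, atol=1e-12)

    def test_spot_count_and_metadata(self):
        study = make_study(spots=5)
        assert len(study.mixtures.select("M1")) == 5
        assert {sp.spot_index for sp in study.mixtures.select("M1")} == set(range(1, 6))


class TestStudy:
    def test_same_seed_reproduces_byte_identical(self, tmp_path):
        a = make_study(spot_sigma=0.2, additive_sigma=0.01, seed=9)
        b = make_study(spot_sigma=0.2, additive_sigma=0.01, seed=9)
        for s1, s2 in zip(a.mixtures, b.mixtures):
            assert np.array_equal(s1.intensity, s2.intensity)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        sx.write_spectra(a.mixtures, pa, dialect="wide")
        sx.write_spectra(b.mixtures, pb, dialect="wide")
        assert pa.read_bytes() == pb.read_bytes()

    def test_ledger_fractions_sum_to_one(self):
        study = make_study(("1,4-BDT", "4-MBA", "4-MPY"), seed=4)
        sums = study.ledger.groupby("sample_id")[
            ["solution_fraction", "surface_fraction", "effective_weight"]
        ].sum()
        np.testing.assert_allclose(sums.to_numpy(), 1.0, atol=1e-9)

    def test_pure_references_are_labelled(self):
        study = make_study()
        labels = {s.component_label for s in study.pure}
        assert labels == {"4-MBA", "4-MPY"}

    def test_noiseless_end_to_end_recovers_ledger_surface_fractions(self):
        study = make_study(("1,4-BDT", "4-MBA", "4-MPY"), seed=3)
        model = sx.fit_pure_references(study.pure)
        from sersmix.pipeline import predict_surface_compositions

        comps, _, _ = predict_surface_compositions(study.mixtures, model)
        for sid, comp in comps.items():
            truth = sx.ledger_composition(study.ledger, sid, "surface_fraction")
            np.testing.assert_allclose(
                comp.fractions, truth.reorder(comp.component_names).fractions, atol=1e-6
            )


def test_noise_monotonically_degrades_recovery():
    """Median end-to-end composition error over replicate studies increases
    strictly with the additive-noise scale."""
    sigmas = [0.002, 0.02, 0.1]
    medians = []
    for sigma in sigmas:
        errs = []
        for rep in range(50):
            study = make_study(
                compositions={"REF": [0.5, 0.5], "M": [0.25, 0.75]},
                spot_sigma=0.0,
                additive_sigma=sigma,
                spots=3,
                seed=1000 + rep,
                grid=np.arange(600.0, 1801.0, 8.0),
            )
            ana = sx.analyze_simulated(study, "REF", warn=False)
            truth = sx.ledger_composition(study.ledger, "M", "solution_fraction")
            comp = ana.solution["M"]
            errs.append(
                np.abs(comp.fractions - truth.reorder(comp.component_names).fractions).mean()
            )
        medians.append(float(np.median(errs)))
    assert medians[0] < medians[1] < medians[2]
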