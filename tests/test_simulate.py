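"""Deterministic integration and cell-ensemble simulation."""

import numpy as np
import pytest

from erkpulse import (CellEnsembleSpec, build_parameters, sample_ensemble,
                      simulate_deterministic, simulate_ensemble)
from erkpulse.model import CONSERVED_CYCLES
from erkpulse.stimulus import StimulusProtocol, make_sustained


class TestDeterministic:
    def test_zero_dose_trace_is_flat(self, full_params):
        tr = simulate_deterministic(full_params, make_sustained("EGF", 0, 10, 60))
        assert np.max(np.abs(tr.erk - tr.erk[0])) < 1e-6

    def test_tolerance_refinement_self_consistency(self, full_params):
        """Halving integrator tolerances changes the solution by < 1e-5
        relative (the default tolerances are converged)."""
        pr = make_sustained("NGF", 50, 10, 70)
        a = simulate_deterministic(full_params, pr, rtol=1e-8, atol=1e-10)
        b = simulate_deterministic(full_params, pr, rtol=5e-9, atol=5e-11)
        scale = np.max(np.abs(a.erk))
        assert np.max(np.abs(a.erk - b.erk)) / scale < 1e-5

    def test_uniform_grid_and_finite_values(self, sustained_high_ngf):
        dt = np.diff(sustained_high_ngf.t)
        assert np.allclose(dt, dt[0])
        assert np.all(np.isfinite(sustained_high_ngf.erk))

    def test_nonnegative_states(self, full_params):
        pr = make_sustained("NGF", 50, 10, 120)
        tr = simulate_deterministic(full_params, pr, full_state=True)
        assert tr.states.min() >= -1e-9

    @pytest.mark.parametrize("variant", ["FULL", "NO_DUSP", "NO_NFB_CROSSTALK",
                                         "RECEPTOR_INTERNALIZATION"])
    def test_conservation_all_variants(self, variant):
        """Every conserved protein cycle keeps |active + inactive - total|
        below 1e-6 relative throughout the simulation."""
        p = build_parameters(variant)
        pr = make_sustained("EGF", 25, 10, 90)
        tr = simulate_deterministic(p, pr, full_state=True)
        for total_name, idx in CONSERVED_CYCLES:
            tot = getattr(p, total_name)
            act = tr.states[:, idx]
            assert np.all((act >= -1e-9) & (act <= tot + 1e-6))

    def test_egf_invariant_to_pfb_parameters(self, full_params):
        """The positive-feedback pathway carries zero flux under EGF."""
        pr = make_sustained("EGF", 25, 10, 70)
        a = simulate_deterministic(full_params, pr)
        changed = build_parameters("FULL", {"pfb_raf_gain": 50.0,
                                            "k_pfb_act": 1.0,
                                            "pfb_basal": 0.9})
        b = simulate_deterministic(changed, pr)
        assert np.allclose(a.erk, b.erk, atol=1e-10)


class TestEnsemble:
    def test_sampling_reproducible(self, full_params):
        spec = CellEnsembleSpec(n_cells=20, seed=5)
        a = sample_ensemble(spec, full_params)
        b = sample_ensemble(spec, full_params)
        for pa, pb in zip(a, b):
            assert pa == pb

    def test_sample_medians_near_base(self, full_params):
        """At n = 1000 the sample median of every varied total is within 5%
        of the base value (lognormal with median = base)."""
        spec = CellEnsembleSpec(n_cells=1000, seed=1)
        cells = sample_ensemble(spec, full_params)
        for name in spec.varied_fields:
            vals = np.array([getattr(c, name) for c in cells])
            assert np.all(vals > 0)
            assert np.median(vals) == pytest.approx(getattr(full_params, name),
                                                    rel=0.05)

    def test_degenerate_ensemble_matches_deterministic(self, full_params):
        pr = make_sustained("NGF", 50, 10, 40)
        spec = CellEnsembleSpec(n_cells=1, lognormal_sigma=1e-9, seed=0)
        [tr] = simulate_ensemble(spec, full_params, pr)
        ref = simulate_deterministic(full_params, pr)
        assert np.allclose(tr.erk, ref.erk, rtol=1e-6, atol=1e-8)

    def test_order_matches_sampling_order(self, full_params):
        pr = make_sustained("EGF", 25, 10, 30)
        spec = CellEnsembleSpec(n_cells=4, seed=9)
        trajs = simulate_ensemble(spec, full_params, pr)
        assert [t.meta["cell_id"] for t in trajs] == [f"cell_{i:04d}" for i in range(4)]


class TestBistabilityMaintenance:
    def test_latched_cell_sustained_indefinitely_without_dusp(self, full_params):
        """With ERK-induced DUSP expression removed, a cell latched by a 10'
        high-dose NGF pulse holds its high state for hours (robust
        bistability); with DUSP intact the state eventually decays."""
        from erkpulse.metrics import peak_amplitude

        pr = StimulusProtocol("NGF", 50, 10, ((10.0, True), (590.0, False)))
        no_dusp = build_parameters("FULL", {"dusp_mrna_syn": 1e-12})
        tr = simulate_deterministic(no_dusp, pr)
        amp = peak_amplitude(tr, 10.0)
        late_excess = tr.erk[-1] - tr.erk[10]
        assert late_excess >= 0.5 * amp  # still latched at 10 h
        with_dusp = simulate_deterministic(full_params, pr)
        assert (with_dusp.erk[-1] - with_dusp.erk[10]) < late_excess
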