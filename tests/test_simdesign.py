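"""Generator contracts: design layout, effect embedding, spectrum linearity."""

import numpy as np
import pandas as pd
import pytest

from nmrmeat.panel import (
    AGING_TYPE_METABOLITES,
    CATTLE_TYPE_METABOLITES,
    default_panel,
)
from nmrmeat.simdesign import (
    AcquisitionSettings,
    generate_design,
    simulate_concentrations,
    simulate_spectrum,
)
from nmrmeat.spectra import integrate


class TestGenerateDesign:
    def test_default_study_layout(self, default_design):
        d = default_design
        assert d.n_samples == 150
        sizes = sorted(d.animals.aging_run.value_counts().tolist())
        assert sizes == [3, 4, 4, 4]
        # every animal in exactly one run; every (animal, day, type) once
        assert d.samples.groupby("animal_id").aging_run.nunique().eq(1).all()
        combos = d.samples.groupby(["animal_id", "aging_day", "aging_type"]).size()
        assert (combos == 1).all()
        assert len(combos) == 15 * 5 * 2
        day0 = d.samples[d.samples.aging_day == 0]
        assert set(day0.aging_type) == {"dry", "wet"}

    def test_minimal_design(self):
        d = generate_design(1, 0, [0], 1, seed=0)
        assert d.n_samples == 2
        assert set(d.samples.aging_type) == {"dry", "wet"}

    def test_small_design_enumeration(self):
        # 4 animals x 2 days x 2 aging types = 16 samples, balanced runs
        d = generate_design(2, 2, [0, 28], 2, seed=7)
        assert d.n_samples == 16
        assert sorted(d.animals.aging_run.value_counts().tolist()) == [2, 2]
        assert sorted(d.samples.cattle_type.value_counts().tolist()) == [8, 8]

    def test_determinism_and_seed_sensitivity(self):
        a = generate_design(seed=5).animals
        b = generate_design(seed=5).animals
        c = generate_design(seed=6).animals
        pd.testing.assert_frame_equal(a, b)
        assert not a.aging_run.equals(c.aging_run)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_heifers=0, n_cows=0),
            dict(n_runs=0),
            dict(n_runs=99),
            dict(days=[]),
            dict(days=[0, 0, 7]),
            dict(days=[7, 0]),
            dict(days=[-1, 0]),
        ],
    )
    def test_invalid_inputs(self, kwargs):
        base = dict(n_heifers=2, n_cows=2, days=[0, 7], n_runs=2, seed=0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            generate_design(**base)


class TestSimulateConcentrations:
    def test_noiseless_limit_equals_trajectory_means(self, default_design, noiseless_panel):
        conc = simulate_concentrations(default_design, noiseless_panel, seed=0)
        iso = next(m for m in noiseless_panel if m.name == "isoleucine")
        for day in [0, 7, 14, 21, 28]:
            vals = conc.loc[conc.aging_day == day, "isoleucine"]
            assert np.allclose(vals, iso.mean_at(day, 28.0), rtol=0, atol=1e-12)

    def test_day_endpoint_means_match_trajectories(self, conc_table):
        # day-0 / day-28 sample means within 3 SE of the model-implied pooled
        # means (half the samples are dry-aged and carry the aging-type slope)
        panel = default_panel()
        m = next(x for x in panel if x.name == "isoleucine")
        for day, mean, sd in [(0, m.mean_day0, m.within_sd_day0),
                              (28, m.mean_day28, m.within_sd_day28)]:
            vals = conc_table.loc[conc_table.aging_day == day, m.name]
            pooled_mean = mean + 0.5 * m.agingtype_slope_delta * day
            tot_sd = np.sqrt(sd**2 + m.animal_re_sd**2 + m.run_re_sd**2)
            se = tot_sd / np.sqrt(len(vals))
            assert abs(vals.mean() - pooled_mean) < 3 * se + 1e-9

    def test_seed_contract(self, default_design, panel):
        a = simulate_concentrations(default_design, panel, seed=3)
        b = simulate_concentrations(default_design, panel, seed=3)
        c = simulate_concentrations(default_design, panel, seed=4)
        pd.testing.assert_frame_equal(a, b)
        assert not np.allclose(a["alanine"], c["alanine"])

    def test_concentrations_nonnegative(self, conc_table, panel):
        names = [m.name for m in panel]
        assert (conc_table[names].to_numpy() >= 0).all()

    def test_effect_embedding_counts(self, panel):
        n_cattle = sum(m.cattle_offset != 0 for m in panel)
        n_aging = sum(m.agingtype_slope_delta != 0 for m in panel)
        n_trend = sum(m.mean_day28 != m.mean_day0 for m in panel)
        assert n_cattle == 8
        assert n_aging == 12
        assert n_trend == 28
        assert {m.name for m in panel if m.cattle_offset != 0} == set(CATTLE_TYPE_METABOLITES)
        assert {m.name for m in panel if m.agingtype_slope_delta != 0} == set(
            AGING_TYPE_METABOLITES
        )

    def test_empty_panel_rejected(self, default_design):
        with pytest.raises(ValueError):
            simulate_concentrations(default_design, [], seed=0)


class TestSimulateSpectrum:
    def test_signal_integral_linear_in_concentration(self, noiseless_panel, quiet_acq):
        lact = next(m for m in noiseless_panel if m.name == "lactic acid")
        sig = lact.nmr_signals[0]
        areas = []
        for c in (1.0, 2.0):
            sp = simulate_spectrum({"lactic acid": c}, noiseless_panel, quiet_acq, seed=0)
            areas.append(integrate(sp, sig.ppm_lo, sig.ppm_hi, baseline="linear"))
        # area = c * mass_g * fraction * N * response
        expected = 1.0 * 0.2 * 1.0 * sig.n_protons
        assert areas[0] == pytest.approx(expected, rel=1e-4)
        assert areas[1] == pytest.approx(2 * areas[0], rel=1e-6)

    def test_empty_panel_gives_standard_only(self, noiseless_panel, quiet_acq):
        sp = simulate_spectrum({}, noiseless_panel, quiet_acq, seed=0)
        std = integrate(sp, 6.15, 6.40)
        off = integrate(sp, 1.0, 4.5)
        assert std > 1.0  # 0.6 µmol x 2 protons
        # far from the standard singlet only its slowly decaying tail remains
        assert abs(off) < 1e-3 * std

    def test_unknown_metabolite_rejected(self, noiseless_panel, quiet_acq):
        with pytest.raises(KeyError):
            simulate_spectrum({"unobtainium": 1.0}, noiseless_panel, quiet_acq, seed=0)

    def test_spectrum_determinism(self, panel):
        acq = AcquisitionSettings()
        a = simulate_spectrum({"alanine": 3.0}, panel, acq, seed=11)
        b = simulate_spectrum({"alanine": 3.0}, panel, acq, seed=11)
        c = simulate_spectrum({"alanine": 3.0}, panel, acq, seed=12)
        assert np.array_equal(a.intensity, b.intensity)
        assert not np.array_equal(a.intensity, c.intensity)
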