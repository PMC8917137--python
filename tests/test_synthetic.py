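"""Generator contracts: design enumeration, dose-response shape, spectra physics."""

import numpy as np
import pandas as pd
import pytest

from phospec import synthetic
from phospec.synthetic import (
    BAND_CENTERS,
    BAND_SIGMAS,
    P_LEVELS_UM,
    DoseResponseParams,
    FieldParams,
    GeneratorConfig,
    dose_response,
    gaussian_area,
    make_design,
    simulate_field_dataset,
    simulate_field_truth,
    simulate_lab_dataset,
    simulate_spectrum,
)


class TestMakeDesign:
    def test_default_design_has_78_surviving_plants(self):
        design = make_design()
        assert len(design) == 78

    def test_without_mortality_design_has_81_plants(self):
        # 9 distinct conditions x 9 replicates, optimal condition shared
        assert len(make_design(drop_dead=False)) == 81

    def test_single_condition_single_replicate(self):
        design = make_design(
            n_replicates=1, conditions=[("P-series", 150.0, 6.0)], drop_dead=False
        )
        assert len(design) == 1
        assert design.loc[0, "p_conc_uM"] == 150.0

    def test_condition_replicate_counts_close(self):
        design = make_design()
        counts = design.groupby(["series", "p_conc_uM", "n_conc_mM"]).size()
        assert len(counts) == 9
        low_p = counts[("P-series", 1.0, 6.0)]
        assert low_p == 6  # 9 minus the 3 dead plants
        assert (counts.drop(("P-series", 1.0, 6.0)) == 9).all()

    def test_plant_ids_unique(self):
        design = make_design()
        assert design["plant_id"].is_unique


class TestDoseResponse:
    def test_cl_fold_change_is_exactly_three(self):
        d = DoseResponseParams()
        low = np.mean([d.cl_ratio(p) for p in (1.0, 10.0, 30.0)])
        assert d.cl_ratio(500.0) / low == pytest.approx(3.0, rel=1e-12)

    def test_cellulose_threshold_between_30_and_150(self):
        c = {p: dose_response(p, 6.0)["cellulose"] for p in (10.0, 30.0, 150.0)}
        assert c[150.0] / c[30.0] > c[30.0] / c[10.0]

    def test_monotone_responses_across_p_levels(self):
        amps = [dose_response(p, 6.0) for p in P_LEVELS_UM]
        for key in ("Pi", "Po"):
            vals = [a[key] for a in amps]
            assert vals == sorted(vals)
        lignin = [a["lignin"] for a in amps]
        assert lignin == sorted(lignin, reverse=True)
        cl = [a["cellulose"] / a["lignin"] for a in amps]
        assert cl == sorted(cl)

    def test_cl_ratio_nondecreasing_in_p(self):
        d = DoseResponseParams()
        p_grid = np.geomspace(1.0, 500.0, 200)
        cl = d.cl_ratio(p_grid)
        assert np.all(np.diff(cl) >= 0)

    def test_stress_markers_elevated_at_lowest_p(self):
        a1 = dose_response(1.0, 6.0)
        a10 = dose_response(10.0, 6.0)
        a30 = dose_response(30.0, 6.0)
        for key in ("lipid", "amide"):
            assert a1[key] > a10[key] and a1[key] > a30[key]

    def test_nutrient_responsive_components_maximal_at_optimum(self):
        design = make_design(drop_dead=False)
        amps = {
            (r.p_conc_uM, r.n_conc_mM): dose_response(r.p_conc_uM, r.n_conc_mM)
            for r in design.itertuples()
        }
        opt = amps[(500.0, 6.0)]
        for key in ("Pi", "Po", "cellulose"):
            assert opt[key] == pytest.approx(max(a[key] for a in amps.values()))

    def test_amide_increases_with_n(self):
        vals = [dose_response(500.0, n)["amide"] for n in (0.01, 0.1, 0.3, 1.5, 6.0)]
        assert vals == sorted(vals)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            dose_response(-1.0, 6.0)
        with pytest.raises(ValueError):
            dose_response(10.0, 0.0)


class TestSimulateSpectrum:
    def test_zero_amplitudes_zero_noise_gives_zero_spectrum(self):
        sp = simulate_spectrum({k: 0.0 for k in BAND_CENTERS}, 0.0, (), seed=0)
        assert np.all(sp.absorbance == 0.0)

    def test_single_band_peaks_at_lignin_center(self):
        sp = simulate_spectrum({"lignin": 1.0}, 0.0, (), seed=0)
        peak = sp.wavenumbers[np.argmax(sp.absorbance)]
        nearest = sp.wavenumbers[np.argmin(np.abs(sp.wavenumbers - 1510.0))]
        assert peak == nearest

    def test_band_integral_matches_closed_form(self):
        sp = simulate_spectrum({"lignin": 0.7}, 0.0, (), seed=0)
        numeric = np.trapezoid(sp.absorbance, sp.wavenumbers)
        analytic = gaussian_area(0.7, BAND_SIGMAS["lignin"])
        assert numeric == pytest.approx(analytic, rel=1e-3)

    def test_amplitude_linearity_leaves_other_bands_unchanged(self):
        base = {"cellulose": 0.4, "lignin": 0.3}
        doubled = {"cellulose": 0.8, "lignin": 0.3}
        sp1 = simulate_spectrum(base, 0.0, (), seed=0)
        sp2 = simulate_spectrum(doubled, 0.0, (), seed=0)
        diff_area = np.trapezoid(sp2.absorbance - sp1.absorbance, sp1.wavenumbers)
        assert diff_area == pytest.approx(
            gaussian_area(0.4, BAND_SIGMAS["cellulose"]), rel=1e-3
        )
        # far from the cellulose band the spectra agree
        far = sp1.wavenumbers > 1400
        np.testing.assert_allclose(
            sp1.absorbance[far], sp2.absorbance[far], atol=1e-12
        )

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            simulate_spectrum({"lignin": 1.0}, 0.0, (), grid=np.array([]))

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            simulate_spectrum({"lignin": 1.0}, -0.1, ())


class TestLabDataset:
    def test_default_dataset_shape(self, lab_data):
        sset, truth = lab_data
        assert len(sset) == 234            # 78 plants x 3 technical replicates
        assert len(truth) == 78
        assert truth["plant_id"].is_unique

    def test_identical_seed_is_bit_identical(self):
        a_set, a_truth = simulate_lab_dataset(42)
        b_set, b_truth = simulate_lab_dataset(42)
        np.testing.assert_array_equal(a_set.absorbance, b_set.absorbance)
        pd.testing.assert_frame_equal(a_truth, b_truth)

    def test_zero_noise_triplicates_identical(self):
        cfg = GeneratorConfig(noise_sd=0.0)
        sset, truth = simulate_lab_dataset(3, cfg)
        pid = truth.loc[0, "plant_id"]
        rows = sset.metadata.index[sset.metadata["plant_id"] == pid]
        mats = [sset[s].absorbance for s in rows]
        assert len(mats) == 3
        np.testing.assert_array_equal(mats[0], mats[1])
        np.testing.assert_array_equal(mats[0], mats[2])

    def test_truth_cl_ratio_consistent_with_amplitudes(self, lab_data):
        _, truth = lab_data
        np.testing.assert_allclose(
            truth["true_cl_ratio"],
            truth["amp_cellulose"] / truth["amp_lignin"],
            rtol=1e-12,
        )


class TestFieldDataset:
    def test_default_field_shape(self, field_data):
        sset, table = field_data
        assert len(sset) == 300            # 2 sites x 30 plants x 5 timepoints
        assert len(table) == 300
        assert set(table["timepoint"]) == {"T1", "T2", "T3", "T4", "T5"}

    def test_truth_only_table_matches_rendered(self):
        _, rendered = simulate_field_dataset(9)
        truth = simulate_field_truth(9)
        pd.testing.assert_frame_equal(rendered, truth)

    def test_seasonal_trends_by_construction(self, field_data):
        _, table = field_data
        hp = table[table["site"] == "high-P-site"]
        pi = hp.groupby("timepoint")["amp_Pi"].mean()
        po = hp.groupby("timepoint")["amp_Po"].mean()
        cl = table.groupby(["site", "timepoint"])["true_cl_ratio"].mean()
        assert pi["T5"] > pi["T4"] > pi["T1"]          # late-season Pi spike
        assert po["T4"] > po["T5"]                     # Po declines at senescence
        for site in ("low-P-site", "high-P-site"):
            vals = cl[site][["T1", "T2", "T3", "T4", "T5"]].to_numpy()
            assert np.all(np.diff(vals) < 0)           # C/L declines over season
        assert (cl["high-P-site"] > cl["low-P-site"]).all()

    def test_zero_site_effect_equalizes_sites(self):
        fp = FieldParams(site_effect=0.0)
        table = simulate_field_truth(11, fp)
        means = table.groupby("site")[
            ["amp_Pi", "amp_Po", "amp_cellulose", "amp_lignin"]
        ].mean()
        diff = (means.loc["high-P-site"] - means.loc["low-P-site"]).abs()
        sds = table.groupby("site")[
            ["amp_Pi", "amp_Po", "amp_cellulose", "amp_lignin"]
        ].std().mean()
        # site mean difference within Monte-Carlo error (~3 SE)
        assert (diff < 3.0 * sds / np.sqrt(150)).all()

    def test_t5_pipo_ratio_positively_associated_with_biomass(self, field_data):
        _, table = field_data
        t5 = table[table["timepoint"] == "T5"]
        from scipy.stats import spearmanr

        rho = spearmanr(t5["true_pi_po_ratio"], t5["second_year_biomass_g"]).statistic
        assert rho > 0
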