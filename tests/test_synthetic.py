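"""Generator: design structure, moisture schedule, effect injection, determinism."""

import numpy as np
import pandas as pd
import pytest

from droughtflux import qpcr, synthetic
from droughtflux import flux as fluxmod


class TestGenerateDesign:
    def test_factorial_counts_match_field_campaign(self, default_design):
        # 2 warming x 3 vegetation x 5 reps = 30 Oro-Arctic units;
        # 2 warming x 9 reps = 18 alpine units; 48 total, 4 microcosms each
        units = default_design.drop_duplicates("unit_id")
        per_site = units.groupby("site").size()
        assert per_site["oro_arctic"] == 30
        assert per_site["alpine"] == 18
        assert len(units) == 48
        assert len(default_design) == 192
        assert (default_design.groupby("unit_id").size() == 4).all()

    def test_each_unit_has_one_microcosm_per_arm(self, default_design):
        arms = default_design.groupby(["unit_id", "drought", "harvest_day"]).size()
        assert (arms == 1).all()
        assert default_design["microcosm_id"].is_unique

    def test_zero_replicates_gives_empty_design(self):
        site = synthetic.SiteConfig(
            site_id="s", vegetation_types=("v",), replicates_per_cell=0, pwp=9.0
        )
        assert len(synthetic.generate_design([site])) == 0

    def test_duplicate_site_id_rejected(self):
        s = synthetic.oro_arctic_site()
        with pytest.raises(ValueError, match="duplicate site_id"):
            synthetic.generate_design([s, s])

    def test_site_config_validates_moisture_ordering(self):
        with pytest.raises(ValueError):
            synthetic.SiteConfig(site_id="s", vegetation_types=("v",), replicates_per_cell=1,
                                 pwp=70.0, whc_target=60.0)


class TestMoistureSeries:
    @staticmethod
    def _microcosm(drought, day=0):
        return pd.Series({"microcosm_id": "m", "drought": drought, "harvest_day": day})

    def test_control_series_is_constant_at_whc(self):
        site = synthetic.oro_arctic_site()
        ms = synthetic.simulate_moisture_series(self._microcosm("control"), site)
        assert ms.moisture_pct.min() == ms.moisture_pct.max() == site.whc_target

    def test_drought_reaches_pwp_then_holds(self):
        site = synthetic.oro_arctic_site()
        ms = synthetic.simulate_moisture_series(self._microcosm("drought"), site, drydown_rate=1.5)
        below = np.nonzero(ms.moisture_pct <= site.pwp)[0]
        assert ms.commencement_day == below[0]
        # monotone non-increasing down to PWP, held exactly at PWP for 35 days
        assert (np.diff(ms.moisture_pct[: ms.commencement_day + 1]) <= 0).all()
        held = ms.moisture_pct[ms.commencement_day : ms.commencement_day + 36]
        assert np.allclose(held, site.pwp)

    def test_day56_arm_rewets_to_whc(self):
        site = synthetic.oro_arctic_site()
        ms = synthetic.simulate_moisture_series(self._microcosm("drought", day=56), site)
        assert ms.moisture_pct[-1] == site.whc_target

    def test_faster_drydown_never_delays_commencement(self):
        site = synthetic.oro_arctic_site()
        slow = synthetic.simulate_moisture_series(self._microcosm("drought"), site, drydown_rate=1.0)
        fast = synthetic.simulate_moisture_series(self._microcosm("drought"), site, drydown_rate=2.0)
        assert fast.commencement_day <= slow.commencement_day

    def test_pwp_above_start_is_flagged(self):
        site = synthetic.SiteConfig(site_id="s", vegetation_types=("v",), replicates_per_cell=1,
                                    pwp=59.0, whc_target=60.0)
        # a soil already drier than its wilting point (e.g. after storage) is a
        # degenerate drought: trivially satisfied, flagged rather than rejected
        site.pwp = 60.0
        ms = synthetic.simulate_moisture_series(self._microcosm("drought"), site)
        assert ms.flagged and ms.commencement_day == 0
        assert np.allclose(ms.moisture_pct, site.pwp)


class TestSimulateQpcr:
    def test_zero_noise_duplicates_identical(self, default_design, noiseless_config):
        rng = np.random.default_rng(0)
        q, _, _ = synthetic.simulate_qpcr(default_design, noiseless_config, rng)
        spread = q.groupby(["microcosm_id", "gene"])["cq"].agg(lambda v: v.max() - v.min())
        assert (spread == 0).all()

    def test_calibration_points_span_curve_range(self, small_sim):
        calib = small_sim["calibration"]
        for _, grp in calib.groupby("gene"):
            assert sorted(grp["log10_copies"]) == [4.0, 5.0, 6.0, 7.0, 8.0, 9.0]

    def test_drought_multiplier_shifts_ground_truth_geometric_mean(self, default_design):
        # multiplier 2.0 on pmoA: mean log10 true copies differs by log10(2)
        # between drought and control cells, within Monte-Carlo error
        cfg = synthetic.EffectConfig(
            genes=("pmoA",),
            warming_mult={}, drought_mult={"pmoA": 2.0}, day56_mult={},
            vegetation_mult={}, interactions={},
            unit_sd_log10=0.0, microcosm_sd_log10=0.1, cq_noise_sd=0.0,
        )
        diffs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            _, _, truth = synthetic.simulate_qpcr(default_design, cfg, rng)
            t = truth.merge(default_design[["microcosm_id", "drought"]], on="microcosm_id")
            logc = np.log10(t["true_copies_per_g"])
            diffs.append(logc[t["drought"] == "drought"].mean() - logc[t["drought"] == "control"].mean())
        # ~1920 draws per side across seeds: MC error << 0.01
        assert np.mean(diffs) == pytest.approx(np.log10(2.0), abs=0.01)

    def test_effect_injection_exact_on_truth_at_zero_noise(self, default_design, noiseless_config):
        rng = np.random.default_rng(0)
        _, _, truth = synthetic.simulate_qpcr(default_design, noiseless_config, rng)
        t = truth.merge(default_design, on="microcosm_id")
        day0 = t[(t.gene == "pmoA") & (t.harvest_day == 0) & (t.vegetation_type == "wet_meadow")
                 & (t.warming == "ambient")]
        gm = day0.groupby("drought")["true_copies_per_g"].apply(lambda v: np.exp(np.log(v).mean()))
        cfg = noiseless_config
        assert gm["drought"] / gm["control"] == pytest.approx(cfg.drought_mult["pmoA"], rel=1e-12)


class TestSimulateHeadspace:
    def test_every_series_has_four_time_points(self, small_sim):
        counts = small_sim["headspace"].groupby(["microcosm_id", "species"]).size()
        assert (counts == 4).all()

    def test_zero_flux_zero_noise_gives_constant_series(self, default_design):
        cfg = synthetic.EffectConfig(
            flux_base={"CO2": 0.0, "CH4": 0.0, "N2O": 0.0},
            flux_warming_add={}, flux_drought_add={}, flux_day56_add={}, flux_vegetation_add={},
            flux_sd={"CO2": 0.0, "CH4": 0.0, "N2O": 0.0},
            conc_noise_ppm={"CO2": 0.0, "CH4": 0.0, "N2O": 0.0},
        )
        rng = np.random.default_rng(0)
        gas, _ = synthetic.simulate_headspace(default_design.head(4), cfg, rng)
        spread = gas.groupby(["microcosm_id", "species"])["concentration_ppm"].agg(np.ptp)
        assert (spread == 0).all()

    def test_round_trip_recovers_configured_flux_exactly(self, default_design, noiseless_config):
        rng = np.random.default_rng(0)
        gas, truth = synthetic.simulate_headspace(default_design, noiseless_config, rng)
        est = fluxmod.estimate_fluxes(gas, default_design)
        merged = est.merge(truth, on=["microcosm_id", "species"])
        err = np.abs(merged["flux_ug_g_h"] - merged["true_flux_ug_g_h"])
        denom = np.abs(merged["true_flux_ug_g_h"])
        # additive effect combinations can cancel to a true flux of exactly 0;
        # compare those absolutely
        rel = np.where(denom > 0, err / np.where(denom > 0, denom, 1.0), err)
        assert (rel < 1e-9).all()


class TestDeterminism:
    def test_same_seed_same_tables(self):
        a = synthetic.simulate_experiment(seed=11)
        b = synthetic.simulate_experiment(seed=11)
        for name in a:
            pd.testing.assert_frame_equal(a[name], b[name])

    def test_different_seed_different_draws(self):
        a = synthetic.simulate_experiment(seed=11)
        b = synthetic.simulate_experiment(seed=12)
        assert not a["qpcr"]["cq"].equals(b["qpcr"]["cq"])


def test_full_quantification_round_trip_at_zero_noise(default_design, noiseless_config):
    """Generator -> curve fit -> quantify reproduces true copies to 1e-9 relative."""
    rng = np.random.default_rng(0)
    q, calib, truth = synthetic.simulate_qpcr(default_design, noiseless_config, rng)
    abund = qpcr.quantify_table(q, calib, default_design)
    merged = abund.merge(truth, on=["microcosm_id", "gene"])
    rel = np.abs(merged["copies_per_g"] - merged["true_copies_per_g"]) / merged["true_copies_per_g"]
    assert (rel < 1e-9).all()
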