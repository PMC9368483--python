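"""Cohort generator: determinism, calibration fidelity, correlation structure."""

import dataclasses
import math

import numpy as np
import pytest

from retphys import (
    GroupCalibration,
    calibrate_within_correlation,
    cohort_truth_table,
    default_cohort_config,
    generate_cohort,
)
from retphys.synthgen import (
    DRAWN_METRICS,
    FAD_CALIBRATION,
    WT_CALIBRATION,
    calibrate_o2av_correlation,
    pooled_moments,
)

from conftest import scaled_calibrations


class TestDeterminism:
    def test_same_seed_identical_tables(self):
        cfg = default_cohort_config(seed=123)
        t1 = cohort_truth_table(generate_cohort(cfg))
        t2 = cohort_truth_table(generate_cohort(cfg))
        assert t1.to_csv(index=False) == t2.to_csv(index=False)

    def test_different_seed_differs(self):
        t1 = cohort_truth_table(generate_cohort(default_cohort_config(seed=1)))
        t2 = cohort_truth_table(generate_cohort(default_cohort_config(seed=2)))
        assert t1.to_csv(index=False) != t2.to_csv(index=False)

    def test_leading_animals_shared_across_cohort_sizes(self):
        small = default_cohort_config(seed=9, calibrations=scaled_calibrations(3))
        large = default_cohort_config(seed=9, calibrations=scaled_calibrations(5))
        t_small = cohort_truth_table(generate_cohort(small, raw_signals=False))
        t_large = cohort_truth_table(generate_cohort(large, raw_signals=False))
        wt_small = t_small[t_small.group == "WT"].reset_index(drop=True)
        wt_large = t_large[t_large.group == "WT"].head(3).reset_index(drop=True)
        assert wt_small.equals(wt_large)


class TestCalibrationFidelity:
    @staticmethod
    def truncated_moments_oracle(mu, sd, lam=0.0):
        """(mean, sd) of a positivity-truncated draw, by quadrature.

        Residual-only redraw means the truncation acts conditionally on the
        shared factor f: x | f is normal(mu + sd*lam*f, sd*sqrt(1-lam^2))
        truncated at 0; the marginal moments integrate over f using the
        standard truncated-normal formulas E = m + s*h and
        Var = s^2 (1 + a*h - h^2) with hazard h = phi(a)/(1-Phi(a)).
        """
        from scipy import integrate
        from scipy import stats as ss

        s = sd * math.sqrt(1.0 - lam**2)

        def moments(f):
            m = mu + sd * lam * f
            a = -m / s
            h = ss.norm.pdf(a) / ss.norm.sf(a)
            e1 = m + s * h
            var = s**2 * (1.0 + a * h - h**2)
            return e1, var + e1**2

        e1 = integrate.quad(lambda f: ss.norm.pdf(f) * moments(f)[0], -8, 8)[0]
        e2 = integrate.quad(lambda f: ss.norm.pdf(f) * moments(f)[1], -8, 8)[0]
        return e1, math.sqrt(e2 - e1**2)

    def test_large_cohort_matches_calibration(self):
        # 10^4 animals per group: drawn means within 1% of the calibration
        # (positivity-truncation corrected), SDs within 2% where the
        # truncated mass is negligible
        from retphys.synthgen import (
            CORRELATED_BLOCK,
            calibrate_o2av_correlation,
            calibrate_within_correlation,
        )
        from scipy import stats as ss

        cfg = default_cohort_config(
            seed=31, calibrations=scaled_calibrations(10_000)
        )
        cals = cfg.calibrations
        lam = {
            "v_v_mm_s": calibrate_within_correlation(
                cals, "o2a_ml_dl", "v_v_mm_s", -0.57
            ),
            "nfl_rgcl": calibrate_within_correlation(
                cals, "o2a_ml_dl", "nfl_rgcl", -0.53
            ),
            "o2v_ml_dl": calibrate_o2av_correlation(cals[0]),
        }
        table = cohort_truth_table(generate_cohort(cfg, raw_signals=False))
        for cal in cals:
            sub = table[table.group == cal.group]
            for metric in DRAWN_METRICS:
                mu, sigma = cal.means[metric], cal.sds[metric]
                e_mean, e_sd = self.truncated_moments_oracle(
                    mu, sigma, lam.get(metric, 0.0)
                )
                mean, sd = sub[metric].mean(), sub[metric].std(ddof=1)
                assert mean == pytest.approx(e_mean, rel=0.01), metric
                assert sd == pytest.approx(e_sd, rel=0.02), metric
                if ss.norm.cdf(-mu / sigma) < 0.005:  # negligible truncation
                    assert mean == pytest.approx(mu, rel=0.01), metric
                    assert sd == pytest.approx(sigma, rel=0.02), metric
        # the derived O2AV spread follows its calibrated reference, up to
        # the truncation shrinkage of the venous content
        wt = table[table.group == "WT"]
        assert wt["o2av_ml_dl"].std(ddof=1) == pytest.approx(1.3, rel=0.15)

    def test_degenerate_sds_collapse_to_means(self):
        # single group: with both groups at zero SD the pooled correlation is
        # fixed at -1 by the group means alone and no calibration can exist
        tiny = (
            dataclasses.replace(
                WT_CALIBRATION, n_animals=4, sds={k: 1e-9 for k in WT_CALIBRATION.sds}
            ),
        )
        cfg = default_cohort_config(seed=2, calibrations=tiny, within_eye_cv=0.0)
        table = cohort_truth_table(generate_cohort(cfg, raw_signals=False))
        for cal in tiny:
            sub = table[table.group == cal.group]
            for metric in DRAWN_METRICS:
                assert np.allclose(sub[metric], cal.means[metric], atol=1e-6)

    def test_all_truths_positive_under_default_noise(self):
        cfg = default_cohort_config(seed=17, calibrations=scaled_calibrations(200))
        table = cohort_truth_table(generate_cohort(cfg, raw_signals=False))
        drawn = table[list(DRAWN_METRICS)]
        assert (drawn > 0).all().all()


class TestPooledCorrelationCalibration:
    def test_pooled_r_formula_hits_target(self):
        cals = (WT_CALIBRATION, FAD_CALIBRATION)
        rho_w = calibrate_within_correlation(cals, "o2a_ml_dl", "v_v_mm_s", -0.57)
        vx, vy, cov = pooled_moments(cals, "o2a_ml_dl", "v_v_mm_s", rho_w)
        assert cov / math.sqrt(vx * vy) == pytest.approx(-0.57, abs=1e-10)
        assert -1.0 < rho_w < 0.0  # within-group coupling is also inverse

    def test_unreachable_target_rejected(self):
        with pytest.raises(ValueError, match="not.*achievable"):
            calibrate_within_correlation(
                (WT_CALIBRATION, FAD_CALIBRATION), "o2a_ml_dl", "v_v_mm_s", 0.999
            )

    def test_inconsistent_o2av_sd_rejected(self):
        bad = dataclasses.replace(
            WT_CALIBRATION,
            sds={**WT_CALIBRATION.sds, "o2av_ml_dl": 20.0},
        )
        with pytest.raises(ValueError, match="inconsistent"):
            calibrate_o2av_correlation(bad)

    def test_large_cohort_truth_correlations(self):
        cfg = default_cohort_config(
            seed=77, calibrations=scaled_calibrations(4000)
        )
        table = cohort_truth_table(generate_cohort(cfg, raw_signals=False))
        r_vv = np.corrcoef(table["o2a_ml_dl"], table["v_v_mm_s"])[0, 1]
        r_nfl = np.corrcoef(table["o2a_ml_dl"], table["nfl_rgcl"])[0, 1]
        assert r_vv == pytest.approx(-0.57, abs=0.025)
        assert r_nfl == pytest.approx(-0.53, abs=0.025)


class TestGroupCalibrationValidation:
    def test_rejects_nonpositive_entries(self):
        with pytest.raises(ValueError):
            GroupCalibration(
                group="X",
                n_animals=5,
                means={**WT_CALIBRATION.means, "v_v_mm_s": -1.0},
                sds=WT_CALIBRATION.sds,
            )
        with pytest.raises(ValueError):
            GroupCalibration(
                group="X",
                n_animals=1,
                means=WT_CALIBRATION.means,
                sds=WT_CALIBRATION.sds,
            )

    def test_derived_trbf_consistent_with_printed_reference(self):
        # four veins at the WT means imply TRBF ~ 1.78 uL/min, matching the
        # calibrated reference 1.73 +/- 0.52 within a third of its SD
        from retphys import vein_flow

        q = 4 * vein_flow(WT_CALIBRATION.means["v_v_mm_s"],
                          WT_CALIBRATION.means["d_v_um"])
        ref = WT_CALIBRATION.means["trbf_ul_min"]
        assert abs(q - ref) < WT_CALIBRATION.sds["trbf_ul_min"] / 3


class TestBoundaryStructure:
    def test_boundaries_strictly_increasing_and_average_to_truth(self):
        cfg = default_cohort_config(seed=5)
        animals = generate_cohort(cfg)
        for a in animals[:4]:
            for region in ("nasal", "temporal"):
                depths = a.boundaries[region].depths_um
                assert depths[0] == 0.0
                assert np.all(np.diff(depths) > 0)
            nasal_t = np.diff(a.boundaries["nasal"].depths_um)
            temporal_t = np.diff(a.boundaries["temporal"].depths_um)
            layer_mean = 0.5 * (nasal_t + temporal_t)
            expected = [a.metrics[k] for k in
                        ("nfl_rgcl", "ipl", "inl", "opl", "onl", "prl")]
            assert np.allclose(layer_mean, expected, rtol=1e-12)

    def test_vein_count_matches_config(self):
        cfg = default_cohort_config(seed=5, n_veins_per_eye=5, n_arteries_per_eye=3)
        a = generate_cohort(cfg)[0]
        veins = [v for v in a.vessels if v.vessel_type == "vein"]
        arteries = [v for v in a.vessels if v.vessel_type == "artery"]
        assert len(veins) == 5 and len(arteries) == 3
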