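"""Tests of background correction, KDE thresholding and cell classification."""

import numpy as np
import pandas as pd
import pytest

from dyedrop import gating
from dyedrop.gating import GateThresholds
from dyedrop.synthetic import IntensityModel, simulate_cell_table


def _exact_mixture_minimum(mu1, sd1, mu2, sd2):
    """Brute-force grid minimum of an equal-weight two-Gaussian density."""
    from scipy.stats import norm

    grid = np.linspace(mu1, mu2, 20001)
    dens = 0.5 * norm.pdf(grid, mu1, sd1) + 0.5 * norm.pdf(grid, mu2, sd2)
    return grid[np.argmin(dens)]


def _thresholds(**kw):
    base = dict(
        ldr_cutoff=2.0, edu_cutoff=2.0, ph3_cutoff=2.0,
        dna_g1_low=2.85, dna_g1_high=3.1, dna_g2_low=3.25, dna_g2_high=3.45,
        corpse_floor=10.0,
    )
    base.update(kw)
    return GateThresholds(**base)


class TestBackgroundCorrection:
    def test_subtracts_ring(self):
        rec = pd.Series({"ldr_nuclear": 500.0, "ldr_ring": 100.0})
        assert gating.correct_background(rec, "ldr") == 400.0

    def test_clamps_at_floor(self):
        rec = pd.Series({"edu_nuclear": 100.0, "edu_ring": 150.0})
        assert gating.correct_background(rec, "edu") == 1.0

    def test_unknown_channel_rejected(self):
        with pytest.raises(ValueError):
            gating.correct_background(pd.Series(), "hoechst")

    def test_constant_ring_is_pure_shift(self):
        rng = np.random.default_rng(0)
        sig = rng.lognormal(5, 1, 500)
        df = pd.DataFrame({"ph3_nuclear": sig + 75.0, "ph3_ring": 75.0})
        np.testing.assert_allclose(gating.correct_background(df, "ph3"), sig)


class TestDnaContent:
    def test_product_of_mean_and_area(self):
        rec = pd.Series({"hoechst_nuclear": 10.0, "nuclear_area": 50.0})
        assert gating.dna_content(rec) == 500.0

    def test_linear_in_area(self):
        a = pd.Series({"hoechst_nuclear": 10.0, "nuclear_area": 50.0})
        b = pd.Series({"hoechst_nuclear": 10.0, "nuclear_area": 100.0})
        assert gating.dna_content(b) == 2 * gating.dna_content(a)

    def test_simulated_mode_ratio_is_two(self):
        well = simulate_cell_table({"G1": 2000, "G2": 2000}, seed=1)
        dna = gating.dna_content(well.cells)
        g1 = np.median(dna[well.cells["true_class"] == "G1"])
        g2 = np.median(dna[well.cells["true_class"] == "G2"])
        assert g2 / g1 == pytest.approx(2.0, abs=0.05)


class TestFindCutoff:
    def test_bimodal_cutoff_near_exact_mixture_minimum(self):
        rng = np.random.default_rng(42)
        logv = np.concatenate([rng.normal(1.0, 0.15, 2000), rng.normal(2.5, 0.15, 2000)])
        cut, flags = gating.find_cutoff(10.0**logv)
        assert flags == []
        assert 1.4 < cut < 2.1
        # the exact equal-weight mixture minimum is ~1.75
        assert abs(cut - _exact_mixture_minimum(1.0, 0.15, 2.5, 0.15)) < 0.25

    def test_unimodal_fallback_flagged(self):
        rng = np.random.default_rng(1)
        vals = 10.0 ** rng.normal(1.0, 0.15, 1000)
        cut, flags = gating.find_cutoff(vals)
        assert "unimodal_fallback" in flags
        logv = np.log10(vals)
        assert cut > np.median(logv)  # everything classifies negative

    def test_translation_equivariance_in_log_domain(self):
        rng = np.random.default_rng(7)
        logv = np.concatenate([rng.normal(1.0, 0.15, 2000), rng.normal(2.5, 0.15, 2000)])
        c1, _ = gating.find_cutoff(10.0**logv)
        c2, _ = gating.find_cutoff(10.0 ** (logv + 1.0))
        assert c2 - c1 == pytest.approx(1.0, abs=0.02)

    def test_empty_rejected_identical_flagged(self):
        with pytest.raises(ValueError):
            gating.find_cutoff(np.array([]))
        cut, flags = gating.find_cutoff(np.full(500, 100.0))
        assert "unimodal_fallback" in flags and cut == pytest.approx(2.0)

    def test_sparse_well_flagged(self):
        rng = np.random.default_rng(2)
        vals = 10.0 ** np.concatenate(
            [rng.normal(1.0, 0.15, 50), rng.normal(2.5, 0.15, 50)]
        )
        _, flags = gating.find_cutoff(vals)
        assert "too_few_cells" in flags


class TestFindDnaWindows:
    def test_windows_bracket_modes_boundary_between(self):
        rng = np.random.default_rng(3)
        dna = np.concatenate(
            [1000.0 * 10 ** rng.normal(0, 0.05, 3000), 2000.0 * 10 ** rng.normal(0, 0.05, 2000)]
        )
        (g1_lo, g1_hi, g2_lo, g2_hi), flags = gating.find_dna_windows(dna)
        assert "g2_imputed" not in flags
        assert g1_lo < np.log10(1000) < g1_hi
        assert g2_lo < np.log10(2000) < g2_hi
        assert np.log10(1150) < g1_hi < np.log10(1800)

    def test_single_peak_imputes_g2_at_twice_g1(self):
        rng = np.random.default_rng(4)
        dna = 1000.0 * 10 ** rng.normal(0, 0.05, 3000)
        (g1_lo, _, _, g2_hi), flags = gating.find_dna_windows(dna)
        assert "g2_imputed" in flags
        g1_mode = g1_lo + 0.15
        assert 10.0 ** (g2_hi - 0.15) == pytest.approx(2.0 * 10.0**g1_mode, rel=0.1)

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            gating.find_dna_windows(np.full(50, 1000.0))


class TestClassifyCells:
    def _row(self, ldr=1.0, edu=1.0, ph3=1.0, dna_mean=10.0, area=100.0):
        return dict(
            nuclear_area=area, hoechst_nuclear=dna_mean,
            ldr_nuclear=ldr, ldr_ring=0.0,
            edu_nuclear=edu, edu_ring=0.0,
            ph3_nuclear=ph3, ph3_ring=0.0,
        )

    def test_every_decision_branch(self):
        """Hand-built 9-row table hitting each rule in precedence order."""
        thr = _thresholds()
        rows = [
            self._row(ldr=1e4, dna_mean=0.01),             # corpse (LDR+, no DNA)
            self._row(ldr=1e4, dna_mean=10.0),             # dead
            self._row(ph3=1e4, edu=1e4, dna_mean=20.0),    # M wins over S
            self._row(edu=1e4, dna_mean=15.0),             # S
            self._row(dna_mean=3.0),                       # subG1 (dna=300)
            self._row(dna_mean=10.0),                      # G1 (1000)
            self._row(dna_mean=15.0),                      # S_dropout (1500)
            self._row(dna_mean=20.0),                      # G2 (2000)
            self._row(dna_mean=50.0),                      # beyondG2 (5000)
        ]
        out = gating.classify_cells(pd.DataFrame(rows), thr)
        assert list(out["viability"]) == ["corpse", "dead"] + ["alive"] * 7
        assert list(out["phase"]) == [
            "none", "none", "M", "S", "subG1", "G1", "S_dropout", "G2", "beyondG2",
        ]

    def test_missing_column_named(self):
        df = pd.DataFrame([self._row()]).drop(columns=["edu_ring"])
        with pytest.raises(KeyError, match="edu_ring"):
            gating.classify_cells(df, _thresholds())

    def test_partition_no_cell_dropped(self, mixed_well):
        thr = gating.fit_thresholds(mixed_well.cells)
        out = gating.classify_cells(mixed_well.cells, thr)
        assert len(out) == len(mixed_well.cells)
        alive = out["viability"] == "alive"
        assert (out.loc[alive, "phase"] != "none").all()
        assert (out.loc[~alive, "phase"] == "none").all()

    def test_intensity_scale_equivariance(self, mixed_well):
        """Scaling one channel shifts its cutoff but not the labels."""
        cells = mixed_well.cells
        thr = gating.fit_thresholds(cells)
        scaled = cells.copy()
        scaled["edu_nuclear"] = (scaled["edu_nuclear"] - scaled["edu_ring"]) * 100.0
        scaled["edu_ring"] = 0.0
        thr2 = gating.fit_thresholds(scaled)
        assert thr2.edu_cutoff - thr.edu_cutoff == pytest.approx(2.0, abs=0.05)
        a = gating.classify_cells(cells, thr)
        b = gating.classify_cells(scaled, thr2)
        assert (a["phase"] == b["phase"]).mean() > 0.999


class TestSummarizeWell:
    def test_arithmetic(self):
        labels = pd.DataFrame(
            {
                "viability": ["alive"] * 90 + ["dead"] * 10,
                "phase": ["G1"] * 50 + ["S"] * 20 + ["G2"] * 15 + ["M"] * 5 + ["none"] * 10,
            }
        )
        s = gating.summarize_well(labels)
        assert s["live"] == 90 and s["dead"] == 10 and s["total"] == 100
        assert s["f_S"] == pytest.approx(2 / 9)
        fr = sum(s[f"f_{p}"] for p in gating.PHASES)
        assert fr == pytest.approx(1.0, abs=1e-12)

    def test_all_corpses_flagged(self):
        labels = pd.DataFrame({"viability": ["corpse"] * 5, "phase": ["none"] * 5})
        s = gating.summarize_well(labels)
        assert s["live"] == 0 and s["dead"] == 5 and s["corpse"] == 5
        assert np.isnan(s["f_G1"]) and "empty_live" in s["flags"]

    def test_matches_simulator_ground_truth(self, mixed_well):
        thr = gating.fit_thresholds(mixed_well.cells)
        s = gating.summarize_well(gating.classify_cells(mixed_well.cells, thr))
        tc = mixed_well.true_counts
        live_true = tc["G1"] + tc["S"] + tc["G2"] + tc["M"] + tc["subG1"]
        assert abs(s["live"] - live_true) / live_true < 0.02
        assert abs(s["dead"] - (tc["dead"] + tc["corpse"])) / (tc["dead"] + tc["corpse"]) < 0.02
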