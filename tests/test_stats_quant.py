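"""Probit dose-response, likelihood-ratio equality test, delta-delta-Ct."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from mule_unmask import (
    ddct_fold_change,
    fit_probit,
    lrt_equality,
    resistance_ratio,
    summarize_bioassays,
)
from mule_unmask.util import format_sig

DOSES7 = np.logspace(-1.5, 1.5, 7)


def simulate_assay(lc50, slope, rng, doses=DOSES7, n=50):
    scaled = doses * lc50
    p = norm.cdf(slope * (np.log10(scaled) - np.log10(lc50)))
    return pd.DataFrame({"dose": scaled, "n": n, "dead": rng.binomial(n, p)})


class TestFitProbit:
    def test_symmetric_data_lc50_at_midpoint(self):
        """50% mortality at dose d with symmetric flanks puts LC50 at d."""
        d = 3.7
        data = pd.DataFrame(
            {
                "dose": [d / 100, d / 10, d, d * 10, d * 100],
                "n": [50] * 5,
                "dead": [4, 15, 25, 35, 46],
            }
        )
        fit = fit_probit(data)
        assert fit.converged
        assert fit.lc50 == pytest.approx(d, rel=1e-6)
        assert fit.ci95[0] < d < fit.ci95[1]

    def test_degenerate_mortality_flagged(self):
        data = pd.DataFrame({"dose": [1, 2, 4], "n": [50] * 3, "dead": [50] * 3})
        fit = fit_probit(data)
        assert not fit.converged and fit.lc50 is None

    def test_too_few_doses_rejected(self):
        data = pd.DataFrame({"dose": [1, 2], "n": [50, 50], "dead": [10, 40]})
        with pytest.raises(ValueError, match="doses"):
            fit_probit(data)

    def test_recovery_and_ci_coverage(self):
        """Simulation recovery: small LC50 bias and ~95% CI coverage."""
        rng = np.random.default_rng(12)
        estimates, covered = [], 0
        n_sim = 200
        for _ in range(n_sim):
            fit = fit_probit(simulate_assay(10.0, 1.2, rng))
            assert fit.converged
            estimates.append(fit.lc50)
            covered += fit.ci95[0] <= 10.0 <= fit.ci95[1]
        assert abs(np.median(estimates) - 10.0) / 10.0 < 0.05
        assert abs(np.mean(np.log10(estimates)) - 1.0) < 0.02
        assert 0.90 <= covered / n_sim <= 0.99


class TestResistanceRatio:
    def test_published_lc50_ratios(self):
        """Ratios of the printed LC50s reproduce the printed RRs."""
        lc50s = {"1X": 1.07, "4H": 3.19, "62H2": 1563.0, "88H2": 1606.0, "92H6": 10830.0}
        ref = lc50s["1X"]
        assert resistance_ratio(lc50s["4H"], ref) == pytest.approx(2.98, rel=1e-3)
        assert resistance_ratio(lc50s["62H2"], ref) == pytest.approx(1460, rel=1e-3)
        assert resistance_ratio(lc50s["88H2"], ref) == pytest.approx(1501, rel=1e-3)
        assert resistance_ratio(lc50s["92H6"], ref) > 10_000

    def test_identity_and_formatting(self):
        assert resistance_ratio(2.5, 2.5) == 1.0
        assert format_sig(resistance_ratio(3.19, 1.07)) == "2.98"
        assert format_sig(resistance_ratio(1563.0, 1.07)) == "1,460"

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            resistance_ratio(0.0, 1.0)
        with pytest.raises(ValueError):
            resistance_ratio(1.0, -2.0)

    def test_scale_invariance(self):
        """Multiplying all doses of both assays by c leaves RR unchanged."""
        rng = np.random.default_rng(3)
        a = simulate_assay(2.0, 1.5, rng)
        b = simulate_assay(40.0, 1.5, rng)
        rr = resistance_ratio(fit_probit(b), fit_probit(a))
        for df in (a, b):
            df["dose"] *= 37.0
        rr_scaled = resistance_ratio(fit_probit(b), fit_probit(a))
        assert rr_scaled == pytest.approx(rr, rel=1e-9)


class TestLRT:
    def test_identical_datasets_null(self):
        rng = np.random.default_rng(5)
        d = simulate_assay(5.0, 1.2, rng)
        res = lrt_equality([d, d.copy()])
        assert res.chi2 == pytest.approx(0.0, abs=1e-8)
        assert res.df == 2
        assert res.p_value == pytest.approx(1.0, abs=1e-6)

    def test_separated_lc50s_rejected(self):
        rng = np.random.default_rng(6)
        res = lrt_equality(
            [simulate_assay(1.0, 1.2, rng), simulate_assay(1000.0, 1.2, rng)]
        )
        assert res.p_value < 0.01

    def test_failed_member_fit_raises(self):
        rng = np.random.default_rng(7)
        dead = pd.DataFrame({"dose": [1, 2, 4], "n": [50] * 3, "dead": [50] * 3})
        with pytest.raises(ValueError, match="failed"):
            lrt_equality([simulate_assay(1.0, 1.2, rng), dead])


class TestDdct:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["sample", "gene", "ct"])

    def test_equal_cts_give_unity(self):
        t = self._table(
            [(s, g, 20.0) for s in ("a", "b") for g in ("tgt", "hk")]
        )
        out = ddct_fold_change(t, ["tgt"], ["hk"], "a")
        assert (out["fold_change"] == 1.0).all()

    def test_one_cycle_difference_doubles(self):
        t = self._table(
            [("test", "tgt", 19.0), ("test", "hk", 20.0),
             ("cal", "tgt", 20.0), ("cal", "hk", 20.0)]
        )
        out = ddct_fold_change(t, ["tgt"], ["hk"], "cal")
        fold = out.set_index("sample")["fold_change"]
        assert fold["test"] == pytest.approx(2.0)

    def test_two_housekeepers_match_geometric_mean_oracle(self):
        """Normalising by the mean Ct of two housekeepers equals dividing
        the linear quantity by the geometric mean of theirs."""
        t = self._table(
            [("s", "tgt", 18.5), ("s", "hk1", 20.0), ("s", "hk2", 22.0),
             ("cal", "tgt", 21.0), ("cal", "hk1", 21.0), ("cal", "hk2", 21.5)]
        )
        out = ddct_fold_change(t, ["tgt"], ["hk1", "hk2"], "cal")
        fold = out.set_index("sample")["fold_change"]

        def linear_ratio(ct_t, ct_h1, ct_h2):
            return 2.0**-ct_t / np.sqrt(2.0**-ct_h1 * 2.0**-ct_h2)

        oracle = linear_ratio(18.5, 20.0, 22.0) / linear_ratio(21.0, 21.0, 21.5)
        assert fold["s"] == pytest.approx(oracle, rel=1e-12)

    def test_missing_ct_error_names_offender(self):
        t = self._table([("s", "tgt", 20.0), ("cal", "tgt", 20.0),
                         ("cal", "hk", 20.0)])
        with pytest.raises(ValueError, match="hk"):
            ddct_fold_change(t, ["tgt"], ["hk"], "cal")


def test_bioassay_summary_table_shape():
    rng = np.random.default_rng(9)
    datasets = {
        "ref": simulate_assay(1.0, 1.5, rng),
        "res": simulate_assay(500.0, 1.2, rng),
    }
    table = summarize_bioassays(datasets, "ref").set_index("clone")
    assert table.loc["res", "rr"] > 50
    assert table.loc["res", "p_value"] < 0.01
    assert {"lc50", "ci_low", "ci_high", "slope", "slope_se"} <= set(table.columns)
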