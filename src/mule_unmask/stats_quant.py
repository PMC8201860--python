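"""Dose-response and expression statistics.

Probit analysis on log10 dose is the field-standard model for insecticide
bioassays (the POLO convention): mortality p(d) = Phi(b0 + b1*log10 d),
LC50 = 10^(-b0/b1), with the LC50's 95% CI from Fieller's theorem on the
ratio -b0/b1 (delta-method fallback, flagged, when the Fieller
discriminant is unusable).  Resistance ratios divide a clone's LC50 by the
susceptible reference's.  Equality of dose-response curves is tested by a
likelihood-ratio test of k separate probit regressions against one pooled
regression (2(k-1) degrees of freedom: slope and intercept per extra
group).  Relative expression from qPCR uses the delta-delta-Ct method with
the arithmetic mean of housekeeping Cts as normaliser (equivalently, the
log of the geometric mean of the linear quantities).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

Z95 = stats.norm.ppf(0.975)


def _validate(data: pd.DataFrame) -> pd.DataFrame:
    required = {"dose", "n", "dead"}
    if not required <= set(data.columns):
        raise ValueError(f"dose-response data needs columns {sorted(required)}")
    if (data["dose"] <= 0).any():
        raise ValueError("doses must be positive")
    if ((data["dead"] < 0) | (data["dead"] > data["n"])).any():
        raise ValueError("dead counts must lie in [0, n]")
    if data["dose"].nunique() < 3:
        raise ValueError("need at least 3 distinct doses to fit")
    return data


@dataclass
class ProbitFit:
    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    lc50: float | None
    ci95: tuple[float, float] | None
    loglik: float
    converged: bool
    ci_method: str | None = None
    message: str = ""


def fit_probit(data: pd.DataFrame) -> ProbitFit:
    """Maximum-likelihood binomial probit of mortality on log10(dose).

    All-dead or all-alive data cannot localise an LC50 and come back
    flagged (``converged`` False, no estimate) rather than raising.
    """
    data = _validate(data)
    dead = data["dead"].to_numpy(float)
    n = data["n"].to_numpy(float)
    if dead.sum() == 0 or (n - dead).sum() == 0:
        return ProbitFit(
            np.nan, np.nan, np.nan, np.nan, None, None, np.nan, False,
            message="degenerate mortality (all dead or all alive)",
        )
    x = sm.add_constant(np.log10(data["dose"].to_numpy(float)))
    model = sm.GLM(np.column_stack([dead, n - dead]), x,
                   family=sm.families.Binomial(sm.families.links.Probit()))
    try:
        res = model.fit()
    except Exception as exc:  # pragma: no cover - pathological data
        return ProbitFit(np.nan, np.nan, np.nan, np.nan, None, None, np.nan,
                         False, message=f"fit failed: {exc}")
    b0, b1 = res.params
    se0, se1 = res.bse
    cov = res.cov_params()
    if not np.isfinite([b0, b1, se0, se1]).all() or b1 <= 0:
        return ProbitFit(b1, se1, b0, se0, None, None, res.llf, False,
                         message="non-finite or non-positive slope")
    lc50 = 10 ** (-b0 / b1)
    ci, method = _fieller_ci(b0, b1, np.asarray(cov))
    return ProbitFit(b1, se1, b0, se0, lc50, ci, res.llf, True, ci_method=method)


def _fieller_ci(b0: float, b1: float, cov: np.ndarray) -> tuple[tuple[float, float], str]:
    """95% CI for LC50 = 10**(-b0/b1) via Fieller's theorem on a = -b0, b = b1."""
    a, b = -b0, b1
    var_a, var_b = cov[0, 0], cov[1, 1]
    cov_ab = -cov[0, 1]
    rho = a / b
    g = Z95**2 * var_b / b**2
    disc = var_a - 2 * rho * cov_ab + rho**2 * var_b - g * (var_a - cov_ab**2 / var_b)
    if g < 1 and disc > 0:
        centre = rho - g * cov_ab / var_b
        halfwidth = (Z95 / b) * np.sqrt(disc)
        lo, hi = (centre - halfwidth) / (1 - g), (centre + halfwidth) / (1 - g)
        return (10**lo, 10**hi), "fieller"
    se = np.sqrt(max(var_a + rho**2 * var_b - 2 * rho * cov_ab, 0.0)) / abs(b)
    return (10 ** (rho - Z95 * se), 10 ** (rho + Z95 * se)), "delta"


def resistance_ratio(lc50: float | ProbitFit, reference_lc50: float | ProbitFit) -> float:
    """RR = LC50 / LC50(reference); full precision (format separately)."""
    x = lc50.lc50 if isinstance(lc50, ProbitFit) else lc50
    r = reference_lc50.lc50 if isinstance(reference_lc50, ProbitFit) else reference_lc50
    if x is None or r is None or x <= 0 or r <= 0:
        raise ValueError("resistance ratio needs positive LC50s")
    return x / r


@dataclass
class LRTResult:
    chi2: float
    df: int
    p_value: float


def lrt_equality(datasets: list[pd.DataFrame]) -> LRTResult:
    """Likelihood-ratio test that k probit regressions share slope and
    intercept (pooled fit as the null); df = 2(k-1)."""
    if len(datasets) < 2:
        raise ValueError("need at least two datasets")
    fits = [fit_probit(d) for d in datasets]
    bad = [i for i, f in enumerate(fits) if not f.converged]
    if bad:
        raise ValueError(f"member fit(s) failed: datasets {bad}")
    pooled = fit_probit(pd.concat(datasets, ignore_index=True))
    if not pooled.converged:
        raise ValueError("pooled fit failed")
    chi2 = 2.0 * (sum(f.loglik for f in fits) - pooled.loglik)
    chi2 = max(chi2, 0.0)
    df = 2 * (len(datasets) - 1)
    return LRTResult(chi2=chi2, df=df, p_value=float(stats.chi2.sf(chi2, df)))


def ddct_fold_change(
    ct_table: pd.DataFrame,
    target_genes: list[str],
    housekeeping_genes: list[str],
    calibrator_sample: str,
) -> pd.DataFrame:
    """Relative expression (fold change) by the delta-delta-Ct method.

    ``ct_table`` has columns (sample, gene, ct); every sample must carry a
    Ct for every target and housekeeping gene.  Normalisation subtracts the
    arithmetic mean of the housekeeping Cts — the log2-scale equivalent of
    dividing by the geometric mean of their linear abundances.  Returns a
    tidy frame (sample, gene, delta_ct, fold_change) calibrated so the
    calibrator sample's fold change is 1.
    """
    required = {"sample", "gene", "ct"}
    if not required <= set(ct_table.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    if not housekeeping_genes:
        raise ValueError("need at least one housekeeping gene")
    wide = ct_table.pivot_table(index="sample", columns="gene", values="ct")
    missing = [
        (s, g)
        for g in list(target_genes) + list(housekeeping_genes)
        for s in wide.index
        if g not in wide.columns or pd.isna(wide.at[s, g])
    ]
    if missing:
        raise ValueError(f"missing Ct values for (sample, gene): {missing}")
    if calibrator_sample not in wide.index:
        raise ValueError(f"calibrator sample {calibrator_sample!r} not in table")
    norm = wide[housekeeping_genes].mean(axis=1)
    rows = []
    for gene in target_genes:
        dct = wide[gene] - norm
        ddct = dct - dct[calibrator_sample]
        for sample in wide.index:
            rows.append(
                {
                    "sample": sample,
                    "gene": gene,
                    "delta_ct": dct[sample],
                    "fold_change": 2.0 ** (-ddct[sample]),
                }
            )
    return pd.DataFrame(rows)


def summarize_bioassays(
    datasets: dict[str, pd.DataFrame], reference: str
) -> pd.DataFrame:
    """Bioassay summary table: LC50 with CI, slope +/- SE, RR against the
    reference clone, and the equality LRT of each clone vs the reference."""
    if reference not in datasets:
        raise ValueError(f"reference clone {reference!r} not among datasets")
    from .util import format_sig

    fits = {c: fit_probit(d) for c, d in datasets.items()}
    ref_fit = fits[reference]
    rows = []
    for clone, fit in fits.items():
        row: dict = {"clone": clone}
        if fit.converged:
            row.update(
                lc50=fit.lc50,
                ci_low=fit.ci95[0],
                ci_high=fit.ci95[1],
                slope=fit.slope,
                slope_se=fit.slope_se,
            )
            if clone != reference and ref_fit.converged:
                row["rr"] = resistance_ratio(fit, ref_fit)
                row["rr_3sf"] = format_sig(row["rr"], 3)
                lrt = lrt_equality([datasets[reference], datasets[clone]])
                row.update(chi2=lrt.chi2, df=lrt.df, p_value=lrt.p_value)
        else:
            row["note"] = fit.message
        rows.append(row)
    return pd.DataFrame(rows)
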