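"""Logistic association between EMS-3D scores and antibody outcomes.

The mismatch-level model is a plain logistic regression of a binary
donor-specific antibody (DSA) call on the EMS-3D score (continuous), with
optional covariates such as lymphocyte dose.  DSA calls derive from
single-antigen-bead MFI at thresholds of 2000 (positive) and 8000
(high-level).  Odds ratios are reported per 0.1-unit increase of EMS-3D,
the scale on which locus-level effects are usually quoted.  Quartile odds
ratios and observed-rate bins illustrate the continuous fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

_Z95 = 1.959963984540054


class AssociationError(ValueError):
    """Degenerate data or failed model fit."""


def make_outcome_frame(
    ems3d: Sequence[float],
    mfi: Sequence[float],
    pair_id: Sequence[str] | None = None,
    locus: Sequence[str] | None = None,
    **covariates: Sequence[float],
) -> pd.DataFrame:
    """Assemble an outcome table; DSA calls are derived from MFI thresholds."""
    mfi_arr = np.asarray(mfi, dtype=float)
    if (mfi_arr < 0).any():
        raise AssociationError("MFI values must be non-negative")
    df = pd.DataFrame({"ems3d": np.asarray(ems3d, dtype=float), "mfi": mfi_arr})
    df["dsa_2000"] = df["mfi"] >= 2000
    df["dsa_8000"] = df["mfi"] >= 8000
    if pair_id is not None:
        df.insert(0, "pair_id", list(pair_id))
    if locus is not None:
        df.insert(1, "locus", list(locus))
    for name, vals in covariates.items():
        df[name] = np.asarray(vals, dtype=float)
    return df


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit with Wald inference.

    ``or_per_01`` is exp(0.1 * beta_ems3d), the odds ratio per 0.1-unit
    increase of EMS-3D, with its 95% Wald confidence interval.
    """

    params: pd.Series
    bse: pd.Series
    cov: pd.DataFrame
    llf: float
    nobs: int
    outcome: str
    or_per_01: float
    or_ci: tuple[float, float]
    results: object = field(repr=False, default=None)

    def summary(self) -> str:
        lines = [
            f"Logistic regression of {self.outcome} ({self.nobs} records, "
            f"log-likelihood {self.llf:.3f})",
            f"{'term':>12} {'coef':>10} {'se':>9} {'OR/0.1U':>9} {'95% CI':>19}",
        ]
        for term in self.params.index:
            b, se = self.params[term], self.bse[term]
            if term == "ems3d":
                orr, (lo, hi) = self.or_per_01, self.or_ci
                lines.append(
                    f"{term:>12} {b:>10.4f} {se:>9.4f} {orr:>9.3f} "
                    f"[{lo:>7.3f}, {hi:>7.3f}]"
                )
            else:
                lines.append(f"{term:>12} {b:>10.4f} {se:>9.4f} {'':>9} {'':>19}")
        return "\n".join(lines)


def fit_logistic(
    records: pd.DataFrame,
    outcome: str = "dsa_2000",
    covariates: Sequence[str] = (),
    cluster: str | None = None,
    score_col: str = "ems3d",
) -> LogisticFit:
    """Fit DSA ~ intercept + EMS-3D (+ covariates) by maximum likelihood.

    ``cluster`` names a column for cluster-robust (per-pair) standard
    errors.  Raises on a constant outcome, perfect separation, or
    non-convergence.
    """
    y = records[outcome].astype(float).to_numpy()
    n_events = int(y.sum())
    if n_events == 0 or n_events == len(y):
        raise AssociationError(
            f"outcome {outcome!r} is constant ({n_events}/{len(y)} events); "
            "logistic model is degenerate"
        )
    cols = [score_col, *covariates]
    x = sm.add_constant(records[cols].astype(float), has_constant="add")
    model = sm.Logit(y, x)
    try:
        if cluster is not None:
            res = model.fit(
                disp=0, maxiter=200,
                cov_type="cluster",
                cov_kwds={"groups": records[cluster].to_numpy()},
            )
        else:
            res = model.fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises PerfectSeparation subclasses
        if "separation" in str(exc).lower() or "Singular" in str(exc):
            raise AssociationError(f"complete separation detected: {exc}") from exc
        raise
    if not res.mle_retvals.get("converged", True):
        raise AssociationError(
            f"logistic fit did not converge within {res.mle_retvals.get('iterations')} iterations"
        )
    beta = float(res.params[score_col])
    se = float(res.bse[score_col])
    if not math.isfinite(se) or se > 1e3:
        raise AssociationError(
            "unstable standard errors (likely quasi-complete separation)"
        )
    lo, hi = beta - _Z95 * se, beta + _Z95 * se
    return LogisticFit(
        params=res.params,
        bse=res.bse,
        cov=pd.DataFrame(res.cov_params(), index=res.params.index, columns=res.params.index),
        llf=float(res.llf),
        nobs=int(res.nobs),
        outcome=outcome,
        or_per_01=math.exp(0.1 * beta),
        or_ci=(math.exp(0.1 * lo), math.exp(0.1 * hi)),
        results=res,
    )


def assign_quartiles(values: np.ndarray) -> np.ndarray:
    """Quartile labels 1-4 from empirical 25/50/75 percentiles.

    Values exactly at a cut point go to the lower quartile.
    """
    q25, q50, q75 = np.percentile(values, [25, 50, 75])
    return 1 + (values > q25).astype(int) + (values > q50).astype(int) + (values > q75).astype(int)


def quartile_or(
    records: pd.DataFrame, outcome: str = "dsa_2000", score_col: str = "ems3d"
) -> pd.DataFrame:
    """Odds ratios of each EMS-3D quartile versus the first.

    ORs come from 2x2 tables with Wald CIs on the log odds ratio; a zero
    cell triggers the Haldane-Anscombe 0.5 continuity correction, noted in
    the output rather than reported as a silent infinity.
    """
    if len(records) < 8:
        raise AssociationError("need at least 8 records for a quartile split")
    values = records[score_col].to_numpy(dtype=float)
    y = records[outcome].astype(bool).to_numpy()
    quartile = assign_quartiles(values)
    ref_events = int(y[quartile == 1].sum())
    ref_n = int((quartile == 1).sum())
    rows = []
    for q in (1, 2, 3, 4):
        sel = quartile == q
        n, events = int(sel.sum()), int(y[sel].sum())
        if q == 1:
            rows.append(
                {"quartile": q, "n": n, "events": events, "odds_ratio": 1.0,
                 "ci_low": np.nan, "ci_high": np.nan, "note": "reference"}
            )
            continue
        a, b = events, n - events
        c, d = ref_events, ref_n - ref_events
        note = ""
        if 0 in (a, b, c, d):
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
            note = "continuity correction (0.5) applied to a zero cell"
        log_or = math.log((a * d) / (b * c))
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        rows.append(
            {"quartile": q, "n": n, "events": events,
             "odds_ratio": math.exp(log_or),
             "ci_low": math.exp(log_or - _Z95 * se),
             "ci_high": math.exp(log_or + _Z95 * se),
             "note": note}
        )
    return pd.DataFrame(rows)


def two_by_two_or(a: int, b: int, c: int, d: int) -> float:
    """Cross-product odds ratio of a 2x2 table [[a, b], [c, d]]."""
    if 0 in (b, c):
        raise AssociationError("zero cell: odds ratio undefined without correction")
    return (a * d) / (b * c)


def probability_curve(
    fit: LogisticFit,
    ems3d_grid: Sequence[float],
    covariate_values: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Predicted DSA probability over an EMS-3D grid with a 95% Wald band.

    Covariates absent from ``covariate_values`` are held at zero.  The band
    is the delta-method (linear-predictor) pointwise interval mapped through
    the inverse logit.
    """
    grid = np.asarray(ems3d_grid, dtype=float)
    terms = list(fit.params.index)
    x = np.zeros((grid.size, len(terms)))
    for j, term in enumerate(terms):
        if term == "const":
            x[:, j] = 1.0
        elif term == "ems3d":
            x[:, j] = grid
        else:
            x[:, j] = (covariate_values or {}).get(term, 0.0)
    beta = fit.params.to_numpy(dtype=float)
    cov = fit.cov.to_numpy(dtype=float)
    lp = x @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", x, cov, x))
    return pd.DataFrame(
        {
            "ems3d": grid,
            "probability": expit(lp),
            "ci_low": expit(lp - _Z95 * se),
            "ci_high": expit(lp + _Z95 * se),
        }
    )


def binned_observed_rate(
    records: pd.DataFrame,
    bounds: Sequence[float],
    outcome: str = "dsa_2000",
    score_col: str = "ems3d",
) -> pd.DataFrame:
    """Observed event counts and percent per EMS-3D bin.

    ``bounds`` are ordered bin edges; bin i covers [bounds[i], bounds[i+1]).
    Percent is rounded to the nearest integer (half away from zero) and
    reported as missing for empty bins.
    """
    edges = np.asarray(bounds, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise AssociationError("bounds must be a strictly increasing sequence of >= 2 edges")
    values = records[score_col].to_numpy(dtype=float)
    y = records[outcome].astype(bool).to_numpy()
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (values >= lo) & (values < hi)
        count, events = int(sel.sum()), int(y[sel].sum())
        percent = float(math.floor(100.0 * events / count + 0.5)) if count else np.nan
        rows.append({"low": lo, "high": hi, "count": count, "events": events, "percent": percent})
    return pd.DataFrame(rows)
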