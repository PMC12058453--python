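"""Covariate regressions for cycle period and amplitude.

Cycle metrics across herds are related to bottom-up (NDVI/DHI productivity,
winter climate), top-down (predator richness, wolf presence) and biological
(biome, subspecies) covariates with Gaussian identity-link GLMs — ordinary
least squares — simplified by backward stepwise selection on AIC after a
pairwise collinearity screen at |r| > 0.7.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import InvalidParameterError

__all__ = [
    "HERD_COVARIATES",
    "RegressionResult",
    "collinearity_screen",
    "fit_glm",
    "backward_stepwise_aic",
    "residual_diagnostics",
    "period_amplitude_association",
]

log = logging.getLogger(__name__)

#: the full candidate covariate set, one row per herd
HERD_COVARIATES = [
    "latitude",
    "ndvi_dhi",
    "winter_tmin",
    "winter_precip",
    "n_predator_species",
    "wolf_present",
    "biome",
    "subspecies",
    "ecotype",
    "semi_domesticated",
]

#: dropped first when collinear, mirroring the usual confound structure of
#: herd metadata (management status and ecotype recapitulate subspecies/biome)
DEFAULT_DROP_PRIORITY = ("semi_domesticated", "ecotype")


@dataclass
class RegressionResult:
    """Outcome of a stepwise-simplified Gaussian GLM."""

    response: str
    terms: list
    params: dict
    bse: dict
    aic: float
    aic_trace: list               # [(dropped_term_or_None, aic), ...]
    dropped_collinear: list = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)
    model: object = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "terms": list(self.terms),
            "coefficients": {k: float(v) for k, v in self.params.items()},
            "standard_errors": {k: float(v) for k, v in self.bse.items()},
            "aic": float(self.aic),
            "aic_trace": [[t, float(a)] for t, a in self.aic_trace],
            "dropped_collinear": list(self.dropped_collinear),
            "diagnostics": self.diagnostics,
        }


def _numeric_blocks(df: pd.DataFrame) -> dict:
    """Numeric coding of each covariate: numeric/boolean as one column,
    categoricals as a drop-first dummy block."""
    blocks = {}
    for col in df.columns:
        s = df[col]
        if s.dtype == bool:
            blocks[col] = s.astype(float).to_frame()
        elif pd.api.types.is_numeric_dtype(s):
            blocks[col] = s.astype(float).to_frame()
        else:
            # full one-hot (no reference level): a category aliased with
            # another variable's level must show r = 1, which drop-first
            # coding can hide
            blocks[col] = pd.get_dummies(s, prefix=col).astype(float)
    return blocks


def collinearity_screen(
    covariates: pd.DataFrame,
    threshold: float = 0.7,
    priority=DEFAULT_DROP_PRIORITY,
):
    """Flag covariate pairs with |r| above the threshold and drop one member.

    Categorical covariates are dummy-coded; the correlation between two
    covariates is the largest absolute correlation among their column
    pairs (point-biserial for boolean/numeric pairs).  For each flagged
    pair, the member appearing in ``priority`` is dropped; otherwise the
    member with the larger mean |r| against all remaining covariates goes.

    Returns
    -------
    kept : list of column names
    report : list of (var_a, var_b, r) tuples for every flagged pair
    """
    cols = [c for c in covariates.columns if c != "herd_id"]
    if len(cols) < 2:
        return cols, []
    blocks = _numeric_blocks(covariates[cols])
    corr = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            rmax = 0.0
            for ca in blocks[a].columns:
                va = blocks[a][ca]
                if va.std() == 0:
                    continue
                for cb in blocks[b].columns:
                    vb = blocks[b][cb]
                    if vb.std() == 0:
                        continue
                    r = abs(np.corrcoef(va, vb)[0, 1])
                    rmax = max(rmax, 0.0 if np.isnan(r) else r)
            corr.loc[a, b] = corr.loc[b, a] = rmax
    flagged = [
        (a, b, float(corr.loc[a, b]))
        for i, a in enumerate(cols)
        for b in cols[i + 1:]
        if corr.loc[a, b] > threshold
    ]
    flagged.sort(key=lambda t: -t[2])
    dropped = set()
    for a, b, r in flagged:
        if a in dropped or b in dropped:
            continue
        in_priority = [v for v in (a, b) if v in priority]
        if in_priority:
            victim = in_priority[0]
        else:
            victim = a if corr.loc[a].mean() >= corr.loc[b].mean() else b
        dropped.add(victim)
        log.info("collinearity screen: dropping %s (|r|=%.2f with %s)", victim, r, a if victim == b else b)
    kept = [c for c in cols if c not in dropped]
    return kept, flagged


def _term_expr(df: pd.DataFrame, term: str) -> str:
    s = df[term]
    if s.dtype == bool or not pd.api.types.is_numeric_dtype(s):
        return f"C({term})"
    return term


def fit_glm(data: pd.DataFrame, response: str, terms) -> object:
    """Gaussian identity-link GLM (ordinary least squares).

    Categorical terms use treatment contrasts with the alphabetically first
    level as reference.  AIC follows the statsmodels OLS convention
    ``-2 logL + 2 (p + 1)`` with the Gaussian log-likelihood profiled over
    the error variance; the variance parameter itself is not counted, a
    constant offset that cancels in comparisons.

    Raises
    ------
    InvalidParameterError
        If there are too few herds for the parameter count, or the design
        is rank deficient (the aliased columns are named).
    """
    terms = list(terms)
    formula = f"{response} ~ " + (" + ".join(_term_expr(data, t) for t in terms) if terms else "1")
    model = smf.ols(formula, data=data)
    n_params = model.exog.shape[1]
    if len(data) <= n_params + 1:
        raise InvalidParameterError(
            f"need n > p + 1 (n={len(data)}, p={n_params}) to fit {response!r}"
        )
    rank = np.linalg.matrix_rank(model.exog)
    if rank < n_params:
        u, sv, vt = np.linalg.svd(model.exog)
        aliased = [model.exog_names[i] for i in np.argsort(np.abs(vt[-1]))[::-1][: n_params - rank + 1]]
        raise InvalidParameterError(f"rank-deficient design; aliased terms include {aliased}")
    fit = model.fit()
    fit.herdcycles_terms = terms
    fit.herdcycles_response = response
    fit.herdcycles_data = data
    return fit


def backward_stepwise_aic(fitted, use_aicc: bool = False) -> RegressionResult:
    """Backward elimination on AIC starting from a fitted full model.

    At each step the single term (categorical terms as whole blocks) whose
    removal lowers AIC the most is dropped; the procedure stops when no
    removal lowers AIC.  Deterministic: ties break alphabetically, and the
    outcome does not depend on the order predictor columns were supplied.
    """
    def crit(fit):
        if not use_aicc:
            return fit.aic
        n, p = fit.nobs, fit.df_model + 1
        corr = 2 * p * (p + 1) / max(n - p - 1, 1e-9)
        return fit.aic + corr

    data = fitted.herdcycles_data
    response = fitted.herdcycles_response
    terms = sorted(fitted.herdcycles_terms)
    current = fit_glm(data, response, terms)
    trace = [(None, float(crit(current)))]
    while terms:
        candidates = []
        for term in terms:
            reduced = [t for t in terms if t != term]
            try:
                fit = fit_glm(data, response, reduced)
            except InvalidParameterError:
                continue
            candidates.append((float(crit(fit)), term, fit))
        if not candidates:
            break
        candidates.sort(key=lambda c: (c[0], c[1]))
        best_aic, best_term, best_fit = candidates[0]
        if best_aic >= crit(current):
            break
        current = best_fit
        terms = [t for t in terms if t != best_term]
        trace.append((best_term, best_aic))
    return RegressionResult(
        response=response,
        terms=terms,
        params=dict(current.params),
        bse=dict(current.bse),
        aic=float(crit(current)),
        aic_trace=trace,
        model=current,
    )


def residual_diagnostics(fitted, plot_path=None) -> dict:
    """Normality and homoscedasticity checks on a fitted model.

    Returns the correlation of the normal quantile–quantile plot and the
    slope test of |residual| on fitted values (a significant positive slope
    flags variance growing with the mean).  Optionally writes the two
    diagnostic panels to ``plot_path``.
    """
    resid = np.asarray(fitted.resid, dtype=float)
    fittedvals = np.asarray(fitted.fittedvalues, dtype=float)
    n = len(resid)
    from scipy import stats

    order = np.sort(resid)
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    qq_corr = float(np.corrcoef(order, theo)[0, 1]) if n >= 3 else float("nan")
    if np.ptp(fittedvals) > 0:
        het = sm.OLS(np.abs(resid), sm.add_constant(fittedvals)).fit()
        het_slope = float(het.params[1])
        het_p = float(het.pvalues[1])
    else:  # intercept-only fit: no mean-variance slope to test
        het_slope, het_p = float("nan"), float("nan")
    out = {
        "qq_correlation": qq_corr,
        "het_slope": het_slope,
        "het_p_value": het_p,
        "heteroscedastic": bool(het_p < 0.05 and het_slope > 0),
        "low_n": bool(n < 10),
        "n": int(n),
    }
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(8, 3.5))
        axes[0].scatter(theo, order, s=12)
        lo, hi = theo.min(), theo.max()
        axes[0].plot([lo, hi], [lo * order.std() + order.mean(), hi * order.std() + order.mean()],
                     "k--", lw=1)
        axes[0].set_xlabel("normal quantiles")
        axes[0].set_ylabel("residual quantiles")
        axes[1].scatter(fittedvals, resid, s=12)
        axes[1].axhline(0, color="k", lw=1)
        axes[1].set_xlabel("fitted")
        axes[1].set_ylabel("residual")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return out


def period_amplitude_association(metrics: pd.DataFrame):
    """Slope (and SE) of cycle period regressed on cycle amplitude.

    Period is the response: the question is how much longer cycles get per
    unit increase in relative amplitude.  Requires >= 3 cyclic herds.
    """
    df = metrics[metrics["is_cyclic"].astype(bool)].dropna(subset=["period", "amplitude"])
    if len(df) < 3:
        raise InvalidParameterError(f"need >= 3 cyclic herds, got {len(df)}")
    fit = sm.OLS(df["period"].astype(float),
                 sm.add_constant(df["amplitude"].astype(float))).fit()
    return float(fit.params["amplitude"]), float(fit.bse["amplitude"])
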