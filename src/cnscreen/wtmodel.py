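"""Multiplicative (log-linear) model of wild-type growth across the grid.

Independent contributions of a carbon source and a nitrogen source to
growth rate should combine multiplicatively, i.e. additively on the log
scale.  Ordinary least squares of log(rate) on carbon main effects,
nitrogen main effects and carbon x nitrogen interactions — reference-cell
coding with glucose and ammonium as baselines, so the intercept is the log
glucose:ammonium rate and every other fitted mean is relative to it — makes
each significant interaction term a carbon:nitrogen pair whose joint effect
deviates from independence.

Fitting is replicate-level (all wild-type replicate rates per condition),
which yields the standard errors of the displayed terms.  Zero rates are
excluded from the log fit and counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .datatypes import Condition

DEFAULT_ALPHA = 0.01


class MissingCellError(ValueError):
    """A condition has no (or a single) positive wild-type rate."""


def _tidy(wt_rates) -> pd.DataFrame:
    """Accept dict[label -> rates] or a tidy frame; return carbon/nitrogen/rate."""
    if isinstance(wt_rates, dict):
        rows = []
        for label, vals in wt_rates.items():
            cond = Condition.parse(label).pair
            for v in np.asarray(vals, dtype=float).ravel():
                rows.append((cond.carbon, cond.nitrogen, v))
        df = pd.DataFrame(rows, columns=["carbon", "nitrogen", "rate"])
    else:
        df = pd.DataFrame(wt_rates)[["carbon", "nitrogen", "rate"]].copy()
    return df.dropna(subset=["rate"])


@dataclass
class WtModelFit:
    """Fitted terms of the log-linear wild-type model."""

    intercept: tuple[float, float, float]            # (estimate, SE, p)
    carbon_terms: dict[str, tuple[float, float, float]]
    nitrogen_terms: dict[str, tuple[float, float, float]]
    interaction_terms: dict[tuple[str, str], tuple[float, float, float]]
    alpha: float
    n_zero_excluded: int
    result: object = None                            # statsmodels fit, for diagnostics

    def term_table(self) -> pd.DataFrame:
        rows = [("intercept", *self.intercept)]
        rows += [(f"carbon[{c}]", *t) for c, t in sorted(self.carbon_terms.items())]
        rows += [(f"nitrogen[{n}]", *t) for n, t in sorted(self.nitrogen_terms.items())]
        rows += [(f"interaction[{c}:{n}]", *t)
                 for (c, n), t in sorted(self.interaction_terms.items())]
        df = pd.DataFrame(rows, columns=["term", "estimate", "se", "p"])
        df["significant"] = df["p"] < self.alpha
        return df

    def nonsignificant_interactions(self) -> list[tuple[str, str]]:
        """Fitted interaction terms not significant at alpha: the condition
        pairs whose wild-type rate is predictable from independent carbon and
        nitrogen contributions."""
        return sorted((cn for cn, (_, _, p) in self.interaction_terms.items()
                       if not (p < self.alpha)))


def fit_wt_model(wt_rates, alpha: float = DEFAULT_ALPHA) -> WtModelFit:
    """OLS of log wild-type rate on carbon, nitrogen and their interaction."""
    df = _tidy(wt_rates)
    cells = set(map(tuple, df[["carbon", "nitrogen"]].drop_duplicates().to_numpy()))
    n_zero = int((df["rate"] <= 0).sum())
    df = df[df["rate"] > 0].copy()
    counts = df.groupby(["carbon", "nitrogen"]).size()
    thin = sorted(cell for cell in cells if counts.get(cell, 0) < 2)
    if thin or df.empty:
        missing = [f"{c}:{n}" for c, n in thin] or ["<all>"]
        raise MissingCellError(f"conditions lacking >=2 positive wild-type rates: {missing}")
    df["log_rate"] = np.log(df["rate"])
    formula = ("log_rate ~ C(carbon, Treatment('glucose'))"
               " * C(nitrogen, Treatment('ammonium'))")
    fit = smf.ols(formula, data=df).fit()

    carbon: dict[str, tuple[float, float, float]] = {}
    nitrogen: dict[str, tuple[float, float, float]] = {}
    interaction: dict[tuple[str, str], tuple[float, float, float]] = {}
    intercept = (0.0, 0.0, 1.0)
    for name in fit.params.index:
        triple = (float(fit.params[name]), float(fit.bse[name]), float(fit.pvalues[name]))
        if name == "Intercept":
            intercept = triple
        elif ":" in name:
            c = name.split("[T.")[1].split("]")[0]
            n = name.split("[T.")[2].split("]")[0]
            interaction[(c, n)] = triple
        elif name.startswith("C(carbon"):
            carbon[name.split("[T.")[1].split("]")[0]] = triple
        else:
            nitrogen[name.split("[T.")[1].split("]")[0]] = triple
    return WtModelFit(intercept, carbon, nitrogen, interaction, alpha, n_zero, fit)


def compare_model_families(wt_rates) -> pd.DataFrame:
    """Multiplicative (log-additive) vs additive (raw-scale) fit summaries.

    Both are saturated carbon x nitrogen OLS fits; log-likelihoods are put
    on a common scale by evaluating both densities on the raw rates (the
    log-normal model's likelihood carries the 1/y Jacobian).  Lower AIC
    marks the better family.
    """
    df = _tidy(wt_rates)
    df = df[df["rate"] > 0].copy()
    if df.empty:
        raise MissingCellError("no positive wild-type rates")
    df["log_rate"] = np.log(df["rate"])
    inter = "C(carbon, Treatment('glucose')) * C(nitrogen, Treatment('ammonium'))"
    fit_mult = smf.ols(f"log_rate ~ {inter}", data=df).fit()
    fit_add = smf.ols(f"rate ~ {inter}", data=df).fit()

    ll_mult = float(fit_mult.llf - df["log_rate"].sum())  # change of variables
    ll_add = float(fit_add.llf)
    k_mult = fit_mult.df_model + 2  # + intercept + sigma
    k_add = fit_add.df_model + 2
    rows = [
        ("multiplicative", float((fit_mult.resid ** 2).sum()), ll_mult,
         float(2 * k_mult - 2 * ll_mult)),
        ("additive", float((fit_add.resid ** 2).sum()), ll_add,
         float(2 * k_add - 2 * ll_add)),
    ]
    return pd.DataFrame(rows, columns=["family", "rss", "loglik", "aic"]).set_index("family")
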