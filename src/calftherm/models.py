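"""Growth-model selection chain: screening, backward elimination, mixed
models, and Tukey post-hoc contrasts.

The statistical procedure mirrors common practice in veterinary
epidemiology.  Each candidate explanatory variable is first screened in a
univariable model of DLWG (ordinary least squares for the hutch phase; a
linear mixed model with random intercepts for rearing group, igloo pen and
milk-feeder system for the group phase).  Terms with a whole-term p-value
below ``alpha_screen`` (default 0.20) enter a maximal multivariable model,
which is then reduced by backward elimination: at each step the term with
the largest whole-term p-value at or above ``alpha_retain`` (default 0.05)
is dropped, until every remaining term is significant.  Random intercepts
are structural and never dropped.

Whole-term tests are partial F-tests (OLS) or maximum-likelihood
likelihood-ratio tests (mixed models; the final model itself is fitted by
REML).  Pairwise contrasts among the levels of a retained factor use the
Tukey–Kramer studentised-range adjustment on the model-adjusted level
effects.

Usage follows the statsmodels idiom::

    model = DlwgModel.from_dataframe(df, response="dlwg",
                                     candidate_terms=["prop_cat", "birth_weight"],
                                     random_terms=["group_id"])
    res = model.fit()          # screen -> select -> final (RE)ML fit
    print(res.summary())
    res.tukey("prop_cat")
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import patsy
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "ModelSpec",
    "DlwgModel",
    "DlwgResults",
    "univariable_screen",
    "backward_select",
    "fit_lmm",
    "tukey_posthoc",
]

_GROUP_COL = "_unit_group"  # constant grouping column for crossed VCs


@dataclass(frozen=True)
class ModelSpec:
    """Response, candidate terms and thresholds for one phase's analysis."""

    response: str = "dlwg"
    candidate_terms: tuple[str, ...] = ()
    random_terms: tuple[str, ...] = ()
    alpha_screen: float = 0.20
    alpha_retain: float = 0.05

    def __post_init__(self):
        if not 0 < self.alpha_retain < 1 or not 0 < self.alpha_screen < 1:
            raise ValueError("thresholds must lie in (0, 1)")
        if self.alpha_retain >= self.alpha_screen:
            raise ValueError("alpha_retain must be below alpha_screen")

    @property
    def is_mixed(self) -> bool:
        return bool(self.random_terms)


def _is_factor(series: pd.Series) -> bool:
    return (isinstance(series.dtype, pd.CategoricalDtype)
            or series.dtype == object or series.dtype == bool)


class DlwgModel:
    """Growth model with univariable screening and backward elimination.

    Parameters
    ----------
    data : DataFrame with the response, all candidate terms and (for a
        mixed model) the random-intercept grouping columns; rows with
        missing values in used columns are not allowed.
    spec : ModelSpec
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        used = ([spec.response] + list(spec.candidate_terms)
                + list(spec.random_terms))
        missing = [c for c in used if c not in data.columns]
        if missing:
            raise ValueError(f"data is missing column(s): {missing}")
        if data[used].isna().any().any():
            raise ValueError("missing values in modelling columns")
        self.data = data.reset_index(drop=True).copy()
        for col in used:
            if isinstance(self.data[col].dtype, pd.CategoricalDtype):
                self.data[col] = self.data[col].cat.remove_unused_categories()
        self.data[_GROUP_COL] = 1
        # random terms need >= 2 observed levels to be estimable
        random_terms = []
        for rt in spec.random_terms:
            if self.data[rt].nunique() < 2:
                warnings.warn(f"random term {rt!r} has < 2 levels; dropped")
            else:
                random_terms.append(rt)
        self.spec = replace(spec, random_terms=tuple(random_terms))
        self._cache: dict = {}

    @classmethod
    def from_dataframe(cls, data, response="dlwg", candidate_terms=(),
                       random_terms=(), alpha_screen=0.20, alpha_retain=0.05):
        spec = ModelSpec(response=response,
                         candidate_terms=tuple(candidate_terms),
                         random_terms=tuple(random_terms),
                         alpha_screen=alpha_screen,
                         alpha_retain=alpha_retain)
        return cls(data, spec)

    # -- formula plumbing -------------------------------------------------

    def is_factor(self, term: str) -> bool:
        return _is_factor(self.data[term])

    def _piece(self, term: str) -> str:
        return f"C({term})" if self.is_factor(term) else term

    def _formula(self, terms) -> str:
        rhs = " + ".join(self._piece(t) for t in terms) if terms else "1"
        return f"{self.spec.response} ~ {rhs}"

    # -- fitting ----------------------------------------------------------

    def _fit(self, terms, reml=True, method=None):
        """Fit OLS or the mixed model for a given fixed-term set (cached)."""
        key = (tuple(sorted(terms)), reml if self.spec.is_mixed else None, method)
        if key in self._cache:
            return self._cache[key]
        formula = self._formula(terms)
        if not self.spec.is_mixed:
            res = smf.ols(formula, data=self.data).fit()
        else:
            vcf = {rt: f"0 + C({rt})" for rt in self.spec.random_terms}
            mod = smf.mixedlm(formula, data=self.data, groups=_GROUP_COL,
                              vc_formula=vcf)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                # powell: derivative-free, handles boundary (zero-variance)
                # optima where the gradient optimizers stall
                res = mod.fit(reml=reml, method=method or ["powell", "nm"])
        self._cache[key] = res
        return res

    def term_pvalue(self, terms, term) -> float:
        """Whole-term p-value of ``term`` within the model built on ``terms``.

        Partial F-test for OLS; ML likelihood-ratio test for the mixed
        model (matching chi-square reporting of lmer-style analyses).
        """
        reduced = [t for t in terms if t != term]
        if self.spec.is_mixed:
            try:
                full = self._fit(terms, reml=False)
                red = self._fit(reduced, reml=False)
                lr = 2.0 * (full.llf - red.llf)
                df = full.k_fe - red.k_fe
                return float(stats.chi2.sf(max(lr, 0.0), df))
            except (np.linalg.LinAlgError, ValueError) as exc:
                warnings.warn(
                    f"mixed model unestimable for term {term!r} ({exc}); "
                    "falling back to a fixed-effects fit")
        # OLS path (also the mixed-model fallback)
        full = smf.ols(self._formula(terms), data=self.data).fit()
        red = smf.ols(self._formula(reduced), data=self.data).fit()
        df_num = red.df_resid - full.df_resid
        if df_num <= 0 or full.df_resid <= 0:
            return 1.0
        f = (red.ssr - full.ssr) / df_num / (full.ssr / full.df_resid)
        return float(stats.f.sf(max(f, 0.0), df_num, full.df_resid))

    # -- the selection chain ----------------------------------------------

    def screen(self) -> pd.DataFrame:
        """Univariable screening of every candidate term.

        Each candidate is fitted alone (with the random intercepts for a
        mixed spec) and kept iff its whole-term p-value is below
        ``alpha_screen``.  Constant columns are skipped with a warning.
        """
        rows = []
        for term in self.spec.candidate_terms:
            if self.data[term].nunique() <= 1:
                warnings.warn(f"candidate {term!r} is constant; skipped")
                rows.append({"term": term, "pvalue": np.nan, "kept": False,
                             "note": "constant; skipped"})
                continue
            p = self.term_pvalue([term], term)
            rows.append({"term": term, "pvalue": p,
                         "kept": bool(p < self.spec.alpha_screen), "note": ""})
        return pd.DataFrame(rows, columns=["term", "pvalue", "kept", "note"])

    def _drop_rank_deficient(self, terms, trace) -> list:
        """Remove terms whose design columns add no rank (later term loses)."""
        kept: list[str] = []
        rank = 1  # intercept
        design = np.ones((len(self.data), 1))
        for term in terms:
            cols = patsy.dmatrix(f"0 + {self._piece(term)}", self.data,
                                 return_type="matrix")
            cand = np.hstack([design, np.asarray(cols)])
            new_rank = np.linalg.matrix_rank(cand)
            expected = rank + (self.data[term].nunique() - 1
                               if self.is_factor(term) else 1)
            if new_rank < expected:
                warnings.warn(f"term {term!r} is collinear with earlier terms; "
                              "dropped")
                trace.append({"step": "collinearity", "dropped": term,
                              "pvalue": None})
                continue
            kept.append(term)
            design, rank = cand, new_rank
        return kept

    def backward_select(self, terms) -> "DlwgResults":
        """Backward elimination from ``terms`` down to significant terms.

        At each step the term with the largest whole-term p >= alpha_retain
        is dropped (ties broken by dropping the term later in the candidate
        order); random intercepts are never candidates for removal.
        """
        trace: list[dict] = []
        current = self._drop_rank_deficient(list(terms), trace)
        order = {t: i for i, t in enumerate(self.spec.candidate_terms)}
        while current:
            pvals = {t: self.term_pvalue(current, t) for t in current}
            droppable = {t: p for t, p in pvals.items()
                         if p >= self.spec.alpha_retain}
            if not droppable:
                break
            worst = max(droppable, key=lambda t: (droppable[t], order.get(t, -1)))
            trace.append({"step": "drop", "dropped": worst,
                          "pvalue": droppable[worst]})
            current.remove(worst)
        return self._results(current, trace=trace)

    def fit(self, screen: bool = True, select: bool = True) -> "DlwgResults":
        """Run the full chain: screening, backward elimination, final fit.

        ``screen=False`` starts the multivariable model from all candidate
        terms; ``select=False`` fits the (screened) maximal model directly.
        """
        screening = None
        terms = list(self.spec.candidate_terms)
        if screen:
            screening = self.screen()
            terms = [t for t in screening.loc[screening["kept"], "term"]]
        if select:
            res = self.backward_select(terms)
        else:
            trace: list[dict] = []
            terms = self._drop_rank_deficient(terms, trace)
            res = self._results(terms, trace=trace)
        res.screening = screening
        return res

    # -- results assembly --------------------------------------------------

    def _results(self, terms, trace=None, term_tests=True) -> "DlwgResults":
        fitted = self._fit(terms, reml=True)
        term_pvalues = ({t: self.term_pvalue(terms, t) for t in terms}
                        if term_tests else {})
        if self.spec.is_mixed:
            params = fitted.fe_params
            bse = fitted.bse_fe
            resid_var = float(fitted.scale)
            vcomp = {name: float(v) for name, v in
                     zip(fitted.model.exog_vc.names,
                         np.atleast_1d(fitted.vcomp))}
            converged = bool(getattr(fitted, "converged", True))
            df_resid = int(len(self.data) - fitted.k_fe)
        else:
            params = fitted.params
            bse = fitted.bse
            resid_var = float(fitted.ssr / fitted.df_resid)
            vcomp = {}
            converged = True
            df_resid = int(fitted.df_resid)
        return DlwgResults(
            model=self, retained=list(terms), fitted=fitted,
            params=params, bse=bse,
            level_pvalues=pd.Series(fitted.pvalues).reindex(params.index),
            term_pvalues=term_pvalues, trace=trace or [],
            n=len(self.data), resid_var=resid_var, vcomp=vcomp,
            df_resid=df_resid, converged=converged,
        )


@dataclass
class DlwgResults:
    """Fitted growth model: estimates, uncertainties, trace, diagnostics.

    ``params``/``bse`` are the fixed-effect estimates and standard errors
    (patsy coefficient naming); ``level_pvalues`` tests each non-reference
    factor level against the reference; ``term_pvalues`` are the whole-term
    tests; ``vcomp`` maps each random term to its intercept variance
    (mixed models only); ``trace`` records the elimination path.
    """

    model: DlwgModel
    retained: list
    fitted: object
    params: pd.Series
    bse: pd.Series
    level_pvalues: pd.Series
    term_pvalues: dict
    trace: list
    n: int
    resid_var: float
    vcomp: dict
    df_resid: int
    converged: bool
    screening: pd.DataFrame | None = None

    # -- coefficient access -------------------------------------------------

    def _level_names(self, factor: str) -> list:
        col = self.model.data[factor]
        if isinstance(col.dtype, pd.CategoricalDtype):
            return [str(c) for c in col.cat.categories]
        return [str(v) for v in pd.unique(np.sort(col.astype(str)))]

    def _coef_name(self, factor: str, level: str) -> str:
        return f"C({factor})[T.{level}]"

    def factor_effects(self, factor: str) -> tuple[list, np.ndarray, np.ndarray]:
        """Level names, level effects (reference = 0) and their covariance."""
        levels = self._level_names(factor)
        names = [self._coef_name(factor, lv) for lv in levels[1:]]
        missing = [nm for nm in names if nm not in self.params.index]
        if missing:
            raise KeyError(f"coefficients not in model: {missing}")
        eff = np.concatenate([[0.0], self.params[names].to_numpy()])
        cov_all = np.asarray(self.fitted.cov_params())
        cov_names = list(self.params.index)
        idx = [cov_names.index(nm) for nm in names]
        k = len(levels)
        cov = np.zeros((k, k))
        cov[1:, 1:] = cov_all[np.ix_(idx, idx)]
        return levels, eff, cov

    # -- post hoc -----------------------------------------------------------

    def tukey(self, factor: str) -> pd.DataFrame:
        """Tukey–Kramer pairwise contrasts among a retained factor's levels.

        Returns one row per level pair with the model-adjusted difference,
        its standard error and the studentised-range adjusted p-value.
        """
        if factor not in self.retained:
            raise ValueError(f"factor {factor!r} is not in the final model")
        if not self.model.is_factor(factor):
            raise ValueError(f"{factor!r} is not a categorical term")
        levels, eff, cov = self.factor_effects(factor)
        k = len(levels)
        rows = []
        for i in range(k):
            for j in range(i + 1, k):
                est = eff[j] - eff[i]
                se = float(np.sqrt(cov[i, i] + cov[j, j] - 2 * cov[i, j]))
                q = abs(est) / se * np.sqrt(2.0)
                p = float(stats.studentized_range.sf(q, k, self.df_resid))
                rows.append({"level_1": levels[i], "level_2": levels[j],
                             "estimate": est, "se": se, "p_adjusted": p})
        return pd.DataFrame(rows)

    # -- presentation -------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Final-model table: Variable / Level / Estimate / SE / p-values."""
        rows = [{"variable": "Intercept", "level": "",
                 "estimate": self.params.get("Intercept", np.nan),
                 "se": self.bse.get("Intercept", np.nan),
                 "p_reference": np.nan,
                 "p_effect": np.nan}]
        for term in self.retained:
            if self.model.is_factor(term):
                levels = self._level_names(term)
                rows.append({"variable": term, "level": levels[0] + " (ref)",
                             "estimate": np.nan, "se": np.nan,
                             "p_reference": np.nan,
                             "p_effect": self.term_pvalues.get(term, np.nan)})
                for lv in levels[1:]:
                    nm = self._coef_name(term, lv)
                    rows.append({"variable": term, "level": lv,
                                 "estimate": self.params.get(nm, np.nan),
                                 "se": self.bse.get(nm, np.nan),
                                 "p_reference": self.level_pvalues.get(nm, np.nan),
                                 "p_effect": np.nan})
            else:
                rows.append({"variable": term, "level": "",
                             "estimate": self.params.get(term, np.nan),
                             "se": self.bse.get(term, np.nan),
                             "p_reference": np.nan,
                             "p_effect": self.term_pvalues.get(term, np.nan)})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable summary of the selection chain and final model."""
        kind = "linear mixed model" if self.model.spec.is_mixed else "linear model"
        lines = [f"DLWG {kind}  (n = {self.n})",
                 f"response: {self.model.spec.response}"]
        if self.screening is not None and len(self.screening):
            kept = ", ".join(self.screening.loc[self.screening["kept"], "term"]) \
                or "(none)"
            lines.append(
                f"screening (alpha = {self.model.spec.alpha_screen:g}): "
                f"kept {kept}")
        for step in self.trace:
            p = step.get("pvalue")
            lines.append(f"dropped {step['dropped']!r}"
                         + (f" (p = {p:.3f})" if p is not None else
                            " (collinear)"))
        tbl = self.to_frame()
        with pd.option_context("display.float_format", "{:0.3f}".format):
            lines.append(tbl.to_string(index=False, na_rep=""))
        if self.vcomp:
            vc = ", ".join(f"{k}: {v:.4f}" for k, v in self.vcomp.items())
            lines.append(f"random-intercept variances: {vc}")
        lines.append(f"residual variance: {self.resid_var:.4f}")
        return "\n".join(lines)

    def plot_effects(self, factor: str, ax=None):
        """Point-and-interval plot of a factor's model-adjusted effects."""
        import matplotlib.pyplot as plt

        levels, eff, cov = self.factor_effects(factor)
        se = np.sqrt(np.diag(cov))
        if ax is None:
            _, ax = plt.subplots()
        ax.errorbar(range(len(levels)), eff, yerr=1.96 * se, fmt="o")
        ax.set_xticks(range(len(levels)), levels)
        ax.set_xlabel(factor)
        ax.set_ylabel(f"effect on {self.model.spec.response} (kg/d)")
        return ax


# -- functional wrappers (one per pipeline step) ----------------------------

def univariable_screen(data: pd.DataFrame, spec: ModelSpec
                       ) -> tuple[list, pd.DataFrame]:
    """Screen candidates univariably; return (surviving terms, p-value table)."""
    model = DlwgModel(data, spec)
    table = model.screen()
    return list(table.loc[table["kept"], "term"]), table


def backward_select(data: pd.DataFrame, terms, spec: ModelSpec) -> DlwgResults:
    """Backward-eliminate ``terms`` down to the significant set."""
    return DlwgModel(data, spec).backward_select(list(terms))


def fit_lmm(data: pd.DataFrame, fixed_terms, random_terms,
            response: str = "dlwg", term_tests: bool = True) -> DlwgResults:
    """Fit a linear mixed model with crossed random intercepts directly.

    REML estimates; whole-term p-values from ML likelihood-ratio tests.
    """
    spec = ModelSpec(response=response, candidate_terms=tuple(fixed_terms),
                     random_terms=tuple(random_terms))
    model = DlwgModel(data, spec)
    return model._results(list(fixed_terms), term_tests=term_tests)


def tukey_posthoc(result: DlwgResults, factor: str) -> pd.DataFrame:
    """All pairwise Tukey–Kramer contrasts for a retained factor."""
    return result.tukey(factor)
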