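"""Mixed-model trait adjustment.

The analyses downstream never test raw trait values: each trait is first
residualized on the significant environmental fixed effects (parity, litter
size, their interaction) and a litter random intercept, optionally including
body weight at dissection as a covariate (the "adjusted" version of a trait).
Residuals are centred so the overall mean is zero.

Fixed effects are chosen per trait by backward elimination at a nominal 5%
level, interactions dropped before main effects, and a main effect is kept
whenever a retained interaction contains it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import patsy
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .designs import ModelSpec, _term_to_patsy
from .simulate import FOCAL_TRAIT  # noqa: F401  (re-export convenience)

DEFAULT_CANDIDATES = ("parity", "litter_size", "parity:litter_size")

#: litter variance below this fraction of residual variance is treated as the
#: REML boundary and triggers the fixed-effects-only fallback
_BOUNDARY_FRACTION = 1e-6


class DegenerateDesignError(ValueError):
    """Raised when the adjustment design is singular (e.g. a single litter)."""


@dataclass
class AdjustedTrait:
    """Residualized values for one trait plus the fit that produced them."""

    trait: str
    residuals: pd.Series          # aligned to the cohort index; NaN propagates
    spec: ModelSpec
    var_litter: float
    var_residual: float
    n: int
    mixed: bool                   # False if the OLS fallback was used


def derive_traits(cohort: pd.DataFrame) -> pd.DataFrame:
    """Add composite columns: total fat pad weight and body-weight gains.

    Total fat is the sum of inguinal, gonadal and perirenal pads; when the
    perirenal pad was not recorded the sum of the other two is used and the
    boolean ``total_fat_partial`` column flags it.  Gains are successive
    differences of the recorded body-weight schedule.
    """
    df = cohort.copy()
    for col in ("inguinal_fat", "gonadal_fat"):
        if col not in df.columns:
            raise ValueError(f"missing fat pad column {col!r}")
    if "perirenal_fat" in df.columns:
        df["total_fat"] = (df["inguinal_fat"] + df["gonadal_fat"]
                           + df["perirenal_fat"])
        df["total_fat_partial"] = False
    else:
        df["total_fat"] = df["inguinal_fat"] + df["gonadal_fat"]
        df["total_fat_partial"] = True
    ages = sorted(int(c.removeprefix("bw_wk")) for c in df.columns
                  if c.startswith("bw_wk"))
    for a1, a2 in zip(ages, ages[1:]):
        df[f"gain_{a1}_{a2}"] = df[f"bw_wk{a2}"] - df[f"bw_wk{a1}"]
    return df


def _fit_mixed(df: pd.DataFrame, formula: str, reml: bool = True):
    last_exc: Exception | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = smf.mixedlm(formula, data=df, groups=df["litter_id"])
        # lbfgs can stall on the variance boundary and report convergence;
        # powell is slower but robust.  Fit with both and keep the higher
        # restricted likelihood; nm is a last resort if both error out.
        fits = []
        for method in ("lbfgs", "powell"):
            try:
                fits.append(model.fit(reml=reml, method=method))
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_exc = exc
        if not fits:
            try:
                fits.append(model.fit(reml=reml, method="nm"))
            except (np.linalg.LinAlgError, ValueError) as exc:
                raise last_exc or exc
        return max(fits, key=lambda r: (np.isfinite(r.llf), r.llf))


def _term_pvalues(result, design_info) -> dict[str, float]:
    """Wald chi-square P value for each non-intercept term's coefficient block."""
    fe = np.asarray(result.fe_params)
    cov = np.asarray(result.cov_params())[: len(fe), : len(fe)]
    out = {}
    for term, sl in design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        b = fe[sl]
        v = cov[sl, sl]
        try:
            stat = float(b @ np.linalg.solve(v, b))
        except np.linalg.LinAlgError:
            out[term] = np.nan
            continue
        out[term] = float(stats.chi2.sf(stat, df=len(b)))
    return out


def _patsy_formula(trait: str, terms: Sequence[str],
                   covariate: Optional[str] = None) -> str:
    rhs = " + ".join(_term_to_patsy(t) for t in terms) or "1"
    if covariate:
        rhs += f" + {covariate}"
    return f"Q('{trait}') ~ {rhs}"


def _parents(term: str) -> set[str]:
    return set(term.split(":")) if ":" in term else set()


def select_fixed_effects(cohort: pd.DataFrame, trait: str,
                         candidates: Iterable[str] = DEFAULT_CANDIDATES,
                         alpha: float = 0.05) -> ModelSpec:
    """Backward-eliminate fixed effects in the litter mixed model for a trait.

    Starting from the full candidate model, the least significant droppable
    term with Wald P >= alpha is removed and the model refit, interactions
    before main effects; a main effect is droppable only when no retained
    interaction contains it.  Returns the :class:`ModelSpec` of surviving
    terms together with the drop log.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidates must be non-empty")
    df = cohort.dropna(subset=[trait])
    if df["litter_id"].nunique() < 2:
        raise DegenerateDesignError(
            "fixed-effect selection needs at least two litters")
    current = list(candidates)
    dropped: list[tuple[str, float]] = []
    while current:
        formula = _patsy_formula(trait, current)
        try:
            result = _fit_mixed(df, formula)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise DegenerateDesignError(str(exc)) from exc
        design_info = patsy.dmatrices(formula, df,
                                      return_type="dataframe")[1].design_info
        # map symbolic terms to patsy term names
        patsy_names = {t: _patsy_term_name(t, design_info) for t in current}
        pvals = _term_pvalues(result, design_info)
        interactions = {t for t in current if ":" in t}
        protected = set().union(*(_parents(t) for t in interactions)) if interactions else set()
        droppable = [t for t in current
                     if ":" in t or t not in protected]
        worst, worst_p = None, -1.0
        for t in sorted(droppable, key=lambda t: (":" not in t)):
            p = pvals.get(patsy_names[t], np.nan)
            if np.isnan(p) or p >= alpha:
                if np.isnan(p) or p > worst_p:
                    worst, worst_p = t, (1.0 if np.isnan(p) else p)
                if ":" in t:       # always clear interactions first
                    break
        if worst is None:
            break
        current.remove(worst)
        dropped.append((worst, worst_p))
    return ModelSpec(fixed_terms=tuple(current), random_litter=True,
                     dropped=tuple(dropped))


def _patsy_term_name(term: str, design_info) -> str:
    frag = _term_to_patsy(term)
    for name in design_info.term_names:
        if name == frag or set(name.split(":")) == set(frag.split(":")):
            return name
    return frag


def adjust_trait(cohort: pd.DataFrame, trait: str, spec: ModelSpec,
                 covariate: Optional[str] = None,
                 name: Optional[str] = None) -> AdjustedTrait:
    """Residualize one trait on its retained fixed effects and litter.

    Fits the REML mixed model ``trait ~ fixed_terms (+ covariate)`` with a
    litter random intercept; the residual is the observation minus the
    fixed-effect prediction and the litter BLUP, centred to overall mean
    zero.  If the litter variance collapses to the boundary (or the fit
    fails) an ordinary least-squares fit without the random effect is used
    instead, with a warning.
    """
    covariate = covariate or spec.covariate
    use_cols = [trait, "litter_id"] + ([covariate] if covariate else [])
    mask = cohort[use_cols].notna().all(axis=1)
    df = cohort.loc[mask]
    if df.empty:
        raise ValueError(f"no complete observations for trait {trait!r}")
    if df["litter_id"].nunique() < 2 and spec.random_litter:
        raise DegenerateDesignError("mixed adjustment needs >= 2 litters")
    formula = _patsy_formula(trait, spec.fixed_terms, covariate)

    mixed = spec.random_litter
    resid = var_litter = var_resid = None
    if mixed:
        try:
            result = _fit_mixed(df, formula)
            var_litter = float(np.asarray(result.cov_re).ravel()[0])
            var_resid = float(result.scale)
            if not np.isfinite(var_litter) or var_litter <= _BOUNDARY_FRACTION * var_resid:
                raise _BoundaryFit
            blup = pd.Series({g: float(np.asarray(v).ravel()[0])
                              for g, v in result.random_effects.items()})
            # fixed-effect prediction only (fittedvalues already adds BLUPs)
            fixed_pred = pd.Series(result.model.exog @ result.fe_params,
                                   index=df.index)
            resid = df[trait] - fixed_pred - df["litter_id"].map(blup)
        except (_BoundaryFit, np.linalg.LinAlgError, ValueError):
            warnings.warn(
                f"litter variance at boundary for {trait!r}; "
                "falling back to fixed-effects-only adjustment")
            mixed = False
    if not mixed:
        ols = smf.ols(formula, data=df).fit()
        resid = ols.resid
        var_litter = 0.0
        var_resid = float(ols.mse_resid)

    resid = resid - resid.mean()
    full = pd.Series(np.nan, index=cohort.index, name=name or f"adj_{trait}")
    full.loc[resid.index] = resid
    return AdjustedTrait(trait=trait, residuals=full,
                         spec=ModelSpec(spec.fixed_terms, spec.random_litter,
                                        covariate, spec.dropped),
                         var_litter=var_litter, var_residual=var_resid,
                         n=int(mask.sum()), mixed=mixed)


class _BoundaryFit(Exception):
    pass


def adjust_cohort(cohort: pd.DataFrame, traits: Sequence[str],
                  candidates: Iterable[str] = DEFAULT_CANDIDATES,
                  alpha: float = 0.05,
                  covariate_traits: Sequence[str] = (),
                  covariate: str = "bw_wk16",
                  select: bool = True) -> tuple[pd.DataFrame, list[AdjustedTrait]]:
    """Adjust a list of traits; returns the cohort with ``adj_*`` columns.

    Traits named in ``covariate_traits`` additionally include the body-weight
    covariate (their residuals are the "adjusted" trait variants).  With
    ``select=False`` all candidate terms are retained unconditionally.
    """
    out = cohort.copy()
    fits: list[AdjustedTrait] = []
    for trait in traits:
        spec = (select_fixed_effects(cohort, trait, candidates, alpha)
                if select else ModelSpec(fixed_terms=tuple(candidates)))
        cov = covariate if trait in covariate_traits else None
        fit = adjust_trait(cohort, trait, spec, covariate=cov)
        out[fit.residuals.name] = fit.residuals
        fits.append(fit)
    return out, fits


def fit_report(fits: Sequence[AdjustedTrait]) -> pd.DataFrame:
    """Tidy per-trait adjustment report (terms, variance components, n)."""
    return pd.DataFrame([{
        "trait": f.trait,
        "fixed_terms": "+".join(f.spec.fixed_terms) or "intercept",
        "covariate": f.spec.covariate or "",
        "var_litter": f.var_litter,
        "var_residual": f.var_residual,
        "n": f.n,
        "mixed": f.mixed,
        "dropped": ";".join(f"{t}(P={p:.3g})" for t, p in f.spec.dropped),
    } for f in fits])
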