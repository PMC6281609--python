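"""Quantitative complementation test.

In a four-way cross segregating a knockout allele and a QTL allele on a
uniform background, a significant knockout-by-QTL interaction in a two-way
factorial ANOVA ("failure to complement") is genetic evidence that the
knocked-out locus and the QTL are the same; a non-significant interaction
("complementation") indicates distinct loci.  Sums of squares are marginal
(Type III via sum-to-zero contrasts) so unbalanced cells are handled, and a
MANOVA screen for a three-way allele-by-allele-by-sex interaction decides
per trait group whether the sexes may be pooled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .group_tests import manova, significance_summary

FAILURE_TO_COMPLEMENT = "failure_to_complement"
COMPLEMENT = "complement"

_INTERPRETATION = {
    FAILURE_TO_COMPLEMENT: "locus identical to QTL",
    COMPLEMENT: "locus distinct from QTL",
}


@dataclass
class InteractionTestResult:
    trait: str
    terms: pd.DataFrame      # index term: f_value, df, p_value
    lsmeans: pd.DataFrame    # index (ko, qtl): mean, se, n
    n: int

    @property
    def interaction_p(self) -> float:
        return float(self.terms.loc["ko:qtl", "p_value"])


@dataclass
class ComplementationCall:
    label: str
    marginal: bool
    interaction_p: float
    alpha: float
    marginal_band: float

    @property
    def interpretation(self) -> str:
        return _INTERPRETATION[self.label]


def interaction_test(cohort: pd.DataFrame, trait: str,
                     include_sex: bool = False) -> InteractionTestResult:
    """Two-way factorial ANOVA of a trait on the KO and QTL alleles.

    Fits ``trait ~ KO * QTL`` (optionally crossed with sex) on the supplied
    values — normally mixed-model-adjusted residuals — with sum-to-zero
    contrasts, and reports marginal (Type III) F tests for every term plus
    least-squares means for the four genotype cells (averaged over sex when
    included).
    """
    df = cohort.dropna(subset=[trait, "ko_allele", "qtl_allele"]).copy()
    cells = df.groupby(["ko_allele", "qtl_allele"], observed=True).size()
    if len(cells) < 4 or (cells < 1).any():
        raise ValueError("interaction inestimable: empty genotype cell")
    df["ko"] = df["ko_allele"]
    df["qtl"] = df["qtl_allele"]
    rhs = "C(ko, Sum) * C(qtl, Sum)"
    if include_sex:
        rhs += " * C(sex, Sum)"
    formula = f"Q('{trait}') ~ {rhs}"
    fit = smf.ols(formula, data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = sm.stats.anova_lm(fit, typ=3)
    terms = table.drop(index=[i for i in ("Intercept", "Residual")
                              if i in table.index])
    terms = terms.rename(index=_plain_term_name)
    terms = pd.DataFrame({"sum_sq": terms["sum_sq"], "df": terms["df"],
                          "f_value": terms["F"], "p_value": terms["PR(>F)"]})
    lsmeans = _cell_lsmeans(fit, df, trait, include_sex)
    return InteractionTestResult(trait, terms, lsmeans, len(df))


def _plain_term_name(name: str) -> str:
    return (name.replace("C(ko, Sum)", "ko")
                .replace("C(qtl, Sum)", "qtl")
                .replace("C(sex, Sum)", "sex"))


def _cell_lsmeans(fit, df: pd.DataFrame, trait: str,
                  include_sex: bool) -> pd.DataFrame:
    """LS mean +- SE for each allele cell, averaging evenly over sex levels."""
    design_info = fit.model.data.design_info
    kos = sorted(df["ko"].unique())
    qtls = sorted(df["qtl"].unique())
    sexes = sorted(df["sex"].unique()) if include_sex else [None]
    cov = fit.cov_params().to_numpy()
    rows = []
    for ko in kos:
        for qtl in qtls:
            grid = pd.DataFrame([{"ko": ko, "qtl": qtl, "sex": s}
                                 for s in sexes])
            X = np.asarray(patsy.build_design_matrices([design_info], grid)[0])
            x = X.mean(axis=0)
            mean = float(x @ fit.params.to_numpy())
            se = float(np.sqrt(x @ cov @ x))
            n = int(((df["ko"] == ko) & (df["qtl"] == qtl)).sum())
            rows.append((ko, qtl, mean, se, n))
    return pd.DataFrame(rows, columns=["ko", "qtl", "mean", "se", "n"]
                        ).set_index(["ko", "qtl"])


def classify_complementation(result: InteractionTestResult | float,
                             alpha: float = 0.05,
                             marginal_band: float = 0.10) -> ComplementationCall:
    """Call complementation from the interaction P value.

    ``failure_to_complement`` iff P < alpha (the two loci behave as one);
    otherwise ``complement``, flagged marginal when alpha <= P <=
    marginal_band.
    """
    p = result if isinstance(result, float) else result.interaction_p
    if not 0.0 <= p <= 1.0:
        raise ValueError("interaction P must lie in [0, 1]")
    if p < alpha:
        return ComplementationCall(FAILURE_TO_COMPLEMENT, False, p,
                                   alpha, marginal_band)
    return ComplementationCall(COMPLEMENT, p <= marginal_band, p,
                               alpha, marginal_band)


def sex_pooling_decision(cohort: pd.DataFrame,
                         trait_groups: dict[str, list[str]],
                         alpha: float = 0.05) -> pd.Series:
    """Decide per trait group whether the sexes can be pooled.

    Runs MANOVA with the full KO x QTL x sex factorial per trait group and
    returns ``pool=True`` where the three-way interaction is non-significant
    on every one of the four multivariate statistics.  A single-sex cohort
    pools trivially (with a warning).
    """
    if cohort["sex"].nunique() < 2:
        warnings.warn("single-sex cohort: sex pooling is trivially allowed")
        return pd.Series({g: True for g in trait_groups}, name="pool")
    factors = cohort[["ko_allele", "qtl_allele", "sex"]].rename(
        columns={"ko_allele": "ko", "qtl_allele": "qtl"})
    out = {}
    for group, traits in trait_groups.items():
        res = manova(cohort[list(traits)], factors,
                     "C(ko) * C(qtl) * C(sex)")
        term = next(t for t in res.tables
                    if set(t.replace("C(", "").replace(")", "").split(":"))
                    == {"ko", "qtl", "sex"})
        flags = significance_summary(res, alpha)
        out[group] = not bool(flags.loc[term, "significant_any_statistic"])
    return pd.Series(out, name="pool")


def complementation_report(results: list[InteractionTestResult],
                           alpha: float = 0.05,
                           marginal_band: float = 0.10) -> pd.DataFrame:
    """One row per trait: term F/P, cell LS means, call and marginal flag."""
    rows = []
    for r in results:
        call = classify_complementation(r, alpha, marginal_band)
        row = {"trait": r.trait, "n": r.n}
        for term in ("ko", "qtl", "ko:qtl"):
            row[f"F_{term}"] = r.terms.loc[term, "f_value"]
            row[f"P_{term}"] = r.terms.loc[term, "p_value"]
        for (ko, qtl), cell in r.lsmeans.iterrows():
            row[f"lsmean_{ko}/{qtl}"] = cell["mean"]
            row[f"se_{ko}/{qtl}"] = cell["se"]
        row["call"] = call.label
        row["marginal"] = call.marginal
        row["interpretation"] = call.interpretation
        rows.append(row)
    return pd.DataFrame(rows)
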