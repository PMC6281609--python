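"""Causal inference test (CIT) for genotype -> expression -> trait mediation.

Four conditional-regression component tests decide whether variation in a
quantitative trait T is caused by genotype G via the expression E of a
candidate gene:

* Test 1 — G is associated with T (coefficient of G in ``T ~ G``);
* Test 2 — G is associated with E given T (coefficient of G in ``E ~ G + T``);
* Test 3 — E is associated with T given G (coefficient of E in ``T ~ E + G``);
* Test 4 — G is independent of T given E (coefficient of G in ``T ~ E + G``
  is *non*-significant).

The causal (G -> E -> T) call requires the first three to be significant and
the fourth not; a Test 3 P value inside a marginal band yields a marginal
causal call.  Test 4's accept-the-null logic is the conventional reading of
independence here and carries the usual caveat that low power favours a
causal call.  Genotype is coded numerically (0/1 for the two-genotype
design); inputs are normally litter-adjusted residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CAUSAL = "causal"
CAUSAL_MARGINAL = "causal_marginal"
NOT_CAUSAL = "not_causal"

_COLLINEAR_TOL = 1e-9


@dataclass
class CitComponents:
    p1: float
    p2: float
    p3: float
    p4: float
    p_expression: float  # unconditional E ~ G association, for reporting


@dataclass
class CitResult:
    trait: str
    components: CitComponents
    r_squared: float
    slope_sign: int
    label: str
    alpha: float
    marginal_band: float


def _coef_pvalues(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided t-test P value for every coefficient of an OLS fit."""
    n, p = X.shape
    if n <= p:
        raise ValueError("too few observations for the design")
    xtx = X.T @ X
    if np.linalg.cond(xtx) > 1.0 / _COLLINEAR_TOL:
        raise ValueError("collinear design matrix")
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / (n - p)
    if sigma2 <= 0:
        raise ValueError("degenerate fit: zero residual variance")
    se = np.sqrt(sigma2 * np.diag(np.linalg.inv(xtx)))
    t = beta / se
    return 2.0 * stats.t.sf(np.abs(t), df=n - p)


def _validate(G, E, T):
    G = np.asarray(G, dtype=float)
    E = np.asarray(E, dtype=float)
    T = np.asarray(T, dtype=float)
    if not (len(G) == len(E) == len(T)):
        raise ValueError("G, E, T must be aligned")
    if np.isnan(np.concatenate([G, E, T])).any():
        raise ValueError("missing values in the (G, E, T) triples")
    levels, counts = np.unique(G, return_counts=True)
    if len(levels) < 2:
        raise ValueError("genotype must have at least two levels")
    if len(levels) > 2:
        raise ValueError(
            "more than two genotype levels: supply a numeric coding for the "
            "contrast of interest (the test is defined for a 0/1 design)")
    if counts.min() < 3:
        raise ValueError("need at least 3 animals per genotype level")
    for name, v in (("E", E), ("T", T)):
        if np.std(v) < 1e-12 * max(1.0, np.abs(v).mean()):
            raise ValueError(f"degenerate fit: {name} is constant")
    return G, E, T


def cit_component_tests(G, E, T) -> CitComponents:
    """Compute the four component P values plus the unconditional E ~ G P.

    Tests 3 and 4 come from coefficients of the same fitted model
    ``T ~ E + G``.  Raises on constant inputs or a collinear design (e.g. T
    duplicating E).
    """
    G, E, T = _validate(G, E, T)
    if abs(np.corrcoef(E, T)[0, 1]) > 1 - _COLLINEAR_TOL:
        raise ValueError("collinear design matrix: T duplicates E")
    one = np.ones_like(G)
    p1 = _coef_pvalues(np.column_stack([one, G]), T)[1]
    p2 = _coef_pvalues(np.column_stack([one, G, T]), E)[1]
    p34 = _coef_pvalues(np.column_stack([one, E, G]), T)
    p_expr = _coef_pvalues(np.column_stack([one, G]), E)[1]
    return CitComponents(float(p1), float(p2), float(p34[1]), float(p34[2]),
                         float(p_expr))


def classify_cit(p1: float, p2: float, p3: float, p4: float,
                 alpha: float = 0.05,
                 marginal_band: float = 0.10) -> str:
    """Causal classification from the four component P values.

    ``causal`` iff p1, p2, p3 < alpha and p4 >= alpha; ``causal_marginal``
    when only Test 3 sits in [alpha, marginal_band]; otherwise
    ``not_causal``.
    """
    for p in (p1, p2, p3, p4):
        if not 0.0 <= p <= 1.0:
            raise ValueError("P values must lie in [0, 1]")
    if p1 < alpha and p2 < alpha and p4 >= alpha:
        if p3 < alpha:
            return CAUSAL
        if alpha <= p3 <= marginal_band:
            return CAUSAL_MARGINAL
    return NOT_CAUSAL


def variance_explained(E, T) -> tuple[float, int]:
    """Fraction of trait variance explained by expression.

    Returns (R^2, sign of the regression slope); R^2 is the squared Pearson
    correlation, identical to simple-regression R^2.
    """
    E = np.asarray(E, dtype=float)
    T = np.asarray(T, dtype=float)
    if len(E) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(E) == 0 or np.std(T) == 0:
        raise ValueError("zero-variance input")
    r = float(np.corrcoef(E, T)[0, 1])
    return r * r, int(np.sign(r)) if r != 0 else 0


def cit_screen(data: pd.DataFrame, traits: list[str],
               genotype_col: str = "g", expression_col: str = "expression",
               alpha: float = 0.05,
               marginal_band: float = 0.10) -> pd.DataFrame:
    """Run the CIT over many traits; one row per trait, Table-style schema.

    ``data`` holds one animal per row with the numeric genotype code, the
    (litter-adjusted) expression value and the trait columns.  Traits whose
    values duplicate the expression vector are flagged degenerate, excluded
    with a warning.  Group means are reported with the pooled-SE convention
    of a least-squares fit.
    """
    rows = []
    G = data[genotype_col].to_numpy(float)
    E = data[expression_col].to_numpy(float)
    levels = np.unique(G)
    for trait in traits:
        T = data[trait].to_numpy(float)
        try:
            comp = cit_component_tests(G, E, T)
        except ValueError as exc:
            warnings.warn(f"trait {trait!r} excluded: {exc}")
            continue
        r2, sign = variance_explained(E, T)
        label = classify_cit(comp.p1, comp.p2, comp.p3, comp.p4,
                             alpha, marginal_band)
        row = {"trait": trait}
        # pooled residual SE per group, as a least-squares means table
        resid_ss = sum(((T[G == lv] - T[G == lv].mean()) ** 2).sum()
                       for lv in levels)
        mse = resid_ss / (len(T) - len(levels))
        for lv in levels:
            sel = G == lv
            row[f"n_g{lv:g}"] = int(sel.sum())
            row[f"mean_g{lv:g}"] = float(T[sel].mean())
            row[f"se_g{lv:g}"] = float(np.sqrt(mse / sel.sum()))
        row.update({"p1": comp.p1, "p2": comp.p2, "p3": comp.p3,
                    "p4": comp.p4, "p_expression": comp.p_expression,
                    "r_squared": r2, "slope_sign": sign, "label": label})
        rows.append(row)
    return pd.DataFrame(rows)
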