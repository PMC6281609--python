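"""Group comparison machinery: one-way ANOVA, Tukey HSD letters, MANOVA.

These are the shared statistics behind the F2 qualitative analyses and the
MANOVA screens of the complementation study: per-trait one-way ANOVA with
least-squares group means, all-pairs Tukey HSD with a compact letter display,
and per-trait-group MANOVA reporting the four classical multivariate
statistics.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.multivariate.manova import MANOVA


@dataclass
class OneWayResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    group_means: pd.DataFrame  # index group: mean, se, n
    ms_within: float


@dataclass
class TukeyResult:
    pairwise: pd.DataFrame     # columns: group1, group2, diff, q, p_value
    letters: dict[str, str]    # group -> letter string (shared letter = n.s.)
    alpha: float


@dataclass
class ManovaResult:
    tables: dict[str, pd.DataFrame]  # term -> four statistics with F, dfs, P
    n: int
    responses: tuple[str, ...]

    def p_values(self, term: str) -> pd.Series:
        return self.tables[term]["p_value"]


def _clean_groups(values, groups):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    keep = np.isfinite(values)
    values, groups = values[keep], groups[keep]
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if np.any(counts < 2):
        raise ValueError("every group needs at least two observations")
    return values, groups, labels, counts


def one_way_anova(values, groups) -> OneWayResult:
    """Classical one-way between/within decomposition.

    With a single factor and no covariates the least-squares group means are
    the raw group means; their standard errors use the pooled within-group
    mean square.  Identical values across all groups yield F = 0, P = 1.
    """
    values, groups, labels, counts = _clean_groups(values, groups)
    n, k = len(values), len(labels)
    grand = values.mean()
    means = np.array([values[groups == g].mean() for g in labels])
    ss_between = float(np.sum(counts * (means - grand) ** 2))
    ss_within = float(sum(np.sum((values[groups == g] - m) ** 2)
                          for g, m in zip(labels, means)))
    df_b, df_w = k - 1, n - k
    ms_w = ss_within / df_w
    if ms_w == 0.0:
        f = 0.0 if ss_between <= 1e-300 else np.inf
        p = 1.0 if f == 0.0 else 0.0
    else:
        f = (ss_between / df_b) / ms_w
        p = float(stats.f.sf(f, df_b, df_w))
    gm = pd.DataFrame({"mean": means,
                       "se": np.sqrt(ms_w / counts) if ms_w > 0 else 0.0,
                       "n": counts}, index=pd.Index(labels, name="group"))
    return OneWayResult(float(f), df_b, df_w, p, gm, ms_w)


def tukey_hsd(values, groups, alpha: float = 0.05) -> TukeyResult:
    """All-pairs Tukey HSD with Tukey–Kramer adjustment for unequal n.

    Pairwise P values come from the studentized range distribution with the
    pooled within-group variance; letters are assigned by the insert-and-
    absorb algorithm so that two groups share a letter iff their pairwise
    P >= alpha.
    """
    anova = one_way_anova(values, groups)
    labels = list(anova.group_means.index)
    means = anova.group_means["mean"]
    ns = anova.group_means["n"]
    k, df_w, ms_w = len(labels), anova.df_within, anova.ms_within
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            g1, g2 = labels[i], labels[j]
            diff = means[g2] - means[g1]
            se = np.sqrt(ms_w / 2.0 * (1.0 / ns[g1] + 1.0 / ns[g2]))
            if se == 0.0:
                q = 0.0 if diff == 0 else np.inf
            else:
                q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, df_w)) if np.isfinite(q) else 0.0
            rows.append((g1, g2, float(diff), float(q), min(max(p, 0.0), 1.0)))
    pairwise = pd.DataFrame(rows, columns=["group1", "group2", "diff", "q",
                                           "p_value"])
    letters = _letter_display(labels, means, pairwise, alpha)
    return TukeyResult(pairwise, letters, alpha)


def _letter_display(labels, means, pairwise, alpha) -> dict[str, str]:
    """Compact letter display via insert-and-absorb.

    Start with one letter set holding every group; for each significantly
    different pair found in both members of a set, split the set in two (one
    without each member); absorb sets contained in others; letter the sets
    in order of mean.
    """
    order = sorted(labels, key=lambda g: means[g])
    sets: list[set] = [set(order)]
    sig_pairs = [(r.group1, r.group2) for r in pairwise.itertuples()
                 if r.p_value < alpha]
    for a, b in sig_pairs:
        new_sets = []
        for s in sets:
            if a in s and b in s:
                new_sets.extend([s - {a}, s - {b}])
            else:
                new_sets.append(s)
        # absorb: drop sets contained in another
        sets = [s for s in new_sets
                if s and not any(s < t for t in new_sets)]
        # deduplicate
        uniq = []
        for s in sets:
            if s not in uniq:
                uniq.append(s)
        sets = uniq
    sets.sort(key=lambda s: min(means[g] for g in s))
    letters = {g: "" for g in labels}
    for letter, s in zip(string.ascii_lowercase, sets):
        for g in s:
            letters[g] += letter
    return {g: "".join(sorted(v)) for g, v in letters.items()}


_STAT_NAMES = {
    "Wilks' lambda": "wilks_lambda",
    "Pillai's trace": "pillai_trace",
    "Hotelling-Lawley trace": "hotelling_lawley",
    "Roy's greatest root": "roys_root",
}


def manova(trait_matrix: pd.DataFrame, factors: pd.DataFrame,
           formula_rhs: str) -> ManovaResult:
    """MANOVA of several responses on a factor model.

    ``formula_rhs`` is the right-hand side (e.g. ``"C(genotype) * C(sex)"``).
    Rows with any missing response or factor are dropped (complete-case per
    trait group).  Reports Wilks' lambda, Pillai's trace, the
    Hotelling–Lawley trace and Roy's greatest root per term with their
    standard F approximations (Roy's as an upper bound).
    """
    responses = list(trait_matrix.columns)
    data = pd.concat([trait_matrix, factors], axis=1).dropna()
    n = len(data)
    if n <= len(responses) + 1:
        raise ValueError("too few complete cases for the number of responses")
    ren = {c: f"resp_{i}" for i, c in enumerate(responses)}
    data = data.rename(columns=ren)
    lhs = " + ".join(ren.values())
    if len(responses) == 1:
        return _manova_single(data, lhs, formula_rhs, n, responses)
    resp = data[list(ren.values())].to_numpy(float)
    centered = resp - resp.mean(axis=0)
    if np.linalg.matrix_rank(centered) < resp.shape[1]:
        raise ValueError(
            "singular error SSCP matrix; collinear responses: "
            f"{_collinear_responses(trait_matrix)}")
    try:
        fit = MANOVA.from_formula(f"{lhs} ~ {formula_rhs}", data=data)
        res = fit.mv_test()
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular error SSCP matrix; collinear responses: "
            f"{_collinear_responses(trait_matrix)}") from exc
    tables = {}
    for term in res.results:
        stat = res.results[term]["stat"]
        rows = []
        for raw, name in _STAT_NAMES.items():
            r = stat.loc[raw]
            rows.append((name, float(r["Value"]), float(r["F Value"]),
                         float(r["Num DF"]), float(r["Den DF"]),
                         float(r["Pr > F"])))
        tables[term] = pd.DataFrame(
            rows, columns=["statistic", "value", "f_value", "df_num",
                           "df_den", "p_value"]).set_index("statistic")
    return ManovaResult(tables, n, tuple(responses))


def _manova_single(data, lhs, formula_rhs, n, responses) -> ManovaResult:
    """Single-response reduction: every multivariate statistic collapses to
    the univariate F test of the term's coefficient block.

    With one response the single eigenvalue is lam = SSH/SSE, so Wilks =
    1/(1+lam), Pillai = lam/(1+lam), Hotelling-Lawley = Roy = lam, and all
    four share the ANOVA F and P exactly.
    """
    import statsmodels.formula.api as smf

    fit = smf.ols(f"{lhs} ~ {formula_rhs}", data=data).fit()
    design_info = fit.model.data.design_info
    tables = {}
    for term, sl in design_info.term_name_slices.items():
        L = np.zeros((sl.stop - sl.start, len(fit.params)))
        for i, j in enumerate(range(sl.start, sl.stop)):
            L[i, j] = 1.0
        wt = fit.wald_test(L, use_f=True, scalar=True)
        f_val = float(wt.statistic)
        dfn, dfd = float(wt.df_num), float(wt.df_denom)
        p = float(wt.pvalue)
        lam = f_val * dfn / dfd
        values = {"wilks_lambda": 1.0 / (1.0 + lam),
                  "pillai_trace": lam / (1.0 + lam),
                  "hotelling_lawley": lam,
                  "roys_root": lam}
        tables[term] = pd.DataFrame(
            [(name, val, f_val, dfn, dfd, p) for name, val in values.items()],
            columns=["statistic", "value", "f_value", "df_num", "df_den",
                     "p_value"]).set_index("statistic")
    return ManovaResult(tables, n, tuple(responses))


def _collinear_responses(trait_matrix: pd.DataFrame) -> list[str]:
    corr = trait_matrix.corr().abs()
    pairs = []
    cols = corr.columns
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if corr.iloc[i, j] > 1 - 1e-10:
                pairs.append(f"{cols[i]}~{cols[j]}")
    return pairs or ["(rank deficiency not due to a response pair)"]


def significance_summary(result: ManovaResult, alpha: float = 0.05) -> pd.DataFrame:
    """Per-term flags: any of the four statistics significant / all four.

    The permissive "any" reading corresponds to calling a term significant
    when at least Roy's greatest root (the most liberal statistic) crosses
    alpha.
    """
    rows = []
    for term, tab in result.tables.items():
        p = tab["p_value"]
        rows.append({"term": term,
                     "significant_any_statistic": bool((p < alpha).any()),
                     "significant_all_statistics": bool((p < alpha).all())})
    return pd.DataFrame(rows).set_index("term")
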