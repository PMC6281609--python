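"""End-to-end study orchestration.

Three studies, each reproducible from a :class:`RunConfig` and a seed:

* the quantitative complementation study on a four-way cross (mixed-model
  residualization, sex-pooling MANOVA screen, per-trait-group MANOVA,
  per-trait two-way interaction tests and complementation calls);
* the F2 qualitative phenotypic study (per-group MANOVA, per-trait one-way
  ANOVA with Tukey HSD letters);
* the causal (CIT) study on the two-genotype male F2 subset (Ct panel ->
  2^-ddCt -> litter residualization -> four component tests per trait).

Every run writes tidy TSV tables plus a manifest (config hash, seed,
version) sufficient to reproduce the outputs bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .adjust import adjust_trait, fit_report, select_fixed_effects
from .adjust import derive_traits
from .cit import cit_screen, variance_explained
from .complementation import (complementation_report, interaction_test,
                              sex_pooling_decision)
from .designs import CrossDesign, MediationModel, ModelSpec, QpcrParams
from .group_tests import manova, one_way_anova, significance_summary, tukey_hsd
from .qpcr import delta_delta_ct, group_summary
from .simulate import (EXPRESSION_FLOOR, simulate_ct_panel,
                       simulate_f2_intercross, simulate_four_way_cross)

#: trait-group scheme: composite totals and the male-only trait are kept out
#: of the multivariate groups (they are tested per trait only)
BASE_TRAIT_GROUPS: dict[str, list[str]] = {
    "body_weight": [f"bw_wk{a}" for a in (1, 3, 6, 10, 13, 16)],
    "body_weight_gain": ["gain_1_3", "gain_3_6", "gain_6_10",
                         "gain_10_13", "gain_13_16"],
    "body_length": ["tail_length", "head_body_length"],
    "organ_weight": ["liver", "kidney", "heart", "lung", "spleen"],
    "fat_weight": ["inguinal_fat", "gonadal_fat", "perirenal_fat"],
}
#: groups 6-8 are the body-weight-adjusted variants of lengths/organs/fat
ADJUSTED_GROUPS = ("body_length", "organ_weight", "fat_weight")

#: the 20 fat and organ traits entering the causal screen (10 raw + 10
#: body-weight-adjusted)
CIT_TRAITS = ["total_fat", "inguinal_fat", "gonadal_fat", "perirenal_fat",
              "liver", "kidney", "heart", "lung", "spleen", "testis"]


@dataclass
class RunConfig:
    """Parameters of one pipeline run."""

    design_four_way: CrossDesign = field(default_factory=CrossDesign.four_way)
    design_f2: CrossDesign = field(default_factory=CrossDesign.f2)
    model: MediationModel = field(default_factory=MediationModel)
    qpcr: QpcrParams = field(default_factory=QpcrParams)
    alpha: float = 0.05
    marginal_band: float = 0.10
    seed: int = 0
    outdir: Optional[str] = None
    calibration: str = "group_mean"
    calibrator_group: str = "KO/B6J"
    n_cit_per_group: int = 12
    dissection_covariate: str = "bw_wk16"
    select_fixed: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, typ in (("design_four_way", CrossDesign),
                         ("design_f2", CrossDesign),
                         ("model", MediationModel),
                         ("qpcr", QpcrParams)):
            if key in d and isinstance(d[key], dict):
                sub = {k: tuple(v) if isinstance(v, list) else v
                       for k, v in d[key].items()}
                d[key] = typ(**sub)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_listify(self.to_dict()), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(_listify(self.to_dict()), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    if isinstance(obj, list):
        return [_listify(v) for v in obj]
    return obj


def _write(outdir: Optional[str], name: str, df: pd.DataFrame) -> None:
    if outdir is None:
        return
    path = Path(outdir)
    path.mkdir(parents=True, exist_ok=True)
    df.to_csv(path / name, sep="\t", index=False, float_format="%.10g")


def _manifest(config: RunConfig, study: str, tables: list[str]) -> dict:
    return {"study": study, "seed": config.seed,
            "config_hash": config.config_hash,
            "package_version": __version__, "tables": tables}


def _write_manifest(outdir: Optional[str], manifest: dict) -> None:
    if outdir is None:
        return
    with open(Path(outdir) / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def residualize_cohort(cohort: pd.DataFrame, config: RunConfig,
                       groups: dict[str, list[str]] = BASE_TRAIT_GROUPS,
                       extra_traits: tuple[str, ...] = ("total_fat",
                                                        "total_length")):
    """Residualize every analysis trait; returns (cohort, groups, fits).

    Each trait is residualized on its selected fixed effects plus the litter
    random intercept (``res_`` columns); length, organ and fat traits get a
    second, body-weight-covariate-adjusted variant (``adj_`` columns) using
    the same final model, forming trait groups 6-8.
    """
    out = cohort.copy()
    fits = []
    full_groups: dict[str, list[str]] = {}
    covariate_traits = {t for g in ADJUSTED_GROUPS for t in groups[g]}
    covariate_traits |= {"total_fat", "total_length"}
    all_traits = sorted({t for ts in groups.values() for t in ts}
                        | set(extra_traits))
    res_name = {}
    for trait in all_traits:
        if config.select_fixed:
            spec = select_fixed_effects(out, trait, alpha=config.alpha)
        else:
            spec = ModelSpec(fixed_terms=())
        fit = adjust_trait(out, trait, spec, name=f"res_{trait}")
        out[fit.residuals.name] = fit.residuals
        fits.append(fit)
        res_name[trait] = fit.residuals.name
        if trait in covariate_traits:
            fit2 = adjust_trait(out, trait, spec,
                                covariate=config.dissection_covariate,
                                name=f"adj_{trait}")
            out[fit2.residuals.name] = fit2.residuals
            fits.append(fit2)
    for gname, traits in groups.items():
        full_groups[gname] = [res_name[t] for t in traits]
    for gname in ADJUSTED_GROUPS:
        full_groups[f"adjusted_{gname}"] = [f"adj_{t}" for t in groups[gname]]
    return out, full_groups, fits


def run_complementation_study(config: RunConfig) -> dict:
    """Four-way-cross complementation study, start to finish."""
    cohort = simulate_four_way_cross(config.design_four_way, config.model,
                                     config.seed)
    cohort = derive_traits(cohort)
    cohort, trait_groups, fits = residualize_cohort(cohort, config)

    pooling = sex_pooling_decision(cohort, trait_groups, config.alpha)

    manova_rows = []
    for gname, traits in trait_groups.items():
        rhs = ("C(ko) * C(qtl)" if pooling[gname]
               else "C(ko) * C(qtl) * C(sex)")
        factors = cohort[["ko_allele", "qtl_allele", "sex"]].rename(
            columns={"ko_allele": "ko", "qtl_allele": "qtl"})
        res = manova(cohort[traits], factors, rhs)
        flags = significance_summary(res, config.alpha)
        for term, tab in res.tables.items():
            if term == "Intercept":
                continue
            for statname, r in tab.iterrows():
                manova_rows.append({
                    "trait_group": gname, "term": term, "statistic": statname,
                    "value": r["value"], "f_value": r["f_value"],
                    "df_num": r["df_num"], "df_den": r["df_den"],
                    "p_value": r["p_value"],
                    "significant_any":
                        flags.loc[term, "significant_any_statistic"],
                    "significant_all":
                        flags.loc[term, "significant_all_statistics"]})
    manova_table = pd.DataFrame(manova_rows)

    per_trait = []
    for gname, traits in trait_groups.items():
        for trait in traits:
            per_trait.append(interaction_test(
                cohort, trait, include_sex=not pooling[gname]))
    # composite totals are tested per trait even though they sit outside the
    # multivariate groups
    for trait, gname in (("res_total_fat", "fat_weight"),
                         ("adj_total_fat", "adjusted_fat_weight"),
                         ("res_total_length", "body_length"),
                         ("adj_total_length", "adjusted_body_length")):
        if trait in cohort.columns:
            per_trait.append(interaction_test(
                cohort, trait, include_sex=not pooling[gname]))
    calls = complementation_report(per_trait, config.alpha,
                                   config.marginal_band)

    report = fit_report(fits)
    _write(config.outdir, "sex_pooling.tsv",
           pooling.rename_axis("trait_group").reset_index())
    _write(config.outdir, "manova.tsv", manova_table)
    _write(config.outdir, "interaction_tests.tsv", calls)
    _write(config.outdir, "adjustment_report.tsv", report)
    manifest = _manifest(config, "complementation",
                         ["sex_pooling.tsv", "manova.tsv",
                          "interaction_tests.tsv", "adjustment_report.tsv"])
    _write_manifest(config.outdir, manifest)
    return {"cohort": cohort, "pooling": pooling, "manova": manova_table,
            "calls": calls, "adjustment": report, "manifest": manifest}


def run_intercross_study(config: RunConfig) -> dict:
    """F2 qualitative phenotypic study: MANOVA, one-way ANOVA, Tukey letters."""
    cohort = simulate_f2_intercross(config.design_f2, config.model,
                                    config.seed)
    cohort = derive_traits(cohort)
    cohort, trait_groups, fits = residualize_cohort(cohort, config)

    manova_rows, anova_rows = [], []
    for gname, traits in trait_groups.items():
        rhs = ("C(genotype) * C(sex)" if cohort["sex"].nunique() > 1
               else "C(genotype)")
        res = manova(cohort[traits], cohort[["genotype", "sex"]], rhs)
        flags = significance_summary(res, config.alpha)
        for term, tab in res.tables.items():
            if term == "Intercept":
                continue
            for statname, r in tab.iterrows():
                manova_rows.append({
                    "trait_group": gname, "term": term, "statistic": statname,
                    "value": r["value"], "f_value": r["f_value"],
                    "p_value": r["p_value"],
                    "significant_any":
                        flags.loc[term, "significant_any_statistic"]})
        for trait in traits:
            aov = one_way_anova(cohort[trait], cohort["genotype"])
            tuk = tukey_hsd(cohort[trait], cohort["genotype"], config.alpha)
            for g, row in aov.group_means.iterrows():
                anova_rows.append({
                    "trait_group": gname, "trait": trait, "genotype": g,
                    "lsmean": row["mean"], "se": row["se"], "n": row["n"],
                    "letters": tuk.letters[g],
                    "f_value": aov.f_statistic, "p_value": aov.p_value})
    manova_table = pd.DataFrame(manova_rows)
    anova_table = pd.DataFrame(anova_rows)

    _write(config.outdir, "manova.tsv", manova_table)
    _write(config.outdir, "anova_tukey.tsv", anova_table)
    _write(config.outdir, "adjustment_report.tsv", fit_report(fits))
    manifest = _manifest(config, "intercross",
                         ["manova.tsv", "anova_tukey.tsv",
                          "adjustment_report.tsv"])
    _write_manifest(config.outdir, manifest)
    return {"cohort": cohort, "manova": manova_table, "anova": anova_table,
            "manifest": manifest}


def run_cit_study(config: RunConfig) -> dict:
    """Causal study on the two-genotype male subset of the F2 intercross."""
    cohort = simulate_f2_intercross(config.design_f2, config.model,
                                    config.seed)
    cohort = derive_traits(cohort)
    males = cohort[cohort["sex"] == "M"]
    subset = pd.concat([
        males[males["genotype"] == "KO/B6J"].head(config.n_cit_per_group),
        males[males["genotype"] == "B6J/B6J"].head(config.n_cit_per_group),
    ]).copy()
    if subset["genotype"].value_counts().min() < 3:
        raise ValueError("too few males per genotype for the causal study; "
                         "increase design_f2.n_animals")
    subset["genotype_group"] = subset["genotype"]

    # qPCR detection floor: the instrument model needs positive expression
    subset["expression"] = subset["expression"].clip(lower=EXPRESSION_FLOOR)
    panel = simulate_ct_panel(subset, config.qpcr, config.seed + 1)
    rel = delta_delta_ct(panel, config.calibrator_group,
                         convention=config.calibration)
    expr_summary = group_summary(rel)
    subset = subset.merge(rel[["sample_id", "relative"]],
                          left_on="animal_id", right_on="sample_id")
    subset["g"] = (subset["genotype"] == "B6J/B6J").astype(int)

    # litter-adjusted inputs: expression and every trait residualized on the
    # litter random intercept (body-weight covariate for adjusted variants)
    spec = ModelSpec(fixed_terms=())
    subset["expr_resid"] = adjust_trait(subset, "relative", spec).residuals
    traits = []
    for t in CIT_TRAITS:
        subset[f"res_{t}"] = adjust_trait(subset, t, spec,
                                          name=f"res_{t}").residuals
        subset[f"adj_{t}"] = adjust_trait(
            subset, t, spec, covariate=config.dissection_covariate,
            name=f"adj_{t}").residuals
        traits += [f"res_{t}", f"adj_{t}"]
    table = cit_screen(subset, traits, genotype_col="g",
                       expression_col="expr_resid", alpha=config.alpha,
                       marginal_band=config.marginal_band)
    r2, sign = variance_explained(subset["expr_resid"],
                                  subset["adj_inguinal_fat"])

    _write(config.outdir, "cit_table.tsv", table)
    _write(config.outdir, "expression_summary.tsv",
           expr_summary.reset_index())
    manifest = _manifest(config, "cit",
                         ["cit_table.tsv", "expression_summary.tsv"])
    manifest["focal_r_squared"] = r2
    manifest["focal_slope_sign"] = sign
    _write_manifest(config.outdir, manifest)
    return {"subset": subset, "expression": rel,
            "expression_summary": expr_summary, "table": table,
            "focal_r_squared": r2, "focal_slope_sign": sign,
            "manifest": manifest}
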