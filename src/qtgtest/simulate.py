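"""Synthetic cohort generation.

Generates mouse cohorts with the genetic, covariate and mediation structure
the downstream analyses assume:

* a four-way cross in which a knockout (KO) allele and a QTL allele segregate
  independently, each 1:1, on a uniform background (the quantitative
  complementation design);
* an F2 intercross segregating one locus 1:2:1;
* the two-genotype, single-sex sampling design used for the causal inference
  test (heterozygous vs homozygous-wildtype males);
* simulated qPCR Ct panels, the inverse of the 2^-ddCt transform.

All randomness flows from one master seed through named
:class:`numpy.random.SeedSequence` sub-streams, so a pipeline is reproducible
end to end while individual stages remain independently perturbable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .designs import (
    BODY_WEIGHT_AGES,
    F2,
    FOUR_WAY,
    CrossDesign,
    MediationModel,
    QpcrParams,
)

FOCAL_TRAIT = "inguinal_fat"

#: qPCR detection floor (fold units): applied when preparing a cohort for Ct
#: simulation, since a knocked-out locus yields at most trace signal and the
#: log2 inverse transform needs strictly positive expression.
EXPRESSION_FLOOR = 0.02

# population body-weight curve on a high-fat regimen (grams at each age week)
_BW_BASE = {1: 5.2, 3: 12.0, 6: 20.5, 10: 25.5, 13: 28.5, 16: 32.0}
# additional grams for males at each age
_BW_SEX = {1: 0.2, 3: 0.8, 6: 2.0, 10: 3.0, 13: 3.5, 16: 4.0}
_BW_AGE_NOISE = 0.8   # grams, per-age measurement noise
_BW_SCALE_SD = 0.06   # relative SD of the animal-level growth scale

# non-focal traits: name -> (mean, sd, male shift, slope on body weight g/g)
_TRAIT_BASE = {
    "gonadal_fat": (1.77, 0.35, 0.10, 0.040),
    "perirenal_fat": (0.91, 0.18, 0.05, 0.020),
    "liver": (1.15, 0.13, 0.06, 0.020),
    "kidney": (0.37, 0.035, 0.02, 0.004),
    "heart": (0.119, 0.012, 0.004, 0.0012),
    "lung": (0.141, 0.012, 0.003, 0.0008),
    "spleen": (0.081, 0.017, 0.002, 0.0008),
    "testis": (0.21, 0.03, 0.0, 0.0),       # males only
    "total_length": (16.8, 0.5, 0.25, 0.030),  # cm
    "tail_length": (7.6, 0.3, 0.10, 0.012),    # cm
    "head_body_length": (9.3, 0.35, 0.15, 0.018),  # cm
}

_STREAMS = ("structure", "genotype", "bodyweight", "expression", "traits", "qpcr")


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _litter_structure(design: CrossDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Assign animals to litters; sizes uniform on the design's range.

    Litters are filled sequentially; the last litter used may be truncated and
    its realized size is what the litter_size covariate records.
    """
    lo, hi = design.litter_size_range
    sizes = rng.integers(lo, hi + 1, size=design.n_litters)
    while sizes.sum() < design.n_animals:
        # top up random litters below the cap so the configured litter count
        # can hold the cohort
        room = np.flatnonzero(sizes < hi)
        if len(room) == 0:
            raise ValueError("litters cannot hold n_animals; increase n_litters")
        take = min(len(room), design.n_animals - sizes.sum())
        sizes[rng.choice(room, size=take, replace=False)] += 1
    parities = rng.choice(list(design.parity_levels), size=design.n_litters)
    litter_id, parity = [], []
    for i, size in enumerate(sizes):
        take = min(size, design.n_animals - len(litter_id))
        litter_id += [i + 1] * take
        parity += [parities[i]] * take
        if len(litter_id) >= design.n_animals:
            break
    df = pd.DataFrame({"litter_id": litter_id, "parity": parity})
    df["litter_size"] = df.groupby("litter_id")["litter_id"].transform("size")
    df["sex"] = np.where(rng.random(design.n_animals) < design.sex_ratio, "M", "F")
    df.insert(0, "animal_id", np.arange(1, design.n_animals + 1))
    return df


def _body_weights(df: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    n = len(df)
    scale = 1.0 + _BW_SCALE_SD * rng.standard_normal(n)
    male = (df["sex"] == "M").to_numpy(float)
    for age in BODY_WEIGHT_AGES:
        w = (_BW_BASE[age] * scale + _BW_SEX[age] * male
             + _BW_AGE_NOISE * rng.standard_normal(n))
        df[f"bw_wk{age}"] = np.maximum(w, 0.5)
    return df


def _litter_effects(df: pd.DataFrame, sd: float,
                    rng: np.random.Generator) -> np.ndarray:
    """One N(0, sd) intercept per litter, broadcast to animals."""
    litters = df["litter_id"].unique()
    eff = pd.Series(sd * rng.standard_normal(len(litters)), index=litters)
    return df["litter_id"].map(eff).to_numpy()


def _covariate_shift(df: pd.DataFrame, model: MediationModel) -> np.ndarray:
    male = (df["sex"] == "M").to_numpy(float)
    bw16 = df["bw_wk16"].to_numpy()
    return (model.sex_effect * male
            + model.parity_effect * (df["parity"].to_numpy() - df["parity"].min())
            + model.litter_size_effect
            * (df["litter_size"].to_numpy() - df["litter_size"].mean())
            + model.bw_effect * (bw16 - bw16.mean()))


def _nonfocal_traits(df: pd.DataFrame, model: MediationModel,
                     rng: np.random.Generator) -> pd.DataFrame:
    male = (df["sex"] == "M").to_numpy(float)
    bw16 = df["bw_wk16"].to_numpy()
    litter_ratio = (model.sigma_litter / model.sigma_t) if model.sigma_t > 0 else 0.0
    for name, (mean, sd, sex_shift, slope) in _TRAIT_BASE.items():
        val = (mean + sex_shift * male + slope * (bw16 - bw16.mean())
               + _litter_effects(df, litter_ratio * sd, rng)
               + sd * rng.standard_normal(len(df)))
        if name == "testis":
            val = np.where(male == 1.0, val, np.nan)
        df[name] = np.maximum(val, 0.0)
    return df


def _expression_and_trait(df: pd.DataFrame, g_func: np.ndarray,
                          model: MediationModel,
                          rng_e: np.random.Generator,
                          rng_t: np.random.Generator) -> pd.DataFrame:
    """Generate (E, T) for the focal trait under the model's topology.

    ``g_func`` is the functional-allele dose per animal.
    """
    n = len(df)
    litter_e = _litter_effects(df, model.sigma_litter, rng_e)
    litter_t = _litter_effects(df, model.sigma_litter, rng_t)
    eps_e = model.sigma_e * rng_e.standard_normal(n)
    eps_t = model.sigma_t * rng_t.standard_normal(n)
    covar = _covariate_shift(df, model)

    if model.topology == "reactive":
        trait = model.mu_t + model.beta_gt * g_func + covar + litter_t + eps_t
        centre = model.mu_t + model.beta_gt * float(np.mean(g_func))
        expr = 1.0 + model.beta_et * (trait - centre) + litter_e + eps_e
    else:
        expr = model.mu_e + model.beta_ge * g_func + litter_e + eps_e
        if model.topology == "causal":
            trait = model.mu_t + model.beta_et * expr + covar + litter_t + eps_t
        elif model.topology == "independent":
            trait = model.mu_t + model.beta_gt * g_func + covar + litter_t + eps_t
        else:  # null
            trait = model.mu_t + covar + litter_t + eps_t

    df["expression"] = expr
    df[FOCAL_TRAIT] = np.maximum(trait, 0.0)
    return df


def simulate_four_way_cross(design: CrossDesign, model: MediationModel,
                            seed: int) -> pd.DataFrame:
    """Simulate the four-way complementation cohort.

    Each animal receives one allele at the KO locus (``KO`` or ``B6J``, each
    with probability 1/2) from one F1 parent and one allele at the QTL locus
    (``SR`` or ``B6JJcl``, each 1/2) from the other, independently.  The focal
    fat trait carries the model's KO/QTL/interaction cell effects plus litter
    and covariate structure; the reciprocal cross direction is recorded but
    has no simulated effect.
    """
    if design.kind != FOUR_WAY:
        raise ValueError("simulate_four_way_cross requires a four_way design")
    rngs = _rngs(seed)
    df = _litter_structure(design, rngs["structure"])
    g = rngs["genotype"]
    df["ko_allele"] = np.where(g.random(design.n_animals) < 0.5, "KO", "B6J")
    df["qtl_allele"] = np.where(g.random(design.n_animals) < 0.5, "SR", "B6JJcl")
    # direction of the reciprocal F1 x F1 mating, constant within litter
    direction = {lid: d for lid, d in zip(
        df["litter_id"].unique(),
        g.choice(["AxB", "BxA"], size=df["litter_id"].nunique()))}
    df["cross_direction"] = df["litter_id"].map(direction)
    df["genotype"] = df["ko_allele"] + "/" + df["qtl_allele"]
    df = _body_weights(df, rngs["bodyweight"])

    ko = (df["ko_allele"] == "KO").to_numpy(float)
    qtl = (df["qtl_allele"] == "SR").to_numpy(float)
    rng_t = rngs["traits"]
    trait = (model.mu_t + model.beta_ko * ko + model.beta_qtl * qtl
             + model.beta_koxqtl * ko * qtl
             + _covariate_shift(df, model)
             + _litter_effects(df, model.sigma_litter, rng_t)
             + model.sigma_t * rng_t.standard_normal(design.n_animals))
    df[FOCAL_TRAIT] = np.maximum(trait, 0.0)
    return _nonfocal_traits(df, model, rng_t)


def simulate_f2_intercross(design: CrossDesign, model: MediationModel,
                           seed: int) -> pd.DataFrame:
    """Simulate an F2 intercross segregating the KO locus 1:2:1.

    ``ko_copies`` counts knockout alleles (0, 1 or 2); the functional dose
    entering the mediation model is ``2 - ko_copies``.  Expression and the
    focal fat trait follow the model topology; all other traits carry litter
    and body-weight structure only.
    """
    if design.kind != F2:
        raise ValueError("simulate_f2_intercross requires an f2 design")
    rngs = _rngs(seed)
    df = _litter_structure(design, rngs["structure"])
    df["ko_copies"] = rngs["genotype"].choice(
        [0, 1, 2], size=design.n_animals, p=[0.25, 0.5, 0.25])
    df["genotype"] = df["ko_copies"].map(
        {2: "KO/KO", 1: "KO/B6J", 0: "B6J/B6J"})
    df = _body_weights(df, rngs["bodyweight"])
    g_func = (2 - df["ko_copies"]).to_numpy(float)
    df = _expression_and_trait(df, g_func, model,
                               rngs["expression"], rngs["traits"])
    return _nonfocal_traits(df, model, rngs["traits"])


def simulate_cit_input(model: MediationModel, seed: int,
                       n_per_group: int = 12) -> pd.DataFrame:
    """Simulate the two-genotype male sampling design of the causal analysis.

    Heterozygous (one functional copy) and homozygous-wildtype (two copies)
    males, ``n_per_group`` each, coded ``g = 0`` / ``g = 1``; littermate pairs
    share a litter.  Returns columns (animal_id, litter_id, genotype_group,
    g, expression, trait).
    """
    if n_per_group < 3:
        raise ValueError("need at least 3 animals per genotype group")
    rngs = _rngs(seed)
    n = 2 * n_per_group
    df = pd.DataFrame({
        "animal_id": np.arange(1, n + 1),
        # littermate pairs: one animal of each genotype per litter
        "litter_id": np.repeat(np.arange(1, n_per_group + 1), 2),
        "g": np.tile([0, 1], n_per_group),
    })
    df["genotype_group"] = df["g"].map({0: "KO/B6J", 1: "B6J/B6J"})
    df["sex"] = "M"
    g_func = (df["g"] + 1).to_numpy(float)  # functional copies: 1 or 2

    litter_e = _litter_effects(df, model.sigma_litter, rngs["expression"])
    litter_t = _litter_effects(df, model.sigma_litter, rngs["traits"])
    eps_e = model.sigma_e * rngs["expression"].standard_normal(n)
    eps_t = model.sigma_t * rngs["traits"].standard_normal(n)
    if model.topology == "reactive":
        trait = model.mu_t + model.beta_gt * g_func + litter_t + eps_t
        centre = model.mu_t + model.beta_gt * 1.5
        expr = 1.0 + model.beta_et * (trait - centre) + litter_e + eps_e
    else:
        expr = model.mu_e + model.beta_ge * g_func + litter_e + eps_e
        if model.topology == "causal":
            trait = model.mu_t + model.beta_et * expr + litter_t + eps_t
        elif model.topology == "independent":
            trait = model.mu_t + model.beta_gt * g_func + litter_t + eps_t
        else:
            trait = model.mu_t + litter_t + eps_t
    df["expression"] = expr
    df["trait"] = np.maximum(trait, 0.0)
    return df


def simulate_ct_panel(cohort: pd.DataFrame, qpcr: QpcrParams, seed: int,
                      sample_col: str = "animal_id",
                      group_col: str | None = "genotype_group",
                      tissue: str = "liver") -> pd.DataFrame:
    """Simulate a long-format Ct panel from true expression values.

    The target gene's expected Ct is ``target_baseline - log2(expression)``
    (doubling expression lowers Ct by one cycle); the endogenous control sits
    at a constant baseline.  Gaussian replicate noise with SD
    ``qpcr.replicate_sd`` is added to every well.
    """
    if "expression" not in cohort.columns:
        raise ValueError("cohort has no 'expression' column")
    expr = cohort["expression"].to_numpy(float)
    if np.any(~np.isfinite(expr)) or np.any(expr <= 0):
        raise ValueError("expression values must be finite and positive")
    rng = _rngs(seed)["qpcr"]
    groups = (cohort[group_col] if group_col and group_col in cohort.columns
              else pd.Series("all", index=cohort.index))
    rows = []
    for sample, group, e in zip(cohort[sample_col], groups, expr):
        for gene, base in (("target", qpcr.target_baseline - np.log2(e)),
                           ("control", qpcr.control_baseline)):
            for rep in range(1, qpcr.n_replicates + 1):
                rows.append((sample, group, tissue, gene, rep,
                             base + qpcr.replicate_sd * rng.standard_normal()))
    return pd.DataFrame(rows, columns=["sample_id", "genotype_group", "tissue",
                                       "gene", "replicate", "ct"])
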