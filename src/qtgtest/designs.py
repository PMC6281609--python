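"""Cross designs, generative mediation models and qPCR parameters.

These dataclasses parameterize the synthetic cohorts used throughout the
package: a four-way cross segregating a knockout (KO) allele and a QTL allele
on a uniform background, and an F2 intercross segregating a single locus
1:2:1.  The mediation model describes how genotype (G), a focal gene's
expression (E) and a focal trait (T, a fat-pad weight in grams) are related.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

FOUR_WAY = "four_way"
F2 = "f2"

#: ages (weeks) at which body weight is recorded
BODY_WEIGHT_AGES = (1, 3, 6, 10, 13, 16)

TOPOLOGIES = ("causal", "reactive", "independent", "null")


@dataclass(frozen=True)
class CrossDesign:
    """Structure of a mouse cross: cohort size, sexes, litters, parities.

    Parameters
    ----------
    kind:
        ``"four_way"`` (two loci, one allele pair segregating from each side)
        or ``"f2"`` (one locus, genotypes 1:2:1).
    n_animals:
        Cohort size. Defaults mirror the study designs: 352 for the four-way
        cross, 108 for the F2 intercross.
    sex_ratio:
        Probability an animal is male.
    n_litters:
        Number of litters; litter sizes are drawn uniformly from
        ``litter_size_range`` and litters are filled sequentially.
    parity_levels:
        Ordinal dam parities, assigned uniformly per litter.
    """

    kind: str = FOUR_WAY
    n_animals: int = 352
    sex_ratio: float = 0.5
    n_litters: int = 44
    parity_levels: Sequence[int] = (1, 2, 3)
    litter_size_range: tuple[int, int] = (4, 10)

    def __post_init__(self) -> None:
        if self.kind not in (FOUR_WAY, F2):
            raise ValueError(f"unknown cross kind {self.kind!r}")
        if self.n_animals <= 0:
            raise ValueError("n_animals must be positive")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be a fraction in [0, 1]")
        if self.n_litters <= 0:
            raise ValueError("n_litters must be positive")
        lo, hi = self.litter_size_range
        if lo <= 0 or hi < lo:
            raise ValueError("litter_size_range must be a positive interval")
        if hi * self.n_litters < self.n_animals:
            raise ValueError(
                "litter capacity (n_litters * max litter size) cannot hold "
                f"{self.n_animals} animals"
            )

    @classmethod
    def four_way(cls, **kw) -> "CrossDesign":
        kw.setdefault("n_animals", 352)
        kw.setdefault("n_litters", 44)
        return cls(kind=FOUR_WAY, **kw)

    @classmethod
    def f2(cls, **kw) -> "CrossDesign":
        kw.setdefault("n_animals", 108)
        kw.setdefault("n_litters", 14)
        return cls(kind=F2, **kw)


@dataclass(frozen=True)
class MediationModel:
    """Generative model linking genotype, expression and the focal fat trait.

    The genotype dose ``g`` entering the equations is the number of functional
    (non-knockout) alleles at the locus.  Under ``topology="causal"``::

        E = mu_e + beta_ge * g            + litter_E + Normal(0, sigma_e)
        T = mu_t + beta_et * E + covariates + litter_T + Normal(0, sigma_t)

    ``independent`` replaces the E term of T with a direct genotype effect
    ``beta_gt * g``; ``reactive`` generates T first and feeds it back into E
    (``beta_et`` then acts as the T->E coefficient); ``null`` sets every
    genetic effect to zero.  Litter random intercepts (SD ``sigma_litter``)
    are drawn independently for E and T.

    Defaults are calibrated so that, in the two-genotype comparison the causal
    analysis uses (one vs two functional copies), the expression ratio is
    about 2.1, the focal-trait group difference about 0.35 g, and the
    population R^2 of trait on expression about 0.29.

    The four-way-cross fields ``beta_ko``, ``beta_qtl`` and ``beta_koxqtl``
    are cell effects (grams) on the focal trait for carrying the KO allele,
    the QTL (wild-derived) allele, and their combination.
    """

    topology: str = "causal"
    beta_ge: float = 1.13     # fold units per functional allele copy
    beta_et: float = -0.31    # grams per fold unit (T->E coefficient if reactive)
    beta_gt: float = 0.0      # grams per functional allele copy (direct path)
    mu_e: float = -0.13       # fold units
    mu_t: float = 2.726       # grams (focal fat pad)
    sigma_e: float = 0.30
    sigma_t: float = 0.31
    sigma_litter: float = 0.10
    sex_effect: float = 0.20          # grams added for males, focal trait
    parity_effect: float = 0.0        # grams per parity level above the first
    litter_size_effect: float = -0.02  # grams per pup above the mean size
    bw_effect: float = 0.05           # grams of focal trait per gram body weight
    # four-way cross allele effects on the focal trait (grams)
    beta_ko: float = 0.0
    beta_qtl: float = 0.0
    beta_koxqtl: float = 0.0

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}")
        for name in ("sigma_e", "sigma_t", "sigma_litter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.topology == "null":
            if any((self.beta_ge, self.beta_et, self.beta_gt,
                    self.beta_ko, self.beta_qtl, self.beta_koxqtl)):
                raise ValueError("null topology requires all genetic effects = 0")
        if self.topology == "causal":
            if self.beta_gt != 0.0:
                raise ValueError("causal topology requires beta_gt = 0")
            if self.beta_ge == 0.0 or self.beta_et == 0.0:
                raise ValueError("causal topology requires beta_ge, beta_et != 0")

    @classmethod
    def causal(cls, **kw) -> "MediationModel":
        return cls(topology="causal", **kw)

    @classmethod
    def independent(cls, **kw) -> "MediationModel":
        kw.setdefault("beta_gt", -0.35)
        return cls(topology="independent", **kw)

    @classmethod
    def reactive(cls, **kw) -> "MediationModel":
        kw.setdefault("beta_gt", -0.35)
        kw.setdefault("beta_et", -0.9)
        return cls(topology="reactive", **kw)

    @classmethod
    def null(cls, **kw) -> "MediationModel":
        for name in ("beta_ge", "beta_et", "beta_gt",
                     "beta_ko", "beta_qtl", "beta_koxqtl"):
            kw.setdefault(name, 0.0)
        return cls(topology="null", **kw)

    def replace(self, **kw) -> "MediationModel":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class QpcrParams:
    """Instrument model for simulated Ct panels.

    Target-gene Ct is ``target_baseline - log2(expression) + noise``; the
    endogenous-control Ct is ``control_baseline + noise``.  ``replicate_sd``
    is the technical replicate SD in cycles.
    """

    target_baseline: float = 24.0
    control_baseline: float = 18.0
    replicate_sd: float = 0.10
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.replicate_sd < 0:
            raise ValueError("replicate_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class ModelSpec:
    """Fixed/random structure retained for one trait's adjustment model."""

    fixed_terms: tuple[str, ...] = ()
    random_litter: bool = True
    covariate: Optional[str] = None
    dropped: tuple[tuple[str, float], ...] = field(default_factory=tuple)

    def formula(self, trait: str) -> str:
        rhs = " + ".join(_term_to_patsy(t) for t in self.fixed_terms) or "1"
        if self.covariate:
            rhs += f" + {self.covariate}"
        return f"Q('{trait}') ~ {rhs}"


def _term_to_patsy(term: str) -> str:
    """Map a symbolic term name to its patsy formula fragment.

    parity is modelled as categorical, litter size as continuous.
    """
    mapping = {
        "parity": "C(parity)",
        "litter_size": "litter_size",
        "sex": "C(sex)",
        "parity:litter_size": "C(parity):litter_size",
    }
    return mapping.get(term, term)
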