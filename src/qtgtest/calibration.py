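"""Monte-Carlo calibration harness.

Replicated-simulation estimates of the operating characteristics the
pipeline's conclusions rest on: the type-I rate of the complementation call
under a null cross, the false-causal rate of the CIT conjunction under a
non-mediated (independent) model, and the power of the causal call in the
effect-size regime the studies target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cit import NOT_CAUSAL, cit_component_tests, classify_cit
from .complementation import FAILURE_TO_COMPLEMENT, classify_complementation, \
    interaction_test
from .designs import CrossDesign, MediationModel
from .simulate import FOCAL_TRAIT, simulate_cit_input, simulate_four_way_cross


@dataclass
class RateEstimate:
    rate: float
    n_replicates: int

    @property
    def se(self) -> float:
        p = self.rate
        return float(np.sqrt(p * (1 - p) / self.n_replicates))


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)


def complementation_type_i_rate(n_replicates: int = 1000,
                                n_animals: int = 352,
                                alpha: float = 0.05,
                                seed: int = 0) -> RateEstimate:
    """Fraction of null four-way cohorts called failure-to-complement.

    Simulates cohorts with no genetic effect on the focal fat trait and runs
    the two-way interaction test on its raw values (no environmental effects
    need removing under the null model used here).
    """
    design = CrossDesign.four_way(n_animals=n_animals)
    model = MediationModel.null()
    hits = 0
    for s in _spawn_seeds(seed, n_replicates):
        cohort = simulate_four_way_cross(design, model, int(s))
        res = interaction_test(cohort, FOCAL_TRAIT)
        hits += classify_complementation(res, alpha).label \
            == FAILURE_TO_COMPLEMENT
    return RateEstimate(hits / n_replicates, n_replicates)


def cit_false_causal_rate(n_replicates: int = 1000,
                          model: MediationModel | None = None,
                          n_per_group: int = 12,
                          alpha: float = 0.05,
                          marginal_band: float = 0.10,
                          seed: int = 0) -> RateEstimate:
    """Fraction of non-mediated replicates labelled causal or marginal.

    The default model is ``independent``: genotype drives expression and the
    trait separately, the worst case for a spurious mediation call.
    """
    model = model or MediationModel.independent()
    hits = 0
    for s in _spawn_seeds(seed, n_replicates):
        d = simulate_cit_input(model, int(s), n_per_group)
        c = cit_component_tests(d["g"], d["expression"], d["trait"])
        label = classify_cit(c.p1, c.p2, c.p3, c.p4, alpha, marginal_band)
        hits += label != NOT_CAUSAL
    return RateEstimate(hits / n_replicates, n_replicates)


def cit_power(n_replicates: int = 400,
              model: MediationModel | None = None,
              n_per_group: int = 12,
              alpha: float = 0.05,
              marginal_band: float = 0.10,
              strict: bool = False,
              seed: int = 0) -> RateEstimate:
    """Power of the causal call under a truly mediated model.

    ``strict=True`` counts only the full ``causal`` label; otherwise the
    marginal call also counts as a detection.
    """
    model = model or MediationModel.causal()
    hits = 0
    for s in _spawn_seeds(seed, n_replicates):
        d = simulate_cit_input(model, int(s), n_per_group)
        c = cit_component_tests(d["g"], d["expression"], d["trait"])
        label = classify_cit(c.p1, c.p2, c.p3, c.p4, alpha, marginal_band)
        hits += (label == "causal") if strict else (label != NOT_CAUSAL)
    return RateEstimate(hits / n_replicates, n_replicates)
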