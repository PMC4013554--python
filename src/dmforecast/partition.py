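"""Compartment partitioning and incidence decomposition.

Each living stratum population is split into four pools: Healthy
(non-obese, non-smoking, non-diabetic), Obese, Smokers (non-obese
smokers) and Diabetes. Two adjustments resolve overlaps between pools:

1. Obese smokers are assigned to the Obese pool, so the Smokers pool
   holds only non-obese smokers (smoking prevalence times one minus
   obesity prevalence).
2. Diabetics attributable to an exposure are removed from that exposure
   pool using the population attributable risk (Levin's formula), so the
   Obese and Smokers pools hold only people without diabetes.

Because the disease-incidence input is an overall population rate while
transitions need state-specific rates, the overall incidence is
decomposed into the incidence among the Healthy via the weighted-sum
identity I = p_h·I_h + p_o·I_h·RR_o + p_s·I_h·RR_s, where the weights
are the shares of the non-diabetic pool in each state.
"""

from __future__ import annotations

from dataclasses import dataclass


def smoker_only_prevalence(smoking_prev: float, obesity_prev: float) -> float:
    """Prevalence of non-obese smokers, assuming independence of the two
    exposures: ``smoking_prev * (1 - obesity_prev)``."""
    for name, v in (("smoking_prev", smoking_prev), ("obesity_prev", obesity_prev)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} {v} outside [0, 1]")
    return smoking_prev * (1.0 - obesity_prev)


def levin_par(p_exposed: float, rr: float) -> float:
    """Population attributable risk by Levin's formula.

    PAR = p(RR - 1) / (1 + p(RR - 1)): the fraction of cases attributable
    to an exposure with prevalence ``p_exposed`` and relative risk ``rr``.
    Strictly below 1 for finite inputs; monotone increasing in both
    arguments. Protective exposures (RR < 1) are out of scope.
    """
    if not 0.0 <= p_exposed <= 1.0:
        raise ValueError(f"p_exposed {p_exposed} outside [0, 1]")
    if rr < 1.0:
        raise ValueError(f"rr must be >= 1, got {rr}")
    excess = p_exposed * (rr - 1.0)
    return excess / (1.0 + excess)


@dataclass(frozen=True)
class ExposureShares:
    """Shares of the non-diabetic living population in each state."""

    p_healthy: float
    p_obese: float
    p_smoker: float

    def __post_init__(self) -> None:
        for v in (self.p_healthy, self.p_obese, self.p_smoker):
            if not -1e-12 <= v <= 1.0 + 1e-12:
                raise ValueError(f"share {v} outside [0, 1]")
        total = self.p_healthy + self.p_obese + self.p_smoker
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"shares must sum to 1, got {total}")


@dataclass(frozen=True)
class Compartments:
    """Living-compartment sizes of one stratum at one point in time."""

    healthy: float
    obese: float
    smokers: float
    diabetes: float

    @property
    def living(self) -> float:
        return self.healthy + self.obese + self.smokers + self.diabetes

    def nondiabetic_shares(self) -> ExposureShares:
        pool = self.healthy + self.obese + self.smokers
        if pool <= 0.0:
            # Degenerate stratum (everyone diabetic): treat as all-healthy
            # so downstream decomposition is well defined.
            return ExposureShares(1.0, 0.0, 0.0)
        return ExposureShares(
            self.healthy / pool, self.obese / pool, self.smokers / pool
        )


def partition_stratum(
    living_pop: float,
    diabetes_count: float,
    obesity_prev: float,
    smoking_prev: float,
    rr_obese: float,
    rr_smoker: float,
) -> Compartments:
    """Split a stratum's living population into the four pools.

    Survey prevalences are whole-population proportions; the PAR
    subtraction removes from each exposure pool the diabetics whose
    disease is attributable to that exposure. Pools are floored at zero
    and, if the non-diabetic mass is exceeded, shrunk proportionally so
    the compartments always sum to ``living_pop``.
    """
    if diabetes_count > living_pop + 1e-9 * max(1.0, living_pop):
        raise ValueError(
            f"diabetes_count {diabetes_count} exceeds living population {living_pop}"
        )
    diabetes_count = min(diabetes_count, living_pop)

    smoker_prev = smoker_only_prevalence(smoking_prev, obesity_prev)
    obese = max(
        0.0,
        obesity_prev * living_pop
        - levin_par(obesity_prev, rr_obese) * diabetes_count,
    )
    smokers = max(
        0.0,
        smoker_prev * living_pop
        - levin_par(smoker_prev, rr_smoker) * diabetes_count,
    )

    nondiabetic = living_pop - diabetes_count
    exposed = obese + smokers
    if exposed > nondiabetic:
        # Exposure pools cannot exceed the non-diabetic mass; shrink both
        # proportionally (edge arises when diabetes dominates the stratum).
        scale = nondiabetic / exposed if exposed > 0.0 else 0.0
        obese *= scale
        smokers *= scale
    healthy = nondiabetic - obese - smokers
    healthy = max(0.0, healthy)
    return Compartments(
        healthy=healthy, obese=obese, smokers=smokers, diabetes=diabetes_count
    )


def decompose_incidence(
    overall_incidence: float,
    shares: ExposureShares,
    rr_obese: float,
    rr_smoker: float,
) -> float:
    """Incidence among the Healthy implied by the overall incidence.

    Solves the weighted-sum identity for I_h:
    ``I_h = I / (p_h + p_o·RR_o + p_s·RR_s)``. The exposed-state
    incidences are then ``I_h·RR_o`` and ``I_h·RR_s``.
    """
    if overall_incidence < 0.0:
        raise ValueError(f"incidence must be >= 0, got {overall_incidence}")
    denom = (
        shares.p_healthy
        + shares.p_obese * rr_obese
        + shares.p_smoker * rr_smoker
    )
    if denom <= 0.0:
        raise ValueError("degenerate exposure shares: zero denominator")
    return overall_incidence / denom
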