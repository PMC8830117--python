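import numpy as np
import pandas as pd
import pytest

from healthineq.simulate import CovariateModel, OutcomeModel, ScenarioConfig

BASE_ROW = {
    "woman_id": "W0",
    "state": "UP",
    "weight": 1.0,
    "wealth_score": 0.0,
    "wealth_quintile": 3,
    "residence": "rural",
    "age_group": "15-24",
    "birth_order": "1",
    "education": "none",
    "caste": "Others",
    "media_exposure": "no",
    "anc_visits": 0,
    "tt_injections": 0,
    "ifa_count": 0,
    "institutional_delivery": False,
    "skilled_attendant_at_home": False,
    "pnc_within_48h": False,
    "months_since_last_birth": 12,
}


@pytest.fixture
def row_factory():
    """Build a canonical-schema frame from per-row overrides of a base record."""

    def make(rows):
        out = []
        for i, over in enumerate(rows):
            row = dict(BASE_ROW, woman_id=f"W{i}", wealth_score=float(i))
            row.update(over)
            out.append(row)
        return pd.DataFrame(out)

    return make


def flat_covariates():
    """Covariate models with no wealth dependence at all."""
    return {
        "residence": CovariateModel(("urban", "rural"), (0.3, 0.7)),
        "age_group": CovariateModel(("15-24", "25-34", "35-49"), (0.35, 0.45, 0.20)),
        "birth_order": CovariateModel(("1", "2", "3+"), (0.3, 0.3, 0.4)),
        "education": CovariateModel(("none", "primary", "secondary", "higher"),
                                    (0.4, 0.2, 0.3, 0.1)),
        "caste": CovariateModel(("SC", "ST", "OBC", "Others"), (0.1, 0.1, 0.3, 0.5)),
        "media_exposure": CovariateModel(("no", "yes"), (0.4, 0.6)),
    }


def make_scenario(n=10000, *, name="custom", weight_dispersion=0.0,
                  covariates=None, outcomes=None):
    """A ScenarioConfig with null effects unless overridden."""
    default_outcomes = {o: OutcomeModel(intercept=0.0) for o in ("full_anc", "sba", "pnc")}
    if outcomes:
        default_outcomes.update(outcomes)
    return ScenarioConfig(
        name=name, n=n,
        states=(("UP", 0.5), ("WB", 0.5)),
        weight_dispersion=weight_dispersion,
        covariates=covariates or flat_covariates(),
        outcomes=default_outcomes,
    )


def planted_education_scenario(n=20000, direction=+1):
    """Only education drives the outcome, and education tilts with wealth.

    ``direction=+1`` plants a pro-rich gradient (higher education both more
    common among the rich and more predictive of care); ``-1`` flips the
    education-wealth association, planting a pro-poor gradient.
    """
    cov = flat_covariates()
    cov["education"] = CovariateModel(
        ("none", "primary", "secondary", "higher"), (0.4, 0.2, 0.3, 0.1),
        tuple(direction * s for s in (-1.5, 0.0, 1.2, 2.5)))
    edu_effect = {"edu_primary": 0.4, "edu_secondary": 1.0, "edu_higher": 1.6}
    outcomes = {o: OutcomeModel(intercept=-1.5, coefs=dict(edu_effect))
                for o in ("full_anc", "sba", "pnc")}
    return make_scenario(n, name=f"planted_education_{direction:+d}",
                         covariates=cov, outcomes=outcomes)


def mc_se_of_ci(p: float, n: int) -> float:
    """Monte-Carlo standard error of C for a binary outcome independent of rank.

    Under independence var(cov(y,R)) ≈ var(y)·var(R)/n with var(R)=1/12, so
    SE(C) ≈ (2/p)·sqrt(p(1-p)/(12n)) for equal weights.
    """
    return 2.0 / p * np.sqrt(p * (1 - p) / (12.0 * n))
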