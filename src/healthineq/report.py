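"""Config-driven orchestration of the full inequality analysis.

``run_analysis`` executes the whole chain — load or simulate, eligibility
filter, indicator recodes, wealth ranking, concentration indices (national
and by state), Wagstaff-type decomposition and the poor/non-poor gap table —
and ``write_tables`` serialises every report artifact as tidy CSV/JSON with
a checksum manifest.  Identical (input, config) pairs produce byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .decompose import (DecompositionResult, build_design, percent_contributions,
                        wagstaff_decompose)
from .ranking import (RANKING_BASES, ConcentrationResult, ci_by_group,
                      concentration_index, ranks_for_table)
from .simulate import generate_population, scenario_preset
from .survey import (GapTable, SurveyTable, derive_indicators, filter_eligible,
                     gap_table, load_survey)

logger = logging.getLogger("healthineq.report")

__all__ = ["ConfigError", "RunConfig", "ReportBundle", "run_analysis", "write_tables"]

KNOWN_OUTCOMES = ("full_anc", "sba", "pnc")


class ConfigError(ValueError):
    """A run configuration names unknown options or columns."""


@dataclass
class RunConfig:
    """Everything one analysis run depends on.

    Exactly one of ``input_path`` (a CSV with the documented columns) or
    ``scenario`` (a synthetic preset name) must be set.
    """

    input_path: str | None = None
    scenario: str | None = None
    n: int = 20000
    seed: int = 0
    outcomes: tuple[str, ...] = KNOWN_OUTCOMES
    ranking_basis: str = "continuous_score"
    model_kind: str = "lpm"
    percent_denominator: str = "total"
    group_column: str = "state"
    min_group_n: int = 250
    window_months: int = 60
    outdir: str = "results"
    column_dictionary: dict[str, str] | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown run-config field(s): {', '.join(sorted(unknown))}")
        if "outcomes" in raw:
            raw["outcomes"] = tuple(raw["outcomes"])
        return cls(**raw)

    def validate(self) -> None:
        if (self.input_path is None) == (self.scenario is None):
            raise ConfigError("exactly one of input_path or scenario must be set")
        for o in self.outcomes:
            if o not in KNOWN_OUTCOMES:
                raise ConfigError(f"unknown outcome {o!r}; known: {KNOWN_OUTCOMES}")
        if self.ranking_basis not in RANKING_BASES:
            raise ConfigError(f"unknown ranking_basis {self.ranking_basis!r}")
        if self.model_kind not in ("lpm", "logit_ame"):
            raise ConfigError(f"unknown model_kind {self.model_kind!r}")
        if self.percent_denominator not in ("total", "explained"):
            raise ConfigError(f"unknown percent_denominator {self.percent_denominator!r}")


@dataclass
class ReportBundle:
    """All artifacts of one run, cross-referencing a single filtered table."""

    table: SurveyTable
    gap: GapTable
    national_ci: dict[str, ConcentrationResult]
    state_ci: dict[str, dict[str, ConcentrationResult]]
    decompositions: dict[str, DecompositionResult]
    percents: dict[str, dict[str, float]]
    metadata: dict = field(default_factory=dict)


def _stage(name: str, before: int, after: int) -> None:
    logger.info("stage %-12s: %d -> %d rows", name, before, after)


def run_analysis(config: RunConfig) -> ReportBundle:
    """Execute filter → recode → rank → CI → decompose → gap table."""
    config.validate()
    row_counts: dict[str, int] = {}

    if config.scenario is not None:
        scenario = scenario_preset(config.scenario, n=config.n)
        table = generate_population(scenario, config.seed)
    else:
        table = load_survey(config.input_path, dictionary=config.column_dictionary)
    row_counts["loaded"] = len(table)

    filtered = filter_eligible(table, window_months=config.window_months)
    _stage("eligibility", len(table), len(filtered))
    row_counts["eligible"] = len(filtered)

    derived = derive_indicators(filtered)
    row_counts["analysis"] = len(derived)

    df = derived.data
    weights = df["weight"].to_numpy(float)
    ranks = ranks_for_table(derived, config.ranking_basis)
    alt_basis = "quintile_groups" if config.ranking_basis == "continuous_score" \
        else "continuous_score"
    alt_ranks = ranks_for_table(derived, alt_basis)

    national: dict[str, ConcentrationResult] = {}
    basis_divergence: dict[str, dict[str, float]] = {}
    decompositions: dict[str, DecompositionResult] = {}
    percents: dict[str, dict[str, float]] = {}
    state_ci: dict[str, dict[str, ConcentrationResult]] = {}
    design = build_design(derived)

    for outcome in config.outcomes:
        y = df[outcome].to_numpy(float)
        try:
            national[outcome] = concentration_index(y, ranks, weights,
                                                    ranking_basis=config.ranking_basis)
        except Exception as exc:
            raise type(exc)(f"[stage concentration_index/{outcome}] {exc}") from exc
        alt = concentration_index(y, alt_ranks, weights, ranking_basis=alt_basis)
        diff = abs(alt.index - national[outcome].index)
        if diff > 0.005:
            logger.info("ranking bases differ for %s: %s=%.4f vs %s=%.4f",
                        outcome, config.ranking_basis, national[outcome].index,
                        alt_basis, alt.index)
            basis_divergence[outcome] = {config.ranking_basis: national[outcome].index,
                                         alt_basis: alt.index}
        try:
            state_ci[outcome] = ci_by_group(derived, outcome, config.group_column,
                                            min_n=config.min_group_n,
                                            ranking_basis=config.ranking_basis)
        except Exception as exc:
            logger.warning("[stage ci_by_group/%s] %s; emitting empty map", outcome, exc)
            state_ci[outcome] = {}
        try:
            decompositions[outcome] = wagstaff_decompose(
                y, design, weights, ranks, model_kind=config.model_kind)
        except Exception as exc:
            raise type(exc)(f"[stage decomposition/{outcome}] {exc}") from exc
        percents[outcome] = percent_contributions(decompositions[outcome],
                                                  denominator=config.percent_denominator)

    gap = gap_table(derived, outcomes=tuple(config.outcomes))

    metadata = {
        "software_version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "row_counts": row_counts,
        "ranking_basis_divergence": basis_divergence,
        "design_decisions": {
            "eligibility_window": "half-open, months_since_last_birth < window",
            "rank_construction": "Lerman-Yitzhaki weighted midpoints, tied blocks share",
            "covariance_form": "population (no n-1)",
            "percent_denominator": config.percent_denominator,
            "model_kind": config.model_kind,
        },
    }
    return ReportBundle(table=derived, gap=gap, national_ci=national,
                        state_ci=state_ci, decompositions=decompositions,
                        percents=percents, metadata=metadata)


def _decomposition_frame(result: DecompositionResult) -> pd.DataFrame:
    rows = result.as_frame().rename(columns={
        "regressor": "regressor", "beta": "marginal_effect", "ck": "regressor_ci",
    })
    summary = pd.DataFrame([
        {"regressor": "Explained CI", "contribution": result.explained},
        {"regressor": "Total CI", "contribution": result.total},
        {"regressor": "Residual", "contribution": result.residual},
    ])
    return pd.concat([rows, summary], ignore_index=True)


def write_tables(bundle: ReportBundle, outdir) -> dict[str, str]:
    """Serialise the bundle; returns {filename: sha256} manifest.

    Emits ``gap_table.csv``, ``ci_by_state.csv``, ``curves.csv``, one
    ``decomposition_<outcome>.csv`` per outcome, ``percent_contributions.csv``
    and ``run_metadata.json``.  The linear-model additivity identity is
    asserted on every decomposition before anything is written.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    for outcome, result in bundle.decompositions.items():
        if result.model_kind == "lpm":
            gap_err = abs(result.explained + result.residual - result.total)
            assert gap_err <= 1e-10, \
                f"additivity violated for {outcome}: |gap| = {gap_err:.3e}"

    def emit(name: str, frame: pd.DataFrame) -> None:
        path = out / name
        frame.to_csv(path, index=False)
        manifest[name] = hashlib.sha256(path.read_bytes()).hexdigest()

    emit("gap_table.csv", bundle.gap.data)

    ci_rows = []
    for outcome, per_state in bundle.state_ci.items():
        for state, res in sorted(per_state.items()):
            ci_rows.append({"state": state, "outcome": outcome, "n": res.n,
                            "mu": res.mu, "ci": res.index,
                            "ranking_basis": res.ranking_basis})
    if not ci_rows:
        logger.warning("no state met the minimum sample size; ci_by_state.csv is header-only")
    emit("ci_by_state.csv", pd.DataFrame(
        ci_rows, columns=["state", "outcome", "n", "mu", "ci", "ranking_basis"]))

    curve_rows = []
    for outcome, res in bundle.national_ci.items():
        for p, L in zip(res.curve.p, res.curve.L):
            curve_rows.append({"outcome": outcome, "p": p, "L": L})
    emit("curves.csv", pd.DataFrame(curve_rows, columns=["outcome", "p", "L"]))

    for outcome, result in bundle.decompositions.items():
        emit(f"decomposition_{outcome}.csv", _decomposition_frame(result))

    pct_rows = [{"outcome": outcome, "regressor": reg, "percent": pct,
                 "denominator": bundle.metadata["design_decisions"]["percent_denominator"]}
                for outcome, per_reg in bundle.percents.items()
                for reg, pct in per_reg.items()]
    emit("percent_contributions.csv",
         pd.DataFrame(pct_rows, columns=["outcome", "regressor", "percent", "denominator"]))

    meta_path = out / "run_metadata.json"
    meta_path.write_text(json.dumps(bundle.metadata, indent=2, sort_keys=True))
    manifest["run_metadata.json"] = hashlib.sha256(meta_path.read_bytes()).hexdigest()
    return manifest
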