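"""End-to-end pipeline: simulate/ingest → filter → components → KDM → evaluate.

``run_pipeline`` wires the stages together per sex, persists every
intermediate table when an output directory is given, and returns a
:class:`PipelineResult` holding, for each sex stratum: the component model,
the fitted Klemera–Doubal model with its diagnostics (R² against CA, SD of
BA − CA), the importance table, the 2.5-year calibration table, the
age-acceleration group fractions, per-outcome survival evaluations on the
healthy subset (and optionally the whole population), the stepwise-Cox
benchmark score comparison, per-biomarker linearity diagnostics, and the
reduced-panel sensitivity analysis.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import components as comp
from . import eligibility, kdm, simulate, survival
from .errors import ConfigurationError, EmptyRiskSetError

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "SexResult",
    "run_pipeline",
    "reduced_panel_analysis",
    "linearity_diagnostics",
]

DEFAULT_ADJUSTMENT = ("imd_quintile", "smoking", "alcohol", "center")


@dataclass
class PipelineConfig:
    """Configuration of one full analysis run."""

    simulation: simulate.SimulationConfig = field(
        default_factory=simulate.SimulationConfig
    )
    input_table: str | None = None  # path to a cohort CSV; None = simulate
    seed: int = 0
    sexes: tuple[str, ...] = ("M", "F")
    outcomes: tuple[str, ...] = ("mortality", "admission")
    adjust: tuple[str, ...] = DEFAULT_ADJUSTMENT
    run_adjusted: bool = True
    run_whole_population: bool = False
    run_benchmark: bool = True
    reduced_panel_size: int | None = 10
    eigenvalue_threshold: float = comp.EIGENVALUE_THRESHOLD
    loading_cutoff: float = comp.LOADING_CUTOFF
    acceleration_threshold: float = 5.0
    bin_width: float = 2.5
    max_prior_episodes: int = 2

    def validate(self) -> None:
        if self.input_table is None:
            self.simulation.validate()
        if self.reduced_panel_size is not None and self.reduced_panel_size <= 0:
            raise ConfigurationError(
                f"reduced_panel_size={self.reduced_panel_size} must be positive"
            )
        if self.bin_width <= 0:
            raise ConfigurationError(f"bin_width={self.bin_width} must be positive")
        if self.acceleration_threshold < 0:
            raise ConfigurationError("acceleration_threshold must be >= 0")


@dataclass
class SexResult:
    """All per-sex artifacts of one pipeline run."""

    sex: str
    n_total: int
    n_healthy: int
    audit: pd.DataFrame
    component_model: comp.ComponentModel
    kdm_model: kdm.KDMModel
    importance: pd.DataFrame
    calibration: pd.DataFrame
    group_fractions: dict[str, float]
    evaluations: dict[str, survival.OutcomeEvaluation]
    whole_population: dict[str, survival.OutcomeEvaluation] = field(default_factory=dict)
    sd_ba_ca_healthy: float | None = None
    sd_ba_ca_whole: float | None = None
    benchmark: dict[str, float] = field(default_factory=dict)
    linearity: pd.DataFrame | None = None
    reduced: "ReducedPanelResult | None" = None


@dataclass
class ReducedPanelResult:
    """Reduced-panel sensitivity analysis for one sex."""

    biomarkers: list[str]
    correlation_with_full_ba: float
    r_squared: float | None
    evaluations: dict[str, survival.OutcomeEvaluation]


@dataclass
class PipelineResult:
    config: PipelineConfig
    cohort: pd.DataFrame
    by_sex: dict[str, SexResult]

    def check_invariants(self) -> None:
        for res in self.by_sex.values():
            for ev in list(res.evaluations.values()) + list(res.whole_population.values()):
                ev.check_ordering()


def linearity_diagnostics(
    table: pd.DataFrame, biomarkers: list[str], ca_col: str = "ca"
) -> pd.DataFrame:
    """Per-biomarker age-trend summary: linear slope and a curvature flag.

    Fits ``x = a + b*CA + c*CA²`` per biomarker and reports the linear slope
    from the simple regression plus the t-statistic of the quadratic term; a
    large |t| flags departure from linearity.
    """
    ca = table[ca_col].to_numpy(dtype=float)
    ca_c = ca - ca.mean()
    design = np.column_stack([np.ones_like(ca_c), ca_c, ca_c**2])
    rows = []
    for name in biomarkers:
        y = table[name].to_numpy(dtype=float)
        slope = float(np.dot(ca_c, y - y.mean()) / np.dot(ca_c, ca_c))
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        dof = max(len(y) - 3, 1)
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.inv(design.T @ design)
        t_quad = float(coef[2] / np.sqrt(cov[2, 2])) if cov[2, 2] > 0 else 0.0
        rows.append((name, slope, float(coef[2]), t_quad))
    return pd.DataFrame(rows, columns=["biomarker", "slope", "quadratic", "quadratic_t"])


def _evaluate_all(
    table: pd.DataFrame,
    outcomes: tuple[str, ...],
    *,
    sex: str,
    adjust: list[str] | None,
    acceleration_threshold: float,
) -> dict[str, survival.OutcomeEvaluation]:
    out = {}
    for outcome in outcomes:
        risk = (
            eligibility.admission_risk_set(table) if outcome == "admission" else table
        )
        if len(risk) == 0:
            raise EmptyRiskSetError(f"empty risk set for outcome {outcome!r}")
        out[outcome] = survival.evaluate_outcome(
            risk,
            outcome=outcome,
            sex=sex,
            adjust=adjust,
            acceleration_threshold=acceleration_threshold,
        )
    return out


def _fit_sex(
    cohort: pd.DataFrame, config: PipelineConfig, sex: str
) -> SexResult:
    biomarkers = list(config.simulation.biomarkers)
    sex_rows = cohort[cohort["sex"] == sex].copy()
    healthy, audit = eligibility.apply_healthy_filter(
        sex_rows, eligibility.default_rules(config.max_prior_episodes)
    )
    if len(healthy) < 3 * len(biomarkers):
        raise EmptyRiskSetError(
            f"only {len(healthy)} healthy rows for sex {sex!r}; too few to fit"
        )

    model = comp.fit_component_model(
        sex_rows,
        biomarkers,
        fit_rows=healthy.index,
        sex=sex,
        threshold=config.eigenvalue_threshold,
        cutoff=config.loading_cutoff,
    )
    scores = model.transform(sex_rows)
    scores_healthy = scores.loc[healthy.index]
    kdm_model = kdm.fit_kdm(scores_healthy, healthy["ca"], sex=sex)
    importance = kdm.component_importance(kdm_model)

    sex_rows["ba"] = kdm.compute_ba(scores, kdm_model)
    healthy = sex_rows.loc[healthy.index]

    calibration = kdm.calibration_table(
        healthy["ba"].to_numpy(), healthy["ca"].to_numpy(), config.bin_width
    )
    _, fractions = kdm.age_acceleration_groups(
        healthy["ba"].to_numpy(), healthy["ca"].to_numpy(), config.acceleration_threshold
    )

    adjust = list(config.adjust) if config.run_adjusted else None
    evaluations = _evaluate_all(
        healthy,
        config.outcomes,
        sex=sex,
        adjust=adjust,
        acceleration_threshold=config.acceleration_threshold,
    )

    res = SexResult(
        sex=sex,
        n_total=len(sex_rows),
        n_healthy=len(healthy),
        audit=audit,
        component_model=model,
        kdm_model=kdm_model,
        importance=importance,
        calibration=calibration,
        group_fractions=fractions,
        evaluations=evaluations,
        sd_ba_ca_healthy=float(np.std(healthy["ba"] - healthy["ca"], ddof=1)),
        sd_ba_ca_whole=float(np.std(sex_rows["ba"] - sex_rows["ca"], ddof=1)),
        linearity=linearity_diagnostics(healthy, biomarkers),
    )

    if config.run_whole_population:
        res.whole_population = _evaluate_all(
            sex_rows,
            config.outcomes,
            sex=sex,
            adjust=adjust,
            acceleration_threshold=config.acceleration_threshold,
        )

    if config.run_benchmark:
        # Benchmark: mortality score from stepwise Cox on the component
        # scores, assessed on the admissions outcome for comparison with BA.
        times = healthy["mortality_time"].to_numpy(dtype=float)
        events = healthy["mortality_event"].to_numpy(dtype=int)
        if events.sum() > 0 and "admission" in config.outcomes:
            selected, _, predictor = survival.stepwise_mortality_score(
                scores_healthy, times, events
            )
            risk = eligibility.admission_risk_set(healthy)
            pred_risk = (
                pd.Series(predictor, index=healthy.index).loc[risk.index].to_numpy()
            )
            res.benchmark = {
                "n_selected": float(len(selected)),
                "c_admission_mortality_score": survival.harrells_c(
                    pred_risk,
                    risk["admission_time"].to_numpy(dtype=float),
                    risk["admission_event"].to_numpy(dtype=int),
                ),
                "c_admission_ba": res.evaluations["admission"].c_ba,
            }

    if config.reduced_panel_size is not None:
        res.reduced = reduced_panel_analysis(
            sex_rows,
            healthy.index,
            model,
            kdm_model,
            importance,
            config,
            sex=sex,
        )
    return res


def reduced_panel_analysis(
    sex_rows: pd.DataFrame,
    healthy_index: pd.Index,
    model: comp.ComponentModel,
    kdm_model: kdm.KDMModel,
    importance: pd.DataFrame,
    config: PipelineConfig,
    *,
    sex: str,
    top_k: int | None = None,
    cutoff: float | None = None,
) -> ReducedPanelResult:
    """Re-run components → KDM → evaluation on a reduced biomarker panel.

    The panel is the union of the primary biomarkers (|rotated loading| above
    the cutoff, falling back to the top-loading biomarker) of the ``top_k``
    most important components of the full model.
    """
    top_k = config.reduced_panel_size if top_k is None else top_k
    cutoff = config.loading_cutoff if cutoff is None else cutoff
    n_retained = len(model.component_names)
    if top_k is None or top_k <= 0:
        raise ConfigurationError(f"reduced panel size {top_k} must be positive")
    if top_k > n_retained:
        raise ConfigurationError(
            f"reduced panel size {top_k} exceeds {n_retained} retained components"
        )
    top = importance.head(top_k)["component"].tolist()
    names = np.array(model.biomarkers)
    panel: list[str] = []
    for c in top:
        j = model.component_names.index(c)
        col = model.loadings[:, j]
        strong = [names[i] for i in np.argsort(-np.abs(col)) if abs(col[i]) > cutoff]
        if not strong:
            strong = [names[int(np.argmax(np.abs(col)))]]
        for b in strong:
            if b not in panel:
                panel.append(b)

    reduced_model = comp.fit_component_model(
        sex_rows,
        panel,
        fit_rows=healthy_index,
        sex=sex,
        threshold=config.eigenvalue_threshold,
        cutoff=cutoff,
    )
    reduced_scores = reduced_model.transform(sex_rows)
    reduced_kdm = kdm.fit_kdm(
        reduced_scores.loc[healthy_index], sex_rows.loc[healthy_index, "ca"], sex=sex
    )
    reduced_table = sex_rows.copy()
    reduced_table["ba"] = kdm.compute_ba(reduced_scores, reduced_kdm)
    healthy = reduced_table.loc[healthy_index]

    corr = float(np.corrcoef(healthy["ba"], sex_rows.loc[healthy_index, "ba"])[0, 1])
    adjust = list(config.adjust) if config.run_adjusted else None
    evaluations = _evaluate_all(
        healthy,
        config.outcomes,
        sex=sex,
        adjust=adjust,
        acceleration_threshold=config.acceleration_threshold,
    )
    return ReducedPanelResult(
        biomarkers=panel,
        correlation_with_full_ba=corr,
        r_squared=reduced_kdm.r_squared,
        evaluations=evaluations,
    )


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return float(o)
        return str(o)

    payload = json.dumps(dataclasses.asdict(config), default=default, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _persist(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.cohort.to_csv(out_dir / "cohort.csv", index=False)
    lines = [
        f"config_hash: {_config_hash(result.config)}",
        f"seed: {result.config.seed}",
        f"n_cohort: {len(result.cohort)}",
    ]
    for sex, res in result.by_sex.items():
        d = out_dir / f"sex_{sex}"
        d.mkdir(exist_ok=True)
        res.audit.to_csv(d / "filter_audit.csv", index=False)
        m = res.component_model
        pd.DataFrame(
            {
                "biomarker": m.biomarkers,
                "mean": m.standardization.means,
                "sd": m.standardization.sds,
            }
        ).to_csv(d / "standardization.csv", index=False)
        pd.DataFrame({"eigenvalue": m.eigenvalues}).to_csv(d / "eigenvalues.csv", index=False)
        pd.DataFrame(m.loadings, index=m.biomarkers, columns=m.component_names).to_csv(
            d / "rotated_loadings.csv"
        )
        pd.DataFrame(
            [(r.component, r.q, r.k, r.s, r.n_fit) for r in res.kdm_model.regressions],
            columns=["component", "q", "k", "s", "n_fit"],
        ).to_csv(d / "kdm_regressions.csv", index=False)
        res.importance.to_csv(d / "importance.csv", index=False)
        res.calibration.to_csv(d / "calibration.csv", index=False)
        rows = []
        for scope, evs in (("healthy", res.evaluations), ("whole", res.whole_population)):
            for name, ev in evs.items():
                rows.append(
                    {
                        "scope": scope,
                        "outcome": name,
                        "n": ev.n,
                        "n_events": ev.n_events,
                        "ll_null": ev.ll_null,
                        "ll_ca": ev.ll_ca,
                        "ll_ba": ev.ll_ba,
                        "ll_both": ev.ll_both,
                        "proportion_explained_ba": ev.proportion_explained_ba,
                        "lrt_p": ev.lrt_ba_over_ca[2],
                        "c_ca": ev.c_ca,
                        "c_ba": ev.c_ba,
                        "c_both": ev.c_both,
                        "c_ca_adjusted": ev.c_ca_adjusted,
                        "c_ba_adjusted": ev.c_ba_adjusted,
                        "c_both_adjusted": ev.c_both_adjusted,
                        "log_rank_p": ev.log_rank_test[2],
                    }
                )
                for group, curve in ev.km_curves.items():
                    curve.to_csv(d / f"km_{scope}_{name}_{group}.csv", index=False)
        pd.DataFrame(rows).to_csv(d / "evaluation.csv", index=False)
        if res.linearity is not None:
            res.linearity.to_csv(d / "linearity.csv", index=False)
        lines += [
            f"sex_{sex}_n_total: {res.n_total}",
            f"sex_{sex}_n_healthy: {res.n_healthy}",
            f"sex_{sex}_kdm_r_squared: {res.kdm_model.r_squared}",
        ]
    (out_dir / "run_log.txt").write_text("\n".join(lines) + "\n")


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full analysis and (optionally) persist all artifacts."""
    config.validate()
    if config.input_table is not None:
        cohort = pd.read_csv(config.input_table)
    else:
        sim = config.simulation.replace(seed=config.seed)
        cohort = simulate.generate_cohort(sim)
        config = dataclasses.replace(config, simulation=sim)
    by_sex = {sex: _fit_sex(cohort, config, sex) for sex in config.sexes}
    result = PipelineResult(config=config, cohort=cohort, by_sex=by_sex)
    result.check_invariants()
    if out_dir is not None:
        _persist(result, Path(out_dir))
    return result
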