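"""Evaluation harness: how often does each method infer interaction correctly?

For each simulated replicate of a scenario, the three inference methods are
applied (DI; SSF with the partner's occurrence distribution, SSF-OD; SSF
with the distance to the partner, SSF-DIST) and, for the SSFs, under three
model structures:

* ``full`` — interaction covariate plus the landscape covariate;
* ``individual`` — interaction covariate only (no environmental data);
* ``spatialplus`` — the ``individual`` model after the Spatial+
  residualisation of the interaction covariate.

A result is *correct* when the interaction is non-significant in the
landscape-driven scenarios (A.a, A.b, B, C: true negatives) and significant
with attraction sign in the social scenario D (true positives).  The
scenario-C barrier sweep additionally regresses the outcome on the barrier
proportion, coding 1 = non-significant (correct), so a rising
false-positive rate yields a negative logistic slope.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .dynamic_interaction import DIConfig, di_index
from .simulator import ScenarioConfig, SimulationResult, simulate_pair
from .spatial_plus import SpatialPlusConfig, fit_spatial_plus_ssf
from .ssf import (
    InestimableCovariateError,
    SSFConfig,
    attach_covariates,
    fit_ssf,
    fit_step_distributions,
    generate_available_steps,
    occurrence_distribution,
)

__all__ = [
    "EvaluationConfig",
    "BarrierSweepResult",
    "classify_correct",
    "collinearity_check",
    "evaluate_pair",
    "run_scenario",
    "barrier_sweep",
    "aggregate_proportions",
]

LANDSCAPE_SCENARIOS = ("A.a", "A.b", "B", "C")


@dataclass(frozen=True)
class EvaluationConfig:
    alpha: float = 0.05
    n_reps: int = 20
    model_structures: tuple[str, ...] = ("full", "individual", "spatialplus")
    methods: tuple[str, ...] = ("di", "ssf_od", "ssf_dist")
    collinearity_threshold: float = 0.7
    overlap_epsilon: float = 1e-8
    overlap_fraction: float = 0.99
    barrier_proportions: tuple[float, ...] = tuple(np.round(np.arange(0, 0.5001, 0.005), 4))
    n_extreme_reps: int = 20
    extreme_proportion: float = 0.70

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@dataclass(frozen=True)
class BarrierSweepResult:
    """Per-run significance flags and the fitted logistic slopes."""

    runs: pd.DataFrame
    slopes: pd.DataFrame


RECORD_COLUMNS = [
    "scenario",
    "method",
    "model_structure",
    "replicate",
    "interaction_estimate",
    "interaction_p",
    "landscape_estimate",
    "landscape_p",
    "significant",
    "correct",
    "skipped_reason",
]


def classify_correct(interaction_p: float, interaction_estimate: float, scenario: str, alpha: float = 0.05) -> bool:
    """Scenario truth: A/B/C should be non-significant, D significant with
    attraction (positive) sign."""
    if scenario == "D":
        return bool(interaction_p < alpha and interaction_estimate > 0)
    return bool(interaction_p >= alpha)


def collinearity_check(strata: pd.DataFrame, cov_a: str, cov_b: str, used_only: bool = True) -> float:
    """Pearson correlation between two covariates (at used steps by default)."""
    df = strata[strata["case"] == 1] if used_only else strata
    a = df[cov_a].to_numpy(dtype=float)
    b = df[cov_b].to_numpy(dtype=float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined: zero-variance covariate")
    return float(np.corrcoef(a, b)[0, 1])


def _record(scenario, method, structure, rep, *, est=np.nan, p=np.nan, land_est=np.nan,
            land_p=np.nan, alpha=0.05, skipped=None):
    significant = bool(p < alpha) if np.isfinite(p) else False
    correct = (
        classify_correct(p, est, scenario, alpha) if skipped is None and np.isfinite(p) else np.nan
    )
    return {
        "scenario": scenario,
        "method": method,
        "model_structure": structure,
        "replicate": rep,
        "interaction_estimate": est,
        "interaction_p": p,
        "landscape_estimate": land_est,
        "landscape_p": land_p,
        "significant": significant if skipped is None else np.nan,
        "correct": correct,
        "skipped_reason": skipped,
    }


def _od_overlaps(strata: pd.DataFrame, od_max: float, eval_cfg: EvaluationConfig) -> bool:
    od = strata["od"].to_numpy(dtype=float)
    frac_empty = float(np.mean(od < eval_cfg.overlap_epsilon * od_max))
    return frac_empty <= eval_cfg.overlap_fraction


def build_strata(sim: SimulationResult, ssf_config: SSFConfig | None = None, rng=None):
    """Strata for the focal individual (``traj_a``) with landscape, dist and
    od covariates attached (landscape only when the scenario has one).

    Returns ``(strata, od_max)`` where ``od_max`` is the peak of the
    partner's occurrence density (used by the overlap rule).
    """
    cfg = ssf_config or SSFConfig()
    if rng is None:
        rng = np.random.default_rng(sim.config.seed + 1)
    focal, partner = sim.traj_a, sim.traj_b
    dists = fit_step_distributions(focal)
    strata = generate_available_steps(focal, dists, cfg.n_available, rng, area_size=sim.config.area_size)
    grid = sim.landscape
    covs = ["dist"]
    if grid is not None:
        covs.append("landscape")
    # the OD is a smooth KDE (bandwidth >> cell size), so it is rasterised on
    # a dedicated 100x100 grid over the arena rather than the landscape grid
    from .landscapes import make_gradient_landscape

    od_grid = make_gradient_landscape(100, 100, sim.config.area_size / 100)
    od = occurrence_distribution(partner, od_grid)
    covs.append("od")
    strata = attach_covariates(
        strata,
        grid=grid,
        other_traj=partner,
        od=od,
        config=SSFConfig(covariate_set=tuple(covs), dist_sign=cfg.dist_sign),
    )
    return strata, float(od.density.max())


def _fit_structure(strata, cov, structure, scenario, eval_cfg, ssf_cfg, sp_cfg, rng, spatial_basis_cache=None):
    """Fit one SSF model structure; returns (est, p, land_est, land_p, skipped_reason)."""
    has_landscape = "landscape" in strata.columns
    if structure == "full":
        if scenario == "C" or not has_landscape:
            return None  # no environmental covariate extracted
        r = collinearity_check(strata, cov, "landscape")
        if abs(r) > eval_cfg.collinearity_threshold:
            # refuse the joint model; refit with the landscape covariate only
            fit = fit_ssf(strata, ["landscape"], replace(ssf_cfg, covariate_set=("landscape",)))
            return (np.nan, np.nan, fit.coefficients["landscape"], fit.p_values["landscape"], "collinear")
        fit = fit_ssf(strata, [cov, "landscape"], replace(ssf_cfg, covariate_set=(cov, "landscape")))
        return (
            fit.coefficients[cov],
            fit.p_values[cov],
            fit.coefficients["landscape"],
            fit.p_values["landscape"],
            None,
        )
    if structure == "individual":
        fit = fit_ssf(strata, [cov], replace(ssf_cfg, covariate_set=(cov,)))
        return (fit.coefficients[cov], fit.p_values[cov], np.nan, np.nan, None)
    if structure == "spatialplus":
        fit = fit_spatial_plus_ssf(
            strata, cov, sp_cfg, rng, standardize=ssf_cfg.standardize, basis=spatial_basis_cache
        )
        res = f"{cov}_residual"
        return (fit.coefficients[res], fit.p_values[res], np.nan, np.nan, None)
    raise ValueError(f"unknown model structure {structure!r}")


def evaluate_pair(
    sim: SimulationResult,
    eval_cfg: EvaluationConfig,
    replicate: int = 0,
    ssf_cfg: SSFConfig | None = None,
    sp_cfg: SpatialPlusConfig | None = None,
    di_cfg: DIConfig | None = None,
    rng=None,
) -> list[dict]:
    """Apply every requested method x structure to one simulated pair."""
    scenario = sim.config.scenario
    alpha = eval_cfg.alpha
    ssf_cfg = ssf_cfg or SSFConfig()
    sp_cfg = sp_cfg or SpatialPlusConfig()
    if rng is None:
        rng = np.random.default_rng(sim.config.seed + 10_000)
    records: list[dict] = []

    if "di" in eval_cfg.methods:
        res = di_index(sim.traj_a, sim.traj_b, di_cfg or DIConfig(), rng)
        records.append(
            _record(scenario, "di", "none", replicate, est=res.di, p=res.p_value, alpha=alpha)
        )

    need_ssf = [m for m in eval_cfg.methods if m.startswith("ssf")]
    if not need_ssf:
        return records

    strata, od_max = build_strata(sim, ssf_cfg, rng)
    overlap_ok = _od_overlaps(strata, od_max, eval_cfg)
    basis_cache = None
    if "spatialplus" in eval_cfg.model_structures:
        from .spatial_plus import spatial_basis

        basis_cache = spatial_basis(strata, sp_cfg, rng)

    for method in need_ssf:
        cov = "od" if method == "ssf_od" else "dist"
        for structure in eval_cfg.model_structures:
            if method == "ssf_od" and not overlap_ok and structure in ("individual", "spatialplus"):
                records.append(
                    _record(scenario, method, structure, replicate, alpha=alpha, skipped="no_overlap")
                )
                continue
            try:
                out = _fit_structure(
                    strata, cov, structure, scenario, eval_cfg, ssf_cfg, sp_cfg, rng, basis_cache
                )
            except (InestimableCovariateError, np.linalg.LinAlgError, ValueError) as exc:
                records.append(
                    _record(scenario, method, structure, replicate, alpha=alpha, skipped=f"fit_error:{exc}")
                )
                continue
            if out is None:
                continue
            est, p, land_est, land_p, skipped = out
            records.append(
                _record(
                    scenario, method, structure, replicate,
                    est=est, p=p, land_est=land_est, land_p=land_p, alpha=alpha, skipped=skipped,
                )
            )
    return records


def run_scenario(
    scenario: str,
    eval_config: EvaluationConfig | None = None,
    scenario_config: ScenarioConfig | None = None,
    seed: int = 0,
    ssf_cfg: SSFConfig | None = None,
    sp_cfg: SpatialPlusConfig | None = None,
    di_cfg: DIConfig | None = None,
) -> pd.DataFrame:
    """Simulate ``n_reps`` replicate pairs of a scenario and evaluate each."""
    eval_cfg = eval_config or EvaluationConfig()
    template = scenario_config or ScenarioConfig(scenario=scenario)
    if template.scenario != scenario:
        template = replace(template, scenario=scenario)
    seeder = np.random.default_rng(seed)
    records: list[dict] = []
    for rep in range(eval_cfg.n_reps):
        cfg = replace(template, seed=int(seeder.integers(2**31)))
        sim = simulate_pair(cfg)
        rng = np.random.default_rng(int(seeder.integers(2**31)))
        records.extend(evaluate_pair(sim, eval_cfg, rep, ssf_cfg, sp_cfg, di_cfg, rng))
    return pd.DataFrame.from_records(records, columns=RECORD_COLUMNS)


def _logistic_slope(y: np.ndarray, x: np.ndarray, ridge: float = 1e-3):
    """Logistic regression of y on x; (slope, se, p, separated).

    Falls back to a ridge-penalised Newton fit (and flags separation) when
    the MLE diverges or the outcome is degenerate.
    """
    X = np.column_stack([np.ones_like(x), x])

    def _penalized():
        beta = np.zeros(2)
        for _ in range(200):
            eta = X @ beta
            mu = 1.0 / (1.0 + np.exp(-eta))
            W = mu * (1 - mu)
            grad = X.T @ (y - mu) - ridge * beta
            H = (X * W[:, None]).T @ X + ridge * np.eye(2)
            step = np.linalg.solve(H, grad)
            beta = beta + step
            if np.max(np.abs(step)) < 1e-10:
                break
        cov = np.linalg.inv(H)
        return beta, np.sqrt(np.diag(cov))

    if len(np.unique(y)) < 2:
        beta, se = _penalized()
        return float(beta[1]), float(se[1]), np.nan, True

    try:
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        separated = (not fit.mle_retvals.get("converged", True)) or np.max(np.abs(fit.params)) > 40
        if not separated:
            return float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1]), False
    except Exception:
        pass
    beta, se = _penalized()
    from scipy import stats as _st

    p = 2 * _st.norm.sf(abs(beta[1] / se[1])) if se[1] > 0 else np.nan
    return float(beta[1]), float(se[1]), float(p), True


def barrier_sweep(
    eval_config: EvaluationConfig | None = None,
    scenario_config_template: ScenarioConfig | None = None,
    seed: int = 0,
    ssf_cfg: SSFConfig | None = None,
    sp_cfg: SpatialPlusConfig | None = None,
) -> BarrierSweepResult:
    """Scenario-C sweep over barrier proportions plus the extreme case.

    One simulation (fresh landscape and seed) per barrier proportion in
    ``eval_config.barrier_proportions`` plus ``n_extreme_reps`` repetitions
    at the extreme proportion; SSF-OD and SSF-DIST are fitted with the
    ``individual`` and ``spatialplus`` structures.  Per method x structure
    a logistic regression of outcome (1 = non-significant interaction,
    i.e. correct) on barrier proportion is fitted.
    """
    eval_cfg = eval_config or EvaluationConfig()
    template = scenario_config_template or ScenarioConfig(scenario="C")
    sweep_cfg = replace(
        eval_cfg,
        methods=("ssf_od", "ssf_dist"),
        model_structures=("individual", "spatialplus"),
    )
    seeder = np.random.default_rng(seed)
    props = list(eval_cfg.barrier_proportions) + [eval_cfg.extreme_proportion] * eval_cfg.n_extreme_reps
    rows: list[dict] = []
    for run_id, prop in enumerate(props):
        cfg = replace(template, scenario="C", barrier_proportion=float(prop), seed=int(seeder.integers(2**31)))
        sim = simulate_pair(cfg)
        rng = np.random.default_rng(int(seeder.integers(2**31)))
        for rec in evaluate_pair(sim, sweep_cfg, run_id, ssf_cfg, sp_cfg, rng=rng):
            rec["barrier_proportion"] = prop
            rows.append(rec)
    runs = pd.DataFrame.from_records(rows)

    slope_rows = []
    for (method, structure), grp in runs.groupby(["method", "model_structure"]):
        ok = grp[grp["skipped_reason"].isna() & np.isfinite(grp["interaction_p"])]
        y = (ok["interaction_p"].to_numpy() >= eval_cfg.alpha).astype(float)  # 1 = correct
        x = ok["barrier_proportion"].to_numpy(dtype=float)
        slope, se, p, separated = _logistic_slope(y, x)
        slope_rows.append(
            {
                "method": method,
                "model_structure": structure,
                "slope": slope,
                "se": se,
                "p_value": p,
                "separated": separated,
                "n_runs": len(ok),
            }
        )
    return BarrierSweepResult(runs=runs, slopes=pd.DataFrame(slope_rows))


def aggregate_proportions(records: pd.DataFrame) -> pd.DataFrame:
    """Proportion correct per scenario x method x structure (Fig-2 analogue).

    Cells whose every record was skipped are reported as missing (NaN), not
    as zero.
    """
    rows = []
    for (scenario, method, structure), grp in records.groupby(
        ["scenario", "method", "model_structure"], dropna=False
    ):
        valid = grp[grp["skipped_reason"].isna() & grp["correct"].notna()]
        rows.append(
            {
                "scenario": scenario,
                "method": method,
                "model_structure": structure,
                "n": len(valid),
                "n_skipped": int(grp["skipped_reason"].notna().sum()),
                "proportion_correct": float(valid["correct"].mean()) if len(valid) else np.nan,
            }
        )
    return pd.DataFrame(rows)
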