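"""Composite-likelihood demographic inference from the folded joint SFS.

Sites are treated as independent, so the likelihood of an observed joint
SFS given a demographic model is multinomial over polymorphic cells with
cell probabilities estimated by coalescent simulation (the standard
simulation-based composite-likelihood approach of SFS inference tools).
Model selection uses AIC = 2k - 2 lnL; uncertainty comes from a parametric
bootstrap (refit on data simulated at the fitted parameters).

Optimisation is multi-start Nelder-Mead over log-parameters.  Within a
start, every likelihood evaluation reuses the same simulation seed (common
random numbers), which turns the stochastic likelihood surface into a
smooth deterministic one per start; fresh streams are used across starts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import optimize

from .coalescent import (
    DemographicModel,
    JointSFS,
    SampleConfig,
    SizeEpoch,
    domestication_scenario,
    expected_sfs,
    sample_sfs,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FitConfig",
    "ModelSpec",
    "FitResult",
    "BootstrapResult",
    "composite_log_likelihood",
    "fit_model",
    "model_select",
    "parametric_bootstrap",
    "profile_likelihood",
    "MODEL_ARCHETYPES",
]


@dataclass(frozen=True)
class FitConfig:
    """Simulation settings shared by all likelihood evaluations."""

    sample_config: SampleConfig
    n_loci: int = 10_000
    locus_bp: int = 1_000
    mu: float = 1e-8
    folded: bool = True


def composite_log_likelihood(observed: JointSFS, expected: JointSFS) -> float:
    """Multinomial composite lnL: Σ m_cell · ln p_cell over polymorphic cells.

    ``expected`` must hold floor-bounded probabilities (as produced by
    expected_sfs) on the same dimensions and folding as ``observed``.
    """
    if (observed.n_w, observed.n_d) != (expected.n_w, expected.n_d):
        raise ValueError("SFS dimensions do not match")
    if observed.folded != expected.folded:
        raise ValueError("SFS folding does not match")
    mask = observed.polymorphic_mask()
    m = observed.matrix[mask]
    p = expected.matrix[mask]
    nz = m > 0
    if np.any(p[nz] <= 0):
        raise ValueError("expected SFS has zero mass in an observed cell; apply a floor")
    return float(np.sum(m[nz] * np.log(p[nz])))


# ---------------------------------------------------------------------------
# model specifications


@dataclass(frozen=True)
class ModelSpec:
    """A named demographic model family.

    ``builder`` maps a full parameter dict (free + fixed) to a
    DemographicModel; ``bounds`` give positive (low, high) ranges for each
    free parameter, searched on a log scale.
    """

    name: str
    free_params: tuple[str, ...]
    bounds: Mapping[str, tuple[float, float]]
    fixed_params: Mapping[str, float]
    builder: Callable[[Mapping[str, float]], DemographicModel]

    def __post_init__(self):
        if not self.free_params:
            raise ValueError("a model needs at least one free parameter")
        for p in self.free_params:
            lo, hi = self.bounds[p]
            if not (0 < lo < hi):
                raise ValueError(f"bounds for {p} must be positive and ordered")

    @property
    def k(self) -> int:
        return len(self.free_params)

    def build(self, free_values: Mapping[str, float]) -> DemographicModel:
        params = dict(self.fixed_params)
        params.update(free_values)
        return self.builder(params)


def _si_builder(p: Mapping[str, float]) -> DemographicModel:
    return DemographicModel(
        wild_epochs=(SizeEpoch(0.0, p["n_w"]),),
        dom_epochs=(SizeEpoch(0.0, p["n_d"]),),
        t_div=p["t_div"],
        n_anc=p["n_anc"],
        m_wd=p.get("m", 0.0),
        m_dw=p.get("m", 0.0),
    )


def _two_epoch_builder(p: Mapping[str, float]) -> DemographicModel:
    """Size changes in one or both daughters; missing events collapse."""
    wild = [SizeEpoch(0.0, p["n_w_recent"])]
    if p.get("t_w_change", 0.0) > 0 and p.get("n_w_past") is not None:
        wild.append(SizeEpoch(p["t_w_change"], p["n_w_past"]))
    dom = [SizeEpoch(0.0, p["n_d_recent"])]
    if p.get("t_d_change", 0.0) > 0 and p.get("n_d_past") is not None:
        dom.append(SizeEpoch(p["t_d_change"], p["n_d_past"]))
    return DemographicModel(
        wild_epochs=tuple(wild),
        dom_epochs=tuple(dom),
        t_div=p["t_div"],
        n_anc=p["n_anc"],
        m_wd=p.get("m", 0.0),
        m_dw=p.get("m", 0.0),
    )


def _scenario_builder(p: Mapping[str, float]) -> DemographicModel:
    return domestication_scenario(
        t_div_yr=p["t_div_yr"],
        n_dom_early=p["n_dom_early"],
        n_dom_recent=p["n_dom_recent"],
        t_dom_expand_yr=p["t_dom_expand_yr"],
        n_wild_historic=p["n_wild_historic"],
        n_wild_recent=p["n_wild_recent"],
        t_wild_decline_yr=p["t_wild_decline_yr"],
        n_anc=p.get("n_anc"),
        m_wd=p.get("m", 0.0),
        m_dw=p.get("m", 0.0),
    )


def _make_archetypes() -> dict[str, ModelSpec]:
    """Representative two-population model family.

    Strict isolation (SI), isolation-with-migration (IM), each optionally
    with an instantaneous bottleneck/size change in the wild daughter, the
    domestic daughter or both, plus the full domestication scenario with a
    recent wild decline.  Sizes in diploids, times in generations (the
    scenario models take years BP and convert internally).
    """
    nb = {"n_w": (100.0, 1e6), "n_d": (100.0, 1e6), "t_div": (10.0, 1e5), "n_anc": (100.0, 1e6)}
    tb = {
        "n_w_recent": (100.0, 1e6),
        "n_w_past": (100.0, 1e6),
        "n_d_recent": (100.0, 1e6),
        "n_d_past": (100.0, 1e6),
        "t_w_change": (5.0, 1e5),
        "t_d_change": (5.0, 1e5),
        "t_div": (10.0, 1e5),
        "n_anc": (100.0, 1e6),
        "m": (1e-8, 1e-2),
    }
    sb = {
        "t_div_yr": (100.0, 3e5),
        "n_dom_early": (50.0, 1e6),
        "n_dom_recent": (50.0, 1e6),
        "t_dom_expand_yr": (50.0, 1e5),
        "n_wild_historic": (50.0, 1e6),
        "n_wild_recent": (50.0, 1e6),
        "t_wild_decline_yr": (10.0, 1e4),
        "m": (1e-8, 1e-2),
    }
    anc = {"n_anc": 20_000.0}
    specs = [
        ModelSpec("si", ("n_w", "n_d", "t_div"), nb, anc, _si_builder),
        ModelSpec("im", ("n_w", "n_d", "t_div", "m"), {**nb, "m": (1e-8, 1e-2)}, anc, _si_builder),
        ModelSpec(
            "si_wild_change",
            ("n_w_recent", "n_w_past", "t_w_change", "n_d_recent", "t_div"),
            tb,
            anc,
            _two_epoch_builder,
        ),
        ModelSpec(
            "si_dom_change",
            ("n_w_recent", "n_d_recent", "n_d_past", "t_d_change", "t_div"),
            tb,
            anc,
            _two_epoch_builder,
        ),
        ModelSpec(
            "si_both_change",
            (
                "n_w_recent",
                "n_w_past",
                "t_w_change",
                "n_d_recent",
                "n_d_past",
                "t_d_change",
                "t_div",
            ),
            tb,
            anc,
            _two_epoch_builder,
        ),
        ModelSpec(
            "im_wild_change",
            ("n_w_recent", "n_w_past", "t_w_change", "n_d_recent", "t_div", "m"),
            tb,
            anc,
            _two_epoch_builder,
        ),
        ModelSpec(
            "im_dom_change",
            ("n_w_recent", "n_d_recent", "n_d_past", "t_d_change", "t_div", "m"),
            tb,
            anc,
            _two_epoch_builder,
        ),
        ModelSpec(
            "im_both_change",
            (
                "n_w_recent",
                "n_w_past",
                "t_w_change",
                "n_d_recent",
                "n_d_past",
                "t_d_change",
                "t_div",
                "m",
            ),
            tb,
            anc,
            _two_epoch_builder,
        ),
        ModelSpec(
            "scenario_si",
            (
                "t_div_yr",
                "n_dom_early",
                "n_dom_recent",
                "t_dom_expand_yr",
                "n_wild_historic",
                "n_wild_recent",
                "t_wild_decline_yr",
            ),
            sb,
            {},
            _scenario_builder,
        ),
        ModelSpec(
            "scenario_im",
            (
                "t_div_yr",
                "n_dom_early",
                "n_dom_recent",
                "t_dom_expand_yr",
                "n_wild_historic",
                "n_wild_recent",
                "t_wild_decline_yr",
                "m",
            ),
            sb,
            {},
            _scenario_builder,
        ),
    ]
    return {s.name: s for s in specs}


MODEL_ARCHETYPES: dict[str, ModelSpec] = _make_archetypes()


def load_model_specs(path) -> list[ModelSpec]:
    """Model specifications from YAML.

    Each entry names a base archetype and may narrow its free parameters,
    override bounds, or pin parameters::

        - name: my_si
          base: si
          free_params: [t_div]
          fixed: {n_w: 20000, n_d: 5000}
          bounds: {t_div: [100, 50000]}
    """
    import yaml

    with open(path) as fh:
        entries = yaml.safe_load(fh)
    if not isinstance(entries, list):
        raise ValueError("model spec YAML must be a list of entries")
    specs = []
    for entry in entries:
        base = MODEL_ARCHETYPES[entry["base"]]
        free = tuple(entry.get("free_params", base.free_params))
        fixed = dict(base.fixed_params)
        fixed.update(entry.get("fixed", {}))
        # parameters dropped from the free list must be pinned somewhere
        for p in base.free_params:
            if p not in free and p not in fixed:
                raise ValueError(f"parameter {p} is neither free nor fixed in {entry['name']}")
        bounds = {p: tuple(b) for p, b in {**dict(base.bounds), **entry.get("bounds", {})}.items()}
        specs.append(
            ModelSpec(
                name=entry["name"],
                free_params=free,
                bounds=bounds,
                fixed_params=fixed,
                builder=base.builder,
            )
        )
    return specs


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    model: str
    params: dict[str, float]
    lnl: float
    k: int
    n_starts: int
    converged: bool
    start_log: list[dict] = field(default_factory=list)

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.lnl

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": self.params,
            "lnl": self.lnl,
            "k": self.k,
            "aic": self.aic,
            "n_starts": self.n_starts,
            "converged": self.converged,
        }


def _neg_lnl_factory(observed, spec, fit_config, eval_seed):
    names = spec.free_params
    lo = np.log([spec.bounds[p][0] for p in names])
    hi = np.log([spec.bounds[p][1] for p in names])

    def neg_lnl(log_theta: np.ndarray) -> float:
        penalty = float(np.sum(np.maximum(lo - log_theta, 0) + np.maximum(log_theta - hi, 0)))
        clipped = np.clip(log_theta, lo, hi)
        values = dict(zip(names, np.exp(clipped)))
        try:
            model = spec.build(values)
            exp = expected_sfs(
                model,
                fit_config.sample_config,
                fit_config.n_loci,
                fit_config.locus_bp,
                fit_config.mu,
                seed=eval_seed,
                folded=fit_config.folded,
            )
            lnl = composite_log_likelihood(observed, exp)
        except (ValueError, RuntimeError):
            return 1e12
        return -lnl + 1e4 * penalty

    return neg_lnl, lo, hi


def fit_model(
    observed: JointSFS,
    spec: ModelSpec,
    fit_config: FitConfig,
    n_starts: int = 50,
    seed: int = 0,
    maxiter: int = 200,
) -> FitResult:
    """Maximise the composite likelihood by multi-start simplex search.

    Each start draws a log-uniform initial point within the bounds and runs
    Nelder-Mead on log-parameters with a fixed simulation seed (common
    random numbers); the best start is returned.
    """
    if observed.total_polymorphic() <= 0:
        raise ValueError("observed SFS has no polymorphic cells")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    best: FitResult | None = None
    log = []
    for start in range(n_starts):
        eval_seed = int(rng.integers(2**31 - 1))
        neg_lnl, lo, hi = _neg_lnl_factory(observed, spec, fit_config, eval_seed)
        x0 = rng.uniform(lo, hi)
        res = optimize.minimize(
            neg_lnl,
            x0,
            method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-3, "fatol": 1e-2},
        )
        values = dict(zip(spec.free_params, np.exp(np.clip(res.x, lo, hi))))
        entry = {"start": start, "lnl": -float(res.fun), "converged": bool(res.success)}
        log.append(entry)
        if res.fun >= 1e11:
            continue
        if best is None or -res.fun > best.lnl:
            best = FitResult(
                model=spec.name,
                params={k: float(v) for k, v in values.items()},
                lnl=-float(res.fun),
                k=spec.k,
                n_starts=n_starts,
                converged=bool(res.success),
                start_log=log,
            )
    if best is None:
        raise RuntimeError(f"no start converged for model {spec.name}: {log}")
    best.start_log = log
    return best


def model_select(fits: Sequence[FitResult]) -> list[dict]:
    """Rank fitted models by AIC (ascending) with ΔAIC."""
    if not fits:
        raise ValueError("no fits to rank")
    ranked = sorted(fits, key=lambda f: f.aic)
    best_aic = ranked[0].aic
    return [
        {**f.to_dict(), "delta_aic": f.aic - best_aic}
        for f in ranked
    ]


@dataclass
class BootstrapResult:
    params: dict[str, list[float]]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    n_requested: int
    n_converged: int

    def to_dict(self) -> dict:
        return {
            "n_requested": self.n_requested,
            "n_converged": self.n_converged,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "replicates": self.params,
        }


def parametric_bootstrap(
    best_fit: FitResult,
    spec: ModelSpec,
    fit_config: FitConfig,
    n_reps: int = 100,
    n_starts: int = 5,
    seed: int = 0,
    min_converged_frac: float = 0.8,
) -> BootstrapResult:
    """Percentile 95% CIs from refits on data simulated at the estimate.

    Each replicate simulates a fresh SFS (same number of loci as the fit
    configuration) under the fitted parameters and refits the model.
    Errors out if fewer than ``min_converged_frac`` of replicates converge.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    model = spec.build(best_fit.params)
    rng = np.random.default_rng(seed)
    estimates: dict[str, list[float]] = {p: [] for p in spec.free_params}
    n_converged = 0
    for rep in range(n_reps):
        rep_seed = int(rng.integers(2**31 - 1))
        sim = sample_sfs(
            model,
            fit_config.sample_config,
            fit_config.n_loci,
            fit_config.locus_bp,
            fit_config.mu,
            seed=rep_seed,
            folded=fit_config.folded,
        )
        try:
            fit = fit_model(sim, spec, fit_config, n_starts=n_starts, seed=rep_seed)
        except RuntimeError:
            continue
        n_converged += 1
        for p in spec.free_params:
            estimates[p].append(fit.params[p])
    if n_converged < min_converged_frac * n_reps:
        raise RuntimeError(
            f"only {n_converged}/{n_reps} bootstrap replicates converged"
        )
    ci_low = {p: float(np.percentile(v, 2.5)) for p, v in estimates.items()}
    ci_high = {p: float(np.percentile(v, 97.5)) for p, v in estimates.items()}
    return BootstrapResult(estimates, ci_low, ci_high, n_reps, n_converged)


# ---------------------------------------------------------------------------
# 1-D profiles (used for parameter-recovery experiments)


def profile_likelihood(
    observed: JointSFS,
    build_model: Callable[[float], DemographicModel],
    grid: np.ndarray,
    fit_config: FitConfig,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Composite lnL along a 1-D parameter grid; returns (grid, lnLs, argmax).

    All grid points share one simulation seed (common random numbers) so
    the profile is smooth in the parameter.
    """
    grid = np.asarray(grid, dtype=float)
    lnls = np.empty(len(grid))
    for i, value in enumerate(grid):
        exp = expected_sfs(
            build_model(float(value)),
            fit_config.sample_config,
            fit_config.n_loci,
            fit_config.locus_bp,
            fit_config.mu,
            seed=seed,
            folded=fit_config.folded,
        )
        lnls[i] = composite_log_likelihood(observed, exp)
    return grid, lnls, float(grid[int(np.argmax(lnls))])


def write_fit_results(fits: Sequence[FitResult], path, bootstrap: BootstrapResult | None = None) -> None:
    payload = {"models": model_select(fits)}
    if bootstrap is not None:
        payload["bootstrap"] = bootstrap.to_dict()
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
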