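"""Replicate simulation studies: type-I error, recovery, coverage, calibration.

These loops tie the simulator and the two-stage estimator together and
back the package's evaluation suite: simulate a dataset under known true
parameters, fit it, and collect per-replicate estimates, standard errors,
Wald p-values, and fit-test p-values.  All randomness derives from one
user seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import RelationshipCache, fit_model
from .model import check_identification
from .simulator import SimulationConfig, simulate_dataset

__all__ = ["ReplicateResult", "run_replicates", "coverage_table",
           "rejection_rate"]


@dataclass
class ReplicateResult:
    """Long-format per-replicate results plus fit-test p-values."""

    params: pd.DataFrame   # rep, mode, name, role, true, estimate, se, p
    fits: pd.DataFrame     # rep, mode, index, statistic, df, p
    n_failed: int = 0


def run_replicates(config: SimulationConfig, n_reps: int, seed: int = 0,
                   weight: str = "diag", modes=(False,),
                   mc_reps: int = 20_000, compute_indices: bool = False,
                   n_polish: int = 3, ea_population: int = 20,
                   ea_generations: int = 10) -> ReplicateResult:
    """Simulate and fit ``n_reps`` independent datasets.

    ``modes`` lists the ascertainment-analysis settings to run on each
    dataset (e.g. ``(False, True)`` analyzes every replicate both without
    and with the ascertainment correction).  Replicates whose fit raises
    are counted in ``n_failed`` and skipped.
    """
    import copy as _copy

    from .simulator import DEFAULT_PANEL_PARAMS, generate_synthetic_panel

    config = _copy.copy(config)
    if config.ascertainment is not None:
        config.ascertainment = dict(config.ascertainment)
    mm = simulate_config_matrices(config)
    check_identification(mm)
    theta_true = _true_vector(mm, config)
    names = mm.param_names
    roles = mm.roles
    master = np.random.default_rng(seed)
    rep_seeds = master.integers(0, 2**31 - 1, size=n_reps)
    if config.panel is None:
        # one panel (hence one set of allele frequencies) for the whole study
        pp = dict(DEFAULT_PANEL_PARAMS,
                  seed=int(master.integers(0, 2**31 - 1)))
        pp.update(config.panel_params)
        config.panel = generate_synthetic_panel(**pp)
    sim_cache: dict = {}
    est_cache = RelationshipCache()
    prows, frows = [], []
    n_failed = 0
    for rep in range(n_reps):
        data = simulate_dataset(config, seed=int(rep_seeds[rep]),
                                rel_cache=sim_cache)
        if (config.ascertainment is not None
                and config.ascertainment.get("threshold") is None):
            # affection threshold is a population constant; reuse it
            config.ascertainment["threshold"] = data.threshold
        for mode in modes:
            try:
                fm = fit_model(data.peds, mm, ibd=data.ibd, ascertained=mode,
                               weight=weight, seed=int(rep_seeds[rep]),
                               mc_reps=mc_reps,
                               compute_indices=compute_indices,
                               check_ident=False, cache=est_cache,
                               n_polish=n_polish,
                               ea_population=ea_population,
                               ea_generations=ea_generations)
            except Exception:
                n_failed += 1
                continue
            for i, name in enumerate(names):
                prows.append((rep, mode, name, roles[i], theta_true[i],
                              fm.theta[i], fm.se[i], fm.p[i]))
            if compute_indices and fm.fit is not None:
                for (idx_name, stat, dfv, pv) in fm.fit.as_rows():
                    frows.append((rep, mode, idx_name, stat, dfv, pv))
    params = pd.DataFrame(prows, columns=["rep", "mode", "name", "role",
                                          "true", "estimate", "se", "p"])
    fits = pd.DataFrame(frows, columns=["rep", "mode", "index", "statistic",
                                        "df", "p"])
    return ReplicateResult(params=params, fits=fits, n_failed=n_failed)


def simulate_config_matrices(config: SimulationConfig):
    from .simulator import _compile

    return _compile(config.model)


def _true_vector(mm, config: SimulationConfig):
    from .simulator import _resolve_theta

    return _resolve_theta(mm, config.theta_true)


def coverage_table(params: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Per-parameter coverage of nominal ``level`` Wald intervals."""
    from scipy import stats

    zq = stats.norm.ppf(0.5 + level / 2.0)
    df = params.copy()
    df["covered"] = (np.abs(df["estimate"] - df["true"]) <= zq * df["se"])
    out = (df.groupby(["mode", "name", "role"], sort=False)
             .agg(coverage=("covered", "mean"),
                  mean_estimate=("estimate", "mean"),
                  true=("true", "first"),
                  n=("covered", "size"))
             .reset_index())
    return out


def rejection_rate(params: pd.DataFrame, name: str,
                   alphas=(0.05, 0.01, 0.001)) -> dict:
    """Empirical rejection rate of the Wald test for one parameter."""
    p = params.loc[params["name"] == name, "p"].to_numpy()
    return {a: float(np.mean(p < a)) for a in alphas}
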