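"""Monte-Carlo harness: type-I error calibration and estimator accuracy.

Each experiment draws ``reps`` multinomial samples from a model at a true
parameter, computes a p-value per sample (chi-square asymptotic or
parametric bootstrap), and reports the fraction at or below each nominal
level — the empirical type-I error.  The accuracy study reports the root
mean square deviation (RMSD) of the estimator from the true parameter.

Replicate-level randomness comes from independent SeedSequence substreams,
so results are reproducible and independent of batching.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .divergences import penalized_divergence_batch, power_divergence
from .estimation import EstimationError, fit_mpe, fit_mpe_batch
from .gof import bootstrap_pvalue, test_statistic
from .models import ParametricModel, get_model

__all__ = [
    "ExperimentSpec",
    "SimulationResult",
    "type1_error_experiment",
    "rmsd_experiment",
    "run_table",
    "load_config",
    "config_path",
    "available_configs",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExperimentSpec:
    """One cell of a simulation table."""

    model: str
    theta_true: float
    n: int
    reps: int
    lambda1: float
    h1: float
    lambda2: float
    h2: float
    method: str = "asymptotic"  # or "bootstrap"
    B: Optional[int] = None
    alphas: Sequence[float] = (0.05, 0.10)
    seed: int = 0

    def __post_init__(self):
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if any(not (0 < a <= 1) for a in self.alphas):
            raise ValueError("alphas must lie in (0, 1]")
        if self.method not in ("asymptotic", "bootstrap"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.method == "bootstrap" and (self.B is None or self.B < 1):
            raise ValueError("bootstrap method needs B >= 1")


@dataclass
class SimulationResult:
    rejection_rate: Dict[float, float]
    mc_stderr: Dict[float, float]
    reps_completed: int
    seed: int
    rmsd: Optional[float] = None
    spec: Optional[ExperimentSpec] = None


def _draw_samples(model: ParametricModel, theta, n, reps, seed_children):
    """One multinomial sample per replicate substream."""
    p = np.asarray(model.probs(np.atleast_1d(theta)), dtype=float)
    X = np.empty((reps, model.k), dtype=np.int64)
    for r, child in enumerate(seed_children):
        X[r] = np.random.default_rng(child).multinomial(n, p)
    return X


def _batch_T(X, model, phi1, h1, phi2, h2):
    n = int(X[0].sum())
    thetas = fit_mpe_batch(X, model, phi2, h2)
    P_fit = model.probs_batch(thetas)
    D = penalized_divergence_batch(X / n, P_fit, phi1, h1)
    return 2.0 * n / phi1.d2_at_1 * (D - phi1.value_at_1), thetas


def type1_error_experiment(spec: ExperimentSpec) -> SimulationResult:
    """Empirical type-I error of the chosen calibration at the spec's cell.

    Weak inequality throughout: a p-value exactly equal to the nominal
    level counts as a rejection.
    """
    model = get_model(spec.model)
    phi1 = power_divergence(spec.lambda1)
    phi2 = power_divergence(spec.lambda2)
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(spec.reps)
    failed = 0
    if spec.method == "asymptotic":
        X = _draw_samples(model, spec.theta_true, spec.n, spec.reps, children)
        if model.s == 1 and model.probs_batch is not None:
            T, _ = _batch_T(X, model, phi1, spec.h1, phi2, spec.h2)
        else:
            T = np.empty(spec.reps)
            for r in range(spec.reps):
                try:
                    T[r], _ = test_statistic(
                        X[r], model, phi1, spec.h1, phi2, spec.h2
                    )
                except EstimationError:
                    T[r] = np.nan
                    failed += 1
            if failed > 0.01 * spec.reps:
                raise EstimationError(
                    f"{failed}/{spec.reps} replicates failed to fit"
                )
        pvals = stats.chi2.sf(T, model.k - model.s - 1)
    else:
        p_true = np.asarray(
            model.probs(np.atleast_1d(spec.theta_true)), dtype=float
        )
        pvals = np.empty(spec.reps)
        for r, child in enumerate(children):
            data_ss, boot_ss = child.spawn(2)
            X_r = np.random.default_rng(data_ss).multinomial(spec.n, p_true)
            try:
                res = bootstrap_pvalue(
                    X_r, model, phi1, spec.h1, phi2, spec.h2,
                    B=spec.B, seed=boot_ss,
                )
                pvals[r] = res.p_bootstrap
            except EstimationError:
                pvals[r] = np.nan
                failed += 1
            if spec.reps >= 10 and (r + 1) % max(spec.reps // 10, 1) == 0:
                logger.info(
                    "bootstrap cell %s n=%d: %d/%d replicates",
                    spec.model, spec.n, r + 1, spec.reps,
                )
        if failed > 0.01 * spec.reps:
            raise EstimationError(
                f"{failed}/{spec.reps} replicates failed to fit"
            )
    ok = np.isfinite(pvals)
    reps_done = int(ok.sum())
    rate = {
        a: float(np.count_nonzero(pvals[ok] <= a)) / reps_done
        for a in spec.alphas
    }
    stderr = {
        a: float(np.sqrt(r * (1 - r) / reps_done)) for a, r in rate.items()
    }
    return SimulationResult(
        rejection_rate=rate, mc_stderr=stderr, reps_completed=reps_done,
        seed=spec.seed, spec=spec,
    )


def rmsd_experiment(
    model: Union[str, ParametricModel],
    theta_true: float,
    n: int,
    phi2,
    h2: float,
    reps: int,
    seed: int,
) -> SimulationResult:
    """Root mean square deviation of the estimator over ``reps`` samples:
    ``sqrt(mean (theta_hat - theta_true)^2)``."""
    if isinstance(model, str):
        model = get_model(model)
    if isinstance(phi2, (int, float)):
        phi2 = power_divergence(phi2)
    root = np.random.SeedSequence(seed)
    children = root.spawn(reps)
    X = _draw_samples(model, theta_true, n, reps, children)
    if model.s == 1 and model.probs_batch is not None:
        thetas = fit_mpe_batch(X, model, phi2, h2)
    else:
        thetas = np.array([
            fit_mpe(x, model, phi2, h2, compute_cov=False).theta_hat[0]
            for x in X
        ])
    rmsd = float(np.sqrt(np.mean((thetas - theta_true) ** 2)))
    return SimulationResult(
        rejection_rate={}, mc_stderr={}, reps_completed=reps, seed=seed,
        rmsd=rmsd,
    )


# ---------------------------------------------------------------------------
# experiment tables from config files
# ---------------------------------------------------------------------------

def config_path(name: str):
    """Path of a shipped experiment config (e.g. ``"table1"``)."""
    from importlib import resources

    fname = name if name.endswith(".yaml") else f"{name}.yaml"
    ref = resources.files("penphi") / "configs" / fname
    if not ref.is_file():
        raise KeyError(f"no shipped config {name!r}")
    return ref


def available_configs() -> list:
    from importlib import resources

    d = resources.files("penphi") / "configs"
    return sorted(p.name[:-5] for p in d.iterdir() if p.name.endswith(".yaml"))


def load_config(path) -> List[ExperimentSpec]:
    """Expand a YAML experiment config into a list of cells.

    Schema: scalar keys ``model, theta_true, method, reps, B, alphas, seed``
    plus a list ``n`` of sample sizes and a list ``settings`` of divergence
    choices ``{lambda1, h1, lambda2, h2}``; the grid is their product.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not cfg:
        return []
    specs = []
    for n, setting in itertools.product(cfg["n"], cfg["settings"]):
        specs.append(ExperimentSpec(
            model=cfg["model"],
            theta_true=float(cfg["theta_true"]),
            n=int(n),
            reps=int(cfg["reps"]),
            lambda1=float(setting["lambda1"]),
            h1=float(setting["h1"]),
            lambda2=float(setting["lambda2"]),
            h2=float(setting["h2"]),
            method=cfg.get("method", "asymptotic"),
            B=cfg.get("B"),
            alphas=tuple(cfg.get("alphas", (0.05, 0.10))),
            seed=int(cfg.get("seed", 0)),
        ))
    return specs


def run_table(
    specs: List[ExperimentSpec],
    out: Optional[str] = None,
    reference: Optional[Dict] = None,
) -> pd.DataFrame:
    """Run a grid of experiments and return a tidy table.

    One output row per (cell, alpha): model, n, divergence settings, method,
    empirical rate, Monte-Carlo standard error, reps and seed.  With ``out``
    the table is also written as TSV.  Cells are derived from independent
    seeds (spec seed offset by cell index) so rerunning a sub-grid
    reproduces its rows.
    """
    rows = []
    for i, spec in enumerate(specs):
        cell = replace(spec, seed=spec.seed + i)
        logger.info(
            "running cell %d/%d: %s n=%d lambda1=%g h1=%g (%s)",
            i + 1, len(specs), cell.model, cell.n, cell.lambda1, cell.h1,
            cell.method,
        )
        try:
            res = type1_error_experiment(cell)
        except EstimationError:
            # flush what completed so a long grid is not lost, then abort
            if out is not None:
                pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
            raise
        for a in cell.alphas:
            rows.append({
                "model": cell.model, "n": cell.n,
                "lambda1": cell.lambda1, "h1": cell.h1,
                "lambda2": cell.lambda2, "h2": cell.h2,
                "alpha": a, "method": cell.method,
                "rate": res.rejection_rate[a],
                "stderr": res.mc_stderr[a],
                "reps": res.reps_completed, "B": cell.B or "",
                "seed": cell.seed,
            })
    table = pd.DataFrame(rows)
    if out is not None:
        table.to_csv(out, sep="\t", index=False)
    return table
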