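"""Goodness-of-fit testing with penalized phi-divergence statistics.

The statistic is

    T = 2n / phi1''(1) * { D_{phi1,h1}(pi_hat, P(theta_hat)) - phi1(1) }

with ``theta_hat`` a minimum penalized phi2-divergence estimate; under the
null that ``pi`` belongs to the family, T is asymptotically chi-square with
``k - s - 1`` degrees of freedom, for any choice of generators and
penalties.  The chi-square approximation degrades badly when some cells
have tiny probabilities, so the null distribution can instead be estimated
by a parametric bootstrap — resampling from the fitted law ``P(theta_hat)``
and refitting each resample — which is consistent whether or not the null
holds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .counts import as_count_vector
from .divergences import (
    PhiSpec,
    penalized_divergence,
    penalized_divergence_batch,
)
from .estimation import (
    EstimationError,
    OptimizerSettings,
    fit_mpe,
    fit_mpe_batch,
)
from .models import ParametricModel

__all__ = [
    "GofTestResult",
    "test_statistic",
    "asymptotic_pvalue",
    "bootstrap_pvalue",
]

logger = logging.getLogger(__name__)


@dataclass
class GofTestResult:
    """Outcome of the penalized-divergence goodness-of-fit test."""

    T_obs: float
    df: int
    p_asymptotic: float
    theta_hat: np.ndarray
    B: Optional[int] = None
    p_bootstrap: Optional[float] = None
    seed: Optional[int] = None
    n_failed_refits: int = 0
    settings: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "T_obs": self.T_obs,
            "df": self.df,
            "p_asymptotic": self.p_asymptotic,
            "p_bootstrap": self.p_bootstrap,
            "B": self.B,
            "seed": self.seed,
            "n_failed_refits": self.n_failed_refits,
            "theta_hat": [float(t) for t in np.atleast_1d(self.theta_hat)],
            "settings": self.settings,
        }


def test_statistic(
    counts,
    model: ParametricModel,
    phi1: PhiSpec,
    h1: float,
    phi2: PhiSpec,
    h2: float,
    opts: Optional[OptimizerSettings] = None,
):
    """Observed statistic ``T`` and the estimate ``theta_hat`` behind it."""
    cv = as_count_vector(counts)
    est = fit_mpe(cv, model, phi2, h2, opts=opts, compute_cov=False)
    pi_hat = cv.counts / cv.n
    p_fit = np.asarray(model.probs(est.theta_hat), dtype=float)
    D = penalized_divergence(pi_hat, p_fit, phi1, h1)
    T = 2.0 * cv.n / phi1.d2_at_1 * (D - phi1.value_at_1)
    return float(T), est.theta_hat


def asymptotic_pvalue(T: float, k: int, s: int) -> float:
    """Upper-tail chi-square probability at ``T`` with ``k - s - 1`` df."""
    df = k - s - 1
    if df <= 0:
        raise ValueError(f"degrees of freedom k-s-1 must be >= 1, got {df}")
    return float(stats.chi2.sf(T, df))


def _bootstrap_statistics(
    cv, model, phi1, h1, phi2, h2, theta_hat, B, seed_seq, opts
):
    """B bootstrap statistics T*, drawn replicate-by-replicate from
    independent substreams so the result is invariant to execution order."""
    n, k = cv.n, cv.k
    p_fit = np.asarray(model.probs(theta_hat), dtype=float)
    children = seed_seq.spawn(B)
    X = np.empty((B, k), dtype=np.int64)
    for b, child in enumerate(children):
        X[b] = np.random.default_rng(child).multinomial(n, p_fit)
    n_failed = 0
    if model.s == 1 and model.probs_batch is not None:
        thetas = fit_mpe_batch(X, model, phi2, h2)
        P_star = model.probs_batch(thetas)
        D = penalized_divergence_batch(X / n, P_star, phi1, h1)
        T_star = 2.0 * n / phi1.d2_at_1 * (D - phi1.value_at_1)
    else:
        T_list = []
        for b in range(B):
            try:
                est = fit_mpe(X[b], model, phi2, h2, opts=opts,
                              compute_cov=False)
            except EstimationError:
                n_failed += 1
                continue
            p_b = np.asarray(model.probs(est.theta_hat), dtype=float)
            D = penalized_divergence(X[b] / n, p_b, phi1, h1)
            T_list.append(2.0 * n / phi1.d2_at_1 * (D - phi1.value_at_1))
            if B >= 10 and (b + 1) % max(B // 10, 1) == 0:
                logger.info("bootstrap progress: %d/%d replicates", b + 1, B)
        T_star = np.asarray(T_list)
    return T_star, n_failed


def bootstrap_pvalue(
    counts,
    model: ParametricModel,
    phi1: PhiSpec,
    h1: float,
    phi2: PhiSpec,
    h2: float,
    B: int,
    seed: "int | np.random.SeedSequence",
    opts: Optional[OptimizerSettings] = None,
) -> GofTestResult:
    """Parametric-bootstrap p-value of the goodness-of-fit test.

    Draws ``B`` multinomial resamples of size ``n`` from the fitted law
    ``P(theta_hat)``, refits each with ``(phi2, h2)``, computes its
    statistic ``T*`` with ``(phi1, h1)``, and reports
    ``p_hat = #{b : T*_b >= T_obs} / B`` (weak inequality; no +1
    correction, so ``p_hat`` may be exactly 0 at resolution ``1/B``).

    Replicates whose refit fails to converge are excluded from the
    denominator with a warning; more than 10% failures is an error.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    cv = as_count_vector(counts)
    T_obs, theta_hat = test_statistic(cv, model, phi1, h1, phi2, h2, opts)
    seed_seq = (
        seed if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    T_star, n_failed = _bootstrap_statistics(
        cv, model, phi1, h1, phi2, h2, theta_hat, B, seed_seq, opts
    )
    if n_failed > 0.1 * B:
        raise EstimationError(
            f"{n_failed}/{B} bootstrap refits failed to converge"
        )
    if n_failed:
        warnings.warn(
            f"{n_failed}/{B} bootstrap refits failed and were excluded "
            "from the p-value denominator",
            UserWarning, stacklevel=2,
        )
    denom = B - n_failed
    p_boot = float(np.count_nonzero(T_star >= T_obs)) / denom
    return GofTestResult(
        T_obs=T_obs,
        df=model.k - model.s - 1,
        p_asymptotic=asymptotic_pvalue(T_obs, model.k, model.s),
        theta_hat=theta_hat,
        B=B,
        p_bootstrap=p_boot,
        seed=seed_val,
        n_failed_refits=n_failed,
        settings={
            "model": model.name,
            "lambda1": phi1.lam, "h1": h1,
            "lambda2": phi2.lam, "h2": h2,
        },
    )
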