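"""Parametric multinomial families P(theta) with derivatives.

A model is the map ``theta -> (p_1(theta), ..., p_k(theta))`` from an open
box ``Theta`` in R^s onto strictly positive cell probabilities summing to
one, with ``k - s - 1 > 0`` so the goodness-of-fit test has positive degrees
of freedom.  First and second derivatives of the cell probabilities enter
the asymptotic covariance machinery; built-in models carry analytic ones and
:func:`numeric_derivatives` fills them by central differences otherwise.

Three one-parameter examples ship with the package:

* ``example1`` — ``p = (1/3 - t, 2/3 - t, 2t)`` on ``0 < t < 1/3``; near the
  upper boundary ``p_1`` is tiny, producing chronically empty first cells.
* ``example2`` — ``p = (0.5 - 2t, 0.5 + t, t)`` on ``0 < t < 1/4``.
* ``example3-hw`` — the Hardy-Weinberg-type law ``p = (t^2, t(1-t), t(1-t),
  (1-t)^2)`` on ``0 < t < 1``, used for the land-cover classification data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, Optional

import numpy as np

__all__ = [
    "ParametricModel",
    "DomainError",
    "model_example1",
    "model_example2",
    "model_example3",
    "numeric_derivatives",
    "get_model",
    "register_model",
    "available_models",
    "load_models_config",
]


class DomainError(ValueError):
    """Parameter outside the open parameter box of a model."""


@dataclass
class ParametricModel:
    """A parametric family of k-cell multinomial probabilities.

    Parameters
    ----------
    name : str
    s, k : int
        Parameter dimension and number of cells; ``k - s - 1 > 0``.
    lower, upper : (s,) arrays
        Open box Theta = prod (lower_j, upper_j).
    probs : callable
        ``theta (s,) -> p (k,)``, strictly positive, summing to one on the
        box interior.
    jacobian : callable, optional
        ``theta -> (s, k)``; column i is the gradient of ``p_i``.
    hessians : callable, optional
        ``theta -> (k, s, s)``; slice i is the Hessian of ``p_i``.
    probs_batch : callable, optional
        For ``s == 1``: ``thetas (R,) -> (R, k)``, vectorized evaluation used
        by the batched fitters.
    """

    name: str
    s: int
    k: int
    lower: np.ndarray
    upper: np.ndarray
    probs: Callable[[np.ndarray], np.ndarray]
    jacobian: Optional[Callable[[np.ndarray], np.ndarray]] = None
    hessians: Optional[Callable[[np.ndarray], np.ndarray]] = None
    probs_batch: Optional[Callable[[np.ndarray], np.ndarray]] = field(
        default=None, repr=False
    )

    def __post_init__(self):
        self.lower = np.atleast_1d(np.asarray(self.lower, dtype=float))
        self.upper = np.atleast_1d(np.asarray(self.upper, dtype=float))
        if self.k - self.s - 1 <= 0:
            raise ValueError(
                f"need k - s - 1 > 0, got k={self.k}, s={self.s}"
            )

    # -- domain handling ---------------------------------------------------
    def check_domain(self, theta) -> np.ndarray:
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        if theta.shape != (self.s,):
            raise ValueError(
                f"theta must have shape ({self.s},), got {theta.shape}"
            )
        if np.any(theta <= self.lower) or np.any(theta >= self.upper):
            raise DomainError(
                f"theta={theta} outside the open box "
                f"({self.lower}, {self.upper}) of model {self.name!r}"
            )
        return theta

    def clamped_bounds(self, eps_frac: float = 1e-10):
        """Closed optimization box [lo + eps, hi - eps], eps a fraction of
        the box width, keeping iterates strictly inside the open domain."""
        width = self.upper - self.lower
        return self.lower + eps_frac * width, self.upper - eps_frac * width

    def p(self, theta) -> np.ndarray:
        """Validated probability vector at ``theta``."""
        theta = self.check_domain(theta)
        return np.asarray(self.probs(theta), dtype=float)

    def cell_hessian(self, theta, i: int) -> np.ndarray:
        """Hessian of ``p_i`` at theta, shape (s, s)."""
        if self.hessians is None:
            raise ValueError(
                f"model {self.name!r} has no Hessians; wrap it with "
                "numeric_derivatives()"
            )
        return np.asarray(self.hessians(np.atleast_1d(theta)))[i]

    def with_derivatives(self) -> "ParametricModel":
        """Self if derivatives are present, else a numeric-derivative wrap."""
        if self.jacobian is not None and self.hessians is not None:
            return self
        return numeric_derivatives(self)


# ---------------------------------------------------------------------------
# built-in examples (s = 1, analytic derivatives, vectorized batch evaluation)
# ---------------------------------------------------------------------------

def _linear_model(name, k, coeffs, intercepts, lower, upper):
    """Family with affine cell probabilities p_i = a_i * t + b_i (s=1)."""
    a = np.asarray(coeffs, dtype=float)
    b = np.asarray(intercepts, dtype=float)

    def probs(theta):
        return a * theta[0] + b

    def probs_batch(thetas):
        return np.outer(thetas, a) + b

    def jacobian(theta):
        return a.reshape(1, k)

    def hessians(theta):
        return np.zeros((k, 1, 1))

    return ParametricModel(
        name=name, s=1, k=k, lower=[lower], upper=[upper],
        probs=probs, jacobian=jacobian, hessians=hessians,
        probs_batch=probs_batch,
    )


def model_example1() -> ParametricModel:
    """``p = (1/3 - t, 2/3 - t, 2t)`` on ``0 < t < 1/3``."""
    return _linear_model(
        "example1", 3, [-1.0, -1.0, 2.0], [1.0 / 3.0, 2.0 / 3.0, 0.0],
        0.0, 1.0 / 3.0,
    )


def model_example2() -> ParametricModel:
    """``p = (0.5 - 2t, 0.5 + t, t)`` on ``0 < t < 1/4``."""
    return _linear_model(
        "example2", 3, [-2.0, 1.0, 1.0], [0.5, 0.5, 0.0], 0.0, 0.25,
    )


def model_example3() -> ParametricModel:
    """Hardy-Weinberg-type law ``p = (t^2, t(1-t), t(1-t), (1-t)^2)``.

    The four cells are the outcomes of two latent Bernoulli(t) trials with
    the two mixed outcomes kept separate, so the minimum-divergence estimate
    of ``t`` behaves like an allele-frequency estimate from 2n trials.
    """

    def probs(theta):
        t = theta[0]
        return np.array([t * t, t * (1 - t), t * (1 - t), (1 - t) ** 2])

    def probs_batch(thetas):
        t = np.asarray(thetas, dtype=float)
        return np.stack(
            [t * t, t * (1 - t), t * (1 - t), (1 - t) ** 2], axis=-1
        )

    def jacobian(theta):
        t = theta[0]
        return np.array([[2 * t, 1 - 2 * t, 1 - 2 * t, -2 * (1 - t)]])

    def hessians(theta):
        return np.array([2.0, -2.0, -2.0, 2.0]).reshape(4, 1, 1)

    return ParametricModel(
        name="example3-hw", s=1, k=4, lower=[0.0], upper=[1.0],
        probs=probs, jacobian=jacobian, hessians=hessians,
        probs_batch=probs_batch,
    )


# ---------------------------------------------------------------------------
# numeric derivatives
# ---------------------------------------------------------------------------

def numeric_derivatives(model: ParametricModel) -> ParametricModel:
    """Return a copy of ``model`` with missing derivatives filled by central
    differences (step ``max(1e-6, |theta_j| * 1e-6)`` per coordinate).

    Within one step of the domain boundary the difference becomes one-sided
    and a warning is emitted.
    """
    s = model.s

    def steps(theta):
        return np.maximum(1e-6, np.abs(theta) * 1e-6)

    def eval_shift(theta, j, delta):
        t = theta.copy()
        t[j] += delta
        return np.asarray(model.probs(t), dtype=float)

    def d1_coord(theta, j):
        hj = steps(theta)[j]
        lo, hi = model.lower[j], model.upper[j]
        if theta[j] - hj <= lo or theta[j] + hj >= hi:
            warnings.warn(
                f"theta[{j}]={theta[j]} within one step of the boundary of "
                f"{model.name!r}; using a one-sided difference",
                UserWarning, stacklevel=2,
            )
            if theta[j] - hj <= lo:
                return (eval_shift(theta, j, hj) - model.probs(theta)) / hj
            return (model.probs(theta) - eval_shift(theta, j, -hj)) / hj
        return (eval_shift(theta, j, hj) - eval_shift(theta, j, -hj)) / (2 * hj)

    def jacobian(theta):
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        return np.stack([d1_coord(theta, j) for j in range(s)], axis=0)

    def hessians(theta):
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        # wider step than the jacobian: second differences lose ~eps/h^2
        # to roundoff, so 1e-6 would leave only ~4 accurate digits
        h = np.maximum(1e-4, np.abs(theta) * 1e-4)
        k = model.k
        H = np.empty((k, s, s))
        p0 = np.asarray(model.probs(theta), dtype=float)
        for a in range(s):
            for b in range(a, s):
                if a == b:
                    pp = eval_shift(theta, a, h[a])
                    pm = eval_shift(theta, a, -h[a])
                    H[:, a, a] = (pp - 2 * p0 + pm) / h[a] ** 2
                else:
                    tpp = theta.copy(); tpp[[a, b]] += [h[a], h[b]]
                    tpm = theta.copy(); tpm[[a, b]] += [h[a], -h[b]]
                    tmp = theta.copy(); tmp[[a, b]] += [-h[a], h[b]]
                    tmm = theta.copy(); tmm[[a, b]] += [-h[a], -h[b]]
                    mixed = (
                        np.asarray(model.probs(tpp))
                        - np.asarray(model.probs(tpm))
                        - np.asarray(model.probs(tmp))
                        + np.asarray(model.probs(tmm))
                    ) / (4 * h[a] * h[b])
                    H[:, a, b] = H[:, b, a] = mixed
        return H

    return replace(
        model,
        jacobian=model.jacobian if model.jacobian is not None else jacobian,
        hessians=model.hessians if model.hessians is not None else hessians,
    )


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

_REGISTRY: Dict[str, Callable[[], ParametricModel]] = {
    "example1": model_example1,
    "example2": model_example2,
    "example3-hw": model_example3,
}


def get_model(name: str) -> ParametricModel:
    try:
        return _REGISTRY[name]()
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available: {sorted(_REGISTRY)}"
        ) from None


def register_model(name: str, factory: Callable[[], ParametricModel]) -> None:
    _REGISTRY[name] = factory


def available_models() -> list:
    return sorted(_REGISTRY)


def load_models_config(path) -> list:
    """Register user models from a YAML file of symbolic probability
    expressions, e.g.::

        mymodel:
          params: [theta]
          probs: ["theta**2", "2*theta*(1-theta)", "(1-theta)**2"]
          lower: [0.0]
          upper: [1.0]

    Expressions are parsed with sympy and differentiated symbolically, so
    plug-in models get analytic jacobians and Hessians.  Returns the list of
    registered names.
    """
    import sympy as sp
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    names = []
    for name, block in cfg.items():
        syms = sp.symbols(block["params"])
        if not isinstance(syms, (list, tuple)):
            syms = (syms,)
        exprs = [sp.sympify(e) for e in block["probs"]]
        s, k = len(syms), len(exprs)
        f = sp.lambdify(syms, exprs, "numpy")
        jac_exprs = [[sp.diff(e, v) for e in exprs] for v in syms]
        jac_f = sp.lambdify(syms, jac_exprs, "numpy")
        hess_exprs = [
            [[sp.diff(e, va, vb) for vb in syms] for va in syms]
            for e in exprs
        ]
        hess_f = sp.lambdify(syms, hess_exprs, "numpy")

        def make(name=name, f=f, jac_f=jac_f, hess_f=hess_f, s=s, k=k,
                 lower=block["lower"], upper=block["upper"]):
            def factory():
                probs = lambda th: np.asarray(f(*th), dtype=float)
                jacobian = lambda th: np.asarray(jac_f(*th), dtype=float)
                hessians = lambda th: np.asarray(
                    hess_f(*th), dtype=float
                )
                probs_batch = None
                if s == 1:
                    probs_batch = lambda ts: np.stack(
                        np.broadcast_arrays(
                            *[np.asarray(c, dtype=float)
                              for c in f(np.asarray(ts))]
                        ),
                        axis=-1,
                    )
                return ParametricModel(
                    name=name, s=s, k=k, lower=lower, upper=upper,
                    probs=probs, jacobian=jacobian, hessians=hessians,
                    probs_batch=probs_batch,
                )
            return factory

        register_model(name, make())
        names.append(name)
    return names
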