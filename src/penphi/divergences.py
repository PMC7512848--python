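"""Power-divergence generators and (penalized) phi-divergences.

A phi-divergence between probability vectors ``Q`` and ``P`` (``P`` strictly
positive) is ``D_phi(Q, P) = sum_i p_i * phi(q_i / p_i)`` for a strictly
convex generator ``phi`` with ``phi(1) = 0``.  When ``Q`` has empty cells and
``phi(0) = +inf`` (e.g. the modified chi-square generator, ``lambda = -2``),
the divergence is infinite; the *penalized* divergence replaces the weight
``phi(0)`` on empty cells by a finite tuning constant ``h > 0``:

    D_{phi,h}(Q, P) = sum_{i: q_i > 0} p_i phi(q_i/p_i) + h sum_{i: q_i = 0} p_i

which keeps estimation well defined for sparse multinomial data.

The power-divergence family ``PD_lambda`` covers the classical chi-square
statistics: ``lambda = 1`` is Pearson's X^2, ``lambda = 0`` the likelihood
ratio G^2, and ``lambda = -2`` the Neyman (modified) chi-square.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "PhiSpec",
    "ProbabilityVector",
    "PenalizedDivergenceSpec",
    "pd_lambda",
    "power_divergence",
    "generic_phi",
    "divergence",
    "penalized_divergence",
]

_ArrayLike = "np.ndarray | float"


@dataclass(frozen=True)
class PhiSpec:
    """A convex divergence generator with first and second derivatives.

    Attributes
    ----------
    kind : str
        ``"power-divergence"`` or ``"generic"``.
    value, d1, d2 : callables
        ``phi``, ``phi'``, ``phi''`` on ``(0, inf)``; vectorized over arrays.
    value_at_1, d2_at_1 : float
        ``phi(1)`` and ``phi''(1)`` (the normalizations entering the
        goodness-of-fit statistic).
    value_at_0 : float
        ``phi(0)`` as the limit from the right; may be ``+inf``.
    lam : float or None
        Power-divergence index ``lambda`` when ``kind == "power-divergence"``.
    """

    kind: str
    value: Callable[..., np.ndarray]
    d1: Callable[..., np.ndarray]
    d2: Callable[..., np.ndarray]
    value_at_1: float
    d2_at_1: float
    value_at_0: float
    lam: Optional[float] = None
    # stable per-cell contribution p * phi(q/p); generic fallback if None
    _cell_term: Optional[Callable[..., np.ndarray]] = field(
        default=None, repr=False, compare=False
    )

    def cell_term(self, q, p):
        """Per-cell contribution ``p * phi(q/p)`` for ``q > 0``, ``p > 0``.

        Uses algebraically rearranged closed forms for the common power
        indices to avoid cancellation when ``q`` is close to ``p`` and
        overflow when ``p`` is small.
        """
        q = np.asarray(q, dtype=float)
        p = np.asarray(p, dtype=float)
        if self._cell_term is not None:
            return self._cell_term(q, p)
        return p * self.value(q / p)

    def __repr__(self) -> str:  # compact; callables are noise
        if self.kind == "power-divergence":
            return f"PhiSpec(power-divergence, lambda={self.lam})"
        return "PhiSpec(generic)"


def pd_lambda(lam: float, x) -> "np.ndarray | float":
    """Evaluate the power-divergence generator ``PD_lambda`` at ``x > 0``.

    ``PD_lambda(x) = (x^(lambda+1) - x - lambda(x-1)) / (lambda(lambda+1))``
    for ``lambda`` outside ``{0, -1}``, with the continuous limits
    ``PD_0(x) = x log x - x + 1`` and ``PD_-1(x) = -log x + x - 1``.

    Nonnegative, zero exactly at ``x = 1``.
    """
    if not np.isfinite(lam):
        raise ValueError(f"lambda must be finite, got {lam}")
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)) or np.any(x <= 0):
        raise ValueError("pd_lambda requires finite x > 0")
    if lam == 0:
        out = x * np.log(x) - x + 1.0
    elif lam == -1:
        out = -np.log(x) + x - 1.0
    else:
        out = (x ** (lam + 1.0) - x - lam * (x - 1.0)) / (lam * (lam + 1.0))
    return out if out.ndim else float(out)


def _power_cell_term(lam: float):
    """Stable closed form for ``p * PD_lambda(q/p)`` at the common indices."""
    if lam == 1:
        return lambda q, p: (q - p) ** 2 / (2.0 * p)
    if lam == -2:
        return lambda q, p: (q - p) ** 2 / (2.0 * q)
    if lam == 0:
        return lambda q, p: q * np.log(q / p) - q + p
    if lam == -1:
        return lambda q, p: p * np.log(p / q) + q - p
    if lam == 2:
        return lambda q, p: (q - p) ** 2 * (q + 2.0 * p) / (6.0 * p ** 2)
    c = lam * (lam + 1.0)
    return lambda q, p: p * (
        (q / p) ** (lam + 1.0) - q / p - lam * (q / p - 1.0)
    ) / c


def power_divergence(lam: float) -> PhiSpec:
    """Build the :class:`PhiSpec` for the power-divergence index ``lam``.

    ``phi(0)`` is the right limit: ``1/(lam+1)`` for ``lam > -1``
    (``lam != 0``), ``1`` for ``lam = 0``, ``+inf`` for ``lam <= -1``.
    """
    if not np.isfinite(lam):
        raise ValueError(f"lambda must be finite, got {lam}")
    if lam == 0:
        value = lambda x: x * np.log(x) - x + 1.0
        d1 = np.log
        d2 = lambda x: 1.0 / x
        value_at_0 = 1.0
    elif lam == -1:
        value = lambda x: -np.log(x) + x - 1.0
        d1 = lambda x: 1.0 - 1.0 / x
        d2 = lambda x: x ** -2.0
        value_at_0 = math.inf
    else:
        c = lam * (lam + 1.0)
        value = lambda x: (x ** (lam + 1.0) - x - lam * (x - 1.0)) / c
        d1 = lambda x: (x ** lam - 1.0) / lam
        d2 = lambda x: x ** (lam - 1.0)
        value_at_0 = 1.0 / (lam + 1.0) if lam > -1 else math.inf
    return PhiSpec(
        kind="power-divergence",
        value=value,
        d1=d1,
        d2=d2,
        value_at_1=0.0,
        d2_at_1=1.0,
        value_at_0=value_at_0,
        lam=lam,
        _cell_term=_power_cell_term(lam),
    )


def generic_phi(
    value: Callable,
    d1: Callable,
    d2: Callable,
    value_at_1: float,
    d2_at_1: float,
    value_at_0: float = math.inf,
) -> PhiSpec:
    """Wrap a user-supplied generator as a :class:`PhiSpec`.

    Strict convexity (``phi'' > 0``) cannot be proven mechanically; it is
    spot-checked on a log-spaced grid and a warning (not an error) is issued
    on violation.
    """
    probe = np.logspace(-3, 3, 25)
    if np.any(np.asarray(d2(probe)) <= 0):
        warnings.warn(
            "supplied phi'' is not positive on a log-spaced probe grid; "
            "strict convexity is required for the asymptotic theory",
            UserWarning,
            stacklevel=2,
        )
    return PhiSpec(
        kind="generic",
        value=value,
        d1=d1,
        d2=d2,
        value_at_1=float(value_at_1),
        d2_at_1=float(d2_at_1),
        value_at_0=float(value_at_0),
    )


@dataclass(frozen=True)
class ProbabilityVector:
    """A point of the closed probability simplex, with its support recorded.

    Zero entries are detected by exact equality: empty multinomial cells are
    exact zeros (``X_i = 0`` implies ``X_i / n == 0.0`` in floating point),
    and the penalty term of the penalized divergence is defined on them.
    """

    entries: np.ndarray
    positive_mask: np.ndarray
    m: int

    @classmethod
    def from_array(cls, a, check: bool = True) -> "ProbabilityVector":
        a = np.asarray(a, dtype=float)
        if check:
            if a.ndim != 1 or a.size < 2:
                raise ValueError("probability vector must be 1-D with k >= 2")
            if np.any(a < 0) or not np.all(np.isfinite(a)):
                raise ValueError("probabilities must be finite and >= 0")
            if abs(a.sum() - 1.0) > 1e-12:
                raise ValueError(
                    f"probabilities must sum to 1 (got {a.sum()!r})"
                )
        mask = a > 0
        return cls(entries=a, positive_mask=mask, m=int(mask.sum()))

    @property
    def k(self) -> int:
        return self.entries.size

    def __len__(self) -> int:
        return self.entries.size


@dataclass(frozen=True)
class PenalizedDivergenceSpec:
    """A generator paired with its empty-cell penalty ``h > 0``."""

    phi: PhiSpec
    h: float

    def __post_init__(self):
        if not np.isfinite(self.h) or self.h <= 0:
            raise ValueError(f"penalty h must be finite and > 0, got {self.h}")

    def __call__(self, Q, P) -> float:
        return penalized_divergence(Q, P, self.phi, self.h)


def _as_entries(v) -> np.ndarray:
    if isinstance(v, ProbabilityVector):
        return v.entries
    return np.asarray(v, dtype=float)


def _check_pair(q: np.ndarray, p: np.ndarray) -> None:
    if q.shape != p.shape:
        raise ValueError(f"length mismatch: Q has {q.shape}, P has {p.shape}")
    if np.any(p <= 0):
        raise ValueError("P must be strictly positive in every cell")


def divergence(Q, P, phi: PhiSpec) -> float:
    """Unpenalized phi-divergence ``sum_i p_i phi(q_i / p_i)``.

    Returns ``+inf`` when ``phi(0) = +inf`` and ``Q`` has an empty cell.
    """
    q, p = _as_entries(Q), _as_entries(P)
    _check_pair(q, p)
    pos = q > 0
    total = float(np.sum(phi.cell_term(q[pos], p[pos])))
    zero_weight = float(np.sum(p[~pos]))
    if zero_weight > 0:
        if math.isinf(phi.value_at_0):
            return math.inf
        total += phi.value_at_0 * zero_weight
    return total


def penalized_divergence(Q, P, phi: PhiSpec, h: float) -> float:
    """Penalized phi-divergence ``D_{phi,h}(Q, P)``; always finite.

    Equals :func:`divergence` whenever ``Q`` has no empty cell (the penalty
    term is then an empty sum, so the value does not depend on ``h``).
    """
    if not np.isfinite(h):
        raise ValueError(f"penalty h must be finite, got {h}")
    q, p = _as_entries(Q), _as_entries(P)
    _check_pair(q, p)
    pos = q > 0
    return float(np.sum(phi.cell_term(q[pos], p[pos])) + h * np.sum(p[~pos]))


def penalized_divergence_batch(
    Q: np.ndarray, P: np.ndarray, phi: PhiSpec, h: float
) -> np.ndarray:
    """Row-wise ``D_{phi,h}`` for stacked vectors ``Q, P`` of shape (R, k).

    Vectorized workhorse behind the simulation and bootstrap loops; empty
    cells are exact zeros of ``Q``.
    """
    pos = Q > 0
    q_safe = np.where(pos, Q, 1.0)  # masked out below; avoids 0-division
    terms = np.where(pos, phi.cell_term(q_safe, P), h * P)
    return terms.sum(axis=-1)
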