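"""Slice-within-Gibbs machinery for the hierarchical Cauchy models.

The models in :mod:`ithshift.models` decompose into blocks whose elements are
conditionally independent given the rest (per-observation residuals, per-case
locations and scales, per-group means), so each Gibbs sweep applies a
univariate slice sampler (Neal 2003: stepping-out then shrinkage) to every
block, vectorized over the block's elements. Heavy-tailed Cauchy conditionals
are exactly the case slice sampling handles without tuning, which is why it
is preferred here over random-walk Metropolis.

Also provides the Gelman–Rubin potential scale reduction factor used as the
convergence diagnostic.
"""

from __future__ import annotations

from typing import Callable, Dict, Union

import numpy as np

__all__ = [
    "cauchy_logpdf",
    "half_cauchy_logpdf",
    "slice_sample",
    "gelman_rubin",
]

_LOG_PI = float(np.log(np.pi))


def cauchy_logpdf(x, loc, scale):
    """Elementwise Cauchy log-density (no normalization dropped)."""
    z = (np.asarray(x, dtype=float) - loc) / scale
    return -_LOG_PI - np.log(scale) - np.log1p(z * z)


def half_cauchy_logpdf(x, scale):
    """Half-Cauchy (location 0) log-density; -inf for x <= 0."""
    x = np.asarray(x, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = x / scale
        out = np.log(2.0) - _LOG_PI - np.log(scale) - np.log1p(z * z)
    return np.where(x > 0, out, -np.inf)


def slice_sample(
    x0: np.ndarray,
    logp: Callable[[np.ndarray], np.ndarray],
    rng: np.random.Generator,
    width: float = 1.0,
    max_stepout: int = 30,
    max_shrink: int = 200,
) -> np.ndarray:
    """One slice-sampling update of a vector of independent conditionals.

    ``logp`` must return, for a full candidate vector, the per-element
    conditional log-density (an array of the same shape). All elements are
    updated simultaneously; interactions between elements must be absent
    from their conditionals, which the callers guarantee by construction.

    Shrinkage makes the update unconditionally valid even if stepping-out is
    truncated; if shrinkage itself exhausts its budget (pathological
    conditionals) the current value is kept, which preserves detailed balance.
    """
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    shape = x0.shape
    lp0 = np.asarray(logp(x0), dtype=float)
    if lp0.shape != shape:
        raise ValueError("logp must return one value per element")
    if not np.all(np.isfinite(lp0)):
        raise FloatingPointError("slice_sample started from a zero-density point")

    # vertical level, in log space
    y = lp0 + np.log1p(-rng.random(shape))

    u = rng.random(shape)
    left = x0 - width * u
    right = left + width
    for _ in range(max_stepout):
        grow = logp(left) > y
        if not grow.any():
            break
        left = np.where(grow, left - width, left)
    for _ in range(max_stepout):
        grow = logp(right) > y
        if not grow.any():
            break
        right = np.where(grow, right + width, right)

    x1 = x0.copy()
    active = np.ones(shape, dtype=bool)
    for _ in range(max_shrink):
        prop = left + rng.random(shape) * (right - left)
        lp = logp(prop)
        accept = active & (lp >= y)
        x1[accept] = prop[accept]
        active &= ~accept
        if not active.any():
            break
        low = active & (prop < x0)
        high = active & ~low
        left[low] = prop[low]
        right[high] = prop[high]
    return x1


def _psrf(chains: np.ndarray, split: bool) -> float:
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise ValueError("expected draws with shape (n_chains, n_draws)")
    m, n = chains.shape
    if m < 2:
        raise ValueError("Gelman-Rubin diagnostic needs at least two chains")
    if split:
        half = n // 2
        if half < 2:
            raise ValueError("too few draws to split chains")
        chains = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
        m, n = chains.shape
    means = chains.mean(axis=1)
    variances = chains.var(axis=1, ddof=1)
    w = variances.mean()
    b = n * means.var(ddof=1)
    if w == 0.0:
        return 1.0 if b == 0.0 else float("inf")
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def gelman_rubin(
    draws: Union[np.ndarray, Dict[str, np.ndarray]], split: bool = True
) -> Union[float, Dict[str, np.ndarray]]:
    """Potential scale reduction factor, R-hat.

    ``draws`` is either a ``(n_chains, n_draws)`` array (returns a float) or,
    for convenience, a mapping name -> ``(n_chains, n_draws[, n_groups])``
    array (returns a mapping of the same shape minus the chain/draw axes).
    Values near 1 indicate converged chains. By default chains are split in
    half so that within-chain drift also inflates the statistic.
    """
    if isinstance(draws, dict):
        out: Dict[str, np.ndarray] = {}
        for name, arr in draws.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 2:
                out[name] = np.asarray(_psrf(arr, split))
            elif arr.ndim == 3:
                out[name] = np.array(
                    [_psrf(arr[:, :, g], split) for g in range(arr.shape[2])]
                )
            else:
                raise ValueError(f"cannot interpret draws for {name!r}")
        return out
    return _psrf(np.asarray(draws), split)
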