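"""Branch-probability estimation from observed trial counts.

Chance-node probabilities in a trial-based decision tree come from the
numbers of patients observed to take each branch.  Two point-estimation
regimes are supported:

``mle``
    Maximum likelihood: ``p_i = x_i / n``.  This is the conventional
    base-case rule (e.g. 3 of 15 pregnancies lost before 24 weeks gives
    0.2 / 0.8).

``uniform_prior``
    Posterior mean under a flat Dirichlet(1, ..., 1) prior:
    ``p_i = (x_i + 1) / (n + K)`` for K categories.  With no data this
    is the uniform distribution; it shrinks small-sample estimates away
    from 0 and 1, which matters in a 31-patient trial where several
    branches have zero observed events.

For probabilistic sensitivity analysis the same counts parameterise a
Dirichlet posterior (Beta in the two-branch case) from which whole
probability vectors are drawn.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "mle_probs",
    "uniform_prior_probs",
    "dirichlet_alpha",
    "sample_probs",
    "sample_probs_matrix",
]

#: Sampling regimes accepted by :func:`dirichlet_alpha` and friends.
SAMPLING_REGIMES = ("mle_centred", "uniform_prior", "auto")


def _as_counts(counts) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("count vector must be 1-D with at least 2 categories")
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValueError("counts must be finite and non-negative")
    if np.any(arr != np.floor(arr)):
        raise ValueError("counts must be integers")
    return arr


def mle_probs(counts) -> np.ndarray:
    """Maximum-likelihood branch probabilities ``x_i / n``.

    Raises
    ------
    ValueError
        If the counts sum to zero ("no observations at node").
    """
    arr = _as_counts(counts)
    n = arr.sum()
    if n == 0:
        raise ValueError("no observations at node")
    return arr / n


def uniform_prior_probs(counts) -> np.ndarray:
    """Posterior-mean probabilities ``(x_i + 1) / (n + K)`` under a flat
    Dirichlet prior.  Defined for all-zero counts (returns uniform)."""
    arr = _as_counts(counts)
    return (arr + 1.0) / (arr.sum() + arr.size)


def dirichlet_alpha(counts, regime: str = "mle_centred") -> np.ndarray:
    """Dirichlet concentration parameters for PSA sampling.

    ``mle_centred`` uses alpha = counts (mean = the MLE), and rejects
    zero counts because Dirichlet(alpha) is undefined at alpha_i = 0;
    switch that node to the ``uniform_prior`` regime or fix its
    probabilities instead.  ``uniform_prior`` uses alpha = counts + 1.
    ``auto`` is mle-centred where every count is positive and falls back
    to counts + 1 at nodes containing zeros.
    """
    arr = _as_counts(counts)
    if regime == "mle_centred":
        if np.any(arr == 0):
            raise ValueError(
                "zero count under the mle-centred regime: Dirichlet(alpha) is "
                "undefined at alpha_i = 0; use the uniform_prior regime or a "
                "fixed probability vector for this node"
            )
        return arr
    if regime == "uniform_prior":
        return arr + 1.0
    if regime == "auto":
        return arr if np.all(arr > 0) else arr + 1.0
    raise ValueError(f"unknown sampling regime {regime!r}")


def sample_probs(counts, regime: str = "mle_centred", rng=None) -> np.ndarray:
    """Draw one probability vector from the Dirichlet posterior.

    ``rng`` may be a :class:`numpy.random.Generator` or an integer seed;
    identical seeds give identical draws.  The two-category case is the
    Beta distribution (a Dirichlet(a, b) first component is Beta(a, b)).
    """
    return sample_probs_matrix(counts, regime=regime, n=1, rng=rng)[0]


def sample_probs_matrix(counts, regime: str = "mle_centred", n: int = 1, rng=None) -> np.ndarray:
    """Draw ``n`` probability vectors as an (n, K) array (vectorised PSA)."""
    alpha = dirichlet_alpha(counts, regime)
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    return gen.dirichlet(alpha, size=int(n))
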