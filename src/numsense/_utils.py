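"""Small shared helpers: seeding, truncated normals, validation."""

from __future__ import annotations

import numpy as np
from scipy import stats

MAX_SEED = 2**31 - 1


def rng_from(seed) -> np.random.Generator:
    """Coerce an int seed, SeedSequence, or Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Fan a single master seed out into ``n`` independent child seeds.

    Children are drawn through a SeedSequence so stages stay statistically
    independent while the whole run remains reproducible from one integer.
    """
    ss = np.random.SeedSequence(seed)
    return [int(s) % MAX_SEED for s in ss.generate_state(n)]


def trunc_normal(rng: np.random.Generator, mean, sigma, size) -> np.ndarray:
    """Draw from a normal truncated at zero (activations are non-negative)."""
    mean = np.asarray(mean, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    a = (0.0 - mean) / sigma  # lower bound in standard units
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sigma,
                               size=size, random_state=rng)


def trunc_normal_moments(mean, sigma):
    """Exact (mean, std) of a normal truncated at zero."""
    mean = np.asarray(mean, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    a = (0.0 - mean) / sigma
    m = stats.truncnorm.mean(a, np.inf, loc=mean, scale=sigma)
    s = stats.truncnorm.std(a, np.inf, loc=mean, scale=sigma)
    return m, s
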