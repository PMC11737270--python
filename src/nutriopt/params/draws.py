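"""Monte Carlo draw generation.

Every parameter carrying a 95% interval (the antenatal effect table and the
baseline coverages) is resampled independently per draw: mean differences
from a (split-)normal on the natural scale, relative risks from a
(split-)normal on the log scale.  Draw 0 is the point-estimate set, matching
the convention that the first draw reproduces the central run.  The same
draw index is used with identical parameters in every scenario, so scenario
contrasts are computed within draws.
"""

from __future__ import annotations

import copy

import numpy as np

from .model import ParameterDraw, Uncertain, iter_uncertain


def generate_draws(
    base: ParameterDraw,
    n_draws: int,
    seed: int,
    include_point: bool = True,
) -> list[ParameterDraw]:
    """Return ``n_draws`` parameter sets sampled around ``base``.

    Parameters
    ----------
    base
        The point-estimate parameter set.  Its :class:`Uncertain` fields
        define the sampling intervals.
    n_draws
        Number of draws (>= 1).
    seed
        Seed for the sampling stream; a fixed seed is bit-reproducible.
    include_point
        If true (default), draw 0 is ``base`` itself.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    for path, u in iter_uncertain(base):
        if u.has_interval() and u.lo > u.hi:
            raise ValueError(f"inverted interval bounds at {path}")

    rng = np.random.default_rng(seed)
    draws: list[ParameterDraw] = []
    for k in range(n_draws):
        if k == 0 and include_point:
            d = copy.deepcopy(base)
            d.label = f"{base.label}/draw0"
            draws.append(d)
            continue
        d = copy.deepcopy(base)
        for path, u in iter_uncertain(d):
            if not u.has_interval():
                continue
            x = u.sample(rng)
            if path.startswith("coverage.baseline"):
                x = float(np.clip(x, 0.0, 1.0))
            u.value = x
        d.label = f"{base.label}/draw{k}"
        draws.append(d)
    return draws


def sample_uncertain(u: Uncertain, n: int, seed: int) -> np.ndarray:
    """Vector of ``n`` independent samples from one uncertain parameter."""
    rng = np.random.default_rng(seed)
    return np.array([u.sample(rng) for _ in range(n)])
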