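"""Seeded random parameter draws over the biologically relevant region.

The region operationalises "biologically relevant parameter values" for the
sweep-style checks (uniqueness, determinant positivity, sign structure):
log-uniform draws with eta4 in (1e-4, 1/9), eta2 in (1e-5, eta4) so that a
positive dimensional origin exists, eta3 in (1e-3, 10) and eta1 in
(1e-3, 10). All draws go through a caller-supplied seed or generator.
"""

from __future__ import annotations

import numpy as np

from .params import DimensionlessParams

__all__ = ["sample_dimensionless", "sample_dimensionless_arrays"]


def _log_uniform(rng, lo, hi, n):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))


def sample_dimensionless_arrays(n: int, seed=None) -> tuple[np.ndarray, ...]:
    """(eta1, eta2, eta3, eta4) arrays of n draws from the region above."""
    rng = np.random.default_rng(seed)
    eta4 = _log_uniform(rng, 1e-4, 1.0 / 9.0, n)
    eta2 = np.exp(rng.uniform(np.log(1e-5), np.log(eta4)))
    eta3 = _log_uniform(rng, 1e-3, 10.0, n)
    eta1 = _log_uniform(rng, 1e-3, 10.0, n)
    return eta1, eta2, eta3, eta4


def sample_dimensionless(n: int, seed=None) -> list[DimensionlessParams]:
    """n validated DimensionlessParams draws (convenience wrapper)."""
    return [
        DimensionlessParams(*vals)
        for vals in zip(*sample_dimensionless_arrays(n, seed))
    ]
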