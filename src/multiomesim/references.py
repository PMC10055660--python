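"""Reference kinetic-parameter pools used for rank-based scaling.

The simulator never uses the raw CIF x GIV products directly as kinetic
parameters; it maps them, rank for rank, onto draws from an empirical
reference pool so that the marginal distribution of k_on, k_off, s (and of
the accessibility matrix) looks like plausible single-cell data.

The pools shipped here are *synthetic*: log-normal samples with a distinct,
fixed shape per parameter (and a zero-inflated pool for accessibility),
generated deterministically from fixed internal seeds. Any user-supplied
positive sample pool can be used instead — rank scaling only consumes an
empirical sample, not a parametric family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: fixed internal seeds — the pools are a versioned part of the package
_POOL_SEEDS = {"kon": 7001, "koff": 7002, "s": 7003, "atac": 7004}
_POOL_SIZE = 20000

# log-normal shape per kinetic parameter (log-mean, log-sd). Chosen so that
# with d = 1 the stationary burst fraction k_on/(k_on+k_off) has median ~0.3
# and mean expression s * k_on/(k_on+k_off) is a few counts — sparse but not
# empty count matrices, as in typical UMI data.
_LOGNORMAL_SHAPES = {
    "kon": (-1.0, 1.0),
    "koff": (0.5, 1.0),
    "s": (3.0, 1.0),
}
#: zero fraction of the accessibility pool (open chromatin is the exception)
_ATAC_ZERO_FRAC = 0.7
_ATAC_SHAPE = (0.5, 1.0)


@dataclass(frozen=True)
class ReferenceDistribution:
    """An empirical sample pool to draw ordered values from."""

    name: str
    samples: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 1 or s.size == 0:
            raise ValueError("reference samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(s)):
            raise ValueError("reference samples must be finite")
        if np.any(s < 0):
            raise ValueError("reference samples must be non-negative")
        if self.name in ("kon", "koff", "s") and np.any(s <= 0):
            raise ValueError(f"'{self.name}' samples must be strictly positive")
        object.__setattr__(self, "samples", s)

    @property
    def zero_fraction(self) -> float:
        return float(np.mean(self.samples == 0))


def builtin_reference(name: str, size: int = _POOL_SIZE) -> ReferenceDistribution:
    """Return the packaged synthetic reference pool for ``name``.

    ``name`` must be one of ``kon``, ``koff``, ``s``, ``atac``. The pools
    are generated from fixed seeds, so repeated calls are bit-identical.
    """
    if name not in _POOL_SEEDS:
        raise ValueError(
            f"unknown reference '{name}'; expected one of "
            f"{sorted(_POOL_SEEDS)}")
    rng = np.random.default_rng(_POOL_SEEDS[name])
    if name == "atac":
        vals = np.exp(rng.normal(*_ATAC_SHAPE, size=size))
        zero = rng.random(size) < _ATAC_ZERO_FRAC
        vals[zero] = 0.0
        return ReferenceDistribution("atac", vals)
    mu, sd = _LOGNORMAL_SHAPES[name]
    return ReferenceDistribution(name, np.exp(rng.normal(mu, sd, size=size)))
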