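"""Chromatin accessibility generation and rank-based scaling.

The accessibility matrix is the product of the k_on cell-identity factors
with region identity vectors, mapped rank-for-rank onto draws from an
empirical accessibility pool (so its marginal distribution, including the
zero excess, matches the reference), plus a small truncated Gaussian
intrinsic noise. A binary region-to-gene matrix links each gene to 1-3
consecutive regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .references import ReferenceDistribution

__all__ = [
    "rank_scale",
    "QuantileScaler",
    "generate_atac",
    "build_region_to_gene",
]


def rank_scale(x: np.ndarray, pool: np.ndarray, rng: np.random.Generator,
               key: Optional[np.ndarray] = None) -> np.ndarray:
    """Replace the values of ``x`` by order statistics from ``pool``.

    ``n = x.size`` values are drawn from the pool (with replacement),
    sorted, and written back in the rank order of ``x`` (or of ``key`` when
    given), so ranks are preserved exactly and the output marginal matches
    the pool. Ties are broken by stable flattened index order.
    """
    pool = np.asarray(pool, dtype=float)
    flat = np.asarray(x, dtype=float).ravel() if key is None \
        else np.asarray(key, dtype=float).ravel()
    draws = np.sort(rng.choice(pool, size=flat.size, replace=True))
    order = np.argsort(flat, kind="stable")
    out = np.empty(flat.size)
    out[order] = draws
    return out.reshape(np.shape(x))


class QuantileScaler:
    """A frozen monotone map from a raw-value distribution onto a pool.

    Fit once on a representative raw matrix: it records matched quantiles of
    the raw values and of sorted pool draws, and then transforms any array
    by monotone interpolation. Used where values must be scaled row-by-row
    (sequential cell simulation) while keeping one global distribution
    match; for a full matrix it agrees with :func:`rank_scale` up to
    interpolation at repeated values.
    """

    def __init__(self, raw: np.ndarray, pool: np.ndarray,
                 rng: np.random.Generator):
        raw = np.asarray(raw, dtype=float).ravel()
        draws = np.sort(rng.choice(np.asarray(pool, dtype=float),
                                   size=raw.size, replace=True))
        self._xs = np.sort(raw)
        self._ys = draws

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.interp(x, self._xs, self._ys,
                         left=self._ys[0], right=self._ys[-1])


def generate_atac(cif_kon: np.ndarray, riv: np.ndarray,
                  atac_reference: ReferenceDistribution,
                  rng: np.random.Generator,
                  noise_sd: Optional[float] = None) -> np.ndarray:
    """cells x regions accessibility: CIF x RIV, rank-scaled to the
    reference pool, plus truncated Gaussian intrinsic noise.

    ``noise_sd`` defaults to 5% of the pool's standard deviation; noise
    never pushes entries below zero.
    """
    if cif_kon.shape[1] != riv.shape[0]:
        raise ValueError("CIF width and RIV width disagree")
    pool = atac_reference.samples
    raw = cif_kon @ riv
    scaled = rank_scale(raw, pool, rng)
    if noise_sd is None:
        noise_sd = 0.05 * float(pool.std())
    if noise_sd > 0:
        # noise perturbs open regions only; closed chromatin stays closed,
        # preserving the reference zero fraction
        open_mask = scaled > 0
        noise = rng.normal(0.0, noise_sd, size=scaled.shape)
        scaled = np.where(open_mask, scaled + noise, scaled)
        np.clip(scaled, 0.0, None, out=scaled)
    return scaled


def build_region_to_gene(n_region: int, n_gene: int,
                         region_dist: Sequence[float],
                         rng: np.random.Generator) -> np.ndarray:
    """Binary n_region x n_gene matrix Z.

    For each gene a region count k in {1..len(region_dist)} is drawn from
    ``region_dist`` and k consecutive regions are assigned; genes claim
    consecutive region blocks left to right in gene order, so assignments
    never overlap. Leftover regions stay gene-free (they still carry
    accessibility signal).
    """
    region_dist = np.asarray(region_dist, dtype=float)
    if region_dist.ndim != 1 or not np.isclose(region_dist.sum(), 1.0):
        raise ValueError("region_dist must be a probability vector")
    ks = rng.choice(np.arange(1, region_dist.size + 1), size=n_gene,
                    p=region_dist)
    if ks.sum() > n_region:
        raise ValueError(
            f"n_region={n_region} too small to host {int(ks.sum())} "
            f"region-gene assignments")
    Z = np.zeros((n_region, n_gene), dtype=np.int8)
    start = 0
    for g, k in enumerate(ks):
        Z[start:start + k, g] = 1
        start += k
    return Z
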