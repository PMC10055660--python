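"""Kinetic-parameter assembly and count generation.

Expression follows the two-state promoter model: a gene switches on at rate
k_on and off at rate k_off, synthesises mRNA at rate s while on, and
transcripts degrade at rate d. The stationary count law of this model is
the Beta-Poisson mixture, used for fast "true count" generation; the full
kinetic model integrates the on/off dynamics explicitly and yields spliced
and unspliced counts plus ground-truth RNA velocity v = beta*xu - d*xs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.stats import rankdata
from sklearn.neighbors import NearestNeighbors

from .atac import rank_scale
from .references import ReferenceDistribution

__all__ = [
    "assemble_kon",
    "assemble_koff",
    "assemble_s",
    "sample_true_counts",
    "theoretical_mean",
    "FullKineticState",
    "init_kinetic_state",
    "simulate_full_kinetic",
    "knn_average_velocity",
]

#: cap on integration steps per gene cycle; protects against extreme
#: k_on/k_off ratios drawn from the log-normal pool tails
MAX_KINETIC_STEPS = 100


def assemble_kon(raw_kon: np.ndarray, atac: np.ndarray, Z: np.ndarray,
                 kon_reference: ReferenceDistribution, E_a: float,
                 rng: np.random.Generator, B: float = 0.0) -> np.ndarray:
    """Promoter activation rate with chromatin-accessibility coupling.

    The accessibility channel is ``atac @ Z`` (per-gene accessibility mass);
    its zero entries are backfilled with the CIF-derived channel ``raw_kon``
    rescaled below the smallest non-zero accessibility value, so closed
    chromatin still yields ordered (but uniformly small) activation. The
    two channels are combined as a convex blend of their ranks with weight
    ``E_a`` on accessibility, then rank-scaled onto the k_on reference pool
    and divided by (1 + B).
    """
    if not 0 <= E_a <= 1:
        raise ValueError("E_a must be in [0, 1]")
    if raw_kon.shape[0] != atac.shape[0]:
        raise ValueError("cell counts disagree")
    m1p = atac @ Z                        # accessibility channel
    m1p = _backfill_zeros(m1p, raw_kon)
    r_atac = rankdata(m1p.ravel(), method="ordinal")
    r_cif = rankdata(raw_kon.ravel(), method="ordinal")
    blended = (E_a * r_atac + (1.0 - E_a) * r_cif).reshape(raw_kon.shape)
    kon = rank_scale(raw_kon, kon_reference.samples, rng, key=blended)
    return kon / (1.0 + B)


def _backfill_zeros(m1p: np.ndarray, m1: np.ndarray) -> np.ndarray:
    """Replace zeros of the accessibility channel by the CIF channel,
    monotonically mapped into (0, min nonzero of the accessibility channel)."""
    out = m1p.astype(float).copy()
    zero = out == 0
    if not zero.any():
        return out
    vals = m1[zero]
    if zero.all():
        ceiling = 1.0
    else:
        ceiling = 0.9 * out[~zero].min()
    lo, hi = vals.min(), vals.max()
    span = hi - lo
    if span == 0:
        out[zero] = 0.5 * ceiling
    else:
        # affine map to (~0, ceiling]; strictly below any open-chromatin value
        out[zero] = (vals - lo) / span * ceiling * 0.999 + 1e-12
    return out


def assemble_koff(raw_koff: np.ndarray,
                  koff_reference: ReferenceDistribution, B: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Rank-scale the raw k_off channel onto the reference pool and divide
    by (1 + B); larger B downscales switching rates, increasing
    bimodality."""
    if B < 0:
        raise ValueError("B must be >= 0")
    return rank_scale(raw_koff, koff_reference.samples, rng) / (1.0 + B)


def assemble_s(raw_s: np.ndarray, s_reference: ReferenceDistribution,
               scale_s: float, rng: np.random.Generator) -> np.ndarray:
    """Rank-scale the raw synthesis-rate channel onto the reference pool
    and multiply by the cell-size factor ``scale_s``."""
    if scale_s <= 0:
        raise ValueError("scale_s must be > 0")
    return rank_scale(raw_s, s_reference.samples, rng) * scale_s


def theoretical_mean(kon: np.ndarray, koff: np.ndarray,
                     s: np.ndarray) -> np.ndarray:
    """Stationary mean expression s * k_on / (k_on + k_off)."""
    return s * kon / (kon + koff)


def sample_true_counts(kon: np.ndarray, koff: np.ndarray, s: np.ndarray,
                       sigma_i: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Beta-Poisson expression with tunable intrinsic noise.

    Per entry: y ~ Beta(k_on, k_off), x ~ Poisson(y * s). The output is
    ``sigma_i * x + (1 - sigma_i) * s * k_on/(k_on+k_off)`` — at sigma_i = 0
    the deterministic stationary mean, at sigma_i = 1 a pure sample
    (real-valued in between).
    """
    if not 0 <= sigma_i <= 1:
        raise ValueError("sigma_i must be in [0, 1]")
    for name, arr in (("kon", kon), ("koff", koff), ("s", s)):
        bad = ~np.isfinite(arr) | (np.asarray(arr) <= 0)
        if np.any(bad):
            idx = np.argwhere(bad)[0]
            raise ValueError(
                f"non-finite or non-positive {name} at index {tuple(idx)}")
    mean = theoretical_mean(kon, koff, s)
    if sigma_i == 0:
        return mean.astype(float)
    y = rng.beta(kon, koff)
    x = rng.poisson(y * s).astype(float)
    return sigma_i * x + (1.0 - sigma_i) * mean


@dataclass
class FullKineticState:
    """Spliced/unspliced counts and promoter state carried between cells."""

    xs: np.ndarray
    xu: np.ndarray
    on: np.ndarray              # boolean promoter state per gene


def init_kinetic_state(kon: np.ndarray, koff: np.ndarray, s: np.ndarray,
                       beta: np.ndarray, d: np.ndarray,
                       rng: np.random.Generator,
                       steady_state_init: bool = False) -> FullKineticState:
    """Initial counts for a root cell.

    Default initialisation puts the splicing rate in the spliced numerator
    and the degradation rate in the unspliced numerator (xs = s*k_on*beta /
    (k_on+k_off), xu = s*k_on*d / (k_on+k_off)); ``steady_state_init``
    switches to the stationary alternative with the rates in the
    denominators.
    """
    frac = kon / (kon + koff)
    if steady_state_init:
        xs = s * frac / d
        xu = s * frac / beta
    else:
        xs = s * frac * beta
        xu = s * frac * d
    on = rng.random(kon.shape) < frac
    return FullKineticState(xs.astype(float), xu.astype(float), on)


def cycle_length_and_steps(kon: np.ndarray, koff: np.ndarray,
                           eta_L: float = 1.0
                           ) -> Tuple[np.ndarray, np.ndarray]:
    """Promoter cycle length L = eta_L * (1/k_on + 1/k_off) and the step
    count m = ceil(L / min(1/k_on, 1/k_off)), capped at
    ``MAX_KINETIC_STEPS``."""
    L = eta_L * (1.0 / kon + 1.0 / koff)
    m = np.ceil(L / np.minimum(1.0 / kon, 1.0 / koff)).astype(int)
    return L, np.minimum(np.maximum(m, 1), MAX_KINETIC_STEPS)


def simulate_full_kinetic(kon: np.ndarray, koff: np.ndarray, s: np.ndarray,
                          beta: np.ndarray, d: np.ndarray, eta_L: float,
                          state: FullKineticState,
                          rng: np.random.Generator
                          ) -> Tuple[np.ndarray, np.ndarray, np.ndarray,
                                     FullKineticState]:
    """One cell's promoter cycle under the full kinetic model (vectorised
    over genes).

    Starting from ``state`` (the predecessor cell's counts), the promoter
    switches stochastically with per-step probabilities p_on = k_on * L / m
    and p_off = k_off * L / m (clipped to [0, 1]) and counts follow Euler
    updates with step size L/m:

        xs <- xs + (L/m) (beta*xu - d*xs)
        xu <- xu + (L/m) (s - beta*xu)     while on
        xu <- xu - (L/m) beta*xu           while off

    Counts are clamped at zero each step. Returns the step-m spliced and
    unspliced counts, the velocity v = beta*xu - d*xs, and the final state.
    """
    kon, koff, s = (np.asarray(a, dtype=float) for a in (kon, koff, s))
    L, m = cycle_length_and_steps(kon, koff, eta_L)
    dt = L / m
    p_on = np.clip(kon * L / m, 0.0, 1.0)
    p_off = np.clip(koff * L / m, 0.0, 1.0)
    xs = state.xs.copy()
    xu = state.xu.copy()
    on = state.on.copy()
    max_m = int(m.max())
    for t in range(1, max_m + 1):
        active = t <= m
        u = rng.random(kon.shape)
        switch_on = ~on & (u < p_on)
        switch_off = on & (u < p_off)
        on = np.where(active, (on | switch_on) & ~switch_off, on)
        new_xs = xs + dt * (beta * xu - d * xs)
        new_xu = np.where(on, xu + dt * (s - beta * xu),
                          xu - dt * beta * xu)
        xs = np.where(active, np.maximum(new_xs, 0.0), xs)
        xu = np.where(active, np.maximum(new_xu, 0.0), xu)
    v = beta * xu - d * xs
    return xs, xu, v, FullKineticState(xs, xu, on)


def knn_average_velocity(v: np.ndarray, embedding: np.ndarray,
                         k: Optional[int] = None
                         ) -> Tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel kNN smoothing of the velocity field.

    ``k`` defaults to ceil(n_cell / 50). Each cell's velocity is replaced by
    the kernel-weighted average over itself and its k nearest neighbors in
    ``embedding`` (bandwidth = the cell's median neighbor distance).
    Returns the smoothed field and the per-cell norms of the smoothed
    velocity (normalisation factors).
    """
    n = v.shape[0]
    if k is None:
        k = int(np.ceil(n / 50))
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError("k must be < n_cell")
    # k+1 neighbors: the query point itself is returned at distance 0
    nn = NearestNeighbors(n_neighbors=min(k + 1, n)).fit(embedding)
    dist, idx = nn.kneighbors(embedding)
    bw = np.median(dist, axis=1)
    bw[bw == 0] = 1.0
    w = np.exp(-0.5 * (dist / bw[:, None]) ** 2)
    smoothed = np.empty_like(v, dtype=float)
    for i in range(n):
        smoothed[i] = w[i] @ v[idx[i]] / w[i].sum()
    norms = np.linalg.norm(smoothed, axis=1)
    return smoothed, norms
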