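"""Technical noise, batch effects, and ATAC observation.

True counts are turned into observed counts by a three-stage chain that
mimics library preparation: binomial capture of transcripts at a per-cell
efficiency alpha, a few rounds of stochastic amplification, and allocation
of a per-cell sequencing depth across the amplified molecules. With a UMI
protocol, reads are collapsed back to distinct captured molecules; with a
non-UMI protocol, read counts are reported directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "NoiseModel",
    "add_technical_noise",
    "add_batch_effects",
    "observe_atac",
]


@dataclass
class NoiseModel:
    """Per-cell capture efficiency and sequencing depth distributions."""

    alpha_mean: float = 0.1
    alpha_sd: float = 0.02
    depth_mean: float = 1e5
    depth_sd: float = 3000.0
    protocol: str = "UMI"
    amplification_rounds: int = 2
    amplification_rate: float = 0.7

    def __post_init__(self) -> None:
        if not 0 < self.alpha_mean <= 1:
            raise ValueError("alpha_mean must be in (0, 1]")
        if self.protocol not in ("UMI", "nonUMI"):
            raise ValueError("protocol must be 'UMI' or 'nonUMI'")

    def sample_alpha(self, n_cell: int, rng: np.random.Generator,
                     per_cell_scale: Optional[np.ndarray] = None
                     ) -> np.ndarray:
        a = rng.normal(self.alpha_mean, self.alpha_sd, size=n_cell)
        if per_cell_scale is not None:
            a = a * per_cell_scale
        return np.clip(a, 1e-6, 1.0)

    def sample_depth(self, n_cell: int,
                     rng: np.random.Generator) -> np.ndarray:
        d = rng.normal(self.depth_mean, self.depth_sd, size=n_cell)
        return np.maximum(np.round(d), 1).astype(np.int64)


def add_technical_noise(true_counts: np.ndarray, model: NoiseModel,
                        rng: np.random.Generator,
                        per_gene_alpha_scale: Optional[np.ndarray] = None,
                        per_cell_alpha_scale: Optional[np.ndarray] = None
                        ) -> np.ndarray:
    """Observed integer counts from true counts (cells x genes).

    Optional per-gene / per-cell multipliers on the capture efficiency give
    fine-grained control over detection rates (e.g. to emulate housekeeping
    genes).
    """
    true_counts = np.asarray(true_counts)
    if np.any(true_counts < 0):
        raise ValueError("true counts must be non-negative")
    n_cell, n_gene = true_counts.shape
    molecules = np.round(true_counts).astype(np.int64)
    alpha = model.sample_alpha(n_cell, rng, per_cell_alpha_scale)
    depth = model.sample_depth(n_cell, rng)

    p_capture = np.repeat(alpha[:, None], n_gene, axis=1)
    if per_gene_alpha_scale is not None:
        p_capture = np.clip(p_capture * per_gene_alpha_scale[None, :],
                            0.0, 1.0)
    captured = rng.binomial(molecules, p_capture)

    amplified = captured.copy()
    for _ in range(model.amplification_rounds):
        amplified = amplified + rng.binomial(amplified,
                                             model.amplification_rate)

    observed = np.zeros_like(captured)
    for c in range(n_cell):
        total = amplified[c].sum()
        if total == 0:
            continue
        reads = rng.multinomial(depth[c], amplified[c] / total)
        if model.protocol == "nonUMI":
            observed[c] = reads
        else:
            # UMI collapse: a captured molecule is observed iff at least one
            # of its amplified copies is read (occupancy approximation)
            cap = captured[c]
            nz = cap > 0
            p_seen = np.zeros(n_gene)
            p_seen[nz] = 1.0 - (1.0 - 1.0 / cap[nz]) ** reads[nz]
            observed[c, nz] = rng.binomial(cap[nz], p_seen[nz])
    return observed.astype(np.int64)


def add_batch_effects(counts: np.ndarray, n_batch: int, e_b: float,
                      rng: np.random.Generator
                      ) -> Tuple[np.ndarray, np.ndarray]:
    """Split cells into batches and apply per-(gene, batch) shifts.

    For gene j, a center mu_j ~ N(0, 1) is drawn; each batch's shift is
    Uniform(mu_j - e_b, mu_j + e_b) and counts are multiplied by
    exp(shift) (log-additive, so counts stay non-negative) and re-rounded.
    Returns (shifted counts, batch label per cell).
    """
    if n_batch < 1:
        raise ValueError("n_batch must be >= 1")
    n_cell, n_gene = counts.shape
    if n_batch > n_cell:
        raise ValueError("n_batch must be <= n_cell")
    if e_b < 0:
        raise ValueError("e_b must be >= 0")
    labels = np.arange(n_cell) % n_batch
    mu = rng.normal(0.0, 1.0, size=n_gene)
    shifts = rng.uniform(mu - e_b, mu + e_b, size=(n_batch, n_gene))
    factors = np.exp(shifts)
    out = np.round(counts * factors[labels]).astype(np.int64)
    return out, labels


def observe_atac(atac_true: np.ndarray, atac_obs_prob: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Per-entry Bernoulli thinning of the accessibility matrix: each entry
    is retained with probability ``atac_obs_prob``, else set to zero."""
    if not 0 <= atac_obs_prob <= 1:
        raise ValueError("atac_obs_prob must be in [0, 1]")
    if atac_obs_prob == 1:
        return atac_true.copy()
    keep = rng.random(atac_true.shape) < atac_obs_prob
    return np.where(keep, atac_true, 0.0)
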