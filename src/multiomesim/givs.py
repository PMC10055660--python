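"""Gene Identity Vectors (GIV) and Region Identity Vectors (RIV).

A GIV column holds the weights with which a gene responds to each cell
identity factor; multiplying the CIF matrix by a GIV matrix yields a raw
cells x genes kinetic-parameter matrix. GIVs mirror the CIF segment layout
(nd | diff | tf | lig). The TF and ligand blocks are all zeros for k_on and
k_off (regulators and ligands act on the synthesis rate only); for s the TF
block is the GRN effect matrix and the diff block couples targets to their
regulators so that co-regulated genes share trajectory structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

from .grn import GrnSpec

__all__ = [
    "sample_sparse_gaussian",
    "build_diff_giv_with_grn",
    "GivMatrix",
    "build_giv",
    "sample_riv",
]

#: GIV weight given to each of the two chosen diff dimensions of a TF gene
SMALL_VALUE = 1.0


def sample_sparse_gaussian(rows: int, cols: int, p0: float, mean: float,
                           sd: float, rng: np.random.Generator) -> np.ndarray:
    """Each entry is 0 with probability ``p0``, else N(mean, sd)."""
    if not 0 <= p0 <= 1:
        raise ValueError("p0 must be in [0, 1]")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    vals = rng.normal(mean, sd, size=(rows, cols))
    mask = rng.random((rows, cols)) < p0
    vals[mask] = 0.0
    return vals


def build_diff_giv_with_grn(effect_matrix: np.ndarray, grn: GrnSpec,
                            n_diff: int, n_gene: int,
                            rng: np.random.Generator,
                            p0: float = 0.7, mean: float = 0.0,
                            sd: float = 1.0,
                            small_value: float = SMALL_VALUE) -> np.ndarray:
    """Differential GIV block (n_diff x n_gene) for the s parameter.

    TF genes get two randomly chosen diff dimensions set to ``small_value``.
    A pure target's column is the product of the TF columns with the effect
    matrix column (so targets inherit their regulators' diff weights,
    combined by regulation strength). A gene that is both TF and target gets
    the average of the two. Genes outside the network are sampled from the
    sparse Gaussian GIV distribution.
    """
    return _diff_giv_with_grn(effect_matrix, grn, n_diff, n_gene, rng,
                              p0, mean, sd, small_value)


@dataclass
class GivMatrix:
    """Full GIV matrix for one kinetic parameter, segment widths recorded."""

    matrix: np.ndarray          # (n_nd + n_diff + n_tf + n_lig_slots) x n_gene
    parameter: str
    n_nd: int
    n_diff: int
    n_tf: int
    n_lig_slots: int

    @property
    def width(self) -> int:
        return self.matrix.shape[0]


def build_giv(parameter: str, grn: Optional[GrnSpec], n_gene: int,
              n_nd: int, n_diff: int, n_lig_slots: int,
              p0: float, mean: float, sd: float,
              rng: np.random.Generator,
              lig_block: Optional[np.ndarray] = None,
              grn_on_kon_koff: bool = False) -> GivMatrix:
    """Assemble the GIV matrix for one kinetic parameter.

    ``lig_block`` (n_lig_slots x n_gene), when given, carries the
    ligand-receptor effect entries used for the s parameter in spatial mode.
    ``grn_on_kon_koff`` optionally injects the GRN effect matrix into k_on /
    k_off as well (off by default: the GRN acts on s).
    """
    if parameter not in ("kon", "koff", "s"):
        raise ValueError("parameter must be kon/koff/s")
    n_tf = grn.n_tf if grn is not None else 0
    nd = sample_sparse_gaussian(n_nd, n_gene, p0, mean, sd, rng)

    uses_grn = parameter == "s" or grn_on_kon_koff
    if grn is not None and uses_grn:
        from .grn import build_effect_matrix
        effect = build_effect_matrix(grn, n_gene)          # n_gene x n_tf
        diff = _diff_giv_with_grn(effect, grn, n_diff, n_gene, rng,
                                  p0, mean, sd)
        tf = effect.T                                      # n_tf x n_gene
    else:
        diff = sample_sparse_gaussian(n_diff, n_gene, p0, mean, sd, rng)
        tf = np.zeros((n_tf, n_gene))

    if parameter == "s" and lig_block is not None:
        lig = lig_block
        if lig.shape != (n_lig_slots, n_gene):
            raise ValueError("lig_block shape mismatch")
    else:
        lig = np.zeros((n_lig_slots, n_gene))
    matrix = np.vstack([nd, diff, tf, lig])
    return GivMatrix(matrix, parameter, n_nd, n_diff, n_tf, n_lig_slots)


def _diff_giv_with_grn(effect_matrix: np.ndarray, grn: GrnSpec, n_diff: int,
                       n_gene: int, rng: np.random.Generator,
                       p0: float, mean: float, sd: float,
                       small_value: float = SMALL_VALUE) -> np.ndarray:
    if n_diff < 2:
        raise ValueError("n_diff must be >= 2 to place two TF entries")
    n_tf = effect_matrix.shape[1]
    tf_block = np.zeros((n_diff, n_tf))
    for j in range(n_tf):
        rows = rng.choice(n_diff, size=2, replace=False)
        tf_block[rows, j] = small_value
    target_part = tf_block @ effect_matrix.T               # n_diff x n_gene

    out = sample_sparse_gaussian(n_diff, n_gene, p0, mean, sd, rng)
    # target-hood follows the edge list, not the effect values, so a
    # zero-effect edge still marks its target as GRN-governed
    is_target = np.zeros(n_gene, dtype=bool)
    is_target[[t for t in grn.targets if t < n_gene]] = True
    tf_genes = set(grn.tf_set)
    for g in range(n_gene):
        is_tf = g in tf_genes
        if is_tf and is_target[g]:
            j = grn.tf_set.index(g)
            out[:, g] = 0.5 * (tf_block[:, j] + target_part[:, g])
        elif is_tf:
            j = grn.tf_set.index(g)
            out[:, g] = tf_block[:, j]
        elif is_target[g]:
            out[:, g] = target_part[:, g]
    return out


def sample_riv(width: int, n_region: int, p0: float, mean: float, sd: float,
               rng: np.random.Generator) -> np.ndarray:
    """Region identity vectors: a width x n_region sparse-Gaussian matrix."""
    return sample_sparse_gaussian(width, n_region, p0, mean, sd, rng)
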