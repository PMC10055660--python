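"""Ground-truth gene regulatory network and its effect on cells.

The GRN is an edge list (regulator TF, target gene, effect strength). It is
encoded into expression through two channels: the TF block of the gene
identity vectors (the *effect matrix*), and the TF block of each cell's
identity factors, which tracks the regulators' expression in the cell's
predecessor along the trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

__all__ = [
    "GrnSpec",
    "load_grn",
    "build_effect_matrix",
    "update_tf_cif",
    "evolve_cell_specific_grn",
    "synthetic_benchmark_grn",
]


@dataclass
class GrnSpec:
    """Edge list (tf, target, effect) plus the ordered TF set."""

    edges: List[Tuple[int, int, float]]

    def __post_init__(self) -> None:
        seen = set()
        for tf, tgt, eff in self.edges:
            if (tf, tgt) in seen:
                raise ValueError(f"duplicate edge ({tf}, {tgt})")
            seen.add((tf, tgt))
            if not np.isfinite(eff):
                raise ValueError(f"edge ({tf}, {tgt}) has non-finite effect")
        # TF order: first appearance in the edge list (deterministic)
        self.tf_set: List[int] = []
        for tf, _, _ in self.edges:
            if tf not in self.tf_set:
                self.tf_set.append(tf)

    @property
    def n_tf(self) -> int:
        return len(self.tf_set)

    @property
    def targets(self) -> List[int]:
        out: List[int] = []
        for _, tgt, _ in self.edges:
            if tgt not in out:
                out.append(tgt)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges,
                            columns=["regulator", "target", "effect"])

    def save(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)


def load_grn(path: Union[str, Path]) -> GrnSpec:
    """Read a 3-column (regulator, target, effect) CSV/TSV edge list."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 3:
        raise ValueError("GRN file needs 3 columns: regulator, target, effect")
    edges = [(int(r), int(t), float(e))
             for r, t, e in df.iloc[:, :3].itertuples(index=False)]
    return GrnSpec(edges)


def build_effect_matrix(grn: Optional[GrnSpec], n_gene: int) -> np.ndarray:
    """Dense n_gene x n_TF matrix; entry (i, j) is the strength of TF j on
    gene i (zero when no edge)."""
    if grn is None or not grn.edges:
        return np.zeros((n_gene, 0))
    col = {tf: j for j, tf in enumerate(grn.tf_set)}
    out = np.zeros((n_gene, grn.n_tf))
    for tf, tgt, eff in grn.edges:
        if tgt >= n_gene or tf >= n_gene:
            raise ValueError(f"edge ({tf}, {tgt}) references a gene >= n_gene")
        out[tgt, col[tf]] = eff
    return out


def update_tf_cif(prev_expression: np.ndarray) -> np.ndarray:
    """TF block of a cell's identity factors from its predecessor's TF
    expression: entry i = x_i / (x_i + mean(x)).

    Values lie in [0, 1). When every TF is silent the denominator vanishes;
    a silent TF exerts no effect, so the result is defined as all zeros.
    """
    x = np.asarray(prev_expression, dtype=float)
    m = x.mean() if x.size else 0.0
    denom = x + m
    out = np.zeros_like(x)
    nz = denom > 0
    out[nz] = x[nz] / denom[nz]
    return out


def evolve_cell_specific_grn(grn: GrnSpec, n_cells: int, change_rate: float,
                             rng: np.random.Generator,
                             n_gene: Optional[int] = None
                             ) -> List[GrnSpec]:
    """Per-cell GRN sequence: walking cells in pseudotime order, each
    existing edge is deleted w.p. ``change_rate`` per step and a new random
    TF-to-gene edge is added w.p. ``change_rate`` per step, with the effect
    drawn from the empirical pool of existing effects.
    """
    if change_rate < 0:
        raise ValueError("change_rate must be >= 0")
    if n_gene is None:
        n_gene = max(max(t for _, t, _ in grn.edges),
                     max(tf for tf, _, _ in grn.edges)) + 1
    effect_pool = np.array([e for _, _, e in grn.edges])
    tf_pool = list(grn.tf_set)
    edges = list(grn.edges)
    out = [GrnSpec(list(edges))]
    for _ in range(1, n_cells):
        kept = [e for e in edges if rng.random() >= change_rate]
        if rng.random() < change_rate and tf_pool:
            # a newly generated edge is always a genuinely new pair
            existing = {(tf, t) for tf, t, _ in edges} \
                | {(tf, t) for tf, t, _ in kept}
            for _attempt in range(10):
                tf = tf_pool[rng.integers(len(tf_pool))]
                tgt = int(rng.integers(n_gene))
                if tgt != tf and (tf, tgt) not in existing:
                    kept.append((tf, tgt,
                                 float(rng.choice(effect_pool))))
                    break
        edges = kept
        out.append(GrnSpec(list(edges)))
    return out


def synthetic_benchmark_grn(n_gene: int = 100, n_tf: int = 10,
                            n_edges: int = 150,
                            seed: int = 2023) -> GrnSpec:
    """A synthetic benchmark-scale GRN (default: 100 genes, 10 TFs).

    Stands in for curated benchmark networks of similar size: TFs are the
    first ``n_tf`` gene indices, targets are drawn from the remaining genes
    with preferential attachment to earlier TFs (hub structure), and effect
    strengths are Uniform(1, 5).
    """
    rng = np.random.default_rng(seed)
    tfs = list(range(n_tf))
    weights = 1.0 / (1.0 + np.arange(n_tf))
    weights /= weights.sum()
    edges = []
    seen = set()
    while len(edges) < n_edges:
        tf = int(rng.choice(tfs, p=weights))
        # mostly non-TF targets, but allow TF-to-TF edges (dual roles)
        if rng.random() < 0.1:
            tgt = int(rng.integers(n_tf))
        else:
            tgt = int(rng.integers(n_tf, n_gene))
        if tgt == tf or (tf, tgt) in seen:
            continue
        seen.add((tf, tgt))
        edges.append((tf, tgt, float(rng.uniform(1.0, 5.0))))
    return GrnSpec(edges)
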