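"""End-to-end simulation: from tree + GRN + config to a full multi-modal
output with ground truth.

The generation order mirrors the biology encoded in the model: chromatin
accessibility is generated first (it gates promoter activation), kinetic
parameters are assembled from cell identity factors and gene identity
vectors, expression is simulated cell by cell along the differentiation
tree (so regulator expression in a cell influences its successor), and
technical noise / batch effects are layered on last. Every intermediate
ground-truth quantity is kept in the returned :class:`SimOutput`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd

from .atac import QuantileScaler, build_region_to_gene, generate_atac
from .config import SimulationConfig
from .givs import GivMatrix, build_giv, sample_riv
from .grn import GrnSpec, update_tf_cif
from .kinetics import (FullKineticState, assemble_kon, assemble_koff,
                       init_kinetic_state, knn_average_velocity,
                       sample_true_counts, simulate_full_kinetic)
from .metrics import pca_embedding
from .noise import NoiseModel, add_batch_effects, add_technical_noise, \
    observe_atac
from .population import (CellAssignment, DifferentiationTree, assign_cells,
                         builtin_tree, generate_diff_cif, generate_nd_cif,
                         parse_newick, predecessor_order)
from .references import builtin_reference

__all__ = ["SimOutput", "run_simulation", "rng_stream"]

_STREAM_IDS = {
    "population": 1,
    "giv": 2,
    "riv": 3,
    "atac": 4,
    "kinetics": 5,
    "expression": 6,
    "noise": 7,
    "batch": 8,
    "spatial": 9,
    "grn": 10,
    "velocity": 11,
    "cif": 12,
    "scale": 13,
}


def rng_stream(seed: int, name: str) -> np.random.Generator:
    """Named random sub-stream derived from the global seed.

    Each simulation stage draws from its own stream, so enabling or
    disabling one stage does not perturb the randomness of the others.
    """
    return np.random.default_rng(np.random.SeedSequence([seed,
                                                         _STREAM_IDS[name]]))


@dataclass
class SimOutput:
    """Everything a run produces: data modalities plus ground truth."""

    config: SimulationConfig
    counts_true: np.ndarray                  # cells x genes
    counts_obs: Optional[np.ndarray]         # cells x genes, integer
    atac_true: np.ndarray                    # cells x regions
    atac_obs: Optional[np.ndarray]
    kon: np.ndarray
    koff: np.ndarray
    s: np.ndarray
    region_to_gene: np.ndarray               # regions x genes, binary
    cell_meta: pd.DataFrame                  # cell_id, type_label, branch,
                                             # pseudotime, batch
    grn: Optional[GrnSpec] = None
    unspliced: Optional[np.ndarray] = None
    velocity: Optional[np.ndarray] = None
    velocity_smoothed: Optional[np.ndarray] = None
    velocity_norms: Optional[np.ndarray] = None
    beta: Optional[np.ndarray] = None        # per-gene splicing rate
    d_rate: Optional[np.ndarray] = None      # per-gene degradation rate
    batch_labels: Optional[np.ndarray] = None
    locations: Optional[pd.DataFrame] = None       # spatial mode
    ctype_cci: Optional[pd.DataFrame] = None       # spatial mode
    pair_cci: Optional[pd.DataFrame] = None        # spatial mode
    lr_database: Optional[pd.DataFrame] = None     # spatial mode

    @property
    def pseudotime(self) -> np.ndarray:
        return self.cell_meta["pseudotime"].to_numpy()

    @property
    def type_labels(self) -> np.ndarray:
        return self.cell_meta["type_label"].to_numpy()

    def to_anndata(self):
        """Bundle the RNA modality (with ground truth in layers/obs)."""
        import anndata as ad

        adata = ad.AnnData(X=self.counts_true.astype(float),
                           obs=self.cell_meta.set_index("cell_id"))
        if self.counts_obs is not None:
            adata.layers["observed"] = self.counts_obs.astype(float)
        if self.unspliced is not None:
            adata.layers["unspliced"] = self.unspliced
        if self.velocity is not None:
            adata.layers["velocity"] = self.velocity
        return adata


def _resolve_tree(tree: Union[str, DifferentiationTree, None]
                  ) -> DifferentiationTree:
    if tree is None:
        return builtin_tree("phyla1")
    if isinstance(tree, DifferentiationTree):
        return tree
    return parse_newick(tree)


def run_simulation(config: SimulationConfig,
                   tree: Union[str, DifferentiationTree, None] = None,
                   grn: Optional[GrnSpec] = None,
                   lr_database: Optional[pd.DataFrame] = None,
                   atac_tree: Union[str, DifferentiationTree, None] = None
                   ) -> SimOutput:
    """Run a full simulation.

    ``tree`` may be a Newick string, a parsed tree, or None (linear
    single-branch default). ``atac_tree`` optionally drives the
    accessibility modality with a different population structure.
    In spatial mode (``config.cci_on``) the time-step simulation of
    :mod:`multiomesim.spatial` is used and ``lr_database`` is required.
    """
    config.validate()
    tree = _resolve_tree(tree)
    if config.cci_on:
        from .spatial import run_spatial_simulation
        return run_spatial_simulation(config, tree, grn, lr_database)

    seed = config.seed
    rng_pop = rng_stream(seed, "population")
    assignment = assign_cells(tree, config.n_cell, config.discrete, rng_pop)
    order, pred = predecessor_order(tree, assignment)

    n_tf = grn.n_tf if grn is not None else 0
    cif, giv = _build_factors(config, tree, assignment, grn, n_lig_slots=0)

    atac_true, Z = _build_atac(config, tree, assignment, cif["kon"],
                               atac_tree)

    rng_kin = rng_stream(seed, "kinetics")
    raw_kon = cif["kon"] @ giv["kon"].matrix
    raw_koff = cif["koff"] @ giv["koff"].matrix
    kon = assemble_kon(raw_kon, atac_true, Z, builtin_reference("kon"),
                       config.E_a, rng_kin, B=config.B)
    koff = assemble_koff(raw_koff, builtin_reference("koff"), config.B,
                         rng_kin)

    counts, s_mat, unspliced, velocity, beta, d_rate = \
        _sequential_expression(config, grn, cif, giv, kon, koff, order,
                               pred)

    vel_smooth = vel_norms = None
    if config.velocity and velocity is not None:
        emb = pca_embedding(counts)
        vel_smooth, vel_norms = knn_average_velocity(velocity, emb)

    counts_obs, batch_labels = _observe(config, counts)
    atac_obs = observe_atac(atac_true, config.atac_obs_prob,
                            rng_stream(seed, "noise"))

    meta = pd.DataFrame({
        "cell_id": [f"cell{i}" for i in range(config.n_cell)],
        "type_label": assignment.type_label,
        "branch": assignment.branch,
        "pseudotime": assignment.pseudotime,
        "batch": batch_labels if batch_labels is not None
        else np.zeros(config.n_cell, dtype=int),
    })
    return SimOutput(config=config, counts_true=counts,
                     counts_obs=counts_obs, atac_true=atac_true,
                     atac_obs=atac_obs, kon=kon, koff=koff, s=s_mat,
                     region_to_gene=Z, cell_meta=meta, grn=grn,
                     unspliced=unspliced, velocity=velocity,
                     velocity_smoothed=vel_smooth,
                     velocity_norms=vel_norms, beta=beta, d_rate=d_rate,
                     batch_labels=batch_labels)


# ---------------------------------------------------------------------------
# building blocks shared with the spatial pipeline


def _build_factors(config: SimulationConfig, tree: DifferentiationTree,
                   assignment: CellAssignment, grn: Optional[GrnSpec],
                   n_lig_slots: int,
                   lig_block: Optional[np.ndarray] = None):
    """CIF matrices (cells x width) and GIV matrices per kinetic parameter.

    The TF and ligand CIF segments of k_on / k_off (and the initial TF
    segment of s, which the sequential pass overwrites) are N(1, sigma_cif)
    samples.
    """
    seed = config.seed
    rng_pop = rng_stream(seed, "cif")
    rng_giv = rng_stream(seed, "giv")
    n_tf = grn.n_tf if grn is not None else 0
    cif: Dict[str, np.ndarray] = {}
    giv: Dict[str, GivMatrix] = {}
    for param in ("kon", "koff", "s"):
        nd = generate_nd_cif(config.n_cell, config.n_nd, config.sigma_cif,
                             rng_pop, param)
        diff = generate_diff_cif(tree, assignment, config.n_diff,
                                 config.sigma_cif, config.discrete,
                                 rng_pop, param)
        tf = rng_pop.normal(1.0, config.sigma_cif,
                            size=(config.n_cell, n_tf))
        lig = rng_pop.normal(1.0, config.sigma_cif,
                             size=(config.n_cell, n_lig_slots))
        cif[param] = np.hstack([nd.matrix, diff.matrix, tf, lig])
        giv[param] = build_giv(param, grn, config.n_gene, config.n_nd,
                               config.n_diff, n_lig_slots, config.p0_G,
                               config.giv_mean, config.giv_sd, rng_giv,
                               lig_block=lig_block if param == "s" else None)
    return cif, giv


def _build_atac(config: SimulationConfig, tree: DifferentiationTree,
                assignment: CellAssignment, cif_kon: np.ndarray,
                atac_tree: Union[str, DifferentiationTree, None]):
    """Accessibility matrix and region-to-gene map.

    When ``atac_tree`` is given, the accessibility modality follows that
    tree's population structure instead of the RNA tree.
    """
    seed = config.seed
    rng_riv = rng_stream(seed, "riv")
    rng_atac = rng_stream(seed, "atac")
    n_region = config.resolved_n_region
    width = cif_kon.shape[1]
    if atac_tree is not None:
        atree = _resolve_tree(atac_tree)
        a_assign = assign_cells(atree, config.n_cell, config.discrete,
                                rng_atac)
        nd = generate_nd_cif(config.n_cell, config.n_nd, config.sigma_cif,
                             rng_atac, "kon")
        diff = generate_diff_cif(atree, a_assign, config.n_diff,
                                 config.sigma_cif, config.discrete,
                                 rng_atac, "kon")
        extra = width - config.n_cif
        rest = rng_atac.normal(1.0, config.sigma_cif,
                               size=(config.n_cell, extra))
        cif_for_atac = np.hstack([nd.matrix, diff.matrix, rest])
    else:
        cif_for_atac = cif_kon
    riv = sample_riv(width, n_region, config.p0_R, config.riv_mean,
                     config.riv_sd, rng_riv)
    atac_true = generate_atac(cif_for_atac, riv, builtin_reference("atac"),
                              rng_atac)
    Z = build_region_to_gene(n_region, config.n_gene, config.region_dist,
                             rng_atac)
    return atac_true, Z


def _sequential_expression(config: SimulationConfig, grn: Optional[GrnSpec],
                           cif: Dict[str, np.ndarray],
                           giv: Dict[str, GivMatrix],
                           kon: np.ndarray, koff: np.ndarray,
                           order: np.ndarray, pred: np.ndarray):
    """Simulate expression cell by cell along the tree.

    The synthesis rate of each cell is recomputed from its identity factors
    with the TF segment taken from its predecessor's expression, mapped
    onto the s reference pool through a quantile map frozen before the
    pass (so the sequential update cannot shift the global distribution).
    """
    seed = config.seed
    rng_scale = rng_stream(seed, "scale")
    rng_expr = rng_stream(seed, "expression")
    rng_vel = rng_stream(seed, "velocity")
    n_cell, n_gene = config.n_cell, config.n_gene
    giv_s = giv["s"].matrix
    n_tf = giv["s"].n_tf
    n_static = config.n_cif            # nd + diff columns
    static_cif = cif["s"][:, :n_static]
    tf_init = cif["s"][:, n_static:n_static + n_tf]
    lig_cols = cif["s"][:, n_static + n_tf:]

    raw_init = cif["s"] @ giv_s
    scaler = QuantileScaler(raw_init, builtin_reference("s").samples,
                            rng_scale)

    tf_genes = np.array(grn.tf_set, dtype=int) if grn is not None else \
        np.array([], dtype=int)

    counts = np.zeros((n_cell, n_gene))
    s_mat = np.zeros((n_cell, n_gene))
    unspliced = velocity = None
    states: List[Optional[FullKineticState]] = [None] * n_cell
    beta = d_rate = None
    if config.velocity:
        beta = np.maximum(rng_vel.normal(config.beta_mean, config.beta_sd,
                                         n_gene), 1e-3)
        d_rate = np.maximum(rng_vel.normal(config.d_mean, config.d_sd,
                                           n_gene), 1e-3)
        unspliced = np.zeros((n_cell, n_gene))
        velocity = np.zeros((n_cell, n_gene))

    non_tf = np.setdiff1d(np.arange(n_gene), tf_genes)

    for c in order:
        p = int(pred[c])
        if p < 0 or n_tf == 0:
            tf_cif = tf_init[c]
        else:
            tf_cif = update_tf_cif(counts[p, tf_genes])
        row_cif = np.concatenate([static_cif[c], tf_cif, lig_cols[c]])
        s_row = scaler.transform(row_cif @ giv_s) * config.scale_s

        if config.velocity:
            s_mat[c] = s_row
            if p < 0:
                state = init_kinetic_state(kon[c], koff[c], s_row, beta,
                                           d_rate, rng_vel)
            else:
                state = states[p]
            xs, xu, v, new_state = simulate_full_kinetic(
                kon[c], koff[c], s_row, beta, d_rate, config.eta_L,
                state, rng_vel)
            counts[c] = xs
            unspliced[c] = xu
            velocity[c] = v
            states[c] = new_state
        elif n_tf:
            # Regulation acts within the cell: the TF genes are drawn
            # first (their own synthesis seeded by the predecessor's TF
            # state), and the rest of the transcriptome responds to this
            # cell's own TF counts.
            counts[c, tf_genes] = sample_true_counts(
                kon[c, tf_genes], koff[c, tf_genes], s_row[tf_genes],
                config.sigma_i, rng_expr)
            own_tf_cif = update_tf_cif(counts[c, tf_genes])
            row2 = np.concatenate([static_cif[c], own_tf_cif,
                                   lig_cols[c]])
            s2 = scaler.transform(row2 @ giv_s) * config.scale_s
            s2[tf_genes] = s_row[tf_genes]
            s_mat[c] = s2
            counts[c, non_tf] = sample_true_counts(
                kon[c, non_tf], koff[c, non_tf], s2[non_tf],
                config.sigma_i, rng_expr)
        else:
            s_mat[c] = s_row
            counts[c] = sample_true_counts(kon[c], koff[c], s_row,
                                           config.sigma_i, rng_expr)
    return counts, s_mat, unspliced, velocity, beta, d_rate


def _observe(config: SimulationConfig, counts: np.ndarray):
    """Technical noise plus (optional) batch effects on the RNA modality."""
    rng_noise = rng_stream(config.seed, "noise")
    rng_batch = rng_stream(config.seed, "batch")
    model = NoiseModel(alpha_mean=config.alpha_mean,
                       alpha_sd=config.alpha_sd,
                       depth_mean=config.depth_mean,
                       depth_sd=config.depth_sd,
                       protocol=config.protocol)
    obs = add_technical_noise(counts, model, rng_noise)
    if config.n_batch > 1:
        obs, labels = add_batch_effects(obs, config.n_batch, config.e_b,
                                        rng_batch)
    else:
        labels = np.zeros(config.n_cell, dtype=int)
    return obs, labels
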