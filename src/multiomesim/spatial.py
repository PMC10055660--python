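"""Spatial grid placement and cell-cell interaction simulation.

The spatial mode runs a time-stepped simulation: at each step one newborn
cell (in the root state of the differentiation tree) is added to a square
grid — with probability ``p_n`` next to a cell of its own type — and every
existing cell advances one increment along its randomly chosen root-to-tip
path. A cell's ligand identity factors carry the normalised ligand-gene
expression of its grid neighbors from the previous step, and the
ligand-receptor effects enabled for that cell pair (the CCI ground truth)
feed the receptor's synthesis rate. Only the final step is emitted, as in
real spatial data; cells born at different steps are then at different
developmental stages, so all types are present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .atac import QuantileScaler
from .config import SimulationConfig
from .grn import GrnSpec, update_tf_cif
from .kinetics import (assemble_kon, assemble_koff, init_kinetic_state,
                       sample_true_counts, simulate_full_kinetic)
from .noise import observe_atac
from .population import CellAssignment, DifferentiationTree
from .references import builtin_reference

__all__ = [
    "SpatialState",
    "place_new_cell",
    "sample_cci_ground_truth",
    "run_spatial_simulation",
    "cci_correlation_analysis",
    "example_lr_database",
]

#: neighbor slots 1-4: right, up, left, down (unit grid distance)
_OFFSETS = ((1, 0), (0, 1), (-1, 0), (0, -1))

#: fraction of a cell's counts renewed per simulation step. One step is
#: one mRNA lifetime (d = 1), so counts relax toward the current target
#: with weight 1 - exp(-1): expression carries short-term memory of the
#: preceding steps, as transcripts persist while the cell develops.
STEP_RELAX = 1.0 - float(np.exp(-1.0))


@dataclass
class SpatialState:
    """Grid occupancy, coordinates, and per-cell neighbor slots."""

    side: int
    n_nbs: int
    grid: Dict[Tuple[int, int], int] = field(default_factory=dict)
    coords: List[Tuple[int, int]] = field(default_factory=list)
    types: List[str] = field(default_factory=list)
    # per cell: slot index (0..3) -> neighbor cell id
    neighbors: List[Dict[int, int]] = field(default_factory=list)

    @property
    def n_placed(self) -> int:
        return len(self.coords)

    def free_sites(self) -> List[Tuple[int, int]]:
        return [(x, y) for x in range(self.side) for y in range(self.side)
                if (x, y) not in self.grid]

    def adjacent_free(self, pos: Tuple[int, int]) -> List[Tuple[int, int]]:
        out = []
        for dx, dy in _OFFSETS:
            q = (pos[0] + dx, pos[1] + dy)
            if 0 <= q[0] < self.side and 0 <= q[1] < self.side \
                    and q not in self.grid:
                out.append(q)
        return out


def place_new_cell(state: SpatialState, cell_type: str, p_n: float,
                   rng: np.random.Generator,
                   strategy: str = "same_type") -> int:
    """Place one newborn cell and update neighbor slots.

    Strategies: ``same_type`` — with probability ``p_n`` the cell takes a
    free site adjacent to a same-type cell (random free site if none
    exists); ``random`` — always a random free site. Returns the new cell
    id.
    """
    if strategy not in ("same_type", "random"):
        raise ValueError("strategy must be 'same_type' or 'random'")
    free = state.free_sites()
    if not free:
        raise RuntimeError("grid is full")
    pos = None
    if strategy == "same_type" and state.n_placed > 0 \
            and rng.random() < p_n:
        candidates = []
        for cid, c_pos in enumerate(state.coords):
            if state.types[cid] == cell_type:
                candidates.extend(state.adjacent_free(c_pos))
        if candidates:
            candidates = sorted(set(candidates))
            pos = candidates[rng.integers(len(candidates))]
    if pos is None:
        pos = free[rng.integers(len(free))]

    cid = state.n_placed
    state.grid[pos] = cid
    state.coords.append(pos)
    state.types.append(cell_type)
    state.neighbors.append({})
    # register mutual neighbor slots, capped at n_nbs CCI neighbors each
    for slot, (dx, dy) in enumerate(_OFFSETS):
        q = (pos[0] + dx, pos[1] + dy)
        other = state.grid.get(q)
        if other is None:
            continue
        if len(state.neighbors[cid]) < state.n_nbs \
                and len(state.neighbors[other]) < state.n_nbs:
            state.neighbors[cid][slot] = other
            # the reciprocal slot is the opposite direction
            state.neighbors[other][(slot + 2) % 4] = cid
    return cid


def sample_cci_ground_truth(lr_database: pd.DataFrame,
                            cell_types: Sequence[str],
                            rng: np.random.Generator,
                            per_pair_count_range: Tuple[int, int] = (3, 6),
                            include_same_type: bool = False
                            ) -> Dict[Tuple[str, str], np.ndarray]:
    """Type-pair-level CCI ground truth.

    For every unordered pair of distinct cell types (same-type pairs only
    when requested), a random subset of ligand-receptor rows of size drawn
    from ``per_pair_count_range`` is enabled. Row indices refer to
    ``lr_database``.
    """
    m = len(lr_database)
    lo, hi = per_pair_count_range
    if lo > m:
        raise ValueError(f"per-pair count {lo} exceeds database size {m}")
    hi = min(hi, m)
    out: Dict[Tuple[str, str], np.ndarray] = {}
    types = sorted(set(cell_types))
    for i, a in enumerate(types):
        for b in types[i:]:
            if a == b and not include_same_type:
                continue
            k = int(rng.integers(lo, hi + 1))
            out[(a, b)] = np.sort(rng.choice(m, size=k, replace=False))
    return out


def _pair_rows(ctype_cci, type_a: str, type_b: str) -> np.ndarray:
    key = (type_a, type_b) if (type_a <= type_b) else (type_b, type_a)
    return ctype_cci.get(key, np.array([], dtype=int))


def example_lr_database(n_gene: int, grn: Optional[GrnSpec] = None,
                        n_pairs: int = 6, seed: int = 2024) -> pd.DataFrame:
    """A small ligand-receptor table wired into the regulatory network.

    Ligand genes are taken from the top of the gene index range (outside
    the GRN when it occupies the lower indices); receptors are GRN TFs plus
    a non-TF gene, so interaction effects propagate into the network.
    Effects are Uniform(1, 5), the same scale as the synthetic GRN weights.
    """
    rng = np.random.default_rng(seed)
    ligands = list(range(n_gene - n_pairs, n_gene))
    if grn is not None and grn.n_tf > 0:
        receptors = list(grn.tf_set[:max(1, n_pairs - 1)])
        non_tf = [t for t in grn.targets if t not in grn.tf_set]
        receptors += non_tf[:n_pairs - len(receptors)]
    else:
        receptors = list(range(n_pairs))
    rows = []
    for i in range(n_pairs):
        rows.append((ligands[i % len(ligands)],
                     receptors[i % len(receptors)],
                     float(rng.uniform(1.0, 5.0))))
    df = pd.DataFrame(rows, columns=["ligand", "receptor", "effect"])
    return df.drop_duplicates(subset=["ligand", "receptor"])


# ---------------------------------------------------------------------------


def _ligand_reference(x_lig: np.ndarray) -> np.ndarray:
    """Per-ligand saturation constant: the ligand's mean expression over
    cells (floored at 1 so silent ligands map to 0, not 0/0)."""
    ref = x_lig.mean(axis=0) if x_lig.ndim == 2 else np.asarray(x_lig)
    return np.maximum(ref, 1.0)


def _assign_paths(config: SimulationConfig, tree: DifferentiationTree,
                  rng: np.random.Generator):
    """Birth-time development: cell c is born at step c at the tree root
    and walks a random root-to-tip path one increment per step. Returns
    its final position (edge, offset), pseudotime, and type label."""
    n = config.n_cell
    n_steps = config.resolved_n_steps
    inc = tree.max_depth / n_steps
    tips = tree.tips
    branch = np.empty(n, dtype=int)
    offset = np.empty(n)
    pseudotime = np.empty(n)
    labels = np.empty(n, dtype=object)
    paths = []
    for c in range(n):
        tip = tips[rng.integers(len(tips))]
        path = tree.path_to_tip(tip)
        cumlen = np.cumsum([tree.edges[e].length for e in path])
        paths.append((path, cumlen))
        path_len = tree.depth(tip)
        traveled = min(max(n_steps - 1 - c, 0) * inc, path_len)
        pseudotime[c] = max(traveled, 1e-9)
        # locate (edge, offset) at distance `traveled` from the root
        rem = max(traveled, 1e-9)
        for e_idx in path:
            length = tree.edges[e_idx].length
            if rem <= length or e_idx == path[-1]:
                branch[c] = e_idx
                offset[c] = min(rem, length)
                break
            rem -= length
        labels[c] = tree.edges[branch[c]].child
    assignment = CellAssignment(branch, offset, pseudotime,
                                labels.astype(str), False)
    return assignment, paths, inc


def _type_at(tree: DifferentiationTree, path_info, traveled: float) -> str:
    """Type label at distance ``traveled`` along a root-to-tip path: the
    child node of the branch currently being traversed (the type the cell
    is differentiating into), matching the final-position labelling."""
    path, cumlen = path_info
    idx = int(np.searchsorted(cumlen, traveled, side="left"))
    return tree.edges[path[min(idx, len(path) - 1)]].child


def run_spatial_simulation(config: SimulationConfig,
                           tree: DifferentiationTree,
                           grn: Optional[GrnSpec],
                           lr_database: Optional[pd.DataFrame]):
    """Time-stepped spatial simulation with CCI effects (final step out)."""
    from .pipeline import (SimOutput, _build_atac, _build_factors, _observe,
                           rng_stream)

    if lr_database is None or len(lr_database) == 0:
        raise ValueError("spatial mode requires a ligand-receptor database")
    config.validate()
    if config.resolved_n_steps < config.n_cell:
        raise ValueError("n_steps must be >= n_cell (one birth per step)")
    seed = config.seed
    rng_sp = rng_stream(seed, "spatial")
    rng_expr = rng_stream(seed, "expression")
    rng_scale = rng_stream(seed, "scale")

    n_cell, n_gene = config.n_cell, config.n_gene
    n_steps = config.resolved_n_steps
    ligands = list(dict.fromkeys(int(g) for g in lr_database["ligand"]))
    lig_index = {g: i for i, g in enumerate(ligands)}
    n_lig = len(ligands)
    n_nbs = config.n_nbs
    n_slots = n_lig * n_nbs

    assignment, paths, step_inc = _assign_paths(config, tree, rng_sp)

    # diff-CIF is pinned per cell across steps (trajectory preserved)
    cif, giv = _build_factors(config, tree, assignment, grn,
                              n_lig_slots=n_slots)
    atac_true, Z = _build_atac(config, tree, assignment, cif["kon"], None)

    rng_kin = rng_stream(seed, "kinetics")
    kon = assemble_kon(cif["kon"] @ giv["kon"].matrix, atac_true, Z,
                       builtin_reference("kon"), config.E_a, rng_kin,
                       B=config.B)
    koff = assemble_koff(cif["koff"] @ giv["koff"].matrix,
                         builtin_reference("koff"), config.B, rng_kin)

    giv_s = giv["s"].matrix
    n_tf = giv["s"].n_tf
    n_static = config.n_cif
    static_cif = cif["s"][:, :n_static]
    tf_init = cif["s"][:, n_static:n_static + n_tf]
    scaler = QuantileScaler(cif["s"] @ giv_s,
                            builtin_reference("s").samples, rng_scale)
    tf_genes = np.array(grn.tf_set, dtype=int) if grn is not None else \
        np.array([], dtype=int)

    # CCI ground truth at cell-type level, over every tree node: cells
    # pass through ancestor types while developing, so interactions are
    # defined for intermediate types as well
    all_types = sorted({e.child for e in tree.edges} | {tree.root})
    ctype_cci = sample_cci_ground_truth(lr_database, all_types, rng_sp)
    lr_rows = list(lr_database[["ligand", "receptor", "effect"]]
                   .itertuples(index=False, name=None))

    side = int(np.ceil(np.sqrt(config.grid_capacity)))
    state = SpatialState(side=side, n_nbs=n_nbs)

    # genes that must be tracked at every step: regulators, ligands and
    # receptors (everything that feeds the next step's identity factors)
    receptors = [int(g) for g in lr_database["receptor"]]
    step_genes = np.array(sorted(set(tf_genes.tolist()) | set(ligands)
                                 | set(receptors)), dtype=int)
    pos_in_step = {g: i for i, g in enumerate(step_genes)}

    tf_cif = np.zeros((n_cell, n_tf))
    lig_cif = np.zeros((n_cell, n_slots))
    x_step = np.zeros((n_cell, step_genes.size))
    born = np.zeros(n_cell, dtype=bool)

    def lig_contribution(cells, gene_subset, types):
        """Receptor-gene boost from neighbors' ligand identity factors,
        gated by the CCI ground truth for the pair's (current) types."""
        pos = {g: i for i, g in enumerate(gene_subset)}
        out = np.zeros((len(cells), len(gene_subset)))
        for row_i, c in enumerate(cells):
            for slot, j in state.neighbors[c].items():
                rows = _pair_rows(ctype_cci, types[c], types[j])
                for r_idx in rows:
                    lig, rec, eff = lr_rows[r_idx]
                    if rec in pos:
                        val = lig_cif[c, slot * n_lig + lig_index[lig]]
                        out[row_i, pos[rec]] += eff * val
        return out

    def expression_for(cells, gene_subset, rng, types):
        rows = np.array(cells, dtype=int)
        cif_rows = np.hstack([static_cif[rows], tf_cif[rows]])
        giv_sub = giv_s[:n_static + n_tf, :][:, gene_subset]
        raw = cif_rows @ giv_sub
        raw = raw + lig_contribution(cells, gene_subset, types)
        s_sub = scaler.transform(raw) * config.scale_s
        return sample_true_counts(kon[rows][:, gene_subset],
                                  koff[rows][:, gene_subset],
                                  s_sub, config.sigma_i, rng), s_sub

    lig_positions = [pos_in_step[g] for g in ligands]
    tf_positions = [pos_in_step[g] for g in tf_genes]
    birth_step = np.arange(n_cell)

    def current_types(t):
        types = {}
        for c in range(min(t + 1, n_cell)):
            traveled = min(max(t - birth_step[c], 0) * step_inc,
                           paths[c][1][-1])
            types[c] = _type_at(tree, paths[c], traveled)
        return types

    for t in range(n_steps):
        if t < n_cell:
            c = place_new_cell(state, assignment.type_label[t],
                               config.p_n, rng_sp)
            born[c] = True
            tf_cif[c] = tf_init[c]
            lig_cif[c] = 0.0
        active = np.flatnonzero(born)
        types_now = current_types(t)
        x_new, _ = expression_for(active, step_genes, rng_expr, types_now)
        # counts relax toward the step's target: transcripts persist
        # across steps, so expression carries short-term memory
        x_step[active] = (1 - STEP_RELAX) * x_step[active] \
            + STEP_RELAX * x_new
        if t < n_cell:
            x_step[t] = x_new[np.searchsorted(active, t)]
        # update next-step identity factors from this step's expression
        for c in active:
            if n_tf:
                tf_cif[c] = update_tf_cif(x_step[c, tf_positions])
        # saturating per-ligand normalisation x / (x + mean-over-cells):
        # each ligand is scaled against its own population level, so
        # ligands do not compete with each other inside one cell
        lig_ref = _ligand_reference(x_step[active][:, lig_positions])
        new_lig = np.zeros_like(lig_cif)
        for c in active:
            for slot, j in state.neighbors[c].items():
                xl = x_step[j, lig_positions]
                new_lig[c, slot * n_lig:(slot + 1) * n_lig] = \
                    xl / (xl + lig_ref)
        lig_cif[:] = new_lig

    # Final-step full-transcriptome output. The snapshot is emitted
    # synchronously: ligand genes are drawn first and fed into the ligand
    # identity factors, then TF genes (so receptors that are TFs see the
    # emitted ligand counts), then the rest of the transcriptome responds
    # to the emitted TF counts — no one-step lag within the snapshot.
    all_cells = list(range(n_cell))
    final_types = {c: state.types[c] for c in all_cells}
    lig_arr = np.array(ligands, dtype=int)
    fresh_lig, _ = expression_for(all_cells, lig_arr, rng_expr, final_types)
    x_lig_final = (1 - STEP_RELAX) * x_step[:, lig_positions] \
        + STEP_RELAX * fresh_lig
    lig_ref = _ligand_reference(x_lig_final)
    for c in all_cells:
        for slot, j in state.neighbors[c].items():
            lig_cif[c, slot * n_lig:(slot + 1) * n_lig] = \
                x_lig_final[j] / (x_lig_final[j] + lig_ref)
    if n_tf:
        tf_arr = np.array(sorted(set(tf_genes.tolist())), dtype=int)
        fresh_tf, _ = expression_for(all_cells, tf_arr, rng_expr,
                                     final_types)
        x_tf_final = (1 - STEP_RELAX) \
            * x_step[:, [pos_in_step[g] for g in sorted(tf_arr)]] \
            + STEP_RELAX * fresh_tf
        for c in all_cells:
            tf_cif[c] = update_tf_cif(
                x_tf_final[c, [int(np.searchsorted(tf_arr, g))
                               for g in tf_genes]])
    counts, s_mat = expression_for(all_cells, np.arange(n_gene), rng_expr,
                                   final_types)
    # step-tracked genes keep their accumulated history in the snapshot
    handled = set(lig_arr.tolist()) | (set(tf_arr.tolist()) if n_tf
                                       else set())
    for g in step_genes:
        if int(g) not in handled:
            counts[:, g] = (1 - STEP_RELAX) * x_step[:, pos_in_step[g]] \
                + STEP_RELAX * counts[:, g]
    counts[:, lig_arr] = x_lig_final
    if n_tf:
        counts[:, tf_arr] = x_tf_final

    unspliced = velocity = beta = d_rate = None
    if config.velocity:
        rng_vel = rng_stream(seed, "velocity")
        beta = np.maximum(rng_vel.normal(config.beta_mean, config.beta_sd,
                                         n_gene), 1e-3)
        d_rate = np.maximum(rng_vel.normal(config.d_mean, config.d_sd,
                                           n_gene), 1e-3)
        unspliced = np.zeros((n_cell, n_gene))
        velocity = np.zeros((n_cell, n_gene))
        for c in range(n_cell):
            st = init_kinetic_state(kon[c], koff[c], s_mat[c], beta, d_rate,
                                    rng_vel)
            xs, xu, v, _ = simulate_full_kinetic(kon[c], koff[c], s_mat[c],
                                                 beta, d_rate, config.eta_L,
                                                 st, rng_vel)
            counts[c] = xs
            unspliced[c] = xu
            velocity[c] = v

    counts_obs, batch_labels = _observe(config, counts)
    atac_obs = observe_atac(atac_true, config.atac_obs_prob,
                            rng_stream(seed, "noise"))

    locations = pd.DataFrame({
        "cell_id": [f"cell{i}" for i in range(n_cell)],
        "x": [p[0] for p in state.coords],
        "y": [p[1] for p in state.coords],
        "type_label": state.types,
    })
    ctype_df = pd.DataFrame(
        [(a, b, *lr_rows[r]) for (a, b), rows in ctype_cci.items()
         for r in rows],
        columns=["type_a", "type_b", "ligand", "receptor", "effect"])
    pair_records = []
    for i in range(n_cell):
        for slot, j in state.neighbors[i].items():
            rows = _pair_rows(ctype_cci, state.types[i], state.types[j])
            for r in rows:
                lig, rec, eff = lr_rows[r]
                pair_records.append((i, j, lig, rec))
    pair_df = pd.DataFrame(pair_records,
                           columns=["cell_i", "cell_j", "ligand",
                                    "receptor"])

    meta = pd.DataFrame({
        "cell_id": [f"cell{i}" for i in range(n_cell)],
        "type_label": assignment.type_label,
        "branch": assignment.branch,
        "pseudotime": assignment.pseudotime,
        "batch": batch_labels,
    })
    return SimOutput(config=config, counts_true=counts,
                     counts_obs=counts_obs, atac_true=atac_true,
                     atac_obs=atac_obs, kon=kon, koff=koff, s=s_mat,
                     region_to_gene=Z, cell_meta=meta, grn=grn,
                     unspliced=unspliced, velocity=velocity,
                     beta=beta, d_rate=d_rate,
                     batch_labels=batch_labels, locations=locations,
                     ctype_cci=ctype_df, pair_cci=pair_df,
                     lr_database=lr_database)


def cci_correlation_analysis(output, lr_pair: Optional[Tuple[int, int]]
                             = None, counts: Optional[np.ndarray] = None,
                             seed: int = 0) -> Dict[str, object]:
    """Ligand-receptor expression correlations across cell pairs.

    For each enabled ligand-receptor pair (or a single chosen one), collect
    (ligand expression in cell i, receptor expression in cell j) over (a)
    neighbor pairs with ground-truth CCI, (b) neighbor pairs without CCI,
    and (c) 4 sampled non-adjacent cells per cell; same-type pairs are
    excluded throughout. Returns the mean correlation per group.
    """
    if output.pair_cci is None:
        raise ValueError("output has no CCI ground truth")
    x = output.counts_true if counts is None else counts
    types = output.locations["type_label"].to_numpy()
    n = x.shape[0]
    rng = np.random.default_rng(seed)

    neighbor_pairs = set()
    coords = list(zip(output.locations["x"], output.locations["y"]))
    pos_of = {p: i for i, p in enumerate(coords)}
    for i, (cx, cy) in enumerate(coords):
        for dx, dy in _OFFSETS:
            j = pos_of.get((cx + dx, cy + dy))
            if j is not None:
                neighbor_pairs.add((i, j))

    cci_pairs = set()
    by_lr: Dict[Tuple[int, int], set] = {}
    for _, row in output.pair_cci.iterrows():
        key = (int(row["ligand"]), int(row["receptor"]))
        by_lr.setdefault(key, set()).add((int(row["cell_i"]),
                                          int(row["cell_j"])))
        cci_pairs.add((int(row["cell_i"]), int(row["cell_j"])))

    lr_keys = [lr_pair] if lr_pair is not None else sorted(by_lr)

    def corr_over(pairs, lig, rec):
        pairs = [(i, j) for i, j in pairs if types[i] != types[j]]
        if len(pairs) < 3:
            return np.nan
        a = np.array([x[i, lig] for i, _ in pairs])
        b = np.array([x[j, rec] for _, j in pairs])
        if a.std() == 0 or b.std() == 0:
            return np.nan
        return float(np.corrcoef(a, b)[0, 1])

    groups = {"neighbor_cci": [], "neighbor_no_cci": [], "non_neighbor": []}
    for lig, rec in lr_keys:
        with_cci = by_lr.get((lig, rec), set())
        nb_with = [p for p in neighbor_pairs if p in with_cci]
        nb_without = [p for p in neighbor_pairs if p not in with_cci]
        non_nb = []
        for i in range(n):
            choices = rng.choice(n, size=min(4, n - 1), replace=False)
            for j in choices:
                if j != i and (i, int(j)) not in neighbor_pairs:
                    non_nb.append((i, int(j)))
        groups["neighbor_cci"].append(corr_over(nb_with, lig, rec))
        groups["neighbor_no_cci"].append(corr_over(nb_without, lig, rec))
        groups["non_neighbor"].append(corr_over(non_nb, lig, rec))
    return {k: float(np.nanmean(v)) if np.any(~np.isnan(v)) else np.nan
            for k, v in ((k, np.array(v)) for k, v in groups.items())}
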