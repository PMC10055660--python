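"""Simulation configuration: the single source of truth for a run.

Every user-tunable scalar of the simulator lives in :class:`SimulationConfig`.
The defaults describe a mid-sized experiment (500 cells, 200 genes, 50 cell
identity factors) with moderate heterogeneity and realistic technical noise
(capture efficiency ``alpha ~ N(0.1, 0.02)``, sequencing depth
``depth ~ N(1e5, 3000)``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple, Union


class ConfigError(ValueError):
    """Raised when a configuration field is out of its valid range."""


def _check(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"config field '{field_name}': {msg}")


@dataclass
class SimulationConfig:
    """All tunable parameters of a simulation run.

    Parameters
    ----------
    n_cell, n_gene, n_region
        Output dimensions. ``n_region`` defaults to ``3 * n_gene`` so that
        every gene can claim up to three consecutive chromatin regions.
    n_cif
        Number of cell identity factors (CIFs) shared between the
        non-differential and differential blocks. TF and ligand CIF segments
        are sized by the regulatory network / ligand-receptor inputs and come
        on top of this.
    sigma_cif
        Standard deviation of CIF sampling and of the per-unit-length
        Brownian walk along the differentiation tree. Smaller values give
        tighter clusters / crisper trajectories.
    r_d
        Ratio of differential to total CIFs, in (0, 1]. ``n_diff =
        max(1, round(r_d * n_cif))``.
    sigma_i
        Intrinsic-noise weight in [0, 1]: 1 returns pure Beta-Poisson
        samples, 0 returns the theoretical mean expression.
    E_a
        ATAC effect in [0, 1]: how strongly chromatin accessibility drives
        the promoter activation rate k_on.
    B
        Bimodality factor; k_on and k_off are divided by (1 + B).
    scale_s
        Linear scaling of the synthesis rate s (cell size knob).
    p0_G, p0_R
        Zero probability of the sparse-Gaussian gene/region identity vector
        distributions.
    region_dist
        Probability that a gene is regulated by 1, 2 or 3 consecutive
        chromatin regions.
    discrete
        Discrete clusters (tree tips only) instead of a continuous
        trajectory.
    velocity
        Use the full kinetic model and emit unspliced counts + RNA velocity.
    beta_mean, beta_sd, d_mean, d_sd
        Per-gene splicing (beta) and degradation (d) rate distributions
        (velocity mode only; the Beta-Poisson mode fixes d = 1).
    eta_L
        Scaling factor of the promoter cycle length L = 1/k_on + 1/k_off.
    cci_on, p_n, n_nbs, grid_factor, n_steps
        Spatial / cell-cell interaction controls. ``p_n`` is the probability
        that a newborn cell is placed next to a same-type cell; the grid
        holds ``ceil(grid_factor * n_cell)`` sites; ``n_steps`` defaults to
        ``n_cell`` (one birth per step).
    n_batch, e_b
        Number of batches and batch-shift half-width.
    alpha_mean, alpha_sd, depth_mean, depth_sd, protocol
        Technical-noise model: per-cell capture efficiency and sequencing
        depth, with a UMI or non-UMI read-counting protocol.
    atac_obs_prob
        Per-entry retention probability when thinning the true ATAC matrix
        into the observed one.
    seed
        Global seed; all named random streams are derived from it.
    """

    n_cell: int = 500
    n_gene: int = 200
    n_region: Optional[int] = None
    n_cif: int = 50
    sigma_cif: float = 0.1
    r_d: float = 0.5
    sigma_i: float = 1.0
    E_a: float = 0.5
    B: float = 0.0
    scale_s: float = 1.0
    p0_G: float = 0.7
    p0_R: float = 0.7
    giv_mean: float = 0.0
    giv_sd: float = 1.0
    riv_mean: float = 0.0
    riv_sd: float = 1.0
    region_dist: Tuple[float, ...] = (0.1, 0.5, 0.4)
    discrete: bool = False
    velocity: bool = False
    beta_mean: float = 1.0
    beta_sd: float = 0.1
    d_mean: float = 1.0
    d_sd: float = 0.1
    eta_L: float = 1.0
    cci_on: bool = False
    p_n: float = 0.8
    n_nbs: int = 4
    grid_factor: float = 2.5
    n_steps: Optional[int] = None
    n_batch: int = 1
    e_b: float = 1.0
    alpha_mean: float = 0.1
    alpha_sd: float = 0.02
    depth_mean: float = 1e5
    depth_sd: float = 3000.0
    protocol: str = "UMI"
    atac_obs_prob: float = 0.3
    seed: int = 1

    def __post_init__(self) -> None:
        self.validate()

    # -- derived quantities -------------------------------------------------
    @property
    def n_diff(self) -> int:
        return max(1, round(self.r_d * self.n_cif))

    @property
    def n_nd(self) -> int:
        return self.n_cif - self.n_diff

    @property
    def resolved_n_region(self) -> int:
        return 3 * self.n_gene if self.n_region is None else self.n_region

    @property
    def resolved_n_steps(self) -> int:
        return self.n_cell if self.n_steps is None else self.n_steps

    @property
    def grid_capacity(self) -> int:
        import math

        return math.ceil(self.grid_factor * self.n_cell)

    # -- validation ---------------------------------------------------------
    def validate(self) -> "SimulationConfig":
        _check(self.n_cell >= 1, "n_cell", "must be >= 1")
        _check(self.n_gene >= 1, "n_gene", "must be >= 1")
        _check(self.n_cif >= 1, "n_cif", "must be >= 1")
        if self.n_region is not None:
            _check(self.n_region >= 1, "n_region", "must be >= 1")
        _check(self.sigma_cif >= 0, "sigma_cif", "must be >= 0")
        _check(0 < self.r_d <= 1, "r_d", "must be in (0, 1]")
        _check(0 <= self.sigma_i <= 1, "sigma_i", "must be in [0, 1]")
        _check(0 <= self.E_a <= 1, "E_a", "must be in [0, 1]")
        _check(self.B >= 0, "B", "must be >= 0")
        _check(self.scale_s > 0, "scale_s", "must be > 0")
        for name in ("p0_G", "p0_R", "p_n", "atac_obs_prob"):
            v = getattr(self, name)
            _check(0 <= v <= 1, name, "must be in [0, 1]")
        _check(self.giv_sd >= 0, "giv_sd", "must be >= 0")
        _check(self.riv_sd >= 0, "riv_sd", "must be >= 0")
        rd = tuple(float(x) for x in self.region_dist)
        _check(1 <= len(rd) <= 3, "region_dist", "length must be 1-3")
        _check(all(x >= 0 for x in rd), "region_dist", "entries must be >= 0")
        _check(abs(sum(rd) - 1.0) < 1e-9, "region_dist", "must sum to 1")
        self.region_dist = rd
        for name in ("beta_mean", "d_mean", "eta_L", "grid_factor"):
            _check(getattr(self, name) > 0, name, "must be > 0")
        for name in ("beta_sd", "d_sd", "e_b", "alpha_sd", "depth_sd"):
            _check(getattr(self, name) >= 0, name, "must be >= 0")
        _check(1 <= self.n_nbs <= 4, "n_nbs", "must be in 1..4")
        if self.n_steps is not None:
            _check(self.n_steps >= 1, "n_steps", "must be >= 1")
        _check(self.n_batch >= 1, "n_batch", "must be >= 1")
        _check(self.n_batch <= self.n_cell, "n_batch", "must be <= n_cell")
        _check(0 < self.alpha_mean <= 1, "alpha_mean", "must be in (0, 1]")
        _check(self.depth_mean > 0, "depth_mean", "must be > 0")
        _check(self.protocol in ("UMI", "nonUMI"), "protocol",
               "must be 'UMI' or 'nonUMI'")
        _check(self.grid_capacity >= self.n_cell, "grid_factor",
               "grid capacity must hold all cells")
        _check(isinstance(self.seed, int), "seed", "must be an integer")
        return self

    # -- (de)serialization --------------------------------------------------
    def to_text(self) -> str:
        """Serialize as a flat ``key = value`` text block."""
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(repr(x) for x in v)
            lines.append(f"{f.name} = {v}")
        return "\n".join(lines) + "\n"

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def from_text(cls, text: str) -> "SimulationConfig":
        fields_by_name = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"line {lineno}: expected 'key = value'")
            key, val = (part.strip() for part in line.split("=", 1))
            if key not in fields_by_name:
                raise ConfigError(f"line {lineno}: unknown field '{key}'")
            kwargs[key] = _parse_value(key, val)
        return cls(**kwargs)


def _parse_value(key: str, val: str):
    if val == "None":
        return None
    if key == "region_dist":
        return tuple(float(x) for x in val.split(","))
    if key == "protocol":
        return val
    if val in ("True", "False"):
        return val == "True"
    try:
        if any(c in val for c in ".eE") and not val.lstrip("+-").isdigit():
            return float(val)
        return int(val)
    except ValueError as exc:
        raise ConfigError(f"field '{key}': cannot parse value {val!r}") from exc


def load_config(path: Optional[Union[str, Path]] = None,
                **overrides) -> SimulationConfig:
    """Load a configuration from a flat key-value file, or build defaults.

    Keyword overrides are applied on top of the file (or of the defaults
    when ``path`` is None).
    """
    if path is None:
        cfg = SimulationConfig(**overrides)
    else:
        cfg = SimulationConfig.from_text(Path(path).read_text())
        if overrides:
            cfg = dataclasses.replace(cfg, **overrides)
    return cfg
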