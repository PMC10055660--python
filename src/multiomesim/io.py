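"""Writers for the stable output-directory layout.

All matrices go out as MatrixMarket sparse text (cells as rows), metadata
and ground-truth tables as CSV, and the configuration as the flat text
dialect it was read from.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .pipeline import SimOutput

__all__ = ["write_outputs"]


def _write_mtx(path: Path, matrix: np.ndarray) -> None:
    spio.mmwrite(str(path), sparse.csr_matrix(matrix))


def write_outputs(output: SimOutput, out_dir: Union[str, Path]) -> Path:
    """Write a :class:`SimOutput` to ``out_dir`` (created if missing)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    _write_mtx(out / "counts_true.mtx", output.counts_true)
    if output.counts_obs is not None:
        _write_mtx(out / "counts_obs.mtx", output.counts_obs)
    _write_mtx(out / "atac.mtx", output.atac_true)
    if output.atac_obs is not None:
        _write_mtx(out / "atac_obs.mtx", output.atac_obs)
    if output.unspliced is not None:
        _write_mtx(out / "unspliced.mtx", output.unspliced)
    if output.velocity is not None:
        pd.DataFrame(output.velocity).to_csv(out / "velocity.csv",
                                             index=False, header=False)

    output.cell_meta.to_csv(out / "cells.csv", index=False)
    n_gene = output.counts_true.shape[1]
    pd.DataFrame({"gene_id": [f"gene{g}" for g in range(n_gene)]}) \
        .to_csv(out / "genes.csv", index=False)
    n_region = output.atac_true.shape[1]
    pd.DataFrame({"region_id": [f"region{r}" for r in range(n_region)]}) \
        .to_csv(out / "regions.csv", index=False)

    regions, genes = np.nonzero(output.region_to_gene)
    pd.DataFrame({"region": regions, "gene": genes}) \
        .to_csv(out / "region_to_gene.csv", index=False)

    if output.grn is not None:
        output.grn.save(out / "grn_truth.csv")
    if output.locations is not None:
        output.locations.to_csv(out / "locations.csv", index=False)
    if output.pair_cci is not None:
        output.pair_cci.to_csv(out / "cci_truth.csv", index=False)
    if output.ctype_cci is not None:
        output.ctype_cci.to_csv(out / "cci_type_truth.csv", index=False)

    (out / "config_used.txt").write_text(output.config.to_text())
    return out
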