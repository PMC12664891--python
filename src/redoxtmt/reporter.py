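"""Reporter-intensity processing: impurity correction, carrier handling,
missing-value semantics and protein-level normalization.

Observed reporter intensities are a mixture of the true per-channel
signals: if x is the true vector and M the row-stochastic lot-sheet
matrix (row = true channel, column = observed channel), the instrument
records y = M'x (M' = M transpose).  Correction inverts that mixing as a
non-negative least-squares problem, which is exact for well-conditioned
M and never produces negative intensities.

Cysteine-peptide signal tracks both oxidation and protein abundance;
dividing each sample channel by the same channel of the peptide's
leading razor protein group (log2 ratio) removes the protein-level
trend so that changes reflect the modification.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.optimize

from .design import ChannelDesign, DesignError
from . import mq_tables as mq

#: condition number above which NNLS inversion is refused
COND_THRESHOLD = 1e8


class IllConditionedMatrixError(ValueError):
    """Impurity matrix too ill-conditioned for a stable solve."""


def reporter_matrix(
    table: pd.DataFrame, design: ChannelDesign, family: str = mq.RAW_FAMILY
) -> pd.DataFrame:
    """Extract the rows x channels intensity matrix, indexed by row id."""
    cols = mq.reporter_columns(table.columns, family)
    if len(cols) != design.n_channels:
        raise DesignError(
            f"{len(cols)} {family!r} columns for a {design.n_channels}-channel design"
        )
    out = table[cols].astype(float).copy()
    out.columns = design.names
    out.index = pd.Index(table["id"].astype(int), name="id")
    return out


def _check_impurity_matrix(m: np.ndarray, n: int) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape != (n, n):
        raise ValueError(f"impurity matrix must be {n}x{n}, got {m.shape}")
    if (m < 0).any():
        raise ValueError("impurity matrix entries must be non-negative")
    if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9, rtol=0):
        raise ValueError("impurity matrix rows must sum to 1")
    return m


def correct_isotope_impurities(
    observed: np.ndarray | pd.DataFrame,
    impurity_matrix: np.ndarray,
    mode: str = "nnls",
) -> np.ndarray | pd.DataFrame:
    """Undo cross-channel isotope contamination of reporter intensities.

    Solves min ||M'x - y|| subject to x >= 0 per row (mode="nnls").
    mode="clip" does the unconstrained solve and clips negatives to 0 —
    faster, adequate for diagonally dominant lot sheets.  Missing values
    are treated as 0 for the solve and restored afterwards; an all-
    missing row stays all-missing.
    """
    arr = np.asarray(observed, dtype=float)
    squeeze = arr.ndim == 1
    y = np.atleast_2d(arr)
    m = _check_impurity_matrix(impurity_matrix, y.shape[1])
    cond = np.linalg.cond(m)
    if cond > COND_THRESHOLD:
        raise IllConditionedMatrixError(
            f"impurity matrix condition number {cond:.3g} exceeds {COND_THRESHOLD:.0e}; "
            "consider a pseudo-inverse ('clip') mode or a corrected matrix"
        )
    nan_mask = np.isnan(y)
    y_filled = np.where(nan_mask, 0.0, y)
    mt = m.T
    if mode == "clip":
        x = np.clip(np.linalg.solve(mt, y_filled.T).T, 0.0, None)
    elif mode == "nnls":
        x = np.empty_like(y_filled)
        for i in range(y_filled.shape[0]):
            x[i], _ = scipy.optimize.nnls(mt, y_filled[i])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    x[nan_mask] = np.nan
    if squeeze:
        x = x[0]
    if isinstance(observed, pd.DataFrame):
        return pd.DataFrame(x, index=observed.index, columns=observed.columns)
    return x


def zeros_to_missing(matrix: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Convert the 0 = "not observed" encoding into missing values."""
    if isinstance(matrix, pd.DataFrame):
        return matrix.mask(matrix == 0)
    arr = np.asarray(matrix, dtype=float).copy()
    arr[arr == 0] = np.nan
    return arr


def split_carrier(
    matrix: pd.DataFrame, design: ChannelDesign
) -> tuple[pd.DataFrame, pd.Series]:
    """Separate the carrier column from the experimental sample columns.

    The carrier vector is returned for QC only; everything quantitative
    downstream sees the sample matrix.  With no carrier declared the
    carrier vector is empty.
    """
    ci = design.carrier_index
    if ci is None:
        return matrix.copy(), pd.Series(dtype=float, name="carrier")
    carrier_name = design.names[ci]
    samples = matrix[design.sample_names].copy()
    carrier = matrix[carrier_name].rename("carrier")
    return samples, carrier


def normalize_to_protein(
    peptide_matrix: pd.DataFrame,
    protein_matrix: pd.DataFrame,
    peptide_protein: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-channel log2 ratio of peptide signal to its razor protein's signal.

    `peptide_protein` maps peptide row id -> protein accession;
    `protein_matrix` is indexed by accession with the same channel
    columns.  Peptides whose protein has no surviving group row are
    routed to the returned "unnormalizable" frame with a reason column.
    Missing in either input stays missing in the output.
    """
    have = peptide_protein.isin(protein_matrix.index)
    orphans = pd.DataFrame(
        {
            "id": peptide_matrix.index[~have],
            "protein": peptide_protein[~have],
            "reason": "no surviving protein group",
        }
    )
    pep = peptide_matrix.loc[have]
    prot = protein_matrix.loc[peptide_protein[have]].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2(pep.to_numpy(dtype=float) / prot)
    ratio[~np.isfinite(ratio)] = np.nan
    out = pd.DataFrame(ratio, index=pep.index, columns=pep.columns)
    return out, orphans
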