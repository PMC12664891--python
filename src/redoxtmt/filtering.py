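"""Row-exclusion rules applied before quantification.

Four pure row predicates, each returning the filtered table together
with a FilterReport so the whole chain is auditable: decoy/contaminant
removal, protein-group quality (no "only identified by site", at least
one unique peptide), the cysteine-count requirement, and the
complete-case rule (quantified in every experimental sample channel).
All filters are idempotent and commute.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .design import ChannelDesign, DesignError
from . import mq_tables as mq

#: completeness interpretations for complete_case_filter
ALL_SAMPLES = "all-samples"
ANY_CONDITION = "any-condition-complete"


@dataclasses.dataclass(frozen=True)
class FilterReport:
    stage: str
    rows_in: int
    rows_out: int
    rule: str

    def __post_init__(self) -> None:
        if self.rows_out > self.rows_in:
            raise ValueError("rows_out cannot exceed rows_in")

    @property
    def removed(self) -> int:
        return self.rows_in - self.rows_out


def write_filter_log(reports: Iterable[FilterReport], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in reports]).to_csv(
        path, sep="\t", index=False
    )


def remove_decoys_contaminants(table: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Drop rows flagged as reverse (decoy) or potential contaminant."""
    keep = ~(table["Reverse"].astype(bool) | table["Potential contaminant"].astype(bool))
    out = table.loc[keep].reset_index(drop=True)
    return out, FilterReport(
        "remove_decoys_contaminants", len(table), len(out),
        "drop Reverse or Potential contaminant",
    )


def filter_protein_groups(table: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Drop groups only identified by site or with zero unique peptides."""
    keep = (~table["Only identified by site"].astype(bool)) & (
        table["Unique peptides"].astype(int) >= 1
    )
    out = table.loc[keep].reset_index(drop=True)
    return out, FilterReport(
        "filter_protein_groups", len(table), len(out),
        "drop Only identified by site or Unique peptides == 0",
    )


def filter_cys_peptides(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, FilterReport]:
    """Partition peptides into cysteine-containing and non-cysteine evidence.

    Rows with C count < 1 are not discarded: they are the non-cysteine
    proteome evidence used for protein-level context.
    """
    counts = pd.to_numeric(table["C count"], errors="coerce").fillna(0)
    is_cys = counts >= 1
    cys = table.loc[is_cys].reset_index(drop=True)
    non_cys = table.loc[~is_cys].reset_index(drop=True)
    report = FilterReport(
        "filter_cys_peptides", len(table), len(cys),
        "partition by C count >= 1 (complement kept as non-Cys evidence)",
    )
    return cys, non_cys, report


def complete_case_filter(
    table: pd.DataFrame,
    design: ChannelDesign,
    family: str = mq.RAW_FAMILY,
    mode: str = ALL_SAMPLES,
) -> tuple[pd.DataFrame, FilterReport]:
    """Keep rows quantified (positive intensity) in the required sample channels.

    mode=ALL_SAMPLES (default): positive in every non-carrier channel.
    mode=ANY_CONDITION: positive in all replicates of at least one
    condition.  The carrier channel never counts toward completeness.
    """
    if design is None:
        raise DesignError("complete_case_filter requires a channel design")
    cols = mq.reporter_columns(table.columns, family)
    if len(cols) != design.n_channels:
        raise DesignError(
            f"table has {len(cols)} {family!r} columns, design has {design.n_channels}"
        )
    sample_cols = [cols[i] for i in design.sample_indices]
    values = table[sample_cols].to_numpy(dtype=float)
    positive = np.nan_to_num(values, nan=0.0) > 0
    if mode == ALL_SAMPLES:
        keep = positive.all(axis=1)
    elif mode == ANY_CONDITION:
        groups = design.sample_groups()
        keep = np.zeros(len(table), dtype=bool)
        for cond in design.conditions:
            idx = [i for i, name in enumerate(design.sample_names) if groups[name] == cond]
            keep |= positive[:, idx].all(axis=1)
    else:
        raise ValueError(f"unknown completeness mode {mode!r}")
    out = table.loc[keep].reset_index(drop=True)
    return out, FilterReport(
        "complete_case_filter", len(table), len(out),
        f"positive intensity required ({mode}; carrier excluded)",
    )
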