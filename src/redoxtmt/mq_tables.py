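"""Reading, validating and merging MaxQuant-dialect output tables.

The quantification workflow consumes four tab-separated tables:
``proteinGroups.txt`` (protein-level reporter intensities),
``modificationSpecificPeptides.txt`` (one row per peptide x modification
state, the quantitative evidence), ``peptides.txt`` (sequence-level
metadata: Cys count, protein coordinates, razor protein) and the light
and heavy ``Carbamidomethyl (C)Sites.txt`` tables (per-cysteine-site
rows with localisation scores).  ``merge_site_columns`` reproduces the
Perseus "Matching by row" join that decorates each modified-peptide row
with the site-level columns.

Conventions of the dialect:

* all protein coordinates are 1-based inclusive;
* boolean flags are encoded as ``+`` (set) / empty (unset);
* cross-references between tables are integer ids, possibly
  semicolon-separated lists;
* reporter intensity 0 means "not observed" and is preserved verbatim at
  this stage (conversion to missing happens in reporter processing);
* two reporter column families exist, ``Reporter intensity N`` (raw) and
  ``Reporter intensity corrected N`` (impurity-corrected); which one is
  authoritative is a caller choice.
"""

from __future__ import annotations

import enum
import logging
import re
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .design import ChannelDesign

logger = logging.getLogger(__name__)

#: Modification names of the two cysteine alkylation states.
LIGHT_MOD = "Carbamidomethyl (C)"
HEAVY_MOD = "Carbamidomethyl-heavy (C)"

RAW_FAMILY = "Reporter intensity"
CORRECTED_FAMILY = "Reporter intensity corrected"


class SchemaError(ValueError):
    """A required column is missing or unparseable."""


class IntegrityError(ValueError):
    """Table content violates an id-uniqueness or cross-reference contract."""


class TableKind(str, enum.Enum):
    PROTEIN_GROUPS = "proteinGroups"
    PEPTIDES = "peptides"
    MOD_PEPTIDES = "modificationSpecificPeptides"
    SITES = "sites"


class LabelState(str, enum.Enum):
    LIGHT = "LIGHT"
    HEAVY = "HEAVY"
    MIXED = "MIXED"
    NONE = "NONE"


#: Canonical on-disk file names written by the simulator / expected by readers.
FILE_NAMES = {
    TableKind.PROTEIN_GROUPS: "proteinGroups.txt",
    TableKind.PEPTIDES: "peptides.txt",
    TableKind.MOD_PEPTIDES: "modificationSpecificPeptides.txt",
    "light_sites": "Carbamidomethyl (C)Sites.txt",
    "heavy_sites": "Carbamidomethyl-heavy (C)Sites.txt",
}

_FLAG_COLUMNS = {
    TableKind.PROTEIN_GROUPS: ["Reverse", "Potential contaminant", "Only identified by site"],
    TableKind.PEPTIDES: ["Reverse", "Potential contaminant"],
    TableKind.MOD_PEPTIDES: ["Reverse", "Potential contaminant"],
    TableKind.SITES: ["Reverse", "Potential contaminant"],
}

_REQUIRED = {
    TableKind.PROTEIN_GROUPS: [
        "id", "Protein IDs", "Unique peptides",
        "Reverse", "Potential contaminant", "Only identified by site",
    ],
    TableKind.PEPTIDES: [
        "id", "Sequence", "C Count", "Start position", "End position",
        "Leading razor protein", "Reverse", "Potential contaminant",
    ],
    TableKind.MOD_PEPTIDES: [
        "id", "Sequence", "Modifications", "Peptide ID",
        "Reverse", "Potential contaminant",
    ],
    TableKind.SITES: [
        "id", "Protein", "Position", "Score diff", "Localization prob",
        "Mod. peptide IDs",
    ],
}

_INT_COLUMNS = {
    TableKind.PROTEIN_GROUPS: ["id", "Unique peptides"],
    TableKind.PEPTIDES: ["id", "C Count", "Start position", "End position"],
    TableKind.MOD_PEPTIDES: ["id", "Peptide ID"],
    TableKind.SITES: ["id", "Position"],
}

_FLOAT_COLUMNS = {
    TableKind.SITES: ["Score diff", "Localization prob"],
}

_HAS_REPORTERS = {TableKind.PROTEIN_GROUPS, TableKind.MOD_PEPTIDES}


def reporter_columns(
    columns: Iterable[str], family: str = RAW_FAMILY
) -> list[str]:
    """Reporter columns of one family, ordered by channel number.

    Matches ``<family> N`` exactly (so the raw family does not swallow
    the corrected one).
    """
    pat = re.compile(rf"^{re.escape(family)} (\d+)$")
    hits = [(int(m.group(1)), c) for c in columns if (m := pat.match(c))]
    return [c for _, c in sorted(hits)]


def read_mq_table(
    path: str | Path,
    kind: TableKind,
    design: ChannelDesign | None = None,
) -> pd.DataFrame:
    """Read one MaxQuant-dialect TSV and validate its schema.

    Flags become booleans, id/count/position columns become integers,
    reporter columns become floats (0 preserved).  Extra columns are kept
    untouched.  If `design` is given, each present reporter family must
    have exactly one column per channel.
    """
    path = Path(path)
    kind = TableKind(kind)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED[kind] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s): {', '.join(missing)}")

    for col in _FLAG_COLUMNS[kind]:
        if col in df.columns:  # optional on site tables
            df[col] = df[col].str.strip() == "+"
    for col in _INT_COLUMNS[kind]:
        try:
            df[col] = df[col].replace("", np.nan).astype(float).astype("Int64")
        except ValueError as exc:
            raise SchemaError(f"{path.name}: column {col!r} is not integer-valued: {exc}") from None
    for col in _FLOAT_COLUMNS.get(kind, []):
        try:
            df[col] = pd.to_numeric(df[col].replace("", np.nan))
        except ValueError as exc:
            raise SchemaError(f"{path.name}: column {col!r} is not numeric: {exc}") from None

    if kind in _HAS_REPORTERS:
        for family in (CORRECTED_FAMILY, RAW_FAMILY):
            cols = reporter_columns(df.columns, family)
            if not cols:
                continue
            try:
                df[cols] = df[cols].replace("", np.nan).astype(float)
            except ValueError as exc:
                raise SchemaError(f"{path.name}: reporter columns not numeric: {exc}") from None
            if (df[cols].to_numpy() < 0).any():
                raise SchemaError(f"{path.name}: negative reporter intensity in family {family!r}")
            if design is not None and len(cols) != design.n_channels:
                raise SchemaError(
                    f"{path.name}: {len(cols)} {family!r} columns but design has "
                    f"{design.n_channels} channels"
                )

    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise IntegrityError(f"{path.name}: duplicate id values {dupes[:5]}")
    return df


def write_mq_table(df: pd.DataFrame, path: str | Path, kind: TableKind) -> None:
    """Write a parsed table back in the on-disk dialect (round-trip safe)."""
    kind = TableKind(kind)
    out = df.copy()
    for col in _FLAG_COLUMNS[kind]:
        if col in out.columns:
            out[col] = np.where(out[col].astype(bool), "+", "")
    out.to_csv(path, sep="\t", index=False, na_rep="")


def parse_label_state(modifications: str) -> LabelState:
    """Classify the Modifications string into a cysteine labeling state.

    Entries are comma-separated, each optionally prefixed by a
    multiplicity ("2 Carbamidomethyl (C)").  A peptide carrying both
    light and heavy carbamidomethyl (on different cysteines) is MIXED.
    """
    has_light = has_heavy = False
    for token in str(modifications).split(","):
        token = token.strip()
        name = re.sub(r"^\d+\s+", "", token)
        if name == LIGHT_MOD:
            has_light = True
        elif name == HEAVY_MOD:
            has_heavy = True
    if has_light and has_heavy:
        return LabelState.MIXED
    if has_light:
        return LabelState.LIGHT
    if has_heavy:
        return LabelState.HEAVY
    return LabelState.NONE


def _split_ids(field) -> list[int]:
    if field is None or (isinstance(field, float) and np.isnan(field)):
        return []
    return [int(x) for x in str(field).split(";") if x != ""]


def _site_links(site_table: pd.DataFrame) -> pd.DataFrame:
    """Explode a sites table into one row per (mod-peptide id, site)."""
    rows = []
    for _, r in site_table.iterrows():
        for pid in _split_ids(r["Mod. peptide IDs"]):
            rows.append(
                {
                    "Peptide ref": pid,
                    "Position": int(r["Position"]),
                    "Score diff": r["Score diff"],
                    "Localization prob": r["Localization prob"],
                }
            )
    return pd.DataFrame(rows, columns=["Peptide ref", "Position", "Score diff", "Localization prob"])


def merge_site_columns(
    mod_peptides: pd.DataFrame,
    peptides: pd.DataFrame,
    heavy_sites: pd.DataFrame,
    light_sites: pd.DataFrame,
) -> pd.DataFrame:
    """Annotate modified-peptide rows with sequence- and site-level columns.

    Left joins only: the output has exactly the rows of `mod_peptides`,
    in order.  Sequence-level columns (C count, Start/End position,
    Leading razor protein) come from `peptides` via the ``Peptide ID``
    cross-reference; site positions and localisation scores come from
    whichever site table references the row (semicolon-separated
    multi-id links are split).  A site row referencing an id absent from
    the peptide table is skipped with a logged warning.
    """
    pep_cols = peptides.set_index("id")[
        ["C Count", "Start position", "End position", "Leading razor protein"]
    ]
    out = mod_peptides.copy()
    out = out.join(pep_cols.rename(columns={"C Count": "C count"}), on="Peptide ID")
    out["Label state"] = out["Modifications"].map(lambda m: parse_label_state(m).value)

    known = set(out["id"].astype(int))
    positions: dict[int, list[int]] = {}
    score_diff: dict[int, float] = {}
    loc_prob: dict[int, float] = {}
    for table in (light_sites, heavy_sites):
        links = _site_links(table)
        for _, link in links.iterrows():
            pid = int(link["Peptide ref"])
            if pid not in known:
                logger.warning(
                    "site row references unknown modified-peptide id %d; skipped", pid
                )
                continue
            positions.setdefault(pid, [])
            if link["Position"] not in positions[pid]:
                positions[pid].append(int(link["Position"]))
            for store, key in ((score_diff, "Score diff"), (loc_prob, "Localization prob")):
                v = link[key]
                if pd.notna(v):
                    store[pid] = min(store.get(pid, np.inf), float(v))

    ids = out["id"].astype(int)
    out["Site positions"] = [
        ";".join(str(p) for p in sorted(positions.get(i, []))) for i in ids
    ]
    out["Score diff"] = [score_diff.get(i, np.nan) for i in ids]
    out["Localization prob"] = [loc_prob.get(i, np.nan) for i in ids]
    return out


def site_positions_list(field: str) -> list[int]:
    """Parse the merged ``Site positions`` column back into integers."""
    if field is None or field == "" or (isinstance(field, float) and np.isnan(field)):
        return []
    return [int(x) for x in str(field).split(";")]
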