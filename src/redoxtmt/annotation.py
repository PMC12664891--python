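"""Positional feature annotation of cysteine sites and GO category counting.

Sites are annotated by interval containment against UniProt-style
sequence features (active site, disulfide bond, metal binding, ...):
a site (protein, position) carries feature type T iff some feature of
type T on that protein spans the position.  Feature tables are accepted
either as a UniProt tab-separated feature export or as GFF3 feature
lines.  GO annotation is a flat accession -> term multimap; category
counting ranks terms by the number of annotated proteins (no DAG
reasoning).
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

UNANNOTATED = "unannotated"

#: exclusive-mode priority, most specific first
FEATURE_PRIORITY = [
    "active site",
    "metal binding",
    "disulfide bond",
    "binding site",
    "modified residue",
]

FEATURE_COLUMNS = ["Protein", "Feature type", "Begin", "End", "Description"]


def read_uniprot_features(path: str | Path) -> pd.DataFrame:
    """Read a UniProt feature export TSV (accession, type, begin, end[, description])."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in FEATURE_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing feature column(s) {missing}")
    if "Description" not in df.columns:
        df["Description"] = ""
    df["Begin"] = df["Begin"].astype(int)
    df["End"] = df["End"].astype(int)
    bad = df["Begin"] > df["End"]
    if bad.any():
        raise ValueError(f"{path}: {bad.sum()} feature(s) with Begin > End")
    return df[FEATURE_COLUMNS]


def read_features_gff3(path: str | Path) -> pd.DataFrame:
    """Read protein features from GFF3 lines (seqid=accession, type in column 3)."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 5:
            continue
        rows.append(
            {
                "Protein": parts[0],
                "Feature type": parts[2].replace("_", " ").lower(),
                "Begin": int(parts[3]),
                "End": int(parts[4]),
                "Description": parts[8] if len(parts) > 8 else "",
            }
        )
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def annotate_sites(
    sites: Iterable[tuple[str, int]], features: pd.DataFrame
) -> dict[tuple[str, int], list[str]]:
    """Map each site to the feature types whose interval contains it.

    Output order of types per site is deterministic (priority order
    first, then alphabetical); a site matching nothing maps to an empty
    list.  Pure function of its inputs — feature row order is
    irrelevant.
    """
    by_protein: dict[str, list[tuple[int, int, str]]] = {}
    for _, f in features.iterrows():
        by_protein.setdefault(f["Protein"], []).append(
            (int(f["Begin"]), int(f["End"]), f["Feature type"])
        )

    def type_key(t: str):
        try:
            return (0, FEATURE_PRIORITY.index(t))
        except ValueError:
            return (1, t)

    out: dict[tuple[str, int], list[str]] = {}
    for prot, pos in sites:
        pos = int(pos)
        hits = {
            ftype
            for begin, end, ftype in by_protein.get(prot, [])
            if begin <= pos <= end
        }
        out[(prot, pos)] = sorted(hits, key=type_key)
    return out


def exclusive_annotation(types: Sequence[str]) -> str:
    """Collapse a multi-annotation to one label by fixed priority."""
    if not types:
        return UNANNOTATED
    for t in FEATURE_PRIORITY:
        if t in types:
            return t
    return sorted(types)[0]


def category_fraction_report(
    annotations: Mapping[tuple[str, int], Sequence[str]],
    exclusive: bool = False,
) -> pd.DataFrame:
    """Fraction of sites per feature type.

    exclusive=True recodes each site to a single label (priority order)
    so fractions sum to 1; otherwise a site counts once in every type it
    carries and rows are flagged as multimap fractions.
    """
    n = len(annotations)
    if n == 0:
        return pd.DataFrame(columns=["feature_type", "count", "fraction", "mode"])
    counts: Counter = Counter()
    if exclusive:
        for types in annotations.values():
            counts[exclusive_annotation(list(types))] += 1
    else:
        for types in annotations.values():
            if types:
                counts.update(types)
            else:
                counts[UNANNOTATED] += 1
    rows = [
        {"feature_type": t, "count": c, "fraction": c / n,
         "mode": "exclusive" if exclusive else "multimap"}
        for t, c in sorted(counts.items())
    ]
    return pd.DataFrame(rows)


def read_go_map(path: str | Path) -> dict[str, list[str]]:
    """Read a two-column (accession, term) TSV into a multimap."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    acc_col, term_col = df.columns[:2]
    out: dict[str, list[str]] = {}
    for acc, term in zip(df[acc_col], df[term_col]):
        out.setdefault(acc, [])
        if term not in out[acc]:
            out[acc].append(term)
    return out


def go_category_counting(
    proteins: Iterable[str],
    go_map: Mapping[str, Sequence[str]],
    top_k: int = 10,
) -> pd.DataFrame:
    """Rank GO terms by how many of the given proteins carry them.

    A protein counts once per distinct term it carries.  Ties are broken
    lexicographically by term, making the ranking deterministic under
    input shuffling.  Fractions are relative to the number of proteins
    with at least one term.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    proteins = set(proteins)
    counts: Counter = Counter()
    annotated = 0
    for p in sorted(proteins):
        terms = set(go_map.get(p, ()))
        if terms:
            annotated += 1
            counts.update(terms)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
    return pd.DataFrame(
        [
            {"term": t, "count": c, "fraction": c / annotated if annotated else 0.0}
            for t, c in ranked
        ],
        columns=["term", "count", "fraction"],
    )
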