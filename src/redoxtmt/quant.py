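"""Site-level oxidation stoichiometry from paired light/heavy evidence.

A cysteine site is identified by (protein accession, 1-based position).
All surviving peptide evidences mapping to the same site and labeling
state (charge states, missed-cleavage variants) are summed per channel;
when both the light (reduced) and heavy (reversibly oxidized) pools of
a site are quantified, their sum is taken as 100% of that site and the
oxidation stoichiometry per sample is 100*H/(H+L).  The ratio is
invariant to any factor shared by H and L — peptide ionization
efficiency and the protein-abundance normalization both cancel.

MIXED-label peptides (light and heavy on different cysteines of the
same peptide) are excluded: their per-site H/L attribution is ambiguous.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import mq_tables as mq

SITE_INDEX = ["Protein", "Position"]

PAIRED = "paired"
LIGHT_ONLY = "light-only"
HEAVY_ONLY = "heavy-only"


def site_evidence(
    merged: pd.DataFrame, intensities: pd.DataFrame
) -> pd.DataFrame:
    """Explode labeled peptide rows into one evidence row per cysteine site.

    `merged` is the output of merge_site_columns after filtering;
    `intensities` the analysis-ready sample matrix indexed by row id.
    A peptide with several same-label cysteines contributes its full
    intensity vector to each of its sites.  MIXED and unlabeled rows
    are skipped (the former are returned separately by callers that
    need them).
    """
    records = []
    channel_cols = list(intensities.columns)
    for _, row in merged.iterrows():
        state = row["Label state"]
        if state not in (mq.LabelState.LIGHT.value, mq.LabelState.HEAVY.value):
            continue
        rid = int(row["id"])
        if rid not in intensities.index:
            continue
        positions = mq.site_positions_list(row.get("Site positions", ""))
        vec = intensities.loc[rid]
        for pos in positions:
            rec = {
                "Protein": row["Leading razor protein"],
                "Position": int(pos),
                "Label state": state,
                "id": rid,
            }
            rec.update({c: vec[c] for c in channel_cols})
            records.append(rec)
    cols = SITE_INDEX + ["Label state", "id"] + channel_cols
    return pd.DataFrame(records, columns=cols)


def aggregate_evidences(
    evidence: pd.DataFrame, channel_cols: list[str]
) -> pd.DataFrame:
    """Sum evidence intensities per (site, label state) channel-wise.

    Missing values count as 0 in the sum but a channel to which every
    contributing evidence is missing stays missing.  The number of
    contributing evidences is recorded as ``n_evidences``.
    """
    if evidence.empty:
        return pd.DataFrame(
            columns=SITE_INDEX + ["Label state", "n_evidences"] + channel_cols
        )
    keys = SITE_INDEX + ["Label state"]
    grouped = evidence.groupby(keys, sort=True)
    sums = grouped[channel_cols].sum(min_count=1)  # all-NaN -> NaN
    n = grouped.size().rename("n_evidences")
    out = pd.concat([n, sums], axis=1).reset_index()
    return out


def pair_light_heavy(
    aggregated: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Partition sites into paired / light-only / heavy-only.

    A site is paired iff both labeling states survived upstream
    filtering.  The three partitions are disjoint and exhaustive over
    sites with at least one surviving state.  Paired output is a wide
    frame with a column level per label state.
    """
    light = aggregated[aggregated["Label state"] == mq.LabelState.LIGHT.value]
    heavy = aggregated[aggregated["Label state"] == mq.LabelState.HEAVY.value]
    light = light.set_index(SITE_INDEX)
    heavy = heavy.set_index(SITE_INDEX)
    both = light.index.intersection(heavy.index)
    paired = pd.concat(
        {"L": light.loc[both], "H": heavy.loc[both]}, axis=1
    ).sort_index()
    light_only = light.drop(both).sort_index()
    heavy_only = heavy.drop(both).sort_index()
    return paired, light_only, heavy_only


def compute_stoichiometry(H, L):
    """Percent oxidized, 100*H/(H+L), elementwise.

    Missing wherever H or L is missing or H+L == 0.  Computed so that
    the complement identity s(H,L) + s(L,H) == 100 holds exactly in
    floating point: the smaller pool's share is computed directly and
    the larger pool's share as its complement.
    """
    H_arr = np.asarray(H, dtype=float)
    L_arr = np.asarray(L, dtype=float)
    total = H_arr + L_arr
    with np.errstate(divide="ignore", invalid="ignore"):
        direct = 100.0 * (H_arr / total)            # used where H <= L
        complement = 100.0 - 100.0 * (L_arr / total)  # used where H > L
    s = np.where(H_arr <= L_arr, direct, complement)
    s = np.where(np.isnan(H_arr) | np.isnan(L_arr) | (total == 0), np.nan, s)
    if np.isscalar(H) and np.isscalar(L):
        return float(s)
    return s


def stoichiometry_table(paired: pd.DataFrame, channel_cols: list[str]) -> pd.DataFrame:
    """Per-sample stoichiometry (percent) for every paired site."""
    H_mat = paired["H"][channel_cols].to_numpy(dtype=float)
    L_mat = paired["L"][channel_cols].to_numpy(dtype=float)
    return pd.DataFrame(
        compute_stoichiometry(H_mat, L_mat), index=paired.index, columns=channel_cols
    )


def compute_cv(values) -> float:
    """Percent coefficient of variation of replicate measurements.

    100 * sample standard deviation / mean on the linear scale; missing
    with fewer than 2 non-missing values or zero mean.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 2:
        return float("nan")
    m = arr.mean()
    if m == 0:
        return float("nan")
    return float(100.0 * arr.std(ddof=1) / m)


def cv_by_condition(
    matrix: pd.DataFrame, groups: pd.Series
) -> pd.DataFrame:
    """Row-wise percent CV within each condition's replicate channels.

    `matrix` holds linear-scale intensities (columns = sample channels);
    `groups` maps channel name -> condition label.
    """
    out = {}
    for cond in pd.unique(groups):
        cols = [c for c in matrix.columns if groups.get(c) == cond]
        sub = matrix[cols].to_numpy(dtype=float)
        n = np.sum(~np.isnan(sub), axis=1)
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(np.where(np.isnan(sub), np.nan, sub), axis=1)
            sd = np.full(len(sub), np.nan)
            ok = n >= 2
            if ok.any():
                sd[ok] = np.nanstd(sub[ok], axis=1, ddof=1)
        cv = 100.0 * sd / mean
        cv[(n < 2) | (mean == 0)] = np.nan
        out[cond] = cv
    return pd.DataFrame(out, index=matrix.index)
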