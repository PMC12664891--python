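"""Permutation-FDR significance testing and category enrichment.

Differential oxidation is tested row-wise (one row per site or peptide,
one column per sample) with a two-sample t statistic or a one-way F
statistic, optionally variance-moderated by a SAM-style fudge constant
s0 added to the standard-error denominator.  The null distribution is
built by permuting the condition labels of the columns — every distinct
permutation when few exist, otherwise a seeded random sample — and the
q-value at threshold t* is the average number of permuted statistics
exceeding t* divided by the number of observed statistics exceeding t*,
monotonized step-up.  This mirrors the Perseus/SAM procedure.

Category enrichment of a selection against a background uses the
two-sided Fisher exact test with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests


class ConfigError(ValueError):
    """Invalid test configuration (group sizes, label levels)."""


@dataclasses.dataclass(frozen=True)
class PermutationConfig:
    """Settings for permutation-based FDR testing.

    n_permutations: random permutations drawn when exhaustive
        enumeration is infeasible.
    s0: fudge constant added to the statistic denominator (0 = plain
        t/F).
    fdr_threshold: q-value cutoff for the `significant` call.
    rng_seed: seed for the permutation sampler.
    max_exact: enumerate all distinct permutations when their count is
        at most this.
    use_raw_p: call significance on the unadjusted permutation p-value
        instead of the q-value (single-comparison volcano mode).
    """

    n_permutations: int = 250
    s0: float = 0.0
    fdr_threshold: float = 0.05
    rng_seed: int = 0
    max_exact: int = 10_000
    use_raw_p: bool = False

    def __post_init__(self) -> None:
        if self.n_permutations < 100:
            raise ConfigError("n_permutations must be >= 100")
        if self.s0 < 0:
            raise ConfigError("s0 must be non-negative")
        if not 0 < self.fdr_threshold < 1:
            raise ConfigError("fdr_threshold must be in (0, 1)")


def _group_indices(groups: Sequence) -> tuple[list, list[np.ndarray]]:
    labels = pd.unique(np.asarray(groups, dtype=object))
    g = np.asarray(groups, dtype=object)
    idx = [np.flatnonzero(g == lab) for lab in labels]
    for lab, ix in zip(labels, idx):
        if len(ix) < 2:
            raise ConfigError(f"group {lab!r} has {len(ix)} samples; need >= 2")
    return list(labels), idx


def _moderated_t(X: np.ndarray, i1: np.ndarray, i2: np.ndarray, s0: float):
    """Row-wise two-sample pooled-variance t with s0 moderation (nan-aware)."""
    x1, x2 = X[:, i1], X[:, i2]
    n1 = np.sum(~np.isnan(x1), axis=1)
    n2 = np.sum(~np.isnan(x2), axis=1)
    with np.errstate(invalid="ignore"):
        m1 = np.nanmean(x1, axis=1)
        m2 = np.nanmean(x2, axis=1)
        v1 = np.nansum((x1 - m1[:, None]) ** 2, axis=1)
        v2 = np.nansum((x2 - m2[:, None]) ** 2, axis=1)
    df = n1 + n2 - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        sp = np.sqrt((v1 + v2) / df)
        se = sp * np.sqrt(1.0 / n1 + 1.0 / n2)
        t = (m1 - m2) / (s0 + se)
    return t, m1, m2, se, n1, n2


def _moderated_f(X: np.ndarray, idx: list[np.ndarray], s0: float):
    """Row-wise one-way F with the within-group scale moderated by s0."""
    means, ns, sses = [], [], []
    for ix in idx:
        xg = X[:, ix]
        n = np.sum(~np.isnan(xg), axis=1)
        with np.errstate(invalid="ignore"):
            m = np.nanmean(xg, axis=1)
            sse = np.nansum((xg - m[:, None]) ** 2, axis=1)
        means.append(m)
        ns.append(n)
        sses.append(sse)
    means_arr = np.stack(means)          # k x R
    ns_arr = np.stack(ns)
    sse_arr = np.stack(sses)
    k = len(idx)
    n_tot = ns_arr.sum(axis=0)
    grand = (means_arr * ns_arr).sum(axis=0) / n_tot
    ssb = (ns_arr * (means_arr - grand) ** 2).sum(axis=0)
    ssw = sse_arr.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        msb = ssb / (k - 1)
        msw = ssw / (n_tot - k)
        f = msb / (np.sqrt(msw) + s0) ** 2
    return f, means_arr, msw, ns_arr


def _partition_key(labels: np.ndarray) -> frozenset:
    groups = {}
    for i, g in enumerate(labels):
        groups.setdefault(int(g), []).append(i)
    return frozenset(frozenset(v) for v in groups.values())


def _enumerate_assignments(sizes: list[int], config: PermutationConfig):
    """Yield group-label vectors (int codes) over columns.

    All distinct multiset permutations if their count is within
    max_exact, else n_permutations seeded uniform shuffles.
    Assignments whose induced column partition equals the observed one
    (the identity labeling and, for equal-sized groups, its
    relabelings) are skipped: they reproduce the observed statistics
    and are not draws from the null.
    """
    n = sum(sizes)
    total = math.factorial(n)
    for s in sizes:
        total //= math.factorial(s)
    base = np.repeat(np.arange(len(sizes)), sizes)
    base_key = _partition_key(base)
    if total <= config.max_exact:
        if len(sizes) == 2:
            for combo in itertools.combinations(range(n), sizes[0]):
                lab = np.ones(n, dtype=int)
                lab[list(combo)] = 0
                if _partition_key(lab) == base_key:
                    continue
                yield lab
        else:
            from sympy.utilities.iterables import multiset_permutations

            for perm in multiset_permutations(base.tolist()):
                arr = np.asarray(perm, dtype=int)
                if _partition_key(arr) == base_key:
                    continue
                yield arr
    else:
        rng = np.random.default_rng(config.rng_seed)
        drawn = 0
        while drawn < config.n_permutations:
            lab = rng.permutation(base)
            if _partition_key(lab) == base_key:
                continue
            drawn += 1
            yield lab


def n_distinct_permutations(sizes: Sequence[int]) -> int:
    total = math.factorial(sum(sizes))
    for s in sizes:
        total //= math.factorial(s)
    return total


def _permutation_fdr(
    X: np.ndarray,
    index: pd.Index,
    stat_fn,
    group_sizes: list[int],
    config: PermutationConfig,
) -> pd.DataFrame:
    """Shared permutation machinery.

    `stat_fn(labels)` returns the row-wise statistic for a label-code
    vector over the (group-block-reordered) columns.
    """
    base_labels = np.repeat(np.arange(len(group_sizes)), group_sizes)
    obs = stat_fn(base_labels)
    obs_abs = np.abs(obs)

    sorted_obs = np.sort(obs_abs)  # ascending
    r = len(obs_abs)
    pooled_ge = np.zeros(r)
    per_row_ge = np.zeros(r)
    n_perms = 0
    for labels in _enumerate_assignments(group_sizes, config):
        perm_abs = np.abs(stat_fn(labels))
        n_perms += 1
        sp = np.sort(perm_abs)
        pooled_ge += r - np.searchsorted(sp, sorted_obs, side="left")
        per_row_ge += (perm_abs >= obs_abs).astype(float)

    pos = np.searchsorted(sorted_obs, obs_abs, side="left")
    obs_ge = r - pos
    fp = pooled_ge[pos] / n_perms
    raw_p = (per_row_ge + 1.0) / (n_perms + 1.0)
    # SAM-style pi0: fraction of rows that look null, from the upper half
    # of the permutation p-value range
    pi0 = min(1.0, float(np.sum(raw_p > 0.5)) / (0.5 * r)) if r else 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        raw_q = np.minimum(pi0 * fp / obs_ge, 1.0)
    # step-up monotonization: q at a looser threshold never below q at a
    # stricter one
    order = np.argsort(-obs_abs, kind="stable")
    q_sorted = np.minimum.accumulate(raw_q[order][::-1])[::-1]
    q = np.empty(r)
    q[order] = q_sorted

    crit = raw_p if config.use_raw_p else q
    return pd.DataFrame(
        {
            "statistic": obs,
            "raw_p": raw_p,
            "q_value": q,
            "significant": crit <= config.fdr_threshold,
        },
        index=index,
    )


def permutation_fdr_ttest(
    data: pd.DataFrame, groups: Sequence, config: PermutationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-group moderated t test with permutation-based FDR.

    `data`: rows = features, columns = samples; `groups`: one condition
    label per column (exactly two levels).  Returns (results, excluded):
    rows without >= 2 non-missing values per group, or with zero pooled
    variance at s0 = 0, are excluded with a reason.
    """
    labels, idx = _group_indices(groups)
    if len(labels) != 2:
        raise ConfigError(
            f"t test needs exactly 2 condition levels, got {len(labels)}; "
            "use permutation_fdr_anova for more"
        )
    X = data.to_numpy(dtype=float)
    t, m1, m2, se, n1, n2 = _moderated_t(X, idx[0], idx[1], config.s0)
    enough = (n1 >= 2) & (n2 >= 2)
    zero_var = enough & (se == 0) & (config.s0 == 0)
    usable = enough & ~zero_var
    reasons = np.where(~enough, "insufficient replicates", "zero variance")
    excluded = pd.DataFrame(
        {"reason": reasons[~usable]}, index=data.index[~usable]
    )

    Xu = X[usable]
    col_order = np.concatenate(idx)
    Xu = Xu[:, col_order]
    sizes = [len(idx[0]), len(idx[1])]

    def stat_fn(label_codes: np.ndarray) -> np.ndarray:
        i1 = np.flatnonzero(label_codes == 0)
        i2 = np.flatnonzero(label_codes == 1)
        return _moderated_t(Xu, i1, i2, config.s0)[0]

    res = _permutation_fdr(Xu, data.index[usable], stat_fn, sizes, config)
    res[f"mean {labels[0]}"] = m1[usable]
    res[f"mean {labels[1]}"] = m2[usable]
    res["difference"] = (m1 - m2)[usable]
    return res, excluded


def permutation_fdr_anova(
    data: pd.DataFrame, groups: Sequence, config: PermutationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-way moderated F test (>= 3 groups) with permutation-based FDR."""
    labels, idx = _group_indices(groups)
    if len(labels) < 3:
        raise ConfigError(
            f"ANOVA needs >= 3 condition levels, got {len(labels)}; "
            "use permutation_fdr_ttest for 2"
        )
    X = data.to_numpy(dtype=float)
    f, means_arr, msw, ns_arr = _moderated_f(X, idx, config.s0)
    enough = (ns_arr >= 2).all(axis=0)
    zero_var = enough & (msw == 0) & (config.s0 == 0)
    usable = enough & ~zero_var
    reasons = np.where(~enough, "insufficient replicates", "zero variance")
    excluded = pd.DataFrame({"reason": reasons[~usable]}, index=data.index[~usable])

    col_order = np.concatenate(idx)
    Xu = X[usable][:, col_order]
    sizes = [len(ix) for ix in idx]

    def stat_fn(label_codes: np.ndarray) -> np.ndarray:
        gidx = [np.flatnonzero(label_codes == g) for g in range(len(sizes))]
        return _moderated_f(Xu, gidx, config.s0)[0]

    res = _permutation_fdr(Xu, data.index[usable], stat_fn, sizes, config)
    for g, lab in enumerate(labels):
        res[f"mean {lab}"] = means_arr[g][usable]
    return res, excluded


def fisher_two_sided_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for one 2x2 table."""
    return float(scipy.stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def fisher_enrichment(
    selection: set,
    background: set,
    categories: Mapping[object, Sequence[str]],
    fdr: float = 0.02,
) -> pd.DataFrame:
    """Two-sided Fisher exact enrichment of a selection within a background.

    `categories` maps each id to its category labels (multimap).  Per
    category the 2x2 table {in/out selection x in/out category} over the
    background is tested; q-values are Benjamini-Hochberg.  Relative
    enrichment is (selection fraction in category) / (background
    fraction in category).  Categories with no background members are
    absent from the output.
    """
    selection = set(selection)
    background = set(background)
    if not selection <= background:
        orphans = sorted(map(str, selection - background))[:5]
        raise ValueError(f"selection is not a subset of background (e.g. {orphans})")
    members: dict[str, set] = {}
    for item in background:
        for cat in categories.get(item, ()):
            members.setdefault(cat, set()).add(item)
    rows = []
    n_sel, n_bg = len(selection), len(background)
    for cat in sorted(members):
        in_cat = members[cat]
        a = len(selection & in_cat)
        b = n_sel - a
        c = len(in_cat) - a
        d = (n_bg - n_sel) - c
        p = fisher_two_sided_p(a, b, c, d)
        enr = (a / n_sel) / (len(in_cat) / n_bg) if n_sel else np.nan
        rows.append(
            {"category": cat, "a": a, "b": b, "c": c, "d": d,
             "selection_size": n_sel, "category_size": len(in_cat),
             "relative_enrichment": enr, "p_value": p}
        )
    out = pd.DataFrame(
        rows,
        columns=["category", "a", "b", "c", "d", "selection_size",
                 "category_size", "relative_enrichment", "p_value"],
    )
    if len(out):
        reject, q, _, _ = multipletests(out["p_value"], alpha=fdr, method="fdr_bh")
        out["q_value"] = q
        out["significant"] = reject
    else:
        out["q_value"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out
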