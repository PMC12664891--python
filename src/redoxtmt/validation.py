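"""Parameter-recovery and calibration experiments for the whole workflow.

Each function sets up a seeded in-silico experiment, runs the package's
own estimation path on it, and measures how well known quantities are
recovered: exactness in the noiseless limit, stoichiometry error under
realistic noise, the carrier's detection boost, impurity-correction
round-trips, permutation-FDR calibration and power, Fisher/BH agreement
with exact enumeration, filter accounting, and the ratio-compression
shrinkage law.  The oracles used for comparison (rule enumeration,
exact hypergeometric sums, a hand-rolled BH step-up) are written
independently of the code paths they check.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import filtering as flt
from . import mq_tables as mq
from . import quant
from . import stats as st
from .design import tmt_like_impurity_matrix
from .model import RedoxStoichiometryModel
from .pipeline import compare_with_truth
from .reporter import correct_isotope_impurities
from .simulate import SimParams, simulate_experiment


def _sub_seed(seed: int, k: int) -> int:
    return (seed * 1000 + k) % (2**31 - 1)


# ---------------------------------------------------------------------------
# stoichiometry recovery


def noiseless_recovery(seed: int, n_proteins: int = 60) -> dict:
    """Max |estimate - truth| with all noise sources off (expected ~0)."""
    params = SimParams(
        rng_seed=_sub_seed(seed, 1), n_proteins=n_proteins,
        reporter_cv=0.0, interference_rho=0.0, impurity_leak=0.0,
        detection_threshold=0.0, carrier_factor=0.0,
    )
    tables, truth, design = simulate_experiment(params)
    res = RedoxStoichiometryModel.from_tables(tables, design).fit()
    groups = design.sample_groups()
    worst = 0.0
    n_vals = 0
    for ch in res.stoichiometry.columns:
        true_pct = 100.0 * truth.sites.loc[res.stoichiometry.index, groups[ch]].to_numpy()
        err = np.abs(res.stoichiometry[ch].to_numpy(dtype=float) - true_pct)
        worst = max(worst, float(np.nanmax(err)))
        n_vals += int(np.sum(~np.isnan(err)))
    return {"max_abs_error_pct": worst, "n_sites": len(res.stoichiometry), "n": n_vals}


def default_run_recovery(seed: int) -> dict:
    """Recovery metrics of the reference experiment (default SimParams)."""
    params = SimParams(rng_seed=_sub_seed(seed, 2))
    tables, truth, design = simulate_experiment(params)
    res = RedoxStoichiometryModel.from_tables(tables, design).fit()
    tests, _ = res.test_stoichiometry(
        st.PermutationConfig(rng_seed=_sub_seed(seed, 3))
    )
    score = compare_with_truth(res, truth, tests)
    n_light = int((res.peptide_table["Label state"] == "LIGHT").sum())
    score["n_cys_peptides"] = n_light
    return score


# ---------------------------------------------------------------------------
# carrier boost


def carrier_boost(
    seed: int,
    factors: tuple[float, ...] = (0.0, 1.0, 10.0, 100.0),
    n_repeats: int = 10,
    n_proteins: int = 50,
    detection_threshold: float = 2e6,
) -> dict:
    """Identified heavy-row counts across carrier loadings, per seeded repeat.

    The detection threshold is set high enough to censor most heavy rows
    without a carrier; the count must be non-decreasing in the carrier
    factor within every repeat.
    """

    def heavy_count(params: SimParams) -> int:
        tables, _, _ = simulate_experiment(params)
        mod = tables["modificationSpecificPeptides"]
        labels = mod["Modifications"].map(lambda s: mq.parse_label_state(s).value)
        return int((labels == "HEAVY").sum())

    counts = []
    censored = []
    for r in range(n_repeats):
        run_seed = _sub_seed(seed, 10 + r)
        row = [
            heavy_count(
                SimParams(
                    rng_seed=run_seed, n_proteins=n_proteins,
                    carrier_factor=c, detection_threshold=detection_threshold,
                )
            )
            for c in factors
        ]
        total = heavy_count(
            SimParams(rng_seed=run_seed, n_proteins=n_proteins,
                      carrier_factor=0.0, detection_threshold=0.0)
        )
        counts.append(row)
        censored.append(1.0 - row[0] / total if total else np.nan)
    arr = np.asarray(counts)
    monotone = (np.diff(arr, axis=1) >= 0).all(axis=1)
    return {
        "factors": list(factors),
        "counts": counts,
        "monotone_fraction": float(monotone.mean()),
        "censored_fraction_at_c0": float(np.nanmean(censored)),
        "n": n_repeats,
    }


# ---------------------------------------------------------------------------
# impurity correction round-trip


def _random_diag_dominant_stochastic(rng, n: int) -> np.ndarray:
    off = rng.uniform(0.0, 1.0, size=(n, n))
    np.fill_diagonal(off, 0.0)
    mass = rng.uniform(0.0, 0.4, size=n)  # off-diagonal row mass < diagonal
    row_sums = off.sum(axis=1)
    row_sums[row_sums == 0] = 1.0
    off = off * (mass / row_sums)[:, None]
    m = off.copy()
    np.fill_diagonal(m, 1.0 - off.sum(axis=1))
    return m


def impurity_roundtrip(seed: int, n_trials: int = 100, max_channels: int = 18) -> dict:
    """Max |correct(M'x) - x| over random non-negative x and lot sheets."""
    rng = np.random.default_rng(_sub_seed(seed, 20))
    worst = 0.0
    for t in range(n_trials):
        n = int(rng.integers(2, max_channels + 1))
        if t % 2 == 0:
            m = _random_diag_dominant_stochastic(rng, n)
        else:
            m = tmt_like_impurity_matrix(n, float(rng.uniform(0.0, 0.12)))
        x = rng.uniform(0.0, 1.0, size=n)
        out = correct_isotope_impurities(m.T @ x, m)
        worst = max(worst, float(np.max(np.abs(out - x))))
    return {"max_abs_error": worst, "n": n_trials}


# ---------------------------------------------------------------------------
# FDR calibration and power


def fdr_calibration(
    seed: int,
    n_repeats: int = 20,
    n_null: int = 500,
    n_planted: int = 50,
    effect_sd: float = 10.0,
    alpha: float = 0.05,
) -> dict:
    """Null calibration and planted-effect power of both permutation tests.

    t test: 5 vs 5 samples; ANOVA: 3 x 3.  Null rows are standard
    normal; planted rows are shifted by `effect_sd` pooled standard
    deviations in one group.
    """
    rng = np.random.default_rng(_sub_seed(seed, 30))
    out = {}
    for test_name, groups, shift_cols in (
        ("ttest", ["a"] * 5 + ["b"] * 5, slice(5, 10)),
        ("anova", ["a"] * 3 + ["b"] * 3 + ["c"] * 3, slice(6, 9)),
    ):
        runner = (
            st.permutation_fdr_ttest if test_name == "ttest" else st.permutation_fdr_anova
        )
        null_fracs = []
        sens = []
        for r in range(n_repeats):
            config = st.PermutationConfig(
                fdr_threshold=alpha, rng_seed=_sub_seed(seed, 31 + r)
            )
            null = pd.DataFrame(rng.normal(size=(n_null, len(groups))))
            res, _ = runner(null, groups, config)
            null_fracs.append(res["significant"].mean())

            planted = pd.DataFrame(rng.normal(size=(n_null, len(groups))))
            planted.iloc[:n_planted, shift_cols] += effect_sd
            res, _ = runner(planted, groups, config)
            sens.append(res["significant"].iloc[:n_planted].mean())
        null_fracs_arr = np.asarray(null_fracs, dtype=float)
        out[test_name] = {
            "mean_null_fraction_significant": float(null_fracs_arr.mean()),
            "mc_se": float(null_fracs_arr.std(ddof=1) / math.sqrt(n_repeats)),
            "planted_sensitivity": float(np.mean(sens)),
            "n": n_repeats,
        }
    return out


# ---------------------------------------------------------------------------
# Fisher / BH oracles


def hypergeom_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p by direct hypergeometric enumeration.

    Integer-weight comparison makes tie handling exact.
    """
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    w_obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    total = math.comb(r1 + r2, c1)
    acc = 0
    for k in range(lo, hi + 1):
        w = math.comb(r1, k) * math.comb(r2, c1 - k)
        if w <= w_obs:
            acc += w
    return acc / total


def bh_step_up_reference(p: np.ndarray) -> np.ndarray:
    """Independent Benjamini-Hochberg step-up implementation."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fisher_vs_enumeration(max_total: int = 30) -> dict:
    """Compare the package's Fisher p to the oracle on every table with
    grand total <= max_total (hence every margin <= max_total)."""
    worst = 0.0
    count = 0
    for n in range(1, max_total + 1):
        for r1 in range(0, n + 1):
            r2 = n - r1
            for c1 in range(0, n + 1):
                lo, hi = max(0, c1 - r2), min(r1, c1)
                for a in range(lo, hi + 1):
                    b, c, d = r1 - a, c1 - a, r2 - (c1 - a)
                    p = st.fisher_two_sided_p(a, b, c, d)
                    q = hypergeom_two_sided_oracle(a, b, c, d)
                    worst = max(worst, abs(p - q))
                    count += 1
    return {"max_abs_diff": worst, "n": count}


def bh_vs_reference(seed: int, n_vectors: int = 1000) -> dict:
    """Compare production BH q-values to the reference on random p-vectors."""
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(_sub_seed(seed, 40))
    worst = 0.0
    for _ in range(n_vectors):
        p = rng.uniform(size=int(rng.integers(2, 200)))
        _, q, _, _ = multipletests(p, method="fdr_bh")
        worst = max(worst, float(np.max(np.abs(q - bh_step_up_reference(p)))))
    return {"max_abs_diff": worst, "n": n_vectors}


# ---------------------------------------------------------------------------
# filter accounting on a fixed fixture


def _raw_cols(n: int) -> list[str]:
    return [f"{mq.RAW_FAMILY} {i + 1}" for i in range(n)]


def filter_fixture_audit() -> dict:
    """Run the filter chain on a fixed 20-row fixture and cross-check every
    report count against an independent pure-Python enumeration."""
    from .design import simple_design

    design = simple_design(["a", "b"], 2, carrier=True)  # 4 samples + carrier
    cols = _raw_cols(5)

    proteins = pd.DataFrame(
        {
            "id": range(20),
            "Unique peptides": [0 if i in (6, 7) else 3 for i in range(20)],
            "Only identified by site": [i in (3, 4, 5) for i in range(20)],
            "Reverse": [i in (0, 1) for i in range(20)],
            "Potential contaminant": [i == 2 for i in range(20)],
        }
    )
    peptide_rows = []
    for i in range(20):
        intensities = [10.0] * 5
        if i in (5, 6):
            intensities[1] = 0.0          # incomplete in a sample channel
        if i == 8:
            intensities[4] = 0.0          # zero only in the carrier: complete
        row = {
            "id": i,
            "C count": 0 if i in (2, 3, 4) else 2,
            "Reverse": i == 0,
            "Potential contaminant": i == 1,
        }
        row.update(dict(zip(cols, intensities)))
        peptide_rows.append(row)
    peptides = pd.DataFrame(peptide_rows)

    # package path
    pg1, rep_pg_decoy = flt.remove_decoys_contaminants(proteins)
    pg2, rep_pg_rules = flt.filter_protein_groups(pg1)
    pep1, rep_pep_decoy = flt.remove_decoys_contaminants(peptides)
    cys, non_cys, rep_cys = flt.filter_cys_peptides(pep1)
    complete, rep_complete = flt.complete_case_filter(cys, design)

    # independent enumeration (plain python, no pandas filtering)
    prot_rows = proteins.to_dict("records")
    pep_rows = peptides.to_dict("records")
    surv_pg1 = [r for r in prot_rows if not (r["Reverse"] or r["Potential contaminant"])]
    surv_pg2 = [r for r in surv_pg1
                if not r["Only identified by site"] and r["Unique peptides"] >= 1]
    surv_pep1 = [r for r in pep_rows if not (r["Reverse"] or r["Potential contaminant"])]
    surv_cys = [r for r in surv_pep1 if r["C count"] >= 1]
    sample_cols = [cols[i] for i in design.sample_indices]
    surv_complete = [r for r in surv_cys if all(r[c] > 0 for c in sample_cols)]

    expected = {
        "remove_decoys_contaminants(proteins)": (len(prot_rows), len(surv_pg1)),
        "filter_protein_groups": (len(surv_pg1), len(surv_pg2)),
        "remove_decoys_contaminants(peptides)": (len(pep_rows), len(surv_pep1)),
        "filter_cys_peptides": (len(surv_pep1), len(surv_cys)),
        "complete_case_filter": (len(surv_cys), len(surv_complete)),
    }
    observed = {
        "remove_decoys_contaminants(proteins)": (rep_pg_decoy.rows_in, rep_pg_decoy.rows_out),
        "filter_protein_groups": (rep_pg_rules.rows_in, rep_pg_rules.rows_out),
        "remove_decoys_contaminants(peptides)": (rep_pep_decoy.rows_in, rep_pep_decoy.rows_out),
        "filter_cys_peptides": (rep_cys.rows_in, rep_cys.rows_out),
        "complete_case_filter": (rep_complete.rows_in, rep_complete.rows_out),
    }
    mismatches = sum(1 for k in expected if expected[k] != observed[k])
    return {
        "expected": expected,
        "observed": observed,
        "mismatches": mismatches,
        "n_non_cys": len(non_cys),
        "n": len(expected),
    }


# ---------------------------------------------------------------------------
# ratio compression


def ratio_compression(seed: int, rho: float = 0.5, n_proteins: int = 200) -> dict:
    """Shrinkage of between-condition stoichiometry differences under
    co-isolation interference, against the (1 - rho) mixing law.

    Protein levels are held constant across conditions and reporter
    noise is off so the law is the only effect; no carrier, so the plex
    mean is over sample channels alone.
    """
    deltas = {}
    for r in (0.0, rho):
        params = SimParams(
            rng_seed=_sub_seed(seed, 50), n_proteins=n_proteins,
            reporter_cv=0.0, interference_rho=r, carrier=False,
            carrier_factor=0.0, detection_threshold=0.0,
            protein_fold_log2_sd=0.0, effect_fraction=0.5,
        )
        tables, _, design = simulate_experiment(params)
        res = RedoxStoichiometryModel.from_tables(tables, design).fit()
        by_cond = res.stoichiometry_by_condition
        deltas[r] = by_cond.iloc[:, -1] - by_cond.iloc[:, 0]
    base, mixed = deltas[0.0], deltas[rho]
    common = base.index.intersection(mixed.index)
    big = common[np.abs(base.loc[common]) > 1.0]
    ratio = (mixed.loc[big] / base.loc[big]).to_numpy(dtype=float)
    return {
        "rho": rho,
        "mean_shrinkage_factor": float(np.nanmean(ratio)),
        "expected_factor": 1.0 - rho,
        "n": int(len(big)),
    }
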