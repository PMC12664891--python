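"""End-to-end orchestration: simulate -> quantify -> test -> score.

`run_pipeline` sequences the stages behind a single validated config
and writes a manifest (config, versions, row counts, output checksums)
so that seeded reruns are verifiably identical.  `compare_with_truth`
scores a fitted result against simulator ground truth: stoichiometry
RMSE and bias, partition counts, and sensitivity / empirical FDR of the
significance calls.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import annotation as ann
from . import filtering as flt
from . import mq_tables as mq
from . import simulate as sim
from . import stats as st
from .design import ChannelDesign
from .model import RedoxResults, RedoxStoichiometryModel

logger = logging.getLogger(__name__)


class ConfigValidationError(ValueError):
    """Run configuration is incomplete or inconsistent."""


@dataclasses.dataclass
class RunConfig:
    """Everything one pipeline run needs; validated before any stage runs."""

    out_dir: Path
    seed: int = 0
    sim_params: sim.SimParams | None = None
    input_dir: Path | None = None
    design_path: Path | None = None
    intensity_family: str = mq.RAW_FAMILY
    completeness_mode: str = flt.ALL_SAMPLES
    n_permutations: int = 250
    s0: float = 0.0
    fdr_threshold: float = 0.05
    feature_table: Path | None = None
    go_table: Path | None = None

    def validate(self) -> None:
        if self.sim_params is None:
            if self.input_dir is None:
                raise ConfigValidationError(
                    "either simulation parameters or an input directory is required"
                )
            if self.design_path is None:
                raise ConfigValidationError(
                    "a channel design file is required for non-simulated input"
                )
        if self.intensity_family not in (mq.RAW_FAMILY, mq.CORRECTED_FAMILY):
            raise ConfigValidationError(
                f"unknown intensity family {self.intensity_family!r}"
            )

    def permutation_config(self) -> st.PermutationConfig:
        return st.PermutationConfig(
            n_permutations=self.n_permutations,
            s0=self.s0,
            fdr_threshold=self.fdr_threshold,
            rng_seed=self.seed + 1,
        )

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, Path):
                d[k] = str(v)
        if self.sim_params is not None:
            d["sim_params"] = dataclasses.asdict(self.sim_params)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def compare_with_truth(
    results: RedoxResults,
    truth: sim.GroundTruth,
    test_results: pd.DataFrame | None = None,
) -> dict:
    """Score fitted stoichiometries (and optional significance calls) vs truth.

    Stoichiometry error is evaluated per paired site and sample channel
    against 100 x the true oxidation fraction of the channel's
    condition.  Sensitivity and empirical FDR require `test_results`
    (any frame with a boolean ``significant`` indexed by site).
    """
    est = results.stoichiometry
    missing = est.index.difference(truth.sites.index)
    if len(missing):
        raise KeyError(
            f"{len(missing)} estimated site(s) absent from ground truth, "
            f"e.g. {list(missing[:3])}"
        )
    groups = results.design.sample_groups()
    errors = []
    for ch in est.columns:
        cond = groups[ch]
        true_pct = 100.0 * truth.sites.loc[est.index, cond].to_numpy(dtype=float)
        errors.append(est[ch].to_numpy(dtype=float) - true_pct)
    err = np.concatenate(errors)
    err = err[~np.isnan(err)]
    score = {
        "n_sites_scored": int(len(est)),
        "stoichiometry_rmse_pct": float(np.sqrt(np.mean(err**2))) if err.size else None,
        "stoichiometry_bias_pct": float(np.mean(err)) if err.size else None,
        "partition_counts": results.partition_counts,
        "median_cv_pct": results.median_cv,
    }
    if test_results is not None:
        regulated = truth.sites["regulated"].astype(bool)
        tested = test_results.index
        reg_tested = regulated.loc[tested]
        called = test_results["significant"].astype(bool)
        tp = int((called & reg_tested).sum())
        fp = int((called & ~reg_tested).sum())
        n_reg = int(reg_tested.sum())
        n_called = int(called.sum())
        score["n_tested"] = int(len(tested))
        score["n_regulated_tested"] = n_reg
        score["n_called"] = n_called
        score["sensitivity"] = tp / n_reg if n_reg else None
        score["empirical_fdr"] = fp / n_called if n_called else None
    return score


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages, write the result bundle and manifest, return a summary.

    Stage order: (optional) simulation, table reading, filtering +
    quantification (the model fit), significance testing, (optional)
    annotation, (simulation only) truth scoring, manifest.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    truth = None
    if config.sim_params is not None:
        logger.info("stage simulate: seed %d", config.sim_params.rng_seed)
        tables, truth, design = sim.simulate_experiment(config.sim_params)
        sim_dir = out_dir / "simulated"
        outputs += sim.write_maxquant_tables(tables, sim_dir)
        truth.write(sim_dir)
        outputs += [sim_dir / "truth_proteins.tsv", sim_dir / "truth_sites.tsv"]
        design.to_yaml(sim_dir / "design.yaml")
        outputs.append(sim_dir / "design.yaml")
        input_dir = sim_dir
    else:
        design = ChannelDesign.from_yaml(config.design_path)
        input_dir = Path(config.input_dir)

    logger.info("stage quantify: reading %s", input_dir)
    model = RedoxStoichiometryModel.from_directory(input_dir, design)
    results = model.fit(
        intensity_family=config.intensity_family,
        completeness_mode=config.completeness_mode,
    )
    res_dir = out_dir / "results"
    outputs += results.write(res_dir)

    logger.info("stage test: %d paired sites", len(results.stoichiometry))
    test_results, excluded = results.test_stoichiometry(config.permutation_config())
    test_path = res_dir / "stoichiometry_tests.tsv"
    test_results.to_csv(test_path, sep="\t")
    outputs.append(test_path)
    excluded_path = res_dir / "stoichiometry_tests_excluded.tsv"
    excluded.to_csv(excluded_path, sep="\t")
    outputs.append(excluded_path)

    if config.feature_table is not None:
        logger.info("stage annotate: %s", config.feature_table)
        features = ann.read_uniprot_features(config.feature_table)
        annotations = results.annotate_sites(features)
        report = ann.category_fraction_report(annotations, exclusive=True)
        p = res_dir / "site_annotation_fractions.tsv"
        report.to_csv(p, sep="\t", index=False)
        outputs.append(p)
    if config.go_table is not None:
        go_map = ann.read_go_map(config.go_table)
        proteins = {prot for prot, _ in results.stoichiometry.index}
        counting = ann.go_category_counting(proteins, go_map)
        p = res_dir / "go_category_counts.tsv"
        counting.to_csv(p, sep="\t", index=False)
        outputs.append(p)

    score = None
    if truth is not None:
        score = compare_with_truth(results, truth, test_results)
        p = out_dir / "truth_score.json"
        p.write_text(json.dumps(score, indent=2))
        outputs.append(p)

    manifest = {
        "package_version": __version__,
        "config": config.to_jsonable(),
        "row_counts": {
            r.stage: {"rows_in": r.rows_in, "rows_out": r.rows_out}
            for r in results.filter_reports
        },
        "partitions": results.partition_counts,
        "outputs": {str(p.relative_to(out_dir)): _sha256(p) for p in outputs},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "results": results,
        "tests": test_results,
        "score": score,
        "manifest": manifest,
        "out_dir": out_dir,
    }
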