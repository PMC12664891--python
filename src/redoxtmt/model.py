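"""Model/Results interface over the whole quantification workflow.

`RedoxStoichiometryModel` holds the four MaxQuant-dialect evidence
tables plus the channel design; `fit()` runs the analysis chain —
decoy/contaminant removal, protein-group and cysteine filters, the
complete-case rule, impurity correction, carrier separation,
protein-level normalization, site aggregation and light/heavy pairing —
and returns a `RedoxResults` carrying site stoichiometries, CVs,
partition bookkeeping and an audit trail, with methods for significance
testing, annotation, enrichment and export.
"""

from __future__ import annotations

import dataclasses
import io
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import annotation as ann
from . import filtering as flt
from . import mq_tables as mq
from . import quant
from . import reporter as rep
from . import stats as st
from .design import ChannelDesign


class RedoxStoichiometryModel:
    """Site-level cysteine oxidation stoichiometry estimator.

    Parameters
    ----------
    protein_groups, peptides, mod_peptides, light_sites, heavy_sites :
        Parsed MaxQuant-dialect tables (see `mq_tables.read_mq_table`).
    design :
        Channel design declaring sample/carrier roles and, optionally,
        the isotope impurity matrix.
    """

    def __init__(
        self,
        protein_groups: pd.DataFrame,
        peptides: pd.DataFrame,
        mod_peptides: pd.DataFrame,
        light_sites: pd.DataFrame,
        heavy_sites: pd.DataFrame,
        design: ChannelDesign,
    ) -> None:
        self.protein_groups = protein_groups
        self.peptides = peptides
        self.mod_peptides = mod_peptides
        self.light_sites = light_sites
        self.heavy_sites = heavy_sites
        self.design = design

    @classmethod
    def from_directory(cls, path: str | Path, design: ChannelDesign) -> "RedoxStoichiometryModel":
        """Build from a directory holding the canonical MaxQuant file names."""
        path = Path(path)
        return cls(
            protein_groups=mq.read_mq_table(
                path / mq.FILE_NAMES[mq.TableKind.PROTEIN_GROUPS],
                mq.TableKind.PROTEIN_GROUPS, design),
            peptides=mq.read_mq_table(
                path / mq.FILE_NAMES[mq.TableKind.PEPTIDES], mq.TableKind.PEPTIDES),
            mod_peptides=mq.read_mq_table(
                path / mq.FILE_NAMES[mq.TableKind.MOD_PEPTIDES],
                mq.TableKind.MOD_PEPTIDES, design),
            light_sites=mq.read_mq_table(
                path / mq.FILE_NAMES["light_sites"], mq.TableKind.SITES),
            heavy_sites=mq.read_mq_table(
                path / mq.FILE_NAMES["heavy_sites"], mq.TableKind.SITES),
            design=design,
        )

    @classmethod
    def from_tables(
        cls, tables: Mapping[str, pd.DataFrame], design: ChannelDesign
    ) -> "RedoxStoichiometryModel":
        """Build from in-memory tables keyed like the simulator's output."""
        return cls(
            protein_groups=tables["proteinGroups"],
            peptides=tables["peptides"],
            mod_peptides=tables["modificationSpecificPeptides"],
            light_sites=tables["light_sites"],
            heavy_sites=tables["heavy_sites"],
            design=design,
        )

    def fit(
        self,
        intensity_family: str = mq.RAW_FAMILY,
        completeness_mode: str = flt.ALL_SAMPLES,
        impurity_mode: str = "nnls",
    ) -> "RedoxResults":
        """Run the full chain and return the fitted results.

        intensity_family selects which reporter column family is
        authoritative; with the raw family and a design that declares an
        impurity matrix, non-negative least-squares correction is
        applied (the corrected family is taken as already corrected).
        """
        design = self.design
        reports: list[flt.FilterReport] = []

        # protein level
        pg, r = flt.remove_decoys_contaminants(self.protein_groups)
        reports.append(r)
        pg, r = flt.filter_protein_groups(pg)
        reports.append(r)

        # peptide level: merge, decoys, cysteine partition, completeness
        merged = mq.merge_site_columns(
            self.mod_peptides, self.peptides, self.heavy_sites, self.light_sites
        )
        merged, r = flt.remove_decoys_contaminants(merged)
        reports.append(r)
        cys, non_cys, r = flt.filter_cys_peptides(merged)
        reports.append(r)
        cys, r = flt.complete_case_filter(
            cys, design, family=intensity_family, mode=completeness_mode
        )
        reports.append(r)
        mixed = cys[cys["Label state"] == mq.LabelState.MIXED.value].copy()

        # analysis-ready intensities
        def analysis_matrix(table: pd.DataFrame) -> pd.DataFrame:
            mat = rep.reporter_matrix(table, design, intensity_family)
            if intensity_family == mq.RAW_FAMILY and design.impurity_matrix is not None:
                mat = rep.correct_isotope_impurities(
                    mat, design.impurity_matrix, mode=impurity_mode
                )
            return rep.zeros_to_missing(mat)

        pep_mat = analysis_matrix(cys)
        pep_samples, pep_carrier = rep.split_carrier(pep_mat, design)

        pg_mat = analysis_matrix(pg)
        accession = pg["Protein IDs"].str.split(";").str[0]
        pg_samples, pg_carrier = rep.split_carrier(pg_mat, design)
        pg_samples = pg_samples.set_axis(accession, axis=0)

        razor = pd.Series(
            cys["Leading razor protein"].to_numpy(), index=pep_samples.index
        )
        normalized, orphans = rep.normalize_to_protein(pep_samples, pg_samples, razor)

        # site-level aggregation and pairing on raw-scale sample intensities
        evidence = quant.site_evidence(cys, pep_samples)
        channel_cols = list(pep_samples.columns)
        aggregated = quant.aggregate_evidences(evidence, channel_cols)
        paired, light_only, heavy_only = quant.pair_light_heavy(aggregated)
        stoich = quant.stoichiometry_table(paired, channel_cols)

        groups = design.sample_groups()
        stoich_by_cond = pd.DataFrame(
            {
                cond: stoich[[c for c in channel_cols if groups[c] == cond]].mean(axis=1)
                for cond in design.conditions
            }
        )

        # reproducibility: CV of protein-normalized linear intensities
        linear_norm = pd.DataFrame(
            np.exp2(normalized.to_numpy(dtype=float)),
            index=normalized.index, columns=normalized.columns,
        )
        cv = quant.cv_by_condition(linear_norm, groups)

        return RedoxResults(
            model=self,
            design=design,
            intensity_family=intensity_family,
            completeness_mode=completeness_mode,
            filter_reports=reports,
            protein_table=pg,
            protein_matrix=pg_samples,
            peptide_table=cys,
            non_cys_table=non_cys,
            mixed_table=mixed,
            peptide_matrix=pep_samples,
            peptide_carrier=pep_carrier,
            normalized=normalized,
            unnormalizable=orphans,
            aggregated=aggregated,
            paired=paired,
            light_only=light_only,
            heavy_only=heavy_only,
            stoichiometry=stoich,
            stoichiometry_by_condition=stoich_by_cond,
            peptide_cv=cv,
        )


@dataclasses.dataclass
class RedoxResults:
    """Fitted quantities of one experiment, plus testing/annotation methods."""

    model: RedoxStoichiometryModel
    design: ChannelDesign
    intensity_family: str
    completeness_mode: str
    filter_reports: list[flt.FilterReport]
    protein_table: pd.DataFrame
    protein_matrix: pd.DataFrame
    peptide_table: pd.DataFrame
    non_cys_table: pd.DataFrame
    mixed_table: pd.DataFrame
    peptide_matrix: pd.DataFrame
    peptide_carrier: pd.Series
    normalized: pd.DataFrame
    unnormalizable: pd.DataFrame
    aggregated: pd.DataFrame
    paired: pd.DataFrame
    light_only: pd.DataFrame
    heavy_only: pd.DataFrame
    stoichiometry: pd.DataFrame
    stoichiometry_by_condition: pd.DataFrame
    peptide_cv: pd.DataFrame

    # -- descriptive ------------------------------------------------------
    @property
    def partition_counts(self) -> dict[str, int]:
        return {
            quant.PAIRED: len(self.paired),
            quant.LIGHT_ONLY: len(self.light_only),
            quant.HEAVY_ONLY: len(self.heavy_only),
        }

    @property
    def median_cv(self) -> float:
        """Median percent CV of quantified peptides across replicates."""
        vals = self.peptide_cv.to_numpy(dtype=float).ravel()
        vals = vals[~np.isnan(vals)]
        return float(np.median(vals)) if vals.size else float("nan")

    def site_table(self) -> pd.DataFrame:
        """Tidy one-row-per-paired-site summary with per-condition stoichiometry."""
        out = self.stoichiometry_by_condition.copy()
        out.columns = [f"stoichiometry {c} (%)" for c in out.columns]
        out["n light evidences"] = self.paired[("L", "n_evidences")]
        out["n heavy evidences"] = self.paired[("H", "n_evidences")]
        return out

    def summary(self) -> str:
        """Human-readable run summary (counts per stage, partitions, CV)."""
        buf = io.StringIO()
        print("Cysteine oxidation stoichiometry fit", file=buf)
        print("=" * 44, file=buf)
        print(f"channels: {self.design.n_channels} "
              f"({len(self.design.sample_indices)} samples"
              f"{', 1 carrier' if self.design.carrier_index is not None else ''})",
              file=buf)
        print(f"conditions: {', '.join(self.design.conditions)}", file=buf)
        print(f"intensity family: {self.intensity_family!r}", file=buf)
        print("-" * 44, file=buf)
        for r in self.filter_reports:
            print(f"{r.stage:<28} {r.rows_in:>7} -> {r.rows_out:>7}", file=buf)
        print("-" * 44, file=buf)
        counts = self.partition_counts
        print(f"paired sites:      {counts[quant.PAIRED]:>7}", file=buf)
        print(f"light-only sites:  {counts[quant.LIGHT_ONLY]:>7}", file=buf)
        print(f"heavy-only sites:  {counts[quant.HEAVY_ONLY]:>7}", file=buf)
        print(f"MIXED-label rows excluded from stoichiometry: {len(self.mixed_table)}",
              file=buf)
        print(f"median peptide CV: {self.median_cv:.2f}%", file=buf)
        return buf.getvalue()

    # -- statistics --------------------------------------------------------
    def _groups(self) -> list[str]:
        g = self.design.sample_groups()
        return [g[c] for c in self.stoichiometry.columns]

    def test_stoichiometry(
        self, config: st.PermutationConfig | None = None
    ) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Permutation-FDR test of oxidation stoichiometry across conditions.

        Two conditions: moderated t test; three or more: moderated
        one-way F test, as in the workflow's volcano/heatmap analyses.
        """
        config = config or st.PermutationConfig()
        groups = self._groups()
        if len(set(groups)) == 2:
            return st.permutation_fdr_ttest(self.stoichiometry, groups, config)
        return st.permutation_fdr_anova(self.stoichiometry, groups, config)

    def test_label_intensity(
        self, label: str = "LIGHT", config: st.PermutationConfig | None = None
    ) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Test protein-normalized log2 intensities of one labeling state.

        This is the analysis applied when a site's partner state is not
        quantified: changes in the reduced (light) pool mirror oxidation
        changes of the site.
        """
        config = config or st.PermutationConfig()
        ids = self.peptide_table.loc[
            self.peptide_table["Label state"] == label, "id"
        ].astype(int)
        data = self.normalized.loc[self.normalized.index.intersection(ids)]
        groups = [self.design.sample_groups()[c] for c in data.columns]
        if len(set(groups)) == 2:
            return st.permutation_fdr_ttest(data, groups, config)
        return st.permutation_fdr_anova(data, groups, config)

    @staticmethod
    def volcano_table(results: pd.DataFrame) -> pd.DataFrame:
        """Difference vs -log10 p, ready for a volcano plot."""
        out = results.copy()
        if "difference" not in out.columns:
            mean_cols = [c for c in out.columns if c.startswith("mean ")]
            out["difference"] = out[mean_cols[-1]] - out[mean_cols[0]]
        out["-log10 p"] = -np.log10(out["raw_p"].clip(lower=1e-300))
        return out[["difference", "-log10 p", "q_value", "significant"]]

    def plot_volcano(self, results: pd.DataFrame, ax=None):
        """Scatter the volcano table; significant rows emphasised."""
        import matplotlib.pyplot as plt

        table = self.volcano_table(results)
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        sig = table["significant"].astype(bool)
        ax.scatter(table.loc[~sig, "difference"], table.loc[~sig, "-log10 p"],
                   s=8, c="0.6", label="n.s.")
        ax.scatter(table.loc[sig, "difference"], table.loc[sig, "-log10 p"],
                   s=16, c="crimson", label="significant")
        ax.set_xlabel("difference")
        ax.set_ylabel("-log10 p")
        ax.legend(frameon=False)
        return ax

    # -- annotation --------------------------------------------------------
    def annotate_sites(self, features: pd.DataFrame) -> dict[tuple[str, int], list[str]]:
        """Feature-type annotation of every site with >= 1 surviving state."""
        sites = set(self.paired.index) | set(self.light_only.index) | set(
            self.heavy_only.index
        )
        return ann.annotate_sites(sorted(sites), features)

    def enrichment(
        self,
        selection: Sequence,
        categories: Mapping,
        fdr: float = 0.02,
    ) -> pd.DataFrame:
        """Fisher enrichment of selected paired sites against all paired sites."""
        background = set(self.stoichiometry.index)
        return st.fisher_enrichment(set(selection), background, categories, fdr)

    # -- export ------------------------------------------------------------
    def write(self, out_dir: str | Path) -> list[Path]:
        """Write the result bundle as TSV files."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []

        def emit(df: pd.DataFrame, name: str, index: bool = True):
            p = out_dir / name
            df.to_csv(p, sep="\t", index=index)
            written.append(p)

        flt.write_filter_log(self.filter_reports, out_dir / "filter_audit.tsv")
        written.append(out_dir / "filter_audit.tsv")
        emit(self.stoichiometry, "stoichiometry_per_sample.tsv")
        emit(self.stoichiometry_by_condition, "stoichiometry_per_condition.tsv")
        emit(self.site_table(), "site_quantification.tsv")
        emit(self.normalized, "normalized_log2_peptides.tsv")
        emit(self.peptide_cv, "peptide_cv.tsv")
        emit(self.light_only, "sites_light_only.tsv")
        emit(self.heavy_only, "sites_heavy_only.tsv")
        emit(self.unnormalizable, "unnormalizable_peptides.tsv", index=False)
        return written
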