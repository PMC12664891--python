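"""Ground-truth-known simulator of carrier-boosted TMT redox experiments.

The generator produces the same MaxQuant-dialect tables the real
workflow consumes, from a known ground truth, so that every downstream
stage can be validated by parameter recovery:

1. a random proteome (FASTA) is digested in silico with trypsin
   (C-terminal to K/R, not before P, up to 2 missed cleavages, minimum
   length 6 — the search settings of the workflow);
2. every cysteine site gets a true reversible-oxidation fraction:
   baseline drawn from a Beta favouring low oxidation (cells are
   strongly reducing), with a configured fraction of sites receiving
   dose-dependent logit-scale shifts across conditions;
3. each cysteine peptide appears in a light (reduced) and a heavy
   (oxidized) labeling state whose expected reporter signal in sample
   channel k is  protein abundance x peptide ionization x fraction
   (heavy) or x (1 - fraction) (light).  The carrier channel carries a
   fully heavy-labeled proteome at ``carrier_factor`` times one
   sample's loading: heavy rows get carrier_factor x base abundance x
   ionization, light rows get 0 there;
4. a peptide row is identified iff its expected signal summed over all
   channels (carrier included) exceeds the detection threshold — the
   mechanism by which the carrier rescues low-abundance oxidized
   peptides;
5. observed intensities are expected x mean-one log-normal noise, then
   co-isolation interference (convex mixing of each channel toward the
   row's plex average), then isotope impurity mixing by the transposed
   lot-sheet matrix.

Peptide molecules are treated as fully light or fully heavy (their
cysteines oxidize together), so sites sharing a peptide share one true
fraction; see the methods note for why this two-state model is the one
under which site-level ratio-of-sums recovery is exact.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import parser as pyt_parser

from . import mq_tables as mq
from .design import ChannelDesign, simple_design, tmt_like_impurity_matrix

TRYPSIN_RULE = pyt_parser.expasy_rules["trypsin"]

# Average amino-acid frequencies (vertebrate-like); cysteine is set
# explicitly by SimParams and the rest renormalized.
_AA_FREQS = {
    "A": 0.074, "D": 0.059, "E": 0.058, "F": 0.040, "G": 0.074,
    "H": 0.029, "I": 0.038, "K": 0.072, "L": 0.076, "M": 0.018,
    "N": 0.044, "P": 0.050, "Q": 0.037, "R": 0.042, "S": 0.081,
    "T": 0.062, "V": 0.068, "W": 0.013, "Y": 0.033,
}


@dataclasses.dataclass(frozen=True)
class SimParams:
    """Study conditions of a simulated carrier-boosted TMT redox experiment.

    Defaults describe the reference design: 500 proteins, three
    conditions (vehicle / low / high oxidant dose) in triplicate plus a
    10x carrier in a 10-plex, 10% reporter noise, no interference and a
    clean lot sheet unless the experiment dials them in.
    """

    rng_seed: int
    n_proteins: int = 500
    protein_length_log_mean: float = math.log(420.0)
    protein_length_log_sd: float = 0.35
    cys_frequency: float = 0.018
    conditions: tuple[str, ...] = ("vehicle", "low_h2o2", "high_h2o2")
    n_replicates: int = 3
    carrier: bool = True
    carrier_factor: float = 10.0
    detection_threshold: float = 2e5
    reporter_cv: float = 0.1
    interference_rho: float = 0.0
    baseline_oxidation: tuple[float, float] = (1.0, 19.0)  # Beta(a, b), mean 5%
    effect_fraction: float = 0.1
    effect_size: float = 2.0          # logit shift at the top condition
    protein_abundance_log_mean: float = math.log(1e6)
    protein_abundance_log_sd: float = 1.0
    protein_fold_log2_sd: float = 0.25
    ionization_log_sd: float = 1.0
    missed_cleavage_rate: float = 0.25
    max_missed_cleavages: int = 2
    min_peptide_length: int = 6
    non_cys_peptides_per_protein: int = 5
    mixed_peptide_rate: float = 0.0
    impurity_leak: float = 0.0        # 0 -> identity lot sheet
    n_decoys: int = 20
    n_contaminants: int = 10
    n_site_only_groups: int = 5
    n_zero_unique_groups: int = 5

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        for name in ("carrier_factor", "detection_threshold", "reporter_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.interference_rho < 1:
            raise ValueError("interference_rho must be in [0, 1)")
        if not 0 <= self.cys_frequency < 1:
            raise ValueError("cys_frequency must be in [0, 1)")
        if not 0 <= self.effect_fraction <= 1:
            raise ValueError("effect_fraction must be in [0, 1]")
        if not 0 <= self.missed_cleavage_rate <= 1:
            raise ValueError("missed_cleavage_rate must be in [0, 1]")


@dataclasses.dataclass
class GroundTruth:
    """True quantities behind one simulated experiment.

    proteins: per-protein abundance, columns ``base`` plus one per
    condition.  sites: per-(Protein, Position) oxidation fraction per
    condition, plus the ``regulated`` flag and the logit effect applied
    at the top condition.
    """

    proteins: pd.DataFrame
    sites: pd.DataFrame

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        self.proteins.to_csv(out_dir / "truth_proteins.tsv", sep="\t")
        self.sites.to_csv(out_dir / "truth_sites.tsv", sep="\t")

    @classmethod
    def read(cls, out_dir: str | Path) -> "GroundTruth":
        out_dir = Path(out_dir)
        proteins = pd.read_csv(out_dir / "truth_proteins.tsv", sep="\t", index_col=0)
        sites = pd.read_csv(out_dir / "truth_sites.tsv", sep="\t", index_col=[0, 1])
        return cls(proteins=proteins, sites=sites)


def design_from_params(params: SimParams) -> ChannelDesign:
    n = len(params.conditions) * params.n_replicates + (1 if params.carrier else 0)
    matrix = None
    if params.impurity_leak > 0:
        matrix = tmt_like_impurity_matrix(n, params.impurity_leak)
    return simple_design(
        list(params.conditions), params.n_replicates,
        carrier=params.carrier, impurity_matrix=matrix,
    )


def generate_proteome(
    n_proteins: int,
    seed: int,
    length_log_mean: float = math.log(420.0),
    length_log_sd: float = 0.35,
    cys_frequency: float = 0.018,
) -> list[SeqRecord]:
    """Random protein records with a controlled cysteine frequency."""
    rng = np.random.default_rng(seed)
    other = {aa: f for aa, f in _AA_FREQS.items()}
    scale = (1.0 - cys_frequency) / sum(other.values())
    letters = list(other) + ["C"]
    probs = np.array([other[aa] * scale for aa in other] + [cys_frequency])
    records = []
    for i in range(n_proteins):
        length = max(20, int(rng.lognormal(length_log_mean, length_log_sd)))
        seq = "".join(rng.choice(letters, size=length, p=probs))
        acc = f"SIMP{i + 1:05d}"
        records.append(SeqRecord(Seq(seq), id=acc, description=f"simulated protein {i + 1}"))
    return records


def write_fasta(records: Sequence[SeqRecord], path: str | Path) -> None:
    SeqIO.write(list(records), str(path), "fasta")


def read_fasta(path: str | Path) -> list[SeqRecord]:
    return list(SeqIO.parse(str(path), "fasta"))


def _missed_cleavages(peptide: str) -> int:
    """Internal uncleaved K/R (not before P) within a tryptic product."""
    count = 0
    for i, aa in enumerate(peptide[:-1]):
        if aa in "KR" and peptide[i + 1] != "P":
            count += 1
    return count


def digest_in_silico(
    sequence: str, max_missed: int = 2, min_length: int = 6
) -> list[tuple[str, int, int, int]]:
    """Tryptic digest with positions.

    Returns (peptide, start, end, n_missed) with 1-based inclusive
    protein coordinates; cleaves C-terminal to K/R except before P.
    """
    out = []
    for start0, pep in pyt_parser.icleave(
        sequence, TRYPSIN_RULE, missed_cleavages=max_missed, min_length=min_length
    ):
        end = start0 + len(pep)
        out.append((pep, start0 + 1, end, _missed_cleavages(pep)))
    out.sort(key=lambda t: (t[1], t[2]))
    return out


def _site_clusters(peptide_sites: list[list[tuple[str, int]]]) -> dict[tuple[str, int], int]:
    """Union-find over sites: sites sharing any peptide share a cluster."""
    parent: dict[tuple[str, int], tuple[str, int]] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for sites in peptide_sites:
        for s in sites:
            parent.setdefault(s, s)
        for a, b in zip(sites, sites[1:]):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    roots = {}
    labels: dict[tuple[str, int], int] = {}
    for s in sorted(parent):
        r = find(s)
        if r not in roots:
            roots[r] = len(roots)
        labels[s] = roots[r]
    return labels


def assign_ground_truth(
    records: Sequence[SeqRecord], params: SimParams
) -> tuple[GroundTruth, pd.DataFrame, dict]:
    """Digest the proteome and draw true abundances and oxidation fractions.

    Returns (truth, peptide table, site->fraction-row lookup).  The
    peptide table has one row per retained digest product per protein
    with its cysteine positions.  Sites that co-occur on any peptide
    share a cluster and hence one oxidation trajectory.
    """
    rng = np.random.default_rng(params.rng_seed)
    conditions = list(params.conditions)

    # --- protein abundances ------------------------------------------------
    accs = [r.id for r in records]
    base = rng.lognormal(params.protein_abundance_log_mean,
                         params.protein_abundance_log_sd, size=len(accs))
    prot = pd.DataFrame({"base": base}, index=pd.Index(accs, name="Protein"))
    for cond in conditions:
        fold = 2.0 ** rng.normal(0.0, params.protein_fold_log2_sd, size=len(accs))
        prot[cond] = base * fold

    # --- digestion ---------------------------------------------------------
    pep_rows = []
    for rec in records:
        seq = str(rec.seq)
        for pep, start, end, n_missed in digest_in_silico(
            seq, params.max_missed_cleavages, params.min_peptide_length
        ):
            if n_missed > 0 and rng.random() >= params.missed_cleavage_rate ** n_missed:
                continue
            cys_pos = [start + i for i, aa in enumerate(pep) if aa == "C"]
            pep_rows.append(
                {"Protein": rec.id, "Sequence": pep, "Start": start, "End": end,
                 "n_missed": n_missed, "cys_positions": cys_pos}
            )
    peptides = pd.DataFrame(pep_rows)

    # --- site truth --------------------------------------------------------
    cys_lists = [
        [(r["Protein"], p) for p in r["cys_positions"]]
        for _, r in peptides.iterrows() if r["cys_positions"]
    ]
    clusters = _site_clusters(cys_lists)
    n_clusters = max(clusters.values()) + 1 if clusters else 0
    a, b = params.baseline_oxidation
    base_frac = rng.beta(a, b, size=n_clusters)
    regulated = rng.random(n_clusters) < params.effect_fraction
    signs = rng.choice([-1.0, 1.0], size=n_clusters)
    effects = np.where(regulated, signs * params.effect_size, 0.0)

    def logistic(x):
        return 1.0 / (1.0 + np.exp(-x))

    logit_base = np.log(base_frac / (1.0 - base_frac))
    denom = max(len(conditions) - 1, 1)
    frac_by_cond = {
        cond: logistic(logit_base + effects * (j / denom))
        for j, cond in enumerate(conditions)
    }
    if clusters:
        site_index = pd.MultiIndex.from_tuples(
            sorted(clusters), names=["Protein", "Position"]
        )
    else:
        site_index = pd.MultiIndex.from_arrays([[], []], names=["Protein", "Position"])
    cluster_of = np.array([clusters[s] for s in site_index], dtype=int)
    sites = pd.DataFrame(
        {cond: frac_by_cond[cond][cluster_of] for cond in conditions},
        index=site_index,
    )
    sites["cluster"] = cluster_of
    sites["regulated"] = regulated[cluster_of]
    sites["effect"] = effects[cluster_of]

    truth = GroundTruth(proteins=prot, sites=sites)
    lookup = {
        "frac_by_cond": frac_by_cond,
        "cluster_by_site": clusters,
    }
    return truth, peptides, lookup


def _random_peptide(rng, length: int) -> str:
    letters = list(_AA_FREQS)
    probs = np.array(list(_AA_FREQS.values()))
    probs = probs / probs.sum()
    return "".join(rng.choice(letters, size=length, p=probs))


def simulate_measurement(
    truth: GroundTruth,
    peptides: pd.DataFrame,
    lookup: dict,
    params: SimParams,
    design: ChannelDesign | None = None,
) -> dict[str, pd.DataFrame]:
    """Turn ground truth into MaxQuant-shaped tables.

    Returns a dict with keys ``proteinGroups``, ``peptides``,
    ``modificationSpecificPeptides``, ``light_sites``, ``heavy_sites``.
    The noise stream is drawn independently of carrier_factor and
    detection_threshold so identification is monotone in the carrier.
    """
    if design is None:
        design = design_from_params(params)
    rng = np.random.default_rng(params.rng_seed + 1)
    conditions = list(params.conditions)
    n_ch = design.n_channels
    ci = design.carrier_index
    cond_of_channel = [
        None if c.is_carrier else c.condition for c in design.channels
    ]
    sigma = math.sqrt(math.log(1.0 + params.reporter_cv**2))
    m = design.impurity_matrix
    raw_cols = [f"{mq.RAW_FAMILY} {i + 1}" for i in range(n_ch)]
    corr_cols = [f"{mq.CORRECTED_FAMILY} {i + 1}" for i in range(n_ch)]

    def observe(expected: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Apply noise, interference and impurity mixing to one row."""
        if sigma > 0:
            noise = np.exp(rng.normal(0.0, sigma, size=n_ch) - sigma**2 / 2.0)
        else:
            noise = np.ones(n_ch)
        y = expected * noise
        rho = params.interference_rho
        if rho > 0:
            y = (1.0 - rho) * y + rho * y.mean()
        corrected = y
        raw = m.T @ y if m is not None else y
        return raw, corrected

    frac_by_cond = lookup["frac_by_cond"]
    clusters = lookup["cluster_by_site"]
    prot = truth.proteins

    # --- peptide-level tables ----------------------------------------------
    pep_records = []
    mod_records = []
    pep_id = 0
    mod_id = 0
    light_links: dict[tuple[str, int], list[int]] = {}
    heavy_links: dict[tuple[str, int], list[int]] = {}
    non_cys_seen: dict[str, int] = {}

    def mod_string(n: int, name: str) -> str:
        return name if n == 1 else f"{n} {name}"

    for _, row in peptides.iterrows():
        acc = row["Protein"]
        ion = rng.lognormal(0.0, params.ionization_log_sd)
        cys = row["cys_positions"]
        abundance = np.array(
            [prot.loc[acc, c] if c is not None else 0.0 for c in cond_of_channel]
        )
        states: list[tuple[str, float, float]] = []  # (label, sample frac, carrier frac)
        if cys:
            cluster = clusters[(acc, cys[0])]
            p_by_ch = np.array(
                [
                    frac_by_cond[c][cluster] if c is not None else 0.0
                    for c in cond_of_channel
                ]
            )
            states.append(("LIGHT", 1.0, 0.0))
            states.append(("HEAVY", 0.0, 1.0))
            if len(cys) > 1 and params.mixed_peptide_rate > 0:
                if rng.random() < params.mixed_peptide_rate:
                    states.append(("MIXED", 0.0, 0.0))
        else:
            seen = non_cys_seen.get(acc, 0)
            if seen >= params.non_cys_peptides_per_protein:
                continue
            non_cys_seen[acc] = seen + 1
            states.append(("NONE", 0.0, 0.0))

        this_pep_id = pep_id
        pep_records.append(
            {
                "id": this_pep_id, "Sequence": row["Sequence"],
                "C Count": len(cys),
                "Start position": row["Start"], "End position": row["End"],
                "Leading razor protein": acc,
                "Reverse": False, "Potential contaminant": False,
            }
        )
        pep_id += 1

        for label, _, _ in states:
            expected = np.zeros(n_ch)
            for k in range(n_ch):
                if k == ci:
                    continue
                if label == "LIGHT":
                    expected[k] = abundance[k] * ion * (1.0 - p_by_ch[k])
                elif label == "HEAVY":
                    expected[k] = abundance[k] * ion * p_by_ch[k]
                elif label == "MIXED":
                    # ambiguous isotopolog: small fraction of either pool
                    expected[k] = abundance[k] * ion * 0.02
                else:
                    expected[k] = abundance[k] * ion
            if ci is not None and label in ("HEAVY", "NONE"):
                # carrier proteome is fully reduced then heavy labeled: it
                # contributes to heavy-labeled and unmodified rows only
                expected[ci] = params.carrier_factor * prot.loc[acc, "base"] * ion
            raw, corrected = observe(expected)
            if expected.sum() <= params.detection_threshold:
                continue
            if label == "LIGHT":
                mods = mod_string(len(cys), mq.LIGHT_MOD)
            elif label == "HEAVY":
                mods = mod_string(len(cys), mq.HEAVY_MOD)
            elif label == "MIXED":
                mods = (
                    mod_string(1, mq.LIGHT_MOD) + "," +
                    mod_string(max(len(cys) - 1, 1), mq.HEAVY_MOD)
                )
            else:
                mods = "Unmodified"
            rec = {
                "id": mod_id, "Sequence": row["Sequence"], "Modifications": mods,
                "Peptide ID": this_pep_id,
                "Reverse": False, "Potential contaminant": False,
            }
            rec.update(dict(zip(raw_cols, raw)))
            rec.update(dict(zip(corr_cols, corrected)))
            mod_records.append(rec)
            if label == "LIGHT":
                for p in cys:
                    light_links.setdefault((acc, p), []).append(mod_id)
            elif label == "HEAVY":
                for p in cys:
                    heavy_links.setdefault((acc, p), []).append(mod_id)
            mod_id += 1

    # --- decoy / contaminant spike-ins -------------------------------------
    def spike(n: int, flag: str, prefix: str):
        nonlocal pep_id, mod_id
        for i in range(n):
            seq = _random_peptide(rng, int(rng.integers(8, 18)))
            acc = f"{prefix}{i + 1:04d}"
            pep_records.append(
                {
                    "id": pep_id, "Sequence": seq, "C Count": seq.count("C"),
                    "Start position": 1, "End position": len(seq),
                    "Leading razor protein": acc,
                    "Reverse": flag == "Reverse",
                    "Potential contaminant": flag == "Potential contaminant",
                }
            )
            rec = {
                "id": mod_id, "Sequence": seq,
                "Modifications": mod_string(max(seq.count("C"), 1), mq.LIGHT_MOD)
                if seq.count("C") else "Unmodified",
                "Peptide ID": pep_id,
                "Reverse": flag == "Reverse",
                "Potential contaminant": flag == "Potential contaminant",
            }
            intensities = rng.lognormal(math.log(1e5), 0.5, size=n_ch)
            rec.update(dict(zip(raw_cols, intensities)))
            rec.update(dict(zip(corr_cols, intensities)))
            mod_records.append(rec)
            pep_id += 1
            mod_id += 1

    spike(params.n_decoys, "Reverse", "REV__SIMP")
    spike(params.n_contaminants, "Potential contaminant", "CON__SIMP")

    # --- site tables --------------------------------------------------------
    def site_table(links: dict[tuple[str, int], list[int]]) -> pd.DataFrame:
        rows = []
        for sid, ((acc, pos), ids) in enumerate(sorted(links.items())):
            rows.append(
                {
                    "id": sid, "Protein": acc, "Position": pos,
                    "Score diff": float(np.round(rng.exponential(20.0), 4)),
                    "Localization prob": float(np.round(rng.uniform(0.9, 1.0), 4)),
                    "Mod. peptide IDs": ";".join(str(i) for i in ids),
                }
            )
        return pd.DataFrame(
            rows,
            columns=["id", "Protein", "Position", "Score diff",
                     "Localization prob", "Mod. peptide IDs"],
        )

    # --- protein groups -----------------------------------------------------
    pg_records = []
    pg_id = 0
    if pep_records:
        unique_counts = pd.DataFrame(pep_records).groupby("Leading razor protein").size()
    else:
        unique_counts = pd.Series(dtype=int)
    for acc in prot.index:
        ion = rng.lognormal(0.0, 0.3)
        expected = np.array(
            [
                prot.loc[acc, c] * ion if c is not None
                else params.carrier_factor * prot.loc[acc, "base"] * ion
                for c in cond_of_channel
            ]
        )
        raw, corrected = observe(expected)
        rec = {
            "id": pg_id, "Protein IDs": acc,
            "Unique peptides": int(unique_counts.get(acc, 0)),
            "Reverse": False, "Potential contaminant": False,
            "Only identified by site": False,
        }
        rec.update(dict(zip(raw_cols, raw)))
        rec.update(dict(zip(corr_cols, corrected)))
        pg_records.append(rec)
        pg_id += 1

    def spike_group(n: int, **flags):
        nonlocal pg_id
        for i in range(n):
            rec = {
                "id": pg_id,
                "Protein IDs": f"SPIKE{pg_id:04d}",
                "Unique peptides": flags.pop("unique_peptides", 2)
                if "unique_peptides" in flags else 2,
                "Reverse": flags.get("Reverse", False),
                "Potential contaminant": flags.get("Potential contaminant", False),
                "Only identified by site": flags.get("Only identified by site", False),
            }
            intensities = rng.lognormal(math.log(1e5), 0.5, size=n_ch)
            rec.update(dict(zip(raw_cols, intensities)))
            rec.update(dict(zip(corr_cols, intensities)))
            pg_records.append(rec)
            pg_id += 1

    spike_group(params.n_site_only_groups, **{"Only identified by site": True})
    spike_group(params.n_zero_unique_groups, unique_peptides=0)
    spike_group(3, Reverse=True)
    spike_group(3, **{"Potential contaminant": True})

    mod_cols = (
        ["id", "Sequence", "Modifications", "Peptide ID", "Reverse",
         "Potential contaminant"] + raw_cols + corr_cols
    )
    pg_cols = (
        ["id", "Protein IDs", "Unique peptides", "Reverse",
         "Potential contaminant", "Only identified by site"] + raw_cols + corr_cols
    )
    return {
        "proteinGroups": pd.DataFrame(pg_records, columns=pg_cols),
        "peptides": pd.DataFrame(
            pep_records,
            columns=["id", "Sequence", "C Count", "Start position", "End position",
                     "Leading razor protein", "Reverse", "Potential contaminant"],
        ),
        "modificationSpecificPeptides": pd.DataFrame(mod_records, columns=mod_cols),
        "light_sites": site_table(light_links),
        "heavy_sites": site_table(heavy_links),
    }


def simulate_experiment(
    params: SimParams,
) -> tuple[dict[str, pd.DataFrame], GroundTruth, ChannelDesign]:
    """Full generator: proteome -> truth -> MaxQuant-shaped tables."""
    records = generate_proteome(
        params.n_proteins, params.rng_seed,
        params.protein_length_log_mean, params.protein_length_log_sd,
        params.cys_frequency,
    )
    truth, peptides, lookup = assign_ground_truth(records, params)
    design = design_from_params(params)
    tables = simulate_measurement(truth, peptides, lookup, params, design)
    return tables, truth, design


def write_maxquant_tables(tables: dict[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write the simulated tables under their canonical MaxQuant file names."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    kinds = {
        "proteinGroups": mq.TableKind.PROTEIN_GROUPS,
        "peptides": mq.TableKind.PEPTIDES,
        "modificationSpecificPeptides": mq.TableKind.MOD_PEPTIDES,
        "light_sites": mq.TableKind.SITES,
        "heavy_sites": mq.TableKind.SITES,
    }
    names = {
        "proteinGroups": mq.FILE_NAMES[mq.TableKind.PROTEIN_GROUPS],
        "peptides": mq.FILE_NAMES[mq.TableKind.PEPTIDES],
        "modificationSpecificPeptides": mq.FILE_NAMES[mq.TableKind.MOD_PEPTIDES],
        "light_sites": mq.FILE_NAMES["light_sites"],
        "heavy_sites": mq.FILE_NAMES["heavy_sites"],
    }
    written = []
    for key, df in tables.items():
        path = out_dir / names[key]
        mq.write_mq_table(df, path, kinds[key])
        written.append(path)
    return written
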