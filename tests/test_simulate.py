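"""Simulator: digestion, ground truth, determinism and table round-trips."""

import numpy as np
import pandas as pd
import pytest

import redoxtmt as rt
from redoxtmt import mq_tables as mq
from redoxtmt import simulate as sim


def digest_oracle(seq, max_missed, min_length):
    """Rule-based enumeration written independently of the implementation:
    cut after K/R unless followed by P; 0..max_missed internal skips."""
    cuts = [0]
    for i, aa in enumerate(seq[:-1]):
        if aa in "KR" and seq[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(seq))
    out = set()
    for i in range(len(cuts) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(cuts))):
            pep = seq[cuts[i]:cuts[j]]
            if len(pep) >= min_length:
                out.add((pep, cuts[i] + 1, cuts[j], j - i - 1))
    return out


class TestDigestion:
    def test_spec_example(self):
        # cleavage after K(5) and R(6); only the C-terminal peptide is long enough
        out = sim.digest_in_silico("AAAAKRCCCCCC", max_missed=0, min_length=6)
        assert out == [("CCCCCC", 7, 12, 0)]

    def test_no_cleavage_sites(self):
        out = sim.digest_in_silico("AAAAAAGGGGGG", max_missed=2, min_length=6)
        assert out == [("AAAAAAGGGGGG", 1, 12, 0)]

    def test_proline_blocks_cleavage(self):
        out = sim.digest_in_silico("AAAKPRGGGGGG", max_missed=0, min_length=3)
        # K before P is not a site; R at 6 is
        assert ("AAAKPR", 1, 6, 0) in out
        assert all(p[1] != 5 for p in out)

    def test_matches_independent_oracle_on_random_sequences(self, rng):
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(30):
            seq = "".join(rng.choice(letters, size=int(rng.integers(10, 80))))
            mm = int(rng.integers(0, 3))
            ml = int(rng.integers(4, 8))
            assert set(sim.digest_in_silico(seq, mm, ml)) == digest_oracle(seq, mm, ml)


class TestProteomeGeneration:
    def test_deterministic_under_seed(self):
        a = sim.generate_proteome(3, seed=7)
        b = sim.generate_proteome(3, seed=7)
        assert [str(r.seq) for r in a] == [str(r.seq) for r in b]

    def test_unique_accessions(self):
        recs = sim.generate_proteome(100, seed=1)
        assert len({r.id for r in recs}) == 100

    def test_zero_cys_frequency(self):
        recs = sim.generate_proteome(5, seed=2, cys_frequency=0.0)
        assert all("C" not in str(r.seq) for r in recs)

    def test_fasta_round_trip(self, tmp_path):
        recs = sim.generate_proteome(4, seed=3)
        sim.write_fasta(recs, tmp_path / "prot.fasta")
        back = sim.read_fasta(tmp_path / "prot.fasta")
        assert [str(r.seq) for r in recs] == [str(r.seq) for r in back]


class TestGroundTruth:
    def test_zero_effect_fraction_gives_identical_conditions(self):
        params = rt.SimParams(rng_seed=5, n_proteins=10, effect_fraction=0.0)
        recs = sim.generate_proteome(10, 5, cys_frequency=params.cys_frequency)
        truth, _, _ = sim.assign_ground_truth(recs, params)
        conds = list(params.conditions)
        for c in conds[1:]:
            np.testing.assert_allclose(truth.sites[c], truth.sites[conds[0]])
        assert not truth.sites["regulated"].any()

    def test_fractions_in_unit_interval(self, small_sim):
        sites = small_sim["truth"].sites
        for c in small_sim["params"].conditions:
            assert sites[c].between(0, 1).all()

    def test_sites_share_cluster_fraction(self, small_sim):
        sites = small_sim["truth"].sites
        cond = small_sim["params"].conditions[0]
        for _, grp in sites.groupby("cluster"):
            assert grp[cond].nunique() == 1

    def test_truth_round_trip(self, small_sim, tmp_path):
        truth = small_sim["truth"]
        truth.write(tmp_path)
        back = sim.GroundTruth.read(tmp_path)
        pd.testing.assert_frame_equal(truth.proteins, back.proteins)
        pd.testing.assert_frame_equal(truth.sites, back.sites)


class TestSimulateMeasurement:
    def test_byte_identical_reruns(self, tmp_path):
        params = rt.SimParams(rng_seed=9, n_proteins=8)
        for d in ("a", "b"):
            tables, _, _ = rt.simulate_experiment(params)
            sim.write_maxquant_tables(tables, tmp_path / d)
        for name in sorted((tmp_path / "a").iterdir()):
            assert name.read_bytes() == (tmp_path / "b" / name.name).read_bytes()

    def test_round_trip_through_readers(self, small_sim, tmp_path):
        tables = small_sim["tables"]
        design = small_sim["design"]
        sim.write_maxquant_tables(tables, tmp_path)
        model = rt.RedoxStoichiometryModel.from_directory(tmp_path, design)
        raw_cols = mq.reporter_columns(tables["modificationSpecificPeptides"].columns)
        np.testing.assert_allclose(
            model.mod_peptides[raw_cols].to_numpy(dtype=float),
            tables["modificationSpecificPeptides"][raw_cols].to_numpy(dtype=float),
        )
        assert len(model.peptides) == len(tables["peptides"])

    def test_decoy_and_contaminant_spike_ins_flagged(self, small_sim):
        mod = small_sim["tables"]["modificationSpecificPeptides"]
        params = small_sim["params"]
        assert mod["Reverse"].sum() == params.n_decoys
        assert mod["Potential contaminant"].sum() == params.n_contaminants

    def test_carrier_zero_for_light_rows(self, small_sim):
        tables = small_sim["tables"]
        design = small_sim["design"]
        mod = tables["modificationSpecificPeptides"]
        carrier_col = f"{mq.RAW_FAMILY} {design.carrier_index + 1}"
        labels = mod["Modifications"].map(lambda m: mq.parse_label_state(m).value)
        light = mod.loc[labels == "LIGHT", carrier_col]
        assert (light == 0).all()
        heavy = mod.loc[labels == "HEAVY", carrier_col]
        assert (heavy > 0).all()

    def test_heavy_identification_monotone_in_carrier(self):
        # seeded, high threshold: identified heavy rows never decrease with c
        for seed in (1, 2, 3):
            counts = []
            for c in (0.0, 10.0, 100.0):
                params = rt.SimParams(
                    rng_seed=seed, n_proteins=15,
                    carrier_factor=c, detection_threshold=2e6,
                )
                tables, _, _ = rt.simulate_experiment(params)
                mod = tables["modificationSpecificPeptides"]
                labels = mod["Modifications"].map(lambda m: mq.parse_label_state(m).value)
                counts.append(int((labels == "HEAVY").sum()))
            assert counts == sorted(counts)

    def test_mixed_rows_emitted_when_enabled(self):
        params = rt.SimParams(rng_seed=4, n_proteins=30, mixed_peptide_rate=1.0,
                              cys_frequency=0.08)
        tables, _, _ = rt.simulate_experiment(params)
        mod = tables["modificationSpecificPeptides"]
        labels = mod["Modifications"].map(lambda m: mq.parse_label_state(m).value)
        assert (labels == "MIXED").any()

    def test_empty_simulation_writes_header_only_files(self, tmp_path):
        params = rt.SimParams(
            rng_seed=1, n_proteins=1, cys_frequency=0.0,
            non_cys_peptides_per_protein=0, detection_threshold=1e30,
            n_decoys=0, n_contaminants=0, n_site_only_groups=0,
            n_zero_unique_groups=0,
        )
        tables, _, _ = rt.simulate_experiment(params)
        assert tables["modificationSpecificPeptides"].empty
        paths = sim.write_maxquant_tables(tables, tmp_path)
        for p in paths:
            assert p.read_text().count("\n") >= 1  # header survives
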