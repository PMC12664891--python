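# redoxtmt

Site-level cysteine oxidation stoichiometry from carrier-boosted TMT
redox proteomics.

## The problem

Reversible cysteine oxidation (sulfenylation, S-nitrosylation,
disulfides) is a central signaling mechanism, but oxidized thiols are
rare in the reducing intracellular environment and hard to quantify.
A sequential-alkylation workflow solves this without enrichment: free
thiols are capped with **light** iodoacetamide (IAA) during lysis,
reversibly oxidized cysteines are then reduced and capped with
**heavy** IAA (13C2/2H2, +4 Da), and the peptides are TMT-labeled so
one MS run quantifies every condition at once.  One TMT channel can be
loaded with an excess, fully heavy-labeled **carrier** proteome, which
raises precursor signal enough for the scarce oxidized peptides to be
selected and identified.

When both labeling states of a cysteine site are quantified, their sum
is taken as 100% of the site and the oxidation stoichiometry per
sample is

```
stoichiometry (%) = 100 · H / (H + L)
```

with `H` and `L` the summed heavy/light reporter intensities of the
site.  The ratio is invariant to peptide ionization efficiency and to
protein-level normalization, both of which multiply `H` and `L`
equally.  Differential oxidation across conditions is tested row-wise
with a moderated t/F statistic and permutation-based FDR (SAM/Perseus
family), and sites are annotated against UniProt-style sequence
features and GO categories.

`redoxtmt` implements the computational arm of this workflow — from
MaxQuant-dialect tables (`proteinGroups.txt`,
`modificationSpecificPeptides.txt`, `peptides.txt`, light/heavy
`Carbamidomethyl (C)Sites.txt`) to per-site stoichiometries,
significance calls and annotation — together with a ground-truth
simulator that generates those tables from known oxidation fractions,
so every stage is testable by parameter recovery without raw MS data.
It is for proteomics analysts who want a scriptable, auditable
alternative to spreadsheet/Perseus processing of redox TMT data, and
for method developers who need a simulator with known truth.

## Worked example

Simulate a 10-plex experiment (three conditions in triplicate plus a
10x carrier) with known per-site oxidation fractions, fit the model,
test for regulation and score against the truth:

```python
import redoxtmt as rt

params = rt.SimParams(rng_seed=42, n_proteins=60)
tables, truth, design = rt.simulate_experiment(params)

model = rt.RedoxStoichiometryModel.from_tables(tables, design)
results = model.fit()
print(results.summary())
```

```
Cysteine oxidation stoichiometry fit
============================================
channels: 10 (9 samples, 1 carrier)
conditions: vehicle, low_h2o2, high_h2o2
intensity family: 'Reporter intensity'
--------------------------------------------
remove_decoys_contaminants        76 ->      70
filter_protein_groups             70 ->      64
remove_decoys_contaminants      1624 ->    1594
filter_cys_peptides             1594 ->    1294
complete_case_filter            1294 ->    1294
--------------------------------------------
paired sites:          451
light-only sites:        0
heavy-only sites:        0
MIXED-label rows excluded from stoichiometry: 0
median peptide CV: 11.31%
```

The audit block is the filter chain: decoy/contaminant removal,
protein-group quality, the cysteine partition (the 300 rows removed
there are the non-cysteine proteome evidence, kept separately), and
the complete-case rule over sample channels.  451 cysteine sites have
both labeling states quantified, so their stoichiometry is defined.

```python
tests, excluded = results.test_stoichiometry(rt.PermutationConfig(rng_seed=1))
print("significant sites:", int(tests["significant"].sum()), "of", len(tests))

score = rt.compare_with_truth(results, truth, tests)
for k in ("stoichiometry_rmse_pct", "stoichiometry_bias_pct",
          "sensitivity", "empirical_fdr"):
    print(k, "=", round(score[k], 4))
```

```
significant sites: 45 of 451
stoichiometry_rmse_pct = 0.788
stoichiometry_bias_pct = 0.0194
sensitivity = 1.0
empirical_fdr = 0.0
```

Under 10% reporter noise the per-site stoichiometry is recovered with
0.8 percentage-point RMSE and negligible bias; the permutation-FDR
ANOVA finds every truly regulated site with no false calls in this
run.  `results.site_table()` gives one row per paired site:

```
                    stoichiometry vehicle (%)  stoichiometry low_h2o2 (%)  stoichiometry high_h2o2 (%)  n light evidences  n heavy evidences
Protein   Position
SIMP00001 177                            0.46                        0.41                         0.41                  3                  3
          385                            1.57                        1.74                         1.62                  1                  1
          404                            2.23                        2.27                         2.48                  1                  1
```

The same workflow is available from the shell:

```sh
redoxtmt simulate --config sim.yaml --seed 42 --out run/sim
redoxtmt quantify --input run/sim --design run/sim/design.yaml --out run/quant
redoxtmt test --stoichiometry run/quant/stoichiometry_per_sample.tsv \
              --design run/sim/design.yaml --out run/tests.tsv
redoxtmt run-all --config sim.yaml --seed 42 --out run/all   # everything + manifest
```

## Layout

- `redoxtmt.mq_tables` — MaxQuant-dialect readers/writers and the
  Perseus-style site merge
- `redoxtmt.filtering` — row-exclusion rules with an audit trail
- `redoxtmt.reporter` — impurity correction (NNLS), carrier
  separation, protein normalization
- `redoxtmt.quant` — site aggregation, light/heavy pairing,
  stoichiometry, CV
- `redoxtmt.stats` — permutation-FDR t/ANOVA, Fisher enrichment
- `redoxtmt.annotation` — sequence-feature and GO annotation
- `redoxtmt.simulate` — the ground-truth simulator
- `redoxtmt.model` / `redoxtmt.pipeline` / `redoxtmt.cli` — the
  Model/Results interface, orchestration and CLI

See `docs/methods.md` for the underlying model, its assumptions and
the numerical choices.
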