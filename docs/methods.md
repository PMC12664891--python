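# Methods

## The quantity being estimated

Each cysteine site `s` on a protein has, in each biological condition,
a fraction `p_s` of its molecules carrying a reversible oxidative
modification.  Sequential alkylation converts this chemistry into two
measurable peptide species: the reduced pool capped with light
iodoacetamide (carbamidomethyl) and the reversibly-oxidized pool,
reduced after the first capping, carrying the heavy (13C2/2H2, +4.019 Da
monoisotopic) adduct.  Under the assumption that the two pools are
exhaustive — irreversible oxidation (sulfinic/sulfonic acids) is not
captured and is outside the method — their reporter-ion intensities
satisfy `H + L = 100%` of the site, and

    stoichiometry_s = 100 · H_s / (H_s + L_s)   [percent, per sample channel]

Because `H` and `L` of a site share the peptide's ionization
efficiency and the protein's abundance, the ratio needs no
normalization: any common factor cancels.  The implementation exploits
this by computing stoichiometry on impurity-corrected, carrier-excluded,
raw-scale intensities; protein-normalized log2 ratios are still
produced, but they feed the CV statistics and the label-state-level
tests, not the stoichiometry.

## Processing chain

1. **Parsing.**  Four tab-separated tables in the MaxQuant dialect.
   Flags are `+`/empty; reporter intensity 0 means "not observed" and
   is converted to missing only after parsing; both the raw
   (`Reporter intensity N`) and corrected
   (`Reporter intensity corrected N`) column families are accepted,
   with a caller switch for which is authoritative (MaxQuant versions
   and simulator output differ).  Coordinates are 1-based inclusive.
2. **Site merge.**  Modified-peptide rows gain sequence-level columns
   (Cys count, protein start/end, razor protein) through the
   `Peptide ID` cross-reference and site-level columns (positions,
   localization probability, score difference) through the reverse
   lookup of semicolon-separated `Mod. peptide IDs`.  The join is
   strictly left: the output has exactly the input's peptide rows.
3. **Filters**, each a pure row predicate with an audit record:
   decoy/contaminant removal; protein groups must not be
   "only identified by site" and need ≥ 1 unique peptide; peptides
   with Cys count < 1 are split off as non-cysteine proteome evidence;
   the complete-case rule requires positive intensity in every
   experimental sample channel.  "Robustly quantified in all
   replicates" is interpreted strictly as complete-case over all
   sample channels (the Perseus-default reading); a relaxed mode
   ("complete in all replicates of at least one condition") is a
   config switch.  The carrier channel never counts toward
   completeness — it is a detection booster, not a sample.
4. **Reporter processing.**  Isotope impurity correction solves
   `min ‖Mᵀx − y‖, x ≥ 0` per row (scipy NNLS) with the row-stochastic
   lot-sheet matrix `M`; matrices with condition number above 1e8 are
   refused.  A fast unconstrained-solve-then-clip mode exists for
   diagonally dominant lot sheets.  The carrier column is then split
   off (kept for QC) and zeros become missing.
5. **Normalization.**  Per channel, `log2(peptide_k / protein_k)`
   against the leading razor protein's same-channel intensity — the
   only reading that yields a per-sample normalization.  Peptides
   whose protein group did not survive filtering are routed to an
   "unnormalizable" sink with a reason.
6. **Site quantification.**  Evidences (charge states, missed-cleavage
   variants) of one (site, label state) are summed per channel —
   ratio-of-sums is more stable than mean-of-ratios when heavy
   evidences are weak.  A peptide with several same-label cysteines
   contributes its intensity to each site; peptides carrying both
   labels (MIXED) are excluded from stoichiometry and reported
   separately, since their per-site H/L attribution is ambiguous.
   Sites with both states surviving are "paired" and get per-channel
   stoichiometries plus per-condition means; light-only/heavy-only
   partitions are kept (their regulation is assessed on normalized
   intensities instead).
7. **Statistics.**  Two-group comparisons use a pooled-variance t
   statistic, multi-group a one-way F, both optionally moderated by a
   SAM-style fudge constant `s0` added to the standard-error scale
   (default `s0 = 0`, plain t/F; the constant is exposed because
   Perseus exposes it).  The null distribution comes from permuting
   the column condition labels — exhaustively when ≤ 10,000 distinct
   assignments exist (e.g. 252 for 5 vs 5, 1680 for 3×3×3), otherwise
   250 seeded draws.  Assignments whose induced column partition
   equals the observed one are excluded: they reproduce the observed
   statistics and are not null draws.  The q-value at threshold `t*`
   is `π̂0 ·` (mean permuted statistics ≥ `t*`) / (observed ≥ `t*`),
   monotonized step-up, with `π̂0` the Storey estimate (λ = 0.5) from
   the permutation p-values; this is the SAM definition of the
   permutation FDR.  Under extreme null contamination (many huge
   planted effects) the pooled estimator remains slightly
   conservative, and a borderline row can land within a hair of the
   threshold.  An unadjusted-p mode supports single-comparison
   volcano analyses.  Category enrichment uses the two-sided Fisher
   exact test with Benjamini–Hochberg adjustment and relative
   enrichment (selection fraction / background fraction).
8. **Annotation.**  Interval containment of the cysteine position in
   UniProt-style features (TSV export or GFF3); a site may carry
   several types.  For pie-chart-style summaries an exclusive recode
   applies the fixed priority active site > metal binding > disulfide
   bond > binding site > modified residue.  GO category counting is a
   flat accession→term multimap ranked by protein count, ties broken
   lexicographically; no DAG propagation.

## The simulator

The generator emulates the data-generating process far enough that the
analysis chain can be validated by parameter recovery:

- **Proteome**: random sequences (vertebrate-like residue frequencies,
  log-normal lengths, median ≈ 420 aa), cysteine frequency 1.8% —
  chosen so the default 500-protein run yields roughly 5,000 quantified
  cysteine peptides, the scale of a real single-plex experiment.
  Tryptic digestion (C-terminal to K/R, not before P), up to 2 missed
  cleavages, minimum length 6 — the workflow's search settings; a
  missed-cleavage product survives with probability 0.25 per missed
  site.
- **Truth**: per-site oxidation fractions drawn from Beta(1, 19)
  (mean 5%, right-skewed — cells are strongly reducing); 10% of sites
  are "regulated", receiving a ±2 logit shift applied proportionally
  along the condition axis (a dose–response design: vehicle, low,
  high).  Protein abundances are log-normal (ln-sd 1) with log2-sd
  0.25 condition fold-changes.
- **Two-state labeling**: a peptide molecule is either fully light or
  fully heavy; expected heavy signal in channel `k` is
  `abundance × ionization × p`, light `× (1 − p)`.  Consequently sites
  sharing a digest peptide share one true fraction.  A per-cysteine
  independent-labeling model would distribute multi-Cys peptides over
  mixed isotopologs whose pure forms no longer estimate the site
  fraction; under the two-state model the pipeline's ratio-of-sums is
  exactly unbiased, which is what makes the noiseless limit a sharp
  specification of correctness (recovery to 1e-9).  MIXED rows can be
  spiked in via `mixed_peptide_rate` to exercise their exclusion path.
- **Carrier**: a fully reduced, heavy-labeled proteome at
  `carrier_factor` (default 10) times one sample's loading; it
  contributes to heavy-labeled and unmodified rows, never to light
  rows.
- **Detection**: a row is identified iff its expected signal summed
  over all channels including the carrier exceeds
  `detection_threshold` (default 2e5, censoring a realistic share of
  carrier-free heavy rows).  Thresholding the noise-free sum keeps
  identification deterministic in the carrier factor, which makes the
  carrier's boost a provable monotone property rather than a
  statistical one.
- **Noise**: mean-one log-normal reporter noise (`reporter_cv`,
  default 0.1, the regime that reproduces ≈ 11–12% median peptide CV
  after protein normalization); then co-isolation interference
  `y ← (1−ρ)·y + ρ·mean(y)` over the row's channels (default ρ = 0 —
  interference is a dial for dedicated experiments, because with a
  large carrier in the plex mean even small ρ inflates sample-channel
  heavy signal and biases stoichiometry upward, a real and documented
  carrier artifact); finally impurity mixing `y ← Mᵀy` with an
  optional TMT-like tridiagonal lot sheet.  The raw column family
  records the post-mixing values, the corrected family the pre-mixing
  values, so the NNLS correction can be validated end to end.
- Decoy, contaminant, "only identified by site" and zero-unique-peptide
  rows are spiked in so the filters always have work to do.

Everything derives from one integer seed; reruns are byte-identical.

What the simulator does **not** model: MS2 spectral quality and
fragmentation stochasticity, retention time and co-elution structure,
plex-to-plex batch effects, charge-state-dependent co-isolation of the
light/heavy pair, irreversible oxidation, and the long-tailed
abundance distribution of real proteomes.  Passing recovery tests
therefore demonstrates the correctness of the estimation chain under
its stated model, not the field performance of the wet-lab workflow;
in particular, real heavy/light identification asymmetries are larger
than the default simulation produces.

## Validation experiments (tests/test_acceptance.py, scripts/acceptance.py)

- Noiseless limit: all noise off, no carrier, no censoring → estimated
  stoichiometry equals truth to 1e-9 points for every site.
- Default-noise recovery: the 500-protein reference run → RMSE
  < 5 points, |bias| < 0.5 points across all site × channel estimates.
- Carrier property: at a threshold censoring ≥ 80% of heavy rows
  without a carrier, identified heavy rows are non-decreasing in
  carrier factor over {0, 1, 10, 100} in each of 10 seeded repeats.
- Impurity round-trip: `correct(Mᵀx) = x` to 1e-8 over random
  diagonally dominant stochastic matrices up to 18×18.
- FDR calibration: 500 all-null rows, 20 repeats → mean significant
  fraction within 3 Monte-Carlo SEs of 0.05; 50 planted 10-sd effects
  → sensitivity 1.0 (t test 5 vs 5; ANOVA 3×3×3).
- Fisher/BH oracles: exact hypergeometric enumeration over every 2×2
  table with grand total ≤ 30 (integer-weight tie handling), and an
  independent BH step-up on 1,000 random p-vectors, both to 1e-12.
- Filter accounting: a fixed 20-row fixture with known decoys,
  contaminants, site-only groups, zero-unique groups, non-Cys and
  incomplete rows; every audit count must equal an independent
  pure-Python enumeration.
- Ratio compression: with ρ = 0.5, constant protein levels and no
  carrier, between-condition stoichiometry differences shrink by
  exactly (1−ρ) — the mixing algebra predicts
  `s′_k = (1−ρ)·s_k + ρ·s̄` whenever total peptide signal is
  channel-independent, which the experiment arranges.  With a carrier
  present or proteins regulated the law is only approximate.

Problem sizes in these experiments (40–500 proteins, 10–20 repeats)
are the package's chosen defaults; they keep the full validation run
in the low minutes on one CPU while leaving every measured margin far
from its bound.

## Known limitations

- Single-plex semantics: the complete-case rule and all statistics act
  within one plex; multi-plex bridging is out of scope.
- The method cannot distinguish which reversible modification produced
  the heavy label, and underestimates total oxidation by ignoring
  irreversible states.
- MIXED-label peptides are excluded rather than apportioned; sites
  covered only by multi-Cys peptides in mixed states are lost.
- GO analysis is flat category counting; no term ancestry.
- The permutation FDR needs ≥ 2 replicates per condition per row and
  is undefined for zero-variance rows at `s0 = 0` (they are excluded
  and reported, not silently dropped).
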