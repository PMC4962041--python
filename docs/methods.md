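# Methods

This note records the models implemented in `ddikit`, the assumptions
behind them, the defaults and why they were chosen, and what the
synthetic-data generators do and do not emulate.

## PICS data-analysis cascade

A PICS assay exposes a proteome-derived peptide library — digested by
working proteases and with all primary amines blocked — to a test
protease. Cleavage creates new free N-termini, which are biotinylated,
enriched and sequenced. The cascade in `ddikit.pics` reconstructs the
protease's P4…P1 | P1′…P4′ specificity from four identification lists
(test reaction, mock reaction, catalytically-inactive-enzyme reaction,
unprocessed library):

1. **Label filter** — only peptides carrying the biotinylation-derived
   N-terminal modification can originate from a test-protease cut.
2. **Confidence filter** — test peptides must exceed 0.80 confidence,
   control peptides 0.10. The asymmetry is deliberate: controls are
   kept permissive so the background they define is as complete as
   possible. "Over" is read strictly (a peptide at exactly 0.80 is
   removed); a config switch makes the comparison inclusive.
3. **Background subtraction** — any test peptide whose exact sequence
   appears in mock ∪ inactive ∪ library is removed. Matching is by
   sequence string only; modification state is not compared.
4. **Proteome mapping** — each surviving peptide is located in the
   proteome by exact substring search. The four residues preceding an
   occurrence give the P side; the peptide's own first four residues
   give the P′ side. When occurrences disagree on the preceding
   tetrapeptide (or start within the first four residues of a protein)
   the P side is recorded as unknown; such windows contribute their P′
   columns only. This is a documented choice where the protocol wording
   is ambiguous about ambiguous-mapping peptides: contributing P′-only
   keeps the observed (MS-measured) half of the window without
   inventing P-side residues. A config switch (`ambiguous_p_side =
   drop`) discards such peptides entirely instead. Duplicate sequences
   are deduplicated before counting (configurable), so a peptide found
   at many homologous positions counts once.
5. **Specificity matrix** — per-position residue frequencies; windows
   with unknown P side are excluded from the P4…P1 denominators only,
   so P′ counts are always ≥ P counts.

The whole cascade is a pure function of its inputs; survivor counts per
stage are logged and monotone non-increasing.

## Synthetic PICS experiment

`ddikit.simulate.simulate_pics_experiment` emulates the assay at the
list level (no spectra, chromatography or isotopes):

* **Digestion** by trypsin (after K/R, blocked before Pro) and GluC
  (after E only; Glu-only specificity is the conservative default since
  the buffer-dependent Asp cleavage is not assumed, and no proline
  block, both configurable per rule). Default is a combined digest
  (cuts at the union of sites); a pooled mode (independent digests,
  products pooled) is available since the protocol does not state which
  was used. Zero missed cleavages by default (configurable 0–2);
  fragments then tile each protein exactly.
* **Blocking** is modeled purely as the boolean "N-terminus labeled";
  the analysis cascade needs nothing else (no masses).
* **Planted cleavage.** The planted protease carries per-position
  probability weights over the 20 residues for P4…P4′. Each candidate
  site inside an MS-retained peptide (length window 6–30 by default,
  typical MS observability) is cut with probability
  `efficiency × Π w(pos, aa) / Π max w(pos)` — the window's likelihood
  relative to the best possible window. Because residues are i.i.d.
  under the synthetic proteome, the residue distribution at each
  constrained position among true cuts equals the planted weights,
  which is what makes exact recovery checks possible.
* **Observability bias (a real PICS feature the simulator reproduces):**
  with zero missed cleavages no library peptide contains an internal
  K/R/E, so planted preferences for those residues at P′ positions are
  unobservable (the labeled fragment would be a boundary fragment of
  length ≤ 1). Recovery tests therefore plant preferences on residues
  the working digest leaves observable, and the P′-distribution
  closeness tolerance (Jensen–Shannon divergence < 0.15 bits) is set to
  absorb the K/R/E depletion at unconstrained P′ positions
  (≈ 0.08 bits against a uniform reference) plus multinomial noise at
  the ~10² windows a desk-scale run recovers.
* **Confidences and background.** True identifications draw confidence
  from Beta(8, 2), contaminants from Beta(2, 2) — both straddle the
  0.80/0.10 thresholds so the filters are genuinely exercised. A shared
  contaminant pool (modeling incompletely blocked termini that survive
  enrichment) appears in every run with a carryover probability of 0.9;
  the pool is sized so contaminants are a target fraction (default 0.3)
  of the raw test list. Mock and inactive lists contain only such
  contaminants; the library list adds blocked (unlabeled) peptides.

What passing recovery tests show: the cascade correctly inverts the
generative model above. What they do not show: robustness to search-
engine score miscalibration, modified residues, non-exact peptide
matching, or proteome redundancy beyond random repeats — real data
features outside the generator.

## Titration simulation and K_d estimation

Binding is 1:1 with fast exchange (single averaged peak per residue) —
the regime in which a continuously moving peak tracks the bound
fraction. The forward model per residue and titration point is
δ = δ_free + f_b·Δδ_max + ε with f_b the root of the equilibrium
quadratic in total concentrations and ε Gaussian (defaults 0.005 ppm
for ¹H, 0.025 ppm for ¹⁵N — amide nitrogen shifts are noisier in ppm).
The default schedule titrates a 50×-protein ligand stock to 10-fold
molar excess over 8 points; protein dilution is computed exactly and
both concentrations are recorded per point, because large molar-excess
endpoints dilute the protein appreciably and assuming constant P biases
K_d.

Fitting (`ddikit.csp.fit_kd`):

* combined CSP uses α = 0.2 for ¹⁵N scaling (the common convention;
  0.154 is available via configuration);
* per-reporter nonlinear least squares with free (K_d, Δδ_max), both
  positive via log-parameterization; initialization K_d₀ = median
  ligand concentration, Δδ_max₀ = 1.2 × endpoint CSP;
* fits whose K_d collapses outside [10⁻⁴, 10⁴] mM are flagged
  non-converged rather than reported — at the edge of identifiability
  the estimate carries no information and would distort the min–max
  range;
* the primary aggregate is the (min, max) range over converged
  reporters, because per-residue ranges are how weak-affinity CSP
  results are conventionally reported; a global shared-K_d fit (one
  K_d, per-residue Δδ_max) and a case-resampling bootstrap percentile
  interval on it are provided as secondary estimators since it is
  generally unstated which convention produced any given published
  range;
* reporter auto-selection uses an iterated mean + 1·sd threshold over
  reliable residues (falling back to the top 5 by CSP); this is a
  stated convention, not an established rule, and explicit residue
  lists are first-class so a published reporter set can be reproduced
  exactly.

Desk-scale accuracy at the default conditions (K_d = 1 mM, 0.005 ppm
noise, 8 points, 10 reporters): the test suite and acceptance script
measure the median |log K̂_d/K_d| across 200 replicate simulations and
the coverage of the min–max range; noiseless data is recovered to
better than 10⁻⁶ relative.

## Sequence statistics

Global alignment is Needleman–Wunsch with affine gaps via Biopython's
PairwiseAligner. Defaults mirror EMBOSS needle — BLOSUM62, gap open 10,
extend 0.5, a length-L gap costing open + L·extend, end gaps free —
because published identity/similarity percentages usually come from
needle-like defaults, and the scoring is fully configurable for
parameter exploration. Identity is identical columns over the full
alignment length (gap columns included, needle's convention;
gapless-only denominator available); similarity counts columns with a
positive substitution score. Scores are validated against an
independent Gotoh dynamic-programming oracle in the tests. Ties among
optimal alignments are broken deterministically (first optimal
traceback of the aligner).

Motif scanning is an exhaustive position-by-position match of
fixed/wildcard patterns, reporting all (possibly overlapping) matches
1-based.

## Structure comparison

* **Kabsch superposition**: closed-form SVD solution with the
  determinant correction, so a reflection is never returned; collinear
  point sets and < 3 pairs are rejected. Agreement with an independent
  quaternion (Horn) solution to 10⁻⁹ Å is part of the test suite and
  acceptance script.
* **Ensemble precision**: all models are superposed on the first,
  averaged, re-superposed on the mean and so on until the mean moves
  < 10⁻⁶ Å (cap 100 iterations) — the standard converged definition,
  chosen because precision-statistic protocols are rarely printed. The
  representative model is the one with minimum RMSD to the converged
  mean. "Backbone" means {N, CA, C, O}; "heavy" means all
  non-hydrogen. For an ensemble generated with i.i.d. Gaussian atomic
  displacements of sd σ, the expected per-model RMSD to the mean is
  σ√(3(n−1)/n), which the tests verify within 5%.
* **Motif RMSD** is computed in two frames — fitted on the motif atoms
  themselves, and evaluated in a frame fitted on a larger selection —
  because published motif RMSDs rarely state their frame; callers
  supply a name map (e.g. OG1→OG) when comparing Ser/Thr-variant
  motifs.
* **Iterative alignment** seeds CA pairs from a sequence alignment and
  alternately fits and prunes pairs deviating more than 2× the current
  RMSD (never below 3 pairs, with a 10⁻⁶ Å floor on the threshold so
  numerically identical structures are not pruned on rounding noise)
  until stable. The 2× factor and the floor are conventional,
  configurable choices.

Residue numbering is always the source file's; selections never remap,
avoiding silent off-by-N errors when construct and database numbering
differ. Alternate locations resolve to the highest-occupancy conformer
(ties to the first in file order); insertion codes are distinct
residues.

## Problem sizes

The test suite and acceptance script run desk-scale problems chosen as
representative rather than exhaustive: 300-protein × 300-residue
proteomes (≈ 200–400 planted cuts, ≈ 100 recovered windows), 200
replicate titrations for Monte-Carlo accuracy, 30–40-model synthetic
ensembles, and 500–1000 random superposition instances. All randomness
flows from explicit integer seeds; there is no global random state.

## Known limitations

* Peptide matching is exact-string; no I/L equivalence or modification
  tolerance.
* Only 1:1 fast-exchange binding; slow/intermediate exchange and other
  stoichiometries are out of scope.
* The PICS simulator works at the identification-list level; it does
  not model spectra, retention, or FDR structure.
* Statistics over the deposited reference structures require the user
  to supply the PDB/UniProt files locally; the package performs no
  network access.
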