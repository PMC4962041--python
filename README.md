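# ddikit

Analysis toolkit for the structural and functional characterization of
Ddi-family proteins (DNA-damage-inducible, UBL–RVP domain proteins such
as human Ddi2). It packages, as tested reusable code, the four
computations such a study needs:

1. **PICS protease-specificity profiling** (`ddikit.pics`) — turn MS
   peptide-identification lists from a PICS assay (Proteomic
   Identification of protease Cleavage Sites) into a P4…P4′
   substrate-specificity matrix: label filtering, asymmetric confidence
   thresholds for test vs control runs, background subtraction against
   mock/inactive-mutant/unprocessed-library controls, proteome mapping
   of neo-N-termini, and per-position amino-acid frequencies.
2. **NMR chemical-shift-perturbation K_d fitting** (`ddikit.csp`) —
   combine per-residue amide shifts as Δδ = √(Δδ_H² + (α·Δδ_N)²),
   and fit the 1:1 fast-exchange binding isotherm

       Δδ_obs = Δδ_max · ((P + L + K_d) − √((P + L + K_d)² − 4PL)) / (2P)

   per reporter residue (nonlinear least squares, log-parameterized,
   dilution-aware), reporting the min–max K_d range over reporters, an
   optional global shared-K_d fit, and a bootstrap interval.
3. **Sequence statistics** (`ddikit.seqtools`) — needle-style global
   alignment with percent identity/similarity, and consensus-motif
   scanning (e.g. the ubiquitin-interacting-motif signature
   L-x-x-A-x-x-x-S).
4. **Structure comparison** (`ddikit.structure`) — Kabsch (SVD)
   superposition, NMR-ensemble precision (RMSD to the converged mean
   structure, representative-model choice), active-site motif RMSD in
   two frame conventions, and sequence-seeded iterative CA alignment
   for cross-ortholog comparisons.

`ddikit.simulate` generates every input the stages consume — synthetic
proteomes, trypsin/GluC digests, simulated PICS identification lists
with a *planted* protease specificity, titrations with known K_d, and
perturbed coordinate ensembles — so the whole pipeline runs and is
validated end-to-end against known ground truth, with no downloads.

## Worked example

Simulate a PICS experiment with a planted specificity (P1 biased to
Phe, P1′ to Ala) and recover it:

```sh
ddikit simulate-library --out-dir sim --seed 5 --n-proteins 150
# -> wrote simulated experiment with 194 true cuts to sim
ddikit pics-run --test sim/test.csv --mock sim/mock.csv \
    --inactive sim/inactive.csv --library sim/library.csv \
    --proteome sim/proteome.fasta --out pics.json
```

`pics.json` then holds the stage-by-stage survivor counts and the
recovered matrix; for this run:

```
report: {'input_counts': {'test': 154, ...}, 'after_label_filter': {'test': 135, ...},
         'after_confidence_filter': {'test': 61, ...},
         'after_background_subtraction': 58, 'windows': 58}
P1 frequency of F: 0.638
```

i.e. of 154 raw test identifications, 58 survive the cascade and map to
unambiguous cleavage windows, and Phe dominates the recovered P1 column
— the planted preference (0.7) recovered from noisy, contaminated
lists. A titration fit looks like:

```sh
ddikit simulate-titration --out tit.csv --seed 6 --kd 0.8
ddikit csp-fit --titration tit.csv --reporters auto --bootstrap 100 --seed 3
# -> kd range: [0.011, 1.432]  global: 0.753  95% CI: [0.585, 0.850]
```

The per-residue min–max range brackets the planted K_d of 0.8 mM and
the global shared-K_d fit lands within 6% of it; weakly-shifting
reporters produce the wide range edges, which is why the global fit and
bootstrap interval are reported alongside.

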