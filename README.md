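# shmcontext

Sequence-context analysis of somatic hypermutation (SHM) at AGCT hotspot
motifs in human immunoglobulin heavy-chain variable (IGHV) regions.

During affinity maturation, activation-induced deaminase (AID) mutates
antibody V regions preferentially at WRCH hotspots (W=A/T, R=A/G,
H=A/C/T). The palindromic hotspot AGCT is among the most mutated — yet
identical AGCT motifs within one V region mutate at very different
rates, and the conserved AGCT near the 5' end of framework region 1
(FW1) is strikingly cold. `shmcontext` is a pipeline for dissecting this
differential mutability in terms of local sequence context: an E-box
transcription-factor motif (CAGCTG, bound by E2A) that suppresses
mutation of the AGCT inside it, and pyrimidine-dimer (PyPy) richness
upstream of the motif that enhances it.

The pipeline is exercised end to end on a synthetic B-cell-receptor
repertoire generator with planted, known effect sizes, so every stage is
testable without any sequencing data:

1. **simulate** — germline-like V alleles segmented into IMGT-style
   subregions (L-intron-L, FW1, CDR1, FW2, CDR2, FW3), a per-site
   mutation-rate model with E-box suppression and PyPy enhancement, and
   Bernoulli-mutated clonally independent repertoires.
2. **kmers** — sliding-window 15-mers, observed per-site mutation
   frequencies, AGCT-centred filtering, one-hot encoding.
3. **train / predict** — a small convolutional regressor mapping a
   one-hot 4×15 matrix to the predicted mutation frequency of the
   central base (in [0, 1]).
4. **attribute** — integrated gradients against a zero baseline:
   per-base, per-position attribution of each prediction, with
   subregion-level box-plot summaries and logo letter frequencies.
5. **scan / census** — log-odds PWM scanning with an exact p-value score
   threshold (dynamic programming over the background score
   distribution), and a CAGCTG / CANNTG E-box census per subregion.
6. **features / stats** — upstream PyPy counts, flanking-base pairs and
   E-box indicators; Pearson/Wald correlation, OLS with R², Welch t,
   Mann-Whitney U, Fisher's exact test; and the synonymous-mutation
   contingency analysis of the FW1 CAGCTG (below).

## The contingency analysis

The FW1 CAGCTG occupies V-segment positions 7–12, in frame, so the Gs at
motif sites 3 and 6 (V positions 9 and 12) sit at third codon positions:
G₃→A is synonymous (CAG/CAA, Gln) and G₆→H is synonymous (CTG/CTA/CTC/CTT,
Leu) while destroying the E-box. Cross-classifying clonally independent
sequences by site-3 × site-6 status gives a 2×2 table from which the
conditional site-3 mutation frequencies

    f(G₃ mut | G₆ intact) = n(A₃G₆) / [n(G₃G₆) + n(A₃G₆)]
    f(G₃ mut | G₆ mutated) = n(A₃H₆) / [n(G₃H₆) + n(A₃H₆)]

are compared with a two-sided Fisher exact test. If the intact E-box
suppresses AID, losing G₆ should raise the site-3 frequency.

## Worked example

Feeding a published-scale contingency table of clone counts
(rows = site-6 status, columns = site-3 status) through the stats layer:

```python
>>> import shmcontext as sc
>>> table = sc.ContingencyTable2x2(426962, 45537, 24988, 6846)
>>> res = sc.contingency_from_table(table)
>>> table.total
504333
>>> round(100 * res.freq_g3_given_g6_unmut, 1)
9.6
>>> round(100 * res.freq_g3_given_g6_mut, 1)
21.5
>>> res.fisher_log10_p_bound
-791.1502309070887
```

The site-3 mutation frequency rises from 9.6% while the E-box is intact
to 21.5% once site 6 is mutated; the log-space hypergeometric bound
certifies the two-sided Fisher p-value below 10⁻⁷⁹¹ — an E-box-dependent
difference that cannot plausibly be sampling noise.

Running the whole synthetic pipeline from a shell:

```sh
shmcontext -v all -c config.yaml -o out/
```

writes FASTA/TSV artifacts for every stage plus `out/stats.json` and a
checksum manifest. On a small run (3 alleles, 200 clones/allele, seed 7)
the feature regressions in `stats.json` already show the planted
structure — PyPy count correlating positively and the E-box indicator
negatively with observed mutation frequency, and the combined model
explaining at least as much variance as either alone:

```json
"pypy_ebox_regression": {
  "pypy_only": {"r": 0.247, "r_squared": 0.061, "coef": 0.0171},
  "ebox_only": {"r": -0.592, "r_squared": 0.350, "coef": -0.1389},
  "combined": {"r_squared": 0.442, "coef_pypy": 0.0211, "coef_ebox": -0.1456},
  "n": 26
}
```

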