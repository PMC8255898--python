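# growthlnc

Tools for a two-stage livestock transcriptome design: locate the growth
inflection point of a herd from longitudinal weights, then analyse how the
muscle transcriptome — in particular its long non-coding RNAs (lncRNAs) —
differs between the fastest-growth stage and the growth plateau.

The package is aimed at animal-science and transcriptomics researchers who
have (a) repeated body-weight records, (b) assembled transcripts with
coding-potential scores, and (c) replicated two-condition expression
matrices, and who want the whole chain — growth-curve fitting, lncRNA
identification, differential expression, cis-neighbor prediction, trait
comparison — as composable, tested Python functions. Synthetic-data
generators with known ground truth stand in for real cohorts and RNA-seq
libraries, so every stage can be exercised end to end with no downloads.

## The models and statistics at the core

**Growth curves.** Three classical sigmoidal models, each with asymptotic
weight *A* (kg), shape constant *B* and rate *k* (per day):

| model           | W(t)                  | inflection age | inflection weight | max daily gain |
|-----------------|-----------------------|----------------|-------------------|----------------|
| logistic        | A / (1 + B e^(−kt))   | ln(B)/k        | A/2               | k·w/2          |
| Gompertz        | A exp(−B e^(−kt))     | ln(B)/k        | A/e               | k·w            |
| von Bertalanffy | A (1 − B e^(−kt))³    | ln(3B)/k       | 8A/27             | 3k·w/2         |

(*w* = inflection weight; gains reported in g/day.) Fits are
Levenberg–Marquardt least squares on log-parameters; models are ranked by
R² = 1 − SSE/SST.

**lncRNA identification.** A candidate transcript is rejected if length
< 200 nt, exon count < 1 or read support < 3 reads (strict inequalities,
first-failing-rule attribution); a survivor is a lncRNA iff CNCI < 0 and
CPC < −1, otherwise an mRNA. The CNCI/CPC coding-potential scores are
consumed as precomputed inputs.

**Differential expression.** Expression is quantified as TPM (each sample
sums to 10⁶). For each gene the statistic is (M, D): M = log₂ ratio of
condition means (pseudocount 0.5), D = absolute difference of means. An
empirical null of (M\*, D\*) is pooled from all within-condition replicate
pairs over all genes, and p = (1 + #{|M\*| ≥ |M| and D\* ≥ D}) / (1 + N).
A gene is significant when p < 0.05 and |M| ≥ 1.

**Cis neighbors.** All lncRNA × mRNA pairs are screened: co-expressed if
|PCC| > 0.8 with two-sided p < 0.05 (t transform on n−2 df); a cis
neighbor additionally requires the same chromosome, an interval gap
≤ 100 kb (0 if overlapping, symmetric in direction) and |PCC| > 0.9.
Neighbor-gene sets are tested by hypergeometric upper tail with
Benjamini–Hochberg adjustment across sets.

**Traits.** Two-group trait tables are compared by Welch's t-test
(pooled Student's available), and fatty-acid columns are summed into
SFA/MUFA/PUFA class totals.

## Worked example

```bash
python examples/growth_inflection.py
```

```
simulated 126 animals, 2268 weighings
          model        A       B      k     R2  inflection_day  inflection_weight_kg  max_daily_gain_g  converged
       logistic 134.8987 22.2042 0.0170 0.9701        182.0002               67.4494          574.4832       True
       gompertz 148.0736  4.4401 0.0097 0.9672        153.3547               54.4733          529.5027       True
von_bertalanffy 158.3240  0.9085 0.0074 0.9641        136.3459               46.9108          517.4553       True

Best model: logistic (R2=0.9701); the herd reaches its maximum daily gain of 574 g/d at day 182.0 (67.4 kg).
```

A herd of 126 animals is simulated from a logistic truth
(A = 135.63 kg, B = 22.075, k = 0.017/d) with 2-kg measurement noise and
10% between-animal variation, and all three models are fitted to the
pooled records. The logistic fit recovers the generating parameters and
ranks first by R²; its inflection row says the herd grows fastest
(~574 g/d) around day 182 at ~67 kg — the age a two-stage sampling design
would target for the "maximum growth" group.

The other scripts in `examples/` walk the remaining capabilities —
`identify_lncrnas.py` (filter cascade and biotype characteristics),
`differential_expression.py` (TPM + DE with planted truth),
`cis_neighbor_screen.py` (cis-pair recovery and enrichment) and
`trait_comparison.py` (Welch tests and fatty-acid classes) — each printing
the numbers it computes and what they mean.

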