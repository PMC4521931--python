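# Methods

## The model

A three-plex SILAC experiment compares three cell states in one MS run.
Cells are grown in media carrying unlabeled Lys/Arg (light, K0R0),
²H₄-Lys + ¹³C₆-Arg (medium, K4R6), or ¹³C₆¹⁵N₂-Lys + ¹³C₆¹⁵N₄-Arg
(heavy, K8R10); lysates are mixed 1:1:1 and digested with trypsin, so
nearly every peptide carries exactly one labelable residue at its
C-terminus. The three channel forms of a peptide co-elute and differ in
mass by an exactly known shift, so per-channel MS1 intensities report the
relative abundance of the parent protein across the three states.

The quantitative chain implemented here is:

1. peptide intensity ratios M/L and H/L per evidence row;
2. per-protein, per-replicate ratio = median of defined peptide ratios;
3. replicate intersection (a protein needs a ratio in both replicates)
   and arithmetic averaging of the per-replicate ratios;
4. per data set (channel × replicate), log2 ratios standardized by the
   population mean and sample SD: z = (log2 r − m)/s;
5. replicate z-scores averaged, then confidence tiers assigned at the
   two-sided normal critical values 1.960 / 2.576 / 3.291 σ (95 / 99 /
   99.9%), direction by sign;
6. term over-representation of the regulated set by one-tailed Fisher and
   the EASE jackknife, filtered at count ≥ 2 and EASE < 0.1;
7. hierarchical clustering of the regulated z matrix.

The z-score model assumes the log2-ratio population is approximately
Gaussian and dominated by unregulated proteins, so its spread estimates
biological-plus-technical null variation; calls are relative to the
population, not an error model per protein, and no multiple-testing
correction is applied (the tiers themselves encode stringency).

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| label deltas K4/K8/R6/R10 | 4.025107 / 8.014199 / 6.020129 / 10.008269 | Da | monoisotopic sums of ²H, ¹³C, ¹⁵N mass differences |
| Pro-conversion deltas | 5.016774 (M), 6.013809 (H) | Da | ¹³C₅ and ¹³C₅¹⁵N₁ left in proline made from labeled Arg |
| m/z convention | (M + z·1.0072765)/z | Th | proton mass; residue masses from the standard monoisotopic table (water 18.0105646) |
| triplet tolerance | 10 | ppm | Orbitrap-class mass accuracy; the original processing tolerance is not stated, this default is declared not inferred |
| satellite threshold | 5 | % of main peak | conversion is reported qualitatively in such studies; 5% is a conservative flag level |
| min peptide length | 6 | residues | the identification filter of the upstream search |
| required replicates | 2 | — | replicate-intersection quantitation rule |
| aggregation | median | — | robust to single outlier peptides; mean available |
| confidence tiers | 95 / 99 / 99.9 | % | |z| ≥ 1.960 / 2.576 / 3.291 σ, inclusive comparison |
| enrichment filters | count ≥ 2, EASE < 0.1 | — | the standard DAVID/EASE screening thresholds |
| clustering | Euclidean, average linkage | — | metric/linkage for the published heat map are unstated; defaults declared, configurable |

## Normalization modes

The faithful reading of "parameters per data set" computes a mean/SD per
channel per replicate (`per-channel`, the default). The printed reference
tables, however, are numerically consistent with standardizing **both**
channels by the M/L parameters (mean −0.072, SD 1.237): every printed
z-score in both channels, 162 rows, back-computes from the printed log2
within ±0.01 under those parameters, while the printed H/L parameter row
(−0.151, 1.143) does not reproduce the printed H/L z-scores. Because the
intended convention cannot be recovered, both are provided:
`paper-compat` standardizes both channels with one shared parameter set
and is what table-level validation uses. No claim is made about which the
original analysis intended.

Replicates are combined by averaging z-scores (not ratios) before tier
assignment; ratio averages are reported alongside because the reference
tables print the arithmetic mean of ratios next to its log2.

## The synthetic-data generator

`simulate_evidence` emulates the structure the analysis assumes, at the
study's scale: 2000 proteins (the quantified set was 1766), two
replicates, 1 + Poisson(4) peptides per protein, log-normal base
intensities (median 10⁶, geometric SD 4), per-protein true log2 ratios
from N(−0.07, 0.8) — a background centred slightly below zero with most
proteins inside ±1 — and a 6% regulated fraction (≈120 proteins,
matching the ~110 + 87 calls among 1766) whose effects have |log2| drawn
uniformly from 2.3–5.3, i.e. 5-fold to 40-fold, signed and assigned to
M/L only, H/L only, or both channels with equal probability (emulating
stage-specific vs shared regulation). Peptide-level noise is Gaussian on
the log2 scale (SD 0.3), replicates get a protein-level N(0, 0.05) shift,
and channels are masked independently at 5%. Each protein's first peptide
always passes the length filter, so quantifiability is guaranteed and
noise-free runs recover every true ratio exactly. One global seed feeds a
`SeedSequence`-spawned hierarchy, making every table byte-reproducible.

What it does **not** model: chromatographic elution and co-isolation,
isotope-envelope fine structure, intensity-dependent missingness,
shared/razor peptides, or identification error. Passing tests therefore
show the statistics behave correctly on data satisfying the model's
assumptions, not that the model is robust to those real-data artifacts.

The annotation generator assigns terms uniformly at random, except
"planted" terms which sample regulated proteins at a configurable
multiple (default 8×) of the uniform rate. For null-behavior checks the
calibrated condition is a 50-protein list against 30 terms of mean size 8
in a 2000-protein universe; there, no term passes the EASE < 0.1 screen
in ≥ 93% of seeds. With larger terms or lists the family-wise false-pass
rate of an uncorrected 0.1 screen is substantial — which is an honest
property of the EASE filter, not of this implementation.

## Numerical choices

- Sample SD uses the n−1 denominator.
- Tier comparison is inclusive (|z| ≥ threshold), and validation against
  2-decimal printed z values uses those values as printed.
- A ratio is defined only when both channel intensities are present and
  positive; missing propagates, and a missing channel yields tier "none",
  never an error. Degenerate populations (SD 0) raise.
- Triplet matching is greedy by smallest combined ppm error with each
  peak used at most once; candidate partners are the nearest peak within
  tolerance of the expected position. Peptides with no labelable residue
  return no triplets (the channels coincide).
- Fisher/EASE tails are computed by `scipy.stats.hypergeom.sf`; the test
  suite checks them against an exact integer-arithmetic enumeration to
  1e-12 over randomized margins.
- Linkage ties follow scipy's deterministic nearest-neighbor-chain order,
  so leaf order is reproducible given the input order; missing z values
  are imputed to 0 σ (the population mean) for distance computation only
  and rendered as a distinct color.
- Fold-change reciprocal symmetry holds to one floating-point rounding of
  the reciprocal.

## Problem sizes

The test suite and the acceptance script run the null-rate simulation at
10,000 proteins, the calibration run at the default 2000, the exact-oracle
comparison on 1000 randomized margins (universe ≤ 300), and planted
cluster/enrichment recovery at 40 rows / 30 terms; these sizes give
stable estimates (binomial SE of the null rate ≈ 0.002) while keeping a
full run in tens of seconds.

## Known limitations

- Protein-group inference is out of scope; one accession per evidence row.
- The z-score tiers are not p-values and are not corrected for multiple
  testing; the enrichment module's BH column is informational only.
- The printed-table fixtures inherit the 2-decimal rounding of their
  source; consistency checks use rounding-interval logic where ±0.02 on
  log2 cells is arithmetically impossible for small ratios.
- The original study's full-proteome identifications, annotation-service
  versions and network analysis are not reproducible offline; those
  stages are validated by the property-based substitutes described above.
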