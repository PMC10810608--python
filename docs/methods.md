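# Methods

## Germline model

The package ships a down-scaled murine immunoglobulin germline: 20 Igh-V,
10 Igh-D, 4 Igh-J; 15 Igk-V and 5 named Igk-J genes of which 4 are
functional (*Igkj3* is flagged as a pseudogene and never drawn, which
preserves the meaning of *Igkj5* as the last editing station); and the
Igl locus exactly as its two-cassette architecture — {*Iglv2*, *Iglv3*}
linked to *Iglj2-c2* (family λ2), and {*Iglv1*} linked to *Iglj3-c3*
(λ3) and *Iglj1-c1* (λ1). Real loci carry >100 V genes; 20/15 V genes
are enough to estimate usage vectors while keeping exhaustive alignment
cheap. The λ family of a rearrangement is read off the J call through
the J–C linkage, since constant regions are not part of the simulated
reads.

Sequences are random coding-like DNA (stop-free codons) with implanted
junction anchors: each V carries an in-frame Cys codon 9 nt before its
3' end, each J a [FW]-G-x-G motif 12 nt after its 5' end. Gene identity,
not sequence content, carries every statistic; no claim of biological
sequence realism is made. All coordinates are 0-based, intervals
half-open. V segments are 150 nt (anchor at 141), J segments 48 nt
(anchor at 12), D segments 12 nt — the headroom beyond each anchor (6 nt
V-side, 12 nt J-side) bounds exonuclease trimming so anchors always
survive.

## Simulator

### Empirical mode

Each cell draws one heavy and one light rearrangement. Junctional
diversity follows the standard model: per-end exonuclease trimming ~
Geometric(0.25) capped at 6 nt, N additions ~ Poisson(4) per heavy
N-region and Poisson(1) for light chains (arbitrary but conventional
magnitudes, all in `JunctionParams`). Productivity of every read is then
forced to a Bernoulli draw from the preset's per-locus unproductive
fraction: out-of-frame reads get junction length ≢ 0 mod 3, stop-codon
reads get an in-frame TAA injected into the N-region, and productive
reads have any junctional stop scrubbed (middle base → C turns every
stop into serine). This makes classifier recovery a clean binomial
experiment with a known rate.

`kappa_fraction` is defined as the κ share among cells with a
*productive* light chain — the quantity actually measured on real
repertoires, where surface-BCR⁻ cells drop out. Because the per-locus
unproductive fractions differ, the raw locus draw is reweighted
(κ-weight ∝ kappa_fraction / productive-rate(Igk), λ-weight analogous)
so the productive-conditional share equals the preset value in
expectation.

Heavy V and J genes are drawn with fixed geometric propensity weights
(decay 0.75 across the ordered gene list), shared by all genotypes. Real
heavy-gene usage is strongly non-uniform and stable across genotypes;
that stable skew is precisely what makes cross-genotype Pearson
correlations of usage vectors informative (uniform usage would have zero
signal variance and replicate correlations near 0). Igk-V usage stays
uniform; Igk-J and the λ-family/V/J weights come from the preset tables.

Shipped presets:

| preset | mode | key values |
|---|---|---|
| `ctrl` | empirical | κ = 0.83; λ weights (λ1,λ2,λ3) = (.44,.41,.15); Igkj5 = 0.10; unproductive IGH/IGK/IGL = .92/.15/.10 |
| `bko` | empirical | κ = 0.98; λ weights (.69,.12,.19); Igkj5 = 0.142; unproductive .93/.18/.20; one 5 % *Ighv10-1* clone |
| `wt_lambda` | empirical | κ = 0; λ weights (.62,.31,.07) |
| `kappa_ko` | mechanistic | Igk silenced |
| `macroself` | mechanistic | every κ chain autoreactive |

The `ctrl`/`bko` λ-family weights are derived jointly from the J-usage
and V-usage shares they must reproduce (family ≡ J–C unit, and
*Iglv1* = λ1 + λ3 under the cassette map); the wild-type λ distribution
(62/31/7) is carried by its own preset because, with family ≡ J, it
cannot coexist with the control J-usage vector in a single preset — the
two measurements use different denominators in real data. Light-locus
unproductive fractions are package choices that preserve the observed
knockout/control ratios (1.2× for Igk, 2× for Igl). The knockout's
unproductive λ reads are biased toward stop codons
(`unproductive_stop_fraction = 0.7`), mirroring the stop-codon series
seen in that genotype. Clone members share one forced-productive heavy
rearrangement; their light chains are drawn independently, so light-chain
statistics are unaffected by clonality.

Decoy reads (random 200-nt DNA, default 2 % of Ig reads) exercise the
non-Ig classifier. Randomness uses one master seed with per-cell
sub-streams keyed by (seed, cell index), so growing `n_cells` never
reshuffles earlier cells; clone assignment and decoys use dedicated
sub-streams.

### Mechanistic mode

A per-cell state machine embodies the three factors shaping λ output:
(i) Igl-locus opening (Bernoulli `p_igl_open`, decided once per cell),
(ii) precursor life-span — a per-attempt death hazard
1 − 0.5^(1/`survival_halflife`), the half-life measured in rearrangement
attempts, and (iii) editing efficiency — κ attempts walk the functional
J genes in ascending order across two alleles (so *Igkj5* users have
strictly more editing rounds than *Igkj1* users), with autoreactive
productive chains (`p_autoreactive_kappa`, or always under `macroself`)
sending the cell back into editing; after `max_edit_attempts` or allele
exhaustion (the RS-deletion analogue) only the open Igl locus remains.
The per-attempt success probability `p_igk_productive` is reused for λ
attempts — no evidence distinguishes the two at this resolution. No
quantitative rates for editing or death are available, so this mode is
validated only by orderings and limits (λ fraction monotone in opening
probability and half-life, antitone in κ success; silenced-κ → all-λ;
macroself → no κ survivors), never against printed frequencies. Dead
cells are discarded and simulation continues until `n_cells` survivors.

## Annotation

Two-stage alignment: a fast edit-distance prescreen (edlib, infix mode;
V probes are 45-nt 5' prefixes since V 3' ends are trimmed, J probes are
full segments) shortlists candidates within 3 edits of the best, with a
hard ceiling of 12 edits — beyond that no segment can reach the non-Ig
score threshold; the shortlist is then scored exactly by affine-gap
local alignment (match 2, mismatch −1, gap open −3, extend −1; ties to
the lexicographically smallest name). The locus call maximises V+J score
over same-locus pairs. The junction is read off the alignment path by
projecting the germline anchor offsets onto the read.

Productivity is decided in fixed order: (1) `non_ig` when either best
score is below `min_ig_score` = 0.6·(2·30) = 36 or the anchors cannot be
projected (random 300-nt DNA fails the threshold with p > 0.999, checked
by simulation in the tests); (2) `out_of_frame` when junction length ≢ 0
mod 3; (3) `stop_codon` when translation from the first full V codon
through the J anchor contains a stop — the scan deliberately starts at
the V start, a documented convention for edge cases upstream of the
junction; (4) otherwise productive. D genes are reported only on an
exact ≥ 5-nt match of a D core inside the N-region and feed no
statistic. Identical (v_call, j_call, junction) reads within one cell
collapse into one record with `duplicate_count` summed; tables are
sorted by sequence id, so annotation is permutation-invariant.

## Statistics

Preprocessing keeps productive records with CDR3 ≥ 4 aa occurring ≥ 2
times within their chain. The 4-aa floor is the smallest biologically
sensible CDR3 and is exposed as a flag; both thresholds are parameters.
Denominators: isotype/λ-family over cells with a productive light chain
(a cell's light chain is its best-scoring productive light record);
gene usage over productive records within the locus (duplicate-collapsed
records, stated here because raw-read weighting would differ);
productivity fractions over raw reads weighted by `duplicate_count`, so
every read lands in exactly one bucket. CDR3 net charge counts R,K as +1
and D,E as −1 with histidine neutral (pH-7 approximation; a flag
includes H). Pearson r between usage vectors union-aligns labels with
zero fill and uses the two-tailed t-test (n−2 df).

## Similarity networks

Networks are built per chain (heavy, κ, λ) on post-preprocess unique
CDR3s, following the same filtering order as the frequency analyses.
True Levenshtein distance is used — the metric is named explicitly, and
length-±1 indel neighbors belong in it — with a substitutions-only
Hamming mode behind a flag. Construction keys every string by itself and
its single-deletion variants; any pair at distance 1 shares a key, and
candidate pairs are verified with an exact bounded edit-distance check,
giving near-linear runtime in total neighborhood size. Components come
from the graph's connected components; `min_cluster_size` = 3 flags
expanded components and is configurable, never asserted against external
values.

## Validation strategy and problem sizes

Because empirical-mode presets encode known frequencies, the whole
pipeline is validated end to end as parameter recovery: simulate 10,000
cells, annotate the nucleotide reads, and require each recovered
frequency to sit within 3 binomial standard errors (computed on the
realized denominator where the statistic conditions on a subset, e.g. λ
records under the κ-dominated knockout). The heavy-chain unproductive
fraction is checked on 5,000 raw heavy reads. Network construction is
checked against a brute-force O(n²) dynamic-programming oracle on 1,000
random strings; mechanistic orderings use 3-point grids at 5,000 cells
with fixed seeds. These sizes give comfortable statistical power while
keeping the full suite fast.

## What the generator does and does not emulate

Emulated: paired heavy/light architecture, locus choice with receptor
editing semantics, cassette-constrained λ rearrangement, junctional
diversity, controlled unproductive fractions with distinct failure
modes, non-Ig contamination, clonal expansion. Not emulated: sequencing
error, UMI/chemistry artifacts, somatic hypermutation, class switching,
allelic variants, transcript abundance. Passing recovery tests therefore
shows the analysis correctly measures repertoires whose reads are
error-free copies of rearranged germline; robustness to sequencing noise
or allele-level ambiguity is out of scope, and on real data the
alignment prescreen margins and `min_ig_score` may need loosening.

## Known limitations

* The toy germline's random segments are more mutually distinguishable
  than real gene families; annotation accuracy on real alleles would be
  lower.
* Empirical presets force productivity post hoc, so junction sequence
  content is mildly non-biological (scrubbed stops, injected TAA).
* The mechanistic mode's rates are not calibrated to any measured
  kinetics; only its orderings are meaningful.
* Heavy-chain clonal expansion reuses one rearrangement verbatim;
  somatic variants within a clone are not modelled (network clustering
  of near-variants is exercised synthetically in tests instead).
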