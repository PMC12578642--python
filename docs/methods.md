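# Methods

This note records the models, conventions and numerical choices behind
`h2profile`, and what the synthetic benchmarks do and do not demonstrate.

## Translated read classification

Reads are translated in six frames under genetic code 11 (bacterial/
archaeal). Trailing partial codons are dropped, codons containing an
ambiguous base yield `X`, and stop codons are emitted as `*`, which never
scores as a match. Frame peptides are aligned to reference proteins with
affine-gap local Smith–Waterman using BLOSUM62 and the BLAST gap cost
convention: a gap of length *k* costs 11 + *k*·1, i.e. the first gap column
scores −12 and each extension −1. The engine is Biopython's
`PairwiseAligner`; its optimal score is exact (a property test holds it to a
full-matrix three-state Gotoh oracle), and among co-optimal tracebacks its
canonical first path is reported, so results are deterministic.

Candidate references for a frame are selected with an exact amino-acid
k-mer index (default k = 5), the same seed-and-extend shape as a translated
BLAST search. A read whose true homolog shares no 5-mer with the reference
(possible only at extreme divergence) can be missed, which mirrors the
sensitivity trade of any seeded search; `seed_len = 0` performs the fully
exhaustive all-pairs search and is used wherever single reads are checked
against exact filter boundaries.

The single best hit (maximal score over frames × references; ties broken by
higher identity, then lexicographically smallest reference id) is retained
only if

* aligned query length ≥ `min_len_aa` (28 aa default; 26 aa in the
  `health26` profile), and
* identity ≥ the best-hit family's threshold (percent identities over all
  alignment columns, gap columns included).

Filters apply to the best hit only; a read whose best hit fails is
unclassified rather than reassigned to a weaker reference. The shipped
threshold profile is 50% for most reductase/oxidase families and
[NiFe]-hydrogenases, 60% for [NiFe] group 4, [FeFe]-hydrogenases and NuoF,
and 70% for AtpA and YgfK; thresholds live in the family metadata TSV, so
the profile is a default, not a constant. No E-value model is used; an
optional raw-score floor (off by default) exists for very short reads.

## Abundance normalization

RPKM uses each read's own best-hit reference length (×3 for nucleotides),
since a translated search has no per-family canonical gene length. Copies
per genome divides family RPKM by the arithmetic mean RPKM of 14 universal
single-copy ribosomal protein families (L2, L3, L4, L5, L6, L14, L15, L16,
L18, L22, L24, S3, S8, S17 by default — the membership is configuration,
overridable per run). Zero-RPKM markers stay in the mean: an undetected
marker honestly shrinks the genome-count denominator. A guard requiring at
least 7 detected markers (configurable) refuses to quantify degenerate
samples, as does a zero marker mean.

RNA:DNA ratios default to the cohort convention — mean RNA RPKM over
samples divided by mean DNA RPKM — which matches reporting one ratio per
family across a set of paired samples; a per-sample mode (mean of per-pair
ratios, pseudocount 10⁻⁶ on the denominator) is also provided because
published summaries rarely say which convention they used. TPM is computed
from externally supplied per-gene counts and lengths only.

Rarefaction is reservoir sampling with numpy's PCG64 generator, reproducible
across platforms from a single seed; requesting more reads than exist is an
error, never a silent pass-through.

## Genome collection profiling

Genome QC keeps completeness > 90% and contamination < 5%, with strict
inequalities on both sides; failing genomes are flagged, not deleted.
Proteome proteins are assigned to at most one family (their best hit) to
prevent double-counting across related subgroups, and count only when query
and subject coverage (aligned span over full length, per side, on the best
local alignment) are each ≥ 80% and identity meets the family threshold.

## Cohort statistics

The two-sided Wilcoxon rank-sum statistic is the sum of midranks of the
first group. The exact p-value — twice the smaller tail of the enumerated
null, capped at 1 — is used automatically for tie-free data with combined
n ≤ 12; otherwise the tie-corrected normal approximation with a 0.5
continuity correction applies. The approximation tracks the exact null to
within 0.02 once each group has 6–12 observations; for smaller samples the
exact two-sided p jumps by as much as 0.3 between adjacent values of the
statistic, so no smooth approximation can track it uniformly — which is
precisely why the exact path covers that regime. Holm–Bonferroni adjustment
is applied across the families of one cohort comparison (not across
comparisons). Fold changes are ratios of cohort means with pseudocount
10⁻⁶; the group-B:group-A1 style family ratio uses the same pseudocount,
with per-sample ratios feeding the rank-sum test.

## Electron balance

Available electrons follow the degree-of-reduction convention
γ = 4C + H − 2O − 3N (nitrogen referenced to ammonia), so CO₂ carries 0 and
H₂ carries 2. Because the accounting reference for a published "fraction of
fermentation electrons in H₂" is often unstated, both denominators are
implemented: electrons of substrate consumed, and the electron sum of
recovered products including H₂ (the default, robust to assimilation into
biomass — which is ignored throughout and is the usual cause of recoveries
below 1). The full γ table is written with every balance report. Headspace
H₂ given as ppm is converted to mol by the ideal gas law at 1 atm.

## Synthetic data and what the benchmarks show

The simulator emulates exactly the statistical structure the cpg
normalization assumes: communities of genomes each carrying one copy of
every marker family and configurable copies of hydrogenase families, read
origins drawn ∝ abundance × copy number × gene length (× a per-family
expression multiplier for RNA), uniform start positions with reads
truncating at gene ends, i.i.d. substitution errors, and i.i.d. uniform
background sequence. Expected cpg values are closed-form
(abundance-weighted mean copy numbers; 1 for markers). Homologs at
controlled identity replace exactly `round((1−t/100)·L)` residues; the
"even" placement mode spreads mutations uniformly so every alignment window
matches the global identity, which is what makes exact threshold-boundary
checks possible.

The default verification community has 5 genomes at abundances
0.30/0.25/0.20/0.15/0.10 with truth cpg 2.0 (FeFe_B), 1.0 (FeFe_A1),
0.5 (FeFe_A3) and 0.25 (NiFe_4a), 10% protein divergence from the
references, 150-nt reads and 0.5% substitution error; recovery runs use
10⁵ reads (about two minutes on one CPU) and paired RNA:DNA runs 2×2×10⁴.
Reference proteins are seeded random sequences of similar length
(300–360 aa), which makes family assignment unambiguous and lets
edge-truncation losses cancel between markers and target families.

These choices mean a passing benchmark demonstrates the correctness of the
numeric chain — translation, alignment, filtering, normalization,
statistics — under the model's own assumptions. It does not demonstrate
robustness to real-data phenomena the simulator omits: homologous families
with genuine sequence similarity to each other, indels, GC and coverage
bias, quality-dependent errors, strain mixtures, or incomplete marker
inventories. The RNA:DNA recovery also carries a small compositional
shrinkage (a 3× multiplier on one family inflates the RNA library total, so
the recovered ratio sits a few percent below 3), which is a property of
relative-abundance data generally, not of this implementation.

## Known limitations

* Seeded candidate search can miss homologs with no shared 5-mer; use
  `seed_len=0` when exhaustiveness matters more than speed.
* The classifier is single-threaded; the CLI accepts `--threads` for
  interface stability but currently runs one worker.
* Exact Wilcoxon enumeration is refused above combined n = 24; the
  DP-counted null used in verification has no such limit but is not wired
  into the user-facing test.
* Electron balances ignore biomass; recoveries below ~1 are expected for
  growing cultures.
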