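# h2profile

Hydrogen (H₂) turnover is a central but under-measured currency of the human
gut microbiome: fermentative bacteria dispose of excess electrons by reducing
protons with hydrogenases, and other community members re-oxidize that H₂
through acetogenesis, methanogenesis, sulfate reduction or respiration.
`h2profile` is a reusable pipeline for quantifying this hydrogen economy from
shotgun sequencing: it classifies metagenome/metatranscriptome reads into
hydrogenase subgroups ([FeFe] groups A1–C, [NiFe] groups 1–4, [Fe]) and
H₂-linked terminal reductase families, converts counts into
copies-per-genome, compares cohorts, profiles isolate genome collections,
and closes fermentation electron balances.

It is aimed at microbial ecologists and anaerobe physiologists who want the
full numeric chain — from raw reads to "how many hydrogenase copies does the
average organism in this community carry, and how transcribed are they" — in
tested, scriptable form, together with a mock-community simulator whose
ground truth every stage can be checked against.

## Method

**Read classification.** Reads are translated in all six frames (code 11)
and aligned to a reference protein database with affine-gap local
Smith–Waterman (BLOSUM62; gap open 11, extend 1; exact k-mer seeding for
candidate selection). The best-scoring hit is kept only if the aligned
length is ≥ 28 aa (26 aa in the `health26` profile) and the percent identity
reaches the best-hit family's threshold (50/60/70% depending on family).

**Copies per genome.** Per-family read counts are normalized to RPKM
(reads per kilobase of gene per million screened reads); metagenome RPKM is
then divided by the mean RPKM of 14 universal single-copy ribosomal marker
genes:

    cpg(f) = RPKM(f) / mean_{m in markers} RPKM(m)

which estimates the average per-organism copy number of family *f* in the
community. Paired metatranscriptomes give RNA:DNA transcription ratios;
isolate transcript counts are summarized in TPM.

**Cohort statistics.** Per-family case–control differences are tested with a
two-sided Wilcoxon rank-sum test implemented from first principles (exact
enumeration for small tie-free samples, tie-corrected normal approximation
with continuity correction otherwise) and Holm–Bonferroni adjusted.

**Genome profiling.** Isolate proteomes (completeness > 90%, contamination
< 5%) are searched with the same aligner; a protein counts toward its
best-hit family when query and subject coverage are both ≥ 80% and identity
meets the family threshold.

**Electron balance.** Available electrons per compound follow the
degree-of-reduction convention γ = 4C + H − 2O − 3N; the H₂ electron
fraction is 2·n(H₂) divided by either substrate electrons consumed or the
recovered-product electron sum.

## Worked example

```python
from h2profile import (classify_reads, profile_sample,
                       example_community, example_reference_db, simulate_reads)

db = example_reference_db(seed=17)            # synthetic reference DB, 32 families
spec = example_community(seed=1)              # 5 genomes, truth cpg 2.0/1.0/0.5/0.25
reads, truth = simulate_reads(spec, 10_000, db, seed=1)
profile = profile_sample(classify_reads(iter(reads), db), db, "mock")
for fam in ("FeFe_B", "FeFe_A1", "FeFe_A3", "NiFe_4a", "marker_rpl2"):
    print(f"{fam:12s} cpg={profile.family_cpg[fam]:.3f}  truth={truth.expected_cpg.get(fam)}")
```

prints (10,000 reads, 0.5% substitution error):

```
FeFe_B       cpg=2.042  truth=2.0
FeFe_A1      cpg=0.946  truth=1.0
FeFe_A3      cpg=0.505  truth=0.5
NiFe_4a      cpg=0.238  truth=0.25
marker_rpl2  cpg=1.019  truth=1.0
```

i.e. the full simulate → classify → normalize chain recovers each family's
average copy number per organism within a few percent, and the single-copy
markers sit at 1 as they must.

The same stages are available as a CLI:

```sh
h2profile simulate --n-reads 100000 --seed 1 --out sim/
h2profile classify --reads sim/dna.fastq --db-fasta sim/reference.faa \
    --db-tsv sim/reference.tsv --out cls/
h2profile quantify --hits cls/hits.tsv --screened cls/screened.txt \
    --db-fasta sim/reference.faa --db-tsv sim/reference.tsv --out quant/
```

plus `build-db`, `profile-genomes`, `compare` and `balance` subcommands.

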