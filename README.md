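# vdjprof

Immune-repertoire (AIRR-seq) profiling for T- and B-cell receptor loci
(TRA, TRB, IGH, IGK, IGL): germline database handling, paired-read
preprocessing, V(D)J annotation with CDR3 extraction, repertoire summary
statistics, Chao1/rarefaction diversity estimation, and per-position FR3
somatic-hypermutation (SHM) analysis — together with a ground-truthed
V(D)J read simulator used to validate every stage.

It is aimed at researchers analysing bulk 5'-RACE/multiplex-PCR receptor
sequencing of organisms with incomplete germline references (e.g. rhesus
macaque), where besides the usual usage/length/diversity statistics one
wants to flag FR3 positions whose "mutations" are really unreported
germline alleles.

## The analysis in brief

Reads are quality-filtered (drop a pair if either mate has mean phred
< 15 or > 5% N bases) and merged by exhaustive overlap search. Each merged
sequence is locally aligned (Smith-Waterman, +1/−1 match/mismatch, −3/−1
gaps) against every functional germline V and J gene; functional genes are
those carrying the conserved CDR3 anchors — an in-frame cysteine codon in
the last 30 nt of V, and the [FW]GXG motif in J. The CDR3 runs from that
cysteine codon through the [FW] codon, inclusive. The junction between the
V and J alignments is decomposed into the canonical seven sections — 3'V,
5'D, 3'D, 5'J deletions and V−D/D−J (or V−J) insertions — with the D
segment placed as the longest contiguous exact match in the inter-anchor
gap.

Clonotypes are triples (CDR3 nt, V gene, J gene). On the clonotype table
the package computes V/J/V−J usage, CDR3 length and amino-acid
composition, rank-abundance curves, junction indel length distributions and
inserted-nucleotide composition. Richness is estimated with Chao1,

    S1 = S_obs + F1² / (2·F2),

where F1/F2 are singleton/doubleton clonotype counts, with rarefaction at
ten subsampling depths × ten replicates, and the captured fraction
100·S_obs/S1.

For BCR loci, reads contributing to each V gene build a per-position FR3
profile (FR3 = nt 196–310 of the V reference under IMGT numbering):
coverage, mismatch counts and observed-base composition. Positions with
coverage ≤ 30 are masked; a position with mutation frequency strictly
above 10% is a hotspot; a deep position (≥ 1000 bases) where one single
non-reference base carries 40–60% of the coverage is called a polymorphic
site — evidence of an unreported heterozygous germline allele rather than
SHM.

## Worked example

Simulate a TRB library and run the full pipeline on it:

```bash
vdjprof simulate --locus TRB --out-dir sim --seed 9 --n-clonotypes 60
vdjprof run --locus TRB \
    --r1 sim/reads_R1.fastq --r2 sim/reads_R2.fastq \
    --v-fasta sim/germline_V.fasta --d-fasta sim/germline_D.fasta \
    --j-fasta sim/germline_J.fasta --out-dir run
```

The `run` command prints a one-line JSON summary (numbers from seed 9):

```
{"locus": "TRB", "raw_pairs": 119, "merged": 119, "assigned": 119,
 "productive": 21, "distinct_cdr3_nt": 14}
```

meaning: 119 simulated read pairs all passed QC and merged, all were
assigned a V and J gene, 21 reads carry an in-frame, stop-free CDR3 with
functional genes (random junctions are mostly out of frame or contain
stops, as in real data), and those productive reads collapse to 14
distinct CDR3 nucleotide sequences. `run/` then contains, among others,
`clonotypes.tsv`, `usage_v.tsv`, `cdr3_length_aa.tsv`, `rarefaction.tsv`
and `run_summary.json`; a BCR run additionally writes per-gene
`shm_profile_*.tsv`, `shm_hotspots.tsv` and `shm_polymorphic.tsv`.

The same machinery is available as a library:

```python
from vdjprof import simulate, diversity

print(diversity.chao1(10, 4, 2))            # 14.0
print(diversity.fraction_captured(198447, 250790))  # 79
```

## Layout

| module | contents |
|---|---|
| `vdjprof.germline` | FASTA reading, motif filtering, anchors, FR3 span |
| `vdjprof.simulate` | config, rearrangement generator, read emission, synthetic references |
| `vdjprof.preprocess` | quality filter, pair merging, QC report |
| `vdjprof.annotate` | V/(D)/J assignment, CDR3, productivity, junction decomposition, IGK/IGL demultiplexing, error collapse |
| `vdjprof.repstats` | usage, lengths, composition, rank-abundance, junction statistics |
| `vdjprof.diversity` | Chao1, capture fraction, rarefaction |
| `vdjprof.shm` | FR3 profiles, mutation rates, hotspots, polymorphic sites, spectra |
| `vdjprof.validation` | end-to-end parameter-recovery experiments |
| `vdjprof.cli` / `vdjprof.pipeline` | command-line entry points and orchestration |

See `docs/methods.md` for the models, conventions and their rationale.
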