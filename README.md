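# kclust

Fast, sensitive greedy clustering of protein sequence databases down to
20–30% pairwise sequence identity.

Sequence databases grow faster than they can be searched; clustering them
into homologous groups — one representative per cluster — makes searches
faster and more sensitive and keeps profile databases non-redundant.
Clustering below ~50% identity is the hard regime: exact k-mer counting
prefilters (the CD-HIT/UCLUST approach) lose either speed or sensitivity
there. This package implements the alternative strategy of scoring
*similar* k-mers: an alignment-free prefilter that sums BLOSUM62
similarity scores over all similar spaced 6-mers between a query and the
cluster representatives, and a two-stage anchor aligner that chains
similar spaced 4-mer matches by dynamic programming and refines them to a
residue-level alignment. It is aimed at people who need to cluster
protein FASTA databases from Python or the shell and at people studying
alignment-free k-mer statistics.

## Method

**Greedy incremental clustering.** Sequences are sorted by length,
longest first. Each query is compared with the representatives of the
clusters created so far and joins the first one fulfilling all three
criteria; otherwise it founds a new cluster:

1. alignment score per column ≥ 1.12 half-bits (≈ 30% identity),
2. E-value ≤ 10⁻³,
3. the alignment covers ≥ 80% of the representative's residues
   (so members share essentially the whole domain architecture).

**Similar-k-mer prefilter.** For every spaced 6-mer x of the query, the
list of all 6-mers y with Σⱼ S(xⱼ, yⱼ) ≥ S_min is generated (default
S_min = 4.3 half-bits/column = 25.8 half-bits), and each occurrence of a
listed y in an indexed representative adds its similarity score to that
representative's accumulator. Representatives scoring ≥ 0.55 half-bits
per query position are passed to the aligner. Lists are produced by a
branch-and-bound over prefixes with per-position bounds
S_min,j = S_min − Σ_{i>j} S(xᵢ, xᵢ), sped up by pre-sorted amino-acid
dimer lists; k-mers are indexed at ∑ⱼ xⱼ·21^(k−j) in an inverted table,
and the accumulator is reset between queries by walking only the touched
sequences.

**Anchor alignment (k-mer dynamic programming).** Similar spaced 4-mer
matches between the pair (list threshold calibrated to a mean list length
of ≈ 200) are chained to maximize Σ anchor scores − gap costs
(gap_open + gap_extend·|Δdiagonal|); the optimal residue-level local
alignment constrained through the chained anchors is then computed by
affine-gap dynamic programming restricted to the corridors between
anchors. Scores are exact integer half-bits throughout.

**Profile-based second iteration.** Each cluster is summarized by a star
MSA, a consensus sequence, and a position-specific profile with
matrix-derived pseudocounts; a second greedy pass replaces substitution
scores with profile scores in both stages and merges clusters, which can
only reduce the cluster count.

Spaced patterns (default `110101011` for the 6-mer stage, `11011` for the
4-mer stage) decorrelate neighboring window scores.

## Worked example

```sh
$ kclust synth family --families 3 --members 8 --length 150 \
    --id-lo 0.5 --id-hi 0.8 --seed 7 -o demo.fasta
24 sequences in 3 families -> demo.fasta

$ kclust cluster -i demo.fasta -d out1
5 clusters for 24 sequences -> out1

$ kclust iterate -i out1 -d out2
5 clusters merged into 3 -> out2

$ kclust eval -c out2/clusters.tsv -l demo.fasta.labels.tsv
clusters	3
corrupted_clusters	0
corrupted_fraction	0
wrong_per_corrupted	0
```

Three synthetic families of eight members each (50–80% identity to their
family seed, so mutual identities reach down to ~30%) first cluster into
5 clusters; the profile iteration merges them into the 3 true families
with no corrupted cluster (no cluster mixing two families).
`out1/clusters.tsv` maps representative to member ids
(`fam0_5<TAB>fam0_7`, one line per member), `representatives.fasta` holds
one sequence per cluster, and `out1/log` records the per-stage counters
(here 24 queries, 24 prefilter hits, 19 alignments, 19 acceptances).
`kclust prefilter` and `kclust align` expose the two stages individually
as TSV, and `--block-size` activates the disk-spilling block mode for
databases that should not be indexed all at once.

The same pipeline is available as a library:

```python
from kclust import cluster, ClusterParams
from kclust.seqio import read_fasta

clustering = cluster(read_fasta("demo.fasta"), ClusterParams())
print(len(clustering))
```

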