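# Methods

## Sequence model and scoring

Sequences are encoded over a 21-letter alphabet: the 20 amino acids in
substitution-matrix row order (A R N D C Q E G H I L K M F P S T W Y V,
codes 0–19) plus a wildcard class (code 20) to which every ambiguity or
non-standard letter (B, Z, J, U, O, X, …) is mapped. All similarity
scores are BLOSUM62 entries, which are integer half-bit log-odds; score
accumulation is therefore exact integer arithmetic, and only thresholds
may be fractional. The wildcard scores 0 against everything; k-mer
windows containing it are neither indexed nor queried. Background
amino-acid frequencies are the Robinson–Robinson values used by BLAST.

## Similar-k-mer lists

The similar-k-mer list of a query k-mer x at threshold S_min is
{ y : Σⱼ S(xⱼ, yⱼ) ≥ S_min } with scores. It is generated depth-first,
extending prefixes position by position and pruning with
S_min,j = S_min − Σ_{i>j} S(xᵢ, xᵢ) (the self score is the row maximum,
so no pruned prefix can reach S_min). Candidate extensions are visited
in descending score order, so generation cost is proportional to the
list length. The production path extends two positions at a time from
pre-sorted 400-entry dimer lists (cached per query residue pair); a
single-letter variant exists and is tested to return identical lists.

Defaults: the 6-mer stage uses 4.3 half-bits per column (25.8 total).
The 4-mer stage threshold was calibrated once with
`calibrate_threshold` to a target mean list length of 200 over 2000
background-composition 4-mers (seed 42) and frozen at 13 half-bits
(measured mean 189). Under the same background sampling, the 6-mer
stage's mean list length at 25.8 half-bits is ≈ 255 (median ≈ 51 — the
distribution is heavy-tailed, dominated by queries of high-self-score
residues, while queries composed of common residues such as A/S/T can
have self scores below threshold and empty lists).

Spaced patterns default to `110101011` (weight 6, span 9) and `11011`
(weight 4, span 5); both begin and end with match positions. The
original patterns are not published; these were chosen once to spread
match positions and are configurable. The per-column threshold is
applied to the k match positions only, not to the span.

## Prefilter

Representatives are indexed by spaced 6-mer code (base-21 positional
code, one bucket entry per occurrence, so a k-mer occurring twice in a
representative contributes its score twice). Scoring a query walks its
spaced 6-mers, generates each similar list, and adds each list score to
the accumulator of every sequence containing the k-mer. A touched-list
makes the reset between queries O(#touched), not O(#indexed). The raw
score is normalized by the full query length (wildcard positions
included); the default candidate threshold is 0.55 half-bits per query
position. Hits are ordered by raw score descending, ties by sequence
number ascending, making the downstream candidate order deterministic.

## Anchor alignment

Stage one records all pairs of spaced 4-mers scoring ≥ the 4-mer
threshold, found by looking up the query's similar-4-mer lists in a
dictionary index of the target (never by all-pairs scoring). Overlapping
same-diagonal anchors are merged into runs whose score is recomputed
over the union of matched positions, so no residue pair is counted
twice. Chaining maximizes Σ anchor scores − gap costs over subsets
strictly increasing in both coordinates, where colinear non-overlapping
neighbours are free and a diagonal change of d costs
gap_open + gap_extend·d; the empty chain (score 0) is allowed, ties are
broken toward fewer anchors, then smaller start. The chaining recurrence
and the corridor refinement are this package's reconstruction of
"optimal alignment through matched k-mer pairs"; the original algorithm
is unpublished.

Stage two computes the optimal affine-gap local alignment constrained to
pass through every matched position of the chain: full DP inside the
rectangular corridors between consecutive constrained pairs, plus
anchored local extensions before the first and after the last pair.
Constrained pairs are match columns, so gaps cannot span them, which
keeps the segment DPs independent. The result never exceeds the
unconstrained Smith–Waterman score and equals it whenever the optimal
path passes through the chain (verified against Biopython's
PairwiseAligner).

Gap penalties default to 22/2 half-bits (open/extend), the half-bit
analogue of the BLAST convention. Alignment statistics: score per column
divides the raw score by aligned pairs plus gapped columns; identity is
the fraction of columns with equal residues; coverage is the spanned
fraction of the target (the representative, always the longer sequence).
The E-value is K·L_query·N_db·exp(−λ·S_nats) with S converted from
half-bits to nats and the standard gapped-BLOSUM62 parameters λ = 0.267,
K = 0.041; N_db is fixed to the total residue count of the input
database rather than the evolving representative set, so E-values do not
depend on processing order. No published E-value parameterization exists
for this aligner; the formula above is a conventional reconstruction, and
its absolute scale should not be over-interpreted.

## Greedy clustering

Queries are processed in descending length (stable ties). Candidates are
tried in prefilter order and the query joins the first accepted
representative; there is no candidate cap by default (a configurable
limit exists). Acceptance thresholds default to 1.12 half-bits/column,
E ≤ 10⁻³, coverage ≥ 0.8. The `--id` convenience flag maps an identity
percentage to a score-per-column threshold: the mapping is anchored so
30% ↦ 1.12 exactly and interpolates a seeded calibration curve measured
on synthetic pairs at a grid of identities; identity 0 disables
criterion 1 (maximum sensitivity).

Block mode processes the length-sorted input in blocks: each block is
first compared against the representatives of earlier blocks (re-read
from a FASTA spill file), and the remainder is clustered within the
block. With block size ≥ database size the output is identical to the
in-memory mode; with smaller blocks only the partition and
member-validity invariants are guaranteed, since block boundaries change
the candidate encounter order.

## Profile iteration

Each cluster yields a star MSA (members placed on the representative's
columns via their stored pairwise alignments; insertions relative to the
representative are dropped), a consensus (per column the residue
maximizing the expected substitution score against the gap-excluded
column frequencies, ties to the lower code, all-gap columns falling back
to the representative), and a profile. Profile scores are
2·log₂(p(y)/f_y) rounded to integer half-bits and clipped at −64, with
p(y) = (1−τ)·obs(y) + τ·Σₓ obs(x)·f_y·2^{S(x,y)/2}. The pseudocount
mixture is deliberately left unnormalized so that τ = 1 on a
single-sequence column reproduces the substitution-matrix row exactly;
the normalization deviation is < a few percent and absorbed by rounding.
The admixture schedule is τ = 1/(1 + m/10) for m member sequences
(no published value exists; chosen once so that small clusters stay
matrix-like and large clusters become data-driven).

The merge pass sorts clusters by consensus length and repeats the greedy
loop with the consensus driving k-mer extraction and the profile columns
replacing matrix rows in both the prefilter and the aligner; targets are
the consensus sequences of already-created merged clusters
(profile-vs-consensus, not profile-vs-profile). Merging unions member
sets, preserves the partition, and cannot increase the cluster count.

## Synthetic data

`random_sequence` draws i.i.d. background residues. `mutate_to_identity`
substitutes exactly round((1−identity)·L) uniformly chosen positions,
drawing replacements from the matrix-conditional distribution
P(y|x) ∝ f_y·2^{S(x,y)/2} with the original residue excluded, so the
realized gapless identity is exact to 1/L and substituted residues have
realistic k-mer statistics. Families are stars around a seed sequence
(member identities uniform in a range, lengths jittered ±10% by terminal
truncation/extension); two-domain databases concatenate members of two
families and reject draws whose longer domain exceeds 80% of the total
length. Truth labels ride in FASTA headers as whitespace-separated
`|FAM=` / `|ARCH=` tags. Everything is deterministic per seed.

What the generator does **not** emulate: insertions/deletions (off by
default, so coverage is essentially 1 for generated pairs), low
complexity and compositional bias, and — most consequentially — the
blockwise conservation structure of real homologous pairs. Substituted
sites are chosen uniformly, so a pair at 30% identity almost never
retains a run of six conserved match positions. Real homologs at the
same identity keep conserved motifs, which is precisely what a
similar-6-mer prefilter exploits. The prefilter sensitivity measured on
these synthetic pairs (≈ 35–40% of accepted 25–40%-identity pairs pass
0.55 half-bits/position; `scripts/acceptance.py`) is therefore a hard
lower bound that should not be read as the tool's sensitivity on real
databases, where accepted cluster members are also dominated by much
higher identities. An experiment with gamma-distributed site rates
(shape 0.3–1.0) moved this number by only a few points, so the simpler
uniform model was kept. The two-domain construction, by contrast,
transfers well: corrupted-cluster counts on it measure exactly the
coverage criterion's architecture safety.

## Problem sizes and numerical choices

The bundled tests run the full pipeline on databases of a few hundred
sequences of length ~100–250 and the sensitivity benchmark on 500 pairs
of length 200–400 — sizes chosen so the whole suite completes in a few
minutes on one core while still exercising every stage at realistic
per-sequence scale. All randomness flows through explicit integer seeds;
clustering itself is deterministic given the input order. Degenerate
inputs are defined rather than erroneous: sequences shorter than the
seed span are indexed with zero entries and can only found singleton
clusters; all-wildcard queries produce empty hit lists; empty anchor
chains yield empty alignments with score 0 (statistics are refused on
zero aligned columns).

## Known limitations

Single-threaded; the index is not persisted between runs; no
composition-based E-value correction; profile mode stops at score
replacement (no insert/delete states, i.e. no profile HMM); header
merging/annotation of cluster members is out of scope. The E-value
parameterization is a reconstruction (see above), so criterion 2 should
be treated as a scale-dependent filter rather than a calibrated
significance level.
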