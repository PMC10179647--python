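# Methods

## The reporter model

The package models a bivalent traffic-light editing reporter: a single
transcription unit encoding, in order, a constitutive mCherry, a 2A
peptide, an exchangeable sequence-of-interest (SOI), a second 2A peptide,
a P2A–mTagBFP2 cassette displaced by −2 nt from the main reading frame,
and a T2A–NanoLuc cassette displaced by −1 nt. In the unedited state only
mCherry (and the in-frame SOI) is translated. A CRISPR-induced indel in
mCherry or the SOI shifts the downstream register: a net indel length
congruent to −1 (mod 3) brings the NanoLuc cassette into frame (secreted
luminescence), −2 (mod 3) brings mTagBFP2 into frame (nuclear
fluorescence), and 0 (mod 3) disrupts the target without a frameshift.
Homology-directed repair from a single-stranded template (two 80-nt
homology arms around a 39-nt restored segment; 199 nt in total) converts
the defective moxGFP-like SOI back to its intact form, read out as
mCherry⁺/moxGFP⁺.

Frame classes are therefore *equivalence classes of the net indel length
mod 3*, grouping insertions and deletions together (a 1-nt deletion and a
2-nt insertion are both N−1). `frame_class` implements exactly this
arithmetic; a brute-force enumeration over all (insertion, deletion)
length pairs in [0,9]² backs it in the tests.

The phenotype table (`predict_phenotype`) follows from the architecture:

| region  | class        | mCherry | moxGFP | mTagBFP2 | NanoLuc |
|---------|--------------|---------|--------|----------|---------|
| any     | unedited/subst. | ✓    | –      | –        | –       |
| any     | HDR          | ✓       | ✓      | –        | –       |
| mCherry | N−1          | –       | –      | –        | ✓       |
| mCherry | N−2          | –       | –      | ✓        | –       |
| mCherry | N−3 in-frame | –*      | –      | –        | –       |
| SOI     | N−1          | ✓       | –      | –        | ✓       |
| SOI     | N−2          | ✓       | –      | ✓        | –       |
| SOI     | N−3 in-frame | ✓       | –      | –        | –       |

\* In-frame indels inside mCherry are assumed to destroy fluorescence
(`inframe_disrupts_function=True` by default). Whether very small in-frame
indels retain function is not knowable from the model, so this is an
explicit flag rather than a hard-coded guess. In-frame indels inside the
SOI necessarily leave mCherry intact — its 2A peptide lies upstream of the
break.

A cell's phenotype is the elementwise OR over its integrants
(`cell_phenotype`). This is what makes multi-integrant clones
diagnostic: a single-integrant cell can never be moxGFP⁺/mTagBFP2⁺
(each integrant is either repaired or frameshifted, not both), whereas a
k-integrant cell is double-positive with probability
1 − P(no HDR) − P(no N−2) + P(no HDR ∧ no N−2), each factor binomial in k.
The simulator is tested against this closed form.

## Frame-constrained codon design

An SOI must carry no stop triplet (TAA/TAG/TGA) in any of the three
reading frames, otherwise a frameshift would terminate before reaching the
downstream cassettes. Any off-frame stop triplet spans exactly two
adjacent codons, so feasibility and optimality decompose over codon
junctions. `optimize` runs a dynamic program whose states are *pairs* of
adjacent synonymous codons: a transition (a,b)→(b,c) is allowed when the
6-mer b+c carries no stop at offsets 1–2 and no forbidden motif touches
both codons, and when no forbidden motif spans the full 9-mer a+b+c. Pair
states (rather than single-codon states) make the motif exclusion exact
for motifs up to 7 nt — a 6-mer such as the Esp3I site CGTCTC can span
three codons — at a cost of at most 6³ transitions per residue. Motifs
longer than 7 nt are post-checked on the assembled CDS and reported as
infeasible if present.

Scores are summed log usage weights (uniform by default, since no
organism-specific table is assumed; a TSV table can be supplied). Ties
break toward the lexicographically smallest CDS for cross-platform
determinism. The DP is verified against an exhaustive depth-first search
over all codon assignments on all 400 dipeptides and on 200 random
proteins of length ≤ 8.

Some proteins are genuinely infeasible: methionine's single codon ATG
followed by any residue whose codons all start with A (Thr, Asn, Lys,
Ile, Met) forces TGA in frame +1. The optimizer reports the first
infeasible junction instead of silently relaxing a constraint.

## The synthetic construct

`build_synthetic_reporter` generates, from a seed, a ~1 kb construct with
the full architecture: the region from the mCherry ATG through the end of
the reporter cassettes contains *no stop triplet at any offset* (so
frameshifted translation reads through, as in the real construct), exactly
two Esp3I sites with distinct 4-nt overhangs flanking the SOI
head-to-head, a frame-consistent main ORF, and a terminal stop. The SOI is
a 201-nt "defective" form of a 240-nt sequence with a 39-nt internal
deletion; the matching HDR template (80+39+80), a unique spCas9 guide
whose blunt cut falls at the deletion junction, sequencing primers
delimiting a 380-nt amplicon, and a 100-nt analysis window centred on the
cut are derived alongside. Generation is constraint-propagating base
sampling with deterministic retry, so the whole bundle is reproducible
text, not stored data. The construct mirrors the published architecture,
not any deposited sequence — codon content, promoter and cassette bodies
are random subject to the constraints above.

## Simulation

Cut sites: spCas9/saCas9 cut blunt 3 nt 5′ of the PAM; asCas12a
(5′ TTTV PAM) is modelled with the standard staggered geometry, cut after
protospacer positions 18/23, with the position-18 cut as the blunt
representative. NHEJ outcomes draw from an indel spectrum — by default
geometric-tailed deletions (p = 0.5, truncated at 30 nt) mixed 4:1 with
1-nt insertions. This default is a generic desk-scale stand-in, not an
estimate of any particular repair profile; it is configurable via TSV, and
every analysis result is conditioned on it only through class masses (the
classifier recovers whatever mixture was simulated). Deletions are centred
on the cut; insertions are placed immediately 3′ of it.

Amplicon sequencing is modelled as: uniform sampling over molecules,
paired 250-nt reads from the two amplicon ends, i.i.d. substitution errors
(default 0.001), constant Q30 qualities. No PCR bias, chimeras, indel
sequencing errors or quality degradation are modelled — so passing tests
show correctness of the classification logic under calibrated substitution
noise, not robustness to platform artifacts. Sorting gates are treated as
exact: a simulated "sorted population" contains exactly its nominal
mixture.

## Amplicon classification

Reads are 3′ quality-trimmed (sliding window mean < Q20 cuts at the first
failing base; survivors < 40 nt dropped), mates are merged over the
overlap minimizing the mismatch fraction (≥ 20 nt, ≤ 10% mismatches,
higher-quality base wins conflicts), and merged reads are aligned to the
full reporter reference with affine gaps (match +2, mismatch −3, gap
open −6, extend −1; a gap of length L costs −6−L), free end gaps on the
reference side only. Alignment is delegated to Biopython's
`PairwiseAligner`; determinism comes from its canonical first optimal
alignment plus explicit left-alignment of every indel within
homopolymer/repeat context before event reporting. An independently coded
Gotoh DP verifies optimal scores in the tests. With this scoring a
substitution (−3) is always cheaper than the indel pair that could mimic
it (−7 −7), which is why substitution noise cannot create frame calls.

Reads that do not span the full analysis window are excluded with a reason
code, never partially counted. Unique window haplotypes are counted and
classified: no indels and byte-identical to the reference window →
UNEDITED; no indels otherwise → SUBSTITUTION_ONLY; otherwise by the net
indel sum mod 3 → N−1 / N−2 / N−3.

**Template repair calls.** When a repaired reference (defective reference
with the restored segment inserted) is supplied, each read is assigned the
backbone that explains it with the higher alignment score, and a
repaired-backbone read with *no indel in the window* is classified HDR.
Point substitutions on the repaired backbone are treated as sequencing
noise — exactly as they are for unedited reads on the defective backbone.
The alternative rule (byte-exact window match) would misclassify
≈ 1−(1−e)^w of genuinely repaired molecules at error e over a w-nt window
(≈ 9.5% at e = 0.001, w = 100) as in-frame insertions, which contradicts
what a sorted, fully repaired population should report. A repaired-backbone
read that *does* carry extra indels is classified by its total net shift
relative to the defective reference. A consequence worth knowing: a
molecule carrying the restored segment plus a compensating indel elsewhere
in the window is not called HDR.

## Integration mapping

Junction reads are retained when any substring lies within Levenshtein
distance 2 of either terminal 15-mer of the transgene, on either strand
(edlib infix alignment; equivalent to a full-DP oracle in tests —
"edit distance" is read literally as Levenshtein). For each passing read
the matched k-mer is located, the read is canonicalized so the transgene
appears in forward orientation, and the read must continue past the k-mer
into the transgene body (≤ 10% edits over up to 50 nt). This continuation
check matters: a terminal 15-mer finds a near-match (distance ≤ 2) in
random sequence at roughly 10⁻³ per 150-mer, and such a genome-resident
match recurs in *every* read covering that locus, producing a phantom
junction that no support threshold can remove.

The genomic flank (≥ 20 nt) adjacent to the transgene segment is placed on
the reference genome by unique exact 20-mer search on both strands;
ambiguous or error-carrying seeds skip the read. Junctions on the same
contig and orientation within 10 nt (tagmentation-position jitter) merge
into one call, reported at the cluster median with its supporting-read
count and which transgene end(s) were seen; clusters below `min_support`
(default 2) are dropped. Exact seeding is deliberate: at toy-genome scale
it is unambiguous and dependency-free; mapping against a real genome at
scale is out of scope.

## Problem sizes and numerical choices

Simulated read sets are 5,000 pairs for pure sorted populations and
10,000 pairs for mixtures, with 3-contig 60-kb toy genomes and a 1.5-kb
transgene for integration mapping — sizes at which every stochastic check
has clear separations (3 SD binomial/multinomial bands) while the full
suite runs in minutes. Determinism: all randomness flows from explicit
integer seeds through `numpy.random.default_rng` or `random.Random`;
identical seeds reproduce byte-identical FASTQ output. Class fractions
always sum to 1 by construction (counts over classified reads only).

## Known limitations

- The indel spectrum is a fixture; real gRNA-specific repair profiles
  differ and the simulator makes no attempt to predict them (guide
  efficiency prediction is explicitly out of scope).
- Phenotype prediction is purely frame-logical: 2A cleavage efficiency,
  protein stability, promoter strength and spectral overlap are not
  modelled.
- Sorting-gate impurity is not modelled; observed mixtures in real sorted
  populations fold gate purity into the class fractions.
- The integration mapper targets desk-scale genomes; it uses exact
  seeding, not a BWT aligner, and does not handle repetitive flanks beyond
  skipping ambiguous seeds.
- Merging assumes amplicons shorter than twice the read length; longer
  amplicons are emitted as unmerged pairs and excluded with a reason code.
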