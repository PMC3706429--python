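# Methods

This note records the models behind each stage, the parameters that matter,
the numerical choices made where the design was genuinely open, and what the
synthetic cohorts do and do not establish about real data.

## Coordinate model

All coordinates are 1-based and inclusive (GenBank convention): the interval
(start, end) spans `end − start + 1` bases. Reverse-strand features are
extracted and translated in reading orientation. RNA input is normalised
U→T on read, so splice rules stated on the message (a 3' U at the end of
exon 1) are tested as T at the DNA level. The only half-open output is the
optional BED writer, which converts at the boundary.

## Genome relatedness

**ANI.** Fragment-based, in the style of whole-genome ANI estimators: the
query is cut into consecutive non-overlapping 1 kb fragments; each fragment
is mapped to the subject with edlib in infix mode on both strands; the
fragment's best-scoring aligned sub-segment (a Kadane pass over the
alignment path, +2 per match / −3 per mismatch-or-gap column) plays the
role of a local high-scoring pair. Fragments are retained when that segment
covers ≥ 70% of the fragment at ≥ 70% identity; a direction's value is the
mean identity (over aligned columns) of retained fragments, and the
reported ANI is the mean of the two directions — exactly symmetric by
construction. The per-fragment HSP step matters: a fragment straddling a
large insertion would otherwise count the insertion as error and bias ANI
down by ~0.01 on 30 kb genomes.

**Alignment scoring.** Proteins: BLOSUM62 with affine gaps in the BLAST
convention (a gap of length L costs 11 + L); global identity is identical
pairs over the shorter sequence length — robust to terminal extensions and
in-frame insertions such as inteins. Nucleotide local alignment: match +2,
mismatch −3, gap 5 + 2L. E-values follow Karlin–Altschul,
E = K·m·n·exp(−λS), with fixed constants (nt λ=1.28, K=0.46; aa, gapped
BLOSUM62-11-1, λ=0.267, K=0.041). The constants are deliberately not
estimated from data: the only threshold applied to an E-value is 10⁻⁵⁰,
so the choice cannot flip a classification outside a negligible band.

**Phams.** Two proteins are related when global identity ≥ 0.325 **or**
local E ≤ 10⁻⁵⁰ (both inclusive); phamilies are the connected components
(single linkage), isolated proteins are orphams, and pham ids follow each
component's lexicographically smallest (genome, gene) member so outputs are
stable. Two caveats are inherent to these definitions: pham membership is
database-dependent (an intermediate sequence can bridge two components), so
counts computed inside a large database differ from counts over a few
supplied genomes; and the min-length identity denominator lets a short
protein reach 32.5% against a much longer unrelated one through scattered
matches. The edit-distance prescreen used for speed therefore only skips
length-comparable pairs (shorter ≥ 0.8 × longer) below 15% edit identity —
levels unreachable by any pair that could pass either threshold.

## Insertion discovery

Between a carrier and a reference genome, a collinear chain of unique
shared 15-mers (longest increasing subsequence on the reference coordinate)
frames the comparison. An adjacent anchor pair where the carrier advances
≥ `min_len` (50 bp) more than the reference brackets a candidate element.
Boundaries come from X-drop flank extension along the two
anchor-synchronized diagonals: greedy gap-free extension scoring +1/−2 with
X = 20, taking the (last) argmax as the end of flank homology. Homologous
flanks (divergence well below one third) drift upward at ≈ 1 − 3d per base;
unrelated element content drifts down at ≈ −1.25 per base, so the argmax
sits at the junction whenever the junction bases determine it. Left and
right extensions meeting — or overlapping — on the reference classify the
event: a positive remainder is co-deleted target sequence (reported in the
call evidence, up to `max_ref_gap` = 50 bp, sized to admit the
deletion-associated endonuclease arrivals this pipeline must call); an
overlap is a duplicated target, and the region is rewound by the overlap so
the duplicate is part of the call. Pure insertions are then
**left-normalised** (shifted to the smallest start while the base before
the segment equals its last base), the indel-calling convention, and the
number of equivalent placements is reported.

A junction immediately adjacent to a reference-private substitution is
genuinely ambiguous in that one pair. `consensus_scan` therefore votes
boundaries across several references — calls are grouped by overlap and the
modal (start, end, deleted-sequence) triple wins, ties falling to the
earliest (closest) reference — which recovers the true junction whenever
any reference is locally clean. A carrier-private substitution at a
junction is invisible to every pairwise comparison; no detector can resolve
it, which is why the synthetic generator keeps planted junctions clear of
the carrier's own substitutions (below).

## Element classification

Evidence gathered per call: internal ORFs (six-frame, ATG/GTG/TTG starts,
one ORF per stop, ≥ 50 codons, each flagged for the literal LAGLIDADG
motif), TSD reconstruction, splice restoration when the call sits in an
annotated CDS, a protein-level intein test when the interrupted gene still
reads through, and target reconstruction (precise vs deletion-associated).

**Splice restoration.** Candidate excisions shift both call boundaries
within ±10 bp (in-frame fusions only); each fused gene is translated and
compared to the best reference homolog (best global identity ≥ 0.4 among
reference CDSs — safely below the 0.9+ identities of true homologs in a
cohort, safely above spurious pairing). A fusion with an internal stop
scores zero. The winner maximises identical residues **over the reference
protein's length** — the min-length denominator would reward over-excision
— with ties broken by (a) both group I hallmarks, (b) exact length match,
(c) leftmost boundaries.

**TSD reconstruction.** For duplication lengths d from 15 down to 1, over
excision placements within ±15 bp of the call, accept the largest d such
that the placement excises the same sequence as the call (an equivalent
description of the same event, so the reference necessarily holds exactly
one target copy) and the first d excised bases equal the d bases following
the excision. d = 0 is a precise insertion. All equally maximal placements
are reported.

**Precedence** is intein → intron → transposon → endonuclease →
unclassified. The protein-level test outranks the DNA splice test because a
true in-frame intein also excises cleanly at DNA level, while a true intron
never lets the host gene read through in frame and so cannot fire the
intein test (its 100-residue minimum also excludes the rare short in-frame
interruption). An intron must restore ≥ 0.8 identity at matching length
(±10 aa, allowing for codon indels in the homolog) **and** show both group
I hallmarks; a transposon needs a TSD of ≥ 2 bp and an internal ORF of
≥ 200 aa; a free-standing endonuclease is an intergenic (or gene-replacing)
insertion with an ORF ≥ 100 aa and no TSD of ≥ 2 bp (1 bp flanking repeats
are indistinguishable from placement ambiguity and do not count).

**In-silico PCR** predicts product sizes between a primer pair (≥ 15 bp,
≤ 2 mismatches, 3'-terminal 5 bases exact, unique sites required), and the
spliced-template product when an excised interval lies between the primers;
the size difference equals the intron length.

## Integration sites

The attP/attB common core is the longest exact substring (both strands)
shared between the 1 kb window downstream of the integrase gene's 3' end
and the host chromosome, accepted at ≥ 25 bp — long enough that a random
collision between a 1 kb window and a chromosome is improbable, short
enough to find 40–50 bp cores. Host tRNA overlap is reported, never
required. Arm-type sites are 10-mers matching the consensus
5'-TGCATACg/tPuPy: positions 2,3 (GC) and 5,6,7 (TAC) are mandatory;
positions 1 (T), 4 (A), 8 (G/T), 9 (A/G), 10 (C/T) are scored with a
mismatch budget (default ≤ 1). The paper-style naming P1/P2 (left of core)
and P3/P4 (right) is positional, orientation-agnostic (a reverse-strand
cassette carries inverted arms). attL/attR junctions are host-upstream +
core + phage-downstream and phage-upstream + core + host-downstream with
200 bp context; `simulate_integration` builds the full prophage by
core-to-core crossover of the circularised phage, and
`design_integration_fragment` returns the int-through-core interval with
margins, the shape of an integration-vector insert.

## Capsid stoichiometry

T = h² + hk + k² for non-negative lattice indices; a capsid holds 60T
subunits (12 pentamers + 10(T−1) hexamers). In tailed phages one pentameric
vertex is replaced by the portal, removing five subunits: a T=13 virion
carries 60·13 − 5 = 775 copies of the major capsid protein — the only
arithmetic consistent with that printed copy number, stated here explicitly
because the portal correction is often left implicit. Both chiral classes
(h,k) and (k,h) are reported; T=13 admits (3,1) and (1,3).

## Synthetic cohorts and what they establish

`make_cohort("cluster_j_like")` derives six genomes from one ancestor by
per-site substitutions (per-genome rates 0.008–0.112, chosen so pairwise
identities span 0.79–0.97, the ANI range of the cohorts this emulates) and
sparse indels (rate 2 × 10⁻⁵/site, geometric sizes, codon-sized inside
CDSs, never within 10 bp of a CDS terminus). The ancestor is an i.i.d.
sequence at 61% GC organised as stop-free CDSs (~Normal(900, 180) bp,
min 150) in alternating strand blocks with 1–100 bp gaps. Substitutions
that would create an internal stop or break a start/stop codon are
redirected to another base at the same site — purifying selection that
keeps genes translatable while preserving the substituted-site count, hence
the per-site identity (1−r₁)(1−r₂) + r₁r₂/3 recorded by the truth log.

Planted per cohort: a 265 bp intron in a tail-like gene, an 819 bp intron
with a reverse-strand 150-codon LAGLIDADG ORF in a capsid-like gene, a
340 aa intein at residue 104 of a terminase-like gene, a 1.5 kb transposon
duplicating a 5 bp CACTG target, one precise and one deletion-associated
(35 bp) endonuclease gene, and one shared 44 bp att core written downstream
of a designated integrase gene in every genome and into the 3' half of a
host tRNA, bracketed by arm-type repeats (P1,P2 / P3,P4) with an inverted
pair overlapping the int start codon.

**Unambiguous ground truth.** Recovery tests need a unique correct answer,
so the generator (not the detector) removes the ambiguities evolution would
otherwise create at planted junctions: element edge bases (two per side)
are pinned to differ from the flanking context and, for deletion-associated
insertions, from the co-deleted bases; planted junctions keep 7–10 bp
neighbourhoods free of the carrier's own substitutions; the transposon's
target motif is written into the ancestor so every relative carries the
empty allele; intergenic plants stay ≥ 200 bp from genome termini; the
intron's T|…G hallmark pair itself pins its junctions. Every event is
logged with final coordinates, and replaying the log on the rebuilt
ancestor reproduces each genome byte for byte.

**What passing does not show.** The divergence process is a stand-in — no
selection beyond stop avoidance, no codon model, no recombination between
lineages, no mosaic exchange with other clusters; genome termini are blunt
(single-stranded genome-end overhangs are out of model); real junctions
carry the ambiguities the generator suppresses, so boundary-exactness on
real cohorts will be bounded by local divergence in ways these tests do not
measure; and real att cores, arm sites, and homing-endonuclease content are
under selection this generator does not imitate. The tests establish that
the inference machinery is correct where the answer is determined, not that
real data always determines the answer.

## Problem sizes and budgets

The cluster-like scenario defaults to 110 kb phage / 50 kb host, the
genome scale of the cohorts it emulates. The test suite and the recovery
check run the same scenario at 30 kb / 12 kb over 20 seeds — small enough
for a laptop-scale run, large enough that every genome carries ~30 genes
and each pair retains ~30 ANI fragments. Oracle-equivalence checks run
200–500 randomised cases per operation against independent brute-force
implementations (quadratic DP, six-frame enumeration, exhaustive TSD
placement, transitive closure, literal rule evaluation).

## Known limitations

* Single-contig, linear, N-free genomes; ambiguity codes beyond N and
  circular wraparound features are out of scope.
* `find_insertions` is blind within ~15 bp of genome ends (no flanking
  anchor) and reports reference-side alleles for co-deleted bases (the
  carrier's historical copy is unobservable).
* Splice testing assumes an annotated host CDS and a reference homolog at
  ≥ 0.4 identity; unannotated or fully diverged genes fall back to an
  explicit no-homolog marker.
* The classifier's thresholds (0.8 restored identity, ±10 bp splice search,
  ≥ 200 aa transposase, ≥ 100 aa endonuclease ORF) are pragmatic choices
  validated against the synthetic truth, not fitted quantities.
* E-value constants are fixed, not estimated; scores near the 10⁻⁵⁰
  boundary (a band of a few bits) could classify differently under other
  constants.
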