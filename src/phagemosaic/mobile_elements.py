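"""Discovery and classification of intervening segments between related genomes.

Closely related phage genomes differ by discrete intervening segments:
self-splicing group I introns inside structural genes, in-frame protein
inteins, transposons flanked by target-site duplications (TSDs), and
free-standing homing-endonuclease genes inserted precisely or with collateral
loss of target sequence.  This module finds such segments by anchor-based
comparison of a carrier genome against an element-free relative, refines and
left-normalises their boundaries, and classifies them from the evidence a
comparative genomicist would use: splice restoration of the interrupted
protein, protein-level insertion testing, flanking-repeat reconstruction,
and ORF content.

Boundary convention: insertion boundaries inside repeats are ambiguous; calls
are left-aligned (smallest start coordinate), as indel callers normalise
variants, and the number of equivalent placements is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

from .genome_io import (GeneFeature, GenomeRecord, extract_gene_dna,
                        interval_length, revcomp, translate_cds)
from .pairwise_align import global_align_aa

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class InsertionCall:
    carrier: str
    reference: str
    start: int
    end: int
    host_gene: Optional[str] = None
    flank_anchor_len: int = 0
    type: str = "unclassified"
    evidence: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return interval_length(self.start, self.end)


@dataclass
class SpliceHypothesis:
    exon1_end: int
    intron_start: int
    intron_end: int
    exon2_start: int
    restored_protein_len: int
    reference_protein_len: int
    restored_identity: float
    exon1_3prime_base: str
    intron_3prime_base: str
    group_I_flags: tuple[bool, bool]  # (exon1 ends T, intron ends G)
    marker: str = "ok"


@dataclass
class TsdCall:
    tsd_seq: str
    tsd_len: int
    element_start: int
    element_end: int
    alternatives: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class InteinCall:
    host_protein: tuple[str, str]
    insertion_aa_start: int
    insertion_aa_end: int
    intein_len: int
    extein1_identity: float
    extein2_identity: float


@dataclass
class TargetReconstruction:
    kind: str                 # precise | deletion_associated
    deleted_bp: int = 0
    deleted_seq: str = ""
    ambiguous: bool = False


def left_normalize(seq: str, start: int, end: int) -> tuple[int, int, int]:
    """Shift an insertion interval leftward through repeat ambiguity.

    Returns (start, end, n_shifts): the canonical smallest-start placement of
    the inserted segment [start, end] (1-based) within ``seq``.
    """
    n = 0
    while start > 1 and seq[start - 2] == seq[end - 1]:
        start -= 1
        end -= 1
        n += 1
    return start, end, n


def _unique_kmer_positions(seq: str, k: int) -> dict[str, int]:
    pos: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if kmer in dup:
            continue
        if kmer in pos:
            del pos[kmer]
            dup.add(kmer)
        else:
            pos[kmer] = i
    return pos


def _anchor_chain(a: str, b: str, k: int) -> list[tuple[int, int]]:
    """Collinear chain of unique shared k-mers (0-based positions)."""
    pa = _unique_kmer_positions(a, k)
    pb = _unique_kmer_positions(b, k)
    pairs = sorted((pa[m], pb[m]) for m in pa.keys() & pb.keys())
    if not pairs:
        return []
    # longest strictly-increasing subsequence on the b coordinate
    import bisect
    tails: list[int] = []
    back: list[int] = []
    idx: list[int] = []
    for i, (_, y) in enumerate(pairs):
        j = bisect.bisect_left(tails, y)
        if j == len(tails):
            tails.append(y)
            idx.append(i)
        else:
            tails[j] = y
            idx[j] = i
        back.append(idx[j - 1] if j > 0 else -1)
    chain = []
    i = idx[len(tails) - 1]
    while i != -1:
        chain.append(pairs[i])
        i = back[i]
    return chain[::-1]


def _xdrop(cseq: str, rseq: str, x: int = 20) -> int:
    """Length of the homologous prefix shared by two sequences.

    Greedy gap-free extension along the synchronized diagonal (+1 match,
    -2 mismatch), terminating once the score drops ``x`` below its maximum;
    returns the (last) argmax — the number of leading positions that belong
    to flank homology rather than to an intervening element.  Homologous
    flanks (divergence well under one third) drift upward, unrelated element
    content drifts down at about -1.25 per base, so the argmax sits at the
    junction whenever the junction bases determine it.
    """
    best = score = arg = 0
    for i in range(min(len(cseq), len(rseq))):
        score += 1 if cseq[i] == rseq[i] else -2
        if score >= best:
            best, arg = score, i + 1
        elif score < best - x:
            break
    return arg


def find_insertions(carrier: GenomeRecord, reference: GenomeRecord,
                    min_len: int = 50, k: int = 15,
                    max_ref_gap: int = 50) -> list[InsertionCall]:
    """Segments present in the carrier but absent from the reference.

    A collinear chain of unique shared 15-mers frames the comparison; between
    adjacent anchors where the carrier advances at least ``min_len`` more than
    the reference (and the reference's unmatched stretch stays within
    ``max_ref_gap`` — large enough to admit deletion-associated endonuclease
    arrivals), the region pair is aligned and the carrier-only run taken as
    the insertion, then left-normalised.  Reference bases co-deleted at the
    target are recorded in the evidence.
    """
    chain = _anchor_chain(carrier.seq, reference.seq, k)
    if not chain:
        warnings.warn(f"no shared anchors between {carrier.id} and "
                      f"{reference.id}; genomes may be unrelated")
        return []
    calls: list[InsertionCall] = []
    for (c1, r1), (c2, r2) in zip(chain, chain[1:]):
        gap_c = c2 - (c1 + k)
        gap_r = r2 - (r1 + k)
        if gap_c - gap_r < min_len:
            continue
        ck, rk = c1 + k, r1 + k
        if gap_r < 0:
            # the flanking anchors overlap on the reference: both copies of a
            # duplicated target matched the same reference bases.  Rewind the
            # region by the overlap so the duplicate is part of the call.
            o = min(-gap_r, k)
            ck -= o
            rk -= o
        cseq = carrier.seq[ck:c2]
        rseq = reference.seq[rk:r2]
        xl = _xdrop(cseq, rseq)
        xr = _xdrop(cseq[::-1], rseq[::-1])
        overlap = max(0, xl + xr - len(rseq))   # flanks meet/overlap on the ref
        tlen = len(rseq) - xl - xr + overlap
        q_lo = xl - overlap                     # leftmost equivalent placement
        qlen = len(cseq) - xr - q_lo
        if qlen - tlen < min_len or tlen > max_ref_gap or qlen <= 0:
            continue
        start = ck + q_lo + 1                   # 1-based in carrier
        end = start + qlen - 1
        ref_after = rk + xl - overlap           # after this 1-based ref pos
        ref_deleted = reference.seq[ref_after:ref_after + tlen]
        n_shift = 0
        if tlen == 0:
            start, end, n_shift = left_normalize(carrier.seq, start, end)
            ref_after -= n_shift
        host = next((f for f in carrier.cds_features()
                     if f.start <= start and end <= f.end), None)
        flank = _exact_flank(carrier.seq, reference.seq, start, end,
                             ref_after, ref_deleted)
        calls.append(InsertionCall(
            carrier.id, reference.id, start, end,
            host.gene_number if host else None, flank, "unclassified",
            {"ref_after": ref_after, "ref_deleted_seq": ref_deleted,
             "left_shifts": n_shift, "tsd_overlap": overlap}))
    return calls


def _exact_flank(cseq: str, rseq: str, start: int, end: int,
                 ref_after: int, ref_deleted: str, cap: int = 200) -> int:
    """Minimum exact-match run on the two sides of the junction."""
    left = 0
    ra = ref_after
    while (left < cap and start - 2 - left >= 0 and ra - 1 - left >= 0
           and cseq[start - 2 - left] == rseq[ra - 1 - left]):
        left += 1
    right = 0
    rb = ref_after + len(ref_deleted)
    while (right < cap and end + right < len(cseq) and rb + right < len(rseq)
           and cseq[end + right] == rseq[rb + right]):
        right += 1
    return max(1, min(left, right))


def excised_sequence(carrier: GenomeRecord, call: InsertionCall) -> str:
    """Carrier sequence with the called element removed and any logged
    target deletion re-inserted: the reconstructed pre-insertion state."""
    deleted = call.evidence.get("ref_deleted_seq", "")
    return carrier.seq[:call.start - 1] + deleted + carrier.seq[call.end:]


# ---------------------------------------------------------------------------
# splice restoration

def _reference_homolog(carrier_protein: str, reference: GenomeRecord,
                       min_identity: float = 0.4
                       ) -> Optional[tuple[GeneFeature, str, float]]:
    best = None
    for f in reference.cds_features():
        prot = f.translation or translate_cds(
            extract_gene_dna(reference, f), initiator=True)
        prot = prot.rstrip("*")
        if not prot or min(len(prot), len(carrier_protein)) \
                < 0.25 * max(len(prot), len(carrier_protein)):
            continue
        ident = global_align_aa(carrier_protein, prot).identity
        if best is None or ident > best[2]:
            best = (f, prot, ident)
    if best is None or best[2] < min_identity:
        return None
    return best


def test_splice_restoration(call: InsertionCall, carrier: GenomeRecord,
                            reference: GenomeRecord, search: int = 10,
                            min_ref_identity: float = 0.4) -> SpliceHypothesis:
    """Test whether excising the called segment restores the interrupted gene.

    Candidate excisions shift both boundaries within ±``search`` bp of the
    call (in-frame fusions only); each is excised, the fused gene translated,
    and compared with the best reference homolog.  The excision maximising
    restored identity wins, with ties broken by (a) both group I hallmarks
    present (exon 1 ending T, intron ending G on the coding strand),
    (b) exact protein-length match, (c) leftmost boundaries.  A fusion with
    an internal stop codon scores zero identity.
    """
    if call.host_gene is None:
        raise ValueError("splice testing needs a call inside an annotated CDS")
    f = carrier.feature_by_number(call.host_gene)
    g = extract_gene_dna(carrier, f)
    if f.strand == "+":
        os0, oe0 = call.start - f.start + 1, call.end - f.start + 1
    else:
        os0, oe0 = f.end - call.end + 1, f.end - call.start + 1

    def no_splice(marker: str) -> SpliceHypothesis:
        return SpliceHypothesis(os0 - 1, os0, oe0, oe0 + 1, 0, 0, 0.0,
                                g[os0 - 2] if os0 >= 2 else "N",
                                g[oe0 - 1],
                                (os0 >= 2 and g[os0 - 2] == "T",
                                 g[oe0 - 1] == "G"), marker)

    excised0 = g[:os0 - 1] + g[oe0:]
    probe = translate_cds(excised0, initiator=True) if len(excised0) >= 3 else ""
    hom = _reference_homolog(probe, reference, min_ref_identity)
    if hom is None:
        return no_splice("no_reference_homolog")
    _, ref_prot, _ = hom

    best = None
    for i in range(-search, search + 1):
        os = os0 + i
        if os < 2:
            continue
        for j in range(-search, search + 1):
            oe = oe0 + j
            if oe < os or oe >= len(g):
                continue
            if (len(g) - (oe - os + 1)) % 3 != 0:
                continue
            fused = g[:os - 1] + g[oe:]
            prot = translate_cds(fused, initiator=True)
            full = len(fused) // 3
            if len(prot) < full - 1:       # internal stop: not a viable fusion
                continue
            aln = global_align_aa(prot, ref_prot)
            # identical pairs over the reference length: over-excised fusions
            # must not gain from shrinking the min-length denominator
            ident = aln.identity * min(len(prot), len(ref_prot)) / len(ref_prot)
            flags = (g[os - 2] == "T", g[oe - 1] == "G")
            key = (-ident, not (flags[0] and flags[1]),
                   len(prot) != len(ref_prot), os, oe)
            if best is None or key < best[0]:
                best = (key, os, oe, prot, ident, flags)
    if best is None:
        return no_splice("no_viable_splice")
    _, os, oe, prot, ident, flags = best
    return SpliceHypothesis(
        exon1_end=os - 1, intron_start=os, intron_end=oe, exon2_start=oe + 1,
        restored_protein_len=len(prot), reference_protein_len=len(ref_prot),
        restored_identity=ident, exon1_3prime_base=g[os - 2],
        intron_3prime_base=g[oe - 1], group_I_flags=flags)


# ---------------------------------------------------------------------------
# ORFs, inteins, TSDs

@dataclass
class OrfHit:
    strand: str
    start: int      # 1-based inclusive, forward-strand coordinates of segment
    end: int        # includes the stop codon
    protein: str
    has_laglidadg: bool


def find_internal_orfs(segment: str, min_aa: int = 50) -> list[OrfHit]:
    """All ORFs (ATG/GTG/TTG start to in-frame stop) of >= min_aa codons on
    both strands of a segment; one ORF per stop (the longest), each flagged
    for the literal LAGLIDADG homing-endonuclease motif."""
    hits: list[OrfHit] = []
    n = len(segment)
    for strand, s in (("+", segment), ("-", revcomp(segment))):
        for frame in range(3):
            start_at: Optional[int] = None
            for p in range(frame, n - 2, 3):
                codon = s[p:p + 3]
                if codon in STOP_CODONS:
                    if start_at is not None and (p - start_at) // 3 >= min_aa:
                        prot = translate_cds(s[start_at:p], initiator=True)
                        if strand == "+":
                            lo, hi = start_at + 1, p + 3
                        else:
                            lo, hi = n - (p + 3) + 1, n - start_at
                        hits.append(OrfHit(strand, lo, hi, prot,
                                           "LAGLIDADG" in prot))
                    start_at = None
                elif start_at is None and codon in START_CODONS:
                    start_at = p
    return sorted(hits, key=lambda h: (h.start, h.strand))


def detect_intein(carrier_protein: str, reference_protein: str,
                  min_len: int = 100,
                  host: tuple[str, str] = ("", "")) -> Optional[InteinCall]:
    """Protein-level test for an in-frame intervening domain: the longest
    internal run of >= min_len carrier residues aligned to gaps in the
    reference, with extein identities measured on the flanking blocks."""
    if not carrier_protein or not reference_protein:
        raise ValueError("empty protein")
    from .pairwise_align import _aligner, _identity_from_blocks
    aln = _aligner("aa", "global").align(carrier_protein, reference_protein)[0]
    tb, qb = aln.aligned
    best = None
    for m in range(len(tb) - 1):
        c_adv = tb[m + 1][0] - tb[m][1]
        r_adv = qb[m + 1][0] - qb[m][1]
        if r_adv == 0 and c_adv >= min_len:
            if best is None or c_adv > best[1]:
                best = (m, c_adv)
    if best is None:
        return None
    m, c_adv = best
    left_blocks = ([tuple(x) for x in tb[:m + 1]], [tuple(x) for x in qb[:m + 1]])
    right_blocks = ([tuple(x) for x in tb[m + 1:]], [tuple(x) for x in qb[m + 1:]])
    id1, c1 = _identity_from_blocks(carrier_protein, reference_protein, left_blocks)
    id2, c2 = _identity_from_blocks(carrier_protein, reference_protein, right_blocks)
    return InteinCall(
        host_protein=host,
        insertion_aa_start=int(tb[m][1]) + 1,
        insertion_aa_end=int(tb[m + 1][0]),
        intein_len=c_adv,
        extein1_identity=id1 / c1 if c1 else 0.0,
        extein2_identity=id2 / c2 if c2 else 0.0)


def detect_tsd(call: InsertionCall, carrier: GenomeRecord,
               reference: Optional[GenomeRecord] = None,
               max_tsd: int = 15) -> TsdCall:
    """Reconstruct a target-site duplication around an insertion call.

    For d from ``max_tsd`` down to 1, over excision placements shifted within
    ±max_tsd of the call, accept the largest d such that (i) excising the
    shifted interval leaves the same sequence as excising the call — i.e. the
    placement is an equivalent description of the same insertion event, so
    the reference necessarily holds exactly one copy of the repeat at the
    target — and (ii) the first d excised bases equal the d bases that follow
    the excision: the element is then flanked by two identical copies in the
    carrier.  d = 0 means a precise insertion.  All equally maximal
    placements are reported; the primary call is the leftmost.
    """
    seq = carrier.seq
    L = call.length
    w = 60
    a = max(0, call.start - 1 - max_tsd - w)
    b = min(len(seq), call.end + max_tsd + w)

    def excision(x: int) -> Optional[str]:
        if x - 1 < a or x + L - 1 > b:
            return None
        return seq[a:x - 1] + seq[x + L - 1:b]

    base = excision(call.start)
    found: list[tuple[int, int]] = []   # (x, d)
    for d in range(min(max_tsd, L - 1), 0, -1):
        for x in range(call.start - max_tsd, call.start + max_tsd + 1):
            if x < d + 1:
                continue
            if seq[x - 1:x - 1 + d] != seq[x + L - 1:x + L - 1 + d]:
                continue
            if excision(x) != base:
                continue
            found.append((x, d))
        if found:
            break
    if not found:
        return TsdCall("", 0, call.start, call.end,
                       alternatives=[(call.start, call.end)])
    found.sort()
    x, d = found[0]
    return TsdCall(seq[x - 1:x - 1 + d], d, x + d, x + L - 1,
                   alternatives=[(xx + dd, xx + L - 1) for xx, dd in found])


def reconstruct_target(call: InsertionCall, carrier: GenomeRecord,
                       reference: GenomeRecord) -> TargetReconstruction:
    """Was the element's arrival precise, or did it delete target sequence?

    Precise iff the reference junction is the carrier's left flank joined
    directly to its right flank; otherwise the reference bases missing from
    the carrier are reported.  Junctions inside repeats are flagged ambiguous
    and the leftmost reconstruction returned.
    """
    deleted = call.evidence.get("ref_deleted_seq", "")
    ambiguous = bool(call.evidence.get("left_shifts", 0))
    if not deleted:
        return TargetReconstruction("precise", ambiguous=ambiguous)
    return TargetReconstruction("deletion_associated", len(deleted), deleted,
                                ambiguous=ambiguous)


# ---------------------------------------------------------------------------
# classification and orchestration

@dataclass
class ElementReport:
    call: InsertionCall
    splice: Optional[SpliceHypothesis] = None
    intein: Optional[InteinCall] = None
    tsd: Optional[TsdCall] = None
    orfs: list[OrfHit] = field(default_factory=list)
    reconstruction: Optional[TargetReconstruction] = None


def classify_insertion(call: InsertionCall,
                       splice: Optional[SpliceHypothesis] = None,
                       tsd: Optional[TsdCall] = None,
                       orfs: list[OrfHit] = (),
                       intein: Optional[InteinCall] = None,
                       min_restored_identity: float = 0.8,
                       length_match_tol: int = 10) -> str:
    """Precedence: intein > intron > transposon > endonuclease > unclassified.

    The protein-level test outranks the DNA-splice test because an in-frame
    intein also excises cleanly at the DNA level, while a true intron never
    lets the interrupted gene read through in frame — so the intein test
    cannot fire on one.  An intron must additionally show both group I
    hallmarks (exon 1 ending T, intron ending G on the coding strand).
    """
    max_orf = max((len(o.protein) for o in orfs), default=0)
    if intein is not None:
        return "intein"
    if (call.host_gene is not None and splice is not None
            and splice.restored_identity >= min_restored_identity
            and abs(splice.restored_protein_len - splice.reference_protein_len)
            <= length_match_tol
            and splice.group_I_flags == (True, True)):
        return "intron"
    if tsd is not None and tsd.tsd_len >= 2 and max_orf >= 200:
        return "transposon"
    if call.host_gene is None and max_orf >= 100 \
            and (tsd is None or tsd.tsd_len < 2):
        return "endonuclease"
    return "unclassified"


def analyze_insertion(call: InsertionCall, carrier: GenomeRecord,
                      reference: GenomeRecord) -> ElementReport:
    """Run the full evidence battery on one call and classify it."""
    segment = carrier.seq[call.start - 1:call.end]
    report = ElementReport(call)
    if len(segment) >= 150:
        report.orfs = find_internal_orfs(segment)
    report.tsd = detect_tsd(call, carrier, reference)
    if call.host_gene is not None:
        report.splice = test_splice_restoration(call, carrier, reference)
        f = carrier.feature_by_number(call.host_gene)
        gdna = extract_gene_dna(carrier, f)
        prot = translate_cds(gdna, initiator=True)
        if len(prot) >= (len(gdna) // 3) - 1:   # reads through: in-frame element
            hom = _reference_homolog(prot, reference)
            if hom is not None:
                report.intein = detect_intein(prot, hom[1],
                                              host=(carrier.id, f.gene_number))
    report.reconstruction = reconstruct_target(call, carrier, reference)
    call.type = classify_insertion(call, report.splice, report.tsd,
                                   report.orfs, report.intein)
    return report


def scan_pair(carrier: GenomeRecord, reference: GenomeRecord,
              min_len: int = 50) -> list[ElementReport]:
    """find_insertions + full analysis for every call of a genome pair."""
    return [analyze_insertion(c, carrier, reference)
            for c in find_insertions(carrier, reference, min_len=min_len)]


def consensus_scan(carrier: GenomeRecord, references: list[GenomeRecord],
                   min_len: int = 50) -> list[ElementReport]:
    """Insertion discovery against several references with boundary voting.

    A boundary next to a reference-private substitution is ambiguous in that
    one pair but sequence-determined in every reference lacking the
    mutation, so the modal (start, end, target-deletion) triple across
    references recovers the true junctions.  Calls are grouped by interval
    overlap; each group's modal boundaries win (ties fall to the earliest
    reference in the given order, so put the closest relative first), and
    the full evidence battery runs against a reference that voted for them.
    """
    per_ref: list[tuple[GenomeRecord, list[InsertionCall]]] = [
        (ref, find_insertions(carrier, ref, min_len=min_len))
        for ref in references]
    groups: list[list[tuple[int, GenomeRecord, InsertionCall]]] = []
    for ri, (ref, calls) in enumerate(per_ref):
        for call in calls:
            for grp in groups:
                if any(c.start <= call.end and call.start <= c.end
                       for _, _, c in grp):
                    grp.append((ri, ref, call))
                    break
            else:
                groups.append([(ri, ref, call)])
    reports = []
    for grp in sorted(groups, key=lambda g: min(c.start for _, _, c in g)):
        votes: dict[tuple[int, int, str], list[int]] = {}
        for ri, _, c in grp:
            key = (c.start, c.end, c.evidence.get("ref_deleted_seq", ""))
            votes.setdefault(key, []).append(ri)
        key = min(votes, key=lambda k: (-len(votes[k]), min(votes[k])))
        ri = min(votes[key])
        ref, call = per_ref[ri][0], next(
            c for r, _, c in grp
            if r == ri and (c.start, c.end,
                            c.evidence.get("ref_deleted_seq", "")) == key)
        reports.append(analyze_insertion(call, carrier, ref))
    return reports


def write_calls_bed(calls: list[InsertionCall], path) -> None:
    """BED output for insertion calls; the 1-based inclusive coordinates are
    converted to 0-based half-open here, at the writer boundary only."""
    with open(path, "w") as fh:
        for c in calls:
            fh.write(f"{c.carrier}\t{c.start - 1}\t{c.end}\t"
                     f"{c.type}:vs:{c.reference}\n")


# ---------------------------------------------------------------------------
# in-silico PCR

@dataclass
class PcrResult:
    product_len: Optional[int]
    spliced_len: Optional[int]
    forward_sites: int
    reverse_sites: int
    ambiguous: bool


def _primer_sites(genome_seq: str, primer: str, max_mismatch: int,
                  exact_3prime: int, is_forward: bool) -> list[int]:
    """0-based start positions of annealing sites on the forward strand.

    Forward primers match the + strand as written (3' end rightmost);
    reverse primers are searched as their reverse complement (3' end
    leftmost on the forward strand)."""
    probe = primer if is_forward else revcomp(primer)
    seed = probe[-exact_3prime:] if is_forward else probe[:exact_3prime]
    hits = []
    at = genome_seq.find(seed)
    while at != -1:
        start = at - (len(probe) - exact_3prime) if is_forward else at
        if 0 <= start <= len(genome_seq) - len(probe):
            site = genome_seq[start:start + len(probe)]
            if sum(1 for x, y in zip(site, probe) if x != y) <= max_mismatch:
                hits.append(start)
        at = genome_seq.find(seed, at + 1)
    return hits


def insilico_pcr(genome: GenomeRecord, primer_f: str, primer_r: str,
                 spliced_coords: Optional[tuple[int, int]] = None,
                 max_mismatch: int = 2, exact_3prime: int = 5) -> PcrResult:
    """Predicted PCR product size(s) between a primer pair.

    Product length runs between the two primers' 5' ends, inclusive.  When
    ``spliced_coords`` (the excised intron) lies between the primers, the
    length of the spliced template's product is also reported — the size
    difference equals the intron length.  Zero or multiple sites for either
    primer is reported as ambiguous.
    """
    if len(primer_f) < 15 or len(primer_r) < 15:
        raise ValueError("primers must be >= 15 bp")
    fsites = _primer_sites(genome.seq, primer_f, max_mismatch, exact_3prime, True)
    rsites = _primer_sites(genome.seq, primer_r, max_mismatch, exact_3prime, False)
    if len(fsites) != 1 or len(rsites) != 1:
        return PcrResult(None, None, len(fsites), len(rsites), True)
    f5 = fsites[0] + 1                        # forward primer 5' end, 1-based
    r5 = rsites[0] + len(primer_r)            # reverse primer 5' end, 1-based
    if r5 <= f5:
        return PcrResult(None, None, 1, 1, True)
    product = r5 - f5 + 1
    spliced = None
    if spliced_coords is not None:
        lo, hi = spliced_coords
        if f5 < lo and hi < r5:
            spliced = product - interval_length(lo, hi)
    return PcrResult(product, spliced, 1, 1, False)
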