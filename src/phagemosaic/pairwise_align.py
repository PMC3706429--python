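"""Alignment primitives: global/local alignment, fragment ANI, dotplots, LCS.

Scoring conventions
-------------------
Protein alignments use BLOSUM62 with affine gaps in the BLAST convention: a
gap of length L costs ``open + L * extend`` with open=11, extend=1.
Nucleotide local alignments use match +2 / mismatch -3, gap open 5, extend 2.
E-values follow Karlin-Altschul, E = K * m * n * exp(-lambda * S), with fixed
constants (nt: lambda=1.28, K=0.46; aa, gapped BLOSUM62-11-1: lambda=0.267,
K=0.041) rather than estimated ones: the thresholds this package applies are
so extreme (1e-50) that constant choice cannot flip a classification outside
a negligible boundary band.

ANI dialect
-----------
The fragment-based ANI cuts the query genome into consecutive non-overlapping
1 kb fragments, maps each to the subject with edlib (infix mode, both
strands), takes each fragment's best-scoring aligned sub-segment (a local
high-scoring pair), retains fragments covering >= 70% of their length at
>= 70% identity, and averages retained identities; the reported ANI is the
mean of the two directions, which makes it exactly symmetric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import edlib
from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import GenomeRecord, revcomp

# Karlin-Altschul constants (fixed, see module docstring)
NT_LAMBDA, NT_K = 1.28, 0.46
AA_LAMBDA, AA_K = 0.267, 0.041


@dataclass
class AlignmentResult:
    identity: float
    aligned_cols: int
    score: float
    evalue: float
    coords: Optional[tuple[tuple[int, int], tuple[int, int]]] = None  # 1-based inclusive


@dataclass
class AniResult:
    ani: float
    fraction_aligned: tuple[float, float]
    n_fragments: tuple[int, int]
    per_direction: tuple[float, float]


@lru_cache(maxsize=None)
def _aligner(kind: str, mode: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = mode
    if kind == "aa":
        al.substitution_matrix = substitution_matrices.load("BLOSUM62")
        # BLAST 11/1: gap of length L costs 11 + L (end gaps scored like internal)
        al.open_gap_score = -12.0
        al.extend_gap_score = -1.0
    else:
        al.match_score = 2.0
        al.mismatch_score = -3.0
        # gap of length L costs 5 + 2L
        al.open_gap_score = -7.0
        al.extend_gap_score = -2.0
    return al


def _identity_from_blocks(a: str, b: str, blocks) -> tuple[int, int]:
    """(#identical pairs, #aligned columns) over the aligned block list."""
    ident = cols = 0
    for (a0, a1), (b0, b1) in zip(blocks[0], blocks[1]):
        cols += a1 - a0
        ident += sum(1 for x, y in zip(a[a0:a1], b[b0:b1]) if x == y)
    return ident, cols


def global_align_aa(a: str, b: str) -> AlignmentResult:
    """Needleman-Wunsch on proteins; identity = identical pairs / min length.

    The shorter-sequence denominator makes the figure robust to terminal
    extensions and in-frame insertions (inteins): a protein carrying a large
    intervening domain still scores high identity to its intein-less homolog.
    """
    if not a or not b:
        raise ValueError("empty protein sequence")
    aligner = _aligner("aa", "global")
    alns = aligner.align(a, b)
    aln = alns[0]
    ident, cols = _identity_from_blocks(a, b, aln.aligned)
    return AlignmentResult(identity=ident / min(len(a), len(b)),
                           aligned_cols=max(cols, 1),
                           score=alns.score, evalue=math.inf)


def _local_align(a: str, b: str, kind: str, lam: float, k: float) -> AlignmentResult:
    if not a or not b:
        raise ValueError("empty sequence")
    aligner = _aligner(kind, "local")
    alns = aligner.align(a, b)
    score = alns.score
    if score <= 0:
        return AlignmentResult(0.0, 0, 0.0, math.inf, None)
    aln = alns[0]
    blocks = aln.aligned
    ident, cols = _identity_from_blocks(a, b, blocks)
    coords = ((int(blocks[0][0][0]) + 1, int(blocks[0][-1][1])),
              (int(blocks[1][0][0]) + 1, int(blocks[1][-1][1])))
    exponent = math.log(k) + math.log(len(a)) + math.log(len(b)) - lam * score
    evalue = math.exp(exponent) if exponent < 700 else math.inf
    return AlignmentResult(identity=ident / cols if cols else 0.0,
                           aligned_cols=cols, score=score, evalue=evalue,
                           coords=coords)


def local_align_nt(a: str, b: str) -> AlignmentResult:
    """Smith-Waterman on DNA (+2/-3, gap 5+2L) with a Karlin-Altschul E-value."""
    return _local_align(a, b, "nt", NT_LAMBDA, NT_K)


def local_align_aa(a: str, b: str) -> AlignmentResult:
    """Smith-Waterman on proteins (BLOSUM62, gap 11+L); the BlastP-like route."""
    return _local_align(a, b, "aa", AA_LAMBDA, AA_K)


def _cigar_columns(cigar: str):
    n = 0
    for ch in cigar:
        if ch.isdigit():
            n = n * 10 + int(ch)
        else:
            yield n, ch
            n = 0


def _best_hsp(cigar: str) -> tuple[float, float]:
    """(identity over aligned columns, query coverage) of the best-scoring
    contiguous sub-segment of an edlib alignment path (+2 match / -3
    mismatch or gap column), emulating a local high-scoring pair."""
    runs = list(_cigar_columns(cigar))
    best = cur = 0.0
    cur_stats = [0, 0, 0]          # matches, columns, query bases
    best_stats = (0, 0, 0)
    for n, op in runs:
        score = 2 * n if op == "=" else -3 * n
        if cur <= 0 < score:
            cur = 0.0
            cur_stats = [0, 0, 0]
        cur += score
        cur_stats[0] += n if op == "=" else 0
        cur_stats[1] += n
        cur_stats[2] += n if op in ("=", "X", "I") else 0
        if cur > best:
            best = cur
            best_stats = tuple(cur_stats)
    m, cols, qbases = best_stats
    if cols == 0:
        return 0.0, 0.0
    return m / cols, qbases


def _fragment_identity(frag: str, subject: str, subject_rc: str
                       ) -> tuple[float, float]:
    """(identity, coverage) of the fragment's best match in the subject."""
    best = None
    for target in (subject, subject_rc):
        r = edlib.align(frag, target, mode="HW", task="path")
        if r["editDistance"] == -1:
            continue
        ident, qbases = _best_hsp(r["cigar"])
        cov = qbases / len(frag)
        if best is None or ident * cov > best[0] * best[1]:
            best = (ident, cov)
    return best if best is not None else (0.0, 0.0)


def _ani_direction(query: GenomeRecord, subject: GenomeRecord,
                   fragment: int, min_identity: float) -> tuple[float, float, int]:
    frags = [query.seq[i:i + fragment]
             for i in range(0, len(query.seq) - fragment + 1, fragment)]
    subject_rc = revcomp(subject.seq)
    kept = []
    for frag in frags:
        ident, cov = _fragment_identity(frag, subject.seq, subject_rc)
        if ident >= min_identity and cov >= min_identity:
            kept.append(ident)
    mean = sum(kept) / len(kept) if kept else 0.0
    return mean, (len(kept) / len(frags) if frags else 0.0), len(frags)


def ani(a: GenomeRecord, b: GenomeRecord, fragment: int = 1000,
        min_identity: float = 0.70) -> AniResult:
    """Fragment-based average nucleotide identity (bidirectional mean)."""
    if len(a.seq) < 2 * fragment or len(b.seq) < 2 * fragment:
        raise ValueError("genomes must be at least twice the fragment length")
    ab, frac_ab, n_ab = _ani_direction(a, b, fragment, min_identity)
    ba, frac_ba, n_ba = _ani_direction(b, a, fragment, min_identity)
    return AniResult(ani=(ab + ba) / 2.0, fraction_aligned=(frac_ab, frac_ba),
                     n_fragments=(n_ab, n_ba), per_direction=(ab, ba))


def ani_matrix(genomes: list[GenomeRecord], fragment: int = 1000) -> dict:
    """Pairwise ANI for a genome set, keyed by (id_i, id_j)."""
    out = {}
    for i, gi in enumerate(genomes):
        for gj in genomes[i + 1:]:
            r = ani(gi, gj, fragment=fragment)
            out[(gi.id, gj.id)] = r
            out[(gj.id, gi.id)] = r
    return out


def dotplot_matches(a: str, b: str, k: int) -> list[tuple[int, int, str]]:
    """All exact k-mer matches between a and b, both strands, 1-based.

    A '-' match at (i, j) means a[i..i+k-1] equals the reverse complement of
    b[j..j+k-1]; j is the leftmost coordinate on b's forward strand.
    """
    if k < 8:
        raise ValueError("word size must be >= 8")
    index: dict[str, list[int]] = {}
    for j in range(len(b) - k + 1):
        index.setdefault(b[j:j + k], []).append(j + 1)
    out: list[tuple[int, int, str]] = []
    for i in range(len(a) - k + 1):
        kmer = a[i:i + k]
        for j in index.get(kmer, ()):
            out.append((i + 1, j, "+"))
        for j in index.get(revcomp(kmer), ()):
            out.append((i + 1, j, "-"))
    return out


def _common_substring_at(a: str, b: str, length: int) -> Optional[tuple[int, int]]:
    """Smallest (posA0, posB0) of a common substring of given length, else None."""
    if length == 0 or length > len(a) or length > len(b):
        return None
    base, mod = 1114111, (1 << 61) - 1
    power = pow(base, length - 1, mod)

    def hashes(s: str):
        h = 0
        for i, ch in enumerate(s):
            h = (h * base + ord(ch)) % mod
            if i >= length:
                h = (h - ord(s[i - length]) * power * base) % mod
            if i >= length - 1:
                yield i - length + 1, h

    table: dict[int, int] = {}
    for j, h in hashes(b):
        table.setdefault(h, j)  # keep smallest posB
    hits = []
    for i, h in hashes(a):
        j = table.get(h)
        if j is not None and a[i:i + length] == b[j:j + length]:
            return i, j
        if j is not None:
            hits.append(i)  # hash collision; extremely rare
    for i in hits:
        sub = a[i:i + length]
        j = b.find(sub)
        if j != -1:
            return i, j
    return None


def _lcs_forward(a: str, b: str) -> tuple[int, int, int]:
    """(length, posA0, posB0) of the longest common substring of a and b."""
    lo, hi = 0, min(len(a), len(b))
    best = (0, 0, 0)
    while lo < hi:
        mid = (lo + hi + 1) // 2
        hit = _common_substring_at(a, b, mid)
        if hit is not None:
            best = (mid, hit[0], hit[1])
            lo = mid
        else:
            hi = mid - 1
    if best[0]:
        # re-resolve at the final length so posA is globally smallest
        i, j = _common_substring_at(a, b, best[0])
        best = (best[0], i, j)
    return best


def longest_common_substring(a: str, b: str, search_revcomp: bool = True
                             ) -> tuple[int, int, int, str]:
    """Maximal exact shared substring of a and b.

    Returns (length, posA, posB, strand), 1-based.  Ties prefer the smallest
    posA, then posB, and the + strand over -.  For a '-' hit, posB is the
    leftmost forward-strand coordinate on b of the matched segment.  A length
    of 0 means no common base.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    lf, ia, jb = _lcs_forward(a, b)
    best = (lf, ia + 1, jb + 1, "+")
    if search_revcomp:
        brc = revcomp(b)
        lr, ra, rb = _lcs_forward(a, brc)
        if lr > lf:
            best = (lr, ra + 1, len(b) - (rb + lr) + 1, "-")
    if best[0] == 0:
        return (0, 0, 0, "+")
    return best
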