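"""attP/attB common-core discovery, arm-type repeats, and integration design.

Temperate phages of this kind integrate by site-specific recombination
between a phage attachment site (attP) and a bacterial site (attB) sharing
an identical common core, typically 40-50 bp, frequently overlapping a host
tRNA gene so integration regenerates an intact tRNA.  The core lies just
downstream of the integrase gene (int), flanked by pairs of short degenerate
arm-type integrase binding sites (P1/P2 left, P3/P4 right).  Recombination
produces the hybrid junctions attL and attR.

The arm-type consensus used here is the 10-mer 5'-TGCATACg/tPuPy: positions
2,3 (GC) and 5,6,7 (TAC) are mandatory; positions 1 (T), 4 (A), 8 (G/T),
9 (A/G), 10 (C/T) are scored, with a configurable mismatch budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .genome_io import GeneFeature, GenomeRecord, revcomp
from .pairwise_align import longest_common_substring

# position (1-based) -> required base(s); MANDATORY must match exactly,
# SCORED positions count toward the mismatch budget.
ARM_MANDATORY = {2: "G", 3: "C", 5: "T", 6: "A", 7: "C"}
ARM_SCORED = {1: "T", 4: "A", 8: "GT", 9: "AG", 10: "CT"}
ARM_LEN = 10


@dataclass
class ArmSite:
    name: str  # P1..P4 or "other"
    start: int
    end: int
    orientation: str  # direct | inverted
    mismatches: int
    seq: str


@dataclass
class AttSite:
    core_seq: str
    phage_interval: tuple[int, int]
    host_interval: tuple[int, int]
    strand: str
    trna_overlap: Optional[GeneFeature]
    distance_from_int_3prime: int
    arm_sites: list[ArmSite] = field(default_factory=list)
    found: bool = True
    best_length: int = 0


def arm_mismatches(tenmer: str) -> Optional[int]:
    """Mismatch count of a 10-mer vs the arm consensus, or None when a
    mandatory position fails."""
    if len(tenmer) != ARM_LEN:
        return None
    for pos, base in ARM_MANDATORY.items():
        if tenmer[pos - 1] != base:
            return None
    return sum(1 for pos, allowed in ARM_SCORED.items()
               if tenmer[pos - 1] not in allowed)


def sample_arm_site(rng) -> str:
    """Draw an exact-consensus 10-mer (degenerate positions sampled)."""
    out = []
    for pos in range(1, ARM_LEN + 1):
        if pos in ARM_MANDATORY:
            out.append(ARM_MANDATORY[pos])
        else:
            allowed = ARM_SCORED[pos]
            out.append(allowed[int(rng.integers(len(allowed)))])
    return "".join(out)


def scan_arm_sites(seq: str, region: Optional[tuple[int, int]] = None,
                   max_mismatch: int = 1,
                   core_interval: Optional[tuple[int, int]] = None) -> list[ArmSite]:
    """All arm-type consensus hits in a region, both orientations.

    When ``core_interval`` is given, direct-orientation hits left of the core
    are named P1/P2 and those right of it P3/P4, in left-to-right order
    (nearest-to-core last on the left side); everything else is "other".
    """
    lo, hi = region if region else (1, len(seq))
    if lo < 1 or hi > len(seq) or hi < lo:
        raise ValueError(f"region {lo}..{hi} out of bounds")
    hits: list[ArmSite] = []
    for start in range(lo, hi - ARM_LEN + 2):
        window = seq[start - 1:start - 1 + ARM_LEN]
        mm = arm_mismatches(window)
        if mm is not None and mm <= max_mismatch:
            hits.append(ArmSite("other", start, start + ARM_LEN - 1, "direct", mm, window))
        mm = arm_mismatches(revcomp(window))
        if mm is not None and mm <= max_mismatch:
            hits.append(ArmSite("other", start, start + ARM_LEN - 1, "inverted", mm, window))
    if core_interval is not None:
        # the two nearest hits on each side of the core, in left-to-right
        # order, regardless of orientation (a reverse-strand cassette
        # carries its arms in inverted orientation)
        cs, ce = core_interval
        left = sorted((h for h in hits if h.end < cs), key=lambda h: h.start)
        right = sorted((h for h in hits if h.start > ce), key=lambda h: h.start)
        for i, h in enumerate(left[-2:]):
            h.name = f"P{i + 1}"
        for i, h in enumerate(right[:2]):
            h.name = f"P{i + 3}"
    return sorted(hits, key=lambda h: (h.start, h.orientation))


def _int_3prime(int_gene: GeneFeature) -> tuple[int, int]:
    """(coordinate of the 3' end, +1/-1 downstream direction)."""
    return (int_gene.end, +1) if int_gene.strand == "+" else (int_gene.start, -1)


def find_att_core(phage: GenomeRecord, host: GenomeRecord, int_gene: GeneFeature,
                  window: int = 1000, min_core: int = 25,
                  max_mismatch: int = 1) -> AttSite:
    """Locate the attP/attB common core: the longest exact substring shared
    between the region downstream of int and the host chromosome.

    tRNA overlap on the host is reported when present but never required.
    """
    end3, step = _int_3prime(int_gene)
    if step > 0:
        w_lo, w_hi = end3 + 1, min(len(phage.seq), end3 + window)
        wseq = phage.seq[w_lo - 1:w_hi]
    else:
        w_lo, w_hi = max(1, end3 - window), end3 - 1
        wseq = revcomp(phage.seq[w_lo - 1:w_hi])
    length, pos_w, pos_h, strand = longest_common_substring(wseq, host.seq, True)
    if length < min_core:
        return AttSite("", (0, 0), (0, 0), "+", None, 0, [], found=False,
                       best_length=length)
    if step > 0:
        p_lo = w_lo + pos_w - 1
    else:  # window was reverse-complemented; map back to genome coordinates
        p_lo = w_hi - (pos_w - 1) - length + 1
    p_hi = p_lo + length - 1
    h_lo, h_hi = pos_h, pos_h + length - 1
    core = wseq[pos_w - 1:pos_w - 1 + length]
    trna = next((f for f in host.features
                 if f.kind == "tRNA" and f.start <= h_hi and f.end >= h_lo), None)
    dist = (p_lo - end3) if step > 0 else (end3 - p_hi)
    scan_lo = max(1, p_lo - 200)
    scan_hi = min(len(phage.seq), p_hi + 200)
    arms = scan_arm_sites(phage.seq, (scan_lo, scan_hi), max_mismatch,
                          core_interval=(p_lo, p_hi))
    return AttSite(core, (p_lo, p_hi), (h_lo, h_hi), strand, trna, dist, arms)


def predict_attL_attR(phage: GenomeRecord, host: GenomeRecord, site: AttSite,
                      context: int = 200) -> tuple[str, str, bool]:
    """Hybrid junction sequences after integration.

    attL = host-upstream + core + phage-downstream-of-core;
    attR = phage-upstream-of-core + core + host-downstream.
    Returns (attL, attR, truncated); truncated is set when a core sits closer
    than ``context`` to a sequence end.
    """
    if not site.found:
        raise ValueError("no att site to build junctions from")
    (p_lo, p_hi), (h_lo, h_hi) = site.phage_interval, site.host_interval
    hseq = host.seq
    if site.strand == "-":
        hseq = revcomp(hseq)
        h_lo, h_hi = len(hseq) - h_hi + 1, len(hseq) - h_lo + 1
    core = site.core_seq
    host_up = hseq[max(0, h_lo - 1 - context):h_lo - 1]
    host_down = hseq[h_hi:h_hi + context]
    phage_up = phage.seq[max(0, p_lo - 1 - context):p_lo - 1]
    phage_down = phage.seq[p_hi:p_hi + context]
    truncated = any(len(s) < context for s in (host_up, host_down, phage_up, phage_down))
    return host_up + core + phage_down, phage_up + core + host_down, truncated


def simulate_integration(phage: GenomeRecord, host: GenomeRecord,
                         site: AttSite) -> str:
    """Prophage chromosome from core-to-core crossover of the circularised
    phage into the host attB (host orientation; + strand sites)."""
    if not site.found:
        raise ValueError("no att site")
    if site.strand != "+":
        raise ValueError("simulate_integration expects a +-strand core")
    (p_lo, p_hi), (h_lo, h_hi) = site.phage_interval, site.host_interval
    return (host.seq[:h_hi]                  # host left arm + core (attL core copy)
            + phage.seq[p_hi:]               # phage downstream of attP core
            + phage.seq[:p_hi]               # around the circle back through the core
            + host.seq[h_hi:])               # host right arm


def design_integration_fragment(phage: GenomeRecord, int_gene: GeneFeature,
                                site: AttSite, margin: int = 300) -> tuple[int, int]:
    """Inclusive interval covering int plus the att core with margins, clamped
    to the genome; the shape of an integration-vector insert."""
    lo = min(int_gene.start, site.phage_interval[0]) - margin
    hi = max(int_gene.end, site.phage_interval[1]) + margin
    return max(1, lo), min(len(phage.seq), hi)
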