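"""Synthetic phage-genome cohorts with planted mobile elements and a truth log.

The generator emulates the study system this package targets: sets of ~110 kb
temperate phage genomes at ~61% GC deriving from one ancestor by point
substitutions and small indels (pairwise identities tunable across the
0.79-0.97 range), carrying planted group-I-style introns (T|...G splice
hallmarks, optional internal reverse-strand LAGLIDADG ORF), in-frame protein
inteins, a transposon insertion flanked by a direct target-site duplication,
free-standing endonuclease gene insertions (precise or deletion-associated),
and a 44 bp attP/attB common core shared with a host chromosome inside a
tRNA gene, flanked by arm-type repeats.

Every planted event is recorded in a TruthLog whose replay on the ancestor
reproduces each final genome byte-for-byte; the log is the ground truth for
all recovery tests.  One root seed drives everything; per-genome and
per-operation RNG streams are derived from it with fixed offsets so adding an
element class does not perturb earlier draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .genome_io import GeneFeature, GenomeRecord, revcomp, translate_cds
from .integration_sites import ARM_LEN, sample_arm_site

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")

# codon ending in a non-G base for every amino acid (table 11), used when a
# planted in-frame element must not end with G (see plant(), intein notes)
_NONG_CODON = {
    "A": "GCA", "C": "TGC", "D": "GAC", "E": "GAA", "F": "TTC", "G": "GGA",
    "H": "CAC", "I": "ATC", "K": "AAA", "L": "CTC", "N": "AAC", "P": "CCA",
    "Q": "CAA", "R": "CGC", "S": "TCC", "T": "ACA", "V": "GTC", "W": "TGG",
    "Y": "TAC", "M": "ATG",
}
_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class EvolutionConfig:
    substitution_rate: float
    indel_rate: float = 0.0
    indel_size_geometric_p: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.substitution_rate, self.indel_rate):
            if not (0.0 <= r <= 0.5):
                raise ValueError("rates must lie in [0, 0.5]")
        if not (0.0 < self.indel_size_geometric_p <= 1.0):
            raise ValueError("indel_size_geometric_p must lie in (0, 1]")


@dataclass
class PlantSpec:
    kind: str  # intron | intein | transposon | endonuclease
    target: Optional[str] = None       # gene number, or None to auto-pick
    payload: object = None             # DNA, protein, or integer length
    options: dict = field(default_factory=dict)


@dataclass
class TruthEvent:
    kind: str
    genome: str
    start: int = 0     # 1-based inclusive coordinates in the final sequence
    end: int = 0
    payload: str = ""
    options: dict = field(default_factory=dict)


@dataclass
class TruthLog:
    events: list[TruthEvent] = field(default_factory=list)
    seed: int = 0
    scenario: str = ""
    meta: dict = field(default_factory=dict)

    def for_genome(self, genome_id: str, kinds: Optional[set[str]] = None
                   ) -> list[TruthEvent]:
        return [e for e in self.events if e.genome == genome_id
                and (kinds is None or e.kind in kinds)]

    def planted(self) -> list[TruthEvent]:
        return [e for e in self.events
                if e.kind in ("intron", "intein", "transposon", "endonuclease")]

    def planted_identity(self, a: str, b: str) -> float:
        """Expected per-site identity of two descendants: both unmutated, or
        both mutated to the same base (1/3 of coincident hits)."""
        ra = self.meta.get("substitution_rates", {}).get(a, 0.0)
        rb = self.meta.get("substitution_rates", {}).get(b, 0.0)
        return (1.0 - ra) * (1.0 - rb) + ra * rb / 3.0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"seed": self.seed, "scenario": self.scenario,
                       "meta": self.meta,
                       "events": [asdict(e) for e in self.events]}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthLog":
        with open(path) as fh:
            d = json.load(fh)
        return cls([TruthEvent(**e) for e in d["events"]], d["seed"],
                   d["scenario"], d["meta"])


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, seed])


def _rand_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    if n <= 0:
        return ""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _rand_codons(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """Stop-free random codons at the target GC."""
    out: list[str] = []
    while len(out) < n_codons:
        chunk = _rand_bases(rng, 3 * (n_codons - len(out) + 8), gc)
        out.extend(c for i in range(0, len(chunk) - 2, 3)
                   if (c := chunk[i:i + 3]) not in _STOPS)
    return "".join(out[:n_codons])


def _rand_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(_AA20[i] for i in rng.integers(0, len(_AA20), size=n))


def _codons_for(rng: np.random.Generator, aa: str, gc: float) -> str:
    """A coding sequence for a protein: random stop-free codons are drawn and
    the required residue substituted per position via a fixed codon table."""
    return "".join(_NONG_CODON[ch] for ch in aa)


def generate_ancestor(length: int, gc: float, gene_mean: int = 900,
                      seed: int = 0) -> GenomeRecord:
    """An ancestral genome: i.i.d. bases at the target GC organised as a grid
    of stop-free CDSs (size ~ Normal(gene_mean, gene_mean/5), floored to a
    codon multiple, min 150 bp) separated by 1-100 bp intergenic gaps, with
    genes laid out in alternating strand blocks.
    """
    if length < 1000:
        raise ValueError("length must be >= 1000")
    if not (0.0 < gc < 1.0):
        raise ValueError("gc must lie in (0, 1)")
    if gene_mean < 150:
        raise ValueError("gene_mean must be >= 150")
    rng = _rng(seed, 1)
    pieces: list[str] = []
    features: list[GeneFeature] = []
    pos = 0  # 0-based cursor
    gene_no = 0
    strand = "+"
    block_left = int(rng.integers(3, 8))
    lead = int(rng.integers(20, 80))
    pieces.append(_rand_bases(rng, lead, gc))
    pos += lead
    while True:
        glen = int(max(150, round(rng.normal(gene_mean, gene_mean / 5)) // 3 * 3))
        gap = int(rng.integers(1, 101))
        if pos + glen + gap > length - 60:
            break
        n_codons = glen // 3 - 2
        cds = "ATG" + _rand_codons(rng, n_codons, gc) + "TGA"
        gene_no += 1
        if strand == "-":
            cds = revcomp(cds)
        pieces.append(cds)
        features.append(GeneFeature(str(gene_no), pos + 1, pos + glen, strand))
        pos += glen
        pieces.append(_rand_bases(rng, gap, gc))
        pos += gap
        block_left -= 1
        if block_left == 0:
            strand = "-" if strand == "+" else "+"
            block_left = int(rng.integers(3, 8))
    pieces.append(_rand_bases(rng, length - pos, gc))
    return GenomeRecord("ancestor", "".join(pieces), features, "synthetic")


# ---------------------------------------------------------------------------
# sequence surgery with feature bookkeeping

def _insert(genome: GenomeRecord, after: int, segment: str,
            new_id: Optional[str] = None) -> GenomeRecord:
    """Insert ``segment`` after 1-based position ``after`` (0 = before start)."""
    if not (0 <= after <= len(genome.seq)):
        raise ValueError("insertion point out of bounds")
    seq = genome.seq[:after] + segment + genome.seq[after:]
    n = len(segment)
    feats = []
    for f in genome.features:
        if f.start > after:
            feats.append(f.shifted(n))
        elif f.end > after:  # insertion inside the feature
            feats.append(GeneFeature(f.gene_number, f.start, f.end + n,
                                     f.strand, f.kind, f.product, f.translation))
        else:
            feats.append(f)
    return GenomeRecord(new_id or genome.id, seq, feats, "synthetic")


def _delete(genome: GenomeRecord, start: int, end: int,
            new_id: Optional[str] = None) -> GenomeRecord:
    """Delete the 1-based inclusive interval [start, end]."""
    if not (1 <= start <= end <= len(genome.seq)):
        raise ValueError("deletion interval out of bounds")
    n = end - start + 1
    seq = genome.seq[:start - 1] + genome.seq[end:]
    feats = []
    for f in genome.features:
        if f.end < start:
            feats.append(f)
        elif f.start > end:
            feats.append(f.shifted(-n))
        elif f.start < start and f.end > end:  # deletion strictly inside
            feats.append(GeneFeature(f.gene_number, f.start, f.end - n,
                                     f.strand, f.kind, f.product, f.translation))
        else:
            raise ValueError(
                f"deletion {start}..{end} would truncate feature {f.gene_number}")
    return GenomeRecord(new_id or genome.id, seq, feats, "synthetic")


def _intergenic_ranges(genome: GenomeRecord, pad: int = 5) -> list[tuple[int, int]]:
    """1-based inclusive intervals lying in no feature, with a safety pad."""
    out = []
    cursor = 1
    for f in genome.features:
        if f.start - pad > cursor + pad:
            out.append((cursor + pad, f.start - pad - 1))
        cursor = max(cursor, f.end + 1)
    if len(genome.seq) - pad > cursor + pad:
        out.append((cursor + pad, len(genome.seq) - pad))
    return out


# ---------------------------------------------------------------------------
# evolution

def evolve(genome: GenomeRecord, config: EvolutionConfig,
           new_id: Optional[str] = None) -> tuple[GenomeRecord, TruthLog]:
    """Diverge a genome by per-site substitutions and small indels.

    Indels never land within 10 bp of a CDS terminus; inside a CDS they are
    rounded up to codon multiples so reading frames survive, and deletions
    never cross feature boundaries.  The truth log lists every event in
    replay order.
    """
    rng = _rng(config.seed, 2)
    gid = new_id or genome.id
    log = TruthLog(seed=config.seed)
    seq = bytearray(genome.seq.encode())
    # substitutions: per-site draws; inside a CDS a draw that would create an
    # internal stop codon (or break the start/stop codon) is redirected to
    # another base — nonsense changes never fix in functional genes, and the
    # substituted-site count (hence per-site identity) is preserved
    if config.substitution_rate > 0:
        import bisect
        feats = genome.features
        starts = [f.start for f in feats]
        idx = np.nonzero(rng.random(len(seq)) < config.substitution_rate)[0]
        draw = rng.integers(0, 3, size=idx.size)
        positions, bases = [], []
        order = b"ACGT"
        for i, d in zip(idx.tolist(), draw.tolist()):
            pos = i + 1
            cur = seq[i]
            alts = [b for b in order if b != cur]
            alts = alts[d % 3:] + alts[:d % 3]
            j = bisect.bisect_right(starts, pos) - 1
            f = feats[j] if 0 <= j and feats[j].start <= pos <= feats[j].end else None
            chosen = None
            if f is None or f.kind != "CDS":
                chosen = alts[0]
            else:
                if f.strand == "+":
                    ci = (pos - f.start) // 3
                    c0 = f.start + 3 * ci
                else:
                    ci = (f.end - pos) // 3
                    c0 = f.end - 3 * ci - 2
                n_codons = f.length // 3
                for cand in alts:
                    codon = bytes(seq[c0 - 1:c0 + 2])
                    k = pos - c0
                    codon = codon[:k] + bytes([cand]) + codon[k + 1:]
                    oriented = codon.decode()
                    if f.strand == "-":
                        oriented = revcomp(oriented)
                    if ci == n_codons - 1:
                        ok = oriented in _STOPS
                    elif ci == 0:
                        ok = oriented in ("ATG", "GTG", "TTG")
                    else:
                        ok = oriented not in _STOPS
                    if ok:
                        chosen = cand
                        break
            if chosen is not None:
                seq[i] = chosen
                positions.append(pos)
                bases.append(chr(chosen))
        if positions:
            log.events.append(TruthEvent(
                "substitutions", gid,
                options={"positions": positions, "bases": bases}))
    out = GenomeRecord(gid, seq.decode(), genome.features, "synthetic")
    # indels
    n_events = rng.poisson(config.indel_rate * len(out.seq)) if config.indel_rate else 0
    applied = []
    for _ in range(n_events):
        pos = int(rng.integers(1, len(out.seq) + 1))
        size = int(rng.geometric(config.indel_size_geometric_p))
        is_ins = bool(rng.random() < 0.5)
        host = next((f for f in out.features if f.start <= pos <= f.end), None)
        if host is not None:
            if host.kind != "CDS":
                continue
            if pos < host.start + 10 or pos > host.end - 10:
                continue
            size = -(-size // 3) * 3  # codon-preserving inside a CDS
            if not is_ins and pos + size - 1 > host.end - 10:
                continue
        elif not is_ins:
            nxt = next((f for f in out.features if f.start > pos), None)
            if nxt is not None and pos + size - 1 >= nxt.start - 5:
                continue
            if pos + size - 1 > len(out.seq):
                continue
        if is_ins:
            seg = _rand_bases(rng, size, 0.61)
            out = _insert(out, pos, seg)
            applied.append(TruthEvent("indel_insertion", gid, pos + 1, pos + size, seg))
        else:
            deleted = out.seq[pos - 1:pos + size - 1]
            out = _delete(out, pos, pos + size - 1)
            applied.append(TruthEvent("indel_deletion", gid, pos, pos + size - 1,
                                      deleted, {"deleted": deleted}))
    log.events.extend(applied)
    return out, log


def replay(ancestor: GenomeRecord, events: list[TruthEvent],
           genome_id: str) -> GenomeRecord:
    """Re-apply logged events in order; byte-identical to the generated genome."""
    g = GenomeRecord(genome_id, ancestor.seq, ancestor.features, "synthetic")
    for e in events:
        if e.genome != genome_id:
            continue
        if e.kind == "substitutions":
            seq = list(g.seq)
            for pos, base in zip(e.options["positions"], e.options["bases"]):
                seq[pos - 1] = base
            g = GenomeRecord(g.id, "".join(seq), g.features, "synthetic")
        elif e.kind == "indel_insertion":
            g = _insert(g, e.start - 1, e.payload)
        elif e.kind == "indel_deletion":
            g = _delete(g, e.start, e.start + len(e.payload) - 1)
        elif e.kind in ("intron", "intein", "transposon", "endonuclease"):
            if e.options.get("motif_overwrite"):
                pos, motif = e.options["motif_overwrite"]
                g = GenomeRecord(g.id, g.seq[:pos - 1] + motif
                                 + g.seq[pos - 1 + len(motif):], g.features,
                                 "synthetic")
            if e.options.get("deleted_target"):
                deleted = e.options["deleted_target"]
                g = _delete(g, e.start, e.start + len(deleted) - 1)
            g = _insert(g, e.start - 1, e.options["inserted_genomic"])
        elif e.kind == "att_core":
            seq = g.seq
            for (lo, hi), sub in zip(e.options["intervals"], e.options["written"]):
                seq = seq[:lo - 1] + sub + seq[hi:]
            g = GenomeRecord(g.id, seq, g.features, "synthetic")
    return g


# ---------------------------------------------------------------------------
# planting

def _oriented_offset_to_genomic(f: GeneFeature, offset: int) -> int:
    """Genomic 'insert-after' position for an insertion after ``offset``
    oriented bases of the gene."""
    return f.start + offset - 1 if f.strand == "+" else f.end - offset


def _pick_gene(genome: GenomeRecord, rng, min_len: int = 450) -> GeneFeature:
    cands = [f for f in genome.cds_features() if f.length >= min_len]
    if not cands:
        raise ValueError("no CDS long enough to host the element")
    return cands[int(rng.integers(len(cands)))]


def plant(genome: GenomeRecord, spec: PlantSpec, seed: int = 0
          ) -> tuple[GenomeRecord, TruthEvent]:
    """Insert one mobile element and return the carrier plus its truth entry.

    intron       inside a CDS at a point whose preceding (oriented) base is T,
                 with a payload ending in G — the group I hallmarks; option
                 ``internal_orf`` embeds a reverse-strand LAGLIDADG ORF.
    intein       in-frame codons inside a CDS (payload is a protein or an aa
                 length); the final codon avoids G so the element cannot
                 masquerade as a DNA-level intron.
    transposon   intergenic insertion duplicating a target d-mer (options
                 ``tsd_len``, ``tsd_motif``).
    endonuclease intergenic gene insertion, precise or with
                 ``deletion_at_target`` bases removed on arrival.

    attP/attB cores involve two genomes and are planted by plant_att_core().
    """
    rng = _rng(seed, 3)
    kind = spec.kind
    if kind == "intron":
        return _plant_intron(genome, spec, rng)
    if kind == "intein":
        return _plant_intein(genome, spec, rng)
    if kind == "transposon":
        return _plant_transposon(genome, spec, rng)
    if kind == "endonuclease":
        return _plant_endonuclease(genome, spec, rng)
    raise ValueError(f"unknown plant kind {kind!r} (att_core: use plant_att_core)")


def make_intron_payload(rng, length: int = 819, gc: float = 0.61,
                        internal_orf: bool = False, orf_codons: int = 150
                        ) -> tuple[str, Optional[str]]:
    """Intron sequence (oriented as the host gene) ending in G; optionally
    carrying a bottom-strand homing-endonuclease ORF with the literal
    LAGLIDADG motif, guarded by an adjacent in-frame stop so the ORF's
    extent is unambiguous."""
    if internal_orf:
        aa = _rand_protein(rng, orf_codons - 1)
        mid = (orf_codons - 1) // 2
        aa = aa[:mid] + "LAGLIDADG" + aa[mid + 9:]
        orf_dna = "ATG" + _codons_for(rng, aa, gc) + "TGA"
        room = length - len(orf_dna) - 6
        if room < 20:
            raise ValueError("intron too short for the requested internal ORF")
        pre_n = int(rng.integers(10, room - 9))
        pre = _rand_bases(rng, pre_n, gc)
        post = "TTA" + _rand_bases(rng, room - pre_n + 2, gc)
        payload = pre + revcomp(orf_dna) + post
        payload = payload[:length - 1] + "G"
        orf_protein = "M" + aa
    else:
        payload = _rand_bases(rng, length - 1, gc) + "G"
        orf_protein = None
    return payload, orf_protein


def _plant_intron(genome: GenomeRecord, spec: PlantSpec, rng
                  ) -> tuple[GenomeRecord, TruthEvent]:
    f = (genome.feature_by_number(spec.target) if spec.target
         else _pick_gene(genome, rng, 600))
    opts = spec.options
    if isinstance(spec.payload, str):
        payload, orf_protein = spec.payload, opts.get("orf_protein")
    else:
        payload, orf_protein = make_intron_payload(
            rng, int(spec.payload or 819), opts.get("gc", 0.61),
            bool(opts.get("internal_orf", False)))
    if payload[-1] != "G":
        raise ValueError("intron payload must end in G (group I hallmark)")
    oriented = genome.seq[f.start - 1:f.end]
    if f.strand == "-":
        oriented = revcomp(oriented)
    legal = [i for i in range(30, f.length - 30) if oriented[i - 1] == "T"]
    # drop points where the hallmark would be left-shiftable into ambiguity
    legal = [i for i in legal if oriented[i] != payload[0]]
    if not legal:
        raise ValueError(f"gene {f.gene_number} has no legal T insertion point")
    avoid = opts.get("avoid_positions")
    clean = [i for i in legal
             if _junction_clear(avoid, _oriented_offset_to_genomic(f, i) - 10,
                                _oriented_offset_to_genomic(f, i) + 11)]
    if clean:
        legal = clean
    off = legal[int(rng.integers(len(legal)))]
    # pin second-rank edge bases too (the 3' G and the exon's 3' T already
    # disambiguate the first rank)
    payload = (payload[0] + _pin(payload[1], oriented[off + 1])
               + payload[2:-2]
               + _pin(payload[-2], oriented[off - 2]) + payload[-1])
    after = _oriented_offset_to_genomic(f, off)
    inserted = payload if f.strand == "+" else revcomp(payload)
    carrier = _insert(genome, after, inserted)
    ev = TruthEvent("intron", genome.id, after + 1, after + len(payload), payload,
                    {"gene": f.gene_number, "strand": f.strand,
                     "inserted_genomic": inserted,
                     "exon1_end_oriented_base": "T", "intron_end_oriented_base": "G",
                     "orf_protein": orf_protein})
    return carrier, ev


def _plant_intein(genome: GenomeRecord, spec: PlantSpec, rng
                  ) -> tuple[GenomeRecord, TruthEvent]:
    opts = spec.options
    if isinstance(spec.payload, str):
        aa = spec.payload
    else:
        aa = _rand_protein(rng, int(spec.payload or 340))
    res = int(opts.get("insert_at_aa", 104))
    f = (genome.feature_by_number(spec.target) if spec.target
         else _pick_gene(genome, rng, 3 * (res + 60)))
    if f.length < 3 * (res + 30):
        raise ValueError(f"gene {f.gene_number} too short for residue {res}")
    avoid = opts.get("avoid_positions")
    for cand in [res] + [res + d for k in range(1, 15) for d in (k, -k)]:
        if not (30 < cand < f.length // 3 - 30):
            continue
        x = _oriented_offset_to_genomic(f, 3 * (cand - 1))
        if _junction_clear(avoid, x - 10, x + 11):
            res = cand
            break
    # build the coding sequence with pinned edge codons: the first two bases
    # differ from the junction's downstream context and the last two from its
    # upstream context (so the in-frame placement is sequence-determined),
    # and the final base avoids G so the element cannot pass for a DNA-level
    # intron.  A codon ending in C is always sense, as is any G-led codon.
    oriented = genome.seq[f.start - 1:f.end]
    if f.strand == "-":
        oriented = revcomp(oriented)
    at = 3 * (res - 1)
    c_first = _pin("A", oriented[at]) + _pin("A", oriented[at + 1]) + "C"
    c_last = ("G" + _pin("A", oriented[at - 2])
              + _pin("A", oriented[at - 1], "G"))
    dna = c_first + _codons_for(rng, aa[1:-1], opts.get("gc", 0.61)) + c_last
    aa = translate_cds(dna)
    after = _oriented_offset_to_genomic(f, 3 * (res - 1))
    inserted = dna if f.strand == "+" else revcomp(dna)
    carrier = _insert(genome, after, inserted)
    ev = TruthEvent("intein", genome.id, after + 1, after + len(dna), dna,
                    {"gene": f.gene_number, "strand": f.strand,
                     "inserted_genomic": inserted,
                     "intein_aa": aa, "insert_at_aa": res})
    return carrier, ev


def make_orf_payload(rng, n_codons: int, gc: float = 0.61,
                     pad: tuple[int, int] = (40, 40)) -> str:
    """An intergenic gene cassette: pads around a stop-free ORF."""
    orf = "ATG" + _rand_codons(rng, n_codons - 2, gc) + "TGA"
    return (_rand_bases(rng, pad[0], gc) + orf + _rand_bases(rng, pad[1], gc))


def _pin(base: str, *not_these: str) -> str:
    """The base itself, or the next base cyclically that avoids the given
    ones — used to pin planted-element edges so junctions are unambiguous."""
    order = "ACGT"
    if base not in not_these:
        return base
    i = order.index(base)
    return next(order[(i + j) % 4] for j in range(1, 4)
                if order[(i + j) % 4] not in not_these)


def _junction_clear(avoid: Optional[set[int]], lo: int, hi: int) -> bool:
    """True when no logged substitution falls in [lo, hi] (1-based).

    Planting is kept away from the carrier's own substitutions so every
    planted junction is sequence-determined: a carrier-private variant right
    at a junction would make the element's true extent unknowable from any
    pairwise comparison, and recovery tests need a unique correct answer.
    """
    if not avoid:
        return True
    return all(p not in avoid for p in range(lo, hi + 1))


def _pick_intergenic(genome: GenomeRecord, rng, need: int = 1,
                     exclude: Optional[tuple[int, int]] = None,
                     avoid: Optional[set[int]] = None, pad: int = 10,
                     tries: int = 50,
                     clear_windows: Optional[list[tuple[int, int]]] = None
                     ) -> int:
    # keep clear of the genome termini: comparative detection needs anchored
    # flanking sequence on both sides of any planted element
    ranges = [(max(r[0], 200), min(r[1], len(genome.seq) - 200))
              for r in _intergenic_ranges(genome)]
    ranges = [r for r in ranges if r[1] - r[0] + 1 >= need]
    if exclude is not None:
        ranges = [r for r in ranges
                  if r[1] < exclude[0] or r[0] > exclude[1]]
    if not ranges:
        raise ValueError("no intergenic range wide enough")
    if clear_windows is None:
        clear_windows = [(-pad, need + pad)]
    for _ in range(tries):
        lo, hi = ranges[int(rng.integers(len(ranges)))]
        pos = int(rng.integers(lo, hi - need + 2))
        if all(_junction_clear(avoid, pos + a, pos + b)
               for a, b in clear_windows):
            return pos
    return pos


def _plant_transposon(genome: GenomeRecord, spec: PlantSpec, rng
                      ) -> tuple[GenomeRecord, TruthEvent]:
    opts = spec.options
    d = int(opts.get("tsd_len", 5))
    if not (0 <= d <= 15):
        raise ValueError("tsd_len must lie in [0, 15]")
    if isinstance(spec.payload, str):
        payload = spec.payload
    else:
        length = int(spec.payload or 1500)
        payload = make_orf_payload(rng, (length - 86) // 3, opts.get("gc", 0.61),
                                   (40, 40))
        payload += _rand_bases(rng, length - len(payload), opts.get("gc", 0.61))
    motif = opts.get("tsd_motif")
    exclude = opts.get("exclude")
    avoid = opts.get("avoid_positions")
    genome2 = genome
    overwrite = None
    if motif is not None:
        if len(motif) != d and d > 0:
            d = len(motif)
        # prefer an intact occurrence with a substitution-free neighbourhood;
        # relax the clearance before falling back to writing the motif in
        # (an overwritten motif is absent from relatives, which makes the
        # planted event a replacement rather than a clean insertion)
        pos = None
        for pad in (7, 3, 0):
            for lo, hi in _intergenic_ranges(genome):
                if exclude is not None and not (hi < exclude[0]
                                                or lo > exclude[1]):
                    continue
                lo2, hi2 = max(lo, 200), min(hi, len(genome.seq) - 200)
                at = lo2 - 1
                while 0 <= at and (hit := genome.seq.find(motif, at, hi2)) != -1:
                    if _junction_clear(avoid, hit + 1 - pad, hit + d + pad):
                        pos = hit + 1
                        break
                    at = hit + 1
                if pos is not None:
                    break
            if pos is not None:
                break
        if pos is None:  # write the motif into an intergenic site first
            pos = _pick_intergenic(genome, rng, d + 2, exclude, avoid)
            seq = genome.seq[:pos - 1] + motif + genome.seq[pos - 1 + d:]
            genome2 = GenomeRecord(genome.id, seq, genome.features, "synthetic")
            overwrite = [pos, motif]
    else:
        pos = _pick_intergenic(genome2, rng, max(d, 1) + 2, exclude, avoid)
    tsd = genome2.seq[pos - 1:pos - 1 + d]
    # pin two payload bases at each edge against the junction context: the
    # leftmost equivalent placement then starts exactly at the target copy,
    # the rightmost ends before the downstream flank, and no single
    # coincidental match can re-anchor a boundary — the planted event's
    # left-normalised coordinates stay the unique sequence-determined answer
    ctx = genome2.seq
    prev = [ctx[pos - 2] if pos >= 2 else "A",
            ctx[pos - 3] if pos >= 3 else "A"]
    foll = [ctx[pos - 1 + d + i] if pos - 1 + d + i < len(ctx) else "A"
            for i in range(2)]
    payload = (_pin(payload[0], foll[0]) + _pin(payload[1], foll[1])
               + payload[2:-2]
               + _pin(payload[-2], prev[1]) + _pin(payload[-1], prev[0]))
    inserted = payload + tsd
    after = pos + d - 1 if d > 0 else pos - 1
    carrier = _insert(genome2, after, inserted)
    ev = TruthEvent("transposon", genome2.id, after + 1, after + len(inserted),
                    payload,
                    {"tsd_len": d, "tsd_seq": tsd,
                     "inserted_genomic": inserted,
                     "motif_overwrite": overwrite,
                     "element_interval": [after + 1, after + len(payload)]})
    return carrier, ev


def _plant_endonuclease(genome: GenomeRecord, spec: PlantSpec, rng
                        ) -> tuple[GenomeRecord, TruthEvent]:
    opts = spec.options
    deletion = int(opts.get("deletion_at_target", 0))
    if deletion < 0:
        raise ValueError("deletion_at_target must be >= 0")
    if isinstance(spec.payload, str):
        payload = spec.payload
    else:
        payload = make_orf_payload(rng, int(spec.payload or 150),
                                   opts.get("gc", 0.61), (30, 30))
    # only the two junction neighbourhoods need to be substitution-free;
    # carrier variants inside the co-deleted span vanish with it
    windows = ([(-7, 2), (deletion - 2, deletion + 7)] if deletion
               else [(-7, 9)])
    pos = _pick_intergenic(genome, rng, deletion + 2, opts.get("exclude"),
                           opts.get("avoid_positions"), clear_windows=windows)
    deleted = ""
    g = genome
    if deletion:
        deleted = g.seq[pos - 1:pos - 1 + deletion]
        g = _delete(g, pos, pos + deletion - 1)
    # pin two bases at each payload edge so the insertion has a unique
    # placement: the edges must differ from the flanking context AND from the
    # edges of any co-deleted target bases, or boundary reconstruction would
    # be genuinely ambiguous (ground truth must stay unambiguous)
    nxt = [g.seq[pos - 1 + i] if pos - 1 + i < len(g.seq) else "A"
           for i in range(2)]
    prv = [g.seq[pos - 2] if pos >= 2 else "A",
           g.seq[pos - 3] if pos >= 3 else "A"]
    payload = (_pin(payload[0], nxt[0], deleted[0] if deleted else nxt[0])
               + _pin(payload[1], nxt[1], deleted[1] if deleted else nxt[1])
               + payload[2:-2]
               + _pin(payload[-2], prv[1],
                      deleted[-2] if deleted else prv[1])
               + _pin(payload[-1], prv[0],
                      deleted[-1] if deleted else prv[0]))
    carrier = _insert(g, pos - 1, payload)
    ev = TruthEvent("endonuclease", genome.id, pos, pos + len(payload) - 1, payload,
                    {"deletion_at_target": deletion, "deleted_target": deleted,
                     "inserted_genomic": payload})
    return carrier, ev


def plant_att_core(phage: GenomeRecord, host: GenomeRecord,
                   int_gene_number: str, core_seq: Optional[str] = None,
                   core_len: int = 44, seed: int = 0,
                   core_offset: int = 100
                   ) -> tuple[GenomeRecord, GenomeRecord, list[TruthEvent]]:
    """Write an identical attP/attB common core into a phage and its host.

    Phage side: the core is written ``core_offset`` bp downstream of the
    designated integrase gene's 3' end, bracketed by direct arm-type repeats
    P1/P2 (left) and P3/P4 (right), with an inverted arm pair overlapping the
    int start codon.  Host side: the core overwrites the 3' half of a tRNA
    feature, running past its end, so attB overlaps the tRNA.
    """
    rng = _rng(seed, 4)
    intf = phage.feature_by_number(int_gene_number)
    if core_seq is None:
        core_seq = _rand_bases(rng, core_len - 1, 0.61) + "C"
    core_len = len(core_seq)
    arms = [sample_arm_site(rng) for _ in range(4)]
    inv = [sample_arm_site(rng) for _ in range(2)]

    spacers = [int(rng.integers(8, 18)) for _ in range(2)]
    arm_offsets = [0, 10 + spacers[0]]          # P1, P2 (0-based in block)
    block = arms[0] + _rand_bases(rng, spacers[0], 0.61) + arms[1]
    block += _rand_bases(rng, 12, 0.61)
    core_at = len(block)                        # 0-based offset of core
    block += core_seq + _rand_bases(rng, 12, 0.61)
    arm_offsets.append(len(block))              # P3
    block += arms[2] + _rand_bases(rng, spacers[1], 0.61)
    arm_offsets.append(len(block))              # P4
    block += arms[3]

    end3 = intf.end if intf.strand == "+" else intf.start
    if intf.strand == "+":
        b_lo = end3 + core_offset - core_at  # core begins ~core_offset after int
        written_block = block
        inv_block = revcomp(inv[1]) + _rand_bases(rng, 4, 0.61) + revcomp(inv[0])
        inv_lo = intf.start - 5
        arm_or = "direct"

        def to_genomic(off: int) -> tuple[int, int]:
            return b_lo + off, b_lo + off + ARM_LEN - 1
        p_core = (b_lo + core_at, b_lo + core_at + core_len - 1)
    else:
        b_lo = end3 - core_offset - len(block) + 1
        b_hi = b_lo + len(block) - 1
        written_block = revcomp(block)
        inv_block = inv[0] + _rand_bases(rng, 4, 0.61) + inv[1]
        inv_lo = intf.end - len(inv_block) + 6
        arm_or = "inverted"

        def to_genomic(off: int) -> tuple[int, int]:
            hi = b_hi - off
            return hi - ARM_LEN + 1, hi
        p_hi = b_hi - core_at
        p_core = (p_hi - core_len + 1, p_hi)
    if b_lo < 1 or b_lo + len(block) - 1 > len(phage.seq) or inv_lo < 1:
        raise ValueError("no room downstream of int for the att cassette")
    arm_intervals = [to_genomic(off) for off in arm_offsets]
    pseq = phage.seq
    pseq = pseq[:b_lo - 1] + written_block + pseq[b_lo - 1 + len(block):]
    pseq = pseq[:inv_lo - 1] + inv_block + pseq[inv_lo - 1 + len(inv_block):]

    trna = next((f for f in host.features if f.kind == "tRNA"), None)
    if trna is None:
        raise ValueError("host carries no tRNA feature")
    h_lo = trna.start + (trna.length // 2)
    h_hi = h_lo + core_len - 1
    if h_hi > len(host.seq):
        raise ValueError("tRNA too close to the host end")
    hseq = host.seq[:h_lo - 1] + core_seq + host.seq[h_hi:]
    host2 = GenomeRecord(host.id, hseq, host.features, "synthetic")

    # pin the phage bases flanking the core against the host's so the region
    # of phage/host identity is exactly the planted core; on a reverse-strand
    # cassette the comparison is complemented and side-swapped
    p0, p1 = p_core[0] - 2, p_core[1]        # 0-based flanking indices
    if intf.strand == "+":
        left_vs, right_vs = hseq[h_lo - 2], hseq[h_hi]
    else:
        left_vs, right_vs = revcomp(hseq[h_hi]), revcomp(hseq[h_lo - 2])
    pseq = (pseq[:p0] + _pin(pseq[p0], left_vs)
            + pseq[p0 + 1:p1] + _pin(pseq[p1], right_vs) + pseq[p1 + 1:])
    written_block = pseq[b_lo - 1:b_lo - 1 + len(block)]
    phage2 = GenomeRecord(phage.id, pseq, phage.features, "synthetic")

    events = [
        TruthEvent("att_core", phage.id, p_core[0], p_core[1], core_seq,
                   {"intervals": [[b_lo, b_lo + len(block) - 1],
                                  [inv_lo, inv_lo + len(inv_block) - 1]],
                    "written": [written_block, inv_block],
                    "core_interval": list(p_core),
                    "arm_sites": arms, "inverted_arms": inv,
                    "arm_intervals": [list(iv) for iv in arm_intervals],
                    "arm_orientation": arm_or,
                    "inv_interval": [inv_lo, inv_lo + len(inv_block) - 1],
                    "inv_orientation": "inverted" if intf.strand == "+" else "direct",
                    "int_gene": intf.gene_number, "strand": intf.strand}),
        TruthEvent("att_core", host.id, h_lo, h_hi, core_seq,
                   {"intervals": [[h_lo, h_hi]], "written": [core_seq],
                    "core_interval": [h_lo, h_hi],
                    "trna_gene": trna.gene_number}),
    ]
    return phage2, host2, events


# ---------------------------------------------------------------------------
# cohorts

#: per-genome substitution rates giving pairwise identities 0.79-0.97,
#: the ANI span reported for the six-genome cluster this emulates
CLUSTER_RATES = [0.008, 0.024, 0.05, 0.07, 0.10, 0.112]

SCENARIOS = ("cluster_j_like", "minimal")


def make_cohort(n_genomes: int = 6, scenario: str = "cluster_j_like",
                seed: int = 0, length: int = 110_000, host_length: int = 50_000,
                gc: float = 0.61
                ) -> tuple[list[GenomeRecord], GenomeRecord, TruthLog]:
    """Generate a phage cohort plus host with every element class planted.

    ``cluster_j_like`` derives six genomes from one ancestor at pairwise
    identities spanning 0.79-0.97 and plants: two introns (one carrying an
    internal LAGLIDADG ORF), one ~340 aa intein, one transposon with a 5 bp
    CACTG-style TSD, one precise and one deletion-associated (35 bp)
    endonuclease insertion, and one shared 44 bp att core present in every
    genome and in a host tRNA.  ``minimal`` is a two-genome smoke-test
    version.  ``length`` rescales the genomes (the study-like default is
    110 kb phage / 50 kb host).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    if scenario == "minimal":
        n_genomes = min(n_genomes, 2) or 2
        rates = CLUSTER_RATES[:2]
    else:
        n_genomes = 6
        rates = CLUSTER_RATES
    ancestor = generate_ancestor(length, gc, seed=seed)
    truth = TruthLog(seed=seed, scenario=scenario,
                     meta={"substitution_rates": {}, "length": length,
                           "gc": gc, "ancestor_id": ancestor.id})
    # designate roles on the shared gene grid
    cds = ancestor.cds_features()
    if len(cds) < 8:
        raise ValueError("genome too short for a cohort scenario")

    def gene_at(frac: float, min_len: int = 0) -> str:
        target = frac * length
        cands = [f for f in cds if f.length >= min_len] or cds
        return min(cands, key=lambda f: abs((f.start + f.end) / 2 - target)).gene_number

    roles = {
        "capsid_like": gene_at(0.15, 900),
        "tail_like": gene_at(0.60, 900),
        "terminase_like": gene_at(0.05, 3 * 180),
        "int": gene_at(0.46),
    }
    truth.meta["roles"] = roles

    # seed the transposon's target motif into the ancestor at a few
    # intergenic sites, so every descendant inherits a bona fide target and
    # the planted insertion is a clean duplication relative to relatives
    motif = "CACTG"
    intf0 = ancestor.feature_by_number(roles["int"])
    zone = (intf0.start - 100, intf0.end + 400)
    mrng = np.random.default_rng([8, seed])
    motif_sites = []
    aseq = ancestor.seq
    for _ in range(6):
        p = _pick_intergenic(ancestor, mrng, len(motif) + 2, zone)
        aseq = aseq[:p - 1] + motif + aseq[p - 1 + len(motif):]
        motif_sites.append(p)
    ancestor = GenomeRecord(ancestor.id, aseq, ancestor.features, "synthetic")
    truth.meta["motif"] = motif
    truth.meta["motif_sites"] = motif_sites

    genomes: list[GenomeRecord] = []
    sub_positions: dict[str, set[int]] = {}
    for i in range(n_genomes):
        gid = f"synJ{i + 1}"
        cfg = EvolutionConfig(substitution_rate=rates[i], indel_rate=2e-5,
                              seed=int(np.random.default_rng([5, seed, i])
                                       .integers(2**31)))
        g, elog = evolve(ancestor, cfg, new_id=gid)
        truth.events.extend(elog.events)
        truth.meta["substitution_rates"][gid] = rates[i]
        # substitution coordinates, corrected for the indels applied after
        # them, so junction-clearance checks see final coordinates
        pos: list[int] = []
        for e in elog.events:
            if e.kind == "substitutions":
                pos = list(e.options["positions"])
            elif e.kind == "indel_insertion":
                n = len(e.payload)
                pos = [p + n if p >= e.start else p for p in pos]
            elif e.kind == "indel_deletion":
                n = len(e.payload)
                pos = [p - n if p > e.end else p
                       for p in pos if not (e.start <= p <= e.end)]
        sub_positions[gid] = set(pos)
        genomes.append(g)

    host_seed = int(np.random.default_rng([6, seed]).integers(2**31))
    host = generate_ancestor(host_length, 0.655, seed=host_seed)
    host = GenomeRecord("host", host.seq, host.features, "synthetic")
    # add a tRNA feature in a wide intergenic gap near the chromosome centre
    gaps = [r for r in _intergenic_ranges(host) if r[1] - r[0] >= 90]
    lo = min(gaps, key=lambda r: abs((r[0] + r[1]) / 2 - host_length / 2))[0]
    host = GenomeRecord("host", host.seq,
                        host.features + [GeneFeature("trnL", lo, lo + 74, "+", "tRNA",
                                                     "tRNA-Leu")],
                        "synthetic")

    def plant_into(i: int, spec: PlantSpec, pseed: int) -> None:
        # keep intergenic plants away from the future att cassette around int
        intf = genomes[i].feature_by_number(roles["int"])
        spec.options.setdefault("exclude", (intf.start - 100, intf.end + 400))
        spec.options.setdefault("avoid_positions", sub_positions[genomes[i].id])
        genomes[i], ev = plant(genomes[i], spec, seed=pseed)
        truth.events.append(ev)

    base = int(np.random.default_rng([7, seed]).integers(2**30))
    if scenario == "minimal":
        plant_into(1, PlantSpec("intron", roles["tail_like"], 819), base + 1)
    else:
        plant_into(0, PlantSpec("intron", roles["tail_like"], 265), base + 1)
        plant_into(2, PlantSpec("intron", roles["capsid_like"], 819,
                                {"internal_orf": True}), base + 2)
        plant_into(1, PlantSpec("intein", roles["terminase_like"], 340,
                                {"insert_at_aa": 104}), base + 3)
        plant_into(3, PlantSpec("transposon", None, 1500,
                                {"tsd_len": 5, "tsd_motif": "CACTG"}), base + 4)
        plant_into(4, PlantSpec("endonuclease", None, 150), base + 5)
        plant_into(5, PlantSpec("endonuclease", None, 150,
                                {"deletion_at_target": 35}), base + 6)
    core = None
    for i in range(len(genomes)):
        genomes[i], host_or_same, evs = _plant_att(genomes[i], host, roles["int"],
                                                   core, seed, first=(i == 0))
        if i == 0:
            host = host_or_same
            core = evs[0].payload
            truth.events.extend(evs)
        else:
            truth.events.append(evs[0])
    truth.meta["core_seq"] = core
    return genomes, host, truth


def _plant_att(phage, host, int_gene, core_seq, seed, first):
    """Helper: plant the shared core; the host is only written once."""
    p2, h2, evs = plant_att_core(phage, host, int_gene, core_seq, seed=seed)
    if first:
        return p2, h2, evs
    return p2, host, [evs[0]]


def rebuild_ancestor(truth: TruthLog) -> GenomeRecord:
    """Reconstruct a cohort's effective ancestor from its truth log, so that
    replaying the logged events reproduces every final genome byte-for-byte."""
    anc = generate_ancestor(truth.meta["length"], truth.meta["gc"],
                            seed=truth.seed)
    seq = anc.seq
    motif = truth.meta.get("motif")
    for p in truth.meta.get("motif_sites", []):
        seq = seq[:p - 1] + motif + seq[p - 1 + len(motif):]
    return GenomeRecord(anc.id, seq, anc.features, "synthetic")
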