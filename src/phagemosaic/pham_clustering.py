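"""Sorting phage proteins into phamilies ("phams") and counting shared genes.

Two proteins are related when either route fires: global identity >= 32.5%
(identical pairs over the shorter length) or a local-alignment E-value
<= 1e-50.  Both thresholds are inclusive.  Phams are the connected components
of the resulting graph (single linkage), so two proteins in one pham need not
themselves satisfy a threshold; isolated proteins form single-member phams
(orphams).

Note that pham membership is database-dependent: counts computed inside a
large multi-cluster database will differ from counts over a handful of
supplied genomes, because intermediate sequences can bridge components.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import networkx as nx

from .pairwise_align import global_align_aa, local_align_aa

ProteinKey = tuple[str, str]  # (genome id, gene number)


@dataclass(frozen=True)
class PhamConfig:
    identity_threshold: float = 0.325
    evalue_threshold: float = 1e-50

    def __post_init__(self) -> None:
        if not (0.0 < self.identity_threshold < 1.0):
            raise ValueError("identity_threshold must be in (0, 1)")
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be positive")


@dataclass
class Pham:
    pham_id: int
    members: frozenset[ProteinKey]


def related(a: str, b: str, config: PhamConfig = PhamConfig()) -> bool:
    """Dual-threshold relatedness test for one protein pair."""
    if global_align_aa(a, b).identity >= config.identity_threshold:
        return True
    return local_align_aa(a, b).evalue <= config.evalue_threshold


def _prescreen(a: str, b: str, floor: float = 0.15) -> bool:
    """Cheap filter: skip full scoring only for length-comparable pairs whose
    edit identity is far below anything that could pass either threshold.

    Pairs with dissimilar lengths are always fully scored: the min-length
    identity denominator lets a short protein reach 32.5% against a much
    longer unrelated one through scattered matches, which edit distance
    cannot anticipate."""
    shorter, longer = sorted((len(a), len(b)))
    if shorter < 0.8 * longer:
        return True
    k = int(shorter * (1 - floor)) + (longer - shorter)
    d = edlib.align(a, b, mode="NW", k=k)["editDistance"]
    if d == -1:
        return False
    return 1.0 - d / shorter >= floor


def score_edges(proteins: list[tuple[ProteinKey, str]],
                config: PhamConfig = PhamConfig(),
                prescreen: bool = True) -> list[tuple[ProteinKey, ProteinKey]]:
    """Undirected relatedness edges over a protein list.

    ``prescreen=False`` disables the edit-distance prefilter and scores every
    pair with the full dual-route test (used by the oracle tests).
    """
    if len(proteins) < 1:
        raise ValueError("need at least one protein")
    keys = [k for k, _ in proteins]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (genome, gene) protein ids")
    edges = []
    for i in range(len(proteins)):
        ki, si = proteins[i]
        for j in range(i + 1, len(proteins)):
            kj, sj = proteins[j]
            if prescreen and not _prescreen(si, sj):
                continue
            if related(si, sj, config):
                edges.append((ki, kj))
    return edges


def build_phams(edges: list[tuple[ProteinKey, ProteinKey]],
                proteins: list[tuple[ProteinKey, str]]) -> list[Pham]:
    """Connected components under single linkage; deterministic pham ids.

    Pham ids are assigned in order of each component's lexicographically
    smallest (genome, gene) member, so outputs are stable across runs.
    """
    known = {k for k, _ in proteins}
    for u, v in edges:
        if u not in known or v not in known:
            raise ValueError(f"edge references unknown protein {u if u not in known else v}")
    g = nx.Graph()
    g.add_nodes_from(known)
    g.add_edges_from(edges)
    comps = sorted(nx.connected_components(g), key=lambda c: min(c))
    return [Pham(i + 1, frozenset(c)) for i, c in enumerate(comps)]


def shared_gene_count(a: str, b: str, phams: list[Pham]) -> int:
    """Number of genes of genome a whose pham also holds a gene of genome b.

    Not symmetric in general: two paralogs in a matching one gene in b count
    twice from a's side but once from b's.
    """
    genomes = {gid for p in phams for gid, _ in p.members}
    if a not in genomes or b not in genomes:
        missing = a if a not in genomes else b
        raise ValueError(f"unknown genome id {missing!r}")
    count = 0
    for p in phams:
        a_genes = sum(1 for gid, _ in p.members if gid == a)
        if a_genes and (a == b or any(gid == b for gid, _ in p.members)):
            count += a_genes
    return count


def pham_table(phams: list[Pham]) -> list[dict]:
    """Rows for the TSV writer: pham_id, size, semicolon-joined members."""
    rows = []
    for p in sorted(phams, key=lambda p: p.pham_id):
        members = ";".join(f"{g}:{n}" for g, n in sorted(p.members))
        rows.append({"pham_id": p.pham_id, "size": len(p.members), "members": members})
    return rows
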