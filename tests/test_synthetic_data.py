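"""Synthetic cohort generator: determinism, truth-log replay, plant round-trips."""

import numpy as np
import pytest

from phagemosaic.genome_io import extract_gene_dna, gc_content, revcomp, translate_cds
from phagemosaic.synthetic_data import (EvolutionConfig, PlantSpec, evolve,
                                        generate_ancestor, make_cohort, plant,
                                        plant_att_core, replay)


# ----------------------------------------------------------------- ancestor

def test_ancestor_length_and_gene_grid():
    g = generate_ancestor(20_000, 0.61, seed=7)
    assert len(g.seq) == 20_000
    assert len(g.features) >= 10
    strands = {f.strand for f in g.features}
    assert strands == {"+", "-"}
    for f in g.features:  # stop-free ORFs with a start codon
        prot = translate_cds(extract_gene_dna(g, f), initiator=True)
        assert len(prot) == f.length // 3 - 1


def test_ancestor_gc_concentrates_at_target():
    g = generate_ancestor(100_000, 0.61, seed=8)
    assert gc_content(g) == pytest.approx(0.61, abs=0.02)


def test_ancestor_deterministic():
    a = generate_ancestor(20_000, 0.61, seed=9)
    b = generate_ancestor(20_000, 0.61, seed=9)
    assert a.seq == b.seq
    assert [(f.start, f.end, f.strand) for f in a.features] == \
        [(f.start, f.end, f.strand) for f in b.features]


def test_ancestor_rejects_bad_parameters():
    with pytest.raises(ValueError):
        generate_ancestor(500, 0.61)
    with pytest.raises(ValueError):
        generate_ancestor(20_000, 1.2)


# ------------------------------------------------------------------- evolve

def test_evolve_zero_rate_is_identity():
    anc = generate_ancestor(20_000, 0.61, seed=10)
    out, log = evolve(anc, EvolutionConfig(0.0, 0.0, seed=1))
    assert out.seq == anc.seq
    assert log.events == []


def test_evolve_deterministic_and_replayable():
    anc = generate_ancestor(20_000, 0.61, seed=11)
    cfg = EvolutionConfig(0.05, 1e-4, seed=2)
    a, loga = evolve(anc, cfg, new_id="d")
    b, _ = evolve(anc, cfg, new_id="d")
    assert a.seq == b.seq
    assert replay(anc, loga.events, "d").seq == a.seq


def test_evolve_realized_rate_near_nominal():
    anc = generate_ancestor(50_000, 0.61, seed=12)
    out, log = evolve(anc, EvolutionConfig(0.05, 0.0, seed=3))
    n_subs = len(log.events[0].options["positions"])
    assert n_subs == pytest.approx(0.05 * 50_000, rel=0.1)
    diffs = sum(1 for x, y in zip(anc.seq, out.seq) if x != y)
    assert diffs == n_subs


def test_evolve_keeps_genes_translatable():
    anc = generate_ancestor(30_000, 0.61, seed=13)
    out, _ = evolve(anc, EvolutionConfig(0.1, 0.0, seed=4))
    for f in out.cds_features():
        prot = translate_cds(extract_gene_dna(out, f), initiator=True)
        assert len(prot) == f.length // 3 - 1  # no nonsense mutations fixed


def test_evolution_config_validation():
    with pytest.raises(ValueError):
        EvolutionConfig(0.7)
    with pytest.raises(ValueError):
        EvolutionConfig(0.1, indel_size_geometric_p=0.0)


# -------------------------------------------------------------------- plant

@pytest.fixture(scope="module")
def base_genome():
    return generate_ancestor(25_000, 0.61, seed=20)


def test_plant_intron_round_trip_and_hallmarks(base_genome):
    carrier, ev = plant(base_genome, PlantSpec("intron", None, 265), seed=21)
    assert len(carrier.seq) == len(base_genome.seq) + 265
    restored = carrier.seq[:ev.start - 1] + carrier.seq[ev.end:]
    assert restored == base_genome.seq
    # group I hallmarks on the oriented gene
    f = carrier.feature_by_number(ev.options["gene"])
    g = extract_gene_dna(carrier, f)
    if f.strand == "+":
        os, oe = ev.start - f.start + 1, ev.end - f.start + 1
    else:
        os, oe = f.end - ev.end + 1, f.end - ev.start + 1
    assert g[os - 2] == "T"       # exon 1 ends in T (U on the message)
    assert g[oe - 1] == "G"       # intron ends in G


def test_plant_intron_internal_orf_is_recoverable(base_genome):
    carrier, ev = plant(base_genome,
                        PlantSpec("intron", None, 819, {"internal_orf": True}),
                        seed=22)
    from phagemosaic.mobile_elements import find_internal_orfs
    hits = find_internal_orfs(ev.payload)
    planted = ev.options["orf_protein"]
    match = [h for h in hits if h.protein == planted]
    assert match and match[0].strand == "-" and match[0].has_laglidadg


def test_plant_intein_extends_protein_in_frame(base_genome):
    carrier, ev = plant(base_genome, PlantSpec("intein", None, 340,
                                               {"insert_at_aa": 104}), seed=23)
    f0 = base_genome.feature_by_number(ev.options["gene"])
    f1 = carrier.feature_by_number(ev.options["gene"])
    p0 = translate_cds(extract_gene_dna(base_genome, f0), initiator=True)
    p1 = translate_cds(extract_gene_dna(carrier, f1), initiator=True)
    assert len(p1) == len(p0) + 340
    res = ev.options["insert_at_aa"]
    assert p1[:res - 1] == p0[:res - 1]
    assert p1[res - 1 + 340:] == p0[res - 1:]


def test_plant_transposon_duplicates_target(base_genome):
    from phagemosaic.genome_io import GenomeRecord
    from phagemosaic.synthetic_data import _pick_intergenic
    rng = np.random.default_rng(24)
    pos = _pick_intergenic(base_genome, rng, 7)
    ref = GenomeRecord(base_genome.id,
                       base_genome.seq[:pos - 1] + "CACTG"
                       + base_genome.seq[pos + 4:], base_genome.features)
    carrier, ev = plant(ref, PlantSpec("transposon", None, 1500,
                                       {"tsd_len": 5, "tsd_motif": "CACTG"}),
                        seed=24)
    assert ev.options["motif_overwrite"] is None  # found the planted target
    tsd = ev.options["tsd_seq"]
    assert tsd == "CACTG"
    seg = carrier.seq[ev.start - 1:ev.end]
    left = carrier.seq[ev.start - 1 - 5:ev.start - 1]
    assert left == tsd and seg.endswith(tsd)     # carrier: two flanking copies
    restored = carrier.seq[:ev.start - 1] + carrier.seq[ev.end:]
    assert restored == ref.seq                   # empty allele: one copy


def test_plant_endonuclease_with_target_deletion(base_genome):
    carrier, ev = plant(base_genome,
                        PlantSpec("endonuclease", None, 150,
                                  {"deletion_at_target": 35}), seed=25)
    deleted = ev.options["deleted_target"]
    assert len(deleted) == 35
    assert len(carrier.seq) == len(base_genome.seq) + (ev.end - ev.start + 1) - 35
    restored = (carrier.seq[:ev.start - 1] + deleted + carrier.seq[ev.end:])
    assert restored == base_genome.seq


def test_plant_unknown_kind_rejected(base_genome):
    with pytest.raises(ValueError):
        plant(base_genome, PlantSpec("prophage"))


def test_plant_att_core_writes_identical_core(base_genome):
    host = generate_ancestor(10_000, 0.655, seed=26)
    from phagemosaic.genome_io import GeneFeature, GenomeRecord
    host = GenomeRecord("host", host.seq,
                        host.features + [GeneFeature("trnL", 5000, 5074, "+",
                                                     "tRNA", "tRNA-Leu")])
    int_gene = base_genome.cds_features()[len(base_genome.cds_features()) // 2]
    phage2, host2, events = plant_att_core(base_genome, host,
                                           int_gene.gene_number, seed=27)
    pev, hev = events
    core = pev.payload
    assert len(core) == 44
    p_lo, p_hi = pev.options["core_interval"]
    phage_core = phage2.seq[p_lo - 1:p_hi]
    if pev.options["strand"] == "-":
        phage_core = revcomp(phage_core)
    assert phage_core == core
    h_lo, h_hi = hev.options["core_interval"]
    assert host2.seq[h_lo - 1:h_hi] == core
    # core overlaps the tRNA
    assert h_lo <= 5074 and h_hi >= 5000


# ------------------------------------------------------------------ cohorts

def test_minimal_cohort_smoke():
    genomes, host, truth = make_cohort(scenario="minimal", seed=5,
                                       length=20_000, host_length=8_000)
    assert len(genomes) == 2
    assert any(f.kind == "tRNA" for f in host.features)
    assert truth.events


def test_cluster_cohort_has_every_element_class(cohort):
    genomes, host, truth = cohort
    kinds = {e.kind for e in truth.planted()}
    assert kinds == {"intron", "intein", "transposon", "endonuclease"}
    assert sum(1 for e in truth.events if e.kind == "att_core") == 7  # 6+host
    deletions = [e for e in truth.planted()
                 if e.options.get("deletion_at_target")]
    assert deletions and deletions[0].options["deletion_at_target"] == 35


def test_cohort_deterministic():
    a = make_cohort(scenario="cluster_j_like", seed=3, length=30_000,
                    host_length=12_000)
    b = make_cohort(scenario="cluster_j_like", seed=3, length=30_000,
                    host_length=12_000)
    assert [g.seq for g in a[0]] == [g.seq for g in b[0]]
    assert a[1].seq == b[1].seq
    assert a[2].events == b[2].events


def test_cohort_rejects_unknown_scenario():
    with pytest.raises(ValueError):
        make_cohort(scenario="galaxy_brain", seed=1)


def test_cohort_feature_bookkeeping(cohort):
    genomes, host, truth = cohort
    for g in genomes:
        starts = [f.start for f in g.features]
        assert starts == sorted(starts)
        assert all(1 <= f.start <= f.end <= len(g.seq) for f in g.features)


def test_planted_identity_accounts_for_double_hits(cohort):
    _, _, truth = cohort
    r1 = truth.meta["substitution_rates"]["synJ1"]
    r6 = truth.meta["substitution_rates"]["synJ6"]
    expected = (1 - r1) * (1 - r6) + r1 * r6 / 3
    assert truth.planted_identity("synJ1", "synJ6") == pytest.approx(expected)


def test_truth_log_json_round_trip(tmp_path, cohort):
    _, _, truth = cohort
    p = tmp_path / "truth.json"
    truth.to_json(p)
    from phagemosaic.synthetic_data import TruthLog
    back = TruthLog.from_json(p)
    assert back.seed == truth.seed
    assert back.events == truth.events
    assert back.meta == truth.meta


def test_cohort_replay_reproduces_final_genomes(cohort):
    from phagemosaic.synthetic_data import rebuild_ancestor
    genomes, host, truth = cohort
    anc = rebuild_ancestor(truth)
    for g in genomes:
        assert replay(anc, truth.events, g.id).seq == g.seq
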