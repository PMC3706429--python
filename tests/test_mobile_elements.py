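"""Insertion discovery, splice restoration, inteins, TSDs, classification, PCR."""

import numpy as np
import pytest

from phagemosaic.genome_io import GenomeRecord, revcomp, translate_cds
from phagemosaic.mobile_elements import (OrfHit, analyze_insertion,
                                         consensus_scan, detect_intein,
                                         detect_tsd, excised_sequence,
                                         find_insertions, find_internal_orfs,
                                         insilico_pcr, left_normalize,
                                         reconstruct_target, scan_pair)
from phagemosaic.mobile_elements import test_splice_restoration as splice_restoration
from phagemosaic.synthetic_data import PlantSpec, generate_ancestor, plant

BASES = np.array(list("ACGT"))
AA = "ACDEFGHIKLMNPQRSTVWY"


def _rand_dna(rng, n):
    return "".join(BASES[rng.integers(0, 4, n)])


def _closest_refs(genomes, truth, carrier_id):
    rates = truth.meta["substitution_rates"]
    return sorted((g for g in genomes if g.id != carrier_id),
                  key=lambda g: rates[g.id])


# ----------------------------------------------------------- find_insertions

def test_identical_genomes_no_insertions():
    g = generate_ancestor(20_000, 0.61, seed=30)
    assert find_insertions(g, g) == []


def test_unrelated_genomes_warn_and_return_empty():
    a = generate_ancestor(5_000, 0.61, seed=31)
    b = generate_ancestor(5_000, 0.30, seed=32)
    with pytest.warns(UserWarning, match="unrelated"):
        assert find_insertions(a, b) == []


def test_clean_insertion_called_exactly():
    rng = np.random.default_rng(33)
    ref = GenomeRecord("ref", _rand_dna(rng, 6_000))
    ins = _rand_dna(rng, 300)
    carrier = GenomeRecord("car", ref.seq[:3000] + ins + ref.seq[3000:])
    calls = find_insertions(carrier, ref)
    assert len(calls) == 1
    want = left_normalize(carrier.seq, 3001, 3300)[:2]
    assert (calls[0].start, calls[0].end) == want
    assert calls[0].evidence["ref_deleted_seq"] == ""


def test_planted_insertions_recovered_on_cohort(cohort):
    genomes, host, truth = cohort
    by_id = {g.id: g for g in genomes}
    for ev in truth.planted():
        carrier = by_id[ev.genome]
        refs = _closest_refs(genomes, truth, ev.genome)
        reps = consensus_scan(carrier, refs)
        want = left_normalize(carrier.seq, ev.start, ev.end)[:2]
        match = [r for r in reps if (r.call.start, r.call.end) == want]
        assert match, f"{ev.kind} in {ev.genome} not recovered at {want}"
        assert match[0].call.type == ev.kind


# --------------------------------------------------------- splice restoration

def _intron_report(cohort, with_orf):
    genomes, _, truth = cohort
    by_id = {g.id: g for g in genomes}
    ev = next(e for e in truth.planted() if e.kind == "intron"
              and bool(e.options.get("orf_protein")) == with_orf)
    carrier = by_id[ev.genome]
    refs = _closest_refs(genomes, truth, ev.genome)
    reps = consensus_scan(carrier, refs)
    return ev, carrier, [r for r in reps if r.call.type == "intron"][0]


def test_splice_restores_reference_protein(cohort):
    ev, carrier, rep = _intron_report(cohort, with_orf=False)
    sp = rep.splice
    assert sp.restored_identity >= 0.8
    assert sp.restored_protein_len == sp.reference_protein_len
    assert sp.group_I_flags == (True, True)
    assert sp.exon1_3prime_base == "T" and sp.intron_3prime_base == "G"
    assert sp.exon2_start == sp.intron_end + 1


def test_splice_never_scores_a_stop_containing_fusion(cohort):
    # the winning excision must translate cleanly end to end
    ev, carrier, rep = _intron_report(cohort, with_orf=True)
    f = carrier.feature_by_number(rep.call.host_gene)
    from phagemosaic.genome_io import extract_gene_dna
    g = extract_gene_dna(carrier, f)
    sp = rep.splice
    fused = g[:sp.intron_start - 1] + g[sp.intron_end:]
    prot = translate_cds(fused, initiator=True)
    assert len(prot) == len(fused) // 3 - 1


def test_splice_without_homolog_reports_marker():
    rng = np.random.default_rng(34)
    ref = generate_ancestor(8_000, 0.61, seed=35)
    carrier, ev = plant(ref, PlantSpec("intron", None, 265), seed=36)
    stranger = generate_ancestor(8_000, 0.61, seed=99)
    calls = find_insertions(carrier, ref)
    call = next(c for c in calls if c.host_gene is not None)
    hyp = splice_restoration(call, carrier, stranger)
    assert hyp.restored_identity == 0.0
    assert hyp.marker == "no_reference_homolog"


# ------------------------------------------------------------ internal ORFs

def _brute_orfs(segment, min_aa=50):
    """Independent six-frame enumeration: longest ORF per (strand, frame,
    stop), start codons ATG/GTG/TTG."""
    stops = {"TAA", "TAG", "TGA"}
    starts = {"ATG", "GTG", "TTG"}
    hits = []
    n = len(segment)
    for strand, s in (("+", segment), ("-", revcomp(segment))):
        for frame in range(3):
            last_boundary = frame  # scan start of the open stretch
            p = frame
            while p + 3 <= n:
                if s[p:p + 3] in stops:
                    q = last_boundary
                    while q < p and s[q:q + 3] not in starts:
                        q += 3
                    if q < p and (p - q) // 3 >= min_aa:
                        prot = translate_cds(s[q:p], initiator=True)
                        if strand == "+":
                            lo, hi = q + 1, p + 3
                        else:
                            lo, hi = n - (p + 3) + 1, n - q
                        hits.append((strand, lo, hi, prot, "LAGLIDADG" in prot))
                    last_boundary = p + 3
                p += 3
    return sorted(hits)


def test_orfs_empty_without_start_codon():
    assert find_internal_orfs("CCC" * 100) == []


def test_orfs_match_six_frame_oracle():
    rng = np.random.default_rng(37)
    for _ in range(30):
        seg = _rand_dna(rng, 500)
        got = sorted((h.strand, h.start, h.end, h.protein, h.has_laglidadg)
                     for h in find_internal_orfs(seg))
        assert got == _brute_orfs(seg)


# ------------------------------------------------------------------ inteins

def test_intein_absent_for_identical_proteins():
    rng = np.random.default_rng(38)
    p = "".join(rng.choice(list(AA), 400))
    assert detect_intein(p, p) is None


def test_intein_detected_at_planted_residue():
    rng = np.random.default_rng(39)
    ref = "".join(rng.choice(list(AA), 600))
    intein = "".join(rng.choice(list(AA), 340))
    carrier = ref[:103] + intein + ref[103:]
    call = detect_intein(carrier, ref)
    assert call is not None
    assert call.intein_len == 340
    assert abs(call.insertion_aa_start - 104) <= 3
    assert call.extein1_identity == 1.0 and call.extein2_identity == 1.0


def test_intein_extein_identities_track_divergence():
    rng = np.random.default_rng(40)
    ref = "".join(rng.choice(list(AA), 600))
    e1, e2 = list(ref[:103]), list(ref[103:])
    for i in rng.choice(len(e1), size=round(0.02 * len(e1)), replace=False):
        e1[i] = rng.choice([a for a in AA if a != e1[i]])
    for i in rng.choice(len(e2), size=round(0.03 * len(e2)), replace=False):
        e2[i] = rng.choice([a for a in AA if a != e2[i]])
    intein = "".join(rng.choice(list(AA), 340))
    carrier = "".join(e1) + intein + "".join(e2)
    call = detect_intein(carrier, ref)
    assert call.extein1_identity == pytest.approx(0.98, abs=0.015)
    assert call.extein2_identity == pytest.approx(0.97, abs=0.015)


# --------------------------------------------------------------------- TSDs

def _tsd_fixture(rng, d, elem_len=25, flank=30):
    """carrier = L T E T R / ref = L T R with unambiguous junctions."""
    while True:
        L = _rand_dna(rng, flank)
        T = _rand_dna(rng, d) if d else ""
        E = _rand_dna(rng, elem_len)
        R = _rand_dna(rng, flank)
        carrier = L + T + E + T + R
        ref = L + T + R
        ins_len = len(carrier) - len(ref)
        # locate the leftmost valid placement (oracle-style)
        placements = [x for x in range(1, len(carrier) - ins_len + 2)
                      if carrier[:x - 1] + carrier[x - 1 + ins_len:] == ref]
        if placements:
            s = placements[0]
            return carrier, ref, s, s + ins_len - 1


def _exhaustive_tsd(carrier, ref, start, end, max_tsd=15):
    """Oracle: enumerate excision placements against the literal reference."""
    L = end - start + 1
    best = (0, start, end)
    for d in range(min(max_tsd, L - 1), 0, -1):
        hits = []
        for x in range(max(d + 1, start - max_tsd), start + max_tsd + 1):
            if x + L - 1 > len(carrier):
                continue
            if carrier[:x - 1] + carrier[x - 1 + L:] != ref:
                continue
            if carrier[x - 1:x - 1 + d] == carrier[x + L - 1:x + L - 1 + d]:
                hits.append(x)
        if hits:
            x = min(hits)
            return (d, x + d, x + L - 1)
    return best


def test_tsd_recovers_printed_motif_structure():
    rng = np.random.default_rng(41)
    L = _rand_dna(rng, 200)
    R = "A" + _rand_dna(rng, 199)
    E = _rand_dna(rng, 60)
    # element edges differ from the junction context so the duplication is
    # exactly the 5-mer target motif
    E = "T" if R[0] != "T" else "A"
    E = E + _rand_dna(rng, 58) + ("T" if L[-1] != "T" else "A")
    carrier = GenomeRecord("c", L + "CACTG" + E + "CACTG" + R)
    ref = GenomeRecord("r", L + "CACTG" + R)
    s, e, _ = left_normalize(carrier.seq, 206, 206 + 65 - 1)
    from phagemosaic.mobile_elements import InsertionCall
    call = InsertionCall("c", "r", s, e,
                         evidence={"ref_after": s - 1, "ref_deleted_seq": ""})
    tsd = detect_tsd(call, carrier, ref)
    assert (tsd.tsd_len, tsd.tsd_seq) == (5, "CACTG")


def test_tsd_zero_for_precise_insertion():
    rng = np.random.default_rng(42)
    carrier, ref, s, e = _tsd_fixture(rng, d=0)
    from phagemosaic.mobile_elements import InsertionCall
    call = InsertionCall("c", "r", s, e,
                         evidence={"ref_after": s - 1, "ref_deleted_seq": ""})
    tsd = detect_tsd(call, GenomeRecord("c", carrier), GenomeRecord("r", ref))
    # a random precise junction may still show a short coincidental repeat,
    # but never one of 2 bp or more at this fixture's pinned-free sizes
    assert tsd.tsd_len <= 1


def test_tsd_matches_exhaustive_oracle():
    rng = np.random.default_rng(43)
    from phagemosaic.mobile_elements import InsertionCall
    for _ in range(150):
        d = int(rng.integers(0, 6))
        carrier, ref, s, e = _tsd_fixture(rng, d,
                                          elem_len=int(rng.integers(10, 30)),
                                          flank=int(rng.integers(18, 40)))
        call = InsertionCall("c", "r", s, e,
                             evidence={"ref_after": s - 1,
                                       "ref_deleted_seq": ""})
        got = detect_tsd(call, GenomeRecord("c", carrier),
                         GenomeRecord("r", ref))
        want = _exhaustive_tsd(carrier, ref, s, e)
        assert (got.tsd_len, got.element_start, got.element_end) == want


# ------------------------------------------------------ target reconstruction

def test_precise_and_deletion_associated_reconstruction(cohort):
    genomes, _, truth = cohort
    by_id = {g.id: g for g in genomes}
    for ev in truth.planted():
        if ev.kind != "endonuclease":
            continue
        carrier = by_id[ev.genome]
        refs = _closest_refs(genomes, truth, ev.genome)
        reps = consensus_scan(carrier, refs)
        want = left_normalize(carrier.seq, ev.start, ev.end)[:2]
        rep = next(r for r in reps if (r.call.start, r.call.end) == want)
        recon = rep.reconstruction
        d = ev.options["deletion_at_target"]
        if d:
            assert recon.kind == "deletion_associated"
            assert recon.deleted_bp == d
            # the detector reports the reference's allele of the lost bases;
            # it matches the carrier's historical copy up to divergence
            truth_del = ev.options["deleted_target"]
            mismatches = sum(1 for x, y in zip(recon.deleted_seq, truth_del)
                             if x != y)
            assert mismatches <= 10
        else:
            assert recon.kind == "precise"


def test_excision_restores_preinsertion_state():
    rng = np.random.default_rng(44)
    ref = GenomeRecord("ref", _rand_dna(rng, 6_000))
    ins = _rand_dna(rng, 200)
    carrier = GenomeRecord("car", ref.seq[:2500] + ins + ref.seq[2500:])
    call = find_insertions(carrier, ref)[0]
    assert excised_sequence(carrier, call) == ref.seq
    assert reconstruct_target(call, carrier, ref).kind == "precise"


# ----------------------------------------------------------- classification

def test_cohort_classification_confusion_is_diagonal(cohort):
    genomes, _, truth = cohort
    by_id = {g.id: g for g in genomes}
    for ev in truth.planted():
        carrier = by_id[ev.genome]
        refs = _closest_refs(genomes, truth, ev.genome)
        reps = consensus_scan(carrier, refs)
        want = left_normalize(carrier.seq, ev.start, ev.end)[:2]
        types = [r.call.type for r in reps
                 if (r.call.start, r.call.end) == want]
        assert types == [ev.kind]


# -------------------------------------------------------------- in-silico PCR

def test_pcr_product_shrinks_by_intron_length(cohort):
    genomes, _, truth = cohort
    by_id = {g.id: g for g in genomes}
    ev = next(e for e in truth.planted() if e.kind == "intron")
    g = by_id[ev.genome]
    fwd = g.seq[ev.start - 201:ev.start - 181]
    rev = revcomp(g.seq[ev.end + 180:ev.end + 200])
    res = insilico_pcr(g, fwd, rev, spliced_coords=(ev.start, ev.end))
    assert not res.ambiguous
    assert res.product_len - res.spliced_len == ev.end - ev.start + 1


def test_pcr_absent_primer_yields_no_product():
    g = generate_ancestor(10_000, 0.61, seed=45)
    res = insilico_pcr(g, "T" * 20, "A" * 20)
    assert res.ambiguous and res.product_len is None
    assert res.forward_sites == 0


def test_pcr_length_matches_arithmetic_oracle():
    rng = np.random.default_rng(46)
    g = generate_ancestor(10_000, 0.61, seed=47)
    f_start, r_end = 1001, 3500
    fwd = g.seq[f_start - 1:f_start - 1 + 22]
    rev = revcomp(g.seq[r_end - 22:r_end])
    res = insilico_pcr(g, fwd, rev)
    if not res.ambiguous:  # primers unique in this genome
        assert res.product_len == r_end - f_start + 1


def test_pcr_rejects_short_primers():
    g = generate_ancestor(5_000, 0.61, seed=48)
    with pytest.raises(ValueError):
        insilico_pcr(g, "ACGTACGT", "ACGTACGTACGTACGT")


def test_bed_writer_converts_to_half_open(tmp_path):
    from phagemosaic.mobile_elements import InsertionCall, write_calls_bed
    call = InsertionCall("car", "ref", 101, 200, type="intron")
    p = tmp_path / "calls.bed"
    write_calls_bed([call], p)
    assert p.read_text() == "car\t100\t200\tintron:vs:ref\n"
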