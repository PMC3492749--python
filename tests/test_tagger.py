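import random

import pytest

from conftest import seed_database
from rmlstkit.scheme import Allele, AlleleDatabase, Locus
from rmlstkit.search import Hit, SearchParams
from rmlstkit.seqs import has_internal_stop, reverse_complement, translate
from rmlstkit.synthgen import (ErrorModel, build_corpus, evolve_allele,
                               generate_scheme, saturate_synonymous)
from rmlstkit.tagger import (StringencySchedule, TagStatus, classify,
                             extract_cds, iterative_discovery, read_tags_table,
                             scan_isolate, tags_to_table)


def random_dna(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def full_hit(allele_seq, contig_offset, strand="+", locus="rpsB"):
    n = len(allele_seq)
    return Hit(locus, 1, "c1", contig_offset, contig_offset + n, 0, n,
               strand, 1.0, 1.0, n, float(n))


class TestExtractCds:
    def test_full_length_exact(self, small_scheme):
        scheme, ancestors = small_scheme
        seq = ancestors[scheme[0].name]
        rng = random.Random(0)
        contig = random_dna(rng, 50) + seq + random_dna(rng, 50)
        ext = extract_cds(full_hit(seq, 50), contig, len(seq))
        assert ext.sequence == seq
        assert not ext.truncated

    def test_partial_span_extended_to_allele_bounds(self, small_scheme):
        scheme, ancestors = small_scheme
        seq = ancestors[scheme[0].name]
        rng = random.Random(1)
        contig = random_dna(rng, 50) + seq + random_dna(rng, 50)
        # hit covering only allele bases [30, len-30)
        n = len(seq)
        hit = Hit("rpsB", 1, "c1", 80, 50 + n - 30, 30, n - 30, "+",
                  1.0, (n - 60) / n, n - 60, float(n - 60))
        ext = extract_cds(hit, contig, n)
        assert ext.sequence == seq

    def test_truncation_reported(self, small_scheme):
        scheme, ancestors = small_scheme
        seq = ancestors[scheme[0].name]
        # allele start lies 10 bp before the contig start
        contig = seq[10:] + "ACGTACGT"
        n = len(seq)
        hit = Hit("rpsB", 1, "c1", 0, n - 10, 10, n, "+",
                  1.0, (n - 10) / n, n - 10, float(n - 10))
        ext = extract_cds(hit, contig, n)
        assert ext.truncated
        assert ext.missing_start == 10
        assert ext.missing_end == 0

    def test_minus_strand_round_trip(self, small_scheme):
        scheme, ancestors = small_scheme
        seq = ancestors[scheme[0].name]
        rng = random.Random(2)
        contig = random_dna(rng, 40) + reverse_complement(seq) + random_dna(rng, 40)
        ext = extract_cds(full_hit(seq, 40, strand="-"), contig, len(seq))
        assert ext.sequence == seq


class TestClassify:
    def test_complete(self, small_db, small_scheme):
        scheme, ancestors = small_scheme
        seq = ancestors[scheme[0].name]
        from rmlstkit.tagger import Extraction
        hit = full_hit(seq, 0, locus=scheme[0].name)
        assert classify(hit, Extraction(seq), small_db) is TagStatus.COMPLETE

    def test_no_hit_is_missing(self, small_db):
        assert classify(None, None, small_db) is TagStatus.MISSING

    def test_truncated_is_partial(self, small_db, small_scheme):
        scheme, ancestors = small_scheme
        seq = ancestors[scheme[0].name]
        from rmlstkit.tagger import Extraction
        hit = full_hit(seq, 0, locus=scheme[0].name)
        ext = Extraction(seq[10:], missing_start=10)
        assert classify(hit, ext, small_db) is TagStatus.PARTIAL

    def test_homopolymer_deletion_is_pseudogene(self):
        # 1-bp deletion in an AAAA run shifts the frame so the downstream
        # TAA lands in frame 0 before the end (checked with the oracle)
        intact = "ATG" + "AAAA" + "TAA" + "CCC" + "TT"
        slipped = intact[:4] + intact[5:]   # drop one A from the run
        assert len(slipped) % 3 != 0
        db = AlleleDatabase()
        db.add_locus(Locus("rpsB", 6, 1000))
        hit = full_hit(slipped, 0)
        from rmlstkit.tagger import Extraction
        assert classify(hit, Extraction(slipped), db) is TagStatus.PSEUDOGENE
        # translation oracle on the shifted frame: a stop appears early
        assert "*" in translate(slipped)[:-1]


class TestScanIsolate:
    def test_all_exact_loci_complete(self, small_scheme, small_db, small_corpus):
        scheme, _ = small_scheme
        tags = scan_isolate("iso001", small_corpus.genomes["iso001"], small_db)
        primary = [t for t in tags if not t.paralogue]
        assert len(primary) == len(scheme)
        assert all(t.status is TagStatus.COMPLETE for t in primary)
        assert all(t.allele_id == 1 for t in primary)

    def test_missing_locus(self, small_scheme):
        scheme, ancestors = small_scheme
        db = seed_database(scheme, ancestors)
        gone = scheme[3].name
        corpus = build_corpus(scheme, ancestors, 1, seed=77, error_models={
            "iso001": ErrorModel(missing_loci=frozenset({gone}))})
        tags = scan_isolate("iso001", corpus.genomes["iso001"], db)
        by_locus = {t.locus: t for t in tags if not t.paralogue}
        assert by_locus[gone].status is TagStatus.MISSING
        others = [t for name, t in by_locus.items() if name != gone]
        assert all(t.status is TagStatus.COMPLETE for t in others)

    def test_paralogue_secondary_tag(self, small_scheme):
        scheme, ancestors = small_scheme
        db = seed_database(scheme, ancestors)
        name = scheme[0].name
        seq = ancestors[name]
        copy = evolve_allele(seq, 12, "any", seed=5)
        rng = random.Random(6)
        contig = (random_dna(rng, 100) + seq + random_dna(rng, 100)
                  + copy + random_dna(rng, 100))
        tags = scan_isolate("isoP", {"c1": contig}, db, loci=[name])
        primary = [t for t in tags if not t.paralogue]
        secondary = [t for t in tags if t.paralogue]
        assert len(primary) == 1 and primary[0].status is TagStatus.COMPLETE
        assert len(secondary) == 1
        assert secondary[0].locus == name


class TestIterativeDiscovery:
    def test_fixpoint_at_start(self, small_scheme, small_corpus):
        scheme, ancestors = small_scheme
        db = seed_database(scheme, ancestors)
        before = db.allele_count()
        result = iterative_discovery(small_corpus.genomes, db)
        assert result.db.allele_count() == before
        level_one = [r for r in result.rounds if r.level == 0.70
                     and r.phase == "nucleotide"]
        assert level_one[0].new_alleles == 0

    def test_divergent_pair_doubles_database(self, small_scheme):
        scheme, ancestors = small_scheme
        db = seed_database(scheme, ancestors)
        n_loci = len(scheme)
        # genome B carries ~10% diverged variants of every locus
        div = {"iso001": 0, "iso002": None}
        corpus = build_corpus(
            scheme, ancestors, 2, seed=9,
            divergence={"iso001": 0,
                        "iso002": 30})
        result = iterative_discovery(corpus.genomes, db)
        statuses = [t.status for ts in result.tags.values() for t in ts
                    if not t.paralogue]
        assert all(s is TagStatus.COMPLETE for s in statuses)
        assert result.db.allele_count() == 2 * n_loci
        first = result.rounds[0]
        assert first.phase == "nucleotide" and first.level == 0.70

    def test_synonymous_saturated_found_in_translated_phase(self, small_scheme):
        scheme, ancestors = small_scheme
        db = seed_database(scheme, ancestors)
        saturated = {n: saturate_synonymous(s, seed=13)
                     for n, s in ancestors.items()}
        corpus = build_corpus(scheme, saturated, 1, seed=13)
        result = iterative_discovery(corpus.genomes, db)
        for tag in result.tags["iso001"]:
            if tag.paralogue:
                continue
            assert tag.status is TagStatus.COMPLETE
            assert tag.phase == "translated"
        phases = [r.phase for r in result.rounds if r.new_alleles > 0]
        assert set(phases) == {"translated"}

    def test_round_log_monotone(self, small_scheme):
        scheme, ancestors = small_scheme
        db = seed_database(scheme, ancestors)
        corpus = build_corpus(scheme, ancestors, 2, seed=21,
                              divergence={"iso001": 0, "iso002": 20})
        result = iterative_discovery(corpus.genomes, db)
        # stringency never rises within a phase; untagged never increases
        for prev, cur in zip(result.rounds, result.rounds[1:]):
            if prev.phase == cur.phase:
                assert cur.level <= prev.level
            assert cur.untagged_after <= prev.untagged_after

    def test_removing_one_locus_changes_only_that_tag(self, small_scheme):
        scheme, ancestors = small_scheme
        gone = scheme[2].name
        base = build_corpus(scheme, ancestors, 1, seed=31)
        dropped = build_corpus(scheme, ancestors, 1, seed=31, error_models={
            "iso001": ErrorModel(missing_loci=frozenset({gone}))})
        res_a = iterative_discovery(base.genomes,
                                    seed_database(scheme, ancestors))
        res_b = iterative_discovery(dropped.genomes,
                                    seed_database(scheme, ancestors))
        tags_a = {t.locus: t.status for t in res_a.tags["iso001"]
                  if not t.paralogue}
        tags_b = {t.locus: t.status for t in res_b.tags["iso001"]
                  if not t.paralogue}
        assert tags_b.pop(gone) is TagStatus.MISSING
        assert tags_a.pop(gone) is TagStatus.COMPLETE
        assert tags_a == tags_b


def test_tags_table_round_trip(small_scheme, small_db, small_corpus):
    tags = scan_isolate("iso001", small_corpus.genomes["iso001"], small_db)
    table = tags_to_table(tags)
    parsed = read_tags_table(table)
    assert len(parsed) == len(tags)
    for original, back in zip(tags, parsed):
        assert (back.isolate_id, back.locus, back.status, back.allele_id,
                back.contig_id, back.contig_start, back.contig_end,
                back.strand, back.flags) == (
            original.isolate_id, original.locus, original.status,
            original.allele_id, original.contig_id, original.contig_start,
            original.contig_end, original.strand, original.flags)


def test_schedule_levels():
    schedule = StringencySchedule()
    assert schedule.levels() == [0.70, 0.65, 0.60, 0.55, 0.50]
    with pytest.raises(ValueError):
        StringencySchedule(start_identity=0.4, floor=0.5)
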