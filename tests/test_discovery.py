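"""Conserved miRNA calling, family grouping and star-pair detection."""

import random

import pytest

from mirmeta.discovery import (ConservedHit, MatureMiRNA, StarCall,
                               aggregate_expression, assign_families,
                               classify_star_conservation, detect_star_pairs,
                               match_conserved, parse_mirna_name)
from mirmeta.preprocess import UniqueRead, apply_filters, collapse_reads, retained
from mirmeta.simulate import revcomp

MATURE = "UGGAAUGUAAAGAAGUAUGUAU"       # 22 nt


def reads_of(*seq_count):
    return [UniqueRead(sequence=s, count=c) for s, c in seq_count]


def catalog_of(*name_seq):
    return [MatureMiRNA.from_name(n, s) for n, s in name_seq]


def sub(seq, pos, base):
    """1-based substitution."""
    assert seq[pos - 1] != base
    return seq[: pos - 1] + base + seq[pos:]


def hamming_oracle(read, catalog, max_mm=1):
    """Brute-force all-offset Hamming scan (overhangs free, seed exact)."""
    best = None
    for mat in catalog:
        m = mat.sequence
        if abs(len(read) - len(m)) > 2:
            continue
        for off in range(-2, len(m) - len(read) + 3):
            lo, hi = max(0, off), min(len(m), off + len(read))
            if hi <= lo or not (lo <= 1 and 8 <= hi):
                continue
            pairs = [(m[i], read[i - off]) for i in range(lo, hi)]
            seed = all(a == b for a, b in pairs[1 - lo: 8 - lo])
            mm = sum(a != b for a, b in pairs)
            if seed and mm <= max_mm and (best is None or mm < best[0]):
                best = (mm, mat.name)
    return best


class TestMatchConserved:
    def test_identical_read_is_zero_mismatch_hit(self):
        (hit,) = match_conserved(reads_of((MATURE, 5)),
                                 catalog_of(("dre-miR-1", MATURE)))
        assert hit.mismatches == 0 and hit.seed_exact

    def test_one_mismatch_outside_seed_assigned(self):
        read = sub(MATURE, 12, "C")
        (hit,) = match_conserved(reads_of((read, 5)),
                                 catalog_of(("dre-miR-1", MATURE)))
        assert hit.mismatches == 1 and hit.mature_name == "dre-miR-1"

    def test_seed_mismatch_rejected(self):
        read = sub(MATURE, 4, "C")           # seed spans positions 2-8
        assert match_conserved(reads_of((read, 5)),
                               catalog_of(("dre-miR-1", MATURE))) == []

    def test_two_mismatches_rejected(self):
        read = sub(sub(MATURE, 12, "C"), 15, "C")
        assert match_conserved(reads_of((read, 5)),
                               catalog_of(("dre-miR-1", MATURE))) == []

    def test_isomir_end_variation_tolerated(self):
        (hit,) = match_conserved(reads_of((MATURE[:-2], 5)),
                                 catalog_of(("dre-miR-1", MATURE)))
        assert hit.mismatches == 0
        assert hit.overlap_score == pytest.approx(1.0)

    def test_read_outside_discovery_window_ignored(self):
        assert match_conserved(reads_of((MATURE[:15], 5)),
                               catalog_of(("dre-miR-1", MATURE[:15]))) == []

    def test_species_priority_breaks_ties(self):
        catalog = catalog_of(("hsa-miR-1", MATURE), ("dre-miR-1", MATURE))
        (hit,) = match_conserved(reads_of((MATURE, 1)), catalog)
        assert hit.mature_name == "dre-miR-1"

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError):
            match_conserved(reads_of((MATURE, 1)), [])

    def test_agrees_with_brute_force_hamming_oracle(self):
        rng = random.Random(23)
        catalog = []
        for i in range(60):
            seq = "".join(rng.choice("ACGU") for _ in range(22))
            catalog.append(MatureMiRNA.from_name(f"dre-miR-{i + 100}", seq))
        reads = []
        for _ in range(40):
            base = catalog[rng.randrange(len(catalog))].sequence
            seq = list(base)
            for _ in range(rng.randrange(3)):
                p = rng.randrange(22)
                seq[p] = rng.choice([b for b in "ACGU" if b != seq[p]])
            reads.append(UniqueRead(sequence="".join(seq), count=1))
        hits = {h.sequence: h for h in match_conserved(reads, catalog)}
        for read in reads:
            oracle = hamming_oracle(read.sequence, catalog)
            if oracle is None:
                assert read.sequence not in hits
            else:
                assert read.sequence in hits
                assert hits[read.sequence].mismatches == oracle[0]

    def test_every_hit_within_hamming_distance_one(self, clean_library):
        catalog = [MatureMiRNA(name=p.name, sequence=p.mature_seq)
                   for p in clean_library["precursors"]]
        reads = retained(apply_filters(collapse_reads(clean_library["fastq"])))
        hits = match_conserved(reads, catalog)
        assert hits
        by_name = {m.name: m.sequence for m in catalog}
        for h in hits:
            m = by_name[h.mature_name]
            lo, hi = max(0, h.offset), min(len(m), h.offset + len(h.sequence))
            mm = sum(m[i] != h.sequence[i - h.offset] for i in range(lo, hi))
            assert mm == h.mismatches <= 1


class TestAggregate:
    def test_counts_sum_and_high_flag(self):
        hits = [ConservedHit("A" * 22, 9000, "mir-1", 0, 0, 1.0),
                ConservedHit("C" * 22, 2000, "mir-1", 0, 0, 1.0)]
        df = aggregate_expression(hits)
        row = df.set_index("mirna").loc["mir-1"]
        assert row["reads"] == 11000 and row["high_expression"]

    def test_exactly_10000_not_flagged(self):
        hits = [ConservedHit("A" * 22, 10000, "mir-1", 0, 0, 1.0)]
        assert not aggregate_expression(hits)["high_expression"].item()

    def test_no_hits_empty_table(self):
        assert aggregate_expression([]).empty

    def test_total_count_conserved(self):
        hits = [ConservedHit(f"{b}" * 22, c, n, 0, 0, 1.0)
                for b, c, n in [("A", 10, "mir-1"), ("C", 20, "mir-1"),
                                ("G", 5, "mir-2")]]
        assert aggregate_expression(hits)["reads"].sum() == 35


class TestFamilies:
    def test_let7_family_of_ten(self):
        names = [f"let-7{c}" for c in "abcdefghij"]
        df = assign_families(names)
        assert (df["family"] == "let-7").all()
        assert (df["family_size"] == 10).all()

    def test_locus_copies_collapse(self):
        df = assign_families(["pol-mir-199-1", "pol-mir-199-2"])
        assert (df["family"] == "mir-199").all()
        assert (df["family_size"] == 2).all()

    def test_singleton_family(self):
        df = assign_families(["mir-722"])
        assert df["family"].item() == "mir-722"
        assert df["family_size"].item() == 1

    def test_unparseable_name_flagged_not_fatal(self):
        df = assign_families(["not-a-mirna!"])
        assert df["family"].item() == "none"
        assert not df["parsed"].item()

    @pytest.mark.parametrize("name,species,family", [
        ("dre-miR-22a", "dre", "mir-22"),
        ("pol-let-7b", "pol", "let-7"),
        ("mir-133b-3p", None, "mir-133"),
        ("hsa-miR-124-5p", "hsa", "mir-124"),
    ])
    def test_name_parsing(self, name, species, family):
        assert parse_mirna_name(name) == (species, family)


class TestStarPairs:
    def test_planted_star_detected_on_opposite_arm(self):
        from mirmeta.table1 import Precursor

        mature = "UGGAAUGUAAAGAAGUAUGUAU"
        star = revcomp(mature)
        seq = mature + "GCAACAAGGA" + star
        pre = Precursor(name="p1", sequence=seq, mature=(1, 22),
                        star=(33, 54), source="synthetic")
        (call,) = detect_star_pairs(reads_of((star, 8)), [pre])
        assert call.arm == "3p" and call.sequence == star
        assert call.paired_with_mature >= 10

    def test_reads_on_mature_arm_only_yield_nothing(self):
        from mirmeta.table1 import Precursor

        mature = "UGGAAUGUAAAGAAGUAUGUAU"
        seq = mature + "GCAACAAGGA" + revcomp(mature)
        pre = Precursor(name="p1", sequence=seq, mature=(1, 22),
                        star=(33, 54), source="synthetic")
        assert detect_star_pairs(reads_of((mature, 8)), [pre]) == []

    def test_unfoldable_precursor_skipped_with_warning(self, caplog):
        import logging

        from mirmeta.table1 import Precursor

        pre = Precursor(name="flat", sequence="A" * 60, mature=(1, 22),
                        star=(31, 52), source="synthetic")
        with caplog.at_level(logging.WARNING):
            assert detect_star_pairs(reads_of(("A" * 20, 3)), [pre]) == []
        assert "does not fold" in caplog.text

    def test_most_abundant_star_wins(self):
        from mirmeta.table1 import Precursor

        mature = "UGGAAUGUAAAGAAGUAUGUAU"
        star = revcomp(mature)
        seq = mature + "GCAACAAGGA" + star
        pre = Precursor(name="p1", sequence=seq, mature=(1, 22),
                        star=(33, 54), source="synthetic")
        minor, major = star[:20], star
        (call,) = detect_star_pairs(reads_of((minor, 2), (major, 9)), [pre])
        assert call.sequence == major

    def test_zero_noise_recovery_complete_and_clean(self, clean_library):
        """Every sampled planted star recovered; no spurious calls."""
        reads = collapse_reads(clean_library["fastq"])
        precursors = clean_library["precursors"]
        calls = detect_star_pairs(reads, precursors)
        truth = clean_library["read_truth"]
        sampled = set(truth[truth["origin"] == "star"]["source"])
        planted = {p.name: p.star_seq for p in precursors}
        assert {c.precursor for c in calls} == sampled
        for c in calls:
            assert c.sequence == planted[c.precursor]


class TestStarConservation:
    def known(self):
        return [MatureMiRNA(name="dre-miR-1-star",
                            sequence="ACAUACUUCUUUAUAUGCCCAU")]

    def call_with(self, seq):
        return StarCall(precursor="p", sequence=seq, count=3, arm="5p",
                        start=1, paired_with_mature=12)

    def test_identical_star_conserved(self):
        (out,) = classify_star_conservation(
            [self.call_with("ACAUACUUCUUUAUAUGCCCAU")], self.known())
        assert out.status == "conserved" and out.mismatches_to_known == 0

    def test_three_mismatches_still_conserved(self):
        seq = sub(sub(sub("ACAUACUUCUUUAUAUGCCCAU", 3, "G"), 9, "G"), 15, "C")
        (out,) = classify_star_conservation([self.call_with(seq)], self.known())
        assert out.status == "conserved" and out.mismatches_to_known == 3

    def test_four_mismatches_need_validation(self):
        seq = "ACAUACUUCUUUAUAUGCCCAU"
        for pos in (3, 9, 15, 20):
            seq = sub(seq, pos, "G")
        (out,) = classify_star_conservation([self.call_with(seq)], self.known())
        assert out.status == "needs-validation"

    def test_empty_catalog_all_need_validation(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            (out,) = classify_star_conservation(
                [self.call_with("ACAUACUUCUUUAUAUGCCCAU")], [])
        assert out.status == "needs-validation"
        assert "empty" in caplog.text
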