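"""Majority-vote consensus assembly, classification and copy recovery."""

import numpy as np
import pytest

from helpers import best_orientation_identity
from repeatburst.alphabet import random_sequence, revcomp
from repeatburst.assembler import (
    assemble_consensus,
    classify_consensus,
    recover_copies,
)
from repeatburst.errors import InputError
from repeatburst.kmers import KmerTable, count_kmers
from repeatburst.simulate import TEFamilySpec, plant_copies_in_genome, simulate_te_copies


class TestAssemble:
    def test_single_planted_family_recovered(self, planted_single_family):
        fam, genome, _ = planted_single_family
        cons = assemble_consensus(count_kmers(genome, 25), min_count=10)
        assert len(cons) == 1
        st = best_orientation_identity(cons[0].sequence, fam.master)
        assert st.identity >= 0.99
        assert st.coverage(cons[0].length, len(fam.master))[1] >= 0.95

    def test_all_singletons_yield_nothing(self):
        genome = random_sequence(20000, np.random.default_rng(1))
        table = count_kmers(genome, 25)
        assert max(table.counts.values()) < 3  # unique background
        assert assemble_consensus(table, min_count=3, min_length=100) == []

    def test_two_families_two_consensuses(self):
        fams = [
            simulate_te_copies(TEFamilySpec(f"fam{i}", 1500, [0.0], [30], 0.3), seed=i)
            for i in (1, 2)
        ]
        copies = fams[0].copies + fams[1].copies
        ids = ["fam1"] * 30 + ["fam2"] * 30
        genome, _ = plant_copies_in_genome(200000, copies, seed=3, family_ids=ids)
        cons = assemble_consensus(count_kmers(genome, 25), min_count=10)
        assert len(cons) == 2
        matched = set()
        for c in cons:
            for fam in fams:
                st = best_orientation_identity(c.sequence, fam.master)
                if st.identity >= 0.99 and st.columns >= 0.9 * len(fam.master):
                    matched.add(fam.spec.family_id)
        assert matched == {"fam1", "fam2"}

    def test_deterministic_given_table(self, planted_single_family):
        _, genome, _ = planted_single_family
        table = count_kmers(genome, 25)
        a = assemble_consensus(table, min_count=10)
        b = assemble_consensus(table, min_count=10)
        assert [c.sequence for c in a] == [c.sequence for c in b]

    def test_min_count_floor(self):
        with pytest.raises(InputError):
            assemble_consensus(KmerTable(25, {"A" * 25: 5}), min_count=1)


class TestClassify:
    def test_self_match(self, planted_single_family):
        fam, _, _ = planted_single_family
        label, stats = classify_consensus(
            fam.master, {"famA": fam.master, "other": random_sequence(2000, np.random.default_rng(0))}
        )
        assert label == "famA"
        assert stats.identity == 1.0

    def test_longest_alignment_beats_higher_identity(self, rng):
        # refA shares a 1.5 kb block at ~90% identity; refB a 0.8 kb block
        # at ~99%: the longest qualifying alignment wins.
        core = random_sequence(3000, rng)
        blockA = core[:1500]
        blockB = core[1800:2600]

        def mutate(s, p, r):
            out = list(s)
            for i in np.where(r.random(len(s)) < p)[0]:
                out[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[i]]
            return "".join(out)

        refA = random_sequence(400, rng) + mutate(blockA, 0.10, rng) + random_sequence(400, rng)
        refB = random_sequence(400, rng) + mutate(blockB, 0.01, rng) + random_sequence(400, rng)
        label, stats = classify_consensus(core, {"refA": refA, "refB": refB}, min_align_length=500)
        assert label == "refA"
        assert stats.columns >= 1400

    def test_unrelated_is_unknown(self, rng):
        label, stats = classify_consensus(
            random_sequence(2000, rng), {"ref": random_sequence(2000, rng)}
        )
        assert label == "unknown" and stats is None

    def test_empty_library_rejected(self):
        with pytest.raises(InputError):
            classify_consensus("ACGT" * 500, {})


class TestRecover:
    def test_planted_copies_recovered_exactly(self, planted_single_family):
        fam, genome, truth = planted_single_family
        copies = recover_copies(genome, fam.master, min_identity=0.7, min_length=1000)
        assert len(copies) == len(truth.copy_coordinates)
        recovered = {(c.start, c.end) for c in copies}
        for t in truth.copy_coordinates:
            # >= 95% reciprocal overlap with some recovered interval
            assert any(
                min(e, t.end) - max(s, t.start) >= 0.95 * max(e - s, t.end - t.start)
                for s, e in recovered
            )

    def test_minus_strand_round_trip(self, planted_single_family):
        fam, genome, truth = planted_single_family
        copies = recover_copies(genome, fam.master, min_identity=0.7, min_length=1000)
        by_start = {c.start: c for c in copies}
        for t in truth.copy_coordinates:
            c = by_start[t.start]
            assert c.strand == t.strand
            assert c.sequence == fam.master  # consensus orientation, exact copies

    def test_absent_consensus_empty(self, rng):
        genome = {"chr": random_sequence(50000, rng)}
        assert recover_copies(genome, random_sequence(1500, rng)) == []

    def test_threshold_monotonicity(self):
        spec = TEFamilySpec("f", 1500, [1.0], [12], 0.12, model="star")
        fam = simulate_te_copies(spec, seed=4)
        genome, _ = plant_copies_in_genome(60000, fam.copies, seed=5)
        loose = recover_copies(genome, fam.master, min_identity=0.7, min_length=1000)
        strict = recover_copies(genome, fam.master, min_identity=0.9, min_length=1000)
        loose_keys = {(c.start, c.end) for c in loose}
        assert all((c.start, c.end) in loose_keys for c in strict)
        assert len(strict) <= len(loose)

    def test_short_consensus_rejected(self, rng):
        with pytest.raises(InputError):
            recover_copies({"c": random_sequence(5000, rng)}, "ACGT" * 100, min_length=1000)
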