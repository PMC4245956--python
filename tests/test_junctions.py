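"""Junction characterization: microhomology, insertions, flanks, filtering."""

import numpy as np
import pytest

from amprearr import junctions as jx, simulate
from amprearr.model import Breakend, Interval, Junction, Orientation, revcomp
from conftest import mh_shift_oracle, random_junction

LEFT = Orientation.LEFT_RETAINED
RIGHT = Orientation.RIGHT_RETAINED


def _genome_with_flanks(kept_a, cont_a, pre_b, kept_b, pad=60):
    """Two contigs built so a LEFT@len(pad+kept_a) / RIGHT@pad+1 junction has
    exactly the given flank strings."""
    rng = np.random.default_rng(9)

    def rand(n):
        return "".join(rng.choice(list("ACGT"), size=n))

    c1 = rand(pad) + kept_a + cont_a + rand(pad)
    c2 = rand(pad - len(pre_b)) + pre_b + kept_b + rand(pad)
    j = Junction(
        id="t",
        arm_a=Breakend("c1", pad + len(kept_a), LEFT),
        arm_b=Breakend("c2", pad + 1, RIGHT),
    )
    return {"c1": c1, "c2": c2}, j


class TestMicrohomology:
    def test_right_extension_only(self):
        # continuation past A starts "AC...", B starts "AC..." but diverges
        # at the third base; left side shares nothing
        genome, j = _genome_with_flanks(
            kept_a="TTTT", cont_a="ACGGGGG", pre_b="CCCC", kept_b="ACTTTTT"
        )
        # ensure constructions do not accidentally share a left-side base
        assert genome["c1"][:1] != ""
        mh = jx.microhomology_at(j, genome)
        assert (mh.left, mh.right) == (0, 2)

    def test_no_shared_bases(self):
        genome, j = _genome_with_flanks(
            kept_a="AAAA", cont_a="CCCCC", pre_b="GGGG", kept_b="TTTTT"
        )
        mh = jx.microhomology_at(j, genome)
        assert (mh.left, mh.right) == (0, 0)

    def test_two_sided(self):
        genome, j = _genome_with_flanks(
            kept_a="AACGT", cont_a="TTAAC", pre_b="AACGT", kept_b="TTGCC"
        )
        mh = jx.microhomology_at(j, genome)
        assert (mh.left, mh.right) == (5, 2)

    def test_matches_shift_oracle_on_simulated_junctions(self, genome_2x10kb):
        """The prefix-matching caller equals exhaustive breakpoint-shift
        enumeration on 500 random junctions of every orientation pattern."""
        rng = np.random.default_rng(1234)
        for _ in range(500):
            j = random_junction(rng, genome_2x10kb)
            mh = jx.microhomology_at(j, genome_2x10kb, max_window=12)
            assert (mh.left, mh.right) == mh_shift_oracle(j, genome_2x10kb)

    def test_revcomp_genome_invariance(self, genome_2x10kb):
        """Reverse-complementing the genome and flipping orientations leaves
        the total microhomology invariant."""
        rng = np.random.default_rng(77)
        flipped_genome = {c: revcomp(s) for c, s in genome_2x10kb.items()}

        def flip(be):
            chrom_len = len(genome_2x10kb[be.chrom])
            orient = RIGHT if be.orient is LEFT else LEFT
            return Breakend(be.chrom, chrom_len - be.pos + 1, orient)

        for _ in range(100):
            j = random_junction(rng, genome_2x10kb)
            jf = Junction(id=j.id, arm_a=flip(j.arm_a), arm_b=flip(j.arm_b))
            assert (
                jx.microhomology_at(j, genome_2x10kb).total
                == jx.microhomology_at(jf, flipped_genome).total
            )

    def test_truncated_window_flagged(self):
        genome = {"c1": "ACGTACGTAC" * 10, "c2": "TTGCATCGGA" * 10}
        j = Junction(
            id="edge",
            arm_a=Breakend("c1", 5, LEFT),  # within max_window of contig start
            arm_b=Breakend("c2", 50, RIGHT),
        )
        assert jx.microhomology_at(j, genome, max_window=50).truncated


class TestFiltering:
    amplified = [Interval("c1", 100, 200)]

    def make(self, support, pos_a=150, pos_b=500):
        return Junction(
            id="j",
            arm_a=Breakend("c1", pos_a, LEFT),
            arm_b=Breakend("c1", pos_b, RIGHT),
            support=support,
        )

    def test_support_threshold_is_more_than_two(self):
        assert jx.filter_junctions([self.make(2)], amplified=self.amplified) == []
        kept = jx.filter_junctions([self.make(3)], amplified=self.amplified)
        assert len(kept) == 1

    def test_both_arms_outside_removed(self):
        j = self.make(9, pos_a=500, pos_b=700)
        assert jx.filter_junctions([j], amplified=self.amplified) == []

    def test_one_arm_inside_suffices(self):
        j = self.make(9, pos_a=500, pos_b=150)
        assert len(jx.filter_junctions([j], amplified=self.amplified)) == 1


class TestInsertionCalling:
    def test_constructed_insertion(self, genome_2x10kb):
        j = Junction(
            id="i1",
            arm_a=Breakend("c1", 5000, LEFT),
            arm_b=Breakend("c2", 3000, RIGHT),
        )
        A = genome_2x10kb["c1"][5000 - 40 : 5000]
        B = genome_2x10kb["c2"][3000 - 1 : 3000 - 1 + 40]
        j.span_seq = A + "GGTAC" + B
        length, seq = jx.call_insertion(j, genome_2x10kb)
        assert (length, seq) == (5, "GGTAC")

    def test_flush_seam(self, genome_2x10kb):
        j = Junction(
            id="i2",
            arm_a=Breakend("c1", 5000, LEFT),
            arm_b=Breakend("c2", 3000, RIGHT),
        )
        A = genome_2x10kb["c1"][5000 - 40 : 5000]
        B = genome_2x10kb["c2"][3000 - 1 : 3000 - 1 + 40]
        j.span_seq = A + B
        assert jx.call_insertion(j, genome_2x10kb) == (0, "")

    def test_unanchored_raises(self, genome_2x10kb):
        j = Junction(
            id="i3",
            arm_a=Breakend("c1", 5000, LEFT),
            arm_b=Breakend("c2", 3000, RIGHT),
            span_seq="A" * 60,
        )
        with pytest.raises(jx.UnanchoredJunction):
            jx.call_insertion(j, genome_2x10kb)

    def test_simulated_insertions_match_truth(self):
        cfg = simulate.SimConfig(p_insertion=0.5, seed=8)
        truth = simulate.simulate_amplicon(cfg)
        obs = simulate.emit_observables(truth)
        assert any(j.inserted_seq for j in truth.joins)
        for join, oj in zip(truth.joins, obs.junctions):
            length, seq = jx.call_insertion(oj, truth.genome)
            assert seq == join.inserted_seq
            assert length == len(join.inserted_seq)

    def test_mh_and_insertion_mutually_exclusive(self):
        cfg = simulate.SimConfig(p_insertion=0.4, seed=13)
        truth = simulate.simulate_amplicon(cfg)
        obs = simulate.emit_observables(truth)
        for oj in obs.junctions:
            call = jx.characterize_junction(oj, truth.genome)
            assert not (call.mh_len > 0 and call.insertion_len > 0)


class TestTemplateSearch:
    def test_verbatim_copy_found(self, genome_2x10kb):
        j = Junction(
            id="t1",
            arm_a=Breakend("c1", 5000, LEFT),
            arm_b=Breakend("c2", 3000, RIGHT),
        )
        insert = genome_2x10kb["c1"][4800 - 1 : 4800 - 1 + 30]  # 200 bp upstream
        res = jx.search_insert_template(insert, genome_2x10kb, j, flank_window=500)
        assert res.searched
        assert any(h.identity == 1.0 and h.chrom == "c1" for h in res.hits)

    def test_random_insert_no_hits_over_seeds(self):
        """A random 30-mer against random 1 kb flanks essentially never
        reaches 90% identity; assert over 100 seeds."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            genome = {
                "a": "".join(rng.choice(list("ACGT"), size=2000)),
                "b": "".join(rng.choice(list("ACGT"), size=2000)),
            }
            j = Junction(
                id="t", arm_a=Breakend("a", 1000, LEFT), arm_b=Breakend("b", 1000, RIGHT)
            )
            insert = "".join(rng.choice(list("ACGT"), size=30))
            res = jx.search_insert_template(insert, genome, j, flank_window=900)
            assert res.hits == []

    def test_short_insert_flagged_not_searched(self, genome_2x10kb):
        j = Junction(
            id="t", arm_a=Breakend("c1", 500, LEFT), arm_b=Breakend("c2", 500, RIGHT)
        )
        res = jx.search_insert_template("ACGTACGT", genome_2x10kb, j)
        assert not res.searched and res.hits == []


class TestFlankVariants:
    def _span(self, genome, j, mutate=None):
        A = genome[j.arm_a.chrom][j.arm_a.pos - 50 : j.arm_a.pos]
        B = genome[j.arm_b.chrom][j.arm_b.pos - 1 : j.arm_b.pos - 1 + 50]
        if mutate:
            A, B = mutate(A, B)
        return A + B

    def _junction(self):
        return Junction(
            id="v", arm_a=Breakend("c1", 5000, LEFT), arm_b=Breakend("c2", 3000, RIGHT)
        )

    def test_identical_flanks_no_variants(self, genome_2x10kb):
        j = self._junction()
        j.span_seq = self._span(genome_2x10kb, j)
        assert jx.scan_flank_variants(j, genome_2x10kb) == []

    def test_substitution_classified_transition(self, genome_2x10kb):
        j = self._junction()

        def mutate(A, B):
            # force a G at offset -10 then observe A there
            lst = list(A)
            lst[-10] = {"G": "A", "A": "G", "C": "T", "T": "C"}[lst[-10]]
            return "".join(lst), B

        j.span_seq = self._span(genome_2x10kb, j, mutate)
        variants = jx.scan_flank_variants(j, genome_2x10kb)
        assert len(variants) == 1
        v = variants[0]
        assert v.kind == "substitution"
        assert v.klass == "transition"
        assert v.offset == -10

    def test_planted_deletion_reported_with_length(self, genome_2x10kb):
        j = self._junction()

        def mutate(A, B):
            return A[:20] + A[22:], B  # 2 bp deletion in the a-side flank

        j.span_seq = self._span(genome_2x10kb, j, mutate)
        variants = jx.scan_flank_variants(j, genome_2x10kb)
        deletions = [v for v in variants if v.kind == "deletion"]
        assert len(deletions) == 1
        assert deletions[0].length == 2

    def test_ambiguity_codes_rejected(self):
        with pytest.raises(ValueError, match="ambiguity"):
            jx.classify_substitution("N", "A")


class TestSummary:
    def test_all_blunt(self, genome_2x10kb):
        calls = [
            jx.JunctionCall(junction=None, mh_left=0, mh_right=0) for _ in range(5)
        ]
        for c in calls:
            c.junction = Junction(
                id="x", arm_a=Breakend("c1", 10, LEFT), arm_b=Breakend("c1", 99, RIGHT)
            )
        s = jx.junction_summary(calls)
        assert s["fraction_blunt"] == 1.0
        assert s["fraction_mh_insertion_free"] == 0.0

    def test_explicit_denominators(self):
        j = Junction(id="x", arm_a=Breakend("c1", 10, LEFT), arm_b=Breakend("c1", 99, RIGHT))
        calls = [
            jx.JunctionCall(junction=j, mh_left=1, mh_right=0),
            jx.JunctionCall(junction=j, mh_left=0, mh_right=0),
            jx.JunctionCall(junction=j, insertion_len=4, inserted_seq="ACGT"),
        ]
        s = jx.junction_summary(calls)
        assert s["n_insertion_free"] == 2
        assert s["fraction_mh_insertion_free"] == pytest.approx(0.5)
        assert s["fraction_mh_all"] == pytest.approx(1 / 3)
        assert s["fraction_with_insertion"] == pytest.approx(1 / 3)
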