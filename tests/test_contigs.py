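"""Arm links, contig assembly and coordinated-pair detection."""

import numpy as np
import pytest

from amprearr import contigs as cg, oda14, simulate
from amprearr.model import Breakend, Interval, Junction, Orientation

LEFT = Orientation.LEFT_RETAINED
RIGHT = Orientation.RIGHT_RETAINED


def J(jid, a, b):
    return Junction(id=jid, arm_a=a, arm_b=b)


class TestArmLinks:
    def test_facing_pair_printed_cluster_c(self):
        """The two printed cluster-C breakpoints, 61 bp apart, yield the
        61-bp retained fragment of the first printed contig (the retained
        fragment runs from the base after the lower breakpoint through the
        upper one)."""
        j1 = J(
            "a11",
            Breakend("7", 54_668_756, RIGHT),
            Breakend("7", 54_838_000, LEFT),
        )
        j2 = J(
            "a16",
            Breakend("7", 54_668_816, LEFT),
            Breakend("7", 55_000_000, RIGHT),
        )
        (link,) = cg.build_arm_links([j1, j2], max_link=5000)
        assert link.length == 61
        assert link.junction_low == "a11" and link.junction_high == "a16"

    def test_orientation_incompatible_no_link(self):
        j1 = J("x", Breakend("7", 1000, LEFT), Breakend("7", 90_000, RIGHT))
        j2 = J("y", Breakend("7", 1050, LEFT), Breakend("7", 95_000, RIGHT))
        assert cg.build_arm_links([j1, j2], max_link=5000) == []

    def test_same_junction_arms_never_linked(self):
        j1 = J("x", Breakend("7", 1000, RIGHT), Breakend("7", 1100, LEFT))
        assert cg.build_arm_links([j1], max_link=5000) == []

    def test_simulated_links_superset_of_truth_adjacency(self):
        cfg = simulate.SimConfig(seed=33, mode="hsr", p_insertion=0.0)
        truth = simulate.simulate_amplicon(cfg)
        junctions = truth.junction_objects()
        links = cg.build_arm_links(junctions, max_link=5000)
        link_set = {
            (lk.fragment.chrom, lk.fragment.start, lk.fragment.end) for lk in links
        }
        (st,) = truth.structures
        for k in range(1, len(st.elements) - 1):
            frag = truth.fragments[st.elements[k][0]]
            if frag.length <= 5000:
                iv = frag.interval
                assert (iv.chrom, iv.start, iv.end) in link_set

    def test_link_length_is_breakend_arithmetic(self):
        cfg = simulate.SimConfig(seed=34)
        truth = simulate.simulate_amplicon(cfg)
        links = cg.build_arm_links(truth.junction_objects(), max_link=100_000)
        for lk in links:
            assert lk.length == lk.fragment.end - lk.fragment.start + 1


def expected_truth_contigs(truth, max_link):
    """Truth contigs, computed directly from the generative record: maximal
    runs of fragments <= max_link that sit between two junctions, expressed
    as the set of flanking junction ids.  Handles chain interiors and
    wrap-around runs on circles; completely independent of the assembler."""
    out = []
    for st in truth.structures:
        m = len(st.elements)
        qualifies = [
            truth.fragments[fid].length <= max_link for fid, _ in st.elements
        ]
        if st.kind == "chain":
            run = []
            for k in range(1, m - 1):
                if qualifies[k]:
                    run.append(k)
                else:
                    if run:
                        out.append(
                            frozenset(
                                st.join_ids[run[0] - 1 : run[-1] + 1]
                            )
                        )
                    run = []
            if run:
                out.append(frozenset(st.join_ids[run[0] - 1 : run[-1] + 1]))
        else:  # circle
            if all(qualifies):
                out.append(frozenset(st.join_ids))
                continue
            # walk circularly, starting just after a disqualified element
            start = next(k for k in range(m) if not qualifies[k])
            run = []
            for off in range(1, m + 1):
                k = (start + off) % m
                if qualifies[k]:
                    run.append(k)
                else:
                    if run:
                        ids = [st.join_ids[(run[0] - 1) % m]] + [
                            st.join_ids[i % m] for i in run
                        ]
                        out.append(frozenset(ids))
                    run = []
    return out


def recovery_config(seed):
    return simulate.SimConfig(
        genome_length={"c1": 500_000},
        source_regions=[
            Interval("c1", 50_001, 200_000),
            Interval("c1", 300_001, 450_000),
        ],
        n_clusters=8,
        breaks_per_cluster=(2, 2),
        inter_cluster_min_gap=10_000,
        singleton_break_rate=0.0,
        p_insertion=0.0,
        mode="dmin",
        n_episomes=2,
        seed=seed,
    )


class TestAssembly:
    def test_no_links_no_contigs(self):
        assert cg.assemble_contigs([], []) == []

    def test_recovers_planted_chains_over_fifty_seeds(self):
        """On circular amplicons every breakend's nearest facing partner is
        its own fragment's other end, so greedy assembly must recover the
        planted truth contigs exactly on all 50 seeds, with no ambiguity."""
        exact = 0
        for seed in range(50):
            truth = simulate.simulate_amplicon(recovery_config(seed))
            junctions = truth.junction_objects()
            links = cg.build_arm_links(junctions, max_link=5000)
            assembled = cg.assemble_contigs(links, junctions)
            got = sorted(tuple(sorted(c.junction_ids)) for c in assembled)
            want = sorted(
                tuple(sorted(s)) for s in expected_truth_contigs(truth, 5000)
            )
            if got == want and all(not c.ambiguous_breakends for c in assembled):
                exact += 1
        assert exact == 50

    def test_three_fragment_chain_recovered(self):
        """A chain whose fragments are all small assembles into one linear
        contig with fragments = junctions - 1."""
        cfg = simulate.SimConfig(
            genome_length={"c1": 100_000},
            source_regions=[Interval("c1", 50_001, 53_000)],
            n_clusters=1,
            cluster_span=(2000, 2400),
            breaks_per_cluster=(3, 3),
            inter_cluster_min_gap=1,
            singleton_break_rate=0.0,
            p_insertion=0.0,
            mode="hsr",
            seed=5,
        )
        truth = simulate.simulate_amplicon(cfg)
        junctions = truth.junction_objects()
        links = cg.build_arm_links(junctions, max_link=5000)
        (contig,) = cg.assemble_contigs(links, junctions)
        assert not contig.circular
        assert contig.n_junctions == len(junctions)
        assert len(contig.fragments) == contig.n_junctions - 1

    def test_circular_episome_detected(self):
        """A fully small-fragment episome assembles into one circular contig
        with junction count equal to fragment count."""
        cfg = simulate.SimConfig(
            genome_length={"c1": 100_000},
            source_regions=[Interval("c1", 50_001, 53_000)],
            n_clusters=1,
            cluster_span=(2000, 2400),
            breaks_per_cluster=(7, 7),
            inter_cluster_min_gap=1,
            singleton_break_rate=0.0,
            p_insertion=0.0,
            mode="dmin",
            n_episomes=1,
            seed=6,
        )
        truth = simulate.simulate_amplicon(cfg)
        junctions = truth.junction_objects()
        links = cg.build_arm_links(junctions, max_link=5000)
        (contig,) = cg.assemble_contigs(links, junctions)
        assert contig.circular
        assert contig.n_junctions == len(truth.fragments)
        assert len(contig.fragments) == contig.n_junctions

    def test_deterministic_under_permutation(self):
        truth = simulate.simulate_amplicon(recovery_config(3))
        junctions = truth.junction_objects()
        links = cg.build_arm_links(junctions, max_link=5000)
        a = cg.assemble_contigs(links, junctions)
        rng = np.random.default_rng(0)
        perm_links = [links[i] for i in rng.permutation(len(links))]
        perm_junctions = [junctions[i] for i in rng.permutation(len(junctions))]
        b = cg.assemble_contigs(perm_links, perm_junctions)
        key = lambda c: (c.junction_ids, [f.start for f in c.fragments])
        assert sorted(map(key, a)) == sorted(map(key, b))


class TestReport:
    def test_printed_table_statistics(self):
        """Replaying the printed microhomology column: half the contig
        junctions are blunt and under 10% carry more than 2 bp."""
        contigs, mh_map, ins_map = oda14.printed_contigs()
        report = cg.contig_report(contigs, mh_map, ins_map)
        assert report["n_junctions"] == 56
        assert report["fraction_blunt"] == pytest.approx(0.5)
        assert report["fraction_mh_gt2"] <= 0.10

    def test_contig18_large_fragments(self):
        row = next(r for r in oda14.CONTIGS if r["contig"] == 18)
        assert sum(1 for L in row["fragment_lengths"] if L > 10_000) == 4

    def test_source_distances(self):
        c = cg.Contig(
            junction_ids=["j1", "j2", "j3"],
            fragments=[Interval("c1", 100, 200), Interval("c1", 10_000, 10_500)],
        )
        assert c.source_distances() == [9800]


class TestCoordinatedPairs:
    def test_constructed_pair_detected(self):
        p, q = 1_000_000, 1_500_000
        j1 = J("j1", Breakend("7", p, LEFT), Breakend("7", q, RIGHT))
        j2 = J("j2", Breakend("7", p + 126, RIGHT), Breakend("7", q + 82, LEFT))
        (pair,) = cg.detect_coordinated_pairs([j1, j2])
        assert {pair.junction_1, pair.junction_2} == {"j1", "j2"}
        assert pair.separation == pytest.approx(500_000, abs=200)

    def test_one_sided_colocation_not_detected(self):
        p = 1_000_000
        j1 = J("j1", Breakend("7", p, LEFT), Breakend("7", 5_000_000, RIGHT))
        j2 = J("j2", Breakend("7", p + 126, RIGHT), Breakend("7", 9_000_000, LEFT))
        assert cg.detect_coordinated_pairs([j1, j2]) == []

    def test_below_min_inter_not_detected(self):
        p, q = 1_000_000, 1_050_000  # 50 kb apart < default 100 kb
        j1 = J("j1", Breakend("7", p, LEFT), Breakend("7", q, RIGHT))
        j2 = J("j2", Breakend("7", p + 10, RIGHT), Breakend("7", q + 20, LEFT))
        assert cg.detect_coordinated_pairs([j1, j2]) == []

    def test_planted_pairs_recovered_no_false_positives(self):
        """Planted coordinated pairs among remote decoys are all found and
        nothing else is."""
        rng = np.random.default_rng(8)
        junctions = []
        want = set()
        base = 1_000_000
        for i in range(5):
            p = base + i * 3_000_000
            q = p + 700_000
            j1 = J(f"p{i}a", Breakend("7", p, LEFT), Breakend("7", q, RIGHT))
            j2 = J(
                f"p{i}b",
                Breakend("7", p + int(rng.integers(10, 1500)), RIGHT),
                Breakend("7", q + int(rng.integers(10, 1500)), LEFT),
            )
            junctions += [j1, j2]
            want.add(frozenset({j1.id, j2.id}))
        for i in range(20):  # remote decoys
            junctions.append(
                J(
                    f"d{i}",
                    Breakend("8", 1_000_000 + i * 400_000, LEFT),
                    Breakend("8", 50_000_000 + i * 900_000, RIGHT),
                )
            )
        got = {
            frozenset({p.junction_1, p.junction_2})
            for p in cg.detect_coordinated_pairs(junctions)
        }
        assert got == want


def test_link_graph_export(tmp_path):
    truth = simulate.simulate_amplicon(recovery_config(1))
    links = cg.build_arm_links(truth.junction_objects(), max_link=5000)
    path = tmp_path / "links.tsv"
    cg.write_link_graph(links, path)
    rows = path.read_text().splitlines()
    assert len(rows) == len(links) + 1
    assert rows[0].startswith("junction_low\t")
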