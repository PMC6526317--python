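"""Quality filter semantics, the 90 %/55 % edge rule and cluster statistics."""

import networkx as nx
import numpy as np
import pytest

from rdnakit import graph_cluster as gc
from rdnakit import simulate
from rdnakit._align import revcomp
from rdnakit.graph_cluster import GraphParams
from rdnakit.simulate import ArraySpec, ReadSimSpec, build_array, random_dna
from rdnakit.unit_model import ValidationError


def _write_fastq(path, records):
    with open(path, "w") as fh:
        for name, seq, quals in records:
            fh.write(f"@{name}\n{seq}\n+\n{''.join(chr(q + 33) for q in quals)}\n")


class TestQualityFilter:
    def test_ten_low_bases_of_ninety_removed(self):
        # 10/90 = 11.1 % below Q20 -> strictly more than 10 % -> removed
        quals = [40] * 80 + [10] * 10
        assert not gc.read_passes_quality(quals)

    def test_all_q40_kept(self):
        assert gc.read_passes_quality([40] * 90)

    def test_exactly_ten_percent_kept(self):
        # 9/90 = 10.0 %: the rule is strictly greater than 10 %
        quals = [40] * 81 + [19] * 9
        assert gc.read_passes_quality(quals)

    def test_filter_file_roundtrip(self, tmp_path):
        seq = "ACGT" * 23  # 92 bp
        _write_fastq(
            tmp_path / "in.fastq",
            [
                ("good", seq, [40] * 92),
                ("bad", seq, [10] * 92),
            ],
        )
        kept, removed = gc.filter_reads(tmp_path / "in.fastq", tmp_path / "out.fastq")
        assert (kept, removed) == (1, 1)
        names = [n for n, _, _ in gc.parse_fastq(tmp_path / "out.fastq")]
        assert names == ["good"]

    def test_pair_dropped_when_either_mate_fails(self):
        seq = "A" * 90
        good = ("x/1", seq, [40] * 90)
        bad = ("x/2", seq, [10] * 90)
        assert gc.filter_read_pairs([("x", good, bad)]) == []
        assert len(gc.filter_read_pairs([("x", good, good)])) == 1

    def test_malformed_fastq_names_record_index(self, tmp_path):
        (tmp_path / "bad.fastq").write_text("@r1\nACGT\n+\nII\n")  # qual too short
        with pytest.raises(ValidationError, match="record 0"):
            list(gc.parse_fastq(tmp_path / "bad.fastq"))


class TestPairwiseIdentity:
    def test_identical_reads(self):
        a = random_dna(90, 0.5, np.random.default_rng(0))
        assert gc.pairwise_identity(a, a) == (100.0, 1.0)

    def test_nine_mismatches_hits_the_90_percent_boundary(self):
        a = random_dna(90, 0.5, np.random.default_rng(1))
        b = list(a)
        for i in range(5, 86, 10):  # 9 interior substitutions
            b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[i]]
        identity, overlap = gc.pairwise_identity(a, "".join(b))
        assert identity == 90.0 and overlap == 1.0
        assert gc.is_edge(identity, overlap)

    def test_49bp_shared_block_fails_overlap(self):
        block = random_dna(49, 0.5, np.random.default_rng(2))
        a = "A" * 20 + block + "A" * 21
        b = "C" * 20 + block + "C" * 21
        identity, overlap = gc.pairwise_identity(a, b)
        assert identity == 100.0
        assert overlap == pytest.approx(49 / 90, abs=1e-9)
        assert not gc.is_edge(identity, overlap)

    def test_reverse_complement_detected(self):
        a = random_dna(90, 0.5, np.random.default_rng(3))
        assert gc.pairwise_identity(a, revcomp(a)) == (100.0, 1.0)
        params = GraphParams(both_strands=False)
        identity, overlap = gc.pairwise_identity(a, revcomp(a), params)
        # forward-only: at best a short chance match, never a qualifying edge
        assert not gc.is_edge(identity, overlap, params)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            gc.pairwise_identity("", "ACGT")


class TestGraph:
    def test_three_identical_reads_complete_graph(self):
        seq = random_dna(90, 0.5, np.random.default_rng(4))
        g = gc.build_similarity_graph({"a": seq, "b": seq, "c": seq})
        assert g.number_of_edges() == 3

    def test_unrelated_sources_never_connect(self):
        rng = np.random.default_rng(5)
        s1, s2 = random_dna(500, 0.5, rng), random_dna(500, 0.5, rng)
        reads = {}
        for i in range(8):
            reads[f"x{i}"] = s1[i * 40 : i * 40 + 90]
            reads[f"y{i}"] = s2[i * 40 : i * 40 + 90]
        g = gc.build_similarity_graph(reads, exhaustive=True)
        assert not any(
            u.startswith("x") != v.startswith("x") for u, v in g.edges
        )

    def test_reads_tiling_tandem_array_form_one_component(self, unit_700):
        seq, _ = build_array(ArraySpec(unit_700, 3), np.random.default_rng(6))
        reads = {f"r{i}": seq[p : p + 90] for i, p in enumerate(range(0, 2010, 30))}
        g = gc.build_similarity_graph(reads)
        assert nx.number_connected_components(g) == 1

    def test_no_self_edges_and_symmetry(self):
        seq = random_dna(90, 0.5, np.random.default_rng(7))
        g = gc.build_similarity_graph({"a": seq, "b": seq})
        assert not any(u == v for u, v in g.edges)
        assert g.has_edge("b", "a")

    def test_prefilter_equals_exhaustive(self):
        """k-mer-prefiltered components match all-pairs alignment on a mixed
        instance of array reads plus background reads."""
        rng = np.random.default_rng(8)
        src = random_dna(800, 0.5, rng)
        reads = {f"a{i}": src[i * 25 : i * 25 + 90] for i in range(20)}
        for i in range(20):
            reads[f"bg{i}"] = random_dna(90, 0.5, rng)
        fast = gc.build_similarity_graph(reads)
        slow = gc.build_similarity_graph(reads, exhaustive=True)
        comps = lambda g: sorted(frozenset(c) for c in nx.connected_components(g))
        assert comps(fast) == comps(slow)


class TestClusters:
    def test_two_disjoint_cliques(self):
        rng = np.random.default_rng(9)
        s1, s2 = random_dna(90, 0.5, rng), random_dna(90, 0.5, rng)
        g = gc.build_similarity_graph({"a": s1, "b": s1, "c": s2, "d": s2, "e": s2})
        clusters = gc.cluster_reads(g)
        assert [c.size for c in clusters] == [3, 2]
        assert clusters[0].member_reads == frozenset("cde")

    def test_no_edges_all_singletons(self):
        g = nx.Graph()
        g.add_nodes_from("abcd")
        assert [c.size for c in gc.cluster_reads(g)] == [1, 1, 1, 1]

    def test_genome_proportion(self):
        c = gc.ClusterProfile(member_reads=frozenset(f"r{i}" for i in range(100)))
        assert gc.cluster_genome_proportion(c, 10_000) == 0.01
        assert gc.cluster_genome_proportion(c, 100) == 1.0
        with pytest.raises(ValidationError):
            gc.cluster_genome_proportion(c, 0)
        with pytest.raises(ValidationError):
            gc.cluster_genome_proportion(c, 50)

    def test_partition_and_gp_sum(self):
        rng = np.random.default_rng(10)
        src = random_dna(600, 0.5, rng)
        reads = {f"a{i}": src[i * 30 : i * 30 + 90] for i in range(15)}
        for i in range(10):
            reads[f"bg{i}"] = random_dna(90, 0.5, rng)
        clusters = gc.cluster_reads(gc.build_similarity_graph(reads))
        all_members = [r for c in clusters for r in c.member_reads]
        assert sorted(all_members) == sorted(reads)  # partition
        gps = [gc.cluster_genome_proportion(c, len(reads)) for c in clusters]
        assert sum(gps) == pytest.approx(1.0)

    def test_raising_identity_only_splits_clusters(self):
        """Components at a stricter identity threshold are a refinement of
        components at a looser one."""
        rng = np.random.default_rng(11)
        src = random_dna(400, 0.5, rng)
        src2 = simulate.mutate(src, 0.06, rng)  # ~94 % identical haplotype
        reads = {}
        for i in range(10):
            reads[f"h1_{i}"] = src[i * 30 : i * 30 + 90]
            reads[f"h2_{i}"] = src2[i * 30 : i * 30 + 90]
        loose = gc.cluster_reads(
            gc.build_similarity_graph(reads, GraphParams(min_identity=85))
        )
        strict = gc.cluster_reads(
            gc.build_similarity_graph(reads, GraphParams(min_identity=97))
        )
        for s in strict:
            assert any(s.member_reads <= l.member_reads for l in loose)


class TestHomogeneity:
    def test_identical_reads_all_pairs_at_100(self):
        seq = random_dna(90, 0.5, np.random.default_rng(12))
        reads = {f"r{i}": seq for i in range(5)}
        counts, identities = gc.homogeneity_histogram(reads)
        assert identities.size <= 5 * 4 / 2
        assert np.all(identities == 100.0)
        assert counts[99] == identities.size  # top bin
        assert counts.sum() == identities.size

    def test_fewer_than_two_reads_empty(self):
        counts, identities = gc.homogeneity_histogram({"r": "ACGT" * 25})
        assert identities.size == 0 and counts.sum() == 0

    def test_bimodal_histogram_for_two_haplotypes(self):
        """Reads from two ~10 %-divergent units give modes near 100 and 90."""
        rng = np.random.default_rng(13)
        h1 = random_dna(400, 0.5, rng)
        h2 = list(h1)
        for i in range(0, 400, 10):  # exactly 10 % divergence, evenly spread
            h2[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[h2[i]]
        h2 = "".join(h2)
        reads = {}
        for i in range(8):
            reads[f"a{i}"] = h1[i * 38 : i * 38 + 90]
            reads[f"b{i}"] = h2[i * 38 : i * 38 + 90]
        counts, identities = gc.homogeneity_histogram(
            reads, GraphParams(min_overlap_fraction=0.55)
        )
        high = counts[97:].sum()  # within-haplotype pairs
        low = counts[86:94].sum()  # cross-haplotype pairs
        mid = counts[94:97].sum()
        assert high > 0 and low > 0
        assert high + low > 5 * mid  # two modes with a valley between

    def test_heterogeneous_array_lowers_mean_identity(self, unit_700):
        rng = np.random.default_rng(14)
        hom_seq, _ = build_array(ArraySpec(unit_700, 15), rng)
        het_seq, _ = build_array(
            ArraySpec(unit_700, 15, per_copy_sub_rate=0.05), rng
        )
        means = {}
        for name, arr in (("hom", hom_seq), ("het", het_seq)):
            pairs = simulate.simulate_reads(
                arr, ReadSimSpec(coverage=0.6, read_length=90, insert_size=170,
                                 error_rate=0.003, seed=15),
            )
            reads = {p.name + "/1": p.seq1 for p in pairs[:40]}
            means[name] = gc.mean_pair_identity(reads)
        assert means["hom"] > means["het"]
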