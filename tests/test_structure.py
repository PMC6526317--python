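"""Subrepeat detection, 5S classification, digestion and arrangement calls."""

import numpy as np
import pytest

from rdnakit import structure as st
from rdnakit.archetypes import make_subrepeat_motif
from rdnakit.simulate import ArraySpec, PseudogeneEvent, build_array, mutate, random_dna
from rdnakit.unit_model import (
    CanonicalGeneSet,
    RdnaUnitModel,
    Subregion,
    ValidationError,
)


class TestSubrepeats:
    def test_gc_rich_71bp_motif_at_2p8_copies(self):
        """An ITS1-style block of 2.8 copies of a 71-bp, 73 %-GC motif."""
        rng = np.random.default_rng(30)
        motif = make_subrepeat_motif(rng, period=71, gc=0.73)
        block = motif * 2 + motif[: round(0.8 * 71)]
        seq = random_dna(150, 0.5, rng) + block + random_dna(150, 0.5, rng)
        reports = st.detect_subrepeats(seq)
        assert len(reports) == 1
        rep = reports[0]
        assert rep.period == 71
        assert rep.copy_number == pytest.approx(2.8, abs=0.1)
        assert rep.gc_content == pytest.approx(0.73, abs=0.06)

    def test_random_sequence_yields_nothing(self):
        assert st.detect_subrepeats(random_dna(500, 0.5, np.random.default_rng(31))) == []

    def test_exact_triple_of_50mer(self):
        rng = np.random.default_rng(32)
        motif = random_dna(50, 0.5, rng)
        reports = st.detect_subrepeats(motif * 3)
        assert len(reports) == 1
        assert (reports[0].period, reports[0].copy_number) == (50, 3.0)
        assert reports[0].consensus_motif == motif

    def test_flanked_triple_recovers_period_and_copies(self):
        """With random flanks the span boundary may shift by a base or two
        (flank bases can genuinely continue the period), so copy number is
        exact only to ~0.1."""
        rng = np.random.default_rng(32)
        motif = random_dna(50, 0.5, rng)
        seq = random_dna(100, 0.4, rng) + motif * 3 + random_dna(100, 0.4, rng)
        reports = st.detect_subrepeats(seq)
        assert len(reports) == 1
        assert reports[0].period == 50
        assert reports[0].copy_number == pytest.approx(3.0, abs=0.15)

    def test_sequence_too_short_rejected(self):
        with pytest.raises(ValidationError):
            st.detect_subrepeats("ACGT", min_period=10)

    @pytest.mark.parametrize("seed", range(8))
    def test_period_recovery_under_noise(self, seed):
        """Planted period is recovered exactly for periods 20-100 bp,
        2-5 copies, at 2 % motif noise."""
        rng = np.random.default_rng(1000 + seed)
        p = int(rng.integers(20, 101))
        copies = float(rng.uniform(2.0, 5.0))
        motif = random_dna(p, 0.5, rng)
        block = motif * int(copies) + motif[: int(round((copies % 1) * p))]
        block = mutate(block, 0.02, rng)
        seq = random_dna(120, 0.4, rng) + block + random_dna(120, 0.4, rng)
        reports = st.detect_subrepeats(seq, min_period=10)
        assert len(reports) == 1 and reports[0].period == p


class TestFiveSClassifier:
    def _unit(self, copies, name="u"):
        seq = ""
        subs = []
        for i, (label, s) in enumerate(copies):
            subs.append(Subregion(label, len(seq), len(seq) + len(s)))
            seq += s
            spacer = "ATTTTTATC"
            if i < len(copies) - 1:
                subs.append(Subregion("NTS", len(seq), len(seq) + len(spacer)))
                seq += spacer
        return RdnaUnitModel(name, seq, tuple(subs), "S_5S")

    def test_identical_copy_is_functional(self, canonical):
        unit = self._unit([("5S", canonical["5S"])])
        (call,) = st.classify_5s_copies(unit, canonical)
        assert call.cls == "functional"
        assert call.identity_to_canonical == 100.0
        assert call.five_prime_deletion == 0
        assert call.has_bamhi_site

    def test_104bp_diverged_copy_is_pseudogene(self, canonical):
        rng = np.random.default_rng(33)
        diverged = mutate(canonical["5S"][16:], 0.17, rng)
        unit = self._unit([("5S_pseudo", diverged)])
        (call,) = st.classify_5s_copies(unit, canonical)
        assert call.cls == "pseudogene" and call.length == 104

    def test_40bp_5prime_deletion_is_pseudogene(self, canonical):
        unit = self._unit([("5S_pseudo", canonical["5S"][40:])])
        (call,) = st.classify_5s_copies(unit, canonical)
        assert call.cls == "pseudogene"
        assert call.five_prime_deletion == 40
        assert call.length == 80

    def test_truncation_outranks_identity(self, canonical):
        """A full-length 95 % copy is functional; an 80-bp near-perfect copy
        is a pseudogene."""
        rng = np.random.default_rng(34)
        full_95 = mutate(canonical["5S"], 0.05, rng)
        short_99 = canonical["5S"][40:]
        unit = self._unit([("5S", full_95), ("5S_pseudo", short_99)])
        calls = st.classify_5s_copies(unit, canonical)
        assert calls[0].cls == "functional"
        assert calls[1].cls == "pseudogene"

    def test_missing_canonical_5s_rejected(self, canonical):
        unit = self._unit([("5S", canonical["5S"])])
        with pytest.raises(ValidationError, match="5S"):
            st.classify_5s_copies(unit, CanonicalGeneSet({"18S": "ACGT" * 100}))

    def test_all_planted_copies_classified_correctly(self, unit_700, canonical):
        """Simulator truth: every 40-bp-deleted or >=10 %-diverged planted
        copy is called pseudogene; every undamaged copy functional."""
        spec = ArraySpec(
            unit_700,
            n_copies=10,
            pseudogene_events=(PseudogeneEvent("5S", 40, 0.10),),
        )
        seq, truth = build_array(spec, np.random.default_rng(35))
        for t in truth:
            copy_seq = seq[t.start : t.end]
            unit = RdnaUnitModel("copy", copy_seq, t.subregions, "S_5S")
            calls = st.classify_5s_copies(unit, canonical)
            assert len(calls) == 1
            expected = "pseudogene" if t.status == "pseudogene" else "functional"
            assert calls[0].cls == expected


class TestDigestion:
    def test_monomer_ladder_one_site_per_unit(self, gm5s_unit):
        """One BamHI site per 627-bp unit digests an n-copy array into a
        monomer ladder: n-1 internal fragments of exactly 627 bp."""
        array = gm5s_unit.sequence * 8
        result = st.digest_array(array, ("BamHI", "GGATCC"), topology="linear")
        lengths = result.fragment_lengths
        assert lengths.count(627) == 7
        assert sum(lengths) == len(array)
        circ = st.digest_array(array, ("BamHI", "GGATCC"), topology="tandem-circularized")
        assert circ.fragment_lengths == [627] * 8

    def test_zero_sites_whole_array(self):
        seq = ("ACT" * 400).upper()
        for topo in ("linear", "tandem-circularized"):
            result = st.digest_array(seq, ("BamHI", "GGATCC"), topology=topo)
            assert result.fragment_lengths == [1200]

    def test_circularized_two_cuts(self):
        rng = np.random.default_rng(36)
        seq = list(random_dna(1000, 0.5, rng).replace("GGATCC", "GGATCA"))
        seq[100:106] = "GGATCC"
        seq[400:406] = "GGATCC"
        seq = "".join(seq)
        result = st.digest_array(seq, ("BamHI", "GGATCC"), topology="tandem-circularized")
        assert result.fragment_lengths == [300, 700]

    def test_iupac_bstni_both_degenerate_forms(self):
        seq = "T" * 50 + "CCAGG" + "T" * 50 + "CCTGG" + "T" * 50
        cuts = st.find_cut_positions(seq, "CCWGG")
        assert cuts == [50, 105]

    def test_short_recognition_rejected(self):
        with pytest.raises(ValidationError):
            st.find_cut_positions("ACGT" * 10, "ACG")

    @pytest.mark.parametrize("seed", range(10))
    def test_linear_fragments_conserve_length(self, seed):
        rng = np.random.default_rng(200 + seed)
        seq = random_dna(int(rng.integers(300, 3000)), 0.5, rng)
        for name, site in st.DEFAULT_ENZYMES.items():
            result = st.digest_array(seq, (name, site), topology="linear")
            assert sum(result.fragment_lengths) == len(seq)


class TestProbes:
    def test_stui_separates_probes_single_cutter_cohybridizes(self, l_unit, canonical):
        """On a linked unit, StuI (site between 26S and 5S) puts the probes
        on different fragments; BamHI (one cut, inside the 5S gene) leaves
        them on a common fragment."""
        probes = {"26S": canonical["26S"][:120], "5S": canonical["5S"]}
        array = l_unit.sequence
        stu = st.digest_array(array, ("StuI", "AGGCCT"), topology="tandem-circularized")
        st.assign_probes(stu, array, probes)
        assert st.cohybridizing_fragments(stu, "26S", "5S") == []
        hit_probes = set().union(*stu.probe_hits.values())
        assert hit_probes == {"26S", "5S"}

        bam = st.digest_array(array, ("BamHI", "GGATCC"), topology="tandem-circularized")
        st.assign_probes(bam, array, probes)
        assert st.cohybridizing_fragments(bam, "26S", "5S")

    def test_probe_without_match_hits_nothing(self, l_unit):
        array = l_unit.sequence
        digest = st.digest_array(array, ("BamHI", "GGATCC"), topology="tandem-circularized")
        foreign = random_dna(100, 0.5, np.random.default_rng(37))
        st.assign_probes(digest, array, {"foreign": foreign})
        assert digest.probe_hits == {}

    def test_probe_longer_than_array_rejected(self):
        digest = st.digest_array("ACGT" * 30, ("BamHI", "GGATCC"))
        with pytest.raises(ValidationError):
            st.assign_probes(digest, "ACGT" * 30, {"p": "A" * 200})


class TestArrangement:
    def test_co_clustering_implies_l(self):
        report = st.infer_arrangement([{"35S", "5S"}], [], digest_cohyb=False)
        assert report.arrangement_call == "L" and report.co_cluster

    def test_cross_mates_imply_l(self):
        mates = [({"26S"}, {"5S"})] * 2 + [({"26S"}, {"26S"})] * 8
        report = st.infer_arrangement([{"35S"}, {"5S"}], mates, digest_cohyb=False)
        assert report.cross_mate_fraction == pytest.approx(0.2)
        assert report.arrangement_call == "L"

    def test_digest_cohybridization_implies_l(self):
        report = st.infer_arrangement([{"35S"}, {"5S"}], [], digest_cohyb=True)
        assert report.arrangement_call == "L"

    def test_all_negative_with_both_families_is_s(self):
        mates = [({"26S"}, {"18S"})] * 10 + [({"5S"}, {"NTS"})] * 10
        report = st.infer_arrangement([{"35S"}, {"5S"}], mates, digest_cohyb=False)
        assert report.arrangement_call == "S"
        assert report.cross_mate_fraction == 0.0

    def test_missing_5s_is_ambiguous(self):
        report = st.infer_arrangement([{"35S"}], [], digest_cohyb=False)
        assert report.arrangement_call == "ambiguous"
        assert report.warnings

    def test_no_rdna_reads_is_ambiguous_with_warning(self):
        report = st.infer_arrangement([], [], digest_cohyb=None)
        assert report.arrangement_call == "ambiguous"
        assert "no rDNA reads" in report.warnings[0]

    def test_mapping_evidence_detects_families_without_clusters(self):
        mates = [({"26S"}, set())] * 5 + [({"5S"}, set())] * 5
        report = st.infer_arrangement([], mates, digest_cohyb=False)
        assert report.families_detected == frozenset({"35S", "5S"})
        assert report.arrangement_call == "S"
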