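"""Transcript loading, site enumeration, exclusivity, and conservation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sirnakit import transcript_model as tm
from sirnakit import synthetic_data as syn

from conftest import random_rna


def naive_substring_present(needle: str, haystack: str) -> bool:
    """O(L^2) character-by-character substring scan (oracle)."""
    n, k = len(haystack), len(needle)
    for start in range(n - k + 1):
        if all(haystack[start + i] == needle[i] for i in range(k)):
            return True
    return False


class TestLoading:
    def test_fasta_with_exon_table(self, tmp_path):
        fasta = tmp_path / "t.fasta"
        seq = "ACGU" * 17 + "AC"  # length 70
        fasta.write_text(">tx1\n" + seq + "\n")
        structure = tmp_path / "t.tsv"
        structure.write_text("tx1\t0\t30\texon\ntx1\t30\t70\texon\n")
        tset = tm.load_transcripts(fasta, structure)
        t = tset.get("tx1")
        assert len(t) == 70
        assert t.exon_boundaries == [(0, 30), (30, 70)]
        assert t.cds is None

    def test_lowercase_dna_normalized(self, tmp_path):
        fasta = tmp_path / "t.fasta"
        fasta.write_text(">tx1\nacgtacgt\n")
        tset = tm.load_transcripts(fasta)
        assert tset.get("tx1").sequence == "ACGUACGU"

    def test_duplicate_ids_rejected(self, tmp_path):
        fasta = tmp_path / "t.fasta"
        fasta.write_text(">tx1\nACGU\n>tx1\nACGU\n")
        with pytest.raises(ValueError, match="duplicate"):
            tm.load_transcripts(fasta)

    def test_non_tiling_exons_name_transcript(self):
        with pytest.raises(ValueError, match="bad_tx"):
            tm.Transcript(id="bad_tx", sequence="ACGUACGU",
                          exon_boundaries=[(0, 3), (5, 8)])

    def test_gff3_structure(self, tmp_path):
        fasta = tmp_path / "t.fasta"
        fasta.write_text(">tx1\n" + "ACGU" * 20 + "\n")
        gff = tmp_path / "t.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "tx1\t.\texon\t1\t40\t.\t+\t.\tID=e1\n"
            "tx1\t.\texon\t41\t80\t.\t+\t.\tID=e2\n"
            "tx1\t.\tCDS\t11\t70\t.\t+\t.\tID=c1\n"
        )
        t = tm.load_transcripts(fasta, gff).get("tx1")
        assert t.exon_boundaries == [(0, 40), (40, 80)]
        assert t.cds == (10, 70)

    def test_rejects_bad_alphabet(self):
        with pytest.raises(ValueError, match="non-ACGU"):
            tm.Transcript(id="x", sequence="ACGN" * 3)


class TestEnumerateSites:
    def test_count_and_order(self, rng):
        t = tm.Transcript(id="x", sequence=random_rna(rng, 70))
        sites = tm.enumerate_sites(t, 20)
        assert len(sites) == 51
        assert [s.start for s in sites] == list(range(51))
        assert all(s.site_sequence == t.sequence[s.start:s.end] for s in sites)

    def test_window_equals_length_boundary(self, rng):
        t = tm.Transcript(id="x", sequence=random_rna(rng, 20))
        sites = tm.enumerate_sites(t, 20)
        assert len(sites) == 1 and sites[0].start == 0

    def test_length_longer_than_transcript_errors(self, rng):
        t = tm.Transcript(id="x", sequence=random_rna(rng, 10))
        with pytest.raises(ValueError):
            tm.enumerate_sites(t, 11)

    @pytest.mark.parametrize(
        "start,expected",
        [
            (0, tm.Region.UTR5),          # fully before cds
            (35, tm.Region.ORF),          # fully inside
            (60, tm.Region.UTR3),         # fully after
            (25, tm.Region.ORF),          # 5 nt UTR5 / 15 nt ORF -> majority
            (55, tm.Region.UTR3),         # 5 nt ORF / 15 nt UTR3 -> majority
        ],
    )
    def test_region_labels_majority_rule(self, rng, start, expected):
        t = tm.Transcript(id="x", sequence=random_rna(rng, 90), cds=(30, 60))
        site = tm.enumerate_sites(t, 20)[start]
        assert site.region == expected

    def test_region_tie_goes_5prime(self, rng):
        t = tm.Transcript(id="x", sequence=random_rna(rng, 90), cds=(30, 60))
        # start 20: 10 nt UTR5, 10 nt ORF -> tie -> UTR5
        assert tm.enumerate_sites(t, 20)[20].region == tm.Region.UTR5

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(length=st.integers(min_value=20, max_value=120),
           k=st.integers(min_value=8, max_value=20))
    def test_count_property(self, length, k):
        rng = np.random.default_rng(length * 131 + k)
        t = tm.Transcript(id="x", sequence=random_rna(rng, length))
        assert len(tm.enumerate_sites(t, k)) == length - k + 1


class TestExclusiveSites:
    def test_constructed_two_isoform_pair(self, rng):
        shared = random_rna(rng, 40)
        a = tm.Transcript(id="A", sequence=random_rna(rng, 30) + shared)
        b = tm.Transcript(id="B", sequence=random_rna(rng, 20) + shared)
        sites = tm.enumerate_sites(a, 20)
        exclusive = tm.isoform_exclusive_sites(sites, b)
        oracle = [
            s for s in sites
            if not naive_substring_present(s.site_sequence, b.sequence)
        ]
        assert [s.start for s in exclusive] == [s.start for s in oracle]
        assert [s.start for s in exclusive] == list(range(30))

    def test_identical_isoforms_share_everything(self, rng):
        seq = random_rna(rng, 60)
        a = tm.Transcript(id="A", sequence=seq)
        sites = tm.enumerate_sites(a, 20)
        assert tm.isoform_exclusive_sites(sites, a) == []

    def test_unrelated_isoform_keeps_everything(self, rng):
        a = tm.Transcript(id="A", sequence=random_rna(rng, 70))
        b = tm.Transcript(id="B", sequence=random_rna(rng, 70))
        sites = tm.enumerate_sites(a, 20)
        exclusive = tm.isoform_exclusive_sites(sites, b)
        oracle = [
            s for s in sites
            if not naive_substring_present(s.site_sequence, b.sequence)
        ]
        assert len(exclusive) == len(oracle)

    def test_empty_site_list(self, rng):
        b = tm.Transcript(id="B", sequence=random_rna(rng, 30))
        assert tm.isoform_exclusive_sites([], b) == []

    def test_oracle_agreement_many_random_genes(self):
        """>=100 random two-isoform genes against the O(L^2) oracle."""
        for trial in range(100):
            rng = np.random.default_rng(1000 + trial)
            shared_len = int(rng.integers(25, 60))
            excl_len = int(rng.integers(0, 40))
            shared = random_rna(rng, shared_len)
            a_seq = random_rna(rng, excl_len) + shared
            b_seq = random_rna(rng, int(rng.integers(20, 50))) + shared
            if len(a_seq) < 20:
                continue
            a = tm.Transcript(id="A", sequence=a_seq)
            b = tm.Transcript(id="B", sequence=b_seq)
            sites = tm.enumerate_sites(a, 20)
            got = {s.start for s in tm.isoform_exclusive_sites(sites, b)}
            expected = {
                s.start for s in sites
                if not naive_substring_present(s.site_sequence, b.sequence)
            }
            assert got == expected


class TestConservation:
    def test_zero_divergence_all_conserved(self, isoform_gene):
        gene, _ = isoform_gene
        e1 = gene.get("GENE-E1")
        sets, _ = syn.make_orthologs(
            e1, {f"sp{i}": 0.0 for i in range(3)}, seed=7
        )
        site = tm.enumerate_sites(e1, 20)[0]
        per_species, overall = tm.site_conservation(site, sets)
        assert overall and all(per_species.values())

    def test_single_substitution_breaks_species(self, rng):
        seq = random_rna(rng, 60)
        t = tm.Transcript(id="T", sequence=seq)
        site = tm.enumerate_sites(t, 20)[10]
        mutated = list(seq)
        mutated[15] = "A" if mutated[15] != "A" else "C"
        ortholog = tm.TranscriptSet(
            [tm.Transcript(id="T|sp", sequence="".join(mutated), species="sp")],
            role=tm.SetRole.ORTHOLOG,
        )
        per_species, overall = tm.site_conservation(site, [ortholog])
        assert per_species == {"sp": False} and not overall

    def test_empty_species_list_vacuous_true(self, rng):
        t = tm.Transcript(id="T", sequence=random_rna(rng, 30))
        site = tm.enumerate_sites(t, 20)[0]
        with pytest.warns(UserWarning):
            per_species, overall = tm.site_conservation(site, [])
        assert overall and per_species == {}

    def test_monotone_in_species(self, isoform_gene):
        """Adding a species can break but never repair the overall flag."""
        gene, _ = isoform_gene
        e1 = gene.get("GENE-E1")
        sets, _ = syn.make_orthologs(
            e1,
            {"sp0": 0.0, "sp1": 0.02, "sp2": 0.3, "sp3": 0.6},
            seed=3,
        )
        for site in tm.enumerate_sites(e1, 20)[::25]:
            previous = True
            for n in range(1, len(sets) + 1):
                _, overall = tm.site_conservation(site, sets[:n])
                assert not (overall and not previous)
                previous = overall
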