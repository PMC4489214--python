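"""Digestion, membership, and classification behaviour."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srmiso import isoform_db as idb
from srmiso import simulate as sim


def brute_force_membership(peptide, records, max_missed=2, il_equivalent=True):
    """Independent oracle: substring scan over the full isoform sequence,
    accepting only occurrences at tryptic boundaries with the allowed
    number of internal missed cleavages."""

    def fold(s):
        return s.replace("I", "L") if il_equivalent else s

    pep = fold(peptide)
    hits = set()
    for rec in records:
        seq = fold(rec.sequence)
        n, k = len(seq), len(pep)
        for i in range(n - k + 1):
            if seq[i : i + k] != pep:
                continue
            # N-terminal boundary must be a cleavage point (or seq start)
            if i > 0 and not (seq[i - 1] in "KR" and seq[i] != "P"):
                continue
            # C-terminal boundary likewise (or seq end)
            j = i + k
            if j < n and not (seq[j - 1] in "KR" and seq[j] != "P"):
                continue
            internal = sum(
                1
                for t in range(i, j - 1)
                if seq[t] in "KR" and seq[t + 1] != "P"
            )
            if internal <= max_missed:
                hits.add(rec.isoform_id)
                break
    return frozenset(hits)


class TestDigest:
    def test_kr_cleavage_with_proline_suppression(self):
        peps = idb.tryptic_digest("MKWVTFRKPGLR", max_missed=0, parent_id="p")
        assert [p.sequence for p in peps] == ["MK", "WVTFR", "KPGLR"]

    def test_missed_cleavage_products(self):
        peps = idb.tryptic_digest("MKWVTFRKPGLR", max_missed=1, parent_id="p")
        seqs = {p.sequence for p in peps}
        assert seqs == {"MK", "WVTFR", "KPGLR", "MKWVTFR", "WVTFRKPGLR"}
        by_seq = {p.sequence: p for p in peps}
        assert by_seq["MKWVTFR"].missed_cleavages == 1
        assert by_seq["WVTFR"].missed_cleavages == 0

    def test_no_cleavage_sites(self):
        peps = idb.tryptic_digest("AAAA", max_missed=3, parent_id="p")
        assert [p.sequence for p in peps] == ["AAAA"]

    def test_coordinates_slice_back_to_sequence(self, family):
        for rec in family:
            for pep in idb.tryptic_digest(rec, max_missed=2):
                assert rec.sequence[pep.start - 1 : pep.end] == pep.sequence

    def test_zero_missed_digest_concatenates_to_parent(self, family):
        for rec in family:
            peps = idb.tryptic_digest(rec, max_missed=0)
            assert "".join(p.sequence for p in peps) == rec.sequence

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        seq=st.text(alphabet="ACDEGKLPRSTVW", min_size=1, max_size=40),
        max_missed=st.integers(0, 3),
    )
    def test_digest_partition_property(self, seq, max_missed):
        """For any sequence: zero-missed peptides tile the parent, every
        peptide is a correctly located slice, and internal missed
        cleavages are counted exactly."""
        peps = idb.tryptic_digest(seq, max_missed, "p")
        zero = [p.sequence for p in peps if p.missed_cleavages == 0]
        assert "".join(zero) == seq
        for p in peps:
            assert seq[p.start - 1 : p.end] == p.sequence
            assert p.end == len(seq) or (
                p.sequence[-1] in "KR" and seq[p.end] != "P"
            )
            internal = sum(
                1
                for t in range(p.start - 1, p.end - 1)
                if seq[t] in "KR" and seq[t + 1] != "P"
            )
            assert internal == p.missed_cleavages

    @pytest.mark.parametrize("max_missed", [0, 1, 2, 3])
    def test_peptide_count_matches_cut_enumeration(self, max_missed):
        """Count with m missed cleavages equals segments-m windows,
        cross-checked against explicit enumeration over cut points."""
        seq = "AKCRDEKFGHRMK"  # homopolymer-free, sites at K/R
        sites = idb.cleavage_sites(seq)
        bounds = [0] + [s + 1 for s in sites] + [len(seq)]
        expected = {
            seq[bounds[i] : bounds[j]]
            for i, j in itertools.combinations(range(len(bounds)), 2)
            if j - i <= max_missed + 1
        }
        got = {p.sequence for p in idb.tryptic_digest(seq, max_missed, "p")}
        assert got == expected
        nseg = len(bounds) - 1
        closed_form = sum(max(0, nseg - m) for m in range(max_missed + 1))
        assert len(idb.tryptic_digest(seq, max_missed, "p")) == closed_form


class TestFasta:
    def test_round_trip_and_field_mapping(self, tmp_path):
        rec = idb.IsoformRecord(
            "N1_a_AS3+AS4-AS6+", "Nrxn1", "alpha",
            {"AS3": True, "AS4": False, "AS6": True}, "MKWVTFR",
        )
        path = tmp_path / "db.fasta"
        idb.write_isoform_fasta([rec], path)
        (parsed,) = idb.parse_isoform_fasta(path)
        assert parsed.gene == "Nrxn1"
        assert parsed.promoter_class == "alpha"
        assert parsed.insertions == {"AS3": True, "AS4": False, "AS6": True}
        assert parsed.sequence == "MKWVTFR"

    def test_empty_file_warns_and_returns_empty(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with pytest.warns(UserWarning):
            assert idb.parse_isoform_fasta(path) == []

    def test_duplicate_id_rejected(self, tmp_path):
        path = tmp_path / "dup.fasta"
        path.write_text(
            ">x gene=g promoter=alpha\nMKR\n>x gene=g promoter=beta\nMKR\n"
        )
        with pytest.raises(idb.IsoformDatabaseError, match="duplicate"):
            idb.parse_isoform_fasta(path)

    def test_malformed_header_names_entry(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">y gene=g promoter=alpha junk\nMKR\n")
        with pytest.raises(idb.IsoformDatabaseError, match="y"):
            idb.parse_isoform_fasta(path)

    def test_invalid_residue_rejected(self, tmp_path):
        path = tmp_path / "badres.fasta"
        path.write_text(">z gene=g promoter=alpha\nMKXB\n")
        with pytest.raises(idb.IsoformDatabaseError):
            idb.parse_isoform_fasta(path)

    def test_generated_family_round_trips(self, tmp_path, family):
        path = tmp_path / "family.fasta"
        idb.write_isoform_fasta(family, path)
        parsed = idb.parse_isoform_fasta(path)
        assert {r.isoform_id for r in parsed} == {r.isoform_id for r in family}
        by_id = {r.isoform_id: r for r in parsed}
        for rec in family:
            assert by_id[rec.isoform_id].sequence == rec.sequence
            assert by_id[rec.isoform_id].insertions == rec.insertions


class TestMembership:
    def test_shared_suffix_peptide_hits_all_gene_isoforms(self, toy_family):
        assert idb.peptide_membership("DDDK", toy_family) == {"A-alpha", "A-beta"}

    def test_unmatched_peptide_empty(self, toy_family):
        assert idb.peptide_membership("WWWWWWK", toy_family) == frozenset()

    def test_cross_gene_shared_peptide(self, toy_family):
        assert idb.peptide_membership("CCCR", toy_family) == {
            "A-alpha", "A-beta", "B-alpha",
        }

    def test_matches_brute_force_oracle_on_random_families(self):
        n_checked = 0
        for seed in range(20):
            cfg = sim.FamilyConfig(
                seed=seed,
                n_genes=2,
                segments_per_gene={"G1": ("AS3", "AS4"), "G2": ("AS4",)},
                backbone_length=60,
            )
            records = sim.generate_family(cfg)
            index = idb.PeptideIndex(records, max_missed=2)
            peptides = {
                p.sequence
                for r in records[:4]
                for p in idb.tryptic_digest(r, 2)
            }
            for pep in sorted(peptides)[:30]:
                assert index.membership(pep) == brute_force_membership(
                    pep, records
                ), pep
                n_checked += 1
        assert n_checked > 200

    def test_il_equivalence_folds_isobaric_residues(self):
        a = idb.IsoformRecord("a", "g", "alpha", {}, "MILKAAAR")
        b = idb.IsoformRecord("b", "g", "beta", {}, "MLLKAAAR")
        both = idb.peptide_membership("MILK", [a, b], il_equivalent=True)
        assert both == {"a", "b"}
        only_a = idb.peptide_membership("MILK", [a, b], il_equivalent=False)
        assert only_a == {"a"}


class TestClassification:
    def test_pan_alpha_and_insertion_groups(self, family, groups, index):
        by_level = {}
        for g in groups:
            by_level.setdefault(g.level, []).append(g)
        pan = next(g for g in by_level[idb.GENE_PAN] if g.label == "NRX1-pan")
        cls = idb.classify_peptide(pan.member_isoform_ids, groups)
        assert cls.label == "NRX1-pan"
        as4 = next(g for g in by_level[idb.SPLICE_INSERTION] if g.label == "NRX1-AS4+")
        assert idb.classify_peptide(as4.member_isoform_ids, groups).label == "NRX1-AS4+"

    def test_cross_gene_membership_is_non_proteotypic(self, family, groups):
        nrx1 = next(r for r in family if r.gene == "NRX1")
        nrx2 = next(r for r in family if r.gene == "NRX2")
        cls = idb.classify_peptide({nrx1.isoform_id, nrx2.isoform_id}, groups)
        assert cls.label == idb.NON_PROTEOTYPIC
        assert not cls.is_proteotypic

    def test_empty_membership_is_absent(self, groups):
        assert idb.classify_peptide(frozenset(), groups).label == idb.ABSENT

    def test_partial_group_match_is_non_proteotypic(self, family, groups):
        one = next(r for r in family if r.gene == "NRX1")
        assert (
            idb.classify_peptide({one.isoform_id}, groups).label
            == idb.NON_PROTEOTYPIC
        )

    def test_invariant_to_group_order(self, groups):
        target = groups[5]
        fwd = idb.classify_peptide(target.member_isoform_ids, groups)
        rev = idb.classify_peptide(target.member_isoform_ids, list(reversed(groups)))
        assert fwd.label == rev.label

    def test_il_substitution_never_changes_classification(self):
        records = [
            idb.IsoformRecord("a", "g", "alpha", {}, "MIWEKAAADER"),
            idb.IsoformRecord("b", "g", "beta", {}, "MFQEKAAADER"),
        ]
        swapped = [
            idb.IsoformRecord(
                r.isoform_id, r.gene, r.promoter_class, r.insertions,
                r.sequence.replace("I", "L"),
            )
            for r in records
        ]
        groups = idb.build_detection_groups(records)
        for pep in ("MIWEK", "MLWEK", "AAADER", "MFQEK"):
            before = idb.classify_peptide(
                idb.peptide_membership(pep, records), groups
            ).label
            after = idb.classify_peptide(
                idb.peptide_membership(pep, swapped), groups
            ).label
            assert before == after
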