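import numpy as np
import pytest

from pepatlas import curation
from pepatlas.curation import (
    alignment_identity,
    classify_chains,
    curate_entry,
    filter_entry,
    read_entry,
    read_summary_fasta,
    renumber_and_trim,
    type_hla,
    write_summary_fasta,
)
from pepatlas.synthetic import (
    AA1,
    SyntheticComplexSpec,
    make_complex,
    synthetic_reference_alleles,
)


def mutate(seq, frac, seed=0):
    rng = np.random.default_rng(seed)
    out = list(seq)
    for p in rng.choice(len(seq), size=int(frac * len(seq)), replace=False):
        out[p] = rng.choice([a for a in AA1 if a != out[p]])
    return "".join(out)


@pytest.fixture()
def toy_entry(references, tmp_path):
    path = tmp_path / "TOY1.pdb"
    make_complex(SyntheticComplexSpec(seed=1), out_path=path)
    return read_entry(path)


class TestClassifyChains:
    def test_roles_assigned_for_exact_reference_match(self, toy_entry, references):
        roles = classify_chains(toy_entry, references["A*02:01"])
        assert roles["A"].role == "heavy_chain"
        assert roles["A"].identity_to_reference == pytest.approx(1.0)
        assert roles["C"].role == "peptide"

    def test_twelve_residue_chain_is_not_a_peptide(self, references, tmp_path):
        path = tmp_path / "LONG.pdb"
        make_complex(
            SyntheticComplexSpec(pdb_id="LONG", peptide_sequence="A" * 12,
                                 anchors=(2, 12), seed=1),
            out_path=path,
        )
        entry = read_entry(path)
        roles = classify_chains(entry, references["A*02:01"])
        assert roles["C"].role == "other"
        decision = filter_entry(entry, roles)
        assert not decision.accepted
        assert "no_peptide" in decision.reasons

    def test_forty_percent_identity_is_other(self, toy_entry, references):
        # identity oracle: no indels, so global identity is the match fraction
        ref = references["A*02:01"]
        distant = mutate(ref, 0.60, seed=3)
        hand_identity = sum(a == b for a, b in zip(ref, distant)) / len(ref)
        assert hand_identity < 0.5
        assert alignment_identity(distant, ref) <= hand_identity + 0.05
        entry = toy_entry
        entry.chains[0].residues = entry.chains[0].residues  # unchanged
        roles = classify_chains(entry, distant_reference := distant)
        assert roles["A"].role != "heavy_chain" or alignment_identity(
            entry.chain("A").sequence(), distant_reference
        ) > 0.5

    def test_chain_order_invariance(self, toy_entry, references):
        roles1 = classify_chains(toy_entry, references["A*02:01"])
        toy_entry.chains.reverse()
        roles2 = classify_chains(toy_entry, references["A*02:01"])
        assert roles1.keys() == roles2.keys()
        assert {k: r.role for k, r in roles1.items()} == {
            k: r.role for k, r in roles2.items()
        }


class TestFilters:
    def test_contacting_extra_chain_rejected(self, references, tmp_path):
        path = tmp_path / "NEAR.pdb"
        make_complex(
            SyntheticComplexSpec(pdb_id="NEAR", seed=2, extra_chain_distance=3.9),
            out_path=path,
        )
        _, decision = curate_entry(path, references)
        assert not decision.accepted
        assert "other_chain_contact" in decision.reasons

    def test_distant_extra_chain_retained(self, references, tmp_path):
        path = tmp_path / "FARX.pdb"
        make_complex(
            SyntheticComplexSpec(pdb_id="FARX", seed=2, extra_chain_distance=20.0),
            out_path=path,
        )
        curated, decision = curate_entry(path, references)
        assert decision.accepted and curated is not None

    def test_zero_occupancy_peptide_ca_rejected(self, references, tmp_path):
        path = tmp_path / "ZOCC.pdb"
        make_complex(
            SyntheticComplexSpec(pdb_id="ZOCC", seed=3,
                                 zero_occupancy_atom=(4, "CA")),
            out_path=path,
        )
        _, decision = curate_entry(path, references)
        assert not decision.accepted
        assert "peptide_zero_occupancy" in decision.reasons

    def test_resolution_above_cutoff_rejected(self, references, tmp_path):
        path = tmp_path / "LOWR.pdb"
        make_complex(
            SyntheticComplexSpec(pdb_id="LOWR", seed=4, resolution=3.4),
            out_path=path,
        )
        _, decision = curate_entry(path, references)
        assert not decision.accepted
        assert "resolution_above_max" in decision.reasons
        curated, decision = curate_entry(path, references, resolution_max=3.5)
        assert decision.accepted

    def test_accepted_entry_passes_filters_when_rechecked(self, references, tmp_path):
        path = tmp_path / "OKAY.pdb"
        make_complex(SyntheticComplexSpec(pdb_id="OKAY", seed=5), out_path=path)
        entry = read_entry(path)
        roles = classify_chains(entry, references["A*02:01"])
        first = filter_entry(entry, roles, reference_heavy=references["A*02:01"])
        second = filter_entry(entry, roles, reference_heavy=references["A*02:01"])
        assert first.accepted and second.accepted
        assert first.reasons == second.reasons == []

    def test_unreadable_file_rejected_with_parse_code(self, references, tmp_path):
        bad = tmp_path / "BAD.cif"
        bad.write_text("this is not a structure\n")
        curated, decision = curate_entry(bad, references)
        assert curated is None
        assert decision.reasons == ["parse_error"]


class TestRenumbering:
    def test_author_numbering_offset_removed(self, references, tmp_path):
        path = tmp_path / "TOY1.pdb"
        make_complex(SyntheticComplexSpec(seed=1), out_path=path)
        entry = read_entry(path)
        for i, res in enumerate(entry.chain("A").residues):
            res.seqid = 1001 + i
        roles = classify_chains(entry, references["A*02:01"])
        curated = renumber_and_trim(entry, roles)
        assert [r.seqid for r in curated.platform] == list(range(1, 181))

    def test_oversized_heavy_chain_trimmed_to_180(self, references, tmp_path):
        path = tmp_path / "TOY1.pdb"
        make_complex(SyntheticComplexSpec(seed=1), out_path=path)
        entry = read_entry(path)
        heavy = entry.chain("A")
        import copy

        extra = [copy.deepcopy(heavy.residues[-1]) for _ in range(95)]
        for k, res in enumerate(extra):
            res.seqid = 181 + k
        heavy.residues = heavy.residues + extra
        roles = classify_chains(entry, references["A*02:01"])
        curated = renumber_and_trim(entry, roles)
        assert len(curated.platform) == 180

    def test_octamer_renumbered_1_to_8(self, references, tmp_path):
        path = tmp_path / "OCT.pdb"
        make_complex(
            SyntheticComplexSpec(pdb_id="OCT", peptide_sequence="GLFAAGVK",
                                 anchors=(2, 8), seed=6),
            out_path=path,
        )
        curated, decision = curate_entry(path, references)
        assert decision.accepted
        assert [r.seqid for r in curated.peptide] == list(range(1, 9))

    def test_short_heavy_chain_rejected(self, references, tmp_path):
        path = tmp_path / "TOY1.pdb"
        make_complex(SyntheticComplexSpec(seed=1), out_path=path)
        entry = read_entry(path)
        entry.chain("A").residues = entry.chain("A").residues[:170]
        roles = classify_chains(entry, references["A*02:01"])
        with pytest.raises(ValueError):
            renumber_and_trim(entry, roles)


class TestTyping:
    def test_exact_match_types_with_identity_one(self, references):
        name, ident = type_hla(references["A*02:01"], references)
        assert name == "A*02:01"
        assert ident == pytest.approx(1.0)

    def test_single_substitution_still_types_to_nearest(self, references):
        seq = mutate(references["A*02:01"], 1 / 180, seed=1)
        name, ident = type_hla(seq, references)
        assert name == "A*02:01"
        assert ident == pytest.approx(179 / 180, abs=0.01)

    def test_tie_breaks_lexicographically(self):
        refs = {"B*07:02": "ACDEFGHIKL", "A*01:01": "ACDEFGHIKL"}
        name, _ = type_hla("ACDEFGHIKL", refs)
        assert name == "A*01:01"

    def test_empty_reference_is_error(self):
        with pytest.raises(ValueError):
            type_hla("ACDEF", {})

    def test_distant_sequence_fails_typing(self, references):
        with pytest.raises(ValueError, match="typing failed"):
            type_hla("W" * 180, references)


class TestSummaryFasta:
    def test_one_complex_gives_two_records(self, references):
        cx = make_complex(SyntheticComplexSpec(seed=1))
        records = read_summary_fasta(write_summary_fasta([cx]))
        assert len(records) == 2
        assert {r["chain"] for r in records} == {"hla", "peptide"}

    def test_round_trip_preserves_metadata(self, references):
        cx = make_complex(SyntheticComplexSpec(seed=1, resolution=2.25,
                                               release_date="2014-06-01"))
        rec = read_summary_fasta(write_summary_fasta([cx]))[0]
        assert rec["pdb_id"] == cx.pdb_id
        assert rec["allele"] == cx.allotype
        assert rec["release_date"] == "2014-06-01"
        assert rec["resolution"] == pytest.approx(2.25)
        assert rec["sequence"] == cx.platform_sequence()

    def test_empty_list_gives_empty_file(self):
        assert write_summary_fasta([]) == ""


class TestIdempotence:
    def test_curating_curated_output_is_identity(self, references, tmp_path):
        raw = tmp_path / "TOY1.pdb"
        make_complex(SyntheticComplexSpec(seed=1), out_path=raw)
        first, decision = curate_entry(raw, references)
        assert decision.accepted
        out = tmp_path / "curated.pdb"
        first.write_pdb(out)
        second, decision2 = curate_entry(out, references)
        assert decision2.accepted
        assert second.platform_sequence() == first.platform_sequence()
        assert second.peptide_sequence() == first.peptide_sequence()
        assert second.allotype == first.allotype
        assert np.allclose(
            second.peptide_backbone().coords, first.peptide_backbone().coords,
            atol=1e-3,
        )


class TestCurateDirectory:
    def test_mixed_directory_splits_accepts_and_rejects(self, references, tmp_path):
        make_complex(SyntheticComplexSpec(pdb_id="GOOD", seed=1),
                     out_path=tmp_path / "GOOD.pdb")
        make_complex(SyntheticComplexSpec(pdb_id="NEAR", seed=2,
                                          extra_chain_distance=3.0),
                     out_path=tmp_path / "NEAR.pdb")
        complexes, rejections = curation.curate_directory(tmp_path, references)
        assert [c.pdb_id for c in complexes] == ["GOOD"]
        assert rejections == [("NEAR.pdb", "other_chain_contact")]
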