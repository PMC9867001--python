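"""Cleavage-rule compilation and multi-enzyme digestion."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import peptiprospect as pp
from peptiprospect.digestion import (
    AMINO_ACIDS,
    DialectMismatchError,
    NonCanonicalResidueError,
    UnknownTagError,
)

from conftest import random_sequences

sequences = st.text(alphabet=sorted(AMINO_ACIDS), min_size=2, max_size=40)


class TestCompileRuleset:
    def test_biopep_trypsin_carries_kp_block(self):
        (spec,) = pp.compile_ruleset("BIOPEP", ["trypsin"])
        assert spec.ec_number == "3.4.21.4"
        (rule,) = spec.rules
        assert rule.p1_residues == frozenset("KR")
        assert {"P1": frozenset("K"), "P1prime": frozenset("P")} in list(rule.exceptions)

    def test_expasy_trypsin_carries_overrides(self):
        specs = pp.compile_ruleset("EXPASY", ["trypsin", "chymotrypsin_A"])
        assert [s.enzyme_id for s in specs] == ["trypsin", "chymotrypsin_A"]
        (rule,) = specs[0].rules
        overrides = list(rule.exception_overrides)
        assert {"P1": frozenset("K"), "P2": frozenset("W"), "P1prime": frozenset("P")} in overrides
        assert {"P1": frozenset("R"), "P2": frozenset("M"), "P1prime": frozenset("P")} in overrides

    def test_ec_numbers_match_enzyme_identity(self):
        for dialect in ("BIOPEP", "EXPASY"):
            by_id = {s.enzyme_id: s.ec_number for s in pp.compile_ruleset(dialect)}
            assert by_id == {
                "pepsin_ph_gt2": "3.4.23.1",
                "trypsin": "3.4.21.4",
                "chymotrypsin_A": "3.4.21.1",
            }

    def test_unknown_tags_raise_naming_the_tag(self):
        with pytest.raises(UnknownTagError, match="unknown_enzyme"):
            pp.compile_ruleset("BIOPEP", ["unknown_enzyme"])
        with pytest.raises(UnknownTagError, match="KLINGON"):
            pp.compile_ruleset("KLINGON")

    def test_chymotrypsin_h_switch(self):
        (with_h,) = pp.compile_ruleset("EXPASY", ["chymotrypsin_A"])
        (without_h,) = pp.compile_ruleset(
            "EXPASY", ["chymotrypsin_A"], chymotrypsin_h_at_p1=False
        )
        assert "H" in with_h.rules[0].p1_residues
        assert "H" not in without_h.rules[0].p1_residues
        # AAHAA: H cleavable only when H is in the P1 set
        assert pp.find_cut_sites("AAHAA", with_h) == [3]
        assert pp.find_cut_sites("AAHAA", without_h) == []


class TestFindCutSites:
    @pytest.mark.parametrize(
        "sequence, dialect, enzyme, expected",
        [
            ("AAKAA", "EXPASY", "trypsin", [3]),
            ("AAKPA", "EXPASY", "trypsin", []),  # proline blocks
            ("AWKPA", "EXPASY", "trypsin", [3]),  # W-K-P override re-enables
            ("AARPA", "EXPASY", "trypsin", []),
            ("AMRPA", "EXPASY", "trypsin", [3]),  # M-R-P override
            ("ADKDA", "EXPASY", "trypsin", []),  # D..D context blocks K
            ("ACKYA", "EXPASY", "trypsin", []),  # C..Y context blocks K
            ("ARRHA", "EXPASY", "trypsin", [2]),  # R|R cut; R..H blocks second R
            ("AAKPA", "BIOPEP", "trypsin", []),  # K-P blocked in this dialect too
            ("AARPA", "BIOPEP", "trypsin", [3]),  # ...but R-P is cleavable
            ("AAWMA", "EXPASY", "chymotrypsin_A", [4]),  # W|M blocked, M|A cleaves
            ("AAWPA", "EXPASY", "chymotrypsin_A", []),
            ("AAMYA", "EXPASY", "chymotrypsin_A", [4]),  # M|Y blocked, Y|A cleaves
            ("AAHDA", "EXPASY", "chymotrypsin_A", []),  # H blocked by D
            ("AAWMA", "BIOPEP", "chymotrypsin_A", [4]),
            ("AANAA", "BIOPEP", "chymotrypsin_A", [3]),  # N cleavable here only
            ("AANAA", "EXPASY", "chymotrypsin_A", []),
            ("AVI", "BIOPEP", "pepsin_ph_gt2", [1, 2]),
            ("CCFCC", "EXPASY", "pepsin_ph_gt2", [2, 3]),  # F drives P1 and P1'
            ("CKFCC", "EXPASY", "pepsin_ph_gt2", [3]),  # K at P1 blocks the P1' driver
            ("PPFCC", "EXPASY", "pepsin_ph_gt2", []),  # P at P2 blocks both drivers
            ("CCFPC", "EXPASY", "pepsin_ph_gt2", []),  # P at P1'/P2' blocks both
            ("RCFCC", "EXPASY", "pepsin_ph_gt2", [2]),  # R at P3 blocks the P1 driver
        ],
    )
    def test_rule_semantics(self, sequence, dialect, enzyme, expected):
        (spec,) = pp.compile_ruleset(dialect, [enzyme])
        assert pp.find_cut_sites(sequence, spec) == expected

    def test_short_sequences_have_no_internal_bond(self, expasy_specs):
        assert pp.find_cut_sites("K", expasy_specs[1]) == []

    def test_non_canonical_residue_rejected_by_default(self, expasy_specs):
        with pytest.raises(NonCanonicalResidueError, match="X"):
            pp.find_cut_sites("AAKXA", expasy_specs[1])

    def test_permissive_mode_matches_no_rule(self, expasy_specs):
        trypsin = expasy_specs[1]
        assert trypsin.enzyme_id == "trypsin"
        assert pp.find_cut_sites("AXKAA", trypsin, permissive=True) == [3]
        assert pp.find_cut_sites("AAXAA", trypsin, permissive=True) == []


class TestCodigest:
    def test_union_of_enzyme_sites(self):
        specs = pp.compile_ruleset("EXPASY", ["trypsin", "chymotrypsin_A"])
        assert [f.sequence for f in pp.codigest("AKFA", specs)] == ["AK", "F", "A"]

    def test_no_matching_site_returns_whole_sequence(self):
        specs = pp.compile_ruleset("EXPASY", ["trypsin"])
        (frag,) = pp.codigest("AAAA", specs)
        assert (frag.start, frag.end, frag.sequence) == (0, 4, "AAAA")

    def test_blocked_site_leaves_sequence_intact(self):
        specs = pp.compile_ruleset("BIOPEP", ["trypsin"])
        assert [f.sequence for f in pp.codigest("AAKPAA", specs)] == ["AAKPAA"]

    def test_mixed_dialects_rejected(self, biopep_specs, expasy_specs):
        with pytest.raises(DialectMismatchError):
            pp.codigest("AAKAA", [biopep_specs[0], expasy_specs[1]])

    @settings(max_examples=200, deadline=None)
    @given(sequence=sequences, dialect=st.sampled_from(["BIOPEP", "EXPASY"]))
    def test_reassembly(self, sequence, dialect):
        specs = pp.compile_ruleset(dialect)
        frags = pp.codigest(sequence, specs)
        assert "".join(f.sequence for f in frags) == sequence
        assert all(f.sequence == sequence[f.start : f.end] for f in frags)
        bounds = [0] + [f.end for f in frags]
        assert all(f.start == b for f, b in zip(frags, bounds))

    def test_biopep_idempotence(self, biopep_specs):
        # BIOPEP exceptions never look beyond P1/P1', so a fragment carries
        # all context its own cut decisions need: exhaustive digestion is a
        # fixed point.
        for seq in random_sequences(seed=7, n=300):
            for frag in pp.codigest(seq, biopep_specs):
                again = pp.codigest(frag.sequence, biopep_specs)
                assert [g.sequence for g in again] == [frag.sequence]

    def test_expasy_context_loss_at_fragment_boundary(self):
        # EXPASY trypsin blocks R|H when R sits at P2 -- but that P2 arginine
        # is itself a cut site, so the liberated fragment "RHA" re-digests.
        # Context-dependent exceptions make single-pass digestion of the
        # *parent* authoritative; fragment-local re-digestion may add cuts.
        trypsin = pp.compile_ruleset("EXPASY", ["trypsin"])
        frags = [f.sequence for f in pp.codigest("ARRHA", trypsin)]
        assert frags == ["AR", "RHA"]
        assert [f.sequence for f in pp.codigest("RHA", trypsin)] == ["R", "HA"]


class TestDigestProteome:
    def test_pooled_counts_and_provenance(self):
        records = [pp.ProteinRecord("P1", "toy", "AAKAA")]
        pooled = pp.digest_proteome(records, ["EXPASY"])
        assert [f.sequence for f in pooled.fragments] == ["AAK", "AA"]
        assert pooled.total_fragments == 2
        assert pooled.length_histogram == {2: 1, 3: 1}
        assert pooled.unique_sequences["AAK"] == {("P1", "EXPASY")}

    def test_single_residues_excluded_from_headline_total(self):
        records = [pp.ProteinRecord("P1", "toy", "AKFA")]
        pooled = pp.digest_proteome(records, ["EXPASY"], enzyme_ids=["trypsin", "chymotrypsin_A"])
        assert [f.sequence for f in pooled.fragments] == ["AK", "F", "A"]
        assert pooled.total_fragments == 1  # only AK has length >= 2
        assert pooled.length_histogram == {1: 2, 2: 1}

    def test_duplicate_accessions_rejected(self):
        records = [
            pp.ProteinRecord("P1", "a", "AAKAA"),
            pp.ProteinRecord("P1", "b", "AARAA"),
        ]
        with pytest.raises(ValueError, match="P1"):
            pp.digest_proteome(records)

    def test_dialect_separation_mean_fragment_length(self):
        # the BIOPEP rules cut far more densely, yielding mostly di/tripeptides
        means = {}
        for dialect in ("BIOPEP", "EXPASY"):
            specs = pp.compile_ruleset(dialect)
            lengths = [
                len(f)
                for seq in random_sequences(seed=11, n=200)
                for f in pp.codigest(seq, specs)
            ]
            means[dialect] = sum(lengths) / len(lengths)
        assert means["BIOPEP"] <= means["EXPASY"]


class TestLengthFilter:
    def test_bounds_inclusive(self):
        records = [pp.ProteinRecord("P1", "toy", "AAKPAAKFA")]
        pooled = pp.digest_proteome(records, ["BIOPEP"], enzyme_ids=["trypsin"])
        selected = pp.length_filter(pooled, 5, 10)
        assert set(selected) == {"AAKPAAK"}  # "FA" falls below the bound
        assert all(5 <= len(s) <= 10 for s in selected)

    def test_exact_boundary(self):
        pooled = pp.PooledDigest(
            fragments=[pp.PeptideFragment("P", 0, 2, "AK", "EXPASY")]
        )
        assert set(pp.length_filter(pooled, 2, 2)) == {"AK"}

    def test_invalid_bounds_rejected(self):
        pooled = pp.PooledDigest(fragments=[])
        with pytest.raises(ValueError):
            pp.length_filter(pooled, 10, 5)


class TestFragmentConsistency:
    def test_terminal_site_is_consistent(self, expasy_specs):
        assert pp.fragment_consistency("AAK", expasy_specs)

    def test_internal_unblocked_site_is_inconsistent(self, expasy_specs):
        assert not pp.fragment_consistency("AAKAA", expasy_specs)

    def test_known_surviving_product(self, expasy_specs):
        assert pp.fragment_consistency("NSPAM", expasy_specs)

    def test_longlist_sequences_survive_under_some_dialect(
        self, longlist, biopep_specs, expasy_specs
    ):
        for record in longlist:
            assert pp.fragment_consistency(
                record.sequence, expasy_specs
            ) or pp.fragment_consistency(record.sequence, biopep_specs), record.sequence
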