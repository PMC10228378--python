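"""Seeded genus-name mutation pipeline."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from virnomina import (
    EmptyInputError,
    MutationConfig,
    NoVowelError,
    StructuralError,
    TaxonomyIndex,
    apply_substitution_steps,
    forge_genus_names,
    interleave_digits,
    shape_stem,
    strip_digits,
)

terms = st.from_regex(r"[a-z]{1,12}", fullmatch=True)


class TestMutationConfig:
    def test_requires_exactly_three_steps(self):
        with pytest.raises(ValueError):
            MutationConfig(substitution_steps=({}, {}))

    def test_rejects_non_neuter_rank_suffix(self):
        with pytest.raises(ValueError):
            MutationConfig(rank_suffix="viridae")

    def test_rejects_malformed_substitution_keys(self):
        with pytest.raises(ValueError):
            MutationConfig(substitution_steps=({"4a": "b"}, {}, {}))


class TestInterleaveDigits:
    def test_alternating_structure(self):
        out = interleave_digits("ab", np.random.default_rng(0))
        assert len(out) == 4
        assert out[0] in "123" and out[1] == "a" and out[2] in "123" and out[3] == "b"

    @settings(max_examples=100, derandomize=True)
    @given(terms, st.integers(0, 2**31 - 1))
    def test_strip_round_trip_recovers_the_term(self, term, seed):
        out = interleave_digits(term, np.random.default_rng(seed))
        assert strip_digits(out).text == term

    def test_deterministic_for_a_given_seed(self):
        a = interleave_digits("boston", np.random.default_rng(99))
        b = interleave_digits("boston", np.random.default_rng(99))
        assert a == b


class TestApplySubstitutionSteps:
    def test_single_rule_rewrites_the_pair_keeping_the_digit(self):
        config = MutationConfig(substitution_steps=({}, {"2o": "u"}, {}))
        assert apply_substitution_steps("1b2o", config) == "1b2u"

    def test_first_letter_is_never_mutated(self):
        config = MutationConfig(substitution_steps=({"1b": "p"}, {}, {}))
        assert apply_substitution_steps("1b1b", config) == "1b1p"

    def test_empty_maps_are_the_identity(self, identity_config):
        assert apply_substitution_steps("1a2b3c", identity_config) == "1a2b3c"

    def test_steps_apply_in_order(self):
        # step 1 creates a pair that step 2 then rewrites
        config = MutationConfig(substitution_steps=({"1o": "u"}, {"1u": "a"}, {}))
        assert apply_substitution_steps("1b1o", config) == "1b1a"

    @pytest.mark.parametrize("bad", ["1b2", "b2o1", "ab", ""])
    def test_malformed_strings_are_structural_errors(self, bad, default_config):
        with pytest.raises(StructuralError):
            apply_substitution_steps(bad, default_config)

    def test_stripping_an_empty_string_errors(self):
        with pytest.raises(EmptyInputError):
            strip_digits("")


class TestShapeStem:
    @pytest.mark.parametrize(
        "token, expected",
        [
            ("aaronn", "aro"),  # collapse runs, then trim trailing consonant
            ("washington", "washi"),  # truncate to 7, trim 'ng'
            ("boston", "bosto"),
            ("zairense", "zaire"),  # truncate to "zairens", trim "ns"
            ("aqua", "aqua"),
        ],
    )
    def test_hand_traces(self, token, expected, default_config):
        assert shape_stem(token, default_config).text == expected

    def test_all_consonant_terms_error(self, default_config):
        with pytest.raises(NoVowelError):
            shape_stem("bcdfg", default_config)

    @settings(max_examples=200, derandomize=True)
    @given(terms)
    def test_shaped_stems_end_in_a_vowel_and_respect_the_cap(self, term):
        config = MutationConfig()
        try:
            stem = shape_stem(term, config)
        except NoVowelError:
            assert not any(c in "aeiou" for c in term[: config.max_stem_chars])
            return
        assert stem.text[-1] in "aeiou"
        assert len(stem) <= config.max_stem_chars
        assert all(a != b for a, b in zip(stem.text, stem.text[1:]))


class TestForgeGenusNames:
    def test_boston_with_identity_maps_becomes_bostovirus(
        self, identity_config, empty_taxonomy
    ):
        report = forge_genus_names(["boston"], identity_config, empty_taxonomy)
        assert report.names == ["Bostovirus"]

    @pytest.mark.parametrize(
        "term, reason",
        [
            ("aeiou", "consonant-count"),  # 0 consonants
            ("levi", "too-short"),  # 4-char stem
            ("bcdfg", "no-vowel"),
            ("srb", "no-vowel"),
        ],
    )
    def test_rejection_reasons(self, term, reason, identity_config, empty_taxonomy):
        report = forge_genus_names([term], identity_config, empty_taxonomy)
        assert not report.accepted
        assert report.rejected[0].reason == reason

    def test_stem_collision_with_taxonomy(self, identity_config):
        taxonomy = TaxonomyIndex.empty().with_names(["Bostovirus"])
        report = forge_genus_names(["boston"], identity_config, taxonomy)
        assert report.rejected[0].reason == "stem-collision"

    def test_blocklist_is_substring_on_the_stem(self, identity_config, empty_taxonomy):
        report = forge_genus_names(
            ["boston"], identity_config, empty_taxonomy, blocklist=["OSTO"]
        )
        assert report.rejected[0].reason == "blocklist"

    def test_duplicate_outputs_keep_the_first(self, identity_config, empty_taxonomy):
        report = forge_genus_names(["boston", "boston"], identity_config, empty_taxonomy)
        assert report.names == ["Bostovirus"]
        assert report.rejected[0].reason == "duplicate-output"

    def test_accepted_and_rejected_partition_the_input(
        self, default_config, empty_taxonomy
    ):
        inputs = ["boston", "aeiou", "washington", "bcdfg", "zaire"]
        report = forge_genus_names(inputs, default_config, empty_taxonomy)
        assert len(report.accepted) + len(report.rejected) == len(inputs)
        fates = {r.term for r in report.accepted} | {r.term for r in report.rejected}
        assert fates == set(inputs)

    def test_every_accepted_name_is_well_formed(self, default_config, empty_taxonomy):
        import re

        from virnomina import TermSamplerConfig, sample_terms

        inputs = [str(t) for t in sample_terms(TermSamplerConfig(seed=5, n_terms=60))]
        report = forge_genus_names(inputs, default_config, empty_taxonomy)
        assert report.accepted
        pattern = re.compile(r"^[A-Z][a-z]+(virus|satellite|viriform|viroid)$")
        for rec in report.accepted:
            assert pattern.match(rec.name)
            stem = rec.name[: -len("virus")].lower()
            assert stem[-1] in "aeiou"
        assert len(set(report.names)) == len(report.names)

    def test_runs_are_reproducible_from_the_seed(self, default_config, empty_taxonomy):
        inputs = ["boston", "washington", "atlanta", "quebec"]
        a = forge_genus_names(inputs, default_config, empty_taxonomy)
        b = forge_genus_names(inputs, default_config, empty_taxonomy)
        assert a == b

    def test_different_seeds_generically_differ(self, empty_taxonomy):
        from virnomina import TermSamplerConfig, sample_terms

        inputs = [str(t) for t in sample_terms(TermSamplerConfig(seed=3, n_terms=40))]
        a = forge_genus_names(inputs, MutationConfig(seed=1), empty_taxonomy)
        b = forge_genus_names(inputs, MutationConfig(seed=2), empty_taxonomy)
        assert a.names != b.names

    def test_empty_input_errors(self, default_config, empty_taxonomy):
        with pytest.raises(EmptyInputError):
            forge_genus_names([], default_config, empty_taxonomy)

    def test_all_terms_rejected_is_a_report_not_an_error(
        self, identity_config, empty_taxonomy
    ):
        report = forge_genus_names(["bcdfg", "xyz"], identity_config, empty_taxonomy)
        assert report.accepted == ()
        assert len(report.rejected) == 2
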