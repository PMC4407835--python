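import pytest
from hypothesis import given, settings, strategies as st

import espre as E
from espre.text_processing import NEG_PREFIX, RAW_PREFIX


class TestTokenize:
    def test_simple_sentence(self):
        tokens = E.tokenize("No CNS disease.")
        assert [t.text for t in tokens] == ["no", "cns", "disease"]

    def test_empty_text(self):
        assert E.tokenize("") == []

    def test_punctuation_splits_and_offsets_reconstruct(self):
        text = "T-cell ALL (relapsed)"
        tokens = E.tokenize(text)
        assert [t.text for t in tokens] == ["t", "cell", "all", "relapsed"]
        for tok in tokens:
            assert text[tok.start : tok.end].lower() == tok.text

    @settings(derandomize=True, max_examples=100)
    @given(st.text(max_size=60))
    def test_offsets_match_character_scan_oracle(self, text):
        # oracle: independent character-by-character run finder
        expected, run = [], None
        for i, ch in enumerate(text):
            if ch.lower().isascii() and ch.lower().isalnum():
                run = i if run is None else run
            elif run is not None:
                expected.append((run, i))
                run = None
        if run is not None:
            expected.append((run, len(text)))
        tokens = E.tokenize(text)
        assert [(t.start, t.end) for t in tokens] == expected
        assert all(t.start < t.end for t in tokens)
        assert all(
            a.end <= b.start for a, b in zip(tokens, tokens[1:])
        )


def oracle_leftmost_longest(texts, index):
    """Enumerate all matching sub-spans, pick by (start, longest first)."""
    candidates = [
        (i, j)
        for i in range(len(texts))
        for j in range(i + 1, len(texts) + 1)
        if tuple(texts[i:j]) in index.phrase_map
    ]
    chosen, used = [], set()
    for i, j in sorted(candidates, key=lambda s: (s[0], s[0] - s[1])):
        if not (set(range(i, j)) & used):
            chosen.append((i, j))
            used.update(range(i, j))
    return sorted(chosen)


class TestExtractMentions:
    def test_longest_match_beats_shorter_synonym(self, mini_index):
        tokens = E.tokenize("central nervous system disease present")
        mentions = E.extract_mentions(tokens, mini_index)
        assert [(m.concept_id, m.span) for m in mentions] == [("C1", (0, 4))]

    def test_no_dictionary_phrase(self, mini_index):
        tokens = E.tokenize("perfectly healthy child")
        assert E.extract_mentions(tokens, mini_index) == []

    def test_repeated_phrase_yields_two_mentions(self, mini_index):
        tokens = E.tokenize("cns disease cns disease")
        mentions = E.extract_mentions(tokens, mini_index)
        assert [m.span for m in mentions] == [(0, 2), (2, 4)]

    @settings(derandomize=True, max_examples=200)
    @given(
        words=st.lists(
            st.sampled_from(
                ["cns", "disease", "central", "nervous", "system",
                 "fever", "leukemia", "acute", "lymphoblastic", "the"]
            ),
            max_size=12,
        )
    )
    def test_equivalence_with_brute_force_oracle(self, words, mini_index):
        tokens = E.tokenize(" ".join(words))
        mentions = E.extract_mentions(tokens, mini_index)
        spans = [m.span for m in mentions]
        assert spans == oracle_leftmost_longest(
            [t.text for t in tokens], mini_index
        )
        # spans pairwise disjoint and sorted
        assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))


class TestDetectNegation:
    def run(self, text, index, triggers, window=5):
        tokens = E.tokenize(text)
        mentions = E.extract_mentions(tokens, index)
        return tokens, E.detect_negation(tokens, mentions, triggers, window)

    def test_no_cns_disease_negated(self, bundled_index, triggers):
        _, mentions = self.run("No CNS disease", bundled_index, triggers)
        assert [(m.concept_id, m.polarity) for m in mentions] == [
            ("23853001", E.Polarity.NEGATED)
        ]

    def test_pseudo_negation_keeps_assertion(self, mini_index, triggers):
        _, mentions = self.run("not only leukemia", mini_index, triggers)
        assert mentions[0].polarity is E.Polarity.ASSERTED

    def test_scope_cut_at_terminator(self, mini_index, triggers):
        _, mentions = self.run(
            "no fever but cns disease", mini_index, triggers
        )
        polarity = {m.concept_id: m.polarity for m in mentions}
        assert polarity == {
            "C2": E.Polarity.NEGATED,
            "C1": E.Polarity.ASSERTED,
        }

    def test_window_bounds_scope(self, mini_index, triggers):
        # 5 intervening tokens > default window of 5 → out of scope
        far = "no one two three four five fever"
        _, mentions = self.run(far, mini_index, triggers)
        assert mentions[0].polarity is E.Polarity.ASSERTED
        _, mentions = self.run(far, mini_index, triggers, window=7)
        assert mentions[0].polarity is E.Polarity.NEGATED

    def test_negation_never_changes_concept_set(
        self, bundled_index, triggers
    ):
        text = "denies fever without rash but reports headache no nausea"
        tokens = E.tokenize(text)
        before = E.extract_mentions(tokens, bundled_index)
        after = E.detect_negation(tokens, before, triggers)
        assert [m.concept_id for m in before] == [
            m.concept_id for m in after
        ]
        assert [m.span for m in before] == [m.span for m in after]


concept_keys = st.sets(
    st.sampled_from(["11", "22", "33", "44"]), max_size=4
)


class TestTermVector:
    def test_negated_mention_yields_neg_key(self, bundled_index, triggers):
        tokens = E.tokenize("No CNS disease")
        mentions = E.detect_negation(
            tokens, E.extract_mentions(tokens, bundled_index), triggers
        )
        vec = E.to_term_vector(mentions, tokens, include_raw_tokens=True)
        assert vec.terms == {"NEG23853001"}

    def test_empty_inputs_give_empty_vector(self):
        assert len(E.to_term_vector([], [])) == 0

    def test_binary_presence_deduplicates(self, mini_index):
        tokens = E.tokenize("fever and fever")
        vec = E.to_term_vector(
            E.extract_mentions(tokens, mini_index), tokens,
            include_raw_tokens=False,
        )
        assert vec.terms == {"C2"}

    def test_raw_tokens_respect_stopwords_and_mention_spans(
        self, mini_index
    ):
        tokens = E.tokenize("the child has fever today")
        vec = E.to_term_vector(
            E.extract_mentions(tokens, mini_index), tokens,
            include_raw_tokens=True,
        )
        assert vec.terms == {"C2", "w:child", "w:today"}

    def test_asserted_wins_over_negated_on_merge(self):
        vec = E.TermVector.from_keys({"11", "NEG11", "NEG22"})
        assert vec.terms == {"11", "NEG22"}

    @settings(derandomize=True, max_examples=100)
    @given(asserted=concept_keys, negated=concept_keys,
           raw=st.sets(st.sampled_from(["w:a", "w:b"]), max_size=2))
    def test_flip_polarity_is_involution(self, asserted, negated, raw):
        keys = asserted | {NEG_PREFIX + k for k in negated - asserted} | raw
        vec = E.TermVector.from_keys(keys)
        flipped = E.flip_polarity(vec)
        assert E.flip_polarity(flipped).terms == vec.terms
        # raw keys are untouched; concept keys all change polarity
        assert {k for k in flipped.terms if k.startswith(RAW_PREFIX)} == raw

    def test_flip_examples(self):
        assert E.flip_polarity(
            E.TermVector.from_keys({"23853001"})
        ).terms == {"NEG23853001"}
        assert E.flip_polarity(
            E.TermVector.from_keys({"NEG23853001"})
        ).terms == {"23853001"}
        assert E.flip_polarity(E.TermVector()).terms == frozenset()
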