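"""Section segmentation, tokenization, padding and bundle assembly."""

import numpy as np
import pytest

from icufusion.ingest import NoteBundle, RawNote
from icufusion.text_prep import (PAD_ID, UNK_ID, NoteSection, Vocabulary,
                                 assemble_bundle_text, flatten_bundle,
                                 pad_or_truncate, segment_sections, tokenize)

TABLE2 = ["CLINICAL HISTORY", "HISTORY OF PRESENT ILLNESS", "PAST MEDICAL HISTORY",
          "ALLERGIES", "FAMILY HISTORY", "CHIEF COMPLAINT",
          "MAJOR SURGICAL OR INVASIVE PROCEDURE"]


def note(text, t=1.0, stay="s"):
    return RawNote(stay, t, "Nursing", text)


def test_single_header_covers_full_text():
    spans = segment_sections("FAMILY HISTORY: none.")
    assert spans == [("FAMILY HISTORY", (0, 21))]


def test_all_seven_history_sections_recognized_in_order():
    text = " ".join(f"{h}: something here." for h in TABLE2)
    spans = segment_sections(text)
    assert [name for name, _ in spans] == TABLE2


def test_headerless_text_is_single_other_span():
    assert segment_sections("just plain narrative") == [("OTHER", (0, 20))]
    assert segment_sections("") == []


def test_text_before_first_header_goes_to_other():
    spans = segment_sections("preamble words. ALLERGIES: nkda")
    assert spans[0][0] == "OTHER" and spans[1][0] == "ALLERGIES"


def test_surface_variants_map_to_canonical_names():
    spans = segment_sections("HPI: chest pain. PMH: diabetes.")
    assert [n for n, _ in spans] == ["HISTORY OF PRESENT ILLNESS", "PAST MEDICAL HISTORY"]


@pytest.mark.parametrize("seed", range(5))
def test_random_header_permutation_partitions_text_exactly(seed):
    rng = np.random.default_rng(seed)
    headers = list(rng.permutation(TABLE2))
    text = "lead-in. " + " ".join(f"{h}: w{i} w{i}." for i, h in enumerate(headers))
    spans = segment_sections(text)
    # spans are contiguous, ordered and reconstruct the original text
    assert spans[0][1][0] == 0 and spans[-1][1][1] == len(text)
    for (_, (lo1, hi1)), (_, (lo2, _)) in zip(spans, spans[1:]):
        assert hi1 == lo2
    assert "".join(text[lo:hi] for _, (lo, hi) in spans) == text


def test_tokenize_strips_punctuation_and_lowers():
    toks, flags = tokenize("Systolic Blood Pressure.")
    assert toks == ["systolic", "blood", "pressure"]
    assert flags == [False, False, False]


def test_tokenize_flags_stop_words():
    toks, flags = tokenize("the urine")
    assert toks == ["the", "urine"] and flags == [True, False]


def test_tokenize_is_idempotent_on_detokenized_text():
    rng = np.random.default_rng(3)
    words = ["alpha", "beta", "Gamma!", "x9", "the,", "Quick-"]
    for _ in range(20):
        text = " ".join(rng.choice(words, size=8))
        toks, _ = tokenize(text)
        assert tokenize(" ".join(toks))[0] == toks


def test_truncation_keeps_head_to_exactly_max_len():
    seq = pad_or_truncate([f"t{i}" for i in range(1200)], 1000)
    assert seq.content_length == 1000 and seq.max_len == 1000
    assert seq.tokens[0] == "t0" and seq.tokens[-1] == "t999"


def test_shortfall_is_zero_padded():
    seq = pad_or_truncate([f"t{i}" for i in range(900)], 1000)
    assert seq.content_length == 900
    assert (seq.ids[900:] == PAD_ID).all()


def test_empty_input_is_all_pad():
    seq = pad_or_truncate([], 50)
    assert seq.content_length == 0
    assert (seq.ids == PAD_ID).all() and seq.sections == []


def test_tail_truncation_shifts_section_spans():
    sections = [NoteSection("A", 0, 6), NoteSection("B", 6, 10)]
    seq = pad_or_truncate([f"t{i}" for i in range(10)], 5,
                          sections=sections, side="tail")
    assert seq.tokens == ["t5", "t6", "t7", "t8", "t9"]
    assert seq.sections == [NoteSection("A", 0, 1), NoteSection("B", 1, 5)]


def test_section_spans_partition_content_after_clipping():
    sections = [NoteSection("A", 0, 7), NoteSection("B", 7, 12)]
    seq = pad_or_truncate([f"t{i}" for i in range(12)], 9, sections=sections)
    assert seq.sections == [NoteSection("A", 0, 7), NoteSection("B", 7, 9)]


def test_vocabulary_reserves_pad_and_unk():
    v = Vocabulary.build([["b", "a", "b"]])
    assert v.stoi["<pad>"] == PAD_ID and v.stoi["<unk>"] == UNK_ID
    ids = v.encode(["b", "zzz"])
    assert ids[0] == v.stoi["b"] and ids[1] == UNK_ID


def test_history_tokens_precede_window_tokens():
    bundle = NoteBundle("s",
                        window_notes=[note("CHIEF COMPLAINT: fever", t=5.0)],
                        history_notes=[note("ALLERGIES: penicillin", t=-40.0)])
    tokens, _, sections = flatten_bundle(bundle)
    assert tokens.index("penicillin") < tokens.index("fever")
    assert [s.name for s in sections] == ["ALLERGIES", "CHIEF COMPLAINT"]


def test_window_note_order_fixed_by_chart_time():
    n1, n2 = note("ALLERGIES: aaa", t=3.0), note("ALLERGIES: bbb", t=9.0)
    from icufusion.ingest import PatientEpisode, select_notes
    for order in ([n1, n2], [n2, n1]):
        ep = PatientEpisode("s", 50.0, False, [], list(order))
        seq = assemble_bundle_text(select_notes(ep, 48.0), max_len=20)
        assert seq.tokens.index("aaa") < seq.tokens.index("bbb")


def test_non_chronic_bundle_equals_window_note_alone():
    w = note("CHIEF COMPLAINT: fever", t=5.0)
    h = note("ALLERGIES: penicillin", t=-40.0)
    with_history = NoteBundle("s", window_notes=[w], history_notes=[h])
    window_only = NoteBundle("s", window_notes=[w])
    alone = assemble_bundle_text(window_only, max_len=20)
    assert alone.tokens == flatten_bundle(NoteBundle("s", window_notes=[w]))[0]
    assert with_history.K == 1 and window_only.K == 0


def test_empty_bundle_yields_all_pad_sequence():
    seq = assemble_bundle_text(NoteBundle("s"), max_len=30)
    assert seq.content_length == 0 and (seq.ids == PAD_ID).all()


def test_spans_partition_content_for_generated_bundles(small_episodes):
    from icufusion.ingest import select_notes
    episodes, _ = small_episodes
    for ep in episodes[:10]:
        seq = assemble_bundle_text(select_notes(ep, 48.0, chronic=True), max_len=200)
        covered = []
        for s in seq.sections:
            assert 0 <= s.start < s.end <= seq.content_length
            covered.extend(range(s.start, s.end))
        assert covered == list(range(seq.content_length))
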