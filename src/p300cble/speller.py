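"""Row-column speller decoding: aggregate trial scores into character choices.

Each character is spelled by summing the classifier scores of every row code
and every column code across the sequences, then intersecting the best row
with the best column in the 6x6 matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpellerResult",
    "default_layout",
    "normalize_text",
    "char_to_rowcol",
    "decode",
    "accuracy_per_sentence",
]

#: cell that punctuation ('.') is aliased to during normalization
PERIOD_ALIAS = "9"


def default_layout(rows: int = 6, cols: int = 6) -> np.ndarray:
    """Character matrix, filled row-major with A-Z then 0-9."""
    alphabet = [chr(ord("A") + i) for i in range(26)] + [str(d) for d in range(10)]
    if rows * cols > len(alphabet):
        raise ValueError("layout larger than the available alphabet")
    return np.array(alphabet[: rows * cols]).reshape(rows, cols)


def normalize_text(text: str) -> str:
    """Uppercase, strip spaces, alias '.' into the matrix. Keeps other chars."""
    out = []
    for ch in text.upper():
        if ch == " ":
            continue
        out.append(PERIOD_ALIAS if ch == "." else ch)
    return "".join(out)


def char_to_rowcol(ch: str, layout: np.ndarray) -> tuple[int, int]:
    """(row, col) of a normalized character; ValueError if not in the matrix."""
    pos = np.argwhere(layout == ch)
    if len(pos) == 0:
        raise ValueError(f"character {ch!r} is not representable in the matrix")
    return int(pos[0][0]), int(pos[0][1])


@dataclass
class SpellerResult:
    predicted_chars: str
    true_chars: str | None
    per_char_row_scores: np.ndarray  # n_chars x 6
    per_char_col_scores: np.ndarray  # n_chars x 6
    accuracy: float | None

    def __post_init__(self) -> None:
        if self.true_chars is not None and len(self.true_chars) != len(self.predicted_chars):
            raise ValueError("predicted and true character strings differ in length")


def decode(
    scores: np.ndarray,
    stim_code: np.ndarray,
    char_index: np.ndarray,
    sequence_index: np.ndarray,
    layout: np.ndarray | None = None,
    n_sequences: int | None = None,
    true_chars: str | None = None,
) -> SpellerResult:
    """Select one character per spelled position from per-trial scores.

    For each character, the scores of the 6 row codes (1-6) and 6 column
    codes (7-12) are summed across the sequences used; the predicted row and
    column are the argmax of those sums (ties broken toward the lowest
    index).  ``n_sequences`` limits decoding to the first S' sequences for
    learning-curve analyses; the default uses all available sequences.
    """
    if layout is None:
        layout = default_layout()
    n_rows, n_cols = layout.shape
    scores = np.asarray(scores, dtype=float)
    stim_code = np.asarray(stim_code)
    char_index = np.asarray(char_index)
    sequence_index = np.asarray(sequence_index)

    chars = np.unique(char_index)
    row_sums = np.zeros((len(chars), n_rows))
    col_sums = np.zeros((len(chars), n_cols))
    predicted = []
    for k, c in enumerate(chars):
        mask = char_index == c
        if n_sequences is not None:
            mask &= sequence_index < n_sequences
        seqs = np.unique(sequence_index[mask])
        for s in seqs:
            m = mask & (sequence_index == s)
            codes = np.sort(stim_code[m])
            if not np.array_equal(codes, np.arange(1, n_rows + n_cols + 1)):
                raise ValueError(
                    f"character {c}, sequence {s}: expected all codes "
                    f"1..{n_rows + n_cols} exactly once, got {codes.tolist()}"
                )
        codes_c = stim_code[mask]
        scores_c = scores[mask]
        for r in range(n_rows):
            row_sums[k, r] = scores_c[codes_c == r + 1].sum()
        for cc in range(n_cols):
            col_sums[k, cc] = scores_c[codes_c == cc + 1 + n_rows].sum()
        r_hat = int(np.argmax(row_sums[k]))  # argmax takes the first maximum
        c_hat = int(np.argmax(col_sums[k]))
        predicted.append(layout[r_hat, c_hat])

    predicted_chars = "".join(predicted)
    accuracy = None
    if true_chars is not None:
        true_chars = normalize_text(true_chars)
        matches = sum(p == t for p, t in zip(predicted_chars, true_chars))
        accuracy = matches / len(true_chars) if true_chars else float("nan")
    return SpellerResult(
        predicted_chars=predicted_chars,
        true_chars=true_chars,
        per_char_row_scores=row_sums,
        per_char_col_scores=col_sums,
        accuracy=accuracy,
    )


def accuracy_per_sentence(result: SpellerResult, sentence_of_char: np.ndarray) -> list[float]:
    """Fraction of correctly decoded characters, split by sentence."""
    if result.true_chars is None:
        raise ValueError("result carries no true characters")
    sentence_of_char = np.asarray(sentence_of_char)
    correct = np.array(
        [p == t for p, t in zip(result.predicted_chars, result.true_chars)], dtype=float
    )
    return [float(correct[sentence_of_char == s].mean()) for s in np.unique(sentence_of_char)]
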