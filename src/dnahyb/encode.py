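"""Pair encodings for the neural regressors.

Two injective encodings of a sequence pair:

* an *image*: a ``4 x n_max x 2`` grid where each non-padding column is the
  one-hot of one nucleobase (row order A, C, G, T), channel 0 carrying the
  first strand and channel 1 the second, sequences left-aligned and
  zero-padded on the right up to ``n_max``;
* a *token* sequence ``<b> seq_a <s> seq_b <s>``: the two strands joined by
  a separator token, with a beginning marker prepended and the separator
  doubling as the end marker, right-padded with ``<pad>`` when batched.
"""

from __future__ import annotations

import numpy as np

from .seqops import ALPHABET, clean_sequence

N_MAX = 26

ROW_INDEX = {base: i for i, base in enumerate(ALPHABET)}

PAD, BEGIN, SEP = "<pad>", "<b>", "<s>"
VOCABULARY: dict[str, int] = {PAD: 0, BEGIN: 1, SEP: 2,
                              "A": 3, "C": 4, "G": 5, "T": 6}
_INDEX_TO_TOKEN = {i: t for t, i in VOCABULARY.items()}


def encode_image(pair: tuple[str, str], n_max: int = N_MAX) -> np.ndarray:
    """One-hot image of a pair, shape ``(4, n_max, 2)`` float32."""
    a, b = clean_sequence(pair[0]), clean_sequence(pair[1])
    if len(a) > n_max or len(b) > n_max:
        raise ValueError(
            f"sequence longer than n_max={n_max}: lengths {len(a)}, {len(b)}")
    image = np.zeros((4, n_max, 2), dtype=np.float32)
    for channel, seq in enumerate((a, b)):
        for col, base in enumerate(seq):
            image[ROW_INDEX[base], col, channel] = 1.0
    return image


def decode_image(image: np.ndarray) -> tuple[str, str]:
    """Inverse of :func:`encode_image` (padding columns are all-zero)."""
    if image.ndim != 3 or image.shape[0] != 4 or image.shape[2] != 2:
        raise ValueError(f"expected shape (4, n_max, 2), got {image.shape}")
    out = []
    for channel in range(2):
        grid = image[:, :, channel]
        seq = []
        for col in range(grid.shape[1]):
            column = grid[:, col]
            if not column.any():
                break
            if column.sum() != 1.0:
                raise ValueError(f"column {col} channel {channel} is not one-hot")
            seq.append(ALPHABET[int(np.argmax(column))])
        out.append("".join(seq))
    return out[0], out[1]


def encode_tokens(pair: tuple[str, str]) -> list[int]:
    """Token indices ``<b> seq_a <s> seq_b <s>`` (length = len(a)+len(b)+3)."""
    a, b = clean_sequence(pair[0]), clean_sequence(pair[1])
    tokens = [BEGIN, *a, SEP, *b, SEP]
    return [VOCABULARY[t] for t in tokens]


def decode_tokens(token_ids) -> tuple[str, str]:
    """Inverse of :func:`encode_tokens`; trailing padding is ignored."""
    tokens = [_INDEX_TO_TOKEN[int(i)] for i in token_ids]
    while tokens and tokens[-1] == PAD:
        tokens.pop()
    if len(tokens) < 3 or tokens[0] != BEGIN or tokens[-1] != SEP:
        raise ValueError("token stream does not match <b> a <s> b <s> layout")
    try:
        sep_at = tokens.index(SEP)
    except ValueError:  # pragma: no cover - guarded by the check above
        raise ValueError("missing separator token")
    if sep_at == len(tokens) - 1:
        raise ValueError("token stream has a single separator")
    a = "".join(tokens[1:sep_at])
    b = "".join(tokens[sep_at + 1:-1])
    return clean_sequence(a), clean_sequence(b)


def batch_images(pairs, n_max: int = N_MAX) -> np.ndarray:
    """Stack pair images into shape ``(batch, 4, n_max, 2)``."""
    return np.stack([encode_image(p, n_max) for p in pairs])


def batch_tokens(pairs) -> np.ndarray:
    """Encode and right-pad token sequences into an int array
    ``(batch, max_len)``."""
    encoded = [encode_tokens(p) for p in pairs]
    width = max(len(e) for e in encoded)
    out = np.full((len(encoded), width), VOCABULARY[PAD], dtype=np.int64)
    for i, e in enumerate(encoded):
        out[i, :len(e)] = e
    return out
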