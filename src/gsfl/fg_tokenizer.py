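"""Multi-level SMILES tokenization.

A SMILES string is decomposed into three levels of tokens:

* ``functional_group`` — high-frequency chemically meaningful substrings
  (amide ``C(=O)N``, benzene ``c1ccccc1``, nitro ``[N+](=O)[O-]``, ...),
  matched greedily longest-first;
* ``ion_group`` — any remaining bracketed unit ``[...]`` (charge,
  chirality, explicit H) kept whole;
* ``atom`` — every remaining character, with the two-letter organic-subset
  halogens ``Cl``/``Br`` and ``%NN`` ring closures kept whole.

Concatenating the tokens in order always reproduces the input string
exactly, so the decomposition is lossless.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DEFAULT_FUNCTIONAL_GROUPS",
    "LEVEL_FUNCTIONAL_GROUP",
    "LEVEL_ION_GROUP",
    "LEVEL_ATOM",
    "LEVELS",
    "FunctionalGroupVocab",
    "TokenSequence",
    "TokenDictionary",
    "TokenizationError",
    "mine_functional_groups",
    "tokenize",
    "tokenize_characters",
    "build_dictionary",
    "encode_sequence",
]

LEVEL_FUNCTIONAL_GROUP = "functional_group"
LEVEL_ION_GROUP = "ion_group"
LEVEL_ATOM = "atom"
LEVELS = (LEVEL_FUNCTIONAL_GROUP, LEVEL_ION_GROUP, LEVEL_ATOM)

# Default functional-group vocabulary (benzene written in valid aromatic
# ring notation).  The nitro group appears with its bracket ions spelled
# out and is matched at functional-group level before bracket scanning.
DEFAULT_FUNCTIONAL_GROUPS: tuple[str, ...] = (
    "C(=O)N",
    "OCC",
    "[N+](=O)[O-]",
    "c1ccccc1",
    "S(=O)",
    "O=c",
    "NC(=O)",
    "NS(=O)(=O)",
    "OC",
    "S(=O)(=O)",
    "C=O",
    "O=C",
)

_TWO_LETTER_ATOMS = ("Cl", "Br")


class TokenizationError(ValueError):
    pass


@dataclass
class FunctionalGroupVocab:
    """Ordered functional-group patterns with corpus occurrence counts.

    Ordering: descending pattern length, then descending count, then
    lexicographic — the greedy tokenizer tries patterns in this order.
    """

    patterns: list[str]
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.patterns)) != len(self.patterns):
            raise ValueError("functional-group patterns must be unique")
        self.patterns = self._sorted(self.patterns, self.counts)

    @staticmethod
    def _sorted(patterns: Iterable[str], counts: dict[str, int]) -> list[str]:
        return sorted(patterns, key=lambda p: (-len(p), -counts.get(p, 0), p))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"patterns": self.patterns, "counts": self.counts}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FunctionalGroupVocab":
        with open(path) as fh:
            d = json.load(fh)
        return cls(patterns=d["patterns"], counts=d.get("counts", {}))


@dataclass
class TokenSequence:
    tokens: list[str]
    levels: list[str]

    def __post_init__(self):
        if len(self.tokens) != len(self.levels):
            raise ValueError("tokens and levels must be parallel")
        for lv in self.levels:
            if lv not in LEVELS:
                raise ValueError(f"unknown level {lv!r}")

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def smiles(self) -> str:
        return "".join(self.tokens)


@dataclass
class TokenDictionary:
    """Dense token→index map with PAD and UNK specials."""

    index: dict[str, int]
    pad_index: int
    unk_index: int

    PAD = "<pad>"
    UNK = "<unk>"

    def __len__(self) -> int:
        return len(self.index)

    def lookup(self, token: str) -> int:
        return self.index.get(token, self.unk_index)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"index": self.index, "pad": self.pad_index,
                       "unk": self.unk_index}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TokenDictionary":
        with open(path) as fh:
            d = json.load(fh)
        return cls(index=d["index"], pad_index=d["pad"], unk_index=d["unk"])


def mine_functional_groups(
    smiles_corpus: Sequence[str],
    min_count: int = 1,
    candidates: Sequence[str] | None = None,
) -> FunctionalGroupVocab:
    """Build the functional-group vocabulary from a corpus.

    The default patterns are always kept; candidate patterns (by default
    the same family) are counted as plain substring occurrences across
    the corpus and retained when seen at least ``min_count`` times.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    candidates = list(candidates) if candidates is not None else list(DEFAULT_FUNCTIONAL_GROUPS)
    counts: dict[str, int] = {}
    for pat in set(candidates) | set(DEFAULT_FUNCTIONAL_GROUPS):
        n = sum(s.count(pat) for s in smiles_corpus)
        if n:
            counts[pat] = n
    kept = set(DEFAULT_FUNCTIONAL_GROUPS)
    kept.update(p for p in candidates if counts.get(p, 0) >= min_count)
    return FunctionalGroupVocab(patterns=sorted(kept), counts=counts)


def tokenize(smiles: str, fg_vocab: FunctionalGroupVocab | None = None) -> TokenSequence:
    """Greedy left-to-right multi-level tokenization.

    At each position, in priority order: the longest matching functional
    group; a whole bracketed ``[...]`` unit; a two-letter halogen or
    ``%NN`` ring closure; a single character.
    """
    if not smiles:
        raise TokenizationError("empty SMILES string")
    patterns = fg_vocab.patterns if fg_vocab is not None else []
    tokens: list[str] = []
    levels: list[str] = []
    i, n = 0, len(smiles)
    while i < n:
        matched = False
        for pat in patterns:
            if smiles.startswith(pat, i):
                tokens.append(pat)
                levels.append(LEVEL_FUNCTIONAL_GROUP)
                i += len(pat)
                matched = True
                break
        if matched:
            continue
        ch = smiles[i]
        if ch == "[":
            close = smiles.find("]", i + 1)
            if close < 0:
                raise TokenizationError(f"unmatched '[' at position {i} in {smiles!r}")
            tokens.append(smiles[i: close + 1])
            levels.append(LEVEL_ION_GROUP)
            i = close + 1
            continue
        if smiles.startswith(_TWO_LETTER_ATOMS, i):
            tokens.append(smiles[i: i + 2])
            levels.append(LEVEL_ATOM)
            i += 2
            continue
        if ch == "%" and i + 2 < n and smiles[i + 1: i + 3].isdigit():
            tokens.append(smiles[i: i + 3])
            levels.append(LEVEL_ATOM)
            i += 3
            continue
        tokens.append(ch)
        levels.append(LEVEL_ATOM)
        i += 1
    return TokenSequence(tokens=tokens, levels=levels)


def tokenize_characters(smiles: str) -> TokenSequence:
    """Character-level tokenization (the Fg_Splitting-ablated variant)."""
    if not smiles:
        raise TokenizationError("empty SMILES string")
    return TokenSequence(tokens=list(smiles), levels=[LEVEL_ATOM] * len(smiles))


def build_dictionary(sequences: Sequence[TokenSequence]) -> TokenDictionary:
    """Token dictionary over a corpus: PAD=0, UNK=1, tokens sorted after."""
    if not sequences:
        raise ValueError("need at least one sequence")
    vocab = sorted({t for seq in sequences for t in seq.tokens})
    index = {TokenDictionary.PAD: 0, TokenDictionary.UNK: 1}
    for tok in vocab:
        index[tok] = len(index)
    return TokenDictionary(index=index, pad_index=0, unk_index=1)


def encode_sequence(
    seq: TokenSequence,
    dictionary: TokenDictionary,
    max_len: int = 128,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Encode a token sequence as (indices, level_ids, mask), padded/truncated
    to ``max_len``.  Unseen tokens map to UNK; pads have mask 0."""
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    idx = np.full(max_len, dictionary.pad_index, dtype=np.int64)
    lvl = np.zeros(max_len, dtype=np.int64)
    mask = np.zeros(max_len, dtype=np.float64)
    for j, (tok, level) in enumerate(zip(seq.tokens, seq.levels)):
        if j >= max_len:
            break
        idx[j] = dictionary.lookup(tok)
        lvl[j] = LEVELS.index(level)
        mask[j] = 1.0
    return idx, lvl, mask


def one_hot(indices: np.ndarray, size: int) -> np.ndarray:
    out = np.zeros((len(indices), size))
    out[np.arange(len(indices)), indices] = 1.0
    return out
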