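"""Alphabets, sequence encoding, FASTA input and synthetic pair generation.

Strings are treated as sequences of opaque symbols over a finite alphabet of
size ``s``.  Every algorithm in this package operates on :class:`EncodedSequence`
objects whose characters have been mapped to stable integer codes ``1..s``
over a shared :class:`Alphabet`; the alphabet size drives the strip-width
selection and the candidate enumeration of the divide-and-conquer trace.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Alphabet",
    "EncodedSequence",
    "UnknownSymbolError",
    "infer_alphabet",
    "encode_pair",
    "read_pair_fasta",
    "read_pair_text",
    "random_pair",
]

#: Symbol rosters used by :func:`random_pair` for familiar alphabet sizes.
_DNA = "ACGT"
_PROTEIN = "ACDEFGHIKLMNPQRSTVWY"
_GENERIC = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"


class UnknownSymbolError(ValueError):
    """A character of the input is absent from an explicitly given alphabet."""

    def __init__(self, char: str, position: int, which: str = "input"):
        self.char = char
        self.position = position  # 1-based
        super().__init__(
            f"unknown symbol {char!r} at position {position} of {which}: "
            "not in the supplied alphabet"
        )


@dataclass(frozen=True)
class Alphabet:
    """An ordered set of distinct symbols; symbol *i* has code ``i`` (1-based)."""

    symbols: tuple[str, ...]
    _index: dict[str, int] = field(repr=False, compare=False, default_factory=dict)

    def __post_init__(self):
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be distinct")
        object.__setattr__(
            self, "_index", {c: i + 1 for i, c in enumerate(self.symbols)}
        )

    @property
    def size(self) -> int:
        return len(self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, char: str) -> bool:
        return char in self._index

    def code(self, char: str) -> int:
        """1-based code of ``char``; raises ``KeyError`` if absent."""
        return self._index[char]

    def char(self, code: int) -> str:
        return self.symbols[code - 1]

    @classmethod
    def from_strings(cls, strings: Iterable[str]) -> "Alphabet":
        seen: dict[str, None] = {}
        for s in strings:
            for c in s:
                seen.setdefault(c, None)
        return cls(tuple(seen))


@dataclass(frozen=True)
class EncodedSequence:
    """A string together with its per-character codes over a shared alphabet."""

    raw: str
    codes: tuple[int, ...]
    alphabet: Alphabet

    def __len__(self) -> int:
        return len(self.codes)

    def __post_init__(self):
        if len(self.raw) != len(self.codes):
            raise ValueError("raw string and code list disagree in length")

    def decode(self) -> str:
        return "".join(self.alphabet.char(c) for c in self.codes)

    def reverse(self) -> "EncodedSequence":
        return EncodedSequence(self.raw[::-1], self.codes[::-1], self.alphabet)

    def slice(self, start: int, stop: int) -> "EncodedSequence":
        """Sub-sequence of 1-based positions ``start..stop`` inclusive."""
        return EncodedSequence(
            self.raw[start - 1 : stop], self.codes[start - 1 : stop], self.alphabet
        )


def infer_alphabet(strings: Iterable[str]) -> Alphabet:
    """Alphabet containing exactly the characters of ``strings``, first-seen order."""
    return Alphabet.from_strings(strings)


def _encode_one(s: str, alphabet: Alphabet, which: str) -> EncodedSequence:
    codes = []
    for pos, c in enumerate(s, start=1):
        if c not in alphabet:
            raise UnknownSymbolError(c, pos, which)
        codes.append(alphabet.code(c))
    return EncodedSequence(s, tuple(codes), alphabet)


def encode_pair(
    a: str,
    b: str,
    alphabet: Alphabet | None = None,
    *,
    fold_case: bool = False,
) -> tuple[EncodedSequence, EncodedSequence, Alphabet]:
    """Encode two strings over one shared alphabet.

    When ``alphabet`` is absent it is inferred as the union of characters of
    both strings in first-seen order; that inferred size is the ``s`` consumed
    by strip-width selection and crossing-candidate enumeration.  Comparisons
    are case-sensitive unless ``fold_case`` folds both strings to upper case
    first.
    """
    if fold_case:
        a, b = a.upper(), b.upper()
    if alphabet is None:
        alphabet = infer_alphabet([a, b])
    return (
        _encode_one(a, alphabet, "first string"),
        _encode_one(b, alphabet, "second string"),
        alphabet,
    )


def read_pair_fasta(path: str | Path) -> tuple[str, str]:
    """First two record sequences of a FASTA file (plain or gzipped).

    Line wraps and surrounding whitespace are removed; character case is
    preserved.  Raises ``ValueError`` when fewer than two records are present
    or the file does not start with a header line.
    """
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        first = fh.read(1)
        if first not in (">", ""):
            raise ValueError(f"{path}: malformed FASTA (sequence before header)")
        fh.seek(0)
        records = []
        for rec in SeqIO.parse(fh, "fasta"):
            records.append(rec)
            if len(records) == 2:
                break
    if len(records) < 2:
        raise ValueError(f"{path}: need two sequences, found {len(records)}")
    pair = tuple(str(r.seq).replace(" ", "").replace("\t", "") for r in records)
    # Headers kept for callers that want provenance.
    read_pair_fasta.last_headers = (records[0].description, records[1].description)
    return pair


def read_pair_text(path_a: str | Path, path_b: str | Path) -> tuple[str, str]:
    """Plain-text mode: each file holds one raw string on its first line."""

    def one(p):
        with open(p, "rt") as fh:
            return fh.readline().rstrip("\n")

    return one(path_a), one(path_b)


def symbol_roster(s: int) -> str:
    """Symbols used for synthetic alphabets: DNA at s=4, amino acids at s=20."""
    if s == 4:
        return _DNA
    if s == 20:
        return _PROTEIN
    if s > len(_GENERIC):
        raise ValueError(f"synthetic alphabets support at most {len(_GENERIC)} symbols")
    return _GENERIC[:s]


def random_pair(m: int, n: int, s: int, seed: int) -> tuple[str, str]:
    """Reproducible pair of i.i.d.-uniform random strings of lengths m and n."""
    if m < 0 or n < 0:
        raise ValueError("lengths must be nonnegative")
    if s < 1 and (m + n) > 0:
        raise ValueError("alphabet size must be >= 1 for nonempty strings")
    if m + n == 0:
        return "", ""
    roster = symbol_roster(s)
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, s, size=m + n)
    chars = [roster[i] for i in draws]
    return "".join(chars[:m]), "".join(chars[m:])
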