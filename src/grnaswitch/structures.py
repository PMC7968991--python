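"""Secondary-structure representation: pair tables over one or two strands.

Structures are nested (pseudoknot-free) pairings in global coordinates,
where a two-strand complex is the concatenation of its strands with a
nick between them.  Hairpin loops wholly within one strand must span at
least ``min_loop`` unpaired bases; loops spanning the nick are exempt.
"""
from __future__ import annotations

from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .sequences import NucSeq

__all__ = ["SecondaryStructure"]

StrandLike = Union[NucSeq, str, int]


def _strand_lengths(strands: Sequence[StrandLike]) -> Tuple[List[int], Optional[List[NucSeq]]]:
    lengths: List[int] = []
    seqs: List[NucSeq] = []
    have_seqs = True
    for s in strands:
        if isinstance(s, int):
            lengths.append(s)
            have_seqs = False
        elif isinstance(s, NucSeq):
            lengths.append(len(s))
            seqs.append(s)
        else:
            ns = NucSeq("strand", s)
            lengths.append(len(ns))
            seqs.append(ns)
    return lengths, (seqs if have_seqs else None)


class SecondaryStructure:
    """A pair table over 1 or 2 strands.

    ``pairs[i]`` is the global partner of position i, or -1 if unpaired.
    Strands may be given as NucSeq/str (sequences retained) or as bare
    ints (lengths only — useful for design *targets* whose sequences are
    not yet known).
    """

    def __init__(
        self,
        strands: Sequence[StrandLike] | StrandLike,
        pairs: Sequence[int],
        validate: bool = True,
        min_loop: int = 3,
    ) -> None:
        if isinstance(strands, (NucSeq, str, int)):
            strands = [strands]
        if not 1 <= len(strands) <= 2:
            raise ValueError("a structure covers 1 or 2 strands")
        self.lengths, self.strands = _strand_lengths(strands)
        self.n = sum(self.lengths)
        self.pairs = np.asarray(pairs, dtype=np.int64)
        if self.pairs.shape != (self.n,):
            raise ValueError(
                f"pair table length {self.pairs.shape} does not match total strand length {self.n}"
            )
        self.min_loop = min_loop
        if validate:
            self._validate()

    # -- construction -------------------------------------------------
    @classmethod
    def from_dotbracket(
        cls,
        db: str,
        strands: Sequence[StrandLike] | StrandLike | None = None,
        min_loop: int = 3,
        validate: bool = True,
    ) -> "SecondaryStructure":
        """Parse Vienna dot-bracket; '&' separates the strands of a complex."""
        segments = db.split("&")
        if len(segments) > 2:
            raise ValueError("at most one '&' (two strands) supported")
        flat = "".join(segments)
        if strands is None:
            strands = [len(seg) for seg in segments]
        if isinstance(strands, (NucSeq, str, int)):
            strands = [strands]
        lengths, _ = _strand_lengths(strands)
        if [len(seg) for seg in segments] != lengths:
            raise ValueError(
                f"dot-bracket segment lengths {[len(s) for s in segments]} do not match "
                f"strand lengths {lengths}"
            )
        pairs = np.full(len(flat), -1, dtype=np.int64)
        stack: List[int] = []
        for i, c in enumerate(flat):
            if c == "(":
                stack.append(i)
            elif c == ")":
                if not stack:
                    raise ValueError(f"unbalanced ')' at position {i}")
                j = stack.pop()
                pairs[j], pairs[i] = i, j
            elif c != ".":
                raise ValueError(f"invalid dot-bracket character {c!r}")
        if stack:
            raise ValueError("unbalanced '(' in dot-bracket")
        return cls(strands, pairs, validate=validate, min_loop=min_loop)

    def to_dotbracket(self) -> str:
        out = []
        for i, j in enumerate(self.pairs):
            out.append("." if j < 0 else ("(" if j > i else ")"))
        s = "".join(out)
        if self.nick is not None:
            s = s[: self.nick] + "&" + s[self.nick :]
        return s

    # -- properties ---------------------------------------------------
    @property
    def nick(self) -> Optional[int]:
        """Global index of the first position of strand 2, or None."""
        return self.lengths[0] if len(self.lengths) == 2 else None

    def pair_map(self) -> dict:
        """{i: j} with i < j for every pair."""
        return {int(i): int(j) for i, j in enumerate(self.pairs) if j > i}

    def spans_nick(self, i: int, j: int) -> bool:
        nick = self.nick
        return nick is not None and i < nick <= j

    # -- validation ---------------------------------------------------
    def _validate(self) -> None:
        p = self.pairs
        for i in range(self.n):
            j = p[i]
            if j < -1 or j >= self.n:
                raise ValueError(f"partner of {i} out of range: {j}")
            if j == i:
                raise ValueError(f"position {i} pairs itself")
            if j >= 0 and p[j] != i:
                raise ValueError(f"pairing not an involution at ({i}, {j})")
        opened: List[int] = []
        for i in range(self.n):
            j = p[i]
            if j > i:
                opened.append(i)
            elif 0 <= j < i:
                if not opened or opened[-1] != j:
                    raise ValueError(f"crossing (pseudoknotted) pair ({j}, {i})")
                opened.pop()
        # hairpin loops: pairs enclosing no other paired position
        for i in range(self.n):
            j = p[i]
            if j > i and all(p[k] < 0 for k in range(i + 1, j)):
                if (j - i - 1) < self.min_loop and not self.spans_nick(i, j):
                    raise ValueError(
                        f"hairpin loop of pair ({i}, {j}) spans {j - i - 1} < "
                        f"min_loop {self.min_loop} unpaired bases"
                    )

    # -- misc ---------------------------------------------------------
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SecondaryStructure):
            return NotImplemented
        return self.lengths == other.lengths and bool(np.array_equal(self.pairs, other.pairs))

    def __hash__(self) -> int:
        return hash((tuple(self.lengths), self.pairs.tobytes()))

    def __repr__(self) -> str:
        return f"SecondaryStructure({self.to_dotbracket()!r})"
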