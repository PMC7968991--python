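"""Sequence and switch-architecture domain types.

A Cas12a gRNA switch is a 5'-extended guide RNA laid out 5'->3' as

    toehold | clamp | loop | linker | repeat | guide

where the clamp is the reverse complement of the 5' prefix of the
processed direct repeat (the Cas12a "handle"), so that in isolation the
switch folds into an OFF state with the clamp sequestering the handle.
The cognate trigger RNA is laid out 5'->3' as

    revcomp(loop) | middle | revcomp(toehold)

so that toehold and loop hybridize to it antiparallel, releasing the
handle (ON state).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

__all__ = [
    "NucSeq",
    "SwitchArchitecture",
    "GRNASwitch",
    "TriggerSpec",
    "FN_CAS12A_REPEAT",
    "revcomp",
    "assemble_switch",
    "derive_trigger",
]

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_RNA_ALPHABET = frozenset("ACGU")
_AMBIG_ALPHABET = frozenset("ACGUN")


@dataclass(frozen=True)
class NucSeq:
    """An RNA sequence with a short id label.

    Input is canonicalized: upper-cased and T -> U.  Residues must be
    A/C/G/U; ``allow_n=True`` additionally admits N (natural RNAs read
    from FASTA), which design operations reject.
    """

    id: str
    residues: str
    allow_n: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        canon = self.residues.upper().replace("T", "U")
        object.__setattr__(self, "residues", canon)
        if len(canon) < 1:
            raise ValueError(f"{self.id!r}: empty sequence")
        alphabet = _AMBIG_ALPHABET if self.allow_n else _RNA_ALPHABET
        bad = set(canon) - alphabet
        if bad:
            raise ValueError(
                f"{self.id!r}: non-RNA characters {sorted(bad)} (alphabet {sorted(alphabet)})"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    @property
    def length(self) -> int:
        return len(self.residues)

    def require_unambiguous(self) -> "NucSeq":
        if "N" in self.residues:
            raise ValueError(f"{self.id!r}: ambiguous residue N not allowed here")
        return self


def revcomp(seq: NucSeq | str) -> NucSeq:
    """Reverse complement under A-U / G-C Watson-Crick rules."""
    if isinstance(seq, NucSeq):
        rc = "".join(_COMPLEMENT[c] for c in reversed(seq.residues))
        return NucSeq(id=f"{seq.id}_rc", residues=rc)
    rc = "".join(_COMPLEMENT[c] for c in reversed(seq.upper().replace("T", "U")))
    return NucSeq(id="rc", residues=rc)


#: Processed (mature) FnCas12a direct repeat, 19 nt.  Config data, not a
#: hard-coded assumption: any repeat of compatible length may be supplied.
FN_CAS12A_REPEAT = NucSeq(id="FnCas12a_repeat", residues="AAUUUCUACUGUUGUAGAU")


def _is_wc(a: str, b: str) -> bool:
    return _COMPLEMENT[a] == b


def _is_wobble(a: str, b: str) -> bool:
    return (a, b) in (("G", "U"), ("U", "G"))


@dataclass(frozen=True)
class SwitchArchitecture:
    """Sub-domain lengths plus the fixed repeat and guide of a switch.

    The default 15/13/15 toehold/clamp/loop architecture with the 19-nt
    processed repeat and a 24-nt guide gives an 86-nt switch and a 43-nt
    cognate trigger.
    """

    guide: NucSeq
    toehold_len: int = 15
    clamp_len: int = 13
    loop_len: int = 15
    linker_len: int = 0
    repeat: NucSeq = FN_CAS12A_REPEAT
    middle_len: Optional[int] = None  # defaults to clamp_len
    allow_wobble_clamp: bool = False
    min_loop: int = 3

    def __post_init__(self) -> None:
        if min(self.toehold_len, self.clamp_len, self.loop_len) < 1:
            raise ValueError("toehold_len, clamp_len and loop_len must each be >= 1")
        if self.linker_len < 0:
            raise ValueError("linker_len must be >= 0")
        if self.clamp_len > len(self.repeat):
            raise ValueError("clamp_len may not exceed the repeat length")
        if self.loop_len + self.linker_len < self.min_loop:
            raise ValueError(
                "loop_len + linker_len must be >= %d so the OFF-state hairpin "
                "loop satisfies the minimum-loop constraint" % self.min_loop
            )
        self.guide.require_unambiguous()
        self.repeat.require_unambiguous()

    @property
    def middle(self) -> int:
        return self.clamp_len if self.middle_len is None else self.middle_len

    @property
    def switch_length(self) -> int:
        return (
            self.toehold_len
            + self.clamp_len
            + self.loop_len
            + self.linker_len
            + len(self.repeat)
            + len(self.guide)
        )

    @property
    def trigger_length(self) -> int:
        return self.loop_len + self.middle + self.toehold_len

    def default_clamp(self) -> NucSeq:
        """Clamp = reverse complement of the 5' clamp_len prefix of the repeat."""
        return NucSeq(
            id="clamp", residues=revcomp(self.repeat.residues[: self.clamp_len]).residues
        )

    def with_(self, **kwargs) -> "SwitchArchitecture":
        return replace(self, **kwargs)


# sub-domain order within the assembled switch
DOMAIN_ORDER = ("toehold", "clamp", "loop", "linker", "repeat", "guide")


@dataclass(frozen=True)
class GRNASwitch:
    """An assembled switch sequence with its sub-domain coordinate map.

    ``coords`` maps each sub-domain name to a 0-based half-open interval
    in switch coordinates; the intervals tile [0, len(sequence)) in the
    order toehold -> clamp -> loop -> linker -> repeat -> guide.
    """

    arch: SwitchArchitecture
    sequence: NucSeq
    coords: Dict[str, Tuple[int, int]]

    def domain(self, name: str) -> str:
        start, end = self.coords[name]
        return self.sequence.residues[start:end]

    @property
    def toehold(self) -> str:
        return self.domain("toehold")

    @property
    def clamp(self) -> str:
        return self.domain("clamp")

    @property
    def loop(self) -> str:
        return self.domain("loop")

    @property
    def linker(self) -> str:
        return self.domain("linker")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TriggerSpec:
    """A trigger sequence with its loop-complement / middle / toehold-complement layout."""

    sequence: NucSeq
    layout: Dict[str, Tuple[int, int]]

    def segment(self, name: str) -> str:
        start, end = self.layout[name]
        return self.sequence.residues[start:end]

    def __len__(self) -> int:
        return len(self.sequence)


def _check_clamp_pairable(clamp: str, repeat: str, clamp_len: int, allow_wobble: bool) -> None:
    """Clamp position k must pair repeat position clamp_len-1-k."""
    for k in range(clamp_len):
        a, b = clamp[k], repeat[clamp_len - 1 - k]
        if _is_wc(a, b):
            continue
        if allow_wobble and _is_wobble(a, b):
            continue
        raise ValueError(
            f"clamp position {k} ({a}) cannot pair repeat position "
            f"{clamp_len - 1 - k} ({b}) under the current wobble policy"
        )


def assemble_switch(
    arch: SwitchArchitecture,
    toehold: NucSeq | str,
    loop: NucSeq | str,
    linker: NucSeq | str | None = None,
    clamp_override: NucSeq | str | None = None,
) -> GRNASwitch:
    """Assemble toehold|clamp|loop|linker|repeat|guide into a GRNASwitch.

    The clamp is derived from the repeat (reverse complement of its 5'
    ``clamp_len`` prefix) unless an explicit override is supplied, in
    which case the override must be pairable with the repeat prefix under
    the architecture's wobble policy.
    """
    toehold = toehold if isinstance(toehold, NucSeq) else NucSeq("toehold", toehold)
    loop = loop if isinstance(loop, NucSeq) else NucSeq("loop", loop)
    toehold.require_unambiguous()
    loop.require_unambiguous()
    if len(toehold) != arch.toehold_len:
        raise ValueError(f"toehold length {len(toehold)} != arch.toehold_len {arch.toehold_len}")
    if len(loop) != arch.loop_len:
        raise ValueError(f"loop length {len(loop)} != arch.loop_len {arch.loop_len}")

    if arch.linker_len == 0:
        if linker is not None and len(str(linker)) > 0:
            raise ValueError("architecture has no linker but a linker sequence was supplied")
        linker_res = ""
    else:
        if linker is None:
            raise ValueError(f"architecture requires a {arch.linker_len}-nt linker")
        linker = linker if isinstance(linker, NucSeq) else NucSeq("linker", linker)
        linker.require_unambiguous()
        if len(linker) != arch.linker_len:
            raise ValueError(f"linker length {len(linker)} != arch.linker_len {arch.linker_len}")
        linker_res = linker.residues

    if clamp_override is None:
        clamp_res = arch.default_clamp().residues
    else:
        clamp = clamp_override if isinstance(clamp_override, NucSeq) else NucSeq("clamp", clamp_override)
        clamp.require_unambiguous()
        if len(clamp) != arch.clamp_len:
            raise ValueError(f"clamp length {len(clamp)} != arch.clamp_len {arch.clamp_len}")
        clamp_res = clamp.residues
    _check_clamp_pairable(clamp_res, arch.repeat.residues, arch.clamp_len, arch.allow_wobble_clamp)

    parts = {
        "toehold": toehold.residues,
        "clamp": clamp_res,
        "loop": loop.residues,
        "linker": linker_res,
        "repeat": arch.repeat.residues,
        "guide": arch.guide.residues,
    }
    coords: Dict[str, Tuple[int, int]] = {}
    pos = 0
    seq_parts = []
    for name in DOMAIN_ORDER:
        coords[name] = (pos, pos + len(parts[name]))
        seq_parts.append(parts[name])
        pos += len(parts[name])
    sequence = NucSeq(id=f"switch_{arch.guide.id}", residues="".join(seq_parts))
    assert len(sequence) == arch.switch_length
    return GRNASwitch(arch=arch, sequence=sequence, coords=coords)


def derive_trigger(switch: GRNASwitch, middle: NucSeq | str) -> TriggerSpec:
    """Cognate trigger = revcomp(loop) + middle + revcomp(toehold).

    The trigger 5' end binds the loop and the trigger 3' end binds the
    toehold (antiparallel hybridization).
    """
    middle = middle if isinstance(middle, NucSeq) else NucSeq("middle", middle)
    middle.require_unambiguous()
    arch = switch.arch
    if len(middle) != arch.middle:
        raise ValueError(f"middle length {len(middle)} != arch.middle_len {arch.middle}")
    loop_c = revcomp(switch.loop).residues
    toehold_c = revcomp(switch.toehold).residues
    residues = loop_c + middle.residues + toehold_c
    layout = {
        "loop_complement": (0, arch.loop_len),
        "middle": (arch.loop_len, arch.loop_len + arch.middle),
        "toehold_complement": (arch.loop_len + arch.middle, len(residues)),
    }
    return TriggerSpec(
        sequence=NucSeq(id=f"trigger_{switch.sequence.id}", residues=residues),
        layout=layout,
    )
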