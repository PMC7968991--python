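"""Trigger scouting inside natural RNAs.

Long RNAs (an sRNA, an mRNA CDS) are scanned in fixed-length windows
(default 71 nt) folded in isolation; windows with little predicted
structure — high mean unpaired probability — are candidate trigger
subsections.  A chosen window maps onto the switch sensor as

    loop    = revcomp(window[0 : loop_len))
    middle  = window[loop_len : loop_len + middle_len)
    toehold = revcomp(window[loop_len + middle_len : ))

so the trigger 5' end binds the loop and its 3' end binds the toehold.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

from .engine import EngineParams, FoldEngine, ReferenceEngine
from .sequences import NucSeq, SwitchArchitecture, revcomp

__all__ = ["WindowScore", "scan_windows", "pick_windows", "window_to_sensor"]


@dataclass(frozen=True)
class WindowScore:
    """Accessibility score of one window folded in isolation."""

    start: int
    length: int
    accessibility: float  # mean p_unpaired over the window, in [0, 1]
    mfe_score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.accessibility <= 1.0 + 1e-12):
            raise ValueError("accessibility must lie in [0, 1]")


def scan_windows(
    rna: NucSeq,
    length: int = 71,
    params: Optional[EngineParams] = None,
    engine: Optional[FoldEngine] = None,
) -> List[WindowScore]:
    """One WindowScore per start offset 0 .. len(rna) - length."""
    rna.require_unambiguous()
    if len(rna) < length:
        raise ValueError(f"RNA length {len(rna)} shorter than window {length}")
    eng = engine or ReferenceEngine(params)
    scores = []
    for start in range(len(rna) - length + 1):
        window = NucSeq(f"{rna.id}:{start}", rna.residues[start : start + length])
        _, ppm = eng.partition_function(window)
        _, mfe = eng.mfe_fold(window)
        scores.append(
            WindowScore(
                start=start,
                length=length,
                accessibility=float(ppm.p_unpaired.mean()),
                mfe_score=float(mfe),
            )
        )
    return scores


def pick_windows(
    scores: Sequence[WindowScore],
    k: int,
    force_5prime: bool = False,
    five_prime_zone: int = 100,
) -> List[int]:
    """Greedy selection of the k highest-accessibility mutually
    non-overlapping windows (ties to the smaller start); optionally add
    the best window starting within ``five_prime_zone`` nt of the 5' end,
    also non-overlapping.  Returns starts in selection order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not scores:
        raise ValueError("no windows scored")
    ranked = sorted(scores, key=lambda w: (-w.accessibility, w.start))
    chosen: List[WindowScore] = []

    def overlaps(w: WindowScore) -> bool:
        return any(
            w.start < c.start + c.length and c.start < w.start + w.length for c in chosen
        )

    for w in ranked:
        if len(chosen) == k:
            break
        if not overlaps(w):
            chosen.append(w)
    if len(chosen) < k:
        raise ValueError(f"cannot place {k} non-overlapping windows")
    if force_5prime:
        already = any(c.start <= five_prime_zone for c in chosen)
        five = [
            w
            for w in ranked
            if w.start <= five_prime_zone and not overlaps(w) and w not in chosen
        ]
        if not already:
            if not five:
                raise ValueError(
                    "no non-overlapping window available within the 5' zone"
                )
            chosen.append(five[0])
    return [c.start for c in chosen]


def window_to_sensor(
    window: NucSeq, arch: SwitchArchitecture
) -> Tuple[NucSeq, NucSeq, NucSeq]:
    """Map a trigger window onto (toehold, loop, middle_target)."""
    window.require_unambiguous()
    t, l, m = arch.toehold_len, arch.loop_len, arch.middle
    if len(window) != t + l + m:
        raise ValueError(
            f"window length {len(window)} != toehold+middle+loop = {t + m + l}"
        )
    res = window.residues
    loop = revcomp(res[:l])
    middle_target = NucSeq("middle_target", res[l : l + m])
    toehold = revcomp(res[l + m :])
    return (
        NucSeq("toehold", toehold.residues),
        NucSeq("loop", loop.residues),
        middle_target,
    )
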