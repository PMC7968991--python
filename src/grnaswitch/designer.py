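"""Switch design: target states, DU+ notation, prevented patterns and
stochastic ensemble-defect minimization.

The OFF target places the clamp on the 5' prefix of the Cas12a handle
(everything else unpaired); the ON target hybridizes toehold and loop to
the trigger while the handle re-folds into its hairpin.  Free sequence
regions (toehold, loop, trigger middle, optional linker) are optimized
by seeded greedy mutation: sample a position in proportion to its
positional ensemble defect, propose a residue change (propagating
Watson-Crick complementarity to the trigger), and accept the change iff
the summed OFF+ON defect does not increase and no prevented sequence
pattern is introduced in a designable region.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .engine import EngineParams, FoldEngine, ReferenceEngine
from .sequences import (
    GRNASwitch,
    NucSeq,
    SwitchArchitecture,
    TriggerSpec,
    assemble_switch,
    derive_trigger,
    revcomp,
)
from .structures import SecondaryStructure

__all__ = [
    "TargetState",
    "DesignResult",
    "PreventedPatternSet",
    "DEFAULT_PREVENTED_PATTERNS",
    "build_off_structure",
    "build_on_structure",
    "to_du_plus",
    "from_du_plus",
    "check_prevented",
    "design_switch",
]

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U", "T": "U",
    "K": "GU", "M": "AC", "R": "AG", "S": "CG", "W": "AU", "Y": "CU",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
}

DEFAULT_PREVENTED_PATTERNS = (
    "AAAA", "CCCC", "GGGG", "UUUU",
    "KKKKKK", "MMMMMM", "RRRRRR", "SSSSSS", "WWWWWW", "YYYYYY",
)


@dataclass(frozen=True)
class PreventedPatternSet:
    """IUPAC patterns that designed sequences must not contain."""

    patterns: Tuple[str, ...] = DEFAULT_PREVENTED_PATTERNS

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ValueError("pattern set must be non-empty")
        for p in self.patterns:
            if not p:
                raise ValueError("empty pattern")
            for c in p.upper():
                if c not in IUPAC:
                    raise ValueError(f"unknown IUPAC code {c!r} in pattern {p!r}")


@dataclass(frozen=True)
class TargetState:
    """A named conformational target with its defect stop condition."""

    name: str  # "OFF" or "ON"
    lengths: Tuple[int, ...]
    target: SecondaryStructure
    stop_condition: float

    def __post_init__(self) -> None:
        if self.name not in ("OFF", "ON"):
            raise ValueError("state name must be OFF or ON")
        if not (0 < self.stop_condition <= 1):
            raise ValueError("stop_condition must lie in (0, 1]")
        expected = 1 if self.name == "OFF" else 2
        if len(self.lengths) != expected:
            raise ValueError(f"{self.name} state covers {expected} strand(s)")


@dataclass
class DesignResult:
    """Outcome of one seeded design run."""

    switch: GRNASwitch
    trigger: TriggerSpec
    defect_off: float
    defect_on: float
    iterations: int
    seed: int
    converged: bool
    stop_off: float = 0.01
    stop_on: float = 0.05
    off_target: Optional[SecondaryStructure] = None
    on_target: Optional[SecondaryStructure] = None


# ---------------------------------------------------------------------
# target construction
# ---------------------------------------------------------------------

def build_off_structure(arch: SwitchArchitecture) -> SecondaryStructure:
    """Single-strand OFF target: clamp position k pairs repeat position
    clamp_len-1-k; loop+linker form the enclosed hairpin loop; toehold,
    remaining repeat and guide are unpaired."""
    n = arch.switch_length
    if arch.loop_len + arch.linker_len < arch.min_loop:
        raise ValueError("enclosed OFF-state loop shorter than min_loop")
    pairs = np.full(n, -1, dtype=np.int64)
    t, c = arch.toehold_len, arch.clamp_len
    repeat_start = t + c + arch.loop_len + arch.linker_len
    for k in range(c):
        i = t + k
        j = repeat_start + (c - 1 - k)
        pairs[i], pairs[j] = j, i
    return SecondaryStructure([n], pairs, min_loop=arch.min_loop)


def build_on_structure(
    arch: SwitchArchitecture,
    handle_hairpin: Optional[Dict[int, int]] = None,
    engine: Optional[FoldEngine] = None,
    pair_clamp_middle: bool = False,
) -> SecondaryStructure:
    """Two-strand ON target (switch & trigger).

    The toehold pairs the trigger 3' segment, the loop pairs the trigger
    5' segment (both antiparallel), the linker stays unpaired, the guide
    stays unpaired and the repeat adopts ``handle_hairpin`` — by default
    the pair map of the repeat folded alone with the reference engine.
    The clamp and the trigger middle segment form a symmetric internal
    loop, unless ``pair_clamp_middle`` pairs them with each other.
    """
    S = arch.switch_length
    T = arch.trigger_length
    n = S + T
    t, c, l = arch.toehold_len, arch.clamp_len, arch.loop_len
    pairs = np.full(n, -1, dtype=np.int64)
    # toehold (switch 5') binds trigger 3' segment, antiparallel
    for i in range(t):
        j = S + (T - 1 - i)
        pairs[i], pairs[j] = j, i
    # loop binds trigger 5' segment
    for k in range(l):
        i = t + c + k
        j = S + (l - 1 - k)
        pairs[i], pairs[j] = j, i
    if pair_clamp_middle:
        if arch.middle != c:
            raise ValueError("clamp-middle pairing requires middle_len == clamp_len")
        for k in range(c):
            i = t + k
            j = S + l + (c - 1 - k)
            pairs[i], pairs[j] = j, i
    # repeat adopts the handle hairpin
    if handle_hairpin is None:
        eng = engine or ReferenceEngine(EngineParams(min_loop=arch.min_loop))
        folded, _ = eng.mfe_fold(arch.repeat)
        handle_hairpin = folded.pair_map()
    repeat_start = t + c + l + arch.linker_len
    for a, b in handle_hairpin.items():
        if not (0 <= a < b < len(arch.repeat)):
            raise ValueError("handle_hairpin pairs must be internal to the repeat")
        i, j = repeat_start + a, repeat_start + b
        pairs[i], pairs[j] = j, i
    return SecondaryStructure([S, T], pairs, min_loop=arch.min_loop)


# ---------------------------------------------------------------------
# DU+ shorthand
# ---------------------------------------------------------------------

def to_du_plus(s: SecondaryStructure) -> str:
    """Render a structure in DU+ shorthand: ``U<n>`` = n unpaired bases,
    ``D<n>(<inner>)`` = helix of n stacked pairs enclosing <inner>,
    ``+`` = strand break; tokens concatenate 5'->3'."""
    pairs = s.pairs
    nick = s.nick

    def render(lo: int, hi: int) -> List[str]:
        tokens: List[str] = []
        pos = lo
        while pos < hi:
            if nick is not None and pos == nick and pos > lo:
                tokens.append("+")
            if pairs[pos] < 0:
                end = pos
                while end < hi and pairs[end] < 0 and not (end == nick and end > pos):
                    end += 1
                tokens.append(f"U{end - pos}")
                pos = end
            else:
                q = int(pairs[pos])
                if q < pos:
                    raise ValueError("malformed pair table")  # pragma: no cover
                length = 1
                while (
                    pos + length < q - length + 1
                    and pairs[pos + length] == q - length
                    and (pos + length) != nick
                    and (q - length + 1) != nick
                ):
                    length += 1
                inner_lo, inner_hi = pos + length, q - length + 1
                inner: List[str] = []
                if nick is not None and inner_lo == nick and lo < nick:
                    inner.append("+")
                inner.extend(render(inner_lo, inner_hi))
                if nick is not None and inner_hi == nick and inner_lo != nick:
                    inner.append("+")
                tokens.append(f"D{length}(" + " ".join(inner) + ")")
                pos = q + 1
        return tokens

    return " ".join(render(0, s.n))


_DU_TOKEN = re.compile(r"\s*(U(\d+)|D(\d+)\s*\(|\)|\+)")


def from_du_plus(
    text: str, strands: Sequence | None = None, min_loop: int = 3
) -> SecondaryStructure:
    """Parse DU+ shorthand back into a SecondaryStructure.

    ``strands`` may be NucSeq/str sequences or bare lengths; if omitted,
    strand lengths are inferred from the text and the '+' token.
    """
    tokens: List[Tuple[str, int]] = []
    pos = 0
    while pos < len(text):
        m = _DU_TOKEN.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise ValueError(f"malformed DU+ text near {text[pos:pos+10]!r}")
        tok = m.group(1)
        if tok.startswith("U"):
            tokens.append(("U", int(m.group(2))))
        elif tok.startswith("D"):
            tokens.append(("D", int(m.group(3))))
        elif tok == ")":
            tokens.append((")", 0))
        else:
            tokens.append(("+", 0))
        pos = m.end()

    assignments: List[Tuple[int, int]] = []
    nick_positions: List[int] = []
    idx = 0

    def parse(cursor: int) -> Tuple[int, bool]:
        """Consume tokens until ')' or end; returns (cursor, saw_close)."""
        nonlocal idx
        while idx < len(tokens):
            kind, val = tokens[idx]
            if kind == "U":
                idx += 1
                cursor += val
            elif kind == "+":
                idx += 1
                nick_positions.append(cursor)
            elif kind == "D":
                idx += 1
                left = cursor
                inner_end, closed = parse(cursor + val)
                if not closed:
                    raise ValueError("unbalanced 'D(' in DU+ text")
                for k in range(val):
                    assignments.append((left + k, inner_end + val - 1 - k))
                cursor = inner_end + val
            else:  # ')'
                idx += 1
                return cursor, True
        return cursor, False

    total, closed = parse(0)
    if closed:
        raise ValueError("unbalanced ')' in DU+ text")
    if len(nick_positions) > 1:
        raise ValueError("more than one strand break in DU+ text")

    if strands is None:
        if nick_positions:
            strands = [nick_positions[0], total - nick_positions[0]]
        else:
            strands = [total]
    if isinstance(strands, (NucSeq, str, int)):
        strands = [strands]
    lengths = [len(s) if not isinstance(s, int) else s for s in strands]
    if sum(lengths) != total:
        raise ValueError(f"DU+ text covers {total} nt but strands total {sum(lengths)}")
    if len(lengths) == 2:
        if not nick_positions or nick_positions[0] != lengths[0]:
            raise ValueError("strand break position inconsistent with strand lengths")
    elif nick_positions:
        raise ValueError("strand break present but only one strand supplied")

    pairs = np.full(total, -1, dtype=np.int64)
    for i, j in assignments:
        if not (0 <= i < j < total):
            raise ValueError("DU+ pair out of range")
        pairs[i], pairs[j] = j, i
    return SecondaryStructure(strands, pairs, min_loop=min_loop)


# ---------------------------------------------------------------------
# prevented patterns
# ---------------------------------------------------------------------

def check_prevented(
    seq: NucSeq | str, patterns: PreventedPatternSet | Sequence[str] | None = None
) -> List[Tuple[str, int]]:
    """All (pattern, start) occurrences of prevented IUPAC patterns,
    including overlapping ones."""
    if patterns is None:
        patterns = PreventedPatternSet()
    if not isinstance(patterns, PreventedPatternSet):
        patterns = PreventedPatternSet(tuple(patterns))
    residues = seq.residues if isinstance(seq, NucSeq) else NucSeq("q", seq).residues
    hits: List[Tuple[str, int]] = []
    for pat in patterns.patterns:
        p = pat.upper()
        m = len(p)
        for start in range(len(residues) - m + 1):
            if all(residues[start + k] in IUPAC[p[k]] for k in range(m)):
                hits.append((pat, start))
    return hits


def _free_violations(
    residues: str, free_mask: np.ndarray, patterns: PreventedPatternSet
) -> List[Tuple[str, int]]:
    """Prevented-pattern hits that overlap at least one designable
    position (fixed domains such as the repeat are exempt)."""
    out = []
    for pat, start in check_prevented(residues, patterns):
        if free_mask[start : start + len(pat)].any():
            out.append((pat, start))
    return out


# ---------------------------------------------------------------------
# design loop
# ---------------------------------------------------------------------

@dataclass
class _Site:
    """One designable residue: a switch position, a trigger position, or
    a complementarity-linked (switch, trigger) position pair."""

    switch_pos: Optional[int]
    trigger_pos: Optional[int]


def _positional_defects(
    engine: FoldEngine, strands, target: SecondaryStructure
) -> np.ndarray:
    _, ppm = engine.partition_function(strands)
    n = target.n
    d = np.empty(n)
    for i in range(n):
        j = target.pairs[i]
        d[i] = 1.0 - (ppm.p_unpaired[i] if j < 0 else ppm.p[i, j])
    return d


def design_switch(
    arch: SwitchArchitecture,
    guide: Optional[NucSeq] = None,
    mode: str = "synthetic",
    natural_window: Optional[NucSeq] = None,
    patterns: Optional[PreventedPatternSet] = None,
    params: Optional[EngineParams] = None,
    seed: int = 0,
    max_iters: int = 20000,
    stop_off: float = 0.01,
    stop_on: float = 0.05,
    engine: Optional[FoldEngine] = None,
    pair_clamp_middle: bool = False,
) -> DesignResult:
    """Design toehold/loop/middle (and linker) by stochastic greedy
    ensemble-defect minimization.

    synthetic mode: toehold, loop, trigger middle (and linker) are free.
    natural mode: toehold/loop/middle are fixed as complements of the
    supplied trigger window (see ``trigger_scout.window_to_sensor``);
    only the linker (if any) remains free.

    Mutations are accepted iff the summed OFF+ON ensemble defect does
    not increase and no prevented pattern overlapping a designable
    position is introduced.  The run stops when both stop conditions
    are met or after ``max_iters`` proposals; the result records the
    final defects either way.
    """
    from .scout import window_to_sensor  # local import to avoid a cycle

    if guide is not None:
        arch = arch.with_(guide=guide)
    arch.guide.require_unambiguous()
    if mode not in ("synthetic", "natural"):
        raise ValueError("mode must be 'synthetic' or 'natural'")
    patterns = patterns or PreventedPatternSet()
    eng = engine or ReferenceEngine(params or EngineParams(min_loop=arch.min_loop))
    rng = np.random.default_rng(seed)

    t_len, c_len, l_len = arch.toehold_len, arch.clamp_len, arch.loop_len
    k_len, m_len = arch.linker_len, arch.middle
    S = arch.switch_length
    T = arch.trigger_length
    bases = np.array(list("ACGU"))

    # fixed scaffolding
    clamp = arch.default_clamp().residues
    sw = np.array(["A"] * S)
    tr = np.array(["A"] * T)
    sw[t_len : t_len + c_len] = list(clamp)
    rep_start = t_len + c_len + l_len + k_len
    sw[rep_start : rep_start + len(arch.repeat)] = list(arch.repeat.residues)
    sw[rep_start + len(arch.repeat) :] = list(arch.guide.residues)

    sites: List[_Site] = []
    sw_free = np.zeros(S, dtype=bool)
    tr_free = np.zeros(T, dtype=bool)

    def link_toehold(k: int) -> _Site:
        return _Site(switch_pos=k, trigger_pos=T - 1 - k)

    def link_loop(k: int) -> _Site:
        return _Site(switch_pos=t_len + c_len + k, trigger_pos=l_len - 1 - k)

    if mode == "synthetic":
        for k in range(t_len):
            sites.append(link_toehold(k))
        for k in range(l_len):
            sites.append(link_loop(k))
        for k in range(k_len):
            sites.append(_Site(switch_pos=t_len + c_len + l_len + k, trigger_pos=None))
        for k in range(m_len):
            sites.append(_Site(switch_pos=None, trigger_pos=l_len + k))
    else:
        if natural_window is None:
            raise ValueError("natural mode requires a trigger window sequence")
        toehold, loop, middle_target = window_to_sensor(natural_window, arch)
        sw[:t_len] = list(toehold.residues)
        sw[t_len + c_len : t_len + c_len + l_len] = list(loop.residues)
        tr[l_len : l_len + m_len] = list(middle_target.residues)
        for k in range(k_len):
            sites.append(_Site(switch_pos=t_len + c_len + l_len + k, trigger_pos=None))

    for site in sites:
        if site.switch_pos is not None:
            sw_free[site.switch_pos] = True
        if site.trigger_pos is not None:
            tr_free[site.trigger_pos] = True

    def sync_trigger_from_switch() -> None:
        for k in range(t_len):
            tr[T - 1 - k] = _COMPLEMENT[sw[k]]
        for k in range(l_len):
            tr[l_len - 1 - k] = _COMPLEMENT[sw[t_len + c_len + k]]

    def set_site(site: _Site, base: str) -> None:
        if site.switch_pos is not None:
            sw[site.switch_pos] = base
            if site.trigger_pos is not None:
                tr[site.trigger_pos] = _COMPLEMENT[base]
        elif site.trigger_pos is not None:
            tr[site.trigger_pos] = base

    # random initialization of free sites, avoiding prevented patterns
    for site in sites:
        set_site(site, str(rng.choice(bases)))
    sync_trigger_from_switch()
    for _attempt in range(2000):
        viol_sw = _free_violations("".join(sw), sw_free, patterns)
        viol_tr = _free_violations("".join(tr), tr_free, patterns)
        if not viol_sw and not viol_tr:
            break
        for site in sites:
            # resample any site overlapping a violation window
            hit = False
            for pat, start in viol_sw:
                if site.switch_pos is not None and start <= site.switch_pos < start + len(pat):
                    hit = True
            for pat, start in viol_tr:
                if site.trigger_pos is not None and start <= site.trigger_pos < start + len(pat):
                    hit = True
            if hit:
                set_site(site, str(rng.choice(bases)))
        sync_trigger_from_switch()
    else:
        raise ValueError("could not initialize free regions without prevented patterns")

    off_target = build_off_structure(arch)
    on_target = build_on_structure(arch, engine=eng, pair_clamp_middle=pair_clamp_middle)

    def evaluate(sw_arr, tr_arr):
        sw_seq = NucSeq("switch", "".join(sw_arr))
        tr_seq = NucSeq("trigger", "".join(tr_arr))
        d_off = _positional_defects(eng, sw_seq, off_target)
        d_on = _positional_defects(eng, [sw_seq, tr_seq], on_target)
        return d_off, d_on

    d_off, d_on = evaluate(sw, tr)
    defect_off, defect_on = d_off.mean(), d_on.mean()

    iterations = 0
    converged = defect_off <= stop_off and defect_on <= stop_on
    while not converged and iterations < max_iters and sites:
        # positional-defect-proportional site sampling
        weights = np.empty(len(sites))
        for si, site in enumerate(sites):
            w = 0.0
            if site.switch_pos is not None:
                w += d_off[site.switch_pos] + d_on[site.switch_pos]
            if site.trigger_pos is not None:
                w += d_on[S + site.trigger_pos]
            weights[si] = w
        total = weights.sum()
        if total <= 0:
            probs = np.full(len(sites), 1.0 / len(sites))
        else:
            probs = weights / total
        si = int(rng.choice(len(sites), p=probs))
        site = sites[si]
        current = sw[site.switch_pos] if site.switch_pos is not None else tr[site.trigger_pos]
        proposal = str(rng.choice(bases[bases != current]))

        sw_new, tr_new = sw.copy(), tr.copy()

        def set_on(site: _Site, base: str) -> None:
            if site.switch_pos is not None:
                sw_new[site.switch_pos] = base
                if site.trigger_pos is not None:
                    tr_new[site.trigger_pos] = _COMPLEMENT[base]
            elif site.trigger_pos is not None:
                tr_new[site.trigger_pos] = base

        set_on(site, proposal)
        iterations += 1
        if _free_violations("".join(sw_new), sw_free, patterns) or _free_violations(
            "".join(tr_new), tr_free, patterns
        ):
            continue
        d_off_new, d_on_new = evaluate(sw_new, tr_new)
        if d_off_new.mean() + d_on_new.mean() <= defect_off + defect_on:
            sw, tr = sw_new, tr_new
            d_off, d_on = d_off_new, d_on_new
            defect_off, defect_on = d_off.mean(), d_on.mean()
            converged = defect_off <= stop_off and defect_on <= stop_on

    switch = assemble_switch(
        arch,
        toehold="".join(sw[:t_len]),
        loop="".join(sw[t_len + c_len : t_len + c_len + l_len]),
        linker="".join(sw[t_len + c_len + l_len : rep_start]) or None,
    )
    trigger = derive_trigger(switch, "".join(tr[l_len : l_len + m_len]))
    assert trigger.sequence.residues == "".join(tr)
    return DesignResult(
        switch=switch,
        trigger=trigger,
        defect_off=float(defect_off),
        defect_on=float(defect_on),
        iterations=iterations,
        seed=seed,
        converged=bool(converged),
        stop_off=stop_off,
        stop_on=stop_on,
        off_target=off_target,
        on_target=on_target,
    )
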