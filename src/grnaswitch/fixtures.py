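"""Synthetic fixtures: every pipeline stage is testable without downloads.

The generator emulates the study conditions of the switch-design
workflow: random 24-nt guides, 43-nt synthetic triggers with GC content
in the 30-53% band, natural-RNA stand-ins (a 90-nt sRNA-like sequence
with two accessible single-stranded segments; a ~1.7-kb mRNA-like CDS
with embedded low-structure windows), and plate-reader/flow-cytometry
series with known ground-truth normalization values for closed-loop
recovery tests.  All randomness flows from one seeded generator.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .assay import AssayTable
from .sequences import NucSeq, revcomp

__all__ = ["FixtureBundle", "make_fixtures"]

_BASES = np.array(list("ACGU"))


@dataclass
class FixtureBundle:
    guides: List[NucSeq]
    triggers: List[NucSeq]
    srna: NucSeq
    srna_accessible: List[Tuple[int, int]]
    mrna: NucSeq
    mrna_low_structure_starts: List[int]
    assay: AssayTable
    assay_truth: Dict[str, float]  # sample -> injected normalized expression (%)
    facs_means: pd.DataFrame
    facs_truth: Dict[str, float]
    seed: int


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _gc_controlled_seq(
    rng: np.random.Generator, length: int, gc_range: Tuple[float, float]
) -> str:
    lo, hi = gc_range
    if not (0 <= lo <= hi <= 1):
        raise ValueError("invalid GC range")
    feasible = [k for k in range(length + 1) if lo <= k / length <= hi]
    if not feasible:
        raise ValueError(f"GC range {gc_range} infeasible for length {length}")
    n_gc = int(rng.choice(feasible))
    strong = rng.choice(np.array(list("GC")), size=n_gc)
    weak = rng.choice(np.array(list("AU")), size=length - n_gc)
    seq = np.concatenate([strong, weak])
    rng.shuffle(seq)
    return "".join(seq)


def _hairpin(rng: np.random.Generator, stem: int, loop: int) -> str:
    arm = _random_seq(rng, stem)
    return arm + _random_seq(rng, loop) + revcomp(arm).residues


def _accessible_segment(rng: np.random.Generator, length: int) -> str:
    # A/C-rich segments pair poorly with themselves (no A-C pairing)
    return "".join(rng.choice(np.array(list("AACC")), size=length))


def _srna_standin(rng: np.random.Generator) -> Tuple[NucSeq, List[Tuple[int, int]]]:
    """90-nt sRNA-like RNA: two stem-loops flanking two accessible segments."""
    parts = []
    accessible = []
    parts.append(_hairpin(rng, 8, 4))  # 20 nt
    start = sum(len(p) for p in parts)
    parts.append(_accessible_segment(rng, 22))
    accessible.append((start, start + 22))
    parts.append(_hairpin(rng, 7, 4))  # 18 nt
    start = sum(len(p) for p in parts)
    parts.append(_accessible_segment(rng, 22))
    accessible.append((start, start + 22))
    parts.append(_random_seq(rng, 8))
    seq = "".join(parts)
    assert len(seq) == 90
    return NucSeq("sRNA_standin", seq), accessible


def _mrna_standin(
    rng: np.random.Generator, length: int = 1700, window: int = 71
) -> Tuple[NucSeq, List[int]]:
    """mRNA-like CDS stand-in with designed low-structure windows near the
    5' end, mid-ORF and 3' end."""
    seq = list(_random_seq(rng, length))
    starts = [40, length // 2, length - window - 40]
    for s in starts:
        seq[s : s + window] = list(_accessible_segment(rng, window))
    return NucSeq("mRNA_standin", "".join(seq)), starts


def _assay_series(
    rng: np.random.Generator, injected: Dict[str, float]
) -> Tuple[AssayTable, Dict[str, float]]:
    """Plate-reader series in which sample s has fluor = b + r_s * OD with
    rates chosen so its normalized GFP expression equals ``injected[s]``."""
    time = np.arange(0.0, 365.0, 5.0)
    doubling = 40.0
    od0 = 0.02
    od_exp = od0 * np.exp2(time / doubling)
    plateau_t = 250.0
    od = np.where(time <= plateau_t, od_exp, od0 * np.exp2(plateau_t / doubling))
    od = od + np.where(time > plateau_t, 1e-4 * (time - plateau_t), 0.0)

    rate_t, rate_nt = 500.0, 3000.0
    roles = {"targeting": "targeting_control", "nontargeting": "nontargeting_control"}
    rates = {"targeting": rate_t, "nontargeting": rate_nt}
    for s, v in injected.items():
        roles[s] = "experiment"
        rates[s] = rate_t + v / 100.0 * (rate_nt - rate_t)
    fluor = {}
    abs600 = {}
    for s, r in rates.items():
        offset = float(rng.uniform(50, 200))
        fluor[s] = offset + r * od
        abs600[s] = od.copy()
    table = AssayTable(time=time, fluor=fluor, roles=roles, abs600=abs600)
    return table, dict(injected)


def _facs_means(
    rng: np.random.Generator, injected: Dict[str, float]
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    background = float(rng.uniform(80, 160))
    mean_t = background + 300.0
    mean_nt = background + 20300.0
    rows = [
        {"sample": "background", "role": "background", "mean_fluor": background},
        {"sample": "targeting", "role": "targeting_control", "mean_fluor": mean_t},
        {"sample": "nontargeting", "role": "nontargeting_control", "mean_fluor": mean_nt},
    ]
    for s, v in injected.items():
        rows.append(
            {
                "sample": s,
                "role": "experiment",
                "mean_fluor": mean_t + v / 100.0 * (mean_nt - mean_t),
            }
        )
    return pd.DataFrame(rows), dict(injected)


def make_fixtures(
    seed: int,
    n_switches: int = 4,
    n_triggers: int | None = None,
    gc_range: Tuple[float, float] = (0.30, 0.53),
    guide_length: int = 24,
    trigger_length: int = 43,
) -> FixtureBundle:
    """Deterministic fixture bundle; the same seed reproduces it bitwise."""
    rng = np.random.default_rng(seed)
    if n_triggers is None:
        n_triggers = n_switches
    guides = [
        NucSeq(f"guide_{i+1}", _random_seq(rng, guide_length)) for i in range(n_switches)
    ]
    triggers = [
        NucSeq(f"trigger_{i+1}", _gc_controlled_seq(rng, trigger_length, gc_range))
        for i in range(n_triggers)
    ]
    srna, srna_acc = _srna_standin(rng)
    mrna, mrna_starts = _mrna_standin(rng)
    injected_plate = {"switch_A": 25.0, "switch_B": 60.0, "switch_C": 85.0}
    assay, assay_truth = _assay_series(rng, injected_plate)
    injected_facs = {"switch_A": 6.0, "switch_B": 79.0}
    facs, facs_truth = _facs_means(rng, injected_facs)
    return FixtureBundle(
        guides=guides,
        triggers=triggers,
        srna=srna,
        srna_accessible=srna_acc,
        mrna=mrna,
        mrna_low_structure_starts=mrna_starts,
        assay=assay,
        assay_truth=assay_truth,
        facs_means=facs,
        facs_truth=facs_truth,
        seed=seed,
    )
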