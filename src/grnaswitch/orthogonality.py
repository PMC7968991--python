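"""Cross-talk prediction across switch/trigger panels.

Each switch:trigger pair is co-folded at equal total concentration
(default 1 uM) and the equilibrium fraction of switch in the heterodimer
is recorded; pairs above a reporting threshold (default 5%) are flagged.
Separately, the pair's maximum-score structure is inspected for clamp
sequestration: the fraction of OFF-state clamp-handle pairs retained in
the pair MFE (1.0 = the handle is fully blocked, i.e. the switch should
stay OFF with that trigger).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .designer import build_off_structure
from .engine import (
    EngineParams,
    FoldEngine,
    ReferenceEngine,
    complex_equilibrium,
)
from .sequences import GRNASwitch, NucSeq

__all__ = ["CrosstalkMatrix", "crosstalk_matrix", "clamp_sequestration"]


@dataclass
class CrosstalkMatrix:
    """Fraction-complexed and clamp-sequestration results for a panel."""

    switches: List[str]
    triggers: List[str]
    fraction: np.ndarray  # |switches| x |triggers|, in [0, 1]
    flagged: np.ndarray  # fraction > threshold
    clamp_intact: np.ndarray  # fraction of OFF clamp pairs kept in pair MFE
    threshold: float
    c0: float

    def to_frame(self, which: str = "fraction") -> pd.DataFrame:
        data = getattr(self, which)
        return pd.DataFrame(data, index=self.switches, columns=self.triggers)

    def summary(self) -> dict:
        n_sw, n_tr = self.fraction.shape
        diag = min(n_sw, n_tr)
        diagonal = np.array([self.fraction[i, i] for i in range(diag)])
        off_mask = ~np.eye(n_sw, n_tr, dtype=bool)
        return {
            "n_switches": n_sw,
            "n_triggers": n_tr,
            "c0_molar": self.c0,
            "threshold": self.threshold,
            "diagonal_min_fraction": float(diagonal.min()) if diag else None,
            "noncognate_pairs": int(off_mask.sum()),
            "noncognate_flagged": int(self.flagged[off_mask].sum()),
            "noncognate_clamp_fully_sequestered": int(
                (self.clamp_intact[off_mask] >= 1.0).sum()
            ),
        }


def clamp_sequestration(
    switch: GRNASwitch,
    trigger: NucSeq,
    params: Optional[EngineParams] = None,
    engine: Optional[FoldEngine] = None,
) -> float:
    """Fraction of OFF-state clamp-handle pairs present in the pair MFE.

    1.0 means the clamp fully sequesters the Cas12a handle in the
    minimum-free-energy structure of the switch:trigger complex.
    """
    eng = engine or ReferenceEngine(params or EngineParams(min_loop=switch.arch.min_loop))
    off = build_off_structure(switch.arch)
    mfe_struct, _ = eng.mfe_fold([switch.sequence, trigger])
    off_pairs = off.pair_map()
    if not off_pairs:
        return 1.0
    kept = sum(1 for i, j in off_pairs.items() if mfe_struct.pairs[i] == j)
    return kept / len(off_pairs)


def crosstalk_matrix(
    switches: Sequence[GRNASwitch],
    triggers: Sequence[NucSeq],
    c0: float = 1e-6,
    threshold: float = 0.05,
    params: Optional[EngineParams] = None,
    engine: Optional[FoldEngine] = None,
) -> CrosstalkMatrix:
    """Pairwise co-fold of every switch x trigger at equal concentration
    ``c0`` (molar); fraction = [switch:trigger] / c0 at equilibrium."""
    if not switches or not triggers:
        raise ValueError("switch and trigger panels must be non-empty")
    eng = engine or ReferenceEngine(params)
    q_sw = [eng.partition_function(s.sequence)[0] for s in switches]
    q_tr = [eng.partition_function(t)[0] for t in triggers]
    fraction = np.zeros((len(switches), len(triggers)))
    clamp_intact = np.zeros_like(fraction)
    for a, sw in enumerate(switches):
        for b, tr in enumerate(triggers):
            q_ab, _ = eng.partition_function([sw.sequence, tr])
            eq = complex_equilibrium(q_sw[a], q_tr[b], q_ab, c0, c0)
            fraction[a, b] = eq.fraction_complexed
            clamp_intact[a, b] = clamp_sequestration(sw, tr, engine=eng)
    return CrosstalkMatrix(
        switches=[s.sequence.id for s in switches],
        triggers=[t.id for t in triggers],
        fraction=fraction,
        flagged=fraction > threshold,
        clamp_intact=clamp_intact,
        threshold=threshold,
        c0=c0,
    )
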