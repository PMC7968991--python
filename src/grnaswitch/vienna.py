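"""ViennaRNA-backed engine satisfying the :class:`FoldEngine` contract.

Optional: requires the ViennaRNA Python bindings (``import RNA``).  The
adapter reports scores as negated free energies (kcal/mol) so that
"higher is more stable" matches the reference engine's convention, and
partition functions as exp(-G_ensemble / RT), directly usable in
:func:`grnaswitch.engine.complex_equilibrium`.

Numbers from this adapter are nearest-neighbor thermodynamics and are
not expected to agree value-for-value with the reference engine; only
the structural contract (signatures, normalization, mass conservation)
is shared.
"""
from __future__ import annotations

import math
from typing import Optional, Tuple

import numpy as np

from .engine import FoldEngine, PairProbMatrix
from .sequences import NucSeq
from .structures import SecondaryStructure
from .engine import _as_strand_list, Strands

try:  # pragma: no cover - import guard
    import RNA  # type: ignore

    HAVE_VIENNA = True
except ImportError:  # pragma: no cover
    RNA = None
    HAVE_VIENNA = False

__all__ = ["ViennaEngine", "HAVE_VIENNA"]

_GAS_CONSTANT_KCAL = 0.0019872041  # kcal / (mol K)


class ViennaEngine(FoldEngine):
    """Nearest-neighbor engine via ViennaRNA fold compounds."""

    def __init__(self, temperature: float = 37.0) -> None:
        if not HAVE_VIENNA:
            raise ImportError("ViennaRNA Python bindings are not available")
        self.temperature = temperature
        self._rt = _GAS_CONSTANT_KCAL * (273.15 + temperature)

    def _compound(self, seqs) -> "RNA.fold_compound":
        md = RNA.md()
        md.temperature = self.temperature
        joined = "&".join(s.residues for s in seqs)
        return RNA.fold_compound(joined, md)

    def mfe_fold(self, strands: Strands) -> Tuple[SecondaryStructure, float]:
        seqs = _as_strand_list(strands)
        fc = self._compound(seqs)
        db, energy = fc.mfe()
        if len(seqs) == 2 and "&" not in db:
            # dimer dot-bracket comes back unseparated
            na = len(seqs[0])
            db = db[:na] + "&" + db[na:]
        struct = SecondaryStructure.from_dotbracket(db, seqs, validate=False)
        return struct, -float(energy)

    def partition_function(self, strands: Strands) -> Tuple[float, PairProbMatrix]:
        seqs = _as_strand_list(strands)
        fc = self._compound(seqs)
        fc.pf()
        _, g_ensemble = fc.pf()
        q = math.exp(-float(g_ensemble) / self._rt)
        n = sum(len(s) for s in seqs)
        bpp = np.array(fc.bpp())  # (n+1) x (n+1), 1-based
        p = np.zeros((n, n))
        p[:, :] = bpp[1:, 1:]
        p = p + p.T
        p_unpaired = np.clip(1.0 - p.sum(axis=1), 0.0, 1.0)
        return q, PairProbMatrix(n=n, p=p, p_unpaired=p_unpaired)
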