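"""Self-contained RNA secondary-structure ensemble engine.

The model assigns every nested structure an additive stability score
(one term per base pair: GC=3, AU=2, GU=1 by default) and weights it by
exp(beta * score).  This yields a Boltzmann-like ensemble over which the
engine computes the maximum-score (MFE-analogue) structure, the
partition function, exact base-pair probabilities, ensemble defects and
heterodimer equilibria.  Two strands are folded over their concatenation
with the nick exempt from the minimum-loop rule and, optionally, a
one-off duplex initiation penalty for bimolecular complexes.

The simplified scoring model keeps the package self-contained and
testable by brute-force enumeration; callers needing nearest-neighbor
thermodynamics can substitute any engine implementing
:class:`FoldEngine` (see :mod:`grnaswitch.vienna`).
"""
from __future__ import annotations

import abc
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from ._kernels import inside_partition, pair_probabilities, mfe_tables, mfe_traceback
from .sequences import NucSeq
from .structures import SecondaryStructure

__all__ = [
    "EngineParams",
    "PairProbMatrix",
    "EquilibriumResult",
    "FoldEngine",
    "ReferenceEngine",
    "mfe_fold",
    "partition_function",
    "ensemble_defect",
    "complex_equilibrium",
]

Strands = Union[NucSeq, str, Sequence[Union[NucSeq, str]]]


@dataclass(frozen=True)
class EngineParams:
    """Parameters of the additive pair-score ensemble model.

    pair_scores
        Stability score per pair type (applies symmetrically).  The
        defaults count hydrogen bonds (GC=3, AU=2, GU=1), read as
        binding free energies of roughly 1 kcal/mol per hydrogen bond.
    min_loop
        Minimum unpaired bases in a hairpin loop (nick-spanning loops exempt).
    beta
        Inverse-temperature scale for Boltzmann weights.  The default is
        1/RT at 37 degrees C (1.6225 mol/kcal), consistent with reading
        pair scores in kcal/mol; with this scale designed cognate
        switch:trigger pairs are essentially fully complexed at 1 uM.
    duplex_init_penalty
        Score subtracted once from every structure of a bimolecular
        complex that contains at least one inter-strand pair.
    temperature_label
        Reporting label in degrees Celsius; does not enter the model.
    """

    pair_scores: Dict[str, float] = field(
        default_factory=lambda: {"GC": 3.0, "AU": 2.0, "GU": 1.0}
    )
    min_loop: int = 3
    beta: float = 1.6225  # 1/RT at 37 C, RT = 0.61633 kcal/mol
    duplex_init_penalty: float = 0.0
    temperature_label: float = 37.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.pair_scores.values()):
            raise ValueError("pair_scores must be >= 0")
        if self.min_loop < 0:
            raise ValueError("min_loop must be >= 0")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")

    def score_of(self, a: str, b: str) -> Optional[float]:
        key = "".join(sorted((a, b)))
        # sorted pair keys: AU -> 'AU', GC -> 'CG', GU -> 'GU'
        lookup = {"AU": "AU", "CG": "GC", "GU": "GU"}
        name = lookup.get(key)
        if name is None:
            return None
        return self.pair_scores.get(name)


@dataclass
class PairProbMatrix:
    """Equilibrium pair probabilities; p is symmetric n x n."""

    n: int
    p: np.ndarray
    p_unpaired: np.ndarray

    def check_normalization(self, atol: float = 1e-9) -> None:
        total = self.p.sum(axis=1) + self.p_unpaired
        if not np.allclose(total, 1.0, atol=atol):
            raise AssertionError("pairing probabilities do not normalize to 1")


@dataclass(frozen=True)
class EquilibriumResult:
    """Two-species dimerization equilibrium A + B <-> AB."""

    a_free: float
    b_free: float
    ab_complex: float
    fraction_complexed: float


def _as_strand_list(strands: Strands) -> List[NucSeq]:
    if isinstance(strands, (NucSeq, str)):
        strands = [strands]
    out = []
    for s in strands:
        ns = s if isinstance(s, NucSeq) else NucSeq("strand", s)
        ns.require_unambiguous()
        out.append(ns)
    if not 1 <= len(out) <= 2:
        raise ValueError("fold operations accept 1 or 2 strands")
    return out


class FoldEngine(abc.ABC):
    """Adapter contract for substitutable thermodynamic engines.

    Any engine must fold 1 or 2 strands, return pair probabilities that
    satisfy the normalization identity, and partition functions usable
    in :func:`complex_equilibrium` (mass conservation).  Value-level
    agreement between engines is not part of the contract.
    """

    @abc.abstractmethod
    def mfe_fold(self, strands: Strands) -> Tuple[SecondaryStructure, float]:
        ...

    @abc.abstractmethod
    def partition_function(self, strands: Strands) -> Tuple[float, PairProbMatrix]:
        ...

    def ensemble_defect(self, strands: Strands, target: SecondaryStructure) -> float:
        """Mean per-position probability of not being in the target state."""
        seqs = _as_strand_list(strands)
        n = sum(len(s) for s in seqs)
        if target.n != n or target.lengths != [len(s) for s in seqs]:
            raise ValueError(
                f"target strand lengths {target.lengths} do not match input "
                f"{[len(s) for s in seqs]}"
            )
        _, ppm = self.partition_function(seqs)
        defect = 0.0
        for i in range(n):
            j = target.pairs[i]
            defect += 1.0 - (ppm.p_unpaired[i] if j < 0 else ppm.p[i, j])
        return defect / n


class ReferenceEngine(FoldEngine):
    """The package's own enumeration-validated additive-score engine."""

    def __init__(self, params: Optional[EngineParams] = None) -> None:
        self.params = params or EngineParams()

    # -- weight/score matrices ---------------------------------------
    def _score_table(self) -> np.ndarray:
        """4x4 pair-score table indexed A=0, C=1, G=2, U=3; NaN = unpairable."""
        t = np.full((4, 4), np.nan)
        scores = self.params.pair_scores
        if "AU" in scores:
            t[0, 3] = t[3, 0] = scores["AU"]
        if "GC" in scores:
            t[2, 1] = t[1, 2] = scores["GC"]
        if "GU" in scores:
            t[2, 3] = t[3, 2] = scores["GU"]
        return t

    def _matrices(self, seqs: List[NucSeq]) -> Tuple[np.ndarray, np.ndarray, Optional[int]]:
        params = self.params
        seq = "".join(s.residues for s in seqs)
        nick = len(seqs[0]) if len(seqs) == 2 else None
        n = len(seq)
        codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        lut = np.full(256, -1, dtype=np.int64)
        for base, idx in zip(b"ACGU", range(4)):
            lut[base] = idx
        c = lut[codes]
        S = self._score_table()[c[:, None], c[None, :]]
        idx = np.arange(n)
        span_ok = (idx[None, :] - idx[:, None] - 1) >= params.min_loop
        if nick is not None:
            span_ok |= (idx[:, None] < nick) & (idx[None, :] >= nick)
        upper = idx[:, None] < idx[None, :]
        allowed = upper & span_ok & ~np.isnan(S)
        S = np.where(allowed, S, 0.0)
        W = np.where(allowed, np.exp(params.beta * S), 0.0)
        return W, S, nick

    # -- MFE ----------------------------------------------------------
    def mfe_fold(self, strands: Strands) -> Tuple[SecondaryStructure, float]:
        """Maximum-score nested structure.

        Ties broken deterministically: fewest pairs, then the
        lexicographically smallest pair table (unpaired = -1).  For two
        strands the duplex initiation penalty is charged iff the
        structure contains an inter-strand pair.
        """
        seqs = _as_strand_list(strands)
        W, S, nick = self._matrices(seqs)
        allowed = W > 0.0
        M, C = mfe_tables(S, allowed)
        n = S.shape[0]
        pairs = mfe_traceback(S, allowed, M, C)
        score = float(M[0, n])
        if nick is not None and self.params.duplex_init_penalty > 0:
            # compare best joint structure (penalized) with best
            # no-inter-pair structure (independent strand folds)
            Wa, Sa, _ = self._matrices(seqs[:1])
            Wb, Sb, _ = self._matrices(seqs[1:])
            Ma, Ca = mfe_tables(Sa, Wa > 0.0)
            Mb, Cb = mfe_tables(Sb, Wb > 0.0)
            split_score = float(Ma[0, len(seqs[0])] + Mb[0, len(seqs[1])])
            joint = score - self.params.duplex_init_penalty
            if split_score >= joint:
                pa = mfe_traceback(Sa, Wa > 0.0, Ma, Ca)
                pb = mfe_traceback(Sb, Wb > 0.0, Mb, Cb)
                pairs = np.concatenate([pa, np.where(pb >= 0, pb + len(seqs[0]), -1)])
                score = split_score
            else:
                score = joint
        struct = SecondaryStructure(seqs, pairs, validate=False, min_loop=self.params.min_loop)
        return struct, score

    # -- partition function -------------------------------------------
    def partition_function(self, strands: Strands) -> Tuple[float, PairProbMatrix]:
        """Q = sum over nested structures of exp(beta*score), plus exact
        pair probabilities.  The empty structure is always included."""
        seqs = _as_strand_list(strands)
        W, _, nick = self._matrices(seqs)
        n = W.shape[0]
        Q = inside_partition(W)
        Z = float(Q[0, n])
        P = pair_probabilities(W, Q)
        phi = math.exp(-self.params.beta * self.params.duplex_init_penalty)
        if nick is not None and phi != 1.0:
            # mix: structures with no inter-strand pair escape the penalty
            na = len(seqs[0])
            Wa, _, _ = self._matrices(seqs[:1])
            Wb, _, _ = self._matrices(seqs[1:])
            Qa_t = inside_partition(Wa)
            Qb_t = inside_partition(Wb)
            Za, Zb = float(Qa_t[0, na]), float(Qb_t[0, n - na])
            Pa = pair_probabilities(Wa, Qa_t)
            Pb = pair_probabilities(Wb, Qb_t)
            Zsplit = Za * Zb
            Zpen = Zsplit + phi * (Z - Zsplit)
            N_all = P * Z
            N_split = np.zeros_like(P)
            N_split[:na, :na] = Pa * Zsplit
            N_split[na:, na:] = Pb * Zsplit
            P = (phi * (N_all - N_split) + N_split) / Zpen
            Z = Zpen
        Pfull = P + P.T
        p_unpaired = 1.0 - Pfull.sum(axis=1)
        ppm = PairProbMatrix(n=n, p=Pfull, p_unpaired=p_unpaired)
        return Z, ppm


# -- module-level convenience wrappers --------------------------------

def _engine(params: Optional[EngineParams]) -> ReferenceEngine:
    return ReferenceEngine(params)


def mfe_fold(
    strands: Strands, params: Optional[EngineParams] = None
) -> Tuple[SecondaryStructure, float]:
    return _engine(params).mfe_fold(strands)


def partition_function(
    strands: Strands, params: Optional[EngineParams] = None
) -> Tuple[float, PairProbMatrix]:
    return _engine(params).partition_function(strands)


def ensemble_defect(
    strands: Strands,
    target: SecondaryStructure,
    params: Optional[EngineParams] = None,
    engine: Optional[FoldEngine] = None,
) -> float:
    eng = engine if engine is not None else _engine(params)
    return eng.ensemble_defect(strands, target)


def complex_equilibrium(
    q_a: float,
    q_b: float,
    q_ab: float,
    a_total: float,
    b_total: float,
    c_ref: float = 1.0,
) -> EquilibriumResult:
    """Equilibrium of A + B <-> AB from single-strand and complex
    partition functions.

    The association constant is K = Q_ab / (Q_a * Q_b) / c_ref (c_ref =
    1 M), and the complex concentration x solves

        K = x / ((a_total - x) (b_total - x))

    taken at the physical (smaller) root of the quadratic, evaluated in
    a numerically stable form.  Mass is conserved exactly.
    """
    if min(q_a, q_b, q_ab) <= 0:
        raise ValueError("partition functions must be > 0")
    if min(a_total, b_total) <= 0:
        raise ValueError("total concentrations must be > 0")
    K = q_ab / (q_a * q_b) / c_ref
    if K == 0.0:
        x = 0.0
    else:
        # K x^2 - (K(a+b) + 1) x + K a b = 0 ; smaller root, stable form
        b_coef = K * (a_total + b_total) + 1.0
        disc = b_coef * b_coef - 4.0 * K * K * a_total * b_total
        x = 2.0 * K * a_total * b_total / (b_coef + math.sqrt(max(disc, 0.0)))
    x = min(x, a_total, b_total)
    return EquilibriumResult(
        a_free=a_total - x,
        b_free=b_total - x,
        ab_complex=x,
        fraction_complexed=x / a_total,
    )
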