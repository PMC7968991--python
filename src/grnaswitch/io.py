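"""File formats and run configuration.

FASTA is read and written through Biopython; sequences are canonicalized
to RNA (T -> U) on read.  Switch coordinate maps export as BED-like TSV
(0-based half-open) or JSON; structures as Vienna dot-bracket with '&'
separating the strands of a complex.  Run configuration round-trips
through YAML unchanged.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .sequences import GRNASwitch, NucSeq, FN_CAS12A_REPEAT

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_dotbracket",
    "coords_to_bed",
    "coords_to_json",
    "RunConfig",
]


def read_fasta(path, allow_ambiguous: bool = False) -> List[NucSeq]:
    """Read FASTA into NucSeq records (T canonicalized to U).

    ``allow_ambiguous`` admits N residues (natural RNAs); design
    operations reject them downstream.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty FASTA")
    seen = set()
    out = []
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        out.append(NucSeq(id=rec.id, residues=str(rec.seq), allow_n=allow_ambiguous))
    return out


def write_fasta(seqs: List[NucSeq], path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def write_dotbracket(entries, path) -> None:
    """Write (name, sequence_or_None, structure) triples in Vienna style."""
    with open(path, "w") as fh:
        for name, seq, struct in entries:
            fh.write(f">{name}\n")
            if seq is not None:
                fh.write(f"{seq}\n")
            fh.write(struct.to_dotbracket() + "\n")


def coords_to_bed(switch: GRNASwitch) -> pd.DataFrame:
    """Sub-domain intervals as BED-like rows (0-based half-open)."""
    rows = [
        {"chrom": switch.sequence.id, "start": s, "end": e, "name": name}
        for name, (s, e) in switch.coords.items()
        if e > s
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def coords_to_json(switch: GRNASwitch) -> str:
    return json.dumps(
        {
            "sequence_id": switch.sequence.id,
            "length": len(switch.sequence),
            "domains": {k: list(v) for k, v in switch.coords.items()},
        },
        indent=2,
    )


# ---------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------

@dataclass
class ArchitectureConfig:
    toehold_len: int = 15
    clamp_len: int = 13
    loop_len: int = 15
    linker_len: int = 0
    repeat: str = FN_CAS12A_REPEAT.residues
    middle_len: Optional[int] = None
    allow_wobble_clamp: bool = False


@dataclass
class EngineConfig:
    pair_scores: Dict[str, float] = field(
        default_factory=lambda: {"GC": 3.0, "AU": 2.0, "GU": 1.0}
    )
    min_loop: int = 3
    beta: float = 1.6225
    duplex_init_penalty: float = 0.0
    temperature_label: float = 37.0
    adapter: str = "reference"  # or "vienna"
    c_ref_molar: float = 1.0


@dataclass
class DesignConfig:
    stop_off: float = 0.01
    stop_on: float = 0.05
    max_iters: int = 20000
    seed: int = 0
    prevented_patterns: List[str] = field(
        default_factory=lambda: [
            "AAAA", "CCCC", "GGGG", "UUUU",
            "KKKKKK", "MMMMMM", "RRRRRR", "SSSSSS", "WWWWWW", "YYYYYY",
        ]
    )


@dataclass
class CrosstalkConfig:
    c0_molar: float = 1e-6
    threshold: float = 0.05


@dataclass
class ScanConfig:
    window_length: int = 71
    k: int = 2
    force_5prime: bool = True
    five_prime_zone: int = 100


@dataclass
class AssayConfig:
    span_minutes: float = 210.0
    window_points: int = 4
    endpoint_exclusion_minutes: float = 20.0
    representative_time: Optional[float] = None  # default: window midpoint


@dataclass
class RunConfig:
    """Aggregated configuration for all pipeline stages."""

    architecture: ArchitectureConfig = field(default_factory=ArchitectureConfig)
    engine: EngineConfig = field(default_factory=EngineConfig)
    design: DesignConfig = field(default_factory=DesignConfig)
    crosstalk: CrosstalkConfig = field(default_factory=CrosstalkConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)
    assay: AssayConfig = field(default_factory=AssayConfig)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        try:
            is_file = isinstance(source, (str, Path)) and Path(source).exists()
        except OSError:
            is_file = False
        if is_file:
            data = yaml.safe_load(Path(source).read_text())
        else:
            data = yaml.safe_load(source)
        return cls(
            architecture=ArchitectureConfig(**data.get("architecture", {})),
            engine=EngineConfig(**data.get("engine", {})),
            design=DesignConfig(**data.get("design", {})),
            crosstalk=CrosstalkConfig(**data.get("crosstalk", {})),
            scan=ScanConfig(**data.get("scan", {})),
            assay=AssayConfig(**data.get("assay", {})),
        )

    def make_architecture(self, guide: NucSeq):
        from .sequences import SwitchArchitecture

        a = self.architecture
        return SwitchArchitecture(
            guide=guide,
            toehold_len=a.toehold_len,
            clamp_len=a.clamp_len,
            loop_len=a.loop_len,
            linker_len=a.linker_len,
            repeat=NucSeq("repeat", a.repeat),
            middle_len=a.middle_len,
            allow_wobble_clamp=a.allow_wobble_clamp,
        )

    def make_engine_params(self):
        from .engine import EngineParams

        e = self.engine
        return EngineParams(
            pair_scores=dict(e.pair_scores),
            min_loop=e.min_loop,
            beta=e.beta,
            duplex_init_penalty=e.duplex_init_penalty,
            temperature_label=e.temperature_label,
        )
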