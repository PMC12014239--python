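"""Shared I/O and run configuration.

FASTA reading/writing with the normalization contract used throughout the
package (ids to first whitespace, sequences uppercased, U -> T), TSV
helpers, and the serializable :class:`RunConfig` whose defaults mirror the
published analysis parameters (200-bp length filter, 5-mismatch leader
budget, 90% identity / word size 8 collapse, 100-aa ORFs, p < 0.01
enrichment with 0.6 overlap pruning, TPM > 1).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

from .transcripts import Transcript

logger = logging.getLogger(__name__)

__all__ = ["FastaFormatError", "read_fasta", "write_fasta", "RunConfig"]


class FastaFormatError(ValueError):
    pass


def read_fasta(path) -> list[Transcript]:
    """Read a nucleotide FASTA into normalized transcripts.

    Ids are taken to the first whitespace; sequences are uppercased with U
    normalized to T; wrapping is irrelevant.  Duplicate ids and sequence data
    before the first header raise :class:`FastaFormatError`.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s:
                continue
            if not s.startswith(">"):
                raise FastaFormatError(
                    f"{path}: sequence data before first header at line {lineno}"
                )
            break
    out: list[Transcript] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaFormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        out.append(Transcript(id=rec.id, seq=seq))
    if not out:
        logger.warning("read_fasta: %s contained no records", path)
    return out


def write_fasta(transcripts: Iterable[Transcript], path, width: int = 60) -> None:
    """Write transcripts wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.id}\n")
            for i in range(0, len(t.seq), width):
                fh.write(t.seq[i : i + width] + "\n")


@dataclass
class RunConfig:
    """All stage parameters of one end-to-end run; JSON round-trippable."""

    seed: int = 0
    species: str = "synthetic"
    # leader detection
    budget: int = 5
    budget_scope: str = "total"
    max_offset: int = 0
    allow_truncated: bool = False
    # transcript processing
    min_len: int = 200
    identity: float = 0.90
    word_size: int = 8
    min_aa: int = 100
    require_start: bool = True
    # enrichment
    p_cut: float = 0.01
    overlap_cut: float = 0.6
    # expression
    min_tpm: float = 1.0
    # inputs; None for fasta means the synthetic generator supplies the data
    fasta: Optional[str] = None
    annotations: Optional[str] = None
    counts: Optional[str] = None
    sim: Optional[dict] = None  # overrides for SimParams fields

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "RunConfig":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            data = json.loads(Path(source).read_text())
        else:
            data = json.loads(source)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**data)
        cfg._normalize_sim()
        return cfg

    def _normalize_sim(self) -> bool:
        # JSON has no tuples; normalize list-valued sim fields back
        if self.sim:
            for key in ("len_range", "terms_per_gene"):
                if key in self.sim and isinstance(self.sim[key], list):
                    self.sim[key] = tuple(self.sim[key])
            if "rl_count_weights" in self.sim:
                self.sim["rl_count_weights"] = {
                    int(k): float(v) for k, v in self.sim["rl_count_weights"].items()
                }
        return True
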