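"""Degenerate spliced-leader motif search and tandem-arrangement parsing.

Dinoflagellate nuclear mRNAs carry a short spliced leader (DinoSL) at their
5' end.  When a leader-bearing mRNA is reverse-transcribed, reinserted into
the genome and re-expressed, the new transcript is trans-spliced again and
retains a 15-nt "relic" of the old leader (DinoRL) immediately downstream of
the fresh DinoSL.  A transcript whose 5' end parses as ``SL RL{1..n}`` is
therefore diagnostic of a retrogene, and the number of relics counts rounds
of retroposition/recycling.

This module compiles the degenerate leader motifs, performs Hamming-style
mismatch-tolerant anchored search, parses the ``[SL][RL]{1..n}`` grammar and
summarises arrangements, and builds position-frequency matrices for logo-style
consensus output.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DINOSL",
    "DINORL",
    "DINOSL_TRUNC",
    "MotifSpec",
    "LeaderMatch",
    "LeaderArrangement",
    "ArrangementSummary",
    "PositionFrequencyMatrix",
    "compile_motif",
    "count_mismatches",
    "scan_5prime",
    "classify_arrangements",
    "build_pfm",
    "default_motifs",
]

#: Canonical 22-nt dinoflagellate spliced leader; D = A/G/T.
DINOSL = "DCCGTAGCCATTTTGGCTCAAG"
#: 15-nt leader relic: DinoSL minus its first 7 nt.
DINORL = "CCATTTTGGCTCAAG"
#: Truncated leader form observed at the 5' end of many retrogenes.
DINOSL_TRUNC = "CTCAAG"

_IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class MotifSpec:
    """A degenerate nucleotide motif with per-position accepted base sets."""

    name: str
    pattern: str
    allowed_sets: tuple[frozenset[str], ...]

    def __len__(self) -> int:
        return len(self.pattern)


@dataclass(frozen=True)
class LeaderMatch:
    """One motif placement: 0-based half-open span and its mismatch count."""

    motif_name: str
    start: int
    end: int
    mismatches: int


@dataclass(frozen=True)
class LeaderArrangement:
    """Parsed 5'-leader structure of one transcript.

    A transcript is a retrogene call iff it has at least one relic (RL) and
    either a full DinoSL or, when truncated leaders are admitted, the
    CTCAAG-initial form.
    """

    transcript_id: str
    sl_match: Optional[LeaderMatch]
    rl_matches: tuple[LeaderMatch, ...]
    total_mismatches: int
    truncated_leader: bool
    arrangement_class: str

    @property
    def n_rl(self) -> int:
        return len(self.rl_matches)

    @property
    def leader_start(self) -> int:
        return self.sl_match.start if self.sl_match else self.rl_matches[0].start

    @property
    def leader_end(self) -> int:
        return self.rl_matches[-1].end if self.rl_matches else self.sl_match.end

    @property
    def is_retrogene(self) -> bool:
        return self.n_rl >= 1 and (self.sl_match is not None)


def compile_motif(name: str, iupac: str) -> MotifSpec:
    """Expand an IUPAC nucleotide string into per-position accepted-base sets.

    ``U`` is normalized to ``T`` and matching is case-insensitive.  Raises
    ``ValueError`` naming the offending position and character for anything
    outside the IUPAC alphabet.
    """
    if not iupac:
        raise ValueError("motif pattern must be non-empty")
    pattern = _normalize(iupac)
    sets = []
    for i, ch in enumerate(pattern):
        try:
            sets.append(_IUPAC[ch])
        except KeyError:
            raise ValueError(
                f"unknown IUPAC code {ch!r} at position {i} of motif {name!r}"
            ) from None
    return MotifSpec(name=name, pattern=pattern, allowed_sets=tuple(sets))


def default_motifs() -> dict[str, MotifSpec]:
    """The three leader motifs used for retrogene detection."""
    return {
        "DinoSL": compile_motif("DinoSL", DINOSL),
        "DinoRL": compile_motif("DinoRL", DINORL),
        "DinoSL_trunc": compile_motif("DinoSL_trunc", DINOSL_TRUNC),
    }


def count_mismatches(window: str, motif: MotifSpec) -> int:
    """Hamming mismatches of ``window`` against a degenerate motif.

    Any base not in a position's accepted set counts as one mismatch; an
    ambiguous base in the *window* (N or anything non-ACGT) always mismatches.
    """
    window = _normalize(window)
    if len(window) != len(motif):
        raise ValueError(
            f"window length {len(window)} != motif {motif.name!r} length {len(motif)}"
        )
    return sum(1 for b, ok in zip(window, motif.allowed_sets) if b not in ok)


def scan_5prime(
    transcript,
    sl: MotifSpec | None = None,
    rl: MotifSpec | None = None,
    *,
    budget: int = 5,
    max_offset: int = 0,
    allow_truncated: bool = False,
    trunc: MotifSpec | None = None,
    budget_scope: str = "total",
) -> Optional[LeaderArrangement]:
    """Parse the 5' end of a transcript for an ``[SL][RL]{1..n}`` tandem.

    Candidate leader placements are every start position ``0..max_offset``
    for the full DinoSL and, when ``allow_truncated``, the truncated CTCAAG
    form.  Placements are ranked by (mismatches, start, full-before-truncated);
    at each, consecutive relic units are consumed greedily with no gaps, each
    accepted while the mismatch budget holds.  The best-ranked placement that
    yields at least one relic is returned; ``None`` otherwise.

    ``budget_scope`` is ``"total"`` (one budget over the whole leader, the
    default, mirroring a 37-mer search at 5 mismatches) or ``"per-motif"``
    (each motif unit budgeted independently).
    """
    if budget < 0 or max_offset < 0:
        raise ValueError("budget and max_offset must be >= 0")
    if budget_scope not in ("total", "per-motif"):
        raise ValueError(f"budget_scope must be 'total' or 'per-motif', got {budget_scope!r}")
    motifs = default_motifs()
    sl = sl or motifs["DinoSL"]
    rl = rl or motifs["DinoRL"]
    trunc = trunc or motifs["DinoSL_trunc"]

    tid = getattr(transcript, "id", "")
    seq = _normalize(getattr(transcript, "seq", transcript))

    candidates: list[tuple[int, int, bool]] = []  # (mismatches, start, is_trunc)
    for start in range(max_offset + 1):
        if start + len(sl) <= len(seq):
            mm = count_mismatches(seq[start : start + len(sl)], sl)
            if mm <= budget:
                candidates.append((mm, start, False))
        if allow_truncated and start + len(trunc) <= len(seq):
            mm = count_mismatches(seq[start : start + len(trunc)], trunc)
            if mm <= budget:
                candidates.append((mm, start, True))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))

    for sl_mm, start, is_trunc in candidates:
        spec = trunc if is_trunc else sl
        end = start + len(spec)
        total = sl_mm
        rls: list[LeaderMatch] = []
        pos = end
        while pos + len(rl) <= len(seq):
            mm = count_mismatches(seq[pos : pos + len(rl)], rl)
            if budget_scope == "total":
                if total + mm > budget:
                    break
                total += mm
            else:
                if mm > budget:
                    break
                total += mm
            rls.append(LeaderMatch("DinoRL", pos, pos + len(rl), mm))
            pos += len(rl)
        if rls:
            cls = ("SLt" if is_trunc else "SL") + "-RL" * len(rls)
            sl_match = LeaderMatch(spec.name, start, end, sl_mm)
            return LeaderArrangement(
                transcript_id=tid,
                sl_match=sl_match,
                rl_matches=tuple(rls),
                total_mismatches=total,
                truncated_leader=is_trunc,
                arrangement_class=cls,
            )
    return None


@dataclass
class ArrangementSummary:
    """Counts per arrangement class plus the multi-relic fraction."""

    counts: dict[str, int] = field(default_factory=dict)
    multi_rl_fraction: float = float("nan")
    n_total: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.counts.items()), columns=["arrangement_class", "count"]
        )


def classify_arrangements(
    arrangements: Iterable[LeaderArrangement],
) -> ArrangementSummary:
    """Tabulate arrangement classes and the fraction with >= 2 relics."""
    counts: Counter[str] = Counter()
    n_multi = 0
    n = 0
    for arr in arrangements:
        counts[arr.arrangement_class] += 1
        n += 1
        if arr.n_rl >= 2:
            n_multi += 1
    frac = n_multi / n if n else float("nan")
    return ArrangementSummary(counts=dict(counts), multi_rl_fraction=frac, n_total=n)


_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class PositionFrequencyMatrix:
    """Per-column base counts/frequencies over aligned leader windows."""

    length: int
    counts: np.ndarray  # (length, 4) int, columns A C G T
    frequencies: np.ndarray  # (length, 4) float; NaN where no coverage
    covered: np.ndarray  # (length,) bool

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=[f"{b}_count" for b in _BASES])
        for i, b in enumerate(_BASES):
            df[f"{b}_freq"] = self.frequencies[:, i]
        df.insert(0, "position", np.arange(self.length))
        return df


def build_pfm(
    arrangements: Iterable[LeaderArrangement],
    transcripts: Mapping[str, str] | Sequence,
    window_len: int = 37,
) -> PositionFrequencyMatrix:
    """Stack the first ``window_len`` nt from each detected leader start.

    ``transcripts`` maps transcript id to sequence (or is a sequence of
    objects with ``id``/``seq``).  Ambiguous bases are not counted; columns
    past the end of short transcripts simply lack coverage.
    """
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    if not isinstance(transcripts, Mapping):
        transcripts = {t.id: t.seq for t in transcripts}
    counts = np.zeros((window_len, 4), dtype=np.int64)
    for arr in arrangements:
        seq = _normalize(transcripts[arr.transcript_id])
        start = arr.leader_start
        for col in range(window_len):
            pos = start + col
            if pos >= len(seq):
                break
            idx = _BASE_IDX.get(seq[pos])
            if idx is not None:
                counts[col, idx] += 1
    totals = counts.sum(axis=1)
    covered = totals > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = counts / totals[:, None]
    freqs[~covered] = np.nan
    return PositionFrequencyMatrix(
        length=window_len, counts=counts, frequencies=freqs, covered=covered
    )
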