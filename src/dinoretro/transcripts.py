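"""Transcript-level processing around leader detection.

Length filtering of assembled transcripts, within-species redundancy collapse
(greedy longest-first clustering at an identity threshold, keeping the longest
isoform as representative) and longest-ORF extraction on the forward strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio import Align
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

__all__ = [
    "Transcript",
    "Cluster",
    "OrfCall",
    "length_filter",
    "pairwise_identity",
    "collapse_redundancy",
    "find_longest_orf",
]


@dataclass(frozen=True)
class Transcript:
    """One assembled mRNA sequence (5'->3' sense as assembled)."""

    id: str
    seq: str
    species: str = ""

    @property
    def length(self) -> int:
        return len(self.seq)

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"transcript {self.id!r} has empty sequence")


@dataclass
class Cluster:
    """A redundancy cluster; the representative is the longest member."""

    representative_id: str
    member_ids: list[str] = field(default_factory=list)
    identity_to_rep: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class OrfCall:
    """Longest open reading frame of a transcript, forward strand.

    ``start``/``end`` are 0-based half-open nucleotide coordinates on the
    transcript; ``end`` includes the terminal stop codon when one is present.
    """

    transcript_id: str
    frame: int
    start: int
    end: int
    peptide: str
    partial5: bool


def length_filter(transcripts: Sequence[Transcript], min_len: int = 200) -> list[Transcript]:
    """Retain transcripts of length >= ``min_len`` nt, preserving order."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept = [t for t in transcripts if t.length >= min_len]
    logger.info(
        "length_filter: kept %d / %d transcripts (min_len=%d)",
        len(kept), len(transcripts), min_len,
    )
    return kept


# Global alignment with free end gaps: match=1, mismatch=0, internal gaps
# penalized just over 1.  The 2^-20 excess makes the optimal score identify a
# unique (matches, internal gaps) pair for sequences shorter than 2^20 nt, so
# the matched-position count is recoverable from the score alone.
_GAP = -(1.0 + 2.0**-20)
_ALIGNER = Align.PairwiseAligner(
    mode="global", match_score=1.0, mismatch_score=0.0,
    open_internal_gap_score=_GAP, extend_internal_gap_score=_GAP,
    end_insertion_score=0.0, end_deletion_score=0.0,
)


def _alignment_matches(sa: str, sb: str) -> int:
    import math

    score = _ALIGNER.score(sa, sb)
    q = math.ceil(score - 1e-9)  # matches - gaps
    g = round((q - score) * 2**20)
    return q + g


def pairwise_identity(a, b) -> float:
    """Alignment identity = matched positions / length of the shorter sequence.

    Global alignment with free end gaps, match 1, mismatch 0 and internal
    gaps penalized; gaps never enter the numerator.  Symmetric, and a shorter
    sequence that is an exact substring of the longer scores 1.0, so assembly
    fragments collapse into their parent isoform.
    """
    sa = getattr(a, "seq", a).upper()
    sb = getattr(b, "seq", b).upper()
    if not sa or not sb:
        raise ValueError("pairwise_identity requires non-empty sequences")
    return _alignment_matches(sa, sb) / min(len(sa), len(sb))


def _words(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def collapse_redundancy(
    transcripts: Sequence[Transcript],
    threshold: float = 0.90,
    word_size: int = 8,
) -> list[Cluster]:
    """Greedy longest-first clustering at an identity threshold.

    Transcripts are processed by (length desc, id asc); each joins the first
    cluster whose representative shares at least one exact ``word_size``-mer
    and aligns at identity >= ``threshold``, else founds a new cluster.  The
    founders (longest isoforms) are the representatives.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    if word_size < 4:
        raise ValueError("word_size must be >= 4")
    order = sorted(transcripts, key=lambda t: (-t.length, t.id))
    clusters: list[Cluster] = []
    rep_seq: list[str] = []
    rep_words: list[set[str]] = []
    for t in order:
        seq = t.seq.upper()
        words = _words(seq, word_size)
        # pigeonhole: at identity >= threshold over the shorter sequence of
        # length L, at least L*(1 - w*(1-threshold)) - w + 1 of its w-mers
        # survive intact; half of that (distinct-word slack) is demanded
        # before paying for an alignment
        bound = len(seq) * (1 - word_size * (1 - threshold)) - word_size + 1
        min_shared = max(1, int(bound) // 2)
        placed = False
        for ci, cl in enumerate(clusters):
            if len(words & rep_words[ci]) < min_shared:
                continue
            ident = pairwise_identity(seq, rep_seq[ci])
            if ident >= threshold:
                cl.member_ids.append(t.id)
                cl.identity_to_rep[t.id] = ident
                placed = True
                break
        if not placed:
            clusters.append(
                Cluster(representative_id=t.id, member_ids=[t.id],
                        identity_to_rep={t.id: 1.0})
            )
            rep_seq.append(seq)
            rep_words.append(words)
    logger.info(
        "collapse_redundancy: %d transcripts -> %d clusters (id>=%.2f, word=%d)",
        len(transcripts), len(clusters), threshold, word_size,
    )
    return clusters


_STOPS = {"TAA", "TAG", "TGA"}


def find_longest_orf(
    transcript,
    min_aa: int = 100,
    require_start: bool = True,
    start_at: int = 0,
) -> Optional[OrfCall]:
    """Longest forward-strand ORF across frames 0-2.

    Candidates run from an ATG (or from the frame start when
    ``require_start`` is false, flagged ``partial5``) to the next in-frame
    stop or the sequence end.  Returns the longest candidate of at least
    ``min_aa`` residues, ties broken by smaller start; ``None`` when nothing
    qualifies.  ``start_at`` restricts candidate starts (e.g. downstream of a
    detected leader).  Translation uses the standard genetic code.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    tid = getattr(transcript, "id", "")
    seq = getattr(transcript, "seq", transcript).upper().replace("U", "T")
    best: Optional[tuple[int, int, OrfCall]] = None  # (-pep_len, start, call)
    for frame in range(3):
        codon_starts = range(frame, len(seq) - 2, 3)
        seg_start = frame
        segments: list[tuple[int, int, bool]] = []  # (start, end, has_stop)
        for pos in codon_starts:
            if seq[pos : pos + 3] in _STOPS:
                segments.append((seg_start, pos + 3, True))
                seg_start = pos + 3
        tail_end = frame + 3 * ((len(seq) - frame) // 3)
        if seg_start < tail_end:
            segments.append((seg_start, tail_end, False))
        for s, e, has_stop in segments:
            # first in-frame codon position >= start_at within the segment
            lo = s if start_at <= s else s + 3 * ((start_at - s + 2) // 3)
            # a start-codon-free candidate exists only at the frame start
            # (5'-partial transcript); every later segment needs an ATG
            if not require_start and s == frame and lo == s and lo + 3 <= e:
                cand_start = s
                partial5 = seq[s : s + 3] != "ATG"
            else:
                cand_start = None
                p = lo
                while p + 3 <= e:
                    if seq[p : p + 3] == "ATG":
                        cand_start = p
                        break
                    p += 3
                if cand_start is None:
                    continue
                partial5 = False
            n_aa = (e - cand_start) // 3 - (1 if has_stop else 0)
            if n_aa < min_aa:
                continue
            pep = str(Seq(seq[cand_start : e - (3 if has_stop else 0)]).translate())
            key = (-n_aa, cand_start)
            if best is None or key < (best[0], best[1]):
                call = OrfCall(
                    transcript_id=tid, frame=frame, start=cand_start, end=e,
                    peptide=pep, partial5=partial5,
                )
                best = (-n_aa, cand_start, call)
    return best[2] if best else None
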