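"""Synthetic dinoflagellate transcriptome generator with planted truth.

Every downstream stage of the retrogene pipeline is testable without any
download: this module emits transcriptome FASTA records with a known leader
structure — each transcript led by the 22-nt degenerate DinoSL (or its
truncated CTCAAG form), a retrogene subset carrying 1..4 tandem 15-nt DinoRL
relics after the leader — followed by GC-rich coding sequence whose
third-codon GC is controlled independently of amino-acid composition.
Assembly-like noise is layered on: 5'-truncation, near-identical shorter
isoform duplicates, leader point substitutions and minimum-length violations.
Alongside the sequences it produces the planted truth table, a per-gene
annotation table with one term enriched among retrogenes, and a
negative-binomial count table with class-specific means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .codon import SYN_FAMILIES
from .leaders import DINORL, DINOSL_TRUNC
from .transcripts import Transcript

__all__ = [
    "SimParams",
    "SyntheticTruth",
    "SimResult",
    "generate_transcriptome",
    "third_codon_sampler",
    "write_outputs",
]

_SL_CORE = "CCGTAGCCATTTTGGCTCAAG"  # DinoSL minus the degenerate first base
_STOPS = ("TAA", "TAG", "TGA")
_AA = "".join(sorted(SYN_FAMILIES))  # 20 amino acids
_BASES = np.array(list("ACGT"))


@dataclass
class SimParams:
    """Study conditions for one synthetic transcriptome.

    Defaults emulate the compositional facts reported for dinoflagellate
    transcriptomes: ~62% coding GC with ~75% GC3s, a retrogene minority of
    which ~95% carry a single relic, a minority of leaders in the truncated
    CTCAAG form, and mild assembly noise.
    """

    n_normal: int = 2700
    n_retro: int = 300
    rl_count_weights: dict[int, float] = field(
        default_factory=lambda: {1: 0.95, 2: 0.04, 3: 0.008, 4: 0.002}
    )
    gc3_target: float = 0.75
    gc_target: float = 0.62
    len_range: tuple[int, int] = (150, 2400)
    p_truncate5: float = 0.05
    p_trunc_leader: float = 0.3
    dup_rate: float = 0.1
    dup_identity: float = 0.95
    leader_mut_rate: float = 0.01
    n_terms: int = 40
    terms_per_gene: tuple[int, int] = (1, 3)
    enriched_term: str = "T_ENR"
    enriched_p_fg: float = 0.5
    enriched_p_bg: float = 0.05
    mean_count_normal: float = 100.0
    mean_count_retro: float = 200.0
    nb_dispersion: float = 5.0
    species: str = "synthetic"
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_truncate5", "p_trunc_leader", "dup_rate",
                     "leader_mut_rate", "gc3_target", "gc_target",
                     "enriched_p_fg", "enriched_p_bg"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} must be in [0, 1]")
        if self.n_normal < 0 or self.n_retro < 0:
            raise ValueError("transcript counts must be nonnegative")
        if self.n_normal + self.n_retro == 0:
            raise ValueError("requested an empty transcriptome (n_normal + n_retro = 0)")
        if self.len_range[0] < 1 or self.len_range[0] > self.len_range[1]:
            raise ValueError(f"invalid len_range {self.len_range}")
        w = self.rl_count_weights
        if not w or any(c < 0 for c in w.values()) or sum(w.values()) <= 0:
            raise ValueError("rl_count_weights must be nonnegative, not all zero")
        if any(not 1 <= k <= 4 for k in w):
            raise ValueError("rl_count_weights keys must be in 1..4")


@dataclass
class SyntheticTruth:
    """Planted labels for one emitted transcript.

    ``leader_start`` is the offset of the (possibly truncated-form) leader in
    the final sequence; a negative value -k means 5'-truncation clipped the
    first k leader bases.  ``leader_mutations`` are (position, from, to) in
    final-sequence coordinates, restricted to the surviving leader span.
    """

    transcript_id: str
    is_retrogene: bool
    planted_rl_count: int
    planted_leader_start: int
    leader_mutations: list[tuple[int, str, str]] = field(default_factory=list)
    truncated_leader: bool = False


@dataclass
class SimResult:
    transcripts: list[Transcript]
    truths: list[SyntheticTruth]
    annotations: pd.DataFrame  # gene_id, term_id
    counts: pd.DataFrame  # gene_id, length_nt, count
    params: SimParams


def _expected_codon_gc(gc3_target: float) -> dict[str, float]:
    """Expected number of G/C bases per codon for each amino acid under the
    third-position sampler."""
    out = {}
    for aa, codons in SYN_FAMILIES.items():
        probs = _family_probs(codons, gc3_target)
        out[aa] = float(
            sum(p * sum(b in "GC" for b in c) for c, p in zip(codons, probs))
        )
    return out


def _family_probs(codons: tuple[str, ...], gc3_target: float) -> np.ndarray:
    gc_end = np.array([c[2] in "GC" for c in codons])
    n_gc, n_at = int(gc_end.sum()), int((~gc_end).sum())
    w = np.where(
        gc_end,
        gc3_target / n_gc if n_gc else 0.0,
        (1 - gc3_target) / n_at if n_at else 0.0,
    )
    if w.sum() == 0:  # one-sided family at an extreme target
        w = np.ones(len(codons))
    return w / w.sum()


def _aa_weights(gc_target: float, gc3_target: float) -> np.ndarray:
    """Exponentially tilted amino-acid weights whose expected codon GC matches
    ``gc_target`` given the third-position sampler, found by bisection."""
    egc = _expected_codon_gc(gc3_target)
    vals = np.array([egc[aa] / 3.0 for aa in _AA])  # per-base GC fraction per aa

    def mean_gc(lam: float) -> float:
        w = np.exp(lam * vals)
        return float((w * vals).sum() / w.sum())

    lo, hi = -60.0, 60.0
    if gc_target <= mean_gc(lo):
        lam = lo
    elif gc_target >= mean_gc(hi):
        lam = hi
    else:
        for _ in range(80):
            mid = (lo + hi) / 2
            if mean_gc(mid) < gc_target:
                lo = mid
            else:
                hi = mid
        lam = (lo + hi) / 2
    w = np.exp(lam * vals)
    return w / w.sum()


def third_codon_sampler(
    gc3_target: float,
    aa_sequence: str,
    rng: np.random.Generator | int | None = None,
) -> list[str]:
    """Back-translate a peptide choosing synonymous codons so that the
    third position is G/C with probability ``gc3_target``, renormalized
    within each family.  Deterministic for a given generator state."""
    if not 0 <= gc3_target <= 1:
        raise ValueError("gc3_target must be in [0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    aas = aa_sequence.upper()
    bad = sorted(set(aas) - set(SYN_FAMILIES))
    if bad:
        raise ValueError(f"invalid amino-acid symbol {bad[0]!r}")
    arr = np.array(list(aas))
    out: list[str] = [""] * len(aas)
    for aa in sorted(set(aas)):  # family-wise draws, deterministic order
        fam = SYN_FAMILIES[aa]
        probs = _family_probs(fam, gc3_target)
        pos = np.nonzero(arr == aa)[0]
        picks = rng.choice(len(fam), size=len(pos), p=probs)
        for p_i, c_i in zip(pos, picks):
            out[p_i] = fam[c_i]
    return out


def _make_cds(n_aa: int, aa_probs: np.ndarray, params: SimParams,
              rng: np.random.Generator) -> str:
    peptide = "".join(np.array(list(_AA))[rng.choice(len(_AA), size=n_aa, p=aa_probs)])
    body = "".join(third_codon_sampler(params.gc3_target, peptide, rng))
    # stop codon: third-base GC probability follows the same target
    stop = _STOPS[rng.choice(3, p=[(1 - params.gc3_target) / 2,
                                   params.gc3_target / 2,
                                   0.5])]
    return "ATG" + body + stop


def _mutate_leader(
    leader: str, rate: float, rng: np.random.Generator
) -> tuple[str, list[tuple[int, str, str]]]:
    if rate == 0:
        return leader, []
    chars = list(leader)
    muts = []
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for pos in hits:
        old = chars[pos]
        new = str(rng.choice([b for b in "ACGT" if b != old]))
        chars[pos] = new
        muts.append((int(pos), old, new))
    return "".join(chars), muts


def generate_transcriptome(params: SimParams) -> SimResult:
    """Generate transcripts, planted truth, annotations and counts.

    Identical parameters (including the seed) yield byte-identical outputs.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    aa_probs = _aa_weights(params.gc_target, params.gc3_target)

    rl_ks = sorted(params.rl_count_weights)
    rl_ws = np.array([params.rl_count_weights[k] for k in rl_ks], dtype=float)
    rl_ws /= rl_ws.sum()

    n_total = params.n_normal + params.n_retro
    transcripts: list[Transcript] = []
    truths: list[SyntheticTruth] = []

    for i in range(n_total):
        tid = f"tx{i:05d}"
        is_retro = i < params.n_retro
        rl_count = int(rl_ks[rng.choice(len(rl_ks), p=rl_ws)]) if is_retro else 0
        truncated = bool(rng.random() < params.p_trunc_leader)
        if truncated:
            leader = DINOSL_TRUNC + DINORL * rl_count
        else:
            d = str(rng.choice(list("AGT")))
            leader = d + _SL_CORE + DINORL * rl_count
        leader, muts = _mutate_leader(leader, params.leader_mut_rate, rng)

        total_len = int(rng.integers(params.len_range[0], params.len_range[1] + 1))
        n_aa = max(10, (total_len - len(leader) - 6) // 3)
        cds = _make_cds(n_aa, aa_probs, params, rng)
        seq = leader + cds

        leader_start = 0
        if rng.random() < params.p_truncate5:
            k = int(rng.integers(1, 31))
            seq = seq[k:]
            leader_start = -k
            muts = [(p - k, a, b) for p, a, b in muts if p >= k]

        transcripts.append(Transcript(id=tid, seq=seq, species=params.species))
        truths.append(
            SyntheticTruth(
                transcript_id=tid,
                is_retrogene=is_retro,
                planted_rl_count=rl_count,
                planted_leader_start=leader_start,
                leader_mutations=muts,
                truncated_leader=truncated,
            )
        )

    # near-identical shorter isoform duplicates: 3'-truncate and substitute
    # downstream of the leader only (one locus shares one leader)
    dup_flags = rng.random(n_total) < params.dup_rate
    for i in np.nonzero(dup_flags)[0]:
        parent, tr = transcripts[i], truths[i]
        keep = float(rng.uniform(0.80, 0.95))
        cut = max(int(len(parent.seq) * keep), 60)
        chars = list(parent.seq[:cut])
        leader_len = (
            len(DINOSL_TRUNC) if tr.truncated_leader else 22
        ) + tr.planted_rl_count * len(DINORL)
        leader_end = tr.planted_leader_start + leader_len
        sub_rate = 1 - params.dup_identity
        for pos in np.nonzero(rng.random(len(chars)) < sub_rate)[0]:
            if pos < leader_end:
                continue
            chars[pos] = str(rng.choice([b for b in "ACGT" if b != chars[pos]]))
        iso_id = f"{parent.id}_iso"
        transcripts.append(Transcript(id=iso_id, seq="".join(chars),
                                      species=params.species))
        truths.append(
            SyntheticTruth(
                transcript_id=iso_id,
                is_retrogene=tr.is_retrogene,
                planted_rl_count=tr.planted_rl_count,
                planted_leader_start=tr.planted_leader_start,
                leader_mutations=list(tr.leader_mutations),
                truncated_leader=tr.truncated_leader,
            )
        )

    # annotation table: 1-3 generic terms per gene + one planted term
    # carried by retrogenes with elevated probability
    vocab = [f"T{j:03d}" for j in range(params.n_terms)]
    ann_rows = []
    for t, tr in zip(transcripts, truths):
        lo, hi = params.terms_per_gene
        n_terms = int(rng.integers(lo, hi + 1))
        for j in rng.choice(params.n_terms, size=n_terms, replace=False):
            ann_rows.append((t.id, vocab[j]))
        p_enr = params.enriched_p_fg if tr.is_retrogene else params.enriched_p_bg
        if rng.random() < p_enr:
            ann_rows.append((t.id, params.enriched_term))
    annotations = pd.DataFrame(ann_rows, columns=["gene_id", "term_id"])

    # negative-binomial counts with class-specific means
    disp = params.nb_dispersion
    count_rows = []
    for t, tr in zip(transcripts, truths):
        mean = params.mean_count_retro if tr.is_retrogene else params.mean_count_normal
        c = int(rng.negative_binomial(disp, disp / (disp + mean)))
        count_rows.append((t.id, len(t.seq), c))
    counts = pd.DataFrame(count_rows, columns=["gene_id", "length_nt", "count"])

    return SimResult(transcripts, truths, annotations, counts, params)


def write_outputs(result: SimResult, outdir) -> dict[str, Path]:
    """Write FASTA (60-column wrap), truth, annotation and count TSVs."""
    from .io import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "transcriptome.fasta",
        "truth": outdir / "truth.tsv",
        "annotations": outdir / "annotations.tsv",
        "counts": outdir / "counts.tsv",
    }
    write_fasta(result.transcripts, paths["fasta"])
    truth_df = pd.DataFrame(
        [
            {
                "transcript_id": t.transcript_id,
                "is_retrogene": int(t.is_retrogene),
                "rl_count": t.planted_rl_count,
                "leader_start": t.planted_leader_start,
                "truncated": int(t.truncated_leader),
            }
            for t in result.truths
        ]
    )
    truth_df.to_csv(paths["truth"], sep="\t", index=False)
    result.annotations.to_csv(paths["annotations"], sep="\t", index=False)
    result.counts.to_csv(paths["counts"], sep="\t", index=False)
    return paths
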