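"""End-to-end retrogene report: simulate/load -> length filter -> leader
detection -> redundancy collapse -> ORF extraction -> codon usage ->
enrichment -> expression comparison.

The bundle returned by :func:`run_report` is a plain dict (JSON-serializable
after the DataFrame members are exported) and is byte-reproducible for a
fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd

from . import codon, enrichment, expression, leaders, transcripts as tr
from .io import RunConfig, read_fasta
from .simulate import SimParams, generate_transcriptome, write_outputs

logger = logging.getLogger(__name__)

__all__ = ["run_report", "StageError"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapped(*a, **k):
            try:
                return fn(*a, **k)
            except Exception as e:  # noqa: BLE001 - aborting with stage context
                raise StageError(name, e) from e
        return wrapped
    return deco


def run_report(config: RunConfig, outdir=None) -> dict:
    """Run the full pipeline under one config; optionally write the bundle.

    Returns a dict with the retrogene count, arrangement-class table,
    multi-relic fraction, cluster count, ORF-bearing retrogene count, group
    codon summaries, retained enrichment rows and the expression test.
    """
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    # --- input stage: simulate or load -----------------------------------
    annotations = counts = truth = None
    if config.fasta is None:
        sim_kwargs = dict(config.sim or {})
        sim_kwargs.setdefault("seed", config.seed)
        sim_kwargs.setdefault("species", config.species)
        params = SimParams(**sim_kwargs)
        result = _stage("simulate")(generate_transcriptome)(params)
        txs = result.transcripts
        annotations, counts = result.annotations, result.counts
        truth = {t.transcript_id: t for t in result.truths}
        if outdir is not None:
            write_outputs(result, outdir / "sim")
    else:
        txs = _stage("read_fasta")(read_fasta)(config.fasta)
        if config.annotations:
            annotations = pd.read_csv(config.annotations, sep="\t", dtype=str)
        if config.counts:
            counts = pd.read_csv(config.counts, sep="\t")
    n_input = len(txs)

    # --- length filter ----------------------------------------------------
    txs = _stage("length_filter")(tr.length_filter)(txs, config.min_len)

    # --- leader detection -------------------------------------------------
    @_stage("detect")
    def _detect():
        arrs = []
        for t in txs:
            a = leaders.scan_5prime(
                t,
                budget=config.budget,
                max_offset=config.max_offset,
                allow_truncated=config.allow_truncated,
                budget_scope=config.budget_scope,
            )
            if a is not None:
                arrs.append(a)
        return arrs

    arrangements = _detect()
    summary = leaders.classify_arrangements(arrangements)
    retro_ids = {a.transcript_id for a in arrangements}
    by_id = {t.id: t for t in txs}

    # --- redundancy collapse (retrogene set, keep longest isoform) --------
    retro_txs = [t for t in txs if t.id in retro_ids]
    clusters = _stage("collapse")(tr.collapse_redundancy)(
        retro_txs, config.identity, config.word_size
    )
    rep_ids = [c.representative_id for c in clusters]

    # --- ORF extraction ---------------------------------------------------
    @_stage("orf")
    def _orfs():
        arr_by_id = {a.transcript_id: a for a in arrangements}
        calls = {}
        for t in txs:
            start_at = arr_by_id[t.id].leader_end if t.id in arr_by_id else 0
            c = tr.find_longest_orf(
                t, min_aa=config.min_aa,
                require_start=config.require_start, start_at=start_at,
            )
            if c is not None:
                calls[t.id] = c
        return calls

    orf_calls = _orfs()
    retro_orf_ids = [i for i in rep_ids if i in orf_calls]

    # --- codon usage ------------------------------------------------------
    @_stage("codon")
    def _codon():
        records = []
        for tid, call in orf_calls.items():
            group = "retrogene" if tid in retro_ids else "normal"
            cds = by_id[tid].seq[call.start : call.end]
            records.append((tid, group, cds))
        return codon.profile_set(records)

    profiles, codon_summary = _codon()

    # --- enrichment -------------------------------------------------------
    enrich_df = None
    if annotations is not None and retro_ids:
        @_stage("enrich")
        def _enrich():
            annot = enrichment.AnnotationTable.from_frame(annotations)
            bg = sorted(annot.gene_terms.keys() & {t.id for t in txs})
            fg = sorted(set(rep_ids) & set(bg))
            if not fg:
                return None
            return enrichment.enrich_set(
                fg, bg, annot, p_cut=config.p_cut, overlap_cut=config.overlap_cut
            )
        enrich_df = _enrich()

    # --- expression -------------------------------------------------------
    expr = None
    expr_table = None
    if counts is not None:
        @_stage("express")
        def _express():
            df = counts.copy()
            df = df[df["gene_id"].isin(by_id)].reset_index(drop=True)
            df["tpm"] = expression.tpm_normalize(df["count"], df["length_nt"])
            df["class"] = [
                "retrogene" if g in retro_ids else "normal" for g in df["gene_id"]
            ]
            kept = expression.expression_filter(df, config.min_tpm)
            x = kept.loc[kept["class"] == "retrogene", "tpm"].to_numpy()
            y = kept.loc[kept["class"] == "normal", "tpm"].to_numpy()
            test = expression.rank_sum_test(x, y) if len(x) and len(y) else None
            return df, test
        expr_table, expr = _express()

    bundle = {
        "species": config.species,
        "seed": config.seed,
        "n_input": n_input,
        "n_after_length_filter": len(txs),
        "retrogene_count": len(retro_ids),
        "arrangement_classes": dict(sorted(summary.counts.items())),
        "multi_rl_fraction": summary.multi_rl_fraction,
        "cluster_count": len(clusters),
        "retrogene_representatives": len(rep_ids),
        "orf_bearing_retrogenes": len(retro_orf_ids),
        "codon_summary": codon_summary.to_dict(orient="records"),
        "enriched_terms_retained": (
            int(enrich_df["retained"].sum()) if enrich_df is not None else None
        ),
        "expression_test": (
            {
                "statistic": expr.statistic,
                "p": expr.pvalue,
                "method": expr.method,
                "n_retrogene": expr.n_x,
                "n_normal": expr.n_y,
            }
            if expr is not None
            else None
        ),
    }
    if truth is not None:
        planted = {tid for tid, t in truth.items() if t.is_retrogene}
        called = retro_ids
        detectable = planted & {t.id for t in txs}
        tp = len(called & planted)
        bundle["planted_retrogenes"] = len(planted)
        bundle["recall_vs_truth"] = tp / len(detectable) if detectable else None
        bundle["precision_vs_truth"] = tp / len(called) if called else None

    if outdir is not None:
        (outdir / "report.json").write_text(json.dumps(bundle, indent=2, sort_keys=True) + "\n")
        _write_tables(outdir, arrangements, clusters, orf_calls, profiles,
                      codon_summary, enrich_df, expr_table, by_id)
        config.to_json(outdir / "config.json")
    return bundle


def _write_tables(outdir, arrangements, clusters, orf_calls, profiles,
                  codon_summary, enrich_df, expr_table, by_id):
    pd.DataFrame(
        [
            {
                "transcript_id": a.transcript_id,
                "class": a.arrangement_class,
                "sl_start": a.sl_match.start,
                "leader_end": a.leader_end,
                "n_rl": a.n_rl,
                "mismatches": a.total_mismatches,
                "truncated": int(a.truncated_leader),
            }
            for a in arrangements
        ]
    ).to_csv(outdir / "calls.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"rep_id": c.representative_id, "member_id": m,
             "identity": c.identity_to_rep[m]}
            for c in clusters
            for m in c.member_ids
        ]
    ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    pd.DataFrame(
        [dataclasses.asdict(c) for c in orf_calls.values()]
    ).to_csv(outdir / "orfs.tsv", sep="\t", index=False)
    profiles.to_csv(outdir / "codon_profiles.tsv", sep="\t", index=False)
    codon_summary.to_csv(outdir / "codon_summary.tsv", sep="\t", index=False)
    if enrich_df is not None:
        enrich_df.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    if expr_table is not None:
        expr_table.to_csv(outdir / "expression.tsv", sep="\t", index=False)
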