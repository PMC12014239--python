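"""Collapse redundant isoforms and extract the longest ORF per transcript.

Collapse is greedy longest-first at 90% identity (identity = aligned matches
over the shorter sequence), so assembly fragments join their parent and the
longest isoform represents each cluster.  ORFs run ATG to stop on the
forward strand - the leader fixes the orientation.
"""

from dinoretro import (
    SimParams,
    collapse_redundancy,
    find_longest_orf,
    generate_transcriptome,
    length_filter,
)

res = generate_transcriptome(SimParams(n_normal=150, n_retro=50, dup_rate=0.3, seed=3))
txs = length_filter(res.transcripts, 200)
print(f"{len(res.transcripts)} transcripts, {len(txs)} pass the 200-nt filter")

clusters = collapse_redundancy(txs, threshold=0.90, word_size=8)
multi = [c for c in clusters if len(c.member_ids) > 1]
print(f"{len(clusters)} clusters; {len(multi)} contain collapsed isoforms")
example = multi[0]
print(f"example cluster: rep={example.representative_id}, "
      f"members={example.member_ids}, "
      f"identities={ {m: round(v, 3) for m, v in example.identity_to_rep.items()} }")

calls = [c for t in txs if (c := find_longest_orf(t, min_aa=100))]
mean_aa = sum(len(c.peptide) for c in calls) / len(calls)
print(f"{len(calls)} transcripts carry an ORF of >= 100 aa "
      f"(mean peptide {mean_aa:.0f} aa)")
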