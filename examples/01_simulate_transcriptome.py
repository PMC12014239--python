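"""Generate a small synthetic dinoflagellate transcriptome with planted
retrogenes and print what was planted.

Every transcript starts with the 22-nt DinoSL spliced leader (or its
truncated CTCAAG form); retrogenes carry 1-4 tandem 15-nt DinoRL relics
after the leader.  The truth table records exactly what was planted, so
detection can be scored downstream.
"""

from dinoretro import SimParams, generate_transcriptome, write_outputs

params = SimParams(n_normal=180, n_retro=20, seed=42)
result = generate_transcriptome(params)

n_retro = sum(t.is_retrogene for t in result.truths)
n_trunc = sum(t.truncated_leader for t in result.truths)
print(f"transcripts emitted : {len(result.transcripts)}")
print(f"planted retrogenes  : {n_retro}")
print(f"truncated leaders   : {n_trunc}")
print(f"annotation rows     : {len(result.annotations)}")
print(f"count-table rows    : {len(result.counts)}")

paths = write_outputs(result, "scratch/example_sim")
print(f"FASTA + truth/annotation/count TSVs written under {paths['fasta'].parent}")
# The isoform duplicates (ids ending in _iso) and sub-200-nt transcripts are
# deliberate noise for the collapse and length-filter stages.
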