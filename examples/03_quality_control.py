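"""Quality control: length rules, short alignments, chimera screen.

Injects chimeras (spliced from two unrelated references) and short-
fragment artifacts (<300 bp of real sequence in random flanks) into a
community and runs the retention rules. Chimeras are caught because they
align <90% of their length to both the cultured and the environmental
databases; fragments are caught by the <300 bp query-alignment rule.
"""

import microcensus as mc

refs = mc.generate_reference_db(n_bacteria=12, n_archaea=4, length=1000, seed=7)
env_db = mc.generate_environmental_db(refs, 16, seed=8)
spec = mc.CommunitySpec(environment="sediment", n_seqs_per_sample=100,
                        chimera_rate=0.1, short_fragment_rate=0.1, seed=13)
data = mc.generate_environment_dataset(spec, refs)

hits = mc.search_all(data.sequences, refs)
records = data.metadata.set_index("query_id")
records["length"] = [len(data.sequences[q]) for q in records.index]

h = hits.set_index("query_id")
screened = {q: data.sequences[q] for q in records.index
            if h.loc[q, "no_hit"]
            or h.loc[q, "qlen_aligned"] / records.loc[q, "length"] < 0.90}
hits_env = mc.search_all(screened, env_db) if screened else None

report = mc.run_qc(records, hits, hits_env)
print("per-rule removal fractions:")
for outcome, frac in report.removal_fractions().items():
    print(f"  {outcome}: {frac:.3f}")

joined = report.table.join(data.truth.set_index("query_id"))
chim = joined[joined["is_chimera"]]
frag = joined[joined["is_short_fragment"]]
print(f"\nchimeras flagged: {(chim['outcome'] == 'removed_chimera').mean():.0%} "
      f"of {len(chim)}")
print(f"fragments removed: "
      f"{(frag['outcome'] == 'removed_short_alignment').mean():.0%} of {len(frag)}")
clean = joined[~joined["is_chimera"] & ~joined["is_short_fragment"]]
print(f"clean queries retained: {(clean['outcome'] == 'retained').mean():.0%}")
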