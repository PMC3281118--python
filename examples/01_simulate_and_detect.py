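"""Simulate a genome with planted miniature retrotransposons and find them.

The generator plants 292-bp elements (two 85-bp LTRs with TGT...ACA termini
around a 122-bp internal region, flanked by a duplicated 5-bp target site);
the detector recovers them from the sequence alone by scanning for direct
repeats and verifying the structural hallmarks.
"""

from smartltr import SimConfig, detect_elements, simulate_genome

config = SimConfig(
    genome_length=200_000, n_complete=10, n_solo=3, n_fragment=4,
    n_genes=8, max_age_mya=6.0, seed=7,
)
records, genes, truth = simulate_genome(config)
result = detect_elements(records[0])

planted = truth[truth["class"] == "complete"]
called = {(c.start, c.end) for c in result.calls}
recovered = sum(
    (int(r.start), int(r.end)) in called for _, r in planted.iterrows()
)

print(f"planted complete elements : {len(planted)}")
print(f"structural calls          : {len(result.calls)}")
print(f"recovered exactly         : {recovered}")
for call in result.calls[:3]:
    print(f"  {call.id}  [{call.start}, {call.end})  TSD={call.tsd}  "
          f"LTR identity={call.identity:.3f}")
# Each call is a complete element whose repeat pair, terminal motifs and
# duplicated target site all checked out; recovered == planted means the
# scan found every element at its exact boundaries.
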