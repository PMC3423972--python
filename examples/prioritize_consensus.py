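"""Consensus prioritization: rank compounds by co-clustering frequency.

Runs all 28 (measure x linkage) clustering trials on a simulated screen and
ranks every compound by how often it falls in the signature compound's
subcluster, then compares the top ranks with the planted ground truth.
"""

from chemoconsensus import (
    LINKAGES, MEASURES, MinSize, SimParams, consensus_rank, enumerate_trials,
    generate,
)

matrix, truth = generate(SimParams(seed=1))
trials = enumerate_trials(MEASURES, LINKAGES)
ranking = consensus_rank(matrix, truth.signature_id, trials, MinSize(4))

planted = sorted(truth.module_compound_ids - {truth.signature_id})
print(f"signature compound: {truth.signature_id}")
print(f"trials run: {ranking.trials_run} (skipped: {len(ranking.skipped)})")
print(f"planted partners: {planted}\n")
print("rank  compound      co-clustering frequency")
for r, (c, f) in enumerate(ranking.ranking()[:8], start=1):
    tag = " <- planted" if c in truth.module_compound_ids else ""
    print(f"{r:4d}  {c:12s}  {f:.3f}{tag}")
print("\nFrequency = fraction of the 28 trials in which the compound sat in")
print("the signature's minimum-size-4 subcluster. Compounds sharing the")
print("planted module co-cluster under nearly every measure/linkage choice;")
print("background compounds only sporadically.")
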