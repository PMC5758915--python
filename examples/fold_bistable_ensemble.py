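"""Recover a two-conformation ensemble from simulated SHAPE data.

Builds the designed bistable RNA (two mutually exclusive 5-bp hairpins),
simulates a SHAPE profile from a 70/30 mixture of its two conformations,
runs the full refinement pipeline, and prints the recovered conformations
with their populations.
"""

from shapefold import RunConfig, run_pipeline, sensitivity_ppv, simulate_shape
from shapefold.synthetic import bistable_system

seq, conf_a, conf_b = bistable_system()
print(f"sequence ({len(seq)} nt): {seq}")
print(f"conformation A (70%):     {conf_a.to_dotbracket()}")
print(f"conformation B (30%):     {conf_b.to_dotbracket()}")

rexp = simulate_shape([(conf_a, 0.7), (conf_b, 0.3)], seed=11)
result = run_pipeline(seq, rexp, RunConfig(seed=1))

print("\nrecovered ensemble:")
for i, conf in enumerate(result.model.conformations, start=1):
    best = max((sensitivity_ppv(conf.centroid, ref).geometric_mean, name)
               for ref, name in ((conf_a, "A"), (conf_b, "B")))
    flag = "  [below 2% population floor]" if conf.flagged else ""
    print(f"  {i}. population {conf.population:.3f}  "
          f"{conf.centroid.to_dotbracket()}  "
          f"closest to {best[1]} (accuracy {best[0]:.2f}){flag}")
print(f"Shannon entropy per nucleotide: {result.model.shannon_entropy:.4f}")
print("\nThe two substantive clusters match the generating structures and")
print("their populations track the 70/30 mixture the SHAPE data encode.")
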