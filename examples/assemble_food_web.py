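"""Evolve a small food web and summarise the run.

Runs 2000 invasion attempts in each assembly mode at beta = 0.75 and
prints the invasion success rate, the species-richness histogram and
the treelike fraction of the recorded feasible webs.
"""

from evospectra import AssemblyConfig, evolve, metrics, success_rate

for mode in ("treelike", "non_omnivorous", "omnivorous"):
    cfg = AssemblyConfig(mode=mode, beta=0.75, attempts=2000, seed=1)
    history = evolve(cfg)
    m = metrics(history)
    hist = {r: round(f, 3) for r, f in sorted(m["richness_histogram"].items())}
    print(f"{mode}:")
    print(f"  success rate       : {success_rate(history):.3f}")
    print(f"  richness histogram : {hist}")
    print(f"  treelike fraction  : {m['treelike_fraction']:.3f}")
    print(f"  final web richness : {history.final_web.n}")

# The success rate is lowest for treelike assembly (an invader must beat
# a same-niche resident outright), and odd species richness dominates the
# histograms: webs whose species pair up with the nutrient source are the
# ones that admit feasible steady states.
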