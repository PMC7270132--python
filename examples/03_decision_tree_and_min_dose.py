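"""Build the castration-rooted synergy tree and search a minimal dose.

The tree keeps only step-wise therapy additions whose Bliss index is
below 1; the dose search then finds the smallest checkpoint-blockade dose
that still matches the no-interaction benchmark of the CX+ICB pair.
"""

from pcaqsp import (bliss_union, build_decision_tree, default_parameters,
                    minimal_dose_search, screen_combinations)

params = default_parameters()
results = screen_combinations(params, max_size=7)
ti = {r.combo: r.tumor_inhibition for r in results}

tree = build_decision_tree(results, root="CX", bci_threshold=1.0)
print(f"synergy tree: {tree.number_of_nodes()} nodes, "
      f"{tree.number_of_edges()} synergistic edges")
print("edges out of the root (therapy added to castration, BCI):")
for _, child, data in tree.out_edges(("CX",), data=True):
    print(f"  CX -> {'+'.join(child):<8} BCI={data['bci']:.2f}")

target = bliss_union([ti[("CX",)], ti[("ICB",)]])
dose = minimal_dose_search(params, ("CX", "ICB"), "ICB", target)
print(f"\nno-interaction benchmark Ti = {100 * target:.1f}%")
print(f"minimal ICB dose fraction reaching it within CX+ICB: {dose:.2f}")
print("A fraction below 1 would mean the pair's synergy buys a dose "
      "reduction at equal effect.")
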