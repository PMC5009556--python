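"""Reduce a redundant gene-set collection to kappa-cluster representatives.

Gene-set collections contain many near-duplicate sets; counting each copy
inflates overlap-based scores. Sets are clustered by Cohen's kappa of their
membership vectors (single linkage over the kappa >= threshold graph) and
each cluster keeps its largest set as representative.
"""

from cogsyn import GeneSet, GeneSetCollection, cluster_representatives, kappa

universe = frozenset(f"g{i}" for i in range(50))
sets = [
    GeneSet("DNA_REPAIR", frozenset(f"g{i}" for i in range(0, 12))),
    GeneSet("DNA_REPAIR_COPY", frozenset(f"g{i}" for i in range(0, 11))),
    GeneSet("DNA_DAMAGE", frozenset(f"g{i}" for i in range(2, 13))),
    GeneSet("TRANSPORT", frozenset(f"g{i}" for i in range(30, 40))),
]
coll = GeneSetCollection(sets=sets, universe=universe)

print("pairwise kappa:")
for a in sets:
    for b in sets:
        if a.name < b.name:
            print(f"  {a.name:>16} vs {b.name:<16} kappa = {kappa(a, b, universe):+.3f}")

reduced = cluster_representatives(coll, threshold=0.5)
print(f"\n{len(coll)} sets -> {len(reduced)} representatives:")
for name, rep in sorted(reduced.representative_of.items()):
    print(f"  {name} -> {rep}")
print("\nKappa near 1 marks near-duplicate sets; the three DNA sets collapse")
print("to one representative while the disjoint transport set survives.")
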