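"""Infer afferent tuning from a synapse graph and audit direction matching.

Simulates a hair-cell → afferent → projection-neuron graph with coherent
wiring, computes each utricular afferent's synapse-weighted vector-sum
tuning, and checks that canal and utricular inputs onto every projection
neuron agree on vertical direction.
"""

from tipm.connectome import afferent_tuning, projection_inputs, tuning_match
from tipm.simulate import ConnectomeConfig, simulate_connectome

graph = simulate_connectome(ConnectomeConfig(seed=5))
print(f"{len(graph.hair_cells)} hair cells, {len(graph.afferents)} afferents, "
      f"{len(graph.projection_neurons)} projection neurons, {len(graph.edges)} edges")

for aff in graph.afferents:
    if aff.end_organ == "utricle":
        t = afferent_tuning(aff.id, graph)
        print(f"  {aff.id}: class={t.vertical_class}, weight={t.magnitude:.0f}, "
              f"direction z-component={t.direction[2]:+.2f}")

summary, fraction = tuning_match(graph, convention="results")
print(f"canal-utricular direction match: {fraction:.2f} "
      f"({int(summary['match'].count())} neurons with both inputs)")
# With coherent wiring every canal-innervated neuron's utricular tuning
# points the same vertical way as its canal identity implies: fraction 1.0.
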