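"""Apo-vs-ligand difference map and widest-path pathway extraction.

Simulates a 'ligand-bound' condition in which an interface contact
(A:2–B:2) becomes much more persistent than in the 'apo' condition, builds
the thresholded difference map (both noise floors at 10%), then ranks
source→target routes through the high-persistence contact network by
bottleneck persistence.
"""
import amparkit as ak

cfg = ak.RunConfig(exclude_time=0.0, stride_time=100.0)

def condition(p_gained, seed):
    specs = [
        ak.PairDynamicsSpec(pair=(("A", 1), ("B", 1)), stationary_p=0.9,
                            k_switch=0.05),
        ak.PairDynamicsSpec(pair=(("A", 2), ("B", 2)), stationary_p=p_gained,
                            k_switch=0.05),
    ]
    system, _ = ak.simulate_contact_trajectory(specs, n_frames=3000,
                                               frame_dt=100, seed=seed)
    return ak.contact_persistence(system, "chain A", "chain B", cfg,
                                  interface=("chainA", "chainB"))

map_apo = condition(p_gained=0.05, seed=1)
map_lig = condition(p_gained=0.75, seed=2)

dmap = ak.difference_map(map_lig, map_apo, persistence_floor=0.10,
                         delta_floor=0.10)
print("retained pairs after the dual 10% floors:")
for (ra, rb), (p_apo, p_lig, delta) in sorted(dmap.entries.items()):
    print(f"  {ra[0]}:{ra[1]} - {rb[0]}:{rb[1]}  apo={p_apo:.3f} "
          f"ligand={p_lig:.3f}  delta={delta:+.3f}")
print("(the stable A:1-B:1 contact changes little and is filtered out;\n"
      " the ligand-gained A:2-B:2 contact survives both floors)\n")

graph = ak.build_pathway_graph([map_lig], edge_threshold=0.5,
                               sources=[("A", 1)], targets=[("B", 1)])
for path in ak.find_pathways(graph, k=3):
    route = " -> ".join(f"{c}:{r}" for c, r, _ in path.residues)
    print(f"pathway {route}  bottleneck persistence {path.bottleneck:.3f}")
print("the bottleneck is the weakest contact on the route: the higher it "
      "is, the more stable the candidate allosteric pathway.")
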