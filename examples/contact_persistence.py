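"""Contact persistence on a synthetic trajectory with planted occupancies.

Builds a toy two-chain system in which residue pair A:1–B:1 occupies a
contact 80% of the time and A:2–B:2 30% of the time (two-state Markov
dynamics), then recomputes the occupancies from the coordinates with the
4 Å heavy-atom contact statistic.
"""
import amparkit as ak

specs = [
    ak.PairDynamicsSpec(pair=(("A", 1), ("B", 1)), stationary_p=0.8,
                        k_switch=0.05),
    ak.PairDynamicsSpec(pair=(("A", 2), ("B", 2)), stationary_p=0.3,
                        k_switch=0.05),
]
system, truth = ak.simulate_contact_trajectory(specs, n_frames=4000,
                                               frame_dt=100, seed=42)

cfg = ak.RunConfig(contact_cutoff=4.0, exclude_time=0.0, stride_time=100.0)
cmap = ak.contact_persistence(system, "chain A", "chain B", cfg)

print("pair                measured   planted   realised")
for spec in specs:
    (ca, ra), (cb, rb) = spec.pair
    measured = cmap.entries[((ca, ra, "ALA"), (cb, rb, "ALA"))]
    realised = truth[spec.pair].mean()
    print(f"{ca}:{ra} - {cb}:{rb}        {measured:8.4f}  {spec.stationary_p:8.2f}"
          f"  {realised:9.4f}")
print(f"\n{cmap.n_frames_used} frames analysed; 'measured' is the fraction of "
      "frames with any heavy-atom pair closer than 4 Å — it matches the "
      "realised Markov-chain occupancy exactly and the planted stationary "
      "value within sampling error.")
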