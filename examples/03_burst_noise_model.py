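"""Non-bursting activity as background noise: the HMM pipeline end to end.

Generates the burst-gated fixture (two channels coupled only through burst
co-occurrence), then runs decomposition -> AEC -> per-node two-state HMM ->
coincident non-bursting noise statistics -> renormalization, and prints the
three spectrum variants.
"""
from envren import end_to_end_pipeline, fixture_generator

rec, manifest = fixture_generator("burst_gated", master_seed=0)
print(f"fixture: {manifest['scenario']}, burst fraction "
      f"{manifest['burst_fraction']:.2f}, coupling {manifest['coupling']}\n")

frame = end_to_end_pipeline(rec, centers_hz=[4.0, 10.0, 16.0, 22.0],
                            bandwidth_hz=2.0, seed=0, orthogonalize=False)
print(frame.pivot_table(index="center_hz", columns="variant",
                        values="value").round(3))
print("\nRaw AEC peaks at 10 Hz (burst co-occurrence); non-bursting AEC is "
      "flat near zero\n(non-bursting oscillations carry no amplitude "
      "coupling), so they provide the\nbackground-noise moments that the "
      "renormalization uses to level the estimate up.")
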