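"""Build the cube set and the paired-lifting trial design.

The study design uses 15 cubes in three subsets sharing one middle cube:
seven equal-density cubes, five equal-weight (size-weight illusion) cubes and
five cubes of increasing density.  Every unordered pair is lifted, pairs
containing the shared middle cube three times, and each pairing is presented
in both left/right orders.
"""

from weightsense.stimuli import build_stimulus_set, build_trial_list, enumerate_pairs

cubes = build_stimulus_set()
print(f"{len(cubes)} cubes:")
for c in cubes:
    print(
        f"  {c.cube_id:>4}  {c.volume:6.0f} cm^3  {c.weight:6.1f} g"
        f"  {c.density:.3f} g/cm^3  ({c.subset})"
    )

pairs = enumerate_pairs(cubes)
print(f"\n{len(pairs)} unique pairs")  # 105

trials = build_trial_list(pairs, middle_id="M750", seed=0)
print(f"{len(trials)} trials per participant "  # 266
      f"({dict(trials['session'].value_counts().sort_index())} per session)")
print("\nfirst three trials:")
print(trials.head(3).to_string(index=False))
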