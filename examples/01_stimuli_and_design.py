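"""Build the looming stimuli and the block/run/target timeline.

The visual looming stimulus is a 500 ms sequence of radially expanding
annuli (one new annulus every 125 ms); the auditory one is a 14-tone
mixture rising exponentially in amplitude and linearly in frequency.
Blocks of 50 stimuli (660 ms onset asynchrony) fill a 33 s activation
block; 18 blocks per run, 3 per condition, 4 runs over 2 days.
"""

from lamfmri.design import (auditory_looming_trajectories, build_run_design,
                            events_table, schedule_targets,
                            visual_annulus_trajectories)

annuli = visual_annulus_trajectories()
print(f"annuli per stimulus: {len(annuli)} "
      f"(onsets {[t.onset_ms for t in annuli]} ms)")
print(f"each annulus expands 0.25->3.88 deg in {annuli[0].lifetime_s:.4f} s")

t440 = next(t for t in auditory_looming_trajectories() if t.base_hz == 440.0)
print(f"440 Hz tone ramps to {t440.frequency(0.5):.2f} Hz; "
      f"amplitude(0.5 s) = {t440.amplitude(0.5):.4f} x baseline units")

design = build_run_design(rng_seed=0)
print(f"blocks per run: {len(design.run_blocks(1))}, "
      f"stimuli per block: {design.params.stimuli_per_block}, "
      f"run duration: {design.params.run_duration_s:.0f} s")

schedule = schedule_targets(design, rng_seed=1)
totals = schedule.per_condition_totals()
print("targets per condition x modality (all 16 by construction):")
print(totals)

print("\nfirst events of run 1 (BIDS-style):")
print(events_table(design, run=1, schedule=schedule).head(6).to_string())
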