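"""Segment a hypnogram into bouts, split REM by duration, score latency.

A bout is a maximal run of same-state epochs.  REM bouts of at most 4
epochs (16 s) are relabelled REMS_S, longer ones REMS_L.  NREM latency is
the time from drug administration to the first non-REM episode with at
least 3 min of NREM content, tolerating interruptions of up to 14
consecutive epochs and 240 s in total.
"""

import sleepbouts as sb

cfg = sb.default_config(seed=1)
h = sb.simulate_hypnogram(cfg, "rat1", "VEH")

bouts = sb.segment_bouts(h)
split = sb.reclassify_rems(bouts)
bins = sb.bin_bouts(split)

print(f"{h.subject_id}/{h.treatment}: {len(bouts)} bouts in {h.n_epochs} epochs")
n_s = sum(b.state == "REMS_S" for b in split)
n_l = sum(b.state == "REMS_L" for b in split)
print(f"REM bouts: {n_s} short (<=16 s) and {n_l} long")
for k in range(3):
    n = sum(1 for b in bins if b == k)
    print(f"  hour {k + 1}: {n} bout onsets")

lat = sb.nrem_latency(h)
print("NREM latency:", "not reached" if lat is None else f"{lat:.0f} s")
# The latency is the onset of the first sustained NREM episode; short
# wake intrusions within the episode do not reset the clock.
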