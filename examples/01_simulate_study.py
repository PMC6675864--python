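"""Simulate a sleep study and write it as an epoch-scored hypnogram CSV.

Six rats, three treatments (vehicle plus two dose levels), three hours of
4-s epochs each.  State succession follows a per-hour embedded transition
matrix; bout lengths follow spike-and-slab geometric mixtures shared
across treatments, so any treatment contrast comes from transition
frequencies alone.
"""

from pathlib import Path

import sleepbouts as sb

cfg = sb.default_config(seed=1)
study = sb.simulate_study(cfg)

out = Path("scratch_examples")
out.mkdir(exist_ok=True)
sb.write_hypnogram(study, out / "study.csv")

h = study[0]
print(f"simulated {len(study)} hypnograms "
      f"({cfg.n_subjects} subjects x {len(cfg.treatments)} treatments)")
print(f"each {h.n_epochs} epochs of {h.epoch_seconds:.0f} s "
      f"= {h.duration_s / 3600:.1f} h")
print(f"first 10 epochs of {h.subject_id}/{h.treatment}:",
      " ".join(h.states[:10]))
print(f"wrote {out / 'study.csv'}")
# Each row of the CSV is one 4-s epoch with its vigilance-state label;
# read_hypnogram() recovers the identical objects.
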