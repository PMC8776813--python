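"""Simulate one synthetic subject and inspect the experiment design.

Generates a reduced recording (48 trials instead of the full 416 to
keep this example quick), prints the trial bookkeeping and the planted
signal levels.  The full-scale defaults reproduce the study design:
12 subjects, 416 trials (208 active), 128 channels at 1024 Hz.
"""

import numpy as np

import topodecode as td

config = td.SimulationConfig(n_trials=48, n_active=24, inter_trial_gap=2.0)
rec = td.simulate_subject(config, "S01", seed=1, store_clean=True)

print(f"subject {rec.subject_id}: {rec.n_channels} channels, "
      f"{rec.n_samples / rec.sampling_rate:.0f} s at {rec.sampling_rate:.0f} Hz")
print("trials by mode:     ", rec.events["mode"].value_counts().to_dict())
print("active by direction:",
      rec.events.loc[rec.events['mode'] == 'active', 'direction']
      .value_counts().to_dict())
rt = rec.events["true_rt"]
print(f"reaction times: median {rt.median():.3f} s, "
      f"range {rt.min():.3f}-{rt.max():.3f} s")
print(f"EEG amplitude: background RMS {np.std(rec.eeg - rec.clean_eeg):.1f} uV, "
      f"planted MRCP peak {rec.clean_eeg.min():.1f} uV")
# The mode/direction counts are balanced by design; the planted peak is
# negative (a movement-related cortical potential) and smaller than the
# noise floor, so single trials are noisy but averages are clean.
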