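"""From a raw trial to the 16-dimensional feature matrix.

One recording is bandpass-filtered (Butterworth, 20-500 Hz), trimmed
to its valid interval, cut into 400 ms windows every 50 ms, and each
window is reduced to RMS, waveform length, zero crossings and
slope-sign changes per channel.
"""

import semgbench as sb
from semgbench.features import FEATURE_COLUMNS, extract
from semgbench.preprocessing import preprocess

subject = sb.make_subjects(1, seed=0)[0]
rec = sb.generate_recording(
    subject, "WF", sb.ConditionKey("A", "a", 45), 1, sb.GeneratorConfig(seed=0)
)

windows = preprocess(rec)  # bandpass -> trim to [1 s, 4 s) -> segment
print(f"{len(windows)} windows of {windows[0].n_samples} samples "
      f"(400 ms at 2000 Hz, 50 ms step over 3 s of valid data)")

features = extract(windows, eps=20.0)
print("\nfirst rows of the feature matrix (16 features + label):")
print(features[FEATURE_COLUMNS[:4] + ["gesture"]].head().round(1).to_string())
print()
print("CH1_RMS/WL are amplitude measures in signal units; CH1_ZC/SSC are")
print("integer counts of thresholded sign/slope changes (threshold 20 units)")
print("acting as crude frequency-content proxies.")
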