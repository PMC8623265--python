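"""Train the two classifiers on a same-condition gesture decoding task.

Generates two recording groups of all 12 gestures at one condition,
trains LDA (scatter-matrix projection) and PNN (Gaussian-kernel
exemplar classifier) on one group and decodes the other, window by
window, over the 11 analyzed gestures.
"""

import semgbench as sb

subject = sb.make_subjects(1, seed=1)[0]
key = sb.ConditionKey("A", "a", 45)
config = sb.GeneratorConfig(seed=1, n_groups=2)

registry = sb.DatasetRegistry()
profiles = sb.default_profiles()
for group in (1, 2):
    for gesture in sb.ALL_GESTURES:
        registry.add(
            sb.generate_recording(subject, gesture, key, group, config, profiles=profiles)
        )

features = sb.featurize_registry(registry)
for model_type in ("lda", "pnn"):
    result = sb.run_pairing(features, [key], key, model_type, n_rep=2, seed=1)
    print(f"{model_type.upper()}: same-condition decoding accuracy "
          f"{result.mean_accuracy:.3f} +- {result.sd_accuracy:.3f} "
          f"({len(result.records)} repetitions)")
print()
print("Accuracy is the fraction of 400 ms windows assigned the correct of")
print("11 gestures; train and test never share a recording group.")
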