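"""Simulate single trials on an untrained vs a trained network.

Builds the immature network, trains it briefly under the typical-development
diet, and compares multisensory responses to auditory-alone, visual-alone and
congruent audiovisual stimulation of the same phoneme.
"""

import numpy as np

import msinet as M

config = M.ModelConfig()
rng = np.random.default_rng(0)

print("Training 1,500 exposures (3 simulated years) of the TD diet ...")
result = M.train(
    config, M.make_schedule("TD", total_epochs=1500), checkpoints=[], rng=rng
)
immature = M.build_network(config)
young = result.network

for label, net in [("untrained", immature), ("after 3 years", young)]:
    print(f"\n--- {label} network, phoneme 50, auditory efficacy 5 ---")
    for condition in ("A", "V", "AV"):
        trial = M.make_trial(condition, 50, 5, config.space, config.stimulus)
        record = M.simulate_trial(net, trial, np.random.default_rng(1))
        peak = record.max_activity("multisensory").max()
        r = M.recognize(record, 50, config.readout)
        print(
            f"{condition:>3}: peak multisensory activity {peak:.2f} | "
            f"detected={r.detected} recognized={r.recognized_phoneme} "
            f"correct={r.correct}"
        )

print(
    "\nThe multisensory layer reads out the phoneme as the barycenter of its\n"
    "suprathreshold activity (threshold 0.3). Before training nothing crosses\n"
    "threshold; with maturing feedforward weights the audiovisual condition\n"
    "crosses first (multisensory enhancement)."
)
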