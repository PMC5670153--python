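"""The McGurk illusion across development.

Pairs each auditory phoneme with a visual phoneme shifted 4 positions and
classifies the network's percept (correct auditory / fusion / visual capture)
at three developmental stages of the typical-development network.
"""

import numpy as np

import msinet as M

config = M.ModelConfig()
rng = np.random.default_rng(3)

print("Training the TD network with checkpoints at 5, 10 and 17 years ...")
result = M.train(
    config, M.make_schedule("TD"), checkpoints=[2500, 5000, 8500], rng=rng, progress=True
)

for epoch in (2500, 5000, 8500):
    battery = M.mcgurk_battery(
        result.checkpoints[epoch], config, np.random.default_rng(100 + epoch), reps=5
    )
    pct = {k: round(v, 1) for k, v in battery.pct.items()}
    print(
        f"age {M.epoch_to_age(epoch):4.0f} y: {pct} "
        f"(detected {battery.n_detected}/{battery.n_trials})"
    )

print(
    "\nPercentages are over detected trials. With maturation the cross-sensory\n"
    "and visual feedforward projections strengthen, so the shifted visual\n"
    "input increasingly drags the percept away from the auditory phoneme:\n"
    "correct-auditory responses fall and fusion percepts (between the two\n"
    "inputs) dominate the adult network."
)
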