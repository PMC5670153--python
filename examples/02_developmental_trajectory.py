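"""Developmental trajectory of speech-recognition accuracy.

Runs a full typical-development training (8,500 exposures = 17 simulated
years; 500 exposures per year) with small checkpoint batteries and prints the
accuracy trajectory for auditory-alone (A), visual-alone (V) and audiovisual
(AV) stimulation, plus the multisensory gain AV - A.
"""

import msinet as M

run = M.RunConfig(
    schedule_kind="TD",
    checkpoints=tuple(range(0, 8501, 1000)),
    battery=M.BatteryConfig.fast(),
    seed=1,
)
print("Running TD development (a few minutes) ...")
traj = M.run_development(run, progress=True)

cols = ["epoch", "age_years", "pct_A", "pct_V", "pct_AV", "gain", "sum_sa", "sum_sv"]
print(traj.table[cols].round(1).to_string(index=False))

print(
    "\npct_* are % correct recognitions averaged over the 7 auditory efficacy\n"
    "levels (visual efficacy is constant). The audiovisual condition becomes\n"
    "competent first (combined feedforward drive crosses the detection\n"
    "threshold earliest), auditory-alone accuracy matures by ~10 simulated\n"
    "years, and visual-alone recognition stays poor throughout\n"
    "(sum_sa / sum_sv are the summed feedforward weights)."
)
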