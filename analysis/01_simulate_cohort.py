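"""Generate the synthetic study cohort.

Creates 7 AMI-archetype and 7 CTL-archetype subjects (coupled vs
decoupled residual muscle mechanics), one gait trial per condition each,
and writes the trial files plus the subject manifest under results/.
"""

import json
import sys
from pathlib import Path

from bionicgait import io as bg_io
from bionicgait import synth

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    trial_dir = OUT / "trials"
    trial_dir.mkdir(parents=True, exist_ok=True)
    subjects = synth.generate_cohort_trials(n_per_group=7, noise_sd=0.02,
                                            seed=SEED)
    manifest = []
    for s in subjects:
        for cond, tr in s["trials"].items():
            bg_io.write_trial(tr, trial_dir / f"{s['subject']}_{cond}.csv")
        manifest.append({"subject": s["subject"], "group": s["group"],
                         "afferent_target_imp_s": s["afferent"]})
    with open(OUT / "subjects.json", "w") as fh:
        json.dump({"seed": SEED, "subjects": manifest}, fh, indent=2)
    n_trials = len(subjects) * len(synth.CONDITIONS)
    print(f"simulated {len(subjects)} subjects x {len(synth.CONDITIONS)} "
          f"conditions = {n_trials} trials (seed {SEED}) -> {trial_dir}")


if __name__ == "__main__":
    main()
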