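"""Simulate the 1120-compound screen: hypoxia-recovery arm plus normoxia
counter-screen, with planted hits and stress-independent inducers.

Run from the repository root:  python analysis/04_simulate_screen.py
"""

from pathlib import Path

import numpy as np

from sgquant.simulate import PlateSpec, generate_screen_plate, save_plate

OUT = Path("results/screen")
SEED = 20260921

N_DRUGS = 1120
N_CONTROLS = 96
N_HITS = 50  # drugs that genuinely retain granules post-hypoxia
N_INDUCERS = 9  # drugs that induce granules without stress (to be excluded)
HIT_EFFECT = 4.0  # effect size in control-SD units


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=SEED, spawn_key=(99,)))
    picks = rng.choice(np.arange(1, N_DRUGS + 1), size=N_HITS + N_INDUCERS, replace=False)
    spec = PlateSpec(
        n_drugs=N_DRUGS,
        n_control_wells=N_CONTROLS,
        hit_indices=frozenset(int(i) for i in picks[:N_HITS]),
        hit_effect=HIT_EFFECT,
        normoxia_inducer_indices=frozenset(int(i) for i in picks[N_HITS:]),
        seed=SEED,
    )
    for arm, name in (("hypoxia-recovery", "plate_hypoxia.csv"), ("normoxia", "plate_normoxia.csv")):
        plate = generate_screen_plate(spec, arm=arm)
        save_plate(plate, OUT / name)
        n_elevated = int(plate["is_true_hit"].sum() if arm == "hypoxia-recovery" else plate["is_normoxia_inducer"].sum())
        print(f"{name}: {N_DRUGS} drug wells, {N_CONTROLS} controls, "
              f"{n_elevated} wells with a planted effect in this arm")


if __name__ == "__main__":
    main()
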