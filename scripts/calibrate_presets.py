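"""One-off calibration of preset effect sizes.

Sweeps the effect size d and reports the mean single-modality LOOCV
accuracy (19 + 19 subjects) for the two preset geometries, so that the
constants in ``kernelfuse.synthetic.CALIBRATED_EFFECT`` hit the target
solo-accuracy band (~65-75%).  Run from the repository root:

    python scripts/calibrate_presets.py
"""

import numpy as np

from kernelfuse import KernelSVC, generate, loocv_dataset
from kernelfuse.synthetic import ModalitySpec, SyntheticConfig

N_SEEDS = 10


def solo_accuracy(p, d, seeds=range(N_SEEDS)):
    accs = []
    for seed in seeds:
        cfg = SyntheticConfig(
            n_per_class=19,
            modalities=(ModalitySpec("m", p, informative_fraction=0.1, effect_size=d),),
            redundancy=0.0,
            seed=seed,
        )
        accs.append(loocv_dataset(KernelSVC(), generate(cfg)).accuracy)
    return float(np.mean(accs)), float(np.std(accs))


if __name__ == "__main__":
    for label, p in (("small (p=400)", 400), ("paper-scale (p=4000)", 4000)):
        print(f"== {label} ==")
        for d in (0.5, 0.65, 0.75, 0.85, 1.0, 1.2):
            mean, sd = solo_accuracy(p, d)
            print(f"  d={d:4.2f}: mean LOOCV accuracy {100 * mean:5.1f}% (sd {100 * sd:4.1f})")
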