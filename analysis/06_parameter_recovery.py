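#!/usr/bin/env python
"""Does the fitting machinery recover known kinetic constants?

Validation of the refitting loop used throughout: simulate noisy total-KinA
dose-response data from the reference model, perturb one fitted constant
(2x off), and refit it by minimizing the mean relative distance.

Finding: with 5% multiplicative observation noise the KinA translation rate
is recovered with a median relative error of a few percent; a noiseless
refit recovers it to <1%.  Structurally non-identifiable combinations (the
Spo0B synthesis rates tr4 x tl4) are recovered only as a product — see
tests/test_synthetic.py for the explicit demonstration.
"""

from pathlib import Path

import numpy as np

import spornet as sn

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    model = sn.build_reference_network()

    clean = sn.parameter_recovery_study(
        model, ["tl2.k"], cv=0.0, n_seeds=1, seed=0,
        grid=np.linspace(0.0, 20.0, 6),
    )
    print(f"noiseless refit of tl2.k: relative error "
          f"{100*clean.rel_error.iloc[0]:.3f}%")

    noisy = sn.parameter_recovery_study(model, ["tl2.k"], cv=0.05, n_seeds=20, seed=0)
    noisy.to_csv(OUT / "parameter_recovery.csv", index=False)
    print(f"cv=0.05, 20 replicates: median relative error "
          f"{100*noisy.rel_error.median():.2f}%, "
          f"worst {100*noisy.rel_error.max():.2f}%")
    print(f"replicates converged: {int(noisy.converged.sum())}/20")


if __name__ == "__main__":
    main()
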