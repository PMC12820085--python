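#!/usr/bin/env python
"""Hook bending stiffness from orientation-angle fluctuations.

Evaluates the equipartition estimate EI = k_B T L_hook / sigma^2 at the
measured angle spreads of the wrapper (sigma = 0.038 rad) and non-wrapper
(sigma = 0.018 rad) species, compares them, and validates the estimator
end-to-end by recovering a known stiffness from a generated
Ornstein-Uhlenbeck trace.  Writes results/hook/estimates.json.

What it finds: the wrapper's hook is ~4.5x softer than the non-wrapper's,
and the estimator recovers a known ground-truth stiffness within a few
percent from 1e5 samples at 5 ms resolution.
"""

import sys
from pathlib import Path

from flagwrap import io
from flagwrap.hook_stiffness import (SPECIES_SIGMA, compare_species,
                                     estimate_hook_stiffness,
                                     hook_stiffness_from_sigma)
from flagwrap.synthetic import gen_angle_trace

OUT = Path(__file__).resolve().parents[1] / "results" / "hook"


def main(seed=0):
    OUT.mkdir(parents=True, exist_ok=True)
    ests = {name: hook_stiffness_from_sigma(sig, label=name)
            for name, (sig, _) in SPECIES_SIGMA.items()}
    for name, est in ests.items():
        print(f"{name}: sigma={est.sigma} rad -> EI = {est.EI:.3e} N m^2, "
              f"A_hook = {est.A_hook:.3e} N m^2")
    ratios = compare_species(list(ests.values()))
    print(f"stiffness ratio (stiffer/softer): "
          f"{ratios.loc[0, 'EI_ratio']:.2f}")

    EI_true = 1.71e-25
    trace = gen_angle_trace(EI_true, n=100_000, seed=int(seed))
    rec = estimate_hook_stiffness(trace, seed=int(seed))
    print(f"round trip: EI_true = {EI_true:.2e}, EI_est = {rec.EI:.3e} "
          f"({rec.EI / EI_true - 1:+.1%})")

    io.write_json(OUT / "estimates.json", {
        "species": {n: {"sigma_rad": e.sigma, "EI_Nm2": e.EI,
                        "A_hook_Nm2": e.A_hook} for n, e in ests.items()},
        "EI_ratio_stiffer_over_softer": float(ratios.loc[0, "EI_ratio"]),
        "round_trip": {"EI_true_Nm2": EI_true, "EI_est_Nm2": rec.EI,
                       "rel_error": rec.EI / EI_true - 1,
                       "n_samples": rec.n_samples},
        "metadata": io.run_metadata({"seed": int(seed)}, int(seed)),
    })


if __name__ == "__main__":
    main(*(sys.argv[1:] or []))
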