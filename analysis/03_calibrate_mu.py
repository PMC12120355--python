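"""Monitor-unit calibration in the water phantom.

Simulates the clinical calibration conditions (30x30x50 cm water, SSD
100 cm, 10x10 cm field, 6 MV) and derives the number of source particles per
monitor unit from N = 1 cGy / D_d, with D_d the per-particle dose at 1.5 cm
depth on the beam axis.  All physical (Gy-scale) results downstream multiply
per-particle values by N and the beam MU.
"""

import argparse
import json
from pathlib import Path

import cherensim as cs
from cherensim.analysis import scale_to_physical


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--photons", type=int, default=100_000)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/calibration.json"))
    args = ap.parse_args()
    args.out.parent.mkdir(parents=True, exist_ok=True)

    run = cs.run_water_calibration(n_photons=args.photons, seed=args.seed)
    cal = run.calibration
    check_cgy = scale_to_physical(cal.dose_per_particle_gy, cal, 1.0) * 100.0

    print(f"simulated {args.photons} photons (seed {args.seed})")
    print(f"D_d (1.5 cm depth, on axis): {cal.dose_per_particle_gy:.3e} Gy/particle")
    print(f"N = 1 cGy / D_d = {cal.particles_per_mu:.3e} particles/MU")
    print(f"check: dose per 1 MU at the calibration point = {check_cgy:.6f} cGy")

    args.out.write_text(json.dumps({
        "n_photons": args.photons,
        "seed": args.seed,
        "dose_per_particle_gy": cal.dose_per_particle_gy,
        "particles_per_mu": cal.particles_per_mu,
        "dose_per_mu_cgy": check_cgy,
    }, indent=2))
    print(f"written to {args.out}")


if __name__ == "__main__":
    main()
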