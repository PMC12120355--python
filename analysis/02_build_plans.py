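"""Build the default IMRT (2 fixed beams) and VMAT (2 arcs) treatment plans.

The shipped defaults carry the published per-beam characteristics: IMRT
beams at gantry 90 deg (157.5 MU, 8 control points) and 278 deg (155.1 MU,
10 control points); VMAT arcs 100->260 deg CCW (360.7 MU) and 260->100 deg
CW (306.6 MU) with 114 control points each.  Plans are written as YAML.
"""

import argparse
from pathlib import Path

import cherensim as cs
from cherensim.plan import plan_to_yaml


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results/plans"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    for name, plan in (("imrt", cs.default_imrt_plan()), ("vmat", cs.default_vmat_plan())):
        plan_to_yaml(plan, args.out / f"{name}.yaml")
        print(f"{plan.modality}: {len(plan.beams)} beams/arcs, "
              f"total {plan.total_mu:.1f} MU over {plan.fractions} fractions")
        for i, cps in enumerate(plan.beams):
            angles = [cp.gantry_angle for cp in cps]
            mu = sum(cp.mu_weight for cp in cps)
            span = (f"{angles[0]:.0f} deg" if len(set(angles)) == 1
                    else f"{angles[0]:.0f} to {angles[-1]:.0f} deg")
            print(f"  beam {i + 1}: {len(cps)} CPs, {mu:.1f} MU, gantry {span}")
    print(f"plans written to {args.out}/")


if __name__ == "__main__":
    main()
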