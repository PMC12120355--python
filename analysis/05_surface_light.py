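"""Surface light maps and spectra from the simulated treatment runs.

For each persisted run: per-beam surface intensity maps (full 500-1200 nm
band with the 5% threshold and 710-720 nm band with the 10% threshold, both
median filtered), the tumor-born-only map, and peak-normalized spectra of
the emitted light, all surface light, and light on the tumor spot.
Writes CSV tables and PNG figures under results/surface/.
"""

import argparse
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

import cherensim as cs
from cherensim import io
from cherensim.analysis import (
    FULL_BAND_NM,
    NARROW_BAND_NM,
    compute_spectrum,
    identify_tumor_spot,
    surface_intensity_map,
)
from cherensim.phantom import compact_neck_geometry


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--runs", type=Path, default=Path("results/runs"))
    ap.add_argument("--out", type=Path, default=Path("results/surface"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    grid = cs.generate_neck_phantom(compact_neck_geometry(), seed=101)
    mesh = cs.extract_surface_mesh(grid)

    for run_path in sorted(args.runs.glob("*.h5")):
        name = run_path.stem
        run = io.load_run_arrays(run_path)
        exits = io.concatenate_exits([b["exits"] for b in run["beams"]])
        print(f"{name.upper()}: {len(exits)} surface exits")

        for band, tag in ((FULL_BAND_NM, "full"), (NARROW_BAND_NM, "710-720nm")):
            m = surface_intensity_map(exits, mesh, band_nm=band, median_filter=True)
            io.export_surface_map_csv(m, args.out / f"{name}_map_{tag}.csv")
            n_kept = int((m.values > 0).sum())
            print(f"  {tag} band map: {n_kept} elements above the "
                  f"{m.threshold_fraction:.0%} threshold")

        tumor_exits = exits.subset(exits.born_in_tumor.astype(bool))
        m_tum = surface_intensity_map(tumor_exits, mesh, band_nm=FULL_BAND_NM,
                                      median_filter=True)
        io.export_surface_map_csv(m_tum, args.out / f"{name}_map_tumor_born.csv")

        spot = identify_tumor_spot(exits, mesh)
        spot_exits = exits.subset(spot.contains(exits.element_id))
        print(f"  tumor spot: {len(spot)} elements, "
              f"{int(spot.contains(tumor_exits.element_id).sum())} tumor-born exits on it")

        fig, ax = plt.subplots(figsize=(6, 4))
        specs = {
            "surface (all)": compute_spectrum(exits.wavelength),
            "surface (tumor spot)": compute_spectrum(spot_exits.wavelength),
        }
        emitted_lam = [b["emitted_wavelength_nm"] for b in run["beams"]
                       if b.get("emitted_wavelength_nm") is not None]
        if emitted_lam:
            specs["emitted (volume)"] = compute_spectrum(np.concatenate(emitted_lam))
        for label, s in specs.items():
            ax.plot(s.bin_centers_nm, s.intensity, label=label)
            io.export_spectrum_csv(
                s, args.out / f"{name}_spectrum_{label.split('(')[1][:-1].replace(' ', '_')}.csv")
        ax.set_xlabel("wavelength (nm)")
        ax.set_ylabel("normalized intensity")
        ax.legend()
        fig.tight_layout()
        fig.savefig(args.out / f"{name}_spectra.png", dpi=150)
        plt.close(fig)

        nir = float((exits.wavelength > 650).mean())
        print(f"  surface light above 650 nm: {nir:.0%} of photons "
              f"(near-infrared dominant)" )


if __name__ == "__main__":
    main()
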