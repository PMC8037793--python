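"""Steady packing-density sweep on the idealized coiled-dome geometry.

Solves the porous-dome flow at first-coil packing densities 0-30 % on the
2D side-wall geometry, tabulates neck velocity, wall shear stresses, dome
pressure and the residual-flow-volume fraction, and characterizes the
curve shapes (steepest-descent interval, monotone tail, asymptote).  Also
re-characterizes the published patient-specific sweep for comparison.

Writes results/vpd_sweep.csv and results/vpd_sweep_shapes.csv.  Takes a
few minutes at the default 7-point sweep; pass --fine for the full
0-30 % range in 1 % steps (slow).
"""

import argparse
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from porocoil.domain import DomainSpec, build_domain
from porocoil.metrics import characterize_curve, vpd_sweep
from porocoil.reference import reference_sweep
from porocoil.rheology import BloodModel

OUT = Path(__file__).resolve().parents[1] / "results"
D = 3.0e-3


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--fine", action="store_true", help="1 %% VPD steps")
    args = parser.parse_args()

    spec = DomainSpec(
        parent_diameter=D, parent_length=8 * D, dome_radius=2.5e-3,
        neck_width=3.0e-3, grid_spacing=D / 16,
    )
    domain = build_domain(spec)
    blood = BloodModel()
    vpd_values = list(range(0, 31)) if args.fine else [0, 5, 10, 15, 20, 25, 30]
    table, rows, _ = vpd_sweep(
        domain, blood, vpd_values, inflow_velocity=0.35, tol=2e-6, max_iter=8000
    )
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "vpd_sweep.csv", index=False)
    print(table.round(4).to_string(index=False))

    shapes = []
    for source, frame in [("idealized", table), ("published", reference_sweep())]:
        for col in ("wss_aneurysm", "rfv_av_pct", "pressure_aneurysm"):
            shapes.append({"source": source, **asdict(characterize_curve(frame, col))})
    pd.DataFrame(shapes).to_csv(OUT / "vpd_sweep_shapes.csv", index=False)

    own = characterize_curve(table, "wss_aneurysm")
    ref = characterize_curve(reference_sweep(), "rfv_av_pct")
    print(
        f"\ndome WSS: steepest drop over {own.steepest_interval} % VPD, "
        f"asymptote={own.asymptote_flag} -- the first coil does most of the "
        "shear-stress reduction.\n"
        f"published RFV/AV: steepest descent over {ref.steepest_interval} % VPD "
        "(the sigmoid mid-range that motivates packing beyond ~10 %)."
    )


if __name__ == "__main__":
    main()
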