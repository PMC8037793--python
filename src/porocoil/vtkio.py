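"""Legacy-ASCII VTK output of flow fields.

Writes the solved fields as a VTK structured-points dataset (cell data:
velocity vector, pressure, viscosity, cell role) readable by ParaView and
VisIt.  The legacy ASCII format is used for maximal reader compatibility.
"""

from __future__ import annotations


from .domain import Domain
from .solver import FlowField


def write_vtk(path, field: FlowField, domain: Domain, title: str = "porocoil field") -> None:
    nx, ny, h = domain.nx, domain.ny, domain.h
    uc = 0.5 * (field.u[1:, :] + field.u[:-1, :])
    vc = 0.5 * (field.v[:, 1:] + field.v[:, :-1])
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{title}\n")
        fh.write("ASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx + 1} {ny + 1} 1\n")
        fh.write("ORIGIN 0 0 0\n")
        fh.write(f"SPACING {h} {h} {h}\n")
        fh.write(f"CELL_DATA {nx * ny}\n")

        fh.write("VECTORS velocity float\n")
        for j in range(ny):
            for i in range(nx):
                fh.write(f"{uc[i, j]:.6e} {vc[i, j]:.6e} 0.0\n")

        for name, arr in (
            ("pressure", field.p),
            ("viscosity", field.mu),
            ("cell_role", domain.role.astype(float)),
        ):
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            for j in range(ny):
                for i in range(nx):
                    fh.write(f"{arr[i, j]:.6e}\n")
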