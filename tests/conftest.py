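import numpy as np
import pytest

from porocoil.domain import DomainSpec, build_domain
from porocoil.rheology import BloodModel, ergun_coefficients
from porocoil.solver import ProjectionSolver

D_PARENT = 3.0e-3  # m


@pytest.fixture(scope="session")
def blood():
    return BloodModel()


@pytest.fixture(scope="session")
def channel_domain():
    """Plain channel, 16 cells across, no dome."""
    spec = DomainSpec(
        parent_diameter=D_PARENT,
        parent_length=8 * D_PARENT,
        dome_radius=0.0,
        neck_width=0.0,
        grid_spacing=D_PARENT / 16,
    )
    return build_domain(spec)


@pytest.fixture(scope="session")
def dome_domain():
    """Side-wall dome (radius 2.5 mm, neck 3 mm) on the default channel."""
    spec = DomainSpec(
        parent_diameter=D_PARENT,
        parent_length=8 * D_PARENT,
        dome_radius=2.5e-3,
        neck_width=3.0e-3,
        grid_spacing=D_PARENT / 16,
    )
    return build_domain(spec)


@pytest.fixture(scope="session")
def short_dome_domain():
    """Cheaper dome domain for transient property runs."""
    spec = DomainSpec(
        parent_diameter=D_PARENT,
        parent_length=5 * D_PARENT,
        dome_radius=2.0e-3,
        neck_width=2.5e-3,
        grid_spacing=D_PARENT / 16,
    )
    return build_domain(spec)


@pytest.fixture(scope="session")
def poiseuille_field(channel_domain, blood):
    """Converged constant-viscosity channel flow (mu = high-shear plateau)."""
    solver = ProjectionSolver(channel_domain, blood, ergun_coefficients(0.0, blood))
    f = solver.initial_field()
    f.mu[:] = blood.eta_high_plateau
    f = solver.solve_steady(0.2, tol=1e-6, max_iter=8000, init=f, freeze_viscosity=True)
    return solver, f
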