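import numpy as np
import pytest

from blastosim import (
    ActiveParams,
    DiffusionParams,
    MaterialParams,
    ReactionParams,
    build_shell_mesh,
    compute_cell_frames,
)
from blastosim.femsolve import CoupledAssembler, FemSpace


@pytest.fixture(scope="session")
def small_mesh():
    """Coarse shell used by most kernel/FEM tests (192 elements)."""
    return build_shell_mesh(2, 2, 150.0, 135.0)


@pytest.fixture(scope="session")
def small_frames(small_mesh):
    return compute_cell_frames(small_mesh)


@pytest.fixture(scope="session")
def small_space(small_mesh):
    return FemSpace(small_mesh, order=1)


@pytest.fixture(scope="session")
def material():
    return MaterialParams(100.0, 0.4)


@pytest.fixture()
def coupled_assembler(small_space, small_frames, material):
    return CoupledAssembler(
        small_space,
        material,
        diffusion=DiffusionParams(1.0, 0.01),
        reaction=ReactionParams(1e-4, 0.01, 2.0),
        active=ActiveParams(-0.01, True),
        frames=small_frames,
        stab_density=3.0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def convergence_errors():
    """L2 errors of the manufactured steady-diffusion solve at three
    uniform refinements (shared: the fine solve is the expensive part)."""
    from blastosim.femsolve import FemSpace, l2_error, solve_steady_transport
    from manufactured import manufactured_problem

    diff = DiffusionParams(1.0, 0.25)
    k1 = 1e-3
    errs = []
    for refine in (2, 4, 8):
        mesh = build_shell_mesh(2, refine, 150.0, 135.0)
        space = FemSpace(mesh, order=1)
        exact, source = manufactured_problem(space, diff, k1)
        C = solve_steady_transport(space, diffusion=diff, k1=k1, source=source)
        errs.append(l2_error(space, C, exact))
    return errs
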