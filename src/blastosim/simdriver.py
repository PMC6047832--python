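"""Scenario orchestration: configuration, initial conditions, time marching.

A scenario is a fully serialisable :class:`ScenarioConfig` (geometry,
material, coupling, transport, reaction, initial condition, time-stepping
and output controls plus one master RNG seed).  :func:`run` marches the
coupled mechanochemical system from the incompatible initial state
(u = 0, C = C0) using small start-up steps, detects stationarity or solver
breakdown (a gastrulation event eventually inverts elements and Newton
stops converging — the run then exits gracefully with status
``mechanical_collapse`` and the last valid state preserved), and records a
per-step diagnostic trajectory.

Physical units: micrometres, seconds, pascals; concentrations are rescaled
to O(1) (the physical morphogen scale only enters through the product
k_couple * C, see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chemcore import DiffusionParams, MorphogenField, ReactionParams
from .errors import ValidationError
from .femsolve import (
    CoupledAssembler,
    FemSpace,
    SolverControls,
    SystemState,
    TimeStepper,
    advance_time,
)
from .mechcore import ActiveParams, MaterialParams
from .shellmesh import build_shell_mesh, compute_cell_frames

DAY = 86400.0


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


@dataclass
class GeometryConfig:
    n_face: int = 16
    refine: int = 4
    r_outer: float = 150.0
    r_inner: float = 135.0


@dataclass
class MaterialConfig:
    young_E: float = 100.0
    poisson_nu: float = 0.4


@dataclass
class ActiveConfig:
    k_couple: float = -0.01  # 1/(um * unit concentration); < 0: basal
    volume_preserving: bool = True


@dataclass
class DiffusionConfig:
    D_normal: float = 1.0       # um^2/s  (1e-12 m^2/s)
    D_tangential: float = 0.01  # um^2/s  (1e-14 m^2/s)


@dataclass
class ReactionConfig:
    k1_degradation: float = 1e-4   # 1/s
    k2_max_production: float = 0.01  # rescaled concentration / s (1e7 mol m^-3 s^-1)
    km_michaelis: float = 2.0


@dataclass
class InitialConditionConfig:
    mode: str = "random-per-cell"  # or "spot" or "gradient"
    amplitude: float = 1.0


@dataclass
class TimeConfig:
    dt_initial: float = 2.0
    dt_target: float = 20.0
    t_end: float = 20.0 * DAY
    max_steps: int = 100000


@dataclass
class StationarityCriterion:
    window: int = 100
    rtol: float = 1e-6

    def __post_init__(self):
        if self.rtol <= 0 or self.window < 1:
            raise ValidationError("stationarity window/tolerance must be positive")


@dataclass
class OutputConfig:
    snapshot_every: int = 0  # 0 disables VTU snapshots
    log_every: int = 0       # 0 disables console logging


@dataclass
class SolverConfig:
    newton_tol: float = 1e-6
    newton_abs_tol: float = 1e-10
    newton_max_iter: int = 25
    max_backtracks: int = 6
    jacobian_reuse: bool = True
    reuse_max_iter: int = 6
    refresh_every: int = 50
    n_startup_steps: int = 20
    dt_growth: float = 2.0
    predictor: bool = True
    stab_density: float = None  # None -> set from elastic-timescale rule
    stab_damping: float = 1.0
    linear_solver: str = "direct"


_SECTIONS = {
    "geometry": GeometryConfig,
    "material": MaterialConfig,
    "active": ActiveConfig,
    "diffusion": DiffusionConfig,
    "reaction": ReactionConfig,
    "initial": InitialConditionConfig,
    "time": TimeConfig,
    "stationarity": StationarityCriterion,
    "output": OutputConfig,
    "solver": SolverConfig,
}


@dataclass
class ScenarioConfig:
    """Complete, serialisable parameterisation of one run."""

    name: str = "custom"
    seed: int = 0
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    material: MaterialConfig = field(default_factory=MaterialConfig)
    active: ActiveConfig = field(default_factory=ActiveConfig)
    diffusion: DiffusionConfig = field(default_factory=DiffusionConfig)
    reaction: ReactionConfig = field(default_factory=ReactionConfig)
    initial: InitialConditionConfig = field(default_factory=InitialConditionConfig)
    time: TimeConfig = field(default_factory=TimeConfig)
    stationarity: StationarityCriterion = field(default_factory=StationarityCriterion)
    output: OutputConfig = field(default_factory=OutputConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)

    def __post_init__(self):
        for key, cls in _SECTIONS.items():
            val = getattr(self, key)
            if isinstance(val, dict):
                setattr(self, key, cls(**val))
        self.validate()

    def validate(self):
        g = self.geometry
        if g.n_face < 1 or g.refine < 1:
            raise ValidationError("n_face and refine must be >= 1")
        if not (0 < g.r_inner < g.r_outer):
            raise ValidationError("need 0 < r_inner < r_outer")
        t = self.time
        if not (0 < t.dt_initial <= t.dt_target) or t.t_end <= 0 or t.max_steps < 1:
            raise ValidationError("invalid time controls")
        if self.initial.mode not in ("random-per-cell", "spot", "gradient"):
            raise ValidationError(
                f"unknown initial-condition mode {self.initial.mode!r}; "
                "expected random-per-cell, spot or gradient"
            )
        # instantiating the parameter objects validates the physics sections
        MaterialParams(self.material.young_E, self.material.poisson_nu)
        DiffusionParams(self.diffusion.D_normal, self.diffusion.D_tangential)
        ReactionParams(
            self.reaction.k1_degradation,
            self.reaction.k2_max_production,
            self.reaction.km_michaelis,
        )

    def to_dict(self):
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d):
        return cls(**d)

    def to_yaml(self, path=None):
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path_or_text):
        p = Path(path_or_text) if "\n" not in str(path_or_text) else None
        text = p.read_text() if p is not None and p.exists() else str(path_or_text)
        return cls.from_dict(yaml.safe_load(text))

    def stab_density_value(self):
        """Stabilisation coefficient: elastic timescale ~ dt_target.

        rho is chosen so that sqrt(rho / E) * r_outer = dt_target: elastic
        transients relax within about one time step, so each accepted step
        is quasi-static while the six rigid-body modes stay regularised.
        Soft-mode ringing of the plain two-step second difference is
        suppressed by the companion velocity-damping weight (stab_damping).
        """
        if self.solver.stab_density is not None:
            return self.solver.stab_density
        E = self.material.young_E
        return E * (self.time.dt_target / self.geometry.r_outer) ** 2


# --------------------------------------------------------------------------
# initial conditions
# --------------------------------------------------------------------------


def initial_concentration(mesh, frames, mode="random-per-cell", seed=0, amplitude=1.0):
    """Seeded initial morphogen field as a continuous nodal field.

    random-per-cell : one U[0, amplitude] draw per biological cell; interior
        nodes take the cell's draw, nodes on cell boundaries the arithmetic
        mean of the adjacent cells' draws.
    spot : the biological cell nearest the +z pole at ``amplitude``, 0
        elsewhere.
    gradient : linear in z between 0 and ``amplitude``.
    """
    n_cells = mesh.n_bio_cells
    if mode == "random-per-cell":
        rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
        draws = rng.uniform(0.0, amplitude, size=n_cells)
    elif mode == "spot":
        centroids = np.stack([f.m for f in frames])
        pole = int(np.argmax(centroids[:, 2] / np.linalg.norm(centroids, axis=1)))
        draws = np.zeros(n_cells)
        draws[pole] = amplitude
    elif mode == "gradient":
        z = mesh.node_coords[:, 2]
        vals = amplitude * (z - z.min()) / (z.max() - z.min())
        return MorphogenField(nodal_values=vals, timestamp=0.0)
    else:
        raise ValidationError(f"unknown initial-condition mode {mode!r}")

    # average draws of all distinct biological cells adjacent to each node
    n = mesh.n_nodes
    acc = np.zeros(n)
    cnt = np.zeros(n)
    for cid in range(n_cells):
        nodes = np.unique(mesh.hex_connectivity[mesh.bio_cell_id == cid])
        acc[nodes] += draws[cid]
        cnt[nodes] += 1.0
    vals = acc / np.maximum(cnt, 1.0)
    return MorphogenField(nodal_values=vals, timestamp=0.0)


# --------------------------------------------------------------------------
# trajectory / results
# --------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Per-accepted-step diagnostic records."""

    records: list = field(default_factory=list)

    def append(self, **kw):
        self.records.append(kw)

    @property
    def frame(self):
        return pd.DataFrame(self.records)

    def to_csv(self, path):
        self.frame.to_csv(path, index=False)


@dataclass
class RunResult:
    config: ScenarioConfig
    exit_status: str  # stationary | t_end | max_steps | mechanical_collapse
    trajectory: Trajectory
    state: SystemState
    mesh: object
    frames: list
    space: object
    assembler: object
    snapshots: list = field(default_factory=list)


# --------------------------------------------------------------------------
# the run loop
# --------------------------------------------------------------------------


def _radial_displacement_extrema(mesh, u):
    u3 = u.reshape(-1, 3)
    N = mesh.node_coords / np.linalg.norm(mesh.node_coords, axis=1, keepdims=True)
    ur = np.einsum("ni,ni->n", u3, N)
    return float(-ur.min()), float(ur.max())  # (max inward, max outward)


def run(config, out_dir=None, progress=None):
    """Execute a scenario; returns a :class:`RunResult`.

    Fully reproducible given config + seed (deterministic mesh, seeded
    initial conditions, direct linear solver).  If ``out_dir`` is given a
    frozen config copy, JSON metadata, the trajectory CSV and periodic VTU
    snapshots are written there.
    """
    cfg = config
    mesh = build_shell_mesh(
        cfg.geometry.n_face, cfg.geometry.refine, cfg.geometry.r_outer,
        cfg.geometry.r_inner,
    )
    frames = compute_cell_frames(mesh)
    space = FemSpace(mesh, order=1)
    material = MaterialParams(cfg.material.young_E, cfg.material.poisson_nu)
    active = (
        ActiveParams(cfg.active.k_couple, cfg.active.volume_preserving)
        if cfg.active.k_couple != 0.0
        else None
    )
    assembler = CoupledAssembler(
        space,
        material,
        diffusion=DiffusionParams(cfg.diffusion.D_normal, cfg.diffusion.D_tangential),
        reaction=ReactionParams(
            cfg.reaction.k1_degradation,
            cfg.reaction.k2_max_production,
            cfg.reaction.km_michaelis,
        ),
        active=active,
        frames=frames,
        stab_density=cfg.stab_density_value(),
        stab_damping=cfg.solver.stab_damping,
    )
    controls = SolverControls(
        newton_tol=cfg.solver.newton_tol,
        newton_abs_tol=cfg.solver.newton_abs_tol,
        newton_max_iter=cfg.solver.newton_max_iter,
        max_backtracks=cfg.solver.max_backtracks,
        jacobian_reuse=cfg.solver.jacobian_reuse,
        reuse_max_iter=cfg.solver.reuse_max_iter,
        refresh_every=cfg.solver.refresh_every,
        dt_initial=cfg.time.dt_initial,
        dt_target=cfg.time.dt_target,
        n_startup_steps=cfg.solver.n_startup_steps,
        dt_growth=cfg.solver.dt_growth,
        predictor=cfg.solver.predictor,
        linear_solver=cfg.solver.linear_solver,
        stab_density=cfg.stab_density_value(),
    )
    stepper = TimeStepper(assembler, controls)

    C0 = initial_concentration(
        mesh, frames, cfg.initial.mode, cfg.seed, cfg.initial.amplitude
    )
    state = SystemState.initial(space, C0.nodal_values)
    traj = Trajectory()
    snapshots = []

    out = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cfg.to_yaml(out / "config.yaml")

    def _snapshot(tag):
        if out is None:
            return
        from .patio import write_snapshot

        path = out / f"snapshot_{tag}.vtu"
        write_snapshot(mesh, space, state, assembler=assembler, path=path)
        snapshots.append(str(path))

    hist_u, hist_C = [], []
    dt = cfg.time.dt_initial
    dt_min = cfg.time.dt_initial  # failure at the start-up step size means breakdown
    exit_status = "max_steps"
    wall0 = _time.time()
    _snapshot("000000")

    while state.step < cfg.time.max_steps:
        new_state, report = stepper.step(state, dt)
        if not report.converged:
            if dt > dt_min:
                dt = max(dt / 2.0, dt_min)
                continue
            exit_status = "mechanical_collapse"
            break
        state = new_state
        clipped = 0.0
        if np.any(state.C < 0.0):
            clipped = -float(state.C[state.C < 0.0].sum())
            state.C = np.maximum(state.C, 0.0)
        inward, outward = _radial_displacement_extrema(mesh, state.u)
        traj.append(
            t=state.t,
            dt=dt,
            newton_iters=report.iterations,
            residual=report.residual_norms[-1],
            C_min=float(state.C.min()),
            C_max=float(state.C.max()),
            C_mean=float(state.C.mean()),
            u_inward_max=inward,
            u_outward_max=outward,
            mass=assembler.total_mass(state.u, state.C, reuse_last=True),
            clipped_mass=clipped,
        )
        if cfg.output.log_every and state.step % cfg.output.log_every == 0:
            rec = traj.records[-1]
            msg = (
                f"step {state.step:6d} t={state.t:11.1f}s dt={dt:8.1f}s "
                f"iters={report.iterations} res={rec['residual']:.2e} "
                f"mass={rec['mass']:.4e}"
            )
            print(msg, flush=True)
            if out is not None:
                with open(out / "log.txt", "a") as fh:
                    fh.write(msg + "\n")
        if cfg.output.snapshot_every and state.step % cfg.output.snapshot_every == 0:
            _snapshot(f"{state.step:06d}")
        if progress is not None:
            progress(state, report)

        # stationarity: relative change of ||u|| and ||C|| over the window
        hist_u.append(float(np.linalg.norm(state.u)))
        hist_C.append(float(np.linalg.norm(state.C)))
        w = cfg.stationarity.window
        if len(hist_u) > w:
            hist_u.pop(0)
            hist_C.pop(0)
            du = abs(hist_u[-1] - hist_u[0]) / max(hist_u[-1], 1e-300)
            dC = abs(hist_C[-1] - hist_C[0]) / max(hist_C[-1], 1e-300)
            # a fully decayed state (both fields at roundoff) is stationary
            # even though its relative changes are pure noise
            decayed = (
                hist_C[-1] < 1e-9 * np.sqrt(len(state.C))
                and hist_u[-1] < 1e-9 * np.sqrt(len(state.u))
            )
            if (du < cfg.stationarity.rtol and dC < cfg.stationarity.rtol) or decayed:
                exit_status = "stationary"
                break
        if state.t >= cfg.time.t_end:
            exit_status = "t_end"
            break
        dt = advance_time(dt, report, state.step, controls)

    _snapshot("final")
    if out is not None:
        traj.to_csv(out / "trajectory.csv")
        meta = {
            "package_version": __import__("blastosim").__version__,
            "scenario": cfg.name,
            "seed": cfg.seed,
            "exit_status": exit_status,
            "steps": state.step,
            "model_time_s": state.t,
            "wall_time_s": _time.time() - wall0,
            "mesh": {
                "projection": mesh.metadata.get("projection"),
                "n_bio_cells": mesh.n_bio_cells,
                "n_elements": mesh.n_elements,
                "n_nodes": mesh.n_nodes,
            },
        }
        (out / "metadata.json").write_text(json.dumps(meta, indent=2))
    return RunResult(
        config=cfg,
        exit_status=exit_status,
        trajectory=traj,
        state=state,
        mesh=mesh,
        frames=frames,
        space=space,
        assembler=assembler,
        snapshots=snapshots,
    )


# --------------------------------------------------------------------------
# presets
# --------------------------------------------------------------------------


def _base_config(**over):
    cfg = ScenarioConfig()
    for key, val in over.items():
        obj, attr = cfg, key
        while "." in attr:
            head, attr = attr.split(".", 1)
            obj = getattr(obj, head)
        setattr(obj, attr, val)
    cfg.validate()
    return cfg


_K_BASAL = -0.01  # calibrated |k * C * X2| scale; see docs/methods.md


def _paper_scale(name, **over):
    return _base_config(name=name, **over)


def _reduced(cfg):
    """Desk-scale variant: coarser mesh, larger steps, earlier stationarity.

    The physical parameters are untouched; only the discretisation and the
    numerical budget shrink: n_face 16 -> 8, refine 4 -> 2, dt_target
    20 s -> 4000 s (fully implicit transport tolerates the large step),
    Newton solved to a correspondingly coarser tolerance, and stationarity
    declared at relative field changes below 5e-3 over a 30-step (~1.4 day)
    window.
    """
    cfg.name = cfg.name + "_reduced"
    if cfg.geometry.n_face == 16:
        cfg.geometry.n_face = 8
    else:
        cfg.geometry.n_face = max(cfg.geometry.n_face // 2, 2)
    cfg.geometry.refine = 2
    cfg.time.dt_initial = 50.0
    cfg.time.dt_target = 4000.0
    cfg.time.t_end = 20.0 * DAY
    cfg.time.max_steps = 400
    cfg.solver.newton_tol = 1e-2
    cfg.solver.newton_abs_tol = 1e-6
    cfg.solver.newton_max_iter = 12
    cfg.solver.max_backtracks = 3
    cfg.solver.refresh_every = 30
    cfg.stationarity = StationarityCriterion(window=25, rtol=5e-3)
    cfg.validate()
    return cfg


def preset(name):
    """Named scenario presets for the study's experiments.

    ``fig2_basal`` and ``fig3_apical`` are the two headline feedback loops
    (basal constriction patterning / apical constriction gastrulation);
    ``fig4a``..``fig4f`` are the robustness variants (thickness doubled /
    halved, smaller system, tangential diffusion quartered / removed,
    non-volume-preserving one-sided constriction).  Every preset also has a
    ``*_reduced`` desk-scale variant.
    """
    base = {
        "fig2_basal": lambda: _paper_scale(
            "fig2_basal", **{"active.k_couple": _K_BASAL}
        ),
        "fig3_apical": lambda: _paper_scale(
            "fig3_apical", **{"active.k_couple": -_K_BASAL}
        ),
        "fig4a_thick": lambda: _paper_scale(
            "fig4a_thick", **{"active.k_couple": _K_BASAL, "geometry.r_inner": 120.0}
        ),
        "fig4b_thin": lambda: _paper_scale(
            "fig4b_thin", **{"active.k_couple": _K_BASAL, "geometry.r_inner": 142.5}
        ),
        "fig4c_small": lambda: _paper_scale(
            "fig4c_small",
            **{
                "active.k_couple": _K_BASAL,
                "geometry.n_face": 8,
                "geometry.r_outer": 75.0,
                "geometry.r_inner": 67.5,
            },
        ),
        "fig4d_quarter_dt": lambda: _paper_scale(
            "fig4d_quarter_dt",
            **{"active.k_couple": _K_BASAL, "diffusion.D_tangential": 0.0025},
        ),
        "fig4e_no_dt": lambda: _paper_scale(
            "fig4e_no_dt",
            **{"active.k_couple": _K_BASAL, "diffusion.D_tangential": 0.0},
        ),
        "fig4f_nonpreserving": lambda: _paper_scale(
            "fig4f_nonpreserving",
            **{"active.k_couple": _K_BASAL, "active.volume_preserving": False},
        ),
    }
    aliases = {"fig4a": "fig4a_thick", "fig4b": "fig4b_thin", "fig4c": "fig4c_small",
               "fig4d": "fig4d_quarter_dt", "fig4e": "fig4e_no_dt",
               "fig4f": "fig4f_nonpreserving"}
    key = name
    reduced = key.endswith("_reduced")
    if reduced:
        key = key[: -len("_reduced")]
    key = aliases.get(key, key)
    if key not in base:
        names = sorted(list(base) + [b + "_reduced" for b in base])
        raise ValidationError(f"unknown preset {name!r}; available: {names}")
    cfg = base[key]()
    if reduced:
        cfg = _reduced(cfg)
        if key == "fig4b_thin":
            # subcritical decay: the field is gone long before 400 steps
            cfg.time.max_steps = 250
        if key == "fig3_apical":
            # the invagination grows without bound; a shorter budget is
            # enough to observe monotone deepening or breakdown
            cfg.time.max_steps = 240
    return cfg
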