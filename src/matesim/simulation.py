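"""Multi-cell mating simulations: scenario geometry, multirate time
stepping, field-membrane-shape coupling, and mating detection.

Conventions
-----------
* Lengths in micrometres; one model time unit = 100 s.  Configuration values
  are given in the units a bench scientist would use: diffusion constants in
  um^2/s, boundary speed in um/s, durations in seconds; they are converted
  to model units internally.
* The extracellular fields relax much faster than the membrane moves, so by
  default each membrane step uses a quasi-steady-state (QSS) sparse solve of
  the field equations, with the multiplicative sampling noise applied to the
  membrane-sampled values (``solver_mode='qss'``).  The explicit
  Euler-Maruyama field integrator (``solver_mode='explicit'``) is retained as
  the reference dynamics.
* A simulation is deterministic given (config, seed): every noise source
  (field sampling per cell, u1 noise, v1 noise per cell) draws from its own
  stream spawned from the root seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from matesim.grid import Grid
from matesim.levelset import (
    advance_levelset,
    init_circle_levelset,
    reinitialize_signed_distance,
)
from matesim.membrane import (
    BAND_HALFWIDTH_CELLS,
    MembraneCurve,
    extract_membrane_curve,
    region_masks,
)
from matesim.fields import (
    ExtracellularField,
    QssSolver,
    SourceSpec,
    effective_alpha_decay,
    membrane_source_field,
    normalize_ligand,
    sample_membrane,
    step_field,
)
from matesim.polarity import (
    PolarityParams,
    PolarityState,
    Polarisome,
    circular_moving_average,
    extend_velocity,
    locate_polarisome,
    membrane_velocity,
    resample_membrane_state,
    step_polarity,
    transport_marker_values,
)

#: Seconds per model time unit.
TIME_UNIT_S = 100.0


class CellSpec(BaseModel):
    """One cell: mating type, initial geometry and genotype."""

    model_config = ConfigDict(extra="forbid")

    mating_type: Literal["a", "alpha"]
    center0: tuple[float, float]
    radius0: float = 1.0
    bar1: bool = False            # a-cells only: secrete the Bar1 protease
    supersensitive: bool = False  # beta1 = 2.5 instead of 0.92
    producer: bool = True         # alpha-cells only: secrete alpha-factor
    cell_id: Optional[str] = None

    @model_validator(mode="after")
    def _check_genotype(self) -> "CellSpec":
        if self.radius0 <= 0:
            raise ValueError("radius0 must be positive")
        if self.mating_type == "alpha" and self.bar1:
            raise ValueError("bar1 is only meaningful for a-cells")
        if self.mating_type == "a" and not self.producer:
            raise ValueError("the producer flag is only meaningful for alpha-cells")
        return self


#: beta1 for the supersensitive genotype (default genotype uses
#: PolarityParams.beta1 = 0.92).
BETA1_SUPERSENSITIVE = 2.5


class ScenarioConfig(BaseModel):
    """Full parameterization of one simulation scenario.

    Defaults are the reference study conditions: polarized secretion,
    bar1-delta cells 4 um apart, D_alpha = 100 and D_a = 10 um^2/s, noise
    amplitudes (kappa1, kappa2, kappa3) = (5, 3, 0.1), boundary speed
    amplitude 0.0002 um/s, 1800 s duration with 50 s sampling, and the time
    steps 4e-4 (field) / 0.01 (membrane) in units of 100 s.
    """

    model_config = ConfigDict(extra="forbid")

    # domain
    x_min: float = -3.6
    x_max: float = 3.6
    y_min: float = -1.6
    y_max: float = 1.6
    h: float = 0.04
    n_markers: int = 400

    cells: list[CellSpec] = Field(
        default_factory=lambda: [
            CellSpec(mating_type="a", center0=(-2.0, 0.0)),
            CellSpec(mating_type="alpha", center0=(2.0, 0.0)),
        ]
    )

    # extracellular fields (diffusion in um^2/s; decay per time unit)
    D_alpha: float = 100.0
    D_a: float = 10.0
    D_B: Optional[float] = 30.0       # Bar1 diffusion, um^2/s
    k_alpha: float = 1000.0
    k_a: float = 200.0
    k_B: float = 100.0                # decay of the Bar1 field itself
    k_bar1: float = 3000.0            # Bar1-enhanced alpha-factor degradation
    eps_bar1: float = 1e-6
    background_C: float = 0.0         # uniform alpha-factor production rate
    source_mode: Literal["polarized", "isotropic"] = "polarized"
    exogenous_uniform_pheromone: Optional[float] = None  # no-secretion control

    # noise amplitudes
    kappa1: float = 5.0
    kappa2: float = 3.0
    kappa3: float = 0.1

    # growth
    Vamp: float = 2.0e-4              # um/s
    polarization_ratio: float = 2.0   # max/mean of u2 that activates growth
    polarisome_ratio: float = 1.2     # weaker u2 asymmetry that defines a
                                      # reportable polarisome (no growth yet)
    filter_window_frac: float = 0.05  # moving-average window, fraction of membrane
    filter_time_steps: int = 15       # exponential filter time constant, steps
    tau: float = 0.4                  # polarisome mass-fraction threshold

    # timing (seconds unless noted)
    T_end: float = 1800.0
    dt_field: float = 4.0e-4          # time units
    dt_membrane: float = 0.01         # time units
    sample_interval: float = 50.0
    field_update_interval: int = 1    # membrane steps between field updates
    reinit_interval: int = 10         # membrane steps between reinit/resample

    # success criterion
    success_threshold: Optional[float] = None  # default max(0.04, h)
    trend_window: int = 5             # samples for the approach-trend test

    solver_mode: Literal["qss", "explicit"] = "qss"
    seed: int = 0

    # polarity parameter overrides applied on top of PolarityParams defaults
    polarity: dict[str, float] = Field(default_factory=dict)

    # optional field snapshot recording (seconds); empty = none
    snapshot_times: list[float] = Field(default_factory=list)

    @model_validator(mode="after")
    def _validate(self) -> "ScenarioConfig":
        if self.Vamp <= 0:
            raise ValueError("Vamp must be positive")
        for name in ("kappa1", "kappa2", "kappa3", "background_C"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("D_alpha", "D_a", "k_alpha", "k_a", "k_B", "k_bar1",
                     "T_end", "dt_field", "dt_membrane", "sample_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.D_B is not None and self.D_B <= 0:
            raise ValueError("D_B must be positive")
        if self.n_markers < 16:
            raise ValueError("n_markers must be >= 16")
        if not 0 < self.tau < 1:
            raise ValueError("tau must be in (0, 1)")
        Grid(self.x_min, self.x_max, self.y_min, self.y_max, self.h)  # validates
        return self

    def grid(self) -> Grid:
        return Grid(self.x_min, self.x_max, self.y_min, self.y_max, self.h)

    def threshold(self) -> float:
        """Polarisome contact threshold: the mesh size (0.04 um at the
        reference resolution), never below 0.04."""
        if self.success_threshold is not None:
            return self.success_threshold
        return max(0.04, self.h)

    def polarity_params(self, spec: CellSpec) -> PolarityParams:
        over = dict(self.polarity)
        over.setdefault("kappa2", self.kappa2)
        over.setdefault("kappa3", self.kappa3)
        if spec.supersensitive:
            over["beta1"] = BETA1_SUPERSENSITIVE
        return PolarityParams(**over)


_SCENARIOS = {
    "two_cell",
    "two_cell_close",
    "three_cell_discrim",
    "three_cell_compete",
    "three_cell_offset",
    "five_cell_discrim",
}


def build_scenario(name: str, **overrides) -> ScenarioConfig:
    """Construct one of the named study geometries.

    two_cell            a at (-2,0), alpha at (2,0), [-3.6,3.6]x[-1.6,1.6]
    two_cell_close      center separation 2.5 um (0.5 um boundary gap)
    three_cell_discrim  a at (-2,0); alpha producer at (1,2), non-producer at
                        (1,-2); [-3.6,3.6]x[-3.2,3.2] (tall enough to contain
                        the radius-1 cells centered at y = +-2)
    three_cell_compete  Bar1+ and bar1-delta a-cells at (1,2)/(1,-2) compete
                        for one alpha-cell at (-2,0)
    three_cell_offset   two alpha producers at (1,2)/(1,-2); the a-cell sits
                        0.1 um below the midline at (-2,-0.1)
    five_cell_discrim   a at (0,0); alpha producer at (2,2) and three
                        non-producers at (-2,2),(2,-2),(-2,-2) on
                        [-3.72,3.72]^2

    Keyword overrides are applied on top of the scenario defaults
    (e.g. ``build_scenario('two_cell', background_C=100)``).
    """
    if name not in _SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(_SCENARIOS)}")

    kw: dict = {}
    if name == "two_cell":
        kw["cells"] = [
            CellSpec(mating_type="a", center0=(-2.0, 0.0)),
            CellSpec(mating_type="alpha", center0=(2.0, 0.0)),
        ]
    elif name == "two_cell_close":
        kw["cells"] = [
            CellSpec(mating_type="a", center0=(-1.25, 0.0)),
            CellSpec(mating_type="alpha", center0=(1.25, 0.0)),
        ]
    elif name == "three_cell_discrim":
        kw.update(y_min=-3.2, y_max=3.2)
        kw["cells"] = [
            CellSpec(mating_type="a", center0=(-2.0, 0.0)),
            CellSpec(mating_type="alpha", center0=(1.0, 2.0), producer=True),
            CellSpec(mating_type="alpha", center0=(1.0, -2.0), producer=False),
        ]
    elif name == "three_cell_compete":
        kw.update(y_min=-3.2, y_max=3.2)
        kw["cells"] = [
            CellSpec(mating_type="alpha", center0=(-2.0, 0.0)),
            CellSpec(mating_type="a", center0=(1.0, 2.0), bar1=True),
            CellSpec(mating_type="a", center0=(1.0, -2.0), bar1=False),
        ]
    elif name == "three_cell_offset":
        kw.update(y_min=-3.2, y_max=3.2)
        kw["cells"] = [
            CellSpec(mating_type="a", center0=(-2.0, -0.1)),
            CellSpec(mating_type="alpha", center0=(1.0, 2.0)),
            CellSpec(mating_type="alpha", center0=(1.0, -2.0)),
        ]
    elif name == "five_cell_discrim":
        kw.update(x_min=-3.72, x_max=3.72, y_min=-3.72, y_max=3.72)
        kw["cells"] = [
            CellSpec(mating_type="a", center0=(0.0, 0.0)),
            CellSpec(mating_type="alpha", center0=(2.0, 2.0), producer=True),
            CellSpec(mating_type="alpha", center0=(-2.0, 2.0), producer=False),
            CellSpec(mating_type="alpha", center0=(2.0, -2.0), producer=False),
            CellSpec(mating_type="alpha", center0=(-2.0, -2.0), producer=False),
        ]
    kw.update(overrides)
    return ScenarioConfig(**kw)


def detect_mating(distances: np.ndarray, threshold: float,
                  trend_window: int = 5) -> tuple[bool, Optional[int]]:
    """Apply the mating-success criterion to one sampled distance series.

    Success at the first sample where (a) the polarisome distance is below
    ``threshold`` and (b) the distance has decreased on average over the
    trailing ``trend_window`` inter-sample differences (at least one valid
    difference is required: the projections must be approaching, not passing
    by).  NaN entries (pre-polarization) never trigger.
    """
    d = np.asarray(distances, dtype=float)
    for k in range(1, len(d)):
        if not np.isfinite(d[k]) or d[k] >= threshold:
            continue
        lo = max(0, k - trend_window)
        diffs = np.diff(d[lo: k + 1])
        diffs = diffs[np.isfinite(diffs)]
        if len(diffs) >= 1 and float(np.mean(diffs)) < 0.0:
            return True, k
    return False, None


def projection_length(curve: MembraneCurve) -> float:
    """Mating-projection length: the farthest membrane point's distance from
    the initial cell center, minus the initial radius (floored at 0)."""
    r = np.hypot(*(curve.points - curve.center0).T)
    return max(0.0, float(np.max(r)) - curve.radius0)


@dataclass
class SimulationResult:
    """Sampled trajectories and outcome of one simulation."""

    success: bool
    mating_time: Optional[float]              # seconds
    partner: Optional[tuple[str, str]]        # (a_id, alpha_id) at success
    times: np.ndarray                         # sample times, s
    cell_ids: list[str]
    mating_types: dict[str, str]
    centers0: dict[str, tuple[float, float]]
    polarisome_points: dict[str, np.ndarray]  # (n_samples, 2), NaN before pol.
    polarisome_angles: dict[str, np.ndarray]  # (n_samples,)
    u2_max: dict[str, np.ndarray]
    u2_mean: dict[str, np.ndarray]
    perimeters: dict[str, np.ndarray]
    projection_lengths: dict[str, np.ndarray]
    distances: dict[tuple[str, str], np.ndarray]   # per a-alpha pair
    final_curves: dict[str, np.ndarray]
    clamp_events: dict[str, int]
    seed: int
    config: ScenarioConfig
    snapshots: dict[float, dict[str, np.ndarray]] = dc_field(default_factory=dict)

    def pair_distance(self, a_id: str, alpha_id: str) -> np.ndarray:
        return self.distances[(a_id, alpha_id)]


class _Cell:
    """Mutable per-cell simulation state (internal)."""

    def __init__(self, spec: CellSpec, cfg: ScenarioConfig, grid: Grid,
                 params: PolarityParams, rng_u: np.random.Generator,
                 rng_sample: np.random.Generator, cell_id: str):
        self.spec = spec
        self.id = cell_id
        self.params = params
        self.rng_u = rng_u
        self.rng_sample = rng_sample
        self.phi = init_circle_levelset(spec.center0, spec.radius0, grid, cell_id)
        self.curve = extract_membrane_curve(
            self.phi, cfg.n_markers, center0=np.asarray(spec.center0),
            radius0=spec.radius0,
        )
        self.state = PolarityState.uniform(cfg.n_markers, params)
        self.u2_filt = self.state.u2.copy()
        self.polarized = False
        self.polarisome: Optional[Polarisome] = None
        self.band: Optional[np.ndarray] = None
        # caches refreshed at (re)initialization: band node coordinates for
        # velocity extension and grad(phi) for marker normals
        self.band_nodes: Optional[tuple] = None
        self.grad: Optional[tuple] = None

    @property
    def opposite(self) -> str:
        return "alpha" if self.spec.mating_type == "a" else "a"


class Simulation:
    """Driver coupling level sets, membranes, polarity and fields."""

    def __init__(self, config: ScenarioConfig, seed: Optional[int] = None):
        self.cfg = config
        self.seed = config.seed if seed is None else int(seed)
        self.grid = config.grid()
        if not self.grid.contains(
            np.array([c.center0 for c in config.cells]),
            margin=max(c.radius0 for c in config.cells) if config.cells else 0.0,
        ).all():
            raise ValueError("all cells must lie strictly inside the domain")

        ss = np.random.SeedSequence(self.seed)
        n = len(config.cells)
        children = ss.spawn(3 + 2 * n)
        self.rng_field = {
            "alpha_factor": np.random.default_rng(children[0]),
            "a_factor": np.random.default_rng(children[1]),
            "bar1": np.random.default_rng(children[2]),
        }

        self.cells: list[_Cell] = []
        counts: dict[str, int] = {}
        for i, spec in enumerate(config.cells):
            base = spec.mating_type
            counts[base] = counts.get(base, 0)
            cid = spec.cell_id or f"{base}{counts[base]}"
            counts[base] += 1
            self.cells.append(
                _Cell(spec, config, self.grid, config.polarity_params(spec),
                      np.random.default_rng(children[3 + 2 * i]),
                      np.random.default_rng(children[4 + 2 * i]), cid)
            )

        self.masks = region_masks([c.phi for c in self.cells], self.grid)
        for c, band in zip(self.cells, self.masks.bands):
            c.band = band
        self._refresh_cell_caches()
        self.solvers = {tag: QssSolver(self.grid)
                        for tag in ("alpha_factor", "a_factor", "bar1")}
        # field values (zero outside the exterior mask)
        self.f_alpha = self.grid.zeros()
        self.f_a = self.grid.zeros()
        self.f_B: Optional[np.ndarray] = None
        self.any_bar1 = any(c.spec.bar1 for c in self.cells)
        self.field_clamevents = 0

        # unit conversions
        self.D_alpha_tu = config.D_alpha * TIME_UNIT_S
        self.D_a_tu = config.D_a * TIME_UNIT_S
        self.D_B_tu = (config.D_B if config.D_B is not None else config.D_a) * TIME_UNIT_S
        self.dt_m = config.dt_membrane                # time units
        self.dt_m_s = config.dt_membrane * TIME_UNIT_S  # seconds

        self.source_spec = SourceSpec(
            mode=config.source_mode, background_C=config.background_C
        )
        self._explicit_fields: dict[str, ExtracellularField] = {}

    def _refresh_cell_caches(self) -> None:
        for c in self.cells:
            iy, ix = np.nonzero(c.band)
            nodes = np.column_stack((self.grid.x[ix], self.grid.y[iy]))
            c.band_nodes = (iy, ix, nodes)
            c.grad = self.grid.gradient(c.phi.phi)

    # ------------------------------------------------------------------ fields

    def _cell_source(self, cell: _Cell) -> np.ndarray:
        return membrane_source_field(
            cell.phi, cell.curve, cell.u2_filt, self.source_spec,
            cell.band, polarized_active=cell.polarized,
        )

    def _assemble_sources(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        g0 = self.grid.zeros()
        S_alpha = g0.copy()
        S_a = g0.copy()
        S_B = g0.copy()
        for c in self.cells:
            if c.spec.mating_type == "alpha":
                if c.spec.producer:
                    S_alpha += self._cell_source(c)
            else:
                s = self._cell_source(c)
                S_a += s
                if c.spec.bar1:
                    S_B += self.source_spec.bar1_ratio * s
        if self.cfg.background_C > 0:
            S_alpha = S_alpha + self.cfg.background_C * self.masks.exterior
        return S_alpha, S_a, S_B

    def update_fields(self, elapsed_tu: float) -> None:
        cfg = self.cfg
        ext = self.masks.exterior
        if cfg.exogenous_uniform_pheromone is not None:
            val = cfg.exogenous_uniform_pheromone
            self.f_alpha = np.where(ext, val, 0.0)
            self.f_a = np.where(ext, val, 0.0)
            self.f_B = None
            return
        S_alpha, S_a, S_B = self._assemble_sources()
        if cfg.solver_mode == "qss":
            if self.any_bar1:
                self.f_B = self.solvers["bar1"].solve(ext, self.D_B_tu, cfg.k_B, S_B)
                k_eff = effective_alpha_decay(cfg.k_alpha, cfg.k_bar1,
                                              self.f_B, cfg.eps_bar1)
            else:
                self.f_B = None
                k_eff = cfg.k_alpha
            self.f_alpha = self.solvers["alpha_factor"].solve(
                ext, self.D_alpha_tu, k_eff, S_alpha)
            self.f_a = self.solvers["a_factor"].solve(
                ext, self.D_a_tu, cfg.k_a, S_a)
        else:
            self._explicit_update(ext, S_alpha, S_a, S_B, elapsed_tu)

    def _explicit_update(self, ext: np.ndarray, S_alpha: np.ndarray,
                         S_a: np.ndarray, S_B: np.ndarray,
                         elapsed_tu: float) -> None:
        cfg = self.cfg
        h = self.grid.h
        Dmax = max(self.D_alpha_tu, self.D_a_tu,
                   self.D_B_tu if self.any_bar1 else 0.0)
        dt_cfl = h * h / (4.0 * Dmax)
        dt = min(cfg.dt_field, dt_cfl)
        nsub = max(1, math.ceil(elapsed_tu / dt))
        dt = elapsed_tu / nsub
        if not self._explicit_fields:
            self._explicit_fields = {
                "alpha_factor": ExtracellularField(
                    self.grid, self.grid.zeros(), self.D_alpha_tu,
                    cfg.k_alpha, cfg.kappa1, "alpha_factor"),
                "a_factor": ExtracellularField(
                    self.grid, self.grid.zeros(), self.D_a_tu,
                    cfg.k_a, cfg.kappa1, "a_factor"),
                "bar1": ExtracellularField(
                    self.grid, self.grid.zeros(), self.D_B_tu,
                    cfg.k_B, 0.0, "bar1"),
            }
        fa = self._explicit_fields["alpha_factor"]
        fb = self._explicit_fields["a_factor"]
        fB = self._explicit_fields["bar1"]
        for _ in range(nsub):
            if self.any_bar1:
                fB = step_field(fB, S_B, ext, dt, None)
                k_eff = effective_alpha_decay(cfg.k_alpha, cfg.k_bar1,
                                              fB.values, cfg.eps_bar1)
            else:
                k_eff = cfg.k_alpha
            fa = step_field(fa, S_alpha, ext, dt,
                            self.rng_field["alpha_factor"], k_eff=k_eff)
            fb = step_field(fb, S_a, ext, dt, self.rng_field["a_factor"])
        self._explicit_fields = {"alpha_factor": fa, "a_factor": fb, "bar1": fB}
        self.f_alpha = fa.values
        self.f_a = fb.values
        self.f_B = fB.values if self.any_bar1 else None

    # --------------------------------------------------------------- membrane

    def _sample_input(self, cell: _Cell) -> np.ndarray:
        if cell.spec.mating_type == "a":
            values, k_tu = self.f_alpha, self.cfg.k_alpha
        else:
            values, k_tu = self.f_a, self.cfg.k_a
        f = sample_membrane(values, self.grid, cell.curve, self.masks.exterior)
        if self.cfg.solver_mode == "qss" and self.cfg.kappa1 > 0 \
                and self.cfg.exogenous_uniform_pheromone is None:
            # QSS mode: the multiplicative field noise is applied post hoc to
            # the sampled values at its stationary amplitude.  The linearized
            # field SPDE relaxes at rate k, so the noise term kappa1 f dW
            # (dW ~ N(0, dt)) accumulates to a stationary relative variance
            # kappa1^2/(2k); the relaxation time 1/k is well below the
            # membrane step, making successive samples independent.
            sd = self.cfg.kappa1 / np.sqrt(2.0 * k_tu)
            xi = cell.rng_sample.standard_normal(len(f))
            f = np.maximum(f * (1.0 + sd * xi), 0.0)
        return normalize_ligand(f)

    def _other_phi_min(self, cell: _Cell) -> np.ndarray:
        """Min over other cells of their phi at this cell's markers."""
        out = np.full(cell.curve.n_markers, np.inf)
        for other in self.cells:
            if other is cell:
                continue
            vals = self.grid.interp(other.phi.phi, cell.curve.points)
            out = np.minimum(out, vals)
        return out

    def _membrane_step(self, cell: _Cell) -> None:
        cfg = self.cfg
        f_tilde = self._sample_input(cell)
        cell.state = step_polarity(cell.state, f_tilde, cell.params,
                                   cell.curve.ds, self.dt_m, cell.rng_u)
        window = max(3, int(round(cfg.filter_window_frac * cfg.n_markers)))
        ma = circular_moving_average(cell.state.u2, window)
        cell.u2_filt = cell.u2_filt + (ma - cell.u2_filt) / cfg.filter_time_steps

        mean = float(np.mean(cell.u2_filt))
        ratio = float(np.max(cell.u2_filt)) / mean if mean > 0 else 0.0
        if not cell.polarized and ratio > cfg.polarization_ratio:
            cell.polarized = True
        # the polarisome becomes reportable at a weaker asymmetry than the
        # one that activates growth: cells whose signaling saturates (e.g.
        # supersensitive mutants) still have an intended direction even when
        # the Cdc42 peak never grows strong enough to drive a projection
        if cell.polarized or ratio > cfg.polarisome_ratio:
            cell.polarisome = locate_polarisome(cell.u2_filt, cell.curve, cfg.tau)
        else:
            cell.polarisome = None

        V = (membrane_velocity(cell.u2_filt, cell.curve, cell.polarisome, cfg.Vamp)
             if cell.polarized else np.zeros(cell.curve.n_markers))
        if np.any(V > 0):
            # contact handling: freeze growth where another membrane is within
            # half a mesh width (no interpenetration; the success criterion
            # fires on polarisome proximity before membranes could cross) and
            # where the membrane approaches the domain wall (the cell cannot
            # leave the computational box)
            if len(self.cells) > 1:
                V[self._other_phi_min(cell) < 0.5 * self.grid.h] = 0.0
            at_wall = ~self.grid.contains(cell.curve.points, margin=3.0 * self.grid.h)
            V[at_wall] = 0.0
        if np.any(V != 0.0):
            V_ext = extend_velocity(V, cell.curve, cell.band, self.grid,
                                    band_nodes=cell.band_nodes)
            cell.phi = advance_levelset(cell.phi, V_ext, self.dt_m_s)
            pts = cell.curve.points + (V * self.dt_m_s)[:, None] * cell.curve.normals
            gx, gy = cell.grad  # refreshed at every reinitialization
            nx = self.grid.interp(gx, pts)
            ny = self.grid.interp(gy, pts)
            nrm = np.maximum(np.hypot(nx, ny), 1e-12)
            cell.curve = MembraneCurve(
                points=pts,
                normals=np.column_stack((nx / nrm, ny / nrm)),
                center0=cell.curve.center0,
                radius0=cell.curve.radius0,
                cell_id=cell.id,
            )

    def _reinit_all(self) -> None:
        reinit_band = max(0.6, (BAND_HALFWIDTH_CELLS + 2.0) * self.grid.h)
        for cell in self.cells:
            cell.phi = reinitialize_signed_distance(cell.phi, band_width=reinit_band)
            new_curve = extract_membrane_curve(
                cell.phi, self.cfg.n_markers,
                center0=cell.curve.center0, radius0=cell.curve.radius0,
            )
            cell.state = resample_membrane_state(cell.state, cell.curve, new_curve)
            (cell.u2_filt,) = transport_marker_values(
                [cell.u2_filt], cell.curve, new_curve)
            cell.curve = new_curve
        self.masks = region_masks([c.phi for c in self.cells], self.grid)
        for c, band in zip(self.cells, self.masks.bands):
            c.band = band
        self._refresh_cell_caches()

    # -------------------------------------------------------------------- run

    def run(self) -> SimulationResult:
        cfg = self.cfg
        n_steps = int(round(cfg.T_end / self.dt_m_s))
        sample_every = max(1, int(round(cfg.sample_interval / self.dt_m_s)))
        a_ids = [c.id for c in self.cells if c.spec.mating_type == "a"]
        alpha_ids = [c.id for c in self.cells if c.spec.mating_type == "alpha"]
        pairs = [(a, b) for a in a_ids for b in alpha_ids]
        by_id = {c.id: c for c in self.cells}

        times: list[float] = []
        rec_points = {c.id: [] for c in self.cells}
        rec_angle = {c.id: [] for c in self.cells}
        rec_u2max = {c.id: [] for c in self.cells}
        rec_u2mean = {c.id: [] for c in self.cells}
        rec_perim = {c.id: [] for c in self.cells}
        rec_proj = {c.id: [] for c in self.cells}
        rec_dist = {p: [] for p in pairs}
        snapshots: dict[float, dict[str, np.ndarray]] = {}
        snap_left = sorted(cfg.snapshot_times)

        success = False
        mating_time: Optional[float] = None
        partner: Optional[tuple[str, str]] = None
        threshold = cfg.threshold()

        def record(t_s: float) -> None:
            times.append(t_s)
            for c in self.cells:
                if c.polarisome is not None:
                    rec_points[c.id].append(c.polarisome.point.copy())
                    rec_angle[c.id].append(c.polarisome.angle)
                else:
                    rec_points[c.id].append(np.array([np.nan, np.nan]))
                    rec_angle[c.id].append(np.nan)
                rec_u2max[c.id].append(float(np.max(c.state.u2)))
                rec_u2mean[c.id].append(float(np.mean(c.state.u2)))
                rec_perim[c.id].append(c.curve.perimeter)
                rec_proj[c.id].append(projection_length(c.curve))
            for (ai, bi) in pairs:
                pa = by_id[ai].polarisome
                pb = by_id[bi].polarisome
                if pa is None or pb is None:
                    rec_dist[(ai, bi)].append(np.nan)
                else:
                    rec_dist[(ai, bi)].append(
                        float(np.hypot(*(pa.point - pb.point))))

        record(0.0)
        for step in range(n_steps):
            if step % cfg.field_update_interval == 0:
                self.update_fields(cfg.field_update_interval * self.dt_m)
            for cell in self.cells:
                self._membrane_step(cell)
            if (step + 1) % cfg.reinit_interval == 0:
                self._reinit_all()
            t_s = (step + 1) * self.dt_m_s
            while snap_left and t_s >= snap_left[0] - 1e-9:
                t_snap = snap_left.pop(0)
                snap = {"f_alpha": self.f_alpha.copy(), "f_a": self.f_a.copy()}
                if self.f_B is not None:
                    snap["bar1"] = self.f_B.copy()
                for c in self.cells:
                    snap[f"phi_{c.id}"] = c.phi.phi.copy()
                    snap[f"curve_{c.id}"] = c.curve.points.copy()
                    snap[f"u2_{c.id}"] = c.state.u2.copy()
                snapshots[t_snap] = snap
            if (step + 1) % sample_every == 0:
                record(t_s)
                for p in pairs:
                    ok, idx = detect_mating(np.asarray(rec_dist[p]), threshold,
                                            cfg.trend_window)
                    if ok:
                        success = True
                        partner = p
                        mating_time = times[idx]
                        break
                if success:
                    break

        clamp = {c.id: c.state.clamp_events for c in self.cells}
        return SimulationResult(
            success=success,
            mating_time=mating_time,
            partner=partner,
            times=np.asarray(times),
            cell_ids=[c.id for c in self.cells],
            mating_types={c.id: c.spec.mating_type for c in self.cells},
            centers0={c.id: tuple(c.spec.center0) for c in self.cells},
            polarisome_points={k: np.asarray(v) for k, v in rec_points.items()},
            polarisome_angles={k: np.asarray(v) for k, v in rec_angle.items()},
            u2_max={k: np.asarray(v) for k, v in rec_u2max.items()},
            u2_mean={k: np.asarray(v) for k, v in rec_u2mean.items()},
            perimeters={k: np.asarray(v) for k, v in rec_perim.items()},
            projection_lengths={k: np.asarray(v) for k, v in rec_proj.items()},
            distances={p: np.asarray(v) for p, v in rec_dist.items()},
            final_curves={c.id: c.curve.points.copy() for c in self.cells},
            clamp_events=clamp,
            seed=self.seed,
            config=cfg,
            snapshots=snapshots,
        )


def run_simulation(config: ScenarioConfig,
                   seed: Optional[int] = None) -> SimulationResult:
    """Run one simulation; deterministic given (config, seed)."""
    return Simulation(config, seed=seed).run()
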