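"""3D agent-based model of spheroid formation in a concave well.

Cells are modelled as Brownian hard spheres that sediment in a non-adhesive,
concave (liquid-overlay) well, bind on contact with probability ``p_bind``
per pair per step, and lose existing bonds with probability ``p_unbind`` per
bond per step. Bound clusters move rigidly with size-scaled mobility;
bonded neighbours relax toward contact distance (an overdamped spring), and
hard-sphere overlaps are resolved symmetrically. The curved floor converts
sedimentation into a centre-ward drift, which — together with diffusion and
binding — reproduces the aggregation → compaction phenomenology of
spheroid-formation assays.

Physics, in simulation units (µm, minutes):

* translational diffusion from Stokes–Einstein, D = kT / (6πηr), scaled by
  m^(-1/3) for a cluster of m cells (Stokes radius ∝ m^(1/3));
* sedimentation at the Stokes terminal velocity v = 2Δρ g r² / (9η), where
  the excess density Δρ (mg/ml) is the model's "buoyancy" parameter; a
  cluster of m cells sediments at v·m^(2/3) (buoyant force ∝ m, drag ∝
  m^(1/3));
* the well floor is a spherical cap; constraint violations are resolved by
  projection along the local surface normal, which yields the downhill
  (centre-ward) sliding of settled cells.

The model's readout is the area of the convex hull of the cell centres
projected to the x-y plane, normalised to its frame-0 value (NA), sampled on
a 30-min frame grid.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "SimulationConfig",
    "SimulationState",
    "SimulationTrace",
    "initialize",
    "step",
    "run",
    "normalized_hull_area",
    "hull_area_2d",
]

_KB = 1.380649e-23  # J/K
_G = 9.81  # m/s^2


@dataclass
class SimulationConfig:
    """Parameters of one simulation run.

    The three fitted parameters are ``p_bind``, ``p_unbind`` (per step at
    ``dt_minutes`` = 1 min; rescale as 1-(1-p)^(dt'/dt) when changing dt)
    and ``buoyancy_mg_ml`` (excess density of the cells over the medium).
    The remaining fields are fixed physical and geometric defaults.
    """

    n_cells: int = 50
    p_bind: float = 0.5
    p_unbind: float = 0.05
    buoyancy_mg_ml: float = 2.0
    cell_radius_um: float = 10.0
    dt_minutes: float = 1.0
    frame_every: int = 30
    n_frames: int = 97
    well_radius_um: float = 400.0
    floor_curvature_um: float = 20000.0
    spawn_radius_um: float = 330.0
    spawn_height_um: float = 120.0
    viscosity_pa_s: float = 1.0e-3
    temperature_k: float = 310.0
    diffusion_scale: float = 1.0
    spring_gain: float = 0.2
    contact_tol: float = 1.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_bind <= 1.0 and 0.0 <= self.p_unbind <= 1.0):
            raise ValueError("p_bind and p_unbind must lie in [0, 1]")
        if self.n_cells < 2:
            raise ValueError("need at least two cells")
        if self.buoyancy_mg_ml < 0:
            raise ValueError("buoyancy must be >= 0")
        if self.n_frames < 1 or self.frame_every < 1:
            raise ValueError("n_frames and frame_every must be >= 1")
        if self.spawn_radius_um + self.cell_radius_um > self.well_radius_um:
            raise ValueError("spawn region must fit inside the well radius")
        if self.well_radius_um >= self.floor_curvature_um:
            raise ValueError("floor curvature radius must exceed the well radius")

    # ---- derived physical quantities (µm, minutes) ----

    @property
    def diffusion_um2_per_min(self) -> float:
        r_m = self.cell_radius_um * 1e-6
        d_m2_s = _KB * self.temperature_k / (6.0 * np.pi * self.viscosity_pa_s * r_m)
        return self.diffusion_scale * d_m2_s * 1e12 * 60.0

    @property
    def sedimentation_um_per_min(self) -> float:
        r_m = self.cell_radius_um * 1e-6
        drho = self.buoyancy_mg_ml  # mg/ml == kg/m^3
        v_m_s = 2.0 * drho * _G * r_m**2 / (9.0 * self.viscosity_pa_s)
        return v_m_s * 1e6 * 60.0

    def duration_h(self) -> float:
        return (self.n_frames - 1) * self.frame_every * self.dt_minutes / 60.0


@dataclass
class SimulationState:
    """Mutable state advanced by :func:`step`."""

    positions: np.ndarray  # (n, 3) µm, well centre at x = y = 0, floor apex z = 0
    adjacency: np.ndarray  # (n, n) bool, symmetric, zero diagonal
    rng: np.random.Generator
    config: SimulationConfig
    step_count: int = 0

    @property
    def bonds(self) -> np.ndarray:
        """Current bonds as an (m, 2) array of agent index pairs (i < j)."""
        return np.argwhere(np.triu(self.adjacency, k=1))


def _floor_height(rho: np.ndarray, curvature: float) -> np.ndarray:
    """Height of the spherical-cap floor above its apex at radial distance rho."""
    return curvature - np.sqrt(curvature**2 - rho**2)


@lru_cache(maxsize=64)
def _upper_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Cached upper-triangle (i < j) index pair for n agents."""
    return np.triu_indices(n, k=1)


def _cluster_labels(n: int, pairs_i: np.ndarray, pairs_j: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Connected-component label per agent and component sizes (union-find)."""
    parent = list(range(n))

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    for i, j in zip(pairs_i.tolist(), pairs_j.tolist()):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri
    labels = np.empty(n, dtype=np.intp)
    label_of_root: dict[int, int] = {}
    sizes: list[int] = []
    for i in range(n):
        root = find(i)
        lab = label_of_root.get(root)
        if lab is None:
            lab = label_of_root[root] = len(sizes)
            sizes.append(0)
        labels[i] = lab
        sizes[lab] += 1
    return labels, np.asarray(sizes)


def initialize(config: SimulationConfig) -> SimulationState:
    """Place non-overlapping agents in suspension above the well floor."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.n_cells
    r = config.cell_radius_um
    positions = np.empty((n, 3))
    placed = 0
    attempts = 0
    max_attempts = 2000 * n
    while placed < n:
        if attempts >= max_attempts:
            raise ValueError(
                f"could not place {n} non-overlapping cells of radius {r} µm "
                f"in the spawn volume; reduce n_cells or enlarge the well"
            )
        attempts += 1
        rho = config.spawn_radius_um * np.sqrt(rng.random())
        theta = 2.0 * np.pi * rng.random()
        x, y = rho * np.cos(theta), rho * np.sin(theta)
        z = (
            _floor_height(np.asarray(rho), config.floor_curvature_um)
            + r
            + config.spawn_height_um * rng.random()
        )
        candidate = np.array([x, y, float(z)])
        if placed > 0:
            d2 = np.sum((positions[:placed] - candidate) ** 2, axis=1)
            if d2.min() < (2.0 * r) ** 2:
                continue
        positions[placed] = candidate
        placed += 1
    adjacency = np.zeros((n, n), dtype=bool)
    return SimulationState(positions=positions, adjacency=adjacency, rng=rng,
                           config=config)


def step(state: SimulationState) -> SimulationState:
    """Advance the state by one time step (in place; returns the state).

    Sub-steps, in order: rigid Brownian motion per cluster, sedimentation,
    bond-spring relaxation toward contact distance, symmetric hard-overlap
    resolution, wall/floor constraint projection, then stochastic binding of
    contacting unbound pairs and unbinding of pre-existing bonds.
    """
    cfg = state.config
    n = cfg.n_cells
    r = cfg.cell_radius_um
    dt = cfg.dt_minutes
    pos = state.positions
    adj = state.adjacency
    rng = state.rng

    iu = _upper_indices(n)
    bond_mask = adj[iu]
    bi_all, bj_all = iu[0][bond_mask], iu[1][bond_mask]
    labels, sizes = _cluster_labels(n, bi_all, bj_all)

    # (1) Brownian displacement, rigid per cluster, D ∝ m^(-1/3)
    sd = np.sqrt(2.0 * cfg.diffusion_um2_per_min * dt) * sizes ** (-1.0 / 6.0)
    noise = rng.standard_normal((len(sizes), 3)) * sd[:, None]
    pos += noise[labels]

    # (2) sedimentation, v ∝ m^(2/3)
    v = cfg.sedimentation_um_per_min * sizes ** (2.0 / 3.0)
    pos[:, 2] -= (v * dt)[labels]

    # (3) bonded neighbours relax toward contact distance 2r
    if len(bi_all) > 0:
        i, j = bi_all, bj_all
        delta = pos[j] - pos[i]
        dist = np.linalg.norm(delta, axis=1)
        dist = np.maximum(dist, 1e-9)
        corr = (cfg.spring_gain * 0.5 * (dist - 2.0 * r) / dist)[:, None] * delta
        np.add.at(pos, i, corr)
        np.add.at(pos, j, -corr)

    # (4) hard overlaps resolved by symmetric projection (one sweep)
    diff = pos[:, None, :] - pos[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    overlap = d2[iu] < (2.0 * r) ** 2
    if overlap.any():
        oi, oj = iu[0][overlap], iu[1][overlap]
        delta = pos[oj] - pos[oi]
        dist = np.maximum(np.sqrt(d2[iu][overlap]), 1e-9)
        push = (0.5 * (2.0 * r - dist) / dist)[:, None] * delta
        np.add.at(pos, oi, -push)
        np.add.at(pos, oj, push)

    # (5) wall and floor constraints
    rho = np.hypot(pos[:, 0], pos[:, 1])
    wall_max = cfg.well_radius_um - r
    outside = rho > wall_max
    if outside.any():
        scale = wall_max / rho[outside]
        pos[outside, 0] *= scale
        pos[outside, 1] *= scale
        rho[outside] = wall_max
    floor_z = _floor_height(rho, cfg.floor_curvature_um) + r
    pen = floor_z - pos[:, 2]
    below = pen > 0
    if below.any():
        rho_b = np.maximum(rho[below], 1e-9)
        slope = rho_b / np.sqrt(cfg.floor_curvature_um**2 - rho_b**2)
        gx = -slope * pos[below, 0] / rho_b
        gy = -slope * pos[below, 1] / rho_b
        norm2 = gx**2 + gy**2 + 1.0
        lam = pen[below] / norm2
        pos[below, 0] += lam * gx
        pos[below, 1] += lam * gy
        pos[below, 2] += lam

    if not np.isfinite(pos).all():
        raise FloatingPointError(
            f"non-finite agent positions at step {state.step_count + 1}"
        )

    # (6) stochastic binding of contacting unbound pairs, then unbinding of
    # the bonds that existed before this sub-step. Bond events are
    # independent Bernoulli draws per pair, so evaluation order is
    # immaterial and the draws are vectorised.
    diff = pos[:, None, :] - pos[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    contact2 = (cfg.contact_tol * 2.0 * r) ** 2
    cand_mask = ~adj[iu] & (d2[iu] <= contact2)
    ci, cj = iu[0][cand_mask], iu[1][cand_mask]
    bond_mask = adj[iu]
    ei, ej = iu[0][bond_mask], iu[1][bond_mask]
    if len(ci) > 0:
        formed = rng.random(len(ci)) < cfg.p_bind
        adj[ci[formed], cj[formed]] = True
        adj[cj[formed], ci[formed]] = True
    if len(ei) > 0:
        broken = rng.random(len(ei)) < cfg.p_unbind
        adj[ei[broken], ej[broken]] = False
        adj[ej[broken], ei[broken]] = False

    state.step_count += 1
    return state


@dataclass
class SimulationTrace:
    """Recorded output of one run: per-frame positions, bonds and NA."""

    positions: np.ndarray  # (n_frames, n_cells, 3) µm
    bonds: list  # per frame: (m, 2) int array
    config: SimulationConfig
    na: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def times_h(self) -> np.ndarray:
        per_frame_h = self.config.frame_every * self.config.dt_minutes / 60.0
        return np.arange(self.n_frames) * per_frame_h

    # ---- plain-text serialisation ----

    def to_csv(self, out_dir: str | Path) -> None:
        import pandas as pd

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        n_frames, n, _ = self.positions.shape
        frames = np.repeat(np.arange(n_frames), n)
        agents = np.tile(np.arange(n), n_frames)
        flat = self.positions.reshape(-1, 3)
        pd.DataFrame(
            {"frame": frames, "agent_id": agents,
             "x_um": flat[:, 0], "y_um": flat[:, 1], "z_um": flat[:, 2]}
        ).to_csv(out / "positions.csv", index=False, float_format="%.17g")
        rows = [
            (f, int(a), int(b))
            for f, bond_arr in enumerate(self.bonds)
            for a, b in np.asarray(bond_arr).reshape(-1, 2)
        ]
        pd.DataFrame(rows, columns=["frame", "id_a", "id_b"]).to_csv(
            out / "bonds.csv", index=False
        )
        pd.DataFrame({"frame": np.arange(n_frames), "time_h": self.times_h(),
                      "na": self.na}).to_csv(
            out / "na.csv", index=False, float_format="%.17g"
        )
        (out / "config.json").write_text(json.dumps(asdict(self.config), indent=2))

    @classmethod
    def from_csv(cls, out_dir: str | Path) -> "SimulationTrace":
        import pandas as pd

        out = Path(out_dir)
        config = SimulationConfig(**json.loads((out / "config.json").read_text()))
        pos_df = pd.read_csv(out / "positions.csv", float_precision="round_trip")
        n_frames = int(pos_df["frame"].max()) + 1
        n = int(pos_df["agent_id"].max()) + 1
        positions = (
            pos_df.sort_values(["frame", "agent_id"])[["x_um", "y_um", "z_um"]]
            .to_numpy()
            .reshape(n_frames, n, 3)
        )
        bonds_df = pd.read_csv(out / "bonds.csv")
        bonds = []
        for f in range(n_frames):
            sub = bonds_df[bonds_df["frame"] == f]
            bonds.append(sub[["id_a", "id_b"]].to_numpy(dtype=int).reshape(-1, 2))
        na = pd.read_csv(out / "na.csv", float_precision="round_trip")["na"].to_numpy()
        return cls(positions=positions, bonds=bonds, config=config, na=na)


def hull_area_2d(points: np.ndarray) -> float:
    """Area of the 2D convex hull of a point set (0 if degenerate)."""
    points = np.asarray(points, dtype=float)
    unique = np.unique(points, axis=0)
    if len(unique) < 3:
        return 0.0
    try:
        return float(ConvexHull(unique).volume)  # .volume is the area in 2D
    except QhullError:
        return 0.0  # collinear


def normalized_hull_area(trace_or_positions) -> np.ndarray:
    """Per-frame projected convex-hull area, normalised to frame 0.

    Agent centres are projected to the x-y plane; each frame's hull area is
    divided by the frame-0 hull area, so NA[0] = 1. Degenerate (collinear)
    frames yield area 0 with a warning; a degenerate frame 0 is an error.
    """
    positions = getattr(trace_or_positions, "positions", trace_or_positions)
    positions = np.asarray(positions, dtype=float)
    areas = np.array([hull_area_2d(frame[:, :2]) for frame in positions])
    if areas[0] <= 0:
        raise ValueError("frame 0 projection is degenerate; cannot normalise")
    if np.any(areas[1:] == 0):
        warnings.warn("degenerate (collinear) frame projections; hull area 0",
                      UserWarning, stacklevel=2)
    return areas / areas[0]


def run(config: SimulationConfig) -> SimulationTrace:
    """Execute a full simulation and attach its normalised-area series."""
    state = initialize(config)
    n_frames = config.n_frames
    positions = np.empty((n_frames, config.n_cells, 3))
    bonds: list[np.ndarray] = []
    positions[0] = state.positions
    bonds.append(state.bonds)
    for f in range(1, n_frames):
        for _ in range(config.frame_every):
            step(state)
        positions[f] = state.positions
        bonds.append(state.bonds)
    trace = SimulationTrace(positions=positions, bonds=bonds, config=config)
    trace.na = normalized_hull_area(trace)
    return trace
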