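"""Potential evaluation, reduced-unit Langevin / NVE dynamics, trajectory I/O
and accommodation / dissociation event detection.

Conventions: all masses are 1, k_B = 1, eps_0 = 1; temperature is given in
reduced units (the accommodation study runs at T = 0.5); the timestep default
is 0.002 tau_ru and one reduced time unit maps to roughly 1 ns.  The
thermostat is Langevin (BAOAB splitting) with a default friction of
1 / tau_ru.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile
from scipy.spatial.distance import pdist

from . import _kernels
from .containers import ObservableSeries, Trajectory
from .errors import (
    InstabilityError,
    IntegrityError,
    ParameterError,
    SingularityError,
)
from .forcefield import FLAVOR_V2, Topology
from .structures import Structure, to_atom_array

DEFAULT_TEMPERATURE = 0.5
DEFAULT_DT = 0.002
DEFAULT_FRICTION = 1.0
DEFAULT_STRIDE = 500
ACCOMMODATION_THRESHOLD = 32.5
RELEASE_THRESHOLD = 35.0
ENERGY_BOUND = 1e8


@dataclass
class EnergyBreakdown:
    """Per-term energies in eps_0, mirroring the potential term by term."""

    bonds: float
    angles: float
    impropers: float
    planar: float
    backbone_dihedrals: float
    sidechain_dihedrals: float
    contacts: float
    noncontacts: float

    @property
    def total(self) -> float:
        return (self.bonds + self.angles + self.impropers + self.planar
                + self.backbone_dihedrals + self.sidechain_dihedrals
                + self.contacts + self.noncontacts)


@dataclass
class EventRecord:
    """One accommodation or dissociation event."""

    kind: str                 # "accommodation" | "dissociation"
    entry_time: float         # tau_ru
    exit_time: float | None   # tau_ru, None if never released
    threshold: float          # A

    def __post_init__(self):
        if self.kind not in ("accommodation", "dissociation"):
            raise ParameterError(f"unknown event kind {self.kind!r}")
        if self.exit_time is not None and not self.exit_time > self.entry_time:
            raise IntegrityError("event exit must come after entry")


def _pack(topology: Topology):
    """Flatten a Topology into the arrays the kernels consume (cached)."""
    if "packed" in topology._cache:
        return topology._cache["packed"]
    bt = topology.bonded
    hdih_idx = np.vstack([bt.impropers_idx, bt.planars_idx]).astype(np.int64)
    hdih_x0 = np.concatenate([bt.impropers_x0, bt.planars_x0])
    hdih_k = np.concatenate([bt.impropers_k, bt.planars_k])
    hdih_comp = np.concatenate(
        [np.zeros(len(bt.impropers_idx), np.int64),
         np.ones(len(bt.planars_idx), np.int64)]
    )
    contacts = topology.contacts
    con_idx = np.array([[c.i, c.j] for c in contacts], np.int64).reshape(-1, 2)
    con_sig = np.array([c.sigma for c in contacts], float)
    con_eps = np.array([c.eps * c.weight for c in contacts], float)
    if topology.flavor == FLAVOR_V2:
        con_gw = np.asarray(topology.gauss_width, float)
        flavor = 2
    else:
        con_gw = np.ones(len(contacts), float)
        flavor = 1
    packed = (
        bt.bonds_idx.astype(np.int64), bt.bonds_r0.astype(float), bt.bonds_k.astype(float),
        bt.angles_idx.astype(np.int64), bt.angles_t0.astype(float), bt.angles_k.astype(float),
        hdih_idx, hdih_x0.astype(float), hdih_k.astype(float), hdih_comp,
        bt.propers_idx.astype(np.int64), bt.propers_p0.astype(float),
        bt.propers_k.astype(float), bt.propers_class.astype(np.int64),
        con_idx, con_sig, con_eps, con_gw,
        topology.noncontact_pairs().astype(np.int64),
        float(topology.eps_nc), float(topology.sigma_nc), flavor,
    )
    topology._cache["packed"] = packed
    return packed


def _check_coords(topology: Topology, coordinates: np.ndarray) -> np.ndarray:
    coord = np.ascontiguousarray(coordinates, dtype=float)
    if coord.shape != (topology.n_atoms, 3):
        raise IntegrityError(
            f"coordinate array {coord.shape} does not match roster "
            f"({topology.n_atoms} atoms)"
        )
    if topology.n_atoms >= 2 and topology.n_atoms <= 5000:
        if pdist(coord).min() < 1e-9:
            raise SingularityError("overlapping atoms (r = 0) in a 1/r term")
    return coord


def energy(topology: Topology, coordinates: np.ndarray) -> EnergyBreakdown:
    """Term-by-term potential energy at the given coordinates (eps_0)."""
    coord = _check_coords(topology, coordinates)
    f = np.empty_like(coord)
    ecomp = np.empty(_kernels.N_COMPONENTS)
    _kernels.eval_energy_forces(coord, *_pack(topology), f, ecomp)
    return EnergyBreakdown(*ecomp.tolist())


def forces(topology: Topology, coordinates: np.ndarray) -> np.ndarray:
    """-grad V, (n_atoms, 3), eps_0 / Angstrom."""
    coord = _check_coords(topology, coordinates)
    f = np.empty_like(coord)
    ecomp = np.empty(_kernels.N_COMPONENTS)
    _kernels.eval_energy_forces(coord, *_pack(topology), f, ecomp)
    return f


def run_langevin(
    topology: Topology,
    start: np.ndarray | Structure,
    n_steps: int,
    temperature: float = DEFAULT_TEMPERATURE,
    dt: float = DEFAULT_DT,
    friction: float = DEFAULT_FRICTION,
    seed: int = 0,
    stride: int = DEFAULT_STRIDE,
    stop_below: tuple[int, int, float] | None = None,
    energy_bound: float = ENERGY_BOUND,
) -> Trajectory:
    """Seeded Langevin (BAOAB) run; frames recorded every ``stride`` steps.

    ``stop_below = (i, j, d)`` ends the run at the first step where the i-j
    distance drops below d Angstrom (used for first-passage measurements);
    the stopping step is then available as ``Trajectory.stop_step``.
    """
    if n_steps < 1:
        raise ParameterError("n_steps must be >= 1")
    if stride < 1:
        raise ParameterError("stride must be >= 1")
    if temperature <= 0 or dt <= 0 or friction <= 0:
        raise ParameterError("temperature, dt and friction must be positive")
    coord = start.coord if isinstance(start, Structure) else start
    coord = _check_coords(topology, coord)
    if stop_below is None:
        pi, pj, thr = 0, 0, -1.0
    else:
        pi, pj, thr = int(stop_below[0]), int(stop_below[1]), float(stop_below[2])
    frames, times, nrec, stop_step, bad_step = _kernels.run_langevin_kernel(
        coord, int(n_steps), float(dt), float(temperature), float(friction),
        int(stride), int(seed), *_pack(topology), pi, pj, thr,
        float(energy_bound),
    )
    if bad_step >= 0:
        raise InstabilityError(
            f"energy diverged (|V| > {energy_bound:g}) at step {bad_step}",
            step=int(bad_step),
        )
    traj = Trajectory(
        frames[:nrec].copy(), times[:nrec].copy(),
        topology_hash=topology.content_hash(), seed=int(seed),
        stop_step=int(stop_step) if stop_step >= 0 else None,
    )
    return traj


def first_passage_steps(
    topology: Topology,
    start: np.ndarray | Structure,
    pair: tuple[int, int],
    threshold: float,
    max_steps: int,
    **kwargs,
) -> int | None:
    """Steps until the pair distance first drops below ``threshold``,
    or None if it does not happen within ``max_steps``."""
    traj = run_langevin(
        topology, start, n_steps=max_steps,
        stop_below=(pair[0], pair[1], threshold),
        stride=kwargs.pop("stride", 10_000), **kwargs,
    )
    return traj.stop_step


def run_nve(
    topology: Topology,
    start: np.ndarray | Structure,
    n_steps: int,
    dt: float = DEFAULT_DT,
    stride: int = 100,
    velocities: np.ndarray | None = None,
    energy_bound: float = ENERGY_BOUND,
) -> tuple[Trajectory, ObservableSeries]:
    """Velocity-Verlet microcanonical run (integrator verification harness).

    Returns the trajectory and the total-energy series; with the default
    timestep the drift stays below 1e-4 eps_0 per degree of freedom over
    1e5 steps.
    """
    if n_steps < 1:
        raise ParameterError("n_steps must be >= 1")
    coord = start.coord if isinstance(start, Structure) else start
    coord = _check_coords(topology, coord)
    vel = np.zeros_like(coord) if velocities is None \
        else np.ascontiguousarray(velocities, float)
    if vel.shape != coord.shape:
        raise IntegrityError("velocities shape mismatch")
    frames, times, energies, nrec, bad_step = _kernels.run_nve_kernel(
        coord, vel, int(n_steps), float(dt), int(stride), *_pack(topology),
        float(energy_bound),
    )
    if bad_step >= 0:
        raise InstabilityError(
            f"energy diverged at step {bad_step}", step=int(bad_step)
        )
    traj = Trajectory(frames[:nrec].copy(), times[:nrec].copy(),
                      topology_hash=topology.content_hash())
    eseries = ObservableSeries("total_energy", energies[:nrec].copy(),
                               times[:nrec].copy(), units="eps_0")
    return traj, eseries


# ---------------------------------------------------------------------------
# event detection

def detect_accommodation_events(
    series: ObservableSeries,
    threshold: float = ACCOMMODATION_THRESHOLD,
    release: float = RELEASE_THRESHOLD,
) -> list[EventRecord]:
    """Accommodation events: the probe distance drops below ``threshold``
    (32.5 A in the accommodation study).  Hysteresis: after an event opens it
    closes only once the series rises above ``release``, so boundary jitter
    is not double counted."""
    if len(series) == 0:
        raise ParameterError("empty series")
    if release < threshold:
        raise ParameterError("release must be >= threshold")
    events: list[EventRecord] = []
    open_entry: float | None = None
    for t, v in zip(series.times, series.values):
        if open_entry is None:
            if v < threshold:
                open_entry = float(t)
        else:
            if v > release:
                events.append(EventRecord("accommodation", open_entry, float(t),
                                          threshold))
                open_entry = None
    if open_entry is not None:
        events.append(EventRecord("accommodation", open_entry, None, threshold))
    return events


def detect_dissociation(
    series: ObservableSeries,
    threshold: float = 60.0,
    window: int = 10,
    accommodation_threshold: float = ACCOMMODATION_THRESHOLD,
) -> EventRecord | None:
    """Dissociation: the probe distance stays above ``threshold`` for
    ``window`` consecutive frames before any accommodation event.  The 60 A
    default exceeds the A/T endpoint value (~57 A) so only genuine departures
    trigger."""
    if len(series) == 0:
        raise ParameterError("empty series")
    if window < 1:
        raise ParameterError("window must be >= 1")
    run_start = None
    run_len = 0
    for t, v in zip(series.times, series.values):
        if v < accommodation_threshold:
            return None
        if v > threshold:
            if run_len == 0:
                run_start = float(t)
            run_len += 1
            if run_len >= window:
                return EventRecord("dissociation", run_start, None, threshold)
        else:
            run_len = 0
            run_start = None
    return None


# ---------------------------------------------------------------------------
# trajectory I/O: plain-text table and multi-model PDB

def write_trajectory_tsv(trajectory: Trajectory, path: str) -> None:
    """Flat table: frame, atom, x, y, z, time_tau_ru (tab-separated)."""
    nf, na, _ = trajectory.frames.shape
    df = pd.DataFrame({
        "frame": np.repeat(np.arange(nf), na),
        "atom": np.tile(np.arange(na), nf),
        "x": trajectory.frames[:, :, 0].ravel(),
        "y": trajectory.frames[:, :, 1].ravel(),
        "z": trajectory.frames[:, :, 2].ravel(),
        "time_tau_ru": np.repeat(trajectory.times, na),
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_trajectory_tsv(path: str) -> Trajectory:
    df = pd.read_csv(path, sep="\t")
    nf = int(df["frame"].max()) + 1
    na = int(df["atom"].max()) + 1
    if len(df) != nf * na:
        raise IntegrityError(f"{path}: incomplete frames")
    frames = df[["x", "y", "z"]].to_numpy().reshape(nf, na, 3)
    times = df["time_tau_ru"].to_numpy().reshape(nf, na)[:, 0]
    return Trajectory(frames, times)


def write_trajectory_pdb(trajectory: Trajectory, template: Structure,
                         path: str) -> None:
    """Multi-model PDB; ``template`` supplies the atom naming."""
    if len(template) != trajectory.n_atoms:
        raise IntegrityError("template atom count does not match trajectory")
    arr = to_atom_array(template)
    stack = bst.stack([arr] * len(trajectory))
    stack.coord = trajectory.frames.astype(np.float32)
    f = PDBFile()
    f.set_structure(stack)
    f.write(path)


def read_trajectory_pdb(path: str, dt_per_model: float = 1.0) -> Trajectory:
    f = PDBFile.read(path)
    stack = f.get_structure()
    frames = np.asarray(stack.coord, float)
    times = np.arange(len(frames)) * dt_per_model
    return Trajectory(frames, times)


def read_trajectory(path: str) -> Trajectory:
    """Sniff the format (multi-model PDB or flat table) and read."""
    with open(path) as fh:
        head = fh.read(64)
    if head.startswith(("MODEL", "ATOM", "HETATM", "CRYST", "REMARK")):
        return read_trajectory_pdb(path)
    return read_trajectory_tsv(path)
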