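"""Seeded toy systems and analytic fixtures.

The central fixture is a two-state "arm" system that mimics the geometry of
aa-tRNA accommodation at desk scale: a rigid scaffold (the ribosome frame)
carries an articulated multi-bead arm (the tRNA) attached by a free hinge.
Two endpoint conformations are defined -- state A with the arm raised (the
A/T-like position) and state B with the arm rotated 90 degrees into a binding
pocket (the A/A-like position).  A probe pair plays the role of R_elbow: its
distance is d_A (57 A by default) in state A and d_B (32 A) in state B,
mirroring the endpoint values of the accommodation coordinate.  Each endpoint
has its own native-contact set (a small cradle holds state A; a 10-bead
pocket receives the arm in state B), so the dual-basin potential built from
the two maps produces transitions whose balance is titrated by the A/A
contact weight.  An optional 3-bead steric gate sits on the rotation path
(the H89 analogue): the straight-line interpolation from A to B clashes with
it, so the arm must detour around it.

Beads are single-atom residues (element C) spaced 4 A; the scaffold is held
rigid by a braced bond network, while arm-internal angles and dihedrals keep
the arm a semi-rigid zig-zag rod.  The hinge carries no angular term, so the
basin preference comes from the contacts alone.

Analytic fixtures (rigid-rotation trajectories, two-state Markov series and
i.i.d. Gaussian draws) provide exact oracles for the observable and
statistics layers.  All generators are pure functions of their parameters and
seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .containers import ObservableSeries, Trajectory
from .errors import ParameterError
from .forcefield import (
    BondedTerms,
    FLAVOR_V1,
    FLAVOR_V2,
    Topology,
    build_bonded_terms,
    build_contact_map,
    gaussianize_contacts,
    merge_dual_basin,
)
from .observables import PairRegistry
from .structures import AtomSet, AtomSpec, Structure

BEAD_SPACING = 4.0        # A, arm bond length / excluded-volume scale
CRADLE_OFFSET = 4.1       # A, state-A cradle distance
POCKET_OFFSET = 3.8       # A, state-B pocket distance
GATE_HALF_SPACING = 3.0   # A, gate bead spacing along y
SCAFFOLD_JITTER = 0.15    # A per axis, breaks collinearity deterministically
EPS_PLANARIZE = 2.5       # eps_0, per planarizing hinge-angle term


@dataclass
class TwoStateSystem:
    """Two endpoint conformations of the toy arm plus bookkeeping."""

    state_A: Structure
    state_B: Structure
    arm: AtomSet
    scaffold: AtomSet
    gate: AtomSet
    probe_pair: tuple[AtomSpec, AtomSpec]
    d_A: float
    d_B: float
    connectivity: list[tuple[int, int]]
    registry: PairRegistry
    seed: int

    @property
    def probe_indices(self) -> tuple[int, int]:
        return (self.state_A.index_of(self.probe_pair[0]),
                self.state_A.index_of(self.probe_pair[1]))


@dataclass
class MarkovSeriesParams:
    """Two-state Gaussian-noise Markov chain (fixture for the landscape and
    convergence statistics).  Stationary occupancy of state A is
    p_BA / (p_AB + p_BA)."""

    mean_a: float = 57.0
    mean_b: float = 32.0
    sd: float = 0.8
    p_ab: float = 0.01      # per-step switching probability A -> B
    p_ba: float = 0.01
    length: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.p_ab < 1 and 0 < self.p_ba < 1):
            raise ParameterError("switching probabilities must lie in (0, 1)")
        if self.sd < 0:
            raise ParameterError("noise sd must be non-negative")
        if self.length < 1:
            raise ParameterError("length must be >= 1")


def _rotate_to_b(coord: np.ndarray) -> np.ndarray:
    """Rigid 90-degree rotation about y through the origin: +z -> +x."""
    out = np.empty_like(coord)
    out[:, 0] = coord[:, 2]
    out[:, 1] = coord[:, 1]
    out[:, 2] = -coord[:, 0]
    return out


def _solve_probe(tip_a: np.ndarray, tip_b: np.ndarray, d_a: float,
                 d_b: float) -> np.ndarray:
    """Point in the y = 0 plane at distance d_a from tip_a and d_b from
    tip_b (the solution farther from the origin)."""
    c1 = np.array([tip_a[0], tip_a[2]])
    c2 = np.array([tip_b[0], tip_b[2]])
    d = float(np.linalg.norm(c2 - c1))
    if not (abs(d_a - d_b) < d < d_a + d_b):
        raise ParameterError(
            f"probe distances (d_A={d_a}, d_B={d_b}) are geometrically "
            f"infeasible for tip separation {d:.1f} A"
        )
    a = (d_a ** 2 - d_b ** 2 + d ** 2) / (2 * d)
    h = float(np.sqrt(d_a ** 2 - a ** 2))
    u = (c2 - c1) / d
    base = c1 + a * u
    perp = np.array([-u[1], u[0]])
    cands = [base + h * perp, base - h * perp]
    best = max(cands, key=lambda p: float(np.linalg.norm(p)))
    return np.array([best[0], 0.0, best[1]])


def make_two_state_arm(
    n_arm_beads: int = 8,
    d_A: float = 57.0,
    d_B: float = 32.0,
    gate: bool = True,
    seed: int = 0,
) -> TwoStateSystem:
    """Build the two endpoint structures of the toy accommodation system.

    Deterministic for a fixed seed (the seed jitters scaffold bead positions
    to break exact collinearity).  Both endpoints share the atom roster and
    differ only in the arm coordinates.
    """
    if n_arm_beads < 4:
        raise ParameterError("n_arm_beads must be >= 4")
    if not (d_A > d_B > 0):
        raise ParameterError("require d_A > d_B > 0")
    if d_B < BEAD_SPACING:
        raise ParameterError(
            f"d_B = {d_B} is below the bead excluded-volume scale "
            f"({BEAD_SPACING} A)"
        )
    rng = np.random.default_rng(seed)
    n = int(n_arm_beads)
    dx = 0.35
    dzs = float(np.sqrt(BEAD_SPACING ** 2 - (2 * dx) ** 2))

    arm_a = np.array([[(-1.0) ** k * dx, 0.0, k * dzs] for k in range(1, n + 1)])
    arm_b = _rotate_to_b(arm_a)
    tip_a, tip_b = arm_a[-1], arm_b[-1]

    anchor = np.zeros(3)
    # y-axis beads flanking the hinge; weak angle terms to the arm base keep
    # the arm near the rotation plane without biasing either basin (the
    # reference angle is 90 degrees at every in-plane rotation angle)
    yaxis = np.array([[0.0, BEAD_SPACING, 0.0], [0.0, -BEAD_SPACING, 0.0]])
    # one contact-range cradle bead defines the (shallow) A basin; the second
    # bead only braces the frame and sits outside contact range
    cradle = np.array([arm_a[-1] + [-CRADLE_OFFSET, 0, 0],
                       arm_a[-2] + [-CRADLE_OFFSET - 1.4, 0, 0]])
    pocket_rows = []
    pocket_ids = list(range(max(0, n - 5), n))  # up to the last 5 arm beads
    for k in pocket_ids:
        pocket_rows.append(arm_b[k] + [0, 0, -POCKET_OFFSET])
    for k in pocket_ids:
        pocket_rows.append(arm_b[k] + [0, POCKET_OFFSET, 0])
    pocket = np.array(pocket_rows)
    # permanent wall closing the backward (long-way-around) rotation path, so
    # the corridor between the endpoints is the only route; present with and
    # without the gate
    w0 = 7.5 * np.array([-np.sqrt(0.5), 0.0, np.sqrt(0.5)])
    wall = np.array([w0 + [0, -GATE_HALF_SPACING, 0], w0,
                     w0 + [0, GATE_HALF_SPACING, 0]])
    probe = _solve_probe(tip_a, tip_b, d_A, d_B)

    jitter = rng.uniform(-SCAFFOLD_JITTER, SCAFFOLD_JITTER, (len(cradle) + len(pocket), 3))
    cradle = cradle + jitter[: len(cradle)]
    pocket = pocket + jitter[len(cradle):]

    scaffold_coords = [anchor, yaxis[0], yaxis[1], cradle[0], cradle[1],
                       *pocket, *wall, probe]
    if gate:
        # mid-path obstacle: pushed out along the bead-2 chord midpoint so it
        # clashes with the Cartesian A->B interpolation but touches neither
        # endpoint except for one grazing contact with the arm base in state B
        g0 = 1.18 * 0.5 * (arm_a[1] + arm_b[1])
        gate_coords = np.array([g0 + [0, -GATE_HALF_SPACING, 0], g0,
                                g0 + [0, GATE_HALF_SPACING, 0]])
    else:
        gate_coords = np.zeros((0, 3))

    ns = len(scaffold_coords)
    ng = len(gate_coords)
    coords_a = np.vstack([scaffold_coords, gate_coords, arm_a])
    coords_b = np.vstack([scaffold_coords, gate_coords, arm_b])

    chain = ["S"] * ns + ["G"] * ng + ["A"] * n
    res_id = list(range(1, ns + 1)) + list(range(1, ng + 1)) + list(range(1, n + 1))
    res_name = (["ANC"] + ["YAX"] * 2 + ["CRA"] * 2 + ["POC"] * len(pocket)
                + ["WAL"] * 3 + ["PRB"] + ["GAT"] * ng + ["ARM"] * n)
    atom_name = ["C1"] * (ns + ng + n)
    element = ["C"] * (ns + ng + n)

    state_a = Structure(chain, res_id, res_name, atom_name, element, coords_a)
    state_b = Structure(chain, res_id, res_name, atom_name, element, coords_b)

    # scaffold + gate bond network: each bead bonds its nearest already-placed
    # neighbours (up to 4), which braces the frame rigid without angle terms
    rigid = np.vstack([scaffold_coords, gate_coords])
    connectivity: list[tuple[int, int]] = []
    for m in range(1, len(rigid)):
        dists = np.linalg.norm(rigid[:m] - rigid[m], axis=1)
        for prev in np.argsort(dists)[: min(4, m)]:
            connectivity.append((int(prev), m))
    arm0 = ns + ng
    connectivity.append((0, arm0))                      # hinge: anchor - arm base
    connectivity += [(arm0 + k, arm0 + k + 1) for k in range(n - 1)]

    arm_set = AtomSet(np.arange(arm0, arm0 + n))
    scaffold_set = AtomSet(np.arange(0, ns))
    gate_set = AtomSet(np.arange(ns, ns + ng))
    probe_spec = AtomSpec("S", ns, "C1")                # probe bead is last in S
    tip_spec = AtomSpec("A", n, "C1")
    registry = PairRegistry({"R_elbow": (probe_spec, tip_spec)})

    system = TwoStateSystem(
        state_A=state_a, state_B=state_b, arm=arm_set, scaffold=scaffold_set,
        gate=gate_set, probe_pair=(probe_spec, tip_spec),
        d_A=float(d_A), d_B=float(d_B), connectivity=connectivity,
        registry=registry, seed=int(seed),
    )
    # internal consistency: the probe solver must hit the requested distances
    i, j = system.probe_indices
    for st, d in ((state_a, d_A), (state_b, d_B)):
        got = float(np.linalg.norm(st.coord[j] - st.coord[i]))
        if abs(got - d) > 0.01:
            raise ParameterError(
                f"probe placement failed: {got:.3f} A vs requested {d} A"
            )
    return system


def _restrict_to_arm(bonded: BondedTerms, arm_indices: np.ndarray,
                     anchor: int) -> BondedTerms:
    """Keep only hinge-neutral angle/dihedral terms.

    The scaffold is braced by its bond network alone.  Arm-internal terms are
    kept, as are terms where the anchor appears only as an *end* atom
    (e.g. the angle anchor-a1-a2): those are invariant under rigid rotation
    of the arm about the anchor, so they stiffen the rod without preferring
    either basin.  Terms coupling the arm direction to the scaffold frame
    (anchor as an inner atom) are dropped -- the hinge itself is free.
    """
    arm = set(int(i) for i in arm_indices)

    def keep_angle(row):
        i, j, k = (int(v) for v in row)
        if all(v in arm for v in (i, j, k)):
            return True
        return j in arm and {i, k} <= arm | {anchor}

    def keep_proper(row):
        i, j, k, l = (int(v) for v in row)
        if all(v in arm for v in (i, j, k, l)):
            return True
        return j in arm and k in arm and {i, l} <= arm | {anchor}

    def mask(idx, keep):
        if len(idx) == 0:
            return np.zeros(0, bool)
        return np.array([keep(row) for row in idx])

    ma = mask(bonded.angles_idx, keep_angle)
    mp = mask(bonded.propers_idx, keep_proper)
    return BondedTerms(
        bonded.bonds_idx, bonded.bonds_r0, bonded.bonds_k,
        bonded.angles_idx[ma], bonded.angles_t0[ma], bonded.angles_k[ma],
        bonded.impropers_idx, bonded.impropers_x0, bonded.impropers_k,
        bonded.planars_idx, bonded.planars_x0, bonded.planars_k,
        bonded.propers_idx[mp], bonded.propers_p0[mp], bonded.propers_k[mp],
        bonded.propers_class[mp],
    )


def _add_planarizer(bonded: BondedTerms, system: TwoStateSystem) -> BondedTerms:
    """Weak hinge angles (y-axis bead, anchor, arm base) at 90 degrees.

    Both terms are invariant under in-plane rotation of the arm, so they
    confine the transition path near the rotation plane -- where the gate
    sits -- without preferring either basin.
    """
    coord = system.state_A.coord
    anchor = int(system.scaffold.indices[0])
    yax = [i for i in system.scaffold.indices
           if system.state_A.res_name[i] == "YAX"]
    new_idx, new_t0 = [], []
    for y in yax:
        for a in system.arm.indices:
            u = coord[int(y)] - coord[anchor]
            v = coord[int(a)] - coord[anchor]
            t0 = float(np.arccos(np.clip(
                np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)))
            new_idx.append((int(y), anchor, int(a)))
            new_t0.append(t0)
    return BondedTerms(
        bonded.bonds_idx, bonded.bonds_r0, bonded.bonds_k,
        np.vstack([bonded.angles_idx, np.array(new_idx, int).reshape(-1, 3)]),
        np.concatenate([bonded.angles_t0, new_t0]),
        np.concatenate([bonded.angles_k, np.full(len(new_idx), EPS_PLANARIZE)]),
        bonded.impropers_idx, bonded.impropers_x0, bonded.impropers_k,
        bonded.planars_idx, bonded.planars_x0, bonded.planars_k,
        bonded.propers_idx, bonded.propers_p0, bonded.propers_k,
        bonded.propers_class,
    )


def two_state_topology(
    system: TwoStateSystem,
    weight_AA: float = 0.13,
    flavor: str = FLAVOR_V1,
    gauss_width: float = 0.5,
) -> Topology:
    """Dual-basin topology of the toy system (reference geometry: state A)."""
    import warnings as _warnings

    with _warnings.catch_warnings():
        # the braced scaffold contains exactly collinear bonded quadruplets;
        # their (skipped) dihedrals are filtered out below anyway
        _warnings.simplefilter("ignore")
        bonded = build_bonded_terms(
            system.state_A, system.connectivity,
            classify=lambda names: "backbone",
        )
    bonded = _restrict_to_arm(bonded, system.arm.indices,
                              anchor=int(system.scaffold.indices[0]))
    bonded = _add_planarizer(bonded, system)
    contacts_at = build_contact_map(system.state_A, bonded=bonded)
    contacts_aa = build_contact_map(system.state_B, bonded=bonded)
    merged = merge_dual_basin(contacts_at, contacts_aa, weight_AA,
                              n_atoms=len(system.state_A))
    top = Topology(
        n_atoms=len(system.state_A), bonded=bonded, contacts=merged,
        flavor=FLAVOR_V1,
        provenance={"system": "two-state-arm", "seed": system.seed,
                    "weight_AA": weight_AA},
    )
    if flavor == FLAVOR_V2:
        top = gaussianize_contacts(top, gauss_width)
    elif flavor != FLAVOR_V1:
        raise ParameterError(f"unknown flavor {flavor!r}")
    return top


def make_rotation_series(
    structure: Structure,
    axis: np.ndarray,
    angles: np.ndarray | list[float],
) -> Trajectory:
    """Trajectory whose frame k is the structure rigidly rotated by
    angles[k] degrees about ``axis`` through the structure centroid
    (exact oracle for the pivot-angle observable)."""
    axis = np.asarray(axis, float)
    nrm = float(np.linalg.norm(axis))
    if nrm < 1e-12:
        raise ParameterError("rotation axis must be non-zero")
    if len(structure) == 0:
        raise ParameterError("structure must be non-empty")
    axis = axis / nrm
    centroid = structure.coord.mean(axis=0)
    frames = []
    for ang in angles:
        rot = Rotation.from_rotvec(np.radians(float(ang)) * axis)
        frames.append(rot.apply(structure.coord - centroid) + centroid)
    return Trajectory(np.array(frames), np.arange(len(frames), dtype=float))


def sample_markov_series(params: MarkovSeriesParams) -> ObservableSeries:
    """Seeded two-state Markov chain with Gaussian measurement noise."""
    rng = np.random.default_rng(params.seed)
    u = rng.random(params.length)
    states = np.empty(params.length, dtype=np.int8)
    # start from the stationary distribution so occupancies are unbiased
    pi_a = params.p_ba / (params.p_ab + params.p_ba)
    state = 0 if rng.random() < pi_a else 1
    for t in range(params.length):
        states[t] = state
        if state == 0:
            if u[t] < params.p_ab:
                state = 1
        else:
            if u[t] < params.p_ba:
                state = 0
    means = np.where(states == 0, params.mean_a, params.mean_b)
    noise = rng.normal(0.0, params.sd, params.length) if params.sd > 0 else 0.0
    return ObservableSeries(
        "markov", means + noise, np.arange(params.length, dtype=float), units="A"
    )


def sample_gaussian(mean: float, sd: float, n: int, seed: int) -> ObservableSeries:
    """Seeded i.i.d. normal draws (fixture for the Gaussian-fit statistic)."""
    if sd <= 0:
        raise ParameterError("sd must be positive")
    if n < 2:
        raise ParameterError("n must be >= 2")
    rng = np.random.default_rng(seed)
    return ObservableSeries(
        "gaussian", rng.normal(mean, sd, int(n)),
        np.arange(int(n), dtype=float), units="A",
    )


def _aa_contact_arrays(topology: Topology):
    aa = [c for c in topology.contacts if c.basin == "AA"]
    ii = np.array([c.i for c in aa], int)
    jj = np.array([c.j for c in aa], int)
    sig = np.array([c.sigma for c in aa], float)
    eps = np.array([c.eps for c in aa], float)
    return ii, jj, sig, eps


def titrate_basin_occupancy(
    system: TwoStateSystem,
    weights=(0.05, 0.1, 0.13, 0.2, 0.4),
    reference_weight: float = 0.13,
    n_steps: int = 4_000_000,
    seeds=(101, 202, 303, 404),
    temperature: float = 0.5,
    friction: float = 0.2,
    stride: int = 500,
    formed_ratio: float = 1.3,
    burn_in: float = 0.1,
) -> dict[float, float]:
    """Basin-B occupancy (mean formed fraction of A/A contacts) vs weight.

    The ensemble is sampled at ``reference_weight`` (the titration balance
    point of the accommodation study) with replicas started alternately from
    the two endpoint structures, so the estimate does not hinge on rare
    spontaneous barrier crossings.  Because the A/A contact term is exactly
    linear in the weight, the occupancy at every other weight follows by
    exponential (free-energy-perturbation) reweighting of the same frames:

        <Q>_w = sum_f Q_f exp(-(w - w_ref) U_f / T) / sum_f exp(...)

    where U_f is the unit-weight A/A contact energy of frame f.  Lower
    friction than the thermostat default is used to decorrelate the slow
    rigid-rotation mode; equilibrium averages are friction-independent.
    """
    from . import dynamics  # deferred: dynamics pulls in the JIT kernels

    top = two_state_topology(system, weight_AA=reference_weight)
    ii, jj, sig, eps = _aa_contact_arrays(top)
    q_frames, u_frames = [], []
    starts = (system.state_A, system.state_B)
    for k, seed in enumerate(seeds):
        traj = dynamics.run_langevin(
            top, starts[k % 2].coord, n_steps=n_steps, temperature=temperature,
            friction=friction, seed=int(seed), stride=stride,
        )
        skip = int(burn_in * len(traj))
        frames = traj.frames[skip:]
        d = np.linalg.norm(frames[:, jj] - frames[:, ii], axis=2)
        q_frames.append((d < formed_ratio * sig).mean(axis=1))
        sr6 = (sig / d) ** 6
        u_frames.append((eps * (sr6 * sr6 - 2.0 * sr6)).sum(axis=1))
    q = np.concatenate(q_frames)
    u = np.concatenate(u_frames)
    out = {}
    for w in weights:
        logw = -(float(w) - reference_weight) * u / temperature
        logw -= logw.max()
        fw = np.exp(logw)
        out[float(w)] = float(np.sum(fw * q) / np.sum(fw))
    return out


def gate_mfpt_comparison(
    n_replicates: int = 20,
    weight_AA: float = 0.4,
    threshold: float = 32.5,
    max_steps: int = 1_200_000,
    temperature: float = 0.5,
    friction: float = 0.2,
    system_seed: int = 1,
    first_seed: int = 1,
) -> dict:
    """Mean first-passage steps into the seated basin, with vs without the
    steric gate, over paired seeds.

    First passage is the first step at which the probe distance drops below
    the accommodation rule (32.5 A).  Runs that do not arrive within
    ``max_steps`` are counted at the cap (a lower bound on their true first
    passage, which only makes the gate/no-gate comparison conservative).
    """
    from . import dynamics

    out = {}
    for label, gate in (("no_gate", False), ("gate", True)):
        system = make_two_state_arm(gate=gate, seed=system_seed)
        top = two_state_topology(system, weight_AA=weight_AA)
        pair = system.probe_indices
        fps, censored = [], 0
        for k in range(n_replicates):
            steps = dynamics.first_passage_steps(
                top, system.state_A.coord, pair, threshold,
                max_steps=max_steps, temperature=temperature,
                friction=friction, seed=first_seed + k,
            )
            if steps is None:
                censored += 1
                steps = max_steps
            fps.append(int(steps))
        out[label] = {"first_passage_steps": fps,
                      "mean": float(np.mean(fps)), "censored": censored}
    out["mfpt_ratio"] = out["gate"]["mean"] / out["no_gate"]["mean"]
    return out


def write_manifest(system: TwoStateSystem, path: str) -> None:
    """JSON sidecar describing a written fixture (probe specs, groups,
    connectivity) so a topology can be rebuilt from the PDB pair."""
    doc = {
        "kind": "two-state-arm",
        "seed": system.seed,
        "d_A": system.d_A,
        "d_B": system.d_B,
        "probe_pair": [list(system.probe_pair[0]), list(system.probe_pair[1])],
        "arm": [int(i) for i in system.arm.indices],
        "scaffold": [int(i) for i in system.scaffold.indices],
        "gate": [int(i) for i in system.gate.indices],
        "connectivity": [[int(a), int(b)] for a, b in system.connectivity],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
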