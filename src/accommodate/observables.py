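"""Reaction coordinates and structural measurements on trajectories.

The accommodation study tracks the aa-tRNA through named pair distances
(R_elbow between the O3' atoms of U60/U8 of the aa- and peptidyl-tRNA, R_CCA
between the A76 O3' atoms, R_rolling, R_swi-DIII, R_swi-CCA, R_swi-elbow and
the A35-C61 tRNA compression), the pivot angle theta_tRNA of the plane spanned
by the O3' atoms of C4, A35 and G56 relative to the first frame, per-residue
contact occupancy within 4 A, and the solvent-accessible surface area of the
tRNA in the accommodation corridor.

All observables are invariant under global rotation and translation of every
frame; theta uses the first frame as its internal reference.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import biotite.structure as bst
from scipy.spatial.distance import cdist

from .containers import ObservableSeries, Trajectory
from .errors import GeometryError, ParameterError
from .structures import AtomSet, AtomSpec, Structure, to_atom_array

#: probe-pair registry entries used throughout the study; values are
#: (AtomSpec, AtomSpec).  Chains differ between deposited models, so concrete
#: registries are built per system (see ``make_registry``).
STANDARD_PAIR_NAMES = (
    "R_elbow",      # aa-tRNA U60 O3'  --  P-tRNA U8 O3'
    "R_CCA",        # aa-tRNA A76 O3'  --  P-tRNA A76 O3'
    "R_rolling",    # h14 A465 O3'     --  SRL U4559 O3'
    "R_swi-DIII",   # eEF1A R69 CA     --  eEF1A A425 CA
    "R_swi-CCA",    # eEF1A R69 CA     --  aa-tRNA A76 O3'
    "R_swi-elbow",  # eEF1A K378 CA    --  aa-tRNA U55 O3'
    "R_compression",  # aa-tRNA A35 O3' -- aa-tRNA C61 O3'
)

#: per-element van-der-Waals radii (A) for SASA
SASA_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80, "S": 1.80, "H": 1.20}


class PairRegistry(dict):
    """Mapping observable name -> (AtomSpec, AtomSpec)."""

    def validate(self, structure: Structure) -> None:
        for name, (a, b) in self.items():
            structure.index_of(AtomSpec(*a))
            structure.index_of(AtomSpec(*b))


def make_registry(pairs: Mapping[str, tuple] ) -> PairRegistry:
    return PairRegistry({k: (AtomSpec(*a), AtomSpec(*b))
                         for k, (a, b) in pairs.items()})


def _resolve_pair(structure, name_or_pair, registry):
    if isinstance(name_or_pair, str):
        if registry is None or name_or_pair not in registry:
            raise ParameterError(
                f"observable {name_or_pair!r} not present in the registry"
            )
        a, b = registry[name_or_pair]
        label = name_or_pair
    else:
        a, b = name_or_pair
        label = "distance"
    return structure.index_of(AtomSpec(*a)), structure.index_of(AtomSpec(*b)), label


def pair_distance_series(
    trajectory: Trajectory,
    structure: Structure,
    name_or_pair,
    registry: PairRegistry | None = None,
) -> ObservableSeries:
    """Per-frame Euclidean distance (A) between a registered atom pair."""
    i, j, label = _resolve_pair(structure, name_or_pair, registry)
    d = np.linalg.norm(trajectory.frames[:, j] - trajectory.frames[:, i], axis=1)
    return ObservableSeries(label, d, trajectory.times, units="A")


def theta_series(
    trajectory: Trajectory,
    structure: Structure,
    plane_atoms: Sequence[AtomSpec | tuple],
    reference: int = 0,
    sign_axis: np.ndarray | None = None,
) -> ObservableSeries:
    """Signed pivot angle (degrees) of the plane spanned by three atoms.

    A normal vector to the plane of the three atoms is computed per frame and
    compared against the normal in the ``reference`` frame (which maps to 0
    degrees).  The sign is the sign of the projection of
    (reference normal x current normal) onto ``sign_axis``; by default the
    sign axis is the reference-frame vector from the second plane atom to the
    third (anticodon -> elbow for the C4/A35/G56 convention), making a pivot
    toward that direction positive.
    """
    if len(plane_atoms) != 3:
        raise ParameterError("theta_series needs exactly 3 plane atoms")
    idx = [structure.index_of(AtomSpec(*s)) for s in plane_atoms]
    if not (0 <= reference < len(trajectory)):
        raise ParameterError(f"reference frame {reference} out of range")

    def normal(frame_no):
        p = trajectory.frames[frame_no, idx]
        n = np.cross(p[1] - p[0], p[2] - p[0])
        nn = np.linalg.norm(n)
        if nn < 1e-9:
            raise GeometryError(f"plane atoms collinear in frame {frame_no}")
        return n / nn

    n_ref = normal(reference)
    if sign_axis is None:
        p = trajectory.frames[reference, idx]
        sign_axis = p[2] - p[1]
    axis = np.asarray(sign_axis, float)
    if np.linalg.norm(axis) < 1e-12:
        raise ParameterError("sign axis must be a non-zero vector")
    axis = axis / np.linalg.norm(axis)

    values = np.empty(len(trajectory))
    for k in range(len(trajectory)):
        n_k = normal(k)
        cross = np.cross(n_ref, n_k)
        ang = np.degrees(np.arctan2(np.linalg.norm(cross),
                                    float(np.dot(n_ref, n_k))))
        s = np.sign(np.dot(cross, axis))
        values[k] = ang * (s if s != 0 else 1.0)
    values[reference] = 0.0
    return ObservableSeries("theta", values, trajectory.times, units="deg")


def contact_occupancy(
    trajectory: Trajectory,
    structure: Structure,
    group_a: AtomSet,
    group_b: AtomSet,
    cutoff: float = 4.0,
) -> dict[tuple[str, int], float]:
    """Fraction of frames in which each residue of group B has any heavy atom
    within ``cutoff`` A of any heavy atom of group A (the study's 4 A rule)."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise ParameterError("contact_occupancy groups must be non-empty")
    if set(group_a.indices.tolist()) & set(group_b.indices.tolist()):
        raise ParameterError("groups must be disjoint")
    heavy = structure.heavy_mask()
    ia = np.array([i for i in group_a.indices if heavy[i]], int)
    ib = np.array([i for i in group_b.indices if heavy[i]], int)
    if len(ia) == 0 or len(ib) == 0:
        raise ParameterError("groups contain no heavy atoms")
    residues_b = [(str(structure.chain[i]), int(structure.res_id[i])) for i in ib]
    unique_res = []
    for r in residues_b:
        if r not in unique_res:
            unique_res.append(r)
    hits = {r: 0 for r in unique_res}
    for frame in trajectory.frames:
        d = cdist(frame[ia], frame[ib])
        close = (d <= cutoff).any(axis=0)
        seen = set()
        for col, r in enumerate(residues_b):
            if close[col] and r not in seen:
                hits[r] += 1
                seen.add(r)
    nf = len(trajectory)
    return {r: hits[r] / nf for r in unique_res}


def sasa_series(
    trajectory: Trajectory,
    structure: Structure,
    group: AtomSet,
    probe_radius: float = 1.4,
    sphere_points: int = 960,
    radii: Mapping[str, float] | None = None,
) -> ObservableSeries:
    """Solvent-accessible surface area (A^2) of ``group`` per frame.

    Shrake-Rupley-style numerical integration (via biotite) with the package's
    per-element radius set; all atoms of the structure occlude, only the group
    area is summed.
    """
    if len(group) == 0:
        raise ParameterError("sasa_series group must be non-empty")
    table = dict(SASA_RADII if radii is None else radii)
    vdw = np.empty(len(structure))
    for k, el in enumerate(structure.element):
        if el not in table:
            raise ParameterError(f"no SASA radius for element {el!r}")
        vdw[k] = table[el]
    arr = to_atom_array(structure)
    mask = np.zeros(len(structure), bool)
    mask[group.indices] = True
    values = np.empty(len(trajectory))
    for k in range(len(trajectory)):
        arr.coord = trajectory.frames[k].astype(np.float32)
        per_atom = bst.sasa(
            arr, probe_radius=float(probe_radius), atom_filter=mask,
            ignore_ions=False, point_number=int(sphere_points), vdw_radii=vdw,
        )
        values[k] = float(np.nansum(per_atom))
    return ObservableSeries("SASA", values, trajectory.times, units="A^2")
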