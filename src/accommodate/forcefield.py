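"""Structure-based (Go-model) topology construction.

The potential has harmonic bonds/angles/improper and planar dihedrals, cosine
proper dihedrals, attractive native contacts and a generic excluded-volume
repulsion between all remaining pairs:

    V1 = sum_bonds  eps_r/2 (r - r_o)^2  + sum_angles eps_th/2 (th - th_o)^2
       + sum_imp    eps_xi/2 (x - x_o)^2 + sum_planar eps_xp/2 (x - x_o)^2
       + sum_bb     eps_BB F_D(phi - phi_o) + sum_sc eps_SC F_D(phi - phi_o)
       + sum_contacts    eps_C w_ij [ (sig_ij/r)^12 - 2 (sig_ij/r)^6 ]
       + sum_noncontacts eps_NC (sig_NC/r)^12

with F_D(phi) = (1 - cos phi) + 1/2 (1 - cos 3 phi), eps_r = 50, eps_th = 40,
eps_xi = 10, eps_xp = 40, eps_NC = 0.1, sig_NC = 2.5 A, all in units of
eps_0 = 1.  Every reference value (r_o, th_o, x_o, phi_o, sig_ij) is measured
from the reference structure, which is therefore the exact minimum of the
bonded terms.

The dual-basin construction merges the native-contact maps of two endpoint
conformations: contacts unique to the starting (A/T-like) basin keep weight 1,
contacts unique to the target (A/A-like) basin are down-weighted by
``weight_AA`` (0.13 for the 6-12 flavor, 0.4 for the Gaussian flavor in the
accommodation study), and pairs native in both keep the A/T geometry at
weight 1.

In the Gaussian flavor ("v2") each contact term is replaced by a single
excluded-volume-plus-Gaussian well

    V_c(r) = eps_C w [ (sig_NC/r)^12 - (1 + (sig_NC/sig_ij)^12)
                                        exp(-(r - sig_ij)^2 / (2 gw^2)) ]

whose value at r = sig_ij is exactly -eps_C w, matching the 6-12 minimum
depth; gw defaults to 0.5 A.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import GeometryError, IntegrityError, ParameterError
from .structures import AtomSet, AtomSpec, Structure

EPS_BOND = 50.0
EPS_ANGLE = 40.0
EPS_IMPROPER = 10.0
EPS_PLANAR = 40.0
EPS_BACKBONE = 1.0
EPS_SIDECHAIN = 0.5
EPS_NC = 0.1
SIGMA_NC = 2.5
CONTACT_CUTOFF = 4.5
GAUSSIAN_WIDTH = 0.5

FLAVOR_V1 = "v1_6-12"
FLAVOR_V2 = "v2_gaussian"

#: atom names treated as backbone when classifying proper dihedrals
BACKBONE_ATOMS = frozenset(
    ["N", "CA", "C", "O", "P", "OP1", "OP2", "O5'", "C5'", "C4'", "C3'", "O3'"]
)


@dataclass
class BondedTerms:
    """Bonded part of the topology.  Index arrays are (n, k) ints; reference
    values in Angstrom / radians; per-term strengths in eps_0."""

    bonds_idx: np.ndarray
    bonds_r0: np.ndarray
    bonds_k: np.ndarray
    angles_idx: np.ndarray
    angles_t0: np.ndarray
    angles_k: np.ndarray
    impropers_idx: np.ndarray
    impropers_x0: np.ndarray
    impropers_k: np.ndarray
    planars_idx: np.ndarray
    planars_x0: np.ndarray
    planars_k: np.ndarray
    propers_idx: np.ndarray
    propers_p0: np.ndarray
    propers_k: np.ndarray
    propers_class: np.ndarray  # 0 = backbone, 1 = sidechain

    @staticmethod
    def empty() -> "BondedTerms":
        z = np.zeros(0)
        return BondedTerms(
            np.zeros((0, 2), int), z, z, np.zeros((0, 3), int), z, z,
            np.zeros((0, 4), int), z, z, np.zeros((0, 4), int), z, z,
            np.zeros((0, 4), int), z, z, np.zeros(0, int),
        )

    def n_terms(self) -> dict:
        return {
            "bonds": len(self.bonds_idx), "angles": len(self.angles_idx),
            "impropers": len(self.impropers_idx), "planars": len(self.planars_idx),
            "propers": len(self.propers_idx),
        }

    def pair_set(self) -> set[tuple[int, int]]:
        """All atom pairs sharing a bond, angle or dihedral."""
        pairs: set[tuple[int, int]] = set()
        for idx in (self.bonds_idx, self.angles_idx, self.impropers_idx,
                    self.planars_idx, self.propers_idx):
            for row in idx:
                row = row.tolist()
                for a in range(len(row)):
                    for b in range(a + 1, len(row)):
                        i, j = sorted((row[a], row[b]))
                        pairs.add((i, j))
        return pairs


@dataclass
class Contact:
    """A native pair: minimum at the reference distance sigma (A)."""

    i: int
    j: int
    sigma: float
    eps: float = 1.0
    weight: float = 1.0
    basin: str = ""    # "AT", "AA", "shared" once dual-basin merged
    group: str = ""    # free-text group tag, e.g. "codon-anticodon"

    def __post_init__(self):
        if self.i >= self.j:
            self.i, self.j = self.j, self.i
        if self.sigma <= 0:
            raise ParameterError(f"contact ({self.i},{self.j}) has sigma <= 0")

    @property
    def pair(self) -> tuple[int, int]:
        return (self.i, self.j)


@dataclass
class Topology:
    """The complete structure-based model for one system."""

    n_atoms: int
    bonded: BondedTerms
    contacts: list[Contact]
    flavor: str = FLAVOR_V1
    eps_nc: float = EPS_NC
    sigma_nc: float = SIGMA_NC
    gauss_width: np.ndarray | None = None  # per-contact, v2 only
    extra_exclusions: frozenset = field(default_factory=frozenset)
    provenance: dict = field(default_factory=dict)
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if self.flavor not in (FLAVOR_V1, FLAVOR_V2):
            raise ParameterError(f"unknown flavor {self.flavor!r}")
        if self.flavor == FLAVOR_V2:
            if self.gauss_width is None or len(self.gauss_width) != len(self.contacts):
                raise ParameterError("v2 topology needs one Gaussian width per contact")
            if len(self.contacts) and np.min(self.gauss_width) <= 0:
                raise ParameterError("Gaussian widths must be positive")
        for c in self.contacts:
            if c.j >= self.n_atoms:
                raise IntegrityError(f"contact ({c.i},{c.j}) outside atom roster")

    def exclusions(self) -> set[tuple[int, int]]:
        """Pairs removed from the generic repulsion: every pair sharing a
        bonded term, every contact pair, plus explicit extras."""
        if "excl" not in self._cache:
            excl = self.bonded.pair_set()
            excl.update(c.pair for c in self.contacts)
            excl.update(self.extra_exclusions)
            self._cache["excl"] = excl
        return self._cache["excl"]

    def noncontact_pairs(self) -> np.ndarray:
        """(n, 2) indices of all pairs subject to the eps_NC repulsion."""
        if "nc" not in self._cache:
            excl = self.exclusions()
            pairs = [
                (i, j)
                for i in range(self.n_atoms)
                for j in range(i + 1, self.n_atoms)
                if (i, j) not in excl
            ]
            self._cache["nc"] = np.array(pairs, int).reshape(-1, 2)
        return self._cache["nc"]

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(repr((self.n_atoms, self.flavor, self.eps_nc, self.sigma_nc)).encode())
        for arr in (self.bonded.bonds_idx, self.bonded.bonds_r0, self.bonded.angles_idx,
                    self.bonded.angles_t0, self.bonded.propers_idx, self.bonded.propers_p0):
            h.update(np.ascontiguousarray(arr).tobytes())
        for c in self.contacts:
            h.update(repr((c.i, c.j, round(c.sigma, 9), c.eps, c.weight)).encode())
        return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# geometry helpers (reference-value measurement)

def _angle(a, b, c) -> float:
    u, v = a - b, c - b
    cu, cv = np.linalg.norm(u), np.linalg.norm(v)
    cosang = np.clip(np.dot(u, v) / (cu * cv), -1.0, 1.0)
    return float(np.arccos(cosang))


def dihedral_angle(a, b, c, d) -> float:
    """Signed dihedral in radians; raises GeometryError on collinear triples."""
    b1, b2, b3 = b - a, c - b, d - c
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-8 or np.linalg.norm(n2) < 1e-8:
        raise GeometryError("collinear atoms: dihedral undefined")
    y = np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))
    return float(np.arctan2(y, np.dot(n1, n2)))


def _default_classify(names: tuple[str, str, str, str]) -> str:
    inset = sum(n in BACKBONE_ATOMS for n in names)
    return "backbone" if inset >= 3 else "sidechain"


def build_bonded_terms(
    reference: Structure,
    connectivity: Iterable[tuple[int, int]],
    *,
    eps_bond: float = EPS_BOND,
    eps_angle: float = EPS_ANGLE,
    eps_improper: float = EPS_IMPROPER,
    eps_planar: float = EPS_PLANAR,
    eps_backbone: float = EPS_BACKBONE,
    eps_sidechain: float = EPS_SIDECHAIN,
    impropers: Sequence[tuple[int, int, int, int]] = (),
    planars: Sequence[tuple[int, int, int, int]] = (),
    classify: Callable[[tuple[str, str, str, str]], str] | None = None,
) -> BondedTerms:
    """Measure every bonded term from the reference coordinates.

    Angles are generated for every bonded triplet and proper dihedrals for
    every bonded quadruplet implied by ``connectivity``; improper and planar
    dihedral quadruplets are caller-supplied (they encode chirality/planarity
    choices the connectivity graph cannot).  Proper dihedrals are classed
    backbone/sidechain by atom-name convention unless ``classify`` overrides.
    """
    coord = reference.coord
    n = len(reference)
    bonds = []
    adj: dict[int, list[int]] = {}
    for i, j in connectivity:
        i, j = int(i), int(j)
        if not (0 <= i < n and 0 <= j < n) or i == j:
            raise IntegrityError(f"bond ({i},{j}) references non-existent atoms")
        r0 = float(np.linalg.norm(coord[j] - coord[i]))
        if r0 < 1e-6:
            raise GeometryError(f"zero-length bond ({i},{j})")
        i, j = min(i, j), max(i, j)
        if (i, j) in {(b[0], b[1]) for b in bonds}:
            continue
        bonds.append((i, j, r0))
        adj.setdefault(i, []).append(j)
        adj.setdefault(j, []).append(i)

    angles = []
    for jc in sorted(adj):
        nb = sorted(adj[jc])
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                i, k = nb[a], nb[b]
                angles.append((i, jc, k, _angle(coord[i], coord[jc], coord[k])))

    propers = []
    seen_quads = set()
    for (j, k, _r0) in bonds:
        for i in adj.get(j, []):
            if i == k:
                continue
            for l in adj.get(k, []):
                if l == j or l == i:
                    continue
                quad = (i, j, k, l) if (i, j, k, l) <= (l, k, j, i) else (l, k, j, i)
                if quad in seen_quads:
                    continue
                seen_quads.add(quad)
                try:
                    p0 = dihedral_angle(*(coord[q] for q in quad))
                except GeometryError:
                    warnings.warn(
                        f"skipping dihedral {quad}: collinear in reference",
                        stacklevel=2,
                    )
                    continue
                propers.append((quad, p0))

    classify = classify or _default_classify
    cls = np.array(
        [0 if classify(tuple(reference.atom_name[list(q)])) == "backbone" else 1
         for q, _ in propers],
        dtype=int,
    )

    def _harm_dihedrals(quads):
        idx, x0 = [], []
        for q in quads:
            q = tuple(int(x) for x in q)
            idx.append(q)
            x0.append(dihedral_angle(*(coord[i] for i in q)))
        return np.array(idx, int).reshape(-1, 4), np.array(x0)

    imp_idx, imp_x0 = _harm_dihedrals(impropers)
    pla_idx, pla_x0 = _harm_dihedrals(planars)

    bonds_idx = np.array([(b[0], b[1]) for b in bonds], int).reshape(-1, 2)
    return BondedTerms(
        bonds_idx=bonds_idx,
        bonds_r0=np.array([b[2] for b in bonds]),
        bonds_k=np.full(len(bonds), float(eps_bond)),
        angles_idx=np.array([(a, b, c) for a, b, c, _ in angles], int).reshape(-1, 3),
        angles_t0=np.array([t for *_abc, t in angles]),
        angles_k=np.full(len(angles), float(eps_angle)),
        impropers_idx=imp_idx, impropers_x0=imp_x0,
        impropers_k=np.full(len(imp_idx), float(eps_improper)),
        planars_idx=pla_idx, planars_x0=pla_x0,
        planars_k=np.full(len(pla_idx), float(eps_planar)),
        propers_idx=np.array([q for q, _ in propers], int).reshape(-1, 4),
        propers_p0=np.array([p for _, p in propers]),
        propers_k=np.where(cls == 0, eps_backbone, eps_sidechain).astype(float),
        propers_class=cls,
    )


def build_contact_map(
    reference: Structure,
    cutoff: float = CONTACT_CUTOFF,
    bonded: BondedTerms | None = None,
) -> list[Contact]:
    """Native contacts: heavy-atom pairs within ``cutoff`` Angstrom, excluding
    pairs that share a bonded term and pairs within the same residue.
    sigma is the reference distance; eps = weight = 1."""
    if cutoff <= 0:
        raise ParameterError("cutoff must be positive")
    heavy = np.flatnonzero(reference.heavy_mask())
    if len(heavy) == 0:
        return []
    excluded = bonded.pair_set() if bonded is not None else set()
    tree = cKDTree(reference.coord[heavy])
    out = []
    for a, b in sorted(tree.query_pairs(cutoff)):
        i, j = int(heavy[a]), int(heavy[b])
        if i > j:
            i, j = j, i
        if (i, j) in excluded:
            continue
        if (reference.chain[i] == reference.chain[j]
                and reference.res_id[i] == reference.res_id[j]):
            continue
        sigma = float(np.linalg.norm(reference.coord[j] - reference.coord[i]))
        out.append(Contact(i, j, sigma))
    return out


def merge_dual_basin(
    contacts_AT: Sequence[Contact],
    contacts_AA: Sequence[Contact],
    weight_AA: float,
    n_atoms: int | None = None,
) -> list[Contact]:
    """Union of the two endpoint maps.

    Pairs only in the A/T map keep weight 1 (tag "AT"); pairs only in the A/A
    map get ``weight_AA`` (tag "AA"); pairs native in both keep the A/T
    geometry at weight 1 (tag "shared") -- the simulation starts in A/T and
    only the target-basin contacts are down-weighted.
    """
    if not (0 < weight_AA <= 1):
        raise ParameterError("weight_AA must be in (0, 1]")
    if n_atoms is not None:
        for c in list(contacts_AT) + list(contacts_AA):
            if c.j >= n_atoms:
                raise IntegrityError(
                    f"contact ({c.i},{c.j}) outside the common atom roster"
                )
    at = {c.pair: c for c in contacts_AT}
    aa = {c.pair: c for c in contacts_AA}
    merged = []
    for pair in sorted(set(at) | set(aa)):
        if pair in at and pair in aa:
            c = at[pair]
            merged.append(replace(c, weight=1.0, basin="shared"))
        elif pair in at:
            merged.append(replace(at[pair], weight=1.0, basin="AT"))
        else:
            merged.append(replace(aa[pair], weight=float(weight_AA), basin="AA"))
    return merged


def scale_contact_group(
    contacts: Sequence[Contact],
    selector: str | Callable[[Contact], bool],
    factor: float,
) -> list[Contact]:
    """Multiply the weight of every selected contact by ``factor``.

    ``selector`` is a group tag (string) or a predicate on Contact.
    """
    if factor <= 0:
        raise ParameterError("scale factor must be positive")
    if isinstance(selector, str):
        tag = selector
        match = lambda c: c.group == tag  # noqa: E731
    else:
        match = selector
    return [replace(c, weight=c.weight * factor) if match(c) else replace(c)
            for c in contacts]


def label_contact_group(
    contacts: Sequence[Contact],
    structure: Structure,
    name: str,
    predicate: Callable[[Structure, int, int], bool],
) -> list[Contact]:
    """Tag the contacts for which ``predicate(structure, i, j)`` holds."""
    return [replace(c, group=name) if predicate(structure, c.i, c.j) else replace(c)
            for c in contacts]


def gaussianize_contacts(topology: Topology, width_rule=GAUSSIAN_WIDTH) -> Topology:
    """Convert a 6-12 topology to the single-Gaussian contact flavor.

    ``width_rule`` is a width in Angstrom or a callable Contact -> width.
    The well depth at r = sigma_ij equals -eps_C * weight by construction.
    """
    if topology.flavor != FLAVOR_V1:
        raise ParameterError("gaussianize_contacts expects a v1 (6-12) topology")
    if callable(width_rule):
        widths = np.array([float(width_rule(c)) for c in topology.contacts])
    else:
        widths = np.full(len(topology.contacts), float(width_rule))
    if len(widths) and widths.min() <= 0:
        raise ParameterError("Gaussian width must be positive")
    return Topology(
        n_atoms=topology.n_atoms,
        bonded=topology.bonded,
        contacts=[replace(c) for c in topology.contacts],
        flavor=FLAVOR_V2,
        eps_nc=topology.eps_nc,
        sigma_nc=topology.sigma_nc,
        gauss_width=widths,
        extra_exclusions=topology.extra_exclusions,
        provenance=dict(topology.provenance),
    )


def delete_segment(
    topology: Topology,
    structure: Structure,
    ranges: Sequence[tuple[str, int, int]],
    protected: Sequence[AtomSpec] | AtomSet | None = None,
) -> tuple[Topology, Structure]:
    """Virtually remove residue ranges (e.g. an rRNA helix) from the model.

    ``ranges`` is a list of (chain, first residue, last residue), inclusive.
    All atoms of those residues and every bonded term, contact and exclusion
    touching them are removed; remaining indices are remapped.  Atoms listed
    in ``protected`` (e.g. observable probe atoms) may not be deleted.
    """
    if not ranges:
        return topology, structure
    mask = np.zeros(len(structure), dtype=bool)
    for chain, lo, hi in ranges:
        if hi < lo:
            raise ParameterError(f"range ({chain},{lo},{hi}) is reversed")
        hit = (structure.chain == str(chain)) & (structure.res_id >= int(lo)) \
            & (structure.res_id <= int(hi))
        if not hit.any():
            raise ParameterError(f"range ({chain},{lo},{hi}) resolves to no residues")
        mask |= hit
    if protected is not None:
        if isinstance(protected, AtomSet):
            prot_idx = set(int(i) for i in protected.indices)
        else:
            prot_idx = {structure.index_of(AtomSpec(*s)) for s in protected}
        dead = prot_idx & set(np.flatnonzero(mask).tolist())
        if dead:
            raise ParameterError(
                f"refusing to delete protected (probe) atoms at indices {sorted(dead)}"
            )
    keep = ~mask
    new_index = -np.ones(len(structure), dtype=int)
    new_index[keep] = np.arange(int(keep.sum()))

    new_structure = Structure(
        structure.chain[keep], structure.res_id[keep], structure.res_name[keep],
        structure.atom_name[keep], structure.element[keep], structure.coord[keep],
    )

    bt = topology.bonded

    def _filter(idx, *vals):
        if len(idx) == 0:
            return (idx,) + vals
        ok = keep[idx].all(axis=1)
        return (new_index[idx[ok]],) + tuple(v[ok] for v in vals)

    b_idx, b_r0, b_k = _filter(bt.bonds_idx, bt.bonds_r0, bt.bonds_k)
    a_idx, a_t0, a_k = _filter(bt.angles_idx, bt.angles_t0, bt.angles_k)
    i_idx, i_x0, i_k = _filter(bt.impropers_idx, bt.impropers_x0, bt.impropers_k)
    pl_idx, pl_x0, pl_k = _filter(bt.planars_idx, bt.planars_x0, bt.planars_k)
    pr_idx, pr_p0, pr_k, pr_c = _filter(
        bt.propers_idx, bt.propers_p0, bt.propers_k, bt.propers_class
    )
    new_bonded = BondedTerms(
        b_idx, b_r0, b_k, a_idx, a_t0, a_k, i_idx, i_x0, i_k,
        pl_idx, pl_x0, pl_k, pr_idx, pr_p0, pr_k, pr_c,
    )

    new_contacts, new_widths = [], []
    widths = topology.gauss_width
    for ci, c in enumerate(topology.contacts):
        if keep[c.i] and keep[c.j]:
            new_contacts.append(
                replace(c, i=int(new_index[c.i]), j=int(new_index[c.j]))
            )
            if widths is not None:
                new_widths.append(widths[ci])
    new_extra = frozenset(
        (int(new_index[i]), int(new_index[j]))
        for i, j in topology.extra_exclusions
        if keep[i] and keep[j]
    )
    new_top = Topology(
        n_atoms=int(keep.sum()),
        bonded=new_bonded,
        contacts=new_contacts,
        flavor=topology.flavor,
        eps_nc=topology.eps_nc,
        sigma_nc=topology.sigma_nc,
        gauss_width=np.array(new_widths) if widths is not None else None,
        extra_exclusions=new_extra,
        provenance=dict(topology.provenance, deleted=list(map(tuple, ranges))),
    )
    return new_top, new_structure
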