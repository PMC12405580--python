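"""Plain-text topology serialization.

The dialect follows the GROMACS .top sectioning idea (one bracketed section
per term type, whitespace-separated columns, ';' comments) but is its own
documented format:

    [ header ]     key value pairs: natoms, flavor, eps_nc, sigma_nc, plus
                   free-form provenance entries (prefixed "prov.")
    [ bonds ]      i j r0 k
    [ angles ]     i j k theta0 eps
    [ impropers ]  i j k l chi0 eps
    [ planars ]    i j k l chi0 eps
    [ dihedrals ]  i j k l phi0 eps class(0=backbone,1=sidechain)
    [ contacts ]   i j sigma eps weight basin group gauss_width
    [ exclusions ] i j        (extra exclusions only; bonded- and
                               contact-derived exclusions are implicit)

Indices are 0-based.  Reference values carry full double precision so a
round trip reproduces the topology exactly.
"""

from __future__ import annotations

import numpy as np

from .errors import FormatError
from .forcefield import BondedTerms, Contact, FLAVOR_V2, Topology


def write_topology(topology: Topology, path: str) -> None:
    bt = topology.bonded
    lines = ["[ header ]", f"natoms {topology.n_atoms}",
             f"flavor {topology.flavor}",
             f"eps_nc {topology.eps_nc!r}", f"sigma_nc {topology.sigma_nc!r}"]
    for k, v in topology.provenance.items():
        lines.append(f"prov.{k} {v}")

    def section(name, idx, *cols):
        lines.append(f"[ {name} ]")
        for row in range(len(idx)):
            parts = [str(int(v)) for v in idx[row]]
            for col in cols:
                v = col[row]
                parts.append(repr(float(v)) if isinstance(v, (float, np.floating))
                             else str(int(v)))
            lines.append(" ".join(parts))

    section("bonds", bt.bonds_idx, bt.bonds_r0, bt.bonds_k)
    section("angles", bt.angles_idx, bt.angles_t0, bt.angles_k)
    section("impropers", bt.impropers_idx, bt.impropers_x0, bt.impropers_k)
    section("planars", bt.planars_idx, bt.planars_x0, bt.planars_k)
    section("dihedrals", bt.propers_idx, bt.propers_p0, bt.propers_k,
            bt.propers_class)
    lines.append("[ contacts ]")
    widths = topology.gauss_width
    for ci, c in enumerate(topology.contacts):
        gw = float(widths[ci]) if widths is not None else 0.0
        group = c.group if c.group else "-"
        basin = c.basin if c.basin else "-"
        lines.append(f"{c.i} {c.j} {c.sigma!r} {c.eps!r} {c.weight!r} "
                     f"{basin} {group} {gw!r}")
    lines.append("[ exclusions ]")
    for i, j in sorted(topology.extra_exclusions):
        lines.append(f"{i} {j}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_topology(path: str) -> Topology:
    sections: dict[str, list[list[str]]] = {}
    current = None
    for lineno, raw in enumerate(open(path), start=1):
        line = raw.split(";")[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line.strip("[] ").strip()
            sections[current] = []
            continue
        if current is None:
            raise FormatError(f"{path}:{lineno}: data before any section")
        sections[current].append(line.split())

    if "header" not in sections:
        raise FormatError(f"{path}: missing [ header ] section")
    header = {row[0]: " ".join(row[1:]) for row in sections["header"]}
    try:
        natoms = int(header["natoms"])
        flavor = header["flavor"]
        eps_nc = float(header["eps_nc"])
        sigma_nc = float(header["sigma_nc"])
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path}: bad header: {exc}") from exc
    provenance = {k[5:]: v for k, v in header.items() if k.startswith("prov.")}

    def arrays(name, n_idx, n_val):
        rows = sections.get(name, [])
        idx = np.array([[int(v) for v in r[:n_idx]] for r in rows],
                       int).reshape(-1, n_idx)
        vals = [np.array([float(r[n_idx + c]) for r in rows])
                for c in range(n_val)]
        return idx, vals

    try:
        b_idx, (b_r0, b_k) = arrays("bonds", 2, 2)
        a_idx, (a_t0, a_k) = arrays("angles", 3, 2)
        i_idx, (i_x0, i_k) = arrays("impropers", 4, 2)
        p_idx, (p_x0, p_k) = arrays("planars", 4, 2)
        d_idx, (d_p0, d_k, d_cls) = arrays("dihedrals", 4, 3)
        bonded = BondedTerms(
            b_idx, b_r0, b_k, a_idx, a_t0, a_k, i_idx, i_x0, i_k,
            p_idx, p_x0, p_k, d_idx, d_p0, d_k, d_cls.astype(int),
        )
        contacts, widths = [], []
        for r in sections.get("contacts", []):
            contacts.append(Contact(
                int(r[0]), int(r[1]), float(r[2]), float(r[3]), float(r[4]),
                "" if r[5] == "-" else r[5], "" if r[6] == "-" else r[6],
            ))
            widths.append(float(r[7]))
        extra = frozenset((int(r[0]), int(r[1]))
                          for r in sections.get("exclusions", []))
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}: malformed record: {exc}") from exc
    return Topology(
        n_atoms=natoms, bonded=bonded, contacts=contacts, flavor=flavor,
        eps_nc=eps_nc, sigma_nc=sigma_nc,
        gauss_width=np.array(widths) if flavor == FLAVOR_V2 else None,
        extra_exclusions=extra, provenance=provenance,
    )
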