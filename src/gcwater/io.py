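"""Readers and writers: PDB structures (via gemmi), parameter sidecars,
columnar numeric artifacts and JSON summaries.

PDB files carry no force-field information, so hosts travel as a PDB plus a
plain-text parameter sidecar with one row per non-water atom::

    # index  sigma(A)  epsilon(kcal/mol)  charge(e)
    0  3.00  0.150  -0.40

Water residues (HOH/WAT) in the PDB are collected as crystallographic
oxygens for evaluation and never become host sites.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np

from .model import HostStructure, ParticleSite
from .titration import TitrationCurve
from .watersites import WaterSiteCluster

__all__ = [
    "read_host_pdb",
    "write_host_pdb",
    "write_waters_pdb",
    "write_clusters_pdb",
    "write_titration_csv",
    "read_titration_csv",
    "write_alchemical_leg",
    "read_alchemical_leg",
    "dump_json",
]

_WATER_RESNAMES = {"HOH", "WAT"}
_WATER_OXYGENS = {"O", "OW"}


def _read_sidecar(path) -> np.ndarray:
    rows = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        parts = s.split()
        if len(parts) != 4:
            raise ValueError(f"{path}:{ln}: expected 4 columns (index sigma eps charge)")
        rows.append([float(x) for x in parts])
    return np.array(rows).reshape(-1, 4)


def read_host_pdb(path, parameter_sidecar) -> HostStructure:
    """Host sites from a PDB plus parameter sidecar; HOH/WAT oxygens become
    crystallographic waters."""
    st = gemmi.read_structure(str(path))
    atoms, labels, waters = [], [], []
    for model in st:
        for chain in model:
            for res in chain:
                if res.name.strip() in _WATER_RESNAMES:
                    for atom in res:
                        if atom.name.strip() in _WATER_OXYGENS:
                            waters.append([atom.pos.x, atom.pos.y, atom.pos.z])
                else:
                    for atom in res:
                        atoms.append([atom.pos.x, atom.pos.y, atom.pos.z])
                        labels.append(f"{chain.name}/{res.name}{res.seqid.num}/{atom.name}")
        break  # first model defines the host
    params = _read_sidecar(parameter_sidecar)
    if len(params) != len(atoms):
        bad = min(len(params), len(atoms))
        name = labels[bad] if bad < len(labels) else labels[-1]
        raise ValueError(
            f"parameter sidecar has {len(params)} rows for {len(atoms)} non-water atoms; "
            f"first unmatched atom: {name}"
        )
    sites = [
        ParticleSite(pos, lj_sigma=row[1], lj_epsilon=row[2], charge=row[3], label=lab)
        for pos, row, lab in zip(atoms, params, labels)
    ]
    return HostStructure(sites, crystal_water_oxygens=waters if waters else None)


def write_host_pdb(host: HostStructure, pdb_path, sidecar_path) -> None:
    """Export a host (synthetic or otherwise) to PDB + parameter sidecar, in
    the same convention :func:`read_host_pdb` consumes."""
    st = gemmi.Structure()
    st.name = "host"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    res = gemmi.Residue()
    res.name = "CGE"
    res.seqid = gemmi.SeqId(1, " ")
    res.het_flag = "H"
    for i, s in enumerate(host.sites):
        atom = gemmi.Atom()
        atom.name = f"X{i + 1}"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*s.position)
        res.add_atom(atom)
    chain.add_residue(res)
    if host.crystal_water_oxygens.size:
        for i, w in enumerate(host.crystal_water_oxygens):
            wres = gemmi.Residue()
            wres.name = "HOH"
            wres.seqid = gemmi.SeqId(100 + i, " ")
            wres.het_flag = "H"
            atom = gemmi.Atom()
            atom.name = "O"
            atom.element = gemmi.Element("O")
            atom.pos = gemmi.Position(*w)
            wres.add_atom(atom)
            chain.add_residue(wres)
    model.add_chain(chain)
    st.add_model(model)
    st.write_pdb(str(pdb_path))
    lines = ["# index  sigma(A)  epsilon(kcal/mol)  charge(e)"]
    for i, s in enumerate(host.sites):
        lines.append(f"{i}  {s.lj_sigma:.6f}  {s.lj_epsilon:.6f}  {s.charge:.6f}")
    Path(sidecar_path).write_text("\n".join(lines) + "\n")


def write_waters_pdb(frames: Sequence[np.ndarray], path) -> None:
    """Sampled region waters as a multi-model PDB (oxygens only)."""
    st = gemmi.Structure()
    st.name = "gcmc-waters"
    for fi, frame in enumerate(frames):
        model = gemmi.Model(str(fi + 1))
        chain = gemmi.Chain("W")
        for wi, pos in enumerate(np.atleast_2d(np.asarray(frame, dtype=float))):
            if pos.size == 0:
                continue
            res = gemmi.Residue()
            res.name = "HOH"
            res.seqid = gemmi.SeqId(wi + 1, " ")
            res.het_flag = "H"
            atom = gemmi.Atom()
            atom.name = "O"
            atom.element = gemmi.Element("O")
            atom.pos = gemmi.Position(*pos)
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
        st.add_model(model)
    st.write_pdb(str(path))


def write_clusters_pdb(clusters: Sequence[WaterSiteCluster], path) -> None:
    """Hydration sites as pseudo-atoms; occupancy is stored in the occupancy
    column and, as a percentage, in the B-factor column."""
    st = gemmi.Structure()
    st.name = "hydration-sites"
    model = gemmi.Model("1")
    chain = gemmi.Chain("S")
    for i, c in enumerate(clusters):
        res = gemmi.Residue()
        res.name = "HOH"
        res.seqid = gemmi.SeqId(i + 1, " ")
        res.het_flag = "H"
        atom = gemmi.Atom()
        atom.name = "O"
        atom.element = gemmi.Element("O")
        atom.pos = gemmi.Position(*c.centroid)
        atom.occ = c.occupancy
        atom.b_iso = 100.0 * c.occupancy
        res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.write_pdb(str(path))


def write_titration_csv(curve: TitrationCurve, path) -> None:
    """Columnar text: B, per-repeat means, pooled mean and standard error."""
    header = (
        "B,"
        + ",".join(f"repeat{r}" for r in range(curve.n_repeats))
        + ",mean,sem"
    )
    body = np.column_stack([curve.b_values, curve.occupancies.T, curve.mean, curve.sem])
    np.savetxt(path, body, delimiter=",", header=header, comments="")


def read_titration_csv(path) -> TitrationCurve:
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    n_rep = data.shape[1] - 3
    return TitrationCurve(data[:, 0], data[:, 1 : 1 + n_rep].T)


def dump_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_alchemical_leg(leg, basepath) -> None:
    """Serialize a leg's reduced-potential matrix as columnar text plus a
    JSON sidecar (ladder, per-window counts, environment), so the estimation
    step can be re-run without re-sampling."""
    base = Path(basepath)
    np.savetxt(
        base.with_suffix(".u.txt"), leg.u_kn.T, fmt="%.10g",
        header="reduced potentials u_k(x_n); one row per sample, one column per window",
    )
    meta = {
        "lambdas": list(map(float, leg.lambdas)),
        "n_k": list(map(int, leg.n_k)),
        "environment": leg.environment,
        "dg": leg.dg,
        "dg_err": leg.dg_err,
        "seed": leg.metadata.get("seed"),
    }
    dump_json(meta, base.with_suffix(".json"))


def read_alchemical_leg(basepath):
    """Load a leg written by :func:`write_alchemical_leg`."""
    from .alchemical import AlchemicalLeg

    base = Path(basepath)
    meta = json.loads(base.with_suffix(".json").read_text())
    u = np.loadtxt(base.with_suffix(".u.txt"), ndmin=2).T
    leg = AlchemicalLeg(
        lambdas=np.array(meta["lambdas"]),
        u_kn=u,
        n_k=np.array(meta["n_k"]),
        environment=meta["environment"],
        dg=meta.get("dg"),
        dg_err=meta.get("dg_err"),
        metadata={"seed": meta.get("seed")},
    )
    return leg
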