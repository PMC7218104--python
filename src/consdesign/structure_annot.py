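"""Structural context of candidate positions: distances to named sites and
residue burial.

Distances are minimum heavy-atom distances (any non-hydrogen atom of the
residue to any atom of the site). Burial is classed from relative solvent
accessibility: Shrake–Rupley solvent-accessible surface area of the residue
(probe 1.4 Å) divided by the residue type's theoretical maximum, with
residues under 10% accessibility called buried and over 30% called surface.

For multicopper oxidases the two catalytic sites of interest are the
mononuclear T1 copper (substrate oxidation) and the trinuclear T2/T3 copper
cluster (O2 reduction); :func:`classify_copper_sites` resolves them from the
copper-copper distance pattern (the three cluster coppers sit within a few Å
of each other, the T1 copper is isolated).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

WATER_NAMES = {"HOH", "WAT", "DOD"}

#: theoretical maximum accessible surface area per residue type (Å^2),
#: Tien et al. 2013 theoretical values — the standard reference scale for
#: relative solvent accessibility
MAX_ASA: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLU": 223.0, "GLN": 225.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

BURIED_MAX: float = 0.10
SURFACE_MIN: float = 0.30


class StructureError(ValueError):
    """Raised for unusable structures or site selections."""


@dataclass
class StructureModel:
    """Parsed structure plus resolved named atom sites."""

    atoms: struc.AtomArray
    named_sites: dict[str, struc.AtomArray]


@dataclass(frozen=True)
class SiteAnnotation:
    query_position: int
    distances: dict[str, float]
    relative_accessibility: float | None
    burial_class: str


def _select(atoms: struc.AtomArray, selection: dict) -> struc.AtomArray:
    mask = np.ones(atoms.array_length(), dtype=bool)
    fields = {
        "element": atoms.element,
        "res_name": atoms.res_name,
        "atom_name": atoms.atom_name,
        "chain": atoms.chain_id,
        "res_id": atoms.res_id,
    }
    for key, value in selection.items():
        if key not in fields:
            raise StructureError(f"unknown site-selection key {key!r}")
        wanted = value if isinstance(value, (list, tuple, set)) else [value]
        if key == "res_id":
            mask &= np.isin(fields[key], [int(v) for v in wanted])
        else:
            mask &= np.isin(
                np.char.upper(fields[key].astype(str)),
                [str(v).upper() for v in wanted],
            )
    return atoms[mask]


def load_structure(
    path: str | Path, site_spec: dict[str, dict] | None = None
) -> StructureModel:
    """Read a PDB file (first model), resolve alternate locations by highest
    occupancy, drop waters, and resolve each named site selection.

    An empty site selection is a hard error naming the site.
    """
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1, altloc="occupancy")
    atoms = atoms[~np.isin(atoms.res_name, list(WATER_NAMES))]
    if atoms.array_length() == 0:
        raise StructureError(f"no atoms found in {path}")
    sites: dict[str, struc.AtomArray] = {}
    for label, selection in (site_spec or {}).items():
        selected = _select(atoms, selection)
        if selected.array_length() == 0:
            raise StructureError(f"site {label!r} selects no atoms")
        sites[label] = selected
    return StructureModel(atoms=atoms, named_sites=sites)


def classify_copper_sites(
    model: StructureModel, cluster_cutoff: float = 6.0
) -> dict[str, struc.AtomArray]:
    """Split copper atoms into the isolated T1 site and the T2/T3 cluster.

    The copper whose nearest copper neighbour is farthest away is the T1
    copper; coppers within ``cluster_cutoff`` Å of another copper form the
    trinuclear cluster.
    """
    cu = model.atoms[model.atoms.element == "CU"]
    if cu.array_length() < 2:
        raise StructureError(
            f"need at least 2 copper atoms to classify sites, found {cu.array_length()}"
        )
    coords = cu.coord
    dists = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    np.fill_diagonal(dists, np.inf)
    nearest = dists.min(axis=1)
    t1_index = int(np.argmax(nearest))
    cluster_mask = np.arange(cu.array_length()) != t1_index
    sites = {"T1Cu": cu[~cluster_mask], "T2/T3": cu[cluster_mask]}
    model.named_sites.update(sites)
    return sites


def _residue_atoms(
    model: StructureModel, residue_number: int, chain: str | None
) -> struc.AtomArray:
    atoms = model.atoms
    mask = (atoms.res_id == residue_number) & ~atoms.hetero
    if chain is not None:
        mask &= atoms.chain_id == chain
    mask &= atoms.element != "H"
    res = atoms[mask]
    if res.array_length() == 0:
        raise StructureError(
            f"residue {residue_number} (chain {chain or 'any'}) not found"
        )
    return res


def site_distance(
    model: StructureModel, residue_number: int, site: str, chain: str | None = None
) -> float:
    """Minimum heavy-atom distance (Å) from a residue to a named site."""
    if site not in model.named_sites:
        raise StructureError(f"site {site!r} not defined on this model")
    res = _residue_atoms(model, residue_number, chain)
    site_coords = model.named_sites[site].coord
    diffs = res.coord[:, None, :] - site_coords[None, :, :]
    return float(np.linalg.norm(diffs, axis=-1).min())


def relative_accessibility(
    model: StructureModel,
    residue_number: int,
    chain: str | None = None,
    probe_radius: float = 1.4,
    point_number: int = 1000,
) -> float | None:
    """Residue SASA divided by its theoretical maximum; ``None`` for residue
    types outside the 20 standard amino acids."""
    res = _residue_atoms(model, residue_number, chain)
    res_name = res.res_name[0]
    max_asa = MAX_ASA.get(res_name)
    if max_asa is None:
        return None
    protein = model.atoms[~model.atoms.hetero & (model.atoms.element != "H")]
    per_atom = struc.sasa(
        protein,
        probe_radius=probe_radius,
        point_number=point_number,
        vdw_radii="Single",
    )
    mask = (protein.res_id == residue_number)
    if chain is not None:
        mask &= protein.chain_id == chain
    total = float(np.nansum(per_atom[mask]))
    return total / max_asa


def burial_class(rsa: float | None) -> str:
    if rsa is None:
        return "unknown"
    if rsa < BURIED_MAX:
        return "buried"
    if rsa <= SURFACE_MIN:
        return "partially buried"
    return "surface"


def annotate_position(
    model: StructureModel,
    query_position: int,
    chain: str | None = None,
    sites: list[str] | None = None,
    probe_radius: float = 1.4,
    point_number: int = 1000,
) -> SiteAnnotation:
    """Distances to every (or the given) named site plus burial class for one
    residue, assuming structure numbering matches query numbering."""
    site_labels = sites if sites is not None else list(model.named_sites)
    distances = {
        label: site_distance(model, query_position, label, chain)
        for label in site_labels
    }
    rsa = relative_accessibility(
        model, query_position, chain, probe_radius, point_number
    )
    return SiteAnnotation(
        query_position=query_position,
        distances=distances,
        relative_accessibility=rsa,
        burial_class=burial_class(rsa),
    )


def write_annotation_table(
    annotations: list[SiteAnnotation], path: str | Path
) -> None:
    site_labels: list[str] = []
    for ann in annotations:
        for label in ann.distances:
            if label not in site_labels:
                site_labels.append(label)
    with open(path, "w") as fh:
        header = ["position"] + [f"dist_{s}" for s in site_labels]
        header += ["relative_accessibility", "burial_class"]
        fh.write("\t".join(header) + "\n")
        for ann in annotations:
            row = [str(ann.query_position)]
            row += [
                f"{ann.distances[s]:.1f}" if s in ann.distances else "NA"
                for s in site_labels
            ]
            rsa = (
                f"{ann.relative_accessibility:.3f}"
                if ann.relative_accessibility is not None
                else "NA"
            )
            row += [rsa, ann.burial_class]
            fh.write("\t".join(row) + "\n")
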