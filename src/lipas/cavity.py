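"""Grid-based detection of interior protein cavities and ligand torsions.

The detector follows the classic dual-probe scheme: a small probe
(``probe_in``, water-sized 1.4 Å) defines which grid points are sterically
free, while a large probe (``probe_out``, 4.0 Å) defines which free space
is reachable from the bulk solvent. Points free to the small probe but
unreachable by the large probe form the interior cavities; connected
components (6-connectivity) below ``min_volume`` are discarded and volume
is reported as voxel count × spacing³ in ų.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .lipid_models import dihedral_angle

log = logging.getLogger(__name__)

#: van der Waals radii in Å (single published element table); unknown
#: elements fall back to 1.70 Å with a logged warning.
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "H": 1.20,
}
FALLBACK_RADIUS = 1.70

#: marker written by the synthetic-structure generator when per-atom radii
#: are carried in the B-factor column
RADII_IN_BFACTOR_REMARK = "RADII ENCODED IN B-FACTOR COLUMN"

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


@dataclass
class Structure:
    """Flat atom table with assigned van der Waals radii."""

    serial: np.ndarray
    name: list
    resname: list
    chain: list
    resnum: np.ndarray
    xyz: np.ndarray  # (n, 3) Å
    element: list
    occupancy: np.ndarray
    is_hetero: np.ndarray
    radii: np.ndarray

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if not np.isfinite(self.xyz).all():
            raise ValidationError("non-finite coordinates in structure")
        self.radii = np.asarray(self.radii, dtype=float)
        if (self.radii <= 0).any():
            raise ValidationError("every atom needs a positive radius")

    def __len__(self):
        return self.xyz.shape[0]

    @classmethod
    def from_arrays(cls, xyz, radii, element="C", resname="UNK",
                    chain="A", is_hetero=True):
        """Build a structure from bare coordinates (synthetic fixtures)."""
        xyz = np.asarray(xyz, dtype=float)
        n = xyz.shape[0]
        radii = np.broadcast_to(np.asarray(radii, dtype=float), (n,)).copy()
        # one residue per atom: PDB atom names are 4 chars, so per-residue
        # name uniqueness cannot be guaranteed for large fixtures
        return cls(
            serial=np.arange(1, n + 1),
            name=[f"X{(i % 999) + 1}" for i in range(n)],
            resname=[resname] * n,
            chain=[chain] * n,
            resnum=np.arange(1, n + 1),
            xyz=xyz,
            element=[element] * n,
            occupancy=np.ones(n),
            is_hetero=np.full(n, bool(is_hetero)),
            radii=radii,
        )


def assign_radii(elements) -> np.ndarray:
    out = np.empty(len(elements))
    unknown = set()
    for i, el in enumerate(elements):
        el = (el or "").strip().upper()
        if el in VDW_RADII:
            out[i] = VDW_RADII[el]
        else:
            out[i] = FALLBACK_RADIUS
            unknown.add(el or "?")
    if unknown:
        log.warning(
            "unknown element(s) %s assigned fallback radius %.2f Å",
            sorted(unknown), FALLBACK_RADIUS,
        )
    return out


def read_structure(source, chain: str | None = None,
                   strip_hetero: bool = False,
                   radii_from_bfactor: bool | None = None) -> Structure:
    """Parse a PDB file into a flat atom table.

    Keeps the first model only and, among alternate locations of an atom,
    the highest-occupancy one (first on ties). Water is always stripped;
    other heteroatoms are stripped when ``strip_hetero`` is set. When
    ``radii_from_bfactor`` is None it is auto-enabled for files carrying
    the generator's REMARK marker.
    """
    import gemmi

    path = str(source)
    try:
        st = gemmi.read_pdb(path)
    except (RuntimeError, ValueError) as exc:
        raise ValidationError(f"cannot parse PDB {path}: {exc}") from exc
    if len(st) == 0:
        raise ValidationError(f"no models in {path}")
    if radii_from_bfactor is None:
        radii_from_bfactor = any(
            RADII_IN_BFACTOR_REMARK in r for r in st.raw_remarks
        )
    model = st[0]
    serial, name, resname, chain_id, resnum = [], [], [], [], []
    xyz, element, occ, het, bfac = [], [], [], [], []
    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        for res in ch:
            if res.name.strip() in _WATER_NAMES or res.is_water():
                continue
            is_het = res.het_flag == "H"
            if strip_hetero and is_het:
                continue
            # highest-occupancy altloc per atom name
            best: dict[str, "gemmi.Atom"] = {}
            for atom in res:
                cur = best.get(atom.name)
                if cur is None or atom.occ > cur.occ:
                    best[atom.name] = atom
            for atom in best.values():
                serial.append(atom.serial)
                name.append(atom.name)
                resname.append(res.name)
                chain_id.append(ch.name)
                resnum.append(res.seqid.num)
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
                element.append(atom.element.name)
                occ.append(atom.occ)
                het.append(is_het)
                bfac.append(atom.b_iso)
    if not xyz:
        raise ValidationError(
            f"empty selection from {path} (chain={chain!r}, "
            f"strip_hetero={strip_hetero})"
        )
    radii = (
        np.asarray(bfac, dtype=float)
        if radii_from_bfactor
        else assign_radii(element)
    )
    if radii_from_bfactor and (radii <= 0).any():
        raise ValidationError("B-factor-encoded radii must be positive")
    return Structure(
        serial=np.asarray(serial, dtype=int),
        name=name,
        resname=resname,
        chain=chain_id,
        resnum=np.asarray(resnum, dtype=int),
        xyz=np.asarray(xyz, dtype=float),
        element=element,
        occupancy=np.asarray(occ, dtype=float),
        is_hetero=np.asarray(het, dtype=bool),
        radii=radii,
    )


def write_structure_pdb(structure: Structure, path,
                        radii_in_bfactor: bool = False) -> None:
    """Write a Structure as a plain PDB file."""
    lines = []
    if radii_in_bfactor:
        lines.append(f"REMARK  99 {RADII_IN_BFACTOR_REMARK}")
    for i in range(len(structure)):
        rec = "HETATM" if structure.is_hetero[i] else "ATOM  "
        nm = structure.name[i]
        nm4 = f" {nm:<3s}" if len(nm) < 4 else nm[:4]
        b = structure.radii[i] if radii_in_bfactor else 0.0
        x, y, z = structure.xyz[i]
        el = (structure.element[i] or "C")[:2]
        lines.append(
            f"{rec}{int(structure.serial[i]) % 100000:5d} {nm4}"
            f" {structure.resname[i][:3]:>3s} {structure.chain[i][:1]:1s}"
            f"{int(structure.resnum[i]) % 10000:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{structure.occupancy[i]:6.2f}{b:6.2f}"
            f"          {el:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class Cavity:
    voxel_count: int
    volume: float  # ų
    centroid: tuple
    voxel_indices: np.ndarray = field(repr=False, default=None)


@dataclass
class CavityReport:
    spacing: float
    probe_in: float
    probe_out: float
    min_volume: float
    cavities: list
    grid_origin: np.ndarray = field(repr=False, default=None)
    grid_shape: tuple = None

    @property
    def volumes(self):
        return [c.volume for c in self.cavities]

    def to_dict(self):
        return {
            "parameters": {
                "spacing": self.spacing,
                "probe_in": self.probe_in,
                "probe_out": self.probe_out,
                "min_volume": self.min_volume,
            },
            "cavities": [
                {
                    "voxel_count": c.voxel_count,
                    "volume_A3": c.volume,
                    "centroid": list(c.centroid),
                }
                for c in self.cavities
            ],
        }


def _stamp_spheres(mask, origin, spacing, centers, radii):
    """Set mask voxels whose centers fall inside any sphere."""
    shape = mask.shape
    for c, r in zip(centers, radii):
        lo = np.maximum(np.floor((c - r - origin) / spacing).astype(int), 0)
        hi = np.minimum(
            np.ceil((c + r - origin) / spacing).astype(int) + 1, shape
        )
        if (lo >= hi).any():
            continue
        ax = [origin[d] + spacing * np.arange(lo[d], hi[d]) - c[d] for d in range(3)]
        d2 = (
            ax[0][:, None, None] ** 2
            + ax[1][None, :, None] ** 2
            + ax[2][None, None, :] ** 2
        )
        sub = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        sub |= d2 <= r * r


def detect_cavities(structure: Structure, spacing: float = 0.6,
                    probe_in: float = 1.4, probe_out: float = 4.0,
                    min_volume: float = 5.0,
                    voxel_budget: int = 300_000_000) -> CavityReport:
    """Detect interior cavities of a structure on a regular grid.

    A voxel belongs to a cavity when it lies outside every
    (atom radius + probe_in) sphere yet cannot be touched by the
    probe_out sphere rolling in from the bulk. Components below
    ``min_volume`` ų are dropped; the report is sorted by volume
    descending.
    """
    if spacing <= 0:
        raise ValidationError("spacing must be positive")
    if not (probe_out > probe_in > 0):
        raise ValidationError("need probe_out > probe_in > 0")
    if len(structure) < 4:
        raise ValidationError("structure too small for cavity detection (<4 atoms)")
    xyz = structure.xyz
    radii = structure.radii
    margin = probe_out + radii.max() + 2 * spacing
    # snap the origin to an absolute lattice so voxelization does not
    # depend on the margin (probe_out) choice
    origin = spacing * np.floor((xyz.min(axis=0) - margin) / spacing)
    top = xyz.max(axis=0) + margin
    shape = tuple(np.ceil((top - origin) / spacing).astype(int) + 1)
    n_vox = int(np.prod(shape))
    if n_vox > voxel_budget:
        raise ValidationError(
            f"grid of {n_vox} voxels exceeds budget {voxel_budget}; "
            "increase spacing or the budget"
        )
    occ_in = np.zeros(shape, dtype=bool)
    _stamp_spheres(occ_in, origin, spacing, xyz, radii + probe_in)
    occ_out = np.zeros(shape, dtype=bool)
    _stamp_spheres(occ_out, origin, spacing, xyz, radii + probe_out)

    # bulk = big-probe centers connected to the box boundary
    free_out = ~occ_out
    labels, _ = ndimage.label(free_out)
    boundary_labels = set()
    for sl in (labels[0], labels[-1], labels[:, 0], labels[:, -1],
               labels[:, :, 0], labels[:, :, -1]):
        boundary_labels.update(np.unique(sl))
    boundary_labels.discard(0)
    reachable_centers = np.isin(labels, list(boundary_labels))
    # space covered by the big probe = within probe_out of a reachable center
    dist = ndimage.distance_transform_edt(
        ~reachable_centers, sampling=(spacing,) * 3
    )
    exterior = dist <= probe_out

    cavity_mask = (~occ_in) & (~exterior)
    labels, n_lab = ndimage.label(
        cavity_mask, structure=ndimage.generate_binary_structure(3, 1)
    )
    cavities = []
    if n_lab:
        counts = np.bincount(labels.ravel())
        for lab in range(1, n_lab + 1):
            count = int(counts[lab])
            volume = count * spacing**3
            if volume < min_volume:
                continue
            idx = np.argwhere(labels == lab)
            centroid = tuple(origin + spacing * idx.mean(axis=0))
            cavities.append(
                Cavity(voxel_count=count, volume=volume,
                       centroid=centroid, voxel_indices=idx)
            )
    cavities.sort(key=lambda c: c.volume, reverse=True)
    return CavityReport(
        spacing=spacing,
        probe_in=probe_in,
        probe_out=probe_out,
        min_volume=min_volume,
        cavities=cavities,
        grid_origin=origin,
        grid_shape=shape,
    )


def cavity_voxels_pdb(report: CavityReport) -> str:
    """Cavity voxels as PDB pseudo-atoms, one residue per cavity."""
    lines = []
    serial = 1
    for k, cav in enumerate(report.cavities, start=1):
        for idx in cav.voxel_indices:
            x, y, z = report.grid_origin + report.spacing * idx
            lines.append(
                f"HETATM{serial % 100000:5d}  DU  CAV A{k % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          DU"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


_CARBON_NUM = re.compile(r"^C(\d+)['A]?$")


def extract_ligand_torsions(structure: Structure, resname: str,
                            chain: str | None = None) -> np.ndarray:
    """Backbone dihedrals of a ligand's carbon chain, in degrees.

    Carbons of the named residue are bonded when closer than 1.8 Å; the
    chain must be linear (two terminal carbons, the rest with exactly two
    carbon neighbours). Torsions are ordered from C1 (or the
    lowest-numbered/lowest-serial terminus) toward the terminal methyl.
    """
    sel = [
        i for i in range(len(structure))
        if structure.resname[i].strip() == resname
        and (chain is None or structure.chain[i] == chain)
        and (structure.element[i] or "").strip().upper() == "C"
    ]
    if not sel:
        raise ValidationError(
            f"ligand {resname!r} (chain {chain!r}) not found or has no carbons"
        )
    xyz = structure.xyz[sel]
    n = len(sel)
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    adj = (d <= 1.8) & ~np.eye(n, dtype=bool)
    deg = adj.sum(axis=1)
    ends = np.where(deg == 1)[0]
    if (deg > 2).any() or len(ends) != 2:
        branch = [structure.name[sel[i]] for i in np.where(deg > 2)[0]]
        raise ValidationError(
            f"carbon skeleton of {resname} is not a single linear chain "
            f"(termini: {len(ends)}, branch points: {branch or 'none'})"
        )

    def atom_number(i):
        m = _CARBON_NUM.match(structure.name[sel[i]].strip())
        return int(m.group(1)) if m else None

    nums = [atom_number(e) for e in ends]
    if all(v is not None for v in nums):
        start = ends[int(np.argmin(nums))]
    else:
        start = ends[int(np.argmin([structure.serial[sel[e]] for e in ends]))]
    # walk the path
    order = [start]
    prev = -1
    while len(order) < n:
        nbrs = [j for j in np.where(adj[order[-1]])[0] if j != prev]
        if not nbrs:
            raise ValidationError(f"carbon chain of {resname} is disconnected")
        prev = order[-1]
        order.append(nbrs[0])
    path = xyz[order]
    return np.array(
        [
            dihedral_angle(path[t], path[t + 1], path[t + 2], path[t + 3])
            for t in range(n - 3)
        ]
    )
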