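"""Fatty-acid chain topologies and torsion-angle conformation building.

A free fatty acid is represented as a united-atom chain: every backbone
carbon is a single interaction site and the carboxylate head is one united
site at position C1. Geometry is rigid internal coordinates — fixed bond
lengths (1.53 Å C–C, 1.33 Å C=C) and fixed valence angles (111° at sp³
carbons, 120° at sp² carbons) — so a conformation is fully determined by
its backbone torsion angles. Torsions that span a C=C double bond are
frozen at the declared geometry (cis → 0°, trans → 180°).

Angle convention throughout: IUPAC signed dihedrals, degrees, (−180, 180].
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError

BOND_CC = 1.53  # Å, single C–C
BOND_CDC = 1.33  # Å, C=C
ANGLE_SP3 = 111.0  # deg
ANGLE_SP2 = 120.0  # deg

#: torsion-class labels used by the energy model
CLASS_FROZEN = "frozen"
CLASS_SP3 = "sp3_sp3"
CLASS_ALLYLIC = "allylic"


def normalize_angle(angle_deg: float) -> float:
    """Map an angle in degrees to the (−180, 180] convention."""
    a = math.fmod(angle_deg, 360.0)
    if a <= -180.0:
        a += 360.0
    elif a > 180.0:
        a -= 360.0
    return a


@dataclass(frozen=True)
class AcylChainTopology:
    """Declarative description of a fatty-acid chain.

    Parameters
    ----------
    name : str
        Label, e.g. ``"oleic"``.
    n_carbons : int
        Backbone length including the carboxylate united site C1
        (2–24 supported).
    double_bonds : tuple of (int, str)
        Each entry ``(p, geometry)`` places a C=C between carbons ``p``
        and ``p+1`` (1-based), geometry ``"cis"`` or ``"trans"``.
    head_group : str
        Only ``"carboxylate-united-atom"`` is implemented.
    """

    name: str
    n_carbons: int
    double_bonds: tuple[tuple[int, str], ...] = ()
    head_group: str = "carboxylate-united-atom"

    def __post_init__(self) -> None:
        if not (2 <= self.n_carbons <= 24):
            raise ValidationError(
                f"n_carbons must be in [2, 24], got {self.n_carbons}"
            )
        if self.head_group != "carboxylate-united-atom":
            raise ValidationError(f"unsupported head group {self.head_group!r}")
        object.__setattr__(
            self,
            "double_bonds",
            tuple((int(p), str(g)) for p, g in self.double_bonds),
        )
        prev = None
        for p, geom in self.double_bonds:
            if geom not in ("cis", "trans"):
                raise ValidationError(f"double-bond geometry must be cis/trans, got {geom!r}")
            if not (2 <= p <= self.n_carbons - 1):
                raise ValidationError(
                    f"double-bond position {p} outside valid range "
                    f"[2, {self.n_carbons - 1}]"
                )
            if prev is not None:
                if p <= prev:
                    raise ValidationError(
                        f"double-bond positions must be strictly increasing "
                        f"({prev} then {p})"
                    )
                if p == prev + 1:
                    raise ValidationError(
                        f"cumulated diene at positions {prev},{p} not allowed"
                    )
            prev = p

    # ---- derived geometry ------------------------------------------------

    @property
    def n_torsions(self) -> int:
        """Number of backbone torsions (= n_carbons − 3)."""
        return max(self.n_carbons - 3, 0)

    @property
    def sp2_atoms(self) -> frozenset[int]:
        """0-based indices of sp² carbons."""
        out = set()
        for p, _ in self.double_bonds:
            out.update((p - 1, p))
        return frozenset(out)

    def bond_lengths(self) -> np.ndarray:
        """Length of bond i (between atoms i and i+1, 0-based), in Å."""
        double = {p - 1 for p, _ in self.double_bonds}
        return np.array(
            [BOND_CDC if i in double else BOND_CC for i in range(self.n_carbons - 1)]
        )

    def bond_angles(self) -> np.ndarray:
        """Valence angle at atom j (j = 1..n−2), in degrees."""
        sp2 = self.sp2_atoms
        return np.array(
            [ANGLE_SP2 if j in sp2 else ANGLE_SP3 for j in range(1, self.n_carbons - 1)]
        )

    def torsion_classes(self) -> list[str]:
        """Class of each torsion t (atoms t..t+3, central bond t+1–t+2)."""
        frozen = {p - 2 for p, _ in self.double_bonds}
        allylic = set()
        for p, _ in self.double_bonds:
            allylic.update((p - 3, p - 1))
        classes = []
        for t in range(self.n_torsions):
            if t in frozen:
                classes.append(CLASS_FROZEN)
            elif t in allylic:
                classes.append(CLASS_ALLYLIC)
            else:
                classes.append(CLASS_SP3)
        return classes

    def frozen_torsions(self) -> dict[int, float]:
        """Map torsion index → frozen value in degrees (cis 0, trans 180)."""
        out = {}
        for p, geom in self.double_bonds:
            t = p - 2
            if 0 <= t < self.n_torsions:
                out[t] = 0.0 if geom == "cis" else 180.0
        return out

    def site_types(self) -> list[str]:
        """United-atom site type per backbone position."""
        sp2 = self.sp2_atoms
        types = []
        for i in range(self.n_carbons):
            if i == 0:
                types.append("COO")
            elif i == self.n_carbons - 1:
                types.append("CH3")
            elif i in sp2:
                types.append("CH")
            else:
                types.append("CH2")
        return types

    # ---- serialization ---------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "n_carbons": self.n_carbons,
                "double_bonds": [[p, g] for p, g in self.double_bonds],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "AcylChainTopology":
        d = json.loads(text)
        return cls(
            name=d["name"],
            n_carbons=d["n_carbons"],
            double_bonds=tuple((p, g) for p, g in d.get("double_bonds", [])),
        )


#: the four chains discussed throughout: saturated stearic acid, the
#: mono-unsaturated oleic and cis-vaccenic acids, and di-unsaturated
#: linoleic acid.
REGISTRY: dict[str, AcylChainTopology] = {
    "stearic": AcylChainTopology("stearic", 18, ()),
    "oleic": AcylChainTopology("oleic", 18, ((9, "cis"),)),
    "linoleic": AcylChainTopology("linoleic", 18, ((9, "cis"), (12, "cis"))),
    "cis-vaccenic": AcylChainTopology("cis-vaccenic", 18, ((11, "cis"),)),
}


def make_topology(name_or_spec) -> AcylChainTopology:
    """Look up a registered chain or validate an explicit specification.

    Accepts a registry key (``"oleic"``, ...), an :class:`AcylChainTopology`
    (validated on construction, returned as-is), or a dict with keys
    ``name``, ``n_carbons``, ``double_bonds``.
    """
    if isinstance(name_or_spec, AcylChainTopology):
        return name_or_spec
    if isinstance(name_or_spec, str):
        try:
            return REGISTRY[name_or_spec]
        except KeyError:
            raise ValidationError(
                f"unknown lipid {name_or_spec!r}; known: {sorted(REGISTRY)}"
            ) from None
    if isinstance(name_or_spec, dict):
        return AcylChainTopology(
            name=name_or_spec.get("name", "custom"),
            n_carbons=name_or_spec["n_carbons"],
            double_bonds=tuple(
                (p, g) for p, g in name_or_spec.get("double_bonds", ())
            ),
        )
    raise ValidationError(f"cannot interpret topology spec {name_or_spec!r}")


@dataclass
class Conformation:
    """A 3-D realization of a chain at given backbone torsions."""

    topology: AcylChainTopology
    torsions: np.ndarray  # degrees, (−180, 180], length n_carbons − 3
    coordinates: np.ndarray = field(repr=False)  # (n_carbons, 3) Å

    def pairwise_distances(self) -> np.ndarray:
        d = self.coordinates[:, None, :] - self.coordinates[None, :, :]
        return np.sqrt((d**2).sum(-1))

    def to_xyz(self) -> str:
        lines = [str(self.topology.n_carbons), self.topology.name]
        for (x, y, z) in self.coordinates:
            lines.append(f"C {x:.6f} {y:.6f} {z:.6f}")
        return "\n".join(lines) + "\n"

    def to_pdb(self) -> str:
        """Minimal single-chain HETATM record block (element C throughout)."""
        lines = []
        res = self.topology.name[:3].upper() or "LIG"
        for i, (x, y, z) in enumerate(self.coordinates, start=1):
            lines.append(
                f"HETATM{i:5d}  C{i:<2d} {res:>3s} A   1    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {'C':>2s}"
            )
        lines.append("END")
        return "\n".join(lines) + "\n"


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral of four points, IUPAC convention, degrees."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return normalize_angle(math.degrees(math.atan2(y, x)))


def measure_torsions(coordinates: np.ndarray) -> np.ndarray:
    """Backbone dihedrals along a linear chain of coordinates, degrees."""
    coords = np.asarray(coordinates, dtype=float)
    n = coords.shape[0]
    return np.array(
        [dihedral_angle(coords[t], coords[t + 1], coords[t + 2], coords[t + 3])
         for t in range(n - 3)]
    )


def _expand_torsions(topology: AcylChainTopology, torsions) -> np.ndarray:
    """Validate/expand a torsion vector to full length, filling frozen slots."""
    frozen = topology.frozen_torsions()
    torsions = np.asarray(torsions, dtype=float)
    nt = topology.n_torsions
    n_free = nt - len(frozen)
    if torsions.shape == (nt,):
        full = np.array([normalize_angle(a) for a in torsions])
        for t, val in frozen.items():
            if abs(normalize_angle(full[t] - val)) > 1e-6:
                raise ValidationError(
                    f"torsion {t} spans a double bond and is frozen at "
                    f"{val}°; got {full[t]}°"
                )
            full[t] = val
        return full
    if torsions.shape == (n_free,):
        full = np.empty(nt)
        it = iter(torsions)
        for t in range(nt):
            full[t] = frozen[t] if t in frozen else normalize_angle(next(it))
        return full
    raise ValidationError(
        f"torsion vector length {torsions.shape} incompatible with "
        f"{topology.name}: expected {nt} (full) or {n_free} (rotatable only)"
    )


def build_coordinates(topology: AcylChainTopology, torsions) -> Conformation:
    """Build Cartesian coordinates from a torsion vector by chain extension.

    The first three atoms are placed canonically (C1 at the origin, C2 on
    the +x axis, C3 in the xy-plane); each subsequent atom is appended in
    the natural-extension reference frame from its bond length, valence
    angle and dihedral. Frozen double-bond torsions may be omitted from
    ``torsions`` or supplied at their declared value.
    """
    topology = make_topology(topology)
    full = _expand_torsions(topology, torsions)
    r = topology.bond_lengths()
    theta = np.radians(topology.bond_angles())
    phi = np.radians(full)
    coords = _nerf_build(topology.n_carbons, r, theta, phi)
    return Conformation(topology=topology, torsions=full, coordinates=coords)


def _nerf_build(n: int, r: np.ndarray, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    coords = np.zeros((n, 3))
    if n >= 2:
        coords[1] = (r[0], 0.0, 0.0)
    if n >= 3:
        coords[2] = coords[1] + r[1] * np.array(
            [-math.cos(theta[0]), math.sin(theta[0]), 0.0]
        )
    for i in range(3, n):
        a, b, c = coords[i - 3], coords[i - 2], coords[i - 1]
        bc = c - b
        bc /= np.linalg.norm(bc)
        ab = b - a
        nvec = np.cross(ab, bc)
        nvec /= np.linalg.norm(nvec)
        mvec = np.cross(nvec, bc)
        bl, th, ph = r[i - 1], theta[i - 2], phi[i - 3]
        d_local = np.array(
            [
                -bl * math.cos(th),
                bl * math.sin(th) * math.cos(ph),
                bl * math.sin(th) * math.sin(ph),
            ]
        )
        coords[i] = c + d_local[0] * bc + d_local[1] * mvec + d_local[2] * nvec
    return coords
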