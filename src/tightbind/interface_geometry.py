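"""Structural measurements for protease-inhibitor complexes.

Implements the measurement suite used to characterize serine-protease /
Kunitz-inhibitor interfaces:

* least-squares rigid superposition (Kabsch) and C-alpha RMSD,
* the *docking angle* — after superimposing the protease partners of two
  complexes, the residual best-fit rotation that maps one inhibitor copy
  onto the other, reported as an axis-angle magnitude,
* side-chain chi1 dihedrals (IUPAC signed N-CA-CB-gamma), used to track
  catalytic-histidine rotamer changes,
* distance-based contact classification (hydrogen bond / ionic / van der
  Waals / sub-van-der-Waals close approach),
* bond angles subtended at a central atom (tetrahedral-intermediate
  geometry at the P1 carbonyl carbon), and
* Lee-Richards solvent-accessible surface area by z-slice arc integration,
  with buried interface area as SASA(A) + SASA(B) - SASA(AB).

All operations take :class:`~tightbind.structure_io.StructureModel`
selections and are invariant under global rigid motion of the input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .structure_io import (
    AtomRecord,
    SelectionError,
    StructureModel,
    ResidueSelector,
    ca_atoms,
    select,
    select_chain,
)

__all__ = [
    "Superposition",
    "DihedralMeasure",
    "ContactRecord",
    "ContactThresholds",
    "SasaResult",
    "GeometryError",
    "superpose",
    "rotation_angle",
    "docking_angle",
    "chi1",
    "dihedral",
    "contacts",
    "atom_distance",
    "angles_at_center",
    "sasa",
    "buried_area",
    "CHOTHIA_RADII",
]


class GeometryError(ValueError):
    """Degenerate or inconsistent geometry input."""


# ---------------------------------------------------------------------------
# superposition

@dataclass(frozen=True)
class Superposition:
    """Rigid transform ``x -> R x + t`` minimizing the RMSD of paired atoms."""

    rotation: np.ndarray  # (3, 3), proper orthogonal
    translation: np.ndarray  # (3,)
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def _paired_coords(obj) -> np.ndarray:
    if isinstance(obj, StructureModel):
        return obj.coords
    return np.asarray(obj, dtype=float)


def superpose(moving, fixed) -> Superposition:
    """Least-squares rigid superposition of *moving* onto *fixed*.

    Arguments are equal-length paired atom sets (StructureModel or (n, 3)
    arrays).  Collinear or coincident point sets leave the rotation
    underdetermined and raise :class:`GeometryError`.
    """
    mv, fx = _paired_coords(moving), _paired_coords(fixed)
    if mv.shape != fx.shape or mv.ndim != 2 or mv.shape[1] != 3:
        raise GeometryError(
            f"paired atom sets must have identical (n, 3) shapes; got "
            f"{mv.shape} and {fx.shape}"
        )
    n = mv.shape[0]
    if n < 3:
        raise GeometryError("superposition needs >= 3 paired atoms")
    cm, cf = mv.mean(axis=0), fx.mean(axis=0)
    mv_c, fx_c = mv - cm, fx - cf
    # Rotation is only determined when the paired set spans a plane.
    if np.linalg.matrix_rank(mv_c, tol=1e-8) < 2:
        raise GeometryError("degenerate (collinear or coincident) atom set")
    rot, _ = Rotation.align_vectors(fx_c, mv_c)
    r = rot.as_matrix()
    t = cf - r @ cm
    diff = mv @ r.T + t - fx
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return Superposition(rotation=r, translation=t, rmsd=rmsd, n_atoms=n)


def rotation_angle(sup: Superposition | np.ndarray) -> float:
    """Axis-angle magnitude of a rotation, in degrees within [0, 180]."""
    r = sup.rotation if isinstance(sup, Superposition) else np.asarray(sup)
    cos = (np.trace(r) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


def _pair_by_residue(a: StructureModel, b: StructureModel) -> tuple[np.ndarray, np.ndarray]:
    """Pair single-atom-per-residue sets by (resnum, icode); unpaired dropped."""
    index_a = {(x.resnum, x.icode): x for x in a.atoms}
    index_b = {(x.resnum, x.icode): x for x in b.atoms}
    shared = [k for k in index_a if k in index_b]
    if not shared:
        missing = sorted(set(index_a) - set(index_b))[:5]
        raise SelectionError(
            f"no shared residues between {a.label!r} and {b.label!r}; "
            f"first unmatched: {missing}"
        )
    ca = np.array([index_a[k].xyz for k in shared])
    cb = np.array([index_b[k].xyz for k in shared])
    return ca, cb


def docking_angle(
    complex1: StructureModel,
    complex2: StructureModel,
    protease_chains: str | tuple[str, str],
    inhibitor_chains: str | tuple[str, str],
) -> float:
    """Rotation (degrees) relating two copies of an inhibitor after their
    protease partners are superimposed.

    The protease chains of the two complexes are superimposed over shared
    C-alpha atoms; that transform is applied to the first complex, and the
    residual best-fit rotation of inhibitor copy 1 onto copy 2 (again over
    shared C-alpha atoms) is returned as an axis-angle magnitude.
    """
    pc = (protease_chains, protease_chains) if isinstance(protease_chains, str) else protease_chains
    ic = (inhibitor_chains, inhibitor_chains) if isinstance(inhibitor_chains, str) else inhibitor_chains
    prot1, prot2 = ca_atoms(complex1, pc[0]), ca_atoms(complex2, pc[1])
    inh1, inh2 = ca_atoms(complex1, ic[0]), ca_atoms(complex2, ic[1])
    p1, p2 = _pair_by_residue(prot1, prot2)
    sup_prot = superpose(p1, p2)
    i1, i2 = _pair_by_residue(inh1, inh2)
    sup_inh = superpose(sup_prot.apply(i1), i2)
    return rotation_angle(sup_inh)


# ---------------------------------------------------------------------------
# dihedrals and angles

def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle (degrees, IUPAC convention) of four points."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    # b0 points from the pivot back to the first atom so that an eclipsed
    # (cis) arrangement reads 0 degrees, per the IUPAC convention.
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    n1 = np.linalg.norm(b1)
    if n1 == 0:
        raise GeometryError("coincident central atoms in dihedral")
    b1u = b1 / n1
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    return float(np.degrees(np.arctan2(y, x)))


#: Gamma atom defining chi1 per residue type (IUPAC).
_CHI1_GAMMA = {
    "SER": "OG", "THR": "OG1", "CYS": "SG", "VAL": "CG1", "ILE": "CG1",
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "GLN": "CG", "GLU": "CG",
    "HIS": "CG", "LEU": "CG", "LYS": "CG", "MET": "CG", "PHE": "CG",
    "PRO": "CG", "TRP": "CG", "TYR": "CG",
}


@dataclass(frozen=True)
class DihedralMeasure:
    """A named side-chain torsion of one residue."""

    selector: ResidueSelector
    resname: str
    angle_name: str
    degrees: float


def chi1(model: StructureModel, residue: ResidueSelector | str) -> DihedralMeasure:
    """Signed chi1 (N-CA-CB-gamma) of one residue, in (-180, 180]."""
    if isinstance(residue, str):
        from .structure_io import parse_selector

        residue = parse_selector(residue)
    res_atoms = select(model, ResidueSelector(residue.resnum, residue.chain,
                                              None, residue.icode))
    resname = res_atoms.atoms[0].resname
    gamma = _CHI1_GAMMA.get(resname)
    if gamma is None:
        raise GeometryError(f"residue {resname} {residue} has no chi1")
    positions = {}
    for name in ("N", "CA", "CB", gamma):
        match = [a for a in res_atoms.atoms if a.name == name]
        if not match:
            raise GeometryError(
                f"residue {resname} {residue} is missing atom {name} for chi1"
            )
        positions[name] = match[0].xyz
    value = dihedral(positions["N"], positions["CA"], positions["CB"], positions[gamma])
    if value <= -180.0:
        value += 360.0
    return DihedralMeasure(residue, resname, "chi1", value)


def _single_atom(model: StructureModel, sel: ResidueSelector | str) -> AtomRecord:
    sub = select(model, sel)
    if len(sub) != 1:
        raise SelectionError(
            f"selector {sel} is ambiguous: matches {len(sub)} atoms"
        )
    return sub.atoms[0]


def atom_distance(model: StructureModel, sel_a, sel_b) -> float:
    """Euclidean distance (Angstrom) between two single-atom selections."""
    a, b = _single_atom(model, sel_a), _single_atom(model, sel_b)
    return float(np.linalg.norm(a.xyz - b.xyz))


def angles_at_center(
    model: StructureModel, center, substituents
) -> tuple[list[float], float]:
    """All unique pairwise angles (degrees) subtended at *center* by the
    substituent atoms, plus their arithmetic mean."""
    c = _single_atom(model, center).xyz
    subs = [_single_atom(model, s).xyz for s in substituents]
    if len(subs) < 2:
        raise GeometryError("need >= 2 substituent atoms")
    vecs = []
    for p in subs:
        v = p - c
        norm = np.linalg.norm(v)
        if norm == 0:
            raise GeometryError("substituent coincides with the central atom")
        vecs.append(v / norm)
    angles = []
    for i in range(len(vecs)):
        for j in range(i + 1, len(vecs)):
            cos = float(np.clip(np.dot(vecs[i], vecs[j]), -1.0, 1.0))
            angles.append(float(np.degrees(np.arccos(cos))))
    return angles, float(np.mean(angles))


# ---------------------------------------------------------------------------
# contacts

@dataclass(frozen=True)
class ContactThresholds:
    """Distance cutoffs (Angstrom) for contact classification."""

    hbond: float = 3.2  # donor/acceptor heavy-atom pairs
    ionic: float = 4.0  # oppositely charged side-chain groups
    vdw: float = 4.0  # any heavy-atom pair
    close_approach: float = 3.4  # below normal van der Waals contact


@dataclass(frozen=True)
class ContactRecord:
    atom_a: AtomRecord
    atom_b: AtomRecord
    distance: float
    contact_class: str  # hbond | ionic | vdw | close_approach


# Heavy-atom donor/acceptor typing (no hydrogens at these resolutions).
_DONORS = {
    ("*", "N"),  # backbone amide (PRO excluded below)
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"), ("CYS", "SG"),
    ("ASN", "ND2"), ("GLN", "NE2"), ("HIS", "ND1"), ("HIS", "NE2"),
    ("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("TRP", "NE1"), ("HOH", "O"),
}
_ACCEPTORS = {
    ("*", "O"), ("*", "OXT"),  # backbone carbonyl / C-terminal carboxylate
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
    ("ASN", "OD1"), ("GLN", "OE1"),
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
    ("HIS", "ND1"), ("HIS", "NE2"), ("MET", "SD"), ("HOH", "O"),
}
_POSITIVE = {
    ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE"),
    ("LYS", "NZ"), ("HIS", "ND1"), ("HIS", "NE2"),
}
_NEGATIVE = {
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
    ("*", "OXT"),
}


def _typed(a: AtomRecord, table: set) -> bool:
    if (a.resname, a.name) in table:
        return True
    if ("*", a.name) in table:
        if a.name == "N" and a.resname == "PRO":
            return False
        return True
    return False


def contacts(
    group_a: StructureModel,
    group_b: StructureModel,
    thresholds: ContactThresholds = ContactThresholds(),
) -> list[ContactRecord]:
    """Classified inter-group heavy-atom contacts.

    Every A-B pair within the maximum threshold appears exactly once.
    Classification priority: *ionic* (oppositely charged groups within the
    ionic cutoff) > *hbond* (donor/acceptor pair within the H-bond cutoff)
    > *close_approach* (below normal van der Waals contact distance)
    > *vdw*.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise SelectionError("both contact groups must be non-empty")
    atoms_a = [a for a in group_a.atoms if a.element != "H"]
    atoms_b = [a for a in group_b.atoms if a.element != "H"]
    max_d = max(thresholds.hbond, thresholds.ionic, thresholds.vdw)
    tree = cKDTree(np.array([a.xyz for a in atoms_b]))
    records: list[ContactRecord] = []
    for a in atoms_a:
        for j in tree.query_ball_point(a.xyz, max_d):
            b = atoms_b[j]
            d = float(np.linalg.norm(a.xyz - b.xyz))
            if d <= 0:
                raise GeometryError(
                    f"coincident atoms {a.chain}:{a.resnum}:{a.name} and "
                    f"{b.chain}:{b.resnum}:{b.name}"
                )
            opposite = (
                (_typed(a, _POSITIVE) and _typed(b, _NEGATIVE))
                or (_typed(a, _NEGATIVE) and _typed(b, _POSITIVE))
            )
            donor_acceptor = (
                (_typed(a, _DONORS) and _typed(b, _ACCEPTORS))
                or (_typed(a, _ACCEPTORS) and _typed(b, _DONORS))
            )
            if opposite and d <= thresholds.ionic:
                cls = "ionic"
            elif donor_acceptor and d <= thresholds.hbond:
                cls = "hbond"
            elif d < thresholds.close_approach:
                cls = "close_approach"
            elif d <= thresholds.vdw:
                cls = "vdw"
            else:
                continue
            records.append(ContactRecord(a, b, d, cls))
    records.sort(key=lambda r: r.distance)
    return records


# ---------------------------------------------------------------------------
# solvent-accessible surface area (Lee & Richards z-slice integration)

#: United heavy-atom radii (Angstrom), Chothia-style.
CHOTHIA_RADII = {"C": 1.87, "N": 1.65, "O": 1.40, "S": 1.85, "P": 1.90}

DEFAULT_PROBE = 1.4
DEFAULT_SLICE = 0.1


@dataclass
class SasaResult:
    """Per-atom and total solvent-accessible surface areas (Angstrom^2)."""

    per_atom: np.ndarray
    probe: float
    slice_spacing: float
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())


def _merge_arc_length(intervals: list[tuple[float, float]]) -> float:
    """Total length of the union of angular (start, length) intervals on a
    circle, handling wrap-around at 2*pi."""
    if not intervals:
        return 0.0
    two_pi = 2.0 * math.pi
    segments: list[tuple[float, float]] = []
    for start, length in intervals:
        if length >= two_pi:
            return two_pi
        s = start % two_pi
        e = s + length
        if e <= two_pi:
            segments.append((s, e))
        else:
            segments.append((s, two_pi))
            segments.append((0.0, e - two_pi))
    segments.sort()
    total = 0.0
    cur_s, cur_e = segments[0]
    for s, e in segments[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    total += cur_e - cur_s
    return min(total, two_pi)


def atom_radii(
    atoms: list[AtomRecord], radii: dict[str, float] | None = None
) -> np.ndarray:
    radii = radii or CHOTHIA_RADII
    out = np.empty(len(atoms))
    for i, a in enumerate(atoms):
        r = radii.get(a.element)
        if r is None:
            raise GeometryError(
                f"no radius for element {a.element!r} of atom "
                f"{a.chain}:{a.resnum}:{a.name}; supply a radii table"
            )
        out[i] = r
    return out


def sasa(
    model: StructureModel,
    probe: float = DEFAULT_PROBE,
    slice_spacing: float = DEFAULT_SLICE,
    radii: dict[str, float] | None = None,
    include_waters: bool = False,
) -> SasaResult:
    """Lee-Richards solvent-accessible surface area.

    Each atom sphere is expanded by the probe radius and cut by planes
    normal to z at the given spacing; on each plane the accessible arc of
    the atom's circle (the part not inside any neighbouring expanded
    sphere) is integrated, and the zone area ``2 pi R dz`` is weighted by
    the accessible fraction.  Deterministic for fixed slice spacing.
    Hydrogens are ignored (united heavy-atom radii).
    """
    atoms = [
        a for a in model.atoms
        if a.element != "H" and (include_waters or not a.is_water)
    ]
    if not atoms:
        raise GeometryError("no atoms with assigned radii to compute SASA for")
    rad = atom_radii(atoms, radii) + probe
    xyz = np.array([a.xyz for a in atoms])
    n = len(atoms)
    tree = cKDTree(xyz)
    max_r = rad.max()
    pairs = tree.query_pairs(2.0 * max_r, output_type="ndarray")
    neighbors: list[list[int]] = [[] for _ in range(n)]
    for i, j in pairs:
        if np.linalg.norm(xyz[i] - xyz[j]) < rad[i] + rad[j]:
            neighbors[i].append(j)
            neighbors[j].append(i)

    # Slicing planes lie on an absolute grid (multiples of the spacing
    # offset by half a step) so that the areas of disjoint subsets add
    # exactly and part/complex differences are free of grid jitter.
    z_min = 0.0
    areas = np.zeros(n)
    two_pi = 2.0 * math.pi
    for i in range(n):
        ri = rad[i]
        zi = xyz[i, 2]
        nbr = neighbors[i]
        nbr_xyz = xyz[nbr] if nbr else np.empty((0, 3))
        nbr_rad = rad[nbr] if nbr else np.empty(0)
        dx = nbr_xyz[:, 0] - xyz[i, 0] if nbr else np.empty(0)
        dy = nbr_xyz[:, 1] - xyz[i, 1] if nbr else np.empty(0)
        d_xy = np.hypot(dx, dy)
        azimuth = np.arctan2(dy, dx)
        # global slicing planes so disjoint unions are strictly additive
        k_lo = int(math.ceil((zi - ri - z_min) / slice_spacing - 0.5))
        k_hi = int(math.floor((zi + ri - z_min) / slice_spacing - 0.5))
        area_i = 0.0
        for k in range(k_lo, k_hi + 1):
            z = z_min + (k + 0.5) * slice_spacing
            dz = z - zi
            under = ri * ri - dz * dz
            if under <= 0.0:
                continue
            r_slice = math.sqrt(under)
            # slab represented by this plane; outermost slabs absorb the
            # polar caps so the slab heights sum exactly to the diameter
            lower = z - slice_spacing / 2.0 if k > k_lo else zi - ri
            upper = z + slice_spacing / 2.0 if k < k_hi else zi + ri
            height = upper - lower
            occluded: list[tuple[float, float]] = []
            buried = False
            for m in range(len(nbr)):
                dzj = z - nbr_xyz[m, 2]
                under_j = nbr_rad[m] ** 2 - dzj * dzj
                if under_j <= 0.0:
                    continue
                rj = math.sqrt(under_j)
                d = d_xy[m]
                if d >= r_slice + rj:
                    continue
                if d + r_slice <= rj:
                    buried = True
                    break
                if d + rj <= r_slice:
                    continue
                cos_half = (d * d + r_slice * r_slice - rj * rj) / (2.0 * d * r_slice)
                half = math.acos(min(max(cos_half, -1.0), 1.0))
                occluded.append((azimuth[m] - half, 2.0 * half))
            if buried:
                continue
            acc = two_pi - _merge_arc_length(occluded)
            # zone area of a sphere between parallel planes: 2*pi*R*height
            area_i += acc * ri * height
        areas[i] = area_i
    return SasaResult(per_atom=areas, probe=probe,
                      slice_spacing=slice_spacing, atoms=atoms)


def buried_area(
    complex_model: StructureModel,
    part_a_chains,
    part_b_chains,
    probe: float = DEFAULT_PROBE,
    slice_spacing: float = DEFAULT_SLICE,
    radii: dict[str, float] | None = None,
) -> float:
    """Interface area buried between two parts of a complex (Angstrom^2).

    ``SASA(A alone) + SASA(B alone) - SASA(A+B)``; symmetric in the two
    parts.  Parts are named by chain ids and must not overlap.
    """
    part_a_chains = [part_a_chains] if isinstance(part_a_chains, str) else list(part_a_chains)
    part_b_chains = [part_b_chains] if isinstance(part_b_chains, str) else list(part_b_chains)
    overlap = set(part_a_chains) & set(part_b_chains)
    if overlap:
        raise GeometryError(f"part selections overlap on chains {sorted(overlap)}")

    def part(chains) -> StructureModel:
        sub = complex_model.filter(
            lambda a: a.chain in chains and not a.is_water,
            label=f"{complex_model.label}[{'+'.join(chains)}]",
        )
        if len(sub) == 0:
            raise SelectionError(f"chains {chains} match no atoms")
        return sub

    a = part(part_a_chains)
    b = part(part_b_chains)
    ab = part(part_a_chains + part_b_chains)
    kwargs = dict(probe=probe, slice_spacing=slice_spacing, radii=radii)
    return sasa(a, **kwargs).total + sasa(b, **kwargs).total - sasa(ab, **kwargs).total
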