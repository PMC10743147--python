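"""Conformer ensembles, orientations, and gold-nanoparticle label placement.

This module prepares the atomic-coordinate side of a single-object
scattering simulation: it generates synthetic single-stranded-RNA-like
conformer ensembles (a stand-in for MD snapshots), loads PDB structures,
applies random rigid orientations, and attaches two gold nanoparticle
(AuNP) labels to phosphate oxygens (RNA) or backbone carbonyl oxygens
(proteins) under collision and distance constraints.

Coordinates are in Angstrom throughout, lab frame: the X-ray propagates
along +z and the detector plane spans x-y.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Atom",
    "Conformer",
    "Ensemble",
    "EulerAngles",
    "LabelPair",
    "LabeledStructure",
    "GeometryError",
    "NoFeasibleLabelingError",
    "PDBFormatError",
    "generate_synthetic_ensemble",
    "load_pdb",
    "rotate",
    "orientation_ensemble",
    "enumerate_label_sites",
    "place_aunp",
    "select_label_pairs",
    "labeled_structures",
    "save_labeled_ensemble",
    "load_labeled_ensemble",
]

SUPPORTED_ELEMENTS = {"H", "C", "N", "O", "P", "S", "AU"}

#: Aliases for the two free phosphate oxygens across PDB naming conventions.
RNA_LABEL_NAMES = {"O1P", "O2P", "OP1", "OP2"}


class GeometryError(ValueError):
    """Raised when a labeling site lacks the geometry needed for placement."""


class NoFeasibleLabelingError(RuntimeError):
    """Raised when no AuNP pair satisfies the labeling constraints."""


class PDBFormatError(ValueError):
    """Raised for unreadable or empty PDB input."""


@dataclass(frozen=True)
class Atom:
    """A single atom: element symbol, lab-frame position (A), residue and name."""

    element: str
    position: np.ndarray
    residue_index: int
    atom_name: str


@dataclass
class Conformer:
    """One structural snapshot.

    Atom attributes are stored as parallel arrays (positions ``(n, 3)`` in
    Angstrom) so that scattering sums and distance scans vectorize; the
    ``atoms`` property offers per-atom records when convenient.
    """

    elements: np.ndarray  # (n,) of str, e.g. "O", "AU"
    positions: np.ndarray  # (n, 3) float, Angstrom
    residue_index: np.ndarray  # (n,) int
    atom_names: np.ndarray  # (n,) of str
    snapshot_id: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n, 3)")
        if len(self.elements) == 0:
            raise ValueError("conformer must contain at least one atom")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("atom positions must be finite")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    @property
    def atoms(self) -> list[Atom]:
        return [
            Atom(str(e), p, int(r), str(a))
            for e, p, r, a in zip(
                self.elements, self.positions, self.residue_index, self.atom_names
            )
        ]

    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    def atom_index(self, residue_index: int, atom_name: str) -> int:
        hits = np.flatnonzero(
            (self.residue_index == residue_index) & (self.atom_names == atom_name)
        )
        if hits.size == 0:
            raise KeyError(f"no atom {atom_name!r} in residue {residue_index}")
        return int(hits[0])

    def with_positions(self, positions: np.ndarray, snapshot_id: int | None = None) -> "Conformer":
        return Conformer(
            elements=self.elements,
            positions=np.asarray(positions, dtype=float),
            residue_index=self.residue_index,
            atom_names=self.atom_names,
            snapshot_id=self.snapshot_id if snapshot_id is None else snapshot_id,
        )


@dataclass
class Ensemble:
    """A list of same-topology conformers (identical atom count and ordering)."""

    conformers: list[Conformer]
    source: str = "synthetic"  # "synthetic" | "pdb_multi_orientation"

    def __post_init__(self) -> None:
        if not self.conformers:
            raise ValueError("ensemble must contain at least one conformer")
        n0 = self.conformers[0].n_atoms
        for c in self.conformers:
            if c.n_atoms != n0:
                raise ValueError("all conformers must share the same atom count")

    def __len__(self) -> int:
        return len(self.conformers)

    def __iter__(self):
        return iter(self.conformers)

    def __getitem__(self, i: int) -> Conformer:
        return self.conformers[i]


@dataclass(frozen=True)
class EulerAngles:
    """Intrinsic z-y'-z'' Euler angles in radians."""

    alpha: float
    beta: float
    gamma: float


@dataclass
class LabelPair:
    """Two AuNP labeling sites plus the per-conformer particle centers.

    ``r_aunp`` is the center-to-center distance |c_b - c_a| per conformer;
    every entry must exceed ``2.4 * radius`` so the two particles stay well
    separated.
    """

    site_a: tuple[int, str]  # (residue_index, atom_name)
    site_b: tuple[int, str]
    radius: float  # AuNP radius R, Angstrom
    centers: np.ndarray  # (n_conformers, 2, 3), Angstrom
    r_aunp: np.ndarray  # (n_conformers,), Angstrom

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.r_aunp = np.asarray(self.r_aunp, dtype=float)
        d = np.linalg.norm(self.centers[:, 1] - self.centers[:, 0], axis=1)
        if not np.allclose(d, self.r_aunp, rtol=1e-9, atol=1e-9):
            raise ValueError("r_aunp must equal |c_b - c_a| for every conformer")


@dataclass
class LabeledStructure:
    """One conformer with its two AuNP centers and the ground-truth vector."""

    conformer: Conformer
    center_a: np.ndarray
    center_b: np.ndarray
    radius: float
    d_true: np.ndarray = field(init=False)
    substituted_indices: tuple[int, ...] = ()  # oxygens replaced by the labels

    def __post_init__(self) -> None:
        self.center_a = np.asarray(self.center_a, dtype=float)
        self.center_b = np.asarray(self.center_b, dtype=float)
        self.d_true = self.center_b - self.center_a

    @property
    def r_aunp(self) -> float:
        return float(np.linalg.norm(self.d_true))


# ---------------------------------------------------------------------------
# Synthetic ssRNA-like ensemble generation
# ---------------------------------------------------------------------------

def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _nucleotide_template() -> list[tuple[str, str, np.ndarray]]:
    """A 32-atom nucleotide-like cluster in a local residue frame.

    Local axes: +x points radially outward from the chain axis (so the
    free phosphate oxygens O1P/O2P face solvent and AuNPs placed on them
    clear the chain), +z runs along the chain.  Geometry is idealized —
    bond lengths are approximately correct, ring geometry is schematic —
    which is sufficient for a scattering-level stand-in for MD snapshots.
    22 heavy atoms (adenine-like purine nucleotide) plus 10 hydrogens.
    """
    t: list[tuple[str, str, np.ndarray]] = []
    # phosphate group; O1P/O2P 1.52 A from P.  The free oxygens are kept
    # close to radial (their bisector exactly so) so a label placed along
    # the P->O direction leans away from the chain, as on a
    # solvent-exposed phosphate; their mutual angle is compressed relative
    # to a real phosphate as part of that idealization.
    t.append(("P", "P", np.zeros(3)))
    t.append(("O1P", "O", 1.52 * _unit([1.0, 0.40, 0.0])))
    t.append(("O2P", "O", 1.52 * _unit([1.0, -0.40, 0.0])))
    # sugar-phosphate backbone, kept inward of the phosphate
    t.append(("O5'", "O", np.array([-0.76, -0.24, 0.80])))
    t.append(("C5'", "C", np.array([-1.40, 0.60, 1.48])))
    t.append(("C4'", "C", np.array([-2.30, 0.00, 2.28])))
    t.append(("O4'", "O", np.array([-3.30, -0.75, 1.84])))
    t.append(("C3'", "C", np.array([-2.95, 1.00, 3.04])))
    t.append(("O3'", "O", np.array([-2.25, 1.25, 3.96])))
    t.append(("C2'", "C", np.array([-4.25, 0.35, 3.32])))
    t.append(("O2'", "O", np.array([-5.35, 1.20, 3.48])))
    t.append(("C1'", "C", np.array([-4.40, -0.45, 2.32])))
    # purine-like base, pointing inward (-x), compact enough to stay
    # inside the chain cylinder
    base = [
        ("N9", "N", (-5.45, -0.75, 2.28)),
        ("C8", "C", (-5.51, -1.70, 3.04)),
        ("N7", "N", (-6.11, -2.50, 2.84)),
        ("C5", "C", (-6.47, -2.05, 1.92)),
        ("C6", "C", (-7.13, -2.45, 1.32)),
        ("N6", "N", (-7.67, -3.40, 1.56)),
        ("N1", "N", (-7.28, -1.75, 0.44)),
        ("C2", "C", (-6.80, -0.75, 0.20)),
        ("N3", "N", (-6.17, -0.30, 0.72)),
        ("C4", "C", (-5.99, -1.00, 1.60)),
    ]
    t.extend((n, e, np.array(p)) for n, e, p in base)
    # hydrogens, offset ~1 A from their parent atoms
    hydrogens = [
        ("H5'1", (-0.75, 1.25, 1.88)),
        ("H5'2", (-1.95, 1.20, 1.00)),
        ("H4'", (-1.75, -0.70, 2.76)),
        ("H3'", (-3.75, 1.65, 3.24)),
        ("H2'", (-4.65, -0.25, 3.96)),
        ("HO2'", (-6.05, 0.75, 3.88)),
        ("H1'", (-4.55, 0.20, 1.64)),
        ("H8", (-5.12, -1.85, 3.68)),
        ("H61", (-8.12, -3.65, 1.08)),
        ("H2", (-6.95, -0.20, -0.52)),
    ]
    t.extend((n, "H", np.array(p)) for n, p in hydrogens)
    assert len(t) == 32
    return t


def _terminal_template() -> list[tuple[str, str, np.ndarray]]:
    """A 15-atom 3'-terminal cap (schematic hydroxyl/phosphate tail)."""
    entries = [
        ("PT", "P", (0.0, 0.0, 0.0)),
        ("O1T", "O", (1.35, 0.55, 0.30)),
        ("O2T", "O", (1.10, -0.90, -0.45)),
        ("O5T", "O", (-0.80, 0.95, 0.95)),
        ("C5T", "C", (-1.45, 1.80, 1.80)),
        ("C4T", "C", (-2.35, 1.15, 2.80)),
        ("O4T", "O", (-3.35, 0.45, 2.25)),
        ("C3T", "C", (-3.00, 2.15, 3.75)),
        ("O3T", "O", (-2.30, 2.40, 4.90)),
        ("C2T", "C", (-4.30, 1.50, 4.10)),
        ("HT1", (-0.80, 2.45, 2.30)),
        ("HT2", (-2.00, 2.40, 1.20)),
        ("HT3", (-1.80, 0.45, 3.40)),
        ("HT4", (-3.80, 2.80, 4.00)),
        ("HT5", (-4.70, 0.90, 4.90)),
    ]
    out: list[tuple[str, str, np.ndarray]] = []
    for e in entries:
        if len(e) == 3 and isinstance(e[1], str):
            out.append((e[0], e[1], np.array(e[2], dtype=float)))
        else:
            out.append((e[0], "H", np.array(e[1], dtype=float)))
    assert len(out) == 15
    return out


def _helical_backbone(
    n_points: int,
    radius: float = 5.0,
    rise: float = 4.5,
    twist_deg: float = 72.0,
    super_radius: float = 23.0,
    climb: float = 0.115,
) -> tuple[np.ndarray, np.ndarray]:
    """Reference P positions of a compact solenoidal chain.

    A local helix (radius ``radius``, rise ``rise`` per residue, twist
    ``twist_deg``) is wound around a gently climbing circular axis of
    radius ``super_radius``, folding the chain into a compact globule a
    few tens of Angstrom across — the size regime of a folded RNA domain,
    where inter-site distances stay resolvable by the detector's fringe
    sampling.  Returns the P reference points and the local outward radial
    direction used to orient each residue frame.
    """
    h = rise * np.arange(n_points)  # arc position along the solenoid axis
    horiz = math.sqrt(1.0 - climb * climb)
    phi = h * horiz / super_radius
    axis = np.stack(
        [super_radius * np.cos(phi), super_radius * np.sin(phi), climb * h], axis=1
    )
    # axis frame: tangent T, outward-of-circle normal N, binormal B
    tangent = np.stack(
        [-horiz * np.sin(phi), horiz * np.cos(phi), np.full(n_points, climb)], axis=1
    )
    normal = np.stack([np.cos(phi), np.sin(phi), np.zeros(n_points)], axis=1)
    normal = normal - np.sum(normal * tangent, axis=1, keepdims=True) * tangent
    normal /= np.linalg.norm(normal, axis=1, keepdims=True)
    binormal = np.cross(tangent, normal)

    theta = np.deg2rad(twist_deg) * np.arange(n_points)
    radial = np.cos(theta)[:, None] * normal + np.sin(theta)[:, None] * binormal
    pts = axis + radius * radial
    return pts, radial


def _frames_along_curve(points: np.ndarray, outward_hint: np.ndarray) -> np.ndarray:
    """Orthonormal (normal, binormal, tangent) frame at each curve point."""
    n_pts = points.shape[0]
    tangents = np.gradient(points, axis=0)
    frames = np.empty((n_pts, 3, 3))
    for i in range(n_pts):
        t = _unit(tangents[i])
        n = outward_hint[i] - np.dot(outward_hint[i], t) * t
        if np.linalg.norm(n) < 1e-8:  # hint parallel to tangent; pick any normal
            n = np.array([1.0, 0.0, 0.0]) - t[0] * t
        n = _unit(n)
        b = np.cross(t, n)
        frames[i] = np.stack([n, b, t], axis=1)  # columns: local x, y, z
    return frames


def generate_synthetic_ensemble(
    n_residues: int = 70,
    n_snapshots: int = 100,
    fluctuation_amplitude: float = 2.0,
    seed: int = 0,
    n_bend_modes: int = 3,
) -> Ensemble:
    """Generate an ssRNA-like conformer ensemble with structural fluctuations.

    Each conformer is a helical chain of ``n_residues`` 32-atom
    nucleotide-like clusters (phosphate, ribose-like sugar, purine-like
    base, hydrogens) plus a 15-atom terminal cap, so 70 residues give
    2255 atoms.  Snapshot-to-snapshot variation combines ``n_bend_modes``
    low-frequency collective bending modes of the backbone (RMS amplitude
    ``fluctuation_amplitude``) with i.i.d. Gaussian atomic jitter of
    0.15x that amplitude, emulating the correlated inter-site distance
    fluctuations of an MD trajectory.  Each snapshot additionally receives
    an independent uniform random rigid orientation: in a single-object
    experiment every recorded molecule arrives in a fresh, isotropic
    orientation relative to the beam, so inter-label vectors must sample
    directions uniformly.  Deterministic for a given seed.
    """
    if n_residues < 2:
        raise ValueError(f"n_residues must be >= 2, got {n_residues}")
    if n_snapshots < 1:
        raise ValueError(f"n_snapshots must be >= 1, got {n_snapshots}")
    if fluctuation_amplitude < 0:
        raise ValueError("fluctuation_amplitude must be non-negative")

    rng = np.random.default_rng(seed)
    template = _nucleotide_template()
    terminal = _terminal_template()

    names, elements, res_idx = [], [], []
    for r in range(n_residues):
        for nm, el, _ in template:
            names.append(nm)
            elements.append(el)
            res_idx.append(r + 1)
    for nm, el, _ in terminal:
        names.append(nm)
        elements.append(el)
        res_idx.append(n_residues + 1)
    names = np.array(names)
    elements = np.array(elements)
    res_idx = np.array(res_idx, dtype=int)

    base_pts, outward = _helical_backbone(n_residues + 1)
    s = np.linspace(0.0, 1.0, n_residues + 1)  # arclength fraction for modes

    conformers: list[Conformer] = []
    for snap in range(n_snapshots):
        pts = base_pts.copy()
        if fluctuation_amplitude > 0:
            # low-frequency collective bending: random direction & phase per mode
            for m in range(1, n_bend_modes + 1):
                direction = _unit(rng.normal(size=3))
                phase = rng.uniform(0, 2 * np.pi)
                amp = fluctuation_amplitude * rng.normal() / math.sqrt(n_bend_modes)
                profile = np.sin(np.pi * m * s + phase) * math.sqrt(2.0)
                pts = pts + amp * profile[:, None] * direction[None, :]
        frames = _frames_along_curve(pts, outward)

        positions = np.empty((len(names), 3))
        i = 0
        for r in range(n_residues):
            F = frames[r]
            origin = pts[r]
            for _, _, local in template:
                positions[i] = origin + F @ local
                i += 1
        F = frames[n_residues]
        origin = pts[n_residues]
        for _, _, local in terminal:
            positions[i] = origin + F @ local
            i += 1

        if fluctuation_amplitude > 0:
            positions = positions + rng.normal(
                scale=0.15 * fluctuation_amplitude, size=positions.shape
            )
            # fresh isotropic orientation per snapshot (molecular tumbling /
            # a new molecule per pulse); skipped for the degenerate frozen
            # case, which contracts to bitwise-identical snapshots
            rot = Rotation.from_euler(
                "ZYZ",
                [
                    rng.uniform(0, 2 * np.pi),
                    math.acos(rng.uniform(-1.0, 1.0)),
                    rng.uniform(0, 2 * np.pi),
                ],
            )
            centroid = positions.mean(axis=0)
            positions = rot.apply(positions - centroid) + centroid
        conformers.append(
            Conformer(
                elements=elements,
                positions=positions,
                residue_index=res_idx,
                atom_names=names,
                snapshot_id=snap,
            )
        )
    return Ensemble(conformers=conformers, source="synthetic")


# ---------------------------------------------------------------------------
# PDB input
# ---------------------------------------------------------------------------

def load_pdb(path: str | Path) -> Conformer:
    """Load the first model of a PDB file as a Conformer.

    Elements come from the element column when present; otherwise gemmi's
    atom-name heuristic is used.  Raises :class:`PDBFormatError` for files
    without any ATOM/HETATM records.
    """
    import gemmi

    path = Path(path)
    try:
        structure = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise PDBFormatError(f"cannot read PDB file {path}: {exc}") from exc

    if len(structure) == 0:
        raise PDBFormatError(f"{path}: no models found (line 1)")
    model = structure[0]

    elements, positions, res_idx, names = [], [], [], []
    residue_counter = 0
    for chain in model:
        for residue in chain:
            residue_counter += 1
            for atom in residue:
                el = atom.element.name.upper() if atom.element else ""
                if not el or el == "X":
                    el = gemmi.Element(atom.name.strip()[:1]).name.upper()
                elements.append(el)
                positions.append([atom.pos.x, atom.pos.y, atom.pos.z])
                res_idx.append(residue_counter)
                names.append(atom.name.strip())
    if not positions:
        raise PDBFormatError(f"{path}: no ATOM/HETATM records (line 1)")

    return Conformer(
        elements=np.array(elements),
        positions=np.array(positions, dtype=float),
        residue_index=np.array(res_idx, dtype=int),
        atom_names=np.array(names),
        snapshot_id=0,
    )


# ---------------------------------------------------------------------------
# Rigid-body orientation
# ---------------------------------------------------------------------------

def rotate(conformer: Conformer, angles: EulerAngles) -> Conformer:
    """Rigidly rotate a conformer about its centroid (intrinsic z-y'-z'')."""
    rot = Rotation.from_euler("ZYZ", [angles.alpha, angles.beta, angles.gamma])
    c = conformer.centroid()
    new_pos = rot.apply(conformer.positions - c) + c
    return conformer.with_positions(new_pos)


def random_euler_angles(rng: np.random.Generator) -> EulerAngles:
    """Euler angles drawn so the resulting rotation is uniform on SO(3)."""
    alpha = rng.uniform(0.0, 2.0 * np.pi)
    gamma = rng.uniform(0.0, 2.0 * np.pi)
    beta = math.acos(rng.uniform(-1.0, 1.0))
    return EulerAngles(alpha, beta, gamma)


def orientation_ensemble(conformer: Conformer, n_orient: int, seed: int = 0) -> Ensemble:
    """Random rigid orientations of one structure (e.g. 30 per PDB entry)."""
    if n_orient < 1:
        raise ValueError(f"n_orient must be >= 1, got {n_orient}")
    rng = np.random.default_rng(seed)
    conformers = []
    for i in range(n_orient):
        c = rotate(conformer, random_euler_angles(rng))
        c.snapshot_id = i
        conformers.append(c)
    return Ensemble(conformers=conformers, source="pdb_multi_orientation")


# ---------------------------------------------------------------------------
# AuNP labeling
# ---------------------------------------------------------------------------

def enumerate_label_sites(
    conformer: Conformer, molecule_kind: str = "rna"
) -> list[tuple[int, str]]:
    """Candidate AuNP attachment sites.

    RNA: the two free phosphate oxygens (O1P/O2P, aliases OP1/OP2).
    Protein: backbone carbonyl oxygens (atom name "O").
    """
    if molecule_kind == "rna":
        mask = np.isin(conformer.atom_names, sorted(RNA_LABEL_NAMES))
    elif molecule_kind == "protein":
        mask = conformer.atom_names == "O"
    else:
        raise ValueError(f"molecule_kind must be 'rna' or 'protein', got {molecule_kind!r}")
    return [
        (int(r), str(n))
        for r, n in zip(conformer.residue_index[mask], conformer.atom_names[mask])
    ]


def _bonded_partner(conformer: Conformer, site_index: int, max_bond: float = 2.6) -> int:
    """Index of the heavy atom bonded to the labeled oxygen (same residue).

    The covalent partner of a labeled oxygen is never another oxygen
    (P for phosphate oxygens, the carbonyl C for peptide oxygens), so
    oxygens are excluded from the search — the sibling phosphate oxygen
    can otherwise be geometrically nearer than the phosphorus.
    """
    res = conformer.residue_index[site_index]
    pos = conformer.positions[site_index]
    cand = np.flatnonzero(
        (conformer.residue_index == res)
        & (conformer.elements != "H")
        & (conformer.elements != "O")
        & (np.arange(conformer.n_atoms) != site_index)
    )
    if cand.size == 0:
        raise GeometryError(f"no heavy-atom partner for site index {site_index}")
    dists = np.linalg.norm(conformer.positions[cand] - pos, axis=1)
    best = int(cand[np.argmin(dists)])
    if dists.min() > max_bond:
        raise GeometryError(
            f"nearest heavy atom to site index {site_index} is {dists.min():.2f} A away; "
            f"no bonded partner within {max_bond} A"
        )
    return best


#: Atoms within this distance (A) of the labeled oxygen belong to the
#: covalent attachment moiety and are exempt from the steric clash test.
#: Because the sphere surface passes through the oxygen, its directly
#: bonded neighbors necessarily sit just inside the R + margin shell; a
#: clash rule with no such exemption rejects every bonded site.
ATTACHMENT_RADIUS = 4.0


def place_aunp(
    conformer: Conformer,
    site: tuple[int, str],
    radius: float,
    clash_margin: float = 0.5,
    exclude_indices: tuple[int, ...] = (),
    attachment_radius: float = ATTACHMENT_RADIUS,
) -> np.ndarray | None:
    """Place an AuNP on a labeling site, or return None on steric rejection.

    The particle center sits at the labeled oxygen displaced outward by the
    radius ``R`` along the bonded-heavy-atom -> oxygen direction, so the
    sphere surface passes through the original oxygen position.  Rejected
    (None) if any heavy atom lies within ``R + clash_margin`` of the
    center, excluding the labeled oxygen itself, atoms of its covalent
    attachment moiety (within ``attachment_radius`` of the oxygen), and
    ``exclude_indices`` (e.g. the partner label's oxygen).  Hydrogens are
    skipped, as in standard steric screens: their van der Waals volume is
    subsumed in the margin.
    """
    idx = conformer.atom_index(*site)
    partner = _bonded_partner(conformer, idx)
    o_pos = conformer.positions[idx]
    direction = _unit(o_pos - conformer.positions[partner])
    center = o_pos + radius * direction

    mask = conformer.elements != "H"
    mask[list({idx, *exclude_indices})] = False
    mask &= np.linalg.norm(conformer.positions - o_pos, axis=1) > attachment_radius
    d = np.linalg.norm(conformer.positions[mask] - center, axis=1)
    if np.any(d < radius + clash_margin):
        return None
    return center


def _site_placements(
    ensemble: Ensemble,
    sites: list[tuple[int, str]],
    radius: float,
    clash_margin: float,
) -> tuple[np.ndarray, list[list[set[int]]]]:
    """Per-site AuNP centers and per-conformer clash-violator index sets.

    Returns ``centers`` shaped (n_sites, n_conformers, 3) and ``violators``
    [site][conformer] -> set of atom indices inside the clash shell
    (excluding the labeled oxygen itself).  Keeping the violator sets lets a
    pair be judged exactly: the partner label's substituted oxygen does not
    count as a clash.
    """
    c0 = ensemble[0]
    site_idx = [c0.atom_index(*s) for s in sites]
    # bonded partners are resolved on the ensemble-mean structure so that
    # per-snapshot thermal jitter cannot flip the inferred topology
    mean_conf = c0.with_positions(np.mean([c.positions for c in ensemble], axis=0))
    partners = [_bonded_partner(mean_conf, i) for i in site_idx]

    n_sites, n_conf = len(sites), len(ensemble)
    centers = np.empty((n_sites, n_conf, 3))
    violators: list[list[set[int]]] = [[set() for _ in range(n_conf)] for _ in range(n_sites)]

    heavy = ensemble[0].elements != "H"
    for ci, conf in enumerate(ensemble):
        pos = conf.positions
        for si, (idx, pi) in enumerate(zip(site_idx, partners)):
            o = pos[idx]
            center = o + radius * _unit(o - pos[pi])
            centers[si, ci] = center
            d = np.linalg.norm(pos - center, axis=1)
            d_site = np.linalg.norm(pos - o, axis=1)
            bad = np.flatnonzero(
                (d < radius + clash_margin) & (d_site > ATTACHMENT_RADIUS) & heavy
            )
            violators[si][ci] = {int(b) for b in bad if b != idx}
    return centers, violators


def select_label_pairs(
    ensemble: Ensemble,
    molecule_kind: str = "rna",
    radius: float = 9.0,
    n_pairs_min: int = 2,
    n_pairs_max: int = 6,
    min_spread: float = 10.0,
    seed: int = 0,
    clash_margin: float = 0.5,
) -> list[LabelPair]:
    """Randomly select AuNP labeling-site pairs under the separation and spread constraints.

    Every returned pair satisfies, in *every* conformer of the ensemble:
    both placements are sterically accepted and the center-to-center
    distance exceeds ``2.4 * radius``.  Across returned pairs the
    ensemble-mean distances differ pairwise by at least ``min_spread`` so
    the pairs probe a broad range of distances.  Deterministic per seed.
    """
    sites = enumerate_label_sites(ensemble[0], molecule_kind)
    if not sites:
        raise NoFeasibleLabelingError(
            f"no candidate {molecule_kind} labeling sites found"
        )
    # unique sites only (residue, name) and a stable order for determinism
    sites = sorted(set(sites))
    centers, violators = _site_placements(ensemble, sites, radius, clash_margin)

    c0 = ensemble[0]
    site_atom_idx = [c0.atom_index(*s) for s in sites]
    n_conf = len(ensemble)

    # a site is usable if its only possible violator is a partner oxygen
    def pair_feasible(a: int, b: int) -> bool:
        ia, ib = site_atom_idx[a], site_atom_idx[b]
        for ci in range(n_conf):
            if violators[a][ci] - {ib}:
                return False
            if violators[b][ci] - {ia}:
                return False
        return True

    # enumerate all feasible pairs first, then pack by mean-distance spread
    all_pairs = [(a, b) for a in range(len(sites)) for b in range(a + 1, len(sites))]
    n_rej_dist = n_rej_clash = 0
    feasible: list[tuple[int, int, np.ndarray, float]] = []
    for a, b in all_pairs:
        r = np.linalg.norm(centers[b] - centers[a], axis=1)
        if np.any(r <= 2.4 * radius):
            n_rej_dist += 1
            continue
        if not pair_feasible(a, b):
            n_rej_clash += 1
            continue
        feasible.append((a, b, r, float(r.mean())))

    if not feasible:
        raise NoFeasibleLabelingError(
            f"no feasible pairs (need >= {n_pairs_min}); rejections: "
            f"{n_rej_dist} by r_AuNP <= 2.4R = {2.4 * radius:.1f} A, "
            f"{n_rej_clash} by steric clash (margin {clash_margin} A)"
        )

    # randomized greedy packing, restarted; the largest spread-compatible
    # subset found wins (deterministic per seed).  Greedy over pairs sorted
    # by mean distance maximizes the subset size for this 1-D spread
    # constraint, so it serves as the fallback when random restarts pack
    # fewer pairs.
    rng = np.random.default_rng(seed)

    def pack(order) -> list[int]:
        chosen: list[int] = []
        means: list[float] = []
        for fi in order:
            m = feasible[fi][3]
            if all(abs(m - x) >= min_spread for x in means):
                chosen.append(int(fi))
                means.append(m)
                if len(chosen) >= n_pairs_max:
                    break
        return chosen

    sorted_best = pack(np.argsort([f[3] for f in feasible]))
    best: list[int] = []
    for _ in range(30):
        chosen = pack(rng.permutation(len(feasible)))
        if len(chosen) > len(best):
            best = chosen
        if len(best) >= min(n_pairs_max, len(sorted_best)):
            break
    if len(sorted_best) > len(best):
        best = sorted_best

    if len(best) < n_pairs_min:
        raise NoFeasibleLabelingError(
            f"only {len(best)} pairs satisfy the {min_spread} A mean-distance "
            f"spread (need >= {n_pairs_min}); {len(feasible)} feasible pairs "
            f"existed before the spread constraint; rejections: "
            f"{n_rej_dist} by r_AuNP <= 2.4R = {2.4 * radius:.1f} A, "
            f"{n_rej_clash} by steric clash (margin {clash_margin} A)"
        )
    return [
        LabelPair(
            site_a=sites[feasible[fi][0]],
            site_b=sites[feasible[fi][1]],
            radius=radius,
            centers=np.stack([centers[feasible[fi][0]], centers[feasible[fi][1]]], axis=1),
            r_aunp=feasible[fi][2],
        )
        for fi in best
    ]


def rebuild_label_pairs(
    ensemble: Ensemble,
    pairs: list[LabelPair],
    radius: float,
    clash_margin: float = 0.5,
) -> list[LabelPair]:
    """Re-place AuNPs of existing site pairs at a different radius.

    Used by radius sweeps to keep the labeling sites fixed across the grid
    (only the particle size changes); pairs that become infeasible at the
    new radius — separation <= 2.4R or a steric clash — are dropped.
    """
    sites = sorted({s for p in pairs for s in (p.site_a, p.site_b)})
    site_pos = {s: i for i, s in enumerate(sites)}
    centers, violators = _site_placements(ensemble, sites, radius, clash_margin)
    c0 = ensemble[0]
    site_atom_idx = [c0.atom_index(*s) for s in sites]

    out: list[LabelPair] = []
    for p in pairs:
        a, b = site_pos[p.site_a], site_pos[p.site_b]
        r = np.linalg.norm(centers[b] - centers[a], axis=1)
        if np.any(r <= 2.4 * radius):
            continue
        ia, ib = site_atom_idx[a], site_atom_idx[b]
        if any(violators[a][ci] - {ib} or violators[b][ci] - {ia}
               for ci in range(len(ensemble))):
            continue
        out.append(
            LabelPair(
                site_a=p.site_a,
                site_b=p.site_b,
                radius=radius,
                centers=np.stack([centers[a], centers[b]], axis=1),
                r_aunp=r,
            )
        )
    return out


def labeled_structures(ensemble: Ensemble, pair: LabelPair) -> list[LabeledStructure]:
    """Expand a label pair into per-conformer labeled structures."""
    out = []
    for ci, conf in enumerate(ensemble):
        ia = conf.atom_index(*pair.site_a)
        ib = conf.atom_index(*pair.site_b)
        out.append(
            LabeledStructure(
                conformer=conf,
                center_a=pair.centers[ci, 0],
                center_b=pair.centers[ci, 1],
                radius=pair.radius,
                substituted_indices=(ia, ib),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Ensemble + label archive (NPZ)
# ---------------------------------------------------------------------------

def save_labeled_ensemble(
    path: str | Path, ensemble: Ensemble, pairs: list[LabelPair], metadata: dict | None = None
) -> None:
    """Write ensemble coordinates and label geometry to a single NPZ archive."""
    import json

    c0 = ensemble[0]
    arrays = {
        "positions": np.stack([c.positions for c in ensemble]),
        "elements": c0.elements.astype("U4"),
        "atom_names": c0.atom_names.astype("U6"),
        "residue_index": c0.residue_index,
        "snapshot_ids": np.array([c.snapshot_id for c in ensemble]),
        "n_pairs": np.array(len(pairs)),
        "metadata_json": np.array(json.dumps(metadata or {})),
        "source": np.array(ensemble.source),
    }
    for i, p in enumerate(pairs):
        arrays[f"pair{i}_centers"] = p.centers
        arrays[f"pair{i}_r_aunp"] = p.r_aunp
        arrays[f"pair{i}_sites"] = np.array(
            [p.site_a[0], p.site_b[0]], dtype=int
        )
        arrays[f"pair{i}_site_names"] = np.array([p.site_a[1], p.site_b[1]], dtype="U6")
        arrays[f"pair{i}_radius"] = np.array(p.radius)
    np.savez_compressed(path, **arrays)


def load_labeled_ensemble(path: str | Path) -> tuple[Ensemble, list[LabelPair], dict]:
    """Read back an archive written by :func:`save_labeled_ensemble`."""
    import json

    try:
        data = np.load(path, allow_pickle=False)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read archive {path}: {exc}") from exc
    positions = data["positions"]
    elements = data["elements"]
    atom_names = data["atom_names"]
    residue_index = data["residue_index"]
    snapshot_ids = data["snapshot_ids"]
    conformers = [
        Conformer(
            elements=elements,
            positions=positions[i],
            residue_index=residue_index,
            atom_names=atom_names,
            snapshot_id=int(snapshot_ids[i]),
        )
        for i in range(positions.shape[0])
    ]
    ensemble = Ensemble(conformers=conformers, source=str(data["source"]))
    pairs = []
    for i in range(int(data["n_pairs"])):
        res = data[f"pair{i}_sites"]
        nm = data[f"pair{i}_site_names"]
        pairs.append(
            LabelPair(
                site_a=(int(res[0]), str(nm[0])),
                site_b=(int(res[1]), str(nm[1])),
                radius=float(data[f"pair{i}_radius"]),
                centers=data[f"pair{i}_centers"],
                r_aunp=data[f"pair{i}_r_aunp"],
            )
        )
    metadata = json.loads(str(data["metadata_json"]))
    return ensemble, pairs, metadata
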