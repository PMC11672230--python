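"""Conformation-level interfacial metrics from atomic coordinates.

Given an adsorbed-protein conformation (coordinates + masses) and a
surface plane, this module computes the quantities used to compare
simulation against reflectivity-derived profiles: mass density profiles
along the surface normal, the mass-center-to-surface distance, the
number of protein atoms in contact with the surface (within a distance
cutoff, 5 Å by default), RMSD between conformations with optional
rigid-body superposition, and a shape comparison between an atomistic
density profile and a slab-model volume-fraction profile.

The surface plane is, by convention, the z of the topmost
surface-tagged atom; distances are measured from it, positive into the
solvent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .layers import VolumeFractionProfile

logger = logging.getLogger(__name__)

#: Average atomic masses (amu) for the elements of a protein/silica system.
ATOM_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SI": 28.085, "NA": 22.990, "CL": 35.45, "K": 39.098,
    "MG": 24.305, "CA": 40.078, "FE": 55.845, "ZN": 65.38,
}


@dataclass
class AtomSet:
    """Coordinates (Å), masses (amu) and labels of one conformation."""

    coordinates: np.ndarray  # (N, 3)
    masses: np.ndarray  # (N,)
    labels: list[str] | None = None
    group: str = "protein"

    def __post_init__(self) -> None:
        self.coordinates = np.atleast_2d(np.asarray(self.coordinates, dtype=float))
        self.masses = np.asarray(self.masses, dtype=float)
        if self.coordinates.shape[0] != self.masses.shape[0]:
            raise ValueError("coordinates and masses must have equal length")
        if np.any(self.masses <= 0):
            raise ValueError("all masses must be positive")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.masses)

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())

    def translated(self, shift) -> "AtomSet":
        return AtomSet(
            coordinates=self.coordinates + np.asarray(shift, dtype=float),
            masses=self.masses.copy(),
            labels=self.labels,
            group=self.group,
        )


@dataclass
class DensityProfile:
    """Mass density along z: bin centers (Å from surface) and amu per Å of height."""

    z: np.ndarray
    density: np.ndarray  # amu / Å (per unit area if divided by box area)
    bin_width: float

    def __post_init__(self) -> None:
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")

    @property
    def total_mass(self) -> float:
        return float(self.density.sum() * self.bin_width)

    def normalized(self) -> "DensityProfile":
        """Unit-area version of the profile (shape comparison)."""
        area = self.density.sum() * self.bin_width
        if area <= 0:
            raise ValueError("empty profile cannot be normalized")
        return DensityProfile(self.z.copy(), self.density / area, self.bin_width)


def surface_plane(surface: AtomSet) -> float:
    """z of the topmost surface atom (the solid/liquid boundary)."""
    if len(surface) == 0:
        raise ValueError("empty surface atom set")
    return float(surface.coordinates[:, 2].max())


def density_profile(
    atoms: AtomSet,
    surface_z: float = 0.0,
    bin_width: float = 1.0,
    z_max: float | None = None,
) -> DensityProfile:
    """Mass histogram of the atoms along z - surface_z.

    Conserves total mass for any bin width.  Atoms below the surface are
    flagged with a warning but still binned.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    z = atoms.coordinates[:, 2] - surface_z
    n_below = int(np.sum(z < 0))
    if n_below:
        warnings.warn(
            f"{n_below} atoms lie below the surface plane; binned anyway",
            stacklevel=2,
        )
    lo = min(0.0, float(z.min()))
    hi = z_max if z_max is not None else float(z.max()) + bin_width
    nbins = max(1, int(np.ceil((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(nbins + 1)
    hist, _ = np.histogram(z, bins=edges, weights=atoms.masses)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(z=centers, density=hist / bin_width, bin_width=bin_width)


def average_density_profile(
    snapshots: list[AtomSet], surface_z: float = 0.0, bin_width: float = 1.0
) -> DensityProfile:
    """Snapshot-averaged density profile on one common grid."""
    if not snapshots:
        raise ValueError("no snapshots")
    all_z = np.concatenate(
        [a.coordinates[:, 2] - surface_z for a in snapshots]
    )
    lo = min(0.0, float(all_z.min()))
    hi = float(all_z.max()) + bin_width
    nbins = max(1, int(np.ceil((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(nbins + 1)
    dens = np.zeros(nbins)
    for a in snapshots:
        hist, _ = np.histogram(
            a.coordinates[:, 2] - surface_z, bins=edges, weights=a.masses
        )
        dens += hist / bin_width
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(z=centers, density=dens / len(snapshots), bin_width=bin_width)


def md_mass_center_distance(atoms: AtomSet, surface_z: float = 0.0) -> float:
    """Mass-weighted mean height of the atoms above the surface plane (Å)."""
    if len(atoms) == 0:
        raise ValueError("empty atom selection")
    z = atoms.coordinates[:, 2] - surface_z
    return float(np.average(z, weights=atoms.masses))


def contact_count(
    protein: AtomSet, surface: AtomSet, cutoff: float = 5.0
) -> int:
    """Number of distinct protein atoms within ``cutoff`` of any surface atom.

    The boundary is closed: an atom exactly at the cutoff distance
    counts.  Euclidean distances, no periodicity.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if len(protein) == 0 or len(surface) == 0:
        warnings.warn("empty protein or surface group; contact count is 0",
                      stacklevel=2)
        return 0
    tree = cKDTree(surface.coordinates)
    # a tiny epsilon keeps atoms at exactly the cutoff inside the closed ball
    d, _ = tree.query(protein.coordinates, k=1, distance_upper_bound=cutoff * (1 + 1e-12))
    return int(np.sum(d <= cutoff * (1 + 1e-12)))


def rmsd(
    coords_a: np.ndarray, coords_b: np.ndarray, superpose: bool = False
) -> float:
    """Root-mean-square deviation between two conformations (Å).

    With ``superpose=True`` the optimal rigid-body rotation+translation
    (Kabsch) is applied first, so the result is invariant under rigid
    motion of either set.
    """
    a = np.atleast_2d(np.asarray(coords_a, dtype=float))
    b = np.atleast_2d(np.asarray(coords_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError(f"atom count mismatch: {a.shape} vs {b.shape}")
    if superpose:
        a = a - a.mean(axis=0)
        b = b - b.mean(axis=0)
        rot, _ = Rotation.align_vectors(a, b)
        b = rot.apply(b)
    diff = a - b
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def profile_extent(z: np.ndarray, w: np.ndarray, fraction: float = 0.95) -> float:
    """z at which the cumulative (normalised) mass first reaches ``fraction``."""
    w = np.asarray(w, dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("empty profile")
    cum = np.cumsum(w) / total
    idx = int(np.searchsorted(cum, fraction))
    return float(z[min(idx, len(z) - 1)])


def compare_profiles(
    md: DensityProfile, nr: VolumeFractionProfile
) -> dict:
    """Shape comparison between an MD density profile and an NR phi(z) profile.

    Both are scaled to unit area on a common grid; reports the
    mass-center difference (Å), each profile's 95%-mass extent, and the
    overlap integral of the unit-area shapes (1 = identical support and
    shape, 0 = disjoint).
    """
    z_lo = max(float(md.z.min()), float(nr.z.min()))
    z_hi = min(float(md.z.max()), float(nr.z.max()))
    md_center = float(np.average(md.z, weights=md.density)) if md.density.sum() > 0 else np.nan
    nr_area = np.trapezoid(nr.phi, nr.z)
    nr_center = float(np.trapezoid(nr.z * nr.phi, nr.z) / nr_area)

    result = {
        "mass_center_md": md_center,
        "mass_center_nr": nr_center,
        "mass_center_difference": md_center - nr_center,
        "extent95_md": profile_extent(md.z, md.density),
        "extent95_nr": profile_extent(nr.z, nr.phi * np.gradient(nr.z)),
        "overlap": 0.0,
    }
    if z_hi <= z_lo:
        return result
    grid = np.linspace(z_lo, z_hi, 1001)
    f = np.interp(grid, md.z, md.density, left=0.0, right=0.0)
    g = np.interp(grid, nr.z, nr.phi, left=0.0, right=0.0)
    # normalise each to unit area over its own full support, then overlap
    f_area = np.trapezoid(np.interp(md.z, md.z, md.density), md.z)
    g_area = nr_area
    if f_area > 0 and g_area > 0:
        overlap = np.trapezoid(np.minimum(f / f_area, g / g_area), grid)
        result["overlap"] = float(overlap)
    return result


# ---------------------------------------------------------------------------
# Coordinate readers: PDB (via Biopython) and plain XYZ-with-mass tables.


def read_pdb(path, selection: str | None = None) -> AtomSet:
    """Read ATOM/HETATM coordinates from a PDB file.

    ``selection`` restricts to chain IDs, comma-separated (e.g. "A,B").
    Masses are assigned from the element column.
    """
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tolerate sloppy PDB headers
        structure = PDBParser(QUIET=True).get_structure("s", str(path))
    chains = None
    if selection:
        chains = {c.strip() for c in selection.split(",")}
    coords, masses, labels = [], [], []
    for model in structure:
        for chain in model:
            if chains is not None and chain.id not in chains:
                continue
            for residue in chain:
                for atom in residue:
                    elem = (atom.element or atom.get_name()[:1]).upper()
                    mass = ATOM_MASSES.get(elem)
                    if mass is None:
                        logger.warning("unknown element %r; using carbon mass", elem)
                        mass = ATOM_MASSES["C"]
                    coords.append(atom.coord)
                    masses.append(mass)
                    labels.append(f"{chain.id}:{residue.id[1]}:{atom.get_name()}")
        break  # first model only
    if not coords:
        raise ValueError(f"no atoms read from {path}")
    return AtomSet(np.array(coords, dtype=float), np.array(masses), labels)


def read_xyzm(path) -> AtomSet:
    """Read a plain whitespace table: label x y z mass (one atom per line)."""
    labels, rows = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 5:
                raise ValueError(f"xyzm line needs 'label x y z mass': {line!r}")
            labels.append(parts[0])
            rows.append([float(p) for p in parts[1:5]])
    if not rows:
        raise ValueError(f"no atoms in {path}")
    arr = np.array(rows)
    return AtomSet(coordinates=arr[:, :3], masses=arr[:, 3], labels=labels)


def write_xyzm(path, atoms: AtomSet) -> None:
    with open(path, "w") as fh:
        fh.write("# label x y z mass\n")
        labels = atoms.labels or [f"X{i}" for i in range(len(atoms))]
        for lab, (x, y, z), m in zip(labels, atoms.coordinates, atoms.masses):
            fh.write(f"{lab} {x:.4f} {y:.4f} {z:.4f} {m:.4f}\n")
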