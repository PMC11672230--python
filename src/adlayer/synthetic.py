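"""Synthetic study data: simulated multi-contrast reflectivity from known
slab stacks, and pseudo-protein atom clouds near a planar surface.

The generator emulates the measurement conditions of the adsorbed-mAb
study: a 2-slab protein layer on a Si/SiO2 substrate measured in three
water contrasts (D2O, CM4, H2O) over Q = 0.008-0.25 Å^-1 with a 2%
relative counting-noise floor and a 5e-7 flat background, and IgG-like
three-fragment (Fab/Fab/Fc) atom clouds in "flat-on" or "tilted"
orientations.  Every dataset carries its generating ground truth so
recovery can be checked exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .layers import (
    CM4,
    D2O,
    H2O,
    ContrastSolvent,
    LayerStack,
    ProteinSpecies,
    Slab,
    Substrate,
    get_protein,
)
from .mdprofiles import AtomSet
from .reflectivity import InstrumentModel, ReflectivityCurve, model_curve
from .fitting import ContrastDataset

#: Default simulated Q range and sampling (log-spaced), Å^-1.
DEFAULT_Q_RANGE = (0.008, 0.25)
DEFAULT_N_POINTS = 80

#: Printed 2-slab parameters of the adsorbed COE-3 layer at the two pHs:
#: (thickness Å, protein volume fraction) from the surface outward.
TABLE1_SLABS = {
    "5.5": [(42.5, 0.441), (20.0, 0.183)],
    "9": [(35.0, 0.405), (43.0, 0.187)],
}


@dataclass(frozen=True)
class NoiseModel:
    """Counting-statistics emulation: sigma = max(floor * R, background)."""

    relative_error_floor: float = 0.02
    background_level: float = 5e-7
    seed: int = 0


@dataclass
class GroundTruth:
    """Generating parameters stored beside each synthetic dataset."""

    slabs: list[tuple[float, float, float]]  # (tau, phi, sigma)
    substrate: dict
    protein: str
    contrasts: list[str]
    instrument: dict
    noise: dict
    q_range: tuple[float, float]
    n_points: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["slabs"] = [tuple(s) for s in d["slabs"]]
        d["q_range"] = tuple(d["q_range"])
        return cls(**d)

    def stack(self) -> LayerStack:
        return LayerStack(
            substrate=Substrate(**self.substrate),
            slabs=[Slab(t, p, s) for t, p, s in self.slabs],
            protein=get_protein(self.protein),
        )


def make_table1_stack(
    ph_label: str,
    protein: ProteinSpecies | None = None,
    substrate: Substrate | None = None,
) -> LayerStack:
    """The published 2-slab COE-3 stack at pH 5.5 or pH 9."""
    key = str(ph_label)
    if key not in TABLE1_SLABS:
        raise ValueError(f"unknown pH label {ph_label!r}; use one of {sorted(TABLE1_SLABS)}")
    return LayerStack(
        substrate=substrate or Substrate(),
        slabs=[Slab(thickness=t, phi_protein=p) for t, p in TABLE1_SLABS[key]],
        protein=protein or get_protein("COE3"),
    )


def default_contrasts() -> list[ContrastSolvent]:
    return [D2O, CM4, H2O]


def simulate_contrast_set(
    stack: LayerStack,
    contrasts: list[ContrastSolvent] | None = None,
    q_range: tuple[float, float] = DEFAULT_Q_RANGE,
    n_points: int = DEFAULT_N_POINTS,
    noise: NoiseModel | None = None,
    instrument: InstrumentModel | None = None,
) -> tuple[list[ContrastDataset], GroundTruth]:
    """Forward-model the stack in each contrast and add counting noise.

    Each curve is the smeared, scaled, background-added model with
    Gaussian noise of sigma = max(floor * R, background); the sigma is
    stored as the curve's uncertainty.  Identical seeds give identical
    datasets.
    """
    if n_points < 20:
        raise ValueError("need at least 20 Q points")
    contrasts = contrasts or default_contrasts()
    noise = noise or NoiseModel()
    instrument = instrument or InstrumentModel()
    rng = np.random.default_rng(noise.seed)
    q = np.logspace(np.log10(q_range[0]), np.log10(q_range[1]), n_points)

    datasets = []
    for contrast in contrasts:
        clean = model_curve(stack, contrast, q, instrument)
        sigma = np.maximum(noise.relative_error_floor * clean.r, noise.background_level)
        # noise is left uncensored: weak points may fluctuate below zero,
        # as background-subtracted reflectivity does
        r_noisy = clean.r + rng.normal(0.0, 1.0, size=q.shape) * sigma
        curve = ReflectivityCurve(q=q.copy(), r=r_noisy, dr=sigma)
        datasets.append(
            ContrastDataset(solvent=contrast, curve=curve, instrument=instrument)
        )

    truth = GroundTruth(
        slabs=[(s.thickness, s.phi_protein, s.roughness) for s in stack.slabs],
        substrate=dataclasses.asdict(stack.substrate),
        protein=stack.protein.name,
        contrasts=[c.name for c in contrasts],
        instrument=dataclasses.asdict(instrument),
        noise=dataclasses.asdict(noise),
        q_range=q_range,
        n_points=n_points,
    )
    return datasets, truth


# ---------------------------------------------------------------------------
# Pseudo-protein atom clouds


#: Fragment masses (amu): two Fabs and one Fc summing to the mAb mass.
_FAB_MASS = 47.3e3
_FC_MASS = 144.8e3 - 2 * 47.3e3

#: Ellipsoid semi-axes (Å).  The Fab minor axis is ~45 Å full length;
#: the Fc major axis is ~70 Å full length.
_FAB_AXES = (40.0, 25.0, 22.5)
_FC_AXES = (35.0, 25.0, 22.5)


def _ellipsoid_cloud(
    rng: np.random.Generator, n: int, semi_axes: tuple[float, float, float]
) -> np.ndarray:
    """Uniform point cloud inside an ellipsoid centred at the origin."""
    pts = rng.normal(size=(n, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    radii = rng.uniform(0.0, 1.0, size=(n, 1)) ** (1.0 / 3.0)
    return pts * radii * np.array(semi_axes)


def make_pseudo_protein(
    layout: str = "flat_on",
    center_z: float | None = 27.5,
    seed: int = 0,
    n_per_fragment: int = 400,
) -> AtomSet:
    """IgG-like three-fragment point cloud adsorbed on the z = 0 surface.

    ``flat_on`` rests the two Fabs on the surface with their short (45 Å)
    axes vertical and the Fc beside them, slightly elevated -- the
    compact adsorbed geometry; ``tilted`` keeps the Fabs anchored but
    stands the Fc up with its long (70 Å) axis along z, extending the
    cloud's vertical reach by tens of Å.  If ``center_z`` is given the
    cloud is translated so its mass center sits exactly there; ``None``
    keeps the as-built geometry (natural center ~28 Å flat-on, ~40 Å
    tilted).
    """
    if center_z is not None and center_z <= 0:
        raise ValueError("center_z must be positive")
    if layout not in ("flat_on", "tilted"):
        raise ValueError(f"unknown layout {layout!r}")
    rng = np.random.default_rng(seed)

    frags = []
    if layout == "flat_on":
        # Fabs resting on the surface, short axis vertical; Fc beside
        # them with its lower half in the dense inner region
        frags.append((_ellipsoid_cloud(rng, n_per_fragment, _FAB_AXES)
                      + [-55.0, 0.0, 24.0], _FAB_MASS))
        frags.append((_ellipsoid_cloud(rng, n_per_fragment, _FC_AXES)
                      + [0.0, 0.0, 36.0], _FC_MASS))
        frags.append((_ellipsoid_cloud(rng, n_per_fragment, _FAB_AXES)
                      + [55.0, 0.0, 24.0], _FAB_MASS))
    else:  # tilted: Fabs at the surface, Fc stood up along z
        frags.append((_ellipsoid_cloud(rng, n_per_fragment, _FAB_AXES)
                      + [-30.0, 0.0, 24.0], _FAB_MASS))
        frags.append((_ellipsoid_cloud(rng, n_per_fragment, _FAB_AXES)
                      + [30.0, 0.0, 24.0], _FAB_MASS))
        # Fc major axis (70 Å) along z, raised above the Fabs
        frags.append((_ellipsoid_cloud(rng, n_per_fragment, (22.5, 25.0, 35.0))
                      + [0.0, 0.0, 70.0], _FC_MASS))

    coords = np.vstack([c for c, _ in frags])
    masses = np.concatenate(
        [np.full(len(c), m / len(c)) for c, m in frags]
    )
    atoms = AtomSet(coordinates=coords, masses=masses, group="protein")
    if center_z is None:
        return atoms
    shift = center_z - float(np.average(atoms.coordinates[:, 2], weights=atoms.masses))
    return atoms.translated([0.0, 0.0, shift])


def make_surface_slab(
    size: float = 200.0,
    spacing: float = 4.0,
    n_layers: int = 2,
    top_z: float = 0.0,
) -> AtomSet:
    """Regular silica-like lattice of surface atoms with its top plane at ``top_z``."""
    xs = np.arange(-size / 2, size / 2 + spacing / 2, spacing)
    zs = top_z - spacing * np.arange(n_layers)
    xx, yy, zz = np.meshgrid(xs, xs, zs, indexing="ij")
    coords = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    # SiO2 unit mass per site
    masses = np.full(len(coords), 60.08)
    return AtomSet(coordinates=coords, masses=masses, group="surface")


def write_contrast_set(
    outdir, datasets: list[ContrastDataset], truth: GroundTruth
) -> list[str]:
    """Write each contrast as ASCII plus the ground-truth JSON sidecar."""
    from pathlib import Path

    from .reflectivity import write_curve

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for ds in datasets:
        p = outdir / f"reflectivity_{ds.solvent.name}.dat"
        write_curve(
            p,
            ds.curve,
            header={
                "contrast": ds.solvent.name,
                "solvent_sld_A^-2": f"{ds.solvent.sld:.3e}",
                "scale": ds.instrument.scale,
                "background": ds.instrument.background,
                "dq_over_q": ds.instrument.dq_over_q,
            },
        )
        paths.append(str(p))
    truth.to_json(outdir / "ground_truth.json")
    return paths
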