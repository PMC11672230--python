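"""Slab-model data structures and composition arithmetic for adsorbed protein layers.

An adsorbed antibody layer at the SiO2/water interface is modelled as a
stack of homogeneous slabs on top of a Si/SiO2 substrate.  Each slab is
described by a thickness ``tau`` (Å), a protein volume fraction ``phi``
and a Gaussian interfacial roughness ``sigma`` (Å).  The slab scattering
length density (SLD) is the volume-fraction-weighted mixture of protein
and solvent SLDs; protein and solvent together fill the slab, so
``phi_water = 1 - phi_protein``.

From the slab parameters this module derives the quantities reported for
such layers: per-slab and total adsorbed amount

    Gamma_i = tau_i * phi_i * MW / (V * N_A)      [mg m^-2]

(with MW the protein molecular weight in g/mol and V its molecular
volume in Å^3), the protein volume-fraction profile phi(z), and the
mass-center-to-surface distance as the first moment of phi(z).  The z
axis has its origin at the oxide/solvent boundary and increases into the
solvent.

Because labile hydrogens exchange with the solvent, the protein SLD
depends on the isotopic contrast of the solvent; it is interpolated
linearly between its H2O and D2O values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import yaml
from scipy.special import erf

#: Avogadro's constant, mol^-1 (exact SI value).
N_A = 6.02214076e23

#: SLD of pure H2O / pure D2O at room temperature, Å^-2.  Water mixtures
#: used for contrast variation lie between these bounds.
SLD_H2O = -0.56e-6
SLD_D2O = 6.35e-6


class NoContrastError(ValueError):
    """Protein and solvent SLD coincide; volume fraction is unconstrained."""


@dataclass(frozen=True)
class ContrastSolvent:
    """An isotopic water contrast, e.g. D2O, CM4 or H2O."""

    name: str
    sld: float  # Å^-2

    def __post_init__(self) -> None:
        if not (SLD_H2O - 1e-12 <= self.sld <= SLD_D2O + 1e-12):
            raise ValueError(
                f"solvent SLD {self.sld:.3g} outside the physical range "
                f"[{SLD_H2O:.3g}, {SLD_D2O:.3g}] for H2O/D2O mixtures"
            )


#: The three contrasts used throughout: D2O, contrast-matched SLD=4 water, H2O.
D2O = ContrastSolvent("D2O", SLD_D2O)
CM4 = ContrastSolvent("CM4", 4.0e-6)
H2O = ContrastSolvent("H2O", SLD_H2O)


@dataclass(frozen=True)
class ProteinSpecies:
    """Protein constants: molecular weight, volume and contrast-dependent SLD.

    ``sld_by_contrast`` maps solvent SLD (Å^-2) to protein SLD (Å^-2) and
    must contain entries at the H2O and D2O solvent SLDs; these anchor
    the linear H/D-exchange interpolation.
    """

    name: str
    mw: float  # g/mol
    volume: float  # Å^3
    sld_by_contrast: dict[float, float]

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError("molecular weight must be positive")
        if self.volume <= 0:
            raise ValueError("molecular volume must be positive")
        for anchor in (SLD_H2O, SLD_D2O):
            if not any(math.isclose(k, anchor, rel_tol=1e-6, abs_tol=1e-12)
                       for k in self.sld_by_contrast):
                raise ValueError(
                    f"sld_by_contrast must contain an entry at solvent SLD "
                    f"{anchor:.3g} (H2O/D2O anchors)"
                )

    def _anchor(self, solvent_sld: float) -> float:
        for k, v in self.sld_by_contrast.items():
            if math.isclose(k, solvent_sld, rel_tol=1e-6, abs_tol=1e-12):
                return v
        raise KeyError(solvent_sld)

    @property
    def sld_h2o(self) -> float:
        return self._anchor(SLD_H2O)

    @property
    def sld_d2o(self) -> float:
        return self._anchor(SLD_D2O)

    @property
    def mass_density(self) -> float:
        """Dry protein mass density MW/(V*N_A) in g/cm^3."""
        return self.mw / (self.volume * 1e-24 * N_A)


@dataclass
class Slab:
    """One homogeneous sublayer: thickness (Å), protein volume fraction, roughness (Å)."""

    thickness: float
    phi_protein: float
    roughness: float = 0.0

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError("slab thickness must be positive")
        if not 0.0 <= self.phi_protein <= 1.0:
            raise ValueError("protein volume fraction must lie in [0, 1]")
        if self.roughness < 0:
            raise ValueError("roughness must be non-negative")

    @property
    def phi_water(self) -> float:
        return 1.0 - self.phi_protein


@dataclass
class Substrate:
    """Si fronting plus native oxide layer.

    Default SLDs are the literature-standard values for silicon and
    amorphous SiO2; the oxide on polished wafers is ultrathin (~15 Å).
    ``oxide_hydration`` is the volume fraction of solvent mixed into the
    oxide (0 = dense oxide).
    """

    fronting_sld: float = 2.07e-6
    oxide_thickness: float = 15.0
    oxide_sld: float = 3.41e-6
    oxide_roughness: float = 3.0
    oxide_hydration: float = 0.0

    def __post_init__(self) -> None:
        if self.oxide_thickness < 0:
            raise ValueError("oxide thickness must be non-negative")
        if not 0.0 <= self.oxide_hydration <= 1.0:
            raise ValueError("oxide hydration must lie in [0, 1]")


@dataclass
class LayerStack:
    """Substrate + ordered protein slabs (surface -> solvent) + protein constants."""

    substrate: Substrate
    slabs: list[Slab]
    protein: ProteinSpecies

    @property
    def total_thickness(self) -> float:
        return sum(s.thickness for s in self.slabs)


@dataclass
class LayerSummary:
    """Per-slab and aggregate structural quantities of an adsorbed layer.

    Mirrors the standard report layout: per-slab thickness, volume
    fraction and adsorbed amount, plus the totals, the thickness-weighted
    mean volume fraction, per-slab mass fractions and the mass-center
    distance from the surface.
    """

    thicknesses: list[float]  # Å
    volume_fractions: list[float]  # dimensionless
    gammas: list[float]  # mg/m^2
    total_thickness: float
    total_gamma: float
    mean_volume_fraction: float  # thickness-weighted
    mass_fractions: list[float]
    mass_center: float  # Å

    def to_frame(self):
        """Table-layout DataFrame (one column per slab plus Total/Average)."""
        import pandas as pd

        cols = [f"Slab {i + 1}" for i in range(len(self.thicknesses))]
        data = {
            c: [t, 100.0 * phi, g]
            for c, t, phi, g in zip(
                cols, self.thicknesses, self.volume_fractions, self.gammas
            )
        }
        data["Total/Average"] = [
            self.total_thickness,
            100.0 * self.mean_volume_fraction,
            self.total_gamma,
        ]
        return pd.DataFrame(
            data,
            index=[
                "Thickness (A)",
                "Volume Fraction (%)",
                "Adsorbed Amount (mg m^-2)",
            ],
        )


@dataclass
class VolumeFractionProfile:
    """phi(z) on a z grid with z = 0 at the oxide/solvent boundary."""

    z: np.ndarray  # Å
    phi: np.ndarray

    def integral(self) -> float:
        """Integral of phi dz (Å); the protein-equivalent thickness."""
        return float(np.trapezoid(self.phi, self.z))


# ---------------------------------------------------------------------------
# SLD mixing (two-component slab composition)


def mix_sld(phi_protein: float, sld_protein: float, sld_water: float) -> float:
    """Slab SLD from protein volume fraction and the two component SLDs.

    The slab is filled by protein and water only, so
    ``rho = phi * rho_protein + (1 - phi) * rho_water``.
    """
    if not 0.0 <= phi_protein <= 1.0:
        raise ValueError(f"volume fraction {phi_protein} outside [0, 1]")
    return phi_protein * sld_protein + (1.0 - phi_protein) * sld_water


def invert_sld(
    sld_slab: float,
    sld_protein: float,
    sld_water: float,
    out_of_range: str = "error",
) -> float:
    """Protein volume fraction from a fitted slab SLD (inverse of :func:`mix_sld`).

    Parameters
    ----------
    out_of_range:
        ``"error"`` (default) rejects slab SLDs outside the interval
        spanned by the protein and water SLDs; ``"clamp"`` clamps the
        result to [0, 1] with a warning (useful for noisy fits).
    """
    if sld_protein == sld_water:
        raise NoContrastError(
            "protein and solvent SLD are equal; volume fraction is undetermined"
        )
    phi = (sld_slab - sld_water) / (sld_protein - sld_water)
    if not 0.0 <= phi <= 1.0:
        if out_of_range == "clamp":
            warnings.warn(
                f"inverted volume fraction {phi:.4f} outside [0, 1]; clamped",
                stacklevel=2,
            )
            return float(np.clip(phi, 0.0, 1.0))
        raise ValueError(
            f"slab SLD {sld_slab:.4g} lies outside the [protein, water] "
            f"interval; inverted volume fraction {phi:.4f} is unphysical"
        )
    return phi


def protein_sld_for_solvent(protein: ProteinSpecies, solvent_sld: float) -> float:
    """Protein SLD in a given water contrast, from labile-H/D exchange.

    Linear interpolation between the H2O and D2O anchor values; the CM4
    entries of the shipped constants are consistent with linearity.
    """
    if not (SLD_H2O - 1e-12 <= solvent_sld <= SLD_D2O + 1e-12):
        raise ValueError(
            f"solvent SLD {solvent_sld:.3g} outside [{SLD_H2O:.3g}, {SLD_D2O:.3g}]"
        )
    frac = (solvent_sld - SLD_H2O) / (SLD_D2O - SLD_H2O)
    return protein.sld_h2o + frac * (protein.sld_d2o - protein.sld_h2o)


# ---------------------------------------------------------------------------
# Adsorbed amount, profiles, summaries


def adsorbed_amount(
    slabs: Sequence[Slab], protein: ProteinSpecies
) -> tuple[list[float], float]:
    """Per-slab and total adsorbed amount Gamma in mg/m^2.

    Gamma_i = tau_i * phi_i * MW / (V * N_A) with tau in Å, MW in g/mol
    and V in Å^3; the factor 1e23 converts g/Å^2 to mg/m^2.
    """
    per_slab = [
        s.thickness * s.phi_protein * protein.mw / (protein.volume * N_A) * 1e23
        for s in slabs
    ]
    return per_slab, sum(per_slab)


def volume_fraction_profile(
    stack: LayerStack,
    z_grid: np.ndarray | None = None,
    broadened: bool = False,
    margin: float = 25.0,
    dz: float = 0.1,
) -> VolumeFractionProfile:
    """Protein volume-fraction profile phi(z) of the stack.

    The unbroadened profile is the step function of the slab phi values.
    With ``broadened=True`` adjacent steps are joined by error-function
    transitions whose widths are the slab roughnesses; the integral is
    preserved (transitions are antisymmetric about each boundary).
    """
    if z_grid is None:
        z_grid = np.arange(0.0, stack.total_thickness + margin + dz, dz)
    z_grid = np.asarray(z_grid, dtype=float)

    boundaries = np.concatenate([[0.0], np.cumsum([s.thickness for s in stack.slabs])])
    phis = np.array([s.phi_protein for s in stack.slabs])

    if not broadened:
        phi = np.zeros_like(z_grid)
        for lo, hi, p in zip(boundaries[:-1], boundaries[1:], phis):
            phi[(z_grid >= lo) & (z_grid < hi)] = p
    else:
        # phi(z) = sum over boundaries of (step change) * smooth step.
        # Boundary j has the roughness of the slab below it (slab j-1);
        # the 0-boundary uses the substrate oxide roughness.
        sigmas = np.concatenate(
            [[stack.substrate.oxide_roughness], [s.roughness for s in stack.slabs]]
        )
        levels = np.concatenate([[0.0], phis, [0.0]])  # oxide side, slabs, solvent
        phi = np.full_like(z_grid, levels[0])
        for j, zb in enumerate(boundaries):
            step = levels[j + 1] - levels[j]
            sig = sigmas[j]
            if sig > 0:
                phi = phi + step * 0.5 * (1.0 + erf((z_grid - zb) / (sig * math.sqrt(2))))
            else:
                phi = phi + step * (z_grid >= zb)
    return VolumeFractionProfile(z=z_grid, phi=phi)


def mass_center_distance(profile: VolumeFractionProfile) -> float:
    """First moment of phi(z): the layer mass center's distance from the surface (Å)."""
    area = profile.integral()
    if area <= 0:
        raise ValueError("profile carries no protein; mass center undefined")
    return float(np.trapezoid(profile.z * profile.phi, profile.z) / area)


def _step_mass_center(slabs: Sequence[Slab]) -> float:
    """Analytic first moment of the step profile (no grid discretisation)."""
    area = 0.0
    moment = 0.0
    z0 = 0.0
    for s in slabs:
        a = s.thickness * s.phi_protein
        area += a
        moment += a * (z0 + s.thickness / 2.0)
        z0 += s.thickness
    if area <= 0:
        raise ValueError("stack carries no protein; mass center undefined")
    return moment / area


def summarize(stack: LayerStack) -> LayerSummary:
    """Per-slab and aggregate report for a layer stack.

    Totals are sums over slabs; the mean volume fraction is weighted by
    slab thickness; mass fractions are each slab's share of the total
    adsorbed amount; the mass center is the analytic first moment of the
    step profile.
    """
    gammas, total_gamma = adsorbed_amount(stack.slabs, stack.protein)
    taus = [s.thickness for s in stack.slabs]
    phis = [s.phi_protein for s in stack.slabs]
    total_tau = sum(taus)
    mean_phi = sum(t * p for t, p in zip(taus, phis)) / total_tau
    mass_fractions = [g / total_gamma for g in gammas] if total_gamma > 0 else [0.0] * len(gammas)
    return LayerSummary(
        thicknesses=taus,
        volume_fractions=phis,
        gammas=gammas,
        total_thickness=total_tau,
        total_gamma=total_gamma,
        mean_volume_fraction=mean_phi,
        mass_fractions=mass_fractions,
        mass_center=_step_mass_center(stack.slabs),
    )


# ---------------------------------------------------------------------------
# Protein constants shipped with the package


def load_protein_table() -> dict[str, ProteinSpecies]:
    """Load the shipped protein constants (full IgG1 mAb, Fab, Fc fragments)."""
    text = resources.files("adlayer").joinpath("data/proteins.yaml").read_text()
    raw = yaml.safe_load(text)
    table = {}
    for name, entry in raw.items():
        table[name] = ProteinSpecies(
            name=name,
            mw=float(entry["mw"]),
            volume=float(entry["volume"]),
            sld_by_contrast={
                float(k): float(v) for k, v in entry["sld_by_contrast"].items()
            },
        )
    return table


def get_protein(name: str) -> ProteinSpecies:
    table = load_protein_table()
    try:
        return table[name]
    except KeyError:
        raise KeyError(
            f"unknown protein {name!r}; shipped entries: {sorted(table)}"
        ) from None
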