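"""Surface density of adsorbed protein films from ellipsometric layer
parameters, via De Feijter's relation.

A fitted optical layer (thickness tau, refractive index n_f at 630 nm,
Cauchy dispersion n(lambda) = A + B/lambda^2 with lambda in micrometres)
is converted to an adsorbed amount

    Gamma = tau * (n_f - n_0) / (dn/dc)

where n_0 is the ambient buffer index and dn/dc the refractive-index
increment of protein in solution (0.18 mL/g is the standard value at
630 nm).  Kinetic adsorption series Gamma(t) are reduced to a plateau
value and a time-to-plateau.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Standard protein refractive-index increment at 630 nm, mL/g.
DEFAULT_DNDC = 0.18

#: Ambient aqueous-buffer refractive index at 630 nm.
DEFAULT_N_AMBIENT = 1.335


@dataclass(frozen=True)
class CauchyModel:
    """Cauchy dispersion n(lambda) = A + B/lambda^2 (lambda in micrometres)."""

    a: float = 1.45
    b: float = 0.003  # um^2

    def __post_init__(self) -> None:
        if self.a < 1.0:
            raise ValueError("Cauchy A must be >= 1 (vacuum index)")


@dataclass
class KineticPoint:
    """One time point of a kinetic adsorption run."""

    time: float  # s
    thickness: float  # Å
    n_film: float
    gamma: float  # mg/m^2

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("adsorbed amount must be non-negative")


def cauchy_index(model: CauchyModel, wavelength: float) -> float:
    """Refractive index at a wavelength given in nanometres."""
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    lam_um = wavelength * 1e-3
    return model.a + model.b / lam_um**2


def defeijter_gamma(
    tau: float,
    n_film: float,
    n_ambient: float = DEFAULT_N_AMBIENT,
    dndc: float = DEFAULT_DNDC,
) -> float:
    """Adsorbed amount Gamma in mg/m^2 from layer thickness and index.

    tau is in Å, dndc in mL/g.  Dimensionally: tau[cm] * dn / (dn/dc)[cm^3/g]
    gives g/cm^2; 1 g/cm^2 = 1e7 mg/m^2.
    """
    if dndc <= 0:
        raise ValueError("dn/dc must be positive")
    if n_film < n_ambient:
        raise ValueError(
            f"film index {n_film} below ambient {n_ambient}: unphysical film"
        )
    tau_cm = tau * 1e-8
    gamma_g_cm2 = tau_cm * (n_film - n_ambient) / dndc
    return gamma_g_cm2 * 1e7


def kinetic_series(
    times: np.ndarray,
    thicknesses: np.ndarray,
    n_films: np.ndarray,
    n_ambient: float = DEFAULT_N_AMBIENT,
    dndc: float = DEFAULT_DNDC,
) -> list[KineticPoint]:
    """Convert arrays of (t, tau, n_f) into Gamma(t) kinetic points."""
    return [
        KineticPoint(
            time=float(t),
            thickness=float(tau),
            n_film=float(nf),
            gamma=defeijter_gamma(tau, nf, n_ambient, dndc),
        )
        for t, tau, nf in zip(times, thicknesses, n_films)
    ]


def saturation_stats(
    series: list[KineticPoint],
    window: float | None = None,
    plateau_tolerance: float = 0.05,
) -> dict:
    """Plateau adsorbed amount and time-to-plateau of a kinetic series.

    The plateau is the mean Gamma over the final averaging window
    (default: the last 20% of the time span); its spread is the sample
    standard deviation over the same window.  The time to plateau is the
    first time after which Gamma stays within ``plateau_tolerance``
    (relative) of the plateau value.
    """
    if len(series) < 3:
        raise ValueError("need at least 3 kinetic points")
    t = np.array([p.time for p in series])
    g = np.array([p.gamma for p in series])
    span = t[-1] - t[0]
    if window is None:
        window = 0.2 * span
    if window <= 0:
        raise ValueError("averaging window must be positive")
    in_window = t >= t[-1] - window
    if not np.any(in_window):
        raise ValueError("averaging window contains no points")
    plateau = float(np.mean(g[in_window]))
    sd = float(np.std(g[in_window], ddof=1)) if np.sum(in_window) > 1 else 0.0

    within = np.abs(g - plateau) <= plateau_tolerance * abs(plateau) if plateau != 0 else g == 0
    # first index from which every later point stays within tolerance
    stays = np.flip(np.logical_and.accumulate(np.flip(within)))
    idx = int(np.argmax(stays)) if stays.any() else len(t) - 1
    return {
        "plateau_gamma": plateau,
        "plateau_sd": sd,
        "time_to_plateau": float(t[idx] - t[0]),
        "n_window_points": int(np.sum(in_window)),
    }


def read_kinetic_csv(path, n_ambient: float = DEFAULT_N_AMBIENT,
                     dndc: float = DEFAULT_DNDC) -> list[KineticPoint]:
    """Read a kinetic series CSV with columns time, thickness, n_film."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"time", "thickness", "n_film"}
    if not required.issubset(df.columns):
        raise ValueError(f"kinetic CSV needs columns {sorted(required)}")
    return kinetic_series(
        df["time"].to_numpy(),
        df["thickness"].to_numpy(),
        df["n_film"].to_numpy(),
        n_ambient,
        dndc,
    )


def write_gamma_csv(path, series: list[KineticPoint]) -> None:
    """Write Gamma(t) as CSV for plotting."""
    import pandas as pd

    pd.DataFrame(
        {
            "time": [p.time for p in series],
            "thickness": [p.thickness for p in series],
            "n_film": [p.n_film for p in series],
            "gamma": [p.gamma for p in series],
        }
    ).to_csv(path, index=False)
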