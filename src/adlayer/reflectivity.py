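"""Specular neutron reflectivity forward model for stratified interfaces.

Implements the optical (Abeles) transfer-matrix method for a stack of
homogeneous slabs between a semi-infinite fronting (silicon, through
which the beam enters) and a semi-infinite backing (the solvent).  The
perpendicular wavevector in medium ``i`` is

    k_i = sqrt((Q/2)^2 - 4*pi*(rho_i - rho_fronting))

with the complex square root taken on the branch with non-negative
imaginary part so that evanescent waves decay.  Interfacial Gaussian
roughness enters through Nevot-Croce damping of the Fresnel
coefficients, ``r_i *= exp(-2 k_i k_{i+1} sigma^2)``.

Below the critical edge Q_c = 4*sqrt(pi*(rho_backing - rho_fronting))
the model returns total reflection (R = 1); instrument effects (scale,
flat background, Gaussian dQ/Q resolution smearing) are applied
separately so the bare model obeys 0 <= R <= 1.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass

import numpy as np

from .layers import ContrastSolvent, LayerStack, mix_sld, protein_sld_for_solvent


@dataclass
class ReflectivityCurve:
    """R(Q) with optional 1-sigma uncertainties and resolution widths."""

    q: np.ndarray  # Å^-1, strictly increasing
    r: np.ndarray
    dr: np.ndarray | None = None
    dq: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if self.q.size == 0:
            raise ValueError("empty Q grid")
        if np.any(self.q <= 0) or np.any(np.diff(self.q) <= 0):
            raise ValueError("Q grid must be positive and strictly increasing")
        if self.dr is not None:
            self.dr = np.asarray(self.dr, dtype=float)
        if self.dq is not None:
            self.dq = np.asarray(self.dq, dtype=float)


@dataclass
class InstrumentModel:
    """Multiplicative scale, additive background, fractional Gaussian resolution."""

    scale: float = 1.0
    background: float = 0.0
    dq_over_q: float = 0.04

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.background < 0:
            raise ValueError("background must be non-negative")
        if not 0.0 <= self.dq_over_q <= 0.2:
            raise ValueError("dq/q must lie in [0, 0.2]")


def q_from_angle(theta: float, wavelength: float) -> float:
    """Momentum transfer Q = 4*pi*sin(theta)/lambda (theta in degrees, lambda in Å)."""
    if not 0.0 < theta < 90.0:
        raise ValueError("incident angle must lie in (0, 90) degrees")
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    return 4.0 * math.pi * math.sin(math.radians(theta)) / wavelength


def critical_q(delta_rho: float) -> float:
    """Critical edge Q_c = 4*sqrt(pi*delta_rho) for backing-fronting SLD contrast.

    Returns 0 when delta_rho <= 0 (no total external reflection).
    """
    if delta_rho <= 0:
        return 0.0
    return 4.0 * math.sqrt(math.pi * delta_rho)


def _slab_arrays(
    stack: LayerStack, contrast: ContrastSolvent
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resolve the stack into (SLD, thickness, roughness) arrays, fronting first.

    The protein SLD is adjusted for H/D exchange in the given contrast
    and mixed with the solvent SLD by each slab's volume fraction.  The
    roughness array entry j is the width of the interface *above*
    layer j (between layers j and j+1).
    """
    sub = stack.substrate
    rho_protein = protein_sld_for_solvent(stack.protein, contrast.sld)
    rho_oxide = mix_sld(1.0 - sub.oxide_hydration, sub.oxide_sld, contrast.sld)

    slds = [sub.fronting_sld]
    thick = [0.0]
    rough = []  # interface widths; rough[j] sits between layers j and j+1
    if sub.oxide_thickness > 0:
        slds.append(rho_oxide)
        thick.append(sub.oxide_thickness)
        rough.append(sub.oxide_roughness)  # Si/oxide
    # the substrate surface roughness applies to the first interface into
    # the adsorbed layer (or solvent); each slab's own roughness applies
    # to the interface above it.
    sigma_below = sub.oxide_roughness
    for slab in stack.slabs:
        slds.append(mix_sld(slab.phi_protein, rho_protein, contrast.sld))
        thick.append(slab.thickness)
        rough.append(sigma_below)
        sigma_below = slab.roughness
    slds.append(contrast.sld)
    thick.append(0.0)
    rough.append(sigma_below)  # top interface to solvent
    return np.array(slds), np.array(thick), np.array(rough)


try:  # compiled kernel; the numpy path below is the reference fallback
    import numba as _numba
except ImportError:  # pragma: no cover
    _numba = None


if _numba is not None:

    @_numba.njit(cache=False, fastmath=False)
    def _abeles_compiled(q, slds, thick, rough):  # pragma: no cover - exercised via _abeles
        four_pi = 4.0 * np.pi
        m_pts, nlay = slds.shape
        out = np.empty(m_pts)
        for m in range(m_pts):
            k_j = complex(q[m] / 2.0, 0.0)
            m00 = 1.0 + 0.0j
            m01 = 0.0 + 0.0j
            m10 = 0.0 + 0.0j
            m11 = 1.0 + 0.0j
            for j in range(nlay - 1):
                kz2 = (q[m] / 2.0) ** 2 - four_pi * (slds[m, j + 1] - slds[m, 0])
                k_next = np.sqrt(complex(kz2, 0.0))
                if k_next.imag < 0.0:
                    k_next = -k_next
                rj = (k_j - k_next) / (k_j + k_next)
                if rough[j] > 0.0:
                    rj *= np.exp(-2.0 * k_j * k_next * rough[j] ** 2)
                beta = 1j * k_j * thick[j]
                e_pos = np.exp(beta)
                e_neg = 1.0 / e_pos
                c00 = e_pos
                c01 = rj * e_pos
                c10 = rj * e_neg
                c11 = e_neg
                n00 = m00 * c00 + m01 * c10
                n01 = m00 * c01 + m01 * c11
                n10 = m10 * c00 + m11 * c10
                n11 = m10 * c01 + m11 * c11
                m00, m01, m10, m11 = n00, n01, n10, n11
                k_j = k_next
            if m00 == 0.0:
                out[m] = 1.0
            else:
                amp = m10 / m00
                r = amp.real * amp.real + amp.imag * amp.imag
                if not np.isfinite(r):
                    r = 1.0
                out[m] = min(max(r, 0.0), 1.0)
        return out


def _abeles(
    q: np.ndarray, slds: np.ndarray, thick: np.ndarray, rough: np.ndarray
) -> np.ndarray:
    """Transfer-matrix reflectivity for layers given fronting-first arrays.

    Vectorized over Q.  ``slds[0]`` is the fronting, ``slds[-1]`` the
    backing; ``thick`` matches ``slds`` (0 for the semi-infinite media);
    ``rough[j]`` is the Gaussian width of the interface between layers
    j and j+1.  ``slds`` may also be a (len(q), nlay) matrix giving a
    per-point layer structure (used to batch several contrasts into one
    kernel call).
    """
    q = np.asarray(q, dtype=float)
    slds = np.asarray(slds, dtype=float)
    if slds.ndim == 1:
        slds = np.broadcast_to(slds[None, :], (len(q), len(slds)))
    if _numba is not None:
        return _abeles_compiled(
            np.ascontiguousarray(q),
            np.ascontiguousarray(slds),
            np.ascontiguousarray(np.asarray(thick, dtype=float)),
            np.ascontiguousarray(np.asarray(rough, dtype=float)),
        )
    return _abeles_numpy(q, slds, thick, rough)


def _abeles_numpy(
    q: np.ndarray, slds: np.ndarray, thick: np.ndarray, rough: np.ndarray
) -> np.ndarray:
    """Pure-numpy reference implementation of the transfer-matrix kernel."""
    nlay = slds.shape[1]
    kz2 = (q[:, None] / 2.0) ** 2 - 4.0 * math.pi * (slds - slds[:, :1])
    k = np.sqrt(kz2.astype(complex))
    # decaying branch: non-negative imaginary part
    k = np.where(k.imag < 0, -k, k)

    # interface Fresnel coefficients with Nevot-Croce damping
    rj = (k[:, :-1] - k[:, 1:]) / (k[:, :-1] + k[:, 1:])
    rj = rj * np.exp(-2.0 * k[:, :-1] * k[:, 1:] * rough[None, :] ** 2)

    # characteristic-matrix product, fronting to backing
    m00 = np.ones(q.shape, dtype=complex)
    m01 = np.zeros_like(m00)
    m10 = np.zeros_like(m00)
    m11 = np.ones_like(m00)
    for j in range(nlay - 1):
        beta = 1j * k[:, j] * thick[j]  # thick[0] = 0 for the fronting
        e_pos = np.exp(beta)
        e_neg = np.exp(-beta)
        c00 = e_pos
        c01 = rj[:, j] * e_pos
        c10 = rj[:, j] * e_neg
        c11 = e_neg
        n00 = m00 * c00 + m01 * c10
        n01 = m00 * c01 + m01 * c11
        n10 = m10 * c00 + m11 * c10
        n11 = m10 * c01 + m11 * c11
        m00, m01, m10, m11 = n00, n01, n10, n11

    with np.errstate(divide="ignore", invalid="ignore"):
        refl = np.abs(m10 / m00) ** 2
    refl = np.where(np.isfinite(refl), refl, 1.0)
    return np.clip(refl.real, 0.0, 1.0)


def abeles_reflectivity(
    stack: LayerStack, contrast: ContrastSolvent, q: np.ndarray
) -> ReflectivityCurve:
    """Unpolarized specular reflectivity of the stack in the given contrast."""
    q = np.asarray(q, dtype=float)
    if q.size == 0:
        raise ValueError("empty Q grid")
    slds, thick, rough = _slab_arrays(stack, contrast)
    return ReflectivityCurve(q=q, r=_abeles(q, slds, thick, rough))


# 13-point Gaussian quadrature abscissae/weights over +-3.5 sigma for
# constant-dQ/Q smearing (weights renormalised over the truncated window).
_N_SMEAR = 13
_SMEAR_X = np.linspace(-3.5, 3.5, _N_SMEAR)
_SMEAR_W = np.exp(-0.5 * _SMEAR_X**2)
_SMEAR_W /= _SMEAR_W.sum()

#: FWHM -> sigma for a Gaussian.
_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))


def smear_function(
    q: np.ndarray, r_of_q, dq_over_q: float
) -> np.ndarray:
    """Gaussian resolution smearing of a model function R(Q).

    ``dq_over_q`` is the fractional FWHM resolution; sigma_Q =
    (dq_over_q / 2.355) * Q.  Evaluates the model on a 13-point
    Gaussian-weighted stencil around each Q.
    """
    q = np.asarray(q, dtype=float)
    if dq_over_q < 0:
        raise ValueError("dq/q must be non-negative")
    if dq_over_q == 0:
        return np.asarray(r_of_q(q), dtype=float)
    sigma = (dq_over_q / _FWHM) * q
    qs = q[:, None] + sigma[:, None] * _SMEAR_X[None, :]
    qs = np.maximum(qs, 1e-8)
    rs = np.asarray(r_of_q(qs.ravel()), dtype=float).reshape(qs.shape)
    return rs @ _SMEAR_W


def smear(curve: ReflectivityCurve, dq_over_q: float) -> ReflectivityCurve:
    """Smear a tabulated curve by interpolating it (linear in log R) onto the stencil."""
    if dq_over_q == 0:
        return ReflectivityCurve(q=curve.q.copy(), r=curve.r.copy())

    def interp(qx):
        return interpolate_log(qx, curve.q, curve.r)

    r_sm = smear_function(curve.q, interp, dq_over_q)
    dq = (dq_over_q / _FWHM) * curve.q
    return ReflectivityCurve(q=curve.q.copy(), r=r_sm, dq=dq)


def interpolate_log(qx: np.ndarray, q: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Interpolate R onto qx, linear in log R where R > 0 (linear otherwise)."""
    qx = np.asarray(qx, dtype=float)
    if np.all(r > 0):
        return np.exp(np.interp(qx, q, np.log(r)))
    return np.interp(qx, q, r)


def apply_instrument(
    curve: ReflectivityCurve, instrument: InstrumentModel
) -> ReflectivityCurve:
    """Scale and background: R' = scale * R + background."""
    return ReflectivityCurve(
        q=curve.q.copy(),
        r=instrument.scale * curve.r + instrument.background,
        dr=None if curve.dr is None else instrument.scale * curve.dr,
        dq=None if curve.dq is None else curve.dq.copy(),
    )


def model_curve(
    stack: LayerStack,
    contrast: ContrastSolvent,
    q: np.ndarray,
    instrument: InstrumentModel | None = None,
) -> ReflectivityCurve:
    """Full instrument-convolved model: Abeles + dQ/Q smearing + scale/background."""
    instrument = instrument or InstrumentModel()
    slds, thick, rough = _slab_arrays(stack, contrast)
    r = smear_function(
        np.asarray(q, dtype=float),
        lambda qq: _abeles(qq, slds, thick, rough),
        instrument.dq_over_q,
    )
    return ReflectivityCurve(
        q=np.asarray(q, dtype=float),
        r=instrument.scale * r + instrument.background,
    )


# ---------------------------------------------------------------------------
# ASCII I/O: 2-4 whitespace/comma-delimited columns (Q, R[, dR[, dQ]]) with
# '#'-prefixed header lines in the ORSO plain-text spirit.


def write_curve(path, curve: ReflectivityCurve, header: dict | None = None) -> None:
    """Write a reflectivity curve as delimited ASCII with a commented header."""
    cols = [curve.q, curve.r]
    names = ["Qz [1/angstrom]", "R [dimensionless]"]
    if curve.dr is not None:
        cols.append(curve.dr)
        names.append("sR [dimensionless]")
    if curve.dq is not None:
        if curve.dr is None:
            cols.insert(2, np.zeros_like(curve.q))
            names.insert(2, "sR [dimensionless]")
        cols.append(curve.dq)
        names.append("sQz [1/angstrom]")
    buf = io.StringIO()
    for key, val in (header or {}).items():
        buf.write(f"# {key}: {val}\n")
    buf.write("# columns: " + " | ".join(names) + "\n")
    np.savetxt(buf, np.column_stack(cols), fmt="%.8e")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_curve(path) -> ReflectivityCurve:
    """Read 2-4 column ASCII reflectivity (Q, R[, dR[, dQ]]); '#' lines ignored."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "!", ";")):
                continue
            parts = line.replace(",", " ").split()
            rows.append([float(p) for p in parts])
    if not rows:
        raise ValueError(f"no data rows in {path}")
    arr = np.array(rows)
    ncol = arr.shape[1]
    if ncol < 2:
        raise ValueError(f"{path}: need at least Q and R columns")
    return ReflectivityCurve(
        q=arr[:, 0],
        r=arr[:, 1],
        dr=arr[:, 2] if ncol >= 3 else None,
        dq=arr[:, 3] if ncol >= 4 else None,
    )
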