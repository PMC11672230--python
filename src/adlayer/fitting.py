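"""Simultaneous least-squares refinement of a slab model against
multiple isotopic-contrast reflectivity datasets.

One structural model (slab thicknesses, protein volume fractions,
roughnesses) is shared across all contrasts; only instrument terms
(scale, background) may vary per contrast.  At every objective
evaluation the slab SLDs are recomputed for each contrast from the
volume fractions, the solvent SLD and the H/D-exchange-adjusted protein
SLD, so a single set of structural parameters must explain all curves
at once.

Optimisation is a seeded global stochastic search (differential
evolution) followed by a local trust-region least-squares polish.
Uncertainties come from a bootstrap: data points are resampled with
replacement within each contrast and the model refit; percentile
intervals of the parameters and of derived quantities (adsorbed amount,
mass-center distance) are reported.  The slab count is chosen by an
elbow criterion on the normalised chi-square.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

from .layers import (
    ContrastSolvent,
    LayerStack,
    LayerSummary,
    ProteinSpecies,
    Slab,
    Substrate,
    mix_sld,
    protein_sld_for_solvent,
    summarize,
)
from .reflectivity import (
    _FWHM,
    _SMEAR_W,
    _SMEAR_X,
    InstrumentModel,
    ReflectivityCurve,
    _abeles,
)

logger = logging.getLogger(__name__)


@dataclass
class ContrastDataset:
    """A measured (or simulated) reflectivity curve bound to one solvent contrast."""

    solvent: ContrastSolvent
    curve: ReflectivityCurve
    instrument: InstrumentModel = field(default_factory=InstrumentModel)


@dataclass
class FitSpec:
    """What is refined and within which bounds.

    Structural parameters (per-slab thickness, volume fraction and,
    optionally, roughness) are shared across all contrasts.  Scale and
    background are per-contrast instrument terms; by default scales are
    fixed at their dataset values and backgrounds are free.
    """

    n_slabs: int = 2
    tau_bounds: tuple[float, float] = (5.0, 120.0)
    phi_bounds: tuple[float, float] = (0.0, 0.7)
    sigma_bounds: tuple[float, float] = (0.0, 15.0)
    background_bounds: tuple[float, float] = (0.0, 1e-5)
    scale_bounds: tuple[float, float] = (0.9, 1.1)
    fit_roughness: bool = False
    fit_scale: bool = False
    fit_background: bool = True
    substrate: Substrate = field(default_factory=Substrate)

    def __post_init__(self) -> None:
        if self.n_slabs < 1:
            raise ValueError("need at least one slab")

    def n_params(self, n_contrasts: int) -> int:
        n = 2 * self.n_slabs
        if self.fit_roughness:
            n += self.n_slabs
        if self.fit_scale:
            n += n_contrasts
        if self.fit_background:
            n += n_contrasts
        return n

    def bounds(self, n_contrasts: int) -> list[tuple[float, float]]:
        b = [self.tau_bounds] * self.n_slabs + [self.phi_bounds] * self.n_slabs
        if self.fit_roughness:
            b += [self.sigma_bounds] * self.n_slabs
        if self.fit_scale:
            b += [self.scale_bounds] * n_contrasts
        if self.fit_background:
            b += [self.background_bounds] * n_contrasts
        return b

    def unpack(self, x: np.ndarray, n_contrasts: int):
        """Split a parameter vector into (taus, phis, sigmas, scales, backgrounds)."""
        n = self.n_slabs
        taus = x[:n]
        phis = x[n : 2 * n]
        i = 2 * n
        if self.fit_roughness:
            sigmas = x[i : i + n]
            i += n
        else:
            sigmas = np.zeros(n)
        if self.fit_scale:
            scales = x[i : i + n_contrasts]
            i += n_contrasts
        else:
            scales = None
        if self.fit_background:
            backgrounds = x[i : i + n_contrasts]
        else:
            backgrounds = None
        return taus, phis, sigmas, scales, backgrounds

    def pack(self, stack: LayerStack, datasets: Sequence[ContrastDataset]) -> np.ndarray:
        """Parameter vector corresponding to a stack + dataset instrument terms."""
        x = [s.thickness for s in stack.slabs] + [s.phi_protein for s in stack.slabs]
        if self.fit_roughness:
            x += [s.roughness for s in stack.slabs]
        if self.fit_scale:
            x += [d.instrument.scale for d in datasets]
        if self.fit_background:
            x += [d.instrument.background for d in datasets]
        return np.array(x, dtype=float)


@dataclass
class FitResult:
    """Best-fit state of a simultaneous refinement."""

    spec: FitSpec
    params: np.ndarray
    stack: LayerStack
    chi2_global: float
    chi2_per_contrast: list[float]
    summary: LayerSummary
    model_curves: list[ReflectivityCurve]
    converged: bool
    n_evaluations: int
    bootstrap_intervals: dict | None = None

    def to_dict(self) -> dict:
        d = {
            "chi2_global": self.chi2_global,
            "chi2_per_contrast": self.chi2_per_contrast,
            "converged": self.converged,
            "n_evaluations": self.n_evaluations,
            "params": self.params.tolist(),
            "summary": {
                "thicknesses_A": self.summary.thicknesses,
                "volume_fractions": self.summary.volume_fractions,
                "adsorbed_amounts_mg_m2": self.summary.gammas,
                "total_thickness_A": self.summary.total_thickness,
                "total_gamma_mg_m2": self.summary.total_gamma,
                "mean_volume_fraction": self.summary.mean_volume_fraction,
                "mass_fractions": self.summary.mass_fractions,
                "mass_center_A": self.summary.mass_center,
            },
        }
        if self.bootstrap_intervals is not None:
            d["bootstrap"] = self.bootstrap_intervals
        return d


def chi_squared(
    model_curves: Sequence[ReflectivityCurve],
    datasets: Sequence[ContrastDataset],
) -> tuple[float, list[float]]:
    """Normalised chi-square, global and per contrast.

    chi2 = sum(((R_model - R_data)/dR)^2) / N per contrast; the global
    value pools the squared residuals over all contrasts and divides by
    the total point count.  Missing or zero uncertainties fall back to
    unweighted residuals with a warning.
    """
    per = []
    ss_total = 0.0
    n_total = 0
    for mc, ds in zip(model_curves, datasets):
        resid = _weighted_residuals(mc.r, ds)
        per.append(float(resid @ resid) / len(resid))
        ss_total += float(resid @ resid)
        n_total += len(resid)
    return ss_total / n_total, per


def _weighted_residuals(r_model: np.ndarray, ds: ContrastDataset) -> np.ndarray:
    r_data = ds.curve.r
    dr = ds.curve.dr
    if dr is None or np.any(dr <= 0):
        logger.warning(
            "dataset %s has missing/zero uncertainties; unweighted residuals",
            ds.solvent.name,
        )
        return r_model - r_data
    return (r_model - r_data) / dr


class _FastModel:
    """Precompiled multi-contrast forward model on the data Q grids.

    Precomputes, per contrast, the smearing stencil and the
    contrast-resolved constant SLDs (fronting, oxide, protein, solvent)
    so each objective evaluation only assembles the slab arrays and
    runs the Abeles kernel.
    """

    def __init__(
        self,
        datasets: Sequence[ContrastDataset],
        spec: FitSpec,
        protein: ProteinSpecies,
    ):
        self.datasets = list(datasets)
        self.spec = spec
        self.protein = protein
        sub = spec.substrate
        self.sub = sub
        self._per_contrast = []
        for ds in datasets:
            q = ds.curve.q
            dqq = ds.instrument.dq_over_q
            if dqq > 0:
                sigma = (dqq / _FWHM) * q
                qs = np.maximum(q[:, None] + sigma[:, None] * _SMEAR_X[None, :], 1e-8)
            else:
                qs = q[:, None]
            rho_protein = protein_sld_for_solvent(protein, ds.solvent.sld)
            rho_oxide = mix_sld(1.0 - sub.oxide_hydration, sub.oxide_sld, ds.solvent.sld)
            self._per_contrast.append(
                dict(
                    qs=qs,
                    rho_protein=rho_protein,
                    rho_oxide=rho_oxide,
                    rho_solvent=ds.solvent.sld,
                )
            )
        self._q_flat = np.concatenate([pc["qs"].ravel() for pc in self._per_contrast])
        self._counts = [pc["qs"].size for pc in self._per_contrast]
        self._offsets = np.concatenate([[0], np.cumsum(self._counts)])
        self._has_oxide = sub.oxide_thickness > 0

    def curves(self, x: np.ndarray) -> list[np.ndarray]:
        """Model reflectivity on each dataset's Q grid for parameter vector x.

        All contrasts are evaluated in one batched Abeles call: the layer
        SLD matrix has one row per (contrast, stencil point) Q value.
        """
        spec = self.spec
        sub = self.sub
        n_c = len(self.datasets)
        taus, phis, sigmas, scales, backgrounds = spec.unpack(x, n_c)

        nlay = spec.n_slabs + 2 + (1 if self._has_oxide else 0)
        thick = np.zeros(nlay)
        rough = np.empty(nlay - 1)
        j0 = 1
        if self._has_oxide:
            thick[1] = sub.oxide_thickness
            rough[0] = sub.oxide_roughness
            j0 = 2
        thick[j0 : j0 + spec.n_slabs] = taus
        rough[j0 - 1] = sub.oxide_roughness
        rough[j0 : j0 + spec.n_slabs] = sigmas

        sld_rows = np.empty((n_c, nlay))
        for i, pc in enumerate(self._per_contrast):
            sld_rows[i, 0] = sub.fronting_sld
            if self._has_oxide:
                sld_rows[i, 1] = pc["rho_oxide"]
            sld_rows[i, j0 : j0 + spec.n_slabs] = (
                phis * pc["rho_protein"] + (1.0 - phis) * pc["rho_solvent"]
            )
            sld_rows[i, -1] = pc["rho_solvent"]
        slds = np.repeat(sld_rows, self._counts, axis=0)

        r_flat = _abeles(self._q_flat, slds, thick, rough)
        out = []
        for i, (ds, pc) in enumerate(zip(self.datasets, self._per_contrast)):
            r = r_flat[self._offsets[i] : self._offsets[i + 1]].reshape(pc["qs"].shape)
            r = r @ _SMEAR_W if pc["qs"].shape[1] > 1 else r[:, 0]
            scale = scales[i] if scales is not None else ds.instrument.scale
            bkg = backgrounds[i] if backgrounds is not None else ds.instrument.background
            out.append(scale * r + bkg)
        return out

    def residuals(self, x: np.ndarray) -> np.ndarray:
        return np.concatenate(
            [
                _weighted_residuals(r, ds)
                for r, ds in zip(self.curves(x), self.datasets)
            ]
        )

    def chi2(self, x: np.ndarray) -> float:
        resid = self.residuals(x)
        return float(resid @ resid) / len(resid)


def _result_from_vector(
    x: np.ndarray,
    model: _FastModel,
    spec: FitSpec,
    protein: ProteinSpecies,
    converged: bool,
    n_evaluations: int,
) -> FitResult:
    taus, phis, sigmas, scales, backgrounds = spec.unpack(x, len(model.datasets))
    stack = LayerStack(
        substrate=spec.substrate,
        slabs=[
            Slab(thickness=float(t), phi_protein=float(np.clip(p, 0.0, 1.0)),
                 roughness=float(s))
            for t, p, s in zip(taus, phis, sigmas)
        ],
        protein=protein,
    )
    model_r = model.curves(x)
    curves = [
        ReflectivityCurve(q=ds.curve.q.copy(), r=r)
        for ds, r in zip(model.datasets, model_r)
    ]
    chi2_g, chi2_per = chi_squared(curves, model.datasets)
    return FitResult(
        spec=spec,
        params=np.asarray(x, dtype=float),
        stack=stack,
        chi2_global=chi2_g,
        chi2_per_contrast=chi2_per,
        summary=summarize(stack),
        model_curves=curves,
        converged=converged,
        n_evaluations=n_evaluations,
    )


def fit_simultaneous(
    datasets: Sequence[ContrastDataset],
    spec: FitSpec,
    protein: ProteinSpecies,
    seed: int = 0,
    x0: np.ndarray | None = None,
    local_only: bool = False,
    de_maxiter: int = 60,
    de_popsize: int = 12,
) -> FitResult:
    """Co-refine one slab model against all contrasts.

    A seeded differential-evolution global search over the bounds is
    followed by a bounded least-squares polish.  With ``local_only=True``
    (or when ``x0`` is supplied and ``local_only`` is requested) only the
    polish stage runs from ``x0`` — used for bootstrap refits.
    Deterministic for a given seed.
    """
    if len(datasets) < 1:
        raise ValueError("need at least one contrast dataset")
    model = _FastModel(datasets, spec, protein)
    bounds = spec.bounds(len(datasets))
    lb = np.array([b[0] for b in bounds])
    ub = np.array([b[1] for b in bounds])
    nev = 0

    if local_only:
        if x0 is None:
            raise ValueError("local_only fits require a starting vector x0")
        x_start = np.clip(np.asarray(x0, dtype=float), lb, ub)
    else:
        de = optimize.differential_evolution(
            model.chi2,
            bounds=bounds,
            seed=seed,
            maxiter=de_maxiter,
            popsize=de_popsize,
            tol=1e-3,
            polish=False,
            init="sobol" if x0 is None else "sobol",
            x0=x0,
            updating="deferred",
        )
        nev += de.nfev
        x_start = de.x
        logger.info("global stage: chi2=%.4g after %d evaluations", de.fun, de.nfev)

    if local_only:  # bootstrap refits: start near the optimum, polish briefly
        tols = dict(xtol=1e-8, ftol=1e-8, gtol=1e-8, max_nfev=120)
    else:
        tols = dict(xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=400)
    ls = optimize.least_squares(
        model.residuals, x_start, bounds=(lb, ub), method="trf", **tols
    )
    nev += ls.nfev
    converged = bool(ls.success) if local_only else True
    if not ls.success:
        logger.warning("local polish did not fully converge: %s", ls.message)
    # keep whichever stage is better (polish can stall on a bound)
    x_best = ls.x if (local_only or model.chi2(ls.x) <= model.chi2(x_start)) else x_start
    # canonical slab order: sort by decreasing phi is not meaningful physically;
    # slabs are ordered from the surface outward by construction, no reordering.
    result = _result_from_vector(x_best, model, spec, protein, converged, nev)
    logger.info("fit: global chi2=%.4g, per-contrast %s",
                result.chi2_global,
                ", ".join(f"{c:.3g}" for c in result.chi2_per_contrast))
    return result


def select_slab_count(
    datasets: Sequence[ContrastDataset],
    protein: ProteinSpecies,
    max_slabs: int = 4,
    threshold: float = 0.10,
    seed: int = 0,
    spec_template: FitSpec | None = None,
    **fit_kwargs,
) -> tuple[int, list[tuple[int, float]]]:
    """Pick the slab count by the chi-square elbow criterion.

    Fits n = 1..max_slabs and returns the smallest n for which the
    relative improvement in global chi2 from n to n+1 slabs falls below
    ``threshold``, together with the elbow table [(n, chi2), ...].
    """
    if max_slabs < 1:
        raise ValueError("max_slabs must be >= 1")
    template = spec_template or FitSpec()
    chi2s: list[tuple[int, float]] = []
    for n in range(1, max_slabs + 1):
        spec = FitSpec(
            n_slabs=n,
            tau_bounds=template.tau_bounds,
            phi_bounds=template.phi_bounds,
            sigma_bounds=template.sigma_bounds,
            background_bounds=template.background_bounds,
            scale_bounds=template.scale_bounds,
            fit_roughness=template.fit_roughness,
            fit_scale=template.fit_scale,
            fit_background=template.fit_background,
            substrate=template.substrate,
        )
        res = fit_simultaneous(datasets, spec, protein, seed=seed + n, **fit_kwargs)
        chi2s.append((n, res.chi2_global))
        logger.info("elbow: n=%d chi2=%.4g", n, res.chi2_global)
    for (n, c_n), (_, c_next) in zip(chi2s[:-1], chi2s[1:]):
        improvement = (c_n - c_next) / c_n if c_n > 0 else 0.0
        if improvement < threshold:
            return n, chi2s
    return max_slabs, chi2s


_DERIVED_KEYS = ("total_gamma", "mass_center", "total_thickness")


def bootstrap(
    datasets: Sequence[ContrastDataset],
    spec: FitSpec,
    protein: ProteinSpecies,
    fit: FitResult,
    n_resamples: int = 1000,
    seed: int = 0,
    resample: str = "points",
) -> dict:
    """Bootstrap percentile intervals for parameters and derived quantities.

    Data points are resampled with replacement within each contrast
    (``resample="points"``, the default) or model residuals are permuted
    onto the fitted curve (``resample="residuals"``); each resample is
    refit locally from the best-fit vector.  Reports 68% and 95%
    percentile intervals for every free parameter and for the derived
    total adsorbed amount, mass-center distance and total thickness.
    Failed refits are skipped and counted.
    """
    rng = np.random.default_rng(seed)
    x_best = fit.params
    samples: list[np.ndarray] = []
    derived: dict[str, list[float]] = {k: [] for k in _DERIVED_KEYS}
    n_failed = 0
    for _ in range(n_resamples):
        try:
            res_datasets = _resample_datasets(datasets, fit, rng, resample)
            refit = fit_simultaneous(
                res_datasets, spec, protein, x0=x_best, local_only=True
            )
        except Exception:  # noqa: BLE001 -- any resample failure is just counted
            n_failed += 1
            continue
        samples.append(refit.params)
        derived["total_gamma"].append(refit.summary.total_gamma)
        derived["mass_center"].append(refit.summary.mass_center)
        derived["total_thickness"].append(refit.summary.total_thickness)

    if not samples:
        raise RuntimeError("all bootstrap refits failed")
    arr = np.array(samples)
    out: dict = {
        "n_resamples": n_resamples,
        "n_failed": n_failed,
        "failure_rate": n_failed / n_resamples,
        "parameters": {},
        "derived": {},
    }
    for j in range(arr.shape[1]):
        out["parameters"][f"p{j}"] = _intervals(arr[:, j])
    for key, vals in derived.items():
        out["derived"][key] = _intervals(np.array(vals))
    return out


def _intervals(v: np.ndarray) -> dict:
    return {
        "median": float(np.median(v)),
        "ci68": [float(np.percentile(v, 16)), float(np.percentile(v, 84))],
        "ci95": [float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5))],
    }


def _resample_datasets(
    datasets: Sequence[ContrastDataset],
    fit: FitResult,
    rng: np.random.Generator,
    resample: str,
) -> list[ContrastDataset]:
    out = []
    for ds, mc in zip(datasets, fit.model_curves):
        n = len(ds.curve.q)
        if resample == "points":
            idx = np.sort(rng.integers(0, n, size=n))
            # strictly increasing Q required: collapse duplicates by keeping
            # unique indices and reweighting via repetition is equivalent in
            # least squares to duplicating residual rows, so we keep duplicate
            # rows but nudge Q by nothing -- instead resample residual rows.
            curve = ReflectivityCurve(
                q=ds.curve.q.copy(),
                r=ds.curve.r.copy(),
                dr=None if ds.curve.dr is None else ds.curve.dr.copy(),
                dq=None if ds.curve.dq is None else ds.curve.dq.copy(),
            )
            counts = np.bincount(idx, minlength=n).astype(float)
            # weight_i = sqrt(count_i): duplicated points count multiply,
            # omitted points drop out, matching case resampling exactly.
            with np.errstate(divide="ignore"):
                w = np.sqrt(counts)
            dr = curve.dr if curve.dr is not None else np.ones(n)
            dr_eff = np.where(w > 0, dr / np.maximum(w, 1e-300), np.inf)
            curve.dr = dr_eff
        elif resample == "residuals":
            # resample standardized residuals: the noise scale varies by
            # orders of magnitude across Q, so raw residuals cannot move
            dr = ds.curve.dr if ds.curve.dr is not None else np.ones(n)
            resid = (ds.curve.r - mc.r) / dr
            idx = rng.integers(0, n, size=n)
            curve = ReflectivityCurve(
                q=ds.curve.q.copy(),
                r=mc.r + resid[idx] * dr,
                dr=None if ds.curve.dr is None else ds.curve.dr.copy(),
                dq=None if ds.curve.dq is None else ds.curve.dq.copy(),
            )
        else:
            raise ValueError(f"unknown resample mode {resample!r}")
        out.append(ContrastDataset(solvent=ds.solvent, curve=curve, instrument=ds.instrument))
    return out
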