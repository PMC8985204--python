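"""Simultaneous multi-contrast fitting of the core-shell sphere model.

Several reduced curves of the same particle dispersion, measured under
different solvent/core isotopic contrasts, are fitted together: the
structural parameters (core radius, shell thickness, polydispersity, shell
hydration, volume fraction) are shared across datasets while the core and
solvent SLDs are held fixed at their computed values and only background
(and optionally an intensity scale) floats per dataset.

The shell SLD is not itself a fit parameter: the shell is a mixture of dry
surfactant and solvent, so its SLD in dataset j is

    rho_shell_j = (1 - h) * rho_dry + h * rho_solvent_j

with a single hydration fraction h shared by every contrast.  This keeps
the fit physically consistent across H2O and D2O datasets; the
conventional "fitted shell SLD" is reported per contrast as a derived
quantity.

Optimisation is bounded trust-region least squares with seeded
Latin-hypercube multi-start; uncertainties come from the Jacobian at the
optimum scaled by the reduced chi^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from . import composition
from .composition import mix_sld
from .dataset import SASDataset
from .formfactor import CoreShellParams, polydisperse_intensity
from .resolution import smear

__all__ = [
    "FitProblem",
    "FitResult",
    "BatteryReport",
    "build_problem",
    "resolve_contrast",
    "fit",
    "derived_quantities",
    "scenario_battery",
]

SHARED_PARAMS = (
    "core_radius",
    "shell_thickness",
    "polydispersity",
    "hydration",
    "volume_fraction",
)

DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "core_radius": (50.0, 600.0),
    "shell_thickness": (0.0, 100.0),
    "polydispersity": (0.0, 0.6),
    "hydration": (0.0, 1.0),
    "volume_fraction": (1e-4, 0.3),
    "background": (0.0, np.inf),
    "scale": (0.1, 10.0),
}


def resolve_contrast(label: str, radiation: str = "neutron") -> tuple[float, float]:
    """(sld_core, sld_solvent) for a contrast label like 'hLNC/D2O'.

    The prefix 'h'/'d' selects the protiated Labrafac core or the 5%
    deuterated-acid blend; the suffix names the solvent ('H2O', 'D2O', or
    'f=0.146' for a mixture).  SLDs are computed from the bundled component
    compositions.
    """
    try:
        core_part, solvent_part = label.split("/")
    except ValueError:
        raise ValueError(f"contrast label {label!r} is not '<core>/<solvent>'")
    core_kind = core_part.strip().lower()[:1]
    if radiation == "xray":
        if core_kind not in ("h", "d"):
            raise ValueError(f"unknown core kind in contrast label {label!r}")
        return (
            composition.sld(composition.LABRAFAC, "xray"),
            composition.sld(composition.WATER, "xray"),
        )
    if core_kind == "h":
        sld_core = composition.sld(composition.LABRAFAC)
    elif core_kind == "d":
        sld_core = composition.labrafac_d_blend().sld()
    else:
        raise ValueError(f"unknown core kind in contrast label {label!r}")
    solvent_part = solvent_part.strip()
    if solvent_part.upper() == "H2O":
        f = 0.0
    elif solvent_part.upper() == "D2O":
        f = 1.0
    elif solvent_part.lower().startswith("f="):
        f = float(solvent_part[2:])
    else:
        raise ValueError(f"unknown solvent in contrast label {label!r}")
    return sld_core, composition.solvent_sld(f)


@dataclass
class FitProblem:
    """A multi-dataset fit specification with shared structural parameters."""

    datasets: list[SASDataset]
    shared_free: tuple[str, ...] = SHARED_PARAMS
    per_dataset_free: tuple[str, ...] = ("background",)
    fixed: dict[str, float] = field(default_factory=dict)
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    dry_shell_sld: float = 0.13
    quadrature_points: int = 35

    def __post_init__(self) -> None:
        if not self.datasets:
            raise ValueError("need at least one dataset")
        for name in self.shared_free:
            if name not in SHARED_PARAMS:
                raise ValueError(f"unknown shared parameter {name!r}")
        for name in self.per_dataset_free:
            if name not in ("background", "scale"):
                raise ValueError(f"unknown per-dataset parameter {name!r}")
        for name in SHARED_PARAMS:
            if name not in self.shared_free and name not in self.fixed:
                raise ValueError(f"parameter {name!r} neither free nor fixed")
        for name in self.shared_free + self.per_dataset_free:
            lo, hi = self.get_bounds(name)
            if not lo < hi:
                raise ValueError(f"invalid bounds for {name!r}: ({lo}, {hi})")

    def get_bounds(self, name: str) -> tuple[float, float]:
        return self.bounds.get(name, DEFAULT_BOUNDS[name])

    @property
    def param_names(self) -> list[str]:
        names = list(self.shared_free)
        for j in range(len(self.datasets)):
            names += [f"{p}_{j}" for p in self.per_dataset_free]
        return names


@dataclass
class FitResult:
    """Estimates, uncertainties and goodness-of-fit of one joint fit."""

    estimates: dict[str, float]
    uncertainties: dict[str, float]
    covariance: np.ndarray
    param_names: list[str]
    chi2_reduced: float
    per_dataset_chi2: list[float]
    n_points: int
    at_bounds: list[str] = field(default_factory=list)
    derived: dict = field(default_factory=dict)
    success: bool = True

    def __getitem__(self, name: str) -> float:
        return self.estimates[name]


def build_problem(
    datasets: Sequence[SASDataset],
    radiation: str = "neutron",
    shared_free: tuple[str, ...] = SHARED_PARAMS,
    per_dataset_free: tuple[str, ...] = ("background",),
    fixed: Optional[dict[str, float]] = None,
    bounds: Optional[dict[str, tuple[float, float]]] = None,
    dry_shell_sld: Optional[float] = None,
) -> FitProblem:
    """Assemble a :class:`FitProblem`, resolving SLDs from contrast labels.

    Datasets whose ``sld_core``/``sld_solvent`` are both zero get them
    computed from their ``contrast_label`` via the bundled compositions.
    ``dry_shell_sld`` defaults to the conventional dry Kolliphor HS 15
    value for the chosen radiation (0.13 for neutrons, the reference the
    hydration inversion is defined against; the computed value
    approximates it).
    """
    out = []
    for ds in datasets:
        if ds.sld_core == 0.0 and ds.sld_solvent == 0.0:
            if not ds.contrast_label:
                raise ValueError("dataset lacks SLDs and a contrast label")
            core, solv = resolve_contrast(ds.contrast_label, radiation)
            ds = ds.replace(sld_core=core, sld_solvent=solv)
        out.append(ds)
    if dry_shell_sld is None:
        dry_shell_sld = (
            0.13 if radiation == "neutron"
            else composition.sld(composition.KOLLIPHOR_HS15, "xray")
        )
    return FitProblem(
        datasets=out,
        shared_free=tuple(shared_free),
        per_dataset_free=tuple(per_dataset_free),
        fixed=dict(fixed or {}),
        bounds=dict(bounds or {}),
        dry_shell_sld=dry_shell_sld,
    )


def _shell_sld(problem: FitProblem, ds: SASDataset, hydration: float) -> float:
    return mix_sld(
        [(problem.dry_shell_sld, 1.0 - hydration), (ds.sld_solvent, hydration)]
    )


def _model_curve(problem: FitProblem, ds: SASDataset, shared: dict,
                 per: dict) -> np.ndarray:
    """Reference forward model for one dataset (form factor -> smear)."""
    p = CoreShellParams(
        core_radius=shared["core_radius"],
        shell_thickness=shared["shell_thickness"],
        sld_core=ds.sld_core,
        sld_shell=_shell_sld(problem, ds, shared["hydration"]),
        sld_solvent=ds.sld_solvent,
        volume_fraction=shared["volume_fraction"],
        polydispersity=shared["polydispersity"],
        background=0.0,
    )
    base = smear(
        ds.q,
        lambda qq: polydisperse_intensity(qq, p, problem.quadrature_points),
        ds.resolution,
    )
    return per.get("scale", 1.0) * base + per.get("background", 0.0)


class _ModelCache:
    """Shared-kernel fast path for the joint residual.

    The sphere-kernel matrices Phi(q R_t), Phi(q R_c) over the (smearing
    node) x (radius quadrature) grid depend only on the structural
    parameters, not on the contrast, so for datasets sharing a q grid and
    resolution they are computed once per evaluation and the per-contrast
    intensity follows from the quadratic form

        <F^2> = c1^2 <Vt^2 Pt^2> + 2 c1 c2 <Vt Vc Pt Pc> + c2^2 <Vc^2 Pc^2>

    with c1 = rho_shell - rho_solv and c2 = rho_core - rho_shell.  Agrees
    with the reference route to machine precision (tested).
    """

    def __init__(self, problem: FitProblem) -> None:
        self.problem = problem
        from .resolution import DEFAULT_SMEAR_NODES, _hermgauss

        groups: dict[bytes, list[int]] = {}
        self.nodes: dict[bytes, np.ndarray] = {}
        self.weights: dict[bytes, np.ndarray] = {}
        self.ds_group: list[bytes] = []
        for j, ds in enumerate(problem.datasets):
            sig = ds.resolution.sigma_q(ds.q)
            key = ds.q.tobytes() + sig.tobytes()
            self.ds_group.append(key)
            if key in groups:
                groups[key].append(j)
                continue
            groups[key] = [j]
            if np.all(sig == 0):
                self.nodes[key] = ds.q
                self.weights[key] = None  # identity
            else:
                x, w = _hermgauss(DEFAULT_SMEAR_NODES)
                nodes = ds.q[:, None] + np.sqrt(2.0) * sig[:, None] * x[None, :]
                weights = np.broadcast_to(w[None, :], nodes.shape).copy()
                weights[nodes <= 0] = 0.0
                nodes = np.where(nodes > 0, nodes, ds.q[:, None])
                self.nodes[key] = nodes.ravel()
                self.weights[key] = weights / weights.sum(axis=1, keepdims=True)

    @staticmethod
    def _kernel_pair(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Phi(x) and Phi'(x) from one sin/cos pass.

        Same series/closed-form switch as :func:`sphere_kernel`, so the
        fast path matches the reference route bit-for-bit; Phi'(x) =
        3[(x^2-3) sin x + 3x cos x]/x^4 with its own series.
        """
        x2 = x * x
        sx, cx = np.sin(x), np.cos(x)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi_full = 3.0 * (sx - x * cx) / (x2 * x)
            dphi_full = 3.0 * ((x2 - 3.0) * sx + 3.0 * x * cx) / (x2 * x2)
        small = x < 0.02
        phi = np.where(
            small, 1.0 - x2 / 10.0 + x2 * x2 / 280.0 - x2 * x2 * x2 / 15120.0,
            phi_full,
        )
        dphi = np.where(
            small, -x / 5.0 + x2 * x / 70.0 - x2 * x2 * x / 2520.0, dphi_full
        )
        return phi, dphi

    def _quadrature(self, mu: float, pd: float):
        """Radius nodes/weights plus their parameter derivatives.

        Matches :func:`formfactor._radius_quadrature` exactly; returns
        (r, w, dr_dmu, dr_dpd, dw_dpd).  Node positions scale linearly
        with mu, so dr/dmu = r/mu and the weights are mu-independent;
        only a truncated (pd > 1/3) distribution makes the weights depend
        on pd.
        """
        from .formfactor import _LEGGAUSS_CACHE, _radius_quadrature

        n = self.problem.quadrature_points
        r, w = _radius_quadrature(mu, pd, n)
        lx, _ = _LEGGAUSS_CACHE[n]
        sigma = pd * mu
        clamped = mu - 3.0 * sigma < 0
        dr_dmu = r / mu
        if not clamped:
            dr_dpd = 3.0 * mu * lx
            dw_dpd = np.zeros_like(w)
        else:
            dr_dpd = 1.5 * mu * (lx + 1.0)
            u = (r - mu) / sigma
            du_dpd = dr_dpd / sigma - u / pd
            raw = -w * u * du_dpd  # d(unnormalised)/dpd over normalisation
            dw_dpd = raw - w * raw.sum()
        return r, w, dr_dmu, dr_dpd, dw_dpd

    def evaluate(self, shared: dict, per: list[dict], want_jac: bool = False):
        """Model curves for every dataset, optionally with the Jacobian.

        The Jacobian is analytic: Phi' reuses the sin/cos of the function
        evaluation, node positions are affine in (core_radius, pd), and
        the per-contrast intensity is a quadratic form in the contrast
        coefficients.  Validated against finite differences (tested).
        """
        problem = self.problem
        mu = shared["core_radius"]
        t = shared["shell_thickness"]
        pd = shared["polydispersity"]
        h = shared["hydration"]
        phi_vol = shared["volume_fraction"]
        if pd > 0:
            r, w, dr_dmu, dr_dpd, dw_dpd = self._quadrature(mu, pd)
        else:
            r, w = np.array([mu]), np.array([1.0])
            dr_dmu, dr_dpd = np.array([1.0]), np.array([0.0])
            dw_dpd = np.array([0.0])
        rt = r + t
        v_c = 4.0 * np.pi / 3.0 * r**3
        v_t = 4.0 * np.pi / 3.0 * rt**3
        s_c = 4.0 * np.pi * r**2   # dVc/dr
        s_t = 4.0 * np.pi * rt**2  # dVt/dRt
        mean_v = float(v_t @ w)
        # mean_v derivatives: d<V>/dmu, /dt, /dpd
        dmv = {
            "core_radius": float((s_t * dr_dmu) @ w),
            "shell_thickness": float(s_t @ w),
            "polydispersity": float((s_t * dr_dpd) @ w + v_t @ dw_dpd),
        }

        structural = ("core_radius", "shell_thickness", "polydispersity")
        moments: dict[bytes, dict] = {}
        for key, q_nodes in self.nodes.items():
            q = q_nodes[:, None]
            phi_t, dphi_t = self._kernel_pair(q * rt[None, :])
            phi_c, dphi_c = self._kernel_pair(q * r[None, :])
            a = v_t * phi_t
            b = v_c * phi_c
            entry = {
                "tt": (a * a) @ w, "tc": (a * b) @ w, "cc": (b * b) @ w,
            }
            if want_jac:
                # dA/dRt and dB/dr (per element)
                da_drt = s_t * phi_t + v_t * q * dphi_t
                db_dr = s_c * phi_c + v_c * q * dphi_c
                for name, drt, dr_ in (
                    ("core_radius", dr_dmu, dr_dmu),
                    ("shell_thickness", np.ones_like(r), np.zeros_like(r)),
                    ("polydispersity", dr_dpd, dr_dpd),
                ):
                    da = da_drt * drt
                    db = db_dr * dr_
                    d_tt = (2.0 * a * da) @ w
                    d_tc = (da * b + a * db) @ w
                    d_cc = (2.0 * b * db) @ w
                    if name == "polydispersity" and dw_dpd.any():
                        d_tt = d_tt + (a * a) @ dw_dpd
                        d_tc = d_tc + (a * b) @ dw_dpd
                        d_cc = d_cc + (b * b) @ dw_dpd
                    entry["d_" + name] = (d_tt, d_tc, d_cc)
            moments[key] = entry

        names = problem.param_names
        n_points = sum(len(ds) for ds in problem.datasets)
        jac = np.zeros((n_points, len(names))) if want_jac else None
        curves = []
        row = 0
        col_of = {name: k for k, name in enumerate(names)}
        k_conv = 1e-4
        for j, (ds, p) in enumerate(zip(problem.datasets, per)):
            key = self.ds_group[j]
            m = moments[key]
            rho_sh = _shell_sld(problem, ds, h)
            c1 = rho_sh - ds.sld_solvent
            c2 = ds.sld_core - rho_sh
            f2 = c1 * c1 * m["tt"] + 2.0 * c1 * c2 * m["tc"] + c2 * c2 * m["cc"]
            pref = k_conv * phi_vol / mean_v
            i_pre = pref * f2
            weights = self.weights[key]

            def fold(v):
                if weights is None:
                    return v
                return (v.reshape(weights.shape) * weights).sum(axis=1)

            base = fold(i_pre)
            scale = p.get("scale", 1.0)
            curves.append(scale * base + p.get("background", 0.0))
            if not want_jac:
                continue
            rows = slice(row, row + len(ds))
            for name in structural:
                if name not in col_of:
                    continue
                d_tt, d_tc, d_cc = m["d_" + name]
                df2 = (c1 * c1 * d_tt + 2.0 * c1 * c2 * d_tc
                       + c2 * c2 * d_cc)
                d_pre = pref * df2 - i_pre * (dmv[name] / mean_v)
                jac[rows, col_of[name]] = scale * fold(d_pre)
            if "hydration" in col_of:
                e_d = ds.sld_solvent - problem.dry_shell_sld
                df2 = 2.0 * e_d * (c1 * (m["tt"] - m["tc"])
                                   + c2 * (m["tc"] - m["cc"]))
                jac[rows, col_of["hydration"]] = scale * fold(pref * df2)
            if "volume_fraction" in col_of:
                jac[rows, col_of["volume_fraction"]] = scale * base / phi_vol
            if f"background_{j}" in col_of:
                jac[rows, col_of[f"background_{j}"]] = 1.0
            if f"scale_{j}" in col_of:
                jac[rows, col_of[f"scale_{j}"]] = base
            row += len(ds)
        return curves, jac

    def curves(self, shared: dict, per: list[dict]) -> list[np.ndarray]:
        return self.evaluate(shared, per, want_jac=False)[0]


def _unpack(problem: FitProblem, x: np.ndarray) -> tuple[dict, list[dict]]:
    shared = dict(problem.fixed)
    n_s = len(problem.shared_free)
    shared.update(zip(problem.shared_free, x[:n_s]))
    per = []
    k = n_s
    for _ in problem.datasets:
        d = {}
        for name in problem.per_dataset_free:
            d[name] = x[k]
            k += 1
        per.append(d)
    return shared, per


def _residuals(problem: FitProblem, x: np.ndarray,
               cache: Optional[_ModelCache] = None) -> np.ndarray:
    shared, per = _unpack(problem, x)
    if cache is not None:
        curves = cache.curves(shared, per)
    else:
        curves = [
            _model_curve(problem, ds, shared, p)
            for ds, p in zip(problem.datasets, per)
        ]
    return np.concatenate(
        [(c - ds.i) / ds.sigma_i for c, ds in zip(curves, problem.datasets)]
    )


class _Objective:
    """Memoising residual/Jacobian pair for the optimiser.

    The analytic Jacobian shares the transcendental work with the function
    evaluation, so both are produced in one pass and cached on x.
    """

    def __init__(self, problem: FitProblem, cache: _ModelCache) -> None:
        self.problem = problem
        self.cache = cache
        self.sigma = np.concatenate([ds.sigma_i for ds in problem.datasets])
        self.data = np.concatenate([ds.i for ds in problem.datasets])
        self._key: Optional[bytes] = None
        self._res: Optional[np.ndarray] = None
        self._jac: Optional[np.ndarray] = None

    def _compute(self, x: np.ndarray) -> None:
        key = x.tobytes()
        if key == self._key:
            return
        shared, per = _unpack(self.problem, x)
        curves, jac = self.cache.evaluate(shared, per, want_jac=True)
        model = np.concatenate(curves)
        self._res = (model - self.data) / self.sigma
        self._jac = jac / self.sigma[:, None]
        self._key = key

    def fun(self, x: np.ndarray) -> np.ndarray:
        self._compute(x)
        return self._res

    def jac(self, x: np.ndarray) -> np.ndarray:
        self._compute(x)
        return self._jac


def _start_bounds(problem: FitProblem) -> tuple[np.ndarray, np.ndarray]:
    """Finite box used for Latin-hypercube start sampling."""
    los, his = [], []
    max_i = max(float(np.max(ds.i)) for ds in problem.datasets)
    for name in problem.param_names:
        base = name.rsplit("_", 1)[0] if name[-1].isdigit() else name
        lo, hi = problem.get_bounds(base)
        if not np.isfinite(hi):
            hi = max_i if base == "background" else lo + 1.0
        los.append(lo)
        his.append(hi)
    return np.array(los), np.array(his)


def fit(problem: FitProblem, seed: int = 0, n_starts: int = 5,
        max_nfev: Optional[int] = None) -> FitResult:
    """Run the bounded multi-start least-squares fit.

    ``n_starts`` Latin-hypercube starting points are drawn inside the
    (finite-ised) bounds with the given seed; each start is refined coarsely
    and the best is polished to full tolerance, so the result is
    deterministic given the seed.  Ties break toward the lowest chi^2, then
    the smallest core radius.
    """
    names = problem.param_names
    lo = np.array([
        problem.get_bounds(n.rsplit("_", 1)[0] if n[-1].isdigit() else n)[0]
        for n in names
    ])
    hi = np.array([
        problem.get_bounds(n.rsplit("_", 1)[0] if n[-1].isdigit() else n)[1]
        for n in names
    ])
    s_lo, s_hi = _start_bounds(problem)
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    starts = s_lo + sampler.random(n_starts) * (s_hi - s_lo)
    cache = _ModelCache(problem)
    objective = _Objective(problem, cache)
    x_scale = np.where(np.isfinite(s_hi - s_lo), s_hi - s_lo, 1.0)

    trials = []
    for x0 in starts:
        r = least_squares(
            objective.fun, x0, jac=objective.jac, bounds=(lo, hi),
            method="trf", x_scale=x_scale, max_nfev=40, ftol=1e-6, xtol=1e-8,
        )
        trials.append(r)
    rc_idx = names.index("core_radius") if "core_radius" in names else 0
    trials.sort(key=lambda r: (r.cost, r.x[rc_idx]))
    best = least_squares(
        objective.fun, trials[0].x, jac=objective.jac, bounds=(lo, hi),
        method="trf", x_scale=x_scale,
        max_nfev=max_nfev if max_nfev is not None else 400,
        ftol=1e-10, xtol=1e-11,
    )
    # status 0 = iteration budget exhausted: report the best-so-far state
    # flagged unsuccessful rather than discarding it (near-degenerate
    # problems, e.g. fully contrast-matched data, crawl along flat valleys)

    n_points = sum(len(ds) for ds in problem.datasets)
    dof = max(n_points - len(names), 1)
    chi2_red = float(2.0 * best.cost / dof)

    jtj = best.jac.T @ best.jac
    cov = np.linalg.pinv(jtj) * chi2_red
    sigmas = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    shared, per = _unpack(problem, best.x)
    per_chi2 = []
    for ds, p in zip(problem.datasets, per):
        r = (_model_curve(problem, ds, shared, p) - ds.i) / ds.sigma_i
        per_chi2.append(float((r**2).sum() / max(len(ds) - 1, 1)))

    span = np.where(np.isfinite(hi - lo), hi - lo, 1.0)
    at_bounds = [
        n for n, x, l, h, s in zip(names, best.x, lo, hi, span)
        if min(x - l, h - x) < 1e-8 * s
    ]
    result = FitResult(
        estimates=dict(zip(names, map(float, best.x))),
        uncertainties=dict(zip(names, map(float, sigmas))),
        covariance=cov,
        param_names=names,
        chi2_reduced=chi2_red,
        per_dataset_chi2=per_chi2,
        n_points=n_points,
        at_bounds=at_bounds,
        success=bool(best.success),
    )
    result.derived = derived_quantities(result, problem)
    return result


def derived_quantities(result: FitResult, problem: FitProblem,
                       particle_density: float = 1.0) -> dict:
    """Quantities derived from a converged fit.

    Total radius (with covariance-aware error propagation), the per-contrast
    shell SLD implied by the hydration parameter, hydration as a
    percentage, and the fitted vs theoretical volume fraction (mass
    concentration over particle density, ``particle_density`` in g/mL).
    """
    names = result.param_names
    est = dict(problem.fixed)
    est.update(result.estimates)
    rc, t = est["core_radius"], est["shell_thickness"]
    total = rc + t
    var = 0.0
    if "core_radius" in names and "shell_thickness" in names:
        i, j = names.index("core_radius"), names.index("shell_thickness")
        var = result.covariance[i, i] + result.covariance[j, j] \
            + 2.0 * result.covariance[i, j]
    elif "core_radius" in names:
        var = result.uncertainties["core_radius"] ** 2
    elif "shell_thickness" in names:
        var = result.uncertainties["shell_thickness"] ** 2
    h = est["hydration"]
    shell_slds = {
        ds.contrast_label or f"dataset_{j}": _shell_sld(problem, ds, h)
        for j, ds in enumerate(problem.datasets)
    }
    concs = [ds.concentration_mg_ml for ds in problem.datasets
             if ds.concentration_mg_ml > 0]
    theoretical_phi = (
        float(np.mean(concs)) / 1000.0 / particle_density if concs else None
    )
    return {
        "total_radius": total,
        "total_radius_err": float(np.sqrt(max(var, 0.0))),
        "shell_sld_per_contrast": shell_slds,
        "hydration_pct": 100.0 * h,
        "effective_volume_fraction": est["volume_fraction"],
        "theoretical_volume_fraction": theoretical_phi,
    }


@dataclass
class BatteryReport:
    """Cross-scenario consistency report."""

    table: pd.DataFrame
    param_consistent: dict[str, bool]
    all_consistent: bool
    phi_linearity_r2: Optional[float]
    results: list[FitResult]


_STRUCTURAL = ("core_radius", "shell_thickness", "polydispersity", "hydration")


def scenario_battery(problems: Sequence[FitProblem], seed: int = 0,
                     n_starts: int = 5) -> BatteryReport:
    """Fit a family of scenarios and check structural stability.

    Scenarios are expected to differ only in external conditions
    (concentration, temperature, salt); the structural parameters are
    checked for pairwise agreement within joint 95% confidence intervals,
    and when concentrations differ the fitted volume fraction is regressed
    against concentration (linearity check).
    """
    if len(problems) < 2:
        raise ValueError("need at least two scenarios")
    free_sets = {p.shared_free for p in problems}
    if len(free_sets) != 1:
        raise ValueError("scenarios have incompatible free-parameter sets")
    results = [fit(p, seed=seed, n_starts=n_starts) for p in problems]

    rows = []
    for j, (p, r) in enumerate(zip(problems, results)):
        concs = [ds.concentration_mg_ml for ds in p.datasets]
        row = {"scenario": j, "concentration_mg_ml": float(np.mean(concs)),
               "chi2_reduced": r.chi2_reduced}
        for name in p.shared_free:
            row[name] = r.estimates[name]
            row[name + "_err"] = r.uncertainties[name]
        rows.append(row)
    table = pd.DataFrame(rows)

    consistent: dict[str, bool] = {}
    for name in _STRUCTURAL:
        if name not in problems[0].shared_free:
            continue
        ok = True
        for a in range(len(results)):
            for b in range(a + 1, len(results)):
                da = results[a].estimates[name] - results[b].estimates[name]
                s = np.hypot(results[a].uncertainties[name],
                             results[b].uncertainties[name])
                if s > 0 and abs(da) > 1.96 * s:
                    ok = False
        consistent[name] = ok

    r2 = None
    concs = table["concentration_mg_ml"].to_numpy()
    if "volume_fraction" in table.columns and len(np.unique(concs)) > 2:
        phi = table["volume_fraction"].to_numpy()
        coeff = np.polyfit(concs, phi, 1)
        pred = np.polyval(coeff, concs)
        ss_res = float(((phi - pred) ** 2).sum())
        ss_tot = float(((phi - phi.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    return BatteryReport(
        table=table,
        param_consistent=consistent,
        all_consistent=all(consistent.values()),
        phi_linearity_r2=r2,
        results=results,
    )
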