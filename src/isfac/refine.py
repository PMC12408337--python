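"""Full-matrix weighted least-squares refinement against intensities.

The parameter vector holds one overall scale followed by, per site, the free
fractional coordinates, displacement parameters and the ionic fraction nu.
Iterations are damped Gauss-Newton (Levenberg-Marquardt) on the normal
equations built from analytic derivatives; restraints (total-charge SUMP row,
optional distance restraints) enter as extra weighted residual rows.
Estimated standard uncertainties come from the inverse normal matrix scaled
by the goodness of fit, and convergence is declared on max |shift/esd|.

Between refinement rounds two protocols mirror established practice for
ionic-fraction refinement: a site whose fraction refines negative has its ion
replaced by the opposite sign (an anion modelled where a cation belongs shows
up as nu < 0), and a site whose fraction keeps crossing zero at small
magnitude is fixed neutral.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .crystal import CrystalModel, ReflectionData
from .scattering import ScatteringLibrary
from .structure_factors import SFCalculator


class EmptyDataError(ValueError):
    pass


class SingularMatrixError(np.linalg.LinAlgError):
    def __init__(self, message: str, null_parameters: list[str]):
        super().__init__(message)
        self.null_parameters = null_parameters


@dataclass
class SumpRestraint:
    """Soft linear restraint on the total charge: sum_j c_j nu_j = target,
    weighted by 1/sigma.  Default coefficients are dZ * occupancy per free
    site, so the restrained combination is the charge of the asymmetric
    unit's cell content (occupancy counts special positions correctly); for
    full-occupancy sites this reduces to the familiar signed-unit syntax."""

    target: float = 0.0
    sigma: float = 0.001
    coefficients: dict[str, float] | None = None

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("restraint sigma must be positive")

    def coefficient(self, site) -> float:
        if self.coefficients is not None:
            if site.label not in self.coefficients:
                raise ValueError(f"SUMP restraint misses site {site.label!r}")
            return self.coefficients[site.label]
        return float(site.ion.dZ) * site.occupancy


@dataclass
class DistanceRestraint:
    label_a: str
    label_b: str
    target: float
    sigma: float = 0.02

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("restraint sigma must be positive")


@dataclass
class RefinementConfig:
    max_cycles: int = 200
    shift_esd_tol: float = 0.01
    sump: SumpRestraint | None = None
    distance_restraints: list[DistanceRestraint] = field(default_factory=list)
    d_min: float | None = None
    d_max: float | None = None
    free_hydrogens: bool = True
    refine_adp: bool = True
    weighting: str = "sigma"  # w = 1/sigma^2(I); "shelx" adds a two-par term
    weight_a: float = 0.0
    weight_b: float = 0.0

    def __post_init__(self):
        if self.shift_esd_tol <= 0:
            raise ValueError("convergence threshold must be positive")

    def weights(self, data: ReflectionData) -> np.ndarray:
        if self.weighting == "sigma":
            return 1.0 / data.sigma**2
        if self.weighting == "shelx":
            p = np.maximum(data.i_obs, 0.0)
            return 1.0 / (data.sigma**2 + (self.weight_a * p) ** 2 + self.weight_b * p)
        raise ValueError(f"unknown weighting scheme {self.weighting!r}")


@dataclass(frozen=True)
class ParamRef:
    kind: str          # "scale" | "x" | "adp" | "nu"
    label: str = ""
    component: int = 0

    @property
    def name(self) -> str:
        if self.kind == "scale":
            return "scale"
        if self.kind == "x":
            return f"{self.label}.{'xyz'[self.component]}"
        if self.kind == "adp":
            return f"{self.label}.U{self.component}"
        return f"{self.label}.nu"


def assemble_parameters(model: CrystalModel, config: RefinementConfig,
                        scale: float = 1.0) -> tuple[np.ndarray, list[ParamRef]]:
    """Initial parameter vector and its site mapping."""
    if not model.sites:
        raise ValueError("model has no atom sites")
    from .crystal import free_coordinate_mask
    refs: list[ParamRef] = [ParamRef("scale")]
    values: list[float] = [scale]
    for site in model.sites:
        riding = site.is_hydrogen and not config.free_hydrogens
        if not site.coordinates_fixed and not riding:
            mask = free_coordinate_mask(model, site)
            for m in range(3):
                if not mask[m]:
                    continue  # pinned by the site symmetry
                refs.append(ParamRef("x", site.label, m))
                values.append(site.xyz[m])
        if config.refine_adp and not site.adp_fixed and not riding:
            if site.is_isotropic:
                refs.append(ParamRef("adp", site.label, 0))
                values.append(float(site.adp))
            else:
                for m in range(6):
                    refs.append(ParamRef("adp", site.label, m))
                    values.append(site.adp[m])
        if not site.nu_fixed:
            refs.append(ParamRef("nu", site.label))
            values.append(site.nu)
    return np.array(values, dtype=float), refs


def apply_parameters(model: CrystalModel, refs: list[ParamRef],
                     values: np.ndarray) -> float:
    """Write a parameter vector back into the model; returns the scale."""
    scale = 1.0
    for ref, v in zip(refs, values):
        if ref.kind == "scale":
            scale = float(v)
            continue
        site = model.site(ref.label)
        if ref.kind == "x":
            xyz = list(site.xyz)
            xyz[ref.component] = float(v)
            site.xyz = tuple(xyz)
        elif ref.kind == "adp":
            if site.is_isotropic:
                site.adp = float(v)
            else:
                adp = list(site.adp)
                adp[ref.component] = float(v)
                site.adp = tuple(adp)
        elif ref.kind == "nu":
            site.nu = float(v)
    return scale


def _free_site_labels(refs: list[ParamRef]) -> dict[str, set[str]]:
    want: dict[str, set[str]] = {}
    for ref in refs:
        if ref.kind == "scale":
            continue
        want.setdefault(ref.label, set()).add(
            {"x": "xyz", "adp": "adp", "nu": "nu"}[ref.kind])
    return want


def residuals_jacobian(model: CrystalModel, data: ReflectionData,
                       config: RefinementConfig, refs: list[ParamRef],
                       values: np.ndarray, library: ScatteringLibrary):
    """Weighted residual vector and analytic Jacobian.

    Data rows are sqrt(w) * (I_obs - I_calc); restraint rows follow, scaled
    by 1/sigma.  Returns (r, J, n_data).
    """
    cut = data.resolution_cut(model.cell, config.d_min, config.d_max)
    if len(cut) == 0:
        raise EmptyDataError("no reflections remain inside the resolution cuts")
    apply_parameters(model, refs, values)
    calc = SFCalculator(model, library, cut.hkl)
    return _residuals_jacobian_with_calc(model, cut, config, refs, values, calc)


def _sump_row(model, sump: SumpRestraint, refs, values):
    total = 0.0
    row = np.zeros((1, len(values)))
    for k, ref in enumerate(refs):
        if ref.kind != "nu":
            continue
        site = model.site(ref.label)
        c = sump.coefficient(site)
        total += c * values[k]
        row[0, k] = c / sump.sigma
    return np.array([(total - sump.target) / sump.sigma]), row


def _distance_row(model, restraint: DistanceRestraint, refs):
    a = model.site(restraint.label_a)
    b = model.site(restraint.label_b)
    orth = model.cell.orthogonalization
    delta = (np.asarray(a.xyz) - np.asarray(b.xyz) + 0.5) % 1.0 - 0.5
    cart = orth @ delta
    dist = float(np.linalg.norm(cart))
    row = np.zeros((1, len(refs)))
    if dist > 1e-9:
        grad_frac = (orth.T @ cart) / dist  # d(dist)/d(frac delta)
        for k, ref in enumerate(refs):
            if ref.kind != "x":
                continue
            if ref.label == a.label:
                row[0, k] = grad_frac[ref.component] / restraint.sigma
            elif ref.label == b.label:
                row[0, k] = -grad_frac[ref.component] / restraint.sigma
    return np.array([(dist - restraint.target) / restraint.sigma]), row


@dataclass
class RefinementResult:
    values: np.ndarray
    refs: list[ParamRef]
    esd: np.ndarray
    covariance: np.ndarray
    scale: float
    r1: float
    wr2: float
    goof: float | None
    converged: bool
    n_data: int
    n_params: int
    cycle_log: list[dict] = field(default_factory=list)
    nu_history: dict[str, list[float]] = field(default_factory=dict)
    flipped_sites: list[str] = field(default_factory=list)
    fixed_neutral_sites: list[str] = field(default_factory=list)

    def index_of(self, kind: str, label: str = "", component: int = 0) -> int:
        for k, ref in enumerate(self.refs):
            if ref.kind == kind and ref.label == label and ref.component == component:
                return k
        raise KeyError(f"no refined parameter {kind}/{label}/{component}")

    def nu(self, label: str) -> float:
        return float(self.values[self.index_of("nu", label)])

    def nu_esd(self, label: str) -> float:
        return float(self.esd[self.index_of("nu", label)])

    def nu_covariance(self, labels: list[str]) -> np.ndarray:
        idx = [self.index_of("nu", lb) for lb in labels]
        return self.covariance[np.ix_(idx, idx)]

    @property
    def param_names(self) -> list[str]:
        return [ref.name for ref in self.refs]


def optimal_scale(i_obs: np.ndarray, f_abs2: np.ndarray, w: np.ndarray) -> float:
    """Linear least-squares scale for I_obs ~ scale * |F|^2."""
    denom = float(np.sum(w * f_abs2**2))
    if denom <= 0:
        return 1.0
    return float(np.sum(w * i_obs * f_abs2) / denom)


def refine(model: CrystalModel, data: ReflectionData,
           config: RefinementConfig, library: ScatteringLibrary,
           scale: float | None = None) -> RefinementResult:
    """Damped Gauss-Newton refinement of scale, coordinates, ADPs and ionic
    fractions; mutates ``model`` to the refined values."""
    cut = data.resolution_cut(model.cell, config.d_min, config.d_max)
    if len(cut) == 0:
        raise EmptyDataError("no reflections remain inside the resolution cuts")
    calc = SFCalculator(model, library, cut.hkl)
    if scale is None:
        F0 = calc.f()
        scale = optimal_scale(cut.i_obs, np.abs(F0) ** 2, config.weights(cut))
    values, refs = assemble_parameters(model, config, scale)
    if len(cut) <= len(values):
        warnings.warn(
            f"only {len(cut)} reflections for {len(values)} parameters")

    def rj(v):
        return _residuals_jacobian_with_calc(model, cut, config, refs, v, calc)

    r, J, n_data = rj(values)
    cost = float(r @ r)
    lam = 0.0
    cycle_log = []
    nu_history = {ref.label: [] for ref in refs if ref.kind == "nu"}
    converged = False
    N = J.T @ J
    diag = np.diag(N)
    dead = diag < 1e-14 * max(float(diag.max()), 1e-300)
    if np.any(dead):
        names = [refs[i].name for i in np.nonzero(dead)[0]]
        raise SingularMatrixError(
            f"normal matrix singular; data carry no information on: "
            f"{', '.join(names)}", names)
    for cycle in range(config.max_cycles):
        g = J.T @ r
        step = None
        for _ in range(30):
            try:
                damped = N + lam * np.diag(np.maximum(np.diag(N), 1e-12))
                step = -np.linalg.solve(damped, g)
            except np.linalg.LinAlgError:
                step = None
            if step is not None:
                trial = values + step
                r_try, J_try, _ = rj(trial)
                cost_try = float(r_try @ r_try)
                if cost_try <= cost * (1 + 1e-14):
                    break
            lam = 1e-4 if lam == 0.0 else lam * 10.0
            if lam > 1e10:
                break
        else:
            break
        if step is None or float(r_try @ r_try) > cost * (1 + 1e-14):
            break  # no acceptable step found
        values, r, J = trial, r_try, J_try
        new_cost = float(r_try @ r_try)
        N = J.T @ J
        esd = _esd_from_normal(N, r, n_data, len(values))[0]
        shift_esd = np.max(np.abs(step) / np.maximum(esd, 1e-14))
        cycle_log.append({"cycle": cycle, "cost": new_cost,
                          "max_shift_esd": float(shift_esd), "lambda": lam})
        for k, ref in enumerate(refs):
            if ref.kind == "nu":
                nu_history[ref.label].append(float(values[k]))
        cost = new_cost
        # convergence only counts for a near-undamped step: heavy damping
        # shrinks shifts without reaching a stationary point
        if shift_esd < config.shift_esd_tol and lam <= 1e-3:
            converged = True
            break
        lam = lam / 10.0 if lam > 1e-12 else 0.0
    esd, cov, goof = _esd_from_normal(N, r, n_data, len(values), full=True)
    scale = apply_parameters(model, refs, values)
    r1, wr2, _ = r_factors(model, cut, config, library, scale, calc=calc)
    return RefinementResult(
        values=values, refs=refs, esd=esd, covariance=cov, scale=scale,
        r1=r1, wr2=wr2, goof=goof, converged=converged,
        n_data=n_data, n_params=len(values), cycle_log=cycle_log,
        nu_history=nu_history,
    )


def _residuals_jacobian_with_calc(model, cut, config, refs, values, calc):
    scale = apply_parameters(model, refs, values)
    want = _free_site_labels(refs)
    F, derivs = calc.f_and_derivs(want)
    i_calc = scale * np.abs(F) ** 2
    w = config.weights(cut)
    sw = np.sqrt(w)
    r = sw * (cut.i_obs - i_calc)
    J = np.zeros((len(cut), len(values)))
    for k, ref in enumerate(refs):
        if ref.kind == "scale":
            dI = np.abs(F) ** 2
        else:
            d = derivs[ref.label]
            if ref.kind == "nu":
                dF = d["nu"]
            elif ref.kind == "x":
                dF = d["xyz"][:, ref.component]
            else:
                dF = d["adp"] if np.ndim(d["adp"]) == 1 else d["adp"][:, ref.component]
            dI = 2.0 * scale * np.real(np.conj(F) * dF)
        J[:, k] = -sw * dI
    rows_r, rows_J = [r], [J]
    if config.sump is not None:
        rr, JJ = _sump_row(model, config.sump, refs, values)
        rows_r.append(rr)
        rows_J.append(JJ)
    for restraint in config.distance_restraints:
        rr, JJ = _distance_row(model, restraint, refs)
        rows_r.append(rr)
        rows_J.append(JJ)
    return np.concatenate(rows_r), np.vstack(rows_J), len(cut)


def _esd_from_normal(N, r, n_data, n_par, full=False):
    dof = n_data - n_par
    goof = float(np.sqrt(np.sum(r[:n_data] ** 2) / dof)) if dof > 0 else None
    try:
        cov = np.linalg.inv(N)
    except np.linalg.LinAlgError:
        eigval, eigvec = np.linalg.eigh(N)
        null = [int(np.argmax(np.abs(eigvec[:, i])))
                for i in range(len(eigval)) if eigval[i] < 1e-12 * eigval[-1]]
        raise SingularMatrixError(
            "singular normal matrix", [f"param[{i}]" for i in null])
    if goof is not None:
        cov = cov * goof**2
    esd = np.sqrt(np.maximum(np.diag(cov), 0.0))
    if full:
        return esd, cov, goof
    return esd, None, goof


def r_factors(model: CrystalModel, data: ReflectionData,
              config: RefinementConfig, library: ScatteringLibrary,
              scale: float, calc: SFCalculator | None = None):
    """R1 (on |F|), wR2 (on I), goodness of fit."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    if calc is None:
        calc = SFCalculator(model, library, data.hkl)
    F = calc.f()
    i_calc = scale * np.abs(F) ** 2
    f_obs = np.sqrt(np.maximum(data.i_obs, 0.0) / scale)
    f_cal = np.abs(F)
    r1 = float(np.sum(np.abs(f_obs - f_cal)) / max(np.sum(f_obs), 1e-300))
    w = config.weights(data)
    wr2 = float(np.sqrt(np.sum(w * (data.i_obs - i_calc) ** 2) /
                        max(np.sum(w * data.i_obs**2), 1e-300)))
    # GooF needs the refined parameter count; callers with a result use its dof
    return r1, wr2, None


# -- protocols ---------------------------------------------------------------

def apply_sign_flip(model: CrystalModel, result: RefinementResult,
                    tol: float = 0.01) -> list[str]:
    """Negate the charge offset of every non-H site whose refined fraction is
    negative beyond ``tol`` and reset nu to |nu|.  Returns flipped labels;
    caller re-refines.  Hydrogens are never flipped (the proton curve is the
    only hydrogen species used)."""
    flipped = []
    for site in model.sites:
        if site.is_hydrogen or site.nu_fixed or site.ion.dZ == 0:
            continue
        try:
            nu = result.nu(site.label)
        except KeyError:
            continue
        if nu < -tol:
            site.ion = site.ion.__class__(site.ion.element, site.ion.Z0,
                                          -site.ion.dZ)
            site.nu = abs(nu)
            flipped.append(site.label)
    return flipped


def fix_fluctuating_neutral(model: CrystalModel,
                            history: dict[str, list[float]],
                            threshold: float = 0.05) -> list[str]:
    """Fix sites whose fraction changes sign across cycles while staying small
    in magnitude: they are effectively neutral and their parameter is removed."""
    fixed = []
    for label, values in history.items():
        if len(values) < 2:
            continue
        signs = np.sign([v for v in values if v != 0.0])
        if len(signs) >= 2 and np.any(np.diff(signs) != 0) \
                and max(abs(v) for v in values) < threshold:
            site = model.site(label)
            site.nu = 0.0
            site.nu_fixed = True
            fixed.append(label)
    return fixed


def refine_with_protocols(model: CrystalModel, data: ReflectionData,
                          config: RefinementConfig, library: ScatteringLibrary,
                          max_rounds: int = 6,
                          neutral_threshold: float = 0.05) -> RefinementResult:
    """Refine, then alternate sign flips / neutral fixing with re-refinement
    until the ion assignment is stable."""
    round_nu: dict[str, list[float]] = {}
    all_flipped: list[str] = []
    all_fixed: list[str] = []
    result = None
    adp_retries = 0
    for _ in range(max_rounds):
        result = refine(model, data, config, library)
        # a refinement that drove a displacement parameter negative sits in an
        # unphysical false minimum (the ADP mimics the ionic 1/s^2 falloff):
        # reject it, restore sane ADPs and push the fractions outward
        bad_adp = _reset_negative_adps(model)
        if bad_adp and adp_retries < 3:
            adp_retries += 1
            kick = 0.2 * 2 ** (adp_retries - 1)
            for site in model.sites:
                if not site.nu_fixed and abs(site.nu) < kick:
                    site.nu = kick if site.nu >= 0 else -kick
            continue
        for site in model.sites:
            if not site.nu_fixed:
                round_nu.setdefault(site.label, []).append(site.nu)
        flipped = apply_sign_flip(model, result)
        # a site that keeps getting flipped while small is effectively neutral
        oscillating = {lb: vals for lb, vals in round_nu.items()
                       if lb in flipped and len(vals) >= 2}
        fixed = fix_fluctuating_neutral(model, oscillating, neutral_threshold)
        if not flipped and not fixed:
            break
        all_flipped.extend(flipped)
        all_fixed.extend(fixed)
    else:
        result = refine(model, data, config, library)
    result.flipped_sites = list(dict.fromkeys(all_flipped))
    result.fixed_neutral_sites = list(dict.fromkeys(all_fixed))
    return result


def _reset_negative_adps(model: CrystalModel, floor: float = 0.02) -> list[str]:
    """Replace negative U_iso (or negative anisotropic diagonal) with a sane
    positive value; returns affected labels."""
    bad = []
    for site in model.sites:
        if site.is_isotropic:
            if float(site.adp) < 0:
                site.adp = floor
                bad.append(site.label)
        else:
            if min(site.adp[0], site.adp[1], site.adp[2]) < 0:
                site.adp = (floor, floor, floor, 0.0, 0.0, 0.0)
                bad.append(site.label)
    return bad


# -- stability diagnostics ---------------------------------------------------

@dataclass
class RCompleteReport:
    hkl: np.ndarray
    cv_residuals: np.ndarray      # | |Fo| - |Fc^(omit)| | per omitted reflection
    r_complete: float
    dq_per_omission: dict[str, np.ndarray]
    dq_stats: dict[str, dict[str, float]]


def r_complete(model: CrystalModel, data: ReflectionData,
               config: RefinementConfig, library: ScatteringLibrary,
               baseline: RefinementResult | None = None,
               max_cycles: int = 8) -> RCompleteReport:
    """Leave-one-out cross-validation: each reflection in turn is omitted,
    the model re-refined from the baseline, and the omitted reflection's
    cross-validated |F| residual plus every atom's partial charge recorded."""
    work = model.copy()
    if baseline is None:
        baseline = refine(work, data, config, library)
    if not baseline.converged:
        raise RuntimeError("baseline refinement did not converge; "
                           "leave-one-out statistics would be meaningless")
    cut = data.resolution_cut(model.cell, config.d_min, config.d_max)
    n = len(cut)
    free_nu = [s.label for s in model.sites if not s.nu_fixed]
    dq = {lb: np.zeros(n) for lb in free_nu}
    cv = np.zeros(n)
    sub_config = RefinementConfig(**{**config.__dict__,
                                     "max_cycles": max_cycles})
    sub_config.distance_restraints = list(config.distance_restraints)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        sub = cut.select(mask)
        work_i = model.copy()
        apply_parameters(work_i, baseline.refs, baseline.values)
        res_i = refine(work_i, sub, sub_config, library, scale=baseline.scale)
        calc = SFCalculator(work_i, library, cut.hkl[i:i + 1])
        f_omit = float(np.abs(calc.f())[0])
        f_obs = float(np.sqrt(max(cut.i_obs[i], 0.0) / res_i.scale))
        cv[i] = abs(f_obs - f_omit)
        for lb in free_nu:
            site = work_i.site(lb)
            dq[lb][i] = res_i.nu(lb) * site.ion.dZ
    f_obs_all = np.sqrt(np.maximum(cut.i_obs, 0.0) / baseline.scale)
    stats = {}
    for lb, v in dq.items():
        site = model.site(lb)
        stats[lb] = {
            "mean": float(np.mean(v)), "std": float(np.std(v, ddof=1)),
            "min": float(np.min(v)), "max": float(np.max(v)),
            # baseline standard uncertainty of the charge: the scale on
            # which omission-induced shifts should be judged
            "esu": float(baseline.nu_esd(lb) * abs(site.ion.dZ)),
        }
    return RCompleteReport(
        hkl=cut.hkl, cv_residuals=cv,
        r_complete=float(np.sum(cv) / max(np.sum(f_obs_all), 1e-300)),
        dq_per_omission=dq, dq_stats=stats,
    )


def resolution_scan(model: CrystalModel, data: ReflectionData,
                    config: RefinementConfig, library: ScatteringLibrary,
                    cuts: list[float]) -> list[dict]:
    """Refinement repeated per d_min cut; per-atom charge and esu per row."""
    rows = []
    for d_cut in cuts:
        cfg = RefinementConfig(**{**config.__dict__, "d_min": d_cut})
        cfg.distance_restraints = list(config.distance_restraints)
        work = model.copy()
        cut = data.resolution_cut(work.cell, cfg.d_min, cfg.d_max)
        row = {"d_min": d_cut, "n_reflections": len(cut)}
        try:
            values, refs = assemble_parameters(work, cfg)
            if len(cut) <= len(values):
                row["flag"] = "fewer reflections than parameters"
            res = refine(work, cut, cfg, library)
            row["converged"] = res.converged
            row["charges"] = {
                s.label: (res.nu(s.label) * s.ion.dZ,
                          res.nu_esd(s.label) * abs(s.ion.dZ))
                for s in work.sites if not s.nu_fixed
            }
        except (EmptyDataError, SingularMatrixError) as exc:
            row["flag"] = str(exc)
        rows.append(row)
    return rows
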