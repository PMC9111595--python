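"""Bivariate A/C/D/E variance decomposition over family blocks.

The phenotype at the two occasions is modelled per family as a single
multivariate-normal vector.  Stacking members person-major with the two
occasions innermost, the family covariance is

    Sigma_f = sum_k  R_k (x) Gamma_k        (Kronecker product)

where k runs over the included components, R_A is the additive
relatedness (2*Phi, MZ co-twins 1), R_C the 0/1 household indicator
(spouse pairs share a household; every individual has unit diagonal),
R_D the dominance/fraternity matrix and R_E the identity, and Gamma_k is
the component's symmetric 2x2 cross-occasion block.  E is purely
within-person and absorbs measurement error.  Missing cells (a person
observed at only one occasion) are deleted from the family block, never
the whole family.

Each Gamma_k is parameterized by the log-Cholesky factor of its 2x2
block, which keeps every component positive semidefinite without
constrained optimization; two grand means (one per occasion) are
estimated jointly.  Age and sex are regressed out per occasion before
fitting.  Nested models (AE, ACE, ADE inside ACDE) are compared with the
-2 log-likelihood chi-square test; boundary components make this test
conservative.

Standardized results divide each component's variance by the occasion's
total, and the component cross-time correlation is
cov_k / sqrt(v_pre,k * v_pan,k).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from qolped.pedigree import Pedigree, RelatednessSet, relatedness_matrices

COMPONENT_ORDER = ["A", "C", "D", "E"]


class VarCompError(RuntimeError):
    pass


@dataclass
class ComponentMatrix:
    """One component's 2x2 cross-occasion covariance block."""

    component: str
    v_pre: float
    v_pan: float
    cov: float
    se_v_pre: float | None = None
    se_v_pan: float | None = None
    se_cov: float | None = None

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.v_pre, self.cov], [self.cov, self.v_pan]])

    def is_psd(self, tol: float = 1e-10) -> bool:
        return (
            self.v_pre >= -tol
            and self.v_pan >= -tol
            and self.cov**2 <= self.v_pre * self.v_pan + tol
        )

    def cross_correlation(self) -> float:
        """cov / sqrt(v_pre * v_pan); NaN when either variance is zero."""
        denom = self.v_pre * self.v_pan
        if denom <= 0:
            return float("nan")
        return self.cov / float(np.sqrt(denom))


@dataclass(frozen=True)
class ModelSpec:
    """A subset of {A, C, D, E} components; E is always included."""

    components: tuple[str, ...]

    def __post_init__(self):
        comps = tuple(c for c in COMPONENT_ORDER if c in self.components)
        if "E" not in comps:
            raise ValueError("every model must include the E component")
        unknown = set(self.components) - set(COMPONENT_ORDER)
        if unknown:
            raise ValueError(f"unknown components: {sorted(unknown)}")
        object.__setattr__(self, "components", comps)

    @classmethod
    def from_label(cls, label: str) -> "ModelSpec":
        return cls(tuple(label.upper()))

    @property
    def label(self) -> str:
        return "".join(self.components)

    @property
    def n_params(self) -> int:
        # 3 per 2x2 block + 2 means
        return 3 * len(self.components) + 2

    def is_nested_in(self, other: "ModelSpec") -> bool:
        return set(self.components) <= set(other.components)


@dataclass
class FitResult:
    spec: ModelSpec
    estimates: dict[str, ComponentMatrix]
    means: tuple[float, float]
    loglik: float
    n_params: int
    n_families: int
    n_observations: int
    converged: bool
    boundary_components: list[str] = field(default_factory=list)
    standardized: dict | None = None
    total_var: tuple[float, float] | None = None
    total_cov: float | None = None
    component_corr: dict | None = None
    covariance_shares: dict | None = None

    def to_dict(self) -> dict:
        d = {
            "model": self.spec.label,
            "loglik": self.loglik,
            "n_params": self.n_params,
            "n_families": self.n_families,
            "n_observations": self.n_observations,
            "converged": self.converged,
            "boundary_components": self.boundary_components,
            "means": list(self.means),
            "estimates": {
                k: {
                    "v_pre": cm.v_pre, "v_pan": cm.v_pan, "cov": cm.cov,
                    "se_v_pre": cm.se_v_pre, "se_v_pan": cm.se_v_pan,
                    "se_cov": cm.se_cov,
                }
                for k, cm in self.estimates.items()
            },
        }
        if self.standardized is not None:
            d.update(
                standardized=self.standardized,
                total_var=list(self.total_var),
                total_cov=self.total_cov,
                component_corr=self.component_corr,
                covariance_shares=self.covariance_shares,
            )
        return d


# ---------------------------------------------------------------------------
# residualization

def residualize(values, age, sex):
    """OLS residuals of one occasion's phenotype on intercept + age + sex.

    ``sex`` is a sequence of 'M'/'F' labels (or a 0/1 indicator).
    Missing phenotypes stay missing; rows with missing age are centered
    on the mean age.  A constant age or sex column is dropped from the
    design with a warning rather than failing.
    """
    y = np.asarray(values, dtype=float)
    age = np.asarray(age, dtype=float)
    sexnum = np.array([1.0 if s in ("F", 1, 1.0, "1") else 0.0 for s in sex])
    obs = ~np.isnan(y)
    if obs.sum() < 3:
        raise VarCompError("need at least 3 complete observations to residualize")
    age_f = age.copy()
    age_f[np.isnan(age_f)] = np.nanmean(age_f[obs]) if np.isfinite(np.nanmean(age_f[obs])) else 0.0
    cols = [np.ones_like(y)]
    for name, c in (("age", age_f), ("sex", sexnum)):
        if np.ptp(c[obs]) == 0:
            warnings.warn(f"{name} is constant; dropped from residualization design")
        else:
            cols.append(c)
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X[obs], y[obs], rcond=None)
    out = np.full_like(y, np.nan)
    out[obs] = y[obs] - X[obs] @ beta
    return out


def residualize_pedigree(ped: Pedigree) -> Pedigree:
    """Copy of the pedigree with qol_pre / qol_pan replaced by residuals
    from occasion-specific age + sex regressions."""
    df = ped.df.copy()
    df["qol_pre"] = residualize(df["qol_pre"], df["age_pre"], df["sex"])
    df["qol_pan"] = residualize(df["qol_pan"], df["age_pan"], df["sex"])
    return Pedigree(df, validate=False)


# ---------------------------------------------------------------------------
# covariance assembly

_R_ATTR = {"A": "additive", "C": "household", "D": "dominance", "E": "identity"}


def family_covariance(
    rel: RelatednessSet, estimates: dict[str, ComponentMatrix], observed: np.ndarray
) -> np.ndarray:
    """Model covariance of the observed cells of one family.

    ``observed`` is an (n_members, 2) boolean mask over (person,
    occasion) cells; rows/columns for unobserved cells are deleted from
    sum_k R_k (x) Gamma_k.
    """
    n = len(rel.member_order)
    observed = np.asarray(observed, dtype=bool)
    if observed.shape != (n, 2):
        raise ValueError(f"observed mask must be ({n}, 2)")
    full = np.zeros((2 * n, 2 * n))
    for comp, cm in estimates.items():
        R = getattr(rel, _R_ATTR[comp])
        full += np.kron(R, cm.matrix)
    keep = observed.reshape(-1)
    return full[np.ix_(keep, keep)]


@dataclass
class _FamilyData:
    """Observed cells of one family prepared for the likelihood."""

    y: np.ndarray          # observed residualized values, cell order
    occ: np.ndarray        # occasion index (0 pre, 1 pan) per cell
    R_sub: dict[str, np.ndarray]  # per component, R restricted to the cells


def _prepare(ped: Pedigree, components: tuple[str, ...]) -> list[_FamilyData]:
    fams = []
    for fam_id, grp in ped.df.groupby("fam_id", sort=False):
        vals = grp[["qol_pre", "qol_pan"]].to_numpy(dtype=float)
        mask = ~np.isnan(vals)
        if not mask.any():
            continue
        rel = relatedness_matrices(ped, fam_id)
        person_idx, occ_idx = np.nonzero(mask)
        R_sub = {}
        for comp in components:
            R = getattr(rel, _R_ATTR[comp])
            R_sub[comp] = R[np.ix_(person_idx, person_idx)]
        fams.append(_FamilyData(vals[mask], occ_idx, R_sub))
    return fams


def _group_families(fams: list[_FamilyData], components) -> list[tuple]:
    """Group families sharing identical (R_sub stack, occasion pattern) so
    one Cholesky factorization serves the whole group."""
    groups: dict[bytes, list[_FamilyData]] = {}
    for f in fams:
        key = f.occ.tobytes() + b"|" + b"|".join(
            np.round(f.R_sub[c], 12).tobytes() for c in components
        )
        groups.setdefault(key, []).append(f)
    out = []
    for members in groups.values():
        proto = members[0]
        Y = np.vstack([m.y for m in members])
        out.append((proto.occ, proto.R_sub, Y))
    return out


LOG2PI = float(np.log(2.0 * np.pi))


def _group_loglik(occ, R_sub, Y, gammas: dict[str, np.ndarray], means: np.ndarray) -> float:
    m = len(occ)
    oi = occ[:, None]
    oj = occ[None, :]
    sigma = np.zeros((m, m))
    for comp, G in gammas.items():
        sigma += R_sub[comp] * G[oi, oj]
    try:
        c, low = cho_factor(sigma, lower=True)
    except np.linalg.LinAlgError:
        return -np.inf
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    resid = Y - means[occ]
    z = solve_triangular(c, resid.T, lower=low, check_finite=False)
    quad = float(np.sum(z * z))
    n_fam = Y.shape[0]
    return -0.5 * (n_fam * (m * LOG2PI + logdet) + quad)


def _unpack(theta: np.ndarray, components) -> tuple[dict[str, np.ndarray], np.ndarray]:
    gammas = {}
    for i, comp in enumerate(components):
        l11 = np.exp(theta[3 * i])
        l21 = theta[3 * i + 1]
        l22 = np.exp(theta[3 * i + 2])
        L = np.array([[l11, 0.0], [l21, l22]])
        gammas[comp] = L @ L.T
    means = theta[3 * len(components):]
    return gammas, means


def _pack_start(ped: Pedigree, components, rng: np.random.Generator | None = None):
    v_pre = float(np.nanvar(ped.df["qol_pre"]))
    v_pan = float(np.nanvar(ped.df["qol_pan"]))
    if v_pre <= 0 or v_pan <= 0:
        raise VarCompError("zero phenotypic variance at an occasion")
    both = ped.df[["qol_pre", "qol_pan"]].dropna()
    c_pp = float(both.cov().iloc[0, 1]) if len(both) > 2 else 0.0
    k = len(components)
    theta = []
    for _ in components:
        # equal split of each occasion's variance; half the phenotypic
        # cross-covariance shared over components
        vp, vq, cv = v_pre / k, v_pan / k, 0.5 * c_pp / k
        cv = float(np.clip(cv, -0.9 * np.sqrt(vp * vq), 0.9 * np.sqrt(vp * vq)))
        l11 = np.sqrt(vp)
        l21 = cv / l11
        l22 = np.sqrt(max(vq - l21 * l21, 1e-4))
        theta += [np.log(l11), l21, np.log(l22)]
    theta += [float(np.nanmean(ped.df["qol_pre"])), float(np.nanmean(ped.df["qol_pan"]))]
    theta = np.array(theta)
    if rng is not None:
        theta = theta + rng.normal(0.0, 0.25, size=theta.shape)
    return theta


def _negloglik(theta, groups, components):
    gammas, means = _unpack(theta, components)
    ll = 0.0
    for occ, R_sub, Y in groups:
        ll += _group_loglik(occ, R_sub, Y, gammas, means)
    if not np.isfinite(ll):
        return 1e12
    return -ll


def loglik(
    ped: Pedigree, estimates: dict[str, ComponentMatrix], means: tuple[float, float]
) -> float:
    """Total log-likelihood of the pedigree's phenotypes under given
    component blocks and grand means (no fitting)."""
    components = tuple(c for c in COMPONENT_ORDER if c in estimates)
    fams = _prepare(ped, components)
    groups = _group_families(fams, components)
    gammas = {c: estimates[c].matrix for c in components}
    mu = np.asarray(means, dtype=float)
    return float(sum(_group_loglik(occ, R, Y, gammas, mu) for occ, R, Y in groups))


def fit(
    ped: Pedigree,
    spec: ModelSpec | str,
    n_restarts: int = 2,
    seed: int = 0,
    standard_errors: bool = True,
) -> FitResult:
    """Maximum-likelihood fit of a bivariate variance-component model.

    The pedigree's qol columns are taken as the (residualized)
    phenotypes.  The total log-likelihood sums multivariate-normal
    family-block densities with missing cells deleted.  Optimization is
    quasi-Newton (L-BFGS-B) on the log-Cholesky parameterization from a
    deterministic moment-based start plus ``n_restarts`` seeded random
    perturbations, keeping the best converged solution.  Components whose
    fitted block is numerically at the PSD boundary are flagged.

    With ``standard_errors`` the observed-information (numerical
    Hessian) standard errors of the unstandardized block entries are
    attached.  Returns a summarized :class:`FitResult`.
    """
    if isinstance(spec, str):
        spec = ModelSpec.from_label(spec)
    components = spec.components
    fams = _prepare(ped, components)
    if len(fams) < 2:
        raise VarCompError("need at least 2 families with data")
    groups = _group_families(fams, components)
    n_obs = int(sum(Y.size for _, _, Y in groups))

    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(1 + n_restarts):
        theta0 = _pack_start(ped, components, rng if attempt else None)
        res = optimize.minimize(
            _negloglik, theta0, args=(groups, components), method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        if best.success and attempt >= 1:
            break
    if best is None or not np.isfinite(best.fun):
        raise VarCompError("optimization failed to produce a finite likelihood")
    if not best.success and not np.isfinite(best.fun):
        raise VarCompError(f"non-convergence: best -loglik {best.fun}")

    gammas, means = _unpack(best.x, components)
    estimates = {
        comp: ComponentMatrix(comp, G[0, 0], G[1, 1], G[0, 1])
        for comp, G in gammas.items()
    }
    boundary = [
        comp for comp, cm in estimates.items()
        if min(cm.v_pre, cm.v_pan) < 1e-6 or cm.cov**2 > 0.999999 * cm.v_pre * cm.v_pan
    ]
    result = FitResult(
        spec=spec,
        estimates=estimates,
        means=(float(means[0]), float(means[1])),
        loglik=-float(best.fun),
        n_params=spec.n_params,
        n_families=len(fams),
        n_observations=n_obs,
        converged=bool(best.success),
        boundary_components=boundary,
    )
    if standard_errors:
        _attach_standard_errors(result, best.x, groups, components)
    return summarize(result)


def _attach_standard_errors(result, theta, groups, components):
    """Delta-method SEs of the block entries from the observed information."""
    p = len(theta)
    h = 1e-4 * np.maximum(np.abs(theta), 1.0)

    def f(t):
        return _negloglik(t, groups, components)

    H = np.empty((p, p))
    f0 = f(theta)
    # central second differences
    fp = np.empty(p)
    fm = np.empty(p)
    for i in range(p):
        e = np.zeros(p); e[i] = h[i]
        fp[i] = f(theta + e)
        fm[i] = f(theta - e)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
    for i in range(p):
        for j in range(i + 1, p):
            ei = np.zeros(p); ei[i] = h[i]
            ej = np.zeros(p); ej[j] = h[j]
            fpp = f(theta + ei + ej)
            fmm = f(theta - ei - ej)
            H[i, j] = H[j, i] = (
                fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fmm
            ) / (2 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return
    # Jacobian of each block entry w.r.t. theta, by central differences
    def entries(t):
        gs, _ = _unpack(t, components)
        return np.concatenate([[gs[c][0, 0], gs[c][1, 1], gs[c][0, 1]] for c in components])

    J = np.empty((3 * len(components), p))
    for i in range(p):
        e = np.zeros(p); e[i] = h[i]
        J[:, i] = (entries(theta + e) - entries(theta - e)) / (2 * h[i])
    var_entries = np.einsum("ip,pq,iq->i", J, cov, J)
    var_entries = np.where(var_entries > 0, var_entries, np.nan)
    se = np.sqrt(var_entries)
    for i, comp in enumerate(components):
        cm = result.estimates[comp]
        cm.se_v_pre = float(se[3 * i])
        cm.se_v_pan = float(se[3 * i + 1])
        cm.se_cov = float(se[3 * i + 2])


def compare(full: FitResult, nested: FitResult) -> tuple[float, int, float]:
    """-2 log-likelihood chi-square test of a nested model against a
    fuller one; returns (chi2, df, p).  Boundary components make the
    nominal chi-square reference conservative."""
    if not nested.spec.is_nested_in(full.spec):
        raise VarCompError(
            f"{nested.spec.label} is not nested in {full.spec.label}"
        )
    chi2 = -2.0 * (nested.loglik - full.loglik)
    if chi2 < -1e-3:
        raise VarCompError(
            f"nested model log-likelihood exceeds the full model's by {-chi2 / 2:.3g}"
        )
    chi2 = max(chi2, 0.0)
    df = full.n_params - nested.n_params
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return chi2, df, p


def summarize(result: FitResult) -> FitResult:
    """Fill the standardized fields of a fit: per-occasion variance
    shares, total variances, total cross-time covariance and its
    per-component shares, and component cross-time correlations."""
    comps = result.spec.components
    P_pre = sum(result.estimates[c].v_pre for c in comps)
    P_pan = sum(result.estimates[c].v_pan for c in comps)
    total_cov = sum(result.estimates[c].cov for c in comps)
    result.total_var = (float(P_pre), float(P_pan))
    result.total_cov = float(total_cov)
    result.standardized = {
        c: {
            "pre": result.estimates[c].v_pre / P_pre,
            "pan": result.estimates[c].v_pan / P_pan,
        }
        for c in comps
    }
    result.covariance_shares = {
        c: (result.estimates[c].cov / total_cov if total_cov != 0 else float("nan"))
        for c in comps
    }
    result.component_corr = {
        c: result.estimates[c].cross_correlation() for c in comps
    }
    return result


def summarize_components(estimates: dict[str, ComponentMatrix]) -> FitResult:
    """Standardize a set of component blocks directly (no fitting), e.g.
    blocks transcribed from a published table."""
    spec = ModelSpec(tuple(estimates))
    res = FitResult(
        spec=spec, estimates=dict(estimates), means=(0.0, 0.0),
        loglik=float("nan"), n_params=spec.n_params, n_families=0,
        n_observations=0, converged=True,
    )
    return summarize(res)
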