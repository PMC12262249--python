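"""Growth-law models: first-order RelA/SpoT kinetics of (p)ppGpp control,
the proteome-sector cell-size model, scaling classification and hyperbolic
size-growth fitting with residual bootstrap.

Kinetic model
-------------
Ribosomes split into an inactive pool and an elongating pool set by
initiation activity, f_active = k_i / (k_i + k_ref).  Elongating ribosomes
cycle between a "dwelling" state (A-site awaiting ternary-complex capture,
mean time tau_d) and a "translocating" state (mean time tau_t), so at steady
state the elongating pool divides R_D : R_T = tau_d : tau_t.  Under
single-amino-acid limitation ribosomes queue behind the hungry codon: the
queued fraction is stalled with a charged A-site and counted in the
translocating (degradation-stimulating) pool.  Queuing is itself suppressed
by (p)ppGpp (high alarmone levels throttle initiation and dissolve queues),
q_eff = q * queue_g0 / (queue_g0 + g), which is what lets RelA mask the
SpoT-mediated inversion in the wild type while the relA deletion exposes it.

RelA synthesises (p)ppGpp in proportion to R_D (coefficient alpha); SpoT
degrades it in proportion to R_T (coefficient beta) and synthesises a small
constitutive flux sigma:

    dg/dt = alpha * R_D + sigma - beta * R_T * g.

(p)ppGpp sets ribosome allocation through a Hill response,
phi_R = phi_max / (1 + (g / g0)^h), and growth is proportional to total
translation flux, lambda = c_lambda * f_active * phi_R * (1 - q_eff) / (tau_d + tau_t).

Genotypes: "WT" has both enzymes; "relA" (RelA deletion) sets alpha = 0;
"relA_spoT" (double deletion) has no (p)ppGpp at all, pinning g = 0 and
phi_R = phi_max.

Size model
----------
Division occurs on accumulating a threshold amount of division proteins
residing in the sector phi_NC not repressed by (p)ppGpp, so mean volume
V = V0 / phi_NC = V0 / (1 - a1*phi_R - b1) where the repressed sector is
linear in the ribosome sector, phi_C = a1*phi_R + b1.  Composed with a
linear ribosome growth law phi_R = a2*lambda + b2 this yields the negative
hyperbolic size law V = A / (1 - k*lambda).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "KineticParams",
    "KineticState",
    "SectorParams",
    "ScalingFit",
    "kinetic_steady_state",
    "perturbation_scan",
    "ribosome_law_fit",
    "volume_from_sectors",
    "classify_scaling",
    "fit_hyperbolic",
    "fit_exponential",
    "joint_fit",
    "beta_kappa",
    "perimeter_correction",
    "PERTURBATION_AXES",
]

GENOTYPES = ("WT", "relA", "relA_spoT")


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of the RelA/SpoT (p)ppGpp control circuit."""

    k_i: float = 1.0        # initiation activity
    k_ref: float = 0.25     # competing rate setting the active fraction
    tau_d: float = 0.25     # mean A-site dwell time (awaiting capture)
    tau_t: float = 0.75     # mean translocation time
    q: float = 0.0          # queuing propensity under single-AA limitation
    queue_g0: float = 0.02  # (p)ppGpp level suppressing ribosome queues
    alpha: float = 1.0      # RelA synthesis coefficient
    beta: float = 2.0       # SpoT-dependent degradation coefficient
    sigma: float = 0.001    # SpoT basal synthesis flux
    phi_max: float = 0.55   # maximal ribosome allocation
    g0: float = 0.4         # allocation half-response (p)ppGpp level
    h: float = 1.0          # allocation Hill exponent
    c_lambda: float = 4.0   # translation-flux-to-growth conversion
    genotype: str = "WT"

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}")
        for name in ("k_i", "k_ref", "tau_d", "tau_t", "beta", "phi_max", "g0", "h", "c_lambda"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.alpha < 0 or self.sigma < 0:
            raise ValueError("alpha and sigma must be >= 0")
        if not 0.0 <= self.q < 1.0:
            raise ValueError("q must be in [0, 1)")
        if self.queue_g0 <= 0:
            raise ValueError("queue_g0 must be > 0")

    @property
    def f_active(self) -> float:
        return self.k_i / (self.k_i + self.k_ref)

    @property
    def effective_alpha(self) -> float:
        return 0.0 if self.genotype in ("relA", "relA_spoT") else self.alpha


@dataclass
class KineticState:
    """Steady state of the kinetic model."""

    growth_rate: float      # lambda
    phi_R: float            # ribosome proteome fraction
    g: float                # (p)ppGpp level
    R_D: float              # dwelling pool (proteome-fraction units)
    R_T: float              # translocating (+ queued) pool
    f_active: float
    q_eff: float = 0.0      # realised queued fraction


def _q_eff(p: KineticParams, g: float) -> float:
    """Realised queued fraction: queues dissolve when (p)ppGpp throttles initiation."""
    return p.q * p.queue_g0 / (p.queue_g0 + g)


def _pools(p: KineticParams, phi_R: float, q_eff: float) -> tuple[float, float]:
    elongating = p.f_active * phi_R
    share_d = p.tau_d / (p.tau_d + p.tau_t)
    R_D = (1.0 - q_eff) * elongating * share_d
    R_T = elongating * ((1.0 - q_eff) * (1.0 - share_d) + q_eff)
    return R_D, R_T


def _phi_of_g(p: KineticParams, g: float) -> float:
    return p.phi_max / (1.0 + (g / p.g0) ** p.h)


def _lambda_of(p: KineticParams, phi_R: float, q_eff: float) -> float:
    return p.c_lambda * p.f_active * phi_R * (1.0 - q_eff) / (p.tau_d + p.tau_t)


def kinetic_steady_state(
    p: KineticParams,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> KineticState:
    """Self-consistent fixed point of the (p)ppGpp balance and allocation.

    Solved by damped fixed-point iteration on g; in the sigma -> 0, q = 0
    limit the answer is the closed form g* = (alpha/beta) * (tau_d/tau_t),
    independent of initiation activity.
    """
    if p.genotype == "relA_spoT":
        phi_R = p.phi_max
        qe = _q_eff(p, 0.0)
        R_D, R_T = _pools(p, phi_R, qe)
        return KineticState(_lambda_of(p, phi_R, qe), phi_R, 0.0, R_D, R_T, p.f_active, qe)
    alpha = p.effective_alpha
    g = (alpha / p.beta) * (p.tau_d / p.tau_t) + p.sigma  # starting guess
    for _ in range(max_iter):
        phi_R = _phi_of_g(p, g)
        qe = _q_eff(p, g)
        R_D, R_T = _pools(p, phi_R, qe)
        g_new = (alpha * R_D + p.sigma) / (p.beta * R_T)
        if abs(g_new - g) <= tol * max(1.0, abs(g)):
            g = g_new
            break
        g = 0.5 * g + 0.5 * g_new
    else:
        raise RuntimeError("fixed-point iteration did not converge")
    phi_R = _phi_of_g(p, g)
    qe = _q_eff(p, g)
    R_D, R_T = _pools(p, phi_R, qe)
    return KineticState(_lambda_of(p, phi_R, qe), phi_R, g, R_D, R_T, p.f_active, qe)


#: perturbation axis -> parameter transform at severity m >= 1
PERTURBATION_AXES = (
    "capture",        # ternary-complex capture impaired: tau_d * m
    "translocation",  # translocation impaired: tau_t * m
    "initiation",     # initiation impaired: k_i / m
    "single_AA",      # one amino acid limiting: tau_d * m, queued fraction rises
    "multi_AA",       # many amino acids limiting: tau_d * m, no queuing
    "stalk",          # ribosome-stalk loss: tau_d, tau_t * m and k_i / m
)


def _perturb(p: KineticParams, axis: str, m: float, q_max: float = 0.5) -> KineticParams:
    if m < 1.0:
        raise ValueError("severity must be >= 1")
    if axis == "capture":
        return replace(p, tau_d=p.tau_d * m)
    if axis == "translocation":
        return replace(p, tau_t=p.tau_t * m)
    if axis == "initiation":
        return replace(p, k_i=p.k_i / m)
    if axis == "single_AA":
        # modest extra dwell at the hungry codon plus rising queuing propensity
        return replace(p, tau_d=p.tau_d * (1.0 + 0.3 * (m - 1.0)), q=q_max * (1.0 - 1.0 / m))
    if axis == "multi_AA":
        return replace(p, tau_d=p.tau_d * m, q=0.0)
    if axis == "stalk":
        return replace(p, tau_d=p.tau_d * m, tau_t=p.tau_t * m, k_i=p.k_i / m)
    raise ValueError(f"unknown perturbation axis {axis!r}")


def perturbation_scan(
    p: KineticParams,
    axis: str,
    grid: np.ndarray | list[float] | None = None,
) -> pd.DataFrame:
    """Steady states along one perturbation axis.

    ``grid`` is a list of severities m >= 1 (1 = unperturbed).  Returns a
    tidy frame (axis, knob, growth_rate, phi_R, g) with the least-squares
    slope of phi_R vs lambda attached as ``df.attrs['slope']``.
    """
    if grid is None:
        grid = np.linspace(1.0, 3.0, 9)
    rows = []
    for m in grid:
        st = kinetic_steady_state(_perturb(p, axis, float(m)))
        rows.append(
            {"axis": axis, "knob": float(m), "growth_rate": st.growth_rate,
             "phi_R": st.phi_R, "g": st.g}
        )
    df = pd.DataFrame(rows)
    a2, b2, _ = ribosome_law_fit(df["growth_rate"].to_numpy(), df["phi_R"].to_numpy())
    df.attrs["slope"] = a2
    df.attrs["intercept"] = b2
    return df


def ribosome_law_fit(growth_rate: np.ndarray, phi_R: np.ndarray):
    """Least-squares line phi_R = a2 * lambda + b2; returns (a2, b2, r_squared)."""
    lam = np.asarray(growth_rate, dtype=float)
    phi = np.asarray(phi_R, dtype=float)
    if lam.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(lam) == 0:
        raise ValueError("degenerate growth-rate range")
    A = np.column_stack([lam, np.ones_like(lam)])
    coef, *_ = np.linalg.lstsq(A, phi, rcond=None)
    a2, b2 = float(coef[0]), float(coef[1])
    resid = phi - A @ coef
    ss_tot = float(((phi - phi.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return a2, b2, r2


@dataclass(frozen=True)
class SectorParams:
    """Proteome-sector size model: phi_C = a1*phi_R + b1, V = V0/(1 - phi_C)."""

    a1: float = 1.3
    b1: float = 0.05
    V0: float = 1.0

    def __post_init__(self) -> None:
        if self.V0 <= 0:
            raise ValueError("V0 must be > 0")


def volume_from_sectors(phi_R, sp: SectorParams):
    """Mean cell volume from the ribosome fraction: V = V0 / (1 - a1*phi_R - b1).

    Raises when the non-repressed sector 1 - phi_C would vanish (cell-size
    divergence).
    """
    phi = np.asarray(phi_R, dtype=float)
    denom = 1.0 - sp.a1 * phi - sp.b1
    if np.any(denom <= 0):
        raise ValueError("non-repressed sector vanishes: 1 - a1*phi_R - b1 <= 0")
    V = sp.V0 / denom
    return float(V) if V.ndim == 0 else V


def classify_scaling(
    growth_rate: np.ndarray,
    length: np.ndarray,
    slope_threshold: float = 0.2,
    eligibility_growth: float = 0.9,
) -> tuple[str, float | None]:
    """Classify a gene's size-growth scaling from its sgRNA series.

    Least-squares slope of log2(length) vs growth rate (doublings/h):
    slope > +0.2 -> "SMK", < -0.2 -> "inverse", otherwise "flat".
    Ineligible (returns ("ineligible", None)) without >= 3 points or without
    at least one point below 0.9 doublings/h.
    """
    lam = np.asarray(growth_rate, dtype=float)
    L = np.asarray(length, dtype=float)
    ok = np.isfinite(lam) & np.isfinite(L) & (L > 0)
    lam, L = lam[ok], L[ok]
    if lam.size < 3 or lam.min() >= eligibility_growth or np.ptp(lam) == 0:
        return "ineligible", None
    A = np.column_stack([lam, np.ones_like(lam)])
    coef, *_ = np.linalg.lstsq(A, np.log2(L), rcond=None)
    slope = float(coef[0])
    if slope > slope_threshold:
        return "SMK", slope
    if slope < -slope_threshold:
        return "inverse", slope
    return "flat", slope


def _check_hyperbolic_inputs(lam, V):
    lam = np.asarray(lam, dtype=float)
    V = np.asarray(V, dtype=float)
    if lam.size < 3:
        raise ValueError("need at least 3 points")
    if np.any(V <= 0):
        raise ValueError("volumes must be positive")
    return lam, V


def fit_hyperbolic(growth_rate, volume):
    """Fit V = A / (1 - k*lambda) by linear least squares on 1/V = u - w*lambda.

    Returns (A, k, rss) with A = 1/u, k = w/u and rss evaluated in V-space.
    """
    lam, V = _check_hyperbolic_inputs(growth_rate, volume)
    X = np.column_stack([np.ones_like(lam), -lam])
    coef, *_ = np.linalg.lstsq(X, 1.0 / V, rcond=None)
    u, w = float(coef[0]), float(coef[1])
    A, k = 1.0 / u, w / u
    pred = A / (1.0 - k * lam)
    rss = float(((V - pred) ** 2).sum())
    return A, k, rss


def fit_exponential(growth_rate, volume):
    """Fit V = V0 * exp(k_e*lambda) by linear least squares on ln V.

    Returns (V0, k_e, rss) with rss evaluated in V-space.
    """
    lam, V = _check_hyperbolic_inputs(growth_rate, volume)
    X = np.column_stack([np.ones_like(lam), lam])
    coef, *_ = np.linalg.lstsq(X, np.log(V), rcond=None)
    V0, k_e = float(math.exp(coef[0])), float(coef[1])
    pred = V0 * np.exp(k_e * lam)
    rss = float(((V - pred) ** 2).sum())
    return V0, k_e, rss


@dataclass
class ScalingFit:
    """Joint linearised hyperbolic fit: shared intercept u, per-class slope w.

    1/V = u - w_c * lambda for class c, i.e. V = (1/u) / (1 - (w_c/u) lambda);
    the flat-class trendline is the common intersection level V = 1/u at
    lambda = 0.  ``ci`` maps parameter name -> (lo, hi) residual-bootstrap
    95 % interval.
    """

    u: float
    slopes: dict[str, float]
    k: dict[str, float]           # k_c = w_c / u
    flat_level: float             # 1/u
    rss: float
    n_parameters: int
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def contains(self, name: str, value: float) -> bool:
        lo, hi = self.ci[name]
        return lo <= value <= hi


def _joint_design(class_points: dict[str, tuple[np.ndarray, np.ndarray]]):
    names = list(class_points)
    lam_all, y_all, cls_idx = [], [], []
    for ci, name in enumerate(names):
        lam, V = _check_hyperbolic_inputs(*class_points[name])
        lam_all.append(lam)
        y_all.append(1.0 / V)
        cls_idx.append(np.full(lam.size, ci))
    lam_all = np.concatenate(lam_all)
    y_all = np.concatenate(y_all)
    cls_idx = np.concatenate(cls_idx)
    X = np.zeros((lam_all.size, 1 + len(names)))
    X[:, 0] = 1.0
    for ci in range(len(names)):
        X[cls_idx == ci, 1 + ci] = -lam_all[cls_idx == ci]
    return names, X, y_all, lam_all, cls_idx


def joint_fit(
    class_points: dict[str, tuple[np.ndarray, np.ndarray]],
    n_boot: int = 2000,
    seed: int | np.random.Generator | None = None,
    ci_level: float = 0.95,
) -> ScalingFit:
    """Simultaneous hyperbolic fit to several perturbation classes.

    With two classes this is the three-parameter fit (shared u, one slope per
    class).  95 % CIs come from a residual bootstrap in 1/V space: residuals
    are resampled within class, refit, and percentile intervals taken for u,
    each w_c and each derived k_c.
    """
    names, X, y, lam_all, cls_idx = _joint_design(class_points)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    u = float(coef[0])
    slopes = {name: float(coef[1 + i]) for i, name in enumerate(names)}
    resid = y - X @ coef
    k = {name: slopes[name] / u for name in names}
    pred_V = 1.0 / (X @ coef)
    V_obs = 1.0 / y
    rss = float(((V_obs - pred_V) ** 2).sum())

    rng = np.random.default_rng(seed)
    boot = {name: [] for name in ("u", *names)}
    boot_k = {name: [] for name in names}
    for _ in range(n_boot):
        r_star = np.empty_like(resid)
        for ci in range(len(names)):
            mask = cls_idx == ci
            r_c = resid[mask]
            r_star[mask] = rng.choice(r_c, size=r_c.size, replace=True)
        y_star = X @ coef + r_star
        c_star, *_ = np.linalg.lstsq(X, y_star, rcond=None)
        boot["u"].append(c_star[0])
        for i, name in enumerate(names):
            boot[name].append(c_star[1 + i])
            boot_k[name].append(c_star[1 + i] / c_star[0])
    lo_q, hi_q = 100 * (1 - ci_level) / 2, 100 * (1 + ci_level) / 2
    ci: dict[str, tuple[float, float]] = {}
    for key, vals in boot.items():
        ci[key] = (float(np.percentile(vals, lo_q)), float(np.percentile(vals, hi_q)))
    for name, vals in boot_k.items():
        ci[f"k_{name}"] = (float(np.percentile(vals, lo_q)), float(np.percentile(vals, hi_q)))
    return ScalingFit(
        u=u,
        slopes=slopes,
        k=k,
        flat_level=1.0 / u,
        rss=rss,
        n_parameters=1 + len(names),
        ci=ci,
    )


def beta_kappa(
    ribosome_laws: dict[str, tuple[float, float]],
    size_scaling_k: dict[str, float],
) -> pd.DataFrame:
    """Per-class ribosome scaling constant beta (= a2) against volume scaling
    constant kappa (= k), with the kappa/beta proportionality diagnostic.

    Under the sector model kappa = a1*beta / (1 - b1 - a1*b2), so classes
    sharing the sector parameters and intercept b2 have identical ratios.
    """
    if len(ribosome_laws) < 2:
        raise ValueError("need at least 2 classes")
    rows = []
    for name, (a2, b2) in ribosome_laws.items():
        kappa = size_scaling_k[name]
        rows.append(
            {"class": name, "beta": a2, "kappa": kappa,
             "ratio": kappa / a2 if a2 != 0 else np.nan}
        )
    df = pd.DataFrame(rows)
    ratios = df["ratio"].dropna()
    df.attrs["ratio_spread"] = float(ratios.max() - ratios.min()) if len(ratios) else np.nan
    return df


def perimeter_correction(
    class_points: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
    n_boot: int = 200,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Compare the joint hyperbolic fit of raw volume against volume
    normalised by mid-cell perimeter (pi*W) and by cross-section (pi*(W/2)^2).

    ``class_points`` maps class -> (lambda, V, W).  Fit quality is the
    scale-invariant fraction of variance unexplained, RSS / sum(V^2), so a
    constant width reproduces the raw fit exactly.
    """
    out = []
    for norm_name, norm_fn in (
        ("raw", lambda V, W: V),
        ("perimeter", lambda V, W: V / (np.pi * W)),
        ("cross_section", lambda V, W: V / (np.pi * (W / 2.0) ** 2)),
    ):
        pts = {}
        for name, (lam, V, W) in class_points.items():
            lam = np.asarray(lam, float)
            V = np.asarray(V, float)
            W = np.asarray(W, float)
            pts[name] = (lam, norm_fn(V, W))
        fit = joint_fit(pts, n_boot=n_boot, seed=seed)
        total = sum(float((np.asarray(v[1]) ** 2).sum()) for v in pts.values())
        out.append(
            {"normalization": norm_name, "rss": fit.rss, "relative_rss": fit.rss / total}
        )
    return pd.DataFrame(out)
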