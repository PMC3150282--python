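"""Reaction--diffusion segregation model, stability analysis and patch statistics.

Five coupled fields on the contact interface: free receptor R, free small
ligand L, complex C, long ligand I (concentrations, um^-2) and the local
inter-membrane separation z.  Species diffuse; R + L <-> C with a
separation-dependent off-rate koff0*exp(E_C(z)); the complex and the long
ligand drift down the gradients of their spring energies; and the
membrane relaxes overdamped against bending rigidity kappa, tension
sigma, and the spring forces:

    dR/dt = D_R lap R - kon R L + koff(z) C
    dL/dt = D_L lap L - kon R L + koff(z) C
    dC/dt = D_C div(grad C + C grad E_C) + kon R L - koff(z) C
    dI/dt = D_I div(grad I + I grad E_I)
    M dz/dt = -kappa lap^2 z + sigma lap z - dE/dz,
        dE/dz = 2 lambda_C C (z - z_C) + 2 lambda_I I (z - z_I)

This is an exact gradient flow of the free energy
F = sum_X X(ln X - 1) + C(E_C - ln K) + I E_I + elastic(z), which makes
the linear stability of a uniform steady state equivalent to positive
definiteness of the free-energy Hessian.  Reducing the Hessian (Schur
complements over the conserved densities) gives the analytic instability
margin at wavenumber k,

    2 lambda_C C (2 e_C^2 - 1) + 2 lambda_I I (2 e_I^2 - 1)
        > kappa k^4 + sigma k^2,

which is largest at k = 0 (the elastic penalty only stabilises).  Using
the steady-state force balance sqrt(lambda_C) C e_C = sqrt(lambda_I) I e_I
the k = 0 condition collapses to SQRE coordinates,

    e_I (2 e_C^2 - 1) + beta e_C (2 e_I^2 - 1) > 0,
    beta = sqrt(lambda_I / lambda_C),

so the stability curve in the (e_C, e_I) plane is determined by the
spring-constant ratio alone -- the quantity the image regression
measures.  The analytic condition is validated against the numerical
eigenvalues of the full 5-variable linearisation (`dispersion_relation`).

Internal unit system: lengths um (separations converted from nm at the
API), energies kT, time s.  Spring constants are converted kT nm^-2 ->
kT um^-2 (x 1e6) internally; the API accepts the field's nm-based units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.fft import dctn, idctn
from scipy.ndimage import label
from scipy.optimize import brentq
from scipy.stats import norm

from .energy_model import RegressionLine, SpringParams

__all__ = [
    "example_params",
    "DynamicsParams",
    "SteadyState",
    "StabilityCurve",
    "PatternationResult",
    "Trajectory",
    "CFLError",
    "uniform_steady_states",
    "dispersion_relation",
    "instability_condition",
    "sqre_margin",
    "stability_curve",
    "patternation_test",
    "simulate_pde",
    "close_contact_patch_stats",
    "kd_2d_from_enrichment",
]

_NM2UM = 1.0e-3          # nm -> um
_LAM_NM2UM = 1.0e6       # kT nm^-2 -> kT um^-2


class CFLError(RuntimeError):
    """Raised when a requested time step violates the stability bound."""


@dataclass(frozen=True)
class DynamicsParams:
    """Parameters of the segregation model.

    Diffusivities and kon in um^2 s^-1, koff0 s^-1, kappa kT, sigma
    kT nm^-2, M (membrane response coefficient, sets the separation
    relaxation rate; kT s um^-4 in internal units).  ``totals`` are the
    cell-averaged total densities (um^-2) of receptor, small ligand and
    long ligand, with ``area_ratio`` the contact-interface : free-surface
    area ratio used to partition the unbound pools.
    """

    springs: SpringParams
    D_R: float = 0.1
    D_L: float = 0.1
    D_C: float = 0.05
    D_I: float = 0.1
    kon: float = 0.05
    koff0: float = 1.0
    kappa: float = 25.0
    sigma: float = 0.02
    M: float = 1.0e5
    R_tot: float = 190.0
    L_tot: float = 300.0
    I_tot: float = 500.0
    area_ratio: float = 0.3

    def __post_init__(self) -> None:
        for name in ("D_R", "D_L", "D_C", "D_I", "kon", "koff0",
                     "R_tot", "L_tot", "I_tot", "area_ratio"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.M <= 0 or self.kappa <= 0 or self.sigma <= 0:
            raise ValueError("M, kappa, sigma must be positive")

    def with_(self, **kw) -> "DynamicsParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class SteadyState:
    """A spatially uniform steady state of the interface."""

    z_star: float          # nm
    R: float
    L: float
    C: float
    I: float
    e_C_star: float
    e_I_star: float
    stable_homog: bool
    stable_spatial: bool
    residual: float = 0.0


@dataclass(frozen=True)
class StabilityCurve:
    """Zero-level set of the k=0 margin in the (e_C, e_I) plane."""

    e_C: np.ndarray
    e_I: np.ndarray
    beta: float

    def margin(self, e_C, e_I):
        return sqre_margin(e_C, e_I, self.beta)

    def is_stable(self, e_C, e_I):
        return self.margin(e_C, e_I) < 0


@dataclass(frozen=True)
class PatternationResult:
    """Intersection of the regression line with the instability region."""

    intersects: bool
    crossings: tuple        # e_C values where the margin changes sign
    unstable_segments: tuple  # (e_C_lo, e_C_hi) pairs along the line
    line: RegressionLine


def example_params(regime: str = "unstable") -> DynamicsParams:
    """Reference parameter sets exhibiting the model's regimes.

    "stable": complex-dominated interface whose uniform state resists
    patternation.  "unstable": a spatially unstable uniform state (the
    patternating regime).  "three_state": multistable, with an
    intermediate state that is unstable to homogeneous perturbations.
    All use the default springs (beta = 0.7, alpha = 1.6).
    """
    from .synthetic_data import default_springs

    sp = default_springs()
    if regime == "stable":
        return DynamicsParams(springs=sp)
    if regime == "unstable":
        return DynamicsParams(springs=sp, kon=1e-3, koff0=0.1,
                              I_tot=100.0, L_tot=50.0)
    if regime == "three_state":
        return DynamicsParams(springs=sp, kon=1e-4, koff0=0.1,
                              I_tot=100.0, L_tot=1000.0)
    raise ValueError(f"unknown regime {regime!r}")


# ---------------------------------------------------------------------------
# Uniform steady states
# ---------------------------------------------------------------------------

def _equilibrium_concentrations(z_nm: float, p: DynamicsParams):
    """Interface concentrations with composition equilibrated at separation z.

    Unbound pools partition between interface and free surface; the long
    ligand is Boltzmann-suppressed in the interface by its spring energy.
    Returns (R, L, C, I) in um^-2.
    """
    s = p.springs
    E_C = s.lambda_C * (z_nm - s.z_C) ** 2
    E_I = s.lambda_I * (z_nm - s.z_I) ** 2
    koff = p.koff0 * np.exp(np.minimum(E_C, 500.0))
    A = p.area_ratio
    f = A / (1.0 + A)
    # kon (R_tot - f C)(L_tot - f C) = koff C: stable quadratic solve
    if p.kon == 0 or p.R_tot == 0 or p.L_tot == 0:
        C = 0.0
    elif f == 0:
        C = p.kon * p.R_tot * p.L_tot / koff
    else:
        a = p.kon * f * f
        b = -(p.kon * f * (p.R_tot + p.L_tot) + koff)
        c = p.kon * p.R_tot * p.L_tot
        disc = b * b - 4 * a * c
        C = 2 * c / (-b + np.sqrt(disc))  # smaller root, cancellation-free
        C = min(C, min(p.R_tot, p.L_tot) / f)
    R = p.R_tot - f * C
    L = p.L_tot - f * C
    w = np.exp(-E_I)
    I_fs = p.I_tot * (1.0 + A) / (1.0 + A * w)
    I = I_fs * w
    return R, L, C, I


def _force_balance(z_nm: float, p: DynamicsParams) -> float:
    s = p.springs
    R, L, C, I = _equilibrium_concentrations(z_nm, p)
    return s.lambda_C * C * (z_nm - s.z_C) + s.lambda_I * I * (z_nm - s.z_I)


def _make_state(z_nm: float, p: DynamicsParams) -> SteadyState:
    s = p.springs
    R, L, C, I = _equilibrium_concentrations(z_nm, p)
    e_C = np.sqrt(s.lambda_C) * abs(z_nm - s.z_C)
    e_I = np.sqrt(s.lambda_I) * abs(z_nm - s.z_I)
    st = SteadyState(
        z_star=z_nm, R=R, L=L, C=C, I=I,
        e_C_star=float(e_C), e_I_star=float(e_I),
        stable_homog=True, stable_spatial=True,
        residual=abs(_force_balance(z_nm, p)),
    )
    lam_max = _max_growth_homog(st, p)
    spatial = instability_condition(st, p, k=0.0) < 0
    return replace(st, stable_homog=bool(lam_max < 1e-9), stable_spatial=bool(spatial))


def uniform_steady_states(p: DynamicsParams, n_brackets: int = 400) -> list[SteadyState]:
    """All uniform steady states, by bracketed scan over the separation.

    Scans z on [z_C - 5, z_I + 5] nm with ``n_brackets`` intervals,
    bisects each sign change of the force balance, and merges roots
    closer than 1e-4 nm.  The model admits 1 or 3 states; other counts
    are returned as found (numerical near-degeneracies are reported via
    the merged list).  Each state is annotated with homogeneous-mode
    (k=0 eigenvalue) and spatial (instability-margin) stability flags.
    """
    s = p.springs
    lo = max(s.z_C - 5.0, 1e-3)
    hi = s.z_I + 5.0
    zs = np.linspace(lo, hi, n_brackets + 1)
    vals = np.array([_force_balance(z, p) for z in zs])
    roots: list[float] = []
    for i in range(n_brackets):
        a, b = zs[i], zs[i + 1]
        fa, fb = vals[i], vals[i + 1]
        if fa == 0.0:
            roots.append(a)
        elif fa * fb < 0:
            try:
                roots.append(brentq(_force_balance, a, b, args=(p,), xtol=1e-10))
            except ValueError as exc:  # pragma: no cover - diagnostic path
                raise RuntimeError(
                    f"root refinement failed on [{a}, {b}]; bracket scan: "
                    f"{list(zip(zs, vals))[:5]}..."
                ) from exc
    if vals[-1] == 0.0:
        roots.append(zs[-1])
    merged: list[float] = []
    for r in sorted(roots):
        if not merged or r - merged[-1] > 1e-4:
            merged.append(r)
    return [_make_state(z, p) for z in merged]


# ---------------------------------------------------------------------------
# Linear stability
# ---------------------------------------------------------------------------

def _jacobian(state: SteadyState, p: DynamicsParams, k: float) -> np.ndarray:
    """5x5 linearisation at spatial mode k (um^-1) around a steady state.

    Variables ordered (R, L, C, I, z[um]).  Built directly from the PDE
    right-hand sides; this is the *numerical* twin of the analytic
    Hessian criterion and deliberately shares no algebra with it.
    """
    s = p.springs
    lamC = s.lambda_C * _LAM_NM2UM
    lamI = s.lambda_I * _LAM_NM2UM
    zC = s.z_C * _NM2UM
    zI = s.z_I * _NM2UM
    z = state.z_star * _NM2UM
    R, L, C, I = state.R, state.L, state.C, state.I
    E_C = lamC * (z - zC) ** 2
    dEC = 2 * lamC * (z - zC)          # kT um^-1
    dEI = 2 * lamI * (z - zI)
    koff = p.koff0 * np.exp(min(E_C, 500.0))
    koff_z = koff * dEC
    k2 = k * k
    J = np.zeros((5, 5))
    # R row
    J[0] = [-p.D_R * k2 - p.kon * L, -p.kon * R, koff, 0.0, koff_z * C]
    # L row
    J[1] = [-p.kon * L, -p.D_L * k2 - p.kon * R, koff, 0.0, koff_z * C]
    # C row: diffusion + drift down grad E_C + reactions
    J[2] = [p.kon * L, p.kon * R, -p.D_C * k2 - koff, 0.0,
            -p.D_C * k2 * C * dEC - koff_z * C]
    # I row: diffusion + drift down grad E_I
    J[3] = [0.0, 0.0, 0.0, -p.D_I * k2, -p.D_I * k2 * I * dEI]
    # z row: overdamped membrane
    J[4] = [0.0, 0.0, -dEC / p.M, -dEI / p.M,
            -(2 * lamC * C + 2 * lamI * I + p.kappa * k2 * k2 + p.sigma * _LAM_NM2UM * k2) / p.M]
    return J


def _check_steady(state: SteadyState, p: DynamicsParams, tol: float) -> None:
    s = p.springs
    res_force = abs(
        s.lambda_C * state.C * (state.z_star - s.z_C)
        + s.lambda_I * state.I * (state.z_star - s.z_I)
    )
    scale = s.lambda_C * max(state.C, 1.0) * (s.z_I - s.z_C) + 1e-12
    koff = p.koff0 * np.exp(min(s.lambda_C * (state.z_star - s.z_C) ** 2, 500.0))
    res_mass = abs(p.kon * state.R * state.L - koff * state.C)
    mscale = p.kon * max(state.R * state.L, 1.0) + koff * max(state.C, 1.0) + 1e-12
    if res_force / scale > tol or res_mass / mscale > tol:
        raise ValueError(
            "input is not a steady state "
            f"(force residual {res_force/scale:.2e}, mass residual {res_mass/mscale:.2e})"
        )


def _max_growth_homog(state: SteadyState, p: DynamicsParams) -> float:
    """Largest real part over the non-conserved eigenmodes at k=0."""
    J = _jacobian(state, p, 0.0)
    ev = np.linalg.eigvals(J)
    scale = max(np.abs(ev).max(), 1.0)
    nz = ev[np.abs(ev) > 1e-10 * scale]
    return float(nz.real.max()) if nz.size else 0.0


def dispersion_relation(state: SteadyState, p: DynamicsParams, k: float,
                        tol: float = 1e-6) -> float:
    """Largest real eigenvalue of the linearisation at wavenumber k (s^-1)."""
    _check_steady(state, p, tol)
    ev = np.linalg.eigvals(_jacobian(state, p, float(k)))
    return float(ev.real.max())


def instability_condition(state: SteadyState, p: DynamicsParams, k: float = 0.0,
                          tol: float = 1e-6) -> float:
    """Analytic instability margin at wavenumber k; positive = unstable.

    The raw criterion is
    2 lam_C C (2 e_C^2 - 1) + 2 lam_I I (2 e_I^2 - 1) - (kappa k^4 + sigma k^2) > 0
    (internal um units); the returned margin is normalised by the total
    membrane stiffness so it is an O(1) signed number whose sign matches
    the most-unstable growth rate at and near that wavenumber (k = 0 is
    the most unstable mode: the elastic penalty only ever stabilises).
    """
    _check_steady(state, p, tol)
    s = p.springs
    lamC = s.lambda_C * _LAM_NM2UM
    lamI = s.lambda_I * _LAM_NM2UM
    eC2 = state.e_C_star**2
    eI2 = state.e_I_star**2
    penalty = p.kappa * k**4 + p.sigma * _LAM_NM2UM * k**2
    raw = (2 * lamC * state.C * (2 * eC2 - 1)
           + 2 * lamI * state.I * (2 * eI2 - 1) - penalty)
    stiffness = 2 * lamC * state.C + 2 * lamI * state.I + penalty
    if stiffness == 0:
        return 0.0
    return float(raw / stiffness)


def sqre_margin(e_C, e_I, beta: float):
    """k=0 instability margin in SQRE coordinates (positive = unstable).

    g(e_C, e_I) = e_I (2 e_C^2 - 1) + beta e_C (2 e_I^2 - 1); the
    force-balance-reduced form of the margin, valid for any steady state
    with the given spring ratio beta^2 = lambda_I/lambda_C.
    """
    e_C = np.asarray(e_C, dtype=float)
    e_I = np.asarray(e_I, dtype=float)
    return e_I * (2 * e_C**2 - 1) + beta * e_C * (2 * e_I**2 - 1)


def stability_curve(line: RegressionLine, p: DynamicsParams | None = None,
                    e_C_max: float = 5.0, n: int = 400) -> StabilityCurve:
    """Sample the marginal-stability curve in the (e_C, e_I) quadrant.

    For each e_C > 0 the zero of g in e_I solves the quadratic
    2 beta e_C e_I^2 + (2 e_C^2 - 1) e_I - beta e_C = 0 (positive root);
    the region above the curve is unstable, below is stable.  Only the
    slope magnitude beta of the regression line enters.
    """
    beta = line.beta
    if beta <= 0:
        raise ValueError("beta must be positive")
    e_C = np.linspace(1e-6, e_C_max, n)
    b = 2 * e_C**2 - 1
    disc = b * b + 8 * beta**2 * e_C**2
    e_I = (-b + np.sqrt(disc)) / (4 * beta * e_C)
    return StabilityCurve(e_C=e_C, e_I=e_I, beta=beta)


def patternation_test(line: RegressionLine, p: DynamicsParams | None = None,
                      n_scan: int = 2001) -> PatternationResult:
    """Does the regression line cross into the instability region?

    The line e_I = alpha - beta e_C (restricted to the physical quadrant
    e_C in [0, alpha/beta]) is the locus of uniform steady states as
    ligand concentrations vary; segments with positive k=0 margin are
    steady states that would spontaneously patternate.  The elastic
    parameters drop out at k = 0, so only the line itself matters.
    """
    eC_hi = line.e_C_max
    grid = np.linspace(0.0, eC_hi, n_scan)
    h = sqre_margin(grid, line.alpha - line.beta * grid, line.beta)
    crossings: list[float] = []
    for i in range(n_scan - 1):
        if h[i] == 0.0:
            crossings.append(float(grid[i]))
        elif h[i] * h[i + 1] < 0:
            f = lambda x: float(sqre_margin(x, line.alpha - line.beta * x, line.beta))
            crossings.append(float(brentq(f, grid[i], grid[i + 1], xtol=1e-12)))
    segments: list[tuple[float, float]] = []
    bounds = [0.0] + sorted(crossings) + [eC_hi]
    for a, b in zip(bounds[:-1], bounds[1:]):
        mid = 0.5 * (a + b)
        if sqre_margin(mid, line.alpha - line.beta * mid, line.beta) > 0:
            segments.append((a, b))
    return PatternationResult(
        intersects=bool(segments),
        crossings=tuple(sorted(crossings)),
        unstable_segments=tuple(segments),
        line=line,
    )


# ---------------------------------------------------------------------------
# PDE simulation
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Snapshots of the five fields plus run metadata."""

    times: np.ndarray
    R: np.ndarray           # (n_save, ny, nx)
    L: np.ndarray
    C: np.ndarray
    I: np.ndarray
    z: np.ndarray           # nm
    dx: float               # um
    params: DynamicsParams = field(repr=False, default=None)
    seed: int | None = None

    def totals(self, idx: int):
        """Conserved totals (integrated R+C, L+C, I) at snapshot idx."""
        area = self.dx**2
        return (
            float((self.R[idx] + self.C[idx]).sum() * area),
            float((self.L[idx] + self.C[idx]).sum() * area),
            float(self.I[idx].sum() * area),
        )


def _div_flux(X, mob, dx, dEdx=None, dEdy=None):
    """-div of the no-flux flux  F = -mob*(grad X + X grad E)  (flux form).

    Face fluxes vanish on the boundary, so the cell-sum is conserved to
    machine precision on the closed domain.
    """
    gx = (X[:, 1:] - X[:, :-1]) / dx      # x-face gradients, (ny, nx-1)
    gy = (X[1:, :] - X[:-1, :]) / dx
    if dEdx is not None:
        gx = gx + 0.5 * (X[:, 1:] + X[:, :-1]) * dEdx
        gy = gy + 0.5 * (X[1:, :] + X[:-1, :]) * dEdy
    Fx = -mob * gx
    Fy = -mob * gy
    out = np.zeros_like(X)
    out[:, :-1] -= Fx / dx   # -(F_right - F_left)/dx per cell
    out[:, 1:] += Fx / dx
    out[:-1, :] -= Fy / dx
    out[1:, :] += Fy / dx
    return out


def simulate_pde(
    p: DynamicsParams,
    init: dict,
    dx: float = 0.1,
    t_end: float = 10.0,
    dt: float | None = None,
    seed: int | None = None,
    noise_amp: float = 0.0,
    n_save: int = 20,
) -> Trajectory:
    """Integrate the 5-field model on a no-flux rectangle.

    ``init`` maps field names ("R", "L", "C", "I", "z") to 2D arrays
    (z in nm).  Species use explicit flux-form finite differences
    (mass-conserving to machine precision on the closed domain); the
    membrane's stiff elastic operator is integrated semi-implicitly in a
    cosine basis (Neumann-consistent), with the spring forces explicit.
    The grid spacing should resolve sqrt(kappa/sigma); ``dt`` defaults to
    a conservative stability bound and a caller-supplied ``dt`` above the
    bound raises :class:`CFLError` with a suggestion.  Optional seeded
    white noise of amplitude ``noise_amp`` (nm per sqrt(s)) forces z.
    """
    s = p.springs
    R = np.array(init["R"], dtype=float)
    L = np.array(init["L"], dtype=float)
    C = np.array(init["C"], dtype=float)
    I = np.array(init["I"], dtype=float)
    z = np.array(init["z"], dtype=float) * _NM2UM
    ny, nx = z.shape
    lamC = s.lambda_C * _LAM_NM2UM
    lamI = s.lambda_I * _LAM_NM2UM
    zC, zI = s.z_C * _NM2UM, s.z_I * _NM2UM
    sig = p.sigma * _LAM_NM2UM

    # stability bound: species diffusion + drift + reaction stiffness
    D_max = max(p.D_R, p.D_L, p.D_C, p.D_I)
    E_C0 = lamC * (z - zC) ** 2
    koff_max = p.koff0 * float(np.exp(np.minimum(E_C0, 50.0)).max())
    grad_scale = 2 * max(lamC, lamI) * (zI - zC)  # kT/um over the range
    v_max = D_max * grad_scale
    spring_rate = (2 * lamC * max(C.max(), 1.0) + 2 * lamI * max(I.max(), 1.0)) / p.M
    react_rate = koff_max + p.kon * max(R.max() + L.max(), 1.0)
    dt_bound = 0.5 * min(
        dx * dx / (4 * D_max) if D_max > 0 else np.inf,
        dx / v_max if v_max > 0 else np.inf,
        1.0 / react_rate,
        1.0 / spring_rate,
    )
    if dt is None:
        dt = 0.5 * dt_bound
    elif dt > dt_bound:
        raise CFLError(
            f"dt={dt:g} exceeds the stability bound {dt_bound:g}; "
            f"use dt <= {0.5 * dt_bound:g}"
        )

    # cosine-basis symbol of the implicit elastic operator
    qx = np.pi * np.arange(nx) / (nx * dx)
    qy = np.pi * np.arange(ny) / (ny * dx)
    q2 = qy[:, None] ** 2 + qx[None, :] ** 2
    sym = 1.0 + (dt / p.M) * (p.kappa * q2 * q2 + sig * q2)

    rng = np.random.default_rng(seed)
    n_steps = max(1, int(round(t_end / dt)))
    save_at = np.unique(np.linspace(0, n_steps, n_save).astype(int))
    snaps = {name: [] for name in ("R", "L", "C", "I", "z")}
    times = []

    def record(step):
        times.append(step * dt)
        snaps["R"].append(R.copy())
        snaps["L"].append(L.copy())
        snaps["C"].append(C.copy())
        snaps["I"].append(I.copy())
        snaps["z"].append(z.copy() / _NM2UM)

    record(0)
    for step in range(1, n_steps + 1):
        E_C = lamC * (z - zC) ** 2
        E_I = lamI * (z - zI) ** 2
        dECx = (E_C[:, 1:] - E_C[:, :-1]) / dx
        dECy = (E_C[1:, :] - E_C[:-1, :]) / dx
        dEIx = (E_I[:, 1:] - E_I[:, :-1]) / dx
        dEIy = (E_I[1:, :] - E_I[:-1, :]) / dx
        koff = p.koff0 * np.exp(np.minimum(E_C, 50.0))
        react = p.kon * R * L - koff * C
        dR = _div_flux(R, p.D_R, dx) - react
        dL = _div_flux(L, p.D_L, dx) - react
        dC = _div_flux(C, p.D_C, dx, dECx, dECy) + react
        dI = _div_flux(I, p.D_I, dx, dEIx, dEIy)
        force = -2 * lamC * C * (z - zC) - 2 * lamI * I * (z - zI)
        if noise_amp > 0:
            force = force + (noise_amp * _NM2UM) * p.M * rng.standard_normal(z.shape) / np.sqrt(dt)
        R += dt * dR
        L += dt * dL
        C += dt * dC
        I += dt * dI
        zt = dctn(z + (dt / p.M) * force, type=2, norm="ortho")
        z = idctn(zt / sym, type=2, norm="ortho")
        if step in save_at:
            record(step)

    return Trajectory(
        times=np.array(times),
        R=np.array(snaps["R"]), L=np.array(snaps["L"]),
        C=np.array(snaps["C"]), I=np.array(snaps["I"]),
        z=np.array(snaps["z"]), dx=dx, params=p, seed=seed,
    )


# ---------------------------------------------------------------------------
# Close-contact patch statistics
# ---------------------------------------------------------------------------

def _grf_squared_exponential(shape, corr_len_px, rng):
    """Unit-variance Gaussian random field, squared-exponential covariance."""
    ny, nx = shape
    wn = rng.standard_normal(shape)
    qy = 2 * np.pi * np.fft.fftfreq(ny)
    qx = 2 * np.pi * np.fft.fftfreq(nx)
    q2 = qy[:, None] ** 2 + qx[None, :] ** 2
    # spectrum of exp(-r^2/(2 l^2)) ~ exp(-q^2 l^2 / 2); amplitude = sqrt
    amp = np.exp(-q2 * corr_len_px**2 / 4.0)
    f = np.fft.ifft2(np.fft.fft2(wn) * amp).real
    f /= f.std()
    return f


def close_contact_patch_stats(
    mean_sep: float = 18.0,
    sd_sep: float = 3.0,
    corr_len: float = 30.0,
    threshold: float = 12.0,
    domain_size: float = 4.0,
    dx_nm: float = 5.0,
    n_rep: int = 8,
    seed: int | None = None,
) -> dict:
    """Monte-Carlo statistics of thermal close-contact patches.

    The pre-binding membrane separation is emulated as a stationary
    Gaussian random field (squared-exponential covariance, correlation
    length ``corr_len`` nm) with the given mean and sd (nm); pixels below
    ``threshold`` nm are "close contact" where short bonds can nucleate.
    ``domain_size`` is the side of the simulated patch of membrane in um.
    Returns measured area fraction, mean equivalent-circle patch diameter
    (nm), patch density (um^-2), the Gaussian-tail expectation of the
    area fraction, and Monte-Carlo standard errors over ``n_rep`` fields.
    """
    if sd_sep <= 0:
        raise ValueError("sd_sep must be positive")
    if corr_len <= dx_nm:
        raise ValueError("correlation length must exceed the grid spacing")
    rng = np.random.default_rng(seed)
    npx = int(round(domain_size * 1e3 / dx_nm))
    area_um2 = (npx * dx_nm * 1e-3) ** 2
    fracs, diams, dens, areas = [], [], [], []
    struct = np.ones((3, 3), dtype=int)  # 8-connectivity
    for _ in range(n_rep):
        fld = mean_sep + sd_sep * _grf_squared_exponential((npx, npx), corr_len / dx_nm, rng)
        maskv = fld < threshold
        fracs.append(maskv.mean())
        lab, n_patch = label(maskv, structure=struct)
        if n_patch:
            sizes = np.bincount(lab.ravel())[1:]  # pixels per patch
            d_eq = 2 * np.sqrt(sizes * dx_nm**2 / np.pi)
            diams.append(d_eq.mean())
            areas.append(sizes.mean() * (dx_nm * 1e-3) ** 2)
            dens.append(n_patch / area_um2)
        else:
            diams.append(0.0)
            areas.append(0.0)
            dens.append(0.0)
    fracs = np.array(fracs)
    expected = float(norm.cdf((threshold - mean_sep) / sd_sep))
    return {
        "area_fraction": float(fracs.mean()),
        "area_fraction_se": float(fracs.std(ddof=1) / np.sqrt(n_rep)) if n_rep > 1 else 0.0,
        "expected_area_fraction": expected,
        "mean_patch_diameter_nm": float(np.mean(diams)),
        "mean_patch_area_um2": float(np.mean(areas)),
        "patch_density_um2": float(np.mean(dens)),
        "n_rep": n_rep,
    }


def kd_2d_from_enrichment(B_opt: float, L_fs: float, R_density: float) -> dict:
    """Order-of-magnitude 2D dissociation constant from optimal enrichment.

    Mass action at the optimal separation: B_opt = R L / K_d, so
    K_d = R L / B_opt (um^-2).  The receptor density is a population
    average and the estimate is order-of-magnitude only (flagged).
    """
    if not (B_opt > 0 and L_fs > 0 and R_density > 0):
        raise ValueError("inputs must be positive" if B_opt != 0 else "B_opt = 0")
    return {
        "K_d": R_density * L_fs / B_opt,
        "order_of_magnitude_only": True,
    }
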