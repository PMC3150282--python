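"""Spring energies, Boltzmann exclusion energies and the SQRE line.

The size-exclusion picture: a short receptor--ligand complex (CD2--CD58,
KIR--HLA-Cw6; natural bond length ``z_C`` ~ 12--14 nm) and a long unbound
ligand (ICAM1, exodomain length ``z_I`` ~ 18 nm) both couple elastically to
the local inter-membrane separation ``z``.  Each species pays a quadratic
spring energy

    E_s(z) = lambda_s * (z - z_s)**2        [kT]

for residing at a pixel whose separation differs from its own natural
length (k_B T is absorbed into the spring constants).  At thermodynamic
equilibrium the local concentration of a species follows the Boltzmann
factor ``c = c_ref * exp(-E)`` relative to its optimal reference
environment.  Eliminating the hidden separation from the two quadratics
yields a *linear* relation between the square-root energies (SQRE)
``e_s = sqrt(E_s)``:

    e_I = alpha - beta * e_C,   beta = sqrt(lambda_I / lambda_C),
                                alpha = sqrt(lambda_I) * (z_I - z_C),

valid on the physical branch z_C <= z <= z_I (mutual exclusion: the two
species prefer opposite ends of the separation range, hence the negative
slope).  This line is the falsifiable signature of segregation by size
that the inference machinery tests on image data.

Units throughout: lengths nm, energies kT, spring constants kT nm^-2,
concentrations um^-2, rates s^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import i0, k0

__all__ = [
    "SpringParams",
    "ExclusionEnergies",
    "RegressionLine",
    "NormalizedSeparation",
    "spring_energy",
    "off_rate",
    "boltzmann_concentration",
    "energy_from_concentration",
    "sqre_line_from_springs",
    "separation_from_sqre",
    "effective_spring_constant",
]


@dataclass(frozen=True)
class SpringParams:
    """Elastic parametrisation of the two species.

    Attributes
    ----------
    lambda_C : float
        Spring constant of the receptor--ligand complex, kT nm^-2.
    lambda_I : float
        Spring constant of the long unbound ligand (ICAM1), kT nm^-2.
    z_C : float
        Natural bond length of the complex, nm (12--14 nm for CD2--CD58).
    z_I : float
        Exodomain length of the long ligand, nm (18 nm for ICAM1).
    """

    lambda_C: float
    lambda_I: float
    z_C: float
    z_I: float

    def __post_init__(self) -> None:
        if not (self.lambda_C > 0 and self.lambda_I > 0):
            raise ValueError("spring constants must be positive")
        if not (0 < self.z_C < self.z_I):
            raise ValueError("require 0 < z_C < z_I")


@dataclass(frozen=True)
class ExclusionEnergies:
    """Per-pixel exclusion energies (kT) and their square roots (kT^1/2)."""

    E_C: np.ndarray
    E_I: np.ndarray
    e_C: np.ndarray
    e_I: np.ndarray

    @classmethod
    def from_energies(cls, E_C, E_I) -> "ExclusionEnergies":
        E_C = np.asarray(E_C, dtype=float)
        E_I = np.asarray(E_I, dtype=float)
        if np.any(E_C < 0) or np.any(E_I < 0):
            raise ValueError("exclusion energies must be non-negative")
        return cls(E_C=E_C, E_I=E_I, e_C=np.sqrt(E_C), e_I=np.sqrt(E_I))


@dataclass(frozen=True)
class RegressionLine:
    """The SQRE line e_I = alpha - beta * e_C.

    ``beta`` is the *magnitude* of the slope (the line slopes downward:
    mutual exclusion).  alpha in kT^1/2, beta dimensionless.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("require alpha > 0 and beta > 0")

    def e_I_of(self, e_C):
        """e_I on the line, clipped at zero (energies are non-negative)."""
        return np.maximum(0.0, self.alpha - self.beta * np.asarray(e_C, float))

    @property
    def e_C_max(self) -> float:
        """Zero crossing of the line: the pure long-ligand end."""
        return self.alpha / self.beta


@dataclass(frozen=True)
class NormalizedSeparation:
    """Latent separation rescaled to z_hat = (z - z_C)/(z_I - z_C)."""

    z_hat: np.ndarray


def spring_energy(z, p: SpringParams, species: str):
    """Quadratic spring energy E = lambda * (z - z0)**2 in kT.

    ``species`` is "complex" (minimum at the bond length z_C) or
    "long_ligand" (minimum at the exodomain length z_I; for ICAM1 the
    quadratic represents the interplay of compression against the
    membranes and attractive glycocalyx forces).
    """
    z = np.asarray(z, dtype=float)
    if np.any(z <= 0):
        raise ValueError("separation must be positive")
    if species == "complex":
        lam, z0 = p.lambda_C, p.z_C
    elif species == "long_ligand":
        lam, z0 = p.lambda_I, p.z_I
    else:
        raise ValueError(f"unknown species {species!r}")
    return lam * (z - z0) ** 2


def off_rate(z, p: SpringParams, koff0: float):
    """Separation-dependent complex off-rate koff0 * exp(E_C(z)).

    Stretching the bond away from its natural length accelerates
    unbinding; the on-rate is held constant (the standard simplifying
    assumption -- only the ratio matters for equilibria).
    """
    if not koff0 > 0:
        raise ValueError("koff0 must be positive")
    return koff0 * np.exp(spring_energy(z, p, "complex"))


def boltzmann_concentration(E, ref_conc):
    """Concentration at energy E relative to a reference: c = c_ref exp(-E)."""
    E = np.asarray(E, dtype=float)
    if np.any(E < 0):
        raise ValueError("exclusion energy must be non-negative")
    if np.any(np.asarray(ref_conc, float) < 0):
        raise ValueError("reference concentration must be non-negative")
    return ref_conc * np.exp(-E)


def energy_from_concentration(conc, ref_conc, clamp: bool = False):
    """Exclusion energy E = -ln(conc / ref_conc) >= 0 in kT.

    A concentration above the reference is non-physical enrichment and
    raises, unless ``clamp=True`` in which case E is clamped to 0 (the
    caller has explicitly asked for the boundary).
    """
    conc = np.asarray(conc, dtype=float)
    ref = np.asarray(ref_conc, dtype=float)
    if np.any(conc <= 0) or np.any(ref <= 0):
        raise ValueError("concentrations must be positive")
    ratio = conc / ref
    if np.any(ratio > 1 + 1e-12):
        if not clamp:
            raise ValueError(
                "concentration exceeds reference (non-physical enrichment); "
                "pass clamp=True to clamp at E=0"
            )
        ratio = np.minimum(ratio, 1.0)
    return -np.log(np.minimum(ratio, 1.0))


def sqre_line_from_springs(p: SpringParams) -> RegressionLine:
    """Regression constants of the SQRE line implied by the springs.

    beta = sqrt(lambda_I/lambda_C), alpha = sqrt(lambda_I) * (z_I - z_C).
    On the branch z in [z_C, z_I] the identity e_I = alpha - beta*e_C is
    exact (algebra of the two quadratics).
    """
    beta = float(np.sqrt(p.lambda_I / p.lambda_C))
    alpha = float(np.sqrt(p.lambda_I) * (p.z_I - p.z_C))
    return RegressionLine(alpha=alpha, beta=beta)


def separation_from_sqre(e_C, p: SpringParams) -> NormalizedSeparation:
    """Reconstruct the hidden separation from the complex SQRE.

    On the physical branch z >= z_C (the positive root),
    e_C = sqrt(lambda_C) * (z - z_C), so
    z_hat = e_C / (sqrt(lambda_C) * (z_I - z_C)).
    """
    e_C = np.asarray(e_C, dtype=float)
    if np.any(e_C < 0):
        raise ValueError("SQRE must be non-negative")
    z_hat = e_C / (np.sqrt(p.lambda_C) * (p.z_I - p.z_C))
    return NormalizedSeparation(z_hat=z_hat)


def effective_spring_constant(
    kappa: float,
    sigma: float,
    a: float,
    outer_radius_factor: float = 20.0,
):
    """Point-load stiffness of a tension + bending-rigidity sheet.

    The membrane is modelled as an infinite elastic sheet with bending
    rigidity ``kappa`` (kT) and surface tension ``sigma`` (kT nm^-2); a
    protein of radius ``a`` (nm) pushing on it feels an effective
    harmonic restoring constant (kT nm^-2).  The deflection field obeys

        kappa * lap^2 w - sigma * lap w = 0        (r > a),

    whose radial solutions are spanned by {1, ln r, K0(r/l), I0(r/l)}
    with l = sqrt(kappa/sigma).  We load the rim r = a with unit total
    force, clamp the sheet at R = outer_radius_factor * l (the tension
    response is logarithmic, so a finite support radius is required; the
    result depends on it only logarithmically), solve the 4x4 boundary
    system exactly, and return stiffness = F / w(a).

    Returns ``(lam_eff, valid)`` where ``valid`` flags the small-protein
    regime a << l in which the sheet model applies.
    """
    if not (kappa > 0 and sigma > 0 and a > 0):
        raise ValueError("kappa, sigma, a must be positive")
    ell = float(np.sqrt(kappa / sigma))
    valid = a < 0.2 * ell
    R = outer_radius_factor * ell
    if R <= a * 1.5:
        raise ValueError("outer radius must exceed the protein radius")

    # Basis w(r) = c0 + c1 ln(r) + c2 K0(r/l) + c3 I0(r/l).
    # Conditions: w(R)=0, w'(R)=0 (clamped far field), zero bending moment
    # at the rim (lap w (a) = 0: the protein applies pure transverse
    # force), and unit total transverse force through the rim:
    #   2 pi a [kappa * d/dr(lap w) - sigma * w'] |_{r=a} = 1.
    from scipy.special import i1, k1

    def basis_rows(r):
        x = r / ell
        w = np.array([1.0, np.log(r), k0(x), i0(x)])
        wp = np.array([0.0, 1.0 / r, -k1(x) / ell, i1(x) / ell])
        # lap of K0(r/l) = K0/l^2; of I0 = I0/l^2; of ln r and 1: 0
        lap = np.array([0.0, 0.0, k0(x) / ell**2, i0(x) / ell**2])
        lap_p = np.array([0.0, 0.0, -k1(x) / ell**3, i1(x) / ell**3])
        return w, wp, lap, lap_p

    wR, wpR, _, _ = basis_rows(R)
    wa, wpa, lapa, lap_pa = basis_rows(a)
    A = np.vstack(
        [
            wR,
            wpR,
            lapa,
            2 * np.pi * a * (kappa * lap_pa - sigma * wpa),
        ]
    )
    b = np.array([0.0, 0.0, 0.0, 1.0])  # unit force pushing w positive at the rim
    c = np.linalg.solve(A, b)
    w_a = float(c @ wa)
    lam_eff = 1.0 / w_a
    return lam_eff, bool(valid)
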