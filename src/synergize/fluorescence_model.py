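"""Photon-count observation model for two-colour synapse images.

A fluorescence measurement is a count of contributing fluorophores per
pixel, so after deconvolution pixels are modelled as independent draws
from a counting distribution (Poisson by default; Gaussian or Gamma
variants absorb detector gain and the skew seen in cell-conjugate data).

Free-surface (fs) pixels have homogeneous means per channel and pin down
the global parameter combinations.  Contact-interface (ci) pixels carry
the biophysics through the per-pixel SQREs:

    small-ligand channel:  mu = Gamma * mu_fs_small * + A_B * exp(-e_C^2) + bg
    long-ligand  channel:  mu = mu_fs_long * exp(-e_I^2) + bg

i.e. free (barrier-discounted) ligand + bound complex + background for
the small species, and Boltzmann-excluded free ligand for the long one.
Emission/detection efficiencies are never separated from concentrations:
only the products (the mu's and A_B) are exposed or estimable.

For 3D z-stacks the membrane has an apparent thickness; a transect
perpendicular to the contour is modelled with a Gaussian profile whose
amplitude carries the concentration signal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import gammaln

__all__ = [
    "FluorModelSpec",
    "PixelObservation",
    "ci_mean_small",
    "ci_mean_long",
    "fs_mean",
    "pixel_loglik",
    "thickness_profile",
    "image_loglik",
]

_FAMILIES = ("poisson", "gaussian", "gamma")


@dataclass(frozen=True)
class FluorModelSpec:
    """Global observation-model parameters.

    Attributes
    ----------
    mu_fs_small, mu_fs_long : float
        Free-surface mean counts per channel (concentration x efficiency).
    A_B : float
        Optimal-binding complex amplitude in counts: the small-channel
        enrichment at a pixel where the complex sits at its energy
        minimum (e_C = 0).
    Gamma_barrier : float
        Entry-barrier discount on the free small ligand inside the
        contact interface, in (0, 1].
    bg_small, bg_long : float
        Background (autofluorescence) counts per channel.
    noise_family : str
        "poisson", "gaussian" (variance = overdispersion * mean) or
        "gamma" (shape = overdispersion, scale = mean / shape).
    overdispersion : float
        Family-specific positive scalar; unused by poisson.
    thickness_fs, thickness_ci : float
        Apparent membrane widths in pixels (3D stacks only); the free
        surface is at least as wide as the contact interface.
    """

    mu_fs_small: float = 50.0
    mu_fs_long: float = 100.0
    A_B: float = 200.0
    Gamma_barrier: float = 0.63
    bg_small: float = 0.0
    bg_long: float = 0.0
    noise_family: str = "poisson"
    overdispersion: float = 1.0
    thickness_fs: float = 2.0
    thickness_ci: float = 1.2

    def __post_init__(self) -> None:
        if self.noise_family not in _FAMILIES:
            raise ValueError(f"noise_family must be one of {_FAMILIES}")
        if not (0 < self.Gamma_barrier <= 1):
            raise ValueError("Gamma_barrier must be in (0, 1]")
        for name in ("mu_fs_small", "mu_fs_long", "A_B", "bg_small", "bg_long"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.overdispersion <= 0:
            raise ValueError("overdispersion must be positive")
        if self.thickness_fs < self.thickness_ci:
            raise ValueError("free-surface width must be >= interface width")

    def with_(self, **kw) -> "FluorModelSpec":
        return replace(self, **kw)


@dataclass(frozen=True)
class PixelObservation:
    """One pixel's counts with its region label (and 3D transect offset)."""

    counts_small: float
    counts_long: float
    region: str  # "free_surface" | "contact_interface"
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.counts_small < 0 or self.counts_long < 0:
            raise ValueError("counts must be non-negative")
        if self.region not in ("free_surface", "contact_interface"):
            raise ValueError("region must be free_surface or contact_interface")


def fs_mean(spec: FluorModelSpec, channel: str):
    """Free-surface expected counts (ligand level + background)."""
    if channel == "small":
        return spec.mu_fs_small + spec.bg_small
    if channel == "long":
        return spec.mu_fs_long + spec.bg_long
    raise ValueError("channel must be 'small' or 'long'")


def ci_mean_small(spec: FluorModelSpec, e_C):
    """Contact-interface mean of the small-ligand channel at SQRE e_C."""
    e_C = np.asarray(e_C, dtype=float)
    if np.any(e_C < 0):
        raise ValueError("SQRE must be non-negative")
    return (
        spec.Gamma_barrier * spec.mu_fs_small
        + spec.A_B * np.exp(-(e_C**2))
        + spec.bg_small
    )


def ci_mean_long(spec: FluorModelSpec, e_I):
    """Contact-interface mean of the long-ligand channel at SQRE e_I.

    No enrichment is possible: the long ligand does not bind, so its
    mean never exceeds the free-surface level (plus background).
    """
    e_I = np.asarray(e_I, dtype=float)
    if np.any(e_I < 0):
        raise ValueError("SQRE must be non-negative")
    return spec.mu_fs_long * np.exp(-(e_I**2)) + spec.bg_long


def pixel_loglik(counts, mean, spec: FluorModelSpec):
    """Log-likelihood of counts under the spec's noise family.

    Poisson uses the continuous extension (log-gamma in place of the
    factorial) so deconvolved non-integer counts are handled; Gaussian
    has variance = overdispersion * mean; Gamma has shape k =
    overdispersion and scale mean/k, capturing free-surface skew.
    """
    counts = np.asarray(counts, dtype=float)
    mean = np.asarray(mean, dtype=float)
    if np.any(mean <= 0):
        raise ValueError("mean must be positive")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    fam = spec.noise_family
    if fam == "poisson":
        return counts * np.log(mean) - mean - gammaln(counts + 1.0)
    if fam == "gaussian":
        var = spec.overdispersion * mean
        return -0.5 * (np.log(2 * np.pi * var) + (counts - mean) ** 2 / var)
    # gamma: shape k, scale mean/k  (zero counts have -inf density for k>1)
    k = spec.overdispersion
    theta = mean / k
    with np.errstate(divide="ignore"):
        return (k - 1) * np.log(counts) - counts / theta - k * np.log(theta) - gammaln(k)


def thickness_profile(spec: FluorModelSpec, amplitude, offset, region: str):
    """Expected counts on a transect across the membrane contour (3D).

    Gaussian cross-section: amplitude * exp(-offset^2 / (2 width^2)) +
    background, with the region-specific apparent width.  Background is
    the small-channel one by convention unless the caller adds its own.
    """
    width = spec.thickness_ci if region == "contact_interface" else spec.thickness_fs
    if width <= 0:
        raise ValueError("membrane width must be positive")
    offset = np.asarray(offset, dtype=float)
    return np.asarray(amplitude, float) * np.exp(-(offset**2) / (2 * width**2))


def image_loglik(
    counts_small,
    counts_long,
    fs_mask,
    ci_mask,
    e_C,
    e_I,
    spec: FluorModelSpec,
):
    """Total log-likelihood of a two-channel image.

    ``fs_mask``/``ci_mask`` are boolean arrays partitioning the analysed
    pixels; ``e_C``/``e_I`` give the SQREs for the ci pixels (flat arrays
    in ci_mask order, i.e. counts[ci_mask] order).
    """
    counts_small = np.asarray(counts_small, dtype=float)
    counts_long = np.asarray(counts_long, dtype=float)
    fs_mask = np.asarray(fs_mask, dtype=bool)
    ci_mask = np.asarray(ci_mask, dtype=bool)
    if np.any(fs_mask & ci_mask):
        raise ValueError("region masks must be disjoint")
    if fs_mask.sum() == 0 or ci_mask.sum() == 0:
        raise ValueError("both regions must contain pixels")
    ll = 0.0
    ll += pixel_loglik(counts_small[fs_mask], fs_mean(spec, "small"), spec).sum()
    ll += pixel_loglik(counts_long[fs_mask], fs_mean(spec, "long"), spec).sum()
    ll += pixel_loglik(counts_small[ci_mask], ci_mean_small(spec, e_C), spec).sum()
    ll += pixel_loglik(counts_long[ci_mask], ci_mean_long(spec, e_I), spec).sum()
    return float(ll)
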