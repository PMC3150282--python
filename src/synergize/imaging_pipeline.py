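"""Image I/O, preprocessing, deconvolution, contour tracking, regions.

The measurement chain for real data: flat-field/background correction,
Richardson--Lucy deconvolution against a measured PSF, a single global
chromatic-shift correction between the channels, then region extraction
-- for 2D bilayer images a pair of user-supplied masks, for 3D z-stacks
a per-slice membrane contour traced on the summed-channel image with
user-annotated contact-interface limits, plus perpendicular transect
samples feeding the membrane-thickness model.

Coordinates are 0-based (row, col[, slice]); masks are written as
unsigned-byte TIFF; everything is deterministic given inputs and config.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = [
    "TwoChannelImage",
    "RegionMasks",
    "load_two_channel_tiff",
    "save_masks_tiff",
    "preprocess",
    "richardson_lucy",
    "correct_chromatic_shift",
    "track_contour",
    "extract_regions",
    "channel_correlation",
]

BILAYER_PIXEL_NM = 167.0
STACK_VOXEL_NM = (93.0, 93.0, 360.0)


@dataclass
class TwoChannelImage:
    """Two-channel 2D image or 3D z-stack (non-negative intensities)."""

    small: np.ndarray
    long: np.ndarray
    pixel_size_nm: float = BILAYER_PIXEL_NM
    channel_names: tuple = ("small_ligand", "long_ligand")

    def __post_init__(self) -> None:
        self.small = np.asarray(self.small, float)
        self.long = np.asarray(self.long, float)
        if self.small.shape != self.long.shape:
            raise ValueError("channel shapes must match")

    @property
    def is_stack(self) -> bool:
        return self.small.ndim == 3


@dataclass
class RegionMasks:
    """Free-surface / contact-interface partition (+ 3D contour chains)."""

    free_surface: np.ndarray
    contact_interface: np.ndarray
    contours: list = field(default_factory=list)       # per-slice (n,2) chains
    contour_labels: list = field(default_factory=list)  # per-slice str arrays
    transect_offsets: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.free_surface = np.asarray(self.free_surface, bool)
        self.contact_interface = np.asarray(self.contact_interface, bool)
        if np.any(self.free_surface & self.contact_interface):
            raise ValueError("region masks must be disjoint")


def load_two_channel_tiff(path_small, path_long, pixel_size_nm=BILAYER_PIXEL_NM):
    return TwoChannelImage(
        small=tifffile.imread(path_small),
        long=tifffile.imread(path_long),
        pixel_size_nm=pixel_size_nm,
    )


def save_masks_tiff(masks: RegionMasks, path) -> None:
    """Masks as a 2-page uint8 TIFF (page 0 fs, page 1 ci)."""
    arr = np.stack(
        [masks.free_surface.astype(np.uint8), masks.contact_interface.astype(np.uint8)]
    )
    tifffile.imwrite(path, arr)


def preprocess(image, flat_field=None, background=0.0, warn_clip_frac=0.05):
    """Flat-field division and background subtraction, clipped at zero.

    Returns ``(corrected, clip_fraction)``; a clip fraction above
    ``warn_clip_frac`` triggers a warning (the background estimate is
    probably too high).
    """
    img = np.asarray(image, float)
    if flat_field is not None:
        ff = np.asarray(flat_field, float)
        if np.any(ff <= 0):
            raise ValueError("flat field must be positive")
        img = img / ff
    img = img - background
    clip_frac = float((img < 0).mean())
    if clip_frac > warn_clip_frac:
        warnings.warn(
            f"{clip_frac:.1%} of pixels clipped at zero after background "
            "subtraction", stacklevel=2)
    return np.maximum(img, 0.0), clip_frac


def richardson_lucy(image, psf, n_iter: int = 50):
    """Richardson--Lucy deconvolution (multiplicative updates).

    The PSF is normalised to unit sum (with a warning if it was not).
    Convolutions use reflective boundaries, so a flat image is an exact
    fixed point and edges are not darkened over the iterations (an
    FFT/zero-padded implementation leaks boundary error a PSF-radius per
    iteration).  Non-negativity is preserved by construction and total
    intensity is approximately conserved.
    """
    from scipy.ndimage import convolve as ndconvolve

    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    psf = np.asarray(psf, float)
    s = psf.sum()
    if s <= 0:
        raise ValueError("PSF must have positive sum")
    if abs(s - 1.0) > 1e-6:
        warnings.warn("PSF not normalised; normalising to unit sum", stacklevel=2)
        psf = psf / s
    img = np.maximum(np.asarray(image, float), 0.0)
    psf_mirror = psf[::-1, ::-1]
    est = np.full_like(img, max(img.mean(), 1e-12))
    eps = 1e-12
    for _ in range(n_iter):
        blurred = ndconvolve(est, psf, mode="reflect")
        ratio = img / np.maximum(blurred, eps)
        est = est * ndconvolve(ratio, psf_mirror, mode="reflect")
    return np.maximum(est, 0.0)


def correct_chromatic_shift(ch1, ch2, max_shift_px: int = 3, mask=None):
    """Global integer chromatic shift between channels.

    Scans all integer shifts within ``max_shift_px`` and picks the one
    maximising the *magnitude* of the Pearson correlation on the
    overlap -- synapse channels are anti-correlated, so the magnitude is
    the right objective (a bead/fiducial image gives the same answer).
    ``mask`` restricts the objective to the cell of interest (the
    structureless background otherwise dilutes the correlation peak).
    Returns ``(shift, ch2_shifted)``: ``shift`` is the displacement
    (drow, dcol) of ch2 relative to ch1 (ch2 ~ ch1 translated by shift),
    and ``ch2_shifted`` has that displacement undone (zero-filled edges).
    """
    a = np.asarray(ch1, float)
    b = np.asarray(ch2, float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("cannot register a flat (zero-variance) channel")
    mask = np.ones(a.shape, bool) if mask is None else np.asarray(mask, bool)
    best, best_val = (0, 0), -np.inf
    m = max_shift_px
    for dr in range(-m, m + 1):
        for dc in range(-m, m + 1):
            sl_a = (slice(max(dr, 0) or None, a.shape[0] + min(dr, 0) or None),
                    slice(max(dc, 0) or None, a.shape[1] + min(dc, 0) or None))
            sl_b = (slice(max(-dr, 0) or None, b.shape[0] + min(-dr, 0) or None),
                    slice(max(-dc, 0) or None, b.shape[1] + min(-dc, 0) or None))
            keep = mask[sl_a]
            a_sl = a[sl_a][keep]
            b_sl = b[sl_b][keep]
            if a_sl.size < 9 or a_sl.std() == 0 or b_sl.std() == 0:
                continue
            r = abs(np.corrcoef(a_sl, b_sl)[0, 1])
            if r > best_val:
                best_val, best = r, (dr, dc)
    dr, dc = best
    shifted = np.zeros_like(b)
    src = (slice(max(-dr, 0), b.shape[0] + min(-dr, 0)),
           slice(max(-dc, 0), b.shape[1] + min(-dc, 0)))
    dst = (slice(max(dr, 0), b.shape[0] + min(dr, 0)),
           slice(max(dc, 0), b.shape[1] + min(dc, 0)))
    shifted[dst] = b[src]
    return (-dr, -dc), shifted


def track_contour(
    slice_img,
    seed_point,
    intensity_threshold: float,
    n_angles: int = 720,
    max_radius_jump: float = 4.0,
):
    """Trace the closed membrane ridge around a cell in one slice.

    Ridge following in polar coordinates about the cell centre (an
    intensity-weighted refinement of ``seed_point``): for each angle the
    maximum-intensity radius is taken on a lightly smoothed image,
    subject to a continuity limit of ``max_radius_jump`` px between
    neighbouring angles; the radial profile r(theta) is then smoothed
    with a short circular moving average (shot noise makes the raw
    argmax meander off the ridge centre-line) and consecutive polar
    samples are joined with 8-connected line segments.  The chain is
    ordered counter-clockwise (in array coordinates) regardless of the
    seed, and closed.  A broken ridge (sub-threshold maximum) raises
    with the gap's angular location.
    """
    from scipy.ndimage import gaussian_filter

    img = np.asarray(slice_img, float)
    img = gaussian_filter(img, 1.0)
    ny, nx = img.shape
    r0, c0 = seed_point
    # refine centre on the bright neighbourhood
    yy, xx = np.mgrid[0:ny, 0:nx]
    w = np.where(img > intensity_threshold, img, 0.0)
    if w.sum() > 0:
        r0 = float((yy * w).sum() / w.sum())
        c0 = float((xx * w).sum() / w.sum())
    max_r = min(ny, nx) / 2.0 - 1
    radii = np.arange(1.0, max_r, 0.5)
    angles = np.linspace(-np.pi, np.pi, n_angles, endpoint=False)
    from scipy.ndimage import map_coordinates

    ridge_r = np.empty(n_angles)
    prev = None
    for i, th in enumerate(angles):
        rr = r0 + radii * np.sin(th)
        cc = c0 + radii * np.cos(th)
        prof = map_coordinates(img, [rr, cc], order=1, mode="constant")
        if prev is not None:
            ok = np.abs(radii - prev) <= max_radius_jump
            cand = np.where(ok, prof, -np.inf)
        else:
            cand = prof
        j = int(np.argmax(cand))
        if cand[j] < intensity_threshold:
            raise ValueError(
                f"broken membrane ridge near angle {np.degrees(th):.0f} deg "
                f"(max intensity {prof.max():.3g} below threshold)")
        prev = radii[j]
        ridge_r[i] = radii[j]

    # circular moving average of the radial profile
    w = 9
    kern = np.ones(w) / w
    padded = np.concatenate([ridge_r[-(w // 2):], ridge_r, ridge_r[: w // 2]])
    ridge_r = np.convolve(padded, kern, mode="valid")

    # resample the polar path at ~1 px arc spacing: rasterising every
    # sub-pixel angular step would zig-zag and inflate the chain
    step = max(1, int(round(n_angles / (2 * np.pi * max(ridge_r.mean(), 1.0)))))
    angles = angles[::step]
    ridge_r = ridge_r[::step]

    pts_r = r0 + ridge_r * np.sin(angles)
    pts_c = c0 + ridge_r * np.cos(angles)
    from skimage.draw import line

    chain: list[tuple[int, int]] = []
    n = len(angles)
    for i in range(n):
        r1, c1 = int(round(pts_r[i])), int(round(pts_c[i]))
        r2, c2 = int(round(pts_r[(i + 1) % n])), int(round(pts_c[(i + 1) % n]))
        rr, cc = line(r1, c1, r2, c2)
        seg = list(zip(rr.tolist(), cc.tolist()))[:-1]  # drop duplicate endpoint
        chain.extend(seg if seg else [(r1, c1)])
    out: list[tuple[int, int]] = []
    for pt in chain:
        if not out or pt != out[-1]:
            out.append(pt)
    if len(out) > 1 and out[0] == out[-1]:
        out.pop()
    return np.array(out, dtype=int)


def extract_regions(
    stack,
    contours: list,
    interface_annotations: list,
    transect_halfwidth: int = 3,
):
    """Region masks and transect samples from per-slice contour chains.

    ``interface_annotations`` gives, per slice, ``None`` (slice unusable
    / skipped) or a pair of indices (i0, i1) into the slice's contour
    chain delimiting the contact-interface arc (wrapping allowed).
    Contour pixels inside the arc are labelled contact interface, the
    rest free surface; for each contour pixel, samples along the local
    outward normal at offsets -transect_halfwidth..+transect_halfwidth
    px are recorded for the membrane-thickness model.

    Returns ``(RegionMasks, transects)`` where transects is a list of
    dicts with slice index, contour position, region, offsets, values.
    """
    stack = np.asarray(stack, float)
    if stack.ndim != 3:
        raise ValueError("expected a z-stack (slices, rows, cols)")
    ns, ny, nx = stack.shape
    fs = np.zeros((ny, nx), bool)
    ci = np.zeros((ny, nx), bool)
    labels_all: list[np.ndarray] = []
    transects: list[dict] = []
    offsets = np.arange(-transect_halfwidth, transect_halfwidth + 1, dtype=float)
    from scipy.ndimage import map_coordinates

    for si, chain in enumerate(contours):
        ann = interface_annotations[si] if si < len(interface_annotations) else None
        n = len(chain)
        if n == 0 or ann is None:
            labels_all.append(np.empty(0, dtype="U16"))
            continue
        i0, i1 = ann
        if not (0 <= i0 < n and 0 <= i1 < n):
            raise ValueError(f"slice {si}: annotation indices outside contour")
        idx = np.arange(n)
        in_ci = ((idx - i0) % n) <= ((i1 - i0) % n)
        labels = np.where(in_ci, "contact", "free").astype("U16")
        labels_all.append(labels)
        centre = chain.mean(axis=0)
        for j, (r, c) in enumerate(chain):
            (ci if in_ci[j] else fs)[r, c] = True
            nb = chain[(j + 2) % n] - chain[(j - 2) % n]
            t_norm = np.hypot(*nb)
            if t_norm == 0:
                continue
            normal = np.array([nb[1], -nb[0]]) / t_norm
            if np.dot(normal, np.array([r, c]) - centre) < 0:
                normal = -normal  # signed toward the cell exterior
            rr = r + offsets * normal[0]
            cc = c + offsets * normal[1]
            vals = map_coordinates(stack[si], [rr, cc], order=1, mode="nearest")
            transects.append({
                "slice": si, "index": j,
                "region": "contact_interface" if in_ci[j] else "free_surface",
                "offsets": offsets.copy(), "values": vals,
            })
    fs &= ~ci  # ci wins where arcs touch
    return RegionMasks(
        free_surface=fs, contact_interface=ci,
        contours=list(contours), contour_labels=labels_all,
        transect_offsets=offsets,
    ), transects


def channel_correlation(image: TwoChannelImage, mask) -> float:
    """Pearson correlation between the channels over masked pixels.

    The headline mutual-exclusion statistic: patterned synapses show
    significantly negative values (the experimental systems ranged from
    -0.39 to -0.69 per synapse).
    """
    mask = np.asarray(mask, bool)
    a = image.small[mask]
    b = image.long[mask]
    if a.size < 2:
        raise ValueError("need at least 2 pixels")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance within mask")
    return float(np.corrcoef(a, b)[0, 1])
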