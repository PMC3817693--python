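"""Density simulation and scoring.

Two scoring routes are provided:

* :func:`masked_residue_cc` — the classic masked real-space correlation: a
  Pearson correlation of calculated vs. observed density over a neighbourhood
  mask around each residue, recomputed from the current coordinates on every
  call.  Robust, interpretable, slow.

* :func:`build_spline_field` / :func:`fast_density_score` — the fast unmasked
  score: for each atom type the cross-correlation (atom kernel * rho_obs) is
  computed once over the whole map by Fourier-space convolution on a densely
  sampled grid, and a tricubic B-spline over that field then gives the
  per-atom score contribution and its analytic gradient in O(1) per atom.
  The per-call cost is linear in the number of atoms and independent of map
  size, which is what makes density-guided minimization cheap.

Atoms are modelled as isotropic Gaussians with sigma = resolution/(pi*sqrt(2))
and amplitudes proportional to electron counts; each residue contributes its
backbone N/CA/C/O plus a virtual-CB side-chain centroid.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import fft as sp_fft
from scipy import ndimage

from . import constants as k
from .model import BackboneModel

_SUPPORT_SIGMAS = 4.5  # real-space kernel support used in direct summation
_INTERIOR_MARGIN = 2.0  # voxels; evaluation clamps to this margin


@dataclasses.dataclass
class DensityMap:
    """Orthogonal 3D density grid. ``values[i, j, k]`` sits at
    ``origin + (i, j, k) * spacing`` (axes x, y, z)."""

    values: np.ndarray
    spacing: np.ndarray  # (3,) A per step
    origin: np.ndarray   # (3,) A
    resolution: float    # nominal high-resolution limit, A

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.spacing = np.broadcast_to(np.asarray(self.spacing, float), (3,)).copy()
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("map contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def world_to_grid(self, pts: np.ndarray) -> np.ndarray:
        return (np.asarray(pts, float) - self.origin) / self.spacing

    def grid_to_world(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx, float) * self.spacing + self.origin

    def standardized(self) -> "DensityMap":
        v = self.values
        sd = v.std()
        if sd == 0:
            raise ValueError("zero-variance map")
        return DensityMap((v - v.mean()) / sd, self.spacing.copy(),
                          self.origin.copy(), self.resolution)


@dataclasses.dataclass(frozen=True)
class AtomKernel:
    """Isotropic Gaussian scattering kernel for one atom type."""

    atom_type: str
    sigma: float      # A
    amplitude: float  # integrated mass (~ electron count)

    @classmethod
    def for_resolution(cls, atom_type: str, resolution: float) -> "AtomKernel":
        sigma = resolution / (math.pi * math.sqrt(2.0))
        return cls(atom_type, sigma, k.ATOM_ELECTRONS[atom_type])

    def real_space(self, r2: np.ndarray) -> np.ndarray:
        """Density at squared distance r2, normalised to integrate to
        ``amplitude``."""
        norm = self.amplitude / ((2.0 * math.pi) ** 1.5 * self.sigma**3)
        return norm * np.exp(-0.5 * r2 / self.sigma**2)

    def fourier(self, k2: np.ndarray) -> np.ndarray:
        """Fourier transform at squared spatial frequency k2 (cycles/A)^2."""
        return self.amplitude * np.exp(-2.0 * math.pi**2 * self.sigma**2 * k2)


def default_kernels(resolution: float) -> dict[str, AtomKernel]:
    return {t: AtomKernel.for_resolution(t, resolution) for t in k.ATOM_TYPES}


def _model_atoms(model: BackboneModel):
    """(positions (m,3), type index (m,), residue index (m,)) for all finite
    atoms incl. the virtual CB centroid.

    Type indices follow ``constants.ATOM_TYPES`` = (N, CA, C, O, CB); the CB
    slot is the virtual side-chain centroid, present for every residue with
    full N/CA/C coordinates.
    """
    n = model.n_res
    has = np.isfinite(model.coords[:, :3]).all(axis=(1, 2))  # N, CA, C present
    pos5 = np.concatenate([model.coords, model.virtual_cb()[:, None, :]], axis=1)
    fin = np.isfinite(pos5).all(axis=2) & has[:, None]
    res, types = np.nonzero(fin)
    return pos5[res, types], types, res


def simulate_map(model: BackboneModel, spacing: float, resolution: float,
                 padding: float = 6.0) -> DensityMap:
    """Sum of per-atom Gaussian kernels on an orthogonal grid enclosing the
    model plus ``padding`` on every side."""
    if spacing > resolution / 3.0 + 1e-9:
        raise ValueError(
            f"spacing {spacing} too coarse for resolution {resolution}: "
            f"need spacing <= resolution/3 = {resolution / 3.0:.3f} A"
        )
    pos, types, _ = _model_atoms(model)
    if len(pos) == 0:
        raise ValueError("model has no atoms with coordinates")
    lo = pos.min(axis=0) - padding
    hi = pos.max(axis=0) + padding
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    dmap = DensityMap(np.zeros(shape), np.full(3, float(spacing)), lo, resolution)
    kernels = default_kernels(resolution)
    _add_atoms(dmap, pos, [k.ATOM_TYPES[t] for t in types], kernels)
    return dmap


def simulate_on_grid(model: BackboneModel, like: DensityMap,
                     resolution: float | None = None) -> DensityMap:
    """Simulate model density on an existing map's grid geometry."""
    res = like.resolution if resolution is None else resolution
    dmap = DensityMap(np.zeros(like.shape), like.spacing.copy(), like.origin.copy(), res)
    pos, types, _ = _model_atoms(model)
    kernels = default_kernels(res)
    _add_atoms(dmap, pos, [k.ATOM_TYPES[t] for t in types], kernels)
    return dmap


def _add_atoms(dmap: DensityMap, pos, type_names, kernels) -> None:
    shape = np.asarray(dmap.shape)
    for p, tname in zip(pos, type_names):
        ker = kernels[tname]
        r = _SUPPORT_SIGMAS * ker.sigma
        gi = dmap.world_to_grid(p)
        lo = np.maximum(np.ceil(gi - r / dmap.spacing), 0).astype(int)
        hi = np.minimum(np.floor(gi + r / dmap.spacing), shape - 1).astype(int)
        if np.any(lo > hi):
            continue
        ax = [np.arange(lo[d], hi[d] + 1) * dmap.spacing[d] + dmap.origin[d] - p[d]
              for d in range(3)]
        r2 = (ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
              + ax[2][None, None, :] ** 2)
        dmap.values[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] += \
            ker.real_space(r2)


# ---------------------------------------------------------------------------
# Masked per-residue correlation (the original slow score).
# ---------------------------------------------------------------------------

def masked_residue_cc(model: BackboneModel, observed: DensityMap,
                      mask_radius: float = 3.2):
    """Per-residue Pearson correlation of calculated vs. observed density over
    voxels within ``mask_radius`` of any atom of the residue.

    Returns ``(per_residue, total)`` where ``per_residue`` is an (n,) array
    with NaN for residues whose mask is empty, and ``total`` is the negative
    mean over defined residues (lower is better).
    """
    calc = simulate_on_grid(model, observed)
    cb = model.virtual_cb()
    shape = np.asarray(observed.shape)
    per_res = np.full(model.n_res, np.nan)
    for i in range(model.n_res):
        if not model.has_coords(i):
            continue
        atoms = np.vstack([model.coords[i, :4], cb[i:i + 1]])
        atoms = atoms[np.isfinite(atoms).all(axis=1)]
        gi = observed.world_to_grid(atoms)
        lo = np.maximum(np.floor(gi.min(0) - mask_radius / observed.spacing), 0).astype(int)
        hi = np.minimum(np.ceil(gi.max(0) + mask_radius / observed.spacing),
                        shape - 1).astype(int)
        if np.any(lo > hi):
            continue
        ax = [np.arange(lo[d], hi[d] + 1) * observed.spacing[d] + observed.origin[d]
              for d in range(3)]
        in_mask = np.zeros(tuple(hi - lo + 1), dtype=bool)
        for p in atoms:
            r2 = ((ax[0] - p[0])[:, None, None] ** 2
                  + (ax[1] - p[1])[None, :, None] ** 2
                  + (ax[2] - p[2])[None, None, :] ** 2)
            in_mask |= r2 <= mask_radius**2
        if not in_mask.any():
            continue
        sub = (slice(lo[0], hi[0] + 1), slice(lo[1], hi[1] + 1), slice(lo[2], hi[2] + 1))
        a = calc.values[sub][in_mask]
        b = observed.values[sub][in_mask]
        if a.std() == 0 or b.std() == 0:
            continue
        per_res[i] = float(np.corrcoef(a, b)[0, 1])
    defined = np.isfinite(per_res)
    total = -float(np.mean(per_res[defined])) if defined.any() else 0.0
    return per_res, total


# ---------------------------------------------------------------------------
# Fast unmasked score: FFT convolution + tricubic B-spline field.
# ---------------------------------------------------------------------------

def _bspline_weights(u: np.ndarray):
    """Cubic B-spline basis weights and derivatives for fractional offsets u
    in [0, 1). Returns (w, dw), each (m, 4) for taps at offsets -1..2."""
    u2 = u * u
    u3 = u2 * u
    w = np.stack([
        (1 - u) ** 3 / 6.0,
        (3 * u3 - 6 * u2 + 4) / 6.0,
        (-3 * u3 + 3 * u2 + 3 * u + 1) / 6.0,
        u3 / 6.0,
    ], axis=-1)
    dw = np.stack([
        -((1 - u) ** 2) / 2.0,
        (3 * u2 - 4 * u) / 2.0,
        (-3 * u2 + 2 * u + 1) / 2.0,
        u2 / 2.0,
    ], axis=-1)
    return w, dw


class SplineScoreField:
    """Per-atom-type cross-correlation fields with tricubic B-spline
    evaluation of values and analytic gradients.

    The fields are periodic (they come out of an FFT), so the spline uses
    wrap boundary conditions; evaluation points are clamped to an interior
    margin and a clamp counter is kept so refinement excursions outside the
    box degrade gracefully instead of crashing.
    """

    def __init__(self, values: dict[str, np.ndarray], origin: np.ndarray,
                 spacing: np.ndarray, source_resolution: float):
        self.node_values = values
        self.origin = np.asarray(origin, float)
        self.spacing = np.asarray(spacing, float)
        self.source_resolution = float(source_resolution)
        self.shape = next(iter(values.values())).shape
        self.coeffs = {
            t: ndimage.spline_filter(v, order=3, mode="grid-wrap")
            for t, v in values.items()
        }
        self.n_clamped = 0

    def interpolate(self, atom_type: str, pts: np.ndarray,
                    with_gradient: bool = True):
        """Spline value (and gradient, per A) at world points (m, 3)."""
        pts = np.atleast_2d(np.asarray(pts, float))
        t = (pts - self.origin) / self.spacing
        shape = np.asarray(self.shape)
        lo = _INTERIOR_MARGIN
        hi = shape - 1 - _INTERIOR_MARGIN
        clamped = np.clip(t, lo, hi)
        self.n_clamped += int(np.sum(np.any(clamped != t, axis=1)))
        t = clamped
        base = np.floor(t).astype(int)
        u = t - base
        coeffs = self.coeffs[atom_type]
        wx, dwx = _bspline_weights(u[:, 0])
        wy, dwy = _bspline_weights(u[:, 1])
        wz, dwz = _bspline_weights(u[:, 2])
        offs = np.arange(-1, 3)
        ix = (base[:, 0:1] + offs) % shape[0]
        iy = (base[:, 1:2] + offs) % shape[1]
        iz = (base[:, 2:3] + offs) % shape[2]
        block = coeffs[ix[:, :, None, None], iy[:, None, :, None], iz[:, None, None, :]]
        val = np.einsum("mijk,mi,mj,mk->m", block, wx, wy, wz)
        if not with_gradient:
            return val
        gx = np.einsum("mijk,mi,mj,mk->m", block, dwx, wy, wz) / self.spacing[0]
        gy = np.einsum("mijk,mi,mj,mk->m", block, wx, dwy, wz) / self.spacing[1]
        gz = np.einsum("mijk,mi,mj,mk->m", block, wx, wy, dwz) / self.spacing[2]
        return val, np.stack([gx, gy, gz], axis=1)


def build_spline_field(observed: DensityMap,
                       kernels: dict[str, AtomKernel] | None = None,
                       oversample: int = 2) -> SplineScoreField:
    """Cross-correlate each atom kernel with the observed map by Fourier-space
    convolution on an ``oversample``-times denser grid and fit the tricubic
    spline coefficients."""
    if kernels is None:
        kernels = default_kernels(observed.resolution)
    shape = np.asarray(observed.shape)
    fine_shape = shape * oversample
    spec = sp_fft.fftn(observed.values)
    freqs = [sp_fft.fftfreq(int(n), d=float(h))
             for n, h in zip(shape, observed.spacing)]
    k2 = (freqs[0][:, None, None] ** 2 + freqs[1][None, :, None] ** 2
          + freqs[2][None, None, :] ** 2)
    fields = {}
    scale = float(np.prod(fine_shape) / np.prod(shape))
    for t, ker in kernels.items():
        prod = spec * ker.fourier(k2)
        if oversample == 1:
            fine = sp_fft.ifftn(prod).real
        else:
            pad = np.zeros(tuple(fine_shape), dtype=complex)
            n0, n1, n2 = (int(n) for n in shape)
            h0, h1, h2 = n0 // 2, n1 // 2, n2 // 2
            sl = [(slice(0, h + 1), slice(-(n - h - 1), None) if n - h - 1 > 0 else None)
                  for n, h in ((n0, h0), (n1, h1), (n2, h2))]
            for s0 in sl[0]:
                for s1 in sl[1]:
                    for s2 in sl[2]:
                        if s0 is None or s1 is None or s2 is None:
                            continue
                        pad[s0, s1, s2] = prod[s0, s1, s2]
            fine = sp_fft.ifftn(pad).real * scale
        fields[t] = fine
    fine_spacing = observed.spacing / oversample
    return SplineScoreField(fields, observed.origin, fine_spacing,
                            observed.resolution)


def fast_density_score(model: BackboneModel, field: SplineScoreField):
    """Fast unmasked density score and per-atom Cartesian gradients.

    score = -sum over atoms of field[type](position); gradients point
    downhill in the score.  Returns ``(score, grads)`` where ``grads`` has
    shape (n_res, 5, 3) in atom slots N, CA, C, O, CB (virtual CB included;
    rows for missing atoms are zero).
    """
    pos, types, res = _model_atoms(model)
    grads = np.zeros((model.n_res, 5, 3))
    if len(pos) == 0:
        return 0.0, grads
    score = 0.0
    for ti, tname in enumerate(k.ATOM_TYPES):
        sel = types == ti
        if not sel.any():
            continue
        val, grad = field.interpolate(tname, pos[sel])
        score -= float(val.sum())
        grads[res[sel], ti] = -grad
    return score, grads
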