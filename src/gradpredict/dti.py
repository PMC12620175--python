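"""Diffusion tensor simulation, weighted linear least squares fitting, and
scalar parameter maps.

Signal model: S_i = S0 exp(-B_i . d), where B_i is the b-matrix row
[b gx^2, b gy^2, b gz^2, 2b gx gy, 2b gx gz, 2b gy gz] (s/mm^2) and d the
six unique elements [Dxx, Dyy, Dzz, Dxy, Dxz, Dyz] of the diffusion tensor
(mm^2/s).  Fitting log-linearizes the model and runs two passes: ordinary
least squares, then weighted least squares with weights equal to the
squared predicted signals (the log-transform noise propagation weights).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

# index pairs of the 6-vector in the 3x3 tensor
_IJ = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]


@dataclass
class DiffusionProtocol:
    """Diffusion encoding directions, b-values and the b-matrix."""

    directions: np.ndarray  # (n, 3) unit vectors (arbitrary for b=0)
    b_values: np.ndarray  # (n,) s/mm^2
    b_matrix: np.ndarray  # (n, 6)

    @property
    def n(self) -> int:
        return self.b_values.size


#: Classic dual-gradient 6-direction scheme.
DUAL_GRADIENT_DIRECTIONS = np.array(
    [
        [1, 1, 0],
        [1, -1, 0],
        [1, 0, 1],
        [1, 0, -1],
        [0, 1, 1],
        [0, 1, -1],
    ],
    dtype=float,
) / np.sqrt(2.0)


def make_bmatrix(
    directions: np.ndarray,
    b: float | np.ndarray,
    include_b0: bool = True,
    check_rank: bool = True,
) -> DiffusionProtocol:
    """Build the diffusion protocol from unit directions and b-value(s).

    ``check_rank=False`` permits under-determined protocols (e.g. a single
    direction for closed-form signal checks); fitting requires rank 6.
    """
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    norms = np.linalg.norm(directions, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-9):
        raise ValueError("directions must be unit vectors")
    b = np.broadcast_to(np.asarray(b, dtype=float), (directions.shape[0],)).copy()
    if include_b0:
        directions = np.vstack([[1.0, 0.0, 0.0], directions])
        b = np.concatenate([[0.0], b])
    rows = []
    for bv, g in zip(b, directions):
        gx, gy, gz = g
        rows.append(
            bv
            * np.array([gx**2, gy**2, gz**2, 2 * gx * gy, 2 * gx * gz, 2 * gy * gz])
        )
    bmat = np.asarray(rows)
    if check_rank:
        nz = bmat[b > 0]
        if np.linalg.matrix_rank(nz) < 6:
            raise ValueError("b-matrix rank < 6: tensor not identifiable")
    return DiffusionProtocol(directions=directions, b_values=b, b_matrix=bmat)


@dataclass
class TensorField:
    """Per-voxel diffusion tensors (..., 3, 3) with S0 and a validity mask."""

    tensors: np.ndarray
    s0: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.ones(self.s0.shape, dtype=bool)

    def d6(self) -> np.ndarray:
        """Unique elements (..., 6) in [xx, yy, zz, xy, xz, yz] order."""
        return np.stack([self.tensors[..., i, j] for i, j in _IJ], axis=-1)

    @staticmethod
    def from_d6(d6: np.ndarray, s0: np.ndarray, mask=None) -> "TensorField":
        shape = d6.shape[:-1]
        t = np.zeros(shape + (3, 3))
        for k, (i, j) in enumerate(_IJ):
            t[..., i, j] = d6[..., k]
            t[..., j, i] = d6[..., k]
        return TensorField(tensors=t, s0=s0, mask=mask)


def simulate_dwi(
    tensors: TensorField,
    protocol: DiffusionProtocol,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Mono-exponential tensor signals (..., n_volumes), optional Rician noise."""
    d6 = tensors.d6()
    expo = np.tensordot(d6, protocol.b_matrix, axes=(-1, -1))  # (..., n)
    s = tensors.s0[..., None] * np.exp(-expo)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        s = np.abs(
            s
            + noise_sigma * rng.normal(size=s.shape)
            + 1j * noise_sigma * rng.normal(size=s.shape)
        )
    return s


def fit_wlls(signals: np.ndarray, protocol: DiffusionProtocol) -> TensorField:
    """Two-pass weighted linear least squares tensor fit.

    ``signals``: (..., n_volumes) magnitudes.  Voxels with any non-positive
    signal are masked out rather than failing globally.
    """
    sig = np.asarray(signals, dtype=float)
    if sig.shape[-1] != protocol.n:
        raise ValueError("signal count does not match the protocol")
    shape = sig.shape[:-1]
    flat = sig.reshape(-1, protocol.n)
    mask = np.all(flat > 0, axis=1)
    design = np.column_stack([np.ones(protocol.n), -protocol.b_matrix])  # (n, 7)
    beta = np.zeros((flat.shape[0], 7))
    if np.any(mask):
        y = np.log(flat[mask])
        # pass 1: OLS
        coef, *_ = np.linalg.lstsq(design, y.T, rcond=None)
        coef = coef.T  # (v, 7)
        # pass 2: WLLS with weights = predicted signal squared
        w = np.exp(design @ coef.T).T ** 2  # (v, n)
        xtx = np.einsum("vn,ni,nj->vij", w, design, design)
        xty = np.einsum("vn,ni,vn->vi", w, design, y)
        beta[mask] = np.linalg.solve(xtx, xty[:, :, None])[:, :, 0]
    s0 = np.exp(beta[:, 0]).reshape(shape)
    d6 = beta[:, 1:].reshape(shape + (6,))
    s0 = np.where(mask.reshape(shape), s0, 0.0)
    return TensorField.from_d6(d6, s0, mask=mask.reshape(shape))


@dataclass
class ParameterMaps:
    """Scalar diffusion maps with a validity mask and QC info."""

    md: np.ndarray
    fa: np.ndarray
    rd: np.ndarray
    ad: np.ndarray
    mask: np.ndarray
    negative_eigenvalue_fraction: float = 0.0

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"MD": self.md, "FA": self.fa, "RD": self.rd, "AD": self.ad}


def tensor_metrics(tensors: TensorField) -> ParameterMaps:
    """MD, FA, RD, AD from the tensor eigenvalues (clamped at zero).

    MD = (l1+l2+l3)/3, FA = sqrt(3/2) ||l - MD|| / ||l||, RD = (l2+l3)/2,
    AD = l1, with l1 >= l2 >= l3.  FA of an all-zero tensor is defined as 0.
    """
    evals = np.linalg.eigvalsh(tensors.tensors)[..., ::-1]  # descending
    neg_frac = float(np.mean(np.any(evals < 0, axis=-1)[tensors.mask])) if np.any(
        tensors.mask
    ) else 0.0
    evals = np.clip(evals, 0.0, None)
    md = evals.mean(axis=-1)
    norm = np.sqrt((evals**2).sum(axis=-1))
    dev = np.sqrt(((evals - md[..., None]) ** 2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * dev / norm
    fa = np.where(norm > 0, fa, 0.0)
    fa = np.clip(fa, 0.0, 1.0)
    return ParameterMaps(
        md=md,
        fa=fa,
        rd=0.5 * (evals[..., 1] + evals[..., 2]),
        ad=evals[..., 0],
        mask=tensors.mask.copy(),
        negative_eigenvalue_fraction=neg_frac,
    )


def parameter_correlation(
    maps_a: ParameterMaps, maps_b: ParameterMaps, threshold: float = 0.05
) -> dict[str, float]:
    """Pearson correlation per parameter over FA-thresholded voxels.

    The mask keeps voxels valid in both fits whose FA exceeds ``threshold``
    in both maps; the same mask is applied to MD/RD/AD.
    """
    if maps_a.md.shape != maps_b.md.shape:
        raise ValueError("parameter map grids differ")
    sel = (
        maps_a.mask
        & maps_b.mask
        & (maps_a.fa > threshold)
        & (maps_b.fa > threshold)
    )
    if np.count_nonzero(sel) < 10:
        raise ValueError("fewer than 10 voxels above threshold")
    out = {}
    for name in ("MD", "FA", "RD", "AD"):
        a = maps_a.as_dict()[name][sel]
        b = maps_b.as_dict()[name][sel]
        out[name] = float(stats.pearsonr(a, b).statistic)
    out["n_voxels"] = int(np.count_nonzero(sel))
    return out


def make_tensor_phantom(
    n: int = 96, fov: float = 0.03
) -> tuple[TensorField, "np.ndarray"]:
    """Brain-like tensor phantom: isotropic matrix with anisotropic tracts.

    Returns the tensor field and the S0 image.  Tract regions carry
    eigenvalues (1.7, 0.3, 0.3)e-3 mm^2/s with in-plane orientations;
    the background is isotropic at 0.8e-3 mm^2/s.
    """
    from .recon import _ellipse_mask  # shared analytic geometry helpers

    outer = _ellipse_mask(n, 0.8, 0.9, 0.0, 0.0, 0.0)
    s0 = np.where(outer, 1.0, 0.0)
    d6 = np.zeros((n, n, 6))
    iso = 0.8e-3
    d6[outer, 0] = iso
    d6[outer, 1] = iso
    d6[outer, 2] = iso
    lam = np.array([1.7e-3, 0.3e-3, 0.3e-3])
    tracts = [
        (_ellipse_mask(n, 0.5, 0.12, 0.0, -0.45, 0.0), 0.0),
        (_ellipse_mask(n, 0.12, 0.45, 0.45, 0.15, 0.0), 90.0),
        (_ellipse_mask(n, 0.35, 0.1, -0.3, 0.35, 45.0), 45.0),
    ]
    for mask_t, angle in tracts:
        th = np.deg2rad(angle)
        e1 = np.array([np.cos(th), np.sin(th), 0.0])
        e2 = np.array([-np.sin(th), np.cos(th), 0.0])
        e3 = np.array([0.0, 0.0, 1.0])
        d = lam[0] * np.outer(e1, e1) + lam[1] * np.outer(e2, e2) + lam[2] * np.outer(e3, e3)
        m = mask_t & outer
        for k, (i, j) in enumerate(_IJ):
            d6[m, k] = d[i, j]
    return TensorField.from_d6(d6, s0, mask=outer), s0
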