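"""Single-tensor diffusion model: forward signal, log-linear fit, FA.

The acquisition emulated throughout the package is single-shell
(b = 1000 s/mm^2, 30 directions, one b0 volume).  Per voxel the signal is

    S_i = S0 * exp(-b_i * g_i^T D g_i)

with D a symmetric positive 3x3 diffusion tensor.  Fitting inverts this by
ordinary (unweighted) log-linear least squares, the classical approach of
standard DTI tools, which is exact on noiseless data and therefore gives
the test suite a closed-form round-trip oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

B0_THRESHOLD = 50.0  # s/mm^2; volumes below this count as b0


@dataclass
class DWIDataset:
    """4D diffusion-weighted volume with gradient table and affine.

    Attributes
    ----------
    signal : (nx, ny, nz, nvol) float array, arbitrary units
    bvals : (nvol,) b-values in s/mm^2
    bvecs : (nvol, 3) unit gradient vectors (zero rows for b0 volumes)
    brain_mask : (nx, ny, nz) bool array
    affine : (4, 4) voxel-index -> world-mm map (RAS)
    """

    signal: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    brain_mask: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float).reshape(-1, 3)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4D (x, y, z, volume)")
        nvol = self.signal.shape[3]
        if len(self.bvals) != nvol or len(self.bvecs) != nvol:
            raise ValueError("gradient table length does not match volume count")
        if not np.any(self.bvals < B0_THRESHOLD):
            raise ValueError("dataset needs at least one b~0 volume")
        norms = np.linalg.norm(self.bvecs, axis=1)
        dw = self.bvals >= B0_THRESHOLD
        if not np.allclose(norms[dw], 1.0, atol=1e-6):
            raise ValueError("diffusion-weighted bvecs must be unit vectors")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals < B0_THRESHOLD


@dataclass
class TensorField:
    """Per-voxel eigensystem of the fitted diffusion tensor.

    eigenvalues are sorted descending (lambda1 >= lambda2 >= lambda3,
    mm^2/s); ``eigenvectors[..., :, k]`` is the unit eigenvector of
    eigenvalue k; ``fa`` is fractional anisotropy in [0, 1]; voxels where
    the fit failed (non-positive signal, non-finite solution) are False in
    ``valid_mask`` and zero elsewhere.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    fa: np.ndarray
    valid_mask: np.ndarray
    affine: np.ndarray
    tensors: np.ndarray = field(default=None, repr=False)  # (..., 3, 3), for interpolation

    @property
    def shape(self) -> tuple:
        return self.fa.shape

    def principal_direction(self) -> np.ndarray:
        """Unit eigenvector of the largest eigenvalue, (..., 3)."""
        return self.eigenvectors[..., :, 0]


def fa(eigenvalues: np.ndarray) -> np.ndarray:
    """Fractional anisotropy of eigenvalue triples.

    FA = sqrt(3/2) * ||lambda - mean(lambda)|| / ||lambda||, clamped to
    [0, 1]; an all-zero triple is defined to have FA 0.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.linalg.norm(lam - mean, axis=-1)
    den = np.linalg.norm(lam, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.sqrt(1.5) * num / den
    out = np.where(den > 0, out, 0.0)
    return np.clip(out, 0.0, 1.0)


def design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows b*(gx^2, gy^2, gz^2, 2gxgy, 2gxgz, 2gygz) so that row @ d
    equals b * g^T D g for d = (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)."""
    g = np.asarray(bvecs, dtype=float)
    b = np.asarray(bvals, dtype=float)[:, None]
    return b * np.column_stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ]
    )


def tensors_from_components(d6: np.ndarray) -> np.ndarray:
    """(..., 6) tensor components -> (..., 3, 3) symmetric matrices."""
    d6 = np.asarray(d6, dtype=float)
    out = np.empty(d6.shape[:-1] + (3, 3), dtype=float)
    out[..., 0, 0] = d6[..., 0]
    out[..., 1, 1] = d6[..., 1]
    out[..., 2, 2] = d6[..., 2]
    out[..., 0, 1] = out[..., 1, 0] = d6[..., 3]
    out[..., 0, 2] = out[..., 2, 0] = d6[..., 4]
    out[..., 1, 2] = out[..., 2, 1] = d6[..., 5]
    return out


def forward_signal(
    tensors: np.ndarray, bvals: np.ndarray, bvecs: np.ndarray, s0: float | np.ndarray
) -> np.ndarray:
    """Noiseless single-tensor signal S0*exp(-b g^T D g) per voxel/volume.

    ``tensors`` is (..., 3, 3); the result has shape (..., nvol).
    """
    X = design_matrix(bvals, bvecs)  # (nvol, 6)
    t = np.asarray(tensors, dtype=float)
    d6 = np.stack(
        [
            t[..., 0, 0],
            t[..., 1, 1],
            t[..., 2, 2],
            t[..., 0, 1],
            t[..., 0, 2],
            t[..., 1, 2],
        ],
        axis=-1,
    )
    s0 = np.asarray(s0, dtype=float)
    return s0[..., None] * np.exp(-(d6 @ X.T))


def fit_tensors(dwi: DWIDataset) -> TensorField:
    """Log-linear least-squares tensor fit per masked voxel.

    S0 is the mean over all b~0 volumes.  Voxels with any non-positive
    signal or a non-finite solution are flagged invalid rather than
    raised.  Negative fitted eigenvalues are clamped to zero; the voxel
    stays valid only while lambda1 > 0.
    """
    b0 = dwi.b0_mask
    dw = ~b0
    n_dw = int(dw.sum())
    if n_dw < 6:
        raise ValueError("underdetermined tensor: need >= 6 diffusion-weighted volumes")
    X = design_matrix(dwi.bvals[dw], dwi.bvecs[dw])
    if np.linalg.matrix_rank(X) < 6:
        raise ValueError("underdetermined tensor: gradient directions not independent")
    if not dwi.brain_mask.any():
        raise ValueError("brain mask is empty")

    shape = dwi.signal.shape[:3]
    idx = np.nonzero(dwi.brain_mask)
    sig = dwi.signal[idx]  # (nvox, nvol)
    s0 = sig[:, b0].mean(axis=1)
    s_dw = sig[:, dw]

    ok = (s0 > 0) & np.all(s_dw > 0, axis=1)
    y = np.full_like(s_dw, np.nan)
    y[ok] = -np.log(s_dw[ok] / s0[ok, None])  # y = b g^T D g
    pinv = np.linalg.pinv(X)
    d6 = np.full((len(s0), 6), np.nan)
    d6[ok] = y[ok] @ pinv.T

    finite = ok & np.all(np.isfinite(d6), axis=1)
    tens = tensors_from_components(np.where(finite[:, None], d6, 0.0))
    w, v = np.linalg.eigh(tens)  # ascending
    w = w[:, ::-1]
    v = v[:, :, ::-1]
    w = np.clip(w, 0.0, None)
    valid = finite & (w[:, 0] > 0)

    eigenvalues = np.zeros(shape + (3,))
    eigenvectors = np.zeros(shape + (3, 3))
    fa_map = np.zeros(shape)
    valid_mask = np.zeros(shape, dtype=bool)
    tensors = np.zeros(shape + (3, 3))

    eigenvalues[idx] = np.where(valid[:, None], w, 0.0)
    eigenvectors[idx] = np.where(valid[:, None, None], v, 0.0)
    fa_map[idx] = np.where(valid, fa(w), 0.0)
    valid_mask[idx] = valid
    tensors[idx] = np.where(valid[:, None, None], tens, 0.0)

    return TensorField(
        eigenvalues=eigenvalues,
        eigenvectors=eigenvectors,
        fa=fa_map,
        valid_mask=valid_mask,
        affine=dwi.affine.copy(),
        tensors=tensors,
    )
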