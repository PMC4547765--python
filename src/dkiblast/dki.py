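"""Voxelwise diffusion-kurtosis estimation: MD, FA and MK maps.

The estimator works direction-by-direction. For each gradient direction the
multi-shell log-signal is fit with the two-parameter kurtosis decay

    ln[S(b)/S0] = -b * D_app + (1/6) * b^2 * D_app^2 * K_app,

linear in ``x1 = D_app`` and ``x2 = D_app^2 * K_app``. Mean kurtosis (MK)
is the arithmetic mean of K_app over all non-degenerate directions. The
diffusion tensor for MD/FA is then fit by linear least squares to the
kurtosis-corrected per-direction diffusivities, ``D_app = n^T D n``.

An alternate joint mode fits all 21 parameters (6 tensor + 15 kurtosis
tensor components) in one weighted linear solve per voxel; both modes agree
to numerical precision on noise-free data.

Voxels are classified with exhaustive failure codes: ok, negative-signal
(S0 <= 0), degenerate (no direction admits a positive diffusivity), or
clamped (a kurtosis or eigenvalue clamp fired).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .gradients import GradientScheme
from .synthetic import d_design_row, w_design_row

__all__ = [
    "DWISeries",
    "DirectionalFit",
    "DiffusionTensorEstimate",
    "ParamMaps",
    "FitConfig",
    "FLAG_OK",
    "FLAG_NEGATIVE_SIGNAL",
    "FLAG_DEGENERATE",
    "FLAG_CLAMPED",
    "smooth_dwi",
    "fit_direction",
    "fit_dti_tensor",
    "tensor_metrics",
    "compute_mk",
    "fit_volume",
]

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...

FLAG_OK = 0
FLAG_NEGATIVE_SIGNAL = 1
FLAG_DEGENERATE = 2
FLAG_CLAMPED = 3


@dataclass
class DWISeries:
    """A 4D diffusion-weighted series bound to its scheme and geometry."""

    data: np.ndarray  # (x, y, z, volume)
    voxel_size: tuple  # mm per axis
    scheme: GradientScheme
    mask: np.ndarray | None = None
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4D; got shape {self.data.shape}")
        if self.data.shape[3] != self.scheme.n_volumes:
            raise ValueError(
                f"series has {self.data.shape[3]} volumes but the scheme "
                f"defines {self.scheme.n_volumes}"
            )
        if np.any(self.data < 0):
            raise ValueError("signals must be >= 0 (magnitude data)")
        if len(self.voxel_size) != 3:
            raise ValueError("voxel_size must have 3 entries (mm)")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:3]:
                raise ValueError("mask shape must match the voxel grid")
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size) + [1.0])

    @classmethod
    def from_tables(cls, data, bvals, bvecs, voxel_size, mask=None, affine=None):
        """Build a series from per-volume b-value/vector tables in any order.

        Volumes are reordered into the canonical layout (b0 block first, then
        shells in ascending b, each in a shared direction order), so maps are
        invariant to a joint permutation of volumes and table rows.
        """
        data = np.asarray(data, dtype=float)
        bvals = np.asarray(bvals, dtype=float).ravel()
        bvecs = np.asarray(bvecs, dtype=float)
        if bvecs.shape == (3, bvals.size):
            bvecs = bvecs.T
        if bvecs.shape != (bvals.size, 3):
            raise ValueError(
                f"bvecs shape {bvecs.shape} does not match {bvals.size} b-values"
            )
        if data.shape[3] != bvals.size:
            raise ValueError(
                f"series has {data.shape[3]} volumes but {bvals.size} b-values"
            )
        b0_idx = np.flatnonzero(bvals == 0)
        if b0_idx.size == 0:
            raise ValueError("at least one b = 0 volume is required")
        nonzero = np.flatnonzero(bvals > 0)
        norms = np.linalg.norm(bvecs[nonzero], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-3):
            bad = nonzero[int(np.argmax(np.abs(norms - 1.0)))]
            raise ValueError(
                f"volume {bad}: non-unit gradient vector (norm {norms.max():.4f}) "
                "at b > 0"
            )
        shells = np.unique(bvals[nonzero])
        counts = {b: int(np.sum(bvals == b)) for b in shells}
        if len(set(counts.values())) > 1:
            raise ValueError(f"unequal direction counts across shells: {counts}")
        ref_idx = np.flatnonzero(bvals == shells[0])
        ref_dirs = bvecs[ref_idx] / np.linalg.norm(bvecs[ref_idx], axis=1, keepdims=True)
        order = list(b0_idx)
        for b in shells:
            idx = np.flatnonzero(bvals == b)
            dirs = bvecs[idx] / np.linalg.norm(bvecs[idx], axis=1, keepdims=True)
            # match each reference direction to this shell's volume
            dots = np.abs(ref_dirs @ dirs.T)
            perm = np.argmax(dots, axis=1)
            if len(set(perm.tolist())) != len(perm) or np.any(
                dots[np.arange(len(perm)), perm] < 1.0 - 1e-6
            ):
                raise ValueError(
                    f"shell b = {b}: directions do not match the reference shell"
                )
            order.extend(idx[perm])
        order = np.asarray(order)
        scheme = GradientScheme(
            directions=ref_dirs, shell_bvalues=tuple(shells), n_b0=b0_idx.size
        )
        return cls(
            data=data[..., order],
            voxel_size=tuple(voxel_size),
            scheme=scheme,
            mask=mask,
            affine=affine,
        )


@dataclass(frozen=True)
class DirectionalFit:
    """Two-parameter kurtosis fit along one gradient direction."""

    D_app: float  # mm^2/s
    K_app: float  # dimensionless
    residual: float  # RMS of log-signal residuals
    clamped: bool = False
    degenerate: bool = False


@dataclass
class DiffusionTensorEstimate:
    """Symmetric diffusion tensor with its eigensystem."""

    components: np.ndarray  # [Dxx, Dyy, Dzz, Dxy, Dxz, Dyz], mm^2/s
    eigenvalues: np.ndarray  # descending, clamped to >= 0
    eigenvectors: np.ndarray  # columns match eigenvalues
    n_clamped_eigenvalues: int = 0

    @property
    def tensor(self) -> np.ndarray:
        c = self.components
        return np.array(
            [[c[0], c[3], c[4]], [c[3], c[1], c[5]], [c[4], c[5], c[2]]]
        )


@dataclass
class ParamMaps:
    """Voxelwise MD/FA/MK maps plus fit diagnostics."""

    MD: np.ndarray
    FA: np.ndarray
    MK: np.ndarray
    flags: np.ndarray  # int codes, FLAG_*
    n_clamped_kapp: int = 0
    n_excluded_directions: np.ndarray | None = None
    affine: np.ndarray | None = None
    voxel_size: tuple | None = None


@dataclass
class FitConfig:
    """Estimator configuration.

    kapp_clamp
        Physically motivated bounds on directional kurtosis; prevents
        noise-driven blow-up where D_app approaches 0. Clamps are recorded.
    signal_floor
        Signals below ``signal_floor * S0`` are raised to it before the log,
        since magnitude data can reach zero after smoothing edge effects.
    mode
        "directional" (per-direction two-parameter fits, the default) or
        "joint" (21-parameter weighted linear solve).
    """

    kapp_clamp: tuple = (0.0, 3.0)
    signal_floor: float = 1e-6
    mode: str = "directional"

    def __post_init__(self):
        if self.mode not in ("directional", "joint"):
            raise ValueError(f"unknown fit mode {self.mode!r}")


def smooth_dwi(series: DWISeries, fwhm_mm: float) -> DWISeries:
    """Isotropic 3D Gaussian smoothing of every volume.

    The kernel SD is ``fwhm / (2 sqrt(2 ln 2))`` mm, converted to voxels per
    axis so anisotropic voxel sizes are honored. ``fwhm_mm = 0`` is the
    identity. Applied to the full volume, before any masking.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return DWISeries(
            data=series.data.copy(),
            voxel_size=series.voxel_size,
            scheme=series.scheme,
            mask=series.mask,
            affine=series.affine,
        )
    sigma_vox = [
        (fwhm_mm / FWHM_TO_SIGMA) / vs for vs in series.voxel_size
    ]
    out = ndimage.gaussian_filter(
        series.data, sigma=sigma_vox + [0.0], truncate=6.0
    )
    return DWISeries(
        data=out,
        voxel_size=series.voxel_size,
        scheme=series.scheme,
        mask=series.mask,
        affine=series.affine,
    )


def _directional_design(bvalues: np.ndarray) -> np.ndarray:
    b = np.asarray(bvalues, dtype=float)
    return np.column_stack([-b, b * b / 6.0])


def fit_direction(log_ratios, bvalues, kapp_clamp=(0.0, 3.0)) -> DirectionalFit:
    """Least-squares kurtosis fit of ln(S/S0) over the shells of one direction.

    Solves ``ln(S/S0) = -b x1 + (b^2/6) x2`` and reports ``D_app = x1``,
    ``K_app = x2 / x1^2`` clamped to ``kapp_clamp``. A non-positive fitted
    diffusivity marks the direction degenerate and returns (0, 0).
    """
    y = np.asarray(log_ratios, dtype=float)
    b = np.asarray(bvalues, dtype=float)
    if y.shape != b.shape:
        raise ValueError("log_ratios and bvalues must align")
    if np.unique(b[b > 0]).size < 2:
        raise ValueError("need >= 2 distinct positive b-values for 2 unknowns")
    if not np.all(np.isfinite(y)):
        raise ValueError("log_ratios must be finite")
    A = _directional_design(b)
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = float(np.sqrt(np.mean((A @ x - y) ** 2)))
    if x[0] <= 0:
        return DirectionalFit(0.0, 0.0, resid, clamped=False, degenerate=True)
    k = float(x[1] / (x[0] * x[0]))
    lo, hi = kapp_clamp
    clamped = k < lo or k > hi
    k = float(np.clip(k, lo, hi))
    return DirectionalFit(float(x[0]), k, resid, clamped=clamped)


def fit_dti_tensor(directional_Dapp, directions) -> DiffusionTensorEstimate:
    """Fit the symmetric diffusion tensor to per-direction diffusivities.

    Linear least squares of ``D_app = n^T D n`` over >= 6 directions that
    span 3-space; eigenvalues are returned descending with any negative
    values clamped to 0 (and counted).
    """
    d = np.asarray(directional_Dapp, dtype=float)
    dirs = np.atleast_2d(np.asarray(directions, dtype=float))
    if d.size != dirs.shape[0]:
        raise ValueError("one D_app per direction required")
    if dirs.shape[0] < 6:
        raise ValueError(
            f"{dirs.shape[0]} directions: 6 unknown tensor components need >= 6"
        )
    A = np.stack([d_design_row(n) for n in dirs])
    if np.linalg.matrix_rank(A) < 6:
        raise ValueError("direction set is rank-deficient for a tensor fit")
    comps, *_ = np.linalg.lstsq(A, d, rcond=None)
    T = np.array(
        [
            [comps[0], comps[3], comps[4]],
            [comps[3], comps[1], comps[5]],
            [comps[4], comps[5], comps[2]],
        ]
    )
    evals, evecs = np.linalg.eigh(T)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_clamped = int(np.sum(evals < 0))
    evals = np.maximum(evals, 0.0)
    return DiffusionTensorEstimate(
        components=comps,
        eigenvalues=evals,
        eigenvectors=evecs,
        n_clamped_eigenvalues=n_clamped,
    )


def tensor_metrics(tensor: DiffusionTensorEstimate):
    """Mean diffusivity and fractional anisotropy from the eigensystem.

    MD = mean eigenvalue; FA = sqrt(3/2) * ||lambda - MD|| / ||lambda||,
    defined as 0 for the all-zero tensor.
    """
    lam = np.asarray(tensor.eigenvalues, dtype=float)
    md = float(np.mean(lam))
    denom = float(np.sqrt(np.sum(lam * lam)))
    if denom == 0.0:
        return md, 0.0
    fa = float(np.sqrt(1.5) * np.sqrt(np.sum((lam - md) ** 2)) / denom)
    return md, min(fa, 1.0)


def compute_mk(fits):
    """Mean kurtosis: arithmetic mean of K_app over non-degenerate directions.

    Returns ``(MK, n_excluded)``; MK is NaN when every direction is
    degenerate (the voxel should then be flagged).
    """
    fits = list(fits)
    if not fits:
        raise ValueError("at least one directional fit required")
    good = [f.K_app for f in fits if not f.degenerate]
    n_excluded = len(fits) - len(good)
    if not good:
        return float("nan"), n_excluded
    return float(np.mean(good)), n_excluded


def _fit_joint(y, scheme, config):
    """21-parameter linear DKI solve; returns per-direction (D_app, K_app).

    Variables are the 6 tensor components and the 15 components of
    ``V = MD^2 * W``, making the model linear; directional kurtosis is then
    ``K_app = V_app / D_app^2``.
    """
    dirs = scheme.directions
    d_design = np.stack([d_design_row(n) for n in dirs])  # (ndir, 6)
    w_design = np.stack([w_design_row(n) for n in dirs])  # (ndir, 15)
    rows = []
    for b in scheme.shell_bvalues:
        rows.append(np.hstack([-b * d_design, (b * b / 6.0) * w_design]))
    A = np.vstack(rows)  # (nshell*ndir, 21)
    x = y @ np.linalg.pinv(A).T  # (nvox, 21)
    d_app = x[:, :6] @ d_design.T  # (nvox, ndir)
    v_app = x[:, 6:] @ w_design.T
    with np.errstate(divide="ignore", invalid="ignore"):
        k_raw = v_app / (d_app * d_app)
    return d_app, k_raw


def fit_volume(series: DWISeries, config: FitConfig | None = None) -> ParamMaps:
    """Voxelwise kurtosis reconstruction over the (optionally masked) grid.

    Per voxel: the b0 volumes are averaged into S0, signals are floored at
    ``signal_floor * S0`` before the log, every direction is fit for
    (D_app, K_app), MK is the mean retained K_app, and the diffusion tensor
    for MD/FA is fit to the per-direction diffusivities. Deterministic.
    """
    config = config or FitConfig()
    scheme = series.scheme
    shape = series.data.shape[:3]
    nvox = int(np.prod(shape))
    data = series.data.reshape(nvox, scheme.n_volumes)
    mask = (
        series.mask.reshape(nvox)
        if series.mask is not None
        else np.ones(nvox, dtype=bool)
    )

    flags = np.zeros(nvox, dtype=np.int16)
    MD = np.zeros(nvox)
    FA = np.zeros(nvox)
    MK = np.zeros(nvox)
    n_excl = np.zeros(nvox, dtype=np.int32)

    S0 = data[:, : scheme.n_b0].mean(axis=1)
    bad_s0 = mask & (S0 <= 0)
    flags[bad_s0] = FLAG_NEGATIVE_SIGNAL
    flags[~mask] = FLAG_NEGATIVE_SIGNAL  # excluded voxels carry no estimate
    ok = mask & ~bad_s0
    if not ok.any():
        return ParamMaps(
            MD=MD.reshape(shape),
            FA=FA.reshape(shape),
            MK=MK.reshape(shape),
            flags=flags.reshape(shape),
            n_excluded_directions=n_excl.reshape(shape),
            affine=series.affine,
            voxel_size=series.voxel_size,
        )

    idx = np.flatnonzero(ok)
    s0 = S0[idx][:, None]
    ndir, nshell = scheme.n_directions, scheme.n_shells
    weighted = data[idx, scheme.n_b0 :].reshape(idx.size, nshell, ndir)
    floor = config.signal_floor * s0[..., None]
    weighted = np.maximum(weighted, floor)
    y = np.log(weighted / s0[..., None])  # (nok, nshell, ndir)

    lo, hi = config.kapp_clamp
    if config.mode == "joint":
        d_app, k_raw = _fit_joint(
            y.reshape(idx.size, nshell * ndir), scheme, config
        )
        resid_clamped = 0
    else:
        A = _directional_design(np.asarray(scheme.shell_bvalues))
        pinv = np.linalg.pinv(A)  # (2, nshell)
        x = np.einsum("ps,vsd->vpd", pinv, y)  # (nok, 2, ndir)
        d_app = x[:, 0, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            k_raw = x[:, 1, :] / (d_app * d_app)
        resid_clamped = 0

    degenerate = ~(d_app > 0) | ~np.isfinite(k_raw)
    k_app = np.clip(np.where(degenerate, 0.0, k_raw), lo, hi)
    clamped_dir = ~degenerate & ((k_raw < lo) | (k_raw > hi))
    n_clamped = int(clamped_dir.sum())

    good = ~degenerate
    n_good = good.sum(axis=1)
    n_excl[idx] = ndir - n_good
    all_degenerate = n_good == 0

    with np.errstate(invalid="ignore"):
        mk = np.where(
            all_degenerate, np.nan, np.sum(np.where(good, k_app, 0.0), axis=1)
        )
        mk = mk / np.where(all_degenerate, 1, n_good)
    MK[idx] = np.where(all_degenerate, 0.0, mk)

    # diffusion tensor from per-direction diffusivities
    d_design = np.stack([d_design_row(n) for n in scheme.directions])
    pinv_d = np.linalg.pinv(d_design)  # (6, ndir)
    d_for_tensor = np.where(good, d_app, 0.0)
    comps = d_for_tensor @ pinv_d.T  # (nok, 6)
    T = np.empty((idx.size, 3, 3))
    T[:, 0, 0], T[:, 1, 1], T[:, 2, 2] = comps[:, 0], comps[:, 1], comps[:, 2]
    T[:, 0, 1] = T[:, 1, 0] = comps[:, 3]
    T[:, 0, 2] = T[:, 2, 0] = comps[:, 4]
    T[:, 1, 2] = T[:, 2, 1] = comps[:, 5]
    evals = np.linalg.eigvalsh(T)  # ascending
    n_eig_clamped = int(np.sum(evals < 0))
    evals = np.maximum(evals, 0.0)
    md = evals.mean(axis=1)
    denom = np.sqrt(np.sum(evals * evals, axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        fa = np.sqrt(1.5) * np.sqrt(np.sum((evals - md[:, None]) ** 2, axis=1)) / denom
    fa = np.where(denom == 0, 0.0, np.minimum(fa, 1.0))
    MD[idx] = np.where(all_degenerate, 0.0, md)
    FA[idx] = np.where(all_degenerate, 0.0, fa)

    vox_flags = np.zeros(idx.size, dtype=np.int16)
    vox_clamped = clamped_dir.any(axis=1)
    vox_flags[vox_clamped] = FLAG_CLAMPED
    vox_flags[all_degenerate] = FLAG_DEGENERATE
    flags[idx] = vox_flags

    return ParamMaps(
        MD=MD.reshape(shape),
        FA=FA.reshape(shape),
        MK=MK.reshape(shape),
        flags=flags.reshape(shape),
        n_clamped_kapp=n_clamped,
        n_excluded_directions=n_excl.reshape(shape),
        affine=series.affine,
        voxel_size=series.voxel_size,
    )
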