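"""Synthetic inputs with known ground truth.

Every input class the pipeline consumes can be generated here: multi-shell
diffusion-weighted phantoms obeying the kurtosis signal model, balanced
two-group longitudinal cohort tables with a configurable effect structure,
metabolite concentration tables with Cramér-Rao lower bounds, and
fluorescence micrographs with a known labeled-pixel fraction.

Signal model
------------
Along a unit direction ``n`` at diffusion weighting ``b`` (s/mm^2),

    ln[S(b)/S0] = -b * D_app + (1/6) * b^2 * D_app^2 * K_app

where ``D_app = n^T D n`` is the apparent diffusivity (mm^2/s) and
``K_app`` the apparent (directional) kurtosis. When the kurtosis ground
truth is given as a full rank-4 tensor ``W``,

    K_app = (MD^2 / D_app^2) * sum_ijkl n_i n_j n_k n_l W_ijkl,
    MD    = trace(D) / 3.

Setting ``K_app = 0`` (or ``W = 0``) recovers the mono-exponential
Gaussian (DTI) decay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gradients import GradientScheme, make_scheme

__all__ = [
    "GroundTruthField",
    "CohortSpec",
    "dki_forward_signal",
    "add_noise",
    "make_phantom",
    "make_cohort_table",
    "make_metabolite_table",
    "make_histo_image",
    "uniform_isotropic_field",
    "two_block_field",
    "tract_field",
    "W_INDEX",
    "w_design_row",
    "d_design_row",
]

# Canonical ordering of the 15 unique components of a fully symmetric
# rank-4 tensor in 3D, as monomial exponents (px, py, pz) with sum 4.
W_INDEX = (
    (4, 0, 0), (0, 4, 0), (0, 0, 4),
    (3, 1, 0), (3, 0, 1), (1, 3, 0), (0, 3, 1), (1, 0, 3), (0, 1, 3),
    (2, 2, 0), (2, 0, 2), (0, 2, 2),
    (2, 1, 1), (1, 2, 1), (1, 1, 2),
)

_FACT = (1, 1, 2, 6, 24)


def _multiplicity(p) -> int:
    return _FACT[4] // (_FACT[p[0]] * _FACT[p[1]] * _FACT[p[2]])


def w_design_row(n: np.ndarray) -> np.ndarray:
    """Row of 15 monomials with multiplicities so that W_app = row @ w15."""
    n = np.asarray(n, dtype=float)
    return np.array(
        [_multiplicity(p) * n[0] ** p[0] * n[1] ** p[1] * n[2] ** p[2] for p in W_INDEX]
    )


def d_design_row(n: np.ndarray) -> np.ndarray:
    """Row of 6 monomials so that D_app = row @ [Dxx,Dyy,Dzz,Dxy,Dxz,Dyz]."""
    n = np.asarray(n, dtype=float)
    return np.array(
        [n[0] ** 2, n[1] ** 2, n[2] ** 2, 2 * n[0] * n[1], 2 * n[0] * n[2], 2 * n[1] * n[2]]
    )


def _as_tensor33(D) -> np.ndarray:
    """Accept a 3x3 symmetric matrix or a 6-vector [xx,yy,zz,xy,xz,yz]."""
    D = np.asarray(D, dtype=float)
    if D.shape == (3, 3):
        return D
    if D.shape == (6,):
        return np.array(
            [[D[0], D[3], D[4]], [D[3], D[1], D[5]], [D[4], D[5], D[2]]]
        )
    raise ValueError(f"diffusion tensor must be (3,3) or (6,); got {D.shape}")


def dki_forward_signal(S0, D, direction, b, W=None, kapp=None):
    """Noise-free diffusion-kurtosis signal along one direction.

    Parameters
    ----------
    S0 : float
        Unweighted signal (> 0).
    D : (3, 3) or (6,) array
        Symmetric diffusion tensor, mm^2/s.
    direction : (3,) unit vector
    b : float
        Diffusion weighting, s/mm^2 (>= 0).
    W : (15,) array, optional
        Unique components of the fully symmetric kurtosis tensor
        (ordering ``W_INDEX``); mutually exclusive with ``kapp``.
    kapp : float, optional
        Directional kurtosis to apply directly along ``direction``.

    Returns
    -------
    float
        ``S0 * exp(-b D_app + b^2 D_app^2 K_app / 6)``.
    """
    n = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(n) - 1.0) > 1e-6:
        raise ValueError(f"direction must be unit-norm; |n| = {np.linalg.norm(n):.8f}")
    if b < 0:
        raise ValueError("b must be >= 0")
    if W is not None and kapp is not None:
        raise ValueError("give either W or kapp, not both")
    D33 = _as_tensor33(D)
    d_app = float(n @ D33 @ n)
    if b == 0:
        return float(S0)
    if d_app <= 0:
        raise ValueError(f"D_app = {d_app:.3e} <= 0: kurtosis signal model undefined")
    if W is not None:
        md = np.trace(D33) / 3.0
        w_app = float(w_design_row(n) @ np.asarray(W, dtype=float))
        k_app = (md * md) / (d_app * d_app) * w_app
    else:
        k_app = 0.0 if kapp is None else float(kapp)
    return float(S0 * np.exp(-b * d_app + b * b * d_app * d_app * k_app / 6.0))


def add_noise(signal_array, sigma: float, model: str = "rician", seed: int = 0):
    """Add magnitude-MR (Rician) or additive Gaussian noise.

    Rician: ``sqrt((s + e1)^2 + e2^2)`` with independent zero-mean Gaussian
    ``e1, e2`` of SD ``sigma`` — the magnitude of a complex signal whose two
    channels are independently corrupted. Deterministic for a fixed seed.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    s = np.asarray(signal_array, dtype=float)
    if sigma == 0:
        return s.copy()
    rng = np.random.default_rng(seed)
    if model == "rician":
        e1 = rng.normal(0.0, sigma, s.shape)
        e2 = rng.normal(0.0, sigma, s.shape)
        return np.sqrt((s + e1) ** 2 + e2**2)
    if model == "gaussian":
        return s + rng.normal(0.0, sigma, s.shape)
    raise ValueError(f"unknown noise model {model!r}; expected 'rician' or 'gaussian'")


@dataclass
class GroundTruthField:
    """Voxelwise ground truth for phantom synthesis.

    ``D`` holds a symmetric tensor per voxel as a 6-vector
    ``[Dxx, Dyy, Dzz, Dxy, Dxz, Dyz]`` (mm^2/s). Kurtosis ground truth is
    either a per-voxel directional kurtosis ``K`` (applied identically along
    every direction) or a per-voxel 15-component ``W`` tensor.
    """

    S0: np.ndarray  # (x, y, z)
    D: np.ndarray  # (x, y, z, 6)
    K: np.ndarray | None = None  # (x, y, z)
    W: np.ndarray | None = None  # (x, y, z, 15)
    mask: np.ndarray | None = None  # (x, y, z) bool

    def __post_init__(self):
        self.S0 = np.asarray(self.S0, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        if self.D.shape != self.S0.shape + (6,):
            raise ValueError("D must be S0.shape + (6,)")
        if (self.K is None) == (self.W is None):
            raise ValueError("exactly one of K or W must be given")
        if self.mask is None:
            self.mask = np.ones(self.S0.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("ground-truth field must contain at least one masked voxel")
        if np.any(self.S0[self.mask] <= 0):
            raise ValueError("S0 must be > 0 in masked voxels")

    @property
    def shape(self):
        return self.S0.shape


def _iso6(md: float) -> np.ndarray:
    return np.array([md, md, md, 0.0, 0.0, 0.0])


def uniform_isotropic_field(
    shape=(8, 8, 4), s0: float = 1000.0, md: float = 1.0e-3, kapp: float = 0.0
) -> GroundTruthField:
    """Uniform isotropic block: one MD and one K_app everywhere."""
    S0 = np.full(shape, s0)
    D = np.broadcast_to(_iso6(md), shape + (6,)).copy()
    K = np.full(shape, kapp)
    return GroundTruthField(S0=S0, D=D, K=K)


def two_block_field(
    shape=(8, 8, 4),
    s0: float = 1000.0,
    md: float = 1.0e-3,
    kapp_a: float = 0.6,
    kapp_b: float = 1.2,
) -> GroundTruthField:
    """Two compartments split along the first axis with distinct kurtosis."""
    f = uniform_isotropic_field(shape, s0, md, kapp_a)
    half = shape[0] // 2
    f.K[half:] = kapp_b
    return f


def tract_field(
    shape=(16, 16, 4),
    s0: float = 1000.0,
    eigenvalues=(1.7e-3, 0.4e-3, 0.3e-3),
    background_md: float = 0.7e-3,
    kapp: float = 0.8,
    radius: float = 3.0,
) -> GroundTruthField:
    """Cigar-shaped anisotropic "tract" along x inside an isotropic background."""
    f = uniform_isotropic_field(shape, s0, background_md, kapp)
    l1, l2, l3 = eigenvalues
    cy, cz = (shape[1] - 1) / 2.0, (shape[2] - 1) / 2.0
    yy, zz = np.meshgrid(np.arange(shape[1]), np.arange(shape[2]), indexing="ij")
    inside = (yy - cy) ** 2 + (zz - cz) ** 2 <= radius**2
    tract = np.array([l1, l2, l3, 0.0, 0.0, 0.0])
    f.D[:, inside] = tract
    return f


def _forward_volume(field: GroundTruthField, scheme: GradientScheme) -> np.ndarray:
    """Vectorized noise-free 4D signal for every voxel and volume."""
    shape = field.shape
    nvox = int(np.prod(shape))
    D = field.D.reshape(nvox, 6)
    S0 = field.S0.reshape(nvox)
    dirs = scheme.directions
    d_design = np.stack([d_design_row(n) for n in dirs])  # (ndir, 6)
    d_app = D @ d_design.T  # (nvox, ndir)
    if np.any(d_app[field.mask.reshape(nvox)] <= 0):
        raise ValueError("ground-truth D_app <= 0 along a scheme direction")
    if field.W is not None:
        w_design = np.stack([w_design_row(n) for n in dirs])  # (ndir, 15)
        w_app = field.W.reshape(nvox, 15) @ w_design.T
        md = (D[:, 0] + D[:, 1] + D[:, 2]) / 3.0
        k_app = (md[:, None] ** 2) / (d_app**2) * w_app
    else:
        k_app = np.broadcast_to(field.K.reshape(nvox, 1), d_app.shape)

    data = np.empty((nvox, scheme.n_volumes))
    data[:, : scheme.n_b0] = S0[:, None]
    for i, b in enumerate(scheme.shell_bvalues):
        sl = scheme.weighted_index(i)
        data[:, sl] = S0[:, None] * np.exp(
            -b * d_app + (b * b / 6.0) * d_app**2 * k_app
        )
    return data.reshape(shape + (scheme.n_volumes,))


def make_phantom(
    field: GroundTruthField,
    scheme: GradientScheme,
    sigma: float = 0.0,
    seed: int = 0,
    voxel_size=(0.234, 0.234, 1.0),
    noise_model: str = "rician",
):
    """Synthesize a 4D diffusion series from a ground-truth field.

    Each b0 volume is an independently noised copy of S0, mirroring repeated
    unweighted acquisitions. Returns ``(DWISeries, GroundTruthField)``.
    """
    from .dki import DWISeries  # local import avoids a cycle

    clean = _forward_volume(field, scheme)
    noisy = add_noise(clean, sigma, model=noise_model, seed=seed)
    series = DWISeries(
        data=noisy, voxel_size=tuple(voxel_size), scheme=scheme, mask=field.mask
    )
    return series, field


@dataclass
class CohortSpec:
    """Balanced two-group repeated-measures cohort design.

    ``means[(group, time)]`` are the cell means of the generated measure;
    ``between_sd`` is the SD of the per-subject random intercept and
    ``within_sd`` the residual SD. Defaults mirror a two-arm small-animal
    imaging study: 6 subjects per arm over baseline and four post-injury
    days.
    """

    n_per_group: int = 6
    groups: tuple = ("sham", "injured")
    timepoints: tuple = ("baseline", "d1", "d7", "d14", "d28")
    means: dict | None = None
    between_sd: float = 0.05
    within_sd: float = 0.05
    region: str = "hippocampus"
    measure: str = "MK"
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.between_sd < 0 or self.within_sd < 0:
            raise ValueError("SDs must be >= 0")
        if self.means is None:
            self.means = {(g, t): 1.0 for g in self.groups for t in self.timepoints}
        missing = [
            (g, t)
            for g in self.groups
            for t in self.timepoints
            if (g, t) not in self.means
        ]
        if missing:
            raise ValueError(f"means table incomplete; missing cells {missing}")


def make_cohort_table(spec: CohortSpec) -> pd.DataFrame:
    """Generate one record per subject x time for the design's measure.

    value = cell mean + subject random intercept + residual. Balanced and
    deterministic for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for g in spec.groups:
        subject_effects = rng.normal(0.0, spec.between_sd, spec.n_per_group)
        for s in range(spec.n_per_group):
            subject = f"{g}_{s + 1:02d}"
            for t in spec.timepoints:
                value = (
                    spec.means[(g, t)]
                    + subject_effects[s]
                    + rng.normal(0.0, spec.within_sd)
                )
                rows.append(
                    dict(
                        subject=subject,
                        group=g,
                        time=t,
                        region=spec.region,
                        measure=spec.measure,
                        value=value,
                    )
                )
    return pd.DataFrame(rows)


def make_metabolite_table(
    metabolites,
    concentrations,
    crlbs,
    seed: int = 0,
    noise_sd: float = 0.0,
    tcr_concentration: float = 8.0,
    tcr_crlb: float = 3.0,
) -> pd.DataFrame:
    """Metabolite concentration table at the spectral-fit output level.

    Emulates the fitted-concentration table a spectral-fitting package
    reports: one row per metabolite with its concentration (institutional
    units) and CRLB (%). A total-creatine (tCr) reference row is appended
    when not supplied, since downstream ratios are taken against it.
    """
    metabolites = list(metabolites)
    concentrations = [float(c) for c in concentrations]
    crlbs = [float(c) for c in crlbs]
    if not (len(metabolites) == len(concentrations) == len(crlbs)):
        raise ValueError("metabolites, concentrations and crlbs must align")
    if any(c < 0 for c in crlbs):
        raise ValueError("CRLBs must be >= 0")
    rng = np.random.default_rng(seed)
    rows = [
        dict(
            name=m,
            concentration=c + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0),
            crlb_percent=cr,
        )
        for m, c, cr in zip(metabolites, concentrations, crlbs)
    ]
    if "tCr" not in metabolites:
        rows.append(
            dict(name="tCr", concentration=tcr_concentration, crlb_percent=tcr_crlb)
        )
    return pd.DataFrame(rows, columns=["name", "concentration", "crlb_percent"])


def make_histo_image(
    shape=(360, 450),
    background_level: float = 1000.0,
    labeled_fraction: float = 0.0,
    label_multiple: float = 3.0,
    seed: int = 0,
    jitter_sd: float = 0.0,
) -> np.ndarray:
    """Grayscale micrograph with a known labeled-pixel fraction.

    Exactly ``round(labeled_fraction * n_pixels)`` pixels, chosen at random,
    are set to ``label_multiple * background_level``; the rest sit at the
    background level. Optional Gaussian jitter emulates shot noise; with the
    default jitter of 0 the image is exact and quantification recovers the
    construction fraction to machine precision. Returned as uint16.
    """
    if not 0.0 <= labeled_fraction <= 1.0:
        raise ValueError("labeled_fraction must be in [0, 1]")
    if label_multiple <= 0:
        raise ValueError("label_multiple must be > 0")
    rng = np.random.default_rng(seed)
    n_pixels = int(np.prod(shape))
    img = np.full(n_pixels, float(background_level))
    n_labeled = int(round(labeled_fraction * n_pixels))
    if n_labeled > 0:
        idx = rng.choice(n_pixels, size=n_labeled, replace=False)
        img[idx] = label_multiple * background_level
    if jitter_sd > 0:
        img += rng.normal(0.0, jitter_sd, n_pixels)
    img = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    return img.reshape(shape)
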