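"""Multi-shell diffusion gradient schemes.

A scheme is the acquisition's gradient table: a set of unit direction
vectors shared across every non-zero b-value shell, plus a block of
unweighted (b = 0) volumes. The default parameters mirror a typical
preclinical multi-shell kurtosis protocol: 30 directions at
b = 1000/1500/2000 s/mm^2 after 5 b = 0 volumes, with gradient duration
delta = 4 ms and separation Delta = 23 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GradientScheme", "make_scheme"]

_UNIT_TOL = 1e-6


@dataclass(frozen=True)
class GradientScheme:
    """Directions and b-values defining a multi-shell acquisition.

    Parameters
    ----------
    directions : (n_directions, 3) ndarray
        Unit gradient directions, shared by every shell.
    shell_bvalues : tuple of float
        Non-zero b-values, s/mm^2, one per shell.
    n_b0 : int
        Number of unweighted (b = 0) volumes, stored first.
    delta_ms, Delta_ms : float or None
        Optional gradient-pulse duration and separation metadata (ms).

    Volume ordering is the b0 block followed by the shells in order, each
    shell containing every direction (shell-major).
    """

    directions: np.ndarray
    shell_bvalues: tuple
    n_b0: int
    delta_ms: float | None = None
    Delta_ms: float | None = None

    def __post_init__(self):
        dirs = np.atleast_2d(np.asarray(self.directions, dtype=float))
        if dirs.ndim != 2 or dirs.shape[1] != 3:
            raise ValueError(f"directions must be (n, 3); got {dirs.shape}")
        norms = np.linalg.norm(dirs, axis=1)
        if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
            bad = int(np.argmax(np.abs(norms - 1.0)))
            raise ValueError(
                f"direction {bad} has norm {norms[bad]:.8f}, expected 1 +/- {_UNIT_TOL}"
            )
        bvals = tuple(float(b) for b in self.shell_bvalues)
        if any(b <= 0 for b in bvals):
            raise ValueError(f"shell b-values must be > 0; got {bvals}")
        if self.n_b0 < 1:
            raise ValueError("at least one b = 0 volume is required")
        object.__setattr__(self, "directions", dirs)
        object.__setattr__(self, "shell_bvalues", bvals)

    @property
    def n_directions(self) -> int:
        return self.directions.shape[0]

    @property
    def n_shells(self) -> int:
        return len(self.shell_bvalues)

    @property
    def n_volumes(self) -> int:
        return self.n_b0 + self.n_directions * self.n_shells

    @property
    def bvals(self) -> np.ndarray:
        """Per-volume b-values (s/mm^2); 0 for the b0 block."""
        out = np.zeros(self.n_volumes)
        for i, b in enumerate(self.shell_bvalues):
            lo = self.n_b0 + i * self.n_directions
            out[lo : lo + self.n_directions] = b
        return out

    @property
    def bvecs(self) -> np.ndarray:
        """Per-volume gradient vectors, (n_volumes, 3); zero rows for b0."""
        out = np.zeros((self.n_volumes, 3))
        for i in range(self.n_shells):
            lo = self.n_b0 + i * self.n_directions
            out[lo : lo + self.n_directions] = self.directions
        return out

    def weighted_index(self, shell: int) -> slice:
        """Volume slice for one shell (all directions at that b)."""
        lo = self.n_b0 + shell * self.n_directions
        return slice(lo, lo + self.n_directions)


def _repulsion(points: np.ndarray, n_iter: int = 400, step: float = 0.05) -> np.ndarray:
    """Spread antipodally-symmetric unit vectors by electrostatic repulsion.

    Each point interacts with every other point and its antipode with an
    inverse-square force; the tangential component moves the point, which is
    re-normalized each iteration. Deterministic for a fixed starting set.
    """
    p = points / np.linalg.norm(points, axis=1, keepdims=True)
    for _ in range(n_iter):
        force = np.zeros_like(p)
        for signed in (p, -p):
            diff = p[:, None, :] - signed[None, :, :]  # (n, n, 3)
            dist2 = np.sum(diff * diff, axis=2)
            np.fill_diagonal(dist2, np.inf)
            dist2[dist2 < 1e-12] = np.inf
            force += np.sum(diff / dist2[..., None] ** 1.5, axis=1)
        # keep only the tangential component
        force -= np.sum(force * p, axis=1, keepdims=True) * p
        fmax = np.max(np.linalg.norm(force, axis=1))
        if fmax > 0:
            p = p + step * force / fmax
        p /= np.linalg.norm(p, axis=1, keepdims=True)
    return p


def make_scheme(
    n_directions: int,
    shell_bvalues,
    n_b0: int,
    seed: int = 0,
    delta_ms: float | None = 4.0,
    Delta_ms: float | None = 23.0,
) -> GradientScheme:
    """Build a multi-shell scheme with approximately uniform directions.

    Directions start from a seeded random draw on the sphere and are refined
    by electrostatic repulsion with antipodal symmetry, the standard way to
    construct well-conditioned diffusion encoding sets when the scanner's
    table is not available. The same direction set is reused on every shell.

    Raises
    ------
    ValueError
        If ``n_directions < 6`` (a diffusion tensor fit would be
        underdetermined), any shell b-value is non-positive, or ``n_b0 < 1``.
    """
    if n_directions < 6:
        raise ValueError(
            f"n_directions = {n_directions} < 6: tensor fit would be underdetermined"
        )
    rng = np.random.default_rng(seed)
    pts = rng.standard_normal((n_directions, 3))
    pts = _repulsion(pts)
    return GradientScheme(
        directions=pts,
        shell_bvalues=tuple(shell_bvalues),
        n_b0=n_b0,
        delta_ms=delta_ms,
        Delta_ms=Delta_ms,
    )
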