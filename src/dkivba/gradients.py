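"""Diffusion gradient tables (b-values and encoding directions).

A multi-shell acquisition is described by one b-value and one unit direction
per acquired volume.  Direction sets are laid out by electrostatic repulsion
on the half-sphere, the standard construction when a scanner's native vectors
are not available.  FSL-style ``bvals``/``bvecs`` text files are the on-disk
form.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "GradientScheme",
    "InvalidSchemeError",
    "make_scheme",
    "repulsion_directions",
    "sphere_directions",
    "read_bvals_bvecs",
    "write_bvals_bvecs",
]

_MIN_DIRECTIONS_DT = 6  # a diffusion tensor has 6 free elements
_MIN_DIRECTIONS_KT = 15  # a kurtosis tensor adds 15 more


class InvalidSchemeError(ValueError):
    """Raised when a gradient table cannot support the requested fit."""


@dataclass(frozen=True)
class GradientScheme:
    """Per-volume b-values (s/mm^2) and unit gradient directions.

    The direction of a b=0 volume is stored as the zero vector.
    """

    bvals: np.ndarray  # (n_volumes,)
    bvecs: np.ndarray  # (n_volumes, 3)

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float)
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.shape != (bvals.size, 3):
            raise InvalidSchemeError(
                f"bvecs shape {bvecs.shape} does not match {bvals.size} b-values"
            )
        if np.any(bvals < 0):
            raise InvalidSchemeError("negative b-values")
        if not np.any(bvals == 0):
            raise InvalidSchemeError("at least one b=0 volume is required")
        norms = np.linalg.norm(bvecs[bvals > 0], axis=1)
        if norms.size and not np.allclose(norms, 1.0, atol=1e-6):
            raise InvalidSchemeError("nonzero-b directions must be unit vectors")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    @property
    def n_volumes(self) -> int:
        return self.bvals.size

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def shells(self) -> np.ndarray:
        """Sorted unique nonzero b-values."""
        return np.unique(self.bvals[self.bvals > 0])

    def unique_directions(self, decimals: int = 8) -> np.ndarray:
        """Distinct nonzero-b directions, antipodes identified."""
        vecs = self.bvecs[self.bvals > 0]
        # canonicalize sign so n and -n collapse
        lead = vecs[np.arange(len(vecs)), np.argmax(np.abs(vecs), axis=1)]
        canon = vecs * np.where(lead < 0, -1.0, 1.0)[:, None]
        return np.unique(np.round(canon, decimals), axis=0)

    def validate_for_kurtosis(self) -> None:
        """Check identifiability of the 22-parameter diffusion-kurtosis model."""
        if len(self.shells) < 2:
            raise InvalidSchemeError("kurtosis fitting needs >= 2 nonzero shells")
        if len(self.unique_directions()) < _MIN_DIRECTIONS_KT:
            raise InvalidSchemeError(
                "kurtosis fitting needs >= 15 unique directions"
            )


def _repulsion_energy(flat: np.ndarray, n: int) -> float:
    pts = flat.reshape(n, 3)
    pts = pts / np.linalg.norm(pts, axis=1, keepdims=True)
    iu = np.triu_indices(n, k=1)
    diff = np.linalg.norm(pts[iu[0]] - pts[iu[1]], axis=1)
    summ = np.linalg.norm(pts[iu[0]] + pts[iu[1]], axis=1)
    return float(np.sum(1.0 / np.maximum(diff, 1e-12) + 1.0 / np.maximum(summ, 1e-12)))


@functools.lru_cache(maxsize=32)
def _repulsion_cached(n: int, seed: int) -> tuple:
    rng = np.random.default_rng(seed)
    x0 = rng.standard_normal((n, 3))
    x0 /= np.linalg.norm(x0, axis=1, keepdims=True)
    res = minimize(
        _repulsion_energy, x0.ravel(), args=(n,), method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-10},
    )
    pts = res.x.reshape(n, 3)
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    # flip to the +z half-sphere for a canonical layout
    flip = pts[:, 2] < 0
    pts[flip] *= -1.0
    return tuple(map(tuple, pts))


def repulsion_directions(n: int, seed: int = 0) -> np.ndarray:
    """``n`` quasi-uniform unit vectors from electrostatic repulsion.

    Pairs interact through a Coulomb potential applied to both a point and
    its antipode, so the layout is uniform over orientations (the quantity
    that matters for diffusion encoding).  Deterministic for a fixed seed.
    """
    if n < 1:
        raise InvalidSchemeError("need at least one direction")
    return np.array(_repulsion_cached(int(n), int(seed)), dtype=float)


def sphere_directions(n: int = 321) -> np.ndarray:
    """A deterministic dense direction set (Fibonacci half-sphere layout)."""
    i = np.arange(n) + 0.5
    z = i / n  # half sphere: z in (0, 1)
    phi = np.pi * (1.0 + 5.0**0.5) * i
    r = np.sqrt(1.0 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def make_scheme(
    n_dirs_per_shell: int,
    bvals: list[float] | np.ndarray,
    seed: int = 0,
) -> GradientScheme:
    """Build a multi-shell scheme: one b=0 volume per listed zero, plus the
    same ``n_dirs_per_shell`` repulsion directions replicated on every
    nonzero shell.

    Raises
    ------
    InvalidSchemeError
        If fewer than 6 directions are requested (a diffusion tensor would
        be underdetermined) or no b=0 is included.
    """
    if n_dirs_per_shell < _MIN_DIRECTIONS_DT:
        raise InvalidSchemeError(
            f"{n_dirs_per_shell} directions cannot determine a diffusion tensor"
        )
    bvals = np.asarray(bvals, dtype=float)
    if not np.any(bvals == 0):
        raise InvalidSchemeError("scheme must include b=0")
    dirs = repulsion_directions(n_dirs_per_shell, seed=seed)
    all_b = []
    all_v = []
    for b in bvals[bvals == 0]:
        all_b.append(np.array([0.0]))
        all_v.append(np.zeros((1, 3)))
    for b in np.sort(bvals[bvals > 0]):
        all_b.append(np.full(n_dirs_per_shell, float(b)))
        all_v.append(dirs)
    return GradientScheme(np.concatenate(all_b), np.vstack(all_v))


def read_bvals_bvecs(bvals_path: str | Path, bvecs_path: str | Path) -> GradientScheme:
    """Read an FSL-style gradient table (one row of b; three rows of x/y/z)."""
    bvals = np.loadtxt(bvals_path).ravel()
    bvecs = np.loadtxt(bvecs_path)
    if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        # ambiguous 3x3: FSL convention is 3 rows of components
        bvecs = bvecs.T
    return GradientScheme(bvals, bvecs)


def write_bvals_bvecs(
    scheme: GradientScheme, bvals_path: str | Path, bvecs_path: str | Path
) -> None:
    np.savetxt(bvals_path, scheme.bvals[None, :], fmt="%.1f")
    np.savetxt(bvecs_path, scheme.bvecs.T, fmt="%.8f")
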