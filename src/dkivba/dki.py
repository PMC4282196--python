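"""Diffusional kurtosis model: per-voxel fitting and scalar map derivation.

The signal of water diffusing in tissue deviates from the mono-exponential
Gaussian decay when probed at high diffusion weighting.  Along a gradient
direction ``n`` the magnitude signal follows

    ln S(b, n) = ln S0 - b * D_app(n) + (1/6) * b^2 * D_app(n)^2 * K_app(n)

with the directional projections

    D_app(n) = sum_ij  n_i n_j D_ij
    K_app(n) = (MD^2 / D_app(n)^2) * sum_ijkl n_i n_j n_k n_l W_ijkl

where ``D`` is the symmetric 2nd-order diffusion tensor (6 unique elements,
mm^2/s), ``W`` the fully symmetric 4th-order kurtosis tensor (15 unique
elements, dimensionless) and ``MD = trace(D)/3``.

Estimation is by linear least squares on the log-signal in the 22 parameters
``(ln S0, D, V)`` with ``V = MD^2 * W`` entering linearly, followed by one
reweighting pass with weights equal to the squared predicted signal (the
standard heteroscedasticity correction for log-transformed Rician-magnitude
data).  ``W`` is recovered as ``V / MD^2`` afterwards.

Scalar maps:

* mean kurtosis ``MK``    — K_app averaged over a direction set;
* axial kurtosis ``K//``  — eigen-kurtosis along the principal diffusion
  eigenvector;
* radial kurtosis ``K_|_``— mean of the eigen-kurtoses along the two
  non-principal eigenvectors,

where the eigen-kurtosis along eigenvector i is
``Khat_i = (MD^2 / lambda_i^2) * What_iiii`` and ``What`` is the kurtosis
tensor rotated into the diffusion-tensor eigenframe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gradients import GradientScheme, sphere_directions

__all__ = [
    "KurtosisFit",
    "KurtosisMaps",
    "DirectionalKurtosis",
    "FLAG_NONPOS_SIGNAL",
    "FLAG_NONPOS_D",
    "FLAG_CLIPPED",
    "FLAG_FIT_FAIL",
    "W_INDICES",
    "W_MULTIPLICITY",
    "design_matrix",
    "quadratic_form",
    "quartic_form",
    "w15_to_full",
    "full_to_w15",
    "rotate_kt",
    "fit_voxel",
    "fit_volume",
    "apparent_along",
    "kurtosis_maps",
]

# quality-flag bits
FLAG_NONPOS_SIGNAL = 1  # voxel had a non-positive signal sample; excluded
FLAG_NONPOS_D = 2       # non-positive-definite diffusion tensor
FLAG_CLIPPED = 4        # a kurtosis metric hit the clip range
FLAG_FIT_FAIL = 8       # linear system singular or non-finite result

# the 15 unique elements of a fully symmetric 4th-order tensor, with the
# number of index permutations each represents
W_INDICES: tuple[tuple[int, int, int, int], ...] = (
    (0, 0, 0, 0), (1, 1, 1, 1), (2, 2, 2, 2),
    (0, 0, 0, 1), (0, 0, 0, 2), (0, 1, 1, 1),
    (1, 1, 1, 2), (0, 2, 2, 2), (1, 2, 2, 2),
    (0, 0, 1, 1), (0, 0, 2, 2), (1, 1, 2, 2),
    (0, 0, 1, 2), (0, 1, 1, 2), (0, 1, 2, 2),
)
W_MULTIPLICITY = np.array([1, 1, 1, 4, 4, 4, 4, 4, 4, 6, 6, 6, 12, 12, 12], dtype=float)

# 6 unique elements of a symmetric 2nd-order tensor: xx, yy, zz, xy, xz, yz
D_INDICES = ((0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2))
D_MULTIPLICITY = np.array([1, 1, 1, 2, 2, 2], dtype=float)


def _quad_design(vecs: np.ndarray) -> np.ndarray:
    """(n, 6) rows such that row @ D6 = n^T D n."""
    v = np.atleast_2d(vecs)
    cols = [v[:, i] * v[:, j] for i, j in D_INDICES]
    return np.column_stack(cols) * D_MULTIPLICITY


def _quart_design(vecs: np.ndarray) -> np.ndarray:
    """(n, 15) rows such that row @ W15 = sum n_i n_j n_k n_l W_ijkl."""
    v = np.atleast_2d(vecs)
    cols = [v[:, i] * v[:, j] * v[:, k] * v[:, l] for i, j, k, l in W_INDICES]
    return np.column_stack(cols) * W_MULTIPLICITY


def quadratic_form(d6: np.ndarray, vecs: np.ndarray) -> np.ndarray:
    """Evaluate n^T D n for unique-element vector(s) ``d6`` (..., 6)."""
    return np.asarray(d6) @ _quad_design(vecs).T


def quartic_form(w15: np.ndarray, vecs: np.ndarray) -> np.ndarray:
    """Evaluate the full quartic contraction of ``W`` along direction(s)."""
    return np.asarray(w15) @ _quart_design(vecs).T


def w15_to_full(w15: np.ndarray) -> np.ndarray:
    """Expand 15 unique elements to the full symmetric (3,3,3,3) tensor."""
    w15 = np.asarray(w15, dtype=float)
    full = np.zeros(w15.shape[:-1] + (3, 3, 3, 3))
    from itertools import permutations

    for val_idx, idx in enumerate(W_INDICES):
        for perm in set(permutations(idx)):
            full[..., perm[0], perm[1], perm[2], perm[3]] = w15[..., val_idx]
    return full


def full_to_w15(full: np.ndarray) -> np.ndarray:
    full = np.asarray(full, dtype=float)
    out = np.empty(full.shape[:-4] + (15,))
    for k, (i, j, a, b) in enumerate(W_INDICES):
        out[..., k] = full[..., i, j, a, b]
    return out


def d6_to_matrix(d6: np.ndarray) -> np.ndarray:
    d6 = np.asarray(d6, dtype=float)
    m = np.zeros(d6.shape[:-1] + (3, 3))
    for k, (i, j) in enumerate(D_INDICES):
        m[..., i, j] = d6[..., k]
        m[..., j, i] = d6[..., k]
    return m


def matrix_to_d6(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    out = np.empty(m.shape[:-2] + (6,))
    for k, (i, j) in enumerate(D_INDICES):
        out[..., k] = m[..., i, j]
    return out


def design_matrix(scheme: GradientScheme) -> np.ndarray:
    """(n_volumes, 22) design for the log-linear diffusion-kurtosis model.

    Columns: intercept ln S0; -b * quadratic terms (6); (b^2/6) * quartic
    terms (15).  The quartic coefficients estimate ``V = MD^2 * W``.
    """
    b = scheme.bvals[:, None]
    quad = _quad_design(scheme.bvecs)
    quart = _quart_design(scheme.bvecs)
    return np.hstack([np.ones((scheme.n_volumes, 1)), -b * quad, (b**2 / 6.0) * quart])


@dataclass
class KurtosisFit:
    """Per-voxel diffusion-kurtosis fit; arrays share a leading voxel shape.

    Attributes
    ----------
    s0 : baseline signal, arbitrary units.
    d6 : diffusion tensor unique elements (xx, yy, zz, xy, xz, yz), mm^2/s.
    w15 : kurtosis tensor unique elements, dimensionless (order ``W_INDICES``).
    md : mean diffusivity trace(D)/3, mm^2/s.
    eigvals : diffusion eigenvalues sorted descending, mm^2/s.
    eigvecs : orthonormal eigenvectors as columns, matching ``eigvals``.
    flags : integer bit-field of quality flags.
    """

    s0: np.ndarray
    d6: np.ndarray
    w15: np.ndarray
    md: np.ndarray = field(init=False)
    eigvals: np.ndarray = field(init=False)
    eigvecs: np.ndarray = field(init=False)
    flags: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.s0 = np.asarray(self.s0, dtype=float)
        self.d6 = np.asarray(self.d6, dtype=float)
        self.w15 = np.asarray(self.w15, dtype=float)
        if self.flags is None:
            self.flags = np.zeros(self.s0.shape, dtype=np.int16)
        else:
            self.flags = np.asarray(self.flags, dtype=np.int16)
        self.md = self.d6[..., :3].mean(axis=-1)
        mats = d6_to_matrix(self.d6)
        vals, vecs = np.linalg.eigh(mats)  # ascending
        order = np.argsort(vals, axis=-1)[..., ::-1]
        self.eigvals = np.take_along_axis(vals, order, axis=-1)
        self.eigvecs = np.take_along_axis(vecs, order[..., None, :], axis=-1)
        self.flags = self.flags | np.where(
            self.eigvals[..., -1] <= 0, FLAG_NONPOS_D, 0
        ).astype(np.int16)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.s0.shape


@dataclass
class DirectionalKurtosis:
    """Apparent diffusivity and kurtosis along one direction."""

    d_app: np.ndarray
    k_app: np.ndarray


@dataclass
class KurtosisMaps:
    """Scalar kurtosis volumes with a validity mask and the clip flags."""

    mk: np.ndarray
    k_axial: np.ndarray
    k_radial: np.ndarray
    valid_mask: np.ndarray
    flags: np.ndarray


def fit_volume(
    signals: np.ndarray,
    scheme: GradientScheme,
    mask: np.ndarray | None = None,
) -> KurtosisFit:
    """Weighted linear least-squares diffusion-kurtosis fit.

    Parameters
    ----------
    signals : array, shape (..., n_volumes)
        Diffusion-weighted intensities; any leading voxel shape.
    scheme : GradientScheme
        Must satisfy the 2-shell / 15-direction identifiability requirement.
    mask : boolean array matching the leading shape, optional
        Voxels outside the mask are skipped (flagged as fit failures).

    Degenerate voxels (non-positive samples, singular systems, non-positive
    mean diffusivity) are flagged, never raised.
    """
    scheme.validate_for_kurtosis()
    signals = np.asarray(signals, dtype=float)
    vshape = signals.shape[:-1]
    flat = signals.reshape(-1, scheme.n_volumes)
    nvox = flat.shape[0]
    if mask is None:
        inmask = np.ones(nvox, dtype=bool)
    else:
        inmask = np.asarray(mask, dtype=bool).reshape(-1)

    # solve in rescaled units (b in ms/um^2, D in um^2/ms) so the design
    # columns are O(1); rescale the coefficients back afterwards
    scaled = GradientScheme(scheme.bvals * 1e-3, scheme.bvecs)
    X = design_matrix(scaled)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("gradient scheme yields a singular design matrix")

    flags = np.zeros(nvox, dtype=np.int16)
    flags[~inmask] |= FLAG_FIT_FAIL
    pos = np.all(flat > 0, axis=1) & np.all(np.isfinite(flat), axis=1)
    flags[inmask & ~pos] |= FLAG_NONPOS_SIGNAL
    good = inmask & pos

    beta = np.zeros((nvox, 22))
    if np.any(good):
        lns = np.log(flat[good])
        # pass 1: ordinary least squares
        b0 = np.linalg.lstsq(X, lns.T, rcond=None)[0].T  # (ngood, 22)
        # pass 2: weights = squared predicted signal, solved by batched QR
        # on the sqrt-weighted design (avoids squaring the conditioning)
        sw = np.exp(b0 @ X.T)  # sqrt of the weights
        Xw = sw[:, :, None] * X[None, :, :]
        with np.errstate(all="ignore"):
            Q, R = np.linalg.qr(Xw)
            qty = np.einsum("vnj,vn->vj", Q, sw * lns, optimize=True)
            try:
                sol = np.linalg.solve(R, qty[..., None])[..., 0]
            except np.linalg.LinAlgError:
                sol = np.full_like(qty, np.nan)
                for i in range(R.shape[0]):
                    try:
                        sol[i] = np.linalg.solve(R[i], qty[i])
                    except np.linalg.LinAlgError:
                        pass
        bad = ~np.all(np.isfinite(sol), axis=1)
        sol[bad] = b0[bad]  # fall back to the unweighted solution
        beta[good] = sol

    s0 = np.exp(beta[:, 0])
    s0[~good] = 0.0
    d6 = beta[:, 1:7] * 1e-3   # um^2/ms -> mm^2/s
    v15 = beta[:, 7:22] * 1e-6
    md = d6[:, :3].mean(axis=1)
    w15 = np.zeros_like(v15)
    ok_md = md > 0
    w15[ok_md] = v15[ok_md] / (md[ok_md, None] ** 2)
    flags[good & ~ok_md] |= FLAG_NONPOS_D

    fit = KurtosisFit(
        s0=s0.reshape(vshape),
        d6=d6.reshape(vshape + (6,)),
        w15=w15.reshape(vshape + (15,)),
        flags=flags.reshape(vshape),
    )
    return fit


def fit_voxel(signals: np.ndarray, scheme: GradientScheme) -> KurtosisFit:
    """Fit a single voxel's signal vector (convenience wrapper)."""
    return fit_volume(np.asarray(signals, dtype=float)[None, :], scheme)


def apparent_along(fit: KurtosisFit, direction: np.ndarray) -> DirectionalKurtosis:
    """Apparent diffusivity and kurtosis along a unit direction.

    Voxels with non-positive directional diffusivity return NaN kurtosis.
    """
    n = np.asarray(direction, dtype=float)
    if not np.isclose(np.linalg.norm(n), 1.0, atol=1e-6):
        raise ValueError("direction must be unit-norm")
    d_app = quadratic_form(fit.d6, n)[..., 0]
    quart = quartic_form(fit.w15, n)[..., 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        k_app = np.where(d_app > 0, fit.md**2 / d_app**2 * quart, np.nan)
    return DirectionalKurtosis(d_app=d_app, k_app=k_app)


def rotate_kt(fit: KurtosisFit) -> np.ndarray:
    """Kurtosis tensor in the diffusion-tensor eigenframe (15 elements).

    With R the matrix whose columns are the unit eigenvectors ordered by
    descending eigenvalue, the transformed tensor is
    ``What_ijkl = sum_abcd R_ai R_bj R_ck R_dl W_abcd``; full index symmetry
    is preserved by construction.
    """
    full = w15_to_full(fit.w15)
    R = fit.eigvecs
    rotated = np.einsum(
        "...ai,...bj,...ck,...dl,...abcd->...ijkl", R, R, R, R, full, optimize=True
    )
    return full_to_w15(rotated)


def kurtosis_maps(
    fit: KurtosisFit,
    scheme: GradientScheme | None = None,
    mk_directions: str | np.ndarray = "acquired",
    clip_range: tuple[float, float] = (0.0, 10.0),
) -> KurtosisMaps:
    """Derive MK, axial and radial kurtosis volumes from a fit.

    Eigen-kurtoses are ``Khat_i = (MD^2/lambda_i^2) * What_iiii``;
    ``k_axial = Khat_1`` (principal eigenvector, largest eigenvalue) and
    ``k_radial = (Khat_2 + Khat_3)/2``.  MK is the unweighted mean of
    ``K_app`` over the chosen direction set.

    Parameters
    ----------
    mk_directions : "acquired" | "sphere321" | array (n, 3)
        Direction set over which MK averages.  "acquired" uses the scheme's
        unique nonzero-b directions (requires ``scheme``); "sphere321" a
        dense deterministic 321-point half-sphere layout.
    clip_range : (lo, hi)
        Metrics outside this range are clipped and the voxel flagged.
    """
    if isinstance(mk_directions, str):
        if mk_directions == "acquired":
            if scheme is None:
                raise ValueError("mk_directions='acquired' requires a scheme")
            dirs = scheme.unique_directions()
        elif mk_directions == "sphere321":
            dirs = sphere_directions(321)
        else:
            raise ValueError(f"unknown mk_directions policy {mk_directions!r}")
    else:
        dirs = np.asarray(mk_directions, dtype=float)

    flags = fit.flags.copy()
    lam = fit.eigvals
    pos_lam = lam[..., -1] > 0

    with np.errstate(divide="ignore", invalid="ignore"):
        # eigen-kurtoses: quartic form of W along each eigenvector
        khat = np.empty(fit.shape + (3,))
        for i in range(3):
            v = fit.eigvecs[..., :, i]
            quart = np.einsum("...j,...j->...", _quart_vec(v), fit.w15)
            khat[..., i] = fit.md**2 / lam[..., i] ** 2 * quart
        k_axial = khat[..., 0]
        k_radial = 0.5 * (khat[..., 1] + khat[..., 2])

        d_app = quadratic_form(fit.d6, dirs)  # (..., ndirs)
        quart = quartic_form(fit.w15, dirs)
        k_app = fit.md[..., None] ** 2 / d_app**2 * quart
        mk = k_app.mean(axis=-1)

    valid = pos_lam & ((flags & (FLAG_NONPOS_SIGNAL | FLAG_FIT_FAIL)) == 0)
    flags[~pos_lam] |= FLAG_NONPOS_D

    lo, hi = clip_range
    for arr in (mk, k_axial, k_radial):
        arr[~valid] = np.nan
        clipped = valid & ((arr < lo) | (arr > hi))
        flags[clipped] |= FLAG_CLIPPED
        np.clip(arr, lo, hi, out=arr)

    return KurtosisMaps(mk=mk, k_axial=k_axial, k_radial=k_radial,
                        valid_mask=valid, flags=flags)


def _quart_vec(v: np.ndarray) -> np.ndarray:
    """Per-voxel quartic design row for a field of directions (..., 3)."""
    comps = [
        v[..., i] * v[..., j] * v[..., k] * v[..., l] for i, j, k, l in W_INDICES
    ]
    return np.stack(comps, axis=-1) * W_MULTIPLICITY
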