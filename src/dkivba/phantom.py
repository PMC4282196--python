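"""Synthetic multi-shell DWI phantoms, two-group cohorts and clinical scores.

The generator emulates, at desk scale, a gray-matter DKI study: a 3D grid of
voxels with known ground-truth diffusion and kurtosis tensors, a multi-shell
acquisition (b = 0/1000/2000 s/mm^2, 25 directions per shell), Rician
magnitude noise at a b=0 SNR in the 26-46 range typical of 3 T echo-planar
DWI, a localized "lesion" in which the patient group's kurtosis tensor is
scaled down, and clinical-score tables drawn from stated group means/SDs.

The per-subject score table of the source cohort (18 patients with internet
gaming addiction, 21 healthy controls: sex, age, education, CIAS, SAS, SDS
and BIS-11 scores) ships as a plain-CSV fixture, loadable with
:func:`load_table2_fixture`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from . import dki
from .gradients import GradientScheme

__all__ = [
    "Region",
    "PhantomSpec",
    "EffectSpec",
    "ScoreModel",
    "GroupScoreParams",
    "isotropic_w15",
    "default_phantom",
    "simulate_signals",
    "simulate_cohort",
    "simulate_scores",
    "default_score_model",
    "load_table2_fixture",
    "InvalidGroundTruthError",
    "UnknownRegionError",
]


class InvalidGroundTruthError(ValueError):
    """Ground-truth tensors produce a non-positive apparent diffusivity."""


class UnknownRegionError(KeyError):
    """An effect refers to a region_id absent from the phantom."""


def isotropic_w15(k: float) -> np.ndarray:
    """Unique elements of an isotropic kurtosis tensor with K_app = k in
    every direction: W_iiii = k, W_iijj = k/3, odd elements zero."""
    w = np.zeros(15)
    w[0:3] = k
    w[9:12] = k / 3.0
    return w


@dataclass
class Region:
    """A labelled voxel set sharing one ground-truth tensor pair.

    ``eigvals`` are the diffusion-tensor eigenvalues (mm^2/s, descending);
    ``w15`` the kurtosis tensor's 15 unique elements in the region frame;
    ``frame`` an optional rotation whose columns are the principal axes
    (identity = tensors aligned with the grid axes).
    """

    region_id: str
    mask: np.ndarray
    eigvals: tuple[float, float, float]
    w15: np.ndarray
    frame: np.ndarray | None = None

    def tensors(self) -> tuple[np.ndarray, np.ndarray]:
        """Lab-frame (d6, w15) for this region."""
        lam = np.sort(np.asarray(self.eigvals, dtype=float))[::-1]
        if lam[-1] <= 0:
            raise InvalidGroundTruthError(f"region {self.region_id}: eigenvalues must be > 0")
        if self.frame is None:
            d6 = np.array([lam[0], lam[1], lam[2], 0.0, 0.0, 0.0])
            return d6, np.asarray(self.w15, dtype=float)
        R = np.asarray(self.frame, dtype=float)
        D = R @ np.diag(lam) @ R.T
        d6 = dki.matrix_to_d6(D)
        full = dki.w15_to_full(self.w15)
        rot = np.einsum("ia,jb,kc,ld,abcd->ijkl", R, R, R, R, full)
        return d6, dki.full_to_w15(rot)


@dataclass
class PhantomSpec:
    """Geometry, ground truth and noise level of a DWI phantom.

    ``snr_b0`` is the signal-to-noise ratio of tissue at b=0 (noise sigma =
    s0 / snr_b0, applied to the complex channels before taking magnitude);
    ``np.inf`` disables noise.
    """

    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    regions: list[Region] = field(default_factory=list)
    snr_b0: float = 46.0
    s0: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if not self.snr_b0 > 0:
            raise ValueError("snr_b0 must be > 0")
        occupancy = np.zeros(self.grid_shape, dtype=int)
        for r in self.regions:
            if r.mask.shape != tuple(self.grid_shape):
                raise ValueError(f"region {r.region_id} mask shape mismatch")
            occupancy += r.mask.astype(int)
        if np.any(occupancy > 1):
            raise ValueError("regions overlap")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size) + [1.0])
        return aff

    def tissue_mask(self) -> np.ndarray:
        m = np.zeros(self.grid_shape, dtype=bool)
        for r in self.regions:
            m |= r.mask
        return m

    def region(self, region_id: str) -> Region:
        for r in self.regions:
            if r.region_id == region_id:
                return r
        raise UnknownRegionError(region_id)


@dataclass(frozen=True)
class EffectSpec:
    """Patient-group alteration: scale the kurtosis tensor down in a region.

    ``kurtosis_scale`` in (0, 1]: 1 means no effect; values below 1 reduce
    every kurtosis metric (MK, axial, radial) in the region by that factor.
    """

    region_id: str
    kurtosis_scale: float = 1.0
    applies_to: tuple[str, ...] = ("mk", "k_axial", "k_radial")

    def __post_init__(self) -> None:
        if not 0.0 < self.kurtosis_scale <= 1.0:
            raise ValueError("kurtosis_scale must be in (0, 1]")


def default_phantom(
    snr_b0: float = 46.0,
    seed: int = 0,
    grid: int = 24,
    lesion_size: int = 5,
) -> PhantomSpec:
    """Two-class phantom: a gray-matter-like ball with an embedded cubic
    lesion region of identical baseline tensors.

    GM-like tissue: mildly anisotropic diffusion, eigenvalues
    (1.2, 1.0, 0.9) x 1e-3 mm^2/s, isotropic kurtosis giving MK ~ 0.9 —
    values in the physiological range for cortical gray matter at 3 T.
    """
    shape = (grid, grid, grid)
    center = (np.array(shape) - 1) / 2.0
    ijk = np.indices(shape).reshape(3, -1).T
    radius = grid * 0.42
    ball = (np.linalg.norm(ijk - center, axis=1) <= radius).reshape(shape)

    lo = grid // 2 - lesion_size // 2
    lesion = np.zeros(shape, dtype=bool)
    lesion[lo : lo + lesion_size, lo : lo + lesion_size, lo : lo + lesion_size] = True
    lesion &= ball
    gm = ball & ~lesion

    eigvals = (1.2e-3, 1.0e-3, 0.9e-3)
    w15 = isotropic_w15(0.9)
    regions = [
        Region("gm", gm, eigvals, w15.copy()),
        Region("lesion", lesion, eigvals, w15.copy()),
    ]
    return PhantomSpec(grid_shape=shape, regions=regions, snr_b0=snr_b0, seed=seed)


def _ground_truth_beta(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-voxel (d6, w15) arrays and the tissue mask."""
    d6 = np.zeros(spec.grid_shape + (6,))
    w15 = np.zeros(spec.grid_shape + (15,))
    for r in spec.regions:
        rd6, rw15 = r.tensors()
        d6[r.mask] = rd6
        w15[r.mask] = rw15
    return d6, w15, spec.tissue_mask()


def ground_truth_maps(
    spec: PhantomSpec, scheme: GradientScheme, mk_directions: str = "acquired"
) -> dki.KurtosisMaps:
    """Noise-free kurtosis maps implied by the phantom's tensors."""
    d6, w15, tissue = _ground_truth_beta(spec)
    fit = dki.KurtosisFit(
        s0=np.where(tissue, spec.s0, 0.0), d6=d6, w15=w15,
        flags=np.where(tissue, 0, dki.FLAG_FIT_FAIL).astype(np.int16),
    )
    return dki.kurtosis_maps(fit, scheme, mk_directions=mk_directions)


def simulate_signals(
    spec: PhantomSpec,
    scheme: GradientScheme,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dki.KurtosisMaps]:
    """Forward-simulate a 4D DWI volume from the phantom's ground truth.

    Noise-free signal per voxel and volume:
    ``S = s0 * exp(-b * D_app + (1/6) b^2 D_app^2 K_app)``; Rician noise is
    the magnitude of ``(S + e1, e2)`` with ``e ~ Normal(0, s0/snr_b0)``.
    Background voxels carry no signal, only the noise floor.

    Returns the noisy 4D volume (grid + volume axis) and the ground-truth
    kurtosis maps evaluated over the scheme's directions.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    d6, w15, tissue = _ground_truth_beta(spec)

    # positivity of D_app over the scheme for every region
    for r in spec.regions:
        rd6, _ = r.tensors()
        dapp = dki.quadratic_form(rd6, scheme.bvecs[scheme.bvals > 0])
        if np.any(dapp <= 0):
            raise InvalidGroundTruthError(
                f"region {r.region_id}: non-positive apparent diffusivity"
            )

    X = dki.design_matrix(scheme)
    md = d6[..., :3].mean(axis=-1)
    v15 = w15 * md[..., None] ** 2
    beta = np.concatenate(
        [np.log(np.maximum(spec.s0, 1e-300)) * np.ones(spec.grid_shape + (1,)), d6, v15],
        axis=-1,
    )
    signal = np.where(
        tissue[..., None], np.exp(np.einsum("...p,np->...n", beta, X)), 0.0
    )

    if np.isfinite(spec.snr_b0):
        sigma = spec.s0 / spec.snr_b0
        e1 = rng.normal(0.0, sigma, size=signal.shape)
        e2 = rng.normal(0.0, sigma, size=signal.shape)
        signal = np.sqrt((signal + e1) ** 2 + e2**2)

    truth = ground_truth_maps(spec, scheme)
    return signal, truth


def apply_effect(spec: PhantomSpec, effect: EffectSpec) -> PhantomSpec:
    """Phantom with the patient-group alteration applied (W scaled)."""
    target = spec.region(effect.region_id)  # raises UnknownRegionError
    regions = []
    for r in spec.regions:
        w = np.asarray(r.w15, dtype=float).copy()
        if r.region_id == effect.region_id:
            w = w * effect.kurtosis_scale
        regions.append(Region(r.region_id, r.mask, r.eigvals, w, r.frame))
    return PhantomSpec(
        grid_shape=spec.grid_shape, voxel_size=spec.voxel_size, regions=regions,
        snr_b0=spec.snr_b0, s0=spec.s0, seed=spec.seed,
    )


def simulate_cohort(
    spec: PhantomSpec,
    effect: EffectSpec,
    n_patients: int,
    n_controls: int,
    scheme: GradientScheme,
    seed: int = 0,
):
    """Simulate a two-group cohort of noisy DWI volumes.

    Controls are drawn from ``spec``; patients from ``spec`` with the
    kurtosis tensor scaled by ``effect.kurtosis_scale`` inside the effect
    region.  Every subject gets independent noise; the whole cohort is
    deterministic under a fixed seed.

    Returns ``(volumes, labels, truths)``: a list of 4D arrays, a list of
    "patient"/"control" labels, and the two ground-truth map sets
    ``{"patient": ..., "control": ...}``.
    """
    if n_patients < 2 or n_controls < 2:
        raise ValueError("need at least 2 subjects per group")
    patient_spec = apply_effect(spec, effect)
    rng = np.random.default_rng(seed)
    volumes: list[np.ndarray] = []
    labels: list[str] = []
    for _ in range(n_patients):
        vol, _t = simulate_signals(patient_spec, scheme, rng=rng)
        volumes.append(vol)
        labels.append("patient")
    for _ in range(n_controls):
        vol, _t = simulate_signals(spec, scheme, rng=rng)
        volumes.append(vol)
        labels.append("control")
    truths = {
        "patient": ground_truth_maps(patient_spec, scheme),
        "control": ground_truth_maps(spec, scheme),
    }
    return volumes, labels, truths


# ---------------------------------------------------------------------------
# clinical scores

#: valid integer ranges of the instruments (min, max)
SCALE_RANGES = {
    "age": (10, 80),
    "education_years": (0, 25),
    "cias": (26, 104),
    "sas": (25, 100),
    "sds": (25, 100),
    "bis_attentional": (8, 32),
    "bis_motor": (11, 44),
    "bis_nonplanning": (11, 44),
    "bis_total": (30, 120),
}


@dataclass
class GroupScoreParams:
    """Mean/SD per scale plus the male fraction for one group."""

    means: dict[str, float]
    sds: dict[str, float]
    male_fraction: float


@dataclass
class ScoreModel:
    """Generative model of the clinical-score table.

    ``linkage_r`` optionally ties the patient group's CIAS score to a
    per-subject regional-kurtosis deviation (z-score): CIAS z-scores are
    ``r * z_k + sqrt(1 - r^2) * eps`` so the population correlation between
    CIAS and the regional metric equals ``r``.
    """

    patient: GroupScoreParams
    control: GroupScoreParams
    linkage_r: float = 0.0

    def __post_init__(self) -> None:
        for grp in (self.patient, self.control):
            for k, sd in grp.sds.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {k}")
        if not -1.0 < self.linkage_r < 1.0:
            raise ValueError("linkage_r must be in (-1, 1)")


def default_score_model(linkage_r: float = 0.0) -> ScoreModel:
    """Score model parameterized by the study's printed group statistics
    (patients: CIAS 74.44 +- 8.33, SAS 53.66 +- 9.71, SDS 54.72 +- 10.44,
    BIS-11 63.94 +- 8.26, age 20.5 +- 3.55, education 11.39 +- 1.85;
    controls: CIAS 38.43 +- 9.10, SAS 40.95 +- 8.44, SDS 38.57 +- 6.67,
    BIS-11 50.81 +- 6.95, age 21.95 +- 2.39, education 12.38 +- 2.13).
    BIS-11 subscale moments are taken from the per-subject fixture."""
    fx = load_table2_fixture()
    sub_means: dict[str, dict[str, float]] = {}
    sub_sds: dict[str, dict[str, float]] = {}
    for grp, key in (("IGA", "patient"), ("control", "control")):
        g = fx[fx["group"] == grp]
        sub_means[key] = {
            c: float(g[c].mean())
            for c in ("bis_attentional", "bis_motor", "bis_nonplanning")
        }
        sub_sds[key] = {
            c: float(g[c].std(ddof=1))
            for c in ("bis_attentional", "bis_motor", "bis_nonplanning")
        }
    patient = GroupScoreParams(
        means={"age": 20.5, "education_years": 11.39, "cias": 74.44, "sas": 53.66,
               "sds": 54.72, "bis_total": 63.94, **sub_means["patient"]},
        sds={"age": 3.55, "education_years": 1.85, "cias": 8.33, "sas": 9.71,
             "sds": 10.44, "bis_total": 8.26, **sub_sds["patient"]},
        male_fraction=15 / 18,
    )
    control = GroupScoreParams(
        means={"age": 21.95, "education_years": 12.38, "cias": 38.43, "sas": 40.95,
               "sds": 38.57, "bis_total": 50.81, **sub_means["control"]},
        sds={"age": 2.39, "education_years": 2.13, "cias": 9.10, "sas": 8.44,
             "sds": 6.67, "bis_total": 6.95, **sub_sds["control"]},
        male_fraction=18 / 21,
    )
    return ScoreModel(patient=patient, control=control, linkage_r=linkage_r)


def simulate_scores(
    model: ScoreModel,
    n_per_group: tuple[int, int] | int,
    seed: int = 0,
    kurtosis_deviation: np.ndarray | None = None,
) -> pd.DataFrame:
    """Draw a cohort score table from the model.

    Each scale is drawn ``Normal(mean, sd)``, rounded to the nearest
    integer, and clipped to the instrument's valid range.  Sex is assigned
    by the group's male fraction.  When ``model.linkage_r`` is nonzero, the
    patient group's CIAS is correlated with ``kurtosis_deviation``
    (per-patient z-scores; drawn internally when not supplied, and returned
    in column ``regional_kurtosis_z`` either way).

    Returns a table with the cohort-score schema (subject_id, group, sex,
    age, education_years, cias, sas, sds, bis_* columns).
    """
    if isinstance(n_per_group, int):
        n_pat = n_con = n_per_group
    else:
        n_pat, n_con = n_per_group
    if n_pat < 2 or n_con < 2:
        raise ValueError("need at least 2 subjects per group")
    rng = np.random.default_rng(seed)

    rows = []
    for group, params, n in (("IGA", model.patient, n_pat),
                             ("control", model.control, n_con)):
        z_link = None
        if group == "IGA" and model.linkage_r != 0.0:
            if kurtosis_deviation is not None:
                z_link = np.asarray(kurtosis_deviation, dtype=float)
                if z_link.shape != (n,):
                    raise ValueError("kurtosis_deviation length must equal n_patients")
            else:
                z_link = rng.standard_normal(n)
        for i in range(n):
            row: dict[str, object] = {
                "subject_id": f"{'IGA' if group == 'IGA' else 'CON'}{i + 1}",
                "group": group,
                "sex": "M" if rng.random() < params.male_fraction else "F",
            }
            for scale, mu in params.means.items():
                sd = params.sds[scale]
                if scale == "cias" and z_link is not None:
                    r = model.linkage_r
                    z = r * z_link[i] + np.sqrt(1 - r**2) * rng.standard_normal()
                    val = mu + sd * z
                else:
                    val = rng.normal(mu, sd)
                lo, hi = SCALE_RANGES[scale]
                row[scale] = int(np.clip(np.rint(val), lo, hi))
            if z_link is not None:
                row["regional_kurtosis_z"] = float(z_link[i])
            rows.append(row)
    df = pd.DataFrame(rows)
    if "regional_kurtosis_z" in df.columns:
        cols = [c for c in df.columns if c != "regional_kurtosis_z"]
        df = df[cols + ["regional_kurtosis_z"]]
    return df


def load_table2_fixture() -> pd.DataFrame:
    """The packaged per-subject score table: 39 subjects (IGA1-IGA18,
    CON1-CON21) with sex, age, education years, CIAS, SAS, SDS and BIS-11
    subscale/total scores, exactly as published."""
    with resources.files("dkivba.data").joinpath("cohort_scores.csv").open() as fh:
        return pd.read_csv(fh)
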