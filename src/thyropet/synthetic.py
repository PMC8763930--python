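"""Synthetic PET phantoms and patient cohorts.

Two generators make the whole pipeline testable without any patient data:

``generate_phantom``
    builds a two-lobe "thyroid" SUV volume with an embedded FDG-avid
    lesion of controlled volume, shape irregularity and texture
    coarseness, plus the ground-truth lesion mask and a clean
    contralateral-lobe mask for threshold estimation.

``generate_cohort``
    builds a tabular cohort with the statistical structure the feature
    selection and risk model stages assume: two informative features
    (sphericity and GLCM autocorrelation, both LOWER in malignant
    lesions), anchor PET metrics, redundant features rank-correlated
    with the anchors, independent noise features, TSH, cytology class
    and final histology.

All randomness flows from the single ``seed`` in each spec; the same spec
always yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .segmentation import LesionMask, PetVolume

__all__ = ["PhantomSpec", "CohortSpec", "Phantom", "generate_phantom", "generate_cohort"]

# Centre effects: multiplicative SUV bias and noise inflation per scanner.
# Centre A is the reference; centre B simulates a second scanner with a
# slightly different calibration and reconstruction noise.
CENTER_SUV_BIAS = {"A": 1.0, "B": 1.12}
CENTER_NOISE_SCALE = {"A": 1.0, "B": 1.2}

# Relative SD of the intra-lesion texture field (fraction of the
# lesion/background contrast).  Fixed: texture_coarseness only moves the
# spatial correlation length, never the marginal variance.
TEXTURE_REL_SD = 0.18

# Gaussian-smoothing sigma range (voxels) mapped from texture_coarseness.
TEXTURE_SIGMA_MIN = 0.3
TEXTURE_SIGMA_MAX = 3.0

# Radial perturbation amplitude at shape_irregularity = 1 (fraction of the
# nominal radius).
SHAPE_PERTURB_MAX = 0.45


@dataclass
class PhantomSpec:
    """Parameters of a single two-lobe PET phantom."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    background_suv: float = 1.2
    lesion_center: tuple[int, int, int] | None = None
    lesion_volume_ml: float = 8.0
    shape_irregularity: float = 0.0
    texture_coarseness: float = 0.5
    lesion_mean_suv: float = 5.0
    noise_sd: float = 0.08
    #: peri-nodular (ipsilateral) background as a fraction of the
    #: contralateral background.  Normal tissue around a hot nodule shows
    #: slightly suppressed uptake; this keeps the contralateral-lobe
    #: threshold ~2 noise-SDs above the local background, which is what
    #: makes the fixed-threshold protocol well-posed on noisy images (at a
    #: factor of 1.0 half the ipsilateral lobe sits above the threshold
    #: and region growing floods it).
    ipsilateral_background_factor: float = 0.85
    center_id: str = "A"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be strictly positive")
        if not self.lesion_mean_suv > self.background_suv:
            raise ValueError(
                "lesion_mean_suv must exceed background_suv: the lesion must "
                "be FDG-avid to be segmentable by the contralateral threshold"
            )
        if not 0.0 <= self.shape_irregularity <= 1.0:
            raise ValueError("shape_irregularity must lie in [0, 1]")
        if not 0.0 <= self.texture_coarseness <= 1.0:
            raise ValueError("texture_coarseness must lie in [0, 1]")
        if self.center_id not in CENTER_SUV_BIAS:
            raise ValueError(f"unknown center_id {self.center_id!r}")
        if self.lesion_center is None:
            # centre of the "right" lobe (first axis = x, lobes split on x)
            nx, ny, nz = self.grid_shape
            self.lesion_center = (int(nx * 0.28), ny // 2, nz // 2)


@dataclass
class Phantom:
    """Output bundle of :func:`generate_phantom`."""

    volume: PetVolume
    truth_mask: LesionMask
    contralateral_mask: LesionMask
    spec: PhantomSpec


def _radial_profile(rng: np.random.Generator, n_waves: int = 6):
    """A smooth zero-mean random function on the unit sphere.

    Random low-frequency cosine waves of the direction vector (random
    Fourier features of a smooth Gaussian process on S^2).  Returned as a
    closure ``g(u)`` for an (n, 3) array of unit directions, normalised to
    unit RMS over a reference direction sample so the irregularity dial has
    a comparable effect across seeds.
    """
    omega = rng.normal(size=(n_waves, 3)) * rng.uniform(2.0, 4.0, size=(n_waves, 1))
    phase = rng.uniform(0, 2 * np.pi, size=n_waves)
    coeff = rng.normal(size=n_waves)

    def raw(u: np.ndarray) -> np.ndarray:
        return np.cos(u @ omega.T + phase) @ coeff

    ref = rng.normal(size=(2048, 3))
    ref /= np.linalg.norm(ref, axis=1, keepdims=True)
    vals = raw(ref)
    mean, sd = vals.mean(), vals.std()
    if sd < 1e-12:  # degenerate draw; fall back to a sphere
        return lambda u: np.zeros(len(u))
    return lambda u: (raw(u) - mean) / sd


def _lesion_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Rasterise a star-convex lesion of the target volume.

    The boundary radius is ``r0 * (1 + a * g(u))`` with ``g`` a smooth random
    sphere function and ``a = SHAPE_PERTURB_MAX * shape_irregularity``; ``r0``
    is calibrated by bisection so the rasterised volume matches
    ``lesion_volume_ml`` to within half a voxel layer.
    """
    g = _radial_profile(rng)
    a = SHAPE_PERTURB_MAX * spec.shape_irregularity
    target_vox = spec.lesion_volume_ml * 1000.0 / float(np.prod(spec.voxel_spacing))

    grids = np.indices(spec.grid_shape).astype(float)
    offsets = [
        (grids[k] - spec.lesion_center[k]) * spec.voxel_spacing[k] for k in range(3)
    ]
    dist = np.sqrt(sum(o**2 for o in offsets))
    r_sphere = (3.0 * spec.lesion_volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)

    # evaluate the angular profile only inside a bounding shell
    shell = dist <= r_sphere * (1.0 + a) + max(spec.voxel_spacing)
    u = np.stack([o[shell] for o in offsets], axis=1)
    norms = np.maximum(np.linalg.norm(u, axis=1, keepdims=True), 1e-9)
    radius_factor = np.clip(1.0 + a * g(u / norms), 0.25, None)
    d_shell = dist[shell]

    def count(r0: float) -> int:
        return int(np.count_nonzero(d_shell < r0 * radius_factor))

    lo, hi = 0.5 * r_sphere, 1.6 * r_sphere
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if count(mid) < target_vox:
            lo = mid
        else:
            hi = mid
    r0 = 0.5 * (lo + hi)

    inside = np.zeros(spec.grid_shape, dtype=bool)
    inside[shell] = d_shell < r0 * radius_factor

    # keep the largest 26-connected component (thin spikes can detach)
    labels, n = ndimage.label(inside, structure=np.ones((3, 3, 3)))
    if n > 1:
        sizes = ndimage.sum_labels(inside, labels, index=np.arange(1, n + 1))
        inside = labels == (1 + int(np.argmax(sizes)))
    return inside


def _lobe_masks(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Two ellipsoidal 'thyroid lobes' split along the first axis."""
    nx, ny, nz = spec.grid_shape
    sx, sy, sz = spec.voxel_spacing
    grids = np.indices(spec.grid_shape).astype(float)
    semi = (0.24 * nx * sx, 0.30 * ny * sy, 0.42 * nz * sz)

    def ellipsoid(cx_frac: float) -> np.ndarray:
        c = (cx_frac * nx, ny / 2.0, nz / 2.0)
        q = sum(
            ((grids[k] - c[k]) * spec.voxel_spacing[k] / semi[k]) ** 2 for k in range(3)
        )
        return q <= 1.0

    return ellipsoid(0.28), ellipsoid(0.72)


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Build a seeded two-lobe PET phantom with an embedded lesion.

    Returns the SUV volume, the ground-truth lesion mask, and the
    contralateral-lobe mask (the clean lobe, for threshold estimation).
    Raises if the lesion does not fit inside the grid, naming the axis.
    """
    rng = np.random.default_rng(spec.seed)
    lesion = _lesion_mask(spec, rng)

    # fit check: lesion must not touch the grid boundary
    idx = np.argwhere(lesion)
    for k, axis_name in enumerate("xyz"):
        if idx[:, k].min() == 0 or idx[:, k].max() == spec.grid_shape[k] - 1:
            raise ValueError(
                f"lesion does not fit inside the grid along axis {axis_name!r}: "
                f"reduce lesion_volume_ml or move lesion_center"
            )

    lobe_lesion_side, lobe_contra = _lobe_masks(spec)

    img = np.full(spec.grid_shape, 0.05)  # soft-tissue/air floor
    img[lobe_lesion_side] = spec.background_suv * spec.ipsilateral_background_factor
    img[lobe_contra] = spec.background_suv

    # intra-lesion texture: Gaussian random field, correlation length from
    # texture_coarseness, rescaled to a fixed marginal SD
    sigma = TEXTURE_SIGMA_MIN + spec.texture_coarseness * (
        TEXTURE_SIGMA_MAX - TEXTURE_SIGMA_MIN
    )
    white = rng.normal(size=spec.grid_shape)
    smooth = ndimage.gaussian_filter(white, sigma=sigma)
    # Gaussian-copula marginal: rank-transform the in-lesion field to fixed
    # Gaussian quantiles, so texture_coarseness changes ONLY the spatial
    # arrangement of values, never their distribution (otherwise the
    # sample minimum, which anchors grey-level binning, would leak the
    # correlation length into first-order statistics).
    from scipy.special import ndtri

    contrast = spec.lesion_mean_suv - spec.background_suv
    inside = smooth[lesion]
    n_in = inside.size
    ranks = np.argsort(np.argsort(inside))
    quantiles = ndtri((ranks + 0.5) / n_in)
    img[lesion] = spec.lesion_mean_suv + TEXTURE_REL_SD * contrast * quantiles

    if spec.noise_sd > 0:
        noise_sd = spec.noise_sd * CENTER_NOISE_SCALE[spec.center_id]
        img = img + rng.normal(scale=noise_sd, size=spec.grid_shape)

    img *= CENTER_SUV_BIAS[spec.center_id]
    img = np.clip(img, 0.0, None)

    volume = PetVolume(img, spec.voxel_spacing, center_id=spec.center_id)
    truth = LesionMask(lesion, spec.voxel_spacing)
    contra = LesionMask(lobe_contra & ~lesion, spec.voxel_spacing)
    return Phantom(volume, truth, contra, spec)


# ---------------------------------------------------------------------------
# Tabular cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Parameters of a simulated indeterminate-nodule cohort.

    Defaults emulate the study conditions of a 78-patient cohort with 23
    malignant lesions, Bethesda III/IV split 35/43, and two informative
    radiomics features (sphericity and GLCM autocorrelation, both shifted
    DOWN in malignant lesions) among correlated and independent nuisance
    features.
    """

    n_patients: int = 78
    prevalence_malignant: float = 23.0 / 78.0
    bethesda_iv_fraction: float = 43.0 / 78.0
    n_noise_features: int = 40
    n_redundant_features: int = 6
    redundancy_rho: float = 0.9
    #: standardized benign-minus-malignant mean shift for
    #: (sphericity, autocorrelation); positive = lower in malignant
    effect_sizes: tuple[float, float] = (0.8, 0.8)
    tsh_median: float = 1.7
    tsh_iqr: tuple[float, float] = (1.1, 2.3)
    center_split: float = 0.85  # fraction of patients from centre A
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence_malignant < 1.0:
            raise ValueError("prevalence_malignant must lie in (0, 1)")
        if not 0.0 <= self.bethesda_iv_fraction <= 1.0:
            raise ValueError("bethesda_iv_fraction must lie in [0, 1]")


#: Conditional P(Bethesda IV | histology), from a 78-patient work-up with
#: 18/23 malignant and 25/55 benign lesions in class IV.
_P_IV_GIVEN_MALIGNANT = 18.0 / 23.0
_P_IV_GIVEN_BENIGN = 25.0 / 55.0


def _spearman_to_pearson(rho_s: float) -> float:
    """Gaussian-copula conversion: Pearson r giving Spearman rho_s."""
    return float(2.0 * np.sin(np.pi * rho_s / 6.0))


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a patient cohort as a feature table.

    Columns: ``patient_id``, ``center_id``, ``TSH``, ``SUVmax``, ``SUVmean``,
    ``MTV``, ``TLG`` (= SUVmean x MTV exactly), ``shape_Sphericity``,
    ``glcm_Autocorrelation``, ``redundant_k`` features rank-correlated with
    SUVmax/MTV at ``redundancy_rho``, ``noise_k`` independent features,
    ``bethesda_iv`` and ``malignant`` flags.

    The number of malignant rows is a stratified draw:
    ``round(prevalence * n)`` exactly.  Informative features are drawn from
    class-conditional Gaussians with equal variance, so the malignancy
    posterior is exactly logistic in the two features; effect signs make
    LOWER sphericity and LOWER autocorrelation malignant-like.
    """
    n = spec.n_patients
    n_mal = int(round(spec.prevalence_malignant * n))
    if n_mal < 2 or n - n_mal < 2:
        raise ValueError(
            "prevalence x n_patients leaves fewer than 2 patients in a class; "
            "downstream models cannot be fit"
        )
    rng = np.random.default_rng(spec.seed)

    malignant = np.zeros(n, dtype=int)
    malignant[rng.choice(n, size=n_mal, replace=False)] = 1

    center = np.where(rng.random(n) < spec.center_split, "A", "B")

    # informative features on the standardized scale (unit within-class SD)
    d_sph, d_auto = spec.effect_sizes
    sphericity = rng.normal(size=n) - d_sph * malignant
    autocorr = rng.normal(size=n) - d_auto * malignant
    # map to plausible raw scales (affine, so rank/association structure is kept)
    sphericity = 0.72 + 0.08 * sphericity
    autocorr = 14.0 + 3.0 * autocorr

    # anchor PET metrics: lognormal, mildly malignancy-associated SUVmax
    suvmax = np.exp(rng.normal(1.6, 0.45, size=n) + 0.15 * malignant)
    suvmean = suvmax * rng.uniform(0.55, 0.75, size=n)
    mtv = np.exp(rng.normal(1.9, 0.6, size=n))
    mtv = 3.0 + mtv  # volumes below 3 mL are excluded upstream
    tlg = suvmean * mtv

    # TSH: lognormal matched to the target median and IQR; uninformative
    # lognormal quartile ratio: q3/q1 = exp(1.349 sigma)
    lo, hi = spec.tsh_iqr
    sigma_tsh = max(np.log(hi / lo) / 1.349, 0.05)
    tsh = np.exp(rng.normal(np.log(spec.tsh_median), sigma_tsh, size=n))

    # cytology conditional on histology
    p_iv = np.where(malignant == 1, _P_IV_GIVEN_MALIGNANT, _P_IV_GIVEN_BENIGN)
    # recalibrate to hit the marginal IV fraction in expectation
    target = spec.bethesda_iv_fraction
    marginal = p_iv.mean()
    p_iv = np.clip(p_iv + (target - marginal), 0.02, 0.98)
    bethesda_iv = (rng.random(n) < p_iv).astype(int)

    data: dict[str, np.ndarray] = {
        "patient_id": np.array([f"P{i:03d}" for i in range(n)]),
        "center_id": center,
        "TSH": tsh,
        "SUVmax": suvmax,
        "SUVmean": suvmean,
        "MTV": mtv,
        "TLG": tlg,
        "shape_Sphericity": sphericity,
        "glcm_Autocorrelation": autocorr,
    }

    # redundant features: Gaussian-copula correlated with SUVmax or MTV
    r = _spearman_to_pearson(spec.redundancy_rho)
    anchors = {"SUVmax": suvmax, "MTV": mtv}
    anchor_names = list(anchors)
    for k in range(spec.n_redundant_features):
        anchor = anchor_names[k % len(anchor_names)]
        z_anchor = (np.argsort(np.argsort(anchors[anchor])) + 0.5) / n
        z_anchor = np.sqrt(2) * _erfinv_vec(2 * z_anchor - 1)
        z = r * z_anchor + np.sqrt(1 - r**2) * rng.normal(size=n)
        data[f"redundant_{k}"] = z

    for k in range(spec.n_noise_features):
        data[f"noise_{k}"] = rng.normal(size=n)

    data["bethesda_iv"] = bethesda_iv
    data["malignant"] = malignant
    return pd.DataFrame(data)


def _erfinv_vec(x: np.ndarray) -> np.ndarray:
    from scipy.special import erfinv

    return erfinv(np.clip(x, -1 + 1e-12, 1 - 1e-12))


def write_phantom(phantom: Phantom, directory: str | Path, stem: str) -> None:
    """Write a phantom as NIfTI volumes plus a flat key=value spec file."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    phantom.volume.to_nifti(directory / f"{stem}_suv.nii.gz")
    phantom.truth_mask.to_nifti(directory / f"{stem}_truth.nii.gz")
    phantom.contralateral_mask.to_nifti(directory / f"{stem}_contra.nii.gz")
    with open(directory / f"{stem}_spec.cfg", "w") as fh:
        for key, value in asdict(phantom.spec).items():
            if isinstance(value, tuple):
                value = ",".join(str(v) for v in value)
            fh.write(f"{key}={value}\n")
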