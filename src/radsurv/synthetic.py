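"""Synthetic phantom cohorts with a planted texture-outcome signal.

Each phantom is an ellipsoidal "tumor" on a CT-like background whose internal
texture is driven by per-patient latent factors:

* factor 0 scales the spatial correlation length of a smoothed Gaussian
  random field (coarse vs. fine texture; moves GLCM contrast, NGTDM
  coarseness),
* factor 1 scales the amplitude of an independent voxel-wise white-noise
  component (moves first-order variance and co-occurrence dispersion),
* factor 2 scales the amplitude of the correlated field itself (moves the
  spatially-structured share of the variance, e.g. GLCM correlation and
  size-zone statistics).

Outcomes are generated from the same latent factors: survival times follow an
exponential proportional-hazards model h0 * exp(beta' z) with independent
uniform censoring calibrated to a target censoring fraction, and recurrence
labels follow a logistic model.  Clinical covariates (gender, T stage,
N stage, site, resection; integer-coded) are drawn from realistic marginal
frequencies and are independent of the latent factors by default, so a model
built on them is uninformative by construction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .imaging import ImageVolume, write_volume

#: marginal frequencies used for the clinical covariates (integer codes)
CLINICAL_MARGINALS: dict[str, dict[int, float]] = {
    "gender": {0: 0.392, 1: 0.608},            # 0 = female, 1 = male
    "t_stage": {0: 0.068, 1: 0.595, 2: 0.338}, # 0 = T2, 1 = T3, 2 = T4
    "n_stage": {0: 0.554, 1: 0.446},           # 0 = N0, 1 = N1
    "site": {0: 0.797, 1: 0.041, 2: 0.041, 3: 0.081, 4: 0.041},
    "resection": {0: 0.689, 1: 0.311},         # 0 = no, 1 = yes
}
CLINICAL_COLUMNS = list(CLINICAL_MARGINALS)


@dataclass
class TextureParams:
    """Generative texture knobs (intensities in CT-like arbitrary units)."""

    base_intensity: float = 100.0
    noise_sd: float = 30.0            # amplitude of the correlated field
    white_noise_sd: float = 15.0      # amplitude of the voxel-wise noise
    lump_sd: float = 20.0             # amplitude of the long-range field
    correlation_length_mm: float = 3.0
    lump_length_mm: float = 6.0
    contrast_amplitude: float = 40.0  # tumor-background offset
    factor_gain: float = 0.35         # log-scale gain of latent factors

    def __post_init__(self) -> None:
        for name in ("correlation_length_mm", "lump_length_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("noise_sd", "white_noise_sd", "lump_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort.

    ``effect_sizes`` are log-hazard coefficients on the latent texture
    factors; ``recurrence_slopes``/``recurrence_intercept`` parameterize the
    logistic recurrence model on the same factors.
    """

    n_patients: int = 74
    image_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    texture_params: TextureParams = field(default_factory=TextureParams)
    effect_sizes: tuple[float, ...] = (1.0, 1.0, 1.0)
    censor_rate: float = 0.3
    recurrence_intercept: float = -0.3
    recurrence_slopes: tuple[float, ...] = (1.0, 1.0, 1.0)
    baseline_median_days: float = 330.0
    clinical_outcome_association: float = 0.0  # optional weak leak into N stage
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 6:
            raise ValueError("n_patients must be >= 6")
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor_rate must lie in [0, 1)")
        if any(s < 16 for s in self.image_shape):
            raise ValueError("image_shape must be >= 16 voxels per axis")
        if len(self.effect_sizes) != len(self.recurrence_slopes):
            raise ValueError("effect_sizes and recurrence_slopes must have equal length")


@dataclass
class PhantomPatient:
    patient_id: str
    volume: ImageVolume
    mask: ImageVolume
    clinical: dict[str, int]
    survival_time: float
    event: int
    recurrence: int
    latent_factors: np.ndarray


@dataclass
class PhantomCohort:
    spec: CohortSpec
    patients: list[PhantomPatient]
    achieved_censor_rate: float

    def clinical_table(self) -> pd.DataFrame:
        rows = [{"patient_id": p.patient_id, **p.clinical} for p in self.patients]
        return pd.DataFrame(rows).set_index("patient_id")

    def survival_table(self) -> pd.DataFrame:
        rows = [
            {"patient_id": p.patient_id, "time": p.survival_time, "event": p.event}
            for p in self.patients
        ]
        return pd.DataFrame(rows).set_index("patient_id")

    def recurrence_table(self) -> pd.DataFrame:
        rows = [{"patient_id": p.patient_id, "recurrence": p.recurrence} for p in self.patients]
        return pd.DataFrame(rows).set_index("patient_id")

    def latent_table(self) -> pd.DataFrame:
        rows = [
            {"patient_id": p.patient_id,
             **{f"factor_{i}": v for i, v in enumerate(p.latent_factors)}}
            for p in self.patients
        ]
        return pd.DataFrame(rows).set_index("patient_id")

    def save(self, outdir: str | Path) -> None:
        """Write NRRD volume/mask pairs, CSV tables and a JSON manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for p in self.patients:
            write_volume(p.volume, outdir / f"{p.patient_id}_image.nrrd")
            write_volume(
                ImageVolume(p.mask.data.astype(np.uint8), p.mask.spacing_mm, p.mask.origin),
                outdir / f"{p.patient_id}_mask.nrrd",
            )
        self.clinical_table().to_csv(outdir / "clinical.csv")
        self.survival_table().to_csv(outdir / "survival.csv")
        self.recurrence_table().to_csv(outdir / "recurrence.csv")
        self.latent_table().to_csv(outdir / "latent_factors.csv")
        manifest = {
            "n_patients": self.spec.n_patients,
            "image_shape": list(self.spec.image_shape),
            "voxel_size_mm": list(self.spec.voxel_size_mm),
            "effect_sizes": list(self.spec.effect_sizes),
            "censor_rate": self.spec.censor_rate,
            "achieved_censor_rate": self.achieved_censor_rate,
            "seed": self.spec.seed,
            "patient_ids": [p.patient_id for p in self.patients],
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_cohort(outdir: str | Path) -> PhantomCohort:
    """Load a cohort previously written by :meth:`PhantomCohort.save`."""
    from .imaging import read_volume

    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    clinical = pd.read_csv(outdir / "clinical.csv", index_col="patient_id")
    survival = pd.read_csv(outdir / "survival.csv", index_col="patient_id")
    recurrence = pd.read_csv(outdir / "recurrence.csv", index_col="patient_id")
    latent = pd.read_csv(outdir / "latent_factors.csv", index_col="patient_id")
    spec = CohortSpec(
        n_patients=manifest["n_patients"],
        image_shape=tuple(manifest["image_shape"]),
        voxel_size_mm=tuple(manifest["voxel_size_mm"]),
        effect_sizes=tuple(manifest["effect_sizes"]),
        censor_rate=manifest["censor_rate"],
        seed=manifest["seed"],
    )
    patients = []
    for pid in manifest["patient_ids"]:
        vol = read_volume(outdir / f"{pid}_image.nrrd")
        msk = read_volume(outdir / f"{pid}_mask.nrrd")
        msk.data = msk.data > 0
        patients.append(
            PhantomPatient(
                patient_id=pid,
                volume=vol,
                mask=msk,
                clinical={c: int(clinical.loc[pid, c]) for c in clinical.columns},
                survival_time=float(survival.loc[pid, "time"]),
                event=int(survival.loc[pid, "event"]),
                recurrence=int(recurrence.loc[pid, "recurrence"]),
                latent_factors=latent.loc[pid].to_numpy(dtype=float),
            )
        )
    return PhantomCohort(
        spec=spec, patients=patients,
        achieved_censor_rate=float(manifest["achieved_censor_rate"]),
    )


def _unit_field(shape, sigma_vox, rng) -> np.ndarray:
    """Gaussian-smoothed white noise rescaled to unit variance."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma_vox, mode="wrap")
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_phantom(
    latent_factors: np.ndarray,
    image_shape: tuple[int, int, int] = (24, 24, 24),
    texture_params: TextureParams | None = None,
    seed: int | np.random.Generator = 0,
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0),
) -> tuple[ImageVolume, ImageVolume]:
    """Generate one phantom volume and its ellipsoidal tumor mask.

    The tumor interior is ``base + contrast`` plus three stochastic
    components whose correlation length and amplitudes are monotone
    (exponential) functions of the latent factors, so discrete texture
    statistics shift systematically across factor values.  Masks with fewer
    than 27 voxels are rejected and the axes resampled.
    """
    if any(s < 16 for s in image_shape):
        raise ValueError("image_shape must be >= 16 voxels per axis")
    tp = texture_params or TextureParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = np.zeros(3)
    lf = np.asarray(latent_factors, dtype=float).ravel()
    z[: min(3, lf.size)] = lf[:3]
    spacing = np.asarray(voxel_size_mm, dtype=float)

    # ellipsoid mask with randomized semi-axes (mm), resampled if degenerate
    center = (np.asarray(image_shape) - 1) / 2.0
    grid = np.stack(
        np.meshgrid(*[np.arange(s) for s in image_shape], indexing="ij"), axis=-1
    ) - center
    grid_mm = grid * spacing
    for _ in range(100):
        axes_mm = rng.uniform(7.0, 12.0, size=3)
        mask = np.sum((grid_mm / axes_mm) ** 2, axis=-1) <= 1.0
        if mask.sum() >= 27:
            break
    else:
        raise RuntimeError("could not draw a non-degenerate mask")

    corr_mm = tp.correlation_length_mm * np.exp(tp.factor_gain * z[0])
    sigma_vox = corr_mm / spacing
    amp_white = tp.white_noise_sd * np.exp(tp.factor_gain * z[1])
    amp_corr = tp.noise_sd * np.exp(tp.factor_gain * z[2])

    data = np.full(image_shape, tp.base_intensity, dtype=np.float64)
    data += tp.contrast_amplitude * mask
    if amp_corr > 0:
        data += amp_corr * _unit_field(image_shape, sigma_vox, rng)
    if amp_white > 0:
        data += amp_white * rng.standard_normal(image_shape)
    if tp.lump_sd > 0:
        data += tp.lump_sd * _unit_field(image_shape, tp.lump_length_mm / spacing, rng)

    vol = ImageVolume(data, tuple(spacing), (0.0, 0.0, 0.0))
    msk = ImageVolume(mask, tuple(spacing), (0.0, 0.0, 0.0))
    return vol, msk


def _solve_censor_horizon(times: np.ndarray, target: float) -> float:
    """Horizon c of U(0, c) censoring achieving the target censored fraction.

    P(censored | T = t) = P(C < t) = min(t / c, 1); the expectation over the
    drawn times is monotone decreasing in c.
    """
    def censored_frac(c):
        return float(np.mean(np.minimum(times / c, 1.0)))

    lo, hi = times.min() * 1e-6, times.max() * 1e6
    if censored_frac(hi) > target:  # unattainable even with a huge horizon
        return hi
    return float(optimize.brentq(lambda c: censored_frac(c) - target, lo, hi))


def generate_cohort(spec: CohortSpec) -> PhantomCohort:
    """Generate a full phantom cohort with images, covariates and outcomes."""
    rng = np.random.default_rng(spec.seed)
    k = len(spec.effect_sizes)
    z = rng.standard_normal((spec.n_patients, k))
    beta = np.asarray(spec.effect_sizes, dtype=float)

    # survival: exponential PH model, h0 from the baseline median
    h0 = np.log(2.0) / spec.baseline_median_days
    hazards = h0 * np.exp(z @ beta)
    true_times = rng.exponential(1.0 / hazards)

    if spec.censor_rate > 0:
        horizon = _solve_censor_horizon(true_times, spec.censor_rate)
        cens = rng.uniform(0.0, horizon, size=spec.n_patients)
        times = np.minimum(true_times, cens)
        events = (true_times <= cens).astype(int)
    else:
        times, events = true_times, np.ones(spec.n_patients, dtype=int)
    times = np.maximum(times, 1e-3)
    achieved = 1.0 - events.mean()
    if spec.censor_rate > 0 and abs(achieved - spec.censor_rate) > 0.15:
        warnings.warn(
            f"target censor rate {spec.censor_rate:.2f} not achieved "
            f"(got {achieved:.2f})", stacklevel=2,
        )

    # recurrence: logistic on the latent factors
    slopes = np.asarray(spec.recurrence_slopes, dtype=float)
    p_rec = 1.0 / (1.0 + np.exp(-(spec.recurrence_intercept + z @ slopes)))
    recurrence = (rng.uniform(size=spec.n_patients) < p_rec).astype(int)

    # clinical covariates: independent of z unless a weak association is asked
    clinical_rows = []
    for i in range(spec.n_patients):
        row = {}
        for col, marg in CLINICAL_MARGINALS.items():
            codes = np.array(list(marg.keys()))
            probs = np.array(list(marg.values()))
            probs = probs / probs.sum()
            if col == "n_stage" and spec.clinical_outcome_association != 0:
                # tilt N stage with the first latent factor
                logit = np.log(probs[1] / probs[0]) + spec.clinical_outcome_association * z[i, 0]
                p1 = 1.0 / (1.0 + np.exp(-logit))
                probs = np.array([1 - p1, p1])
            row[col] = int(rng.choice(codes, p=probs))
        clinical_rows.append(row)

    width = len(str(spec.n_patients))
    patients = []
    for i in range(spec.n_patients):
        vol, msk = generate_phantom(
            z[i], spec.image_shape, spec.texture_params, rng, spec.voxel_size_mm
        )
        patients.append(
            PhantomPatient(
                patient_id=f"P{i:0{width}d}",
                volume=vol,
                mask=msk,
                clinical=clinical_rows[i],
                survival_time=float(times[i]),
                event=int(events[i]),
                recurrence=int(recurrence[i]),
                latent_factors=z[i].copy(),
            )
        )
    return PhantomCohort(spec=spec, patients=patients, achieved_censor_rate=float(achieved))
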