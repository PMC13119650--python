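"""Synthetic multi-modal tumor phantoms and survival cohorts.

The phantom generator emulates the structure of a BraTS-style case at desk
scale: a 2D slice with four MRI modalities (T1, T1Gd, T2, T2-FLAIR) and a
nested integer label map {0 background, 1 NCR, 2 ED, 3 ET}, where the
composite views satisfy ET <= TC <= WT (TC = NCR u ET, WT = NCR u ED u ET).
Tumor geometry is concentric disks with an optional elliptical warp; the
modality means reproduce the radiological contrast the channel attention is
expected to discover (T1Gd bright on enhancing tumor, FLAIR bright on edema).

The survival generator draws event times from an exponential proportional-
hazards model with independent exponential censoring, so every moment of the
cohort is analytically checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

MODALITIES = ("t1", "t1ce", "t2", "flair")
LABEL_NAMES = {0: "background", 1: "NCR", 2: "ED", 3: "ET"}

# mean intensity per (modality, tissue class) on the 8-bit scale;
# rows: T1, T1Gd, T2, FLAIR; cols: background, NCR, ED, ET
DEFAULT_MODALITY_MEANS = np.array([
    [60.0, 50.0, 75.0, 90.0],    # T1
    [60.0, 40.0, 80.0, 200.0],   # T1Gd: ET enhances, NCR dark
    [60.0, 95.0, 130.0, 110.0],  # T2
    [60.0, 100.0, 140.0, 120.0],  # FLAIR: ED bright
])


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, contrast and noise of one synthetic slice."""

    image_size: int = 64
    tumor_center: tuple = (32, 32)
    radii: tuple = (5, 8, 12)          # (r_ET, r_NCR, r_ED), strictly increasing
    modality_means: np.ndarray = field(
        default_factory=lambda: DEFAULT_MODALITY_MEANS.copy())
    noise_sd: float = 15.0
    ellipticity: float = 1.0           # row-axis stretch of all disks
    seed: int = 0

    def validate(self) -> None:
        r_et, r_ncr, r_ed = self.radii
        if not (r_et < r_ncr < r_ed):
            raise ValueError(f"radii must be strictly increasing, got {self.radii}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        cy, cx = self.tumor_center
        r_out = r_ed * max(self.ellipticity, 1.0)
        if (cy - r_out < 0 or cx - r_ed < 0 or cy + r_out >= self.image_size
                or cx + r_ed >= self.image_size):
            raise ValueError("tumor extends outside image bounds")
        mm = np.asarray(self.modality_means)
        if mm.shape != (4, 4):
            raise ValueError("modality_means must be 4 modalities x 4 classes")


@dataclass(frozen=True)
class SurvivalCohortSpec:
    """Exponential proportional-hazards cohort with exponential censoring."""

    n_subjects: int = 200
    beta_true: tuple = (0.693,)
    baseline_rate: float = 1.0
    censor_rate: float = 0.34   # ~20% censoring for a balanced binary covariate
    covariate_dist: str = "binary"  # "binary" (p=1/2) or "normal"
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be > 0")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")
        if not np.all(np.isfinite(self.beta_true)):
            raise ValueError("beta_true must be finite")
        if self.covariate_dist not in ("binary", "normal"):
            raise ValueError(f"unknown covariate_dist {self.covariate_dist!r}")


@dataclass
class SurvivalRecord:
    """One subject: observed follow-up time, event flag and covariates."""

    time: float
    event: int
    covariates: np.ndarray


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render one multi-modal slice and its nested label mask.

    Returns
    -------
    image : (H, W, 4) float array, modality order T1, T1Gd, T2, FLAIR.
    labels : (H, W) int array with values in {0, 1, 2, 3}.
    """
    spec.validate()
    n = spec.image_size
    cy, cx = spec.tumor_center
    yy, xx = np.mgrid[0:n, 0:n]
    # elliptical radius: stretch the row axis by `ellipticity`
    rho = np.sqrt(((yy - cy) / spec.ellipticity) ** 2 + (xx - cx) ** 2)
    r_et, r_ncr, r_ed = spec.radii

    labels = np.zeros((n, n), dtype=np.int64)
    labels[rho <= r_ed] = 2    # ED annulus (outermost tumor region)
    labels[rho <= r_ncr] = 1   # NCR annulus
    labels[rho <= r_et] = 3    # ET innermost disk

    means = np.asarray(spec.modality_means, dtype=np.float64)
    image = means[:, labels].transpose(1, 2, 0)  # (H, W, 4)
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    return np.clip(image, 0.0, 255.0), labels


def composite_views(labels: np.ndarray) -> dict:
    """WT / TC / ET binary views of a 4-class BraTS-style label map."""
    return {
        "WT": labels > 0,
        "TC": np.isin(labels, (1, 3)),
        "ET": labels == 3,
    }


def random_phantom_spec(rng: np.random.Generator, image_size: int = 64,
                        noise_sd: float = 15.0) -> PhantomSpec:
    """Draw a randomized but always-valid phantom geometry."""
    r_et = int(rng.integers(3, 8))
    r_ncr = r_et + int(rng.integers(2, 5))
    r_ed = r_ncr + int(rng.integers(3, 7))
    ell = float(rng.uniform(0.85, 1.15))
    margin = int(np.ceil(r_ed * max(ell, 1.0))) + 2
    cy = int(rng.integers(margin, image_size - margin))
    cx = int(rng.integers(margin, image_size - margin))
    return PhantomSpec(image_size=image_size, tumor_center=(cy, cx),
                       radii=(r_et, r_ncr, r_ed), noise_sd=noise_sd,
                       ellipticity=ell, seed=int(rng.integers(0, 2 ** 31 - 1)))


def make_phantom_dataset(n: int, image_size: int = 64, seed: int = 0,
                         noise_sd: float = 15.0) -> tuple[np.ndarray, np.ndarray]:
    """Generate a stack of phantoms: X (n,H,W,4), y (n,H,W)."""
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for _ in range(n):
        img, lab = generate_phantom(random_phantom_spec(rng, image_size, noise_sd))
        xs.append(img)
        ys.append(lab)
    return np.stack(xs), np.stack(ys)


def generate_survival_cohort(spec: SurvivalCohortSpec) -> list[SurvivalRecord]:
    """Simulate an exponential PH cohort with independent censoring."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    beta = np.asarray(spec.beta_true, dtype=np.float64)
    p = beta.size
    if spec.covariate_dist == "binary":
        x = rng.integers(0, 2, size=(spec.n_subjects, p)).astype(np.float64)
    else:
        x = rng.normal(size=(spec.n_subjects, p))
    rate = spec.baseline_rate * np.exp(x @ beta)
    t_event = rng.exponential(1.0 / rate)
    if spec.censor_rate > 0:
        t_cens = rng.exponential(1.0 / spec.censor_rate, size=spec.n_subjects)
    else:
        t_cens = np.full(spec.n_subjects, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return [SurvivalRecord(float(t), int(e), x[i].copy())
            for i, (t, e) in enumerate(zip(time, event))]


def censor_rate_for_fraction(target: float, beta: float,
                             baseline_rate: float = 1.0) -> float:
    """Censor rate giving a target censoring fraction for a balanced binary covariate.

    For a balanced binary covariate the censored fraction at censor rate r is
    (r/(r+h0) + r/(r+h0*exp(beta))) / 2; solved by bisection.
    """
    from scipy.optimize import brentq
    h0, h1 = baseline_rate, baseline_rate * np.exp(beta)

    def f(r):
        return 0.5 * (r / (r + h0) + r / (r + h1)) - target

    return float(brentq(f, 1e-9, 1e6))


def save_case(case_dir, image: np.ndarray, labels: np.ndarray | None = None,
              spacing: float = 1.0) -> None:
    """Write one phantom as BraTS-style NIfTI files plus a PNG preview."""
    import nibabel as nib

    case_dir = Path(case_dir)
    case_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag([spacing, spacing, 1.0, 1.0])
    name = case_dir.name
    for i, mod in enumerate(MODALITIES):
        vol = image[:, :, i][:, :, None].astype(np.float32)
        nib.save(nib.Nifti1Image(vol, affine), case_dir / f"{name}_{mod}.nii.gz")
    if labels is not None:
        vol = labels[:, :, None].astype(np.int16)
        nib.save(nib.Nifti1Image(vol, affine), case_dir / f"{name}_seg.nii.gz")
    _save_preview(case_dir / f"{name}_preview.png", image, labels)


def _save_preview(path, image, labels=None):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ncols = 4 + (labels is not None)
    fig, axes = plt.subplots(1, ncols, figsize=(3 * ncols, 3))
    for i, mod in enumerate(MODALITIES):
        axes[i].imshow(image[:, :, i], cmap="gray", vmin=0, vmax=255)
        axes[i].set_title(mod.upper())
        axes[i].axis("off")
    if labels is not None:
        axes[-1].imshow(labels, cmap="viridis", vmin=0, vmax=3)
        axes[-1].set_title("labels")
        axes[-1].axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=80)
    plt.close(fig)
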