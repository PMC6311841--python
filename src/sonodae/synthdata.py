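"""Seeded ultrasound-like lesion ROI phantoms.

Each phantom realises the additive inhomogeneity model directly: a
hypoechoic (dark) lesion on a brighter background, multiplicative
log-normal speckle, and an injected low-order polynomial bias field
with zero constant term — so the generator doubles as a ground-truth
oracle for the correction stage.

Class structure follows the qualitative radiology cues the classifier
is meant to learn: benign lesions have a smooth elliptical margin;
malignant lesions have a lobulated margin r(theta) =
r0(theta) * (1 + A sin(K theta + phi)) and optionally a partially
erased ("missing") boundary arc where the lesion/background contrast is
locally blended away.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidSpecError, InvalidSplitError
from .image import save_gray
from .inhomogeneity import PolynomialSurface, normalized_grid

BENIGN, MALIGNANT = "benign", "malignant"


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic lesion ROI.

    Defaults give a 28x28 benign phantom. ``margin_amplitude`` (A) and
    ``margin_lobes`` (K) control margin irregularity; malignant phantoms
    default to A=0.25, K=7. ``boundary_dropout`` is the fraction of the
    margin arc erased. ``bias`` is the injected bias surface (zero
    constant term). Intensities must satisfy mu_lesion < mu_background
    (lesions are hypoechoic).
    """

    size: int = 28
    class_label: str = BENIGN
    lesion_center: tuple[float, float] = (13.5, 13.5)  # (row, col), pixel units
    lesion_axes: tuple[float, float] = (6.0, 4.0)      # semi-axes (row, col)
    margin_amplitude: float = 0.0
    margin_lobes: int = 0
    mu_lesion: float = 0.30
    mu_background: float = 0.62
    speckle_sigma: float = 0.05
    bias: PolynomialSurface = field(default_factory=PolynomialSurface.zero)
    boundary_dropout: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.class_label not in (BENIGN, MALIGNANT):
            raise InvalidSpecError(f"unknown class {self.class_label!r}")
        if not (0.0 <= self.mu_lesion < self.mu_background <= 1.0):
            raise InvalidSpecError("need 0 <= mu_lesion < mu_background <= 1")
        if self.margin_amplitude < 0 or self.margin_lobes < 0:
            raise InvalidSpecError("margin irregularity parameters must be >= 0")
        if not (0.0 <= self.boundary_dropout < 1.0):
            raise InvalidSpecError("boundary_dropout must be in [0, 1)")
        cy, cx = self.lesion_center
        ry, rx = self.lesion_axes
        reach = (1.0 + self.margin_amplitude) * max(ry, rx)
        if (
            cy - reach < 0 or cy + reach > self.size - 1
            or cx - reach < 0 or cx + reach > self.size - 1
        ):
            raise InvalidSpecError("lesion (including margin lobes) exceeds image bounds")


def malignant_spec(**kwargs) -> PhantomSpec:
    """PhantomSpec with the malignant margin defaults (A=0.25, K=7)."""
    kwargs.setdefault("margin_amplitude", 0.25)
    kwargs.setdefault("margin_lobes", 7)
    return PhantomSpec(class_label=MALIGNANT, **kwargs)


def _margin_radius(spec: PhantomSpec, theta: np.ndarray, phi: float) -> np.ndarray:
    ry, rx = spec.lesion_axes
    # ellipse polar radius about the centre, theta measured from +col axis
    r0 = (ry * rx) / np.sqrt((rx * np.sin(theta)) ** 2 + (ry * np.cos(theta)) ** 2)
    return r0 * (1.0 + spec.margin_amplitude * np.sin(spec.margin_lobes * theta + phi))


def lesion_mask(spec: PhantomSpec) -> np.ndarray:
    """Boolean lesion mask: pixel inside iff its polar radius about the
    centre is below the (possibly lobulated) margin radius r(theta)."""
    rng = np.random.default_rng(spec.seed)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    cy, cx = spec.lesion_center
    rows, cols = np.mgrid[0 : spec.size, 0 : spec.size]
    dy, dx = rows - cy, cols - cx
    theta = np.arctan2(dy, dx)
    rad = np.hypot(dy, dx)
    return rad < _margin_radius(spec, theta, phi)


def render_phantom(spec: PhantomSpec) -> tuple[np.ndarray, int, np.ndarray, np.ndarray]:
    """Render one phantom.

    Returns (image, label01, true_bias_field, mask) where label01 is 1
    for malignant. The pipeline: two-level clean image -> boundary
    dropout blending -> mean-one multiplicative log-normal speckle ->
    additive bias field -> clip to [0, 1]. The rng is seeded from the
    spec alone and consumed in a fixed order, so the same seed with and
    without bias differs exactly by the bias field (pre-clip).
    """
    rng = np.random.default_rng(spec.seed)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    cy, cx = spec.lesion_center
    rows, cols = np.mgrid[0 : spec.size, 0 : spec.size]
    dy, dx = rows - cy, cols - cx
    theta = np.arctan2(dy, dx)
    rad = np.hypot(dy, dx)
    r_margin = _margin_radius(spec, theta, phi)
    mask = rad < r_margin

    clean = np.where(mask, spec.mu_lesion, spec.mu_background)

    # erase a fraction of the margin arc: blend contrast toward the mean
    # in a band around the boundary, emulating a missing boundary part
    dropout_start = rng.uniform(0.0, 2.0 * np.pi)
    if spec.boundary_dropout > 0.0:
        half = spec.boundary_dropout * np.pi  # arc half-width
        ang = np.angle(np.exp(1j * (theta - dropout_start)))
        in_arc = np.abs(ang) < half
        band = np.abs(rad - r_margin) < 1.5
        blend = in_arc & band
        clean = np.where(blend, 0.5 * (spec.mu_lesion + spec.mu_background), clean)

    noise = rng.normal(0.0, spec.speckle_sigma, size=clean.shape)
    if spec.speckle_sigma > 0:
        # mean-one log-normal multiplicative speckle
        speckled = clean * np.exp(noise - 0.5 * spec.speckle_sigma**2)
    else:
        speckled = clean

    bias_field = spec.bias.evaluate_grid(spec.size, spec.size)
    image = np.clip(speckled + bias_field, 0.0, 1.0)
    return image, int(spec.class_label == MALIGNANT), bias_field, mask


def random_bias_surface(
    rng: np.random.Generator, size: int, peak: float, degree: int = 2
) -> PolynomialSurface:
    """Random bias surface of the given degree scaled so its maximum
    absolute value over the size x size grid equals ``peak``."""
    from .inhomogeneity import monomial_exponents

    n = len(monomial_exponents(degree))
    coeffs = rng.normal(size=n)
    surf = PolynomialSurface(degree, coeffs)
    m = surf.max_abs(size, size)
    if peak == 0.0 or m == 0.0:
        return PolynomialSurface.zero(degree)
    return PolynomialSurface(degree, coeffs * (peak / m))


@dataclass
class PhantomSample:
    image: np.ndarray
    label: int          # 1 = malignant
    bias_field: np.ndarray
    mask: np.ndarray
    spec: PhantomSpec
    name: str


@dataclass
class DatasetSplit:
    train: list[PhantomSample]
    test: list[PhantomSample]

    def arrays(self, subset: str) -> tuple[np.ndarray, np.ndarray]:
        samples = getattr(self, subset)
        X = np.stack([s.image.ravel() for s in samples])
        y = np.array([s.label for s in samples])
        return X, y


def _jittered_spec(rng: np.random.Generator, label: str, size: int, bias_strength: float,
                   speckle_sigma: float) -> PhantomSpec:
    centre = (size - 1) / 2.0
    cy = centre + rng.uniform(-2.0, 2.0)
    cx = centre + rng.uniform(-2.0, 2.0)
    ry = rng.uniform(4.5, 6.5)
    rx = rng.uniform(3.0, 5.0)
    mu_l = rng.uniform(0.28, 0.32)
    mu_b = rng.uniform(0.60, 0.64)
    if label == MALIGNANT:
        A = rng.uniform(0.20, 0.35)
        K = int(rng.integers(5, 10))
        dropout = rng.uniform(0.05, 0.25)
    else:
        A, K, dropout = 0.0, 0, 0.0
    bias = random_bias_surface(rng, size, peak=bias_strength, degree=2)
    # shrink axes if lobes would reach the border
    reach = (1.0 + A) * max(ry, rx)
    limit = min(cy, cx, size - 1 - cy, size - 1 - cx)
    if reach >= limit:
        scale = 0.95 * limit / reach
        ry, rx = ry * scale, rx * scale
    return PhantomSpec(
        size=size,
        class_label=label,
        lesion_center=(cy, cx),
        lesion_axes=(ry, rx),
        margin_amplitude=A,
        margin_lobes=K,
        mu_lesion=mu_l,
        mu_background=mu_b,
        speckle_sigma=speckle_sigma,
        bias=bias,
        boundary_dropout=dropout,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def make_dataset(
    n_benign: int = 74,
    n_malignant: int = 96,
    test_fraction: float = 27.0 / 170.0,
    seed: int = 0,
    bias_strength: float = 0.15,
    size: int = 28,
    speckle_sigma: float = 0.05,
) -> DatasetSplit:
    """Generate a stratified train/test phantom dataset.

    Per-sample geometry, intensities and bias coefficients are jittered
    from a single seeded stream; the split is stratified by class. The
    defaults mirror a 170-image study with a 143/27 random split.
    """
    if n_benign + n_malignant < 4:
        raise InvalidSplitError("need at least 4 samples")
    if not (0.0 < test_fraction < 1.0):
        raise InvalidSplitError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)

    samples: list[PhantomSample] = []
    for i in range(n_benign + n_malignant):
        label = BENIGN if i < n_benign else MALIGNANT
        spec = _jittered_spec(rng, label, size, bias_strength, speckle_sigma)
        image, y, bias_field, mask = render_phantom(spec)
        samples.append(
            PhantomSample(image, y, bias_field, mask, spec, name=f"{label}_{i:04d}.png")
        )

    n_total = len(samples)
    n_test = int(round(test_fraction * n_total))
    n_test = max(2, min(n_test, n_total - 2))
    test_idx: list[int] = []
    for label01 in (0, 1):
        idx = np.array([i for i, s in enumerate(samples) if s.label == label01])
        k = int(round(n_test * idx.size / n_total))
        k = max(1, min(k, idx.size - 2))
        test_idx.extend(rng.choice(idx, size=k, replace=False).tolist())
    test_set = set(test_idx)
    train = [s for i, s in enumerate(samples) if i not in test_set]
    test = [s for i, s in enumerate(samples) if i in test_set]
    for subset, minimum in ((train, 2), (test, 1)):
        for label01 in (0, 1):
            if sum(s.label == label01 for s in subset) < minimum:
                raise InvalidSplitError("a class has too few samples after the split")
    return DatasetSplit(train=train, test=test)


def write_dataset(split: DatasetSplit, out_dir: str | Path, write_truth: bool = True) -> None:
    """Write PNGs, labels.csv and (optionally) truth/ bias fields as
    32-bit TIFF under ``out_dir``."""
    import tifffile  # local import: only needed when truth output is requested

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    truth_dir = out / "truth"
    if write_truth:
        truth_dir.mkdir(exist_ok=True)
    for subset in ("train", "test"):
        for s in getattr(split, subset):
            save_gray(out / s.name, s.image)
            rows.append({"filename": s.name, "label": BENIGN if s.label == 0 else MALIGNANT,
                         "subset": subset})
            if write_truth:
                tifffile.imwrite(
                    truth_dir / (Path(s.name).stem + "_bias.tiff"),
                    s.bias_field.astype(np.float32),
                )
    pd.DataFrame(rows).to_csv(out / "labels.csv", index=False)
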