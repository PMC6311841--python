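"""Intensity-inhomogeneity (bias-field) correction for ultrasound ROIs.

The observed image is modelled additively as

    O_i = mu_psi(i) + P(x_i, y_i) + n_i

where ``mu_psi`` is the mean intensity of the homogeneous region the
pixel belongs to (foreground F = hypoechoic lesion, background B),
``P`` is a low-order bivariate polynomial bias surface with no constant
term (the constant is carried entirely by the class means, which makes
the model identifiable), and ``n_i`` is the unmodelled residual.

Correction alternates two steps:

1. a fuzzy cell-based bipartition of the current corrected estimate into
   F/B — 2-cluster fuzzy c-means on per-cell mean intensities, pixels
   inheriting the membership of their cell (the cell pooling acts as
   spatial regularisation);
2. a joint linear least-squares fit of (mu_F, mu_B, polynomial
   coefficients) on the ORIGINAL image, minimising the mean squared
   residual eps^2 = (1/Npix) sum_i (O_i - mu_psi(i) - P_i)^2.

The corrected image is clip(original - P_hat, 0, 1). Coordinates are
normalised per-axis to [-1, 1] via (2*idx - (len-1))/(len-1), 0-based,
so fitted coefficients are reproducible across image sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateBipartitionError, InvalidArgumentError
from .image import as_gray_image, require_min_size

logger = logging.getLogger(__name__)

MAX_DEGREE = 4


def monomial_exponents(degree: int) -> list[tuple[int, int]]:
    """Exponent pairs (j, k) for x^j y^k with 1 <= j+k <= degree.

    Graded lexicographic order: total degree ascending, then x-exponent
    descending — degree 2 gives [x, y, x^2, xy, y^2].
    """
    if degree < 0:
        raise InvalidArgumentError("degree must be >= 0")
    out: list[tuple[int, int]] = []
    for total in range(1, degree + 1):
        for j in range(total, -1, -1):
            out.append((j, total - j))
    return out


def build_design_matrix(coords: np.ndarray, degree: int) -> np.ndarray:
    """Monomial design matrix; one row per (x, y) point, one column per
    monomial x^j y^k with 1 <= j+k <= degree. degree 0 gives 0 columns."""
    coords = np.atleast_2d(np.asarray(coords, dtype=np.float64))
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise InvalidArgumentError("coords must be an (n, 2) array of (x, y)")
    exps = monomial_exponents(degree)
    x, y = coords[:, 0], coords[:, 1]
    cols = [x**j * y**k for j, k in exps]
    if not cols:
        return np.empty((coords.shape[0], 0))
    return np.column_stack(cols)


def normalized_grid(height: int, width: int) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-centre coordinate grids mapped to [-1, 1] per axis."""
    ys = (2.0 * np.arange(height) - (height - 1)) / (height - 1)
    xs = (2.0 * np.arange(width) - (width - 1)) / (width - 1)
    X, Y = np.meshgrid(xs, ys)
    return X, Y


@dataclass(frozen=True)
class PolynomialSurface:
    """Bias surface P(x, y) = sum c_jk x^j y^k over normalized coords.

    The j+k=0 monomial is excluded, so a degree-0 surface is identically
    zero and the coefficient count is (N+1)(N+2)/2 - 1.
    """

    degree: int
    coefficients: np.ndarray

    def __post_init__(self):
        coeffs = np.asarray(self.coefficients, dtype=np.float64)
        expected = len(monomial_exponents(self.degree))
        if coeffs.shape != (expected,):
            raise InvalidArgumentError(
                f"degree {self.degree} needs {expected} coefficients, got {coeffs.shape}"
            )
        object.__setattr__(self, "coefficients", coeffs)

    @classmethod
    def zero(cls, degree: int = 0) -> "PolynomialSurface":
        return cls(degree, np.zeros(len(monomial_exponents(degree))))

    def evaluate(self, coords: np.ndarray) -> np.ndarray:
        A = build_design_matrix(coords, self.degree)
        return A @ self.coefficients

    def evaluate_grid(self, height: int, width: int) -> np.ndarray:
        X, Y = normalized_grid(height, width)
        pts = np.column_stack([X.ravel(), Y.ravel()])
        return self.evaluate(pts).reshape(height, width)

    def max_abs(self, height: int, width: int) -> float:
        return float(np.abs(self.evaluate_grid(height, width)).max())


@dataclass(frozen=True)
class BipartitionMap:
    """Fuzzy foreground/background split of an image.

    ``membership`` holds the foreground (lesion, lower-mean) membership
    per pixel; hard label is F where membership >= 0.5.
    """

    membership: np.ndarray
    mu_F: float
    mu_B: float

    @property
    def hard_foreground(self) -> np.ndarray:
        return self.membership >= 0.5

    def validate_nonempty(self) -> None:
        hard = self.hard_foreground
        if not hard.any() or hard.all():
            raise DegenerateBipartitionError("one region is empty after hard assignment")


@dataclass
class CorrectionResult:
    corrected: np.ndarray
    surface: PolynomialSurface
    bipartition: BipartitionMap | None
    epsilon2: float
    iterations: int
    converged: bool
    epsilon2_trace: list[float] = field(default_factory=list)


def _fcm_two_cluster(
    values: np.ndarray,
    init_centers: np.ndarray,
    fuzzifier: float,
    max_iter: int,
    tol: float,
):
    """2-cluster fuzzy c-means on a 1-D sample from given initial centers.

    Returns (membership matrix (n, 2), centers). Fully deterministic.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    centers = np.asarray(init_centers, dtype=np.float64).copy()
    if centers[1] - centers[0] <= 0:
        raise DegenerateBipartitionError("initial cluster centres coincide")
    expo = 2.0 / (fuzzifier - 1.0)
    u = np.full((v.size, 2), 0.5)
    for _ in range(max_iter):
        d = np.abs(v[:, None] - centers[None, :])
        d = np.maximum(d, 1e-12)
        inv = d ** (-expo)
        u_new = inv / inv.sum(axis=1, keepdims=True)
        um = u_new**fuzzifier
        denom = um.sum(axis=0)
        if np.any(denom == 0):
            raise DegenerateBipartitionError("a fuzzy cluster lost all weight")
        centers = (um * v[:, None]).sum(axis=0) / denom
        delta = np.abs(u_new - u).max()
        u = u_new
        if delta < tol:
            break
    return u, centers


def fuzzy_bipartition(
    image: np.ndarray,
    cell_size: int = 4,
    fuzzifier: float = 2.0,
    max_iter: int = 100,
    tol: float = 1e-5,
) -> BipartitionMap:
    """Cell-based fuzzy two-class split of an image.

    Two-stage scheme. First, 2-cluster FCM runs on the per-cell mean
    intensities (cell_size x cell_size tiles, edge cells may be
    smaller); pooling over cells regularises the centre estimates
    against speckle and local structure. Second, a pixel-level FCM pass
    seeded with those cell-level centres assigns each pixel its own
    membership, sharpening the region boundary below cell granularity.
    The cluster with the lower centre is foreground (lesions are
    hypoechoic); mu_F/mu_B are membership-weighted pixel means.

    Raises DegenerateBipartitionError for (near-)constant images or when
    a hard region ends up empty.
    """
    img = as_gray_image(image)
    if cell_size < 2:
        raise InvalidArgumentError("cell_size must be >= 2")
    if fuzzifier <= 1.0:
        raise InvalidArgumentError("fuzzifier must be > 1")
    if np.ptp(img) == 0.0:
        raise DegenerateBipartitionError("constant image has no bipartition")

    h, w = img.shape
    n_cy = -(-h // cell_size)
    n_cx = -(-w // cell_size)
    cell_means = np.empty(n_cy * n_cx)
    idx = 0
    for cy in range(n_cy):
        for cx in range(n_cx):
            block = img[cy * cell_size : (cy + 1) * cell_size, cx * cell_size : (cx + 1) * cell_size]
            cell_means[idx] = block.mean()
            idx += 1

    # stage 1: FCM on cell means; deterministic wide-percentile init so
    # a small lesion still seeds the low cluster
    init = np.percentile(cell_means, [5.0, 95.0])
    _, centers = _fcm_two_cluster(cell_means, init, fuzzifier, max_iter, tol)
    # stage 2: pixel-level FCM seeded with the pooled centres
    u_pix, centers = _fcm_two_cluster(img.ravel(), np.sort(centers), fuzzifier, max_iter, tol)
    lower = int(np.argmin(centers))
    membership = u_pix[:, lower].reshape(h, w)

    w_sum = membership.sum()
    b_sum = (1.0 - membership).sum()
    if w_sum == 0 or b_sum == 0:
        raise DegenerateBipartitionError("one fuzzy region carries no weight")
    mu_F = float((membership * img).sum() / w_sum)
    mu_B = float(((1.0 - membership) * img).sum() / b_sum)
    bp = BipartitionMap(membership=membership, mu_F=mu_F, mu_B=mu_B)
    bp.validate_nonempty()
    return bp


def fit_surface(
    image: np.ndarray, bipartition: BipartitionMap, degree: int
) -> tuple[PolynomialSurface, float, float, float]:
    """Joint least-squares fit of class means and bias polynomial.

    Solves min over {mu_F, mu_B, c_jk} of the mean squared residual
    (1/Npix) sum_i (O_i - mu_psi(i) - P_i)^2, with mu_psi selected by
    the hard label. The design matrix concatenates the two region
    indicator columns with the monomial columns. Returns
    (surface, mu_F, mu_B, epsilon2).
    """
    img = as_gray_image(image)
    if degree < 1:
        raise InvalidArgumentError("fit_surface requires degree >= 1")
    if degree > MAX_DEGREE:
        raise InvalidArgumentError(f"degree > {MAX_DEGREE} rejected (conditioning)")
    bipartition.validate_nonempty()

    h, w = img.shape
    fore = bipartition.hard_foreground.ravel()
    X, Y = normalized_grid(h, w)
    pts = np.column_stack([X.ravel(), Y.ravel()])
    M = build_design_matrix(pts, degree)
    A = np.column_stack([fore.astype(float), (~fore).astype(float), M])
    b = img.ravel()

    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < A.shape[1]:
        logger.warning("rank-deficient bias-fit system (rank %d < %d); minimum-norm solution used", rank, A.shape[1])
    mu_F, mu_B = float(sol[0]), float(sol[1])
    surface = PolynomialSurface(degree, sol[2:])
    resid = b - A @ sol
    epsilon2 = float(resid @ resid / b.size)
    return surface, mu_F, mu_B, epsilon2


def correct_image(
    image: np.ndarray,
    degree: int = 2,
    cell_size: int = 4,
    max_outer_iter: int = 10,
    tol: float = 1e-4,
    fuzzifier: float = 2.0,
) -> CorrectionResult:
    """Estimate and subtract the bias field of an ROI image.

    Alternates fuzzy bipartition of the current corrected estimate with
    a least-squares surface fit on the original image, stopping when the
    relative change of eps^2 drops below ``tol`` or after
    ``max_outer_iter`` passes. If eps^2 would increase after a
    re-bipartition the previous iterate is kept and the loop stops, so
    the reported eps^2 trace is non-increasing.

    A degenerate bipartition (e.g. constant image) falls back to the
    identity: the input is returned unchanged with a zero surface and
    converged=False.
    """
    img = require_min_size(image)
    h, w = img.shape

    corrected = img
    best: CorrectionResult | None = None
    prev_eps = np.inf
    trace: list[float] = []
    converged = False
    iterations = 0

    for _ in range(max_outer_iter):
        try:
            bp = fuzzy_bipartition(corrected, cell_size=cell_size, fuzzifier=fuzzifier)
        except DegenerateBipartitionError as exc:
            if best is None:
                logger.warning("degenerate bipartition (%s); returning input unchanged", exc)
                return CorrectionResult(
                    corrected=img.copy(),
                    surface=PolynomialSurface.zero(),
                    bipartition=None,
                    epsilon2=float(np.var(img)),
                    iterations=0,
                    converged=False,
                    epsilon2_trace=[],
                )
            break
        surface, mu_F, mu_B, eps2 = fit_surface(img, bp, degree)
        if eps2 > prev_eps:  # re-bipartition made things worse: keep previous
            break
        iterations += 1
        trace.append(eps2)
        corrected = np.clip(img - surface.evaluate_grid(h, w), 0.0, 1.0)
        best = CorrectionResult(
            corrected=corrected,
            surface=surface,
            bipartition=bp,
            epsilon2=eps2,
            iterations=iterations,
            converged=False,
            epsilon2_trace=trace,
        )
        if np.isfinite(prev_eps) and abs(prev_eps - eps2) < tol * max(eps2, 1e-30):
            converged = True
            break
        prev_eps = eps2

    assert best is not None
    best.converged = converged
    best.epsilon2_trace = trace
    best.iterations = iterations
    return best
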