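"""Objective reconstruction metrics and their resampling statistics.

MSE, PSNR and SSIM are computed on the 0-255 pixel scale.  SSIM follows the
global-statistics form of the index (one window spanning the whole image)
with the standard constants C1 = (0.01*255)^2, C2 = (0.03*255)^2; a windowed
variant is available behind a flag for comparison.

Two resampled two-alternative statistics summarize reconstruction quality:

* ``ssim_accuracy`` - for each reconstruction, is it closer (by SSIM) to its
  own ground truth than to a randomly drawn distractor image?
* ``roi_reconstruction_accuracy`` - for each test stimulus, are its predicted
  attribute features closer (by Euclidean distance) to their ground-truth
  features than to a random distractor's features?

Both repeat the distractor draw (default 40 times), yielding a distribution
of accuracies tested against the 0.5 chance level with a one-sample t-test
and Benjamini-Hochberg FDR adjustment across conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .utils import check_shapes_match

C1 = (0.01 * 255) ** 2
C2 = (0.03 * 255) ** 2


@dataclass
class ImagePairMetrics:
    mse: float
    psnr: float
    ssim: float


def mse(x, y):
    """Mean squared pixel difference."""
    x, y = check_shapes_match(x, y)
    return float(np.mean((np.asarray(x, float) - np.asarray(y, float)) ** 2))


def psnr(x, y, max_value=255.0):
    """Peak signal-to-noise ratio in dB; +inf (with a warning) for identical images."""
    m = mse(x, y)
    if m == 0.0:
        warnings.warn("images identical (MSE = 0); PSNR is infinite")
        return float("inf")
    return float(10.0 * np.log10(max_value**2 / m))


def ssim(x, y, c1=C1, c2=C2, windowed=False):
    """Structural similarity; global image statistics by default.

    ``windowed=True`` delegates to the conventional sliding-window SSIM
    (scikit-image) for comparison.
    """
    x, y = check_shapes_match(x, y)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if windowed:
        from skimage.metrics import structural_similarity

        return float(structural_similarity(x, y, data_range=255.0))
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = ((x - mx) * (y - my)).mean()
    return float(((2 * mx * my + c1) * (2 * cov + c2)) / ((mx**2 + my**2 + c1) * (vx + vy + c2)))


def image_pair_metrics(x, y) -> ImagePairMetrics:
    return ImagePairMetrics(mse(x, y), psnr(x, y), ssim(x, y))


@dataclass
class ResamplingResult:
    """Per-repeat accuracies of a two-alternative statistic plus its test."""

    values: np.ndarray
    chance: float
    units: str = "proportion"  # or "percent"
    label: str = ""
    t: float = field(default=np.nan)
    p_raw: float = field(default=np.nan)
    p_fdr: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.t, self.p_raw = _one_sample_t(self.values, self.chance)

    @property
    def mean(self):
        return float(self.values.mean())

    @property
    def sd(self):
        return float(self.values.std(ddof=1)) if len(self.values) > 1 else 0.0

    @property
    def n_repeats(self):
        return len(self.values)

    def summary(self):
        p_fdr = "n/a" if self.p_fdr is None else f"{self.p_fdr:.4g}"
        return (
            f"{self.label or 'accuracy'}: mean {self.mean:.4g} {self.units} "
            f"(SD {self.sd:.3g}, {self.n_repeats} repeats), "
            f"t = {self.t:.3g} vs {self.chance:g}, p = {self.p_raw:.4g}, p_FDR = {p_fdr}"
        )


def _one_sample_t(values, null_value):
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least two values for a one-sample t-test")
    if np.allclose(values, null_value):
        return 0.0, 1.0
    t, p = stats.ttest_1samp(values, null_value)
    return float(t), float(p)


def test_against_null(values, null_value):
    """One-sample t-test of ``values`` against ``null_value``.

    Returns (t, p_raw, p_fdr); with a single condition the BH-adjusted p
    equals the raw p.  Use :func:`fdr_adjust` to correct a batch of results.
    """
    t, p = _one_sample_t(values, null_value)
    return t, p, p


def fdr_adjust(results):
    """Benjamini-Hochberg adjustment across a batch of ResamplingResults (in place)."""
    results = list(results)
    if not results:
        return results
    p_raw = [r.p_raw for r in results]
    _, p_adj, _, _ = multipletests(p_raw, method="fdr_bh")
    for r, p in zip(results, p_adj):
        r.p_fdr = float(p)
    return results


def _pairwise_global_ssim(recons, pool):
    """All-pairs global-statistics SSIM between two image stacks (vectorized)."""
    a = np.asarray(recons, dtype=float).reshape(len(recons), -1)
    b = np.asarray(pool, dtype=float).reshape(len(pool), -1)
    n = a.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1), b.var(axis=1)
    cov = (a @ b.T) / n - np.outer(ma, mb)
    num = (2 * np.outer(ma, mb) + C1) * (2 * cov + C2)
    den = (ma[:, None] ** 2 + mb[None, :] ** 2 + C1) * (va[:, None] + vb[None, :] + C2)
    return num / den


def _draw_distractors(rng, n_items, pool_size, exclude_self):
    idx = rng.integers(0, pool_size - (1 if exclude_self else 0), size=n_items)
    if exclude_self:
        shift = idx >= np.arange(n_items)
        idx = idx + shift
    return idx


def ssim_accuracy(recons, truths, distractor_pool=None, n_repeats=40, seed=0, label="") -> ResamplingResult:
    """Resampled SSIM two-alternative accuracy against the 0.5 chance level.

    Per repeat, each reconstruction's SSIM with its ground truth (SSIM1) is
    compared to its SSIM with a uniformly drawn distractor from the pool,
    excluding the ground truth itself (SSIM2); ties count as failures.
    Repeat ``r`` draws its distractors with seed ``seed + r``.
    """
    recons = np.asarray(recons)
    truths = np.asarray(truths)
    if len(recons) != len(truths):
        raise ValueError("recons and truths must be aligned")
    if distractor_pool is None:
        distractor_pool = truths
        exclude_self = True
    else:
        distractor_pool = np.asarray(distractor_pool)
        exclude_self = False
    if len(distractor_pool) < 2:
        raise ValueError("distractor pool must contain at least 2 images")
    sim = _pairwise_global_ssim(recons, distractor_pool)
    ssim1 = np.array([ssim(r, t) for r, t in zip(recons, truths)])
    n = len(recons)
    accs = np.empty(n_repeats)
    for r in range(n_repeats):
        rng = np.random.default_rng(seed + r)
        idx = _draw_distractors(rng, n, len(distractor_pool), exclude_self)
        ssim2 = sim[np.arange(n), idx]
        accs[r] = np.mean(ssim1 > ssim2)
    return ResamplingResult(accs, chance=0.5, units="proportion", label=label or "SSIM accuracy")


def roi_reconstruction_accuracy(predicted_features, true_features, attribute="", n_repeats=40, seed=0) -> ResamplingResult:
    """Resampled feature-space two-alternative accuracy (percent vs 50%).

    Euclidean distance from each test item's predicted attribute-block
    features to its own ground-truth features is compared against the
    distance to a random other item's ground-truth features.
    """
    pred = np.atleast_2d(np.asarray(predicted_features, dtype=float))
    true = np.atleast_2d(np.asarray(true_features, dtype=float))
    if pred.shape != true.shape:
        raise ValueError("predicted and true features must be aligned with equal dims")
    n = len(pred)
    if n < 2:
        raise ValueError("need at least 2 test items")
    d2 = (
        np.sum(pred**2, axis=1)[:, None]
        + np.sum(true**2, axis=1)[None, :]
        - 2.0 * pred @ true.T
    )
    d_self = np.diag(d2)
    accs = np.empty(n_repeats)
    for r in range(n_repeats):
        rng = np.random.default_rng(seed + r)
        idx = _draw_distractors(rng, n, n, exclude_self=True)
        accs[r] = np.mean(d_self < d2[np.arange(n), idx])
    return ResamplingResult(
        100.0 * accs, chance=50.0, units="percent", label=f"{attribute} reconstruction accuracy".strip()
    )
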