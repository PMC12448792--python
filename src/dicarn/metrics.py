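"""Evaluation metrics for contact-map enhancement.

Four similarity scores are implemented from their defining formulas rather than
wrapped from image libraries, because each is applied to Hi-C matrices with
conventions (stratification by diagonal, random-walk denoising, explicit
dynamic range) that generic implementations do not expose:

* ``ssim`` — structural similarity index, windowed mean/variance/covariance
  comparison with stability constants C1, C2;
* ``psnr`` — peak signal-to-noise ratio in dB for dynamic range L;
* ``genomedisco_score`` — concordance after random-walk denoising of the two
  maps (1 minus a normalized elementwise L1 distance);
* ``hicrep_scc`` — stratum-adjusted correlation coefficient pooling covariance
  and variance per diagonal stratum.

``summarize`` aggregates per-chromosome scores into mean +/- sample SD, the
layout used for benchmark tables in this field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import DataError, ShapeError, UndefinedScoreError
from .hic_io import ContactMatrix

PSNR_INF = float("inf")


@dataclass
class MetricParams:
    """Shared metric settings.

    ``L`` is the dynamic range (1.0 on min-max-normalized matrices); the SSIM
    stability constants default to the customary ``(0.01 L)^2`` and
    ``(0.03 L)^2`` with an 11-wide uniform window.  ``disco_t`` is the number
    of random-walk denoising steps; strata for the SCC run from diagonal
    offset 1 up to ``scc_strata_max`` and need at least ``scc_min_pairs``
    entries to participate.
    """

    L: float = 1.0
    C1: float | None = None
    C2: float | None = None
    ssim_window: int = 11
    disco_t: int = 3
    scc_strata_max: int | None = None
    scc_min_pairs: int = 2
    scc_smooth_h: int = 0  # optional mean-filter pre-smoothing; 0 disables

    def __post_init__(self) -> None:
        if self.C1 is None:
            self.C1 = (0.01 * self.L) ** 2
        if self.C2 is None:
            self.C2 = (0.03 * self.L) ** 2
        if self.L <= 0 or self.C1 <= 0 or self.C2 <= 0:
            raise ValueError("L, C1, C2 must be positive")
        if self.ssim_window % 2 == 0 or self.ssim_window < 1:
            raise ValueError("ssim_window must be odd and positive")
        if self.disco_t < 1:
            raise ValueError("disco_t must be >= 1")


@dataclass
class MetricReport:
    """Per-chromosome metric values with mean and sample SD per metric."""

    per_chromosome: dict[str, dict[str, float]]
    mean: dict[str, float]
    sd: dict[str, float]
    single_sample: bool = False

    def to_tsv(self) -> str:
        metrics = list(next(iter(self.per_chromosome.values())).keys())
        lines = ["metric\t" + "\t".join(self.per_chromosome) + "\tmean\tsd"]
        for met in metrics:
            row = [met]
            row += [f"{self.per_chromosome[c][met]:.6g}" for c in self.per_chromosome]
            row += [f"{self.mean[met]:.6g}", f"{self.sd[met]:.6g}"]
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"


def _values(x) -> np.ndarray:
    if isinstance(x, ContactMatrix):
        return x.values
    return np.asarray(x, dtype=float)


def compute_mse(p, q) -> float:
    """Mean squared error ``(1/m^2) sum (P - Q)^2`` between equally shaped maps."""
    p, q = _values(p), _values(q)
    if p.shape != q.shape:
        raise ShapeError(f"shape mismatch {p.shape} vs {q.shape}")
    return float(np.mean((p - q) ** 2))


def ssim(x, y, p: MetricParams | None = None, mode: str = "windowed") -> float:
    """Structural similarity index between two maps of equal shape.

    ``mode='windowed'`` averages the per-window SSIM over every fully contained
    ``ssim_window x ssim_window`` patch (uniform window, population moments);
    ``mode='global'`` treats the whole image as one window.  Symmetric in its
    arguments, 1.0 iff the maps are identical.
    """
    p = p or MetricParams()
    x, y = _values(x), _values(y)
    if x.shape != y.shape:
        raise ShapeError(f"shape mismatch {x.shape} vs {y.shape}")
    c1, c2 = p.C1, p.C2

    def _ssim_from_moments(mx, my, vx, vy, cxy):
        return ((2 * mx * my + c1) * (2 * cxy + c2)) / (
            (mx**2 + my**2 + c1) * (vx + vy + c2)
        )

    if mode == "global" or min(x.shape) < p.ssim_window:
        mx, my = x.mean(), y.mean()
        vx, vy = x.var(), y.var()
        cxy = ((x - mx) * (y - my)).mean()
        return float(_ssim_from_moments(mx, my, vx, vy, cxy))
    w = p.ssim_window
    xw = sliding_window_view(x, (w, w))
    yw = sliding_window_view(y, (w, w))
    mx = xw.mean(axis=(-2, -1))
    my = yw.mean(axis=(-2, -1))
    vx = (xw**2).mean(axis=(-2, -1)) - mx**2
    vy = (yw**2).mean(axis=(-2, -1)) - my**2
    cxy = (xw * yw).mean(axis=(-2, -1)) - mx * my
    return float(_ssim_from_moments(mx, my, vx, vy, cxy).mean())


def psnr(x, y, p: MetricParams | None = None) -> float:
    """Peak signal-to-noise ratio ``10 log10(L^2 / MSE)`` in dB.

    Returns ``inf`` for identical inputs (MSE = 0).
    """
    p = p or MetricParams()
    mse = compute_mse(x, y)
    if mse == 0:
        return PSNR_INF
    return float(10.0 * np.log10(p.L**2 / mse))


def _random_walk(a: np.ndarray, t: int) -> np.ndarray:
    """Row-normalize to a transition matrix and take ``t`` walk steps."""
    rs = a.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(rs > 0, a / np.where(rs > 0, rs, 1.0), 0.0)
    return np.linalg.matrix_power(p, t)


def genomedisco_score(a1, a2, p: MetricParams | None = None) -> float:
    """Concordance score ``S = 1 - D`` between two contact maps.

    Each map is row-normalized to a transition matrix and denoised by a
    ``disco_t``-step random walk; ``D`` is the elementwise L1 distance between
    the denoised maps divided by ``N``, the number of bins with a nonzero
    marginal in either map.  ``S`` is at most 1, attained iff the denoised maps
    coincide.
    """
    p = p or MetricParams()
    a1, a2 = _values(a1), _values(a2)
    if a1.shape != a2.shape:
        raise ShapeError(f"shape mismatch {a1.shape} vs {a2.shape}")
    m1 = a1.sum(axis=1) > 0
    m2 = a2.sum(axis=1) > 0
    n_nodes = int(np.count_nonzero(m1 | m2))
    if n_nodes == 0:
        raise UndefinedScoreError("both maps are all-zero; concordance undefined")
    d = float(np.abs(_random_walk(a1, p.disco_t) - _random_walk(a2, p.disco_t)).sum()) / n_nodes
    return 1.0 - d


def _smooth(a: np.ndarray, h: int) -> np.ndarray:
    if h <= 0:
        return a
    from scipy.ndimage import uniform_filter

    return uniform_filter(a, size=2 * h + 1, mode="constant")


def hicrep_scc(x, y, p: MetricParams | None = None) -> float:
    """Stratum-adjusted correlation coefficient between two contact maps.

    Pairs are stratified by diagonal offset ``k = 1..K``; per-stratum population
    covariance and variances are pooled as
    ``sum_k cov_k / sqrt(sum_k var_x,k * sum_k var_y,k)``.  Strata with fewer
    than ``scc_min_pairs`` pairs are skipped.  Equals 1 whenever ``y`` is a
    positive multiple of ``x``.
    """
    p = p or MetricParams()
    x, y = _values(x), _values(y)
    if x.shape != y.shape:
        raise ShapeError(f"shape mismatch {x.shape} vs {y.shape}")
    if p.scc_smooth_h > 0:
        x, y = _smooth(x, p.scc_smooth_h), _smooth(y, p.scc_smooth_h)
    n = x.shape[0]
    kmax = n - 1 if p.scc_strata_max is None else min(p.scc_strata_max, n - 1)
    cov_sum = 0.0
    varx_sum = 0.0
    vary_sum = 0.0
    for k in range(1, kmax + 1):
        xk = np.diagonal(x, offset=k)
        yk = np.diagonal(y, offset=k)
        if xk.size < p.scc_min_pairs:
            continue
        mx, my = xk.mean(), yk.mean()
        cov_sum += ((xk - mx) * (yk - my)).mean()
        varx_sum += ((xk - mx) ** 2).mean()
        vary_sum += ((yk - my) ** 2).mean()
    denom = varx_sum * vary_sum
    if denom <= 0:
        raise UndefinedScoreError("all strata degenerate (zero variance)")
    return float(cov_sum / np.sqrt(denom))


def summarize(reports: dict[str, dict[str, float]]) -> MetricReport:
    """Aggregate per-chromosome metric dicts into mean +/- sample SD.

    Chromosome ordering is preserved; a single chromosome yields SD 0 with the
    ``single_sample`` flag set.
    """
    if not reports:
        raise DataError("no chromosomes to summarize")
    metrics = list(next(iter(reports.values())).keys())
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    single = len(reports) == 1
    for met in metrics:
        vals = np.array([reports[c][met] for c in reports], dtype=float)
        mean[met] = float(vals.mean())
        sd[met] = 0.0 if single else float(vals.std(ddof=1))
    return MetricReport(per_chromosome=dict(reports), mean=mean, sd=sd, single_sample=single)
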