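"""Imputing interaction frequencies from DNase-seq chromatin accessibility and
building accessibility-augmented training sets.

The model is a linear regression of a pair's (KR-normalized) interaction
frequency on the accessibility of the two bins and their 1-D genomic
separation::

    epsilon_{k,l} = alpha1 * R_k + alpha2 * R_l + alpha3 * D_{k,l}

where ``R_k`` is the mean accessibility of bin ``k`` and ``D_{k,l} = |k - l| *
bin_size``.  Fitted coefficients applied across a chromosome give a dense
imputed IF matrix which, after symmetrization, clipping and KR balancing, is
structurally parallel to a real contact map and can be appended to a Hi-C
training set (Target mode: imputed data from the target cell line's test
chromosomes; Source mode: from the source cell line's training chromosomes).

The regression target is configurable: ``regress_target="if"`` (default) fits
the normalized IF directly; ``regress_target="distance"`` treats the model
output as a spatial-distance proxy and converts it to an IF through the
inverse power law :func:`distance_to_if`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError, ShapeError, SplitError, ValidationError
from .hic_io import (
    KR,
    ContactMatrix,
    Tile,
    TileSet,
    downsample_reads,
    kr_balance,
    minmax_normalize,
    tile_matrix,
)


@dataclass
class DNaseTrack:
    """Per-bin mean accessibility signal aligned to a contact matrix's bins."""

    chrom: str
    bin_size: int
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 1:
            raise ShapeError("signal must be one-dimensional")
        if np.any(self.signal < 0):
            raise ValidationError("accessibility signal must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.signal.size


@dataclass
class ImputationParams:
    """Fitted regression coefficients with their residual and fitting band."""

    alpha1: float
    alpha2: float
    alpha3: float
    fit_residual: float = 0.0
    distance_cap: int = 400
    rank_deficient: bool = False

    def __post_init__(self) -> None:
        for a in (self.alpha1, self.alpha2, self.alpha3, self.fit_residual):
            if not np.isfinite(a):
                raise ValidationError("imputation parameters must be finite")
        if self.fit_residual < 0:
            raise ValidationError("fit_residual must be >= 0")


@dataclass
class AugmentedDataset:
    """Hi-C tile pairs plus accessibility-imputed tile pairs with provenance.

    ``pairs`` is an ordered list of ``(lr_tile, hr_tile, origin)`` with origin
    ``"hic"`` or ``"dnase_inferred"``; ``mode`` records which augmentation
    scenario produced the imputed tiles.
    """

    pairs: list[tuple[Tile, Tile, str]]
    mode: str

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def hic_pairs(self):
        return [(a, b) for a, b, o in self.pairs if o == "hic"]

    @property
    def dnase_pairs(self):
        return [(a, b) for a, b, o in self.pairs if o == "dnase_inferred"]

    def training_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lr = np.stack([a.values for a, _, _ in self.pairs])
        hr = np.stack([b.values for _, b, _ in self.pairs])
        return lr, hr


# ---------------------------------------------------------------------------
# Signal aggregation
# ---------------------------------------------------------------------------

def read_bedgraph(path, chrom: str | None = None) -> np.ndarray:
    """Load a 4-column bedGraph into ``(start, end, value)`` rows."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                     names=["chrom", "start", "end", "value"],
                     dtype={"chrom": str})
    df = df[~df["chrom"].str.startswith("track")]
    if chrom is not None:
        df = df[df["chrom"] == chrom]
    elif df["chrom"].nunique() > 1:
        raise ValidationError("bedGraph mixes chromosomes; pass chrom explicitly")
    return df[["start", "end", "value"]].to_numpy(dtype=float)


def read_bed_bins(path, chrom: str | None = None) -> np.ndarray:
    """Load BED3 bin intervals as ``(start, end)`` rows."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={"chrom": str})
    if chrom is not None:
        df = df[df["chrom"] == chrom]
    elif df["chrom"].nunique() > 1:
        raise ValidationError("bin BED mixes chromosomes; pass chrom explicitly")
    return df[["start", "end"]].to_numpy(dtype=float)


def read_bigwig_track(path, chrom: str, n_bins: int, bin_size: int) -> "DNaseTrack":
    """Mean per-bin signal from a bigWig file (requires pyBigWig)."""
    import pyBigWig

    bw = pyBigWig.open(str(path))
    try:
        vals = bw.stats(chrom, 0, n_bins * bin_size, nBins=n_bins, type="mean")
    finally:
        bw.close()
    signal = np.array([v if v is not None else 0.0 for v in vals], dtype=float)
    return DNaseTrack(chrom=chrom, bin_size=bin_size, signal=np.maximum(signal, 0.0))


def aggregate_signal_to_bins(track: np.ndarray, bins: np.ndarray,
                             chrom: str = "", bin_size: int | None = None) -> DNaseTrack:
    """Coverage-weighted mean of interval values per uniform genomic bin.

    ``track`` rows are sorted, non-overlapping ``(start, end, value)``
    intervals; ``bins`` rows are uniform ``(start, end)`` intervals.  Bins with
    no overlapping signal get 0.
    """
    track = np.asarray(track, dtype=float).reshape(-1, 3)
    bins = np.asarray(bins, dtype=float).reshape(-1, 2)
    if bins.size == 0:
        raise DataError("no bins given")
    widths = bins[:, 1] - bins[:, 0]
    if not np.allclose(widths, widths[0]):
        raise ValidationError("bins must be uniform width")
    if track.size:
        order = np.argsort(track[:, 0])
        track = track[order]
        if np.any(track[1:, 0] < track[:-1, 1] - 1e-9):
            raise ValidationError("signal intervals overlap each other")
    out = np.zeros(len(bins))
    for b, (bs, be) in enumerate(bins):
        if track.size == 0:
            break
        ov_start = np.maximum(track[:, 0], bs)
        ov_end = np.minimum(track[:, 1], be)
        w = np.maximum(ov_end - ov_start, 0.0)
        tot = w.sum()
        if tot > 0:
            out[b] = float((w * track[:, 2]).sum() / tot)
    return DNaseTrack(chrom=chrom, bin_size=int(bin_size or widths[0]), signal=out)


# ---------------------------------------------------------------------------
# Regression
# ---------------------------------------------------------------------------

def genomic_distance_matrix(n_bins: int, bin_size: int) -> np.ndarray:
    """``D[k, l] = |k - l| * bin_size``: symmetric, zero diagonal."""
    if n_bins < 1:
        raise ParameterError("n_bins must be >= 1")
    idx = np.arange(n_bins)
    return np.abs(idx[:, None] - idx[None, :]).astype(float) * bin_size


def fit_imputation_params(
    r: DNaseTrack,
    d: np.ndarray,
    target: ContactMatrix,
    distance_cap: int = 400,
    tie_alphas: bool = False,
) -> ImputationParams:
    """Least-squares fit of ``target ≈ a1 R_k + a2 R_l + a3 D_{k,l}``.

    Uses each unordered upper-triangle pair with ``|k - l| <= distance_cap``
    and a nonzero target once.  ``tie_alphas=True`` enforces the symmetric
    ``a1 = a2`` model by fitting on ``R_k + R_l``.  The RMS residual of the fit
    is stored; a rank-deficient design sets ``rank_deficient``.
    """
    n = target.n_bins
    if r.n_bins != n:
        raise ShapeError(f"track has {r.n_bins} bins, matrix has {n}")
    kk, ll = np.triu_indices(n)
    band = np.abs(kk - ll) <= distance_cap
    nz = target.values[kk, ll] != 0
    sel = band & nz
    kk, ll = kk[sel], ll[sel]
    y = target.values[kk, ll]
    if y.size < 3:
        raise DataError(f"only {y.size} eligible pairs; need at least 3")
    dv = d[kk, ll]
    if tie_alphas:
        x = np.column_stack([r.signal[kk] + r.signal[ll], dv])
    else:
        x = np.column_stack([r.signal[kk], r.signal[ll], dv])
    coef, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = float(np.sqrt(np.mean((x @ coef - y) ** 2)))
    if tie_alphas:
        a1 = a2 = float(coef[0])
        a3 = float(coef[1])
        deficient = rank < 2
    else:
        a1, a2, a3 = (float(c) for c in coef)
        deficient = rank < 3
    return ImputationParams(a1, a2, a3, fit_residual=resid,
                            distance_cap=distance_cap, rank_deficient=deficient)


def distance_to_if(dist: np.ndarray, exponent: float = 1.0, epsilon: float = 1.0) -> np.ndarray:
    """Inverse power-law conversion ``IF = (dist + epsilon) ** (-exponent)``.

    Strictly decreasing in distance; ``epsilon`` keeps the zero diagonal
    finite.
    """
    if exponent <= 0:
        raise ParameterError("exponent must be positive")
    dist = np.asarray(dist, dtype=float)
    if np.any(dist < 0):
        raise ValidationError("distances must be non-negative")
    return (dist + epsilon) ** (-exponent)


def _predict_block(r: DNaseTrack, params: ImputationParams, d_block: np.ndarray,
                   rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    return (params.alpha1 * r.signal[rows][:, None]
            + params.alpha2 * r.signal[cols][None, :]
            + params.alpha3 * d_block)


def impute_if_matrix(
    r: DNaseTrack,
    params: ImputationParams,
    n_bins: int,
    bin_size: int,
    regress_target: str = "if",
    dist_exponent: float = 1.0,
    dist_epsilon: float = 1.0,
    balance: bool = True,
) -> ContactMatrix:
    """Dense imputed IF matrix from an accessibility track.

    Applies the linear model, symmetrizes, clips negatives to zero, optionally
    converts a distance-valued prediction to an IF, and finally KR-balances so
    the result is consistent with normalized Hi-C data.
    """
    if r.n_bins != n_bins:
        raise ShapeError(f"track has {r.n_bins} bins, expected {n_bins}")
    d = genomic_distance_matrix(n_bins, bin_size)
    idx = np.arange(n_bins)
    eps = _predict_block(r, params, d, idx, idx)
    eps = (eps + eps.T) / 2.0
    eps = np.maximum(eps, 0.0)
    if regress_target == "distance":
        eps = distance_to_if(eps, exponent=dist_exponent, epsilon=dist_epsilon)
    elif regress_target != "if":
        raise ParameterError(f"regress_target must be 'if' or 'distance', got {regress_target!r}")
    m = ContactMatrix(chrom=r.chrom, resolution=bin_size, values=eps)
    return kr_balance(m) if balance else m


def impute_chromosome_chunked(
    r: DNaseTrack,
    hic: ContactMatrix,
    chunk: int = 200,
    params: ImputationParams | None = None,
    distance_cap: int = 400,
    regress_target: str = "if",
    balance: bool = True,
) -> ContactMatrix:
    """Chunked imputation of a whole chromosome, then a single KR balance.

    The prediction for a pair depends only on its two bins, so evaluating the
    model block-by-block over a 2-D grid of bin chunks and reassembling
    reproduces the unchunked matrix exactly; KR balancing is applied once to
    the assembled whole-chromosome matrix (``balance=False`` returns the
    pre-balance matrix).  When ``params`` is omitted they are first fitted on
    ``hic`` (KR-balancing it if still raw).
    """
    n = hic.n_bins
    if r.n_bins != n:
        raise ShapeError(f"track has {r.n_bins} bins, matrix has {n}")
    if chunk < 40:
        raise ParameterError("chunk must be >= 40 bins")
    chunk = min(chunk, n)  # oversized chunk falls back to a single chunk
    if params is None:
        target = hic if hic.norm_state == KR else kr_balance(hic)
        d = genomic_distance_matrix(n, hic.resolution)
        params = fit_imputation_params(r, d, target, distance_cap=distance_cap)
    dfull = genomic_distance_matrix(n, hic.resolution)
    raw = np.zeros((n, n))
    starts = list(range(0, n, chunk))
    for rs in starts:
        re_ = min(rs + chunk, n)
        for cs in starts:
            ce = min(cs + chunk, n)
            rows = np.arange(rs, re_)
            cols = np.arange(cs, ce)
            raw[rs:re_, cs:ce] = _predict_block(r, params, dfull[rs:re_, cs:ce], rows, cols)
    raw = (raw + raw.T) / 2.0
    raw = np.maximum(raw, 0.0)
    if regress_target == "distance":
        raw = distance_to_if(raw)
    m = ContactMatrix(chrom=r.chrom, resolution=hic.resolution, values=raw)
    return kr_balance(m) if balance else m


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def imputed_matrix_to_pairs(
    imputed: ContactMatrix,
    downsample_ratio: float,
    seed: int,
    pseudo_depth: float = 1e6,
    tile_size: int = 40,
    stride: int | None = None,
    max_diag_distance: int = 400,
    clip_quantile: float = 1.0,
) -> tuple[TileSet, TileSet]:
    """Turn an imputed matrix into (LR, HR) tile sets parallel to Hi-C pairs.

    The KR-balanced imputed matrix is rescaled to integer pseudo-counts of
    total about ``pseudo_depth``, read-thinned at the same ratio as the Hi-C
    training data, and both versions are min-max normalized and tiled.
    """
    total = imputed.values.sum()
    if total <= 0:
        raise DataError("imputed matrix is all zero")
    counts = np.rint(imputed.values * (pseudo_depth / total))
    hr = ContactMatrix(chrom=imputed.chrom, resolution=imputed.resolution, values=counts)
    lr = downsample_reads(hr, downsample_ratio, seed=seed)
    hr_n = minmax_normalize(hr, clip_quantile)
    lr_n = minmax_normalize(lr, clip_quantile)
    hr_t = tile_matrix(hr_n, size=tile_size, stride=stride, max_diag_distance=max_diag_distance)
    lr_t = tile_matrix(lr_n, size=tile_size, stride=stride, max_diag_distance=max_diag_distance)
    return lr_t, hr_t


def build_augmented_dataset(
    source_hic_pairs: tuple[TileSet, TileSet],
    dnase_imputed: dict[str, ContactMatrix],
    mode: str,
    train_chroms: list[str],
    test_chroms: list[str],
    downsample_ratio: float = 1.0 / 16.0,
    seed: int = 0,
    **pair_kw,
) -> AugmentedDataset:
    """Concatenate Hi-C pairs with accessibility-imputed pairs.

    ``mode="target"`` draws imputed tiles from the target cell line's test
    chromosomes; ``mode="source"`` from the source cell line's training
    chromosomes.  Every emitted pair carries an origin tag and ordering is
    deterministic (Hi-C pairs first, then imputed pairs in chromosome order).
    """
    if mode not in ("target", "source"):
        raise ParameterError(f"mode must be 'target' or 'source', got {mode!r}")
    overlap = set(train_chroms) & set(test_chroms)
    if overlap:
        raise SplitError(f"chromosomes {sorted(overlap)} in both train and test lists")
    lr_ts, hr_ts = source_hic_pairs
    pairs: list[tuple[Tile, Tile, str]] = [
        (a, b, "hic") for a, b in zip(lr_ts.tiles, hr_ts.tiles)
    ]
    wanted = test_chroms if mode == "target" else train_chroms
    for ci, chrom in enumerate(wanted):
        if chrom not in dnase_imputed:
            continue
        lr_t, hr_t = imputed_matrix_to_pairs(
            dnase_imputed[chrom], downsample_ratio, seed=seed + ci, **pair_kw
        )
        pairs.extend((a, b, "dnase_inferred") for a, b in zip(lr_t.tiles, hr_t.tiles))
    return AugmentedDataset(pairs=pairs, mode=mode)
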