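"""Reading, writing, normalizing, downsampling, tiling and reassembling Hi-C contact matrices.

A contact matrix is the symmetric ``n x n`` table of interaction frequencies (IFs)
between evenly sized genomic bins of one chromosome.  All coordinates inside the
toolkit are 0-based bin indices with half-open intervals; base-pair positions
appear only at I/O boundaries.

Supported on-disk dialects:

* ``triplet_text`` — whitespace-separated ``bin_i bin_j count`` rows (optionally
  base-pair coordinates), the exchange format the toolkit itself emits;
* ``dense_archive`` — an ``.npz`` archive keyed by chromosome label holding dense
  matrices;
* ``cooler`` — single-resolution ``.cool`` HDF5 files, read directly through h5py
  (``bins`` and ``pixels`` tables).  Multi-resolution trees and ``.hic`` binaries
  are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import (
    BoundsError,
    ConvergenceError,
    FormatError,
    ParameterError,
    ShapeError,
    StateError,
    ValidationError,
)

RAW = "raw_counts"
KR = "kr_balanced"
MINMAX = "minmax"

_SYM_TOL = 1e-9


@dataclass
class ContactMatrix:
    """Symmetric non-negative per-chromosome interaction-frequency matrix.

    Parameters
    ----------
    chrom : chromosome label.
    resolution : bin size in base pairs.
    values : ``(n_bins, n_bins)`` float array, symmetric and non-negative.
    norm_state : one of ``raw_counts``, ``kr_balanced``, ``minmax``.
    scale : multiplicative factor mapping ``values`` back to the pre-``minmax``
        scale (1.0 unless min-max normalized).
    """

    chrom: str
    resolution: int
    values: np.ndarray
    norm_state: str = RAW
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def validate(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ShapeError(f"contact matrix must be square, got {v.shape}")
        if np.any(v < 0):
            raise ValidationError("contact matrix has negative entries")
        denom = max(float(np.abs(v).max()), 1.0)
        if float(np.abs(v - v.T).max()) > _SYM_TOL * denom:
            raise ValidationError("contact matrix is not symmetric")
        if self.norm_state not in (RAW, KR, MINMAX):
            raise ValidationError(f"unknown norm_state {self.norm_state!r}")

    def copy_with(self, **kw) -> "ContactMatrix":
        return replace(self, **kw)


@dataclass
class Tile:
    """One ``size x size`` sub-matrix with its genomic placement (bin offsets)."""

    row_offset: int
    col_offset: int
    values: np.ndarray
    chrom: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class TileSet:
    """Ordered tile collection that can be reassembled onto its source grid."""

    tiles: list[Tile]
    source_shape: tuple[int, int]
    stride: int
    chrom: str = ""
    resolution: int = 0
    norm_state: str = RAW

    def __len__(self) -> int:
        return len(self.tiles)

    def __iter__(self):
        return iter(self.tiles)

    def arrays(self) -> np.ndarray:
        """Stack tile values into an ``(n_tiles, size, size)`` array."""
        return np.stack([t.values for t in self.tiles])

    def with_values(self, stacked: np.ndarray, norm_state: str | None = None) -> "TileSet":
        """Same offsets/ordering, new per-tile values."""
        if stacked.shape[0] != len(self.tiles):
            raise ShapeError("tile count mismatch")
        tiles = [
            Tile(t.row_offset, t.col_offset, stacked[i], t.chrom)
            for i, t in enumerate(self.tiles)
        ]
        return TileSet(
            tiles,
            self.source_shape,
            self.stride,
            self.chrom,
            self.resolution,
            self.norm_state if norm_state is None else norm_state,
        )


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------

def _read_triplets(path, resolution: int, bp_coords: bool) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith(("#", "track")):
                continue
            try:
                i, j, c = float(parts[0]), float(parts[1]), float(parts[2])
            except (ValueError, IndexError):
                if line_no == 1:  # tolerated header line
                    continue
                raise FormatError(f"{path}: unparseable triplet at line {line_no}")
            rows.append((i, j, c))
    if not rows:
        return np.empty((0, 3))
    arr = np.asarray(rows, dtype=float)
    if bp_coords:
        arr[:, :2] = arr[:, :2] // resolution
    return arr


def _triplets_to_dense(trip: np.ndarray, n_bins: int) -> np.ndarray:
    m = np.zeros((n_bins, n_bins))
    if trip.size == 0:
        return m
    if np.any(trip[:, 2] < 0):
        raise ValidationError("negative counts in triplet input")
    idx = trip[:, :2].astype(int)
    if np.any(idx < 0) or np.any(idx >= n_bins):
        raise BoundsError(f"bin index outside [0, {n_bins}) in triplet input")
    # populate both (i, j) and (j, i); duplicated symmetric rows must agree,
    # so overwrite rather than accumulate across mirror images
    np.add.at(m, (idx[:, 0], idx[:, 1]), trip[:, 2])
    lower = idx[:, 0] != idx[:, 1]
    mirrored = np.zeros_like(m)
    np.add.at(mirrored, (idx[lower, 1], idx[lower, 0]), trip[lower, 2])
    # where the file already gave both triangles, the mirror would double count:
    # take elementwise max of (given, mirrored) instead of the sum
    m = np.maximum(m, mirrored)
    return m


def _read_cooler(path, chrom: str, resolution: int) -> np.ndarray:
    import h5py

    with h5py.File(path, "r") as f:
        names = [n.decode() if isinstance(n, bytes) else str(n) for n in f["chroms/name"][:]]
        if chrom not in names:
            raise FormatError(f"{path}: chromosome {chrom!r} not in cooler file")
        cid = names.index(chrom)
        bin_chrom = f["bins/chrom"][:]
        in_chrom = np.flatnonzero(bin_chrom == cid)
        b0, b1 = int(in_chrom[0]), int(in_chrom[-1]) + 1
        n = b1 - b0
        binsize = int(f.attrs.get("bin-size", resolution))
        if binsize != resolution:
            raise FormatError(
                f"{path}: cooler bin size {binsize} != requested resolution {resolution}"
            )
        b1id = f["pixels/bin1_id"][:]
        b2id = f["pixels/bin2_id"][:]
        count = f["pixels/count"][:].astype(float)
        sel = (b1id >= b0) & (b1id < b1) & (b2id >= b0) & (b2id < b1)
        m = np.zeros((n, n))
        i = (b1id[sel] - b0).astype(int)
        j = (b2id[sel] - b0).astype(int)
        np.add.at(m, (i, j), count[sel])
        off = i != j
        np.add.at(m, (j[off], i[off]), count[sel][off])
    return m


def read_contact_matrix(
    path,
    fmt: str,
    chrom: str,
    resolution: int,
    n_bins: int | None = None,
    bp_coords: bool = False,
) -> ContactMatrix:
    """Read one chromosome's contact matrix.

    ``fmt`` is ``triplet_text``, ``dense_archive`` or ``cooler``.  For triplet
    text, ``n_bins`` may be omitted and is then inferred as ``max index + 1``;
    ``bp_coords=True`` declares base-pair rather than bin-unit coordinates.
    The result is symmetrized (each triplet populates both ``[i, j]`` and
    ``[j, i]``) and tagged ``raw_counts``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "triplet_text":
        trip = _read_triplets(path, resolution, bp_coords)
        if n_bins is None:
            n_bins = int(trip[:, :2].max()) + 1 if trip.size else 0
        values = _triplets_to_dense(trip, n_bins)
    elif fmt == "dense_archive":
        with np.load(path) as npz:
            if chrom not in npz:
                raise FormatError(f"{path}: chromosome {chrom!r} not in archive")
            values = np.asarray(npz[chrom], dtype=float)
    elif fmt == "cooler":
        values = _read_cooler(path, chrom, resolution)
    else:
        raise FormatError(f"unknown contact-matrix format {fmt!r}")
    return ContactMatrix(chrom=chrom, resolution=resolution, values=values)


def write_contact_matrix(m: ContactMatrix, path, fmt: str = "triplet_text") -> None:
    """Write a matrix in ``triplet_text`` (upper triangle, nonzero entries) or
    ``dense_archive`` dialect."""
    path = Path(path)
    if fmt == "triplet_text":
        iu = np.triu_indices(m.n_bins)
        vals = m.values[iu]
        nz = vals != 0
        with open(path, "w") as fh:
            fh.write(f"# chrom={m.chrom} resolution={m.resolution} "
                     f"n_bins={m.n_bins} norm={m.norm_state}\n")
            for i, j, v in zip(iu[0][nz], iu[1][nz], vals[nz]):
                fh.write(f"{i} {j} {v:.10g}\n")
    elif fmt == "dense_archive":
        np.savez_compressed(path, **{m.chrom: m.values})
    else:
        raise FormatError(f"unknown contact-matrix format {fmt!r}")


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def downsample_reads(m: ContactMatrix, ratio: float, seed: int) -> ContactMatrix:
    """Binomially thin raw counts, emulating lower sequencing coverage.

    Each upper-triangle count ``c`` is replaced by a Binomial(``c``, ``ratio``)
    draw and mirrored, so every entry keeps expectation ``ratio * c`` and the
    matrix stays symmetric.  Deterministic given ``seed``.
    """
    if not (0 < ratio <= 1):
        raise ParameterError(f"downsampling ratio must be in (0, 1], got {ratio}")
    if m.norm_state != RAW:
        raise StateError("downsampling requires raw counts")
    counts = m.values
    rounded = np.rint(counts)
    if not np.allclose(counts, rounded, atol=1e-6):
        raise StateError("downsampling requires integer counts")
    if ratio == 1.0:
        return m.copy_with(values=counts.copy())
    rng = np.random.default_rng(seed)
    n = m.n_bins
    iu = np.triu_indices(n)
    thinned = rng.binomial(rounded[iu].astype(np.int64), ratio).astype(float)
    out = np.zeros_like(counts)
    out[iu] = thinned
    out = out + out.T - np.diag(np.diag(out))
    return m.copy_with(values=out)


def kr_balance(m: ContactMatrix, tol: float = 1e-6, max_iter: int = 3000) -> ContactMatrix:
    """Knight-Ruiz style matrix balancing by symmetric diagonal scaling.

    All-zero rows are masked out first; on the remaining sub-matrix a scaling
    vector ``x`` is iterated (``B = diag(x) A diag(x)``) until the coefficient
    of variation of the row sums drops below ``tol``, then ``B`` is rescaled so
    unmasked row sums equal 1.  Masked rows/columns come back as zeros.
    """
    v = m.values
    mask = v.sum(axis=1) > 0
    out = np.zeros_like(v)
    if mask.sum() == 0:
        return m.copy_with(values=out, norm_state=KR)
    sub = v[np.ix_(mask, mask)]
    x = np.ones(sub.shape[0])
    residual = np.inf
    for _ in range(max_iter):
        r = x * (sub @ x)
        mean_r = r.mean()
        if mean_r <= 0:
            raise ConvergenceError("balancing degenerate: zero mean row sum", np.inf)
        residual = float(r.std() / mean_r)
        if residual < tol:
            break
        # guard rows whose current sum is zero (disconnected support)
        ratio = np.where(r > 0, r / mean_r, 1.0)
        x = x / np.sqrt(ratio)
    else:
        raise ConvergenceError(
            f"KR balancing did not reach tol={tol} in {max_iter} iterations "
            f"(residual {residual:.3g})",
            residual,
        )
    bal = sub * np.outer(x, x)
    bal = bal / bal.sum(axis=1).mean()
    bal = (bal + bal.T) / 2.0
    out[np.ix_(mask, mask)] = bal
    return m.copy_with(values=out, norm_state=KR)


def minmax_normalize(m: ContactMatrix, clip_quantile: float = 1.0) -> ContactMatrix:
    """Clip at the given upper quantile and scale to [0, 1].

    The clip value is recorded in ``scale`` so the transform can be inverted.
    An all-zero matrix comes back unchanged with unit scale.
    """
    if not (0 < clip_quantile <= 1):
        raise ParameterError("clip_quantile must be in (0, 1]")
    hi = float(np.quantile(m.values, clip_quantile))
    if hi <= 0:
        return m.copy_with(values=np.zeros_like(m.values), norm_state=MINMAX, scale=1.0)
    scaled = np.minimum(m.values, hi) / hi
    return m.copy_with(values=scaled, norm_state=MINMAX, scale=hi)


# ---------------------------------------------------------------------------
# Tiling
# ---------------------------------------------------------------------------

def tile_matrix(
    m: ContactMatrix,
    size: int = 40,
    stride: int | None = None,
    max_diag_distance: int = 400,
) -> TileSet:
    """Cut the matrix into ``size x size`` blocks near the diagonal.

    Offsets step by ``stride`` (default: ``size``, i.e. non-overlapping); only
    blocks with ``|row_offset - col_offset| <= max_diag_distance`` are kept,
    restricting training data to the informative near-diagonal band.  Edge
    blocks that would run past the chromosome are dropped, never padded.
    Ordering is row-major and deterministic.
    """
    if stride is None:
        stride = size
    n = m.n_bins
    if size > n:
        raise ShapeError(f"tile size {size} exceeds matrix size {n}")
    if stride < 1:
        raise ParameterError("stride must be >= 1")
    tiles = []
    for r in range(0, n - size + 1, stride):
        for c in range(0, n - size + 1, stride):
            if abs(r - c) <= max_diag_distance:
                tiles.append(Tile(r, c, m.values[r : r + size, c : c + size].copy(), m.chrom))
    return TileSet(tiles, (n, n), stride, m.chrom, m.resolution, m.norm_state)


def assemble_tiles(ts: TileSet) -> ContactMatrix:
    """Reassemble a tile set onto its source grid.

    Overlapping coverage is averaged, uncovered positions stay zero, and the
    result is symmetrized by averaging with its transpose (exact for symmetric
    coverage).  A tile extending beyond ``source_shape`` raises ``BoundsError``.
    """
    n = ts.source_shape[0]
    acc = np.zeros((n, n))
    cnt = np.zeros((n, n))
    for t in ts.tiles:
        s = t.values.shape[0]
        if t.row_offset < 0 or t.col_offset < 0 or t.row_offset + s > n or t.col_offset + s > n:
            raise BoundsError(
                f"tile at ({t.row_offset}, {t.col_offset}) size {s} exceeds shape {ts.source_shape}"
            )
        acc[t.row_offset : t.row_offset + s, t.col_offset : t.col_offset + s] += t.values
        cnt[t.row_offset : t.row_offset + s, t.col_offset : t.col_offset + s] += 1.0
    with np.errstate(invalid="ignore"):
        avg = np.where(cnt > 0, acc / np.maximum(cnt, 1), 0.0)
    sym = (avg + avg.T) / 2.0
    sym = np.maximum(sym, 0.0)
    return ContactMatrix(
        chrom=ts.chrom,
        resolution=ts.resolution or 1,
        values=sym,
        norm_state=ts.norm_state,
    )
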