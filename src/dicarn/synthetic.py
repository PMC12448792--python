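"""Synthetic Hi-C and DNase-seq data with the statistical structure the
enhancement method assumes.

The generator emulates the three features a chromosome's contact map shows at
fixed bin size: a power-law distance decay of the expected interaction
frequency, block-wise enrichment inside topologically associating domains
(TADs), and focal loop peaks between anchor pairs.  Counts are drawn Poisson
(or negative-binomial when over-dispersion is requested) around that expected
surface and scaled to a target read depth; the paired low-coverage variant is
produced by binomial read thinning, the same operation applied to real data.
A per-bin accessibility track is derived from the expected contact marginal so
its coupling to structure is known exactly — the property the accessibility-
based imputation is premised on.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .hic_io import ContactMatrix, downsample_reads, write_contact_matrix


@dataclass
class SyntheticSpec:
    """Generation parameters for one synthetic chromosome.

    Defaults describe a 400-bin chromosome at 10 kb resolution with decay
    exponent 1, two-fold TAD enrichment, a handful of loops, 5e6 total reads
    and 1/16 read thinning — a scale at which the full pipeline stays fast
    while every structural feature is present.
    """

    n_bins: int = 400
    bin_size: int = 10_000
    decay_exponent: float = 1.0
    tad_boundaries: tuple[int, ...] = (90, 180, 260, 330)
    tad_enrichment: float = 2.0
    loops: tuple[tuple[int, int, float, float], ...] = (
        (40, 85, 4.0, 2.0),
        (120, 170, 4.0, 2.0),
        (200, 250, 5.0, 2.0),
        (290, 320, 4.0, 2.0),
    )
    read_depth: float = 5e6
    noise_dispersion: float = 0.0
    downsample_ratio: float = 1.0 / 16.0
    seed: int = 0

    def __post_init__(self) -> None:
        b = list(self.tad_boundaries)
        if b != sorted(b) or len(set(b)) != len(b) or (b and (b[0] < 0 or b[-1] > self.n_bins)):
            raise ValidationError("tad_boundaries must be strictly increasing within [0, n_bins]")
        for i, j, s, w in self.loops:
            if not (0 <= i < self.n_bins and 0 <= j < self.n_bins):
                raise ValidationError(f"loop anchor ({i}, {j}) out of bounds")
            if s < 0 or w <= 0:
                raise ValidationError("loop strength must be >= 0 and width > 0")
        if self.read_depth <= 0:
            raise ValidationError("read_depth must be positive")
        if not (0 < self.downsample_ratio <= 1):
            raise ValidationError("downsample_ratio must be in (0, 1]")


def expected_if(spec: SyntheticSpec) -> np.ndarray:
    """Expected interaction-frequency surface, scaled to ``read_depth``.

    ``lambda_ij ∝ (|i-j|+1)^(-decay) * enrichment^[same TAD] *
    (1 + sum of Gaussian loop bumps)``; the full-matrix sum equals
    ``read_depth``.
    """
    n = spec.n_bins
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])
    lam = (dist + 1.0) ** (-spec.decay_exponent)

    tad_id = np.searchsorted(np.asarray(spec.tad_boundaries), idx, side="right")
    same_tad = tad_id[:, None] == tad_id[None, :]
    lam = lam * np.where(same_tad, spec.tad_enrichment, 1.0)

    bumps = np.zeros((n, n))
    for i, j, s, w in spec.loops:
        g = np.exp(-((idx[:, None] - i) ** 2 + (idx[None, :] - j) ** 2) / (2 * w**2))
        bumps += s * (g + g.T)
    lam = lam * (1.0 + bumps)
    lam = (lam + lam.T) / 2.0
    return lam * (spec.read_depth / lam.sum())


def generate_truth_matrix(spec: SyntheticSpec) -> ContactMatrix:
    """Draw the high-coverage count matrix around :func:`expected_if`.

    Poisson counts by default; negative-binomial (gamma-mixed Poisson) when
    ``noise_dispersion > 0``.  Upper triangle is drawn and mirrored, so the
    result is exactly symmetric.  Deterministic given ``spec.seed``.
    """
    lam = expected_if(spec)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_bins
    iu = np.triu_indices(n)
    mu = lam[iu]
    if spec.noise_dispersion > 0:
        # NB as Poisson with gamma-distributed rate: var = mu + dispersion * mu^2
        shape = 1.0 / spec.noise_dispersion
        rate = rng.gamma(shape, mu / shape)
        counts = rng.poisson(rate).astype(float)
    else:
        counts = rng.poisson(mu).astype(float)
    m = np.zeros((n, n))
    m[iu] = counts
    m = m + m.T - np.diag(np.diag(m))
    return ContactMatrix(chrom="synthetic", resolution=spec.bin_size, values=m)


def generate_pair(spec: SyntheticSpec) -> tuple[ContactMatrix, ContactMatrix]:
    """(HR, LR) pair: the truth matrix and its read-thinned counterpart."""
    hr = generate_truth_matrix(spec)
    lr = downsample_reads(hr, spec.downsample_ratio, seed=spec.seed + 1)
    return hr, lr


def generate_dnase_track(spec: SyntheticSpec, coupling: float = 1.0):
    """Per-bin accessibility signal with a known tie to contact structure.

    ``signal = coupling * s + (1 - coupling) * noise`` where ``s`` is the
    expected-IF row marginal rescaled to [0, 1] and ``noise`` is seeded
    uniform noise on [0, 1].  ``coupling = 1`` makes the signal a deterministic
    monotone transform of the contact marginal; ``coupling = 0`` makes it
    independent of structure.  Always non-negative.
    """
    if not (0 <= coupling <= 1):
        raise ValidationError("coupling must be in [0, 1]")
    from .dnase import DNaseTrack

    marg = expected_if(spec).sum(axis=1)
    lo, hi = marg.min(), marg.max()
    s = (marg - lo) / (hi - lo) if hi > lo else np.zeros_like(marg)
    rng = np.random.default_rng(spec.seed + 7)
    noise = rng.uniform(0.0, 1.0, size=spec.n_bins)
    signal = coupling * s + (1.0 - coupling) * noise
    return DNaseTrack(chrom="synthetic", bin_size=spec.bin_size, signal=signal)


# ---------------------------------------------------------------------------
# Fixture suite
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def make_fixture_suite(out_dir, n_bins: int = 400, seed: int = 0,
                       chroms: tuple[str, ...] = ("chrS1", "chrS2", "chrS3"),
                       coupling: float = 1.0) -> dict:
    """Write a small canonical fixture set and return its manifest.

    Three synthetic chromosomes (so train/validation/test splits can be
    pairwise disjoint), each with HR and LR triplet-text matrices, a BED file
    of bins and a bedGraph accessibility track; a plain-text manifest records
    SHA-256 checksums.  Regeneration with the same seed is byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"n_bins": n_bins, "seed": seed, "files": {}}
    base = SyntheticSpec()
    scale = n_bins / base.n_bins  # structural coordinates follow the bin count
    boundaries = tuple(sorted({int(b * scale) for b in base.tad_boundaries if 0 < int(b * scale) < n_bins}))
    loops = tuple(
        (int(i * scale), int(j * scale), s, max(w * scale, 1.0))
        for i, j, s, w in base.loops
        if int(i * scale) < n_bins and int(j * scale) < n_bins
    )
    for ci, chrom in enumerate(chroms):
        spec = SyntheticSpec(n_bins=n_bins, tad_boundaries=boundaries, loops=loops,
                             seed=seed + 100 * ci)
        hr, lr = generate_pair(spec)
        hr = hr.copy_with(chrom=chrom)
        lr = lr.copy_with(chrom=chrom)
        track = generate_dnase_track(spec, coupling=coupling)
        files = {
            f"{chrom}_hr.txt": lambda p, m=hr: write_contact_matrix(m, p),
            f"{chrom}_lr.txt": lambda p, m=lr: write_contact_matrix(m, p),
        }
        for name, writer in files.items():
            writer(out / name)
        bed = out / f"{chrom}_bins.bed"
        with open(bed, "w") as fh:
            for b in range(n_bins):
                fh.write(f"{chrom}\t{b * spec.bin_size}\t{(b + 1) * spec.bin_size}\n")
        bg = out / f"{chrom}_dnase.bedGraph"
        with open(bg, "w") as fh:
            for b, v in enumerate(track.signal):
                fh.write(f"{chrom}\t{b * spec.bin_size}\t{(b + 1) * spec.bin_size}\t{v:.8g}\n")
        for name in [f"{chrom}_hr.txt", f"{chrom}_lr.txt", bed.name, bg.name]:
            manifest["files"][name] = _sha256(out / name)
        manifest[chrom] = {"bin_size": spec.bin_size, "ratio": spec.downsample_ratio,
                           "seed": spec.seed}
    with open(out / "MANIFEST.txt", "w") as fh:
        fh.write(f"# synthetic fixture suite  n_bins={n_bins} seed={seed}\n")
        for name, digest in manifest["files"].items():
            fh.write(f"{digest}  {name}\n")
    return manifest
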