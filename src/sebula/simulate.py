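"""Synthetic singlet/doublet data generation.

Two levels of fixture are produced.  The fast, matrix-level generator draws
binary site-hit profiles for singlet nuclei from a heavy-tailed per-site
rate law modulated by a per-cell depth multiplier, which yields the
right-skewed, Poisson-overdispersed HCLC distributions seen in real
droplet ATAC libraries.  Artificial doublets are then formed, as in
hashing-based benchmarks, by pairing singlets at random and replacing each
pair with one barcode whose profile is the elementwise union of the two.
A slower fragment-level generator writes a toy ``fragments.tsv.gz`` whose
designated loci carry three overlapping fragments, for end-to-end testing
of the preprocessing chain.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse

from .fragments import GenomicInterval, MultiReadSiteMatrix

__all__ = [
    "SimulationConfig",
    "LabeledDataset",
    "simulate_singlet_profiles",
    "make_artificial_doublets",
    "simulate_dataset",
    "simulate_fragments",
]


@dataclass
class SimulationConfig:
    """Generator settings; defaults emulate a permissively cell-called droplet library.

    ``n_cells`` is the final library size: real nuclei (singlets plus
    artificial doublets formed among them) together with a
    ``low_quality_fraction`` of low-quality barcodes (debris and
    ambient-dominated droplets that survive permissive cell calling).
    The default emulates the standard artificial-doublet benchmark, which
    pairs QC-passing cells from a called library, so no junk barcodes are
    included; set ``low_quality_fraction`` > 0 to study truncation
    threshold selection on an unfiltered library.  Site hit rates are
    lognormal (median ``site_rate_median``, log-sd
    ``site_rate_sigma``), giving a heavy-tailed rate spectrum; per-cell
    depth multipliers are lognormal with log-sd ``depth_sigma`` (about a
    25% coefficient of variation by default, typical of real nuclei).
    Mean singlet HCLC under the defaults is roughly 50 with a
    variance/mean ratio near 8, the magnitude seen in droplet snATAC
    libraries after AMULET-style multi-read-locus counting.

    Low-quality barcodes carry depth multiplier
    ``low_quality_depth_scale`` (lognormal spread
    ``low_quality_depth_sigma``).  Because a single HCLC unit requires
    three fragments overlapping one locus, the rate of nonzero HCLC falls
    off roughly as the cube of relative depth, so these barcodes sit
    almost entirely at HCLC zero — the zero-inflated junk pile that
    ``x_min`` truncation exists to remove.  They are never used as
    artificial-doublet constituents: doublet benchmarks pair real cells.
    """

    n_cells: int = 20_000
    n_loci: int = 2_500
    doublet_proportion: float = 0.10
    site_rate_median: float = 0.013
    site_rate_sigma: float = 0.6
    depth_sigma: float = 0.25
    low_quality_fraction: float = 0.0
    low_quality_depth_scale: float = 2e-4
    low_quality_depth_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.doublet_proportion <= 0.5):
            raise ValueError("doublet_proportion must lie in [0, 0.5]")
        if not (0.0 <= self.low_quality_fraction < 1.0):
            raise ValueError("low_quality_fraction must lie in [0, 1)")
        if self.n_cells < 1 or self.n_loci < 1:
            raise ValueError("n_cells and n_loci must be positive")


@dataclass
class LabeledDataset:
    """A simulated multi-read-site matrix with ground-truth labels."""

    matrix: MultiReadSiteMatrix
    is_doublet: np.ndarray  # bool per barcode
    provenance: dict[str, tuple[str, str]] = field(default_factory=dict)
    is_low_quality: np.ndarray | None = None  # bool per barcode; junk barcodes

    @property
    def doublet_fraction(self) -> float:
        return float(np.mean(self.is_doublet))


def _synthetic_loci(n_loci: int) -> list[GenomicInterval]:
    return [GenomicInterval("chrS", 10_000 * i, 10_000 * i + 500) for i in range(n_loci)]


def _barcodes(n: int, prefix: str = "BC") -> list[str]:
    return [f"{prefix}{i:07d}-1" for i in range(n)]


def _profile_matrix(q: np.ndarray, d: np.ndarray, rng: np.random.Generator) -> sparse.csc_matrix:
    """Binary site-hit matrix: site i of cell j hit w.p. min(1, d_j * q_i)."""
    blocks = []
    n = d.size
    chunk = max(1, min(n, 4000))
    for j0 in range(0, n, chunk):
        p = np.minimum(1.0, np.outer(q, d[j0 : j0 + chunk]))
        hits = rng.random(p.shape) < p
        blocks.append(sparse.csc_matrix(hits, dtype=np.int8))
    return sparse.hstack(blocks, format="csc", dtype=np.int8)


def simulate_singlet_profiles(
    config: SimulationConfig, n_cells: int | None = None, rng: np.random.Generator | None = None
) -> MultiReadSiteMatrix:
    """Draw binary singlet site-hit profiles for real (non-junk) nuclei.

    Site i of cell j is hit with probability min(1, d_j * q_i), with q_i
    lognormal across sites and d_j lognormal across cells; hits are
    independent given (d, q).  The resulting HCLC (column sums) is
    right-skewed and overdispersed (variance/mean well above 1.5 under the
    defaults).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = n_cells if n_cells is not None else config.n_cells
    q = config.site_rate_median * np.exp(config.site_rate_sigma * rng.standard_normal(config.n_loci))
    d = np.exp(config.depth_sigma * rng.standard_normal(n))
    mat = _profile_matrix(q, d, rng)

    hclc = np.asarray(mat.sum(axis=0)).ravel()
    if hclc.sum() == 0:
        raise ValueError("simulation produced an all-zero matrix; raise the site rates")
    if np.all(hclc == config.n_loci):
        raise ValueError("simulation produced an all-one matrix; lower the site rates")
    return MultiReadSiteMatrix(_synthetic_loci(config.n_loci), _barcodes(n), mat)


def make_artificial_doublets(
    singlets: MultiReadSiteMatrix,
    proportion: float,
    seed: int | np.random.Generator = 0,
) -> LabeledDataset:
    """Pair singlets at random and replace each pair with its profile union.

    ``proportion`` is the doublet fraction of the FINAL dataset: from n_s
    available singlets, k doublets consume 2k singlets and contribute k
    barcodes, so k solves k = round(proportion * (n_s - k)).  Pairing is
    without replacement; each doublet's profile is the elementwise maximum
    of its constituents and its provenance records both source barcodes.
    """
    if not (0.0 <= proportion <= 0.5):
        raise ValueError("proportion must lie in [0, 0.5]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_s = singlets.n_cells
    k = int(round(proportion * n_s / (1.0 + proportion)))
    if 2 * k > n_s:
        raise ValueError("not enough singlets to form the requested doublet proportion")

    perm = rng.permutation(n_s)
    paired = perm[: 2 * k].reshape(k, 2)
    kept = np.sort(perm[2 * k :])

    mat = singlets.matrix
    if k > 0:
        union = ((mat[:, paired[:, 0]] + mat[:, paired[:, 1]]) > 0).astype(np.int8)
        new_mat = sparse.hstack([mat[:, kept], sparse.csc_matrix(union)], format="csc", dtype=np.int8)
    else:
        new_mat = mat[:, kept]

    src = np.asarray(singlets.barcodes)
    doublet_bcs = [f"DBL{i:07d}-1" for i in range(k)]
    barcodes = [src[i] for i in kept] + doublet_bcs
    is_doublet = np.zeros(len(barcodes), dtype=bool)
    is_doublet[len(kept) :] = True
    provenance = {
        bc: (str(src[a]), str(src[b])) for bc, (a, b) in zip(doublet_bcs, paired)
    }
    msm = MultiReadSiteMatrix(list(singlets.loci), barcodes, new_mat)
    return LabeledDataset(msm, is_doublet, provenance)


def simulate_dataset(config: SimulationConfig) -> LabeledDataset:
    """Generate a labeled dataset of ``config.n_cells`` final barcodes.

    The library is assembled in three parts: good singlets, ``k =
    round(doublet_proportion * n_cells)`` artificial doublets paired among
    the good singlets, and ``round(low_quality_fraction * n_cells)``
    low-quality junk barcodes (almost all HCLC zero) appended last.  The
    true doublet fraction of the final library equals
    ``doublet_proportion`` exactly up to rounding.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    k = int(round(config.doublet_proportion * n))
    n_junk = int(round(config.low_quality_fraction * n))
    n_real = n - n_junk  # good singlets + doublets after pairing
    if n_real - 2 * k < 0:
        raise ValueError("doublet and low-quality fractions leave too few singlets")
    singlets = simulate_singlet_profiles(config, n_cells=n_real + k, rng=rng)
    # express k as a fraction of the real-cell pool so pairing yields k exactly
    real = make_artificial_doublets(singlets, k / n_real if n_real else 0.0, seed=rng)

    if n_junk:
        q = config.site_rate_median * np.exp(
            config.site_rate_sigma * rng.standard_normal(config.n_loci)
        )
        d = config.low_quality_depth_scale * np.exp(
            config.low_quality_depth_sigma * rng.standard_normal(n_junk)
        )
        junk_mat = _profile_matrix(q, d, rng)
        mat = sparse.hstack([real.matrix.matrix, junk_mat], format="csc", dtype=np.int8)
        barcodes = list(real.matrix.barcodes) + _barcodes(n_junk, prefix="LQ")
    else:
        mat = real.matrix.matrix
        barcodes = list(real.matrix.barcodes)

    is_doublet = np.zeros(len(barcodes), dtype=bool)
    is_doublet[: real.is_doublet.size] = real.is_doublet
    is_low_quality = np.zeros(len(barcodes), dtype=bool)
    is_low_quality[real.is_doublet.size :] = True
    msm = MultiReadSiteMatrix(list(real.matrix.loci), barcodes, mat)
    return LabeledDataset(msm, is_doublet, real.provenance, is_low_quality=is_low_quality)


def simulate_fragments(
    out_dir: str | Path,
    n_singlets: int = 100,
    n_loci: int = 40,
    doublet_proportion: float = 0.1,
    locus_rate: float = 0.2,
    seed: int = 0,
) -> tuple[Path, Path, "np.ndarray", "np.ndarray"]:
    """Write a toy fragments.tsv.gz with known per-cell HCLC truth.

    Each singlet activates each of ``n_loci`` candidate loci independently
    with probability ``locus_rate``; an active locus receives three
    staggered overlapping fragments (coverage depth 3 on a core interval),
    so after preprocessing the cell's HCLC equals its number of active
    loci.  Doublets carry the union of two singlets' fragment sets under a
    single barcode.  Returns (fragments path, barcodes path, expected
    HCLC array, doublet-truth array); barcodes and truth are also written
    as ``labels.tsv``.
    """
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    active = rng.random((n_singlets, n_loci)) < locus_rate
    k = int(round(doublet_proportion * n_singlets / (1.0 + doublet_proportion)))
    perm = rng.permutation(n_singlets)
    paired = perm[: 2 * k].reshape(k, 2)
    kept = np.sort(perm[2 * k :])

    profiles = [active[i] for i in kept] + [active[a] | active[b] for a, b in paired]
    barcodes = [f"SIM{i:05d}-1" for i in range(len(profiles))]
    is_doublet = np.zeros(len(profiles), dtype=bool)
    is_doublet[len(kept) :] = True
    expected_hclc = np.array([p.sum() for p in profiles], dtype=np.int64)

    locus_start = 10_000 * (1 + np.arange(n_loci))
    rows: list[tuple[int, str]] = []
    for bc, prof in zip(barcodes, profiles):
        for li in np.flatnonzero(prof):
            p = int(locus_start[li])
            for off in (0, 50, 100):  # depth 3 on [p+100, p+300)
                rows.append((p + off, f"chr1\t{p + off}\t{p + off + 300}\t{bc}\t1\n"))
    rows.sort()

    frag_path = out / "fragments.tsv.gz"
    with gzip.open(frag_path, "wt") as fh:
        fh.write("# synthetic fragment fixture\n")
        for _, line in rows:
            fh.write(line)
    bc_path = out / "barcodes.tsv"
    bc_path.write_text("\n".join(barcodes) + "\n")
    with open(out / "labels.tsv", "w") as fh:
        fh.write("barcode\texpected_hclc\tis_doublet\n")
        for bc, h, d in zip(barcodes, expected_hclc, is_doublet):
            fh.write(f"{bc}\t{h}\t{int(d)}\n")
    return frag_path, bc_path, expected_hclc, is_doublet
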