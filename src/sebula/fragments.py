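"""Fragment-file preprocessing: high-coverage loci and the HCLC statistic.

A droplet ATAC experiment reports, per sequenced fragment, the genomic
interval it covers and the cell barcode it came from (the 10x
``fragments.tsv.gz`` dialect: chrom, start, end, barcode, duplicate count;
BED-style 0-based half-open coordinates).  A *high-coverage locus* for a
cell is a maximal genomic interval covered by more than two of that cell's
fragments; loci from all cells are merged into one non-redundant set per
chromosome, a binary loci x cells matrix records which cells have any
fragment overlapping each merged locus, and the per-cell column sum is the
high-coverage locus count (HCLC).  Multiplets carry more than two copies of
each chromosome and therefore show elevated HCLC.
"""

from __future__ import annotations

import gzip
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "FragmentRecord",
    "GenomicInterval",
    "MultiReadSiteMatrix",
    "DEFAULT_MAX_INSERT",
    "DEFAULT_MIN_DEPTH",
    "default_autosomes",
    "read_fragments",
    "find_high_coverage_loci",
    "merge_loci",
    "build_matrix",
    "fragments_to_matrix",
    "write_matrix_dir",
    "read_hclc_tsv",
    "write_hclc_tsv",
]

DEFAULT_MAX_INSERT = 900
DEFAULT_MIN_DEPTH = 3  # ">2 overlapping fragments"


@dataclass(frozen=True)
class FragmentRecord:
    """One sequenced fragment interval with its cell barcode."""

    chrom: str
    start: int
    end: int
    barcode: str
    dup_count: int = 1

    @property
    def insert_size(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: end must exceed start"
            )


@dataclass
class MultiReadSiteMatrix:
    """Binary multi-read-site matrix (loci x cells) with the derived HCLC.

    ``matrix`` is a scipy sparse CSC matrix of 0/1 indicators; ``hclc[j]``
    is the number of merged high-coverage loci that cell ``j`` overlaps,
    i.e. the column sum.
    """

    loci: list[GenomicInterval]
    barcodes: list[str]
    matrix: sparse.csc_matrix
    hclc: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.matrix = sparse.csc_matrix(self.matrix, dtype=np.int8)
        self.hclc = np.asarray(self.matrix.sum(axis=0)).ravel().astype(np.int64)

    @property
    def n_loci(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]

    def hclc_series(self) -> pd.Series:
        return pd.Series(self.hclc, index=pd.Index(self.barcodes, name="barcode"), name="hclc")


def default_autosomes() -> frozenset[str]:
    """Human autosome names, with and without the ``chr`` prefix."""
    names = [str(i) for i in range(1, 23)]
    return frozenset(names) | frozenset("chr" + n for n in names)


def _open_text(path: str | Path) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def read_fragments(
    path: str | Path,
    barcodes: Iterable[str],
    max_insert: int = DEFAULT_MAX_INSERT,
    autosomes: Iterable[str] | None = None,
) -> Iterator[FragmentRecord]:
    """Stream filtered fragment records from a fragments.tsv(.gz) file.

    Keeps only fragments whose barcode is in ``barcodes``, whose chromosome
    is in the ``autosomes`` whitelist, and whose insert size is strictly
    less than ``max_insert``.  Header/comment lines starting with ``#`` are
    skipped.  Malformed lines raise ``ValueError`` naming the line number.
    """
    allowed = set(barcodes)
    if not allowed:
        raise ValueError("barcode set is empty")
    whitelist = default_autosomes() if autosomes is None else set(autosomes)

    n_yielded = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise ValueError(f"line {lineno}: expected 5 tab-separated columns, got {len(fields)}")
            chrom, start_s, end_s, barcode = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
                dup = int(fields[4]) if len(fields) >= 5 else 1
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer coordinate or count") from exc
            if chrom not in whitelist or barcode not in allowed:
                continue
            if end - start >= max_insert:
                continue
            n_yielded += 1
            yield FragmentRecord(chrom, start, end, barcode, dup)
    if n_yielded == 0:
        warnings.warn("no fragments retained after filtering", stacklevel=2)


def find_high_coverage_loci(
    fragments: Sequence[FragmentRecord] | Sequence[tuple[int, int]],
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> list[tuple[int, int]]:
    """Maximal intervals where fragment coverage depth reaches ``min_depth``.

    Sweep-line over sorted interval endpoints: depth rises by one at each
    fragment start and falls at each end; a locus opens when the running
    depth first reaches ``min_depth`` and closes when it drops below.
    Duplicate-identical fragments each contribute a unit of depth.  All
    fragments are assumed to lie on one chromosome (one cell's fragments).
    """
    if len(fragments) == 0:
        return []
    if isinstance(fragments[0], FragmentRecord):
        ivals = [(f.start, f.end) for f in fragments]  # type: ignore[union-attr]
    else:
        ivals = list(fragments)  # type: ignore[assignment]

    events = np.empty((2 * len(ivals), 2), dtype=np.int64)
    for i, (s, e) in enumerate(ivals):
        events[2 * i] = (s, +1)
        events[2 * i + 1] = (e, -1)
    # starts before ends at equal coordinate so a depth transition at a
    # shared boundary is handled in one step (half-open: end does not cover)
    order = np.lexsort((-events[:, 1], events[:, 0]))
    events = events[order]

    loci: list[tuple[int, int]] = []
    depth = 0
    open_at: int | None = None
    for pos, delta in events:
        new_depth = depth + delta
        if depth < min_depth <= new_depth:
            open_at = int(pos)
        elif new_depth < min_depth <= depth:
            assert open_at is not None
            if pos > open_at:
                if loci and loci[-1][1] == open_at:
                    loci[-1] = (loci[-1][0], int(pos))  # fuse zero-length gap
                else:
                    loci.append((open_at, int(pos)))
            open_at = None
        depth = new_depth
    return loci


def merge_loci(interval_lists: Iterable[Sequence[tuple[int, int]]]) -> list[tuple[int, int]]:
    """Greedy union of overlapping intervals (one chromosome).

    Single pass over start-sorted intervals, growing the current interval
    while successors overlap it.  Intervals touching only at a boundary
    coordinate are half-open-disjoint and stay separate.
    """
    pooled = sorted(iv for lst in interval_lists for iv in lst)
    if not pooled:
        return []
    merged = [pooled[0]]
    for s, e in pooled[1:]:
        cs, ce = merged[-1]
        if s < ce:
            if e > ce:
                merged[-1] = (cs, e)
        else:
            merged.append((s, e))
    return merged


def build_matrix(
    merged_loci: dict[str, Sequence[tuple[int, int]]],
    fragments_by_cell: dict[str, Sequence[FragmentRecord]],
    barcodes: Sequence[str] | None = None,
) -> MultiReadSiteMatrix:
    """Fill the binary loci x cells matrix from merged loci and fragments.

    Entry (i, j) is 1 when cell j has any fragment overlapping merged locus
    i.  Loci overlapped by no cell are dropped.  Overlap uses binary search
    on the start-sorted disjoint loci per chromosome.
    """
    if barcodes is None:
        barcodes = sorted(fragments_by_cell)
    barcodes = list(barcodes)
    col_of = {b: j for j, b in enumerate(barcodes)}

    chroms = sorted(merged_loci)
    locus_rows: list[GenomicInterval] = []
    offsets: dict[str, int] = {}
    starts_by_chrom: dict[str, np.ndarray] = {}
    ends_by_chrom: dict[str, np.ndarray] = {}
    for chrom in chroms:
        ivs = list(merged_loci[chrom])
        offsets[chrom] = len(locus_rows)
        locus_rows.extend(GenomicInterval(chrom, s, e) for s, e in ivs)
        starts_by_chrom[chrom] = np.array([s for s, _ in ivs], dtype=np.int64)
        ends_by_chrom[chrom] = np.array([e for _, e in ivs], dtype=np.int64)

    rows: list[int] = []
    cols: list[int] = []
    for barcode, frags in fragments_by_cell.items():
        j = col_of.get(barcode)
        if j is None:
            continue
        hit: set[int] = set()
        for f in frags:
            starts = starts_by_chrom.get(f.chrom)
            if starts is None or starts.size == 0:
                continue
            ends = ends_by_chrom[f.chrom]
            # loci with locus.start < f.end and locus.end > f.start
            lo = int(np.searchsorted(ends, f.start, side="right"))
            hi = int(np.searchsorted(starts, f.end, side="left"))
            for i in range(lo, hi):
                hit.add(offsets[f.chrom] + i)
        rows.extend(hit)
        cols.extend([j] * len(hit))

    mat = sparse.csc_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(len(locus_rows), len(barcodes)),
    )
    keep = np.asarray(mat.sum(axis=1)).ravel() > 0
    mat = mat[keep]
    kept_loci = [iv for iv, k in zip(locus_rows, keep) if k]
    return MultiReadSiteMatrix(kept_loci, barcodes, mat)


def fragments_to_matrix(
    path: str | Path,
    barcodes: Sequence[str],
    max_insert: int = DEFAULT_MAX_INSERT,
    min_depth: int = DEFAULT_MIN_DEPTH,
    autosomes: Iterable[str] | None = None,
    blacklist: Sequence[GenomicInterval] | None = None,
) -> MultiReadSiteMatrix:
    """Full preprocessing chain: fragments file -> multi-read-site matrix.

    Per (cell, chromosome) group, high-coverage loci are detected by the
    sweep-line; loci are merged per chromosome across cells; the matrix is
    filled against the merged set.  ``blacklist`` intervals, if given,
    remove any merged locus they overlap.
    """
    by_cell: dict[str, list[FragmentRecord]] = {}
    for rec in read_fragments(path, barcodes, max_insert=max_insert, autosomes=autosomes):
        by_cell.setdefault(rec.barcode, []).append(rec)

    per_chrom_lists: dict[str, list[list[tuple[int, int]]]] = {}
    for frags in by_cell.values():
        groups: dict[str, list[tuple[int, int]]] = {}
        for f in frags:
            groups.setdefault(f.chrom, []).append((f.start, f.end))
        for chrom, ivs in groups.items():
            loci = find_high_coverage_loci(ivs, min_depth=min_depth)
            if loci:
                per_chrom_lists.setdefault(chrom, []).append(loci)

    merged = {chrom: merge_loci(lists) for chrom, lists in per_chrom_lists.items()}
    if blacklist:
        by_bl: dict[str, list[tuple[int, int]]] = {}
        for iv in blacklist:
            by_bl.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for chrom, ivs in list(merged.items()):
            bl = by_bl.get(chrom)
            if bl:
                merged[chrom] = [
                    (s, e) for s, e in ivs if not any(s < be and e > bs for bs, be in bl)
                ]
    return build_matrix(merged, by_cell, barcodes=list(barcodes))


def write_matrix_dir(msm: MultiReadSiteMatrix, out_dir: str | Path) -> None:
    """Write MTX + loci BED + barcodes TSV + HCLC TSV into ``out_dir``."""
    from scipy.io import mmwrite

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mmwrite(str(out / "matrix.mtx"), msm.matrix.tocoo())
    with open(out / "loci.bed", "w") as fh:
        for iv in msm.loci:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    with open(out / "barcodes.tsv", "w") as fh:
        fh.write("\n".join(msm.barcodes) + ("\n" if msm.barcodes else ""))
    write_hclc_tsv(msm.hclc_series(), out / "hclc.tsv")


def write_hclc_tsv(hclc: pd.Series, path: str | Path) -> None:
    hclc.rename("hclc").to_csv(path, sep="\t", header=True, index_label="barcode")


def read_hclc_tsv(path: str | Path) -> pd.Series:
    """Read a two-column (barcode, hclc) TSV, with or without a header."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.iloc[0, 1] is not None and not str(df.iloc[0, 1]).lstrip("-").isdigit():
        df = df.iloc[1:]
    s = pd.Series(
        df.iloc[:, 1].astype(np.int64).to_numpy(),
        index=pd.Index(df.iloc[:, 0], name="barcode"),
        name="hclc",
    )
    return s
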