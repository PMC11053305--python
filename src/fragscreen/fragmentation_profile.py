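"""Per-sample short-fragment proportion profiles over genomic bins.

The feature of interest is, for every ~5-Mb bin, the number of cfDNA
fragments of 100–167 nt divided by the number of fragments of all sizes in
that bin.  This normalizes away coverage fluctuation in shallow whole-genome
sequencing without any GC correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .genome_binning import BinSet

logger = logging.getLogger(__name__)

DEFAULT_MAPQ_MIN = 30
DEFAULT_SIZE_LO = 100
DEFAULT_SIZE_HI = 167
#: fragments longer than this are treated as chimeric artifacts and dropped
DEFAULT_MAX_LENGTH = 1000
#: samples with fewer retained fragments fail QC (paper-scale default)
DEFAULT_MIN_FRAGMENTS = 5_000_000


@dataclass(frozen=True)
class FragmentRecord:
    """One sequenced cfDNA fragment (outer coordinates of a read pair)."""

    chrom: str
    start: int
    end: int
    mapq: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ReadStats:
    """Bookkeeping for fragment extraction."""

    n_seen: int = 0
    n_low_mapq: int = 0
    n_degenerate: int = 0
    n_yielded: int = 0


def read_fragments(
    path: str | Path,
    mapq_min: int = DEFAULT_MAPQ_MIN,
    stats: ReadStats | None = None,
) -> Iterator[FragmentRecord]:
    """Stream fragments from a fragment BED or a coordinate-sorted BAM.

    BED columns: chrom, start, end, and optionally name and mapq (BED5
    score column).  A missing mapq column is treated as passing.  For BAM
    input each properly-paired pair yields one fragment from the pair's
    outer coordinates (taken from read 1 with positive template length).
    Fragments with mapq below ``mapq_min`` or non-positive span are dropped
    and counted.
    """
    path = Path(path)
    stats = stats if stats is not None else ReadStats()
    if path.suffix.lower() in {".bam", ".sam", ".cram"}:
        yield from _read_bam(path, mapq_min, stats)
    else:
        yield from _read_bed(path, mapq_min, stats)
    if stats.n_low_mapq or stats.n_degenerate:
        logger.info(
            "%s: %d fragments kept, %d dropped (mapq < %d), %d degenerate",
            path.name, stats.n_yielded, stats.n_low_mapq, mapq_min, stats.n_degenerate,
        )


def _read_bed(path: Path, mapq_min: int, stats: ReadStats) -> Iterator[FragmentRecord]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            mapq = int(fields[4]) if len(fields) >= 5 else 60
            stats.n_seen += 1
            if end - start <= 0:
                stats.n_degenerate += 1
                continue
            if mapq < mapq_min:
                stats.n_low_mapq += 1
                continue
            stats.n_yielded += 1
            yield FragmentRecord(chrom=chrom, start=start, end=end, mapq=mapq)


def _read_bam(path: Path, mapq_min: int, stats: ReadStats) -> Iterator[FragmentRecord]:
    import pysam

    with pysam.AlignmentFile(str(path)) as bam:
        for read in bam:
            if (
                not read.is_proper_pair
                or read.is_secondary
                or read.is_supplementary
                or read.is_unmapped
                or not read.is_read1
            ):
                continue
            stats.n_seen += 1
            tlen = read.template_length
            if tlen <= 0:
                stats.n_degenerate += 1
                continue
            if read.mapping_quality < mapq_min:
                stats.n_low_mapq += 1
                continue
            start = read.reference_start
            stats.n_yielded += 1
            yield FragmentRecord(
                chrom=read.reference_name, start=start, end=start + tlen,
                mapq=read.mapping_quality,
            )


@dataclass
class SampleProfile:
    """Per-bin short and total fragment counts and their ratio for one sample.

    ``proportions`` is NaN for bins with zero total count (missing).
    """

    sample_id: str
    bin_labels: list[str]
    short_counts: np.ndarray
    total_counts: np.ndarray
    qc_pass: bool = True

    def __post_init__(self) -> None:
        self.short_counts = np.asarray(self.short_counts, dtype=np.int64)
        self.total_counts = np.asarray(self.total_counts, dtype=np.int64)
        n = len(self.bin_labels)
        if self.short_counts.shape != (n,) or self.total_counts.shape != (n,):
            raise ValueError("count vectors must match the bin set size")
        if np.any(self.short_counts > self.total_counts):
            raise ValueError("short counts exceed total counts in some bin")

    @property
    def proportions(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.total_counts > 0, self.short_counts / self.total_counts, np.nan
            )

    @property
    def n_fragments_total(self) -> int:
        return int(self.total_counts.sum())


def compute_profile(
    fragments: Iterable[FragmentRecord],
    binset: BinSet,
    sample_id: str = "sample",
    size_lo: int = DEFAULT_SIZE_LO,
    size_hi: int = DEFAULT_SIZE_HI,
    max_length: int = DEFAULT_MAX_LENGTH,
) -> SampleProfile:
    """Count fragments per bin and form short-fragment proportions.

    The short-size window is inclusive on both ends (``size_lo <= L <=
    size_hi``); the total counts every fragment with ``1 <= L <=
    max_length`` whose midpoint falls in a bin.
    """
    if len(binset) == 0:
        raise ValueError("bin set is empty")
    short = np.zeros(len(binset), dtype=np.int64)
    total = np.zeros(len(binset), dtype=np.int64)
    n_any = 0
    # chunked vectorized assignment keeps memory bounded on large streams
    chunk: list[FragmentRecord] = []

    def _flush() -> None:
        nonlocal n_any
        if not chunk:
            return
        chroms = np.array([f.chrom for f in chunk])
        starts = np.array([f.start for f in chunk], dtype=np.int64)
        ends = np.array([f.end for f in chunk], dtype=np.int64)
        lengths = ends - starts
        keep = (lengths >= 1) & (lengths <= max_length)
        idx = binset.lookup_midpoints(chroms[keep], starts[keep], ends[keep])
        inbin = idx >= 0
        np.add.at(total, idx[inbin], 1)
        is_short = (lengths[keep] >= size_lo) & (lengths[keep] <= size_hi)
        np.add.at(short, idx[inbin & is_short], 1)
        n_any += len(chunk)
        chunk.clear()

    for frag in fragments:
        chunk.append(frag)
        if len(chunk) >= 500_000:
            _flush()
    _flush()

    profile = SampleProfile(
        sample_id=sample_id,
        bin_labels=binset.labels,
        short_counts=short,
        total_counts=total,
        qc_pass=n_any > 0,
    )
    if n_any == 0:
        logger.warning("%s: no fragments at all; profile marked qc_pass=False", sample_id)
    return profile


def qc_filter(profile: SampleProfile, min_fragments: int = DEFAULT_MIN_FRAGMENTS) -> bool:
    """Pass iff the sample retains at least ``min_fragments`` fragments.

    Mirrors the exclusion of under-sequenced samples; the threshold is
    configurable (scaled down for reduced-depth simulations).
    """
    profile.qc_pass = profile.n_fragments_total >= min_fragments
    return profile.qc_pass


@dataclass
class ProfileMatrix:
    """Samples x bins matrix of short-fragment proportions."""

    sample_ids: list[str]
    bin_labels: list[str]
    values: np.ndarray
    centered: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.bin_labels)):
            raise ValueError("matrix shape inconsistent with sample/bin labels")

    @classmethod
    def from_profiles(cls, profiles: Sequence[SampleProfile]) -> "ProfileMatrix":
        if not profiles:
            raise ValueError("no profiles")
        labels = profiles[0].bin_labels
        for p in profiles:
            if p.bin_labels != labels:
                raise ValueError(f"profile {p.sample_id} has a different bin set")
        return cls(
            sample_ids=[p.sample_id for p in profiles],
            bin_labels=list(labels),
            values=np.vstack([p.proportions for p in profiles]),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.bin_labels)

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path, centered: bool = False) -> "ProfileMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            sample_ids=[str(s) for s in df.index],
            bin_labels=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
            centered=centered,
        )


def impute_missing(matrix: ProfileMatrix) -> ProfileMatrix:
    """Replace NaN proportions with the sample's mean proportion.

    Neutral under subsequent row-centering; rows with no observed bins at
    all raise, naming the sample.
    """
    values = matrix.values.copy()
    for i, sid in enumerate(matrix.sample_ids):
        row = values[i]
        missing = np.isnan(row)
        if missing.all():
            raise ValueError(f"sample {sid}: all bins missing, cannot impute")
        if missing.any():
            row[missing] = np.nanmean(row)
    return replace(matrix, values=values)


def center_rows(matrix: ProfileMatrix) -> ProfileMatrix:
    """Subtract each sample's mean proportion from its row (visualization
    normalization); idempotent up to floating-point error."""
    values = matrix.values
    if np.isnan(values).any():
        bad = [s for s, row in zip(matrix.sample_ids, values) if np.isnan(row).any()]
        raise ValueError(f"missing values present (impute first): samples {bad[:5]}")
    centered = values - values.mean(axis=1, keepdims=True)
    return replace(matrix, values=centered, centered=True)


def case_control_ratio(matrix: ProfileMatrix, labels: Sequence[int | bool]) -> np.ndarray:
    """Per-bin ratio of mean case proportion to mean control proportion.

    Computed on uncentered proportions.  Bins whose control mean is zero
    get NaN with a warning.
    """
    if matrix.centered:
        raise ValueError("case/control ratios are defined on uncentered proportions")
    y = np.asarray(labels, dtype=bool)
    if len(y) != len(matrix.sample_ids):
        raise ValueError("label vector length mismatch")
    if y.all() or not y.any():
        raise ValueError("both cases and controls are required")
    case_mean = np.nanmean(matrix.values[y], axis=0)
    ctrl_mean = np.nanmean(matrix.values[~y], axis=0)
    zero = ctrl_mean == 0
    if zero.any():
        logger.warning("%d bins have zero control mean; ratio set to NaN", int(zero.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(zero, np.nan, case_mean / ctrl_mean)
    return ratio


@dataclass
class ClusterResult:
    """Hierarchical clustering of samples on centered profiles."""

    order: list[str]
    linkage: np.ndarray
    two_group_labels: np.ndarray


def cluster_samples(
    matrix: ProfileMatrix, method: str = "ward", metric: str = "euclidean"
) -> ClusterResult:
    """Agglomerative clustering of samples (Ward / Euclidean by default).

    Operates on row-centered values (centers internally if needed) and
    returns the dendrogram leaf order plus a two-group cut for concordance
    assessment against case/control labels.
    """
    if len(matrix.sample_ids) < 2:
        raise ValueError("clustering requires at least 2 samples")
    centered = matrix if matrix.centered else center_rows(impute_missing(matrix))
    dist = pdist(centered.values, metric=metric)
    Z = hierarchy.linkage(dist, method=method)
    leaves = hierarchy.leaves_list(Z)
    two = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    return ClusterResult(
        order=[matrix.sample_ids[i] for i in leaves],
        linkage=Z,
        two_group_labels=two,
    )
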