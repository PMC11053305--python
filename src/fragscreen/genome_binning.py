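"""Genome bin scheme: 100-kb source bins merged into ~5-Mb analysis windows.

Analysis windows never cross a chromosome-arm boundary and carry labels of
the form ``<arm>_<index>`` where the index is a single global sequential
number over the genome-sorted windows (``1q_1`` ... ``22q_504`` style).
Coordinates are 0-based, half-open throughout, as in BED.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: number of 100-kb source bins merged into one full analysis window
DEFAULT_TARGET_SPAN = 5_000_000
DEFAULT_SOURCE_SPAN = 100_000


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Order chromosomes numerically where possible (chr1 < chr2 < chr10)."""
    c = chrom.removeprefix("chr")
    return (int(c), "") if c.isdigit() else (10**6, c)


@dataclass(frozen=True)
class SourceBin:
    """One 100-kb (or other fixed-span) source bin with its arm annotation."""

    chrom: str
    start: int
    end: int
    arm: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"source bin {self.chrom}:{self.start}-{self.end} has non-positive span"
            )


@dataclass(frozen=True)
class GenomicBin:
    """A merged analysis window.

    Attributes
    ----------
    chrom, start, end
        Genomic interval (0-based, half-open).
    arm
        Chromosome arm, e.g. ``"12q"``; all constituent source bins share it.
    label
        ``<arm>_<global sequential index>``, e.g. ``"12q_370"``.
    n_source_bins
        Number of constituent source bins.
    """

    chrom: str
    start: int
    end: int
    arm: str
    label: str
    n_source_bins: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"bin {self.label}: start must be < end")
        if self.n_source_bins < 1:
            raise ValueError(f"bin {self.label}: needs at least one source bin")

    @property
    def span(self) -> int:
        return self.end - self.start

    def midpoint_contains(self, frag_start: int, frag_end: int) -> bool:
        mid = (frag_start + frag_end) // 2
        return self.start <= mid < self.end


@dataclass
class BinSet:
    """Ordered, non-overlapping collection of analysis windows.

    Provides O(log n) fragment-midpoint lookup via per-chromosome sorted
    interval arrays.
    """

    bins: list[GenomicBin]
    genome_build: str = "synthetic"
    _index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        init=False, repr=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        self._validate()
        self._build_index()

    def _validate(self) -> None:
        labels = [b.label for b in self.bins]
        if len(set(labels)) != len(labels):
            raise ValueError("bin labels are not unique")
        by_chrom: dict[str, list[GenomicBin]] = {}
        for b in self.bins:
            by_chrom.setdefault(b.chrom, []).append(b)
        for chrom, bl in by_chrom.items():
            for a, b in zip(bl, bl[1:]):
                if a.end > b.start:
                    raise ValueError(f"bins overlap or are unsorted on {chrom}: {a.label}, {b.label}")

    def _build_index(self) -> None:
        by_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for i, b in enumerate(self.bins):
            by_chrom.setdefault(b.chrom, []).append((b.start, b.end, i))
        for chrom, triples in by_chrom.items():
            starts = np.array([t[0] for t in triples], dtype=np.int64)
            ends = np.array([t[1] for t in triples], dtype=np.int64)
            idx = np.array([t[2] for t in triples], dtype=np.int64)
            self._index[chrom] = (starts, ends, idx)

    def __len__(self) -> int:
        return len(self.bins)

    def __iter__(self):
        return iter(self.bins)

    @property
    def labels(self) -> list[str]:
        return [b.label for b in self.bins]

    def lookup_midpoint(self, chrom: str, start: int, end: int) -> int | None:
        """Index of the bin containing the fragment midpoint, or None."""
        entry = self._index.get(chrom)
        if entry is None:
            return None
        starts, ends, idx = entry
        mid = (start + end) // 2
        j = int(np.searchsorted(starts, mid, side="right")) - 1
        if j < 0 or mid >= ends[j]:
            return None
        return int(idx[j])

    def lookup_midpoints(
        self, chroms: Sequence[str], starts: Sequence[int], ends: Sequence[int]
    ) -> np.ndarray:
        """Vectorized midpoint lookup; -1 marks fragments outside all bins."""
        chroms = np.asarray(chroms)
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        mids = (starts + ends) // 2
        out = np.full(len(mids), -1, dtype=np.int64)
        for chrom in np.unique(chroms):
            entry = self._index.get(str(chrom))
            if entry is None:
                continue
            bstarts, bends, idx = entry
            mask = chroms == chrom
            j = np.searchsorted(bstarts, mids[mask], side="right") - 1
            ok = (j >= 0) & (mids[mask] < bends[np.clip(j, 0, None)])
            sel = np.where(mask)[0]
            out[sel[ok]] = idx[j[ok]]
        return out

    def to_manifest(self) -> pd.DataFrame:
        """Bin manifest: label, chrom, start, end, arm, n_source_bins."""
        return pd.DataFrame(
            {
                "label": [b.label for b in self.bins],
                "chrom": [b.chrom for b in self.bins],
                "start": [b.start for b in self.bins],
                "end": [b.end for b in self.bins],
                "arm": [b.arm for b in self.bins],
                "n_source_bins": [b.n_source_bins for b in self.bins],
            }
        )

    def write_manifest(self, path: str | Path) -> None:
        self.to_manifest().to_csv(path, sep="\t", index=False)

    def write_bed(self, path: str | Path) -> None:
        """BED4: chrom, start, end, label."""
        self.to_manifest()[["chrom", "start", "end", "label"]].to_csv(
            path, sep="\t", index=False, header=False
        )

    @classmethod
    def from_manifest(cls, path: str | Path, genome_build: str = "synthetic") -> "BinSet":
        df = pd.read_csv(path, sep="\t")
        required = {"label", "chrom", "start", "end", "arm", "n_source_bins"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
        bins = [
            GenomicBin(
                chrom=str(r.chrom),
                start=int(r.start),
                end=int(r.end),
                arm=str(r.arm),
                label=str(r.label),
                n_source_bins=int(r.n_source_bins),
            )
            for r in df.itertuples()
        ]
        bins.sort(key=lambda b: (_chrom_sort_key(b.chrom), b.start))
        return cls(bins=bins, genome_build=genome_build)


def load_source_bins(path: str | Path) -> list[SourceBin]:
    """Load annotated 100-kb source bins from a BED4+ file.

    Columns: chrom, start, end, arm (tab- or whitespace-separated, no
    header). Records are sorted by genomic coordinate; overlaps raise.
    """
    path = Path(path)
    bins: list[SourceBin] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(
                    f"{path}:{lineno}: expected at least 4 columns (chrom start end arm), got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            bins.append(SourceBin(chrom=fields[0], start=start, end=end, arm=fields[3]))
    bins.sort(key=lambda b: (_chrom_sort_key(b.chrom), b.start))
    for a, b in zip(bins, bins[1:]):
        if a.chrom == b.chrom and a.end > b.start:
            raise ValueError(
                f"overlapping source bins: {a.chrom}:{a.start}-{a.end} and {b.chrom}:{b.start}-{b.end}"
            )
    arms = sorted({b.arm for b in bins})
    logger.info("loaded %d source bins on %d arms from %s", len(bins), len(arms), path)
    return bins


def filter_excluded(
    source_bins: Sequence[SourceBin],
    exclusion: Iterable[tuple[str, int, int]],
    max_overlap_fraction: float = 0.5,
) -> list[SourceBin]:
    """Drop source bins overlapping an exclusion region by more than the
    given fraction of the bin span (blacklist / low-mappability regions)."""
    excl: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in exclusion:
        excl.setdefault(chrom, []).append((s, e))
    kept: list[SourceBin] = []
    for b in source_bins:
        overlap = 0
        for s, e in excl.get(b.chrom, ()):
            overlap += max(0, min(b.end, e) - max(b.start, s))
        if overlap <= max_overlap_fraction * (b.end - b.start):
            kept.append(b)
    dropped = len(source_bins) - len(kept)
    if dropped:
        logger.info("exclusion filter dropped %d of %d source bins", dropped, len(source_bins))
    return kept


def merge_to_windows(
    source_bins: Sequence[SourceBin],
    target_span: int = DEFAULT_TARGET_SPAN,
    source_span: int = DEFAULT_SOURCE_SPAN,
    genome_build: str = "synthetic",
) -> BinSet:
    """Merge consecutive same-arm source bins into ~`target_span` windows.

    Within each arm, runs of consecutive source bins are grouped greedily
    into windows of ``target_span // source_span`` bins.  A trailing group
    with at least half that count becomes its own window; a smaller trailing
    group is merged into the previous window (or kept alone if the arm has
    no previous window).  Windows never cross an arm boundary; labels are
    assigned in genomic order with a single global sequential index.
    """
    if not source_bins:
        raise ValueError("no source bins to merge")
    per_window = max(1, target_span // source_span)
    min_trailing = max(1, per_window // 2)

    ordered = sorted(source_bins, key=lambda b: (_chrom_sort_key(b.chrom), b.start))
    # contiguous runs share chrom and arm; order within an arm is positional
    arm_runs: list[list[SourceBin]] = []
    for b in ordered:
        if arm_runs and arm_runs[-1][-1].chrom == b.chrom and arm_runs[-1][-1].arm == b.arm:
            arm_runs[-1].append(b)
        else:
            arm_runs.append([b])

    windows: list[list[SourceBin]] = []
    for run in arm_runs:
        groups = [run[i : i + per_window] for i in range(0, len(run), per_window)]
        if len(groups) > 1 and len(groups[-1]) < min_trailing:
            tail = groups.pop()
            groups[-1].extend(tail)
        windows.extend(groups)

    bins = [
        GenomicBin(
            chrom=grp[0].chrom,
            start=grp[0].start,
            end=grp[-1].end,
            arm=grp[0].arm,
            label=f"{grp[0].arm}_{i}",
            n_source_bins=len(grp),
        )
        for i, grp in enumerate(windows, start=1)
    ]
    logger.info("merged %d source bins into %d windows", len(ordered), len(bins))
    return BinSet(bins=bins, genome_build=genome_build)


def assign_bin(chrom: str, start: int, end: int, binset: BinSet) -> str | None:
    """Label of the window containing the fragment midpoint, or None.

    Midpoint assignment with half-open intervals: a midpoint exactly at a
    window start belongs to that window.  Fragments on chromosomes absent
    from the bin set return None.
    """
    idx = binset.lookup_midpoint(chrom, start, end)
    return None if idx is None else binset.bins[idx].label
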