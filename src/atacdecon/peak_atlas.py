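"""Peak-call input, filtering, and non-redundant atlas construction.

Reference samples arrive as per-sample peak calls (ENCODE narrowPeak or
BED). Before any quantification the calls are cleaned — weak peaks and
blacklisted regions removed — and collapsed into one non-redundant,
coordinate-sorted atlas shared by every reference sample. Redundancy is
resolved greedily by peak significance: the most significant peak wins its
locus and every overlapping call is discarded.

All coordinates are BED-style 0-based half-open; "overlap" means at least
one shared base pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "PeakInterval",
    "PeakAtlas",
    "PeakFormatError",
    "read_peak_files",
    "filter_weak_and_blacklisted",
    "merge_nonredundant",
    "write_atlas_bed",
]


class PeakFormatError(ValueError):
    """A peak file line could not be parsed into a valid interval."""


@dataclass(frozen=True, order=True)
class PeakInterval:
    """One open-chromatin region with a significance score.

    ``score`` is -log10(q) of the peak call (MACS2 column 9 in narrowPeak).
    Coordinates are 0-based half-open.
    """

    chrom: str
    start: int
    end: int
    score: float = 0.0
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise PeakFormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.score < 0:
            raise PeakFormatError(f"negative score {self.score} for {self.chrom}:{self.start}")

    def overlaps(self, other: "PeakInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    @property
    def peak_id(self) -> str:
        return f"{self.chrom}_{self.start}_{self.end}"


@dataclass
class PeakAtlas:
    """A coordinate-sorted, mutually non-overlapping list of peaks."""

    peaks: list[PeakInterval]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: (p.chrom, p.start, p.end))
        for a, b in zip(self.peaks, self.peaks[1:]):
            if a.overlaps(b):
                raise ValueError(f"atlas peaks overlap: {a.peak_id} / {b.peak_id}")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def feature_ids(self) -> list[str]:
        return [p.peak_id for p in self.peaks]


def _parse_line(
    line: str, fmt: str, score_col: int, fileno: str, lineno: int, sample_id: str
) -> PeakInterval | None:
    line = line.rstrip("\n")
    if not line or line.startswith(("#", "track", "browser")):
        return None
    fields = line.split("\t")
    if len(fields) == 1:  # tolerate space-delimited files
        fields = line.split()
    min_cols = 10 if fmt == "narrowPeak" else max(3, score_col + 1)
    if len(fields) < min_cols:
        raise PeakFormatError(
            f"{fileno}:{lineno}: expected >= {min_cols} columns, got {len(fields)}"
        )
    try:
        start, end = int(fields[1]), int(fields[2])
        score = float(fields[score_col])
    except ValueError as exc:
        raise PeakFormatError(f"{fileno}:{lineno}: {exc}") from None
    try:
        return PeakInterval(fields[0], start, end, score=score, sample_id=sample_id)
    except PeakFormatError as exc:
        raise PeakFormatError(f"{fileno}:{lineno}: {exc}") from None


def read_peak_files(
    paths: Sequence[str | Path],
    format: str = "narrowPeak",
    score_col: int | None = None,
) -> list[PeakInterval]:
    """Read peak calls from narrowPeak or BED files.

    Parameters
    ----------
    paths
        Files to read; each file's stem becomes its ``sample_id``.
    format
        ``"narrowPeak"`` (10-column BED6+4; -log10 q in column 9, index 8)
        or ``"bed6+"`` (score taken from ``score_col``, default column 5,
        index 4).
    score_col
        0-based column index holding -log10(q); overrides the format default.

    Raises
    ------
    PeakFormatError
        On an unparseable coordinate, negative-length interval or negative
        score; the message names the file and line.
    """
    if format not in ("narrowPeak", "bed6+"):
        raise ValueError(f"unknown peak format: {format!r}")
    col = score_col if score_col is not None else (8 if format == "narrowPeak" else 4)
    peaks: list[PeakInterval] = []
    for path in paths:
        path = Path(path)
        sample_id = path.stem.removesuffix(".narrowPeak")
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                rec = _parse_line(line, format, col, str(path), lineno, sample_id)
                if rec is not None:
                    peaks.append(rec)
    return peaks


def _sorted_by_chrom(intervals: Iterable[PeakInterval]) -> dict[str, list[PeakInterval]]:
    by_chrom: dict[str, list[PeakInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for lst in by_chrom.values():
        lst.sort(key=lambda p: (p.start, p.end))
    return by_chrom


def _overlaps_any(peak: PeakInterval, sorted_intervals: list[PeakInterval]) -> bool:
    # binary search over start-sorted intervals on the same chromosome
    import bisect

    starts = [iv.start for iv in sorted_intervals]
    idx = bisect.bisect_right(starts, peak.end - 1)
    for iv in sorted_intervals[:idx][::-1]:
        if iv.end > peak.start:
            return True
        # intervals are not guaranteed non-overlapping, so we cannot stop
        # at the first non-hit unless ends are monotone; scan is bounded in
        # practice because blacklists are short
    return False


def filter_weak_and_blacklisted(
    peaks: Sequence[PeakInterval],
    min_neg_log_q: float = 2.0,
    blacklist: Sequence[PeakInterval] = (),
) -> list[PeakInterval]:
    """Drop weak peaks (score <= ``min_neg_log_q``) and blacklist hits.

    A peak survives only if its -log10(q) is strictly greater than the
    threshold and it shares no base pair with any blacklist interval.
    """
    if min_neg_log_q < 0:
        raise ValueError("min_neg_log_q must be >= 0")
    strong = [p for p in peaks if p.score > min_neg_log_q]
    if not blacklist:
        return strong
    bl_by_chrom = _sorted_by_chrom(blacklist)
    kept = []
    for p in strong:
        bl = bl_by_chrom.get(p.chrom)
        if bl is None or not _overlaps_any(p, bl):
            kept.append(p)
    return kept


def merge_nonredundant(peaks: Sequence[PeakInterval]) -> PeakAtlas:
    """Collapse overlapping peak calls into a non-redundant atlas.

    Greedy score-ranked selection: peaks are ranked by score descending
    (ties broken by chromosome, then start, ascending); the top peak is
    kept and every remaining peak overlapping it is discarded, iterating
    until no peaks remain. The result is sorted by coordinate and pairwise
    non-overlapping, and the operation is idempotent.
    """
    ranked = sorted(peaks, key=lambda p: (-p.score, p.chrom, p.start, p.end))
    kept_by_chrom: dict[str, list[tuple[int, int]]] = {}
    kept: list[PeakInterval] = []
    for p in ranked:
        spans = kept_by_chrom.setdefault(p.chrom, [])
        if any(p.start < e and s < p.end for s, e in spans):
            continue
        spans.append((p.start, p.end))
        kept.append(p)
    provenance = sorted({p.sample_id for p in kept if p.sample_id})
    return PeakAtlas(peaks=kept, provenance=provenance)


def write_atlas_bed(atlas: PeakAtlas, path: str | Path) -> None:
    """Write the atlas as BED4: chrom, start, end, peak_id."""
    with open(path, "w") as fh:
        for p in atlas:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\n")
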