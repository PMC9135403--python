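"""Regulatory-element ranking and classification from chromatin signal.

Accessible sites (ATAC peaks) are ranked by the ratio of H3K4me1 to
H3K4me3 ChIP signal averaged over a 2-kb window centred on the peak
midpoint: high ratios mark enhancer-like elements, low ratios
promoter-like ones.  Peaks in the bottom fraction (default 5%) of either
mark are excluded before ranking.  Independently, promoters are defined
as annotated promoters falling within broad H3K27ac domains, and
enhancers as ATAC peaks overlapping p300 peaks minus anything overlapping
those promoters.

All coordinates are 0-based half-open (BED convention); signal tracks are
stepwise-constant coverage (bedGraph, values in normalised signal per
million reads), with uncovered bases contributing 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import rankdata

__all__ = [
    "GenomicInterval",
    "SignalTrack",
    "RankedPeak",
    "PeakClassSpec",
    "SyntheticTrackSpec",
    "window_around_midpoint",
    "mean_signal",
    "filter_bottom_fraction",
    "rank_by_ratio",
    "rank_statement",
    "classify_elements",
    "generate_tracks",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
]

DEFAULT_WINDOW = 2000
DEFAULT_BOTTOM_FRACTION = 0.05
#: pseudocount added to both marks before taking the ratio; 1.0 matches
#: the default of standard coverage-comparison utilities
DEFAULT_PSEUDOCOUNT = 1.0


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class SignalTrack:
    """Stepwise-constant coverage: per-chromosome sorted, non-overlapping
    (start, end, value) segments; uncovered bases have value 0."""

    def __init__(self, segments: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._segs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in segments.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(ends <= starts):
                raise ValueError(f"{chrom}: segment with end <= start")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"{chrom}: overlapping segments")
            if np.any(values < 0):
                raise ValueError(f"{chrom}: negative signal values")
            self._segs[chrom] = (starts, ends, values)

    @classmethod
    def empty(cls) -> "SignalTrack":
        return cls({})

    def chromosomes(self) -> list[str]:
        return sorted(self._segs)

    def mean(self, interval: GenomicInterval) -> float:
        """Length-weighted mean signal over ``interval`` (uncovered = 0)."""
        if interval.length <= 0:
            raise ValueError("zero-length window")
        segs = self._segs.get(interval.chrom)
        if segs is None:
            return 0.0
        starts, ends, values = segs
        lo = np.searchsorted(ends, interval.start, side="right")
        hi = np.searchsorted(starts, interval.end, side="left")
        if lo >= hi:
            return 0.0
        ov = (
            np.minimum(ends[lo:hi], interval.end)
            - np.maximum(starts[lo:hi], interval.start)
        ).clip(min=0)
        return float((ov * values[lo:hi]).sum() / interval.length)


@dataclass(frozen=True)
class RankedPeak:
    """A peak with its windowed mark means, pseudocounted ratio and
    percentile from the top (rank 1 = highest ratio, percentile = 100*rank/N;
    small percentile = enhancer-like)."""

    interval: GenomicInterval
    mean_me1: float
    mean_me3: float
    ratio: float
    percentile: float


def window_around_midpoint(
    interval: GenomicInterval, width: int = DEFAULT_WINDOW
) -> GenomicInterval:
    """Fixed-width window centred on the peak midpoint, clipped at 0."""
    if width <= 0 or width % 2:
        raise ValueError("window width must be positive and even")
    m = interval.midpoint
    half = width // 2
    return GenomicInterval(
        chrom=interval.chrom,
        start=max(m - half, 0),
        end=m + half,
        name=interval.name,
    )


def mean_signal(track: SignalTrack, interval: GenomicInterval) -> float:
    """Average signal over ``interval`` (see :meth:`SignalTrack.mean`)."""
    return track.mean(interval)


def filter_bottom_fraction(
    peaks: Sequence[GenomicInterval],
    me1_means: Sequence[float],
    me3_means: Sequence[float],
    frac: float = DEFAULT_BOTTOM_FRACTION,
) -> tuple[list[GenomicInterval], np.ndarray]:
    """Drop peaks in the bottom ``frac`` quantile of either mark.

    Exclusion is strict (< the linear-interpolation quantile), so fully
    tied inputs lose nothing.  Returns (retained peaks, keep mask).
    """
    if not (0.0 <= frac < 1.0):
        raise ValueError("frac must lie in [0, 1)")
    me1 = np.asarray(me1_means, dtype=np.float64)
    me3 = np.asarray(me3_means, dtype=np.float64)
    if not (len(peaks) == len(me1) == len(me3)):
        raise ValueError("peaks and mean arrays must have equal length")
    if len(peaks) == 0 or frac == 0.0:
        return list(peaks), np.ones(len(peaks), dtype=bool)
    q1 = np.quantile(me1, frac)
    q3 = np.quantile(me3, frac)
    keep = ~((me1 < q1) | (me3 < q3))
    return [p for p, k in zip(peaks, keep) if k], keep


def rank_by_ratio(
    peaks: Sequence[GenomicInterval],
    me1_means: Sequence[float],
    me3_means: Sequence[float],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[RankedPeak]:
    """Rank peaks by pseudocounted me1:me3 ratio, highest first.

    ratio = (mean_me1 + eps) / (mean_me3 + eps).  Ties receive their
    average rank; percentile = 100 * rank / N with rank 1 = highest ratio,
    so percentile <= X reads "top X%".  With ``pseudocount=0`` the raw
    ratio is used and zero-me3 peaks get an infinite ratio (ranked first).
    """
    me1 = np.asarray(me1_means, dtype=np.float64)
    me3 = np.asarray(me3_means, dtype=np.float64)
    if np.any(me1 < 0) or np.any(me3 < 0):
        raise ValueError("mark means must be non-negative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    with np.errstate(divide="ignore"):
        ratio = (me1 + pseudocount) / (me3 + pseudocount)
    n = len(peaks)
    if n == 0:
        return []
    ranks = rankdata(-ratio, method="average")
    percentile = 100.0 * ranks / n
    order = np.argsort(ranks, kind="stable")
    return [
        RankedPeak(
            interval=peaks[i],
            mean_me1=float(me1[i]),
            mean_me3=float(me3[i]),
            ratio=float(ratio[i]),
            percentile=float(percentile[i]),
        )
        for i in order
    ]


def rank_statement(peak: RankedPeak, n: int) -> str:
    """Human-readable placement, e.g. ``"top 32%"`` or ``"bottom 21%"``.

    Elements in the upper half are reported from the top (ceiling of the
    percentile), the rest from the bottom.
    """
    if peak.percentile <= 50.0:
        return f"top {math.ceil(peak.percentile)}%"
    from_bottom = 100.0 - peak.percentile + 100.0 / n
    return f"bottom {math.ceil(from_bottom)}%"


# ---------------------------------------------------------------------------
# Promoter / enhancer set definitions
# ---------------------------------------------------------------------------

def _build_trees(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def _overlaps_any(iv: GenomicInterval, trees: dict[str, IntervalTree]) -> bool:
    tree = trees.get(iv.chrom)
    return bool(tree is not None and tree.overlap(iv.start, iv.end))


def classify_elements(
    atac_peaks: Sequence[GenomicInterval],
    p300_peaks: Sequence[GenomicInterval],
    annotated_promoters: Sequence[GenomicInterval],
    k27ac_broad_domains: Sequence[GenomicInterval],
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Define active promoters and enhancers by set arithmetic (>= 1 bp
    overlap, half-open coordinates).

    promoters  = annotated promoters overlapping any broad H3K27ac domain
    enhancers  = ATAC peaks overlapping any p300 peak, minus ATAC peaks
                 overlapping an active promoter

    The returned sets are disjoint (no enhancer overlaps a promoter) and
    are subsets of their respective inputs.
    """
    domain_trees = _build_trees(k27ac_broad_domains)
    promoters = [p for p in annotated_promoters if _overlaps_any(p, domain_trees)]
    p300_trees = _build_trees(p300_peaks)
    promoter_trees = _build_trees(promoters)
    enhancers = [
        a
        for a in atac_peaks
        if _overlaps_any(a, p300_trees) and not _overlaps_any(a, promoter_trees)
    ]
    return promoters, enhancers


# ---------------------------------------------------------------------------
# Synthetic track generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakClassSpec:
    """Designed signal levels (SPMR) for one element class.

    Per-peak me1/me3 levels are log-normal around the geometric means
    given here; the defaults put enhancer-like peaks at me1 >> me3 and
    promoter-like peaks at the reverse, so their pseudocounted ratios have
    essentially non-overlapping supports.
    """

    n_peaks: int
    me1_geometric_mean: float
    me3_geometric_mean: float
    log_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.n_peaks < 0:
            raise ValueError("n_peaks must be >= 0")
        if self.me1_geometric_mean < 0 or self.me3_geometric_mean < 0:
            raise ValueError("signal levels must be non-negative")
        if self.log_sd < 0:
            raise ValueError("log_sd must be >= 0")


@dataclass(frozen=True)
class SyntheticTrackSpec:
    """Layout of a synthetic chromosome of classed peaks."""

    classes: Mapping[str, PeakClassSpec] = field(
        default_factory=lambda: {
            "enhancer": PeakClassSpec(250, me1_geometric_mean=8.0, me3_geometric_mean=1.0),
            "promoter": PeakClassSpec(250, me1_geometric_mean=1.0, me3_geometric_mean=8.0),
        }
    )
    chrom: str = "chrS"
    peak_width: int = 400
    spacing: int = 5000
    signal_width: int = DEFAULT_WINDOW
    segments_per_peak: int = 4
    segment_noise_sd: float = 0.1


def generate_tracks(
    spec: SyntheticTrackSpec | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> tuple[SignalTrack, SignalTrack, list[GenomicInterval]]:
    """Generate designed me1/me3 tracks and classed peaks.

    Peaks are laid out evenly along a synthetic chromosome, classes
    interleaved; each peak's marks are constant-plateau signal (split into
    a few noisy sub-segments) across the ranking window centred on its
    midpoint, at per-peak log-normal levels from its class spec.  The BED
    name field carries ``<class>_<i>``.  Returns (me1 track, me3 track,
    peaks); if ``outdir`` is given, also writes ``me1.bedGraph``,
    ``me3.bedGraph`` and ``peaks.bed``.
    """
    spec = spec or SyntheticTrackSpec()
    rng = np.random.default_rng(seed)
    labels = [
        (cls, i) for cls, cs in spec.classes.items() for i in range(cs.n_peaks)
    ]
    # interleave classes along the chromosome so rank order is not positional
    labels = [labels[i] for i in rng.permutation(len(labels))]
    peaks: list[GenomicInterval] = []
    me1_segs: list[tuple[int, int, float]] = []
    me3_segs: list[tuple[int, int, float]] = []
    half_peak = spec.peak_width // 2
    half_sig = spec.signal_width // 2
    for k, (cls, i) in enumerate(labels):
        cs = spec.classes[cls]
        mid = half_sig + k * spec.spacing
        peaks.append(
            GenomicInterval(
                spec.chrom, mid - half_peak, mid + half_peak, name=f"{cls}_{i}"
            )
        )
        level1 = cs.me1_geometric_mean * math.exp(rng.normal(0.0, cs.log_sd))
        level3 = cs.me3_geometric_mean * math.exp(rng.normal(0.0, cs.log_sd))
        bounds = np.linspace(
            mid - half_sig, mid + half_sig, spec.segments_per_peak + 1
        ).astype(int)
        for s, e in zip(bounds[:-1], bounds[1:]):
            me1_segs.append(
                (int(s), int(e), level1 * math.exp(rng.normal(0.0, spec.segment_noise_sd)))
            )
            me3_segs.append(
                (int(s), int(e), level3 * math.exp(rng.normal(0.0, spec.segment_noise_sd)))
            )

    def _to_track(segs: list[tuple[int, int, float]]) -> SignalTrack:
        if not segs:
            return SignalTrack.empty()
        arr = np.array(segs, dtype=np.float64)
        return SignalTrack(
            {spec.chrom: (arr[:, 0].astype(np.int64), arr[:, 1].astype(np.int64), arr[:, 2])}
        )

    me1, me3 = _to_track(me1_segs), _to_track(me3_segs)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_bedgraph(me1, outdir / "me1.bedGraph")
        write_bedgraph(me3, outdir / "me3.bedGraph")
        write_bed(peaks, outdir / "peaks.bed")
    return me1, me3, peaks


# ---------------------------------------------------------------------------
# BED / bedGraph I/O (plain 3-4 column text)
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED4+ intervals (extra columns ignored)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            name = fields[3] if len(fields) > 3 else ""
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2]), name))
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\n")


def read_bedgraph(path: str | Path) -> SignalTrack:
    """Read a 4-column bedGraph into a :class:`SignalTrack`."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    df = df[~df["chrom"].str.startswith(("track", "browser"))]
    segs = {
        str(chrom): (
            g["start"].to_numpy(np.int64),
            g["end"].to_numpy(np.int64),
            g["value"].to_numpy(np.float64),
        )
        for chrom, g in df.groupby("chrom", sort=False)
    }
    return SignalTrack(segs)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chromosomes():
            starts, ends, values = track._segs[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")
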