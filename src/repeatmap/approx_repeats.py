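"""Repeats with mismatches: k-mer Hamming clusters, segmental-duplication
tables, and power-law exponent fitting.

Exact-repeat counting misses repeat families whose copies have diverged by
point substitutions.  Two complementary views are provided:

* **Hamming clustering** of the canonical k-mer types present in a genome:
  types are nodes, edges join types within ``M`` mismatches (strand-aware),
  and connected components approximate mismatch-tolerant repeat families.
  Practical for small k or small genomes; the number of distinct types must
  fit memory.
* **Segmental-duplication (SegDup) tables** in the UCSC genomicSuperDups
  dialect: long (>= 1 kb) pairwise alignments at > 90 % identity.  Their
  length and copy-number histograms are heavy-tailed; exponents are read
  off by least squares in log-log coordinates against the reference curves
  1/D, 1/D^2, 1/D^3 (lengths) and 1/C^3 (copies).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .genome_io import Genome, GenomicInterval, reverse_complement
from .kmer_mappability import count_canonical_kmers

__all__ = [
    "PairwiseDuplicationRecord",
    "ClusterSet",
    "PowerLawFit",
    "hamming_clusters",
    "read_segdup_table",
    "segdup_length_histogram",
    "segdup_copy_histogram",
    "log_bin_edges",
    "histogram_density_points",
    "fit_powerlaw_exponent",
    "fit_powerlaw_mle",
]

SEGDUP_COLUMNS = [
    "chrom",
    "start",
    "end",
    "name",
    "otherChrom",
    "otherStart",
    "otherEnd",
    "fracMatch",
]


@dataclass(frozen=True)
class PairwiseDuplicationRecord:
    """One SegDup-style pairwise alignment line (two loci + label + identity)."""

    label: str
    interval_a: GenomicInterval
    interval_b: GenomicInterval
    identity: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError(f"identity {self.identity} outside [0, 1]")


@dataclass
class ClusterSet:
    """Connected components of k-mer types under a Hamming-distance cutoff."""

    k: int
    M: int
    components: list[frozenset[str]]
    occurrence_counts: dict[str, int]

    def component_occurrences(self, comp: frozenset[str]) -> int:
        return sum(self.occurrence_counts[t] for t in comp)

    def repeating_components(self) -> list[frozenset[str]]:
        """Components whose types together occur at least twice in the genome."""
        return [c for c in self.components if self.component_occurrences(c) >= 2]


@dataclass
class PowerLawFit:
    """y ~ x^(-exponent); least-squares in log10-log10 coordinates."""

    exponent: float
    intercept: float
    fit_range: tuple[float, float]
    n_points: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        return 10.0 ** (self.intercept - self.exponent * np.log10(np.asarray(x)))


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def strand_aware_hamming(a: str, b: str) -> int:
    """min over strand readings: H(a, b) or H(a, revcomp(b))."""
    return min(_hamming(a, b), _hamming(a, reverse_complement(b)))


def hamming_clusters(
    genome: Genome, k: int, M: int, strand_aware: bool = True
) -> ClusterSet:
    """Cluster the genome's canonical k-mer types at <= M mismatches.

    Nodes are the canonical k-mer types present; edges join pairs within
    ``M`` substitutions (by default comparing both strand readings and
    taking the minimum); components are graph connected components.  A
    component "repeats" when its summed occurrence count is >= 2, which at
    M=0 reduces exactly to the exact-repeat types.
    """
    if M >= k:
        raise ValueError(f"M={M} >= k={k}: every pair of k-mers would connect")
    if M < 0:
        raise ValueError("M must be >= 0")
    counts = count_canonical_kmers(genome, k)
    types = sorted(counts)
    dist = strand_aware_hamming if strand_aware else _hamming
    g = nx.Graph()
    g.add_nodes_from(types)
    for i, a in enumerate(types):
        for b in types[i + 1 :]:
            if dist(a, b) <= M:
                g.add_edge(a, b)
    components = sorted(
        (frozenset(c) for c in nx.connected_components(g)),
        key=lambda c: sorted(c)[0],
    )
    return ClusterSet(k=k, M=M, components=components, occurrence_counts=counts)


class SegDupFormatError(ValueError):
    """Raised for malformed duplication-table lines; message carries line number."""


def read_segdup_table(path: str | Path) -> list[PairwiseDuplicationRecord]:
    """Parse a tab-delimited pairwise-duplication table.

    Columns: chrom, start, end, name, otherChrom, otherStart, otherEnd,
    fracMatch (0-based half-open coordinates).  A header line is detected
    by a non-numeric second field and skipped.
    """
    with open(path) as fh:
        first = fh.readline()
    fields = first.rstrip("\n").split("\t")
    has_header = len(fields) >= 2 and not _is_number(fields[1])
    df = pd.read_csv(
        path,
        sep="\t",
        header=0 if has_header else None,
        names=SEGDUP_COLUMNS,
        usecols=range(len(SEGDUP_COLUMNS)),
        dtype=str,
    )
    records = []
    for i, row in df.iterrows():
        lineno = i + (2 if has_header else 1)
        try:
            start, end = int(row.start), int(row.end)
            o_start, o_end = int(row.otherStart), int(row.otherEnd)
            frac = float(row.fracMatch)
        except (TypeError, ValueError) as exc:
            raise SegDupFormatError(f"{path}: line {lineno}: {exc}") from exc
        if end <= start or o_end <= o_start:
            raise SegDupFormatError(
                f"{path}: line {lineno}: interval end must exceed start"
            )
        if not (0.0 <= frac <= 1.0):
            raise SegDupFormatError(
                f"{path}: line {lineno}: fracMatch {frac} outside [0, 1]"
            )
        records.append(
            PairwiseDuplicationRecord(
                label=str(row["name"]),
                interval_a=GenomicInterval(str(row.chrom), start, end),
                interval_b=GenomicInterval(str(row.otherChrom), o_start, o_end),
                identity=frac,
            )
        )
    return records


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def filter_segdup(
    records: Iterable[PairwiseDuplicationRecord],
    min_length: int = 1000,
    min_identity: float = 0.9,
) -> list[PairwiseDuplicationRecord]:
    """Apply the standard SegDup admission filter (>= 1 kb, > 90 % identity)."""
    return [
        r
        for r in records
        if len(r.interval_a) >= min_length and r.identity > min_identity
    ]


def log_bin_edges(lo: float, hi: float, bins_per_decade: int = 10) -> np.ndarray:
    """Logarithmic bin edges spanning [lo, hi] at the given density."""
    if not (0 < lo < hi):
        raise ValueError("need 0 < lo < hi")
    n = int(np.ceil(np.log10(hi / lo) * bins_per_decade)) + 1
    return np.logspace(np.log10(lo), np.log10(hi), max(n, 2))


def segdup_length_histogram(
    records: Sequence[PairwiseDuplicationRecord],
    bins: np.ndarray | None = None,
    symmetric: bool = False,
) -> dict[tuple[float, float], int]:
    """Histogram of duplication lengths over (by default logarithmic) bins.

    Each record contributes the length of its primary interval once (or both
    intervals when ``symmetric``).  Returns ``{(lo, hi): count}``.
    """
    if not records:
        raise ValueError("no duplication records")
    lengths = [len(r.interval_a) for r in records]
    if symmetric:
        lengths += [len(r.interval_b) for r in records]
    arr = np.asarray(lengths, dtype=float)
    if bins is None:
        bins = log_bin_edges(arr.min(), arr.max() + 1)
    counts, edges = np.histogram(arr, bins=bins)
    return {
        (float(lo), float(hi)): int(c)
        for lo, hi, c in zip(edges[:-1], edges[1:], counts)
    }


def segdup_copy_histogram(
    records: Sequence[PairwiseDuplicationRecord],
) -> dict[int, int]:
    """Copy-number histogram over duplication labels.

    A label aligned in ``m`` pairwise lines represents ``m + 1`` genomic
    copies; the histogram maps copy number C to the number of labels.
    """
    if not records:
        raise ValueError("no duplication records")
    per_label = pd.Series([r.label for r in records]).value_counts()
    copies = (per_label + 1).value_counts().sort_index()
    return {int(c): int(n) for c, n in copies.items()}


def histogram_density_points(
    hist: Mapping[tuple[float, float], int] | Mapping[int, int],
) -> list[tuple[float, float]]:
    """(x, density) points for exponent fitting.

    Binned histograms use the geometric bin centre and count / bin width
    (log bins widen with x, so raw counts of a x^(-a) law decay like
    x^(-(a-1)); the width correction restores the exponent).  Integer-keyed
    histograms (unit-width bins) pass through as-is.  Empty bins drop out.
    """
    pts = []
    for key, c in hist.items():
        if c <= 0:
            continue
        if isinstance(key, tuple):
            lo, hi = key
            pts.append((float(np.sqrt(lo * hi)), c / (hi - lo)))
        else:
            pts.append((float(key), float(c)))
    return sorted(pts)


def fit_powerlaw_exponent(
    points: Sequence[tuple[float, float]],
    fit_range: tuple[float, float] | None = None,
) -> PowerLawFit:
    """OLS of log10(y) on log10(x); exponent is the negated slope.

    Matches reading a straight-line slope off a log-log plot.  Requires at
    least three strictly positive points inside ``fit_range``.
    """
    pts = [
        (x, y)
        for x, y in points
        if x > 0
        and y > 0
        and (fit_range is None or fit_range[0] <= x <= fit_range[1])
    ]
    if len(pts) < 3:
        raise ValueError(
            f"need >= 3 positive points in range, got {len(pts)}"
        )
    lx = np.log10([p[0] for p in pts])
    ly = np.log10([p[1] for p in pts])
    slope, intercept = np.polyfit(lx, ly, 1)
    if fit_range is None:
        fit_range = (float(min(p[0] for p in pts)), float(max(p[0] for p in pts)))
    return PowerLawFit(
        exponent=float(-slope),
        intercept=float(intercept),
        fit_range=fit_range,
        n_points=len(pts),
    )


def fit_powerlaw_mle(samples: Sequence[float], x_min: float = 1.0) -> float:
    """Discrete maximum-likelihood exponent (Hill-style estimator).

    Alternative to least squares on binned counts; uses the continuous
    approximation ``1 + n / sum(ln(x / (x_min - 1/2)))`` for integer data.
    """
    x = np.asarray([s for s in samples if s >= x_min], dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 samples at or above x_min")
    return float(1.0 + x.size / np.sum(np.log(x / (x_min - 0.5))))
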