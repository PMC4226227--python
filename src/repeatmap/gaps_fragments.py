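"""Assembly-gap (N-run) statistics and fragment mappability classification.

Unassembled stretches of a reference genome are written as runs of N; their
amount differs sharply between chromosome classes (the repeat-rich short
arms of acrocentric chromosomes are largely unassembled, metacentric
chromosomes much less so).  :func:`gap_report` tabulates N content per
contig and per class, including the "metacentric excluding the large
heterochromatin carriers chr1/9/16" aggregate.

Fragment-level mappability follows from comparing a repeat length D with
the read length R and fragment length F: a repeat shorter than the read is
harmless, one longer than the whole fragment defeats even paired-end
anchoring, and anything between may or may not be rescued by the mate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .genome_io import Contig, Genome, GenomicInterval

__all__ = [
    "GapReport",
    "FragmentModel",
    "n_run_intervals",
    "gap_report",
    "classify_fragment",
    "DEFAULT_CLASS_MAP",
    "default_class_map",
]

ACROCENTRIC = {"chr13", "chr14", "chr15", "chr21", "chr22", "chrY"}
LARGE_HETEROCHROMATIN = {"chr1", "chr9", "chr16"}
_AUTOSOME_OR_X = {f"chr{i}" for i in range(1, 23)} | {"chrX"}


def default_class_map() -> dict[str, str]:
    """Human chromosome classes: acrocentric vs metacentric, with the large
    heterochromatin carriers (chr1, chr9, chr16) separable."""
    m = {}
    for name in sorted(_AUTOSOME_OR_X | {"chrY"}):
        if name in ACROCENTRIC:
            m[name] = "acrocentric"
        elif name in LARGE_HETEROCHROMATIN:
            m[name] = "large-heterochromatin"
        else:
            m[name] = "metacentric"
    return m


DEFAULT_CLASS_MAP = default_class_map()

_N_RUN = re.compile("N+")


def n_run_intervals(contig: Contig) -> list[GenomicInterval]:
    """Maximal runs of N as sorted 0-based half-open intervals."""
    return [
        GenomicInterval(contig.name, m.start(), m.end())
        for m in _N_RUN.finditer(contig.residues)
    ]


@dataclass
class GapReport:
    """Per-contig and aggregate N-content tables (pandas DataFrames)."""

    per_contig: pd.DataFrame  # name, length, n_bases, n_fraction, class
    per_class: pd.DataFrame  # class, length, n_bases, n_fraction

    @property
    def overall_n_fraction(self) -> float:
        total = self.per_contig["length"].sum()
        return float(self.per_contig["n_bases"].sum() / total) if total else 0.0

    def class_fraction(self, cls: str) -> float:
        row = self.per_class.set_index("class")
        return float(row.loc[cls, "n_fraction"])


def gap_report(
    genome: Genome, class_map: Mapping[str, str] | None = None
) -> GapReport:
    """Tabulate N content per contig and per chromosome class.

    Contigs absent from the class map are classed ``unknown`` (with a
    warning) and excluded from named-class aggregates.  In addition to one
    aggregate row per class, the report carries ``all`` (every contig),
    ``metacentric+large-heterochromatin`` (the non-acrocentric contrast
    class), and ``metacentric-excl-chr1-9-16``.
    """
    import warnings

    cmap = dict(DEFAULT_CLASS_MAP if class_map is None else class_map)
    rows = []
    for c in genome:
        cls = cmap.get(c.name)
        if cls is None:
            warnings.warn(f"contig {c.name} missing from class map; classed unknown")
            cls = "unknown"
        n = c.residues.count("N")
        rows.append(
            {
                "name": c.name,
                "length": c.length,
                "n_bases": n,
                "n_fraction": n / c.length if c.length else 0.0,
                "class": cls,
            }
        )
    per_contig = pd.DataFrame(rows)

    def _aggregate(label: str, sub: pd.DataFrame) -> dict:
        length = int(sub["length"].sum())
        n = int(sub["n_bases"].sum())
        return {
            "class": label,
            "length": length,
            "n_bases": n,
            "n_fraction": n / length if length else 0.0,
        }

    agg = [
        _aggregate(cls, grp)
        for cls, grp in per_contig.groupby("class")
        if cls != "unknown"
    ]
    known = per_contig[per_contig["class"] != "unknown"]
    agg.append(_aggregate("all", per_contig))
    non_acro = known[known["class"] != "acrocentric"]
    if len(non_acro):
        agg.append(_aggregate("metacentric+large-heterochromatin", non_acro))
    meta_only = known[known["class"] == "metacentric"]
    if len(meta_only):
        agg.append(_aggregate("metacentric-excl-chr1-9-16", meta_only))
    return GapReport(per_contig=per_contig, per_class=pd.DataFrame(agg))


@dataclass(frozen=True)
class FragmentModel:
    """Lengths governing mappability: fragment F, read R, repeat D (bases)."""

    D: int
    R: int
    F: int

    def __post_init__(self) -> None:
        if self.R > self.F:
            raise ValueError(f"read length R={self.R} exceeds fragment F={self.F}")
        if min(self.D, self.R, self.F) < 1:
            raise ValueError("lengths must be positive")


def classify_fragment(model: FragmentModel) -> str:
    """Classify a fragment overlapping a length-D repeat.

    D < R: the read extends past the repeat, unique placement — mappable.
    D > F: the repeat swallows the whole fragment — unmappable.
    Otherwise (R <= D <= F, boundaries included): ambiguous — the mate pair
    may or may not anchor the fragment.
    """
    if model.D < model.R:
        return "mappable"
    if model.D > model.F:
        return "unmappable"
    return "ambiguous"
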