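"""Marker-gene normalization of functional-gene depths.

Per-sample functional-gene coverage is expressed as "percent of genomes
carrying the gene" by dividing by genome equivalents (GE): the mean
per-base sequencing depth of 16 universal single-copy ribosomal protein
genes.  Because every genome contributes exactly one copy of each
marker, GE estimates the summed genome coverage of the community, and

    fraction_of_genomes = 100 * depth(gene) / GE

is the coverage-weighted carriage of the gene.  Values above 100% are
real (multi-copy gene families) and are flagged, not clipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "N_MARKERS",
    "DEFAULT_READ_LENGTH",
    "MarkerDepthSet",
    "DegenerateSampleError",
    "genome_equivalents",
    "fraction_of_genomes",
    "is_multicopy",
    "taxon_breakdown",
    "counts_to_depth",
    "profile",
]

#: Number of universal single-copy ribosomal marker genes.
N_MARKERS = 16
#: Read length (nt) used to convert raw counts to depth (2x250 bp libraries).
DEFAULT_READ_LENGTH = 250.0


class DegenerateSampleError(ValueError):
    """A sample with no usable marker-gene signal (GE <= 0)."""


@dataclass(frozen=True)
class MarkerDepthSet:
    """Mean per-base coverages of the 16 markers in one sample."""

    sample: str
    marker_depths: Sequence[float]

    def __post_init__(self) -> None:
        if len(self.marker_depths) != N_MARKERS:
            raise ValueError(
                f"expected {N_MARKERS} marker depths, got {len(self.marker_depths)}"
            )
        if any(d < 0 for d in self.marker_depths):
            raise ValueError("negative marker depth")


def genome_equivalents(markers: MarkerDepthSet) -> float:
    """Genome equivalents: the arithmetic mean of the 16 marker depths."""
    ge = float(np.mean(np.asarray(markers.marker_depths, dtype=float)))
    if ge <= 0:
        raise DegenerateSampleError(f"all marker depths zero in {markers.sample}")
    return ge


def fraction_of_genomes(gene_depth_sum: float, ge: float) -> float:
    """Percent of genomes carrying a gene: 100 * depth / GE.

    May exceed 100 for multi-copy families; see :func:`is_multicopy`.
    """
    if ge <= 0:
        raise DegenerateSampleError("genome equivalents must be positive")
    if gene_depth_sum < 0:
        raise ValueError("gene depth must be non-negative")
    return 100.0 * gene_depth_sum / ge


def is_multicopy(fraction_pct: float) -> bool:
    """Whether a carriage fraction implies more than one copy per genome."""
    return fraction_pct > 100.0


def taxon_breakdown(table: pd.DataFrame, gene_family: str) -> pd.Series:
    """Share of one gene family's total depth per taxon, percent.

    ``table`` holds columns ``gene_family``, ``taxon``, ``depth``
    (optionally pre-filtered to one sample).  Proportions sum to 100
    and are sorted descending.  An absent family returns an empty
    result with a warning.
    """
    sub = table[table["gene_family"] == gene_family]
    total = sub["depth"].sum()
    if sub.empty or total <= 0:
        warnings.warn(f"gene family {gene_family!r} absent", stacklevel=2)
        return pd.Series(dtype=float, name=gene_family)
    shares = 100.0 * sub.groupby("taxon")["depth"].sum() / total
    return shares.sort_values(ascending=False).rename(gene_family)


def counts_to_depth(
    count: float, gene_length: float, read_length: float = DEFAULT_READ_LENGTH
) -> float:
    """Convert a raw read count into mean per-base depth."""
    if gene_length <= 0:
        raise ValueError("gene length must be positive")
    return count * read_length / gene_length


def profile(genes: pd.DataFrame, markers: pd.DataFrame) -> pd.DataFrame:
    """Per-sample, per-family genome-carriage profile.

    ``genes``: long table with ``sample``, ``gene_family``, ``taxon``,
    ``depth``.  ``markers``: long table with ``sample``, ``marker``,
    ``depth`` (16 markers per sample).  Returns one row per sample and
    gene family with the carriage percent and a multi-copy flag.
    """
    out = []
    for sample, mk in markers.groupby("sample"):
        ge = genome_equivalents(MarkerDepthSet(sample, mk["depth"].tolist()))
        sub = genes[genes["sample"] == sample]
        for family, fam in sub.groupby("gene_family"):
            pct = fraction_of_genomes(fam["depth"].sum(), ge)
            out.append(
                {
                    "sample": sample,
                    "gene_family": family,
                    "genome_equivalents": ge,
                    "fraction_of_genomes_pct": pct,
                    "multicopy": is_multicopy(pct),
                }
            )
    return pd.DataFrame(
        out,
        columns=[
            "sample",
            "gene_family",
            "genome_equivalents",
            "fraction_of_genomes_pct",
            "multicopy",
        ],
    )
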