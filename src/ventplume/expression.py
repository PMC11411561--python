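"""RPKM and TPM metrics for mapped-read count tables.

RPKM_i = reads_i * 1e9 / (length_i * total_mapped_reads) measures
abundance against the whole library; TPM first length-normalizes each
feature (rate_i = reads_i / length_i) then rescales so the sample sums
to one million, which makes TPM values comparable across samples.  A
housekeeping baseline — the mean TPM of constitutively expressed
reference genes — provides the yardstick for calling a pathway "highly
transcribed", and per-sample gene ratios track shifts between
hydrogen- and sulfur-oxidation transcription across plume stages.

Counts are fragments (read pairs) by default; pass single reads if the
library was counted that way — both metrics are homogeneous of degree
zero in the count unit.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "DegenerateLibraryError",
    "MissingHousekeepingError",
    "rpkm",
    "tpm",
    "housekeeping_baseline",
    "above_baseline",
    "niche_contrast",
]


class DegenerateLibraryError(ValueError):
    """A library with no mapped reads."""


class MissingHousekeepingError(KeyError):
    """None of the housekeeping genes are present in the TPM table."""


def _check_counts(counts: pd.DataFrame) -> pd.DataFrame:
    for col in ("feature_id", "length", "count"):
        if col not in counts.columns:
            raise ValueError(f"counts table lacks column {col!r}")
    if (counts["length"] <= 0).any():
        raise ValueError("feature lengths must be positive")
    if (counts["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    return counts


def rpkm(counts: pd.DataFrame, total_mapped_reads: float | None = None) -> pd.Series:
    """Reads per kilobase per million mapped reads, per feature.

    ``total_mapped_reads`` is library-wide and may exceed the column
    sum (reads mapping outside the feature set); defaults to the sum.
    """
    _check_counts(counts)
    total = counts["count"].sum() if total_mapped_reads is None else total_mapped_reads
    if total <= 0:
        raise DegenerateLibraryError("no mapped reads in library")
    values = counts["count"] * 1e9 / (counts["length"] * total)
    return pd.Series(values.values, index=counts["feature_id"].values, name="rpkm")


def tpm(counts: pd.DataFrame) -> pd.Series:
    """Transcripts per million, per feature; sums to 1e6 per sample."""
    _check_counts(counts)
    rates = counts["count"] / counts["length"]
    denom = rates.sum()
    if denom <= 0:
        raise DegenerateLibraryError("all-zero counts")
    values = 1e6 * rates / denom
    return pd.Series(values.values, index=counts["feature_id"].values, name="tpm")


def housekeeping_baseline(tpms: pd.Series, housekeeping: Iterable[str]) -> float:
    """Mean TPM over the housekeeping genes present in the table."""
    hk = [g for g in housekeeping if g in tpms.index]
    if not hk:
        raise MissingHousekeepingError("no housekeeping gene present in TPM table")
    return float(tpms.loc[hk].mean())


def above_baseline(tpms: pd.Series, housekeeping: Iterable[str]) -> pd.Series:
    """Per-feature flag: transcribed above the housekeeping mean."""
    return tpms > housekeeping_baseline(tpms, housekeeping)


def niche_contrast(
    tpms_by_sample: Mapping[str, pd.Series] | pd.DataFrame,
    gene_a: str,
    gene_b: str,
) -> pd.Series:
    """Per-sample TPM ratio gene_a / gene_b, sample order preserved.

    Undefined ratios (gene_b at zero or either gene missing) are
    reported as NA, never as zero or infinity.
    """
    if isinstance(tpms_by_sample, pd.DataFrame):
        items = [(c, tpms_by_sample[c]) for c in tpms_by_sample.columns]
    else:
        items = list(tpms_by_sample.items())
    present = any(
        gene_a in s.index or gene_b in s.index for _, s in items
    )
    if not present:
        warnings.warn(
            f"neither {gene_a!r} nor {gene_b!r} present in any sample", stacklevel=2
        )
        return pd.Series(dtype=float, name=f"{gene_a}/{gene_b}")
    ratios = {}
    for sample, tpms in items:
        a = tpms.get(gene_a)
        b = tpms.get(gene_b)
        ratios[sample] = a / b if a is not None and b not in (None, 0) and b > 0 else float("nan")
    return pd.Series(ratios, name=f"{gene_a}/{gene_b}")
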