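"""Turbidity-based classification of hydrothermal plume samples.

CTD bottle samples are binned by their turbidity anomaly (dNTU above
local background): background water, above/below-plume water, the
non-buoyant plume layer, and the rising plume stem.  The printed field
thresholds (<0.01 background, <0.02 above/below plume, >0.02
non-buoyant plume, >0.06 rising plume) overlap as strict inequalities;
this module uses the disjoint convention

    background        [0, 0.01)
    near-plume        [0.01, 0.02)   -> above/below by vertical context
    non-buoyant plume [0.02, 0.06]
    rising plume      (0.06, inf)

which honours every strict inequality and makes classification a total
function of non-negative turbidity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "BACKGROUND_MAX",
    "NEAR_PLUME_MAX",
    "NON_BUOYANT_MAX",
    "CATEGORIES",
    "CTDSample",
    "PlumeLabel",
    "InvalidTurbidityError",
    "SchemaError",
    "DiscordantLabelWarning",
    "classify_turbidity",
    "assign_vertical_context",
    "parse_bottle_table",
    "classify_bottles",
    "load_reference_bottles",
    "audit_printed_labels",
]

BACKGROUND_MAX = 0.01
NEAR_PLUME_MAX = 0.02
NON_BUOYANT_MAX = 0.06

CATEGORIES = frozenset(
    {
        "background",
        "above_plume",
        "below_plume",
        "non_buoyant_plume",
        "rising_plume",
        "unclassified",
    }
)


class InvalidTurbidityError(ValueError):
    """Negative turbidity anomaly."""


class SchemaError(ValueError):
    """A mandatory bottle-table column is missing."""


class DiscordantLabelWarning(UserWarning):
    """A printed sample label conflicts with its turbidity threshold."""


@dataclass
class CTDSample:
    """One CTD bottle record."""

    name: str
    depth: float  # metres
    delta_ntu: Optional[float] = None
    potential_temperature: Optional[float] = None  # degC
    salinity: Optional[float] = None  # PSU
    delta_he3: Optional[float] = None  # percent
    eh: Optional[float] = None  # volts
    latitude: Optional[float] = None
    longitude: Optional[float] = None

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError(f"depth must be positive for {self.name}")
        if self.delta_ntu is not None and self.delta_ntu < 0:
            raise InvalidTurbidityError(f"negative dNTU for {self.name}")


@dataclass(frozen=True)
class PlumeLabel:
    category: str
    evidence: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def classify_turbidity(delta_ntu: float) -> str:
    """Turbidity class of a single dNTU value.

    Returns one of ``background``, ``near_plume`` (above/below pending
    vertical context), ``non_buoyant_plume``, ``rising_plume``.  Rising
    takes precedence over non-buoyant where the printed ranges overlap.
    """
    if delta_ntu is None or (isinstance(delta_ntu, float) and math.isnan(delta_ntu)):
        raise InvalidTurbidityError("missing turbidity")
    if delta_ntu < 0:
        raise InvalidTurbidityError(f"negative dNTU {delta_ntu}")
    if delta_ntu < BACKGROUND_MAX:
        return "background"
    if delta_ntu < NEAR_PLUME_MAX:
        return "near_plume"
    if delta_ntu <= NON_BUOYANT_MAX:
        return "non_buoyant_plume"
    return "rising_plume"


def _has_ntu(s: CTDSample) -> bool:
    return s.delta_ntu is not None and not math.isnan(s.delta_ntu)


def assign_vertical_context(samples: Sequence[CTDSample]) -> list[PlumeLabel]:
    """Resolve near-plume samples of one cast into above/below plume.

    "Above" and "below" are positions relative to the plume layer, so
    the reference depth is the deepest sample with plume-range turbidity
    (> 0.02 dNTU) — the bottom of the detected plume; if the cast shows
    no plume-range sample, the depth of the turbidity maximum is used.
    Near-plume samples at or above the reference are ``above_plume``,
    deeper ones ``below_plume``.  A cast whose only turbidity-bearing
    sample is near-plume has no vertical reference and stays
    ``unclassified``.
    """
    with_ntu = [s for s in samples if _has_ntu(s)]
    labels: list[PlumeLabel] = []
    if not with_ntu:
        return [
            PlumeLabel("unclassified", "no turbidity anomaly recorded") for _ in samples
        ]

    plume_range = [s for s in with_ntu if s.delta_ntu > NEAR_PLUME_MAX]
    if plume_range:
        ref_depth = max(s.depth for s in plume_range)
        ref_note = f"plume base at {ref_depth:g} m"
    else:
        ref = max(with_ntu, key=lambda s: s.delta_ntu)
        ref_depth = ref.depth
        ref_note = f"turbidity maximum at {ref_depth:g} m"

    for s in samples:
        if not _has_ntu(s):
            labels.append(PlumeLabel("unclassified", "no turbidity anomaly recorded"))
            continue
        cls = classify_turbidity(s.delta_ntu)
        if cls != "near_plume":
            labels.append(PlumeLabel(cls, f"dNTU={s.delta_ntu:g}"))
            continue
        if len(with_ntu) == 1:
            labels.append(
                PlumeLabel(
                    "unclassified",
                    f"dNTU={s.delta_ntu:g} in [0.01,0.02) but single-sample "
                    "cast gives no vertical reference",
                )
            )
        elif s.depth <= ref_depth:
            labels.append(
                PlumeLabel(
                    "above_plume",
                    f"dNTU={s.delta_ntu:g}; {s.depth:g} m above {ref_note}",
                )
            )
        else:
            labels.append(
                PlumeLabel(
                    "below_plume",
                    f"dNTU={s.delta_ntu:g}; {s.depth:g} m below {ref_note}",
                )
            )
    return labels


# ---------------------------------------------------------------------------
# Bottle-table IO
# ---------------------------------------------------------------------------

_NUMERIC_OPTIONAL = (
    "delta_ntu",
    "potential_temperature",
    "salinity",
    "delta_he3",
    "eh",
    "latitude",
    "longitude",
)
_MISSING_TOKENS = {"", "-", "–", "—", "na", "NA", "NaN", "nan", "None"}


def _to_float(value) -> Optional[float]:
    if value is None:
        return None
    text = str(value).strip()
    if text in _MISSING_TOKENS:
        return None
    try:
        return float(text)
    except ValueError:
        return None  # ranges like "15-29" are not single bottle values


def parse_bottle_table(path) -> list[CTDSample]:
    """Read a delimited bottle table into CTD samples.

    Mandatory columns: ``name``, ``depth``, ``delta_ntu``.  Missing
    numeric entries (dashes, blanks) become absent values, never zero.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if df.empty and len(df.columns) <= 1:
        warnings.warn("empty bottle table", stacklevel=2)
        return []
    for col in ("name", "depth", "delta_ntu"):
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column {col!r}")
    samples = []
    for _, row in df.iterrows():
        kwargs = {
            col: _to_float(row[col]) for col in _NUMERIC_OPTIONAL if col in df.columns
        }
        samples.append(
            CTDSample(name=str(row["name"]), depth=float(row["depth"]), **kwargs)
        )
    if not samples:
        warnings.warn("empty bottle table", stacklevel=2)
    return samples


def _cast_id(sample_field: str) -> str:
    return str(sample_field).split("_")[0]


def classify_bottles(df: pd.DataFrame, cast_col: str = "sample") -> pd.DataFrame:
    """Classify a bottle table, cast by cast.

    Adds ``category`` and ``evidence`` columns.  Rows sharing the same
    cast identifier (the part of ``cast_col`` before the first ``_``,
    e.g. ``502CTD``) are treated as one vertical profile.
    """
    out = df.copy()
    out["category"] = "unclassified"
    out["evidence"] = ""
    casts = (
        out[cast_col].map(_cast_id)
        if cast_col in out.columns
        else pd.Series("all", index=out.index)
    )
    for _, idx in out.groupby(casts).groups.items():
        samples = [
            CTDSample(
                name=str(out.at[i, "name"]),
                depth=float(out.at[i, "depth"]),
                delta_ntu=_to_float(out.at[i, "delta_ntu"]),
            )
            for i in idx
        ]
        for i, label in zip(idx, assign_vertical_context(samples)):
            out.at[i, "category"] = label.category
            out.at[i, "evidence"] = label.evidence
    return out


def load_reference_bottles() -> pd.DataFrame:
    """The published MAR bottle table (20 samples, four vent fields)."""
    with resources.files("ventplume.data").joinpath("mar_ctd_bottles.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"name": str, "sample": str})
    for col in _NUMERIC_OPTIONAL:
        if col in df.columns:
            df[col] = df[col].map(_to_float)
    return df


# Printed sample characters vs the literal turbidity constraints they imply.
# Each constraint is one-sided, equality at the printed resolution allowed
# (the thresholds themselves are strict-but-overlapping in the field rule).
_PRINTED_CONSTRAINTS = {
    "Backgr.": ("le", BACKGROUND_MAX),
    "Above plume": ("le", NEAR_PLUME_MAX),
    "Below plume": ("le", NEAR_PLUME_MAX),
    "Plume": ("ge", NEAR_PLUME_MAX),
    "Rising plume": ("ge", NON_BUOYANT_MAX),
}


def audit_printed_labels(df: pd.DataFrame) -> pd.DataFrame:
    """Check printed sample characters against the turbidity thresholds.

    Returns the discordant rows (sample name, printed character, dNTU,
    violated constraint) and emits one :class:`DiscordantLabelWarning`
    per discordance.  Fluid and diffuse-fluid samples carry no plume
    label and are skipped.
    """
    records = []
    for _, row in df.iterrows():
        character = str(row.get("character", "")).strip()
        key = "Rising plume" if character.startswith("Rising plume") else character
        if key not in _PRINTED_CONSTRAINTS:
            continue
        ntu = _to_float(row.get("delta_ntu"))
        if ntu is None:
            continue
        op, bound = _PRINTED_CONSTRAINTS[key]
        ok = ntu <= bound if op == "le" else ntu >= bound
        if not ok:
            constraint = f"dNTU {'<=' if op == 'le' else '>='} {bound}"
            records.append(
                {
                    "name": row["name"],
                    "character": character,
                    "delta_ntu": ntu,
                    "violated": constraint,
                }
            )
            warnings.warn(
                f"{row['name']}: printed '{character}' but dNTU={ntu:g} "
                f"violates {constraint}",
                DiscordantLabelWarning,
                stacklevel=2,
            )
    return pd.DataFrame(records, columns=["name", "character", "delta_ntu", "violated"])
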