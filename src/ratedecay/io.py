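"""Reading, validating and writing tables of molecular rate estimates.

The atomic data point is a :class:`RateEstimate`: one published (or newly
computed) substitution-rate estimate together with the age of the oldest
calibration used to obtain it, and the metadata needed to stratify the
meta-analysis (marker class, taxonomic group, species, source study,
calibration type).

The canonical on-disk dialect is a UTF-8, tab-separated table with a header
row and "." as decimal separator; scientific notation (``1.78E-10``) is
accepted for the numeric columns.  A column-mapping dictionary lets callers
ingest tables whose headers differ from the canonical names, and an alias
table normalizes the inconsistent categorical labels found in literature
compilations ("non-coding", "NC", ...).
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "MarkerClass",
    "TaxonGroup",
    "CalibrationType",
    "RateEstimate",
    "Dataset",
    "read_rate_table",
    "write_dataset",
    "write_results",
    "CANONICAL_COLUMNS",
]


class _LabelledEnum(str, enum.Enum):
    """String enum with case-insensitive, alias-aware parsing."""

    @classmethod
    def _aliases(cls) -> Mapping[str, str]:
        return {}

    @classmethod
    def parse(cls, label: Any, extra_aliases: Mapping[str, str] | None = None):
        if isinstance(label, cls):
            return label
        key = str(label).strip().lower().replace("-", "").replace("_", "").replace(" ", "")
        table = {**cls._aliases()}
        if extra_aliases:
            table.update(
                {k.strip().lower().replace("-", "").replace("_", "").replace(" ", ""): v
                 for k, v in extra_aliases.items()}
            )
        key = table.get(key, key).replace("_", "")
        for member in cls:
            if member.value.replace("_", "") == key:
                return member
        accepted = sorted(m.value for m in cls)
        raise ValidationError(
            f"unknown {cls.__name__} label {label!r}; accepted labels: {accepted}"
        )


class MarkerClass(_LabelledEnum):
    CODING = "coding"
    NONCODING = "noncoding"

    @classmethod
    def _aliases(cls) -> Mapping[str, str]:
        return {"nc": "noncoding", "noncodingmarker": "noncoding", "cds": "coding"}


class TaxonGroup(_LabelledEnum):
    INSECTS = "insects"
    REPTILES = "reptiles"
    BIRDS = "birds"
    MAMMALS = "mammals"

    @classmethod
    def _aliases(cls) -> Mapping[str, str]:
        return {"insect": "insects", "reptile": "reptiles", "bird": "birds",
                "mammal": "mammals", "aves": "birds", "mammalia": "mammals"}


class CalibrationType(_LabelledEnum):
    FOSSIL_BIOGEOGRAPHIC = "fossil_biogeographic"
    ANCIENT_DNA = "ancient_dna"
    PEDIGREE = "pedigree"
    #: only produced by pooling records of mixed calibration types; never
    #: accepted from input tables
    MIXED = "mixed"

    @classmethod
    def _aliases(cls) -> Mapping[str, str]:
        return {
            "fossil": "fossil_biogeographic",
            "biogeographic": "fossil_biogeographic",
            "biogeography": "fossil_biogeographic",
            "fossilbiogeographical": "fossil_biogeographic",
            "adna": "ancient_dna",
            "ancientdna": "ancient_dna",
        }


#: canonical header names, in canonical column order
CANONICAL_COLUMNS = (
    "rate",
    "calibration_time",
    "marker_class",
    "marker_name",
    "taxon_group",
    "species",
    "study_id",
    "calibration_type",
)


@dataclass(frozen=True)
class RateEstimate:
    """One substitution-rate estimate with its calibration age and metadata.

    Parameters
    ----------
    rate
        Substitution rate, substitutions/site/year.  Must be positive: the
        analysis regresses log10(rate).
    calibration_time
        Age of the oldest calibration used for the estimate, in years: the
        oldest fossil/biogeographic constraint, the oldest ancient-DNA
        sample, or the depth of the pedigree.  Must be positive.
    marker_class
        Whether the marker(s) are protein/RNA coding or non-coding
        (e.g., control region).
    """

    rate: float
    calibration_time: float
    marker_class: MarkerClass
    marker_name: str
    taxon_group: TaxonGroup
    species: str
    study_id: str
    calibration_type: CalibrationType

    def __post_init__(self) -> None:
        for name in ("rate", "calibration_time"):
            value = getattr(self, name)
            try:
                value = float(value)
            except (TypeError, ValueError):
                raise ValidationError(f"{name} must be a number, got {value!r}") from None
            if not math.isfinite(value) or value <= 0:
                raise ValidationError(
                    f"{name} must be positive and finite (log-transform must be "
                    f"defined), got {value!r}"
                )
            object.__setattr__(self, name, value)
        object.__setattr__(self, "marker_class", MarkerClass.parse(self.marker_class))
        object.__setattr__(self, "taxon_group", TaxonGroup.parse(self.taxon_group))
        object.__setattr__(
            self, "calibration_type", CalibrationType.parse(self.calibration_type)
        )

    @property
    def genetic_distance(self) -> float:
        """Total genetic distance implied by the estimate: rate x time
        (substitutions/site)."""
        return self.rate * self.calibration_time

    def as_row(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        for col in ("marker_class", "taxon_group", "calibration_type"):
            d[col] = d[col].value
        return d


@dataclass
class Dataset:
    """An ordered collection of validated rate estimates.

    Preparation steps (pooling, averaging, subsetting) only ever remove or
    merge records — the count never grows — and each step appends a line to
    ``provenance`` so a result can be traced back to the operations that
    produced its input.
    """

    records: list[RateEstimate] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[RateEstimate]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def with_records(self, records: Iterable[RateEstimate], note: str) -> "Dataset":
        """New Dataset with `records`, provenance extended by `note`."""
        return Dataset(records=list(records), provenance=[*self.provenance, note])

    def to_frame(self) -> pd.DataFrame:
        """Canonical tabular view (one row per record, canonical columns)."""
        if not self.records:
            return pd.DataFrame(columns=list(CANONICAL_COLUMNS))
        return pd.DataFrame([r.as_row() for r in self.records], columns=list(CANONICAL_COLUMNS))


def _rename_columns(df: pd.DataFrame, column_map: Mapping[str, str] | None) -> pd.DataFrame:
    if column_map:
        # column_map: canonical name -> name used in the file
        missing = [src for src in column_map.values() if src not in df.columns]
        if missing:
            raise SchemaError(f"column mapping refers to absent column(s): {missing}")
        df = df.rename(columns={src: dst for dst, src in column_map.items()})
    return df


def read_rate_table(
    path: str | Path,
    *,
    sep: str = "\t",
    column_map: Mapping[str, str] | None = None,
    aliases: Mapping[str, Mapping[str, str]] | None = None,
) -> Dataset:
    """Read a rate-estimate table into a validated :class:`Dataset`.

    Parameters
    ----------
    path
        Delimited text file with a header row naming the eight canonical
        fields (possibly via `column_map`).
    sep
        Field separator; the canonical dialect is tab-separated.
    column_map
        Optional mapping ``canonical name -> header used in the file``.
    aliases
        Optional per-field extra alias tables for the enum columns, e.g.
        ``{"marker_class": {"non coding region": "noncoding"}}``.

    Raises
    ------
    SchemaError
        If a required column is absent.
    ValidationError
        If a row has a non-positive/unparseable rate or calibration time, or
        an unknown categorical label; the message carries the 1-based data
        row number.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input table not found: {path}")
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df = _rename_columns(df, column_map)
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"missing required column(s) {missing}; found columns {list(df.columns)}"
        )
    aliases = aliases or {}
    records: list[RateEstimate] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        vals = {c: getattr(row, c) for c in CANONICAL_COLUMNS}
        if all(str(v).strip() == "" for v in vals.values()):
            continue  # skip blank lines
        try:
            rec = RateEstimate(
                rate=_parse_positive(vals["rate"], "rate"),
                calibration_time=_parse_positive(vals["calibration_time"], "calibration_time"),
                marker_class=MarkerClass.parse(vals["marker_class"], aliases.get("marker_class")),
                marker_name=vals["marker_name"].strip(),
                taxon_group=TaxonGroup.parse(vals["taxon_group"], aliases.get("taxon_group")),
                species=vals["species"].strip(),
                study_id=vals["study_id"].strip(),
                calibration_type=CalibrationType.parse(
                    vals["calibration_type"], aliases.get("calibration_type")
                ),
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from None
        records.append(rec)
    return Dataset(records=records, provenance=[f"read {len(records)} records from {path.name}"])


def _parse_positive(text: Any, name: str) -> float:
    s = str(text).strip()
    if s == "":
        raise ValidationError(f"{name} is missing (rows without {name} are rejected)")
    try:
        value = float(s)
    except ValueError:
        raise ValidationError(f"{name} is not a number: {s!r}") from None
    if not math.isfinite(value) or value <= 0:
        raise ValidationError(f"{name} must be positive and finite, got {s!r}")
    return value


def write_dataset(data: Dataset, path: str | Path, *, sep: str = "\t") -> None:
    """Write a Dataset in the canonical dialect, full float precision."""
    df = data.to_frame()
    # repr-roundtrip precision so read(write(x)) == x on numeric fields
    df["rate"] = df["rate"].map(lambda v: format(float(v), ".17g"))
    df["calibration_time"] = df["calibration_time"].map(lambda v: format(float(v), ".17g"))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False)


def _to_record(obj: Any) -> dict[str, Any]:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        d = {}
        for f in dataclasses.fields(obj):
            v = getattr(obj, f.name)
            if isinstance(v, enum.Enum):
                v = v.value
            elif hasattr(v, "tolist"):
                v = v.tolist()
            d[f.name] = v
        return d
    if isinstance(obj, Mapping):
        return dict(obj)
    raise TypeError(f"cannot serialize result of type {type(obj).__name__}")


def write_results(
    results: Any,
    path: str | Path,
    format: str = "tsv",  # noqa: A002 - mirrors the public signature
) -> None:
    """Write one result or a collection of results to TSV or JSON.

    TSV output has a header plus one row per result; JSON output preserves
    nesting (used for randomization-test results, whose null-distribution
    summary is structured).  Numeric fields are written at full precision so
    the file round-trips.
    """
    if results is None:
        raise ValidationError("refusing to write empty results")
    if dataclasses.is_dataclass(results) and not isinstance(results, type):
        items: Sequence[Any] = [results]
    elif isinstance(results, Mapping):
        items = [results]
    else:
        items = list(results)
    if not items:
        raise ValidationError("refusing to write empty results")
    rows = [_to_record(x) for x in items]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "tsv":
        df = pd.DataFrame(rows)
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    elif format == "json":
        payload: Any = rows[0] if len(rows) == 1 else rows
        path.write_text(json.dumps(payload, indent=2, default=float) + "\n")
    else:
        raise ValidationError(f"unknown output format {format!r} (tsv or json)")
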