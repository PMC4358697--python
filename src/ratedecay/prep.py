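"""Data-preparation rules that collapse redundant estimates before regression.

Literature compilations of rate estimates carry two kinds of redundancy that
would otherwise overweight single species in the regression:

* a study may report one rate per mitochondrial marker for the same species —
  those are averaged into one point per (study, species, marker class);
* several independent studies may estimate the rate of the same species on
  the same calibration (the classic case being human pedigree studies) —
  those are pooled into a single data point.

Both reductions use plain means by default.  Because the downstream
regression is on the log10 scale, a geometric-mean variant is provided as
well; the choice is a documented configuration knob, not a behavioural fork.
"""

from __future__ import annotations

import math
from typing import Callable, Mapping, Sequence

from .errors import ValidationError
from .io import CalibrationType, Dataset, MarkerClass, RateEstimate

__all__ = ["average_markers_within_study", "pool_point_group", "selector_from_mapping"]

Selector = Callable[[RateEstimate], bool]


def _mean(values: Sequence[float], kind: str) -> float:
    if kind == "arithmetic":
        return sum(values) / len(values)
    if kind == "geometric":
        return math.exp(sum(math.log(v) for v in values) / len(values))
    raise ValidationError(f"unknown mean kind {kind!r} (arithmetic or geometric)")


def average_markers_within_study(data: Dataset, *, mean: str = "arithmetic") -> Dataset:
    """Collapse multi-marker reports into one estimate per study/species/class.

    Records sharing (study_id, species, marker_class) are replaced by a
    single record whose rate is the mean of the group's rates; the merged
    record sits at the position of the group's first member, so overall
    order is stable.  Groups whose members disagree on calibration time are
    ambiguous and raise :class:`ValidationError`.  Coding and non-coding
    markers are analysed separately and therefore never merged with each
    other.
    """
    groups: dict[tuple[str, str, MarkerClass], list[int]] = {}
    for i, rec in enumerate(data):
        groups.setdefault((rec.study_id, rec.species, rec.marker_class), []).append(i)

    merged: dict[int, RateEstimate] = {}
    drop: set[int] = set()
    n_collapsed = 0
    for key, idxs in groups.items():
        if len(idxs) == 1:
            continue
        members = [data[i] for i in idxs]
        times = {m.calibration_time for m in members}
        if len(times) != 1:
            raise ValidationError(
                f"cannot average markers for study={key[0]!r} species={key[1]!r}: "
                f"members have unequal calibration times {sorted(times)}"
            )
        first = members[0]
        merged[idxs[0]] = RateEstimate(
            rate=_mean([m.rate for m in members], mean),
            calibration_time=first.calibration_time,
            marker_class=first.marker_class,
            marker_name="; ".join(dict.fromkeys(m.marker_name for m in members)),
            taxon_group=first.taxon_group,
            species=first.species,
            study_id=first.study_id,
            calibration_type=first.calibration_type,
        )
        drop.update(idxs[1:])
        n_collapsed += 1

    out = [merged.get(i, rec) for i, rec in enumerate(data) if i not in drop]
    return data.with_records(
        out,
        f"averaged markers within study ({mean} mean): "
        f"{len(data)} -> {len(out)} records ({n_collapsed} groups collapsed)",
    )


def selector_from_mapping(clauses: Mapping[str, object]) -> Selector:
    """Build a record predicate from field/value match clauses.

    ``{"species": "Homo sapiens", "calibration_type": "pedigree"}`` matches
    records satisfying *all* clauses.  Enum-valued fields compare by their
    normalized label.
    """
    known = {
        "rate", "calibration_time", "marker_class", "marker_name",
        "taxon_group", "species", "study_id", "calibration_type",
    }
    unknown = set(clauses) - known
    if unknown:
        raise ValidationError(f"selector refers to unknown field(s): {sorted(unknown)}")

    def predicate(rec: RateEstimate) -> bool:
        for fld, want in clauses.items():
            have = getattr(rec, fld)
            if hasattr(have, "value"):
                have = have.value
                want_n = type(getattr(rec, fld)).parse(want).value
            else:
                want_n = want
            if have != want_n:
                return False
        return True

    return predicate


def pool_point_group(
    data: Dataset,
    selector: Selector | Mapping[str, object],
    label: str,
    *,
    mean: str = "arithmetic",
) -> Dataset:
    """Pool all records matched by `selector` into a single data point.

    The pooled record takes the mean rate and the mean calibration time of
    the matched records and sits at the position of the first match.  All
    matched records must share a marker class (pooling across classes would
    mix separately analysed strata).  Species and study fields are set to
    `label`; the calibration type is kept if uniform across the group and
    set to ``mixed`` otherwise.
    """
    if isinstance(selector, Mapping):
        selector = selector_from_mapping(selector)
    idxs = [i for i, rec in enumerate(data) if selector(rec)]
    if not idxs:
        raise ValidationError(f"pooling selector {label!r} matched no records")
    members = [data[i] for i in idxs]
    classes = {m.marker_class for m in members}
    if len(classes) != 1:
        raise ValidationError(
            f"pooling selector {label!r} matched records of both marker classes; "
            "pool within one class at a time"
        )
    if len(idxs) == 1:
        return data.with_records(
            list(data), f"pooling {label!r}: single match, dataset unchanged"
        )
    cal_types = {m.calibration_type for m in members}
    pooled = RateEstimate(
        rate=_mean([m.rate for m in members], mean),
        calibration_time=_mean([m.calibration_time for m in members], mean),
        marker_class=members[0].marker_class,
        marker_name="; ".join(dict.fromkeys(m.marker_name for m in members)),
        taxon_group=members[0].taxon_group,
        species=label,
        study_id=label,
        calibration_type=cal_types.pop() if len(cal_types) == 1 else CalibrationType.MIXED,
    )
    first = idxs[0]
    dropped = set(idxs[1:])
    out = [pooled if i == first else rec for i, rec in enumerate(data) if i not in dropped]
    return data.with_records(
        out,
        f"pooled {len(idxs)} records into one point {label!r} ({mean} mean): "
        f"{len(data)} -> {len(out)} records",
    )
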