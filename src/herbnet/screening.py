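"""ADME / Lipinski screening of candidate herbal ingredients.

Candidate compounds extracted from traditional-medicine databases are
screened through a cascade of pharmacokinetic and druglikeness criteria:

* oral bioavailability (OB) strictly greater than 30 %,
* gastrointestinal (GI) absorption class ``High``,
* druglikeness index (DL) strictly greater than 0.18,
* Lipinski's rule of five: molecular weight <= 500 g/mol, hydrogen-bond
  donors <= 5, hydrogen-bond acceptors <= 10, iLOGP <= 5.

A compound must satisfy every criterion to survive.  Compounds missing a
value for any criterion are rejected: only fully characterised compounds
are screened.  Survivors are then partitioned into herb-shared (present
in two or more herbs) and herb-specific compounds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import isnan
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "IngredientRecord",
    "HerbTally",
    "ScreenError",
    "read_ingredient_table",
    "merge_duplicate_ingredients",
    "apply_adme_filter",
    "tally_herb_membership",
    "write_screened_table",
]

#: columns holding numeric screening properties
NUMERIC_FIELDS = ("OB", "DL", "MW", "Hdon", "Hacc", "iLOGP")


class ScreenError(ValueError):
    """Raised for malformed ingredient tables."""


@dataclass
class IngredientRecord:
    """One candidate compound with its screening properties.

    ``herbs`` is the set of herb codes the compound belongs to (a compound
    listed under several herbs is merged into a single record).  Numeric
    properties are ``None`` when the source database gave no value.
    """

    ingredient_id: str
    name: str
    herbs: set[str] = field(default_factory=set)
    OB: float | None = None          # oral bioavailability, percent
    GI: str | None = None            # gastrointestinal absorption class
    DL: float | None = None          # druglikeness, unitless fraction
    MW: float | None = None          # molecular weight, g/mol
    Hdon: float | None = None        # hydrogen-bond donors
    Hacc: float | None = None        # hydrogen-bond acceptors
    iLOGP: float | None = None       # implicit logP

    def passes_adme(self) -> bool:
        """Evaluate the full screening cascade for this record."""
        if any(getattr(self, f) is None for f in NUMERIC_FIELDS):
            return False
        if self.GI is None or str(self.GI).strip().lower() != "high":
            return False
        return (
            self.OB > 30.0
            and self.DL > 0.18
            and self.MW <= 500.0
            and self.Hdon <= 5
            and self.Hacc <= 10
            and self.iLOGP <= 5
        )


@dataclass
class HerbTally:
    """Partition of screened compounds into shared vs herb-specific."""

    shared_count: int
    specific_counts: dict[str, int]
    total: int

    def as_dict(self) -> dict:
        return {
            "shared_count": self.shared_count,
            "specific_counts": dict(self.specific_counts),
            "total": self.total,
        }


def _parse_number(value, record_id: str, column: str) -> float | None:
    if value is None:
        return None
    if isinstance(value, float) and isnan(value):
        return None
    if isinstance(value, str):
        value = value.strip()
        if value == "" or value.upper() in {"NA", "NAN", "NONE", "NULL"}:
            return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ScreenError(
            f"ingredient {record_id!r}: cannot parse column {column!r} "
            f"value {value!r} as a number"
        ) from None


def read_ingredient_table(path: str | Path, sep: str | None = None) -> list[IngredientRecord]:
    """Read a candidate table (one row per ingredient-herb pair) and merge.

    Expected columns: ``ingredient_id, name, herb, OB, GI, DL, MW, Hdon,
    Hacc, iLOGP``.  Tab- or comma-separated, inferred from the extension
    unless ``sep`` is given.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep, dtype=str)
    missing = {"ingredient_id", "herb"} - set(frame.columns)
    if missing:
        raise ScreenError(f"ingredient table lacks columns: {sorted(missing)}")
    return records_from_frame(frame)


def records_from_frame(frame: pd.DataFrame) -> list[IngredientRecord]:
    """Build merged :class:`IngredientRecord` objects from a long table."""
    rows = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        rid = str(d["ingredient_id"]).strip()
        gi = d.get("GI")
        if isinstance(gi, str):
            gi = gi.strip() or None
        elif isinstance(gi, float) and isnan(gi):
            gi = None
        rec = IngredientRecord(
            ingredient_id=rid,
            name=str(d.get("name", rid)),
            herbs={str(d["herb"]).strip()},
            GI=gi,
        )
        for col in NUMERIC_FIELDS:
            setattr(rec, col, _parse_number(d.get(col), rid, col))
        rows.append(rec)
    return merge_duplicate_ingredients(rows)


def merge_duplicate_ingredients(records: Iterable[IngredientRecord]) -> list[IngredientRecord]:
    """Merge records sharing an ``ingredient_id`` by taking the herb union.

    Required for the shared/specific partition to be well defined: the
    same compound listed under several herbs is one compound belonging to
    several herbs.  Property values are taken from the first occurrence;
    a conflicting duplicate value raises :class:`ScreenError`.
    """
    merged: dict[str, IngredientRecord] = {}
    order: list[str] = []
    for rec in records:
        if rec.ingredient_id not in merged:
            merged[rec.ingredient_id] = IngredientRecord(
                ingredient_id=rec.ingredient_id,
                name=rec.name,
                herbs=set(rec.herbs),
                GI=rec.GI,
                **{f: getattr(rec, f) for f in NUMERIC_FIELDS},
            )
            order.append(rec.ingredient_id)
        else:
            prev = merged[rec.ingredient_id]
            prev.herbs |= rec.herbs
            for f in NUMERIC_FIELDS:
                a, b = getattr(prev, f), getattr(rec, f)
                if a is not None and b is not None and a != b:
                    raise ScreenError(
                        f"ingredient {rec.ingredient_id!r}: conflicting "
                        f"{f} values {a} and {b} across herb rows"
                    )
                if a is None:
                    setattr(prev, f, b)
    return [merged[rid] for rid in order]


def apply_adme_filter(records: Iterable[IngredientRecord]) -> list[IngredientRecord]:
    """Return, in input order, the records passing the full cascade.

    The OB and DL inequalities are strict; the four Lipinski bounds are
    inclusive.  GI matching is case-insensitive on the token ``high``.
    Records missing any criterion value are rejected.
    """
    return [rec for rec in records if rec.passes_adme()]


def tally_herb_membership(records: Iterable[IngredientRecord]) -> HerbTally:
    """Partition screened compounds into shared and herb-specific.

    A compound is *shared* when it belongs to two or more herbs and
    *specific* to a herb when that herb is its sole membership; the two
    classes partition the input, so ``shared + sum(specific) == total``.
    """
    records = list(records)
    shared = 0
    specific: dict[str, int] = {}
    for rec in records:
        if not rec.herbs:
            raise ScreenError(f"ingredient {rec.ingredient_id!r} has no herb membership")
        if len(rec.herbs) >= 2:
            shared += 1
        else:
            (herb,) = rec.herbs
            specific[herb] = specific.get(herb, 0) + 1
    return HerbTally(shared_count=shared, specific_counts=specific, total=len(records))


def write_screened_table(records: Iterable[IngredientRecord], path: str | Path,
                         tally_path: str | Path | None = None) -> None:
    """Write screened records as TSV (herbs joined by ``;``), plus optional tally JSON."""
    records = list(records)
    frame = pd.DataFrame(
        {
            "ingredient_id": [r.ingredient_id for r in records],
            "name": [r.name for r in records],
            "herbs": [";".join(sorted(r.herbs)) for r in records],
            **{f: [getattr(r, f) for r in records] for f in NUMERIC_FIELDS},
            "GI": [r.GI for r in records],
        }
    )
    frame.to_csv(path, sep="\t", index=False)
    if tally_path is not None:
        tally = tally_herb_membership(records)
        Path(tally_path).write_text(json.dumps(tally.as_dict(), indent=2) + "\n")
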