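"""Zone-table input/output and data subsetting.

The canonical record is one within-field soil management zone in one season:
zone mean yield (t/ha), extractable nutrient concentrations (mg/L), soil pH,
depth class and planar coordinates.  Tables are delimited text (comma or
tab) with a header row; a "dialect" mapping adapts arbitrary commercial
export headers to the canonical names.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CROPS = ("feed", "milling", "other")
DEPTH_CLASSES = ("shallow", "medium", "deep")

MANDATORY_COLUMNS = ("zone_id", "farm_id", "east", "north", "season", "crop", "yield_t_ha")
OPTIONAL_COLUMNS = ("p_mgL", "k_mgL", "mg_mgL", "ph", "depth_class")

NUTRIENT_COLUMNS = {"P": "p_mgL", "K": "k_mgL", "Mg": "mg_mgL"}


@dataclass(frozen=True)
class ZoneRecord:
    """One management zone's yield, nutrient status and location."""

    zone_id: str
    farm_id: str
    east: float
    north: float
    season: int
    crop: str
    yield_t_ha: float
    p_mgL: float | None = None
    k_mgL: float | None = None
    mg_mgL: float | None = None
    ph: float | None = None
    depth_class: str | None = None

    def validate(self) -> None:
        if self.crop not in CROPS:
            raise ValueError(f"unknown crop {self.crop!r}")
        if not np.isfinite(self.yield_t_ha) or self.yield_t_ha < 0:
            raise ValueError("yield must be finite and non-negative")
        for name in ("p_mgL", "k_mgL", "mg_mgL"):
            v = getattr(self, name)
            if v is not None and (not np.isfinite(v) or v <= 0):
                raise ValueError(f"{name} must be positive when present")
        if self.ph is not None and not (3.0 <= self.ph <= 10.0):
            raise ValueError("ph must lie in [3, 10] when present")
        if self.depth_class is not None and self.depth_class not in DEPTH_CLASSES:
            raise ValueError(f"unknown depth class {self.depth_class!r}")

    def nutrient(self, name: str) -> float | None:
        return getattr(self, NUTRIENT_COLUMNS[name])


def depth_class_from_cm(depth_cm: float) -> str:
    """Bin a numeric depth: <30 cm shallow, 30–50 cm medium, >50 cm deep."""
    if depth_cm < 30.0:
        return "shallow"
    if depth_cm <= 50.0:
        return "medium"
    return "deep"


_ALL_COLUMNS = MANDATORY_COLUMNS + OPTIONAL_COLUMNS
_FLOAT_COLS = ("east", "north", "yield_t_ha", "p_mgL", "k_mgL", "mg_mgL", "ph")


def records_to_frame(records: list[ZoneRecord]) -> pd.DataFrame:
    rows = [{f.name: getattr(r, f.name) for f in dc_fields(ZoneRecord)} for r in records]
    return pd.DataFrame(rows, columns=list(_ALL_COLUMNS))


def frame_to_records(df: pd.DataFrame) -> list[ZoneRecord]:
    """Validate a canonical-column frame row by row; invalid rows are logged
    and dropped."""
    records: list[ZoneRecord] = []
    n_dropped = 0
    seen: set[tuple[str, int]] = set()
    for i, row in df.iterrows():
        try:
            kwargs = {}
            for name in _ALL_COLUMNS:
                v = row.get(name)
                if pd.isna(v):
                    if name in MANDATORY_COLUMNS:
                        raise ValueError(f"missing mandatory value {name}")
                    kwargs[name] = None
                elif name in _FLOAT_COLS:
                    kwargs[name] = float(v)
                elif name == "season":
                    kwargs[name] = int(v)
                else:
                    kwargs[name] = str(v)
            rec = ZoneRecord(**kwargs)
            rec.validate()
            key = (rec.zone_id, rec.season)
            if key in seen:
                raise ValueError(f"duplicate (zone_id, season) {key}")
            seen.add(key)
            records.append(rec)
        except (ValueError, TypeError) as exc:
            n_dropped += 1
            logger.warning("dropping row %s: %s", i, exc)
    if n_dropped:
        logger.warning("dropped %d invalid row(s); kept %d", n_dropped, len(records))
    return records


def read_zone_table(path, dialect: dict[str, str] | None = None) -> list[ZoneRecord]:
    """Read a delimited zone table (comma or tab, header row, UTF-8).

    ``dialect`` maps canonical column names to the names used in the file,
    e.g. ``{"yield_t_ha": "Yield (t/ha)"}``.  A missing mandatory column is
    a hard error; rows violating record invariants are logged and dropped.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") > header.count(",") else ","
    df = pd.read_csv(path, sep=sep, encoding="utf-8", float_precision="round_trip")
    if dialect:
        rename = {src: canon for canon, src in dialect.items() if src in df.columns}
        df = df.rename(columns=rename)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    for c in OPTIONAL_COLUMNS:
        if c not in df.columns:
            df[c] = None
    for c in _FLOAT_COLS + ("season",):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    return frame_to_records(df)


def write_zone_table(records: list[ZoneRecord], path, sep: str = ",") -> None:
    """Write records to delimited text with canonical headers (full float
    precision, missing values as empty cells)."""
    df = records_to_frame(records)
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# subsetting

PH_INTERVALS = {
    "ph<=7": (None, 7.0),
    "7<ph<=7.5": (7.0, 7.5),
    "7.5<ph<=8": (7.5, 8.0),
    "ph>8": (8.0, None),
}


def subset_records(records: list[ZoneRecord], rule: str | None) -> list[ZoneRecord]:
    """Select records by one rule: a pH interval (half-open, closed on the
    right: pH 7.0 belongs to "ph<=7", 7.5 to "7<ph<=7.5"), a depth class
    ("depth:shallow"), a crop ("crop:milling") or a season ("season:2016").

    Records missing the field the rule tests are excluded (and counted in a
    log message).  An empty result is returned with a warning.
    """
    if rule is None:
        return list(records)
    rule = str(rule).strip().lower().replace(" ", "")
    if rule in PH_INTERVALS:
        lo, hi = PH_INTERVALS[rule]
        n_missing = sum(r.ph is None for r in records)
        out = [
            r for r in records
            if r.ph is not None
            and (lo is None or r.ph > lo)
            and (hi is None or r.ph <= hi)
        ]
        if n_missing:
            logger.info("pH rule %r: %d record(s) without pH excluded", rule, n_missing)
    elif rule.startswith("depth:"):
        cls = rule.split(":", 1)[1]
        if cls not in DEPTH_CLASSES:
            raise ValueError(f"unknown depth class {cls!r}")
        n_missing = sum(r.depth_class is None for r in records)
        out = [r for r in records if r.depth_class == cls]
        if n_missing:
            logger.info("depth rule %r: %d record(s) without depth excluded", rule, n_missing)
    elif rule.startswith("crop:"):
        crop = rule.split(":", 1)[1]
        if crop not in CROPS:
            raise ValueError(f"unknown crop {crop!r}")
        out = [r for r in records if r.crop == crop]
    elif rule.startswith("season:"):
        season = int(rule.split(":", 1)[1])
        out = [r for r in records if r.season == season]
    else:
        raise ValueError(f"unrecognized subset rule {rule!r}")
    if not out:
        logger.warning("subset rule %r matched no records", rule)
    return out
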