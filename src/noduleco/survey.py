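"""Survey domain records, tabular IO, and image quality-control filters.

The unit of observation is a single vertically oriented seafloor photograph
(:class:`ImageRecord`) with its imaged area and percentage nodule cover, plus
the megafauna specimens annotated on it (:class:`SpecimenRecord`).  A
:class:`SurveyDataset` bundles both with provenance metadata and enforces
referential integrity.

Tables are exchanged as UTF-8 TSV (default) or CSV with '.' decimal
separators.  Documented headers:

* image table: ``image_id, transect_id, landscape, sequence_index,
  altitude_m, area_m2, cover_pct, nodule_areas_cm2, junction`` where
  ``nodule_areas_cm2`` is an optional ';'-separated list.
* specimen table: ``specimen_id, image_id, morphospecies, group,
  life_habit, feeding, body_length_cm, biovolume_ml``.

Extra columns are preserved on read but ignored by the analysis.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import pandas as pd

LANDSCAPES = ("flat", "ridge", "trough")
GROUPS = ("metazoan", "xenophyophore")
LIFE_HABITS = ("NA", "FM", "unknown")
FEEDING_GROUPS = ("suspension", "deposit", "predator", "scavenger", "unknown")

IMAGE_COLUMNS = (
    "image_id", "transect_id", "landscape", "sequence_index",
    "altitude_m", "area_m2", "cover_pct", "nodule_areas_cm2", "junction",
)
SPECIMEN_COLUMNS = (
    "specimen_id", "image_id", "morphospecies", "group",
    "life_habit", "feeding", "body_length_cm", "biovolume_ml",
)

#: tolerance (percentage points) between declared cover and the cover implied
#: by per-nodule areas
COVER_CONSISTENCY_PP = 1.0


class SchemaError(ValueError):
    """A required column is missing or a cell cannot be parsed."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


class ReferentialError(ValueError):
    """A specimen points at an image that does not exist."""


@dataclass
class ImageRecord:
    """One seafloor photograph and its nodule-cover measurement."""

    image_id: str
    transect_id: str
    landscape: str
    sequence_index: int
    altitude: float          # m above seafloor
    area: float              # m^2 of imaged seabed
    cover: float             # % of imaged area occupied by nodules
    nodule_areas: list[float] | None = None   # cm^2, individually delineated
    junction_flag: bool = False

    def __post_init__(self) -> None:
        if self.landscape not in LANDSCAPES:
            raise ValidationError(
                f"image {self.image_id!r}: landscape {self.landscape!r} "
                f"not one of {LANDSCAPES}")
        if self.sequence_index < 0:
            raise ValidationError(
                f"image {self.image_id!r}: sequence_index must be >= 0")
        if not self.altitude > 0:
            raise ValidationError(
                f"image {self.image_id!r}: altitude must be > 0 m")
        if not self.area > 0:
            raise ValidationError(
                f"image {self.image_id!r}: area must be > 0 m^2")
        if not 0.0 <= self.cover <= 100.0:
            raise ValidationError(
                f"image {self.image_id!r}: cover {self.cover} outside [0, 100]%")
        if self.nodule_areas is not None:
            if any(a <= 0 for a in self.nodule_areas):
                raise ValidationError(
                    f"image {self.image_id!r}: nodule areas must be > 0 cm^2")
            implied = sum(self.nodule_areas) / (self.area * 1e4) * 100.0
            if abs(implied - self.cover) > COVER_CONSISTENCY_PP:
                raise ValidationError(
                    f"image {self.image_id!r}: nodule areas imply "
                    f"{implied:.2f}% cover but cover_pct is {self.cover:.2f}%")


@dataclass
class SpecimenRecord:
    """One annotated individual (metazoan or xenophyophore)."""

    specimen_id: str
    image_id: str
    morphospecies: str
    group: str
    life_habit: str = "unknown"
    feeding: str = "unknown"
    body_length: float | None = None   # cm
    biovolume: float | None = None     # mL (~ g fresh wet weight)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"specimen {self.specimen_id!r}: group {self.group!r} "
                f"not one of {GROUPS}")
        if self.life_habit not in LIFE_HABITS:
            warnings.warn(
                f"specimen {self.specimen_id!r}: unknown life habit "
                f"{self.life_habit!r} mapped to 'unknown'")
            self.life_habit = "unknown"
        if self.feeding not in FEEDING_GROUPS:
            warnings.warn(
                f"specimen {self.specimen_id!r}: unknown feeding group "
                f"{self.feeding!r} mapped to 'unknown'")
            self.feeding = "unknown"
        if self.body_length is not None and not self.body_length > 0:
            raise ValidationError(
                f"specimen {self.specimen_id!r}: body length must be > 0 cm")
        if self.biovolume is not None and self.biovolume < 0:
            raise ValidationError(
                f"specimen {self.specimen_id!r}: biovolume must be >= 0 mL")


@dataclass
class SurveyDataset:
    """Images plus specimens with enforced referential integrity."""

    images: list[ImageRecord]
    specimens: list[SpecimenRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        image_ids = [im.image_id for im in self.images]
        if len(set(image_ids)) != len(image_ids):
            dupes = sorted({i for i in image_ids if image_ids.count(i) > 1})
            raise ValidationError(f"duplicate image_id(s): {dupes[:5]}")
        specimen_ids = [sp.specimen_id for sp in self.specimens]
        if len(set(specimen_ids)) != len(specimen_ids):
            dupes = sorted({i for i in specimen_ids if specimen_ids.count(i) > 1})
            raise ValidationError(f"duplicate specimen_id(s): {dupes[:5]}")
        known = set(image_ids)
        dangling = sorted({sp.image_id for sp in self.specimens
                           if sp.image_id not in known})
        if dangling:
            raise ReferentialError(
                f"{len(dangling)} specimen image_id(s) have no image record: "
                f"{dangling[:10]}")

    def subset_images(self, keep: list[ImageRecord]) -> "SurveyDataset":
        """Restrict to ``keep`` images; specimens on dropped images are removed."""
        ids = {im.image_id for im in keep}
        return SurveyDataset(
            images=list(keep),
            specimens=[sp for sp in self.specimens if sp.image_id in ids],
            provenance=dict(self.provenance),
        )


# ---------------------------------------------------------------------------
# tabular IO


def _sep(dialect: str) -> str:
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"dialect must be 'tsv' or 'csv', got {dialect!r}")
    return "\t" if dialect == "tsv" else ","


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _parse_nodule_areas(cell) -> list[float] | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    text = str(cell).strip()
    if not text:
        return None
    return [float(tok) for tok in text.split(";")]


def read_image_table(path, dialect: str = "tsv") -> list[ImageRecord]:
    """Read an image table, validating every row; row order is preserved."""
    df = pd.read_csv(path, sep=_sep(dialect), dtype=str, keep_default_na=False)
    _require_columns(df, tuple(c for c in IMAGE_COLUMNS
                               if c != "nodule_areas_cm2"), path)
    records = []
    for pos, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(ImageRecord(
                image_id=row.image_id,
                transect_id=row.transect_id,
                landscape=row.landscape,
                sequence_index=int(row.sequence_index),
                altitude=float(row.altitude_m),
                area=float(row.area_m2),
                cover=float(row.cover_pct),
                nodule_areas=_parse_nodule_areas(
                    getattr(row, "nodule_areas_cm2", None)),
                junction_flag=_parse_bool(row.junction),
            ))
        except (TypeError, ValueError) as exc:
            if isinstance(exc, ValidationError):
                raise
            raise SchemaError(f"{path} line {pos}: {exc}") from exc
    return records


def _parse_bool(cell) -> bool:
    text = str(cell).strip().lower()
    if text in ("1", "true", "t", "yes"):
        return True
    if text in ("0", "false", "f", "no", ""):
        return False
    raise ValueError(f"unparsable boolean {cell!r}")


def _opt_float(cell) -> float | None:
    text = str(cell).strip()
    if not text or text.upper() == "NA":
        return None
    return float(text)


def read_specimen_table(path, dialect: str = "tsv") -> list[SpecimenRecord]:
    """Read a specimen table; unknown categorical labels degrade to 'unknown'."""
    df = pd.read_csv(path, sep=_sep(dialect), dtype=str, keep_default_na=False)
    _require_columns(df, SPECIMEN_COLUMNS, path)
    records = []
    for pos, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(SpecimenRecord(
                specimen_id=row.specimen_id,
                image_id=row.image_id,
                morphospecies=row.morphospecies,
                group=row.group,
                life_habit=row.life_habit,
                feeding=row.feeding,
                body_length=_opt_float(row.body_length_cm),
                biovolume=_opt_float(row.biovolume_ml),
            ))
        except (TypeError, ValueError) as exc:
            if isinstance(exc, ValidationError):
                raise
            raise SchemaError(f"{path} line {pos}: {exc}") from exc
    return records


def images_to_frame(images: list[ImageRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "image_id": [im.image_id for im in images],
        "transect_id": [im.transect_id for im in images],
        "landscape": [im.landscape for im in images],
        "sequence_index": [im.sequence_index for im in images],
        "altitude_m": [repr(im.altitude) for im in images],
        "area_m2": [repr(im.area) for im in images],
        "cover_pct": [repr(im.cover) for im in images],
        "nodule_areas_cm2": [
            "" if im.nodule_areas is None
            else ";".join(repr(a) for a in im.nodule_areas)
            for im in images],
        "junction": [int(im.junction_flag) for im in images],
    })


def specimens_to_frame(specimens: list[SpecimenRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "specimen_id": [sp.specimen_id for sp in specimens],
        "image_id": [sp.image_id for sp in specimens],
        "morphospecies": [sp.morphospecies for sp in specimens],
        "group": [sp.group for sp in specimens],
        "life_habit": [sp.life_habit for sp in specimens],
        "feeding": [sp.feeding for sp in specimens],
        "body_length_cm": ["" if sp.body_length is None else repr(sp.body_length)
                           for sp in specimens],
        "biovolume_ml": ["" if sp.biovolume is None else repr(sp.biovolume)
                         for sp in specimens],
    })


def write_image_table(images: list[ImageRecord], path,
                      dialect: str = "tsv") -> None:
    """Write images so that ``read_image_table`` round-trips bit-equal floats."""
    images_to_frame(images).to_csv(path, sep=_sep(dialect), index=False)


def write_specimen_table(specimens: list[SpecimenRecord], path,
                         dialect: str = "tsv") -> None:
    specimens_to_frame(specimens).to_csv(path, sep=_sep(dialect), index=False)


# ---------------------------------------------------------------------------
# quality control


def qc_filter(images: list[ImageRecord], altitude_min: float = 2.0,
              altitude_max: float = 4.0) -> list[ImageRecord]:
    """Apply the survey's photographic quality-control filters, in order.

    1. drop images flagged as transect junctions (vehicle turning);
    2. within each transect keep every second remaining image, starting from
       the first, to avoid overlap between consecutive frames;
    3. drop images outside the ``[altitude_min, altitude_max]`` altitude
       window (consistent specimen/nodule detectability).

    Input order is preserved; an empty result is permitted.
    """
    no_junction = [im for im in images if not im.junction_flag]
    position: dict[str, int] = {}
    alternated = []
    for im in no_junction:
        k = position.get(im.transect_id, 0)
        if k % 2 == 0:
            alternated.append(im)
        position[im.transect_id] = k + 1
    return [im for im in alternated
            if altitude_min <= im.altitude <= altitude_max]


def area_from_altitude(altitude: float, reference_area: float = 1.71,
                       reference_altitude: float = 3.0) -> float:
    """Imaged seabed area (m^2) at ``altitude``, scaled from a reference.

    A fixed camera field of view makes the footprint scale with the square of
    altitude; the survey reference is 1.71 m^2 at the 3 m target altitude.
    """
    if altitude <= 0 or reference_area <= 0 or reference_altitude <= 0:
        raise ValueError("altitude, reference_area and reference_altitude "
                         "must all be > 0")
    return reference_area * (altitude / reference_altitude) ** 2
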