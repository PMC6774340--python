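"""Equal-specimen-count partition of images along the nodule-cover gradient.

Images are ordered by nodule cover and split into ``k`` contiguous classes at
cover breakpoints chosen so each class holds approximately equal numbers of
focal-group specimens (a greedy sweep against cumulative-count targets
round(j*T/k)).  Metazoans and xenophyophores are partitioned separately; the
compositional analyses reuse the metazoan class boundaries by default.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survey import ImageRecord, SpecimenRecord


class PartitionError(ValueError):
    """The requested partition is infeasible."""


@dataclass(frozen=True)
class CoverClass:
    class_index: int          # 1..k, ordered by increasing cover
    cover_low: float          # % (min member cover)
    cover_high: float         # % (max member cover)
    image_ids: tuple
    specimen_count: int       # focal-group specimens in the class
    mean_cover: float         # % (unweighted mean over member images)


@dataclass(frozen=True)
class CoverClassPartition:
    k: int
    focal_group: str
    classes: tuple

    def class_of(self) -> dict:
        """image_id -> class_index lookup."""
        return {iid: c.class_index for c in self.classes for iid in c.image_ids}

    @property
    def mean_covers(self) -> np.ndarray:
        return np.array([c.mean_cover for c in self.classes])


def partition_equal_count(images: list[ImageRecord],
                          specimens: list[SpecimenRecord],
                          k: int = 10,
                          focal_group: str = "metazoan") -> CoverClassPartition:
    """Greedy equal-count partition of cover-ordered images into k classes.

    Images are sorted by (cover, image_id); class j is closed at the first
    image where the cumulative focal-group specimen count reaches
    round(j*T/k), T being the focal-group total.  Each class is guaranteed at
    least one image, and the last class absorbs the remainder, so classes are
    contiguous and exhaustive.  The partition is invariant to input row order.
    """
    if k < 2:
        raise PartitionError("k must be >= 2")
    per_image = Counter(sp.image_id for sp in specimens
                        if sp.group == focal_group)
    total = sum(per_image.values())
    if total < k:
        raise PartitionError(
            f"{total} focal-group specimens cannot fill {k} classes")
    ordered = sorted(images, key=lambda im: (im.cover, im.image_id))
    if len(ordered) < k:
        raise PartitionError(f"{len(ordered)} images cannot fill {k} classes")

    classes: list[CoverClass] = []
    cum = 0
    members: list[ImageRecord] = []
    count = 0
    j = 1
    for pos, im in enumerate(ordered):
        members.append(im)
        c = per_image.get(im.image_id, 0)
        cum += c
        count += c
        remaining_images = len(ordered) - pos - 1
        # close class j at the first image reaching the cumulative target;
        # force a close when only one image per remaining class is left, so
        # every class is non-empty
        close = (j < k
                 and remaining_images >= k - j
                 and (cum >= round(j * total / k)
                      or remaining_images == k - j))
        if close:
            classes.append(_make_class(j, members, count))
            members, count = [], 0
            j += 1
    classes.append(_make_class(j, members, count))
    assert j == k and len(classes) == k
    return CoverClassPartition(k=k, focal_group=focal_group,
                               classes=tuple(classes))


def _make_class(index: int, members: list[ImageRecord],
                count: int) -> CoverClass:
    covers = [im.cover for im in members]
    return CoverClass(
        class_index=index,
        cover_low=min(covers),
        cover_high=max(covers),
        image_ids=tuple(im.image_id for im in members),
        specimen_count=count,
        mean_cover=float(np.mean(covers)),
    )


def class_summary_table(partition: CoverClassPartition) -> pd.DataFrame:
    """One row per class: cover interval, image count, specimen count."""
    return pd.DataFrame([{
        "class_index": c.class_index,
        "cover_low": c.cover_low,
        "cover_high": c.cover_high,
        "n_images": len(c.image_ids),
        "specimen_count": c.specimen_count,
        "mean_cover": c.mean_cover,
    } for c in partition.classes])


def write_partition_table(partition: CoverClassPartition, path) -> None:
    class_summary_table(partition).to_csv(path, sep="\t", index=False,
                                          float_format="%.6g")
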