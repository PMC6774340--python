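"""Count- and area-controlled bootstrap-like resampling of survey images.

Within one nodule-cover class, images are drawn uniformly with replacement
until a stopping rule is met:

* **count rule** — stop at the first draw where the accumulated focal-group
  specimen count reaches ``min_count`` (the last drawn image is kept, so the
  overshoot is bounded by the largest per-image count);
* **area rule** — draw until the accumulated seabed area reaches
  ``area_low``; the attempt is accepted only if the total stays within
  ``area_high``, otherwise it is discarded and redrawn from scratch.

Each rule is repeated ``reps`` times, giving replicate samples whose
per-replicate statistics are summarized by a mean/median and a simple
percentile 95% confidence interval.

Random streams: a root seed spawns one independent child stream per
(class, rule) via :class:`numpy.random.SeedSequence`, so classes can be
recomputed independently and bit-identically.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .survey import ImageRecord, SpecimenRecord


class ResamplingError(ValueError):
    """The stopping rule cannot be satisfied on this class."""


class ContractError(TypeError):
    """A statistic was requested from samples built under the wrong rule."""


@dataclass
class SpecimenIndex:
    """Columnar view of one image class for fast resampling.

    ``counts[i, s]`` is the number of specimens of species ``s`` (column order
    ``species``) on image ``i`` (row order ``image_ids``); ``focal`` restricts
    to the focal group; ``biovolume`` holds per-image summed metazoan
    biovolume (NaN where any metazoan lacks one).
    """

    image_ids: np.ndarray          # (n,) str
    areas: np.ndarray              # (n,) m^2
    species: tuple                 # (S,) morphospecies names, sorted
    species_group: np.ndarray      # (S,) group label per species
    species_life_habit: np.ndarray
    species_feeding: np.ndarray
    counts: np.ndarray             # (n, S) int
    focal_group: str
    biovolume: np.ndarray          # (n,) mL, metazoans summed

    @property
    def focal_counts(self) -> np.ndarray:
        return self.counts[:, self.species_group == self.focal_group].sum(axis=1)

    @classmethod
    def build(cls, images: list[ImageRecord], specimens: list[SpecimenRecord],
              focal_group: str = "metazoan",
              species_universe: tuple | None = None) -> "SpecimenIndex":
        row = {im.image_id: i for i, im in enumerate(images)}
        if species_universe is None:
            species_universe = tuple(sorted({sp.morphospecies
                                             for sp in specimens}))
        col = {name: j for j, name in enumerate(species_universe)}
        n, S = len(images), len(species_universe)
        counts = np.zeros((n, S), dtype=np.int64)
        biovol = np.zeros(n)
        missing_biovol = np.zeros(n, dtype=bool)
        meta = {}
        for sp in specimens:
            i = row.get(sp.image_id)
            if i is None:
                continue
            counts[i, col[sp.morphospecies]] += 1
            meta.setdefault(sp.morphospecies,
                            (sp.group, sp.life_habit, sp.feeding))
            if sp.group == "metazoan":
                if sp.biovolume is None:
                    missing_biovol[i] = True
                else:
                    biovol[i] += sp.biovolume
        biovol[missing_biovol] = np.nan
        groups = np.array([meta.get(s, ("metazoan", "unknown", "unknown"))[0]
                           for s in species_universe])
        habits = np.array([meta.get(s, ("", "unknown", ""))[1]
                           for s in species_universe])
        feeding = np.array([meta.get(s, ("", "", "unknown"))[2]
                            for s in species_universe])
        return cls(
            image_ids=np.array([im.image_id for im in images]),
            areas=np.array([im.area for im in images]),
            species=species_universe,
            species_group=groups,
            species_life_habit=habits,
            species_feeding=feeding,
            counts=counts,
            focal_group=focal_group,
            biovolume=biovol,
        )


@dataclass
class BootstrapSample:
    """One resampled image multiset with its tallies (materialized view)."""

    class_index: int
    rule: str                      # "count" | "area"
    draws: np.ndarray              # image_ids with multiplicity, draw order
    n_images: int
    total_area: float              # m^2, with multiplicity
    focal_count: int
    abundance: dict                # morphospecies -> count, zeros omitted


@dataclass
class BootstrapSet:
    """``reps`` replicate samples from one class under one stopping rule.

    Per-replicate scalars are stored as arrays; per-replicate species
    abundance is materialized lazily (``abundance_matrix``) because many
    summaries (density, biovolume) never need it.
    """

    class_index: int
    rule: str                      # "count" | "area"
    rule_params: dict
    seed_key: tuple
    index: SpecimenIndex
    draw_indices: list             # reps arrays of image row indices
    focal_counts: np.ndarray       # (reps,)
    total_areas: np.ndarray        # (reps,)
    _abundance: np.ndarray | None = field(default=None, repr=False)

    @property
    def reps(self) -> int:
        return len(self.draw_indices)

    def abundance_matrix(self) -> np.ndarray:
        """(reps, S) specimen counts per replicate, all species columns."""
        if self._abundance is None:
            n = len(self.index.image_ids)
            mult = np.zeros((self.reps, n))
            for r, idx in enumerate(self.draw_indices):
                mult[r] = np.bincount(idx, minlength=n)
            self._abundance = mult @ self.index.counts
        return self._abundance

    def multiplicity_dot(self, per_image: np.ndarray) -> np.ndarray:
        """Sum a per-image quantity over each replicate, with multiplicity."""
        return np.array([per_image[idx].sum() for idx in self.draw_indices])

    def samples(self):
        """Materialize :class:`BootstrapSample` views (iterator)."""
        ab = self.abundance_matrix()
        for r, idx in enumerate(self.draw_indices):
            abundance = {s: int(c) for s, c in zip(self.index.species, ab[r])
                         if c > 0}
            yield BootstrapSample(
                class_index=self.class_index,
                rule=self.rule,
                draws=self.index.image_ids[idx],
                n_images=len(idx),
                total_area=float(self.total_areas[r]),
                focal_count=int(self.focal_counts[r]),
                abundance=abundance,
            )


def class_rng(seed: int, class_index: int, rule: str,
              group: str = "metazoan") -> np.random.Generator:
    """Deterministic per-(group, class, rule) child stream from a root seed."""
    rule_code = {"count": 0, "area": 1}[rule]
    group_code = {"metazoan": 0, "xenophyophore": 1}.get(group, 2)
    ss = np.random.SeedSequence(entropy=seed,
                                spawn_key=(group_code, class_index, rule_code))
    return np.random.default_rng(ss)


def _draw_block(rng, n_images: int, reps: int, block: int) -> np.ndarray:
    return rng.integers(0, n_images, size=(reps, block))


def bootstrap_by_count(index: SpecimenIndex, class_index: int,
                       min_count: int = 500, reps: int = 1000,
                       rng=None, seed: int | None = None) -> BootstrapSet:
    """Resample images with replacement until >= ``min_count`` focal specimens.

    Stopping is minimal: removing the last drawn image would leave the count
    below ``min_count``.
    """
    if rng is None:
        rng = class_rng(0 if seed is None else seed, class_index, "count",
                        index.focal_group)
    focal = index.focal_counts
    n = len(focal)
    if n == 0 or focal.sum() == 0:
        raise ResamplingError(
            f"class {class_index}: no focal-group specimens; the count rule "
            "would never terminate")
    mean = focal.mean()
    if mean == 0:
        raise ResamplingError(f"class {class_index}: zero mean focal count")
    expected = min_count / mean
    block = int(expected + 10.0 * math.sqrt(expected) + 16)

    draws = _draw_block(rng, n, reps, block)
    cum = focal[draws].cumsum(axis=1)
    # extend the rare replicates that did not reach the target in one block
    while True:
        unfinished = np.flatnonzero(cum[:, -1] < min_count)
        if unfinished.size == 0:
            break
        extra = _draw_block(rng, n, len(unfinished), block)
        draws = np.concatenate([draws, np.zeros_like(draws[:, :block])], axis=1)
        draws[unfinished, -block:] = extra
        add = focal[extra].cumsum(axis=1) + cum[unfinished, -1][:, None]
        cum = np.concatenate(
            [cum, np.tile(cum[:, -1][:, None], (1, block))], axis=1)
        cum[unfinished, -block:] = add

    stop = (cum < min_count).sum(axis=1)       # index of the stopping draw
    draw_indices = [draws[r, :stop[r] + 1] for r in range(reps)]
    focal_counts = cum[np.arange(reps), stop]
    total_areas = np.array([index.areas[idx].sum() for idx in draw_indices])
    return BootstrapSet(
        class_index=class_index, rule="count",
        rule_params={"min_count": min_count, "reps": reps},
        seed_key=(class_index, "count"),
        index=index, draw_indices=draw_indices,
        focal_counts=focal_counts.astype(int), total_areas=total_areas)


def bootstrap_by_area(index: SpecimenIndex, class_index: int,
                      area_low: float = 650.0, area_high: float = 670.0,
                      reps: int = 1000, rng=None, seed: int | None = None,
                      max_rejections: int = 1000) -> BootstrapSet:
    """Resample until cumulative area >= ``area_low``; accept if <= ``area_high``.

    Rejected attempts (overshooting the window) are redrawn from scratch;
    ``max_rejections`` consecutive rejections raise a configuration error
    advising a wider window.
    """
    if not 0 < area_low <= area_high:
        raise ResamplingError("need 0 < area_low <= area_high")
    areas = index.areas
    n = len(areas)
    if n == 0:
        raise ResamplingError(f"class {class_index}: empty image class")
    if areas.min() > area_high:
        raise ResamplingError(
            f"class {class_index}: smallest image area {areas.min():.3g} m^2 "
            f"exceeds area_high={area_high} m^2")
    if rng is None:
        rng = class_rng(0 if seed is None else seed, class_index, "area",
                        index.focal_group)
    mean = areas.mean()
    expected = area_low / mean
    block = int(expected + 10.0 * math.sqrt(expected) + 16)

    draw_indices: list = []
    focal = index.focal_counts
    rejections = 0
    while len(draw_indices) < reps:
        pend = reps - len(draw_indices)
        draws = _draw_block(rng, n, pend, block)
        cum = areas[draws].cumsum(axis=1)
        while (cum[:, -1] < area_low).any():
            unfinished = np.flatnonzero(cum[:, -1] < area_low)
            extra = _draw_block(rng, n, len(unfinished), block)
            draws = np.concatenate(
                [draws, np.zeros_like(draws[:, :block])], axis=1)
            draws[unfinished, -block:] = extra
            add = areas[extra].cumsum(axis=1) + cum[unfinished, -1][:, None]
            cum = np.concatenate(
                [cum, np.tile(cum[:, -1][:, None], (1, block))], axis=1)
            cum[unfinished, -block:] = add
        stop = (cum < area_low).sum(axis=1)
        totals = cum[np.arange(pend), stop]
        accepted = totals <= area_high
        for r in np.flatnonzero(accepted):
            draw_indices.append(draws[r, :stop[r] + 1])
        n_rej = int((~accepted).sum())
        rejections = 0 if accepted.any() else rejections + n_rej
        if rejections >= max_rejections:
            raise ResamplingError(
                f"class {class_index}: {rejections} consecutive rejections; "
                f"the area window [{area_low}, {area_high}] m^2 is too narrow "
                "for these image areas — widen it")
    draw_indices = draw_indices[:reps]
    focal_counts = np.array([focal[idx].sum() for idx in draw_indices])
    total_areas = np.array([areas[idx].sum() for idx in draw_indices])
    return BootstrapSet(
        class_index=class_index, rule="area",
        rule_params={"area_low": area_low, "area_high": area_high,
                     "reps": reps},
        seed_key=(class_index, "area"),
        index=index, draw_indices=draw_indices,
        focal_counts=focal_counts, total_areas=total_areas)


def summarize_bootstrap(values, center: str = "mean",
                        level: float = 0.95) -> tuple[float, float, float]:
    """Center and simple-percentile confidence interval of replicate values.

    The interval uses the order statistics at ranks floor((B+1)*alpha) and
    ceil((B+1)*(1-alpha)) with alpha = (1-level)/2, clamped to [1, B]; for
    B = 1000 and level 0.95 these are ranks 25 and 976.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2 or not np.isfinite(v).all():
        raise ValueError("need >= 2 finite replicate values")
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    b = v.size
    alpha = (1.0 - level) / 2.0
    lo_rank = min(max(math.floor((b + 1) * alpha), 1), b)
    hi_rank = min(max(math.ceil((b + 1) * (1.0 - alpha)), 1), b)
    s = np.sort(v)
    ctr = float(np.mean(v) if center == "mean" else np.median(v))
    return ctr, float(s[lo_rank - 1]), float(s[hi_rank - 1])
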