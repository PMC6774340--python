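"""Per-replicate ecological statistics.

Standing stocks (numerical density, biovolume density), Hill diversity
numbers of orders 0/1/2 expressed as effective species counts, morphospecies
density from area-controlled samples, functional-group densities, and the
square-root-transformed abundance matrix feeding the ordination.

Density conventions: a re-drawn image contributes its specimens *and* its
area again (multiplicity appears in both numerator and denominator).
Diversity is computed on metazoan morphospecies by default; xenophyophores
contribute standing stocks only.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bootstrap import BootstrapSample, BootstrapSet, ContractError, SpecimenIndex


@dataclass(frozen=True)
class DiversityProfile:
    """Hill numbers of orders 0, 1, 2 as effective numbers of morphospecies."""

    richness: int            # S_N, order 0
    exp_shannon: float       # exp(H'), order 1, natural log
    inv_simpson: float       # 1/D, order 2


def hill_numbers(counts) -> DiversityProfile:
    """Hill diversity from an abundance vector.

    S_N = number of species with n_i > 0; exp H' = exp(-sum p_i ln p_i)
    (0 ln 0 = 0); 1/D = 1 / sum p_i^2, with p_i = n_i / N.  Requires N > 0.
    """
    n = np.asarray(list(counts.values()) if isinstance(counts, dict)
                   else counts, dtype=float)
    if (n < 0).any():
        raise ValueError("abundances must be >= 0")
    total = n.sum()
    if total <= 0:
        raise ValueError("Hill numbers undefined for an empty sample (N = 0)")
    p = n[n > 0] / total
    return DiversityProfile(
        richness=int((n > 0).sum()),
        exp_shannon=float(np.exp(-(p * np.log(p)).sum())),
        inv_simpson=float(1.0 / (p ** 2).sum()),
    )


# ---------------------------------------------------------------------------
# per-sample statistics (contract-level operations)


def numerical_density(sample: BootstrapSample, index: SpecimenIndex,
                      group: str | None = None) -> float:
    """Specimens per m^2 over the sample's accumulated area, optional group filter."""
    if sample.total_area <= 0:
        raise ValueError("zero total area")
    if group is None:
        matched = sum(sample.abundance.values())
    else:
        cols = {s for s, g in zip(index.species, index.species_group)
                if g == group}
        matched = sum(c for s, c in sample.abundance.items() if s in cols)
    return matched / sample.total_area


def biovolume_density(sample: BootstrapSample, index: SpecimenIndex) -> float:
    """Metazoan biovolume (mL) per m^2; errors if any metazoan lacks biovolume."""
    row = {iid: i for i, iid in enumerate(index.image_ids)}
    total = 0.0
    for iid in sample.draws:
        v = index.biovolume[row[iid]]
        if np.isnan(v):
            raise ValueError(
                f"image {iid!r} has metazoan specimens without biovolume")
        total += v
    return total / sample.total_area


def morphospecies_density(sample: BootstrapSample,
                          index: SpecimenIndex) -> int:
    """S_A: distinct focal-group morphospecies in an area-controlled sample."""
    if sample.rule != "area":
        raise ContractError(
            "morphospecies density (S_A) is defined on area-controlled "
            f"samples; got a {sample.rule!r}-controlled sample")
    focal = {s for s, g in zip(index.species, index.species_group)
             if g == index.focal_group}
    return sum(1 for s, c in sample.abundance.items()
               if c > 0 and s in focal)


def group_densities(sample: BootstrapSample, index: SpecimenIndex,
                    grouping: str = "life_habit") -> dict:
    """Densities by life habit, feeding group, or higher taxon.

    Higher taxa are read from the morphospecies name prefix (the token before
    ``-msp``).  Densities over the groups of a partition sum to the matching
    total density (the 'unknown' category included).
    """
    if sample.total_area <= 0:
        raise ValueError("zero total area")
    labels = _species_labels(index, grouping)
    out: dict = {}
    for s, c in sample.abundance.items():
        lab = labels[s]
        out[lab] = out.get(lab, 0) + c
    return {lab: c / sample.total_area for lab, c in sorted(out.items())}


def _species_labels(index: SpecimenIndex, grouping: str) -> dict:
    if grouping == "life_habit":
        return dict(zip(index.species, index.species_life_habit))
    if grouping == "feeding":
        return dict(zip(index.species, index.species_feeding))
    if grouping == "higher_taxon":
        return {s: s.split("-msp")[0] for s in index.species}
    raise ValueError(f"unknown grouping {grouping!r}")


# ---------------------------------------------------------------------------
# vectorized per-replicate statistics for a whole BootstrapSet


def density_replicates(bset: BootstrapSet, group: str | None = None,
                       species_mask=None) -> np.ndarray:
    """Per-replicate numerical density (ind m^-2), optional group/species filter."""
    if species_mask is None:
        if group is None:
            mask = np.ones(len(bset.index.species), dtype=bool)
        else:
            mask = bset.index.species_group == group
    else:
        mask = np.asarray(species_mask, dtype=bool)
    if group is not None and species_mask is None \
            and group == bset.index.focal_group:
        # the focal totals were accumulated during drawing; avoid the matrix
        return bset.focal_counts / bset.total_areas
    counts = bset.abundance_matrix()[:, mask].sum(axis=1)
    return counts / bset.total_areas


def biovolume_replicates(bset: BootstrapSet) -> np.ndarray:
    """Per-replicate metazoan biovolume density (mL m^-2)."""
    if np.isnan(bset.index.biovolume).any():
        bad = bset.index.image_ids[np.isnan(bset.index.biovolume)]
        raise ValueError(
            f"{bad.size} image(s) carry metazoans without biovolume, e.g. "
            f"{bad[:5].tolist()}")
    totals = bset.multiplicity_dot(bset.index.biovolume)
    return totals / bset.total_areas


def diversity_replicates(bset: BootstrapSet,
                         group: str = "metazoan") -> pd.DataFrame:
    """Per-replicate Hill numbers (columns S_N, expH, invD)."""
    ab = bset.abundance_matrix()[:, bset.index.species_group == group]
    rows = []
    for r in range(ab.shape[0]):
        prof = hill_numbers(ab[r])
        rows.append((prof.richness, prof.exp_shannon, prof.inv_simpson))
    return pd.DataFrame(rows, columns=["S_N", "expH", "invD"])


def richness_replicates(bset: BootstrapSet,
                        group: str | None = None) -> np.ndarray:
    """Per-replicate morphospecies richness (S_A when the set is area-controlled)."""
    if bset.rule != "area":
        raise ContractError(
            "S_A requires an area-controlled BootstrapSet; got "
            f"{bset.rule!r}-controlled")
    if group is None:
        group = bset.index.focal_group
    ab = bset.abundance_matrix()[:, bset.index.species_group == group]
    return (ab > 0).sum(axis=1)


def group_density_replicates(bset: BootstrapSet, grouping: str,
                             restrict_group: str | None = "metazoan"
                             ) -> pd.DataFrame:
    """Per-replicate densities by functional group (columns = group labels)."""
    labels = _species_labels(bset.index, grouping)
    lab_arr = np.array([labels[s] for s in bset.index.species])
    in_scope = np.ones(len(bset.index.species), dtype=bool)
    if restrict_group is not None:
        in_scope = bset.index.species_group == restrict_group
    ab = bset.abundance_matrix()
    out = {}
    for lab in sorted(set(lab_arr[in_scope])):
        mask = (lab_arr == lab) & in_scope
        out[lab] = ab[:, mask].sum(axis=1) / bset.total_areas
    return pd.DataFrame(out)


def abundance_matrix(bsets: list[BootstrapSet], transform: str = "sqrt",
                     group: str = "metazoan") -> pd.DataFrame:
    """Stacked (replicate x morphospecies) transformed-density matrix.

    Entries are sqrt(count/total_area) (or raw densities with
    ``transform=None``); all-zero species columns are preserved; the row
    index records (class_index, replicate).
    """
    if not bsets:
        raise ValueError("no bootstrap sets supplied")
    species = bsets[0].index.species
    mask = bsets[0].index.species_group == group
    for b in bsets:
        if b.index.species != species:
            raise ValueError("bootstrap sets use different species universes")
    blocks, idx = [], []
    for b in bsets:
        dens = b.abundance_matrix()[:, mask] / b.total_areas[:, None]
        blocks.append(dens)
        idx.extend((b.class_index, r) for r in range(b.reps))
    X = np.vstack(blocks)
    if transform == "sqrt":
        X = np.sqrt(X)
    elif transform is not None:
        raise ValueError(f"unknown transform {transform!r}")
    cols = tuple(np.array(species)[mask])
    return pd.DataFrame(
        X, columns=cols,
        index=pd.MultiIndex.from_tuples(idx, names=["class_index",
                                                    "replicate"]))
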