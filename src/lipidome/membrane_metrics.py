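"""Membrane biophysics statistics: DBI, MCL and charge-composition profiles.

For a set of lipids with abundance weights, the double-bond index (DBI)
and mean chain length (MCL) are abundance-weighted means,

    DBI = Σᵢ dᵢ·wᵢ / Σᵢ wᵢ          MCL = Σᵢ Lᵢ·wᵢ / Σᵢ wᵢ

where dᵢ is lipid i's total double-bond count, Lᵢ its total acyl carbon
count, and wᵢ its log2-transformed abundance.  DBI proxies membrane
unsaturation (fluidity) and MCL bilayer thickness.  They are computed
over the differential lipids of a comparison by convention, with an
option to extend to all detected lipids for exploratory use.

Weights must be positive for the weighted-mean reading to hold, so the
convenience wrapper :func:`membrane_indices` takes log2 *raw*
intensities, before median centering (centered values can be negative).
A caller who insists on centered values must shift them positive first;
the primitive rejects negative weights with that advice.

The charge profile aggregates total-normalized abundances into headgroup
net-charge classes per sample: anionic = PG + CL, zwitterionic =
PC + PE, neutral = DG + TG + sphingolipids (Cer, HexCer).  The default
basis excludes PA from the profile — exactly the enumeration used in
temporal net-charge figures — while ``all_classes`` includes PA under
anionic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from lipidome.nomenclature import LipidSpecies, chain_summary
from lipidome.preprocess import IntensityMatrix

__all__ = [
    "MembraneIndices",
    "ChargeProfile",
    "double_bond_index",
    "mean_chain_length",
    "membrane_indices",
    "charge_profile",
]

#: Charge-class membership used by profiles.  ``fig8_classes_only``
#: drops PA entirely; ``all_classes`` counts it as anionic.
PROFILE_CLASSES = {
    "fig8_classes_only": {
        "anionic": ("PG", "CL"),
        "zwitterionic": ("PC", "PE"),
        "neutral": ("DG", "TG", "Cer", "HexCer"),
    },
    "all_classes": {
        "anionic": ("PG", "CL", "PA"),
        "zwitterionic": ("PC", "PE"),
        "neutral": ("DG", "TG", "Cer", "HexCer"),
    },
}


@dataclass
class MembraneIndices:
    """DBI and MCL over a stated lipid subset."""

    dbi: float
    mcl: float
    n_lipids_used: int
    subset_description: str = ""


@dataclass
class ChargeProfile:
    """Per-sample anionic/zwitterionic/neutral abundance fractions."""

    fractions: pd.DataFrame  # samples × (anionic, zwitterionic, neutral)
    basis: str


def _weighted_mean(
    species_abundances: Iterable[tuple[LipidSpecies, float]],
    attribute,
) -> float:
    pairs = list(species_abundances)
    if not pairs:
        raise ValueError("empty lipid subset")
    weights = np.array([w for _, w in pairs], dtype=float)
    if np.any(weights < 0):
        raise ValueError(
            "negative abundance weight: weights are log2 raw intensities; "
            "median-centered values must be shifted positive before use"
        )
    total = weights.sum()
    if total == 0:
        raise ValueError("weights sum to zero")
    values = np.array([attribute(sp) for sp, _ in pairs], dtype=float)
    return float(np.dot(values, weights) / total)


def double_bond_index(
    species_abundances: Iterable[tuple[LipidSpecies, float]]
) -> float:
    """Abundance-weighted mean double-bond count of a lipid set."""
    return _weighted_mean(species_abundances, lambda sp: sp.total_double_bonds)


def mean_chain_length(
    species_abundances: Iterable[tuple[LipidSpecies, float]]
) -> float:
    """Abundance-weighted mean total acyl chain length of a lipid set."""
    return _weighted_mean(
        species_abundances, lambda sp: chain_summary(sp).chain_length
    )


def membrane_indices(
    m: IntensityMatrix,
    lipid_ids: Sequence[str],
    samples: Sequence[str] | None = None,
    subset_description: str = "",
) -> MembraneIndices:
    """DBI/MCL for a lipid subset of a raw-state matrix.

    Each lipid's weight is its mean log2 raw intensity over ``samples``
    (all samples when omitted), missing peaks excluded.  ``lipid_ids``
    is typically the significant set of a differential comparison.
    Ambiguous species contribute their primary annotation;
    sum-composition species their composition totals.
    """
    if m.state != "raw":
        raise ValueError(
            f"indices weight log2 raw intensities; got state {m.state!r}"
        )
    if not len(lipid_ids):
        raise ValueError("empty lipid subset")
    cols = list(samples) if samples is not None else m.sample_ids
    species = m.species()
    pairs = []
    for lipid in lipid_ids:
        sp = species.get(lipid)
        if sp is None:
            raise ValueError(f"lipid {lipid!r} is unknown or unparseable")
        row = m.values.loc[lipid, cols].astype(float)
        row = row[row > 0]
        if row.empty:
            raise ValueError(f"lipid {lipid!r} has no positive intensity")
        pairs.append((sp, float(np.log2(row).mean())))
    return MembraneIndices(
        dbi=double_bond_index(pairs),
        mcl=mean_chain_length(pairs),
        n_lipids_used=len(pairs),
        subset_description=subset_description,
    )


def charge_profile(
    m: IntensityMatrix, basis: str = "fig8_classes_only"
) -> ChargeProfile:
    """Per-sample headgroup-charge composition of a total-normalized matrix."""
    if m.state != "total_normalized":
        raise ValueError(
            f"charge profiles need total_normalized state, got {m.state!r}"
        )
    try:
        membership = PROFILE_CLASSES[basis]
    except KeyError:
        raise ValueError(
            f"unknown basis {basis!r}; choose from {sorted(PROFILE_CLASSES)}"
        ) from None
    species = m.species()
    class_of = {
        lipid: sp.lipid_class for lipid, sp in species.items() if sp is not None
    }
    sums = {}
    for charge, classes in membership.items():
        rows = [l for l in m.lipid_ids if class_of.get(l) in classes]
        sums[charge] = m.values.loc[rows].sum(axis=0, skipna=True) if rows else pd.Series(0.0, index=m.sample_ids)
    frame = pd.DataFrame(sums)
    totals = frame.sum(axis=1)
    dead = totals[totals == 0]
    if len(dead):
        raise ValueError(
            "no included-class abundance for sample(s): "
            + ", ".join(map(str, dead.index))
        )
    return ChargeProfile(fractions=frame.div(totals, axis=0), basis=basis)
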