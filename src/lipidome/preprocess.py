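"""Intensity-table ingestion and normalization.

The unit of analysis is a wide peak-intensity table: rows are lipid
species named in shorthand nomenclature, columns are samples.  Positive-
and negative-ionization-mode data arrive as separate tables and are
always normalized separately per mode; an :class:`IntensityMatrix` can
hold one mode or the row-concatenation of both.

Two normalization schemes are supported:

* ``total`` — each intensity divided by its (sample, mode) block total,
  giving compositional relative abundances (used for class-composition
  and charge profiles).
* ``log2median`` — log2 transform followed by subtraction of each
  sample's median log2 intensity within the mode (equivalently, division
  by the median intensity before the log).  This is the input state for
  differential testing, clustering and the multivariate models.

Missing peaks are carried as NaN, never as zero: they are excluded from
medians, contribute nothing to block totals, and differential tests use
only the available replicates.  No pseudocount is applied by default; a
nonpositive intensity under the log2 scheme is an error unless the
caller opts in to the half-minimum substitution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import IO, Iterable

import numpy as np
import pandas as pd

from lipidome.nomenclature import LipidNameError, LipidSpecies, parse_lipid_name

__all__ = [
    "IntensityMatrix",
    "read_intensity_table",
    "read_sample_metadata",
    "total_intensity_normalize",
    "log2_median_normalize",
    "merge_modes",
]

MODES = ("negative", "positive")
STATES = ("raw", "total_normalized", "log2_median")

#: Sample-metadata columns recognized by condition selectors.
META_FIELDS = ("salinity", "hrt", "growth_mode", "replicate", "timepoint")


@dataclass
class IntensityMatrix:
    """Lipids × samples abundance grid with per-row mode and sample metadata.

    ``values`` is indexed by unique lipid IDs (shorthand names, possibly
    with isomer suffixes) with one column per sample; NaN marks a
    missing peak.  ``mode_of`` gives each lipid's ionization mode.
    ``sample_meta`` (optional) is indexed by sample ID and provides the
    condition fields used by selectors: salinity (% NaCl), hrt (hours),
    growth_mode (planktonic/biofilm), replicate, timepoint.
    """

    values: pd.DataFrame
    mode_of: pd.Series
    sample_meta: pd.DataFrame | None = None
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate lipid IDs: {', '.join(map(str, dups))}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValueError(f"duplicate sample IDs: {', '.join(map(str, dups))}")
        missing_mode = self.values.index.difference(self.mode_of.index)
        if len(missing_mode):
            raise ValueError(f"lipids without a mode: {list(missing_mode)[:5]}")
        self.mode_of = self.mode_of.reindex(self.values.index)
        bad = set(self.mode_of.unique()) - set(MODES)
        if bad:
            raise ValueError(f"unknown ionization modes: {sorted(bad)}")
        if self.sample_meta is not None:
            extra = self.values.columns.difference(self.sample_meta.index)
            if len(extra):
                raise ValueError(
                    f"samples missing from metadata: {list(extra)[:5]}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def lipid_ids(self) -> list[str]:
        return list(self.values.index)

    def species(self) -> dict[str, LipidSpecies | None]:
        """Parse every lipid ID; unparseable IDs map to ``None``."""
        out: dict[str, LipidSpecies | None] = {}
        for name in self.values.index:
            try:
                out[name] = parse_lipid_name(name)
            except LipidNameError:
                out[name] = None
        return out

    def select_samples(self, selector: dict | None) -> list[str]:
        """Sample IDs whose metadata match every (field, value) pair.

        Values may be scalars or iterables of allowed values.  An
        unknown field, or a selector matching nothing, is an error.
        """
        if not selector:
            return self.sample_ids
        if self.sample_meta is None:
            raise ValueError("matrix has no sample metadata to select on")
        mask = pd.Series(True, index=self.sample_meta.index)
        for field_name, wanted in selector.items():
            if field_name not in self.sample_meta.columns:
                raise KeyError(
                    f"unknown metadata field {field_name!r}; available: "
                    + ", ".join(self.sample_meta.columns)
                )
            col = self.sample_meta[field_name]
            if isinstance(wanted, (list, tuple, set, frozenset)):
                mask &= col.isin(list(wanted))
            else:
                mask &= col == wanted
        chosen = [s for s in self.sample_ids if mask.get(s, False)]
        if not chosen:
            raise ValueError(f"selector {selector!r} matches no samples")
        return chosen


def read_sample_metadata(source: str | IO) -> pd.DataFrame:
    """Read a sample-metadata CSV/TSV keyed by sample ID (first column)."""
    meta = pd.read_csv(source, sep=None, engine="python", index_col=0)
    meta.index = meta.index.astype(str)
    return meta


def read_intensity_table(
    source: str | IO,
    mode: str,
    sample_meta: pd.DataFrame | None = None,
) -> IntensityMatrix:
    """Read a wide intensity table (lipids × samples) for one mode.

    The first column holds shorthand lipid names, the header row sample
    IDs.  Empty cells are missing peaks.  Every lipid name is validated
    through the nomenclature parser; a name that fails to parse keeps
    its row but triggers a warning — it stays usable for normalization
    and testing, only class-aware summaries skip it.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    df = pd.read_csv(source, sep=None, engine="python", index_col=0)
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique()
        raise ValueError(f"duplicate lipid names: {', '.join(dups)}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"non-numeric cell at lipid {row!r}, sample {col!r}: "
                f"{df.loc[row, col]!r}"
            )
        df[col] = coerced
    for name in df.index:
        try:
            parse_lipid_name(name)
        except LipidNameError as exc:
            warnings.warn(
                f"unparseable lipid name {name!r} kept unclassified: {exc}",
                stacklevel=2,
            )
    mode_of = pd.Series(mode, index=df.index)
    return IntensityMatrix(df, mode_of, sample_meta=sample_meta, state="raw")


def _iter_mode_blocks(m: IntensityMatrix) -> Iterable[tuple[str, pd.Index]]:
    for mode in MODES:
        rows = m.mode_of.index[m.mode_of == mode]
        if len(rows):
            yield mode, rows


def total_intensity_normalize(m: IntensityMatrix) -> IntensityMatrix:
    """Divide each value by its (sample, mode) block total.

    Missing peaks contribute zero to the total and stay missing.  After
    normalization every sample's within-mode sum equals 1.
    """
    if m.state != "raw":
        raise ValueError(f"expected a raw matrix, got state {m.state!r}")
    if (m.values < 0).any().any():
        raise ValueError("negative raw intensities")
    out = m.values.copy()
    for mode, rows in _iter_mode_blocks(m):
        block = out.loc[rows]
        totals = block.sum(axis=0, skipna=True)
        dead = totals[totals == 0]
        if len(dead):
            raise ValueError(
                f"all-zero {mode}-mode block for sample(s): "
                + ", ".join(map(str, dead.index))
            )
        out.loc[rows] = block / totals
    return replace(m, values=out, state="total_normalized")


def log2_median_normalize(
    m: IntensityMatrix, zero_policy: str = "error"
) -> IntensityMatrix:
    """Log2-transform, then subtract each sample's within-mode median.

    Parameters
    ----------
    zero_policy : {"error", "half_min"}
        ``error`` (default) rejects nonpositive intensities with their
        coordinates.  ``half_min`` substitutes half the smallest
        positive intensity of the same sample/mode block before the log
        — an explicit opt-in, since the upstream workflow defines no
        pseudocount.
    """
    if m.state != "raw":
        raise ValueError(f"expected a raw matrix, got state {m.state!r}")
    if zero_policy not in ("error", "half_min"):
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    vals = m.values.copy()
    nonpos = (vals <= 0).fillna(False)
    if nonpos.any().any():
        if zero_policy == "error":
            i, j = np.argwhere(nonpos.to_numpy())[0]
            raise ValueError(
                "nonpositive intensity at lipid "
                f"{vals.index[i]!r}, sample {vals.columns[j]!r}; pass "
                "zero_policy='half_min' to substitute half the minimum "
                "positive value"
            )
        for mode, rows in _iter_mode_blocks(m):
            block = vals.loc[rows]
            floor = block[block > 0].min(axis=0) / 2.0
            vals.loc[rows] = block.mask((block <= 0), floor, axis=1)
    out = np.log2(vals)
    for _mode, rows in _iter_mode_blocks(m):
        out.loc[rows] = out.loc[rows] - out.loc[rows].median(axis=0, skipna=True)
    return replace(m, values=out, state="log2_median")


def merge_modes(neg: IntensityMatrix, pos: IntensityMatrix) -> IntensityMatrix:
    """Row-concatenate the two per-mode matrices over a shared sample set."""
    if neg.state != pos.state:
        raise ValueError(
            f"mode matrices in different states: {neg.state!r} vs {pos.state!r}"
        )
    a, b = set(neg.sample_ids), set(pos.sample_ids)
    if a != b:
        diff = sorted(a.symmetric_difference(b))
        raise ValueError(f"sample sets differ between modes: {diff}")
    shared = neg.values.index.intersection(pos.values.index)
    if len(shared):
        raise ValueError(
            f"lipid ID(s) present in both modes: {list(shared)[:5]}; "
            "reconcile upstream before merging"
        )
    values = pd.concat([neg.values, pos.values[neg.values.columns]], axis=0)
    mode_of = pd.concat([neg.mode_of, pos.mode_of])
    meta = neg.sample_meta if neg.sample_meta is not None else pos.sample_meta
    return IntensityMatrix(values, mode_of, sample_meta=meta, state=neg.state)
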