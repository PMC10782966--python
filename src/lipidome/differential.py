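"""Pairwise differential-abundance testing and summary tallies.

Lipid profiles of two sample groups are compared per lipid with a
two-sided equal-variance (Student's) t-test on log2 median-centered
intensities, plus a log2 fold-change effect-size criterion.  A lipid is
called significantly differential when both thresholds are met — by
default P < 0.05 and |log2 FC| > 1.5, with a stricter (0.01, 2.5) pass
available for narrowing to the most discriminant species.  Raw p-values
are used by default (matching the threshold-pair filtering convention
of the upstream workflow); Benjamini–Hochberg adjustment is available
behind a flag.

The fold-change sign convention is ``B_over_A``: positive values mean
higher abundance in the second-listed group, so a comparison written
"13%–20%" yields positive values for species elevated at 20% salinity.
The convention used is stored on every table.

Also provided: per-subclass tallies of the significant species with a
headgroup-charge roll-up, count/percentage summaries, and a one-way
ANOVA screen for picking the most discriminant lipids across all
samples (heatmap top-k).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from lipidome.preprocess import IntensityMatrix

__all__ = [
    "DifferentialTable",
    "SubclassComposition",
    "CountSummary",
    "student_t",
    "log2_fc",
    "differential_table",
    "subclass_composition",
    "summarize_counts",
    "anova_screen",
    "approx_percent",
    "percent",
]


def approx_percent(count: float, total: float) -> float:
    """Percentage rounded to the nearest integer ("~" figures)."""
    return float(round(100.0 * count / total))


def percent(count: float, total: float, decimals: int = 1) -> float:
    """Percentage rounded to ``decimals`` places."""
    return float(round(100.0 * count / total, decimals))


def student_t(a, b) -> tuple[float, float]:
    """Two-sided equal-variance t-test; returns (t, p).

    df = nA + nB − 2.  Degenerate zero-pooled-variance inputs follow the
    convention p = 1 when the means are equal and p = 0 (with a warning)
    when they differ.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    if sp2 == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        warnings.warn(
            "zero pooled variance with unequal means: p = 0 by convention",
            stacklevel=2,
        )
        return math.copysign(float("inf"), a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def log2_fc(a, b, convention: str = "B_over_A") -> float:
    """Log2 fold change between two groups of log2-space values.

    ``B_over_A`` (default): mean(b) − mean(a), positive when elevated in
    the second-listed group.  ``A_over_B`` negates it.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("groups must be nonempty")
    fc = float(np.nanmean(b) - np.nanmean(a))
    if convention == "B_over_A":
        return fc
    if convention == "A_over_B":
        return -fc
    raise ValueError(f"unknown convention {convention!r}")


@dataclass
class DifferentialTable:
    """Per-lipid differential-abundance results for one A-vs-B comparison.

    ``table`` is indexed by lipid ID with columns: p_value, log2_fc,
    significant, direction (up_in_B / down_in_B / none), untestable,
    n_a, n_b, lipid_class, charge_class.  Untestable lipids (< 2
    replicates in either group) carry NaN statistics and are excluded
    from all counts.
    """

    table: pd.DataFrame
    label_a: str
    label_b: str
    p_threshold: float
    fc_threshold: float
    convention: str = "B_over_A"
    adjust: str = "none"

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


def _group_stats(block: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = np.sum(~np.isnan(block), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(block, axis=1)
        var = np.nanvar(block, axis=1, ddof=1)
    return n, mean, var


def differential_table(
    m: IntensityMatrix,
    selector_a: dict | list | None,
    selector_b: dict | list | None,
    p_threshold: float = 0.05,
    fc_threshold: float = 1.5,
    label_a: str | None = None,
    label_b: str | None = None,
    convention: str = "B_over_A",
    equal_var: bool = True,
    adjust: str = "none",
) -> DifferentialTable:
    """Differential-abundance table between two disjoint sample groups.

    Selectors are metadata (field → value) dicts resolved against the
    matrix's sample metadata, or explicit sample-ID lists.  The matrix
    must be in log2-median state.  ``adjust="bh"`` applies
    Benjamini–Hochberg FDR control to the p-values before thresholding.
    """
    if m.state != "log2_median":
        raise ValueError(
            f"differential testing expects log2_median state, got {m.state!r}"
        )
    if adjust not in ("none", "bh"):
        raise ValueError(f"unknown adjust {adjust!r}")
    samples_a = list(selector_a) if isinstance(selector_a, list) else m.select_samples(selector_a)
    samples_b = list(selector_b) if isinstance(selector_b, list) else m.select_samples(selector_b)
    overlap = set(samples_a) & set(samples_b)
    if overlap:
        raise ValueError(f"selectors overlap on samples: {sorted(overlap)}")
    if not samples_a or not samples_b:
        raise ValueError("both groups must be nonempty")

    block_a = m.values[samples_a].to_numpy(dtype=float)
    block_b = m.values[samples_b].to_numpy(dtype=float)
    na, ma, va = _group_stats(block_a)
    nb, mb, vb = _group_stats(block_b)

    testable = (na >= 2) & (nb >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        if equal_var:
            df = na + nb - 2
            sp2 = ((na - 1) * va + (nb - 1) * vb) / df
            se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        else:
            se2a, se2b = va / na, vb / nb
            se = np.sqrt(se2a + se2b)
            df = (se2a + se2b) ** 2 / (
                se2a**2 / (na - 1) + se2b**2 / (nb - 1)
            )
        t = (mb - ma) / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
    # degenerate: zero pooled variance
    degenerate = testable & (se == 0)
    p = np.where(degenerate & (ma == mb), 1.0, p)
    p = np.where(degenerate & (ma != mb), 0.0, p)
    if np.any(degenerate & (ma != mb)):
        warnings.warn(
            "zero-variance lipid(s) with unequal means: p = 0 by convention",
            stacklevel=2,
        )
    fc = mb - ma
    if convention == "A_over_B":
        fc = -fc
    elif convention != "B_over_A":
        raise ValueError(f"unknown convention {convention!r}")

    p = np.where(testable, p, np.nan)
    fc = np.where(testable, fc, np.nan)
    p_crit = p.copy()
    if adjust == "bh":
        mask = ~np.isnan(p)
        p_crit = np.full_like(p, np.nan)
        if mask.any():
            p_crit[mask] = stats.false_discovery_control(p[mask], method="bh")

    significant = testable & (p_crit < p_threshold) & (np.abs(fc) > fc_threshold)
    up = fc > 0 if convention == "B_over_A" else fc < 0
    direction = np.where(
        significant, np.where(up, "up_in_B", "down_in_B"), "none"
    )

    species = m.species()
    classes = [
        species[l].lipid_class if species[l] is not None else None
        for l in m.lipid_ids
    ]
    charges = [
        species[l].charge_class if species[l] is not None else None
        for l in m.lipid_ids
    ]
    table = pd.DataFrame(
        {
            "p_value": p_crit if adjust == "bh" else p,
            "log2_fc": fc,
            "significant": significant,
            "direction": direction,
            "untestable": ~testable,
            "n_a": na,
            "n_b": nb,
            "lipid_class": classes,
            "charge_class": charges,
        },
        index=pd.Index(m.lipid_ids, name="lipid"),
    )
    return DifferentialTable(
        table=table,
        label_a=label_a or ",".join(map(str, samples_a[:3])),
        label_b=label_b or ",".join(map(str, samples_b[:3])),
        p_threshold=p_threshold,
        fc_threshold=fc_threshold,
        convention=convention,
        adjust=adjust,
    )


@dataclass
class SubclassComposition:
    """Tally of significant species by lipid class with charge roll-up."""

    class_counts: dict[str, int]
    class_percent: dict[str, float]
    charge_counts: dict[str, int]
    charge_percent: dict[str, float]
    total: int
    direction: str | None = None


def subclass_composition(
    table: DifferentialTable, direction: str | None = None
) -> SubclassComposition:
    """Count significant lipids by class (lyso under the parent class).

    ``direction`` filters to "up" (up_in_B) or "down" (down_in_B);
    ``None`` keeps all significant species.  Percentages are of the
    matching total; an empty selection yields empty tallies.
    """
    sig = table.significant
    if direction == "up":
        sig = sig[sig["direction"] == "up_in_B"]
    elif direction == "down":
        sig = sig[sig["direction"] == "down_in_B"]
    elif direction is not None:
        raise ValueError(f"direction must be 'up', 'down' or None, got {direction!r}")
    sig = sig[sig["lipid_class"].notna()]
    total = len(sig)
    class_counts = sig["lipid_class"].value_counts().to_dict()
    charge_counts = sig["charge_class"].value_counts().to_dict()
    class_percent = {
        k: 100.0 * v / total for k, v in class_counts.items()
    } if total else {}
    charge_percent = {
        k: 100.0 * v / total for k, v in charge_counts.items()
    } if total else {}
    return SubclassComposition(
        class_counts=class_counts,
        class_percent=class_percent,
        charge_counts=charge_counts,
        charge_percent=charge_percent,
        total=total,
        direction=direction,
    )


@dataclass
class CountSummary:
    n_significant: int
    percent_of_detected: float
    n_up: int
    n_down: int
    percent_up: float


def summarize_counts(
    table: DifferentialTable, detected_total: int
) -> CountSummary:
    """Headline counts: significant / detected, and the up/down split.

    Percentages are raw; round with :func:`approx_percent` (nearest
    integer, for "~" figures) or :func:`percent` (one decimal).
    """
    n_sig = table.n_significant
    if detected_total < n_sig:
        raise ValueError("detected_total smaller than the significant count")
    n_up = int((table.table["direction"] == "up_in_B").sum())
    n_down = int((table.table["direction"] == "down_in_B").sum())
    return CountSummary(
        n_significant=n_sig,
        percent_of_detected=100.0 * n_sig / detected_total if detected_total else 0.0,
        n_up=n_up,
        n_down=n_down,
        percent_up=100.0 * n_up / n_sig if n_sig else 0.0,
    )


def anova_screen(
    m: IntensityMatrix, labels, k: int
) -> list[str]:
    """Top-k most discriminant lipids by one-way ANOVA across groups.

    ``labels`` maps sample → group (mapping or pandas Series).  Lipids
    are sorted by ascending p-value, ties broken by descending F then
    lexicographic ID.  With two groups the ANOVA p equals the
    equal-variance t-test p (F = t²).
    """
    labels = pd.Series(labels).reindex(m.sample_ids)
    if labels.isna().any():
        missing = labels.index[labels.isna()]
        raise ValueError(f"samples without a label: {list(missing)[:5]}")
    groups = labels.groupby(labels).groups
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    records = []
    vals = m.values
    for lipid in m.lipid_ids:
        row = vals.loc[lipid]
        parts = [
            row[list(idx)].dropna().to_numpy() for idx in groups.values()
        ]
        if any(len(part) < 2 for part in parts):
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f, p = stats.f_oneway(*parts)
        if np.isnan(p):
            continue
        records.append((lipid, float(p), float(f)))
    records.sort(key=lambda r: (r[1], -r[2], r[0]))
    if k > len(records):
        warnings.warn(
            f"k={k} exceeds the {len(records)} testable lipids; returning all",
            stacklevel=2,
        )
    return [r[0] for r in records[: max(k, 0)]]
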