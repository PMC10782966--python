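"""Synthetic lipidome generation with planted ground truth.

Emulates the statistical shape of a microbial membrane lipidomics
dataset — ~194 species across 13 subclasses split over two ionization
modes, a factorial design of salinity (7/13/20 % NaCl) × hydraulic
retention time (19.2/24/48 h) × replicate for planktonic growth plus a
biofilm arm, log-normal peak intensities with per-lipid baselines over a
realistic LC-MS dynamic range (log2 means uniform on [10, 25]), and
condition effects planted on selected lipids or subclasses on the log2
scale so ground-truth fold changes are exact.

The generator returns the raw intensity matrix together with a
:class:`SyntheticTruth` record of what was planted, so recovery,
calibration and power properties of the downstream pipeline can be
tested without any instrument data.  Missing peaks are inserted at a
configurable rate but never wipe out an entire replicate group.

All randomness flows from one integer seed; a fixed seed yields a
bit-identical matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from lipidome.nomenclature import parse_lipid_name
from lipidome.preprocess import IntensityMatrix

__all__ = [
    "PAPER_NAME_CORPUS",
    "SyntheticConfig",
    "SyntheticTruth",
    "PlantedEffect",
    "default_lipid_catalog",
    "simulate_lipidome",
    "simulate_two_group",
    "write_tables",
]

#: Shorthand names exercising every grammar feature: fully resolved
#: chains, lyso "0:0" slots, sum compositions, ambiguous dual
#: annotations, sphingoid bases and chromatographic isomer suffixes.
#: Always included in the default catalog.
PAPER_NAME_CORPUS: tuple[str, ...] = (
    "PG(14:1/15:1)",
    "PG(35:1)",
    "PG(14:1/14:1)",
    "PG(12:0/13:0)",
    "PG(18:1/0:0)_A",
    "PG(18:1/0:0)_B",
    "PG(14:0/0:0)_B",
    "PG(16:0/16:1)_B",
    "PE(16:0/18:1)/PE(16:1/18:0)",
    "PE(17:1/18:0)/PE(16:0/19:1)",
    "PE(16:0/17:1)",
    "PE(19:1/19:1)",
    "PE(17:1/19:1)",
    "PC(18:0/19:1)",
    "PC(16:0/18:0)",
    "PC(16:1/0:0)_B",
    "CL(17:1/16:0/16:1/17:1)",
    "CL(14:0/16:1/16:1/16:1)",
    "DG(32:1)",
    "DG(16:1/0:0/16:1)",
    "DG(14:0/16:1/0:0)_B/DG(14:1/16:0/0:0)",
    "DG(15:1/16:1/0:0)",
    "DG(14:0/16:1/0:0)_A",
    "HexCer(d18:2/16:1)_B",
)

#: Ionization mode per lipid class (ESI polarity in which each class is
#: detected in this kind of study).
MODE_OF_CLASS: dict[str, str] = {
    "PG": "negative",
    "PE": "negative",
    "PA": "negative",
    "CL": "negative",
    "PC": "positive",
    "DG": "positive",
    "TG": "positive",
    "Cer": "positive",
    "HexCer": "positive",
}

#: Default subclass composition of the catalog (13 subclasses: the nine
#: classes plus the four lyso phospholipid forms).  Fractions sum to 1.
DEFAULT_SUBCLASS_FRACTIONS: dict[str, float] = {
    "PG": 0.18,
    "PE": 0.14,
    "PC": 0.12,
    "PA": 0.05,
    "CL": 0.10,
    "DG": 0.12,
    "TG": 0.08,
    "Cer": 0.05,
    "HexCer": 0.05,
    "LPG": 0.04,
    "LPE": 0.03,
    "LPC": 0.03,
    "LPA": 0.01,
}


def _random_chain(rng: np.random.Generator, sphingoid: bool = False) -> str:
    carbons = int(rng.integers(12, 23))
    db = int(rng.integers(0, 4))
    return ("d" if sphingoid else "") + f"{carbons}:{db}"


def _make_name(subclass: str, rng: np.random.Generator) -> str:
    lyso = subclass.startswith("L")
    cls = subclass[1:] if lyso else subclass
    if cls in ("Cer", "HexCer"):
        return f"{cls}({_random_chain(rng, sphingoid=True)}/{_random_chain(rng)})"
    n_slots = {"PG": 2, "PE": 2, "PC": 2, "PA": 2, "CL": 4, "DG": 3, "TG": 3}[cls]
    if not lyso and rng.random() < 0.10:  # occasional sum composition
        carbons = int(rng.integers(26, 61))
        db = int(rng.integers(0, 5))
        return f"{cls}({carbons}:{db})"
    chains = [_random_chain(rng) for _ in range(n_slots)]
    if lyso:
        chains[int(rng.integers(0, n_slots))] = "0:0"
    elif cls == "DG":  # three glycerol slots, one positional placeholder
        chains[int(rng.integers(0, 3))] = "0:0"
    name = f"{cls}({'/'.join(chains)})"
    if not lyso and cls == "PE" and rng.random() < 0.15:
        # ambiguous dual annotation sharing totals: swap one double bond
        a, b = chains[0].split(":"), chains[1].split(":")
        if int(a[1]) > 0:
            alt = f"{cls}({a[0]}:{int(a[1]) - 1}/{b[0]}:{int(b[1]) + 1})"
            name = f"{name}/{alt}"
    return name


def default_lipid_catalog(n: int = 194, seed: int = 0) -> list[str]:
    """Generate ``n`` unique, parseable shorthand names.

    The reference name corpus is always included (when ``n`` allows);
    the remainder is drawn per the default subclass fractions, with
    isomer suffixes (``_A``/``_B``) disambiguating collisions.
    """
    if n < 13:
        raise ValueError("need n >= 13 to cover all subclasses")
    rng = np.random.default_rng(seed)
    names: list[str] = list(PAPER_NAME_CORPUS[:n])
    seen = set(names)
    subclasses = list(DEFAULT_SUBCLASS_FRACTIONS)
    weights = np.array([DEFAULT_SUBCLASS_FRACTIONS[s] for s in subclasses])
    weights = weights / weights.sum()
    while len(names) < n:
        subclass = rng.choice(subclasses, p=weights)
        name = _make_name(str(subclass), rng)
        if name in seen:
            for suffix in ("_A", "_B", "_C"):
                if "_" not in name.rsplit(")", 1)[-1]:
                    cand = name + suffix
                    if cand not in seen and "/" + name.split("(")[0] not in name:
                        name = cand
                        break
            if name in seen:
                continue
        parse_lipid_name(name)  # generator-parser contract
        seen.add(name)
        names.append(name)
    return names


@dataclass
class PlantedEffect:
    """A log2-scale abundance shift applied to matching samples.

    ``lipids`` selects species by ID; ``subclass`` selects every species
    of a class (e.g. ``"PG"``) instead.  ``where`` is a metadata
    selector (field → value) naming the condition that receives the
    shift, e.g. ``{"salinity": 20}``.
    """

    where: dict
    delta_log2: float
    lipids: list[str] | None = None
    subclass: str | None = None


@dataclass
class SyntheticConfig:
    """Study design and noise model for the generator.

    Defaults mirror the emulated study: 194 lipids over 13 subclasses,
    planktonic growth at 3 salinities × 3 HRTs × 3 replicates (n = 27)
    plus a biofilm arm at 3 salinities × 3 replicates (n = 9), log2
    baselines uniform on [10, 25] and replicate noise σ = 0.5 (log2).
    """

    n_lipids: int = 194
    n_replicates: int = 3
    salinities: tuple[float, ...] = (7.0, 13.0, 20.0)
    hrts: tuple[float, ...] = (19.2, 24.0, 48.0)
    include_biofilm: bool = True
    biofilm_hrt: float = 48.0
    baseline_log2_range: tuple[float, float] = (10.0, 25.0)
    sigma: float = 0.5
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    missing_rate: float = 0.0
    seed: int = 0
    catalog: list[str] | None = None

    def __post_init__(self) -> None:
        lo, hi = self.baseline_log2_range
        if not lo < hi:
            raise ValueError("baseline_log2_range must be increasing")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulation: what was planted, and where."""

    planted: list[dict]  # {"lipid", "where", "delta_log2"}
    lipid_class: dict[str, str]
    charge_class: dict[str, str]
    seed: int

    @property
    def planted_lipids(self) -> list[str]:
        return sorted({p["lipid"] for p in self.planted})


def _design_metadata(cfg: SyntheticConfig) -> pd.DataFrame:
    rows = []
    for sal in cfg.salinities:
        for hrt in cfg.hrts:
            for rep in range(1, cfg.n_replicates + 1):
                rows.append(
                    (f"PEL_S{sal:g}_H{hrt:g}_r{rep}", sal, hrt, "planktonic", rep)
                )
    if cfg.include_biofilm:
        for sal in cfg.salinities:
            for rep in range(1, cfg.n_replicates + 1):
                rows.append(
                    (f"BF_S{sal:g}_r{rep}", sal, cfg.biofilm_hrt, "biofilm", rep)
                )
    meta = pd.DataFrame(
        rows, columns=["sample", "salinity", "hrt", "growth_mode", "replicate"]
    ).set_index("sample")
    meta["timepoint"] = None
    return meta


def _match_samples(meta: pd.DataFrame, where: dict) -> list[str]:
    mask = pd.Series(True, index=meta.index)
    for field_name, wanted in where.items():
        if field_name not in meta.columns:
            raise KeyError(f"unknown metadata field {field_name!r} in selector")
        col = meta[field_name]
        if isinstance(wanted, (list, tuple, set, frozenset)):
            mask &= col.isin(list(wanted))
        else:
            mask &= col == wanted
    return list(meta.index[mask])


def _simulate(
    cfg: SyntheticConfig, meta: pd.DataFrame
) -> tuple[IntensityMatrix, SyntheticTruth]:
    rng = np.random.default_rng(cfg.seed)
    catalog = cfg.catalog if cfg.catalog is not None else default_lipid_catalog(
        cfg.n_lipids, seed=cfg.seed
    )
    if len(catalog) != cfg.n_lipids:
        raise ValueError("catalog length does not match n_lipids")
    species = {name: parse_lipid_name(name) for name in catalog}

    lo, hi = cfg.baseline_log2_range
    baselines = rng.uniform(lo, hi, size=cfg.n_lipids)
    log2_vals = (
        baselines[:, None]
        + rng.normal(0.0, cfg.sigma, size=(cfg.n_lipids, len(meta)))
    )

    planted_records: list[dict] = []
    lipid_pos = {name: i for i, name in enumerate(catalog)}
    col_pos = {s: j for j, s in enumerate(meta.index)}
    for effect in cfg.planted_effects:
        if effect.lipids is not None:
            targets = list(effect.lipids)
            unknown = [l for l in targets if l not in lipid_pos]
            if unknown:
                raise ValueError(f"planted selector names unknown lipids: {unknown}")
        elif effect.subclass is not None:
            targets = [
                name
                for name, sp in species.items()
                if sp.subclass == effect.subclass or sp.lipid_class == effect.subclass
            ]
        else:
            raise ValueError("planted effect needs a lipid list or subclass")
        if not targets:
            raise ValueError(f"planted selector matches no lipid: {effect}")
        cols = [col_pos[s] for s in _match_samples(meta, effect.where)]
        if not cols:
            raise ValueError(f"planted condition matches no sample: {effect.where}")
        for lipid in targets:
            log2_vals[lipid_pos[lipid], cols] += effect.delta_log2
            planted_records.append(
                {
                    "lipid": lipid,
                    "where": dict(effect.where),
                    "delta_log2": effect.delta_log2,
                }
            )

    values = pd.DataFrame(
        np.exp2(log2_vals), index=pd.Index(catalog, name="lipid"), columns=meta.index
    )

    if cfg.missing_rate > 0:
        miss = rng.random(values.shape) < cfg.missing_rate
        # never wipe an entire replicate group for any lipid
        group_cols = [c for c in ("salinity", "hrt", "growth_mode") if c in meta]
        if not group_cols:
            group_cols = [c for c in meta.columns if c != "timepoint"]
        for _, samples in meta.groupby(group_cols, dropna=False).groups.items():
            cols = [col_pos[s] for s in samples]
            block = miss[:, cols]
            wiped = block.all(axis=1)
            for i in np.flatnonzero(wiped):
                keep = rng.integers(0, len(cols))
                miss[i, cols[keep]] = False
        values = values.mask(miss)

    mode_of = pd.Series(
        {name: MODE_OF_CLASS[sp.lipid_class] for name, sp in species.items()}
    )
    matrix = IntensityMatrix(values, mode_of, sample_meta=meta, state="raw")
    truth = SyntheticTruth(
        planted=planted_records,
        lipid_class={n: sp.lipid_class for n, sp in species.items()},
        charge_class={n: sp.charge_class for n, sp in species.items()},
        seed=cfg.seed,
    )
    return matrix, truth


def simulate_lipidome(
    cfg: SyntheticConfig,
) -> tuple[IntensityMatrix, SyntheticTruth]:
    """Simulate a full-design lipidome; returns (raw matrix, truth)."""
    return _simulate(cfg, _design_metadata(cfg))


def simulate_two_group(
    n_lipids: int = 194,
    n_per_group: int = 3,
    planted_lipids: int | list[str] = 0,
    delta_log2: float = 3.0,
    sigma: float = 0.5,
    missing_rate: float = 0.0,
    seed: int = 0,
    catalog: list[str] | None = None,
) -> tuple[IntensityMatrix, SyntheticTruth]:
    """Two-condition simulation (groups "A" and "B" in metadata ``group``).

    ``planted_lipids`` is either a count (the first k catalog lipids get
    a +``delta_log2`` shift in group B) or an explicit ID list.  This is
    the workhorse design for calibration, power and biomarker tests.
    """
    samples = [f"A_r{i + 1}" for i in range(n_per_group)] + [
        f"B_r{i + 1}" for i in range(n_per_group)
    ]
    meta = pd.DataFrame(
        {"group": ["A"] * n_per_group + ["B"] * n_per_group},
        index=pd.Index(samples, name="sample"),
    )
    if catalog is None:
        catalog = default_lipid_catalog(n_lipids, seed=seed)
    if isinstance(planted_lipids, int):
        planted = catalog[:planted_lipids]
    else:
        planted = list(planted_lipids)
    effects = (
        [PlantedEffect(where={"group": "B"}, delta_log2=delta_log2, lipids=planted)]
        if planted
        else []
    )
    cfg = SyntheticConfig(
        n_lipids=n_lipids,
        sigma=sigma,
        missing_rate=missing_rate,
        planted_effects=effects,
        seed=seed,
        catalog=catalog,
    )
    return _simulate(cfg, meta)


def write_tables(
    matrix: IntensityMatrix, truth: SyntheticTruth, outdir: str | Path
) -> dict[str, Path]:
    """Write mode-split intensity CSVs, metadata CSV and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for mode in ("negative", "positive"):
        rows = matrix.mode_of.index[matrix.mode_of == mode]
        path = outdir / f"intensities_{mode}.csv"
        matrix.values.loc[rows].to_csv(path)
        paths[mode] = path
    meta_path = outdir / "sample_metadata.csv"
    if matrix.sample_meta is not None:
        matrix.sample_meta.to_csv(meta_path)
        paths["metadata"] = meta_path
    truth_path = outdir / "truth.json"
    truth_path.write_text(
        json.dumps(
            {
                "planted": truth.planted,
                "lipid_class": truth.lipid_class,
                "charge_class": truth.charge_class,
                "seed": truth.seed,
            },
            indent=2,
        )
    )
    paths["truth"] = truth_path
    return paths
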