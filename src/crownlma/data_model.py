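"""Domain types, trait computation and CSV I/O for whorl-wise crown trait data.

One observation is a needle *cluster* sampled from a branch whorl of a larch
crown on a given day of year (DOY).  Its vertical position is the relative
depth into the crown (RDINC = depth below the tree top / crown length,
0 = apex, 1 = crown base).  From the raw measurements — dry weight WD (g),
fresh weight WF (g) and projected leaf area LA (m^2) — the two traits are

    LMA  = WD / LA   (leaf mass per area, g/m^2)
    LDMC = WD / WF   (leaf dry matter content, g/g)

Records additionally carry categorical labels: the crown layer (UC/MC/LC,
upper/middle/lower, by RDINC tertiles), the leaf growth phase (EG/MG/LG,
early = 1 Jun-15 Jul, middle = 16 Jul-31 Aug, late = 1 Sep onward, non-leap
calendar) and the biweekly sampling-period bin start (doy_group).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClusterRecord",
    "Dataset",
    "compute_traits",
    "assign_growth_phase",
    "assign_crown_layer",
    "assign_doy_group",
    "read_dataset",
    "write_dataset",
    "CSV_COLUMNS",
    "CROWN_LAYERS",
    "GROWTH_PHASES",
]

CROWN_LAYERS = ("UC", "MC", "LC")
GROWTH_PHASES = ("EG", "MG", "LG")

# Non-leap civil calendar: 1 Jun = 152, 15 Jul = 196, 31 Aug = 243, 1 Sep = 244.
_EG_START, _MG_START, _LG_START = 152, 197, 244

#: Default crown-layer cut points (RDINC tertiles): UC below, LC at/above.
DEFAULT_LAYER_CUTS = (1.0 / 3.0, 2.0 / 3.0)

#: Biweekly sampling-period bins: starts 150..225, width 15, top bin closed at 240.
DOY_GROUP_ANCHOR = 150
DOY_GROUP_WIDTH = 15
DOY_GROUP_LAST = 225

CSV_COLUMNS = [
    "plot_id",
    "tree_id",
    "whorl_index",
    "rdinc",
    "doy",
    "wf_g",
    "wd_g",
    "la_m2",
    "lma_g_m2",
    "ldmc_g_g",
    "crown_layer",
    "growth_phase",
    "doy_group",
]

_MANDATORY = ("rdinc", "doy")
_RAW = ("wd_g", "wf_g", "la_m2")
_TRAITS = ("lma_g_m2", "ldmc_g_g")


def compute_traits(wd: float, wf: float, la: float, ldmc_formula: str = "standard"):
    """Compute (LMA, LDMC) from dry weight, fresh weight and projected area.

    Parameters
    ----------
    wd, wf : float
        Dry and fresh cluster weight in grams; requires ``0 < wd <= wf``.
    la : float
        Projected leaf area in m^2, positive.
    ldmc_formula : {"standard", "as_printed"}
        ``"standard"`` gives LDMC = WD/WF (g dry per g fresh, in (0, 1]);
        ``"as_printed"`` gives the reciprocal WF/WD for comparison with
        sources that define it that way.

    Returns
    -------
    (lma, ldmc) : tuple of float
        LMA in g/m^2 and LDMC in g/g.
    """
    for name, value in (("wd", wd), ("wf", wf), ("la", la)):
        if not (value > 0):
            raise ValueError(f"{name} must be positive, got {value!r}")
    if wf < wd:
        raise ValueError(f"fresh weight wf={wf} cannot be below dry weight wd={wd}")
    lma = wd / la
    if ldmc_formula == "standard":
        ldmc = wd / wf
    elif ldmc_formula == "as_printed":
        ldmc = wf / wd
    else:
        raise ValueError(f"unknown ldmc_formula {ldmc_formula!r}")
    return lma, ldmc


def assign_growth_phase(doy: int) -> str:
    """Leaf growth phase for a day of year (non-leap calendar).

    EG (early growth) covers 1 Jun-15 Jul (DOY 152-196), MG (middle)
    16 Jul-31 Aug (197-243), LG (late) 1 Sep onward (>= 244).  Days before
    the season start are labelled EG with a warning.
    """
    doy = int(doy)
    if not 1 <= doy <= 366:
        raise ValueError(f"doy must be in [1, 366], got {doy}")
    if doy < _EG_START:
        warnings.warn(f"doy={doy} precedes the growing season; labelled EG", stacklevel=2)
        return "EG"
    if doy < _MG_START:
        return "EG"
    if doy < _LG_START:
        return "MG"
    return "LG"


def assign_crown_layer(rdinc: float, cuts: Sequence[float] = DEFAULT_LAYER_CUTS) -> str:
    """Crown layer (UC/MC/LC) for a relative crown depth.

    The default cut points are RDINC tertiles: UC for rdinc < 1/3,
    MC for 1/3 <= rdinc < 2/3, LC otherwise.  ``cuts`` may be overridden.
    """
    if not (0 < rdinc <= 1):
        raise ValueError(f"rdinc must be in (0, 1], got {rdinc!r}")
    lo, hi = cuts
    if rdinc < lo:
        return "UC"
    if rdinc < hi:
        return "MC"
    return "LC"


def assign_doy_group(doy: int) -> int:
    """Biweekly sampling-period bin start (150, 165, ..., 225) for a DOY.

    The top bin [225, 240] is right-closed; values outside the sampling
    window clamp to the nearest bin.
    """
    g = DOY_GROUP_ANCHOR + DOY_GROUP_WIDTH * math.floor(
        (int(doy) - DOY_GROUP_ANCHOR) / DOY_GROUP_WIDTH
    )
    return int(min(max(g, DOY_GROUP_ANCHOR), DOY_GROUP_LAST))


@dataclass
class ClusterRecord:
    """One needle-cluster observation: covariates, traits and group labels."""

    plot_id: str
    tree_id: str
    whorl_index: int
    rdinc: float
    doy: int
    lma: float
    ldmc: float
    wf: Optional[float] = None
    wd: Optional[float] = None
    la: Optional[float] = None
    crown_layer: str = ""
    growth_phase: str = ""
    doy_group: int = 0

    def __post_init__(self):
        if not (0 < self.rdinc <= 1):
            raise ValueError(f"rdinc must be in (0, 1], got {self.rdinc}")
        if not (self.lma > 0):
            raise ValueError(f"lma must be positive, got {self.lma}")
        if not (0 < self.ldmc < 1):
            raise ValueError(f"ldmc must be in (0, 1), got {self.ldmc}")
        if self.whorl_index < 1:
            raise ValueError(f"whorl_index must be >= 1, got {self.whorl_index}")
        if self.wd is not None and self.wf is not None and self.la is not None:
            lma, ldmc = compute_traits(self.wd, self.wf, self.la)
            if not (
                math.isclose(lma, self.lma, rel_tol=1e-9)
                and math.isclose(ldmc, self.ldmc, rel_tol=1e-9)
            ):
                raise ValueError(
                    "stored traits disagree with recomputation from raw weights: "
                    f"lma {self.lma} vs {lma}, ldmc {self.ldmc} vs {ldmc}"
                )
        if not self.crown_layer:
            self.crown_layer = assign_crown_layer(self.rdinc)
        if not self.growth_phase:
            self.growth_phase = assign_growth_phase(self.doy)
        if not self.doy_group:
            self.doy_group = assign_doy_group(self.doy)


@dataclass
class Dataset:
    """An ordered collection of cluster records with provenance.

    Internally a pandas DataFrame with the canonical column schema; the
    ``records`` property materialises :class:`ClusterRecord` objects.
    """

    df: pd.DataFrame
    provenance: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.df) == 0:
            raise ValueError("dataset must be non-empty")
        for col in ("lma_g_m2", "rdinc", "doy"):
            if col not in self.df.columns:
                raise ValueError(f"dataset missing mandatory column {col!r}")
            if self.df[col].isna().any():
                idx = int(self.df.index[self.df[col].isna()][0])
                raise ValueError(f"missing {col!r} at row {idx}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def records(self) -> list:
        out = []
        for _, row in self.df.iterrows():
            out.append(
                ClusterRecord(
                    plot_id=str(row.get("plot_id", "")),
                    tree_id=str(row.get("tree_id", "")),
                    whorl_index=int(row.get("whorl_index", 1)),
                    rdinc=float(row["rdinc"]),
                    doy=int(row["doy"]),
                    lma=float(row["lma_g_m2"]),
                    ldmc=float(row["ldmc_g_g"]),
                    wf=_opt(row.get("wf_g")),
                    wd=_opt(row.get("wd_g")),
                    la=_opt(row.get("la_m2")),
                    crown_layer=str(row.get("crown_layer", "")),
                    growth_phase=str(row.get("growth_phase", "")),
                    doy_group=int(row.get("doy_group", 0)),
                )
            )
        return out

    @classmethod
    def from_records(cls, records: Sequence[ClusterRecord], provenance: str = "") -> "Dataset":
        rows = [
            {
                "plot_id": r.plot_id,
                "tree_id": r.tree_id,
                "whorl_index": r.whorl_index,
                "rdinc": r.rdinc,
                "doy": r.doy,
                "wf_g": r.wf,
                "wd_g": r.wd,
                "la_m2": r.la,
                "lma_g_m2": r.lma,
                "ldmc_g_g": r.ldmc,
                "crown_layer": r.crown_layer,
                "growth_phase": r.growth_phase,
                "doy_group": r.doy_group,
            }
            for r in records
        ]
        return cls(pd.DataFrame(rows, columns=CSV_COLUMNS), provenance=provenance)

    def subset(self, index, provenance_suffix: str = "") -> "Dataset":
        return Dataset(
            self.df.loc[index].reset_index(drop=True),
            provenance=self.provenance + provenance_suffix,
            meta=dict(self.meta),
        )


def _opt(v):
    if v is None or (isinstance(v, float) and math.isnan(v)) or pd.isna(v):
        return None
    return float(v)


def _apply_labels(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorised recomputation of layer / phase / doy-group labels."""
    rdinc = df["rdinc"].to_numpy(dtype=float)
    doy = df["doy"].to_numpy(dtype=int)
    lo, hi = DEFAULT_LAYER_CUTS
    df["crown_layer"] = np.select([rdinc < lo, rdinc < hi], ["UC", "MC"], default="LC")
    if (doy < _EG_START).any():
        warnings.warn("some records precede the growing season; labelled EG", stacklevel=3)
    df["growth_phase"] = np.select(
        [doy < _MG_START, doy < _LG_START], ["EG", "MG"], default="LG"
    )
    g = DOY_GROUP_ANCHOR + DOY_GROUP_WIDTH * np.floor(
        (doy - DOY_GROUP_ANCHOR) / DOY_GROUP_WIDTH
    )
    df["doy_group"] = np.clip(g, DOY_GROUP_ANCHOR, DOY_GROUP_LAST).astype(int)
    return df


def read_dataset(path, column_map: Optional[dict] = None) -> Dataset:
    """Read a cluster CSV into a validated :class:`Dataset`.

    The file must carry ``rdinc`` and ``doy`` plus either the raw columns
    (``wd_g``, ``wf_g``, ``la_m2``) or the trait columns (``lma_g_m2``,
    ``ldmc_g_g``).  ``column_map`` maps file header names to schema names
    (``{"my_lma": "lma_g_m2"}``).  Traits are recomputed from raw weights
    when present; group labels are always recomputed.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)

    for col in _MANDATORY:
        if col not in df.columns:
            raise ValueError(f"missing mandatory column {col!r}")
    have_raw = all(c in df.columns for c in _RAW) and not df[list(_RAW)].isna().any().any()
    have_traits = all(c in df.columns for c in _TRAITS)
    if not (have_raw or have_traits):
        raise ValueError(
            f"need either raw columns {_RAW} or trait columns {_TRAITS}"
        )

    if have_raw:
        wd = df["wd_g"].to_numpy(float)
        wf = df["wf_g"].to_numpy(float)
        la = df["la_m2"].to_numpy(float)
        for name, v in (("wd_g", wd), ("wf_g", wf), ("la_m2", la)):
            if (v <= 0).any():
                raise ValueError(
                    f"non-positive {name} at row {int(np.argmax(v <= 0))}"
                )
        if (wf < wd).any():
            raise ValueError(
                f"wf_g < wd_g at row {int(np.argmax(wf < wd))}"
            )
        df["lma_g_m2"] = wd / la
        df["ldmc_g_g"] = wd / wf

    for col, ok in (
        ("rdinc", lambda v: (v > 0) & (v <= 1)),
        ("lma_g_m2", lambda v: v > 0),
        ("ldmc_g_g", lambda v: (v > 0) & (v < 1)),
    ):
        v = df[col].to_numpy(float)
        bad = ~ok(v)
        if bad.any():
            raise ValueError(f"invariant violation for {col!r} at row {int(np.argmax(bad))}")

    df = _apply_labels(df)
    for col in CSV_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return Dataset(df[CSV_COLUMNS], provenance=str(path))


def write_dataset(dataset: Dataset, path) -> None:
    """Write a dataset to CSV (comma-separated, UTF-8, 6 significant digits)."""
    df = dataset.df.copy()
    for col in CSV_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df[CSV_COLUMNS].to_csv(path, index=False, float_format="%.6g")
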