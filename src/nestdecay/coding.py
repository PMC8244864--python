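"""Covariate coding: Low/Medium/High binning, tree-species categories, and
assembly of the per-nest factor index table (the model design).

Factors and their category counts:

====== ============================================== ==========
symbol meaning                                        categories
====== ============================================== ==========
F      forest type (swamp / terra firma)              2
E      exposure (close / open to sky)                 2
P      position (side branch / treetop)               2
C      construction (single tree / integrated)        2
A      absolute nest height (m)                       3
H      relative height = nest height / tree height    3
W      mean daily rainfall over nest lifetime (mm)    3
S      mean daily storm count over nest lifetime      3
T      minimum temperature on construction day (C)    3
D      diurnal temperature range on construction day  3
R      rain in interval c on construction day         2
Sp     tree species (10 most frequent + "other")      11
====== ============================================== ==========

Continuous covariates are cut into Low / Medium / High either at fixed
cut-offs (the defaults below) or at the data's mean +/- 1 SD.  Boundary ties
go to the extreme categories: Low is ``x <= low_cut``, High is
``x >= high_cut``, Medium is open on both sides.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ValidationError

__all__ = [
    "BinSpec",
    "DEFAULT_BIN_SPECS",
    "FACTOR_LEVELS",
    "bin_continuous",
    "code_tree_species",
    "build_design",
    "category_frequencies",
]

FACTOR_LEVELS = {"F": 2, "E": 2, "P": 2, "C": 2, "A": 3, "H": 3, "W": 3,
                 "S": 3, "T": 3, "D": 3, "R": 2, "Sp": 11}

# Binary factor level order: index 1, index 2.
BINARY_LEVELS = {
    "F": ("swamp", "terra_firma"),
    "E": ("close", "open"),
    "P": ("side_branch", "top"),
    "C": ("single_tree", "integrated"),
    "R": ("no", "yes"),
}


@dataclass(frozen=True)
class BinSpec:
    """Cut-offs for one continuous factor.

    ``mode="fixed"`` uses ``low_cut``/``high_cut`` as given;
    ``mode="data_mean_sd"`` recomputes them as mean -/+ 1 sample SD of the
    data being binned (n-1 denominator).
    """

    factor: str
    low_cut: float
    high_cut: float
    mode: str = "fixed"

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "data_mean_sd"):
            raise ValidationError(f"unknown binning mode {self.mode!r}")
        if not self.low_cut < self.high_cut:
            raise ValidationError(f"{self.factor}: low_cut must be < high_cut")


# Fixed cut-offs matching the field study's published category boundaries.
DEFAULT_BIN_SPECS = {
    "A": BinSpec("A", 13.0, 23.0),
    "H": BinSpec("H", 0.8, 0.95),
    "W": BinSpec("W", 3.0, 9.0),
    "S": BinSpec("S", 0.02, 0.12),
    "T": BinSpec("T", 18.0, 22.0),
    "D": BinSpec("D", 4.0, 8.0),
}


def bin_continuous(values, spec: BinSpec) -> np.ndarray:
    """Map values to category indices 1 (Low), 2 (Medium), 3 (High)."""
    x = np.asarray(values, dtype=float)
    if spec.mode == "data_mean_sd":
        if x.size < 2:
            raise ValidationError(f"{spec.factor}: need >= 2 values for "
                                  "data_mean_sd binning")
        sd = float(np.std(x, ddof=1))
        if sd == 0:
            raise ValidationError(f"{spec.factor}: zero SD, cannot bin by "
                                  "mean +/- SD")
        mean = float(np.mean(x))
        low_cut, high_cut = mean - sd, mean + sd
    else:
        low_cut, high_cut = spec.low_cut, spec.high_cut
    cat = np.full(x.shape, 2, dtype=int)
    cat[x <= low_cut] = 1
    cat[x >= high_cut] = 3
    return cat


def code_tree_species(records, top_k: int = 10) -> tuple[dict[str, int], pd.Series]:
    """Species categories: the ``top_k`` most frequent species among
    non-integrated nests get categories 1..top_k (ranked by count, ties
    broken alphabetically); every other species -- and every integrated
    nest, whatever its species -- maps to category ``top_k + 1``.

    Returns ``(species -> category map, per-nest Sp index Series keyed by
    nest_id)``.
    """
    records = list(records)
    if not records:
        raise ValidationError("code_tree_species: no records")
    counts = Counter(r.tree_species for r in records
                     if r.construction != "integrated")
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    other = top_k + 1
    spmap = {sp: i + 1 for i, (sp, _) in enumerate(ranked[:top_k])}
    indices = pd.Series(
        {r.nest_id: other if r.construction == "integrated"
         else spmap.get(r.tree_species, other) for r in records},
        name="Sp")
    return spmap, indices


def build_design(records, ages: pd.DataFrame, nest_climate: pd.DataFrame,
                 bin_specs: dict[str, BinSpec] | None = None,
                 top_k_species: int = 10) -> pd.DataFrame:
    """Assemble the per-nest factor index table.

    One row per nest; columns are the factor symbols, values the 1-based
    category indices.  Binary factors come straight from the nest record,
    A and H from the recorded heights, W/S/T/D/R from the per-nest climate
    covariates, Sp from :func:`code_tree_species`.
    """
    records = list(records)
    specs = dict(DEFAULT_BIN_SPECS)
    if bin_specs:
        specs.update(bin_specs)
    clim = nest_climate.set_index("nest_id")
    for nest in records:
        if nest.nest_id not in clim.index:
            raise ValidationError(f"missing climate covariates for nest "
                                  f"{nest.nest_id}")
    _, sp_idx = code_tree_species(records, top_k=top_k_species)

    ids = [r.nest_id for r in records]
    out = pd.DataFrame(index=pd.Index(ids, name="nest_id"))
    for f in ("F", "E", "P", "C"):
        attr = {"F": "forest_type", "E": "exposure", "P": "position",
                "C": "construction"}[f]
        levels = BINARY_LEVELS[f]
        out[f] = [levels.index(getattr(r, attr)) + 1 for r in records]
    out["A"] = bin_continuous([r.nest_height_m for r in records], specs["A"])
    out["H"] = bin_continuous([r.nest_height_m / r.tree_height_m for r in records],
                              specs["H"])
    for f in ("W", "S", "T", "D"):
        col = {"W": "W_avg", "S": "S_avg", "T": "T", "D": "D"}[f]
        out[f] = bin_continuous(clim.loc[ids, col].to_numpy(), specs[f])
    out["R"] = [BINARY_LEVELS["R"].index(clim.loc[i, "R"]) + 1 for i in ids]
    out["Sp"] = sp_idx.loc[ids].to_numpy()
    return out.reset_index()


def category_frequencies(design: pd.DataFrame) -> pd.DataFrame:
    """Long-format count of nests per (factor, category)."""
    rows = []
    for f, k in FACTOR_LEVELS.items():
        if f not in design.columns:
            continue
        counts = design[f].value_counts()
        for j in range(1, k + 1):
            rows.append({"factor": f, "category": j,
                         "n_nests": int(counts.get(j, 0))})
    return pd.DataFrame(rows)
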