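"""Experiment data model: harvest records, validation, annual accumulation.

The experiment grows white clover (*Trifolium repens*) populations, perennial
ryegrass and chicory as pure stands and clover-based mixtures in a randomized
complete block design at two sites.  Harvest tables are long-format delimited
text, one row per plot x harvest, carrying the total dry-matter yield and the
botanical fractions obtained by manual separation (clover, grass, chicory and
a non-sown "weed" fraction).

All yields are in one consistent mass-per-area unit; by convention the docs
and the synthetic generator use t DM ha^-1.  Non-sown biomass is carried
through the data model but never enters diversity-effect computations, which
are defined on sown species only.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd

#: Sown species, in canonical order.
SPECIES = ("clover", "grass", "chicory")

#: Pure-stand composition -> sown species.
PURE_COMPOSITIONS = {
    "pure_clover": "clover",
    "pure_grass": "grass",
    "pure_chicory": "chicory",
}

#: Mixture composition -> sown species.
MIXTURE_COMPOSITIONS = {
    "TL": ("clover", "grass"),
    "TC": ("clover", "chicory"),
    "TLC": ("clover", "grass", "chicory"),
}

#: Every legal stand composition -> tuple of sown species.
COMPOSITION_SPECIES = {
    **{k: (v,) for k, v in PURE_COMPOSITIONS.items()},
    **MIXTURE_COMPOSITIONS,
}

#: Sowing proportions RY_E per composition.  Two-species mixtures are sown
#: clover:partner = 0.4:0.6, the three-species mixture 0.4:0.3:0.3.
SOWING_PROPORTIONS = {
    "pure_clover": {"clover": 1.0},
    "pure_grass": {"grass": 1.0},
    "pure_chicory": {"chicory": 1.0},
    "TL": {"clover": 0.4, "grass": 0.6},
    "TC": {"clover": 0.4, "chicory": 0.6},
    "TLC": {"clover": 0.4, "grass": 0.3, "chicory": 0.3},
}

#: Compositions that may carry fertilized (N1) plots: only the non-leguminous
#: pure stands.  All clover-containing stands are unfertilized.
N1_COMPOSITIONS = ("pure_grass", "pure_chicory")

#: Required columns of a harvest table.
HARVEST_COLUMNS = [
    "site",
    "block",
    "plot",
    "composition",
    "population",
    "n_level",
    "replicate_id",
    "year",
    "harvest_no",
    "total_dm",
    "frac_clover",
    "frac_grass",
    "frac_chicory",
    "frac_nonsown",
]

#: Columns of an annual-yield table (one row per plot-year).
ANNUAL_COLUMNS = [
    "site",
    "block",
    "plot",
    "composition",
    "population",
    "n_level",
    "replicate_id",
    "year",
    "yield_clover",
    "yield_grass",
    "yield_chicory",
    "yield_nonsown",
    "total_sown_yield",
]

_PLOT_KEY = ["site", "block", "plot", "composition", "population", "n_level", "replicate_id"]


class SchemaError(ValueError):
    """A table does not have the documented structure (e.g. missing column)."""


class ValidationError(ValueError):
    """Rows violate an invariant of the data model.

    Attributes
    ----------
    rows : list of int
        Zero-based positional indices of the offending rows.
    """

    def __init__(self, message: str, rows: Iterable[int] = ()):
        self.rows = sorted(int(r) for r in rows)
        if self.rows:
            shown = ", ".join(map(str, self.rows[:20]))
            more = "" if len(self.rows) <= 20 else f" (+{len(self.rows) - 20} more)"
            message = f"{message} [rows: {shown}{more}]"
        super().__init__(message)


def _normalize(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in ("site", "block", "plot", "composition", "n_level"):
        out[col] = out[col].astype(str)
    pop = out["population"]
    out["population"] = pop.where(pop.notna(), "").astype(str).replace({"nan": "", "None": ""})
    out["replicate_id"] = (
        pd.to_numeric(out["replicate_id"], errors="coerce").fillna(1).astype(int)
    )
    out["year"] = out["year"].astype(int)
    return out


def validate_harvest_frame(df: pd.DataFrame, *, fraction_tol: float = 0.01) -> pd.DataFrame:
    """Validate a harvest table against the data-model invariants.

    Checks column presence, fraction ranges and sums, stand legality
    (compositions, fertilization only on non-leguminous pure stands,
    population given exactly for clover-containing stands) and non-negative
    yields.  Returns a normalized copy; raises :class:`SchemaError` or
    :class:`ValidationError` (listing offending row positions) otherwise.
    """
    missing = [c for c in HARVEST_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"harvest table is missing column(s): {', '.join(missing)}")
    df = _normalize(df)

    bad = df.index[~df["composition"].isin(COMPOSITION_SPECIES)]
    if len(bad):
        raise ValidationError("illegal stand composition", bad)

    clover_sown = df["composition"].isin(["pure_clover", "TL", "TC", "TLC"])
    bad = df.index[clover_sown & (df["population"] == "")]
    if len(bad):
        raise ValidationError("clover-containing stand without population label", bad)
    bad = df.index[~clover_sown & (df["population"] != "")]
    if len(bad):
        raise ValidationError("population label on a stand without clover", bad)

    bad = df.index[~df["n_level"].isin(["N0", "N1"])]
    if len(bad):
        raise ValidationError("n_level must be N0 or N1", bad)
    bad = df.index[(df["n_level"] == "N1") & ~df["composition"].isin(N1_COMPOSITIONS)]
    if len(bad):
        raise ValidationError(
            "fertilized (N1) plots are only legal for non-leguminous pure stands", bad
        )

    bad = df.index[(df["harvest_no"] < 1) | (df["harvest_no"] > 4)]
    if len(bad):
        raise ValidationError("harvest_no outside 1..4", bad)
    bad = df.index[(df["total_dm"] < 0) | ~np.isfinite(df["total_dm"])]
    if len(bad):
        raise ValidationError("total_dm must be finite and >= 0", bad)

    frac_cols = ["frac_clover", "frac_grass", "frac_chicory", "frac_nonsown"]
    fr = df[frac_cols].to_numpy(dtype=float)
    bad = df.index[((fr < 0) | (fr > 1) | ~np.isfinite(fr)).any(axis=1)]
    if len(bad):
        raise ValidationError("species fractions must lie in [0, 1]", bad)
    s = fr.sum(axis=1)
    bad = df.index[np.abs(s - 1.0) > fraction_tol]
    if len(bad):
        raise ValidationError(
            f"fraction sum outside 1 +/- {fraction_tol:g}", bad
        )

    # species fractions must be zero for species not sown in the stand
    for sp in SPECIES:
        sown = df["composition"].map(lambda c, sp=sp: sp in COMPOSITION_SPECIES[c])
        bad = df.index[~sown & (df[f"frac_{sp}"] > 0)]
        if len(bad):
            raise ValidationError(f"nonzero frac_{sp} in a stand where {sp} is not sown", bad)

    return df


def write_table(df: pd.DataFrame, path, *, sep: str = ",") -> None:
    """Write a table as delimited text with round-trip float precision."""
    df.to_csv(path, index=False, sep=sep, float_format="%.17g")


def read_harvest_table(
    path, *, sep: str | None = None, fraction_tol: float = 0.01
) -> pd.DataFrame:
    """Read and validate a long-format harvest table.

    Parameters
    ----------
    path : str or path-like
        Delimited text file, UTF-8, one row per plot-harvest, with the columns
        in :data:`HARVEST_COLUMNS` (comma-separated by default, tab accepted).
    sep : str, optional
        Field separator; autodetected between ``,`` and tab when omitted.
    fraction_tol : float
        Tolerance on the botanical fraction sum (default 0.01, reflecting
        rounding in the manual separation of 250 g subsamples).
    """
    if sep is None:
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline()
        sep = "\t" if header.count("\t") > header.count(",") else ","
    df = pd.read_csv(path, sep=sep, dtype={"population": str},
                     float_precision="round_trip")
    return validate_harvest_frame(df, fraction_tol=fraction_tol)


def accumulate_annual(
    records: pd.DataFrame, *, strict: bool = True, harvests_per_year: int = 4
) -> pd.DataFrame:
    """Accumulate per-harvest records into annual species yields.

    For each plot-year the species yield is ``sum over harvests of
    total_dm * fraction``; the non-sown yield is computed identically and
    carried along but never enters diversity-effect computations.

    Parameters
    ----------
    records : DataFrame
        Validated harvest table (see :func:`validate_harvest_frame`).
    strict : bool
        If True (default), every plot-year must have exactly
        ``harvests_per_year`` harvests; otherwise plot-years with fewer
        harvests are summed over what exists, with a warning.
    """
    df = records
    dup = df.duplicated(subset=["site", "plot", "year", "harvest_no"])
    if dup.any():
        raise ValidationError("duplicate (plot, year, harvest_no)", df.index[dup])

    for sp in SPECIES:
        df = df.assign(**{f"yield_{sp}": df["total_dm"] * df[f"frac_{sp}"]})
    df = df.assign(yield_nonsown=df["total_dm"] * df["frac_nonsown"])

    grouped = df.groupby(_PLOT_KEY + ["year"], as_index=False, sort=True).agg(
        yield_clover=("yield_clover", "sum"),
        yield_grass=("yield_grass", "sum"),
        yield_chicory=("yield_chicory", "sum"),
        yield_nonsown=("yield_nonsown", "sum"),
        n_harvests=("harvest_no", "size"),
    )
    short = grouped["n_harvests"] != harvests_per_year
    if short.any():
        msg = (
            f"{int(short.sum())} plot-year(s) with fewer than "
            f"{harvests_per_year} harvests"
        )
        if strict:
            raise ValidationError(msg + " (strict mode)", grouped.index[short])
        warnings.warn(msg + "; summing available harvests", stacklevel=2)
    grouped["total_sown_yield"] = grouped[[f"yield_{sp}" for sp in SPECIES]].sum(axis=1)
    return grouped[ANNUAL_COLUMNS]


def average_duplicate_references(
    annual: pd.DataFrame, *, allow_any_count: bool = False
) -> pd.DataFrame:
    """Average the duplicate ryegrass pure-stand plots within each block.

    The design sows the perennial ryegrass pure stand twice per block and
    fertilization level; the mean of the two replicates is used in all
    downstream calculations.  Other stands pass through untouched.

    Raises :class:`ValidationError` on more than two replicates unless
    ``allow_any_count`` is set.
    """
    is_grass = annual["composition"] == "pure_grass"
    grass = annual[is_grass]
    rest = annual[~is_grass]
    if grass.empty:
        return annual.copy()

    key = ["site", "block", "year", "n_level"]
    counts = grass.groupby(key).size()
    if not allow_any_count and (counts > 2).any():
        raise ValidationError(
            "more than two ryegrass pure-stand replicates in a block "
            "(design violation; pass allow_any_count=True to average anyway)"
        )

    val_cols = ["yield_clover", "yield_grass", "yield_chicory", "yield_nonsown",
                "total_sown_yield"]
    agg = {c: (c, "mean") for c in val_cols}
    merged = grass.groupby(key + ["composition", "population"], as_index=False).agg(
        plot=("plot", lambda p: "+".join(sorted(p))),
        **agg,
    )
    merged["replicate_id"] = 0
    out = pd.concat([rest, merged[ANNUAL_COLUMNS]], ignore_index=True)
    return out.sort_values(_PLOT_KEY + ["year"], ignore_index=True)
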