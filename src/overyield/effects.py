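"""Additive partitioning of diversity effects and corrected relative yields.

For every mixture plot-year the net biodiversity effect is split into
complementarity and selection components (Loreau–Hector additive partition):

    NE = Y_O - Y_E = CE + SE
    CE = N * mean(dRY_i) * mean(M_i)
    SE = N * cov(dRY_i, M_i)

where ``N`` is the number of sown species, ``M_i`` the pure-stand yield of
species *i* averaged across the site's blocks, ``Y_O`` the summed observed
mixture species yields and ``Y_E = sum RY_E,i * M_i`` the yield expected from
pure stands weighted by sowing proportions.  The covariance uses divisor ``N``
(population covariance); together with ``dRY_i = Y_i / M_i - RY_E,i`` this
makes ``NE = CE + SE`` an exact algebraic identity.

Species-level overyielding is reported as the corrected relative yield

    RY_C = RY_O / RY_E,    RY_O = Y_i(mixture) / Y_i(pure stand, same block)

where the within-block pure stand serves as the reference so that shared
block effects cancel.  ``RY_C > 1`` means the species yields more in mixture
than expected from its pure stand after accounting for sowing proportion.

Every quantity is computed against two alternative reference baselines:

* ``N0`` — unfertilized pure stands of all three species;
* ``N1`` — nitrogen-fertilized grass and chicory pure stands.  No fertilized
  clover stands exist, so the clover reference remains the unfertilized pure
  stand of the *same* population (flagged in the output provenance).
  Contrasting the two baselines isolates the clover's nitrogen-facilitation
  contribution to overyielding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .schema import (
    MIXTURE_COMPOSITIONS,
    SOWING_PROPORTIONS,
    SPECIES,
    average_duplicate_references,
)

BASELINES = ("N0", "N1")

#: Provenance string for the clover reference under the fertilized baseline.
CLOVER_N1_PROVENANCE = "N0 (no fertilized legume stands exist)"

EFFECTS_COLUMNS = [
    "site", "block", "plot", "population", "mixtype", "year", "baseline",
    "N", "Y_O", "Y_E", "CE", "SE", "NE", "flags",
]
SPECIES_COLUMNS = [
    "site", "block", "plot", "population", "mixtype", "year", "baseline",
    "species", "RY_O", "RY_E", "delta_RY", "RY_C", "reference_provenance",
    "flags",
]


@dataclass
class SpeciesRelativeYield:
    """Relative-yield statistics of one species in one mixture plot-year."""

    species: str
    ry_o: float
    ry_e: float
    delta_ry: float
    ry_c: float
    flag: str | None = None


@dataclass
class DiversityEffects:
    """Additive partition of the net biodiversity effect for one plot-year."""

    n: int
    y_o: float
    y_e: float
    ce: float
    se: float
    ne: float
    flag: str | None = None


@dataclass
class ReferenceSet:
    """Pure-stand references for one site, year and baseline.

    ``block_refs`` holds the within-block pure-stand yields (used for RY_O);
    ``means`` the cross-block means M_i (used for CE/SE and Y_E).  Clover
    entries are keyed by population: each mixture is referenced against the
    clover pure stand of its own population.
    """

    baseline: str
    site: str
    year: int
    block_refs: pd.DataFrame
    means: pd.DataFrame
    issues: list[str] = field(default_factory=list)

    def block_ref(self, species: str, block, population: str = "") -> float:
        df = self.block_refs
        m = (
            (df["species"] == species)
            & (df["block"] == str(block))
            & (df["population"] == (population if species == "clover" else ""))
        )
        vals = df.loc[m, "ref_yield"]
        return float(vals.iloc[0]) if len(vals) else float("nan")

    def m(self, species: str, population: str = "") -> float:
        df = self.means
        m = (df["species"] == species) & (
            df["population"] == (population if species == "clover" else "")
        )
        vals = df.loc[m, "M"]
        return float(vals.iloc[0]) if len(vals) else float("nan")


def _reference_long(annual: pd.DataFrame, baseline: str) -> pd.DataFrame:
    """Within-block pure-stand reference yields, long over species.

    One row per (site, block, year, species[, population]); provenance records
    which fertilization level the reference came from.
    """
    parts = []
    for sp, comp in (("clover", "pure_clover"), ("grass", "pure_grass"),
                     ("chicory", "pure_chicory")):
        level = "N0" if sp == "clover" else baseline
        sub = annual[(annual["composition"] == comp) & (annual["n_level"] == level)]
        prov = (
            CLOVER_N1_PROVENANCE
            if (sp == "clover" and baseline == "N1")
            else f"{level} pure stand"
        )
        parts.append(pd.DataFrame({
            "site": sub["site"].to_numpy(),
            "block": sub["block"].to_numpy(),
            "year": sub["year"].to_numpy(),
            "species": sp,
            "population": sub["population"].to_numpy() if sp == "clover" else "",
            "ref_yield": sub[f"yield_{sp}"].to_numpy(),
            "provenance": prov,
        }))
    return pd.concat(parts, ignore_index=True)


def _means_long(block_refs: pd.DataFrame) -> pd.DataFrame:
    """Cross-block means M_i per site-year (and population for clover)."""
    g = block_refs.groupby(
        ["site", "year", "species", "population"], as_index=False
    ).agg(M=("ref_yield", "mean"), n_blocks=("ref_yield", "size"),
          provenance=("provenance", "first"))
    return g


def build_reference_set(
    annual: pd.DataFrame,
    baseline: str,
    site: str,
    year: int,
    *,
    average_duplicates: bool = True,
) -> ReferenceSet:
    """Assemble the pure-stand reference set for one site-year and baseline.

    Under ``N0`` all references come from unfertilized pure stands; under
    ``N1`` the grass and chicory references come from fertilized pure stands
    while the clover reference stays the unfertilized stand of the same
    population (no fertilized clover exists; flagged in provenance).
    """
    if baseline not in BASELINES:
        raise ValueError(f"baseline must be one of {BASELINES}, got {baseline!r}")
    if average_duplicates:
        annual = average_duplicate_references(annual)
    sub = annual[(annual["site"].astype(str) == str(site)) & (annual["year"] == year)]
    block_refs = _reference_long(sub, baseline)
    means = _means_long(block_refs)
    issues = []
    blocks = sorted(sub["block"].astype(str).unique())
    for sp in SPECIES:
        have = set(
            block_refs.loc[block_refs["species"] == sp, "block"].astype(str)
        )
        for b in blocks:
            if b not in have:
                issues.append(f"no {sp} pure-stand reference in block {b}")
    return ReferenceSet(baseline, str(site), int(year), block_refs, means, issues)


def relative_yields(
    mixture_yield: float,
    block_ref_yield: float,
    ry_e: float,
    *,
    species: str = "",
) -> SpeciesRelativeYield:
    """Observed, expected and corrected relative yields of one species.

    ``RY_O = mixture yield / within-block pure-stand yield``;
    ``delta_RY = RY_O - RY_E``; ``RY_C = RY_O / RY_E``.  A missing or
    non-positive pure-stand yield leaves the quantities undefined and flags
    the record (it is excluded from downstream aggregation, never imputed).
    """
    if not np.isfinite(block_ref_yield) or block_ref_yield <= 0:
        return SpeciesRelativeYield(
            species, np.nan, ry_e, np.nan, np.nan,
            flag="undefined: pure-stand reference missing or zero",
        )
    ry_o = mixture_yield / block_ref_yield
    return SpeciesRelativeYield(species, ry_o, ry_e, ry_o - ry_e, ry_o / ry_e)


def partition_effects(
    mixture_yields: Mapping[str, float],
    m_values: Mapping[str, float],
    sowing: Mapping[str, float],
) -> DiversityEffects:
    """Additive partition NE = CE + SE for one mixture plot-year.

    Parameters map species name to the observed mixture yield, the
    cross-block pure-stand mean M_i and the sowing proportion RY_E,i.
    The deviation ``dRY_i = Y_i / M_i - RY_E,i`` is taken against M_i and the
    covariance in SE uses divisor N, so the identity is exact.
    """
    species = list(mixture_yields)
    if set(species) != set(m_values) or set(species) != set(sowing):
        raise ValueError("mixture_yields, m_values and sowing must share species keys")
    y = np.array([mixture_yields[s] for s in species], dtype=float)
    m = np.array([m_values[s] for s in species], dtype=float)
    rye = np.array([sowing[s] for s in species], dtype=float)
    n = len(species)
    if not np.all(np.isfinite(m)) or np.any(m <= 0) or not np.all(np.isfinite(y)):
        return DiversityEffects(
            n, np.nan, np.nan, np.nan, np.nan, np.nan,
            flag="incomputable: missing or zero pure-stand mean",
        )
    dry = y / m - rye
    y_o = float(y.sum())
    y_e = float((rye * m).sum())
    ce = float(dry.sum() * m.sum() / n)
    se = float((dry * m).sum() - dry.sum() * m.sum() / n)
    return DiversityEffects(n, y_o, y_e, ce, se, y_o - y_e)


def effects_table(
    annual: pd.DataFrame,
    *,
    baselines: tuple[str, ...] = BASELINES,
    clover_ryc_n1: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Diversity effects and species relative yields for a whole design.

    Computes, for every mixture plot-year and every requested baseline, the
    additive partition (one row of the effects table) and the per-species
    relative yields (one row each in the species table).  Duplicate ryegrass
    reference plots are block-averaged first.  Plot-years with missing or
    zero references are retained with NaN results and an explanatory flag,
    never silently dropped.

    By default the clover RY_C rows are omitted under the fertilized baseline
    (the clover reference there is itself unfertilized, so its RY_C duplicates
    the N0 value); pass ``clover_ryc_n1=True`` to emit them flagged.
    """
    annual = average_duplicate_references(annual)
    mix = annual[annual["composition"].isin(MIXTURE_COMPOSITIONS)].copy()
    mix["site"] = mix["site"].astype(str)
    mix["block"] = mix["block"].astype(str)
    n_rows = len(mix)

    eff_frames, sp_frames = [], []
    for baseline in baselines:
        if baseline not in BASELINES:
            raise ValueError(f"unknown baseline {baseline!r}")
        refs = _reference_long(annual, baseline)
        refs["site"] = refs["site"].astype(str)
        refs["block"] = refs["block"].astype(str)
        means = _means_long(refs)

        y = np.full((n_rows, 3), np.nan)
        b = np.full((n_rows, 3), np.nan)
        m = np.full((n_rows, 3), np.nan)
        rye = np.full((n_rows, 3), np.nan)
        prov = np.full((n_rows, 3), "", dtype=object)
        sown = np.zeros((n_rows, 3), dtype=bool)

        for j, sp in enumerate(SPECIES):
            sown[:, j] = [
                sp in MIXTURE_COMPOSITIONS[c] for c in mix["composition"]
            ]
            rye[:, j] = [
                SOWING_PROPORTIONS[c].get(sp, np.nan) for c in mix["composition"]
            ]
            keys = ["site", "block", "year"] + (["population"] if sp == "clover" else [])
            r = refs[refs["species"] == sp]
            left = mix[["site", "block", "year", "population"]].copy()
            if sp != "clover":
                r = r.drop(columns=["population"])
            merged = left.merge(r, on=keys, how="left")
            b[:, j] = merged["ref_yield"].to_numpy()
            prov[:, j] = merged["provenance"].fillna("").to_numpy()
            mk = ["site", "year"] + (["population"] if sp == "clover" else [])
            mm = means[means["species"] == sp]
            if sp != "clover":
                mm = mm.drop(columns=["population"])
            merged_m = left.merge(mm, on=mk, how="left")
            m[:, j] = merged_m["M"].to_numpy()
            y[:, j] = np.where(sown[:, j], mix[f"yield_{sp}"].to_numpy(), np.nan)

        n_sp = sown.sum(axis=1)
        b_s = np.where(sown, b, np.nan)
        m_s = np.where(sown, m, np.nan)
        ref_ok = sown & np.isfinite(b) & (b > 0) & np.isfinite(m) & (m > 0)
        valid = (ref_ok == sown).all(axis=1)

        flags = np.full(n_rows, "", dtype=object)
        for j, sp in enumerate(SPECIES):
            badm = sown[:, j] & ~valid & (
                ~np.isfinite(b[:, j]) | (b[:, j] <= 0)
                | ~np.isfinite(m[:, j]) | (m[:, j] <= 0)
            )
            flags[badm] = np.where(
                flags[badm] == "",
                f"missing or zero {sp} reference",
                flags[badm] + f"; missing or zero {sp} reference",
            )

        with np.errstate(invalid="ignore", divide="ignore"):
            dry_m = y / m_s - rye
            s_dry = np.nansum(np.where(valid[:, None], dry_m, np.nan), axis=1)
            s_m = np.nansum(m_s, axis=1)
            ce = np.where(valid, s_dry * s_m / n_sp, np.nan)
            se = np.where(
                valid, np.nansum(dry_m * m_s, axis=1) - s_dry * s_m / n_sp, np.nan
            )
            y_o = np.where(valid, np.nansum(y, axis=1), np.nan)
            y_e = np.where(valid, np.nansum(rye * m_s, axis=1), np.nan)
            ne = y_o - y_e
            ry_o = y / b_s
            ry_c = ry_o / rye

        eff = pd.DataFrame({
            "site": mix["site"].to_numpy(),
            "block": mix["block"].to_numpy(),
            "plot": mix["plot"].to_numpy(),
            "population": mix["population"].to_numpy(),
            "mixtype": mix["composition"].to_numpy(),
            "year": mix["year"].to_numpy(),
            "baseline": baseline,
            "N": n_sp,
            "Y_O": y_o, "Y_E": y_e, "CE": ce, "SE": se, "NE": ne,
            "flags": flags,
        })
        eff_frames.append(eff)

        for j, sp in enumerate(SPECIES):
            rows = sown[:, j]
            if sp == "clover" and baseline == "N1" and not clover_ryc_n1:
                continue
            sflag = np.where(
                np.isfinite(b[:, j]) & (b[:, j] > 0),
                "", "undefined: pure-stand reference missing or zero",
            )
            spf = pd.DataFrame({
                "site": mix["site"].to_numpy()[rows],
                "block": mix["block"].to_numpy()[rows],
                "plot": mix["plot"].to_numpy()[rows],
                "population": mix["population"].to_numpy()[rows],
                "mixtype": mix["composition"].to_numpy()[rows],
                "year": mix["year"].to_numpy()[rows],
                "baseline": baseline,
                "species": sp,
                "RY_O": ry_o[rows, j],
                "RY_E": rye[rows, j],
                "delta_RY": ry_o[rows, j] - rye[rows, j],
                "RY_C": ry_c[rows, j],
                "reference_provenance": prov[rows, j],
                "flags": sflag[rows],
            })
            sp_frames.append(spf)

    effects = pd.concat(eff_frames, ignore_index=True)[EFFECTS_COLUMNS]
    species = pd.concat(sp_frames, ignore_index=True)[SPECIES_COLUMNS]
    sort_keys = ["baseline", "site", "block", "year", "population", "mixtype"]
    effects = effects.sort_values(sort_keys, ignore_index=True)
    species = species.sort_values(sort_keys + ["species"], ignore_index=True)
    return effects, species
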