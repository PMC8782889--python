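"""Synthetic harvest data with the field experiment's exact factor structure.

The generator emulates a five-year, two-site randomized complete block trial:
per site, 4 blocks of 38 plots (8 white-clover populations x {pure stand,
clover-grass TL, clover-chicory TC, clover-grass-chicory TLC}, two duplicate
ryegrass pure-stand plots at each of N0/N1, and one chicory pure-stand plot
at each of N0/N1), harvested 4 times per year.

The statistical model is deliberately phenomenological: the true relative
performance of each mixture species is parameterized directly as a ratio
``r_i`` so that recovery targets are exact.  Pure-stand annual expectations
are

    E[Y_pure,i] = mu_s * g_i * (1 + a_p if clover) * (1 + beta if N1 non-legume)
                  * (1 - d_y if N0 non-legume) * drought_{i,y}

and mixture species expectations are

    E[Y_mix,i] = RY_E,i * Y_pure,i(block level, N0) * r_i(p, y)

so that, by construction, the true N0-baseline corrected relative yield of
species *i* equals ``r_i`` and the true N1-baseline RY_C of non-legumes is
``r_i * (1 - d_y) / (1 + beta)``.  Multiplicative lognormal block effects are
shared by every plot of a block (so within-block relative yields cancel
them); lognormal residual noise acts per plot-year; annual totals are split
over four harvests by fixed proportions, and a non-sown (weed) fraction is
added to the harvested totals.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .schema import HARVEST_COLUMNS, MIXTURE_COMPOSITIONS, SOWING_PROPORTIONS, SPECIES

_SITE_NAMES = ("R", "D")


def _per_year(value, years: int) -> np.ndarray:
    """Scalar or per-year sequence; longer sequences are truncated so that
    scaled-down studies (fewer years) can reuse a config unchanged."""
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(years, float(arr))
    if arr.shape[0] < years:
        raise ValueError(f"expected scalar or >= length-{years} sequence, got {arr.shape}")
    return arr[:years]


def _pop_year(value, n_pop: int, years: int) -> np.ndarray:
    """Broadcast a scalar / per-year / per-population value to (pop, year)."""
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full((n_pop, years), float(arr))
    if arr.ndim == 1:
        if arr.shape[0] == n_pop:
            return np.repeat(arr[:, None], years, axis=1)
        if arr.shape[0] >= years:
            return np.repeat(arr[None, :years], n_pop, axis=0)
        raise ValueError(
            f"1-d ratio must have length n_populations ({n_pop}) or >= years ({years})"
        )
    if arr.shape[0] == n_pop and arr.shape[1] >= years:
        return arr[:, :years].copy()
    raise ValueError(f"ratio array must broadcast to ({n_pop}, {years}), got {arr.shape}")


@dataclass
class SyntheticConfig:
    """Parameters of the generative model.

    Yields are in t DM ha^-1 a^-1.  Defaults describe a productive temperate
    forage trial: unfertilized pure stands of clover ~8, ryegrass ~5.5 and
    chicory ~7 t at the better site, a fertilization response of +80% for
    non-legumes at 240 kg N, mild progressive nitrogen depletion of
    unfertilized non-legume stands, grass overyielding in mixture
    (r_grass > 1), clover underyielding (r_clover < 1) and neutral chicory.
    """

    seed: int = 0
    n_sites: int = 2
    n_blocks: int = 4
    n_populations: int = 8
    years: int = 5
    harvests_per_year: int = 4
    #: site productivity mu_s (t DM ha^-1 a^-1), one value per site
    site_productivity: tuple = (10.0, 8.5)
    #: species pure-stand multipliers g_i of site productivity
    g_clover: float = 0.8
    g_grass: float = 0.55
    g_chicory: float = 0.7
    #: relative pure-stand deviation of each clover population (a_p)
    pop_deviation: tuple = (0.0,) * 8
    #: relative yield gain of non-legume pure stands under fertilization
    beta: float = 0.8
    #: relative decline of unfertilized non-legume pure stands by year (d_y)
    depletion: tuple = (0.0, 0.05, 0.10, 0.15, 0.20)
    #: per-species drought multipliers, scalar or per-year
    drought_clover: tuple | float = 1.0
    drought_grass: tuple | float = 1.0
    drought_chicory: tuple | float = 1.0
    #: true relative-performance ratios r_i; scalar, per-population,
    #: per-year, or (population, year) arrays
    r_clover: object = 0.85
    r_grass: object = 1.35
    r_chicory: object = 1.0
    #: facilitation share per population: fraction of (r_grass - 1)
    #: attributable to nitrogen (used by the scenario presets to tie r_grass
    #: to the fertilization response)
    facilitation_share: tuple = (0.5,) * 8
    #: lognormal block-effect SD (log scale), shared by all plots of a block
    sigma_block: float = 0.10
    #: residual coefficient of variation per plot-year
    sigma_res: float = 0.10
    #: residual noise family: "lognormal" (default) or "normal"
    noise: str = "lognormal"
    #: non-sown (weed) fraction of harvested biomass
    nonsown_fraction: float = 0.05
    #: fixed proportions splitting the annual total over harvests
    harvest_split: tuple = (0.30, 0.30, 0.25, 0.15)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.n_sites < 1 or self.n_sites > len(_SITE_NAMES):
            raise ValueError(f"n_sites must be in 1..{len(_SITE_NAMES)}")
        if len(self.site_productivity) < self.n_sites:
            raise ValueError("site_productivity must give one value per site")
        if any(m <= 0 for m in self.site_productivity[: self.n_sites]):
            raise ValueError("site productivities must be positive")
        for name in ("g_clover", "g_grass", "g_chicory"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if len(self.pop_deviation) != self.n_populations:
            raise ValueError("pop_deviation must have one entry per population")
        if len(self.facilitation_share) != self.n_populations:
            raise ValueError("facilitation_share must have one entry per population")
        if not all(0.0 <= f <= 1.0 for f in self.facilitation_share):
            raise ValueError("facilitation shares must lie in [0, 1]")
        if not 0.0 <= self.nonsown_fraction <= 0.2:
            raise ValueError("nonsown_fraction must lie in [0, 0.2]")
        split = np.asarray(self.harvest_split, dtype=float)
        if len(split) != self.harvests_per_year or abs(split.sum() - 1.0) > 1e-9:
            raise ValueError("harvest_split must have one positive entry per "
                             "harvest and sum to 1")
        if np.any(split <= 0):
            raise ValueError("harvest_split proportions must be positive")
        if self.sigma_block < 0 or self.sigma_res < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.noise not in ("lognormal", "normal"):
            raise ValueError("noise must be 'lognormal' or 'normal'")
        _per_year(self.depletion, self.years)
        if np.any(np.asarray(self.depletion, dtype=float) >= 1.0):
            raise ValueError("depletion must stay below 1")
        for sp in SPECIES:
            _per_year(getattr(self, f"drought_{sp}"), self.years)
            r = _pop_year(getattr(self, f"r_{sp}"), self.n_populations, self.years)
            if np.any(r < 0):
                raise ValueError(f"r_{sp} must be non-negative")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        def plain(v):
            if isinstance(v, (np.ndarray, tuple, list)):
                return np.asarray(v).tolist()
            if isinstance(v, np.generic):
                return v.item()
            return v
        return {f.name: plain(getattr(self, f.name)) for f in dataclasses.fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                v = d[f.name]
                if isinstance(v, list):
                    v = np.asarray(v) if f.name.startswith("r_") else tuple(v)
                kwargs[f.name] = v
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **kwargs) -> "SyntheticConfig":
        return dataclasses.replace(self, **kwargs)


def generate_design(config: SyntheticConfig, seed: int | None = None) -> pd.DataFrame:
    """Plot layout of the randomized complete block design.

    Per site and block: the 8 clover populations each contribute a pure stand
    and the three mixtures (32 plots), ryegrass pure stands are duplicated at
    both fertilization levels (4 plots) and chicory pure stands appear once
    per level (2 plots) — 38 plots per block, 152 per site.  Plot order
    within each block is randomized under the seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    for s in range(config.n_sites):
        site = _SITE_NAMES[s]
        for b in range(1, config.n_blocks + 1):
            block_rows = []
            for p in range(1, config.n_populations + 1):
                pop = f"T{p}"
                block_rows.append(("pure_clover", pop, "N0", 1))
                for mixtype in MIXTURE_COMPOSITIONS:
                    block_rows.append((mixtype, pop, "N0", 1))
            for rep in (1, 2):
                for n_level in ("N0", "N1"):
                    block_rows.append(("pure_grass", "", n_level, rep))
            for n_level in ("N0", "N1"):
                block_rows.append(("pure_chicory", "", n_level, 1))
            order = rng.permutation(len(block_rows))
            for pos, idx in enumerate(order, start=1):
                comp, pop, n_level, rep = block_rows[idx]
                rows.append({
                    "site": site,
                    "block": f"B{b}",
                    "plot": f"{site}{b}-{pos:02d}",
                    "composition": comp,
                    "population": pop,
                    "n_level": n_level,
                    "replicate_id": rep,
                })
    return pd.DataFrame(rows)


def _expected_annual(layout: pd.DataFrame, config: SyntheticConfig) -> pd.DataFrame:
    """Noise-free per-species annual expectations, one row per plot-year.

    The block effect is *not* included here; it multiplies both pure stands
    and mixtures downstream, mirroring why relative yields are taken within
    blocks.
    """
    years = np.arange(1, config.years + 1)
    d_y = _per_year(config.depletion, config.years)
    drought = {sp: _per_year(getattr(config, f"drought_{sp}"), config.years)
               for sp in SPECIES}
    g = {"clover": config.g_clover, "grass": config.g_grass,
         "chicory": config.g_chicory}
    r = {sp: _pop_year(getattr(config, f"r_{sp}"), config.n_populations, config.years)
         for sp in SPECIES}
    mu = {_SITE_NAMES[s]: config.site_productivity[s] for s in range(config.n_sites)}
    a_p = {f"T{p + 1}": config.pop_deviation[p] for p in range(config.n_populations)}
    r_idx = {f"T{p + 1}": p for p in range(config.n_populations)}

    frame = layout.loc[layout.index.repeat(config.years)].reset_index(drop=True)
    frame["year"] = np.tile(years, len(layout))
    yi = frame["year"].to_numpy() - 1
    mu_s = frame["site"].map(mu).to_numpy()
    pop_i = frame["population"].map(r_idx).fillna(-1).astype(int).to_numpy()
    a = frame["population"].map(a_p).fillna(0.0).to_numpy()
    comp = frame["composition"].to_numpy()
    n1 = (frame["n_level"] == "N1").to_numpy()

    for sp in SPECIES:
        sown = np.array([sp in SOWING_PROPORTIONS[c] for c in comp])
        rye = np.array([SOWING_PROPORTIONS[c].get(sp, 0.0) for c in comp])
        legume = sp == "clover"
        # pure-stand expectation of this species at N0, block level,
        # population-matched for clover
        base = mu_s * g[sp] * drought[sp][yi]
        if legume:
            base = base * (1.0 + a)
        pure_n0 = base * (1.0 - (0.0 if legume else 1.0) * d_y[yi])
        pure_n1 = base * (1.0 + (0.0 if legume else 1.0) * config.beta)
        is_pure = comp == ("pure_" + sp)
        is_mix = np.isin(comp, list(MIXTURE_COMPOSITIONS)) & sown
        ratio = np.ones(len(frame))
        valid_pop = pop_i >= 0
        ratio[valid_pop] = r[sp][pop_i[valid_pop], yi[valid_pop]]
        exp_y = np.zeros(len(frame))
        exp_y[is_pure] = np.where(n1, pure_n1, pure_n0)[is_pure]
        exp_y[is_mix] = (rye * pure_n0 * ratio)[is_mix]
        frame[f"exp_{sp}"] = exp_y
    return frame


def generate_yields(
    layout: pd.DataFrame, config: SyntheticConfig, seed: int | None = None
) -> pd.DataFrame:
    """Simulate a harvest table for the given plot layout.

    Returns a validated-format long table, one row per plot x harvest, with
    total dry matter and botanical fractions.  Identical config and seed give
    a byte-identical table.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    frame = _expected_annual(layout, config)

    # multiplicative block effects (mean 1), shared by all plots of a block
    keys = frame["site"].astype(str) + ":" + frame["block"].astype(str)
    uniq = sorted(keys.unique())
    if config.sigma_block > 0:
        z = rng.standard_normal(len(uniq))
        bvals = np.exp(config.sigma_block * z - 0.5 * config.sigma_block**2)
    else:
        bvals = np.ones(len(uniq))
    beff = keys.map(dict(zip(uniq, bvals))).to_numpy()

    # residual noise per plot-year (mean 1), applied to all species at once
    if config.sigma_res > 0:
        if config.noise == "lognormal":
            sd = np.sqrt(np.log1p(config.sigma_res**2))
            eps = np.exp(sd * rng.standard_normal(len(frame)) - 0.5 * sd**2)
        else:
            eps = np.clip(
                1.0 + config.sigma_res * rng.standard_normal(len(frame)), 0.0, None
            )
    else:
        eps = np.ones(len(frame))

    for sp in SPECIES:
        frame[f"yield_{sp}"] = frame[f"exp_{sp}"] * beff * eps
    sown_total = sum(frame[f"yield_{sp}"] for sp in SPECIES)

    w = config.nonsown_fraction
    total = sown_total / (1.0 - w)
    split = np.asarray(config.harvest_split, dtype=float)

    n = len(frame)
    h = config.harvests_per_year
    out = frame.loc[frame.index.repeat(h)].reset_index(drop=True)
    out["harvest_no"] = np.tile(np.arange(1, h + 1), n)
    out["total_dm"] = np.repeat(total.to_numpy(), h) * np.tile(split, n)
    with np.errstate(invalid="ignore", divide="ignore"):
        for sp in SPECIES:
            share = np.where(
                sown_total.to_numpy() > 0,
                frame[f"yield_{sp}"].to_numpy() / sown_total.to_numpy(),
                0.0,
            )
            out[f"frac_{sp}"] = np.repeat(share * (1.0 - w), h)
    out["frac_nonsown"] = w
    return out[HARVEST_COLUMNS].copy()


def simulate(config: SyntheticConfig, seed: int | None = None) -> pd.DataFrame:
    """Generate the design and its harvest table in one call."""
    seed = config.seed if seed is None else seed
    layout = generate_design(config, seed)
    return generate_yields(layout, config, seed + 1)


def scenario_presets() -> dict[str, SyntheticConfig]:
    """Named scenario configurations used throughout the tests and docs.

    ``null``
        No diversity effects, no noise, no fertilization response: every
        NE/CE/SE is exactly zero and every RY_C exactly one.
    ``population-facilitation``
        The eight clover populations deliver increasing amounts of nitrogen
        to their companions: facilitation shares f_p rise from 0.25 to 1.0
        and the grass ratio is r_grass,p = 1 + f_p * beta.  Complementarity
        under N0 is therefore ordered by f_p.  Also serves as the
        strong-population-effect scenario for inference power checks.
    ``facilitation-matched``
        The hypothesis-3 mechanism in its pure form: every companion boost is
        fully nitrogen-mediated and exactly equivalent to fertilization
        (f_p = 1, r_companion = 1 + beta), while populations differ in
        pure-stand vigour (a_p from -25% to +25%).  Referencing against
        fertilized stands removes the facilitation term, so complementarity
        and its population differences collapse under N1.
    ``temporal-depletion``
        Unfertilized non-legume references deplete progressively while
        absolute mixture yields hold steady, so grass RY_C (N0) rises over
        the first years and levels off; drought in years 4-5 cuts clover
        performance.
    """
    beta = 0.8
    f_p = tuple(np.round(np.linspace(0.25, 1.0, 8), 4))
    presets = {}

    presets["null"] = SyntheticConfig(
        r_clover=1.0, r_grass=1.0, r_chicory=1.0,
        beta=0.0, depletion=(0.0,) * 5, pop_deviation=(0.0,) * 8,
        facilitation_share=(0.0,) * 8,
        sigma_block=0.0, sigma_res=0.0, nonsown_fraction=0.0,
    )

    presets["population-facilitation"] = SyntheticConfig(
        beta=beta,
        facilitation_share=f_p,
        r_grass=np.array([1.0 + f * beta for f in f_p]),
        r_clover=0.85, r_chicory=1.0,
        depletion=(0.0,) * 5,
    )

    presets["facilitation-matched"] = SyntheticConfig(
        beta=beta,
        facilitation_share=(1.0,) * 8,
        r_grass=1.0 + beta, r_chicory=1.0 + beta, r_clover=1.0,
        pop_deviation=tuple(np.round(np.linspace(-0.25, 0.25, 8), 4)),
        depletion=(0.0,) * 5,
    )

    d_y = np.array([0.0, 0.10, 0.20, 0.20, 0.20])
    presets["temporal-depletion"] = SyntheticConfig(
        beta=beta,
        depletion=tuple(d_y),
        r_grass=1.25 / (1.0 - d_y),
        r_chicory=1.0 / (1.0 - 0.5 * d_y),
        r_clover=np.array([0.85, 0.95, 1.0, 0.80, 0.70]),
        drought_clover=(1.0, 1.0, 1.0, 0.70, 0.70),
        drought_grass=(1.0, 1.0, 1.0, 0.85, 0.85),
        drought_chicory=(1.0, 1.0, 1.0, 0.90, 0.90),
    )
    return presets
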