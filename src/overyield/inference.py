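"""Factorial mixed-model inference on diversity-effect tables.

Reproduces the experiment's analysis workflow: each response (NE, CE, SE, or
a species' RY_C, per reference baseline) is modelled as a function of clover
population, experimental year (categorical), mixture type and site with all
their interactions as fixed effects, and plot nested in block as random
intercepts.  RY_C responses are square-root transformed.  The full model is
simplified by backward elimination on the small-sample-corrected Akaike
criterion (AICc, under maximum likelihood) respecting marginality, and the
fixed effects retained in the minimum adequate model are tested with
sequential (type-I) Wald chi-square tests, reported as F = chi2 / df with the
convention of the mixed-model ecosystem the analysis mirrors.

Model fitting is delegated to :class:`statsmodels.regression.mixed_linear_model.MixedLM`;
the AICc bookkeeping, the marginality-respecting search and the sequential
Wald tests (GLS whitening at the estimated variance components followed by
sequential decomposition) are implemented here.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import patsy
from scipy import stats
import statsmodels.api as sm

#: Canonical factor order (also the sequential-test order for main effects).
FACTORS = ("population", "year", "mixtype", "site")

Term = tuple[str, ...]


class InferenceError(RuntimeError):
    """Model could not be fitted (degenerate design or non-convergence)."""


def _respects_marginality(terms: tuple[Term, ...]) -> bool:
    tset = {frozenset(t) for t in terms}
    return all(
        frozenset(sub) in tset
        for t in terms
        for k in range(1, len(t))
        for sub in itertools.combinations(t, k)
    )


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one response model.

    ``response`` is a column of the effects table ("NE", "CE", "SE") or
    "RY_C" (then ``species`` selects the species from the species table).
    ``transform="auto"`` square-root transforms RY_C responses and leaves
    the partition components untransformed.  ``fixed=None`` means the full
    factorial over every factor with >= 2 levels in the data.
    """

    response: str
    baseline: str = "N0"
    species: str | None = None
    transform: str = "auto"
    fixed: tuple[Term, ...] | None = None

    def __post_init__(self):
        if self.fixed is not None:
            object.__setattr__(
                self, "fixed", tuple(tuple(t) for t in self.fixed)
            )
            if not _respects_marginality(self.fixed):
                raise ValueError("fixed terms violate marginality")

    def resolved_transform(self) -> str:
        if self.transform == "auto":
            return "sqrt" if self.response == "RY_C" else "none"
        return self.transform


def full_factorial_terms(factors: tuple[str, ...]) -> tuple[Term, ...]:
    """All main effects and interactions, ordered by interaction order and
    canonical factor order (the order of the experiment's tables)."""
    factors = tuple(f for f in FACTORS if f in factors)
    terms: list[Term] = []
    for order in range(1, len(factors) + 1):
        terms.extend(itertools.combinations(factors, order))
    return tuple(terms)


def _term_formula(term: Term) -> str:
    return ":".join(f"C({f})" for f in term)


def prepare_data(
    table: pd.DataFrame, spec: ModelSpec, *, drop_flagged: bool = True
) -> pd.DataFrame:
    """Select and transform the response for one model specification.

    Returns a frame with the response in column ``_y_``, the available fixed
    factors, and ``_block_`` / ``_plot_`` grouping labels.
    """
    df = table[table["baseline"] == spec.baseline].copy()
    if spec.response == "RY_C":
        if "species" not in df.columns:
            raise ValueError("RY_C responses require the species table")
        if spec.species is None:
            raise ValueError("spec.species must name the species for RY_C models")
        df = df[df["species"] == spec.species]
        resp = "RY_C"
    else:
        resp = spec.response
        if resp not in df.columns:
            raise ValueError(f"response column {resp!r} not in table")
    if drop_flagged and "flags" in df.columns:
        df = df[(df["flags"] == "") & np.isfinite(df[resp])]
    if df.empty:
        raise InferenceError(f"no rows for {spec}")

    y = df[resp].astype(float)
    if spec.resolved_transform() == "sqrt":
        if (y < 0).any():
            raise ValueError(
                "square-root transform requires a non-negative response"
            )
        y = np.sqrt(y)
    elif spec.resolved_transform() != "none":
        raise ValueError(f"unknown transform {spec.transform!r}")

    out = pd.DataFrame({
        "_y_": y.to_numpy(),
        "population": df["population"].astype(str).to_numpy(),
        "year": df["year"].astype(int).to_numpy(),
        "mixtype": df["mixtype"].astype(str).to_numpy(),
        "site": df["site"].astype(str).to_numpy(),
    })
    block = df["site"].astype(str) + ":" + df["block"].astype(str)
    out["_block_"] = block.to_numpy()
    out["_plot_"] = (block + ":" + df["plot"].astype(str)).to_numpy()
    return out


def _available_factors(data: pd.DataFrame) -> tuple[str, ...]:
    return tuple(f for f in FACTORS if data[f].nunique() >= 2)


def _resolve_terms(data: pd.DataFrame, spec: ModelSpec) -> tuple[Term, ...]:
    if spec.fixed is not None:
        terms = tuple(tuple(t) for t in spec.fixed)
        if not _respects_marginality(terms):
            raise ValueError("fixed terms violate marginality")
        return terms
    return full_factorial_terms(_available_factors(data))


@dataclass
class FittedModel:
    """A fitted mixed model plus the metadata the workflow needs."""

    spec: ModelSpec
    terms: tuple[Term, ...]
    data: pd.DataFrame
    result: object
    reml: bool
    formula: str

    @property
    def n_obs(self) -> int:
        return len(self.data)

    @property
    def k_params(self) -> int:
        # fixed effects + block variance + plot variance + residual variance
        return len(self.result.fe_params) + 3

    @property
    def loglike(self) -> float:
        return float(self.result.llf)

    @property
    def aicc(self) -> float:
        """AICc from the likelihood actually optimised (use ML fits when
        comparing fixed-effect structures)."""
        n, k = self.n_obs, self.k_params
        if n - k - 1 <= 0:
            return np.inf
        return -2.0 * self.loglike + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)

    def variance_components(self) -> dict:
        res = self.result
        block = float(np.asarray(res.cov_re).ravel()[0]) if res.cov_re.size else 0.0
        plot = float(res.vcomp[0]) if len(res.vcomp) else 0.0
        return {"block": block, "plot": plot, "residual": float(res.scale)}


def fit_model(
    data: pd.DataFrame | None = None,
    spec: ModelSpec | None = None,
    *,
    table: pd.DataFrame | None = None,
    reml: bool = True,
) -> FittedModel:
    """Fit the linear mixed model for one specification.

    ``data`` is either a prepared frame (from :func:`prepare_data`) or, via
    ``table=``, a raw effects/species table.  Random structure is always a
    block intercept plus plot-within-block intercept; it is never simplified.
    """
    if data is None:
        if table is None:
            raise ValueError("provide prepared data or table=")
        data = prepare_data(table, spec)
    elif "_y_" not in data.columns:
        data = prepare_data(data, spec)
    for f in _available_factors(data):
        if data[f].nunique() < 2:
            raise InferenceError(f"factor {f} has a single level")
    if data["_block_"].nunique() < 2:
        raise InferenceError(
            "design is degenerate (single block); more replication is needed "
            "to separate block, plot and residual variation"
        )
    terms = _resolve_terms(data, spec)
    rhs = " + ".join(_term_formula(t) for t in terms) if terms else "1"
    formula = f"_y_ ~ {rhs}"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.MixedLM.from_formula(
                formula,
                data,
                groups="_block_",
                re_formula="1",
                vc_formula={"plot": "0 + C(_plot_)"},
            )
            result = model.fit(reml=reml, method="lbfgs", maxiter=200)
            if not np.isfinite(result.llf):
                raise InferenceError("non-finite likelihood")
        except InferenceError:
            raise
        except Exception as exc:  # statsmodels raises assorted numeric errors
            raise InferenceError(
                f"mixed model failed for formula {formula!r}: {exc}"
            ) from exc
    return FittedModel(spec, terms, data, result, reml, formula)


@dataclass
class SelectionStep:
    step: int
    dropped: Term | None
    aicc: float
    candidates: dict


@dataclass
class SelectionResult:
    spec: ModelSpec
    final: FittedModel
    path: list[SelectionStep] = field(default_factory=list)

    @property
    def retained(self) -> tuple[Term, ...]:
        return self.final.terms

    def path_table(self) -> pd.DataFrame:
        rows = []
        for s in self.path:
            for term, aicc in s.candidates.items():
                rows.append({
                    "step": s.step,
                    "candidate_drop": ":".join(term),
                    "aicc_without": aicc,
                    "dropped": term == s.dropped,
                })
            rows.append({
                "step": s.step, "candidate_drop": "(keep all)",
                "aicc_without": s.aicc, "dropped": s.dropped is None,
            })
        return pd.DataFrame(rows)


def _droppable(terms: tuple[Term, ...]) -> list[Term]:
    sets = [frozenset(t) for t in terms]
    return [
        t for t, ts in zip(terms, sets)
        if not any(ts < other for other in sets)
    ]


def simplify_aicc(
    data: pd.DataFrame, spec: ModelSpec, *, verbose: bool = False
) -> SelectionResult:
    """Backward AICc elimination over the fixed terms, respecting marginality.

    At each step every currently droppable term (one not nested in a retained
    higher-order term) is removed in turn, the model refitted by maximum
    likelihood, and the removal that most lowers AICc accepted; ties prefer
    dropping the higher-order term.  The search stops when no removal lowers
    AICc.  The random structure is never simplified.  The final model is
    refitted by REML.
    """
    if "_y_" not in getattr(data, "columns", ()):
        data = prepare_data(data, spec)
    terms = _resolve_terms(data, spec)
    current = fit_model(data, replace(spec, fixed=terms), reml=False)
    path: list[SelectionStep] = []
    step = 0
    while True:
        step += 1
        candidates: dict[Term, float] = {}
        fits: dict[Term, FittedModel] = {}
        for t in _droppable(current.terms):
            reduced = tuple(x for x in current.terms if x != t)
            try:
                cand = fit_model(data, replace(spec, fixed=reduced), reml=False)
            except InferenceError as exc:
                warnings.warn(f"candidate drop {t} skipped: {exc}", stacklevel=2)
                continue
            candidates[t] = cand.aicc
            fits[t] = cand
        improving = {t: a for t, a in candidates.items() if a < current.aicc}
        if not improving:
            path.append(SelectionStep(step, None, current.aicc, candidates))
            break
        best = min(improving, key=lambda t: (round(improving[t], 10), -len(t)))
        path.append(SelectionStep(step, best, current.aicc, candidates))
        if verbose:
            print(f"step {step}: drop {best} AICc {current.aicc:.2f} -> "
                  f"{improving[best]:.2f}")
        current = fits[best]
    final_spec = replace(spec, fixed=current.terms)
    final = fit_model(data, final_spec, reml=True)
    return SelectionResult(final_spec, final, path)


def _group_whitener(data: pd.DataFrame, vc: dict) -> np.ndarray:
    """Inverse-Cholesky whitening matrix blocks for V at the fitted variance
    components, returned as one block-diagonal operator applied row-wise."""
    n = len(data)
    W = np.zeros((n, n))
    idx = np.arange(n)
    for _, rows in data.groupby("_block_", sort=False).indices.items():
        rows = np.asarray(rows)
        m = len(rows)
        plots = data["_plot_"].to_numpy()[rows]
        same_plot = (plots[:, None] == plots[None, :]).astype(float)
        V = (
            vc["residual"] * np.eye(m)
            + vc["block"] * np.ones((m, m))
            + vc["plot"] * same_plot
        )
        L = np.linalg.cholesky(V)
        W[np.ix_(rows, rows)] = np.linalg.inv(L)
    return W


def sequential_tests(
    fit: FittedModel, *, all_terms: tuple[Term, ...] | None = None
) -> pd.DataFrame:
    """Sequential (type-I) Wald chi-square tests of the retained fixed terms.

    Terms are tested in the canonical order (population, year, mixtype, site,
    then interactions), each adjusted for the terms before it: the design is
    whitened by the inverse Cholesky factor of the fitted covariance and the
    Wald chi-square of each term is the drop in whitened residual sum of
    squares when its columns enter.  Reported as F = chi2 / df with the
    p-value from F(df, ddf), where the denominator df follows the containment
    convention of the nlme ecosystem: terms constant within plots are tested
    against the plot stratum, terms varying within plots against the residual
    stratum.  Terms of ``all_terms`` that were not retained appear with
    ``retained=False`` and missing statistics (printed as "–").
    """
    data = fit.data
    order_ref = all_terms if all_terms is not None else fit.terms
    order_ref = full_factorial_terms(tuple({f for t in order_ref for f in t}))
    retained = [t for t in order_ref if t in fit.terms]
    missing = [t for t in order_ref if t not in fit.terms]

    rhs = " + ".join(_term_formula(t) for t in retained) if retained else "1"
    y_dm, X_dm = patsy.dmatrices(f"_y_ ~ {rhs}", data, return_type="dataframe")
    slices = X_dm.design_info.term_name_slices
    X = X_dm.to_numpy()
    y = y_dm.to_numpy().ravel()

    W = _group_whitener(data, fit.variance_components())
    Xw = W @ X
    yw = W @ y

    cols: list[int] = list(range(*slices["Intercept"].indices(X.shape[1])))
    rss_prev = _rss(Xw[:, cols], yw)
    n = len(yw)
    n_plots = data["_plot_"].nunique()
    n_blocks = data["_block_"].nunique()

    # containment: a term whose design columns are constant within plots is
    # tested in the plot stratum, otherwise in the residual stratum
    plot_codes = data["_plot_"].astype("category").cat.codes.to_numpy()
    def _between_plot(term_cols: list[int]) -> bool:
        sub = pd.DataFrame(X[:, term_cols])
        return int(sub.groupby(plot_codes).nunique().max().max() or 1) == 1

    term_info = []
    for t in retained:
        name = _term_formula(t)
        sl = slices[name]
        new_cols = list(range(*sl.indices(X.shape[1])))
        rank_before = np.linalg.matrix_rank(Xw[:, cols])
        cols = cols + new_cols
        rank_after = np.linalg.matrix_rank(Xw[:, cols])
        df_t = rank_after - rank_before
        rss = _rss(Xw[:, cols], yw)
        chi2 = max(rss_prev - rss, 0.0)
        rss_prev = rss
        term_info.append((t, df_t, chi2, _between_plot(new_cols)))

    p_between = 1 + sum(df for _, df, _, bet in term_info if bet)
    p_within = sum(df for _, df, _, bet in term_info if not bet)
    ddf_between = max(n_plots - (n_blocks - 1) - p_between, 1)
    ddf_within = max(n - n_plots - p_within, 1)

    rows = []
    for t, df_t, chi2, between in term_info:
        fval = chi2 / df_t if df_t else np.nan
        ddf = ddf_between if between else ddf_within
        pval = float(stats.f.sf(fval, df_t, ddf)) if df_t else np.nan
        rows.append({
            "term": ":".join(t), "retained": True, "df": df_t, "ddf": ddf,
            "chi2": chi2, "F": fval, "P": pval,
        })
    for t in missing:
        rows.append({
            "term": ":".join(t), "retained": False, "df": np.nan, "ddf": np.nan,
            "chi2": np.nan, "F": np.nan, "P": np.nan,
        })
    out = pd.DataFrame(rows)
    key = {":".join(t): i for i, t in enumerate(order_ref)}
    return out.sort_values("term", key=lambda s: s.map(key), ignore_index=True)


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def analyze(
    table: pd.DataFrame, spec: ModelSpec
) -> tuple[SelectionResult, pd.DataFrame]:
    """Full workflow for one response: prepare, simplify by AICc, test.

    Returns the selection result and the sequential Wald test table over the
    full factorial term set (dropped terms marked not retained).
    """
    data = prepare_data(table, spec)
    sel = simplify_aicc(data, spec)
    tests = sequential_tests(
        sel.final, all_terms=full_factorial_terms(_available_factors(data))
    )
    return sel, tests
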