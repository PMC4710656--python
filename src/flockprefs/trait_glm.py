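"""Fixed-effects linear model for the measured ewe traits.

Each trait y (body weight, body length, heart girth, BCS, milk yield, price)
is analysed with the fixed linear model

    y = mu + Site + Farmer(Site) + Breed + Quality + Breed:Site + e

where Farmer(Site) is a *fixed* effect nested within site (farmer labels are
meaningful only within their site) and Quality is the within-flock class
Best/Average/Poor.  Age (from dentition) and the Quality:Breed and
Quality:Site interactions are screened in preliminary fits and kept only if
significant.

Terms are tested with Type II (marginal, respecting the containment
hierarchy) F tests by default; least-squares means are predictions averaged
with equal weight over the levels of the non-focal factors, with farmers
weighted equally within their site.  Pairwise LS-mean comparisons are
summarized as a compact letter display (unadjusted t tests at alpha = 0.05
by default; Tukey HSD behind a flag).

The design matrix is built here explicitly (treatment coding, nested farmer
dummies) so that the same cell encoder serves both the fit and the LS-mean
reference grid; the least-squares solve itself is statsmodels OLS.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .survey_data import DEFAULT_BREEDS, QUALITY_CLASSES

TRAIT_RESPONSES = ("body_weight", "body_length", "heart_girth",
                   "bcs", "milk_yield", "price")

DEFAULT_TERMS = ("site", "farmer(site)", "breed", "quality", "breed:site")
SCREEN_CANDIDATES = ("age", "quality:breed", "quality:site")

# factor content of each term, for the Type II containment hierarchy
_TERM_FACTORS: Mapping[str, frozenset[str]] = {
    "site": frozenset({"site"}),
    "farmer(site)": frozenset({"site", "farmer"}),
    "breed": frozenset({"breed"}),
    "quality": frozenset({"quality"}),
    "breed:site": frozenset({"breed", "site"}),
    "quality:breed": frozenset({"quality", "breed"}),
    "quality:site": frozenset({"quality", "site"}),
    "age": frozenset({"age"}),
}


@dataclass(frozen=True)
class ModelSpec:
    """Response trait plus the model terms to fit."""

    response: str
    terms: tuple[str, ...] = DEFAULT_TERMS

    def __post_init__(self):
        unknown = [t for t in self.terms if t not in _TERM_FACTORS]
        if unknown:
            raise ValueError(f"unknown model term(s): {unknown}")
        if "farmer(site)" in self.terms and "site" not in self.terms:
            raise ValueError("farmer(site) requires its parent term site")

    def with_terms(self, *extra: str) -> "ModelSpec":
        return replace(self, terms=tuple(self.terms) + tuple(t for t in extra
                                                             if t not in self.terms))


def _contains(a: str, b: str) -> bool:
    """Term a strictly contains term b in the marginality hierarchy."""
    return a != b and _TERM_FACTORS[a] >= _TERM_FACTORS[b]


def _ordered_levels(values: pd.Series, preferred: Sequence[str]) -> list[str]:
    present = list(pd.unique(values))
    ordered = [l for l in preferred if l in present]
    ordered += sorted(set(present) - set(ordered))
    return ordered


@dataclass
class Design:
    """Reduced-rank (treatment-coded) design matrix plus its cell encoder."""

    X: np.ndarray
    y: np.ndarray
    columns: list[str]
    term_cols: dict[str, list[int]]
    levels: dict[str, list[str]]
    farmers_by_site: dict[str, list[str]]
    spec: ModelSpec
    terms: tuple[str, ...]       # terms actually encoded (degenerate ones dropped)
    age_mean: float | None
    dropped_terms: list[str]
    observed_cells: set[tuple]
    _encoders: list[Callable] = field(repr=False, default_factory=list)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def encode(self, site: str, farmer: str, breed: str, quality: str,
               age: float | None = None) -> np.ndarray:
        cell = {"site": site, "farmer": farmer, "breed": breed,
                "quality": quality, "age": age}
        return np.array([enc(cell) for enc in self._encoders], dtype=float)

    def simulate_response(self, beta: Sequence[float], sigma: float,
                          rng: np.random.Generator) -> np.ndarray:
        """Draw y = X beta + N(0, sigma^2) — used by recovery simulations."""
        beta = np.asarray(beta, dtype=float)
        if beta.shape != (self.p,):
            raise ValueError(f"beta must have length {self.p}")
        return self.X @ beta + rng.normal(0.0, sigma, size=self.n)


def build_design(df: pd.DataFrame, spec: ModelSpec) -> Design:
    """Build the treatment-coded design matrix for ``spec`` from tidy data.

    Farmer-within-site dummies are constructed per site (reference farmer is
    each site's first), so the nested effect is identified alongside the site
    main effect.  Terms whose factor has a single level in the data are
    dropped with a warning rather than producing an all-zero block.
    """
    needed = {"site", "farmer_id", "breed", "quality", spec.response}
    if "age" in spec.terms:
        needed.add("age")
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"data lacks column(s) {sorted(missing)}")
    df = df.copy()
    if "age" in spec.terms and df["age"].isna().any():
        n0 = len(df)
        df = df[df["age"].notna()]
        warnings.warn(f"dropped {n0 - len(df)} record(s) with missing age",
                      stacklevel=2)
    if df.empty:
        raise ValueError("no records to fit")

    sites = _ordered_levels(df["site"], ())
    breeds = _ordered_levels(df["breed"], DEFAULT_BREEDS)
    quals = _ordered_levels(df["quality"], QUALITY_CLASSES)
    farmers_by_site = {
        s: sorted(df.loc[df["site"] == s, "farmer_id"].unique()) for s in sites
    }
    levels = {"site": sites, "breed": breeds, "quality": quals}

    dropped: list[str] = []
    terms: list[str] = []
    for t in spec.terms:
        fac = _TERM_FACTORS[t] - {"age", "farmer"}
        degenerate = any(len(levels[f]) < 2 for f in fac)
        if t == "farmer(site)":
            degenerate = all(len(v) < 2 for v in farmers_by_site.values())
        if t == "age":
            degenerate = df["age"].nunique() < 2
        if degenerate:
            dropped.append(t)
            warnings.warn(f"term {t!r} dropped: factor has a single level",
                          stacklevel=2)
        else:
            terms.append(t)

    columns: list[str] = ["Intercept"]
    encoders: list[Callable] = [lambda cell: 1.0]
    term_cols: dict[str, list[int]] = {"Intercept": [0]}

    def add(term: str, label: str, enc: Callable) -> None:
        term_cols.setdefault(term, []).append(len(columns))
        columns.append(label)
        encoders.append(enc)

    def ind(key: str, level: str) -> Callable:
        return lambda cell, k=key, l=level: 1.0 if cell[k] == l else 0.0

    for t in terms:
        if t == "site":
            for s in sites[1:]:
                add(t, f"site[{s}]", ind("site", s))
        elif t == "farmer(site)":
            for s in sites:
                for f in farmers_by_site[s][1:]:
                    add(t, f"farmer[{f}]in[{s}]", ind("farmer", f))
        elif t == "breed":
            for b in breeds[1:]:
                add(t, f"breed[{b}]", ind("breed", b))
        elif t == "quality":
            for q in quals[1:]:
                add(t, f"quality[{q}]", ind("quality", q))
        elif t == "breed:site":
            for b, s in itertools.product(breeds[1:], sites[1:]):
                add(t, f"breed[{b}]:site[{s}]",
                    lambda cell, b=b, s=s: float(cell["breed"] == b and cell["site"] == s))
        elif t == "quality:breed":
            for q, b in itertools.product(quals[1:], breeds[1:]):
                add(t, f"quality[{q}]:breed[{b}]",
                    lambda cell, q=q, b=b: float(cell["quality"] == q and cell["breed"] == b))
        elif t == "quality:site":
            for q, s in itertools.product(quals[1:], sites[1:]):
                add(t, f"quality[{q}]:site[{s}]",
                    lambda cell, q=q, s=s: float(cell["quality"] == q and cell["site"] == s))
        elif t == "age":
            add(t, "age", lambda cell: float(cell["age"]))

    cells = df[["site", "farmer_id", "breed", "quality"]].to_numpy()
    ages = df["age"].to_numpy() if "age" in df.columns else np.full(len(df), np.nan)
    X = np.empty((len(df), len(columns)))
    for i in range(len(df)):
        cell = {"site": cells[i, 0], "farmer": cells[i, 1],
                "breed": cells[i, 2], "quality": cells[i, 3], "age": ages[i]}
        X[i] = [enc(cell) for enc in encoders]

    observed = {tuple(r) for r in df[["site", "breed", "quality"]].to_numpy()}
    age_mean = float(df["age"].mean()) if "age" in df.columns and df["age"].notna().any() else None
    return Design(X=X, y=df[spec.response].to_numpy(dtype=float),
                  columns=columns, term_cols=term_cols, levels=levels,
                  farmers_by_site=farmers_by_site, spec=spec,
                  terms=tuple(terms),
                  age_mean=age_mean, dropped_terms=dropped,
                  observed_cells=observed, _encoders=encoders)


@dataclass
class ModelFit:
    """OLS fit of a Design: coefficients, covariance and residual summaries."""

    design: Design
    params: np.ndarray
    cov: np.ndarray
    df_resid: int
    rss: float
    mse_resid: float
    fitted: np.ndarray
    resid: np.ndarray

    @property
    def spec(self) -> ModelSpec:
        return self.design.spec

    def coef_table(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov))
        return pd.DataFrame({"coef": self.params, "se": se},
                            index=self.design.columns)

    def residual_diagnostics(self) -> dict[str, float]:
        """Numeric stand-in for the visual Q-Q/histogram normality check."""
        r = self.resid
        w, p = st.shapiro(r) if 3 <= len(r) <= 5000 else (np.nan, np.nan)
        return {
            "n": int(len(r)),
            "skewness": float(st.skew(r)),
            "excess_kurtosis": float(st.kurtosis(r)),
            "shapiro_w": float(w),
            "shapiro_p": float(p),
        }


def fit_ols(design: Design) -> ModelFit:
    """Least-squares fit; errors out naming aliased columns if rank-deficient."""
    X, y = design.X, design.y
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # pivoted QR fingers the dependent columns
        _, r, piv = _qr_pivot(X)
        aliased = [design.columns[j] for j in piv[rank:]]
        raise np.linalg.LinAlgError(
            f"design is rank deficient (rank {rank} < {X.shape[1]}); "
            f"aliased column(s): {aliased}")
    if X.shape[0] <= X.shape[1]:
        raise np.linalg.LinAlgError("no residual degrees of freedom")
    res = sm.OLS(y, X).fit()
    return ModelFit(design=design, params=np.asarray(res.params),
                    cov=np.asarray(res.cov_params()),
                    df_resid=int(res.df_resid), rss=float(res.ssr),
                    mse_resid=float(res.mse_resid),
                    fitted=np.asarray(res.fittedvalues),
                    resid=np.asarray(res.resid))


def _qr_pivot(X: np.ndarray):
    import scipy.linalg as sl
    q, r, piv = sl.qr(X, pivoting=True, mode="economic")
    return q, r, piv


def _rss(X: np.ndarray, y: np.ndarray, cols: Sequence[int]) -> tuple[float, int]:
    Xs = X[:, list(cols)]
    beta, res, rank, _ = np.linalg.lstsq(Xs, y, rcond=None)
    resid = y - Xs @ beta
    return float(resid @ resid), int(rank)


def significance_code(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def anova_table(fit: ModelFit, ss_type: str = "II") -> pd.DataFrame:
    """Term-wise F tests (Type I sequential, II marginal, or III drop-term).

    Type II, the default, tests each term against the model containing all
    terms that do not contain it in the marginality hierarchy; the error
    mean square always comes from the complete model.
    """
    design = fit.design
    if fit.df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")
    terms = [t for t in design.term_cols if t != "Intercept"]
    X, y = design.X, design.y
    rows = []
    seq_cols = [0]
    for t in terms:
        if ss_type == "I":
            reduced_cols = list(seq_cols)
            full_cols = reduced_cols + design.term_cols[t]
            seq_cols = full_cols
        elif ss_type == "II":
            keep = [s for s in terms if s != t and not _contains(s, t)]
            reduced_cols = [0] + [c for s in keep for c in design.term_cols[s]]
            full_cols = reduced_cols + design.term_cols[t]
        elif ss_type == "III":
            full_cols = [0] + [c for s in terms for c in design.term_cols[s]]
            reduced_cols = [c for c in full_cols if c not in design.term_cols[t]]
        else:
            raise ValueError(f"unknown sum-of-squares type {ss_type!r}")
        rss_red, rank_red = _rss(X, y, reduced_cols)
        rss_full, rank_full = _rss(X, y, full_cols)
        df_t = rank_full - rank_red
        ss = rss_red - rss_full
        if df_t <= 0:
            f_val, p = np.nan, np.nan
        else:
            f_val = (ss / df_t) / fit.mse_resid
            p = float(st.f.sf(f_val, df_t, fit.df_resid))
        rows.append({"term": t, "df": df_t, "sum_sq": ss, "F": f_val,
                     "p": p, "signif": significance_code(p)})
    rows.append({"term": "Residual", "df": fit.df_resid, "sum_sq": fit.rss,
                 "F": np.nan, "p": np.nan, "signif": ""})
    return pd.DataFrame(rows)


def screen_terms(
    df: pd.DataFrame,
    base_spec: ModelSpec,
    candidates: Sequence[str] = SCREEN_CANDIDATES,
    alpha: float = 0.05,
    ss_type: str = "II",
) -> tuple[ModelSpec, pd.DataFrame]:
    """Preliminary screening: add each candidate to the base model, keep if p < alpha.

    Each candidate is tested one at a time on top of the base model with a
    Type II F test; candidates that cannot be estimated (aliased, degenerate)
    are reported and treated as not retained.  Returns the retained spec and
    a report frame with one row per candidate.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    rows, retained = [], []
    if "age" in candidates and "age" in df.columns and df["age"].isna().any():
        df = df[df["age"].notna()]
        warnings.warn("screening restricted to records with known age", stacklevel=2)
    for cand in candidates:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                design = build_design(df, base_spec.with_terms(cand))
                if cand not in design.terms:
                    raise ValueError("candidate degenerate in this data")
                fit = fit_ols(design)
            tab = anova_table(fit, ss_type=ss_type).set_index("term")
            f_val, p, df_t = (tab.loc[cand, "F"], tab.loc[cand, "p"],
                              tab.loc[cand, "df"])
            keep = bool(p < alpha)
        except (np.linalg.LinAlgError, ValueError, KeyError) as exc:
            f_val, p, df_t, keep = np.nan, np.nan, 0, False
            rows.append({"candidate": cand, "df": df_t, "F": f_val, "p": p,
                         "retained": keep, "note": f"inestimable: {exc}"})
            continue
        if keep:
            retained.append(cand)
        rows.append({"candidate": cand, "df": int(df_t), "F": float(f_val),
                     "p": float(p), "retained": keep, "note": ""})
    return base_spec.with_terms(*retained), pd.DataFrame(rows)


@dataclass
class LsMeansTable:
    """LS-means for one factor margin, with the contrast rows that built them."""

    factors: tuple[str, ...]
    table: pd.DataFrame          # level columns + estimate, se, estimable
    L: np.ndarray                # one contrast row per margin cell
    fit: ModelFit

    def with_letters(self, alpha: float = 0.05, adjust: str | None = None) -> pd.DataFrame:
        out = self.table.copy()
        out["letters"] = letter_groups(self, alpha=alpha, adjust=adjust)
        return out


def ls_means(fit: ModelFit, factors: Sequence[str]) -> LsMeansTable:
    """Least-squares means for a factor margin (e.g. ("breed", "site")).

    Each margin cell's estimate is the model prediction averaged with equal
    weight over the levels of every non-focal factor; farmers are averaged
    within their own site (and sites equally when site is not focal).  A
    margin with no observed records in any contributing design cell is
    flagged ``estimable = False`` but still reported.
    """
    design = fit.design
    for f in factors:
        if f not in ("site", "breed", "quality"):
            raise ValueError(f"cannot take LS-means over {f!r}")
    margin_levels = [design.levels[f] for f in factors]
    rows, Ls = [], []
    for combo in itertools.product(*margin_levels):
        fixed = dict(zip(factors, combo))
        sites = [fixed["site"]] if "site" in fixed else design.levels["site"]
        breeds = [fixed["breed"]] if "breed" in fixed else design.levels["breed"]
        quals = [fixed["quality"]] if "quality" in fixed else design.levels["quality"]
        L = np.zeros(design.p)
        for s in sites:
            farmers = design.farmers_by_site[s]
            for f_ in farmers:
                for b in breeds:
                    for q in quals:
                        w = (1 / len(sites)) * (1 / len(farmers)) \
                            * (1 / len(breeds)) * (1 / len(quals))
                        L += w * design.encode(s, f_, b, q, age=design.age_mean)
        est = float(L @ fit.params)
        se = float(np.sqrt(L @ fit.cov @ L))
        estimable = any(
            (s, b, q) in design.observed_cells
            for s in sites for b in breeds for q in quals
        )
        if not estimable:
            warnings.warn(f"margin {fixed} has no observed records; "
                          "its LS-mean is an extrapolation", stacklevel=2)
        rows.append({**fixed, "estimate": est, "se": se, "estimable": estimable})
        Ls.append(L)
    return LsMeansTable(factors=tuple(factors), table=pd.DataFrame(rows),
                        L=np.vstack(Ls), fit=fit)


def pairwise_pvalues(lsm: LsMeansTable, adjust: str | None = None) -> np.ndarray:
    """Symmetric matrix of pairwise LS-mean difference p-values.

    ``adjust=None`` gives plain two-sided t tests on each difference (the
    convention behind "significantly different at p < 0.05" footnotes);
    ``adjust="tukey"`` uses the studentized range.
    """
    k = lsm.L.shape[0]
    fit = lsm.fit
    P = np.full((k, k), np.nan)
    np.fill_diagonal(P, 1.0)
    for i, j in itertools.combinations(range(k), 2):
        l = lsm.L[i] - lsm.L[j]
        var = float(l @ fit.cov @ l)
        if var <= 0:
            p = 1.0
        else:
            tval = float(l @ fit.params) / np.sqrt(var)
            if adjust is None:
                p = 2.0 * float(st.t.sf(abs(tval), fit.df_resid))
            elif adjust == "tukey":
                p = float(st.studentized_range.sf(abs(tval) * np.sqrt(2), k,
                                                  fit.df_resid))
            else:
                raise ValueError(f"unknown adjustment {adjust!r}")
        P[i, j] = P[j, i] = p
    return P


def letter_groups(lsm: LsMeansTable, alpha: float = 0.05,
                  adjust: str | None = None) -> list[str]:
    """Compact letter display by insert-and-absorb.

    Levels sharing a letter are not significantly different at ``alpha``;
    letters are assigned in order of descending estimate (the best mean gets
    'a').  Returned in the row order of ``lsm.table``.
    """
    est = lsm.table["estimate"].to_numpy()
    k = len(est)
    P = pairwise_pvalues(lsm, adjust=adjust)
    groups: list[frozenset[int]] = [frozenset(range(k))]
    for i, j in itertools.combinations(range(k), 2):
        if P[i, j] < alpha:
            new: list[frozenset[int]] = []
            for s in groups:
                if i in s and j in s:
                    new.extend([s - {i}, s - {j}])
                else:
                    new.append(s)
            # absorb: drop empties, duplicates and strict subsets
            uniq = []
            for s in new:
                if s and s not in uniq:
                    uniq.append(s)
            groups = [s for s in uniq
                      if not any(s < t for t in uniq)]
    # order groups by their best (largest-estimate) member
    order = np.argsort(-est, kind="stable")
    rank_of = {int(lvl): r for r, lvl in enumerate(order)}
    groups.sort(key=lambda s: min(rank_of[m] for m in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = ["" for _ in range(k)]
    for gi, s in enumerate(groups):
        for m in s:
            letters[m] += alphabet[gi]
    return ["".join(sorted(l)) for l in letters]
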