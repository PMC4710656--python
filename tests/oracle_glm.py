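"""Independent brute-force linear-model oracle for the test suite.

Deliberately naive: its own dummy coding, normal equations solved with an
explicit inverse, F tests from residual-sum-of-squares differences computed
through projections, LS-means as explicitly enumerated weighted prediction
contrasts.  Shares no code with flockprefs.trait_glm.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import scipy.stats as st

BREED_ORDER = ("Red Maasai", "Dorper", "Cross")
QUALITY_ORDER = ("Best", "Average", "Poor")

TERM_FACTORS = {
    "site": {"site"}, "farmer(site)": {"site", "farmer"},
    "breed": {"breed"}, "quality": {"quality"},
    "breed:site": {"breed", "site"}, "quality:breed": {"quality", "breed"},
    "quality:site": {"quality", "site"}, "age": {"age"},
}


def _levels(df: pd.DataFrame):
    sites = sorted(df["site"].unique())
    breeds = [b for b in BREED_ORDER if b in set(df["breed"])]
    breeds += sorted(set(df["breed"]) - set(breeds))
    quals = [q for q in QUALITY_ORDER if q in set(df["quality"])]
    farmers = {s: sorted(df.loc[df["site"] == s, "farmer_id"].unique())
               for s in sites}
    return sites, breeds, quals, farmers


def design_matrix(df: pd.DataFrame, terms):
    """Treatment-coded design; returns (X, labelled term -> column indices)."""
    sites, breeds, quals, farmers = _levels(df)
    cols = [np.ones(len(df))]
    term_cols = {"Intercept": [0]}

    def block(term, vectors):
        idx = []
        for v in vectors:
            idx.append(len(cols))
            cols.append(v.astype(float))
        if idx:
            term_cols[term] = idx

    for t in terms:
        if t == "site":
            block(t, [(df["site"] == s).to_numpy() for s in sites[1:]])
        elif t == "farmer(site)":
            vs = []
            for s in sites:
                for f in farmers[s][1:]:
                    vs.append((df["farmer_id"] == f).to_numpy())
            block(t, vs)
        elif t == "breed":
            block(t, [(df["breed"] == b).to_numpy() for b in breeds[1:]])
        elif t == "quality":
            block(t, [(df["quality"] == q).to_numpy() for q in quals[1:]])
        elif t == "breed:site":
            block(t, [((df["breed"] == b) & (df["site"] == s)).to_numpy()
                      for b, s in itertools.product(breeds[1:], sites[1:])])
        elif t == "quality:breed":
            block(t, [((df["quality"] == q) & (df["breed"] == b)).to_numpy()
                      for q, b in itertools.product(quals[1:], breeds[1:])])
        elif t == "quality:site":
            block(t, [((df["quality"] == q) & (df["site"] == s)).to_numpy()
                      for q, s in itertools.product(quals[1:], sites[1:])])
        elif t == "age":
            block(t, [df["age"].to_numpy()])
        else:
            raise ValueError(t)
    return np.column_stack(cols), term_cols


def fit(df: pd.DataFrame, response: str, terms):
    """Normal-equations OLS: beta, covariance, RSS, residual df."""
    X, term_cols = design_matrix(df, terms)
    y = df[response].to_numpy(dtype=float)
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    df_resid = len(y) - X.shape[1]
    s2 = float(resid @ resid) / df_resid
    return {"X": X, "y": y, "term_cols": term_cols, "beta": beta,
            "cov": s2 * XtX_inv, "rss": float(resid @ resid),
            "df_resid": df_resid, "s2": s2}


def _rss_proj(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    XtX = X.T @ X
    P = X @ np.linalg.pinv(XtX) @ X.T
    r = y - P @ y
    return float(r @ r), int(np.linalg.matrix_rank(X))


def type2_tests(df: pd.DataFrame, response: str, terms):
    """Type II F tests via projection RSS differences, full-model error MS."""
    res = fit(df, response, terms)
    X, y, tc = res["X"], res["y"], res["term_cols"]
    mse = res["s2"]
    out = {}
    for t in terms:
        keep = [s for s in terms
                if s != t and not TERM_FACTORS[s] >= TERM_FACTORS[t]]
        red_cols = [0] + [c for s in keep for c in tc[s]]
        full_cols = red_cols + tc[t]
        rss_r, rank_r = _rss_proj(X[:, red_cols], y)
        rss_f, rank_f = _rss_proj(X[:, full_cols], y)
        dft = rank_f - rank_r
        f_val = ((rss_r - rss_f) / dft) / mse
        out[t] = {"df": dft, "F": f_val,
                  "p": float(st.f.sf(f_val, dft, res["df_resid"]))}
    return out


def lsmeans(df: pd.DataFrame, response: str, terms, factors):
    """LS-means via explicit enumeration of prediction-cell contrast rows."""
    res = fit(df, response, terms)
    sites, breeds, quals, farmers = _levels(df)
    lev = {"site": sites, "breed": breeds, "quality": quals}
    age_mean = float(df["age"].mean()) if "age" in terms else None

    def encode(site, farmer, breed, quality):
        row = df.iloc[[0]].copy()
        row.loc[:, ["site", "farmer_id", "breed", "quality"]] = \
            [site, farmer, breed, quality]
        if age_mean is not None:
            row.loc[:, "age"] = age_mean
        Xr, _ = design_matrix(pd.concat([df, row]).reset_index(drop=True), terms)
        return Xr[-1]

    out = []
    for combo in itertools.product(*[lev[f] for f in factors]):
        fixed = dict(zip(factors, combo))
        ss = [fixed.get("site")] if "site" in fixed else sites
        bs = [fixed.get("breed")] if "breed" in fixed else breeds
        qs = [fixed.get("quality")] if "quality" in fixed else quals
        L = np.zeros(res["X"].shape[1])
        for s in ss:
            for f in farmers[s]:
                for b in bs:
                    for q in qs:
                        w = 1 / (len(ss) * len(farmers[s]) * len(bs) * len(qs))
                        L += w * encode(s, f, b, q)
        out.append({**fixed, "estimate": float(L @ res["beta"]),
                    "se": float(np.sqrt(L @ res["cov"] @ L))})
    return pd.DataFrame(out)


def nsd_letter_patterns(pvals: np.ndarray, est: np.ndarray, alpha: float):
    """All-maximal-clique compact letter display by subset enumeration.

    Independent check for small k: letters are the maximal cliques of the
    'not significantly different' graph, ordered by their best member.
    """
    k = len(est)
    nsd = pvals >= alpha
    cliques = []
    for r in range(k, 0, -1):
        for sub in itertools.combinations(range(k), r):
            if all(nsd[i, j] for i, j in itertools.combinations(sub, 2)):
                if not any(set(sub) <= set(c) for c in cliques):
                    cliques.append(set(sub))
    order = np.argsort(-est, kind="stable")
    rank = {int(l): r for r, l in enumerate(order)}
    cliques.sort(key=lambda s: min(rank[m] for m in s))
    letters = ["" for _ in range(k)]
    for gi, s in enumerate(cliques):
        for m in s:
            letters[m] += "abcdefghijklmnopqrstuvwxyz"[gi]
    return ["".join(sorted(l)) for l in letters]
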