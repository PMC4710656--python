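"""Fixed-effects trait model: design build, fit, ANOVA, LS-means, letters.

The deep checks run against two independent oracles: a brute-force
normal-equations implementation (tests/oracle_glm.py) on random small
instances, and values frozen from an external statistical system
(car-style Type II ANOVA and reference-grid marginal means) on a
deterministic synthetic fixture.
"""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

import oracle_glm
from conftest import random_survey_frame
from flockprefs import trait_glm as glm


def _fit(df, spec=None):
    spec = spec or glm.ModelSpec("body_weight")
    return glm.fit_ols(glm.build_design(df, spec))


# ---------------------------------------------------------------------------
# design construction

def test_balanced_toy_design_column_count():
    # 2 sites x 2 farmers/site x 2 breeds x 3 classes:
    # 1 + 1 + 2 + 1 + 2 + 1 = 8 free parameters
    rows = []
    for s, f, b, q in itertools.product(
            ("Amboseli", "Isinya"), ("f1", "f2"), ("Dorper", "Cross"),
            ("Best", "Average", "Poor")):
        rows.append({"ewe_id": f"{s}{f}{b}{q}", "farmer_id": s[:1] + f,
                     "site": s, "breed": b, "quality": q,
                     "body_weight": 40.0})
    design = glm.build_design(pd.DataFrame(rows), glm.ModelSpec("body_weight"))
    assert design.p == 8
    assert np.linalg.matrix_rank(design.X) == 8


def test_single_site_drops_site_terms():
    rng = np.random.default_rng(0)
    df = random_survey_frame(rng)
    df = df[df.site == "Amboseli"]
    with pytest.warns(UserWarning, match="dropped"):
        design = glm.build_design(df, glm.ModelSpec("body_weight"))
    assert "site" not in design.terms
    assert "breed:site" not in design.terms
    assert "site" in design.dropped_terms


def test_design_deterministic_for_fixed_seed(r_oracle_df):
    d1 = glm.build_design(r_oracle_df, glm.ModelSpec("body_weight"))
    d2 = glm.build_design(r_oracle_df, glm.ModelSpec("body_weight"))
    assert d1.columns == d2.columns
    assert np.array_equal(d1.X, d2.X)


# ---------------------------------------------------------------------------
# fitting

def test_intercept_only_recovers_sample_mean(survey_df):
    fit = _fit(survey_df, glm.ModelSpec("body_weight", terms=()))
    assert fit.params[0] == pytest.approx(survey_df["body_weight"].mean())


def test_one_factor_model_recovers_group_means(survey_df):
    fit = _fit(survey_df, glm.ModelSpec("body_weight", terms=("breed",)))
    design = fit.design
    means = survey_df.groupby("breed")["body_weight"].mean()
    ref = design.levels["breed"][0]
    assert fit.params[0] == pytest.approx(means[ref])
    for lbl, c in zip(design.columns[1:], fit.params[1:]):
        level = lbl.split("[")[1].rstrip("]")
        assert c == pytest.approx(means[level] - means[ref])


def test_rank_deficient_design_names_aliased_columns(survey_df):
    df = survey_df.copy()
    df["breed"] = np.where(df["site"] == "Amboseli", "Dorper", "Cross")
    with pytest.raises(np.linalg.LinAlgError, match="aliased"):
        _fit(df, glm.ModelSpec("body_weight",
                               terms=("site", "breed", "breed:site")))


def test_fitted_plus_residual_reconstructs_response(survey_df):
    fit = _fit(survey_df)
    assert np.allclose(fit.fitted + fit.resid, fit.design.y, atol=1e-10)


# ---------------------------------------------------------------------------
# oracle equivalence

@pytest.mark.parametrize("seed", range(8))
def test_matches_bruteforce_oracle_on_random_instances(seed):
    rng = np.random.default_rng(100 + seed)
    df = random_survey_frame(rng)
    fit = _fit(df)
    ora = oracle_glm.fit(df, "body_weight", fit.design.terms)
    assert np.allclose(fit.params, ora["beta"], rtol=1e-8, atol=1e-10)
    assert np.allclose(fit.cov, ora["cov"], rtol=1e-8, atol=1e-10)
    tab = glm.anova_table(fit).set_index("term")
    oraF = oracle_glm.type2_tests(df, "body_weight", fit.design.terms)
    for t, vals in oraF.items():
        assert tab.loc[t, "df"] == vals["df"]
        assert tab.loc[t, "F"] == pytest.approx(vals["F"], rel=1e-8)
    for factors in (("breed", "site"), ("quality",)):
        lsm = glm.ls_means(fit, factors)
        exp = oracle_glm.lsmeans(df, "body_weight", fit.design.terms, factors)
        got = lsm.table.merge(exp, on=list(factors), suffixes=("", "_o"))
        assert np.allclose(got["estimate"], got["estimate_o"], rtol=1e-8)
        assert np.allclose(got["se"], got["se_o"], rtol=1e-8)


def test_matches_frozen_external_oracle(r_oracle_df):
    """Frozen from an independent statistical system on the deterministic
    balanced-farm fixture (body weight, Type II tests, reference-grid
    marginal means averaged over farmers within site)."""
    fit = _fit(r_oracle_df)
    tab = glm.anova_table(fit).set_index("term")
    expected_F = {"site": 31.30839, "farmer(site)": 2.47864, "breed": 2.68767,
                  "quality": 21.83361, "breed:site": 4.45224}
    expected_df = {"site": 1, "farmer(site)": 16, "breed": 2, "quality": 2,
                   "breed:site": 2}
    for t, f in expected_F.items():
        assert tab.loc[t, "F"] == pytest.approx(f, abs=2e-5)
        assert tab.loc[t, "df"] == expected_df[t]
    assert tab.loc["Residual", "df"] == 114

    lsm = glm.ls_means(fit, ("breed", "site")).table.set_index(["breed", "site"])
    frozen = {  # (estimate, se)
        ("Cross", "Amboseli"): (35.44815, 1.1201938),
        ("Dorper", "Amboseli"): (38.11746, 1.4869090),
        ("Red Maasai", "Amboseli"): (36.93757, 1.2222316),
        ("Cross", "Isinya"): (44.12963, 1.1201938),
        ("Dorper", "Isinya"): (43.51093, 1.4869090),
        ("Red Maasai", "Isinya"): (38.62663, 1.2222316),
    }
    for key, (est, se) in frozen.items():
        assert lsm.loc[key, "estimate"] == pytest.approx(est, abs=1e-4)
        assert lsm.loc[key, "se"] == pytest.approx(se, abs=1e-5)
    lsq = glm.ls_means(fit, ("quality",)).table.set_index("quality")
    for q, (est, se) in {"Best": (43.61825, 0.8717311),
                         "Average": (39.15086, 0.8717311),
                         "Poor": (35.61608, 0.8717311)}.items():
        assert lsq.loc[q, "estimate"] == pytest.approx(est, abs=1e-4)
        assert lsq.loc[q, "se"] == pytest.approx(se, abs=1e-5)


# ---------------------------------------------------------------------------
# ANOVA behaviour

def test_type1_equals_type2_in_balanced_orthogonal_design():
    rng = np.random.default_rng(7)
    rows = []
    for s, b, q in itertools.product(("A", "B"), ("Dorper", "Cross"),
                                     ("Best", "Poor")):
        for k in range(3):
            rows.append({"farmer_id": "f" + s, "site": s, "breed": b,
                         "quality": q, "body_weight": float(rng.normal(40, 4))})
    df = pd.DataFrame(rows)
    spec = glm.ModelSpec("body_weight", terms=("site", "breed", "quality"))
    fit = _fit(df, spec)
    t1 = glm.anova_table(fit, "I").set_index("term")["sum_sq"]
    t2 = glm.anova_table(fit, "II").set_index("term")["sum_sq"]
    assert np.allclose(t1.drop("Residual"), t2.drop("Residual"), rtol=1e-10)


def test_significance_codes():
    assert glm.significance_code(0.0001) == "***"
    assert glm.significance_code(0.005) == "**"
    assert glm.significance_code(0.03) == "*"
    assert glm.significance_code(0.3) == "ns"


def test_response_shift_invariance(survey_df):
    """Adding a constant to y shifts LS-means by it and leaves F unchanged."""
    fit1 = _fit(survey_df)
    shifted = survey_df.copy()
    shifted["body_weight"] = shifted["body_weight"] + 100.0
    fit2 = _fit(shifted)
    a1 = glm.anova_table(fit1).set_index("term")["F"].drop("Residual")
    a2 = glm.anova_table(fit2).set_index("term")["F"].drop("Residual")
    assert np.allclose(a1, a2, rtol=1e-9)
    l1 = glm.ls_means(fit1, ("quality",)).table["estimate"]
    l2 = glm.ls_means(fit2, ("quality",)).table["estimate"]
    assert np.allclose(l2 - l1, 100.0, atol=1e-8)


# ---------------------------------------------------------------------------
# screening

def test_empty_candidate_list_returns_base_spec(survey_df):
    spec = glm.ModelSpec("body_weight")
    out, report = glm.screen_terms(survey_df, spec, candidates=())
    assert out == spec and report.empty


def test_null_age_effect_is_dropped_in_most_seeds():
    from flockprefs.simstudies import _study_design, _true_beta, _TRUE_SIGMA
    design, df = _study_design(3)
    beta = _true_beta(design)     # no age effect in the truth
    rng = np.random.default_rng(3)
    dropped = 0
    n_seeds = 20
    for _ in range(n_seeds):
        dd = df.copy()
        dd["body_weight"] = design.X @ beta + rng.normal(0, _TRUE_SIGMA, design.n)
        spec, _ = glm.screen_terms(dd, glm.ModelSpec("body_weight"),
                                   candidates=("age",))
        dropped += "age" not in spec.terms
    assert dropped >= 0.9 * n_seeds


def test_strong_quality_site_interaction_is_retained():
    from flockprefs.simstudies import _study_design, _true_beta, _TRUE_SIGMA
    design, df = _study_design(4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aug = glm.build_design(df, glm.ModelSpec("body_weight",
                                                 terms=glm.DEFAULT_TERMS
                                                 + ("quality:site",)))
    beta = np.zeros(aug.p)
    beta[0] = 36.0
    for c in aug.term_cols["quality:site"]:
        beta[c] = 8.0
    rng = np.random.default_rng(4)
    dd = df.copy()
    dd["body_weight"] = aug.X @ beta + rng.normal(0, _TRUE_SIGMA, aug.n)
    spec, report = glm.screen_terms(dd, glm.ModelSpec("body_weight"))
    assert "quality:site" in spec.terms
    assert report.set_index("candidate").loc["quality:site", "p"] < 0.05


def test_inestimable_candidate_reported_not_retained(survey_df):
    df = survey_df.copy()
    df["age"] = 4.0       # constant -> degenerate covariate
    spec, report = glm.screen_terms(df, glm.ModelSpec("body_weight"),
                                    candidates=("age",))
    assert "age" not in spec.terms
    row = report.iloc[0]
    assert not row["retained"] and "inestimable" in row["note"]


# ---------------------------------------------------------------------------
# letter display

def _lsm_from_groups(means, n=8, sd=1.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for gi, m in enumerate(means):
        for k in range(n):
            rows.append({"farmer_id": "f1", "site": "A",
                         "breed": f"G{gi}", "quality": "Best",
                         "body_weight": float(rng.normal(m, sd))})
    df = pd.DataFrame(rows)
    fit = _fit(df, glm.ModelSpec("body_weight", terms=("breed",)))
    return glm.ls_means(fit, ("breed",))


def test_letters_all_distinct_when_all_pairs_differ():
    lsm = _lsm_from_groups([0.0, 20.0, 40.0])
    assert sorted(glm.letter_groups(lsm)) == ["a", "b", "c"]


def test_letters_shared_when_nothing_differs():
    lsm = _lsm_from_groups([0.0, 0.0, 0.0], sd=5.0, seed=1)
    P = glm.pairwise_pvalues(lsm)
    assert (P[np.triu_indices(3, 1)] >= 0.05).all()   # construction sanity
    assert glm.letter_groups(lsm) == ["a", "a", "a"]


def test_letters_match_clique_enumeration_oracle():
    """Random 3-5 group instances: insert-and-absorb must reproduce the
    maximal-clique display, including the a/ab/b middle-overlap pattern."""
    from flockprefs.trait_glm import pairwise_pvalues
    seen_aab = False
    for seed in range(40):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(3, 6))
        means = np.sort(rng.uniform(0, 3, size=k)) * 2
        lsm = _lsm_from_groups(means, n=6, sd=1.5, seed=seed)
        got = glm.letter_groups(lsm)
        P = pairwise_pvalues(lsm)
        exp = oracle_glm.nsd_letter_patterns(P, lsm.table["estimate"].to_numpy(),
                                             alpha=0.05)
        assert got == exp, (seed, got, exp)
        if sorted(got) == ["a", "ab", "b"]:
            seen_aab = True
    assert seen_aab


def test_tukey_adjustment_is_more_conservative():
    lsm = _lsm_from_groups([0.0, 1.2, 2.4], n=6, sd=1.0, seed=3)
    from flockprefs.trait_glm import pairwise_pvalues
    p_plain = pairwise_pvalues(lsm)
    p_tukey = pairwise_pvalues(lsm, adjust="tukey")
    iu = np.triu_indices(3, 1)
    assert (p_tukey[iu] >= p_plain[iu] - 1e-12).all()


def test_balanced_design_lsmeans_equal_cell_means():
    rng = np.random.default_rng(5)
    rows = []
    for f, b, q in itertools.product(("f1", "f2"), ("Dorper", "Cross"),
                                     ("Best", "Average", "Poor")):
        rows.append({"farmer_id": f, "site": "A", "breed": b, "quality": q,
                     "body_weight": float(rng.normal(40, 4))})
    df = pd.DataFrame(rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = _fit(df, glm.ModelSpec("body_weight"))
    lsm = glm.ls_means(fit, ("breed",)).table.set_index("breed")
    raw = df.groupby("breed")["body_weight"].mean()
    assert np.allclose(lsm["estimate"], raw[lsm.index], atol=1e-8)


def test_unbalanced_lsmean_differs_from_raw_mean_but_matches_contrast(survey_df):
    df = pd.concat([survey_df, survey_df.iloc[[0]]], ignore_index=True)
    df.loc[len(df) - 1, "ewe_id"] = "dup"
    fit = _fit(df)
    lsm = glm.ls_means(fit, ("quality",)).table.set_index("quality")
    raw = df.groupby("quality")["body_weight"].mean()
    assert abs(lsm.loc["Best", "estimate"] - raw["Best"]) > 1e-6
    exp = oracle_glm.lsmeans(df, "body_weight", fit.design.terms,
                             ("quality",)).set_index("quality")
    assert lsm.loc["Best", "estimate"] == pytest.approx(
        exp.loc["Best", "estimate"], rel=1e-10)


def test_unobserved_margin_flagged_not_dropped(survey_df):
    # no Poor Dorpers observed: the model (no breed:quality term) still
    # yields a prediction, but the margin must be flagged, not dropped
    df = survey_df[~((survey_df.breed == "Dorper")
                     & (survey_df.quality == "Poor"))]
    fit = _fit(df)
    with pytest.warns(UserWarning, match="extrapolation"):
        lsm = glm.ls_means(fit, ("breed", "quality"))
    tab = lsm.table.set_index(["breed", "quality"])
    assert not tab.loc[("Dorper", "Poor"), "estimable"]
    assert tab.loc[("Dorper", "Best"), "estimable"]
    assert len(tab) == 9


def test_published_isinya_breed_gap_recovered_within_two_se():
    """Embedding the published Isinya Dorper-minus-Red-Maasai body-weight
    gap (6.8 kg) in the model equation, the LS-mean difference must land
    within 2 SE of the truth in at least ~95% of seeds."""
    from flockprefs.simstudies import _study_design, _TRUE_SIGMA
    design, df = _study_design(0)
    beta = np.zeros(design.p)
    beta[0] = 38.0
    cols = {design.columns[c]: c for c in range(design.p)}
    beta[cols["breed[Dorper]"]] = 2.0
    beta[cols["breed[Dorper]:site[Isinya]"]] = 4.8
    true_gap = 6.8
    rng = np.random.default_rng(99)
    hits, n_seeds = 0, 40
    for _ in range(n_seeds):
        dd = df.copy()
        dd["body_weight"] = design.simulate_response(beta, _TRUE_SIGMA, rng)
        fit = _fit(dd)
        lsm = glm.ls_means(fit, ("breed", "site"))
        keys = list(map(tuple, lsm.table[["breed", "site"]].to_numpy()))
        l = (lsm.L[keys.index(("Dorper", "Isinya"))]
             - lsm.L[keys.index(("Red Maasai", "Isinya"))])
        est = float(l @ fit.params)
        se = float(np.sqrt(l @ fit.cov @ l))
        hits += abs(est - true_gap) <= 2 * se
    assert hits >= 36, hits
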