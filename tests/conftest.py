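import warnings

import numpy as np
import pandas as pd
import pytest

from flockprefs.survey_data import ewes_to_frame
from flockprefs.synthetic import FlockDesign, generate_flocks


@pytest.fixture(scope="session")
def default_survey():
    """One deterministic default-design survey shared across tests."""
    return generate_flocks(FlockDesign.default(seed=11), seed=11)


@pytest.fixture(scope="session")
def survey_df(default_survey):
    ewes, _, _ = default_survey
    return ewes_to_frame(ewes)


def balanced_farm_design(seed: int = 42) -> FlockDesign:
    """9 farms per site (same availability mix) — keeps the farmer coding
    comparable with an external nested-factor parameterization."""
    base = FlockDesign.default(seed=seed)
    patterns = {
        s: [{"breeds": ["Red Maasai", "Dorper", "Cross"], "n_farms": 5},
            {"breeds": ["Red Maasai", "Cross"], "n_farms": 3},
            {"breeds": ["Dorper", "Cross"], "n_farms": 1}]
        for s in ("Amboseli", "Isinya")
    }
    return FlockDesign(
        sites={"Amboseli": 9, "Isinya": 9}, farm_patterns=patterns,
        ewes_per_group=base.ewes_per_group, farmer_sd_frac=base.farmer_sd_frac,
        traits=base.traits, rank_preference=base.rank_preference,
        age_probs=base.age_probs, coat_colours=base.coat_colours, seed=seed)


@pytest.fixture(scope="session")
def r_oracle_df():
    """The deterministic fixture behind the frozen external-software oracle."""
    ewes, _, _ = generate_flocks(balanced_farm_design(42), seed=42)
    return ewes_to_frame(ewes)


def random_survey_frame(rng: np.random.Generator, max_records: int = 60) -> pd.DataFrame:
    """Small random full-rank survey frame for oracle-equivalence checks."""
    while True:
        n_sites = 2
        sites = ["Amboseli", "Isinya"][:n_sites]
        breeds = ["Red Maasai", "Dorper", "Cross"][: int(rng.integers(2, 4))]
        quals = ["Best", "Average", "Poor"][: int(rng.integers(2, 4))]
        rows = []
        for s in sites:
            for fi in range(int(rng.integers(2, 4))):
                farmer = f"{s[:3]}{fi}"
                for b in breeds:
                    for q in quals:
                        if rng.random() < 0.85:
                            rows.append({
                                "ewe_id": f"{farmer}-{b}-{q}", "farmer_id": farmer,
                                "site": s, "breed": b, "quality": q,
                                "body_weight": float(rng.normal(40, 5)),
                                "age": float(rng.integers(1, 9)),
                            })
        df = pd.DataFrame(rows)
        if len(df) > max_records:
            continue
        # accept only full-rank instances with residual df
        from flockprefs import trait_glm as glm
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                design = glm.build_design(df, glm.ModelSpec("body_weight"))
            if (np.linalg.matrix_rank(design.X) == design.p
                    and design.n > design.p
                    and len(design.spec.terms) == 5):
                return df
        except Exception:
            continue
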