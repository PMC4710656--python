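#!/usr/bin/env python
"""Fixed-effects models for all six traits on the simulated survey.

For each trait: preliminary screening of age and the quality interactions,
then the model mu + Site + Farmer(Site) + Breed + Quality + Breed:Site with
Type II tests, LS-means by breed-within-site and by quality class with
compact letter displays, and a numeric residual-normality summary.  Writes
one significance table across traits plus per-trait LS-mean tables.
"""

from pathlib import Path

import pandas as pd

from flockprefs import trait_glm as glm
from flockprefs.survey_data import ewes_to_frame, load_ewe_records

ROOT = Path(__file__).resolve().parent.parent
EWES = ROOT / "results" / "synthetic" / "ewes.csv"
OUT = ROOT / "results"


def main() -> None:
    if not EWES.exists():
        raise SystemExit("run 02_simulate_survey.py first")
    ewes, _ = load_ewe_records(EWES)
    df = ewes_to_frame(ewes)

    signif = {}
    for resp in glm.TRAIT_RESPONSES:
        spec, screening = glm.screen_terms(df, glm.ModelSpec(resp))
        dropped = screening.loc[~screening["retained"], "candidate"].tolist()
        fit = glm.fit_ols(glm.build_design(df, spec))
        anova = glm.anova_table(fit)
        signif[resp] = anova.set_index("term")["signif"]
        lsm = glm.ls_means(fit, ("breed", "site")).with_letters()
        lsm.to_csv(OUT / f"lsmeans_breed_site_{resp}.csv", index=False)
        glm.ls_means(fit, ("quality",)).with_letters().to_csv(
            OUT / f"lsmeans_quality_{resp}.csv", index=False)
        diag = fit.residual_diagnostics()
        print(f"{resp:12s} screened out {dropped or 'nothing'}; residual "
              f"skew {diag['skewness']:+.2f}, Shapiro p {diag['shapiro_p']:.2f}")

    table = pd.DataFrame(signif).drop(index="Residual")
    table.to_csv(OUT / "significance_by_trait.csv")
    print("\nsignificance of model terms by trait:")
    print(table.to_string())
    print(f"\nwrote {OUT}/significance_by_trait.csv and per-trait LS-mean tables")


if __name__ == "__main__":
    main()
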