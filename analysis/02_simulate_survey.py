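#!/usr/bin/env python
"""Generate the default synthetic flock survey and check its structure.

Emits ewes.csv, reasons.csv and the generation ledger under
results/synthetic/, then summarizes the design arithmetic: 19 farms over two
sites, 147 ewes (51 Red Maasai, 39 Dorper, 57 Crosses), three ordered
reasons per ewe.
"""

from pathlib import Path

from flockprefs.survey_data import ewes_to_frame, write_records
from flockprefs.synthetic import FlockDesign, generate_flocks

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"
SEED = 11


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ewes, reasons, ledger = generate_flocks(FlockDesign.default(seed=SEED),
                                            seed=SEED)
    write_records(ewes, OUT / "ewes.csv")
    write_records(reasons, OUT / "reasons.csv", kind="reason")
    ledger.to_json(OUT / "ledger.json")

    df = ewes_to_frame(ewes)
    print(f"generated {len(ewes)} ewes / {len(reasons)} reasons (seed {SEED})")
    print("ewes per breed:", df.groupby("breed")["ewe_id"].count().to_dict())
    print("farms per site:",
          df.groupby("site")["farmer_id"].nunique().to_dict())
    print("body weight mean (kg) by breed x site:")
    print(df.groupby(["site", "breed"])["body_weight"].mean().round(1)
          .unstack().to_string())
    print(f"wrote {OUT}/ewes.csv, reasons.csv, ledger.json")


if __name__ == "__main__":
    main()
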