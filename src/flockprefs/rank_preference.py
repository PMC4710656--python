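"""Across-breed rank rescaling and per-site breed rank summaries.

After classing ewes within breed groups, each farmer ranks all their study
ewes across breed groups from 1 (most preferred) to n, where n is 9 on farms
with three breed groups and 6 on farms with two.  Ranks from 6-ewe farms are
rescaled onto the common 1-9 scale with the affine map

    new = 1 + (old - 1) * 1.6

which is the n = 6 case of the general endpoint-preserving map
``new = 1 + (old - 1) * 8 / (n - 1)`` (identity at n = 9).  Rescaled ranks
are kept as reals; site x breed summaries report their plain means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .survey_data import EweRecord, ewes_to_frame


@dataclass(frozen=True)
class RankRescaler:
    """Endpoint-preserving affine map from a 1..n_source scale onto [1, 9]."""

    n_source: int

    def __post_init__(self):
        if self.n_source < 2:
            raise ValueError("need at least 2 ranked ewes to define a scale")

    @property
    def slope(self) -> float:
        return 8.0 / (self.n_source - 1)

    def __call__(self, old: int) -> float:
        if not (1 <= old <= self.n_source):
            raise ValueError(f"rank {old} outside 1..{self.n_source}")
        return 1.0 + (old - 1) * self.slope


def rescale_rank(old: int, n_ewes_on_farm: int) -> float:
    """Rescale a raw within-farm rank onto the 1-9 scale.

    Identity for 9-ewe farms; ``1 + (old - 1) * 1.6`` for 6-ewe farms.
    """
    if old != int(old):
        raise ValueError(f"rank must be an integer, got {old!r}")
    return RankRescaler(n_ewes_on_farm)(int(old))


def summarize_breed_ranks(
    ewes: Sequence[EweRecord], per_farm: bool = False
) -> pd.DataFrame:
    """Mean rescaled across-breed rank per site x breed (1 = best, 9 = worst).

    The number of ranked ewes per farm sets each farm's source scale.  Ewes
    without a rank are excluded pairwise and counted in ``n_missing``.  With
    ``per_farm`` the breed means are first taken within farm, then averaged
    across farms, giving every farmer equal weight regardless of flock
    composition.  Sites with no ranked ewes are omitted with a warning.
    """
    df = ewes_to_frame(list(ewes))
    if df.empty:
        warnings.warn("no ewes provided; empty rank summary", stacklevel=2)
        return pd.DataFrame(columns=["site", "breed", "mean_rank", "n_ewes", "n_missing"])
    ranked = df[df["across_breed_rank"].notna()].copy()
    dropped_sites = sorted(set(df["site"]) - set(ranked["site"]))
    if dropped_sites:
        warnings.warn(f"site(s) with no ranked ewes omitted: {dropped_sites}",
                      stacklevel=2)
    if ranked.empty:
        return pd.DataFrame(columns=["site", "breed", "mean_rank", "n_ewes", "n_missing"])

    # the source scale is the farm's total number of study ewes, so a missing
    # rank does not silently shrink the scale of its farm-mates
    farm_size = df.groupby("farmer_id")["ewe_id"].count()
    ranked["rescaled"] = [
        rescale_rank(int(r), int(farm_size[f]))
        for r, f in zip(ranked["across_breed_rank"], ranked["farmer_id"])
    ]
    if per_farm:
        farm_means = (ranked.groupby(["site", "farmer_id", "breed"])["rescaled"]
                      .mean().reset_index())
        means = farm_means.groupby(["site", "breed"])["rescaled"].mean()
    else:
        means = ranked.groupby(["site", "breed"])["rescaled"].mean()
    n_ranked = ranked.groupby(["site", "breed"])["ewe_id"].count()
    n_all = df.groupby(["site", "breed"])["ewe_id"].count()
    out = (means.rename("mean_rank").reset_index())
    out["n_ewes"] = out.set_index(["site", "breed"]).index.map(n_ranked)
    out["n_missing"] = (
        out.set_index(["site", "breed"]).index.map(n_all).values - out["n_ewes"].values
    )
    return out
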