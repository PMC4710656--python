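"""Weighted-reasons preference indices per breed x site x quality class.

For each stratum, let ``X_ji`` be the number of respondents giving an order-j
reason (j = 1, 2, 3) for trait group i.  With order weights r_1 = 3, r_2 = 2,
r_3 = 1 the weighted-reasons index of trait i is

    WR_i = sum_j r_j X_ji / sum_i sum_j r_j X_ji

i.e. the trait's share of the total order-weighted reason mass in the
stratum.  The published preference tables print the weighted contributions
``c_ji = r_j * X_ji`` per order, their plain sum ``S_i`` and WR_i rounded
half-up to two decimals; this module reproduces all three, and additionally
clusters the seven trait groups into four broader categories (Body Size and
Growth, Condition, Reproduction and Milk, Adaptation) with Breed Attributes
excluded and the shares renormalized over the remaining groups.

All arithmetic on counts and contributions is integer-exact under the default
weights; WR values are exact ratios until display rounding.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .reason_mapping import TRAIT_GROUPS
from .survey_data import EweRecord, ReasonRecord, ewes_to_frame

STRATA = ("site", "quality", "breed")
ORDERS = (1, 2, 3)

CLUSTER_NAMES = ("Body Size and Growth", "Condition", "Reproduction and Milk",
                 "Adaptation")


@dataclass(frozen=True)
class WeightScheme:
    """Order -> weight map; default is the conventional 3/2/1."""

    weights: Mapping[int, float] = field(
        default_factory=lambda: {1: 3, 2: 2, 3: 1})

    def __post_init__(self):
        if not all(w > 0 for w in self.weights.values()):
            raise ValueError("order weights must be positive")

    def weight(self, order: int) -> float:
        try:
            return self.weights[order]
        except KeyError:
            raise KeyError(f"no weight defined for reason order {order}") from None


@dataclass(frozen=True)
class ClusterScheme:
    """Trait-group -> broader-category map with an excluded set.

    The default merges Milk Production with Reproduction and Mothering
    Ability ("Reproduction and Milk") and the two adaptive traits into
    "Adaptation", drops Breed Attributes (few, heterogeneous answers) and
    renormalizes shares over the non-excluded groups.
    """

    mapping: Mapping[str, str] = field(default_factory=lambda: {
        "Body Size and Growth": "Body Size and Growth",
        "Condition": "Condition",
        "Milk Production": "Reproduction and Milk",
        "Reproduction and Mothering Ability": "Reproduction and Milk",
        "Drought Tolerance": "Adaptation",
        "Disease Resistance": "Adaptation",
    })
    excluded: frozenset[str] = frozenset({"Breed Attributes"})
    renormalize: bool = True

    def __post_init__(self):
        uncovered = [g for g in TRAIT_GROUPS
                     if g not in self.mapping and g not in self.excluded]
        if uncovered:
            raise ValueError(f"trait group(s) neither clustered nor excluded: {uncovered}")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.125 -> 0.13), as used for display."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


def tally_counts(
    reasons: Sequence[ReasonRecord],
    ewes: Sequence[EweRecord],
    stratify_by: Sequence[str] = STRATA,
) -> pd.DataFrame:
    """Cross-tabulate mapped reasons into X_ji counts per stratum.

    Returns a tidy frame with the stratification columns, ``trait`` and
    ``x1, x2, x3``; every (stratum, trait) cell present in the data appears,
    missing cells are zero.  Unmapped reasons are an error here — run
    :func:`flockprefs.reason_mapping.map_reasons` first and act on its report.
    """
    unmapped = [r for r in reasons if r.trait_group is None]
    if unmapped:
        raise ValueError(
            f"{len(unmapped)} reason record(s) have no trait group; map them "
            "first (see reason_mapping.map_reasons and its unmapped report)")
    ewe_df = ewes_to_frame(ewes)[["ewe_id", *stratify_by]]
    rs = pd.DataFrame([(r.ewe_id, r.order, r.trait_group) for r in reasons],
                      columns=["ewe_id", "order", "trait"])
    merged = rs.merge(ewe_df, on="ewe_id", how="left", validate="many_to_one")
    if merged[list(stratify_by)].isna().any().any():
        bad = merged.loc[merged[list(stratify_by)].isna().any(axis=1), "ewe_id"].unique()
        raise ValueError(f"reason records reference unknown ewes: {list(bad)[:5]}")
    counts = (merged.groupby([*stratify_by, "trait", "order"]).size()
              .unstack("order", fill_value=0))
    for j in ORDERS:
        if j not in counts.columns:
            counts[j] = 0
    counts = counts[list(ORDERS)].astype(int)
    counts.columns = [f"x{j}" for j in ORDERS]
    # complete the trait index within each stratum so zero rows are explicit
    traits = [*TRAIT_GROUPS,
              *sorted(set(merged["trait"]) - set(TRAIT_GROUPS))]
    strata = counts.reset_index()[list(stratify_by)].drop_duplicates()
    full_index = pd.MultiIndex.from_frame(
        strata.merge(pd.DataFrame({"trait": traits}), how="cross"))
    full = (counts.reindex(full_index, fill_value=0).reset_index())
    return full


def weighted_contributions(
    counts: pd.DataFrame, scheme: WeightScheme = WeightScheme()
) -> pd.DataFrame:
    """Add weighted contribution columns c_j = r_j * x_j and their sum S.

    Integer-exact with integer weights; raises if an order present in the
    data has no weight.
    """
    out = counts.copy()
    total = 0
    for j in ORDERS:
        w = scheme.weight(j)
        out[f"c{j}"] = out[f"x{j}"] * w
        total += out[f"c{j}"]
    out["sum"] = total
    return out


def compute_wr(contrib: pd.DataFrame,
               stratify_by: Sequence[str] = STRATA) -> pd.DataFrame:
    """Normalize trait sums S_i into WR_i shares within each stratum.

    Strata whose grand total is zero get empty (NaN) WR values and are listed
    in the frame's ``attrs['degenerate_strata']``.
    """
    out = contrib.copy()
    grand = out.groupby(list(stratify_by))["sum"].transform("sum")
    out["wr"] = out["sum"] / grand.where(grand > 0)
    degenerate = (out.loc[grand == 0, list(stratify_by)]
                  .drop_duplicates().to_records(index=False).tolist())
    out.attrs["degenerate_strata"] = degenerate
    return out


def preference_table(
    counts: pd.DataFrame,
    scheme: WeightScheme = WeightScheme(),
    stratify_by: Sequence[str] = STRATA,
) -> pd.DataFrame:
    """Counts -> full preference table (contributions, sums, WR shares)."""
    return compute_wr(weighted_contributions(counts, scheme), stratify_by)


def cluster_wr(
    contrib: pd.DataFrame,
    scheme: ClusterScheme = ClusterScheme(),
    stratify_by: Sequence[str] = STRATA,
) -> pd.DataFrame:
    """Accumulate trait sums into the four-category clustering.

    With ``renormalize`` (the default) the shares are computed over the
    non-excluded groups only, so they sum to one after exclusion — this is
    the convention that reproduces the published clustered table.
    """
    df = contrib[~contrib["trait"].isin(scheme.excluded)].copy()
    df["cluster"] = df["trait"].map(dict(scheme.mapping))
    agg = (df.groupby([*stratify_by, "cluster"])["sum"].sum().reset_index())
    if scheme.renormalize:
        denom = agg.groupby(list(stratify_by))["sum"].transform("sum")
    else:
        keep = contrib.copy()
        denom_map = keep.groupby(list(stratify_by))["sum"].sum()
        agg = agg.join(denom_map.rename("denom"), on=list(stratify_by))
        denom = agg.pop("denom")
    agg["wr"] = agg["sum"] / denom.where(denom > 0)
    return agg


# ---------------------------------------------------------------------------
# Printed-table fixture ingestion

def load_printed_contributions(path: str | Path | None = None) -> pd.DataFrame:
    """Load published weighted-contribution columns (c1, c2, c3) per stratum.

    The bundled file carries the printed per-order weighted contributions of
    the Best/Poor preference tables for all three breed groups at both sites.
    Returns a frame in the same layout as :func:`weighted_contributions`
    output (with ``sum`` recomputed, not copied).
    """
    if path is None:
        ref = resources.files("flockprefs.data").joinpath("printed_contributions.csv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    df["sum"] = df["c1"] + df["c2"] + df["c3"]
    return df


def contributions_to_counts(
    contrib: pd.DataFrame, scheme: WeightScheme = WeightScheme()
) -> pd.DataFrame:
    """Invert printed contributions c_j back to raw counts X_j = c_j / r_j.

    Requires exact divisibility — printed contributions are r_j times an
    integer respondent count by construction.
    """
    out = contrib.copy()
    for j in ORDERS:
        w = scheme.weight(j)
        x = out[f"c{j}"] / w
        if not (x.round(9) % 1 == 0).all():
            bad = out.loc[x % 1 != 0]
            raise ValueError(
                f"contribution column c{j} not divisible by weight {w}:\n{bad}")
        out[f"x{j}"] = x.astype(int)
    return out


def render_preference_report(table: pd.DataFrame, ndigits: int = 2) -> pd.DataFrame:
    """Display form of a preference (or clustered) table.

    Shares are formatted with half-up rounding to ``ndigits`` decimals, as
    strings so that trailing zeros are kept ("0.30", not "0.3").
    """
    out = table.copy()
    fmt = f"{{:.{ndigits}f}}"
    out["wr"] = [
        "" if pd.isna(v) else fmt.format(round_half_up(v, ndigits))
        for v in out["wr"]
    ]
    return out
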