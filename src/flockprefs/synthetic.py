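"""Synthetic flock-survey generator.

No raw per-ewe data accompany the study design this package analyses, so the
generator emits datasets with the same *statistical structure* the pipeline
assumes: 19 farms over two sites with the published breed-group availability
pattern (147 ewes by default), trait values drawn from normal distributions
per breed x site x quality cell (published cell means/SDs, site shifts from
the published marginal means) with a shared farmer effect, ordered reasons
drawn from the published weighted-reasons profiles, and across-breed ranks
driven by a latent site x breed preference.

Every latent draw (farmer effects, true cell means, reason category draws,
latent rank scores) is recorded in a :class:`GenerationLedger`, so recovery
tests can compare pipeline output against the generator's own bookkeeping
rather than against re-derived quantities.

Ordered reasons are drawn independently per order from the stratum's
category profile: a farmer may cite the same trait category at two orders
(through different phrases), which is what makes single-category weighted
shares above one half attainable, as the published tables show.  The emitted
phrases within one ewe stay distinct.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .preference_index import load_printed_contributions
from .reason_mapping import TRAIT_GROUPS, Lexicon
from .survey_data import EweRecord, ReasonRecord

TRAITS = ("body_weight", "body_length", "heart_girth", "bcs", "milk_yield", "price")
_QUALITIES = ("Best", "Average", "Poor")


@dataclass(frozen=True)
class FlockDesign:
    """Configuration of the synthetic survey; defaults mirror the study design."""

    sites: Mapping[str, int]
    farm_patterns: Mapping[str, Sequence[Mapping]]
    ewes_per_group: int
    farmer_sd_frac: float
    traits: Mapping[str, Mapping]
    rank_preference: Mapping
    age_probs: Sequence[float]
    coat_colours: Sequence[str]
    reason_profiles: Mapping[tuple[str, str, str], np.ndarray] = field(default=None)
    seed: int = 0

    def __post_init__(self):
        if not self.sites or any(n <= 0 for n in self.sites.values()):
            raise ValueError("every site needs a positive farmer count")
        if self.ewes_per_group <= 0:
            raise ValueError("ewes_per_group must be positive")
        if not 0 <= self.farmer_sd_frac < 1:
            raise ValueError("farmer_sd_frac must be in [0, 1)")
        if abs(sum(self.age_probs) - 1) > 1e-9:
            raise ValueError("age_probs must sum to 1")
        for s, pats in self.farm_patterns.items():
            if sum(p["n_farms"] for p in pats) != self.sites[s]:
                raise ValueError(f"farm patterns for {s} do not sum to {self.sites[s]}")
        if self.reason_profiles is None:
            object.__setattr__(self, "reason_profiles", default_reason_profiles())
        for key, p in self.reason_profiles.items():
            if np.any(np.asarray(p) < 0) or not np.isclose(np.sum(p), 1.0):
                raise ValueError(f"reason profile {key} does not normalize")

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int = 0) -> "FlockDesign":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(sites=raw["sites"], farm_patterns=raw["farm_patterns"],
                   ewes_per_group=raw["ewes_per_group"],
                   farmer_sd_frac=raw["farmer_sd_frac"], traits=raw["traits"],
                   rank_preference=raw["rank_preference"],
                   age_probs=raw["age_probs"], coat_colours=raw["coat_colours"],
                   seed=seed)

    @classmethod
    def default(cls, seed: int = 0) -> "FlockDesign":
        ref = resources.files("flockprefs.data").joinpath("design_defaults.yaml")
        with resources.as_file(ref) as p:
            return cls.from_yaml(p, seed=seed)

    def n_ewes(self) -> int:
        return sum(len(pat["breeds"]) * pat["n_farms"] * self.ewes_per_group
                   for pats in self.farm_patterns.values() for pat in pats)

    def cell_mean_sd(self, trait: str, breed: str, site: str, quality: str
                     ) -> tuple[float, float]:
        spec = self.traits[trait]
        mean, sd = spec["cells"][breed][quality]
        offset = spec["site_offset"][breed]
        sites = list(self.sites)
        shift = +offset / 2 if site == sites[1] else -offset / 2
        return mean + shift, sd


def default_reason_profiles() -> dict[tuple[str, str, str], np.ndarray]:
    """Category profiles per (site, breed, quality) from the published tables.

    Best and Poor profiles are the published weighted-contribution shares;
    the Average class (not analysed in the source tables) gets the mean of
    its stratum's Best and Poor profiles.
    """
    printed = load_printed_contributions()
    profiles: dict[tuple[str, str, str], np.ndarray] = {}
    for (site, qual, breed), g in printed.groupby(["site", "quality", "breed"]):
        s = g.set_index("trait")["sum"].reindex(TRAIT_GROUPS).fillna(0).to_numpy(float)
        profiles[(site, breed, qual)] = s / s.sum()
    for site, breed in {(s, b) for s, b, _ in profiles}:
        p = (profiles[(site, breed, "Best")] + profiles[(site, breed, "Poor")]) / 2
        profiles[(site, breed, "Average")] = p / p.sum()
    return profiles


@dataclass
class GenerationLedger:
    """Complete record of latent values behind one generated dataset."""

    seed: int
    n_ewes: int
    farmer_effects: dict[str, dict[str, float]]        # farm -> trait -> effect
    cell_means: dict[str, float]                        # "trait|breed|site|quality"
    reason_draws: dict[str, list[str]]                  # ewe -> ordered categories
    latent_rank: dict[str, float]                       # ewe -> latent preference
    latent_quality: dict[str, float]                    # ewe -> latent quality score

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=1, sort_keys=True)

    def reason_counts(self, ewe_ids: Sequence[str]) -> dict[str, dict[int, int]]:
        """Category -> {order: count} over the given ewes, from the ledger."""
        out: dict[str, dict[int, int]] = {g: {1: 0, 2: 0, 3: 0} for g in TRAIT_GROUPS}
        for eid in ewe_ids:
            for j, g in enumerate(self.reason_draws.get(eid, []), start=1):
                out[g][j] += 1
        return out


def _snap_bcs(x: float) -> float:
    return float(min(5.0, max(1.0, round(x * 2) / 2)))


def generate_reasons(
    ewe: EweRecord,
    design: FlockDesign,
    rng: np.random.Generator,
    lexicon: Lexicon | None = None,
) -> tuple[list[ReasonRecord], list[str]]:
    """Draw up to three ordered reasons for one ewe from its stratum profile.

    Categories are drawn independently per order (repeats allowed, phrases
    distinct); returns the records and the drawn category sequence.  A
    degenerate all-zero profile yields no reasons.
    """
    lexicon = lexicon or Lexicon.default()
    key = (ewe.site, ewe.breed, ewe.quality)
    profile = np.asarray(design.reason_profiles[key], dtype=float)
    if profile.sum() <= 0:
        import warnings
        warnings.warn(f"degenerate reason profile for {key}; no reasons emitted",
                      stacklevel=2)
        return [], []
    cats = [TRAIT_GROUPS[i]
            for i in rng.choice(len(TRAIT_GROUPS), size=3, p=profile)]
    used: set[str] = set()
    records = []
    for j, cat in enumerate(cats, start=1):
        pool = [p for p in lexicon.phrases_for(cat) if p not in used] \
            or lexicon.phrases_for(cat)
        phrase = pool[int(rng.integers(len(pool)))]
        used.add(phrase)
        records.append(ReasonRecord(ewe_id=ewe.ewe_id, order=j, phrase=phrase))
    return records, cats


def generate_flocks(
    design: FlockDesign | None = None,
    seed: int | None = None,
    lexicon: Lexicon | None = None,
) -> tuple[list[EweRecord], list[ReasonRecord], GenerationLedger]:
    """Generate a full synthetic survey: ewe records, reasons and the ledger."""
    design = design or FlockDesign.default()
    seed = design.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    lexicon = lexicon or Lexicon.default()
    sites = list(design.sites)

    ledger = GenerationLedger(seed=int(seed), n_ewes=0, farmer_effects={},
                              cell_means={}, reason_draws={}, latent_rank={},
                              latent_quality={})
    for trait in TRAITS:
        for breed in design.traits[trait]["cells"]:
            for site in sites:
                for q in _QUALITIES:
                    m, _ = design.cell_mean_sd(trait, breed, site, q)
                    ledger.cell_means[f"{trait}|{breed}|{site}|{q}"] = float(m)

    ewes: list[EweRecord] = []
    reasons: list[ReasonRecord] = []
    qshift = design.rank_preference["quality_shift"]
    latent_pref = design.rank_preference["latent"]
    noise_sd = design.rank_preference["noise_sd"]

    for site in sites:
        farm_no = 0
        for pattern in design.farm_patterns[site]:
            for _ in range(pattern["n_farms"]):
                farm_no += 1
                farmer_id = f"{site[:3].upper()}{farm_no:02d}"
                # shared flock effect per trait, scaled to the trait's spread
                effects = {}
                for trait in TRAITS:
                    sds = [sd for b in design.traits[trait]["cells"].values()
                           for (_, sd) in b.values()]
                    farmer_sd = design.farmer_sd_frac * float(np.median(sds))
                    effects[trait] = float(rng.normal(0.0, farmer_sd))
                ledger.farmer_effects[farmer_id] = effects

                farm_ewes: list[EweRecord] = []
                for breed in pattern["breeds"]:
                    for k, q in enumerate(_QUALITIES[:design.ewes_per_group]):
                        ewe_id = f"{farmer_id}-{breed.replace(' ', '')[:4]}-{q[0]}{k}"
                        values = {}
                        for trait in TRAITS:
                            m, sd = design.cell_mean_sd(trait, breed, site, q)
                            fsd = design.farmer_sd_frac * sd
                            rsd = float(np.sqrt(max(sd * sd - fsd * fsd, 1e-12)))
                            values[trait] = m + effects[trait] + rng.normal(0.0, rsd)
                        age = int(rng.choice(np.arange(1, 10),
                                             p=np.asarray(design.age_probs)))
                        # latent quality score: decreasing Best > Average > Poor
                        lq = float({"Best": 1.0, "Average": 0.0, "Poor": -1.0}[q]
                                   + rng.normal(0, 0.1))
                        ledger.latent_quality[ewe_id] = lq
                        ewe = EweRecord(
                            ewe_id=ewe_id, farmer_id=farmer_id, site=site,
                            breed=breed, quality=q,
                            body_weight=round(max(values["body_weight"], 5.0), 1),
                            body_length=round(max(values["body_length"], 20.0), 1),
                            heart_girth=round(max(values["heart_girth"], 30.0), 1),
                            bcs=_snap_bcs(values["bcs"]),
                            milk_yield=round(max(values["milk_yield"], 0.0), 2),
                            price=int(max(round(values["price"]), 300)),
                            age=float(age),
                            coat_colour=str(rng.choice(list(design.coat_colours))),
                        )
                        farm_ewes.append(ewe)
                # across-breed rank on the farm's raw 1..n scale
                latents = []
                for e in farm_ewes:
                    lat = (latent_pref[site][e.breed] + qshift[e.quality]
                           + rng.normal(0.0, noise_sd))
                    ledger.latent_rank[e.ewe_id] = float(lat)
                    latents.append(lat)
                order = np.argsort(np.argsort(latents))  # 0 = lowest latent = best
                farm_ewes = [
                    replace(e, across_breed_rank=int(r) + 1)
                    for e, r in zip(farm_ewes, order)
                ]
                for e in farm_ewes:
                    recs, cats = generate_reasons(e, design, rng, lexicon)
                    reasons.extend(recs)
                    ledger.reason_draws[e.ewe_id] = cats
                ewes.extend(farm_ewes)

    ledger.n_ewes = len(ewes)
    return ewes, reasons, ledger
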