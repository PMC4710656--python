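"""Map transcribed free-text reasons to the seven trait groups.

Farmers answer open questions in their own terminology; an enumerator
transcribes the answers into English, and the analysis groups them into seven
trait categories: Body Size and Growth, Condition, Milk Production,
Reproduction and Mothering Ability, Drought Tolerance, Disease Resistance and
Breed Attributes.  Because the grouping of transcribed phrases is itself an
interpretive step, the lexicon is *data* (a YAML file of pattern -> group
entries), not code, and users can swap in their own.

Matching is deliberately dumb: normalized substring containment with
longest-pattern-first resolution.  No stemming, no embeddings — a phrase the
lexicon does not cover is reported as unmapped, never guessed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .survey_data import ReasonRecord

TRAIT_GROUPS = (
    "Body Size and Growth",
    "Condition",
    "Milk Production",
    "Reproduction and Mothering Ability",
    "Drought Tolerance",
    "Disease Resistance",
    "Breed Attributes",
)

_WS = re.compile(r"\s+")


def normalize_phrase(phrase: str) -> str:
    """Casefold, collapse internal whitespace, strip. Idempotent."""
    return _WS.sub(" ", str(phrase)).strip().casefold()


@dataclass(frozen=True)
class Lexicon:
    """Ordered pattern -> trait-group table.

    ``entries`` preserves file order: among equally long matching patterns the
    first one in the file wins (and the tie is logged by :func:`map_reasons`).
    """

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self):
        seen: dict[str, str] = {}
        for pat, group in self.entries:
            if group not in TRAIT_GROUPS:
                raise ValueError(f"unknown trait group {group!r} for pattern {pat!r}")
            prev = seen.get(pat)
            if prev is not None and prev != group:
                raise ValueError(f"pattern {pat!r} maps to both {prev!r} and {group!r}")
            seen[pat] = group
        groups = {g for _, g in self.entries}
        missing = set(TRAIT_GROUPS) - groups
        if missing:
            raise ValueError(f"lexicon leaves trait group(s) unreachable: {sorted(missing)}")

    @classmethod
    def from_entries(cls, entries: Iterable[tuple[str, str]]) -> "Lexicon":
        return cls(tuple((normalize_phrase(p), g) for p, g in entries))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Lexicon":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls.from_entries((e["pattern"], e["trait_group"]) for e in raw["entries"])

    @classmethod
    def default(cls) -> "Lexicon":
        """The study lexicon shipped with the package (data/lexicon.yaml)."""
        ref = resources.files("flockprefs.data").joinpath("lexicon.yaml")
        with resources.as_file(ref) as p:
            return cls.from_yaml(p)

    def phrases_for(self, group: str) -> list[str]:
        return [p for p, g in self.entries if g == group]

    def match(self, phrase: str) -> tuple[str | None, bool]:
        """Return (trait_group or None, had_length_tie).

        Longest normalized pattern contained in the normalized phrase wins;
        a length tie between patterns of *different* groups falls back to
        file order and is flagged.
        """
        norm = normalize_phrase(phrase)
        best: tuple[str, str] | None = None
        tie = False
        for pat, group in self.entries:
            if pat and pat in norm:
                if best is None or len(pat) > len(best[0]):
                    best, tie = (pat, group), False
                elif len(pat) == len(best[0]) and group != best[1]:
                    tie = True  # first-in-file already held; keep it
        return (best[1] if best else None), tie


@dataclass
class MappingReport:
    n_total: int
    n_mapped: int
    unmapped: list[tuple[str, str]]  # (ewe_id, phrase)
    ties: list[str]

    @property
    def n_unmapped(self) -> int:
        return len(self.unmapped)


def map_reasons(
    reasons: Sequence[ReasonRecord], lexicon: Lexicon
) -> tuple[list[ReasonRecord], MappingReport]:
    """Assign a trait group to every reason the lexicon covers.

    Unmapped phrases are a report entry, not an error: the caller decides
    whether to extend the lexicon or drop the records.
    """
    out: list[ReasonRecord] = []
    report = MappingReport(n_total=len(reasons), n_mapped=0, unmapped=[], ties=[])
    for rec in reasons:
        group, tie = lexicon.match(rec.phrase)
        if tie:
            report.ties.append(f"length tie for {rec.phrase!r}; kept first-in-file match")
        if group is None:
            report.unmapped.append((rec.ewe_id, rec.phrase))
            out.append(rec)
        else:
            out.append(replace(rec, trait_group=group))
            report.n_mapped += 1
    return out, report
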