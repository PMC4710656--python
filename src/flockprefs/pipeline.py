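"""End-to-end pipeline: data in (or simulated), preference/rank/GLM tables out.

A run is configured by :class:`RunConfig` (constructable from YAML), writes
all outputs under one directory, and finishes with a JSON manifest listing
every emitted file with its SHA-256 checksum, so two runs with the same
inputs and seed can be compared byte for byte.  Log lines carry no
timestamps for exactly that reason.

Stage failures raise :class:`ValidationError` (bad inputs/config) or
:class:`EstimationError` (model could not be fit); partial outputs written
before the failure stay on disk and the manifest records the failure point.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import preference_index as pi
from . import rank_preference as rp
from . import trait_glm as glm
from .reason_mapping import Lexicon, map_reasons
from .survey_data import load_ewe_records, load_reason_records, write_records
from .synthetic import FlockDesign, generate_flocks

log = logging.getLogger("flockprefs")


class ValidationError(RuntimeError):
    """Bad inputs or configuration (CLI exit code 2)."""


class EstimationError(RuntimeError):
    """A model could not be estimated (CLI exit code 3)."""


@dataclass
class RunConfig:
    out_dir: str
    ewes_csv: str | None = None          # both None -> simulate
    reasons_csv: str | None = None
    lexicon_path: str | None = None
    design_path: str | None = None
    seed: int = 0
    weights: tuple[float, float, float] = (3, 2, 1)
    alpha: float = 0.05
    ss_type: str = "II"
    responses: Sequence[str] = glm.TRAIT_RESPONSES
    screen: bool = True
    log_level: str = "INFO"

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            cfg = cls(**raw)
        except TypeError as exc:
            raise ValidationError(f"bad config {path}: {exc}") from None
        if cfg.weights is not None:
            cfg.weights = tuple(cfg.weights)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: list[Path]) -> None:
    df.to_csv(path, index=False)
    manifest.append(path)


def reproduce_printed_tables(out_dir: str | Path,
                             weights: Sequence[float] = (3, 2, 1)) -> dict[str, Path]:
    """Recompute the published preference tables from their printed columns.

    Loads the bundled printed weighted-contribution columns, recomputes the
    WR shares and the four-category clustered shares, and writes both in the
    published layouts (values half-up rounded to 2 decimals).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scheme = pi.WeightScheme({1: weights[0], 2: weights[1], 3: weights[2]})
    printed = pi.load_printed_contributions()
    counts = pi.contributions_to_counts(printed, scheme)
    table = pi.preference_table(counts[["site", "quality", "breed", "trait",
                                        "x1", "x2", "x3"]], scheme)
    clustered = pi.cluster_wr(table)
    paths = {}
    p1 = out / "preference_tables.csv"
    pi.render_preference_report(table).to_csv(p1, index=False)
    paths["preferences"] = p1
    p2 = out / "clustered_categories.csv"
    pi.render_preference_report(clustered).to_csv(p2, index=False)
    paths["clustered"] = p2
    return paths


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; return the manifest dict (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level,
                        format="%(levelname)s %(name)s: %(message)s")
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(fh)
    produced: list[Path] = []
    manifest: dict = {"config": {**asdict(config),
                                 "responses": list(config.responses),
                                 "weights": list(config.weights)},
                      "status": "ok", "failed_stage": None, "files": {}}
    try:
        try:
            lexicon = (Lexicon.from_yaml(config.lexicon_path)
                       if config.lexicon_path else Lexicon.default())
        except FileNotFoundError:
            raise ValidationError(f"lexicon file not found: {config.lexicon_path}")

        # -- stage 0: published-table reproduction (self-contained)
        for p in reproduce_printed_tables(out, config.weights).values():
            produced.append(p)
        log.info("printed preference tables reproduced")

        # -- stage 1: data
        if config.ewes_csv is None:
            design = (FlockDesign.from_yaml(config.design_path, seed=config.seed)
                      if config.design_path else FlockDesign.default(seed=config.seed))
            ewes, reasons, ledger = generate_flocks(design, config.seed, lexicon)
            write_records(ewes, out / "ewes.csv")
            write_records(reasons, out / "reasons.csv", kind="reason")
            ledger.to_json(out / "ledger.json")
            produced += [out / "ewes.csv", out / "reasons.csv", out / "ledger.json"]
            log.info("simulated %d ewes / %d reasons (seed %d)",
                     len(ewes), len(reasons), config.seed)
        else:
            ewes, ereport = load_ewe_records(config.ewes_csv)
            if not ewes:
                raise ValidationError(f"no valid ewe records in {config.ewes_csv}")
            if config.reasons_csv is None:
                raise ValidationError("ewes_csv given without reasons_csv")
            reasons, rreport = load_reason_records(config.reasons_csv, ewes)
            log.info("loaded %d ewes (%d quarantined), %d reasons (%d quarantined)",
                     len(ewes), ereport.n_quarantined, len(reasons),
                     rreport.n_quarantined)
            quarantine = pd.DataFrame(
                [("ewe", i, r) for i, r in ereport.quarantined]
                + [("reason", i, r) for i, r in rreport.quarantined],
                columns=["table", "row", "reason"])
            _write(quarantine, out / "quarantine.csv", produced)

        # -- stage 2: reason mapping
        mapped, mreport = map_reasons(reasons, lexicon)
        if mreport.n_unmapped:
            log.warning("%d reason(s) unmapped; excluded from preference tables",
                        mreport.n_unmapped)
            _write(pd.DataFrame(mreport.unmapped, columns=["ewe_id", "phrase"]),
                   out / "unmapped_reasons.csv", produced)
        mapped = [r for r in mapped if r.trait_group is not None]

        # -- stage 3: preference indices on the survey data
        scheme = pi.WeightScheme({1: config.weights[0], 2: config.weights[1],
                                  3: config.weights[2]})
        counts = pi.tally_counts(mapped, ewes)
        table = pi.preference_table(counts, scheme)
        _write(pi.render_preference_report(table), out / "survey_preferences.csv",
               produced)
        _write(pi.render_preference_report(pi.cluster_wr(table)),
               out / "survey_clustered.csv", produced)

        # -- stage 4: across-breed ranks
        ranks = rp.summarize_breed_ranks(ewes)
        _write(ranks, out / "ranks.csv", produced)

        # -- stage 5: trait models
        from .survey_data import ewes_to_frame
        df = ewes_to_frame(ewes)
        for resp in config.responses:
            try:
                spec = glm.ModelSpec(response=resp)
                if config.screen:
                    spec, screening = glm.screen_terms(df, spec, alpha=config.alpha,
                                                       ss_type=config.ss_type)
                    _write(screening, out / f"screening_{resp}.csv", produced)
                fit = glm.fit_ols(glm.build_design(df, spec))
                _write(glm.anova_table(fit, config.ss_type),
                       out / f"anova_{resp}.csv", produced)
                lsm = glm.ls_means(fit, ("breed", "site"))
                _write(lsm.with_letters(config.alpha),
                       out / f"lsmeans_breed_site_{resp}.csv", produced)
                lsq = glm.ls_means(fit, ("quality",))
                _write(lsq.with_letters(config.alpha),
                       out / f"lsmeans_quality_{resp}.csv", produced)
                diag = fit.residual_diagnostics()
                log.info("%s: residual skew %.2f, excess kurtosis %.2f",
                         resp, diag["skewness"], diag["excess_kurtosis"])
            except Exception as exc:
                raise EstimationError(f"model for {resp} failed: {exc}") from exc
    except (ValidationError, EstimationError) as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = str(exc)
        _finalize_manifest(manifest, produced, out)
        log.removeHandler(fh)
        fh.close()
        raise
    _finalize_manifest(manifest, produced, out)
    log.removeHandler(fh)
    fh.close()
    return manifest


def _finalize_manifest(manifest: dict, produced: list[Path], out: Path) -> None:
    for p in produced:
        if p.exists():
            manifest["files"][p.name] = {"sha256": _sha256(p),
                                         "bytes": p.stat().st_size}
    with open(out / "manifest.json", "w", encoding="utf-8") as fhm:
        json.dump(manifest, fhm, indent=1, sort_keys=True)
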