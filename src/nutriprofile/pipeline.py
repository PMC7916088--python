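"""End-to-end orchestration: clean -> relevance -> refine -> thresholds -> score -> validate.

Every stage is deterministic given (input, config); the run report
records the seed, a hash of the effective configuration, and row counts
so a rerun can be checked byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal

import pandas as pd
import yaml

from . import ingest
from .core import ClaimLimits
from .refine import DEFAULT_N_BINS, detect_modes, split_category
from .relevance import analyzable_subset, relevance_report
from .scoring import score_category, threshold_family
from .thresholds import MIN_PRODUCTS, TooFewProductsError, derive_thresholds
from .validation import agreement_summary

log = logging.getLogger("nutriprofile")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_config"]

SCHEMA_VERSION = "1"


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on besides the input table."""

    input: str | None = None
    out_dir: str | None = None
    targets: tuple[float, ...] = (50.0, 15.0)
    seed: int = 0
    m_nacl: float = ingest.NACL_MOLAR_MASS
    paper_exact: bool = False  # use the as-printed NaCl molar mass
    n_bins: int = DEFAULT_N_BINS
    anchor_zero: bool = False
    min_products: int = MIN_PRODUCTS
    excluded_categories: tuple[str, ...] = ()
    clamp: bool = True
    qualifying_clamp: Literal["raise", "lower"] = "raise"
    limits_file: str | None = None
    rating_column: str = "rating"

    @property
    def effective_m_nacl(self) -> float:
        return ingest.NACL_MOLAR_MASS_AS_PRINTED if self.paper_exact else self.m_nacl

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("targets", "excluded_categories"):
        if key in doc and doc[key] is not None:
            doc[key] = tuple(doc[key])
    return PipelineConfig(**doc)


@dataclass
class PipelineResult:
    cleaned: pd.DataFrame
    cleaning_report: dict
    relevance: dict
    partition: dict
    thresholds: dict
    scores: pd.DataFrame
    validation: dict
    run_info: dict
    skipped: list[dict] = field(default_factory=list)


def _json_dump(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def run_pipeline(
    products: pd.DataFrame, config: PipelineConfig, limits: ClaimLimits | None = None
) -> PipelineResult:
    """Run every stage on an already-parsed product table."""
    if limits is None:
        limits = (
            ClaimLimits.from_yaml(config.limits_file)
            if config.limits_file
            else ClaimLimits.default()
        )

    df = products
    if config.excluded_categories:
        df = df[~df["category"].isin(config.excluded_categories)]

    report = ingest.CleaningReport()
    df = ingest.apply_salt_conversion(df, config.effective_m_nacl, report)
    df, report = ingest.clean(df, report)
    df = ingest.reconstitute_powders(df, report=report)

    relevance_out: dict = {}
    partition_out: dict = {}
    thresholds_out: dict = {}
    score_frames: list[pd.DataFrame] = []
    validation_out: dict = {}
    skipped: list[dict] = []

    if len(df):
        initial = ingest.partition_by_basis(df)
    else:
        initial = {}
        log.warning("no products after cleaning")

    for (label, basis), group in initial.items():
        cat_key = ingest.initial_category_label(label, basis)
        rep = relevance_report(group, limits, basis)
        relevant = sorted((n for n, r in rep.items() if r["relevant"]), key=lambda n: n.value)
        relevance_out[cat_key] = {
            "n_products": len(group),
            "relevant": [n.value for n in relevant],
            "nutrients": {n.value: r for n, r in rep.items()},
        }
        if not relevant:
            skipped.append({"category": cat_key, "reason": "no category-relevant nutrient"})
            continue
        subset = analyzable_subset(group, set(relevant))
        relevance_out[cat_key]["n_analyzable"] = len(subset)
        if len(subset) == 0:
            skipped.append({"category": cat_key, "reason": "empty analyzable subset"})
            continue

        detections = {
            nut: detect_modes(
                subset[nut.value],
                n_bins=config.n_bins,
                nutrient=nut,
                anchor_zero=config.anchor_zero,
            )
            for nut in relevant
        }
        part = split_category(subset, detections, category=cat_key)
        partition_out[cat_key] = part.to_dict()

        for sub_label in sorted(part.cell_counts):
            sub = subset[part.labels == sub_label]
            try:
                per_target = {
                    f"{x:g}": derive_thresholds(
                        sub,
                        relevant,
                        x,
                        limits=limits,
                        basis=basis,
                        clamp=config.clamp,
                        qualifying_clamp=config.qualifying_clamp,
                        min_products=config.min_products,
                    ).to_dict()
                    for x in config.targets
                }
            except TooFewProductsError as exc:
                skipped.append({"category": sub_label, "reason": str(exc)})
                continue
            thresholds_out[sub_label] = {
                "n_products": len(sub),
                "basis": basis.value,
                "targets": per_target,
            }
            family = threshold_family(
                sub, relevant, limits=limits, basis=basis,
                min_products=config.min_products,
            )
            scores = score_category(sub, family, category=sub_label)
            if config.rating_column in sub.columns:
                scores[config.rating_column] = sub[config.rating_column].to_numpy()
            score_frames.append(scores)

    if score_frames:
        all_scores = pd.concat(score_frames, ignore_index=True)
    else:
        all_scores = pd.DataFrame(
            columns=["product_id", "category", "score", "x_min", "assessable"]
        )

    rc = config.rating_column
    if rc in all_scores.columns and all_scores[rc].notna().sum() >= 3:
        rated = all_scores[all_scores[rc].notna() & all_scores["assessable"]]
        if len(rated) >= 3:
            summary = agreement_summary(
                rated["score"], rated[rc], product_ids=rated["product_id"]
            )
            validation_out = summary.to_dict()

    run_info = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "rows_in": len(products),
        "rows_cleaned": len(df),
        "n_initial_categories": len(initial),
        "n_subcategories_with_thresholds": len(thresholds_out),
        "rows_scored": len(all_scores),
    }
    return PipelineResult(
        cleaned=df,
        cleaning_report=report.to_dict(),
        relevance=relevance_out,
        partition=partition_out,
        thresholds=thresholds_out,
        scores=all_scores,
        validation=validation_out,
        run_info=run_info,
        skipped=skipped,
    )


def write_artifacts(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.cleaned.to_csv(out / "cleaned.csv", index=False)
    _json_dump(result.cleaning_report, out / "cleaning_report.json")
    _json_dump(result.relevance, out / "relevance.json")
    _json_dump(result.partition, out / "partition.json")
    _json_dump(
        {"schema_version": SCHEMA_VERSION, "categories": result.thresholds},
        out / "thresholds.json",
    )
    result.scores.to_csv(out / "scores.csv", index=False)
    _json_dump(result.validation, out / "validation.json")
    _json_dump({**result.run_info, "skipped": result.skipped}, out / "run.json")
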