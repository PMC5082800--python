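"""End-to-end derivation pipeline and run configuration.

``derive_score`` chains the stages — per-code screening, hierarchical
shrinkage, interval selection, category building, multivariable
weighting, source combination, integer weights — into one call, which
both the command-line pipeline and the bootstrap-optimism machinery
reuse.  ``RunConfig`` is the single YAML-backed configuration with every
seed explicit; each pipeline stage echoes its effective config and input
hashes into a manifest so reruns are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .coding import (
    ExposureWindow,
    MappingTable,
    extract_exposures,
    hospitalisation_flag,
    read_events_csv,
)
from .score_builder import (
    OverrideFile,
    WeightTable,
    build_categories,
    cap_weights,
    combine_sources,
    derive_weights,
    fit_weight_model,
)
from .shrinkage import (
    HierarchySpec,
    attach_hierarchy,
    estimate_code_hazards,
    fit_hierarchy,
    select_codes,
)
from .synthetic import GeneratorConfig, INDEX_DATE, generate, survival_records

__all__ = ["RunConfig", "DerivationResult", "derive_score", "run_pipeline", "validate_config"]


@dataclass
class DerivationResult:
    """Artifacts of one full derivation run."""

    estimates: pd.DataFrame
    posterior: object
    selection: pd.DataFrame
    categories: dict
    fit: object
    combine_decisions: pd.DataFrame
    weights: WeightTable

    @property
    def n_selected_codes(self) -> int:
        return int(self.selection["selected"].sum())


def derive_score(
    records: pd.DataFrame,
    exposures: pd.DataFrame,
    mapping: MappingTable,
    hierarchy_spec: HierarchySpec | None = None,
    hr_threshold: float = 1.2,
    selection_level: float = 0.99,
    combine_alpha: float = 0.005,
    retention_rule: str = "null",
    retention_level: float = 0.99,
    overrides: OverrideFile | None = None,
    hospitalisation: pd.Series | None = None,
    weight_cap: int | None = None,
) -> DerivationResult:
    """Run the full derivation on an assembled cohort.

    ``records``: per-patient survival table (patient_id, time, event,
    age, sex); ``exposures``: window-filtered exposure set.  An empty
    selection yields an empty (but valid) weight table.
    """
    spec = hierarchy_spec or HierarchySpec(level=selection_level)
    est = estimate_code_hazards(records, exposures)
    est = attach_hierarchy(est, mapping)
    posterior = fit_hierarchy(est, spec)
    selection = select_codes(posterior, hr_threshold=hr_threshold, level=spec.level)
    picked = selection[selection["selected"]].merge(
        est[["code", "terminology", "subchapter"]], on=["code", "terminology"]
    )
    categories = build_categories(picked, mapping, overrides)
    empty = WeightTable(
        rows=pd.DataFrame(
            columns=["category", "source", "hr", "ci_low", "ci_high", "weight", "provenance"]
        )
    )
    if not categories:
        return DerivationResult(est, posterior, selection, categories, None, pd.DataFrame(), empty)
    adjust = ("age", "sex", "hospitalisation") if hospitalisation is not None else ("age", "sex")
    fit, design = fit_weight_model(
        records, exposures, categories, hospitalisation=hospitalisation, adjust=adjust
    )
    fit, design, decisions = combine_sources(fit, design, alpha=combine_alpha)
    weights = derive_weights(
        fit, categories, rule=retention_rule, retention_level=retention_level
    )
    if weight_cap is not None:
        weights = cap_weights(weights, weight_cap)
    return DerivationResult(est, posterior, selection, categories, fit, decisions, weights)


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Pipeline configuration; defaults reproduce the main analysis."""

    out_dir: str = "runs/default"
    seed: int = 1
    # paths (None -> generate synthetically)
    patients_csv: str | None = None
    events_csv: str | None = None
    mapping_csv: str | None = None
    # generation
    generator: dict = field(default_factory=dict)
    # windows
    exclusion_months: int = 2
    min_follow_up_months: int = 0
    # thresholds
    hr_threshold: float = 1.2
    selection_level: float = 0.99
    combine_alpha: float = 0.005
    retention_rule: str = "null"
    retention_level: float = 0.99
    weight_cap: int | None = None
    score_cap: int | None = 20
    # sampler
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)


def validate_config(config: RunConfig) -> list:
    """Schema check; returns a list of violation messages (empty = valid)."""
    v = []
    if config.exclusion_months not in (2, 6):
        v.append("exclusion_months: must be 2 (main analysis) or 6 (sensitivity)")
    if config.min_follow_up_months not in (0, 1, 3, 6):
        v.append("min_follow_up_months: must be one of 0, 1, 3, 6")
    if config.weight_cap is not None and config.weight_cap < 1:
        v.append("weight_cap: must be >= 1 when set")
    if config.score_cap is not None and config.score_cap < 1:
        v.append("score_cap: must be >= 1 when set")
    if not 0 < config.selection_level < 1:
        v.append("selection_level: must lie in (0, 1)")
    if not 0 < config.combine_alpha < 1:
        v.append("combine_alpha: must lie in (0, 1)")
    if config.retention_rule not in ("null", "hr12"):
        v.append("retention_rule: must be 'null' or 'hr12'")
    if config.hr_threshold < 1:
        v.append("hr_threshold: must be >= 1")
    for name in ("chains", "warmup", "draws"):
        if getattr(config, name) < 1:
            v.append(f"{name}: must be >= 1")
    if config.seed < 0:
        v.append("seed: must be a non-negative integer")
    return v


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, stages=("generate", "derive", "score", "validate")):
    """Run the requested stages in dependency order, writing artifacts
    and a manifest (config echo + input hashes) under ``config.out_dir``.

    Returns a dict of the in-memory artifacts.  Reruns with an identical
    config produce identical files.
    """
    from .scorer import score_cohort
    from .survival import harrells_c
    from .validation import split_cohort

    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}, "inputs": {}}
    artifacts: dict = {}

    # --- inputs: generate or load
    if "generate" in stages or config.patients_csv is None:
        gen_cfg = GeneratorConfig(**{"seed": config.seed, **config.generator})
        patients, events, mapping_df, truth = generate(gen_cfg)
        patients.to_csv(out / "patients.csv", index=False)
        events.to_csv(out / "events.csv", index=False)
        mapping_df.to_csv(out / "mapping.csv", index=False)
        truth.to_yaml(out / "truth.yaml")
        manifest["stages"]["generate"] = {"n_patients": len(patients), "n_events": len(events)}
    else:
        patients = pd.read_csv(config.patients_csv)
        events = read_events_csv(config.events_csv)
        mapping_df = pd.read_csv(config.mapping_csv, dtype=str)
        for key, p in (
            ("patients", config.patients_csv),
            ("events", config.events_csv),
            ("mapping", config.mapping_csv),
        ):
            manifest["inputs"][key] = _sha256(Path(p))
    mapping = MappingTable(dict(zip(mapping_df["icd_subchapter"], mapping_df["read_subchapter"])))
    artifacts.update(patients=patients, events=events, mapping=mapping)

    window = ExposureWindow(INDEX_DATE, exclusion_months=config.exclusion_months)
    records = survival_records(patients)
    if config.min_follow_up_months:
        min_days = int(round(config.min_follow_up_months * 365.25 / 12))
        records = records[records["time"] >= min_days].reset_index(drop=True)
    exposures = extract_exposures(events, window)
    exposures = exposures[exposures["patient_id"].isin(records["patient_id"])]
    hosp = hospitalisation_flag(
        events, window.index_date, patient_ids=records["patient_id"],
        exclusion_months=config.exclusion_months,
    )
    artifacts.update(records=records, exposures=exposures, hospitalisation=hosp)

    if "derive" in stages:
        dev, val = split_cohort(records, fraction=0.5, seed=config.seed)
        dev_exp = exposures[exposures["patient_id"].isin(dev["patient_id"])]
        spec = HierarchySpec(
            chains=config.chains,
            warmup=config.warmup,
            draws=config.draws,
            seed=config.seed,
            level=config.selection_level,
        )
        result = derive_score(
            dev,
            dev_exp,
            mapping,
            hierarchy_spec=spec,
            hr_threshold=config.hr_threshold,
            combine_alpha=config.combine_alpha,
            retention_rule=config.retention_rule,
            retention_level=config.retention_level,
            hospitalisation=hosp,
            weight_cap=config.weight_cap,
        )
        result.estimates.to_csv(out / "estimates.csv", index=False)
        result.posterior.table().to_csv(out / "posterior.csv", index=False)
        result.weights.to_csv(out / "weights.csv")
        manifest["stages"]["derive"] = {
            "n_codes": len(result.estimates),
            "n_selected": result.n_selected_codes,
            "n_categories": len(result.categories),
            "n_weighted": len(result.weights.rows),
        }
        artifacts.update(derivation=result, development=dev, validation=val)

    if "score" in stages and "derivation" in artifacts:
        scores = score_cohort(
            exposures,
            artifacts["derivation"].weights,
            cap=config.score_cap,
            patient_ids=records["patient_id"],
        )
        scores.to_csv(out / "scores.csv", index=False)
        artifacts["scores"] = scores
        manifest["stages"]["score"] = {
            "n_scored": len(scores),
            "mean_score": float(scores["score"].mean()) if len(scores) else 0.0,
        }

    if "validate" in stages and "scores" in artifacts:
        val = artifacts["validation"]
        sc = artifacts["scores"].set_index("patient_id")["score"]
        c = harrells_c(val["time"], val["event"], sc.reindex(val["patient_id"]).to_numpy())
        report = {
            "harrells_c": {
                "c": round(c.c, 4),
                "ci_low": round(c.ci_low, 4),
                "ci_high": round(c.ci_high, 4),
            },
            "n_validation": int(len(val)),
        }
        with open(out / "report.yaml", "w") as fh:
            yaml.safe_dump(report, fh)
        manifest["stages"]["validate"] = report

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    artifacts["manifest"] = manifest
    return artifacts
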