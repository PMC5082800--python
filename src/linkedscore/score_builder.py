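"""From selected codes to an integer weight table.

Selected codes are grouped by subchapter into candidate categories (ICD
groups merging onto their mapped Read group where one exists), reviewed
via a declarative override file in place of manual clinical review, and
entered into a single multivariable Cox model — one indicator per
category *per coding source*, adjusted for age, sex and recent
hospitalisation.  Categories whose Read- and ICD-derived coefficients do
not differ (Wald p >= 0.005) are combined into a single indicator and
the model refit; the rest keep separate weights, which is how a handful
of conditions end up with a hospital-specific weight.

Weights are the Cox coefficients times ten, rounded half-up to the
nearest integer.  By default a category is retained when its coefficient
is positive and its credible/confidence interval excludes the null; a
stricter hazard-ratio > 1.2 retention variant is available by
configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .coding import MappingTable, Terminology, normalize_code
from .survival import CoxFit, fit_cox_arrays

__all__ = [
    "CandidateCategory",
    "OverrideFile",
    "WeightTable",
    "build_categories",
    "fit_weight_model",
    "combine_sources",
    "derive_weights",
    "cap_weights",
    "round_half_up_weight",
]

ADJUSTERS = ("age", "sex", "hospitalisation")


def round_half_up_weight(beta: float) -> int:
    """weight = round(10 * beta), ties away from the floor (half-up)."""
    return int(math.floor(10.0 * beta + 0.5))


@dataclass
class CandidateCategory:
    """A candidate score category: subchapter-grouped selected codes."""

    label: str
    origin: str  # "read" | "icd" | "combined"
    read_subchapters: set = field(default_factory=set)
    icd_subchapters: set = field(default_factory=set)
    read_codes: set = field(default_factory=set)  # normalized code values
    icd_codes: set = field(default_factory=set)

    @property
    def n_codes(self) -> int:
        return len(self.read_codes) + len(self.icd_codes)


class OverrideFile:
    """Declarative replacement for the manual clinical review step.

    A YAML list of edits applied deterministically in file order:

    - ``{action: drop_code, terminology: READ|ICD10, code: ...}``
    - ``{action: move_code, terminology: ..., code: ..., from: ..., to: ...}``
    - ``{action: rename_category, from: ..., to: ...}``
    - ``{action: merge_categories, from: [a, b], to: ...}``
    """

    def __init__(self, edits=None):
        self.edits = list(edits or [])

    @classmethod
    def load(cls, path) -> "OverrideFile":
        with open(path) as fh:
            edits = yaml.safe_load(fh) or []
        if not isinstance(edits, list):
            raise ValueError("override file must contain a YAML list of edits")
        return cls(edits)

    def apply(self, categories: dict) -> dict:
        cats = {k: replace(v) for k, v in categories.items()}
        for edit in self.edits:
            action = edit.get("action")
            if action == "drop_code":
                self._with_code(cats, edit)
            elif action == "move_code":
                src = cats.get(edit["from"])
                dst = cats.get(edit["to"])
                if src is None or dst is None:
                    raise ValueError(f"override references unknown category: {edit}")
                attr = (
                    "read_codes"
                    if edit["terminology"] == Terminology.READ.value
                    else "icd_codes"
                )
                code = edit["code"]
                if code not in getattr(src, attr):
                    raise ValueError(f"override references unknown code: {edit}")
                getattr(src, attr).remove(code)
                getattr(dst, attr).add(code)
            elif action == "rename_category":
                if edit["from"] not in cats:
                    raise ValueError(f"override references unknown category: {edit}")
                cat = cats.pop(edit["from"])
                cat.label = edit["to"]
                cats[edit["to"]] = cat
            elif action == "merge_categories":
                missing = [k for k in edit["from"] if k not in cats]
                if missing:
                    raise ValueError(f"override references unknown categories: {missing}")
                merged = CandidateCategory(label=edit["to"], origin="combined")
                for k in edit["from"]:
                    c = cats.pop(k)
                    merged.read_subchapters |= c.read_subchapters
                    merged.icd_subchapters |= c.icd_subchapters
                    merged.read_codes |= c.read_codes
                    merged.icd_codes |= c.icd_codes
                cats[edit["to"]] = merged
            else:
                raise ValueError(f"unknown override action: {action!r}")
        return {k: v for k, v in cats.items() if v.n_codes > 0}

    @staticmethod
    def _with_code(cats, edit):
        attr = (
            "read_codes"
            if edit["terminology"] == Terminology.READ.value
            else "icd_codes"
        )
        for cat in cats.values():
            if edit["code"] in getattr(cat, attr):
                getattr(cat, attr).remove(edit["code"])
                return cat, attr
        raise ValueError(f"override references unknown code: {edit}")


def build_categories(
    selected: pd.DataFrame,
    mapping: MappingTable,
    overrides: OverrideFile | None = None,
) -> dict:
    """Group selected codes into candidate categories.

    ``selected`` needs columns code, terminology, subchapter (only rows
    for selected codes).  Read codes group by Read subchapter; ICD codes
    by ICD subchapter; an ICD group whose mapped Read subchapter also has
    a group merges into a combined category.  Unmapped ICD groups stay
    ICD-only.  Overrides are applied last.  Returns {label: category}.
    """
    cats: dict = {}
    read_rows = selected[selected["terminology"] == Terminology.READ.value]
    for sub, grp in read_rows.groupby("subchapter"):
        cats[sub] = CandidateCategory(
            label=sub,
            origin="read",
            read_subchapters={sub},
            read_codes={normalize_code(c, Terminology.READ) for c in grp["code"]},
        )
    icd_rows = selected[selected["terminology"] == Terminology.ICD10.value]
    for sub, grp in icd_rows.groupby("subchapter"):
        codes = {normalize_code(c, Terminology.ICD10) for c in grp["code"]}
        target = mapping.map_group(sub)
        if target != "unmapped" and target in cats:
            cat = cats[target]
            cat.origin = "combined"
            cat.icd_subchapters.add(sub)
            cat.icd_codes |= codes
        else:
            label = f"icd:{sub}"
            cats[label] = CandidateCategory(
                label=label,
                origin="icd",
                icd_subchapters={sub},
                icd_codes=codes,
            )
    if overrides is not None:
        cats = overrides.apply(cats)
    return cats


def _indicator_matrix(exposures: pd.DataFrame, categories: dict, patient_index):
    """Per-category per-source exposure indicators over patients.

    Returns a DataFrame indexed like ``patient_index`` with one 0/1
    column per (category, source) that has member codes, named
    ``{label}|read`` / ``{label}|icd``.
    """
    pos = {pid: i for i, pid in enumerate(patient_index)}
    n = len(patient_index)
    cols = {}
    norm = [
        normalize_code(c, Terminology(t))
        for c, t in zip(exposures["code"], exposures["terminology"])
    ]
    exp_norm = exposures.assign(norm=norm)
    read_exp = exp_norm[exp_norm["terminology"] == Terminology.READ.value]
    icd_exp = exp_norm[exp_norm["terminology"] == Terminology.ICD10.value]
    for label, cat in sorted(categories.items()):
        if cat.read_codes:
            hit = read_exp[read_exp["norm"].isin(cat.read_codes)]["patient_id"]
            x = np.zeros(n)
            x[[pos[p] for p in hit.unique() if p in pos]] = 1.0
            cols[f"{label}|read"] = x
        if cat.icd_codes:
            hit = icd_exp[icd_exp["norm"].isin(cat.icd_codes)]["patient_id"]
            x = np.zeros(n)
            x[[pos[p] for p in hit.unique() if p in pos]] = 1.0
            cols[f"{label}|icd"] = x
    return pd.DataFrame(cols, index=patient_index)


def fit_weight_model(
    records: pd.DataFrame,
    exposures: pd.DataFrame,
    categories: dict,
    hospitalisation: pd.Series | None = None,
    adjust=ADJUSTERS,
) -> tuple:
    """Multivariable Cox fit with separate Read/ICD indicators.

    ``records`` is the per-patient survival table (patient_id, time,
    event, age, sex).  Returns ``(fit, design)`` where ``design`` is the
    full design matrix used (indicator columns plus adjusters) — it is
    needed again when sources are combined and for refits.
    """
    recs = records.reset_index(drop=True)
    design = _indicator_matrix(exposures, categories, recs["patient_id"])
    empty = [c for c in design.columns if design[c].sum() == 0]
    if empty:
        raise ValueError(f"category indicator(s) all zero (inestimable): {empty}")
    design = design.reset_index(drop=True)
    if "age" in adjust:
        design["age"] = recs["age"].to_numpy(float)
    if "sex" in adjust:
        design["sex"] = recs["sex"].to_numpy(float)
    if "hospitalisation" in adjust:
        if hospitalisation is None:
            raise ValueError("hospitalisation adjuster requested but no flag given")
        design["hospitalisation"] = (
            hospitalisation.reindex(recs["patient_id"], fill_value=False)
            .to_numpy(bool)
            .astype(float)
        )
    fit = fit_cox_arrays(
        design.to_numpy(float),
        recs["time"].to_numpy(float),
        recs["event"].to_numpy(bool),
        names=list(design.columns),
    )
    return fit, pd.concat([recs[["patient_id", "time", "event"]], design], axis=1)


def combine_sources(
    fit: CoxFit, design: pd.DataFrame, alpha: float = 0.005
) -> tuple:
    """Merge Read and ICD indicators where their coefficients agree.

    For every category with both sources in the fit, a Wald test
    z = (b_read - b_icd) / sqrt(se_r^2 + se_i^2) decides: p >= alpha
    merges both into one "either source" indicator and the model is
    refit; p < alpha keeps separate weights.  Returns
    ``(fit, design, decisions)``.
    """
    pairs = {}
    for name in fit.names:
        if "|" in name:
            label, source = name.rsplit("|", 1)
            pairs.setdefault(label, {})[source] = name
    decisions = []
    merged_any = False
    design = design.copy()
    for label, sources in sorted(pairs.items()):
        if set(sources) != {"read", "icd"}:
            continue
        br, bi = fit.coef(sources["read"]), fit.coef(sources["icd"])
        ser, sei = fit.se_of(sources["read"]), fit.se_of(sources["icd"])
        z = (br - bi) / math.sqrt(ser**2 + sei**2)
        p = 2.0 * stats.norm.sf(abs(z))
        merge = p >= alpha
        decisions.append(
            {"category": label, "z": z, "p": p, "combined": merge}
        )
        if merge:
            merged_any = True
            combined = (
                (design[sources["read"]] + design[sources["icd"]]) > 0
            ).astype(float)
            design = design.drop(columns=[sources["read"], sources["icd"]])
            design[f"{label}|combined"] = combined
    decisions = pd.DataFrame(decisions, columns=["category", "z", "p", "combined"])
    if not merged_any:
        return fit, design, decisions
    covar_cols = [c for c in design.columns if c not in ("patient_id", "time", "event")]
    new_fit = fit_cox_arrays(
        design[covar_cols].to_numpy(float),
        design["time"].to_numpy(float),
        design["event"].to_numpy(bool),
        names=covar_cols,
    )
    return new_fit, design, decisions


@dataclass
class WeightTable:
    """Categories with integer weights and resolved code sets.

    ``rows`` has one row per (category, source) with columns category,
    source (read|combined|icd), hr, ci_low, ci_high, weight, provenance.
    A category matched from Read codes scores its read/combined weight;
    matched from ICD-10 codes it scores the ICD weight when present,
    else the combined one; matched from both, the higher.
    """

    rows: pd.DataFrame
    read_codes: dict = field(default_factory=dict)  # category -> set of codes
    icd_codes: dict = field(default_factory=dict)
    provenance: str = "derived"
    cap: int | None = None

    def __post_init__(self) -> None:
        w = self.rows["weight"]
        if (w < 0).any():
            raise ValueError("weights must be non-negative integers")
        if len(self.rows) and not self.rows.groupby("category").size().ge(1).all():
            raise ValueError("every category needs at least one weight row")

    @property
    def categories(self) -> list:
        return sorted(self.rows["category"].unique())

    def base_weight(self, category) -> int | None:
        """Read-or-combined weight (None when the category is ICD-only)."""
        r = self.rows[
            (self.rows["category"] == category)
            & (self.rows["source"].isin(["read", "combined"]))
        ]
        return int(r["weight"].iloc[0]) if len(r) else None

    def icd_weight(self, category) -> int | None:
        """ICD-specific weight where one exists, else the base weight."""
        r = self.rows[
            (self.rows["category"] == category) & (self.rows["source"] == "icd")
        ]
        if len(r):
            return int(r["weight"].iloc[0])
        return self.base_weight(category)

    @property
    def n_dual_weight(self) -> int:
        """Categories carrying a hospital-source-specific weight."""
        return int((self.rows["source"] == "icd").sum())

    @property
    def max_weight(self) -> int:
        return int(self.rows["weight"].max())

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def derive_weights(
    fit: CoxFit,
    categories: dict,
    rule: str = "null",
    retention_level: float = 0.99,
    report_level: float = 0.95,
) -> WeightTable:
    """Translate the final Cox fit into an integer weight table.

    Retention (configurable): ``"null"`` keeps categories with a positive
    coefficient whose ``retention_level`` interval excludes the null;
    ``"hr12"`` requires the interval to lie above hazard ratio 1.2.
    Weight = round(10 * beta), half-up.  Hazard ratios are reported with
    ``report_level`` intervals.
    """
    if rule not in ("null", "hr12"):
        raise ValueError("rule must be 'null' or 'hr12'")
    thr = 0.0 if rule == "null" else math.log(1.2)
    rows = []
    read_codes, icd_codes = {}, {}
    for name in fit.names:
        if "|" not in name:
            continue
        label, source = name.rsplit("|", 1)
        beta = fit.coef(name)
        lo99, _ = fit.ci(name, retention_level)
        if not (beta > 0 and lo99 > thr):
            continue
        lo, hi = fit.ci(name, report_level)
        rows.append(
            {
                "category": label,
                "source": source,
                "hr": math.exp(beta),
                "ci_low": math.exp(lo),
                "ci_high": math.exp(hi),
                "weight": round_half_up_weight(beta),
                "provenance": "derived",
            }
        )
        cat = categories[label]
        if source in ("read", "combined") and cat.read_codes:
            read_codes[label] = set(cat.read_codes)
        if source in ("icd", "combined") and cat.icd_codes:
            icd_codes[label] = set(cat.icd_codes)
        if source == "read" and cat.icd_codes and not any(
            n == f"{label}|icd" for n in fit.names
        ):
            # read-only weight but ICD member codes exist: they score the
            # same weight (no ICD-specific row was estimable/retained)
            icd_codes[label] = set(cat.icd_codes)
    table = pd.DataFrame(
        rows,
        columns=["category", "source", "hr", "ci_low", "ci_high", "weight", "provenance"],
    )
    return WeightTable(rows=table, read_codes=read_codes, icd_codes=icd_codes)


def drop_category(table: WeightTable, category: str) -> WeightTable:
    """Remove one category from a weight table (its weights contribute
    zero), e.g. dropping diabetes before using the score to adjust a
    diabetes analysis.  Raises if the category is absent."""
    if category not in set(table.rows["category"]):
        raise ValueError(f"category {category!r} not in weight table")
    rows = table.rows[table.rows["category"] != category].reset_index(drop=True)
    return WeightTable(
        rows=rows,
        read_codes={k: set(v) for k, v in table.read_codes.items() if k != category},
        icd_codes={k: set(v) for k, v in table.icd_codes.items() if k != category},
        provenance=table.provenance,
        cap=table.cap,
    )


def cap_weights(table: WeightTable, cap: int) -> WeightTable:
    """Cap all weights at ``cap`` (idempotent); provenance notes the cap."""
    if cap < 1:
        raise ValueError("cap must be >= 1")
    rows = table.rows.copy()
    rows["weight"] = rows["weight"].clip(upper=cap)
    rows["provenance"] = [
        p if p.endswith(f"capped@{cap}") else f"{p}|capped@{cap}"
        for p in rows["provenance"]
    ]
    return WeightTable(
        rows=rows,
        read_codes={k: set(v) for k, v in table.read_codes.items()},
        icd_codes={k: set(v) for k, v in table.icd_codes.items()},
        provenance=table.provenance,
        cap=table.cap,
    )
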