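"""Apply a weight table to patient code histories.

Each category enters a patient's score once, with the highest applicable
weight: a category matched through Read codes scores its read/combined
weight, through ICD-10 codes its ICD-specific weight when one exists
(else the combined weight), and when both settings recorded it, the
higher of the two.  Totals can be capped (the published distribution
comparison caps at 20).  Unknown codes are ignored with a count — real
dictionaries always outrun code lists.

Comparator indices (Charlson, Elixhauser) plug in through the same
machinery: a :class:`ComparatorDefinition` is just a single-weight-per-
category table in the same code-list format.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .coding import Terminology, normalize_code, read_code_list_csv
from .score_builder import WeightTable

__all__ = [
    "PatientScore",
    "ComparatorDefinition",
    "load_weight_table",
    "score_patient",
    "score_cohort",
    "score_comparator",
]


@dataclass
class PatientScore:
    """One patient's score with per-category contributions."""

    patient_id: object
    total: int
    contributions: dict  # category -> (weight used, source used)
    capped: bool = False
    n_unknown_codes: int = 0


@dataclass
class ComparatorDefinition:
    """A named comparator index: one weight per category plus code lists."""

    name: str
    table: WeightTable


def load_weight_table(
    weights_csv,
    read_codelist_csv=None,
    icd_codelist_csv=None,
    provenance: str = "published",
) -> WeightTable:
    """Load a weight table plus its category code lists.

    ``weights_csv`` is the long layout (category, source, hr, ci_low,
    ci_high, weight); the code lists use the two-column layout
    (category_label, code), one file per terminology.  Every weighted
    category must resolve at least one code; duplicate codes within one
    terminology and category only warn.
    """
    rows = pd.read_csv(weights_csv)
    required = {"category", "source", "weight"}
    if not required <= set(rows.columns):
        raise ValueError(f"weights file needs columns {sorted(required)}")
    rows["weight"] = rows["weight"].astype(int)
    if "provenance" not in rows.columns:
        rows["provenance"] = provenance

    read_codes: dict = {}
    icd_codes: dict = {}
    warnings: list = []
    for path, term, store in (
        (read_codelist_csv, Terminology.READ, read_codes),
        (icd_codelist_csv, Terminology.ICD10, icd_codes),
    ):
        if path is None:
            continue
        cl = read_code_list_csv(path, term)
        dup = cl.duplicated()
        if dup.any():
            warnings.append(
                f"duplicate {term.value} codes: {sorted(cl[dup]['code'])}"
            )
            cl = cl[~dup]
        for label, grp in cl.groupby("category_label"):
            store[label] = set(grp["code"])

    orphans = [
        c
        for c in rows["category"].unique()
        if c not in read_codes and c not in icd_codes
    ]
    if orphans:
        raise ValueError(f"weighted categories with no codes: {orphans}")
    table = WeightTable(
        rows=rows,
        read_codes=read_codes,
        icd_codes=icd_codes,
        provenance=provenance,
    )
    table.load_warnings = warnings
    return table


def _lookups(table: WeightTable):
    """code -> (category, weight) maps for each terminology."""
    read_lu, icd_lu = {}, {}
    for cat, codes in table.read_codes.items():
        w = table.base_weight(cat)
        if w is None:
            continue
        for c in codes:
            read_lu[c] = (cat, w)
    for cat, codes in table.icd_codes.items():
        w = table.icd_weight(cat)
        if w is None:
            continue
        for c in codes:
            icd_lu[c] = (cat, w)
    return read_lu, icd_lu


def score_patient(
    exposures: pd.DataFrame, table: WeightTable, cap: int | None = None
) -> PatientScore:
    """Score one patient's window-filtered exposure set.

    ``exposures`` needs columns code, terminology (a patient_id column,
    if present, must be constant).
    """
    pid = exposures["patient_id"].iloc[0] if "patient_id" in exposures and len(exposures) else None
    read_lu, icd_lu = _lookups(table)
    best: dict = {}
    unknown = 0
    for code, term in zip(exposures.get("code", []), exposures.get("terminology", [])):
        t = Terminology(term)
        lu = read_lu if t == Terminology.READ else icd_lu
        hit = lu.get(normalize_code(code, t))
        if hit is None:
            unknown += 1
            continue
        cat, w = hit
        source = "read" if t == Terminology.READ else "icd"
        if cat not in best or w > best[cat][0]:
            best[cat] = (w, source)
    total = sum(w for w, _ in best.values())
    capped = cap is not None and total > cap
    return PatientScore(
        patient_id=pid,
        total=min(total, cap) if cap is not None else total,
        contributions=best,
        capped=capped,
        n_unknown_codes=unknown,
    )


def score_cohort(
    exposures: pd.DataFrame,
    table: WeightTable,
    cap: int | None = None,
    patient_ids=None,
) -> pd.DataFrame:
    """Vectorized scoring of a whole cohort's exposure table.

    Returns a DataFrame (patient_id, score, capped, n_unknown_codes);
    ``patient_ids``, when given, fixes the output universe so patients
    with no matching exposures appear with score 0.
    """
    read_lu, icd_lu = _lookups(table)
    if len(exposures):
        norm = [
            normalize_code(c, Terminology(t))
            for c, t in zip(exposures["code"], exposures["terminology"])
        ]
        is_read = (exposures["terminology"] == Terminology.READ.value).to_numpy()
        hits = [
            (read_lu if r else icd_lu).get(c) for c, r in zip(norm, is_read)
        ]
        df = pd.DataFrame(
            {
                "patient_id": exposures["patient_id"].to_numpy(),
                "category": [h[0] if h else None for h in hits],
                "weight": [h[1] if h else 0 for h in hits],
            }
        )
        unknown = (
            df[df["category"].isna()]
            .groupby("patient_id")
            .size()
            .rename("n_unknown_codes")
        )
        matched = df.dropna(subset=["category"])
        per_cat = (
            matched.groupby(["patient_id", "category"])["weight"].max().reset_index()
        )
        totals = per_cat.groupby("patient_id")["weight"].sum().rename("raw")
    else:
        unknown = pd.Series(dtype=int, name="n_unknown_codes")
        totals = pd.Series(dtype=int, name="raw")
    if patient_ids is None:
        patient_ids = totals.index
    out = pd.DataFrame({"patient_id": list(patient_ids)})
    out["raw"] = totals.reindex(out["patient_id"], fill_value=0).to_numpy()
    out["capped"] = False if cap is None else out["raw"] > cap
    out["score"] = out["raw"] if cap is None else out["raw"].clip(upper=cap)
    out["n_unknown_codes"] = unknown.reindex(out["patient_id"], fill_value=0).to_numpy()
    return out[["patient_id", "score", "capped", "n_unknown_codes"]].astype(
        {"score": int, "n_unknown_codes": int}
    )


def score_comparator(
    exposures: pd.DataFrame,
    definition: ComparatorDefinition,
    cap: int | None = None,
    patient_ids=None,
) -> pd.DataFrame:
    """Score a comparator index with identical matching semantics."""
    return score_cohort(exposures, definition.table, cap=cap, patient_ids=patient_ids)


def distribution_summary(scores: pd.DataFrame) -> pd.DataFrame:
    """Histogram of attained score values (for distribution comparisons)."""
    counts = scores["score"].value_counts().sort_index()
    return pd.DataFrame({"score": counts.index, "n": counts.to_numpy()})
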