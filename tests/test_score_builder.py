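"""Category building, source combination, and the integer weight rule."""

import math

import numpy as np
import pandas as pd
import pytest

from linkedscore.coding import MappingTable
from linkedscore.score_builder import (
    CandidateCategory,
    OverrideFile,
    WeightTable,
    build_categories,
    cap_weights,
    combine_sources,
    derive_weights,
    drop_category,
    fit_weight_model,
    round_half_up_weight,
)


def _selected(rows):
    return pd.DataFrame(rows, columns=["code", "terminology", "subchapter"])


def test_category_count_follows_set_arithmetic():
    """3 Read groups + 3 ICD groups with 2 ICD groups mapped onto Read
    groups -> 4 categories."""
    sel = _selected(
        [
            ("A11..", "READ", "A1"),
            ("B21..", "READ", "B2"),
            ("C31..", "READ", "C3"),
            ("K70", "ICD10", "K7"),
            ("L10", "ICD10", "L1"),
            ("M30", "ICD10", "M3"),
        ]
    )
    mapping = MappingTable({"K7": "A1", "L1": "B2"})
    cats = build_categories(sel, mapping)
    assert len(cats) == 4
    assert cats["A1"].origin == "combined" and "K70" in cats["A1"].icd_codes
    assert cats["icd:M3"].origin == "icd"


def test_empty_selection_empty_categories():
    assert build_categories(_selected([]), MappingTable({})) == {}


def test_override_moves_and_drops_codes():
    sel = _selected([("A11..", "READ", "A1"), ("A12..", "READ", "A1"), ("B21..", "READ", "B2")])
    ov = OverrideFile(
        [
            {"action": "move_code", "terminology": "READ", "code": "A12", "from": "A1", "to": "B2"},
            {"action": "drop_code", "terminology": "READ", "code": "A11"},
        ]
    )
    cats = build_categories(sel, MappingTable({}), overrides=ov)
    assert "A1" not in cats  # emptied by the two edits
    assert cats["B2"].read_codes == {"B21", "A12"}
    total = sum(c.n_codes for c in cats.values())
    assert total == 2


def test_override_unknown_reference_errors():
    sel = _selected([("A11..", "READ", "A1")])
    ov = OverrideFile([{"action": "drop_code", "terminology": "READ", "code": "ZZZ"}])
    with pytest.raises(ValueError, match="unknown code"):
        build_categories(sel, MappingTable({}), overrides=ov)


@pytest.mark.parametrize(
    "hr,weight",
    [(2.9, 11), (2.0, 7), (2.4, 9), (1.6, 5), (1.0, 0)],
)
def test_weight_rule_half_up(hr, weight):
    assert round_half_up_weight(math.log(hr)) == weight


def test_weight_rule_half_up_tie():
    assert round_half_up_weight(0.45) == 5  # .05 ties round away from zero


def _records_and_exposures(seed=0, n=4000, betas=(0.7, 0.0)):
    """Two categories, the first with a real effect."""
    rng = np.random.default_rng(seed)
    x1 = rng.binomial(1, 0.15, n)
    x2 = rng.binomial(1, 0.15, n)
    age = np.clip(rng.normal(55, 15, n), 20, 95)
    sex = rng.integers(0, 2, n)
    lp = betas[0] * x1 + betas[1] * x2 + 0.03 * (age - 55)
    t = np.minimum(np.ceil(rng.exponential(1 / (0.05 * np.exp(lp))) * 365.25), 1826)
    e = t < 1826
    records = pd.DataFrame(
        {"patient_id": np.arange(1, n + 1), "time": t, "event": e, "age": age, "sex": sex}
    )
    rows = []
    for i in range(n):
        if x1[i]:
            rows.append((i + 1, "A11..", "READ"))
        if x2[i]:
            rows.append((i + 1, "B21..", "READ"))
    exposures = pd.DataFrame(rows, columns=["patient_id", "code", "terminology"])
    cats = {
        "A1": CandidateCategory("A1", "read", {"A1"}, set(), {"A11"}, set()),
        "B2": CandidateCategory("B2", "read", {"B2"}, set(), {"B21"}, set()),
    }
    return records, exposures, cats


def test_weight_model_recovers_category_effect():
    records, exposures, cats = _records_and_exposures()
    fit, _ = fit_weight_model(records, exposures, cats, adjust=("age", "sex"))
    assert abs(fit.coef("A1|read") - 0.7) < 3 * fit.se_of("A1|read")


def test_weight_model_errors_on_empty_indicator():
    records, exposures, cats = _records_and_exposures()
    cats["Z9"] = CandidateCategory("Z9", "read", {"Z9"}, set(), {"Z99"}, set())
    with pytest.raises(ValueError, match="Z9"):
        fit_weight_model(records, exposures, cats, adjust=("age", "sex"))


def test_derive_weights_retains_only_positive_significant():
    records, exposures, cats = _records_and_exposures()
    fit, _ = fit_weight_model(records, exposures, cats, adjust=("age", "sex"))
    table = derive_weights(fit, cats)
    assert "A1" in table.categories
    assert "B2" not in table.categories  # null category gets no weight
    w = table.base_weight("A1")
    assert abs(w - round_half_up_weight(fit.coef("A1|read"))) == 0


def test_combine_sources_wald_decision():
    """b_read=0.3, b_icd=0.7, both se 0.05: z = 5.66, p ~ 1.5e-8 < 0.005,
    so the sources stay separate; identical coefficients merge."""
    from scipy import stats

    z = (0.3 - 0.7) / math.sqrt(0.05**2 + 0.05**2)
    p = 2 * stats.norm.sf(abs(z))
    assert p < 0.005 and abs(z) == pytest.approx(5.657, abs=1e-3)

    # end-to-end behavioral check on data where read and icd effects agree
    rng = np.random.default_rng(5)
    n = 6000
    xr = rng.binomial(1, 0.12, n)
    xi = rng.binomial(1, 0.12, n)
    lp = 0.6 * xr + 0.6 * xi
    t = np.minimum(np.ceil(rng.exponential(1 / (0.06 * np.exp(lp))) * 365.25), 1826)
    records = pd.DataFrame(
        {
            "patient_id": np.arange(1, n + 1),
            "time": t,
            "event": t < 1826,
            "age": np.full(n, 60.0) + rng.normal(0, 8, n),
            "sex": rng.integers(0, 2, n),
        }
    )
    rows = [(i + 1, "A11..", "READ") for i in range(n) if xr[i]]
    rows += [(i + 1, "K70", "ICD10") for i in range(n) if xi[i]]
    exposures = pd.DataFrame(rows, columns=["patient_id", "code", "terminology"])
    cats = {"A1": CandidateCategory("A1", "combined", {"A1"}, {"K7"}, {"A11"}, {"K70"})}
    fit, design = fit_weight_model(records, exposures, cats, adjust=("age", "sex"))
    fit2, design2, decisions = combine_sources(fit, design)
    assert decisions.loc[0, "combined"]
    assert "A1|combined" in fit2.names
    table = derive_weights(fit2, cats)
    assert table.rows.loc[0, "source"] == "combined"
    # combined categories score from either terminology
    assert "A1" in table.read_codes and "A1" in table.icd_codes


def test_single_source_category_untouched_by_combine():
    records, exposures, cats = _records_and_exposures()
    fit, design = fit_weight_model(records, exposures, cats, adjust=("age", "sex"))
    fit2, _, decisions = combine_sources(fit, design)
    assert decisions.empty
    assert fit2 is fit


def _table(weights):
    rows = pd.DataFrame(
        {
            "category": list(weights),
            "source": ["combined"] * len(weights),
            "hr": np.exp(np.array(list(weights.values())) / 10),
            "ci_low": 1.0,
            "ci_high": 2.0,
            "weight": list(weights.values()),
            "provenance": "derived",
        }
    )
    return WeightTable(rows=rows, read_codes={k: {f"{k}x"} for k in weights})


def test_cap_weights_examples_and_idempotence():
    t = _table({"A": 29, "B": 5})
    capped = cap_weights(t, 10)
    assert capped.rows.set_index("category")["weight"].to_dict() == {"A": 10, "B": 5}
    twice = cap_weights(capped, 10)
    pd.testing.assert_frame_equal(capped.rows, twice.rows)
    with pytest.raises(ValueError):
        cap_weights(t, 0)


def test_drop_category_removes_weights_and_codes():
    t = _table({"A": 4, "B": 2})
    out = drop_category(t, "A")
    assert out.categories == ["B"] and "A" not in out.read_codes
    with pytest.raises(ValueError):
        drop_category(t, "missing")


def test_weight_table_rejects_negative_weights():
    with pytest.raises(ValueError):
        WeightTable(
            rows=pd.DataFrame(
                {"category": ["A"], "source": ["combined"], "hr": [1.0],
                 "ci_low": [1.0], "ci_high": [1.0], "weight": [-1], "provenance": ["x"]}
            )
        )
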