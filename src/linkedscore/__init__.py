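"""linkedscore: a linked primary/secondary-care comorbidity score.

Derivation, validation and application of an integer comorbidity score
for linked Read-coded primary care and ICD-10-coded hospital records:
per-code Cox screening, hierarchical Bayesian shrinkage over the coding
hierarchies, interval-based code selection, multivariable category
weighting, and the published weight table ready to apply to patient
histories.
"""

from importlib.resources import files as _files

__version__ = "0.1.0"


def data_path(name: str):
    """Path to a packaged data file (published weights, code lists)."""
    return _files("linkedscore.data").joinpath(name)


def published_weight_table():
    """The packaged published weight table with its category code lists.

    Weights and hazard ratios are the published ones; the member code
    lists are synthetic stand-ins in the published CSV layout (the
    original supplementary lists are not redistributed here).
    """
    from .scorer import load_weight_table

    return load_weight_table(
        data_path("published_weights.csv"),
        data_path("linked_score_read_codes_synthetic.csv"),
        data_path("linked_score_icd10_codes_synthetic.csv"),
    )
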