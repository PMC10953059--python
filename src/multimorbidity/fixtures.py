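"""Access to the packaged fixture codelists, rules and weights.

The fixture content is synthetic: code strings follow the shape of Read
v2 / BNF codes but are fabricated, and the weights file holds fixed
plausible values clearly labelled as such (published development-study
coefficients can be swapped in as a user-supplied file of the same
layout).  The fixtures exist so the whole pipeline can be exercised and
tested without access to restricted data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .codemap import Codelist, Domain, Framework, load_codelist_table
from .phenotype import ConditionRule, compile_rules
from .score import ScoreWeights, load_weights


def _data_path(name: str):
    return resources.files("multimorbidity").joinpath("data", name)


def load_fixture_codelists() -> dict[str, Codelist]:
    """All fixture codelists keyed by the names the rule config references.

    Diagnosis lists are named ``<condition>_diag``, prescription lists
    ``<condition>_rx``, and the eGFR test list ``egfr_test``.
    """
    out: dict[str, Codelist] = {}
    diag = load_codelist_table(
        _data_path("codelists_diagnosis_read2.csv"), Framework.READ2, Domain.DIAGNOSIS
    )
    for cid, cl in diag.items():
        out[f"{cid}_diag"] = cl
    rx = load_codelist_table(
        _data_path("codelists_prescription_bnf.csv"), Framework.BNF, Domain.PRESCRIPTION
    )
    for cid, cl in rx.items():
        out[f"{cid}_rx"] = cl
    out["egfr_test"] = load_codelist_table(
        _data_path("codelists_test_read2.csv"), Framework.READ2, Domain.TEST
    )["chronic_kidney_disease"]
    return out


def load_fixture_rules(codelists=None) -> dict[str, ConditionRule]:
    """Compiled phenotyping rules for all 37 conditions."""
    if codelists is None:
        codelists = load_fixture_codelists()
    with resources.as_file(_data_path("rules.yaml")) as path:
        return compile_rules(path, codelists)


def load_fixture_weights() -> dict[str, ScoreWeights]:
    """The synthetic fixture score weights (general, mortality, hospital)."""
    with resources.as_file(_data_path("weights_fixture.csv")) as path:
        return load_weights(path)


def load_fixture_lookup() -> pd.DataFrame:
    """Read2 -> CTV3 fixture lookup table."""
    with resources.as_file(_data_path("lookup_read2_ctv3.csv")) as path:
        return pd.read_csv(path, dtype=str)


def load_fixture_overrides() -> pd.DataFrame:
    """Manual-override fixture table for the Read2 -> CTV3 mapping."""
    with resources.as_file(_data_path("overrides_read2_ctv3.csv")) as path:
        return pd.read_csv(path, dtype=str)
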