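"""Bundled worked-example inputs.

A small published-style table of pathogenic / likely pathogenic (P/LP)
findings from a young sudden-death cohort, with the epilepsy and
cardiomyopathy/arrhythmia panel memberships needed to reproduce its
per-decedent summary, plus the cohort-level accounting numbers of the
same study (enrollment, exclusions, demographics).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .datatypes import CohortManifest, GenePanel

__all__ = [
    "load_plp_example",
    "example_panels",
    "example_enrollment_manifest",
]


def load_plp_example() -> pd.DataFrame:
    """The worked-example variant table (canonical TSV dialect)."""
    with resources.files("sdyburden.data").joinpath(
        "plp_worked_example.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"sample_id": str})


def example_panels() -> list[GenePanel]:
    """Minimal epilepsy and cardiac panels covering the example genes."""
    epilepsy = GenePanel(
        name="epilepsy",
        genes=frozenset({"QARS", "CLN8", "PPT1", "CSTB", "KCNH2", "SCN1A"}),
    )
    cmar1 = GenePanel(
        name="cmar1",
        genes=frozenset({"FKRP", "TTR", "CALM3", "DSP", "KCNH2", "MYH7"}),
    )
    return [epilepsy, cmar1]


def example_enrollment_manifest(
    n_enrolled: int = 230,
    n_failed_inclusion: int = 4,
    n_failed_sequencing: int = 15,
    n_detailed_phenotype: int = 152,
    n_male_detailed: int = 93,
    n_male_not_detailed: int = 36,
) -> CohortManifest:
    """Enrollment manifest reproducing the study's cohort accounting.

    Defaults encode the published flow: 230 decedents enrolled, 4
    excluded for failed inclusion criteria and 15 for failed sequencing
    (211 retained), 152 retained cases with detailed phenotype data, and
    93 + 36 genetic males among the detailed / not-detailed strata.
    """
    n_retained = n_enrolled - n_failed_inclusion - n_failed_sequencing
    rows = []
    reasons = (
        ["failed_inclusion"] * n_failed_inclusion
        + ["failed_sequencing"] * n_failed_sequencing
        + [""] * n_retained
    )
    # demographics only matter for retained samples; lay them out
    # deterministically across the retained block
    detail = [True] * n_detailed_phenotype + [False] * (n_retained - n_detailed_phenotype)
    males = [True] * n_male_detailed + [False] * (
        n_detailed_phenotype - n_male_detailed
    )
    males += [True] * n_male_not_detailed + [False] * (
        (n_retained - n_detailed_phenotype) - n_male_not_detailed
    )
    retained_iter = iter(zip(detail, males))
    for i, reason in enumerate(reasons):
        if reason:
            has_detail, is_male = False, False
        else:
            has_detail, is_male = next(retained_iter)
        rows.append(
            {
                "sample_id": f"SDY{i:04d}",
                "arm": "case",
                "sex": "male" if is_male else "female",
                "cause_category": "unexplained" if has_detail else "unavailable",
                "age_at_death": np.nan,
                "exclusion_reasons": reason,
            }
        )
    return CohortManifest(pd.DataFrame(rows))
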