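"""Shared fixtures: one fitted default cohort reused across test modules."""

import numpy as np
import pytest

from mced_cascade import (CohortSpec, fit_crs, fit_poc, generate_cohort,
                          score_crs, score_poc)


@pytest.fixture(scope="session")
def default_cohort():
    """Default-spec synthetic cohort, seed 1 (617 cancer / 580 noncancer)."""
    return generate_cohort(CohortSpec(), seed=1)


@pytest.fixture(scope="session")
def fitted(default_cohort):
    """POC + CRS models fitted on the default cohort, with their scores."""
    records = default_cohort
    poc_model = fit_poc(records)
    poc = score_poc(poc_model, records)
    crs_model = fit_crs(records, poc)
    crs = score_crs(crs_model, records, poc)
    y = (records["group"] == "cancer").to_numpy()
    return {
        "records": records, "y": y,
        "poc_model": poc_model, "poc": np.asarray(poc),
        "crs_model": crs_model, "crs": np.asarray(crs),
    }
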