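import numpy as np
import pandas as pd
import pytest

from psilc.cohort_io import CLINICAL_COLUMNS, ExpressionCohort


def make_cohort(
    values,
    genes=None,
    samples=None,
    time=None,
    event=None,
    cohort_id="toy",
    is_normal=None,
    standardized=False,
    **clinical_overrides,
):
    """Assemble an ExpressionCohort from plain arrays."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = genes or [f"g{i+1}" for i in range(n_genes)]
    samples = samples or [f"s{i+1}" for i in range(n_samples)]
    clin = pd.DataFrame(index=pd.Index(samples), columns=CLINICAL_COLUMNS,
                        dtype=object)
    clin["time"] = time if time is not None else np.nan
    clin["event"] = event if event is not None else np.nan
    clin["endpoint"] = "OS"
    clin["age"] = 60.0
    clin["t_stage"] = "T1"
    clin["nodal"] = 0
    clin["purity"] = 0.7
    clin["chemo"] = np.nan
    clin["tnbc_or_her2"] = 0
    clin["is_normal"] = is_normal if is_normal is not None else False
    for key, val in clinical_overrides.items():
        clin[key] = val
    return ExpressionCohort(
        cohort_id,
        pd.DataFrame(values, index=genes, columns=samples),
        clin,
        standardized=standardized,
    )


@pytest.fixture
def gaussian_pair():
    """Tumour/normal cohorts of pure noise with matched genes."""

    def _build(n_genes=200, n_tumour=50, n_normal=50, sd=0.5, seed=0):
        rng = np.random.default_rng(seed)
        t = make_cohort(rng.normal(7.0, sd, (n_genes, n_tumour)), cohort_id="tumour")
        n = make_cohort(
            rng.normal(7.0, sd, (n_genes, n_normal)),
            genes=list(t.genes),
            samples=[f"n{i}" for i in range(n_normal)],
            cohort_id="normal",
        )
        return t, n

    return _build
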