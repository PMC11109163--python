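import numpy as np
import pandas as pd
import pytest

from utr3qtl import synthdata, variant_pipeline as vp


@pytest.fixture(scope="session")
def small_config():
    return synthdata.SimulationConfig(
        n_tumors=60, n_normals=8, n_genes=40, n_variants=120, seed=11
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return synthdata.generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    matrix = vp.merge_caller_calls(
        small_cohort.tumor_calls, small_cohort.genotyper_calls
    )
    filtered, _ = vp.apply_filters(matrix, small_cohort.tumor_calls)
    return filtered


def call_row(sample, chrom, pos, ref, alt, gt, dp=30, ad_alt=10, flt="PASS",
             caller="tumor-caller"):
    return {
        "sample_id": sample, "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
        "gt": gt, "dp": dp, "ad_ref": dp - ad_alt, "ad_alt": ad_alt,
        "filter": flt, "caller": caller,
    }


@pytest.fixture
def make_calls():
    def _make(rows):
        return pd.DataFrame([call_row(*r[:6], **(r[6] if len(r) > 6 else {}))
                             for r in rows])

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(0)
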