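import numpy as np
import pandas as pd
import pytest

from concordmut import CohortConfig, analyze_cohort, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default 27-pair synthetic cohort, fixed seed."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def default_analysis(default_cohort):
    """Full pipeline results on the default cohort."""
    return analyze_cohort(default_cohort)


@pytest.fixture(scope="session")
def tiny_config():
    """A small, fast cohort configuration for IO/CLI tests."""
    return CohortConfig(
        n_pairs=4,
        n_genes=120,
        n_pathways=6,
        genes_per_pathway=8,
        n_dereg_pathways=2,
        somatic_rate_dna=20.0,
        noncoding_ratio=2.0,
        germline_rate=20.0,
        rna_only_rate=30.0,
        driver_recurrence=(2, 2, 2, 2, 0, 0, 0, 0, 0, 0),
        frac_highrisk=0.5,
        seed=7,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def random_site_table(rng, n=200, sample="S1"):
    """A random paired site table with valid structure (helper, not a fixture)."""
    pos = rng.choice(np.arange(1, 10 * n), size=n, replace=False)
    ref = np.array(list("ACGT"))[pos % 4]
    alt = np.array(list("ACGT"))[(pos % 4 + 1 + pos % 3) % 4]
    dn = rng.integers(0, 61, n)
    dt = rng.integers(0, 61, n)
    an = rng.binomial(dn, rng.uniform(0, 0.6, n))
    at = rng.binomial(dt, rng.uniform(0, 0.6, n))
    return pd.DataFrame(
        {
            "sample": sample,
            "chrom": "1",
            "pos": np.sort(pos),
            "ref": ref,
            "alt": alt,
            "normal_ref": dn - an,
            "normal_alt": an,
            "tumor_ref": dt - at,
            "tumor_alt": at,
            "gene": [f"G{p % 50:03d}" for p in np.sort(pos)],
            "func_class": rng.choice(
                ["nonsynonymous", "synonymous", "stopgain", "other"], n
            ),
        }
    )
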