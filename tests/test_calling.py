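"""Somatic classification: allele frequencies, Fisher exact test, call logic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from concordmut import (
    AlleleDepth,
    CallingParams,
    CallStatus,
    SiteKey,
    call_somatic,
    classify_site,
    classify_table,
    fisher_somatic_pvalue,
    snv_agreement,
    variant_allele_frequency,
)
from tests._oracles import fisher_one_sided_bruteforce

SITE = SiteKey("1", 100, "A", "G")


class TestVariantAlleleFrequency:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [(10, 0, 0.0), (5, 5, 0.5), (92, 8, 0.08), (0, 7, 1.0)],
    )
    def test_values(self, ref, alt, expected):
        assert variant_allele_frequency(AlleleDepth(ref, alt)) == pytest.approx(expected)

    def test_zero_depth_undefined(self):
        with pytest.raises(ValueError, match="zero depth"):
            variant_allele_frequency(AlleleDepth(0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            AlleleDepth(-1, 3)


class TestFisherSomaticPvalue:
    @pytest.mark.parametrize(
        "normal,tumor,expected",
        [
            # identical tables: the tail carries all the mass
            ((10, 0), (10, 0), 1.0),
            # all 8 alts in the tumor: 1 / C(16, 8)
            ((8, 0), (0, 8), 7.77000777000777e-05),
            # pinned by brute-force tail enumeration before implementation
            ((20, 0), (12, 8), 0.001638001638001638),
            ((30, 0), (12, 8), 2.346340276336189e-04),
            ((30, 0), (17, 3), 0.058163265306122446),
        ],
    )
    def test_pinned_values(self, normal, tumor, expected):
        p = fisher_somatic_pvalue(AlleleDepth(*normal), AlleleDepth(*tumor))
        assert p == pytest.approx(expected, abs=1e-12)

    def test_zero_depth_error(self):
        with pytest.raises(ValueError, match="positive depth"):
            fisher_somatic_pvalue(AlleleDepth(0, 0), AlleleDepth(5, 5))

    @given(
        dn=st.integers(1, 40),
        dt=st.integers(1, 40),
        data=st.data(),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_bruteforce(self, dn, dt, data):
        """Random tables agree with an explicit log-factorial tail sum."""
        an = data.draw(st.integers(0, dn))
        at = data.draw(st.integers(0, dt))
        p = fisher_somatic_pvalue(AlleleDepth(dn - an, an), AlleleDepth(dt - at, at))
        assert p == pytest.approx(fisher_one_sided_bruteforce(dn - an, an, dt - at, at), abs=1e-10)

    def test_monotone_in_tumor_alt(self):
        """For fixed margins, p never increases as tumor alt count grows."""
        for dn, an, dt in [(30, 0, 20), (25, 3, 40), (8, 1, 6)]:
            ps = [
                fisher_somatic_pvalue(AlleleDepth(dn - an, an), AlleleDepth(dt - at, at))
                for at in range(dt + 1)
            ]
            assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))


class TestClassifySite:
    def test_low_normal_coverage(self):
        call = classify_site(SITE, AlleleDepth(7, 0), AlleleDepth(20, 10))
        assert call.status is CallStatus.INSUFFICIENT_COVERAGE

    def test_low_tumor_coverage(self):
        call = classify_site(SITE, AlleleDepth(30, 0), AlleleDepth(3, 2))
        assert call.status is CallStatus.INSUFFICIENT_COVERAGE

    def test_somatic_forced_by_pinned_p(self):
        # Fisher p = 2.35e-4 < 0.05 with a clean normal and tumor af 0.4
        call = classify_site(SITE, AlleleDepth(30, 0), AlleleDepth(12, 8))
        assert call.status is CallStatus.SOMATIC
        assert call.somatic_p == pytest.approx(2.346340276336189e-04, abs=1e-12)
        assert call.tumor_af == pytest.approx(0.4)

    def test_subthreshold_is_reference(self):
        # same table pinned at p = 0.058 >= 0.05
        call = classify_site(SITE, AlleleDepth(30, 0), AlleleDepth(17, 3))
        assert call.status is CallStatus.REFERENCE

    def test_germline(self):
        call = classify_site(SITE, AlleleDepth(15, 14), AlleleDepth(10, 10))
        assert call.status is CallStatus.GERMLINE

    def test_loh_toward_reference(self):
        call = classify_site(SITE, AlleleDepth(20, 20), AlleleDepth(40, 0))
        assert call.status is CallStatus.LOH

    def test_p_threshold_is_strict(self):
        params = CallingParams(p_somatic=2.346340276336189e-04)
        call = classify_site(SITE, AlleleDepth(30, 0), AlleleDepth(12, 8), params)
        assert call.status is not CallStatus.SOMATIC

    def test_vectorized_matches_scalar(self, rng):
        from tests.conftest import random_site_table

        table = random_site_table(rng, n=400)
        out = classify_table(table)
        for row, status in zip(table.itertuples(index=False), out["status"]):
            site = SiteKey(row.chrom, int(row.pos), row.ref, row.alt)
            ref_call = classify_site(
                site,
                AlleleDepth(int(row.normal_ref), int(row.normal_alt)),
                AlleleDepth(int(row.tumor_ref), int(row.tumor_alt)),
            )
            assert ref_call.status.value == status


class TestCallSomatic:
    def test_empty_table(self):
        empty = pd.DataFrame(
            columns=["chrom", "pos", "ref", "alt", "normal_ref", "normal_alt",
                     "tumor_ref", "tumor_alt", "gene", "func_class"]
        )
        assert len(call_somatic(empty)) == 0

    def test_no_tumor_variant_no_calls(self, rng):
        from tests.conftest import random_site_table

        table = random_site_table(rng, n=100)
        table["tumor_alt"] = 0
        table["tumor_ref"] = 50
        assert len(call_somatic(table)) == 0

    def test_planted_clonal_sites_all_recovered(self):
        n = 50
        pos = np.arange(1, n + 1) * 10
        table = pd.DataFrame(
            {
                "sample": "S1", "chrom": "1", "pos": pos,
                "ref": "A", "alt": "G",
                "normal_ref": 60, "normal_alt": 0,
                "tumor_ref": 36, "tumor_alt": 24,  # af 0.4 at depth 60
                "gene": "G1", "func_class": "nonsynonymous",
            }
        )
        calls = call_somatic(table)
        assert len(calls) == n
        assert (calls["status"] == "Somatic").all()
        assert list(calls["pos"]) == sorted(calls["pos"])

    def test_duplicate_rows_rejected(self):
        table = pd.DataFrame(
            {
                "sample": ["S1", "S1"], "chrom": "1", "pos": [5, 5],
                "ref": "A", "alt": "G",
                "normal_ref": 30, "normal_alt": 0,
                "tumor_ref": 20, "tumor_alt": 10,
                "gene": "G1", "func_class": "nonsynonymous",
            }
        )
        with pytest.raises(ValueError, match="duplicate"):
            call_somatic(table)

    def test_row_order_invariance(self, rng):
        from tests.conftest import random_site_table

        table = random_site_table(rng, n=300)
        shuffled = table.sample(frac=1, random_state=0)
        a = call_somatic(table)
        b = call_somatic(shuffled)
        pd.testing.assert_frame_equal(
            a.reset_index(drop=True), b.reset_index(drop=True)
        )


class TestSnvAgreement:
    def test_disjoint(self):
        n, frac = snv_agreement({("1", 1): "A"}, {("1", 2): "C"})
        assert n == 0 and np.isnan(frac)

    def test_identical(self):
        calls = {("1", i): "G" for i in range(100)}
        assert snv_agreement(calls, dict(calls)) == (100, 1.0)

    def test_one_discordant_of_thousand(self):
        a = {("1", i): "G" for i in range(1000)}
        b = dict(a)
        b[("1", 0)] = "T"
        n, frac = snv_agreement(a, b)
        assert n == 1000 and frac == pytest.approx(0.999)
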