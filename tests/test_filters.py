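import numpy as np
import pandas as pd
import pytest

from conftest import random_callset
from mosaicall.filters import (
    FILTER_NAMES,
    DataIntegrityError,
    FilterConfig,
    apply_filters,
    merge_callsets,
    near_indel,
    pooled_vaf,
)


def _pileups_for(calls, n_extra_samples=0, alt_frac=0.0):
    """Minimal pileup table backing a call table: one row per call plus
    optional clean extra samples (keeps pooled VAF low)."""
    rows = []
    for _, c in calls.iterrows():
        rows.append(
            dict(site_id=c.site_id, chrom=c.chrom, pos=c.pos, ref=c.ref, alt=c.alt,
                 sample_id=c.sample_id, depth_fwd=c.depth // 2,
                 depth_rev=c.depth - c.depth // 2, alt_fwd=c.alt_fwd, alt_rev=c.alt_rev)
        )
        for k in range(n_extra_samples):
            d = 1000
            a = int(alt_frac * d)
            rows.append(
                dict(site_id=c.site_id, chrom=c.chrom, pos=c.pos, ref=c.ref, alt=c.alt,
                     sample_id=f"extra{k}", depth_fwd=d // 2, depth_rev=d - d // 2,
                     alt_fwd=a // 2, alt_rev=a - a // 2)
            )
    return pd.DataFrame(rows).drop_duplicates(["site_id", "sample_id"])


class TestPooledVaf:
    def _pil(self, counts):
        return pd.DataFrame(
            [
                dict(site_id="S1", chrom="chr1", pos=100, ref="A", alt="T",
                     sample_id=f"s{i}", depth_fwd=n // 2, depth_rev=n - n // 2,
                     alt_fwd=x // 2, alt_rev=x - x // 2)
                for i, (x, n) in enumerate(counts)
            ]
        )

    def test_half_everywhere(self):
        assert pooled_vaf(self._pil([(50, 100)] * 4), "S1") == 0.5

    def test_zero_alt(self):
        assert pooled_vaf(self._pil([(0, 100)] * 3), "S1") == 0.0

    def test_arithmetic(self):
        assert pooled_vaf(self._pil([(10, 100), (0, 300)]), "S1") == pytest.approx(0.025)

    def test_zero_depth(self):
        assert pooled_vaf(self._pil([(0, 0)]), "S1") == 0.0

    def test_unknown_site(self):
        with pytest.raises(KeyError):
            pooled_vaf(self._pil([(1, 10)]), "NOPE")


class TestNearIndel:
    def test_boundary_inclusive(self):
        assert near_indel(100, [110], 10) is True

    def test_just_outside(self):
        assert near_indel(100, [111], 10) is False

    def test_empty_list(self):
        assert near_indel(100, [], 10) is False

    def test_below(self):
        assert near_indel(100, [90, 300], 10) is True
        assert near_indel(100, [89, 300], 10) is False


def _clean_call(**kw):
    base = dict(site_id="S1", chrom="chr1", pos=500, ref="A", alt="T",
                sample_id="s1", vaf=0.05, alt_reads=50, depth=1000,
                alt_fwd=25, alt_rev=25, q=0.001)
    base.update(kw)
    return pd.DataFrame([base])


class TestApplyFilters:
    def _run(self, calls, **kw):
        pil = _pileups_for(calls, n_extra_samples=3)
        return apply_filters(calls, pil, FilterConfig(), **kw)

    def test_low_coverage_flag(self):
        out = self._run(_clean_call(depth=40, alt_reads=4, alt_fwd=2, alt_rev=2, vaf=0.1))
        assert out.filter_flags[0] == "low_coverage"
        assert not out.retained[0]

    def test_high_vaf_flag(self):
        out = self._run(_clean_call(vaf=0.40, alt_reads=400, alt_fwd=200, alt_rev=200))
        assert "high_vaf" in out.filter_flags[0]
        assert not out.retained[0]

    def test_few_alt_reads_flag(self):
        out = self._run(_clean_call(alt_reads=3, alt_fwd=2, alt_rev=1, vaf=0.003))
        assert "few_alt_reads" in out.filter_flags[0]

    def test_low_vaf_flag(self):
        out = self._run(_clean_call(vaf=0.002, alt_reads=4, alt_fwd=2, alt_rev=2, depth=2000))
        assert "low_vaf" in out.filter_flags[0]

    def test_strand_flag(self):
        out = self._run(_clean_call(alt_fwd=50, alt_rev=0))
        assert "strand" in out.filter_flags[0]

    def test_fdr_flag(self):
        out = self._run(_clean_call(q=0.02))
        assert out.filter_flags[0] == "fdr"

    def test_clean_call_retained_unchanged(self):
        calls = _clean_call()
        out = self._run(calls)
        assert out.filter_flags[0] == ""
        assert out.retained[0]
        pd.testing.assert_frame_equal(out[calls.columns], calls)

    def test_germline_flag_cohort_pooled(self):
        calls = _clean_call(vaf=0.3, alt_reads=300, alt_fwd=150, alt_rev=150)
        pil = _pileups_for(calls, n_extra_samples=3, alt_frac=0.3)
        out = apply_filters(calls, pil, FilterConfig())
        assert "germline" in out.filter_flags[0]

    def test_near_indel_flag(self):
        calls = _clean_call(pos=500)
        pil = _pileups_for(calls, n_extra_samples=2)
        indels = pd.DataFrame({"chrom": ["chr1"], "pos": [505]})
        out = apply_filters(calls, pil, FilterConfig(), indel_sites=indels)
        assert "near_indel" in out.filter_flags[0]

    def test_population_af_flag_and_missing_entry(self):
        calls = pd.concat([_clean_call(), _clean_call(pos=600, site_id="S1")],
                          ignore_index=True)
        calls.loc[1, "site_id"] = "S1"
        pil = _pileups_for(calls, n_extra_samples=2)
        pop = pd.DataFrame({"chrom": ["chr1"], "pos": [500], "ref": ["A"],
                            "alt": ["T"], "af": [0.05]})
        out = apply_filters(calls, pil, FilterConfig(), pop_af=pop)
        assert "common_population_allele" in out.filter_flags[0]
        assert "common_population_allele" not in out.filter_flags[1]  # missing -> AF 0

    def test_unknown_site_raises(self):
        calls = _clean_call()
        pil = _pileups_for(calls).assign(site_id="OTHER")
        with pytest.raises(KeyError):
            apply_filters(calls, pil, FilterConfig())

    def test_matches_bruteforce_conjunction(self, rng):
        calls = random_callset(rng, n=60)
        pil = _pileups_for(calls, n_extra_samples=1)
        indels = pd.DataFrame({"chrom": ["chr1", "chr2"], "pos": [1000, 2500]})
        pop = calls.sample(10, random_state=1)[["chrom", "pos", "ref", "alt"]].copy()
        pop["af"] = 0.5
        pop = pop.drop_duplicates(["chrom", "pos", "ref", "alt"])
        cfg = FilterConfig()
        out = apply_filters(calls, pil, cfg, pop_af=pop, indel_sites=indels)

        pooled = {}
        for sid in calls.site_id.unique():
            pooled[sid] = pooled_vaf(pil, sid)
        af_key = set(zip(pop.chrom, pop.pos, pop.ref, pop.alt))
        for i, c in calls.iterrows():
            expected = set()
            if pooled[c.site_id] > cfg.germline_pooled_vaf_max:
                expected.add("germline")
            if c.depth < cfg.min_coverage:
                expected.add("low_coverage")
            if c.vaf > cfg.max_vaf:
                expected.add("high_vaf")
            if c.vaf < cfg.min_vaf:
                expected.add("low_vaf")
            if c.alt_reads < cfg.min_alt_reads:
                expected.add("few_alt_reads")
            if c.alt_fwd < 1 or c.alt_rev < 1:
                expected.add("strand")
            ind = [1000] if c.chrom == "chr1" else [2500]
            if near_indel(c.pos, ind, cfg.indel_window):
                expected.add("near_indel")
            if (c.chrom, c.pos, c.ref, c.alt) in af_key:
                expected.add("common_population_allele")
            if c.q > cfg.q_max:
                expected.add("fdr")
            got = set(out.filter_flags[i].split(";")) - {""}
            assert got == expected, f"row {i}"
            assert out.retained[i] == (not expected)

    def test_monotone_in_thresholds(self, rng):
        calls = random_callset(rng, n=50)
        pil = _pileups_for(calls, n_extra_samples=1)
        tight = FilterConfig()
        loose_variants = [
            FilterConfig(min_coverage=25),
            FilterConfig(max_vaf=0.5),
            FilterConfig(min_vaf=0.001),
            FilterConfig(min_alt_reads=2),
            FilterConfig(q_max=0.05),
            FilterConfig(germline_pooled_vaf_max=0.4),
            FilterConfig(require_both_strands=False),
            FilterConfig(indel_window=0),
        ]
        base = apply_filters(calls, pil, tight)
        kept = set(base.index[base.retained])
        for cfg in loose_variants:
            out = apply_filters(calls, pil, cfg)
            assert kept <= set(out.index[out.retained])

    def test_flag_order_independent_of_input_order(self, rng):
        calls = random_callset(rng, n=30)
        pil = _pileups_for(calls, n_extra_samples=1)
        out1 = apply_filters(calls, pil, FilterConfig())
        shuffled = calls.sample(frac=1, random_state=7)
        out2 = apply_filters(shuffled, pil, FilterConfig())
        merged = out1.merge(
            out2, on=["site_id", "sample_id", "pos", "vaf", "depth"], suffixes=("_a", "_b")
        )
        assert (merged.filter_flags_a == merged.filter_flags_b).all()


def _calls_with_keys(n, start=0):
    return pd.DataFrame(
        {
            "sample_id": [f"s{i % 7}" for i in range(start, start + n)],
            "chrom": "chr1",
            "pos": np.arange(start, start + n) * 10 + 100,
            "ref": "A",
            "alt": "T",
            "vaf": 0.05,
        }
    )


class TestMergeCallsets:
    def test_reported_union_arithmetic(self):
        a = _calls_with_keys(428)
        b = _calls_with_keys(509, start=428 - 111)  # 111 shared keys
        merged = merge_callsets(a, b)
        assert len(merged) == 826
        assert (merged.provenance == "both").sum() == 111

    def test_disjoint(self):
        a, b = _calls_with_keys(5), _calls_with_keys(7, start=100)
        assert len(merge_callsets(a, b)) == 12

    def test_identical(self):
        a = _calls_with_keys(9)
        merged = merge_callsets(a, a.copy())
        assert len(merged) == 9
        assert (merged.provenance == "both").all()

    def test_stats_kept_from_a(self):
        a = _calls_with_keys(4).assign(vaf=0.11)
        b = _calls_with_keys(4).assign(vaf=0.99)
        merged = merge_callsets(a, b)
        assert (merged.vaf == 0.11).all()

    def test_ref_conflict(self):
        a = _calls_with_keys(3)
        b = _calls_with_keys(3).assign(ref="G")
        with pytest.raises(DataIntegrityError):
            merge_callsets(a, b)

    def test_union_size_formula(self, rng):
        for _ in range(5):
            na, nb, start = rng.integers(1, 40), rng.integers(1, 40), rng.integers(0, 30)
            a, b = _calls_with_keys(na), _calls_with_keys(nb, start=start)
            ka = set(map(tuple, a[["sample_id", "pos"]].to_numpy()))
            kb = set(map(tuple, b[["sample_id", "pos"]].to_numpy()))
            assert len(merge_callsets(a, b)) == len(ka) + len(kb) - len(ka & kb)


class TestGermlineRecall:
    def test_planted_germline_flagged_and_clones_spared(self, small_cohort):
        from mosaicall.calling import call_variants

        b = small_cohort
        calls = call_variants(b.pileups, b.metadata)
        cfg = FilterConfig(germline_by_donor=True)
        out = apply_filters(calls, b.pileups, cfg, metadata=b.metadata)
        flags = out.set_index(["site_id", "sample_id"]).filter_flags

        germ_sites = set(b.truth.query("category == 'germline_het'").site_id)
        clone_keys = {
            (t.site_id, s)
            for _, t in b.truth.query("category == 'somatic_clone'").iterrows()
            for s in t.sample_ids.split(",")
        }
        germ_called = out[out.site_id.isin(germ_sites)]
        if len(germ_called):
            frac = germ_called.filter_flags.str.contains("germline").mean()
            assert frac >= 0.99
        clone_called = out[
            [k in clone_keys for k in zip(out.site_id, out.sample_id)]
        ]
        assert len(clone_called) > 0
        assert clone_called.filter_flags.str.contains("germline").mean() <= 0.01
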