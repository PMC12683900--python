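"""Locus construction and single-causal ABF colocalization."""

import numpy as np
import pandas as pd
import pytest

from chromv2g.coloc import (
    ColocPriors,
    assign_egenes,
    build_loci,
    coloc_abf,
    concordance_summary,
    wakefield_labf,
)
from chromv2g.core import SummaryStatRecord
from chromv2g.v2g import Proxy, Sentinel


def stat(vid, beta, se):
    return SummaryStatRecord(vid, "chr1", 100, "A", "G", beta, se)


def brute_force_coloc(trait_stats, eqtl_stats, priors, W1, W2):
    """Independent oracle: explicit enumeration of single-causal configurations.

    Works in Decimal arithmetic so huge Bayes factors (z-scores of 50+) stay
    representable without the log-space tricks used by the implementation.
    """
    from decimal import Decimal, getcontext

    getcontext().prec = 60
    a1 = [Decimal(wakefield_labf(s.beta, s.se, W1)).exp() for s in trait_stats]
    a2 = [Decimal(wakefield_labf(s.beta, s.se, W2)).exp() for s in eqtl_stats]
    n = len(a1)
    p1, p2, p12 = Decimal(priors.p1), Decimal(priors.p2), Decimal(priors.p12)
    h = [
        Decimal(1),
        p1 * sum(a1),
        p2 * sum(a2),
        p1 * p2 * sum(a1[i] * a2[j] for i in range(n) for j in range(n) if i != j),
        p12 * sum(a1[i] * a2[i] for i in range(n)),
    ]
    total = sum(h)
    return [float(x / total) for x in h]


class TestWakefield:
    def test_null_effect(self):
        assert wakefield_labf(0.0, 1.0, 0.0225) == pytest.approx(-0.011125, abs=1e-6)

    def test_strong_effect(self):
        assert wakefield_labf(5.0, 1.0, 0.0225) == pytest.approx(0.263936, abs=1e-6)

    def test_vanishing_prior_variance_limit(self):
        for z in (0.0, 3.0, 12.0):
            assert abs(wakefield_labf(z, 1.0, 1e-12)) < 1e-10

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            wakefield_labf(float("nan"), 1.0, 0.04)
        with pytest.raises(ValueError):
            wakefield_labf(1.0, 0.0, 0.04)


class TestColocAbf:
    def test_single_snp_has_zero_h3(self):
        res = coloc_abf([stat("s1", 0.5, 0.1)], [stat("s1", 0.3, 0.1)])
        assert res.pp["PP.H3"] == 0.0
        assert sum(res.pp.values()) == pytest.approx(1.0, abs=1e-9)

    def test_all_null_betas_favour_h0(self):
        t = [stat(f"s{i}", 0.0, 1.0) for i in range(3)]
        e = [stat(f"s{i}", 0.0, 1.0) for i in range(3)]
        res = coloc_abf(t, e)
        assert res.pp["PP.H0"] > 0.999

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 6))
        priors = ColocPriors()
        t = [stat(f"s{i}", float(rng.normal(0, 0.5)), float(rng.uniform(0.02, 0.4))) for i in range(n)]
        e = [stat(f"s{i}", float(rng.normal(0, 0.5)), float(rng.uniform(0.02, 0.4))) for i in range(n)]
        res = coloc_abf(t, e, priors)
        oracle = brute_force_coloc(t, e, priors, priors.W_cc, priors.W_quant)
        got = [res.pp[k] for k in ("PP.H0", "PP.H1", "PP.H2", "PP.H3", "PP.H4")]
        assert np.allclose(got, oracle, atol=1e-10)
        assert sum(res.per_snp_pp_h4.values()) == pytest.approx(1.0, abs=1e-9)

    def test_snp_order_irrelevant(self):
        rng = np.random.default_rng(7)
        t = [stat(f"s{i}", float(rng.normal()), 0.1) for i in range(6)]
        e = [stat(f"s{i}", float(rng.normal()), 0.1) for i in range(6)]
        res1 = coloc_abf(t, e)
        res2 = coloc_abf(t[::-1], e[::-1])
        for k in res1.pp:
            assert res1.pp[k] == pytest.approx(res2.pp[k], abs=1e-12)

    def test_unit_rescaling_with_matching_prior_is_invariant(self):
        # the ABF depends on (z, V/W): rescaling one study's effect scale is
        # exactly neutral when its prior effect variance rescales with it
        rng = np.random.default_rng(8)
        t = [stat(f"s{i}", float(rng.normal()), 0.1) for i in range(5)]
        e = [stat(f"s{i}", float(rng.normal()), 0.1) for i in range(5)]
        c = 3.0
        scaled = [stat(s.variant_id, c * s.beta, c * s.se) for s in t]
        p1 = ColocPriors()
        p2 = ColocPriors(W_cc=p1.W_cc * c * c)
        res1 = coloc_abf(t, e, p1, trait_type="cc")
        res2 = coloc_abf(scaled, e, p2, trait_type="cc")
        for k in res1.pp:
            assert res1.pp[k] == pytest.approx(res2.pp[k], rel=1e-9)

    def test_no_shared_variants_errors(self):
        with pytest.raises(ValueError, match="shared"):
            coloc_abf([stat("a", 0.1, 0.1)], [stat("b", 0.1, 0.1)])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicated"):
            coloc_abf([stat("a", 0.1, 0.1), stat("a", 0.2, 0.1)], [stat("a", 0.1, 0.1)])


def _sentinel(vid, chrom, pos, trait="MS"):
    return Sentinel(trait, vid, chrom, pos)


def _proxy_block(sent, lo, hi, n=5):
    step = max(1, (hi - lo) // max(1, n - 1))
    return [
        Proxy(f"{sent.variant_id}_p{i}", sent.chrom, lo + i * step, 0.9, sent)
        for i in range(n)
    ]


class TestBuildLoci:
    def test_single_sentinel_extends_by_flank(self):
        s = _sentinel("rs1", "chr1", 1_000_000)
        proxies = [
            Proxy("p1", "chr1", 990_000, 0.9, s),
            Proxy("p2", "chr1", 1_010_000, 0.9, s),
        ]
        (locus,) = build_loci([s], proxies, flank=250_000)
        assert (locus.interval.start, locus.interval.end) == (739_999, 1_260_000)

    def test_high_ld_sentinels_merge(self):
        s1 = _sentinel("rs1", "chr1", 1_000_000)
        s2 = _sentinel("rs2", "chr1", 1_300_000)
        proxies = _proxy_block(s1, 990_000, 1_010_000) + _proxy_block(s2, 1_290_000, 1_310_000)
        loci = build_loci([s1, s2], proxies, ld_r2={frozenset({"rs1", "rs2"}): 0.9})
        assert len(loci) == 1
        assert loci[0].member_sentinels == frozenset({"rs1", "rs2"})

    def test_low_ld_sentinels_split_at_midpoint(self):
        s1 = _sentinel("rs1", "chr1", 1_000_000)
        s2 = _sentinel("rs2", "chr1", 1_300_000)
        proxies = _proxy_block(s1, 990_000, 1_010_000) + _proxy_block(s2, 1_290_000, 1_310_000)
        loci = build_loci([s1, s2], proxies, ld_r2={frozenset({"rs1", "rs2"}): 0.3})
        assert len(loci) == 2
        a, b = sorted(loci, key=lambda l: l.interval.start)
        # midpoint between span end (1_010_000) and next span start (1_289_999)
        assert a.interval.end == b.interval.start == (1_010_000 + 1_289_999) // 2
        assert a.member_sentinels == frozenset({"rs1"})

    def test_missing_ld_for_coresident_sentinels_errors(self):
        s1 = _sentinel("rs1", "chr1", 1_000_000)
        s2 = _sentinel("rs2", "chr1", 1_100_000)
        proxies = _proxy_block(s1, 990_000, 1_010_000) + _proxy_block(s2, 1_090_000, 1_110_000)
        with pytest.raises(KeyError, match="rs1"):
            build_loci([s1, s2], proxies, ld_r2={})

    @pytest.mark.parametrize("seed", range(30))
    def test_random_configurations_non_overlapping_and_stable(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 8))
        sentinels, proxies = [], []
        ld = {}
        for i in range(n):
            pos = int(rng.integers(300_000, 20_000_000))
            s = _sentinel(f"rs{i}", "chr1", pos)
            sentinels.append(s)
            lo = pos - int(rng.integers(1_000, 60_000))
            hi = pos + int(rng.integers(1_000, 60_000))
            proxies += _proxy_block(s, lo, hi, n=int(rng.integers(2, 8)))
        for i in range(n):
            for j in range(i + 1, n):
                ld[frozenset({f"rs{i}", f"rs{j}"})] = float(rng.choice([0.1, 0.9]))
        loci = build_loci(sentinels, proxies, ld_r2=ld)
        ordered = sorted(loci, key=lambda l: l.interval.start)
        for a, b in zip(ordered, ordered[1:]):
            assert a.interval.end <= b.interval.start
        # determinism / idempotence: identical inputs give identical loci
        again = build_loci(sentinels, proxies, ld_r2=ld)
        assert [(l.interval.start, l.interval.end, l.member_sentinels) for l in again] == [
            (l.interval.start, l.interval.end, l.member_sentinels) for l in loci
        ]
        # every sentinel lands in exactly one locus
        assigned = [sid for l in loci for sid in l.member_sentinels]
        assert sorted(assigned) == sorted(s.variant_id for s in sentinels)


class TestAssignEgenes:
    def _locus(self):
        from chromv2g.coloc import Locus
        from chromv2g.core import GenomicInterval

        return Locus("locus_1", "chr1", GenomicInterval("chr1", 900_000, 1_100_000),
                     frozenset({"rs1"}))

    def _eqtl(self, rows):
        return pd.DataFrame(
            rows,
            columns=["variant_id", "chrom", "pos", "gene_id", "gene_chrom",
                     "beta", "se", "fdr", "cell_type", "dataset"],
        )

    def test_variant_outside_all_loci_excluded(self):
        eqtl = self._eqtl([("v1", "chr1", 2_000_000, "G1", "chr1", 0.3, 0.05, 0.01, "t", "d")])
        out = assign_egenes([self._locus()], eqtl, proxies=None, require_high_ld_variant=False)
        assert out.empty

    def test_trans_gene_excluded_same_chrom_rule(self):
        eqtl = self._eqtl([("v1", "chr1", 1_000_000, "G1", "chr2", 0.3, 0.05, 0.01, "t", "d")])
        out = assign_egenes([self._locus()], eqtl, proxies=None, require_high_ld_variant=False)
        assert out.empty

    def test_significant_proxy_variant_included(self):
        s = Sentinel("MS", "rs1", "chr1", 1_000_000)
        proxies = [Proxy("v1", "chr1", 1_000_500, 0.9, s)]
        eqtl = self._eqtl([
            ("v1", "chr1", 1_000_500, "G1", "chr1", 0.3, 0.05, 0.01, "t", "d"),
            ("v_other", "chr1", 1_000_600, "G2", "chr1", 0.3, 0.05, 0.01, "t", "d"),  # not a proxy
            ("v1", "chr1", 1_000_500, "G3", "chr1", 0.3, 0.05, 0.5, "t", "d"),  # fails FDR
        ])
        out = assign_egenes([self._locus()], eqtl, proxies=proxies)
        assert set(out["gene_id"]) == {"G1"}


class TestConcordance:
    def test_disjoint_sets(self):
        out = concordance_summary({"a"}, {"b"})
        assert out["n_common"] == 0 and out["pct_of_egenes"] == 0 and out["pct_of_v2g"] == 0

    def test_nested_sets_directional_percentages(self):
        v2g = {f"g{i}" for i in range(200)}
        egenes = {f"g{i}" for i in range(50)}
        out = concordance_summary(v2g, egenes)
        assert out["pct_of_egenes"] == pytest.approx(100.0)
        assert out["pct_of_v2g"] == pytest.approx(25.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_set_intersection_oracle(self, seed):
        rng = np.random.default_rng(seed)
        v2g = {f"g{i}" for i in rng.choice(100, 40, replace=False)}
        egenes = {f"g{i}" for i in rng.choice(100, 30, replace=False)}
        out = concordance_summary(v2g, egenes)
        common = len(v2g & egenes)
        assert out["n_common"] == common
        assert out["pct_of_egenes"] == pytest.approx(100 * common / 30)
        assert out["pct_of_v2g"] == pytest.approx(100 * common / 40)
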