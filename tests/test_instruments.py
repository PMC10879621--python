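"""Instrument selection: F statistics, greedy LD clumping, cis-eQTL rules."""

import numpy as np
import pytest

from mrmediation import (NoInstrumentsError, SelectionConfig, SnpLookupError,
                         compute_f_stat, ld_clump, select_cis_eqtls,
                         select_instruments)
from mrmediation.sumstats import LDMatrix

from conftest import sumstats_frame


def ld_from(ids, r2):
    return LDMatrix(tuple(ids), np.asarray(r2, float))


def brute_force_greedy(df, ld, r2_threshold, window_bp):
    """Literal re-statement of the greedy rule, used as the oracle."""
    idx = {s: i for i, s in enumerate(ld.snp_ids)}
    remaining = df.sort_values(["pval", "pos", "snp_id"], kind="mergesort")
    remaining = list(remaining.itertuples())
    kept = []
    while remaining:
        head = remaining.pop(0)
        kept.append(head.snp_id)
        survivors = []
        for o in remaining:
            close = (window_bp is None) or (
                o.chrom == head.chrom and abs(o.pos - head.pos) <= window_bp)
            if close and ld.r2[idx[head.snp_id], idx[o.snp_id]] >= r2_threshold:
                continue
            survivors.append(o)
        remaining = survivors
    return [s for s in df["snp_id"] if s in set(kept)]


class TestFStat:
    def test_wald_square(self):
        assert compute_f_stat(0.1, 0.01) == pytest.approx(100.0)
        assert compute_f_stat(0.0, 0.5) == 0.0

    def test_marginal_snp_fails_default_threshold(self):
        f = compute_f_stat(0.05, 0.016)
        assert f == pytest.approx(9.765625)
        assert f < SelectionConfig().f_min

    def test_r2_variant_requires_frequency_and_n(self):
        f = compute_f_stat(0.1, 0.01, eaf=0.3, n=10_000, method="r2")
        r2 = 2 * 0.3 * 0.7 * 0.1**2
        assert f == pytest.approx((10_000 - 2) * r2 / (1 - r2))
        with pytest.raises(ValueError):
            compute_f_stat(0.1, 0.01, method="r2")


class TestLDClump:
    def test_linked_pair_keeps_lowest_p(self):
        df = sumstats_frame([
            {"snp_id": "rs1", "pos": 100_000, "pval": 1e-8},
            {"snp_id": "rs2", "pos": 110_000, "pval": 1e-6},
        ])
        ld = ld_from(["rs1", "rs2"], [[1, 0.5], [0.5, 1]])
        kept = ld_clump(df, ld, SelectionConfig())
        assert list(kept["snp_id"]) == ["rs1"]

    def test_pair_outside_window_both_kept(self):
        df = sumstats_frame([
            {"snp_id": "rs1", "pos": 100_000, "pval": 1e-8},
            {"snp_id": "rs2", "pos": 150_000, "pval": 1e-6},
        ])
        ld = ld_from(["rs1", "rs2"], [[1, 0.5], [0.5, 1]])
        kept = ld_clump(df, ld, SelectionConfig())
        assert list(kept["snp_id"]) == ["rs1", "rs2"]

    def test_missing_snp_in_ld_raises(self):
        df = sumstats_frame([{"snp_id": "rs1"}, {"snp_id": "rsX"}])
        ld = ld_from(["rs1"], [[1.0]])
        with pytest.raises(SnpLookupError, match="rsX"):
            ld_clump(df, ld, SelectionConfig())

    @pytest.mark.parametrize("seed", range(30))
    def test_greedy_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        j = int(rng.integers(2, 9))
        rows = []
        for k in range(j):
            rows.append({
                "snp_id": f"rs{k + 1}",
                "chrom": str(rng.integers(1, 3)),
                "pos": int(rng.integers(0, 100_000)),
                "pval": float(rng.choice([1e-8, 1e-7, 1e-6, 1e-6])),
            })
        df = sumstats_frame(rows)
        a = rng.uniform(0, 1, (j, j))
        r2 = (a + a.T) / 2
        np.fill_diagonal(r2, 1.0)
        ld = ld_from(df["snp_id"], r2)
        cfg = SelectionConfig(clump_r2=0.3, clump_window_kb=30)
        kept = list(ld_clump(df, ld, cfg)["snp_id"])
        assert kept == brute_force_greedy(df, ld, 0.3, 30_000.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_retained_set_pairwise_compatible(self, seed):
        rng = np.random.default_rng(100 + seed)
        j = 8
        df = sumstats_frame([
            {"snp_id": f"rs{k}", "chrom": "1", "pos": int(rng.integers(0, 60_000)),
             "pval": float(rng.uniform(1e-9, 1e-5))} for k in range(j)
        ])
        a = rng.uniform(0, 1, (j, j))
        r2 = (a + a.T) / 2
        np.fill_diagonal(r2, 1.0)
        ld = ld_from(df["snp_id"], r2)
        cfg = SelectionConfig(clump_r2=0.4, clump_window_kb=30)
        kept = ld_clump(df, ld, cfg)
        idx = {s: i for i, s in enumerate(ld.snp_ids)}
        for _, x in kept.iterrows():
            for _, y in kept.iterrows():
                if x["snp_id"] == y["snp_id"]:
                    continue
                within = (x["chrom"] == y["chrom"]
                          and abs(x["pos"] - y["pos"]) <= 30_000)
                assert not (within and r2[idx[x["snp_id"]], idx[y["snp_id"]]] >= 0.4)


class TestSelectInstruments:
    def test_nothing_significant_raises(self):
        df = sumstats_frame([{"pval": 0.5} for _ in range(10)])
        ld = ld_from(df["snp_id"], np.eye(10))
        with pytest.raises(NoInstrumentsError):
            select_instruments(df, ld)

    def test_single_strong_snp_retained(self):
        df = sumstats_frame([{"snp_id": "rs1", "pval": 1e-9, "beta": 0.1, "se": 0.01}])
        ld = ld_from(["rs1"], [[1.0]])
        out = select_instruments(df, ld)
        assert list(out["snp_id"]) == ["rs1"]
        assert out["f_stat"].iloc[0] == pytest.approx(100.0)

    def test_planted_panel_matches_hand_enumeration(self):
        # rs1 strong & independent -> kept; rs2 weak F -> dropped at F stage;
        # rs3/rs4 linked pair within window -> rs3 (lower p) kept;
        # rs5 not significant -> dropped at p stage
        df = sumstats_frame([
            {"snp_id": "rs1", "pos": 1_000_000, "pval": 1e-9, "beta": 0.1, "se": 0.01},
            {"snp_id": "rs2", "pos": 2_000_000, "pval": 9e-6, "beta": 0.05, "se": 0.016},
            {"snp_id": "rs3", "pos": 3_000_000, "pval": 1e-8, "beta": 0.12, "se": 0.012},
            {"snp_id": "rs4", "pos": 3_010_000, "pval": 1e-6, "beta": 0.09, "se": 0.012},
            {"snp_id": "rs5", "pos": 4_000_000, "pval": 0.2, "beta": 0.01, "se": 0.01},
        ])
        r2 = np.eye(5)
        r2[2, 3] = r2[3, 2] = 0.8
        ld = ld_from(df["snp_id"], r2)
        out = select_instruments(df, ld)
        assert list(out["snp_id"]) == ["rs1", "rs3"]

    def test_loosening_p_threshold_never_shrinks_candidates(self):
        rng = np.random.default_rng(3)
        df = sumstats_frame([{"pval": float(p)} for p in rng.uniform(1e-9, 1e-3, 20)])
        ld = ld_from(df["snp_id"], np.eye(20))
        prev = set()
        for thr in (1e-8, 1e-6, 1e-4, 1e-2):
            cand = set(df[df["pval"] < thr]["snp_id"])
            assert prev <= cand
            prev = cand


class TestCisEqtls:
    gene = dict(gene_chrom="9", gene_start=95_000_000, gene_end=95_100_000)

    def make(self, rows):
        df = sumstats_frame(rows)
        ld = np.eye(len(rows))
        return df, ld

    def test_snp_beyond_window_excluded(self):
        df = sumstats_frame([
            {"snp_id": "far", "chrom": "9", "pos": 95_000_000 - 1_500_000, "pval": 1e-10},
            {"snp_id": "near", "chrom": "9", "pos": 95_050_000, "pval": 1e-10},
        ])
        ld = ld_from(df["snp_id"], np.eye(2))
        out = select_cis_eqtls(df, ld=ld, **self.gene)
        assert list(out["snp_id"]) == ["near"]

    def test_low_ld_pair_both_kept_high_ld_pruned(self):
        df = sumstats_frame([
            {"snp_id": "e1", "chrom": "9", "pos": 95_000_100, "pval": 1e-10},
            {"snp_id": "e2", "chrom": "9", "pos": 95_600_000, "pval": 1e-8},
        ])
        for r2_off, expected in [(0.29, ["e1", "e2"]), (0.31, ["e1"])]:
            r2 = np.array([[1.0, r2_off], [r2_off, 1.0]])
            ld = ld_from(df["snp_id"], r2)
            out = select_cis_eqtls(df, ld=ld, **self.gene)
            assert list(out["snp_id"]) == expected

    def test_no_distance_window_in_eqtl_pruning(self):
        # 1.9 Mb apart (both cis), r2 0.5: still pruned because the eQTL rule
        # has no window
        df = sumstats_frame([
            {"snp_id": "e1", "chrom": "9", "pos": 94_050_000, "pval": 1e-10},
            {"snp_id": "e2", "chrom": "9", "pos": 95_950_000, "pval": 1e-8},
        ])
        r2 = np.array([[1.0, 0.5], [0.5, 1.0]])
        ld = ld_from(df["snp_id"], r2)
        out = select_cis_eqtls(df, ld=ld, **self.gene)
        assert list(out["snp_id"]) == ["e1"]
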