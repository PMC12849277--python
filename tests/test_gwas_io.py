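"""Reading, harmonisation, clumping and Steiger filtering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mrclustmed import gwas_io
from mrclustmed.gwas_io import LdMatrix, SummaryStatsError

from conftest import make_stats


class TestReadSummaryStats:
    def test_well_formed_file_reads_identically(self, stats_file):
        path = stats_file([{}, {}, {}, {}, {}])
        df, excl = gwas_io.read_summary_stats(path)
        assert len(df) == 5
        assert excl.empty

    def test_duplicate_rsids_are_dropped_entirely(self, stats_file):
        rows = make_stats([{}, {}, {}, {}])
        rows.loc[3, "rsid"] = "rs1"  # rs1 now appears twice
        df, excl = gwas_io.read_summary_stats(stats_file(rows))
        assert len(df) == 2
        assert (excl["reason"] == "duplicate").sum() == 2
        assert "rs1" not in set(df["rsid"])

    @pytest.mark.parametrize("bad,reason", [
        ({"ea": "AT"}, "non-biallelic"),
        ({"ea": "A", "oa": "A"}, "non-biallelic"),
        ({"se": -0.01}, "non-positive-se"),
        ({"p": 1.5}, "p-out-of-range"),
        ({"n": 0}, "n-non-positive"),
        ({"eaf": 1.2}, "eaf-out-of-range"),
    ])
    def test_invariant_violations_dropped_and_tagged(self, stats_file, bad, reason):
        df, excl = gwas_io.read_summary_stats(stats_file([{}, bad]))
        assert len(df) == 1
        assert list(excl["reason"]) == [reason]

    def test_missing_mandatory_column_is_hard_error(self, stats_file, tmp_path):
        df = make_stats([{}]).drop(columns=["se"])
        with pytest.raises(SummaryStatsError, match="se"):
            gwas_io.read_summary_stats(stats_file(df))

    def test_column_map_renames_arbitrary_headers(self, stats_file):
        df = make_stats([{}]).rename(columns={"rsid": "SNP", "p": "pval"})
        path = stats_file(df)
        out, _ = gwas_io.read_summary_stats(path, column_map={"rsid": "SNP", "p": "pval"})
        assert list(out["rsid"]) == ["rs1"]

    def test_inconsistent_p_triggers_warning_not_drop(self, stats_file):
        path = stats_file([{"beta": 0.1, "se": 0.01, "p": 0.5}])  # z=10 but p=0.5
        with pytest.warns(UserWarning, match="inconsistent"):
            df, excl = gwas_io.read_summary_stats(path)
        assert len(df) == 1 and excl.empty


class TestHarmonise:
    def test_swapped_alleles_flip_outcome_sign(self):
        exp = make_stats([{"ea": "A", "oa": "G", "beta": 0.1}])
        out = make_stats([{"ea": "G", "oa": "A", "beta": 0.05, "eaf": 0.7}])
        pairs, excl = gwas_io.harmonise(exp, out)
        assert excl.empty
        row = pairs.iloc[0]
        assert row["flipped"] and row["beta_out"] == -0.05
        assert row["eaf_out"] == pytest.approx(0.3)

    def test_complementary_strand_resolved(self):
        exp = make_stats([{"ea": "A", "oa": "G", "beta": 0.1}])
        out = make_stats([{"ea": "T", "oa": "C", "beta": 0.05}])
        pairs, excl = gwas_io.harmonise(exp, out)
        assert len(pairs) == 1 and not pairs.iloc[0]["flipped"]
        assert pairs.iloc[0]["beta_out"] == 0.05

    def test_palindromic_concordant_frequencies_kept(self):
        exp = make_stats([{"ea": "A", "oa": "T", "eaf": 0.30}])
        out = make_stats([{"ea": "A", "oa": "T", "eaf": 0.31}])
        pairs, excl = gwas_io.harmonise(exp, out, maf_ambiguity_threshold=0.42)
        assert len(pairs) == 1 and pairs.iloc[0]["palindromic"]

    def test_palindromic_inside_ambiguity_band_dropped(self):
        exp = make_stats([{"ea": "A", "oa": "T", "eaf": 0.49}])
        out = make_stats([{"ea": "A", "oa": "T", "eaf": 0.49}])
        pairs, excl = gwas_io.harmonise(exp, out)
        assert pairs.empty
        assert list(excl["reason"]) == ["palindromic-unresolved"]

    def test_palindromic_discordant_frequencies_dropped(self):
        exp = make_stats([{"ea": "A", "oa": "T", "eaf": 0.30}])
        out = make_stats([{"ea": "A", "oa": "T", "eaf": 0.70}])
        pairs, excl = gwas_io.harmonise(exp, out)
        assert list(excl["reason"]) == ["palindromic-unresolved"]

    def test_irreconcilable_pair_dropped_as_mismatch(self):
        exp = make_stats([{"ea": "A", "oa": "G"}])
        out = make_stats([{"ea": "A", "oa": "C"}])
        pairs, excl = gwas_io.harmonise(exp, out)
        assert list(excl["reason"]) == ["mismatch"]

    def test_idempotence_on_own_output(self):
        exp = make_stats([
            {"ea": "A", "oa": "G", "beta": 0.1},
            {"ea": "C", "oa": "T", "beta": -0.2, "eaf": 0.6},
            {"ea": "G", "oa": "C", "eaf": 0.2, "beta": 0.05},
        ])
        out = make_stats([
            {"ea": "G", "oa": "A", "beta": 0.05, "eaf": 0.7},
            {"ea": "G", "oa": "A", "beta": 0.03, "eaf": 0.35},
            {"ea": "G", "oa": "C", "eaf": 0.22, "beta": -0.01},
        ])
        pairs, _ = gwas_io.harmonise(exp, out)
        # rebuild the outcome side from the harmonised orientation
        out2 = pairs.rename(columns={
            "beta_out": "beta", "se_out": "se", "eaf_out": "eaf", "n_out": "n"})
        out2 = out2.assign(p=0.5)[gwas_io.CANONICAL_COLUMNS]
        pairs2, excl2 = gwas_io.harmonise(exp, out2)
        assert excl2.empty or set(excl2["reason"]) <= {"palindromic-unresolved"}
        merged = pairs.merge(pairs2, on="rsid", suffixes=("_a", "_b"))
        assert not merged["flipped_b"].any()
        np.testing.assert_allclose(merged["beta_out_a"], merged["beta_out_b"])


def brute_force_clump(df, ld, window_kb, r2_threshold, p_threshold):
    """Literal re-implementation of the greedy rule for cross-checking."""
    pool = df[df["p"] < p_threshold].sort_values(
        ["p", "chr", "pos"], kind="mergesort").reset_index(drop=True)
    kept, removed = [], set()
    for _, row in pool.iterrows():
        if row["rsid"] in removed:
            continue
        kept.append(row["rsid"])
        for _, other in pool.iterrows():
            if other["rsid"] == row["rsid"] or other["rsid"] in removed:
                continue
            same_chr = other["chr"] == row["chr"]
            close = abs(other["pos"] - row["pos"]) <= window_kb * 1000
            linked = ld is None or ld.lookup(row["rsid"], other["rsid"]) >= r2_threshold
            if same_chr and close and linked and other["rsid"] not in kept:
                removed.add(other["rsid"])
    return kept


class TestClump:
    def test_window_removes_nearby_but_not_distant(self):
        df = make_stats([
            {"pos": 1_000, "p": 1e-20},
            {"pos": 100_000, "p": 1e-10},
            {"pos": 900_000, "p": 1e-9},
        ])
        ld = LdMatrix(list(df["rsid"]), np.full((3, 3), 0.5) + 0.5 * np.eye(3))
        kept = gwas_io.clump(df, ld=ld)
        assert kept == ["rs1", "rs3"]

    def test_no_clumping_across_chromosomes(self):
        df = make_stats([{"chr": "1", "pos": 1000}, {"chr": "2", "pos": 1000}])
        with pytest.warns(UserWarning):
            kept = gwas_io.clump(df, ld=None)
        assert set(kept) == {"rs1", "rs2"}

    def test_nothing_significant_gives_empty_set(self):
        df = make_stats([{"p": 1e-7}, {"p": 0.5}])
        kept = gwas_io.clump(df, ld=None)
        assert kept == []

    def test_pvalue_tie_breaks_by_position(self):
        df = make_stats([
            {"chr": "1", "pos": 500_000, "p": 1e-10},
            {"chr": "1", "pos": 100_000, "p": 1e-10},
        ])
        with pytest.warns(UserWarning):
            kept = gwas_io.clump(df, ld=None)
        assert kept == ["rs2"]  # lower position wins the tie, removes the other

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        df = make_stats([
            {"chr": str(rng.integers(1, 3)), "pos": int(rng.integers(1, 2_000_000)),
             "p": float(10.0 ** rng.uniform(-30, -5))}
            for _ in range(n)
        ])
        r2 = rng.uniform(0, 1, (n, n))
        r2 = (r2 + r2.T) / 2
        np.fill_diagonal(r2, 1.0)
        ld = LdMatrix(list(df["rsid"]), r2)
        kept = gwas_io.clump(df, ld=ld, window_kb=500, r2_threshold=0.3)
        assert kept == brute_force_clump(df, ld, 500, 0.3, 5e-8)
        # retained set is independent: no pair violates the joint criterion
        sub = df.set_index("rsid").loc[kept]
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                ra, rb = sub.loc[a], sub.loc[b]
                violates = (
                    ra["chr"] == rb["chr"]
                    and abs(ra["pos"] - rb["pos"]) <= 500_000
                    and ld.lookup(a, b) >= 0.3
                )
                assert not violates


def _pair_frame(rows):
    defaults = {"rsid": "rs1", "chr": "1", "pos": 1, "ea": "A", "oa": "G",
                "beta_exp": 0.02, "se_exp": 0.002, "eaf_exp": 0.3, "n_exp": 500_000,
                "beta_out": 0.001, "se_out": 0.002, "eaf_out": 0.3, "n_out": 240_000,
                "palindromic": False, "flipped": False}
    out = []
    for i, row in enumerate(rows):
        r = dict(defaults, rsid=f"rs{i + 1}")
        r.update(row)
        out.append(r)
    return pd.DataFrame(out, columns=gwas_io.PAIR_COLUMNS)


class TestSteigerFilter:
    def test_strong_exposure_weak_outcome_retained(self):
        # Z_exp = 10 on n=500k vs Z_out = 0.5 on n=240k
        pairs = _pair_frame([{
            "beta_exp": 0.01, "se_exp": 0.001, "n_exp": 500_000,
            "beta_out": 0.0005, "se_out": 0.001, "n_out": 240_000,
        }])
        kept, excl = gwas_io.steiger_filter(pairs)
        assert len(kept) == 1 and excl.empty
        # cross-check the Fisher test arithmetic by hand
        r_e = np.sqrt(100 / (100 + 500_000))
        r_o = np.sqrt(0.25 / (0.25 + 240_000))
        z = (np.arctanh(r_e) - np.arctanh(r_o)) / np.sqrt(1 / 499_997 + 1 / 239_997)
        assert sps.norm.sf(z) < 0.05

    def test_identical_association_dropped(self):
        pairs = _pair_frame([{
            "beta_exp": 0.01, "se_exp": 0.001, "n_exp": 300_000,
            "beta_out": 0.01, "se_out": 0.001, "n_out": 300_000,
        }])
        kept, excl = gwas_io.steiger_filter(pairs)
        assert kept.empty and list(excl["reason"]) == ["steiger-direction"]

    def test_reversed_direction_dropped_regardless_of_p(self):
        pairs = _pair_frame([{
            "beta_exp": 0.001, "se_exp": 0.001, "beta_out": 0.05, "se_out": 0.001,
        }])
        kept, excl = gwas_io.steiger_filter(pairs, alpha=0.999)
        assert kept.empty and list(excl["reason"]) == ["steiger-direction"]

    def test_tiny_sample_size_dropped(self):
        pairs = _pair_frame([{"n_out": 3}])
        kept, excl = gwas_io.steiger_filter(pairs)
        assert list(excl["reason"]) == ["n-too-small"]

    def test_alpha_one_reduces_to_direction_condition(self, rng):
        rows = [{
            "beta_exp": float(rng.normal(0, 0.02)) or 0.01,
            "beta_out": float(rng.normal(0, 0.02)) or 0.01,
        } for _ in range(40)]
        pairs = _pair_frame(rows)
        kept, _ = gwas_io.steiger_filter(pairs, alpha=1.0)
        z_e = pairs["beta_exp"] / pairs["se_exp"]
        z_o = pairs["beta_out"] / pairs["se_out"]
        r2_e = z_e**2 / (z_e**2 + pairs["n_exp"])
        r2_o = z_o**2 / (z_o**2 + pairs["n_out"])
        assert set(kept["rsid"]) == set(pairs.loc[(r2_e > r2_o).to_numpy(), "rsid"])


class TestLdMatrix:
    def test_round_trip_and_lookup(self, tmp_path):
        ld = LdMatrix(["rs1", "rs2"], np.array([[1.0, 0.4], [0.4, 1.0]]))
        ld.write(tmp_path / "ld.tsv")
        back = LdMatrix.read(tmp_path / "ld.tsv")
        assert back.lookup("rs1", "rs2") == pytest.approx(0.4)
        assert back.lookup("rs1", "absent") == 0.0

    @pytest.mark.parametrize("bad", [
        np.array([[1.0, 0.2], [0.4, 1.0]]),     # asymmetric
        np.array([[0.9, 0.4], [0.4, 1.0]]),     # diagonal not 1
        np.array([[1.0, 1.4], [1.4, 1.0]]),     # out of range
    ])
    def test_invalid_matrices_rejected(self, bad):
        with pytest.raises(ValueError):
            LdMatrix(["rs1", "rs2"], bad)
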