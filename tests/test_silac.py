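"""Tests for SILAC table parsing, filtering, orientation and enrichment."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_h

from endosig import silac
from endosig.silac import (
    combine_replicates,
    differential_analysis,
    filter_records,
    fisher_enrichment,
    flag_significant,
    hypergeom_tail_p,
    impute_missing,
    merge_duplicates,
    normalize_and_orient,
    parse_table,
    read_gmt,
    records_from_frame,
)
from endosig.synth import MAXQUANT_COLUMNS, TableSpec, generate_silac_tables, write_silac_tables


def hypergeom_tail_oracle(k: int, M: int, K: int, N: int) -> float:
    """Exact rational tail sum P(X >= k) via binomial coefficients."""
    denom = math.comb(M, N)
    total = Fraction(0)
    for i in range(max(k, 0, N - (M - K)), min(K, N) + 1):
        total += Fraction(math.comb(K, i) * math.comb(M - K, N - i), denom)
    return float(total)


def _mk_table(rows: list[dict]) -> pd.DataFrame:
    base = {c: "" for c in MAXQUANT_COLUMNS}
    return pd.DataFrame([{**base, **r} for r in rows], columns=MAXQUANT_COLUMNS)


def _clean_row(i: int, ratio="1.0", **kw) -> dict:
    row = {
        "Proteins": f"P{i}", "Gene names": f"G{i}", "Amino acid": "S",
        "Position": str(100 + i), "Localization prob": "0.95",
        "Unique peptides": "5", "Ratio H/L normalized": ratio,
    }
    row.update(kw)
    return row


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


class TestParsing:
    def test_generated_tables_roundtrip(self, tmp_path):
        spec = TableSpec(n_sites=30, missing_rate=0.2, seed=8)
        fwd, rev, _ = generate_silac_tables(spec)
        paths = write_silac_tables(tmp_path, fwd, rev, _)
        parsed = parse_table(paths["forward"])
        assert len(parsed) == len(fwd)
        expected = fwd["Ratio H/L normalized"].astype(float)
        assert np.allclose(parsed["ratio_hl"], expected, equal_nan=True)
        assert parsed["reverse"].sum() == (fwd["Reverse"] == "+").sum()
        assert parsed["contaminant"].sum() == (
            fwd["Potential contaminant"] == "+").sum()

    def test_nan_ratio_becomes_missing_silently(self, tmp_path):
        table = _mk_table([_clean_row(1, ratio="NaN"), _clean_row(2, ratio="2.0")])
        p = tmp_path / "t.txt"
        table.to_csv(p, sep="\t", index=False)
        parsed = parse_table(p)
        assert parsed["ratio_hl"].isna().tolist() == [True, False]

    def test_unparseable_ratio_warns_once(self, tmp_path):
        table = _mk_table([_clean_row(1, ratio="oops"), _clean_row(2)])
        p = tmp_path / "t.txt"
        table.to_csv(p, sep="\t", index=False)
        with pytest.warns(UserWarning, match="unparseable"):
            parsed = parse_table(p)
        assert parsed["ratio_hl"].isna().tolist() == [True, False]

    def test_missing_reverse_column_errors(self, tmp_path):
        table = _mk_table([_clean_row(1)]).drop(columns=["Reverse"])
        p = tmp_path / "t.txt"
        table.to_csv(p, sep="\t", index=False)
        with pytest.raises(ValueError, match="Reverse"):
            parse_table(p)

    def test_protein_groups_join_supplies_peptide_counts(self, tmp_path):
        sites = _mk_table([_clean_row(1), _clean_row(2)]).drop(
            columns=["Unique peptides"])
        pg = _mk_table([
            _clean_row(1, **{"Unique peptides": "7"}),
            _clean_row(2, **{"Unique peptides": "1"}),
        ])
        sp, pp = tmp_path / "sites.txt", tmp_path / "pg.txt"
        sites.to_csv(sp, sep="\t", index=False)
        pg.to_csv(pp, sep="\t", index=False)
        parsed = silac.parse_tables(pp, sp)
        assert parsed["unique_peptides"].tolist() == [7, 1]

    def test_gmt_reader(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("SET_A\tdesc\tG1\tG2\nSET_B\t\tG3\n")
        sets = read_gmt(p)
        assert sets == {"SET_A": {"G1", "G2"}, "SET_B": {"G3"}}


# ---------------------------------------------------------------------------
# filtering + merging
# ---------------------------------------------------------------------------


class TestFiltering:
    def test_six_row_fixture_bookkeeping(self):
        table = _mk_table([
            _clean_row(1, Reverse="+"),
            _clean_row(2, **{"Potential contaminant": "+"}),
            _clean_row(3, **{"Unique peptides": "1"}),
            _clean_row(4), _clean_row(5), _clean_row(6),
        ])
        kept, counts = filter_records(records_from_frame(table))
        assert len(kept) == 3
        assert counts == {"reverse": 1, "contaminant": 1, "low_peptide": 1,
                          "low_localization": 0}
        assert len(kept) + sum(counts.values()) == len(table)

    def test_localization_cutoff(self):
        table = _mk_table([
            _clean_row(1, **{"Localization prob": "0.6"}),
            _clean_row(2, **{"Localization prob": "0.75"}),
        ])
        kept, counts = filter_records(records_from_frame(table),
                                      min_loc_prob=0.75)
        assert len(kept) == 1
        assert counts["low_localization"] == 1

    def test_all_clean_table_is_identity(self):
        table = _mk_table([_clean_row(i) for i in range(4)])
        recs = records_from_frame(table)
        kept, counts = filter_records(recs)
        assert kept.equals(recs)
        assert sum(counts.values()) == 0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st_h.lists(st_h.tuples(st_h.booleans(), st_h.booleans(),
                                  st_h.integers(0, 4),
                                  st_h.floats(0, 1)), max_size=40))
    def test_bookkeeping_holds_on_random_fixtures(self, rows):
        table = _mk_table([
            _clean_row(i, Reverse="+" if rev else "",
                       **{"Potential contaminant": "+" if con else "",
                          "Unique peptides": str(pep),
                          "Localization prob": f"{loc:.3f}"})
            for i, (rev, con, pep, loc) in enumerate(rows)
        ])
        kept, counts = filter_records(records_from_frame(table))
        assert len(kept) + sum(counts.values()) == len(table)


class TestMergeDuplicates:
    def test_two_duplicates_merge_to_log_median(self):
        table = _mk_table([_clean_row(1, ratio="2.0"), _clean_row(1, ratio="8.0")])
        merged = merge_duplicates(records_from_frame(table))
        assert len(merged) == 1
        # median of log2 {1, 3} = 2 -> ratio 4.0
        assert merged["ratio_hl"].iloc[0] == pytest.approx(4.0)
        assert merged["n_merged"].iloc[0] == 2

    def test_three_duplicates(self):
        table = _mk_table([_clean_row(1, ratio=r) for r in ("1", "2", "16")])
        merged = merge_duplicates(records_from_frame(table))
        assert merged["ratio_hl"].iloc[0] == pytest.approx(2.0)

    def test_no_duplicates_is_identity(self):
        table = _mk_table([_clean_row(1), _clean_row(2)])
        recs = records_from_frame(table)
        merged = merge_duplicates(recs)
        assert merged.drop(columns="n_merged").equals(recs)

    def test_distinct_sites_same_protein_kept_separately(self):
        table = _mk_table([
            _clean_row(1, Position="100"),
            _clean_row(1, Position="200"),
        ])
        with pytest.warns(UserWarning, match="distinct site"):
            merged = merge_duplicates(records_from_frame(table))
        assert len(merged) == 2


# ---------------------------------------------------------------------------
# orientation + significance + imputation + combination
# ---------------------------------------------------------------------------


class TestNormalizeOrient:
    def test_median_centering(self):
        table = _mk_table([_clean_row(i, ratio=r) for i, r in
                           enumerate(("1", "2", "4"))])
        out = normalize_and_orient(records_from_frame(table), "heavy")
        assert np.allclose(out["log2c"], [-1, 0, 1])

    def test_reverse_replicate_sign_flip(self):
        # mutant heavy in forward -> a mutant-up site has reverse ratio 0.5
        table = _mk_table([_clean_row(1, ratio="0.5")])
        out = normalize_and_orient(records_from_frame(table), "heavy",
                                   orientation="reverse")
        assert out.attrs["center"] == pytest.approx(1.0)
        assert out["log2c"].iloc[0] + out.attrs["center"] == pytest.approx(1.0)

    def test_light_mutant_flips_forward(self):
        table = _mk_table([_clean_row(1, ratio="4.0"), _clean_row(2, ratio="4.0")])
        out = normalize_and_orient(records_from_frame(table), "light")
        assert out.attrs["center"] == pytest.approx(-2.0)

    def test_all_equal_ratios_center_to_zero(self):
        table = _mk_table([_clean_row(i, ratio="3.0") for i in range(3)])
        out = normalize_and_orient(records_from_frame(table), "heavy")
        assert np.allclose(out["log2c"], 0)

    def test_requires_channel_key(self):
        table = _mk_table([_clean_row(1)])
        with pytest.raises(ValueError, match="heavy.*light|light.*heavy"):
            normalize_and_orient(records_from_frame(table), "medium")


class TestFlagSignificant:
    def test_single_outlier_arithmetic(self):
        values = [0.0] * 9 + [5.0]
        flags, stats = flag_significant(values)
        assert flags.tolist() == [False] * 9 + [True]
        assert stats["mean"] == pytest.approx(0.5)
        assert stats["sd"] == pytest.approx(np.std(values, ddof=1))
        assert stats["upper"] == pytest.approx(0.5 + 2 * np.std(values, ddof=1))

    def test_normal_tail_fraction(self):
        rng = np.random.default_rng(0)
        flags, _ = flag_significant(rng.normal(0, 1, 10_000))
        frac = flags.mean()
        expected = 0.0455  # 2 * (1 - Phi(2))
        assert abs(frac - expected) < 3 * np.sqrt(expected * (1 - expected) / 10_000)

    def test_zero_spread_flags_nothing(self):
        with pytest.warns(UserWarning, match="zero spread"):
            flags, _ = flag_significant([1.0, 1.0, 1.0, 1.0])
        assert not flags.any()

    def test_excluded_values_never_flagged_and_never_drive_stats(self):
        values = np.array([0.0, 0.1, -0.1, 0.05, 50.0])
        exclude = np.array([False, False, False, False, True])
        flags, stats = flag_significant(values, exclude=exclude)
        assert not flags[4]
        assert stats["sd"] == pytest.approx(np.std(values[:4], ddof=1))


class TestImputeAndCombine:
    def test_impute_min_minus_constant(self):
        values = np.array([-3.0, 1.0, np.nan, 0.5])
        filled, imputed = impute_missing(values, constant=0.1)
        assert filled[2] == pytest.approx(-3.1)
        assert imputed.tolist() == [False, False, True, False]

    def test_no_missing_is_identity(self):
        values = np.array([1.0, 2.0])
        filled, imputed = impute_missing(values)
        assert np.array_equal(filled, values)
        assert not imputed.any()

    def test_all_missing_errors(self):
        with pytest.raises(ValueError, match="no observed"):
            impute_missing([np.nan, np.nan])

    def test_imputed_entry_never_significant(self):
        rng = np.random.default_rng(1)
        values = np.append(rng.normal(0, 0.1, 50), np.nan)
        filled, imputed = impute_missing(values, constant=10.0)  # far outlier
        flags, _ = flag_significant(filled, exclude=imputed)
        assert not flags[-1]

    def _oriented(self, pairs):
        rows_f, rows_r = [], []
        for i, (f, r) in enumerate(pairs):
            if f is not None:
                rows_f.append(_clean_row(i, ratio=str(2.0**f)))
            if r is not None:
                rows_r.append(_clean_row(i, ratio=str(2.0**-r)))
        fwd = normalize_and_orient(records_from_frame(_mk_table(rows_f)),
                                   "heavy", "forward", center="mean")
        rev = normalize_and_orient(records_from_frame(_mk_table(rows_r)),
                                   "heavy", "reverse", center="mean")
        return fwd, rev

    def test_combined_is_mean_of_oriented(self):
        fwd, rev = self._oriented([(1.0, 1.0), (0.0, 0.0), (-1.0, -1.0),
                                   (0.5, 0.5), (-0.5, -0.5)])
        combined = combine_replicates(fwd, rev)
        assert np.allclose(np.sort(combined["log2c_combined"]),
                           [-1, -0.5, 0, 0.5, 1])
        assert not combined["single_replicate"].any()

    def test_discordant_flagged(self):
        fwd, rev = self._oriented(
            [(2.0, -2.0)] + [(x / 10, x / 10) for x in range(-3, 4)])
        combined = combine_replicates(fwd, rev)
        row = combined[combined["log2c_forward"].abs() > 1].iloc[0]
        assert row["discordant"]

    def test_single_replicate_site_flagged_with_value_kept(self):
        fwd, rev = self._oriented([(1.0, None), (0.0, 0.0), (-1.0, -1.0)])
        combined = combine_replicates(fwd, rev)
        solo = combined[combined["single_replicate"]]
        assert len(solo) == 1
        assert solo["log2c_combined"].iloc[0] == pytest.approx(
            solo["log2c_forward"].iloc[0])


class TestDifferentialPipeline:
    def test_recovery_of_shifted_sites(self):
        spec = TableSpec(n_sites=2000, seed=13)
        fwd, rev, truth = generate_silac_tables(spec)
        result, info = differential_analysis(
            records_from_frame(fwd), records_from_frame(rev), "heavy")
        merged = result.merge(
            truth.rename(columns={"Proteins": "proteins",
                                  "Gene names": "gene_names",
                                  "Amino acid": "amino_acid",
                                  "Position": "position"}),
            on=["proteins", "gene_names"], how="left")
        site = merged[merged["category"] == "site"]
        assert site.loc[site["shifted"], "significant"].mean() >= 0.8
        assert site.loc[~site["shifted"], "significant"].mean() <= 0.06
        assert info["forward"]["dropped"]["reverse"] == spec.n_decoy_reverse

    def test_label_swap_antisymmetry_noiseless(self):
        spec = TableSpec(n_sites=100, fraction_shifted=0.2, ratio_noise_sd=0,
                         missing_rate=0, seed=6)
        fwd, rev, _ = generate_silac_tables(spec)
        result, _ = differential_analysis(
            records_from_frame(fwd), records_from_frame(rev), "heavy")
        ok = result["log2c_forward"].notna() & result["log2c_reverse"].notna()
        assert np.allclose(result.loc[ok, "log2c_forward"],
                           result.loc[ok, "log2c_reverse"])

    def test_noisy_replicates_correlate_positively(self):
        spec = TableSpec(n_sites=500, fraction_shifted=0.2, seed=21)
        fwd, rev, _ = generate_silac_tables(spec)
        result, _ = differential_analysis(
            records_from_frame(fwd), records_from_frame(rev), "heavy")
        sub = result.dropna(subset=["log2c_forward", "log2c_reverse"])
        r = np.corrcoef(sub["log2c_forward"], sub["log2c_reverse"])[0, 1]
        assert r > 0.2


# ---------------------------------------------------------------------------
# over-representation
# ---------------------------------------------------------------------------


class TestFisherEnrichment:
    def test_zero_overlap_p_is_one(self):
        bg = [f"G{i}" for i in range(20)]
        res = fisher_enrichment(bg[:5], bg, {"S": set(bg[5:10])})
        assert res["p"].iloc[0] == pytest.approx(1.0)
        assert res["overlap"].iloc[0] == 0

    def test_set_equal_to_significant_gives_minimal_p(self):
        bg = [f"G{i}" for i in range(30)]
        sig = bg[:6]
        res = fisher_enrichment(sig, bg, {"S": set(sig)})
        assert res["p"].iloc[0] == pytest.approx(
            hypergeom_tail_oracle(6, 30, 6, 6), abs=1e-12)

    def test_example_table_matches_tail_oracle(self):
        # overlap 5, sig-only 5, set-only 5, rest 85 -> M=100, K=10, N=10
        p = hypergeom_tail_p(5, 100, 10, 10)
        assert p == pytest.approx(hypergeom_tail_oracle(5, 100, 10, 10),
                                  abs=1e-10)

    def test_random_tables_match_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            M = int(rng.integers(2, 200))
            K = int(rng.integers(0, M + 1))
            N = int(rng.integers(0, M + 1))
            k = int(rng.integers(max(0, K + N - M), min(K, N) + 1))
            assert hypergeom_tail_p(k, M, K, N) == pytest.approx(
                hypergeom_tail_oracle(k, M, K, N), abs=1e-10)

    def test_sets_intersected_with_background(self):
        bg = [f"G{i}" for i in range(10)]
        res = fisher_enrichment(bg[:3], bg, {"S": {"G0", "G1", "X999"}})
        assert res["set_size"].iloc[0] == 2

    def test_empty_background_errors(self):
        with pytest.raises(ValueError, match="background"):
            fisher_enrichment([], [], {"S": {"G1"}})

    def test_significant_outside_background_errors(self):
        with pytest.raises(ValueError, match="subset"):
            fisher_enrichment(["X"], ["G1"], {"S": {"G1"}})

    def test_null_enrichment_p_uniform(self):
        """Random gene sets on random significance are ~Uniform(0,1)."""
        rng = np.random.default_rng(3)
        bg = [f"G{i}" for i in range(400)]
        sig = list(rng.choice(bg, size=40, replace=False))
        sets = {f"S{j}": set(rng.choice(bg, size=40, replace=False))
                for j in range(200)}
        res = fisher_enrichment(sig, bg, sets)
        from scipy import stats as sps

        # p-values are discrete and conservative; KS against uniform should
        # not reject at an extreme level, and the median should not collapse
        assert sps.kstest(res["p"], "uniform").pvalue > 1e-4 or \
            res["p"].median() > 0.3
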