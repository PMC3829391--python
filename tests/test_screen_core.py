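"""Well-table I/O, dual-luciferase normalization and per-pool statistics."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from barscreen import screen_core as sc
from conftest import make_wells

WELL_TSV = """\
plate_id\twell_id\tsample_kind\tpool_id\tfirefly\trenilla\treplicate
PL1\tA01\tnegative_control\t\t2000\t1000\t1
PL1\tA02\tnegative_control\t\t1900\t950\t2
PL1\tB01\tpool\tPA\t800\t1000\t1
PL1\tB02\tpool\tPA\t1200\t1000\t2
"""


class TestReadWellTable:
    def test_well_formed_table_parses_fully(self, tmp_path):
        p = tmp_path / "w.tsv"
        p.write_text(WELL_TSV)
        df = sc.read_well_table(p)
        assert len(df) == 4
        assert not df["excluded"].any()
        assert df.loc[2, "pool_id"] == "PA"
        assert df.loc[0, "pool_id"] is None

    def test_zero_renilla_flagged_excluded_not_errored(self, tmp_path):
        p = tmp_path / "w.tsv"
        p.write_text(WELL_TSV + "PL1\tB03\tpool\tPA\t500\t0\t3\n")
        df = sc.read_well_table(p)
        assert len(df) == 5
        assert int(df["excluded"].sum()) == 1
        assert df.loc[df["excluded"], "well_id"].tolist() == ["B03"]

    def test_column_order_is_irrelevant(self, tmp_path):
        p1 = tmp_path / "canonical.tsv"
        p1.write_text(WELL_TSV)
        lines = WELL_TSV.strip().split("\n")
        perm = [4, 0, 6, 2, 1, 5, 3]  # shuffle columns
        shuffled = "\n".join(
            "\t".join(line.split("\t")[i] for i in perm) for line in lines
        )
        p2 = tmp_path / "shuffled.tsv"
        p2.write_text(shuffled + "\n")
        pd.testing.assert_frame_equal(sc.read_well_table(p1), sc.read_well_table(p2))

    def test_missing_column_named_in_error(self, tmp_path):
        p = tmp_path / "w.tsv"
        p.write_text("plate_id\twell_id\nPL1\tA01\n")
        with pytest.raises(ValueError, match="sample_kind"):
            sc.read_well_table(p)

    def test_non_numeric_rlu_reports_line_number(self, tmp_path):
        p = tmp_path / "w.tsv"
        p.write_text(WELL_TSV.replace("1200", "oops"))
        with pytest.raises(ValueError, match="line 5"):
            sc.read_well_table(p)

    def test_pool_well_without_pool_id_rejected(self, tmp_path):
        p = tmp_path / "w.tsv"
        p.write_text(WELL_TSV.replace("pool\tPA\t800", "pool\t\t800"))
        with pytest.raises(ValueError, match="pool well without pool_id"):
            sc.read_well_table(p)


class TestNormalizeRatio:
    @pytest.mark.parametrize(
        "firefly,renilla,expected", [(1000, 1000, 1.0), (500, 1000, 0.5)]
    )
    def test_ratio_arithmetic(self, firefly, renilla, expected):
        assert sc.normalize_ratio(firefly, renilla) == expected

    @given(
        f=st.floats(0.0, 1e6),
        r=st.floats(1e-3, 1e6),
        c=st.floats(1e-3, 1e3),
    )
    def test_scale_invariance(self, f, r, c):
        base = sc.normalize_ratio(f, r)
        scaled = sc.normalize_ratio(f * c, r * c)
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-12)

    def test_zero_renilla_is_an_error(self):
        with pytest.raises(ValueError, match="renilla"):
            sc.normalize_ratio(100.0, 0.0)


class TestSummarizePools:
    def test_percent_of_control_definition(self, small_plate):
        out = sc.summarize_pools(small_plate)
        pa = out[out["pool_id"] == "PA"].iloc[0]
        # median(0.8, 1.0, 1.2) / control median 2.0 -> 50%
        assert pa["percent_of_control"] == pytest.approx(50.0)
        assert pa["log2_effect"] == pytest.approx(-1.0)
        assert pa["direction"] == "down"

    def test_pool_equal_to_controls_is_100_percent_p_1(self, small_plate):
        out = sc.summarize_pools(small_plate)
        pb = out[out["pool_id"] == "PB"].iloc[0]
        assert pb["percent_of_control"] == pytest.approx(100.0)
        assert pb["p_value"] == 1.0
        assert pb["direction"] == "none"

    def test_plate_scale_invariance(self, small_plate):
        base = sc.summarize_pools(small_plate)
        scaled_wells = small_plate.copy()
        scaled_wells["firefly"] *= 37.5
        scaled_wells["renilla"] *= 37.5
        scaled = sc.summarize_pools(scaled_wells)
        for col in ("percent_of_control", "p_value", "log2_effect"):
            np.testing.assert_allclose(base[col], scaled[col], rtol=1e-9)

    def test_control_wells_treated_as_a_pool_sit_at_100_percent(self):
        rng = np.random.default_rng(5)
        rows = []
        ratios = rng.lognormal(0, 0.2, 8)
        for i, r in enumerate(ratios):
            rows.append(("PL1", f"A{i:02d}", "negative_control", None,
                         1000.0 * r, 1000.0, i + 1))
        # a pool made of wells literally identical to the negative controls
        for i, r in enumerate(ratios):
            rows.append(("PL1", f"B{i:02d}", "pool", "PX",
                         1000.0 * r, 1000.0, i + 1))
        out = sc.summarize_pools(make_wells(rows))
        assert out.iloc[0]["percent_of_control"] == pytest.approx(100.0)

    def test_welch_p_matches_exhaustive_permutation_oracle(
        self, control_log2_ratios
    ):
        pool_log2 = np.array([1.1, 0.9, 1.0])
        rows = [
            ("PL1", f"A{i:02d}", "negative_control", None,
             1000.0 * 2.0 ** x, 1000.0, i + 1)
            for i, x in enumerate(control_log2_ratios)
        ] + [
            ("PL1", f"B{i:02d}", "pool", "PX", 1000.0 * 2.0 ** x, 1000.0, i + 1)
            for i, x in enumerate(pool_log2)
        ]
        wells = make_wells(rows)
        p_welch = sc.summarize_pools(wells, test="welch").iloc[0]["p_value"]
        # independent brute-force oracle: exhaustive reassignment of the 11
        # (plate-centred) log2 ratios into groups of 3 and 8
        ctrl_centred = control_log2_ratios - np.median(control_log2_ratios)
        pool_centred = pool_log2 - np.median(control_log2_ratios)
        pooled = np.concatenate([pool_centred, ctrl_centred])
        obs = abs(pool_centred.mean() - ctrl_centred.mean())
        count = total = 0
        for idx in combinations(range(len(pooled)), 3):
            grp = pooled[list(idx)]
            rest = np.delete(pooled, list(idx))
            total += 1
            if abs(grp.mean() - rest.mean()) >= obs - 1e-12:
                count += 1
        p_perm = count / total
        assert abs(p_welch - p_perm) <= 0.02

    def test_permutation_mode_equals_oracle_exactly(self, control_log2_ratios):
        pool_log2 = np.array([0.35, 0.05, 0.35])
        rows = [
            ("PL1", f"A{i:02d}", "negative_control", None,
             1000.0 * 2.0 ** x, 1000.0, i + 1)
            for i, x in enumerate(control_log2_ratios)
        ] + [
            ("PL1", f"B{i:02d}", "pool", "PX", 1000.0 * 2.0 ** x, 1000.0, i + 1)
            for i, x in enumerate(pool_log2)
        ]
        p_impl = sc.summarize_pools(make_wells(rows), test="permutation").iloc[0][
            "p_value"
        ]
        ctrl = control_log2_ratios - np.median(control_log2_ratios)
        pool = pool_log2 - np.median(control_log2_ratios)
        pooled = np.concatenate([pool, ctrl])
        obs = abs(pool.mean() - ctrl.mean())
        count = total = 0
        for idx in combinations(range(len(pooled)), 3):
            grp = pooled[list(idx)]
            rest = np.delete(pooled, list(idx))
            total += 1
            if abs(grp.mean() - rest.mean()) >= obs - 1e-12:
                count += 1
        assert p_impl == pytest.approx(count / total, abs=1e-12)

    def test_pool_with_only_excluded_wells_is_flagged(self, small_plate):
        wells = pd.concat(
            [
                small_plate,
                make_wells([("PL1", "D01", "pool", "PC", 500.0, 0.0, 1)]),
            ],
            ignore_index=True,
        )
        out = sc.summarize_pools(wells)
        pc = out[out["pool_id"] == "PC"].iloc[0]
        assert pc["flagged"]
        assert math.isnan(pc["p_value"])
        assert pc["direction"] == "none"

    def test_plate_without_enough_controls_rejected(self):
        rows = [
            ("PL1", "A01", "negative_control", None, 2000.0, 1000.0, 1),
            ("PL1", "B01", "pool", "PA", 800.0, 1000.0, 1),
        ]
        with pytest.raises(ValueError, match="negative-control"):
            sc.summarize_pools(make_wells(rows))


class TestVolcanoTable:
    def _summaries(self, triples):
        rows = [
            {
                "pool_id": pid, "gene_symbol": g, "percent_of_control": 50.0,
                "p_value": p, "log2_effect": -1.0, "n_replicates": 3,
                "median_ratio": 0.5, "direction": "down", "flagged": False,
            }
            for pid, g, p in triples
        ]
        return pd.DataFrame(rows, columns=sc.SUMMARY_COLUMNS)

    def test_sorted_by_p_ascending(self):
        vol = sc.build_volcano_table(
            self._summaries([("P3", "G3", 0.5), ("P1", "G1", 0.01), ("P2", "G2", 0.1)])
        )
        assert vol["pool_id"].tolist() == ["P1", "P2", "P3"]

    def test_p_ties_broken_by_pool_id(self):
        vol = sc.build_volcano_table(
            self._summaries([("P2", "G2", 0.1), ("P1", "G1", 0.1), ("P3", "G3", 0.1)])
        )
        assert vol["pool_id"].tolist() == ["P1", "P2", "P3"]

    def test_round_trip_preserves_six_significant_digits(
        self, tmp_path, sim_summaries_seed7
    ):
        vol = sc.build_volcano_table(sim_summaries_seed7)
        path = tmp_path / "volcano.tsv"
        sc.write_volcano(vol, path)
        back = sc.read_volcano(path)
        assert back["pool_id"].tolist() == vol["pool_id"].tolist()
        for col in ("percent_of_control", "p_value", "log2_effect"):
            np.testing.assert_allclose(back[col], vol[col], rtol=1e-5)
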