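"""Retrospective annotation, differential abundance, overlap partition."""

import numpy as np
import pandas as pd
import pytest

import dualtrace as dt
from dualtrace.pairing import LibraryEntry


def entry(anchor, mz, rt, origin=("Phe",)):
    return LibraryEntry(anchor, mz, rt, set(origin),
                        labeled_ids={p: {1: f"{anchor}_h"} for p in origin})


def small_query_table(rows, n_samples=2):
    sids = [f"s{i}" for i in range(n_samples)]
    meta = pd.DataFrame({"sample_id": sids, "tissue": "leaf",
                         "genotype": "WT", "replicate": range(1, n_samples + 1)})
    feats = pd.DataFrame(rows, columns=["feature_id", "mz", "rt"])
    for s in sids:
        feats[s] = 10.0
    return dt.validate_table(feats, meta)


class TestAnnotate:
    def test_close_match_within_tolerances(self):
        lib = [entry("M310T325", 310.0935, 325.0, ("Tyr",))]
        table = small_query_table([["q1", 310.0940, 326.0]])
        out = dt.annotate(table, lib, tol_ppm=15, tol_rt=10)
        assert list(out["feature_id"]) == ["q1"]
        assert out.iloc[0]["anchor_id"] == "M310T325"
        assert out.iloc[0]["origin"] == "Tyr"

    def test_mass_gate_rejects(self):
        lib = [entry("M310T325", 310.0935, 325.0)]
        table = small_query_table([["q1", 310.2, 325.0]])
        assert dt.annotate(table, lib).empty

    def test_rt_offset_recovers_drifted_runs(self):
        lib = [entry("a", 310.0935, 325.0)]
        table = small_query_table([["q1", 310.0935, 355.0]])
        assert dt.annotate(table, lib, tol_rt=10).empty
        out = dt.annotate(table, lib, tol_rt=10, rt_offset=30.0)
        assert len(out) == 1

    def test_matches_brute_force_nearest_neighbor(self):
        rng = np.random.default_rng(5)
        lib = [entry(f"L{i}", float(m), float(r))
               for i, (m, r) in enumerate(zip(rng.uniform(100, 900, 40),
                                              rng.uniform(100, 1100, 40)))]
        rows = []
        for i in range(60):
            if i < 40 and rng.random() < 0.7:
                m = lib[i].mz * (1 + rng.normal(0, 5e-6))
                r = lib[i].rt + rng.normal(0, 3)
            else:
                m = rng.uniform(100, 900)
                r = rng.uniform(100, 1100)
            rows.append([f"q{i}", float(m), float(r)])
        table = small_query_table(rows)
        tol_ppm, tol_rt = 15.0, 10.0
        got = dt.annotate(table, lib, tol_ppm=tol_ppm, tol_rt=tol_rt)
        got_map = dict(zip(got["feature_id"], got["anchor_id"]))
        for fid, m, r in rows:
            best = None
            for e in lib:
                tol_mz = tol_ppm * 1e-6 * m
                dmz, drt = abs(e.mz - m), abs(e.rt - r)
                if dmz <= tol_mz and drt <= tol_rt:
                    d = dmz / tol_mz + drt / tol_rt
                    if best is None or d < best[0]:
                        best = (d, e.anchor_id)
            assert got_map.get(fid) == (best[1] if best else None)

    def test_stable_under_library_row_order(self):
        rng = np.random.default_rng(6)
        lib = [entry(f"L{i}", float(m), float(r))
               for i, (m, r) in enumerate(zip(rng.uniform(100, 900, 20),
                                              rng.uniform(100, 1100, 20)))]
        rows = [[f"q{i}", lib[i % 20].mz * (1 + 1e-6), lib[i % 20].rt + 1.0]
                for i in range(20)]
        table = small_query_table(rows)
        a = dt.annotate(table, lib)
        b = dt.annotate(table, list(reversed(lib)))
        pd.testing.assert_frame_equal(
            a.sort_values("feature_id").reset_index(drop=True),
            b.sort_values("feature_id").reset_index(drop=True))

    def test_each_feature_matched_at_most_once(self, default_pipeline):
        table = default_pipeline["table"]
        lib = default_pipeline["library"]
        out = dt.annotate(table, lib)
        assert out["feature_id"].is_unique


def genotype_panel(fold_bmr6, fold_bmr12, cv=0.1, seed=0):
    """Panel of WT + two mutants over a small annotated feature set."""
    rng = np.random.default_rng(seed)
    lib = [entry(f"L{i}", 200.0 + 10 * i, 300.0 + 5 * i) for i in range(20)]
    rows = [[f"L{i}", 200.0 + 10 * i, 300.0 + 5 * i] for i in range(20)]
    sids, meta_rows, cols = [], [], {}
    genotypes = {"WT": {}, "bmr6": fold_bmr6, "bmr12": fold_bmr12}
    sig = np.sqrt(np.log1p(cv ** 2))
    for g, folds in genotypes.items():
        for rep in range(1, 4):
            sid = f"{g}_r{rep}"
            sids.append(sid)
            meta_rows.append((sid, "leaf", g, rep))
            base = 1e5 * np.exp(rng.normal(-sig ** 2 / 2, sig, 20))
            scale = np.array([folds.get(f"L{i}", 1.0) for i in range(20)])
            cols[sid] = base * scale
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "tissue",
                                            "genotype", "replicate"])
    feats = pd.DataFrame(rows, columns=["feature_id", "mz", "rt"])
    for sid in sids:
        feats[sid] = cols[sid]
    table = dt.validate_table(feats, meta)
    groups = {g: [f"{g}_r{r}" for r in range(1, 4)] for g in genotypes}
    annotation = dt.annotate(table, lib)
    return table, annotation, groups


class TestDifferential:
    def test_identical_arms_are_unchanged(self):
        table, annotation, groups = genotype_panel({}, {}, cv=0.1, seed=1)
        res = dt.differential_test(table, annotation, groups, "WT")
        assert (res["direction"] == "unchanged").all()
        assert res["log2_fc"].abs().max() < 0.5

    def test_planted_fourfold_decrease_detected(self):
        """A planted 4x decrease at CV 0.1, n=3 comes back 'down' with
        log2 fold change near -2."""
        folds = {f"L{i}": 0.25 for i in range(5)}
        table, annotation, groups = genotype_panel(folds, {}, seed=2)
        res = dt.differential_test(table, annotation, groups, "WT")
        hit = res[(res["genotype"] == "bmr6")
                  & (res["feature_id"].isin(folds))]
        assert (hit["direction"] == "down").all()
        np.testing.assert_allclose(hit["log2_fc"], -2.0, atol=0.3)

    def test_p_matches_welch_formula(self):
        from test_enrichment import welch_two_sided_oracle
        table, annotation, groups = genotype_panel({"L0": 0.5}, {}, seed=3)
        res = dt.differential_test(table, annotation, groups, "WT")
        row = res[(res["feature_id"] == "L0")
                  & (res["genotype"] == "bmr6")].iloc[0]
        wt = np.log2(table.features.loc["L0", groups["WT"]]
                     .to_numpy(float) + 1)
        mut = np.log2(table.features.loc["L0", groups["bmr6"]]
                      .to_numpy(float) + 1)
        assert row["p_value"] == pytest.approx(
            welch_two_sided_oracle(mut, wt), abs=1e-10)

    def test_insufficient_replicates_raise(self):
        table, annotation, groups = genotype_panel({}, {}, seed=4)
        groups["bmr6"] = groups["bmr6"][:1]
        with pytest.raises(dt.DesignError):
            dt.differential_test(table, annotation, groups, "WT")


class TestPartitionOverlap:
    def frame(self, directions):
        return pd.DataFrame([{"feature_id": fid, "anchor_id": fid,
                              "genotype": "m", "log2_fc": 1.0,
                              "p_value": 0.01, "direction": d,
                              "mol_bias_context": 0.0}
                             for fid, d in directions.items()])

    def test_no_significant_features(self):
        a = self.frame({"f1": "unchanged"})
        b = self.frame({"f1": "unchanged"})
        counts = dt.partition_overlap(a, b)
        assert all(v == 0 for v in counts.values())

    def test_shared_decrease_counted_once(self):
        a = self.frame({"f1": "down", "f2": "down"})
        b = self.frame({"f1": "down", "f3": "up"})
        counts = dt.partition_overlap(a, b)
        assert counts == {"down_a_only": 1, "down_b_only": 0,
                          "down_both": 1, "up_a_only": 0, "up_b_only": 1,
                          "up_both": 0, "opposing": 0}

    def test_opposing_direction_is_possible(self):
        a = self.frame({"f1": "up"})
        b = self.frame({"f1": "down"})
        assert dt.partition_overlap(a, b)["opposing"] == 1

    def test_counts_sum_to_significant_union(self):
        rng = np.random.default_rng(8)
        opts = ("up", "down", "unchanged")
        a = self.frame({f"f{i}": opts[rng.integers(3)] for i in range(50)})
        b = self.frame({f"f{i}": opts[rng.integers(3)] for i in range(50)})
        counts = dt.partition_overlap(a, b)
        sig = {f"f{i}" for i in range(50)} & (
            set(a[a["direction"] != "unchanged"]["feature_id"])
            | set(b[b["direction"] != "unchanged"]["feature_id"]))
        assert sum(counts.values()) == len(sig)


class TestLibraryIO:
    def test_round_trip(self, default_pipeline, tmp_path):
        lib = default_pipeline["library"]
        dt.write_library(lib, tmp_path / "lib.csv")
        back = dt.read_library(tmp_path / "lib.csv")
        assert len(back) == len(lib)
        for a, b in zip(lib, back):
            assert a.anchor_id == b.anchor_id
            assert a.origin == b.origin
            assert a.labeled_ids == b.labeled_ids
            assert a.dual_labeled == b.dual_labeled
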