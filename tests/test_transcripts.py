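"""Gene-family parsing, CPM renormalization, S/D aggregation and comparison."""

import numpy as np
import pandas as pd
import pytest

from fibervit.annotation import VitaminAnnotationRecord, VitaminAnnotationTable
from fibervit.transcripts import (
    StratifiedAbundanceTable,
    aggregate_vitamin_roles,
    compare_sd,
    log2_sd_ratio,
    read_genefamilies,
    taxon_contributions,
    to_cpm,
)

from .conftest import make_stratified


def ann_of(*triples):
    return VitaminAnnotationTable([VitaminAnnotationRecord(f, v, r) for f, v, r in triples])


def meta_of(samples, diets, colonization="SPF"):
    return pd.DataFrame(
        {"diet_group": diets, "colonization": colonization, "batch": 1},
        index=pd.Index(samples, name="sample_id"),
    )


class TestReadGenefamilies:
    def test_parse_fixture_with_strata(self, tmp_path):
        p = tmp_path / "gf.tsv"
        p.write_text(
            "# Gene Family\ts1\ts2\n"
            "F1\t10\t20\n"
            "F1|g__A.s__a\t6\t12\n"
            "F2\t5\t5\n"
        )
        t = read_genefamilies(p)
        assert t.totals().shape == (2, 2)
        assert t.strata().shape == (1, 2)

    def test_empty_data_section(self, tmp_path):
        p = tmp_path / "gf.tsv"
        p.write_text("# Gene Family\ts1\ts2\n")
        t = read_genefamilies(p)
        assert t.data.empty

    def test_stratum_exceeding_total_rejected(self, tmp_path):
        p = tmp_path / "gf.tsv"
        p.write_text("# Gene Family\ts1\nF1\t10\nF1|g__A.s__a\t11\n")
        with pytest.raises(ValueError, match="exceed"):
            read_genefamilies(p)

    def test_stratum_without_total_rejected(self, tmp_path):
        p = tmp_path / "gf.tsv"
        p.write_text("# Gene Family\ts1\nF1|g__A.s__a\t5\n")
        with pytest.raises(ValueError, match="without a TOTAL"):
            read_genefamilies(p)

    def test_duplicate_row_rejected(self, tmp_path):
        p = tmp_path / "gf.tsv"
        p.write_text("# Gene Family\ts1\nF1\t5\nF1\t6\n")
        with pytest.raises(ValueError, match="duplicated"):
            read_genefamilies(p)

    def test_malformed_cell_located(self, tmp_path):
        p = tmp_path / "gf.tsv"
        p.write_text("# Gene Family\ts1\ts2\nF1\t5\toops\n")
        with pytest.raises(ValueError, match="s2"):
            read_genefamilies(p)


class TestToCpm:
    def test_forced_arithmetic(self):
        t = make_stratified({"F1": [30.0], "F2": [70.0]}, ["s1"])
        cpm = to_cpm(t)
        assert cpm.totals().loc["F1", "s1"] == pytest.approx(3e5)
        assert cpm.totals().loc["F2", "s1"] == pytest.approx(7e5)
        assert cpm.units == "cpm"

    def test_normalization_invariant_random(self, rng):
        vals = rng.integers(1, 1000, size=(8, 5)).astype(float)
        t = make_stratified(
            {f"F{i}": list(vals[i]) for i in range(8)}, [f"s{j}" for j in range(5)]
        )
        cpm = to_cpm(t)
        assert cpm.totals().sum(axis=0).to_numpy() == pytest.approx([1e6] * 5, abs=1e-3)

    def test_strata_scaled_by_same_factor(self):
        t = make_stratified({"F1": [100.0], "F1|g__A.s__a": [40.0], "F2": [100.0]}, ["s1"])
        cpm = to_cpm(t)
        assert cpm.data.loc[("F1", "g__A.s__a"), "s1"] == pytest.approx(0.4 * cpm.totals().loc["F1", "s1"])

    def test_idempotence_refused(self):
        t = make_stratified({"F1": [30.0]}, ["s1"])
        with pytest.raises(ValueError, match="expects counts"):
            to_cpm(to_cpm(t))

    def test_zero_total_sample_refused(self):
        t = make_stratified({"F1": [0.0, 5.0]}, ["s1", "s2"])
        with pytest.raises(ValueError, match="s1"):
            to_cpm(t)


class TestAggregateVitaminRoles:
    def test_hand_arithmetic(self):
        t = make_stratified({"FS": [400.0], "FD": [100.0]}, ["s1"], units="cpm")
        vra = aggregate_vitamin_roles(t, ann_of(("FS", "B2", "S"), ("FD", "B2", "D")))
        un = vra.unstratified.set_index(["vitamin", "role"])["relab"]
        assert un.loc[("B2", "S")] == pytest.approx(0.04)
        assert un.loc[("B2", "D")] == pytest.approx(0.01)

    def test_empty_annotation_all_zero(self):
        t = make_stratified({"F1": [400.0]}, ["s1"], units="cpm")
        vra = aggregate_vitamin_roles(t, VitaminAnnotationTable([]))
        assert vra.unstratified.empty or (vra.unstratified["relab"] == 0).all()

    def test_stratified_hand_arithmetic(self):
        t = make_stratified(
            {"FS": [400.0], "FS|taxonA": [300.0], "FS|unclassified": [100.0]},
            ["s1"],
            units="cpm",
        )
        vra = aggregate_vitamin_roles(t, ann_of(("FS", "B2", "S")))
        st = vra.stratified.set_index("taxon")["relab"]
        assert st.loc["taxonA"] / st.sum() == pytest.approx(0.75)
        assert st.loc["unclassified"] / st.sum() == pytest.approx(0.25)

    def test_transport_excluded_by_default_mergeable_by_flag(self):
        ann = ann_of(("FS", "B2", "S"), ("FD", "B2", "D"), ("FT", "B2", "T"))
        t = make_stratified({"FS": [100.0], "FD": [100.0], "FT": [100.0]}, ["s1"], units="cpm")
        d_default = aggregate_vitamin_roles(t, ann).unstratified.set_index(["vitamin", "role"])["relab"]
        d_merged = aggregate_vitamin_roles(t, ann, transport_as_downstream=True).unstratified.set_index(
            ["vitamin", "role"]
        )["relab"]
        assert d_merged.loc[("B2", "D")] == pytest.approx(2 * d_default.loc[("B2", "D")])

    def test_matches_bruteforce_oracle(self, rng, demo_ann):
        # <=20 features: independent loop over annotation records
        feats = [r.feature_id for r in demo_ann.records][:12] + ["BG1", "BG2"]
        samples = [f"s{j}" for j in range(4)]
        vals = rng.uniform(0, 500, size=(len(feats), 4))
        t = make_stratified({f: list(vals[i]) for i, f in enumerate(feats)}, samples, units="cpm")
        vra = aggregate_vitamin_roles(t, demo_ann)
        un = vra.unstratified.set_index(["sample", "vitamin", "role"])["relab"]
        for vit in sorted(demo_ann.vitamins_covered):
            for role in ("S", "D"):
                members = demo_ann.by_role(vit, role)
                for j, s in enumerate(samples):
                    expected = sum(vals[feats.index(f), j] for f in members if f in feats)
                    assert un.loc[(s, vit, role)] == pytest.approx(100 * expected / 1e6)

    def test_conservation_of_strata(self, rng, demo_ann):
        from fibervit.synthdata import SimConfig, gen_metatranscriptome

        table, _ = gen_metatranscriptome(SimConfig(seed=5, groups=[("IN", "SPF", 2), ("FF", "SPF", 2)]))
        vra = aggregate_vitamin_roles(to_cpm(table), demo_ann)
        st = vra.stratified.groupby(["sample", "vitamin", "role"])["relab"].sum()
        un = vra.unstratified.set_index(["sample", "vitamin", "role"])["relab"]
        for key, total in un.items():
            if total > 0:
                assert st.loc[key] == pytest.approx(total, rel=1e-6)

    def test_scale_equivariance(self, demo_ann):
        from fibervit.synthdata import SimConfig, gen_metatranscriptome

        table, _ = gen_metatranscriptome(SimConfig(seed=9, groups=[("IN", "SPF", 2), ("FF", "SPF", 2)]))
        scaled = StratifiedAbundanceTable(table.data * 3.7, units="counts", sample_meta=table.sample_meta)
        r1 = log2_sd_ratio(aggregate_vitamin_roles(to_cpm(table), demo_ann)).table
        r2 = log2_sd_ratio(aggregate_vitamin_roles(to_cpm(scaled), demo_ann)).table
        assert np.allclose(r1["log2_ratio"], r2["log2_ratio"])


class TestLog2SdRatio:
    def _vra(self, s, d, samples):
        rows = []
        for i, samp in enumerate(samples):
            rows.append((samp, "B2", "S", s[i]))
            rows.append((samp, "B2", "D", d[i]))
        from fibervit.transcripts import VitaminRoleAbundance

        return VitaminRoleAbundance(
            pd.DataFrame(rows, columns=["sample", "vitamin", "role", "relab"]),
            pd.DataFrame(columns=["sample", "vitamin", "role", "taxon", "relab"]),
        )

    def test_plain_ratio_no_zeros(self):
        sdr = log2_sd_ratio(self._vra([0.04, 0.04], [0.01, 0.01], ["s1", "s2"]))
        assert sdr.table["log2_ratio"].to_numpy() == pytest.approx([2.0, 2.0])
        assert not sdr.table["pseudocount_applied"].any()

    def test_pseudocount_applied_to_all_samples(self):
        sdr = log2_sd_ratio(self._vra([0.0, 0.04], [0.0, 0.01], ["s1", "s2"]))
        tab = sdr.table.set_index("sample")
        assert tab["pseudocount_applied"].all()
        assert tab.loc["s1", "log2_ratio"] == 0.0  # log2(1/1)
        assert tab.loc["s2", "log2_ratio"] == pytest.approx(np.log2(1.04 / 1.01))

    def test_cpm_scale_flag(self):
        sdr = log2_sd_ratio(self._vra([0.04, 0.0], [0.01, 0.0], ["s1", "s2"]), pseudocount_scale="cpm")
        tab = sdr.table.set_index("sample")
        assert tab.loc["s1", "log2_ratio"] == pytest.approx(np.log2(401 / 101))


class TestCompareSd:
    def _sdr(self, ratios_a, ratios_b):
        from fibervit.transcripts import SDRatioTable

        samples = [f"a{i}" for i in range(len(ratios_a))] + [f"b{i}" for i in range(len(ratios_b))]
        rows = [(s, "B2", 1.0, 1.0, r, False) for s, r in zip(samples, ratios_a + ratios_b)]
        meta = meta_of(samples, ["IN"] * len(ratios_a) + ["FF"] * len(ratios_b))
        return SDRatioTable(
            pd.DataFrame(rows, columns=["sample", "vitamin", "S", "D", "log2_ratio", "pseudocount_applied"]),
            sample_meta=meta,
        )

    def test_identical_groups_p_one(self):
        res = compare_sd(self._sdr([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]), "IN", "FF")
        assert res["B2"].p_raw == pytest.approx(1.0)

    def test_swapped_labels_flip_sign_same_p(self):
        sdr = self._sdr([2.0, 2.5, 3.0, 2.2], [0.5, 1.0, 0.8, 0.4])
        ab = compare_sd(sdr, "IN", "FF")["B2"]
        ba = compare_sd(sdr, "FF", "IN")["B2"]
        assert ab.p_raw == pytest.approx(ba.p_raw)
        assert ab.direction == -ba.direction == 1.0

    def test_degenerate_group_skipped(self):
        res = compare_sd(self._sdr([1.0], [1.0, 2.0, 3.0]), "IN", "FF")
        assert "B2" not in res

    def test_planted_direction_recovered(self, demo_ann):
        from fibervit.synthdata import SimConfig, gen_metatranscriptome

        hits = 0
        for seed in range(10):
            cfg = SimConfig(seed=seed, groups=[("IN", "SPF", 4), ("FF", "SPF", 4)])
            table, truth = gen_metatranscriptome(cfg, demo_ann)
            sdr = log2_sd_ratio(aggregate_vitamin_roles(to_cpm(table), demo_ann))
            res = compare_sd(sdr, "IN", "FF")
            hits += all(res[v].direction == 1.0 for v in truth["planted_sd_effects"])
        assert hits >= 9


class TestTaxonContributions:
    def test_single_taxon_holds_all_signal(self):
        t = make_stratified({"FS": [100.0], "FS|taxA": [100.0]}, ["s1"], units="cpm")
        vra = aggregate_vitamin_roles(t, ann_of(("FS", "B2", "S")))
        tc = taxon_contributions(vra, "B2", "S")
        top = tc[tc["rank"] == 1].iloc[0]
        assert top["taxon"] == "taxA"
        assert top["mean_relab"] == pytest.approx(0.01)  # 100 CPM as %
        assert tc.set_index("taxon").loc["unclassified", "mean_relab"] == pytest.approx(0.0)

    def test_two_taxon_split(self):
        t = make_stratified(
            {"FS": [100.0], "FS|taxA": [75.0], "FS|taxB": [25.0]}, ["s1"], units="cpm"
        )
        vra = aggregate_vitamin_roles(t, ann_of(("FS", "B2", "S")))
        tc = taxon_contributions(vra, "B2", "S").set_index("taxon")
        assert tc.loc["taxA", "mean_relab"] / tc.loc["taxB", "mean_relab"] == pytest.approx(3.0)
        assert tc.loc["taxA", "rank"] == 1

    def test_group_means_recompute_from_raw_strata(self, demo_ann):
        from fibervit.synthdata import SimConfig, gen_metatranscriptome

        table, _ = gen_metatranscriptome(SimConfig(seed=2, groups=[("IN", "SPF", 3), ("FF", "SPF", 3)]))
        vra = aggregate_vitamin_roles(to_cpm(table), demo_ann)
        tc = taxon_contributions(vra, "B2", "S")
        sub = vra.stratified[(vra.stratified["vitamin"] == "B2") & (vra.stratified["role"] == "S")]
        groups = vra.sample_meta["colonization"] + ":" + vra.sample_meta["diet_group"]
        for _, row in tc.iterrows():
            samples = groups.index[groups == row["group"]]
            raw = sub[sub["sample"].isin(samples) & (sub["taxon"] == row["taxon"])]["relab"]
            assert row["mean_relab"] == pytest.approx(raw.mean(), abs=1e-9)

    def test_no_strata_empty(self):
        t = make_stratified({"FS": [100.0]}, ["s1"], units="cpm")
        vra = aggregate_vitamin_roles(t, ann_of(("FX", "B2", "S")))
        assert taxon_contributions(vra, "B2", "S").empty
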