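"""Methylation levels, DMC/DMR calling rules, consensus intersection,
DMR characterization and metagene profiles."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rddmkit import methylome as my
from rddmkit.methylome import (
    CytosineTable,
    call_dmcs,
    call_dmrs,
    characterize_dmrs,
    consensus_hypo_dmrs,
    dmr_set_overlap,
    metagene_profile,
    methylation_level,
    region_weighted_methylation,
    weighted_level,
)


def make_table(rows, n_reps=1, conditions=("A", "B")):
    """Build a CytosineTable from (chrom, pos, context, (mA, uA), (mB, uB))
    tuples; replicate counts are split as evenly as the integers allow."""
    samples = {}
    data = {
        "chrom": [r[0] for r in rows],
        "pos": [r[1] for r in rows],
        "strand": ["+"] * len(rows),
        "context": [r[2] for r in rows],
    }
    for ci, cond in enumerate(conditions):
        for rep in range(1, n_reps + 1):
            name = f"{cond}_{rep}"
            samples[name] = cond
            ms, us = [], []
            for r in rows:
                m, u = r[3 + ci]
                share_m = m // n_reps + (1 if rep <= m % n_reps else 0)
                share_u = u // n_reps + (1 if rep <= u % n_reps else 0)
                ms.append(share_m)
                us.append(share_u)
            data[f"meth_{name}"] = ms
            data[f"unmeth_{name}"] = us
    return CytosineTable(pd.DataFrame(data), samples)


class TestLevels:
    def test_per_site_level(self):
        assert methylation_level(5, 0) == 1.0
        assert methylation_level(0, 7) == 0.0
        assert methylation_level(3, 9) == 0.25
        assert math.isnan(methylation_level(0, 0))

    def test_weighted_level_is_count_weighted_not_mean_of_ratios(self):
        assert weighted_level([2, 8], [8, 2]) == 0.5
        # one fully methylated shallow site against one deep unmethylated site
        assert weighted_level([1, 0], [0, 100]) == pytest.approx(1 / 101)
        assert weighted_level([5, 9], [0, 0]) == 1.0
        assert math.isnan(weighted_level([], []))

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.lists(st.tuples(st.integers(0, 30), st.integers(0, 30)), min_size=1, max_size=8),
        st.lists(st.tuples(st.integers(0, 30), st.integers(0, 30)), min_size=1, max_size=8),
    )
    def test_weighted_level_combines_disjoint_subsets(self, part_a, part_b):
        """The weighted level of a union equals the count-weighted
        combination of its disjoint parts."""
        ma, ua = sum(p[0] for p in part_a), sum(p[1] for p in part_a)
        mb, ub = sum(p[0] for p in part_b), sum(p[1] for p in part_b)
        whole = weighted_level(
            [p[0] for p in part_a + part_b], [p[1] for p in part_a + part_b]
        )
        if ma + ua + mb + ub == 0:
            assert math.isnan(whole)
        else:
            la, lb = weighted_level([ma], [ua]), weighted_level([mb], [ub])
            wa, wb = ma + ua, mb + ub
            combined = (
                (0 if math.isnan(la) else la * wa) + (0 if math.isnan(lb) else lb * wb)
            ) / (wa + wb)
            assert whole == pytest.approx(combined, abs=1e-12)


class TestDMC:
    def test_strong_difference_called_with_known_p(self):
        table = make_table([("c1", 100, "CG", (9, 1), (1, 9))])
        dmcs = call_dmcs(table, "A", "B")
        assert len(dmcs) == 1
        row = dmcs.iloc[0]
        assert row["direction"] == "hyper"
        assert row["p"] == pytest.approx(202 / 184756, abs=1e-12)
        assert row["diff"] == pytest.approx(0.8)

    def test_depth_rule_blocks_shallow_sites(self):
        table = make_table([("c1", 100, "CG", (2, 0), (0, 2))])
        assert call_dmcs(table, "A", "B").empty

    def test_difference_rule_blocks_small_deltas(self):
        table = make_table([("c1", 100, "CG", (6, 4), (4, 6))])
        assert call_dmcs(table, "A", "B").empty

    def test_replicates_are_pooled_before_testing(self):
        single = make_table([("c1", 100, "CG", (9, 1), (1, 9))], n_reps=1)
        split = make_table([("c1", 100, "CG", (9, 1), (1, 9))], n_reps=2)
        a = call_dmcs(single, "A", "B")
        b = call_dmcs(split, "A", "B")
        assert a["p"].iloc[0] == b["p"].iloc[0]

    def test_swap_of_conditions_flips_direction_same_p(self, small_dataset):
        cyt = small_dataset.cytosines
        fwd = call_dmcs(cyt, "R", "normal")
        rev = call_dmcs(cyt, "normal", "R")
        assert len(fwd) == len(rev)
        merged = fwd.merge(rev, on=["chrom", "pos"], suffixes=("_f", "_r"))
        assert len(merged) == len(fwd)
        assert np.allclose(merged["p_f"], merged["p_r"], atol=1e-12)
        flip = {"hypo": "hyper", "hyper": "hypo"}
        assert (merged["direction_r"] == merged["direction_f"].map(flip)).all()

    def test_monotone_in_thresholds(self, small_dataset):
        cyt = small_dataset.cytosines
        strict = call_dmcs(cyt, "R", "normal", p_thresh=0.01, min_diff=0.4)
        loose = call_dmcs(cyt, "R", "normal", p_thresh=0.05, min_diff=0.33)
        strict_keys = set(zip(strict["chrom"], strict["pos"]))
        loose_keys = set(zip(loose["chrom"], loose["pos"]))
        assert strict_keys <= loose_keys

    def test_absent_condition_raises(self):
        table = make_table([("c1", 100, "CG", (9, 1), (1, 9))])
        with pytest.raises(ValueError, match="nope"):
            call_dmcs(table, "A", "nope")


def _dmc_frame(positions, direction="hypo", context="CHH", chrom="c1"):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "strand": "+",
            "context": context,
            "m_a": 0, "u_a": 10, "m_b": 10, "u_b": 0,
            "level_a": 0.0, "level_b": 1.0,
            "diff": -1.0 if direction == "hypo" else 1.0,
            "direction": direction,
            "p": 1e-4,
        }
    )


def _backing_table(positions, chrom="c1", context="CHH"):
    return make_table([(chrom, p, context, (0, 10), (10, 0)) for p in positions])


class TestDMR:
    def test_run_within_gap_becomes_one_region(self):
        pos = [100, 300, 550]
        dmrs = call_dmrs(_dmc_frame(pos), _backing_table(pos), "A", "B")
        assert len(dmrs) == 1
        row = dmrs.iloc[0]
        assert (row["start"], row["end"]) == (100, 551)
        assert row["n_dmcs"] == 3
        assert row["direction"] == "hypo"

    def test_fewer_than_min_dmcs_is_no_region(self):
        pos = [100, 300]
        assert call_dmrs(_dmc_frame(pos), _backing_table(pos), "A", "B").empty

    def test_gap_above_max_splits_runs(self):
        pos = [100, 450, 800]
        assert call_dmrs(_dmc_frame(pos), _backing_table(pos), "A", "B").empty

    def test_region_p_uses_all_cytosines_in_span(self):
        # a non-DMC site with opposing counts inside the span weakens the
        # pooled test relative to the member DMCs alone
        dmc_pos = [100, 300, 550]
        table = make_table(
            [("c1", p, "CHH", (0, 10), (10, 0)) for p in dmc_pos]
            + [("c1", 200, "CHH", (10, 0), (0, 10))]
        )
        dmrs = call_dmrs(_dmc_frame(dmc_pos), table, "A", "B")
        members_only = call_dmrs(_dmc_frame(dmc_pos), _backing_table(dmc_pos), "A", "B")
        assert dmrs.iloc[0]["p"] > members_only.iloc[0]["p"]
        assert dmrs.iloc[0]["level_a"] == pytest.approx(10 / 40)

    def test_reported_dmrs_satisfy_their_invariants(self, small_dataset, small_result):
        cyt = small_dataset.cytosines
        for dmrs, cond_b in (
            (small_result.dmrs_r_vs_normal, "normal"),
            (small_result.dmrs_r_vs_fr, "FR"),
        ):
            assert (dmrs["n_dmcs"] >= 3).all()
            assert (dmrs["p"] <= 0.05).all()
            for row in dmrs.itertuples():
                la = region_weighted_methylation(cyt, "R", row.chrom, row.start, row.end, row.context)
                lb = region_weighted_methylation(cyt, cond_b, row.chrom, row.start, row.end, row.context)
                assert la == pytest.approx(row.level_a, abs=1e-12)
                assert lb == pytest.approx(row.level_b, abs=1e-12)
                if row.direction == "hypo":
                    assert la < lb


def _dmr_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "context", "direction", "n_dmcs",
                 "level_a", "level_b", "p"],
    )


class TestConsensus:
    def test_intersection_of_overlapping_pair(self):
        a = _dmr_frame([("c1", 100, 400, "CHH", "hypo", 3, 0.1, 0.5, 1e-3)])
        b = _dmr_frame([("c1", 300, 600, "CHH", "hypo", 4, 0.2, 0.6, 1e-3)])
        cons = consensus_hypo_dmrs(a, b)
        assert len(cons) == 1
        assert (cons.iloc[0]["start"], cons.iloc[0]["end"]) == (300, 400)
        assert cons.iloc[0]["level_diff"] == pytest.approx(0.4)

    def test_disjoint_inputs_give_nothing(self):
        a = _dmr_frame([("c1", 100, 200, "CHH", "hypo", 3, 0.1, 0.5, 1e-3)])
        b = _dmr_frame([("c1", 300, 400, "CHH", "hypo", 3, 0.1, 0.5, 1e-3)])
        assert consensus_hypo_dmrs(a, b).empty

    def test_identical_regions_are_their_own_consensus(self):
        a = _dmr_frame([("c1", 100, 400, "CHG", "hypo", 3, 0.1, 0.5, 1e-3)])
        cons = consensus_hypo_dmrs(a, a.copy())
        assert (cons.iloc[0]["start"], cons.iloc[0]["end"]) == (100, 400)

    def test_contexts_do_not_mix(self):
        a = _dmr_frame([("c1", 100, 400, "CHH", "hypo", 3, 0.1, 0.5, 1e-3)])
        b = _dmr_frame([("c1", 100, 400, "CHG", "hypo", 3, 0.1, 0.5, 1e-3)])
        assert consensus_hypo_dmrs(a, b).empty

    def test_hyper_input_rejected(self):
        a = _dmr_frame([("c1", 100, 400, "CHH", "hyper", 3, 0.5, 0.1, 1e-3)])
        with pytest.raises(ValueError):
            consensus_hypo_dmrs(a, a)


class TestCharacterizeAndOverlap:
    def test_one_dmr_per_category_gives_quarters(self, toy_annotation):
        dmrs = _dmr_frame(
            [
                ("chr1", 3900, 4100, "CHH", "hypo", 3, 0.1, 0.5, 1e-3),   # promoter
                ("chr1", 5400, 5600, "CHH", "hypo", 3, 0.1, 0.5, 1e-3),   # exon
                ("chr1", 9050, 9200, "CHH", "hypo", 3, 0.1, 0.5, 1e-3),   # TE
                ("chr1", 18000, 18100, "CHH", "hypo", 3, 0.1, 0.5, 1e-3),  # intergenic
            ]
        )
        comp = characterize_dmrs(dmrs, toy_annotation)
        assert comp.to_dict() == {
            "TE": 0.25, "gene_body": 0.25, "intergenic": 0.25, "promoter": 0.25
        }
        assert comp.sum() == pytest.approx(1.0)

    def test_straddling_dmr_assigned_by_midpoint(self, toy_annotation):
        # [4800, 5100) straddles promoter/exon; midpoint 4950 is promoter
        dmrs = _dmr_frame([("chr1", 4800, 5100, "CHH", "hypo", 3, 0.1, 0.5, 1e-3)])
        comp = characterize_dmrs(dmrs, toy_annotation)
        assert comp.to_dict() == {"promoter": 1.0}

    def test_empty_set_gives_empty_composition(self, toy_annotation):
        comp = characterize_dmrs(_dmr_frame([]), toy_annotation)
        assert comp.empty
        assert not comp.isna().any()

    def test_set_overlap_counting_convention(self):
        a3 = _dmr_frame([("c1", i * 1000, i * 1000 + 100, "CHH", "hypo", 3, 0.1, 0.5, 1e-3) for i in range(3)])
        b2 = _dmr_frame([("c1", 5000 + i * 1000, 5100 + i * 1000, "CHH", "hypo", 3, 0.1, 0.5, 1e-3) for i in range(2)])
        res = dmr_set_overlap(a3, b2)
        assert (res.unique_a, res.unique_b, res.overlapping_a, res.overlapping_b) == (3, 2, 0, 0)
        same = dmr_set_overlap(a3, a3.copy())
        assert (same.unique_a, same.unique_b, same.overlapping_a, same.overlapping_b) == (0, 0, 3, 3)
        # one A region spanning two B regions: A-side 1, B-side 2
        a1 = _dmr_frame([("c1", 0, 5000, "CHH", "hypo", 3, 0.1, 0.5, 1e-3)])
        b = _dmr_frame(
            [("c1", 100, 200, "CHH", "hypo", 3, 0.1, 0.5, 1e-3),
             ("c1", 3000, 3200, "CHH", "hypo", 3, 0.1, 0.5, 1e-3)]
        )
        res = dmr_set_overlap(a1, b)
        assert (res.overlapping_a, res.overlapping_b) == (1, 2)


class TestMetagene:
    def test_uniform_methylome_gives_flat_profile(self, toy_annotation):
        rng = np.random.default_rng(0)
        rows = []
        for chrom, clen in toy_annotation.chromosomes.items():
            for pos in range(0, clen, 3):
                rows.append((chrom, pos, "CHH", (int(rng.binomial(20, 0.5)), 0)))
        rows = [(c, p, x, (m, 20 - m), (m, 20 - m)) for (c, p, x, (m, _)) in rows]
        table = make_table(rows)
        prof = metagene_profile(toy_annotation, table, "CHH", "A", flank=2000, bins=20)
        assert prof.values.shape == (60,)
        assert np.nanmax(np.abs(prof.values - 0.5)) < 0.05

    def test_bin_boundaries_partition_each_region_exactly(self, toy_annotation):
        # every covered cytosine lands in exactly one bin: totals add up
        rows = [("chr1", p, "CG", (1, 1), (1, 1)) for p in range(3000, 10000, 11)]
        table = make_table(rows)
        prof = metagene_profile(toy_annotation, table, "CG", "A")
        in_range = sum(
            1 for p in range(3000, 10000, 11) if 5000 - 2000 <= p < 8000 + 2000
        )
        assert prof.total.sum() == in_range * 2

    def test_short_genes_skipped_with_warning(self):
        genes = pd.DataFrame(
            [("tiny", "c1", 100, 110, "+"), ("ok", "c1", 2000, 4000, "+")],
            columns=["gene_id", "chrom", "start", "end", "strand"],
        )
        from rddmkit.annotation import GenomeAnnotation, derive_promoters

        ann = derive_promoters(
            GenomeAnnotation(
                {"c1": 10000},
                genes,
                pd.DataFrame(columns=["gene_id", "chrom", "start", "end"]),
                pd.DataFrame(columns=["chrom", "start", "end"]),
            ),
            500,
        )
        table = make_table([("c1", 3000, "CG", (1, 1), (1, 1))])
        with pytest.warns(UserWarning, match="skipped 1 genes"):
            prof = metagene_profile(ann, table, "CG", "A")
        assert prof.n_skipped == 1

    def test_planted_promoter_hypo_depresses_tss_proximal_bins(self, small_dataset):
        """Under red light the planted promoter windows pull the CHH level
        of the TSS-adjacent upstream bins below both the distal bins and the
        far-red profile, mirroring the generating means."""
        prof_r = metagene_profile(
            small_dataset.annotation, small_dataset.cytosines, "CHH", "R"
        )
        prof_fr = metagene_profile(
            small_dataset.annotation, small_dataset.cytosines, "CHH", "FR"
        )
        # windows cover the kilobase next to the TSS: upstream bins 10..19
        proximal_r = np.nanmean(prof_r.values[10:20])
        distal_r = np.nanmean(prof_r.values[0:5])
        proximal_fr = np.nanmean(prof_fr.values[10:20])
        assert proximal_fr > proximal_r  # planted hypo-methylation under R
        assert proximal_r < distal_r + 0.02


def test_region_weighted_methylation_matches_manual_sum(small_dataset):
    cyt = small_dataset.cytosines
    sub = cyt.data.iloc[:50]
    chrom = sub["chrom"].iloc[0]
    lo, hi = int(sub["pos"].min()), int(sub["pos"].max()) + 1
    got = region_weighted_methylation(cyt, "normal", chrom, lo, hi)
    cols_m = [f"meth_{s}" for s, c in cyt.samples.items() if c == "normal"]
    cols_u = [f"unmeth_{s}" for s, c in cyt.samples.items() if c == "normal"]
    sel = (cyt.data["chrom"] == chrom) & (cyt.data["pos"] >= lo) & (cyt.data["pos"] < hi)
    m = cyt.data.loc[sel, cols_m].to_numpy().sum()
    u = cyt.data.loc[sel, cols_u].to_numpy().sum()
    assert got == pytest.approx(m / (m + u))
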