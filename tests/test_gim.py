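"""GIM selection (matrix.ref/matrix.out), bipartite clustering, merging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import metabotyper as mt
from metabotyper.conditional import final_joint, pool_cohorts, stepwise_conditional
from metabotyper.gim import GIM, GimMatrix, cluster_gims, gim_select, merge_adjacent
from metabotyper.regions import Region
from metabotyper.synthetic_data import (CausalEntry, StudyConfig, TruthTable,
                                        VariantSpec, beta_for_variance,
                                        simulate_genotypes, simulate_study)
from conftest import metabolite_partition_labels


def _matrix(entries: dict, metabolites, region="R1"):
    """GimMatrix from {variant: {metabolite: signed mlog10p}}."""
    df = pd.DataFrame(entries).T.reindex(columns=metabolites).fillna(0.0)
    return GimMatrix(region_id=region, entries=df,
                     marker_order={v: i + 1 for i, v in enumerate(df.index)})


def test_shared_metabolite_merges_variants_into_one_gim():
    m = _matrix({"v1": {"m1": 30.0}, "v2": {"m1": -12.0}}, ["m1"])
    gims = cluster_gims(m)
    assert len(gims) == 1
    assert set(gims[0].variants) == {"v1", "v2"}
    assert gims[0].metabolites == ("m1",)


def test_four_gim_block_structure_recovered():
    # two variants -> {m1, m2}; four -> {m3, m4, m5}; one -> {m6}; one -> {m7}
    entries = {
        "v1": {"m1": 40.0, "m2": 20.0}, "v2": {"m1": 15.0, "m2": 9.0},
        "v3": {"m3": 35.0}, "v4": {"m4": 30.0, "m5": 12.0},
        "v5": {"m3": 10.0, "m4": 9.0}, "v6": {"m5": 22.0},
        "v7": {"m6": 18.0}, "v8": {"m7": 11.0},
    }
    mets = [f"m{i}" for i in range(1, 8)]
    gims = cluster_gims(_matrix(entries, mets))
    assert len(gims) == 4
    groups = sorted(tuple(sorted(g.metabolites)) for g in gims)
    assert groups == [("m1", "m2"), ("m3", "m4", "m5"), ("m6",), ("m7",)]


def test_subthreshold_entries_do_not_cluster():
    # -log10(6e-8) < -log10(5e-8): the association is not significant
    m = _matrix({"v1": {"m1": -np.log10(6e-8)},
                 "v2": {"m2": 30.0}}, ["m1", "m2"])
    gims = cluster_gims(m)
    assert len(gims) == 1
    assert gims[0].metabolites == ("m2",)


def test_empty_matrix_gives_no_gims():
    m = GimMatrix("R1", pd.DataFrame(columns=["m1"]), {})
    assert cluster_gims(m) == []


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 5), st.integers(0, 5)),
                min_size=1, max_size=14))
def test_components_match_union_find_oracle(edges):
    entries = {}
    for vi, mj in edges:
        entries.setdefault(f"v{vi}", {})[f"m{mj}"] = 20.0
    mets = sorted({f"m{mj}" for _, mj in edges})
    gims = cluster_gims(_matrix(entries, mets))

    # independent union-find over the same bipartite edges
    parent = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for vi, mj in edges:
        a, b = find(("v", f"v{vi}")), find(("m", f"m{mj}"))
        parent[a] = b
    comps = {}
    for vi, mj in edges:
        comps.setdefault(find(("v", f"v{vi}")), set()).add(f"m{mj}")
    expected = sorted(tuple(sorted(c)) for c in comps.values())
    got = sorted(tuple(sorted(g.metabolites)) for g in gims)
    assert got == expected


def _two_signal_region(seed=21, n=6000):
    variants = [VariantSpec("1", 1_000_000, maf_target=0.3),
                VariantSpec("1", 2_500_000, maf_target=0.25)]
    dosages = simulate_genotypes(variants, n, ld_decay=1e-5, seed=seed)
    truth = TruthTable(causal_entries=[
        CausalEntry(variants[0].vid, "MA1", beta_for_variance(0.03, 0.3), 0.03),
        CausalEntry(variants[0].vid, "MA2", -beta_for_variance(0.03, 0.3), 0.03),
        CausalEntry(variants[1].vid, "MB1", beta_for_variance(0.03, 0.25), 0.03),
    ])
    from metabotyper.synthetic_data import simulate_metabolites, split_cohorts
    from metabotyper.preprocess import preprocess_metabolites
    mets = simulate_metabolites(dosages, truth, seed=seed)
    cov = pd.DataFrame({"age": np.zeros(n)}, index=dosages.index)
    cohorts = split_cohorts(dosages, mets, cov, (n // 2, n - n // 2, 0),
                            seed=seed)
    residuals = {c: preprocess_metabolites(cohorts[c].metabolites,
                                           min_n=10).residuals
                 for c in ("discovery1", "discovery2")}
    pooled = pool_cohorts({c: cohorts[c] for c in ("discovery1", "discovery2")},
                          residuals)
    region = Region(id="R1", chrom="1", start=1, end=5_000_000,
                    members=[v.vid for v in variants])
    models = []
    for met in ("MA1", "MA2", "MB1"):
        m = stepwise_conditional("R1", met, region.members, pooled)
        m = final_joint(m, pooled)
        if m.variants:
            models.append(m)
    return region, models, pooled, variants, truth


def test_single_association_selected_with_marker_order_one():
    region, models, pooled, variants, _ = _two_signal_region()
    only = [m for m in models if m.metabolite == "MB1"]
    matrix = gim_select(region, only, pooled)
    assert matrix.marker_order == {variants[1].vid: 1}


def test_planted_disjoint_signals_stay_disjoint():
    region, models, pooled, variants, truth = _two_signal_region()
    matrix = gim_select(region, models, pooled)
    gims = cluster_gims(matrix)
    got = {tuple(sorted(g.metabolites)) for g in gims}
    assert got == {("MA1", "MA2"), ("MB1",)}
    # cross entries (each variant vs the other's metabolites) not significant
    sig = matrix.significant()
    assert not bool(sig.loc[variants[0].vid, "MB1"])
    # signed entries carry the direction of the planted effects
    assert matrix.entries.loc[variants[0].vid, "MA1"] > 0
    assert matrix.entries.loc[variants[0].vid, "MA2"] < 0


def test_gim_partition_property_on_full_study(small_study):
    res = mt.run_discovery(small_study.cohorts)
    for rid in {g.region_id for g in res.gims}:
        local = [g for g in res.gims if g.region_id == rid]
        for i in range(len(local)):
            for j in range(i + 1, len(local)):
                assert not (set(local[i].variants) & set(local[j].variants))
                assert not (set(local[i].metabolites)
                            & set(local[j].metabolites))
        sig = res.gim_matrices[rid].significant()
        covered = set()
        for g in local:
            for v in g.variants:
                for m in g.metabolites:
                    if bool(sig.loc[v, m]):
                        covered.add((v, m))
        all_sig = {(v, m) for v in sig.index for m in sig.columns
                   if bool(sig.loc[v, m])}
        assert covered == all_sig


def test_gim_recovery_matches_planted_partition(small_study):
    from sklearn.metrics import adjusted_rand_score
    res = mt.run_discovery(small_study.cohorts)
    mets = small_study.truth.metabolites
    planted = metabolite_partition_labels(
        [g.metabolites for g in small_study.truth.planted_gims], mets)
    got = metabolite_partition_labels(
        [g.metabolites for g in res.gims], mets)
    assert adjusted_rand_score(planted, got) >= 0.9


def test_merge_adjacent_noop_without_shared_metabolites():
    r1 = Region(id="A", chrom="1", start=1, end=100)
    r2 = Region(id="B", chrom="1", start=200, end=300)
    g1 = GIM(id="A_G1", region_id="A", variants={"v1": 1}, metabolites=("m1",))
    g2 = GIM(id="B_G1", region_id="B", variants={"v2": 1}, metabolites=("m2",))

    def recompute(region):  # pragma: no cover - must not be called
        raise AssertionError("merge should not trigger")

    regions, gims = merge_adjacent([r1, r2], [g1, g2], recompute)
    assert {r.id for r in regions} == {"A", "B"}
    assert {g.id for g in gims} == {"A_G1", "B_G1"}


def test_split_locus_recovered_after_adjacent_merge():
    # one causal signal artificially split across two touching regions
    region, models, pooled, variants, _ = _two_signal_region(seed=33)
    left = Region(id="L", chrom="1", start=1, end=1_800_000,
                  members=[variants[0].vid])
    right = Region(id="Rg", chrom="1", start=1_800_001, end=5_000_000,
                   members=[variants[1].vid])

    def analyze(region):
        ms = []
        for met in ("MA1", "MA2", "MB1"):
            m = stepwise_conditional(region.id, met, region.members, pooled)
            m = final_joint(m, pooled)
            if m.variants:
                ms.append(m)
        matrix = gim_select(region, ms, pooled)
        return ms, matrix, cluster_gims(matrix)

    gims = []
    for reg in (left, right):
        gims.extend(analyze(reg)[2])
    # make the split visible: plant MA1 association in both pieces by
    # giving the right region the left's variant as well
    right.members = [v.vid for v in variants]
    _, _, right_gims = analyze(right)
    gims = [g for g in gims if g.region_id != "Rg"] + right_gims
    merged_regions, merged_gims = merge_adjacent([left, right], gims,
                                                 lambda r: analyze(r))
    assert len(merged_regions) == 1
    got = {tuple(sorted(g.metabolites)) for g in merged_gims}
    assert got == {("MA1", "MA2"), ("MB1",)}
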