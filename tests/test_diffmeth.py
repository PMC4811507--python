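"""Delta-beta computation, classification, enrichment, metagene, 5mC."""

import numpy as np
import pandas as pd
import pytest

import epishift as ep
from epishift.diffmeth import DiffCpGSet, rank_sum_pvalues

from conftest import random_manifest


def _toy(beta_dict, conditions):
    beta = pd.DataFrame(beta_dict)
    beta.index = [f"cg{i}" for i in range(len(beta))]
    beta.index.name = "probe_id"
    sheet = pd.DataFrame({
        "sample_id": list(beta.columns),
        "condition": conditions,
        "genotype": ["WT" if c == "reference" else "MUT" for c in conditions],
        "cohort": "t"}).set_index("sample_id", drop=False)
    return beta, sheet


class TestComputeDeltaBeta:
    def test_simple_means(self):
        beta, sheet = _toy({"r1": [0.5], "r2": [0.5], "p1": [0.8],
                            "p2": [0.8]},
                           ["reference", "reference", "perturbed", "perturbed"])
        track = ep.compute_delta_beta(beta, sheet)
        assert track["delta"].iloc[0] == pytest.approx(0.3)

    def test_identical_groups_zero(self, rng):
        vals = rng.random(50)
        beta, sheet = _toy({"r": vals, "p": vals},
                           ["reference", "perturbed"])
        track = ep.compute_delta_beta(beta, sheet)
        assert (track["delta"] == 0).all()

    def test_matches_two_loop_oracle_with_missing(self, rng):
        n = 100
        beta = pd.DataFrame(rng.random((n, 6)),
                            index=[f"cg{i}" for i in range(n)],
                            columns=[f"s{j}" for j in range(6)])
        mask = rng.random((n, 6)) < 0.15
        beta = beta.mask(mask)
        conditions = ["reference"] * 3 + ["perturbed"] * 3
        sheet = pd.DataFrame({"sample_id": beta.columns,
                              "condition": conditions,
                              "genotype": ["WT"] * 3 + ["MUT"] * 3,
                              "cohort": "t"}).set_index("sample_id", drop=False)
        track = ep.compute_delta_beta(beta, sheet)
        for probe in beta.index:
            r = [beta.loc[probe, f"s{j}"] for j in range(3)]
            p = [beta.loc[probe, f"s{j}"] for j in range(3, 6)]
            r = [x for x in r if not np.isnan(x)]
            p = [x for x in p if not np.isnan(x)]
            if not r or not p:
                assert probe not in track.index
            else:
                want = sum(p) / len(p) - sum(r) / len(r)
                assert track.loc[probe, "delta"] == pytest.approx(want)

    def test_antisymmetry_under_group_swap(self, rng):
        beta = pd.DataFrame(rng.random((40, 4)),
                            index=[f"cg{i}" for i in range(40)],
                            columns=list("abcd"))
        sheet_f = pd.DataFrame({"sample_id": list("abcd"),
                                "condition": ["reference"] * 2 + ["perturbed"] * 2,
                                "genotype": ["WT"] * 2 + ["MUT"] * 2,
                                "cohort": "t"}).set_index("sample_id", drop=False)
        sheet_r = sheet_f.copy()
        sheet_r["condition"] = ["perturbed"] * 2 + ["reference"] * 2
        fwd = ep.compute_delta_beta(beta, sheet_f)
        rev = ep.compute_delta_beta(beta, sheet_r)
        assert np.allclose(fwd["delta"], -rev["delta"])

    def test_singleton_groups_allowed(self):
        beta, sheet = _toy({"parental": [0.2], "ko1": [0.6]},
                           ["reference", "perturbed"])
        track = ep.compute_delta_beta(beta, sheet)
        assert track["delta"].iloc[0] == pytest.approx(0.4)

    def test_empty_group_raises(self):
        beta, sheet = _toy({"r1": [0.5]}, ["reference"])
        with pytest.raises(ValueError, match="group"):
            ep.compute_delta_beta(beta, sheet)


class TestClassification:
    def test_threshold_partition(self):
        track = pd.DataFrame({"delta": [0.25, -0.3, 0.1]},
                             index=["p1", "p2", "p3"])
        ds = ep.classify_diff_cpgs(track, 0.2)
        assert ds.hyper == ["p1"] and ds.hypo == ["p2"]

    def test_closed_threshold_rule(self):
        track = pd.DataFrame({"delta": [0.2, -0.2, 0.199999]},
                             index=["a", "b", "c"])
        ds = ep.classify_diff_cpgs(track, 0.2)
        assert ds.hyper == ["a"] and ds.hypo == ["b"]

    def test_matches_filter_oracle(self, rng):
        track = pd.DataFrame({"delta": rng.uniform(-1, 1, 400)},
                             index=[f"cg{i}" for i in range(400)])
        for thr in (0.1, 0.2, 0.5):
            ds = ep.classify_diff_cpgs(track, thr)
            want_hyper = {i for i, d in track["delta"].items() if d >= thr}
            want_hypo = {i for i, d in track["delta"].items() if d <= -thr}
            assert set(ds.hyper) == want_hyper and set(ds.hypo) == want_hypo

    def test_disjoint_classes_enforced(self):
        with pytest.raises(ValueError):
            DiffCpGSet(threshold=0.2, hyper=["a"], hypo=["a"])

    def test_probe_order_invariance(self, rng):
        track = pd.DataFrame({"delta": rng.uniform(-1, 1, 100)},
                             index=[f"cg{i}" for i in range(100)])
        a = ep.classify_diff_cpgs(track, 0.2)
        b = ep.classify_diff_cpgs(track.sample(frac=1, random_state=1), 0.2)
        assert set(a.hyper) == set(b.hyper) and set(a.hypo) == set(b.hypo)


class TestHyperFraction:
    def test_arithmetic(self):
        ds = DiffCpGSet(0.2, hyper=[f"h{i}" for i in range(8)],
                        hypo=["l1", "l2"])
        assert ep.hyper_fraction(ds) == pytest.approx(0.8)

    def test_all_hypo_zero(self):
        ds = DiffCpGSet(0.2, hyper=[], hypo=["a"])
        assert ep.hyper_fraction(ds) == 0.0

    def test_empty_set_undefined(self):
        with pytest.raises(ValueError):
            ep.hyper_fraction(DiffCpGSet(0.2))


class TestFeatureEnrichment:
    def test_uniform_draw_ratios_near_one(self, rng):
        man = random_manifest(rng, n=2_000)
        man["feature"] = rng.choice(["promoter", "body", "intergenic"],
                                    size=len(man), p=[0.25, 0.25, 0.5])
        chosen = rng.choice(man["probe_id"], size=800, replace=False)
        ds = DiffCpGSet(0.2, hyper=list(chosen[:400]), hypo=list(chosen[400:]))
        enr = ep.feature_enrichment(ds, man)
        for feat in ("promoter", "body", "intergenic"):
            assert enr.loc[feat, "hyper_ratio"] == pytest.approx(1.0, abs=0.35)

    def test_intergenic_only_ratio(self, rng):
        man = random_manifest(rng, n=100)
        man.loc[:49, "feature"] = "body"  # 50/50 background
        inter = man.loc[man["feature"] == "intergenic", "probe_id"]
        ds = DiffCpGSet(0.2, hyper=list(inter[:20]))
        enr = ep.feature_enrichment(ds, man)
        assert enr.loc["intergenic", "hyper_ratio"] == pytest.approx(2.0)

    def test_mass_conservation(self, rng):
        man = random_manifest(rng, n=1_000)
        man["feature"] = rng.choice(["promoter", "terminus", "body",
                                     "intergenic"], size=len(man))
        chosen = rng.choice(man["probe_id"], size=300, replace=False)
        ds = DiffCpGSet(0.2, hyper=list(chosen))
        enr = ep.feature_enrichment(ds, man).dropna(subset=["hyper_ratio"])
        total = (enr["hyper_ratio"] * enr["background_fraction"]).sum()
        assert total == pytest.approx(1.0)

    def test_planted_structure_recovered(self, cellline_study, cellline_track):
        ds = ep.classify_diff_cpgs(cellline_track, 0.2)
        enr = ep.feature_enrichment(ds, cellline_study.manifest)
        assert enr["hyper_ratio"].idxmax() == "intergenic"
        assert enr["hypo_ratio"].idxmax() == "terminus"


class TestMetagene:
    def test_flat_profile(self, cellline_study):
        man = cellline_study.manifest
        vals = pd.Series(0.5, index=man["probe_id"])
        prof = ep.metagene_profile(vals, man, cellline_study.genes.head(30))
        got = prof["mean"].dropna()
        assert np.allclose(got, 0.5)

    def test_minus_strand_orientation(self):
        genes = ep.build_gene_table(pd.DataFrame(
            [{"gene_id": "m", "chrom": "chr1", "start": 1_000, "end": 11_000,
              "strand": "-"}]))
        man = pd.DataFrame({"probe_id": ["tes_probe", "tss_probe"],
                            "chrom": "chr1", "pos": [1_000, 10_999]})
        vals = pd.Series([0.9, 0.1], index=["tes_probe", "tss_probe"])
        prof = ep.metagene_profile(vals, man, genes, n_bins=10, flank_frac=0.25)
        filled = prof.dropna(subset=["mean"])
        # TES probe (pos 1000, minus strand) must map near x=1, TSS near x=0
        assert filled.loc[filled["bin_mid"] > 0.9, "mean"].iloc[0] == 0.9
        assert filled.loc[filled["bin_mid"] < 0.1, "mean"].iloc[0] == 0.1

    def test_matches_brute_force_binning(self, cellline_study, cellline_track, rng):
        genes = cellline_study.genes.sample(20, random_state=0)
        man = cellline_study.manifest
        vals = cellline_track["delta"]
        n_bins, flank = 20, 0.25
        prof = ep.metagene_profile(vals, man, genes, n_bins=n_bins,
                                   flank_frac=flank)
        edges = np.linspace(-flank, 1 + flank, n_bins + 1)
        sums = np.zeros(n_bins)
        counts = np.zeros(n_bins)
        for _, g in genes.iterrows():
            L = g.end - g.start
            per_gene = [[] for _ in range(n_bins)]
            for pid, c, pos in man[["probe_id", "chrom", "pos"]].itertuples(
                    index=False):
                if c != g.chrom or pid not in vals.index:
                    continue
                if not (g.start - flank * L <= pos < g.end + flank * L):
                    continue
                x = ((pos - g.start) / L if g.strand == "+"
                     else (g.end - 1 - pos) / L)
                b = min(max(int(np.digitize(x, edges)) - 1, 0), n_bins - 1)
                per_gene[b].append(vals[pid])
            for b in range(n_bins):
                if per_gene[b]:
                    sums[b] += np.mean(per_gene[b])
                    counts[b] += 1
        want = np.divide(sums, counts, out=np.full(n_bins, np.nan),
                         where=counts > 0)
        assert np.allclose(prof["mean"].to_numpy(), want, equal_nan=True)


class TestPercentChange5mC:
    def test_published_style_arithmetic(self):
        # global 5mC per 10^6 dC rises by ~25% and ~36% in the two KOs
        assert ep.percent_change_total_5mC(42_083, 52_581) == \
            pytest.approx(24.95, abs=0.01)
        assert ep.percent_change_total_5mC(42_083, 57_367) == \
            pytest.approx(36.32, abs=0.01)

    def test_identity(self):
        assert ep.percent_change_total_5mC(7.0, 7.0) == 0.0

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            ep.percent_change_total_5mC(0, 10)


class TestRankSum:
    def test_separated_groups_small_p(self, rng):
        beta = pd.DataFrame(
            np.concatenate([rng.uniform(0, 0.2, (20, 5)),
                            rng.uniform(0.8, 1.0, (20, 5))], axis=1),
            index=[f"cg{i}" for i in range(20)],
            columns=[f"s{j}" for j in range(10)])
        sheet = pd.DataFrame({"sample_id": beta.columns,
                              "condition": "reference",
                              "genotype": ["WT"] * 5 + ["MUT"] * 5,
                              "cohort": "t"}).set_index("sample_id", drop=False)
        p = rank_sum_pvalues(beta, sheet)
        assert (p < 0.05).all()
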