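"""H3K36me3 statistics and the EASE-modified Fisher exact test."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact

import epishift as ep
from epishift.diffmeth import DiffCpGSet
from epishift.intervals import PeakSet
from epishift.k36 import (differential_k36_genes, differential_k36_regions,
                          fisher_ease, gene_k36_signal, peak_feature_stats)

from conftest import occupancy, random_manifest


def hypergeom_pmf_exact(x, N, K, n):
    """Exact hypergeometric pmf from binomial coefficients (Fractions)."""
    from fractions import Fraction
    if x < max(0, n + K - N) or x > min(K, n):
        return Fraction(0)
    return Fraction(math.comb(K, x) * math.comb(N - K, n - x),
                    math.comb(N, n))


def oracle_ease(k, K, n, N, mode):
    """Independent enumeration oracle for the EASE-modified Fisher p."""
    kp = max(k - 1, 0)
    lo, hi = max(0, n + K - N), min(K, n)
    if mode == "depletion":
        return float(sum(hypergeom_pmf_exact(x, N, K, n)
                         for x in range(lo, k + 1)))
    if kp < lo:
        return 1.0
    if mode == "enrichment":
        return float(sum(hypergeom_pmf_exact(x, N, K, n)
                         for x in range(kp, hi + 1)))
    p_obs = hypergeom_pmf_exact(kp, N, K, n)
    return float(sum(p for x in range(lo, hi + 1)
                     if (p := hypergeom_pmf_exact(x, N, K, n)) <= p_obs))


class TestCoverage:
    def test_trivial_bounds(self):
        assert ep.genome_coverage_fraction(PeakSet(), 100) == 0.0
        full = PeakSet.from_arrays(["chr1"], [0], [100])
        assert ep.genome_coverage_fraction(full, 100) == 1.0

    def test_random_peaks_match_occupancy(self, rng):
        pairs = [(int(s), int(s + l)) for s, l in
                 zip(rng.integers(0, 9_000, 40), rng.integers(1, 400, 40))]
        ps = PeakSet.from_arrays(["chr1"] * 40, [p[0] for p in pairs],
                                 [p[1] for p in pairs])
        assert ep.genome_coverage_fraction(ps, 10_000) == \
            pytest.approx(occupancy(pairs).sum() / 10_000)

    def test_synthetic_redistribution(self, cellline_study):
        gsize = cellline_study.genome_size
        ref = ep.genome_coverage_fraction(cellline_study.k36_ref, gsize)
        pert = ep.genome_coverage_fraction(cellline_study.k36_pert, gsize)
        assert pert < ref


class TestPeakFeatureStats:
    def test_midpoint_assignment(self, cellline_study):
        genes = cellline_study.genes
        g = genes.iloc[0]
        mid_body = (g.body_start + g.body_end) // 2
        ps = PeakSet.from_arrays([g.chrom], [mid_body - 50], [mid_body + 50])
        stats = peak_feature_stats(ps, genes)
        assert stats.loc["body", "count"] == 1

    def test_lengths_match_direct_recomputation(self, cellline_study):
        stats = peak_feature_stats(cellline_study.k36_ref,
                                   cellline_study.genes)
        merged = cellline_study.k36_ref.merge().df
        lengths = (merged["End"] - merged["Start"]).to_numpy()
        assert stats["count"].sum() == len(merged)
        total_mean = np.nansum(stats["mean_len"] * stats["count"]) / len(merged)
        assert total_mean == pytest.approx(lengths.mean())

    def test_perturbed_shifts_toward_intergenic(self, cellline_study):
        ref = peak_feature_stats(cellline_study.k36_ref, cellline_study.genes)
        pert = peak_feature_stats(cellline_study.k36_pert,
                                  cellline_study.genes)
        ref_share = ref.loc["intergenic", "count"] / ref["count"].sum()
        pert_share = pert.loc["intergenic", "count"] / pert["count"].sum()
        assert pert_share > ref_share


class TestDifferentialGenes:
    def test_fold_change_arithmetic(self):
        sig = pd.DataFrame({"gene_id": ["g"], "signal_ref": [10.0],
                            "signal_pert": [40.0]})
        gain, loss, tab = differential_k36_genes(sig, pseudocount=1.0)
        assert gain == ["g"] and loss == []
        assert tab["log2fc"].iloc[0] == pytest.approx(np.log2(41 / 11))

    def test_equal_signals_neither(self):
        sig = pd.DataFrame({"gene_id": ["g"], "signal_ref": [5.0],
                            "signal_pert": [5.0]})
        gain, loss, _ = differential_k36_genes(sig)
        assert gain == [] and loss == []

    def test_antisymmetric_under_condition_swap(self, cellline_study):
        sig = cellline_study.k36_signal
        swapped = sig.rename(columns={"signal_ref": "signal_pert",
                                      "signal_pert": "signal_ref"})
        g1, l1, _ = differential_k36_genes(sig)
        g2, l2, _ = differential_k36_genes(swapped)
        assert set(g1) == set(l2) and set(l1) == set(g2)

    def test_truth_labels_recovered(self, cellline_study):
        gain, loss, _ = differential_k36_genes(cellline_study.k36_signal,
                                               pseudocount=0.01)
        truth = cellline_study.truth
        correct = (sum(g in loss for g in truth.lost_k36_genes)
                   + sum(g in gain for g in truth.upregulated_genes))
        total = len(truth.lost_k36_genes) + len(truth.upregulated_genes)
        assert correct / total >= 0.99


class TestDifferentialRegions:
    def _cov(self, values):
        bins = [(f"chr1", i * 100, (i + 1) * 100) for i in range(len(values))]
        return pd.DataFrame({"chrom": [b[0] for b in bins],
                             "start": [b[1] for b in bins],
                             "end": [b[2] for b in bins],
                             "value": values})

    def test_identical_coverage_no_regions(self):
        cov = self._cov([5.0] * 10)
        gain, loss = differential_k36_regions(cov, cov)
        assert len(gain) == 0 and len(loss) == 0

    def test_single_doubled_window(self):
        ref = self._cov([10.0] * 10)
        pert = self._cov([10.0] * 4 + [25.0] + [10.0] * 5)
        gain, loss = differential_k36_regions(ref, pert)
        assert len(gain) == 1 and len(loss) == 0
        assert (gain.df.iloc[0]["Start"], gain.df.iloc[0]["End"]) == (400, 500)

    def test_flagged_windows_merge_like_run_oracle(self, rng):
        ref = self._cov([10.0] * 60)
        vals = np.full(60, 10.0)
        flag = rng.random(60) < 0.3
        vals[flag] = 45.0
        pert = self._cov(list(vals))
        gain, _ = differential_k36_regions(ref, pert)
        # oracle: maximal runs of flagged windows
        runs = np.diff(np.flatnonzero(np.diff(
            np.concatenate([[0], flag.astype(int), [0]])))).size // 2 \
            if flag.any() else 0
        want_runs = 0
        i = 0
        while i < 60:
            if flag[i]:
                want_runs += 1
                while i < 60 and flag[i]:
                    i += 1
            else:
                i += 1
        assert len(gain) == want_runs

    def test_mismatched_bins_rejected(self):
        with pytest.raises(ValueError, match="bins"):
            differential_k36_regions(self._cov([1.0] * 3), self._cov([1.0] * 4))


class TestQuadrants:
    def test_no_regions_all_zero(self, rng):
        man = random_manifest(rng, n=50)
        ds = DiffCpGSet(0.2, hyper=list(man["probe_id"][:5]))
        q = ep.cpg_k36_quadrants(ds, PeakSet(), PeakSet(), man)
        assert (q.counts.to_numpy() == 0).all()
        assert (q.labels == "neither").all().all()

    def test_counts_match_point_in_interval_oracle(self, rng):
        man = random_manifest(rng, n=400, n_chroms=1)
        gain = PeakSet.from_arrays(["chr1"], [0], [10_000])
        loss = PeakSet.from_arrays(["chr1"], [12_000], [25_000])
        hyper = list(rng.choice(man["probe_id"], 60, replace=False))
        hypo = [p for p in rng.choice(man["probe_id"], 60, replace=False)
                if p not in hyper]
        ds = DiffCpGSet(0.2, hyper=hyper, hypo=hypo)
        q = ep.cpg_k36_quadrants(ds, gain, loss, man)
        pos = man.set_index("probe_id")["pos"]
        for direction, probes in (("hyper", hyper), ("hypo", hypo)):
            assert q.counts.loc[direction, "gain"] == \
                sum(pos[p] < 10_000 for p in probes)
            assert q.counts.loc[direction, "loss"] == \
                sum(12_000 <= pos[p] < 25_000 for p in probes)
        in_any = ((pos < 10_000) | ((pos >= 12_000) & (pos < 25_000)))
        assert q.counts.to_numpy().sum() == \
            sum(in_any[p] for p in hyper + hypo)

    def test_synthetic_planted_structure(self, cellline_study, cellline_track):
        study = cellline_study
        ds = ep.classify_diff_cpgs(cellline_track, 0.2)
        gain = study.k36_pert.subtract(study.k36_ref)
        loss = study.k36_ref.subtract(study.k36_pert)
        q = ep.cpg_k36_quadrants(ds, gain, loss, study.manifest)
        assert q.labels.loc["hyper", "gain"] == "significant overlap"
        assert q.labels.loc["hypo", "loss"] == "significant overlap"


class TestFisherEase:
    def test_single_overlap_is_null(self):
        assert fisher_ease(1, 10, 10, 100, mode="enrichment") == 1.0

    def test_zero_overlap_is_null(self):
        assert fisher_ease(0, 10, 10, 100, mode="enrichment") == 1.0

    def test_inconsistent_margins_rejected(self):
        with pytest.raises(ValueError):
            fisher_ease(5, 3, 10, 100)
        with pytest.raises(ValueError):
            fisher_ease(1, 50, 10, 20)

    @pytest.mark.parametrize("N", [6, 9, 12])
    def test_matches_enumeration_oracle_small_universes(self, N):
        for K in range(N + 1):
            for n in range(N + 1):
                lo, hi = max(0, n + K - N), min(K, n)
                for k in range(lo, hi + 1):
                    for mode in ("enrichment", "two-tailed", "depletion"):
                        got = fisher_ease(k, K, n, N, mode=mode)
                        want = oracle_ease(k, K, n, N, mode)
                        assert got == pytest.approx(want, abs=1e-10), \
                            (k, K, n, N, mode)

    def test_two_tailed_agrees_with_scipy_on_decremented_table(self):
        # dual route: scipy computes plain Fisher; EASE equals plain Fisher
        # on the table with one overlap removed
        for (k, K, n, N) in [(5, 10, 8, 30), (3, 12, 6, 25), (7, 9, 9, 20)]:
            kp = k - 1
            table = [[kp, n - kp], [K - kp, N - K - n + kp]]
            want = fisher_exact(table, alternative="two-sided")[1]
            assert fisher_ease(k, K, n, N, mode="two-tailed") == \
                pytest.approx(want, rel=1e-9)

    @settings(max_examples=200, derandomize=True)
    @given(st.integers(1, 60).flatmap(
        lambda N: st.tuples(st.just(N), st.integers(0, N), st.integers(0, N))))
    def test_ease_conservative_vs_plain_fisher(self, tKn):
        N, K, n = tKn
        lo, hi = max(0, n + K - N), min(K, n)
        for k in range(lo, hi + 1):
            ease = fisher_ease(k, K, n, N, mode="enrichment")
            plain = float(sum(hypergeom_pmf_exact(x, N, K, n)
                              for x in range(k, hi + 1)))
            assert ease >= plain - 1e-12
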