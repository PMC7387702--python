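import numpy as np
import pandas as pd
import pytest

from gcaqtl import genmap, qtlscan, simdata
from gcaqtl.genmap import GeneticMap, GenotypeMatrix, genotype_probabilities
from gcaqtl.qtlscan import (
    LOD_CAP,
    ScanResult,
    additive_effect,
    call_qtl,
    cim_scan,
    fit_qtl_model,
    permutation_threshold,
    scan_hk,
    select_cofactors,
    support_interval,
)


def make_probs(n_lines=100, n_chrom=2, n_markers=15, length=100.0, seed=0,
               step_cm=None):
    gmap = simdata.make_genetic_map(n_chrom, n_markers, length)
    geno = simdata.simulate_ril_genomes(gmap, n_lines, 11, seed=seed, method="markov")
    step = step_cm if step_cm is not None else length  # markers only by default
    return gmap, geno, genotype_probabilities(geno, gmap, step_cm=step)


def ols_lod_oracle(x, y, covariates=None):
    """Independent LOD computation: two explicit OLS fits."""
    n = len(y)
    C = np.ones((n, 1)) if covariates is None else np.column_stack([np.ones(n), covariates])
    b0, *_ = np.linalg.lstsq(C, y, rcond=None)
    rss0 = float(np.sum((y - C @ b0) ** 2))
    X = np.column_stack([C, x])
    b1, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss1 = float(np.sum((y - X @ b1) ** 2))
    if rss1 <= 0:
        return LOD_CAP
    return min((n / 2.0) * np.log10(rss0 / rss1), LOD_CAP)


class TestScanHK:
    def test_perfect_signal_peak_at_marker(self):
        gmap, geno, probs = make_probs(seed=1)
        m = 7
        y = pd.Series(probs.p2[:, m].copy(), index=geno.line_ids)
        res = scan_hk(probs, y)
        assert int(np.argmax(res.lod)) == m
        assert res.lod[m] == LOD_CAP

    def test_matches_ols_oracle_at_markers(self):
        gmap, geno, probs = make_probs(n_lines=80, seed=2)
        rng = np.random.default_rng(3)
        y = probs.p2[:, 4] + rng.normal(0, 0.7, 80)
        res = scan_hk(probs, pd.Series(y, index=geno.line_ids))
        for j in range(probs.n_positions):
            assert res.lod[j] == pytest.approx(
                ols_lod_oracle(probs.p2[:, j], y), abs=1e-8
            )

    def test_matches_ols_oracle_with_covariates(self):
        gmap, geno, probs = make_probs(n_lines=80, seed=4)
        rng = np.random.default_rng(5)
        C = rng.normal(size=(80, 2))
        y = probs.p2[:, 10] + C @ [0.5, -0.3] + rng.normal(0, 0.5, 80)
        res = scan_hk(probs, pd.Series(y, index=geno.line_ids), covariates=C)
        for j in range(0, probs.n_positions, 3):
            assert res.lod[j] == pytest.approx(
                ols_lod_oracle(probs.p2[:, j], y, C), abs=1e-8
            )

    def test_affine_invariance(self):
        gmap, geno, probs = make_probs(n_lines=60, seed=6)
        rng = np.random.default_rng(7)
        y = probs.p2[:, 3] + rng.normal(0, 1, 60)
        a = scan_hk(probs, pd.Series(y, index=geno.line_ids))
        b = scan_hk(probs, pd.Series(-2.5 * y + 17.0, index=geno.line_ids))
        assert np.allclose(a.lod, b.lod, atol=1e-9)

    def test_constant_response_warns_zero(self):
        gmap, geno, probs = make_probs(n_lines=30, seed=8)
        with pytest.warns(UserWarning, match="no residual variance"):
            res = scan_hk(probs, pd.Series(np.ones(30), index=geno.line_ids))
        assert np.all(res.lod == 0.0)

    def test_null_rarely_exceeds_threshold(self):
        """Independent y stays under its own permutation threshold >=95/100."""
        gmap, geno, probs = make_probs(n_lines=100, n_chrom=3, n_markers=20, seed=9)
        rng = np.random.default_rng(10)
        exceed = 0
        thr = permutation_threshold(
            probs, pd.Series(rng.normal(size=100), index=geno.line_ids),
            n_perm=200, alpha=0.05, seed=1,
        )
        for _ in range(100):
            y = pd.Series(rng.normal(size=100), index=geno.line_ids)
            if scan_hk(probs, y).lod.max() > thr:
                exceed += 1
        assert exceed <= 5 + 5  # 5% expected; allow MC slack


class TestSelectCofactors:
    def test_zero_requested(self):
        gmap, geno, probs = make_probs(n_lines=40, seed=11)
        y = pd.Series(np.arange(40.0), index=geno.line_ids)
        assert select_cofactors(geno, y, 0) == []

    def test_finds_single_qtl_marker(self):
        hits = 0
        for seed in range(50):
            gmap, geno, probs = make_probs(n_lines=200, n_chrom=2, n_markers=20,
                                           seed=100 + seed)
            rng = np.random.default_rng(seed)
            m = 5
            x = geno.dosage()[:, m]
            # ~20% PVE: var(signal)=0.25*var(x dosage in [0,1]) vs noise
            y = pd.Series(x + rng.normal(0, 1.0, 200), index=geno.line_ids)
            chosen = select_cofactors(geno, y, 1)
            j = gmap.marker_index(chosen[0])
            same = gmap.chrom[j] == gmap.chrom[m]
            close = same and abs(gmap.cm[j] - gmap.cm[m]) <= 10.0
            hits += bool(close)
        assert hits >= 45

    def test_duplicate_column_tie_break(self):
        cm = np.array([0.0, 0.0, 10.0])
        m = GeneticMap(["a", "b", "c"], [1, 1, 1], cm, [1.0, 1.001, 11.0])
        rng = np.random.default_rng(12)
        col = rng.integers(0, 2, 50).astype(np.int8) * 2
        other = rng.integers(0, 2, 50).astype(np.int8) * 2
        codes = np.column_stack([col, col, other])
        geno = GenotypeMatrix([f"L{i}" for i in range(50)], m.marker_ids, codes)
        y = pd.Series(col.astype(float), index=geno.line_ids)
        assert select_cofactors(geno, y, 1) == ["a"]

    def test_cap_with_warning(self):
        gmap, geno, probs = make_probs(n_lines=40, n_chrom=1, n_markers=5, seed=13)
        rng = np.random.default_rng(14)
        y = pd.Series(rng.normal(size=40), index=geno.line_ids)
        with pytest.warns(UserWarning, match="capped"):
            chosen = select_cofactors(geno, y, 99)
        assert len(chosen) <= 5


class TestCimScan:
    def test_no_cofactors_equals_scan_hk(self):
        gmap, geno, probs = make_probs(n_lines=60, seed=15)
        rng = np.random.default_rng(16)
        y = pd.Series(probs.p2[:, 2] + rng.normal(0, 1, 60), index=geno.line_ids)
        a = scan_hk(probs, y)
        b = cim_scan(probs, y, [])
        assert np.allclose(a.lod, b.lod)
        assert np.allclose(a.additive, b.additive)

    def test_window_excludes_local_cofactor(self):
        gmap, geno, probs = make_probs(n_lines=80, n_chrom=2, n_markers=10, seed=17)
        rng = np.random.default_rng(18)
        y = pd.Series(rng.normal(size=80), index=geno.line_ids)
        cof = str(gmap.marker_ids[3])
        res = cim_scan(probs, y, [cof], window_cm=10.0)
        j = probs.marker_column(cof)
        # at the cofactor's own position the cofactor must be excluded:
        # LOD equals the plain scan there
        plain = scan_hk(probs, y)
        assert res.lod[j] == pytest.approx(plain.lod[j], abs=1e-9)
        # far away the cofactor is included: matches covariate-adjusted scan
        far = probs.marker_column(str(gmap.marker_ids[-1]))
        adj = scan_hk(probs, y, covariates=probs.p2[:, [j]])
        assert res.lod[far] == pytest.approx(adj.lod[far], abs=1e-9)

    def test_two_qtl_localization_beats_plain_scan(self):
        """Two equal QTL 40 cM apart: composite scan localizes both."""
        ok = 0
        for seed in range(50):
            gmap = simdata.make_genetic_map(1, 23, 110.0)  # 5 cM spacing
            geno = simdata.simulate_ril_genomes(gmap, 250, 11, seed=200 + seed,
                                                method="markov")
            probs = genotype_probabilities(geno, gmap, step_cm=110.0)
            rng = np.random.default_rng(seed)
            d = geno.dosage()
            q1, q2 = 6, 14  # 30 cM and 70 cM
            y = pd.Series(
                1.2 * d[:, q1] + 1.2 * d[:, q2] + rng.normal(0, 1.0, 250),
                index=geno.line_ids,
            )
            cof = select_cofactors(geno, y, 3)
            res = cim_scan(probs, y, cof, window_cm=10.0)
            recs = call_qtl(res, 3.0, probs, y, trait="t", merge_cm=20.0)
            peaks = sorted(r.peak_cm for r in recs)
            good = (
                len(peaks) >= 2
                and min(abs(p - 30.0) for p in peaks) <= 10.0
                and min(abs(p - 70.0) for p in peaks) <= 10.0
            )
            ok += bool(good)
        assert ok >= 40


class TestPermutationThreshold:
    def test_deterministic(self):
        gmap, geno, probs = make_probs(n_lines=50, seed=19)
        y = pd.Series(np.random.default_rng(20).normal(size=50), index=geno.line_ids)
        t1 = permutation_threshold(probs, y, n_perm=200, seed=42)
        t2 = permutation_threshold(probs, y, n_perm=200, seed=42)
        assert t1 == t2
        assert t1 != permutation_threshold(probs, y, n_perm=200, seed=43)

    def test_monotone_in_alpha(self):
        gmap, geno, probs = make_probs(n_lines=50, seed=21)
        y = pd.Series(np.random.default_rng(22).normal(size=50), index=geno.line_ids)
        thrs = [
            permutation_threshold(probs, y, n_perm=200, alpha=a, seed=7)
            for a in (0.01, 0.05, 0.10, 0.25)
        ]
        assert all(a >= b for a, b in zip(thrs, thrs[1:]))

    def test_alpha_validation(self):
        gmap, geno, probs = make_probs(n_lines=30, seed=23)
        y = pd.Series(np.zeros(30) + np.arange(30), index=geno.line_ids)
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                permutation_threshold(probs, y, alpha=bad, n_perm=100)


class TestSupportInterval:
    def _scan(self, lods, cms=None):
        cms = cms if cms is not None else [0.0, 10.0, 20.0, 30.0, 40.0]
        pos = pd.DataFrame(
            {"chrom": [1] * len(lods), "cm": cms, "mb": [c + 1 for c in cms],
             "marker": [""] * len(lods)}
        )
        return ScanResult(pos, np.array(lods, dtype=float), np.zeros(len(lods)))

    def test_hand_case(self):
        si = support_interval(self._scan([1, 2, 5, 2, 1]), 2, drop=1.5)
        assert (si["lo_cm"], si["hi_cm"]) == (10.0, 30.0)
        assert (si["lo_mb"], si["hi_mb"]) == (11.0, 31.0)

    def test_zero_drop_degenerate(self):
        si = support_interval(self._scan([1, 2, 5, 2, 1]), 2, drop=0.0)
        assert si["lo_cm"] == si["hi_cm"] == 20.0

    def test_flat_curve_whole_chromosome(self):
        si = support_interval(self._scan([3, 3, 3, 3, 3]), 2, drop=1.5)
        assert (si["lo_cm"], si["hi_cm"]) == (0.0, 40.0)

    def test_restricted_to_peak_chromosome(self):
        pos = pd.DataFrame(
            {
                "chrom": [1, 1, 2, 2, 2],
                "cm": [0.0, 10.0, 0.0, 10.0, 20.0],
                "mb": [1.0, 11.0, 1.0, 11.0, 21.0],
                "marker": [""] * 5,
            }
        )
        scan = ScanResult(pos, np.array([9.0, 9.0, 1.0, 5.0, 1.0]), np.zeros(5))
        si = support_interval(scan, 3, drop=1.5)
        assert si["lo_cm"] >= 0.0 and si["hi_cm"] <= 20.0


class TestFitQtlModel:
    def test_noiseless_single_qtl_full_pve(self):
        gmap, geno, probs = make_probs(n_lines=80, seed=24)
        y = pd.Series(2.0 * probs.p2[:, 5] + 1.0, index=geno.line_ids)
        fit = fit_qtl_model(probs, y, [5])
        assert fit["model_pve"].iloc[0] == pytest.approx(100.0, abs=1e-6)
        assert fit["additive"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_random_regressor_expected_pve(self):
        """Pure-noise y on one random position: E[R^2] ~ 1/(n-1)."""
        n = 50
        pves = []
        for seed in range(200):
            gmap, geno, probs = make_probs(n_lines=n, n_chrom=1, n_markers=5,
                                           seed=300 + seed)
            rng = np.random.default_rng(seed)
            y = pd.Series(rng.normal(size=n), index=geno.line_ids)
            pves.append(fit_qtl_model(probs, y, [2])["pve"].iloc[0])
        expected = 100.0 / (n - 1)
        assert abs(float(np.mean(pves)) - expected) < 1.0

    def test_two_orthogonal_qtl_additive_pve(self):
        """PVE ~10% + ~20% on different chromosomes -> joint ~30% +/- 5."""
        joints = []
        for seed in range(50):
            gmap, geno, probs = make_probs(n_lines=300, n_chrom=2, n_markers=10,
                                           seed=400 + seed)
            rng = np.random.default_rng(seed)
            x1 = probs.p2[:, 3]   # chromosome 1
            x2 = probs.p2[:, 13]  # chromosome 2
            v1, v2 = np.var(x1), np.var(x2)
            resid = 1.0
            b1 = np.sqrt(0.10 / 0.70 * resid / v1)
            b2 = np.sqrt(0.20 / 0.70 * resid / v2)
            y = pd.Series(
                b1 * x1 + b2 * x2 + rng.normal(0, 1.0, 300), index=geno.line_ids
            )
            joints.append(fit_qtl_model(probs, y, [3, 13])["model_pve"].iloc[0])
        assert abs(float(np.mean(joints)) - 30.0) < 5.0

    def test_collinear_peaks_merged(self):
        gmap, geno, probs = make_probs(n_lines=60, seed=25)
        dup_a = 0
        # find two markers in tight linkage (adjacent on chromosome 1)
        y = pd.Series(probs.p2[:, 0] + 0.01 * np.arange(60), index=geno.line_ids)
        codes = probs.p2.copy()
        probs.p2[:, 1] = probs.p2[:, 0]  # force exact collinearity
        with pytest.warns(UserWarning, match="collinear"):
            fit = fit_qtl_model(probs, y, [0, 1])
        assert len(fit) == 1


class TestAdditiveEffect:
    def _probs_from_codes(self, codes):
        m = GeneticMap(["a"], [1], [0.0], [1.0])
        geno = GenotypeMatrix([f"L{i}" for i in range(len(codes))], ["a"],
                              np.array(codes, dtype=np.int8)[:, None])
        return geno, genotype_probabilities(geno, m, step_cm=1.0)

    def test_sign_convention(self):
        geno, probs = self._probs_from_codes([0, 0, 2, 2])
        y = pd.Series([0.0, 0.0, 2.0, 2.0], index=geno.line_ids)
        assert additive_effect(probs, y, 0) == pytest.approx(1.0)

    def test_antisymmetry(self):
        geno, probs = self._probs_from_codes([2, 2, 0, 0])
        y = pd.Series([0.0, 0.0, 2.0, 2.0], index=geno.line_ids)
        assert additive_effect(probs, y, 0) == pytest.approx(-1.0)

    def test_recovery(self):
        """True a = 0.5 at n = 328, strong signal: within 0.15 in >=90%."""
        close = 0
        for seed in range(50):
            gmap, geno, probs = make_probs(n_lines=328, n_chrom=1, n_markers=10,
                                           seed=500 + seed)
            rng = np.random.default_rng(seed)
            s = 2 * probs.p2[:, 4] - 1  # signed dosage
            gvar = 0.25 * np.var(s) * 4  # var of 0.5*s*2? keep simple below
            y = pd.Series(0.5 * s + rng.normal(0, 0.5, 328), index=geno.line_ids)
            a = additive_effect(probs, y, 4)
            close += bool(abs(a - 0.5) <= 0.15)
        assert close >= 45


class TestCallQtl:
    def test_merges_nearby_maxima(self):
        gmap, geno, probs = make_probs(n_lines=200, n_chrom=1, n_markers=21,
                                       length=100.0, seed=26)
        rng = np.random.default_rng(27)
        y = pd.Series(2.0 * probs.p2[:, 10] + rng.normal(0, 0.8, 200),
                      index=geno.line_ids)
        res = scan_hk(probs, y)
        recs = call_qtl(res, 6.0, probs, y, trait="kt", merge_cm=20.0)
        assert len(recs) == 1
        r = recs[0]
        assert r.name.startswith("qKT1-")
        assert r.lo_cm <= r.peak_cm <= r.hi_cm
        assert 0.0 <= r.pve <= 100.0

    def test_no_peaks_empty(self):
        gmap, geno, probs = make_probs(n_lines=50, seed=28)
        y = pd.Series(np.random.default_rng(29).normal(size=50), index=geno.line_ids)
        res = scan_hk(probs, y)
        assert call_qtl(res, LOD_CAP, probs, y) == []
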