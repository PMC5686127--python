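"""Chemical-shift perturbation profiling and interface calling."""

import numpy as np
import pytest

from tailaccess import (GeneratorConfig, PeakRecord, build_profile, csp,
                        fit_csp_titration, gen_nmr_titration,
                        intensity_fraction, perturbation_calls,
                        quadratic_bound_signal)
from tailaccess.binding_models import DomainError
from tailaccess.nmr_titration import PerturbationProfile, assign_region


def peak(res, aa="A", h=8.0, n=115.0, inten=1.0, point="ref"):
    return PeakRecord(residue_index=res, amino_acid=aa, h_ppm=h, n_ppm=n,
                      intensity=inten, point_id=point)


class TestCsp:
    @pytest.mark.parametrize("dh,dn,expected", [
        (0.1, 0.0, 0.1),
        (0.0, 1.0, 0.14),
        (0.03, 0.40, np.hypot(0.03, 0.14 * 0.40)),  # = 0.063530
    ])
    def test_combined_shift(self, dh, dn, expected):
        ref = peak(400)
        titr = peak(400, h=8.0 + dh, n=115.0 + dn, point="p1")
        assert csp(ref, titr) == pytest.approx(expected, abs=1e-6)

    def test_symmetric_in_reference_choice(self):
        a = peak(400, h=8.1, n=116.0)
        b = peak(400, h=7.9, n=114.5, point="p1")
        assert csp(a, b) == pytest.approx(csp(b, a))

    def test_residue_mismatch_rejected(self):
        with pytest.raises(ValueError, match="matching residue"):
            csp(peak(400), peak(401))


class TestIntensityFraction:
    def test_values(self):
        ref = peak(400, inten=2.0)
        assert intensity_fraction(ref, peak(400, inten=2.0)) == 1.0
        assert intensity_fraction(ref, peak(400, inten=1.0)) == 0.5
        gone = PeakRecord(400, "A", 8.0, 115.0, None, "p1")
        assert intensity_fraction(ref, gone) == 0.0

    def test_zero_reference_flagged(self):
        with pytest.raises(DomainError):
            intensity_fraction(peak(400, inten=0.0), peak(400))


class TestProfileConstruction:
    def test_proline_carries_no_amide(self):
        with pytest.raises(ValueError, match="proline"):
            PeakRecord(380, "P", 8.0, 115.0, 1.0)
        pro = PeakRecord(380, "P", None, None, None)
        assert pro.missing

    def test_disappeared_peak_is_zero_intensity_missing_csp(self):
        ref = [peak(400), peak(401), peak(402)]
        titr = [peak(400, h=8.05, point="p1")]  # 401, 402 vanished
        prof = build_profile(ref, titr)
        i401 = list(prof.residue_index).index(401)
        assert prof.intensity_fraction[i401] == 0.0
        assert np.isnan(prof.csp[i401])
        assert prof.missing_reason[i401] == "disappeared"

    def test_region_assignment(self):
        assert assign_region(400) == "PHD1"
        assert assign_region(430) == "linker"
        assert assign_region(470) == "PHD2"
        assert assign_region(600) == "other"


class TestPerturbationCalls:
    def _profile(self, csps, start=361):
        n = len(csps)
        idx = np.arange(start, start + n)
        return PerturbationProfile(
            residue_index=idx, csp=np.asarray(csps, float),
            intensity_fraction=np.ones(n),
            region=[assign_region(i) for i in idx],
            missing_reason=["none"] * n)

    def test_flat_profile_calls_nothing(self):
        prof = self._profile([0.05] * 10)
        assert perturbation_calls(prof, {"PHD1": 1.0}) == set()

    def test_single_spike_called_alone(self):
        vals = [0.02] * 9 + [0.5]
        prof = self._profile(vals)
        assert perturbation_calls(prof, {"PHD1": 1.0}) == {370}

    def test_matches_independent_threshold_oracle(self):
        """Calls equal a plain recomputation of mean + k*SD per region."""
        rng = np.random.default_rng(17)
        vals = rng.gamma(2.0, 0.02, size=143)
        idx = np.arange(361, 504)
        prof = PerturbationProfile(
            residue_index=idx, csp=vals, intensity_fraction=np.ones(143),
            region=[assign_region(i) for i in idx],
            missing_reason=["none"] * 143)
        mult = {"PHD1": 1.0, "PHD2": 2.0}
        got = perturbation_calls(prof, mult)

        expected = set()
        for region, k in mult.items():
            sub = [(i, v) for i, v in zip(idx, vals)
                   if assign_region(int(i)) == region]
            vs = [v for _, v in sub]
            m = sum(vs) / len(vs)
            sd = (sum((v - m) ** 2 for v in vs) / len(vs)) ** 0.5
            expected |= {int(i) for i, v in sub if v > m + k * sd}
        assert got == expected

    def test_multiplier_extremes(self):
        rng = np.random.default_rng(3)
        prof = self._profile(rng.uniform(0, 0.1, 20))
        assert perturbation_calls(prof, {"PHD1": 1e9}) == set()
        above_mean = perturbation_calls(prof, {"PHD1": 0.0})
        m = prof.csp.mean()
        assert above_mean == {int(i) for i, v in
                              zip(prof.residue_index, prof.csp) if v > m}

    def test_missing_values_excluded_from_statistics(self):
        vals = [0.02] * 9 + [np.nan]
        prof = self._profile(vals)
        assert perturbation_calls(prof, {"PHD1": 1.0}) == set()

    def test_small_region_rejected(self):
        prof = self._profile([0.02] * 4)
        with pytest.raises(ValueError, match="fewer than 5"):
            perturbation_calls(prof, {"PHD1": 1.0})


class TestFitCspTitration:
    def test_noiseless_self_consistency(self):
        """Fast-exchange CSP series at Kd=10 uM, P=100 uM return Kd=10."""
        kd, P = 10.0, 100.0
        L = np.array([0.0, 25.0, 50.0, 100.0, 200.0, 400.0])
        f = quadratic_bound_signal(L, P, kd, 1.0)
        data = {400: 0.2 * f, 401: 0.08 * f}
        res = fit_csp_titration(data, L, P)
        assert res["pooled_kd"] == pytest.approx(kd, abs=1e-4)
        for r, (kd_r, dmax) in res["per_residue"].items():
            assert kd_r == pytest.approx(kd, rel=1e-5)

    def test_unresponsive_residues_excluded_from_pooling(self):
        kd, P = 10.0, 100.0
        L = np.array([0.0, 25.0, 50.0, 100.0, 200.0, 400.0])
        f = quadratic_bound_signal(L, P, kd, 1.0)
        res = fit_csp_titration({400: 0.2 * f, 401: 0.0 * f}, L, P)
        assert 401 in res["excluded"]
        assert set(res["per_residue"]) == {400}

    @staticmethod
    def _csp_series(df, ratios):
        """CSP per residue vs the zero-ligand reference point.

        The reference compared with itself has CSP identically 0."""
        out = {}
        for res in sorted(df["residue"].unique()):
            sub = df[df["residue"] == res].sort_values("molar_ratio")
            h0 = sub["h_ppm"].iloc[0]
            n0 = sub["n_ppm"].iloc[0]
            c = np.hypot(sub["h_ppm"] - h0,
                         0.14 * (sub["n_ppm"] - n0)).to_numpy()
            c[0] = 0.0
            out[int(res)] = c
        return out

    def test_generator_round_trip_recovers_kd(self):
        """Fifty replicate fast-exchange titrations pool back to the
        generating Kd within 5% at 0.005 ppm peak noise."""
        kd, P = 10.0, 100.0
        ratios = np.array([0.0, 0.25, 0.5, 1.0, 2.0, 4.0])
        rng = np.random.default_rng(8)
        resmap = {
            360 + i: {"aa": "A", "h0": 7.5 + 0.01 * i, "n0": 110.0 + 0.1 * i,
                      "dH_max": float(rng.uniform(0.05, 0.2)),
                      "dN_max": float(rng.uniform(0.2, 0.8)), "gamma": 1.0}
            for i in range(50)}
        L = ratios * P
        pooled = []
        for rep in range(50):
            cfg = GeneratorConfig(seed=1000 + rep, n_replicates=1,
                                  nmr_sigma_ppm=0.005)
            df = gen_nmr_titration(resmap, kd, P, ratios, cfg)
            pooled.append(fit_csp_titration(self._csp_series(df, ratios),
                                            L, P)["pooled_kd"])
        assert np.mean(pooled) == pytest.approx(kd, rel=0.05)

    def test_noisy_pooled_kd_within_grid_oracle_interval(self):
        """A single residue's noisy fit lands inside the 95% region of a
        brute-force (Kd, CSPmax) SSE grid."""
        from scipy.stats import f as f_dist

        kd, P = 10.0, 100.0
        L = np.array([0.0, 25.0, 50.0, 100.0, 200.0, 400.0, 800.0])
        rng = np.random.default_rng(12)
        y = 0.15 * quadratic_bound_signal(L, P, kd, 1.0) + \
            rng.normal(0, 0.005, L.size)
        y[0] = 0.0
        res = fit_csp_titration({400: y}, L, P, csp_floor=0.01)
        kd_fit = res["per_residue"][400][0]

        kd_grid = np.geomspace(1.0, 100.0, 200)
        dmax_grid = np.linspace(0.1, 0.2, 200)
        f = np.stack([quadratic_bound_signal(L, P, k, 1.0) for k in kd_grid])
        sse = ((dmax_grid[None, :, None] * f[:, None, :] -
                y[None, None, :]) ** 2).sum(axis=2)
        sse_min = sse.min()
        n, p = L.size, 2
        thresh = sse_min * (1 + p / (n - p) * f_dist.ppf(0.95, p, n - p))
        kd_ok = kd_grid[np.any(sse <= thresh, axis=1)]
        assert kd_ok.min() <= kd_fit <= kd_ok.max()
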