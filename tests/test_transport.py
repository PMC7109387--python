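"""Monte Carlo photon transport: physics limits, statistics, bookkeeping."""

import math

import numpy as np
import pytest
from scipy import stats

from cortexhsi import phantom as ph
from cortexhsi import transport as tr
from cortexhsi.studies import condition_compositions

COLLIMATED = 1e-9  # degrees; effectively a pencil-beam divergence


def slab(extent=(2.4, 2.4, 1.0), voxel=0.1):
    shape = tuple(int(round(e / voxel)) for e in extent)
    labels = np.full(shape, ph.GRAY_MATTER, dtype=np.uint8)
    return ph.CortexPhantom(labels, voxel_size=voxel, extent=extent)


def total_accounted(rec):
    a = rec.accounting
    return (a["detected"] + a["absorbed"] + a["escaped_side"]
            + a["escaped_bottom"] + a["specular"] + a["roulette"]
            + a["step_capped"])


class TestLaunch:
    def test_collimated_limit_covers_source_footprint(self):
        src = tr.SourceConfig(divergence_half_angle_deg=COLLIMATED)
        x, y, uz = tr.sample_entries(src, 20000, seed=1)
        assert np.all(np.abs(x) <= 0.3 + 1e-12)
        assert np.all(np.abs(y) <= 0.3 + 1e-12)
        assert np.allclose(uz, 1.0)

    def test_entry_density_uniform_over_illuminated_section(self):
        x, y, _ = tr.sample_entries(tr.SourceConfig(), 100000, seed=2)
        H, _, _ = np.histogram2d(x, y, bins=4, range=[[-0.6, 0.6], [-0.6, 0.6]])
        chi2 = ((H - H.mean()) ** 2 / H.mean()).sum()
        p = 1 - stats.chi2.cdf(chi2, 15)
        assert p > 0.001

    def test_identical_seed_identical_sequence(self):
        a = tr.sample_entries(tr.SourceConfig(), 1000, seed=9)
        b = tr.sample_entries(tr.SourceConfig(), 1000, seed=9)
        for u, v in zip(a, b):
            assert np.array_equal(u, v)


class TestHenyeyGreenstein:
    def test_isotropic_limit_uniform_cosine(self):
        ct = tr.sample_scatter(0.0, 100000, seed=4)
        d, p = stats.kstest(ct, stats.uniform(loc=-1, scale=2).cdf)
        assert p > 0.001

    def test_mean_cosine_equals_anisotropy(self):
        g = 0.9
        ct = tr.sample_scatter(g, 100000, seed=5)
        se = ct.std(ddof=1) / math.sqrt(ct.size)
        assert abs(ct.mean() - g) < 3 * se

    def test_closed_form_inversion_at_midpoint(self):
        # u = 0.5, g = 0.9: cosθ = [1 + g² − ((1−g²)/(1−g+g))²] / (2g)
        from cortexhsi._kernel import hg_inverse

        g = 0.9
        tmp = (1 - g * g) / (1 - g + 2 * g * 0.5)
        expected = (1 + g * g - tmp * tmp) / (2 * g)
        assert hg_inverse(0.5, g) == pytest.approx(expected, abs=1e-15)
        assert expected == pytest.approx(0.9855, abs=1e-4)


class TestPropagation:
    def test_beer_lambert_in_nonscattering_limit(self):
        # no scattering, matched index, collimated: transmitted weight
        # through thickness L is exactly exp(-mua * L)
        p = slab()
        src = tr.SourceConfig(divergence_half_angle_deg=COLLIMATED)
        mua = 0.7
        rec = tr.run_transport(p, mua_vessel=mua, mua_gray=mua, mus=0.0,
                               g=0.0, n=1.0, source=src, n_photons=2000,
                               seed=11,
                               options=tr.TransportOptions(roulette_threshold=0.0))
        expected = 2000 * math.exp(-mua * 1.0)
        assert rec.accounting["escaped_bottom"] == pytest.approx(expected,
                                                                 abs=1e-12 * 2000)
        assert rec.n_detected == 0

    def test_weight_conservation_with_mirror_walls(self):
        # absorption off, mirror side/bottom walls, matched index: every
        # photon eventually exits the top with weight exactly 1
        p = slab()
        rec = tr.run_transport(
            p, mua_vessel=0.0, mua_gray=0.0, mus=5.0, g=0.5, n=1.0,
            n_photons=3000, seed=12,
            options=tr.TransportOptions(roulette_threshold=0.0,
                                        reflect_walls=True))
        assert rec.n_detected == 3000
        assert np.all(rec.weight == 1.0)
        assert rec.accounting["detected"] == 3000.0

    def test_energy_accounting_closes(self, default_phantom):
        comps = condition_compositions()["baseline"]
        rec = tr.simulate_wavelength(default_phantom, comps, 835.0,
                                     n_photons=50000, seed=13)
        assert total_accounted(rec) == pytest.approx(rec.n_launched, rel=1e-6)

    def test_partial_paths_sum_to_total(self, default_phantom):
        comps = condition_compositions()["baseline"]
        rec = tr.simulate_wavelength(default_phantom, comps, 835.0,
                                     n_photons=20000, seed=14)
        assert rec.n_detected > 0
        # total geometric path is tallied as vessel + gray exactly
        assert np.all(rec.path_vessel >= 0)
        assert np.all(rec.path_gray >= 0)
        assert np.all(rec.weight > 0) and np.all(rec.weight <= 1.0)

    def test_diffuse_reflectance_matches_diffusion_theory(self):
        # semi-infinite homogeneous medium, matched boundary.  Independent
        # oracle: dipole diffusion model integrated over the surface,
        # R = (a'/2) (exp(-mueff z0) + exp(-mueff (z0 + 2 zb)))
        mua, mus_prime, g = 0.01, 1.0, 0.9
        mutr = mua + mus_prime
        albedo = mus_prime / mutr
        mueff = math.sqrt(3.0 * mua * mutr)
        z0 = 1.0 / mutr
        zb = 2.0 / (3.0 * mutr)  # matched-index extrapolated boundary
        r_diffusion = albedo / 2.0 * (math.exp(-mueff * z0)
                                      + math.exp(-mueff * (z0 + 2 * zb)))

        p = slab(extent=(80.0, 80.0, 40.0), voxel=1.0)
        src = tr.SourceConfig(divergence_half_angle_deg=COLLIMATED)
        rec = tr.run_transport(p, mua_vessel=mua, mua_gray=mua,
                               mus=mus_prime / (1 - g), g=g, n=1.0,
                               source=src, n_photons=30000, seed=15)
        r_mc = rec.accounting["detected"] / rec.n_launched
        assert r_mc == pytest.approx(r_diffusion, rel=0.05)

    def test_variance_scales_inversely_with_n(self):
        p = slab()
        comps = condition_compositions()["baseline"]
        sizes = [1000, 10000, 100000]
        variances = []
        for n in sizes:
            fractions = [
                tr.simulate_wavelength(p, comps, 835.0, n_photons=n,
                                       seed=100 + r).accounting["detected"] / n
                for r in range(8)
            ]
            variances.append(np.var(fractions, ddof=1))
        slope = np.polyfit(np.log(sizes), np.log(variances), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.2)

    def test_voxel_size_insensitivity(self):
        comps = condition_compositions()["baseline"]
        weights = []
        for voxel in (0.01, 0.005):
            p = ph.make_default_phantom(seed=7, voxel_size=voxel)
            rec = tr.simulate_wavelength(p, comps, 835.0, n_photons=100000,
                                         seed=16)
            weights.append(rec.accounting["detected"])
        assert weights[1] == pytest.approx(weights[0], rel=0.02)


class TestRecordSets:
    def test_identical_seed_identical_records(self, default_phantom):
        comps = condition_compositions()["baseline"]
        a = tr.simulate_wavelength(default_phantom, comps, 835.0,
                                   n_photons=2000, seed=21)
        b = tr.simulate_wavelength(default_phantom, comps, 835.0,
                                   n_photons=2000, seed=21)
        assert np.array_equal(a.exit_x, b.exit_x)
        assert np.array_equal(a.weight, b.weight)
        assert np.array_equal(a.path_vessel, b.path_vessel)

    def test_batch_size_independence(self, default_phantom):
        # per-photon substreams: the first photons of a larger run reproduce
        # a smaller run exactly
        comps = condition_compositions()["baseline"]
        small = tr.simulate_wavelength(default_phantom, comps, 835.0,
                                       n_photons=1000, seed=22)
        large = tr.simulate_wavelength(default_phantom, comps, 835.0,
                                       n_photons=2000, seed=22)
        n = small.n_detected
        assert np.array_equal(small.exit_x, large.exit_x[:n])
        assert np.array_equal(small.weight, large.weight[:n])

    def test_detected_weight_bounded_by_launched(self, default_phantom):
        comps = condition_compositions()["baseline"]
        rec = tr.simulate_wavelength(default_phantom, comps, 835.0,
                                     n_photons=5000, seed=23)
        assert rec.accounting["detected"] <= rec.n_launched

    def test_gray_matter_dominates_paths(self, default_phantom):
        comps = condition_compositions()["baseline"]
        rec = tr.simulate_wavelength(default_phantom, comps, 835.0,
                                     n_photons=50000, seed=24)
        assert rec.weighted_gray_fraction() > 0.9

    def test_hdf5_round_trip(self, tmp_path, default_phantom):
        comps = condition_compositions()["baseline"]
        rec = tr.simulate_wavelength(default_phantom, comps, 835.0,
                                     n_photons=2000, seed=25)
        rec.to_hdf5(tmp_path / "records.h5")
        import h5py

        with h5py.File(tmp_path / "records.h5") as f:
            assert np.array_equal(f["exit_x"][...], rec.exit_x)
            assert f.attrs["wavelength_nm"] == 835.0

    def test_stream_seed_derivation_stable(self):
        s1 = tr.derive_stream_seed(1, 835.0)
        s2 = tr.derive_stream_seed(1, 835.0)
        assert s1 == s2
        assert tr.derive_stream_seed(1, 836.0) != s1
        assert tr.derive_stream_seed(2, 835.0) != s1
        assert tr.derive_stream_seed(1, 835.0, "independent") != s1
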