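import numpy as np
import pytest

from ramapeak.dbmatch import (
    DbEntry,
    DbFormatError,
    DbValidityError,
    LowConfidenceWarning,
    WeightedEntry,
    entries_to_map,
    filter_quality,
    load_database,
    local_density,
    reconstruct_map,
    select_in_envelope,
    simplify_class,
    write_database,
)
from ramapeak.ramachandran import fold
from ramapeak.scores import default_masks
from ramapeak.spectral_io import interpolate_intensity


def _entry(shifts=(8.0, 122.0, 54.5, 21.0), phi=-63.0, psi=-42.0,
           stride="H", piqc=True, pid="p1", num=1):
    return DbEntry(protein_id=pid, residue_number=num, residue_type="A",
                   shifts=shifts, phi=phi, psi=psi, stride_class=stride,
                   piqc_pass=piqc)


class TestDbEntry:
    def test_valid_entry_and_simple_class(self):
        assert _entry(stride="G").simple_class == "helix"
        assert _entry(stride="E").simple_class == "extended"
        assert _entry(stride="T").simple_class == "other"
        assert _entry(stride="C").simple_class == "coil"

    def test_unknown_stride_rejected(self):
        with pytest.raises(DbValidityError):
            _entry(stride="X")
        with pytest.raises(DbValidityError):
            simplify_class("Q")

    @pytest.mark.parametrize("phi,psi", [(-181.0, 0.0), (0.0, 200.0),
                                         (-180.0, 0.0)])
    def test_angle_range_enforced(self, phi, psi):
        # angles must lie in the half-open interval (-180, 180]
        with pytest.raises(DbValidityError):
            _entry(phi=phi, psi=psi)

    def test_boundary_angle_180_allowed(self):
        e = _entry(phi=180.0, psi=180.0)
        assert e.phi == 180.0

    def test_weight_is_intensity_over_density(self):
        we = WeightedEntry(_entry(), intensity=3.0, density=0.5)
        assert we.weight == pytest.approx(6.0)
        with pytest.raises(ValueError):
            WeightedEntry(_entry(), intensity=1.0, density=0.0)


class TestLoadWrite:
    def test_round_trip(self, tmp_path):
        entries = [_entry(num=i, stride=s, piqc=bool(i % 2))
                   for i, s in enumerate("HEGT", start=1)]
        p = tmp_path / "db.csv"
        write_database(entries, p)
        back = load_database(p)
        assert back == entries

    def test_residue_type_filter(self, tmp_path):
        e1 = _entry(num=1)
        e2 = DbEntry("p1", 2, "V", (8.2, 120.0, 62.0, 32.0), -120.0, 130.0,
                     "E", True)
        p = tmp_path / "db.csv"
        write_database([e1, e2], p)
        assert load_database(p, residue_type="A") == [e1]
        assert load_database(p, residue_type="V") == [e2]

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("protein_id,phi,psi\np1,-60,-40\n")
        with pytest.raises(DbFormatError):
            load_database(p)

    def test_comment_lines_allowed(self, tmp_path):
        p = tmp_path / "db.csv"
        write_database([_entry()], p)
        p.write_text("# provenance comment\n" + p.read_text())
        assert len(load_database(p)) == 1


class TestFilterQuality:
    def test_drops_failed_piqc(self):
        entries = [_entry(num=1, piqc=True), _entry(num=2, piqc=False),
                   _entry(num=3, piqc=True)]
        kept = filter_quality(entries)
        assert [e.residue_number for e in kept] == [1, 3]


class TestSelectInEnvelope:
    def test_threshold_and_intensity_pairing(self, small_peak):
        center = small_peak.max_position
        inside = _entry(shifts=center, num=1)
        # an extended-class entry far out in every dimension: intensity ~ 0
        far = DbEntry("p1", 2, "A", (8.9, 126.5, 57.5, 24.5), -135.0, 140.0,
                      "E", True)
        kept = select_in_envelope([inside, far], small_peak, 0.2)
        assert [e.residue_number for e, _ in kept] == [1]
        assert kept[0][1] == pytest.approx(small_peak.max_intensity)

    def test_coil_excluded_by_default(self, small_peak):
        coil = _entry(shifts=small_peak.max_position, stride="C")
        assert select_in_envelope([coil], small_peak) == []
        kept = select_in_envelope([coil], small_peak, exclude_coil=False)
        assert len(kept) == 1

    def test_nan_shifts_skipped(self, small_peak):
        nan = _entry(shifts=(8.0, float("nan"), 54.5, 21.0))
        good = _entry(shifts=small_peak.max_position, num=2)
        kept = select_in_envelope([nan, good], small_peak)
        assert [e.residue_number for e, _ in kept] == [2]

    def test_out_of_region_shifts_skipped(self, small_peak):
        out = _entry(shifts=(12.0, 122.0, 54.5, 21.0))
        assert select_in_envelope([out], small_peak) == []

    def test_matches_brute_force_oracle(self, small_peak, rng):
        # independent re-implementation: directly interpolate and threshold
        entries = []
        for i in range(300):
            sh = (rng.uniform(7.9, 9.0), rng.uniform(118.2, 127.0),
                  rng.uniform(51.5, 58.0), rng.uniform(18.5, 25.0))
            entries.append(_entry(shifts=sh, num=i,
                                  stride=rng.choice(list("HETC"))))
        got = {e.residue_number
               for e, _ in select_in_envelope(entries, small_peak, 0.2)}
        cutoff = 0.2 * small_peak.max_intensity
        expect = set()
        for e in entries:
            if e.simple_class == "coil":
                continue
            if not all(ax.contains(s) for ax, s in
                       zip(small_peak.axes, e.shifts)):
                continue
            if float(interpolate_intensity(small_peak, e.shifts)) >= cutoff:
                expect.add(e.residue_number)
        assert got == expect
        assert len(expect) > 0  # the oracle comparison must be non-vacuous

    def test_bad_threshold_rejected(self, small_peak):
        with pytest.raises(ValueError):
            select_in_envelope([], small_peak, 0.0)


class TestLocalDensity:
    def test_kde_integrates_like_a_density(self, rng):
        # for n iid points from a wide uniform box, the self-inclusive KDE
        # value at a typical point is 1/volume plus the self-kernel term
        # 1/(n * prod(bw) * (2 pi)^2); boundary deficits pull it down a bit
        lo = np.array([7.0, 110.0, 45.0, 15.0])
        span = np.array([2.0, 20.0, 15.0, 15.0])
        n = 400
        bw = (0.2, 2.0, 1.5, 1.5)
        entries = [_entry(shifts=tuple(lo + span * rng.random(4)), num=i)
                   for i in range(n)]
        d = local_density(entries, bandwidths=bw)
        self_term = 1.0 / (n * np.prod(bw) * (2 * np.pi) ** 2)
        expect = 1.0 / np.prod(span) + self_term
        assert np.median(d) == pytest.approx(expect, rel=0.35)

    def test_denser_cluster_has_higher_density(self, rng):
        tight = [_entry(shifts=tuple(np.array([8.0, 120.0, 54.0, 20.0])
                                     + 0.01 * rng.standard_normal(4)), num=i)
                 for i in range(30)]
        loose = [_entry(shifts=tuple(np.array([8.8, 130.0, 60.0, 28.0])
                                     + 2.0 * rng.standard_normal(4)), num=i)
                 for i in range(30)]
        for method in ("kde", "knn"):
            d = local_density(tight + loose, method=method)
            assert d[:30].min() > d[30:].max()

    def test_kde_cluster_size_ratio(self):
        # two point-clusters of sizes 9 and 1, far apart: self-inclusive
        # KDE density at a cluster is proportional to its size, so the
        # ratio is exactly 9
        a = [_entry(shifts=(8.0, 120.0, 54.0, 20.0), num=i) for i in range(9)]
        b = [_entry(shifts=(9.5, 135.0, 65.0, 35.0), num=9)]
        d = local_density(a + b)
        assert d[0] / d[9] == pytest.approx(9.0, rel=1e-6)

    def test_single_entry_degenerate(self):
        with pytest.warns(LowConfidenceWarning):
            d = local_density([_entry()])
        assert d.tolist() == [1.0]

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            local_density([])
        with pytest.raises(ValueError):
            local_density([_entry(), _entry()], bandwidths=(0, 1, 1, 1))
        with pytest.raises(ValueError):
            local_density([_entry(), _entry()], method="voronoi")


class TestEntriesToMap:
    def test_weighted_histogram_hand_case(self):
        w1 = WeightedEntry(_entry(phi=-63.0, psi=-42.0), 3.0, 1.0)
        w2 = WeightedEntry(_entry(phi=-135.0, psi=140.0), 1.0, 1.0)
        m = entries_to_map([w1, w2])
        # (-63, -42) falls in bin centers (-60, -40); (-135, 140) in (-140, 140)
        assert m.density[6, 7] == pytest.approx(0.75)
        assert m.density[2, 16] == pytest.approx(0.25)
        assert m.density.sum() == pytest.approx(1.0)

    def test_density_compensation_cancels_coverage_bias(self):
        # 9 duplicated helix entries vs 1 extended entry with equal
        # intensity: w = I/P makes the duplicated cluster count once
        helix = [WeightedEntry(_entry(num=i), 1.0, 9.0) for i in range(9)]
        ext = [WeightedEntry(_entry(shifts=(8.5, 124.5, 50.2, 22.8),
                                    phi=-135.0, psi=140.0, stride="E",
                                    num=9), 1.0, 1.0)]
        m = entries_to_map(helix + ext)
        assert m.density[6, 7] == pytest.approx(0.5)
        assert m.density[2, 16] == pytest.approx(0.5)

    def test_nonstandard_bin_width_rejected(self):
        with pytest.raises(ValueError):
            entries_to_map([WeightedEntry(_entry(), 1.0, 1.0)], bin_width=10)
        with pytest.raises(ValueError):
            entries_to_map([])


class TestReconstructMap:
    def _db(self, rng, n=200, p_helix=0.5,
            center=(8.0, 122.0, 54.5, 21.0),
            sigma=(0.3, 1.2, 0.9, 0.9)):
        """Synthetic entries scattered around ``center`` (defaults to the
        small_peak maximum) with class-dependent dihedral angles."""
        entries = []
        for i in range(n):
            sh = np.asarray(center) + np.asarray(sigma) * rng.standard_normal(4)
            if rng.random() < p_helix:
                phi, psi, s = -63.0 + 8 * rng.standard_normal(), \
                    -42.0 + 8 * rng.standard_normal(), "H"
            else:
                phi, psi, s = -135.0 + 8 * rng.standard_normal(), \
                    140.0 + 8 * rng.standard_normal(), "E"
            phi = float(np.clip(phi, -179.9, 180.0))
            psi = float(np.clip(psi, -179.9, 180.0))
            entries.append(_entry(shifts=tuple(sh), phi=phi, psi=psi,
                                  stride=s, num=i))
        return entries

    def test_duplication_invariance_of_kde_weighting(self, small_peak, rng):
        """Exact invariance: k-fold duplicating every entry leaves the
        reconstructed map unchanged (P_i scales by k, counts scale by k)."""
        db = self._db(rng, n=120)
        m1, _ = reconstruct_map(db, small_peak)
        dup = db + [DbEntry(e.protein_id, e.residue_number + 1000,
                            e.residue_type, e.shifts, e.phi, e.psi,
                            e.stride_class, e.piqc_pass) for e in db]
        m2, _ = reconstruct_map(dup, small_peak)
        assert np.allclose(m1.density, m2.density, atol=1e-10)

    def test_piqc_failures_never_contribute(self, small_peak, rng):
        db = self._db(rng, n=120)
        bad = [DbEntry("junk", 5000 + i, "A", small_peak.max_position,
                       60.0, 60.0, "T", False) for i in range(50)]
        m1, w1 = reconstruct_map(db, small_peak)
        m2, w2 = reconstruct_map(db + bad, small_peak)
        assert len(w1) == len(w2)
        assert np.allclose(m1.density, m2.density)

    def test_low_confidence_warning(self, small_peak):
        few = [_entry(shifts=small_peak.max_position, num=i)
               for i in range(3)]
        with pytest.warns(LowConfidenceWarning):
            m, w = reconstruct_map(few, small_peak, min_entries=20)
        assert m.density.sum() == pytest.approx(1.0)

    def test_empty_envelope_raises(self, small_peak):
        out = [_entry(shifts=(8.9, 126.5, 57.5, 24.5), stride="E")]
        with pytest.raises(ValueError):
            reconstruct_map(out, small_peak)

    def test_density_scope_all_runs_and_differs_sensibly(self, small_peak, rng):
        db = self._db(rng, n=200)
        m_env, w_env = reconstruct_map(db, small_peak, density_scope="envelope")
        m_all, w_all = reconstruct_map(db, small_peak, density_scope="all")
        assert len(w_env) == len(w_all)
        assert m_all.density.sum() == pytest.approx(1.0)
        with pytest.raises(ValueError):
            reconstruct_map(db, small_peak, density_scope="global")

    def test_helix_dominates_under_helix_centered_peak(self, small_peak, rng):
        # small_peak is centered between but closer to the helix quadruple;
        # restrict to a peak centered exactly on the helix shifts instead
        from ramapeak.spectral_io import PeakRegion, SpectralAxis

        axes = (
            SpectralAxis("H", 12, 9.0, -0.2),
            SpectralAxis("N", 12, 126.0, -0.8),
            SpectralAxis("CA", 12, 58.5, -0.6),
            SpectralAxis("CB", 12, 22.0, -0.6),
        )
        centers = (8.0, 121.0, 55.0, 18.2)
        parts = [np.exp(-0.5 * ((ax.ppm - c) / s) ** 2)
                 for ax, c, s in zip(axes, centers, (0.3, 1.2, 1.0, 1.0))]
        arr = (parts[0][:, None, None, None] * parts[1][None, :, None, None]
               * parts[2][None, None, :, None] * parts[3][None, None, None, :])
        peak = PeakRegion(arr, axes)
        # class-dependent shift clusters: helix entries under the peak,
        # extended entries offset toward their own quadruple
        db = (self._db(rng, n=200, p_helix=1.0, center=centers)
              + [DbEntry("p2", 1000 + i, "A",
                         tuple(np.array([8.5, 124.5, 56.5, 21.5])
                               + 0.5 * rng.standard_normal(4)),
                         -135.0, 140.0, "E", True) for i in range(200)])
        m, _ = reconstruct_map(db, peak)
        f = fold(m)
        h_mask, e_mask = default_masks()
        assert f.density[h_mask.member].sum() > f.density[e_mask.member].sum()
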