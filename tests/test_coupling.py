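import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from methylrap.coupling import (
    INTRA_METHYL_SCALE,
    contact_map,
    cross_peak_probability,
    effective_coupling,
    n_pair_combinations,
    pair_coupling,
)
from methylrap.geometry import methyl_hydrogens
from methylrap.labelling import LabelledEnsemble, LabellingScheme, assign_isotopomers
from methylrap.structure import ProtonSite, ProteinStructure
from methylrap.synthetic import SyntheticStructureSpec, make_structure

from ._oracles import cross_peak_probability_enum, n_pairs_enum, rss_coupling_enum


def _site(i, coords, res=1, cls="methyl", group=None):
    return ProtonSite(
        atom_index=i, atom_name=f"H{i}", residue_index=res,
        residue_type="VAL", chain="A", coords=tuple(coords),
        site_class=cls, methyl_group_id=group,
        methyl_position=None, prochirality="none",
    )


def _ensemble(sites, occupancy):
    st_ = ProteinStructure(
        [s.atom_name for s in sites], ["H"] * len(sites),
        [s.residue_type for s in sites],
        np.array([s.residue_index for s in sites]),
        [s.chain for s in sites],
        np.array([s.coords for s in sites]),
    )
    scheme = LabellingScheme("custom", "random")
    return LabelledEnsemble(st_, list(sites), np.asarray(occupancy, bool),
                            scheme, seed=0)


class TestPairCoupling:
    def test_two_angstrom_reference_value(self):
        assert pair_coupling(2.0) == pytest.approx(15012.0, rel=1e-3)

    def test_inverse_cube(self):
        assert pair_coupling(4.0) == pytest.approx(pair_coupling(2.0) / 8.0)

    def test_vanishes_at_infinity(self):
        assert pair_coupling(1e6) < 1e-10

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            pair_coupling(0.0)


class TestEffectiveCoupling:
    def test_lone_proton_has_zero_coupling(self):
        sites = [_site(0, (0, 0, 0)), _site(1, (50.0, 0, 0), res=2)]
        ens = _ensemble(sites, [[1, 0], [1, 0]])
        res = effective_coupling(ens)
        assert res[0].d_mean == 0.0 and res[0].sd == 0.0

    def test_fixed_pair_deterministic(self):
        sites = [_site(0, (0, 0, 0)), _site(1, (3.0, 0, 0), res=2)]
        ens = _ensemble(sites, np.ones((10, 2)))
        res = effective_coupling(ens)
        assert res[0].d_mean == pytest.approx(pair_coupling(3.0))
        assert res[0].sd == pytest.approx(0.0, abs=1e-9)
        assert res[0].upper_2sigma == pytest.approx(pair_coupling(3.0))

    def test_full_methyl_hand_enumeration(self):
        h = methyl_hydrogens(np.array([0.0, 0.0, 1.53]), np.zeros(3), bond=1.09)
        sites = [_site(i, h[i], group="A:1:CG1") for i in range(3)]
        ens = _ensemble(sites, np.ones((4, 3)))
        res = effective_coupling(ens)
        r_hh = np.linalg.norm(h[0] - h[1])
        expect = 0.5 * np.sqrt(2.0) * pair_coupling(r_hh)
        for r in res:
            assert r.d_mean == pytest.approx(expect, rel=1e-12)

    def test_matches_brute_force_on_random_ensemble(self, core_structure):
        sch = LabellingScheme("rap", "random", p_methyl=0.3, p_aliphatic=0.3)
        ens = assign_isotopomers(core_structure, sch, 6, seed=5)
        res = effective_coupling(ens)
        coords = [s.coords for s in ens.sites]
        gids = [s.methyl_group_id or f"x{i}" for i, s in enumerate(ens.sites)]
        methyl_idx = [i for i, s in enumerate(ens.sites)
                      if s.site_class == "methyl"]
        for c, j in list(enumerate(methyl_idx))[::7]:
            vals = [
                rss_coupling_enum(
                    coords, ens.occupancy[l], j, pair_coupling,
                    lambda a, b: gids[a] == gids[b],
                )
                for l in range(ens.n_replicas)
            ]
            assert res[c].d_mean == pytest.approx(np.mean(vals), rel=1e-9)

    def test_adding_a_proton_never_decreases_values(self, core_structure):
        sch = LabellingScheme("rap", "random", p_methyl=0.2, p_aliphatic=0.2)
        ens = assign_isotopomers(core_structure, sch, 50, seed=6)
        base = np.array([r.d_mean for r in effective_coupling(ens)])
        occ2 = ens.occupancy.copy()
        empty = np.flatnonzero(~occ2[0])
        occ2[:, empty[0]] = True
        ens2 = LabelledEnsemble(ens.structure, ens.sites, occ2, ens.scheme, 0)
        more = np.array([r.d_mean for r in effective_coupling(ens2)])
        assert np.all(more >= base - 1e-9)

    def test_invalid_cutoff(self, core_structure):
        sch = LabellingScheme("rap", "random")
        ens = assign_isotopomers(core_structure, sch, 2, seed=0)
        with pytest.raises(ValueError):
            effective_coupling(ens, cutoff=0.0)


class TestContactMap:
    def test_uniform_scheme_is_geometric_adjacency(self, core_structure):
        ens = assign_isotopomers(
            core_structure,
            LabellingScheme("u", "uniform", exchangeable_h_fraction=1.0),
            3, seed=0,
        )
        cm = contact_map(ens, cutoff=5.0)
        xyz = np.array([s.coords for s in ens.sites])
        d = np.linalg.norm(xyz[:, None] - xyz[None], axis=-1)
        res_of = {}
        for i, s in enumerate(ens.sites):
            res_of[i] = cm.residue_labels.index(
                (s.chain, s.residue_index, s.residue_type)
            )
        expect = np.zeros_like(cm.frequencies)
        for a in range(len(ens.sites)):
            for b in range(a + 1, len(ens.sites)):
                if d[a, b] <= 5.0:
                    expect[res_of[a], res_of[b]] = 1.0
                    expect[res_of[b], res_of[a]] = 1.0
        assert np.array_equal(cm.frequencies, expect)

    def test_empty_scheme_gives_empty_map(self, core_structure):
        ens = assign_isotopomers(
            core_structure, LabellingScheme("z", "random", 0.0, 0.0, 0.0),
            5, seed=0,
        )
        cm = contact_map(ens)
        assert not cm.frequencies.any()

    def test_single_pair_frequency_is_p_squared(self):
        p = 0.3
        sites = [_site(0, (0, 0, 0), res=1), _site(1, (3.0, 0, 0), res=2)]
        n = 32000
        rng = np.random.default_rng(0)
        occ = rng.random((n, 2)) < p
        ens = _ensemble(sites, occ)
        cm = contact_map(ens, cutoff=5.0)
        se = np.sqrt(p**2 * (1 - p**2) / n)
        assert abs(cm.frequencies[0, 1] - p**2) < 3 * se

    def test_symmetry_and_range(self, core_structure):
        ens = assign_isotopomers(core_structure,
                                 LabellingScheme("r", "random"), 200, seed=1)
        cm = contact_map(ens)
        assert np.array_equal(cm.frequencies, cm.frequencies.T)
        assert cm.frequencies.min() >= 0.0 and cm.frequencies.max() <= 1.0


class TestCrossPeakStatistics:
    def test_two_sites(self):
        assert cross_peak_probability(2, 0.3) == pytest.approx(0.09)

    def test_certain_occupation(self):
        assert cross_peak_probability(8, 1.0) == 1.0

    @pytest.mark.parametrize("N", [2, 4, 6, 9, 12])
    @pytest.mark.parametrize("p", [0.035, 0.3])
    def test_matches_exhaustive_enumeration(self, N, p):
        assert cross_peak_probability(N, p) == pytest.approx(
            cross_peak_probability_enum(N, p), abs=1e-12
        )

    @given(p=st.floats(0.01, 0.5), N=st.integers(2, 15))
    @settings(deadline=None)
    def test_strictly_increasing_in_N_and_p(self, p, N):
        assert cross_peak_probability(N + 1, p) > cross_peak_probability(N, p)
        assert cross_peak_probability(N, p + 0.01) > cross_peak_probability(N, p)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            cross_peak_probability(1, 0.5)
        with pytest.raises(ValueError):
            cross_peak_probability(4, 1.5)

    @pytest.mark.parametrize("N,expect", [(2, 1), (3, 4), (10, 1013)])
    def test_pair_combination_counts(self, N, expect):
        assert n_pair_combinations(N) == expect

    @pytest.mark.parametrize("N", range(2, 11))
    def test_pair_combinations_match_subset_counting(self, N):
        assert n_pair_combinations(N) == n_pairs_enum(N)

    def test_intra_methyl_scale_is_half(self):
        # |P2(cos 90 deg)| = 0.5
        assert INTRA_METHYL_SCALE == pytest.approx(
            abs(0.5 * (3 * np.cos(np.pi / 2) ** 2 - 1))
        )
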