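"""Parasite-host pairing construction and the group-difference tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

import eggshell as es
from eggshell.hostmatch import (
    HostMap,
    PairingSet,
    build_pairs,
    compare_pair_types,
    host_reference_value,
)


def make_table(rows):
    df = pd.DataFrame(rows)
    if "host_species" not in df:
        df["host_species"] = ""
    df["host_species"] = df["host_species"].fillna("")
    return df


@pytest.fixture
def small_table():
    return make_table(
        [
            {"egg_id": "p1", "species": "P", "parasitic": True, "host_species": "H", "sa_nm": 1000.0},
            {"egg_id": "p2", "species": "P", "parasitic": True, "host_species": "H", "sa_nm": 1200.0},
            {"egg_id": "p3", "species": "P", "parasitic": True, "host_species": "H", "sa_nm": 900.0},
            {"egg_id": "h1", "species": "H", "parasitic": False, "sa_nm": 900.0},
            {"egg_id": "h2", "species": "H", "parasitic": False, "sa_nm": 1100.0},
            {"egg_id": "r1", "species": "R1", "parasitic": False, "sa_nm": 2000.0},
            {"egg_id": "r2", "species": "R2", "parasitic": False, "sa_nm": 500.0},
        ]
    )


class TestHostMap:
    def test_self_parasitism_rejected(self):
        with pytest.raises(ValueError):
            HostMap({"P": ["P"]})

    def test_empty_host_list_rejected(self):
        with pytest.raises(ValueError):
            HostMap({"P": []})

    def test_validate_against_table(self, small_table):
        HostMap({"P": ["H"]}).validate_against(small_table)
        with pytest.raises(ValueError, match="not in egg table"):
            HostMap({"P": ["Z"]}).validate_against(small_table)
        with pytest.raises(ValueError, match="parasitic"):
            HostMap({"P": ["P2"]}).validate_against(
                make_table(
                    [
                        {"egg_id": "a", "species": "P", "parasitic": True, "host_species": "P2", "sa_nm": 1.0},
                        {"egg_id": "b", "species": "P2", "parasitic": True, "host_species": "X", "sa_nm": 1.0},
                    ]
                )
            )

    def test_csv_round_trip(self, tmp_path):
        hm = HostMap({"P": ["H1", "H2"], "Q": ["H3"]})
        hm.to_csv(tmp_path / "hosts.csv")
        again = HostMap.from_csv(tmp_path / "hosts.csv")
        assert again.hosts == hm.hosts


class TestHostReferenceValue:
    def test_species_mean_when_host_unrecorded(self, small_table):
        egg = small_table.iloc[0].copy()
        egg["host_species"] = ""  # laying host not recorded
        value = host_reference_value(egg, small_table, HostMap({"P": ["H"]}), "sa_nm")
        assert value == pytest.approx(1000.0)  # mean of {900, 1100}

    def test_mean_of_three_host_species_means(self):
        table = make_table(
            [
                {"egg_id": "p", "species": "P", "parasitic": True, "sa_nm": 1.0},
                {"egg_id": "a1", "species": "A", "parasitic": False, "sa_nm": 700.0},
                {"egg_id": "a2", "species": "A", "parasitic": False, "sa_nm": 900.0},
                {"egg_id": "b", "species": "B", "parasitic": False, "sa_nm": 1000.0},
                {"egg_id": "c", "species": "C", "parasitic": False, "sa_nm": 1200.0},
            ]
        )
        egg = table.iloc[0]
        value = host_reference_value(
            egg, table, HostMap({"P": ["A", "B", "C"]}), "sa_nm"
        )
        assert value == pytest.approx((800.0 + 1000.0 + 1200.0) / 3)

    def test_known_host_uses_an_egg_of_that_species(self, small_table):
        egg = small_table.iloc[0]
        rng = np.random.default_rng(0)
        value = host_reference_value(
            egg, small_table, HostMap({"P": ["H"]}), "sa_nm", rng
        )
        assert value in (900.0, 1100.0)

    def test_no_host_data_returns_none(self, caplog):
        table = make_table(
            [
                {"egg_id": "p", "species": "P", "parasitic": True, "host_species": "H", "sa_nm": 1.0},
                {"egg_id": "h", "species": "H", "parasitic": False, "sa_nm": np.nan},
            ]
        )
        with caplog.at_level("WARNING"):
            value = host_reference_value(
                table.iloc[0], table, HostMap({"P": ["H"]}), "sa_nm"
            )
        assert value is None
        assert "skipped" in caplog.text


class TestBuildPairs:
    def test_counts_one_host_and_one_random_pair_per_egg(self, small_table):
        pairing = build_pairs(small_table, HostMap({"P": ["H"]}), "sa_nm", rng_seed=1)
        assert pairing.n_host_pairs == 3
        assert pairing.n_random_pairs == 3

    def test_no_parasitic_eggs_yields_empty_set(self, caplog):
        table = make_table(
            [
                {"egg_id": "a", "species": "X", "parasitic": False, "sa_nm": 1.0},
                {"egg_id": "b", "species": "Y", "parasitic": False, "sa_nm": 2.0},
            ]
        )
        with caplog.at_level("WARNING"):
            pairing = build_pairs(table, HostMap({"P": ["X"]}), "sa_nm", rng_seed=0)
        assert len(pairing.pairs) == 0
        assert "no parasitic eggs" in caplog.text

    def test_seed_reproducibility(self, small_table):
        hm = HostMap({"P": ["H"]})
        a = build_pairs(small_table, hm, "sa_nm", rng_seed=5)
        b = build_pairs(small_table, hm, "sa_nm", rng_seed=5)
        pd.testing.assert_frame_equal(a.pairs, b.pairs)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_partner_never_host_or_parasitic(self, small_table, seed):
        pairing = build_pairs(small_table, HostMap({"P": ["H"]}), "sa_nm", rng_seed=seed)
        random_partners = pairing.pairs.loc[
            pairing.pairs["pair_type"] == "random", "partner"
        ]
        partner_rows = small_table.set_index("egg_id").loc[random_partners]
        assert not partner_rows["parasitic"].any()
        assert not (partner_rows["species"] == "H").any()

    def test_hosts_allowed_as_random_partners_when_switched(self, small_table):
        seen = set()
        for seed in range(30):
            pairing = build_pairs(
                small_table,
                HostMap({"P": ["H"]}),
                "sa_nm",
                rng_seed=seed,
                exclude_hosts_from_random=False,
            )
            partners = pairing.pairs.loc[
                pairing.pairs["pair_type"] == "random", "partner"
            ]
            seen |= set(small_table.set_index("egg_id").loc[partners, "species"])
        assert "H" in seen

    def test_target_counts_subsample(self, small_table):
        pairing = build_pairs(
            small_table,
            HostMap({"P": ["H"]}),
            "sa_nm",
            rng_seed=2,
            target_counts=(2, 1),
        )
        assert pairing.n_host_pairs == 2
        assert pairing.n_random_pairs == 1


class TestComparePairTypes:
    def test_estimate_reproduced_exactly(self, toy_pairing):
        res = compare_pair_types(toy_pairing, n_permutations=1000, rng_seed=0)
        assert res.estimate == pytest.approx(4.0)
        assert res.df == 4
        assert res.n_host_pairs == res.n_random_pairs == 3

    def test_monte_carlo_matches_exhaustive_enumeration(self, toy_pairing):
        """Permutation p agrees with full enumeration of all C(6,3) = 20
        label assignments (independent oracle computed in-test)."""
        values = toy_pairing.pairs["abs_difference"].to_numpy()
        observed = abs(values[3:].mean() - values[:3].mean())
        exceed = sum(
            1
            for host_idx in itertools.combinations(range(6), 3)
            if abs(
                values[[i for i in range(6) if i not in host_idx]].mean()
                - values[list(host_idx)].mean()
            )
            >= observed - 1e-12
        )
        p_exact = exceed / 20
        assert p_exact == pytest.approx(0.1)
        B = 10_000
        res = compare_pair_types(toy_pairing, n_permutations=B, rng_seed=3)
        assert res.p_permutation == pytest.approx(p_exact, abs=2 / np.sqrt(B))

    def test_identical_groups_give_null_result(self):
        pairs = pd.DataFrame(
            {
                "parasite_egg": list("abcdef"),
                "parasite_species": ["P"] * 6,
                "partner": ["x"] * 6,
                "pair_type": ["host"] * 3 + ["random"] * 3,
                "abs_difference": [2.0] * 6,
            }
        )
        res = compare_pair_types(
            PairingSet(pairs=pairs, trait="sa_nm", rng_seed=0),
            n_permutations=500,
            rng_seed=1,
        )
        assert res.estimate == pytest.approx(0.0)
        assert res.p_permutation == pytest.approx(1.0)

    def test_scale_equivariance(self, toy_pairing):
        doubled = PairingSet(
            pairs=toy_pairing.pairs.assign(
                abs_difference=2 * toy_pairing.pairs["abs_difference"]
            ),
            trait="sa_nm",
            rng_seed=0,
        )
        a = compare_pair_types(toy_pairing, n_permutations=2000, rng_seed=7)
        b = compare_pair_types(doubled, n_permutations=2000, rng_seed=7)
        assert b.estimate == pytest.approx(2 * a.estimate)
        assert b.t == pytest.approx(a.t)
        assert b.p_parametric == pytest.approx(a.p_parametric)
        assert b.p_permutation == pytest.approx(a.p_permutation)

    def test_two_sided_invariance_to_group_relabeling(self, toy_pairing):
        swapped = PairingSet(
            pairs=toy_pairing.pairs.assign(
                pair_type=toy_pairing.pairs["pair_type"].map(
                    {"host": "random", "random": "host"}
                )
            ),
            trait="sa_nm",
            rng_seed=0,
        )
        a = compare_pair_types(toy_pairing, n_permutations=5000, rng_seed=9)
        b = compare_pair_types(swapped, n_permutations=5000, rng_seed=9)
        assert b.estimate == pytest.approx(-a.estimate)
        assert b.p_parametric == pytest.approx(a.p_parametric)
        assert b.p_permutation == pytest.approx(a.p_permutation, abs=0.02)

    def test_anticonservative_under_pure_species_level_variation(self):
        """Documented limitation: when trait variation is almost entirely
        species-level, host-pair differences are clustered (several eggs
        of one parasite vs the same host species), label exchangeability
        fails, and the permutation test rejects a true null too often."""
        rejections = 0
        reps = 100
        for seed in range(reps):
            ds = es.simulate_dataset(
                es.SimulationConfig(
                    n_species=45, n_parasites=14, eggs_per_species=4,
                    trait_mean=0.0, sigma2_p=0.95, sigma2_e=0.05, rng_seed=seed,
                )
            )
            pairing = build_pairs(ds.table, ds.hostmap, "sa_nm", rng_seed=seed)
            res = compare_pair_types(pairing, n_permutations=299, rng_seed=seed + 1)
            rejections += res.p_permutation <= 0.05
        # far above the binomial noise band around the nominal 0.05
        assert rejections / reps > 0.09

    def test_missing_pair_type_rejected(self, toy_pairing):
        only_host = PairingSet(
            pairs=toy_pairing.pairs[toy_pairing.pairs["pair_type"] == "host"],
            trait="sa_nm",
            rng_seed=0,
        )
        with pytest.raises(ValueError):
            compare_pair_types(only_host, n_permutations=10, rng_seed=0)
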