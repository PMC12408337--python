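"""Charge extraction, weighted merging, group sums and Pearson comparison."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from isfac.charges import (ChargeEntry, ChargeSet, average_h_augmentation,
                           combine_datasets, extract_charges, group_charge,
                           pearson, read_reference_charges)


def make_set(values, esus=None, elements=None, provenance=""):
    esus = esus or [0.01] * len(values)
    entries = []
    for i, ((label, q), esu) in enumerate(zip(values.items(), esus)):
        el = (elements or {}).get(label) or \
            "".join(c for c in label if c.isalpha())
        entries.append(ChargeEntry(label=label, element=el, dZ=1 if q >= 0 else -1,
                                   nu=abs(q), dq=q, esu=esu))
    return ChargeSet(entries, provenance=provenance)


class TestExtraction:
    class FakeResult:
        converged = True

        def __init__(self, nus, esds):
            self._nus, self._esds = nus, esds

        def nu(self, label):
            return self._nus[label]

        def nu_esd(self, label):
            return self._esds[label]

    def test_charge_is_nu_times_dz(self):
        from isfac.crystal import AtomSite, CrystalModel, UnitCell
        from isfac.scattering import IonSpec
        cell = UnitCell(8, 8, 8)
        model = CrystalModel(cell, [
            AtomSite("CL1", IonSpec.from_charge("Cl", -1), (0, 0, 0.01), nu=0.5),
            AtomSite("SI1", IonSpec.from_charge("Si", 4), (0.5, 0.5, 0.5),
                     nu=0.125),
        ])
        res = self.FakeResult({"CL1": 0.5, "SI1": 0.125},
                              {"CL1": 0.03, "SI1": 0.01})
        charges = extract_charges(res, model)
        assert charges.value("CL1") == pytest.approx(-0.5)
        assert charges.esu("CL1") == pytest.approx(0.03)   # |dZ| = 1
        assert charges.value("SI1") == pytest.approx(+0.5)
        assert charges.esu("SI1") == pytest.approx(0.04)   # |dZ| = 4

    def test_fixed_neutral_flagged_zero(self):
        from isfac.crystal import AtomSite, CrystalModel, UnitCell
        from isfac.scattering import IonSpec
        cell = UnitCell(8, 8, 8)
        model = CrystalModel(cell, [
            AtomSite("C9", IonSpec.from_charge("C", -1), (0, 0, 0.01),
                     nu=0.0, nu_fixed=True)])
        charges = extract_charges(self.FakeResult({}, {}), model)
        e = charges.entry("C9")
        assert (e.dq, e.esu, e.fixed) == (0.0, 0.0, True)


class TestCombine:
    def test_single_set_identity(self):
        a = make_set({"C1": 0.2, "O1": -0.2})
        out = combine_datasets([a])
        assert out.value("C1") == pytest.approx(0.2)
        assert out.esu("C1") == pytest.approx(0.01)

    def test_duplicate_sets_shrink_esu_by_sqrt2(self):
        a = make_set({"C1": 0.2}, esus=[0.02])
        b = make_set({"C1": 0.2}, esus=[0.02])
        out = combine_datasets([a, b])
        assert out.value("C1") == pytest.approx(0.2)
        assert out.esu("C1") == pytest.approx(0.02 / np.sqrt(2))

    def test_hand_computed_weighted_mean(self):
        # w1 = 100, w2 = 25: qbar = (0.2*100 + 0.4*25)/125 = 0.24
        a = make_set({"X1": 0.2}, esus=[0.1])
        b = make_set({"X1": 0.4}, esus=[0.2])
        out = combine_datasets([a, b])
        assert out.value("X1") == pytest.approx(0.24)
        assert out.esu("X1") == pytest.approx(1 / np.sqrt(125), abs=1e-6)

    def test_permutation_invariance_and_monotone_esu(self):
        sets = [make_set({"C1": 0.2 + 0.01 * i}, esus=[0.02 + 0.005 * i])
                for i in range(4)]
        fwd = combine_datasets(sets)
        rev = combine_datasets(sets[::-1])
        assert fwd.value("C1") == pytest.approx(rev.value("C1"))
        assert fwd.esu("C1") == pytest.approx(rev.esu("C1"))
        esus = [combine_datasets(sets[:k]).esu("C1") for k in range(1, 5)]
        assert all(b < a for a, b in zip(esus, esus[1:]))

    def test_partial_coverage_noted(self):
        a = make_set({"C1": 0.2, "O1": -0.2})
        b = make_set({"C1": 0.21})
        out = combine_datasets([a, b])
        assert "coverage" in out.provenance
        assert out.value("O1") == pytest.approx(-0.2)

    def test_conflicting_exact_values_rejected(self):
        a = make_set({"C1": 0.2}, esus=[0.0])
        b = make_set({"C1": 0.3}, esus=[0.01])
        with pytest.raises(ValueError):
            combine_datasets([a, b])


class TestGroupCharge:
    def test_independent_sum(self):
        s = make_set({"O1": -0.3, "O2": -0.5}, esus=[0.03, 0.04])
        total, esu = group_charge(s, ["O1", "O2"])
        assert total == pytest.approx(-0.8)
        assert esu == pytest.approx(np.sqrt(0.03**2 + 0.04**2))

    def test_empty_group(self):
        s = make_set({"O1": -0.3})
        assert group_charge(s, []) == (0.0, 0.0)

    def test_correlated_pair_uses_covariance(self):
        s = make_set({"A1": 0.1, "B1": 0.2}, esus=[0.02, 0.03])
        cov = np.array([[4e-4, -3e-4], [-3e-4, 9e-4]])
        total, esu = group_charge(s, ["A1", "B1"], covariance=cov,
                                  cov_labels=["A1", "B1"])
        # var = 4e-4 + 9e-4 + 2*(-3e-4) = 7e-4
        assert total == pytest.approx(0.3)
        assert esu == pytest.approx(np.sqrt(7e-4))

    def test_unknown_label_rejected(self):
        with pytest.raises(KeyError):
            group_charge(make_set({"A1": 0.1}), ["ZZ9"])


class TestPearson:
    def test_self_correlation_is_one(self):
        s = make_set({"A1": 0.1, "B1": -0.3, "C1": 0.4, "D1": 0.0})
        assert pearson(s, s).pearson == pytest.approx(1.0)

    def test_negation_is_minus_one(self):
        s = make_set({"A1": 0.1, "B1": -0.3, "C1": 0.4})
        neg = make_set({"A1": -0.1, "B1": 0.3, "C1": -0.4})
        assert pearson(s, neg).pearson == pytest.approx(-1.0)

    def test_five_pair_textbook_formula(self):
        x = {"A1": 0.12, "B1": -0.34, "C1": 0.45, "D1": -0.05, "E1": 0.22}
        y = {"A1": 0.10, "B1": -0.30, "C1": 0.52, "D1": 0.02, "E1": 0.18}
        r = pearson(make_set(x), make_set(y)).pearson
        # oracle: covariance over product of standard deviations, by hand
        xv, yv = np.array(list(x.values())), np.array(list(y.values()))
        cov = np.mean((xv - xv.mean()) * (yv - yv.mean()))
        expected = cov / (xv.std() * yv.std())
        assert r == pytest.approx(expected, rel=1e-12)

    def test_hydrogen_subset_flag(self):
        s_a = make_set({"C1": 0.1, "O1": -0.4, "N1": -0.2, "H1": 0.3},
                       elements={"H1": "H"})
        s_b = make_set({"C1": 0.2, "O1": -0.3, "N1": -0.1, "H1": 0.2},
                       elements={"H1": "H"})
        with_h = pearson(s_a, s_b, include_hydrogens=True)
        without = pearson(s_a, s_b, include_hydrogens=False)
        assert with_h.n_pairs == 4
        assert without.n_pairs == 3

    def test_too_few_pairs_rejected(self):
        a = make_set({"A1": 0.1, "B1": 0.2})
        with pytest.raises(ValueError):
            pearson(a, a)

    def test_zero_variance_rejected(self):
        a = make_set({"A1": 0.1, "B1": 0.1, "C1": 0.1})
        b = make_set({"A1": 0.2, "B1": 0.3, "C1": 0.1})
        with pytest.raises(ValueError):
            pearson(a, b)

    @given(scale=st.floats(0.1, 10.0), shift=st.floats(-1.0, 1.0))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, scale, shift):
        x = {"A1": 0.12, "B1": -0.34, "C1": 0.45, "D1": -0.05}
        y = {k: scale * v + shift for k, v in x.items()}
        r = pearson(make_set(x), make_set(y)).pearson
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_alias_map(self):
        a = make_set({"C1": 0.1, "O1": -0.4, "N1": -0.2})
        b = make_set({"C01": 0.2, "O01": -0.3, "N01": -0.1})
        alias = {"C1": "C01", "O1": "O01", "N1": "N01"}
        assert pearson(a, b, alias=alias).n_pairs == 3


class TestAverageHAugmentation:
    def test_counterbalance_arithmetic(self):
        s = make_set({"C1": -0.4, "O1": -0.8})  # non-H sum -1.2
        out = average_h_augmentation(s, n_h=6)
        h_entries = [e for e in out.entries if e.element == "H"]
        assert len(h_entries) == 6
        for e in h_entries:
            assert e.dq == pytest.approx(0.2)
        assert out.total() == pytest.approx(0.0)

    def test_zero_sum_gives_zero_protons(self):
        s = make_set({"C1": 0.4, "O1": -0.4})
        out = average_h_augmentation(s, n_h=6)
        assert all(e.dq == 0.0 for e in out.entries if e.element == "H")

    def test_invalid_n_h(self):
        with pytest.raises(ValueError):
            average_h_augmentation(make_set({"C1": 0.1}), 0)

    def test_augmentation_raises_pearson_when_h_truly_positive(self):
        # reference with individually known positive H charges; heavy atoms
        # mostly negative -> the heavy-only comparison is poorly constrained
        rng = np.random.default_rng(5)
        heavy_true = {"C1": -0.05, "N1": -0.45, "O1": -0.35, "O2": -0.30,
                      "C2": 0.25}
        h_true = {"H1": 0.18, "H2": 0.22, "H3": 0.2, "H4": 0.12, "H5": 0.18}
        ref = make_set({**heavy_true, **h_true},
                       elements={k: "H" for k in h_true})
        exp_heavy = {k: v + rng.normal(0, 0.08) for k, v in heavy_true.items()}
        exp = make_set(exp_heavy)
        r_heavy = pearson(exp, ref, include_hydrogens=False).pearson
        aug = average_h_augmentation(exp, n_h=5)
        alias = {f"Havg{i+1}": f"H{i+1}" for i in range(5)}
        r_aug = pearson(aug, ref, alias=alias).pearson
        assert r_aug > r_heavy


class TestTables:
    def test_charge_table_round_trip(self):
        s = make_set({"C1": 0.123, "O1": -0.456}, esus=[0.011, 0.022])
        out = ChargeSet.from_table(s.as_table())
        assert out.value("C1") == pytest.approx(0.123, abs=1e-5)
        assert out.esu("O1") == pytest.approx(0.022, abs=1e-5)

    def test_reference_table_reader(self):
        text = "# method NPA\nC1  -0.25\nH1  0.31\n"
        s = read_reference_charges(text)
        assert s.value("C1") == pytest.approx(-0.25)
        assert s.entry("H1").element == "H"
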