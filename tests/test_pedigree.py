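"""Pedigree validation, completeness, A-inverse and data editing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_pedigree
from rngxe.pedigree import (
    EditThresholds,
    a_inverse,
    a_matrix,
    edit_data,
    generations_traced,
    inbreeding_coefficients,
    pedigree_completeness,
    validate_pedigree,
)


class TestValidatePedigree:
    def test_founders_only_is_clean(self):
        ped = pd.DataFrame({"animal_id": [1, 2, 3], "sire_id": 0, "dam_id": 0})
        report = validate_pedigree(ped)
        assert all(len(v) == 0 for v in report.values())

    def test_self_parent_cycle_flagged(self):
        ped = pd.DataFrame({"animal_id": [1], "sire_id": [1], "dam_id": [0]})
        assert validate_pedigree(ped)["cycles"]

    def test_offspring_older_than_parent_flagged(self):
        ped = pd.DataFrame({
            "animal_id": [1, 2], "sire_id": [0, 1], "dam_id": [0, 0],
            "birth_date": pd.to_datetime(["2010-01-01", "2005-01-01"]),
        })
        assert validate_pedigree(ped)["date_conflicts"]

    def test_female_sire_flagged(self):
        ped = pd.DataFrame({
            "animal_id": [1, 2], "sire_id": [0, 1], "dam_id": [0, 0],
            "sex": ["F", "F"],
        })
        conflicts = validate_pedigree(ped)["sex_conflicts"]
        assert conflicts and conflicts[0]["role"] == "sire"

    def test_dangling_parent_reported(self):
        ped = pd.DataFrame({"animal_id": [1], "sire_id": [99], "dam_id": [0]})
        assert validate_pedigree(ped)["dangling_parents"]


def _enumerate_known(parents, animal, depth):
    """Brute-force ancestor enumeration oracle for completeness."""
    total, gen = 0.0, [animal]
    for g in range(1, depth + 1):
        nxt = [p for a in gen for p in parents.get(a, (0, 0)) if p != 0]
        total += len(nxt) / 2.0 ** g
        gen = nxt
    return total / depth


class TestCompleteness:
    def test_complete_pedigree_scores_one(self):
        # three full generations behind the proband
        rows, idx = [], 1
        layers = [[1]]
        rows.append((1, 2, 3))
        layers.append([2, 3])
        rows += [(2, 4, 5), (3, 6, 7)]
        rows += [(i, 0, 0) for i in range(4, 8)]
        ped = pd.DataFrame(rows, columns=["animal_id", "sire_id", "dam_id"])
        assert pedigree_completeness(ped, 1, depth=1) == pytest.approx(1.0)

    def test_unknown_sire_scores_zero(self):
        ped = pd.DataFrame({"animal_id": [1, 2], "sire_id": [0, 0],
                            "dam_id": [0, 1]})
        assert pedigree_completeness(ped, 2, depth=3) == 0.0

    def test_toy_matches_enumeration_oracle(self):
        # sire has both parents known one generation deep; dam is a founder
        ped = pd.DataFrame({
            "animal_id": [10, 20, 30, 40, 50],
            "sire_id": [20, 40, 0, 0, 0],
            "dam_id": [30, 50, 0, 0, 0],
        })
        parents = {10: (20, 30), 20: (40, 50), 30: (0, 0), 40: (0, 0), 50: (0, 0)}
        cs = _enumerate_known(parents, 20, 2)
        cd = _enumerate_known(parents, 30, 2)
        expected = 0.0 if cs + cd == 0 else 2 * cs * cd / (cs + cd)
        assert pedigree_completeness(ped, 10, depth=2) == pytest.approx(expected)
        # concrete values: C_s = (2/2 + 0/4)/2 = 0.5, dam founder -> IPC 0
        assert cs == pytest.approx(0.5)
        assert expected == 0.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(5, 30))
    def test_bounded_and_matches_oracle(self, seed, n):
        ped = random_pedigree(np.random.default_rng(seed), n)
        parents = {a: (s, d) for a, s, d in
                   zip(ped["animal_id"], ped["sire_id"], ped["dam_id"])}
        for animal in ped["animal_id"].sample(3, random_state=seed):
            got = pedigree_completeness(ped, int(animal), depth=4)
            assert 0.0 <= got <= 1.0
            s, d = parents[int(animal)]
            cs = _enumerate_known(parents, s, 4) if s else 0.0
            cd = _enumerate_known(parents, d, 4) if d else 0.0
            expected = 0.0 if cs + cd == 0 else 2 * cs * cd / (cs + cd)
            assert got == pytest.approx(expected)

    def test_monotone_in_added_ancestors(self):
        base = pd.DataFrame({
            "animal_id": [1, 2, 3], "sire_id": [2, 0, 0], "dam_id": [3, 0, 0],
        })
        before = pedigree_completeness(base, 1, depth=3)
        richer = pd.concat([
            base.assign(sire_id=[2, 4, 0], dam_id=[3, 5, 0]),
            pd.DataFrame({"animal_id": [4, 5], "sire_id": 0, "dam_id": 0}),
        ], ignore_index=True)
        after = pedigree_completeness(richer, 1, depth=3)
        assert after >= before


class TestGenerationsTraced:
    def test_founders_have_depth_zero(self):
        ped = pd.DataFrame({"animal_id": [1, 2], "sire_id": 0, "dam_id": 0})
        out = generations_traced(ped)
        assert out["mean_max_depth"] == 0.0
        assert out["mean_cge"] == 0.0

    def test_full_three_generations(self):
        rows = [(1, 2, 3), (2, 4, 5), (3, 6, 7)]
        rows += [(i, i * 2, i * 2 + 1) for i in range(4, 8)]
        rows += [(i, 0, 0) for i in range(8, 16)]
        ped = pd.DataFrame(rows, columns=["animal_id", "sire_id", "dam_id"])
        out = generations_traced(ped, animals=[1])
        assert out["mean_max_depth"] == 3.0
        assert out["mean_cge"] == pytest.approx(3.0)

    def test_matches_recursive_oracle(self):
        rng = np.random.default_rng(17)
        ped = random_pedigree(rng, 25)
        parents = {a: (s, d) for a, s, d in
                   zip(ped["animal_id"], ped["sire_id"], ped["dam_id"])}

        def depth(a):
            return max((1 + depth(p) for p in parents.get(a, (0, 0)) if p), default=0)

        def cge(a):
            return sum(0.5 * (1 + cge(p)) for p in parents.get(a, (0, 0)) if p)

        animals = list(parents)
        out = generations_traced(ped, animals)
        assert out["mean_max_depth"] == pytest.approx(np.mean([depth(a) for a in animals]))
        assert out["mean_cge"] == pytest.approx(np.mean([cge(a) for a in animals]))


class TestAInverse:
    def test_single_founder(self):
        ped = pd.DataFrame({"animal_id": [1], "sire_id": [0], "dam_id": [0]})
        ainv, ids = a_inverse(ped)
        assert ainv.toarray().item() == pytest.approx(1.0)

    def test_trio_closed_form(self, trio_pedigree):
        ainv, ids = a_inverse(trio_pedigree)
        dense = ainv.toarray()
        order = {a: i for i, a in enumerate(ids)}
        s, d, o = order[1], order[2], order[3]
        assert dense[o, o] == pytest.approx(2.0)
        assert dense[o, s] == pytest.approx(-1.0)
        assert dense[o, d] == pytest.approx(-1.0)
        assert dense[s, s] == pytest.approx(1.5)
        assert dense[d, d] == pytest.approx(1.5)
        assert dense[s, d] == pytest.approx(0.5)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(3, 50))
    def test_matches_tabular_inverse(self, seed, n):
        ped = random_pedigree(np.random.default_rng(seed), n)
        A, ids_a = a_matrix(ped)
        ainv, ids_i = a_inverse(ped, use_inbreeding=True)
        assert list(ids_a) == list(ids_i)
        assert np.abs(ainv.toarray() - np.linalg.inv(A)).max() < 1e-8

    def test_inbreeding_matches_tabular_diagonal(self):
        # full-sib mating: offspring of two full sibs has F = 0.25
        ped = pd.DataFrame({
            "animal_id": [1, 2, 3, 4, 5],
            "sire_id": [0, 0, 1, 1, 3],
            "dam_id": [0, 0, 2, 2, 4],
        })
        f = inbreeding_coefficients(ped)
        A, ids = a_matrix(ped)
        for i, a in enumerate(ids):
            assert f[a] == pytest.approx(A[i, i] - 1.0)
        assert f[5] == pytest.approx(0.25)

    def test_cycle_raises(self):
        ped = pd.DataFrame({"animal_id": [1, 2], "sire_id": [2, 1], "dam_id": [0, 0]})
        with pytest.raises(ValueError, match="cycle"):
            a_inverse(ped)


class TestEditData:
    def _data(self, egs):
        rows = []
        for eg, herds, per_herd in egs:
            for h in range(herds):
                for r in range(per_herd):
                    rows.append({"herd_id": f"{eg}h{h}", "eg_label": eg,
                                 "parity": 1, "value": 1.0})
        return pd.DataFrame(rows)

    def test_small_cells_removed(self):
        df = self._data([("A", 6, 20)])
        df.loc[df.index[-1], "parity"] = 9  # a one-record parity cell
        out, audit = edit_data(df, df, EditThresholds(eg_min_levels_mt=1,
                                                      eg_min_records_mt=1),
                               "MT", class_columns=["parity"])
        assert 9 not in set(out["parity"])
        assert any(a["rule"] == "min_obs_per_cell" for a in audit)

    def test_mt_group_with_too_few_levels_dropped(self):
        # 5 herds and plenty of records still fails the 6-level rule
        df = self._data([("A", 5, 2000), ("B", 7, 1000)])
        out, audit = edit_data(df, df, EditThresholds(), "MT")
        assert "A" not in set(out["eg_label"])
        assert "B" in set(out["eg_label"])

    def test_fs_thresholds_are_lower(self):
        df = self._data([("A", 5, 60)])  # 5 levels, 300 records
        out, _ = edit_data(df, df, EditThresholds(), "FS")
        assert len(out) == 300

    def test_idempotent(self):
        df = self._data([("A", 6, 1100), ("B", 3, 10)])
        thr = EditThresholds()
        once, _ = edit_data(df, df, thr, "MT", class_columns=["parity"])
        twice, _ = edit_data(once, once, thr, "MT", class_columns=["parity"])
        pd.testing.assert_frame_equal(once, twice)

    def test_unknown_kind_rejected(self):
        df = self._data([("A", 6, 10)])
        with pytest.raises(ValueError, match="dataset_kind"):
            edit_data(df, df, EditThresholds(), "XX")
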