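import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xlfold.config import ScoreWeights
from xlfold.restraints import (
    AnchorRestraint,
    CompiledScore,
    ContactRestraint,
    CrosslinkRestraint,
    MembraneSlabRestraint,
    RigidGroupRestraint,
    StericsRestraint,
    ambiguous_min_distance,
    count_violations,
    distance_energy,
    restraint_energy,
    total_score,
)

from conftest import make_model, random_model


class TestDistanceEnergy:
    @pytest.mark.parametrize(
        "d,bound,expected",
        [(5.0, 8.0, 0.0), (8.0, 8.0, 0.0), (10.0, 8.0, 4.0), (0.0, 1.0, 0.0)],
    )
    def test_flat_bottom_closed_form(self, d, bound, expected):
        assert distance_energy(d, bound) == pytest.approx(expected)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            distance_energy(-1.0, 8.0)

    def test_site_order_symmetry(self, rng):
        model = random_model(rng)
        r1 = CrosslinkRestraint(("A", 2), ("B", 5), upper_bound=6.0)
        r2 = CrosslinkRestraint(("B", 5), ("A", 2), upper_bound=6.0)
        assert restraint_energy(model, r1) == pytest.approx(
            restraint_energy(model, r2)
        )


class TestAmbiguousMinDistance:
    def test_single_copy_reduces_to_pair_distance(self):
        model = make_model({"A": [[0, 0, 0]], "B": [[3, 4, 0]]})
        r = CrosslinkRestraint(("A", 1), ("B", 1))
        assert ambiguous_min_distance(model, r) == pytest.approx(5.0)

    def test_min_over_four_copies_matches_brute_force(self, rng):
        chains = {c: rng.uniform(-20, 20, (3, 3)) for c in "ABCD"}
        chains["E"] = rng.uniform(-20, 20, (3, 3))
        model = make_model(chains, groups={c: "FB" for c in "ABCD"})
        r = CrosslinkRestraint(("FB", 2), ("E", 3))
        expected = min(
            np.linalg.norm(chains[c][1] - chains["E"][2]) for c in "ABCD"
        )
        assert ambiguous_min_distance(model, r) == pytest.approx(expected)

    def test_rigid_translation_invariance(self, rng):
        model = random_model(rng)
        r = ContactRestraint(("A", 1), ("B", 4), upper_bound=9.0)
        shifted = model.with_coords(model.coords + np.array([13.0, -7.0, 2.0]))
        assert ambiguous_min_distance(model, r) == pytest.approx(
            ambiguous_min_distance(shifted, r)
        )


class TestRestraintEnergies:
    def test_anchor_zero_at_reference(self, rng):
        model = random_model(rng)
        r = AnchorRestraint(
            sites=tuple(("A", i) for i in range(1, 9)),
            reference=model.chain_coords("A"),
        )
        assert restraint_energy(model, r) == 0.0

    def test_anchor_displacement_with_default_force_constant(self):
        # one bead displaced 2 Å at k = 0.1 per Å² -> 0.1 * 2² = 0.4
        model = make_model({"A": [[0, 0, 0], [4, 0, 0], [8, 0, 0]]})
        ref = model.coords.copy()
        ref[1, 2] += 2.0
        r = AnchorRestraint(
            sites=(("A", 1), ("A", 2), ("A", 3)), reference=ref, k=0.1
        )
        assert restraint_energy(model, r) == pytest.approx(0.4)

    def test_rigid_group_invariant_under_rotation(self, rng):
        model = random_model(rng)
        r = RigidGroupRestraint(
            chain_id="A",
            residues=tuple(range(1, 9)),
            reference=model.chain_coords("A").copy(),
        )
        theta = 0.7
        R = np.array(
            [[np.cos(theta), -np.sin(theta), 0],
             [np.sin(theta), np.cos(theta), 0],
             [0, 0, 1]]
        )
        X = model.coords.copy()
        s = model.chain_slice("A")
        X[s] = X[s] @ R.T + np.array([5.0, 1.0, -3.0])
        rotated = model.with_coords(X)
        assert restraint_energy(rotated, r) == pytest.approx(0.0, abs=1e-18)

    def test_slab_energy(self):
        model = make_model({"A": [[0, 0, 0], [0, 0, 17.0], [0, 0, -20.0]]})
        r = MembraneSlabRestraint(sites=(("A", 1), ("A", 2), ("A", 3)),
                                  half_width=15.0)
        assert restraint_energy(model, r) == pytest.approx(2.0**2 + 5.0**2)


class TestTotalScore:
    def test_empty_set_scores_zero(self, rng):
        assert total_score(random_model(rng), []).total == 0.0

    def test_single_violated_crosslink_uses_weight_25(self, two_bead_model):
        # d = 20, bound = 18 -> energy 4, weighted 25 * 4 = 100
        r = CrosslinkRestraint(("A", 1), ("B", 1), upper_bound=18.0)
        breakdown = total_score(two_bead_model, [r])
        assert breakdown.total == pytest.approx(100.0)
        assert breakdown.per_class["crosslink"] == pytest.approx(100.0)

    def test_negative_crosslinks_contribute_no_energy(self, two_bead_model):
        r = CrosslinkRestraint(("A", 1), ("B", 1), upper_bound=30.0,
                               polarity="negative")
        assert total_score(two_bead_model, [r]).total == 0.0

    def test_rigid_invariance_without_anchor_or_slab(self, rng):
        model = random_model(rng)
        rset = [
            CrosslinkRestraint(("A", 1), ("B", 3), upper_bound=5.0),
            ContactRestraint(("A", 4), ("B", 7), upper_bound=6.0, kind="inter"),
            RigidGroupRestraint(chain_id="B", residues=tuple(range(1, 9)),
                                reference=rng.uniform(-5, 5, (8, 3))),
            StericsRestraint(),
        ]
        theta = 1.2
        R = np.array(
            [[1, 0, 0],
             [0, np.cos(theta), -np.sin(theta)],
             [0, np.sin(theta), np.cos(theta)]]
        )
        moved = model.with_coords(model.coords @ R.T + np.array([-4.0, 9.0, 2.5]))
        assert total_score(moved, rset).total == pytest.approx(
            total_score(model, rset).total, rel=1e-9
        )

    def test_adding_satisfied_restraint_leaves_score_unchanged(self, rng):
        model = random_model(rng)
        base = [CrosslinkRestraint(("A", 1), ("B", 2), upper_bound=500.0)]
        satisfied = ContactRestraint(("A", 3), ("B", 4), upper_bound=500.0)
        assert total_score(model, base + [satisfied]).total == pytest.approx(
            total_score(model, base).total
        )


def _random_restraint_set(rng, model, n=30):
    rset = []
    chains = model.topology.chain_ids
    nres = model.topology.chain(chains[0]).n_residues
    for _ in range(n):
        kind = rng.integers(5)
        ca, cb = rng.choice(chains, 2, replace=False)
        ra = int(rng.integers(1, nres + 1))
        rb = int(rng.integers(1, nres + 1))
        bound = float(rng.uniform(3, 25))
        if kind == 0:
            rset.append(CrosslinkRestraint((ca, ra), (cb, rb), upper_bound=bound))
        elif kind == 1:
            rset.append(
                CrosslinkRestraint((ca, ra), (cb, rb), upper_bound=bound,
                                   polarity="negative")
            )
        elif kind == 2:
            rset.append(
                ContactRestraint((ca, ra), (cb, rb), upper_bound=bound,
                                 probability=float(rng.uniform(0.16, 1.0)),
                                 kind="inter" if rng.random() < 0.5 else "intra")
            )
        elif kind == 3:
            rset.append(
                AnchorRestraint(
                    sites=tuple((ca, i) for i in range(1, nres + 1)),
                    reference=rng.uniform(-20, 20, (nres, 3)),
                )
            )
        else:
            rset.append(
                RigidGroupRestraint(
                    chain_id=ca, residues=tuple(range(1, nres + 1)),
                    reference=rng.uniform(-20, 20, (nres, 3)),
                )
            )
    rset.append(MembraneSlabRestraint(
        sites=tuple((chains[0], i) for i in range(1, nres + 1))
    ))
    rset.append(StericsRestraint())
    return rset


class TestOracleEquivalence:
    def test_compiled_score_matches_per_restraint_summation(self, rng):
        """total_score (reference loop) vs CompiledScore (vectorized) and an
        independent per-restraint brute-force sum, 100 random draws."""
        weights = ScoreWeights()
        for _ in range(100):
            model = random_model(rng, n_chains=3, n_res=6)
            rset = _random_restraint_set(rng, model, n=12)
            brute = sum(
                {
                    "crosslink": weights.crosslink,
                    "crosslink_negative": 0.0,
                    "contact_inter": weights.contact_inter,
                    "contact_intra": weights.contact_intra,
                    "rigid": weights.rigid,
                    "anchor": weights.anchor,
                    "slab": weights.slab,
                    "sterics": weights.sterics,
                }[_class_of(r)] * restraint_energy(model, r)
                for r in rset
            )
            ref = total_score(model, rset, weights).total
            fast = CompiledScore(model, rset, weights).energy(model.coords)
            assert ref == pytest.approx(brute, rel=1e-9)
            assert fast == pytest.approx(ref, rel=1e-9)

    def test_count_violations_matches_naive_double_loop(self, rng):
        for _ in range(100):
            model = random_model(rng, n_chains=3, n_res=6)
            rset = _random_restraint_set(rng, model, n=15)
            counts = count_violations(model, rset)
            naive = {"crosslink": 0, "crosslink_negative": 0,
                     "contact_inter": 0, "contact_intra": 0}
            for r in rset:
                if isinstance(r, CrosslinkRestraint):
                    d = ambiguous_min_distance(model, r)
                    if r.polarity == "positive" and d > r.upper_bound:
                        naive["crosslink"] += 1
                    if r.polarity == "negative" and d < r.upper_bound:
                        naive["crosslink_negative"] += 1
                elif isinstance(r, ContactRestraint):
                    if ambiguous_min_distance(model, r) > r.upper_bound:
                        naive[f"contact_{r.kind}"] += 1
            for key, val in naive.items():
                assert counts[key] == val


def _class_of(r):
    from xlfold.restraints import restraint_class

    return restraint_class(r)


class TestCountViolations:
    def test_satisfied_model_has_zero_counts(self):
        model = make_model({"A": [[0, 0, 0]], "B": [[5, 0, 0]]})
        rset = [CrosslinkRestraint(("A", 1), ("B", 1), upper_bound=6.0)]
        assert count_violations(model, rset)["total"] == 0

    def test_constructed_violations_counted_exactly(self):
        # beads at controlled distances: exactly 3 positive bounds exceeded
        model = make_model(
            {"A": [[0, 0, 0], [10, 0, 0], [20, 0, 0], [30, 0, 0]],
             "B": [[0, 5, 0], [10, 9, 0], [20, 9, 0], [30, 9, 0]]}
        )
        rset = [
            CrosslinkRestraint(("A", 1), ("B", 1), upper_bound=6.0),  # d=5 ok
            CrosslinkRestraint(("A", 2), ("B", 2), upper_bound=6.0),  # d=9 broken
            CrosslinkRestraint(("A", 3), ("B", 3), upper_bound=6.0),  # d=9 broken
            CrosslinkRestraint(("A", 4), ("B", 4), upper_bound=6.0),  # d=9 broken
        ]
        assert count_violations(model, rset)["crosslink"] == 3

    @given(tol=st.floats(min_value=0.0, max_value=30.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_counts_non_increasing_in_tolerance(self, tol):
        rng = np.random.default_rng(7)
        model = random_model(rng)
        rset = [
            CrosslinkRestraint(("A", i), ("B", j), upper_bound=8.0)
            for i, j in [(1, 1), (2, 5), (3, 7), (8, 2)]
        ]
        c0 = count_violations(model, rset, tol=0.0)["crosslink"]
        ct = count_violations(model, rset, tol=tol)["crosslink"]
        assert ct <= c0


class TestCompiledGradient:
    def test_ambiguous_restraint_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(31)
        chains = {c: rng.uniform(-15, 15, (4, 3)) for c in "ABCD"}
        chains["E"] = rng.uniform(20, 35, (4, 3))
        model = make_model(chains, groups={c: "FB" for c in "ABCD"})
        rset = [CrosslinkRestraint(("FB", 2), ("E", 3), upper_bound=4.0),
                ContactRestraint(("FB", 1), ("E", 4), upper_bound=5.0)]
        cs = CompiledScore(model, rset)
        X = model.coords.copy()
        f, g = cs.energy_and_grad(X)
        assert f > 0
        h = 1e-6
        for idx in [(1, 0), (5, 1), (9, 2), (13, 0), (18, 1)]:
            Xp = X.copy(); Xp[idx] += h
            Xm = X.copy(); Xm[idx] -= h
            fd = (cs.energy(Xp) - cs.energy(Xm)) / (2 * h)
            assert g[idx] == pytest.approx(fd, rel=1e-4, abs=1e-5)

    def test_analytic_gradient_matches_finite_differences(self, rng):
        model = random_model(rng, n_chains=2, n_res=6)
        rset = _random_restraint_set(rng, model, n=10)
        cs = CompiledScore(model, rset)
        X = model.coords.copy()
        f, g = cs.energy_and_grad(X)
        h = 1e-6
        for idx in [(0, 0), (3, 1), (7, 2), (11, 0)]:
            Xp = X.copy()
            Xp[idx] += h
            Xm = X.copy()
            Xm[idx] -= h
            fd = (cs.energy(Xp) - cs.energy(Xm)) / (2 * h)
            assert g[idx] == pytest.approx(fd, rel=1e-4, abs=1e-5)
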