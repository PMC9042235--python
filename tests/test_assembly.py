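import numpy as np
import pytest

from xlfold.config import AnnealSchedule, ScoreWeights
from xlfold.core import superposed_rmsd
from xlfold.assembly import (
    Stage,
    StagePlan,
    anneal,
    build_ensemble,
    inhibition_complex_plan,
    minimize,
    place_zinc,
    run_stage_plan,
    select_best,
)
from xlfold.io_formats import load_inhibition_complex, write_ca_pdb
from xlfold.restraints import (
    AnchorRestraint,
    CrosslinkRestraint,
    RigidGroupRestraint,
    StericsRestraint,
    ambiguous_min_distance,
    count_violations,
    from_table,
    total_score,
)
from xlfold.synthetic_data import SynthSpec, ideal_helix, make_reference_complex, scramble, simulate_crosslinks

from conftest import make_model

TINY = AnnealSchedule(cycles=2, steps_per_cycle=30, temperatures=(3.0, 1.0),
                      minimize_steps=25)
NOOP = AnnealSchedule(cycles=1, steps_per_cycle=0, temperatures=(1.0,),
                      minimize_steps=0)


class TestMinimize:
    def test_zero_score_model_is_fixed_point(self):
        model = make_model({"A": [[0, 0, 0]], "B": [[5, 0, 0]]})
        rset = [CrosslinkRestraint(("A", 1), ("B", 1), upper_bound=8.0)]
        out = minimize(model, rset)
        np.testing.assert_allclose(out.coords, model.coords, atol=1e-9)

    def test_single_anchor_quadratic_bowl_converges(self):
        model = make_model({"A": [[10.0, -4.0, 2.0]]})
        target = np.array([[1.0, 2.0, 3.0]])
        rset = [AnchorRestraint(sites=(("A", 1),), reference=target, k=0.1)]
        out = minimize(model, rset, steps=500)
        np.testing.assert_allclose(out.coords, target, atol=1e-3)

    def test_two_bead_crosslink_pulled_inside_bound(self, two_bead_model):
        rset = [CrosslinkRestraint(("A", 1), ("B", 1), upper_bound=10.0)]
        out = minimize(two_bead_model, rset, steps=200)
        d = np.linalg.norm(out.coords[0] - out.coords[1])
        assert d <= 10.0 + 1e-3

    def test_score_never_increases(self, rng):
        from xlfold.restraints import CompiledScore
        from xlfold.assembly import _minimize_coords

        model = make_model({"A": rng.uniform(-20, 20, (6, 3)),
                            "B": rng.uniform(-20, 20, (6, 3))})
        rset = [
            CrosslinkRestraint(("A", 2), ("B", 3), upper_bound=5.0),
            StericsRestraint(),
        ]
        cs = CompiledScore(model, rset)
        scores = []
        X = model.coords
        for steps in (0, 5, 10, 20, 40, 80):
            Xs = _minimize_coords(cs, X, steps)
            scores.append(cs.energy(Xs))
        assert all(b <= a + 1e-12 for a, b in zip(scores, scores[1:]))


class TestAnneal:
    def test_noop_schedule_is_identity(self, rng):
        model = make_model({"A": rng.uniform(-9, 9, (5, 3)),
                            "B": rng.uniform(-9, 9, (5, 3))})
        rset = [CrosslinkRestraint(("A", 1), ("B", 1), upper_bound=1.0)]
        out = anneal(model, rset, schedule=NOOP, seed=1)
        np.testing.assert_array_equal(out.model.coords, model.coords)

    def test_same_seed_bit_identical(self, rng):
        model = make_model({"A": rng.uniform(-9, 9, (5, 3)),
                            "B": rng.uniform(-9, 9, (5, 3))})
        rset = [CrosslinkRestraint(("A", 2), ("B", 4), upper_bound=6.0),
                StericsRestraint()]
        a = anneal(model, rset, schedule=TINY, seed=77)
        b = anneal(model, rset, schedule=TINY, seed=77)
        np.testing.assert_array_equal(a.model.coords, b.model.coords)
        assert a.trace == b.trace

    def test_trace_non_increasing_at_cycle_boundaries(self, rng):
        model = make_model({"A": rng.uniform(-30, 30, (8, 3)),
                            "B": rng.uniform(-30, 30, (8, 3))})
        rset = [CrosslinkRestraint(("A", i), ("B", i), upper_bound=6.0)
                for i in (1, 4, 8)] + [StericsRestraint()]
        res = anneal(model, rset, schedule=TINY, seed=3)
        assert all(b <= a + 1e-9 for a, b in zip(res.trace, res.trace[1:]))

    def test_recovery_of_toy_dimer_with_complete_restraints(self):
        """Scrambled two-chain system with all true inter-bead distance
        bounds recovers to zero cross-link violations in >= 8/10 seeds."""
        spec = SynthSpec(helices_per_chain=1, helix_length=10)
        ref = make_reference_complex(spec)
        rset = []
        a, b = ref.topology.chains
        Xa, Xb = ref.chain_coords("A"), ref.chain_coords("B")
        for i in range(1, a.n_residues + 1, 2):
            for j in range(1, b.n_residues + 1, 2):
                d = np.linalg.norm(Xa[i - 1] - Xb[j - 1])
                rset.append(
                    CrosslinkRestraint(("A", i), ("B", j),
                                       upper_bound=float(d) + 0.5)
                )
        for c in ref.topology.chains:
            rset.append(RigidGroupRestraint(
                chain_id=c.chain_id, residues=c.residue_numbers,
                reference=ref.chain_coords(c.chain_id)))
        rset.append(StericsRestraint())
        ok = 0
        for seed in range(10):
            start = scramble(ref, seed=seed, magnitude=25.0)
            res = anneal(start, rset, schedule=AnnealSchedule(), seed=seed)
            if count_violations(res.model, rset)["crosslink"] == 0:
                ok += 1
        assert ok >= 8


class TestStagePlan:
    def test_single_stage_plan_equals_anneal(self, rng):
        model = make_model({"A": rng.uniform(-9, 9, (6, 3)),
                            "B": rng.uniform(-9, 9, (6, 3))})
        rset = [CrosslinkRestraint(("A", 1), ("B", 2), upper_bound=5.0),
                StericsRestraint()]
        plan = StagePlan.single_stage(model.topology)
        cc = {c.chain_id: model.chain_coords(c.chain_id)
              for c in model.topology.chains}
        seed = 42
        result = run_stage_plan(plan, cc, rset, schedule=TINY, seed=seed)
        stage_seed = int(np.random.default_rng(seed).integers(2**31))
        direct = anneal(model, rset, schedule=TINY, seed=stage_seed)
        np.testing.assert_array_equal(result.model.coords, direct.model.coords)

    def test_truncation_removes_residues_and_their_restraints(self, rng):
        model = make_model({"A": rng.uniform(-9, 9, (6, 3)),
                            "B": rng.uniform(-9, 9, (6, 3))})
        rset = [
            CrosslinkRestraint(("A", 1), ("B", 1), upper_bound=50.0),
            CrosslinkRestraint(("A", 6), ("B", 6), upper_bound=50.0),
        ]
        plan = StagePlan(
            topology=model.topology,
            stages=(
                Stage(name="both", add_chains=("A", "B"), place_added=False),
                Stage(name="trim", drop_residues=(("B", (5, 6)),)),
            ),
        )
        cc = {c.chain_id: model.chain_coords(c.chain_id)
              for c in model.topology.chains}
        result = run_stage_plan(plan, cc, rset, schedule=NOOP, seed=0)
        final = result.model
        assert final.topology.chain("B").residue_numbers == (1, 2, 3, 4)
        active_log = [l for l in result.log if "active restraints" in l]
        assert active_log[0].endswith("2 active restraints")
        assert active_log[1].endswith("1 active restraints")

    def test_extra_restraint_on_absent_entity_names_stage(self, rng):
        model = make_model({"A": rng.uniform(-9, 9, (4, 3)),
                            "B": rng.uniform(-9, 9, (4, 3))})
        plan = StagePlan(
            topology=model.topology,
            stages=(
                Stage(name="first", add_chains=("A",),
                      extra_restraints=(
                          CrosslinkRestraint(("A", 1), ("B", 1), upper_bound=9.0),
                      )),
                Stage(name="second", add_chains=("B",)),
            ),
        )
        cc = {c.chain_id: model.chain_coords(c.chain_id)
              for c in model.topology.chains}
        with pytest.raises(ValueError, match="first"):
            run_stage_plan(plan, cc, [], schedule=NOOP, seed=0)

    def test_chain_added_twice_rejected(self, rng):
        model = make_model({"A": rng.uniform(0, 1, (3, 3))})
        with pytest.raises(ValueError, match="added twice"):
            StagePlan(
                topology=model.topology,
                stages=(Stage(name="a", add_chains=("A",)),
                        Stage(name="b", add_chains=("A",))),
            )

    def test_staged_protocol_runs_and_emits_seven_snapshots(self):
        fx = load_inhibition_complex()
        plan = inhibition_complex_plan(fx)
        assert len(plan.stages) == 7
        cc = {
            c.chain_id: ideal_helix(c.n_residues)
            for c in plan.topology.chains
        }
        rset = list(from_table(fx.restraints)) + [StericsRestraint()]
        small = AnnealSchedule(cycles=1, steps_per_cycle=4, temperatures=(2.0,),
                               minimize_steps=4)
        result = run_stage_plan(plan, cc, rset, schedule=small, seed=1)
        assert len(result.snapshots) == 7
        names = [n for n, _ in result.snapshots]
        assert names[0] == "protease-monomer" and names[-1] == "add-spoivfa"
        # proregion gone after stage 5
        sigk = result.model.topology.copies("sigK")[0]
        assert result.model.topology.chain(sigk).residue_numbers[0] == 38
        # final topology matches the fixture complex
        assert result.model.topology.n_residues == fx.topology.n_residues


class TestEnsemble:
    def _toy(self, rng):
        model = make_model({"A": rng.uniform(-9, 9, (5, 3)),
                            "B": rng.uniform(-9, 9, (5, 3))})
        rset = [CrosslinkRestraint(("A", 1), ("B", 1), upper_bound=8.0),
                StericsRestraint()]
        plan = StagePlan.single_stage(model.topology)
        cc = {c.chain_id: model.chain_coords(c.chain_id)
              for c in model.topology.chains}
        return plan, cc, rset

    def test_single_model_is_selected(self, rng):
        plan, cc, rset = self._toy(rng)
        res = build_ensemble(plan, cc, rset, schedule=TINY, n_models=1, base_seed=5)
        assert res.selected_index == 0

    def test_default_ensemble_size_is_eight(self):
        import inspect

        sig = inspect.signature(build_ensemble)
        assert sig.parameters["n_models"].default == 8

    def test_rigged_selection_picks_fewest_crosslink_violations(self):
        counts = [
            {"crosslink": 2}, {"crosslink": 1}, {"crosslink": 4},
            {"crosslink": 0}, {"crosslink": 1},
        ]
        scores = [1.0, 0.5, 0.1, 9.9, 0.2]
        assert select_best(counts, scores) == 3

    def test_tie_breaks_by_score_then_index(self):
        counts = [{"crosslink": 1}] * 3
        assert select_best(counts, [3.0, 1.0, 1.0]) == 1
        assert select_best(counts, [2.0, 2.0, 2.0]) == 0

    def test_serialized_result_is_deterministic(self, rng):
        plan, cc, rset = self._toy(rng)
        r1 = build_ensemble(plan, cc, rset, schedule=TINY, n_models=2, base_seed=9)
        r2 = build_ensemble(plan, cc, rset, schedule=TINY, n_models=2, base_seed=9)
        assert r1.to_json().encode() == r2.to_json().encode()


class TestPlaceZinc:
    def test_centroid_position(self):
        xyz = np.zeros((140, 3))
        xyz[:, 0] = np.arange(140) * 10.0  # spread out, no clash warning
        xyz[136] = [0, 0, 0]   # residue 137
        xyz[42] = [3, 0, 0]    # residue 43
        xyz[46] = [0, 3, 0]    # residue 47
        model = make_model({"A": xyz}, groups={"A": "FB"})
        with pytest.warns(UserWarning, match="zinc site"):
            out = place_zinc(model, chain_group="FB")  # centroid abuts a ligand bead
        np.testing.assert_allclose(out.zinc[0], [1.0, 1.0, 0.0])

    def test_one_zinc_per_tetramer_subunit(self):
        rng = np.random.default_rng(0)
        chains = {c: rng.uniform(0, 200, (140, 3)) for c in "ABCD"}
        model = make_model(chains, groups={c: "FB" for c in "ABCD"})
        out = place_zinc(model, chain_group="FB")
        assert out.zinc.shape == (4, 3)

    def test_zinc_round_trips_through_pdb(self, tmp_path):
        xyz = np.arange(140 * 3, dtype=float).reshape(140, 3) * 3.0
        model = make_model({"A": xyz}, groups={"A": "FB"})
        out = place_zinc(model, chain_group="FB")
        write_ca_pdb(out, tmp_path / "m.pdb")
        text = (tmp_path / "m.pdb").read_text()
        assert sum(1 for l in text.splitlines() if l.startswith("HETATM")) == 1

    def test_missing_ligand_residue_is_hard_error(self):
        model = make_model({"A": np.zeros((10, 3))}, groups={"A": "FB"})
        with pytest.raises(ValueError, match="ligand"):
            place_zinc(model, chain_group="FB")
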