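"""Closed-loop model evolution: flagging, re-optimization, gating, rounds."""

import numpy as np
import pytest

from kbplan import structures as st
from kbplan.cohort import CohortConfig, cohort_stream, generate_cohort, plan_with_skill
from kbplan.evolution import (
    PlanDatabase,
    RefinementConfig,
    default_margins,
    flag_suboptimal,
    reoptimize_plan,
    run_evolution,
    run_refinement_round,
    self_check_gate,
)
from kbplan.model import fit_model, predict_dvh
from kbplan.pqm import score_plan


@pytest.fixture(scope="module")
def world():
    """A 25-plan database with one deliberately poor plan, plus its model."""
    entries = generate_cohort(CohortConfig(n_patients=25, seed=100, sigma_eps=0.03))
    # degrade one plan far beyond the rest
    plan, feats = entries[4]
    bad = plan_with_skill(plan.patient, 0.35)
    entries[4] = (bad, feats)
    db = PlanDatabase(entries=list(entries), version=0)
    model = fit_model(db.entries, version_label="C_0")
    return db, model


def _estimates(model, features):
    return {oar: predict_dvh(model, features, oar, z=0.0) for oar in st.OAR_ENDPOINTS}


class TestFlagging:
    def test_infinite_margin_flags_nothing(self, world):
        db, model = world
        margins = {oar: np.inf for oar in st.OAR_ENDPOINTS}
        assert flag_suboptimal(db, model, margins) == []

    def test_plan_equal_to_prediction_not_flagged(self, world):
        _, model = world
        plan, feats = generate_cohort(CohortConfig(n_patients=1, seed=200))[0]
        synthetic_pred = {
            oar: predict_dvh(model, feats, oar, z=0.0).predicted
            for oar in st.OAR_ENDPOINTS
        }
        mirrored = type(plan)(
            patient_id="mirror",
            curves={**plan.curves, **synthetic_pred},
            prescriptions=plan.prescriptions,
        )
        other, _ = generate_cohort(CohortConfig(n_patients=1, seed=201))[0]
        db = PlanDatabase(entries=[(mirrored, feats), (other, feats)], version=0)
        margins = {oar: 0.0 for oar in st.OAR_ENDPOINTS}
        assert "mirror" not in flag_suboptimal(db, model, margins)

    def test_worst_plan_flagged_at_default_margin(self, world):
        db, model = world
        flagged = flag_suboptimal(db, model)
        assert db.entries[4][0].patient_id in flagged


class TestReoptimize:
    def test_zero_skill_returned_unchanged(self, world):
        _, model = world
        plan, feats = generate_cohort(CohortConfig(n_patients=1, seed=300, sigma_eps=0.0))[0]
        out = reoptimize_plan(plan, _estimates(model, feats), RefinementConfig())
        assert out is plan

    def test_skill_shrinks_by_powers_of_the_reopt_factor(self, world):
        _, model = world
        plan, feats = generate_cohort(CohortConfig(n_patients=1, seed=301))[0]
        bad = plan_with_skill(plan.patient, 0.1)
        out = reoptimize_plan(bad, _estimates(model, feats), RefinementConfig())
        assert out.skill_eps <= 0.1
        candidates = [0.1 * 0.5**k for k in range(9)]
        assert any(out.skill_eps == pytest.approx(c) for c in candidates)

    def test_never_worse_on_any_endpoint(self, world):
        _, model = world
        from kbplan.dvh import evaluate_metric

        for seed in range(302, 308):
            plan, feats = generate_cohort(CohortConfig(n_patients=1, seed=seed))[0]
            out = reoptimize_plan(plan, _estimates(model, feats), RefinementConfig())
            for oar, ep in st.OAR_ENDPOINTS.items():
                assert evaluate_metric(out, oar, ep) <= evaluate_metric(plan, oar, ep) + 1e-9

    def test_external_plan_without_surrogate_rejected(self, world):
        _, model = world
        plan, feats = generate_cohort(CohortConfig(n_patients=1, seed=310))[0]
        stripped = type(plan)(
            patient_id=plan.patient_id,
            curves=plan.curves,
            prescriptions=plan.prescriptions,
            provenance="CP",
        )
        with pytest.raises(NotImplementedError):
            reoptimize_plan(stripped, _estimates(model, feats), RefinementConfig())


class TestGate:
    def test_prediction_itself_is_accepted(self, world):
        _, model = world
        _, feats = generate_cohort(CohortConfig(n_patients=1, seed=400))[0]
        pred_curves = {
            oar: predict_dvh(model, feats, oar, z=0.0).predicted
            for oar in st.OAR_ENDPOINTS
        }
        base, _ = generate_cohort(CohortConfig(n_patients=1, seed=401))[0]
        tie_plan = type(base)(
            patient_id="tie",
            curves={**base.curves, **pred_curves},
            prescriptions=base.prescriptions,
        )
        assert self_check_gate(tie_plan, feats, model)

    def test_worse_plan_rejected(self, world):
        _, model = world
        plan, feats = generate_cohort(CohortConfig(n_patients=1, seed=402))[0]
        very_bad = plan_with_skill(plan.patient, 0.5)
        assert not self_check_gate(very_bad, feats, model)

    def test_reoptimization_composes_with_gate(self, world):
        """Whenever re-optimization reaches its targets, the gate accepts."""
        _, model = world
        from kbplan.dvh import evaluate_metric, evaluate_metric_on_curve

        accepted_any = False
        for seed in range(403, 413):
            plan, feats = generate_cohort(CohortConfig(n_patients=1, seed=seed))[0]
            est = _estimates(model, feats)
            out = reoptimize_plan(plan, est, RefinementConfig())
            reached = all(
                evaluate_metric(out, oar, ep)
                <= evaluate_metric_on_curve(est[oar].predicted, ep)
                for oar, ep in st.OAR_ENDPOINTS.items()
            )
            if reached:
                assert self_check_gate(out, feats, model)
                accepted_any = True
        assert accepted_any


class TestRounds:
    def test_closed_loop_round_keeps_size(self, world):
        db, model = world
        new_db, new_model = run_refinement_round(
            db, model, iter(()), RefinementConfig(), n_additions=0
        )
        assert len(new_db) == len(db)
        assert new_db.version == db.version + 1
        assert new_model.version_label == f"C_{new_db.version}"

    def test_adding_round_grows_by_quota(self, world):
        db, model = world
        stream = cohort_stream(CohortConfig(seed=500))
        new_db, _ = run_refinement_round(db, model, stream, RefinementConfig(), n_additions=5)
        assert len(new_db) == len(db) + 5

    def test_flagged_plans_resolved_or_at_best_effort(self, world):
        """After a closed-loop round, a plan is either no longer flagged
        against the old model or has been driven to its achievable optimum
        (the prediction asks for more than the anatomy allows)."""
        db, model = world
        margins = default_margins(st.OAR_ENDPOINTS)
        before = set(flag_suboptimal(db, model, margins))
        new_db, _ = run_refinement_round(db, model, iter(()), RefinementConfig(), n_additions=0)
        still = set(flag_suboptimal(new_db, model, margins))
        assert still <= before
        exhausted = {p.patient_id for p, _ in new_db.entries if (p.skill_eps or 0) < 1e-3}
        assert still <= exhausted

    def test_exhausted_stream_raises_naming_round(self, world):
        db, model = world
        with pytest.raises(ValueError, match="round 1"):
            run_refinement_round(db, model, iter(()), RefinementConfig(), n_additions=3)


@pytest.fixture(scope="module")
def outcome():
    seed = 1
    initial = generate_cohort(CohortConfig(n_patients=25, seed=seed))
    stream = cohort_stream(CohortConfig(seed=seed + 1))
    eval_cohort = generate_cohort(
        CohortConfig(n_patients=35, seed=seed + 2, sigma_eps=0.0)
    )
    return run_evolution(initial, stream, eval_cohort)


class TestFullEvolution:
    def test_seven_models_with_expected_sizes(self, outcome):
        models, trace = outcome
        assert [m.version_label for m in models] == [f"C_{i}" for i in range(7)]
        assert trace.to_frame()["database_size"].tolist() == [25, 25, 40, 55, 70, 85, 100]

    def test_no_plan_removed_and_ids_unique(self, outcome):
        models, trace = outcome
        sizes = trace.to_frame()["database_size"]
        assert sizes.is_monotonic_increasing

    def test_prediction_error_improves_from_c1_to_c6(self, outcome):
        _, trace = outcome
        df = trace.to_frame().set_index("model")
        for oar in st.OAR_ENDPOINTS:
            assert df.loc["C_6", f"error_{oar}"] < df.loc["C_1", f"error_{oar}"]

    def test_database_quality_does_not_degrade(self, outcome):
        _, trace = outcome
        df = trace.to_frame()
        assert df["mean_pqm"].iloc[-1] >= df["mean_pqm"].iloc[0]
        # round-to-round changes are improvements up to the anatomy mix of
        # newly admitted patients
        assert (df["mean_pqm"].diff().dropna() > -0.2).all()

    def test_determinism_under_fixed_seed(self):
        def run():
            initial = generate_cohort(CohortConfig(n_patients=25, seed=11))
            stream = cohort_stream(CohortConfig(seed=12))
            eval_cohort = generate_cohort(CohortConfig(n_patients=5, seed=13, sigma_eps=0.0))
            cfg = RefinementConfig(n_rounds=2)
            return run_evolution(initial, stream, eval_cohort, cfg)

        m1, t1 = run()
        m2, t2 = run()
        assert t1.to_frame().equals(t2.to_frame())
        for a, b in zip(m1, m2):
            for oar in a.oars:
                assert np.array_equal(a.submodels[oar].coef, b.submodels[oar].coef)
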