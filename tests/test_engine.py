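"""Event-calendar engine: hand traces, conservation laws, M/M/c agreement."""

import numpy as np
import pytest

from edsim.arrivals import ArrivalEventList
from edsim.config import PolicySpec
from edsim.engine import run_experiment, run_replication
from edsim.metrics import summarize, waiting_times
from helpers import erlang_c_mean_wait, exam_config, mmc_scenario, simple_scenario


def scripted(times, levels):
    return ArrivalEventList(np.asarray(times, float), np.asarray(levels, int))


class TestMicroTraces:
    def test_two_patients_one_physician(self):
        """L3 at t=0 and L4 at t=1 with 10-min services: waits (0, 9)."""
        cfg = simple_scenario(physicians=1)
        for policy in ("IFP", "ALT"):
            res = run_replication(cfg, policy, seed=3, arrivals=scripted([0.0, 1.0], [3, 4]))
            r0, r1 = res.records
            assert r0.init_start == pytest.approx(0.0, abs=1e-5)
            assert r0.init_end == pytest.approx(10.0, abs=1e-5)
            assert r1.init_start == pytest.approx(10.0, abs=1e-5)
            assert r1.init_end == pytest.approx(20.0, abs=1e-5)
            assert r1.init_wait == pytest.approx(9.0, abs=1e-5)

    def test_empty_schedule_runs_empty(self):
        res = run_replication(simple_scenario(rate=0.0), "IFP", seed=1)
        assert res.n_arrivals == 0
        assert res.physician_busy_min == 0.0
        assert all(v == 0.0 for v in res.device_busy_min.values())

    def test_exam_chain_timing_single_ct(self):
        """One CT after a consult ending at t=10: processing 10-12.45, results at 42.45."""
        cfg = simple_scenario(physicians=1, exams=exam_config(p_exam=1.0, laboratory=0.0, ultrasound=0.0, xray=0.0, ct=1.0))
        res = run_replication(cfg, "IFP", seed=2, arrivals=scripted([0.0], [4]))
        (rec,) = res.records
        visit = rec.exams[0]
        assert visit.start == pytest.approx(10.0, abs=1e-5)
        assert visit.proc_end == pytest.approx(12.45, abs=1e-5)
        assert rec.t_exam == pytest.approx(42.45, abs=1e-5)
        assert rec.follow_join == pytest.approx(42.45, abs=1e-5)
        assert rec.follow_start == pytest.approx(42.45, abs=1e-5)  # idle physician

    def test_exam_chain_overlapping_reports(self):
        """X-ray (3.99 + 30) then laboratory (1.19 + 20): report delays overlap,
        so all results land at the X-ray report time."""
        cfg = simple_scenario(physicians=1, exams=exam_config(p_exam=1.0, laboratory=1.0, ultrasound=0.0, xray=1.0, ct=0.0))
        res = run_replication(cfg, "IFP", seed=2, arrivals=scripted([0.0], [4]))
        (rec,) = res.records
        xray, lab = rec.exams
        assert (xray.modality, lab.modality) == ("xray", "laboratory")
        assert xray.start == pytest.approx(10.0, abs=1e-5)
        assert lab.start == pytest.approx(13.99, abs=1e-5)  # after X-ray processing
        assert rec.t_exam == pytest.approx(43.99, abs=1e-5)  # X-ray report dominates

    def test_device_contention_emergent_delay(self):
        """Second patient finds the CT busy: extra delay = device free - ready."""
        cfg = simple_scenario(
            physicians=2,
            service_min=5.0,
            exams=exam_config(p_exam=1.0, laboratory=0.0, ultrasound=0.0, xray=0.0, ct=1.0, ct_tau=30.0),
        )
        res = run_replication(cfg, "IFP", seed=2, arrivals=scripted([0.0, 1.0], [4, 4]))
        first, second = res.records
        assert first.exams[0].start == pytest.approx(5.0, abs=1e-5)
        # second ready at 6, CT busy until 35
        assert second.exams[0].ready == pytest.approx(6.0, abs=1e-5)
        assert second.exams[0].start == pytest.approx(35.0, abs=1e-5)
        assert second.exams[0].extra_delay == pytest.approx(29.0, abs=1e-5)

    def test_slack_rule_serves_followup_before_nonurgent_initial(self):
        """At the decisive epoch a follow-up-ready patient outranks a Level-IV
        initial far from its deadline under SBP, but not under IFP."""
        exams = exam_config(p_exam=1.0, laboratory=0.0, ultrasound=0.0, xray=0.0, ct=1.0)
        arrivals = scripted([0.0, 35.0, 44.0], [4, 4, 4])
        sbp = simple_scenario(physicians=1, exams=exams, policy=PolicySpec("SBP", 13.1, 2.0))
        res = run_replication(sbp, seed=4, arrivals=arrivals)
        p0, _, p2 = res.records
        assert p0.t_exam == pytest.approx(42.45, abs=1e-5)
        assert p0.follow_start == pytest.approx(45.0, abs=1e-5)  # wait 10 < 118: P2 not urgent
        assert p2.init_start == pytest.approx(55.0, abs=1e-5)
        res = run_replication(simple_scenario(physicians=1, exams=exams), "IFP", seed=4, arrivals=arrivals)
        p0, _, p2 = res.records
        assert p2.init_start == pytest.approx(45.0, abs=1e-5)  # initials first
        assert p0.follow_start == pytest.approx(55.0, abs=1e-5)


class TestConservationAndCapacity:
    def test_flow_conservation(self, baseline):
        res = run_replication(baseline, "IFP", seed=9)
        n_completed = sum(r.completed_pathway for r in res.records)
        n_partial = sum(
            r.completed_initial and not r.completed_pathway for r in res.records
        )
        n_unserved = sum(not r.completed_initial for r in res.records)
        assert n_completed + n_partial + n_unserved == res.n_arrivals

    def test_queue_update_identities_between_epochs(self, baseline):
        """W(next) = W(prev) + inflow - allocated, per class, at every epoch."""
        res = run_replication(baseline, "SBP", seed=9, record_epochs=True)
        log = res.epoch_log
        assert len(log) > 1000
        for prev, nxt in zip(log, log[1:]):
            for c in range(3):
                assert nxt.before[c] == prev.before[c] - prev.allocated[c] + nxt.inflow[c]

    @pytest.mark.parametrize("policy", ["IFP", "ALT", "SBP"])
    def test_no_consult_starts_beyond_scheduled_capacity(self, baseline, policy):
        res = run_replication(baseline, policy, seed=5)
        starts, ends = [], []
        for r in res.records:
            for s, e in ((r.init_start, r.init_end), (r.follow_start, r.follow_end)):
                if not np.isnan(s):
                    starts.append(s)
                    ends.append(e if not np.isnan(e) else res.horizon)
        starts = np.sort(np.array(starts))
        ends_sorted = np.sort(np.array(ends))
        for t in starts:
            concurrent = (
                np.searchsorted(starts, t, side="right")
                - np.searchsorted(ends_sorted, t, side="right")
            )
            assert concurrent <= baseline.staffing.physicians_at(t)

    def test_nonpreemption_durations_within_bounds(self, baseline):
        res = run_replication(baseline, "ALT", seed=6)
        for r in res.records:
            if r.completed_initial:
                d = r.init_end - r.init_start
                assert baseline.consult_initial.lower <= d <= baseline.consult_initial.upper
            if r.completed_followup:
                d = r.follow_end - r.follow_start
                assert baseline.consult_followup.lower <= d <= baseline.consult_followup.upper

    def test_initial_first_dominance(self, baseline):
        """Under IFP a follow-up consult starts only when both initial queues
        are empty: every earlier-arrived patient has already started."""
        res = run_replication(baseline, "IFP", seed=7)
        follow_starts = sorted(
            r.follow_start for r in res.records if not np.isnan(r.follow_start)
        )
        records = sorted(res.records, key=lambda r: r.arrival)
        arrivals = np.array([r.arrival for r in records])
        init_starts = np.array(
            [r.init_start if not np.isnan(r.init_start) else np.inf for r in records]
        )
        for t in follow_starts[:: max(1, len(follow_starts) // 200)]:
            mask = arrivals < t - 1e-9
            assert np.all(init_starts[mask] <= t + 1e-9)

    def test_patient_timestamps_monotone(self, baseline):
        res = run_replication(baseline, "SBP", seed=8)
        for r in res.records:
            path = [r.arrival, r.init_start, r.init_end, r.t_exam, r.follow_join,
                    r.follow_start, r.follow_end]
            path = [x for x in path if not np.isnan(x)]
            assert all(a <= b + 1e-9 for a, b in zip(path, path[1:]))
            if r.needs_exam and not np.isnan(r.t_exam):
                assert r.t_exam == pytest.approx(
                    max(v.report_ready for v in r.exams), abs=1e-9
                )


class TestStochasticAgreement:
    @pytest.mark.parametrize(
        "lam_hr, mean_svc, c",
        [(10.0, 9.0, 2), (20.0, 9.0, 4), (12.0, 15.0, 5)],
    )
    def test_erlang_c_closed_form(self, lam_hr, mean_svc, c):
        """Constant rate, one class, no exams: mean queue wait matches Erlang-C."""
        cfg = mmc_scenario(lam_hr, mean_svc, c)
        per_rep = []
        for r in range(20):
            wt = waiting_times(run_replication(cfg, "IFP", seed=100 + r))
            per_rep.append(wt.init3.mean())
        se = np.std(per_rep, ddof=1) / np.sqrt(len(per_rep))
        expected = erlang_c_mean_wait(lam_hr / 60.0, 1.0 / mean_svc, c)
        assert abs(np.mean(per_rep) - expected) < 3 * se


class TestDeterminismAndCRN:
    def test_same_seed_bitwise_identical(self, baseline):
        a = run_replication(baseline, "SBP", seed=31)
        b = run_replication(baseline, "SBP", seed=31)
        assert a.trail_dataframe().equals(b.trail_dataframe())
        assert a.physician_busy_min == b.physician_busy_min

    def test_common_random_numbers_share_patient_material(self, baseline):
        """Two policies at the same seed see identical arrivals, levels and
        exam requirements; only scheduling differs."""
        a = run_replication(baseline, "IFP", seed=32)
        b = run_replication(baseline, "SBP", seed=32)
        assert a.n_arrivals == b.n_arrivals
        for ra, rb in zip(a.records, b.records):
            assert ra.arrival == rb.arrival
            assert ra.level == rb.level
            assert ra.needs_exam == rb.needs_exam

    def test_experiment_seeds_offset_from_base(self, baseline):
        runs = run_experiment(baseline, "IFP", n_reps=3, base_seed=40)
        assert [r.seed for r in runs] == [40, 41, 42]
        again = run_replication(baseline, "IFP", seed=41)
        assert runs[1].trail_dataframe().equals(again.trail_dataframe())

    def test_censoring_no_event_beyond_horizon(self, baseline):
        res = run_replication(baseline, "IFP", seed=33)
        for r in res.records:
            for x in (r.init_end, r.follow_end):
                if not np.isnan(x):
                    assert x < res.horizon
        m = summarize(res, baseline)
        assert 0.0 <= m.u_doc <= 1.0
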