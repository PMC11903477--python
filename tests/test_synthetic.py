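"""Synthetic cohort generator and joint-table reconstruction."""

import itertools

import numpy as np
import pytest

from shuntpred.rules import classify_tap_response, krauss_responder
from shuntpred.synthetic import (
    CELL_ORDER,
    Dependence,
    build_fixture_cohort,
    calibrated_dependence,
    default_config,
    load_printed_targets,
    reconstruct_joint_tables,
    simulate_cohort,
)


class TestSimulateCohort:
    @pytest.mark.parametrize("seed", [0, 7, 123])
    def test_group_sizes_exact(self, seed):
        records = simulate_cohort(default_config(seed=seed))
        assert sum(r.outcome_label == "responder" for r in records) == 96
        assert sum(r.outcome_label == "non_responder" for r in records) == 70

    def test_same_seed_identical_cohorts(self):
        assert simulate_cohort(default_config(seed=5)) == simulate_cohort(default_config(seed=5))

    def test_different_seeds_differ(self):
        assert simulate_cohort(default_config(seed=5)) != simulate_cohort(default_config(seed=6))

    def test_rules_reproduce_sampled_status(self, simulated_cohort):
        # back-filled tap assessments and severity scores must round-trip
        # through the classification rules
        for r in simulated_cohort:
            responder = r.outcome_label == "responder"
            _, got = krauss_responder(r.preop_severity_score, r.postop_severity_score)
            assert got == responder

    def test_invariants_hold_by_construction(self, simulated_cohort):
        from shuntpred.cohort import validate_record

        assert all(validate_record(r) == [] for r in simulated_cohort)

    def test_mean_responder_ca_unbiased_across_seeds(self):
        # grand mean over 200 cohorts of 96 responders: SE = 14.62/sqrt(19200)
        means = []
        for seed in range(200):
            records = simulate_cohort(default_config(seed=seed))
            means.append(np.mean([r.imaging.ca for r in records if r.outcome_label == "responder"]))
        se = 14.62 / np.sqrt(96 * 200)
        assert abs(np.mean(means) - 71.21) < 3 * se

    def test_binary_rates_converge_at_large_n(self):
        cfg = default_config(seed=13)
        cfg.n_responders, cfg.n_non_responders = 50_000, 50_000
        records = simulate_cohort(cfg)
        for group, marg, n in (
            ("responder", cfg.responders, 50_000),
            ("non_responder", cfg.non_responders, 50_000),
        ):
            sub = [r for r in records if r.outcome_label == group]
            for name, rate in (("desh", marg.binary["desh"]), ("tap", marg.binary["tap_positive"])):
                if name == "desh":
                    emp = np.mean([r.imaging.desh for r in sub])
                else:
                    emp = np.mean([classify_tap_response(r.tap).positive for r in sub])
                se = np.sqrt(rate * (1 - rate) / n)
                assert abs(emp - rate) < 3 * se, (group, name)

    def test_non_psd_dependence_rejected_before_sampling(self):
        cfg = default_config(seed=0)
        cfg.dependence = Dependence(
            variables=["tap_positive", "desh", "ca"],
            matrix=[[1, 0.9, -0.9], [0.9, 1, 0.9], [-0.9, 0.9, 1]],
        )
        with pytest.raises(ValueError, match="positive definite"):
            simulate_cohort(cfg)

    def test_calibrated_dependence_induces_tap_desh_association(self):
        dep = calibrated_dependence()
        assert np.all(np.linalg.eigvalsh(np.asarray(dep.matrix)) > 0)
        cfg = default_config(seed=21)
        cfg.n_responders, cfg.n_non_responders = 20_000, 3
        cfg.dependence = dep
        records = [r for r in simulate_cohort(cfg) if r.outcome_label == "responder"]
        tap = np.array([classify_tap_response(r.tap).positive for r in records])
        desh = np.array([r.imaging.desh for r in records])
        # positive latent correlation must show as positive phi association
        assert np.corrcoef(tap, desh)[0, 1] > 0.05


# ---------------------------------------------------------------------------
# independent brute-force oracle for the reconstruction (pure-Python loops,
# no shared code with the solver)

def oracle_enumerate(n, tap_pos, desh_pos, printed, sens_side, tol=0.005):
    exact = []
    best_dev, best = float("inf"), []
    for d1 in range(0, min(tap_pos, desh_pos) + 1):
        n11, n10 = d1, tap_pos - d1
        n01, n00 = desh_pos - d1, n - tap_pos - desh_pos + d1
        if min(n10, n01, n00) < 0:
            continue
        for c11 in range(n11 + 1):
            for c10 in range(n10 + 1):
                for c01 in range(n01 + 1):
                    for c00 in range(n00 + 1):
                        pos = {
                            "tap": tap_pos,
                            "desh": desh_pos,
                            "ca": c11 + c10 + c01 + c00,
                            "tap_desh": n - n00,
                            "tap_ca": tap_pos + c01 + c00,
                            "majority": n11 + c10 + c01,
                        }
                        dev = 0.0
                        for rule, target in printed.items():
                            frac = pos[rule] / n if sens_side else (n - pos[rule]) / n
                            dev = max(dev, abs(frac - target))
                        cells = (
                            c11, n11 - c11, c10, n10 - c10,
                            c01, n01 - c01, c00, n00 - c00,
                        )
                        if dev <= tol + 1e-12:
                            exact.append(cells)
                        if dev < best_dev - 1e-12:
                            best_dev, best = dev, [cells]
                        elif abs(dev - best_dev) <= 1e-12:
                            best.append(cells)
    return sorted(exact), sorted(set(best)), best_dev


class TestReconstruction:
    def test_responder_group_exact_solutions_match_oracle(self, reconstruction_report):
        targets = load_printed_targets()
        printed = {r: targets["table4"][r]["sensitivity"] for r in targets["table4"]}
        exact, _, _ = oracle_enumerate(96, 61, 53, printed, sens_side=True)
        assert len(exact) > 0  # an exact responder table exists
        got = sorted(
            t.cells for t in [s.responders for s in reconstruction_report.solutions]
        )
        assert sorted(set(got)) == exact
        assert reconstruction_report.responders["exact"]

    def test_non_responder_group_has_no_exact_table(self, reconstruction_report):
        targets = load_printed_targets()
        printed = {r: targets["table4"][r]["specificity"] for r in targets["table4"]}
        exact, best, best_dev = oracle_enumerate(70, 28, 8, printed, sens_side=False)
        assert exact == []  # the printed values are mutually inconsistent here
        assert not reconstruction_report.non_responders["exact"]
        assert reconstruction_report.non_responders["best_deviation"] == pytest.approx(best_dev)
        got = sorted(set(s.non_responders.cells for s in reconstruction_report.solutions))
        assert got == best
        assert any("non_responders" in note for note in reconstruction_report.notes)

    def test_solver_metrics_recomputed_from_cells(self, reconstruction_report):
        sol = reconstruction_report.canonical()
        for table in (sol.responders, sol.non_responders):
            cells = table.cell_counts
            n = table.n
            ca_pos = sum(v for (t, d, c), v in cells.items() if c)
            expected = ca_pos / n if table.group == "responders" else (n - ca_pos) / n
            assert table.metrics["ca"] == pytest.approx(expected)
            assert sum(cells.values()) == n

    def test_fewer_constraints_enlarge_solution_set(self):
        targets = {
            "group_sizes": {"responders": 8, "non_responders": 6},
            "counts": {
                "responders": {"tap_positive": 5, "desh_positive": 4},
                "non_responders": {"tap_positive": 2, "desh_positive": 1},
            },
            "table4": {
                "tap": {"sensitivity": 5 / 8, "specificity": 4 / 6},
                "desh": {"sensitivity": 4 / 8, "specificity": 5 / 6},
            },
        }
        report = reconstruct_joint_tables(targets=targets)
        assert report.exact
        assert report.total_solutions > 1

    def test_contradictory_targets_yield_infeasibility_report(self):
        targets = load_printed_targets()
        bad = {**targets, "table4": {**targets["table4"]}}
        # a tap+DESH union below the tap margin alone is impossible
        bad["table4"]["tap_desh"] = {"sensitivity": 0.50, "specificity": 0.53, "auc": 0.52}
        report = reconstruct_joint_tables(targets=bad)
        assert not report.responders["exact"]
        assert any("no exact integer table" in n for n in report.notes)

    def test_report_serializes(self, reconstruction_report):
        import json

        d = reconstruction_report.to_dict()
        assert json.dumps(d, sort_keys=True)
        assert d["canonical_solution"]["table4"]["tap"]["sensitivity"] == pytest.approx(61 / 96)


class TestFixtureCohort:
    def test_tap_margins_reproduced(self, fixture_cohort):
        resp = [r for r in fixture_cohort if r.outcome_label == "responder"]
        nonresp = [r for r in fixture_cohort if r.outcome_label == "non_responder"]
        assert len(resp) == 96 and len(nonresp) == 70
        assert sum(classify_tap_response(r.tap).positive for r in resp) == 61
        assert sum(classify_tap_response(r.tap).positive for r in nonresp) == 28

    def test_desh_cross_tab_reproduced(self, fixture_cohort):
        resp = [r for r in fixture_cohort if r.outcome_label == "responder"]
        nonresp = [r for r in fixture_cohort if r.outcome_label == "non_responder"]
        assert sum(r.imaging.desh for r in resp) == 53
        assert sum(not r.imaging.desh for r in resp) == 43
        assert sum(r.imaging.desh for r in nonresp) == 8
        assert sum(not r.imaging.desh for r in nonresp) == 62

    def test_same_seed_identical_fixture(self, reconstruction_report):
        sol = reconstruction_report.canonical()
        a = build_fixture_cohort(sol, default_config(seed=3))
        b = build_fixture_cohort(sol, default_config(seed=3))
        assert a == b

    def test_ca_values_respect_cell_assignment(self, fixture_cohort, reconstruction_report):
        cutoff = 68.7
        sol = reconstruction_report.canonical()
        resp = [r for r in fixture_cohort if r.outcome_label == "responder"]
        ca_pos = sum(r.imaging.ca <= cutoff for r in resp)
        expected = sum(v for (t, d, c), v in sol.responders.cell_counts.items() if c)
        assert ca_pos == expected

    def test_group_size_mismatch_rejected(self, reconstruction_report):
        sol = reconstruction_report.canonical()
        cfg = default_config(seed=0)
        bad = type(sol.responders)(
            group="responders", n=95, cells=sol.responders.cells,
            metrics=sol.responders.metrics, deviations=sol.responders.deviations,
            max_abs_deviation=sol.responders.max_abs_deviation, exact=True,
        )
        bad_sol = type(sol)(responders=bad, non_responders=sol.non_responders)
        with pytest.raises(ValueError, match="sum"):
            build_fixture_cohort(bad_sol, cfg)
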