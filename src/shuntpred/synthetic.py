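"""Synthetic cohorts and fixture reconstruction from printed group tables.

Two distinct data sources live here:

1. :func:`simulate_cohort` draws patient-level cohorts from a latent
   Gaussian copula whose per-group marginals default to the reference
   study's group tables (96 responders / 70 non-responders, with the
   published means, SDs and rates).  Bounded quantities (CSF pressure,
   Evans index, angles, widths) are sampled by a truncated-normal quantile
   transform of the latent normal, so type invariants hold by
   construction.  Tap assessments and severity scores are back-filled so
   that the classification rules reproduce each subject's sampled tap
   status and outcome group exactly.

2. :func:`reconstruct_joint_tables` recovers the per-group joint 2x2x2
   distribution of (tap, DESH, CA-positive) that the printed tables imply:
   it enumerates every integer table honoring the exactly printed tap and
   DESH margins and keeps the tables matching each printed 2-decimal
   sensitivity/specificity within +/-0.005.  When no exact table exists
   the minimal-max-deviation tables are returned instead and the report
   says so.  :func:`build_fixture_cohort` then materializes a full patient
   cohort from a reconstructed table, for exact pipeline reproduction of
   the printed diagnostic-performance rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional

import numpy as np
from scipy import stats as sps

from .cohort import ImagingProfile, PatientRecord, TapAssessment
from .metrics import binary_auc
from .rules import TapCriteria, classify_tap_response

__all__ = [
    "GroupMarginals",
    "Dependence",
    "SimulationConfig",
    "default_config",
    "simulate_cohort",
    "load_printed_targets",
    "GroupTable",
    "JointTableSolution",
    "ReconstructionReport",
    "reconstruct_joint_tables",
    "build_fixture_cohort",
    "canonical_fixture",
    "calibrated_dependence",
    "CELL_ORDER",
]


# ---------------------------------------------------------------------------
# configuration

#: sampling bounds per continuous variable (truncated-normal support);
#: CSF pressure per the normal-pressure inclusion window, EI above the
#: ventricular-enlargement criterion, angles inside (0, 180).
_BOUNDS = {
    "age": (60.0, 95.0),
    "lp_pressure": (80.0, 200.0),
    "disease_duration": (1.0, 60.0),
    "ei": (0.301, 0.60),
    "ca": (1.0, 179.0),
    "z_ei": (0.10, 0.90),
    "bvr": (0.05, 2.50),
    "scca": (1.0, 179.0),
    "temporal_horn_left": (0.5, 20.0),
    "temporal_horn_right": (0.5, 20.0),
    "third_ventricle_width": (1.0, 25.0),
    "posterior_horn_ratio": (0.10, 0.95),
}

_CONTINUOUS = list(_BOUNDS)
_BINARY = [
    "sex_male",
    "tap_positive",
    "desh",
    "symptom_gait",
    "symptom_cognitive",
    "symptom_urinary",
    "comorb_cardiovascular",
    "comorb_endocrine",
    "comorb_neurological",
]


@dataclass
class GroupMarginals:
    """Per-group marginal distributions: (mean, sd) pairs and event rates."""

    continuous: dict  # name -> (mean, sd)
    binary: dict  # name -> rate in [0, 1]


@dataclass
class Dependence:
    """Latent-Gaussian correlation over a subset of simulated variables."""

    variables: list
    matrix: list  # square, symmetric, unit diagonal, positive definite


@dataclass
class SimulationConfig:
    n_responders: int
    n_non_responders: int
    responders: GroupMarginals
    non_responders: GroupMarginals
    ca_cutoff: float = 68.7
    center_weights: tuple = (0.5, 0.3, 0.2)
    dependence: Optional[Dependence] = None
    seed: int = 0


def default_config(seed: int = 0) -> SimulationConfig:
    """Study-condition defaults: the reference cohort's group marginals."""
    resp = GroupMarginals(
        continuous={
            "age": (71.59, 6.91),
            "lp_pressure": (129.40, 17.79),
            "disease_duration": (19.11, 7.44),
            "ei": (0.36, 0.04),
            "ca": (71.21, 14.62),
            "z_ei": (0.46, 0.08),
            "bvr": (0.76, 0.20),
            "scca": (46.25, 14.31),
            "temporal_horn_left": (8.12, 2.17),
            "temporal_horn_right": (7.80, 1.99),
            "third_ventricle_width": (11.50, 2.96),
            "posterior_horn_ratio": (0.62, 0.15),
        },
        binary={
            "sex_male": 60 / 96,
            "tap_positive": 61 / 96,
            "desh": 53 / 96,
            "symptom_gait": 93 / 96,
            "symptom_cognitive": 74 / 96,
            "symptom_urinary": 76 / 96,
            "comorb_cardiovascular": 40 / 96,
            "comorb_endocrine": 28 / 96,
            "comorb_neurological": 33 / 96,
        },
    )
    nonresp = GroupMarginals(
        continuous={
            "age": (70.71, 7.32),
            "lp_pressure": (134.20, 14.49),
            "disease_duration": (17.69, 8.12),
            "ei": (0.35, 0.04),
            "ca": (76.04, 15.06),
            "z_ei": (0.47, 0.07),
            "bvr": (0.81, 0.18),
            "scca": (50.24, 13.77),
            "temporal_horn_left": (7.65, 2.72),
            "temporal_horn_right": (7.33, 2.35),
            "third_ventricle_width": (10.94, 2.81),
            "posterior_horn_ratio": (0.60, 0.12),
        },
        binary={
            "sex_male": 50 / 70,
            "tap_positive": 28 / 70,
            "desh": 8 / 70,
            "symptom_gait": 67 / 70,
            "symptom_cognitive": 55 / 70,
            "symptom_urinary": 54 / 70,
            "comorb_cardiovascular": 33 / 70,
            "comorb_endocrine": 16 / 70,
            "comorb_neurological": 33 / 70,
        },
    )
    return SimulationConfig(
        n_responders=96, n_non_responders=70, responders=resp, non_responders=nonresp, seed=seed
    )


# ---------------------------------------------------------------------------
# cohort simulation

def _trunc_ppf(u: np.ndarray, mean: float, sd: float, lo: float, hi: float) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def _check_dependence(dep: Dependence) -> np.ndarray:
    m = np.asarray(dep.matrix, dtype=float)
    if m.shape != (len(dep.variables), len(dep.variables)):
        raise ValueError("dependence matrix shape does not match its variable list")
    if not np.allclose(m, m.T):
        raise ValueError("dependence matrix must be symmetric")
    if not np.allclose(np.diag(m), 1.0):
        raise ValueError("dependence matrix must have unit diagonal")
    try:
        np.linalg.cholesky(m)
    except np.linalg.LinAlgError as exc:
        raise ValueError("dependence matrix is not positive definite") from exc
    unknown = [v for v in dep.variables if v not in _CONTINUOUS + _BINARY]
    if unknown:
        raise ValueError(f"unknown dependence variable(s): {', '.join(unknown)}")
    return m


def _backfill_tap(rng: np.random.Generator, positive: bool) -> TapAssessment:
    """Pre/post tap measurements consistent with the sampled tap status.

    Positives always meet the gait criterion (improvement fraction in
    [0.25, 0.45]); negatives keep every criterion strictly below its
    threshold (walk changes within [-10%, +12%], MMSE change below the 10%
    gain, urinary never improving).
    """
    pre_time = float(np.clip(rng.normal(25.0, 8.0), 10.0, 90.0))
    pre_steps = int(np.clip(round(rng.normal(32.0, 9.0)), 12, 80))
    pre_mmse = int(np.clip(round(rng.normal(20.0, 4.0)), 5, 30))
    pre_ur = int(np.clip(round(rng.normal(4.0, 2.0)), 0, 9))
    if positive:
        gain = rng.uniform(0.25, 0.45)
        post_time = pre_time * (1.0 - gain)
        post_steps = max(1, int(np.floor(pre_steps * (1.0 - gain))))
        post_mmse = int(np.clip(pre_mmse + rng.integers(-1, 2), 0, 30))
        post_ur = int(np.clip(pre_ur + rng.integers(-1, 1), 0, 10))
    else:
        post_time = pre_time * (1.0 - rng.uniform(-0.10, 0.12))
        post_steps = max(1, int(np.ceil(pre_steps * (1.0 - rng.uniform(-0.10, 0.12)))))
        safe_gain = max(int(np.ceil(pre_mmse * 0.10)) - 1, 0)
        post_mmse = int(np.clip(pre_mmse + rng.integers(-2, safe_gain + 1), 0, 30))
        post_ur = int(min(10, pre_ur + rng.integers(0, 2)))
    tap = TapAssessment(
        pre_walk_time=pre_time,
        pre_walk_steps=pre_steps,
        pre_mmse=pre_mmse,
        pre_urinary=pre_ur,
        post_walk_time=post_time,
        post_walk_steps=post_steps,
        post_mmse=post_mmse,
        post_urinary=post_ur,
    )
    assert classify_tap_response(tap, TapCriteria()).positive == positive
    return tap


def _backfill_severity(rng: np.random.Generator, responder: bool) -> tuple[int, int]:
    """Pre/post severity with Krauss index >= 0.5 iff responder."""
    pre = int(rng.integers(6, 13))
    if responder:
        post = int(rng.integers(0, pre // 2 + 1))
    else:
        post = int(rng.integers(pre // 2 + 1, pre + 2))
    return pre, post


def _centers(rng: np.random.Generator, n: int, weights) -> list:
    w = np.asarray(weights, dtype=float)
    return [str(c) for c in rng.choice(["C1", "C2", "C3"], size=n, p=w / w.sum())]


def simulate_cohort(config: SimulationConfig) -> list[PatientRecord]:
    """Draw a fully synthetic cohort; reproducible per ``config.seed``.

    CA positivity is never sampled separately: it is implied by the sampled
    angle and ``config.ca_cutoff``, so the angle and its dichotomization can
    never disagree.
    """
    dep_matrix = _check_dependence(config.dependence) if config.dependence else None
    rng = np.random.default_rng(config.seed)
    order = _CONTINUOUS + _BINARY
    records: list[PatientRecord] = []
    for group, n, marg in (
        ("responder", config.n_responders, config.responders),
        ("non_responder", config.n_non_responders, config.non_responders),
    ):
        z = rng.standard_normal((n, len(order)))
        if dep_matrix is not None:
            idx = [order.index(v) for v in config.dependence.variables]
            z[:, idx] = rng.standard_normal((n, len(idx))) @ np.linalg.cholesky(dep_matrix).T
        u = sps.norm.cdf(z)
        cont = {
            name: _trunc_ppf(u[:, order.index(name)], *marg.continuous[name], *_BOUNDS[name])
            for name in _CONTINUOUS
        }
        flags = {
            name: u[:, order.index(name)] <= marg.binary[name] for name in _BINARY
        }
        centers = _centers(rng, n, config.center_weights)
        prefix = "R" if group == "responder" else "N"
        for i in range(n):
            pre_sev, post_sev = _backfill_severity(rng, group == "responder")
            records.append(
                PatientRecord(
                    id=f"{prefix}{i + 1:03d}",
                    center_id=centers[i],
                    age=float(cont["age"][i]),
                    sex="male" if flags["sex_male"][i] else "female",
                    lp_pressure=float(cont["lp_pressure"][i]),
                    disease_duration=float(cont["disease_duration"][i]),
                    symptom_gait=bool(flags["symptom_gait"][i]),
                    symptom_cognitive=bool(flags["symptom_cognitive"][i]),
                    symptom_urinary=bool(flags["symptom_urinary"][i]),
                    comorb_cardiovascular=bool(flags["comorb_cardiovascular"][i]),
                    comorb_endocrine=bool(flags["comorb_endocrine"][i]),
                    comorb_neurological=bool(flags["comorb_neurological"][i]),
                    tap=_backfill_tap(rng, bool(flags["tap_positive"][i])),
                    imaging=ImagingProfile(
                        ei=float(cont["ei"][i]),
                        desh=bool(flags["desh"][i]),
                        ca=float(cont["ca"][i]),
                        z_ei=float(cont["z_ei"][i]),
                        bvr=float(cont["bvr"][i]),
                        scca=float(cont["scca"][i]),
                        temporal_horn_left=float(cont["temporal_horn_left"][i]),
                        temporal_horn_right=float(cont["temporal_horn_right"][i]),
                        third_ventricle_width=float(cont["third_ventricle_width"][i]),
                        posterior_horn_ratio=float(cont["posterior_horn_ratio"][i]),
                    ),
                    preop_severity_score=pre_sev,
                    postop_severity_score=post_sev,
                    outcome_label=group if group == "responder" else "non_responder",
                )
            )
    return records


# ---------------------------------------------------------------------------
# joint-table reconstruction

#: cell order (tap, desh, ca_positive) used for lexicographic comparisons
CELL_ORDER = [
    (1, 1, 1), (1, 1, 0), (1, 0, 1), (1, 0, 0),
    (0, 1, 1), (0, 1, 0), (0, 0, 1), (0, 0, 0),
]

_RULES = ("tap", "desh", "ca", "tap_desh", "tap_ca", "majority")


def load_printed_targets() -> dict:
    """Reference targets shipped with the package (printed counts + rows)."""
    with resources.files("shuntpred.data").joinpath("printed_targets.json").open() as fh:
        return json.load(fh)


def _positive_counts(cells: dict) -> dict:
    """Rule-positive subject counts from a {(t,d,c): count} table."""
    def total(pred):
        return sum(v for (t, d, c), v in cells.items() if pred(t, d, c))

    return {
        "tap": total(lambda t, d, c: t),
        "desh": total(lambda t, d, c: d),
        "ca": total(lambda t, d, c: c),
        "tap_desh": total(lambda t, d, c: t or d),
        "tap_ca": total(lambda t, d, c: t or c),
        "majority": total(lambda t, d, c: t + d + c >= 2),
    }


@dataclass(frozen=True)
class GroupTable:
    """One outcome group's integer 2x2x2 table with its derived metrics.

    ``metrics`` holds each rule's value on this group's side of the 2x2
    (sensitivity for responders, specificity for non-responders), computed
    from the cells at full precision — never stored independently.
    """

    group: str
    n: int
    cells: tuple  # counts in CELL_ORDER
    metrics: dict
    deviations: dict
    max_abs_deviation: float
    exact: bool

    @property
    def cell_counts(self) -> dict:
        return dict(zip(CELL_ORDER, self.cells))


@dataclass(frozen=True)
class JointTableSolution:
    """A responder-group table paired with a non-responder-group table."""

    responders: GroupTable
    non_responders: GroupTable

    @property
    def max_abs_deviation(self) -> float:
        return max(self.responders.max_abs_deviation, self.non_responders.max_abs_deviation)

    @property
    def exact(self) -> bool:
        return self.responders.exact and self.non_responders.exact

    def table4(self) -> dict:
        """Full-precision diagnostic-performance rows implied by the tables."""
        out = {}
        for rule in _RULES:
            sens = self.responders.metrics[rule]
            spec = self.non_responders.metrics[rule]
            out[rule] = {
                "sensitivity": sens,
                "specificity": spec,
                "auc": binary_auc(sens, spec),
            }
        return out


@dataclass
class ReconstructionReport:
    solutions: list  # JointTableSolution, lexicographic by (resp, nonresp) cells
    total_solutions: int
    responders: dict  # {"exact", "n_tables", "best_deviation"}
    non_responders: dict
    exact: bool
    notes: list
    targets: dict

    def canonical(self) -> JointTableSolution:
        return self.solutions[0]

    def to_dict(self) -> dict:
        def table_dict(t: GroupTable) -> dict:
            return {
                "cells": {"".join(map(str, k)): v for k, v in t.cell_counts.items()},
                "metrics": t.metrics,
                "deviations": t.deviations,
                "max_abs_deviation": t.max_abs_deviation,
                "exact": t.exact,
            }

        return {
            "exact": self.exact,
            "total_solutions": self.total_solutions,
            "responders": self.responders,
            "non_responders": self.non_responders,
            "notes": list(self.notes),
            "canonical_solution": {
                "responders": table_dict(self.solutions[0].responders),
                "non_responders": table_dict(self.solutions[0].non_responders),
                "table4": self.solutions[0].table4(),
            },
        }


def _solve_group(
    group: str, n: int, tap_pos: int, desh_pos: int, printed: dict, tol: float,
    max_tables: int = 10000,
) -> tuple[list, list, float, int]:
    """Enumerate all 2x2x2 tables with exact tap/DESH margins.

    Returns (exact tables, minimal-deviation tables, best deviation,
    total exact count); the deviation of a table is the largest
    |derived - printed| over the rule metrics present in ``printed`` on
    this group's side.  At most ``max_tables`` tables are materialized
    per list (the count is still exact).
    """
    sens_side = group == "responders"
    rules = [r for r in _RULES if r in printed]
    best_dev = np.inf
    n_exact = 0
    exact_cells: list[tuple] = []
    best_cells: list[tuple] = []

    for d1 in range(max(0, tap_pos + desh_pos - n), min(tap_pos, desh_pos) + 1):
        n11, n10 = d1, tap_pos - d1
        n01, n00 = desh_pos - d1, n - tap_pos - desh_pos + d1
        c11, c10, c01, c00 = np.meshgrid(
            np.arange(n11 + 1), np.arange(n10 + 1), np.arange(n01 + 1), np.arange(n00 + 1),
            indexing="ij", sparse=True,
        )
        pos = {
            "tap": tap_pos,
            "desh": desh_pos,
            "ca": c11 + c10 + c01 + c00,
            "tap_desh": n - n00,
            "tap_ca": tap_pos + c01 + c00,
            "majority": n11 + c10 + c01,
        }
        dev = np.zeros((1, 1, 1, 1))
        for rule in rules:
            frac = pos[rule] / n if sens_side else (n - pos[rule]) / n
            dev = np.maximum(dev, np.abs(frac - printed[rule]))
        dev = np.broadcast_to(dev, (n11 + 1, n10 + 1, n01 + 1, n00 + 1))

        local_min = float(dev.min())
        if local_min < best_dev - 1e-12:
            best_dev = local_min
            best_cells = []
        for pick_exact, sink in ((True, exact_cells), (False, best_cells)):
            mask = dev <= tol + 1e-12 if pick_exact else np.abs(dev - best_dev) <= 1e-12
            if pick_exact:
                n_exact += int(mask.sum())
                if not mask.any():
                    continue
            for i, j, k, l in zip(*np.nonzero(mask)):
                if len(sink) >= max_tables:
                    break
                cells = (
                    int(i), n11 - int(i), int(j), n10 - int(j),
                    int(k), n01 - int(k), int(l), n00 - int(l),
                )
                sink.append(cells)

    exact_cells.sort()
    best_cells = sorted(set(best_cells))

    def to_table(cells: tuple, exact: bool) -> GroupTable:
        cell_map = dict(zip(CELL_ORDER, cells))
        counts = _positive_counts(cell_map)
        metrics = {
            r: counts[r] / n if sens_side else (n - counts[r]) / n for r in _RULES
        }
        deviations = {r: abs(metrics[r] - printed[r]) for r in rules}
        return GroupTable(
            group=group,
            n=n,
            cells=cells,
            metrics=metrics,
            deviations=deviations,
            max_abs_deviation=max(deviations.values()) if deviations else 0.0,
            exact=exact,
        )

    exact_tables = [to_table(c, True) for c in exact_cells]
    best_tables = [to_table(c, False) for c in best_cells]
    return exact_tables, best_tables, best_dev, n_exact


def reconstruct_joint_tables(
    targets: Optional[dict] = None, tol: float = 0.005, max_solutions: int = 10000
) -> ReconstructionReport:
    """Reconstruct per-group joint (tap, DESH, CA) tables from printed values.

    ``targets`` defaults to the shipped reference targets.  Per group, all
    integer tables with the exactly printed tap and DESH margins are
    enumerated; a table is *exact* when every printed 2-decimal rule metric
    is matched within ``tol``.  If a group has no exact table, its
    minimal-max-deviation tables are used and a note records the
    infeasibility (never an exception).
    """
    targets = targets or load_printed_targets()
    sizes = targets["group_sizes"]
    notes = [str(n) for n in targets.get("notes", [])]
    per_group: dict[str, list] = {}
    summary: dict[str, dict] = {}
    for group in ("responders", "non_responders"):
        n = sizes[group]
        counts = targets["counts"][group]
        side = "sensitivity" if group == "responders" else "specificity"
        printed = {
            r: targets["table4"][r][side] for r in _RULES if r in targets["table4"]
        }
        exact_tables, best_tables, best_dev, n_exact = _solve_group(
            group, n, counts["tap_positive"], counts["desh_positive"], printed, tol,
            max_tables=max_solutions,
        )
        if exact_tables:
            per_group[group] = exact_tables
        else:
            per_group[group] = best_tables
            notes.append(
                f"no exact integer table exists for the {group} group within "
                f"+/-{tol:g} of every printed value; using {len(best_tables)} "
                f"minimal-deviation table(s) with max deviation {best_dev:.4f}"
            )
        summary[group] = {
            "exact": bool(exact_tables),
            "n_tables": n_exact if exact_tables else len(best_tables),
            "best_deviation": float(
                min(t.max_abs_deviation for t in per_group[group])
            ),
        }

    total = summary["responders"]["n_tables"] * summary["non_responders"]["n_tables"]
    solutions = []
    for rt in per_group["responders"]:
        for nt in per_group["non_responders"]:
            solutions.append(JointTableSolution(responders=rt, non_responders=nt))
            if len(solutions) >= max_solutions:
                break
        if len(solutions) >= max_solutions:
            break
    solutions.sort(key=lambda s: (s.responders.cells, s.non_responders.cells))
    return ReconstructionReport(
        solutions=solutions,
        total_solutions=total,
        responders=summary["responders"],
        non_responders=summary["non_responders"],
        exact=summary["responders"]["exact"] and summary["non_responders"]["exact"],
        notes=notes,
        targets=targets,
    )


# ---------------------------------------------------------------------------
# fixture materialization

def _trunc_rvs(rng, mean, sd, lo, hi, size=None):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.ppf(rng.uniform(size=size), a, b, loc=mean, scale=sd)


def build_fixture_cohort(
    solution: JointTableSolution, config: Optional[SimulationConfig] = None
) -> list[PatientRecord]:
    """Materialize one patient record per cell occupant of a reconstructed table.

    Binary features are exactly as the cell dictates; CA is drawn from the
    group's truncated normal below/above ``config.ca_cutoff`` according to
    the cell's CA positivity; remaining features follow the group
    marginals.  Deterministic per ``config.seed``.
    """
    config = config or default_config()
    rng = np.random.default_rng(config.seed)
    records: list[PatientRecord] = []
    lo_ca, hi_ca = _BOUNDS["ca"]
    for group, table, marg in (
        ("responder", solution.responders, config.responders),
        ("non_responder", solution.non_responders, config.non_responders),
    ):
        if sum(table.cells) != table.n:
            raise ValueError(f"{group} table cells do not sum to the group size")
        centers = _centers(rng, table.n, config.center_weights)
        prefix = "FR" if group == "responder" else "FN"
        i = 0
        for (t, d, c), count in table.cell_counts.items():
            for _ in range(count):
                if c:
                    ca = float(_trunc_rvs(rng, *marg.continuous["ca"], lo_ca, config.ca_cutoff))
                else:
                    ca = float(
                        _trunc_rvs(
                            rng, *marg.continuous["ca"], np.nextafter(config.ca_cutoff, 180), hi_ca
                        )
                    )
                cont = {
                    name: float(_trunc_rvs(rng, *marg.continuous[name], *_BOUNDS[name]))
                    for name in _CONTINUOUS
                    if name != "ca"
                }
                other_flags = {
                    name: bool(rng.uniform() <= marg.binary[name])
                    for name in _BINARY
                    if name not in ("tap_positive", "desh")
                }
                pre_sev, post_sev = _backfill_severity(rng, group == "responder")
                i += 1
                records.append(
                    PatientRecord(
                        id=f"{prefix}{i:03d}",
                        center_id=centers[i - 1],
                        age=cont["age"],
                        sex="male" if other_flags["sex_male"] else "female",
                        lp_pressure=cont["lp_pressure"],
                        disease_duration=cont["disease_duration"],
                        symptom_gait=other_flags["symptom_gait"],
                        symptom_cognitive=other_flags["symptom_cognitive"],
                        symptom_urinary=other_flags["symptom_urinary"],
                        comorb_cardiovascular=other_flags["comorb_cardiovascular"],
                        comorb_endocrine=other_flags["comorb_endocrine"],
                        comorb_neurological=other_flags["comorb_neurological"],
                        tap=_backfill_tap(rng, bool(t)),
                        imaging=ImagingProfile(
                            ei=cont["ei"],
                            desh=bool(d),
                            ca=ca,
                            z_ei=cont["z_ei"],
                            bvr=cont["bvr"],
                            scca=cont["scca"],
                            temporal_horn_left=cont["temporal_horn_left"],
                            temporal_horn_right=cont["temporal_horn_right"],
                            third_ventricle_width=cont["third_ventricle_width"],
                            posterior_horn_ratio=cont["posterior_horn_ratio"],
                        ),
                        preop_severity_score=pre_sev,
                        postop_severity_score=post_sev,
                        outcome_label=group if group == "responder" else "non_responder",
                    )
                )
    return records


def canonical_fixture(seed: int = 0) -> tuple[list[PatientRecord], ReconstructionReport]:
    """The package's reference fixture: canonical reconstructed tables,
    materialized with the default study-condition config."""
    report = reconstruct_joint_tables()
    config = default_config(seed=seed)
    return build_fixture_cohort(report.canonical(), config), report


# ---------------------------------------------------------------------------
# dependence preset

def _tetrachoric(p11: float, p1: float, p2: float) -> float:
    """Latent correlation matching a 2x2 cell probability under a bivariate
    normal with thresholds at the marginal quantiles."""
    q1, q2 = sps.norm.ppf(p1), sps.norm.ppf(p2)

    def cell(rho):
        cov = [[1.0, rho], [rho, 1.0]]
        return sps.multivariate_normal(mean=[0, 0], cov=cov).cdf([q1, q2])

    from scipy.optimize import brentq

    lo, hi = -0.99, 0.99
    f_lo, f_hi = cell(lo) - p11, cell(hi) - p11
    if f_lo * f_hi > 0:
        return 0.0 if abs(f_lo) < abs(f_hi) else (hi if f_hi < 0 else lo)
    return float(brentq(lambda r: cell(r) - p11, lo, hi, xtol=1e-4))


def calibrated_dependence(report: Optional[ReconstructionReport] = None) -> Dependence:
    """Dependence preset for (tap, DESH, CA) calibrated from the canonical
    reconstructed joint tables (group-size-weighted tetrachoric correlations).

    Approximate by design: the CA latent threshold is taken at the
    reconstructed CA-positive rate.
    """
    report = report or reconstruct_joint_tables()
    pairs = {("tap_positive", "desh"): [], ("tap_positive", "ca"): [], ("desh", "ca"): []}
    weights = []
    key = {"tap_positive": 0, "desh": 1, "ca": 2}
    for table in (report.canonical().responders, report.canonical().non_responders):
        n = table.n
        weights.append(n)
        cells = table.cell_counts
        marg = {
            "tap_positive": sum(v for (t, d, c), v in cells.items() if t) / n,
            "desh": sum(v for (t, d, c), v in cells.items() if d) / n,
            "ca": sum(v for (t, d, c), v in cells.items() if c) / n,
        }
        for (v1, v2), sink in pairs.items():
            i, j = key[v1], key[v2]
            p11 = sum(v for tdc, v in cells.items() if tdc[i] and tdc[j]) / n
            sink.append(_tetrachoric(p11, marg[v1], marg[v2]))
    w = np.asarray(weights, dtype=float)
    w /= w.sum()
    rho = {k: float(np.dot(w, v)) for k, v in pairs.items()}
    m = np.eye(3)
    m[0, 1] = m[1, 0] = rho[("tap_positive", "desh")]
    m[0, 2] = m[2, 0] = rho[("tap_positive", "ca")]
    m[1, 2] = m[2, 1] = rho[("desh", "ca")]
    # nudge to the nearest PD matrix if the pairwise estimates conflict
    evals = np.linalg.eigvalsh(m)
    if evals.min() <= 1e-8:
        m += np.eye(3) * (1e-6 - evals.min())
        m /= m[0, 0]
    return Dependence(variables=["tap_positive", "desh", "ca"], matrix=m.tolist())
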