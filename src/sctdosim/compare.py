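"""Strategy-level dose comparison: gamma, point dose and DVH differences.

Sign convention throughout: synthetic-CT minus reference CT, so a
negative point difference means the synthetic CT underestimates dose.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

from .dvh import DVHMetrics, dvh_metrics, point_dose_difference
from .errors import UsageError
from .gamma import GammaCriteria, GammaResult, gamma_index
from .structures import StructureSet

DEFAULT_CRITERIA = (GammaCriteria(1.0, 1.0), GammaCriteria(3.0, 3.0))


def dose_difference_map(reference, evaluated):
    """Voxelwise dose difference (evaluated - reference) on the shared grid."""
    ref = reference.dose if hasattr(reference, "dose") else reference
    ev = evaluated.dose if hasattr(evaluated, "dose") else evaluated
    if not ref.grid.same_geometry(ev.grid):
        raise UsageError("difference map requires a shared grid")
    return ref.with_values(ev.values - ref.values, unit="Gy")


@dataclass
class StrategyComparison:
    """One synthetic-CT strategy against the reference dose."""

    strategy: str
    gamma_pass_rates: dict[str, float]  # criteria label -> %
    gamma_evaluated: dict[str, int]
    point_diff_percent: float
    dvh_reference: DVHMetrics
    dvh_evaluated: DVHMetrics
    dvh_delta: pd.DataFrame  # evaluated - reference per metric


@dataclass
class ComparisonReport:
    """All strategies for one subject, JSON-serializable."""

    subject: str
    strategies: dict[str, StrategyComparison] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {"subject": self.subject, "strategies": {}}
        for name, s in self.strategies.items():
            out["strategies"][name] = {
                "gamma_pass_rates": {k: float(v) for k, v in s.gamma_pass_rates.items()},
                "gamma_evaluated": {k: int(v) for k, v in s.gamma_evaluated.items()},
                "point_diff_percent": float(s.point_diff_percent),
                "dvh_delta": s.dvh_delta.to_dict(orient="records"),
            }
        return out

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def rows(self) -> pd.DataFrame:
        """Flat rows: one per strategy x criteria plus point diffs."""
        rows = []
        for name, s in self.strategies.items():
            for label, rate in s.gamma_pass_rates.items():
                rows.append({"subject": self.subject, "strategy": name,
                             "metric": f"gpr_{label}", "value": rate})
            rows.append({"subject": self.subject, "strategy": name,
                         "metric": "point_diff_percent", "value": s.point_diff_percent})
        return pd.DataFrame(rows)


_DVH_METRIC_COLUMNS = ("d_mean", "d_max", "d98", "d2", "d1cc", "v100")


def dvh_delta(reference: DVHMetrics, evaluated: DVHMetrics) -> pd.DataFrame:
    ref = reference.table.set_index("roi")
    ev = evaluated.table.set_index("roi")
    if list(ref.index) != list(ev.index):
        raise UsageError("DVH tables cover different ROIs")
    delta = (ev[list(_DVH_METRIC_COLUMNS)] - ref[list(_DVH_METRIC_COLUMNS)]).reset_index()
    delta.insert(1, "role", ref["role"].values)
    return delta


def compare_strategies(
    reference,
    evaluated_by_strategy: dict,
    structures: StructureSet,
    criteria: tuple = DEFAULT_CRITERIA,
    prescriptions_gy: dict | None = None,
    point_roi: str = "ptv_nx",
    subject: str = "subject",
) -> ComparisonReport:
    """Run the full evaluation battery for each strategy's dose grid.

    All dose grids must share the reference grid (the planning-CT grid is
    the comparison grid throughout the pipeline).
    """
    report = ComparisonReport(subject=subject)
    dvh_ref = dvh_metrics(reference, structures, prescriptions_gy)
    for name, dose in evaluated_by_strategy.items():
        rates, counts = {}, {}
        for crit in criteria:
            res: GammaResult = gamma_index(reference, dose, crit)
            rates[crit.label] = res.pass_rate
            counts[crit.label] = res.evaluated_count
        pdiff = point_dose_difference(reference, dose, structures, point_roi)
        dvh_ev = dvh_metrics(dose, structures, prescriptions_gy)
        report.strategies[name] = StrategyComparison(
            strategy=name,
            gamma_pass_rates=rates,
            gamma_evaluated=counts,
            point_diff_percent=pdiff,
            dvh_reference=dvh_ref,
            dvh_evaluated=dvh_ev,
            dvh_delta=dvh_delta(dvh_ref, dvh_ev),
        )
    return report
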