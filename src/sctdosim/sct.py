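"""Bulk-assigned synthetic CTs: piecewise-constant rED maps over ROIs.

Three assignment strategies are supported, mirroring the bulk synthetic-CT
options of an MR-Linac online-adaptive workflow:

``homogeneity``
    the whole body is water-equivalent (rED 1.0);
``icru``
    bone and air take the ICRU Report 46 recommendations (1.61 / 0.001),
    every other ROI its patient-specific mean rED from the planning CT;
``tailor``
    every ROI, including bone and air, takes its patient-specific mean.

Overlapping ROIs are resolved by an explicit precedence order; by default
air overrides everything (an air cavity inside a target stays air), then
bone, then OARs, then targets, then body.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .errors import ConfigError, SctDosimError
from .density import ROIDensitySummary
from .geometry import ImageVolume
from .structures import StructureSet

STRATEGIES = ("homogeneity", "icru", "tailor")

ICRU_BONE_RED = 1.61
ICRU_AIR_RED = 0.001

#: Role precedence, low to high.  Higher-precedence ROIs win on overlap.
DEFAULT_ROLE_PRECEDENCE = ("body", "target", "oar", "bone", "air")


@dataclass(frozen=True)
class AssignmentEntry:
    roi: str
    red: float
    rank: int


@dataclass
class AssignmentTable:
    """Per-ROI bulk rED values plus overlap precedence."""

    strategy: str
    entries: list[AssignmentEntry]
    background_red: float = 0.001
    body_roi: str = "body"

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ConfigError(f"unknown strategy {self.strategy!r}")
        if any(e.red < 0 for e in self.entries):
            raise ConfigError("rED values must be non-negative")
        ranks = [e.rank for e in self.entries]
        if len(set(ranks)) != len(ranks):
            raise ConfigError("precedence ranks must be a total order (unique)")
        bodies = [e for e in self.entries if e.roi == self.body_roi]
        if len(bodies) != 1:
            raise ConfigError("assignment table needs exactly one body entry")
        if self.strategy == "homogeneity" and bodies[0].red != 1.0:
            raise ConfigError("homogeneity strategy requires body rED = 1.0")

    def value_of(self, roi: str) -> float:
        for e in self.entries:
            if e.roi == roi:
                return e.red
        raise KeyError(roi)

    def to_yaml(self, path):
        doc = {
            "strategy": self.strategy,
            "background_red": self.background_red,
            "body_roi": self.body_roi,
            "entries": [
                {"roi": e.roi, "red": float(e.red), "rank": int(e.rank)}
                for e in self.entries
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @staticmethod
    def from_yaml(path) -> "AssignmentTable":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return AssignmentTable(
            doc["strategy"],
            [AssignmentEntry(d["roi"], float(d["red"]), int(d["rank"])) for d in doc["entries"]],
            background_red=float(doc.get("background_red", 0.001)),
            body_roi=doc.get("body_roi", "body"),
        )


@dataclass
class SyntheticCT:
    """A bulk-assigned rED map with its provenance."""

    red_map: ImageVolume
    strategy: str
    table: AssignmentTable
    source_summary: ROIDensitySummary | None = None


def default_precedence(summary: ROIDensitySummary) -> dict[str, int]:
    """Rank ROIs by role (body < target < oar < bone < air), preserving
    summary order within a role.  Later rank wins on overlap."""
    ranks = {}
    rank = 0
    roles = summary.roles()
    for role in DEFAULT_ROLE_PRECEDENCE:
        for name in summary.names:
            if roles[name] == role:
                ranks[name] = rank
                rank += 1
    return ranks


def make_assignment_table(
    strategy: str,
    summary: ROIDensitySummary,
    precedence: dict[str, int] | None = None,
) -> AssignmentTable:
    """Build the assignment table for one strategy from planning-CT ROI
    mean densities."""
    if strategy not in STRATEGIES:
        raise ConfigError(f"unknown strategy {strategy!r}")
    roles = summary.roles()
    bodies = [n for n, r in roles.items() if r == "body"]
    if not bodies:
        raise ConfigError("summary lacks a body ROI")
    body = bodies[0]

    if strategy == "homogeneity":
        return AssignmentTable(strategy, [AssignmentEntry(body, 1.0, 0)], body_roi=body)

    for required_role in ("bone", "air"):
        if required_role not in roles.values():
            raise ConfigError(f"strategy {strategy!r} requires a {required_role!r} ROI")
    empty = set(summary.empty_rois())
    precedence = precedence or default_precedence(summary)
    entries = []
    for name in summary.names:
        if name in empty:
            raise ConfigError(f"ROI {name!r} is empty; cannot derive its mean rED")
        role = roles[name]
        if strategy == "icru" and role == "bone":
            red = ICRU_BONE_RED
        elif strategy == "icru" and role == "air":
            red = ICRU_AIR_RED
        else:
            red = summary.mean_red(name)
        entries.append(AssignmentEntry(name, float(red), int(precedence[name])))
    return AssignmentTable(strategy, entries, body_roi=body)


def build_sct(structures: StructureSet, table: AssignmentTable) -> SyntheticCT:
    """Paint the bulk rED map: each voxel takes the rED of the
    highest-precedence ROI containing it; outside the body, background."""
    for e in table.entries:
        if e.roi not in structures:
            raise ConfigError(f"assignment table ROI {e.roi!r} missing from structure set")
    body_mask = structures[table.body_roi].mask
    covered = np.zeros(structures.grid.shape, dtype=bool)
    out = np.full(structures.grid.shape, float(table.background_red))
    for e in sorted(table.entries, key=lambda e: e.rank):
        mask = structures[e.roi].mask
        out[mask] = e.red
        covered |= mask
    if np.any(body_mask & ~covered):
        raise SctDosimError("body voxels not covered by any assignment entry")
    red = ImageVolume(out, structures.grid, "rED")
    return SyntheticCT(red, table.strategy, table)
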