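"""Role-wise comparison of two phase cascades (unique / common partition)."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .netbuild import IntegratedCascade

logger = logging.getLogger(__name__)

ROLES = ("mr", "tf", "tg")

__all__ = ["PhaseCascadeSummary", "CascadeComparison", "summarize_cascade", "compare_cascades"]


@dataclass
class PhaseCascadeSummary:
    """Disjoint MR / TF / TG id sets for one phase (highest role wins)."""

    phase: str
    mr_ids: set[str]
    top_tf_ids: set[str]
    tg_ids: set[str]

    def __post_init__(self) -> None:
        # a gene takes its highest role: MR > TF > TG
        self.top_tf_ids = set(self.top_tf_ids) - set(self.mr_ids)
        self.tg_ids = set(self.tg_ids) - set(self.mr_ids) - set(self.top_tf_ids)

    def role_sets(self) -> dict[str, set[str]]:
        return {"mr": set(self.mr_ids), "tf": set(self.top_tf_ids), "tg": set(self.tg_ids)}

    def total(self) -> int:
        return len(self.mr_ids) + len(self.top_tf_ids) + len(self.tg_ids)


@dataclass
class CascadeComparison:
    phase_a: str
    phase_b: str
    unique_a: dict[str, set[str]] = field(default_factory=dict)
    unique_b: dict[str, set[str]] = field(default_factory=dict)
    common: dict[str, set[str]] = field(default_factory=dict)

    def counts(self) -> dict[str, dict[str, int]]:
        return {
            part: {role: len(ids) for role, ids in sets.items()}
            for part, sets in (
                ("unique_a", self.unique_a),
                ("unique_b", self.unique_b),
                ("common", self.common),
            )
        }

    def unique_total(self, which: str) -> int:
        sets = self.unique_a if which == "a" else self.unique_b
        return sum(len(ids) for ids in sets.values())


def summarize_cascade(
    cascade: IntegratedCascade,
    phase: str,
    top_tf_ids: set[str] | None = None,
) -> PhaseCascadeSummary:
    """Build a role summary from an integrated cascade.

    ``top_tf_ids`` restricts the TF role to the above-mean-target TFs;
    by default every non-MR TF node is included.
    """
    mrs = cascade.mr_ids()
    tfs = {g for g, n in cascade.nodes.items() if n.role == "TF"}
    if top_tf_ids is not None:
        tfs &= set(top_tf_ids)
    tgs = {g for g, n in cascade.nodes.items() if n.role == "TG"}
    return PhaseCascadeSummary(phase=phase, mr_ids=mrs, top_tf_ids=tfs, tg_ids=tgs)


def compare_cascades(
    a: PhaseCascadeSummary, b: PhaseCascadeSummary
) -> CascadeComparison:
    """Role-wise unique/common partition of two phase summaries."""
    if a.phase == b.phase:
        raise ValueError(f"phase labels must differ, both are {a.phase!r}")
    sets_a, sets_b = a.role_sets(), b.role_sets()
    cmp = CascadeComparison(phase_a=a.phase, phase_b=b.phase)
    for role in ROLES:
        cmp.unique_a[role] = sets_a[role] - sets_b[role]
        cmp.unique_b[role] = sets_b[role] - sets_a[role]
        cmp.common[role] = sets_a[role] & sets_b[role]
    logger.info("cascade comparison counts: %s", cmp.counts())
    return cmp
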