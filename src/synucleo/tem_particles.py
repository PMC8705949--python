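"""TEM nanoparticle-cluster classification.

Immunogold TEM quantification reports the area (nm²) of each gold
nanoparticle cluster; cluster class follows fixed area thresholds:
area < 350 nm² is a monomer, 350–800 nm² (inclusive) a dimer,
800 < area < 2000 nm² a trimer, and anything >= 2000 nm² is reported as
unclassified (never silently dropped).  Class fractions are computed over
classified particles only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_THRESHOLDS",
    "ParticleSet",
    "ClusterCounts",
    "classify_particles",
    "fractions_by_condition",
]

DEFAULT_THRESHOLDS = (350.0, 800.0, 2000.0)  # nm²

_CLASSES = ("monomer", "dimer", "trimer")


@dataclass
class ParticleSet:
    """Cluster areas (nm²) for one condition."""

    areas: np.ndarray
    condition_label: str = ""

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)

    @property
    def n(self) -> int:
        return len(self.areas)


@dataclass
class ClusterCounts:
    monomers: int
    dimers: int
    trimers: int
    unclassified: int
    n_rejected: int = 0
    condition_label: str = ""

    @property
    def n(self) -> int:
        return self.monomers + self.dimers + self.trimers + self.unclassified

    @property
    def n_classified(self) -> int:
        return self.monomers + self.dimers + self.trimers

    @property
    def fractions(self) -> dict[str, float]:
        """Share of each class among classified particles (sums to 1)."""
        nc = self.n_classified
        if nc == 0:
            raise ValueError("no classified particles")
        return {
            "monomer": self.monomers / nc,
            "dimer": self.dimers / nc,
            "trimer": self.trimers / nc,
        }


def classify_particles(
    particles: ParticleSet,
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS,
) -> ClusterCounts:
    """Classify cluster areas into monomer/dimer/trimer by area thresholds.

    Boundary convention ("smaller than"/"larger than" strict, "between"
    inclusive): area < t1 monomer; t1 <= area <= t2 dimer;
    t2 < area < t3 trimer; area >= t3 unclassified.  Non-positive areas
    are rejected with a warning and counted in ``n_rejected``.
    """
    t1, t2, t3 = thresholds
    if not (t1 < t2 < t3):
        raise ValueError("thresholds must be strictly increasing")
    areas = particles.areas
    bad = areas <= 0
    if bad.any():
        warnings.warn(f"rejected {int(bad.sum())} non-positive area record(s)")
    a = areas[~bad]
    return ClusterCounts(
        monomers=int((a < t1).sum()),
        dimers=int(((a >= t1) & (a <= t2)).sum()),
        trimers=int(((a > t2) & (a < t3)).sum()),
        unclassified=int((a >= t3).sum()),
        n_rejected=int(bad.sum()),
        condition_label=particles.condition_label,
    )


def fractions_by_condition(
    counts: Mapping[str, ClusterCounts] | Mapping[str, Sequence[ClusterCounts]],
):
    """Class-fraction table per condition, plus a group test when possible.

    ``counts`` maps condition label to one :class:`ClusterCounts` or a list
    of replicate counts.  Returns ``(table, comparisons)``: ``table`` is a
    DataFrame with one row per condition (replicate-averaged fractions);
    ``comparisons`` maps class name to a :func:`compare_groups` report when
    every condition has >= 3 replicates (else None).
    """
    per_cond: dict[str, list[ClusterCounts]] = {}
    for label, val in counts.items():
        reps = list(val) if isinstance(val, (list, tuple)) else [val]
        if not reps or all(c.n_classified == 0 for c in reps):
            raise ValueError(f"condition {label!r} has zero classified particles")
        per_cond[label] = reps
    rows = []
    for label, reps in per_cond.items():
        fr = pd.DataFrame([c.fractions for c in reps]).mean()
        rows.append(
            {
                "condition": label,
                "n_replicates": len(reps),
                "n_particles": sum(c.n for c in reps),
                **{f"frac_{cls}": fr[cls] for cls in _CLASSES},
            }
        )
    table = pd.DataFrame(rows)
    comparisons = None
    if len(per_cond) >= 2 and all(len(r) >= 3 for r in per_cond.values()):
        from .ephys_analysis import compare_groups

        comparisons = {
            cls: compare_groups(
                {
                    label: np.array([c.fractions[cls] for c in reps])
                    for label, reps in per_cond.items()
                }
            )
            for cls in _CLASSES
        }
    return table, comparisons
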