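"""SILAC comparison design: mapping labeled mixes to biological contrasts.

A two-channel SILAC experiment quantifies one heavy/light mix per MS run.
The resistance screen uses four mixes per time point, each realizing one of
four biological contrasts between a trastuzumab-resistant line and its
parental, drug-sensitive line:

===========  =====================================================
contrast id  meaning (sample vs reference)
===========  =====================================================
A            resistant vs parental, both untreated (baseline pair)
B            resistant+T vs parental+T (treated pair)
C            resistant+T vs resistant (treatment response, resistant)
D            parental+T vs parental (treatment response, parental)
===========  =====================================================

Which channel carries the contrast's *sample* differs between mixes (a
label-swap design): the resistant line is heavy-labeled in the untreated
pair and light-labeled in the treated pair. The ``heavy_is_sample`` flag
records this per contrast so raw H/L ratios can be re-oriented to a common
sample/reference scale downstream.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Tuple

CONTRASTS: Tuple[str, ...] = ("A", "B", "C", "D")
TIMEPOINTS: Tuple[str, ...] = ("T1", "T2", "T3")

#: Default orientation per contrast (resistant heavy in the untreated pair,
#: light in the treated pair; treatment-response mixes follow suit).
_DEFAULT_ORIENTATION: Dict[str, bool] = {"A": True, "B": False, "C": False, "D": True}


@dataclass(frozen=True)
class ContrastMapping:
    """One contrast's realization at one time point."""

    experiment: str  #: experiment key — suffix of the ratio column in the table
    heavy_is_sample: bool  #: True when the heavy channel carries the sample


@dataclass
class ComparisonDesign:
    """Per-time-point mapping from contrast ids to SILAC experiments."""

    mappings: Dict[str, Dict[str, ContrastMapping]] = field(default_factory=dict)

    def validate(self) -> None:
        for tp, contrasts in self.mappings.items():
            if set(contrasts) != set(CONTRASTS):
                raise ValueError(
                    f"time point {tp!r} must map exactly the contrasts "
                    f"{CONTRASTS}, got {sorted(contrasts)}"
                )
            experiments = [m.experiment for m in contrasts.values()]
            if len(set(experiments)) != len(experiments):
                raise ValueError(f"time point {tp!r}: experiment keys not unique")

    @property
    def timepoints(self) -> Tuple[str, ...]:
        return tuple(self.mappings)

    def mapping(self, timepoint: str, contrast: str) -> ContrastMapping:
        return self.mappings[timepoint][contrast]


def default_design(
    timepoints: Iterable[str] = TIMEPOINTS, swapped: bool = False
) -> ComparisonDesign:
    """Build the standard four-mix design for the given time points.

    Parameters
    ----------
    timepoints
        Labels of the time points (default T1/T2/T3).
    swapped
        If True, every mix's channel assignment is exchanged (heavy and
        light cell populations swapped), flipping all orientation flags.
        Analysis of a swapped dataset must yield identical signed fold
        changes — the label-swap invariance the design guarantees.
    """
    mappings: Dict[str, Dict[str, ContrastMapping]] = {}
    for tp in timepoints:
        mappings[tp] = {
            contrast: ContrastMapping(
                experiment=f"mix{i + 1}",
                heavy_is_sample=(not flag) if swapped else flag,
            )
            for i, (contrast, flag) in enumerate(_DEFAULT_ORIENTATION.items())
        }
    design = ComparisonDesign(mappings)
    design.validate()
    return design
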