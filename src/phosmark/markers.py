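"""Set-algebra classification of phosphosites into acquired-resistance markers.

A site is an acquired-resistance marker at a time point when it is
differentially regulated between resistant and parental cells — untreated
(contrast A) or treated (contrast B) — in a consistent direction, this
regulation is not contradicted by the resistant line's own treatment
response (contrast C), and it is not explained by the parental line's
treatment response in the same direction (contrast D). In set terms over
regulated-site sets per direction: ``(A ∪ B) ∩ C° \\ D`` where C° admits
unchanged or same-direction regulation of C.

Opposite-direction regulation in contrast D ("de novo" loss of a
sensitivity-relevant response) is annotated, not excluded. Markers are then
aggregated across time points, requiring a direction-consistent consensus in
at least 2 of 3 (or, at higher stringency, all 3) time points.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import pandas as pd

from .design import CONTRASTS, ComparisonDesign
from .phospho import PhosphositeRecord, orient_ratio, signed_fold_change

logger = logging.getLogger(__name__)

UP = "up"
DOWN = "down"
UNCHANGED = "unchanged"
MISSING = "missing"

RESISTANCE_UP = "resistance_up"
RESISTANCE_DOWN = "resistance_down"
NONE = "none"
INSUFFICIENT = "insufficient_data"

TIER_TWO = "two_of_three"
TIER_THREE = "three_of_three"
TIER_NONE = "none"

_OPPOSITE = {UP: DOWN, DOWN: UP}


@dataclass(frozen=True)
class RegulationCall:
    """Thresholded call for one contrast at one time point."""

    direction: str  # up / down / unchanged / missing
    magnitude: Optional[float] = None  # |signed fold change|, None when missing
    contrast: Optional[str] = None
    timepoint: Optional[str] = None

    @property
    def regulated(self) -> bool:
        return self.direction in (UP, DOWN)


@dataclass(frozen=True)
class TimepointStatus:
    """Per-time-point marker status of one site."""

    status: str  # resistance_up / resistance_down / none / insufficient_data
    de_novo: bool = False
    timepoint: Optional[str] = None

    @property
    def direction(self) -> Optional[str]:
        if self.status == RESISTANCE_UP:
            return UP
        if self.status == RESISTANCE_DOWN:
            return DOWN
        return None


@dataclass
class MarkerClassification:
    """Aggregated marker status of one site across time points."""

    site_key: Optional[str]
    per_timepoint: Dict[str, TimepointStatus]
    consensus_direction: Optional[str]
    overlap_level: int
    tier: str
    de_novo: Dict[str, bool] = field(default_factory=dict)

    @property
    def is_marker(self) -> bool:
        return self.tier != TIER_NONE

    @property
    def de_novo_any(self) -> bool:
        """De novo annotation at any time point contributing to the consensus."""
        if self.consensus_direction is None:
            return False
        return any(
            self.de_novo.get(tp, False)
            for tp, st in self.per_timepoint.items()
            if st.direction == self.consensus_direction
        )


def call_regulation(
    signed_fc: Optional[float],
    cutoff: float = 1.5,
    contrast: Optional[str] = None,
    timepoint: Optional[str] = None,
) -> RegulationCall:
    """Threshold a signed fold change into a regulation call.

    The cutoff is inclusive: |signed FC| >= cutoff counts as regulated.
    """
    if cutoff <= 1.0:
        raise ValueError(f"cutoff must exceed 1, got {cutoff}")
    if signed_fc is None:
        return RegulationCall(MISSING, None, contrast, timepoint)
    if signed_fc >= cutoff:
        direction = UP
    elif signed_fc <= -cutoff:
        direction = DOWN
    else:
        direction = UNCHANGED
    return RegulationCall(direction, abs(signed_fc), contrast, timepoint)


def classify_site_at_timepoint(
    calls: Mapping[str, RegulationCall], timepoint: Optional[str] = None
) -> TimepointStatus:
    """Apply the resistance set logic to one site's four contrast calls.

    With d the direction of contrast A if regulated, else of B, the site has
    status resistance_d iff A or B is regulated in direction d with neither
    regulated opposite, C is unchanged, missing or regulated in direction d,
    and D is not regulated in direction d. Opposite-direction regulation of
    D sets the de_novo annotation. Missing C or D count as unchanged; if
    both A and B are missing the time point is uninformative.
    """
    if set(calls) != set(CONTRASTS):
        raise ValueError(f"need calls for contrasts {CONTRASTS}, got {sorted(calls)}")
    tps = {c.timepoint for c in calls.values() if c.timepoint is not None}
    if len(tps) > 1:
        raise ValueError(f"calls from mismatched time points: {sorted(tps)}")
    if timepoint is None and tps:
        timepoint = tps.pop()

    a, b, c, d = (calls[k] for k in CONTRASTS)
    if a.direction == MISSING and b.direction == MISSING:
        return TimepointStatus(INSUFFICIENT, False, timepoint)
    if a.regulated:
        direction = a.direction
    elif b.regulated:
        direction = b.direction
    else:
        return TimepointStatus(NONE, False, timepoint)
    opposite = _OPPOSITE[direction]
    if a.direction == opposite or b.direction == opposite:
        return TimepointStatus(NONE, False, timepoint)  # A/B direction conflict
    if c.direction == opposite:
        return TimepointStatus(NONE, False, timepoint)
    if d.direction == direction:
        return TimepointStatus(NONE, False, timepoint)  # parental treatment response
    status = RESISTANCE_UP if direction == UP else RESISTANCE_DOWN
    return TimepointStatus(status, d.direction == opposite, timepoint)


def aggregate_over_time(
    statuses: Mapping[str, TimepointStatus],
    min_overlap: int = 2,
    site_key: Optional[str] = None,
) -> MarkerClassification:
    """Combine per-time-point statuses into a temporal-consensus classification.

    ``overlap_level`` is the largest number of time points sharing the same
    resistance direction; time points with the discordant direction never
    count toward it. The stringency tier is three_of_three at full overlap,
    two_of_three at exactly two, none otherwise; the 3/3 set is by
    construction nested inside the >=2/3 set.
    """
    if min_overlap not in (2, 3):
        raise ValueError(f"min_overlap must be 2 or 3, got {min_overlap}")
    n_up = sum(1 for s in statuses.values() if s.status == RESISTANCE_UP)
    n_down = sum(1 for s in statuses.values() if s.status == RESISTANCE_DOWN)
    overlap_level = max(n_up, n_down)
    consensus: Optional[str] = None
    if overlap_level >= 2:
        consensus = UP if n_up > n_down else DOWN
    if overlap_level >= 3:
        tier = TIER_THREE
    elif overlap_level == 2:
        tier = TIER_TWO
    else:
        tier = TIER_NONE
    return MarkerClassification(
        site_key=site_key,
        per_timepoint=dict(statuses),
        consensus_direction=consensus,
        overlap_level=overlap_level,
        tier=tier,
        de_novo={tp: s.de_novo for tp, s in statuses.items()},
    )


@dataclass
class SiteResult:
    """One site's fold changes, calls and classification across the design."""

    key: str
    gene_symbol: str
    residue: str
    position: int
    multiplicity: int
    signed_fc: Dict[str, Dict[str, Optional[float]]]  # timepoint -> contrast -> FC
    classification: MarkerClassification

    @property
    def site_label(self) -> str:
        return f"{self.residue}{self.position}"


def compute_signed_fcs(
    tables: Mapping[str, Sequence[PhosphositeRecord]], design: ComparisonDesign
) -> Dict[str, Dict[str, Dict[str, Optional[float]]]]:
    """Per-site signed fold changes for every contrast and time point.

    Sites are matched across time points by their identity key; a site
    absent from a time point's table yields missing values there.
    """
    index = {tp: {r.key: r for r in records} for tp, records in tables.items()}
    meta: Dict[str, PhosphositeRecord] = {}
    for records in tables.values():
        for r in records:
            meta.setdefault(r.key, r)
    out: Dict[str, Dict[str, Dict[str, Optional[float]]]] = {}
    for key in sorted(meta):
        per_tp: Dict[str, Dict[str, Optional[float]]] = {}
        for tp in design.timepoints:
            record = index.get(tp, {}).get(key)
            fcs: Dict[str, Optional[float]] = {}
            for contrast in CONTRASTS:
                mapping = design.mapping(tp, contrast)
                raw = record.ratios.get(mapping.experiment) if record else None
                fcs[contrast] = signed_fold_change(
                    orient_ratio(raw, mapping.heavy_is_sample)
                )
            per_tp[tp] = fcs
        out[key] = per_tp
    return out


def classify_from_fcs(
    signed_fcs: Mapping[str, Mapping[str, Mapping[str, Optional[float]]]],
    cutoff: float = 1.5,
    min_overlap: int = 2,
) -> Dict[str, MarkerClassification]:
    """Threshold cached signed fold changes and aggregate over time."""
    classifications: Dict[str, MarkerClassification] = {}
    for key, per_tp in signed_fcs.items():
        statuses = {
            tp: classify_site_at_timepoint(
                {
                    contrast: call_regulation(fc, cutoff, contrast, tp)
                    for contrast, fc in fcs.items()
                },
                timepoint=tp,
            )
            for tp, fcs in per_tp.items()
        }
        classifications[key] = aggregate_over_time(statuses, min_overlap, site_key=key)
    return classifications


def classify_dataset(
    tables: Mapping[str, Sequence[PhosphositeRecord]],
    design: ComparisonDesign,
    cutoff: float = 1.5,
    min_overlap: int = 2,
) -> Dict[str, SiteResult]:
    """Full per-site pipeline: orient, transform, call, aggregate."""
    signed_fcs = compute_signed_fcs(tables, design)
    classifications = classify_from_fcs(signed_fcs, cutoff, min_overlap)
    meta: Dict[str, PhosphositeRecord] = {}
    for records in tables.values():
        for r in records:
            meta.setdefault(r.key, r)
    results: Dict[str, SiteResult] = {}
    for key in signed_fcs:
        rec = meta[key]
        results[key] = SiteResult(
            key=key,
            gene_symbol=rec.gene_symbol,
            residue=rec.residue,
            position=rec.position,
            multiplicity=rec.multiplicity,
            signed_fc=signed_fcs[key],
            classification=classifications[key],
        )
    return results


def _consensus_fc(result: SiteResult) -> Optional[float]:
    """Representative signed FC: mean over contributing time points of the
    A-contrast FC when A supports the consensus, else the B-contrast FC."""
    cls = result.classification
    direction = cls.consensus_direction
    if direction is None:
        return None
    values: List[float] = []
    for tp, status in cls.per_timepoint.items():
        if status.direction != direction:
            continue
        fcs = result.signed_fc[tp]
        a, b = fcs.get("A"), fcs.get("B")
        pick = a if (a is not None and (a >= 1 if direction == UP else a <= -1)) else b
        if pick is not None:
            values.append(pick)
    if not values:
        return None
    return sum(values) / len(values)


@dataclass
class MarkerTables:
    """Per-tier, per-direction marker lists with summary counts."""

    table: pd.DataFrame  # all markers (>=2/3), ordered deterministically
    summary: Dict[str, int]

    def subset(self, tier: str, direction: str) -> pd.DataFrame:
        if tier == TIER_THREE:
            mask = self.table["tier"] == TIER_THREE
        else:
            mask = self.table["tier"].isin([TIER_TWO, TIER_THREE])
        return self.table[mask & (self.table["direction"] == direction)]


def select_markers(results: Mapping[str, SiteResult]) -> MarkerTables:
    """Emit marker tables for both stringency tiers with deterministic order.

    Ordering is by |consensus fold change| descending, then site key.
    """
    rows = []
    timepoints = None
    for key in sorted(results):
        res = results[key]
        cls = res.classification
        if timepoints is None:
            timepoints = list(cls.per_timepoint)
        if not cls.is_marker:
            continue
        row = {
            "site_key": res.key,
            "gene_symbol": res.gene_symbol,
            "site": res.site_label,
            "direction": cls.consensus_direction,
            "tier": cls.tier,
            "overlap_level": cls.overlap_level,
            "de_novo": cls.de_novo_any,
            "consensus_fc": _consensus_fc(res),
        }
        for tp in cls.per_timepoint:
            for contrast in CONTRASTS:
                row[f"fc_{contrast}_{tp}"] = res.signed_fc[tp][contrast]
            row[f"status_{tp}"] = cls.per_timepoint[tp].status
        rows.append(row)
    columns = [
        "site_key", "gene_symbol", "site", "direction", "tier", "overlap_level",
        "de_novo", "consensus_fc",
    ]
    if timepoints:
        columns += [f"fc_{c}_{tp}" for tp in timepoints for c in CONTRASTS]
        columns += [f"status_{tp}" for tp in timepoints]
    table = pd.DataFrame(rows, columns=columns)
    if len(table):
        table = table.assign(_mag=table["consensus_fc"].abs()).sort_values(
            ["_mag", "site_key"], ascending=[False, True]
        ).drop(columns="_mag").reset_index(drop=True)
    summary = {
        "up_2of3": int(((table["direction"] == UP)).sum()) if len(table) else 0,
        "down_2of3": int(((table["direction"] == DOWN)).sum()) if len(table) else 0,
        "up_3of3": int(
            ((table["direction"] == UP) & (table["tier"] == TIER_THREE)).sum()
        ) if len(table) else 0,
        "down_3of3": int(
            ((table["direction"] == DOWN) & (table["tier"] == TIER_THREE)).sum()
        ) if len(table) else 0,
    }
    return MarkerTables(table=table, summary=summary)


def marker_predictions(
    classifications: Mapping[str, MarkerClassification], min_overlap: int = 2
) -> Dict[str, str]:
    """Predicted direction-level category per marker site.

    Returns ``{site_key: "resistance_up" | "resistance_down"}`` for sites
    whose overlap level reaches ``min_overlap``.
    """
    if min_overlap not in (2, 3):
        raise ValueError(f"min_overlap must be 2 or 3, got {min_overlap}")
    out: Dict[str, str] = {}
    for key, cls in classifications.items():
        if cls.overlap_level >= min_overlap and cls.consensus_direction is not None:
            out[key] = RESISTANCE_UP if cls.consensus_direction == UP else RESISTANCE_DOWN
    return out
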