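"""Phosphosite table reading, class-1 filtering and ratio transforms.

Input tables follow the MaxQuant phosphosite-table dialect: one row per
(protein, position, multiplicity) site, a localization-probability column,
and one ``Ratio H/L normalized <experiment>`` column per SILAC mix.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

RESIDUES = ("S", "T", "Y")


@dataclass(frozen=True)
class TableDialect:
    """Column naming convention of a phosphosite table."""

    protein: str = "Protein"
    gene: str = "Gene names"
    residue: str = "Amino acid"
    position: str = "Position"
    localization: str = "Localization prob"
    multiplicity: str = "Multiplicity"
    ratio_prefix: str = "Ratio H/L normalized "
    reverse: str = "Reverse"
    contaminant: str = "Potential contaminant"
    #: fraction of rows allowed to fail numeric parsing before a hard error
    max_malformed_fraction: float = 0.1


MAXQUANT_DIALECT = TableDialect()


@dataclass
class PhosphositeRecord:
    """One quantified phosphosite.

    ``ratios`` maps experiment key -> normalized H/L ratio; absent keys mean
    the site was not quantified in that experiment.
    """

    protein_id: str
    gene_symbol: str
    residue: str
    position: int
    localization_probability: float
    multiplicity: int = 1
    ratios: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.localization_probability <= 1.0:
            raise ValueError(
                f"localization probability {self.localization_probability} not in [0, 1]"
            )
        if self.position < 1:
            raise ValueError(f"position {self.position} must be >= 1")
        for key, ratio in self.ratios.items():
            if not ratio > 0:
                raise ValueError(f"ratio for {key!r} must be positive, got {ratio}")

    @property
    def key(self) -> str:
        """Site identity key, unique within a table."""
        return f"{self.protein_id}:{self.residue}{self.position}:{self.multiplicity}"


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def records_from_frame(
    frame: pd.DataFrame, dialect: TableDialect = MAXQUANT_DIALECT
) -> List[PhosphositeRecord]:
    """Convert a phosphosite table into validated records.

    Rows flagged as reverse hits or potential contaminants (``+``) are
    dropped when those columns exist. Malformed rows (bad position,
    probability outside [0, 1], unknown residue) are counted, logged and
    skipped; non-positive or unparseable ratios become missing values.
    Duplicate site keys keep the row with the highest localization
    probability.
    """
    mandatory = [dialect.protein, dialect.residue, dialect.position, dialect.localization]
    missing_cols = [c for c in mandatory if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"phosphosite table missing mandatory columns: {missing_cols}")
    ratio_cols = [c for c in frame.columns if c.startswith(dialect.ratio_prefix)]
    if not ratio_cols:
        raise ValueError(
            f"phosphosite table has no ratio columns with prefix {dialect.ratio_prefix!r}"
        )

    for flag_col in (dialect.reverse, dialect.contaminant):
        if flag_col in frame.columns:
            flagged = frame[flag_col].astype(str).str.strip() == "+"
            if flagged.any():
                logger.info("dropping %d rows flagged in %r", int(flagged.sum()), flag_col)
            frame = frame.loc[~flagged]

    n_malformed = 0
    by_key: Dict[str, PhosphositeRecord] = {}
    for _, row in frame.iterrows():
        try:
            position = int(row[dialect.position])
            locprob = float(row[dialect.localization])
            residue = str(row[dialect.residue]).strip()
            if residue not in RESIDUES:
                raise ValueError(f"unknown residue {residue!r}")
            multiplicity = (
                int(row[dialect.multiplicity]) if dialect.multiplicity in frame.columns else 1
            )
            ratios: Dict[str, float] = {}
            for col in ratio_cols:
                value = pd.to_numeric(row[col], errors="coerce")
                if not _is_missing(value) and value > 0:
                    ratios[col[len(dialect.ratio_prefix) :]] = float(value)
            record = PhosphositeRecord(
                protein_id=str(row[dialect.protein]),
                gene_symbol=str(row.get(dialect.gene, "")),
                residue=residue,
                position=position,
                localization_probability=locprob,
                multiplicity=multiplicity,
                ratios=ratios,
            )
        except (ValueError, TypeError) as exc:
            n_malformed += 1
            logger.debug("skipping malformed row: %s", exc)
            continue
        previous = by_key.get(record.key)
        if previous is None or (
            record.localization_probability > previous.localization_probability
        ):
            if previous is not None:
                logger.info("duplicate site key %s: keeping highest localization", record.key)
            by_key[record.key] = record

    n_rows = len(frame)
    if n_rows and n_malformed / n_rows > dialect.max_malformed_fraction:
        raise ValueError(
            f"{n_malformed}/{n_rows} rows malformed exceeds tolerance "
            f"{dialect.max_malformed_fraction}"
        )
    if n_malformed:
        logger.warning("skipped %d malformed rows", n_malformed)
    return list(by_key.values())


def read_phosphosite_table(
    path, dialect: TableDialect = MAXQUANT_DIALECT
) -> List[PhosphositeRecord]:
    """Read a tab-separated phosphosite table into records."""
    frame = pd.read_csv(path, sep="\t")
    return records_from_frame(frame, dialect)


def filter_class1(
    records: Sequence[PhosphositeRecord], threshold: float = 0.75
) -> List[PhosphositeRecord]:
    """Retain class-1 sites: localization probability strictly above ``threshold``."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    retained = [r for r in records if r.localization_probability > threshold]
    if records:
        logger.info(
            "class-1 filter (> %.2f): retained %d/%d (%.1f%%)",
            threshold,
            len(retained),
            len(records),
            100.0 * len(retained) / len(records),
        )
    return retained


def class1_fraction(
    records: Sequence[PhosphositeRecord], threshold: float = 0.75
) -> float:
    """Share of sites passing the class-1 localization filter."""
    if not records:
        return float("nan")
    return sum(r.localization_probability > threshold for r in records) / len(records)


def orient_ratio(
    raw_hl_ratio: Optional[float], heavy_is_sample: bool
) -> Optional[float]:
    """Re-orient a raw H/L ratio to the contrast's sample/reference scale.

    When the heavy channel is the contrast's sample the H/L ratio already
    reads sample/reference; otherwise it is inverted (L/H). Missing values
    propagate.
    """
    if _is_missing(raw_hl_ratio):
        return None
    if raw_hl_ratio <= 0:
        raise ValueError(f"ratio must be positive, got {raw_hl_ratio}")
    return float(raw_hl_ratio) if heavy_is_sample else 1.0 / raw_hl_ratio


def signed_fold_change(oriented_ratio: Optional[float]) -> Optional[float]:
    """Map a sample/reference ratio r to a signed fold change.

    r >= 1 maps to +r and r < 1 to -1/r, so +1 denotes "no change" and the
    magnitude is always >= 1. Missing propagates.
    """
    if _is_missing(oriented_ratio):
        return None
    if oriented_ratio <= 0:
        raise ValueError(f"ratio must be positive, got {oriented_ratio}")
    if oriented_ratio >= 1.0:
        return float(oriented_ratio)
    return -1.0 / oriented_ratio
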