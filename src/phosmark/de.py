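"""Two-group differential expression with BH FDR and the
trastuzumab-independent gene-selection rule.

The per-gene statistic is a pooled-variance two-sample t, optionally
moderated by shrinking each gene's variance toward the median gene
variance (a lightweight stand-in for an empirical-Bayes moderated fit; the
selection rule downstream — q < 0.05 and fold change > 2 in BOTH the
untreated and the treated resistant-vs-parental contrast, with the same
sign — is what defines trastuzumab-independent regulation).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Mapping, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

CONTRAST_TREATMENT = {"baseline": "untreated", "treated": "treated"}


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 expression with its sample sheet."""

    values: pd.DataFrame  # index: gene, columns: sample names
    samples: pd.DataFrame  # columns: sample, cell_line, treatment, replicate

    def validate(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("gene identifiers are not unique")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        sheet = self.samples.set_index("sample")
        missing = set(self.values.columns) - set(sheet.index)
        if missing:
            raise ValueError(f"samples absent from sample sheet: {sorted(missing)}")
        for (line, treat), group in sheet.groupby(["cell_line", "treatment"]):
            if len(group) < 2:
                raise ValueError(
                    f"group ({line}, {treat}) has {len(group)} replicate(s); need >= 2"
                )

    def group_columns(self, cell_line: str, treatment: str) -> list:
        sheet = self.samples
        mask = (sheet["cell_line"] == cell_line) & (sheet["treatment"] == treatment)
        cols = [s for s in sheet.loc[mask, "sample"] if s in self.values.columns]
        if not cols:
            raise ValueError(f"no samples for group ({cell_line}, {treatment})")
        return cols


def collapse_probes(
    probe_values: pd.DataFrame, probe_to_gene: Mapping[str, str]
) -> pd.DataFrame:
    """Collapse a probes x samples matrix to genes by averaging probe rows.

    Unmapped probes are dropped (and counted in the log); each probe maps
    to at most one gene by construction of the mapping.
    """
    if not probe_to_gene:
        raise ValueError("probe-to-gene mapping is empty")
    genes = probe_values.index.to_series().map(dict(probe_to_gene))
    n_unmapped = int(genes.isna().sum())
    if n_unmapped:
        logger.info("dropping %d unmapped probes", n_unmapped)
    mapped = probe_values.loc[genes.notna()]
    if mapped.empty:
        raise ValueError("no probes map to any gene")
    collapsed = mapped.groupby(genes.dropna()).mean()
    collapsed.index.name = "gene"
    return collapsed


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone, ties stable)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    em: ExpressionMatrix, contrast: str = "baseline", shrink: float = 0.0
) -> pd.DataFrame:
    """Resistant-vs-parental differential expression for one contrast.

    Parameters
    ----------
    em
        Validated expression matrix.
    contrast
        "baseline" (untreated samples) or "treated".
    shrink
        Prior degrees of freedom d0 of the variance moderation; each gene's
        pooled variance is replaced by ``(d0*median(s2) + df*s2)/(d0+df)``
        and the t reference gains d0 degrees of freedom. 0 disables
        moderation (plain pooled t, exactly calibrated under normality).

    Returns a per-gene frame with ``log2fc``, signed linear ``fold_change``
    (magnitude 2^|log2fc|, +1/-1 convention for no change), raw ``p`` and
    BH-adjusted ``q``.
    """
    if contrast not in CONTRAST_TREATMENT:
        raise ValueError(f"unknown contrast {contrast!r}")
    em.validate()
    treatment = CONTRAST_TREATMENT[contrast]
    x = em.values[em.group_columns("resistant", treatment)].to_numpy()
    y = em.values[em.group_columns("parental", treatment)].to_numpy()
    n1, n2 = x.shape[1], y.shape[1]
    df = n1 + n2 - 2
    log2fc = x.mean(axis=1) - y.mean(axis=1)
    s2 = ((n1 - 1) * x.var(axis=1, ddof=1) + (n2 - 1) * y.var(axis=1, ddof=1)) / df
    if np.all(s2 == 0):
        raise ValueError(
            "all genes have zero within-group variance; the test statistic is "
            "undefined — inject measurement noise into the synthetic input"
        )
    dof = df
    if shrink > 0:
        s2 = (shrink * np.median(s2) + df * s2) / (shrink + df)
        dof = df + shrink
    se = np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), np.inf * np.sign(log2fc))
    t = np.where((se == 0) & (log2fc == 0), 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p = np.clip(p, 0.0, 1.0)
    fold = np.where(log2fc >= 0, np.power(2.0, log2fc), -np.power(2.0, -log2fc))
    fold = np.where(log2fc == 0, 1.0, fold)
    result = pd.DataFrame(
        {
            "log2fc": log2fc,
            "fold_change": fold,
            "p": p,
            "q": bh_adjust(p),
        },
        index=em.values.index,
    )
    result.attrs["contrast"] = contrast
    return result


@dataclass
class GeneSets:
    """Trastuzumab-independent regulated genes split by direction."""

    up: Set[str]
    down: Set[str]

    @property
    def all(self) -> Set[str]:
        return self.up | self.down


def select_resistance_genes(
    de_baseline: pd.DataFrame,
    de_treated: pd.DataFrame,
    q_max: float = 0.05,
    fc_min: float = 2.0,
) -> GeneSets:
    """Select genes regulated independently of trastuzumab.

    A gene qualifies iff it is significant (q < q_max, strictly) with
    |fold change| > fc_min (strictly) in BOTH contrasts and with the same
    sign; the output is split into up- and down-regulated sets. The rule is
    symmetric in the two contrasts.
    """
    if set(de_baseline.index) != set(de_treated.index):
        raise ValueError("the two contrasts cover different gene universes")
    b = de_baseline
    t = de_treated.reindex(b.index)
    sig_b = (b["q"] < q_max) & (b["fold_change"].abs() > fc_min)
    sig_t = (t["q"] < q_max) & (t["fold_change"].abs() > fc_min)
    same_sign = np.sign(b["log2fc"]) == np.sign(t["log2fc"])
    selected = sig_b & sig_t & same_sign
    up = set(b.index[selected & (b["log2fc"] > 0)])
    down = set(b.index[selected & (b["log2fc"] < 0)])
    return GeneSets(up=up, down=down)


def load_expression(matrix_path, sample_sheet_path) -> ExpressionMatrix:
    """Read a TSV log2 matrix (gene index) and its sample sheet."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    samples = pd.read_csv(sample_sheet_path, sep="\t")
    em = ExpressionMatrix(values=values, samples=samples)
    em.validate()
    return em
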