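"""Synthetic SILAC phosphosite tables and expression matrices with ground truth.

The generator emulates the study conditions the analysis assumes: per time
point, four SILAC mixes realizing the four biological contrasts with the
label-swap channel design (resistant line heavy in the untreated pair,
light in the treated pair); planted resistance markers (including a
YAP1-Ser109-like dephosphorylation exemplar), treatment-response-only
sites, de-novo-reversal sites and null sites; multiplicative log-normal
ratio noise; a localization-probability distribution targeting a 74%
class-1 share; and per-site-per-experiment missingness. The expression
arm produces a log2 matrix over 2 cell lines x 2 treatments x replicates
with planted >2-fold trastuzumab-independent genes (a TEAD2-like up gene
at 2.24-fold among them).

Ground truth is returned (and serializable) alongside the data so every
downstream stage can be tested without any external download.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .design import CONTRASTS, TIMEPOINTS, ComparisonDesign, default_design
from .phospho import MAXQUANT_DIALECT, TableDialect

SITE_CATEGORIES = (
    "resistance_up",
    "resistance_down",
    "treatment_response_only",
    "de_novo_reversal",
    "null",
)
GENE_CATEGORIES = (
    "trastuzumab_independent_up",
    "trastuzumab_independent_down",
    "treatment_only",
    "null",
)

#: Fold change of the TEAD2-like exemplar gene (first planted up gene).
TEAD2_FOLD = 2.24


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic generator.

    Category fractions are proportions of ``n_sites``; the remainder is
    null. ``effect_size`` is the planted |fold change| on the ratio scale,
    ``noise_sd`` the standard deviation of log10 multiplicative ratio
    noise, ``expr_noise_sd`` the gaussian sd on the log2 expression scale.
    ``partial_marker_fraction`` moves that share of planted resistance
    markers to only 2 of the 3 time points, exercising the 2/3-vs-3/3
    overlap logic (default: effects constant across time points).
    """

    n_sites: int = 5000
    n_genes: int = 2000
    resistance_up: float = 0.01
    resistance_down: float = 0.01
    treatment_response_only: float = 0.01
    de_novo_reversal: float = 0.005
    effect_size: float = 3.0
    noise_sd: float = 0.05
    class1_fraction: float = 0.74
    missing_rate: float = 0.05
    partial_marker_fraction: float = 0.0
    n_expr_up: int = 16
    n_expr_down: int = 20
    n_expr_treatment_only: int = 20
    expr_noise_sd: float = 0.1
    n_replicates_expr: int = 2
    seed: int = 0

    @property
    def fractions(self) -> Dict[str, float]:
        return {
            "resistance_up": self.resistance_up,
            "resistance_down": self.resistance_down,
            "treatment_response_only": self.treatment_response_only,
            "de_novo_reversal": self.de_novo_reversal,
        }

    def validate(self) -> None:
        for name, f in self.fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction {name}={f} not in [0, 1]")
        if sum(self.fractions.values()) > 1.0:
            raise ValueError("category fractions sum to more than 1")
        if self.effect_size <= 0:
            raise ValueError(f"effect_size must be positive, got {self.effect_size}")
        if not 0.0 <= self.class1_fraction <= 1.0:
            raise ValueError("class1_fraction must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.partial_marker_fraction <= 1.0:
            raise ValueError("partial_marker_fraction must lie in [0, 1]")
        if self.n_replicates_expr < 2:
            raise ValueError(
                "n_replicates_expr must be >= 2: the DE stage needs "
                "within-group variance"
            )
        if self.noise_sd < 0 or self.expr_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")


@dataclass
class SiteTruth:
    category: str
    direction: int  # +1 / -1 / 0
    active_timepoints: List[str]
    gene_symbol: str


@dataclass
class SyntheticTruth:
    """Ground-truth labels serialized alongside the generated data."""

    sites: Dict[str, SiteTruth] = field(default_factory=dict)
    genes: Dict[str, str] = field(default_factory=dict)

    def resistance_label(self, key: str) -> Optional[str]:
        """Direction-level truth: de-novo-reversal sites count toward their
        resistance direction (the set logic annotates, not excludes, them)."""
        truth = self.sites[key]
        if truth.category in ("resistance_up", "resistance_down"):
            return truth.category
        if truth.category == "de_novo_reversal":
            return "resistance_up" if truth.direction > 0 else "resistance_down"
        return None

    def to_json(self, path) -> None:
        payload = {
            "sites": {k: asdict(v) for k, v in sorted(self.sites.items())},
            "genes": dict(sorted(self.genes.items())),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            sites={k: SiteTruth(**v) for k, v in payload["sites"].items()},
            genes=dict(payload["genes"]),
        )


def _signed_to_ratio(direction: int, effect: float) -> float:
    if direction > 0:
        return effect
    if direction < 0:
        return 1.0 / effect
    return 1.0


def _site_categories(config: SimulationConfig) -> List[str]:
    counts = {name: int(round(f * config.n_sites)) for name, f in config.fractions.items()}
    labels: List[str] = []
    for name in SITE_CATEGORIES[:-1]:
        labels.extend([name] * counts[name])
    labels.extend(["null"] * (config.n_sites - len(labels)))
    return labels[: config.n_sites]


def generate_silac_dataset(
    config: SimulationConfig,
    swap_labels: bool = False,
    dialect: TableDialect = MAXQUANT_DIALECT,
) -> Tuple[Dict[str, pd.DataFrame], SyntheticTruth, ComparisonDesign]:
    """Generate one phosphosite table per time point plus ground truth.

    Noise is multiplicative log10-normal and is applied on the oriented
    sample/reference ratio before conversion to the stored H/L channel
    value, so regenerating with ``swap_labels=True`` yields tables whose
    raw ratios are exact reciprocals — the structural label-swap
    invariance of the paired design. Identical seed and config give
    identical output.
    """
    config.validate()
    design = default_design(swapped=swap_labels)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[0])
    n = config.n_sites
    categories = _site_categories(config)

    proteins = [f"PSYN{i:05d}" for i in range(n)]
    genes = [f"GENE{i * 7 % max(config.n_genes, 1):05d}" for i in range(n)]
    residues = rng.choice(list("STY"), size=n, p=[0.86, 0.12, 0.02])
    positions = rng.integers(1, 1000, size=n)
    signs = rng.choice([1, -1], size=n)

    directions = np.zeros(n, dtype=int)
    for i, cat in enumerate(categories):
        if cat == "resistance_up":
            directions[i] = 1
        elif cat == "resistance_down":
            directions[i] = -1
        elif cat in ("treatment_response_only", "de_novo_reversal"):
            directions[i] = signs[i]

    # YAP1-Ser109-like exemplar: first resistance_down site.
    try:
        yap_idx = categories.index("resistance_down")
        proteins[yap_idx], genes[yap_idx] = "P46937", "YAP1"
        residues[yap_idx], positions[yap_idx] = "S", 109
    except ValueError:
        pass

    # Active time points: all three, except for the partial-marker share.
    marker_mask = np.array(
        [c in ("resistance_up", "resistance_down", "de_novo_reversal") for c in categories]
    )
    partial = marker_mask & (rng.random(n) < config.partial_marker_fraction)
    active: List[Set[str]] = []
    for i in range(n):
        if partial[i]:
            keep = rng.choice(len(TIMEPOINTS), size=2, replace=False)
            active.append({TIMEPOINTS[j] for j in keep})
        else:
            active.append(set(TIMEPOINTS))

    # Localization probabilities: planted sites are always class-1; null
    # sites absorb the difference so the expected overall share matches.
    planted_frac = float(marker_mask.mean() + (np.array(categories) == "treatment_response_only").mean())
    n_null_like = max(1.0 - planted_frac, 1e-12)
    p_null = float(np.clip((config.class1_fraction - planted_frac) / n_null_like, 0.0, 1.0))
    is_class1 = np.where(
        marker_mask | (np.array(categories) == "treatment_response_only"),
        True,
        rng.random(n) < p_null,
    )
    locprob = np.where(
        is_class1, rng.uniform(0.755, 1.0, size=n), rng.uniform(0.20, 0.745, size=n)
    )

    def true_effects(i: int, tp: str) -> Dict[str, int]:
        """True signed regulation (+1/-1/0) per contrast for site i at tp."""
        cat, d = categories[i], int(directions[i])
        if cat == "null" or tp not in active[i]:
            return {c: 0 for c in CONTRASTS}
        if cat in ("resistance_up", "resistance_down"):
            return {"A": d, "B": d, "C": 0, "D": 0}
        if cat == "treatment_response_only":
            return {"A": 0, "B": 0, "C": d, "D": d}
        if cat == "de_novo_reversal":
            return {"A": d, "B": d, "C": 0, "D": -d}
        raise AssertionError(cat)

    tables: Dict[str, pd.DataFrame] = {}
    for tp in TIMEPOINTS:
        data: Dict[str, list] = {
            dialect.protein: proteins,
            dialect.gene: genes,
            dialect.residue: list(residues),
            dialect.position: list(positions),
            dialect.multiplicity: [1] * n,
            dialect.localization: np.round(locprob, 6),
        }
        for contrast in CONTRASTS:
            mapping = design.mapping(tp, contrast)
            eps = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else np.zeros(n)
            miss = rng.random(n) < config.missing_rate
            oriented = np.array(
                [
                    _signed_to_ratio(true_effects(i, tp)[contrast], config.effect_size)
                    for i in range(n)
                ]
            ) * np.power(10.0, eps)
            raw = oriented if mapping.heavy_is_sample else 1.0 / oriented
            raw = np.where(miss, np.nan, raw)
            data[dialect.ratio_prefix + mapping.experiment] = raw
        data[dialect.reverse] = [""] * n
        data[dialect.contaminant] = [""] * n
        tables[tp] = pd.DataFrame(data)

    truth = SyntheticTruth()
    for i in range(n):
        key = f"{proteins[i]}:{residues[i]}{positions[i]}:1"
        truth.sites[key] = SiteTruth(
            category=categories[i],
            direction=int(directions[i]),
            active_timepoints=sorted(active[i]) if categories[i] != "null" else [],
            gene_symbol=genes[i],
        )
    return tables, truth, design


def generate_expression_dataset(
    config: SimulationConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate a log2 expression matrix, sample sheet and gene truth.

    Planted trastuzumab-independent genes differ between resistant and
    parental cells by the same signed log2 effect in both the untreated and
    treated contrasts; treatment-only genes respond to treatment equally in
    both lines, so they never satisfy the trastuzumab-independent rule.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    n = config.n_genes
    n_planted = config.n_expr_up + config.n_expr_down + config.n_expr_treatment_only
    if n_planted > n:
        raise ValueError("planted gene counts exceed n_genes")

    gene_names = ["TEAD2"] + [f"GENE{i:05d}" for i in range(1, n)] if config.n_expr_up else [
        f"GENE{i:05d}" for i in range(n)
    ]
    labels = (
        ["trastuzumab_independent_up"] * config.n_expr_up
        + ["trastuzumab_independent_down"] * config.n_expr_down
        + ["treatment_only"] * config.n_expr_treatment_only
        + ["null"] * (n - n_planted)
    )

    delta = np.log2(config.effect_size)
    effect = np.zeros(n)
    for i, lab in enumerate(labels):
        if lab == "trastuzumab_independent_up":
            effect[i] = delta
        elif lab == "trastuzumab_independent_down":
            effect[i] = -delta
        elif lab == "treatment_only":
            effect[i] = delta * (1 if rng.random() < 0.5 else -1)
    if config.n_expr_up:
        effect[0] = np.log2(TEAD2_FOLD)  # TEAD2-like exemplar

    base = rng.normal(8.0, 1.5, size=n)
    samples = []
    columns: Dict[str, np.ndarray] = {}
    for cell_line in ("parental", "resistant"):
        for treatment in ("untreated", "treated"):
            for rep in range(1, config.n_replicates_expr + 1):
                name = f"{cell_line}_{treatment}_{rep}"
                mean = base.copy()
                for i, lab in enumerate(labels):
                    if lab.startswith("trastuzumab_independent") and cell_line == "resistant":
                        mean[i] += effect[i]
                    elif lab == "treatment_only" and treatment == "treated":
                        mean[i] += effect[i]
                noise = (
                    rng.normal(0.0, config.expr_noise_sd, size=n)
                    if config.expr_noise_sd > 0
                    else np.zeros(n)
                )
                columns[name] = mean + noise
                samples.append(
                    {"sample": name, "cell_line": cell_line, "treatment": treatment,
                     "replicate": rep}
                )

    matrix = pd.DataFrame(columns, index=pd.Index(gene_names, name="gene")).round(6)
    sample_sheet = pd.DataFrame(samples)
    truth = SyntheticTruth(genes=dict(zip(gene_names, labels)))
    return matrix, sample_sheet, truth


def write_silac_tables(
    tables: Mapping[str, pd.DataFrame], out_dir, prefix: str = "phospho"
) -> Dict[str, Path]:
    """Write per-time-point TSV tables with stable float formatting."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for tp, frame in tables.items():
        path = out_dir / f"{prefix}_{tp}.tsv"
        frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
        paths[tp] = path
    return paths


def write_expression(matrix: pd.DataFrame, sample_sheet: pd.DataFrame, out_dir) -> Tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mpath = out_dir / "expression_log2.tsv"
    spath = out_dir / "samples.tsv"
    matrix.to_csv(mpath, sep="\t", float_format="%.6g")
    sample_sheet.to_csv(spath, sep="\t", index=False)
    return mpath, spath


def truth_evaluation(
    predicted: Mapping[str, str],
    truth: SyntheticTruth,
    categories: Sequence[str] = ("resistance_up", "resistance_down"),
) -> pd.DataFrame:
    """Per-category precision and recall of marker recovery.

    ``predicted`` maps site keys to direction-level categories
    (resistance_up / resistance_down). Truth is compared at the direction
    level (see :meth:`SyntheticTruth.resistance_label`). Precision is NaN
    when nothing was predicted in a category (zero support is reported).
    """
    unknown = set(predicted) - set(truth.sites)
    if unknown:
        raise ValueError(f"predicted identifiers absent from truth: {sorted(unknown)[:5]}")
    rows = []
    for cat in categories:
        true_keys = {k for k in truth.sites if truth.resistance_label(k) == cat}
        pred_keys = {k for k, v in predicted.items() if v == cat}
        tp = len(true_keys & pred_keys)
        fp = len(pred_keys - true_keys)
        fn = len(true_keys - pred_keys)
        rows.append(
            {
                "category": cat,
                "n_true": len(true_keys),
                "n_predicted": len(pred_keys),
                "tp": tp,
                "fp": fp,
                "fn": fn,
                "precision": tp / (tp + fp) if (tp + fp) else float("nan"),
                "recall": tp / (tp + fn) if (tp + fn) else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("category")


def confusion_counts(
    predicted: Mapping[str, str], truth: SyntheticTruth
) -> pd.DataFrame:
    """Counts of (truth category, predicted category) pairs over predictions."""
    pairs: Dict[Tuple[str, str], int] = {}
    for key, pred in predicted.items():
        true_cat = truth.sites[key].category
        pairs[(true_cat, pred)] = pairs.get((true_cat, pred), 0) + 1
    rows = [
        {"truth_category": t, "predicted": p, "count": c}
        for (t, p), c in sorted(pairs.items())
    ]
    return pd.DataFrame(rows, columns=["truth_category", "predicted", "count"])


def evaluate_gene_sets(
    up: Set[str], down: Set[str], truth: SyntheticTruth
) -> pd.DataFrame:
    """Precision/recall of the trastuzumab-independent gene selection."""
    predicted = {g: "trastuzumab_independent_up" for g in up}
    predicted.update({g: "trastuzumab_independent_down" for g in down})
    unknown = set(predicted) - set(truth.genes)
    if unknown:
        raise ValueError(f"predicted genes absent from truth: {sorted(unknown)[:5]}")
    rows = []
    for cat in ("trastuzumab_independent_up", "trastuzumab_independent_down"):
        true_keys = {g for g, lab in truth.genes.items() if lab == cat}
        pred_keys = {g for g, v in predicted.items() if v == cat}
        tp = len(true_keys & pred_keys)
        fp = len(pred_keys - true_keys)
        fn = len(true_keys - pred_keys)
        rows.append(
            {
                "category": cat,
                "n_true": len(true_keys),
                "n_predicted": len(pred_keys),
                "tp": tp,
                "fp": fp,
                "fn": fn,
                "precision": tp / (tp + fp) if (tp + fp) else float("nan"),
                "recall": tp / (tp + fn) if (tp + fn) else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("category")
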