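"""Differential expression, BH adjustment and gene selection."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phosmark.de import (
    ExpressionMatrix,
    bh_adjust,
    collapse_probes,
    differential_expression,
    select_resistance_genes,
)
from phosmark.synthetic import SimulationConfig, generate_expression_dataset


def brute_force_bh(p):
    """Step-up from first principles: q_(i) = min_{j>=i} m p_(j) / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        q[idx] = running
    return q


class TestBH:
    def test_hand_computed_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_and_tied_values(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])
        assert bh_adjust([0.5, 0.5, 0.5]) == pytest.approx([0.5, 0.5, 0.5])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(derandomize=True, max_examples=100)
    def test_matches_brute_force_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(rng.integers(1, 200))
        assert bh_adjust(p) == pytest.approx(brute_force_bh(p))

    def test_monotone_in_p_ranking(self):
        rng = np.random.default_rng(1)
        p = rng.random(500)
        q = bh_adjust(p)
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= p).all()


class TestCollapseProbes:
    def test_mean_of_probes(self):
        probes = pd.DataFrame(
            {"s1": [4.0, 6.0, 3.0], "s2": [2.0, 4.0, 5.0]},
            index=["p1", "p2", "p3"],
        )
        collapsed = collapse_probes(probes, {"p1": "G1", "p2": "G1", "p3": "G2"})
        assert collapsed.loc["G1", "s1"] == pytest.approx(5.0)
        assert collapsed.loc["G2"].tolist() == [3.0, 5.0]

    def test_single_probe_identity_and_unmapped_dropped(self):
        probes = pd.DataFrame({"s1": [4.0, 7.0]}, index=["p1", "px"])
        collapsed = collapse_probes(probes, {"p1": "G1"})
        assert list(collapsed.index) == ["G1"]
        assert collapsed.loc["G1", "s1"] == 4.0

    def test_all_unmapped_is_error(self):
        probes = pd.DataFrame({"s1": [4.0]}, index=["p1"])
        with pytest.raises(ValueError):
            collapse_probes(probes, {"other": "G1"})
        with pytest.raises(ValueError):
            collapse_probes(probes, {})


def simple_matrix(values, n_rep=2):
    """values: gene -> (parental mean, resistant mean); constant across treatment."""
    rng = np.random.default_rng(0)
    samples, cols = [], {}
    for line in ("parental", "resistant"):
        for treat in ("untreated", "treated"):
            for rep in range(1, n_rep + 1):
                name = f"{line}_{treat}_{rep}"
                cols[name] = [
                    v[0 if line == "parental" else 1] + rng.normal(0, 0.05)
                    for v in values.values()
                ]
                samples.append(
                    {"sample": name, "cell_line": line, "treatment": treat, "replicate": rep}
                )
    return ExpressionMatrix(
        pd.DataFrame(cols, index=pd.Index(values.keys(), name="gene")),
        pd.DataFrame(samples),
    )


class TestDifferentialExpression:
    def test_label_swap_negates_log2fc_keeps_p(self):
        em = simple_matrix({"G1": (5.0, 7.0), "G2": (6.0, 6.0)})
        de = differential_expression(em, "baseline")
        swapped_sheet = em.samples.assign(
            cell_line=em.samples["cell_line"].map(
                {"parental": "resistant", "resistant": "parental"}
            )
        )
        de_swapped = differential_expression(
            ExpressionMatrix(em.values, swapped_sheet), "baseline"
        )
        assert de_swapped["log2fc"].to_numpy() == pytest.approx(
            -de["log2fc"].to_numpy()
        )
        assert de_swapped["p"].to_numpy() == pytest.approx(de["p"].to_numpy())

    def test_zero_variance_everywhere_is_instructive_error(self):
        cfg = SimulationConfig(n_genes=20, expr_noise_sd=0.0, seed=0,
                               n_expr_up=2, n_expr_down=2, n_expr_treatment_only=0)
        matrix, samples, _ = generate_expression_dataset(cfg)
        em = ExpressionMatrix(matrix, samples)
        with pytest.raises(ValueError, match="noise"):
            differential_expression(em, "baseline")

    def test_planted_gene_detected_across_replicated_simulations(self):
        """A 4-fold planted gene (log2FC=2, sd 0.1, n=2/group) is recovered
        with FC near 4 and q<0.05 in at least 95% of simulation replicates."""
        rng = np.random.default_rng(42)
        hits, fcs = 0, []
        n_reps = 200
        for _ in range(n_reps):
            n_genes = 200
            base = rng.normal(8, 1, n_genes)
            effect = np.zeros(n_genes)
            effect[0] = 2.0
            cols, samples = {}, []
            for line in ("parental", "resistant"):
                for treat in ("untreated", "treated"):
                    for rep in (1, 2):
                        name = f"{line}_{treat}_{rep}"
                        mean = base + (effect if line == "resistant" else 0)
                        cols[name] = mean + rng.normal(0, 0.1, n_genes)
                        samples.append(
                            {"sample": name, "cell_line": line,
                             "treatment": treat, "replicate": rep}
                        )
            em = ExpressionMatrix(
                pd.DataFrame(cols, index=pd.Index([f"g{i}" for i in range(n_genes)])),
                pd.DataFrame(samples),
            )
            de = differential_expression(em, "baseline", shrink=4.0)
            fcs.append(abs(de.iloc[0]["fold_change"]))
            if de.iloc[0]["q"] < 0.05:
                hits += 1
        assert hits / n_reps >= 0.95
        assert 3.5 <= float(np.median(fcs)) <= 4.6

    def test_null_pvalues_uniform(self):
        """Plain pooled t on pure-noise data: p-values pass a KS test for
        uniformity (alpha 0.01, 5000 null genes)."""
        from scipy import stats

        cfg = SimulationConfig(
            n_genes=5000, n_expr_up=0, n_expr_down=0, n_expr_treatment_only=0,
            expr_noise_sd=0.2, seed=13,
        )
        matrix, samples, _ = generate_expression_dataset(cfg)
        de = differential_expression(ExpressionMatrix(matrix, samples), "baseline")
        assert stats.kstest(de["p"], "uniform").pvalue > 0.01


class TestGeneSelection:
    def make_de(self, rows):
        frame = pd.DataFrame(rows, columns=["gene", "log2fc", "q"]).set_index("gene")
        frame["fold_change"] = np.sign(frame["log2fc"]) * 2.0 ** frame["log2fc"].abs()
        frame["p"] = frame["q"]
        return frame

    def test_both_contrast_same_sign_rule(self):
        base = self.make_de([("G1", 2.0, 0.01), ("G2", 2.0, 0.01), ("G3", 2.0, 0.01),
                             ("G4", -2.0, 0.01)])
        treat = self.make_de([("G1", 2.0, 0.01), ("G2", 0.1, 0.8), ("G3", -2.0, 0.01),
                              ("G4", -2.0, 0.01)])
        sets = select_resistance_genes(base, treat)
        assert sets.up == {"G1"}       # significant up in both
        assert "G2" not in sets.all    # unchanged under treatment
        assert "G3" not in sets.all    # direction conflict
        assert sets.down == {"G4"}

    def test_strict_thresholds(self):
        base = self.make_de([("G1", 1.0, 0.01)])  # FC exactly 2 — excluded
        treat = self.make_de([("G1", 1.0, 0.01)])
        assert select_resistance_genes(base, treat).all == set()
        base2 = self.make_de([("G1", 1.5, 0.05)])  # q exactly 0.05 — excluded
        treat2 = self.make_de([("G1", 1.5, 0.05)])
        assert select_resistance_genes(base2, treat2).all == set()

    def test_symmetry_in_contrast_arguments(self):
        rng = np.random.default_rng(7)
        rows = [(f"G{i}", rng.normal(0, 2), rng.random()) for i in range(50)]
        rows2 = [(f"G{i}", rng.normal(0, 2), rng.random()) for i in range(50)]
        a, b = self.make_de(rows), self.make_de(rows2)
        fwd = select_resistance_genes(a, b)
        rev = select_resistance_genes(b, a)
        assert fwd.up == rev.up and fwd.down == rev.down

    def test_mismatched_universes_rejected(self):
        a = self.make_de([("G1", 2.0, 0.01)])
        b = self.make_de([("G2", 2.0, 0.01)])
        with pytest.raises(ValueError, match="universe"):
            select_resistance_genes(a, b)


def test_end_to_end_gene_recovery():
    """Planted trastuzumab-independent genes recovered from the default-scale
    synthetic matrix with moderated variance; treatment-only genes excluded."""
    from phosmark.synthetic import evaluate_gene_sets

    cfg = SimulationConfig(seed=7)
    matrix, samples, truth = generate_expression_dataset(cfg)
    em = ExpressionMatrix(matrix, samples)
    base = differential_expression(em, "baseline", shrink=4.0)
    treat = differential_expression(em, "treated", shrink=4.0)
    sets = select_resistance_genes(base, treat)
    table = evaluate_gene_sets(sets.up, sets.down, truth)
    assert (table["precision"] == 1.0).all()
    assert (table["recall"] >= 0.9).all()
    treatment_only = {g for g, l in truth.genes.items() if l == "treatment_only"}
    assert not (sets.all & treatment_only)
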