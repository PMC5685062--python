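import math
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from crosstalk_mccv import (
    ExpressionMatrix,
    SampleLabels,
    SimulationConfig,
    benjamini_hochberg,
    deg_list,
    deg_table,
    group_stats,
    moderated_t_test,
    simulate_study,
)
from crosstalk_mccv.dea import DegenerateVarianceError, apply_deg_filter


def _matrix(rows, genes, samples):
    return ExpressionMatrix(
        pd.DataFrame(np.asarray(rows, float), index=genes, columns=samples)
    )


@pytest.fixture
def four_sample_labels():
    return SampleLabels(
        {"c1": "case", "c2": "case", "n1": "control", "n2": "control"}
    )


class TestGroupStats:
    def test_hand_computed_examples(self, four_sample_labels):
        expr = _matrix(
            [[2, 2, 1, 1], [1, 3, 2, 4], [5, 5, 5, 5]],
            ["G1", "G2", "G3"],
            ["c1", "c2", "n1", "n2"],
        )
        st_ = group_stats(expr, four_sample_labels)
        assert st_.log2fc[0] == pytest.approx(1.0)
        assert st_.s2[0] == pytest.approx(0.0)
        # case [1,3], control [2,4]: pooled s^2 = ((1)*2 + (1)*2)/2 = 2
        assert st_.log2fc[1] == pytest.approx(-1.0)
        assert st_.s2[1] == pytest.approx(2.0)
        assert st_.df == 2
        # identical groups: symmetric, zero fold change
        assert st_.log2fc[2] == pytest.approx(0.0)

    def test_single_sample_group_rejected(self):
        expr = _matrix([[1, 2, 3], [4, 5, 6]], ["G1", "G2"], ["a", "b", "c"])
        labels = SampleLabels({"a": "case", "b": "case", "c": "control"})
        with pytest.raises(ValueError, match=">=2 samples"):
            group_stats(expr, labels)


@pytest.fixture(scope="module")
def simulated_stats():
    # per-gene sigma jitter spreads the variance ensemble so the prior df
    # estimate is finite and shrinkage is non-trivial
    expr, labels, _, _ = simulate_study(
        SimulationConfig(
            n_genes=400, seed=21, pathway_size_range=(10, 20), gene_sd_jitter=0.4
        )
    )
    return group_stats(expr, labels)


class TestModeratedT:
    def test_no_shrinkage_equals_ordinary_t(self, simulated_stats):
        _, p = moderated_t_test(simulated_stats, prior_df=0)
        t = simulated_stats.log2fc / np.sqrt(
            simulated_stats.s2
            * (1 / simulated_stats.n_case + 1 / simulated_stats.n_control)
        )
        expected = 2 * stats.t.sf(np.abs(t), simulated_stats.df)
        assert np.max(np.abs(p - expected)) < 1e-12

    def test_equal_variances_are_shrinkage_fixed_point(self, four_sample_labels):
        rng = np.random.default_rng(0)
        fc = rng.normal(size=50)
        frame = np.zeros((50, 4))
        # every gene: case values m+-0.5, control -m+-0.5 -> identical s2 = 0.5
        frame[:, 0] = fc + 0.5
        frame[:, 1] = fc - 0.5
        frame[:, 2] = 0.5
        frame[:, 3] = -0.5
        expr = _matrix(frame, [f"G{i}" for i in range(50)], ["c1", "c2", "n1", "n2"])
        st_ = group_stats(expr, four_sample_labels)
        assert np.allclose(st_.s2, st_.s2[0])
        params, _ = moderated_t_test(st_)
        d0, s0 = params.prior_df, params.prior_var
        if math.isinf(d0):
            post = np.full_like(st_.s2, s0)
        else:
            post = (d0 * s0 + st_.df * st_.s2) / (d0 + st_.df)
        assert np.allclose(post, st_.s2, rtol=1e-6)

    def test_null_pvalues_uniform(self):
        expr, labels, _, _ = simulate_study(
            SimulationConfig(n_genes=1000, effect_size=0.0, seed=13)
        )
        _, p = moderated_t_test(group_stats(expr, labels))
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_shrinkage_monotonicity(self, simulated_stats):
        """Posterior variances lie between the gene variance and the prior."""
        params, _ = moderated_t_test(simulated_stats)
        d0, s0, d = params.prior_df, params.prior_var, simulated_stats.df
        assert math.isfinite(d0)
        post = (d0 * s0 + d * simulated_stats.s2) / (d0 + d)
        lo = np.minimum(simulated_stats.s2, s0)
        hi = np.maximum(simulated_stats.s2, s0)
        assert np.all(post >= lo - 1e-12) and np.all(post <= hi + 1e-12)

    def test_group_swap_negates_lfc_keeps_p(self, simulated_stats):
        expr, labels, _, _ = simulate_study(
            SimulationConfig(n_genes=400, seed=21, pathway_size_range=(10, 20))
        )
        flipped = SampleLabels(
            {
                s: ("control" if g == "case" else "case")
                for s, g in labels.groups.items()
            }
        )
        st_a = group_stats(expr, labels)
        st_b = group_stats(expr, flipped)
        _, p_a = moderated_t_test(st_a)
        _, p_b = moderated_t_test(st_b)
        assert np.allclose(st_a.log2fc, -st_b.log2fc)
        assert np.allclose(p_a, p_b)

    def test_all_zero_variance_rejected(self, four_sample_labels):
        expr = _matrix(
            np.tile([1.0, 1.0, 0.0, 0.0], (12, 1)),
            [f"G{i}" for i in range(12)],
            ["c1", "c2", "n1", "n2"],
        )
        st_ = group_stats(expr, four_sample_labels)
        with pytest.raises(DegenerateVarianceError):
            moderated_t_test(st_)

    def test_matches_limma_ebayes(self, tmp_path):
        """Independent R oracle: limma's eBayes on the same matrix."""
        expr, labels, _, _ = simulate_study(
            SimulationConfig(
                n_genes=200, n_case=5, n_control=5, seed=17,
                pathway_size_range=(10, 20), n_de_genes=10, gene_sd_jitter=0.4,
            )
        )
        st_ = group_stats(expr, labels)
        params, p = moderated_t_test(st_)
        matrix_path = tmp_path / "matrix.tsv"
        expr.frame.to_csv(matrix_path, sep="\t")
        case_flags = ",".join(
            "1" if labels.groups[s] == "case" else "0" for s in expr.sample_ids
        )
        out_path = tmp_path / "limma_out.txt"
        script = textwrap.dedent(f"""
            suppressMessages(library(limma))
            m <- as.matrix(read.delim("{matrix_path}", row.names=1))
            g <- as.numeric(strsplit("{case_flags}", ",")[[1]])
            fit <- eBayes(lmFit(m, cbind(1, g)))
            writeLines(format(c(fit$df.prior, fit$s2.prior, fit$p.value[, 2]),
                              digits=17), "{out_path}")
        """)
        subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        numbers = [float(x) for x in out_path.read_text().split()]
        d0_r, s0_r, p_r = numbers[0], numbers[1], np.array(numbers[2:])
        assert params.prior_df == pytest.approx(d0_r, rel=1e-4)
        assert params.prior_var == pytest.approx(s0_r, rel=1e-6)
        assert np.max(np.abs(p - p_r)) < 1e-9


def bh_brute_force(p):
    """Step-up oracle: fdr_i = min over p_(j) >= p_(i) of min(1, m p_(j)/rank_j)."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    out = np.empty(m)
    for i in range(m):
        candidates = [
            min(1.0, m * ranked[j] / (j + 1)) for j in range(m) if ranked[j] >= ranked[i]
        ]
        out[i] = min(candidates)
    result = np.empty(m)
    result[order] = out
    return result


class TestBenjaminiHochberg:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.03], [0.03]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.005, 0.04], [0.01, 0.04]),
        ],
    )
    def test_worked_examples(self, p, expected):
        assert np.allclose(benjamini_hochberg(np.array(p)), expected, atol=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=50,
        )
    )
    def test_matches_brute_force_step_up(self, p):
        assert np.allclose(
            benjamini_hochberg(np.array(p)), bh_brute_force(p), atol=1e-12
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg(np.array([0.5, 1.5]))

    def test_ties_share_adjusted_value(self):
        fdr = benjamini_hochberg(np.array([0.02, 0.02, 0.9]))
        assert fdr[0] == fdr[1]


class TestDEGFilter:
    def test_published_as_deg_rows_all_pass(self):
        """Reported AS-study DEG rows survive the |log2FC|>1, FDR<0.05 filter."""
        from crosstalk_mccv.reference import load_published_deg_stats

        table = load_published_deg_stats()
        flags = apply_deg_filter(table["log2fc"], table["fdr"])
        assert flags.all()
        row = table.set_index("gene").loc["IL2RB"]
        assert apply_deg_filter(
            np.array([row["log2fc"]]), np.array([row["fdr"]])
        ).all()

    def test_conjunction(self):
        assert not apply_deg_filter(np.array([0.5]), np.array([0.001]))[0]
        assert not apply_deg_filter(np.array([2.0]), np.array([0.2]))[0]
        assert apply_deg_filter(np.array([-1.1]), np.array([0.01]))[0]

    def test_deg_list_sorted_by_fdr(self, simulated_stats):
        _, p = moderated_t_test(simulated_stats)
        table = deg_table(simulated_stats, p)
        genes = deg_list(table)
        fdrs = table.loc[genes, "fdr"].to_numpy()
        assert np.all(np.diff(fdrs) >= 0)
        assert set(genes) == set(table.index[table["is_deg"]])
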