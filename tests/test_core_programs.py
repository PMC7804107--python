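"""QC, normalization, DE and program-set derivation."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import costim
from costim import core_programs as cp
from oracles import bh_stepup


def make_adata(counts, conditions=None):
    counts = np.asarray(counts, dtype=np.int64)
    n, g = counts.shape
    obs = pd.DataFrame(index=[f"c{i}" for i in range(n)])
    if conditions is not None:
        obs[cp.CONDITION_KEY] = conditions
    return ad.AnnData(X=counts, obs=obs,
                      var=pd.DataFrame(index=[f"g{j}" for j in range(g)]))


class TestQCFilter:
    def test_permissive_thresholds_identity(self):
        adata = make_adata(np.arange(12).reshape(3, 4))
        out = cp.qc_filter(adata, min_genes_per_cell=0,
                           max_genes_per_cell=10**9, min_cells_per_gene=0)
        assert out.shape == adata.shape
        assert list(out.obs_names) == list(adata.obs_names)

    def test_toy_thresholds_force_selection(self):
        # detected-gene counts 10, 500, 6000 against [200, 5000]
        counts = np.zeros((3, 6000), dtype=np.int64)
        counts[0, :10] = 1
        counts[1, :500] = 1
        counts[2, :] = 1
        adata = make_adata(counts)
        out = cp.qc_filter(adata, min_genes_per_cell=200,
                           max_genes_per_cell=5000, min_cells_per_gene=1)
        assert list(out.obs_names) == ["c1"]

    def test_planted_dead_cells_removed(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(2.0, size=(200, 50))
        dead = rng.choice(200, size=10, replace=False)
        counts[dead] = 0
        adata = make_adata(counts)
        out = cp.qc_filter(adata, min_genes_per_cell=1,
                           max_genes_per_cell=10**9, min_cells_per_gene=0)
        kept = set(out.obs_names)
        assert all(f"c{i}" not in kept for i in dead)
        assert len(kept) == 190

    def test_all_filtered_raises(self):
        adata = make_adata(np.zeros((3, 4)))
        with pytest.raises(ValueError, match="all cells filtered"):
            cp.qc_filter(adata, min_genes_per_cell=1, max_genes_per_cell=10)


class TestNormalize:
    def test_equal_totals_unit_size_factors(self):
        adata = make_adata([[1, 3], [2, 2], [0, 4]])
        out = cp.normalize(adata)
        assert np.allclose(out.obs["size_factor"], 1.0)

    def test_closed_form_values(self):
        # one cell with counts (2, 0) and size factor 1 -> (ln 3, 0)
        adata = make_adata([[2, 0], [1, 1], [1, 1]])
        out = cp.normalize(adata)
        assert np.allclose(out.layers["lognorm"][0], [np.log(3), 0.0])

    def test_hand_recomputed_and_scaling_behavior(self):
        """Values match a by-hand recomputation on a 3x2 matrix; size
        factors (relative depths) are invariant to scaling all cells by
        a common constant, which then shifts values by the predictable
        ln((c x)/sf + 1)."""
        base = np.array([[1, 2], [3, 4], [5, 6]])
        out1 = cp.normalize(make_adata(base))
        out2 = cp.normalize(make_adata(base * 7))
        totals = base.sum(axis=1)
        sf = totals / np.median(totals)
        by_hand = np.log1p(base / sf[:, None])
        assert np.allclose(out1.layers["lognorm"], by_hand)
        assert np.allclose(out1.obs["size_factor"], out2.obs["size_factor"])
        assert np.allclose(out2.layers["lognorm"],
                           np.log1p(7 * base / sf[:, None]))

    def test_zero_total_cell_named_in_error(self):
        adata = make_adata([[0, 0], [1, 1], [2, 2]])
        with pytest.raises(ValueError, match="c0"):
            cp.normalize(adata)

    def test_size_factor_median_is_one(self, norm_adata):
        assert np.isclose(np.median(norm_adata.obs["size_factor"]), 1.0)


class TestDifferentialExpression:
    def test_null_comparison_calibrated(self):
        """Two halves of the same population: ~5% raw p < 0.05, and
        essentially no FDR-significant calls."""
        rng = np.random.default_rng(1)
        counts = rng.negative_binomial(2, 2 / 4, size=(1000, 400))
        cond = np.array(["x"] * 500 + ["y"] * 500)
        rng.shuffle(cond)
        adata = cp.normalize(make_adata(counts, cond))
        de = cp.differential_expression(adata, "x", "y")
        frac_raw = (de["p_value"] < 0.05).mean()
        assert 0.02 < frac_raw < 0.09
        assert (de["fdr"] <= 0.05).sum() <= 2

    def test_planted_genes_recovered(self, norm_adata, sim_data):
        """>= 95% of 4-fold planted program-A genes are called up."""
        _, truth = sim_data
        de = cp.differential_expression(norm_adata, "stimA", "control")
        a_genes = truth.gene_programs[truth.gene_programs == "A"].index
        called = (de.table.loc[a_genes, "direction"] == "up").mean()
        assert called >= 0.95

    def test_constant_gene_p_one(self):
        # equal library sizes keep gene 0 constant after normalization
        counts = np.ones((20, 3), dtype=int)
        counts[:, 1] = np.arange(20) % 5
        counts[:, 2] = 4 - np.arange(20) % 5
        adata = cp.normalize(make_adata(counts, ["x"] * 10 + ["y"] * 10))
        de = cp.differential_expression(adata, "x", "y")
        assert de["p_value"].iloc[0] == 1.0
        assert de["direction"].iloc[0] == "ns"

    def test_symmetry_swap_inverts_fold_change(self, norm_adata):
        de_ab = cp.differential_expression(norm_adata, "stimA", "control")
        de_ba = cp.differential_expression(norm_adata, "control", "stimA")
        assert np.allclose(de_ab["fold_change"] * de_ba["fold_change"], 1.0,
                           rtol=1e-6)
        assert np.allclose(de_ab["p_value"], de_ba["p_value"])
        swapped = de_ba["direction"].replace({"up": "down", "down": "up"})
        assert (de_ab["direction"] == swapped).all()

    def test_unknown_condition_rejected(self, norm_adata):
        with pytest.raises(ValueError, match="nope"):
            cp.differential_expression(norm_adata, "nope", "control")


@settings(max_examples=200, derandomize=True)
@given(
    st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
             min_size=1, max_size=20)
)
def test_bh_matches_stepup_oracle(pvals):
    """The BH correction used by DE agrees exactly with the literal
    step-up rule on short random p-vectors."""
    from statsmodels.stats.multitest import multipletests

    ours = multipletests(pvals, method="fdr_bh")[1]
    assert np.allclose(ours, bh_stepup(pvals), atol=1e-12)


class TestCoreGenes:
    @staticmethod
    def _de_from_rows(rows):
        table = pd.DataFrame(
            rows, columns=["fold_change", "fdr", "frac_expressed_test"],
            index=[f"g{i}" for i in range(len(rows))],
        )
        table["p_value"] = table["fdr"]
        table["frac_expressed_ref"] = 0.5
        table["direction"] = "up"
        return cp.DEResult(table=table, test_condition="s", ref_condition="c",
                           fc_min=1.5, fdr_max=0.05)

    def test_boundary_exclusions(self):
        de = self._de_from_rows([
            (1.49, 0.01, 0.9),   # fails FC
            (2.0, 0.04, 0.14),   # fails frac
            (1.5, 0.05, 0.15),   # passes all three at the boundary
            (2.0, 0.06, 0.9),    # fails FDR
        ])
        assert cp.define_core_genes(de) == {"g2"}

    def test_monotone_in_thresholds(self, norm_adata):
        de = cp.differential_expression(norm_adata, "stimA", "control")
        base = cp.define_core_genes(de, 1.5, 0.05, 0.15)
        assert base <= cp.define_core_genes(de, 1.2, 0.05, 0.15)
        assert base <= cp.define_core_genes(de, 1.5, 0.10, 0.15)
        assert base <= cp.define_core_genes(de, 1.5, 0.05, 0.05)

    def test_planted_recovery_sensitivity_and_fp(self, norm_adata, sim_data):
        """Sensitivity >= 0.95 on planted 4-fold genes; false positives
        <= 1% of background genes."""
        _, truth = sim_data
        de = cp.differential_expression(norm_adata, "stimA", "control")
        core = cp.define_core_genes(de)
        planted = set(truth.gene_programs[truth.gene_programs.isin(["A", "shared"])].index)
        background = set(truth.gene_programs[truth.gene_programs.isin(["B", "background"])].index)
        sensitivity = len(core & planted) / len(planted)
        fp_rate = len(core & background) / len(background)
        assert sensitivity >= 0.95
        assert fp_rate <= 0.01


class TestProgramSets:
    def test_set_algebra(self):
        p = cp.derive_program_sets({"g1", "g2", "g3"}, {"g2", "g4"})
        assert p.shared == {"g2"}
        assert p.ucg_a == {"g1", "g3"}
        assert p.ucg_b == {"g4"}

    def test_identical_sets_no_ucgs(self):
        p = cp.derive_program_sets({"g1", "g2"}, {"g1", "g2"})
        assert p.ucg_a == frozenset() and p.ucg_b == frozenset()

    def test_constructed_overlap_exact(self):
        rng = np.random.default_rng(0)
        universe = [f"g{i}" for i in range(2000)]
        shared = set(rng.choice(universe, 95, replace=False))
        rest = [g for g in universe if g not in shared]
        a = shared | set(rest[:1046])      # |A| = 1141
        b = shared | set(rest[1046:1331])  # |B| = 380
        p = cp.derive_program_sets(a, b)
        assert len(p.shared) == 95
        assert len(p.core_a) == len(p.ucg_a) + len(p.shared)
        assert len(p.core_b) == len(p.ucg_b) + len(p.shared)


class TestCrossRegulation:
    def test_no_inhibition_mostly_unchanged(self):
        """With no cross-inhibition, UCGs are overwhelmingly unchanged.
        Program genes are kept a small fraction of the transcriptome so
        the compositional shift of library-size factors stays below the
        fold-change threshold."""
        params = costim.CountSimParams(
            n_cells_per_condition=400, n_genes=1000, n_program_genes_a=60,
            n_program_genes_b=60, n_shared_genes=20, cross_inhibition=1.0,
            costim_fractions=(0.0, 0.0, 1.0), seed=21,
        )
        adata, _ = costim.generate_counts(params)
        adn = costim.normalize(adata)
        progs, _ = cp.run_core_program_analysis(adn)
        labels = pd.Series(progs.cross_regulation)
        assert (labels == "unchanged").mean() >= 0.95

    def test_strong_inhibition_detected_on_opposing_program(self):
        """A-dominant-rich costim with strong inhibition flags the
        majority of program-B UCGs as inhibited."""
        params = costim.CountSimParams(
            n_cells_per_condition=400, n_genes=300, n_program_genes_a=60,
            n_program_genes_b=60, n_shared_genes=20, cross_inhibition=0.2,
            costim_fractions=(0.8, 0.1, 0.1), seed=22,
        )
        adata, truth = costim.generate_counts(params)
        adn = costim.normalize(adata)
        progs, _ = cp.run_core_program_analysis(adn)
        b_genes = set(truth.gene_programs[truth.gene_programs == "B"].index)
        ucg_b = progs.ucg_b & b_genes
        assert len(ucg_b) > 0
        inhibited = sum(progs.cross_regulation[g] == "inhibited" for g in ucg_b)
        assert inhibited / len(ucg_b) > 0.5

    def test_missing_costim_condition_rejected(self, no_inhibition_data):
        adn, _ = no_inhibition_data
        sub = adn[(adn.obs[cp.CONDITION_KEY] != "costim").to_numpy()].copy()
        progs = cp.derive_program_sets({"gene0000"}, {"gene0100"})
        with pytest.raises(ValueError, match="costim"):
            cp.classify_cross_regulation(sub, progs)
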