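"""QC, normalization, differential expression and core gene programs.

A stimulus's *core genes* are the genes upregulated versus control at
fold change >= 1.5, FDR <= 0.05 (Wilcoxon rank-sum with Benjamini-Hochberg
correction) and detected in at least 15% of the stimulated cells. The
*unique core genes* (UCGs) of a stimulus are its core genes not shared
with the other program; under co-stimulation each UCG is classified as
inhibited, augmented or unchanged relative to its own single stimulus.

Normalization uses median-scaled library-size factors
(size_factor_i = total_i / median(totals), median exactly 1) and the
shifted log transform ln(count / size_factor + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

LOGNORM_LAYER = "lognorm"
CONDITION_KEY = "condition"

DIRECTION_UP = "up"
DIRECTION_DOWN = "down"
DIRECTION_NS = "ns"

CROSS_INHIBITED = "inhibited"
CROSS_AUGMENTED = "augmented"
CROSS_UNCHANGED = "unchanged"


def _counts(adata: ad.AnnData) -> np.ndarray:
    X = adata.X
    return np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)


def qc_filter(
    adata: ad.AnnData,
    min_genes_per_cell: int = 200,
    max_genes_per_cell: int | None = None,
    min_cells_per_gene: int = 3,
) -> ad.AnnData:
    """Remove low/high-complexity cells and rarely detected genes.

    Cells with a detected-gene count outside [min, max] are dropped (the
    usual proxy for dead cells and doublets); genes detected in fewer
    than ``min_cells_per_gene`` cells are dropped. When ``max`` is None
    it defaults to twice the median detected-gene count. Row/column order
    is preserved.
    """
    if min_genes_per_cell < 0 or min_cells_per_gene < 0:
        raise ValueError("thresholds must be >= 0")
    counts = _counts(adata)
    detected = (counts >= 1).sum(axis=1)
    if max_genes_per_cell is None:
        max_genes_per_cell = int(2 * np.median(detected))
    if min_genes_per_cell >= max_genes_per_cell > 0:
        raise ValueError("min_genes_per_cell must be < max_genes_per_cell")
    keep_cells = (detected >= min_genes_per_cell) & (detected <= max_genes_per_cell)
    if not keep_cells.any():
        raise ValueError("all cells filtered out by QC thresholds")
    sub = adata[keep_cells].copy()
    gene_cells = (_counts(sub) >= 1).sum(axis=0)
    keep_genes = gene_cells >= min_cells_per_gene
    if not keep_genes.any():
        raise ValueError("all genes filtered out by QC thresholds")
    return sub[:, keep_genes].copy()


def normalize(adata: ad.AnnData) -> ad.AnnData:
    """Median-scaled library-size normalization with ln(x/sf + 1) values.

    Adds ``obs['size_factor']`` (positive, median exactly 1) and the
    ``layers['lognorm']`` matrix. Scaling every cell's counts by a common
    constant leaves the normalized values invariant.
    """
    counts = _counts(adata).astype(float)
    totals = counts.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = adata.obs_names[zero[:5]].tolist()
        raise ValueError(f"cells with zero total counts: {names}")
    size_factors = totals / np.median(totals)
    out = adata.copy()
    out.obs["size_factor"] = size_factors
    out.layers[LOGNORM_LAYER] = np.log1p(counts / size_factors[:, None])
    return out


@dataclass
class DEResult:
    """Per-gene differential expression between two conditions."""

    table: pd.DataFrame  # fold_change, p_value, fdr, frac_expressed_*, direction
    test_condition: str
    ref_condition: str
    fc_min: float
    fdr_max: float

    def __getitem__(self, col: str) -> pd.Series:
        return self.table[col]


def _rank_sum_pvalues(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p per column (tie-corrected normal
    approximation); columns constant across both groups get p = 1."""
    res = stats.mannwhitneyu(x, y, axis=0, method="asymptotic")
    p = np.asarray(res.pvalue, dtype=float)
    pooled = np.vstack([x, y])
    constant = pooled.max(axis=0) == pooled.min(axis=0)
    p[constant] = 1.0
    p[np.isnan(p)] = 1.0
    return p


def differential_expression(
    adata: ad.AnnData,
    test_condition: str,
    ref_condition: str,
    fc_min: float = 1.5,
    fdr_max: float = 0.05,
    layer: str = LOGNORM_LAYER,
) -> DEResult:
    """Per-gene Wilcoxon rank-sum test on normalized values with BH FDR.

    Fold change is the ratio of de-logged normalized means,
    (mean(expm1(test)) + eps) / (mean(expm1(ref)) + eps) with eps = 1e-9.
    Direction is 'up' if fold_change >= fc_min and fdr <= fdr_max, 'down'
    if 1/fold_change >= fc_min and fdr <= fdr_max, else 'ns'.
    """
    cond = adata.obs[CONDITION_KEY].astype(str)
    for c in (test_condition, ref_condition):
        if (cond == c).sum() < 2:
            raise ValueError(f"condition {c!r} absent or has < 2 cells")
    vals = np.asarray(adata.layers[layer])
    test = vals[(cond == test_condition).to_numpy()]
    ref = vals[(cond == ref_condition).to_numpy()]

    p = _rank_sum_pvalues(test, ref)
    fdr = multipletests(p, method="fdr_bh")[1]

    eps = 1e-9
    fc = (np.expm1(test).mean(axis=0) + eps) / (np.expm1(ref).mean(axis=0) + eps)

    counts = _counts(adata)
    detected = counts >= 1
    frac_test = detected[(cond == test_condition).to_numpy()].mean(axis=0)
    frac_ref = detected[(cond == ref_condition).to_numpy()].mean(axis=0)

    direction = np.full(adata.n_vars, DIRECTION_NS, dtype=object)
    sig = fdr <= fdr_max
    direction[sig & (fc >= fc_min)] = DIRECTION_UP
    direction[sig & (1.0 / fc >= fc_min)] = DIRECTION_DOWN

    table = pd.DataFrame(
        {
            "fold_change": fc,
            "p_value": p,
            "fdr": fdr,
            "frac_expressed_test": frac_test,
            "frac_expressed_ref": frac_ref,
            "direction": direction,
        },
        index=adata.var_names,
    )
    return DEResult(table=table, test_condition=test_condition,
                    ref_condition=ref_condition, fc_min=fc_min, fdr_max=fdr_max)


def define_core_genes(
    de: DEResult,
    fc_min: float = 1.5,
    fdr_max: float = 0.05,
    frac_min: float = 0.15,
) -> set[str]:
    """Core genes: fold change >= fc_min, FDR <= fdr_max, and detected in
    at least ``frac_min`` of the stimulated (test) cells."""
    t = de.table
    keep = (
        (t["fold_change"] >= fc_min)
        & (t["fdr"] <= fdr_max)
        & (t["frac_expressed_test"] >= frac_min)
    )
    return set(t.index[keep])


@dataclass
class ProgramSets:
    """Core genes and their set decomposition for the two programs.

    ``shared`` = core_a & core_b; ``ucg_a`` / ``ucg_b`` are the unique
    core genes of each program. ``cross_regulation`` maps each UCG to
    inhibited / augmented / unchanged under co-stimulation (filled by
    :func:`classify_cross_regulation`).
    """

    core_a: frozenset[str]
    core_b: frozenset[str]
    cross_regulation: dict[str, str] = field(default_factory=dict)

    @property
    def shared(self) -> frozenset[str]:
        return self.core_a & self.core_b

    @property
    def ucg_a(self) -> frozenset[str]:
        return self.core_a - self.core_b

    @property
    def ucg_b(self) -> frozenset[str]:
        return self.core_b - self.core_a

    def ucg(self, program: str) -> frozenset[str]:
        if program == "A":
            return self.ucg_a
        if program == "B":
            return self.ucg_b
        raise ValueError(f"unknown program {program!r}")

    def cross_inhibited_ucgs(self) -> frozenset[str]:
        return frozenset(
            g for g, lab in self.cross_regulation.items() if lab == CROSS_INHIBITED
        )


def derive_program_sets(core_a: set[str], core_b: set[str]) -> ProgramSets:
    """Decompose two core-gene sets into unique and shared genes."""
    return ProgramSets(core_a=frozenset(core_a), core_b=frozenset(core_b))


def classify_cross_regulation(
    adata: ad.AnnData,
    programs: ProgramSets,
    costim_condition: str = "costim",
    stim_conditions: tuple[str, str] = ("stimA", "stimB"),
    fc_min: float = 1.5,
    fdr_max: float = 0.05,
) -> ProgramSets:
    """Label each UCG inhibited / augmented / unchanged under co-stimulation.

    For program X, differential expression of co-stimulated cells versus
    cells given stimulus X alone is computed across all genes (BH within
    the comparison); a UCG is 'inhibited' if significantly down at the
    thresholds, 'augmented' if up, else 'unchanged'.
    """
    cond = adata.obs[CONDITION_KEY].astype(str)
    if (cond == costim_condition).sum() < 2:
        raise ValueError(f"condition {costim_condition!r} absent or too small")
    cross: dict[str, str] = {}
    for stim, ucg in zip(stim_conditions, (programs.ucg_a, programs.ucg_b)):
        if not ucg:
            continue
        de = differential_expression(
            adata, costim_condition, stim, fc_min=fc_min, fdr_max=fdr_max
        )
        direction = de.table["direction"]
        for g in ucg:
            d = direction.get(g, DIRECTION_NS)
            cross[g] = {
                DIRECTION_DOWN: CROSS_INHIBITED,
                DIRECTION_UP: CROSS_AUGMENTED,
            }.get(d, CROSS_UNCHANGED)
    return replace(programs, cross_regulation=cross)


def run_core_program_analysis(
    adata: ad.AnnData,
    fc_min: float = 1.5,
    fdr_max: float = 0.05,
    frac_min: float = 0.15,
    control: str = "control",
    stim_conditions: tuple[str, str] = ("stimA", "stimB"),
    costim_condition: str = "costim",
) -> tuple[ProgramSets, dict[str, DEResult]]:
    """Convenience chain: DE vs control per stimulus -> core genes ->
    program sets -> cross-regulation labels. ``adata`` must be normalized."""
    de_results = {
        stim: differential_expression(adata, stim, control, fc_min=fc_min,
                                      fdr_max=fdr_max)
        for stim in stim_conditions
    }
    cores = [
        define_core_genes(de_results[s], fc_min=fc_min, fdr_max=fdr_max,
                          frac_min=frac_min)
        for s in stim_conditions
    ]
    programs = derive_program_sets(*cores)
    if (adata.obs[CONDITION_KEY].astype(str) == costim_condition).sum() >= 2:
        programs = classify_cross_regulation(
            adata, programs, costim_condition=costim_condition,
            stim_conditions=stim_conditions, fc_min=fc_min, fdr_max=fdr_max,
        )
    return programs, de_results
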