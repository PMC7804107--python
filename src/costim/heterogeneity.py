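"""Cell-to-cell heterogeneity analyses.

Three views of single-cell variability around the two gene programs:

- :func:`spearman_network` — pairwise Spearman correlation among a gene
  set across single cells, with coefficients whose p-value exceeds 0.05
  masked to 0 (the co-expression network convention used for program
  structure figures).
- :func:`fano_table` — expression noise per gene and condition measured
  by the Fano factor (variance / mean) on size-factor-scaled counts, and
  the shift in Fano under co-stimulation relative to each UCG's own
  single stimulus.
- :func:`ucg_score` — a per-cell program expression score: the mean
  normalized expression over the UCG set minus the mean over a seeded
  random background gene set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats

from .core_programs import CONDITION_KEY, CROSS_INHIBITED, LOGNORM_LAYER, ProgramSets


@dataclass
class MaskedCorrelationMatrix:
    """Pairwise Spearman rho with two-sided p-values; ``rho_masked`` sets
    entries with p > mask_p to 0. Constant genes (zero rank variance) are
    flagged and their off-diagonal entries recorded as rho 0, p 1."""

    genes: list[str]
    rho: pd.DataFrame
    p: pd.DataFrame
    rho_masked: pd.DataFrame
    constant_genes: list[str]
    mask_p: float = 0.05

    def to_long(self) -> pd.DataFrame:
        records = []
        for i, gi in enumerate(self.genes):
            for j, gj in enumerate(self.genes):
                if j <= i:
                    continue
                records.append(
                    (gi, gj, self.rho.iat[i, j], self.p.iat[i, j],
                     self.rho_masked.iat[i, j])
                )
        return pd.DataFrame(records,
                            columns=["gene_i", "gene_j", "rho", "p", "rho_masked"])


def mask_correlations(rho: np.ndarray, p: np.ndarray, mask_p: float) -> np.ndarray:
    """rho with entries set to 0 where p > mask_p (idempotent)."""
    return np.where(p <= mask_p, rho, 0.0)


def spearman_network(
    adata: ad.AnnData,
    genes: Sequence[str],
    condition: str | None = None,
    mask_p: float = 0.05,
    layer: str = LOGNORM_LAYER,
) -> MaskedCorrelationMatrix:
    """Significance-masked Spearman co-expression network.

    p-values come from the t-approximation for Spearman rho on
    tie-corrected ranks; the diagonal is rho = 1, p = 0.
    """
    genes = list(genes)
    missing = [g for g in genes if g not in adata.var_names]
    if missing:
        raise ValueError(f"genes not in matrix: {missing[:5]}")
    if condition is not None:
        sel = (adata.obs[CONDITION_KEY].astype(str) == condition).to_numpy()
        sub = adata[sel]
    else:
        sub = adata
    if sub.n_obs < 3:
        raise ValueError("need at least 3 cells for correlation")
    vals = np.asarray(sub[:, genes].layers[layer])

    # constant genes have zero rank variance: their pairs are recorded
    # as rho 0, p 1, and the correlation is computed on the rest
    constant = vals.max(axis=0) == vals.min(axis=0)
    k_all = len(genes)
    rho = np.zeros((k_all, k_all))
    p = np.ones((k_all, k_all))
    nc = np.flatnonzero(~constant)
    if nc.size == 2:
        r, pv = stats.spearmanr(vals[:, nc[0]], vals[:, nc[1]])
        rho[np.ix_(nc, nc)] = [[1.0, r], [r, 1.0]]
        p[np.ix_(nc, nc)] = [[0.0, pv], [pv, 0.0]]
    elif nc.size > 2:
        r, pv = stats.spearmanr(vals[:, nc])
        rho[np.ix_(nc, nc)] = np.asarray(r)
        p[np.ix_(nc, nc)] = np.asarray(pv)
    rho[np.isnan(rho)] = 0.0
    p[np.isnan(p)] = 1.0
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)

    masked = mask_correlations(rho, p, mask_p)
    idx = pd.Index(genes)
    return MaskedCorrelationMatrix(
        genes=genes,
        rho=pd.DataFrame(rho, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        rho_masked=pd.DataFrame(masked, index=idx, columns=idx),
        constant_genes=[genes[k] for k in np.flatnonzero(constant)],
        mask_p=mask_p,
    )


@dataclass
class NoiseTable:
    """Per-gene, per-condition expression noise.

    ``table`` holds mean, variance (population, ddof=0) and Fano factor
    (NaN where the mean is 0) on size-factor-scaled linear counts.
    ``delta`` holds, for each UCG, fano(costim) - fano(own single
    stimulus); genes with an undefined Fano in either condition are
    excluded.
    """

    table: pd.DataFrame
    delta: pd.DataFrame


def fano_table(
    adata: ad.AnnData,
    programs: ProgramSets | None = None,
    conditions: Iterable[str] | None = None,
    costim_condition: str = "costim",
    stim_conditions: tuple[str, str] = ("stimA", "stimB"),
) -> NoiseTable:
    """Fano factor (variance / mean) per gene and condition.

    Moments are computed over all cells of a condition as a population
    (ddof = 0) on counts divided by the per-cell size factor, keeping the
    Poisson calibration (Fano = 1) of the linear scale.
    """
    if "size_factor" not in adata.obs:
        raise ValueError("run normalize() first (size factors missing)")
    X = adata.X
    counts = np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X, float)
    scaled = counts / adata.obs["size_factor"].to_numpy()[:, None]
    cond = adata.obs[CONDITION_KEY].astype(str)
    conditions = list(conditions) if conditions is not None else sorted(cond.unique())

    rows = []
    fano_by_cond: dict[str, pd.Series] = {}
    for c in conditions:
        sel = (cond == c).to_numpy()
        if not sel.any():
            raise ValueError(f"condition {c!r} has no cells")
        sub = scaled[sel]
        mean = sub.mean(axis=0)
        var = sub.var(axis=0, ddof=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            fano = np.where(mean > 0, var / mean, np.nan)
        fano_by_cond[c] = pd.Series(fano, index=adata.var_names)
        for g, m, v, f in zip(adata.var_names, mean, var, fano):
            rows.append((g, c, m, v, f))
    table = pd.DataFrame(rows, columns=["gene", "condition", "mean", "variance", "fano"])

    delta_rows = []
    if programs is not None and costim_condition in fano_by_cond:
        for stim, ucg, prog in zip(
            stim_conditions, (programs.ucg_a, programs.ucg_b), ("A", "B")
        ):
            if stim not in fano_by_cond:
                continue
            for g in sorted(ucg):
                f_costim = fano_by_cond[costim_condition].get(g, np.nan)
                f_stim = fano_by_cond[stim].get(g, np.nan)
                if np.isnan(f_costim) or np.isnan(f_stim):
                    continue
                delta_rows.append((g, prog, f_costim, f_stim, f_costim - f_stim))
    delta = pd.DataFrame(
        delta_rows,
        columns=["gene", "program", "fano_costim", "fano_single", "delta_fano"],
    )
    return NoiseTable(table=table, delta=delta)


def rank_noise_shifts(
    noise: NoiseTable,
    programs: ProgramSets,
    top_k: int | None = None,
) -> dict[str, list[str]]:
    """Inhibited UCGs per program, sorted by descending delta Fano.

    The sort is stable, so equal shifts keep their input order. Returns
    {'A': [...], 'B': [...]} truncated to ``top_k`` when given.
    """
    inhibited = programs.cross_inhibited_ucgs()
    out: dict[str, list[str]] = {}
    for prog in ("A", "B"):
        sub = noise.delta[
            (noise.delta["program"] == prog) & noise.delta["gene"].isin(inhibited)
        ]
        ordered = sub.sort_values("delta_fano", ascending=False, kind="stable")
        genes = ordered["gene"].tolist()
        out[prog] = genes[:top_k] if top_k is not None else genes
    return out


def ucg_score(
    adata: ad.AnnData,
    ucg: Iterable[str],
    n_background: int = 50,
    seed: int = 0,
    layer: str = LOGNORM_LAYER,
) -> pd.Series:
    """Per-cell program score: mean normalized expression over the UCG set
    minus the mean over ``n_background * |ucg|`` background genes sampled
    uniformly (seeded, without replacement) from the non-UCG genes.

    With ``n_background = 0`` the score is the plain UCG mean. Gene sets
    are processed in sorted-name order so the result is invariant to the
    column order of the matrix.
    """
    ucg = sorted(set(ucg))
    if not ucg:
        raise ValueError("UCG set is empty")
    missing = [g for g in ucg if g not in adata.var_names]
    if missing:
        raise ValueError(f"UCG genes not in matrix: {missing[:5]}")
    vals = pd.DataFrame(
        np.asarray(adata.layers[layer]), index=adata.obs_names, columns=adata.var_names
    )
    # contiguous copies pin the summation order, so scores are
    # bit-identical under any column permutation of the input
    score = np.ascontiguousarray(vals[ucg].to_numpy(float)).mean(axis=1)
    if n_background > 0:
        pool = sorted(set(adata.var_names) - set(ucg))
        if not pool:
            raise ValueError("no background genes available")
        rng = np.random.default_rng(seed)
        n_bg = min(n_background * len(ucg), len(pool))
        bg = sorted(rng.choice(pool, size=n_bg, replace=False).tolist())
        score = score - np.ascontiguousarray(vals[bg].to_numpy(float)).mean(axis=1)
    return pd.Series(score, index=adata.obs_names, name="ucg_score")


def program_scores(
    adata: ad.AnnData,
    programs: ProgramSets,
    n_background: int = 50,
    seed: int = 0,
    condition: str | None = "costim",
) -> pd.DataFrame:
    """score_A / score_B per cell (by default the co-stimulated cells)."""
    if condition is not None:
        sel = (adata.obs[CONDITION_KEY].astype(str) == condition).to_numpy()
        sub = adata[sel]
    else:
        sub = adata
    return pd.DataFrame(
        {
            "score_A": ucg_score(sub, programs.ucg_a, n_background, seed),
            "score_B": ucg_score(sub, programs.ucg_b, n_background, seed + 1),
        }
    )
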