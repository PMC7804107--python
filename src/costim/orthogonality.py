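"""Orthogonal (mutually exclusive) expression via masked odds ratios.

Expression or secretion is binarized per feature, and for every feature
pair a 2x2 contingency table of joint calls is built. The odds ratio
OR = (n11 * n00) / (n10 * n01) compares the odds of being positive for A
when B is positive versus when B is absent; log2(OR) < 0 means the
presence of one feature makes the other less likely — orthogonal
expression. Entries whose two-sided Fisher exact p-value exceeds 0.05
are masked to 0, as in the heatmap convention.

A Haldane-Anscombe 0.5 correction is applied to all four cells whenever
any cell is zero, keeping log2(OR) finite for display and masking; the
Fisher p-value is always computed on the uncorrected table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats

from .core_programs import ProgramSets


@dataclass
class BinaryMatrix:
    """Boolean cells/wells x features matrix with the per-feature
    threshold used and the data provenance ('rna' or 'secretion')."""

    values: pd.DataFrame
    thresholds: pd.Series
    provenance: str

    def __post_init__(self) -> None:
        if not all(self.values.dtypes == bool):
            self.values = self.values.astype(bool)
        missing = [c for c in self.values.columns if c not in self.thresholds.index]
        if missing:
            raise ValueError(f"thresholds missing for features: {missing[:5]}")


def binarize(
    values: pd.DataFrame,
    threshold,
    strict: bool = False,
    provenance: str = "rna",
) -> BinaryMatrix:
    """Binarize a value matrix at per-feature (or scalar) thresholds.

    ``strict=False`` calls positive at value >= threshold (the RNA
    convention, positive iff count >= 2); ``strict=True`` requires
    value > threshold (the secretion convention, since the threshold
    percentile itself is background).
    """
    if np.isscalar(threshold):
        thr = pd.Series(float(threshold), index=values.columns)
    else:
        thr = pd.Series(threshold).reindex(values.columns)
        if thr.isna().any():
            raise ValueError("threshold missing for some features")
    if not np.all(np.isfinite(thr.to_numpy())):
        raise ValueError("thresholds must be finite")
    pos = values.gt(thr, axis=1) if strict else values.ge(thr, axis=1)
    return BinaryMatrix(values=pos, thresholds=thr, provenance=provenance)


def binarize_counts(adata: ad.AnnData, threshold: float = 2.0) -> BinaryMatrix:
    """Binarize UMI counts: a gene is 'expressed' in a cell at >= 2
    detected transcripts (inclusive threshold)."""
    X = adata.X
    counts = np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)
    df = pd.DataFrame(counts, index=adata.obs_names, columns=adata.var_names)
    return binarize(df, threshold, strict=False, provenance="rna")


@dataclass
class OddsRatioResult:
    """Pairwise log2 odds ratios with Fisher masking.

    ``tables`` maps (feature_i, feature_j) with i < j in ``features``
    order to the uncorrected (n11, n10, n01, n00); ``correction_applied``
    flags pairs where the Haldane-Anscombe correction produced the ratio.
    """

    features: list[str]
    log2_or: pd.DataFrame
    p: pd.DataFrame
    log2_or_masked: pd.DataFrame
    tables: dict[tuple[str, str], tuple[int, int, int, int]]
    correction_applied: pd.DataFrame
    mask_p: float = 0.05

    def to_long(self) -> pd.DataFrame:
        rows = []
        for (fi, fj), (n11, n10, n01, n00) in self.tables.items():
            rows.append(
                (
                    fi, fj, n11, n10, n01, n00,
                    2.0 ** self.log2_or.loc[fi, fj],
                    self.log2_or.loc[fi, fj],
                    self.p.loc[fi, fj],
                    self.log2_or_masked.loc[fi, fj],
                    bool(self.correction_applied.loc[fi, fj]),
                )
            )
        return pd.DataFrame(
            rows,
            columns=["feature_i", "feature_j", "n11", "n10", "n01", "n00",
                     "odds_ratio", "log2_or", "p", "log2_or_masked", "corrected"],
        )


def odds_ratio_from_table(
    n11: int, n10: int, n01: int, n00: int
) -> tuple[float, bool]:
    """(OR, corrected): Haldane-Anscombe 0.5 added to all four cells when
    any cell is zero, so the ratio is always finite and nonzero."""
    cells = np.array([n11, n10, n01, n00], dtype=float)
    corrected = bool((cells == 0).any())
    if corrected:
        cells = cells + 0.5
    a, b, c, d = cells
    return (a * d) / (b * c), corrected


def pairwise_odds_ratios(
    binary: BinaryMatrix | pd.DataFrame,
    features: Sequence[str] | None = None,
    mask_p: float = 0.05,
) -> OddsRatioResult:
    """log2 odds-ratio matrix over all feature pairs with Fisher masking.

    The two-sided Fisher exact p (on the uncorrected table) masks
    log2(OR) to 0 where p > ``mask_p``. The diagonal is 0.
    """
    if isinstance(binary, pd.DataFrame):
        binary = BinaryMatrix(
            values=binary.astype(bool),
            thresholds=pd.Series(np.nan, index=binary.columns),
            provenance="unknown",
        )
    feats = list(features) if features is not None else list(binary.values.columns)
    missing = [f for f in feats if f not in binary.values.columns]
    if missing:
        raise ValueError(f"features not in binary matrix: {missing[:5]}")
    if len(feats) < 2:
        raise ValueError("need at least 2 features")
    B = binary.values[feats].to_numpy(bool)
    n = B.shape[0]
    if n < 1:
        raise ValueError("need at least 1 observation")

    Bi = B.astype(np.int64)
    n11 = Bi.T @ Bi
    s = Bi.sum(axis=0)
    n10 = s[:, None] - n11
    n01 = s[None, :] - n11
    n00 = n - n11 - n10 - n01

    k = len(feats)
    log2_or = np.zeros((k, k))
    pmat = np.zeros((k, k))
    corrected = np.zeros((k, k), dtype=bool)
    tables: dict[tuple[str, str], tuple[int, int, int, int]] = {}
    for i in range(k):
        for j in range(i + 1, k):
            tab = (int(n11[i, j]), int(n10[i, j]), int(n01[i, j]), int(n00[i, j]))
            tables[(feats[i], feats[j])] = tab
            orr, corr = odds_ratio_from_table(*tab)
            _, pv = stats.fisher_exact(
                [[tab[0], tab[1]], [tab[2], tab[3]]], alternative="two-sided"
            )
            log2_or[i, j] = log2_or[j, i] = np.log2(orr)
            pmat[i, j] = pmat[j, i] = pv
            corrected[i, j] = corrected[j, i] = corr

    masked = np.where(pmat <= mask_p, log2_or, 0.0)
    idx = pd.Index(feats)
    return OddsRatioResult(
        features=feats,
        log2_or=pd.DataFrame(log2_or, index=idx, columns=idx),
        p=pd.DataFrame(pmat, index=idx, columns=idx),
        log2_or_masked=pd.DataFrame(masked, index=idx, columns=idx),
        tables=tables,
        correction_applied=pd.DataFrame(corrected, index=idx, columns=idx),
        mask_p=mask_p,
    )


def orthogonal_pairs(
    or_result: OddsRatioResult,
    programs: ProgramSets | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Feature pairs with a significant negative log2 odds ratio.

    When program sets are supplied, each pair is annotated within-program
    vs cross-program (based on UCG/shared membership) and the summary
    counts both classes.
    """

    def membership(g: str) -> str:
        if programs is None:
            return "unknown"
        if g in programs.ucg_a:
            return "A"
        if g in programs.ucg_b:
            return "B"
        if g in programs.shared:
            return "shared"
        return "other"

    rows = []
    for (fi, fj), _tab in or_result.tables.items():
        v = or_result.log2_or_masked.loc[fi, fj]
        if v < 0:
            mi, mj = membership(fi), membership(fj)
            if {mi, mj} == {"A", "B"}:
                klass = "cross-program"
            elif mi == mj and mi in ("A", "B"):
                klass = "within-program"
            else:
                klass = "other"
            rows.append((fi, fj, v, or_result.p.loc[fi, fj], mi, mj, klass))
    pairs = pd.DataFrame(
        rows,
        columns=["feature_i", "feature_j", "log2_or_masked", "p",
                 "program_i", "program_j", "pair_class"],
    )
    summary = {
        "cross-program": int((pairs["pair_class"] == "cross-program").sum()) if len(pairs) else 0,
        "within-program": int((pairs["pair_class"] == "within-program").sum()) if len(pairs) else 0,
        "other": int((pairs["pair_class"] == "other").sum()) if len(pairs) else 0,
    }
    return pairs, summary
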