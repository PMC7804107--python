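"""Synthetic count matrices and secretion chips with planted ground truth.

Two generators back the whole test surface of the package:

``generate_counts``
    Negative-binomial UMI counts for four conditions (control, stimA, stimB,
    costim) with two partially overlapping stimulus-induced gene programs.
    Co-stimulated cells are a mixture of A-dominant, B-dominant and mixed
    cells; in dominant cells the opposing program is attenuated by a
    per-gene cross-inhibition factor. Dropout is not modeled separately:
    NB sampling at low baseline means produces the zero inflation that the
    downstream binarization and odds-ratio stages rely on.

``generate_chip``
    Microwell secretion chips: Poisson cell loading (a majority of wells
    empty), a smooth separable spatial background drift, Gaussian read
    noise, and planted secretor profiles, optionally with analyte pairs
    forced to be mutually exclusive across profiles.

Both are deterministic given their seed (byte-identical output) and return
a truth object recording each cell's / well's planted state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd

from .secretion import SecretionChip

CONDITIONS = ("control", "stimA", "stimB", "costim")
#: co-stimulated substates, in the order of ``costim_fractions``
COSTIM_STATES = ("costim:A-dominant", "costim:B-dominant", "costim:mixed")

DEFAULT_ANALYTES = ("TNF", "CCL5", "IL6", "IL12p40", "Chi3l3")


@dataclass(frozen=True)
class SecretorProfile:
    """A planted secretion phenotype: per-analyte signal means (a.f.u.)
    and the fraction of occupied wells carrying it."""

    name: str
    signal: Mapping[str, float]
    fraction: float


#: Default profile panel: three inflammatory-type profiles, one resolving,
#: one mixed, remainder silent — mirroring the qualitative structure of a
#: co-stimulated macrophage secretion experiment. IL6 and Chi3l3 never
#: co-occur in a profile (the planted orthogonal pair).
DEFAULT_PROFILES = (
    SecretorProfile("inflammatory_full", {"IL6": 1500.0, "IL12p40": 1200.0, "TNF": 900.0, "CCL5": 700.0}, 0.15),
    SecretorProfile("inflammatory_il12", {"IL12p40": 1200.0, "TNF": 700.0}, 0.10),
    SecretorProfile("tnf_ccl5", {"TNF": 900.0, "CCL5": 800.0}, 0.10),
    SecretorProfile("resolving", {"Chi3l3": 1600.0, "CCL5": 300.0}, 0.15),
    SecretorProfile("mixed", {"Chi3l3": 800.0, "TNF": 600.0, "CCL5": 500.0}, 0.10),
)


@dataclass(frozen=True)
class CountSimParams:
    """Parameters of the NB count generator.

    ``dispersion`` is the NB shape: variance = mu + mu**2 / dispersion.
    ``costim_fractions`` are (A-dominant, B-dominant, mixed) and must sum
    to 1. ``cross_inhibition`` multiplies the *induced excess* of the
    opposing program in dominant cells: the opposing program mean becomes
    baseline * (1 + (fold - 1) * cross_inhibition), so 1 means no
    inhibition and 0 full silencing back to baseline.
    """

    n_cells_per_condition: int = 1500
    n_genes: int = 1000
    n_program_genes_a: int = 200
    n_program_genes_b: int = 200
    n_shared_genes: int = 50
    baseline_mean: float = 0.5
    induction_fold_a: float = 4.0
    induction_fold_b: float = 4.0
    dispersion: float = 0.5
    costim_fractions: tuple[float, float, float] = (0.45, 0.45, 0.10)
    cross_inhibition: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_cells_per_condition", "n_genes", "n_program_genes_a",
                     "n_program_genes_b", "n_shared_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        n_special = self.n_program_genes_a + self.n_program_genes_b + self.n_shared_genes
        if n_special > self.n_genes:
            raise ValueError(
                f"program blocks ({n_special} genes) exceed n_genes={self.n_genes}"
            )
        for name in ("baseline_mean", "dispersion"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive, got {v}")
        for name in ("induction_fold_a", "induction_fold_b"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 1:
                raise ValueError(f"{name} must be finite and >= 1, got {v}")
        f = self.costim_fractions
        if len(f) != 3 or any(x < 0 for x in f):
            raise ValueError("costim_fractions must be 3 non-negative reals")
        if abs(sum(f) - 1.0) > 1e-9:
            raise ValueError(f"costim_fractions must sum to 1, got {sum(f)}")
        if not 0.0 <= self.cross_inhibition <= 1.0:
            raise ValueError("cross_inhibition must lie in [0, 1]")


@dataclass
class CountTruth:
    """Planted ground truth for a simulated count matrix."""

    cell_states: pd.Series  # cell_id -> state label
    gene_programs: pd.Series  # gene_id -> {A, B, shared, background}
    expected_fold: pd.DataFrame  # genes x states, mean fold over baseline


def _gene_programs(p: CountSimParams) -> pd.Series:
    labels = np.array(["background"] * p.n_genes, dtype=object)
    a, b, s = p.n_program_genes_a, p.n_program_genes_b, p.n_shared_genes
    labels[:a] = "A"
    labels[a:a + b] = "B"
    labels[a + b:a + b + s] = "shared"
    genes = [f"gene{i:04d}" for i in range(p.n_genes)]
    return pd.Series(labels, index=genes, name="program")


def _state_fold(p: CountSimParams, state: str) -> np.ndarray:
    """Per-gene fold over baseline for one cell state."""
    prog = _gene_programs(p).to_numpy()
    fold = np.ones(p.n_genes)
    fa, fb = p.induction_fold_a, p.induction_fold_b
    shared_fold = math.sqrt(fa * fb)  # geometric mean of the two inductions
    inhibited_a = 1.0 + (fa - 1.0) * p.cross_inhibition
    inhibited_b = 1.0 + (fb - 1.0) * p.cross_inhibition
    if state == "control":
        return fold
    if state == "stimA":
        fold[prog == "A"] = fa
        fold[prog == "shared"] = shared_fold
    elif state == "stimB":
        fold[prog == "B"] = fb
        fold[prog == "shared"] = shared_fold
    elif state == "costim:A-dominant":
        fold[prog == "A"] = fa
        fold[prog == "B"] = inhibited_b
        fold[prog == "shared"] = shared_fold
    elif state == "costim:B-dominant":
        fold[prog == "A"] = inhibited_a
        fold[prog == "B"] = fb
        fold[prog == "shared"] = shared_fold
    elif state == "costim:mixed":
        fold[prog == "A"] = fa
        fold[prog == "B"] = fb
        fold[prog == "shared"] = shared_fold
    else:  # pragma: no cover - guarded by callers
        raise ValueError(f"unknown state {state!r}")
    return fold


def expected_means(params: CountSimParams) -> pd.DataFrame:
    """True NB means (genes x states) implied by the parameters."""
    params.validate()
    genes = _gene_programs(params).index
    states = ("control", "stimA", "stimB") + COSTIM_STATES
    data = {s: params.baseline_mean * _state_fold(params, s) for s in states}
    return pd.DataFrame(data, index=genes)


def _largest_remainder_counts(fractions: Sequence[float], n: int) -> np.ndarray:
    """Integer counts summing to n, proportional to fractions (largest
    remainder rule) — keeps planted mixture fractions exact."""
    raw = np.asarray(fractions, dtype=float) * n
    base = np.floor(raw).astype(int)
    short = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base


def generate_counts(params: CountSimParams) -> tuple[ad.AnnData, CountTruth]:
    """Draw a four-condition UMI count matrix with planted programs.

    Returns an :class:`anndata.AnnData` (cells x genes, integer counts in
    ``.X``, ``obs['condition']`` and ``obs['true_state']``, per-gene program
    membership in ``var['program']``) and the matching :class:`CountTruth`.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_cells_per_condition

    # per-cell states; costim substates assigned exactly then shuffled
    states: list[str] = (["control"] * n + ["stimA"] * n + ["stimB"] * n)
    sub_counts = _largest_remainder_counts(params.costim_fractions, n)
    costim_states = np.repeat(np.array(COSTIM_STATES, dtype=object), sub_counts)
    costim_states = rng.permutation(costim_states)
    states.extend(costim_states.tolist())
    state_arr = np.asarray(states, dtype=object)

    counts = np.empty((len(state_arr), params.n_genes), dtype=np.int64)
    r = params.dispersion
    for state in ("control", "stimA", "stimB") + COSTIM_STATES:
        idx = np.flatnonzero(state_arr == state)
        if idx.size == 0:
            continue
        mu = params.baseline_mean * _state_fold(params, state)
        p_nb = r / (r + mu)
        counts[idx] = rng.negative_binomial(r, p_nb, size=(idx.size, params.n_genes))

    programs = _gene_programs(params)
    cell_ids = [f"cell{i:05d}" for i in range(len(state_arr))]
    condition = np.where(
        np.char.startswith(state_arr.astype(str), "costim"), "costim", state_arr
    ).astype(object)

    adata = ad.AnnData(
        X=counts,
        obs=pd.DataFrame(
            {"condition": pd.Categorical(condition, categories=CONDITIONS),
             "true_state": state_arr},
            index=cell_ids,
        ),
        var=pd.DataFrame({"program": programs.to_numpy()}, index=programs.index),
    )
    adata.uns["sim_params"] = asdict(params)

    truth = CountTruth(
        cell_states=pd.Series(state_arr, index=cell_ids, name="true_state"),
        gene_programs=programs,
        expected_fold=pd.DataFrame(
            {s: _state_fold(params, s) for s in ("stimA", "stimB") + COSTIM_STATES},
            index=programs.index,
        ),
    )
    return adata, truth


@dataclass(frozen=True)
class ChipSimParams:
    """Parameters of the microwell secretion-chip generator.

    ``background_drift_amplitude`` scales a smooth separable polynomial in
    the (row, col) coordinates; ``background_noise_sd`` is i.i.d. Gaussian
    read noise. ``secretor_profiles`` mixing fractions apply to *occupied*
    wells; the remainder are silent. ``exclusivity_pairs`` are validated:
    no profile may carry signal for both members of a pair.
    """

    n_wells: int = 5000
    grid_shape: tuple[int, int] = (50, 100)
    mean_cells_per_well: float = 0.5
    analytes: tuple[str, ...] = DEFAULT_ANALYTES
    background_drift_amplitude: float = 200.0
    background_noise_sd: float = 20.0
    secretor_profiles: tuple[SecretorProfile, ...] = DEFAULT_PROFILES
    exclusivity_pairs: tuple[tuple[str, str], ...] = (("IL6", "Chi3l3"),)
    seed: int = 0

    def validate(self) -> None:
        rows, cols = self.grid_shape
        if rows * cols != self.n_wells:
            raise ValueError(
                f"grid_shape {self.grid_shape} holds {rows * cols} wells, "
                f"but n_wells={self.n_wells}"
            )
        if self.mean_cells_per_well < 0:
            raise ValueError("mean_cells_per_well must be >= 0")
        if self.background_drift_amplitude < 0 or self.background_noise_sd < 0:
            raise ValueError("drift amplitude and noise sd must be >= 0")
        total = 0.0
        for prof in self.secretor_profiles:
            if not 0 <= prof.fraction:
                raise ValueError(f"profile {prof.name}: negative fraction")
            total += prof.fraction
            for analyte, mean in prof.signal.items():
                if analyte not in self.analytes:
                    raise ValueError(
                        f"profile {prof.name} references unknown analyte {analyte!r}"
                    )
                if mean < 0:
                    raise ValueError(f"profile {prof.name}: negative signal mean")
        if total > 1.0 + 1e-9:
            raise ValueError(f"profile fractions sum to {total} > 1")
        for x, y in self.exclusivity_pairs:
            for prof in self.secretor_profiles:
                if prof.signal.get(x, 0.0) > 0 and prof.signal.get(y, 0.0) > 0:
                    raise ValueError(
                        f"profile {prof.name} violates exclusivity pair ({x}, {y})"
                    )


@dataclass
class ChipTruth:
    """Planted per-well truth: profile name, 'silent' (occupied, no
    secretion) or 'empty' (zero-cell)."""

    well_profiles: pd.Series


def generate_chip(params: ChipSimParams) -> tuple[SecretionChip, ChipTruth]:
    """Simulate a secretion chip: Poisson loading, smooth drift, noise,
    and planted secretor signal with per-well gamma brightness jitter."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    rows, cols = params.grid_shape
    n = params.n_wells
    analytes = list(params.analytes)

    row = np.repeat(np.arange(rows), cols)
    col = np.tile(np.arange(cols), rows)
    cell_count = rng.poisson(params.mean_cells_per_well, size=n)

    # separable low-order polynomial drift over the array
    r_frac = row / max(rows - 1, 1)
    c_frac = col / max(cols - 1, 1)
    drift = params.background_drift_amplitude * 0.5 * (r_frac**2 + c_frac**2)

    intensity = drift[:, None] + rng.normal(
        0.0, params.background_noise_sd, size=(n, len(analytes))
    )

    # profile assignment for occupied wells
    profiles = np.array(["empty"] * n, dtype=object)
    occupied = cell_count >= 1
    u = rng.random(n)
    edges = np.cumsum([p.fraction for p in params.secretor_profiles])
    profiles[occupied] = "silent"
    for i, prof in enumerate(params.secretor_profiles):
        lo = edges[i - 1] if i else 0.0
        sel = occupied & (u >= lo) & (u < edges[i])
        profiles[sel] = prof.name
        n_sel = int(sel.sum())
        if n_sel == 0:
            continue
        for j, analyte in enumerate(analytes):
            mean = prof.signal.get(analyte, 0.0)
            if mean > 0:
                # gamma(k=10) jitter: mean preserved, CV ~= 0.32
                intensity[sel, j] += mean * rng.gamma(10.0, 0.1, size=n_sel)

    wells = pd.DataFrame(
        {
            "well_id": [f"well{i:05d}" for i in range(n)],
            "row": row,
            "col": col,
            "cell_count": cell_count,
        }
    )
    for j, analyte in enumerate(analytes):
        wells[analyte] = intensity[:, j]

    chip = SecretionChip(wells=wells, analytes=analytes)
    truth = ChipTruth(
        well_profiles=pd.Series(profiles, index=wells["well_id"].to_numpy(),
                                name="profile")
    )
    return chip, truth
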