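"""Generative model of a GPS-peptidome stability screen.

The simulator produces everything the analysis stack consumes, with known
ground truth, so the whole pipeline (gate counts -> PSI -> labels -> model
training) can be exercised and validated offline:

1. A library of random 17-mers drawn from a yeast-like residue background.
2. Each tile's true degron probability from a chosen 20-weight composition
   model (default: the Kyte-Doolittle scale as weights, so hydrophobic
   tiles are degrons), mapped monotonically to a mean GFP/control
   fluorescence ratio (linear, 1.0 at P=0 down to 0.2 at P=1; only
   monotonicity matters for rank-based checks).
3. Per-cell ratios = tile mean x lognormal noise; the pooled cells are cut
   at the 25/50/75% quantiles into four equal-occupancy gates, mirroring an
   equal-cell-number sort.
4. Per-gate sequencing reads drawn multinomially over tiles proportional to
   gate occupancy.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .degron_model import DegronModel, predict_compositions
from .psi_screen import GATE_COLUMNS, GateCountTable
from .seqcore import AMINO_ACIDS, KD_VECTOR, TILE_LENGTH

logger = logging.getLogger("degronscan")

#: Approximate S. cerevisiae proteome amino-acid frequencies (ordered as
#: AMINO_ACIDS); normalized at use.
YEAST_BACKGROUND = np.array([
    0.055,  # A
    0.013,  # C
    0.058,  # D
    0.065,  # E
    0.045,  # F
    0.050,  # G
    0.022,  # H
    0.066,  # I
    0.073,  # K
    0.096,  # L
    0.021,  # M
    0.061,  # N
    0.044,  # P
    0.039,  # Q
    0.044,  # R
    0.090,  # S
    0.059,  # T
    0.056,  # V
    0.010,  # W
    0.034,  # Y
])


@dataclass
class SimConfig:
    """Study-condition knobs for the simulated screen."""

    n_tiles: int = 20_000
    true_weights: np.ndarray | str = "kd"   # 20 values or the "kd" preset
    cells_per_tile: int = 100
    sigma: float = 0.3                      # lognormal noise on the ratio
    reads_per_gate: int | None = None       # default: 25 * n_tiles (~100/tile)
    ratio_at_p0: float = 1.0
    ratio_at_p1: float = 0.2
    gate_quantiles: tuple = (0.25, 0.50, 0.75)
    background: np.ndarray | None = None    # residue distribution (20 values)
    seed: int = 0

    def resolved_weights(self) -> np.ndarray:
        if isinstance(self.true_weights, str):
            if self.true_weights != "kd":
                raise ValueError(f"unknown preset {self.true_weights!r}")
            return KD_VECTOR.copy()
        w = np.asarray(self.true_weights, dtype=float)
        if w.shape != (20,):
            raise ValueError("true_weights must have 20 entries")
        return w

    def resolved_background(self) -> np.ndarray:
        bg = YEAST_BACKGROUND if self.background is None else np.asarray(
            self.background, dtype=float)
        return bg / bg.sum()

    def resolved_reads_per_gate(self) -> int:
        return (25 * self.n_tiles if self.reads_per_gate is None
                else self.reads_per_gate)

    def __post_init__(self) -> None:
        if self.n_tiles <= 0 or self.cells_per_tile <= 0:
            raise ValueError("counts must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass
class SimTruth:
    """Ground truth of one simulated library."""

    sequences: list[str]
    probabilities: np.ndarray      # true degron probability per tile
    mean_ratios: np.ndarray        # true mean fluorescence ratio per tile
    occupancy: np.ndarray | None = None  # (n_tiles, 4) cells per gate
    config: SimConfig | None = None
    seed: int = 0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "peptide_id": [f"tile{i:06d}" for i in range(len(self.sequences))],
            "sequence": self.sequences,
            "true_probability": self.probabilities,
            "true_mean_ratio": self.mean_ratios,
        })
        if self.occupancy is not None:
            for g, col in enumerate(GATE_COLUMNS):
                df[f"occupancy_{col}"] = self.occupancy[:, g]
        return df


def simulate_library(config: SimConfig) -> SimTruth:
    """Draw random tiles and compute their true stabilities."""
    rng = np.random.default_rng(config.seed)
    bg = config.resolved_background()
    w = config.resolved_weights()
    alphabet = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")
    draws = rng.choice(len(AMINO_ACIDS), size=(config.n_tiles, TILE_LENGTH),
                       p=bg)
    sequences = [
        alphabet[row].tobytes().decode() for row in draws
    ]
    # composition from the index draws directly (fast path)
    comp = np.zeros((config.n_tiles, 20))
    for a in range(20):
        comp[:, a] = (draws == a).sum(axis=1) / TILE_LENGTH
    probs = 1.0 / (1.0 + np.exp(-(comp @ w)))
    ratios = config.ratio_at_p0 + (config.ratio_at_p1 - config.ratio_at_p0) * probs
    return SimTruth(sequences=sequences, probabilities=probs,
                    mean_ratios=ratios, config=config, seed=config.seed)


def simulate_sort(truth: SimTruth, config: SimConfig | None = None,
                  strain: str = "control") -> GateCountTable:
    """Sort simulated cells into four equal gates and sequence each gate.

    Each of a tile's cells gets ratio = true mean x lognormal(0, sigma);
    the pooled population is cut at the configured quantiles (default
    quartiles, i.e. equal cell numbers per gate). Reads per gate are
    multinomial over tiles proportional to gate occupancy. Updates
    ``truth.occupancy`` as a side effect.
    """
    config = config or truth.config
    if config is None:
        raise ValueError("simulate_sort needs a config")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n, m = config.n_tiles, config.cells_per_tile
    reads_per_gate = config.resolved_reads_per_gate()
    if reads_per_gate < n:
        logger.warning("simulate_sort: %d reads per gate < %d tiles; counts "
                       "will be sparse", reads_per_gate, n)
    if config.sigma > 0:
        noise = rng.lognormal(mean=0.0, sigma=config.sigma, size=(n, m))
    else:
        noise = np.ones((n, m))
    cells = truth.mean_ratios[:, None] * noise
    edges = np.quantile(cells, config.gate_quantiles)
    # gate index per cell: 0..3, lowest ratio = gate 1 (least stable)
    gate_of_cell = np.searchsorted(edges, cells, side="right")
    occupancy = np.zeros((n, 4), dtype=np.int64)
    for g in range(4):
        occupancy[:, g] = (gate_of_cell == g).sum(axis=1)
    truth.occupancy = occupancy

    counts = np.zeros((n, 4), dtype=np.int64)
    gate_totals = occupancy.sum(axis=0)
    for g in range(4):
        if gate_totals[g] == 0:
            continue
        p = occupancy[:, g] / gate_totals[g]
        counts[:, g] = rng.multinomial(reads_per_gate, p)
    df = pd.DataFrame({
        "peptide_id": [f"tile{i:06d}" for i in range(n)],
        "sequence": truth.sequences,
    })
    for g, col in enumerate(GATE_COLUMNS):
        df[col] = counts[:, g]
    return GateCountTable(counts=df, strain=strain)


def simulate_screen(config: SimConfig,
                    strain: str = "control") -> tuple[SimTruth, GateCountTable]:
    """Library generation plus sort in one call."""
    truth = simulate_library(config)
    return truth, simulate_sort(truth, config, strain=strain)


def inject_stabilization(psi_table: pd.DataFrame, peptide_ids,
                         delta: float,
                         psi_max: float = 4.0) -> pd.DataFrame:
    """Shift the PSI of selected peptides upward (a knockout phenocopy).

    Knockout biology is not modeled mechanistically; stabilization enters
    as a user-specified PSI offset, clipped to the PSI scale.
    """
    out = psi_table.copy()
    mask = out["peptide_id"].isin(set(peptide_ids))
    out.loc[mask, "psi"] = np.minimum(out.loc[mask, "psi"] + delta, psi_max)
    return out


def recovery_report(truth: SimTruth, model: DegronModel | None,
                    psi_table: pd.DataFrame,
                    prob_cutoff: float = 0.85) -> dict:
    """How well the pipeline recovered the simulation's ground truth.

    Reports the Pearson correlation between true and fitted weights, the
    Spearman correlation between PSI and the true mean ratio (both measure
    stability, so it should be strongly positive), and the sensitivity /
    specificity of the fitted model's degron calls against the true ones at
    the probability cutoff. With no true degrons, sensitivity is reported
    as None rather than a number.
    """
    config = truth.config
    report: dict = {"n_tiles": len(truth.sequences), "seed": truth.seed}

    truth_df = truth.to_frame().set_index("peptide_id")
    shared = psi_table.loc[psi_table["peptide_id"].isin(truth_df.index)]
    ref = truth_df.loc[shared["peptide_id"], "true_mean_ratio"]
    if shared["psi"].nunique() > 1 and ref.nunique() > 1:
        rho = stats.spearmanr(shared["psi"], ref)
        report["psi_truth_spearman"] = float(rho.statistic)
    else:
        report["psi_truth_spearman"] = None   # constant input, undefined

    if model is not None and config is not None:
        w_true = config.resolved_weights()
        if np.ptp(w_true) > 0 and np.ptp(model.weights) > 0:
            r = stats.pearsonr(w_true, model.weights)
            report["weight_recovery_pearson"] = float(r.statistic)
        else:
            report["weight_recovery_pearson"] = None

        from .seqcore import composition_matrix
        X = composition_matrix(truth.sequences)
        pred = predict_compositions(model, X) >= prob_cutoff
        true_calls = truth.probabilities >= prob_cutoff
        tp = int((pred & true_calls).sum())
        fp = int((pred & ~true_calls).sum())
        fn = int((~pred & true_calls).sum())
        tn = int((~pred & ~true_calls).sum())
        report["degron_sensitivity"] = (tp / (tp + fn)
                                        if (tp + fn) else None)
        report["degron_specificity"] = (tn / (tn + fp)
                                        if (tn + fp) else None)
        report["confusion"] = {"tp": tp, "fp": fp, "fn": fn, "tn": tn}
    return report
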