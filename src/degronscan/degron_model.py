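"""Composition-based logistic degron predictor and proteome scanning.

The predictor assigns a 17-mer peptide a degron probability from its
amino-acid composition alone:

    P(degron | tile) = sigmoid( sum_a w_a * c_a )

with one weight w_a per amino acid and c_a the fraction of residue a in the
tile. There is no intercept: the fractions sum to 1, so an intercept is a
constant shift of all twenty weights and not identifiable. Because the
features are order-free, the model is exactly permutation-invariant — any
scramble of a peptide scores identically.

Training data come from a PSI screen: tiles with PSI < 2.2 are the degron
(unstable) class, tiles with PSI > 2.8 the non-degron class, and the
mid-band is excluded. The fit is L2-penalized maximum likelihood with the
penalty strength chosen by 5-fold cross-validation.

Whole proteins are scanned by scoring every 17-residue window and assigning
each window's probability to its center residue (the 9th); maximal runs of
center residues at or above the call cutoff (default 0.85) become degron
regions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .seqcore import (
    AMINO_ACIDS,
    KD_VECTOR,
    TILE_LENGTH,
    ProteinRecord,
    SequenceError,
    composition,
    composition_matrix,
)

logger = logging.getLogger("degronscan")

#: Degron-call probability cutoff.
PROB_CUTOFF = 0.85

#: Default L2 regularization grid. C is the PER-SAMPLE inverse penalty
#: strength: the objective is mean log-loss + ||w||^2 / (2 C n), so the fit
#: depends only on the empirical data distribution (duplicating the
#: training set leaves the estimate unchanged).
C_GRID = tuple(10.0 ** k for k in range(0, 7))

HALF_WINDOW = TILE_LENGTH // 2  # 8 residues on each side of a tile center


class ModelError(ValueError):
    pass


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass
class DegronModel:
    """Twenty per-amino-acid log-odds weights plus training metadata."""

    weights: np.ndarray
    n_unstable: int = 0
    n_stable: int = 0
    C: float = 1.0
    converged: bool = True
    training_digest: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (20,):
            raise ModelError(f"expected 20 weights, got {self.weights.shape}")

    def weight_table(self) -> pd.Series:
        return pd.Series(self.weights, index=list(AMINO_ACIDS), name="weight")

    def to_json(self, path) -> None:
        payload = {
            "model": "composition-logistic",
            "features": "amino-acid fractions (count / window length)",
            "intercept": 0.0,
            "weights": {aa: w for aa, w in zip(AMINO_ACIDS, self.weights)},
            "regularization": {"type": "l2", "C": self.C},
            "training": {
                "n_unstable": self.n_unstable,
                "n_stable": self.n_stable,
                "digest": self.training_digest,
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "DegronModel":
        with open(path) as fh:
            payload = json.load(fh)
        w = np.array([payload["weights"][aa] for aa in AMINO_ACIDS])
        tr = payload.get("training", {})
        return cls(
            weights=w,
            n_unstable=tr.get("n_unstable", 0),
            n_stable=tr.get("n_stable", 0),
            C=payload.get("regularization", {}).get("C", 1.0),
            training_digest=tr.get("digest", ""),
        )


@dataclass
class DegronProfile:
    """Per-residue degron probabilities and called regions for one protein.

    ``probabilities[i]`` is the probability assigned to residue i+1; it is
    NaN for the first and last 8 residues, where no 17-mer window is
    centered. Regions are maximal runs of defined residues at or above the
    cutoff, reported in 1-based inclusive center coordinates; the tile
    extent of a region reaches 8 residues beyond each end (clipped to the
    protein).
    """

    protein_id: str
    probabilities: np.ndarray
    regions: list[dict] = field(default_factory=list)
    cutoff: float = PROB_CUTOFF

    @property
    def length(self) -> int:
        return len(self.probabilities)

    def defined_range(self) -> tuple[int, int]:
        """1-based inclusive residue range with defined probabilities."""
        return HALF_WINDOW + 1, self.length - HALF_WINDOW

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "protein_id": self.protein_id,
            "residue_index": np.arange(1, self.length + 1),
            "probability": self.probabilities,
        })


def train(
    sequences,
    labels,
    C_grid=C_GRID,
    cv_folds: int = 5,
    cv_seed: int = 0,
    fit_intercept: bool = False,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> DegronModel:
    """Fit the 20-parameter logistic model on labeled tile sequences.

    Parameters
    ----------
    sequences
        Tile sequences (each length 17).
    labels
        1 for the unstable/degron class, 0 for stable; any boolean-like.
    C_grid
        Per-sample inverse L2 penalty strengths searched by stratified
        5-fold cross-validated log-loss; the grid's best C is refit on all
        data. The penalty is applied per sample (mean-loss convention), so
        the estimate depends only on the empirical distribution.
    fit_intercept
        Off by default (not identifiable with fractions summing to 1);
        available for sensitivity analysis.

    The fit is deterministic: lbfgs with a fixed fold seed and a tight
    gradient tolerance, no stochastic elements.
    """
    y = np.asarray(labels, dtype=int)
    sequences = list(sequences)
    if len(sequences) != len(y):
        raise ModelError("sequences and labels differ in length")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ModelError("training data contain a single class")
    bad = [s for s in sequences if len(s) != TILE_LENGTH]
    if bad:
        raise ModelError(
            f"{len(bad)} training tiles are not length {TILE_LENGTH} "
            f"(first: {bad[0]!r})"
        )
    X = composition_matrix(sequences)

    def fit_one(C: float, X_fit, y_fit) -> LogisticRegression:
        # per-sample penalty: sklearn's C is total-loss scaled, so divide
        # by the sample count to make the fit duplication-invariant
        return LogisticRegression(
            C=C / len(y_fit), fit_intercept=fit_intercept,
            solver="lbfgs", tol=tol, max_iter=max_iter,
        ).fit(X_fit, y_fit)

    best_C = float(C_grid[0])
    if len(C_grid) > 1:
        cv = StratifiedKFold(n_splits=cv_folds, shuffle=True,
                             random_state=cv_seed)
        best_loss = np.inf
        for C in C_grid:
            losses = []
            for train_idx, test_idx in cv.split(X, y):
                clf = fit_one(C, X[train_idx], y[train_idx])
                p = np.clip(clf.predict_proba(X[test_idx])[:, 1],
                            1e-12, 1 - 1e-12)
                losses.append(-np.mean(
                    y[test_idx] * np.log(p)
                    + (1 - y[test_idx]) * np.log(1 - p)
                ))
            mean_loss = float(np.mean(losses))
            if mean_loss < best_loss:
                best_loss, best_C = mean_loss, float(C)
        logger.info("train: selected C=%g (cv log-loss %.4f)", best_C, best_loss)

    clf = fit_one(best_C, X, y)
    if clf.n_iter_[0] >= max_iter:
        raise ModelError(
            f"logistic fit did not converge in {max_iter} iterations "
            f"(C={best_C}, n={len(y)})"
        )
    digest = hashlib.sha256(
        ("\n".join(sequences) + "\n" + "".join(map(str, y))).encode()
    ).hexdigest()[:16]
    return DegronModel(
        weights=clf.coef_[0],
        n_unstable=int((y == 1).sum()),
        n_stable=int((y == 0).sum()),
        C=best_C,
        converged=True,
        training_digest=digest,
    )


def predict(model: DegronModel, sequence: str) -> float:
    """Degron probability of a single 17-mer."""
    if len(sequence) != TILE_LENGTH:
        raise ModelError(
            f"predict expects a {TILE_LENGTH}-mer, got length {len(sequence)} "
            "(use region_score for longer peptides)"
        )
    return float(_sigmoid(composition(sequence) @ model.weights))


def predict_compositions(model: DegronModel, X: np.ndarray) -> np.ndarray:
    """Vectorized probability for pre-computed composition rows."""
    return _sigmoid(np.asarray(X) @ model.weights)


def region_score(model: DegronModel, sequence: str) -> float:
    """Mean probability over all 17-mer windows of a longer peptide.

    A length-L peptide has L-16 windows; for L = 23 the score averages 7
    window probabilities. At L = 17 this reduces to :func:`predict`.
    """
    L = len(sequence)
    if L < TILE_LENGTH:
        raise ModelError(f"region_score needs length >= {TILE_LENGTH}, got {L}")
    windows = [sequence[i:i + TILE_LENGTH] for i in range(L - TILE_LENGTH + 1)]
    return float(np.mean(predict_compositions(
        model, composition_matrix(windows))))


def scan(model: DegronModel, protein: ProteinRecord,
         cutoff: float = PROB_CUTOFF,
         inclusive: bool = True) -> DegronProfile:
    """Score every 17-mer of a protein and call degron regions.

    Each window's probability is assigned to its center residue
    (window start + 8); residues 1-8 and L-7..L remain undefined (NaN).
    Maximal runs of defined residues meeting the cutoff (``>=`` by default,
    ``>`` with ``inclusive=False``) become regions with their maximum
    probability and center residue (midpoint, ties to the N-terminal side).
    """
    L = len(protein)
    if L < TILE_LENGTH:
        raise SequenceError(
            f"{protein.id}: length {L} < window {TILE_LENGTH}"
        )
    seq = protein.sequence
    windows = [seq[i:i + TILE_LENGTH] for i in range(L - TILE_LENGTH + 1)]
    probs = predict_compositions(model, composition_matrix(windows))
    track = np.full(L, np.nan)
    track[HALF_WINDOW:HALF_WINDOW + len(probs)] = probs

    called = (probs >= cutoff) if inclusive else (probs > cutoff)
    regions: list[dict] = []
    i = 0
    while i < len(called):
        if called[i]:
            j = i
            while j + 1 < len(called) and called[j + 1]:
                j += 1
            start = i + HALF_WINDOW + 1          # 1-based center residue
            end = j + HALF_WINDOW + 1
            regions.append({
                "start": start,
                "end": end,
                "center": (start + end) // 2,
                "max_probability": float(probs[i:j + 1].max()),
                "tile_start": max(1, start - HALF_WINDOW),
                "tile_end": min(L, end + HALF_WINDOW),
            })
            i = j + 1
        else:
            i += 1
    return DegronProfile(protein_id=protein.id, probabilities=track,
                         regions=regions, cutoff=cutoff)


def scan_proteome(model: DegronModel, proteins,
                  cutoff: float = PROB_CUTOFF) -> dict[str, DegronProfile]:
    """Scan many proteins, skipping (with a log line) those shorter than 17."""
    profiles: dict[str, DegronProfile] = {}
    skipped = 0
    for rec in proteins:
        if len(rec) < TILE_LENGTH:
            skipped += 1
            continue
        profiles[rec.id] = scan(model, rec, cutoff=cutoff)
    if skipped:
        logger.info("scan_proteome: skipped %d proteins shorter than %d",
                    skipped, TILE_LENGTH)
    return profiles


def weight_hydrophobicity_correlation(model: DegronModel) -> dict:
    """Compare the learned weights with Kyte-Doolittle hydropathy.

    Degron potency tracks hydrophobicity, so a well-trained model's weights
    correlate positively with the KD scale. Returns Pearson and Spearman
    coefficients and the per-amino-acid table for plotting.
    """
    table = pd.DataFrame({
        "amino_acid": list(AMINO_ACIDS),
        "weight": model.weights,
        "kyte_doolittle": KD_VECTOR,
    })
    pearson = stats.pearsonr(model.weights, KD_VECTOR)
    spearman = stats.spearmanr(model.weights, KD_VECTOR)
    return {
        "pearson_r": float(pearson.statistic),
        "pearson_p": float(pearson.pvalue),
        "spearman_rho": float(spearman.statistic),
        "spearman_p": float(spearman.pvalue),
        "table": table,
    }


def mutate_and_rescore(model: DegronModel, sequence: str,
                       positions, replacement: str) -> tuple[float, float]:
    """Score a peptide before and after point substitutions.

    ``positions`` are 1-based residue indices all replaced by the single
    amino acid ``replacement``. Used for charge-insertion analyses (e.g.
    replacing hydrophobic residues with E or R suppresses a degron).
    """
    if len(replacement) != 1 or replacement not in AMINO_ACIDS:
        raise ModelError(f"replacement must be one amino acid, got {replacement!r}")
    letters = list(sequence)
    for pos in positions:
        if not 1 <= pos <= len(letters):
            raise ModelError(
                f"position {pos} out of range 1..{len(letters)}"
            )
        letters[pos - 1] = replacement
    return predict(model, sequence), predict(model, "".join(letters))
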