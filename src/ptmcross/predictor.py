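"""Group-based peptide-similarity prediction of tyrosine sulfation sites.

A candidate peptide ``PY(m, n)`` (m upstream and n downstream residues around
a tyrosine) is scored by its average substitution-matrix similarity to the
known positive peptides:

    S(c) = mean_p max(0, sum_i w_i * M[c_i, p_i])

where ``M`` is a symmetric substitution matrix (BLOSUM62 by default, with the
``'*'`` terminus-padding letter scoring 0 against everything) and ``w`` is a
non-negative per-position weight vector.  Training proceeds in three stages:
motif length selection (pick (m, n) maximising leave-one-out AROC), weight
training (hill-climbing on one position weight at a time), and matrix
mutation (hill-climbing on symmetric matrix entries); a step is kept only if
it strictly improves the leave-one-out AROC, so training can never make the
model worse under that criterion.

Score cutoffs for the high / medium / low prediction levels are calibrated
against target specificities (0.95 / 0.90 / 0.85) on the leave-one-out score
distribution, so the high-level prediction set is always nested inside
medium, and medium inside low.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .io import (
    ModSite,
    PAD,
    PeptideWindow,
    ProteinRecord,
    SiteDataset,
    extract_window,
    windows_for_sites,
)

#: Scoring alphabet: 20 residues, X for ambiguity, '*' for terminus padding.
ALPHABET = "ACDEFGHIKLMNPQRSTVWYX" + PAD
_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
N_LETTERS = len(ALPHABET)
#: Indices eligible for matrix mutation (the 20 standard residues only).
MUTABLE = tuple(range(20))

DEFAULT_WINDOW = (7, 7)
DEFAULT_SP_TARGETS = {"low": 0.85, "medium": 0.90, "high": 0.95}
LEVELS = ("high", "medium", "low")


class ContractError(ValueError):
    """A caller violated an operation's precondition."""


# ---------------------------------------------------------------------------
# substitution matrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric residue-similarity scores over ``ALPHABET``.

    The ``'*'`` row and column are pinned to 0 so terminus padding is inert.
    """

    scores: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.shape != (N_LETTERS, N_LETTERS):
            raise ContractError(f"matrix must be {N_LETTERS}x{N_LETTERS}, got {s.shape}")
        if not np.allclose(s, s.T):
            raise ContractError("substitution matrix must be symmetric")
        if s[_INDEX[PAD]].any() or s[:, _INDEX[PAD]].any():
            raise ContractError("'*' row/column must be zero")
        object.__setattr__(self, "scores", s)

    @classmethod
    def blosum62(cls) -> "SubstitutionMatrix":
        raw = substitution_matrices.load("BLOSUM62")
        s = np.zeros((N_LETTERS, N_LETTERS))
        for i, a in enumerate(ALPHABET[:-1]):
            for j, b in enumerate(ALPHABET[:-1]):
                s[i, j] = raw[a, b]
        return cls(s)

    def lookup(self, a: str, b: str) -> float:
        return float(self.scores[_INDEX[a], _INDEX[b]])

    def mutated(self, i: int, j: int, delta: float) -> "SubstitutionMatrix":
        """Copy with entry (i, j) — and its mirror — shifted by delta."""
        if i not in MUTABLE or j not in MUTABLE:
            raise ContractError("only the 20 standard-residue entries are mutable")
        s = self.scores.copy()
        s[i, j] += delta
        if i != j:
            s[j, i] += delta
        return SubstitutionMatrix(s)


def encode_windows(windows: Sequence[PeptideWindow]) -> np.ndarray:
    """(n_windows, window_length) array of alphabet indices."""
    if not windows:
        return np.zeros((0, 0), dtype=np.intp)
    return np.array([[_INDEX[ch] for ch in w.letters] for w in windows], dtype=np.intp)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def peptide_similarity(
    a: PeptideWindow,
    b: PeptideWindow,
    matrix: SubstitutionMatrix,
    weights: Sequence[float],
) -> float:
    """Weighted, zero-clamped similarity between two equal-shape windows."""
    if (a.m, a.n) != (b.m, b.n):
        raise ContractError(f"window shapes differ: ({a.m},{a.n}) vs ({b.m},{b.n})")
    w = np.asarray(weights, dtype=float)
    if w.shape != (a.m + 1 + a.n,):
        raise ContractError(f"weights length {w.shape} does not match window ({a.m},{a.n})")
    total = sum(
        wi * matrix.lookup(x, y) for wi, x, y in zip(w, a.letters, b.letters)
    )
    return max(0.0, total)


def _pairwise_scores(
    cand: np.ndarray, pos: np.ndarray, matrix: SubstitutionMatrix, weights: np.ndarray
) -> np.ndarray:
    """(n_cand, n_pos) matrix of zero-clamped weighted similarities."""
    per_pos = matrix.scores[cand[:, None, :], pos[None, :, :]]  # (c, p, L)
    sims = per_pos @ weights
    return np.maximum(sims, 0.0)


def _mean_scores(
    cand: np.ndarray,
    pos: np.ndarray,
    matrix: SubstitutionMatrix,
    weights: np.ndarray,
    loo: bool = False,
) -> np.ndarray:
    """Mean similarity of each candidate to the positive set.

    With ``loo=True`` the candidate rows are assumed to *be* the positive set
    and each diagonal self-similarity is excluded from its own mean.
    """
    sims = _pairwise_scores(cand, pos, matrix, weights)
    if loo:
        n = sims.shape[1]
        if n < 2:
            raise ContractError("leave-one-out needs >= 2 positives")
        return (sims.sum(axis=1) - np.diagonal(sims)) / (n - 1)
    return sims.mean(axis=1)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


@dataclass
class ThresholdLevel:
    cutoff: float
    target_sp: float
    achieved_sp: float
    achieved_sn: float | None = None


@dataclass
class ScoreThresholds:
    """Score cutoffs per prediction level; higher target Sp => higher cutoff."""

    levels: dict[str, ThresholdLevel]

    def __post_init__(self) -> None:
        have = [l for l in LEVELS if l in self.levels]
        cuts = [self.levels[l].cutoff for l in have]
        if any(a < b for a, b in zip(cuts, cuts[1:])):
            raise ContractError(f"cutoffs must be ordered high >= medium >= low, got {cuts}")

    def cutoff(self, level: str) -> float:
        return self.levels[level].cutoff


@dataclass
class GPSModel:
    """A trained (or default) group-based scoring model."""

    matrix: SubstitutionMatrix
    weights: np.ndarray
    window: tuple[int, int]
    positives: list[PeptideWindow]
    thresholds: ScoreThresholds | None = None
    training_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        m, n = self.window
        if self.weights.shape != (m + 1 + n,):
            raise ContractError("weight vector length must match window")
        if (self.weights < 0).any():
            raise ContractError("weights must be non-negative")

    @classmethod
    def default(cls, positives: Sequence[PeptideWindow], window: tuple[int, int] = DEFAULT_WINDOW):
        m, n = window
        return cls(
            matrix=SubstitutionMatrix.blosum62(),
            weights=np.ones(m + 1 + n),
            window=window,
            positives=list(positives),
        )

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "alphabet": ALPHABET,
            "matrix": self.matrix.scores.tolist(),
            "weights": self.weights.tolist(),
            "window": list(self.window),
            "positives": [
                [p.protein_id, p.position, p.m, p.n, p.letters] for p in self.positives
            ],
            "thresholds": None
            if self.thresholds is None
            else {
                name: {
                    "cutoff": lv.cutoff,
                    "target_sp": lv.target_sp,
                    "achieved_sp": lv.achieved_sp,
                    "achieved_sn": lv.achieved_sn,
                }
                for name, lv in self.thresholds.levels.items()
            },
            "training_log": self.training_log,
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GPSModel":
        doc = json.loads(text)
        if doc["alphabet"] != ALPHABET:
            raise ContractError("model alphabet does not match this build")
        thresholds = None
        if doc["thresholds"] is not None:
            thresholds = ScoreThresholds(
                {
                    name: ThresholdLevel(
                        lv["cutoff"], lv["target_sp"], lv["achieved_sp"], lv["achieved_sn"]
                    )
                    for name, lv in doc["thresholds"].items()
                }
            )
        return cls(
            matrix=SubstitutionMatrix(np.array(doc["matrix"])),
            weights=np.array(doc["weights"]),
            window=tuple(doc["window"]),
            positives=[PeptideWindow(*p) for p in doc["positives"]],
            thresholds=thresholds,
            training_log=doc.get("training_log", []),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "GPSModel":
        return cls.from_json(Path(path).read_text())


def gps_score(candidate: PeptideWindow, model: GPSModel, exclude_self: bool = False) -> float:
    """Mean similarity of a candidate to the model's positive peptides.

    With ``exclude_self`` any training peptide at the candidate's own
    (protein, position) is left out — the leave-one-out discipline.
    """
    positives = model.positives
    if exclude_self:
        positives = [
            p
            for p in positives
            if (p.protein_id, p.position) != (candidate.protein_id, candidate.position)
        ]
    if not positives:
        raise ContractError("no positives left to score against")
    w = model.weights
    total = sum(peptide_similarity(candidate, p, model.matrix, w) for p in positives)
    return total / len(positives)


# ---------------------------------------------------------------------------
# ROC / metrics
# ---------------------------------------------------------------------------


@dataclass
class ROCCurve:
    """ROC points (1-Sp, Sn) swept over score thresholds, with trapezoid area."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    aroc: float


def roc_curve(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> ROCCurve:
    """ROC over pooled scores; tied scores are grouped at one threshold."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ContractError("need at least one positive and one negative score")
    cuts = np.unique(np.concatenate([pos, neg]))[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for c in cuts:
        tpr.append(float((pos >= c).mean()))
        fpr.append(float((neg >= c).mean()))
    fpr_a = np.array(fpr)
    tpr_a = np.array(tpr)
    aroc = float(np.trapezoid(tpr_a, fpr_a))
    thresholds = np.concatenate([[np.inf], cuts])
    return ROCCurve(fpr_a, tpr_a, thresholds, aroc)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ContractError("confusion counts must be non-negative")


@dataclass(frozen=True)
class PerformanceMetrics:
    """Ac / Sn / Sp / MCC; a metric with a zero denominator is None."""

    ac: float | None
    sn: float | None
    sp: float | None
    mcc: float | None


def compute_metrics(counts: ConfusionCounts) -> PerformanceMetrics:
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    total = tp + fp + tn + fn
    ac = (tp + tn) / total if total else None
    sn = tp / (tp + fn) if tp + fn else None
    sp = tn / (tn + fp) if tn + fp else None
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else None
    return PerformanceMetrics(ac, sn, sp, mcc)


def confusion_at(pos_scores, neg_scores, cutoff: float) -> ConfusionCounts:
    pos = np.asarray(pos_scores)
    neg = np.asarray(neg_scores)
    return ConfusionCounts(
        tp=int((pos >= cutoff).sum()),
        fp=int((neg >= cutoff).sum()),
        tn=int((neg < cutoff).sum()),
        fn=int((pos < cutoff).sum()),
    )


# ---------------------------------------------------------------------------
# validation protocols
# ---------------------------------------------------------------------------


@dataclass
class ValidationResult:
    pos_scores: np.ndarray
    neg_scores: np.ndarray
    roc: ROCCurve


def _dataset_windows(model: GPSModel, dataset: SiteDataset, ptm: str):
    m, n = model.window
    pos_sites = dataset.positives(ptm)
    neg_sites = dataset.negatives(ptm)
    pos_w = windows_for_sites(dataset.proteins, pos_sites, m, n)
    neg_w = windows_for_sites(dataset.proteins, neg_sites, m, n)
    return pos_w, neg_w


def loo_validation(model: GPSModel, dataset: SiteDataset, ptm: str = "sulfation") -> ValidationResult:
    """Leave-one-out validation: each positive scored with itself excluded,
    negatives scored against all positives; ROC over the pooled scores."""
    pos_w, neg_w = _dataset_windows(model, dataset, ptm)
    if len(pos_w) < 2 or not neg_w:
        raise ContractError("LOO needs >= 2 positives and >= 1 negative")
    pos_mat = encode_windows(pos_w)
    neg_mat = encode_windows(neg_w)
    pos_scores = _mean_scores(pos_mat, pos_mat, model.matrix, model.weights, loo=True)
    neg_scores = _mean_scores(neg_mat, pos_mat, model.matrix, model.weights)
    return ValidationResult(pos_scores, neg_scores, roc_curve(pos_scores, neg_scores))


def _deal_folds(n_items: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    order = rng.permutation(n_items)
    return [order[i::k] for i in range(k)]


def k_fold_cv(
    model: GPSModel, dataset: SiteDataset, k: int, seed: int, ptm: str = "sulfation"
) -> ValidationResult:
    """Stratified k-fold cross-validation with pooled ROC.

    Positives and negatives are shuffled independently (seeded) and dealt
    round-robin into k folds; each fold is scored against the positives
    outside it.  Deterministic given the seed.
    """
    pos_w, neg_w = _dataset_windows(model, dataset, ptm)
    if k < 2 or k > len(pos_w):
        raise ContractError(f"k={k} must be in 2..n_pos={len(pos_w)}")
    rng = np.random.default_rng(seed)
    pos_mat = encode_windows(pos_w)
    neg_mat = encode_windows(neg_w)
    pos_folds = _deal_folds(len(pos_w), k, rng)
    neg_folds = _deal_folds(len(neg_w), k, rng)
    pos_scores = np.empty(len(pos_w))
    neg_scores = np.empty(len(neg_w))
    for pf, nf in zip(pos_folds, neg_folds):
        train_mask = np.ones(len(pos_w), dtype=bool)
        train_mask[pf] = False
        train = pos_mat[train_mask]
        if train.shape[0] == 0:
            raise ContractError("a fold exhausted the training positives")
        pos_scores[pf] = _mean_scores(pos_mat[pf], train, model.matrix, model.weights)
        if nf.size:
            neg_scores[nf] = _mean_scores(neg_mat[nf], train, model.matrix, model.weights)
    return ValidationResult(pos_scores, neg_scores, roc_curve(pos_scores, neg_scores))


# ---------------------------------------------------------------------------
# threshold calibration
# ---------------------------------------------------------------------------


def calibrate_thresholds(
    pos_scores: Sequence[float],
    neg_scores: Sequence[float],
    sp_targets: Mapping[str, float] = DEFAULT_SP_TARGETS,
) -> ScoreThresholds:
    """Pick, per level, the smallest score cutoff whose empirical Sp meets the
    target.  Sp(c) is the fraction of negatives scoring below c (a peptide is
    called positive when its score >= c).  If no observed score reaches the
    target the cutoff is placed just above the maximum score, with Sp = 1.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if neg.size == 0:
        raise ContractError("threshold calibration needs scored negatives")
    candidates = np.unique(np.concatenate([pos, neg]))
    levels: dict[str, ThresholdLevel] = {}
    for name, target in sp_targets.items():
        cutoff = None
        for c in candidates:
            sp = float((neg < c).mean())
            if sp >= target:
                cutoff = float(c)
                break
        if cutoff is None:
            cutoff = float(np.nextafter(candidates[-1], np.inf))
        achieved_sp = float((neg < cutoff).mean())
        achieved_sn = float((pos >= cutoff).mean()) if pos.size else None
        levels[name] = ThresholdLevel(cutoff, target, achieved_sp, achieved_sn)
    return ScoreThresholds(levels)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

DEFAULT_MN_GRID = tuple((m, n) for m in range(3, 11) for n in range(3, 11))
#: Multiplicative step grid for weight hill-climbing (log-symmetric).
WEIGHT_STEPS = (0.5, 0.8, 1.25, 2.0)


def motif_length_selection(
    dataset: SiteDataset,
    grid: Sequence[tuple[int, int]] = DEFAULT_MN_GRID,
    ptm: str = "sulfation",
) -> tuple[tuple[int, int], dict[tuple[int, int], float]]:
    """Pick the (m, n) window maximising LOO AROC with unit weights.

    Ties prefer the smaller m+n, then the smaller m.  Deterministic.
    """
    if not grid:
        raise ContractError("candidate grid must be non-empty")
    matrix = SubstitutionMatrix.blosum62()
    arocs: dict[tuple[int, int], float] = {}
    for m, n in grid:
        probe = GPSModel(matrix, np.ones(m + 1 + n), (m, n), [])
        arocs[(m, n)] = loo_validation(probe, dataset, ptm).roc.aroc
    best = max(arocs, key=lambda mn: (arocs[mn], -(mn[0] + mn[1]), -mn[0]))
    return best, arocs


def _loo_aroc(matrix, weights, pos_mat, neg_mat) -> float:
    pos_scores = _mean_scores(pos_mat, pos_mat, matrix, weights, loo=True)
    neg_scores = _mean_scores(neg_mat, pos_mat, matrix, weights)
    return roc_curve(pos_scores, neg_scores).aroc


def weight_training(
    model: GPSModel,
    dataset: SiteDataset,
    iterations: int = 100,
    seed: int = 42,
    ptm: str = "sulfation",
) -> GPSModel:
    """Hill-climb position weights; keep a step only on strict LOO-AROC gain."""
    if iterations < 0:
        raise ContractError("iterations must be >= 0")
    rng = np.random.default_rng(seed)
    pos_w, neg_w = _dataset_windows(model, dataset, ptm)
    pos_mat, neg_mat = encode_windows(pos_w), encode_windows(neg_w)
    weights = model.weights.copy()
    best = _loo_aroc(model.matrix, weights, pos_mat, neg_mat)
    log = list(model.training_log)
    accepted = 0
    for it in range(iterations):
        pos = int(rng.integers(len(weights)))
        step = float(WEIGHT_STEPS[rng.integers(len(WEIGHT_STEPS))])
        trial = weights.copy()
        trial[pos] = max(0.0, trial[pos] * step)
        aroc = _loo_aroc(model.matrix, trial, pos_mat, neg_mat)
        if aroc > best:
            weights, best = trial, aroc
            accepted += 1
    log.append({"stage": "weight_training", "seed": seed, "iterations": iterations,
                "accepted": accepted, "loo_aroc": best})
    return GPSModel(model.matrix, weights, model.window, model.positives,
                    model.thresholds, log)


def matrix_mutation(
    model: GPSModel,
    dataset: SiteDataset,
    iterations: int = 100,
    seed: int = 42,
    ptm: str = "sulfation",
) -> GPSModel:
    """Hill-climb symmetric matrix entries by +-1; strict-improvement rule."""
    if iterations < 0:
        raise ContractError("iterations must be >= 0")
    rng = np.random.default_rng(seed)
    pos_w, neg_w = _dataset_windows(model, dataset, ptm)
    pos_mat, neg_mat = encode_windows(pos_w), encode_windows(neg_w)
    matrix = model.matrix
    best = _loo_aroc(matrix, model.weights, pos_mat, neg_mat)
    log = list(model.training_log)
    accepted = 0
    for it in range(iterations):
        i = int(rng.choice(MUTABLE))
        j = int(rng.choice(MUTABLE))
        delta = float(rng.choice([-1.0, 1.0]))
        trial = matrix.mutated(i, j, delta)
        aroc = _loo_aroc(trial, model.weights, pos_mat, neg_mat)
        if aroc > best:
            matrix, best = trial, aroc
            accepted += 1
    log.append({"stage": "matrix_mutation", "seed": seed, "iterations": iterations,
                "accepted": accepted, "loo_aroc": best})
    return GPSModel(matrix, model.weights, model.window, model.positives,
                    model.thresholds, log)


def train(
    dataset: SiteDataset,
    ptm: str = "sulfation",
    grid: Sequence[tuple[int, int]] | None = None,
    wt_iterations: int = 100,
    mm_iterations: int = 100,
    seed: int = 42,
    sp_targets: Mapping[str, float] = DEFAULT_SP_TARGETS,
) -> GPSModel:
    """Full training pipeline: motif length selection, weight training,
    matrix mutation, then specificity-calibrated thresholds."""
    if grid is None:
        window, arocs = DEFAULT_WINDOW, {}
    else:
        window, arocs = motif_length_selection(dataset, grid, ptm)
    m, n = window
    pos_sites = dataset.positives(ptm)
    positives = windows_for_sites(dataset.proteins, pos_sites, m, n)
    model = GPSModel.default(positives, window)
    model.training_log.append(
        {"stage": "motif_length_selection", "window": [m, n],
         "grid_arocs": {f"{a},{b}": v for (a, b), v in arocs.items()}}
    )
    model = weight_training(model, dataset, wt_iterations, seed, ptm)
    model = matrix_mutation(model, dataset, mm_iterations, seed + 1, ptm)
    result = loo_validation(model, dataset, ptm)
    model.thresholds = calibrate_thresholds(result.pos_scores, result.neg_scores, sp_targets)
    model.training_log.append({"stage": "calibration", "loo_aroc": result.roc.aroc})
    return model


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


def predict(
    proteins: Iterable[ProteinRecord],
    model: GPSModel,
    level: str = "medium",
    ptm: str = "sulfation",
) -> list[ModSite]:
    """Score every tyrosine and emit sites at or above the level's cutoff."""
    if model.thresholds is None:
        raise ContractError("model has no calibrated thresholds; run train() first")
    if level not in model.thresholds.levels:
        raise ContractError(f"unknown level {level!r}")
    cutoff = model.thresholds.cutoff(level)
    m, n = model.window
    pos_mat = encode_windows(model.positives)
    candidates: list[tuple[ProteinRecord, int]] = []
    windows: list[PeptideWindow] = []
    for rec in proteins:
        for i, aa in enumerate(rec.sequence, start=1):
            if aa == "Y":
                candidates.append((rec, i))
                windows.append(extract_window(rec, i, m, n))
    if not windows:
        return []
    scores = _mean_scores(encode_windows(windows), pos_mat, model.matrix, model.weights)
    out = []
    for (rec, pos), score in zip(candidates, scores):
        if score >= cutoff:
            out.append(
                ModSite(rec.id, pos, "Y", ptm, evidence="predicted", score=float(score))
            )
    return out
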