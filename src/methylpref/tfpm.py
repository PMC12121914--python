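"""TFPM-vs-TFPNM classification: RBF-SVM on reduced-alphabet k-mer features.

The model object follows the fit/results pattern: :class:`TfpmModel` holds a
labeled dataset and hyperparameters; :meth:`TfpmModel.fit` trains a
C-support-vector classifier with an RBF kernel exp(-gamma * ||x - x'||^2) on
the k-mer relative-frequency features and returns :class:`TfpmResults`, which
carries the fitted state and provides prediction, independent-test
evaluation, proteome ranking and a text summary.

Defaults are the optimum found by grid search over the reduction-scheme
size, k-mer length and SVM hyperparameters: Op11, k=1, C=0.01, gamma=1.
Features enter the kernel as relative frequencies without further scaling
(they already lie in [0, 1] and sum to 1), and no class weighting is applied.

AUC for evaluation is computed from raw SVM decision values (deterministic
and rank-equivalent to any monotone calibration); ranking and the 0.5
labeling threshold use Platt-calibrated probabilities.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
import pickle
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from methylpref.io import LabeledDataset, ProteinRecord, validate_record
from methylpref.metrics import MetricsReport, compute_metrics, confusion, roc_auc
from methylpref.raac import (
    EncodingError,
    ReductionScheme,
    feature_matrix,
    load_scheme,
    scheme_for_op,
)

logger = logging.getLogger(__name__)

_SERIAL_VERSION = 1


def platt_fit(decision_values, labels, max_iter: int = 100) -> tuple[float, float]:
    """Fit Platt's sigmoid P(y=1|f) = 1 / (1 + exp(A f + B)) by Newton steps.

    Uses the regularized maximum-likelihood targets and the numerically
    robust update of Lin, Weng & Keerthi (2007).  Deterministic given the
    inputs.  Returns (A, B).
    """
    f = np.asarray(decision_values, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    hi = (n_pos + 1.0) / (n_pos + 2.0)
    lo = 1.0 / (n_neg + 2.0)
    t = np.where(y == 1, hi, lo)

    A, B = 0.0, np.log((n_neg + 1.0) / (n_pos + 1.0))
    sigma = 1e-12  # Hessian ridge

    def nll(A, B):
        z = A * f + B
        # log(1 + exp(z)) computed stably, minus t*(-z) bookkeeping per Lin et al.
        return float(np.sum(np.where(z >= 0, t * z + np.log1p(np.exp(-z)),
                                     (t - 1) * z + np.log1p(np.exp(z)))))

    fval = nll(A, B)
    for _ in range(max_iter):
        z = A * f + B
        p = np.where(z >= 0, np.exp(-z) / (1 + np.exp(-z)), 1 / (1 + np.exp(z)))
        q = 1.0 - p  # q = 1/(1+exp(-z))
        d1 = t - p
        d2 = p * q
        g1 = float(np.sum(f * d1))
        g2 = float(np.sum(d1))
        if abs(g1) < 1e-10 and abs(g2) < 1e-10:
            break
        h11 = float(np.sum(f * f * d2)) + sigma
        h22 = float(np.sum(d2)) + sigma
        h21 = float(np.sum(f * d2))
        det = h11 * h22 - h21 * h21
        dA = -(h22 * g1 - h21 * g2) / det
        dB = -(-h21 * g1 + h11 * g2) / det
        gd = g1 * dA + g2 * dB
        step = 1.0
        while step >= 1e-10:
            newA, newB = A + step * dA, B + step * dB
            newf = nll(newA, newB)
            if newf < fval + 1e-4 * step * gd:
                A, B, fval = newA, newB, newf
                break
            step /= 2.0
        else:
            break
    return A, B


def platt_prob(decision_values, A: float, B: float) -> np.ndarray:
    z = A * np.asarray(decision_values, dtype=float) + B
    return np.where(z >= 0, np.exp(-z) / (1 + np.exp(-z)), 1 / (1 + np.exp(z)))


@dataclass(frozen=True)
class HyperParams:
    """(op, k, C, gamma) for the reduced-alphabet k-mer SVM.

    ``op`` is the reduction-scheme group count; ``k`` the window length;
    ``C`` the SVM regularization; ``gamma`` the literal RBF kernel
    coefficient (not a data-dependent heuristic).
    """

    op: int = 11
    k: int = 1
    C: float = 0.01
    gamma: float = 1.0

    def __post_init__(self):
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")

    @property
    def scheme(self) -> ReductionScheme:
        return scheme_for_op(self.op)

    def as_tuple(self) -> tuple:
        return (self.op, self.k, self.C, self.gamma)


@dataclass(frozen=True)
class Prediction:
    """Per-protein output: decision score, calibrated probability, 0/1 label."""

    id: str
    score: float
    probability: float
    label: int
    flagged: bool = False  # True when the record could not be featurized


class TrainingError(ValueError):
    pass


def _featurize_dataset(records, scheme, k, lenient=False):
    return feature_matrix(records, scheme, k, lenient=lenient)


class TfpmModel:
    """TFPM/TFPNM classifier specification: dataset + hyperparameters.

    Parameters
    ----------
    dataset : LabeledDataset
        Training records with binary labels (1 = binds methylated DNA
        preferentially).  Must contain both classes.
    hyperparams : HyperParams, optional
        Reduction scheme size, k-mer length and SVM (C, gamma); defaults to
        the grid-search optimum (Op11, k=1, C=0.01, gamma=1).
    """

    def __init__(self, dataset: LabeledDataset, hyperparams: HyperParams | None = None):
        self.dataset = dataset
        self.hyperparams = hyperparams or HyperParams()

    @classmethod
    def from_fasta(
        cls,
        positive: str,
        negative: str,
        hyperparams: HyperParams | None = None,
        strict: bool = True,
    ) -> "TfpmModel":
        """Build a model from one positive-class and one negative-class FASTA."""
        from methylpref.io import load_dataset

        ds = load_dataset({"positive": [positive], "negative": [negative]}, strict=strict)
        return cls(ds, hyperparams)

    # ------------------------------------------------------------------ fit

    def fit(self, seed: int = 0) -> "TfpmResults":
        """Train the RBF SVM; deterministic given (dataset order, hyperparams, seed)."""
        ds, hp = self.dataset, self.hyperparams
        classes = np.unique(ds.labels)
        if len(ds) == 0 or len(classes) < 2:
            raise TrainingError(
                f"training requires both classes; got labels {classes.tolist()}"
            )
        scheme = hp.scheme
        X = _featurize_dataset(ds.records, scheme, hp.k)
        svm = SVC(C=hp.C, gamma=hp.gamma, kernel="rbf", random_state=seed)
        svm.fit(X, ds.labels)
        # Platt sigmoid on training decision values maps scores to probabilities
        A, B = platt_fit(svm.decision_function(X), ds.labels)
        checksum = hashlib.sha256(X.tobytes() + ds.labels.tobytes()).hexdigest()[:16]
        return TfpmResults(
            model=self,
            svm=svm,
            scheme=scheme,
            seed=seed,
            n_pos=ds.n_pos,
            n_neg=ds.n_neg,
            training_checksum=checksum,
            platt=(A, B),
        )

    # ------------------------------------------------- cross-validation

    def cross_validate(
        self, folds: int = 5, seed: int = 0
    ) -> tuple[MetricsReport, list[MetricsReport]]:
        """Stratified k-fold CV; metrics pooled over held-out predictions.

        Returns the pooled report (AUC from pooled decision values) and the
        per-fold reports.
        """
        ds, hp = self.dataset, self.hyperparams
        if folds < 2:
            raise ValueError(f"folds must be >= 2, got {folds}")
        counts = np.bincount(ds.labels, minlength=2)
        if counts.min() < folds:
            raise TrainingError(
                f"smallest class has {counts.min()} members; cannot stratify into "
                f"{folds} folds"
            )
        scheme = hp.scheme
        X = _featurize_dataset(ds.records, scheme, hp.k)
        y = ds.labels
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        pooled_scores = np.zeros(len(y))
        pooled_pred = np.zeros(len(y), dtype=int)
        fold_reports = []
        for train_idx, test_idx in skf.split(X, y):
            svm = SVC(C=hp.C, gamma=hp.gamma, kernel="rbf", random_state=seed)
            svm.fit(X[train_idx], y[train_idx])
            scores = svm.decision_function(X[test_idx])
            preds = (scores >= 0).astype(int)
            pooled_scores[test_idx] = scores
            pooled_pred[test_idx] = preds
            fold_reports.append(
                compute_metrics(
                    confusion(y[test_idx], preds),
                    auc=roc_auc(y[test_idx], scores),
                )
            )
        pooled = compute_metrics(
            confusion(y, pooled_pred), auc=roc_auc(y, pooled_scores)
        )
        return pooled, fold_reports

    # ------------------------------------------------------ grid search

    def grid_search(
        self,
        ops=(5, 8, 9, 11, 13),
        ks=(1, 2, 3, 4, 5),
        Cs=(1e-3, 1e-2, 1e-1, 1.0, 10.0, 100.0),
        gammas=(1e-2, 1e-1, 1.0, 10.0),
        folds: int = 5,
        seed: int = 0,
    ) -> "GridSearchResult":
        """Exhaustive CV grid search maximizing pooled AUC.

        Ties are broken by lexicographic (op, k, C, gamma) order — the first
        combination encountered wins — and logged.  The full table is
        retained in :attr:`GridSearchResult.table`.
        """
        combos = list(itertools.product(sorted(ops), sorted(ks), sorted(Cs), sorted(gammas)))
        if not combos:
            raise ValueError("empty hyperparameter grid")
        rows = []
        best_hp, best_auc = None, -np.inf
        for op, k, C, gamma in combos:
            hp = HyperParams(op=op, k=k, C=C, gamma=gamma)
            model = TfpmModel(self.dataset, hp)
            pooled, _ = model.cross_validate(folds=folds, seed=seed)
            rows.append(
                {
                    "op": op, "k": k, "C": C, "gamma": gamma,
                    "cv_auc": pooled.auc,
                    "cv_acc": pooled.accuracy,
                    "cv_sn": pooled.sensitivity,
                    "cv_sp": pooled.specificity,
                    "cv_mcc": pooled.mcc,
                }
            )
            if pooled.auc > best_auc:
                best_hp, best_auc = hp, pooled.auc
            elif pooled.auc == best_auc:
                logger.info(
                    "grid tie at AUC=%.4f: keeping %s over %s (lexicographic order)",
                    best_auc, best_hp.as_tuple(), hp.as_tuple(),
                )
        table = pd.DataFrame(rows)
        return GridSearchResult(table=table, best=best_hp, best_cv_auc=float(best_auc))


@dataclass
class GridSearchResult:
    """Full grid-search table and the AUC-maximizing hyperparameters."""

    table: pd.DataFrame
    best: HyperParams
    best_cv_auc: float

    def to_csv(self, path, sep="\t"):
        self.table.to_csv(path, sep=sep, index=False)


class TfpmResults:
    """Fitted TFPM classifier: predictions, evaluation, ranking, summary."""

    def __init__(self, model, svm, scheme, seed, n_pos, n_neg, training_checksum, platt):
        self.model = model
        self.hyperparams = model.hyperparams
        self.svm = svm
        self.scheme = scheme
        self.seed = seed
        self.n_pos = n_pos
        self.n_neg = n_neg
        self.training_checksum = training_checksum
        self.platt = platt  # (A, B) of the calibration sigmoid

    @property
    def n_support_vectors(self) -> int:
        return int(self.svm.n_support_.sum())

    @property
    def feature_dimension(self) -> int:
        return self.scheme.size ** self.hyperparams.k

    # --------------------------------------------------------- predict

    def predict(
        self,
        records: list[ProteinRecord],
        threshold: float = 0.5,
        lenient: bool = True,
    ) -> list[Prediction]:
        """Score records; label 1 iff calibrated probability >= threshold.

        Lenient mode strips non-canonical residues and flags (rather than
        raises on) sequences too short to featurize; such records receive a
        null prediction with ``flagged=True``.
        """
        if not records:
            return []
        hp = self.hyperparams
        preds: list[Prediction] = [None] * len(records)  # type: ignore[list-item]
        rows, row_idx = [], []
        for i, rec in enumerate(records):
            try:
                clean = validate_record(rec, strict=not lenient)
                from methylpref.raac import featurize, reduce_sequence

                fv = featurize(reduce_sequence(clean, self.scheme), self.scheme, hp.k,
                               lenient=lenient)
                if fv.n_windows == 0:
                    preds[i] = Prediction(rec.id, 0.0, 0.0, 0, flagged=True)
                    continue
                rows.append(fv.values)
                row_idx.append(i)
            except EncodingError:
                if not lenient:
                    raise
                preds[i] = Prediction(rec.id, 0.0, 0.0, 0, flagged=True)
        if rows:
            X = np.vstack(rows)
            scores = self.svm.decision_function(X)
            probs = platt_prob(scores, *self.platt)
            for i, s, p in zip(row_idx, scores, probs):
                preds[i] = Prediction(
                    records[i].id, float(s), float(p), int(p >= threshold)
                )
        return preds

    def evaluate(self, dataset: LabeledDataset, threshold: float = 0.5) -> MetricsReport:
        """Independent-test metrics; AUC from raw decision values."""
        preds = self.predict(dataset.records, threshold=threshold)
        labels = np.asarray(dataset.labels)
        pred_labels = np.array([p.label for p in preds])
        scores = np.array([p.score for p in preds])
        return compute_metrics(
            confusion(labels, pred_labels), auc=roc_auc(labels, scores)
        )

    def rank_proteome(
        self, proteome: list[ProteinRecord], top_n: int = 20
    ) -> pd.DataFrame:
        """Rank proteins by TFPM probability (descending; ties by id ascending).

        Returns the full ranked table; the caller may head() the top_n rows —
        the returned frame carries a ``rank`` column and ``top_n`` is
        validated here so CLI/table consumers share one contract.
        """
        if top_n <= 0:
            raise ValueError(f"top_n must be positive, got {top_n}")
        if not proteome:
            raise ValueError("proteome is empty")
        preds = self.predict(proteome, lenient=True)
        df = pd.DataFrame(
            {
                "id": [p.id for p in preds],
                "probability": [p.probability for p in preds],
                "score": [p.score for p in preds],
                "label": [p.label for p in preds],
                "flagged": [p.flagged for p in preds],
            }
        )
        df = df.sort_values(
            ["probability", "id"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
        df.insert(0, "rank", np.arange(1, len(df) + 1))
        df.attrs["top_n"] = min(top_n, len(df))
        return df

    # ----------------------------------------------------- persistence

    def save(self, path) -> None:
        """Serialize to a single versioned file (scheme, hyperparams, SVM state)."""
        payload = {
            "version": _SERIAL_VERSION,
            "scheme_name": self.scheme.name,
            "scheme_groups": self.scheme.groups,
            "hyperparams": self.hyperparams,
            "svm": self.svm,
            "seed": self.seed,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "training_checksum": self.training_checksum,
            "platt": self.platt,
        }
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "TfpmResults":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("version") != _SERIAL_VERSION:
            raise ValueError(f"unsupported model file version: {payload.get('version')}")
        scheme = ReductionScheme(payload["scheme_name"], payload["scheme_groups"])
        dummy_ds = LabeledDataset(records=[], labels=np.array([], dtype=int))
        model = TfpmModel(dummy_ds, payload["hyperparams"])
        res = cls(
            model=model,
            svm=payload["svm"],
            scheme=scheme,
            seed=payload["seed"],
            n_pos=payload["n_pos"],
            n_neg=payload["n_neg"],
            training_checksum=payload["training_checksum"],
            platt=payload["platt"],
        )
        return res

    def summary(self) -> str:
        hp = self.hyperparams
        lines = [
            "TFPM classifier (reduced-alphabet k-mer + RBF SVM)",
            "=" * 52,
            f"scheme:            {self.scheme.name} ({self.scheme.size} groups)",
            f"k-mer length:      {hp.k}",
            f"feature dimension: {self.feature_dimension}",
            f"SVM C / gamma:     {hp.C} / {hp.gamma}",
            f"training set:      {self.n_pos} positives, {self.n_neg} negatives",
            f"support vectors:   {self.n_support_vectors}",
            f"seed:              {self.seed}",
            f"training checksum: {self.training_checksum}",
        ]
        return "\n".join(lines)
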