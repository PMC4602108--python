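"""Sequence-based protein-protein interaction prediction.

Positive interaction pairs are curated (short or ambiguous sequences
dropped, redundant proteins removed by greedy identity clustering), a
balanced negative set is sampled from protein pairs with disjoint
subcellular localizations, and pairs are encoded by lagged auto-covariance
of seven standardized physicochemical property series before being fed to
an RBF support-vector classifier (defaults c = 5.278, gamma = 0.574).

Module-level sub-networks combine three filters: a co-expression weight
threshold alpha = (w_max - w_min) * 0.6 + w_mean over the seed-to-module
weights, the classifier's prediction, and co-localization of the pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .config import ACParams
from .properties import AA_INDEX, AMINO_ACIDS, N_PROPERTIES, standardized_property_matrix

_PROPERTY_MATRIX = standardized_property_matrix()

POSITIVE, NEGATIVE = 1, 0


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with optional subcellular localizations."""

    id: str
    sequence: str
    localizations: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein '{self.id}' has an empty sequence")


@dataclass
class PPIDataset:
    """Labeled unordered protein pairs."""

    pairs: list[tuple[str, str, int]] = field(default_factory=list)
    provenance: str = "curated"

    def __post_init__(self) -> None:
        seen = set()
        for a, b, _ in self.pairs:
            key = frozenset((a, b))
            if key in seen:
                raise ValueError(f"duplicate unordered pair ({a}, {b})")
            seen.add(key)

    def positives(self) -> list[tuple[str, str]]:
        return [(a, b) for a, b, lab in self.pairs if lab == POSITIVE]

    def negatives(self) -> list[tuple[str, str]]:
        return [(a, b) for a, b, lab in self.pairs if lab == NEGATIVE]


# ---------------------------------------------------------------------------
# curation

def sequence_identity(seq_a: str, seq_b: str) -> float:
    """Identical aligned positions divided by the shorter sequence length.

    Global alignment with match 1, mismatch 0, gap -1. Co-optimal
    alignments can differ in their number of identities, so the count is
    made unique by maximizing (score, identities) lexicographically.
    Quadratic time and intended for the modest sequence sets the
    redundancy filter sees; not a general-purpose aligner.
    """
    n, m = len(seq_a), len(seq_b)
    neg = -(10**9)
    prev_s = [-j for j in range(m + 1)]
    prev_i = [0] * (m + 1)
    for i in range(1, n + 1):
        cur_s = [-i] + [neg] * m
        cur_i = [0] * (m + 1)
        ca = seq_a[i - 1]
        for j in range(1, m + 1):
            match = 1 if ca == seq_b[j - 1] else 0
            best_s = prev_s[j - 1] + match
            best_i = prev_i[j - 1] + match
            s_up, i_up = prev_s[j] - 1, prev_i[j]
            if (s_up, i_up) > (best_s, best_i):
                best_s, best_i = s_up, i_up
            s_left, i_left = cur_s[j - 1] - 1, cur_i[j - 1]
            if (s_left, i_left) > (best_s, best_i):
                best_s, best_i = s_left, i_left
            cur_s[j], cur_i[j] = best_s, best_i
        prev_s, prev_i = cur_s, cur_i
    return prev_i[m] / min(n, m)


def curate_positives(
    pairs: list[tuple[str, str]],
    proteins: dict[str, ProteinRecord],
    min_length: int = 50,
    identity_threshold: float | None = 0.4,
) -> tuple[PPIDataset, dict[str, int]]:
    """Apply the sequence-quality and redundancy filters to positive pairs.

    Pairs containing a protein shorter than ``min_length`` residues or with
    any non-canonical residue are removed first. The remaining proteins are
    then clustered greedily by descending length: a protein at least
    ``identity_threshold`` identical to an already-kept representative
    becomes redundant, and every pair containing a redundant protein is
    dropped (``identity_threshold=None`` skips redundancy reduction).
    Returns the curated dataset and per-rule removal counts.
    """
    if not pairs:
        warnings.warn("no pairs to curate", stacklevel=2)
        return PPIDataset(pairs=[], provenance="curated"), {
            "short_or_unknown": 0,
            "redundant": 0,
            "kept": 0,
        }
    canonical = set(AMINO_ACIDS)

    def clean(pid: str) -> bool:
        seq = proteins[pid].sequence
        return len(seq) >= min_length and set(seq) <= canonical

    stage1 = [p for p in pairs if clean(p[0]) and clean(p[1])]
    n_short = len(pairs) - len(stage1)

    redundant: set[str] = set()
    if identity_threshold is not None:
        involved = sorted(
            {pid for pair in stage1 for pid in pair},
            key=lambda pid: (-len(proteins[pid].sequence), pid),
        )
        representatives: list[str] = []
        for pid in involved:
            seq = proteins[pid].sequence
            if any(
                sequence_identity(seq, proteins[rep].sequence) >= identity_threshold
                for rep in representatives
            ):
                redundant.add(pid)
            else:
                representatives.append(pid)
    stage2 = [p for p in stage1 if p[0] not in redundant and p[1] not in redundant]
    report = {
        "short_or_unknown": n_short,
        "redundant": len(stage1) - len(stage2),
        "kept": len(stage2),
    }
    dataset = PPIDataset(
        pairs=[(a, b, POSITIVE) for a, b in stage2], provenance="curated"
    )
    return dataset, report


def build_negative_set(
    proteins: dict[str, ProteinRecord],
    known_pairs: list[tuple[str, str]],
    n: int,
    seed: int,
) -> PPIDataset:
    """Sample non-interacting pairs from disjoint subcellular localizations.

    Eligible pairs have no shared compartment and do not appear in the
    known interaction set; ``n`` of them are drawn uniformly without
    replacement. Raises if fewer than ``n`` eligible pairs exist.
    """
    known = {frozenset(p) for p in known_pairs}
    ids = sorted(proteins)
    eligible = [
        (a, b)
        for a, b in combinations(ids, 2)
        if proteins[a].localizations
        and proteins[b].localizations
        and not (proteins[a].localizations & proteins[b].localizations)
        and frozenset((a, b)) not in known
    ]
    if len(eligible) < n:
        raise ValueError(
            f"only {len(eligible)} eligible negative pairs exist; {n} requested"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=n, replace=False)
    pairs = [(*eligible[i], NEGATIVE) for i in sorted(idx)]
    return PPIDataset(pairs=pairs, provenance="sampled")


# ---------------------------------------------------------------------------
# auto-covariance encoding


def ac_encode(sequence: str, params: ACParams | None = None) -> np.ndarray:
    """Lagged auto-covariance of the standardized property series.

    Each residue is translated into its seven z-scored property values;
    for property j and lag ``l``,
    AC(l, j) = (1 / (n - l)) * sum_i (X_ij - mean_j) (X_(i+l)j - mean_j)
    with the mean taken over the sequence. The output is property-major
    (lags 1..lag_max within each property), length ``7 * lag_max``.
    """
    params = params or ACParams()
    n = len(sequence)
    if n <= params.lag_max:
        raise ValueError(
            f"sequence shorter than lag window ({n} <= {params.lag_max})"
        )
    try:
        cols = [AA_INDEX[c] for c in sequence]
    except KeyError as exc:
        raise ValueError(f"non-canonical residue {exc.args[0]!r}") from exc
    x = _PROPERTY_MATRIX[:, cols]  # 7 x n
    xc = x - x.mean(axis=1, keepdims=True)
    out = np.empty(N_PROPERTIES * params.lag_max)
    for j in range(N_PROPERTIES):
        row = xc[j]
        for lag in range(1, params.lag_max + 1):
            out[j * params.lag_max + lag - 1] = row[: n - lag] @ row[lag:] / (n - lag)
    return out


def encode_pair(
    rec_a: ProteinRecord, rec_b: ProteinRecord, params: ACParams | None = None
) -> np.ndarray:
    """Concatenated AC vectors of the two partners (length 14 * lag_max)."""
    return np.concatenate([ac_encode(rec_a.sequence, params), ac_encode(rec_b.sequence, params)])


# ---------------------------------------------------------------------------
# classifier


@dataclass
class PPIModel:
    """Trained classifier plus the training-set feature scaling.

    Binary calls use Platt-calibrated probabilities (sigmoid fitted on
    cross-validated decision values) at 0.5 rather than the raw decision
    sign: the raw margin's zero point is set by the support vectors and is
    poorly centred for points far from the training cloud, while the
    calibrated cut sits between the held-out score distributions of the
    two classes. Rankings (AUROC) use the raw decision scores.
    """

    svc: SVC
    calibrator: object  # CalibratedClassifierCV over an identical SVC
    feature_min: np.ndarray
    feature_span: np.ndarray
    params: ACParams

    def _scale(self, x: np.ndarray) -> np.ndarray:
        return 2.0 * (x - self.feature_min) / self.feature_span - 1.0

    def _features(
        self, dataset_pairs: list[tuple[str, str]], proteins: dict[str, ProteinRecord]
    ) -> tuple[np.ndarray, np.ndarray]:
        feats = np.array(
            [encode_pair(proteins[a], proteins[b], self.params) for a, b in dataset_pairs]
        )
        half = feats.shape[1] // 2
        swapped = np.hstack([feats[:, half:], feats[:, :half]])
        return self._scale(feats), self._scale(swapped)

    def decision_scores(
        self, dataset_pairs: list[tuple[str, str]], proteins: dict[str, ProteinRecord]
    ) -> np.ndarray:
        """Max decision score over both pair orientations."""
        x, x_swapped = self._features(dataset_pairs, proteins)
        return np.maximum(
            self.svc.decision_function(x), self.svc.decision_function(x_swapped)
        )

    def probabilities(
        self, dataset_pairs: list[tuple[str, str]], proteins: dict[str, ProteinRecord]
    ) -> np.ndarray:
        """Max calibrated interaction probability over both orientations."""
        x, x_swapped = self._features(dataset_pairs, proteins)
        return np.maximum(
            self.calibrator.predict_proba(x)[:, 1],
            self.calibrator.predict_proba(x_swapped)[:, 1],
        )

    def predict(
        self, dataset_pairs: list[tuple[str, str]], proteins: dict[str, ProteinRecord]
    ) -> pd.DataFrame:
        x, x_swapped = self._features(dataset_pairs, proteins)
        scores = np.maximum(
            self.svc.decision_function(x), self.svc.decision_function(x_swapped)
        )
        proba = np.maximum(
            self.calibrator.predict_proba(x)[:, 1],
            self.calibrator.predict_proba(x_swapped)[:, 1],
        )
        return pd.DataFrame(
            {
                "protein_a": [a for a, _ in dataset_pairs],
                "protein_b": [b for _, b in dataset_pairs],
                "score": scores,
                "probability": proba,
                "label": (proba > 0.5).astype(int),
            }
        )


def train_classifier(
    dataset: PPIDataset,
    proteins: dict[str, ProteinRecord],
    params: ACParams | None = None,
    grid_search: bool = False,
    seed: int = 0,
) -> PPIModel:
    """Fit the RBF SVM on AC pair features scaled per-dimension to [-1, 1].

    Every training pair enters in both orientations. With ``grid_search``,
    (c, gamma) are chosen by 5-fold cross-validation over the log2 grids
    c in 2^-5..2^15 and gamma in 2^-15..2^3; otherwise the configured
    defaults are used.
    """
    params = params or ACParams()
    labels = np.array([lab for _, _, lab in dataset.pairs])
    if len(np.unique(labels)) < 2:
        raise ValueError("training set must contain both classes")
    feats = np.array(
        [encode_pair(proteins[a], proteins[b], params) for a, b, _ in dataset.pairs]
    )
    half = feats.shape[1] // 2
    x = np.vstack([feats, np.hstack([feats[:, half:], feats[:, :half]])])
    y = np.concatenate([labels, labels])
    lo = x.min(axis=0)
    hi = x.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    x_scaled = 2.0 * (x - lo) / span - 1.0
    c, gamma = params.svm_c, params.svm_gamma
    if grid_search:
        from sklearn.model_selection import GridSearchCV, StratifiedKFold

        grid = {
            "C": [2.0**e for e in range(-5, 16)],
            "gamma": [2.0**e for e in range(-15, 4)],
        }
        cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
        search = GridSearchCV(SVC(kernel="rbf"), grid, cv=cv, scoring="roc_auc")
        search.fit(x_scaled, y)
        c, gamma = search.best_params_["C"], search.best_params_["gamma"]
    svc = SVC(kernel="rbf", C=c, gamma=gamma, random_state=seed)
    svc.fit(x_scaled, y)
    from sklearn.calibration import CalibratedClassifierCV
    from sklearn.model_selection import StratifiedKFold

    calibrator = CalibratedClassifierCV(
        SVC(kernel="rbf", C=c, gamma=gamma, random_state=seed),
        cv=StratifiedKFold(n_splits=5, shuffle=True, random_state=seed),
        ensemble=False,
    )
    calibrator.fit(x_scaled, y)
    fitted = ACParams(lag_max=params.lag_max, svm_c=c, svm_gamma=gamma)
    return PPIModel(
        svc=svc, calibrator=calibrator, feature_min=lo, feature_span=span, params=fitted
    )


# ---------------------------------------------------------------------------
# co-expression threshold and localization filters


@dataclass(frozen=True)
class AlphaThreshold:
    """Module co-expression cutoff alpha = (w_max - w_min) * 0.6 + w_mean."""

    weight_max: float
    weight_min: float
    weight_average: float

    @property
    def alpha(self) -> float:
        return (self.weight_max - self.weight_min) * 0.6 + self.weight_average


def alpha_threshold(weights) -> AlphaThreshold:
    """Compute the alpha cutoff from a collection of co-expression weights."""
    w = np.asarray(list(weights) if not isinstance(weights, np.ndarray) else weights, float)
    if w.size == 0:
        raise ValueError("empty weight set")
    return AlphaThreshold(
        weight_max=float(w.max()),
        weight_min=float(w.min()),
        weight_average=float(w.mean()),
    )


def coexpression_ppi(
    weights: dict[tuple[str, str], float], alpha: float
) -> list[tuple[str, str]]:
    """Pairs whose co-expression weight strictly exceeds alpha."""
    if not weights:
        raise ValueError("empty weight set")
    return sorted(pair for pair, w in weights.items() if w > alpha)


def colocalization_filter(
    pairs: list[tuple[str, str]],
    proteins: dict[str, ProteinRecord],
    keep_unannotated: bool = False,
) -> list[tuple[str, str]]:
    """Keep pairs whose localization sets intersect.

    Pairs with an unannotated protein are dropped unless
    ``keep_unannotated`` is set.
    """
    kept = []
    for a, b in pairs:
        la = proteins[a].localizations if a in proteins else frozenset()
        lb = proteins[b].localizations if b in proteins else frozenset()
        if not la or not lb:
            if keep_unannotated:
                kept.append((a, b))
            continue
        if la & lb:
            kept.append((a, b))
    return kept


def module_subnetwork(
    seed_genes: list[str],
    module_genes: list[str],
    adjacency: pd.DataFrame,
    model: PPIModel,
    proteins: dict[str, ProteinRecord],
    alpha_override: float | None = None,
    keep_unannotated: bool = False,
    reference_genes: list[str] | None = None,
) -> tuple[pd.DataFrame, AlphaThreshold | None]:
    """Predict a module's seed-anchored interaction sub-network.

    Co-expression weights between the seed genes and the other module
    genes are screened at alpha; the surviving seed-candidate pairs are
    classified by the SVM and the positive predictions filtered for shared
    localization. Returns the edge table and the alpha actually applied.

    Unless overridden, alpha is computed from the seed-to-
    ``reference_genes`` weights (default: the module genes). The formula
    presumes a heterogeneous weight background — on a compact distribution
    it can exceed the maximum weight and screen out everything — so when
    the module itself is small and coherent, pass the whole analyzed gene
    set as the reference.
    """
    others = [g for g in module_genes if g not in set(seed_genes)]
    reference = [
        g for g in (reference_genes if reference_genes is not None else others)
        if g not in set(seed_genes)
    ]
    weights: dict[tuple[str, str], float] = {}
    for s in seed_genes:
        for g in others:
            if s in adjacency.index and g in adjacency.columns:
                weights[(s, g)] = float(adjacency.loc[s, g])
    ref_weights = [
        float(adjacency.loc[s, g])
        for s in seed_genes
        for g in reference
        if s in adjacency.index and g in adjacency.columns
    ]
    columns = ["seed", "candidate", "weight", "score", "predicted", "colocalized"]
    if not weights or not ref_weights:
        warnings.warn("no seed-to-module weights available", stacklevel=2)
        return pd.DataFrame(columns=columns), None
    thr = alpha_threshold(np.array(ref_weights))
    alpha = thr.alpha if alpha_override is None else alpha_override
    candidates = coexpression_ppi(weights, alpha)
    if not candidates:
        warnings.warn("no candidate survives the alpha threshold", stacklevel=2)
        return pd.DataFrame(columns=columns), thr
    scored = model.predict(candidates, proteins)
    coloc = set(
        colocalization_filter(
            [tuple(p) for p in candidates], proteins, keep_unannotated=keep_unannotated
        )
    )
    edges = pd.DataFrame(
        {
            "seed": scored["protein_a"],
            "candidate": scored["protein_b"],
            "weight": [weights[(a, b)] for a, b in candidates],
            "score": scored["score"],
            "predicted": scored["label"].astype(bool),
            "colocalized": [tuple(p) in coloc for p in candidates],
        }
    )
    edges = edges[edges["predicted"] & edges["colocalized"]].reset_index(drop=True)
    return edges, thr
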