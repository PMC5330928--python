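"""Individual recognition from the {ms, ra} feature pair.

For a query/template image pair, ms is the minimum descriptor distance
over all equal-size cyclic-structure pairs and ra the skeleton overlap
ratio after affine registration on the best-matched structures.  A small
three-layer back-propagation network (2 inputs, 10 sigmoid hidden units,
2 sigmoid outputs trained toward [1 0] for "same individual" and [0 1]
for "different") separates the two classes; training stops when the mean
absolute output error drops below the error target or the iteration cap
is reached, and is restarted from several random initializations keeping
the best run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .cycles import (
    CyclicStructure,
    MatchResult,
    align_matched_pair,
    match_structures,
)
from .registration import estimate_affine, overlap_ratio, warp_skeleton
from .skeletongraph import SkeletonGraph

__all__ = [
    "RecognitionFeatures",
    "ClassifierConfig",
    "NeuralClassifier",
    "extract_features",
    "train_classifier",
    "classify",
]


@dataclass
class RecognitionFeatures:
    ms: float
    ra: float
    valid: bool = True

    def as_array(self) -> np.ndarray:
        return np.array([self.ms, self.ra], dtype=float)


@dataclass(frozen=True)
class ClassifierConfig:
    hidden_nodes: int = 10
    error_target: float = 0.01
    max_iterations: int = 500
    repeats: int = 10
    learning_rate: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.hidden_nodes, self.max_iterations, self.repeats) < 1:
            raise ValueError("all counts must be positive")
        if self.error_target <= 0 or self.learning_rate <= 0:
            raise ValueError("error_target and learning_rate must be positive")


@dataclass
class ImageArtifacts:
    """What the pipeline hands recognition: skeleton + structures."""

    skeleton: np.ndarray
    graph: SkeletonGraph            # full graph (with branches)
    structures: list[CyclicStructure]
    vectors: list[np.ndarray]


def register_by_structures(
    query: ImageArtifacts,
    template: ImageArtifacts,
    match: MatchResult,
    top_m: int = 5,
    n_candidates: int = 20,
    inlier_tol: float = 3.0,
):
    """Consensus affine from matched cyclic structures.

    Because the rib/ring network is locally self-similar, the single best
    descriptor match can be a wrong correspondence.  Each of the
    ``n_candidates`` best-matched structure pairs therefore proposes an
    affine (from its own node correspondence); proposals are scored by
    how many structure centroids of the query land within ``inlier_tol``
    pixels of a template centroid, and the winner is refit on the node
    correspondences of its ``top_m`` supporting pairs.  Returns the
    refined transform or None when no valid proposal exists.
    """
    if not match.pairs:
        return None
    cents_q = np.array([c.positions.mean(axis=0) for c in query.structures])
    cents_t = np.array([c.positions.mean(axis=0) for c in template.structures])
    best = None
    for i, j, _s in match.best_pairs(n_candidates):
        pa, pb = align_matched_pair(
            query.structures[i], template.structures[j], query.graph, template.graph
        )
        try:
            T = estimate_affine(list(zip(pa, pb)))
        except (ValueError, np.linalg.LinAlgError):
            continue
        # an individual-to-individual map is close to rigid; wildly
        # anisotropic or strongly scaling proposals are spurious
        svals = np.linalg.svd(T.linear, compute_uv=False)
        if svals.max() > 1.5 or svals.min() < 0.67:
            continue
        warped = cents_q @ T.linear.T + T.translation
        d = np.linalg.norm(warped[:, None, :] - cents_t[None, :, :], axis=2)
        inliers = int(np.sum(d.min(axis=1) < inlier_tol))
        if best is None or inliers > best[0]:
            best = (inliers, i, j, T)
    if best is None:
        return None
    T = best[3]
    # refine on the feature-point sets of all structures: nearest-neighbor
    # correspondences under the current transform, twice with a shrinking
    # gate (a light ICP step on sparse, individually noisy junctions)
    nodes_q = np.unique(
        np.vstack([c.positions for c in query.structures]), axis=0
    )
    nodes_t = np.unique(
        np.vstack([c.positions for c in template.structures]), axis=0
    )
    for gate in (inlier_tol, inlier_tol / 1.5):
        warped = nodes_q @ T.linear.T + T.translation
        d = np.linalg.norm(warped[:, None, :] - nodes_t[None, :, :], axis=2)
        nn = d.argmin(axis=1)
        keep = d[np.arange(len(nodes_q)), nn] < gate
        if keep.sum() < 3:
            break
        try:
            T = estimate_affine(list(zip(nodes_q[keep], nodes_t[nn[keep]])))
        except (ValueError, np.linalg.LinAlgError):
            break
    return T


def extract_features(
    query: ImageArtifacts,
    template: ImageArtifacts,
    tol: float = 1.0,
    top_m: int = 5,
) -> RecognitionFeatures:
    """{ms, ra} between a query image and an individual's template.

    ms is the minimum descriptor distance over all equal-size structure
    pairs; ra the skeleton overlap after the consensus affine estimated
    from the matched structures.  When no equal-size structures exist or
    no usable transform can be built, the features come back flagged
    invalid (ms = inf, ra = 0) and should be excluded from training.
    """
    match = match_structures(query.vectors, template.vectors)
    if not match.valid:
        return RecognitionFeatures(ms=np.inf, ra=0.0, valid=False)
    T = register_by_structures(query, template, match, top_m=top_m)
    if T is None:
        return RecognitionFeatures(ms=float(match.ms), ra=0.0, valid=False)
    warped = warp_skeleton(query.skeleton, T, target_shape=template.skeleton.shape)
    ov = overlap_ratio(warped, template.skeleton, tol=tol)
    return RecognitionFeatures(ms=float(match.ms), ra=float(ov.ra), valid=ov.valid)


# ---------------------------------------------------------------------------
# Three-layer BP network


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class NeuralClassifier:
    """2 -> hidden -> 2 sigmoid network with z-score input normalization."""

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    training_error: float = np.inf

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        Z = (X - self.mean) / self.std
        H = _sigmoid(Z @ self.w1 + self.b1)
        return H, _sigmoid(H @ self.w2 + self.b2)

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        return self.forward(np.atleast_2d(X))[1]

    def to_json(self) -> str:
        return json.dumps(
            {
                k: getattr(self, k).tolist()
                for k in ("w1", "b1", "w2", "b2", "mean", "std")
            }
            | {"training_error": float(self.training_error)}
        )

    @classmethod
    def from_json(cls, text: str) -> "NeuralClassifier":
        d = json.loads(text)
        return cls(
            **{k: np.asarray(d[k]) for k in ("w1", "b1", "w2", "b2", "mean", "std")},
            training_error=d["training_error"],
        )


def _train_once(
    X: np.ndarray,
    Y: np.ndarray,
    mean: np.ndarray,
    std: np.ndarray,
    cfg: ClassifierConfig,
    rng: np.random.Generator,
) -> NeuralClassifier:
    n_in = X.shape[1]
    w1 = rng.normal(0.0, 0.5, size=(n_in, cfg.hidden_nodes))
    b1 = np.zeros(cfg.hidden_nodes)
    w2 = rng.normal(0.0, 0.5, size=(cfg.hidden_nodes, 2))
    b2 = np.zeros(2)
    model = NeuralClassifier(w1, b1, w2, b2, mean, std)
    Z = (X - mean) / std
    lr = cfg.learning_rate
    for _ in range(cfg.max_iterations):
        H = _sigmoid(Z @ model.w1 + model.b1)
        O = _sigmoid(H @ model.w2 + model.b2)
        err = O - Y
        model.training_error = float(np.mean(np.abs(err)))
        if model.training_error < cfg.error_target:
            break
        # backprop of the mean-squared error through the sigmoids
        dO = err * O * (1 - O)
        dH = (dO @ model.w2.T) * H * (1 - H)
        model.w2 -= lr * H.T @ dO / len(X)
        model.b2 -= lr * dO.mean(axis=0)
        model.w1 -= lr * Z.T @ dH / len(X)
        model.b1 -= lr * dH.mean(axis=0)
    return model


def train_classifier(
    C1: list[RecognitionFeatures] | np.ndarray,
    C2: list[RecognitionFeatures] | np.ndarray,
    cfg: ClassifierConfig = ClassifierConfig(),
) -> NeuralClassifier:
    """Train on same-individual (C1) vs different-individual (C2) features.

    Invalid feature pairs are dropped; features are standardized with the
    training statistics; the network is trained ``cfg.repeats`` times from
    fresh random initializations and the run with the lowest training
    error is kept.  Deterministic under ``cfg.seed``.
    """

    def to_matrix(rows) -> np.ndarray:
        if isinstance(rows, np.ndarray):
            return np.atleast_2d(rows.astype(float))
        return np.array([r.as_array() for r in rows if r.valid], dtype=float)

    X1, X2 = to_matrix(C1), to_matrix(C2)
    if len(X1) == 0 or len(X2) == 0:
        raise ValueError("both feature classes must be nonempty")
    X = np.vstack([X1, X2])
    Y = np.vstack(
        [np.tile([1.0, 0.0], (len(X1), 1)), np.tile([0.0, 1.0], (len(X2), 1))]
    )
    std = X.std(axis=0)
    if np.any(std == 0):
        raise ValueError("degenerate (constant) feature dimension")
    mean = X.mean(axis=0)
    rng = np.random.default_rng(cfg.seed)
    best: NeuralClassifier | None = None
    for _ in range(cfg.repeats):
        model = _train_once(X, Y, mean, std, cfg, rng)
        if best is None or model.training_error < best.training_error:
            best = model
    return best


def classify(
    model: NeuralClassifier, feats: RecognitionFeatures | np.ndarray
) -> tuple[str, np.ndarray]:
    """Label a feature pair as "same" or "different" individual."""
    if isinstance(feats, RecognitionFeatures):
        if not feats.valid:
            raise ValueError("cannot classify invalid features")
        x = feats.as_array()
    else:
        x = np.asarray(feats, dtype=float)
    scores = model.predict_scores(x)[0]
    label = "same" if scores[0] >= scores[1] else "different"
    return label, scores
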