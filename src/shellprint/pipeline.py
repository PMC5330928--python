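"""Pipeline orchestration: enhance -> decompose -> segment -> graph ->
cycles -> describe, with per-stage artifacts, manifests, and the pairwise
image-comparison workflow that produces the {ms, ra} features.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from . import cycles, enhancement, multiscale, recognition, registration
from . import skeletongraph as sg
from .enhancement import MFGKParams
from .multiscale import TVDecompositionParams
from .recognition import ImageArtifacts

logger = logging.getLogger("shellprint")

__all__ = [
    "PipelineConfig",
    "StageError",
    "load_image",
    "extract_artifacts",
    "run_pipeline",
    "compare_images",
]


class StageError(RuntimeError):
    """Failure of one pipeline stage, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the end-to-end run, JSON round-trippable."""

    mfgk: MFGKParams = field(default_factory=MFGKParams)
    tv: TVDecompositionParams = field(default_factory=TVDecompositionParams)
    binarize: str = "positive"
    min_pixels: int = 20
    closing_radius: int = 1
    min_spur: float = 5.0
    scale_index: int | None = None     # None = finest level
    max_cycle_len: int = 6
    overlap_tol: float = 1.0
    top_m_matches: int = 5
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        d["mfgk"] = MFGKParams(
            **{**d["mfgk"], "theta_set": tuple(d["mfgk"]["theta_set"])}
        )
        d["tv"] = TVDecompositionParams(**d["tv"])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def load_image(path: str | Path) -> np.ndarray:
    """Read PNG/TIFF/JPEG as float luminance in [0, 1]."""
    try:
        arr = iio.imread(path)
    except Exception as exc:  # corrupt/missing file
        raise StageError("read", f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 3:
        arr = arr[..., :3] @ np.array([0.2126, 0.7152, 0.0722])
    if arr.max() > 1.5:
        arr = arr / 255.0
    return arr


def extract_artifacts(
    img: np.ndarray, config: PipelineConfig, scale_index: int | None = None
) -> ImageArtifacts:
    """Run one image through enhancement, decomposition, skeletonization,
    graph construction and SDFS, returning the matchable artifacts."""
    t0 = time.perf_counter()
    resp = enhancement.mfgk_response(img, config.mfgk)
    f = enhancement.normalize_response(resp)
    stack = multiscale.hierarchical_decompose(f, config.tv, binarize=config.binarize)
    k = scale_index if scale_index is not None else config.scale_index
    if k is None:
        k = len(stack.levels) - 1
    mask = stack.levels[k].binary
    mask = multiscale.clean_components(mask, config.min_pixels)
    mask = multiscale.fill_holes(mask, config.closing_radius)
    skel = sg.skeletonize(mask)
    feats = sg.detect_feature_points(skel)
    graph = sg.build_graph(skel, feats, min_spur=config.min_spur)
    pruned = sg.prune_to_cycle_graph(graph)
    structs = cycles.sdfs_cycles(pruned, config.max_cycle_len)
    vectors = [cycles.describe_cycle(c, graph) for c in structs]
    logger.info(
        "extracted %d structures at scale k=%d in %.2fs",
        len(structs), k, time.perf_counter() - t0,
    )
    return ImageArtifacts(skeleton=skel, graph=graph, structures=structs, vectors=vectors)


def extract_multiscale_artifacts(
    img: np.ndarray, config: PipelineConfig, scale_indices: list[int]
) -> dict[int, ImageArtifacts]:
    """Artifacts at several scales sharing one enhancement/decomposition."""
    resp = enhancement.mfgk_response(img, config.mfgk)
    f = enhancement.normalize_response(resp)
    stack = multiscale.hierarchical_decompose(f, config.tv, binarize=config.binarize)
    out: dict[int, ImageArtifacts] = {}
    for k in scale_indices:
        mask = multiscale.fill_holes(
            multiscale.clean_components(stack.levels[k].binary, config.min_pixels),
            config.closing_radius,
        )
        skel = sg.skeletonize(mask)
        feats = sg.detect_feature_points(skel)
        graph = sg.build_graph(skel, feats, min_spur=config.min_spur)
        pruned = sg.prune_to_cycle_graph(graph)
        structs = cycles.sdfs_cycles(pruned, config.max_cycle_len)
        vectors = [cycles.describe_cycle(c, graph) for c in structs]
        out[k] = ImageArtifacts(
            skeleton=skel, graph=graph, structures=structs, vectors=vectors
        )
    return out


def recognition_experiment(
    base_spec,
    config: PipelineConfig,
    n_individuals: int = 10,
    n_images: int = 4,
    scale_indices: tuple[int, ...] = (3, 4, 5),
    master_seed: int = 0,
    classifier_cfg=None,
) -> dict:
    """End-to-end individual-recognition study on synthetic individuals.

    Per individual, half the images train and half test; the first
    training image is the individual's template.  Training features are
    {ms, ra} of the remaining training images against their own template
    (class C1) and against every other template (class C2).  Test
    accuracy is measured over every (held-out image, template) pair — a
    pair should classify "same" exactly when the template belongs to the
    image's individual; pairs with invalid features count as "different".
    Returns per-scale accuracies keyed by scale index.
    """
    from . import synthetic
    from .recognition import ClassifierConfig, classify, train_classifier

    if classifier_cfg is None:
        classifier_cfg = ClassifierConfig(seed=master_seed)
    images = synthetic.generate_individual_set(
        base_spec, n_individuals, n_images, master_seed=master_seed
    )
    per_image = [
        (ind, extract_multiscale_artifacts(ph.image, config, list(scale_indices)))
        for ind, ph in images
    ]
    n_train = n_images // 2
    accuracies: dict[int, float] = {}
    for k in scale_indices:
        by_ind: dict[int, list] = {}
        for ind, arts in per_image:
            by_ind.setdefault(ind, []).append(arts[k])
        templates = {ind: arts_list[0] for ind, arts_list in by_ind.items()}
        C1, C2 = [], []
        for ind, arts_list in by_ind.items():
            for art in arts_list[1:n_train]:
                C1.append(recognition.extract_features(art, templates[ind],
                                                       tol=config.overlap_tol,
                                                       top_m=config.top_m_matches))
            for other, tmpl in templates.items():
                if other != ind:
                    for art in arts_list[1:n_train]:
                        C2.append(recognition.extract_features(art, tmpl,
                                                               tol=config.overlap_tol,
                                                               top_m=config.top_m_matches))
        try:
            model = recognition.train_classifier(C1, C2, classifier_cfg)
        except ValueError:
            # a scale too coarse to yield structures cannot verify any
            # query; every pair then defaults to "different"
            model = None
        n_correct = 0
        n_total = 0
        for ind, arts_list in by_ind.items():
            for art in arts_list[n_train:]:
                for other, tmpl in templates.items():
                    feats = recognition.extract_features(
                        art, tmpl, tol=config.overlap_tol, top_m=config.top_m_matches
                    )
                    want = "same" if other == ind else "different"
                    if model is None or not feats.valid:
                        got = "different"
                    else:
                        got, _ = classify(model, feats)
                    n_correct += got == want
                    n_total += 1
        accuracies[k] = n_correct / n_total
    return {"accuracy_by_scale": accuracies, "n_pairs_tested": n_total}


def _structures_record(art: ImageArtifacts) -> list[dict]:
    return [
        {
            "n": c.n,
            "nodes": [int(n) for n in c.node_ids],
            "positions": c.positions.tolist(),
            "vector": v.tolist(),
        }
        for c, v in zip(art.structures, art.vectors)
    ]


def run_pipeline(image_path: str | Path, config: PipelineConfig, out_dir: str | Path) -> dict:
    """Full single-image run, writing every intermediate plus a manifest.

    Outputs (all deterministic for a fixed config): the normalized
    response as float TIFF, per-level binary masks and skeletons as PNG,
    and the cyclic structures with their descriptors as JSON.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img = load_image(image_path)
    manifest: dict = {
        "input": str(image_path),
        "config": json.loads(config.to_json()),
        "config_hash": config.config_hash(),
        "artifacts": [],
    }

    def save_png(name: str, arr: np.ndarray) -> None:
        iio.imwrite(out / name, (arr.astype(np.uint8) * 255))
        manifest["artifacts"].append(name)

    try:
        resp = enhancement.mfgk_response(img, config.mfgk)
        f = enhancement.normalize_response(resp)
    except Exception as exc:
        raise StageError("enhance", str(exc)) from exc
    iio.imwrite(out / "response.tif", f.astype(np.float32))
    manifest["artifacts"].append("response.tif")

    try:
        stack = multiscale.hierarchical_decompose(f, config.tv, binarize=config.binarize)
    except Exception as exc:
        raise StageError("decompose", str(exc)) from exc

    records = []
    for k, level in enumerate(stack.levels):
        mask = multiscale.fill_holes(
            multiscale.clean_components(level.binary, config.min_pixels),
            config.closing_radius,
        )
        skel = sg.skeletonize(mask)
        save_png(f"mask_k{k}.png", mask)
        save_png(f"skeleton_k{k}.png", skel)
        try:
            feats = sg.detect_feature_points(skel)
            graph = sg.build_graph(skel, feats, min_spur=config.min_spur)
            pruned = sg.prune_to_cycle_graph(graph)
            structs = cycles.sdfs_cycles(pruned, config.max_cycle_len)
            vectors = [cycles.describe_cycle(c, graph) for c in structs]
        except Exception as exc:
            raise StageError("cycles", f"level {k}: {exc}") from exc
        records.append(
            {
                "level": k,
                "lambda": level.lam,
                "display_index": k + 1,  # reported 1-based as lambda_1..K+1
                "n_structures": len(structs),
                "structures": _structures_record(
                    ImageArtifacts(skel, graph, structs, vectors)
                ),
            }
        )
    (out / "cycles.json").write_text(json.dumps(records, indent=1, sort_keys=True))
    manifest["artifacts"].append("cycles.json")
    manifest["n_levels"] = len(stack.levels)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def compare_images(
    path_a: str | Path, path_b: str | Path, config: PipelineConfig
) -> dict:
    """Pairwise workflow: features, transform, and the mosaic overlay."""
    img_a = load_image(path_a)
    img_b = load_image(path_b)
    side = (
        max(img_a.shape[0], img_b.shape[0]),
        max(img_a.shape[1], img_b.shape[1]),
    )
    img_a = np.pad(img_a, ((0, side[0] - img_a.shape[0]), (0, side[1] - img_a.shape[1])))
    img_b = np.pad(img_b, ((0, side[0] - img_b.shape[0]), (0, side[1] - img_b.shape[1])))
    art_a = extract_artifacts(img_a, config)
    art_b = extract_artifacts(img_b, config)
    feats = recognition.extract_features(
        art_a, art_b, tol=config.overlap_tol, top_m=config.top_m_matches
    )
    mosaic = np.zeros((*side, 3), dtype=np.uint8)
    mosaic[..., 0] = art_b.skeleton * 255
    match = cycles.match_structures(art_a.vectors, art_b.vectors)
    transform = None
    if feats.valid:
        pts = []
        for i, j, _ in match.best_pairs(config.top_m_matches):
            pa, pb = cycles.align_matched_pair(
                art_a.structures[i], art_b.structures[j], art_a.graph, art_b.graph
            )
            pts.extend(zip(pa, pb))
        transform = registration.estimate_affine(pts)
        warped = registration.warp_skeleton(art_a.skeleton, transform, side)
        mosaic[..., 1] = warped * 255
    return {
        "features": feats,
        "transform": transform,
        "mosaic": mosaic,
        "match": match,
    }
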