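"""Reference experiments: self-contained, seeded end-to-end checks.

Each function regenerates its inputs from a seed, runs the relevant part
of the pipeline, and returns measured quantities.  They serve the
verification suite and the reproduction script; nothing here reads
external data.
"""

from __future__ import annotations

import numpy as np

from . import metrics, ncrf, patches, postprocess, quantify, synthetic
from .annotations import (annotation_set_from_mask, mask_to_contours,
                          parse_imagescope_xml, write_imagescope_xml)
from .classifier import ArchSpec, TrainConfig, train_classifier
from .inference import (InferenceConfig, LabelMask, MaskOracleClassifier,
                        sliding_window_predict)
from .synthetic import BACKGROUND, GM, WM

#: patch counts of the reference training corpus (about 310k GM patches,
#: 100k WM, 300k background), whose inverse frequencies give the 1:3:1
#: class-weight ratio
REFERENCE_PATCH_COUNTS = {"GM": 310_000, "WM": 100_000,
                          "background": 300_000}


def class_weight_recovery() -> dict:
    """Inverse-frequency weights of the reference corpus, and the rounded
    GM:WM:background ratio."""
    w = patches.compute_class_weights(REFERENCE_PATCH_COUNTS)
    return {"w_gm": w.w_gm, "w_wm": w.w_wm, "w_background": w.w_background,
            "rounded_ratio": (round(w.w_gm), round(w.w_wm),
                              round(w.w_background))}


def _random_obs(rng, g, scale=1.5):
    n = g * g
    return ncrf.PatchGridObservation(
        grid_shape=(g, g), embeddings=rng.normal(size=(n, 6)),
        unary_scores=scale * rng.normal(size=(n, 3)))


def meanfield_decoupled_max_error(seed: int, per_grid: int = 5) -> float:
    """Max |Q - exact| with zero pairwise weights over grids with N <= 9."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for g in (1, 2, 3):
        for _ in range(per_grid):
            obs = _random_obs(rng, g)
            w = np.zeros((obs.n, obs.n))
            mf = ncrf.meanfield_infer(obs, w)
            exact = ncrf.exact_marginals_bruteforce(obs, w)
            worst = max(worst, float(np.abs(mf.q - exact.q).max()))
    return worst


def kl_monotonicity(seed: int, n_instances: int = 20) -> dict:
    """KL(Q || P) across sequential sweeps vs the enumerated Gibbs joint.

    Returns the worst (most positive) KL increase over consecutive sweeps
    and the number of instances with any increase beyond 1e-9.
    """
    rng = np.random.default_rng(seed)
    worst_increase = -np.inf
    violations = 0
    for k in range(n_instances):
        g = 2 if k % 2 == 0 else 3
        obs = _random_obs(rng, g)
        w = ncrf.grid_pairwise_weights((g, g), float(rng.uniform(0.2, 2.0)))
        _, assignments, p = ncrf.exact_marginals_bruteforce(
            obs, w, return_joint=True)
        kls = []
        for sweeps in range(1, 5):
            field = ncrf.meanfield_infer(obs, w, max_sweeps=sweeps, tol=0.0)
            q_joint = np.prod(field.q[np.arange(obs.n), assignments], axis=1)
            kls.append(float(np.sum(
                q_joint * (np.log(q_joint + 1e-300) - np.log(p + 1e-300)))))
        inc = max(b - a for a, b in zip(kls, kls[1:]))
        worst_increase = max(worst_increase, inc)
        if inc > 1e-9:
            violations += 1
    return {"worst_increase": worst_increase, "violations": violations,
            "n_instances": n_instances}


def _slide(seed: int, size: int = 640, **overrides) -> synthetic.SyntheticSample:
    spec = synthetic.SyntheticSpec(image_width=size, image_height=size,
                                   region_layout_seed=seed, rng_seed=seed,
                                   **overrides)
    return synthetic.generate_tissue_sample(spec)


def reconstruction_exactness(seed: int, n_slides: int = 5,
                             strides=(64, 128, 256)) -> dict:
    """Oracle-classifier sliding window vs direct mask subsampling."""
    mismatches = 0
    checked = 0
    for k in range(n_slides):
        sample = _slide(seed + k)
        oracle = MaskOracleClassifier(sample.mask)
        h, w = sample.mask.shape
        for stride in strides:
            cfg = InferenceConfig(patch_size=256, stride=stride)
            out = sliding_window_predict(sample.image, oracle, cfg)
            ny, nx = -(-h // stride), -(-w // stride)
            grid = np.empty((ny, nx), dtype=sample.mask.dtype)
            for ky in range(ny):
                for kx in range(nx):
                    cy = min(ky * stride + stride // 2, h - 1)
                    cx = min(kx * stride + stride // 2, w - 1)
                    grid[ky, kx] = sample.mask[cy, cx]
            expected = np.repeat(np.repeat(grid, stride, 0),
                                 stride, 1)[:h, :w]
            mismatches += int(np.count_nonzero(out.labels != expected))
            checked += out.labels.size
    return {"mismatching_pixels": mismatches, "pixels_checked": checked}


def postprocess_boundary_behavior(seed: int) -> dict:
    """The stated strict area thresholds, probed at +/-1 px, plus residue
    removal of a detached 2%-area fragment and clean-mask idempotence."""
    n = 2048
    base = np.zeros((n, n), dtype=np.uint8)
    base[256:1152] = GM
    base[1152:1792] = WM
    out = {}

    def planted(area):
        w_ds = 500
        h_ds = area // w_ds
        rem = area - w_ds * h_ds
        small = np.zeros((n // 4, n // 4), dtype=bool)
        small[8:8 + h_ds, 4:4 + w_ds] = True
        if rem:
            small[8 + h_ds, 4:4 + rem] = True
        labels = base.copy()
        full = np.repeat(np.repeat(small, 4, 0), 4, 1)
        labels[full] = WM
        refined = postprocess.refine_mask(LabelMask(labels=labels))
        return bool(np.any(refined.labels[full] == WM))

    out["component_19999_removed"] = not planted(19_999)
    out["component_20001_kept"] = planted(20_001)

    sample = _slide(seed, size=n, plaque_rates={})
    frag_area = int(0.02 * n * n)
    with_frag = synthetic.inject_artifacts(
        sample, [("fragment", frag_area, None)], seed=seed)
    labels = sample.mask.copy()
    frag = np.array(list(with_frag.artifacts[0]))
    labels[frag[:, 0], frag[:, 1]] = GM     # predictor fooled by the fragment
    refined = postprocess.refine_mask(LabelMask(labels=labels))
    out["artifact_fragment_removed"] = bool(
        np.all(refined.labels[frag[:, 0], frag[:, 1]] == BACKGROUND))

    clean = postprocess.refine_mask(LabelMask(labels=base))
    f = 4
    roundtrip = np.repeat(np.repeat(base[::f, ::f], f, 0), f, 1)
    out["clean_mask_fixed_point"] = bool(
        np.array_equal(clean.labels, roundtrip))
    return out


def metric_identity_max_error(seed: int, n_pairs: int = 100) -> float:
    """max |DICE - 2 IoU/(1+IoU)| and |F1 - DICE| over random mask pairs."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_pairs):
        pred = rng.integers(0, 3, size=(24, 24))
        truth = rng.integers(0, 3, size=(24, 24))
        for cls in range(3):
            i = metrics.iou(pred, truth, cls)
            d = metrics.dice(pred, truth, cls)
            worst = max(worst, abs(d - 2 * i / (1 + i)),
                        abs(metrics.f1(pred, truth, cls) - d))
    return worst


def _separated_slide(seed: int, min_separation: float = 33.0):
    """A slide whose deposits are pairwise farther apart than the bound."""
    rates = {("cored", "GM"): 5.0, ("cored", "WM"): 2.0,
             ("diffuse", "GM"): 4.0, ("CAA", "WM"): 1.0}
    for attempt in range(200):
        sample = _slide(seed + 1000 * attempt, plaque_rates=rates)
        pts = np.array([(x, y) for x, y, _ in sample.plaques], dtype=float)
        if len(pts) == 0:
            continue
        if len(pts) == 1:
            return sample
        d = np.sqrt(((pts[None] - pts[:, None]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        if d.min() > min_separation:
            return sample
    raise RuntimeError("could not draw a separated plaque layout")


def quantification_recovery(seed: int, n_slides: int = 5) -> dict:
    """Blob-mode counts with oracle detector and oracle segmentation vs
    the generator's planted ground truth, per (type, region)."""
    total_err = 0
    total_true = 0
    for k in range(n_slides):
        sample = _separated_slide(seed + k)
        oracle = quantify.PlaqueOracle(sample, stride=16)
        g = LabelMask(labels=sample.mask)
        got = quantify.quantify_plaques(sample.image, oracle, g,
                                        mode="blob", stride=16)
        truth = {(t, r): 0 for t in synthetic.PLAQUE_TYPES
                 for r in ("GM", "WM")}
        for x, y, t in sample.plaques:
            region = "GM" if sample.mask[y, x] == GM else "WM"
            truth[(t, region)] += 1
        total_err += sum(abs(got.counts[key] - truth[key])
                         for key in truth)
        total_true += sum(truth.values())
    return {"count_error": total_err, "true_total": total_true}


def xml_roundtrip(seed: int, n_slides: int = 5, tmp_dir=None) -> dict:
    """write -> parse identity on synthetic-mask annotation sets, plus the
    rectangle polygon-area sanity check."""
    import tempfile
    from pathlib import Path
    own = tmp_dir is None
    tmp = Path(tmp_dir) if tmp_dir else Path(tempfile.mkdtemp())
    vertex_mismatch = 0
    region_mismatch = 0
    for k in range(n_slides):
        sample = _slide(seed + k, size=512)
        mask = LabelMask(labels=sample.mask)
        ann = annotation_set_from_mask(mask, decimation=1)
        path = tmp / f"slide_{k}.xml"
        write_imagescope_xml(ann, path)
        back = parse_imagescope_xml(path)
        if len(back.regions) != len(ann.regions):
            region_mismatch += 1
            continue
        for (c1, p1), (c2, p2) in zip(ann.regions, back.regions):
            if c1 != c2 or len(p1) != len(p2):
                region_mismatch += 1
            else:
                vertex_mismatch += int(
                    np.abs(np.rint(p1) - p2).max() > 0)

    rect = np.zeros((64, 100), dtype=np.uint8)
    rect[10:40, 20:70] = GM
    poly = mask_to_contours(LabelMask(labels=rect), GM)[0]
    x, y = poly[:, 0], poly[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    component = float(np.count_nonzero(rect == GM))
    band = 2 * (30 + 50) + 4
    return {"region_mismatches": region_mismatch,
            "vertex_mismatches": vertex_mismatch,
            "rect_area_error": abs(area - component),
            "rect_area_band": band}


def end_to_end_run(seed: int, slide_size: int = 1024, n_patches: int = 1500,
                   max_epochs: int = 10) -> dict:
    """Train the tiny classifier on one synthetic slide, segment a
    held-out slide, refine, and score: the full desk-scale pipeline."""
    train_sample = _slide(seed, size=slide_size)
    heldout = _slide(seed + 500, size=slide_size)

    pool = patches.sample_training_patches(train_sample, n=n_patches,
                                           size=256, seed=seed)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pool))
    cut = int(0.8 * len(pool))
    train_split = [pool[i] for i in order[:cut]]
    val_split = [pool[i] for i in order[cut:]]
    counts = {c: max(1, sum(p.label == c for p in train_split))
              for c in (0, 1, 2)}
    cfg = TrainConfig(class_weights=patches.compute_class_weights(counts),
                      max_epochs=max_epochs, seed=seed)
    model, log = train_classifier(train_split, val_split, cfg, ArchSpec())
    val_acc = max(e["val_acc"] for e in log)

    out = sliding_window_predict(heldout.image, model,
                                 InferenceConfig(patch_size=256, stride=128))
    params = postprocess.scaled_params(heldout.mask.shape)
    refined = postprocess.refine_mask(out, params)
    report = metrics.evaluate_mask(refined, heldout.mask)
    return {"val_acc": float(val_acc), "mean_iou": float(report.mean_iou),
            "fw_iou": float(report.fw_iou),
            "raw_mean_iou": float(
                metrics.evaluate_mask(out, heldout.mask).mean_iou)}


def ncrf_consistency(seed: int, n_slides: int = 3) -> dict:
    """Zero-coupling CRF path vs the plain path, bit for bit."""
    mismatches = 0
    for k in range(n_slides):
        sample = _slide(seed + k)
        oracle = MaskOracleClassifier(sample.mask)
        plain = sliding_window_predict(
            sample.image, oracle, InferenceConfig(stride=128))
        smoothed = sliding_window_predict(
            sample.image, oracle,
            InferenceConfig(stride=128, use_ncrf=True, pairwise_weight=0.0))
        mismatches += int(
            np.count_nonzero(plain.labels != smoothed.labels))
    return {"mismatching_pixels": mismatches}
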