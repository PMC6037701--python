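"""Seeded generator of synthetic fluorescence time-lapse stacks.

Emulates the morphology classes seen when annexins act on supported
membrane patches with free edges, with exact ground truth attached:

``cooperative_roll``
    a rolling front sweeps inward from a few nucleation points on the
    patch edge; cumulative swept area follows a logistic in time and the
    swept intensity is re-deposited in a bright band at the front, so the
    integrated (noiseless) intensity is conserved exactly.
``fragmented_roll``
    many thin fingers advance from edge points with jittered speeds and
    occasional branching; the same conservation rule applies at the
    finger tips.
``lens_coarsening``
    bright dots nucleate near the patch edge, random-walk, and coalesce
    on contact while the patch shrinks proportionally, conserving the
    summed intensity.
``static``
    a constant scene (negative control).

The generator is kinematic by design: the energetics of rolling live in
:mod:`anxmorph.roll`; here only the observable image phenomenology is
reproduced so that the measurement pipeline can be validated against
known ground truth.  Identical spec + seed produce bit-identical stacks.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage import draw

from .dynamics import ImageStack, save_stack

__all__ = ["SceneSpec", "GroundTruth", "generate", "fixture_suite", "MODES"]

MODES = ("cooperative_roll", "fragmented_roll", "lens_coarsening", "static")


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic scene.

    Defaults mirror the imaging conditions the generator emulates:
    128 x 128 px at 0.4 um/px, 10 frames/s, a ~36 um irregular patch,
    and signal-scaled Gaussian noise (sd = alpha*sqrt(signal) + beta)
    approximating shot plus read noise.
    """

    mode: str = "cooperative_roll"
    shape: tuple[int, int] = (128, 128)
    pixel_size_um: float = 0.4
    frame_interval_s: float = 0.1
    n_frames: int | None = None  # None: auto from tau (>= 60)
    patch_vertices: tuple[tuple[float, float], ...] | None = None  # None: seeded blob
    background_level: float = 10.0
    primary_level: float = 30.0
    patch_level: float = 100.0
    band_width_px: float = 1.6  # ~0.64 um at 0.4 um/px, the AFM-scale roll diameter
    tau_true_s: float = 0.7
    t0_s: float | None = None  # None: max(1 s, 2.5 tau)
    n_nucleation_sites: int = 3
    finger_width_px: float = 1.5
    branch_prob: float = 0.05
    lens_area_fraction: float = 0.3
    noise_alpha: float = 0.5
    noise_beta: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if not (self.background_level < self.primary_level < self.patch_level):
            raise ValueError("require background < primary < patch intensity levels")
        if self.mode in ("cooperative_roll", "fragmented_roll") and not self.tau_true_s > 0:
            raise ValueError("tau_true_s must be > 0 for rolling modes")
        if self.n_nucleation_sites < 1:
            raise ValueError("need at least one nucleation site")

    @property
    def t0(self) -> float:
        return self.t0_s if self.t0_s is not None else max(1.0, 2.5 * self.tau_true_s)

    @property
    def T(self) -> int:
        if self.n_frames is not None:
            return self.n_frames
        # run to t0 + 9 tau so the logistic has genuinely plateaued
        return max(60, int(math.ceil((self.t0 + 9.0 * self.tau_true_s) / self.frame_interval_s)) + 1)

    @property
    def pixel_size(self) -> float:
        return self.pixel_size_um * 1e-6


@dataclass
class GroundTruth:
    """Exact per-frame ground truth attached to a synthetic stack."""

    swept_masks: np.ndarray  # (T, H, W) bool
    cumulative_area: np.ndarray  # m^2, length T
    tau_true: float | None
    t0: float | None
    integrated_intensity: np.ndarray  # noiseless, length T
    patch_area: float  # m^2

    def __post_init__(self) -> None:
        if np.any(np.diff(self.cumulative_area) < 0):
            raise ValueError("ground-truth cumulative area must be non-decreasing")
        I = self.integrated_intensity
        if np.max(np.abs(I - I[0])) > 1e-9 * abs(I[0]):
            raise ValueError("noiseless integrated intensity must be conserved")


def _default_patch(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.patch_vertices is not None:
        verts = np.asarray(spec.patch_vertices, dtype=float)
    else:
        h, w = spec.shape
        ang = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        rad = 0.35 * min(h, w) * (1.0 + 0.15 * rng.uniform(-1, 1, ang.size))
        verts = np.stack([h / 2 + rad * np.sin(ang), w / 2 + rad * np.cos(ang)], axis=1)
    mask = np.zeros(spec.shape, bool)
    rr, cc = draw.polygon(verts[:, 0], verts[:, 1], shape=spec.shape)
    mask[rr, cc] = True
    if not mask.any():
        raise ValueError("patch mask is empty")
    return mask


def _edge_pixels(mask: np.ndarray) -> np.ndarray:
    from scipy import ndimage

    inner = ndimage.binary_erosion(mask)
    return np.argwhere(mask & ~inner)


def _gaussian_stamp(frame: np.ndarray, pos: np.ndarray, amount: float, sigma: float) -> None:
    """Add ``amount`` (integral) at float position ``pos`` as a clipped,
    renormalized Gaussian spot; conserves the added total exactly."""
    h, w = frame.shape
    r = int(3 * sigma) + 1
    r0, r1 = int(pos[0]) - r, int(pos[0]) + r + 1
    c0, c1 = int(pos[1]) - r, int(pos[1]) + r + 1
    r0, r1 = max(r0, 0), min(r1, h)
    c0, c1 = max(c0, 0), min(c1, w)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    g = np.exp(-((yy - pos[0]) ** 2 + (xx - pos[1]) ** 2) / (2 * sigma**2))
    s = g.sum()
    if s == 0:
        frame[min(max(int(pos[0]), 0), h - 1), min(max(int(pos[1]), 0), w - 1)] += amount
        return
    frame[r0:r1, c0:c1] += amount * g / s


def generate(spec: SceneSpec) -> tuple[ImageStack, GroundTruth]:
    """Render a synthetic stack and its exact ground truth.

    Noise (seeded, applied last) is the only stochastic layer on top of
    the deterministic noiseless scene; the ground truth describes the
    noiseless scene.
    """
    rng = np.random.default_rng(spec.seed)
    patch = _default_patch(spec, rng)
    T = spec.T
    t_grid = np.arange(T) * spec.frame_interval_s
    excess = spec.patch_level - spec.primary_level

    noiseless = np.empty((T, *spec.shape))
    swept_masks = np.zeros((T, *spec.shape), bool)

    if spec.mode == "static":
        frame = np.full(spec.shape, spec.primary_level)
        frame[patch] = spec.patch_level
        noiseless[:] = frame
    elif spec.mode == "cooperative_roll":
        _render_cooperative(spec, rng, patch, t_grid, noiseless, swept_masks, excess)
    elif spec.mode == "fragmented_roll":
        _render_fragmented(spec, rng, patch, t_grid, noiseless, swept_masks, excess)
    else:
        _render_lenses(spec, rng, patch, noiseless, swept_masks, excess)

    integrated = noiseless.sum(axis=(1, 2))
    px_area = spec.pixel_size**2
    gt = GroundTruth(
        swept_masks=swept_masks,
        cumulative_area=swept_masks.sum(axis=(1, 2)) * px_area,
        tau_true=spec.tau_true_s if spec.mode in ("cooperative_roll", "fragmented_roll") else None,
        t0=spec.t0 if spec.mode == "cooperative_roll" else None,
        integrated_intensity=integrated,
        patch_area=float(patch.sum()) * px_area,
    )
    frames = noiseless
    if spec.noise_alpha > 0 or spec.noise_beta > 0:
        sd = spec.noise_alpha * np.sqrt(np.clip(noiseless, 0, None)) + spec.noise_beta
        frames = noiseless + rng.standard_normal(noiseless.shape) * sd
        frames = np.clip(frames, 0.0, None)
    stack = ImageStack(
        frames=frames,
        pixel_size=spec.pixel_size,
        frame_interval=spec.frame_interval_s,
        ground_truth=gt,
    )
    return stack, gt


def _render_cooperative(spec, rng, patch, t_grid, noiseless, swept_masks, excess):
    edge = _edge_pixels(patch)
    sites = edge[rng.choice(edge.shape[0], size=spec.n_nucleation_sites, replace=False)]
    pix = np.argwhere(patch)
    dists = np.sqrt(
        ((pix[:, None, :] - sites[None, :, :]) ** 2).sum(axis=2)
    ).min(axis=1)
    order = np.argsort(dists, kind="stable")
    phi_sorted = dists[order]
    N = pix.shape[0]
    base = np.full(spec.shape, spec.primary_level)

    frac = 1.0 / (1.0 + np.exp(-(t_grid - spec.t0) / spec.tau_true_s))
    n_swept_t = np.round(N * frac).astype(int)

    last_band = order[-max(1, int(spec.band_width_px)) :]
    for k, n_swept in enumerate(n_swept_t):
        frame = base.copy()
        unswept_idx = order[n_swept:]
        frame[pix[unswept_idx, 0], pix[unswept_idx, 1]] = spec.patch_level
        swept_idx = order[:n_swept]
        m = np.zeros(spec.shape, bool)
        m[pix[swept_idx, 0], pix[swept_idx, 1]] = True
        swept_masks[k] = m
        if n_swept > 0:
            phi_front = phi_sorted[n_swept - 1]
            hi = np.searchsorted(phi_sorted, phi_front + spec.band_width_px, side="right")
            band = order[n_swept:hi]
            if band.size == 0:
                band = last_band
            # Gaussian ridge profile across the band depth
            wts = np.exp(
                -((dists[band] - phi_front - spec.band_width_px / 2.0) ** 2)
                / (2 * (spec.band_width_px / 2.0) ** 2)
            )
            wts = wts / wts.sum()
            frame[pix[band, 0], pix[band, 1]] += excess * n_swept * wts
        noiseless[k] = frame


def _render_fragmented(spec, rng, patch, t_grid, noiseless, swept_masks, excess):
    h, w = spec.shape
    edge = _edge_pixels(patch)
    centroid = np.argwhere(patch).mean(axis=0)
    k0 = spec.n_nucleation_sites
    starts = edge[rng.choice(edge.shape[0], size=k0, replace=False)].astype(float)
    # per-finger inward direction with jittered speed (+-30%)
    dirs = centroid[None, :] - starts
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    duration = t_grid[-1] - spec.t0 / 2 if t_grid[-1] > spec.t0 else t_grid[-1]
    v0 = 0.45 * min(h, w) / max(duration, spec.frame_interval_s) * spec.frame_interval_s
    fingers = [
        {"pos": starts[i].copy(), "dir": dirs[i], "v": v0 * rng.uniform(0.7, 1.3), "alive": True}
        for i in range(k0)
    ]
    swept = np.zeros(spec.shape, bool)
    base = np.full(spec.shape, spec.primary_level)
    yy, xx = np.mgrid[0:h, 0:w]
    rw = spec.finger_width_px

    start_frame = int(spec.t0 / 2 / spec.frame_interval_s)
    for k in range(len(t_grid)):
        if k >= start_frame:
            for f in list(fingers):
                if not f["alive"]:
                    continue
                ang = rng.normal(0.0, 0.15)
                c, s = math.cos(ang), math.sin(ang)
                d = f["dir"]
                f["dir"] = np.array([c * d[0] - s * d[1], s * d[0] + c * d[1]])
                new = f["pos"] + f["dir"] * f["v"]
                seg = np.linspace(f["pos"], new, 4)
                for p in seg:
                    m = (yy - p[0]) ** 2 + (xx - p[1]) ** 2 <= rw**2
                    swept |= m & patch
                f["pos"] = new
                if not (0 <= new[0] < h and 0 <= new[1] < w) or not patch[
                    min(max(int(new[0]), 0), h - 1), min(max(int(new[1]), 0), w - 1)
                ]:
                    f["alive"] = False
                elif rng.random() < spec.branch_prob:
                    ang = rng.uniform(-math.pi / 3, math.pi / 3)
                    c, s = math.cos(ang), math.sin(ang)
                    nd = np.array([c * d[0] - s * d[1], s * d[0] + c * d[1]])
                    fingers.append(
                        {"pos": new.copy(), "dir": nd, "v": v0 * rng.uniform(0.7, 1.3), "alive": True}
                    )
        swept_masks[k] = swept.copy()
        n_swept = int(swept.sum())
        frame = base.copy()
        frame[patch & ~swept] = spec.patch_level
        if n_swept > 0:
            tips = [f["pos"] for f in fingers]
            share = excess * n_swept / len(tips)
            for p in tips:
                _gaussian_stamp(frame, p, share, sigma=1.5)
        noiseless[k] = frame


def _render_lenses(spec, rng, patch, noiseless, swept_masks, excess):
    from scipy import ndimage

    T = noiseless.shape[0]
    edge_dist = ndimage.distance_transform_edt(patch)
    pix = np.argwhere(patch)
    # erode shallow (near-edge) pixels first
    order = np.argsort(edge_dist[pix[:, 0], pix[:, 1]], kind="stable")
    N = pix.shape[0]
    base = np.full(spec.shape, spec.primary_level)

    edge = _edge_pixels(patch)
    sites = edge[rng.choice(edge.shape[0], size=spec.n_nucleation_sites, replace=False)]
    centroid = pix.mean(axis=0)
    dots = []
    for s in sites.astype(float):
        inward = centroid - s
        inward /= np.linalg.norm(inward)
        dots.append({"pos": s + 3.0 * inward, "I": 0.0})

    n_final = int(spec.lens_area_fraction * N)
    per_frame = n_final / max(T - 1, 1)
    eroded = 0.0
    for k in range(T):
        n_eroded = int(round(eroded))
        m = np.zeros(spec.shape, bool)
        idx = order[:n_eroded]
        m[pix[idx, 0], pix[idx, 1]] = True
        swept_masks[k] = m
        total_I = excess * n_eroded
        # random walk, then coalescence conserving summed intensity
        if k > 0:
            for dct in dots:
                dct["pos"] = dct["pos"] + rng.normal(0, 1.0, size=2)
            merged = []
            for dct in dots:
                for other in merged:
                    if np.linalg.norm(dct["pos"] - other["pos"]) < 2.5:
                        wsum = dct["I"] + other["I"]
                        if wsum > 0:
                            other["pos"] = (
                                dct["I"] * dct["pos"] + other["I"] * other["pos"]
                            ) / wsum
                        other["I"] += dct["I"]
                        break
                else:
                    merged.append(dct)
            dots = merged
        share = total_I / len(dots) if dots else 0.0
        frame = base.copy()
        unswept = order[n_eroded:]
        frame[pix[unswept, 0], pix[unswept, 1]] = spec.patch_level
        for dct in dots:
            dct["I"] = share
            if share > 0:
                _gaussian_stamp(frame, dct["pos"], share, sigma=1.5)
        noiseless[k] = frame
        eroded += per_frame


def fixture_suite(out_dir, seed: int = 7) -> dict:
    """Write one deterministic stack per mode with sidecars and a manifest.

    Each stack goes to ``<mode>.tif`` + ``<mode>.json`` (metadata) +
    ``<mode>_truth.json`` (ground-truth summary).  The manifest lists
    SHA-256 checksums of the canonical content (frame bytes and
    ground-truth JSON), so two invocations are bit-comparable regardless
    of container timestamps.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stacks": {}}
    for i, mode in enumerate(MODES):
        # tau/t0 chosen so the rolling modes complete within the 60 frames
        spec = SceneSpec(mode=mode, seed=seed + i, n_frames=60, tau_true_s=0.5, t0_s=1.0)
        stack, gt = generate(spec)
        stem = out / mode
        save_stack(stack, stem.with_suffix(".tif"))
        truth = {
            "mode": mode,
            "tau_true_s": gt.tau_true,
            "t0_s": gt.t0,
            "patch_area_um2": gt.patch_area / 1e-12,
            "cumulative_area_um2": [a / 1e-12 for a in gt.cumulative_area],
            "integrated_intensity": list(gt.integrated_intensity),
        }
        truth_path = Path(str(stem) + "_truth.json")
        truth_text = json.dumps(truth, indent=2)
        truth_path.write_text(truth_text)
        manifest["stacks"][mode] = {
            "tiff": stem.with_suffix(".tif").name,
            "meta": stem.with_suffix(".json").name,
            "truth": truth_path.name,
            "sha256_frames": hashlib.sha256(
                stack.frames.astype(np.float32).tobytes()
            ).hexdigest(),
            "sha256_truth": hashlib.sha256(truth_text.encode()).hexdigest(),
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
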