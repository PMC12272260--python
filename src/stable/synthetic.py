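"""Synthetic two-domain calcium-microscopy generator.

Emulates the statistical structure of the cytosolic-vs-nuclear GCaMP
translation task: both domains share latent cell positions and per-cell
activity traces a_i(t).  Domain A renders each cell as a cytosolic annulus
(bright rim, dim center), domain B as a nuclear disk.  Inside a cell the two
renderings are therefore *anti-monotonic* along a radial profile (bright rim
vs dark rim), while at the cell level the mean intensities are exactly
positively correlated because both are affine in the shared amplitude a_i(t).

Training sets are unpaired by construction: the cell fields behind domain A
and domain B come from disjoint random seeds.  Paired test samples share one
field per pair and carry ground-truth label masks and traces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import scipy.signal

__all__ = [
    "PackingError",
    "NoiseModel",
    "CellField",
    "generate_cell_field",
    "simulate_traces",
    "convolve_spikes",
    "render",
    "ground_truth_mask",
    "PairedSample",
    "SyntheticDataset",
    "make_dataset",
    "save_dataset",
]

#: edge softness (px) of the logistic radial profiles; mimics microscopy blur
EDGE_WIDTH = 1.0
#: residual cytosolic intensity at the cell center, as a fraction of the rim
CENTER_FRACTION = 0.2


class PackingError(ValueError):
    """Requested cell count cannot be placed at the given separation."""


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise (fraction of unit dynamic range) + optional Poisson."""

    gaussian_sigma: float = 0.05
    poisson: bool = False
    #: photon count at intensity 1.0 when ``poisson`` is on
    poisson_scale: float = 100.0


@dataclass
class CellField:
    """Latent ground truth: cell geometry plus per-cell amplitude traces.

    ``x``/``y`` are 0-based pixel coordinates (x = column, y = row).
    ``traces`` is ``(n_cells, T)`` with a_i(t) >= 0, or None before
    :func:`simulate_traces` has been attached.
    """

    x: np.ndarray
    y: np.ndarray
    r_cyto: np.ndarray
    r_nuc: np.ndarray
    image_size: tuple
    background_level: float = 0.1
    traces: np.ndarray | None = None
    seed: int | None = None

    @property
    def n_cells(self) -> int:
        return len(self.x)

    @property
    def n_timepoints(self) -> int:
        return 0 if self.traces is None else self.traces.shape[1]

    def validate(self, min_separation: float | None = None) -> None:
        h, w = self.image_size
        if not np.all(self.r_nuc < self.r_cyto):
            raise ValueError("r_nuc must be strictly smaller than r_cyto for every cell")
        if self.n_cells and not (
            np.all((self.x >= 0) & (self.x <= w - 1))
            and np.all((self.y >= 0) & (self.y <= h - 1))
        ):
            raise ValueError("cell centers must lie inside the image")
        if min_separation is not None and self.n_cells > 1:
            d = np.hypot(self.x[:, None] - self.x[None, :], self.y[:, None] - self.y[None, :])
            np.fill_diagonal(d, np.inf)
            if d.min() < min_separation:
                raise ValueError("pairwise center distance below min_separation")
        if self.traces is not None:
            if not np.all(np.isfinite(self.traces)) or np.any(self.traces < 0):
                raise ValueError("traces must be finite and nonnegative")


def generate_cell_field(
    n_cells: int,
    image_size: tuple = (64, 64),
    r_cyto: float = 8.0,
    r_nuc: float = 4.0,
    radius_jitter: float = 0.0,
    min_separation: float | None = None,
    background_level: float = 0.1,
    seed: int = 0,
) -> CellField:
    """Rejection-sample non-overlapping cell positions.

    Default geometry (soma radius 8 px, nucleus 4 px at 64×64) is a half-scale
    version of somata with ~16 px diameter.  ``min_separation`` defaults to
    ``2·r_cyto`` so soma footprints do not overlap.  Raises
    :class:`PackingError` when the request is infeasible — either up front via
    a random-packing area bound, or after a bounded number of attempts.
    """
    h, w = image_size
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if r_cyto <= 0 or r_nuc <= 0 or r_nuc >= r_cyto:
        raise ValueError("need 0 < r_nuc < r_cyto")
    if h < 4 * r_cyto or w < 4 * r_cyto:
        raise ValueError(f"image {h}x{w} too small: needs H,W >= 4*r_cyto={4 * r_cyto:g}")
    if min_separation is None:
        min_separation = 2.0 * r_cyto
    # random sequential placement of disks of radius min_sep/2 saturates well
    # below hexagonal density; 0.6 is a safely liberal bound.
    if n_cells * np.pi * (min_separation / 2.0) ** 2 > 0.6 * h * w:
        raise PackingError(
            f"cannot place {n_cells} cells with separation {min_separation:g} "
            f"in a {h}x{w} image (random-packing area bound exceeded)"
        )
    rng = np.random.default_rng(seed)
    margin = r_cyto
    for _restart in range(30):
        xs: list[float] = []
        ys: list[float] = []
        attempts = 0
        while len(xs) < n_cells and attempts < 200 * max(n_cells, 1):
            attempts += 1
            # centers snap to the pixel grid: with shared radii every cell then
            # has an identical rasterized footprint, which makes the cell-level
            # intensity relationship between the two domains exactly linear
            cx = float(rng.integers(int(np.ceil(margin)), int(w - 1 - margin) + 1))
            cy = float(rng.integers(int(np.ceil(margin)), int(h - 1 - margin) + 1))
            if all((cx - px) ** 2 + (cy - py) ** 2 >= min_separation**2
                   for px, py in zip(xs, ys)):
                xs.append(cx)
                ys.append(cy)
        if len(xs) == n_cells:
            break
    else:
        raise PackingError(
            f"failed to place {n_cells} cells with separation {min_separation:g} "
            f"in a {h}x{w} image after bounded attempts"
        )
    jit_c = 1.0 + radius_jitter * rng.uniform(-1, 1, n_cells)
    jit_n = 1.0 + radius_jitter * rng.uniform(-1, 1, n_cells)
    fld = CellField(
        x=np.asarray(xs, dtype=np.float64),
        y=np.asarray(ys, dtype=np.float64),
        r_cyto=np.full(n_cells, r_cyto) * jit_c,
        r_nuc=np.full(n_cells, r_nuc) * jit_n,
        image_size=(h, w),
        background_level=background_level,
        seed=seed,
    )
    fld.validate(min_separation=min_separation)
    return fld


def convolve_spikes(spikes: np.ndarray, decay_tau: float, baseline: float) -> np.ndarray:
    """Exponential-kernel convolution of spike amplitudes plus constant baseline.

    Implements a_i(t) = baseline + Σ_spikes amp·exp(−(t−t_spike)/τ) as a
    first-order IIR filter.
    """
    if decay_tau <= 0:
        raise ValueError("decay_tau must be > 0")
    alpha = np.exp(-1.0 / decay_tau)
    out = scipy.signal.lfilter([1.0], [1.0, -alpha], np.atleast_2d(spikes), axis=-1)
    out = out + baseline
    return out if np.asarray(spikes).ndim > 1 else out[0]


def simulate_traces(
    fld: CellField,
    T: int,
    spike_rate: float = 0.05,
    decay_tau: float = 8.0,
    baseline: float = 0.3,
    baseline_jitter: float = 0.3,
    spike_amplitude: float = 0.7,
    seed: int = 0,
) -> np.ndarray:
    """Poisson spike trains convolved with an exponential decay kernel.

    ``spike_rate`` is events/frame, ``decay_tau`` the calcium decay constant in
    frames.  Each cell gets its own constant baseline (``baseline`` scaled by
    a uniform ±``baseline_jitter`` factor), mimicking heterogeneous indicator
    expression.  The result is attached to ``fld.traces`` and returned, shape
    ``(n_cells, T)``, nonnegative.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if spike_rate < 0:
        raise ValueError("spike_rate must be >= 0")
    rng = np.random.default_rng(seed)
    base = baseline * rng.uniform(1 - baseline_jitter, 1 + baseline_jitter, fld.n_cells)
    counts = rng.poisson(spike_rate, size=(fld.n_cells, T))
    amps = counts * spike_amplitude * rng.uniform(0.5, 1.5, size=(fld.n_cells, T))
    traces = convolve_spikes(amps, decay_tau, 0.0) + base[:, None]
    fld.traces = traces
    return traces


def _radial_distance(fld: CellField) -> np.ndarray:
    h, w = fld.image_size
    yy, xx = np.mgrid[0:h, 0:w]
    return np.hypot(
        xx[None] - fld.x[:, None, None], yy[None] - fld.y[:, None, None]
    )


def _soft_disk(r: np.ndarray, radius: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp((r - radius) / EDGE_WIDTH))


def render(
    fld: CellField,
    t: int,
    domain: str,
    noise: NoiseModel | None = None,
    noise_seed: int = 0,
) -> np.ndarray:
    """Render one frame of the field in domain ``"A"`` (annuli) or ``"B"`` (disks).

    Domain A paints a smooth annulus between r_nuc and r_cyto at intensity
    proportional to a_i(t), with the center dimmed to ``CENTER_FRACTION`` of
    the rim; domain B paints a soft disk of radius r_nuc at intensity
    proportional to a_i(t).  Background is constant; noise is added last and
    the output clipped to >= 0.
    """
    domain = domain.upper()
    if domain not in ("A", "B"):
        raise ValueError(f"domain must be 'A' or 'B', got {domain!r}")
    if fld.traces is not None and not 0 <= t < fld.n_timepoints:
        raise ValueError(f"timepoint {t} outside trace length {fld.n_timepoints}")
    h, w = fld.image_size
    img = np.full((h, w), fld.background_level, dtype=np.float64)
    if fld.n_cells:
        a = fld.traces[:, t] if fld.traces is not None else np.ones(fld.n_cells)
        r = _radial_distance(fld)
        rc = fld.r_cyto[:, None, None]
        rn = fld.r_nuc[:, None, None]
        if domain == "A":
            profile = _soft_disk(r, rc) - (1.0 - CENTER_FRACTION) * _soft_disk(r, rn)
        else:
            profile = _soft_disk(r, rn)
        img += (a[:, None, None] * profile).sum(axis=0)
    if noise is not None:
        rng = np.random.default_rng([noise_seed, t, 0 if domain == "A" else 1])
        if noise.poisson:
            img = rng.poisson(np.maximum(img, 0) * noise.poisson_scale) / noise.poisson_scale
        if noise.gaussian_sigma > 0:
            img = img + rng.normal(0.0, noise.gaussian_sigma, img.shape)
    return np.clip(img, 0.0, None)


def ground_truth_mask(fld: CellField, domain: str) -> np.ndarray:
    """Integer label mask: soma disk (A, radius r_cyto) or nuclear disk (B, r_nuc).

    Labels are 1..n_cells; overlapping pixels go to the nearer center.  The
    soma footprint is the *filled* disk, matching what an instance segmenter
    returns for a ring-shaped soma, so each nuclear mask is a subset of its
    soma mask.
    """
    domain = domain.upper()
    h, w = fld.image_size
    mask = np.zeros((h, w), dtype=np.uint16)
    if fld.n_cells == 0:
        return mask
    r = _radial_distance(fld)
    radius = fld.r_cyto if domain == "A" else fld.r_nuc
    inside = r <= radius[:, None, None]
    r_masked = np.where(inside, r, np.inf)
    nearest = r_masked.argmin(axis=0)
    any_inside = inside.any(axis=0)
    mask[any_inside] = (nearest[any_inside] + 1).astype(np.uint16)
    return mask


@dataclass
class PairedSample:
    """One paired test sample: both renderings of a single shared field."""

    fld: CellField
    stack_a: np.ndarray  # (T, H, W)
    stack_b: np.ndarray
    mask_a: np.ndarray
    mask_b: np.ndarray
    traces: np.ndarray  # (n_cells, T)


@dataclass
class SyntheticDataset:
    train_a: np.ndarray  # (N, H, W)
    train_b: np.ndarray
    train_a_seeds: list
    train_b_seeds: list
    test: list
    noise: NoiseModel
    seed: int
    params: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        overlap = set(self.train_a_seeds) & set(self.train_b_seeds)
        if overlap:
            raise ValueError(f"train_A and train_B share field seeds: {sorted(overlap)}")


def _render_training_image(seed: int, domain: str, image_size, n_cells, noise,
                           background_level: float, trace_T: int = 30) -> np.ndarray:
    fld = generate_cell_field(n_cells, image_size, seed=seed,
                              background_level=background_level)
    simulate_traces(fld, trace_T, seed=seed)
    t = int(np.random.default_rng([seed, 7]).integers(0, trace_T))
    return render(fld, t, domain, noise=noise, noise_seed=seed).astype(np.float32)


def make_dataset(
    seed: int = 0,
    n_train: int = 40,
    n_test: int = 4,
    image_size: tuple = (64, 64),
    n_cells: int = 7,
    test_timepoints: int = 20,
    noise: NoiseModel | None = None,
    background_level: float = 0.1,
) -> SyntheticDataset:
    """Build an unpaired two-domain training set plus paired test samples.

    Defaults are the desk-scale study conditions: 40 images per domain at
    64×64 with 7 cells each and Gaussian noise σ = 0.05.  Every training image
    comes from its own cell field; the A- and B-side field seeds are disjoint,
    so the training set is unpaired by construction.  Test pairs share one
    field per pair and include both label masks and the latent traces.
    """
    if noise is None:
        noise = NoiseModel()
    rng = np.random.default_rng(seed)
    n_fields = 2 * n_train + n_test
    field_seeds = rng.integers(0, 2**31 - 1, size=4 * n_fields)
    field_seeds = list(dict.fromkeys(int(s) for s in field_seeds))[:n_fields]
    seeds_a = field_seeds[:n_train]
    seeds_b = field_seeds[n_train : 2 * n_train]
    seeds_test = field_seeds[2 * n_train :]

    train_a = np.stack([
        _render_training_image(s, "A", image_size, n_cells, noise, background_level)
        for s in seeds_a
    ])
    train_b = np.stack([
        _render_training_image(s, "B", image_size, n_cells, noise, background_level)
        for s in seeds_b
    ])
    test = []
    for s in seeds_test:
        fld = generate_cell_field(n_cells, image_size, seed=s,
                                  background_level=background_level)
        traces = simulate_traces(fld, test_timepoints, seed=s)
        stack_a = np.stack([
            render(fld, t, "A", noise=noise, noise_seed=s) for t in range(test_timepoints)
        ]).astype(np.float32)
        stack_b = np.stack([
            render(fld, t, "B", noise=noise, noise_seed=s) for t in range(test_timepoints)
        ]).astype(np.float32)
        test.append(PairedSample(fld, stack_a, stack_b,
                                 ground_truth_mask(fld, "A"),
                                 ground_truth_mask(fld, "B"), traces))
    return SyntheticDataset(
        train_a=train_a,
        train_b=train_b,
        train_a_seeds=seeds_a,
        train_b_seeds=seeds_b,
        test=test,
        noise=noise,
        seed=seed,
        params={
            "n_train": n_train,
            "n_test": n_test,
            "image_size": list(image_size),
            "n_cells": n_cells,
            "test_timepoints": test_timepoints,
            "background_level": background_level,
            "gaussian_sigma": noise.gaussian_sigma,
            "poisson": noise.poisson,
        },
    )


def save_dataset(ds: SyntheticDataset, out_dir) -> None:
    """Write TIFF stacks, integer-label masks, trace CSVs and a metadata sidecar."""
    import tifffile

    out = Path(out_dir)
    for sub in ("train_A", "train_B"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    for i, img in enumerate(ds.train_a):
        tifffile.imwrite(out / "train_A" / f"img_{i:03d}.tif", img, photometric="minisblack")
    for i, img in enumerate(ds.train_b):
        tifffile.imwrite(out / "train_B" / f"img_{i:03d}.tif", img, photometric="minisblack")
    for i, pair in enumerate(ds.test):
        pdir = out / "test" / f"pair_{i:03d}"
        pdir.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(pdir / "stack_A.tif", pair.stack_a, photometric="minisblack")
        tifffile.imwrite(pdir / "stack_B.tif", pair.stack_b, photometric="minisblack")
        tifffile.imwrite(pdir / "mask_A.tif", pair.mask_a, photometric="minisblack")
        tifffile.imwrite(pdir / "mask_B.tif", pair.mask_b, photometric="minisblack")
        np.savetxt(pdir / "traces.csv", pair.traces, delimiter=",")
    meta = {
        "seed": ds.seed,
        "params": ds.params,
        "train_A_field_seeds": ds.train_a_seeds,
        "train_B_field_seeds": ds.train_b_seeds,
        "splits": {
            "train_A": [f"train_A/img_{i:03d}.tif" for i in range(len(ds.train_a))],
            "train_B": [f"train_B/img_{i:03d}.tif" for i in range(len(ds.train_b))],
            "test": [f"test/pair_{i:03d}" for i in range(len(ds.test))],
        },
    }
    (out / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
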