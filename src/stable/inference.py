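"""Applying a trained generator pair to full frames and stacks.

Frames larger than the training patch are translated tile by tile with 25%
overlap and linear feathering, so interior pixels match an untiled forward
pass and seams blend smoothly.  Frames whose sides are not divisible by the
network's pooling factor are reflect-padded and cropped back.
"""

from __future__ import annotations

import numpy as np

from .training import TaskConfig, normalize_stack, pad_to_multiple

__all__ = ["translate_frame", "translate_stack", "tiled_translate"]


def translate_frame(gen_pair, frame: np.ndarray, direction: str,
                    config: TaskConfig) -> np.ndarray:
    """Translate one already-normalized ``(H, W)`` or ``(C, H, W)`` frame."""
    frame = np.asarray(frame, dtype=np.float32)
    if frame.ndim == 2:
        frame = frame[None]
    factor = 2 ** (len(config.levels) - 1)
    padded, crop = pad_to_multiple(frame, factor)
    out = gen_pair.translate(np.ascontiguousarray(padded), direction).data
    return out[(slice(None),) + crop]


def _feather_window(h: int, w: int, overlap: int) -> np.ndarray:
    def ramp(n):
        win = np.ones(n)
        if overlap > 0:
            edge = np.linspace(1.0 / (overlap + 1), 1.0, overlap)
            win[:overlap] = edge
            win[-overlap:] = edge[::-1]
        return win

    return np.outer(ramp(h), ramp(w))


def tiled_translate(gen_pair, frame: np.ndarray, direction: str, config: TaskConfig,
                    tile: int | None = None) -> np.ndarray:
    """Translate a large frame in overlapping tiles with linear feathering.

    ``tile`` defaults to the training patch size; overlap is 25% of the tile.
    A frame no larger than one tile is translated directly (identical to a
    plain forward pass).
    """
    frame = np.asarray(frame, dtype=np.float32)
    if frame.ndim == 2:
        frame = frame[None]
    c, h, w = frame.shape
    tile = tile or config.patch_size
    if h <= tile and w <= tile:
        return translate_frame(gen_pair, frame, direction, config)
    overlap = tile // 4
    step = tile - overlap
    out = None
    weight = np.zeros((h, w), dtype=np.float64)
    rows = list(range(0, max(h - tile, 0) + 1, step))
    cols = list(range(0, max(w - tile, 0) + 1, step))
    if rows[-1] + tile < h:
        rows.append(h - tile)
    if cols[-1] + tile < w:
        cols.append(w - tile)
    win = _feather_window(tile, tile, overlap)
    for r in rows:
        for cidx in cols:
            patch = frame[:, r : r + tile, cidx : cidx + tile]
            tout = translate_frame(gen_pair, patch, direction, config)
            if out is None:
                out = np.zeros((tout.shape[0], h, w), dtype=np.float64)
            out[:, r : r + tile, cidx : cidx + tile] += tout * win
            weight[r : r + tile, cidx : cidx + tile] += win
    return (out / weight[None]).astype(np.float32)


def translate_stack(gen_pair, stack: np.ndarray, direction: str, config: TaskConfig,
                    tile: int | None = None, normalize: bool = True) -> np.ndarray:
    """Normalize (per frame, per the task config) and translate a stack."""
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    if normalize:
        stack = normalize_stack(stack, config)
    frames = [tiled_translate(gen_pair, f, direction, config, tile) for f in stack]
    out = np.stack(frames)
    return out[:, 0] if out.shape[1] == 1 else out
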