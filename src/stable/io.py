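"""File I/O: image stacks, label masks, checkpoints and run manifests.

Formats: multi-page TIFF for grayscale stacks (8/16-bit integer or float),
PNG for RGB images, 16-bit integer TIFF for label masks, YAML for configs,
JSONL for training logs, JSON for manifests.  Arrays are channel/time-first;
pixel coordinates are 0-based ``(row, col)`` everywhere.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "StackReadError",
    "read_stack",
    "write_stack",
    "read_mask",
    "write_mask",
    "save_checkpoint",
    "load_checkpoint",
    "RunManifest",
    "config_hash",
]

__version__ = "0.1.0"


class StackReadError(IOError):
    pass


def read_stack(path):
    """Read a multi-page TIFF (grayscale) or PNG (RGB) into a float array.

    Returns ``(array, metadata)``: TIFF stacks come back as ``(T, H, W)``
    float32 (a single page keeps its T axis of size 1); RGB PNGs come back as
    ``(3, H, W)`` in RGB channel order.  The source dtype is recorded in the
    metadata.
    """
    path = Path(path)
    if not path.exists():
        raise StackReadError(f"no such file: {path}")
    try:
        if path.suffix.lower() in (".png",):
            import imageio.v3 as iio

            arr = iio.imread(path)
            meta = {"source_dtype": str(arr.dtype), "format": "png", "channel_order": "RGB"}
            if arr.ndim == 3:
                arr = arr[..., :3].transpose(2, 0, 1)
            else:
                arr = arr[None]
            return arr.astype(np.float32), meta
        import tifffile

        arr = tifffile.imread(path)
        meta = {"source_dtype": str(arr.dtype), "format": "tiff"}
        if arr.ndim == 2:
            arr = arr[None]
        return arr.astype(np.float32), meta
    except StackReadError:
        raise
    except Exception as exc:  # tifffile/imageio errors -> explicit diagnosis
        size = path.stat().st_size
        raise StackReadError(
            f"cannot read {path} ({size} bytes): {exc}"
        ) from exc


def write_stack(path, stack: np.ndarray, dtype=None) -> None:
    """Write a ``(T, H, W)`` or ``(H, W)`` array as a multi-page TIFF."""
    import tifffile

    arr = np.asarray(stack)
    if dtype is not None:
        arr = arr.astype(dtype)
    tifffile.imwrite(Path(path), arr, photometric="minisblack")


def read_mask(path) -> np.ndarray:
    """Read an integer label mask from TIFF."""
    import tifffile

    arr = tifffile.imread(Path(path))
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"label mask {path} is not integer-typed (got {arr.dtype})")
    return arr


def write_mask(path, mask: np.ndarray) -> None:
    import tifffile

    mask = np.asarray(mask)
    if mask.min() < 0 or mask.max() > np.iinfo(np.uint16).max:
        raise ValueError("labels must fit uint16")
    tifffile.imwrite(Path(path), mask.astype(np.uint16))


# ----------------------------------------------------------------- checkpoints
def save_checkpoint(path, generators, disc_a, disc_b, config, iteration: int = 0) -> None:
    """Serialize all parameter tensors plus the config used to build them."""
    arrays = {}
    for prefix, module in (("gen", generators), ("disc_a", disc_a), ("disc_b", disc_b)):
        for name, arr in module.state_dict().items():
            arrays[f"{prefix}/{name}"] = arr
    arrays["__config_yaml__"] = np.frombuffer(
        config.to_yaml().encode(), dtype=np.uint8
    )
    arrays["__iteration__"] = np.array(iteration)
    np.savez(Path(path), **arrays)


def load_checkpoint(path):
    """Load a checkpoint: returns ``(config, gen, disc_a, disc_b, iteration)``.

    The models are rebuilt from the embedded config; loading a checkpoint
    whose parameters do not match that spec is an error.
    """
    from .training import TaskConfig, build_models

    with np.load(Path(path)) as data:
        cfg_text = bytes(data["__config_yaml__"]).decode()
        config = TaskConfig.from_yaml(cfg_text)
        iteration = int(data["__iteration__"])
        gen, d_a, d_b = build_models(config)
        states = {"gen": {}, "disc_a": {}, "disc_b": {}}
        for key in data.files:
            if key.startswith("__"):
                continue
            prefix, name = key.split("/", 1)
            states[prefix][name] = data[key]
    gen.load_state_dict(states["gen"])
    d_a.load_state_dict(states["disc_a"])
    d_b.load_state_dict(states["disc_b"])
    return config, gen, d_a, d_b, iteration


# -------------------------------------------------------------------- manifest
def config_hash(config) -> str:
    return hashlib.sha256(config.to_yaml().encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Traceability record written next to every produced artifact."""

    task: str
    config_hash: str
    seed: int
    command: str
    software_version: str = __version__
    checkpoints: list = field(default_factory=list)
    datasets: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
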