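"""Whole-volume temporal refinement of aligned 4D label volumes.

A 4D label volume is a ``(T, Z, Y, X)`` grid of integer class labels produced
by running a 3D segmenter independently at each time step of an aligned
time series.  Because the volumes are aligned, every spatial site ``(z, y, x)``
defines one observation sequence over time, and the HMM refines each sequence
independently — the pipeline is embarrassingly parallel over sites, so any
spatial chunking produces bit-identical output to whole-volume processing.

Sites whose observable never changes over time (most of a large volume when
temporal events are localised) are dispatched to the constant-observation
shortcut instead of the full Viterbi recursion.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterator

import numpy as np

from .decode import shortcut_table, viterbi_decode_batch
from .params import HmmSpec, composite_observable, confidence_bin

__all__ = [
    "refine_volume",
    "observe_volume",
    "iter_chunks",
    "read_volume_hdf5",
    "write_volume_hdf5",
    "read_volume_tiff_dir",
    "write_volume_tiff_dir",
]


def _validate(labels: np.ndarray, conf: np.ndarray | None, spec: HmmSpec) -> None:
    if labels.ndim != 4:
        raise ValueError(f"labels must be 4-D (T, Z, Y, X), got {labels.ndim}-D")
    if labels.min() < 0 or labels.max() >= spec.n_classes:
        raise ValueError(
            f"labels out of range [0, {spec.n_classes}) for this spec"
        )
    if spec.n_bins > 1:
        if conf is None:
            raise ValueError(
                "a confidence volume is required when the spec uses "
                f"{spec.n_bins} confidence bins"
            )
        if conf.shape != labels.shape:
            raise ValueError(
                f"confidence shape {conf.shape} != labels shape {labels.shape}"
            )
    elif conf is not None and conf.shape != labels.shape:
        raise ValueError(
            f"confidence shape {conf.shape} != labels shape {labels.shape}"
        )


def observe_volume(
    labels: np.ndarray, conf: np.ndarray | None, spec: HmmSpec
) -> np.ndarray:
    """Map a label (and optional confidence) volume to composite observables.

    With ``n_bins == 1`` this is the identity on the labels; otherwise each
    toxel's leading-class probability is quantized into its confidence bin and
    combined with the predicted class into a composite observable index in
    ``[0, N * b)``.
    """
    labels = np.asarray(labels)
    _validate(labels, conf, spec)
    if spec.n_bins == 1:
        return labels.astype(np.int64)
    bins = confidence_bin(conf, spec.n_classes, spec.n_bins)
    return composite_observable(labels.astype(np.int64), bins, spec.n_bins)


def iter_chunks(
    spatial_shape: tuple[int, int, int], chunk_shape: tuple[int, int, int] | None
) -> Iterator[tuple[slice, slice, slice]]:
    """Yield spatial block slices covering a (Z, Y, X) grid."""
    if chunk_shape is None:
        yield tuple(slice(0, s) for s in spatial_shape)
        return
    if len(chunk_shape) != 3 or any(c < 1 for c in chunk_shape):
        raise ValueError("chunk_shape must be three positive integers")
    z, y, x = spatial_shape
    cz, cy, cx = chunk_shape
    for z0 in range(0, z, cz):
        for y0 in range(0, y, cy):
            for x0 in range(0, x, cx):
                yield (
                    slice(z0, min(z0 + cz, z)),
                    slice(y0, min(y0 + cy, y)),
                    slice(x0, min(x0 + cx, x)),
                )


def refine_volume(
    labels: np.ndarray,
    conf: np.ndarray | None,
    spec: HmmSpec,
    *,
    use_shortcut: bool = True,
    chunk_shape: tuple[int, int, int] | None = None,
    stats_out: dict | None = None,
) -> np.ndarray:
    """Temporally refine a 4D label volume with the HMM.

    Each spatial site's time sequence of observables is replaced by its
    Viterbi-decoded hidden path.  Temporally constant sites take the
    constant-observation shortcut when ``use_shortcut`` is set (the default,
    matching the production pipeline).  Processing is site-independent, so
    the result is bit-identical for any ``chunk_shape``.
    """
    labels = np.asarray(labels)
    conf_arr = np.asarray(conf) if conf is not None else None
    _validate(labels, conf_arr, spec)
    T = labels.shape[0]
    spatial = labels.shape[1:]
    out = np.empty_like(labels, dtype=np.int64)
    lut = shortcut_table(spec) if use_shortcut else None
    n_sites_total = 0
    n_shortcut = 0

    for block in iter_chunks(spatial, chunk_shape):
        idx = (slice(None),) + block
        obs = observe_volume(
            labels[idx], conf_arr[idx] if conf_arr is not None else None, spec
        )
        flat = obs.reshape(T, -1).T  # (n_sites, T)
        decoded = np.empty_like(flat)
        n_sites_total += flat.shape[0]
        if use_shortcut:
            const = np.all(flat == flat[:, :1], axis=1)
            n_shortcut += int(const.sum())
            decoded[const] = lut[flat[const, 0]][:, None]
            if np.any(~const):
                decoded[~const] = viterbi_decode_batch(flat[~const], spec)
        else:
            decoded = viterbi_decode_batch(flat, spec)
        out[idx] = decoded.T.reshape((T,) + obs.shape[1:])
    if stats_out is not None:
        stats_out["n_sites"] = n_sites_total
        stats_out["n_shortcut_sites"] = n_shortcut
        stats_out["shortcut_hit_rate"] = (
            n_shortcut / n_sites_total if n_sites_total else 0.0
        )
    return out


# ---------------------------------------------------------------------------
# volume I/O: HDF5 and per-timestep TIFF stacks
# ---------------------------------------------------------------------------

def read_volume_hdf5(path: str | Path, dataset: str = "labels") -> np.ndarray:
    """Read a (T, Z, Y, X) volume from an HDF5 dataset.

    A 3-D dataset is promoted to a single-timestep 4-D volume.
    """
    import h5py

    with h5py.File(path, "r") as f:
        if dataset not in f:
            raise KeyError(f"dataset {dataset!r} not found in {path}")
        arr = f[dataset][()]
    if arr.ndim == 3:
        arr = arr[None, ...]
    if arr.ndim != 4:
        raise ValueError(f"dataset {dataset!r} must be 3-D or 4-D, got {arr.ndim}-D")
    return arr


def write_volume_hdf5(
    path: str | Path, volume: np.ndarray, dataset: str = "labels"
) -> None:
    import h5py

    with h5py.File(path, "a") as f:
        if dataset in f:
            del f[dataset]
        f.create_dataset(dataset, data=volume)


def read_volume_tiff_dir(directory: str | Path, pattern: str = "*.tif*") -> np.ndarray:
    """Read one multi-page TIFF stack per time step, ordered by filename.

    Filenames must carry a zero-padded time index so lexicographic order is
    temporal order.
    """
    import tifffile

    files = sorted(Path(directory).glob(pattern))
    if not files:
        raise FileNotFoundError(f"no TIFF files matching {pattern!r} in {directory}")
    stacks = [tifffile.imread(f) for f in files]
    shapes = {s.shape for s in stacks}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent per-timestep shapes: {sorted(shapes)}")
    return np.stack(stacks, axis=0)


def write_volume_tiff_dir(
    directory: str | Path, volume: np.ndarray, prefix: str = "t"
) -> list[Path]:
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(volume.shape[0] - 1)))
    paths = []
    for t in range(volume.shape[0]):
        p = directory / f"{prefix}{t:0{width}d}.tif"
        tifffile.imwrite(p, np.asarray(volume[t]), photometric="minisblack")
        paths.append(p)
    return paths
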