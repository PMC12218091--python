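"""Readers and writers for the package's on-disk formats.

Image stacks are multi-page TIFF (uint16) with a JSON description carrying
the optics metadata; centerlines travel as CSV (frame, index, x_um, y_um,
with ds/fps in comment headers) or HDF5 (/coords, /ds, /fps); kymographs and
shape cycles go to HDF5/CSV plus PNG renderings.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .core import CenterlineSeries, CurvatureKymograph, FlexibilityClass
from .errors import FlagkinError
from .render import OpticsParams, SyntheticScene

__all__ = [
    "write_scene_tiff", "read_scene_tiff",
    "write_series_csv", "read_series_csv",
    "write_series_h5", "read_series_h5",
    "write_labels_json", "read_labels_json",
    "write_kymograph_h5", "save_kymograph_png", "save_shape_cycle",
]


def write_scene_tiff(scene: SyntheticScene, path) -> None:
    meta = {
        "pixel_size_um": scene.pixel_size,
        "psf_sigma_um": scene.psf_sigma,
        "origin_um": list(scene.origin),
        "fps": scene.ground_truth.fps,
        "label": scene.label.value if scene.label else None,
    }
    tifffile.imwrite(path, scene.images, description=json.dumps(meta))


def read_scene_tiff(path) -> SyntheticScene:
    """Read a stack written by :func:`write_scene_tiff`.

    The returned scene's ``ground_truth`` is a placeholder holding only the
    frame grid (no true coordinates are available for real recordings).
    """
    with tifffile.TiffFile(path) as tf:
        images = tf.asarray()
        desc = tf.pages[0].description
    try:
        meta = json.loads(desc)
    except (TypeError, json.JSONDecodeError):
        raise FlagkinError(f"{path} lacks the flagkin metadata description")
    if images.ndim == 2:
        images = images[None]
    placeholder = CenterlineSeries(
        coords=np.zeros((images.shape[0], 3, 2)), ds=1.0, fps=meta.get("fps", 250.0)
    )
    label = meta.get("label")
    return SyntheticScene(
        images=images, pixel_size=meta["pixel_size_um"],
        psf_sigma=meta["psf_sigma_um"], origin=tuple(meta["origin_um"]),
        ground_truth=placeholder,
        optics=OpticsParams(pixel_size=meta["pixel_size_um"],
                            psf_sigma=meta["psf_sigma_um"]),
        label=FlexibilityClass(label) if label else None,
        meta=meta,
    )


def write_series_csv(series: CenterlineSeries, path) -> None:
    n_t, n_p = series.n_frames, series.n_points
    frame = np.repeat(np.arange(n_t), n_p)
    index = np.tile(np.arange(n_p), n_t)
    flat = series.coords.reshape(-1, 2)
    df = pd.DataFrame({"frame": frame, "index": index,
                       "x_um": flat[:, 0], "y_um": flat[:, 1]})
    with open(path, "w") as fh:
        fh.write(f"# ds_um={series.ds!r}\n# fps={series.fps!r}\n")
        df.to_csv(fh, index=False)


def read_series_csv(path) -> CenterlineSeries:
    ds = fps = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            if key.strip() == "ds_um":
                ds = float(val)
            elif key.strip() == "fps":
                fps = float(val)
    if ds is None or fps is None:
        raise FlagkinError(f"{path} is missing '# ds_um=' / '# fps=' headers")
    df = pd.read_csv(path, comment="#")
    n_t = int(df["frame"].max()) + 1
    n_p = int(df["index"].max()) + 1
    if len(df) != n_t * n_p:
        raise FlagkinError(f"{path}: ragged centerline table")
    df = df.sort_values(["frame", "index"])
    coords = df[["x_um", "y_um"]].to_numpy().reshape(n_t, n_p, 2)
    return CenterlineSeries(coords=coords, ds=ds, fps=fps)


def write_series_h5(series: CenterlineSeries, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("coords", data=series.coords)
        f.create_dataset("ds", data=series.ds)
        f.create_dataset("fps", data=series.fps)


def read_series_h5(path) -> CenterlineSeries:
    with h5py.File(path, "r") as f:
        return CenterlineSeries(coords=f["coords"][...],
                                ds=float(f["ds"][()]), fps=float(f["fps"][()]))


def write_labels_json(labels: dict[str, str], path) -> None:
    Path(path).write_text(json.dumps(labels, indent=1))


def read_labels_json(path) -> dict[str, str]:
    return json.loads(Path(path).read_text())


def write_kymograph_h5(kym: CurvatureKymograph, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("kappa", data=kym.kappa)
        f.create_dataset("ds", data=kym.ds)
        f.create_dataset("dt", data=kym.dt)


def save_kymograph_png(kym: CurvatureKymograph, path, title: str = "") -> None:
    """Render kappa(s, t) with a diverging colormap (red/blue = bend side)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vmax = float(np.abs(kym.kappa).max()) or 1.0
    fig, ax = plt.subplots(figsize=(7, 3.2))
    im = ax.imshow(
        kym.kappa.T, aspect="auto", origin="lower", cmap="RdBu_r",
        vmin=-vmax, vmax=vmax,
        extent=(0, kym.duration, 0, (kym.n_s - 1) * kym.ds),
    )
    ax.set_xlabel("T (s)")
    ax.set_ylabel("s (µm)")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="κ (1/µm)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_shape_cycle(cycle, png_path=None, csv_path=None) -> None:
    """Write the (t, B1, B2) table and/or the B1-B2 orbit plot."""
    t = np.arange(cycle.coefficients.shape[0]) * cycle.dt
    if csv_path is not None:
        pd.DataFrame({"t": t, "B1": cycle.b1, "B2": cycle.b2}).to_csv(
            csv_path, index=False
        )
    if png_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        ax.plot(cycle.b1, cycle.b2, lw=0.8)
        ax.set_xlabel("$B_1$")
        ax.set_ylabel("$B_2$")
        ax.set_aspect("equal")
        if cycle.circularity is not None:
            ax.set_title(f"circularity = {cycle.circularity:.2f}")
        fig.tight_layout()
        fig.savefig(png_path, dpi=120)
        plt.close(fig)
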