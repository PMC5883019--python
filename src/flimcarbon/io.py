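"""Readers and writers for the package's on-disk formats.

Decay histograms and IRFs travel as two-column CSV (time_ns, counts);
FLIM stacks as multi-page TIFF, one page per time bin, unsigned 16-bit;
label masks as 16-bit label TIFF; parameter maps as 32-bit float TIFF.
An optional reader for Becker & Hickl SDT files is provided when the
``sdtfile`` package is importable.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .decay_model import IRF, DecayHistogram, TimeAxis
from .imaging import FlimImage, LabelMasks, ParameterMaps

__all__ = [
    "write_decay_csv",
    "read_decay_csv",
    "read_irf_csv",
    "write_stack_tiff",
    "read_stack_tiff",
    "write_labels_tiff",
    "read_labels_tiff",
    "write_parameter_maps",
    "read_sdt",
]


def _axis_from_times(times: np.ndarray) -> TimeAxis:
    widths = np.diff(times)
    if len(widths) == 0 or not np.allclose(widths, widths[0], rtol=1e-6):
        raise ValueError("time column must be uniformly spaced")
    return TimeAxis(n_bins=len(times), bin_width=float(widths[0]))


def write_decay_csv(path, hist: DecayHistogram | IRF) -> None:
    """Write a decay histogram or IRF as (time_ns, counts) CSV."""
    pd.DataFrame(
        {"time_ns": hist.axis.times, "counts": hist.counts}
    ).to_csv(path, index=False)


def read_decay_csv(path) -> DecayHistogram:
    df = pd.read_csv(path)
    axis = _axis_from_times(df["time_ns"].to_numpy())
    return DecayHistogram(counts=df["counts"].to_numpy(), axis=axis)


def read_irf_csv(path) -> IRF:
    df = pd.read_csv(path)
    axis = _axis_from_times(df["time_ns"].to_numpy())
    return IRF(counts=df["counts"].to_numpy(), axis=axis)


def write_stack_tiff(path, image: FlimImage) -> None:
    """FLIM stack as multi-page TIFF (page k = time bin k), uint16."""
    pages = np.moveaxis(image.counts.astype(np.uint16), 2, 0)
    tifffile.imwrite(
        path,
        pages,
        metadata={
            "bin_width_ns": image.axis.bin_width,
            "channel": image.channel,
            "field_of_view_um": image.field_of_view,
        },
    )


def read_stack_tiff(path, bin_width_ns: float | None = None) -> FlimImage:
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    counts = np.moveaxis(pages, 0, 2)
    width = bin_width_ns or float(meta.get("bin_width_ns", 12.5 / counts.shape[2]))
    axis = TimeAxis(n_bins=counts.shape[2], bin_width=width)
    return FlimImage(
        counts=counts,
        axis=axis,
        channel=str(meta.get("channel", "NADPH")),
        field_of_view=float(meta.get("field_of_view_um", 270.0)),
    )


def write_labels_tiff(path, masks: LabelMasks) -> None:
    """Cell and nucleus label images as a two-page 16-bit TIFF."""
    pages = np.stack(
        [masks.cell_labels.astype(np.uint16), masks.nucleus_labels.astype(np.uint16)]
    )
    tifffile.imwrite(path, pages, metadata={"pages": ["cells", "nuclei"]})


def read_labels_tiff(path) -> LabelMasks:
    pages = tifffile.imread(path)
    return LabelMasks(cell_labels=pages[0], nucleus_labels=pages[1])


def write_parameter_maps(outdir, maps: ParameterMaps) -> dict[str, Path]:
    """Each map as a 32-bit float single-page TIFF under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, arr in maps.as_dict().items():
        path = outdir / f"{name}.tif"
        tifffile.imwrite(path, arr.astype(np.float32))
        written[name] = path
    return written


def read_sdt(path):
    """Read a Becker & Hickl SDT file into FLIM stacks (optional dependency)."""
    try:
        import sdtfile
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading SDT files requires the optional 'sdtfile' package"
        ) from exc
    sdt = sdtfile.SdtFile(path)
    stacks = []
    for data, times in zip(sdt.data, sdt.times):
        axis = _axis_from_times(np.asarray(times) * 1e9)  # s -> ns
        stacks.append(FlimImage(counts=np.asarray(data), axis=axis))
    return stacks
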