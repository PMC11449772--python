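"""Read-only multi-echo magnitude DICOM input.

Requires the optional ``pydicom`` dependency (``pip install ironaccord[dicom]``).
Echo times come from the EchoTime attribute; files must share one series and
are sorted by EchoTime before an ROI-mean :class:`EchoTrain` is built.
"""
from __future__ import annotations

from pathlib import Path
from typing import Optional, Tuple

import numpy as np

from .relaxometry import EchoTrain

__all__ = ["DicomFormatError", "read_multiecho_dicom"]

MIN_ECHOES = 3


class DicomFormatError(ValueError):
    """A DICOM series that cannot be turned into a valid echo train."""


def _require_pydicom():
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "DICOM input requires the optional 'pydicom' dependency "
            "(pip install ironaccord[dicom])"
        ) from exc
    return pydicom


def read_multiecho_dicom(
    directory: str | Path,
    roi_mask: Optional[np.ndarray] = None,
) -> Tuple[EchoTrain, dict]:
    """Build one ROI-mean echo train from a directory of magnitude DICOMs.

    ``roi_mask`` (boolean, same shape as the pixel arrays) selects the ROI;
    without it the whole-image mean is used. Returns the train plus metadata
    (series UID, per-echo source file names).
    """
    pydicom = _require_pydicom()
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    if not files:
        raise DicomFormatError(f"{directory}: no files")

    echoes = []
    series_uid = None
    for path in files:
        try:
            ds = pydicom.dcmread(path)
        except Exception as exc:
            raise DicomFormatError(f"{path.name}: unreadable DICOM ({exc})") from exc
        te = getattr(ds, "EchoTime", None)
        if te is None:
            raise DicomFormatError(f"{path.name}: missing EchoTime")
        uid = getattr(ds, "SeriesInstanceUID", None)
        if series_uid is None:
            series_uid = uid
        elif uid != series_uid:
            raise DicomFormatError(f"{path.name}: mixed series in directory")
        pixels = ds.pixel_array.astype(float)
        if roi_mask is not None:
            if roi_mask.shape != pixels.shape:
                raise DicomFormatError(
                    f"{path.name}: ROI mask shape {roi_mask.shape} does not "
                    f"match pixel data {pixels.shape}"
                )
            value = float(pixels[roi_mask].mean())
        else:
            value = float(pixels.mean())
        echoes.append((float(te), value, path.name))

    tes = [e[0] for e in echoes]
    if len(set(tes)) != len(tes):
        dupes = {t for t in tes if tes.count(t) > 1}
        raise DicomFormatError(f"duplicate EchoTime values: {sorted(dupes)}")
    if len(echoes) < MIN_ECHOES:
        raise DicomFormatError(f"only {len(echoes)} echoes, need >= {MIN_ECHOES}")

    echoes.sort(key=lambda e: e[0])
    train = EchoTrain(
        np.array([e[0] for e in echoes]), np.array([e[1] for e in echoes])
    )
    meta = {
        "series_uid": str(series_uid),
        "files": [e[2] for e in echoes],
        "n_echoes": len(echoes),
    }
    return train, meta
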