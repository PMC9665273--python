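"""Readers and writers for the pipeline's on-disk formats.

Physio traces travel as two-column TSV (time_s, amplitude) with a JSON
sidecar, or in the BIDS-physio dialect (headerless gzipped TSV + JSON
sidecar with SamplingFrequency/StartTime/Columns).  BOLD data travel as
region x time TSV or 4D NIfTI with an integer label volume; motion
parameters as 6-column whitespace-delimited text; connectivity matrices as
TSV with a region-id header and as long-format pair tables.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix, Parcellation
from .physio import PhysioRecording
from .preprocess import BoldSeries, MotionParams

__all__ = [
    "write_physio", "read_physio",
    "write_bold_tsv", "read_bold_tsv",
    "write_bold_nifti", "read_bold_nifti",
    "block_label_volume", "bold_to_volume",
    "read_motion", "write_motion",
    "write_matrix", "read_matrix", "matrix_to_pairs",
]


def write_physio(rec: PhysioRecording, path, dialect: str = "plain") -> None:
    """Write a physio trace plus sidecar metadata.

    ``plain``: two-column TSV (time_s, amplitude) + ``<stem>.json``.
    ``bids``: headerless gzipped TSV + BIDS-style JSON sidecar.
    """
    path = Path(path)
    meta = {"channel": rec.channel, "SamplingFrequency": rec.rate,
            "StartTime": rec.t0, "quality": rec.quality,
            "present": rec.present}
    if dialect == "plain":
        df = pd.DataFrame({"time_s": rec.times, "amplitude": rec.samples})
        df.to_csv(path, sep="\t", index=False, float_format="%.8g")
        sidecar = path.with_suffix(".json")
    elif dialect == "bids":
        if not str(path).endswith(".tsv.gz"):
            path = path.with_suffix(".tsv.gz")
        meta["Columns"] = [rec.channel]
        with gzip.open(path, "wt") as fh:
            for v in rec.samples:
                fh.write(f"{v:.8g}\n")
        sidecar = Path(str(path)[:-len(".tsv.gz")] + ".json")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    sidecar.write_text(json.dumps(meta, indent=1))


def _sidecar_for(path: Path) -> Optional[dict]:
    if str(path).endswith(".tsv.gz"):
        cand = Path(str(path)[:-len(".tsv.gz")] + ".json")
    else:
        cand = path.with_suffix(".json")
    if cand != path and cand.exists():
        return json.loads(cand.read_text())
    return None


def read_physio(path, dialect: Optional[str] = None,
                channel: Optional[str] = None) -> PhysioRecording:
    """Read a physio trace; empty files yield a missing-channel recording.

    The dialect is inferred from the extension when not given.  Irregular
    explicit timestamps are resampled to a uniform grid at the median
    sampling interval by linear interpolation.
    """
    path = Path(path)
    if dialect is None:
        dialect = "bids" if str(path).endswith(".tsv.gz") else "plain"
    meta = _sidecar_for(path) or {}
    channel = channel or meta.get("channel", "cardiac")
    rate = float(meta.get("SamplingFrequency", 0) or 0)
    t0 = float(meta.get("StartTime", 0.0))
    if dialect == "bids":
        with gzip.open(path, "rt") as fh:
            vals = [float(line) for line in fh if line.strip()]
        if not vals:
            return PhysioRecording(channel=channel, rate=rate or 1.0, t0=t0,
                                   samples=np.array([]), present=False,
                                   quality="missing")
        if rate <= 0:
            raise ValueError("BIDS physio requires SamplingFrequency > 0")
        return PhysioRecording(channel=channel, rate=rate, t0=t0,
                               samples=np.array(vals),
                               quality=meta.get("quality", "clean"))
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        return PhysioRecording(channel=channel, rate=rate or 1.0, t0=t0,
                               samples=np.array([]), present=False,
                               quality="missing")
    t = df["time_s"].to_numpy(float)
    x = df["amplitude"].to_numpy(float)
    dt = np.diff(t)
    if dt.size and (dt <= 0).any():
        raise ValueError("physio timestamps must increase")
    med = np.median(dt) if dt.size else 1.0 / (rate or 1.0)
    if dt.size and not np.allclose(dt, med, rtol=1e-6, atol=1e-9):
        tu = np.arange(t[0], t[-1] + med / 2, med)
        x = np.interp(tu, t, x)
        t = tu
    return PhysioRecording(channel=channel, rate=1.0 / med, t0=t[0],
                           samples=x, quality=meta.get("quality", "clean"))


def write_bold_tsv(bold: BoldSeries, path) -> None:
    df = pd.DataFrame(bold.data,
                      index=pd.RangeIndex(1, bold.n_regions + 1,
                                          name="region_id"))
    df.columns = [f"t{j}" for j in range(bold.n_frames)]
    df.to_csv(path, sep="\t")
    Path(path).with_suffix(".json").write_text(json.dumps(
        {"tr": bold.tr, "n_discarded": bold.n_discarded,
         "units": bold.units, "provenance": bold.provenance}, indent=1))


def read_bold_tsv(path) -> BoldSeries:
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta_path = Path(path).with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return BoldSeries(data=df.to_numpy(float),
                      tr=float(meta.get("tr", 1.25)),
                      n_discarded=int(meta.get("n_discarded", 0)),
                      units=meta.get("units", "raw"),
                      provenance=list(meta.get("provenance", [])))


def block_label_volume(n_regions: int) -> np.ndarray:
    """Toy parcellation volume: one 2x2x2-voxel block per region on a
    compact grid, labels 1..n_regions, 0 elsewhere."""
    side = int(np.ceil(n_regions ** (1 / 3)))
    vol = np.zeros((2 * side, 2 * side, 2 * side), dtype=np.int16)
    rid = 1
    for i in range(side):
        for j in range(side):
            for k in range(side):
                if rid > n_regions:
                    return vol
                vol[2 * i:2 * i + 2, 2 * j:2 * j + 2,
                    2 * k:2 * k + 2] = rid
                rid += 1
    return vol


def bold_to_volume(bold: BoldSeries, labels: np.ndarray) -> np.ndarray:
    """Paint region time series into a 4D volume matching ``labels``
    (every voxel of a region carries the region's series)."""
    vol = np.zeros(labels.shape + (bold.n_frames,), dtype=float)
    for i in range(bold.n_regions):
        vol[labels == i + 1] = bold.data[i]
    return vol


def write_bold_nifti(bold: BoldSeries, labels: np.ndarray, path,
                     label_path) -> None:
    """Write a toy 4D NIfTI plus its integer label volume."""
    import nibabel as nib
    affine = np.eye(4)
    vol = bold_to_volume(bold, labels)
    img = nib.Nifti1Image(vol, affine)
    img.header.set_zooms((1.0, 1.0, 1.0, bold.tr))
    nib.save(img, str(path))
    nib.save(nib.Nifti1Image(labels.astype(np.int16), affine),
             str(label_path))


def read_bold_nifti(path, tr: Optional[float] = None) -> np.ndarray:
    import nibabel as nib
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float)


def read_motion(path) -> MotionParams:
    return MotionParams(params=np.loadtxt(path, ndmin=2))


def write_motion(motion: MotionParams, path) -> None:
    np.savetxt(path, motion.params, fmt="%.6f")


def write_matrix(cm: ConnectivityMatrix, path) -> None:
    df = pd.DataFrame(cm.z, index=cm.region_ids, columns=cm.region_ids)
    df.index.name = "region_id"
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_matrix(path) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    z = df.to_numpy(float)
    excluded = set(int(i) for i in range(z.shape[0])
                   if np.isnan(z[i]).all())
    return ConnectivityMatrix(z=z, excluded=excluded,
                              region_ids=df.index.to_numpy(int))


def matrix_to_pairs(cm: ConnectivityMatrix,
                    parc: Optional[Parcellation] = None) -> pd.DataFrame:
    """Long-format pair table (region_a, region_b, z [, lobes, r])."""
    n = cm.n_regions
    ia, ib = np.triu_indices(n, k=1)
    tab = pd.DataFrame({
        "region_a": cm.region_ids[ia],
        "region_b": cm.region_ids[ib],
        "z": cm.z[ia, ib],
    })
    tab["r"] = np.tanh(tab["z"])
    if parc is not None:
        lobe = parc.table.set_index("id")["lobe"]
        tab["lobe_a"] = lobe.loc[tab["region_a"]].to_numpy()
        tab["lobe_b"] = lobe.loc[tab["region_b"]].to_numpy()
    return tab
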