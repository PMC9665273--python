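"""Parcellated functional connectivity: region extraction, lesion
exclusion, and Pearson/Fisher-z matrices.

The node set is 83 regions: 82 cortical and subcortical grey-matter
parcels (41 per hemisphere) plus one composite ascending-arousal-network
(AAN) brainstem node, giving C(83, 2) = 3403 unordered region pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Set

import numpy as np
import pandas as pd

__all__ = [
    "Parcellation",
    "ConnectivityMatrix",
    "default_parcellation",
    "extract_region_series",
    "lesion_exclusions",
    "connectivity_matrix",
    "count_region_pairs",
    "Z_CLIP",
]

#: |r| is clipped here before the Fisher transform (atanh saturates at 1).
Z_CLIP = 1.0 - 1e-12

# 39 cortical/subcortical parcel names by lobe group, as used in standard
# FreeSurfer-style parcellations; two hemispheres plus four additional
# subcortical parcels (ventral diencephalon and cerebellar cortex, both
# hemispheres) make the 82 grey-matter nodes.  Synthetic-but-plausible
# node table for the toy parcellation.
_PARCELS = {
    "FRO": ["FPo", "SupF", "PrC", "CaudMF", "RosMF", "ParsOp", "ParsTri",
            "ParsOr"],
    "INS": ["Ins"],
    "LIM": ["RosACg", "CaudACg", "IsCg", "PosCg"],
    "TEM": ["TPo", "SupT", "BSupTS", "TrT", "MT", "InfT", "EnRh"],
    "PAR": ["SupP", "InfP", "SuMar", "PosC", "PaC", "PrCun"],
    "OCC": ["LOc", "Cun", "PerCc", "Lin", "PaHip", "Fu"],
    "SBC": ["Pu", "Pal", "CaN", "NAcc", "Amg", "Tha", "Hip"],
}
_EXTRA_SBC = ["VentDC", "CbCtx"]


def _build_region_table() -> pd.DataFrame:
    rows = []
    for hemi in ("lh", "rh"):
        for lobe, names in _PARCELS.items():
            for nm in names:
                rows.append((f"{hemi}-{nm}", lobe))
        for nm in _EXTRA_SBC:
            rows.append((f"{hemi}-{nm}", "SBC"))
    rows.append(("AAN", "AAN"))  # composite brainstem arousal-network node
    df = pd.DataFrame(rows, columns=["name", "lobe"])
    df.insert(0, "id", np.arange(1, len(df) + 1))
    return df


@dataclass
class Parcellation:
    """Region table (id, name, lobe), optional label volume, and per-region
    lesion-overlap fractions."""

    table: pd.DataFrame
    labels: Optional[np.ndarray] = None  # integer label volume
    lesion_overlap: Optional[np.ndarray] = None  # fraction in [0, 1]

    def __post_init__(self):
        ids = self.table["id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise ValueError("region ids must be unique")
        if self.lesion_overlap is None:
            self.lesion_overlap = np.zeros(len(ids))
        self.lesion_overlap = np.asarray(self.lesion_overlap, dtype=float)
        if self.lesion_overlap.shape != (len(ids),):
            raise ValueError("lesion_overlap must have one entry per region")

    @property
    def n_regions(self) -> int:
        return len(self.table)

    @property
    def region_ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()


def default_parcellation(labels: Optional[np.ndarray] = None,
                         lesion_overlap=None) -> Parcellation:
    """The 83-node parcellation (82 grey-matter parcels + composite AAN)."""
    return Parcellation(table=_build_region_table(), labels=labels,
                        lesion_overlap=lesion_overlap)


@dataclass
class ConnectivityMatrix:
    """Symmetric Fisher-z matrix over parcellation nodes.

    The diagonal and all rows/columns of excluded regions are NaN-masked.
    ``saturated`` marks pairs whose |r| hit the clip value.
    """

    z: np.ndarray
    excluded: Set[int] = field(default_factory=set)
    region_ids: Optional[np.ndarray] = None
    saturated: Optional[np.ndarray] = None

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        n = self.z.shape[0]
        if self.z.shape != (n, n):
            raise ValueError("z must be square")
        if self.region_ids is None:
            self.region_ids = np.arange(1, n + 1)
        if self.saturated is None:
            self.saturated = np.zeros_like(self.z, dtype=bool)

    @property
    def n_regions(self) -> int:
        return self.z.shape[0]

    @property
    def n_valid_pairs(self) -> int:
        return count_region_pairs(self.n_regions, self.excluded)

    def pair_values(self) -> np.ndarray:
        """Upper-triangle z values as a flat vector (NaN where masked),
        ordered by (row, column)."""
        iu = np.triu_indices(self.n_regions, k=1)
        return self.z[iu]


def extract_region_series(data: np.ndarray, parc: Parcellation
                          ) -> np.ndarray:
    """Average voxel time series within each region.

    ``data`` is either an (X, Y, Z, T) volume matched to ``parc.labels``
    or an already-parcellated region x time matrix (returned as-is after a
    shape check).  Regions with no voxels yield all-NaN rows.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        if data.shape[0] != parc.n_regions:
            raise ValueError("region x time matrix does not match the "
                             "parcellation node count")
        return data
    if data.ndim != 4:
        raise ValueError("expected a 4D volume or region x time matrix")
    if parc.labels is None:
        raise ValueError("parcellation carries no label volume")
    if parc.labels.shape != data.shape[:3]:
        raise ValueError("label volume grid does not match the data grid")
    out = np.full((parc.n_regions, data.shape[3]), np.nan)
    flat = data.reshape(-1, data.shape[3])
    lab = parc.labels.reshape(-1)
    for i, rid in enumerate(parc.region_ids):
        sel = lab == rid
        if sel.any():
            out[i] = flat[sel].mean(axis=0)
    return out


def lesion_exclusions(parc: Parcellation, min_overlap: float = 0.0
                      ) -> Set[int]:
    """Indices (0-based) of regions whose lesion overlap exceeds
    ``min_overlap`` (default: any overlap)."""
    return set(np.nonzero(parc.lesion_overlap > min_overlap)[0].tolist())


def connectivity_matrix(region_series: np.ndarray,
                        excluded: Iterable[int] = ()) -> ConnectivityMatrix:
    """Pairwise Pearson correlation -> Fisher z over region time series.

    ``excluded`` holds 0-based region indices to mask (e.g. lesioned
    regions).  Constant or all-NaN series are auto-excluded with a
    warning.  |r| is clipped to 1 - 1e-12 before atanh; saturated pairs
    are flagged.
    """
    x = np.atleast_2d(np.asarray(region_series, dtype=float))
    nr, nt = x.shape
    if nt < 3:
        raise ValueError("need at least 3 timepoints for correlation")
    excluded = set(int(i) for i in excluded)
    span = np.ptp(x, axis=1)
    degenerate = np.nonzero((span == 0) | np.isnan(span) |
                            np.isnan(x).any(axis=1))[0]
    new_bad = set(degenerate.tolist()) - excluded
    if new_bad:
        warnings.warn(f"excluding degenerate (constant or NaN) region "
                      f"series: {sorted(new_bad)}")
        excluded |= new_bad
    valid = np.array([i for i in range(nr) if i not in excluded])
    if valid.size < 2:
        raise ValueError("fewer than two regions remain after exclusion")
    r = np.corrcoef(x[valid])
    r = np.clip(r, -Z_CLIP, Z_CLIP)
    z = np.full((nr, nr), np.nan)
    sat = np.zeros((nr, nr), dtype=bool)
    zv = np.arctanh(r)
    z[np.ix_(valid, valid)] = zv
    sat[np.ix_(valid, valid)] = np.abs(r) >= Z_CLIP
    np.fill_diagonal(z, np.nan)
    np.fill_diagonal(sat, False)
    return ConnectivityMatrix(z=z, excluded=excluded, saturated=sat)


def count_region_pairs(n_regions: int, excluded: Iterable[int] = ()) -> int:
    """Unordered region pairs among non-excluded regions: m(m-1)/2."""
    if n_regions < 2:
        raise ValueError("need at least two regions")
    m = n_regions - len(set(excluded))
    if m < 2:
        raise ValueError("fewer than two regions remain after exclusion")
    return m * (m - 1) // 2
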