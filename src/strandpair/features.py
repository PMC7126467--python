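"""Assembly of 2D, 1D and 0D features into the channel-stacked network input.

2D features (contact maps, ridge channels) enter directly; 1D per-residue
features (secondary-structure probabilities, one-hot amino-acid identity)
are broadcast along rows and columns so that cell (i, j) sees both
residues' profiles; scalar 0D features (homolog count N, protein length L)
enter as constant planes.  A symmetric boolean mask marks the valid pairs
(sequence separation >= 3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import CANONICAL_AA, MIN_SEPARATION, ContactMap, SequenceProfile
from .ridge import RidgeMap

#: channel groups that can be dropped for feature-removal experiments
FEATURE_GROUPS = ("maps", "ridge", "ss3", "onehot", "scalars")

_SS3_NAMES = ("helix", "strand", "coil")


def channel_registry(groups=FEATURE_GROUPS) -> list:
    """Ordered channel names for the assembled tensor (56 when all groups on)."""
    names = []
    if "maps" in groups:
        names += ["ccm_map", "dcp_map"]
    if "ridge" in groups:
        names += ["ridge_height_a", "ridge_height_b",
                  "ridge_cos2_a", "ridge_sin2_a", "ridge_cos2_b", "ridge_sin2_b"]
    if "ss3" in groups:
        for s in _SS3_NAMES:
            names += [f"ss3_{s}_row", f"ss3_{s}_col"]
    if "onehot" in groups:
        for aa in CANONICAL_AA:
            names += [f"aa_{aa}_row", f"aa_{aa}_col"]
    if "scalars" in groups:
        names += ["log_n_homologs", "rel_length"]
    return names


@dataclass
class FeatureTensor:
    """Channel-stacked L x L network input with a validity mask."""

    channels: np.ndarray
    channel_names: list
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float32)
        if self.channels.ndim != 3:
            raise ValueError("channels must be C x L x L")
        if self.channels.shape[0] != len(self.channel_names):
            raise ValueError("channel count does not match the registry")
        if self.channels.shape[1] != self.channels.shape[2]:
            raise ValueError("channel planes must be square")
        if not np.all(np.isfinite(self.channels)):
            raise ValueError("feature tensor contains non-finite values")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.channels.shape[1:]:
            raise ValueError("mask shape does not match channels")

    @property
    def length(self) -> int:
        return self.channels.shape[1]

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]


def separation_mask(length: int, min_sep: int = MIN_SEPARATION) -> np.ndarray:
    """Symmetric boolean mask of pairs with |i - j| >= min_sep."""
    idx = np.arange(length)
    return np.abs(np.subtract.outer(idx, idx)) >= min_sep


def broadcast_1d(profile_matrix: np.ndarray) -> np.ndarray:
    """Broadcast an L x k per-residue matrix into 2k L x L channels.

    Column v yields a row channel R[i, j] = v[i] and a column channel
    C[i, j] = v[j] (the transpose), interleaved per input column.
    """
    v = np.asarray(profile_matrix, dtype=float)
    if v.ndim == 1:
        v = v[:, None]
    if v.size == 0:
        raise ValueError("empty 1D feature matrix")
    length, k = v.shape
    out = np.empty((2 * k, length, length))
    for c in range(k):
        out[2 * c] = np.repeat(v[:, c][:, None], length, axis=1)
        out[2 * c + 1] = out[2 * c].T
    return out


def one_hot_sequence(sequence: str) -> np.ndarray:
    """L x 20 one-hot matrix; non-canonical letters map to all-zero rows."""
    idx = {aa: k for k, aa in enumerate(CANONICAL_AA)}
    out = np.zeros((len(sequence), len(CANONICAL_AA)))
    for i, aa in enumerate(sequence.upper()):
        k = idx.get(aa)
        if k is not None:
            out[i, k] = 1.0
    return out


def assemble_features(map_a: ContactMap, map_b: ContactMap,
                      ridge_a: RidgeMap, ridge_b: RidgeMap,
                      profile: SequenceProfile,
                      groups=FEATURE_GROUPS) -> FeatureTensor:
    """Stack all feature channels for one protein.

    map_a is the coupling-score source (CCMpred-style, unbounded above) and
    is divided by its own maximum when that maximum exceeds 1; both map
    channels are then clipped to [0, 1].  Scalars enter as the constant
    planes ln(1 + N) / 10 and L / 500.
    """
    length = map_a.length
    for other, what in ((map_b.length, "second contact map"),
                        (ridge_a.length, "first ridge map"),
                        (ridge_b.length, "second ridge map"),
                        (profile.length, "sequence profile")):
        if other != length:
            raise ValueError(f"length mismatch: {what} has L={other}, expected {length}")

    planes = []
    if "maps" in groups:
        a = map_a.values
        peak = a.max()
        if peak > 1.0:
            a = a / peak
        planes += [np.clip(a, 0.0, 1.0), np.clip(map_b.values, 0.0, 1.0)]
    if "ridge" in groups:
        def _norm_height(r):
            peak = r.height.max()
            return r.height / peak if peak > 0 else r.height
        planes += [_norm_height(ridge_a), _norm_height(ridge_b),
                   ridge_a.direction_cos2, ridge_a.direction_sin2,
                   ridge_b.direction_cos2, ridge_b.direction_sin2]
    if "ss3" in groups:
        planes += list(broadcast_1d(profile.ss3))
    if "onehot" in groups:
        planes += list(broadcast_1d(one_hot_sequence(profile.sequence)))
    if "scalars" in groups:
        planes += [np.full((length, length), np.log1p(profile.n_homologs) / 10.0),
                   np.full((length, length), length / 500.0)]
    return FeatureTensor(channels=np.stack(planes),
                         channel_names=channel_registry(groups),
                         mask=separation_mask(length))


def pad_batch(tensors) -> tuple:
    """Zero-pad a list of FeatureTensors to a common size.

    Returns (batch array B x C x Lmax x Lmax, batch mask B x Lmax x Lmax,
    lengths).  The batch mask is each tensor's own validity mask inside its
    real extent and False in the padding, so unpadding is exact.
    """
    tensors = list(tensors)
    if not tensors:
        raise ValueError("empty batch")
    n_channels = tensors[0].n_channels
    if any(t.n_channels != n_channels for t in tensors):
        raise ValueError("inconsistent channel counts in batch")
    lmax = max(t.length for t in tensors)
    batch = np.zeros((len(tensors), n_channels, lmax, lmax), dtype=np.float32)
    mask = np.zeros((len(tensors), lmax, lmax), dtype=bool)
    lengths = []
    for k, t in enumerate(tensors):
        batch[k, :, :t.length, :t.length] = t.channels
        mask[k, :t.length, :t.length] = t.mask
        lengths.append(t.length)
    return batch, mask, lengths


def unpad_batch(batch: np.ndarray, mask: np.ndarray, lengths, channel_names) -> list:
    """Invert :func:`pad_batch`, recovering the original tensors exactly."""
    out = []
    for k, length in enumerate(lengths):
        out.append(FeatureTensor(channels=batch[k, :, :length, :length],
                                 channel_names=list(channel_names),
                                 mask=mask[k, :length, :length]))
    return out


def cache_tensors(path, tensors: dict) -> None:
    """Dump assembled tensors to an HDF5 container keyed by protein id.

    Layout: one group per id with datasets 'channels' and 'mask' and a
    'channel_names' attribute."""
    import h5py

    with h5py.File(path, "w") as fh:
        for pid, t in tensors.items():
            grp = fh.create_group(str(pid))
            grp.create_dataset("channels", data=t.channels, compression="gzip")
            grp.create_dataset("mask", data=t.mask)
            grp.attrs["channel_names"] = ",".join(t.channel_names)


def load_cached_tensors(path) -> dict:
    """Read a container written by :func:`cache_tensors`."""
    import h5py

    out = {}
    with h5py.File(path, "r") as fh:
        for pid in fh:
            grp = fh[pid]
            out[pid] = FeatureTensor(channels=grp["channels"][...],
                                     channel_names=grp.attrs["channel_names"].split(","),
                                     mask=grp["mask"][...])
    return out
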