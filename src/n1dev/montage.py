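"""Sensor montage: channel labels, unit-sphere positions, electrode clusters.

The default layout emulates a 128-channel geodesic sensor net with the four
cheek electrodes (E43, E48, E119, E120) removed, leaving 124 scalp channels.
Two nine-channel occipito-temporal clusters (LOT over the left hemisphere,
ROT over the right) carry the visual N1 and are the spatial unit for all
cluster mean-amplitude measures.

Coordinate convention: right-handed head frame with +x to the right ear,
+y to the nasion (anterior), +z to the vertex; all positions on the unit
sphere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Left occipito-temporal cluster (includes T5=E58 and O1=E70).
LOT_CHANNELS = ("E57", "E58", "E65", "E70", "E63", "E64", "E69", "E68", "E73")
#: Right occipito-temporal cluster (includes O2=E83 and T6=E96).
ROT_CHANNELS = ("E83", "E90", "E96", "E100", "E89", "E95", "E99", "E88", "E94")
#: Cheek electrodes dropped from the 128-channel net before analysis.
EXCLUDED_CHEEK = ("E43", "E48", "E119", "E120")

DEFAULT_CLUSTERS = {"LOT": list(LOT_CHANNELS), "ROT": list(ROT_CHANNELS)}


@dataclass
class Montage:
    """Ordered channel set with 3-D unit-sphere positions and named clusters.

    Parameters
    ----------
    channels
        Ordered channel labels, unique.
    positions
        ``(n_channels, 3)`` array of unit-norm coordinates, row order
        matching ``channels``.
    clusters
        Mapping cluster name -> list of member channel labels; every member
        must appear in ``channels``.
    """

    channels: list[str]
    positions: np.ndarray
    clusters: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        if self.positions.shape != (len(self.channels), 3):
            raise ValueError(
                f"positions shape {self.positions.shape} does not match "
                f"{len(self.channels)} channels"
            )
        norms = np.linalg.norm(self.positions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("positions must lie on the unit sphere")
        for name, members in self.clusters.items():
            missing = [ch for ch in members if ch not in self.channels]
            if missing:
                raise ValueError(f"cluster {name!r} references unknown channels {missing}")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def index(self, labels) -> np.ndarray:
        """Integer row indices of the given channel labels."""
        lut = {ch: i for i, ch in enumerate(self.channels)}
        try:
            return np.array([lut[ch] for ch in labels], dtype=int)
        except KeyError as err:
            raise KeyError(f"channel {err.args[0]!r} not in montage") from None

    def cluster_index(self, name: str) -> np.ndarray:
        if name not in self.clusters:
            raise KeyError(f"unknown cluster {name!r}; have {sorted(self.clusters)}")
        return self.index(self.clusters[name])

    def to_dataframe(self) -> pd.DataFrame:
        cluster_of = {}
        for name, members in self.clusters.items():
            for ch in members:
                cluster_of[ch] = name
        return pd.DataFrame(
            {
                "label": self.channels,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
                "cluster": [cluster_of.get(ch, "") for ch in self.channels],
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Montage":
        df = pd.read_csv(path, keep_default_na=False)
        clusters: dict[str, list[str]] = {}
        for _, row in df.iterrows():
            if row["cluster"]:
                clusters.setdefault(row["cluster"], []).append(row["label"])
        return cls(
            channels=list(df["label"]),
            positions=df[["x", "y", "z"]].to_numpy(),
            clusters=clusters,
        )


def _tangent_basis(center: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal basis of the tangent plane at a unit vector."""
    ref = np.array([0.0, 0.0, 1.0])
    if abs(center @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(center, ref)
    u /= np.linalg.norm(u)
    v = np.cross(center, u)
    return u, v


def _geodesic_offset(center: np.ndarray, du: float, dv: float) -> np.ndarray:
    """Move along the sphere from `center` by tangent displacement (du, dv)."""
    u, v = _tangent_basis(center)
    step = du * u + dv * v
    r = np.linalg.norm(step)
    if r < 1e-12:
        return center.copy()
    return np.cos(r) * center + np.sin(r) * (step / r)


# Cluster centroids: posterior (-y), inferior-lateral; mirror-symmetric in x.
_LOT_CENTER = np.array([-0.62, -0.68, -0.15])
_LOT_CENTER /= np.linalg.norm(_LOT_CENTER)
_ROT_CENTER = _LOT_CENTER * np.array([-1.0, 1.0, 1.0])

# 3x3 geodesic grid (radians) spanning each nine-channel cluster.
_CLUSTER_GRID = [
    (du * 0.16, dv * 0.16) for dv in (-1, 0, 1) for du in (-1, 0, 1)
]


def cluster_positions() -> dict[str, np.ndarray]:
    """Fixed unit-sphere positions of the 18 LOT/ROT channels.

    ROT is the exact left-right (x) mirror of LOT, channel by channel.
    """
    out: dict[str, np.ndarray] = {}
    for label, (du, dv) in zip(LOT_CHANNELS, _CLUSTER_GRID):
        out[label] = _geodesic_offset(_LOT_CENTER, du, dv)
    for lot_label, rot_label in zip(LOT_CHANNELS, ROT_CHANNELS):
        out[rot_label] = out[lot_label] * np.array([-1.0, 1.0, 1.0])
    return out


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform points on the upper-biased sphere (golden-angle spiral)."""
    i = np.arange(n)
    # keep z in (-0.45, 1): electrodes cover the head, not the neck
    z = 1.0 - 1.45 * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def make_montage(n_channels: int = 124, seed: int = 0) -> Montage:
    """Build a geodesic-style montage containing the LOT and ROT clusters.

    Parameters
    ----------
    n_channels
        Total channel count, 18..124.  124 reproduces the full default net
        (E1..E128 minus the four cheek channels); smaller values keep the 18
        cluster channels and the lowest-numbered remaining labels, which is
        useful for fast simulations.
    seed
        Deterministic jitter of the non-cluster positions (cluster geometry
        is fixed).
    """
    cluster_labels = list(LOT_CHANNELS) + list(ROT_CHANNELS)
    if n_channels < len(cluster_labels):
        raise ValueError(
            f"n_channels={n_channels} cannot hold the occipito-temporal clusters; "
            f"need at least {len(cluster_labels)} channels for {cluster_labels}"
        )
    all_labels = [f"E{i}" for i in range(1, 129) if f"E{i}" not in EXCLUDED_CHEEK]
    if n_channels > len(all_labels):
        raise ValueError(f"n_channels={n_channels} exceeds the {len(all_labels)}-channel net")

    other_labels = [ch for ch in all_labels if ch not in cluster_labels]
    keep_other = other_labels[: n_channels - len(cluster_labels)]
    labels = [ch for ch in all_labels if ch in cluster_labels or ch in keep_other]

    fixed = cluster_positions()
    rng = np.random.default_rng(seed)
    # candidate grid avoiding the cluster patches
    cands = _fibonacci_sphere(max(4 * n_channels, 200))
    cluster_mat = np.array(list(fixed.values()))
    far = (cands @ cluster_mat.T).max(axis=1) < np.cos(0.22)
    cands = cands[far]
    if len(cands) < len(keep_other):  # pragma: no cover - generous grid
        raise RuntimeError("candidate grid exhausted")
    step = len(cands) / max(len(keep_other), 1)
    picks = cands[(np.arange(len(keep_other)) * step).astype(int)]
    jitter = rng.normal(scale=0.01, size=picks.shape)
    picks = picks + jitter - (picks * (jitter * picks).sum(axis=1, keepdims=True))
    picks /= np.linalg.norm(picks, axis=1, keepdims=True)

    other_pos = dict(zip(keep_other, picks))
    positions = np.array([fixed.get(ch, other_pos.get(ch)) for ch in labels])
    return Montage(channels=labels, positions=positions, clusters=dict(DEFAULT_CLUSTERS))
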