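"""Reading, writing and basic kinematics of multi-node wearable recordings.

A recording is a wide delimited table: one column per body-node channel,
uniformly sampled at a declared rate. Three-dimensional channels use the
``node.x`` / ``node.y`` / ``node.z`` suffix convention. The sampling rate
travels either in the ingestion config or in a ``# rate_hz=`` comment line
at the top of the file.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_UNITS = {"rad/s", "m/s", "m/s²", "m/s^2", "m", "unitless"}

#: default body-region name lists; regions are config-defined because sensor
#: grids name joints differently across devices.
DEFAULT_NODE_GROUPS = {
    "lower_body": [
        "pelvis",
        "upper_leg_l", "upper_leg_r",
        "lower_leg_l", "lower_leg_r",
        "foot_l", "foot_r",
    ],
    "pelvic_area": ["pelvis", "upper_leg_l", "upper_leg_r"],
    "feet": ["foot_l", "foot_r"],
}


@dataclass
class KinematicRecording:
    """Uniformly sampled multi-node kinematic signal table.

    Parameters
    ----------
    node_names
        Ordered body-node labels. For 3-D channels the base node name is
        listed once; its components live in ``channels[name]`` as an
        ``(n, 3)`` array.
    sampling_rate_hz
        Positive sampling rate shared by every channel.
    channels
        Mapping node name -> 1-D array (scalar series) or (n, 3) array.
    unit
        Physical unit of the stored values.
    """

    node_names: list[str]
    sampling_rate_hz: float
    channels: dict[str, np.ndarray]
    unit: str = "unitless"
    subject_id: str = ""
    group_label: str = ""
    dropped_rows: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}")
        lengths = set()
        for name in self.node_names:
            if name not in self.channels:
                raise ValueError(f"channel missing for node {name!r}")
            arr = np.asarray(self.channels[name], dtype=float)
            if arr.ndim not in (1, 2):
                raise ValueError(f"channel {name!r} must be 1-D or (n, 3)")
            if arr.ndim == 2 and arr.shape[1] != 3:
                raise ValueError(f"3-D channel {name!r} must have 3 components")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in channel {name!r}")
            self.channels[name] = arr
            lengths.add(len(arr))
        if len(lengths) > 1:
            raise ValueError(f"unequal channel lengths: {sorted(lengths)}")
        if lengths and min(lengths) < 2:
            raise ValueError("recording needs at least 2 samples")

    @property
    def n_samples(self) -> int:
        return len(self.channels[self.node_names[0]])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_hz


@dataclass
class SegmentLengths:
    """Per-node segment lengths (meters) used as COM weights."""

    lengths: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, value in self.lengths.items():
            if not value > 0:
                raise ValueError(f"segment length for {name!r} must be > 0")

    @classmethod
    def equal(cls, node_names: Sequence[str]) -> "SegmentLengths":
        """Equal weights: the COM reduces to a plain mean across nodes."""
        logger.warning(
            "no segment lengths supplied; using equal weights for %d nodes",
            len(node_names),
        )
        return cls({name: 1.0 for name in node_names})


_RATE_RE = re.compile(r"#\s*rate_hz\s*=\s*([0-9.eE+-]+)")


def read_recording(
    path: str | Path,
    *,
    sampling_rate_hz: float | None = None,
    unit: str = "unitless",
    subject_id: str = "",
    group_label: str = "",
    sep: str | None = None,
) -> KinematicRecording:
    """Read a wide delimited table into a :class:`KinematicRecording`.

    The first non-comment row must be a header naming node channels. Columns
    with ``.x/.y/.z`` suffixes are re-assembled into (n, 3) channels. Rows
    containing non-finite entries are dropped and counted.

    Raises
    ------
    ValueError
        If no sampling rate is available, columns are ragged, or fewer than
        two valid samples remain.
    """
    path = Path(path)
    rate = sampling_rate_hz
    with open(path) as fh:
        head = fh.readline()
    if rate is None:
        m = _RATE_RE.search(head)
        if m:
            rate = float(m.group(1))
    if rate is None:
        raise ValueError("sampling rate unspecified: pass sampling_rate_hz "
                         "or include a '# rate_hz=' comment line")
    if sep is None:
        sep = "\t" if "\t" in head else ","
    try:
        df = pd.read_csv(path, sep=sep, comment="#")
    except pd.errors.ParserError as exc:  # ragged columns
        raise ValueError(f"malformed table in {path}: {exc}") from exc
    df = df.apply(pd.to_numeric, errors="coerce")
    n_raw = len(df)
    df = df.dropna()
    dropped = n_raw - len(df)
    if dropped:
        logger.warning("dropped %d row(s) with non-finite entries from %s",
                       dropped, path)
    if len(df) < 2:
        raise ValueError(f"{path}: fewer than 2 valid samples")

    channels: dict[str, np.ndarray] = {}
    node_names: list[str] = []
    vec_parts: dict[str, dict[str, np.ndarray]] = {}
    for col in df.columns:
        m = re.fullmatch(r"(.+)\.([xyz])", col)
        if m:
            vec_parts.setdefault(m.group(1), {})[m.group(2)] = df[col].to_numpy()
        else:
            node_names.append(col)
            channels[col] = df[col].to_numpy(dtype=float)
    for name, parts in vec_parts.items():
        if set(parts) != {"x", "y", "z"}:
            raise ValueError(f"incomplete 3-D channel for node {name!r}")
        node_names.append(name)
        channels[name] = np.column_stack([parts["x"], parts["y"], parts["z"]])

    return KinematicRecording(
        node_names=node_names,
        sampling_rate_hz=float(rate),
        channels=channels,
        unit=unit,
        subject_id=subject_id,
        group_label=group_label,
        dropped_rows=dropped,
    )


def write_recording(recording: KinematicRecording, path: str | Path) -> None:
    """Write a recording as CSV with a ``# rate_hz=`` header comment."""
    cols: dict[str, np.ndarray] = {}
    for name in recording.node_names:
        arr = recording.channels[name]
        if arr.ndim == 1:
            cols[name] = arr
        else:
            for i, suffix in enumerate("xyz"):
                cols[f"{name}.{suffix}"] = arr[:, i]
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(f"# rate_hz={recording.sampling_rate_hz:g}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def com_velocity(
    velocities: Mapping[str, np.ndarray],
    lengths: SegmentLengths | None = None,
) -> np.ndarray:
    """Length-weighted center-of-mass speed, V_com = sum(V_i L_i) / sum(L_i).

    Segment lengths stand in for masses as weights. With no lengths
    supplied, equal weights are used (plain mean) with a logged warning.
    """
    names = list(velocities)
    if not names:
        raise ValueError("no velocity series supplied")
    if lengths is None:
        lengths = SegmentLengths.equal(names)
    missing = set(names) - set(lengths.lengths)
    extra = set(lengths.lengths) - set(names)
    if missing or extra:
        raise ValueError(
            f"node sets differ: missing lengths {sorted(missing)}, "
            f"unused lengths {sorted(extra)}")
    w = np.array([lengths.lengths[n] for n in names], dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("zero total segment length")
    series = [np.asarray(velocities[n], dtype=float) for n in names]
    if len({len(s) for s in series}) > 1:
        raise ValueError("velocity series have unequal lengths")
    stacked = np.vstack(series)
    return (w[:, None] * stacked).sum(axis=0) / total


def euclidean_norm_series(vec3: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm of an (n, 3) position/velocity series."""
    vec3 = np.asarray(vec3, dtype=float)
    if vec3.ndim != 2 or vec3.shape[1] != 3:
        raise ValueError("expected an (n, 3) series of 3-D samples")
    return np.linalg.norm(vec3, axis=1)
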