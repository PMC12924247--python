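"""Read, write, validate and temporally upsample nucleus-tracking time series.

Series use C. elegans-style lineage naming (AceTree conventions): every
division appends one letter from the suffix alphabet ``a p d v l r``
(anterior/posterior/dorsal/ventral/left/right) to the parent's name, so
``Cpaaa`` is the a-a-a great-granddaughter of the C founder blastomere.

The canonical on-disk dialect is a 6-column TSV (frame, name, x, y, z,
diameter); an AceTree-like per-frame CSV directory is read behind the same
interface.  All internal coordinates are µm, frames are 0-based, and
time = frame * frame_interval seconds.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from cmgym.errors import EmptyWindowError, FormatError, ValidationError

#: Default µm-per-pixel scale of the source imagery on (x, y, z).
DEFAULT_VOXEL_SCALE = (0.254, 0.254, 0.1)

#: One-letter division suffixes in lineage names.
SUFFIX_ALPHABET = "apdvlr"

COLUMNS = ["frame", "name", "x", "y", "z", "diameter"]


@dataclass(frozen=True)
class CellRecord:
    """One nucleus observation: lineage name, position (µm), diameter (µm)."""

    name: str
    position: tuple[float, float, float]
    nucleus_size: float
    frame: int
    time: float

    def __post_init__(self):
        if not self.name:
            raise ValidationError("cell name must be non-empty")
        if not self.nucleus_size > 0:
            raise ValidationError(f"nucleus_size must be > 0, got {self.nucleus_size}")
        if not np.all(np.isfinite(self.position)):
            raise ValidationError(f"position must be finite, got {self.position}")


@dataclass(frozen=True)
class LineageRelation:
    """A division event: parent disappears, children (parent+suffix) appear."""

    parent: str
    children: tuple[str, ...]
    division_frame: int


@dataclass
class EmbryoSeries:
    """A time-indexed table of cell records with lineage structure.

    Parameters
    ----------
    table
        DataFrame with columns ``frame, name, x, y, z, diameter``;
        positions in µm, diameter in µm, frames 0-based and contiguous.
    frame_interval
        Seconds between consecutive frames.
    voxel_scale
        µm-per-pixel scale of the source imagery (kept as provenance).
    metadata
        Free-form provenance dict (embryo id, generator spec, ...).
    """

    table: pd.DataFrame
    frame_interval: float = 60.0
    voxel_scale: tuple[float, float, float] = DEFAULT_VOXEL_SCALE
    metadata: dict = field(default_factory=dict)

    # -- structure -----------------------------------------------------

    @property
    def n_frames(self) -> int:
        return 0 if self.table.empty else int(self.table["frame"].max()) + 1

    def frame_table(self, i: int) -> pd.DataFrame:
        """All records of frame ``i`` (copy), sorted by name."""
        sub = self.table[self.table["frame"] == i]
        return sub.sort_values("name").reset_index(drop=True)

    def cells(self) -> set[str]:
        return set(self.table["name"].unique())

    def lifetime(self, name: str) -> tuple[int, int]:
        """(first, last) frame at which ``name`` is present."""
        fr = self.table.loc[self.table["name"] == name, "frame"]
        if fr.empty:
            raise ValidationError(f"cell {name!r} not present in series")
        return int(fr.min()), int(fr.max())

    def positions(self, name: str) -> np.ndarray:
        """Per-frame (x, y, z) of one cell over its lifetime, shape (T, 3)."""
        sub = self.table[self.table["name"] == name].sort_values("frame")
        return sub[["x", "y", "z"]].to_numpy(float)

    def copy(self) -> "EmbryoSeries":
        return replace(self, table=self.table.copy(), metadata=dict(self.metadata))

    def equals(self, other: "EmbryoSeries") -> bool:
        a = self.table.sort_values(["frame", "name"]).reset_index(drop=True)
        b = other.table.sort_values(["frame", "name"]).reset_index(drop=True)
        return a.equals(b) and self.frame_interval == other.frame_interval

    # -- validation ----------------------------------------------------

    def validate(self) -> "EmbryoSeries":
        """Check structural invariants; return self or raise ValidationError."""
        t = self.table
        missing = [c for c in COLUMNS if c not in t.columns]
        if missing:
            raise FormatError(f"missing column(s): {', '.join(missing)}")
        if t.empty:
            raise ValidationError("series has no records")
        if not np.isfinite(t[["x", "y", "z"]].to_numpy()).all():
            raise ValidationError("non-finite position encountered")
        if (t["diameter"] <= 0).any():
            bad = t.loc[t["diameter"] <= 0].iloc[0]
            raise ValidationError(
                f"nucleus diameter must be > 0 (cell {bad['name']!r}, frame {int(bad['frame'])})"
            )
        if (t["name"] == "").any():
            raise ValidationError("empty cell name encountered")
        if t.duplicated(["frame", "name"]).any():
            dup = t[t.duplicated(["frame", "name"])].iloc[0]
            raise ValidationError(
                f"duplicate record for cell {dup['name']!r} at frame {int(dup['frame'])}"
            )
        frames = np.sort(t["frame"].unique())
        if frames[0] != 0 or not np.array_equal(frames, np.arange(len(frames))):
            raise ValidationError("frames must be contiguous integers starting at 0")
        # lifetimes must be contiguous: present at i and j>i implies present between
        for name, sub in t.groupby("name"):
            fr = np.sort(sub["frame"].to_numpy())
            if not np.array_equal(fr, np.arange(fr[0], fr[-1] + 1)):
                raise ValidationError(f"cell {name!r} has a gap in its lifetime")
        return self

    def records(self, frame: int):
        """Iterate CellRecord objects of one frame."""
        for _, row in self.frame_table(frame).iterrows():
            yield CellRecord(
                name=row["name"],
                position=(row["x"], row["y"], row["z"]),
                nucleus_size=row["diameter"],
                frame=frame,
                time=frame * self.frame_interval,
            )


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------


def _finalize(table: pd.DataFrame, frame_interval, voxel_scale, units, metadata) -> EmbryoSeries:
    if units == "px":
        sx, sy, sz = voxel_scale
        table = table.assign(
            x=table["x"] * sx, y=table["y"] * sy, z=table["z"] * sz,
            diameter=table["diameter"] * sx,
        )
    elif units != "um":
        raise FormatError(f"unknown units {units!r} (expected 'um' or 'px')")
    # re-index frames from 0 preserving order
    order = {f: i for i, f in enumerate(sorted(table["frame"].unique()))}
    table = table.assign(frame=table["frame"].map(order).astype(int))
    series = EmbryoSeries(
        table=table.sort_values(["frame", "name"]).reset_index(drop=True),
        frame_interval=frame_interval,
        voxel_scale=tuple(voxel_scale),
        metadata=metadata or {},
    )
    return series.validate()


def read_series(
    path: str,
    dialect: str = "tsv",
    frame_interval: float = 60.0,
    voxel_scale: tuple[float, float, float] = DEFAULT_VOXEL_SCALE,
    units: str = "um",
) -> EmbryoSeries:
    """Read a nucleus-tracking series from disk.

    Parameters
    ----------
    path
        TSV file (dialect ``"tsv"``) or a directory of per-frame CSV files
        (dialect ``"acetree"``, one file per frame with columns
        ``name,x,y,z,diameter``, lexicographic file order = frame order).
    units
        ``"um"`` if coordinates are already µm, ``"px"`` to convert
        pixel/plane coordinates with ``voxel_scale``.
    """
    if dialect == "tsv":
        rows = []
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            header = reader.fieldnames or []
            missing = [c for c in COLUMNS if c not in header]
            if missing:
                raise FormatError(f"missing column(s): {', '.join(missing)}")
            for row in reader:
                rows.append(
                    (int(row["frame"]), row["name"], float(row["x"]),
                     float(row["y"]), float(row["z"]), float(row["diameter"]))
                )
        table = pd.DataFrame(rows, columns=COLUMNS)
    elif dialect == "acetree":
        if not os.path.isdir(path):
            raise FormatError(f"acetree dialect expects a directory, got {path!r}")
        rows = []
        for fi, fname in enumerate(sorted(os.listdir(path))):
            if not fname.endswith(".csv"):
                continue
            with open(os.path.join(path, fname), newline="", encoding="utf-8") as fh:
                reader = csv.DictReader(fh)
                need = ["name", "x", "y", "z", "diameter"]
                missing = [c for c in need if c not in (reader.fieldnames or [])]
                if missing:
                    raise FormatError(
                        f"{fname}: missing column(s): {', '.join(missing)}"
                    )
                for row in reader:
                    rows.append(
                        (fi, row["name"], float(row["x"]), float(row["y"]),
                         float(row["z"]), float(row["diameter"]))
                    )
        if not rows:
            raise FormatError(f"no per-frame CSV files found in {path!r}")
        table = pd.DataFrame(rows, columns=COLUMNS)
    else:
        raise FormatError(f"unknown dialect {dialect!r}")
    return _finalize(table, frame_interval, voxel_scale, units, {"source": str(path)})


def write_series(series: EmbryoSeries, path: str) -> str:
    """Write the canonical 6-column TSV; round-trips bit-exactly."""
    series.validate()
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(COLUMNS)
        sub = series.table.sort_values(["frame", "name"])
        for row in sub.itertuples(index=False):
            # repr() keeps full float precision so read(write(s)) == s exactly
            writer.writerow(
                [int(row.frame), row.name, repr(float(row.x)), repr(float(row.y)),
                 repr(float(row.z)), repr(float(row.diameter))]
            )
    return path


# ---------------------------------------------------------------------------
# temporal upsampling
# ---------------------------------------------------------------------------


def upsample(series: EmbryoSeries, factor: int = 10) -> EmbryoSeries:
    """Linearly interpolate a series in time.

    Output has ``factor * (N - 1) + 1`` frames and a frame interval divided
    by ``factor``.  A cell is interpolated across an original interval only
    if it exists at both endpoint frames; around divisions, a parent's last
    upsampled frame is the copy of its last original frame and children
    first appear at the copy of their first original frame (no mid-interval
    births).  At copies of original frames, values equal the input exactly.
    """
    if factor < 1:
        raise ValueError(f"upsample factor must be >= 1, got {factor}")
    series.validate()
    n = series.n_frames
    if n < 2:
        raise ValueError("upsample needs a series with at least 2 frames")

    t = series.table
    out_rows = []
    for name, sub in t.groupby("name", sort=False):
        sub = sub.sort_values("frame")
        fr = sub["frame"].to_numpy()
        vals = sub[["x", "y", "z", "diameter"]].to_numpy(float)
        # copies of original frames
        for k, f in enumerate(fr):
            out_rows.append((int(f) * factor, name, *vals[k]))
        # interior sub-frames over intervals where the cell exists at both ends
        for k in range(len(fr) - 1):
            a, b = vals[k], vals[k + 1]
            for j in range(1, factor):
                w = j / factor
                out_rows.append((int(fr[k]) * factor + j, name, *((1 - w) * a + w * b)))

    table = pd.DataFrame(out_rows, columns=COLUMNS)
    out = EmbryoSeries(
        table=table.sort_values(["frame", "name"]).reset_index(drop=True),
        frame_interval=series.frame_interval / factor,
        voxel_scale=series.voxel_scale,
        metadata={**series.metadata, "upsample_factor": factor},
    )
    return out.validate()


# ---------------------------------------------------------------------------
# lineage / windows
# ---------------------------------------------------------------------------


def lineage_children(name: str) -> list[str]:
    """Admissible child names: ``name`` plus one suffix letter (a p d v l r)."""
    if not name:
        raise ValueError("lineage name must be non-empty")
    return [name + s for s in SUFFIX_ALPHABET]


def migration_window(series: EmbryoSeries, migrating: str, target: str) -> tuple[int, int]:
    """Frame range (inclusive) over which both cells co-exist.

    This is the intersection of the two cells' lifetimes — from the later
    of their appearances to the earlier of their disappearances (division
    or track end).  Symmetric in its two cell arguments.
    """
    a0, a1 = series.lifetime(migrating)
    b0, b1 = series.lifetime(target)
    lo, hi = max(a0, b0), min(a1, b1)
    if lo > hi:
        raise EmptyWindowError(
            f"cells {migrating!r} ({a0}-{a1}) and {target!r} ({b0}-{b1}) never co-exist"
        )
    return lo, hi
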