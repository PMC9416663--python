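"""Reader for the oscilloscope text-buffer folder dialect.

One measurement = one folder of plain-text files, each file one second of
oscilloscope memory buffer.  Every file starts with a 3-line header followed
by one ``time  voltage`` pair per line; the local time axis restarts at zero
in every buffer.  File names equal the folder name plus a two-digit suffix
giving the buffer's position in the succession, which is the ordering key
used to reconstruct the global time axis.

Folder names encode the measurement metadata through a fixed keyword
grammar (subject code, foot, flexion direction, initial pedal angle,
session flags); :func:`parse_folder_name` resolves it into a
:class:`MeasurementKey`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    AmbiguousKey,
    AnkledynError,
    EmptyBuffer,
    InconsistentBuffer,
    MalformedLine,
    MissingBuffer,
    MissingDirection,
    MissingFoot,
)

#: number of header lines discarded at the top of every buffer file
HEADER_LINES = 3

_DELIMS = re.compile(r"[,\t ]+")
_SUFFIX = re.compile(r"(\d{2})(?:\.txt)?$", re.IGNORECASE)


@dataclass(frozen=True)
class BufferFile:
    """Samples of a single one-second memory buffer."""

    index: int                 # 0-based position in the buffer succession
    times_local: np.ndarray    # s, starting at 0 within the buffer
    voltages: np.ndarray       # V

    def __post_init__(self):
        if len(self.times_local) != len(self.voltages) or len(self.voltages) == 0:
            raise ValueError("times and voltages must be equal-length and non-empty")


@dataclass(frozen=True)
class Recording:
    """A concatenated multi-buffer voltage recording on a global time axis."""

    times: np.ndarray     # s, global, strictly increasing
    voltages: np.ndarray  # V
    fs: float             # Hz
    n_buffers: int
    source: str = ""

    @property
    def duration(self) -> float:
        """Total span in seconds including the final sample period."""
        return float(self.times[-1] - self.times[0]) + 1.0 / self.fs

    def replace_voltages(self, voltages: np.ndarray) -> "Recording":
        return Recording(self.times, np.asarray(voltages, float), self.fs,
                         self.n_buffers, self.source)


@dataclass(frozen=True)
class MeasurementKey:
    """Metadata resolved from a measurement folder name."""

    subject_id: str
    foot: str                    # "left" | "right"
    direction_flag: str          # "plantar" | "dorsi"
    pedal_angle_deg: int | None  # -5 | 0 | +5, None if absent
    session_flags: frozenset[str] = field(default_factory=frozenset)
    acquisition_prefix: str = ""


def read_buffer_file(path: str | Path, index: int = 0) -> BufferFile:
    """Read one buffer file, discarding its 3-line header.

    Data lines are ``time<sep>voltage`` with comma, tab or whitespace
    separators.  Raises :class:`EmptyBuffer` if no data lines remain and
    :class:`MalformedLine` (with the 1-based line number) on a non-numeric
    payload line.
    """
    path = Path(path)
    times, volts = [], []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if line_no <= HEADER_LINES:
                continue
            stripped = line.strip()
            if not stripped:
                continue
            parts = [p for p in _DELIMS.split(stripped) if p]
            try:
                t, v = float(parts[0]), float(parts[1])
            except (ValueError, IndexError):
                raise MalformedLine(str(path), line_no, stripped) from None
            times.append(t)
            volts.append(v)
    if not times:
        raise EmptyBuffer(f"{path}: no data lines after {HEADER_LINES}-line header")
    return BufferFile(index=index,
                      times_local=np.asarray(times, float),
                      voltages=np.asarray(volts, float))


def _buffer_paths(folder: Path) -> list[tuple[int, Path]]:
    """Buffer files of a folder, sorted by their two-digit suffix."""
    out = []
    for p in sorted(folder.iterdir()):
        if not p.is_file():
            continue
        m = _SUFFIX.search(p.name)
        if m:
            out.append((int(m.group(1)), p))
    out.sort(key=lambda kv: kv[0])
    return out


def read_measurement_folder(folder: str | Path) -> Recording:
    """Concatenate all buffer files of a folder onto a global time axis.

    Buffers are ordered by their two-digit suffix.  The buffer duration
    ``T_buffer`` is inferred from buffer 0 as its local time span plus one
    sample period, and the global time of buffer ``k`` is
    ``k * T_buffer + t_local``.  The sampling frequency is recorded as
    ``n_samples_per_buffer / T_buffer``.

    Raises :class:`MissingBuffer` if the suffix sequence has a gap and
    :class:`InconsistentBuffer` if buffers differ in sample count by more
    than one sample.
    """
    folder = Path(folder)
    entries = _buffer_paths(folder)
    if not entries:
        raise MissingBuffer(f"{folder}: no buffer files found")
    suffixes = [s for s, _ in entries]
    expect = list(range(suffixes[0], suffixes[0] + len(suffixes)))
    if suffixes != expect:
        missing = sorted(set(expect) - set(suffixes))
        raise MissingBuffer(f"{folder}: buffer suffix gap, missing {missing}")

    buffers = [read_buffer_file(p, index=i) for i, (_, p) in enumerate(entries)]
    counts = {len(b.voltages) for b in buffers}
    if max(counts) - min(counts) > 1:
        raise InconsistentBuffer(f"{folder}: buffer sample counts vary: {sorted(counts)}")

    b0 = buffers[0]
    n0 = len(b0.times_local)
    dt = (b0.times_local[-1] - b0.times_local[0]) / (n0 - 1) if n0 > 1 else 1.0
    t_buffer = float(b0.times_local[-1] - b0.times_local[0] + dt)
    fs = n0 / t_buffer

    times = np.concatenate([k * t_buffer + b.times_local for k, b in enumerate(buffers)])
    volts = np.concatenate([b.voltages for b in buffers])
    return Recording(times=times, voltages=volts, fs=fs,
                     n_buffers=len(buffers), source=folder.name)


# --- folder-name keyword grammar -----------------------------------------

_SUBJECT = re.compile(r"\bSub\s*([0-9]{1,4})\b", re.IGNORECASE)
_PREFIX = re.compile(r"^\s*([0-9][0-9-]*)")
_ANGLE = re.compile(r"([+−–-]?\s?[05])\s*,")
_TIMEFLAG = re.compile(r"^\d+h$", re.IGNORECASE)

_FOOT_TOKENS = {"lft": "left", "rx": "right", "rgt": "right"}
_DIR_TOKENS = {"pflex": "plantar", "dorsi": "dorsi"}


def parse_folder_name(name: str) -> MeasurementKey:
    """Resolve a measurement folder name into a :class:`MeasurementKey`.

    Grammar (keywords are case-insensitive except the angle tokens, whose
    trailing comma is mandatory): ``Sub XX`` subject code; ``LFT`` left /
    ``RX`` right foot (``RGT`` accepted as a non-standard alias); ``PFlex``
    plantar / ``Dorsi`` dorsiflexion; ``-5,`` ``0,`` ``+5,`` initial pedal
    angle (ASCII hyphen, en-dash or Unicode minus accepted); ``BASELINE``
    and ``2h``-style tokens become session flags.  A leading digit block is
    kept as the acquisition prefix.  Unrecognized comma/space-separated
    tokens are preserved verbatim in ``session_flags``.
    """
    if not name or not name.strip():
        raise AnkledynError("empty folder name")

    m = _SUBJECT.search(name)
    subject = m.group(1).zfill(2) if m else ""
    pm = _PREFIX.match(name)
    prefix = pm.group(1).strip("-") if pm else ""

    angle = None
    am = _ANGLE.search(name)
    if am:
        tok = am.group(1).replace(" ", "")
        sign = -1 if tok[0] in "-−–" else 1
        angle = sign * int(tok.lstrip("+-−–"))

    feet, dirs, flags = set(), set(), set()
    remainder = _SUBJECT.sub(" ", name)
    if pm:
        remainder = remainder.replace(pm.group(1), " ", 1)
    remainder = _ANGLE.sub(" ", remainder)
    for token in re.split(r"[,\s]+", remainder):
        if not token:
            continue
        low = token.lower()
        if low in _FOOT_TOKENS:
            feet.add(_FOOT_TOKENS[low])
        elif low in _DIR_TOKENS:
            dirs.add(_DIR_TOKENS[low])
        elif low == "baseline" or _TIMEFLAG.match(token):
            flags.add(token.upper() if low == "baseline" else low)
        else:
            flags.add(token)

    if len(dirs) > 1:
        raise AmbiguousKey(f"{name!r}: conflicting direction keywords {sorted(dirs)}")
    if len(feet) > 1:
        raise AmbiguousKey(f"{name!r}: conflicting foot keywords {sorted(feet)}")
    if not dirs:
        raise MissingDirection(f"{name!r}: neither PFlex nor Dorsi keyword present")
    if not feet:
        raise MissingFoot(f"{name!r}: neither LFT nor RX keyword present")
    if not subject:
        raise AnkledynError(f"{name!r}: no 'Sub XX' subject keyword")

    return MeasurementKey(subject_id=subject, foot=feet.pop(),
                          direction_flag=dirs.pop(), pedal_angle_deg=angle,
                          session_flags=frozenset(flags),
                          acquisition_prefix=prefix)


def build_index(folders: list[str | Path],
                biometrics: pd.DataFrame | None = None) -> pd.DataFrame:
    """Tabulate measurement folders into one index row per measurement.

    Unparseable folder names do not abort the batch: the row is flagged
    ``valid=False`` with the parse error recorded.  When a ``biometrics``
    table (indexed or keyed by ``subject_id``) is given, its columns are
    joined onto matching rows.  The result is writable as CSV or XLSX via
    pandas.
    """
    rows = []
    for f in folders:
        f = Path(f)
        row = {"folder": str(f), "name": f.name, "valid": True, "error": ""}
        try:
            key = parse_folder_name(f.name)
            row.update(subject_id=key.subject_id, foot=key.foot,
                       direction=key.direction_flag,
                       pedal_angle_deg=key.pedal_angle_deg,
                       session_flags=";".join(sorted(key.session_flags)),
                       acquisition_prefix=key.acquisition_prefix)
        except AnkledynError as exc:
            row.update(valid=False, error=str(exc), subject_id="")
        rows.append(row)
    index = pd.DataFrame(rows)
    if biometrics is not None:
        bio = biometrics.copy()
        if bio.index.name == "subject_id":
            bio = bio.reset_index()
        bio["subject_id"] = bio["subject_id"].astype(str).str.zfill(2)
        index = index.merge(bio, on="subject_id", how="left")
    return index


def write_index(index: pd.DataFrame, csv_path: str | Path,
                xlsx_path: str | Path | None = None) -> None:
    """Write the index as CSV and, optionally, as a mirrored XLSX copy."""
    index.to_csv(csv_path, index=False)
    if xlsx_path is not None:
        index.to_excel(xlsx_path, index=False)
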