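"""Tracking-log data model and CSV round-trip I/O.

One file per treatment fraction.  Line 1 is a metadata header::

    # patient_id=<s> fraction=<int> site=<enum> tracking=<FTT|XLT> version=<...> motion_cm=<real>

line 2 the column header ``time_s,source,err_si_mm,err_lr_mm,err_ap_mm`` and
every following line one timestamped error sample in mm, with ``source`` one
of ``model`` / ``prediction``.  Direction order is fixed as (SI, LR, AP)
everywhere in this package; errors are mm, motion amplitude cm, time seconds.
"""

from __future__ import annotations

import math
import os
import re
from dataclasses import dataclass, field

import numpy as np

from .exceptions import SchemaError

DIRECTIONS: tuple[str, str, str] = ("SI", "LR", "AP")

SOURCES = ("model", "prediction")

SITES = (
    "lung_apex_left",
    "lower_left_lung",
    "upper_left_lung",
    "lower_right_lung",
    "central_right_lung",
    "upper_right_lung",
    "central_left_lung",
    "liver",
    "central_liver",
    "lower_liver",
    "upper_liver",
    "pancreas",
    "chest_wall",
)

TRACKING_MODES = ("FTT", "XLT")

CK_VERSIONS = ("G3_6_2_3", "VSI_8_5", "VSI_9_5")

_COLUMNS = "time_s,source,err_si_mm,err_lr_mm,err_ap_mm"

_HEADER_RE = re.compile(
    r"^# patient_id=(?P<pid>\S+) fraction=(?P<frac>\d+) site=(?P<site>\S+) "
    r"tracking=(?P<mode>\S+) version=(?P<ver>\S+) motion_cm=(?P<motion>\S+)$"
)


@dataclass(frozen=True)
class TrackingSample:
    """One timestamped error observation.

    ``error`` is the (SI, LR, AP) error 3-tuple in mm; ``source`` tells
    whether it is a correlation-model residual or a prediction residual.
    """

    time: float
    source: str
    error: tuple[float, float, float]

    def __post_init__(self):
        if self.source not in SOURCES:
            raise SchemaError(f"unknown source {self.source!r}")
        if not (isinstance(self.time, (int, float)) and math.isfinite(self.time)):
            raise SchemaError(f"non-finite time {self.time!r}")
        if self.time < 0:
            raise SchemaError(f"negative time {self.time!r}")
        if len(self.error) != 3 or not all(math.isfinite(e) for e in self.error):
            raise SchemaError(f"error vector must be 3 finite reals, got {self.error!r}")


@dataclass
class FractionLog:
    """All samples of one treatment fraction plus its metadata.

    Samples are kept sorted by time (stable sort on construction).
    """

    patient_id: str
    fraction_index: int
    site: str
    tracking_mode: str
    ck_version: str
    motion_amplitude_cm: float
    samples: list[TrackingSample] = field(default_factory=list)

    def __post_init__(self):
        if not self.patient_id or re.search(r"\s", self.patient_id):
            raise SchemaError(f"patient_id must be non-empty without whitespace: {self.patient_id!r}")
        if self.fraction_index < 1:
            raise SchemaError(f"fraction_index must be >= 1, got {self.fraction_index}")
        if self.site not in SITES:
            raise SchemaError(f"unknown site {self.site!r}")
        if self.tracking_mode not in TRACKING_MODES:
            raise SchemaError(f"unknown tracking mode {self.tracking_mode!r}")
        if self.ck_version not in CK_VERSIONS:
            raise SchemaError(f"unknown ck_version {self.ck_version!r}")
        if not (self.motion_amplitude_cm >= 0):
            raise SchemaError(f"motion_amplitude_cm must be >= 0, got {self.motion_amplitude_cm}")
        self.samples = sorted(self.samples, key=lambda s: s.time)

    def stream(self, source: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (times, errors) arrays for one source; errors have shape (n, 3)."""
        if source not in SOURCES:
            raise SchemaError(f"unknown source {source!r}")
        sel = [s for s in self.samples if s.source == source]
        times = np.array([s.time for s in sel], dtype=float)
        errs = np.array([s.error for s in sel], dtype=float).reshape(len(sel), 3)
        return times, errs

    def n_samples(self, source: str) -> int:
        return sum(1 for s in self.samples if s.source == source)


@dataclass
class CohortLog:
    """A collection of fraction logs; (patient_id, fraction_index) must be unique."""

    fractions: list[FractionLog] = field(default_factory=list)

    def by_patient(self) -> dict[str, list[FractionLog]]:
        out: dict[str, list[FractionLog]] = {}
        for f in self.fractions:
            out.setdefault(f.patient_id, []).append(f)
        for flist in out.values():
            flist.sort(key=lambda f: f.fraction_index)
        return out

    def by_site(self) -> dict[str, list[FractionLog]]:
        out: dict[str, list[FractionLog]] = {}
        for f in self.fractions:
            out.setdefault(f.site, []).append(f)
        return out


def _fmt(x: float) -> str:
    # repr() gives the shortest string that round-trips the double exactly
    return repr(float(x))


def write_fraction_log(log: FractionLog, path: str | os.PathLike) -> None:
    """Serialize ``log`` to the fraction CSV schema (full float precision)."""
    lines = [
        f"# patient_id={log.patient_id} fraction={log.fraction_index} "
        f"site={log.site} tracking={log.tracking_mode} version={log.ck_version} "
        f"motion_cm={_fmt(log.motion_amplitude_cm)}",
        _COLUMNS,
    ]
    for s in log.samples:
        e = s.error
        lines.append(f"{_fmt(s.time)},{s.source},{_fmt(e[0])},{_fmt(e[1])},{_fmt(e[2])}")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def read_fraction_log(path: str | os.PathLike) -> FractionLog:
    """Parse one fraction CSV file into a validated :class:`FractionLog`.

    Raises :class:`SchemaError` naming the offending 1-based line number on
    malformed headers, non-numeric fields, unknown enum values, or duplicated
    (time, source) rows carrying conflicting values.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if len(lines) < 2:
        raise SchemaError(f"file {path} too short: expected 2 header lines")
    m = _HEADER_RE.match(lines[0])
    if m is None:
        raise SchemaError(f"malformed metadata header: {lines[0]!r}", row=1)
    if lines[1].strip() != _COLUMNS:
        raise SchemaError(f"malformed column header: expected {_COLUMNS!r}", row=2)
    try:
        motion = float(m.group("motion"))
    except ValueError:
        raise SchemaError(f"non-numeric motion_cm {m.group('motion')!r}", row=1) from None

    samples: list[TrackingSample] = []
    for lineno, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 5:
            raise SchemaError(f"expected 5 comma-separated fields, got {len(parts)}", row=lineno)
        t_s, source, *errs = (p.strip() for p in parts)
        if source not in SOURCES:
            raise SchemaError(f"unknown source {source!r}", row=lineno)
        try:
            t = float(t_s)
            e = tuple(float(x) for x in errs)
        except ValueError:
            raise SchemaError(f"non-numeric field in {line!r}", row=lineno) from None
        try:
            samples.append(TrackingSample(time=t, source=source, error=e))  # type: ignore[arg-type]
        except SchemaError as exc:
            raise SchemaError(str(exc), row=lineno) from None

    # duplicate (time, source) rows must not disagree on the error values
    seen: dict[tuple[float, str], tuple[float, float, float]] = {}
    for i, s in enumerate(samples):
        key = (s.time, s.source)
        if key in seen and seen[key] != s.error:
            raise SchemaError(
                f"conflicting duplicate timestamp {s.time} for source {s.source!r}",
                row=i + 3,
            )
        seen.setdefault(key, s.error)

    try:
        return FractionLog(
            patient_id=m.group("pid"),
            fraction_index=int(m.group("frac")),
            site=m.group("site"),
            tracking_mode=m.group("mode"),
            ck_version=m.group("ver"),
            motion_amplitude_cm=motion,
            samples=samples,
        )
    except SchemaError as exc:
        raise SchemaError(f"{exc} (metadata header)", row=1) from None


def validate_cohort(cohort: CohortLog) -> list[str]:
    """Check cohort invariants; return human-readable diagnostics (empty iff valid).

    Pure: never mutates its input.
    """
    diags: list[str] = []
    seen: set[tuple[str, int]] = set()
    for f in cohort.fractions:
        key = (f.patient_id, f.fraction_index)
        tag = f"patient {f.patient_id} fraction {f.fraction_index}"
        if key in seen:
            diags.append(f"{tag}: duplicate (patient_id, fraction_index)")
        seen.add(key)
        times = [s.time for s in f.samples]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            diags.append(f"{tag}: samples not sorted by time")
        if f.n_samples("model") < 1:
            diags.append(f"{tag}: insufficient model samples")
        if f.n_samples("prediction") < 1:
            diags.append(f"{tag}: insufficient prediction samples")
        if not (f.motion_amplitude_cm >= 0):
            diags.append(f"{tag}: negative motion amplitude")
    return diags
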