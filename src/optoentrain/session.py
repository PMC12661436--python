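"""Domain types and session-bundle I/O.

A recording session is modelled as a set of continuous signals (LFP channels),
sorted spike-time lists per unit, optogenetic pulse trains, behavioral trial
blocks and lever-press/reward event streams, all on one session clock in
seconds. On disk a session is a *bundle*: a directory with ``manifest.json``,
delimited event tables under ``events/`` and raw binary signals (declared
dtype and endianness) under ``signals/``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

log = logging.getLogger("optoentrain")

REGIONS = ("VP", "LHb", "MD", "mPFC", "ACC", "PrL", "AC", "other")
TRIAL_TYPES = ("S+A", "S-A", "S+B", "S-B", "plain")

#: spike times closer than this (s) are considered sorter duplicates
DUPLICATE_TOL = 1e-6


class ValidationError(ValueError):
    """A session invariant is violated; the message names the field."""


def _as_float_array(x: Iterable[float]) -> np.ndarray:
    return np.asarray(x, dtype=float)


@dataclass
class ContinuousSignal:
    """Uniformly sampled continuous signal (e.g. an LFP channel)."""

    samples: np.ndarray
    rate: float  # Hz
    t0: float = 0.0  # s, session clock
    region: str = "other"
    name: str = "lfp"

    def __post_init__(self) -> None:
        self.samples = _as_float_array(self.samples)

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.rate

    def validate(self) -> None:
        if not self.rate > 0:
            raise ValidationError(f"ContinuousSignal.rate must be > 0, got {self.rate}")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("ContinuousSignal.samples contains non-finite values")
        if self.region not in REGIONS:
            raise ValidationError(f"ContinuousSignal.region unknown label {self.region!r}")


@dataclass
class SpikeTrain:
    """Sorted spike times of one isolated unit."""

    times: np.ndarray
    unit_id: str = "unit"
    region: str = "other"

    def __post_init__(self) -> None:
        self.times = _as_float_array(self.times)

    @property
    def n_spikes(self) -> int:
        return self.times.size

    def validate(self) -> None:
        t = self.times
        if t.size and t.min() < 0:
            raise ValidationError(f"SpikeTrain.times negative for unit {self.unit_id}")
        if np.any(np.diff(t) <= 0):
            raise ValidationError(
                f"SpikeTrain.times not strictly increasing for unit {self.unit_id}"
            )
        if self.region not in REGIONS:
            raise ValidationError(f"SpikeTrain.region unknown label {self.region!r}")

    def deduplicated(self) -> "SpikeTrain":
        """Collapse near-coincident spikes (< DUPLICATE_TOL apart) to one."""
        t = self.times
        if t.size < 2:
            return self
        keep = np.concatenate([[True], np.diff(t) >= DUPLICATE_TOL])
        if not keep.all():
            log.warning(
                "unit %s: collapsed %d duplicate spike(s) within %.0e s",
                self.unit_id, int((~keep).sum()), DUPLICATE_TOL,
            )
        return SpikeTrain(t[keep], self.unit_id, self.region)


@dataclass
class PulseTrain:
    """Laser on/off intervals; the stimulus clock (phase 0 = pulse onset)."""

    onsets: np.ndarray
    offsets: np.ndarray
    freq: float  # nominal pulse-repetition frequency, Hz
    duty: float = 0.5

    def __post_init__(self) -> None:
        self.onsets = _as_float_array(self.onsets)
        self.offsets = _as_float_array(self.offsets)

    @property
    def n_pulses(self) -> int:
        return self.onsets.size

    @property
    def period(self) -> float:
        return 1.0 / self.freq

    def validate(self) -> None:
        if not self.freq > 0:
            raise ValidationError(f"PulseTrain.freq must be > 0, got {self.freq}")
        if not 0 < self.duty <= 1:
            raise ValidationError(f"PulseTrain.duty must be in (0,1], got {self.duty}")
        if self.onsets.size != self.offsets.size:
            raise ValidationError("PulseTrain onsets/offsets length mismatch")
        if np.any(self.offsets <= self.onsets):
            raise ValidationError("PulseTrain.offsets must follow their onsets")
        if np.any(np.diff(self.onsets) <= 0):
            raise ValidationError("PulseTrain.onsets not increasing")
        width = self.offsets - self.onsets
        if self.onsets.size and not np.allclose(width, self.duty / self.freq, rtol=0.25):
            raise ValidationError("PulseTrain on-widths inconsistent with duty/freq")

    def cycle_spans(self) -> np.ndarray:
        """(n,2) array of full stimulation cycles [onset, onset+period)."""
        return np.column_stack([self.onsets, self.onsets + self.period])


@dataclass
class TrialBlock:
    """One behavioral trial block."""

    type: str
    start: float
    end: float
    opto: bool = False

    @property
    def duration(self) -> float:
        return self.end - self.start

    def validate(self) -> None:
        if self.type not in TRIAL_TYPES:
            raise ValidationError(f"TrialBlock.type unknown label {self.type!r}")
        if not self.end > self.start:
            raise ValidationError(
                f"TrialBlock.end must exceed start ({self.start}..{self.end})"
            )


@dataclass
class EventSeries:
    """Lever presses and reward deliveries."""

    presses: np.ndarray = field(default_factory=lambda: np.empty(0))
    rewards: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.presses = _as_float_array(self.presses)
        self.rewards = _as_float_array(self.rewards)

    def validate(self) -> None:
        for name in ("presses", "rewards"):
            t = getattr(self, name)
            if np.any(np.diff(t) < 0):
                raise ValidationError(f"EventSeries.{name} not sorted")
        if self.rewards.size and self.presses.size == 0:
            raise ValidationError("EventSeries.rewards present without any presses")


@dataclass
class Session:
    """All data streams of one recording/behavior session on one clock."""

    signals: list[ContinuousSignal] = field(default_factory=list)
    spikes: list[SpikeTrain] = field(default_factory=list)
    stim: list[PulseTrain] = field(default_factory=list)
    blocks: list[TrialBlock] = field(default_factory=list)
    events: EventSeries = field(default_factory=EventSeries)
    metadata: dict = field(default_factory=dict)

    def validate(self) -> "Session":
        for sig in self.signals:
            sig.validate()
        for st in self.spikes:
            st.validate()
        for pt in self.stim:
            pt.validate()
        for b in self.blocks:
            b.validate()
        spans = sorted((b.start, b.end) for b in self.blocks)
        for (s0, e0), (s1, _) in zip(spans, spans[1:]):
            if s1 < e0:
                raise ValidationError(
                    f"TrialBlock overlap: block starting {s1} before previous end {e0}"
                )
        self.events.validate()
        return self


# ---------------------------------------------------------------------------
# bundle I/O
# ---------------------------------------------------------------------------

_DTYPES = {"float64": "<f8", "float32": "<f4"}


def _write_table(path: Path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(repr(v) if isinstance(v, float) else str(v) for v in row) + "\n")


def _read_times(path: Path) -> np.ndarray:
    rows = path.read_text().splitlines()[1:]
    return np.array([float(r.split("\t")[0]) for r in rows], dtype=float)


def write_session(session: Session, path: str | Path, force: bool = False) -> Path:
    """Write *session* as a bundle directory; refuses to overwrite unless *force*."""
    session.validate()
    path = Path(path)
    if path.exists() and (path / "manifest.json").exists() and not force:
        raise FileExistsError(f"bundle already exists at {path} (use force=True)")
    (path / "events").mkdir(parents=True, exist_ok=True)
    (path / "signals").mkdir(parents=True, exist_ok=True)

    manifest: dict = {"format": "optoentrain-bundle-1", "metadata": session.metadata,
                      "signals": [], "spikes": [], "stim": [], "events": {}, "blocks": None}

    for i, sig in enumerate(session.signals):
        fname = f"signals/{i:02d}_{sig.name}.bin"
        sig.samples.astype("<f8").tofile(path / fname)
        manifest["signals"].append({
            "file": fname, "rate": sig.rate, "t0": sig.t0, "region": sig.region,
            "name": sig.name, "dtype": "float64", "endianness": "little",
            "n_samples": int(sig.samples.size),
        })
    for i, st in enumerate(session.spikes):
        fname = f"events/spikes_{i:02d}.tsv"
        _write_table(path / fname, ["time_s"], ((float(t),) for t in st.times))
        manifest["spikes"].append({"file": fname, "unit_id": st.unit_id, "region": st.region})
    for i, pt in enumerate(session.stim):
        fname = f"events/stim_{i:02d}.tsv"
        _write_table(path / fname, ["onset_s", "offset_s"],
                     ((float(a), float(b)) for a, b in zip(pt.onsets, pt.offsets)))
        manifest["stim"].append({"file": fname, "freq": pt.freq, "duty": pt.duty})
    if session.blocks:
        _write_table(path / "events/blocks.tsv", ["type", "start_s", "end_s", "opto"],
                     ((b.type, float(b.start), float(b.end), int(b.opto))
                      for b in session.blocks))
        manifest["blocks"] = "events/blocks.tsv"
    for name in ("presses", "rewards"):
        t = getattr(session.events, name)
        fname = f"events/{name}.tsv"
        _write_table(path / fname, ["time_s"], ((float(v),) for v in t))
        manifest["events"][name] = fname

    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return path


def read_session(path: str | Path) -> Session:
    """Read and validate a session bundle written by :func:`write_session`."""
    path = Path(path)
    mpath = path / "manifest.json"
    if not mpath.exists():
        raise FileNotFoundError(f"no manifest.json in {path}")
    manifest = json.loads(mpath.read_text())

    signals = []
    for rec in manifest["signals"]:
        dt = _DTYPES[rec["dtype"]] if rec["endianness"] == "little" else ">" + _DTYPES[rec["dtype"]][1:]
        samples = np.fromfile(path / rec["file"], dtype=dt).astype(float)
        if samples.size != rec["n_samples"]:
            raise ValidationError(f"signal {rec['file']}: n_samples mismatch")
        signals.append(ContinuousSignal(samples, rec["rate"], rec["t0"],
                                        rec["region"], rec.get("name", "lfp")))
    spikes = [SpikeTrain(_read_times(path / rec["file"]), rec["unit_id"], rec["region"])
              for rec in manifest["spikes"]]
    stim = []
    for rec in manifest["stim"]:
        rows = (path / rec["file"]).read_text().splitlines()[1:]
        pairs = [tuple(map(float, r.split("\t"))) for r in rows]
        ons = np.array([p[0] for p in pairs])
        offs = np.array([p[1] for p in pairs])
        stim.append(PulseTrain(ons, offs, rec["freq"], rec["duty"]))
    blocks = []
    if manifest.get("blocks"):
        rows = (path / manifest["blocks"]).read_text().splitlines()[1:]
        for r in rows:
            typ, s, e, o = r.split("\t")
            blocks.append(TrialBlock(typ, float(s), float(e), bool(int(o))))
    events = EventSeries(
        _read_times(path / manifest["events"]["presses"]),
        _read_times(path / manifest["events"]["rewards"]),
    )
    return Session(signals, spikes, stim, blocks, events, manifest.get("metadata", {})).validate()


def sessions_equal(a: Session, b: Session, tol: float = 1e-9) -> bool:
    """Numeric equality of all fields to *tol* (used by round-trip tests)."""
    if len(a.signals) != len(b.signals) or len(a.spikes) != len(b.spikes):
        return False
    if len(a.stim) != len(b.stim) or len(a.blocks) != len(b.blocks):
        return False
    for x, y in zip(a.signals, b.signals):
        if x.rate != y.rate or abs(x.t0 - y.t0) > tol or x.region != y.region:
            return False
        if x.samples.size != y.samples.size or np.abs(x.samples - y.samples).max(initial=0) > tol:
            return False
    for x, y in zip(a.spikes, b.spikes):
        if x.unit_id != y.unit_id or x.region != y.region or x.times.size != y.times.size:
            return False
        if x.times.size and np.abs(x.times - y.times).max() > tol:
            return False
    for x, y in zip(a.stim, b.stim):
        if x.freq != y.freq or x.duty != y.duty or x.n_pulses != y.n_pulses:
            return False
        if x.n_pulses and (np.abs(x.onsets - y.onsets).max() > tol
                           or np.abs(x.offsets - y.offsets).max() > tol):
            return False
    for x, y in zip(a.blocks, b.blocks):
        if x.type != y.type or x.opto != y.opto:
            return False
        if abs(x.start - y.start) > tol or abs(x.end - y.end) > tol:
            return False
    for name in ("presses", "rewards"):
        ta, tb = getattr(a.events, name), getattr(b.events, name)
        if ta.size != tb.size or (ta.size and np.abs(ta - tb).max() > tol):
            return False
    return True
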