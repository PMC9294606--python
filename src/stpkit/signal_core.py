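"""Core trace/protocol data model and text I/O.

All times are seconds internally; currents are pA and voltages mV.
Inhibitory currents recorded with a high-Cl internal are stored as
negative (inward) deflections; analysis code works on magnitudes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import FormatError, ParameterError, ShapeError

__all__ = [
    "Trace",
    "SweepSet",
    "StimulusProtocol",
    "read_trace",
    "write_trace",
    "read_sweeps",
    "write_sweeps",
    "average_sweeps",
]

_KINDS = ("current", "voltage")
_UNITS = {"current": "pA", "voltage": "mV"}
DEFAULT_RATE = 50_000.0  # Hz, matches 50 kHz digitization


@dataclass
class Trace:
    """A uniformly sampled current or voltage signal.

    Parameters
    ----------
    samples : array-like
        Signal values, pA for ``kind='current'`` and mV for
        ``kind='voltage'``.
    sampling_rate : float
        Samples per second (Hz), must be positive.
    start_time : float
        Time of the first sample in seconds.
    kind : {'current', 'voltage'}
        Determines the unit label.
    metadata : dict
        Free-form key/value annotations, preserved by file round-trips.
    """

    samples: np.ndarray
    sampling_rate: float = DEFAULT_RATE
    start_time: float = 0.0
    kind: str = "current"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ParameterError("trace needs at least one sample in a 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ParameterError("trace samples must all be finite")
        if not self.sampling_rate > 0:
            raise ParameterError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.kind not in _KINDS:
            raise ParameterError(f"kind must be one of {_KINDS}, got {self.kind!r}")

    @property
    def units(self) -> str:
        return _UNITS[self.kind]

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def dt(self) -> float:
        """Sample period in seconds."""
        return 1.0 / self.sampling_rate

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate

    def index_of(self, t: float) -> int:
        """Nearest sample index for time ``t`` (seconds)."""
        return int(round((t - self.start_time) * self.sampling_rate))

    def copy_with(self, samples: np.ndarray, **meta) -> "Trace":
        md = dict(self.metadata)
        md.update(meta)
        return Trace(samples, self.sampling_rate, self.start_time, self.kind, md)


@dataclass
class StimulusProtocol:
    """Stimulus timing for evoked-response and current-step protocols.

    ``stimulus_times`` are absolute times (s), strictly ascending.  For
    100 Hz train protocols ``train_frequency`` documents the nominal rate
    and is checked against the actual spacing.  Current-step fields
    describe a rectangular injection (onset s, duration s, amplitude pA).
    """

    stimulus_times: np.ndarray = field(default_factory=lambda: np.array([]))
    train_frequency: float | None = None
    recovery_interval: float | None = None
    step_onset: float | None = None
    step_duration: float | None = None
    step_amplitude: float | None = None
    baseline_potential: float | None = None

    def __post_init__(self):
        self.stimulus_times = np.asarray(self.stimulus_times, dtype=float)
        if self.stimulus_times.ndim != 1:
            raise ParameterError("stimulus_times must be a 1-D array")
        if self.stimulus_times.size > 1 and not np.all(np.diff(self.stimulus_times) > 0):
            raise ParameterError("stimulus_times must be strictly ascending")
        if self.recovery_interval is not None and not self.recovery_interval > 0:
            raise ParameterError("recovery_interval must be > 0")
        if self.train_frequency is not None:
            if not self.train_frequency > 0:
                raise ParameterError("train_frequency must be > 0")
            if self.stimulus_times.size > 1:
                isi = np.diff(self.stimulus_times)
                # spacing must match 1/frequency to within one sample period
                if np.any(np.abs(isi - 1.0 / self.train_frequency) > 1.0 / DEFAULT_RATE):
                    raise ParameterError(
                        "inter-stimulus spacing inconsistent with train_frequency"
                    )

    @property
    def n_stimuli(self) -> int:
        return int(self.stimulus_times.size)

    @classmethod
    def train(
        cls,
        n_stimuli: int = 40,
        frequency: float = 100.0,
        start: float = 0.0,
        **kwargs,
    ) -> "StimulusProtocol":
        """Regular train: ``n_stimuli`` at ``frequency`` Hz from ``start``."""
        times = start + np.arange(n_stimuli) / frequency
        return cls(stimulus_times=times, train_frequency=frequency, **kwargs)

    @classmethod
    def paired_pulse(cls, isi: float = 0.050, start: float = 0.0) -> "StimulusProtocol":
        """Two stimuli separated by ``isi`` seconds (default 50 ms)."""
        return cls(stimulus_times=np.array([start, start + isi]))

    @classmethod
    def current_step(
        cls,
        onset: float = 0.1,
        duration: float = 0.2,
        amplitude: float = 50.0,
        baseline_potential: float = -60.0,
    ) -> "StimulusProtocol":
        """200 ms-style depolarizing step from a hyperpolarized baseline."""
        return cls(
            step_onset=onset,
            step_duration=duration,
            step_amplitude=amplitude,
            baseline_potential=baseline_potential,
        )


@dataclass
class SweepSet:
    """One or more repetitions of the same protocol on the same cell."""

    sweeps: list[Trace]
    protocol: StimulusProtocol | None = None

    def __post_init__(self):
        if len(self.sweeps) < 1:
            raise ShapeError("SweepSet needs at least one sweep")
        ref = self.sweeps[0]
        for s in self.sweeps[1:]:
            if s.sampling_rate != ref.sampling_rate:
                raise ShapeError("sweeps must share a sampling rate")
            if s.n_samples != ref.n_samples:
                raise ShapeError("sweeps must share a length")
            if s.kind != ref.kind:
                raise ShapeError("sweeps must share a kind")

    def __len__(self) -> int:
        return len(self.sweeps)

    def __iter__(self):
        return iter(self.sweeps)


def average_sweeps(sweeps: SweepSet | Sequence[Trace]) -> Trace:
    """Pointwise arithmetic mean of a set of sweeps.

    Metadata of the result records ``n_averaged``.
    """
    if not isinstance(sweeps, SweepSet):
        sweeps = SweepSet(list(sweeps))
    stack = np.stack([s.samples for s in sweeps.sweeps])
    ref = sweeps.sweeps[0]
    return ref.copy_with(stack.mean(axis=0), n_averaged=len(sweeps))


# ---------------------------------------------------------------------------
# Text I/O: '#'-prefixed key: value header then one sample per row.


_DIALECTS = {"tsv": "\t", "csv": ","}


def write_trace(trace: Trace, path, dialect: str = "tsv") -> None:
    """Write a trace as delimited text with a self-describing header."""
    if dialect not in _DIALECTS:
        raise FormatError(f"unknown dialect {dialect!r}; use one of {sorted(_DIALECTS)}")
    path = Path(path)
    lines = [
        f"# sampling_rate: {repr(float(trace.sampling_rate))}",
        f"# kind: {trace.kind}",
        f"# units: {trace.units}",
        f"# start_time: {repr(float(trace.start_time))}",
    ]
    for key, val in trace.metadata.items():
        lines.append(f"# meta.{key}: {json.dumps(val)}")
    body = "\n".join(repr(float(x)) for x in trace.samples)
    path.write_text("\n".join(lines) + "\n" + body + "\n")


def read_trace(path, dialect: str = "tsv") -> Trace:
    """Read a trace written by :func:`write_trace`.

    The header must declare ``sampling_rate`` and ``kind``; metadata keys
    prefixed ``meta.`` are restored verbatim.
    """
    if dialect not in _DIALECTS:
        raise FormatError(f"unknown dialect {dialect!r}; use one of {sorted(_DIALECTS)}")
    path = Path(path)
    header: dict[str, str] = {}
    values: list[float] = []
    delim = _DIALECTS[dialect]
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if ":" not in line:
                raise FormatError(f"{path}:{lineno}: malformed header line {line!r}")
            key, _, val = line[1:].partition(":")
            header[key.strip()] = val.strip()
        else:
            cols = line.split(delim)
            try:
                values.append(float(cols[-1]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric sample {line!r}") from exc
    if "sampling_rate" not in header:
        raise FormatError(f"{path}: header lacks required 'sampling_rate'")
    if "kind" not in header:
        raise FormatError(f"{path}: header lacks required 'kind'")
    metadata = {}
    for key, val in header.items():
        if key.startswith("meta."):
            try:
                metadata[key[5:]] = json.loads(val)
            except json.JSONDecodeError:
                metadata[key[5:]] = val
    try:
        rate = float(header["sampling_rate"])
    except ValueError as exc:
        raise FormatError(f"{path}: ambiguous sampling_rate {header['sampling_rate']!r}") from exc
    return Trace(
        np.asarray(values),
        sampling_rate=rate,
        start_time=float(header.get("start_time", 0.0)),
        kind=header["kind"],
        metadata=metadata,
    )


def write_sweeps(sweeps: SweepSet, directory, dialect: str = "tsv") -> None:
    """Write a SweepSet as a directory: manifest.json + one file per sweep."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    for i, sweep in enumerate(sweeps.sweeps):
        name = f"sweep_{i:03d}.{dialect}"
        write_trace(sweep, directory / name, dialect)
        names.append(name)
    manifest = {"dialect": dialect, "sweeps": names}
    if sweeps.protocol is not None:
        p = sweeps.protocol
        manifest["protocol"] = {
            "stimulus_times": list(map(float, p.stimulus_times)),
            "train_frequency": p.train_frequency,
            "recovery_interval": p.recovery_interval,
            "step_onset": p.step_onset,
            "step_duration": p.step_duration,
            "step_amplitude": p.step_amplitude,
            "baseline_potential": p.baseline_potential,
        }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_sweeps(directory) -> SweepSet:
    """Read a SweepSet written by :func:`write_sweeps`."""
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FormatError(f"{directory}: no manifest.json")
    manifest = json.loads(manifest_path.read_text())
    sweeps = [
        read_trace(directory / name, manifest.get("dialect", "tsv"))
        for name in manifest["sweeps"]
    ]
    protocol = None
    if "protocol" in manifest:
        pd_ = manifest["protocol"]
        protocol = StimulusProtocol(
            stimulus_times=np.asarray(pd_.get("stimulus_times", [])),
            train_frequency=pd_.get("train_frequency"),
            recovery_interval=pd_.get("recovery_interval"),
            step_onset=pd_.get("step_onset"),
            step_duration=pd_.get("step_duration"),
            step_amplitude=pd_.get("step_amplitude"),
            baseline_potential=pd_.get("baseline_potential"),
        )
    return SweepSet(sweeps, protocol)
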