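"""Raw voltammogram stream container and the on-disk binary dialect.

The acquisition system digitizes 1,000 current samples per triangular scan on
each of 16 channels and appends each channel's data to flat binary files in
30 s increments.  Samples are stored as little-endian signed 16-bit counts;
a JSON sidecar (``meta.json``) records the count-to-current scale, amplifier
gain, waveform geometry and segmentation so a recording can be read back
losslessly up to the one-count quantization step.

Layout of one recording directory::

    <recording>/
      meta.json
      ch00/seg000.i16
      ch00/seg001.i16
      ch01/seg000.i16
      ...

The default count scale maps the full int16 range to ±2,000 nA (±10 V at the
standard 200 nA/V gain), i.e. ~0.061 nA per count.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .waveform import RampWaveform

__all__ = [
    "FULL_SCALE_NA",
    "CorruptSegmentError",
    "RawDialectError",
    "ScanStream",
    "default_count_scale",
    "write_raw",
    "read_raw",
    "read_meta",
    "update_meta",
]

#: Current corresponding to the most positive int16 count, nanoamps.
FULL_SCALE_NA = 2000.0

_DTYPE = np.dtype("<i2")  # little-endian signed 16-bit


class RawDialectError(ValueError):
    """Missing or inconsistent sidecar metadata."""


class CorruptSegmentError(RawDialectError):
    """A segment file length is not a whole number of scans."""


def default_count_scale() -> float:
    """Nanoamps per ADC count at the default ±2,000 nA full scale."""
    return FULL_SCALE_NA / np.iinfo(np.int16).max


@dataclass
class ScanStream:
    """Per-channel sequence of voltammogram scans.

    ``scans`` is an (n_scans, samples_per_scan) array of currents in nanoamps;
    ``scan_times`` holds the start time of each scan in seconds from the
    beginning of the recording (scan index / repetition rate).
    """

    channel_id: int
    scans: np.ndarray
    scan_times: np.ndarray
    waveform: RampWaveform
    gain: float = 200.0
    segment_length: float = 30.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scans = np.atleast_2d(np.asarray(self.scans, dtype=float))
        self.scan_times = np.asarray(self.scan_times, dtype=float)

    @property
    def n_scans(self) -> int:
        return self.scans.shape[0]

    @property
    def duration(self) -> float:
        return self.n_scans * self.waveform.period

    def validate(self) -> None:
        if self.scans.shape[1] != self.waveform.samples_per_scan:
            raise ValueError(
                f"scans have {self.scans.shape[1]} samples, waveform expects "
                f"{self.waveform.samples_per_scan}"
            )
        if self.scan_times.shape[0] != self.n_scans:
            raise ValueError("scan_times length does not match scan count")
        if self.n_scans > 1:
            dt = np.diff(self.scan_times)
            if np.any(dt <= 0):
                raise ValueError("scan_times must be strictly increasing")
            if not np.allclose(dt, self.waveform.period, rtol=1e-6, atol=1e-9):
                raise ValueError("scan_times spacing must be 1/repetition_rate")
        if not (0 <= self.channel_id):
            raise ValueError("channel_id must be non-negative")

    def copy_with(self, scans: np.ndarray, **meta_updates) -> "ScanStream":
        """New stream sharing acquisition metadata but with replaced scans."""
        new_meta = dict(self.meta)
        new_meta.update(meta_updates)
        return ScanStream(
            channel_id=self.channel_id,
            scans=np.asarray(scans, dtype=float),
            scan_times=self.scan_times.copy(),
            waveform=self.waveform,
            gain=self.gain,
            segment_length=self.segment_length,
            meta=new_meta,
        )


def _waveform_to_dict(w: RampWaveform) -> dict:
    return {
        "v_hold": w.v_hold,
        "v_peak": w.v_peak,
        "scan_rate": w.scan_rate,
        "samples_per_scan": w.samples_per_scan,
        "repetition_rate": w.repetition_rate,
    }


def _waveform_from_dict(d: dict) -> RampWaveform:
    return RampWaveform(
        v_hold=d["v_hold"],
        v_peak=d["v_peak"],
        scan_rate=d["scan_rate"],
        samples_per_scan=int(d["samples_per_scan"]),
        repetition_rate=d["repetition_rate"],
    )


def write_raw(
    streams: "ScanStream | list[ScanStream]",
    directory: "str | Path",
    count_scale: "float | None" = None,
) -> Path:
    """Write one or more channel streams as the raw int16 dialect.

    Scans are flattened in time order and split into segments of
    ``segment_length`` seconds (300 scans at the 10 Hz / 30 s defaults); a
    final shorter segment holds any remainder.  Currents beyond the ±2,000 nA
    full scale are clipped with a warning.
    """
    if isinstance(streams, ScanStream):
        streams = [streams]
    if not streams:
        raise ValueError("no streams to write")
    if count_scale is None:
        count_scale = default_count_scale()

    ref = streams[0]
    for s in streams:
        s.validate()
        if s.waveform != ref.waveform or s.gain != ref.gain:
            raise ValueError("all channels in a recording must share waveform and gain")
        if s.n_scans != ref.n_scans:
            raise ValueError("all channels must have the same number of scans")

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    w = ref.waveform
    scans_per_segment = max(1, int(round(ref.segment_length * w.repetition_rate)))
    info = np.iinfo(np.int16)

    for s in streams:
        ch_dir = directory / f"ch{s.channel_id:02d}"
        ch_dir.mkdir(exist_ok=True)
        counts = np.round(s.scans / count_scale)
        if counts.max(initial=0) > info.max or counts.min(initial=0) < info.min:
            warnings.warn(
                f"channel {s.channel_id}: currents exceed the ±{FULL_SCALE_NA:g} nA "
                "full scale and were clipped",
                stacklevel=2,
            )
        counts = np.clip(counts, info.min, info.max).astype(_DTYPE)
        for k, start in enumerate(range(0, s.n_scans, scans_per_segment)):
            seg = counts[start : start + scans_per_segment]
            (ch_dir / f"seg{k:03d}.i16").write_bytes(seg.tobytes())

    meta = {
        "format": "fscv-raw",
        "version": 1,
        "endianness": "little",
        "dtype": "int16",
        "count_scale_nA": count_scale,
        "gain_nA_per_V": ref.gain,
        "waveform": _waveform_to_dict(w),
        "segment_length_s": ref.segment_length,
        "scans_per_segment": scans_per_segment,
        "n_scans": ref.n_scans,
        "channels": sorted(s.channel_id for s in streams),
    }
    # preserve user annotations (e.g. calibration factor, stim metadata)
    extra = {k: v for k, v in ref.meta.items() if isinstance(v, (int, float, str, list, dict, bool))}
    meta.update({k: v for k, v in extra.items() if k not in meta})
    (directory / "meta.json").write_text(json.dumps(meta, indent=1))
    return directory


def read_meta(directory: "str | Path") -> dict:
    path = Path(directory) / "meta.json"
    if not path.exists():
        raise RawDialectError(f"missing sidecar metadata: {path}")
    return json.loads(path.read_text())


def update_meta(directory: "str | Path", **entries) -> dict:
    """Merge extra entries (e.g. a calibration factor) into meta.json."""
    meta = read_meta(directory)
    meta.update(entries)
    (Path(directory) / "meta.json").write_text(json.dumps(meta, indent=1))
    return meta


def read_raw(directory: "str | Path") -> "list[ScanStream]":
    """Read all channels of a recording directory back into memory.

    Currents are reconstructed as ``counts * count_scale_nA``; scan times are
    rebuilt from the scan index and repetition rate.
    """
    directory = Path(directory)
    meta = read_meta(directory)
    waveform = _waveform_from_dict(meta["waveform"])
    count_scale = float(meta["count_scale_nA"])
    n_per_scan = waveform.samples_per_scan
    scan_bytes = n_per_scan * _DTYPE.itemsize

    streams = []
    for ch in meta["channels"]:
        ch_dir = directory / f"ch{int(ch):02d}"
        seg_files = sorted(ch_dir.glob("seg*.i16"))
        if not seg_files:
            raise RawDialectError(f"channel {ch}: no segment files in {ch_dir}")
        chunks = []
        for f in seg_files:
            raw = f.read_bytes()
            if len(raw) % scan_bytes:
                raise CorruptSegmentError(
                    f"{f}: {len(raw)} bytes is not a whole number of "
                    f"{n_per_scan}-sample scans"
                )
            counts = np.frombuffer(raw, dtype=_DTYPE).reshape(-1, n_per_scan)
            chunks.append(counts)
        counts = np.concatenate(chunks, axis=0)
        if "n_scans" in meta and counts.shape[0] != meta["n_scans"]:
            raise RawDialectError(
                f"channel {ch}: {counts.shape[0]} scans on disk, sidecar says "
                f"{meta['n_scans']}"
            )
        scans = counts.astype(float) * count_scale
        times = np.arange(counts.shape[0]) * waveform.period
        streams.append(
            ScanStream(
                channel_id=int(ch),
                scans=scans,
                scan_times=times,
                waveform=waveform,
                gain=float(meta["gain_nA_per_V"]),
                segment_length=float(meta["segment_length_s"]),
                meta={"source": str(directory)},
            )
        )
    return streams
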