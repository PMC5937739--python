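"""Recording containers and on-disk layouts.

The native dataset layout is one directory per recording: numeric payloads as
``.npy`` arrays, events as a TSV table (columns ``onset_s``, ``label``), and a
JSON metadata descriptor carrying rates, channel names, montage and
provenance.  A manifest with SHA-256 checksums accompanies every write.

Importers for the standard acquisition formats (EDF, BrainVision, SNIRF) map
channels by name onto the frontal montage; they are read-only.
"""

from __future__ import annotations

import hashlib
import json
import re
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

LAYOUT_VERSION = "1"

#: The ten frontal electrodes used for decoding.
FRONTAL_EEG_CHANNELS = (
    "AFp1", "AFp2", "AFF1h", "AFF2h", "AFF5h", "AFF6h", "F3", "F4", "F7", "F8",
)

#: Full cap montage: ten frontal plus twelve central/parietal/occipital sites.
EEG_CHANNELS = FRONTAL_EEG_CHANNELS + (
    "Cz", "C3", "C4", "T7", "T8", "Pz", "P3", "P4", "P7", "P8", "OI1", "OI2",
)

EOG_CHANNELS = ("EOGvu", "EOGvl", "EOGhl", "EOGhr")

VALID_LABELS = ("MA", "BL")

#: Case-insensitive aliases accepted when mapping external channel names.
_CHANNEL_ALIASES = {
    "oi1": "OI1", "oi2": "OI2", "poo1": "OI1", "poo2": "OI2",
}


class DatasetError(ValueError):
    """Raised when an on-disk dataset is structurally corrupt or invalid."""


def _canonical_name(name: str) -> str | None:
    """Map an external channel name onto the montage (case-insensitive)."""
    key = name.strip().lower()
    if key in _CHANNEL_ALIASES:
        return _CHANNEL_ALIASES[key]
    for known in EEG_CHANNELS + EOG_CHANNELS:
        if known.lower() == key:
            return known
    return None


@dataclass
class Montage:
    """Channel-name metadata for both modalities.

    ``nirs_pairs`` holds (source, detector) indices for the nine prefrontal
    channels; ``distance_mm`` is the inter-optode separation.
    """

    eeg_channels: tuple[str, ...] = EEG_CHANNELS
    eog_channels: tuple[str, ...] = EOG_CHANNELS
    nirs_pairs: tuple[tuple[int, int], ...] = tuple(
        (s, d) for s, d in [(1, 1), (2, 1), (3, 1), (2, 2), (3, 2),
                            (4, 2), (3, 3), (4, 3), (5, 3)]
    )
    distance_mm: float = 30.0

    @property
    def frontal_mask(self) -> np.ndarray:
        return np.array([c in FRONTAL_EEG_CHANNELS for c in self.eeg_channels])

    @property
    def n_nirs_channels(self) -> int:
        return len(self.nirs_pairs)


@dataclass
class RawRecording:
    """Synchronised EEG/EOG/NIRS-intensity streams plus event markers.

    EEG and EOG are in microvolts on a common clock starting at t = 0 s;
    NIRS raw intensities are strictly positive and dimensionless (per
    wavelength).  Event onsets mark the start of the 10 s task period.
    """

    eeg: np.ndarray                      # (n_eeg, n_samp_eeg) µV
    eog: np.ndarray                      # (4, n_samp_eeg) µV
    nirs_intensity: np.ndarray           # (9, 2, n_samp_nirs) a.u.
    events: list[tuple[float, str]]      # (onset_s, "MA"|"BL")
    eeg_rate_hz: float = 1000.0
    nirs_rate_hz: float = 12.5
    nirs_wavelengths_nm: tuple[float, float] = (760.0, 850.0)
    montage: Montage = field(default_factory=Montage)
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.eeg.ndim != 2 or self.eog.ndim != 2:
            raise DatasetError("eeg/eog must be 2-D (channels x samples)")
        if self.eeg.shape[0] != len(self.montage.eeg_channels):
            raise DatasetError(
                f"eeg has {self.eeg.shape[0]} rows but montage names "
                f"{len(self.montage.eeg_channels)} channels")
        if self.eog.shape[0] != len(self.montage.eog_channels):
            raise DatasetError("eog must have one row per EOG channel")
        if self.eeg.shape[1] != self.eog.shape[1]:
            raise DatasetError("eeg and eog sample counts differ")
        if self.nirs_intensity.ndim != 3 or self.nirs_intensity.shape[1] != 2:
            raise DatasetError(
                "nirs_intensity must be (channels, 2 wavelengths, samples)")
        bad = np.argwhere(~(self.nirs_intensity > 0))
        if bad.size:
            c, w, s = bad[0]
            raise DatasetError(
                f"non-positive NIRS intensity at channel {c}, wavelength "
                f"index {w}, sample {s}")
        dur = self.duration_s
        for i, (onset, label) in enumerate(self.events):
            if label not in VALID_LABELS:
                raise DatasetError(f"event {i}: unknown label {label!r}")
            if not 0 <= onset < dur:
                raise DatasetError(
                    f"event {i}: onset {onset} s outside recording "
                    f"(duration {dur:.2f} s)")

    @property
    def duration_s(self) -> float:
        return self.eeg.shape[1] / self.eeg_rate_hz

    @property
    def frontal_eeg(self) -> np.ndarray:
        return self.eeg[self.montage.frontal_mask]

    def __eq__(self, other) -> bool:  # bit-exact payloads, equal metadata
        if not isinstance(other, RawRecording):
            return NotImplemented
        return (
            np.array_equal(self.eeg, other.eeg)
            and np.array_equal(self.eog, other.eog)
            and np.array_equal(self.nirs_intensity, other.nirs_intensity)
            and self.events == other.events
            and self.eeg_rate_hz == other.eeg_rate_hz
            and self.nirs_rate_hz == other.nirs_rate_hz
            and tuple(self.nirs_wavelengths_nm) == tuple(other.nirs_wavelengths_nm)
            and tuple(self.montage.eeg_channels) == tuple(other.montage.eeg_channels)
        )


# ---------------------------------------------------------------------------
# native layout
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_dataset(rec: RawRecording, path: str | Path, *,
                  overwrite: bool = False) -> dict:
    """Write ``rec`` to a dataset directory; return the checksum manifest."""
    rec.validate()
    path = Path(path)
    if path.exists() and any(path.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{path} exists and is not empty (pass overwrite=True)")
    path.mkdir(parents=True, exist_ok=True)

    np.save(path / "eeg.npy", rec.eeg)
    np.save(path / "eog.npy", rec.eog)
    np.save(path / "nirs_intensity.npy", rec.nirs_intensity)
    events = pd.DataFrame(rec.events, columns=["onset_s", "label"])
    events.to_csv(path / "events.tsv", sep="\t", index=False)

    meta = {
        "version": LAYOUT_VERSION,
        "eeg_rate_hz": rec.eeg_rate_hz,
        "nirs_rate_hz": rec.nirs_rate_hz,
        "nirs_wavelengths_nm": list(rec.nirs_wavelengths_nm),
        "eeg_channels": list(rec.montage.eeg_channels),
        "eog_channels": list(rec.montage.eog_channels),
        "nirs_pairs": [list(p) for p in rec.montage.nirs_pairs],
        "distance_mm": rec.montage.distance_mm,
        "units": {"eeg": "uV", "eog": "uV", "nirs_intensity": "a.u."},
        "provenance": rec.meta,
    }
    with open(path / "metadata.json", "w") as f:
        json.dump(meta, f, indent=1, sort_keys=True)

    files = ["eeg.npy", "eog.npy", "nirs_intensity.npy", "events.tsv",
             "metadata.json"]
    manifest = {"version": LAYOUT_VERSION,
                "files": {name: _sha256(path / name) for name in files}}
    with open(path / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1, sort_keys=True)
    return manifest


def read_dataset(path: str | Path) -> RawRecording:
    """Load a native-layout dataset, validating all invariants."""
    path = Path(path)
    meta_path = path / "metadata.json"
    if not meta_path.exists():
        raise DatasetError(f"corrupt dataset: missing {meta_path}")
    with open(meta_path) as f:
        meta = json.load(f)
    if "version" not in meta:
        raise DatasetError("corrupt dataset: metadata lacks a version field")

    eeg = np.load(path / "eeg.npy")
    eog = np.load(path / "eog.npy")
    nirs = np.load(path / "nirs_intensity.npy")
    events_df = pd.read_csv(path / "events.tsv", sep="\t")
    events = []
    for i, row in events_df.iterrows():
        label = str(row["label"])
        if label not in VALID_LABELS:
            raise DatasetError(
                f"events.tsv line {i + 2}: unknown label {label!r}")
        events.append((float(row["onset_s"]), label))

    montage = Montage(
        eeg_channels=tuple(meta["eeg_channels"]),
        eog_channels=tuple(meta["eog_channels"]),
        nirs_pairs=tuple(tuple(p) for p in meta["nirs_pairs"]),
        distance_mm=meta["distance_mm"],
    )
    rec = RawRecording(
        eeg=eeg, eog=eog, nirs_intensity=nirs, events=events,
        eeg_rate_hz=meta["eeg_rate_hz"], nirs_rate_hz=meta["nirs_rate_hz"],
        nirs_wavelengths_nm=tuple(meta["nirs_wavelengths_nm"]),
        montage=montage, meta=meta.get("provenance", {}),
    )
    n_expected = round(rec.nirs_intensity.shape[2]
                       * rec.eeg_rate_hz / rec.nirs_rate_hz)
    if abs(rec.eeg.shape[1] - n_expected) > rec.eeg_rate_hz / rec.nirs_rate_hz:
        raise DatasetError(
            "rate mismatch: EEG and NIRS sample counts disagree with the "
            "declared sampling rates")
    rec.validate()
    return rec


# ---------------------------------------------------------------------------
# standard-format importers
# ---------------------------------------------------------------------------

def import_standard(path: str | Path, kind: str) -> RawRecording:
    """Import an EDF, BrainVision or SNIRF file as a (partial) RawRecording.

    EEG importers return a recording whose montage names only the channels
    found in the file; channels that match the frontal montage by name are
    flagged frontal, unmapped channels are retained unflagged.  The SNIRF
    importer fills only the NIRS block.
    """
    kind = kind.upper()
    if kind == "EDF":
        return _import_edf(Path(path))
    if kind == "BRAINVISION":
        return _import_brainvision(Path(path))
    if kind == "SNIRF":
        return _import_snirf(Path(path))
    raise ValueError(f"unknown import kind {kind!r}")


def _finish_eeg_import(names: list[str], data: np.ndarray,
                       rate: float, events: list[tuple[float, str]],
                       source: str) -> RawRecording:
    canon = [_canonical_name(n) or n for n in names]
    frontal_found = [c for c in canon if c in FRONTAL_EEG_CHANNELS]
    if not frontal_found:
        raise DatasetError(f"{source}: no frontal EEG channels found")
    missing = sorted(set(FRONTAL_EEG_CHANNELS) - set(frontal_found))
    if missing:
        warnings.warn(
            f"{source}: missing {len(missing)} frontal channels: "
            + ", ".join(missing), stacklevel=3)
    eog_idx = [i for i, c in enumerate(canon) if c in EOG_CHANNELS]
    eeg_idx = [i for i in range(len(canon)) if i not in eog_idx]
    n = data.shape[1]
    eog = data[eog_idx] if eog_idx else np.zeros((len(EOG_CHANNELS), n))
    montage = Montage(
        eeg_channels=tuple(canon[i] for i in eeg_idx),
        eog_channels=(tuple(canon[i] for i in eog_idx)
                      if eog_idx else EOG_CHANNELS),
    )
    rec = RawRecording(
        eeg=data[eeg_idx], eog=eog,
        nirs_intensity=np.ones((9, 2, max(1, int(round(n / rate * 12.5))))),
        events=events, eeg_rate_hz=rate, montage=montage,
        meta={"source": source},
    )
    return rec


def _import_edf(path: Path) -> RawRecording:
    """Minimal EDF(+) reader: 16-bit records with physical scaling."""
    with open(path, "rb") as f:
        header = f.read(256)
        if len(header) < 256:
            raise DatasetError(f"{path}: truncated EDF header")
        n_records = int(header[236:244].decode("ascii").strip())
        record_dur = float(header[244:252].decode("ascii").strip())
        ns = int(header[252:256].decode("ascii").strip())

        def fields(width):
            raw = f.read(width * ns)
            return [raw[i * width:(i + 1) * width].decode("ascii").strip()
                    for i in range(ns)]

        labels = fields(16)
        fields(80)                      # transducer
        fields(8)                       # physical dimension
        pmin = np.array([float(x) for x in fields(8)])
        pmax = np.array([float(x) for x in fields(8)])
        dmin = np.array([float(x) for x in fields(8)])
        dmax = np.array([float(x) for x in fields(8)])
        fields(80)                      # prefiltering
        nsamp = np.array([int(x) for x in fields(8)])
        fields(32)                      # reserved

        data = [np.empty(n_records * k, dtype=np.float64) for k in nsamp]
        for r in range(n_records):
            for s in range(ns):
                raw = np.frombuffer(f.read(2 * nsamp[s]), dtype="<i2")
                if raw.size < nsamp[s]:
                    raise DatasetError(f"{path}: truncated EDF data record")
                scale = (pmax[s] - pmin[s]) / (dmax[s] - dmin[s])
                data[s][r * nsamp[s]:(r + 1) * nsamp[s]] = (
                    pmin[s] + (raw - dmin[s]) * scale)

    rates = nsamp / record_dur
    keep = [i for i in range(ns)
            if not labels[i].lower().startswith(("edf annotations",))]
    rate = float(rates[keep[0]])
    if any(rates[i] != rate for i in keep):
        raise DatasetError(f"{path}: mixed EDF sampling rates not supported")
    block = np.vstack([data[i] for i in keep])
    names = [re.sub(r"^(EEG|EOG)\s+", "", labels[i]) for i in keep]
    return _finish_eeg_import(names, block, rate, [], str(path))


def _parse_vhdr(path: Path) -> dict:
    sections: dict[str, dict[str, str]] = {}
    current = None
    for line in path.read_text(encoding="utf-8", errors="replace").splitlines():
        line = line.strip()
        if not line or line.startswith((";", "#")):
            continue
        m = re.match(r"\[(.+)\]$", line)
        if m:
            current = m.group(1)
            sections[current] = {}
        elif "=" in line and current:
            k, v = line.split("=", 1)
            sections[current][k.strip()] = v.strip()
    return sections


def _import_brainvision(path: Path) -> RawRecording:
    """BrainVision .vhdr + binary .eeg (+ optional .vmrk markers)."""
    sec = _parse_vhdr(path)
    common = sec.get("Common Infos", {})
    binary = sec.get("Binary Infos", {})
    chans = sec.get("Channel Infos", {})

    data_file = path.parent / common["DataFile"]
    if not data_file.exists():
        raise IOError(f"{path}: data file {data_file} not found")
    n_ch = int(common["NumberOfChannels"])
    rate = 1e6 / float(common["SamplingInterval"])
    fmt = binary.get("BinaryFormat", "IEEE_FLOAT_32")
    dtype = {"IEEE_FLOAT_32": "<f4", "INT_16": "<i2"}[fmt]

    names, res = [], []
    for i in range(1, n_ch + 1):
        parts = chans[f"Ch{i}"].split(",")
        names.append(parts[0])
        res.append(float(parts[2]) if len(parts) > 2 and parts[2] else 1.0)
    raw = np.fromfile(data_file, dtype=dtype).astype(np.float64)
    data = raw.reshape(-1, n_ch).T * np.asarray(res)[:, None]

    events: list[tuple[float, str]] = []
    marker_file = common.get("MarkerFile")
    if marker_file and (path.parent / marker_file).exists():
        msec = _parse_vhdr(path.parent / marker_file)
        for val in msec.get("Marker Infos", {}).values():
            parts = val.split(",")
            if len(parts) >= 3 and parts[0] == "Stimulus":
                desc = parts[1].strip()
                label = {"S  1": "MA", "S  2": "BL"}.get(desc, desc)
                if label in VALID_LABELS:
                    events.append((int(parts[2]) / rate, label))
    return _finish_eeg_import(names, data, rate, events, str(path))


def _import_snirf(path: Path) -> RawRecording:
    """SNIRF (HDF5) continuous-wave intensity reader: NIRS block only."""
    with h5py.File(path, "r") as f:
        nirs = f["/nirs"] if "nirs" in f else f["/nirs1"]
        data = nirs["data1"]
        ts = np.asarray(data["dataTimeSeries"], dtype=np.float64)  # T x M
        t = np.asarray(data["time"]).ravel()
        rate = 1.0 / np.median(np.diff(t)) if t.size > 1 else 12.5

        meas = []
        for key in sorted(k for k in data.keys()
                          if k.startswith("measurementList")):
            ml = data[key]
            meas.append((int(ml["sourceIndex"][()]),
                         int(ml["detectorIndex"][()]),
                         int(ml["wavelengthIndex"][()])))
        wls = np.asarray(nirs["probe"]["wavelengths"]).ravel()
        if len(wls) != 2:
            raise DatasetError(f"{path}: need exactly two wavelengths, "
                               f"found {len(wls)}")
        pairs = sorted({(s, d) for s, d, _ in meas})
        n_ch, n_t = len(pairs), ts.shape[0]
        block = np.zeros((n_ch, 2, n_t))
        for col, (s, d, w) in enumerate(meas):
            block[pairs.index((s, d)), w - 1] = ts[:, col]

        events = []
        for key in sorted(k for k in nirs.keys() if k.startswith("stim")):
            name = nirs[key]["name"][()]
            name = name.decode() if isinstance(name, bytes) else str(name)
            if name in VALID_LABELS:
                for onset in np.atleast_2d(nirs[key]["data"][()])[:, 0]:
                    events.append((float(onset), name))
        events.sort()

    n_eeg = max(1, int(round(n_t / rate * 1000)))
    montage = Montage(nirs_pairs=tuple(pairs))
    # EEG block left empty: SNIRF carries no electrophysiology.
    rec = RawRecording(
        eeg=np.zeros((len(EEG_CHANNELS), n_eeg)),
        eog=np.zeros((len(EOG_CHANNELS), n_eeg)),
        nirs_intensity=block, events=events,
        nirs_rate_hz=float(rate), nirs_wavelengths_nm=tuple(wls),
        montage=montage, meta={"source": str(path)},
    )
    return rec
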