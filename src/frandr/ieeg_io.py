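"""Reading, validation, resampling and re-referencing of intracranial EEG.

The pipeline's in-memory data model is a :class:`Recording`: a channels-by-time
array in microvolts plus per-channel metadata.  Depth-electrode contacts are
described by :class:`ContactInfo` (shank, position on the shank, anatomical
region, hemisphere, seizure-onset-zone membership); after re-referencing, each
channel is the difference of two adjacent contacts on the same shank
(:class:`BipolarChannelInfo`).

Two on-disk formats are supported: EDF/EDF+ (via :mod:`mne`) and a plain-text
fixture format (whitespace-delimited sample matrix with a leading label column,
plus a metadata CSV) used for synthetic studies and tests.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

logger = logging.getLogger("frandr.ieeg_io")

REGIONS = ("hippocampus", "entorhinal", "amygdala", "other")
HEMISPHERES = ("left", "right")

META_COLUMNS = ["label", "shank_id", "index_on_shank", "region", "hemisphere", "soz"]


class ValidationError(ValueError):
    """Inconsistent channel metadata or unknown labels."""


class UnsupportedFormatError(ValueError):
    """Input file violates a format precondition (e.g. mixed sampling rates)."""


@dataclass(frozen=True)
class ContactInfo:
    """One physical electrode contact."""

    label: str
    shank_id: str
    index_on_shank: int
    region: str
    hemisphere: str
    soz: bool

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ValidationError(f"unknown region {self.region!r} for contact {self.label!r}")
        if self.hemisphere not in HEMISPHERES:
            raise ValidationError(
                f"unknown hemisphere {self.hemisphere!r} for contact {self.label!r}"
            )
        if self.index_on_shank < 1:
            raise ValidationError(f"index_on_shank must be >= 1 for contact {self.label!r}")


@dataclass(frozen=True)
class BipolarChannelInfo:
    """Difference channel between two adjacent contacts on one shank.

    ``soz`` is true when either constituent contact is inside the SOZ;
    ``region`` is inherited from the deeper contact (lower index on the shank)
    when the pair straddles a region boundary.
    """

    anode: ContactInfo
    cathode: ContactInfo
    label: str
    region: str
    soz: bool

    @property
    def hemisphere(self) -> str:
        return self.anode.hemisphere

    @classmethod
    def from_contacts(cls, anode: ContactInfo, cathode: ContactInfo) -> "BipolarChannelInfo":
        if anode.shank_id != cathode.shank_id:
            raise ValidationError(
                f"bipolar pair must share a shank: {anode.label!r} / {cathode.label!r}"
            )
        if abs(anode.index_on_shank - cathode.index_on_shank) != 1:
            raise ValidationError(
                f"bipolar pair must be adjacent: {anode.label!r} / {cathode.label!r}"
            )
        deeper = anode if anode.index_on_shank < cathode.index_on_shank else cathode
        return cls(
            anode=anode,
            cathode=cathode,
            label=f"{anode.label}-{cathode.label}",
            region=deeper.region,
            soz=anode.soz or cathode.soz,
        )


@dataclass
class Recording:
    """Multichannel iEEG segment: ``samples`` is (n_channels, n_samples), µV."""

    samples: np.ndarray
    rate: float
    channels: list
    montage: str  # "referential" | "bipolar"
    t0: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValidationError("samples must be a 2-D (channels x time) array")
        if self.rate <= 0:
            raise ValidationError("sampling rate must be positive")
        if len(self.channels) != self.samples.shape[0]:
            raise ValidationError(
                f"{len(self.channels)} channel descriptors for {self.samples.shape[0]} rows"
            )
        if self.montage not in ("referential", "bipolar"):
            raise ValidationError(f"unknown montage {self.montage!r}")
        if self.montage == "bipolar" and not all(
            isinstance(c, BipolarChannelInfo) for c in self.channels
        ):
            raise ValidationError("bipolar montage requires BipolarChannelInfo channels")
        _check_contact_uniqueness(self.channels)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    @property
    def labels(self) -> list:
        return [c.label for c in self.channels]


def _check_contact_uniqueness(channels, require_contiguous: bool = False) -> None:
    """Duplicate (shank, index) pairs are always an error; contiguity of the
    indices on each shank is enforced only for freshly read recordings
    (channel exclusion legitimately leaves gaps mid-shank)."""
    contacts = [c for c in channels if isinstance(c, ContactInfo)]
    seen = {}
    for c in contacts:
        key = (c.shank_id, c.index_on_shank)
        if key in seen:
            raise ValidationError(
                f"duplicate (shank, index) {key} for contacts {seen[key]!r} and {c.label!r}"
            )
        seen[key] = c.label
    if not require_contiguous:
        return
    by_shank: dict = {}
    for c in contacts:
        by_shank.setdefault(c.shank_id, []).append(c.index_on_shank)
    for shank, idx in by_shank.items():
        idx = sorted(idx)
        if idx != list(range(idx[0], idx[0] + len(idx))):
            raise ValidationError(f"contact indices on shank {shank!r} are not contiguous: {idx}")


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

_LABEL_RE = re.compile(r"^(?P<shank>[A-Za-z]+)(?P<idx>\d+)$")


def _contact_from_label(label: str) -> ContactInfo:
    """Provisional contact metadata parsed from a bare channel label.

    EDF headers carry no anatomical information, so region defaults to
    "other" and the hemisphere is guessed from the customary trailing L/R of
    the shank name.  Use :func:`attach_metadata` to supply the real metadata.
    """
    m = _LABEL_RE.match(label.strip())
    if m:
        shank = m.group("shank")
        idx = int(m.group("idx"))
    else:
        shank, idx = label.strip(), 1
    hemisphere = "right" if shank.upper().endswith("R") else "left"
    return ContactInfo(
        label=label.strip(),
        shank_id=shank,
        index_on_shank=idx,
        region="other",
        hemisphere=hemisphere,
        soz=False,
    )


def _edf_samples_per_record(path: Path) -> tuple[list, list]:
    """Read per-signal labels and samples-per-record from the EDF header."""
    with open(path, "rb") as fh:
        header = fh.read(256)
        if len(header) < 256:
            raise UnsupportedFormatError(f"{path}: truncated EDF header")
        ns = int(header[252:256].decode("ascii").strip())
        sig_header = fh.read(ns * 256)
    labels = [
        sig_header[i * 16 : (i + 1) * 16].decode("ascii", "replace").strip() for i in range(ns)
    ]
    off = ns * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
    spr = [
        int(sig_header[off + i * 8 : off + (i + 1) * 8].decode("ascii").strip())
        for i in range(ns)
    ]
    return labels, spr


def read_edf(path) -> Recording:
    """Read an EDF/EDF+ file into a referential-montage :class:`Recording`.

    Sample values are converted to microvolts using the EDF physical-dimension
    fields.  All channels must share one sampling rate; annotation channels
    are dropped.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    labels, spr = _edf_samples_per_record(path)
    data_spr = {
        lab: n for lab, n in zip(labels, spr) if "annotation" not in lab.lower()
    }
    if len(set(data_spr.values())) > 1:
        counts: dict = {}
        for lab, n in data_spr.items():
            counts.setdefault(n, []).append(lab)
        raise UnsupportedFormatError(
            f"{path}: mixed per-channel sampling rates; offending channels: "
            + "; ".join(f"{n} samples/record: {labs}" for n, labs in sorted(counts.items()))
        )
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    picks = [i for i, name in enumerate(raw.ch_names) if "annotation" not in name.lower()]
    data = raw.get_data(picks=picks) * 1e6  # MNE loads in volts
    channels = [_contact_from_label(raw.ch_names[i]) for i in picks]
    return Recording(samples=data, rate=float(raw.info["sfreq"]), channels=channels,
                     montage="referential")


# ---------------------------------------------------------------------------
# fixture format
# ---------------------------------------------------------------------------


def read_channel_metadata(meta_path) -> list[ContactInfo]:
    """Read contact metadata CSV (columns: label, shank_id, index_on_shank,
    region, hemisphere, soz)."""
    meta = pd.read_csv(meta_path)
    missing = set(META_COLUMNS) - set(meta.columns)
    if missing:
        raise ValidationError(f"metadata file missing columns: {sorted(missing)}")
    contacts = [
        ContactInfo(
            label=str(r.label),
            shank_id=str(r.shank_id),
            index_on_shank=int(r.index_on_shank),
            region=str(r.region),
            hemisphere=str(r.hemisphere),
            soz=_parse_bool(r.soz),
        )
        for r in meta.itertuples()
    ]
    _check_contact_uniqueness(contacts)
    return contacts


def _parse_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("1", "true", "yes")
    return bool(v)


def read_fixture(signal_path, meta_path, rate: float | None = None) -> Recording:
    """Read the plain-text fixture pair into a referential Recording.

    The signal file holds one whitespace-delimited row per channel: the
    channel label followed by its samples in microvolts.  A leading comment
    line ``# rate=<Hz>`` records the sampling rate (or pass ``rate=``).
    Metadata rows are joined to signal rows by label; signal row order wins.
    """
    signal_path = Path(signal_path)
    labels, rows = [], []
    file_rate = None
    with open(signal_path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.search(r"rate\s*=\s*([0-9.eE+-]+)", line)
                if m:
                    file_rate = float(m.group(1))
                continue
            parts = line.split()
            labels.append(parts[0])
            rows.append(np.array(parts[1:], dtype=np.float64))
    if not rows:
        raise UnsupportedFormatError(f"{signal_path}: no channel rows")
    if len({r.size for r in rows}) > 1:
        raise UnsupportedFormatError(f"{signal_path}: channel rows differ in length")
    rate = rate if rate is not None else file_rate
    if rate is None:
        raise UnsupportedFormatError(f"{signal_path}: sampling rate not given in file or call")
    contacts = {c.label: c for c in read_channel_metadata(meta_path)}
    missing = [lab for lab in labels if lab not in contacts]
    if missing:
        raise ValidationError(f"labels absent from metadata: {missing}")
    selected = [contacts[lab] for lab in labels]
    _check_contact_uniqueness(selected, require_contiguous=True)
    return Recording(
        samples=np.vstack(rows),
        rate=float(rate),
        channels=selected,
        montage="referential",
    )


def write_fixture(rec: Recording, signal_path, meta_path) -> None:
    """Write the fixture pair.  Samples use repr-precision ``%.17g`` so a
    read/write round trip is bit-exact for float64 data."""
    if rec.montage != "referential":
        raise ValidationError("fixture format stores referential recordings")
    signal_path, meta_path = Path(signal_path), Path(meta_path)
    with open(signal_path, "w") as fh:
        fh.write(f"# rate={rec.rate:.17g}\n")
        for lab, row in zip(rec.labels, rec.samples):
            fh.write(lab + " " + " ".join(f"{v:.17g}" for v in row) + "\n")
    pd.DataFrame(
        [
            {
                "label": c.label,
                "shank_id": c.shank_id,
                "index_on_shank": c.index_on_shank,
                "region": c.region,
                "hemisphere": c.hemisphere,
                "soz": c.soz,
            }
            for c in rec.channels
        ]
    ).to_csv(meta_path, index=False)


def attach_metadata(rec: Recording, contacts: list[ContactInfo]) -> Recording:
    """Replace provisional channel metadata (e.g. from EDF) by label join."""
    lookup = {c.label: c for c in contacts}
    missing = [lab for lab in rec.labels if lab not in lookup]
    if missing:
        raise ValidationError(f"labels absent from metadata: {missing}")
    return Recording(
        samples=rec.samples,
        rate=rec.rate,
        channels=[lookup[lab] for lab in rec.labels],
        montage=rec.montage,
        t0=rec.t0,
    )


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------


def resample(rec: Recording, target_rate: float) -> Recording:
    """Anti-alias filtered rate conversion (polyphase, Kaiser window).

    Only downsampling (or identity) is supported; the rate ratio must be
    rational.  Duration is preserved to within one sample period.
    """
    if target_rate > rec.rate:
        raise UnsupportedFormatError(
            f"upsampling not supported ({rec.rate} -> {target_rate} Hz)"
        )
    if target_rate == rec.rate:
        return rec
    ratio = Fraction(target_rate / rec.rate).limit_denominator(1000)
    up, down = ratio.numerator, ratio.denominator
    out = sps.resample_poly(rec.samples, up, down, axis=1, window=("kaiser", 8.0))
    return Recording(samples=out, rate=float(target_rate), channels=list(rec.channels),
                     montage=rec.montage, t0=rec.t0)


def to_bipolar(rec: Recording) -> Recording:
    """Re-reference to a bipolar montage: contact_i − contact_{i+1} per shank.

    A shank with a single contact is skipped with a warning.  Shank order
    follows first appearance in the referential recording; within a shank,
    pairs ascend with contact index.
    """
    if rec.montage != "referential":
        raise ValidationError("to_bipolar expects a referential recording")
    shank_order: list = []
    by_shank: dict = {}
    for i, c in enumerate(rec.channels):
        if not isinstance(c, ContactInfo):
            raise ValidationError("to_bipolar expects ContactInfo channels")
        if c.shank_id not in by_shank:
            shank_order.append(c.shank_id)
            by_shank[c.shank_id] = []
        by_shank[c.shank_id].append((c.index_on_shank, i, c))
    rows, infos = [], []
    for shank in shank_order:
        entries = sorted(by_shank[shank])
        if len(entries) < 2:
            logger.warning("shank %r has a single contact; skipped in bipolar montage", shank)
            continue
        for (idx_a, i_a, c_a), (idx_b, i_b, c_b) in zip(entries[:-1], entries[1:]):
            if idx_b - idx_a != 1:
                # gap left by an excluded contact: no valid adjacent pair
                continue
            rows.append(rec.samples[i_a] - rec.samples[i_b])
            infos.append(BipolarChannelInfo.from_contacts(c_a, c_b))
    return Recording(samples=np.vstack(rows) if rows else np.empty((0, rec.n_samples)),
                     rate=rec.rate, channels=infos, montage="bipolar", t0=rec.t0)


def exclude_channels(rec: Recording, exclude: list) -> Recording:
    """Drop the named channels, preserving the order of the rest."""
    unknown = [lab for lab in exclude if lab not in rec.labels]
    if unknown:
        raise ValidationError(f"cannot exclude unknown channels: {unknown}")
    if not exclude:
        return rec
    keep = [i for i, lab in enumerate(rec.labels) if lab not in set(exclude)]
    return Recording(samples=rec.samples[keep], rate=rec.rate,
                     channels=[rec.channels[i] for i in keep],
                     montage=rec.montage, t0=rec.t0)
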