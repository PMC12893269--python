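"""Recording container I/O and result export.

The vendor MEA format is proprietary, so recordings live in a documented open
HDF5 container:

* ``/data`` — float32, channels x samples, in microvolts (recording electrodes
  only, reference excluded);
* ``/layout`` — one row per electrode: grid row, grid column, is_reference;
* ``/epochs`` — (label, start_s, end_s) rows;
* root attributes ``fs_hz``, ``mg_mM``, ``k_mM``, ``drug_name``, ``drug_conc_uM``.

Conventions fixed once for the whole package: voltage in microvolts, time in
seconds, sample indices 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from ictalmea.errors import ConsistencyError, FormatError

EPOCH_LABELS = ("baseline", "treatment", "washout")


@dataclass
class ElectrodeLayout:
    """8x8 MEA grid: 60 electrodes (corners absent), one of them the reference.

    The modelled array has 59 recording electrodes plus 1 reference in an 8x8
    layout, 100 um electrode diameter, 700 um pitch.
    """

    positions: list[tuple[int, int]]
    reference_index: int
    electrode_diameter_um: float = 100.0
    pitch_um: float = 700.0

    def __post_init__(self) -> None:
        if len(self.positions) != 60 or len(set(self.positions)) != 60:
            raise ConsistencyError(f"layout needs exactly 60 unique positions, got {len(self.positions)}")
        if not 0 <= self.reference_index < 60:
            raise ConsistencyError("reference_index out of range")

    @classmethod
    def default(cls) -> "ElectrodeLayout":
        positions = [
            (r, c)
            for r in range(8)
            for c in range(8)
            if (r, c) not in {(0, 0), (0, 7), (7, 0), (7, 7)}
        ]
        return cls(positions=positions, reference_index=0)

    @property
    def n_recording(self) -> int:
        return 59

    @property
    def recording_positions(self) -> list[tuple[int, int]]:
        """Grid positions of the 59 recording electrodes, in channel order."""
        return [p for i, p in enumerate(self.positions) if i != self.reference_index]


@dataclass
class Recording:
    """A multichannel extracellular voltage recording with epoch metadata.

    ``data`` holds the 59 recording electrodes (channels x samples, uV);
    ``condition`` records the pro-ictal ACSF composition ([Mg2+]_o, [K+]_o) and
    any bath-applied drug; ``epochs`` are non-overlapping labelled windows.
    """

    data: np.ndarray
    fs_hz: float
    layout: ElectrodeLayout
    condition: dict = field(default_factory=lambda: {"mg_mM": 0.0, "k_mM": 6.0, "drug_name": "", "drug_conc_uM": 0.0})
    epochs: list[tuple[str, float, float]] = field(default_factory=list)
    preprocessing: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ConsistencyError("data must be channels x samples")
        if self.data.shape[0] != self.layout.n_recording:
            raise ConsistencyError(
                f"data has {self.data.shape[0]} channels; layout defines {self.layout.n_recording} recording electrodes"
            )
        if not np.all(np.isfinite(self.data)):
            raise ConsistencyError("data contains non-finite samples")
        t_max = self.data.shape[1] / self.fs_hz
        prev_end = None
        for label, start, end in sorted(self.epochs, key=lambda e: e[1]):
            if label not in EPOCH_LABELS:
                raise ConsistencyError(f"unknown epoch label {label!r}")
            if not (0.0 <= start < end <= t_max + 1e-9):
                raise ConsistencyError(f"epoch ({label}, {start}, {end}) outside [0, {t_max:.3f}]")
            if prev_end is not None and start < prev_end - 1e-9:
                raise ConsistencyError("epochs overlap")
            prev_end = end
        self.epochs = sorted(self.epochs, key=lambda e: e[1])

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def epoch_slice(self, label: str) -> tuple[float, float]:
        for lab, start, end in self.epochs:
            if lab == label:
                return start, end
        raise KeyError(f"no epoch labelled {label!r}")


_ROOT_ATTRS = ("fs_hz", "mg_mM", "k_mM", "drug_name", "drug_conc_uM")


def write_recording(rec: Recording, path: "str | Path") -> Path:
    """Write a :class:`Recording` to the HDF5 container."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data.astype(np.float32))
        layout_dtype = np.dtype([("row", "i4"), ("col", "i4"), ("is_reference", "i1")])
        layout_arr = np.array(
            [
                (r, c, 1 if i == rec.layout.reference_index else 0)
                for i, (r, c) in enumerate(rec.layout.positions)
            ],
            dtype=layout_dtype,
        )
        f.create_dataset("layout", data=layout_arr)
        ep_dtype = np.dtype([("label", "S16"), ("start_s", "f8"), ("end_s", "f8")])
        ep_arr = np.array(
            [(lab.encode(), s, e) for lab, s, e in rec.epochs], dtype=ep_dtype
        )
        f.create_dataset("epochs", data=ep_arr)
        f.attrs["fs_hz"] = float(rec.fs_hz)
        f.attrs["mg_mM"] = float(rec.condition.get("mg_mM", 0.0))
        f.attrs["k_mM"] = float(rec.condition.get("k_mM", 0.0))
        f.attrs["drug_name"] = str(rec.condition.get("drug_name", ""))
        f.attrs["drug_conc_uM"] = float(rec.condition.get("drug_conc_uM", 0.0))
        f.attrs["electrode_diameter_um"] = rec.layout.electrode_diameter_um
        f.attrs["pitch_um"] = rec.layout.pitch_um
    return path


def read_recording(path: "str | Path") -> Recording:
    """Read a :class:`Recording`; raises :class:`FormatError` naming any missing element."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        for ds in ("data", "layout", "epochs"):
            if ds not in f:
                raise FormatError(f"missing dataset '/{ds}' in {path.name}")
        for attr in _ROOT_ATTRS:
            if attr not in f.attrs:
                raise FormatError(f"missing root attribute '{attr}' in {path.name}")
        data = f["data"][()]
        layout_arr = f["layout"][()]
        positions = [(int(r), int(c)) for r, c, _ in layout_arr]
        ref_idx = [i for i, (_, _, is_ref) in enumerate(layout_arr) if is_ref]
        if len(ref_idx) != 1:
            raise FormatError(f"layout must mark exactly 1 reference electrode, found {len(ref_idx)}")
        layout = ElectrodeLayout(
            positions=positions,
            reference_index=ref_idx[0],
            electrode_diameter_um=float(f.attrs.get("electrode_diameter_um", 100.0)),
            pitch_um=float(f.attrs.get("pitch_um", 700.0)),
        )
        epochs = [
            (lab.decode() if isinstance(lab, bytes) else str(lab), float(s), float(e))
            for lab, s, e in f["epochs"][()]
        ]
        condition = {
            "mg_mM": float(f.attrs["mg_mM"]),
            "k_mM": float(f.attrs["k_mM"]),
            "drug_name": str(f.attrs["drug_name"]),
            "drug_conc_uM": float(f.attrs["drug_conc_uM"]),
        }
        fs = float(f.attrs["fs_hz"])
    if data.shape[0] != layout.n_recording:
        raise ConsistencyError(
            f"data has {data.shape[0]} channels but layout defines {layout.n_recording} recording electrodes"
        )
    return Recording(data=data, fs_hz=fs, layout=layout, condition=condition, epochs=epochs)


EVENT_COLUMNS = [
    "source",
    "kind",
    "start_s",
    "end_s",
    "n_discharges",
    "onset_class",
    "spatial_extent",
    "excluded",
]


def write_results(events, metrics: pd.DataFrame, out_dir: "str | Path", config: dict | None = None, seed: int | None = None) -> dict:
    """Write events and metrics CSVs plus a JSON sidecar with config and seed.

    ``events`` is a list of :class:`~ictalmea.events.EpileptiformEvent` (or an
    already-built DataFrame); ``metrics`` has one row per (source, epoch).
    Values survive a CSV round trip to at least 6 significant digits.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(events, pd.DataFrame):
        ev_df = events
    else:
        ev_df = pd.DataFrame(
            [
                {
                    "source": e.source,
                    "kind": e.kind,
                    "start_s": e.start_s,
                    "end_s": e.end_s,
                    "n_discharges": len(e.discharge_times_s),
                    "onset_class": e.onset_class,
                    "spatial_extent": e.spatial_extent,
                    "excluded": e.excluded,
                }
                for e in events
            ],
            columns=EVENT_COLUMNS,
        )
    events_path = out_dir / "events.csv"
    metrics_path = out_dir / "metrics.csv"
    ev_df.to_csv(events_path, index=False, float_format="%.9g")
    metrics.to_csv(metrics_path, index=False, float_format="%.9g")
    sidecar = {"config": config or {}, "seed": seed, "n_events": int(len(ev_df)), "n_metric_rows": int(len(metrics))}
    sidecar_path = out_dir / "run.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2, default=str))
    return {"events": events_path, "metrics": metrics_path, "sidecar": sidecar_path}


def layout_to_dict(layout: ElectrodeLayout) -> dict:
    d = asdict(layout)
    d["positions"] = [list(p) for p in layout.positions]
    return d
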